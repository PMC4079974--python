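"""Population-genomic statistics on the inbred panel.

Lines are read as single gametes throughout (the panel is inbred to
F ~ 0.99): a residual segregating call is treated as missing for that
line at that site. Nucleotide diversity uses the sample-size-corrected
per-site form

    pi = sum_sites [n/(n-1)] 2 p (1-p) / window_length,

with n the number of non-missing lines at the site; pi_indel is the same
statistic over indel sites, each indel counting once regardless of its
length. Divergence k counts per-bp fixed differences to the outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, spearmanr

from .exact import fisher_exact_2x2
from .outgroup import OutgroupAlignment
from .types import SEG, GenotypeMatrix, LinePanel

fishers_exact = fisher_exact_2x2  # canonical 2x2 exact test for this package


# ----------------------------------------------------------------------
# Segregating sites and inversion association
# ----------------------------------------------------------------------

def segregating_fraction(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Percent of non-missing variant calls that are segregating, per
    line x contig. Lines with zero non-missing calls on a contig get NaN
    and ``defined`` False."""
    rows = []
    contig_arr = matrix.contig_index()
    for contig in matrix.contigs:
        sub = matrix.calls[:, contig_arr == contig]
        non_missing = (sub >= 0).sum(axis=1)
        seg = (sub == SEG).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(non_missing > 0,
                           100.0 * seg / non_missing, np.nan)
        for lid, pc, nm in zip(matrix.line_ids, pct, non_missing):
            rows.append((lid, contig, float(pc), int(nm), nm > 0))
    return pd.DataFrame(
        rows, columns=["line_id", "contig", "percent_segregating",
                       "n_non_missing", "defined"])


def inversion_association(
    profiles: pd.DataFrame,
    panel: LinePanel,
    inversion_arms: dict[str, str],
    threshold: float = 9.0,
    autosomes: list[str] | None = None,
) -> tuple[np.ndarray, float]:
    """2x2 association between high segregating-site load and inversion
    heterokaryotypy over line x autosome-arm combinations.

    Rows: percent segregating {>= threshold, < threshold}; columns:
    {heterokaryotypic for any inversion on the arm, homokaryotypic}.
    Returns the table [[a, b], [c, d]] and the two-sided Fisher p.
    """
    arms = sorted({arm for arm in inversion_arms.values()})
    if autosomes is not None:
        arms = [a for a in arms if a in autosomes]
    table = np.zeros((2, 2), dtype=np.int64)
    for arm in arms:
        invs = [i for i, a in inversion_arms.items() if a == arm]
        sub = profiles[(profiles["contig"] == arm) & profiles["defined"]]
        for _, row in sub.iterrows():
            lid = row["line_id"]
            if lid not in panel.table.index:
                continue
            kar = [panel.karyotype(i).loc[lid] for i in invs]
            if any(pd.isna(k) for k in kar):
                continue
            het = any(int(k) == 1 for k in kar)
            hi = row["percent_segregating"] >= threshold
            table[0 if hi else 1, 0 if het else 1] += 1
    return table, fisher_exact_2x2(table)


# ----------------------------------------------------------------------
# Diversity and divergence in windows
# ----------------------------------------------------------------------

def _windows(length: int, size: int) -> list[tuple[int, int]]:
    return [(s, min(length, s + size)) for s in range(0, length, size)]


def _pi_contribution(h: np.ndarray) -> np.ndarray:
    """Per-site unbiased heterozygosity [n/(n-1)] 2p(1-p) from haploid
    alleles (NaN = missing); 0 where fewer than 2 calls."""
    n = np.sum(~np.isnan(h), axis=0)
    s = np.nansum(h, axis=0)
    contrib = np.zeros(h.shape[1])
    ok = n >= 2
    p = s[ok] / n[ok]
    contrib[ok] = (n[ok] / (n[ok] - 1.0)) * 2.0 * p * (1.0 - p)
    return contrib


def nucleotide_diversity(
    matrix: GenotypeMatrix,
    contig_lengths: dict[str, int],
    window_size: int = 100_000,
    variant_class: str = "snp",
) -> pd.DataFrame:
    """Windowed pi over SNP sites, indel sites (length-blind) or all.

    Windows with zero callable sites in the matrix are flagged
    ``defined=False`` with pi = 0 (nothing observed there).
    """
    if variant_class == "snp":
        cmask = np.array([v.is_snp for v in matrix.variants])
    elif variant_class == "indel":
        cmask = np.array([v.is_indel for v in matrix.variants])
    elif variant_class == "all":
        cmask = np.ones(matrix.n_variants, dtype=bool)
    else:
        raise ValueError(f"unknown variant class {variant_class!r}")
    h = matrix.haploid_alleles()
    contrib = _pi_contribution(h)
    pos = matrix.positions()
    contig_arr = matrix.contig_index()
    rows = []
    for contig, length in contig_lengths.items():
        in_c = (contig_arr == contig) & cmask
        for s, e in _windows(length, window_size):
            sel = in_c & (pos >= s) & (pos < e)
            n_sites = int(sel.sum())
            pi = float(contrib[sel].sum() / (e - s))
            rows.append((contig, s, e, pi, n_sites, n_sites > 0))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "pi",
                                       "n_sites", "defined"])


def divergence(
    matrix: GenotypeMatrix,
    outgroup: OutgroupAlignment,
    contig_lengths: dict[str, int],
    window_size: int = 100_000,
) -> pd.DataFrame:
    """Per-window fixed divergence k to the outgroup.

    A fixed difference is (a) a non-variant position where the aligned
    outgroup differs from the reference, or (b) a variant site at which
    every non-missing line carries the same allele and that allele is not
    the outgroup's. Sites with no outgroup allele are skipped.
    """
    h = matrix.haploid_alleles()
    pos = matrix.positions()
    contig_arr = matrix.contig_index()
    rows = []
    for contig, length in contig_lengths.items():
        in_c = contig_arr == contig
        for s, e in _windows(length, window_size):
            fixed = len(outgroup.substitution_positions(contig, s, e))
            sel = np.flatnonzero(in_c & (pos >= s) & (pos < e))
            for j in sel:
                og = outgroup.allele_at(matrix.variants[j].vid)
                if og is None:
                    continue
                col = h[:, j]
                called = col[~np.isnan(col)]
                if called.size == 0 or not (called == called[0]).all():
                    continue
                v = matrix.variants[j]
                panel_allele = v.ref if called[0] == 0 else v.alt
                if og in (v.ref, v.alt) and og != panel_allele:
                    fixed += 1
            rows.append((contig, s, e, fixed / (e - s), fixed))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "k",
                                       "n_fixed"])


# ----------------------------------------------------------------------
# Indel polarization and frequency spectra
# ----------------------------------------------------------------------

@dataclass
class PolarizedVariant:
    vid: str
    ancestral: str | None
    derived: str | None
    derived_type: str | None  # insertion | deletion | substitution
    derived_count: int
    n_called: int
    status: str  # polarized | unpolarized

    @property
    def derived_frequency(self) -> float:
        return self.derived_count / self.n_called if self.n_called else np.nan


def polarize_variants(
    matrix: GenotypeMatrix,
    outgroup: OutgroupAlignment,
    indels_only: bool = True,
) -> list[PolarizedVariant]:
    """Assign ancestral/derived status by exact match to the outgroup.

    The ancestral allele is the panel allele identical to the outgroup
    sequence over the variant footprint; when neither matches exactly the
    variant is unpolarized and excluded from derived-allele statistics.
    """
    h = matrix.haploid_alleles()
    out: list[PolarizedVariant] = []
    for j, v in enumerate(matrix.variants):
        if indels_only and not v.is_indel:
            continue
        og = outgroup.allele_at(v.vid)
        col = h[:, j]
        called = col[~np.isnan(col)]
        n_called = int(called.size)
        if og == v.ref:
            anc, der = v.ref, v.alt
            derived_count = int(called.sum())
        elif og == v.alt:
            anc, der = v.alt, v.ref
            derived_count = int(n_called - called.sum())
        else:
            out.append(PolarizedVariant(v.vid, None, None, None, 0,
                                        n_called, "unpolarized"))
            continue
        if len(der) < len(anc):
            dtype = "deletion"
        elif len(der) > len(anc):
            dtype = "insertion"
        else:
            dtype = "substitution"
        out.append(PolarizedVariant(v.vid, anc, der, dtype,
                                    derived_count, n_called, "polarized"))
    return out


def derived_deletion_share(polarized: list[PolarizedVariant]) -> float:
    """Share of polarized indels whose derived allele is a deletion."""
    dels = sum(1 for p in polarized if p.derived_type == "deletion")
    ins = sum(1 for p in polarized if p.derived_type == "insertion")
    if dels + ins == 0:
        return np.nan
    return dels / (dels + ins)


def frequency_spectrum(
    matrix: GenotypeMatrix,
    polarity: str = "minor",
    polarized: list[PolarizedVariant] | None = None,
    classes: dict[str, str] | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Allele-frequency histogram per functional class.

    ``polarity='minor'`` bins the minor allele frequency of every variant
    with a defined frequency; ``'derived'`` bins the derived allele
    frequency of polarized variants only. Classes default to the variant
    type. Counts over all classes sum to the number of classified
    variants.
    """
    edges = np.linspace(0.0, 0.5 if polarity == "minor" else 1.0,
                        n_bins + 1)
    if polarity == "minor":
        freqs = {v.vid: f for v, f in
                 zip(matrix.variants, matrix.minor_allele_freq())
                 if not np.isnan(f)}
    elif polarity == "derived":
        if polarized is None:
            polarized = []
        freqs = {p.vid: p.derived_frequency for p in polarized
                 if p.status == "polarized" and p.n_called > 0}
    else:
        raise ValueError("polarity must be 'minor' or 'derived'")
    if classes is None:
        classes = {v.vid: v.vtype for v in matrix.variants}
    labels = sorted(set(classes.values()))
    counts = pd.DataFrame(
        0, index=pd.IntervalIndex.from_breaks(edges, closed="left"),
        columns=labels)
    for vid, f in freqs.items():
        cls = classes.get(vid)
        if cls is None:
            continue
        b = min(np.searchsorted(edges, f, side="right") - 1, n_bins - 1)
        counts.iloc[b, counts.columns.get_loc(cls)] += 1
    return counts


# ----------------------------------------------------------------------
# Karyotype diversity
# ----------------------------------------------------------------------

def karyotype_diversity(
    matrix: GenotypeMatrix,
    panel: LinePanel,
    inversion: str,
    region: tuple[str, int, int],
) -> tuple[float, float, float]:
    """(pi_standard, pi_inverted, pi_between) over a genomic region.

    Within-karyotype pi restricts the windowed estimator to
    homokaryotypic lines of the class; between-karyotype diversity is
    the mean per-site pairwise difference over (standard, inverted) line
    pairs divided by the region length. Classes with < 2 lines yield NaN
    within-pi.
    """
    contig, start, end = region
    kar = panel.karyotype(inversion)
    std_ids = [l for l in matrix.line_ids if kar.get(l, None) == 0]
    inv_ids = [l for l in matrix.line_ids if kar.get(l, None) == 2]
    pos = matrix.positions()
    sel = ((matrix.contig_index() == contig) & (pos >= start)
           & (pos < end))
    sub = matrix.take_variants(sel)
    h = sub.haploid_alleles()
    idx = {l: i for i, l in enumerate(sub.line_ids)}
    length = end - start

    def within(ids: list[str]) -> float:
        if len(ids) < 2:
            return np.nan
        hh = h[[idx[l] for l in ids]]
        return float(_pi_contribution(hh).sum() / length)

    def between() -> float:
        if not std_ids or not inv_ids:
            return np.nan
        hs = h[[idx[l] for l in std_ids]]
        hi = h[[idx[l] for l in inv_ids]]
        with np.errstate(invalid="ignore"):
            ps = np.nanmean(hs, axis=0)
            pv = np.nanmean(hi, axis=0)
        d = ps * (1 - pv) + pv * (1 - ps)
        return float(np.nansum(d) / length)

    return within(std_ids), within(inv_ids), between()


def breakpoint_profile(
    matrix: GenotypeMatrix,
    panel: LinePanel,
    inversion: str,
    region: tuple[str, int, int],
    n_sub: int = 10,
) -> pd.DataFrame:
    """Within/between karyotype diversity in sub-windows along the
    inverted region (no smoothing)."""
    contig, start, end = region
    edges = np.linspace(start, end, n_sub + 1).astype(int)
    rows = []
    for s, e in zip(edges[:-1], edges[1:]):
        ps, pv, pb = karyotype_diversity(matrix, panel, inversion,
                                         (contig, int(s), int(e)))
        rows.append((contig, int(s), int(e), ps, pv, pb))
    return pd.DataFrame(rows, columns=["contig", "start", "end",
                                       "pi_standard", "pi_inverted",
                                       "pi_between"])


# ----------------------------------------------------------------------
# Variant clustering around high-frequency focal variants
# ----------------------------------------------------------------------

def variant_clustering(
    matrix: GenotypeMatrix,
    maf_band: tuple[float, float] = (0.40, 0.50),
    radius: int = 100,
    mac_classes: tuple[int, ...] = (1, 2, 5),
) -> pd.DataFrame:
    """Mean SNP count by distance from high-MAF focal variants,
    stratified by the SNP's minor-allele-count class and by whether it is
    counted among lines carrying vs not carrying the focal minor allele.

    A nearby SNP is counted in a stratum when its minor allele is present
    among the stratum's lines. Distances run 1..radius bp on either side
    (folded).
    """
    maf = matrix.minor_allele_freq()
    focal_idx = np.flatnonzero((maf >= maf_band[0]) & (maf <= maf_band[1]))
    if focal_idx.size == 0:
        raise ValueError("no focal variants in the MAF band")
    snp_mask = np.array([v.is_snp for v in matrix.variants])
    h = matrix.haploid_alleles()
    pos = matrix.positions()
    contig_arr = matrix.contig_index()
    p_alt = matrix.allele_freq()

    edges = list(mac_classes)
    def mac_label(mac: int) -> str:
        for e in edges:
            if mac <= e:
                return f"<={e}"
        return f">{edges[-1]}"

    labels = [f"<={e}" for e in edges] + [f">{edges[-1]}"]
    acc = {(lab, stratum): np.zeros(radius)
           for lab in labels for stratum in ("carrier", "noncarrier")}
    for f in focal_idx:
        col = h[:, f]
        minor_allele = 1.0 if p_alt[f] <= 0.5 else 0.0
        carriers = col == minor_allele
        noncarriers = col == 1.0 - minor_allele
        near = np.flatnonzero(
            (contig_arr == contig_arr[f]) & snp_mask
            & (np.abs(pos - pos[f]) >= 1) & (np.abs(pos - pos[f]) <= radius))
        for j in near:
            d = int(abs(pos[j] - pos[f]))
            cj = h[:, j]
            minor_j = 1.0 if p_alt[j] <= 0.5 else 0.0
            mac = int(np.nansum(cj == minor_j))
            if mac == 0:
                continue
            lab = mac_label(mac)
            if np.any(cj[carriers] == minor_j):
                acc[(lab, "carrier")][d - 1] += 1
            if noncarriers.any() and np.any(cj[noncarriers] == minor_j):
                acc[(lab, "noncarrier")][d - 1] += 1
    rows = []
    for (lab, stratum), counts in acc.items():
        for d in range(radius):
            rows.append((d + 1, lab, stratum,
                         counts[d] / focal_idx.size))
    return pd.DataFrame(rows, columns=["distance", "mac_class",
                                       "stratum", "mean_count"])


# ----------------------------------------------------------------------
# Recombination correlation and chromatin enrichment
# ----------------------------------------------------------------------

def recombination_correlation(
    diversity: pd.DataFrame, recmap: pd.DataFrame
) -> tuple[float, float]:
    """Spearman rank correlation between windowed diversity and the
    recombination rate, on windows matched by (contig, start)."""
    merged = diversity.merge(recmap, on=["contig", "start"],
                             suffixes=("", "_rec"))
    if len(merged) < 3:
        raise ValueError("need at least 3 matched windows")
    x = merged["pi"].to_numpy()
    y = merged["cm_mb"].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


def chromatin_enrichment(
    matrix: GenotypeMatrix,
    domains: pd.DataFrame,
    contig_lengths: dict[str, int],
    variant_class: str = "all",
) -> pd.DataFrame:
    """Fold enrichment of variants per chromatin domain class.

    fold = (variants in domain / domain bp) / (variants total / total
    bp); p is a two-sided binomial test of the domain's count against
    expectation proportional to its length.
    """
    if variant_class == "snp":
        cmask = np.array([v.is_snp for v in matrix.variants])
    elif variant_class == "indel":
        cmask = np.array([v.is_indel for v in matrix.variants])
    else:
        cmask = np.ones(matrix.n_variants, dtype=bool)
    pos = matrix.positions()[cmask]
    contig_arr = matrix.contig_index()[cmask]
    total_bp = sum(contig_lengths.values())
    total_n = int(cmask.sum())
    rows = []
    for dclass, grp in domains.groupby("domain"):
        bp = int((grp["end"] - grp["start"]).sum())
        if bp == 0:
            continue
        n_in = 0
        for _, r in grp.iterrows():
            n_in += int(np.sum((contig_arr == r["contig"])
                               & (pos >= r["start"]) & (pos < r["end"])))
        expected = total_n * bp / total_bp
        fold = (n_in / bp) / (total_n / total_bp) if total_n else np.nan
        p = binomtest(n_in, total_n, bp / total_bp).pvalue if total_n \
            else np.nan
        rows.append((dclass, bp, n_in, expected, fold, p))
    return pd.DataFrame(rows, columns=["domain", "bp", "n_variants",
                                       "expected", "fold", "p"])
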