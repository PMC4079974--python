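"""Cross-caller variant integration and freeze-quality filtering.

The integration design: candidate variants from several callers are
normalized (left-aligned), merged into a consensus list, and every line
is re-genotyped from its supporting/opposing read counts with a binomial
posterior model. Freeze filters then drop low-quality sites and censor
low-quality genotype calls. Haplotype bins group nearby non-SNP variants
so that alternative alignments of the same event are considered together.

The genotype-from-counts model is a documented stand-in for a full
population genotyping likelihood: per line, supporting reads are
Binomial(depth, p) with p = e (hom ref), 1 - e (hom alt) or 1/2
(segregating), where e is the sequencing error rate, combined with a
uniform prior over the three states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exact import fisher_exact_2x2
from .simulate import CallerCalls
from .types import (
    HOM_ALT,
    HOM_REF,
    MISSING,
    SEG,
    GenotypeMatrix,
    VariantRecord,
)

PHRED_CAP = 9999.0


# ----------------------------------------------------------------------
# Haplotype bins
# ----------------------------------------------------------------------

@dataclass
class HaplotypeBin:
    contig: str
    start: int
    end: int
    member_ids: list[str] = field(default_factory=list)
    flank: int = 110


def build_haplotype_bins(
    variants: list[VariantRecord], flank: int = 110
) -> list[HaplotypeBin]:
    """Group non-SNP variants into bins separated by >= ``flank`` bp of
    non-SNP-free sequence; each bin spans its members extended by the
    flank on both sides (clipped at the contig start)."""
    non_snp = [v for v in variants if not v.is_snp]
    for a, b in zip(non_snp, non_snp[1:]):
        if a.contig == b.contig and b.pos < a.pos:
            raise ValueError("variants must be sorted by contig, position")
    bins: list[HaplotypeBin] = []
    last_member_end: int = 0
    for v in non_snp:
        same_bin = (bins and bins[-1].contig == v.contig
                    and v.pos - last_member_end < flank)
        if same_bin:
            b = bins[-1]
            b.end = max(b.end, v.end + flank)
            b.member_ids.append(v.vid)
        else:
            bins.append(HaplotypeBin(v.contig, max(0, v.pos - flank),
                                     v.end + flank, [v.vid], flank))
        last_member_end = max(last_member_end, v.end) if same_bin else v.end
    return bins


# ----------------------------------------------------------------------
# Normalization and consensus
# ----------------------------------------------------------------------

def left_align(seq: str, pos: int, ref: str, alt: str
               ) -> tuple[int, str, str]:
    """Left-align and trim a variant against its contig sequence.

    Alternative right-shifted representations of one indel collapse to a
    single canonical (pos, ref, alt). If ``ref`` disagrees with the
    sequence the record is returned untouched (it cannot be normalized).
    """
    if seq[pos: pos + len(ref)] != ref:
        return pos, ref, alt
    changed = True
    while changed:
        changed = False
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                if pos > 0:
                    base = seq[pos - 1]
                    ref, alt, pos = base + ref[:-1], base + alt[:-1], pos - 1
                    changed = True
            else:
                ref, alt = ref[:-1], alt[:-1]
                changed = True
        if len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
            changed = True
    return pos, ref, alt


@dataclass
class ConsensusResult:
    variants: list[VariantRecord]
    caller_support: np.ndarray          # callers reporting each variant
    support: np.ndarray                 # summed reads, (n_lines, k)
    oppose: np.ndarray
    flagged: list[str] = field(default_factory=list)


def consensus_variants(
    caller_lists: list[CallerCalls],
    n_lines: int,
    reference: dict[str, str] | None = None,
) -> ConsensusResult:
    """Union of caller lists keyed by normalized (contig, pos, ref, alt).

    Read counts are summed over the callers reporting a variant —
    the stand-in for re-genotyping each line from the combined data.
    Records at one position with incompatible reference alleles are kept
    but flagged, never merged.
    """
    merged: dict[tuple, dict] = {}
    for cl in caller_lists:
        for j, v in enumerate(cl.variants):
            pos, ref, alt = v.pos, v.ref, v.alt
            if reference is not None:
                pos, ref, alt = left_align(reference[v.contig], pos, ref, alt)
            key = (v.contig, pos, ref, alt)
            ent = merged.get(key)
            if ent is None:
                ent = merged[key] = {
                    "record": VariantRecord(v.contig, pos, ref, alt,
                                            VariantRecord.classify(ref, alt),
                                            ancestral=v.ancestral),
                    "callers": 0,
                    "support": np.zeros(n_lines, dtype=np.int64),
                    "oppose": np.zeros(n_lines, dtype=np.int64),
                }
            ent["callers"] += 1
            ent["support"] += cl.support[:, j]
            ent["oppose"] += cl.oppose[:, j]

    keys = sorted(merged, key=lambda k: (k[0], k[1], k[2], k[3]))
    variants = [merged[k]["record"] for k in keys]
    callers = np.array([merged[k]["callers"] for k in keys])
    support = (np.stack([merged[k]["support"] for k in keys], axis=1)
               if keys else np.zeros((n_lines, 0), dtype=np.int64))
    oppose = (np.stack([merged[k]["oppose"] for k in keys], axis=1)
              if keys else np.zeros((n_lines, 0), dtype=np.int64))

    flagged: list[str] = []
    by_pos: dict[tuple[str, int], list[VariantRecord]] = {}
    for v in variants:
        by_pos.setdefault((v.contig, v.pos), []).append(v)
    for group in by_pos.values():
        refs = {v.ref for v in group}
        if len(refs) > 1:
            shortest = min(refs, key=len)
            if not all(r.startswith(shortest) for r in refs):
                flagged.extend(v.vid for v in group)
    return ConsensusResult(variants, callers, support, oppose, flagged)


# ----------------------------------------------------------------------
# Genotype-from-counts
# ----------------------------------------------------------------------

@dataclass
class GenotypeCall:
    supporting_reads: int
    opposing_reads: int
    call: int
    genotype_quality: float
    posteriors: np.ndarray  # P(hom_ref), P(seg), P(hom_alt)

    @property
    def depth(self) -> int:
        return self.supporting_reads + self.opposing_reads


def _count_posteriors(support: np.ndarray, oppose: np.ndarray,
                      error: float) -> np.ndarray:
    """Posterior over (hom_ref, seg, hom_alt); shape (..., 3)."""
    s = np.asarray(support, dtype=float)
    o = np.asarray(oppose, dtype=float)
    ps = np.array([error, 0.5, 1.0 - error])
    loglik = (s[..., None] * np.log(ps)
              + o[..., None] * np.log1p(-ps))
    loglik -= loglik.max(axis=-1, keepdims=True)
    lik = np.exp(loglik)
    return lik / lik.sum(axis=-1, keepdims=True)


def genotype_from_counts(support: int, oppose: int,
                         sequencing_error: float = 0.01) -> GenotypeCall:
    """Call one line at one variant from its read counts."""
    if not 0.0 < sequencing_error < 0.5:
        raise ValueError("sequencing_error must lie in (0, 0.5)")
    if support < 0 or oppose < 0:
        raise ValueError("read counts must be nonnegative")
    if support + oppose == 0:
        return GenotypeCall(0, 0, MISSING, 0.0,
                            np.full(3, 1.0 / 3.0))
    post = _count_posteriors(np.array(support), np.array(oppose),
                             sequencing_error)
    best = int(np.argmax(post))
    call = (HOM_REF, SEG, HOM_ALT)[best]
    gq = float(min(PHRED_CAP,
                   -10.0 * np.log10(max(1.0 - post[best], 1e-300))))
    return GenotypeCall(support, oppose, call, gq, post)


def genotype_matrix_from_counts(
    consensus: ConsensusResult,
    line_ids: list[str],
    sequencing_error: float = 0.01,
) -> GenotypeMatrix:
    """Vectorized re-genotyping of every line at every consensus variant.

    Site quality is the phred-scaled evidence against 'no variant
    anywhere': the sum over lines of -10 log10 P(hom ref | counts),
    restricted to lines with coverage, capped at 9999.
    """
    if not 0.0 < sequencing_error < 0.5:
        raise ValueError("sequencing_error must lie in (0, 0.5)")
    s, o = consensus.support, consensus.oppose
    depth = s + o
    post = _count_posteriors(s, o, sequencing_error)
    best = post.argmax(axis=-1)
    calls = np.select(
        [best == 0, best == 1, best == 2],
        [HOM_REF, SEG, HOM_ALT],
    ).astype(np.int8)
    calls[depth == 0] = MISSING
    pmax = np.take_along_axis(post, best[..., None], axis=-1)[..., 0]
    gq = np.minimum(PHRED_CAP,
                    -10.0 * np.log10(np.maximum(1.0 - pmax, 1e-300)))
    gq[depth == 0] = 0.0

    evidence = -10.0 * np.log10(np.maximum(post[..., 0], 1e-300))
    evidence[depth == 0] = 0.0
    site_qual = np.minimum(PHRED_CAP, evidence.sum(axis=0))
    variants = []
    for v, q in zip(consensus.variants, site_qual):
        v.site_quality = float(q)
        variants.append(v)
    return GenotypeMatrix(line_ids, variants, calls, depth=depth, gq=gq)


# ----------------------------------------------------------------------
# Freeze filters
# ----------------------------------------------------------------------

@dataclass
class FilterPolicy:
    min_site_quality: float = 500.0
    min_depth: int = 1
    min_genotype_quality: float = 20.0
    biallelic_only: bool = True
    nonoverlapping_only: bool = True

    def __post_init__(self) -> None:
        if (self.min_site_quality < 0 or self.min_depth < 0
                or self.min_genotype_quality < 0):
            raise ValueError("filter thresholds must be >= 0")


def apply_freeze_filters(
    matrix: GenotypeMatrix, policy: FilterPolicy | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop sites failing site-level criteria; censor calls failing
    genotype-level criteria. Returns the filtered matrix and a report of
    how many sites/calls each criterion removed. Idempotent."""
    policy = policy or FilterPolicy()
    n_var = matrix.n_variants
    keep = np.ones(n_var, dtype=bool)
    report_rows = []

    qual = np.array([v.site_quality for v in matrix.variants])
    low_q = qual < policy.min_site_quality
    report_rows.append(("site_quality", int(low_q.sum())))
    keep &= ~low_q

    if policy.biallelic_only:
        seen: dict[tuple[str, int], int] = {}
        for v in matrix.variants:
            seen[(v.contig, v.pos)] = seen.get((v.contig, v.pos), 0) + 1
        multi = np.array([seen[(v.contig, v.pos)] > 1
                          for v in matrix.variants])
        report_rows.append(("multiallelic", int((multi & keep).sum())))
        keep &= ~multi

    if policy.nonoverlapping_only:
        overlap = np.zeros(n_var, dtype=bool)
        idx = [i for i in range(n_var) if keep[i]]
        idx.sort(key=lambda i: (matrix.variants[i].contig,
                                matrix.variants[i].pos))
        for i, j in zip(idx, idx[1:]):
            a, b = matrix.variants[i], matrix.variants[j]
            if a.contig == b.contig and b.pos < a.end and b.pos > a.pos:
                overlap[i] = overlap[j] = True
        report_rows.append(("overlapping", int(overlap.sum())))
        keep &= ~overlap

    out = matrix.take_variants(keep)
    calls = out.calls.copy()
    censored = 0
    if out.depth is not None:
        bad = (out.depth < policy.min_depth) & (calls != MISSING)
        censored += int(bad.sum())
        calls[bad] = MISSING
    if out.gq is not None:
        bad = (out.gq < policy.min_genotype_quality) & (calls != MISSING)
        censored += int(bad.sum())
        calls[bad] = MISSING
    report_rows.append(("genotype_censored", censored))
    out = GenotypeMatrix(out.line_ids, out.variants, calls,
                         out.depth, out.gq)
    report = pd.DataFrame(report_rows, columns=["criterion", "n_removed"])
    return out, report


# ----------------------------------------------------------------------
# Validation concordance
# ----------------------------------------------------------------------

def concordance_test(
    counts_a: tuple[int, int],
    counts_b: tuple[int, int],
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Fisher's exact test of allele-support concordance between two
    technologies; discordant iff p < alpha (nominal threshold)."""
    table = np.array([counts_a, counts_b])
    if table.sum() == 0:
        return 1.0, True
    p = fisher_exact_2x2(table)
    return p, bool(p >= alpha)


def validation_summary(concordant: int, total: int) -> float:
    """Percent concordance, to two decimals (e.g. 1458/1463 -> 99.66)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= concordant <= total:
        raise ValueError("concordant must lie in [0, total]")
    return round(100.0 * concordant / total, 2)
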