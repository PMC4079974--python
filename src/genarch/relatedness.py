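"""Genomic relationship matrices, LD pruning and principal components.

The realized relationship matrix follows the VanRaden form
G = Z Z' / (2 sum_k p_k (1 - p_k)) with Z = M - 2P, where M codes inbred
lines as 0/2 copies of the alternate allele (residual segregating calls
are missing and mean-imputed per variant) and P carries the allele
frequencies. G is normalized by the mean of its diagonal. Tracy-Widom
significance of leading eigenvalues uses the Patterson moments
normalization with a shifted-gamma approximation to the TW1 law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .types import GenotypeMatrix, RelationshipMatrix

# Shifted-gamma approximation to the beta=1 Tracy-Widom law
# (k, theta, shift); accurate to ~1e-4 over the support of interest.
_TW1_K = 46.44604884387787
_TW1_THETA = 0.18605402228279955
_TW1_ALPHA = 9.848007781128567


def tracy_widom_sf(x: np.ndarray | float) -> np.ndarray | float:
    """Upper-tail probability of the TW1 distribution."""
    return gamma_dist.sf(np.asarray(x) + _TW1_ALPHA, _TW1_K,
                         scale=_TW1_THETA)


# ----------------------------------------------------------------------
# Genotype coding
# ----------------------------------------------------------------------

def _dosage_imputed(matrix: GenotypeMatrix
                    ) -> tuple[np.ndarray, np.ndarray]:
    """0/2 dosage of the alt allele; segregating/missing mean-imputed
    per variant. Returns (dosage, allele frequency p)."""
    h = matrix.haploid_alleles()           # 0/1/NaN
    m = 2.0 * h
    p = matrix.allele_freq()
    col_mean = 2.0 * p
    nan_mask = np.isnan(m)
    m[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    return m, p


def compute_grm(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.8,
    contig: str | None = None,
    normalize: bool = True,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from common variants.

    Variants are filtered to MAF >= ``maf_min`` and call rate >
    ``call_rate_min`` (optionally restricted to one contig); the matrix
    is normalized by the mean of its diagonal.
    """
    keep = (matrix.minor_allele_freq() >= maf_min) \
        & (matrix.call_rate() > call_rate_min)
    if contig is not None:
        keep &= matrix.contig_index() == contig
    if not keep.any():
        raise ValueError("no variants pass the GRM filters")
    sub = matrix.take_variants(keep)
    m, p = _dosage_imputed(sub)
    z = m - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    g = z @ z.T / denom
    g = (g + g.T) / 2.0
    source = (f"maf>={maf_min},call_rate>{call_rate_min}"
              + (f",contig={contig}" if contig else ""))
    if normalize:
        g = g / np.mean(np.diag(g))
        return RelationshipMatrix(sub.line_ids, g, "mean_diagonal", source)
    return RelationshipMatrix(sub.line_ids, g, "raw", source)


def relatedness_summary(
    grm: RelationshipMatrix,
    thresholds: tuple[float, ...] = (0.05, 0.5),
) -> pd.DataFrame:
    """Counts and percentages of unordered line pairs whose relatedness
    exceeds each threshold; total pairs = C(n, 2)."""
    n = grm.n_lines
    iu = np.triu_indices(n, k=1)
    vals = grm.values[iu]
    total = n * (n - 1) // 2
    rows = []
    for t in thresholds:
        cnt = int(np.sum(vals > t))
        rows.append((t, cnt, total, round(100.0 * cnt / total, 2)))
    return pd.DataFrame(rows, columns=["threshold", "n_pairs",
                                       "total_pairs", "percent"])


def pair_histogram(grm: RelationshipMatrix, bins: int = 50
                   ) -> pd.DataFrame:
    iu = np.triu_indices(grm.n_lines, k=1)
    counts, edges = np.histogram(grm.values[iu], bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------

def _r2_matrix(h: np.ndarray) -> np.ndarray:
    """Pairwise r^2 between variant columns (mean-imputed for speed)."""
    x = h.copy()
    mu = np.nanmean(x, axis=0)
    nan = np.isnan(x)
    x[nan] = np.take(mu, np.where(nan)[1])
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / x.shape[0]
    r = c / np.outer(sd, sd)
    return r ** 2


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 500,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy LD pruning: in each moving window of ``window`` retained
    variants, drop the later member of the worst remaining pair until
    every retained pair has r^2 < ``r2_max``. Windows slide over the
    *retained* list and passes repeat to a fixed point, so any
    ``window`` consecutive survivors satisfy the constraint. Returns
    retained variant indices (position order; deterministic)."""
    h = matrix.haploid_alleles()
    n_var = matrix.n_variants
    keep = np.ones(n_var, dtype=bool)
    contig_arr = matrix.contig_index()
    step = max(1, window // 2)
    for contig in matrix.contigs:
        cmask = contig_arr == contig
        for _pass in range(50):
            idx = np.flatnonzero(cmask & keep)
            dropped = False
            for w0 in range(0, max(1, len(idx) - 1), step):
                wi = idx[w0: w0 + window]
                wi = wi[keep[wi]]
                if len(wi) < 2:
                    continue
                r2 = _r2_matrix(h[:, wi])
                np.fill_diagonal(r2, 0.0)
                r2 = np.nan_to_num(r2)
                active = np.ones(len(wi), dtype=bool)
                while True:
                    sub = np.where(np.outer(active, active), r2, 0.0)
                    worst = np.unravel_index(np.argmax(sub), sub.shape)
                    if sub[worst] < r2_max:
                        break
                    active[max(worst)] = False  # drop the later variant
                if (~active).any():
                    keep[wi[~active]] = False
                    dropped = True
            if not dropped:
                break
    return np.flatnonzero(keep)


# ----------------------------------------------------------------------
# PCA with Tracy-Widom significance
# ----------------------------------------------------------------------

@dataclass
class PcaResult:
    line_ids: list[str]
    components: np.ndarray   # (n_lines, n_pc)
    eigenvalues: np.ndarray
    twstats: np.ndarray
    pvalues: np.ndarray
    excluded_regions: list[tuple[str, int, int]] = field(
        default_factory=list)
    n_variants: int = 0


def pca(
    matrix: GenotypeMatrix,
    exclude_regions: list[tuple[str, int, int]] | None = None,
    n_components: int = 10,
) -> PcaResult:
    """Principal components of standardized genotypes.

    Each variant is centered at 2p and scaled by sqrt(2p(1-p)); the
    line x line covariance is eigendecomposed and each leading eigenvalue
    receives a Tracy-Widom statistic under the Patterson moments
    normalization. ``exclude_regions`` drops variants inside the given
    (contig, start, end) intervals — used to remove large inversions.
    """
    keep = np.ones(matrix.n_variants, dtype=bool)
    if exclude_regions:
        pos = matrix.positions()
        contig_arr = matrix.contig_index()
        for contig, s, e in exclude_regions:
            keep &= ~((contig_arr == contig) & (pos >= s) & (pos < e))
    sub = matrix.take_variants(keep)
    m, p = _dosage_imputed(sub)
    ok = (p > 0) & (p < 1)
    m, p = m[:, ok], p[ok]
    n, k = m.shape
    x = (m - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    cov = x @ x.T / k
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_components = min(n_components, n - 1)

    # Patterson moments normalization for successive eigenvalues: the
    # i-th test treats the remaining spectrum as a fresh Wishart problem
    # with n - i samples and an effective marker count estimated from
    # the spread of the remaining eigenvalues.
    tws, pvals = [], []
    lam = np.maximum(evals[: n - 1], 0.0)  # last eigenvalue sums to zero
    for i in range(n_components):
        tail = lam[i:]
        ni = n - i
        s1, s2 = tail.sum(), (tail ** 2).sum()
        denom = (ni - 1) * s2 - s1 ** 2
        if s2 <= 0 or len(tail) < 3 or denom <= 0:
            tws.append(np.nan)
            pvals.append(np.nan)
            continue
        n_eff = (ni + 1) * s1 ** 2 / denom
        ell = (ni - 1) * tail[0] / s1
        sq = np.sqrt(n_eff - 1) + np.sqrt(ni - 1)
        mu = sq ** 2 / n_eff
        sigma = (sq / n_eff) * (1.0 / np.sqrt(n_eff - 1)
                                + 1.0 / np.sqrt(ni - 1)) ** (1.0 / 3.0)
        tw = (ell - mu) / sigma
        tws.append(float(tw))
        pvals.append(float(tracy_widom_sf(tw)))

    comps = evecs[:, :n_components] * np.sqrt(
        np.maximum(evals[:n_components], 0.0))
    return PcaResult(sub.line_ids, comps, evals[:n_components],
                     np.array(tws), np.array(pvals),
                     list(exclude_regions or []), k)


def n_significant_components(result: PcaResult, alpha: float = 0.01
                             ) -> int:
    """Leading components with Tracy-Widom p below alpha (contiguous
    from the top, the usual stopping rule)."""
    n = 0
    for p in result.pvalues:
        if np.isnan(p) or p >= alpha:
            break
        n += 1
    return n
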