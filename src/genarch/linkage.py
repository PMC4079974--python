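"""Linkage disequilibrium on the inbred panel.

Lines are haploid gametes for LD purposes (residual segregating calls
become missing; pairs of sites use pairwise-complete lines). For two
loci with alt-allele frequencies pA, pB and joint alt-alt frequency pAB:

    D  = pAB - pA pB
    r2 = D^2 / (pA (1-pA) pB (1-pB))
    D' = |D| / Dmax,  Dmax = min(pA(1-pB), (1-pA)pB)        if D > 0
                      Dmax = min(pA pB, (1-pA)(1-pB))       if D < 0

r^2 equals the squared Pearson correlation of the 0/1 allele vectors.
Distance between variants is measured between their start coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix


@dataclass
class LdPair:
    vid_a: str
    vid_b: str
    distance: int
    D: float
    D_prime: float
    r2: float
    n_lines: int


class MonomorphicError(ValueError):
    """One of the two sites is monomorphic among the complete lines."""


def ld_pair_from_alleles(a: np.ndarray, b: np.ndarray
                         ) -> tuple[float, float, float, int]:
    """(D, D', r2, n) from two haploid 0/1 allele vectors (NaN missing)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    n = int(ok.sum())
    if n < 2:
        raise MonomorphicError("fewer than 2 pairwise-complete lines")
    a, b = a[ok], b[ok]
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicError("monomorphic site among complete lines")
    pab = np.mean(a * b)
    d = pab - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        dmax = np.nan
    dprime = 0.0 if d == 0 else abs(d) / dmax
    return float(d), float(dprime), float(r2), n


def ld_pair(matrix: GenotypeMatrix, i: int, j: int) -> LdPair:
    """LD between two variants of the matrix by column index."""
    h = matrix.haploid_alleles()
    d, dprime, r2, n = ld_pair_from_alleles(h[:, i], h[:, j])
    va, vb = matrix.variants[i], matrix.variants[j]
    dist = abs(va.pos - vb.pos) if va.contig == vb.contig else -1
    return LdPair(va.vid, vb.vid, dist, d, dprime, r2, n)


# ----------------------------------------------------------------------
# Pair enumeration helpers
# ----------------------------------------------------------------------

def _complete_r2_columns(h: np.ndarray, ii: np.ndarray, jj: np.ndarray,
                         chunk: int = 100_000) -> np.ndarray:
    """Pairwise-complete r^2 for index pairs (ii, jj); NaN where either
    site is monomorphic among the complete lines. Vectorized in chunks
    to bound memory."""
    out = np.full(len(ii), np.nan)
    for lo in range(0, len(ii), chunk):
        hi = min(len(ii), lo + chunk)
        a = h[:, ii[lo:hi]]
        b = h[:, jj[lo:hi]]
        w = (~np.isnan(a) & ~np.isnan(b)).astype(float)
        a0 = np.nan_to_num(a)
        b0 = np.nan_to_num(b)
        n = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = (a0 * w).sum(axis=0) / n
            pb = (b0 * w).sum(axis=0) / n
            pab = (a0 * b0 * w).sum(axis=0) / n
            d = pab - pa * pb
            denom = pa * (1 - pa) * pb * (1 - pb)
            r2 = d * d / denom
        bad = (n < 2) | ~np.isfinite(r2)
        r2[bad] = np.nan
        out[lo:hi] = r2
    return out


def _intra_arm_pairs(pos: np.ndarray, max_distance: int,
                     cap: int | None, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """All index pairs within max_distance, subsampled to ``cap``."""
    ii, jj = [], []
    n = len(pos)
    hi = 0
    for i in range(n):
        while hi < n and pos[hi] - pos[i] <= max_distance:
            hi += 1
        if hi > i + 1:
            ii.append(np.full(hi - i - 1, i))
            jj.append(np.arange(i + 1, hi))
    if not ii:
        return np.empty(0, int), np.empty(0, int)
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    if cap is not None and len(ii) > cap:
        sel = rng.choice(len(ii), size=cap, replace=False)
        ii, jj = ii[sel], jj[sel]
    return ii, jj


def ld_decay(
    matrix: GenotypeMatrix,
    max_distance: int = 10_000,
    n_bins: int = 20,
    maf_min: float = 0.05,
    pair_cap: int = 2_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean r^2 per distance bin per chromosome arm.

    Intra-arm pairs up to ``max_distance`` apart (subsampled to
    ``pair_cap`` per arm) are binned by distance; empty bins are
    omitted.
    """
    rng = np.random.default_rng(seed)
    keep = matrix.minor_allele_freq() >= maf_min
    sub = matrix.take_variants(keep)
    h = sub.haploid_alleles()
    pos = sub.positions()
    contig_arr = sub.contig_index()
    edges = np.linspace(0, max_distance, n_bins + 1)
    rows = []
    for contig in sub.contigs:
        cidx = np.flatnonzero(contig_arr == contig)
        if len(cidx) < 2:
            continue
        order = np.argsort(pos[cidx], kind="stable")
        cidx = cidx[order]
        cpos = pos[cidx]
        ii, jj = _intra_arm_pairs(cpos, max_distance, pair_cap, rng)
        if len(ii) == 0:
            continue
        r2 = _complete_r2_columns(h, cidx[ii], cidx[jj])
        dist = cpos[jj] - cpos[ii]
        which = np.clip(np.searchsorted(edges, dist, side="right") - 1,
                        0, n_bins - 1)
        for b in range(n_bins):
            sel = (which == b) & ~np.isnan(r2)
            if sel.sum() == 0:
                continue
            rows.append((contig, float(edges[b]), float(edges[b + 1]),
                         float(np.mean(r2[sel])), int(sel.sum())))
    return pd.DataFrame(rows, columns=["contig", "bin_start", "bin_end",
                                       "mean_r2", "n_pairs"])


def ld_windows(
    matrix: GenotypeMatrix,
    contig_lengths: dict[str, int],
    pair_min_bp: int = 50,
    pair_max_bp: int = 150,
    window: int = 1_000_000,
    step: int = 100_000,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Sliding-window track of mean r^2 between nearby variant pairs.

    Pairs 50-150 bp apart are assigned to every window containing their
    midpoint; windows of size ``window`` advance by ``step``. Windows
    with no qualifying pair report NaN.
    """
    keep = matrix.minor_allele_freq() >= maf_min
    sub = matrix.take_variants(keep)
    h = sub.haploid_alleles()
    pos = sub.positions()
    contig_arr = sub.contig_index()
    rows = []
    for contig, length in contig_lengths.items():
        cidx = np.flatnonzero(contig_arr == contig)
        order = np.argsort(pos[cidx], kind="stable")
        cidx = cidx[order]
        cpos = pos[cidx]
        ii, jj = _intra_arm_pairs(cpos, pair_max_bp, None,
                                  np.random.default_rng(0))
        if len(ii):
            dist = cpos[jj] - cpos[ii]
            sel = dist >= pair_min_bp
            ii, jj = ii[sel], jj[sel]
        if len(ii):
            r2 = _complete_r2_columns(h, cidx[ii], cidx[jj])
            mid = (cpos[ii] + cpos[jj]) / 2.0
        starts = range(0, length, step)
        for s in starts:
            e = min(length, s + window)
            if len(ii):
                in_w = (mid >= s) & (mid < e) & ~np.isnan(r2)
                val = float(np.mean(r2[in_w])) if in_w.any() else np.nan
                n_pairs = int(in_w.sum())
            else:
                val, n_pairs = np.nan, 0
            rows.append((contig, s, e, val, n_pairs))
    return pd.DataFrame(rows, columns=["contig", "start", "end",
                                       "mean_r2", "n_pairs"])


def high_ld_counts(
    matrix: GenotypeMatrix,
    focal_mac_values: tuple[int, ...] = (1, 2, 3, 5, 10),
    r2_min: float = 0.95,
    local_radius: int = 1_000,
    n_focal: int = 1000,
    seed: int = 0,
    inversion_regions: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Mean number of partners in strong LD with random focal variants.

    For each focal minor-allele count, up to ``n_focal`` focal variants
    are sampled without replacement; for each, partners with r^2 >
    ``r2_min`` are counted genome-wide and locally (< ``local_radius``
    bp), excluding the focal variant itself. When ``inversion_regions``
    is given, focal variants are additionally stratified by membership.
    """
    rng = np.random.default_rng(seed)
    h = matrix.haploid_alleles()
    pos = matrix.positions()
    contig_arr = matrix.contig_index()
    p = matrix.allele_freq()
    minor_is_alt = p <= 0.5
    mac = np.where(minor_is_alt,
                   np.nansum(h == 1, axis=0),
                   np.nansum(h == 0, axis=0)).astype(int)
    poly = ~np.isnan(p) & (p > 0) & (p < 1)

    # precompute standardized matrix for fast r^2 via correlation
    x = h.copy()
    mu = np.nanmean(x, axis=0)
    nan = np.isnan(x)
    x[nan] = np.take(mu, np.where(nan)[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf
    x /= sd

    inv_member = np.zeros(matrix.n_variants, dtype=bool)
    for contig, s, e in inversion_regions or []:
        inv_member |= (contig_arr == contig) & (pos >= s) & (pos < e)

    rows = []
    strata = ([("all", np.ones(matrix.n_variants, bool))]
              if inversion_regions is None
              else [("inside_inversion", inv_member),
                    ("outside_inversion", ~inv_member)])
    n_lines = matrix.n_lines
    for stratum, smask in strata:
        for target_mac in focal_mac_values:
            cand = np.flatnonzero(poly & smask & (mac == target_mac))
            if cand.size == 0:
                continue
            take = min(n_focal, cand.size)
            focal = rng.choice(cand, size=take, replace=False)
            r2_all = (x[:, focal].T @ x) / n_lines
            r2_all = r2_all ** 2
            strong = (r2_all > r2_min) & poly[None, :]
            strong[np.arange(take), focal] = False
            genome = strong.sum(axis=1)
            local = np.zeros(take)
            for k, f in enumerate(focal):
                near = ((contig_arr == contig_arr[f])
                        & (np.abs(pos - pos[f]) < local_radius))
                local[k] = np.sum(strong[k] & near)
            rows.append((stratum, target_mac, take,
                         float(genome.mean()), float(local.mean())))
    return pd.DataFrame(rows, columns=["stratum", "mac", "n_focal",
                                       "mean_genomewide", "mean_local"])
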