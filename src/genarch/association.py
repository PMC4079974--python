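"""Association mapping on line means.

Two-stage design: line means are first adjusted for Wolbachia infection
and major inversion karyotypes by least squares; the adjusted values
enter a single-variant linear mixed model

    y = X b + Z u + e,    Var(u) = A sigma_g^2,  Var(e) = sigma_e^2 I,

where A is the (normalized) genomic relationship matrix. Variance
components are estimated once on the null model by maximum likelihood on
the eigen-rotated data (single-GRM trick); each variant is then tested
by generalized least squares with a Wald test.

Gene-based tests aggregate variants within 1 kb of a gene: a weighted
burden score test (weights 1/sd of the estimated minor allele frequency)
and a linear-kernel SKAT variance-component score test whose null
mixture-of-chi-squares p-value uses the Liu moment-matching
approximation. Binary traits use a logistic null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .genes import Gene
from .types import GenotypeMatrix, LinePanel, RelationshipMatrix

MEDIAN_CHI2_1DF = 0.4549364231195724


# ----------------------------------------------------------------------
# Stage 1: covariate adjustment
# ----------------------------------------------------------------------

@dataclass
class AdjustedPhenotype:
    line_ids: list[str]
    raw: np.ndarray
    adjusted: np.ndarray
    covariates: pd.DataFrame
    dropped_columns: list[str] = field(default_factory=list)


def covariate_design(panel: LinePanel,
                     inversions: list[str] | None = None) -> pd.DataFrame:
    """Wolbachia (0/1) and inversion dosage (0/1/2) design columns."""
    inversions = panel.inversions if inversions is None else inversions
    cols = {"wolbachia": panel.wolbachia.astype(float)}
    for inv in inversions:
        cols[f"kar_{inv}"] = panel.karyotype(inv).astype(float)
    return pd.DataFrame(cols, index=panel.table.index)


def adjust_phenotype(
    line_means: pd.Series,
    panel: LinePanel,
    inversions: list[str] | None = None,
) -> AdjustedPhenotype:
    """Residuals of line means on Wolbachia + inversion covariates,
    re-centered at the grand mean. Aliased (constant or collinear)
    columns are dropped."""
    design = covariate_design(panel, inversions)
    design = design.loc[line_means.index]
    y = line_means.to_numpy(float)

    X = np.column_stack([np.ones(len(y)), design.to_numpy(float)])
    names = ["intercept"] + list(design.columns)
    # drop aliased columns by rank-revealing QR
    dropped = []
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    Xk = X[:, keep]
    beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    adjusted = resid + y.mean()
    return AdjustedPhenotype(list(line_means.index), y, adjusted,
                             design, dropped)


# ----------------------------------------------------------------------
# Mixed-model scan
# ----------------------------------------------------------------------

@dataclass
class MixedModelFit:
    vid: str
    beta: float
    se: float
    p: float
    sigma_g2: float
    sigma_e2: float


def _ml_delta(Uty: np.ndarray, UtX: np.ndarray, lam: np.ndarray
              ) -> tuple[float, float, float]:
    """Maximize the ML likelihood of the null model over
    delta = sigma_e^2 / sigma_g^2. Returns (delta, sigma_g2, sigma_e2)."""
    n = len(Uty)

    def neg_loglik(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = lam + delta
        Xw = UtX / w[:, None]
        beta = np.linalg.solve(UtX.T @ Xw, Xw.T @ Uty)
        r = Uty - UtX @ beta
        sg2 = float(np.sum(r * r / w) / n)
        return 0.5 * (n * np.log(2 * np.pi * sg2) + np.sum(np.log(w)) + n)

    res = optimize.minimize_scalar(neg_loglik, bounds=(-10.0, 10.0),
                                   method="bounded")
    delta = float(np.exp(res.x))
    w = lam + delta
    Xw = UtX / w[:, None]
    beta = np.linalg.solve(UtX.T @ Xw, Xw.T @ Uty)
    r = Uty - UtX @ beta
    sg2 = float(np.sum(r * r / w) / n)
    return delta, sg2, sg2 * delta


def mixed_model_scan(
    adjusted: AdjustedPhenotype,
    matrix: GenotypeMatrix,
    grm: RelationshipMatrix,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Single-variant mixed-model association of the adjusted means.

    The GRM is eigendecomposed once; variance components come from the
    null (intercept-only) model by ML; every variant with MAF >=
    ``maf_min`` is tested by GLS in the rotated frame with a Wald t test
    (df = n - 2). Variants whose rotated design is singular are skipped.
    """
    if adjusted.line_ids != matrix.line_ids or \
            adjusted.line_ids != grm.line_ids:
        raise KeyError("line sets of phenotype, matrix and GRM differ")
    keep = matrix.minor_allele_freq() >= maf_min
    sub = matrix.take_variants(keep)
    y = adjusted.adjusted
    n = len(y)

    lam, U = np.linalg.eigh(grm.values)
    lam = np.maximum(lam, 0.0)
    Uty = U.T @ y
    Ut1 = U.T @ np.ones((n, 1))
    delta, sg2, se2 = _ml_delta(Uty, Ut1, lam)
    w = lam + delta

    h = sub.haploid_alleles()
    mu = np.nanmean(h, axis=0)
    g = h.copy()
    nan = np.isnan(g)
    g[nan] = np.take(mu, np.where(nan)[1])
    g *= 2.0  # dosage scale, inbred lines
    Utg = U.T @ g

    rows = []
    for j, v in enumerate(sub.variants):
        X = np.column_stack([Ut1[:, 0], Utg[:, j]])
        Xw = X / w[:, None]
        xtx = X.T @ Xw
        if abs(np.linalg.det(xtx)) < 1e-12:
            continue
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (Xw.T @ Uty)
        r = Uty - X @ beta
        s2 = float(np.sum(r * r / w) / (n - 2))
        se = float(np.sqrt(s2 * xtx_inv[1, 1]))
        t = beta[1] / se
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        rows.append((v.vid, float(beta[1]), se, float(p), sg2, se2))
    return pd.DataFrame(rows, columns=["vid", "beta", "se", "p",
                                       "sigma_g2", "sigma_e2"])


# ----------------------------------------------------------------------
# Gene-based tests
# ----------------------------------------------------------------------

@dataclass
class GeneTestResult:
    gene_id: str
    test: str       # burden | skat
    statistic: float
    p: float
    n_variants: int
    stratum: str    # all | common | rare


def gene_window_variants(
    matrix: GenotypeMatrix, gene: Gene, flank: int = 1_000,
    stratum: str = "all",
) -> np.ndarray:
    """Indices of variants within ``flank`` bp of the gene span,
    optionally restricted to common (MAF >= 0.05) or rare variants."""
    s, e = gene.span
    pos = matrix.positions()
    sel = ((matrix.contig_index() == gene.contig)
           & (pos >= s - flank) & (pos < e + flank))
    maf = matrix.minor_allele_freq()
    sel &= ~np.isnan(maf) & (maf > 0)
    if stratum == "common":
        sel &= maf >= 0.05
    elif stratum == "rare":
        sel &= maf < 0.05
    return np.flatnonzero(sel)


def _null_model(y: np.ndarray, C: np.ndarray, binary: bool
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Null fit: (residuals, case weights V, dispersion sigma^2).

    Linear: V = I, sigma^2 from the residual variance. Logistic: V =
    diag(p(1-p)), sigma^2 = 1.
    """
    if binary:
        fit = sm.GLM(y, C, family=sm.families.Binomial()).fit()
        mu = fit.fittedvalues
        return y - mu, mu * (1.0 - mu), 1.0
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    r = y - C @ beta
    s2 = float(r @ r / (len(y) - C.shape[1]))
    return r, np.ones(len(y)), s2


def _score_test(y: np.ndarray, C: np.ndarray, b: np.ndarray,
                binary: bool) -> tuple[float, float]:
    """Score test of a single constructed regressor ``b`` given
    covariates C. Returns (chi2 statistic, p)."""
    r, v, s2 = _null_model(y, C, binary)
    U = float(b @ r)
    Cv = C * v[:, None]
    proj = Cv @ np.linalg.solve(C.T @ Cv, C.T @ (v * b))
    var_U = float(b @ (v * b) - b @ proj) * s2
    if var_U <= 0:
        return 0.0, 1.0
    chi2 = U * U / var_U
    return chi2, float(stats.chi2.sf(chi2, df=1))


def burden_test(
    matrix: GenotypeMatrix, gene: Gene, y: np.ndarray,
    covariates: np.ndarray, stratum: str = "all",
    flank: int = 1_000, binary: bool = False,
) -> GeneTestResult | None:
    """Weighted burden score test.

    Per-line burden = sum_j w_j g_j with w_j the reciprocal of the
    standard deviation of variant j's estimated minor allele frequency,
    w_j = 1 / sqrt(p_j (1 - p_j) / n) on the haploid line count.
    """
    idx = gene_window_variants(matrix, gene, flank, stratum)
    if idx.size == 0:
        return None
    sub = matrix.take_variants(idx)
    h = sub.haploid_alleles()
    p = np.nanmean(h, axis=0)
    minor = np.where(p <= 0.5, h, 1.0 - h)
    pm = np.minimum(p, 1.0 - p)
    nan = np.isnan(minor)
    minor[nan] = np.take(pm, np.where(nan)[1])
    n = matrix.n_lines
    w = 1.0 / np.sqrt(pm * (1.0 - pm) / n)
    b = minor @ w
    C = np.column_stack([np.ones(n), covariates]) \
        if covariates.size else np.ones((n, 1))
    chi2, pval = _score_test(y, C, b, binary)
    return GeneTestResult(gene.gene_id, "burden", chi2, pval,
                          int(idx.size), stratum)


def _imhof_pvalue(q: float, lam: np.ndarray) -> float:
    """P(sum lam_i chi^2_1 > q) by Imhof's numerical inversion of the
    characteristic function; exact up to quadrature error."""
    from scipy.integrate import quad

    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], df=1))

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    val, _err = quad(integrand, 0.0, np.inf, limit=200)
    p = 0.5 + val / np.pi
    return float(min(max(p, 0.0), 1.0))


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Moment-matching p-value for Q ~ sum lam_i chi^2_1 (Liu et al.)."""
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    c1, c2 = lam.sum(), np.sum(lam ** 2)
    c3, c4 = np.sum(lam ** 3), np.sum(lam ** 4)
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        d = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * d
    else:
        d = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    q_norm = (q - c1) / np.sqrt(2.0 * c2)
    q_chi = q_norm * np.sqrt(2.0 * df + 4.0 * d) + df + d
    return float(stats.ncx2.sf(q_chi, df, d))


def skat_test(
    matrix: GenotypeMatrix, gene: Gene, y: np.ndarray,
    covariates: np.ndarray, stratum: str = "all",
    flank: int = 1_000, binary: bool = False,
) -> GeneTestResult | None:
    """Linear-kernel SKAT without minor-allele up-weighting.

    Q = r' G G' r with r the null-model residuals and G the (unweighted)
    minor-allele genotype matrix; the null distribution is the usual
    mixture of chi-squares with weights from the projected kernel,
    approximated by Liu moment matching.
    """
    idx = gene_window_variants(matrix, gene, flank, stratum)
    if idx.size == 0:
        return None
    sub = matrix.take_variants(idx)
    h = sub.haploid_alleles()
    p = np.nanmean(h, axis=0)
    minor = np.where(p <= 0.5, h, 1.0 - h)
    pm = np.minimum(p, 1.0 - p)
    nan = np.isnan(minor)
    minor[nan] = np.take(pm, np.where(nan)[1])
    n = matrix.n_lines
    C = np.column_stack([np.ones(n), covariates]) \
        if covariates.size else np.ones((n, 1))
    r, v, s2 = _null_model(y, C, binary)
    q = float(r @ minor @ (minor.T @ r))
    # eigenvalues of G' P G scaled by the null variance
    Gv = minor * np.sqrt(v)[:, None]
    Cv = C * v[:, None]
    H = Gv.T @ Gv - (minor.T @ Cv) @ np.linalg.solve(
        C.T @ Cv, Cv.T @ minor)
    H = (H + H.T) / 2.0
    lam = np.linalg.eigvalsh(H) * s2
    # exact mixture inversion where it converges; moment-matching as a
    # fallback for degenerate spectra or extreme tails
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pval = _imhof_pvalue(q, lam)
        except Exception:
            pval = np.nan
    if not np.isfinite(pval) or pval <= 0.0:
        pval = _liu_pvalue(q, lam)
    return GeneTestResult(gene.gene_id, "skat", q, pval,
                          int(idx.size), stratum)


# ----------------------------------------------------------------------
# Inflation diagnostics and genome-size model
# ----------------------------------------------------------------------

def qq_inflation(pvalues: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor lambda and a QQ table.

    lambda = median(qchisq(1 - p, 1)) / 0.4549...; expected quantiles
    are uniform order statistics.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    lam = float(np.median(chi2) / MEDIAN_CHI2_1DF)
    obs = np.sort(p)
    exp = (np.arange(1, p.size + 1) - 0.5) / p.size
    qq = pd.DataFrame({"expected": exp, "observed": obs})
    return lam, qq


def genome_size_model(
    line_sizes: pd.Series, inversion_counts: pd.Series,
    replicates: pd.DataFrame | None = None,
) -> dict:
    """Regression of line-mean genome size on inversion count, plus an
    among-line one-way ANOVA on replicate measurements when given.

    Returns slope b, its F statistic (1, n-2 df) and p; with replicates,
    adds the among-line ANOVA F and p.
    """
    x = inversion_counts.loc[line_sizes.index].to_numpy(float)
    y = line_sizes.to_numpy(float)
    if np.all(x == x[0]):
        raise ValueError("inversion counts are constant; slope undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    out = {
        "b": float(fit.params[1]),
        "F": float(fit.tvalues[1] ** 2),
        "p": float(fit.pvalues[1]),
        "df": (1, int(fit.df_resid)),
    }
    if replicates is not None:
        groups = [g["genome_size_mb"].to_numpy()
                  for _, g in replicates.groupby("line_id")]
        f, p = stats.f_oneway(*groups)
        out["anova_F"] = float(f)
        out["anova_p"] = float(p)
    return out


def bonferroni(pvalues: np.ndarray, alpha: float = 0.05) -> float:
    """Conservative genome-wide threshold: alpha / number of tests."""
    return alpha / len(pvalues)
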