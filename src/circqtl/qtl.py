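"""Cis-QTL mapping with adaptive permutations and Beta-approximated
empirical p-values.

For each phenotype, variants within a symmetric cis window around the
circRNA's junction boundaries are tested one at a time by ordinary
least squares of the covariate-residualized phenotype on the
covariate-residualized dosage (two-sided t test with
n - n_covariates - 2 degrees of freedom). The best nominal p-value per
phenotype is then calibrated by permuting the phenotype across samples:
permutations stop early once enough permutation minima beat the
observed optimum, the minima are fitted with a maximum-likelihood Beta
distribution, and the Beta CDF at the observed top p gives a smooth
locus-level empirical p-value. Feature-level multiple testing uses
Storey q-values with a single-lambda pi0 estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .formats import GenotypeMatrix, parse_circ_key

log = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000
DEFAULT_B_MIN = 100
DEFAULT_B_MAX = 10_000
DEFAULT_N_HITS_STOP = 15
PERM_CHUNK = 250


@dataclass
class CisQTLResult:
    """Top cis association for one phenotype."""

    key: str
    n_cis_variants: int
    top_variant: str
    slope: float
    slope_se: float
    nominal_p: float
    perms_used: int
    empirical_p: float
    beta_shape1: float
    beta_shape2: float
    beta_p: float
    qvalue: float = np.nan


def residual_projector(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Projector onto the orthogonal complement of [intercept; covariates]."""
    if covariates is None or covariates.size == 0:
        d = np.ones((1, n))
    else:
        d = np.vstack([np.ones((1, n)), covariates])
    q, _ = np.linalg.qr(d.T)  # n x k orthonormal basis of the design space
    return np.eye(n) - q @ q.T


def nominal_scan(phenotype: np.ndarray, dosages: np.ndarray,
                 variant_ids: list[str],
                 covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Per-variant OLS slope/SE/p of the phenotype on each dosage row.

    Covariates (rows x samples) are projected out of both sides;
    monomorphic variants are skipped.
    """
    y = np.asarray(phenotype, float)
    g = np.asarray(dosages, float)
    n = y.size
    ncov = 0 if covariates is None else np.atleast_2d(covariates).shape[0]
    dof = n - ncov - 2
    if dof < 1:
        raise ValueError(f"not enough samples (n={n}) for {ncov} covariates")
    poly = g.var(axis=1) > 0
    if not poly.all():
        log.info("skipping %d monomorphic variant(s)",
                 int((~poly).sum()))
    g = g[poly]
    ids = [v for v, keep in zip(variant_ids, poly) if keep]
    proj = residual_projector(
        None if covariates is None else np.atleast_2d(covariates), n)
    yr = proj @ y
    gr = g @ proj.T
    syy = float(yr @ yr)
    sgg = np.einsum("ij,ij->i", gr, gr)
    sgy = gr @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sgy / sgg
        rss = syy - slope * sgy
        sigma2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(sigma2 / sgg)
        tstat = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return pd.DataFrame({"variant_id": ids, "slope": slope, "se": se,
                         "p": p})


def _min_p_from_r2(max_r2: np.ndarray, dof: int) -> np.ndarray:
    """Smallest two-sided p per permutation from its largest squared
    correlation (p is monotone decreasing in r^2)."""
    r2 = np.clip(max_r2, 0.0, 1.0 - 1e-15)
    t2 = dof * r2 / (1.0 - r2)
    return 2.0 * stats.t.sf(np.sqrt(t2), dof)


def adaptive_permutation(
    phenotype_res: np.ndarray,
    dosages_res: np.ndarray,
    dof: int,
    rng: np.random.Generator,
    b_min: int = DEFAULT_B_MIN,
    b_max: int = DEFAULT_B_MAX,
    n_hits_stop: int = DEFAULT_N_HITS_STOP,
) -> tuple[float, np.ndarray, int]:
    """Permute the residualized phenotype, tracking the best association
    per permutation.

    Stops after ``b_min`` permutations once at least ``n_hits_stop``
    permutation minima are <= the observed minimum (equivalently their
    top r^2 >= observed), or at ``b_max``. Returns
    ``(empirical_p, permutation minimum p-values, perms_used)`` with
    ``empirical_p = (1 + hits) / (1 + perms_used)``.
    """
    if b_min < 1 or b_max < b_min:
        raise ValueError("need 1 <= b_min <= b_max")
    y = np.asarray(phenotype_res, float)
    g = np.asarray(dosages_res, float)
    n = y.size
    sgg = np.einsum("ij,ij->i", g, g)
    syy = float(y @ y)
    denom = sgg * syy
    ok = denom > 0
    if not ok.any():
        raise ValueError("no testable variants for permutation scheme")
    obs_r2 = np.max((g @ y) ** 2 / np.where(ok, denom, np.inf))
    minima: list[np.ndarray] = []
    hits = 0
    used = 0
    while used < b_max:
        chunk = min(PERM_CHUNK, b_max - used)
        perms = np.empty((chunk, n))
        for i in range(chunk):
            perms[i] = y[rng.permutation(n)]
        num = (perms @ g.T) ** 2  # chunk x variants
        r2 = np.max(num / np.where(ok, denom, np.inf), axis=1)
        minima.append(r2)
        hits += int(np.count_nonzero(r2 >= obs_r2))
        used += chunk
        if used >= b_min and hits >= n_hits_stop:
            break
    perm_min_p = _min_p_from_r2(np.concatenate(minima), dof)
    empirical_p = (1.0 + hits) / (1.0 + used)
    return empirical_p, perm_min_p, used


def fit_beta_mle(x: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 100) -> tuple[float, float]:
    """Maximum-likelihood Beta(alpha, beta) fit by Newton iteration from
    a method-of-moments start.

    Falls back to the method-of-moments estimate when Newton fails to
    converge; degenerate (constant) input is an error.
    """
    x = np.clip(np.asarray(x, float), 1e-12, 1.0 - 1e-12)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("Beta fit needs non-degenerate input")
    m, v = x.mean(), x.var()
    v = max(v, 1e-12)
    common = m * (1.0 - m) / v - 1.0
    a = max(m * common, 1e-3)
    b = max((1.0 - m) * common, 1e-3)
    mlog = np.log(x).mean()
    mlog1 = np.log1p(-x).mean()
    a_mom, b_mom = a, b
    for _ in range(max_iter):
        psi_ab = special.psi(a + b)
        grad = np.array([psi_ab - special.psi(a) + mlog,
                         psi_ab - special.psi(b) + mlog1])
        if np.max(np.abs(grad)) < tol:
            return float(a), float(b)
        tri_ab = special.polygamma(1, a + b)
        hess = np.array([[tri_ab - special.polygamma(1, a), tri_ab],
                         [tri_ab, tri_ab - special.polygamma(1, b)]])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        a_new, b_new = a - step[0], b - step[1]
        if a_new <= 0 or b_new <= 0:
            a_new = max(a - 0.5 * step[0], a / 2)
            b_new = max(b - 0.5 * step[1], b / 2)
        a, b = a_new, b_new
    else:
        log.warning("Beta MLE did not converge; using method of moments")
        return float(a_mom), float(b_mom)
    log.warning("Beta MLE Newton step failed; using method of moments")
    return float(a_mom), float(b_mom)


def beta_perm_pvalue(nominal_p_top: float, alpha: float,
                     beta: float) -> float:
    """Beta-CDF adjustment of the observed top p against the fitted
    permutation-null Beta distribution."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta parameters must be positive")
    return float(stats.beta.cdf(nominal_p_top, alpha, beta))


def storey_qvalues(pvals: np.ndarray, lam: float = 0.5,
                   pi0: float | None = None) -> np.ndarray:
    """Storey q-values with the single-lambda pi0 estimate
    pi0 = min(1, #{p > lam} / ((1 - lam) m)) applied to step-up
    (Benjamini-Hochberg) adjusted p-values. ``pi0`` may be fixed
    explicitly (e.g. 1.0 recovers plain step-up adjustment)."""
    p = np.asarray(pvals, float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    if pi0 is None:
        pi0 = min(1.0, np.count_nonzero(p > lam) / ((1.0 - lam) * m))
    elif not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0,1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(pi0 * ranked, 1.0)
    return q


def cis_window_mask(genotypes: GenotypeMatrix, key: str,
                    cis_window: int = DEFAULT_CIS_WINDOW) -> np.ndarray:
    chrom, start, end = parse_circ_key(key)
    lo, hi = start - cis_window, end + cis_window
    return np.array([v.chrom == chrom and lo <= v.pos <= hi
                     for v in genotypes.variants], dtype=bool)


def map_all(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    seed: int,
    cis_window: int = DEFAULT_CIS_WINDOW,
    b_min: int = DEFAULT_B_MIN,
    b_max: int = DEFAULT_B_MAX,
    n_hits_stop: int = DEFAULT_N_HITS_STOP,
    qvalue_threshold: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Run the full per-phenotype cis scan and return the results table
    plus the eCircRNA set (q-value < threshold).

    Phenotype columns, genotype samples and covariate columns must agree
    exactly (same ids, same order); a mismatch is a hard error, not a
    silent reindex. Each phenotype draws its permutations from an
    independent seeded stream keyed by (seed, row index), so results do
    not depend on execution order.
    """
    sample_ids = list(phenotypes.columns)
    if sample_ids != list(genotypes.sample_ids):
        raise ValueError("phenotype/genotype sample ids do not match")
    if covariates is not None and len(covariates):
        if list(covariates.columns) != sample_ids:
            raise ValueError("covariate sample ids do not match")
        cov = covariates.to_numpy(float)
    else:
        cov = None
    n = len(sample_ids)
    ncov = 0 if cov is None else cov.shape[0]
    dof = n - ncov - 2
    proj = residual_projector(cov, n)
    dos_res = genotypes.dosages @ proj.T
    poly = genotypes.dosages.var(axis=1) > 0
    results: list[CisQTLResult] = []
    for idx, key in enumerate(phenotypes.index):
        mask = cis_window_mask(genotypes, key, cis_window) & poly
        if not mask.any():
            log.info("%s: no cis variants in ±%d window; skipped",
                     key, cis_window)
            continue
        nominal = nominal_scan(phenotypes.loc[key].to_numpy(float),
                               genotypes.dosages[mask],
                               [genotypes.variants[i].vid
                                for i in np.flatnonzero(mask)],
                               covariates=cov)
        if nominal.empty or not np.isfinite(nominal["p"]).any():
            continue
        top = nominal.loc[nominal["p"].idxmin()]
        rng = np.random.default_rng([seed, idx])
        y_res = proj @ phenotypes.loc[key].to_numpy(float)
        emp_p, perm_min_p, used = adaptive_permutation(
            y_res, dos_res[mask], dof, rng, b_min, b_max, n_hits_stop)
        try:
            a, b = fit_beta_mle(perm_min_p)
            beta_p = beta_perm_pvalue(float(top["p"]), a, b)
        except ValueError:
            log.warning("%s: degenerate permutation minima; "
                        "using empirical p", key)
            a = b = np.nan
            beta_p = emp_p
        results.append(CisQTLResult(
            key=key, n_cis_variants=int(mask.sum()),
            top_variant=str(top["variant_id"]), slope=float(top["slope"]),
            slope_se=float(top["se"]), nominal_p=float(top["p"]),
            perms_used=used, empirical_p=emp_p,
            beta_shape1=float(a), beta_shape2=float(b), beta_p=beta_p))
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return df, []
    df["qvalue"] = storey_qvalues(df["beta_p"].to_numpy())
    ecirc = sorted(df.loc[df["qvalue"] < qvalue_threshold, "key"])
    return df, ecirc


RESULT_COLS = ("key", "n_cis_variants", "top_variant", "slope", "slope_se",
               "nominal_p", "perms_used", "empirical_p", "beta_shape1",
               "beta_shape2", "beta_p", "qvalue")


def write_qtl_results(df: pd.DataFrame, path,
                      header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, columns=list(RESULT_COLS),
                  float_format="%.6g")
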