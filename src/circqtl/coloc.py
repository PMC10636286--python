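"""Approximate-Bayes-factor colocalization between a circQTL locus and a
GWAS trait.

Each trait contributes per-variant Wakefield log approximate Bayes
factors computed from (beta, se) under a single normal effect prior
N(0, W). Under the single-causal-variant assumption the five hypotheses
(H0 no association, H1/H2 one trait only, H3 two distinct causal
variants, H4 one shared causal variant) have unnormalized weights

    S0 = 1
    S1 = p1 * sum_i BF1_i
    S2 = p2 * sum_i BF2_i
    S3 = p1 * p2 * (sum_i BF1_i * sum_j BF2_j - sum_i BF1_i BF2_i)
    S4 = p12 * sum_i BF1_i BF2_i

evaluated in log space with log-sum-exp for numerical stability, then
normalized to posterior probabilities PP.H0..PP.H4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .formats import SummaryStats

log = logging.getLogger(__name__)

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
DEFAULT_PP4_THRESHOLD = 0.5
DEFAULT_MIN_SHARED = 25
# effect-size prior standard deviations of the ABF model
PRIOR_SD_QUANT = 0.15
PRIOR_SD_CC = 0.2

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class ColocResult:
    key: str
    trait: str
    n_shared: int
    pp: np.ndarray  # PP.H0..PP.H4
    priors: tuple[float, float, float]
    colocalized: bool


def wakefield_abf(beta: np.ndarray, se: np.ndarray,
                  prior_sd: float) -> np.ndarray:
    """Per-variant log approximate Bayes factor.

    With z = beta/se, V = se^2, W = prior_sd^2 and r = W/(V+W):
    log ABF = 0.5 log(1 - r) + z^2 r / 2.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    v = se ** 2
    w = prior_sd ** 2
    r = w / (v + w)
    z2 = (beta / se) ** 2
    return 0.5 * np.log1p(-r) + 0.5 * z2 * r


def prior_sd_for(trait_type: str) -> float:
    return PRIOR_SD_CC if trait_type == "cc" else PRIOR_SD_QUANT


def coloc_posteriors(labf1: np.ndarray, labf2: np.ndarray,
                     p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
                     p12: float = DEFAULT_P12) -> np.ndarray:
    """Posterior probabilities (PP.H0..PP.H4) from two aligned vectors of
    per-variant log ABFs over the same ordered shared variants."""
    l1 = np.asarray(labf1, float)
    l2 = np.asarray(labf2, float)
    if l1.shape != l2.shape or l1.ndim != 1 or l1.size == 0:
        raise ValueError("log-ABF vectors must be equal-length, non-empty")
    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = np.log(p1) + lse1
    lh2 = np.log(p2) + lse2
    # sum_{i != j} BF1_i BF2_j = S1*S2 - S12, computed as a log difference
    cross = lse1 + lse2
    if cross <= lse12 + 1e-12:
        # single variant (or numerically indistinguishable): no H3 mass
        lh3 = -np.inf
        if l1.size > 1:
            log.info("H3 inner term non-positive; clamped to zero mass")
    else:
        lh3 = np.log(p1) + np.log(p2) + cross + np.log1p(-np.exp(lse12 - cross))
    lh4 = np.log(p12) + lse12
    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    return np.exp(lh - logsumexp(lh))


def harmonize_variants(qtl: pd.DataFrame, gwas: pd.DataFrame
                       ) -> pd.DataFrame:
    """Intersect QTL and GWAS records on variant id with allele
    harmonization.

    A GWAS record whose id matches with ref/alt swapped is used with its
    effect sign flipped; strand-ambiguous palindromic variants (A/T,
    C/G) are dropped. Returns a frame with columns
    ``variant_id, beta_qtl, se_qtl, beta_gwas, se_gwas``.
    """
    gwas_direct = {}
    gwas_flipped = {}
    for row in gwas.itertuples():
        parts = row.variant_id.split(":")
        if len(parts) != 4:
            continue
        chrom, pos, ref, alt = parts
        if (ref, alt) in _PALINDROMIC:
            continue
        gwas_direct[row.variant_id] = (row.beta, row.se)
        gwas_flipped[f"{chrom}:{pos}:{alt}:{ref}"] = (-row.beta, row.se)
    out = []
    for row in qtl.itertuples():
        vid = row.variant_id
        parts = vid.split(":")
        if len(parts) == 4 and (parts[2], parts[3]) in _PALINDROMIC:
            continue
        if vid in gwas_direct:
            b, s = gwas_direct[vid]
        elif vid in gwas_flipped:
            b, s = gwas_flipped[vid]
        else:
            continue
        out.append((vid, row.beta, row.se, b, s))
    return pd.DataFrame(out, columns=["variant_id", "beta_qtl", "se_qtl",
                                      "beta_gwas", "se_gwas"])


def run_coloc_all(
    qtl_nominal: dict[str, pd.DataFrame],
    gwas: dict[str, SummaryStats],
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    pp4_threshold: float = DEFAULT_PP4_THRESHOLD,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> list[ColocResult]:
    """Colocalize every (eCircRNA, trait) pair.

    ``qtl_nominal`` maps circRNA key -> per-variant nominal statistics
    (columns ``variant_id, beta, se``) over its cis window; QTL effects
    are on the inverse-normal phenotype scale (quantitative prior).
    Pairs with fewer than ``min_shared`` shared variants after
    harmonization are skipped.
    """
    results: list[ColocResult] = []
    for key in sorted(qtl_nominal):
        qtab = qtl_nominal[key]
        for trait in sorted(gwas):
            ss = gwas[trait]
            shared = harmonize_variants(
                qtab.rename(columns={"slope": "beta"})[
                    ["variant_id", "beta", "se"]],
                ss.table)
            if len(shared) < min_shared:
                log.info("%s x %s: %d shared variants (< %d); skipped",
                         key, trait, len(shared), min_shared)
                continue
            l1 = wakefield_abf(shared["beta_qtl"].to_numpy(),
                               shared["se_qtl"].to_numpy(),
                               PRIOR_SD_QUANT)
            l2 = wakefield_abf(shared["beta_gwas"].to_numpy(),
                               shared["se_gwas"].to_numpy(),
                               prior_sd_for(ss.trait_type))
            pp = coloc_posteriors(l1, l2, p1, p2, p12)
            results.append(ColocResult(
                key=key, trait=trait, n_shared=len(shared), pp=pp,
                priors=(p1, p2, p12),
                colocalized=bool(pp[4] >= pp4_threshold)))
    return results


def coloc_results_frame(results: list[ColocResult]) -> pd.DataFrame:
    rows = [{"key": r.key, "trait": r.trait, "n_shared": r.n_shared,
             "pp_h0": r.pp[0], "pp_h1": r.pp[1], "pp_h2": r.pp[2],
             "pp_h3": r.pp[3], "pp_h4": r.pp[4],
             "colocalized": r.colocalized} for r in results]
    return pd.DataFrame(rows, columns=["key", "trait", "n_shared", "pp_h0",
                                       "pp_h1", "pp_h2", "pp_h3", "pp_h4",
                                       "colocalized"])


def write_coloc_results(results: list[ColocResult], path,
                        header_comment: str | None = None) -> None:
    df = coloc_results_frame(results)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
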