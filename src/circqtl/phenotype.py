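"""Count matrix -> QTL-ready phenotypes and covariates.

The fixed processing order is: population filter -> per-feature z-score
scaling -> rank-based inverse-normal transform (INT) -> hidden-factor
covariates. After INT every feature carries the same set of normal
quantiles Phi^-1((r - 0.5)/n), so the nominal association model sees
distribution-free phenotypes. Hidden expression factors are the top
sample-space principal components of the processed phenotype matrix, a
PCA stand-in for Bayesian factor models commonly used for expression
covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class EmptyPhenotypeError(ValueError):
    """Every feature was removed by filtering."""


def population_filter(counts: pd.DataFrame, min_nonzero_frac: float = 0.2,
                      min_count: int = 2) -> pd.DataFrame:
    """Keep features expressed at >= ``min_count`` in at least
    ``min_nonzero_frac`` of samples."""
    if not 0 <= min_nonzero_frac <= 1:
        raise ValueError("min_nonzero_frac must be in [0,1]")
    frac = (counts >= min_count).mean(axis=1)
    kept = counts.loc[frac >= min_nonzero_frac]
    if kept.empty:
        raise EmptyPhenotypeError(
            f"population filter (count >= {min_count} in "
            f">= {min_nonzero_frac:.0%} of samples) removed every feature")
    return kept


def zscore_scale(mat: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardization to mean 0, sd 1 (sample sd, ddof=1).

    Constant rows cannot be scaled and are dropped with a warning.
    """
    sd = mat.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        log.warning("dropping %d constant feature(s) before scaling",
                    int(constant.sum()))
        mat = mat.loc[~constant]
        sd = sd.loc[~constant]
    return mat.sub(mat.mean(axis=1), axis=0).div(sd, axis=0)


def inverse_normal_transform(mat: pd.DataFrame) -> pd.DataFrame:
    """Rank-based INT per row: rank r (average ranks on ties) maps to
    Phi^-1((r - 0.5)/n)."""
    n = mat.shape[1]
    if n < 3:
        raise ValueError("INT needs at least 3 samples")
    ranks = np.apply_along_axis(stats.rankdata, 1, mat.to_numpy())
    vals = stats.norm.ppf((ranks - 0.5) / n)
    return pd.DataFrame(vals, index=mat.index, columns=mat.columns)


@dataclass
class PhenotypeMatrix:
    """Processed phenotypes plus the ordered transformation log."""

    values: pd.DataFrame
    transform_log: list[str] = field(default_factory=list)

    @property
    def keys(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def prepare_phenotypes(counts: pd.DataFrame, min_nonzero_frac: float = 0.2,
                       min_count: int = 2) -> PhenotypeMatrix:
    """Run the fixed filter -> z-score -> INT pipeline on a count matrix."""
    steps: list[str] = []
    filt = population_filter(counts, min_nonzero_frac, min_count)
    steps.append(f"population_filter(min_count={min_count},"
                 f"min_nonzero_frac={min_nonzero_frac}):"
                 f"{counts.shape[0]}->{filt.shape[0]} features")
    scaled = zscore_scale(filt.astype(float))
    steps.append(f"zscore_scale:{filt.shape[0]}->{scaled.shape[0]} features")
    normed = inverse_normal_transform(scaled)
    steps.append("inverse_normal_transform(offset=0.5)")
    return PhenotypeMatrix(values=normed, transform_log=steps)


def infer_hidden_factors(phenotypes: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k sample-space principal components of the row-centered
    phenotype matrix, orthonormal, ordered by explained variance.

    Returned as a covariates x samples frame with labels
    ``hidden_factor_1..k``.
    """
    n = phenotypes.shape[1]
    if k >= min(phenotypes.shape):
        raise ValueError(f"k={k} must be < min(n_features, n_samples)="
                         f"{min(phenotypes.shape)}")
    if k == 0:
        return pd.DataFrame(np.empty((0, n)), columns=phenotypes.columns)
    x = phenotypes.to_numpy()
    x = x - x.mean(axis=1, keepdims=True)
    # rows of vt are the sample-space PCs; fix sign for determinism
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pcs = vt[:k]
    signs = np.sign(pcs[np.arange(k), np.abs(pcs).argmax(axis=1)])
    pcs = pcs * signs[:, None]
    return pd.DataFrame(pcs, index=[f"hidden_factor_{i + 1}"
                                    for i in range(k)],
                        columns=phenotypes.columns)


def genotype_pcs(dosages: np.ndarray, sample_ids: list[str],
                 k: int) -> pd.DataFrame:
    """Top-k genotype principal components (population-structure
    covariates), labelled ``genotype_pc_1..k``."""
    if k == 0:
        return pd.DataFrame(np.empty((0, len(sample_ids))),
                            columns=sample_ids)
    g = np.asarray(dosages, float)
    g = g - g.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(g, full_matrices=False)
    pcs = vt[:k]
    signs = np.sign(pcs[np.arange(k), np.abs(pcs).argmax(axis=1)])
    pcs = pcs * signs[:, None]
    return pd.DataFrame(pcs, index=[f"genotype_pc_{i + 1}"
                                    for i in range(k)],
                        columns=sample_ids)


def write_phenotype_bed(pheno: pd.DataFrame, path, header_comment=None) -> None:
    """BED-like phenotype table (chrom, start-1, end, key, samples...)."""
    from .formats import parse_circ_key

    rows = []
    for key in pheno.index:
        chrom, start, end = parse_circ_key(key)
        rows.append((chrom, start - 1, end, key))
    meta = pd.DataFrame(rows, columns=["#chrom", "start", "end", "key"],
                        index=pheno.index)
    out = pd.concat([meta, pheno], axis=1)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False)
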