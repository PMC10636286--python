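"""Pipeline configuration: defaults, validation, YAML loading, hashing.

The named constants of the method live here: 149-base pseudo-reference
arms, the 7-base minimum junction overhang, the >= 2 BSJ-read support
filter, consensus cutoff k in {1,2,3}, q-value threshold 0.05 and the
PP.H4 >= 0.5 colocalization call.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigValidationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "circqtl_run"

    # pseudo-reference quantification
    flank_len: int = 149
    min_overhang: int = 7
    seed_k: int = 21
    max_mismatches: int = 2

    # consensus filtering
    min_bsj_reads: int = 2
    consensus_k: int = 3
    methods: tuple[str, ...] = ("circall", "ciri2", "circexplorer2")

    # genotypes / phenotypes
    maf_min: float = 0.05
    min_nonzero_frac: float = 0.2
    min_count: int = 2
    hidden_factors_k: int = 2
    genotype_pcs_k: int = 0

    # cis-QTL mapping
    cis_window: int = 1_000_000
    b_min: int = 100
    b_max: int = 10_000
    n_hits_stop: int = 15
    qvalue_threshold: float = 0.05

    # colocalization
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pp4_threshold: float = 0.5
    min_shared: int = 25

    # simulated-scenario parameters (the synthetic study conditions)
    n_chrom: int = 2
    chrom_len: int = 120_000
    n_transcripts: int = 10
    n_circ: int = 20
    n_samples: int = 40
    n_variants_per_chrom: int = 40
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_rho: float = 0.0
    read_len: int = 75
    frag_len_mean: float = 250.0
    frag_len_sd: float = 30.0
    error_rate: float = 0.0
    n_linear_fragments: int = 500
    mean_junction_count: float = 30.0
    n_planted_qtl: int = 5
    planted_slope: float = 0.35
    gwas_n: int = 20_000
    gwas_h2: float = 0.01

    def validate(self) -> "PipelineConfig":
        checks = [
            (self.flank_len >= 20, "flank_len must be >= 20"),
            (self.min_overhang >= 1, "min_overhang must be >= 1"),
            (self.min_bsj_reads >= 0, "min_bsj_reads must be >= 0"),
            (1 <= self.consensus_k <= len(self.methods),
             f"consensus_k={self.consensus_k} invalid for "
             f"{len(self.methods)} methods"),
            (0 <= self.maf_min < 0.5, "maf_min must be in [0, 0.5)"),
            (0 <= self.min_nonzero_frac <= 1,
             "min_nonzero_frac must be in [0,1]"),
            (0 < self.qvalue_threshold <= 1,
             "qvalue_threshold must be in (0,1]"),
            (0 < self.pp4_threshold <= 1, "pp4_threshold must be in (0,1]"),
            (1 <= self.b_min <= self.b_max, "need 1 <= b_min <= b_max"),
            (self.hidden_factors_k >= 0, "hidden_factors_k must be >= 0"),
            (all(p > 0 for p in
                 (self.coloc_p1, self.coloc_p2, self.coloc_p12)),
             "coloc priors must be positive"),
            (self.cis_window > 0, "cis_window must be positive"),
            (0 <= self.error_rate < 0.5, "error_rate must be in [0, 0.5)"),
            (0 <= self.n_planted_qtl <= self.n_circ,
             "n_planted_qtl must be <= n_circ"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigValidationError(msg)
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigValidationError(
                f"unknown config keys: {sorted(unknown)}")
        coerced = dict(raw)
        for key in ("methods", "maf_range"):
            if key in coerced and isinstance(coerced[key], list):
                coerced[key] = tuple(coerced[key])
        return cls(**coerced).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["maf_range"] = list(self.maf_range)
        return d

    def config_hash(self) -> str:
        """Hash of every analysis-relevant field; the run directory is
        excluded so identical configurations produce identical output
        bytes wherever they are written."""
        d = self.to_dict()
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
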