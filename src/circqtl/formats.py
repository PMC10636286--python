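"""Readers and writers for the external formats the pipeline touches.

All back-splice junction (BSJ) coordinates are harmonized to a single
internal convention: 1-based, inclusive at both ends, ``start < end``.
``start`` is the leftmost base inside the circle (the BSJ acceptor) and
``end`` the rightmost (the BSJ donor), so a circRNA is identified by the
string ``chrom:start:end``. BED-style inputs (0-based half-open) are
converted on read; every other dialect is already 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

METHODS = ("circall", "ciri2", "circexplorer2", "bed")


class ParseError(ValueError):
    """A malformed row or file that cannot be harmonized."""


class ConfigError(ValueError):
    """An invalid option (unknown dialect, out-of-range threshold, ...)."""


@dataclass(frozen=True)
class CircRNACall:
    """One caller's BSJ detection in one sample."""

    sample_id: str
    method: str
    chrom: str
    start: int  # 1-based inclusive, leftmost base in the circle
    end: int    # 1-based inclusive, rightmost base in the circle
    strand: str = "."
    bsj_reads: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}")
        if not (1 <= self.start < self.end):
            raise ParseError(
                f"invalid BSJ interval {self.chrom}:{self.start}:{self.end}"
            )
        if self.bsj_reads < 0:
            raise ParseError("bsj_reads must be non-negative")
        if self.strand not in ("+", "-", "."):
            raise ParseError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}"


def parse_circ_key(key: str) -> tuple[str, int, int]:
    """Split a ``chrom:start:end`` circRNA identifier."""
    chrom, start, end = key.rsplit(":", 2)
    return chrom, int(start), int(end)


def circ_key_sort_tuple(key: str) -> tuple[str, int, int]:
    return parse_circ_key(key)


# ---------------------------------------------------------------------------
# caller output dialects
# ---------------------------------------------------------------------------

# column layouts of the harmonized-on-read dialects; coordinates in the
# ciri2/circall layouts are 1-based inclusive, the BED layouts 0-based
# half-open.
_CIRI2_COLS = ("circRNA_ID", "chr", "circRNA_start", "circRNA_end",
               "junction_reads", "strand")
_CIRCALL_COLS = ("Chr", "Start", "End", "Strand", "JunctionRead")


def _parse_int(text: str, what: str, path: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad {what} {text!r}") from exc


def parse_caller_output(path: str | Path, dialect: str,
                        sample_id: str) -> list[CircRNACall]:
    """Read one caller's table for one sample into harmonized calls.

    Parameters
    ----------
    dialect:
        ``ciri2`` and ``circall`` are headered TSVs with 1-based inclusive
        coordinates; ``circexplorer2`` and ``bed`` are header-less BED6
        (0-based half-open start, score column = BSJ read count).
    """
    path = Path(path)
    if dialect not in METHODS:
        raise ConfigError(f"unknown caller dialect {dialect!r}")
    calls: list[CircRNACall] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    bedlike = dialect in ("circexplorer2", "bed")
    start_line = 0
    if not bedlike:
        if not lines:
            raise ParseError(f"{path}: empty caller table")
        start_line = 1  # header row
    for lineno, line in enumerate(lines[start_line:], start=start_line + 1):
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        try:
            if dialect == "ciri2":
                if len(f) < 6:
                    raise ParseError(f"{path}:{lineno}: expected ≥6 columns")
                chrom, start, end = f[1], f[2], f[3]
                reads, strand = f[4], f[5]
            elif dialect == "circall":
                if len(f) < 5:
                    raise ParseError(f"{path}:{lineno}: expected ≥5 columns")
                chrom, start, end = f[0], f[1], f[2]
                strand, reads = f[3], f[4]
            else:  # circexplorer2 / generic bed
                if len(f) < 5:
                    raise ParseError(f"{path}:{lineno}: expected ≥5 columns")
                chrom, start, end = f[0], f[1], f[2]
                reads = f[4]
                strand = f[5] if len(f) > 5 else "."
            start_i = _parse_int(start, "start", str(path), lineno)
            end_i = _parse_int(end, "end", str(path), lineno)
            if bedlike:
                start_i += 1  # 0-based half-open -> 1-based inclusive
            reads_i = _parse_int(reads, "read count", str(path), lineno)
            call = CircRNACall(sample_id=sample_id, method=dialect,
                               chrom=chrom, start=start_i, end=end_i,
                               strand=strand, bsj_reads=reads_i)
        except ParseError as exc:
            if ":" in str(exc) and str(path) in str(exc):
                raise
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        calls.append(call)
    return calls


HARMONIZED_COLS = ("sample_id", "method", "chrom", "start", "end",
                   "strand", "bsj_reads")


def write_harmonized_calls(calls: Iterable[CircRNACall],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HARMONIZED_COLS) + "\n")
        for c in calls:
            fh.write(f"{c.sample_id}\t{c.method}\t{c.chrom}\t{c.start}\t"
                     f"{c.end}\t{c.strand}\t{c.bsj_reads}\n")


def read_harmonized_calls(path: str | Path) -> list[CircRNACall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = set(HARMONIZED_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [CircRNACall(sample_id=r.sample_id, method=r.method,
                        chrom=r.chrom, start=int(r.start), end=int(r.end),
                        strand=r.strand, bsj_reads=int(r.bsj_reads))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into ``{name: uppercase sequence}``.

    Duplicate record names and empty files are errors; lowercase
    (soft-masked) bases are uppercased.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ParseError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages, variants x samples, entries in [0, 2]."""

    variants: list[Variant]
    dosages: np.ndarray  # shape (n_variants, n_samples), float
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.sample_ids)):
            raise ValueError("dosage matrix shape mismatch")
        seen = set()
        for v in self.variants:
            k = (v.chrom, v.pos, v.ref, v.alt)
            if k in seen:
                raise ValueError(f"duplicate variant {v.vid}")
            seen.add(k)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def maf(self) -> np.ndarray:
        af = self.dosages.mean(axis=1) / 2.0
        return np.minimum(af, 1.0 - af)

    def variant_ids(self) -> list[str]:
        return [v.vid for v in self.variants]

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[idx],
            sample_ids=list(self.sample_ids),
        )


def read_vcf_dosages(path: str | Path, maf_min: float = 0.05) -> GenotypeMatrix:
    """Read biallelic SNP dosages from a VCF.

    Multi-allelic records and indels are dropped, missing genotypes are
    mean-imputed per variant, and variants with minor-allele frequency
    below ``maf_min`` are removed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: VCF has no sample columns")
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue  # indel
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = np.asarray(rec.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        missing = gt == 2
        if missing.all():
            continue
        if missing.any():
            dos[missing] = dos[~missing].mean()
        variants.append(Variant(rec.CHROM, rec.POS, ref, alt))
        rows.append(dos)
    if not rows:
        log.warning("%s: no biallelic SNPs retained", path)
        return GenotypeMatrix([], np.empty((0, len(samples))), samples)
    gm = GenotypeMatrix(variants, np.vstack(rows), samples)
    keep = gm.maf() >= maf_min
    if not keep.any():
        log.warning("%s: all variants removed by MAF ≥ %g filter",
                    path, maf_min)
    return gm.subset(keep)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Per-variant GWAS effect estimates for one trait."""

    trait: str
    trait_type: str  # "quant" or "cc"
    table: pd.DataFrame = field(repr=False)  # variant_id, beta, se, n
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quant", "cc"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "cc":
            if self.case_fraction is None or not (0 < self.case_fraction < 1):
                raise ConfigError(
                    "case_fraction in (0,1) required for case-control traits")
        if self.table["variant_id"].duplicated().any():
            raise ParseError(f"trait {self.trait}: duplicate variant ids")
        if (self.table["se"] <= 0).any():
            raise ParseError(f"trait {self.trait}: non-positive se present")


GWAS_COLS = ("variant_id", "beta", "se", "n")


def read_gwas_sumstats(path: str | Path, trait: str, trait_type: str,
                       case_fraction: float | None = None) -> SummaryStats:
    """Read a GWAS summary-statistics TSV (variant_id, beta, se, n).

    Records with ``se <= 0`` are dropped (count logged) rather than
    failing the whole trait.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(GWAS_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = df["se"] <= 0
    if bad.any():
        log.info("%s: dropped %d records with se <= 0", path, int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    if case_fraction is None and "case_fraction" in df.columns:
        case_fraction = float(df["case_fraction"].iloc[0])
    return SummaryStats(trait=trait, trait_type=trait_type,
                        table=df[list(GWAS_COLS)].copy(),
                        case_fraction=case_fraction)


def write_gwas_sumstats(ss: SummaryStats, path: str | Path) -> None:
    df = ss.table.copy()
    if ss.trait_type == "cc":
        df["case_fraction"] = ss.case_fraction
    df.to_csv(path, sep="\t", index=False)
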