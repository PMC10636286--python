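"""Seeded generators for every input the pipeline consumes.

The simulator stands in for a real cohort (matched ribo-minus RNA-seq
and genotypes plus external GWAS summary statistics): it emits a random
genome with linear transcripts, circRNAs placed inside them, per-method
caller tables with controlled agreement, paired-end reads in which a
known subset of fragments spans each back-splice junction, genotypes
with planted additive cis effects on circRNA abundance, and GWAS
summary statistics whose causal variant is either shared with or
distinct from a planted circQTL. Every generator is a pure function of
(seed, parameters), and a ground-truth bundle records enough (fragment
origins and offsets, planted effects, causal variants) to recompute the
expected output of each pipeline stage by brute force.

The error model is substitution-only (no indels), matching the ungapped
alignment contract of the quantifier, and circRNA fragments never wrap
the circle more than once.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import GenotypeMatrix, SummaryStats, Variant, parse_circ_key
from .pseudo_quant import revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# genome, transcripts, circRNAs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    seq: str


@dataclass
class SimAnnotation:
    genome: dict[str, str]
    transcripts: dict[str, Transcript]
    circ_keys: list[str]

    def transcript_seqs(self) -> dict[str, str]:
        return {name: t.seq for name, t in self.transcripts.items()}

    def circ_sequence(self, key: str) -> str:
        chrom, start, end = parse_circ_key(key)
        return self.genome[chrom][start - 1:end]


def simulate_genome_and_annotation(
    seed: int,
    n_chrom: int = 2,
    chrom_len: int = 120_000,
    n_transcripts: int = 10,
    n_circ: int = 20,
    transcript_len_range: tuple[int, int] = (3_000, 8_000),
    circ_len_range: tuple[int, int] = (150, 450),
    n_short_circ: int = 0,
    flank_len: int = 149,
    junction_kmer: int = 30,
) -> SimAnnotation:
    """Random genome, transcripts as genomic substrings, and circRNAs
    placed inside transcripts.

    Each circRNA's junction ``junction_kmer``-mer (the bases straddling
    its back-splice joint on the pseudo reference) is verified absent
    from every transcript; placement is retried when the check fails.
    ``n_short_circ`` extra circles shorter than ``flank_len`` exercise
    the truncated-arm path.
    """
    if chrom_len < 10 * flank_len:
        raise ValueError("chrom_len must be at least 10x flank_len")
    rng = np.random.default_rng([seed, 101])
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    genome = {c: _random_seq(rng, chrom_len) for c in chroms}

    transcripts: dict[str, Transcript] = {}
    per_chrom = [n_transcripts // n_chrom + (1 if i < n_transcripts % n_chrom
                                             else 0)
                 for i in range(n_chrom)]
    t_idx = 0
    for chrom, n_tx in zip(chroms, per_chrom):
        if n_tx == 0:
            continue
        lengths = rng.integers(transcript_len_range[0],
                               transcript_len_range[1] + 1, size=n_tx)
        free = chrom_len - int(lengths.sum())
        if free < n_tx + 1:
            raise ValueError("transcripts do not fit on chromosome")
        gaps = rng.random(n_tx + 1)
        gaps = np.floor(gaps / gaps.sum() * free).astype(int)
        pos = 1
        for length, gap in zip(lengths, gaps):
            start = pos + int(gap)
            end = start + int(length) - 1
            name = f"tx_{t_idx + 1}"
            transcripts[name] = Transcript(
                name=name, chrom=chrom, start=start, end=end,
                seq=genome[chrom][start - 1:end])
            pos = end + 1
            t_idx += 1

    tx_list = sorted(transcripts.values(), key=lambda t: t.name)
    tx_seqs = [t.seq for t in tx_list]
    circ_keys: list[str] = []
    used: set[tuple[str, int, int]] = set()
    spec = [circ_len_range] * n_circ + [(50, flank_len - 1)] * n_short_circ
    for lo, hi in spec:
        for _ in range(200):
            tx = tx_list[int(rng.integers(len(tx_list)))]
            tx_len = tx.end - tx.start + 1
            if tx_len < lo + 2:
                continue
            length = int(rng.integers(lo, min(hi, tx_len - 1) + 1))
            offset = int(rng.integers(0, tx_len - length + 1))
            start = tx.start + offset
            end = start + length - 1
            if (tx.chrom, start, end) in used:
                continue
            half = junction_kmer // 2
            seq = genome[tx.chrom]
            junction = seq[end - half:end] + seq[start - 1:start - 1 + half]
            if any(junction in s for s in tx_seqs):
                continue
            used.add((tx.chrom, start, end))
            circ_keys.append(f"{tx.chrom}:{start}:{end}")
            break
        else:
            raise RuntimeError("could not place circRNA after 200 tries")
    circ_keys.sort(key=parse_circ_key)
    return SimAnnotation(genome=genome, transcripts=transcripts,
                         circ_keys=circ_keys)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _haplotypes(rng: np.random.Generator, n_hap: int, mafs: np.ndarray,
                rho: float) -> np.ndarray:
    """Haplotype alleles by copying-with-recombination: each haplotype
    copies its previous-variant allele with probability ``rho`` and
    otherwise draws fresh at that variant's frequency (rho=0: fully
    independent variants)."""
    n_var = mafs.size
    hap = np.empty((n_var, n_hap), dtype=np.int8)
    hap[0] = rng.random(n_hap) < mafs[0]
    for j in range(1, n_var):
        fresh = rng.random(n_hap) < mafs[j]
        copy = rng.random(n_hap) < rho
        hap[j] = np.where(copy, hap[j - 1], fresh)
    return hap


def simulate_genotypes(
    seed: int,
    n_samples: int = 40,
    n_variants: int = 40,
    maf_range: tuple[float, float] = (0.1, 0.5),
    region: tuple[str, int, int] = ("chr1", 1, 120_000),
    rho: float = 0.0,
) -> GenotypeMatrix:
    """Biallelic SNP dosages sampled under Hardy-Weinberg at frequencies
    drawn from ``maf_range``; strand-ambiguous (palindromic) allele pairs
    are never emitted."""
    rng = np.random.default_rng([seed, 202])
    chrom, lo, hi = region
    if hi - lo + 1 < n_variants:
        raise ValueError("region too small for requested variant count")
    pos = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_variants,
                             replace=False))
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_variants)
    hap = _haplotypes(rng, 2 * n_samples, mafs, rho)
    dosages = (hap[:, :n_samples] + hap[:, n_samples:]).astype(float)
    variants = []
    bases = "ACGT"
    for p in pos:
        ref = bases[int(rng.integers(4))]
        alts = [b for b in bases if b not in (ref, _COMPLEMENT[ref])]
        alt = alts[int(rng.integers(2))]
        variants.append(Variant(chrom, int(p), ref, alt))
    sample_ids = [f"s{i + 1:03d}" for i in range(n_samples)]
    return GenotypeMatrix(variants, dosages, sample_ids)


def concat_genotypes(parts: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    sample_ids = parts[0].sample_ids
    for p in parts[1:]:
        if p.sample_ids != sample_ids:
            raise ValueError("sample id mismatch between genotype blocks")
    return GenotypeMatrix(
        variants=[v for p in parts for v in p.variants],
        dosages=np.vstack([p.dosages for p in parts]),
        sample_ids=sample_ids,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text VCF 4.2 with GT fields only."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({v.chrom for v in gm.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for v, row in zip(gm.variants, gm.dosages):
            gts = "\t".join(gt_map[int(round(d))] for d in row)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\t"
                     f"PASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# planted QTL effects and expected abundances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedQTL:
    key: str
    variant_id: str
    slope: float  # per-allele effect on log expected abundance


def plant_qtls(seed: int, genotypes: GenotypeMatrix, keys: Sequence[str],
               n_qtl: int, slope: float = 0.35,
               cis_window: int = 1_000_000,
               min_maf: float = 0.2) -> list[PlantedQTL]:
    """Pick ``n_qtl`` circRNAs and one common cis variant each; the
    planted per-allele effect acts multiplicatively on expected
    abundance (exp(slope * dosage))."""
    rng = np.random.default_rng([seed, 303])
    mafs = genotypes.maf()
    planted: list[PlantedQTL] = []
    chosen_keys = sorted(rng.choice(np.asarray(sorted(keys), dtype=object),
                                    size=n_qtl, replace=False).tolist())
    for key in chosen_keys:
        chrom, start, end = parse_circ_key(key)
        candidates = [i for i, v in enumerate(genotypes.variants)
                      if v.chrom == chrom
                      and start - cis_window <= v.pos <= end + cis_window
                      and mafs[i] >= min_maf]
        if not candidates:
            raise ValueError(f"no eligible cis variant for planted QTL {key}")
        vi = candidates[int(rng.integers(len(candidates)))]
        planted.append(PlantedQTL(key=key,
                                  variant_id=genotypes.variants[vi].vid,
                                  slope=slope))
    return planted


def expected_junction_abundance(
    seed: int,
    keys: Sequence[str],
    genotypes: GenotypeMatrix,
    planted: Sequence[PlantedQTL],
    mean_count: float = 30.0,
    sd_log: float = 0.4,
) -> pd.DataFrame:
    """Expected junction-fragment count per (circRNA, sample): a
    lognormal baseline per circRNA scaled by exp(slope * (dosage - mean))
    for planted pairs."""
    rng = np.random.default_rng([seed, 404])
    keys = sorted(keys, key=parse_circ_key)
    base = np.exp(rng.normal(np.log(mean_count), sd_log, size=len(keys)))
    mat = np.tile(base[:, None], (1, genotypes.n_samples))
    vid_index = {v.vid: i for i, v in enumerate(genotypes.variants)}
    key_index = {k: i for i, k in enumerate(keys)}
    for q in planted:
        g = genotypes.dosages[vid_index[q.variant_id]]
        mat[key_index[q.key]] *= np.exp(q.slope * (g - g.mean()))
    return pd.DataFrame(mat, index=keys, columns=genotypes.sample_ids)


# ---------------------------------------------------------------------------
# paired-end reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentOrigin:
    source: str  # "linear" or "circ"
    name: str    # transcript name or circRNA key
    offset: int  # 0-based start on the (circular) source sequence
    frag_len: int


def junction_capture_probability(
    circ_len: int,
    read_len: int,
    frag_lens: np.ndarray,
    min_overhang: int = 7,
) -> float:
    """Probability that a circle fragment with uniform start offset is
    countable: at least one mate covers the back-splice joint with
    >= ``min_overhang`` bases on its shorter side.

    For fragment length f, mate 1 spans acceptably iff the offset lies
    in A = [L - read_len + min_overhang, L - min_overhang]; mate 2 is
    mate 1 shifted by (f - read_len) around the circle. The union of the
    two offset windows is computed exactly per fragment length and
    averaged over the supplied lengths.
    """
    L = circ_len
    rl = read_len
    lo, hi = L - rl + min_overhang, L - min_overhang
    if hi < lo or rl > 2 * min(149, L):
        return 0.0
    base = np.zeros(L, dtype=bool)
    base[max(lo, 0):hi + 1] = True
    p = 0.0
    for f in np.asarray(frag_lens):
        f = int(np.clip(round(float(f)), rl, L))
        shift = (f - rl) % L
        both = base | np.roll(base, -shift)
        p += both.mean()
    return p / len(frag_lens)


def _apply_errors(rng: np.random.Generator, seq: bytes,
                  error_rate: float) -> bytes:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq, dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < error_rate)
    for i in hit:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes()


def simulate_reads(
    seed: int,
    annotation: SimAnnotation,
    circ_abundance: pd.DataFrame,
    sample_ids: Sequence[str],
    n_linear_fragments: int = 500,
    read_len: int = 75,
    frag_len_mean: float = 250.0,
    frag_len_sd: float = 30.0,
    error_rate: float = 0.0,
    out_dir: str | Path = ".",
    gzip_out: bool = False,
    min_overhang: int = 7,
    dispersion: float = 0.0,
) -> dict[str, dict[str, FragmentOrigin]]:
    """Write one paired FASTQ per sample; return per-sample fragment
    origins (the ground truth for oracle counting).

    Linear fragments are drawn from transcripts (probability
    proportional to length). ``circ_abundance`` is the expected number
    of *countable* junction fragments per (circRNA, sample): the total
    circle fragments drawn are Poisson(abundance / p_capture), where
    p_capture is each circle's junction-capture probability, so the
    countable subset is Poisson(abundance) by thinning regardless of
    circle length. Start offsets are uniform on the circle, making
    junction spanning and overhangs computable from the recorded
    offset. Mate 1 is the fragment's first ``read_len`` bases, mate 2
    the reverse complement of its last ``read_len`` bases.
    """
    if read_len >= frag_len_mean:
        raise ValueError("read_len must be below mean fragment length")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tx_list = sorted(annotation.transcripts.values(), key=lambda t: t.name)
    tx_lens = np.array([t.end - t.start + 1 for t in tx_list], dtype=float)
    tx_probs = tx_lens / tx_lens.sum()
    circ_keys = list(circ_abundance.index)
    circ_seqs = {k: annotation.circ_sequence(k) for k in circ_keys}
    prob_rng = np.random.default_rng([seed, 404_404])
    frag_len_sample = prob_rng.normal(frag_len_mean, frag_len_sd, size=400)
    capture = {k: junction_capture_probability(len(circ_seqs[k]), read_len,
                                               frag_len_sample, min_overhang)
               for k in circ_keys}
    origins: dict[str, dict[str, FragmentOrigin]] = {}
    for sample in sample_ids:
        rng = np.random.default_rng([seed, 505, _stable_id(sample)])
        frags: list[tuple[str, str, int, int]] = []
        n_circ = {}
        for k in circ_keys:
            if capture[k] <= 1e-9:
                n_circ[k] = 0
                continue
            lam = circ_abundance.loc[k, sample] / capture[k]
            if dispersion > 0:
                # gamma-Poisson mixture: negative binomial with
                # Var = lam + dispersion * lam^2
                lam = lam * rng.gamma(1.0 / dispersion, dispersion)
            n_circ[k] = int(rng.poisson(lam))
        tx_draw = rng.choice(len(tx_list), size=n_linear_fragments,
                             p=tx_probs)
        lengths = rng.normal(frag_len_mean, frag_len_sd,
                             size=n_linear_fragments)
        for ti, fl in zip(tx_draw, lengths):
            tx = tx_list[ti]
            tx_len = tx.end - tx.start + 1
            flen = int(np.clip(round(fl), read_len, tx_len))
            offset = int(rng.integers(0, tx_len - flen + 1))
            frags.append(("linear", tx.name, offset, flen))
        for key in circ_keys:
            circ_len = len(circ_seqs[key])
            m = n_circ[key]
            if m == 0:
                continue
            lengths = rng.normal(frag_len_mean, frag_len_sd, size=m)
            offs = rng.integers(0, circ_len, size=m)
            for fl, off in zip(lengths, offs):
                flen = int(np.clip(round(fl), read_len, circ_len))
                frags.append(("circ", key, int(off), flen))
        sample_origins: dict[str, FragmentOrigin] = {}
        opener = gzip.open if gzip_out else open
        suffix = ".fastq.gz" if gzip_out else ".fastq"
        f1 = opener(out_dir / f"{sample}_R1{suffix}", "wt")
        f2 = opener(out_dir / f"{sample}_R2{suffix}", "wt")
        with f1, f2:
            for i, (source, name, offset, flen) in enumerate(frags):
                fid = f"{sample}:frag{i + 1}"
                if source == "linear":
                    tx = annotation.transcripts[name]
                    frag = tx.seq[offset:offset + flen]
                else:
                    circ = circ_seqs[name]
                    frag = (circ + circ)[offset:offset + flen]
                r1 = _apply_errors(rng, frag[:read_len].encode(), error_rate)
                r2 = _apply_errors(rng, revcomp(frag[-read_len:].encode()),
                                   error_rate)
                qual = "I" * read_len
                f1.write(f"@{fid}/1\n{r1.decode()}\n+\n{qual}\n")
                f2.write(f"@{fid}/2\n{r2.decode()}\n+\n{qual}\n")
                sample_origins[fid] = FragmentOrigin(source, name, offset,
                                                     flen)
        origins[sample] = sample_origins
    return origins


def _stable_id(text: str) -> int:
    """Deterministic small integer from a string (sum of bytes-weighted
    positions, independent of PYTHONHASHSEED)."""
    h = 0
    for ch in text.encode():
        h = (h * 131 + ch) % (2 ** 31 - 1)
    return h


# ---------------------------------------------------------------------------
# caller tables
# ---------------------------------------------------------------------------

DEFAULT_SENSITIVITY = {"circall": 0.9, "ciri2": 0.85, "circexplorer2": 0.75}
DEFAULT_FP_RATE = {"circall": 3.0, "ciri2": 3.0, "circexplorer2": 3.0}


def simulate_caller_outputs(
    seed: int,
    annotation: SimAnnotation,
    bsj_truth: pd.DataFrame,
    sample_ids: Sequence[str],
    out_dir: str | Path,
    sensitivity: dict[str, float] | None = None,
    fp_rate: dict[str, float] | None = None,
) -> dict[str, list[str]]:
    """Per-method, per-sample caller tables with controlled agreement.

    Each method detects each true circRNA independently with its
    sensitivity (cohort-wide, mimicking a method's systematic blind
    spots) and contributes Poisson(fp_rate) method-specific false keys.
    Reported BSJ read counts are Poisson draws around the per-sample
    truth. Returns the emitted key set per method.
    """
    sensitivity = dict(DEFAULT_SENSITIVITY if sensitivity is None
                       else sensitivity)
    fp_rate = dict(DEFAULT_FP_RATE if fp_rate is None else fp_rate)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    true_keys = list(bsj_truth.index)
    emitted: dict[str, list[str]] = {}
    genome_lens = {c: len(s) for c, s in annotation.genome.items()}
    chroms = sorted(genome_lens)
    for method in sorted(sensitivity):
        rng = np.random.default_rng([seed, 606, _stable_id(method)])
        detected = [k for k in true_keys
                    if rng.random() < sensitivity[method]]
        n_fp = int(rng.poisson(fp_rate[method]))
        fp_keys = []
        for _ in range(n_fp):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(150, 2000))
            start = int(rng.integers(1, genome_lens[chrom] - length))
            fp_keys.append(f"{chrom}:{start}:{start + length - 1}")
        keys = sorted(set(detected) | set(fp_keys), key=parse_circ_key)
        emitted[method] = keys
        for sample in sample_ids:
            rows = []
            for key in keys:
                chrom, start, end = parse_circ_key(key)
                if key in bsj_truth.index:
                    lam = float(bsj_truth.loc[key, sample])
                else:
                    lam = 2.0
                reads = int(rng.poisson(lam))
                if reads == 0:
                    continue
                rows.append((chrom, start, end, reads))
            _write_caller_table(out_dir / f"{method}_{sample}.tsv",
                                method, rows)
    return emitted


def _write_caller_table(path: Path, method: str,
                        rows: list[tuple[str, int, int, int]]) -> None:
    with open(path, "w") as fh:
        if method == "ciri2":
            fh.write("circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t"
                     "junction_reads\tstrand\n")
            for chrom, start, end, reads in rows:
                fh.write(f"{chrom}:{start}:{end}\t{chrom}\t{start}\t{end}\t"
                         f"{reads}\t.\n")
        elif method == "circall":
            fh.write("Chr\tStart\tEnd\tStrand\tJunctionRead\n")
            for chrom, start, end, reads in rows:
                fh.write(f"{chrom}\t{start}\t{end}\t.\t{reads}\n")
        else:  # circexplorer2 / generic bed: 0-based half-open
            for chrom, start, end, reads in rows:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t"
                         f"{chrom}:{start}:{end}\t{reads}\t.\n")


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas_sumstats(
    seed: int,
    genotypes: GenotypeMatrix,
    causal_variant_id: str,
    trait: str,
    h2: float = 0.01,
    n_gwas: int = 20_000,
    trait_type: str = "cc",
    case_fraction: float = 0.4,
    rho: float = 0.0,
) -> SummaryStats:
    """Marginal per-variant GWAS statistics from a latent liability.

    An independent panel of ``n_gwas`` individuals is generated at the
    cohort's allele frequencies (same copying-with-recombination LD
    process), a liability with heritable fraction ``h2`` at the causal
    variant is drawn, and each variant is regressed marginally on the
    liability — cheaper than case-control sampling and exact at the
    level of (beta, se) inputs to colocalization.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0,1)")
    rng = np.random.default_rng([seed, 707, _stable_id(trait)])
    mafs = genotypes.dosages.mean(axis=1) / 2.0
    hap = _haplotypes(rng, 2 * n_gwas, mafs, rho)
    g = (hap[:, :n_gwas] + hap[:, n_gwas:]).astype(float)
    vids = genotypes.variant_ids()
    ci = vids.index(causal_variant_id)
    gc = g[ci]
    var_gc = gc.var()
    if var_gc == 0:
        raise ValueError("causal variant is monomorphic in the GWAS panel")
    b_causal = np.sqrt(h2 / ((1 - h2) * var_gc))
    y = b_causal * gc + rng.normal(size=n_gwas)
    y = y - y.mean()
    gc_ = g - g.mean(axis=1, keepdims=True)
    sgg = np.einsum("ij,ij->i", gc_, gc_)
    sgy = gc_ @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sgy / sgg
        rss = float(y @ y) - beta * sgy
        se = np.sqrt(np.maximum(rss, 0) / (n_gwas - 2) / sgg)
    ok = (sgg > 0) & (se > 0)
    table = pd.DataFrame({"variant_id": [v for v, k in zip(vids, ok) if k],
                          "beta": beta[ok], "se": se[ok],
                          "n": n_gwas})
    return SummaryStats(trait=trait, trait_type=trait_type, table=table,
                        case_fraction=case_fraction
                        if trait_type == "cc" else None)


# ---------------------------------------------------------------------------
# full-scenario truth bundle
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth for one simulated scenario."""

    circ_keys: list[str]
    sample_ids: list[str]
    expected_abundance: pd.DataFrame
    planted_qtls: list[PlantedQTL]
    gwas_truth: dict[str, dict]
    caller_truth: dict[str, list[str]]
    origins: dict[str, dict[str, FragmentOrigin]] = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "circ_keys": self.circ_keys,
            "sample_ids": self.sample_ids,
            "expected_abundance": {
                k: [round(float(x), 6) for x in row]
                for k, row in self.expected_abundance.iterrows()},
            "planted_qtls": [q.__dict__ for q in self.planted_qtls],
            "gwas_truth": self.gwas_truth,
            "caller_truth": self.caller_truth,
            "origins": {
                s: {fid: [o.source, o.name, o.offset, o.frag_len]
                    for fid, o in sorted(per.items())}
                for s, per in sorted(self.origins.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=None,
                      separators=(",", ":"))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        abundance = pd.DataFrame(
            {k: d["expected_abundance"][k] for k in d["circ_keys"]},
        ).T
        abundance.columns = d["sample_ids"]
        return cls(
            circ_keys=d["circ_keys"],
            sample_ids=d["sample_ids"],
            expected_abundance=abundance,
            planted_qtls=[PlantedQTL(**q) for q in d["planted_qtls"]],
            gwas_truth=d["gwas_truth"],
            caller_truth=d["caller_truth"],
            origins={s: {fid: FragmentOrigin(*o) for fid, o in per.items()}
                     for s, per in d["origins"].items()},
        )
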