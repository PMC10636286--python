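"""Pseudo circRNA references and junction-fragment counting.

A circRNA is quantified against a *pseudo reference*: the ``arm_len``
bases ending at the circle's end coordinate, concatenated with the
``arm_len`` bases starting at its start coordinate. A read produced
across the back-splice junction aligns contiguously to this sequence
while no linear transcript contains it. ``arm_len`` is 149 by default,
truncated to the circle length for short circles.

Read placement uses a deterministic seed-and-extend contract: exact
k-mer seeds (disjoint, so any alignment with at most ``max_mismatches``
substitutions is guaranteed a hit when the read holds at least
``max_mismatches + 1`` disjoint seeds), followed by ungapped full-length
comparison. Alignments are end-to-end: the read must be fully contained
in the reference. Reads longer than an arm can therefore never be
counted for that circle; rolling-circle multi-lap reads are out of
scope.

Counting follows two rules. A fragment is discarded when both mates map
end-to-end to the same linear transcript on opposite strands (it is
explainable by the linear transcriptome). A surviving fragment is
counted for a circRNA when at least one mate's alignment covers the
junction with at least ``min_overhang`` (default 7) bases on its shorter
side; a fragment eligible for several circRNAs is assigned to the one
with the fewest total mismatches, ties broken lexicographically.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusSet
from .formats import parse_circ_key

log = logging.getLogger(__name__)

DEFAULT_FLANK_LEN = 149
DEFAULT_MIN_OVERHANG = 7
DEFAULT_SEED_K = 21
DEFAULT_MAX_MISMATCHES = 2

_RC = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: bytes) -> bytes:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class PseudoReference:
    """Junction-spanning reference sequence for one circRNA."""

    key: str
    sequence: str
    arm_len: int

    @property
    def junction_index(self) -> int:
        """1-based position of the last upstream-arm base."""
        return self.arm_len

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.arm_len:
            raise ValueError("pseudo reference length must be 2*arm_len")


def build_pseudo_reference(genome: dict[str, str], key: str,
                           flank_len: int = DEFAULT_FLANK_LEN) -> PseudoReference:
    """Concatenate the upstream arm of ``end`` with the downstream arm of
    ``start`` (both 1-based inclusive circle boundaries)."""
    chrom, start, end = parse_circ_key(key)
    if chrom not in genome:
        raise KeyError(f"chrom {chrom!r} of {key} not in genome")
    if start >= end:
        raise ValueError(f"degenerate circle {key}")
    seq = genome[chrom]
    if end > len(seq) or start < 1:
        raise ValueError(f"{key} outside chromosome bounds (len {len(seq)})")
    circ_len = end - start + 1
    arm = min(flank_len, circ_len)
    upstream = seq[end - arm:end]          # genome[end-arm+1 .. end]
    downstream = seq[start - 1:start - 1 + arm]  # genome[start .. start+arm-1]
    return PseudoReference(key=key, sequence=upstream + downstream, arm_len=arm)


@dataclass(frozen=True)
class Alignment:
    """Ungapped end-to-end placement of one read on one reference."""

    ref: str
    start: int  # 1-based position of the read's first base on the reference
    strand: str
    mismatches: int
    read_len: int

    @property
    def end(self) -> int:
        return self.start + self.read_len - 1

    def overhangs(self, junction_index: int) -> tuple[int, int]:
        """(left, right) bases of this alignment on each side of the BSJ."""
        left = min(self.end, junction_index) - self.start + 1
        left = max(0, min(left, self.read_len))
        return left, self.read_len - left


class KmerIndex:
    """Exact k-mer lookup over a set of named reference sequences."""

    def __init__(self, refs: dict[str, str], k: int = DEFAULT_SEED_K):
        self.k = k
        self.names = sorted(refs)
        self.seqs = {name: refs[name].upper().encode() for name in self.names}
        self.arrays = {name: np.frombuffer(s, dtype=np.uint8)
                       for name, s in self.seqs.items()}
        index: dict[bytes, list[tuple[str, int]]] = {}
        for name in self.names:
            s = self.seqs[name]
            for pos in range(len(s) - k + 1):
                index.setdefault(s[pos:pos + k], []).append((name, pos))
        self._index = index

    def _seed_offsets(self, read_len: int,
                      max_mismatches: int) -> list[int]:
        # max_mismatches+1 disjoint seeds guarantee one exact seed for any
        # alignment with <= max_mismatches substitutions (pigeonhole);
        # shorter reads degrade gracefully to fewer seeds.
        n_seeds = min(max_mismatches + 1, read_len // self.k)
        if n_seeds == 0 and read_len >= self.k:
            n_seeds = 1
        return [i * self.k for i in range(n_seeds)]

    def align_oriented(self, read: bytes,
                       max_mismatches: int) -> list[Alignment]:
        """End-to-end hits of ``read`` as given (no reverse complement)."""
        L = len(read)
        if L < self.k:
            return []
        read_arr = np.frombuffer(read, dtype=np.uint8)
        hits: dict[tuple[str, int], int] = {}
        for off in self._seed_offsets(L, max_mismatches):
            for name, pos in self._index.get(read[off:off + self.k], ()):
                start0 = pos - off
                if start0 < 0 or (name, start0) in hits:
                    continue
                ref_seq = self.seqs[name]
                if start0 + L > len(ref_seq):
                    continue
                if ref_seq[start0:start0 + L] == read:
                    mm = 0
                else:
                    window = self.arrays[name][start0:start0 + L]
                    mm = int(np.count_nonzero(window != read_arr))
                if mm <= max_mismatches:
                    hits[(name, start0)] = mm
        return [Alignment(ref=name, start=start0 + 1, strand="+",
                          mismatches=mm, read_len=L)
                for (name, start0), mm in sorted(hits.items())]

    def align(self, read: bytes, max_mismatches: int) -> list[Alignment]:
        """Hits of the read on both strands of the references."""
        fwd = self.align_oriented(read, max_mismatches)
        rev = [Alignment(ref=a.ref, start=a.start, strand="-",
                         mismatches=a.mismatches, read_len=a.read_len)
               for a in self.align_oriented(revcomp(read), max_mismatches)]
        return fwd + rev


def map_to_pseudo(read: bytes, index: KmerIndex,
                  max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> list[Alignment]:
    """Best end-to-end placements of a read on the pseudo references.

    Returns all alignments sharing the minimal mismatch count (the
    downstream counting tie-break decides between references).
    """
    hits = index.align(read, max_mismatches)
    if not hits:
        return []
    best = min(a.mismatches for a in hits)
    return [a for a in hits if a.mismatches == best]


def fragment_is_linear(r1: bytes, r2: bytes, transcript_index: KmerIndex,
                       max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> bool:
    """True when both mates map end-to-end to one transcript on opposite
    strands — i.e. the fragment is fully explained by a linear transcript."""
    h1 = transcript_index.align(r1, max_mismatches)
    if not h1:
        return False
    h2 = transcript_index.align(r2, max_mismatches)
    if not h2:
        return False
    seen1 = {(a.ref, a.strand) for a in h1}
    return any((a.ref, "+" if a.strand == "-" else "-") in seen1 for a in h2)


def filter_linear_reads(
    fragments: Iterable[tuple[str, bytes, bytes]],
    transcript_index: KmerIndex | None,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> Iterator[tuple[str, bytes, bytes]]:
    """Drop fragments where both mates are end-to-end linear-transcript
    matches; everything else passes through."""
    if transcript_index is None or not transcript_index.names:
        log.warning("empty transcriptome: linear filtering disabled")
        yield from fragments
        return
    for fid, r1, r2 in fragments:
        if not fragment_is_linear(r1, r2, transcript_index, max_mismatches):
            yield fid, r1, r2


def assign_fragment(
    mate_alignments: Sequence[Sequence[Alignment]],
    junction_index: dict[str, int],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> str | None:
    """Decide which circRNA (if any) a fragment counts toward.

    ``mate_alignments`` holds the pseudo-reference alignments of each
    mate. A reference is eligible when at least one mate's alignment has
    min(left, right) junction overhang >= ``min_overhang``; among
    eligible references the fragment goes to the one with the fewest
    total mismatches (summed over mates aligned to it), ties broken by
    key.
    """
    eligible: set[str] = set()
    total_mm: dict[str, int] = {}
    for alns in mate_alignments:
        for a in alns:
            total_mm[a.ref] = total_mm.get(a.ref, 0) + a.mismatches
            left, right = a.overhangs(junction_index[a.ref])
            if left > 0 and right > 0 and min(left, right) >= min_overhang:
                eligible.add(a.ref)
    if not eligible:
        return None
    return min(eligible, key=lambda key: (total_mm[key], key))


# ---------------------------------------------------------------------------
# FASTQ access and cohort-level driver
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fragments(fastq1: str | Path,
                   fastq2: str | Path) -> Iterator[tuple[str, bytes, bytes]]:
    """Yield (fragment_id, mate1, mate2) from a paired FASTQ."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gzip(fastq1) as fh1, _open_maybe_gzip(fastq2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, _), (t2, s2, _) in zip(it1, it2, strict=True):
            fid = t1.split()[0].removesuffix("/1")
            fid2 = t2.split()[0].removesuffix("/2")
            if fid != fid2:
                raise ValueError(f"unpaired reads {t1!r} / {t2!r}")
            yield fid, s1.upper().encode(), s2.upper().encode()


def quantify_sample(
    fragments: Iterable[tuple[str, bytes, bytes]],
    pseudo_index: KmerIndex,
    junction_index: dict[str, int],
    transcript_index: KmerIndex | None,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> dict[str, int]:
    """Junction-fragment counts for one sample (key -> count)."""
    counts = {key: 0 for key in junction_index}
    for fid, r1, r2 in filter_linear_reads(fragments, transcript_index,
                                           max_mismatches):
        alns1 = map_to_pseudo(r1, pseudo_index, max_mismatches)
        alns2 = map_to_pseudo(r2, pseudo_index, max_mismatches)
        key = assign_fragment((alns1, alns2), junction_index, min_overhang)
        if key is not None:
            counts[key] += 1
    return counts


def quantify_cohort(
    samples: Sequence[tuple[str, str | Path, str | Path]],
    consensus: ConsensusSet | Sequence[str],
    genome: dict[str, str],
    transcriptome: dict[str, str],
    flank_len: int = DEFAULT_FLANK_LEN,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    seed_k: int = DEFAULT_SEED_K,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> tuple[pd.DataFrame, dict[str, PseudoReference]]:
    """Count junction fragments for every candidate in every sample.

    Parameters
    ----------
    samples:
        ``(sample_id, fastq1, fastq2)`` triples.
    consensus:
        The candidate set (or a plain list of circRNA keys).

    Returns the integer count matrix (rows = circRNA keys, columns =
    sample ids, in input order) and the pseudo references used.
    """
    keys = list(consensus.candidates if isinstance(consensus, ConsensusSet)
                else consensus)
    if not keys:
        raise ValueError("empty candidate set")
    refs = {key: build_pseudo_reference(genome, key, flank_len)
            for key in keys}
    pseudo_index = KmerIndex({k: r.sequence for k, r in refs.items()},
                             k=seed_k)
    junction_index = {k: r.junction_index for k, r in refs.items()}
    transcript_index = (KmerIndex(transcriptome, k=seed_k)
                        if transcriptome else None)
    mat = pd.DataFrame(0, index=keys,
                       columns=[s for s, _, _ in samples], dtype=int)
    for sample_id, fq1, fq2 in samples:
        frags = iter_fragments(fq1, fq2)
        counts = quantify_sample(frags, pseudo_index, junction_index,
                                 transcript_index, min_overhang,
                                 max_mismatches)
        col = pd.Series(counts)
        if col.sum() == 0:
            log.warning("sample %s: no junction fragments", sample_id)
        mat[sample_id] = col
    return mat, refs


def write_counts(mat: pd.DataFrame, path: str | Path,
                 header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        mat.to_csv(fh, sep="\t", index_label="key")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="key", comment="#")
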