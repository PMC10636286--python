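"""Two-stage consensus filter over multi-caller BSJ detections.

Stage 1 keeps, per caller, the junctions that caller itself saw with at
least ``min_bsj`` supporting reads in at least one sample. Stage 2 keeps
the junctions detected by at least ``k`` callers. Junctions are matched
exactly on ``chrom:start:end`` (harmonization has already removed
coordinate-convention offsets; strand is deliberately ignored because
callers disagree on it far more often than on coordinates).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .formats import CircRNACall, ConfigError, circ_key_sort_tuple, parse_circ_key


@dataclass
class ConsensusSet:
    """High-confidence circRNA candidates and their per-method support."""

    candidates: list[str]
    support: dict[str, frozenset[str]]
    per_method_counts: dict[str, int]
    k: int

    def support_breakdown(self) -> dict[int, int]:
        """Number of candidates detected by exactly 3, 2, 1 ... methods."""
        out: dict[int, int] = defaultdict(int)
        for key in self.candidates:
            out[len(self.support[key])] += 1
        return dict(sorted(out.items(), reverse=True))


def filter_min_bsj_reads(calls: Iterable[CircRNACall],
                         min_bsj: int = 2,
                         methods: Iterable[str] | None = None
                         ) -> dict[str, set[str]]:
    """Per-method junction sets after the read-support filter.

    A junction survives for a method iff that method reported it with
    ``bsj_reads >= min_bsj`` in at least one sample. ``methods`` fixes
    the method universe (a caller with no surviving calls still counts
    toward the consensus denominator with an empty set).
    """
    best: dict[tuple[str, str], int] = {}
    for c in calls:
        k = (c.method, c.key)
        if c.bsj_reads > best.get(k, -1):
            best[k] = c.bsj_reads
    out: dict[str, set[str]] = defaultdict(set)
    if methods is not None:
        for m in methods:
            out[m] = set()
    for (method, key), reads in best.items():
        if reads >= min_bsj:
            out[method].add(key)
    return dict(out)


def consensus_filter(per_method_sets: Mapping[str, set[str]],
                     k: int) -> ConsensusSet:
    """Keep junctions supported by at least ``k`` methods (k=1: union)."""
    n_methods = len(per_method_sets)
    if not 1 <= k <= max(n_methods, 1):
        raise ConfigError(
            f"consensus cutoff k={k} invalid for {n_methods} methods")
    support: dict[str, set[str]] = defaultdict(set)
    for method, keys in per_method_sets.items():
        for key in keys:
            support[key].add(method)
    candidates = sorted(
        (key for key, methods in support.items() if len(methods) >= k),
        key=circ_key_sort_tuple,
    )
    return ConsensusSet(
        candidates=candidates,
        support={key: frozenset(support[key]) for key in candidates},
        per_method_counts={m: len(s) for m, s in sorted(per_method_sets.items())},
        k=k,
    )


def write_consensus(cs: ConsensusSet, bed_path: str | Path,
                    support_path: str | Path) -> None:
    """Candidate BED (0-based half-open) plus a key -> methods TSV."""
    with open(bed_path, "w") as fh:
        for key in cs.candidates:
            chrom, start, end = parse_circ_key(key)
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{key}\t"
                     f"{len(cs.support[key])}\t.\n")
    with open(support_path, "w") as fh:
        fh.write("key\tmethods\n")
        for key in cs.candidates:
            fh.write(f"{key}\t{','.join(sorted(cs.support[key]))}\n")
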