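"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's k-mer seeding, alignment and
log-space code paths: counting decisions are recomputed from the
simulator's ground-truth fragment origins with direct string
comparisons, and colocalization posteriors by naive linear-space
summation.
"""

from __future__ import annotations

import numpy as np

from circqtl.simulate import FragmentOrigin, SimAnnotation
from circqtl.formats import parse_circ_key


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b, strict=True))


def _mate_linear(read: str, tx_seq: str, anchor: int,
                 max_mm: int) -> bool:
    """End-to-end linear placement of a junction-wrapping mate at the
    given transcript anchor (0-based), allowing <= max_mm mismatches."""
    if anchor < 0 or anchor + len(read) > len(tx_seq):
        return False
    return _hamming(read, tx_seq[anchor:anchor + len(read)]) <= max_mm


def oracle_fragment_count(
    origin: FragmentOrigin,
    annotation: SimAnnotation,
    circ_to_tx: dict[str, tuple[str, int]],
    read_len: int,
    flank_len: int = 149,
    min_overhang: int = 7,
    max_mismatches: int = 2,
) -> str | None:
    """Which circRNA key (if any) an error-free fragment counts toward,
    decided from its ground-truth origin and offset.

    ``circ_to_tx`` maps circRNA key -> (transcript name, 0-based offset
    of the circle start within the transcript). Linear-origin fragments
    never count. A circle-origin fragment counts for its own circRNA iff
    at least one mate wraps the back-splice joint with min(left, right)
    >= min_overhang, both wrapped pieces fit the pseudo-reference arms,
    and the fragment is not discarded by the linear filter (i.e. not
    both mates end-to-end transcript matches).
    """
    if origin.source == "linear":
        return None
    key = origin.name
    chrom, start, end = parse_circ_key(key)
    L = end - start + 1
    arm = min(flank_len, L)
    tx_name, circ_off = circ_to_tx[key]
    tx_seq = annotation.transcripts[tx_name].seq
    circ = annotation.circ_sequence(key)
    doubled = circ + circ

    # mate start offsets on the circle (mate 2 read spans the fragment end)
    o1 = origin.offset
    o2 = (origin.offset + origin.frag_len - read_len) % L

    mate_spans = []
    mate_is_linear = []
    for o in (o1, o2):
        wraps = o + read_len > L
        read = doubled[o:o + read_len]
        if not wraps:
            mate_is_linear.append(read in tx_seq)
            mate_spans.append(False)
            continue
        left = L - o
        right = read_len - left
        # left-anchored and right-anchored end-to-end linear placements
        linear = (_mate_linear(read, tx_seq, circ_off + o, max_mismatches)
                  or _mate_linear(read, tx_seq, circ_off - left,
                                  max_mismatches))
        mate_is_linear.append(linear)
        fits = left <= arm and right <= arm
        mate_spans.append(fits and min(left, right) >= min_overhang)
    if all(mate_is_linear):
        return None
    return key if any(mate_spans) else None


def oracle_count_matrix(
    origins: dict[str, dict[str, FragmentOrigin]],
    annotation: SimAnnotation,
    keys: list[str],
    read_len: int,
    flank_len: int = 149,
    min_overhang: int = 7,
    max_mismatches: int = 2,
):
    """Brute-force (key x sample) junction-fragment counts from ground
    truth, as a plain dict-of-dicts."""
    circ_to_tx: dict[str, tuple[str, int]] = {}
    for key in keys:
        chrom, start, end = parse_circ_key(key)
        for tx in annotation.transcripts.values():
            if tx.chrom == chrom and tx.start <= start and end <= tx.end:
                circ_to_tx[key] = (tx.name, start - tx.start)
                break
        else:
            raise AssertionError(f"{key} not inside any transcript")
    counts = {k: {s: 0 for s in origins} for k in keys}
    for sample, per in origins.items():
        for origin in per.values():
            if origin.source != "circ" or origin.name not in circ_to_tx:
                continue
            key = oracle_fragment_count(origin, annotation, circ_to_tx,
                                        read_len, flank_len, min_overhang,
                                        max_mismatches)
            if key is not None:
                counts[key][sample] += 1
    return counts


def naive_coloc_posteriors(labf1, labf2, p1, p2, p12) -> np.ndarray:
    """Direct linear-space hypothesis sums (overflow-prone; only for
    small, moderate-evidence loci)."""
    bf1 = np.exp(np.asarray(labf1, dtype=float))
    bf2 = np.exp(np.asarray(labf2, dtype=float))
    s1, s2 = bf1.sum(), bf2.sum()
    s12 = float(bf1 @ bf2)
    h = np.array([1.0, p1 * s1, p2 * s2,
                  max(p1 * p2 * (s1 * s2 - s12), 0.0), p12 * s12])
    return h / h.sum()


def exhaustive_permutation_pvalue(y: np.ndarray, g: np.ndarray,
                                  n_perm: int, rng: np.random.Generator
                                  ) -> float:
    """Plain full-enumeration permutation p for the best association:
    re-runs the per-variant correlation scan for every permutation."""
    from scipy import stats

    n = y.size
    dof = n - 2
    def best_p(vec):
        ps = []
        for row in g:
            r = np.corrcoef(vec, row)[0, 1]
            r2 = min(r * r, 1 - 1e-15)
            t = np.sqrt(dof * r2 / (1 - r2))
            ps.append(2 * stats.t.sf(t, dof))
        return min(ps)
    obs = best_p(y)
    hits = sum(best_p(y[rng.permutation(n)]) <= obs for _ in range(n_perm))
    return (1 + hits) / (1 + n_perm)
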