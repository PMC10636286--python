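import numpy as np
import pytest

from circqtl import pseudo_quant as pq
from circqtl.pseudo_quant import (Alignment, KmerIndex, assign_fragment,
                                  build_pseudo_reference,
                                  fragment_is_linear, map_to_pseudo,
                                  quantify_cohort, revcomp)
from circqtl.simulate import simulate_reads, expected_junction_abundance


def _random_genome(rng, length=5000, chrom="chr1"):
    return {chrom: rng.choice(np.frombuffer(b"ACGT", np.uint8),
                              size=length).tobytes().decode()}


class TestBuildPseudoReference:
    def test_arm_sequences_and_junction(self, rng):
        g = _random_genome(rng)
        ref = build_pseudo_reference(g, "chr1:1000:1600")
        seq = g["chr1"]
        # 1-based [1452..1600] ++ [1000..1148]
        assert ref.sequence == seq[1451:1600] + seq[999:1148]
        assert len(ref.sequence) == 298
        assert ref.junction_index == 149

    def test_short_circle_truncates_arms(self, rng):
        g = _random_genome(rng)
        ref = build_pseudo_reference(g, "chr1:1000:1099")
        assert ref.arm_len == 100
        assert len(ref.sequence) == 200
        assert ref.sequence == g["chr1"][999:1099] * 2

    def test_out_of_bounds_rejected(self, rng):
        g = _random_genome(rng, length=1200)
        with pytest.raises(ValueError):
            build_pseudo_reference(g, "chr1:1000:1600")

    def test_junction_kmer_absent_from_transcripts(self, annotation):
        """The 30-mer straddling each simulated junction never occurs in
        the linear transcriptome (the pseudo reference is circle-specific)."""
        for key in annotation.circ_keys:
            ref = build_pseudo_reference(annotation.genome, key)
            j = ref.junction_index
            kmer = ref.sequence[j - 15:j + 15]
            assert not any(kmer in t.seq
                           for t in annotation.transcripts.values())


class TestMapToPseudo:
    def _index(self, rng, n=3):
        g = _random_genome(rng, 20000)
        refs = {f"chr1:{1000 + i * 3000}:{1000 + i * 3000 + 600}":
                build_pseudo_reference(g, f"chr1:{1000 + i * 3000}:"
                                       f"{1000 + i * 3000 + 600}")
                for i in range(n)}
        return refs, KmerIndex({k: r.sequence for k, r in refs.items()})

    def test_exact_substring_single_hit(self, rng):
        refs, idx = self._index(rng)
        key = sorted(refs)[0]
        read = refs[key].sequence[100:175].encode()
        hits = map_to_pseudo(read, idx)
        assert [(h.ref, h.start, h.mismatches) for h in hits] == \
            [(key, 101, 0)]

    def test_reverse_complement_found(self, rng):
        refs, idx = self._index(rng)
        key = sorted(refs)[0]
        read = revcomp(refs[key].sequence[100:175].encode())
        hits = map_to_pseudo(read, idx)
        assert len(hits) == 1 and hits[0].strand == "-"
        assert hits[0].start == 101

    def test_no_hit_for_foreign_sequence(self, rng):
        _, idx = self._index(rng)
        read = ("ACGT" * 20)[:75].encode()
        assert map_to_pseudo(read, idx) == []

    def test_shared_arm_returns_both_references(self, rng):
        """Two references sharing a downstream arm tie on reads inside it."""
        g = _random_genome(rng, 20000)
        a = build_pseudo_reference(g, "chr1:2000:2600")
        shared = a.sequence[149:]  # downstream arm (starts at start coord)
        b_seq = build_pseudo_reference(g, "chr1:9000:9600").sequence[:149] \
            + shared
        idx = KmerIndex({"a": a.sequence, "b": b_seq})
        read = shared[10:85].encode()
        hits = map_to_pseudo(read, idx)
        assert sorted(h.ref for h in hits) == ["a", "b"]

    def test_mismatches_counted_and_capped(self, rng):
        refs, idx = self._index(rng)
        key = sorted(refs)[0]
        read = bytearray(refs[key].sequence[100:175].encode())
        for pos in (30, 60):
            read[pos] = ord("A") if read[pos] != ord("A") else ord("C")
        assert map_to_pseudo(bytes(read), idx)[0].mismatches == 2
        read[45] = ord("A") if read[45] != ord("A") else ord("C")
        assert map_to_pseudo(bytes(read), idx) == []


class TestOverhangs:
    @pytest.mark.parametrize("start,end,expected", [
        (143, 217, (7, 68)),   # exactly the 7-base minimum on the left
        (144, 218, (6, 69)),   # one base short
        (150, 224, (0, 75)),   # does not span the junction
    ])
    def test_overhang_accounting(self, start, end, expected):
        a = Alignment("k", start, "+", 0, end - start + 1)
        assert a.overhangs(149) == expected

    def test_boundary_sweep_matches_enumeration(self, rng):
        """Slide a 75-mer over a 298-nt pseudo reference: the counted
        offsets are exactly those with min(left, right) >= 7."""
        g = _random_genome(rng, 5000)
        ref = build_pseudo_reference(g, "chr1:1000:1600")
        idx = KmerIndex({ref.key: ref.sequence})
        junction = {ref.key: ref.junction_index}
        counted = set()
        for s in range(len(ref.sequence) - 75 + 1):
            read = ref.sequence[s:s + 75].encode()
            hits = map_to_pseudo(read, idx)
            if assign_fragment([hits], junction) is not None:
                counted.add(s)
        expected = {s for s in range(224)
                    if min(max(149 - s, 0), 75 - max(149 - s, 0)) >= 7}
        assert counted == expected


class TestLinearFilter:
    def _setup(self, rng):
        g = _random_genome(rng, 9000)
        tx = {"tx1": g["chr1"][1000:4000], "tx2": g["chr1"][5000:8000]}
        return g, tx, KmerIndex(tx)

    def test_proper_pair_discarded(self, rng):
        _, tx, idx = self._setup(rng)
        frag = tx["tx1"][100:350]
        r1 = frag[:75].encode()
        r2 = revcomp(frag[-75:].encode())
        assert fragment_is_linear(r1, r2, idx)

    def test_junction_spanning_mate_survives(self, rng, annotation):
        tx_index = KmerIndex(annotation.transcript_seqs())
        key = annotation.circ_keys[0]
        ref = build_pseudo_reference(annotation.genome, key)
        j = ref.junction_index
        r1 = ref.sequence[j - 37:j + 38].encode()  # centered on the BSJ
        r2 = revcomp(ref.sequence[j - 60:j + 15].encode())
        assert not fragment_is_linear(r1, r2, tx_index)

    def test_mismatch_threshold(self, rng):
        _, tx, idx = self._setup(rng)
        frag = tx["tx1"][100:350]
        r1 = bytearray(frag[:75].encode())
        # two seed windows hit, one left intact: detection stays guaranteed
        for pos in (10, 30, 40):
            r1[pos] = ord("A") if r1[pos] != ord("A") else ord("C")
        r2 = revcomp(frag[-75:].encode())
        assert not fragment_is_linear(bytes(r1), r2, idx,
                                      max_mismatches=2)
        assert fragment_is_linear(bytes(r1), r2, idx, max_mismatches=3)


class TestAssignFragment:
    J = {"a": 149, "b": 149}

    def test_counted_once_when_both_mates_span(self):
        alns = ([Alignment("a", 120, "+", 0, 75)],
                [Alignment("a", 130, "-", 0, 75)])
        assert assign_fragment(alns, self.J) == "a"

    def test_tie_broken_by_fewest_mismatches_then_key(self):
        alns = ([Alignment("b", 120, "+", 1, 75),
                 Alignment("a", 120, "+", 0, 75)],)
        assert assign_fragment(alns, self.J) == "a"
        tie = ([Alignment("b", 120, "+", 1, 75),
                Alignment("a", 120, "+", 1, 75)],)
        assert assign_fragment(tie, self.J) == "a"

    def test_non_spanning_alignments_do_not_count(self):
        alns = ([Alignment("a", 150, "+", 0, 75)],
                [Alignment("a", 10, "+", 0, 75)])
        assert assign_fragment(alns, self.J) is None


class TestQuantifyCohort:
    def _cohort(self, annotation, tmp_path, n_samples=2, abundance=12.0):
        samples = [f"s{i + 1:03d}" for i in range(n_samples)]
        import pandas as pd
        ab = pd.DataFrame(abundance, index=annotation.circ_keys,
                          columns=samples)
        simulate_reads(11, annotation, ab, samples,
                       n_linear_fragments=300, out_dir=tmp_path)
        return [(s, tmp_path / f"{s}_R1.fastq",
                 tmp_path / f"{s}_R2.fastq") for s in samples]

    def test_sample_order_equivariance(self, annotation, tmp_path):
        samples = self._cohort(annotation, tmp_path)
        mat1, _ = quantify_cohort(samples, annotation.circ_keys,
                                  annotation.genome,
                                  annotation.transcript_seqs())
        mat2, _ = quantify_cohort(samples[::-1], annotation.circ_keys,
                                  annotation.genome,
                                  annotation.transcript_seqs())
        assert (mat1 == mat2[mat1.columns]).all().all()

    def test_no_double_counting(self, annotation, tmp_path):
        samples = self._cohort(annotation, tmp_path, n_samples=1)
        mat, _ = quantify_cohort(samples, annotation.circ_keys,
                                 annotation.genome,
                                 annotation.transcript_seqs())
        n_frags = sum(1 for _ in pq.iter_fragments(samples[0][1],
                                                   samples[0][2]))
        assert mat.to_numpy().sum() <= n_frags

    def test_empty_candidate_set_rejected(self, annotation):
        with pytest.raises(ValueError):
            quantify_cohort([], [], annotation.genome,
                            annotation.transcript_seqs())
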