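import hashlib

import numpy as np
import pandas as pd
import pytest

from circqtl import simulate
from circqtl.consensus import consensus_filter, filter_min_bsj_reads
from circqtl.formats import parse_caller_output, parse_circ_key, read_vcf_dosages
from circqtl.pseudo_quant import build_pseudo_reference
from circqtl.simulate import (junction_capture_probability,
                              simulate_caller_outputs,
                              simulate_genome_and_annotation,
                              simulate_genotypes, simulate_gwas_sumstats,
                              simulate_reads, write_vcf)


def _hash_file(path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestGenomeAnnotation:
    def test_seeded_rerun_is_identical(self):
        a = simulate_genome_and_annotation(3, n_circ=5, n_transcripts=4)
        b = simulate_genome_and_annotation(3, n_circ=5, n_transcripts=4)
        assert a.genome == b.genome
        assert a.circ_keys == b.circ_keys

    def test_requested_circ_count(self, annotation):
        assert len(annotation.circ_keys) == 8

    def test_circles_inside_transcripts(self, annotation):
        for key in annotation.circ_keys:
            chrom, start, end = parse_circ_key(key)
            assert any(t.chrom == chrom and t.start <= start
                       and end <= t.end
                       for t in annotation.transcripts.values())

    def test_short_circles_supported(self):
        ann = simulate_genome_and_annotation(5, n_circ=3, n_short_circ=2)
        lens = sorted(e - s + 1 for _, s, e in
                      map(parse_circ_key, ann.circ_keys))
        assert sum(1 for L in lens if L < 149) == 2


class TestGenotypes:
    def test_maf_within_binomial_ci(self):
        gm = simulate_genotypes(1, n_samples=500, n_variants=50,
                                maf_range=(0.3, 0.3))
        af = gm.dosages.mean(axis=1) / 2
        maf = np.minimum(af, 1 - af)
        se = np.sqrt(0.3 * 0.7 / 1000)
        assert np.all(np.abs(maf - 0.3) < 5 * se)

    def test_independent_variants_uncorrelated(self):
        gm = simulate_genotypes(2, n_samples=800, n_variants=20, rho=0.0)
        cors = [abs(np.corrcoef(gm.dosages[i], gm.dosages[i + 1])[0, 1])
                for i in range(19)]
        assert np.median(cors) < 0.1

    def test_ld_copying_creates_correlation(self):
        gm = simulate_genotypes(2, n_samples=800, n_variants=20, rho=0.9)
        cors = [np.corrcoef(gm.dosages[i], gm.dosages[i + 1])[0, 1]
                for i in range(19)]
        assert np.median(cors) > 0.5

    def test_vcf_roundtrip(self, tmp_path, genotypes):
        p = tmp_path / "g.vcf"
        write_vcf(genotypes, p)
        gm = read_vcf_dosages(p, maf_min=0.0)
        assert gm.sample_ids == genotypes.sample_ids
        np.testing.assert_allclose(gm.dosages, genotypes.dosages)

    def test_no_palindromic_alleles(self, genotypes):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        assert all(v.alt != comp[v.ref] for v in genotypes.variants)


class TestReads:
    def _abundance(self, annotation, samples, value=15.0):
        return pd.DataFrame(value, index=annotation.circ_keys,
                            columns=samples)

    def test_seeded_fastq_bytes_stable(self, annotation, tmp_path):
        samples = ["s001"]
        ab = self._abundance(annotation, samples)
        h = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            simulate_reads(9, annotation, ab, samples, out_dir=d,
                           n_linear_fragments=100)
            h.append((_hash_file(d / "s001_R1.fastq"),
                      _hash_file(d / "s001_R2.fastq")))
        assert h[0] == h[1]

    def test_errorfree_junction_reads_are_pseudo_substrings(
            self, annotation, tmp_path):
        samples = ["s001"]
        ab = self._abundance(annotation, samples)
        origins = simulate_reads(9, annotation, ab, samples,
                                 out_dir=tmp_path, n_linear_fragments=0,
                                 error_rate=0.0)
        refs = {k: build_pseudo_reference(annotation.genome, k)
                for k in annotation.circ_keys}
        from circqtl.pseudo_quant import iter_fragments, revcomp
        checked = 0
        for fid, r1, r2 in iter_fragments(tmp_path / "s001_R1.fastq",
                                          tmp_path / "s001_R2.fastq"):
            o = origins["s001"][fid]
            chrom, start, end = parse_circ_key(o.name)
            L = end - start + 1
            seq = refs[o.name].sequence.encode()
            if o.offset + 75 > L:  # mate 1 wraps the junction
                assert r1 in seq or revcomp(r1) in seq
                checked += 1
        assert checked > 0

    def test_capture_probability_scales_counts(self, annotation, tmp_path):
        """Counted-fragment expectation is abundance, not raw fragments."""
        samples = [f"s{i:03d}" for i in range(4)]
        ab = self._abundance(annotation, samples, value=25.0)
        origins = simulate_reads(9, annotation, ab, samples,
                                 out_dir=tmp_path, n_linear_fragments=0)
        rng = np.random.default_rng(0)
        flens = rng.normal(250, 30, 400)
        for key in annotation.circ_keys:
            chrom, start, end = parse_circ_key(key)
            L = end - start + 1
            p = junction_capture_probability(L, 75, flens)
            n_frag = sum(1 for per in origins.values()
                         for o in per.values() if o.name == key)
            expected_total = 4 * 25.0 / p
            assert n_frag == pytest.approx(expected_total,
                                           abs=6 * np.sqrt(expected_total))


class TestCallerOutputs:
    def test_perfect_callers_consensus_equals_truth(self, annotation,
                                                    tmp_path):
        samples = ["s001", "s002"]
        truth = pd.DataFrame(20.0, index=annotation.circ_keys,
                             columns=samples)
        simulate_caller_outputs(
            4, annotation, truth, samples, tmp_path,
            sensitivity={m: 1.0 for m in ("circall", "ciri2",
                                          "circexplorer2")},
            fp_rate={m: 0.0 for m in ("circall", "ciri2",
                                      "circexplorer2")})
        calls = []
        for method in ("circall", "ciri2", "circexplorer2"):
            for s in samples:
                calls.extend(parse_caller_output(
                    tmp_path / f"{method}_{s}.tsv", method, s))
        cs = consensus_filter(filter_min_bsj_reads(calls, 2), 3)
        assert cs.candidates == annotation.circ_keys

    def test_dead_method_empties_full_consensus(self, annotation, tmp_path):
        samples = ["s001"]
        truth = pd.DataFrame(20.0, index=annotation.circ_keys,
                             columns=samples)
        emitted = simulate_caller_outputs(
            4, annotation, truth, samples, tmp_path,
            sensitivity={"circall": 0.0, "ciri2": 1.0,
                         "circexplorer2": 1.0},
            fp_rate={m: 0.0 for m in ("circall", "ciri2",
                                      "circexplorer2")})
        assert emitted["circall"] == []
        calls = []
        for method in ("circall", "ciri2", "circexplorer2"):
            for s in samples:
                calls.extend(parse_caller_output(
                    tmp_path / f"{method}_{s}.tsv", method, s))
        per_method = filter_min_bsj_reads(
            calls, 2, methods=("circall", "ciri2", "circexplorer2"))
        cs = consensus_filter(per_method, 3)
        assert cs.candidates == []


class TestGwasSumstats:
    def test_causal_variant_strongest_signal(self, genotypes):
        vid = genotypes.variant_ids()[5]
        ss = simulate_gwas_sumstats(1, genotypes, vid, "t", h2=0.02,
                                    n_gwas=5000)
        z = (ss.table["beta"] / ss.table["se"]).abs()
        assert ss.table.loc[z.idxmax(), "variant_id"] == vid

    def test_all_se_positive_and_variants_unique(self, genotypes):
        ss = simulate_gwas_sumstats(1, genotypes,
                                    genotypes.variant_ids()[0], "t")
        assert (ss.table["se"] > 0).all()
        assert ss.table["variant_id"].is_unique


class TestDispersion:
    def test_negative_binomial_inflates_variance(self, annotation,
                                                 tmp_path):
        """The gamma-Poisson knob widens fragment-count spread across
        samples without shifting the mean appreciably."""
        samples = [f"s{i:03d}" for i in range(30)]
        ab = pd.DataFrame(25.0, index=annotation.circ_keys,
                          columns=samples)
        counts = {}
        for name, disp in (("poisson", 0.0), ("nb", 0.5)):
            origins = simulate_reads(13, annotation, ab, samples,
                                     out_dir=tmp_path / name,
                                     n_linear_fragments=0,
                                     dispersion=disp)
            per_sample = np.array(
                [sum(o.name == annotation.circ_keys[0]
                     for o in per.values())
                 for per in origins.values()])
            counts[name] = per_sample
        assert counts["nb"].var() > 2 * counts["poisson"].var()
        assert counts["nb"].mean() == pytest.approx(
            counts["poisson"].mean(), rel=0.35)
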