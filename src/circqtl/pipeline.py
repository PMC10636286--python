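"""Stage orchestration with content-hash resumability.

Stages run in the fixed order simulate -> consensus -> quantify ->
prepare -> qtl -> coloc, each reading the previous stage's files from
the run directory and recording a ``<stage>.done.json`` marker holding
the configuration hash. On resume, a stage whose marker matches the
current configuration is skipped; a mismatching marker is refused (stale
outputs are never silently reused). Every tabular output embeds the
configuration hash in a header comment.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import consensus as consensus_mod
from . import phenotype as pheno_mod
from . import pseudo_quant as quant_mod
from . import qtl as qtl_mod
from . import simulate as sim_mod
from .config import PipelineConfig
from .formats import (parse_caller_output, read_genome_fasta,
                      read_gwas_sumstats, read_vcf_dosages, write_fasta,
                      write_gwas_sumstats, write_harmonized_calls)

log = logging.getLogger(__name__)

STAGES = ("simulate", "consensus", "quantify", "prepare", "qtl", "coloc")


class StageError(RuntimeError):
    pass


def _done_path(out: Path, stage: str) -> Path:
    return out / f"{stage}.done.json"


def _mark_done(out: Path, stage: str, cfg: PipelineConfig,
               counts: dict) -> None:
    with open(_done_path(out, stage), "w") as fh:
        json.dump({"stage": stage, "config_hash": cfg.config_hash(),
                   "counts": counts}, fh, sort_keys=True)


def _check_resume(out: Path, stage: str, cfg: PipelineConfig) -> bool:
    """True when the stage is already complete under this config."""
    p = _done_path(out, stage)
    if not p.exists():
        return False
    with open(p) as fh:
        marker = json.load(fh)
    if marker.get("config_hash") != cfg.config_hash():
        raise StageError(
            f"stage {stage}: existing outputs were produced under a "
            f"different configuration; remove {out} to re-run")
    return True


def _sample_ids(cfg: PipelineConfig) -> list[str]:
    return [f"s{i + 1:03d}" for i in range(cfg.n_samples)]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    sim_dir = out / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    ann = sim_mod.simulate_genome_and_annotation(
        cfg.seed, n_chrom=cfg.n_chrom, chrom_len=cfg.chrom_len,
        n_transcripts=cfg.n_transcripts, n_circ=cfg.n_circ,
        flank_len=cfg.flank_len)
    write_fasta(ann.genome, sim_dir / "genome.fa")
    write_fasta(ann.transcript_seqs(), sim_dir / "transcripts.fa")

    parts = []
    for ci in range(cfg.n_chrom):
        parts.append(sim_mod.simulate_genotypes(
            cfg.seed + ci, n_samples=cfg.n_samples,
            n_variants=cfg.n_variants_per_chrom,
            maf_range=cfg.maf_range,
            region=(f"chr{ci + 1}", 1, cfg.chrom_len), rho=cfg.ld_rho))
    gm = sim_mod.concat_genotypes(parts)
    sim_mod.write_vcf(gm, sim_dir / "genotypes.vcf")

    planted = sim_mod.plant_qtls(cfg.seed, gm, ann.circ_keys,
                                 n_qtl=cfg.n_planted_qtl,
                                 slope=cfg.planted_slope,
                                 cis_window=cfg.cis_window)
    abundance = sim_mod.expected_junction_abundance(
        cfg.seed, ann.circ_keys, gm, planted,
        mean_count=cfg.mean_junction_count)
    origins = sim_mod.simulate_reads(
        cfg.seed, ann, abundance, gm.sample_ids,
        n_linear_fragments=cfg.n_linear_fragments, read_len=cfg.read_len,
        frag_len_mean=cfg.frag_len_mean, frag_len_sd=cfg.frag_len_sd,
        error_rate=cfg.error_rate, out_dir=sim_dir / "reads")
    caller_truth = sim_mod.simulate_caller_outputs(
        cfg.seed, ann, abundance, gm.sample_ids, sim_dir / "calls")

    gwas_truth: dict[str, dict] = {}
    if planted:
        # the shared-causal trait targets a planted circQTL that every
        # caller detected, so the colocalization signal is quantifiable
        # at the strictest consensus setting
        seen_by_all = set.intersection(*(set(v) for v in
                                         caller_truth.values()))
        eligible = [q for q in planted if q.key in seen_by_all]
        shared_vid = (eligible[0] if eligible else planted[0]).variant_id
        shared_chrom = shared_vid.split(":")[0]
        others = [v.vid for v in gm.variants
                  if v.vid != shared_vid and v.chrom == shared_chrom]
        distinct_vid = others[len(others) // 2]
        for trait, vid, shared in (("trait_shared", shared_vid, True),
                                   ("trait_distinct", distinct_vid, False)):
            ss = sim_mod.simulate_gwas_sumstats(
                cfg.seed, gm, vid, trait, h2=cfg.gwas_h2, n_gwas=cfg.gwas_n,
                trait_type="cc")
            write_gwas_sumstats(ss, sim_dir / f"gwas_{trait}.tsv")
            gwas_truth[trait] = {"causal_variant": vid, "shared": shared,
                                 "trait_type": "cc", "case_fraction": 0.4}
    with open(sim_dir / "gwas_meta.json", "w") as fh:
        json.dump(gwas_truth, fh, sort_keys=True)

    truth = sim_mod.SimTruth(
        circ_keys=ann.circ_keys, sample_ids=gm.sample_ids,
        expected_abundance=abundance, planted_qtls=planted,
        gwas_truth=gwas_truth, caller_truth=caller_truth, origins=origins)
    truth.to_json(sim_dir / "truth.json")
    return {"circ_keys": len(ann.circ_keys), "samples": cfg.n_samples,
            "variants": gm.n_variants}


def stage_consensus(cfg: PipelineConfig, out: Path) -> dict:
    calls_dir = out / "sim" / "calls"
    cons_dir = out / "consensus"
    cons_dir.mkdir(parents=True, exist_ok=True)
    calls = []
    for method in cfg.methods:
        for sample in _sample_ids(cfg):
            path = calls_dir / f"{method}_{sample}.tsv"
            if not path.exists():
                raise StageError(f"missing caller table {path}")
            dialect = method if method in ("ciri2", "circall") else "circexplorer2"
            calls.extend(parse_caller_output(path, dialect, sample))
    write_harmonized_calls(calls, cons_dir / "harmonized_calls.tsv")
    per_method = consensus_mod.filter_min_bsj_reads(
        calls, cfg.min_bsj_reads, methods=cfg.methods)
    cs = consensus_mod.consensus_filter(per_method, cfg.consensus_k)
    consensus_mod.write_consensus(cs, cons_dir / "consensus.bed",
                                  cons_dir / "support.tsv")
    return {"calls": len(calls), "candidates": len(cs.candidates),
            "breakdown": {str(k): v
                          for k, v in cs.support_breakdown().items()}}


def _read_candidates(out: Path) -> list[str]:
    df = pd.read_csv(out / "consensus" / "support.tsv", sep="\t")
    return list(df["key"])


def stage_quantify(cfg: PipelineConfig, out: Path) -> dict:
    quant_dir = out / "quant"
    quant_dir.mkdir(parents=True, exist_ok=True)
    genome = read_genome_fasta(out / "sim" / "genome.fa")
    transcriptome = read_genome_fasta(out / "sim" / "transcripts.fa")
    candidates = _read_candidates(out)
    reads_dir = out / "sim" / "reads"
    samples = [(s, reads_dir / f"{s}_R1.fastq", reads_dir / f"{s}_R2.fastq")
               for s in _sample_ids(cfg)]
    counts, refs = quant_mod.quantify_cohort(
        samples, candidates, genome, transcriptome,
        flank_len=cfg.flank_len, min_overhang=cfg.min_overhang,
        seed_k=cfg.seed_k, max_mismatches=cfg.max_mismatches)
    write_fasta({k: r.sequence for k, r in sorted(refs.items())},
                quant_dir / "pseudo_refs.fa")
    quant_mod.write_counts(counts, quant_dir / "counts.tsv",
                           header_comment=f"config_hash={cfg.config_hash()}")
    return {"candidates": len(candidates),
            "total_fragments_counted": int(counts.to_numpy().sum())}


def stage_prepare(cfg: PipelineConfig, out: Path) -> dict:
    pheno_dir = out / "pheno"
    pheno_dir.mkdir(parents=True, exist_ok=True)
    counts = quant_mod.read_counts(out / "quant" / "counts.tsv")
    pm = pheno_mod.prepare_phenotypes(counts,
                                      min_nonzero_frac=cfg.min_nonzero_frac,
                                      min_count=cfg.min_count)
    k = cfg.hidden_factors_k
    cov = pheno_mod.infer_hidden_factors(pm.values, k)
    if cfg.genotype_pcs_k > 0:
        gm = read_vcf_dosages(out / "sim" / "genotypes.vcf", cfg.maf_min)
        gpc = pheno_mod.genotype_pcs(gm.dosages, gm.sample_ids,
                                     cfg.genotype_pcs_k)
        cov = pd.concat([cov, gpc])
    pheno_mod.write_phenotype_bed(
        pm.values, pheno_dir / "phenotypes.bed",
        header_comment=f"config_hash={cfg.config_hash()}")
    with open(pheno_dir / "covariates.tsv", "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\n")
        cov.to_csv(fh, sep="\t", index_label="covariate",
                   float_format="%.10g")
    with open(pheno_dir / "transform_log.json", "w") as fh:
        json.dump(pm.transform_log, fh)
    return {"phenotypes": pm.values.shape[0], "covariates": cov.shape[0]}


def read_phenotype_bed(path: Path) -> pd.DataFrame:
    # the optional first line is a "# config_hash=..." comment; the header
    # itself starts with "#chrom" and must not be treated as a comment
    with open(path) as fh:
        skip = 1 if fh.readline().startswith("# ") else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    df = df.set_index("key")
    return df.drop(columns=["#chrom", "start", "end"])


def stage_qtl(cfg: PipelineConfig, out: Path) -> dict:
    qtl_dir = out / "qtl"
    qtl_dir.mkdir(parents=True, exist_ok=True)
    pheno = read_phenotype_bed(out / "pheno" / "phenotypes.bed")
    cov = pd.read_csv(out / "pheno" / "covariates.tsv", sep="\t",
                      comment="#", index_col="covariate")
    gm = read_vcf_dosages(out / "sim" / "genotypes.vcf", cfg.maf_min)
    results, ecirc = qtl_mod.map_all(
        pheno, gm, cov if len(cov) else None, seed=cfg.seed,
        cis_window=cfg.cis_window, b_min=cfg.b_min, b_max=cfg.b_max,
        n_hits_stop=cfg.n_hits_stop,
        qvalue_threshold=cfg.qvalue_threshold)
    qtl_mod.write_qtl_results(results, qtl_dir / "qtl_results.tsv",
                              header_comment=f"config_hash={cfg.config_hash()}")
    # per-variant nominal statistics of eCircRNAs feed colocalization
    cov_arr = cov.to_numpy(float) if len(cov) else None
    rows = []
    for key in ecirc:
        mask = qtl_mod.cis_window_mask(gm, key, cfg.cis_window)
        nom = qtl_mod.nominal_scan(
            pheno.loc[key].to_numpy(float), gm.dosages[mask],
            [gm.variants[i].vid for i in np.flatnonzero(mask)],
            covariates=cov_arr)
        nom.insert(0, "key", key)
        rows.append(nom)
    nominal = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame(columns=["key", "variant_id", "slope",
                                          "se", "p"]))
    with open(qtl_dir / "nominal.tsv", "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\n")
        nominal.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    with open(qtl_dir / "ecircrna.json", "w") as fh:
        json.dump(sorted(ecirc), fh)
    return {"phenotypes_tested": len(results), "ecircrna": len(ecirc)}


def stage_coloc(cfg: PipelineConfig, out: Path) -> dict:
    coloc_dir = out / "coloc"
    coloc_dir.mkdir(parents=True, exist_ok=True)
    with open(out / "qtl" / "ecircrna.json") as fh:
        ecirc = json.load(fh)
    nominal = pd.read_csv(out / "qtl" / "nominal.tsv", sep="\t", comment="#")
    with open(out / "sim" / "gwas_meta.json") as fh:
        gwas_meta = json.load(fh)
    gwas = {}
    for trait, meta in sorted(gwas_meta.items()):
        gwas[trait] = read_gwas_sumstats(
            out / "sim" / f"gwas_{trait}.tsv", trait,
            meta["trait_type"], meta.get("case_fraction"))
    qtl_nominal = {key: grp.drop(columns="key")
                   for key, grp in nominal.groupby("key") if key in ecirc}
    results = coloc_mod.run_coloc_all(
        qtl_nominal, gwas, p1=cfg.coloc_p1, p2=cfg.coloc_p2,
        p12=cfg.coloc_p12, pp4_threshold=cfg.pp4_threshold,
        min_shared=cfg.min_shared)
    coloc_mod.write_coloc_results(
        results, coloc_dir / "coloc.tsv",
        header_comment=f"config_hash={cfg.config_hash()}")
    n_coloc = sum(r.colocalized for r in results)
    return {"pairs_tested": len(results), "colocalized": n_coloc}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "consensus": stage_consensus,
    "quantify": stage_quantify,
    "prepare": stage_prepare,
    "qtl": stage_qtl,
    "coloc": stage_coloc,
}


def run(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in pipeline order; completed stages
    with a matching config hash are skipped. Returns the run report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash(), "stages": {}}
    report_path = out / "report.json"
    if report_path.exists():
        with open(report_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == cfg.config_hash():
            report["stages"] = old.get("stages", {})
    for stage in STAGES:
        if stage not in stages:
            continue
        if _check_resume(out, stage, cfg):
            log.info("stage %s: up to date, skipped", stage)
            continue
        log.info("stage %s: running", stage)
        try:
            counts = _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            raise StageError(f"stage {stage} failed: {exc}") from exc
        _mark_done(out, stage, cfg, counts)
        report["stages"][stage] = counts
        with open(report_path, "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
    return report
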