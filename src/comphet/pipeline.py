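"""End-to-end discovery pipeline: QC -> parentage -> ROH -> linkage ->
variant funnel -> consequence -> ranked candidate report.

The stage order embodies the family-study narrative: verify the declared
pedigree from the array data, look for a shared autozygous interval (the
simple-recessive hypothesis), scan for allele-sharing linkage, then run the
sequenced trios through the privacy/inheritance funnel and rank the
surviving candidates by positional support.  Every stage logs its
input/output counts; given identical inputs and seed the report is
reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

from comphet import autozygosity, genotype_qc, linkage, variant_filter
from comphet.io_formats import read_genotypes, read_vcf, read_gene_models
from comphet.pedigree import read_fam, verify_parentage
from comphet.variant_filter import ControlCohort


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _require(config: dict, key: str):
    if key not in config:
        raise PipelineError("config", f"missing required key {key!r}")
    return config[key]


def run_discover(config: dict, outdir: str | None = None) -> dict:
    """Run the full pipeline from a config mapping; returns the run report.

    Required config keys: ``genotypes_ped``, ``genotypes_map``,
    ``pedigree_fam``, ``family_vcf``, ``local_counts``, ``global_counts``,
    ``seed``.  Optional: ``gene_models_bed`` + ``fasta``, per-stage
    parameter blocks ``qc``, ``roh``, ``linkage``, ``filter``.
    """
    log: dict = {"stages": {}, "params": {}}
    seed = _require(config, "seed")

    ped = read_fam(_require(config, "pedigree_fam"))
    gm = read_genotypes(_require(config, "genotypes_ped"),
                        _require(config, "genotypes_map"))
    log["stages"]["input"] = {"samples": gm.n_samples, "markers": gm.n_markers}

    # --- QC ---------------------------------------------------------------
    qc_cfg = config.get("qc", {})
    rates = genotype_qc.sample_call_rates(
        gm, qc_cfg.get("min_sample_call_rate", 0.90))
    gm = genotype_qc.prune_markers_by_missingness(
        gm, qc_cfg.get("max_marker_missing", 0.10))
    log["stages"]["qc"] = {
        "low_call_samples": rates.flagged,
        "markers_after_pruning": gm.n_markers}

    # --- parentage --------------------------------------------------------
    affected = [i for i in ped.affected() if i in gm.sample_ids]
    if len(affected) < 2:
        raise PipelineError("parentage", "need >= 2 genotyped affected animals")
    parentage = {}
    for a in affected:
        sire = ped[a].sire_id
        if sire and sire in gm.sample_ids:
            v = verify_parentage(gm, a, sire)
            parentage[a] = v.verdict
            if v.verdict == "excluded":
                raise PipelineError(
                    "parentage", f"declared sire {sire} excluded for {a}")
    log["stages"]["parentage"] = parentage

    # --- autozygosity -----------------------------------------------------
    roh_cfg = config.get("roh", {})
    params = autozygosity.ROHParams(**roh_cfg) if roh_cfg else \
        autozygosity.ROHParams().scaled_to(gm.n_markers)
    log["params"]["roh"] = asdict(params)
    segments = {a: autozygosity.detect_roh(gm, a, params) for a in affected}
    shared = autozygosity.shared_autozygosity(segments, gm, affected, params)
    log["stages"]["roh"] = {
        "segments_per_case": {a: len(s) for a, s in segments.items()},
        "shared_intervals": len(shared)}

    # --- linkage ----------------------------------------------------------
    lk_cfg = config.get("linkage", {})
    lk_params = linkage.LinkageParams(
        n_reps=lk_cfg.get("n_reps", 1000),
        gap_markers=lk_cfg.get("gap_markers",
                               linkage.LinkageParams.gap_markers),
        seed=lk_cfg.get("seed", seed))
    log["params"]["linkage"] = asdict(lk_params)
    log["params"]["qc"] = {
        "min_sample_call_rate": qc_cfg.get("min_sample_call_rate", 0.90),
        "max_marker_missing": qc_cfg.get("max_marker_missing", 0.10)}
    scan, regions = linkage.scan_and_merge(gm, ped, affected, lk_params)
    log["stages"]["linkage"] = {
        "markers_scanned": len(scan),
        "defined_markers": int(scan["Z"].notna().sum()),
        "positive_regions": len(regions)}

    # --- variant funnel ---------------------------------------------------
    variants = read_vcf(_require(config, "family_vcf"))
    local = ControlCohort.from_table(_require(config, "local_counts"), "local")
    global_ = ControlCohort.from_table(_require(config, "global_counts"), "global")
    vcf_samples = sorted({s for v in variants for s in v.genotypes})
    cases = [c for c in ped.affected() if c in vcf_samples]
    trios = [(c, ped[c].sire_id, ped[c].dam_id) for c in cases
             if ped[c].sire_id in vcf_samples and ped[c].dam_id in vcf_samples]
    if not trios:
        raise PipelineError("filter", "no complete sequenced trio")
    funnel = variant_filter.run_funnel(variants, trios, cases, local, global_,
                                       config.get("filter", {}).get(
                                           "max_control_carriers", 0))
    log["stages"]["funnel"] = funnel["log"]

    # --- prioritisation ---------------------------------------------------
    report = variant_filter.prioritize(funnel["final_calls"], regions, shared)
    ranked = []
    for c in report.candidates:
        ranked.append({
            "gene": c.call.gene_id,
            "mode": c.call.mode,
            "variants": [f"{v.chrom}:{v.pos1}{v.ref}>{v.alt}"
                         for v in c.call.variants],
            "in_linked_region": c.in_linked_region,
            "in_shared_roh": c.in_shared_roh,
            "support_lod": c.support_lod,
            "rationale": c.rationale})
    log["candidates"] = ranked

    # --- consequence (optional) -------------------------------------------
    if "gene_models_bed" in config:
        from comphet.consequence import TranscriptModel, annotate_all_isoforms
        models = [TranscriptModel.from_gene_model(m) for m in read_gene_models(
            config["gene_models_bed"], _require(config, "fasta"))]
        ann = []
        for c in report.candidates[:1]:
            for v in c.call.variants:
                for call in annotate_all_isoforms(v, models):
                    ann.append({"variant": f"{v.chrom}:{v.pos1}{v.ref}>{v.alt}",
                                **asdict(call)})
        log["consequences"] = ann

    if outdir:
        os.makedirs(outdir, exist_ok=True)
        scan.to_csv(os.path.join(outdir, "linkage_scan.tsv"),
                    sep="\t", index=False)
        autozygosity.write_bed(
            [s for segs in segments.values() for s in segs],
            os.path.join(outdir, "roh.bed"))
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(log, fh, indent=2, default=str)
    return log
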