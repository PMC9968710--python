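"""End-to-end orchestration: filter -> adjust -> correlate -> variability ->
snpdetect -> crossdb -> lookup-table export.

Both a Raw and an Adj (cell-composition adjusted) branch are produced when
adjustment is configured.  Every run is deterministic under a fixed seed and
config, and the lookup table reconciles exactly with each stage's own
output tables.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, fields
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import qc
from .adjust import residualize
from .corr import (across_subject_correlation, ancestry_pcs, coupling,
                   mds_embedding, per_subject_correlation, stack_samples,
                   summarize, within_subject_cpg_correlation)
from .crossdb import align_and_compare, annotate_mqtl, triple_intersection
from .snpdetect import SnpDetectParams, detect_snp_probes
from .synth import (ConfigurationError, SimulationConfig, SyntheticTruth,
                    generate_cohort, inject_detection_failures, make_annotation)
from .types import MultiTissueDataset, brain_peripheral_pairs, pair_label
from .varcpg import classify_variable, intersect_variable

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")


def _sim_config_from_dict(d: dict) -> SimulationConfig:
    valid = {f.name for f in fields(SimulationConfig)}
    unknown = set(d) - valid - {"annotation"}
    if unknown:
        raise PipelineError("simulate", "config", f"unknown simulate keys: {sorted(unknown)}")
    return SimulationConfig(**{k: v for k, v in d.items() if k in valid})


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError("config", "config", "config file must hold a mapping")
    return cfg


def simulate_inputs(cfg: dict, outdir: str,
                    ) -> Tuple[MultiTissueDataset, pd.DataFrame,
                               Optional[Dict[str, pd.DataFrame]], SyntheticTruth]:
    """Generate a cohort plus annotation/detection-p and write them as TSV."""
    sim_cfg = dict(cfg.get("simulate") or {})
    ann_cfg = dict(sim_cfg.pop("annotation", None) or {})
    if "seed" not in sim_cfg and "seed" in cfg:
        sim_cfg["seed"] = cfg["seed"]
    config = _sim_config_from_dict(sim_cfg)
    dataset, truth = generate_cohort(config)
    annotation = make_annotation(
        dataset.probes, truth,
        frac_snp_proximal=ann_cfg.get("frac_snp_proximal", 0.025),
        frac_non_cpg=ann_cfg.get("frac_non_cpg", 0.003),
        seed=config.seed)
    detp = None
    if config.frac_detection_fail > 0:
        detp, det_truth = inject_detection_failures(dataset, config)
        truth.detection_bad_probes = det_truth.detection_bad_probes
        truth.detection_bad_samples = det_truth.detection_bad_samples

    inputs_dir = mio.ensure_dir(os.path.join(outdir, "inputs"))
    for tissue, beta in dataset.betas.items():
        mio.write_matrix(beta, os.path.join(inputs_dir, f"beta_{tissue}.tsv"))
    mio.write_proportions(dataset.cell_proportions,
                          os.path.join(inputs_dir, "cell_proportions.tsv"))
    mio.write_annotation(annotation, os.path.join(inputs_dir, "annotation.tsv"))
    if detp is not None:
        for tissue, mat in detp.items():
            mio.write_matrix(mat, os.path.join(inputs_dir, f"detection_p_{tissue}.tsv"))
    mio.write_table(truth.to_frame(), os.path.join(inputs_dir, "truth.tsv"))
    with open(os.path.join(inputs_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump({"simulate": asdict(config)}, fh, sort_keys=True)
    return dataset, annotation, detp, truth


def load_inputs(cfg: dict) -> Tuple[MultiTissueDataset, Optional[pd.DataFrame],
                                    Optional[Dict[str, pd.DataFrame]]]:
    inputs = cfg.get("inputs") or {}
    if "beta" not in inputs:
        raise PipelineError("load", "input", "config lacks inputs.beta (or a simulate section)")
    betas = {t: mio.read_matrix(p) for t, p in inputs["beta"].items()}
    props = mio.read_proportions(inputs["proportions"]) if "proportions" in inputs else {}
    dataset = MultiTissueDataset(betas=betas, cell_proportions=props)
    annotation = (mio.read_annotation(inputs["annotation"])
                  if "annotation" in inputs else None)
    detp = None
    if "detection_p" in inputs:
        detp = {t: mio.read_matrix(p) for t, p in inputs["detection_p"].items()}
    return dataset, annotation, detp


def filter_stage(dataset: MultiTissueDataset, annotation: Optional[pd.DataFrame],
                 detp: Optional[Dict[str, pd.DataFrame]], cfg: dict,
                 outdir: str) -> Tuple[MultiTissueDataset, dict]:
    fcfg = cfg.get("filter") or {}
    max_dist = fcfg.get("max_dist", 5)
    threshold = fcfg.get("threshold", 0.01)
    reports = {}
    filtered = {}
    for tissue, beta in dataset.betas.items():
        out, report = qc.apply_filters(
            beta, annotation=annotation,
            detp=(detp or {}).get(tissue),
            max_dist=max_dist, threshold=threshold)
        filtered[tissue] = out
        reports[tissue] = {
            "n_input_probes": report.n_input_probes,
            "removed_snp_proximity": report.removed_snp_proximity,
            "removed_detection": report.removed_detection,
            "removed_context": report.removed_context,
            "n_removed_unique": report.n_removed_unique,
            "n_surviving": report.n_surviving,
            "removed_samples": report.removed_samples,
        }
    # keep the subject panel common across tissues after sample removals
    common_subjects = None
    for beta in filtered.values():
        cols = list(beta.columns)
        common_subjects = cols if common_subjects is None else [
            s for s in common_subjects if s in set(cols)]
    filtered = {t: b[common_subjects] for t, b in filtered.items()}
    out_ds = MultiTissueDataset(betas=filtered,
                                cell_proportions=dataset.cell_proportions)
    with open(os.path.join(outdir, "filter_report.yaml"), "w") as fh:
        yaml.safe_dump(reports, fh, sort_keys=True)
    return out_ds, reports


def adjust_stage(dataset: MultiTissueDataset, cfg: dict) -> MultiTissueDataset:
    if not dataset.cell_proportions:
        raise PipelineError("adjust", "input", "no cell proportions provided")
    adjusted = {}
    for tissue, beta in dataset.betas.items():
        result = residualize(beta, dataset.cell_proportions[tissue], tissue)
        adjusted[tissue] = result.beta
    return MultiTissueDataset(betas=adjusted,
                              cell_proportions=dataset.cell_proportions)


def correlate_stage(dataset: MultiTissueDataset, cfg: dict, branch_dir: str,
                    ) -> Dict[str, pd.DataFrame]:
    ccfg = cfg.get("correlate") or {}
    min_n = ccfg.get("min_n", 5)
    tissues = dataset.tissues
    if "brain" in tissues:
        pairs = [("brain", t) for t in tissues if t != "brain"]
    else:
        pairs = [(tissues[0], t) for t in tissues[1:]]
    records: Dict[str, pd.DataFrame] = {}
    summaries = []
    for a, b in pairs:
        label = pair_label(a, b)
        table = within_subject_cpg_correlation(
            dataset.betas[a], dataset.betas[b], min_n=min_n, tissue_pair=label)
        records[label] = table
        mio.write_table(table, os.path.join(branch_dir, f"correlations_{label}.tsv"))
        across = across_subject_correlation(dataset.betas[a], dataset.betas[b],
                                            tissue_pair=label)
        summ = summarize(table)
        summaries.append({
            "tissue_pair": label,
            "across_subject_r": across.r,
            "n_probes": across.n_probes,
            "frac_nominal": summ.frac_nominal,
            "frac_moderate": summ.frac_moderate,
            "rho_mean": summ.rho_mean,
            "rho_median": summ.rho_median,
            "n_bh_significant": summ.n_bh_significant,
        })
    mio.write_table(pd.DataFrame(summaries),
                    os.path.join(branch_dir, "summary.tsv"))

    per_subj = per_subject_correlation(dataset)
    mio.write_table(per_subj.reset_index(),
                    os.path.join(branch_dir, "per_subject_correlations.tsv"))
    couplings = []
    cols = list(per_subj.columns)
    for i, x in enumerate(cols):
        for y in cols[i + 1:]:
            r, p = coupling(per_subj, x, y)
            couplings.append({"pair_x": x, "pair_y": y, "r": r, "p": p})
    mio.write_table(pd.DataFrame(couplings),
                    os.path.join(branch_dir, "couplings.tsv"))
    return records


def variability_stage(dataset: MultiTissueDataset, cfg: dict, branch_dir: str,
                      ) -> Tuple[Dict[str, pd.DataFrame], List[str]]:
    vcfg = cfg.get("variability") or {}
    flags = {}
    for tissue, beta in dataset.betas.items():
        f = classify_variable(beta, trim=vcfg.get("trim", 10),
                              range_threshold=vcfg.get("range_threshold", 0.05))
        f.insert(1, "tissue", tissue)
        flags[tissue] = f
        mio.write_table(f, os.path.join(branch_dir, f"variability_{tissue}.tsv"))
    common = intersect_variable(flags)
    pd.Series(common, name="probe_id").to_frame().to_csv(
        os.path.join(branch_dir, "variable_all_tissues.tsv"), sep="\t", index=False)
    return flags, common


def snpdetect_stage(dataset: MultiTissueDataset, cfg: dict, branch_dir: str,
                    ) -> Dict[str, pd.DataFrame]:
    scfg = cfg.get("snpdetect") or {}
    params = SnpDetectParams(
        k_max=scfg.get("k_max", 3), B=scfg.get("B", 50),
        min_cluster_size=scfg.get("min_cluster_size", 2),
        min_separation=scfg.get("min_separation", 0.2),
        seed=scfg.get("seed", cfg.get("seed", 0)))
    tissues = scfg.get("tissues") or dataset.tissues
    reports = {}
    for tissue in tissues:
        rep = detect_snp_probes(dataset.betas[tissue], params)
        rep.insert(1, "tissue", tissue)
        reports[tissue] = rep
        flat = rep.copy()
        flat["cluster_centers"] = flat["cluster_centers"].map(
            lambda c: ",".join(f"{v:.6g}" for v in c))
        flat["cluster_sizes"] = flat["cluster_sizes"].map(
            lambda c: ",".join(str(v) for v in c))
        mio.write_table(flat, os.path.join(branch_dir, f"snp_report_{tissue}.tsv"))
    return reports


def crossdb_stage(records: Dict[str, pd.DataFrame], cfg: dict, branch_dir: str,
                  ) -> Optional[pd.DataFrame]:
    xcfg = cfg.get("crossdb") or {}
    ref_path = xcfg.get("reference_table")
    if not ref_path:
        return None
    reference = mio.read_correlation_table(ref_path)
    own = pd.concat(records.values(), ignore_index=True)
    merged, rho_of_rho = align_and_compare(
        own, reference, threshold=xcfg.get("threshold", 0.2))
    mio.write_table(merged, os.path.join(branch_dir, "crossdb_records.tsv"))
    summary = pd.DataFrame(
        [{"tissue_pair": k, "rho_of_rho_r": v} for k, v in sorted(rho_of_rho.items())])
    summary["n_stable_all_pairs"] = triple_intersection(merged)
    mio.write_table(summary, os.path.join(branch_dir, "crossdb_summary.tsv"))
    return merged


def export_lookup(dataset: MultiTissueDataset,
                  records: Dict[str, pd.DataFrame],
                  flags: Dict[str, pd.DataFrame],
                  snp_reports: Dict[str, pd.DataFrame],
                  crossdb_records: Optional[pd.DataFrame],
                  mqtl_list: Optional[pd.DataFrame],
                  branch_dir: str) -> pd.DataFrame:
    """Merge every stage's per-probe columns into one lookup table."""
    probes = sorted(set().union(*(set(r["probe_id"]) for r in records.values())))
    lookup = pd.DataFrame({"probe_id": probes})
    for label, table in sorted(records.items()):
        sub = table[["probe_id", "rho", "p", "q"]].rename(columns={
            "rho": f"rho_{label}", "p": f"p_{label}", "q": f"q_{label}"})
        lookup = lookup.merge(sub, on="probe_id", how="left")
    for tissue, f in sorted(flags.items()):
        sub = f[["probe_id", "trimmed_range", "variable"]].rename(columns={
            "trimmed_range": f"trimmed_range_{tissue}",
            "variable": f"variable_{tissue}"})
        lookup = lookup.merge(sub, on="probe_id", how="left")
    if snp_reports:
        combined = pd.concat(snp_reports.values(), ignore_index=True)
        agg = combined.groupby("probe_id").agg(
            snp_flagged=("flagged", "any"), snp_k=("chosen_k", "max")).reset_index()
        lookup = lookup.merge(agg, on="probe_id", how="left")
    if crossdb_records is not None:
        for label, grp in crossdb_records.groupby("tissue_pair"):
            sub = grp[["probe_id", "delta", "stable"]].rename(columns={
                "delta": f"crossdb_delta_{label}", "stable": f"crossdb_stable_{label}"})
            lookup = lookup.merge(sub, on="probe_id", how="left")
    if mqtl_list is not None:
        lookup = annotate_mqtl(lookup, mqtl_list)
    lookup = lookup.sort_values("probe_id", kind="mergesort").reset_index(drop=True)
    mio.write_table(lookup, os.path.join(branch_dir, "lookup.tsv"))
    return lookup


def run_pipeline(cfg: dict, outdir: str) -> Dict[str, pd.DataFrame]:
    """Run every configured stage; returns the lookup table per branch."""
    mio.ensure_dir(outdir)
    stage = "load"
    try:
        if "simulate" in cfg:
            dataset, annotation, detp, _truth = simulate_inputs(cfg, outdir)
        else:
            dataset, annotation, detp = load_inputs(cfg)

        prefilter = dataset
        stage = "filter"
        dataset, filter_reports = filter_stage(dataset, annotation, detp, cfg, outdir)

        branches = {"raw": dataset}
        if (cfg.get("adjust") or {}).get("enabled", False):
            stage = "adjust"
            branches["adj"] = adjust_stage(dataset, cfg)

        mqtl_list = None
        if (cfg.get("mqtl") or {}).get("list"):
            mqtl_list = mio.read_probe_list(cfg["mqtl"]["list"])

        lookups = {}
        for branch, ds in branches.items():
            branch_dir = mio.ensure_dir(os.path.join(outdir, branch))
            stage = f"correlate[{branch}]"
            records = correlate_stage(ds, cfg, branch_dir)
            stage = f"variability[{branch}]"
            flags, _common = variability_stage(ds, cfg, branch_dir)
            stage = f"snpdetect[{branch}]"
            snp_reports = snpdetect_stage(ds, cfg, branch_dir)
            stage = f"crossdb[{branch}]"
            xdb = crossdb_stage(records, cfg, branch_dir)
            stage = f"export[{branch}]"
            lookups[branch] = export_lookup(ds, records, flags, snp_reports,
                                            xdb, mqtl_list, branch_dir)

        stage = "embedding"
        samples = stack_samples(dataset)
        if samples.shape[0] >= 3 and samples.shape[1] >= 1:
            emb = mds_embedding(samples, k=2)
            mio.write_table(emb.reset_index(), os.path.join(outdir, "mds.tsv"))
        if annotation is not None:
            # SNP-overlapping probes are removed by QC, so ancestry PCs use
            # the pre-filter matrix of the first tissue (blood by convention)
            pc_tissue = "blood" if "blood" in prefilter.betas else prefilter.tissues[0]
            try:
                pcs = ancestry_pcs(prefilter.betas[pc_tissue], annotation)
                mio.write_table(pcs.reset_index(),
                                os.path.join(outdir, "ancestry_pcs.tsv"))
            except ValueError:
                logger.info("ancestry PCs skipped (no SNP-proximal probes)")

        with open(os.path.join(outdir, "run_log.yaml"), "w") as fh:
            import methconcord
            yaml.safe_dump({
                "version": getattr(methconcord, "__version__", "unknown"),
                "seed": cfg.get("seed"),
                "config": cfg,
                "filter_reports": filter_reports,
                "branches": sorted(branches),
            }, fh, sort_keys=True)
        return lookups
    except (PipelineError, ConfigurationError):
        raise
    except Exception as exc:                                 # noqa: BLE001
        raise PipelineError(stage, "stage_failure", str(exc)) from exc


def query_probes(lookup: pd.DataFrame, probe_ids) -> Tuple[pd.DataFrame, List[str]]:
    """Exact-match retrieval from a lookup table; unknown ids are reported."""
    wanted = [str(p) for p in probe_ids]
    known = set(lookup["probe_id"].astype(str))
    unknown = [p for p in wanted if p not in known]
    if unknown:
        logger.warning("unknown probe ids: %s", ", ".join(unknown))
    subset = lookup[lookup["probe_id"].astype(str).isin(set(wanted))]
    return subset.reset_index(drop=True), unknown
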