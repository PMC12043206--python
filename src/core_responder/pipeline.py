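"""End-to-end orchestrator: diversity -> differential -> core call ->
networks -> neighbor-shift drivers -> isolate matching.

A run is driven by one YAML/dict config and a single integer seed; every
stochastic stage derives its own substream from the seed and the stage name,
so two runs with the same config are byte-identical. All thresholds and the
seed land in ``run_log.json``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, differential, netshift, network, strain_match, synthetic_data
from ._util import stage_rng
from .io_model import (
    StudyDesign,
    read_count_table,
    read_design,
    read_taxonomy,
    to_relative_abundance,
    filter_singletons,
    write_count_table,
    write_design,
    write_taxonomy,
)

DEFAULT_THRESHOLDS = {
    "abundance_min": 0.001,  # DA candidate filter (0.1%)
    "alpha": 0.05,
    "k_core": 5,
    "f_min": 1.2,
    "net_abund_min": 0.002,  # network candidate filter (0.2%)
    "net_min_prev": 2,
    "rho_min": 0.9,
    "q_max": 0.05,
    "nesh_tau": None,  # None -> mean scaled NESH
    "driver_min_ecotypes": 4,
    "id_min": 0.97,
    "n_null": 200,
    "n_perm": 999,
}


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(config):
    if isinstance(config, dict):
        return json.loads(json.dumps(config))  # defensive copy
    with open(config) as fh:
        return yaml.safe_load(fh)


def _float_frame(frame: pd.DataFrame) -> pd.DataFrame:
    return frame


def run_pipeline(config, output_dir=None) -> dict:
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(cfg.get("thresholds", {}))
    outdir = Path(output_dir or cfg.get("output_dir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {}

    def emit(name, frame, **to_csv_kwargs):
        path = outdir / name
        frame.to_csv(path, sep="\t", **to_csv_kwargs)
        outputs[name] = str(path)

    # ---- inputs -----------------------------------------------------------
    stage = "input"
    try:
        inputs = cfg.get("input", {}) or {}
        truth = None
        asv_records = isolate_records = None
        if inputs.get("counts"):
            table = read_count_table(inputs["counts"])
            design = read_design(inputs["design"])
            taxonomy = read_taxonomy(inputs["taxonomy"]) if inputs.get("taxonomy") else None
            if inputs.get("asv_fasta") and inputs.get("isolate_fasta"):
                asv_records = strain_match.read_fasta(inputs["asv_fasta"])
                isolate_records = strain_match.read_fasta(inputs["isolate_fasta"])
        else:
            syn = dict(cfg.get("synthetic", {}) or {})
            syn.setdefault("seed", seed)
            spec = synthetic_data.SyntheticSpec(**syn)
            table, design, truth, taxonomy = synthetic_data.generate_community(spec)
            seq_cfg = cfg.get("sequences", {}) or {}
            n_isolates = int(seq_cfg.get("n_isolates", 0))
            if n_isolates:
                asvs, isolates, pairing = synthetic_data.generate_sequences(
                    n_asvs=len(table.taxon_ids),
                    n_isolates=n_isolates,
                    divergence=float(seq_cfg.get("divergence", 0.01)),
                    seed=seed,
                )
                asv_records = [strain_match.SequenceRecord(i, s) for i, s in asvs]
                isolate_records = [strain_match.SequenceRecord(i, s) for i, s in isolates]
                with open(outdir / "isolate_pairing.json", "w") as fh:
                    json.dump(pairing, fh, indent=1, sort_keys=True)
                outputs["isolate_pairing.json"] = str(outdir / "isolate_pairing.json")
            write_count_table(table, outdir / "counts.tsv")
            write_design(design, outdir / "design.tsv")
            write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
            truth.to_json(outdir / "truth.json")
            outputs.update(
                {n: str(outdir / n) for n in ("counts.tsv", "design.tsv", "taxonomy.tsv", "truth.json")}
            )
        table = filter_singletons(table)
        design.validate_with(table)
        rel = to_relative_abundance(table)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- diversity --------------------------------------------------------
    stage = "diversity"
    try:
        emit("alpha_diversity.tsv", diversity.alpha_diversity(table), index_label="sample_id")
        dm = diversity.bray_curtis(rel)
        emit("bray_curtis.tsv", dm.to_frame(), index_label="sample_id")
        ord_res = diversity.pcoa(dm)
        emit("pcoa_coordinates.tsv", ord_res.coordinates, index_label="sample_id")
        with open(outdir / "pcoa_eigenvalues.json", "w") as fh:
            json.dump(
                {
                    "eigenvalues": ord_res.eigenvalues.tolist(),
                    "proportion_explained": ord_res.proportion_explained.tolist(),
                },
                fh,
                indent=1,
            )
        outputs["pcoa_eigenvalues.json"] = str(outdir / "pcoa_eigenvalues.json")
        sub = design.frame.loc[table.sample_ids]
        rng = stage_rng(seed, "permanova")
        rows = []
        for factor in ("ecotype", "treatment"):
            res = diversity.permanova(
                dm,
                sub[factor],
                factor=factor,
                n_perm=int(thresholds["n_perm"]),
                seed=int(rng.integers(2**32)),
            )
            rows.append(
                {"factor": factor, "mode": "one-factor", "r2": res.r2,
                 "pseudo_f": res.pseudo_f, "p": res.p, "n_perm": res.n_perm}
            )
        one = pd.DataFrame(rows)
        seq = diversity.permanova_sequential(
            dm, sub, ["ecotype", "treatment"],
            n_perm=int(thresholds["n_perm"]), seed=int(rng.integers(2**32)),
        )
        seq = seq.assign(n_perm=int(thresholds["n_perm"]))[
            ["factor", "mode", "r2", "pseudo_f", "p", "n_perm"]
        ]
        emit("permanova.tsv", pd.concat([one, seq], ignore_index=True), index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- differential + core call ----------------------------------------
    stage = "differential"
    try:
        da = differential.da_all_ecotypes(
            rel,
            design,
            abundance_min=float(thresholds["abundance_min"]),
            alpha=float(thresholds["alpha"]),
        )
        emit("da_results.tsv", da, index=False)
        folds = differential.fold_matrix(da)
        emit("fold_matrix.tsv", folds)
        core = differential.call_core_responsive(
            da, k_core=int(thresholds["k_core"]), f_min=float(thresholds["f_min"])
        )
        emit("core_calls.tsv", core, index=False)
        has_both = {"tolerant", "sensitive"} <= set(
            design.frame.loc[table.sample_ids, "tolerance_class"]
        )
        if has_both:
            contrast = differential.group_fold_contrast(core, folds, design)
            emit("group_contrast.tsv", contrast, index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- networks ---------------------------------------------------------
    stage = "network"
    try:
        netdir = outdir / "networks"
        netdir.mkdir(exist_ok=True)
        rng = stage_rng(seed, "cohesion")
        nets = {}
        metric_rows = []
        cohesion_rows = []
        contexts = [
            (eco, treatment)
            for eco in design.ecotypes(include_bulk=True)
            for treatment in ("control", "drought")
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for eco, treatment in contexts:
                net = network.build_network(
                    rel,
                    design,
                    eco,
                    treatment,
                    abund_min=float(thresholds["net_abund_min"]),
                    min_prev=int(thresholds["net_min_prev"]),
                    rho_min=float(thresholds["rho_min"]),
                    q_max=float(thresholds["q_max"]),
                )
                nets[(eco, treatment)] = net
                metrics = network.topology(net)
                metric_rows.append(
                    {"ecotype": eco, "treatment": treatment, **metrics.summary()}
                )
                network.write_graphml(net, netdir / f"{eco}_{treatment}.graphml")
                net.edge_frame().to_csv(
                    netdir / f"{eco}_{treatment}_edges.tsv", sep="\t", index=False
                )
                samples = design.samples_for(ecotype=eco, treatment=treatment)
                coh = network.cohesion(
                    rel,
                    samples,
                    n_null=int(thresholds["n_null"]),
                    seed=int(rng.integers(2**32)),
                )
                cohesion_rows.append(
                    {
                        "ecotype": eco,
                        "treatment": treatment,
                        "positive": coh.positive,
                        "negative": coh.negative,
                        "total": coh.total,
                    }
                )
        emit("network_metrics.tsv", pd.DataFrame(metric_rows), index=False)
        emit("cohesion.tsv", pd.DataFrame(cohesion_rows), index=False)
        outputs["networks/"] = str(netdir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- neighbor-shift drivers ------------------------------------------
    stage = "netshift"
    try:
        nsdir = outdir / "netshift"
        nsdir.mkdir(exist_ok=True)
        reports = {}
        for eco in design.ecotypes(include_bulk=True):
            report = netshift.nesh_scores(
                nets[(eco, "control")], nets[(eco, "drought")], ecotype=eco
            )
            netshift.identify_drivers(report, tau=thresholds["nesh_tau"])
            key = "bulk" if design.tolerance_of(eco) == "bulk" else eco
            reports[key] = report
            report.table.to_csv(nsdir / f"{eco}_drivers.tsv", sep="\t", index=False)
            netshift.write_comparison_graphml(report, nsdir / f"{eco}_comparison.graphml")
        core_df = netshift.core_drivers(
            reports,
            taxonomy=taxonomy,
            min_ecotypes=int(thresholds["driver_min_ecotypes"]),
        )
        emit("core_drivers.tsv", core_df, index=False)
        outputs["netshift/"] = str(nsdir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- isolate matching -------------------------------------------------
    if asv_records and isolate_records:
        stage = "strain_match"
        try:
            clusters = strain_match.dereplicate_and_cluster(
                isolate_records, id_min=float(thresholds["id_min"])
            )
            emit("otu_clusters.tsv", strain_match.cluster_frame(clusters), index=False)
            core_taxa = set(
                core.loc[core["status"].isin(["core_enriched", "core_depleted"]), "taxon"]
            )
            queries = [r for r in asv_records if r.id in core_taxa] or asv_records
            report = strain_match.match_asvs(
                queries, clusters, id_min=float(thresholds["id_min"])
            )
            emit("match_report.tsv", report, index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    log = {
        "seed": seed,
        "thresholds": thresholds,
        "n_samples": len(table.sample_ids),
        "n_taxa": len(table.taxon_ids),
        "outputs": sorted(outputs),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    outputs["run_log.json"] = str(outdir / "run_log.json")
    return outputs
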