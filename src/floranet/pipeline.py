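"""End-to-end orchestration of the analysis stages from a single config.

The pipeline consumes a directory of standard-format inputs (as written
by ``floranet simulate`` or assembled from real data), executes stages in
dependency order, and writes per-stage outputs plus a JSON run report.
All stochastic stages are seeded from the config; outputs are
byte-deterministic given config + seed (timing goes to the log, never
into outputs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import read_expression, read_genes, read_peaks, read_edge_list
from .targets import assign_targets, assignments_to_frame
from .dynamics import stage_profiles
from .network import build_meta_network, cross_regulation_matrix
from .motifs import (
    count_autoregulation,
    count_feedback_loops,
    find_sims,
    motif_enrichment,
    sim_ppi_enrichment,
)
from .ffl import annotate_ffls, ffls_to_frame
from .robustness import attack_curve, compare_curves
from .domains import bound_fraction, call_domain_genes, quartet_targets
from .regress import RegressionDataset, fit_lasso

log = logging.getLogger("floranet")

STAGE_NAMES = (
    "targets", "dynamics", "network", "motifs", "ffl", "robustness",
    "domains", "regress",
)

DEFAULT_CONFIG = {
    "data_dir": ".",
    "out_dir": "out",
    "seed": None,
    "window": 3000,
    "pseudocount": 1.0,
    "p_cut": 0.05,
    "fc_cut": 2.0,
    "n_rand": 100,
    "folds": 10,
    "repeats": 5,
    "min_abs_r": 0.5,
    "ffl_fc_threshold": 1.0,
    "attack_max_fraction": 0.2,
    "ppi_n_iter": 200,
    "stages": list(STAGE_NAMES),
}

_STOCHASTIC_STAGES = {"motifs", "regress"}


def validate_config(config: dict) -> dict:
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULT_CONFIG, **config}
    bad = set(merged["stages"]) - set(STAGE_NAMES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    if merged["seed"] is None and _STOCHASTIC_STAGES & set(merged["stages"]):
        raise ValueError(
            "a seed is required when stochastic stages "
            f"{sorted(_STOCHASTIC_STAGES)} are enabled"
        )
    return merged


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in dependency order; return the report."""
    cfg = validate_config(config)
    data = Path(cfg["data_dir"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(cfg["stages"])
    report: dict = {"version": __version__, "config": cfg, "stages": {}}

    state: dict = {}

    def run_stage(name, fn):
        if name not in enabled:
            return
        t0 = time.perf_counter()
        try:
            report["stages"][name] = fn()
        except Exception as exc:  # pragma: no cover - error path
            raise StageError(name, exc) from exc
        log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)

    # --- targets ----------------------------------------------------------
    def stage_targets():
        genes = read_genes(data / "genes.tsv")
        regulators = sorted(
            pd.read_csv(data / "regulators.txt", header=None)[0].astype(str)
        )
        peaks = []
        for bed in sorted((data / "peaks").glob("*.bed")):
            tf, stage = bed.stem.rsplit("_", 1)
            peaks.extend(read_peaks(bed, tf=tf, stage=stage))
        assignments = assign_targets(peaks, genes, window=cfg["window"])
        assignments_to_frame(assignments).to_csv(
            out / "targets.tsv", sep="\t", index=False
        )
        state.update(genes=genes, regulators=regulators, assignments=assignments)
        return {"n_peaks": len(peaks), "n_assignments": len(assignments)}

    # --- dynamics ---------------------------------------------------------
    def stage_dynamics():
        expr = read_expression(data / "expr.tsv")
        mirna_expr = read_expression(data / "mirna_expr.tsv")
        profiles = stage_profiles(expr, pseudocount=cfg["pseudocount"])
        mirna_profiles = stage_profiles(mirna_expr, pseudocount=cfg["pseudocount"])
        frame = pd.DataFrame(
            [
                {
                    "gene_id": p.gene_id,
                    "max_abs_log2fc": p.max_abs_log2fc,
                    "de_flag": p.de_flag,
                    "de_fdr": p.de_fdr,
                }
                for p in profiles + mirna_profiles
            ]
        )
        frame.to_csv(out / "profiles.tsv", sep="\t", index=False)
        state.update(
            expr=expr,
            mirna_expr=mirna_expr,
            profiles=profiles,
            mirna_profiles={p.gene_id: p for p in mirna_profiles},
        )
        return {
            "n_de": int(sum(p.de_flag for p in profiles)),
            "n_de_mirna": int(
                sum(p.de_flag for p in state["mirna_profiles"].values())
            ),
        }

    # --- network ----------------------------------------------------------
    def stage_network():
        genes = state["genes"]
        regulators = set(state["regulators"])
        mirnas = {g.gene_id for g in genes if g.gene_class == "miRNA_precursor"}
        de = {p.gene_id for p in state["profiles"] if p.de_flag}
        de_tfs = {g.gene_id for g in genes if g.is_tf and g.gene_id in de}
        mirna_targets = read_edge_list(data / "mirna_targets.tsv")
        net = build_meta_network(
            state["assignments"], mirna_targets, regulators, mirnas,
            de_tfs | regulators,
        )
        net.to_edge_frame().to_csv(out / "edges.tsv", sep="\t", index=False)
        _, auto = cross_regulation_matrix(
            net, [r for r in regulators if r in net.graph]
        )
        state["network"] = net
        return {
            "n_nodes": net.n_nodes,
            "n_binds": len(net.edges_of_type("binds")),
            "n_silences": len(net.edges_of_type("silences")),
            "n_autoregulators": int(auto.sum()),
        }

    # --- motifs -----------------------------------------------------------
    def stage_motifs():
        net = state["network"]
        enrich = motif_enrichment(net, n_rand=cfg["n_rand"], seed=cfg["seed"])
        sims = find_sims(net)
        ppi_df = read_edge_list(data / "ppi.tsv", columns=("gene_a", "gene_b"))
        ppi = {
            frozenset((a, b))
            for a, b in zip(ppi_df["gene_a"], ppi_df["gene_b"])
        }
        sim_ppi = sim_ppi_enrichment(
            net, ppi, n_iter=cfg["ppi_n_iter"], seed=cfg["seed"]
        )
        payload = {
            "autoregulation": sorted(count_autoregulation(net)),
            "n_feedback_loops": len(count_feedback_loops(net)),
            "n_sims": len(sims),
            "sim_ppi_p": sim_ppi.p_value,
            "triads": [dataclasses.asdict(e) for e in enrich],
        }
        with open(out / "motifs.json", "w") as fh:
            json.dump(payload, fh, indent=1, allow_nan=True)
        return {
            "n_autoregulators": len(payload["autoregulation"]),
            "n_feedback_loops": payload["n_feedback_loops"],
            "n_sims": payload["n_sims"],
            "ffl_class_z": next(
                e.z for e in enrich if e.class_id == "030T"
            ),
        }

    # --- ffl --------------------------------------------------------------
    def stage_ffl():
        net = state["network"]
        binding = assignments_to_frame(state["assignments"])
        ffls = annotate_ffls(
            net,
            state["expr"],
            state["mirna_expr"],
            state["mirna_profiles"],
            binding,
            min_abs_r=cfg["min_abs_r"],
            fc_threshold=cfg["ffl_fc_threshold"],
        )
        ffls_to_frame(ffls).to_csv(out / "ffls.tsv", sep="\t", index=False)
        n_dyn = sum(f.dynamic for f in ffls)
        return {
            "n_ffls": len(ffls),
            "n_dynamic": int(n_dyn),
            "dynamic_fraction": n_dyn / len(ffls) if ffls else 0.0,
        }

    # --- robustness -------------------------------------------------------
    def stage_robustness():
        net = state["network"]
        full = attack_curve(net, max_fraction=cfg["attack_max_fraction"])
        stripped_net = net.without_etype("silences")
        stripped = attack_curve(
            stripped_net, max_fraction=cfg["attack_max_fraction"]
        )
        cmp = compare_curves(stripped, full)
        pd.DataFrame(
            {
                "fraction_removed": full.fractions,
                "loss_full": full.losses,
                "loss_without_mirna": stripped.losses,
            }
        ).to_csv(out / "curves.tsv", sep="\t", index=False)
        return {
            "auc_full": full.auc(),
            "auc_without_mirna": stripped.auc(),
            "ks_p": cmp.p_value,
        }

    # --- domains ----------------------------------------------------------
    def stage_domains():
        from .domains import DomainExpressionTable

        trap = DomainExpressionTable.from_frame(
            pd.read_csv(data / "trap.tsv", sep="\t", index_col=0)
        )
        calls = call_domain_genes(trap, p_cut=cfg["p_cut"], fc_cut=cfg["fc_cut"])
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "category": c.category,
                    "anova_p": c.anova_p,
                    "max_fc": c.max_fc,
                    "stage_support": c.stage_support,
                }
                for c in calls
            ]
        ).to_csv(out / "domain_calls.tsv", sep="\t", index=False)
        target_sets: dict[str, set] = {}
        for a in state["assignments"]:
            target_sets.setdefault(a.tf, set()).add(a.gene_id)
        universe = {g.gene_id for g in state["genes"]}
        bf = bound_fraction(calls, target_sets, universe)
        result = {
            "n_domain_specific": bf.n_called,
            "n_bound_ge2": bf.n_bound,
            "bound_fraction": bf.fraction,
            "enrichment_p": bf.enrichment_p,
        }
        try:
            organs = quartet_targets(target_sets)
            pd.DataFrame(
                [(o, g) for o, gs in organs.items() for g in sorted(gs)],
                columns=["organ", "gene_id"],
            ).to_csv(out / "quartet_targets.tsv", sep="\t", index=False)
            result["quartet_set_sizes"] = {o: len(g) for o, g in organs.items()}
        except KeyError:
            log.info("quartet complex members not all present; skipping")
        return result

    # --- regress ----------------------------------------------------------
    def stage_regress():
        df = pd.read_csv(data / "regression.tsv", sep="\t", index_col=0)
        y = df.pop("y").values
        ds = RegressionDataset(
            genes=list(df.index),
            feature_names=list(df.columns),
            X=df.values,
            y=y,
        )
        model = fit_lasso(
            ds, n_repeats=cfg["repeats"], n_folds=cfg["folds"], seed=cfg["seed"]
        )
        with open(out / "model.json", "w") as fh:
            json.dump(
                {
                    "coefficients": model.coefficients.round(10).to_dict(),
                    "intercept": round(model.intercept, 10),
                    "lambda": model.lambda_,
                    "cv_error_mean": model.cv_error_mean,
                    "cv_error_sd": model.cv_error_sd,
                },
                fh,
                indent=1,
            )
        return {
            "n_selected": int((model.coefficients != 0).sum()),
            "lambda": model.lambda_,
        }

    run_stage("targets", stage_targets)
    run_stage("dynamics", stage_dynamics)
    run_stage("network", stage_network)
    run_stage("motifs", stage_motifs)
    run_stage("ffl", stage_ffl)
    run_stage("robustness", stage_robustness)
    run_stage("domains", stage_domains)
    run_stage("regress", stage_regress)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, allow_nan=True, sort_keys=True)
    return report


def write_bundle(bundle, outdir: str | Path) -> None:
    """Write a synthetic bundle to disk in the pipeline's input layout."""
    from .io import write_expression, write_genes_tsv, write_peaks

    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    write_genes_tsv(outdir / "genes.tsv", bundle.annotation)
    with open(outdir / "regulators.txt", "w") as fh:
        for r in bundle.config.regulator_names():
            fh.write(r + "\n")
    write_expression(outdir / "expr.tsv", bundle.expression)
    write_expression(outdir / "mirna_expr.tsv", bundle.mirna_expression)
    bundle.mirna_targets.to_csv(outdir / "mirna_targets.tsv", sep="\t", index=False)
    for (tf, stage), plist in sorted(bundle.peaks.items()):
        write_peaks(outdir / "peaks" / f"{tf}_{stage}.bed", plist)
    trap = bundle.translatome.to_frame()
    trap.index.name = "gene_id"
    trap.to_csv(outdir / "trap.tsv", sep="\t")
    pd.DataFrame(
        sorted(sorted(p) for p in bundle.ppi), columns=["gene_a", "gene_b"]
    ).to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    reg = pd.DataFrame(
        bundle.regression.X,
        index=bundle.regression.genes,
        columns=bundle.regression.feature_names,
    )
    reg["y"] = bundle.regression.y
    reg.index.name = "gene_id"
    reg.round(10).to_csv(outdir / "regression.tsv", sep="\t")
    bundle.truth.to_json(outdir / "truth.json")
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=1)
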