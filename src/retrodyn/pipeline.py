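"""End-to-end orchestration: simulate/load -> DE -> modules -> GO -> TF -> network.

A single :class:`PipelineConfig` carries every threshold the analysis uses
(DET FDR, the strict term-FDR filter, the module z floor, the TF F-score
floor and z-group cuts, the network sensitivity/growth floors and growth
schedule).  :func:`run_pipeline` executes the stages in order, returns an
in-memory result object and optionally writes the stage tables plus a
manifest that suffices to reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import coexpress, de, go, network, simulate, tf
from . import io as rio


@dataclass
class PipelineConfig:
    counts: str | None = None
    metadata: str | None = None
    go_gmt: str | None = None
    go_categories: str | None = None
    tf_gmt: str | None = None
    ppi_edges: str | None = None
    simulate: bool = True
    n_transcripts: int = 2000
    det_fdr: float = 0.05
    term_fdr_max: float = 1e-4
    z_min: float = 2.0
    f_min: float = 20.0
    z_cuts: tuple = tf.DEFAULT_Z_CUTS
    sens_min: float = 40.0
    growth_min: float = 150.0
    schedule: tuple = network.DEFAULT_SCHEDULE
    zscore_variance_factor: float = 1.0
    min_module_size: int = 20
    cut_height: float = 0.99
    beta_candidates: tuple = tuple(range(1, 31))
    n_combined_modules: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("det_fdr", "term_fdr_max", "z_min", "f_min", "sens_min", "growth_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.schedule:
            raise ValueError("schedule must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("z_cuts", "schedule", "beta_candidates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        for key in ("z_cuts", "schedule", "beta_candidates"):
            d[key] = list(d[key])
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    de_result: de.DEResult
    pca_scores: pd.DataFrame
    partition: coexpress.ModulePartition | None
    eigengenes: pd.DataFrame | None
    det_terms: set[str]
    det_rollup: pd.DataFrame
    group_enrichment: pd.DataFrame
    best_predictor: dict[str, str]
    tf_table: pd.DataFrame
    tf_groups: dict[int, list[str]]
    trajectories: list[network.GrowthTrajectory]
    selection: network.NetworkSelection | None
    tiers: dict[str, str] | None
    selected_rollup: pd.DataFrame
    manifest: dict[str, Any]
    truth: simulate.GroundTruth | None = None


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        study = simulate.simulate_study(simulate.default_design(seed=cfg.seed, n_transcripts=cfg.n_transcripts))
        return study
    for name in ("counts", "metadata", "go_gmt", "go_categories", "tf_gmt", "ppi_edges"):
        path = getattr(cfg, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {path}")
    counts = rio.read_counts_tsv(cfg.counts)
    meta = rio.read_metadata(cfg.metadata)
    term_map = rio.read_gmt(cfg.go_gmt)
    category_map = rio.read_category_map(cfg.go_categories)
    tf_targets = rio.read_gmt(cfg.tf_gmt)
    graph = network.InteractionGraph.from_edges(rio.read_edge_list(cfg.ppi_edges))
    return simulate.SimulatedStudy(counts, meta, term_map, category_map, tf_targets, graph, None)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    cfg.validate()
    study = _load_inputs(cfg)
    counts, meta = study.counts, study.meta
    manifest: dict[str, Any] = {"config": cfg.to_dict(), "stages": {}}

    # --- differential expression -----------------------------------------
    sf = de.size_factors(counts)
    der = de.nb_lrt(counts, meta, sf, det_fdr_threshold=cfg.det_fdr)
    expr = de.vst(counts.loc[der.table.index], sf)
    scores, var_frac = de.pca_embedding(expr, n_components=2)
    dets = set(der.table.index[der.table["is_det"]])
    tested = set(der.table.index)
    manifest["stages"]["de"] = {
        "n_tested": len(tested),
        "n_dropped_all_zero": len(der.dropped_all_zero),
        "det_count": len(dets),
        "pc_variance_fractions": [round(float(v), 4) for v in var_frac],
    }

    # --- co-expression modules -------------------------------------------
    partition = eig = profiles = None
    module_sets: dict[int, set[str]] = {}
    if len(dets) >= max(cfg.min_module_size, 20):
        det_expr = expr.loc[sorted(dets)]
        st = coexpress.pick_soft_threshold(det_expr, list(cfg.beta_candidates))
        # block-structured DET sets are not scale-free; when the criterion is
        # unreachable fall back to the hardest candidate threshold, which
        # sharpens the block structure instead of blurring it
        beta = st.beta if not st.warning else max(cfg.beta_candidates)
        adj = coexpress.signed_adjacency(det_expr, beta)
        tom = coexpress.tom_similarity(adj)
        partition = coexpress.detect_modules(
            tom, list(det_expr.index), cfg.min_module_size, cfg.cut_height
        )
        eig, _, profiles = coexpress.module_eigengenes(det_expr, partition, meta["time"])
        module_sets = partition.module_sets()
        manifest["stages"]["modules"] = {
            "beta": beta,
            "beta_warning": st.warning,
            "n_modules": partition.n_modules,
            "module_sizes": partition.module_sizes,
            "unassigned_pct": round(partition.unassigned_fraction(), 2),
        }
    else:
        manifest["stages"]["modules"] = {"skipped": "too few DETs"}

    # --- GO enrichment ----------------------------------------------------
    det_terms: set[str] = set()
    det_rollup = pd.DataFrame(columns=["category", "count", "percentage"])
    group_records = pd.DataFrame()
    assignment: dict[str, str] = {}
    if dets:
        det_enrich = go.hypergeom_enrich(dets, study.term_map, tested)
        det_kept = go.filter_terms(det_enrich, cfg.term_fdr_max)
        det_terms = set(det_kept["term"])
        det_rollup, n_uncat = go.rollup_processes(det_terms, study.category_map)
        manifest["stages"]["go_dets"] = {
            "n_terms_tested": int(len(det_enrich)),
            "n_terms_kept": len(det_terms),
            "n_uncategorized": n_uncat,
        }
        if module_sets:
            per_module = go.module_group_enrichment(
                {f"[{m}]": s for m, s in module_sets.items()}, dets, study.term_map,
                cfg.term_fdr_max, cfg.z_min, cfg.zscore_variance_factor,
            )
            term_counts = per_module.loc[per_module["enriched"]].groupby("group").size()
            top = [int(name.strip("[]")) for name in
                   term_counts.sort_values(ascending=False).index[: cfg.n_combined_modules]]
            if not top:
                top = sorted(module_sets, key=lambda m: -len(module_sets[m]))[: cfg.n_combined_modules]
            groups = go.enumerate_module_groups(module_sets, top)
            group_records = go.module_group_enrichment(
                groups, dets, study.term_map, cfg.term_fdr_max, cfg.z_min, cfg.zscore_variance_factor
            )
            assignment, counts_per_group = go.best_predictor_assignment(group_records)
            manifest["stages"]["go_groups"] = {
                "combined_modules": top,
                "n_groups": len(groups),
                "n_enriched_pairs": int(group_records["enriched"].sum()) if len(group_records) else 0,
                "best_predictor_counts": {k: int(v) for k, v in counts_per_group.items()},
            }

    # --- TF enrichment ----------------------------------------------------
    tf_table = pd.DataFrame()
    tf_groups: dict[int, list[str]] = {}
    if dets and len(tested - dets):
        tf_table = tf.tf_overrepresentation(dets, tested - dets, study.tf_targets)
        tf_groups = tf.filter_and_group_tfs(tf_table, cfg.f_min, cfg.z_cuts)
        manifest["stages"]["tf"] = {
            "n_tfs": int(len(tf_table)),
            "group_sizes": {g: len(m) for g, m in tf_groups.items()},
        }

    # --- network retro-analysis -------------------------------------------
    trajectories: list[network.GrowthTrajectory] = []
    selection = tiers = None
    selected_rollup = pd.DataFrame(columns=["category", "count", "percentage"])
    if det_terms and tf_groups:
        for gi, members in tf_groups.items():
            seeds = [m for m in members if m in study.graph]
            if not seeds:
                continue
            trajectories.append(
                network.build_trajectory(
                    gi, study.graph, seeds, study.term_map, tested, det_terms,
                    cfg.schedule, cfg.term_fdr_max,
                )
            )
        if trajectories:
            selection = network.select_network(trajectories, cfg.sens_min, cfg.growth_min)
            if len(selection.nodes) >= 3:
                tiers = network.partition_network_kmeans(selection.nodes, study.graph, seed=cfg.seed)
            sel_traj = next(t for t in trajectories if t.tf_group == selection.tf_group)
            sel_terms = sel_traj.layers[selection.layer].enriched_terms
            selected_rollup, _ = go.rollup_processes(sel_terms, study.category_map)
            manifest["stages"]["network"] = {
                "n_trajectories": len(trajectories),
                "selected_group": selection.tf_group,
                "selected_layer": selection.layer,
                "selected_n_nodes": len(selection.nodes),
                "sensitivity_pct": round(selection.sensitivity_pct, 2),
                "specificity_pct": round(selection.specificity_pct, 2),
                "growth_pct": round(selection.growth_pct, 2),
                "relaxed": selection.relaxed,
            }

    result = PipelineResult(
        config=cfg, de_result=der, pca_scores=scores, partition=partition,
        eigengenes=eig, det_terms=det_terms, det_rollup=det_rollup,
        group_enrichment=group_records, best_predictor=assignment,
        tf_table=tf_table, tf_groups=tf_groups, trajectories=trajectories,
        selection=selection, tiers=tiers, selected_rollup=selected_rollup,
        manifest=manifest, truth=study.truth,
    )
    if outdir is not None:
        _write_outputs(result, profiles, Path(outdir))
    return result


def _write_outputs(res: PipelineResult, profiles, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.de_result.table.to_csv(outdir / "de_table.tsv", sep="\t")
    res.pca_scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    if res.partition is not None:
        res.partition.labels.to_csv(outdir / "module_partition.tsv", sep="\t")
    if res.eigengenes is not None:
        res.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
    if profiles is not None:
        profiles.to_csv(outdir / "module_profiles.tsv", sep="\t")
    if len(res.group_enrichment):
        res.group_enrichment.to_csv(outdir / "group_enrichment.tsv", sep="\t", index=False)
    res.det_rollup.to_csv(outdir / "det_rollup.tsv", sep="\t", index=False)
    if len(res.tf_table):
        res.tf_table.to_csv(outdir / "tf_table.tsv", sep="\t", index=False)
    if res.selection is not None:
        (outdir / "network_selection.json").write_text(
            json.dumps(
                {
                    "tf_group": res.selection.tf_group,
                    "layer": res.selection.layer,
                    "nodes": sorted(res.selection.nodes),
                    "sensitivity_pct": res.selection.sensitivity_pct,
                    "specificity_pct": res.selection.specificity_pct,
                    "growth_pct": res.selection.growth_pct,
                    "relaxed": res.selection.relaxed,
                },
                indent=1,
            )
        )
    if res.tiers:
        pd.Series(res.tiers, name="tier").rename_axis("node").to_csv(outdir / "network_tiers.tsv", sep="\t")
    (outdir / "manifest.json").write_text(json.dumps(res.manifest, indent=1, sort_keys=True))
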