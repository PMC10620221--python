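"""End-to-end orchestration of the two analysis arms.

The network arm runs merge → prune → filter → rank per declared cell type;
the secretion arm runs quantify → normalize → log-fold-change →
dose–response → group comparison.  Every intermediate artifact is written to
the output directory together with a run manifest (config dump + hash,
seeds, package version) sufficient to re-execute the run; reruns on
unchanged inputs are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .errors import InflamnetError, StageError
from .expression import ExpressionTable, filter_by_expression
from .network import merge_networks, read_sif, write_sif
from .pruning import MediatorPanel, enumerate_simple_paths, induce_subnetwork
from .quant import curves_to_frame, quantify_plate, read_plate_csv
from .stats import (
    compare_groups,
    dose_response_correlation,
    log_fold_change,
    normalize_to_control,
    results_to_frame,
)
from .topology import rank_nodes

logger = logging.getLogger(__name__)


class NetworkArmConfig(BaseModel):
    networks: list[str]
    node_attrs: list[str] = Field(default_factory=list)
    panel: str
    expression: str
    cell_types: list[str]
    max_nodes: int = 8
    count_mode: str = "nodes"
    threshold: float = 1.0
    keep_panel: bool = True
    order: str = "prune-filter"  # or "filter-prune" for sensitivity analysis


class SecretionArmConfig(BaseModel):
    plates: list[str]  # one CSV per independent experiment, in order
    control_condition: str = "LPS"
    baseline_condition: str = "media"
    dose_conditions: dict[str, float] = Field(default_factory=dict)
    alpha: float = 0.05
    r2_tolerance: float = 0.95
    log_base: float = 2.0
    bonferroni_posthoc: bool = True


class PipelineConfig(BaseModel):
    """Full pipeline configuration; fixed constants default to the analysis
    constants (depth cap 8 nodes, alpha 0.05, R² tolerance 0.95)."""

    outdir: str
    seed: int = 0
    network: NetworkArmConfig | None = None
    secretion: SecretionArmConfig | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.model_validate(tomllib.load(fh))


def _write_manifest(config: PipelineConfig, outdir: Path, arm: str) -> None:
    dump = config.model_dump()
    blob = json.dumps(dump, sort_keys=True).encode()
    manifest = {
        "arm": arm,
        "config": dump,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "inflamnet_version": __version__,
    }
    (outdir / f"manifest_{arm}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def run_network_arm(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """merge → prune → filter → rank, per cell type.

    Returns the topology report per cell type.  A degenerate configuration
    (e.g. a depth cap no path satisfies) exits cleanly with a warning and an
    empty report for every cell type.
    """
    if config.network is None:
        raise StageError("config", "no [network] section configured")
    cfg = config.network
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        attrs = list(cfg.node_attrs) + [None] * (len(cfg.networks) - len(cfg.node_attrs))
        nets = [read_sif(p, node_attrs=a) for p, a in zip(cfg.networks, attrs)]
        combined = merge_networks(nets, name="combined")
        write_sif(combined, outdir / "combined.sif", outdir / "combined_nodes.tsv")
    except InflamnetError as exc:
        raise StageError("merge", str(exc)) from exc

    try:
        panel = MediatorPanel.read_tsv(cfg.panel)
        pathset = enumerate_simple_paths(
            combined, panel, max_nodes=cfg.max_nodes, count_mode=cfg.count_mode
        )
        pathset.write_paths(outdir / "paths.txt")
        pruned = induce_subnetwork(combined, pathset)
        write_sif(pruned, outdir / "pruned.sif", outdir / "pruned_nodes.tsv")
    except InflamnetError as exc:
        raise StageError("prune", str(exc)) from exc
    if len(pathset) == 0:
        logger.warning(
            "no admissible paths at depth cap %d; emitting empty reports",
            cfg.max_nodes,
        )

    table = ExpressionTable.from_long(cfg.expression)
    reports: dict[str, pd.DataFrame] = {}
    for cell in cfg.cell_types:
        try:
            if cfg.order == "prune-filter":
                cell_net = filter_by_expression(
                    pruned, table, cell, cfg.threshold,
                    keep_panel=panel if cfg.keep_panel else None,
                )
            elif cfg.order == "filter-prune":
                pre = filter_by_expression(
                    combined, table, cell, cfg.threshold,
                    keep_panel=panel if cfg.keep_panel else None,
                )
                ps = enumerate_simple_paths(
                    pre, panel, max_nodes=cfg.max_nodes, count_mode=cfg.count_mode
                )
                cell_net = induce_subnetwork(pre, ps)
            else:
                raise ValueError(f"unknown order {cfg.order!r}")
            safe = cell.replace(" ", "_")
            write_sif(cell_net, outdir / f"{safe}.sif", outdir / f"{safe}_nodes.tsv")
            if cell_net.n_nodes < 2:
                logger.warning("%s: network too small to rank (%d nodes)",
                               cell, cell_net.n_nodes)
                report = pd.DataFrame()
            else:
                report = rank_nodes(cell_net)
            report.to_csv(outdir / f"{safe}_topology.tsv", sep="\t", index=False)
            reports[cell] = report
        except (InflamnetError, ValueError) as exc:
            raise StageError(f"rank[{cell}]", str(exc)) from exc

    _write_manifest(config, outdir, "network")
    return reports


def run_secretion_arm(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """quantify → normalize → LFC → dose–response → group comparisons.

    Values from non-accepted standard curves are never propagated (they are
    excluded at quantification).  Returns the output tables keyed by name.
    """
    if config.secretion is None:
        raise StageError("config", "no [secretion] section configured")
    cfg = config.secretion
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        frames, curve_frames = [], []
        for exp_idx, plate_path in enumerate(cfg.plates, start=1):
            wells = read_plate_csv(plate_path)
            conc, curves = quantify_plate(wells, r2_tolerance=cfg.r2_tolerance)
            conc["experiment"] = exp_idx
            cf = curves_to_frame(curves)
            cf["experiment"] = exp_idx
            frames.append(conc)
            curve_frames.append(cf)
        conc_all = pd.concat(frames, ignore_index=True)
        curves_all = pd.concat(curve_frames, ignore_index=True)
        n_out_of_range = int((conc_all["qualifier"] != "ok").sum())
        if n_out_of_range:
            logger.warning("%d well(s) out of curve range, excluded", n_out_of_range)
        conc_ok = conc_all[conc_all["qualifier"] == "ok"].reset_index(drop=True)
        curves_all.to_csv(outdir / "curves.csv", index=False)
        conc_all.to_csv(outdir / "concentrations.csv", index=False)
    except InflamnetError as exc:
        raise StageError("quantify", str(exc)) from exc

    try:
        normalized = normalize_to_control(conc_ok, cfg.control_condition)
        normalized.to_csv(outdir / "normalized.csv", index=False)
    except InflamnetError as exc:
        raise StageError("normalize", str(exc)) from exc

    try:
        lfc = log_fold_change(
            conc_ok, cfg.baseline_condition, base=cfg.log_base
        )
        lfc.to_csv(outdir / "lfc.csv", index=False)
    except InflamnetError as exc:
        raise StageError("lfc", str(exc)) from exc

    dose_df = pd.DataFrame()
    if cfg.dose_conditions:
        dosed = conc_ok[conc_ok["condition"].isin(cfg.dose_conditions)].copy()
        dosed["dose"] = dosed["condition"].map(cfg.dose_conditions)
        dose_df = dose_response_correlation(dosed)
        dose_df.to_csv(outdir / "dose_response.csv", index=False)

    try:
        results = compare_groups(
            normalized, alpha=cfg.alpha, bonferroni_posthoc=cfg.bonferroni_posthoc
        )
        stats_df = results_to_frame(results)
        stats_df.to_csv(outdir / "stats.csv", index=False)
    except (InflamnetError, ValueError) as exc:
        raise StageError("compare", str(exc)) from exc

    _write_manifest(config, outdir, "secretion")
    return {
        "concentrations": conc_all,
        "curves": curves_all,
        "normalized": normalized,
        "lfc": lfc,
        "dose_response": dose_df,
        "stats": stats_df,
    }
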