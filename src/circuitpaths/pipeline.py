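"""End-to-end pipeline: configuration, staged execution, run manifest.

One configuration object carries every scalar setting of the analysis
(neighbourhood, percentile levels, pathway levels, impedance rule set,
bootstrap replicates, seed). ``run_pipeline`` executes the stages in
order — pairwise circuit solves, cumulative accumulation, percentile
thresholding, spanning-tree ranking, pathway delineation, PAC overlay,
bootstrap baseline, impedance action maps — writing text outputs
(ESRI ASCII grids, CSV tables, GeoJSON) plus a JSON run manifest that
inventories every file, stage wall-times and warnings.

Current maps are streamed into the accumulator rather than stored: the
full range-wide analysis has ~14k pairs, and only the ranked spanning-tree
edges need their per-edge maps kept for pathway delineation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, circuit, gridio, impedance, maps, network, overlay
from .grids import CumulativeMap, GridGeoreference, LandCoverRaster, ZoneMask

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and scalar settings for one pipeline run.

    Defaults reproduce the reference analysis settings: Queen's-case
    adjacency, thresholds at the 50th–95th percentiles by 5 plus the 99th,
    pathway delineation at the 99/99.5/99.75th, the 95th percentile as the
    top-connectivity level for impedance intersection, and the
    cultivation>25%/canopy>10% rule set.
    """

    resistance_raster: str = ""
    node_table: str = ""
    edge_table: str = ""
    pac_polygons: str = ""
    mz_polygons: str = ""
    cultivation_raster: str = ""
    canopy_raster: str = ""
    output_dir: str = "outputs"
    crs_label: str = "synthetic-albers"

    neighborhood: str = "queen-8"
    threshold_levels: list = field(
        default_factory=lambda: list(maps.DEFAULT_THRESHOLD_LEVELS))
    pathway_levels: list = field(
        default_factory=lambda: list(maps.PATHWAY_LEVELS))
    top_level: float = 95.0
    top_k_pathways: int = 4
    use_provided_betweenness: bool = True
    rule_set: str = impedance.DEFAULT_RULES.name
    focal_radius_m: float = impedance.FOCAL_RADIUS_M
    bootstrap_reps: int = 200
    seed: int = 0
    keep_pair_maps: bool = False  # retain every per-edge current map (.asc)

    def __post_init__(self) -> None:
        if self.rule_set not in impedance.RULE_SETS:
            raise ValueError(
                f"unknown rule_set {self.rule_set!r}; "
                f"available: {sorted(impedance.RULE_SETS)}")
        if self.neighborhood not in ("queen-8", "rook-4"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if not 0 < self.top_level < 100:
            raise ValueError("top_level must lie in (0, 100)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config: dict
    package_version: str
    input_checksums: dict
    stage_seconds: dict
    warnings: list
    outputs: list

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def load_inputs(config: PipelineConfig):
    """Read and validate every input referenced by the config."""
    georef, values = gridio.read_ascii_grid(config.resistance_raster,
                                            crs_label=config.crs_label)
    raster = circuit.ResistanceRaster(georef, np.nan_to_num(values, nan=1.0)
                                      if georef.nodata_mask is not None else values)
    nodes = gridio.read_node_table(config.node_table)
    edges = gridio.read_edge_table(config.edge_table)
    net = network.GeneticNetwork(nodes, edges)
    pac_polys, pac_labels, _ = gridio.read_polygons_geojson(config.pac_polygons)
    mz_polys, mz_labels, _ = gridio.read_polygons_geojson(config.mz_polygons)
    cg, cv = gridio.read_ascii_grid(config.cultivation_raster,
                                    crs_label=config.crs_label)
    cult = LandCoverRaster(cg, cv, kind="cultivation")
    kg, kv = gridio.read_ascii_grid(config.canopy_raster,
                                    crs_label=config.crs_label)
    canopy = LandCoverRaster(kg, kv, kind="canopy")
    return raster, net, (pac_polys, pac_labels), (mz_polys, mz_labels), cult, canopy


def run_pipeline(config: PipelineConfig,
                 inputs=None) -> RunManifest:
    """Execute every stage and return the run manifest.

    ``inputs`` may carry pre-loaded objects (as returned by
    :func:`load_inputs`) to skip file reads; otherwise the config's paths
    are read. Identical config + inputs + seed give identical outputs.
    """
    collector = _WarningCollector()
    logging.getLogger("circuitpaths").addHandler(collector)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seconds: dict[str, float] = {}
    outputs: list[str] = []
    checksums: dict[str, str] = {}

    def emit(name: str) -> Path:
        p = out / name
        outputs.append(str(p))
        return p

    try:
        if inputs is None:
            inputs = load_inputs(config)
            for key in ("resistance_raster", "node_table", "edge_table",
                        "pac_polygons", "mz_polygons", "cultivation_raster",
                        "canopy_raster"):
                path = getattr(config, key)
                if path:
                    checksums[key] = _sha256(path)
        raster, net, (pac_polys, pac_labels), (mz_polys, mz_labels), cult, canopy = inputs
        georef = raster.georef

        # fail fast on config/input mismatches before any compute
        rules = impedance.RULE_SETS[config.rule_set]
        known_mz = set(mz_labels)
        referenced = {r.mz for r in rules.rules}
        unknown = referenced - known_mz
        if unknown:
            raise ValueError(
                f"rule set {rules.name!r} references MZ labels absent from "
                f"the MZ polygon set: {sorted(unknown)}")

        # --- stage: pairwise circuit solves + accumulation ---------------
        t0 = time.perf_counter()
        graph = circuit.build_resistance_graph(raster, config.neighborhood)
        total = np.zeros(georef.shape)
        res_rows = []
        n_pairs = 0
        for sol in circuit.solve_all_pairs(graph, net):
            total += sol.current_map
            res_rows.append((sol.edge_id, sol.source_node, sol.ground_node,
                             sol.effective_resistance))
            if config.keep_pair_maps:
                gridio.write_ascii_grid(emit(f"current_{sol.edge_id}.asc"),
                                        georef, sol.current_map)
            n_pairs += 1
        cmap = CumulativeMap(georef, total, n_pairs_summed=n_pairs)
        res_table = pd.DataFrame(res_rows, columns=[
            "edge_id", "node_a", "node_b", "effective_resistance"])
        res_table.to_csv(emit("pairwise_resistance.csv"), index=False)
        gridio.write_ascii_grid(emit("cumulative_connectivity.asc"),
                                georef, cmap.values)
        stage_seconds["solve_accumulate"] = time.perf_counter() - t0

        # --- stage: percentile thresholds ---------------------------------
        t0 = time.perf_counter()
        masks = maps.threshold_series(cmap, config.threshold_levels)
        pd.DataFrame(
            [(m.percentile_level, m.threshold_value, m.area_km2) for m in masks],
            columns=["level", "threshold_value", "area_km2"],
        ).to_csv(emit("threshold_table.csv"), index=False)
        for m in masks:
            gridio.write_ascii_grid(emit(f"threshold_{m.percentile_level:g}.asc"),
                                    georef, m.mask.astype(float))
        top_mask = next(m for m in masks
                        if m.percentile_level == config.top_level)
        stage_seconds["threshold"] = time.perf_counter() - t0

        # --- stage: spanning tree + ranking --------------------------------
        t0 = time.perf_counter()
        ranking = network.rank_mst_edges(
            net, use_provided=config.use_provided_betweenness,
            top_k=config.top_k_pathways)
        ranking.table.to_csv(emit("edge_ranking.csv"), index=False)
        stage_seconds["rank"] = time.perf_counter() - t0

        # --- stage: pathway delineation (re-solve only the ranked edges) ---
        t0 = time.perf_counter()
        ranked_ids = set(ranking.table["edge_id"])
        pathways = []
        for sol in circuit.solve_all_pairs(graph, net):
            if sol.edge_id not in ranked_ids:
                continue
            rank = int(ranking.table.loc[
                ranking.table["edge_id"] == sol.edge_id, "rank"].iloc[0])
            pw = maps.delineate_pathway(sol, config.pathway_levels, rank=rank)
            pathways.append(pw)
            for lv, m in pw.masks.items():
                gridio.write_ascii_grid(
                    emit(f"pathway_edge{sol.edge_id}_p{lv:g}.asc"),
                    georef, m.astype(float))
        stage_seconds["delineate"] = time.perf_counter() - t0

        # --- stage: PAC overlay --------------------------------------------
        t0 = time.perf_counter()
        pac = overlay.rasterize_polygons(pac_polys, georef, label="pac")
        prop_in = overlay.connectivity_within(cmap, pac)
        deciles = overlay.decile_partition(cmap, pac)
        deciles.to_csv(emit("decile_table.csv"), index=False)
        area_table = overlay.threshold_area_table(masks, pac)
        area_table.to_csv(emit("threshold_area_table.csv"), index=False)
        pd.DataFrame(
            [(pw.edge_id, pw.rank, lv, pct)
             for pw in pathways
             for lv, pct in overlay.pathway_overlap(pw, pac).items()],
            columns=["edge_id", "rank", "level", "pct_in_pac"],
        ).to_csv(emit("pathway_overlap.csv"), index=False)
        stage_seconds["overlay"] = time.perf_counter() - t0

        # --- stage: bootstrap baseline --------------------------------------
        t0 = time.perf_counter()
        boot = overlay.bootstrap_random_overlap(
            cmap, pac_polys, n_reps=config.bootstrap_reps, seed=config.seed)
        boot.to_frame().to_csv(emit("bootstrap_replicates.csv"), index=False)
        pd.DataFrame([{"observed": boot.observed, "replicate_mean": boot.mean,
                       "observed_over_random": boot.ratio,
                       "n_reps": boot.n_reps, "seed": boot.seed}]).to_csv(
            emit("bootstrap_summary.csv"), index=False)
        stage_seconds["bootstrap"] = time.perf_counter() - t0

        # --- stage: impedance action maps ------------------------------------
        t0 = time.perf_counter()
        mz_masks = [overlay.rasterize_polygons([poly], georef, label=lab)
                    for poly, lab in zip(mz_polys, mz_labels)]
        # MZ strips rasterized per-polygon can double-count boundary cells;
        # assign each cell to its first matching zone to keep the partition
        claimed = np.zeros(georef.shape, dtype=bool)
        for zm in mz_masks:
            zm.mask &= ~claimed
            claimed |= zm.mask
        summaries = {}
        for layer in (cult, canopy):
            focal = impedance.focal_fraction(layer, config.focal_radius_m)
            frac = impedance.resample_to_grid(focal, georef, method="mean")
            exceed = impedance.exceedance_mask(frac, mz_masks, rules,
                                               landcover=layer.kind)
            summary = impedance.action_map_summary(exceed, top_mask, pac,
                                                   landcover=layer.kind)
            summaries[layer.kind] = summary
            classes = impedance.action_class_grid(exceed, top_mask)
            gridio.write_ascii_grid(emit(f"action_map_{layer.kind}.asc"),
                                    georef, classes.astype(float))
        pd.concat(
            [s.table.assign(landcover=kind) for kind, s in summaries.items()]
        ).to_csv(emit("action_summary.csv"), index=False)
        stage_seconds["impedance"] = time.perf_counter() - t0

        # --- manifest ---------------------------------------------------------
        summary = {
            "n_pairs": n_pairs,
            "connectivity_within_pac": prop_in,
            "bootstrap_ratio": boot.ratio,
        }
        (out / "run_summary.json").write_text(
            json.dumps(summary, indent=2))
        outputs.append(str(out / "run_summary.json"))
        config.to_yaml(out / "config.yaml")
        outputs.append(str(out / "config.yaml"))
        manifest = RunManifest(asdict(config), __version__, checksums,
                               stage_seconds, collector.messages, outputs)
        manifest.write(out / "manifest.json")
        return manifest
    finally:
        logging.getLogger("circuitpaths").removeHandler(collector)
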