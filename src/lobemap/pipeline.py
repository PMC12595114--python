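"""End-to-end orchestration: preprocess → barcode → vessels → stats.

The whole run is described by one structured config (YAML or JSON) so a
quantification is reproducible from a single artefact; identical config and
seed give byte-identical outputs. Each stage's products (masks, code map,
labels, vessel maps, records) are also returned in memory so library users
and tests can drive the stages directly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import barcode as bc
from . import phantoms, preprocess, stats, vessels
from .core import ChannelSet, MetastasisRecord, VoxelGrid
from .io import read_volume, write_records, write_volume
from .preprocess import PreprocessParams

logger = logging.getLogger("lobemap")

__all__ = ["PipelineConfig", "LobeResult", "quantify_lobe", "run_pipeline", "validate_config", "load_config"]

_CHANNELS = ("sapphire", "venus", "tdtomato", "vessel")
_INPUT_KINDS = ("channels", "masks", "probability", "phantom")


@dataclass
class PipelineConfig:
    """Validated description of one whole-lobe quantification run."""

    input_kind: str = "channels"
    channel_paths: dict[str, str] = field(default_factory=dict)
    phantom_spec_path: str | None = None
    spacing: tuple[float, float, float] | None = None
    preprocess_default: PreprocessParams = field(default_factory=PreprocessParams)
    preprocess_overrides: dict[str, PreprocessParams] = field(default_factory=dict)
    barcode: bc.BarcodeParams = field(default_factory=bc.BarcodeParams)
    bin_preset: str = "fig3"
    corrections_path: str | None = None
    lung_volume_um3: float | None = None
    diversity_base: float | None = None
    mouse_id: str = "m1"
    group: str = "IV"
    output_dir: str = "lobemap_out"
    qc_maps: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def params_for(self, channel: str) -> PreprocessParams:
        return self.preprocess_overrides.get(channel, self.preprocess_default)


def _params_from_dict(d: Mapping) -> PreprocessParams:
    return PreprocessParams(**{k: d[k] for k in d})


def load_config(path) -> PipelineConfig:
    """Parse a YAML/JSON config file into a :class:`PipelineConfig`."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    pre = raw.get("preprocess", {}) or {}
    cfg = PipelineConfig(
        input_kind=raw.get("input", {}).get("kind", "channels"),
        channel_paths={c: raw.get("input", {}).get(c) for c in _CHANNELS
                       if raw.get("input", {}).get(c)},
        phantom_spec_path=raw.get("input", {}).get("phantom_spec"),
        spacing=tuple(raw["spacing"]) if raw.get("spacing") else None,
        preprocess_default=_params_from_dict(pre.get("default", {})),
        preprocess_overrides={
            c: _params_from_dict(pre[c]) for c in _CHANNELS if c in pre
        },
        barcode=bc.BarcodeParams(**(raw.get("barcode", {}) or {})),
        bin_preset=raw.get("bin_preset", "fig3"),
        corrections_path=raw.get("corrections"),
        lung_volume_um3=(raw.get("stats", {}) or {}).get("lung_volume_um3"),
        diversity_base=(raw.get("stats", {}) or {}).get("diversity_base"),
        mouse_id=str(raw.get("mouse_id", "m1")),
        group=str(raw.get("group", "IV")),
        output_dir=raw.get("output_dir", "lobemap_out"),
        qc_maps=bool(raw.get("qc_maps", False)),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    return cfg


def validate_config(path) -> list[str]:
    """List config violations without running anything (empty list = valid)."""
    violations: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        return [f"config file not found: {path}"]
    except yaml.YAMLError as e:
        return [f"unparseable config: {e}"]
    if not isinstance(raw, dict):
        return ["config must be a mapping"]

    kind = raw.get("input", {}).get("kind", "channels")
    if kind not in _INPUT_KINDS:
        violations.append(f"input.kind: unknown kind {kind!r}")
    if kind == "phantom":
        sp = raw.get("input", {}).get("phantom_spec")
        if not sp:
            violations.append("input.phantom_spec: required for phantom input")
        elif not Path(sp).exists():
            violations.append(f"input.phantom_spec: no such file {sp!r}")
    else:
        for c in _CHANNELS:
            p = raw.get("input", {}).get(c)
            if not p:
                violations.append(f"input.{c}: path required")
            elif not Path(p).exists():
                violations.append(f"input.{c}: no such file {p!r}")
        spacing = raw.get("spacing")
        if spacing is None:
            violations.append("spacing: required for volume inputs")
        elif len(spacing) != 3 or any(s <= 0 for s in spacing):
            violations.append(f"spacing: must be three positive values, got {spacing!r}")
    if raw.get("bin_preset", "fig3") not in bc.SIZE_BIN_PRESETS:
        violations.append(f"bin_preset: unknown preset {raw.get('bin_preset')!r}")
    try:
        pre = raw.get("preprocess", {}) or {}
        _params_from_dict(pre.get("default", {}))
        for c in _CHANNELS:
            if c in pre:
                _params_from_dict(pre[c])
    except (TypeError, ValueError) as e:
        violations.append(f"preprocess: {e}")
    try:
        bc.BarcodeParams(**(raw.get("barcode", {}) or {}))
    except (TypeError, ValueError) as e:
        violations.append(f"barcode: {e}")
    corrections = raw.get("corrections")
    if corrections and not Path(corrections).exists():
        violations.append(f"corrections: no such file {corrections!r}")
    return violations


@dataclass
class LobeResult:
    """Everything one lobe run produces, in memory."""

    records: list[MetastasisRecord]
    removed_ids: list[int]
    labels: VoxelGrid
    code_grid: VoxelGrid
    union: VoxelGrid
    vessel_mask: VoxelGrid
    maps: vessels.VesselMaps
    summary: dict


def _binarise_channels(channels: ChannelSet, cfg: PipelineConfig) -> dict[str, VoxelGrid]:
    masks = {}
    for name in _CHANNELS:
        grid: VoxelGrid = getattr(channels, name)
        params = cfg.params_for(name)
        if cfg.input_kind == "masks" or grid.dtype_role == "binary":
            masks[name] = VoxelGrid((grid.data != 0).astype(np.uint8), grid.spacing, "binary")
        elif cfg.input_kind == "probability":
            masks[name] = preprocess.threshold_mask(grid, params.prob_cutoff)
        else:
            masks[name] = preprocess.preprocess_channel(grid, params)
    return masks


def quantify_lobe(channels: ChannelSet, cfg: PipelineConfig,
                  corrections: pd.DataFrame | None = None) -> LobeResult:
    """Run the full measurement chain on an in-memory channel set."""
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    masks = _binarise_channels(channels, cfg)
    timings["preprocess_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    code_grid = bc.encode_barcodes(masks["sapphire"], masks["venus"], masks["tdtomato"])
    union = bc.union_mask(masks["sapphire"], masks["venus"], masks["tdtomato"])
    labels, n_objects = bc.label_objects(union, cfg.barcode.connectivity)
    records = bc.build_records(labels, mouse_id=cfg.mouse_id, group=cfg.group)
    records, removed = bc.filter_small_objects(records, cfg.barcode.min_volume_um3)
    records = bc.assign_object_barcodes(records, labels, code_grid, cfg.barcode.presence_fraction)
    if corrections is not None:
        records = bc.apply_corrections(records, corrections)
    records = [r.evolve(size_class=bc.classify_size(r.volume_um3, cfg.bin_preset)) for r in records]
    timings["barcode_s"] = time.perf_counter() - t0
    logger.info("barcode stage: %d objects, %d below volume filter", n_objects, len(removed))

    t0 = time.perf_counter()
    try:
        maps = vessels.compute_vessel_maps(masks["vessel"])
    except ValueError as e:
        raise ValueError(f"vessels stage: {e}") from e
    # keep only surviving objects in the label grid before measuring
    survivors = {r.object_id for r in records}
    lab = labels.data.copy()
    lab[~np.isin(lab, sorted(survivors))] = 0
    labels_f = VoxelGrid(lab, labels.spacing, "label")
    records = vessels.attach_vessel_metrics(records, labels_f, maps)
    timings["vessels_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    biomass = stats.biomass_fractions(code_grid, labels_f)
    lung = {cfg.mouse_id: cfg.lung_volume_um3} if cfg.lung_volume_um3 else None
    summary = {
        "mouse_id": cfg.mouse_id,
        "group": cfg.group,
        "n_objects_raw": n_objects,
        "n_removed_by_volume_filter": len(removed),
        "n_metastases": len(records),
        "n_monochromatic": sum(r.chromatic_class == "monochromatic" for r in records),
        "n_polychromatic": sum(r.chromatic_class == "polychromatic" for r in records),
        "biomass_fractions": biomass.as_named(),
        "n_bps_detected": biomass.n_bps_detected,
        "total_biomass_um3": biomass.total_biomass_um3,
        "shannon_biomass": stats.shannon_diversity(list(biomass.fractions.values()), cfg.diversity_base)
        if biomass.total_biomass_um3 > 0 else 0.0,
        "shannon_counts": stats.shannon_diversity(list(stats.count_fractions(records).values()),
                                                  cfg.diversity_base) if records else 0.0,
        "mono_poly": mono_poly_rows(records, lung),
    }
    timings["stats_s"] = time.perf_counter() - t0
    summary["timings"] = {k: round(v, 3) for k, v in timings.items()}

    return LobeResult(
        records=records,
        removed_ids=removed,
        labels=labels_f,
        code_grid=code_grid,
        union=union,
        vessel_mask=masks["vessel"],
        maps=maps,
        summary=summary,
    )


def mono_poly_rows(records, lung_volumes) -> list[dict]:
    df = stats.mono_poly_summary(records, lung_volumes) if records else pd.DataFrame()
    return df.to_dict(orient="records") if not df.empty else []


def _load_channels(cfg: PipelineConfig) -> ChannelSet:
    if cfg.input_kind == "phantom":
        with open(cfg.phantom_spec_path) as fh:
            spec = phantoms.spec_from_dict(yaml.safe_load(fh))
        channels, _ = phantoms.generate_phantom(spec)
        return channels
    role = "binary" if cfg.input_kind == "masks" else "intensity"
    grids = {}
    for name in _CHANNELS:
        if name not in cfg.channel_paths:
            raise ValueError(f"missing input path for channel {name!r}")
        grids[name] = read_volume(cfg.channel_paths[name], cfg.spacing, dtype_role=role)
    return ChannelSet(**grids)


def run_pipeline(config: PipelineConfig | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute a config end-to-end and write records CSV + summary JSON.

    Returns a manifest of output paths. Identical config and seed produce
    byte-identical outputs.
    """
    cfg = load_config(config) if not isinstance(config, PipelineConfig) else config
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        channels = _load_channels(cfg)
        corrections = pd.read_csv(cfg.corrections_path) if cfg.corrections_path else None
        result = quantify_lobe(channels, cfg, corrections)

        records_path = out / "records.csv"
        write_records(result.records, records_path)
        summary = dict(result.summary)
        summary["removed_object_ids"] = result.removed_ids
        summary["config"] = _echo_config(cfg)
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))

        manifest = {"records": str(records_path), "summary": str(summary_path)}
        if cfg.qc_maps:
            for name, grid in (
                ("union_mask", result.union),
                ("code_map", result.code_grid),
                ("distance_um", result.maps.distance_um),
                ("thickness_um", result.maps.thickness_um),
            ):
                p = out / f"qc_{name}.tif"
                write_volume(grid, p)
                manifest[name] = str(p)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _echo_config(cfg: PipelineConfig) -> dict:
    d = {
        "input_kind": cfg.input_kind,
        "spacing": list(cfg.spacing) if cfg.spacing else None,
        "bin_preset": cfg.bin_preset,
        "mouse_id": cfg.mouse_id,
        "group": cfg.group,
        "seed": cfg.seed,
        "barcode": vars(cfg.barcode),
        "preprocess_default": vars(cfg.preprocess_default),
        "preprocess_overrides": {k: vars(v) for k, v in cfg.preprocess_overrides.items()},
        "lung_volume_um3": cfg.lung_volume_um3,
        "diversity_base": cfg.diversity_base,
    }
    return d
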