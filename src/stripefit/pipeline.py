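"""Pipeline configuration, validation and orchestration.

A single YAML document drives the full analysis: obtain a viewpoint/control
ratio profile (either generated synthetically from known parameters or
extracted from a contact matrix), fit the extrusion model on a (p, d) grid,
optionally estimate roadblocks, and write all artifacts (profiles, ratio,
MSD surface, fit report, log) into an output directory.  Given the same
config and seed the primary outputs are byte-identical across reruns.

Genomic coordinates are 0-based half-open internally (BED convention);
viewpoint strand W means the profile reads toward increasing coordinates,
C toward decreasing ones.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fitting import FitConfig, estimate_blocks, fit_report, grid_fit
from .model import ExtrusionParams, Roadblock, RoadblockSet
from .profiles import (
    ContactProfile,
    RatioProfile,
    SMOOTHING_PRESETS,
    Viewpoint,
    average_controls,
    extract_profile,
    load_matrix,
    ratio,
)
from .synthetic import PRESETS, SyntheticSpec, scenario_presets, synth_profile_counts

__all__ = ["load_config", "validate_config", "run_pipeline"]

log = logging.getLogger("stripefit")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    cfg.setdefault("_base", str(Path(path).parent))
    return cfg


def _tsv_bin_width(path: Path) -> float | None:
    try:
        import pandas as pd

        d = pd.read_csv(path, sep="\t", usecols=["distance_kb"], nrows=3)["distance_kb"]
        return float(d.iloc[1] - d.iloc[0]) if len(d) > 1 else None
    except Exception:
        return None


def validate_config(cfg: dict) -> list[str]:
    """Static checks; an empty list means the config is runnable."""
    issues: list[str] = []
    base = Path(cfg.get("_base", "."))

    if "synth" not in cfg and "matrix" not in cfg and "ratio" not in cfg:
        issues.append("config: one of 'synth', 'matrix' or 'ratio' input is required")

    synth = cfg.get("synth")
    if synth is not None:
        preset = synth.get("preset")
        if preset is not None and preset not in PRESETS:
            issues.append(f"synth.preset: unknown preset {preset!r}")
        if preset is None and "params" not in synth:
            issues.append("synth: either 'preset' or 'params' is required")
        params = synth.get("params", {})
        if params.get("processivity_p", 1) <= 0:
            issues.append("synth.params.processivity_p: must be > 0")
        if not 0 <= params.get("density_d", 0) <= 1:
            issues.append("synth.params.density_d: must be in [0, 1]")

    matrix = cfg.get("matrix")
    if matrix is not None:
        path = base / matrix.get("path", "")
        if not path.exists():
            issues.append(f"matrix.path: {path} does not exist")
        vp = matrix.get("viewpoint")
        if not vp:
            issues.append("matrix.viewpoint: required (chrom, center_bp, strand)")
        smoothing = matrix.get("smoothing", "whole_chromosome")
        if isinstance(smoothing, str) and smoothing not in SMOOTHING_PRESETS:
            issues.append(f"matrix.smoothing: unknown preset {smoothing!r}")
        widths = set()
        for ctrl in matrix.get("controls", []):
            cpath = base / ctrl
            if not cpath.exists():
                issues.append(f"matrix.controls: {cpath} does not exist")
            else:
                bw = _tsv_bin_width(cpath)
                if bw is not None:
                    widths.add(round(bw, 9))
        if len(widths) > 1:
            issues.append(f"matrix.controls: mixed bin widths {sorted(widths)}")

    if "ratio" in cfg:
        rpath = base / cfg["ratio"]
        if not rpath.exists():
            issues.append(f"ratio: {rpath} does not exist")

    fit = cfg.get("fit", {})
    for key, lo in (("p_min", 0.0), ("p_max", 0.0), ("p_step", 0.0)):
        if key in fit and fit[key] <= lo:
            issues.append(f"fit.{key}: must be > {lo:g} (p_grid)")
    for key in ("d_min", "d_max"):
        if key in fit and not 0 <= fit[key] <= 1:
            issues.append(f"fit.{key}: must be in [0, 1] (d_grid)")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        issues.append("seed: must be an integer")
    return issues


def _fit_config(cfg: dict, terminal: float | None) -> FitConfig:
    fit = cfg.get("fit", {})
    p_grid = np.arange(
        fit.get("p_min", 10.0), fit.get("p_max", 500.0) + 1e-9, fit.get("p_step", 10.0)
    )
    d_grid = np.round(
        np.arange(fit.get("d_min", 0.01), fit.get("d_max", 0.30) + 1e-9, fit.get("d_step", 0.01)),
        10,
    )
    window = tuple(fit.get("window", (10.0, None)))
    known = [
        Roadblock(b["position_kb"], b.get("pause_alpha", 1.0), b.get("domain_width", 0.0))
        for b in fit.get("known_blocks", [])
    ]
    return FitConfig(
        p_grid=p_grid,
        d_grid=d_grid,
        fit_window=window,
        known_blocks=RoadblockSet(known, fit.get("terminal_kb", terminal)),
        gamma=fit.get("gamma", 1.5),
    )


def _synth_spec(cfg: dict) -> SyntheticSpec:
    from dataclasses import replace

    synth = dict(cfg.get("synth", {}))
    preset = synth.pop("preset", None)
    spec = scenario_presets(preset) if preset else None
    params = synth.pop("params", None)
    if params:
        blocks = RoadblockSet(
            [
                Roadblock(b["position_kb"], b["pause_alpha"], b.get("domain_width", 0.0))
                for b in synth.pop("blocks", [])
            ]
        )
        spec = SyntheticSpec(ExtrusionParams(**params), blocks)
    fields = {k: v for k, v in synth.items() if k in SyntheticSpec.__dataclass_fields__}
    return replace(spec, seed=cfg.get("seed", 0), **fields)


def _ratio_from_synth(cfg: dict, outdir: Path) -> tuple[RatioProfile, float]:
    spec = _synth_spec(cfg)
    pairs = synth_profile_counts(spec)
    ratios = [ratio(vp, ctrl) for vp, ctrl in pairs]
    stack = np.vstack([r.values for r in ratios])
    mean = np.nanmean(stack, axis=0)
    sem = (
        np.nanstd(stack, axis=0, ddof=1) / np.sqrt(len(ratios)) if len(ratios) > 1 else None
    )
    merged = RatioProfile(ratios[0].distances, mean, sem)
    for i, (vp, ctrl) in enumerate(pairs, 1):
        vp.to_tsv(outdir / f"profile_rep{i}.tsv")
        ctrl.to_tsv(outdir / f"control_rep{i}.tsv")
    log.info("synthetic data: preset=%s p=%g d=%g replicates=%d depth=%d",
             spec.name, spec.params.processivity_p, spec.params.density_d,
             spec.replicates, spec.total_contacts)
    return merged, spec.arm_length


def _ratio_from_matrix(cfg: dict, outdir: Path) -> tuple[RatioProfile, float | None]:
    mcfg = cfg["matrix"]
    base = Path(cfg.get("_base", "."))
    vp_spec = mcfg["viewpoint"]
    viewpoint = Viewpoint(
        vp_spec["chromosome"], vp_spec["center_bp"],
        vp_spec.get("window_kb", 3.0), vp_spec.get("strand", "W"),
    )
    matrix = load_matrix(
        base / mcfg["path"], viewpoint.chromosome, mcfg.get("apply_weights", False),
        bin_width=mcfg.get("bin_width", 1.0),
    )
    smoothing = mcfg.get("smoothing", "whole_chromosome")
    kernel, order = (
        SMOOTHING_PRESETS[smoothing] if isinstance(smoothing, str) else tuple(smoothing)
    )
    profile = extract_profile(matrix, viewpoint, kernel, order)
    profile.to_tsv(outdir / "profile.tsv")

    controls: list[ContactProfile] = []
    for entry in mcfg.get("controls", []):
        if isinstance(entry, str):
            controls.append(ContactProfile.from_tsv(base / entry))
        else:
            cvp = Viewpoint(
                entry["chromosome"], entry["center_bp"],
                entry.get("window_kb", 3.0), entry.get("strand", "W"),
            )
            controls.append(extract_profile(matrix, cvp, kernel, order))
    if not controls:
        raise ValueError("matrix mode requires at least one control viewpoint/profile")
    control = average_controls(controls)
    control.to_tsv(outdir / "control.tsv")
    return ratio(profile, control), None


def run_pipeline(cfg: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run synth/extract -> ratio -> fit -> report; returns the report dict."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {i}" for i in issues))

    outdir = Path(outdir or cfg.get("outdir", "stripefit_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("stripefit %s; seed=%s", __version__, cfg.get("seed", 0))
        stage = "input"
        terminal = None
        if "synth" in cfg:
            merged, terminal = _ratio_from_synth(cfg, outdir)
        elif "matrix" in cfg:
            merged, terminal = _ratio_from_matrix(cfg, outdir)
        else:
            merged = RatioProfile.from_tsv(Path(cfg.get("_base", ".")) / cfg["ratio"])
        merged.to_tsv(outdir / "ratio.tsv")

        stage = "fit"
        fconfig = _fit_config(cfg, terminal)
        result = grid_fit(merged, fconfig)
        if cfg.get("estimate_blocks", False):
            stage = "blocks"
            estimate_blocks(merged, result)
        result.surface_frame().to_csv(outdir / "msd_surface.tsv", sep="\t")

        stage = "report"
        report = fit_report(result)
        report["seed"] = cfg.get("seed", 0)
        (outdir / "fit_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        log.info("best fit: p=%g kb, d=%g, msd=%g",
                 report["best_processivity_kb"], report["best_density"], report["min_msd"])
        return report
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
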