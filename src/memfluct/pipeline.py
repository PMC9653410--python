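"""Config-driven orchestration of the analysis stages.

A single flat YAML config describes the input (a trajectory on disk or a
synthetic system to generate), which stages to run, and their parameters.
Stages execute in dependency order (io/generate -> heights / lipids /
modulus / orient -> landscape); every table is written as TSV with a fixed
float format, and a JSON manifest records parameters, seeds and SHA-256
checksums of all outputs, so a rerun with the same config and inputs
produces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .frames import INNER, OUTER
from .heights import compute_diagnostics, compute_height_map, compute_radial_envelope
from .lipids import count_contacts, depletion_enrichment, occupancy_heatmap
from .mechanics import build_height_field, compute_spectrum, fit_bending_modulus
from .orientation import (
    build_landscape,
    detect_minima,
    orientation_series,
    series_from_angles,
)
from .synthetic import (
    AngularPotential,
    DeformationTemplate,
    FootprintSpec,
    SyntheticSpec,
    apply_deformation_field,
    generate_undulating_membrane,
    plant_enrichment,
    sample_rotating_dimers,
)
from .trajio import SelectionConfig, load_trajectory, write_frames_hdf5

log = logging.getLogger("memfluct")

STAGES = ("generate", "heights", "lipids", "modulus", "orient", "landscape")
FLOAT_FORMAT = "%.6g"


class ConfigError(ValueError):
    """Invalid run configuration; the message itemizes every problem."""


@dataclass
class RunConfig:
    raw: dict
    output_dir: Path
    seed: int
    temperature: float
    enabled: dict[str, bool] = dc_field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        problems = []
        raw = dict(raw)
        out = raw.get("output_dir")
        if not out:
            problems.append("output_dir: required")
        seed = raw.get("seed", 0)
        if not isinstance(seed, int):
            problems.append("seed: must be an integer")
        temperature = raw.get("temperature", 310.0)
        if not isinstance(temperature, (int, float)) or temperature <= 0:
            problems.append("temperature: must be a positive number")
        enabled = {}
        for stage in STAGES:
            sect = raw.get(stage, {})
            if sect and not isinstance(sect, Mapping):
                problems.append(f"{stage}: must be a mapping")
                sect = {}
            enabled[stage] = bool(sect.get("enabled", False)) if sect else False
        gen = raw.get("generate", {}) or {}
        inp = raw.get("input", {}) or {}
        needs_frames = any(
            enabled[s] for s in ("heights", "lipids", "modulus", "orient")
        )
        if needs_frames and not enabled["generate"] and not inp.get("topology"):
            problems.append(
                "input.topology: required when analysis stages run without generate"
            )
        if inp.get("topology") and not Path(inp["topology"]).exists():
            problems.append(f"input.topology: no such file {inp['topology']!r}")
        if enabled["generate"]:
            for key in ("box_x", "box_y"):
                v = gen.get(key)
                if v is not None and (not isinstance(v, (int, float)) or v <= 0):
                    problems.append(f"generate.{key}: must be positive")
        if problems:
            raise ConfigError("invalid config:\n  - " + "\n  - ".join(problems))
        return cls(
            raw=raw,
            output_dir=Path(out),
            seed=int(seed),
            temperature=float(temperature),
            enabled=enabled,
        )

    def section(self, stage: str) -> dict:
        return dict(self.raw.get(stage, {}) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _build_synthetic(cfg: RunConfig):
    gen = cfg.section("generate")
    spec = SyntheticSpec(
        box_x=float(gen.get("box_x", 256.0)),
        box_y=float(gen.get("box_y", 256.0)),
        lipids_per_leaflet=int(gen.get("lipids_per_leaflet", 1024)),
        bending_modulus=float(gen.get("bending_modulus", 20.0)),
        surface_tension=float(gen.get("surface_tension", 0.0)),
        temperature=cfg.temperature,
        n_frames=int(gen.get("n_frames", 100)),
        seed=cfg.seed,
    )
    frames = generate_undulating_membrane(spec)
    placements = []
    for d in gen.get("deformations", []) or []:
        fp = FootprintSpec(
            center_xy=tuple(d["center"]),
            orientation=float(d.get("orientation", 0.0)),
            footprint_radius=float(d.get("footprint_radius", 25.0)),
            enrichment=d.get("enrichment", {}) or {},
            dimer_id=str(d.get("dimer_id", f"D{len(placements) + 1}")),
        )
        tmpl = DeformationTemplate(
            amplitude=float(d.get("amplitude", 5.0)),
            angular_order=int(d.get("angular_order", 2)),
            radial_center=float(d.get("radial_center", 25.0)),
            radial_width=float(d.get("radial_width", 10.0)),
            decay_length=float(d.get("decay_length", 30.0)),
        )
        placements.append((fp, tmpl))
    if placements:
        frames = apply_deformation_field(frames, placements)
        cutoff = float(gen.get("enrichment_cutoff", 7.0))
        for k, (fp, _t) in enumerate(placements):
            if fp.enrichment:
                frames = plant_enrichment(
                    frames, fp, cutoff=cutoff, seed=cfg.seed + 1000 + k
                )
    return frames


def run_pipeline(
    config: RunConfig | Mapping[str, Any] | str | Path,
    output_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the enabled stages and return the output manifest."""
    if isinstance(config, (str, Path)):
        cfg = RunConfig.from_file(config)
    elif isinstance(config, RunConfig):
        cfg = config
    else:
        cfg = RunConfig.from_dict(config)
    if output_dir is not None:
        cfg.output_dir = Path(output_dir)
    if seed is not None:
        cfg.seed = int(seed)
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)

    outputs: dict[str, str] = {}
    frames = None

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        _write_tsv(df, path)
        outputs[name] = _sha256(path)
        log.info("wrote %s", path)

    if cfg.enabled["generate"]:
        log.info("stage generate: seed=%d", cfg.seed)
        frames = _build_synthetic(cfg)
        h5 = out / "system.h5"
        write_frames_hdf5(frames, h5)
        outputs["system.h5"] = _sha256(h5)
    elif any(cfg.enabled[s] for s in ("heights", "lipids", "modulus", "orient")):
        inp = cfg.section("input")
        log.info("stage io: loading %s", inp.get("topology"))
        sel = SelectionConfig(window=tuple(inp["window"]) if inp.get("window") else None)
        frames = load_trajectory(inp["topology"], inp.get("trajectory"), sel)

    if cfg.enabled["heights"]:
        sect = cfg.section("heights")
        bin_size = float(sect.get("bin_size", 2.0))
        log.info("stage heights: bin_size=%g", bin_size)
        for leaf in (OUTER, INNER):
            hm = compute_height_map(frames, leaf, bin_size=bin_size)
            emit(f"height_map_{hm.leaflet_name}.tsv", hm.to_frame())
        if frames[0].dimers:
            ring = float(sect.get("ring_width", 5.0))
            did = frames[0].dimers[0].dimer_id
            for leaf in (OUTER, INNER):
                env = compute_radial_envelope(frames, did, leaf, ring_width=ring)
                emit(f"radial_envelope_{did}_{'oi'[leaf == INNER]}.tsv".replace(
                    "_o.", "_outer.").replace("_i.", "_inner."), env.to_frame())
        diag = compute_diagnostics(frames, bin_size=bin_size)
        emit("membrane_area.tsv", diag.area_series)
        emit("mass_profiles.tsv", diag.mass_profiles)

    if cfg.enabled["lipids"]:
        sect = cfg.section("lipids")
        cutoff = float(sect.get("cutoff", 7.0))
        log.info("stage lipids: cutoff=%g A", cutoff)
        if frames[0].dimers:
            did = frames[0].dimers[0].dimer_id
            contacts = count_contacts(frames, did, cutoff=cutoff)
            emit("contact_series.tsv", contacts.data)
            table = depletion_enrichment(frames, cutoff=cutoff)
            emit("depletion_enrichment.tsv", table.data)
            for lt in sect.get("heatmap_types", []) or []:
                for leaf_name in ("outer", "inner"):
                    try:
                        grid, xe, ye = occupancy_heatmap(frames, lt, leaf_name)
                    except ValueError:
                        continue
                    xc = 0.5 * (xe[:-1] + xe[1:])
                    yc = 0.5 * (ye[:-1] + ye[1:])
                    xx, yy = np.meshgrid(xc, yc, indexing="ij")
                    emit(
                        f"occupancy_{lt}_{leaf_name}.tsv",
                        pd.DataFrame(
                            {"x": xx.ravel(), "y": yy.ravel(),
                             "density": grid.ravel()}
                        ),
                    )
        else:
            log.warning("lipids stage skipped: no protein dimers in frames")

    if cfg.enabled["modulus"]:
        sect = cfg.section("modulus")
        grid_bin = float(sect.get("grid_bin", 1.0))
        excl = float(sect.get("exclusion_radius", 7.0 if frames[0].dimers else 0.0))
        log.info("stage modulus: grid_bin=%g exclusion=%g", grid_bin, excl)
        stack = build_height_field(frames, exclusion_radius=excl, grid_bin=grid_bin)
        if stack.occupancy < 0.9:
            log.warning("spectrum grid only %.0f%% populated", 100 * stack.occupancy)
        spectrum = compute_spectrum(stack)
        emit("fluctuation_spectrum.tsv", spectrum.to_frame())
        fit = fit_bending_modulus(spectrum, temperature=cfg.temperature)
        emit("bending_fit.tsv", pd.DataFrame([fit.to_row()]))

    series = None
    if cfg.enabled["orient"]:
        if frames[0].dimers:
            log.info("stage orient: %d dimers", len(frames[0].dimers))
            series = orientation_series(frames)
            emit("orientation_series.tsv", series.to_frame())
        else:
            log.warning("orient stage skipped: no protein dimers in frames")

    if cfg.enabled["landscape"]:
        sect = cfg.section("landscape")
        if sect.get("source", "potential") == "potential":
            pot = AngularPotential.from_wells(
                wells=[tuple(w) for w in sect.get("wells", [[45, 45], [135, 135]])],
                depth=float(sect.get("depth", 4.0)),
                width=float(sect.get("width", 40.0)),
            )
            n_steps = int(sect.get("n_steps", 30000))
            log.info("stage landscape: sampling %d Metropolis steps", n_steps)
            t1, t2, acc = sample_rotating_dimers(pot, n_steps, seed=cfg.seed + 7)
            log.info("sampler acceptance %.2f", acc)
            series = series_from_angles(t1, t2)
        elif series is None:
            raise ConfigError("landscape.source=series requires the orient stage")
        land = build_landscape(
            series,
            bin_width=float(sect.get("bin_width", 5.0)),
            temperature=cfg.temperature,
            smoothing_deg=float(sect.get("smoothing_deg", 0.0)),
        )
        emit("free_energy_landscape.tsv", land.to_frame())
        minima = detect_minima(land, depth_threshold=float(sect.get("depth_threshold", 1.0)))
        emit("landscape_minima.tsv", pd.DataFrame(minima or [],
             columns=["theta1", "theta2", "free_energy", "persistence"]))

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "temperature": cfg.temperature,
        "stages": {s: cfg.enabled[s] for s in STAGES},
        "parameters": {s: cfg.section(s) for s in STAGES if cfg.enabled[s]},
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
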