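"""End-to-end orchestration: generate or load, analyze, write a report bundle.

A run is described by one :class:`RunConfig` (YAML-friendly): either a
synthetic membrane spec or input file paths, a list of analysis stages,
grid spacings and cutoffs, and a seed.  Outputs are CSV tables plus a
``manifest.json`` recording inputs, parameters, package version and seed,
so any run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .clustering import aggregation_timeseries
from .colocalization import colocalization_table, default_targets
from .density_structure import (
    assign_leaflets,
    density_profile,
    enrichment_map,
    thickness_map,
    undulation_metric,
    unsaturation_histogram,
)
from .synthetic_membrane import MembraneSpec, build_membrane
from .trajectory_io import (
    Trajectory,
    bead_name_labels,
    read_composition,
    read_frames,
    residue_bead_labels,
    write_composition,
    write_frames,
)

ALL_STAGES = ("colocal", "density", "map2d", "thickness", "undulation", "unsat", "clusters")


@dataclass
class RunConfig:
    output_dir: str = "memshadow_run"
    seed: int = 0
    membrane: dict[str, Any] | None = None  # MembraneSpec overrides (synthetic input)
    trajectory_path: str | None = None  # or existing files
    composition_path: str | None = None
    analyses: tuple[str, ...] = ALL_STAGES
    grid_spacing: float = 0.5  # colocalization grid, nm
    map_spacing: float = 1.0  # enrichment/thickness maps, nm
    density_bin: float = 0.1  # nm
    cluster_cutoff: float = 1.0  # nm
    reference_residue: str = "NP"
    frame_range: tuple[int, int] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        if "frame_range" in raw and raw["frame_range"] is not None:
            raw["frame_range"] = tuple(raw["frame_range"])
        return cls(**raw)

    def validate(self) -> None:
        bad = [a for a in self.analyses if a not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown analyses: {bad}")
        if self.membrane is None and self.trajectory_path is None:
            raise ValueError("config needs either a synthetic membrane spec or input paths")
        for p in (self.trajectory_path, self.composition_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the manifest (also written).

    Validation is fail-fast: nothing is written if the config is invalid.
    A stage failure aborts with the stage name; the manifest written so far
    lists the completed outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "memshadow",
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "outputs": {},
    }

    if config.membrane is not None:
        mem = {k: v for k, v in config.membrane.items() if v is not None}
        if isinstance(mem.get("composition"), str):
            mem["composition"] = read_composition(mem["composition"])
        spec = MembraneSpec(**{**mem, "seed": config.seed})
        traj, truth = build_membrane(spec)
        write_frames(traj, out / "membrane.gro")
        write_composition(spec.composition, out / "composition.csv")
        truth.to_json(out / "ground_truth.json")
        manifest["outputs"]["membrane.gro"] = _sha256(out / "membrane.gro")
        manifest["outputs"]["composition.csv"] = _sha256(out / "composition.csv")
        manifest["outputs"]["ground_truth.json"] = _sha256(out / "ground_truth.json")
        comp = spec.composition
    else:
        comp = read_composition(config.composition_path) if config.composition_path else None
        traj = read_frames(config.trajectory_path, composition=comp)

    frame_range = slice(*config.frame_range) if config.frame_range else None
    frame0 = traj[0]
    stage = ""
    try:
        if "colocal" in config.analyses:
            stage = "colocal"
            ref = residue_bead_labels(frame0, config.reference_residue)
            targets = default_targets(comp, frame0)
            table = colocalization_table(
                traj, ref, targets, grid_spacing=config.grid_spacing, frame_range=frame_range
            )
            table.to_csv(out / "colocalization.csv", index=False)
            manifest["outputs"]["colocalization.csv"] = _sha256(out / "colocalization.csv")
        if "density" in config.analyses:
            stage = "density"
            selectors = {"PO4": bead_name_labels(frame0, ("PO4",))}
            try:
                selectors[config.reference_residue] = residue_bead_labels(
                    frame0, config.reference_residue
                )
            except ValueError:
                pass
            prof = density_profile(traj, selectors, bin_width=config.density_bin)
            prof.to_frame().to_csv(out / "density_profile.csv", index=False)
            manifest["outputs"]["density_profile.csv"] = _sha256(out / "density_profile.csv")
        if "map2d" in config.analyses:
            stage = "map2d"
            emap = enrichment_map(
                traj, residue_bead_labels(frame0, config.reference_residue),
                grid_spacing=config.map_spacing,
            )
            emap.to_frame().to_csv(out / "enrichment_np.csv", index=False)
            manifest["outputs"]["enrichment_np.csv"] = _sha256(out / "enrichment_np.csv")
        if "thickness" in config.analyses:
            stage = "thickness"
            tmap = thickness_map(traj, grid_spacing=config.map_spacing)
            pd.DataFrame(tmap.values).to_csv(out / "thickness.csv", index=False)
            manifest["outputs"]["thickness.csv"] = _sha256(out / "thickness.csv")
        if "undulation" in config.analyses:
            stage = "undulation"
            rms, spectrum = undulation_metric(traj)
            spectrum.insert(0, "rms_nm", rms)
            spectrum.to_csv(out / "undulation.csv", index=False)
            manifest["outputs"]["undulation.csv"] = _sha256(out / "undulation.csv")
        if "unsat" in config.analyses and comp is not None:
            stage = "unsat"
            hist = unsaturation_histogram(comp)
            hist.fractions.to_csv(out / "unsaturation.csv")
            manifest["outputs"]["unsaturation.csv"] = _sha256(out / "unsaturation.csv")
        if "clusters" in config.analyses:
            stage = "clusters"
            ts = aggregation_timeseries(
                traj, residue_bead_labels(frame0, config.reference_residue),
                cutoff=config.cluster_cutoff,
            )
            ts.to_csv(out / "clusters.csv", index=False)
            manifest["outputs"]["clusters.csv"] = _sha256(out / "clusters.csv")
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
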