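"""File I/O: HDF5 cubes, CSV phase series, run manifests, fixture generation."""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lens import PhaseLookup, design_lens
from .radar import (
    OccupancyScript,
    RadarConfig,
    SlowTimeCube,
    VitalScenario,
    beat_signal,
    occupancy_cube,
    scenario,
)

__all__ = [
    "RunManifest",
    "save_cube",
    "load_cube",
    "save_phase_csv",
    "load_phase_csv",
    "load_scenario_yaml",
    "make_fixtures",
]


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    seed: int | None
    config: dict
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    started: float = field(default_factory=time.time)
    elapsed_s: float | None = None
    version: str = __version__
    python: str = platform.python_version()

    def finish(self) -> "RunManifest":
        self.elapsed_s = time.time() - self.started
        return self

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if is_dataclass(obj):
        return asdict(obj)
    return str(obj)


def save_cube(cube: SlowTimeCube, path) -> None:
    """Write a slow-time cube to HDF5 (datasets iq, truth/*, config attrs)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("iq", data=cube.iq)
        fh.create_dataset("timestamps", data=cube.timestamps)
        if cube.truth_displacement is not None:
            fh.create_dataset("truth/displacement", data=cube.truth_displacement)
        if cube.truth_state is not None:
            fh.create_dataset(
                "truth/state", data=np.char.encode(cube.truth_state.astype(str))
            )
        fh.attrs["config"] = json.dumps(asdict(cube.config))
        if cube.scenario is not None:
            fh.attrs["scenario"] = json.dumps(asdict(cube.scenario), default=_jsonable)
        fh.attrs["meta"] = json.dumps(cube.meta, default=_jsonable)


def load_cube(path) -> SlowTimeCube:
    with h5py.File(path, "r") as fh:
        config = RadarConfig(**json.loads(fh.attrs["config"]))
        scn = None
        if "scenario" in fh.attrs:
            raw = json.loads(fh.attrs["scenario"])
            raw["motion_band"] = tuple(raw["motion_band"])
            scn = VitalScenario(**raw)
        truth_disp = fh["truth/displacement"][()] if "truth/displacement" in fh else None
        truth_state = (
            np.char.decode(fh["truth/state"][()]).astype(str)
            if "truth/state" in fh
            else None
        )
        return SlowTimeCube(
            iq=fh["iq"][()],
            config=config,
            timestamps=fh["timestamps"][()],
            truth_displacement=truth_disp,
            truth_state=truth_state,
            scenario=scn,
            meta=json.loads(fh.attrs.get("meta", "{}")),
        )


def save_phase_csv(times: np.ndarray, phase: np.ndarray, path) -> None:
    pd.DataFrame({"t_s": times, "phase_rad": phase}).to_csv(path, index=False)


def load_phase_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#")
    return df["t_s"].to_numpy(), df["phase_rad"].to_numpy()


def load_scenario_yaml(path) -> VitalScenario:
    """Scenario spec from YAML: either preset (condition/with_lens) or full fields."""
    spec = yaml.safe_load(open(path)) or {}
    if "condition" in spec:
        condition = spec.pop("condition")
        with_lens = bool(spec.pop("with_lens", True))
        if "motion_band" in spec:
            spec["motion_band"] = tuple(spec["motion_band"])
        return scenario(condition, with_lens, **spec)
    if "motion_band" in spec:
        spec["motion_band"] = tuple(spec["motion_band"])
    return VitalScenario(**spec)


def make_fixtures(kind: str, seed: int, outdir) -> list[Path]:
    """Write small deterministic inputs for tests and demos.

    Kinds: ``tones`` (two-tone CSV with generating parameters in a header
    comment), ``vitals`` (standby cube), ``occupancy`` (120 s scripted
    cube), ``lens`` (default 37×37 layout JSON + element CSV + lookup CSV).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "tones":
        fs, dur, f1, f2, a2 = 13.249, 120.0, 0.3, 1.2, 0.5
        t = np.arange(int(dur * fs)) / fs
        x = np.cos(2 * np.pi * f1 * t) + a2 * np.cos(2 * np.pi * f2 * t)
        path = outdir / "tones.csv"
        with open(path, "w") as fh:
            fh.write(f"# two tones: f1={f1} Hz (amp 1.0), f2={f2} Hz (amp {a2}), fs={fs} Hz\n")
            pd.DataFrame({"t_s": t, "phase_rad": x}).to_csv(fh, index=False)
        written.append(path)
    elif kind == "vitals":
        scn = scenario("standby", with_lens=True, duration=60.0, seed=seed)
        cube = beat_signal(scn, seed=seed)
        path = outdir / "vitals_standby.h5"
        save_cube(cube, path)
        written.append(path)
    elif kind == "occupancy":
        cube = occupancy_cube(OccupancyScript.standard(), seed=seed)
        path = outdir / "occupancy_script.h5"
        save_cube(cube, path)
        written.append(path)
    elif kind == "lens":
        layout = design_lens()
        j = outdir / "layout.json"
        c = outdir / "layout_elements.csv"
        l = outdir / "lookup.csv"
        layout.to_json(j)
        layout.to_element_csv(c)
        PhaseLookup.synthetic().to_csv(l)
        written.extend([j, c, l])
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
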