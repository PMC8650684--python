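"""AutoDock-Vina adapter: configuration, invocation (or a mock), log parsing.

Scores follow the Vina convention of kcal/mol with more negative = more
favorable; cascade thresholds therefore compare with ``<=``. The default box
and search settings mirror a common screening protocol: a 2.5 nm cube
centered on the pocket mass center, exhaustiveness 8, 20 binding modes,
energy range 3 kcal/mol.

The mock engine makes the whole pipeline runnable and testable without a
docking binary: it returns a deterministic affinity computed from the
ligand's heavy-atom count and the seed, with synthetic poses placed inside
the search box.
"""

from __future__ import annotations

import re
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .mol_io import StructureModel, PocketDefinition, read_pose_coords


@dataclass
class DockingConfig:
    center: tuple[float, float, float]  # Å
    size: tuple[float, float, float] = (25.0, 25.0, 25.0)  # Å (2.5 nm cube)
    exhaustiveness: int = 8
    num_modes: int = 20
    energy_range: float = 3.0  # kcal/mol

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise ValueError("box sizes must be positive")
        if self.exhaustiveness < 1:
            raise ValueError("exhaustiveness must be >= 1")


@dataclass
class DockedPose:
    mode: int
    affinity: float  # kcal/mol
    rmsd_lb: float
    rmsd_ub: float
    coords: list[tuple[str, float, float, float]] = field(default_factory=list)


@dataclass
class DockingResult:
    poses: list[DockedPose]

    @property
    def best_affinity(self) -> float:
        return min(p.affinity for p in self.poses)

    @property
    def best_pose(self) -> DockedPose:
        return min(self.poses, key=lambda p: p.affinity)


def make_config(pocket: PocketDefinition, **overrides) -> DockingConfig:
    """Box centered on the pocket mass center with the default search settings."""
    return DockingConfig(center=pocket.mass_center, **overrides)


def write_config_file(config: DockingConfig, path: str | Path,
                      receptor: str | Path | None = None,
                      ligand: str | Path | None = None) -> Path:
    path = Path(path)
    lines = []
    if receptor is not None:
        lines.append(f"receptor = {receptor}")
    if ligand is not None:
        lines.append(f"ligand = {ligand}")
    for axis, c in zip("xyz", config.center):
        lines.append(f"center_{axis} = {c}")
    for axis, s in zip("xyz", config.size):
        lines.append(f"size_{axis} = {s}")
    lines += [f"exhaustiveness = {config.exhaustiveness}",
              f"num_modes = {config.num_modes}",
              f"energy_range = {config.energy_range}"]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_config_file(path: str | Path) -> DockingConfig:
    vals: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            vals[k.strip()] = v.strip()
    return DockingConfig(
        center=tuple(float(vals[f"center_{a}"]) for a in "xyz"),
        size=tuple(float(vals[f"size_{a}"]) for a in "xyz"),
        exhaustiveness=int(vals.get("exhaustiveness", 8)),
        num_modes=int(vals.get("num_modes", 20)),
        energy_range=float(vals.get("energy_range", 3.0)),
    )


class MockDockingEngine:
    """Deterministic stand-in engine for tests and dry runs.

    The affinity of the best mode is ``-(2.0 + 0.18 * n_heavy) + jitter``
    where the jitter is drawn from a generator keyed by (seed, ligand
    composition), so the same ligand + seed always docks identically. Poses
    are uniform draws inside the configured box.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed

    def _rng_for(self, ligand_coords) -> np.random.Generator:
        key = hash(tuple(round(v, 3) for a in ligand_coords for v in a[1:])) & 0x7FFFFFFF
        return np.random.default_rng((self.seed, key))

    def dock(self, receptor: StructureModel,
             ligand_coords: Sequence[tuple[str, float, float, float]],
             config: DockingConfig) -> DockingResult:
        if not ligand_coords:
            raise ValueError("empty ligand")
        rng = self._rng_for(ligand_coords)
        n_heavy = sum(1 for el, *_ in ligand_coords if el.capitalize() not in ("H", "D"))
        base = -(2.0 + 0.18 * n_heavy) + float(rng.normal(0, 0.4))
        center = np.array(config.center)
        half = np.array(config.size) / 2.0
        poses = []
        elements = [el for el, *_ in ligand_coords]
        for mode in range(1, config.num_modes + 1):
            affinity = base + 0.25 * (mode - 1)
            if mode > 1 and affinity - base > config.energy_range:
                break
            # poses land off the box center: a non-cognate ligand settles in
            # shallow peripheral minima rather than the pocket focus
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            origin = center + direction * rng.uniform(4.0, 10.0)
            spread = rng.uniform(-1.5, 1.5, size=(len(elements), 3))
            xyz = np.clip(origin + spread, center - half, center + half)
            coords = [(el, *map(float, p)) for el, p in zip(elements, xyz)]
            poses.append(DockedPose(mode=mode, affinity=round(affinity, 1),
                                    rmsd_lb=0.0 if mode == 1 else round(mode * 0.9, 1),
                                    rmsd_ub=0.0 if mode == 1 else round(mode * 1.4, 1),
                                    coords=coords))
        return DockingResult(poses=poses)


class ExternalVinaEngine:
    """Thin adapter over an installed ``vina`` binary (not bundled)."""

    def __init__(self, executable: str = "vina"):
        self.executable = executable

    def dock_files(self, receptor_path: str | Path, ligand_path: str | Path,
                   config: DockingConfig, workdir: str | Path) -> DockingResult:
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        conf = write_config_file(config, workdir / "conf.txt",
                                 receptor=receptor_path, ligand=ligand_path)
        out_path = workdir / "out.pdbqt"
        proc = subprocess.run(
            [self.executable, "--config", str(conf), "--out", str(out_path)],
            capture_output=True, text=True, timeout=3600)
        if proc.returncode != 0:
            raise RuntimeError(f"vina failed: {proc.stderr.strip()[:500]}")
        result = parse_docking_log(proc.stdout)
        for pose in result.poses:
            try:
                pose.coords = read_pose_coords(out_path, model=pose.mode)
            except ValueError:
                pass
        return result


def run_docking(engine, receptor, ligand, config: DockingConfig) -> DockingResult:
    """Dispatch one docking run; engine crashes propagate as RuntimeError so a
    batch caller can record the failure and continue."""
    if isinstance(engine, MockDockingEngine):
        return engine.dock(receptor, ligand, config)
    if isinstance(engine, ExternalVinaEngine):
        raise TypeError("external engine needs file paths; use dock_files()")
    raise TypeError(f"unknown engine: {engine!r}")


_ROW_RE = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)"
                     r"\s+(-?\d+(?:\.\d+)?)\s*$")


def parse_docking_log(text: str) -> DockingResult:
    """Parse a Vina-style result table (mode | affinity | rmsd l.b. | u.b.)."""
    poses = []
    for line in text.splitlines():
        m = _ROW_RE.match(line)
        if m:
            poses.append(DockedPose(mode=int(m.group(1)),
                                    affinity=float(m.group(2)),
                                    rmsd_lb=float(m.group(3)),
                                    rmsd_ub=float(m.group(4))))
    if not poses:
        raise ValueError("no docking result table found in log")
    poses.sort(key=lambda p: p.mode)
    return DockingResult(poses=poses)
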