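"""Post-analysis of binding-stability MD and metadynamics output.

Binding stability over a trajectory is judged by the ligand RMSD after
least-squares superposition of each frame onto a reference over the protein
Cα atoms — superposing on the protein separates ligand motion from global
tumbling — together with the count of protein–ligand hydrogen bonds per
frame. The free-energy surface along a collective variable s is estimated
from a metadynamics hills log as the negated sum of the deposited Gaussians:

    F(s) = − Σ_k h_k · exp(−(s − s_k)² / (2 σ_k²))

Default hydrogen-bond criterion: donor–acceptor distance ≤ 3.5 Å and
D–H···A angle ≥ 130°; both are configurable since published criteria vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class Trajectory:
    """Frames of one simulation plus static atom metadata and selections.

    ``coords`` is ``(n_frames, n_atoms, 3)`` in Å; ``times`` in ps, strictly
    increasing. Selections are atom-index lists; ``donors`` pairs each donor
    heavy atom with its hydrogen.
    """

    times: np.ndarray
    coords: np.ndarray
    elements: list[str]
    ligand_atoms: list[int] = field(default_factory=list)
    calpha_atoms: list[int] = field(default_factory=list)
    donors: list[tuple[int, int]] = field(default_factory=list)  # (D, H)
    acceptors: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times and frames disagree")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.5       # donor–acceptor distance, Å
    angle_min: float = 130.0  # D–H···A angle, degrees

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0 < self.angle_min <= 180):
            raise ValueError("angle_min must be in (0, 180]")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation R, mobile centroid, reference centroid) such that
    ``(x - mob_c) @ R + ref_c`` maps mobile-frame coordinates onto the
    reference frame, minimizing the RMSD over the matched points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("superposition selections must match in size")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return R, mc, rc


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    measure_selection: Sequence[int] | None = None,
    superpose_selection: Sequence[int] | None = None,
) -> list[tuple[float, float]]:
    """Per-frame RMSD after least-squares superposition.

    Each frame is superposed onto the reference frame over
    ``superpose_selection`` (default: protein Cα), then the RMSD is measured
    over ``measure_selection`` (default: ligand atoms).
    """
    measure = list(measure_selection if measure_selection is not None
                   else traj.ligand_atoms)
    superpose = list(superpose_selection if superpose_selection is not None
                     else traj.calpha_atoms)
    if not measure:
        raise ValueError("empty measure selection")
    if len(superpose) < 3:
        raise ValueError("superpose selection needs at least 3 atoms")
    ref = traj.coords[reference_frame]
    out = []
    for t, frame in zip(traj.times, traj.coords):
        R, mc, rc = kabsch_superpose(frame[superpose], ref[superpose])
        moved = (frame[measure] - mc) @ R + rc
        diff = moved - ref[measure]
        rmsd = float(np.sqrt((diff ** 2).sum() / len(measure)))
        out.append((float(t), rmsd))
    return out


def hbond_series(traj: Trajectory,
                 criteria: HBondCriteria = HBondCriteria()
                 ) -> list[tuple[float, int]]:
    """Count donor–H···acceptor hydrogen bonds per frame.

    A triple counts when the donor–acceptor distance is ≤ ``d_max`` and the
    D–H···A angle is ≥ ``angle_min``; an acceptor identical to the donor or
    its hydrogen is skipped.
    """
    if not traj.donors or not traj.acceptors:
        raise ValueError("donor and acceptor selections must be non-empty")
    out = []
    for t, frame in zip(traj.times, traj.coords):
        count = 0
        for d_idx, h_idx in traj.donors:
            for a_idx in traj.acceptors:
                if a_idx in (d_idx, h_idx):
                    continue
                d_xyz, h_xyz, a_xyz = frame[d_idx], frame[h_idx], frame[a_idx]
                if np.linalg.norm(a_xyz - d_xyz) > criteria.d_max:
                    continue
                v1 = d_xyz - h_xyz
                v2 = a_xyz - h_xyz
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                cosang = np.clip(v1 @ v2 / denom, -1.0, 1.0)
                if np.degrees(np.arccos(cosang)) >= criteria.angle_min:
                    count += 1
        out.append((float(t), count))
    return out


# -- metadynamics ------------------------------------------------------------

@dataclass
class HillsLog:
    """Deposited Gaussian hills: (time, CV center s, width σ, height h)."""

    times: np.ndarray
    centers: np.ndarray
    sigmas: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        n = len(self.times)
        if n == 0:
            raise ValueError("hills log must contain at least one hill")
        if any(len(a) != n for a in (self.centers, self.sigmas, self.heights)):
            raise ValueError("hills columns must have equal length")
        if np.any(self.sigmas <= 0):
            raise ValueError("hill widths must be positive")
        if np.any(self.heights < 0):
            raise ValueError("hill heights must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class FESGrid:
    grid: np.ndarray
    values: np.ndarray

    def minimum(self) -> tuple[float, float]:
        i = int(np.argmin(self.values))
        return float(self.grid[i]), float(self.values[i])


def read_hills(path: str | Path) -> HillsLog:
    """Read a whitespace-delimited hills file (time, center, sigma, height);
    comment lines starting with # are skipped."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "@")):
            continue
        parts = line.split()
        rows.append([float(v) for v in parts[:4]])
    if not rows:
        raise ValueError(f"no hills found in {path}")
    arr = np.array(rows)
    return HillsLog(times=arr[:, 0], centers=arr[:, 1], sigmas=arr[:, 2],
                    heights=arr[:, 3])


def default_grid(hills: HillsLog, n_points: int = 512) -> np.ndarray:
    """Grid spanning [min center − 3σ_max, max center + 3σ_max]."""
    pad = 3.0 * float(hills.sigmas.max())
    return np.linspace(hills.centers.min() - pad, hills.centers.max() + pad,
                       n_points)


def reconstruct_fes(hills: HillsLog, grid: np.ndarray | None = None,
                    shift_min_to_zero: bool = False,
                    bias_factor: float | None = None) -> FESGrid:
    """Free-energy estimate: negated sum of the deposited Gaussians.

    ``bias_factor`` γ applies the well-tempered rescaling γ/(γ−1) to the
    negated bias; left off by default. ``shift_min_to_zero`` renormalizes so
    the global minimum sits at 0.
    """
    if len(hills) == 0:
        raise ValueError("empty hills log")
    s = default_grid(hills) if grid is None else np.asarray(grid, dtype=float)
    # vectorized Gaussian sum: (n_grid, n_hills)
    diff = s[:, None] - hills.centers[None, :]
    bias = (hills.heights[None, :]
            * np.exp(-diff ** 2 / (2.0 * hills.sigmas[None, :] ** 2))).sum(axis=1)
    F = -bias
    if bias_factor is not None:
        if bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        F = F * bias_factor / (bias_factor - 1.0)
    if shift_min_to_zero:
        F = F - F.min()
    return FESGrid(grid=s, values=F)


def write_fes(fes: FESGrid, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# cv free_energy\n")
        for s, f in zip(fes.grid, fes.values):
            fh.write(f"{s:.8g} {f:.8g}\n")
    return path


def stability_rank(rmsd_by_candidate: dict[str, Sequence[tuple[float, float]]],
                   k: int) -> list[str]:
    """Top-k candidate ids by ascending mean ligand RMSD.

    Ties keep the candidates' input order (insertion order of the dict).
    """
    n = len(rmsd_by_candidate)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} candidates")
    means = {name: float(np.mean([r for _, r in series]))
             for name, series in rmsd_by_candidate.items()}
    order = sorted(means, key=lambda name: means[name])
    return order[:k]


# -- trajectory file I/O -----------------------------------------------------

def read_multimodel_pdb(path: str | Path, dt_ps: float = 1.0) -> Trajectory:
    """Read frames from a multi-model PDB; element from columns 77–78."""
    frames: list[list[tuple[str, float, float, float]]] = []
    current: list[tuple[str, float, float, float]] = []
    in_model = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("MODEL"):
            in_model = True
            current = []
        elif line.startswith("ENDMDL"):
            frames.append(current)
            in_model = False
        elif line.startswith(("ATOM", "HETATM")):
            el = line[76:78].strip() or line[12:16].strip()[0]
            current.append((el.capitalize(), float(line[30:38]),
                            float(line[38:46]), float(line[46:54])))
    if in_model and current:
        frames.append(current)
    if not frames and current:
        frames.append(current)
    if not frames:
        raise ValueError(f"no frames in {path}")
    n_atoms = len(frames[0])
    if any(len(f) != n_atoms for f in frames):
        raise ValueError("atom count varies across frames")
    coords = np.array([[(x, y, z) for _, x, y, z in f] for f in frames])
    elements = [el for el, *_ in frames[0]]
    times = np.arange(len(frames), dtype=float) * dt_ps
    return Trajectory(times=times, coords=coords, elements=elements)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for m, frame in enumerate(traj.coords, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (el, (x, y, z)) in enumerate(zip(traj.elements, frame), start=1):
                fh.write("ATOM  {0:5d} {1:^4s} MOL A   1    {2:8.3f}{3:8.3f}"
                         "{4:8.3f}  1.00  0.00          {5:>2s}\n"
                         .format(i, el[:4], x, y, z, el[:2]))
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path
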