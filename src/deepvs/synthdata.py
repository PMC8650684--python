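"""Synthetic inputs for every pipeline stage, plus the published score tables.

Everything the cascade consumes can be generated here without downloads:

* planted-signal pocket–ligand libraries for the pair-vector classifier —
  token-level "molecules" where each pocket carries a hidden key token and a
  ligand binds iff it carries the complementary key, with labels flipped at a
  controlled noise rate;
* tiny 3-D pocket-shell complexes for the interface classifier and the mock
  docking engine;
* stable / drifting ligand trajectories for the stability analysis;
* Gaussian hills logs for free-energy reconstruction;
* the two published candidate score tables, shipped verbatim as CSV with
  pinned checksums.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .cascade import ScoreRecord
from .interface import DockedComplex
from .mol_io import StructureModel
from .traj import HillsLog, Trajectory

TABLE_CHECKSUMS = {
    "table1.csv": "4e66902cbbb4b2d554656b8547bbc1557a72202c82229a7509921bd1ff7b5168",
    "table2.csv": "4d8710f3c5d15e24a246c8d2d084cd92cf5852e66b4b68f40bee976fa3602040",
}


# -- planted-signal pair library ---------------------------------------------

@dataclass(frozen=True)
class PlantedLibrarySpec:
    """Conditions for a planted-signal pocket–ligand library.

    ``signal_strength`` s flips each rule-determined label with probability
    (1 − s)/2, so s = 1 is noiseless and s = 0 makes labels independent of
    content. ``binder_rate`` controls the fraction of cognate-key ligands
    (actives are deliberately the minority, as in a screening library).
    Defaults give 50 × 40 = 2,000 pairs.
    """

    n_pockets: int = 50
    ligands_per_pocket: int = 40
    signal_strength: float = 0.9
    alphabet_size: int = 6
    seed: int = 7
    binder_rate: float = 0.1

    def __post_init__(self):
        if self.n_pockets < 2:
            raise ValueError("n_pockets must be >= 2")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")


@dataclass
class PlantedPair:
    pair_id: str
    pocket_id: str
    pocket_sentence: list[str]
    ligand_sentence: list[str]
    label: int          # observed (possibly flipped) binary label
    true_binder: bool   # the underlying token rule, pre-flip


_POCKET_FILLER = 40
_LIGAND_FILLER = 60
_POCKET_LEN = 15
_LIGAND_LEN = 12
_DISTRACTOR_RATE = 0.2  # non-binders may carry a mismatched key token


def generate_planted_library(spec: PlantedLibrarySpec) -> list[PlantedPair]:
    """Generate token-level pocket–ligand pairs with a planted binding rule.

    Pocket ``p`` carries hidden key token ``PK<k>``; a ligand truly binds iff
    its sentence contains the complementary ``LK<k>``. Non-binders may carry
    a mismatched key (distractor), so the classifier must learn the pairing,
    not mere key presence. The observed label equals the rule outcome flipped
    with probability (1 − signal_strength)/2.
    """
    rng = np.random.default_rng(spec.seed)
    flip_p = (1.0 - spec.signal_strength) / 2.0
    pairs: list[PlantedPair] = []
    for p in range(spec.n_pockets):
        key = int(rng.integers(spec.alphabet_size))
        filler = rng.integers(_POCKET_FILLER, size=_POCKET_LEN - 1)
        pocket_sentence = [f"PK{key}"] + [f"PF{j}" for j in filler]
        rng.shuffle(pocket_sentence)
        pocket_id = f"pocket{p}"
        for l in range(spec.ligands_per_pocket):
            is_binder = bool(rng.random() < spec.binder_rate)
            filler = rng.integers(_LIGAND_FILLER, size=_LIGAND_LEN - 1)
            sentence = [f"LF{j}" for j in filler]
            if is_binder:
                sentence.append(f"LK{key}")
            elif spec.alphabet_size > 1 and rng.random() < _DISTRACTOR_RATE:
                wrong = int(rng.integers(spec.alphabet_size - 1))
                if wrong >= key:
                    wrong += 1
                sentence.append(f"LK{wrong}")
            else:
                sentence.append(f"LF{int(rng.integers(_LIGAND_FILLER))}")
            rng.shuffle(sentence)
            label = int(is_binder)
            if rng.random() < flip_p:
                label = 1 - label
            pairs.append(PlantedPair(pair_id=f"pocket{p}_lig{l}",
                                     pocket_id=pocket_id,
                                     pocket_sentence=pocket_sentence,
                                     ligand_sentence=sentence,
                                     label=label, true_binder=is_binder))
    return pairs


# -- tiny 3-D complexes for interface / docking tests ------------------------

_SHELL_ELEMENTS = ["C", "C", "C", "N", "O", "S"]
_LIGAND_ELEMENTS = ["C", "C", "C", "N", "O", "F"]


def generate_toy_complexes(n: int = 8, seed: int = 0,
                           n_shell: int = 30,
                           n_ligand: int = 10) -> list[DockedComplex]:
    """Random pocket shells with a cognate ligand placed at the center.

    Each complex is a spherical shell of heavy atoms (radius 5–8 Å) around
    its own center, with the cognate ligand tucked inside — a compact
    interface with many close contacts, in contrast to the sparse interfaces
    mock cross-docked poses produce.
    """
    if n < 1:
        raise ValueError("need at least one complex")
    rng = np.random.default_rng(seed)
    complexes = []
    for i in range(n):
        center = rng.uniform(-50, 50, size=3)
        atoms = []
        for j in range(n_shell):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            xyz = center + direction * rng.uniform(5.0, 8.0)
            el = _SHELL_ELEMENTS[int(rng.integers(len(_SHELL_ELEMENTS)))]
            atoms.append((el, el, "POC", j + 1, "A",
                          float(xyz[0]), float(xyz[1]), float(xyz[2])))
        structure = StructureModel(atoms=atoms)
        lig = []
        for j in range(n_ligand):
            xyz = center + rng.uniform(-2.0, 2.0, size=3)
            el = _LIGAND_ELEMENTS[int(rng.integers(len(_LIGAND_ELEMENTS)))]
            lig.append((el, float(xyz[0]), float(xyz[1]), float(xyz[2])))
        complexes.append(DockedComplex(complex_id=f"cpx{i}", structure=structure,
                                       ligand_coords=lig,
                                       box_center=tuple(float(v) for v in center)))
    return complexes


# -- trajectories ------------------------------------------------------------

def generate_trajectory(kind: str = "stable", n_frames: int = 100,
                        noise: float = 0.3, drift: float = 0.1,
                        seed: int = 0, n_calpha: int = 12,
                        n_ligand: int = 6, dt_ps: float = 100.0) -> Trajectory:
    """Emulate a stable or steadily drifting bound ligand.

    ``stable``: ligand coordinates are the reference plus isotropic Gaussian
    noise (Å). ``drifting``: additionally displaced along a fixed direction
    by ``drift`` Å per frame, cumulative. The protein Cα cage is near-rigid:
    its jitter is noise/6, so a zero-noise trajectory is exactly rigid.
    """
    if kind not in ("stable", "drifting"):
        raise ValueError("kind must be 'stable' or 'drifting'")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    # reference geometry: Cα ring of radius 8 Å, ligand blob at center
    angles = np.linspace(0, 2 * np.pi, n_calpha, endpoint=False)
    calpha_ref = np.stack([8.0 * np.cos(angles), 8.0 * np.sin(angles),
                           np.linspace(-3, 3, n_calpha)], axis=1)
    ligand_ref = rng.uniform(-1.5, 1.5, size=(n_ligand, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)

    frames = []
    for f in range(n_frames):
        cal = calpha_ref + rng.normal(0, noise / 6.0, size=calpha_ref.shape)
        lig = ligand_ref + rng.normal(0, noise, size=ligand_ref.shape)
        if kind == "drifting":
            lig = lig + direction * (drift * f)
        frames.append(np.vstack([cal, lig]))
    coords = np.stack(frames)
    elements = ["C"] * n_calpha + ["C"] * n_ligand
    return Trajectory(times=np.arange(n_frames, dtype=float) * dt_ps,
                      coords=coords, elements=elements,
                      ligand_atoms=list(range(n_calpha, n_calpha + n_ligand)),
                      calpha_atoms=list(range(n_calpha)))


# -- hills logs --------------------------------------------------------------

def generate_hills(n: int = 500, center_range: tuple[float, float] = (0.0, 3.0),
                   sigma_range: tuple[float, float] = (0.05, 0.3),
                   height_range: tuple[float, float] = (0.1, 1.5),
                   seed: int = 0, dt: float = 1.0) -> HillsLog:
    """Uniform random Gaussian hills inside the given ranges, seeded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return HillsLog(times=np.arange(n, dtype=float) * dt,
                    centers=rng.uniform(*center_range, size=n),
                    sigmas=rng.uniform(*sigma_range, size=n),
                    heights=rng.uniform(*height_range, size=n))


def write_hills(hills: HillsLog, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# time center sigma height\n")
        for t, s, sig, h in zip(hills.times, hills.centers, hills.sigmas,
                                hills.heights):
            fh.write(f"{t:.6g} {s:.10g} {sig:.10g} {h:.10g}\n")
    return path


# -- published score tables ---------------------------------------------------

def _read_fixture(name: str) -> tuple[str, list[ScoreRecord]]:
    text = resources.files("deepvs").joinpath("data", name).read_text()
    records = []
    for line in text.strip().splitlines()[1:]:
        name_, bc, dock, df = line.rsplit(",", 3)
        records.append(ScoreRecord(name=name_, deepbindbc=float(bc),
                                   docking=float(dock), dfcnn=float(df)))
    return text, records


def verify_fixtures() -> None:
    """Raise if a packaged table was edited (sha256 pinned at release)."""
    for fname, expected in TABLE_CHECKSUMS.items():
        text, _ = _read_fixture(fname)
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != expected:
            raise RuntimeError(f"fixture {fname} was modified "
                               f"(sha256 {digest} != {expected})")


def load_table_fixtures() -> tuple[list[ScoreRecord], list[ScoreRecord]]:
    """The two published candidate tables, rows verbatim in printed order."""
    verify_fixtures()
    _, table1 = _read_fixture("table1.csv")
    _, table2 = _read_fixture("table2.csv")
    return table1, table2
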