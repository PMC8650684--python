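"""Protein–ligand interface featurization and native-vs-decoy pose scoring.

The second (structure-aware) screening stage. Each docked pose is reduced to
a fixed-size 2-D map: one row per protein-heavy-atom / ligand-heavy-atom pair
within a distance cutoff, sorted by distance, each row encoding the two
element identities (one-hot over a small alphabet) and the scaled distance.
A small convolutional network with identity skip connections classifies maps
as native-like versus decoy; decoys come from cross-docking — docking each
ligand into receptors from *other* complexes.

The exact tensor layout (alphabet, cutoff 10 Å, 256 rows, distance scaled by
1/cutoff) is declared here and echoed in saved model files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import nn
from .mol_io import StructureModel

#: one-hot element alphabet; halogens share a slot, everything else -> other
ELEMENT_ALPHABET = ("C", "N", "O", "S", "P", "X", "other")
_HALOGENS = {"F", "Cl", "Br", "I"}
_HYDROGEN = {"H", "D"}

DEFAULT_CUTOFF = 10.0  # Å
DEFAULT_MAX_ROWS = 256
N_CHANNELS = 2 * len(ELEMENT_ALPHABET) + 1


def _element_slot(symbol: str) -> int:
    s = symbol.capitalize()
    if s in _HALOGENS:
        return ELEMENT_ALPHABET.index("X")
    if s in ELEMENT_ALPHABET:
        return ELEMENT_ALPHABET.index(s)
    return ELEMENT_ALPHABET.index("other")


@dataclass
class InterfaceMap:
    """``(max_rows, channels)`` matrix: protein one-hot ++ ligand one-hot ++
    scaled distance, rows ascending by distance, zero-padded."""

    matrix: np.ndarray
    cutoff: float
    n_contacts: int


@dataclass
class PoseLabel:
    label: str  # "native" | "decoy"
    origin: str  # "experimental" | "cross_docked"

    def __post_init__(self):
        if self.origin == "cross_docked" and self.label != "decoy":
            raise ValueError("cross-docked poses are decoys by construction")


def featurize_interface(
    structure: StructureModel,
    pose_coords: Sequence[tuple[str, float, float, float]],
    cutoff: float = DEFAULT_CUTOFF,
    max_rows: int = DEFAULT_MAX_ROWS,
) -> InterfaceMap:
    """Build the contact map of a pose against its receptor.

    One row per (protein heavy atom, ligand heavy atom) pair with distance
    <= cutoff; rows sorted ascending by distance with ties broken by
    (protein atom index, ligand atom index); truncated to the ``max_rows``
    closest contacts and zero-padded. An empty interface yields an all-pad
    map rather than an error.
    """
    if len(pose_coords) == 0:
        raise ValueError("pose must contain at least one atom")
    prot_idx = [i for i, a in enumerate(structure.atoms) if a[0] not in _HYDROGEN]
    lig = [(j, el, np.array([x, y, z]))
           for j, (el, x, y, z) in enumerate(pose_coords)
           if el.capitalize() not in _HYDROGEN]

    matrix = np.zeros((max_rows, N_CHANNELS))
    if not prot_idx or not lig:
        return InterfaceMap(matrix=matrix, cutoff=cutoff, n_contacts=0)

    pxyz = structure.coordinates()[prot_idx]
    lxyz = np.vstack([c for _, _, c in lig])
    d = np.sqrt(((pxyz[:, None, :] - lxyz[None, :, :]) ** 2).sum(axis=2))
    rows: list[tuple[float, int, int, int, int]] = []
    for pi in range(len(prot_idx)):
        for li in range(len(lig)):
            dist = d[pi, li]
            if dist <= cutoff:
                rows.append((float(dist), prot_idx[pi], lig[li][0],
                             _element_slot(structure.atoms[prot_idx[pi]][0]),
                             _element_slot(lig[li][1])))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    n = len(rows)
    for r, (dist, _pi, _li, pslot, lslot) in enumerate(rows[:max_rows]):
        matrix[r, pslot] = 1.0
        matrix[r, len(ELEMENT_ALPHABET) + lslot] = 1.0
        matrix[r, -1] = dist / cutoff
    return InterfaceMap(matrix=matrix, cutoff=cutoff, n_contacts=n)


@dataclass
class DockedComplex:
    """A receptor with its cognate ligand pose, for decoy generation."""

    complex_id: str
    structure: StructureModel
    ligand_coords: list[tuple[str, float, float, float]]
    box_center: tuple[float, float, float]


def build_cross_docking_decoys(
    complexes: Sequence[DockedComplex],
    docking_engine,
    n_per_complex: int = 2,
    seed: int = 0,
    box_size: tuple[float, float, float] = (25.0, 25.0, 25.0),
) -> list[tuple[DockedComplex, list[tuple[str, float, float, float]], PoseLabel]]:
    """Dock non-cognate ligands into each receptor and keep the best pose.

    For receptor ``i``, up to ``n_per_complex`` ligands ``j != i`` are drawn
    (seeded, without replacement), docked with ``docking_engine``, and the
    lowest-affinity pose per (i, j) pair is labelled a cross-docked decoy.
    Engine failures on a pair are logged and the pair skipped.
    Returns (receptor complex, pose coords, label) triples.
    """
    from .dock import DockingConfig  # local import to avoid cycle
    import logging

    if len(complexes) < 2:
        raise ValueError("need at least 2 complexes for cross-docking")
    rng = np.random.default_rng(seed)
    out = []
    for i, receptor in enumerate(complexes):
        others = [j for j in range(len(complexes)) if j != i]
        k = min(n_per_complex, len(others))
        chosen = rng.choice(others, size=k, replace=False)
        config = DockingConfig(center=receptor.box_center, size=box_size)
        for j in sorted(int(j) for j in chosen):
            try:
                result = docking_engine.dock(receptor.structure,
                                             complexes[j].ligand_coords, config)
            except Exception as exc:  # engine crash: skip pair, keep going
                logging.getLogger(__name__).warning(
                    "docking failed for (%s, %s): %s", receptor.complex_id,
                    complexes[j].complex_id, exc)
                continue
            best = result.poses[0]
            out.append((receptor, best.coords,
                        PoseLabel(label="decoy", origin="cross_docked")))
    return out


@dataclass
class InterfaceClassifier:
    """Conv-residual pose classifier over interface maps."""

    network: nn.Network
    channels: int
    n_blocks: int
    max_rows: int
    cutoff: float
    seed: int

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.network.state_arrays())}
        np.savez(path, __format__=np.array("deepvs-interface-v1"),
                 channels=np.array(self.channels), n_blocks=np.array(self.n_blocks),
                 max_rows=np.array(self.max_rows), cutoff=np.array(self.cutoff),
                 seed=np.array(self.seed), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "InterfaceClassifier":
        data = np.load(path, allow_pickle=False)
        if str(data["__format__"]) != "deepvs-interface-v1":
            raise ValueError("not a deepvs interface model file")
        obj = cls(network=nn.conv_resnet(N_CHANNELS, int(data["channels"]),
                                         int(data["n_blocks"]), seed=int(data["seed"])),
                  channels=int(data["channels"]), n_blocks=int(data["n_blocks"]),
                  max_rows=int(data["max_rows"]), cutoff=float(data["cutoff"]),
                  seed=int(data["seed"]))
        n = len(obj.network.state_arrays())
        obj.network.load_state_arrays([data[f"p{i}"] for i in range(n)])
        return obj


def train_interface_classifier(
    maps: Sequence[InterfaceMap],
    labels: Sequence[PoseLabel | str | int],
    channels: int = 16,
    n_blocks: int = 4,
    epochs: int = 20,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> InterfaceClassifier:
    """Fit the native-vs-decoy classifier; native -> 1, decoy -> 0."""
    y = np.array([_label_to_int(l) for l in labels], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both native and decoy poses")
    X = np.stack([m.matrix for m in maps])
    net = nn.conv_resnet(X.shape[2], channels=channels, n_blocks=n_blocks, seed=seed)
    net.fit(X, y, epochs=epochs, batch_size=batch_size,
            learning_rate=learning_rate, seed=seed)
    return InterfaceClassifier(network=net, channels=channels, n_blocks=n_blocks,
                               max_rows=maps[0].matrix.shape[0],
                               cutoff=maps[0].cutoff, seed=seed)


def _label_to_int(label) -> int:
    if isinstance(label, PoseLabel):
        return 1 if label.label == "native" else 0
    if isinstance(label, str):
        return 1 if label == "native" else 0
    return int(label)


def predict_pose_score(classifier: InterfaceClassifier,
                       interface_map: InterfaceMap) -> float:
    """Score in [0, 1]; higher = more native-like. Valid on all-pad maps."""
    return float(classifier.network.predict_proba(
        interface_map.matrix[None, :, :])[0])


def predict_pose_scores(classifier: InterfaceClassifier,
                        maps: Sequence[InterfaceMap]) -> np.ndarray:
    return classifier.network.predict_proba(np.stack([m.matrix for m in maps]))
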