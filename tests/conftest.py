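from __future__ import annotations

import numpy as np
import pytest

from deepvs.mol_io import StructureModel


@pytest.fixture
def toy_structure() -> StructureModel:
    """Three one-atom 'residues' at 4, 9.9 and 10.1 Å from a ligand atom at
    the origin — brackets the 1 nm pocket cutoff."""
    atoms = [
        ("C", "CA", "ALA", 1, "A", 4.0, 0.0, 0.0),
        ("C", "CA", "GLY", 2, "A", 9.9, 0.0, 0.0),
        ("C", "CA", "SER", 3, "A", 10.1, 0.0, 0.0),
    ]
    return StructureModel(atoms=atoms)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_structure(rng: np.random.Generator, n_res: int = 8,
                     atoms_per_res: int = 4, spread: float = 12.0) -> StructureModel:
    """Random small protein-like structure for oracle comparisons."""
    elements = ["C", "N", "O", "S"]
    atoms = []
    for r in range(n_res):
        for a in range(atoms_per_res):
            xyz = rng.uniform(-spread, spread, size=3)
            atoms.append((elements[int(rng.integers(len(elements)))],
                          f"A{a}", "RES", r + 1, "A",
                          float(xyz[0]), float(xyz[1]), float(xyz[2])))
    return StructureModel(atoms=atoms)
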