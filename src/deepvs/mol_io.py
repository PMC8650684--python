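"""Molecule and structure I/O, pocket extraction, and docking-input preparation.

Small-molecule libraries are read with RDKit (SMILES / SDF / MOL2); receptor
structures are read from PDB with Biopython. Internally every coordinate is in
Ångström. Pocket cutoffs are accepted in nanometres, the unit binding-site
definitions are usually quoted in, and converted (1 nm = 10 Å).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

NM_TO_ANGSTROM = 10.0

#: elements treated as hydrogens and ignored in pocket-distance tests
_HYDROGEN = {"H", "D"}


class EmptyLibraryError(ValueError):
    """A library file contained no parseable molecule."""


class EmptyPocketError(ValueError):
    """No residue lies within the cutoff of the reference ligand."""


@dataclass
class MoleculeRecord:
    """One library compound: an id, a SMILES, and optional 3D coordinates."""

    id: str
    smiles: str
    coords: list[tuple[str, float, float, float]] | None = None
    source: str = ""

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {self.id!r}: {self.smiles!r}")
        return mol


@dataclass
class StructureModel:
    """A receptor structure as a flat atom table.

    Each atom is (element, atom name, residue name, residue number, chain id,
    x, y, z) with coordinates in Å.
    """

    atoms: list[tuple[str, str, str, int, str, float, float, float]]

    def coordinates(self) -> np.ndarray:
        return np.array([a[5:8] for a in self.atoms], dtype=float)

    def residues(self) -> dict[tuple[str, int], list[int]]:
        """Map (chain, residue number) -> atom indices, in file order."""
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a[4], a[3]), []).append(i)
        return out


@dataclass
class PocketDefinition:
    """Binding pocket: residues within ``cutoff_nm`` of a reference ligand.

    ``mass_center`` is the unweighted arithmetic mean of the pocket heavy-atom
    coordinates (Å) — no atomic-mass weighting.
    """

    residue_ids: set[tuple[str, int]]
    cutoff_nm: float
    mass_center: tuple[float, float, float]
    structure: StructureModel | None = field(default=None, repr=False)

    def atom_indices(self) -> list[int]:
        if self.structure is None:
            raise ValueError("pocket carries no structure reference")
        res = self.structure.residues()
        out: list[int] = []
        for key in sorted(self.residue_ids):
            out.extend(res[key])
        return out


def _iter_smiles(path: Path) -> Iterable[tuple[str, Chem.Mol | None, str]]:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
        yield name, Chem.MolFromSmiles(smiles), smiles


def read_library(path: str | Path, format: str | None = None) -> list[MoleculeRecord]:
    """Read a compound library (``smiles``, ``sdf`` or ``mol2``).

    Malformed entries are skipped with a warning; an unreadable file raises
    ``OSError`` and a file with zero parseable records raises
    :class:`EmptyLibraryError`.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"library file not found: {path}")
    if format is None:
        format = {".smi": "smiles", ".smiles": "smiles", ".sdf": "sdf",
                  ".mol2": "mol2"}.get(path.suffix.lower(), "smiles")

    records: list[MoleculeRecord] = []
    n_skipped = 0
    RDLogger.DisableLog("rdApp.error")
    try:
        if format == "smiles":
            for name, mol, smiles in _iter_smiles(path):
                if mol is None:
                    n_skipped += 1
                    logger.warning("skipping unparseable SMILES %r (%s)", smiles, name)
                    continue
                records.append(MoleculeRecord(id=name, smiles=Chem.MolToSmiles(mol),
                                              source=str(path)))
        elif format == "sdf":
            supplier = Chem.SDMolSupplier(str(path), removeHs=False)
            for i, mol in enumerate(supplier):
                if mol is None:
                    n_skipped += 1
                    logger.warning("skipping unparseable SDF entry %d", i)
                    continue
                records.append(_record_from_mol(mol, f"sdf{i}", str(path)))
        elif format == "mol2":
            # RDKit's mol2 reader handles one molecule per block
            blocks = _split_mol2(path.read_text())
            for i, block in enumerate(blocks):
                mol = Chem.MolFromMol2Block(block, removeHs=False)
                if mol is None:
                    n_skipped += 1
                    logger.warning("skipping unparseable MOL2 entry %d", i)
                    continue
                records.append(_record_from_mol(mol, f"mol2_{i}", str(path)))
        else:
            raise ValueError(f"unknown library format: {format!r}")
    finally:
        RDLogger.EnableLog("rdApp.error")

    if not records:
        raise EmptyLibraryError(f"no parseable molecules in {path}")
    if n_skipped:
        logger.warning("%d malformed entries skipped in %s", n_skipped, path)
    # de-duplicate ids
    seen: dict[str, int] = {}
    for rec in records:
        if rec.id in seen:
            seen[rec.id] += 1
            rec.id = f"{rec.id}_{seen[rec.id]}"
        else:
            seen[rec.id] = 0
    return records


def _split_mol2(text: str) -> list[str]:
    blocks: list[str] = []
    current: list[str] = []
    for line in text.splitlines(keepends=True):
        if line.startswith("@<TRIPOS>MOLECULE") and current:
            blocks.append("".join(current))
            current = []
        current.append(line)
    if current:
        blocks.append("".join(current))
    return blocks


def _record_from_mol(mol: Chem.Mol, fallback_id: str, source: str) -> MoleculeRecord:
    name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name").strip() \
        else fallback_id
    coords = None
    if mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        coords = [(a.GetSymbol(), *conf.GetAtomPosition(a.GetIdx()))
                  for a in mol.GetAtoms()]
        coords = [(el, float(x), float(y), float(z)) for el, x, y, z in coords]
    return MoleculeRecord(id=name, smiles=Chem.MolToSmiles(Chem.RemoveHs(mol)),
                          coords=coords, source=source)


def write_library(records: Sequence[MoleculeRecord], path: str | Path) -> Path:
    """Write records as tab-separated SMILES lines (smiles<TAB>id)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")
    return path


def read_pdb(path: str | Path) -> StructureModel:
    """Read a PDB file into a flat :class:`StructureModel` (first model only)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    atoms = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            resnum = residue.id[1]
            for atom in residue:
                x, y, z = atom.coord
                atoms.append((atom.element.strip().capitalize() or atom.get_name()[0],
                              atom.get_name(), residue.get_resname(), int(resnum),
                              chain.id, float(x), float(y), float(z)))
    return StructureModel(atoms=atoms)


def extract_pocket(
    structure: StructureModel,
    ligand_coords: Sequence[tuple[float, float, float]],
    cutoff_nm: float = 1.0,
) -> PocketDefinition:
    """Select residues with any heavy atom within ``cutoff_nm`` of the ligand.

    The boundary is inclusive (distance == cutoff keeps the residue) and
    hydrogens are ignored on the protein side. The pocket mass center is the
    plain mean of the selected residues' heavy-atom coordinates.
    """
    if len(ligand_coords) == 0:
        raise ValueError("ligand_coords must be non-empty")
    if cutoff_nm <= 0:
        raise ValueError("cutoff_nm must be positive")
    cutoff = cutoff_nm * NM_TO_ANGSTROM
    lig = np.asarray(ligand_coords, dtype=float)

    selected: set[tuple[str, int]] = set()
    pocket_atoms: list[np.ndarray] = []
    residues = structure.residues()
    coords = structure.coordinates()
    for key, idxs in residues.items():
        heavy = [i for i in idxs if structure.atoms[i][0] not in _HYDROGEN]
        if not heavy:
            continue
        res_xyz = coords[heavy]
        d = np.sqrt(((res_xyz[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2))
        if d.min() <= cutoff:
            selected.add(key)
            pocket_atoms.append(res_xyz)
    if not selected:
        raise EmptyPocketError(f"no residue within {cutoff_nm} nm of the ligand")
    all_xyz = np.vstack(pocket_atoms)
    center = tuple(float(v) for v in all_xyz.mean(axis=0))
    return PocketDefinition(residue_ids=selected, cutoff_nm=cutoff_nm,
                            mass_center=center, structure=structure)


_PDB_FMT = ("ATOM  {serial:5d} {name:^4s} {res:>3s} {chain:1s}{resnum:4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n")


def structure_to_pdb_block(structure: StructureModel,
                           atom_indices: Sequence[int] | None = None) -> str:
    """Render (a subset of) a structure as a PDB block."""
    idxs = range(len(structure.atoms)) if atom_indices is None else atom_indices
    lines = []
    for serial, i in enumerate(idxs, start=1):
        el, name, res, resnum, chain, x, y, z = structure.atoms[i]
        lines.append(_PDB_FMT.format(serial=serial, name=name[:4], res=res[:3],
                                     chain=(chain or "A")[:1], resnum=resnum,
                                     x=x, y=y, z=z, el=el[:2]))
    lines.append("END\n")
    return "".join(lines)


def _ensure_conformer(mol: Chem.Mol, seed: int = 2024) -> Chem.Mol:
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError("3D embedding failed")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    return mol


def write_pdbqt_inputs(structure: StructureModel, molecule: MoleculeRecord,
                       outdir: str | Path, seed: int = 2024) -> tuple[Path, Path]:
    """Write receptor and ligand files for a docking run; returns their paths.

    The receptor is written as PDB; the ligand as a minimal rigid PDBQT
    (coordinates + element types, no rotatable-bond tree), generating 3D
    coordinates with ETKDG when the record has none. Molecules that cannot be
    embedded raise per-molecule ``ValueError`` so a batch caller can skip them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    receptor_path = outdir / "receptor.pdb"
    receptor_path.write_text(structure_to_pdb_block(structure))

    if molecule.coords:
        coords = [(el, x, y, z) for el, x, y, z in molecule.coords
                  if el not in _HYDROGEN]
    else:
        mol = molecule.to_mol()
        if mol.GetNumAtoms() == 0:
            raise ValueError(f"empty molecule: {molecule.id!r}")
        mol3d = _ensure_conformer(mol, seed=seed)
        conf = mol3d.GetConformer()
        coords = [(a.GetSymbol(), *map(float, conf.GetAtomPosition(a.GetIdx())))
                  for a in mol3d.GetAtoms() if a.GetSymbol() not in _HYDROGEN]
    if not coords:
        raise ValueError(f"no heavy atoms for {molecule.id!r}")

    safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in molecule.id)
    ligand_path = outdir / f"ligand_{safe}.pdbqt"
    with ligand_path.open("w") as fh:
        fh.write("ROOT\n")
        for serial, (el, x, y, z) in enumerate(coords, start=1):
            fh.write("ATOM  {0:5d} {1:^4s} LIG A   1    {2:8.3f}{3:8.3f}{4:8.3f}"
                     "  1.00  0.00    +0.000 {5:<2s}\n".format(serial, el[:4], x, y, z, el[:2]))
        fh.write("ENDROOT\nTORSDOF 0\n")
    return receptor_path, ligand_path


def read_pose_coords(path: str | Path, model: int = 1) -> list[tuple[str, float, float, float]]:
    """Read heavy-atom (element, x, y, z) tuples from a PDB/PDBQT pose file.

    For multi-model docking output, ``model`` selects the MODEL block
    (1-based); files without MODEL records are treated as a single pose.
    """
    current = 0
    coords: list[tuple[str, float, float, float]] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("MODEL"):
            current = int(line.split()[1])
        elif line.startswith(("ATOM", "HETATM")):
            if current not in (0, model):
                continue
            el = line[76:78].strip() or line[12:16].strip()[0]
            el = el.capitalize()
            if el in _HYDROGEN:
                continue
            coords.append((el, float(line[30:38]), float(line[38:46]),
                           float(line[46:54])))
    if not coords:
        raise ValueError(f"no atoms found in {path} (model {model})")
    return coords
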