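"""Substructure-sentence embeddings of molecules and pockets.

A molecule is rendered as a "sentence" of Morgan substructure identifiers —
one token per heavy atom per radius 0..R, in atom order — the same convention
mol2vec uses to treat molecules as text. Token vectors are learned with
skip-gram + negative sampling (word2vec-style) on a sentence corpus, and a
molecule vector is the sum of its token vectors. The classifier input is the
concatenated (pocket ++ ligand) vector, z-normalized with statistics computed
from the training pairs only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .mol_io import MoleculeRecord, PocketDefinition, structure_to_pdb_block

STD_FLOOR = 1e-8  # floor on per-dimension std before division


@dataclass
class SubstructureSentence:
    """Ordered Morgan-identifier tokens: one per heavy atom per radius 0..R."""

    tokens: list[str]

    def __len__(self) -> int:
        return len(self.tokens)


def _mol_sentence(mol: Chem.Mol, radius: int) -> SubstructureSentence:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    env: dict[tuple[int, int], int] = {}
    for identifier, hits in ao.GetBitInfoMap().items():
        for atom_idx, rad in hits:
            env[(atom_idx, rad)] = identifier
    tokens = []
    for atom in mol.GetAtoms():
        for rad in range(radius + 1):
            ident = env.get((atom.GetIdx(), rad))
            if ident is not None:
                tokens.append(str(ident))
    return SubstructureSentence(tokens=tokens)


def mol_to_sentence(molecule: MoleculeRecord | str, radius: int = 1) -> SubstructureSentence:
    """Sentence of a small molecule; canonicalization makes it independent of
    the SMILES spelling."""
    smiles = molecule.smiles if isinstance(molecule, MoleculeRecord) else molecule
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))  # canonical atom order
    return _mol_sentence(mol, radius)


def pocket_to_sentence(pocket: PocketDefinition, radius: int = 1) -> SubstructureSentence:
    """Sentence of a binding pocket.

    The pocket residues are treated as disconnected components of one
    molecular graph (bonds inferred from interatomic distances); sentences are
    generated per residue and concatenated in residue order.
    """
    if not pocket.residue_ids:
        raise ValueError("empty pocket")
    structure = pocket.structure
    if structure is None:
        raise ValueError("pocket carries no structure reference")
    residues = structure.residues()
    tokens: list[str] = []
    for key in sorted(pocket.residue_ids):
        block = structure_to_pdb_block(structure, residues[key])
        mol = Chem.MolFromPDBBlock(block, sanitize=False, proximityBonding=True)
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            Chem.SanitizeMol(
                mol,
                Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION
                | Chem.SanitizeFlags.SANITIZE_SYMMRINGS,
            )
        tokens.extend(_mol_sentence(mol, radius).tokens)
    if not tokens:
        raise ValueError("pocket produced no substructure tokens")
    return SubstructureSentence(tokens=tokens)


@dataclass
class EmbeddingModel:
    """Token → vector lookup with an out-of-vocabulary fallback.

    ``unk_vector`` is the zero vector by default so unknown substructures
    contribute nothing to a molecule vector.
    """

    dim: int
    vocab: dict[str, np.ndarray]
    radius: int
    seed: int
    unk_vector: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.unk_vector is None:
            self.unk_vector = np.zeros(self.dim)

    def vector(self, token: str) -> np.ndarray:
        return self.vocab.get(token, self.unk_vector)

    def save(self, path: str | Path) -> Path:
        """Persist as a versioned key-value text file with a metadata header."""
        path = Path(path)
        with path.open("w") as fh:
            header = {"format": "deepvs-embedding", "version": 1, "dim": self.dim,
                      "radius": self.radius, "seed": self.seed}
            fh.write("#" + json.dumps(header) + "\n")
            for token in sorted(self.vocab):
                vals = " ".join(repr(float(v)) for v in self.vocab[token])
                fh.write(f"{token} {vals}\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#"):
            raise ValueError("missing embedding metadata header")
        meta = json.loads(lines[0][1:])
        if meta.get("format") != "deepvs-embedding":
            raise ValueError("not a deepvs embedding file")
        vocab = {}
        for line in lines[1:]:
            parts = line.split()
            vocab[parts[0]] = np.array([float(v) for v in parts[1:]])
        return cls(dim=meta["dim"], vocab=vocab, radius=meta["radius"],
                   seed=meta["seed"])


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embedding(
    sentences: Iterable[SubstructureSentence | Sequence[str]],
    dim: int = 100,
    window: int = 10,
    min_count: int = 1,
    seed: int = 0,
    epochs: int = 3,
    negatives: int = 5,
    learning_rate: float = 0.025,
) -> EmbeddingModel:
    """Train skip-gram-with-negative-sampling token vectors.

    Single-threaded and fully deterministic given ``seed``. Tokens below
    ``min_count`` are dropped from the vocabulary and map to the unk (zero)
    vector at embedding time.
    """
    corpus = [list(s.tokens if isinstance(s, SubstructureSentence) else s)
              for s in sentences]
    corpus = [s for s in corpus if s]
    if not corpus:
        raise ValueError("empty corpus")

    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab_tokens = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab_tokens:
        raise ValueError("no token reaches min_count")
    index = {t: i for i, t in enumerate(vocab_tokens)}
    V = len(vocab_tokens)

    rng = np.random.default_rng(seed)
    # near-unit-norm Gaussian init keeps the vocabulary matrix well
    # conditioned, so summed molecule vectors remain an approximate
    # isometry of token counts even on co-occurrence-poor corpora
    W_in = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(V, dim))
    W_out = np.zeros((V, dim))

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[t] for t in vocab_tokens], dtype=float) ** 0.75
    neg_prob = freq / freq.sum()

    encoded = [[index[t] for t in sent if t in index] for sent in corpus]
    encoded = [s for s in encoded if s]
    for _epoch in range(epochs):
        for sent in encoded:
            n = len(sent)
            for pos, center in enumerate(sent):
                w = int(rng.integers(1, window + 1))
                lo, hi = max(0, pos - w), min(n, pos + w + 1)
                context = [sent[i] for i in range(lo, hi) if i != pos]
                if not context:
                    continue
                negs = rng.choice(V, size=negatives * len(context), p=neg_prob)
                targets = np.concatenate([np.array(context), negs])
                labels = np.concatenate([np.ones(len(context)),
                                         np.zeros(len(negs))])
                v = W_in[center]
                out = W_out[targets]
                g = (_sigmoid(out @ v) - labels) * learning_rate
                grad_v = g @ out
                W_out[targets] -= np.outer(g, v)
                W_in[center] -= grad_v

    vocab = {t: W_in[i].copy() for t, i in index.items()}
    return EmbeddingModel(dim=dim, vocab=vocab, radius=-1, seed=seed)


def embed_molecule(model: EmbeddingModel,
                   sentence: SubstructureSentence | Sequence[str]) -> np.ndarray:
    """Molecule vector = sum of token vectors (unk → zero vector)."""
    tokens = sentence.tokens if isinstance(sentence, SubstructureSentence) else sentence
    vec = np.zeros(model.dim)
    for tok in tokens:
        vec += model.vector(tok)
    return vec


@dataclass
class NormalizationStats:
    """Per-dimension mean/std of training pair vectors (std floored)."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def from_training(cls, pair_matrix: np.ndarray) -> "NormalizationStats":
        X = np.asarray(pair_matrix, dtype=float)
        return cls(mean=X.mean(axis=0),
                   std=np.maximum(X.std(axis=0), STD_FLOOR))

    @classmethod
    def identity(cls, dim2: int) -> "NormalizationStats":
        return cls(mean=np.zeros(dim2), std=np.ones(dim2))


@dataclass
class PairVector:
    """Normalized concatenation of a pocket vector and a ligand vector."""

    values: np.ndarray


def make_pair_vector(pocket_vec: np.ndarray, ligand_vec: np.ndarray,
                     stats: NormalizationStats) -> PairVector:
    """(concat(pocket, ligand) − mean) / std, elementwise."""
    pocket_vec = np.asarray(pocket_vec, dtype=float)
    ligand_vec = np.asarray(ligand_vec, dtype=float)
    if pocket_vec.shape != ligand_vec.shape:
        raise ValueError("pocket and ligand vectors must have the same length")
    raw = np.concatenate([pocket_vec, ligand_vec])
    if raw.shape != stats.mean.shape:
        raise ValueError(
            f"pair vector length {raw.shape[0]} != stats length {stats.mean.shape[0]}")
    return PairVector(values=(raw - stats.mean) / stats.std)
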