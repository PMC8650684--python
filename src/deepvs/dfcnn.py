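"""Dense fully connected binding-probability classifier (first screening stage).

Takes normalized pocket++ligand pair vectors and returns a binding
probability in [0, 1]. Positive training pairs are cognate pocket–ligand
complexes; negatives are made by cross-combination — pairing each pocket with
ligands drawn from *other* complexes, excluding any ligand identical (by
canonical SMILES or ligand id) to the pocket's own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .embed import NormalizationStats, make_pair_vector

DEFAULT_HIDDEN = (512, 256, 128, 64)


@dataclass
class ComplexEntry:
    """One cognate pocket–ligand complex (a positive example)."""

    complex_id: str
    pocket_vector: np.ndarray
    ligand_vector: np.ndarray
    ligand_key: str  # canonical SMILES, or any identity key for the ligand


@dataclass
class TrainingPairSet:
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]
    seed: int
    vectors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict,
                                                              repr=False)

    def design_matrix(self, stats: NormalizationStats | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Stack positive then negative raw pair vectors; y = 1 then 0."""
        rows, ys = [], []
        for (pid, lid), y in [(p, 1.0) for p in self.positives] + \
                             [(p, 0.0) for p in self.negatives]:
            pv, _ = self.vectors[pid]
            _, lv = self.vectors[lid]
            rows.append(np.concatenate([pv, lv]))
            ys.append(y)
        X = np.vstack(rows)
        if stats is not None:
            X = (X - stats.mean) / stats.std
        return X, np.array(ys)


def build_cross_combination_negatives(
    complexes: Sequence[ComplexEntry],
    ratio: int = 1,
    seed: int = 0,
) -> TrainingPairSet:
    """Sample non-cognate (pocket_i, ligand_j) pairs uniformly without replacement.

    A pair is admissible when i != j and ligand_j is not identical to
    pocket_i's own ligand (canonical-SMILES key), so a repeated ligand never
    produces a mislabeled negative. Draws ``ratio`` negatives per positive, or
    every admissible pair if fewer exist.
    """
    if len(complexes) < 2:
        raise ValueError("need at least 2 complexes to cross-combine")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    admissible = [
        (ci.complex_id, cj.complex_id)
        for ci in complexes for cj in complexes
        if ci.complex_id != cj.complex_id and ci.ligand_key != cj.ligand_key
    ]
    if not admissible:
        raise ValueError("no admissible cross pairs (all ligands identical)")
    n_want = min(ratio * len(complexes), len(admissible))
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(admissible), size=n_want, replace=False)
    negatives = [admissible[i] for i in sorted(picked)]
    positives = [(c.complex_id, c.complex_id) for c in complexes]
    vectors = {c.complex_id: (np.asarray(c.pocket_vector, dtype=float),
                              np.asarray(c.ligand_vector, dtype=float))
               for c in complexes}
    return TrainingPairSet(positives=positives, negatives=negatives, seed=seed,
                           vectors=vectors)


@dataclass
class DFCNNModel:
    """Trained dense classifier plus the normalization attached at fit time."""

    network: nn.Network
    stats: NormalizationStats
    hidden: tuple[int, ...]
    seed: int

    @property
    def n_inputs(self) -> int:
        return self.network.layers[0].W.shape[0]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.network.state_arrays())}
        np.savez(path, __format__=np.array("deepvs-dfcnn-v1"),
                 hidden=np.array(self.hidden), seed=np.array(self.seed),
                 mean=self.stats.mean, std=self.stats.std, **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "DFCNNModel":
        data = np.load(path, allow_pickle=False)
        if str(data["__format__"]) != "deepvs-dfcnn-v1":
            raise ValueError("not a deepvs DFCNN model file")
        hidden = tuple(int(h) for h in data["hidden"])
        stats = NormalizationStats(mean=data["mean"], std=data["std"])
        seed = int(data["seed"])
        net = nn.mlp(len(stats.mean), hidden, seed=seed)
        n_arrays = len(net.state_arrays())
        net.load_state_arrays([data[f"p{i}"] for i in range(n_arrays)])
        return cls(network=net, stats=stats, hidden=hidden, seed=seed)


def fit_pair_classifier(
    X_raw: np.ndarray,
    y: np.ndarray,
    hidden: Sequence[int] = DEFAULT_HIDDEN,
    epochs: int = 40,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
) -> DFCNNModel:
    """Fit the dense classifier on raw (unnormalized) pair vectors.

    Normalization statistics are computed from the training pairs only and
    attached to the model, so test-time inputs are scaled with training
    mean/std. Training is single-threaded and deterministic given the seed.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if (y == 1).sum() < 10 or (y == 0).sum() < 10:
        raise ValueError("need at least 10 positives and 10 negatives")
    stats = NormalizationStats.from_training(X_raw)
    X = (X_raw - stats.mean) / stats.std
    net = nn.mlp(X.shape[1], tuple(hidden), seed=seed)
    net.fit(X, y, epochs=epochs, batch_size=batch_size,
            learning_rate=learning_rate, seed=seed)
    return DFCNNModel(network=net, stats=stats, hidden=tuple(hidden), seed=seed)


def train_dfcnn(
    pairs: TrainingPairSet,
    hidden: Sequence[int] = DEFAULT_HIDDEN,
    epochs: int = 40,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
) -> DFCNNModel:
    """Fit the dense classifier on a cross-combination pair set."""
    X_raw, y = pairs.design_matrix(stats=None)
    return fit_pair_classifier(X_raw, y, hidden=hidden, epochs=epochs,
                               learning_rate=learning_rate,
                               batch_size=batch_size, seed=seed)


def predict_binding_probability(model: DFCNNModel, pair) -> float:
    """Score one normalized pair vector; deterministic, in [0, 1]."""
    values = pair.values if hasattr(pair, "values") else np.asarray(pair, dtype=float)
    values = np.asarray(values, dtype=float).reshape(-1)
    if values.shape[0] != model.n_inputs:
        raise ValueError(f"pair vector length {values.shape[0]} != "
                         f"model input {model.n_inputs}")
    return float(model.network.predict_proba(values[None, :])[0])


def predict_batch(model: DFCNNModel, pair_matrix: np.ndarray) -> np.ndarray:
    X = np.asarray(pair_matrix, dtype=float)
    if X.shape[1] != model.n_inputs:
        raise ValueError("pair vector length mismatch")
    return model.network.predict_proba(X)


def score_raw_pairs(model: DFCNNModel, pocket_vec: np.ndarray,
                    ligand_vecs: Sequence[np.ndarray]) -> np.ndarray:
    """Convenience: normalize raw (pocket, ligand) pairs with the model's own
    stats and score them."""
    rows = [make_pair_vector(pocket_vec, lv, model.stats).values
            for lv in ligand_vecs]
    return predict_batch(model, np.vstack(rows))
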