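"""Threshold cascade over score tables, ranking, and chemotype clustering.

A screening run leaves every compound with three scores: the pair-vector
classifier probability (``dfcnn``), the interface classifier probability
(``deepbindbc``), both in [0, 1], and a docking score in kcal/mol where more
negative is better. Candidate selection keeps a compound iff

    deepbindbc > min_deepbindbc  AND  docking <= max_docking  AND
    dfcnn > min_dfcnn

with strict ``>`` on the two model probabilities and inclusive ``<=`` on the
docking score — exactly the operator pattern the selection criteria are
quoted with, so boundary docking values are kept. Three named presets ship:
``list1`` (0.99, -10, 0.99), ``list2`` (0.99, -8.5, 0.998) and ``tcm``
(0.9, -6, 0.9).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator, DataStructs
from rdkit.ML.Cluster import Butina

from .mol_io import MoleculeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreRecord:
    """One compound's three stage scores."""

    name: str
    deepbindbc: float
    docking: float
    dfcnn: float


@dataclass(frozen=True)
class CascadeCriteria:
    min_deepbindbc: float  # strict >
    max_docking: float     # inclusive <=
    min_dfcnn: float       # strict >
    exclude: frozenset[str] = frozenset()

    def keeps(self, rec: ScoreRecord) -> bool:
        return (rec.deepbindbc > self.min_deepbindbc
                and rec.docking <= self.max_docking
                and rec.dfcnn > self.min_dfcnn
                and rec.name not in self.exclude)


#: the three published selection presets
PRESETS: dict[str, CascadeCriteria] = {
    "list1": CascadeCriteria(0.99, -10.0, 0.99),
    "list2": CascadeCriteria(0.99, -8.5, 0.998),
    "tcm": CascadeCriteria(0.9, -6.0, 0.9),
}


@dataclass
class CandidateList:
    records: list[ScoreRecord]
    criteria: CascadeCriteria
    sort_key: str | None = None

    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def apply_criteria(records: Sequence[ScoreRecord],
                   criteria: CascadeCriteria) -> CandidateList:
    """Filter a score table; comparisons are on the values as given, no
    rounding. An empty result is allowed."""
    if not records:
        raise ValueError("empty score table")
    kept = [r for r in records if criteria.keeps(r)]
    return CandidateList(records=kept, criteria=criteria)


_SORT_KEYS = {
    "deepbindbc": (lambda r: -r.deepbindbc),
    "docking": (lambda r: r.docking),
    "dfcnn": (lambda r: -r.dfcnn),
}


def rank_candidates(candidates: CandidateList, key: str = "deepbindbc") -> CandidateList:
    """Stable sort: deepbindbc/dfcnn descending, docking ascending; ties keep
    input order."""
    if key not in _SORT_KEYS:
        raise ValueError(f"unknown sort key {key!r}; one of {sorted(_SORT_KEYS)}")
    ordered = sorted(candidates.records, key=_SORT_KEYS[key])
    return CandidateList(records=ordered, criteria=candidates.criteria, sort_key=key)


@dataclass
class ClusterAssignment:
    """Partition of candidates into chemotype groups."""

    assignment: dict[str, int]
    similarity_threshold: float
    representatives: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster_id: int) -> list[str]:
        return [n for n, c in self.assignment.items() if c == cluster_id]


def cluster_candidates(
    molecules: Sequence[MoleculeRecord],
    similarity_threshold: float = 0.6,
    scores: dict[str, float] | None = None,
    n_bits: int = 2048,
    radius: int = 2,
) -> ClusterAssignment:
    """Butina (leader-style) clustering on hashed circular fingerprints.

    Two molecules join a cluster when their Tanimoto similarity exceeds
    ``similarity_threshold``. Deterministic given input order. When per-name
    ``scores`` are supplied the representative of each cluster is its
    highest-scoring member; otherwise the cluster centroid molecule.
    Unparseable molecules are excluded with a warning.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps, names = [], []
    for rec in molecules:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning("excluding unparseable molecule %r", rec.id)
            continue
        fps.append(gen.GetFingerprint(mol))
        names.append(rec.id)
    if not fps:
        raise ValueError("no parseable molecules to cluster")

    # condensed lower-triangle distance list, Butina's expected layout
    dists = []
    for i in range(1, len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        dists.extend(1.0 - s for s in sims)
    clusters = Butina.ClusterData(dists, len(fps), 1.0 - similarity_threshold,
                                  isDistData=True)

    assignment: dict[str, int] = {}
    representatives: dict[int, str] = {}
    for cid, members in enumerate(clusters):
        for idx in members:
            assignment[names[idx]] = cid
        member_names = [names[i] for i in members]
        if scores:
            representatives[cid] = max(member_names,
                                       key=lambda n: scores.get(n, float("-inf")))
        else:
            representatives[cid] = names[members[0]]  # Butina centroid
    return ClusterAssignment(assignment=assignment,
                             similarity_threshold=similarity_threshold,
                             representatives=representatives)


# -- score-table I/O ---------------------------------------------------------

def read_score_table(path: str | Path) -> list[ScoreRecord]:
    """Read a delimited table with header name,deepbindbc,docking,dfcnn."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"name", "deepbindbc", "docking", "dfcnn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate compound names: {dupes}")
    return [ScoreRecord(str(r.name), float(r.deepbindbc), float(r.docking),
                        float(r.dfcnn))
            for r in df.itertuples(index=False)]


def write_score_table(records: Sequence[ScoreRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)
    return path


def summarize_clusters(assignment: ClusterAssignment) -> str:
    lines = [f"{assignment.n_clusters} clusters at Tanimoto threshold "
             f"{assignment.similarity_threshold}"]
    for cid in sorted(set(assignment.assignment.values())):
        members = assignment.members(cid)
        rep = assignment.representatives.get(cid, "")
        lines.append(f"  cluster {cid}: {len(members)} compounds "
                     f"(representative: {rep})")
    return "\n".join(lines)
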