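from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deepvs.dock import MockDockingEngine
from deepvs.interface import (ELEMENT_ALPHABET, InterfaceClassifier, N_CHANNELS,
                              PoseLabel, _element_slot,
                              build_cross_docking_decoys, featurize_interface,
                              predict_pose_score, train_interface_classifier)
from deepvs.mol_io import StructureModel
from deepvs.synthdata import generate_toy_complexes


def brute_force_rows(structure, pose, cutoff):
    rows = []
    for pi, atom in enumerate(structure.atoms):
        if atom[0] in ("H", "D"):
            continue
        for li, (el, x, y, z) in enumerate(pose):
            if el.capitalize() in ("H", "D"):
                continue
            d = float(np.linalg.norm(np.array(atom[5:8]) - np.array([x, y, z])))
            if d <= cutoff:
                rows.append((d, pi, li, atom[0], el))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    return rows


class TestFeaturize:
    def test_empty_interface_all_pad(self, toy_structure):
        m = featurize_interface(toy_structure, [("C", 500.0, 0.0, 0.0)],
                                cutoff=10.0, max_rows=8)
        assert m.n_contacts == 0
        np.testing.assert_array_equal(m.matrix, np.zeros((8, N_CHANNELS)))

    def test_single_carbon_pair(self):
        s = StructureModel(atoms=[("C", "CA", "ALA", 1, "A", 0.0, 0.0, 0.0)])
        m = featurize_interface(s, [("C", 3.0, 0.0, 0.0)], cutoff=10.0,
                                max_rows=4)
        assert m.n_contacts == 1
        row = m.matrix[0]
        c = ELEMENT_ALPHABET.index("C")
        assert row[c] == 1.0 and row[len(ELEMENT_ALPHABET) + c] == 1.0
        assert row[-1] == pytest.approx(3.0 / 10.0)  # scaled distance
        np.testing.assert_array_equal(m.matrix[1:], 0.0)

    def test_five_contact_toy_matches_sorted_pairs(self):
        s = StructureModel(atoms=[
            ("C", "C1", "RES", 1, "A", 0.0, 0.0, 0.0),
            ("N", "N1", "RES", 1, "A", 0.0, 4.0, 0.0),
        ])
        pose = [("O", 1.0, 0.0, 0.0), ("C", 0.0, 2.0, 0.0), ("S", 9.0, 0.0, 0.0)]
        m = featurize_interface(s, pose, cutoff=10.0, max_rows=10)
        expected = brute_force_rows(s, pose, 10.0)
        assert m.n_contacts == len(expected)
        np.testing.assert_allclose(m.matrix[:len(expected), -1],
                                   [d / 10.0 for d, *_ in expected])

    @given(seed=st.integers(0, 400))
    @settings(max_examples=40, deadline=None)
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_prot, n_lig = int(rng.integers(2, 40)), int(rng.integers(1, 12))
        elements = ["C", "N", "O", "S", "Cl", "Fe", "H"]
        atoms = [(elements[int(rng.integers(len(elements)))], "X", "RES",
                  i + 1, "A", *map(float, rng.uniform(-10, 10, 3)))
                 for i in range(n_prot)]
        s = StructureModel(atoms=atoms)
        pose = [(elements[int(rng.integers(len(elements)))],
                 *map(float, rng.uniform(-10, 10, 3))) for _ in range(n_lig)]
        max_rows = 16
        m = featurize_interface(s, pose, cutoff=8.0, max_rows=max_rows)
        expected = brute_force_rows(s, pose, 8.0)
        assert m.n_contacts == len(expected)
        k = min(max_rows, len(expected))
        np.testing.assert_allclose(m.matrix[:k, -1],
                                   [d / 8.0 for d, *_ in expected[:k]],
                                   atol=1e-12)
        for r, (_, _, _, pel, lel) in enumerate(expected[:k]):
            assert m.matrix[r, _element_slot(pel)] == 1.0
            assert m.matrix[r, len(ELEMENT_ALPHABET) + _element_slot(lel)] == 1.0

    def test_atom_order_invariance(self, rng):
        atoms = [("C", "X", "R", i + 1, "A", *map(float, rng.uniform(-5, 5, 3)))
                 for i in range(10)]
        pose = [("N", *map(float, rng.uniform(-5, 5, 3))) for _ in range(5)]
        m1 = featurize_interface(StructureModel(atoms=atoms), pose)
        m2 = featurize_interface(StructureModel(atoms=atoms[::-1]), pose[::-1])
        # distances identical after sorting (indices differ, channels match)
        np.testing.assert_allclose(np.sort(m1.matrix[:, -1]),
                                   np.sort(m2.matrix[:, -1]), atol=1e-12)

    def test_truncation_keeps_smallest_distances(self):
        s = StructureModel(atoms=[("C", "X", "R", 1, "A", 0.0, 0.0, 0.0)])
        pose = [("C", float(d), 0.0, 0.0) for d in range(1, 8)]
        m = featurize_interface(s, pose, cutoff=10.0, max_rows=3)
        np.testing.assert_allclose(m.matrix[:, -1], [0.1, 0.2, 0.3])

    def test_halogens_share_slot(self):
        assert _element_slot("Cl") == _element_slot("Br") == \
            ELEMENT_ALPHABET.index("X")
        assert _element_slot("Fe") == ELEMENT_ALPHABET.index("other")


class TestCrossDockingDecoys:
    def test_counts_and_no_cognates(self):
        complexes = generate_toy_complexes(n=3, seed=0)
        decoys = build_cross_docking_decoys(complexes, MockDockingEngine(0),
                                            n_per_complex=2, seed=0)
        assert len(decoys) == 6
        for receptor, pose, label in decoys:
            assert label.origin == "cross_docked"
            assert label.label == "decoy"
            assert pose != receptor.ligand_coords

    def test_single_complex_rejected(self):
        with pytest.raises(ValueError):
            build_cross_docking_decoys(generate_toy_complexes(n=1, seed=0),
                                       MockDockingEngine(0))

    def test_deterministic(self):
        complexes = generate_toy_complexes(n=4, seed=1)
        a = build_cross_docking_decoys(complexes, MockDockingEngine(2), seed=5)
        b = build_cross_docking_decoys(complexes, MockDockingEngine(2), seed=5)
        assert [(r.complex_id, p) for r, p, _ in a] == \
            [(r.complex_id, p) for r, p, _ in b]

    def test_engine_failure_skips_pair(self):
        class FlakyEngine:
            def __init__(self):
                self.calls = 0

            def dock(self, receptor, ligand, config):
                self.calls += 1
                if self.calls == 1:
                    raise RuntimeError("engine crashed")
                return MockDockingEngine(0).dock(receptor, ligand, config)

        complexes = generate_toy_complexes(n=3, seed=2)
        decoys = build_cross_docking_decoys(complexes, FlakyEngine(),
                                            n_per_complex=2, seed=0)
        assert len(decoys) == 5  # one pair lost, pipeline continued

    def test_cross_docked_label_must_be_decoy(self):
        with pytest.raises(ValueError):
            PoseLabel(label="native", origin="cross_docked")


class TestClassifier:
    def _tiny_maps(self, rng, n=30):
        maps, labels = [], []
        s = StructureModel(atoms=[("C", "X", "R", 1, "A", 0.0, 0.0, 0.0)])
        for i in range(n):
            near = bool(rng.random() < 0.5)
            base = 2.0 if near else 8.0
            pose = [("C", float(base + rng.uniform(-0.5, 0.5)), 0.0, 0.0)
                    for _ in range(4)]
            maps.append(featurize_interface(s, pose, cutoff=10.0, max_rows=8))
            labels.append("native" if near else "decoy")
        return maps, labels

    def test_learns_distance_signal(self, rng):
        maps, labels = self._tiny_maps(rng, n=60)
        clf = train_interface_classifier(maps, labels, channels=4, n_blocks=1,
                                         epochs=150, batch_size=8, seed=0)
        scores = np.array([predict_pose_score(clf, m) for m in maps])
        y = np.array([1 if l == "native" else 0 for l in labels])
        assert scores[y == 1].mean() > scores[y == 0].mean() + 0.2

    def test_single_class_rejected(self, rng):
        maps, _ = self._tiny_maps(rng, n=10)
        with pytest.raises(ValueError):
            train_interface_classifier(maps, ["decoy"] * 10)

    def test_all_pad_map_scores_without_crash(self, rng, toy_structure):
        maps, labels = self._tiny_maps(rng, n=20)
        clf = train_interface_classifier(maps, labels, channels=4, n_blocks=1,
                                         epochs=2, seed=0)
        empty = featurize_interface(toy_structure, [("C", 500.0, 0.0, 0.0)],
                                    max_rows=8)
        assert 0.0 <= predict_pose_score(clf, empty) <= 1.0

    def test_save_load_roundtrip(self, rng, tmp_path):
        maps, labels = self._tiny_maps(rng, n=20)
        clf = train_interface_classifier(maps, labels, channels=4, n_blocks=1,
                                         epochs=2, seed=0)
        path = tmp_path / "iface.npz"
        clf.save(path)
        back = InterfaceClassifier.load(path)
        for m in maps[:3]:
            assert predict_pose_score(back, m) == pytest.approx(
                predict_pose_score(clf, m), abs=1e-12)
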