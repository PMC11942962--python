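"""Tests for the synthetic-protein generator and planted labels."""

import numpy as np
import pytest

from structok.core import AMINO_ACIDS, ProteinStructure
from structok.geometry import virtual_ca_dihedrals
from structok.synthetic import (
    HELIX_RADIUS,
    HELIX_RISE,
    HELIX_TURN_DEG,
    SyntheticConfig,
    generate_backbone,
    generate_dataset,
    generate_sequence,
    plant_labels,
    structure_task_config,
)


class TestBackbone:
    def test_minimum_length(self, rng):
        bb = generate_backbone(2, 0.5, 0.0, rng)
        assert bb.shape == (2, 3, 3)
        assert np.isfinite(bb).all()

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_backbone(1, 0.5, 0.0, rng)

    def test_seed_determinism_bitwise(self):
        a = generate_backbone(40, 0.5, 0.3, np.random.default_rng(9))
        b = generate_backbone(40, 0.5, 0.3, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_pure_helix_step_distance_matches_parameterization(self, rng):
        """With helix_fraction=1 and no jitter, every consecutive C-alpha
        step equals the rise-step distance of the parametric helix, computed
        here independently from the helix parameters."""
        bb = generate_backbone(100, 1.0, 0.0, rng)
        steps = np.linalg.norm(np.diff(bb[:, 1, :], axis=0), axis=1)
        w = np.deg2rad(HELIX_TURN_DEG)
        expected = np.sqrt(2 * HELIX_RADIUS**2 * (1 - np.cos(w)) + HELIX_RISE**2)
        np.testing.assert_allclose(steps, expected, atol=1e-9)

    def test_consecutive_ca_distances_in_band(self, rng):
        for frac in (0.0, 0.5, 1.0):
            bb = generate_backbone(60, frac, 0.0, rng)
            steps = np.linalg.norm(np.diff(bb[:, 1, :], axis=0), axis=1)
            assert steps.min() >= 1.4 and steps.max() <= 4.2

    def test_helix_virtual_dihedral_is_right_handed(self, rng):
        bb = generate_backbone(50, 1.0, 0.0, rng)
        d = virtual_ca_dihedrals(bb[:, 1, :])
        d = d[np.isfinite(d)]
        assert (d > 0.5).all() and (d < 1.25).all()


class TestSequence:
    def test_zero_length_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_sequence(0, rng)

    def test_determinism(self):
        a = generate_sequence(50, np.random.default_rng(4))
        b = generate_sequence(50, np.random.default_rng(4))
        assert a == b

    def test_uniform_letter_frequencies(self):
        """Each letter's count stays within 3 binomial sd of n/20."""
        n = 10_000
        seq = generate_sequence(n, np.random.default_rng(11))
        p = 1 / 20
        sd = np.sqrt(n * p * (1 - p))
        for letter in AMINO_ACIDS:
            assert abs(seq.count(letter) - n * p) < 3 * sd


class TestPlantLabels:
    def _protein(self, seq, rng=None):
        rng = rng or np.random.default_rng(0)
        bb = generate_backbone(len(seq), 0.5, 0.0, rng)
        return ProteinStructure(id=f"p{hash(seq) % 10_000}", sequence=seq, backbone=bb)

    def test_motif_substring_fires(self, rng):
        cfg = SyntheticConfig(
            motif_labels=[("m", "WWW", 0.5)], structure_labels=[], label_flip_rate=0.0
        )
        table = plant_labels([self._protein("AWWWA" + "G" * 10)], cfg, rng)
        assert table.truth[0, 0] == 1

    def test_motif_absent_is_zero(self, rng):
        cfg = SyntheticConfig(
            motif_labels=[("m", "WWW", 0.5)], structure_labels=[], label_flip_rate=0.0
        )
        table = plant_labels([self._protein("ACDEFGHIKLMNPQ")], cfg, rng)
        assert table.truth[0, 0] == 0

    def test_unknown_geometry_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown geometry rule"):
            SyntheticConfig(structure_labels=[("x", "torsion_entropy", 0.5)])

    def test_contact_density_matches_brute_force(self):
        """The planted contact-density label equals an O(L^2) all-pairs
        neighbor count coded here from scratch."""
        cfg = SyntheticConfig(
            n_proteins=50,
            motif_labels=[],
            structure_labels=[("c", "contact_density", 6.8)],
            label_flip_rate=0.0,
            seed=21,
        )
        proteins, table = generate_dataset(cfg)
        for prot, got in zip(proteins, table.truth[:, 0]):
            ca = prot.ca
            L = len(prot)
            counts = []
            for i in range(L):
                c = 0
                for j in range(L):
                    if i != j and np.sqrt(((ca[i] - ca[j]) ** 2).sum()) <= 8.0:
                        c += 1
                counts.append(c)
            assert got == int(np.mean(counts) > 6.8)

    def test_empty_protein_list_rejected(self, rng):
        with pytest.raises(ValueError):
            plant_labels([], SyntheticConfig(), rng)


class TestDataset:
    def test_split_ratio_8_1_1(self):
        _, table = generate_dataset(SyntheticConfig(n_proteins=10, seed=1))
        counts = {s: table.split.count(s) for s in ("train", "valid", "test")}
        assert counts == {"train": 8, "valid": 1, "test": 1}

    def test_full_determinism(self):
        cfg = SyntheticConfig(n_proteins=8, seed=5)
        p1, t1 = generate_dataset(cfg)
        p2, t2 = generate_dataset(cfg)
        np.testing.assert_array_equal(t1.truth, t2.truth)
        assert t1.split == t2.split
        for a, b in zip(p1, p2):
            assert a.sequence == b.sequence
            np.testing.assert_array_equal(a.backbone, b.backbone)

    def test_prefix_stability_when_growing_dataset(self):
        """Adding proteins must not perturb earlier ones (per-protein
        substreams)."""
        small, _ = generate_dataset(SyntheticConfig(n_proteins=5, seed=5))
        large, _ = generate_dataset(SyntheticConfig(n_proteins=9, seed=5))
        for a, b in zip(small, large[:5]):
            assert a.sequence == b.sequence
            np.testing.assert_array_equal(a.backbone, b.backbone)

    def test_motif_prevalence_near_target(self):
        cfg = SyntheticConfig(
            n_proteins=300,
            motif_labels=[("m", "WCW", 0.3)],
            structure_labels=[],
            label_flip_rate=0.0,
            seed=13,
        )
        _, table = generate_dataset(cfg)
        assert abs(table.truth[:, 0].mean() - 0.3) < 0.08

    def test_length_range_minimum_enforced(self):
        with pytest.raises(ValueError):
            SyntheticConfig(length_range=(8, 20))

    def test_sequence_carries_no_information_about_structure_labels(self):
        """A logistic probe on amino-acid unigram counts scores AUROC ~ 0.5
        on held-out structure-dependent labels."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        proteins, table = generate_dataset(structure_task_config(seed=29, label_flip_rate=0.0))
        X = np.array(
            [[p.sequence.count(a) / len(p) for a in AMINO_ACIDS] for p in proteins]
        )
        y = table.truth[:, 1]  # median helix-content term (balanced)
        half = len(proteins) // 2
        probe = LogisticRegression(max_iter=1000).fit(X[:half], y[:half])
        auroc = roc_auc_score(y[half:], probe.predict_proba(X[half:])[:, 1])
        assert abs(auroc - 0.5) <= 0.1
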