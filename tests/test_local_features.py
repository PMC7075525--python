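"""Secondary structure, accessibility, agreement terms, clash, N and
spherical smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protqa.geometry import rotation_matrix
from protqa.local_features import (SSAgreementTable, acc_agreement,
                                   assign_secondary_structure, clash_score,
                                   read_accpro, read_psipred_ss2,
                                   relative_accessibility, residue_count,
                                   solvent_accessibility, spherical_smooth,
                                   ss_agreement)
from protqa.structure import Residue, Structure
from protqa.synth import (SyntheticScenario, make_native,
                          make_predictor_files)

from conftest import random_structure


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_h(self, helix_native):
        states = assign_secondary_structure(helix_native)
        interior = states[4:-4]
        assert set(interior) == {"H"}

    def test_single_residue_is_coil(self):
        s = make_native(SyntheticScenario(seed=4, length=10))
        lone = Structure("x", [s.residues[0]])
        assert assign_secondary_structure(lone) == ["C"]

    def test_extended_strand_has_positive_accessibility(self):
        s = make_native(SyntheticScenario(seed=5, length=10,
                                          layout="E" * 10))
        asa = solvent_accessibility(s)
        assert (asa > 0).all()


class TestSSAgreement:
    def test_independent_joint_gives_zero_scores(self):
        # counts built as an exact product of marginals: log-odds vanish
        table = SSAgreementTable(pseudo_count=0.0)
        obs = []
        for d in "HEC":
            for p in "HEC":
                for _ in range(4):
                    obs.append((d, p, 5))
        table.fit(obs)
        sub = table.table_[[1, 3, 7]][:, :, 5]  # H, E, C rows at conf 5
        assert np.allclose(sub, 0.0, atol=1e-12)

    def test_enrichment_recovered_as_log_ratio(self):
        # H<->H at confidence 9 enriched 4x over independence
        obs = []
        obs += [("H", "H", 9)] * 160
        obs += [("H", "E", 9)] * 40
        obs += [("C", "H", 9)] * 40
        obs += [("C", "E", 9)] * 160
        table = SSAgreementTable(pseudo_count=1e-9).fit(obs)
        # p(H,H,9)=0.4, p(H)=0.5, p(H-pred,9)=0.5 -> log(1.6)
        assert table.score("H", "H", 9) == pytest.approx(np.log(1.6),
                                                         abs=1e-3)

    def test_unseen_cell_is_finite(self):
        table = SSAgreementTable(pseudo_count=1.0).fit([("H", "H", 9)])
        assert np.isfinite(table.table_).all()


class TestAccAgreement:
    def test_buried_match(self):
        assert acc_agreement(np.array([0.0]), "A", ["b"])[0] == 1.0

    def test_exposed_mismatch(self):
        asa = np.array([0.9 * 129.0])
        assert acc_agreement(asa, "A", ["b"])[0] == 0.0

    def test_boundary_quarter_is_exposed(self):
        asa = np.array([0.25 * 129.0])
        assert acc_agreement(asa, "A", ["e"])[0] == 1.0

    def test_unknown_residue_invalid(self):
        assert np.isnan(acc_agreement(np.array([10.0]), "X", ["b"])[0])


def _two_atoms(distance, name="C"):
    return Structure("toy", [
        Residue(0, 1, "", "A", {name: np.array([0.0, 0.0, 0.0])}),
        Residue(1, 2, "", "G", {}),
        Residue(2, 3, "", "A", {name: np.array([distance, 0.0, 0.0])}),
    ])


class TestClashScore:
    def test_zero_beyond_contact_distance(self, rng):
        s = random_structure(rng, length=20)
        assert np.allclose(clash_score(s), 0.0)

    def test_full_penalty_at_hard_core(self):
        s = _two_atoms(0.8254 * 3.2)
        scores = clash_score(s)
        assert scores[0] == pytest.approx(-10.0)
        assert scores[2] == pytest.approx(-10.0)

    def test_linear_midpoint_half_penalty(self):
        d = (3.2 + 0.8254 * 3.2) / 2.0
        scores = clash_score(_two_atoms(d))
        assert scores[0] == pytest.approx(-5.0)

    def test_adjacent_residues_excluded(self):
        s = Structure("toy", [
            Residue(0, 1, "", "A", {"C": np.array([0.0, 0.0, 0.0])}),
            Residue(1, 2, "", "A", {"N": np.array([1.33, 0.0, 0.0])}),
        ])
        assert np.allclose(clash_score(s), 0.0)


class TestResidueCount:
    def test_pair_within_radius(self):
        s = Structure("toy", [
            Residue(0, 1, "", "A", {"CA": np.zeros(3)}),
            Residue(1, 2, "", "A", {"CA": np.array([5.0, 0, 0])}),
        ])
        assert residue_count(s).tolist() == [1.0, 1.0]

    def test_pair_beyond_radius(self):
        s = Structure("toy", [
            Residue(0, 1, "", "A", {"CA": np.zeros(3)}),
            Residue(1, 2, "", "A", {"CA": np.array([20.0, 0, 0])}),
        ])
        assert residue_count(s).tolist() == [0.0, 0.0]

    def test_matches_brute_force(self, rng):
        s = random_structure(rng, length=30)
        counts = residue_count(s)
        ca = s.ca_array()
        for i in range(len(s)):
            expected = sum(
                1 for j in range(len(s))
                if j != i and np.linalg.norm(ca[i] - ca[j]) < 15.0)
            assert counts[i] == expected


class TestSphericalSmooth:
    def test_constant_field_preserved(self, rng):
        s = random_structure(rng, length=15)
        out = spherical_smooth(np.full(15, 0.7), s)
        assert np.allclose(out, 0.7)

    def test_isolated_residue_unchanged(self):
        s = Structure("toy", [Residue(0, 1, "", "A", {"CA": np.zeros(3)})])
        assert spherical_smooth([0.3], s)[0] == pytest.approx(0.3)

    def test_two_residue_closed_form(self):
        s = Structure("toy", [
            Residue(0, 1, "", "A", {"CA": np.zeros(3)}),
            Residue(1, 2, "", "A", {"CA": np.array([5.0, 0, 0])}),
        ])
        out = spherical_smooth([0.0, 1.0], s, sigma=5.0)
        w = np.exp(-0.5)
        assert out[0] == pytest.approx(w / (1 + w), abs=1e-12)
        assert out[1] == pytest.approx(1 / (1 + w), abs=1e-12)

    def test_sigma_to_zero_approaches_identity(self, rng):
        s = random_structure(rng, length=10)
        v = rng.uniform(0, 1, 10)
        out = spherical_smooth(v, s, sigma=1e-4)
        assert np.allclose(out, v, atol=1e-9)

    def test_invalid_entries_excluded_from_sums(self, rng):
        s = random_structure(rng, length=8)
        v = np.array([0.5, np.nan, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        out = spherical_smooth(v, s)
        assert np.allclose(out, 0.5)  # NaN neighbour must not poison

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=12,
                    max_size=12))
    def test_range_preservation(self, values):
        s = make_native(SyntheticScenario(seed=21, length=12))
        out = spherical_smooth(np.array(values), s)
        assert out.min() >= min(values) - 1e-9
        assert out.max() <= max(values) + 1e-9

    def test_rigid_motion_invariance(self, rng):
        s = random_structure(rng, length=12)
        moved = s.transformed(rotation_matrix([1, 0, 1], 54.0),
                              np.array([1.0, 2.0, 3.0]))
        v = rng.uniform(0, 1, 12)
        assert np.allclose(spherical_smooth(v, s),
                           spherical_smooth(v, moved), atol=1e-9)


class TestPredictorReaders:
    def test_roundtrip_through_generator(self, tmp_path):
        native = make_native(SyntheticScenario(seed=31, length=20))
        ss2 = tmp_path / "t.ss2"
        acc = tmp_path / "t.acc"
        make_predictor_files(native, 0.0, seed=3, ss2_path=ss2,
                             acc_path=acc)
        psipred = read_psipred_ss2(ss2)
        accpro = read_accpro(acc)
        assert len(psipred) == 20
        assert len(accpro) == 20
        assert all(s in "HEC" and 0 <= c <= 9 for s, c in psipred)
        assert set(accpro) <= {"b", "e"}

    def test_zero_error_rate_matches_native_burial(self, tmp_path):
        native = make_native(SyntheticScenario(seed=32, length=20))
        acc = tmp_path / "t.acc"
        make_predictor_files(native, 0.0, seed=3,
                             ss2_path=tmp_path / "t.ss2", acc_path=acc)
        from protqa.structure import extract_sequence
        seq = extract_sequence(native)
        agreement = acc_agreement(solvent_accessibility(native), seq,
                                  read_accpro(acc))
        valid = ~np.isnan(agreement)
        assert agreement[valid].min() == 1.0
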