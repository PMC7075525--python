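"""Distance-constraint scoring: alignment mapping, clustering, the
Gaussian constraint equations and reliability features."""

import copy

import numpy as np
import pytest

from protqa.disco import (AlignedTemplate, ConstraintEnsemble,
                          build_ensemble, cluster_templates,
                          ensemble_from_files, evaluate_pair, load_alignments,
                          parse_a3m, score_model, template_pair_similarity)
from protqa.structure import extract_sequence
from protqa.synth import (SyntheticScenario, make_native, make_models,
                          make_templates_and_alignments, perturb)


def straight_line_disco(ensemble, model):
    """Literal reimplementation of the constraint equations, no shortcuts."""
    n = len(model)
    ca = model.ca_array()
    disco = np.full(n, np.nan)
    for i in range(n):
        vals = []
        for j in range(n):
            if j == i or np.isnan(ca[i, 0]) or np.isnan(ca[j, 0]):
                continue
            d_ij = float(np.linalg.norm(ca[i] - ca[j]))
            if d_ij >= 15.0:
                continue
            key = (min(i, j), max(i, j))
            if key not in ensemble.pairs:
                continue
            clusters = sorted(ensemble.pairs[key])
            weights = [np.exp(ensemble.gamma * ensemble.cluster_ss[c])
                       for c in clusters]
            wsum = sum(weights)
            s_ij = 0.0
            for c, w in zip(clusters, weights):
                mus = ensemble.pairs[key][c]
                h = sum(np.exp(-0.5 * (d_ij - mu) ** 2)
                        for mu in mus) / len(mus)
                s_ij += (w / wsum) * h
            vals.append(s_ij)
        if vals:
            disco[i] = float(np.mean(vals))
    return disco


def _template(tid, mapping, coords, sim, ident, seq):
    return AlignedTemplate(tid, mapping, seq, coords, sim, ident)


def random_ensemble(rng, n_res=12, n_clusters=2):
    """Hand-built ensemble with random constraints."""
    pairs = {}
    for i in range(n_res):
        for j in range(i + 1, n_res):
            if rng.random() < 0.5:
                continue
            by_c = {}
            for c in range(n_clusters):
                if rng.random() < 0.6:
                    by_c[c] = rng.uniform(3.0, 14.9,
                                          size=rng.integers(1, 4))
            if by_c:
                pairs[(i, j)] = by_c
    return ConstraintEnsemble(
        target_length=n_res, gamma=70.0,
        cluster_ss=rng.uniform(0.2, 0.9, n_clusters),
        cluster_identity=rng.uniform(0.2, 0.9, n_clusters),
        pairs=pairs,
    )


class TestAlignmentMapping:
    def test_self_alignment_identity(self, tmp_path):
        native = make_native(SyntheticScenario(seed=41, length=12))
        scen = SyntheticScenario(seed=41, length=12, n_templates=1,
                                 template_noise=(0.0, 1e-9),
                                 template_coverage=(1.0, 1.0),
                                 template_identity=(1.0, 1.0))
        a3m, tpl_dir = make_templates_and_alignments(native, scen, tmp_path)
        target_seq, templates = load_alignments(a3m, tpl_dir)
        assert target_seq == extract_sequence(native)
        (tpl,) = templates
        assert tpl.target_to_template == {i: i for i in range(12)}
        assert tpl.seq_identity == pytest.approx(1.0)
        assert tpl.seq_similarity == pytest.approx(1.0)

    def test_lowercase_insertion_skipped(self, tmp_path):
        native = make_native(SyntheticScenario(seed=42, length=4))
        seq = extract_sequence(native)
        tpl_dir = tmp_path / "tpls"
        tpl_dir.mkdir()
        from protqa.structure import write_pdb
        from protqa.synth import make_templates_and_alignments  # noqa: F401
        # template = target with one inserted residue after column 2
        ins_native = make_native(SyntheticScenario(seed=43, length=5))
        for r, aa in zip(ins_native, seq[:2] + "A" + seq[2:]):
            r.aa = aa
        write_pdb(ins_native, tpl_dir / "t1.pdb")
        a3m = tmp_path / "t.a3m"
        a3m.write_text(f">target\n{seq}\n>t1\n{seq[:2]}a{seq[2:]}\n")
        _, templates = load_alignments(a3m, tpl_dir)
        (tpl,) = templates
        # insertion consumes template index 2, no target column
        assert tpl.target_to_template == {0: 0, 1: 1, 2: 3, 3: 4}

    def test_terminal_gaps_unmapped(self, tmp_path):
        native = make_native(SyntheticScenario(seed=44, length=8))
        seq = extract_sequence(native)
        from protqa.structure import write_pdb
        from protqa.synth import delete_segment
        tpl_dir = tmp_path / "tpls"
        tpl_dir.mkdir()
        trunc = delete_segment(native, 0, 3)
        for i, r in enumerate(trunc):
            r.number = i + 1
        write_pdb(trunc, tpl_dir / "t1.pdb")
        a3m = tmp_path / "t.a3m"
        a3m.write_text(f">target\n{seq}\n>t1\n---{seq[3:]}\n")
        _, templates = load_alignments(a3m, tpl_dir)
        assert sorted(templates[0].target_to_template) == [3, 4, 5, 6, 7]

    def test_empty_alignment_is_error(self, tmp_path):
        f = tmp_path / "empty.a3m"
        f.write_text("")
        with pytest.raises(ValueError):
            parse_a3m(f)


class TestClustering:
    def _tpl(self, tid, seq, sim):
        return _template(tid, {i: i for i in range(len(seq))},
                         {i: np.zeros(3) for i in range(len(seq))},
                         sim, sim, seq)

    def test_single_template_singleton_cluster(self):
        t = self._tpl("a", "ACDEF", 0.7)
        (c,) = cluster_templates([t])
        assert c.members == [t]
        assert c.avg_seq_similarity == pytest.approx(0.7)

    def test_identical_templates_merge(self):
        a = self._tpl("a", "ACDEF", 0.8)
        b = self._tpl("b", "ACDEF", 0.6)
        (c,) = cluster_templates([a, b])
        assert len(c.members) == 2
        assert c.avg_seq_similarity == pytest.approx(0.7)

    def test_dissimilar_templates_split(self):
        a = self._tpl("a", "AAAAA", 0.8)
        b = self._tpl("b", "WWWWW", 0.6)
        assert template_pair_similarity(a, b) < 0.8
        clusters = cluster_templates([a, b], similarity_threshold=0.95)
        assert len(clusters) == 2


class TestEnsembleConstruction:
    def test_distances_stored_under_cluster(self):
        coords = {0: np.zeros(3), 1: np.array([5.0, 0, 0])}
        tpl = _template("a", {0: 0, 1: 1}, coords, 0.9, 0.9, "AC")
        (c,) = cluster_templates([tpl])
        ens = build_ensemble([c], target_length=2)
        assert set(ens.pairs) == {(0, 1)}
        assert ens.pairs[(0, 1)][0].tolist() == [5.0]

    def test_fifteen_angstrom_boundary_excluded(self):
        coords = {0: np.zeros(3), 1: np.array([15.0, 0, 0])}
        tpl = _template("a", {0: 0, 1: 1}, coords, 0.9, 0.9, "AC")
        ens = build_ensemble(cluster_templates([tpl]), target_length=2)
        assert ens.pairs == {}

    def test_counts_per_cluster(self, rng):
        ens = random_ensemble(rng)
        for key, by_c in ens.pairs.items():
            for c, mus in by_c.items():
                assert len(mus) >= 1
                assert (mus < 15.0).all()


class TestEvaluatePair:
    def test_exact_constraint_scores_one(self):
        ens = ConstraintEnsemble(2, 70.0, np.array([0.5]), np.array([0.5]),
                                 {(0, 1): {0: np.array([5.0])}})
        assert evaluate_pair(ens, 0, 1, 5.0) == pytest.approx(1.0)

    def test_unit_deviation_gives_exp_minus_half(self):
        ens = ConstraintEnsemble(2, 70.0, np.array([0.5]), np.array([0.5]),
                                 {(0, 1): {0: np.array([5.0])}})
        assert evaluate_pair(ens, 0, 1, 6.0) == pytest.approx(
            np.exp(-0.5), abs=1e-12)

    def test_two_close_clusters_logistic_weighting(self):
        # two singleton clusters with similarities 0.276 and 0.273 at
        # gamma=70: the higher-similarity weight is the closed-form
        # logistic 1/(1+exp(-70*0.003))
        ens = ConstraintEnsemble(
            2, 70.0, np.array([0.276, 0.273]), np.array([0.3, 0.3]),
            {(0, 1): {0: np.array([5.0]), 1: np.array([9.0])}})
        w1 = 1.0 / (1.0 + np.exp(-70.0 * 0.003))
        expected = (w1 * np.exp(-0.5 * (5.0 - 5.0) ** 2)
                    + (1 - w1) * np.exp(-0.5 * (5.0 - 9.0) ** 2))
        assert evaluate_pair(ens, 0, 1, 5.0) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_absent_pair_signalled_not_raised(self, rng):
        ens = random_ensemble(rng)
        missing = next((i, j) for i in range(ens.target_length)
                       for j in range(i + 1, ens.target_length)
                       if (i, j) not in ens.pairs)
        assert evaluate_pair(ens, *missing, 5.0) is None

    def test_weights_sum_to_one(self, rng):
        for _ in range(20):
            ens = random_ensemble(rng, n_clusters=3)
            for (i, j), by_c in ens.pairs.items():
                c_idx = np.array(sorted(by_c))
                w = np.exp(ens.gamma * ens.cluster_ss[c_idx])
                w /= w.sum()
                assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_score_bounded_under_fuzzing(self, rng):
        ens = random_ensemble(rng, n_clusters=3)
        for _ in range(200):
            key = list(ens.pairs)[rng.integers(len(ens.pairs))]
            d = float(rng.uniform(0, 30))
            s = evaluate_pair(ens, *key, d)
            assert 0.0 <= s <= 1.0

    def test_gamma_limit_selects_best_cluster(self, rng):
        ens = random_ensemble(rng, n_clusters=3)
        key = next(k for k, v in ens.pairs.items() if len(v) > 1)
        d = 7.0
        big = copy.deepcopy(ens)
        big.gamma = 1e6
        c_idx = sorted(ens.pairs[key])
        best = max(c_idx, key=lambda c: ens.cluster_ss[c])
        mus = ens.pairs[key][best]
        h_best = float(np.mean(np.exp(-0.5 * (d - mus) ** 2)))
        assert evaluate_pair(big, *key, d) == pytest.approx(h_best,
                                                            abs=1e-9)


class TestScoreModel:
    def test_model_equals_template_scores_one(self, tmp_path):
        native = make_native(SyntheticScenario(seed=45, length=15))
        scen = SyntheticScenario(seed=45, length=15, n_templates=1,
                                 template_noise=(0.0, 1e-9),
                                 template_coverage=(1.0, 1.0),
                                 template_identity=(1.0, 1.0))
        a3m, tpl_dir = make_templates_and_alignments(native, scen, tmp_path)
        ens = ensemble_from_files(a3m, tpl_dir)
        res = score_model(ens, native)
        assert np.allclose(res.disco, 1.0)
        assert np.allclose(res.fraction_evaluated, 1.0)

    def test_uncovered_residues_invalid(self, tmp_path):
        native = make_native(SyntheticScenario(seed=46, length=20))
        scen = SyntheticScenario(seed=46, length=20, n_templates=1,
                                 template_noise=(0.0, 1e-9),
                                 template_coverage=(0.5, 0.5),
                                 template_identity=(1.0, 1.0))
        a3m, tpl_dir = make_templates_and_alignments(native, scen, tmp_path)
        ens = ensemble_from_files(a3m, tpl_dir)
        res = score_model(ens, native)
        covered = sorted({i for pair in ens.pairs for i in pair})
        uncovered = [i for i in range(20) if i not in covered]
        assert uncovered
        assert np.isnan(res.disco[uncovered]).all()
        assert (res.fraction_evaluated[uncovered] == 0).all()

    def test_matches_straight_line_oracle(self, tmp_path, rng):
        native = make_native(SyntheticScenario(seed=47, length=15))
        scen = SyntheticScenario(seed=47, length=15, n_templates=3)
        a3m, tpl_dir = make_templates_and_alignments(native, scen, tmp_path)
        ens = ensemble_from_files(a3m, tpl_dir)
        model = perturb(native, 1.0, rng)
        res = score_model(ens, model)
        oracle = straight_line_disco(ens, model)
        assert np.allclose(res.disco, oracle, atol=1e-9, equal_nan=True)

    def test_perturbation_monotonicity(self, tmp_path):
        from scipy.stats import spearmanr

        native = make_native(SyntheticScenario(seed=48, length=20))
        scen = SyntheticScenario(seed=48, length=20, n_templates=2,
                                 template_noise=(0.1, 0.3))
        a3m, tpl_dir = make_templates_and_alignments(native, scen, tmp_path)
        ens = ensemble_from_files(a3m, tpl_dir)
        amps = np.linspace(0.0, 3.0, 20)
        means = []
        for k, a in enumerate(amps):
            m = perturb(native, float(a), np.random.default_rng(900 + k))
            means.append(np.nanmean(score_model(ens, m).disco))
        rho, _ = spearmanr(amps, means)
        assert rho < 0

    def test_length_mismatch_is_error(self, rng):
        ens = random_ensemble(rng, n_res=10)
        model = make_native(SyntheticScenario(seed=49, length=12))
        with pytest.raises(ValueError):
            score_model(ens, model)
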