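"""Pseudo-absences, learners, AUC, thresholds, consensus and risk overlay."""

import numpy as np
import pandas as pd
import pytest

import nichedyn as nd
from nichedyn.sdm import _binary_map

from .conftest import auc_oracle, max_sss_oracle


def _toy_train(n=200, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(sep, 1.0, size=(n // 2, 3))
    neg = rng.normal(0.0, 1.0, size=(n // 2, 3))
    return pd.DataFrame(np.vstack([pos, neg]), columns=list("abc")).assign(
        label=[1] * (n // 2) + [0] * (n // 2))


class TestPseudoAbsences:
    def test_ratio_five_yields_five_times_presences(self, small_stack):
        xs, ys = small_stack.cell_center(range(10), range(10))
        occ = nd.OccurrenceSet(pd.DataFrame({"x": xs, "y": ys,
                                             "population": "P1"}))
        pa = nd.sample_pseudo_absences(small_stack, occ, ratio=5, seed=1)
        assert len(pa) == 50

    def test_no_pseudo_absence_on_presence_cell(self, small_stack):
        xs, ys = small_stack.cell_center(range(10), range(10))
        occ = nd.OccurrenceSet(pd.DataFrame({"x": xs, "y": ys,
                                             "population": "P1"}))
        pa = nd.sample_pseudo_absences(small_stack, occ, ratio=5, seed=2)
        pres_cells = set(zip(*small_stack.cell_of(occ.data.x, occ.data.y)))
        pa_cells = set(zip(*small_stack.cell_of(pa.x, pa.y)))
        assert not pres_cells & pa_cells
        assert len(pa_cells) == 50  # without replacement

    def test_zero_ratio_rejected(self, small_stack):
        occ = nd.OccurrenceSet(pd.DataFrame({"x": [1.0], "y": [-1.0],
                                             "population": "P1"}))
        with pytest.raises(ValueError):
            nd.sample_pseudo_absences(small_stack, occ, ratio=0)


class TestFitSdm:
    @pytest.mark.parametrize("algo", nd.sdm.ALGORITHMS)
    def test_separable_toy_perfect_training_auc(self, algo):
        train = _toy_train(sep=6.0)
        scorer = nd.fit_sdm(algo, train, seed=0)
        scores = scorer(train.drop(columns="label").to_numpy())
        assert nd.auc(scores, train["label"]) == pytest.approx(1.0)

    @pytest.mark.parametrize("algo", nd.sdm.ALGORITHMS)
    def test_permuted_labels_give_chance_auc(self, algo):
        rng = np.random.default_rng(1)
        train = _toy_train(n=500, sep=3.0, seed=1)
        train["label"] = rng.permutation(train["label"].to_numpy())
        test = _toy_train(n=200, sep=3.0, seed=2)
        test["label"] = rng.permutation(test["label"].to_numpy())
        scorer = nd.fit_sdm(algo, train, seed=0)
        a = nd.auc(scorer(test.drop(columns="label").to_numpy()), test["label"])
        assert 0.35 <= a <= 0.65

    def test_same_seed_identical_scorers(self):
        train = _toy_train(seed=3)
        X = train.drop(columns="label").to_numpy()
        s1 = nd.fit_sdm("random_forest", train, seed=9)(X)
        s2 = nd.fit_sdm("random_forest", train, seed=9)(X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self):
        train = _toy_train().assign(label=1)
        with pytest.raises(ValueError):
            nd.fit_sdm("boosted_trees", train)


class TestAuc:
    def test_perfect_and_reversed_ranking(self):
        assert nd.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert nd.auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_hand_enumerated_four_points(self):
        assert nd.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_ties_contribute_half(self):
        assert nd.auc([0.5, 0.5], [0, 1]) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = np.round(rng.uniform(size=30), 2)  # induce ties
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                continue
            a = nd.auc(scores, labels)
            assert a == pytest.approx(auc_oracle(scores, labels), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            nd.auc([0.1, 0.2], [1, 1])


class TestMaxSssThreshold:
    def test_separable_scores_pick_lowest_gap_midpoint(self):
        t = nd.max_sss_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.5)

    def test_achieves_best_over_every_candidate(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.uniform(size=25)
            labels = rng.integers(0, 2, size=25)
            if labels.sum() in (0, 25):
                continue
            t = nd.max_sss_threshold(scores, labels)
            _, best = max_sss_oracle(scores, labels)
            pred = scores >= t
            sens = (pred & (labels == 1)).sum() / labels.sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            assert sens + spec == pytest.approx(best)

    def test_all_equal_scores_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t = nd.max_sss_threshold([0.4, 0.4, 0.4], [0, 1, 1])
        assert t == 0.4


@pytest.fixture(scope="module")
def tiny_ensemble():
    scen = nd.make_invasion_scenario({
        "seed": 21, "n_rows": 24, "n_cols": 24, "n_native": 60,
        "n_invaded": 60, "native_breadth": [0.12] * 4,
        "noise_scale": 0.03})
    ens = nd.run_ensemble(scen.native_stack, scen.native_occ,
                          reps=2, seed=5, dataset="native")
    return scen, ens


class TestEnsembleMechanics:
    def test_run_count_and_agreement_bounds(self, tiny_ensemble):
        _, ens = tiny_ensemble
        assert len(ens.runs) == 6  # 2 reps x 3 algorithms
        assert ens.agreement_count.max() <= 6
        np.testing.assert_array_equal(
            ens.consensus_binary, ens.agreement_count > 3)

    def test_consensus_monotone_in_single_run_flip(self, tiny_ensemble):
        _, ens = tiny_ensemble
        maps = np.stack([r.binary_map for r in ens.runs])
        flipped = maps.copy()
        flipped[0] |= True  # flip run 0 everywhere to presence
        new_consensus = flipped.sum(axis=0) > len(ens.runs) / 2
        old_consensus = ens.consensus_binary
        assert not (old_consensus & ~new_consensus).any()

    def test_projection_onto_training_stack_is_identity(self, tiny_ensemble):
        scen, ens = tiny_ensemble
        proj = nd.project_ensemble(ens, scen.native_stack)
        np.testing.assert_array_equal(proj, ens.consensus_binary)

    def test_projection_with_reordered_layers_rejected(self, tiny_ensemble):
        scen, ens = tiny_ensemble
        names = list(reversed(scen.invaded_stack.layer_names))
        shuffled = scen.invaded_stack.subset_layers(names)
        with pytest.raises(ValueError, match="layer"):
            nd.project_ensemble(ens, shuffled)

    def test_too_few_presences_rejected(self, small_stack):
        occ = nd.OccurrenceSet(pd.DataFrame(
            {"x": [1.0] * 5, "y": [-1.0] * 5, "population": "P1"}))
        with pytest.raises(ValueError, match="presences"):
            nd.run_ensemble(small_stack, occ)


class TestRiskOverlay:
    def test_identical_maps_only_both_and_neither(self):
        m = np.zeros((4, 4), dtype=bool); m[:2] = True
        risk = nd.risk_overlay(m, m.copy())
        assert risk.shares["both"] == 0.5
        assert risk.shares["neither"] == 0.5
        assert risk.shares["native_only"] == risk.shares["invasive_only"] == 0.0

    def test_disjoint_maps_have_no_both_cells(self):
        a = np.zeros((4, 4), dtype=bool); a[0] = True
        b = np.zeros((4, 4), dtype=bool); b[3] = True
        risk = nd.risk_overlay(a, b)
        assert risk.shares["both"] == 0.0
        assert (risk.categories == 3).sum() == 0

    def test_hand_built_three_by_three_counts(self):
        nat = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0]], dtype=bool)
        inv = np.array([[1, 0, 0], [0, 1, 1], [0, 0, 0]], dtype=bool)
        risk = nd.risk_overlay(nat, inv)
        assert (risk.categories == risk.CODES["both"]).sum() == 2
        assert (risk.categories == risk.CODES["native_only"]).sum() == 1
        assert (risk.categories == risk.CODES["invasive_only"]).sum() == 1
        assert (risk.categories == risk.CODES["neither"]).sum() == 5
        assert sum(risk.shares.values()) == pytest.approx(1.0)

    def test_shares_partition_valid_cells(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(size=(6, 6)) > 0.5
        b = rng.uniform(size=(6, 6)) > 0.5
        mask = rng.uniform(size=(6, 6)) > 0.3
        risk = nd.risk_overlay(a, b, mask)
        assert sum(risk.shares.values()) == pytest.approx(1.0)
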