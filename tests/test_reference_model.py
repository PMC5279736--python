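"""Clustering, discriminant fitting, outlier voting and serialization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

from riverpacs import synthetic
from riverpacs.reference_model import (
    BiologicalGroups,
    FitError,
    PredictiveModel,
    cluster_reference_sites,
    compute_group_frequencies,
    fit_discriminant_model,
    select_best_models,
    site_in_model_range,
)
from riverpacs.reference_model import test_outlier as outlier_flags  # avoid test collection


def _groups(labels, index=None):
    index = index if index is not None else [f"s{i}" for i in range(len(labels))]
    return BiologicalGroups(k=max(labels), assignment=pd.Series(labels, index=index))


class TestClustering:
    def test_disjoint_blocks_recovered(self):
        occ = pd.DataFrame(
            [[1, 1, 0, 0]] * 4 + [[0, 0, 1, 1]] * 4,
            index=[f"s{i}" for i in range(8)],
            columns=list("abcd"),
        )
        g = cluster_reference_sites(occ, 2)
        labels = g.assignment
        assert labels.iloc[:4].nunique() == 1 and labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_partition_invariant_to_site_order(self):
        rng = np.random.default_rng(5)
        occ = pd.DataFrame(
            rng.integers(0, 2, size=(20, 8)) | np.eye(20, 8, dtype=int),
            index=[f"s{i}" for i in range(20)],
        )
        occ = occ[occ.sum(axis=1) > 0]
        g1 = cluster_reference_sites(occ, 3).assignment
        perm = occ.sample(frac=1.0, random_state=1)
        g2 = cluster_reference_sites(perm, 3).assignment.loc[g1.index]
        assert adjusted_rand_score(g1, g2) == pytest.approx(1.0)

    def test_three_separated_niches_recovered_exactly(self):
        # 12 sites from 3 communities whose taxon pools barely overlap
        # (within-block dissimilarity << between-block dissimilarity).
        rng = np.random.default_rng(2)
        blocks, truth = [], []
        shared = np.zeros(16, dtype=int)
        shared[15] = 1  # one ubiquitous taxon shared by everyone
        for b in range(3):
            base = shared.copy()
            base[b * 5 : (b + 1) * 5] = 1
            for _ in range(4):
                row = base.copy()
                # small within-block noise: drop one of the block's taxa
                row[b * 5 + rng.integers(5)] = 0
                blocks.append(row)
                truth.append(b)
        occ = pd.DataFrame(blocks, index=[f"s{i}" for i in range(12)])
        g = cluster_reference_sites(occ, 3)
        assert adjusted_rand_score(truth, g.assignment) == pytest.approx(1.0)

    def test_small_groups_absorbed(self):
        occ = pd.DataFrame(
            [[1, 1, 0, 0, 0]] * 6 + [[0, 0, 1, 1, 0]] * 6 + [[0, 0, 0, 0, 1]],
            index=[f"s{i}" for i in range(13)],
        )
        g = cluster_reference_sites(occ, 3, min_group_size=3)
        assert g.k == 2
        assert g.assignment.value_counts().min() >= 3

    def test_empty_site_rejected(self):
        occ = pd.DataFrame([[1, 0], [0, 0], [0, 1]], index=list("abc"))
        with pytest.raises(ValueError, match="empty taxa"):
            cluster_reference_sites(occ, 2)

    def test_k_larger_than_sites_rejected(self):
        occ = pd.DataFrame([[1, 0], [0, 1]], index=list("ab"))
        with pytest.raises(ValueError):
            cluster_reference_sites(occ, 5)


class TestGroupFrequencies:
    def test_count_ratios(self):
        occ = pd.DataFrame(
            {"ubiquitous": [1] * 8, "absent": [0] * 8, "partial": [1, 1, 1, 0, 1, 0, 0, 0]},
            index=[f"s{i}" for i in range(8)],
        )
        groups = _groups([1, 1, 1, 1, 2, 2, 2, 2])
        f = compute_group_frequencies(occ, groups)
        assert (f["ubiquitous"] == 1.0).all()
        assert (f["absent"] == 0.0).all()
        assert f.loc[1, "partial"] == pytest.approx(0.75)
        assert f.loc[2, "partial"] == pytest.approx(0.25)

    def test_invariant_to_site_reordering(self):
        rng = np.random.default_rng(0)
        occ = pd.DataFrame(rng.integers(0, 2, (10, 5)), index=[f"s{i}" for i in range(10)])
        groups = _groups(list(rng.integers(1, 3, 10)))
        f1 = compute_group_frequencies(occ, groups)
        f2 = compute_group_frequencies(occ.sample(frac=1.0, random_state=3), groups)
        pd.testing.assert_frame_equal(f1, f2)


class TestDiscriminant:
    def _two_group_env(self, n=40, delta=2.0, sd=1.0, seed=0, extra_noise_cols=0):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(-delta / 2, sd, n), rng.normal(delta / 2, sd, n)])
        env = pd.DataFrame({"p1": x}, index=[f"s{i}" for i in range(2 * n)])
        for j in range(extra_noise_cols):
            env[f"noise{j}"] = rng.normal(0, 1, 2 * n)
        groups = _groups([1] * n + [2] * n, index=env.index)
        return env, groups

    def test_perfect_separation_gives_loo_accuracy_one(self):
        env, groups = self._two_group_env(delta=50.0, sd=0.01)
        m = fit_discriminant_model(env, groups, ["p1"])
        assert m.cv_accuracy == pytest.approx(1.0)

    def test_constant_predictor_raises_naming_it(self):
        env, groups = self._two_group_env()
        env["flat"] = 3.0
        with pytest.raises(FitError, match="flat"):
            fit_discriminant_model(env, groups, ["p1", "flat"])

    def test_loo_accuracy_near_bayes_rate(self):
        # Means +/-2 with unit variance: Bayes accuracy is Phi(1) per side at
        # the midpoint threshold, i.e. Phi(delta/2) with delta=4... kept to
        # the canonical Phi(2) ~= 0.977 check at delta=4 sd=1.
        env, groups = self._two_group_env(n=200, delta=4.0, sd=1.0, seed=42)
        m = fit_discriminant_model(env, groups, ["p1"])
        assert m.cv_accuracy == pytest.approx(norm.cdf(2.0), abs=0.05)

    def test_priors_sum_and_membership_concentrates(self):
        env, groups = self._two_group_env(delta=8.0)
        m = fit_discriminant_model(env, groups, ["p1"])
        assert m.priors.sum() == pytest.approx(1.0)
        post = m.posterior(env)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        # average membership of group-1 sites concentrates on group 1
        assert post[:40, 0].mean() > 0.95

    def test_selection_ranks_informative_predictor_first(self):
        env, groups = self._two_group_env(n=30, delta=6.0, extra_noise_cols=2, seed=7)
        models = select_best_models(
            env, groups, n_models=3, candidate_subsets=[["noise0"], ["noise1"], ["p1"]]
        )
        assert models[0].predictor_subset == ["p1"]
        accs = [m.cv_accuracy for m in models]
        assert accs == sorted(accs, reverse=True)

    def test_single_candidate_returned_alone(self):
        env, groups = self._two_group_env(n=20)
        models = select_best_models(env, groups, n_models=1, candidate_subsets=[["p1"]])
        assert len(models) == 1 and models[0].predictor_subset == ["p1"]


class TestOutlierRule:
    def _hand_model(self):
        # 1 predictor, group means 0 and 10 (raw), pooled variance 1.
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])
        env = pd.DataFrame({"p1": x}, index=[f"s{i}" for i in range(400)])
        groups = _groups([1] * 200 + [2] * 200, index=env.index)
        return fit_discriminant_model(env, groups, ["p1"])

    def test_hand_computed_mahalanobis_thresholds(self):
        # alpha=0.01, df=1: chi-square quantile 6.635.  Distances from the
        # nearer group mean: env=14 -> ~16 (outlier); env=8 -> ~4 (inside).
        m = self._hand_model()
        env = pd.DataFrame({"p1": [14.0, 8.0]}, index=["far", "near"])
        flags = outlier_flags(env, m, alpha=0.01)
        assert flags.tolist() == [True, False]

    def test_group_mean_never_outlier(self):
        m = self._hand_model()
        env = pd.DataFrame({"p1": [0.0]}, index=["at_mean"])
        for alpha in (0.5, 0.05, 0.001):
            assert not outlier_flags(env, m, alpha=alpha)[0]

    def test_outlier_rule_monotone_in_distance(self):
        m = self._hand_model()
        xs = pd.DataFrame({"p1": np.linspace(10, 40, 40)}, index=[f"g{i}" for i in range(40)])
        flags = outlier_flags(xs, m, alpha=0.01).astype(int)
        assert np.all(np.diff(flags) >= 0)  # once out, stays out

    @pytest.mark.parametrize("n_flagging,expect_out", [(0, False), (2, False), (3, True), (5, True)])
    def test_vote_threshold_three_of_five(self, n_flagging, expect_out):
        # Five single-predictor models on independent predictors p0..p4; the
        # probe sits far outside the range on exactly n_flagging of them.
        rng = np.random.default_rng(3)
        n = 100
        env = pd.DataFrame(
            {f"p{j}": np.concatenate([rng.normal(0, 1, n), rng.normal(10, 1, n)]) for j in range(5)},
            index=[f"s{i}" for i in range(2 * n)],
        )
        groups = _groups([1] * n + [2] * n, index=env.index)
        models = sorted(
            (fit_discriminant_model(env, groups, [f"p{j}"]) for j in range(5)),
            key=lambda m: -m.cv_accuracy,
        )
        pm = PredictiveModel(
            groups=groups,
            models=models,
            frequencies=pd.DataFrame({"t": [0.5, 0.5]}, index=pd.Index([1, 2], name="group")),
            outlier_vote_threshold=3,
        )
        flagged = {m.predictor_subset[0] for m in models[:n_flagging]}
        probe = pd.DataFrame(
            {f"p{j}": [100.0 if f"p{j}" in flagged else 0.0] for j in range(5)}, index=["probe"]
        )
        # sanity: exactly n_flagging individual models flag the probe
        votes = sum(int(m.is_outlier(probe, pm.outlier_alpha)[0]) for m in pm.models)
        assert votes == n_flagging
        assert bool(pm.out_of_range(probe)[0]) is expect_out
        assert bool(site_in_model_range(probe, pm)[0]) is (not expect_out)


class TestSerialization:
    def test_json_round_trip(self, pipeline):
        _, _, pm, _ = pipeline
        text = pm.to_json()
        back = PredictiveModel.from_json(text)
        assert back.to_json() == text
        pd.testing.assert_frame_equal(back.frequencies, pm.frequencies)
        for m1, m2 in zip(pm.models, back.models):
            assert m1.predictor_subset == m2.predictor_subset
            np.testing.assert_allclose(m1.group_means, m2.group_means)
            assert m1.cv_accuracy == m2.cv_accuracy
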