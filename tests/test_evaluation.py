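import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hlrr.evaluation import (CVPlan, ImputationSVMMethod, compute_metrics,
                             confusion_summary, default_param_grid,
                             friedman_statistic, impute_baselines, nemenyi_cd,
                             nested_cv, rank_methods)
from hlrr.synthetic import scaled_down_config, generate
from conftest import make_dataset
import oracles

MODS = ("MRI", "PET", "CSF")


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 1, -1, -1])
        cs = confusion_summary(y, y, scores=[2.0, 1.5, -1.0, -2.0])
        m = compute_metrics(cs)
        assert all(m[k] == 1.0 for k in
                   ("ACC", "SEN", "SPE", "BAC", "PPV", "NPV", "AUC"))

    def test_counting_example(self):
        # TP=3 FN=1 TN=4 FP=2
        yt = [1, 1, 1, 1, -1, -1, -1, -1, -1, -1]
        yp = [1, 1, 1, -1, 1, 1, -1, -1, -1, -1]
        m = compute_metrics(confusion_summary(yt, yp))
        assert m["ACC"] == pytest.approx(0.7)
        assert m["SEN"] == pytest.approx(0.75)
        assert m["SPE"] == pytest.approx(2 / 3)
        assert m["PPV"] == pytest.approx(0.6)
        assert m["NPV"] == pytest.approx(0.8)
        assert m["BAC"] == pytest.approx((0.75 + 2 / 3) / 2)

    def test_auc_for_separated_scores(self):
        yt = [1, 1, -1, -1, -1]
        cs = confusion_summary(yt, yt, scores=[5.0, 4.0, 1.0, 0.5, -2.0])
        assert compute_metrics(cs)["AUC"] == 1.0

    def test_matches_bruteforce_counting(self, rng):
        for _ in range(10):
            yt = rng.choice([1, -1], 20)
            yp = rng.choice([1, -1], 20)
            sc = rng.standard_normal(20).round(1)   # force some score ties
            if len(set(yt)) < 2:
                continue
            m = compute_metrics(confusion_summary(yt, yp, sc))
            o = oracles.metrics_loops(yt, yp, sc)
            for k, v in o.items():
                assert m[k] == pytest.approx(v, nan_ok=True)

    def test_order_and_monotone_invariance(self, rng):
        yt = rng.choice([1, -1], 30)
        yp = rng.choice([1, -1], 30)
        sc = rng.standard_normal(30)
        m1 = compute_metrics(confusion_summary(yt, yp, sc))
        perm = rng.permutation(30)
        m2 = compute_metrics(confusion_summary(yt[perm], yp[perm], sc[perm]))
        m3 = compute_metrics(confusion_summary(yt, yp, np.exp(3 * sc)))
        for k in m1:
            assert m1[k] == pytest.approx(m2[k], nan_ok=True)
        assert m1["AUC"] == pytest.approx(m3["AUC"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_summary([], [])


class TestImputation:
    def test_zero_fills_missing_block_with_zeros(self, rng):
        ds = make_dataset(rng, [MODS, ("MRI", "CSF")], dims=(2, 90, 1))
        table = impute_baselines(ds, "zero")
        assert table.shape == (2, 93)
        np.testing.assert_allclose(table[1, 2:92], 0.0)

    def test_knn_mean_of_identical_neighbors(self, rng):
        # subject 0 misses PET; five donors share an identical PET block v
        v = np.array([7.0, -3.0])
        pats = [("MRI", "CSF")] + [MODS] * 5
        ds = make_dataset(rng, pats, dims=(3, 2, 2))
        for i in range(1, 6):
            ds.features["PET"][i] = v
            ds.features["MRI"][i] = ds.features["MRI"][0]  # equally near
        table = impute_baselines(ds, "knn", k1=5)
        np.testing.assert_allclose(table[0, 3:5], v)

    def test_no_donor_falls_back_to_zero(self, rng):
        pats = [("MRI", "CSF"), ("MRI",), ("MRI", "CSF")]
        ds = make_dataset(rng, pats, dims=(2, 2, 1))
        with pytest.warns(UserWarning, match="no donor"):
            table = impute_baselines(ds, "knn")
        np.testing.assert_allclose(table[:, 2:4], 0.0)


class TestNestedCV:
    def _dataset(self, seed=5):
        cfg = scaled_down_config(seed=seed, n_per_class=(20, 20))
        ds, _ = generate(cfg)
        return ds

    def test_default_grid_endpoints(self):
        grid = default_param_grid(full=True)
        for pts in grid.values():
            assert pts[0] == pytest.approx(1e-7)
            assert pts[-1] == pytest.approx(1e7)
        sub = default_param_grid()
        assert all(len(p) == 5 for p in sub.values())

    def test_fold_sizes_stratified(self):
        ds = self._dataset()
        plan = CVPlan(outer_folds=5, inner_folds=2, param_grid={}, seed=1)
        res = nested_cv(ds, plan,
                        lambda: ImputationSVMMethod("case", "control"),
                        "case")
        for log in res["folds"]:
            y = np.asarray(ds.labels)[log["test_idx"]]
            assert abs((y == "case").sum() - (y == "control").sum()) <= 1

    def test_same_seed_reproduces_everything(self):
        ds = self._dataset()
        plan = CVPlan(outer_folds=4, inner_folds=2,
                      param_grid={"C": [0.1, 1.0]}, seed=7)
        f = lambda: ImputationSVMMethod("case", "control")
        r1 = nested_cv(ds, plan, f, "case")
        r2 = nested_cv(ds, plan, f, "case")
        assert r1["metrics"] == r2["metrics"]
        assert r1["fold_params"] == r2["fold_params"]
        assert [l["test_idx"] for l in r1["folds"]] == \
               [l["test_idx"] for l in r2["folds"]]

    def test_grid_search_selects_a_grid_point(self):
        ds = self._dataset()
        plan = CVPlan(outer_folds=3, inner_folds=2,
                      param_grid={"C": [0.01, 1.0]}, seed=0)
        res = nested_cv(ds, plan,
                        lambda: ImputationSVMMethod("case", "control"),
                        "case")
        assert all(p["C"] in (0.01, 1.0) for p in res["fold_params"])

    def test_single_class_rejected(self, rng):
        ds = make_dataset(rng, [MODS] * 6, labels=["a"] * 6)
        with pytest.raises(ValueError):
            nested_cv(ds, CVPlan(outer_folds=2, inner_folds=2), lambda: None,
                      "a")


class TestFriedman:
    def test_all_tied_gives_zero(self):
        R = np.full((3, 5), 2.0)   # identical mean ranks
        assert friedman_statistic(R) == pytest.approx(0.0)

    def test_fixed_ordering_example(self):
        # 3 methods always ranked 1, 2, 3 over 4 datasets -> 8
        R = np.array([[1.0] * 4, [2.0] * 4, [3.0] * 4])
        assert friedman_statistic(R) == pytest.approx(8.0)

    def test_matches_alternative_formula(self, rng):
        for _ in range(100):
            k, N = rng.integers(2, 7), rng.integers(2, 10)
            scores = rng.standard_normal((k, N))
            R = rank_methods(scores)
            assert friedman_statistic(R) == pytest.approx(
                oracles.friedman_alt(R), abs=1e-10)

    def test_ragged_or_tiny_rejected(self):
        with pytest.raises(ValueError):
            friedman_statistic(np.ones((1, 5)))


class TestNemenyi:
    def test_cd_shrinks_with_more_datasets(self):
        assert nemenyi_cd(5, 10)["cd"] > nemenyi_cd(5, 100)["cd"]

    def test_equal_mean_ranks_never_significant(self):
        out = nemenyi_cd(3, 8, 0.05, mean_ranks=[2.0, 2.0, 2.0])
        assert not np.asarray(out["significant"]).any()

    def test_matches_studentized_range_table(self):
        for k in (2, 3, 5, 10, 20):
            for alpha in (0.05, 0.10):
                got = nemenyi_cd(k, 12, alpha)["cd"]
                ref = oracles.nemenyi_cd_alt(k, 12, alpha)
                assert got == pytest.approx(ref, abs=5e-3)

    def test_unsupported_alpha_rejected(self):
        with pytest.raises(ValueError):
            nemenyi_cd(3, 5, alpha=0.01)


@given(seed=st.integers(0, 100))
@settings(max_examples=20, deadline=None)
def test_rank_table_rows_are_permutation_ranks(seed):
    rng = np.random.default_rng(seed)
    S = rng.standard_normal((4, 6))
    R = rank_methods(S)
    np.testing.assert_allclose(R.sum(axis=0), 4 * 5 / 2)
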