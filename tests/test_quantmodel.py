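"""Linear-model estimation, contrasts, and fold-change-gated BH calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_feature_table
from syndiversity import quantmodel as qm
from syndiversity.synthdata import FeatureTable


def brute_force_bh(pvals: np.ndarray) -> np.ndarray:
    """Textbook step-up definition: q_(i) = min_{j>=i} m p_(j) / j, capped."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = min(running, 1.0)
    return q


def _runs_frame(groups: pd.Series) -> pd.DataFrame:
    return pd.DataFrame({
        "run": groups.index, "animal": groups.index,
        "fraction": "sorted", "region": "CX", "cell_type": "X",
    })


class TestNormalizeRuns:
    def test_constant_offset_between_runs_removed_exactly(self):
        rec, groups = make_feature_table({"G1": 10.0}, n_features=4,
                                         n_runs_per_group=2)
        # shift second run by +1 log2 unit
        m = rec["run"] == "G1_r1"
        rec.loc[m, "intensity"] *= 2.0
        tab = FeatureTable(records=rec, runs=_runs_frame(groups))
        out = qm.normalize_runs(tab)
        piv = out.records.pivot_table(index="feature", columns="run",
                                      values="intensity")
        np.testing.assert_allclose(piv["G1_r0"], piv["G1_r1"], rtol=1e-12)

    def test_run_medians_equalized_on_random_table(self):
        rng = np.random.default_rng(0)
        rows = []
        for r in range(5):
            for f in range(20):
                rows.append({"protein": f"P{f % 7}", "feature": f"f{f}",
                             "run": f"r{r}",
                             "intensity": 2.0 ** rng.normal(10 + r, 2)})
        rec = pd.DataFrame(rows)
        runs = pd.DataFrame({"run": [f"r{r}" for r in range(5)],
                             "animal": list("abcde"), "fraction": "sorted",
                             "region": "CX", "cell_type": "X"})
        out = qm.normalize_runs(FeatureTable(records=rec, runs=runs))
        med = out.records.assign(
            l=np.log2(out.records["intensity"])
        ).groupby("run")["l"].median()
        assert med.max() - med.min() < 1e-9

    def test_empty_run_raises_with_run_name(self):
        rec = pd.DataFrame({"protein": ["P"], "feature": ["f"],
                            "run": ["r1"], "intensity": [4.0]})
        runs = pd.DataFrame({"run": ["r1", "r2"], "animal": ["a", "b"],
                             "fraction": "sorted", "region": "CX",
                             "cell_type": "X"})
        with pytest.raises(ValueError, match="r2"):
            qm.normalize_runs(FeatureTable(records=rec, runs=runs))


class TestTestability:
    @pytest.mark.parametrize(
        "n_features,meas_a,meas_b,expected",
        [(6, 12, 12, True), (5, 24, 24, False), (6, 12, 11, False)],
    )
    def test_feature_and_measurement_thresholds(
        self, n_features, meas_a, meas_b, expected
    ):
        rows = []
        groups = {}
        for cond, n_meas in (("A", meas_a), ("B", meas_b)):
            n_runs = int(np.ceil(n_meas / n_features))
            count = 0
            for r in range(n_runs):
                run = f"{cond}_r{r}"
                groups[run] = cond
                for f in range(n_features):
                    if count >= n_meas:
                        break
                    rows.append({"protein": "P", "feature": f"f{f}",
                                 "run": run, "intensity": 100.0})
                    count += 1
        out = qm.filter_testability(
            pd.DataFrame(rows), pd.Series(groups), ["A", "B"]
        )
        assert out["testable"] is expected
        assert out["n_features"] == n_features


class TestFitProteinModel:
    def test_noiseless_fit_recovers_exact_difference_but_is_untestable(self):
        rec, groups = make_feature_table({"G1": 11.0, "G2": 10.0},
                                         n_features=2, n_runs_per_group=2)
        fit = qm.fit_protein_model(rec, groups, min_features=1,
                                   min_measurements=1)
        i1, i2 = fit.group_index("G1"), fit.group_index("G2")
        assert fit.ls_means[i1] - fit.ls_means[i2] == pytest.approx(1.0)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)
        assert not fit.testable

    def test_noisy_fit_within_three_se_of_truth(self):
        rec, groups = make_feature_table(
            {"G1": 11.0, "G2": 10.0}, n_features=6, n_runs_per_group=6,
            noise_sd=0.1, seed=42,
        )
        fit = qm.fit_protein_model(rec, groups)
        res = qm.compare_groups(fit, {"G1": 1.0, "G2": -1.0})
        assert abs(res.log2fc - 1.0) <= 3 * res.se

    def test_balanced_fit_matches_feature_centered_group_means(self):
        rng = np.random.default_rng(7)
        rec, groups = make_feature_table(
            {"G1": 12.0, "G2": 10.5}, n_features=5, n_runs_per_group=4,
            noise_sd=0.3, seed=3,
        )
        fit = qm.fit_protein_model(rec, groups, min_features=1,
                                   min_measurements=1)
        # oracle: center each feature across all runs, average per run,
        # then per group; the LS-mean difference must match exactly
        df = rec.assign(y=np.log2(rec["intensity"]))
        df["yc"] = df["y"] - df.groupby("feature")["y"].transform("mean")
        run_ab = df.groupby("run")["yc"].mean()
        grp = run_ab.groupby(groups.reindex(run_ab.index)).mean()
        i1, i2 = fit.group_index("G1"), fit.group_index("G2")
        assert fit.ls_means[i1] - fit.ls_means[i2] == pytest.approx(
            grp["G1"] - grp["G2"], abs=1e-9
        )

    def test_all_missing_gives_untestable_fit(self):
        rec = pd.DataFrame(columns=["protein", "feature", "run", "intensity"])
        fit = qm.fit_protein_model(rec, pd.Series(dtype=object))
        assert not fit.testable

    def test_single_observation_features_dropped(self):
        rec, groups = make_feature_table({"G1": 11.0, "G2": 10.0},
                                         n_features=3, n_runs_per_group=3,
                                         noise_sd=0.05, seed=1)
        lone = pd.DataFrame({"protein": ["P1"], "feature": ["only_once"],
                             "run": ["G1_r0"], "intensity": [123.0]})
        fit = qm.fit_protein_model(pd.concat([rec, lone], ignore_index=True),
                                   groups, min_features=1, min_measurements=1)
        assert fit.dropped_features == ["only_once"]
        assert fit.n_features == 3


class TestCompareGroups:
    def _fit(self, means, sigma2, df, n_per_group=5):
        k = len(means)
        return qm.ProteinFit(
            protein="P", groups=[f"G{i+1}" for i in range(k)],
            ls_means=np.array(means, dtype=float),
            cov_unscaled=np.eye(k) / n_per_group,
            sigma2=sigma2, df_resid=df, n_features=6,
            n_measurements={f"G{i+1}": 30 for i in range(k)}, testable=True,
        )

    def test_simple_difference_contrast(self):
        res = qm.compare_groups(self._fit([10.0, 9.0], 0.04, 8),
                                {"G1": 1.0, "G2": -1.0})
        assert res.log2fc == pytest.approx(1.0)

    def test_zero_statistic_reports_p_one(self):
        res = qm.compare_groups(self._fit([10.0, 10.0], 0.04, 8),
                                {"G1": 1.0, "G2": -1.0})
        assert res.t == 0.0 and res.p == 1.0

    def test_t_to_p_conversion_matches_t_distribution(self):
        # choose sigma2 so that t = 1.0 / se = 2.704 at df 13
        se = 1.0 / 2.704
        sigma2 = se**2 / (2 / 5)
        res = qm.compare_groups(self._fit([10.0, 9.0], sigma2, 13),
                                {"G1": 1.0, "G2": -1.0})
        assert res.t == pytest.approx(2.704, abs=1e-9)
        assert res.p == pytest.approx(0.01815, abs=2e-4)

    def test_nonzero_sum_contrast_rejected(self):
        with pytest.raises(ValueError, match="sum to 0"):
            qm.compare_groups(self._fit([10.0, 9.0], 0.1, 8), {"G1": 1.0})

    def test_absent_group_rejected(self):
        with pytest.raises(KeyError, match="G9"):
            qm.compare_groups(self._fit([10.0, 9.0], 0.1, 8),
                              {"G9": 1.0, "G2": -1.0})


def _result(protein, log2fc, p):
    return qm.ComparisonResult(protein=protein, contrast="c", log2fc=log2fc,
                               se=0.1, df=10, t=log2fc / 0.1, p=p)


class TestAdjustAndCall:
    def test_bh_matches_textbook_example(self):
        res = qm.adjust_and_call(
            [_result(f"p{i}", 0.5, p) for i, p in
             enumerate([0.01, 0.02, 0.03, 0.04])]
        )
        np.testing.assert_allclose([r.p_adj for r in res], 0.04, atol=1e-12)

    def test_fc_gate_excludes_small_fold_changes(self):
        res = qm.adjust_and_call(
            [_result("tiny_fc", 0.10, 1e-9), _result("big_fc", 0.5, 0.01)]
        )
        by = {r.protein: r for r in res}
        assert by["tiny_fc"].call == "not significant"
        assert np.isnan(by["tiny_fc"].p_adj)
        assert by["big_fc"].call == "enriched"

    def test_single_gated_protein_keeps_raw_p(self):
        res = qm.adjust_and_call(
            [_result("a", 0.5, 0.013), _result("b", 0.05, 0.5)]
        )
        by = {r.protein: r for r in res}
        assert by["a"].p_adj == pytest.approx(0.013)

    def test_de_enrichment_symmetric(self):
        res = qm.adjust_and_call([_result("a", -0.8, 0.001)])
        assert res[0].call == "de-enriched"

    def test_all_scope_adjusts_everything(self):
        res = qm.adjust_and_call(
            [_result("a", 0.05, 0.01), _result("b", 0.5, 0.01)],
            bh_scope="all",
        )
        assert all(np.isfinite(r.p_adj) for r in res)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_bh_equals_brute_force_step_up(self, pvals):
        res = qm.adjust_and_call(
            [_result(f"p{i}", 1.0, p) for i, p in enumerate(pvals)]
        )
        expected = brute_force_bh(np.array(pvals))
        np.testing.assert_allclose([r.p_adj for r in res], expected,
                                   atol=1e-12)


class TestShiftInvariance:
    def test_constant_run_offset_leaves_results_unchanged(self):
        rec, groups = make_feature_table(
            {"G1": 11.0, "G2": 10.0}, n_features=6, n_runs_per_group=3,
            noise_sd=0.1, seed=5,
        )
        runs = _runs_frame(groups)
        shifted = rec.copy()
        m = shifted["run"] == "G1_r0"
        shifted.loc[m, "intensity"] *= 2.0**1.7
        out = []
        for r in (rec, shifted):
            tab = qm.normalize_runs(FeatureTable(records=r, runs=runs))
            fit = qm.fit_protein_model(tab.records, groups, min_features=1,
                                       min_measurements=1)
            out.append(qm.compare_groups(fit, {"G1": 1.0, "G2": -1.0},
                                         min_features=1, min_measurements=1))
        assert out[0].log2fc == pytest.approx(out[1].log2fc, abs=1e-9)
        assert out[0].p == pytest.approx(out[1].p, abs=1e-9)
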