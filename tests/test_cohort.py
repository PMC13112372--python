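"""Tests for the clinical-cohort statistics module."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from neuroimmune.cohort import (
    apply_gating,
    combined_panel,
    compute_indices,
    fit_logistic,
    mouse_group_stats,
    pearson_correlation,
    rcs_basis,
    rcs_dose_response,
    roc_auc,
    summarize_cohort,
    zscore,
)
from oracles import auc_pair_counting


class TestGating:
    def test_age_boundary(self, toy_cohort):
        df = toy_cohort.copy()
        df.loc[0, "age_onset_years"] = 15.0
        res = apply_gating(df)
        assert res.removed["age"] == 1
        assert len(res.table) == len(df) - 1
        # age exactly 14 is included
        df.loc[0, "age_onset_years"] = 14.0
        assert len(apply_gating(df).table) == len(df)

    def test_all_pass_identity(self, toy_cohort):
        res = apply_gating(toy_cohort)
        pd.testing.assert_frame_equal(res.table, toy_cohort)
        assert sum(res.removed.values()) == 0

    def test_planted_violations(self, toy_cohort):
        df = toy_cohort.copy()
        df.loc[1, "wbc"] = 25.0  # above any pediatric limit
        df.loc[2, "crp"] = np.nan  # missing required field
        res = apply_gating(df)
        assert len(res.table) == len(df) - 2
        assert res.removed["wbc_limit"] == 1
        assert res.removed["missing_field"] == 1

    def test_exclusion_flags(self, toy_cohort):
        df = toy_cohort.copy()
        df["steroid_exposure"] = False
        df.loc[3, "steroid_exposure"] = True
        res = apply_gating(df)
        assert res.removed["steroid_exposure"] == 1


class TestIndices:
    def test_hand_computed(self):
        df = pd.DataFrame(
            {
                "wbc": [6.0],
                "neutrophil_pct": [50.0],
                "lymphocyte_pct": [40.0],
                "platelets": [240.0],
                "crp": [0.1, ],
                "extra": [1],
            }
        )
        df = pd.concat([df, df.assign(neutrophil_pct=40.0)], ignore_index=True)
        out = compute_indices(df)
        assert out.loc[0, "nlr"] == pytest.approx(1.25)
        assert out.loc[0, "sii"] == pytest.approx(300.0)
        assert out.loc[1, "nlr"] == pytest.approx(1.0)  # neut% == lymph%

    def test_zero_platelets_flagged(self):
        df = pd.DataFrame(
            {
                "wbc": [6.0, 6.0],
                "neutrophil_pct": [50.0, 50.0],
                "lymphocyte_pct": [40.0, 40.0],
                "platelets": [0.0, 240.0],
                "crp": [0.1, 0.1],
            }
        )
        out = compute_indices(df)
        assert out.loc[0, "sii"] == 0.0
        assert bool(out.loc[0, "implausible"])

    def test_zero_lymphocytes_rejected(self):
        df = pd.DataFrame(
            {
                "wbc": [6.0],
                "neutrophil_pct": [50.0],
                "lymphocyte_pct": [0.0],
                "platelets": [240.0],
                "crp": [0.1],
            }
        )
        with pytest.raises(ValueError):
            compute_indices(df)


class TestSummaries:
    def test_printed_percentages_recomputed_exactly(self):
        """46/71 male controls and 38/69 male cases give 64.8% and 55.1%."""
        rows = (
            [("SeLECTS", "male")] * 46
            + [("SeLECTS", "female")] * 25
            + [("DRE", "male")] * 38
            + [("DRE", "female")] * 31
        )
        df = pd.DataFrame(rows, columns=["group", "sex"])
        df["age_onset_years"] = 5.0 + 0.01 * np.arange(len(df))
        summary = summarize_cohort(df, continuous=("age_onset_years",),
                                   categorical=("sex",))
        per = summary["sex"].per_group
        assert per["SeLECTS"]["male"][0] == 46
        assert round(per["SeLECTS"]["male"][1], 1) == 64.8
        assert per["DRE"]["male"][0] == 38
        assert round(per["DRE"]["male"][1], 1) == 55.1

    def test_identical_groups_yield_large_p(self, rng):
        x = rng.normal(10, 2, 40)
        df = pd.DataFrame(
            {"group": ["a"] * 40 + ["b"] * 40, "v": np.r_[x, x],
             "sex": ["male", "female"] * 40}
        )
        s = summarize_cohort(df, continuous=("v",), categorical=("sex",))
        assert s["v"].p > 0.99
        assert s["sex"].p == pytest.approx(1.0)

    def test_shapiro_gate_routes_tests(self, rng):
        normal = rng.normal(50, 5, 60)
        skewed = rng.lognormal(0, 1.2, 60)
        df = pd.DataFrame(
            {
                "group": ["a"] * 30 + ["b"] * 30,
                "norm_var": normal[:60],
                "skew_var": skewed,
            }
        )
        s = summarize_cohort(df, continuous=("norm_var", "skew_var"), categorical=())
        assert s["norm_var"].test == "welch_t"
        assert s["skew_var"].test == "mann_whitney_u"
        assert "median" in next(iter(s["skew_var"].per_group.values()))

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"group": ["a", "a", "b", "b"], "v": [1.0] * 4})
        s = summarize_cohort(df, continuous=("v",), categorical=())
        assert s["v"].flag == "constant"
        assert np.isnan(s["v"].p)


class TestZscore:
    def test_hand_computed(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_idempotent_and_location_invariant(self, rng):
        x = rng.normal(3, 7, 100)
        z = zscore(x)
        np.testing.assert_allclose(zscore(z), z, atol=1e-12)
        np.testing.assert_allclose(zscore(x + 100.0), z, atol=1e-9)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0, 2.0])


class TestLogistic:
    @staticmethod
    def _sim(rng, n=1500, beta=1.0):
        z = rng.normal(size=n)
        age = rng.normal(4, 2, n)
        sex = rng.choice(["male", "female"], n)
        bmi = rng.normal(16, 2, n)
        eta = -0.3 + beta * z + 0.1 * (age - 4) - 0.05 * (bmi - 16)
        y = (rng.random(n) < expit(eta)).astype(int)
        return pd.DataFrame(
            {"y": y, "z": z, "age_onset_years": age, "sex": sex, "bmi": bmi}
        )

    def test_parameter_recovery(self, rng):
        est = [
            fit_logistic(self._sim(rng, beta=1.0), "y", "z").table.loc["z", "estimate"]
            for _ in range(20)
        ]
        assert np.mean(est) == pytest.approx(1.0, abs=0.1)

    def test_null_marker_or_near_one(self, rng):
        df = self._sim(rng, beta=0.0)
        fit = fit_logistic(df, "y", "z")
        row = fit.table.loc["z"]
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_ci_brackets_or(self, rng):
        fit = fit_logistic(self._sim(rng), "y", "z")
        t = fit.table
        assert np.all(t["ci_low"] <= t["or_"]) and np.all(t["or_"] <= t["ci_high"])
        assert np.all(t["or_"] > 0)

    def test_single_class_rejected(self):
        df = pd.DataFrame(
            {"y": [1, 1, 1, 1], "z": [0.1, 0.3, -0.2, 0.5],
             "age_onset_years": [1, 2, 3, 4], "sex": ["male"] * 2 + ["female"] * 2,
             "bmi": [15, 16, 17, 18]}
        )
        with pytest.raises(ValueError):
            fit_logistic(df, "y", "z")

    def test_separation_detected(self, rng):
        n = 40
        z = np.r_[np.linspace(-3, -1, n // 2), np.linspace(1, 3, n // 2)]
        df = pd.DataFrame(
            {"y": np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int), "z": z,
             "age_onset_years": rng.normal(3, 1, n),
             "sex": rng.choice(["male", "female"], n),
             "bmi": rng.normal(16, 1, n)}
        )
        with pytest.raises(ValueError, match="separation"):
            fit_logistic(df, "y", "z")


class TestRCS:
    def test_basis_dimension(self, rng):
        x = rng.normal(size=100)
        knots = np.percentile(x, [5, 35, 65, 95])
        assert rcs_basis(x, knots).shape == (100, 3)

    def test_linear_beyond_boundary_knots(self):
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        grid = np.linspace(5.0, 9.0, 50)  # far beyond the last knot
        basis = rcs_basis(grid, knots)
        coef = np.array([1.3, -0.7, 2.1])
        fitted = basis @ coef
        second_diff = np.diff(fitted, 2)
        assert np.max(np.abs(second_diff)) < 1e-6 * max(1.0, np.abs(fitted).max())

    def test_nonlinear_terms_vanish_at_first_knot(self):
        knots = np.array([1.0, 2.0, 3.0, 4.0])
        basis = rcs_basis(np.array([1.0, 0.5]), knots)
        np.testing.assert_allclose(basis[:, 1:], 0.0, atol=1e-12)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.arange(10.0), [1.0, 1.0, 2.0])

    def test_monotone_truth_gives_monotone_curve(self, rng):
        n = 600
        marker = rng.lognormal(0, 0.5, n)
        eta = -1.5 + 1.2 * np.log(marker)
        y = (rng.random(n) < expit(eta)).astype(int)
        df = pd.DataFrame(
            {"y": y, "m": marker,
             "age_onset_years": rng.normal(4, 1, n),
             "sex": rng.choice(["male", "female"], n),
             "bmi": rng.normal(16, 1.5, n)}
        )
        curve = rcs_dose_response(df, "y", "m")
        # fitted curve rises overall and stays inside its own CI band
        assert curve.prob[-1] > curve.prob[0]
        assert np.all(curve.ci_low <= curve.prob) and np.all(curve.prob <= curve.ci_high)
        assert np.all((curve.prob >= 0) & (curve.prob <= 1))

    def test_constant_marker_rejected(self, rng):
        df = pd.DataFrame(
            {"y": [0, 1] * 10, "m": [1.0] * 20,
             "age_onset_years": rng.normal(4, 1, 20),
             "sex": ["male", "female"] * 10, "bmi": rng.normal(16, 1, 20)}
        )
        with pytest.raises(ValueError):
            rcs_dose_response(df, "y", "m")


class TestROC:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),
            ([1, 1, 1, 1], [0, 1, 0, 1], 0.5),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert roc_auc(scores, labels).auc == pytest.approx(expected)

    def test_exhaustive_pair_counting_oracle(self):
        """AUC equals pair counting for every tied dataset up to 5 points,
        plus random 8-point datasets with ties."""
        for n in range(2, 6):
            for scores in itertools.product([0, 1, 2], repeat=n):
                for labels in itertools.product([0, 1], repeat=n):
                    if len(set(labels)) < 2:
                        continue
                    assert roc_auc(scores, labels).auc == pytest.approx(
                        auc_pair_counting(scores, labels)
                    )
        rng = np.random.default_rng(0)
        for _ in range(200):
            scores = rng.integers(0, 4, size=8)
            labels = rng.integers(0, 2, size=8)
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                auc_pair_counting(scores, labels)
            )

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        res = roc_auc(scores, labels)
        assert np.all(np.diff(res.sensitivity) >= 0)
        assert np.all(np.diff(res.specificity) <= 1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestCombinedPanel:
    def test_identical_markers_match_single(self, rng):
        x = rng.normal(size=200)
        y = (rng.random(200) < expit(x)).astype(int)
        df = pd.DataFrame({"y": y, "a": x, "b": x, "c": x})
        panel = combined_panel(df, "y", markers=("a", "b", "c"))
        single = roc_auc(x, y)
        assert panel.auc == pytest.approx(single.auc, abs=1e-9)

    def test_complementary_markers_beat_either_alone(self, rng):
        n = 800
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = (rng.random(n) < expit(1.5 * a + 1.5 * b)).astype(int)
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        panel = combined_panel(df, "y", markers=("a", "b"))
        assert panel.auc > roc_auc(a, y).auc
        assert panel.auc > roc_auc(b, y).auc

    def test_null_markers_near_chance(self, rng):
        n = 1200
        df = pd.DataFrame(
            {"y": rng.integers(0, 2, n), "a": rng.normal(size=n),
             "b": rng.normal(size=n), "c": rng.normal(size=n)}
        )
        assert combined_panel(df, "y", markers=("a", "b", "c")).auc == pytest.approx(
            0.5, abs=0.07
        )


class TestMouseStats:
    def test_group_stats_and_perfect_correlation(self, rng):
        from neuroimmune.simulate import MouseSimConfig, simulate_mouse_phenotypes

        table = simulate_mouse_phenotypes(MouseSimConfig(seed=0))
        stats = mouse_group_stats(table)
        assert stats.loc["nlr", "p"] < 1e-6  # genotypes clearly separated
        x = rng.normal(size=20)
        r, p = pearson_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_equal_means_type_i_error_controlled(self):
        from neuroimmune.simulate import MarkerParams, MouseSimConfig, simulate_mouse_phenotypes

        cfg_kw = dict(
            nlr=MarkerParams(0.4, 0.05, 0.4, 0.05),
            crp=MarkerParams(200.0, 20.0, 200.0, 20.0),
            il6=MarkerParams(100.0, 30.0, 100.0, 30.0),
            pstat3=MarkerParams(1.5, 0.2, 1.5, 0.2),
            coupling_r={"nlr": 0.3, "crp": 0.3, "il6": 0.3},
        )
        rejections = 0
        n_rep = 120
        for seed in range(n_rep):
            t = simulate_mouse_phenotypes(MouseSimConfig(seed=seed, **cfg_kw))
            if mouse_group_stats(t).loc["nlr", "p"] < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 2.5 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
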