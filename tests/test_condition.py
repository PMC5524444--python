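"""Cell aggregation, standardized regressions, BIC, ANOVA, median split."""

import math

import numpy as np
import pandas as pd
import pytest

from metaconf import (
    MODELS,
    aggregate_cells,
    anova_2x2_rm,
    bic,
    fit_condition_regression,
    logodds_error,
    median_split_subgroup,
    medium_rt_difference,
    one_sample_t,
    paired_t,
)


def _cells(conf, rt=None, err=None):
    """8-cell frame for one participant in fixed factorial order."""
    levels = [(m, v, c) for m in ("high", "low") for v in ("high", "low")
              for c in ("red", "blue")]
    rt = rt if rt is not None else [600.0] * 8
    err = err if err is not None else [0.1] * 8
    return pd.DataFrame(
        {
            "participant": 1,
            "mean_level": [m for m, v, c in levels],
            "variance_level": [v for m, v, c in levels],
            "color": [c for m, v, c in levels],
            "n": 128,
            "mean_confidence": conf,
            "mean_correct_rt": rt,
            "error_rate": err,
            "logodds_error": [logodds_error(e, 128) for e in err],
        }
    )


class TestAggregate:
    def test_balanced_session_gives_8_rows_of_128(self, session_trials):
        cells = aggregate_cells(session_trials)
        assert len(cells) == 8
        # misses excluded, so cell n is at most the designed 128
        assert (cells["n"] <= 128).all() and (cells["n"] >= 100).all()

    def test_cell_means_match_groupby_oracle(self, session_trials):
        cells = aggregate_cells(session_trials)
        kept = session_trials[~session_trials["miss"]]
        row = cells[(cells.mean_level == "low") & (cells.variance_level == "high")
                    & (cells.color == "blue")].iloc[0]
        g = kept[(kept.mean_level == "low") & (kept.variance_level == "high")
                 & (kept.color == "blue")]
        assert row["mean_confidence"] == pytest.approx(g["confidence"].mean())
        assert row["error_rate"] == pytest.approx(1 - g["accuracy"].mean())
        assert row["mean_correct_rt"] == pytest.approx(
            g.loc[g.accuracy == 1, "rt"].mean()
        )

    def test_constant_confidence_aggregates_to_that_constant(self, session_trials):
        trials = session_trials.copy()
        trials.loc[~trials["miss"], "confidence"] = 4.0
        cells = aggregate_cells(trials)
        assert (cells["mean_confidence"] == 4.0).all()

    def test_missing_cell_is_named_in_error(self, session_trials):
        broken = session_trials[
            ~((session_trials.mean_level == "high")
              & (session_trials.variance_level == "low")
              & (session_trials.color == "red"))
        ]
        with pytest.raises(ValueError, match="8 design cells"):
            aggregate_cells(broken)


class TestLogOdds:
    def test_half_rate_is_near_zero(self):
        assert logodds_error(0.5, 1_000_000) == pytest.approx(0.0, abs=1e-5)

    def test_uncorrected_value_at_moderate_rate(self):
        # ln(.119/.881) = -2.002; the continuity correction at n=10^6 is tiny
        assert logodds_error(0.119, 1_000_000) == pytest.approx(-2.002, abs=1e-3)

    def test_zero_rate_is_finite_via_correction(self):
        val = logodds_error(0.0, 128)
        assert math.isfinite(val)
        assert val == pytest.approx(math.log(0.5 / 128.5))


class TestRegression:
    def test_outcome_linear_in_accuracy_gives_unit_fit(self):
        cells = _cells(conf=[0.0] * 8,
                       err=[0.05, 0.05, 0.1, 0.1, 0.15, 0.15, 0.25, 0.25])
        cells["mean_confidence"] = -cells["logodds_error"] * 2.0 + 3.0
        res = fit_condition_regression(cells, "M0")
        assert res.r2 == pytest.approx(1.0)
        assert res.betas["accuracy"] == pytest.approx(1.0)
        assert res.bic == -math.inf

    def test_orthogonal_outcome_gives_null_fit(self):
        # color alternates within every condition: orthogonal to all predictors
        cells = _cells(conf=[4.6, 3.4, 4.6, 3.4, 4.6, 3.4, 4.6, 3.4],
                       rt=[580, 580, 600, 600, 620, 620, 660, 660],
                       err=[0.05, 0.05, 0.1, 0.1, 0.15, 0.15, 0.25, 0.25])
        res = fit_condition_regression(cells, "M3")
        assert res.r2 == pytest.approx(0.0, abs=1e-10)
        for b in res.betas.values():
            assert b == pytest.approx(0.0, abs=1e-10)

    def test_betas_match_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        cells = _cells(conf=list(3 + rng.random(8)),
                       rt=list(550 + 100 * rng.random(8)),
                       err=list(0.05 + 0.2 * rng.random(8)))
        res = fit_condition_regression(cells, "M3")
        z = lambda x: (x - x.mean()) / x.std(ddof=1)
        y = z(cells["mean_confidence"].to_numpy())
        X = np.column_stack([
            np.ones(8),
            z(-cells["logodds_error"].to_numpy()),
            z(cells["mean_correct_rt"].to_numpy()),
            z(np.where(cells["mean_level"] == "high", 1.0, -1.0)),
            z(np.where(cells["variance_level"] == "high", 1.0, -1.0)),
        ])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y  # explicit normal equations
        for got, want in zip(res.betas.values(), beta[1:]):
            assert got == pytest.approx(want, abs=1e-10)

    def test_nested_models_never_lose_r2(self, session_trials):
        cells = aggregate_cells(session_trials)
        r2 = {m: fit_condition_regression(cells, m).r2 for m in MODELS}
        assert r2["M3"] >= r2["M2a"] >= r2["M1"] >= r2["M0"] - 1e-12
        assert r2["M3"] >= r2["M2b"] >= r2["M1"] - 1e-12

    def test_standardized_betas_ignore_predictor_units(self, session_trials):
        cells = aggregate_cells(session_trials)
        res_ms = fit_condition_regression(cells, "M1")
        rescaled = cells.copy()
        rescaled["mean_correct_rt"] = rescaled["mean_correct_rt"] / 1000.0 + 7.0
        res_s = fit_condition_regression(rescaled, "M1")
        assert res_ms.betas["rt"] == pytest.approx(res_s.betas["rt"])
        assert res_ms.r2 == pytest.approx(res_s.r2)

    def test_constant_predictor_is_singular(self):
        cells = _cells(conf=[3, 4, 3, 4, 3, 4, 3, 4.0])
        with pytest.raises(ValueError, match="singular|standardized"):
            fit_condition_regression(cells, "M1")  # constant RT column

    def test_model_catalog(self):
        assert MODELS["M3"] == ("accuracy", "rt", "mean", "variance")
        with pytest.raises(ValueError, match="unknown model"):
            fit_condition_regression(_cells([1, 2, 3, 4, 5, 6, 1, 2.0]), "M9")


class TestBIC:
    def test_null_fit_with_no_predictors_scores_zero(self):
        assert bic(0.0, 8, 0) == 0.0

    def test_direct_evaluation(self):
        assert bic(0.35, 8, 1) == pytest.approx(8 * math.log(0.65) + math.log(8))
        assert bic(0.35, 8, 1) == pytest.approx(-1.37, abs=0.01)

    def test_extra_predictors_penalized_at_equal_fit(self):
        assert bic(0.4, 8, 2) > bic(0.4, 8, 1)

    def test_perfect_fit_degenerates(self):
        assert bic(1.0, 8, 4) == -math.inf


class TestSecondOrder:
    def test_t_matches_formula_oracle(self):
        x = np.array([0.2, 0.5, -0.1, 0.4, 0.3])
        t, df, p = one_sample_t(x)
        assert t == pytest.approx(x.mean() / (x.std(ddof=1) / math.sqrt(5)))
        assert df == 4

    def test_symmetric_betas_give_zero_t(self):
        t, _, p = one_sample_t([-0.4, -0.2, 0.2, 0.4])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            one_sample_t([0.3, 0.3, 0.3])

    def test_paired_t_is_t_of_differences(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([0.5, 2.5, 2, 5])
        t_pair, df, _ = paired_t(a, b)
        t_diff, _, _ = one_sample_t(a - b)
        assert t_pair == pytest.approx(t_diff)


class TestAnova:
    @staticmethod
    def _long(matrix):
        rows = []
        for i, row in enumerate(matrix):
            for (m, v), val in zip(
                [("high", "high"), ("high", "low"), ("low", "high"), ("low", "low")],
                row,
            ):
                rows.append({"participant": i, "mean_level": m,
                             "variance_level": v, "value": val})
        return pd.DataFrame(rows)

    def test_constant_outcome_gives_zero_f(self):
        res = anova_2x2_rm(self._long(np.full((4, 4), 2.5)))
        assert all(r.f == 0.0 for r in res)

    def test_pure_additive_effects_have_no_interaction(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        matrix = np.stack([
            [m + v + b for m in (0.0, 1.0) for v in (0.0, 0.5)] for b in base
        ])
        res = {r.effect: r for r in anova_2x2_rm(self._long(matrix))}
        assert res["interaction"].f == pytest.approx(0.0, abs=1e-20)
        assert res["mean"].partial_eta_sq == pytest.approx(1.0)

    def test_f_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(3)
        matrix = rng.normal(3.0, 1.0, size=(4, 4))
        res = {r.effect: r for r in anova_2x2_rm(self._long(matrix))}
        # oracle: explicit within-participant SS decomposition
        hh, hl, lh, ll = matrix.T
        n = 4
        for effect, L in [
            ("mean", (hh + hl) / 2 - (lh + ll) / 2),
            ("variance", (hh + lh) / 2 - (hl + ll) / 2),
        ]:
            ss_eff = n * L.mean() ** 2
            ss_err = ((L - L.mean()) ** 2).sum()
            f_oracle = ss_eff / (ss_err / (n - 1))
            assert res[effect].f == pytest.approx(f_oracle)
            assert res[effect].partial_eta_sq == pytest.approx(
                ss_eff / (ss_eff + ss_err)
            )
            assert res[effect].df == (1, 3)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        long = self._long(rng.normal(4.0, 0.7, size=(6, 4)))
        mine = {r.effect: r for r in anova_2x2_rm(long)}
        ref = pg.rm_anova(data=long, dv="value", subject="participant",
                          within=["mean_level", "variance_level"], detailed=True)
        for effect, label in [("mean", "mean_level"), ("variance", "variance_level"),
                              ("interaction", "mean_level * variance_level")]:
            row = ref[ref["Source"] == label].iloc[0]
            assert mine[effect].f == pytest.approx(row["F"], rel=1e-6)
            assert mine[effect].p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_missing_cell_rejected(self):
        bad = self._long(np.ones((3, 4))).iloc[:-1]
        with pytest.raises(ValueError, match="complete"):
            anova_2x2_rm(bad)


class TestMedianSplit:
    def test_twenty_participants_split_into_ten(self):
        stats = pd.Series(np.linspace(5, 80, 20), index=range(1, 21))
        assert len(median_split_subgroup(stats)) == 10

    def test_membership_matches_sort_and_halve_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.random(11)
        stats = pd.Series(vals, index=[f"p{i}" for i in range(11)])
        got = median_split_subgroup(stats)
        oracle = list(stats.sort_values(kind="stable").index[:6])
        assert got == oracle

    def test_all_equal_ties_break_by_stable_order(self):
        stats = pd.Series([1.0] * 6, index=list("abcdef"))
        assert median_split_subgroup(stats) == ["a", "b", "c"]

    def test_medium_rt_difference_uses_medium_cells_only(self, session_trials):
        diff = medium_rt_difference(session_trials)
        kept = session_trials[(~session_trials.miss) & (session_trials.accuracy == 1)]
        hh = kept[(kept.mean_level == "high") & (kept.variance_level == "high")].rt.mean()
        ll = kept[(kept.mean_level == "low") & (kept.variance_level == "low")].rt.mean()
        assert diff.loc[1] == pytest.approx(abs(hh - ll))
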