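"""Substitution, extrapolation and bootstrap behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latewave.cohort import InviteeTable, VariableSchema, WaveShares
from latewave.estimators import (
    EstimationError,
    SubstitutionInput,
    bootstrap_ci,
    bootstrap_estimates,
    cumulative_points,
    cumulative_points_from_groups,
    estimate_table,
    extrapolation_estimate,
    fit_extrapolation,
    participant_baseline,
    point_estimate,
    population_truth,
    substitution_estimate,
    substitution_from_table,
)
from latewave.summaries import group_mean
from latewave.synthetic import generate_population, scenario_preset


def _ols_oracle(x, y):
    """Closed-form normal equations: b = Sxy/Sxx, a = ybar - b*xbar."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    b = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return ym - b * xm, b


class TestSubstitution:
    def test_matches_weighted_sum_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = tuple(int(c) for c in rng.integers(1, 500, size=4))
            vals = tuple(rng.normal(size=3))
            est = substitution_estimate(SubstitutionInput(WaveShares(counts), vals))
            w = np.array(counts) / sum(counts)
            oracle = w[0] * vals[0] + w[1] * vals[1] + w[2] * vals[2] + w[3] * vals[2]
            assert est.estimate == float(oracle)

    def test_two_wave_hand_arithmetic(self):
        shares = WaveShares((2, 1, 1))  # 0.5 / 0.25 / 0.25
        est = substitution_estimate(SubstitutionInput(shares, (0.2, 0.4)))
        assert est.estimate == pytest.approx(0.5 * 0.2 + 0.5 * 0.4)

    @given(
        counts=st.lists(st.integers(1, 1000), min_size=2, max_size=5),
        raw=st.lists(st.floats(-10, 10), min_size=4, max_size=4),
    )
    @settings(max_examples=200, deadline=None)
    def test_convex_combination_of_group_values(self, counts, raw):
        k = len(counts) - 1
        vals = tuple(raw[:k])
        est = substitution_estimate(SubstitutionInput(WaveShares(tuple(counts)), vals))
        assert min(vals) - 1e-12 <= est.estimate <= max(vals) + 1e-12

    def test_constant_values_recovered_regardless_of_shares(self):
        est = substitution_estimate(
            SubstitutionInput(WaveShares((5495, 970, 402, 7197)), (0.37, 0.37, 0.37))
        )
        assert est.estimate == pytest.approx(0.37)

    def test_empty_declared_wave_errors(self):
        with pytest.raises(EstimationError, match="empty"):
            substitution_estimate(
                SubstitutionInput(WaveShares((10, 0, 5)), (0.1, 0.2))
            )

    def test_true_nonparticipant_value_conserves_population_mean(self, strokestop_cohort):
        # supplying the observed non-participant value makes the identity exact
        _, table, _ = strokestop_cohort
        yn = group_mean(table, "immigrant", "nonparticipant").estimate
        est = substitution_from_table(table, "immigrant", nonparticipant_value=yn)
        truth = population_truth(table, "immigrant")
        assert est.estimate == pytest.approx(truth.estimate, abs=1e-12)

    def test_wald_option_attaches_interval(self, strokestop_cohort):
        _, table, _ = strokestop_cohort
        est = substitution_from_table(table, "immigrant", ci="wald")
        assert est.se > 0
        assert est.ci_low < est.estimate < est.ci_high


class TestExtrapolation:
    def test_two_points_equal_interpolation_extended_to_one(self):
        pts = cumulative_points_from_groups([10, 10], [0.2, 0.4], 40)
        fit = fit_extrapolation(pts)
        (x1, y1), (x2, y2) = (pts[0].x, pts[0].y), (pts[1].x, pts[1].y)
        closed = y2 + (y2 - y1) / (x2 - x1) * (1 - x2)
        assert fit.predicted_at_1 == pytest.approx(closed, abs=1e-14)
        assert fit.residuals == pytest.approx((0.0, 0.0), abs=1e-15)

    def test_ols_matches_normal_equations(self):
        # cumulative-share-like instances: distinct x with decent separation
        rng = np.random.default_rng(1)
        grid = np.arange(1, 100, 2) / 100.0
        for _ in range(100):
            m = rng.integers(2, 6)
            x = np.sort(rng.choice(grid, size=m, replace=False))
            y = rng.uniform(0, 1, size=m)
            fit = fit_extrapolation(
                [type("P", (), {"x": xi, "y": yi, "n": 1})() for xi, yi in zip(x, y)]
            )
            a, b = _ols_oracle(x, y)
            assert abs(fit.intercept - a) <= 1e-12 * max(1.0, abs(a))
            assert abs(fit.slope - b) <= 1e-12 * max(1.0, abs(b))

    def test_flat_points_give_zero_slope(self):
        pts = cumulative_points_from_groups([5, 5, 5], [0.3, 0.3, 0.3], 30)
        fit = fit_extrapolation(pts)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.predicted_at_1 == pytest.approx(0.3)

    def test_reported_two_point_fit(self):
        # primary education in the stool-test arm: line through the two
        # cumulative points predicts 0.18 at full participation
        fit = fit_extrapolation(
            cumulative_points_from_groups([23036, 5786], [0.15, 0.17], 60100)
        )
        assert round(fit.predicted_at_1, 2) == 0.18

    def test_fewer_than_two_points_errors(self):
        with pytest.raises(EstimationError, match="2"):
            fit_extrapolation(cumulative_points_from_groups([10], [0.2], 20))

    def test_tied_shares_error(self):
        pts = cumulative_points_from_groups([10, 10], [0.2, 0.4], 40)
        broken = [pts[0], type(pts[0])(x=pts[0].x, y=0.4, n=20)]
        with pytest.raises(EstimationError, match="tied"):
            fit_extrapolation(broken)

    def test_out_of_range_proportion_flagged_not_clipped(self):
        df = pd.DataFrame(
            {
                "id": range(40),
                "wave": ["wave_0"] * 10 + ["wave_1"] * 10 + ["nonparticipant"] * 20,
                "y": [0.0] * 5 + [1.0] * 5 + [1.0] * 10 + [0.0] * 20,
            }
        )
        table = InviteeTable(df, [VariableSchema("y", "binary")], 2)
        est = extrapolation_estimate(table, "y")
        assert est.estimate > 1.0
        assert est.out_of_range


class TestCumulativePoints:
    def test_x_increasing_and_last_y_equals_baseline(self, strokestop_cohort):
        _, table, _ = strokestop_cohort
        pts = cumulative_points(table, "immigrant")
        xs = [p.x for p in pts]
        assert xs == sorted(xs) and len(set(xs)) == len(xs)
        assert pts[-1].y == pytest.approx(
            participant_baseline(table, "immigrant").estimate, abs=1e-14
        )

    def test_printed_group_values_give_expected_cumulative_sequence(self):
        pts = cumulative_points_from_groups([5495, 970, 402], [0.16, 0.19, 0.22], 14064)
        assert [round(p.x, 3) for p in pts] == [0.391, 0.460, 0.488]
        assert pts[1].y == pytest.approx((5495 * 0.16 + 970 * 0.19) / 6465)
        assert pts[2].y == pytest.approx((5495 * 0.16 + 970 * 0.19 + 402 * 0.22) / 6867)

    def test_missing_entire_wave_errors(self, strokestop_cohort):
        _, table, _ = strokestop_cohort
        df = table.data.copy()
        df.loc[df["wave"] == "wave_2", "immigrant"] = np.nan
        broken = InviteeTable(df, table.schema, table.n_waves)
        with pytest.raises(EstimationError, match="wave 2"):
            cumulative_points(broken, "immigrant")

    def test_participant_baseline_pools_waves(self):
        df = pd.DataFrame(
            {
                "id": range(25),
                "wave": ["wave_0"] * 10 + ["wave_1"] * 10 + ["nonparticipant"] * 5,
                "y": [1.0] * 3 + [0.0] * 7 + [1.0] * 1 + [0.0] * 9 + [0.0] * 5,
            }
        )
        table = InviteeTable(df, [VariableSchema("y", "binary")], 2)
        assert participant_baseline(table, "y").estimate == pytest.approx(4 / 20)


class TestBootstrap:
    def test_same_seed_is_bit_identical(self, strokestop_cohort):
        _, table, _ = strokestop_cohort
        a = bootstrap_ci(table, "immigrant", "substitution", B=50, seed=11)
        b = bootstrap_ci(table, "immigrant", "substitution", B=50, seed=11)
        assert (a.estimate, a.ci_low, a.ci_high) == (b.estimate, b.ci_low, b.ci_high)

    def test_zero_variance_variable_zero_width_ci(self):
        df = pd.DataFrame(
            {"id": range(20), "wave": ["wave_0"] * 10 + ["nonparticipant"] * 10,
             "y": [1.0] * 10 + [0.0] * 10}
        )
        table = InviteeTable(df, [VariableSchema("y", "binary")], 1)
        est = bootstrap_ci(table, "y", "participants", B=50, seed=0)
        assert est.ci_low == est.ci_high == est.estimate == 1.0

    def test_engine_point_estimates_match_public_estimators(self, strokestop_cohort):
        # the vectorised closed-form path and the polyfit/group-mean path
        # must agree on the original sample
        _, table, _ = strokestop_cohort
        res = bootstrap_estimates(table, ["immigrant", "charlson"], B=2, seed=0)
        for var in ("immigrant", "charlson"):
            for method in ("participants", "substitution", "extrapolation"):
                direct = point_estimate(table, var, method)
                assert res[(var, method)].estimate == pytest.approx(
                    direct.estimate, abs=1e-12
                )

    def test_percentile_and_stratified_options_run(self, strokestop_cohort):
        _, table, _ = strokestop_cohort
        est = bootstrap_ci(
            table, "immigrant", "substitution", B=50, seed=3,
            stratified=True, interval="percentile",
        )
        assert est.ci_low < est.estimate < est.ci_high

    def test_bootstrap_se_matches_monte_carlo_sd(self):
        # substitution on a 10,000-invitee cohort: the bootstrap SE from
        # one cohort should approximate the empirical SD of the estimator
        # over independent cohort draws
        cfg = scenario_preset("linear_in_cumshare", n_invited=10_000)
        draws = []
        for rep in range(500):
            table, _ = generate_population(cfg, seed=1000 + rep)
            draws.append(substitution_from_table(table, "risk_score").estimate)
        empirical_sd = np.std(draws, ddof=1)
        table, _ = generate_population(cfg, seed=1000)
        est = bootstrap_ci(table, "risk_score", "substitution", B=1000, seed=5)
        assert est.se == pytest.approx(empirical_sd, rel=0.15)

    def test_too_small_b_errors(self, strokestop_cohort):
        _, table, _ = strokestop_cohort
        with pytest.raises(EstimationError, match="B >= 2"):
            bootstrap_ci(table, "immigrant", "substitution", B=1, seed=0)


class TestEstimateTable:
    def test_truth_rows_only_where_observable(self, strokestop_cohort):
        _, table, _ = strokestop_cohort
        frame = estimate_table(table, ["immigrant", "systolic_bp"])
        imm = frame.query("variable == 'immigrant'")["method"].tolist()
        bp = frame.query("variable == 'systolic_bp'")["method"].tolist()
        assert "true_population" in imm
        assert "true_population" not in bp
        assert {"participants", "substitution", "extrapolation"} <= set(bp)
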