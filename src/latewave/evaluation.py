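"""Repeated-cohort simulation studies of the population estimators.

Measures, per variable and estimator, the mean bias, RMSE, bootstrap-CI
coverage and mean CI width over independently generated cohorts, each
aggregate with its own Monte-Carlo standard error.  Also operationalizes
the qualitative "did the method improve representativity?" judgement as
an absolute-error comparison against the unadjusted participant
baseline, with ties broken conservatively in the baseline's favour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import METHODS, PopulationEstimate, bootstrap_estimates, point_estimate
from .synthetic import ScenarioConfig, ScenarioError, analytic_truth, generate_population

#: cohort size of the fallback truth reference when no closed form exists
MEGA_COHORT_N = 1_000_000


class EvaluationError(RuntimeError):
    """Simulation could not produce usable aggregates."""


@dataclass
class SimulationResult:
    """Replicate-level results and their aggregates for one scenario."""

    scenario: str
    n_reps: int
    truth: dict[str, float]
    replicates: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        """Long-format export: scenario, variable, method, metric, value, mc_se."""
        self.summary.to_csv(path, index=False, float_format="%.10g")


def _truth_for(config: ScenarioConfig, variable: str, seed_seq: np.random.SeedSequence) -> float:
    try:
        return analytic_truth(config, variable)
    except ScenarioError:
        # no closed form / quadrature: pre-masking mean of one mega-cohort
        from dataclasses import replace

        big = replace(config, n_invited=MEGA_COHORT_N)
        _, gt = generate_population(big, seed=np.random.default_rng(seed_seq))
        return gt.values[variable]


def run_simulation(
    config: ScenarioConfig,
    n_reps: int,
    B: int = 0,
    seed: int = 0,
    methods: Sequence[str] = METHODS,
) -> SimulationResult:
    """Generate ``n_reps`` cohorts and score every estimator against truth.

    ``B = 0`` skips the bootstrap (bias/RMSE only, no coverage).  Each
    replicate gets its own child seed spawned from ``seed``, so the
    replicate stream is reproducible and a shorter run with the same seed
    is a prefix of a longer one.  An estimator failing in a replicate is
    recorded, not fatal, unless more than half its replicates fail.
    """
    if n_reps < 2:
        raise EvaluationError("need n_reps >= 2")
    root = np.random.SeedSequence(seed)
    truth_seq = root.spawn(1)[0]
    variables = [v.name for v in config.variables]
    truth = {v: _truth_for(config, v, truth_seq) for v in variables}
    rows = []
    for rep, child in enumerate(root.spawn(n_reps + 1)[1:]):
        rng = np.random.default_rng(child)
        table, _ = generate_population(config, seed=rng)
        if B:
            ests = bootstrap_estimates(table, variables, B=B, seed=rng, methods=methods)
        else:
            ests = {}
            for v in variables:
                for m in methods:
                    try:
                        ests[(v, m)] = point_estimate(table, v, m)
                    except Exception:
                        ests[(v, m)] = PopulationEstimate(
                            method=m, variable=v, estimate=float("nan")
                        )
        for v in variables:
            for m in methods:
                e = ests[(v, m)]
                failed = not np.isfinite(e.estimate) or (B > 0 and e.ci_low is None)
                rows.append(
                    {
                        "rep": rep,
                        "variable": v,
                        "method": m,
                        "estimate": e.estimate,
                        "error": e.estimate - truth[v],
                        "covered": (
                            np.nan
                            if failed or not B
                            else float(e.ci_low <= truth[v] <= e.ci_high)
                        ),
                        "ci_width": (
                            np.nan if failed or not B else e.ci_high - e.ci_low
                        ),
                        "failed": failed,
                    }
                )
    reps = pd.DataFrame(rows)
    summary = _aggregate(reps, config.name, with_ci=B > 0)
    fail = summary.query("metric == 'failure_rate' and value > 0.5")
    if len(fail):
        raise EvaluationError(
            f"estimator failed in >50% of replicates: {fail['method'].tolist()}"
        )
    return SimulationResult(
        scenario=config.name, n_reps=n_reps, truth=truth, replicates=reps, summary=summary
    )


def _aggregate(reps: pd.DataFrame, scenario: str, with_ci: bool) -> pd.DataFrame:
    rows = []
    for (v, m), grp in reps.groupby(["variable", "method"], sort=True):
        R = len(grp)
        ok = grp.loc[~grp["failed"]]
        err = ok["error"].to_numpy()
        r = len(err)

        def add(metric: str, value: float, mc_se: float) -> None:
            rows.append(
                {
                    "scenario": scenario,
                    "variable": v,
                    "method": m,
                    "metric": metric,
                    "value": value,
                    "mc_se": mc_se,
                }
            )

        if r:
            add("bias", float(err.mean()), float(err.std(ddof=1) / np.sqrt(r)) if r > 1 else np.nan)
            rmse = float(np.sqrt((err**2).mean()))
            # delta method: Var(rmse) ~ Var(mean(err^2)) / (4 * mse)
            mc = (
                float((err**2).std(ddof=1) / np.sqrt(r) / (2 * rmse))
                if r > 1 and rmse > 0
                else 0.0 if rmse == 0 else np.nan
            )
            add("rmse", rmse, mc)
        if with_ci and r:
            cov = ok["covered"].to_numpy(dtype=float)
            c = float(np.nanmean(cov))
            add("coverage", c, float(np.sqrt(c * (1 - c) / r)))
            w = ok["ci_width"].to_numpy(dtype=float)
            add(
                "ci_width",
                float(np.nanmean(w)),
                float(np.nanstd(w, ddof=1) / np.sqrt(r)) if r > 1 else np.nan,
            )
        f = float(grp["failed"].mean())
        add("failure_rate", f, float(np.sqrt(f * (1 - f) / R)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# accuracy ranking


@dataclass(frozen=True)
class AccuracyRanking:
    """Absolute errors of each method against a known truth.

    ``winner`` is the method with the smallest absolute error; an exact
    tie involving the participant baseline goes to the baseline, so a
    method is only credited as an improvement when strictly better.
    """

    truth: float
    errors: dict[str, float]
    winner: str
    improved_over_baseline: dict[str, bool]


BASELINE = "participants"


def accuracy_comparison(
    estimates: Sequence[PopulationEstimate], truth: float
) -> AccuracyRanking:
    """Rank estimates by absolute error against the true population value."""
    if not estimates:
        raise EvaluationError("no estimates to compare")
    if not np.isfinite(truth):
        raise EvaluationError("truth must be finite")
    errors = {e.method: abs(e.estimate - truth) for e in estimates}
    best = min(errors.values())
    if BASELINE in errors and errors[BASELINE] == best:
        winner = BASELINE
    else:
        winner = next(m for m, v in errors.items() if v == best)
    improved = {
        m: (BASELINE in errors and v < errors[BASELINE])
        for m, v in errors.items()
        if m != BASELINE
    }
    return AccuracyRanking(
        truth=float(truth), errors=errors, winner=winner, improved_over_baseline=improved
    )
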