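"""Full-population estimators under the continuum-of-resistance model.

Three estimators of a characteristic's mean (or proportion) in the full
invited population, using participant data only:

``participants``
    The unadjusted pooled participant value — the naive baseline.

``substitution``
    Writes the population mean as the share-weighted average of its
    wave-specific components,

        y_pop = a*y_a + b*y_b + c*y_c + (1 - a - b - c)*y_n,

    where a, b, c are the population shares of the participant waves and
    y_n, the unobserved non-participant value, is replaced by the value
    of the wave least prone to participate (the last reminder wave).
    The estimate is a convex combination of the supplied group values,
    so it always lies between their minimum and maximum; if the true
    non-participant value is supplied instead of the stand-in, the
    identity returns the exact full-population mean.

``extrapolation``
    Regresses the *cumulative* participant mean on the *cumulative*
    participation share — one point per wave, point k pooling waves
    0..k — by unweighted ordinary least squares, and predicts at a
    hypothetical cumulative share of 1 (full participation).  With two
    points this is the interpolating line extended to x = 1.  No
    covariates enter the regression.

Uncertainty comes from nonparametrically bootstrapping the entire
procedure: resample invited individuals with replacement, re-estimate
wave shares, wave values and the estimator itself per replicate, and
form a normal interval around the original point estimate using the
bootstrap standard deviation.  Percentile intervals and within-wave
stratified resampling are available as clearly non-default options.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import InviteeTable, WaveShares, wave_counts
from .summaries import PARTICIPANTS, POPULATION, Z975, group_mean

METHODS = ("participants", "substitution", "extrapolation")


class EstimationError(ValueError):
    """Undefined estimator on the given inputs (empty wave, tied shares, ...)."""


# ---------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SubstitutionInput:
    """Wave shares plus wave-specific values feeding the substitution identity.

    ``nonparticipant_value`` is the assigned stand-in; when ``None`` the
    last participant wave's value is used (the default analysis choice).
    """

    shares: WaveShares
    wave_values: tuple[float, ...]
    nonparticipant_value: float | None = None

    def __post_init__(self) -> None:
        if len(self.wave_values) != self.shares.n_waves:
            raise EstimationError(
                f"{len(self.wave_values)} wave values for {self.shares.n_waves} waves"
            )
        object.__setattr__(self, "wave_values", tuple(float(v) for v in self.wave_values))


@dataclass(frozen=True)
class CumulativePoint:
    """A (cumulative participation share, cumulative mean) pair.

    ``x`` counts all invitees through wave k over the full invited
    population; ``y`` averages the non-missing values among those
    participants; ``n`` is the cumulative participant count.
    """

    x: float
    y: float
    n: int


@dataclass(frozen=True)
class ExtrapolationFit:
    """OLS line through cumulative points and its prediction at x = 1."""

    intercept: float
    slope: float
    points: tuple[CumulativePoint, ...]
    predicted_at_1: float
    residuals: tuple[float, ...]


@dataclass(frozen=True)
class PopulationEstimate:
    """A method-labelled estimate for the full invited population."""

    method: str
    variable: str
    estimate: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    out_of_range: bool = False
    n_bootstrap: int | None = None
    failed_replicates: int = 0


# ---------------------------------------------------------------------
# point estimators


def participant_baseline(table: InviteeTable, variable: str) -> PopulationEstimate:
    """Pooled participant mean/proportion with a Wald CI (the naive baseline)."""
    cell = group_mean(table, variable, PARTICIPANTS)
    return PopulationEstimate(
        method="participants",
        variable=variable,
        estimate=cell.estimate,
        se=cell.se,
        ci_low=cell.ci_low,
        ci_high=cell.ci_high,
    )


def substitution_estimate(
    inp: SubstitutionInput, variable: str = ""
) -> PopulationEstimate:
    """Share-weighted population value with the stand-in for non-participants."""
    counts = inp.shares.counts
    if any(c == 0 for c in counts[:-1]):
        raise EstimationError("a declared participant wave is empty; value undefined")
    yn = (
        inp.nonparticipant_value
        if inp.nonparticipant_value is not None
        else inp.wave_values[-1]
    )
    w = inp.shares.shares
    # plain left-to-right accumulation: bit-identical to the written-out sum
    est = 0.0
    for wk, vk in zip(w[:-1], inp.wave_values):
        est += wk * vk
    est += w[-1] * float(yn)
    return PopulationEstimate(method="substitution", variable=variable, estimate=est)


def substitution_from_table(
    table: InviteeTable,
    variable: str,
    nonparticipant_value: float | None = None,
    ci: str = "none",
) -> PopulationEstimate:
    """Substitution estimate computed from an invitee table.

    ``ci="wald"`` attaches an approximate fixed-share delta interval
    Var = sum(w_k^2 se_k^2) with the last wave carrying the combined
    weight of its own share and the non-participant share; shares are
    treated as known.  The bootstrap (see :func:`bootstrap_ci`) is the
    primary interval and accounts for share estimation as well.
    """
    shares = wave_counts(table)
    from .cohort import wave_labels

    cells = [
        group_mean(table, variable, lab) for lab in wave_labels(table.n_waves)[:-1]
    ]
    inp = SubstitutionInput(
        shares=shares,
        wave_values=tuple(c.estimate for c in cells),
        nonparticipant_value=nonparticipant_value,
    )
    est = substitution_estimate(inp, variable=variable)
    if ci == "none":
        return est
    if ci != "wald":
        raise EstimationError(f"unknown ci option {ci!r}")
    w = shares.shares.copy()
    if nonparticipant_value is None:
        w[-2] += w[-1]  # stand-in wave absorbs the non-participant weight
        w[-1] = 0.0
    var = sum(wk**2 * c.se**2 for wk, c in zip(w[:-1], cells))
    se = float(np.sqrt(var))
    return dataclasses.replace(
        est, se=se, ci_low=est.estimate - Z975 * se, ci_high=est.estimate + Z975 * se
    )


def cumulative_points_from_groups(
    counts: Sequence[int], values: Sequence[float], total: int
) -> list[CumulativePoint]:
    """Cumulative points from per-wave group sizes and group values.

    This is the bridge from a printed characteristics table (group n's
    and group means) to the extrapolation model's inputs.
    """
    if len(counts) != len(values):
        raise EstimationError("counts and values must align")
    counts = np.asarray(counts, dtype=float)
    values = np.asarray(values, dtype=float)
    cum_n = counts.cumsum()
    cum_y = (counts * values).cumsum() / cum_n
    return [
        CumulativePoint(x=float(cn / total), y=float(cy), n=int(cn))
        for cn, cy in zip(cum_n, cum_y)
    ]


def cumulative_points(table: InviteeTable, variable: str) -> list[CumulativePoint]:
    """One cumulative point per participant wave, pooled from wave 0 through k.

    The share denominator is the full invited count; the mean uses
    non-missing values only.  The last point's y equals the pooled
    participant baseline by construction.
    """
    codes = table.wave_codes()
    values = table.numeric_values(variable)
    K = table.n_waves
    finite = np.isfinite(values)
    pts: list[CumulativePoint] = []
    cum_n = cum_m = 0
    cum_sum = 0.0
    for k in range(K):
        in_wave = codes == k
        m = int((in_wave & finite).sum())
        if m == 0:
            raise EstimationError(f"variable {variable!r} entirely missing in wave {k}")
        cum_n += int(in_wave.sum())
        cum_m += m
        cum_sum += float(values[in_wave & finite].sum())
        pts.append(CumulativePoint(x=cum_n / table.n, y=cum_sum / cum_m, n=cum_n))
    return pts


def fit_extrapolation(points: Sequence[CumulativePoint]) -> ExtrapolationFit:
    """Unweighted OLS of cumulative mean on cumulative share.

    With exactly two points the fit is the interpolating line and the
    residuals are zero.
    """
    if len(points) < 2:
        raise EstimationError("extrapolation needs at least 2 cumulative points")
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    if np.unique(x).size < len(points):
        raise EstimationError("tied cumulative shares; line undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return ExtrapolationFit(
        intercept=float(intercept),
        slope=float(slope),
        points=tuple(points),
        predicted_at_1=float(intercept + slope),
        residuals=tuple(float(r) for r in resid),
    )


def extrapolation_estimate(table: InviteeTable, variable: str) -> PopulationEstimate:
    """Extrapolation prediction at cumulative share 1 for one variable.

    A proportion prediction outside [0, 1] is reported unclipped with
    ``out_of_range`` set — extrapolation can and does leave the unit
    interval.
    """
    fit = fit_extrapolation(cumulative_points(table, variable))
    est = fit.predicted_at_1
    oor = table.is_proportion(variable) and not (0.0 <= est <= 1.0)
    return PopulationEstimate(
        method="extrapolation", variable=variable, estimate=est, out_of_range=oor
    )


def population_truth(table: InviteeTable, variable: str) -> PopulationEstimate:
    """Observed full-invited-population value (needs non-participant data)."""
    cell = group_mean(table, variable, POPULATION)
    return PopulationEstimate(
        method="true_population",
        variable=variable,
        estimate=cell.estimate,
        se=cell.se,
        ci_low=cell.ci_low,
        ci_high=cell.ci_high,
    )


def point_estimate(table: InviteeTable, variable: str, method: str) -> PopulationEstimate:
    """Dispatch a single point estimator by method label."""
    if method == "participants":
        return participant_baseline(table, variable)
    if method == "substitution":
        return substitution_from_table(table, variable)
    if method == "extrapolation":
        return extrapolation_estimate(table, variable)
    raise EstimationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------
# vectorised wave statistics (shared by point path and bootstrap)


def _wave_stat_arrays(
    table: InviteeTable, variables: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """(codes, values (V,n), finite mask, K) for the resampling engine."""
    codes = table.wave_codes()
    vals = np.stack([table.numeric_values(v) for v in variables])
    return codes, vals, np.isfinite(vals), table.n_waves


def _original_stats(
    codes: np.ndarray, values: np.ndarray, finite: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    G = K + 1
    counts = np.bincount(codes, minlength=G).astype(float)[None, :]
    V = values.shape[0]
    nonmiss = np.empty((V, 1, G))
    sums = np.empty((V, 1, G))
    zeroed = np.where(finite, values, 0.0)
    for j in range(V):
        nonmiss[j, 0] = np.bincount(codes, weights=finite[j].astype(float), minlength=G)
        sums[j, 0] = np.bincount(codes, weights=zeroed[j], minlength=G)
    return counts, nonmiss, sums


def _resampled_stats(
    codes: np.ndarray,
    values: np.ndarray,
    finite: np.ndarray,
    K: int,
    B: int,
    rng: np.random.Generator,
    stratified: bool = False,
    max_draws: int = 4_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-replicate wave counts, non-missing counts and value sums.

    Resamples individuals with replacement (the whole invited cohort by
    default, within each wave group when ``stratified``), in blocks of at
    most ``max_draws`` index draws to bound memory.
    """
    n = codes.size
    G = K + 1
    V = values.shape[0]
    counts = np.empty((B, G))
    nonmiss = np.empty((V, B, G))
    sums = np.empty((V, B, G))
    zeroed = np.where(finite, values, 0.0)
    fmask = finite.astype(float)
    block = max(1, max_draws // max(n, 1))
    group_members = (
        [np.flatnonzero(codes == g) for g in range(G)] if stratified else None
    )
    for start in range(0, B, block):
        b = min(block, B - start)
        if group_members is None:
            idx = rng.integers(0, n, size=(b, n))
        else:
            idx = np.empty((b, n), dtype=np.int64)
            pos = 0
            for members in group_members:
                m = members.size
                if m:
                    idx[:, pos : pos + m] = members[rng.integers(0, m, size=(b, m))]
                    pos += m
        flat = (codes[idx] + (np.arange(b) * G)[:, None]).ravel()
        L = b * G
        counts[start : start + b] = np.bincount(flat, minlength=L).reshape(b, G)
        for j in range(V):
            nonmiss[j, start : start + b] = np.bincount(
                flat, weights=fmask[j][idx].ravel(), minlength=L
            ).reshape(b, G)
            sums[j, start : start + b] = np.bincount(
                flat, weights=zeroed[j][idx].ravel(), minlength=L
            ).reshape(b, G)
    return counts, nonmiss, sums


def _estimates_from_stats(
    counts: np.ndarray,
    nonmiss: np.ndarray,
    sums: np.ndarray,
    K: int,
    methods: Sequence[str],
) -> dict[str, np.ndarray]:
    """Apply the estimators to (B, K+1) wave statistics; NaN marks failures.

    The OLS step uses the closed-form normal equations (b = Sxy/Sxx,
    a = ybar - b*xbar), vectorised over replicates; it is exercised
    against :func:`fit_extrapolation` in the test suite.
    """
    n_tot = counts.sum(axis=1)  # (B,)
    out: dict[str, np.ndarray] = {}  # each (V, B)
    with np.errstate(invalid="ignore", divide="ignore"):
        wave_means = sums[:, :, :K] / nonmiss[:, :, :K]  # (V, B, K)
        ok = (nonmiss[:, :, :K] > 0).all(axis=2) & (counts[:, :K] > 0).all(axis=1)[None, :]
        if "participants" in methods:
            pn = nonmiss[:, :, :K].sum(axis=2)
            est = sums[:, :, :K].sum(axis=2) / pn
            out["participants"] = np.where(pn > 0, est, np.nan)
        if "substitution" in methods:
            shares = counts / n_tot[:, None]  # (B, G)
            est = (shares[None, :, :K] * wave_means).sum(axis=2)
            est += shares[None, :, K] * wave_means[:, :, K - 1]
            out["substitution"] = np.where(ok, est, np.nan)
        if "extrapolation" in methods:
            if K < 2:
                out["extrapolation"] = np.full(nonmiss.shape[:2], np.nan)
            else:
                x = counts[:, :K].cumsum(axis=1) / n_tot[:, None]  # (B, K)
                y = sums[:, :, :K].cumsum(axis=2) / nonmiss[:, :, :K].cumsum(axis=2)
                xm = x.mean(axis=1)  # (B,)
                ym = y.mean(axis=2)  # (V, B)
                dx = x - xm[:, None]
                sxx = (dx * dx).sum(axis=1)  # (B,)
                sxy = (dx[None, :, :] * (y - ym[:, :, None])).sum(axis=2)  # (V, B)
                slope = sxy / sxx[None, :]
                est = ym + slope * (1.0 - xm[None, :])
                out["extrapolation"] = np.where(ok & (sxx > 0)[None, :], est, np.nan)
    return out


# ---------------------------------------------------------------------
# bootstrap


def bootstrap_estimates(
    table: InviteeTable,
    variables: Sequence[str],
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    methods: Sequence[str] = METHODS,
    stratified: bool = False,
    interval: str = "normal",
) -> dict[tuple[str, str], PopulationEstimate]:
    """Bootstrap the entire procedure for several variables at once.

    All variables and methods share the same B resamples of the invited
    cohort, so the replicates reflect a coherent re-run of the whole
    analysis.  Returns ``{(variable, method): PopulationEstimate}``;
    replicates where an estimator is undefined (e.g. an empty wave) are
    dropped and counted as failures.  Deterministic given
    (table, B, seed).
    """
    if B < 2:
        raise EstimationError("need B >= 2 bootstrap replicates")
    if interval not in ("normal", "percentile"):
        raise EstimationError(f"unknown interval type {interval!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes, vals, finite, K = _wave_stat_arrays(table, variables)
    point = _estimates_from_stats(*_original_stats(codes, vals, finite, K), K, methods)
    boot = _estimates_from_stats(
        *_resampled_stats(codes, vals, finite, K, B, rng, stratified=stratified),
        K,
        methods,
    )
    out: dict[tuple[str, str], PopulationEstimate] = {}
    for j, variable in enumerate(variables):
        prop = table.is_proportion(variable)
        for method in methods:
            est = float(point[method][j, 0])
            reps = boot[method][j]
            failed = int(np.isnan(reps).sum())
            good = reps[np.isfinite(reps)]
            if np.isnan(est) or failed > B // 2:
                out[(variable, method)] = PopulationEstimate(
                    method=method,
                    variable=variable,
                    estimate=est,
                    n_bootstrap=B,
                    failed_replicates=failed,
                )
                continue
            if interval == "normal":
                se = float(good.std(ddof=1)) if good.size > 1 else float("nan")
                lo, hi = est - Z975 * se, est + Z975 * se
            else:
                se = float(good.std(ddof=1)) if good.size > 1 else float("nan")
                lo, hi = (float(q) for q in np.percentile(good, [2.5, 97.5]))
            out[(variable, method)] = PopulationEstimate(
                method=method,
                variable=variable,
                estimate=est,
                se=se,
                ci_low=lo,
                ci_high=hi,
                out_of_range=prop and not (0.0 <= est <= 1.0),
                n_bootstrap=B,
                failed_replicates=failed,
            )
    return out


def bootstrap_ci(
    table: InviteeTable,
    variable: str,
    method: str,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    stratified: bool = False,
    interval: str = "normal",
) -> PopulationEstimate:
    """Bootstrap CI for one estimator on one variable.

    Normal-based by default: point estimate on the original data plus or
    minus z * SD of the bootstrap replicates.  Raises when the point
    estimator is undefined on the original data or more than half the
    replicates fail.
    """
    if method not in METHODS:
        raise EstimationError(f"unknown method {method!r}")
    res = bootstrap_estimates(
        table, [variable], B=B, seed=seed, methods=[method],
        stratified=stratified, interval=interval,
    )[(variable, method)]
    if np.isnan(res.estimate):
        raise EstimationError(f"{method} undefined on the original data for {variable!r}")
    if res.ci_low is None:
        raise EstimationError(
            f"{res.failed_replicates}/{B} bootstrap replicates failed for "
            f"{method} on {variable!r}"
        )
    return res


# ---------------------------------------------------------------------
# tabular export


def estimate_table(
    table: InviteeTable,
    variables: Sequence[str] | None = None,
    methods: Sequence[str] = METHODS,
    B: int = 0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Estimates for many variables in the export CSV layout.

    Columns: variable, level, method, estimate, ci_low, ci_high,
    n_bootstrap, failed_replicates, out_of_range.  When non-participants
    carry observed values, ``true_population`` rows are included for
    comparison.  ``B=0`` skips the bootstrap (point estimates only).
    """
    from .summaries import _grid_variables

    specs = _grid_variables(table, variables)
    if B:
        results = bootstrap_estimates(table, specs, B=B, seed=seed, methods=methods)
    else:
        results = {
            (v, m): point_estimate(table, v, m) for v in specs for m in methods
        }
    rows = []
    for spec in specs:
        name, _, level = spec.partition("=")
        ests = [results[(spec, m)] for m in methods]
        if not table.variable(name).participant_only and (
            table.data["wave"].eq("nonparticipant").any()
        ):
            try:
                ests.insert(0, population_truth(table, spec))
            except Exception:
                pass
        for e in ests:
            rows.append(
                {
                    "variable": name,
                    "level": level or "",
                    "method": e.method,
                    "estimate": e.estimate,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "n_bootstrap": e.n_bootstrap,
                    "failed_replicates": e.failed_replicates,
                    "out_of_range": e.out_of_range,
                }
            )
    return pd.DataFrame(rows)
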