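"""Synthetic invitee cohorts with a participation-propensity continuum.

Each individual draws a latent participation propensity U.  Wave
membership is an exact deterministic function of U: the cohort is ranked
by U and cut at fixed sample quantiles matching the target wave shares
(highest U -> wave 0, lowest -> non-participation).  This makes the
continuum assumption literal — waves are contiguous propensity strata —
and reproduces target counts exactly, so share arithmetic in tests is
integer-exact rather than approximate.

Characteristics are generated conditionally independent given U through
a per-variable link:

``flat``              mean does not depend on U (no gradient).
``linear_monotone``   mean = base + gradient * (U - 1/2).
``logistic_monotone`` binary with log-odds = logit(base) + gradient * (U - 1/2)
                      (the gradient is on the log-odds scale).
``non_monotone``      mean = base + gradient * ((U - 1/2)^2 - 1/12), a
                      U-shaped violation of the continuum whose
                      population mean stays ``base`` under uniform U.
``step_monotone``     mean = base + gradient * 1{U >= threshold}, a
                      monotone step; placing the step at the boundary
                      between the last reminder wave and the waves
                      before it makes the non-participant conditional
                      mean equal the last wave's by construction.

Joint dependence among characteristics (income x education, say) is not
modelled; see the methods note for what that limits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import expit, logit

from .cohort import (
    NONPARTICIPANT,
    CohortError,
    InviteeTable,
    VariableSchema,
    wave_label,
)

LinkKind = Literal[
    "flat", "linear_monotone", "logistic_monotone", "non_monotone", "step_monotone"
]


class ScenarioError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class VariableLink:
    """How one characteristic's conditional mean depends on propensity U.

    ``base_level`` is the value of the mean function at U = 1/2 (for the
    step link, the value below the threshold).  ``gradient`` is the
    effect size per unit propensity on the link's natural scale; a
    negative gradient makes the characteristic more common among the
    resistant (low-U) end, which is the typical pattern for markers of
    disadvantage.  ``noise_sd`` is the residual SD for continuous
    variables.
    """

    name: str
    kind: Literal["binary", "continuous"]
    link: LinkKind
    base_level: float
    gradient: float = 0.0
    noise_sd: float = 0.0
    participant_only: bool = False
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.link == "flat" and self.gradient != 0.0:
            raise ScenarioError(f"flat link requires gradient 0 ({self.name!r})")
        if self.link == "logistic_monotone":
            if self.kind != "binary":
                raise ScenarioError(f"logistic link is binary-only ({self.name!r})")
            if not 0.0 < self.base_level < 1.0:
                raise ScenarioError(f"logistic base_level must be in (0,1) ({self.name!r})")
        if self.link == "step_monotone":
            if self.threshold is None or not 0.0 < self.threshold < 1.0:
                raise ScenarioError(f"step link needs threshold in (0,1) ({self.name!r})")
        elif self.threshold is not None:
            raise ScenarioError(f"threshold only meaningful for step link ({self.name!r})")
        if self.kind == "binary":
            for u in (0.0, 0.5, 1.0):
                p = _mean_function(self)(np.array([u]))[0]
                if not 0.0 <= p <= 1.0:
                    raise ScenarioError(
                        f"binary {self.name!r}: mean {p:.3f} outside [0,1] at U={u}"
                    )
        if self.kind == "continuous" and self.noise_sd < 0:
            raise ScenarioError(f"negative noise_sd ({self.name!r})")


def _mean_function(link: VariableLink) -> Callable[[np.ndarray], np.ndarray]:
    b, g = link.base_level, link.gradient
    if link.link == "flat":
        return lambda u: np.full_like(u, b, dtype=float)
    if link.link == "linear_monotone":
        return lambda u: b + g * (u - 0.5)
    if link.link == "logistic_monotone":
        lo = logit(b)
        return lambda u: expit(lo + g * (u - 0.5))
    if link.link == "non_monotone":
        return lambda u: b + g * ((u - 0.5) ** 2 - 1.0 / 12.0)
    if link.link == "step_monotone":
        t = link.threshold
        return lambda u: b + g * (u >= t)
    raise ScenarioError(f"unknown link {link.link!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic cohort: size, wave shares, variables.

    ``wave_shares`` lists the participant waves in order and the
    non-participant share last; they must sum to one.  ``propensity_model``
    is ``"uniform"`` or ``"beta(a,b)"``.
    """

    name: str
    n_invited: int
    wave_shares: tuple[float, ...]
    variables: tuple[VariableLink, ...]
    propensity_model: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_invited < 1:
            raise ScenarioError("n_invited must be >= 1")
        if len(self.wave_shares) < 2:
            raise ScenarioError("need at least one participant wave + non-participants")
        s = float(np.sum(self.wave_shares))
        if abs(s - 1.0) > 1e-9:
            raise ScenarioError(f"wave shares sum to {s}, not 1")
        if any(sh <= 0 for sh in self.wave_shares[:-1]):
            raise ScenarioError("zero or negative participant wave share")
        _propensity_dist(self.propensity_model)  # validate early

    @property
    def n_waves(self) -> int:
        return len(self.wave_shares) - 1

    def variable(self, name: str) -> VariableLink:
        for v in self.variables:
            if v.name == name:
                return v
        raise ScenarioError(f"unknown variable {name!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Pre-masking full-cohort means, recorded before participant-only
    values are hidden for non-participants."""

    values: dict[str, float]
    n: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": list(self.values), "truth": list(self.values.values())}
        )


def _propensity_dist(spec: str):
    if spec == "uniform":
        return stats.uniform()
    m = re.fullmatch(r"beta\(\s*([\d.]+)\s*,\s*([\d.]+)\s*\)", spec)
    if m:
        return stats.beta(float(m.group(1)), float(m.group(2)))
    raise ScenarioError(f"unsupported propensity model {spec!r}")


def realized_wave_counts(config: ScenarioConfig) -> np.ndarray:
    """Integer wave counts from cumulative rounding of the target shares."""
    n = config.n_invited
    cum = np.cumsum(config.wave_shares[:-1])
    bounds = np.rint(cum * n).astype(int)
    counts = np.diff(np.concatenate(([0], bounds, [n])))
    if (counts[:-1] < 1).any():
        raise ScenarioError("a participant wave rounds to zero individuals")
    return counts


def generate_population(
    config: ScenarioConfig, seed: int | np.random.Generator | None = None
) -> tuple[InviteeTable, GroundTruth]:
    """Generate one cohort and its pre-masking ground truth.

    Reproducible: identical config and seed give identical tables.  The
    ``seed`` argument overrides ``config.seed`` (and may be a Generator,
    in which case the caller controls the stream).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    n = config.n_invited
    dist = _propensity_dist(config.propensity_model)
    u = dist.rvs(size=n, random_state=rng)
    counts = realized_wave_counts(config)
    # highest propensity -> wave 0; ties broken by stable order
    order = np.argsort(-u, kind="stable")
    group_of_rank = np.repeat(np.arange(config.n_waves + 1), counts)
    codes = np.empty(n, dtype=np.int64)
    codes[order] = group_of_rank
    labels = np.array(
        [wave_label(k) for k in range(config.n_waves)] + [NONPARTICIPANT], dtype=object
    )
    df = pd.DataFrame({"id": np.arange(1, n + 1), "wave": labels[codes]})
    truth: dict[str, float] = {}
    schema: list[VariableSchema] = []
    nonpart = codes == config.n_waves
    for link in config.variables:
        mu = _mean_function(link)(u)
        if link.kind == "binary":
            vals = (rng.random(n) < mu).astype(float)
        else:
            vals = mu + (rng.normal(0.0, link.noise_sd, n) if link.noise_sd else 0.0)
        truth[link.name] = float(vals.mean())
        if link.participant_only:
            vals = vals.astype(float)
            vals[nonpart] = np.nan
        df[link.name] = vals
        schema.append(
            VariableSchema(
                name=link.name, kind=link.kind, participant_only=link.participant_only
            )
        )
    table = InviteeTable(data=df, schema=schema, n_waves=config.n_waves)
    return table, GroundTruth(values=truth, n=n)


# ---------------------------------------------------------------------
# analytic expectations


def analytic_truth(config: ScenarioConfig, variable: str) -> float:
    """Population expectation of a variable under the config, sample-free.

    Closed form where the link admits one under uniform propensity;
    otherwise Gauss quadrature of the mean function against the
    propensity density.
    """
    link = config.variable(variable)
    if config.propensity_model == "uniform":
        if link.link == "flat":
            return link.base_level
        if link.link == "linear_monotone":
            return link.base_level  # E[U] = 1/2
        if link.link == "non_monotone":
            return link.base_level  # E[(U-1/2)^2] = 1/12
        if link.link == "step_monotone":
            return link.base_level + link.gradient * (1.0 - float(link.threshold))
    dist = _propensity_dist(config.propensity_model)
    mu = _mean_function(link)
    lo, hi = dist.support()
    lo, hi = max(lo, dist.ppf(1e-12)), min(hi, dist.ppf(1 - 1e-12))
    val, err = integrate.quad(lambda t: mu(np.array([t]))[0] * dist.pdf(t), lo, hi)
    if not np.isfinite(val) or err > 1e-8:
        raise ScenarioError(f"quadrature failed for {variable!r} (err={err})")
    return float(val)


def analytic_group_means(config: ScenarioConfig, variable: str) -> np.ndarray:
    """Expected wave-group means (participant waves in order, then
    non-participants), integrating the mean function over each wave's
    propensity stratum."""
    link = config.variable(variable)
    dist = _propensity_dist(config.propensity_model)
    mu = _mean_function(link)
    # cumulative participation share boundaries, from the top of the U scale
    cum = np.concatenate(([0.0], np.cumsum(config.wave_shares)))
    cum[-1] = 1.0
    out = []
    for k in range(config.n_waves + 1):
        hi_q, lo_q = 1.0 - cum[k], 1.0 - cum[k + 1]
        lo, hi = dist.ppf(max(lo_q, 1e-12)), dist.ppf(min(hi_q, 1 - 1e-12))
        mass = hi_q - lo_q
        val, _ = integrate.quad(lambda t: mu(np.array([t]))[0] * dist.pdf(t), lo, hi)
        out.append(val / mass)
    return np.asarray(out)


def expected_baseline_bias(config: ScenarioConfig, variable: str) -> float:
    """Closed-form bias of the pooled-participant baseline.

    For a linear link under uniform propensity: participants occupy the
    top ``s`` propensity stratum, so their mean is
    base + gradient * (1 - s)/2 and the bias is gradient * (1 - s)/2.
    For other links it is the share-weighted participant mean minus the
    analytic truth (via quadrature).
    """
    s = float(np.sum(config.wave_shares[:-1]))
    link = config.variable(variable)
    if config.propensity_model == "uniform" and link.link == "linear_monotone":
        return link.gradient * (1.0 - s) / 2.0
    gm = analytic_group_means(config, variable)
    w = np.asarray(config.wave_shares[:-1]) / s
    return float(np.dot(w, gm[:-1]) - analytic_truth(config, variable))


# ---------------------------------------------------------------------
# presets

#: realized wave counts of the three study-like cohorts; shares are the
#: exact count ratios so the default n reproduces them integer-exactly
_AF_COUNTS = (5495, 970, 402, 7197)        # 14,064 invited, three waves
_FIT_COUNTS = (23036, 5786, 31278)         # 60,100 invited, two waves
_COL_COUNTS = (8131, 2410, 19854)          # 30,395 invited, two waves


def _shares_from_counts(counts: Sequence[int]) -> tuple[float, ...]:
    total = sum(counts)
    return tuple(c / total for c in counts)


def _preset_strokestop(n: int | None) -> ScenarioConfig:
    return ScenarioConfig(
        name="strokestop_like",
        n_invited=n or sum(_AF_COUNTS),
        wave_shares=_shares_from_counts(_AF_COUNTS),
        variables=(
            VariableLink("male", "binary", "logistic_monotone", 0.47, -0.12),
            VariableLink("immigrant", "binary", "logistic_monotone", 0.215, -1.2),
            VariableLink("low_income", "binary", "logistic_monotone", 0.323, -1.54),
            VariableLink("charlson", "continuous", "linear_monotone", 0.70, -0.49, 1.2),
            VariableLink(
                "systolic_bp", "continuous", "linear_monotone", 139.5, -3.0, 17.0,
                participant_only=True,
            ),
        ),
    )


def _preset_screesco_fit(n: int | None) -> ScenarioConfig:
    return ScenarioConfig(
        name="screesco_fit_like",
        n_invited=n or sum(_FIT_COUNTS),
        wave_shares=_shares_from_counts(_FIT_COUNTS),
        variables=(
            VariableLink("male", "binary", "logistic_monotone", 0.50, -0.45),
            VariableLink("primary_edu", "binary", "logistic_monotone", 0.187, -0.86),
            VariableLink(
                "fit_positive", "binary", "logistic_monotone", 0.13, -0.40,
                participant_only=True,
            ),
        ),
    )


def _preset_screesco_col(n: int | None) -> ScenarioConfig:
    return ScenarioConfig(
        name="screesco_col_like",
        n_invited=n or sum(_COL_COUNTS),
        wave_shares=_shares_from_counts(_COL_COUNTS),
        variables=(
            # the late-participant male surplus: U-shaped, peaking mid-propensity
            VariableLink("male", "binary", "non_monotone", 0.528, -0.49),
            VariableLink("primary_edu", "binary", "logistic_monotone", 0.183, -0.65),
        ),
    )


def _preset_linear_in_cumshare(n: int | None) -> ScenarioConfig:
    # linear-in-U + uniform propensity makes the cumulative mean exactly
    # linear in the cumulative share, so extrapolation is correctly specified
    return ScenarioConfig(
        name="linear_in_cumshare",
        n_invited=n or 20_000,
        wave_shares=(0.39, 0.07, 0.03, 0.51),
        variables=(
            VariableLink("risk_score", "continuous", "linear_monotone", 0.69, -0.5, 1.0),
            VariableLink("marker", "binary", "linear_monotone", 0.25, -0.2),
        ),
    )


def _preset_substitution_exact(n: int | None) -> ScenarioConfig:
    # step at the early/late boundary: every reminder wave and the
    # non-participants share one conditional mean, so the last wave is a
    # perfect stand-in.  The step sits away from the last wave's own
    # stratum edges — rank-based assignment shuffles individuals across
    # stratum boundaries, and a discontinuity at the stand-in wave's edge
    # would leak a finite-sample bias into the identity.
    t = 0.51 + 0.03 + 0.07
    return ScenarioConfig(
        name="substitution_exact",
        n_invited=n or 20_000,
        wave_shares=(0.39, 0.07, 0.03, 0.51),
        variables=(
            VariableLink("immigrant", "binary", "step_monotone", 0.27, -0.11, threshold=t),
            VariableLink(
                "comorbidity", "continuous", "step_monotone", 0.82, -0.27, 1.0,
                threshold=t,
            ),
        ),
    )


def _preset_non_monotone(n: int | None) -> ScenarioConfig:
    # expected wave means 0.5 / 0.2 / 0.5 across equal thirds: both
    # estimators are provably biased (the continuum is violated)
    return ScenarioConfig(
        name="non_monotone",
        n_invited=n or 20_000,
        wave_shares=(1 / 3, 1 / 3, 1 / 3),
        variables=(VariableLink("mixed_signal", "binary", "non_monotone", 0.4, 2.7),),
    )


def _preset_flat(n: int | None) -> ScenarioConfig:
    return ScenarioConfig(
        name="flat",
        n_invited=n or 5_000,
        wave_shares=(0.39, 0.07, 0.03, 0.51),
        variables=(
            VariableLink("indicator", "binary", "flat", 0.3),
            VariableLink("score", "continuous", "flat", 0.5, 0.0, 1.0),
        ),
    )


_PRESETS: dict[str, Callable[[int | None], ScenarioConfig]] = {
    "strokestop_like": _preset_strokestop,
    "screesco_fit_like": _preset_screesco_fit,
    "screesco_col_like": _preset_screesco_col,
    "linear_in_cumshare": _preset_linear_in_cumshare,
    "substitution_exact": _preset_substitution_exact,
    "non_monotone": _preset_non_monotone,
    "flat": _preset_flat,
}

PRESET_NAMES = tuple(_PRESETS)


def scenario_preset(name: str, n_invited: int | None = None, seed: int = 0) -> ScenarioConfig:
    """A fully-populated named scenario; ``n_invited`` and ``seed`` override."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise ScenarioError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return replace(builder(n_invited), seed=seed)


# ---------------------------------------------------------------------
# config i/o


def config_to_dict(config: ScenarioConfig) -> dict:
    return {
        "name": config.name,
        "n_invited": config.n_invited,
        "wave_shares": list(config.wave_shares),
        "propensity_model": config.propensity_model,
        "seed": config.seed,
        "variables": [
            {
                k: v
                for k, v in {
                    "name": link.name,
                    "kind": link.kind,
                    "link": link.link,
                    "base_level": link.base_level,
                    "gradient": link.gradient,
                    "noise_sd": link.noise_sd,
                    "participant_only": link.participant_only,
                    "threshold": link.threshold,
                }.items()
                if v is not None
            }
            for link in config.variables
        ],
    }


def config_from_dict(doc: dict) -> ScenarioConfig:
    return ScenarioConfig(
        name=doc.get("name", "custom"),
        n_invited=int(doc["n_invited"]),
        wave_shares=tuple(float(s) for s in doc["wave_shares"]),
        propensity_model=doc.get("propensity_model", "uniform"),
        seed=int(doc.get("seed", 0)),
        variables=tuple(
            VariableLink(
                name=v["name"],
                kind=v["kind"],
                link=v["link"],
                base_level=float(v["base_level"]),
                gradient=float(v.get("gradient", 0.0)),
                noise_sd=float(v.get("noise_sd", 0.0)),
                participant_only=bool(v.get("participant_only", False)),
                threshold=(None if v.get("threshold") is None else float(v["threshold"])),
            )
            for v in doc["variables"]
        ),
    )
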