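"""Per-wave-group averages and proportions with normal-approximation CIs.

Produces the classic invitee-characteristics grid: one row per variable
(or categorical level) and per group — each participant wave, the
non-participants, and the full invited population — with Wald 95%
intervals.  Proportions use se = sqrt(p(1-p)/n); continuous means use
the sample SD (denominator n-1) over sqrt(n).  The normal 0.975
quantile is used exactly (1.959964...), and proportion intervals are
plain Wald with no continuity correction and no clipping: clipping
would break the exact identity that a pooled estimate equals the
wave-share-weighted average of wave estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    NONPARTICIPANT,
    CohortError,
    InviteeTable,
    wave_counts,
    wave_labels,
)

#: exact normal 0.975 quantile used for every 95% interval
Z975 = float(stats.norm.ppf(0.975))

#: pooled / pseudo group labels accepted alongside wave labels
PARTICIPANTS = "participants"
POPULATION = "population"


class SummaryError(ValueError):
    """Empty group or undefined spread for a summary cell."""


@dataclass(frozen=True)
class GroupEstimate:
    """One cell of the summary grid: a group mean/proportion with Wald CI."""

    group: str
    variable: str
    n: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    degenerate: bool = False

    @property
    def ci_outside_unit(self) -> bool:
        """Unclipped proportion CI escaping [0, 1] (reported, flagged)."""
        return self.ci_low < 0.0 or self.ci_high > 1.0


def _group_mask(table: InviteeTable, group: str) -> np.ndarray:
    wave = table.data["wave"]
    if group == PARTICIPANTS:
        return (wave != NONPARTICIPANT).to_numpy()
    if group == POPULATION:
        return np.ones(table.n, dtype=bool)
    if group not in wave_labels(table.n_waves):
        raise SummaryError(f"unknown group {group!r}")
    return (wave == group).to_numpy()


def group_mean(table: InviteeTable, variable: str, group: str) -> GroupEstimate:
    """Mean or proportion of ``variable`` within ``group`` with a 95% Wald CI.

    ``group`` is a wave label, ``participants`` (all waves pooled) or
    ``population`` (everyone invited).  ``variable`` is a binary or
    continuous name, or a ``name=level`` categorical indicator.
    Missing values are dropped from numerator and denominator
    (complete case within variable).
    """
    values = table.numeric_values(variable)[_group_mask(table, group)]
    values = values[np.isfinite(values)]
    n = values.size
    if n == 0:
        raise SummaryError(f"group {group!r} empty for variable {variable!r}")
    est = float(values.mean())
    if table.is_proportion(variable):
        se = float(np.sqrt(est * (1.0 - est) / n))
    else:
        if n == 1:
            raise SummaryError(
                f"cannot form a CI for continuous {variable!r} with n=1 in {group!r}"
            )
        se = float(values.std(ddof=1) / np.sqrt(n))
    return GroupEstimate(
        group=group,
        variable=variable,
        n=int(n),
        estimate=est,
        se=se,
        ci_low=est - Z975 * se,
        ci_high=est + Z975 * se,
        degenerate=se == 0.0,
    )


def expand_categorical(table: InviteeTable, name: str) -> list[str]:
    """Derived binary indicators ``name=level``, one per declared level.

    With ``missing_as_level`` the explicit missing level is included;
    the indicators then partition every group, so their proportions sum
    to one within each group.
    """
    var = table.variable(name)
    if var.kind != "categorical":
        raise CohortError(f"{name!r} is not categorical")
    return [f"{name}={level}" for level in var.levels or ()]


def _grid_variables(table: InviteeTable, variables: Sequence[str] | None) -> list[str]:
    names = variables if variables is not None else [v.name for v in table.schema]
    out: list[str] = []
    for name in names:
        if "=" in name or table.variable(name).kind != "categorical":
            out.append(name)
        else:
            out.extend(expand_categorical(table, name))
    return out


@dataclass
class SummaryGrid:
    """Long-format grid of :class:`GroupEstimate` cells."""

    frame: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")


def summary_grid(table: InviteeTable, variables: Sequence[str] | None = None) -> SummaryGrid:
    """Grid of group estimates over every group present in the table.

    Columns: variable, level, group, n, estimate, se, ci_low, ci_high,
    degenerate.  A ``population`` column appears iff non-participants are
    present; participant-only variables get no non-participant and no
    population cells (the dashes of a characteristics table).
    """
    shares = wave_counts(table)
    has_nonpart = shares.counts[-1] > 0
    rows = []
    for spec in _grid_variables(table, variables):
        name, _, level = spec.partition("=")
        participant_only = table.variable(name).participant_only
        groups = [w for w, c in zip(wave_labels(table.n_waves), shares.counts) if c > 0]
        if participant_only or not has_nonpart:
            groups = [g for g in groups if g != NONPARTICIPANT]
        else:
            groups.append(POPULATION)
        for group in groups:
            cell = group_mean(table, spec, group)
            rows.append(
                {
                    "variable": name,
                    "level": level or "",
                    "group": group,
                    "n": cell.n,
                    "estimate": cell.estimate,
                    "se": cell.se,
                    "ci_low": cell.ci_low,
                    "ci_high": cell.ci_high,
                    "degenerate": cell.degenerate,
                }
            )
    return SummaryGrid(frame=pd.DataFrame(rows))
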