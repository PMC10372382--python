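"""Invitee-level cohort data model.

One row per invited individual, carrying a participation-wave label
(agreed after the initial invitation, after the k-th reminder, or never)
and a set of typed characteristic columns, some of which are observable
only among participants (e.g. measurements taken at the screening visit).

Waves are ordinal: ``wave_0 < wave_1 < ... < nonparticipant``, encoding
decreasing participation propensity.  Non-participants always carry the
distinct sentinel label, never a numeric index, so they cannot leak into
participant-only arithmetic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

NONPARTICIPANT = "nonparticipant"
#: level label used when a categorical variable declares missing_as_level
MISSING_LEVEL = "Missing"
#: token representing a missing value in delimited files
MISSING_TOKEN = ""

VariableKind = Literal["binary", "categorical", "continuous"]


class CohortError(ValueError):
    """Schema or validation failure on invitee-level data."""


def wave_label(k: int) -> str:
    return f"wave_{k}"


def wave_labels(n_waves: int) -> list[str]:
    """All valid labels for a design with ``n_waves`` participant waves."""
    return [wave_label(k) for k in range(n_waves)] + [NONPARTICIPANT]


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one characteristic column.

    Parameters
    ----------
    name
        Column name in the invitee table.
    kind
        ``binary`` (0/1), ``categorical`` (string levels) or ``continuous``.
    participant_only
        The value is observable only among participants (determined at the
        screening itself); it must be missing for every non-participant.
    levels
        Ordered category labels; required for and restricted to categoricals.
    missing_as_level
        For categoricals: treat missingness as an explicit level
        (:data:`MISSING_LEVEL`) instead of excluding those rows.
    """

    name: str
    kind: VariableKind
    participant_only: bool = False
    levels: tuple[str, ...] | None = None
    missing_as_level: bool = False

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if not self.levels:
                raise CohortError(f"categorical variable {self.name!r} needs levels")
            levels = tuple(self.levels)
            if self.missing_as_level and MISSING_LEVEL not in levels:
                levels = levels + (MISSING_LEVEL,)
            object.__setattr__(self, "levels", levels)
        else:
            if self.levels:
                raise CohortError(f"levels only allowed for categorical ({self.name!r})")
            if self.missing_as_level:
                raise CohortError(f"missing_as_level only for categorical ({self.name!r})")
            object.__setattr__(self, "levels", None)


@dataclass(frozen=True)
class WaveShares:
    """Population shares of each participant wave and of non-participants.

    Stored as the underlying integer counts so the shares sum to one
    exactly in rational arithmetic: ``counts = (n_wave0, ..., n_waveK-1,
    n_nonparticipant)``.
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise CohortError("need at least one participant wave and non-participants")
        if any(int(c) != c or c < 0 for c in self.counts):
            raise CohortError("counts must be non-negative integers")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if self.total == 0:
            raise CohortError("empty cohort")

    @property
    def n_waves(self) -> int:
        return len(self.counts) - 1

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def shares(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.total

    @property
    def fractions(self) -> tuple[Fraction, ...]:
        """Exact shares; they sum to 1 by construction."""
        return tuple(Fraction(c, self.total) for c in self.counts)

    @property
    def alpha(self) -> float:
        return self.counts[0] / self.total

    @property
    def later_shares(self) -> np.ndarray:
        return np.asarray(self.counts[1:-1], dtype=float) / self.total

    @property
    def nonparticipant_share(self) -> float:
        return self.counts[-1] / self.total

    @property
    def participant_share(self) -> float:
        return sum(self.counts[:-1]) / self.total


@dataclass
class InviteeTable:
    """Validated invitee-level table.

    ``data`` has an ``id`` column (unique, opaque), a ``wave`` column
    holding labels from :func:`wave_labels`, plus one column per schema
    variable.  Binary columns are floats in {0, 1, NaN}; continuous
    columns are floats; categorical columns are strings (NaN allowed
    unless ``missing_as_level``, in which case missing has already been
    recoded to the explicit level).
    """

    data: pd.DataFrame
    schema: list[VariableSchema]
    n_waves: int

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        df = self.data
        if self.n_waves < 1:
            raise CohortError("need at least one participant wave")
        for col in ("id", "wave"):
            if col not in df.columns:
                raise CohortError(f"missing required column {col!r}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].head(5).tolist()
            raise CohortError(f"duplicate ids, e.g. {dups}")
        valid = set(wave_labels(self.n_waves))
        bad = set(df["wave"].unique()) - valid
        if bad:
            raise CohortError(f"invalid wave labels {sorted(map(str, bad))} for K={self.n_waves}")
        if not (df["wave"] != NONPARTICIPANT).any():
            raise CohortError("table has no participants")
        npart = df["wave"] == NONPARTICIPANT
        for var in self.schema:
            if var.name not in df.columns:
                raise CohortError(f"schema variable {var.name!r} absent from table")
            col = df[var.name]
            if var.kind == "binary":
                vals = pd.to_numeric(col, errors="coerce")
                observed = vals.dropna()
                bad_rows = observed.index[~observed.isin((0.0, 1.0))]
                if len(bad_rows):
                    raise CohortError(
                        f"non-binary values in {var.name!r} at rows {bad_rows[:5].tolist()}"
                    )
                self.data[var.name] = vals.astype(float)
            elif var.kind == "continuous":
                self.data[var.name] = pd.to_numeric(col, errors="raise").astype(float)
            else:
                if var.missing_as_level:
                    col = col.fillna(MISSING_LEVEL)
                    self.data[var.name] = col
                observed = col.dropna()
                extra = set(observed.unique()) - set(var.levels or ())
                if extra:
                    raise CohortError(
                        f"unknown levels {sorted(extra)} in categorical {var.name!r}"
                    )
            if var.participant_only:
                present = self.data.loc[npart, var.name].notna()
                if present.any():
                    raise CohortError(
                        f"participant-only variable {var.name!r} has values for "
                        f"{int(present.sum())} non-participants"
                    )

    # -- accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    def variable(self, name: str) -> VariableSchema:
        for var in self.schema:
            if var.name == name:
                return var
        raise CohortError(f"unknown variable {name!r}")

    def wave_codes(self) -> np.ndarray:
        """Integer codes: participants 0..K-1, non-participants K."""
        order = {lab: k for k, lab in enumerate(wave_labels(self.n_waves))}
        return self.data["wave"].map(order).to_numpy(dtype=np.int64)

    def is_proportion(self, variable: str) -> bool:
        name, _, level = variable.partition("=")
        var = self.variable(name)
        if level:
            if var.kind != "categorical":
                raise CohortError(f"{name!r} is not categorical; cannot take level {level!r}")
            return True
        return var.kind == "binary"

    def numeric_values(self, variable: str) -> np.ndarray:
        """Float array for a variable or a ``name=level`` indicator.

        Missing values come back as NaN.  For a level indicator the value
        is 1 where the categorical equals the level, 0 where it equals a
        different (observed) level, NaN where the categorical is missing.
        """
        name, _, level = variable.partition("=")
        var = self.variable(name)
        col = self.data[name]
        if level:
            if var.kind != "categorical":
                raise CohortError(f"{name!r} is not categorical; cannot take level {level!r}")
            if level not in (var.levels or ()):
                raise CohortError(f"unknown level {level!r} of {name!r}")
            out = (col == level).astype(float)
            out[col.isna()] = np.nan
            return out.to_numpy()
        if var.kind == "categorical":
            raise CohortError(
                f"categorical {name!r} needs a level, e.g. {name}={var.levels[0]}"
            )
        return col.to_numpy(dtype=float)


# ---------------------------------------------------------------------
# exclusions


@dataclass(frozen=True)
class ExclusionRule:
    """Remove rows where ``column == value`` (declarative flag predicate)."""

    name: str
    column: str
    value: object = 1


@dataclass(frozen=True)
class ExclusionAudit:
    """Sequential accounting of exclusions: ``final_n = initial_n - sum removed``."""

    initial_n: int
    per_rule: tuple[tuple[str, int], ...]
    final_n: int

    def __post_init__(self) -> None:
        removed = sum(n for _, n in self.per_rule)
        if self.final_n != self.initial_n - removed or min(
            [self.initial_n, self.final_n] + [n for _, n in self.per_rule], default=0
        ) < 0:
            raise CohortError("inconsistent exclusion audit")


def apply_exclusions(
    table: InviteeTable, rules: Sequence[ExclusionRule]
) -> tuple[InviteeTable, ExclusionAudit]:
    """Drop rows matching any rule; attribute each row to the first rule that hits it.

    Rules apply in declared order, so overlapping rules report sequential
    counts (each rule's tally covers only rows not already removed).
    """
    df = table.data
    keep = pd.Series(True, index=df.index)
    per_rule: list[tuple[str, int]] = []
    for rule in rules:
        if rule.column not in df.columns:
            raise CohortError(f"exclusion rule {rule.name!r}: unknown column {rule.column!r}")
        hit = keep & (df[rule.column] == rule.value)
        per_rule.append((rule.name, int(hit.sum())))
        keep &= ~hit
    audit = ExclusionAudit(initial_n=len(df), per_rule=tuple(per_rule), final_n=int(keep.sum()))
    out = dataclasses.replace(table, data=df.loc[keep].reset_index(drop=True).copy())
    return out, audit


def wave_counts(table: InviteeTable) -> WaveShares:
    """Counts and exact shares per wave label (non-participants last)."""
    codes = table.wave_codes()
    counts = np.bincount(codes, minlength=table.n_waves + 1)
    return WaveShares(counts=tuple(int(c) for c in counts))


# ---------------------------------------------------------------------
# i/o


def read_invitee_table(
    path: str | Path,
    schema: Sequence[VariableSchema],
    n_waves: int,
    wave_column: str = "wave",
    wave_map: Mapping[str, str] | None = None,
    id_column: str = "id",
    missing_token: str = MISSING_TOKEN,
) -> InviteeTable:
    """Read a delimited invitee file into a validated :class:`InviteeTable`.

    ``wave_map`` maps the file's wave codes onto the internal labels;
    by default the file is expected to already contain internal labels
    (``wave_0``, ..., ``nonparticipant``).  Unmapped codes raise, they
    are never coerced.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (id_column, wave_column):
        if col not in df.columns:
            raise CohortError(f"file {path} lacks column {col!r}")
    df = df.replace(missing_token, np.nan)
    if wave_map is None:
        wave_map = {lab: lab for lab in wave_labels(n_waves)}
    raw = df[wave_column]
    if raw.isna().any():
        raise CohortError(f"missing wave codes in column {wave_column!r}")
    unmapped = sorted(set(raw.unique()) - set(wave_map))
    if unmapped:
        raise CohortError(f"unmapped wave codes {unmapped} in column {wave_column!r}")
    mapped = raw.map(dict(wave_map))
    bad = sorted(set(mapped.unique()) - set(wave_labels(n_waves)))
    if bad:
        raise CohortError(f"wave_map produces invalid labels {bad} for K={n_waves}")
    out = df.rename(columns={id_column: "id", wave_column: "wave"})
    out["wave"] = mapped.to_numpy()
    keep = ["id", "wave"] + [v.name for v in schema]
    missing_cols = [c for c in keep if c not in out.columns]
    if missing_cols:
        raise CohortError(f"file {path} lacks schema columns {missing_cols}")
    extra = [c for c in out.columns if c not in keep]
    return InviteeTable(data=out[keep + extra].copy(), schema=list(schema), n_waves=n_waves)


def write_invitee_table(table: InviteeTable, path: str | Path) -> None:
    """Write as RFC-4180 CSV (UTF-8, header row, empty cell = missing).

    Binary columns are written as integer 0/1; floats are written with
    ``repr`` precision so a read back reproduces the values exactly.
    """
    df = table.data.copy()
    for var in table.schema:
        if var.kind == "binary":
            df[var.name] = df[var.name].map(
                lambda v: "" if pd.isna(v) else str(int(v)), na_action=None
            )
        elif var.kind == "continuous":
            df[var.name] = df[var.name].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------
# config documents


def schema_from_config(doc: Mapping) -> tuple[list[VariableSchema], int, str, dict[str, str] | None]:
    """Parse a schema config mapping.

    Expected keys: ``n_waves`` (int), ``variables`` (list of variable
    mappings), optional ``wave_column`` (default ``wave``) and
    ``wave_map`` (file code -> internal label).
    """
    try:
        n_waves = int(doc["n_waves"])
        raw_vars = doc["variables"]
    except KeyError as exc:
        raise CohortError(f"schema config missing key {exc}") from exc
    schema = []
    for entry in raw_vars:
        schema.append(
            VariableSchema(
                name=entry["name"],
                kind=entry["kind"],
                participant_only=bool(entry.get("participant_only", False)),
                levels=tuple(entry["levels"]) if entry.get("levels") else None,
                missing_as_level=bool(entry.get("missing_as_level", False)),
            )
        )
    wave_map = doc.get("wave_map")
    if wave_map is not None:
        wave_map = {str(k): str(v) for k, v in wave_map.items()}
    return schema, n_waves, str(doc.get("wave_column", "wave")), wave_map


def load_schema(path: str | Path) -> tuple[list[VariableSchema], int, str, dict[str, str] | None]:
    """Load a YAML (or JSON, a YAML subset) schema config file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise CohortError(f"schema config {path} is not a mapping")
    return schema_from_config(doc)
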