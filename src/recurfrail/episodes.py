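"""Episode-level recurrent-event data: types, ordering, and validation.

An *episode* is one sickness-absence spell of a worker: a gap-time duration in
whole days measured from certification of the spell, an event indicator
(1 = the spell was observed to end, 0 = right-censored), the within-individual
event order ``k``, and a set of fixed categorical covariates.  A *cohort*
bundles the episodes of many individuals with a covariate schema that fixes
the category ordering and the reference level of every covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Episode",
    "Cohort",
    "ValidationError",
    "ValidationReport",
    "assign_event_order",
    "validate_cohort",
    "read_episodes",
    "write_episodes",
]

#: Columns with a fixed meaning in the episode CSV dialect; everything else is
#: treated as a categorical covariate.
RESERVED_COLUMNS = ("individual_id", "start", "seq", "duration_days", "event",
                    "order_k", "original_rank")

DEFAULT_K_MAX = 5


class ValidationError(ValueError):
    """Raised when episode data violate the cohort contract."""


@dataclass(frozen=True)
class Episode:
    """One sickness-absence spell.

    Parameters
    ----------
    individual_id : opaque identifier of the worker.
    order_k : event order within the individual, after collapsing at ``k_max``.
    duration_days : gap time in whole days (>= 1) from certification to the
        end of the spell or to censoring.
    event : 1 if the end of the spell was observed, 0 if right-censored.
    covariates : mapping covariate name -> category label.
    original_rank : chronological rank before collapsing (defaults to order_k).
    """

    individual_id: object
    order_k: int
    duration_days: int
    event: int
    covariates: Mapping[str, str] = field(default_factory=dict)
    original_rank: int | None = None


@dataclass
class Cohort:
    """Episodes of many individuals plus the covariate schema.

    ``episodes`` is a DataFrame with columns ``individual_id, order_k,
    original_rank, duration_days, event`` followed by one column per
    covariate.  Rows are sorted by (individual, original rank) and the rows of
    one individual are contiguous.  ``schema`` maps covariate name to the
    ordered list of category labels; the first label is the reference level.
    """

    episodes: pd.DataFrame
    schema: dict[str, list[str]]
    k_max: int = DEFAULT_K_MAX

    @property
    def covariate_names(self) -> list[str]:
        return list(self.schema)

    @property
    def n_individuals(self) -> int:
        return self.episodes["individual_id"].nunique()

    def __len__(self) -> int:
        return len(self.episodes)

    def iter_episodes(self) -> Iterable[Episode]:
        covs = self.covariate_names
        for row in self.episodes.itertuples(index=False):
            yield Episode(
                individual_id=row.individual_id,
                order_k=int(row.order_k),
                duration_days=int(row.duration_days),
                event=int(row.event),
                covariates={c: getattr(row, c) for c in covs},
                original_rank=int(row.original_rank),
            )


def _infer_schema(df: pd.DataFrame, covariates: Iterable[str]) -> dict[str, list[str]]:
    # Sorted unique labels; the first (alphabetically) is the reference level
    # unless the caller supplies an explicit schema.
    return {c: sorted(df[c].astype(str).unique()) for c in covariates}


def assign_event_order(
    raw_episodes: pd.DataFrame,
    k_max: int = DEFAULT_K_MAX,
    order_by: str | None = None,
    schema: dict[str, list[str]] | None = None,
) -> Cohort:
    """Rank episodes chronologically within individual and collapse at ``k_max``.

    Episodes are sorted within each individual by ``order_by`` (the ``start``
    column if present, else the integer ``seq`` column) and receive
    ``order_k = min(rank, k_max)``; collapsing repeated episodes into a top
    stratum keeps sparse high-order strata from destabilising event-order
    stratified fits.  The uncollapsed rank is preserved in ``original_rank``
    and no episode is dropped.

    Raises
    ------
    ValidationError
        If no chronological key is available, a key is duplicated within an
        individual, or required columns are missing.
    """
    if k_max < 1:
        raise ValidationError(f"k_max must be >= 1, got {k_max}")
    df = raw_episodes.copy()
    for col in ("individual_id", "duration_days", "event"):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    if order_by is None:
        for candidate in ("start", "seq", "original_rank"):
            if candidate in df.columns:
                order_by = candidate
                break
    if order_by is None:
        raise ValidationError(
            "no chronological key: provide a 'start' (date) or 'seq' (integer) "
            "column, or pass order_by explicitly"
        )
    if order_by not in df.columns:
        raise ValidationError(f"order_by column {order_by!r} not in data")

    dup = df.duplicated(subset=["individual_id", order_by], keep=False)
    if dup.any():
        offenders = sorted(df.loc[dup, "individual_id"].astype(str).unique())
        raise ValidationError(
            f"duplicate chronological key {order_by!r} within individual(s): "
            + ", ".join(offenders[:10])
        )

    df = df.sort_values(["individual_id", order_by], kind="stable").reset_index(drop=True)
    rank = df.groupby("individual_id", sort=False).cumcount() + 1
    df["original_rank"] = rank
    df["order_k"] = rank.clip(upper=k_max)

    covariates = [c for c in df.columns if c not in RESERVED_COLUMNS]
    for c in covariates:
        df[c] = df[c].astype(str)
    if schema is None:
        schema = _infer_schema(df, covariates)

    ordered = ["individual_id", "order_k", "original_rank", "duration_days", "event"]
    out = df[ordered + covariates].copy()
    out["order_k"] = out["order_k"].astype(int)
    out["duration_days"] = out["duration_days"].astype(int)
    out["event"] = out["event"].astype(int)
    return Cohort(episodes=out, schema=dict(schema), k_max=k_max)


@dataclass
class ValidationReport:
    """Counts and invariant violations for a cohort."""

    n_individuals: int = 0
    n_episodes: int = 0
    n_events: int = 0
    n_censored: int = 0
    episodes_per_order: dict[int, int] = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        lines = [
            f"individuals: {self.n_individuals}",
            f"episodes: {self.n_episodes} ({self.n_events} events, {self.n_censored} censored)",
            "episodes per order: "
            + ", ".join(f"k={k}: {n}" for k, n in sorted(self.episodes_per_order.items())),
            f"violations: {len(self.violations)}",
        ]
        return "\n".join(lines + self.violations)


def validate_cohort(cohort: Cohort, strict: bool = False) -> ValidationReport:
    """Check every Episode/Cohort invariant and count the cohort contents.

    In strict mode the first violation raises :class:`ValidationError`;
    otherwise all violations are collected into the report.
    """
    df = cohort.episodes
    rep = ValidationReport()
    if len(df) == 0:
        return rep
    rep.n_individuals = df["individual_id"].nunique()
    rep.n_episodes = len(df)
    rep.n_events = int((df["event"] == 1).sum())
    rep.n_censored = int((df["event"] == 0).sum())
    rep.episodes_per_order = df["order_k"].value_counts().sort_index().to_dict()

    def flag(msg: str) -> None:
        if strict:
            raise ValidationError(msg)
        rep.violations.append(msg)

    for idx in df.index[df["duration_days"] < 1]:
        flag(f"episode row {idx}: duration_days {df.at[idx, 'duration_days']} < 1")
    for idx in df.index[~df["event"].isin([0, 1])]:
        flag(f"episode row {idx}: event {df.at[idx, 'event']} not in {{0, 1}}")
    bad_order = (df["order_k"] < 1) | (df["order_k"] > cohort.k_max)
    for idx in df.index[bad_order]:
        flag(f"episode row {idx}: order_k {df.at[idx, 'order_k']} outside 1..{cohort.k_max}")

    for name, levels in cohort.schema.items():
        if name not in df.columns:
            flag(f"covariate column {name!r} missing from episodes")
            continue
        if df[name].isna().any():
            flag(f"covariate {name!r}: missing values are not allowed")
        unseen = set(df[name].dropna().astype(str)) - set(levels)
        if unseen:
            flag(f"covariate {name!r}: labels {sorted(unseen)} not in schema")

    # per-individual ordering: ranks consecutive from 1, order = min(rank, k_max)
    for ind, grp in df.groupby("individual_id", sort=False):
        ranks = grp["original_rank"].tolist()
        if ranks != list(range(1, len(ranks) + 1)):
            flag(f"individual {ind}: original ranks {ranks} not consecutive from 1")
        expect = [min(r, cohort.k_max) for r in ranks]
        if grp["order_k"].tolist() != expect:
            flag(f"individual {ind}: order_k != min(rank, {cohort.k_max})")
    # contiguity of individuals
    ids = df["individual_id"].to_numpy()
    first_seen: dict = {}
    prev = object()
    for i, v in enumerate(ids):
        if v != prev and v in first_seen:
            flag(f"individual {v}: episodes not contiguous")
            break
        first_seen.setdefault(v, i)
        prev = v
    return rep


def read_episodes(path) -> pd.DataFrame:
    """Read the episode CSV dialect (header required, UTF-8)."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ("individual_id", "duration_days", "event") if c not in df.columns]
    if missing:
        raise ValidationError(f"episode file {path}: missing column(s) {missing}")
    return df


def write_episodes(cohort: Cohort, path) -> None:
    cohort.episodes.to_csv(path, index=False, encoding="utf-8")
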