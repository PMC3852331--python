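"""Person-period expansion: gap-time episodes -> piecewise-exponential layout.

The follow-up of each episode is split over a grid of left-open right-closed
intervals ``(tau_j, tau_{j+1}]`` (the last interval is open-ended).  Each
(episode, interval) cell becomes one person-period record with its exposure
``n_jik`` (days at risk inside the interval) and event indicator ``d_jik``
(1 only on the terminal record of an uncensored episode).  A Poisson
regression of ``d`` with offset ``log n`` on these records is the
piecewise-exponential likelihood, which is how the model family in
:mod:`recurfrail.models` is estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .episodes import Cohort, Episode, ValidationError

__all__ = [
    "IntervalGrid",
    "build_interval_grid",
    "grid_from_durations",
    "expand_episode",
    "expand_cohort",
    "zero_event_cells",
    "read_person_period",
    "write_person_period",
]

PERSON_PERIOD_COLUMNS = ("individual_id", "order_k", "interval_j",
                         "exposure_days", "event")


@dataclass(frozen=True)
class IntervalGrid:
    """Cut points ``0 = tau_1 < tau_2 < ... < tau_J`` in days.

    Interval ``j`` is ``(cuts[j-1], cuts[j]]`` for ``j < J`` and
    ``(cuts[J-1], inf)`` for the final, open-ended interval, so a duration
    equal to a cut point belongs to the earlier interval.
    """

    cuts: tuple[int, ...]

    def __post_init__(self):
        if len(self.cuts) < 1 or self.cuts[0] != 0:
            raise ValueError("grid cuts must start at 0")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("grid cuts must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return len(self.cuts)

    def interval_index(self, t) -> np.ndarray:
        """1-based interval index of time(s) ``t`` (t > 0)."""
        idx = np.searchsorted(np.asarray(self.cuts), np.asarray(t), side="left")
        return np.clip(idx, 1, self.n_intervals)


def build_interval_grid(interval_length_days: int, horizon_days: int) -> IntervalGrid:
    """Equal-length grid ``(0, L, 2L, ...)`` covering ``horizon_days``.

    The default interval length in this package is 90 days; the final
    interval is always open-ended beyond the last cut.
    """
    if interval_length_days < 1:
        raise ValueError(f"interval_length_days must be >= 1, got {interval_length_days}")
    if horizon_days < interval_length_days:
        raise ValueError("horizon_days must be >= interval_length_days")
    n = horizon_days // interval_length_days
    return IntervalGrid(tuple(interval_length_days * j for j in range(n + 1)))


def grid_from_durations(durations, interval_length_days: int = 90) -> IntervalGrid:
    """Data-driven grid: max duration rounded up to a whole interval."""
    mx = int(np.max(durations))
    horizon = interval_length_days * math.ceil(mx / interval_length_days)
    return build_interval_grid(interval_length_days, max(horizon, interval_length_days))


def expand_episode(episode: Episode, grid: IntervalGrid) -> list[dict]:
    """Split one episode into person-period records.

    Exposure sums to ``duration_days`` exactly; the event indicator sits on
    the terminal record only.
    """
    d = int(episode.duration_days)
    if d < 1:
        raise ValidationError(
            f"episode of individual {episode.individual_id}: duration {d} < 1")
    last_j = int(grid.interval_index(d))
    records = []
    for j in range(1, last_j + 1):
        lo = grid.cuts[j - 1]
        hi = grid.cuts[j] if j < grid.n_intervals else math.inf
        exposure = min(d, hi) - lo
        rec = {
            "individual_id": episode.individual_id,
            "order_k": episode.order_k,
            "interval_j": j,
            "exposure_days": int(exposure),
            "event": int(episode.event) if j == last_j else 0,
        }
        rec.update(episode.covariates)
        records.append(rec)
    return records


def expand_cohort(cohort: Cohort, grid: IntervalGrid) -> pd.DataFrame:
    """Vectorised person-period expansion of a whole cohort.

    Returns a DataFrame with one row per (episode, interval) cell, ordered by
    (individual, episode rank, interval), plus an ``episode`` column that
    numbers the source episodes so the expansion is invertible.
    """
    df = cohort.episodes
    if len(df) == 0:
        cols = list(PERSON_PERIOD_COLUMNS) + ["episode"] + cohort.covariate_names
        return pd.DataFrame(columns=cols)

    durations = df["duration_days"].to_numpy(dtype=np.int64)
    if (durations < 1).any():
        bad = df.index[durations < 1].tolist()
        raise ValidationError(f"episodes with duration < 1 at rows {bad[:10]}")
    cuts = np.asarray(grid.cuts, dtype=np.int64)
    n_pieces = grid.interval_index(durations)

    ep_idx = np.repeat(np.arange(len(df)), n_pieces)
    interval_j = np.concatenate([np.arange(1, n + 1) for n in n_pieces])
    lo = cuts[interval_j - 1]
    hi = np.where(interval_j < grid.n_intervals, cuts[np.minimum(interval_j, grid.n_intervals - 1)],
                  np.iinfo(np.int64).max)
    exposure = np.minimum(durations[ep_idx], hi) - lo
    is_last = np.concatenate([(np.arange(1, n + 1) == n) for n in n_pieces])
    event = np.where(is_last, df["event"].to_numpy()[ep_idx], 0)

    out = pd.DataFrame({
        "individual_id": df["individual_id"].to_numpy()[ep_idx],
        "order_k": df["order_k"].to_numpy()[ep_idx],
        "interval_j": interval_j,
        "exposure_days": exposure.astype(np.int64),
        "event": event.astype(np.int64),
        "episode": ep_idx,
    })
    for c in cohort.covariate_names:
        out[c] = df[c].to_numpy()[ep_idx]
    return out


def zero_event_cells(person_period: pd.DataFrame, by_order: bool) -> list[tuple]:
    """Baseline cells with positive exposure but no events.

    The log-hazard of such a cell is unidentified (the MLE is -inf); the
    fitter pins them at a hazard floor, and this helper names them so the
    user can coarsen the grid instead.
    """
    keys = ["interval_j", "order_k"] if by_order else ["interval_j"]
    g = person_period.groupby(keys)["event"].sum()
    return [k if isinstance(k, tuple) else (k,) for k, v in g.items() if v == 0]


def read_person_period(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in PERSON_PERIOD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"person-period file {path}: missing column(s) {missing}")
    return df


def write_person_period(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")
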