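"""Time- and error-based performance indicators from move logs.

The unit of analysis is the per-board *search time*: the sum of the elapsed
times of all false moves leading up to, and including, the correct move on
that board. Board-level times are filtered once with Tukey fences
(``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]``, quartiles by linear interpolation) per
grouping, trials containing an outlying board are excluded, and hint-assisted
boards are excluded from the without-hints statistics. Search efficiency is
summarized by the *search slope* — the rate of increase of search time with
set size (seconds per item) — estimated by OLS on per-board times, with an
optional gamma-family GLM cross-check mirroring the distributional
assumption appropriate for positively skewed response times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import gmean

from .generator import LevelSpec
from .session import LOG_COLUMNS, MoveLogEntry, SessionLog

__all__ = [
    "MetricsError",
    "PerformanceSummary",
    "FilterResult",
    "SlopeFit",
    "board_search_time",
    "board_table",
    "filter_outliers",
    "processing_time_per_item",
    "search_slope",
    "summarize_session",
]


class MetricsError(ValueError):
    """Invalid or incomplete input to a metrics computation."""


@dataclass(frozen=True)
class PerformanceSummary:
    """The session-level performance indicators.

    Without-hints fields are ``None`` when every board used a hint (missing,
    not zero). ``search_slope`` is ``None`` when fewer than two distinct set
    sizes remain.
    """

    task_completion_time: float  # minutes, all moves
    avg_search_time_with_hints: float  # seconds
    avg_search_time_without_hints: float | None  # seconds
    geometric_mean_search_time: float | None  # seconds, hint-free boards
    processing_time_per_item: float | None  # seconds/item, hint-free boards
    search_slope: float | None  # seconds per item of set size
    n_false_moves: int
    n_hints: int
    n_trials_excluded_outlier: int


class FilterResult(NamedTuple):
    mask: np.ndarray  # True = retained
    retained: np.ndarray
    n_removed: int


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    stderr: float
    intercept: float
    n: int


def _entries_frame(entries: "pd.DataFrame | SessionLog | Iterable[MoveLogEntry]") -> pd.DataFrame:
    if isinstance(entries, pd.DataFrame):
        df = entries
    elif isinstance(entries, SessionLog):
        df = entries.to_dataframe()
    else:
        df = pd.DataFrame([e.to_row() for e in entries], columns=LOG_COLUMNS)
    if df.empty:
        raise MetricsError("empty move log")
    return df


def board_search_time(entries: "pd.DataFrame | Iterable[MoveLogEntry]") -> float:
    """Search time for one board: elapsed times of all false moves leading
    up to the correct move, plus the correct move itself, summed."""
    df = _entries_frame(entries)
    if (df["elapsed_time"] <= 0).any():
        raise MetricsError("elapsed_time must be strictly positive")
    n_correct = int((df["accuracy"] == "correct").sum())
    if n_correct != 1:
        raise MetricsError(f"board must end with exactly one correct move, got {n_correct}")
    if df["accuracy"].iloc[-1] != "correct":
        raise MetricsError("the correct move must be the last entry for the board")
    return float(df["elapsed_time"].sum())


def board_table(log: "pd.DataFrame | SessionLog") -> pd.DataFrame:
    """Collapse a move log to one row per board.

    Columns: participant_id, group, trial_id, board_index, w, h, t,
    set_size, search_time, hint_used (of the correct move), n_false.
    """
    df = _entries_frame(log)
    keys = ["participant_id", "group", "trial_id", "board_index"]
    rows = []
    for key, sub in df.groupby(keys, sort=False):
        rows.append(
            {
                **dict(zip(keys, key)),
                "w": int(sub["w"].iloc[0]),
                "h": int(sub["h"].iloc[0]),
                "t": int(sub["t"].iloc[0]),
                "set_size": int(sub["w"].iloc[0]) * int(sub["h"].iloc[0]),
                "search_time": board_search_time(sub),
                "hint_used": bool(sub["hint_used"].any()),
                "n_false": int((sub["accuracy"] == "false").sum()),
            }
        )
    return pd.DataFrame(rows)


def filter_outliers(
    values: Sequence[float],
    groups: Sequence | None = None,
) -> FilterResult:
    """Single-pass Tukey-fence outlier filter, applied per group.

    Values outside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` of their group are
    dropped; quartiles use linear interpolation between order statistics.
    Groups with fewer than 4 observations are passed through untouched with
    a warning. The rule is applied once, not iterated.
    """
    vals = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(len(vals), dtype=int)
    groups = np.asarray(groups)
    if len(groups) != len(vals):
        raise MetricsError("values and groups must have equal length")
    mask = np.ones(len(vals), dtype=bool)
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 4:
            warnings.warn(
                f"group {g!r} has {len(idx)} observations (<4): outlier filter skipped",
                stacklevel=2,
            )
            continue
        q1, q3 = np.percentile(vals[idx], [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        mask[idx] = (vals[idx] >= lo) & (vals[idx] <= hi)
    return FilterResult(mask, vals[mask], int((~mask).sum()))


def processing_time_per_item(search_time: float, level: "LevelSpec | int") -> float:
    """Search time divided by the number of items in the display (w*h)."""
    if search_time < 0:
        raise MetricsError("search_time must be non-negative")
    set_size = level if isinstance(level, int) else level.set_size
    return search_time / set_size


def search_slope(
    records: pd.DataFrame,
    group_col: str | None = None,
    gamma: bool = False,
    gamma_link: str = "log",
):
    """Search slope: seconds of search time per item of set size.

    ``records`` needs columns ``search_time`` and ``set_size`` (plus
    ``group_col`` if given). The primary estimator is OLS on per-board
    search times, fitted per group; returns a :class:`SlopeFit` (or a dict
    of them keyed by group). With ``gamma=True`` additionally returns a
    fitted gamma-family GLM with a set size x group interaction as a
    distributional cross-check (log link by default for numerical
    stability; the canonical inverse link is also accepted).
    """
    if "search_time" not in records or "set_size" not in records:
        raise MetricsError("records must have 'search_time' and 'set_size' columns")
    if records["set_size"].nunique() < 2:
        raise MetricsError("search slope needs at least 2 distinct set sizes")

    def _ols(sub: pd.DataFrame) -> SlopeFit:
        x = sm.add_constant(sub["set_size"].to_numpy(dtype=float))
        fit = sm.OLS(sub["search_time"].to_numpy(dtype=float), x).fit()
        return SlopeFit(
            slope=float(fit.params[1]),
            stderr=float(fit.bse[1]),
            intercept=float(fit.params[0]),
            n=int(fit.nobs),
        )

    if group_col is None:
        primary = _ols(records)
    else:
        primary = {
            g: _ols(sub)
            for g, sub in records.groupby(group_col, sort=True)
            if sub["set_size"].nunique() >= 2
        }
    if not gamma:
        return primary
    links = {"log": sm.families.links.Log(), "inverse": sm.families.links.InversePower()}
    family = sm.families.Gamma(link=links[gamma_link])
    if group_col is None:
        formula = "search_time ~ set_size"
    else:
        formula = f"search_time ~ set_size * C({group_col})"
    glm_fit = smf.glm(formula, data=records, family=family).fit()
    return primary, glm_fit


def summarize_session(
    log: "pd.DataFrame | SessionLog",
    outlier_groups: str | None = None,
    apply_outlier_filter: bool = True,
) -> PerformanceSummary:
    """Compute all performance indicators for a move log.

    Processing order: collapse to boards, filter outlying board search
    times once (per ``outlier_groups`` column if given, else pooled) and
    drop the trials containing them, then compute the without-hints
    statistics on the hint-free remainder. False-move and hint counts are
    raw totals over the whole log.
    """
    df = _entries_frame(log)
    boards = board_table(df)
    completion_min = float(df["elapsed_time"].sum()) / 60.0
    n_false = int((df["accuracy"] == "false").sum())
    n_hints = int(boards["hint_used"].sum())

    n_excluded_trials = 0
    n_trials = boards.groupby(["participant_id", "trial_id"]).ngroups
    if apply_outlier_filter and len(boards) >= 4 and n_trials >= 4:
        groups = boards[outlier_groups] if outlier_groups else None
        res = filter_outliers(boards["search_time"].to_numpy(), groups)
        bad_trials = set(
            zip(
                boards.loc[~res.mask, "participant_id"],
                boards.loc[~res.mask, "trial_id"],
            )
        )
        n_excluded_trials = len(bad_trials)
        keep = [
            (p, t) not in bad_trials
            for p, t in zip(boards["participant_id"], boards["trial_id"])
        ]
        boards = boards.loc[keep]
    if boards.empty:
        raise MetricsError("no boards remain after outlier filtering")

    avg_with = float(boards["search_time"].mean())
    nohint = boards.loc[~boards["hint_used"]]
    if nohint.empty:
        avg_without = geo = ptpi = slope_val = None
    else:
        avg_without = float(nohint["search_time"].mean())
        geo = float(gmean(nohint["search_time"]))
        ptpi = float((nohint["search_time"] / nohint["set_size"]).mean())
        if nohint["set_size"].nunique() >= 2:
            slope_val = float(search_slope(nohint).slope)
        else:
            slope_val = None
    return PerformanceSummary(
        task_completion_time=completion_min,
        avg_search_time_with_hints=avg_with,
        avg_search_time_without_hints=avg_without,
        geometric_mean_search_time=geo,
        processing_time_per_item=ptpi,
        search_slope=slope_val,
        n_false_moves=n_false,
        n_hints=n_hints,
        n_trials_excluded_outlier=n_excluded_trials,
    )
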