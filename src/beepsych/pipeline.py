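"""Reduction of flower-visitation event logs to psychometric response data.

An event log is a time-ordered table of individual feeder visits (one row
per landing) carrying the bee identity (RFID tag string, or ``UNMARKED`` for
untagged foragers), the feeder, its petal color, the sucrose concentration
offered, and whether the visit was rewarded (a visit during a feeder's 10-s
refill delay yields no nectar).  The per-session condition table records
which concentration each color held on each day; the assignment reverses on
consecutive days to cancel positional and color biases.

The reduction drops each marked bee's first 800 visits of a day (the
sampling/exploration phase before plateau performance), converts the rest to
binomial responses — visits to the sweeter color out of all visits — and
pools the two reversal days of a condition by their visit counts.  Secondary
analyses cover marked/unmarked concordance, non-reward rates per
concentration class, win-stay/lose-shift sequential choice, and binned
learning curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fit import ResponseRecord

__all__ = [
    "UNMARKED",
    "DayCondition",
    "EVENT_COLUMNS",
    "read_event_csv",
    "read_condition_csv",
    "write_condition_csv",
    "relative_intensity",
    "plateau_filter_marked",
    "plateau_filter_unmarked",
    "estimate_unmarked_count",
    "daily_response",
    "combine_reversal_pair",
    "reduce_sessions",
    "marked_unmarked_concordance",
    "ConcordanceResult",
    "nonreward_analysis",
    "shift_probability_analysis",
    "learning_curve",
    "PairedTResult",
]

UNMARKED = "UNMARKED"

EVENT_COLUMNS = [
    "time_s",
    "bee_id",
    "feeder_id",
    "color",
    "concentration",
    "rewarded",
]

SESSION_SECONDS = 12 * 3600  # a foraging session runs 12 h


@dataclass(frozen=True)
class DayCondition:
    """One session: which concentration each petal color offered."""

    colony: int
    day: int
    conc_blue: float
    conc_yellow: float

    def __post_init__(self) -> None:
        if self.conc_blue <= 0 or self.conc_yellow <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def intensity(self) -> float:
        return relative_intensity(self.conc_blue, self.conc_yellow)

    @property
    def sweeter_color(self) -> str:
        """Color holding the higher concentration; 'blue' on equal days."""
        return "yellow" if self.conc_yellow > self.conc_blue else "blue"


def relative_intensity(c1: float, c2: float) -> float:
    """Weber-fraction-like stimulus intensity of a concentration pair.

    The absolute difference of the two concentrations (% w/w) divided by
    their mean — increasing in the difference (distance effect), decreasing
    in the common magnitude (magnitude effect).  Symmetric; in [0, 2).
    """
    if c1 <= 0 or c2 <= 0:
        raise ValueError(f"concentrations must be positive, got ({c1}, {c2})")
    return abs(c1 - c2) / ((c1 + c2) / 2.0)


# ---------------------------------------------------------------------------
# event-log IO

def read_event_csv(path) -> pd.DataFrame:
    """Read an event log; validates columns and per-session time ordering."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event CSV lacks columns: {sorted(missing)}")
    if "day" not in df.columns:
        df["day"] = 1
    df["rewarded"] = df["rewarded"].astype(bool)
    for day, grp in df.groupby("day"):
        if not grp.time_s.is_monotonic_increasing:
            raise ValueError(f"timestamps not non-decreasing within day {day}")
    return df


def read_condition_csv(path) -> list[DayCondition]:
    df = pd.read_csv(path)
    return [
        DayCondition(int(r.colony), int(r.day), float(r.conc_blue), float(r.conc_yellow))
        for r in df.itertuples()
    ]


def write_condition_csv(conditions: Sequence[DayCondition], path) -> None:
    pd.DataFrame(
        [
            {
                "colony": c.colony,
                "day": c.day,
                "conc_blue": c.conc_blue,
                "conc_yellow": c.conc_yellow,
            }
            for c in conditions
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# plateau filtering

def plateau_filter_marked(events: pd.DataFrame, cutoff: int = 800) -> pd.DataFrame:
    """Drop each marked bee's first ``cutoff`` visits of each day.

    Unmarked rows are excluded (they are filtered collectively with
    :func:`plateau_filter_unmarked`).  A bee with at most ``cutoff`` visits
    on a day contributes nothing for that day.
    """
    marked = events[events.bee_id != UNMARKED]
    if marked.empty:
        return marked
    rank = marked.groupby([marked.bee_id, marked.get("day", 1)]).cumcount()
    return marked[rank >= cutoff]


def plateau_filter_unmarked(
    events: pd.DataFrame, n_bees_estimate: float, cutoff: int = 800
) -> pd.DataFrame:
    """Drop the first ``round(cutoff * n_bees_estimate)`` unmarked visits per day.

    Approximates the per-bee plateau cut for the anonymous pool, whose
    individual visit sequences cannot be separated.
    """
    unmarked = events[events.bee_id == UNMARKED]
    if unmarked.empty:
        return unmarked
    m = int(round(cutoff * n_bees_estimate))
    rank = unmarked.groupby(unmarked.get("day", 1)).cumcount()
    return unmarked[rank >= m]


def estimate_unmarked_count(
    total_unmarked_visits: float, mean_marked_daily_visits: float
) -> float:
    """Estimated number of unmarked foragers behind a day's anonymous visits."""
    if mean_marked_daily_visits <= 0:
        raise ValueError("mean_marked_daily_visits must be positive")
    return total_unmarked_visits / mean_marked_daily_visits


# ---------------------------------------------------------------------------
# responses

def daily_response(
    events: pd.DataFrame, condition: DayCondition
) -> ResponseRecord | None:
    """Binomial response of one bee group on one day, or None if no visits.

    ``n_sweeter`` counts visits to the color holding the higher
    concentration that day.  On equal-concentration days the record is still
    formed (intensity 0 would be meaningless for fitting, so the nominal
    day intensity is attached by the caller; here blue is used as the
    reference class) but such days are excluded from psychometric fits.
    """
    if events.empty:
        return None
    n_total = len(events)
    n_sweeter = int((events.color == condition.sweeter_color).sum())
    if condition.intensity == 0:
        # degenerate equal-concentration day: counts kept, intensity flagged
        return _unchecked_record(np.nan, n_sweeter, n_total)
    return ResponseRecord(condition.intensity, n_sweeter, n_total)


def _unchecked_record(intensity, n_sweeter, n_total) -> ResponseRecord:
    rec = ResponseRecord.__new__(ResponseRecord)
    object.__setattr__(rec, "intensity_x", float(intensity))
    object.__setattr__(rec, "n_sweeter", int(n_sweeter))
    object.__setattr__(rec, "n_total", int(n_total))
    return rec


def combine_reversal_pair(
    records: Sequence[ResponseRecord | None],
) -> ResponseRecord | None:
    """Pool the two reversal-day presentations of one condition.

    Counts are summed, which equals the visit-weighted average of the two
    daily responses.  A single surviving record passes through; two missing
    records give None.
    """
    present = [r for r in records if r is not None]
    if not present:
        return None
    if len(present) == 1:
        return present[0]
    xvals = [r.intensity_x for r in present]
    if all(np.isnan(v) for v in xvals):
        return _unchecked_record(
            np.nan,
            sum(r.n_sweeter for r in present),
            sum(r.n_total for r in present),
        )
    xs = {round(v, 6) for v in xvals}
    if len(xs) != 1:
        raise ValueError(f"cannot pool records with different intensities: {xs}")
    return ResponseRecord(
        present[0].intensity_x,
        sum(r.n_sweeter for r in present),
        sum(r.n_total for r in present),
    )


def reduce_sessions(
    events: pd.DataFrame,
    conditions: Sequence[DayCondition],
    cutoff: int = 800,
    min_marked_visits: int = 50,
) -> dict[str, list[ResponseRecord]]:
    """Full reduction of a multi-day event log to fit-ready response records.

    Returns response-record lists per group: one entry per marked bee (keyed
    by tag), plus ``UNMARKED`` for the anonymous pool.  Marked bees are
    plateau-filtered per day; the unmarked pool is cut by the estimated
    per-bee equivalent.  Reversal-day pairs (consecutive days with the same
    unordered concentration pair) are pooled; zero-intensity days dropped.
    """
    cond_by_day = {c.day: c for c in conditions}
    unknown = set(events.get("day", pd.Series([1])).unique()) - set(cond_by_day)
    if unknown:
        raise ValueError(f"events reference days without conditions: {sorted(unknown)}")

    marked_all = events[events.bee_id != UNMARKED]
    daily_per_bee = marked_all.groupby(["bee_id", "day"]).size()
    active = daily_per_bee[daily_per_bee >= min_marked_visits]
    mean_daily = float(active.mean()) if len(active) else np.nan

    # pair consecutive days sharing the same unordered concentration pair
    days = sorted(cond_by_day)
    pairs: list[list[int]] = []
    used: set[int] = set()
    for d in days:
        if d in used:
            continue
        pair = [d]
        nxt = d + 1
        if nxt in cond_by_day and {
            cond_by_day[d].conc_blue,
            cond_by_day[d].conc_yellow,
        } == {cond_by_day[nxt].conc_blue, cond_by_day[nxt].conc_yellow}:
            pair.append(nxt)
            used.add(nxt)
        pairs.append(pair)

    out: dict[str, list[ResponseRecord]] = {}

    def add(group: str, day_records: dict[int, ResponseRecord | None]) -> None:
        recs = []
        for pair in pairs:
            combined = combine_reversal_pair([day_records.get(d) for d in pair])
            if combined is not None and not np.isnan(combined.intensity_x):
                recs.append(combined)
        if recs:
            out[group] = recs

    filtered_marked = plateau_filter_marked(events, cutoff)
    for bee, grp in filtered_marked.groupby("bee_id"):
        add(
            str(bee),
            {
                int(day): daily_response(sub, cond_by_day[int(day)])
                for day, sub in grp.groupby("day")
            },
        )

    unmarked = events[events.bee_id == UNMARKED]
    if not unmarked.empty and np.isfinite(mean_daily):
        day_records = {}
        for day, sub in unmarked.groupby("day"):
            n_bees = estimate_unmarked_count(len(sub), mean_daily)
            kept = sub.iloc[int(round(cutoff * n_bees)):]
            day_records[int(day)] = daily_response(kept, cond_by_day[int(day)])
        add(UNMARKED, day_records)
    return out


# ---------------------------------------------------------------------------
# concordance

@dataclass(frozen=True)
class ConcordanceResult:
    rho: float
    s_statistic: float
    p_value: float
    n: int


def marked_unmarked_concordance(day_table: pd.DataFrame) -> ConcordanceResult:
    """Spearman rank correlation between marked and unmarked daily responses.

    ``day_table`` needs columns ``marked_response`` and ``unmarked_response``;
    days lacking either response are excluded.  Ties get midranks, and the
    ``S`` statistic is reported on the classical sum-of-squared-rank-
    differences scale, ``S = (1 - rho) * n (n^2 - 1) / 6``, which is
    fractional under ties.
    """
    df = day_table.dropna(subset=["marked_response", "unmarked_response"])
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 complete day pairs, got {n}")
    res = stats.spearmanr(df.marked_response, df.unmarked_response)
    rho = float(res.statistic)
    s = (1.0 - rho) * n * (n * n - 1) / 6.0
    return ConcordanceResult(rho, float(s), float(res.pvalue), n)


# ---------------------------------------------------------------------------
# paired t helper

@dataclass(frozen=True)
class PairedTResult:
    statistic: float
    p_value: float
    df: int
    mean_difference: float
    zero_variance: bool = False


def _paired_t(a: np.ndarray, b: np.ndarray) -> PairedTResult:
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    if n < 2:
        raise ValueError("paired t needs at least 2 pairs")
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTResult(np.nan, np.nan, n - 1, float(d.mean()), True)
    res = stats.ttest_rel(a, b)
    return PairedTResult(
        float(res.statistic), float(res.pvalue), n - 1, float(d.mean())
    )


# ---------------------------------------------------------------------------
# non-reward analysis

def nonreward_analysis(
    events: pd.DataFrame, conditions: Sequence[DayCondition]
) -> dict:
    """Per-day proportion of non-rewarded visits at each concentration class.

    A non-rewarded visit falls within a feeder's refill delay.  Days are
    paired by class (lower- vs higher-concentration feeders that day) and
    compared with a two-sided paired t test; equal-concentration days, and
    days with no visits in one class, are dropped (and listed in the output).
    """
    cond_by_day = {c.day: c for c in conditions}
    rows, dropped = [], []
    for day, grp in events.groupby(events.get("day", 1)):
        cond = cond_by_day[int(day)]
        if cond.conc_blue == cond.conc_yellow:
            dropped.append(int(day))
            continue
        hi_color = cond.sweeter_color
        hi = grp[grp.color == hi_color]
        lo = grp[grp.color != hi_color]
        if hi.empty or lo.empty:
            dropped.append(int(day))
            continue
        rows.append(
            {
                "day": int(day),
                "p_nonreward_low": float((~lo.rewarded).mean()),
                "p_nonreward_high": float((~hi.rewarded).mean()),
            }
        )
    table = pd.DataFrame(rows)
    result: dict = {"per_day": table, "dropped_days": dropped, "t_test": None}
    if len(table) >= 2:
        result["t_test"] = _paired_t(
            table.p_nonreward_low.to_numpy(), table.p_nonreward_high.to_numpy()
        )
    return result


# ---------------------------------------------------------------------------
# sequential (win-stay / lose-shift) analysis

_PATTERNS = ("RR", "RN", "NN")


def shift_probability_analysis(
    events: pd.DataFrame,
    conditions: Sequence[DayCondition],
    target_intensity: float = 0.67,
    preference_floor: float = 0.90,
    window: int = 800,
    intensity_tol: float = 0.005,
) -> dict:
    """Conditional probabilities of shifting away from the sweeter color.

    For each marked bee's first ``window`` visits on days whose relative
    intensity matches ``target_intensity``, find every run of two
    consecutive visits to the high-concentration color and classify the two
    reward outcomes as RR, RN (reward then none) or NN; the event of
    interest is whether the *next* visit samples the low-concentration
    color.  Bees whose high-color preference in the window never exceeds
    ``preference_floor`` are excluded, as are bees lacking occurrences of a
    pattern (per contrast).  Two paired t tests compare shift probability
    after NN against RN (negative-incentive prediction 1) and against RR
    (prediction 2).
    """
    cond_by_day = {c.day: c for c in conditions}
    per_bee: dict[str, dict[str, list[int]]] = {}
    excluded: list[str] = []

    marked = events[events.bee_id != UNMARKED]
    for bee, bee_events in marked.groupby("bee_id"):
        counts = {p: [0, 0] for p in _PATTERNS}  # pattern -> [shifts, occurrences]
        qualified = False
        for day, grp in bee_events.groupby("day"):
            cond = cond_by_day[int(day)]
            if abs(cond.intensity - target_intensity) > intensity_tol:
                continue
            sub = grp.iloc[:window]
            hi_color = cond.sweeter_color
            is_hi = (sub.color == hi_color).to_numpy()
            rewarded = sub.rewarded.to_numpy()
            if len(sub) < 3 or is_hi.mean() <= preference_floor:
                continue
            qualified = True
            for i in range(1, len(sub) - 1):
                if is_hi[i - 1] and is_hi[i]:
                    if rewarded[i - 1] and rewarded[i]:
                        pat = "RR"
                    elif rewarded[i - 1] and not rewarded[i]:
                        pat = "RN"
                    elif not rewarded[i - 1] and not rewarded[i]:
                        pat = "NN"
                    else:  # non-reward then reward: outside the tested set
                        continue
                    counts[pat][1] += 1
                    counts[pat][0] += int(not is_hi[i + 1])
        if qualified:
            per_bee[str(bee)] = counts
        else:
            excluded.append(str(bee))

    probs = pd.DataFrame(
        {
            pat: {
                bee: (c[pat][0] / c[pat][1] if c[pat][1] else np.nan)
                for bee, c in per_bee.items()
            }
            for pat in _PATTERNS
        }
    )
    result: dict = {"per_bee": probs, "excluded_bees": excluded}
    for name, (p1, p2) in {
        "prediction1_NN_vs_RN": ("NN", "RN"),
        "prediction2_NN_vs_RR": ("NN", "RR"),
    }.items():
        sub = probs[[p1, p2]].dropna()
        result[name] = (
            _paired_t(sub[p1].to_numpy(), sub[p2].to_numpy())
            if len(sub) >= 2
            else None
        )
    return result


# ---------------------------------------------------------------------------
# learning curves

def learning_curve(
    events: pd.DataFrame, condition: DayCondition, bin_size: int = 100
) -> pd.DataFrame:
    """Proportion of visits to the sweeter color in consecutive visit bins.

    The final partial bin is reported with its actual size.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    is_sweet = (events.color == condition.sweeter_color).to_numpy()
    rows = []
    for start in range(0, len(is_sweet), bin_size):
        chunk = is_sweet[start : start + bin_size]
        rows.append(
            {
                "bin": start // bin_size,
                "n_visits": len(chunk),
                "proportion_sweeter": float(chunk.mean()),
            }
        )
    return pd.DataFrame(rows)
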