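"""Published summary data from the two-colony bumblebee discrimination study.

Two *Bombus impatiens* colonies foraged on a 20-feeder array offering two
sucrose concentrations (blue vs. yellow petals, 10 feeders each), with the
concentration–color assignment reversed on consecutive days.  The raw RFID
visit logs were not deposited, but the study's day-by-day summary table and
the fitted psychometric parameters were printed and are reproduced here as
programmatic fixtures: daily conditions, bee counts, visit totals (in
thousands, after the plateau cut) and discrimination responses for marked
and unmarked bees, plus the reported posterior estimates per dataset.

Missing cells (days on which no marked bee cleared the 800-visit plateau
criterion) are NaN, never zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import ResponseRecord
from .pipeline import combine_reversal_pair

__all__ = [
    "day_table",
    "unmarked_response_records",
    "reported_fits",
    "individual_slope_stats",
]

_NA = float("nan")

# colony, day, conc_blue, conc_yellow, intensity, n_marked, n_unmarked_est,
# marked_visits_k, unmarked_visits_k, marked_response, unmarked_response
_DAY_ROWS = [
    (1, 1, 30, 15, 0.67, 0, 0, _NA, _NA, _NA, _NA),
    (1, 2, 15, 30, 0.67, 1, 5, 0.59, 0.90, 0.96, 0.98),
    (1, 3, 45, 30, 0.40, 1, 4, 1.04, 0.76, 0.87, 0.94),
    (1, 4, 30, 45, 0.40, 0, 6, _NA, 0.77, _NA, 0.95),
    (1, 5, 30, 20, 0.40, 0, 7, _NA, 0.94, _NA, 0.87),
    (1, 6, 20, 30, 0.40, 1, 9, 0.02, 1.52, 0.92, 0.88),
    (1, 7, 45, 50, 0.11, 1, 8, 1.90, 1.71, 0.71, 0.70),
    (1, 8, 50, 45, 0.11, 0, 9, _NA, 1.82, _NA, 0.62),
    (1, 9, 35, 45, 0.25, 0, 6, _NA, 0.86, _NA, 0.79),
    (1, 10, 45, 35, 0.25, 1, 9, 1.20, 1.85, 0.83, 0.80),
    (1, 11, 30, 32, 0.06, 1, 7, 0.11, 1.62, 0.45, 0.48),
    (1, 12, 32, 30, 0.06, 1, 9, 0.44, 1.50, 0.49, 0.46),
    (1, 13, 40, 20, 0.67, 2, 13, 3.01, 2.39, 0.89, 0.89),
    (1, 14, 20, 40, 0.67, 2, 12, 4.45, 1.98, 0.92, 0.90),
    (1, 15, 35, 39, 0.11, 2, 14, 1.49, 2.56, 0.83, 0.67),
    (1, 16, 39, 35, 0.11, 1, 17, 0.47, 3.12, 0.56, 0.63),
    (2, 1, 50, 45, 0.11, 5, 20, 3.35, 5.01, 0.52, 0.57),
    (2, 2, 45, 50, 0.11, 2, 10, 0.06, 2.40, 0.52, 0.57),
    (2, 3, 45, 30, 0.40, 0, 11, _NA, 2.73, _NA, 0.85),
    (2, 4, 30, 45, 0.40, 4, 9, 2.71, 2.13, 0.96, 0.92),
    (2, 5, 25, 20, 0.22, 3, 9, 1.20, 2.43, 0.54, 0.65),
    (2, 6, 20, 25, 0.22, 4, 11, 5.51, 2.40, 0.60, 0.62),
    (2, 7, 30, 15, 0.67, 4, 12, 5.64, 2.94, 0.87, 0.84),
    (2, 8, 15, 30, 0.67, 5, 12, 5.31, 3.47, 0.88, 0.79),
    (2, 9, 34, 25, 0.31, 3, 12, 2.65, 2.89, 0.93, 0.91),
    (2, 10, 25, 34, 0.31, 3, 16, 2.92, 3.53, 0.83, 0.66),
    (2, 11, 27, 21, 0.25, 4, 16, 4.36, 3.50, 0.58, 0.56),
    (2, 12, 21, 27, 0.25, 3, 14, 3.16, 3.08, 0.72, 0.68),
]

_DAY_COLUMNS = [
    "colony",
    "day",
    "conc_blue",
    "conc_yellow",
    "intensity",
    "n_marked",
    "n_unmarked_est",
    "marked_visits_k",
    "unmarked_visits_k",
    "marked_response",
    "unmarked_response",
]

# dataset, lapse (lo, mean, hi), threshold (lo, mean, hi), slope (lo, mean, hi), n_days
_FIT_ROWS = [
    ("B20", 0.19, 0.20, 0.21, 0.244, 0.247, 0.251, 10.80, 11.67, 12.59, 7),
    ("B25", 0.33, 0.35, 0.38, 0.22, 0.23, 0.24, 3.19, 4.15, 5.08, 9),
    ("B30", 0.12, 0.13, 0.14, 0.256, 0.26, 0.263, 8.05, 8.82, 9.62, 7),
    ("misc", 0.17, 0.18, 0.19, 0.23, 0.24, 0.26, 2.68, 3.29, 4.35, 24),
    ("unmarked", 0.24, 0.25, 0.26, 0.21, 0.22, 0.23, 2.95, 3.12, 3.29, 27),
    ("pooled", 0.22, 0.23, 0.23, 0.248, 0.251, 0.253, 4.80, 5.30, 5.80, 27),
]


def day_table() -> pd.DataFrame:
    """Day-by-day conditions and responses for both colonies."""
    return pd.DataFrame(_DAY_ROWS, columns=_DAY_COLUMNS)


def reported_fits() -> pd.DataFrame:
    """Reported posterior estimates (mean and 95 % CI) per analysis dataset."""
    cols = ["dataset"]
    for p in ("lapse", "threshold", "slope"):
        cols += [f"{p}_lo", f"{p}_mean", f"{p}_hi"]
    cols.append("n_days")
    return pd.DataFrame(_FIT_ROWS, columns=cols).set_index("dataset")


def individual_slope_stats() -> tuple[float, float]:
    """Mean and SD of the slope posterior means of the three focal bees."""
    slopes = reported_fits().loc[["B20", "B25", "B30"], "slope_mean"].to_numpy()
    return float(slopes.mean()), float(slopes.std(ddof=1))


def unmarked_response_records(colony: int | None = None) -> list[ResponseRecord]:
    """Binomial response records reconstructed from the unmarked-bee columns.

    Visit totals are printed in thousands to two decimals and responses to
    two decimals, so counts carry rounding error of at most five visits.
    Reversal-day pairs of the same concentration condition are pooled by
    summing counts (the visit-weighted average response); a condition whose
    partner day is missing passes through unchanged.
    """
    df = day_table()
    if colony is not None:
        df = df[df.colony == colony]
    records: list[ResponseRecord] = []
    for (_, _), grp in df.groupby(
        ["colony", df.day.sub(1).floordiv(2)], sort=False
    ):
        pair = []
        for row in grp.itertuples():
            if np.isnan(row.unmarked_visits_k) or np.isnan(row.unmarked_response):
                pair.append(None)
                continue
            n = int(round(row.unmarked_visits_k * 1000))
            k = int(round(row.unmarked_response * n))
            pair.append(ResponseRecord(row.intensity, k, n))
        combined = combine_reversal_pair(pair)
        if combined is not None:
            records.append(combined)
    return records
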