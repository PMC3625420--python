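"""Synthetic RFID-style visitation logs with known ground truth.

Emulates the experimental apparatus: a 20-feeder array split into two petal
colors (10 blue, 10 yellow), each color supplied with one sucrose
concentration per 12-h session, concentrations swapping between colors on
consecutive reversal days, and every feeder entering a 10-s refill delay
after dispensing — so visits arriving during the delay go unrewarded, at a
rate set by overall forager traffic rather than by any experimenter dial.

Each simulated bee carries a true psychometric curve; its color choice on a
visit is Bernoulli with probability given by that curve at the session's
relative intensity (directed at whichever color is sweeter that day), with
an optional exponential learning ramp from chance toward the stationary
probability over the first few hundred visits.  Inter-visit intervals are
exponential per bee, the simplest renewal process that produces realistic
refill-delay collisions; feeders within the chosen color are picked
uniformly.  Marked bees carry tag ids; unmarked bees are simulated
individually but logged under the shared ``UNMARKED`` label, exactly as an
RFID reader sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fit import ResponseRecord
from .pipeline import (
    EVENT_COLUMNS,
    SESSION_SECONDS,
    UNMARKED,
    DayCondition,
)
from .psychometric import PsychometricParams, psychometric_value

__all__ = [
    "ColonySimConfig",
    "generate_colony_sessions",
    "generate_binomial_responses",
    "write_event_csv",
]

#: Daily per-bee visit counts observed in the study: mean and SD used to
#: parameterize the lognormal visit-budget distribution.
VISITS_PER_BEE_DAY_MEAN = 1076.0
VISITS_PER_BEE_DAY_SD = 642.0


@dataclass(frozen=True)
class ColonySimConfig:
    """Configuration of one simulated colony experiment."""

    marked_params: Sequence[PsychometricParams]
    unmarked_params: Sequence[PsychometricParams]
    schedule: Sequence[DayCondition]
    visits_mean: float = VISITS_PER_BEE_DAY_MEAN
    visits_sd: float = VISITS_PER_BEE_DAY_SD
    refill_delay_s: float = 10.0
    n_feeders_per_color: int = 10
    learning_tau: float | None = None  # visits-constant of the ramp; None = off
    session_s: float = float(SESSION_SECONDS)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValueError("schedule must contain at least one day")
        if len(self.marked_params) + len(self.unmarked_params) == 0:
            raise ValueError("need at least one bee")
        if self.refill_delay_s < 0:
            raise ValueError("refill_delay_s must be non-negative")
        if self.visits_mean <= 0 or self.visits_sd < 0:
            raise ValueError("visit-count distribution must have positive mean")
        days = [c.day for c in self.schedule]
        if len(days) != len(set(days)):
            raise ValueError("schedule days must be unique")


def _lognormal_counts(rng, mean, sd, size):
    """Integer visit budgets with the requested mean and SD (min 1 visit)."""
    if sd == 0:
        return np.full(size, int(round(mean)))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.maximum(1, np.round(rng.lognormal(mu, np.sqrt(sigma2), size))).astype(int)


def _choice_probability(params, intensity, visit_index, tau):
    """Probability of choosing the sweeter color at a given visit index."""
    if intensity == 0:
        return 0.5
    stationary = psychometric_value(intensity, params)
    if tau is None:
        return stationary
    ramp = 1.0 - np.exp(-visit_index / tau)
    return 0.5 + (stationary - 0.5) * ramp


def generate_colony_sessions(config: ColonySimConfig) -> pd.DataFrame:
    """Simulate every scheduled session and return the merged event log.

    Columns: ``day`` plus the standard event columns (time_s, bee_id,
    feeder_id, color, concentration, rewarded); rows time-ordered within
    each day.  Feeders 1..n carry blue petals, the rest yellow.
    """
    rng = np.random.default_rng(config.seed)
    npc = config.n_feeders_per_color
    bees = [(f"B{i + 1:03d}", p) for i, p in enumerate(config.marked_params)]
    bees += [(UNMARKED, p) for p in config.unmarked_params]

    frames = []
    for cond in sorted(config.schedule, key=lambda c: c.day):
        budgets = _lognormal_counts(
            rng, config.visits_mean, config.visits_sd, len(bees)
        )
        # per-bee visit times: exponential inter-visit intervals at the rate
        # that spends the bee's budget within the session
        times, owner = [], []
        for b, budget in enumerate(budgets):
            scale = config.session_s / (budget + 1)
            t = np.cumsum(rng.exponential(scale, budget))
            t = t[t < config.session_s]
            times.append(t)
            owner.append(np.full(len(t), b))
        t_all = np.concatenate(times)
        o_all = np.concatenate(owner)
        order = np.argsort(t_all, kind="stable")
        t_all, o_all = t_all[order], o_all[order]

        sweeter = cond.sweeter_color
        conc = {"blue": cond.conc_blue, "yellow": cond.conc_yellow}
        intensity = cond.intensity
        visit_counter = np.zeros(len(bees), dtype=int)
        last_dispense = np.full(2 * npc, -np.inf)

        colors = np.empty(len(t_all), dtype=object)
        feeders = np.empty(len(t_all), dtype=int)
        rewarded = np.empty(len(t_all), dtype=bool)
        u_choice = rng.random(len(t_all))
        u_feeder = rng.integers(0, npc, len(t_all))
        for i, (t, b) in enumerate(zip(t_all, o_all)):
            p_sweet = _choice_probability(
                bees[b][1], intensity, visit_counter[b], config.learning_tau
            )
            visit_counter[b] += 1
            pick_sweet = u_choice[i] < p_sweet
            color = sweeter if pick_sweet else ("yellow" if sweeter == "blue" else "blue")
            feeder = int(u_feeder[i]) + (0 if color == "blue" else npc)
            got = t - last_dispense[feeder] > config.refill_delay_s
            if got:
                last_dispense[feeder] = t
            colors[i] = color
            feeders[i] = feeder + 1
            rewarded[i] = got

        frames.append(
            pd.DataFrame(
                {
                    "day": cond.day,
                    "time_s": t_all,
                    "bee_id": [bees[b][0] for b in o_all],
                    "feeder_id": feeders,
                    "color": colors,
                    "concentration": [conc[c] for c in colors],
                    "rewarded": rewarded,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_binomial_responses(
    true_params: PsychometricParams,
    intensities: Sequence[float],
    n_per: int,
    seed: int = 0,
) -> list[ResponseRecord]:
    """Direct binomial response records from a known psychometric curve."""
    if n_per <= 0:
        raise ValueError("n_per must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for x in intensities:
        p = psychometric_value(x, true_params)
        records.append(ResponseRecord(float(x), int(rng.binomial(n_per, p)), n_per))
    return records


def write_event_csv(events: pd.DataFrame, path) -> None:
    """Write an event log in the standard CSV dialect."""
    cols = (["day"] if "day" in events.columns else []) + EVENT_COLUMNS
    events[cols].to_csv(path, index=False)
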