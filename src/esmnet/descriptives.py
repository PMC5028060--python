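"""Per-state descriptive statistics, state contrasts and day-level series.

These summaries answer the bookkeeping questions of a single-subject ESM
study: how severe was each symptom in each clinical state, do the states
differ, what did each day look like on average, and how complete was the
sampling.  Pairwise state contrasts use Welch's two-sample t test (unequal
variances, two-sided, no multiplicity correction) on beep-level ratings;
standard deviations are sample (n-1) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    STATES,
    SYMPTOMS,
    ConfigurationError,
    EsmSeries,
    InsufficientDataError,
)


def _require_states(series: EsmSeries) -> pd.DataFrame:
    if not series.has_states:
        raise ConfigurationError(
            "series must be state-labeled (call derive_states first)"
        )
    return series.answered()


@dataclass(frozen=True)
class StateSummary:
    """Per-(state, symptom) n/mean/sd plus answered beeps per state."""

    table: pd.DataFrame  # tidy: state, symptom, n, mean, sd
    n_beeps: dict[str, int]  # answered beeps per state

    def wide(self, value: str = "mean") -> pd.DataFrame:
        return self.table.pivot(index="symptom", columns="state",
                                values=value).reindex(list(SYMPTOMS))


@dataclass(frozen=True)
class ContrastResult:
    """Welch comparison of one symptom's beep-level ratings between states."""

    symptom: str
    state_a: str
    state_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float

    @property
    def direction(self) -> str:
        if self.mean_a > self.mean_b:
            return "a>b"
        if self.mean_b > self.mean_a:
            return "b>a"
        return "none"


@dataclass(frozen=True)
class CompletionStats:
    """How much of the sampling frame was answered."""

    n_answered: int
    n_scheduled: int
    n_days: int
    fraction: float
    mean_per_day: float
    sd_per_day: float
    min_per_day: int
    max_per_day: int


def state_summary(series: EsmSeries) -> StateSummary:
    """Mean and sample sd of each symptom per state over answered ratings.

    Cells with no observations are reported as missing (never as 0); the sd
    of a single observation is missing as well.
    """
    af = _require_states(series)
    rows = []
    for state in STATES:
        sub = af[af["state"] == state]
        for s in SYMPTOMS:
            vals = sub[s].dropna().astype(float)
            rows.append({
                "state": state,
                "symptom": s,
                "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            })
    n_beeps = {state: int((af["state"] == state).sum()) for state in STATES}
    return StateSummary(table=pd.DataFrame(rows), n_beeps=n_beeps)


def compare_states(series: EsmSeries, symptom: str, state_a: str,
                   state_b: str) -> ContrastResult:
    """Welch two-sample comparison of a symptom between two states."""
    if symptom not in SYMPTOMS:
        raise ConfigurationError(f"unknown symptom '{symptom}'")
    af = _require_states(series)
    a = af.loc[af["state"] == state_a, symptom].dropna().astype(float).to_numpy()
    b = af.loc[af["state"] == state_b, symptom].dropna().astype(float).to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need >= 2 observations per state for '{symptom}' "
            f"({state_a}: {len(a)}, {state_b}: {len(b)})"
        )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return ContrastResult(
        symptom=symptom, state_a=state_a, state_b=state_b,
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        statistic=float(t), p_value=float(p),
    )


def day_level_series(series: EsmSeries) -> pd.DataFrame:
    """Daily mean of answered ratings per symptom (the plot-ready series).

    Indexed by calendar day over all monitored days; days without answered
    beeps (or without a rating for a symptom) are missing, not 0.  The column
    ``n_answered`` counts answered beeps per day.
    """
    df = series.data
    days = df.drop_duplicates("calendar_day")["calendar_day"]
    af = df[df["answered"] == 1]
    means = af.groupby("calendar_day")[list(SYMPTOMS)].mean()
    out = means.reindex(days.to_numpy()).astype(float)
    counts = af.groupby("calendar_day").size()
    out["n_answered"] = counts.reindex(days.to_numpy()).fillna(0).astype(int)
    out.index.name = "calendar_day"
    return out


def _oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA over >= 2 groups; (nan, nan) when below the minimum."""
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        return float("nan"), float("nan")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def day_sd_by_state_anova(series: EsmSeries,
                          min_beeps: int = 2) -> pd.DataFrame:
    """Do within-day symptom sds differ across states?  One-way ANOVA per symptom.

    A day enters for a symptom only if it has at least ``min_beeps`` answered
    ratings of that symptom; states without such days are dropped from that
    symptom's ANOVA (two remaining states give the usual two-group F = t^2).
    """
    af = _require_states(series)
    day_state = af.drop_duplicates("calendar_day").set_index("calendar_day")["state"]
    rows = []
    for s in SYMPTOMS:
        sds = (af.groupby("calendar_day")[s]
               .agg(lambda v: v.dropna().astype(float).std(ddof=1)
                    if v.notna().sum() >= min_beeps else np.nan)
               .dropna())
        groups = [sds[day_state.reindex(sds.index) == state].to_numpy()
                  for state in STATES]
        used = [g for g in groups if len(g) >= 2]
        if len(used) < 2:
            raise InsufficientDataError(
                f"'{s}': need >= 2 states with >= 2 eligible days each"
            )
        f, p = _oneway_anova(used)
        rows.append({"symptom": s, "F": f, "p_value": p,
                     "n_days": int(sum(len(g) for g in used))})
    return pd.DataFrame(rows).set_index("symptom")


@dataclass(frozen=True)
class BeepsPerDayResult:
    """ANOVA of answered-beeps-per-day counts across states."""

    F: float
    p_value: float
    by_state: pd.DataFrame  # index state: n_days, mean, min, max


def beeps_per_day_anova(series: EsmSeries) -> BeepsPerDayResult:
    """Does the number of answered beeps per day depend on the state?

    With fewer than two states present the F statistic is undefined and
    reported as missing (the per-state summary is still returned).
    """
    _require_states(series)
    days = series.day_table().set_index("calendar_day")
    af = series.answered()
    counts = (af.groupby("calendar_day").size()
              .reindex(days.index).fillna(0).astype(int))
    rows, groups = [], []
    for state in STATES:
        vals = counts[days["state"] == state].to_numpy()
        if len(vals):
            groups.append(vals.astype(float))
        rows.append({
            "state": state,
            "n_days": len(vals),
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "min": int(vals.min()) if len(vals) else np.nan,
            "max": int(vals.max()) if len(vals) else np.nan,
        })
    f, p = _oneway_anova(groups)
    return BeepsPerDayResult(F=f, p_value=p,
                             by_state=pd.DataFrame(rows).set_index("state"))


def completion_stats(series: EsmSeries) -> CompletionStats:
    """Answered beeps, completion fraction and per-day answered-count summary.

    The fraction is answered beeps over all scheduled beeps (monitored days
    x beeps per day in the canonical sampling frame).
    """
    df = series.data
    af = df[df["answered"] == 1]
    days = df.drop_duplicates("calendar_day")["calendar_day"]
    per_day = (af.groupby("calendar_day").size()
               .reindex(days.to_numpy()).fillna(0).astype(int))
    n_answered = int(len(af))
    n_scheduled = int(len(df))
    return CompletionStats(
        n_answered=n_answered,
        n_scheduled=n_scheduled,
        n_days=len(days),
        fraction=n_answered / n_scheduled if n_scheduled else float("nan"),
        mean_per_day=float(per_day.mean()) if len(per_day) else float("nan"),
        sd_per_day=float(per_day.std(ddof=1)) if len(per_day) > 1 else float("nan"),
        min_per_day=int(per_day.min()) if len(per_day) else 0,
        max_per_day=int(per_day.max()) if len(per_day) else 0,
    )
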