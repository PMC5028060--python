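"""Data model and bookkeeping for single-subject experience-sampling (ESM) series.

An ESM study signals ("beeps") a subject up to ten times a day at random
moments inside a waking-hours window; at each answered beep the subject rates
momentary symptoms on 1-7 Likert scales.  This module holds the beep-level
data model, CSV input/output, dose-based relapse-state labelling, episode
segmentation, and the construction of within-day lag pairs -- the unit of
observation for the lag-1 network regressions in :mod:`esmnet.networks`.

Conventions used throughout the package:

* five fixed symptoms in canonical order (``down``, ``loss_of_control``,
  ``paranoia``, ``hearing_voices``, ``relaxed``); matrices and tables always
  use this order;
* day and beep indices are 1-based; times are minutes since midnight; all
  intervals are closed;
* ``calendar_day`` counts days since study start (used for de-trending),
  ``day_index`` counts monitored days (the subject monitors only some days
  of each week).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical symptom identifiers, in the fixed order used for all matrices.
SYMPTOMS: tuple[str, ...] = (
    "down",
    "loss_of_control",
    "paranoia",
    "hearing_voices",
    "relaxed",
)

#: Display labels for reports and exported tables.
SYMPTOM_LABELS: dict[str, str] = {
    "down": "Down",
    "loss_of_control": "Loss of control",
    "paranoia": "Paranoia",
    "hearing_voices": "Hearing voices",
    "relaxed": "Relaxed",
}

N_SYMPTOMS = len(SYMPTOMS)

RATING_MIN, RATING_MAX = 1, 7

#: Beeps are scheduled between 7:30 and 22:30 (minutes since midnight).
DAY_WINDOW: tuple[int, int] = (450, 1350)

#: Consecutive scheduled beeps within a day are between 10 min and 3 h apart.
GAP_BOUNDS: tuple[int, int] = (10, 180)

MAX_BEEPS_PER_DAY = 10


class StateLabel(str, enum.Enum):
    """Clinical state of a monitored day, operationalized by the daily dose."""

    STABLE = "stable"
    IMPENDING_RELAPSE = "impending_relapse"
    FULL_RELAPSE = "full_relapse"


STATES: tuple[str, ...] = tuple(s.value for s in StateLabel)

#: Daily antipsychotic (clozapine) dose in mg -> clinical state.  The subject
#: self-titrates between a 350 mg maintenance dose, a 400 mg step-up when a
#: relapse is impending, and 450 mg during a full relapse.
DEFAULT_DOSE_STATE_MAP: dict[int, str] = {
    350: StateLabel.STABLE.value,
    400: StateLabel.IMPENDING_RELAPSE.value,
    450: StateLabel.FULL_RELAPSE.value,
}

DOSE_BY_STATE: dict[str, int] = {v: k for k, v in DEFAULT_DOSE_STATE_MAP.items()}

#: Mandatory column order of the ESM CSV interchange format.
CSV_COLUMNS: tuple[str, ...] = (
    "calendar_day",
    "day_index",
    "beep_index",
    "scheduled_time",
    "answered",
    *SYMPTOMS,
    "dose_mg",
)


class EsmError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(EsmError):
    """A configuration problem (missing column, unmapped dose, bad config)."""


class InsufficientDataError(EsmError):
    """Not enough observations to perform the requested computation."""


class EstimationError(EsmError):
    """A model could not be estimated (rank deficiency, degenerate input)."""


class ValidationError(EsmError):
    """Input rows violate the data-model invariants.

    ``rows`` holds 1-based CSV line numbers (header is line 1) when the data
    came from a file, or 1-based row positions for in-memory frames.
    """

    def __init__(self, message: str, rows: Sequence[int] | None = None):
        self.rows = list(rows) if rows is not None else []
        if self.rows:
            shown = ", ".join(str(r) for r in self.rows[:10])
            more = "" if len(self.rows) <= 10 else f", ... ({len(self.rows)} total)"
            message = f"{message} [rows {shown}{more}]"
        super().__init__(message)


@dataclass(frozen=True)
class EsmBeep:
    """One scheduled assessment moment."""

    day_index: int
    calendar_day: int
    beep_index: int
    scheduled_time: int
    answered: bool
    ratings: Mapping[str, int | None]
    dose_mg: int
    state: str | None = None

    def rating(self, symptom: str) -> int | None:
        return self.ratings.get(symptom)

    @property
    def is_complete(self) -> bool:
        """Answered with all five symptom ratings present."""
        return self.answered and all(self.ratings.get(s) is not None for s in SYMPTOMS)


@dataclass(frozen=True)
class LagPair:
    """An (earlier answered beep, current answered beep) pair within one day.

    The ``curr`` beep is the regression outcome row; ``prev`` supplies the
    lagged predictors.  The pair's state is the state of ``curr`` (states are
    constant within a day, so the two can never disagree).
    """

    prev: EsmBeep
    curr: EsmBeep

    @property
    def state(self) -> str | None:
        return self.curr.state

    @property
    def calendar_day(self) -> int:
        return self.curr.calendar_day

    @property
    def gap_minutes(self) -> int:
        return self.curr.scheduled_time - self.prev.scheduled_time


@dataclass(frozen=True)
class Episode:
    """A maximal run of consecutive monitored days sharing one state.

    ``start_day``/``end_day`` are calendar days; ``duration_days`` counts the
    monitored days in the run (monitored days are typically 4 per week, so
    calendar spans are longer than durations).
    """

    state: str
    start_day: int
    end_day: int
    duration_days: int


def _parse_time(value) -> int | None:
    """Parse a scheduled time as minutes since midnight; None if unparseable."""
    if isinstance(value, str):
        text = value.strip()
        if ":" in text:
            parts = text.split(":")
            try:
                h, m = int(parts[0]), int(parts[1])
            except (ValueError, IndexError):
                return None
            if not (0 <= m < 60 and 0 <= h < 24):
                return None
            return 60 * h + m
        try:
            value = float(text)
        except ValueError:
            return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    if not np.isfinite(f) or f != int(f):
        return None
    return int(f)


def _normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw frame to the canonical dtypes (ratings nullable Int64)."""
    out = df.copy().reset_index(drop=True)
    for col in ("calendar_day", "day_index", "beep_index", "scheduled_time",
                "answered", "dose_mg"):
        out[col] = pd.to_numeric(out[col]).astype(np.int64)
    for s in SYMPTOMS:
        out[s] = pd.to_numeric(out[s]).astype("Int64")
    cols = list(CSV_COLUMNS) + (["state"] if "state" in out.columns else [])
    return out[cols]


def _validate_frame(df: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` if the frame violates any invariant."""
    problems: list[tuple[str, list[int]]] = []

    def rows_of(mask) -> list[int]:
        # +2: header line plus 1-based counting, matching the CSV file.
        return [int(i) + 2 for i in np.flatnonzero(np.asarray(mask))]

    def check(mask, message):
        mask = np.asarray(mask, dtype=bool)
        if mask.any():
            problems.append((message, rows_of(mask)))

    check(df["day_index"].to_numpy() < 1, "day_index must be >= 1")
    check(df["calendar_day"].to_numpy() < 1, "calendar_day must be >= 1")
    beep = df["beep_index"].to_numpy()
    check((beep < 1) | (beep > MAX_BEEPS_PER_DAY),
          f"beep_index must be in 1..{MAX_BEEPS_PER_DAY}")
    t = df["scheduled_time"].to_numpy()
    check((t < DAY_WINDOW[0]) | (t > DAY_WINDOW[1]),
          "scheduled_time outside the 7:30-22:30 sampling window")
    answered = df["answered"].to_numpy()
    check(~np.isin(answered, (0, 1)), "answered must be 0 or 1")

    any_rating = np.zeros(len(df), dtype=bool)
    for s in SYMPTOMS:
        vals = df[s]
        present = vals.notna().to_numpy()
        any_rating |= present
        bad = present & (
            (vals.fillna(RATING_MIN) < RATING_MIN)
            | (vals.fillna(RATING_MIN) > RATING_MAX)
        ).to_numpy()
        check(bad, f"rating '{s}' outside the {RATING_MIN}-{RATING_MAX} Likert range")
    check((answered == 0) & any_rating, "unanswered beep carries ratings")

    # Per-day structure: ordering, gaps, constant dose/day_index/state.
    grp = df.groupby("calendar_day", sort=False)
    tdiff = grp["scheduled_time"].diff()
    within = tdiff.notna()
    check(within & (tdiff <= 0), "beeps not strictly increasing in time within a day")
    pos_gap = within & (tdiff > 0)
    check(pos_gap & ((tdiff < GAP_BOUNDS[0]) | (tdiff > GAP_BOUNDS[1])),
          f"within-day gap outside [{GAP_BOUNDS[0]}, {GAP_BOUNDS[1]}] minutes")
    check(grp["beep_index"].diff().fillna(1) <= 0,
          "beep_index not strictly increasing within a day")
    check(grp["day_index"].transform("nunique") > 1,
          "day_index not constant within a calendar day")
    check(grp["dose_mg"].transform("nunique") > 1,
          "dose_mg not constant within a calendar day")
    if "state" in df.columns:
        check(grp["state"].transform("nunique") > 1,
              "state not constant within a calendar day")
    counts = grp["beep_index"].transform("size")
    check(counts > MAX_BEEPS_PER_DAY,
          f"more than {MAX_BEEPS_PER_DAY} beeps in one day")

    # Across days: calendar_day non-decreasing, day_index increasing with it.
    cal = df["calendar_day"].to_numpy()
    check(np.diff(cal, prepend=cal[0] if len(cal) else 0) < 0,
          "rows not sorted by calendar_day")
    day_tbl = df.drop_duplicates("calendar_day")[["calendar_day", "day_index"]]
    di = day_tbl["day_index"].to_numpy()
    if len(di) > 1 and (np.diff(di) <= 0).any():
        problems.append(("day_index must strictly increase across calendar days", []))

    if problems:
        first_msg, first_rows = problems[0]
        if len(problems) > 1:
            first_msg += f" (+{len(problems) - 1} further problem(s))"
        raise ValidationError(first_msg, first_rows)


@dataclass
class EsmSeries:
    """A validated beep-level ESM series for a single subject.

    The canonical container is a :class:`pandas.DataFrame` with the columns of
    :data:`CSV_COLUMNS` (ratings as nullable ``Int64``) plus, after
    :func:`derive_states`, a ``state`` column.
    """

    data: pd.DataFrame
    subject: str = "subject-1"

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject: str = "subject-1",
                   validate: bool = True) -> "EsmSeries":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing required column(s): {missing}")
        frame = _normalize_frame(df)
        if validate:
            _validate_frame(frame)
        return cls(frame, subject=subject)

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_days(self) -> int:
        return int(self.data["calendar_day"].nunique())

    @property
    def n_answered(self) -> int:
        return int((self.data["answered"] == 1).sum())

    @property
    def has_states(self) -> bool:
        return "state" in self.data.columns

    def answered(self) -> pd.DataFrame:
        """The sub-frame of answered beeps."""
        return self.data[self.data["answered"] == 1]

    def day_table(self) -> pd.DataFrame:
        """One row per monitored day (day_index, calendar_day, dose, state)."""
        cols = ["day_index", "calendar_day", "dose_mg"]
        if self.has_states:
            cols.append("state")
        return (self.data.drop_duplicates("calendar_day")[cols]
                .reset_index(drop=True))

    def beeps(self) -> Iterator[EsmBeep]:
        has_state = self.has_states
        for row in self.data.itertuples(index=False):
            ratings = {
                s: (None if pd.isna(getattr(row, s)) else int(getattr(row, s)))
                for s in SYMPTOMS
            }
            yield EsmBeep(
                day_index=int(row.day_index),
                calendar_day=int(row.calendar_day),
                beep_index=int(row.beep_index),
                scheduled_time=int(row.scheduled_time),
                answered=bool(row.answered),
                ratings=ratings,
                dose_mg=int(row.dose_mg),
                state=str(row.state) if has_state else None,
            )

    def equals(self, other: "EsmSeries") -> bool:
        a = self.data[list(CSV_COLUMNS)].reset_index(drop=True)
        b = other.data[list(CSV_COLUMNS)].reset_index(drop=True)
        return a.equals(b)

    def __eq__(self, other) -> bool:  # type: ignore[override]
        return isinstance(other, EsmSeries) and self.equals(other)

    def copy(self) -> "EsmSeries":
        return EsmSeries(self.data.copy(), subject=self.subject)


def read_esm_csv(path, column_map: Mapping[str, str] | None = None,
                 subject: str | None = None) -> EsmSeries:
    """Read and validate a beep-level ESM CSV file.

    Parameters
    ----------
    path
        CSV file with the columns of :data:`CSV_COLUMNS` (header mandatory;
        empty rating field = missing; ``answered`` in {0, 1}).
    column_map
        Optional mapping ``canonical name -> column name in the file`` for
        foreign files.
    subject
        Subject label; defaults to the file stem.

    Raises
    ------
    ConfigurationError
        If a required column is absent.
    ValidationError
        If any row violates an invariant; the error lists offending CSV line
        numbers (header is line 1).
    """
    path = Path(path)
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing required column(s): {missing}"
        )
    df = raw[list(CSV_COLUMNS)].copy()

    times, bad_rows = [], []
    for i, v in enumerate(df["scheduled_time"].tolist()):
        parsed = _parse_time(v)
        if parsed is None:
            bad_rows.append(i + 2)
            parsed = DAY_WINDOW[0]
        times.append(parsed)
    if bad_rows:
        raise ValidationError("unparseable scheduled_time", bad_rows)
    df["scheduled_time"] = times

    for col in ("calendar_day", "day_index", "beep_index", "answered", "dose_mg"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            raise ValidationError(f"unparseable value in column '{col}'",
                                  rows_from_mask(bad))
        df[col] = coerced
    for s in SYMPTOMS:
        orig = df[s]
        coerced = pd.to_numeric(orig, errors="coerce")
        bad = orig.notna() & coerced.isna()
        if bad.any():
            raise ValidationError(f"unparseable rating in column '{s}'",
                                  rows_from_mask(bad))
        frac = coerced.dropna() % 1
        if (frac != 0).any():
            raise ValidationError(f"non-integer rating in column '{s}'",
                                  rows_from_mask(coerced.notna() & (coerced % 1 != 0)))
        df[s] = coerced
    return EsmSeries.from_frame(df, subject=subject or path.stem)


def rows_from_mask(mask) -> list[int]:
    """1-based CSV line numbers (header = line 1) for a boolean row mask."""
    return [int(i) + 2 for i in np.flatnonzero(np.asarray(mask))]


def write_esm_csv(series: EsmSeries, path) -> Path:
    """Write a series to the canonical CSV format (missing ratings = empty).

    ``read_esm_csv(write_esm_csv(s))`` reproduces ``s`` exactly, including
    item-level missingness.
    """
    path = Path(path)
    series.data[list(CSV_COLUMNS)].to_csv(path, index=False)
    return path


def derive_states(series: EsmSeries,
                  dose_state_map: Mapping[int, str] | None = None) -> EsmSeries:
    """Label every beep with the clinical state implied by its daily dose.

    The mapping must cover every dose present in the series (the default maps
    350 -> stable, 400 -> impending_relapse, 450 -> full_relapse); an unmapped
    dose raises :class:`ConfigurationError` naming the dose and calendar day.
    Idempotent; labels are constant within a calendar day because doses are.
    """
    dose_state_map = {int(k): str(StateLabel(v).value) for k, v in
                      (dose_state_map or DEFAULT_DOSE_STATE_MAP).items()}
    df = series.data.copy()
    doses = df["dose_mg"].to_numpy()
    unmapped = ~np.isin(doses, list(dose_state_map))
    if unmapped.any():
        i = int(np.flatnonzero(unmapped)[0])
        raise ConfigurationError(
            f"dose {doses[i]} mg on calendar day "
            f"{int(df['calendar_day'].iloc[i])} has no state mapping"
        )
    df["state"] = df["dose_mg"].map(dose_state_map)
    return EsmSeries(df, subject=series.subject)


def build_lag_pairs(series: EsmSeries,
                    max_lag_minutes: int | None = None) -> list[LagPair]:
    """Pair each answered beep with the previous answered beep of the same day.

    The lag is the immediately preceding *answered* beep on the same calendar
    day regardless of how many scheduled beeps were missed in between; lags
    never span nights.  The first answered beep of a day contributes no
    outcome row.  ``max_lag_minutes`` optionally drops pairs whose scheduled
    gap exceeds the cutoff (the chain is unaffected: the current beep still
    serves as the lag of the next one).
    """
    if not series.has_states:
        raise ConfigurationError(
            "series must be state-labeled (call derive_states first)"
        )
    pairs: list[LagPair] = []
    prev: EsmBeep | None = None
    prev_day = None
    for beep in series.beeps():
        if not beep.answered:
            continue
        if beep.calendar_day != prev_day:
            prev, prev_day = None, beep.calendar_day
        if prev is not None:
            pair = LagPair(prev=prev, curr=beep)
            if max_lag_minutes is None or pair.gap_minutes <= max_lag_minutes:
                pairs.append(pair)
        prev = beep
    return pairs


def segment_episodes(series: EsmSeries) -> tuple[list[Episode], pd.DataFrame]:
    """Partition the monitored days into state episodes and summarize them.

    Returns the episode list plus a per-state summary frame with episode
    count, total monitored days, and mean/min/max episode duration (in
    monitored days).  States without episodes get count 0 and missing
    duration statistics.
    """
    if not series.has_states:
        raise ConfigurationError(
            "series must be state-labeled (call derive_states first)"
        )
    days = series.day_table()
    episodes: list[Episode] = []
    if len(days):
        states = days["state"].to_numpy()
        cals = days["calendar_day"].to_numpy()
        start = 0
        for i in range(1, len(days) + 1):
            if i == len(days) or states[i] != states[start]:
                episodes.append(Episode(
                    state=str(states[start]),
                    start_day=int(cals[start]),
                    end_day=int(cals[i - 1]),
                    duration_days=i - start,
                ))
                start = i
    rows = []
    for state in STATES:
        durs = [e.duration_days for e in episodes if e.state == state]
        rows.append({
            "state": state,
            "n_episodes": len(durs),
            "total_days": int(np.sum(durs)) if durs else 0,
            "mean_duration": float(np.mean(durs)) if durs else np.nan,
            "min_duration": int(np.min(durs)) if durs else np.nan,
            "max_duration": int(np.max(durs)) if durs else np.nan,
        })
    return episodes, pd.DataFrame(rows).set_index("state")
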