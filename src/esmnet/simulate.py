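"""Synthetic ESM generator with state-dependent lag-1 ground truth.

The generator emulates the sampling frame of a year-long single-subject ESM
study -- 10 beeps/day scheduled at random inside a 7:30-22:30 window with
inter-beep gaps between 10 minutes and 3 hours, ~4 monitored days per week,
~47% beep completion -- and drives the five symptom ratings with a
state-dependent lag-1 vector autoregression on a latent scale:

    x_k = c_s + A_s x_{k-1} + tau * calendar_day + eps,   eps ~ N(0, diag(sigma_s^2))

The first beep of each day is drawn from the state's stationary distribution
(overnight "reset", the default) or carried from the previous day's last beep
("carry").  Observed ratings are ``clamp(round(x), 1, 7)``; beeps are answered
with probability ``completion_prob`` and answered items go missing
independently with probability ``item_missing_prob``.  The per-state matrices
``A_s``, intercepts ``c_s`` and noise levels ``sigma_s`` are exported as
:class:`GroundTruth` so estimators can be tested by parameter recovery.

The default dynamics are test scaffolding, not claims about any real patient:
they produce a chronic-psychosis-like profile (voices frequent, paranoia
moderate, loss of control rare) with a mutually reinforcing down<->paranoia
loop, a mutually damping relaxed<->paranoia loop, and denser, stronger
coupling during relapse.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

from .core import (
    CSV_COLUMNS,
    DAY_WINDOW,
    DOSE_BY_STATE,
    GAP_BOUNDS,
    N_SYMPTOMS,
    RATING_MAX,
    RATING_MIN,
    STATES,
    SYMPTOMS,
    ConfigurationError,
    EsmSeries,
    StateLabel,
)

#: Weekday offsets (0 = Monday) used when choosing k monitored days per week;
#: the first four give the Mon/Wed/Fri/Sat pattern typical of such studies.
_WEEKDAY_ORDER = (0, 2, 4, 5, 1, 3, 6)


def _matrix(diag: float, edges: Mapping[tuple[str, str], float]) -> np.ndarray:
    """Build a 5x5 lag matrix; ``edges[(target, source)] = weight``."""
    A = np.eye(N_SYMPTOMS) * diag
    idx = {s: i for i, s in enumerate(SYMPTOMS)}
    for (target, source), w in edges.items():
        A[idx[target], idx[source]] = w
    return A


def default_lag_matrices() -> dict[str, np.ndarray]:
    """Default state-dependent lag matrices (rows = targets, cols = sources).

    Stable state: moderate autocorrelation, a positive down<->paranoia loop,
    a negative relaxed<->paranoia loop, relaxed damping voices and down
    feeding loss of control.  Impending relapse: the same topology, cross
    edges scaled up.  Full relapse: paranoia becomes a hub, broadcasting to
    every other symptom.
    """
    stable = _matrix(0.30, {
        ("down", "paranoia"): 0.15,
        ("paranoia", "down"): 0.15,
        ("relaxed", "paranoia"): -0.12,
        ("paranoia", "relaxed"): -0.12,
        ("hearing_voices", "relaxed"): -0.16,
        ("loss_of_control", "down"): 0.21,
    })
    impending = _matrix(0.32, {
        ("down", "paranoia"): 0.21,
        ("paranoia", "down"): 0.21,
        ("relaxed", "paranoia"): -0.17,
        ("paranoia", "relaxed"): -0.17,
        ("hearing_voices", "relaxed"): -0.22,
        ("loss_of_control", "down"): 0.29,
    })
    full = _matrix(0.35, {
        ("down", "paranoia"): 0.25,
        ("loss_of_control", "paranoia"): 0.25,
        ("hearing_voices", "paranoia"): 0.25,
        ("relaxed", "paranoia"): -0.25,
        ("paranoia", "relaxed"): -0.20,
        ("paranoia", "hearing_voices"): 0.15,
        ("loss_of_control", "down"): 0.15,
        ("relaxed", "down"): -0.15,
    })
    return {
        StateLabel.STABLE.value: stable,
        StateLabel.IMPENDING_RELAPSE.value: impending,
        StateLabel.FULL_RELAPSE.value: full,
    }


#: Default stationary symptom means per state on the 1-7 scale (down, loss of
#: control, paranoia, hearing voices, relaxed): voices prominent throughout,
#: mood worse and control lower during full relapse, relaxation reduced.
DEFAULT_STATE_MEANS: dict[str, tuple[float, ...]] = {
    StateLabel.STABLE.value: (2.13, 1.60, 2.76, 5.00, 4.05),
    StateLabel.IMPENDING_RELAPSE.value: (1.96, 1.40, 2.53, 4.71, 4.01),
    StateLabel.FULL_RELAPSE.value: (2.64, 2.06, 2.95, 4.78, 3.54),
}

DEFAULT_STATE_SIGMA: dict[str, tuple[float, ...]] = {
    StateLabel.STABLE.value: (1.35, 1.15, 1.65, 1.35, 1.20),
    StateLabel.IMPENDING_RELAPSE.value: (1.40, 1.05, 1.60, 1.35, 1.15),
    StateLabel.FULL_RELAPSE.value: (1.55, 1.45, 1.75, 1.40, 1.15),
}


def intercepts_for_means(A: np.ndarray, means: Sequence[float]) -> np.ndarray:
    """Intercept vector c with stationary mean ``means``: c = (I - A) mu."""
    return (np.eye(N_SYMPTOMS) - np.asarray(A)) @ np.asarray(means, float)


@dataclass(frozen=True)
class EpisodeSpec:
    """A planned relapse episode on the monitored-day axis (1-based)."""

    state: str
    duration_days: int
    start_day: int | None = None  # None => placed randomly (auto plan)


def _default_plan() -> str:
    return "auto"


def _default_A() -> dict[str, np.ndarray]:
    return default_lag_matrices()


def _default_c() -> dict[str, np.ndarray]:
    A = default_lag_matrices()
    return {s: intercepts_for_means(A[s], DEFAULT_STATE_MEANS[s]) for s in STATES}


def _default_sigma() -> dict[str, np.ndarray]:
    return {s: np.asarray(DEFAULT_STATE_SIGMA[s], float) for s in STATES}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic ESM study.

    Defaults reproduce the reference sampling frame: 201 monitored days
    (4 per week over ~1 year), 10 beeps/day in the 7:30-22:30 window with
    gaps in [10, 180] minutes, per-beep completion probability 943/2010
    (~0.469), per-item missingness ~0.004, and an auto state plan with
    4 full-relapse and 2 impending-relapse episodes.
    """

    n_monitored_days: int = 201
    monitored_days_per_week: int = 4
    beeps_per_day: int = 10
    window_minutes: tuple[int, int] = DAY_WINDOW
    gap_bounds_minutes: tuple[int, int] = GAP_BOUNDS
    completion_prob: float = 943 / 2010
    item_missing_prob: float = 0.004
    state_plan: list[EpisodeSpec] | str = field(default_factory=_default_plan)
    n_full_episodes: int = 4
    n_impending_episodes: int = 2
    full_duration_range: tuple[int, int] = (4, 25)
    impending_duration_range: tuple[int, int] = (7, 31)
    A: dict[str, np.ndarray] = field(default_factory=_default_A)
    c: dict[str, np.ndarray] = field(default_factory=_default_c)
    sigma: dict[str, np.ndarray] = field(default_factory=_default_sigma)
    trend: np.ndarray = field(default_factory=lambda: np.zeros(N_SYMPTOMS))
    overnight: str = "reset"  # "reset" | "carry"
    seed: int | None = None

    def __post_init__(self):
        self.A = {k: np.asarray(v, float) for k, v in self.A.items()}
        self.c = {k: np.asarray(v, float) for k, v in self.c.items()}
        self.sigma = {k: np.asarray(v, float) for k, v in self.sigma.items()}
        self.trend = np.asarray(self.trend, float)
        self.window_minutes = tuple(int(v) for v in self.window_minutes)
        self.gap_bounds_minutes = tuple(int(v) for v in self.gap_bounds_minutes)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if not (0 < self.completion_prob <= 1):
            raise ConfigurationError("completion_prob must be in (0, 1]")
        if not (0 <= self.item_missing_prob < 1):
            raise ConfigurationError("item_missing_prob must be in [0, 1)")
        if self.overnight not in ("reset", "carry"):
            raise ConfigurationError("overnight must be 'reset' or 'carry'")
        if not (1 <= self.monitored_days_per_week <= 7):
            raise ConfigurationError("monitored_days_per_week must be in 1..7")
        w0, w1 = self.window_minutes
        g0, g1 = self.gap_bounds_minutes
        if g0 <= 0 or g1 < g0:
            raise ConfigurationError("gap bounds must satisfy 0 < min <= max")
        if (self.beeps_per_day - 1) * g0 > w1 - w0:
            raise ConfigurationError(
                f"{self.beeps_per_day} beeps with minimum gap {g0} min cannot "
                f"fit the {w1 - w0}-min window"
            )
        for state in STATES:
            for store, name in ((self.A, "A"), (self.c, "c"), (self.sigma, "sigma")):
                if state not in store:
                    raise ConfigurationError(f"{name} missing for state '{state}'")
            if self.A[state].shape != (N_SYMPTOMS, N_SYMPTOMS):
                raise ConfigurationError(f"A[{state}] must be 5x5")
            rho = np.max(np.abs(np.linalg.eigvals(self.A[state])))
            if rho >= 1:
                raise ConfigurationError(
                    f"A[{state}] is non-stationary (spectral radius {rho:.3f} >= 1)"
                )
            if (self.sigma[state] < 0).any():
                raise ConfigurationError(f"sigma[{state}] must be non-negative")
        if isinstance(self.state_plan, list):
            self._check_plan(self.state_plan)

    def _check_plan(self, plan: list[EpisodeSpec]) -> None:
        covered = np.zeros(self.n_monitored_days, dtype=bool)
        for ep in plan:
            StateLabel(ep.state)
            if ep.start_day is None:
                raise ConfigurationError("explicit plans need start_day per episode")
            lo, hi = ep.start_day, ep.start_day + ep.duration_days - 1
            if lo < 1 or hi > self.n_monitored_days or ep.duration_days < 1:
                raise ConfigurationError(
                    f"episode {ep.state} days {lo}-{hi} outside 1.."
                    f"{self.n_monitored_days}"
                )
            seg = covered[lo - 1:hi]
            if seg.any():
                raise ConfigurationError(f"episode {ep.state} days {lo}-{hi} overlaps")
            covered[lo - 1:hi] = True

    def stationary_mean(self, state: str, calendar_day: float = 0.0) -> np.ndarray:
        """Stationary latent mean (I - A)^-1 (c + trend * calendar_day)."""
        A, c = self.A[state], self.c[state]
        return np.linalg.solve(np.eye(N_SYMPTOMS) - A,
                               c + self.trend * calendar_day)

    def stationary_cov(self, state: str) -> np.ndarray:
        return solve_discrete_lyapunov(self.A[state],
                                       np.diag(self.sigma[state] ** 2))

    def replace(self, **changes) -> "SyntheticConfig":
        return dataclasses.replace(self, **changes)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_monitored_days": self.n_monitored_days,
            "monitored_days_per_week": self.monitored_days_per_week,
            "beeps_per_day": self.beeps_per_day,
            "window_minutes": list(self.window_minutes),
            "gap_bounds_minutes": list(self.gap_bounds_minutes),
            "completion_prob": self.completion_prob,
            "item_missing_prob": self.item_missing_prob,
            "n_full_episodes": self.n_full_episodes,
            "n_impending_episodes": self.n_impending_episodes,
            "full_duration_range": list(self.full_duration_range),
            "impending_duration_range": list(self.impending_duration_range),
            "A": {k: v.tolist() for k, v in self.A.items()},
            "c": {k: v.tolist() for k, v in self.c.items()},
            "sigma": {k: v.tolist() for k, v in self.sigma.items()},
            "trend": self.trend.tolist(),
            "overnight": self.overnight,
            "seed": self.seed,
        }
        if isinstance(self.state_plan, str):
            d["state_plan"] = self.state_plan
        else:
            d["state_plan"] = [dataclasses.asdict(ep) for ep in self.state_plan]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        plan = d.get("state_plan", "auto")
        if isinstance(plan, list):
            d["state_plan"] = [EpisodeSpec(**ep) for ep in plan]
        for key in ("window_minutes", "gap_bounds_minutes", "full_duration_range",
                    "impending_duration_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GroundTruth:
    """The data-generating truth behind one simulated series."""

    A: dict[str, np.ndarray]
    c: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray]
    trend: np.ndarray
    overnight: str
    state_schedule: pd.DataFrame  # day_index, calendar_day, dose_mg, state
    latent: np.ndarray  # (n_days, beeps_per_day, 5), pre-discretization

    def to_dict(self, include_latent: bool = False) -> dict:
        d = {
            "symptoms": list(SYMPTOMS),
            "A": {k: v.tolist() for k, v in self.A.items()},
            "c": {k: v.tolist() for k, v in self.c.items()},
            "sigma": {k: v.tolist() for k, v in self.sigma.items()},
            "trend": self.trend.tolist(),
            "overnight": self.overnight,
            "state_schedule": self.state_schedule.to_dict(orient="list"),
        }
        if include_latent:
            d["latent"] = self.latent.tolist()
        return d

    def to_json(self, path, include_latent: bool = False) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(include_latent=include_latent)))
        return path


# ---------------------------------------------------------------------------
# Schedule sampling


def _sample_schedules(config: SyntheticConfig, rng: np.random.Generator,
                      n_days: int) -> np.ndarray:
    """Sample beep times for ``n_days`` days; shape (n_days, beeps_per_day).

    Sequential gap sampling with feasibility truncation: each gap is uniform
    on [min_gap, min(max_gap, slack)] where the slack guarantees the
    remaining beeps still fit before the window closes, so every draw yields
    a feasible schedule and the sampler has full support over feasible ones.
    """
    w0, w1 = config.window_minutes
    g0, g1 = config.gap_bounds_minutes
    B = config.beeps_per_day
    if (B - 1) * g0 > w1 - w0:
        raise ConfigurationError("infeasible schedule constraints")
    t = np.empty((n_days, B), dtype=np.int64)
    t[:, 0] = rng.integers(w0, w1 - (B - 1) * g0 + 1, size=n_days)
    for k in range(1, B):
        slack = w1 - (B - 1 - k) * g0 - t[:, k - 1]
        upper = np.minimum(g1, slack)
        t[:, k] = t[:, k - 1] + rng.integers(g0, upper + 1)
    return t


def sample_beep_schedule(config: SyntheticConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample one day's beep times (strictly increasing minutes since midnight)."""
    return _sample_schedules(config, rng, 1)[0]


def _auto_plan(config: SyntheticConfig,
               rng: np.random.Generator) -> list[EpisodeSpec]:
    """Place the configured relapse episodes at random, separated by >= 1 stable day."""
    n = config.n_monitored_days
    for _ in range(200):
        episodes = (
            [EpisodeSpec(StateLabel.FULL_RELAPSE.value,
                         int(rng.integers(config.full_duration_range[0],
                                          config.full_duration_range[1] + 1)))
             for _ in range(config.n_full_episodes)]
            + [EpisodeSpec(StateLabel.IMPENDING_RELAPSE.value,
                           int(rng.integers(config.impending_duration_range[0],
                                            config.impending_duration_range[1] + 1)))
               for _ in range(config.n_impending_episodes)]
        )
        order = rng.permutation(len(episodes))
        episodes = [episodes[i] for i in order]
        k = len(episodes)
        total = sum(ep.duration_days for ep in episodes)
        free = n - total - (k - 1)
        if free < 0:
            continue
        extra = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
        placed, day = [], 1
        for i, ep in enumerate(episodes):
            day += int(extra[i]) + (1 if i > 0 else 0)
            placed.append(dataclasses.replace(ep, start_day=day))
            day += ep.duration_days
        return placed
    raise ConfigurationError(
        "could not place the requested episodes within n_monitored_days"
    )


def sample_state_schedule(config: SyntheticConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Per-monitored-day dose and state implied by the (auto or explicit) plan.

    Returns a frame with columns day_index, calendar_day, dose_mg, state;
    calendar days follow the configured monitored-days-per-week pattern
    (Mon/Wed/Fri/Sat when 4 per week).
    """
    n = config.n_monitored_days
    weekdays = sorted(_WEEKDAY_ORDER[:config.monitored_days_per_week])
    cal = []
    week = 0
    while len(cal) < n:
        for wd in weekdays:
            cal.append(7 * week + wd + 1)
            if len(cal) == n:
                break
        week += 1
    plan = config.state_plan
    if isinstance(plan, str):
        if plan != "auto":
            raise ConfigurationError(f"unknown state_plan '{plan}'")
        plan = _auto_plan(config, rng)
    else:
        config._check_plan(plan)
    states = np.full(n, StateLabel.STABLE.value, dtype=object)
    for ep in plan:
        states[ep.start_day - 1: ep.start_day - 1 + ep.duration_days] = ep.state
    return pd.DataFrame({
        "day_index": np.arange(1, n + 1),
        "calendar_day": np.asarray(cal, dtype=np.int64),
        "dose_mg": [DOSE_BY_STATE[s] for s in states],
        "state": states,
    })


# ---------------------------------------------------------------------------
# Latent dynamics


def _simulate_latent(config: SyntheticConfig, schedule: pd.DataFrame,
                     rng: np.random.Generator) -> np.ndarray:
    """Latent series per (day, beep); shape (n_days, beeps_per_day, 5)."""
    B = config.beeps_per_day
    n_days = len(schedule)
    latent = np.empty((n_days, B, N_SYMPTOMS))
    states = schedule["state"].to_numpy()
    cal = schedule["calendar_day"].to_numpy(dtype=float)

    if config.overnight == "reset":
        # Days are independent under reset: simulate each state's days in
        # parallel (deterministic because states are visited in fixed order).
        for state in STATES:
            idx = np.flatnonzero(states == state)
            if idx.size == 0:
                continue
            A, c, sigma = config.A[state], config.c[state], config.sigma[state]
            L = np.linalg.cholesky(config.stationary_cov(state)
                                   + 1e-12 * np.eye(N_SYMPTOMS))
            drift = c[None, :] + np.outer(cal[idx], config.trend)
            mu0 = np.linalg.solve(np.eye(N_SYMPTOMS) - A, drift.T).T
            x = mu0 + rng.standard_normal((idx.size, N_SYMPTOMS)) @ L.T
            latent[idx, 0] = x
            for k in range(1, B):
                eps = rng.standard_normal((idx.size, N_SYMPTOMS)) * sigma
                x = drift + x @ A.T + eps
                latent[idx, k] = x
    else:  # carry: sequential across days, last beep feeds the next morning
        prev: np.ndarray | None = None
        for d in range(n_days):
            state = states[d]
            A, c, sigma = config.A[state], config.c[state], config.sigma[state]
            drift = c + config.trend * cal[d]
            if prev is None:
                L = np.linalg.cholesky(config.stationary_cov(state)
                                       + 1e-12 * np.eye(N_SYMPTOMS))
                x = config.stationary_mean(state, cal[d]) \
                    + L @ rng.standard_normal(N_SYMPTOMS)
            else:
                x = drift + A @ prev + rng.standard_normal(N_SYMPTOMS) * sigma
            latent[d, 0] = x
            for k in range(1, B):
                x = drift + A @ x + rng.standard_normal(N_SYMPTOMS) * sigma
                latent[d, k] = x
            prev = x
    return latent


def discretize(latent: np.ndarray) -> np.ndarray:
    """Likert observation: round to the nearest integer and clamp to 1..7."""
    return np.clip(np.rint(latent), RATING_MIN, RATING_MAX).astype(np.int64)


def simulate_series(config: SyntheticConfig,
                    seed: int | None = None) -> tuple[EsmSeries, GroundTruth]:
    """Simulate a full ESM series plus its ground truth.

    ``seed`` overrides ``config.seed``.  Identical config + seed give an
    identical series and ground truth.
    """
    config.validate()
    use_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)

    schedule = sample_state_schedule(config, rng)
    times = _sample_schedules(config, rng, len(schedule))
    latent = _simulate_latent(config, schedule, rng)
    ratings = discretize(latent)

    n_days, B = times.shape
    answered = rng.random((n_days, B)) < config.completion_prob
    item_missing = rng.random((n_days, B, N_SYMPTOMS)) < config.item_missing_prob
    observed_mask = answered[:, :, None] & ~item_missing

    flat = {
        "calendar_day": np.repeat(schedule["calendar_day"].to_numpy(), B),
        "day_index": np.repeat(schedule["day_index"].to_numpy(), B),
        "beep_index": np.tile(np.arange(1, B + 1), n_days),
        "scheduled_time": times.reshape(-1),
        "answered": answered.reshape(-1).astype(np.int64),
        "dose_mg": np.repeat(schedule["dose_mg"].to_numpy(), B),
    }
    df = pd.DataFrame(flat)
    for j, s in enumerate(SYMPTOMS):
        vals = pd.array(ratings[:, :, j].reshape(-1), dtype="Int64")
        vals[~observed_mask[:, :, j].reshape(-1)] = pd.NA
        df[s] = vals
    df["state"] = np.repeat(schedule["state"].to_numpy(), B)
    df = df[list(CSV_COLUMNS) + ["state"]]

    series = EsmSeries.from_frame(df, subject=f"synthetic-{use_seed}")
    truth = GroundTruth(
        A={k: v.copy() for k, v in config.A.items()},
        c={k: v.copy() for k, v in config.c.items()},
        sigma={k: v.copy() for k, v in config.sigma.items()},
        trend=config.trend.copy(),
        overnight=config.overnight,
        state_schedule=schedule,
        latent=latent,
    )
    return series, truth


def paper_like_config(**overrides) -> SyntheticConfig:
    """The default year-long study configuration (see class docstring)."""
    return SyntheticConfig(**overrides)
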