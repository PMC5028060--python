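"""Shared fixtures and builders for the esmnet test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from esmnet.core import CSV_COLUMNS, SYMPTOMS, EsmSeries, derive_states
from esmnet.simulate import SyntheticConfig, simulate_series

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_series(days, gap: int = 30, start: int = 450,
                labeled: bool = True, validate: bool = True) -> EsmSeries:
    """Build a valid series from compact day specs.

    ``days`` is a list of ``(calendar_day, dose_mg, beeps)`` where ``beeps``
    is a list whose entries are either ``None`` (unanswered beep) or a list
    of five ratings (ints or ``None`` for item-missing).  Beep times start at
    ``start`` minutes and step by ``gap``.
    """
    rows = []
    for day_index, (cal, dose, beeps) in enumerate(days, start=1):
        for b, ratings in enumerate(beeps):
            row = {
                "calendar_day": cal,
                "day_index": day_index,
                "beep_index": b + 1,
                "scheduled_time": start + gap * b,
                "answered": int(ratings is not None),
                "dose_mg": dose,
            }
            for s, v in zip(SYMPTOMS, ratings or [None] * 5):
                row[s] = v
            rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    series = EsmSeries.from_frame(frame, validate=validate)
    return derive_states(series) if labeled else series


@pytest.fixture(scope="session")
def sim_series() -> EsmSeries:
    """A paper-scale synthetic series (201 days, auto relapse plan)."""
    series, _ = simulate_series(SyntheticConfig(), seed=123)
    return series


@pytest.fixture(scope="session")
def sim_truth():
    series, truth = simulate_series(SyntheticConfig(), seed=123)
    return series, truth


@pytest.fixture()
def tiny_series() -> EsmSeries:
    """Three monitored days: stable, full relapse, stable; some missingness."""
    return make_series([
        (1, 350, [[2, 1, 3, 5, 4], None, [3, 2, 3, 6, 4]]),
        (3, 450, [[4, 3, 5, 6, 2], [5, 4, 5, 7, 2], None, [4, 4, 4, 6, 3]]),
        (5, 350, [[2, 1, 2, 5, 5], [2, None, 3, 5, 4]]),
    ])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924 % 2**31)
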