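"""State-stratified lag-1 symptom network estimation.

The symptom network of one clinical state is the 5x5 matrix of coefficients
from five ordinary least-squares regressions, one per symptom: the current
level of the outcome symptom is regressed on all five symptom levels at the
previous answered beep of the same day, plus calendar time as a linear
de-trending covariate.  ``W[i][j]`` is the edge from symptom ``j`` at t-1 to
symptom ``i`` at t (column = source, row = target), so the diagonal holds the
autoregressive self-loops; each network carries exactly 25 edge weights.
Coefficients are unstandardized (raw 1-7 Likert units) by default.

A rank-based sensitivity variant replaces each coefficient with the Spearman
partial correlation between the current symptom and the lagged source,
conditioning on the remaining four lagged symptoms and calendar time --
mirroring the regression's adjustment set.

Stratification fits each state's models on that state's lag pairs only; an
outcome row enters a given model only if its outcome rating and all five
lagged ratings are present (per-model casewise deletion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import (
    N_SYMPTOMS,
    SYMPTOMS,
    SYMPTOM_LABELS,
    ConfigurationError,
    EsmSeries,
    EstimationError,
    InsufficientDataError,
    LagPair,
    build_lag_pairs,
)

LAG_COLUMNS = tuple(f"lag_{s}" for s in SYMPTOMS)
_MIN_ROWS = 8  # one more than the 7 regression parameters

METHOD_REGRESSION = "regression"
METHOD_SPEARMAN = "spearman_partial"


def build_design(pairs: Sequence[LagPair],
                 state: str | None = None) -> pd.DataFrame:
    """Design rows from lag pairs: current ratings, lagged ratings, time, state.

    Keeps only rows whose five lagged ratings are all present (casewise rule
    for the predictors); individual current ratings may still be missing and
    are dropped per model at fit time.  ``state`` restricts to pairs of that
    state.
    """
    rows = []
    for pair in pairs:
        if state is not None and pair.state != state:
            continue
        lagged = [pair.prev.rating(s) for s in SYMPTOMS]
        if any(v is None for v in lagged):
            continue
        row = {s: (np.nan if pair.curr.rating(s) is None
                   else float(pair.curr.rating(s)))
               for s in SYMPTOMS}
        row.update({c: float(v) for c, v in zip(LAG_COLUMNS, lagged)})
        row["calendar_day"] = float(pair.calendar_day)
        row["state"] = pair.state
        rows.append(row)
    cols = [*SYMPTOMS, *LAG_COLUMNS, "calendar_day", "state"]
    return pd.DataFrame(rows, columns=cols)


def design_from_series(series: EsmSeries, state: str | None = None,
                       max_lag_minutes: int | None = None) -> pd.DataFrame:
    """Vectorized equivalent of ``build_design(build_lag_pairs(series), state)``.

    Used internally for large simulation studies; unit tests pin the two
    routes to identical output.
    """
    if not series.has_states:
        raise ConfigurationError(
            "series must be state-labeled (call derive_states first)"
        )
    af = series.answered()
    grp = af.groupby("calendar_day")
    lags = grp[list(SYMPTOMS)].shift(1)
    keep = lags.notna().all(axis=1)
    if max_lag_minutes is not None:
        gap = af["scheduled_time"] - grp["scheduled_time"].shift(1)
        keep &= gap <= max_lag_minutes
    if state is not None:
        keep &= af["state"] == state
    out = pd.DataFrame(index=af.index[keep])
    for s in SYMPTOMS:
        out[s] = af.loc[keep, s].astype(float)
    for c, s in zip(LAG_COLUMNS, SYMPTOMS):
        out[c] = lags.loc[keep, s].astype(float)
    out["calendar_day"] = af.loc[keep, "calendar_day"].astype(float)
    out["state"] = af.loc[keep, "state"]
    return out.reset_index(drop=True)


@dataclass
class LaggedFit:
    """One fitted lagged regression row of the network."""

    outcome: str
    lag_coef: np.ndarray  # (5,) in canonical symptom order
    intercept: float
    time_coef: float
    lag_se: np.ndarray
    lag_p: np.ndarray
    n: int
    rsquared: float
    degenerate: bool = False  # constant outcome: slopes 0, R^2 undefined


def _design_matrix(design: pd.DataFrame,
                   include_trend: bool) -> tuple[list[str], np.ndarray]:
    cols = list(LAG_COLUMNS) + (["calendar_day"] if include_trend else [])
    return cols, design[cols].to_numpy(float)


def fit_lagged_regression(design: pd.DataFrame, outcome: str,
                          include_trend: bool = True,
                          standardize: bool = False) -> LaggedFit:
    """OLS of one current symptom on the five lagged symptoms plus time.

    Raises :class:`InsufficientDataError` below 8 complete rows and
    :class:`EstimationError` for a rank-deficient design, naming any
    zero-variance column.  A constant outcome yields exact zero slopes with
    an undefined R^2 (flagged ``degenerate``).
    """
    if outcome not in SYMPTOMS:
        raise ConfigurationError(f"unknown outcome '{outcome}'")
    sub = design.dropna(subset=[outcome])
    n = len(sub)
    if n < _MIN_ROWS:
        raise InsufficientDataError(
            f"outcome '{outcome}': {n} complete rows < minimum {_MIN_ROWS}"
        )
    cols, X = _design_matrix(sub, include_trend)
    y = sub[outcome].to_numpy(float)

    if standardize:
        y = _zscore(y, outcome)
        X = np.column_stack([_zscore(X[:, k], cols[k]) for k in range(X.shape[1])])

    constant = [c for c, v in zip(cols, X.var(axis=0)) if v == 0]
    if constant:
        raise EstimationError(
            f"outcome '{outcome}': zero-variance predictor column(s) {constant}"
        )
    X1 = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise EstimationError(
            f"outcome '{outcome}': design matrix is rank deficient "
            f"(collinear predictors among {cols})"
        )
    if np.var(y) == 0:
        return LaggedFit(
            outcome=outcome,
            lag_coef=np.zeros(N_SYMPTOMS),
            intercept=float(y[0]),
            time_coef=0.0,
            lag_se=np.full(N_SYMPTOMS, np.nan),
            lag_p=np.full(N_SYMPTOMS, np.nan),
            n=n, rsquared=float("nan"), degenerate=True,
        )
    res = sm.OLS(y, X1).fit()
    params = np.asarray(res.params)
    ses = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    return LaggedFit(
        outcome=outcome,
        lag_coef=params[1:1 + N_SYMPTOMS],
        intercept=float(params[0]),
        time_coef=float(params[1 + N_SYMPTOMS]) if include_trend else float("nan"),
        lag_se=ses[1:1 + N_SYMPTOMS],
        lag_p=pvals[1:1 + N_SYMPTOMS],
        n=n,
        rsquared=float(res.rsquared),
    )


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise EstimationError(f"cannot standardize zero-variance column '{name}'")
    return (v - v.mean()) / sd


@dataclass
class SymptomNetwork:
    """A 5x5 directed weighted symptom network with self-loops.

    ``W[i][j]`` is the weight of the edge from symptom ``j`` at t-1 to
    symptom ``i`` at t, in the canonical order of :data:`SYMPTOMS`.
    Regression networks also carry intercepts, time (de-trending)
    coefficients and standard errors; the Spearman variant carries the
    partial correlations and their p-values.
    """

    method: str
    state: str | None
    W: np.ndarray
    pvalues: np.ndarray
    n_rows: np.ndarray  # per-outcome rows used
    se: np.ndarray | None = None
    intercepts: np.ndarray | None = None
    time_coefs: np.ndarray | None = None
    standardized: bool = False

    def edge(self, source: str, target: str) -> float:
        i, j = SYMPTOMS.index(target), SYMPTOMS.index(source)
        return float(self.W[i, j])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def opt(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "symptoms": list(SYMPTOMS),
            "orientation": "W[i][j] = edge from symptom j at t-1 to symptom i at t",
            "method": self.method,
            "state": self.state,
            "standardized": self.standardized,
            "W": self.W.tolist(),
            "pvalues": self.pvalues.tolist(),
            "n_rows": np.asarray(self.n_rows).tolist(),
            "se": opt(self.se),
            "intercepts": opt(self.intercepts),
            "time_coefs": opt(self.time_coefs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SymptomNetwork":
        def opt(a):
            return None if a is None else np.asarray(a, float)

        return cls(
            method=d["method"], state=d["state"],
            W=np.asarray(d["W"], float),
            pvalues=np.asarray(d["pvalues"], float),
            n_rows=np.asarray(d["n_rows"], int),
            se=opt(d.get("se")),
            intercepts=opt(d.get("intercepts")),
            time_coefs=opt(d.get("time_coefs")),
            standardized=bool(d.get("standardized", False)),
        )

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path) -> "SymptomNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_graph(self, threshold: float = 0.0) -> nx.DiGraph:
        """Signed weighted digraph (self-loops included) for export/plotting."""
        g = nx.DiGraph(method=self.method, state=str(self.state))
        for s in SYMPTOMS:
            g.add_node(s, label=SYMPTOM_LABELS[s])
        for i, target in enumerate(SYMPTOMS):
            for j, source in enumerate(SYMPTOMS):
                w = float(self.W[i, j])
                if abs(w) > threshold:
                    g.add_edge(source, target, weight=w, sign=int(np.sign(w)))
        return g

    def to_graphml(self, path, threshold: float = 0.0) -> Path:
        path = Path(path)
        nx.write_graphml(self.to_graph(threshold), path)
        return path

    def equals(self, other: "SymptomNetwork", tol: float = 0.0) -> bool:
        return (
            self.method == other.method
            and self.state == other.state
            and np.allclose(self.W, other.W, atol=tol, rtol=0, equal_nan=True)
        )


def _network_from_design(design: pd.DataFrame, state: str | None,
                         include_trend: bool,
                         standardize: bool) -> SymptomNetwork:
    W = np.empty((N_SYMPTOMS, N_SYMPTOMS))
    se = np.empty((N_SYMPTOMS, N_SYMPTOMS))
    pv = np.empty((N_SYMPTOMS, N_SYMPTOMS))
    icpt = np.empty(N_SYMPTOMS)
    tc = np.empty(N_SYMPTOMS)
    ns = np.empty(N_SYMPTOMS, dtype=int)
    for i, outcome in enumerate(SYMPTOMS):
        fit = fit_lagged_regression(design, outcome,
                                    include_trend=include_trend,
                                    standardize=standardize)
        W[i] = fit.lag_coef
        se[i] = fit.lag_se
        pv[i] = fit.lag_p
        icpt[i] = fit.intercept
        tc[i] = fit.time_coef
        ns[i] = fit.n
    return SymptomNetwork(
        method=METHOD_REGRESSION, state=state, W=W, pvalues=pv, n_rows=ns,
        se=se, intercepts=icpt, time_coefs=tc, standardized=standardize,
    )


def spearman_partial_from_design(design: pd.DataFrame,
                                 state: str | None = None) -> SymptomNetwork:
    """Spearman partial-correlation network from a lagged design frame.

    All columns (outcome, five lags, calendar time) are rank-transformed;
    ``W[i][j]`` is then the partial correlation of outcome ``i`` with lagged
    source ``j`` given the other four lagged symptoms and calendar time,
    computed by correlating the residuals of the two rank columns after
    linear adjustment for the conditioning set.  p-values use the usual
    t reference with n - 2 - k degrees of freedom (k = 5 covariates).
    Invariant to strictly increasing transforms of any symptom.
    """
    W = np.empty((N_SYMPTOMS, N_SYMPTOMS))
    pv = np.empty((N_SYMPTOMS, N_SYMPTOMS))
    ns = np.empty(N_SYMPTOMS, dtype=int)
    for i, outcome in enumerate(SYMPTOMS):
        sub = design.dropna(subset=[outcome])
        n = len(sub)
        if n < _MIN_ROWS:
            raise InsufficientDataError(
                f"outcome '{outcome}': {n} complete rows < minimum {_MIN_ROWS}"
            )
        cols = [outcome, *LAG_COLUMNS, "calendar_day"]
        raw = sub[cols].to_numpy(float)
        for name, col in zip(cols, raw.T):
            if np.all(col == col[0]):
                raise EstimationError(
                    f"outcome '{outcome}': zero-variance column '{name}'"
                )
        ranked = np.column_stack([stats.rankdata(col) for col in raw.T])
        y = ranked[:, 0]
        ns[i] = n
        for j in range(N_SYMPTOMS):
            x = ranked[:, 1 + j]
            covars = np.delete(ranked[:, 1:], j, axis=1)  # 4 lags + time
            Z = np.column_stack([np.ones(n), covars])
            rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
            ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            denom = np.sqrt(rx @ rx) * np.sqrt(ry @ ry)
            if denom == 0:
                raise EstimationError(
                    f"outcome '{outcome}': degenerate residuals for "
                    f"source '{SYMPTOMS[j]}'"
                )
            r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
            W[i, j] = r
            dof = n - 2 - (Z.shape[1] - 1)
            if abs(r) >= 1.0 or dof <= 0:
                pv[i, j] = 0.0 if abs(r) >= 1.0 else float("nan")
            else:
                t = r * np.sqrt(dof / (1 - r * r))
                pv[i, j] = float(2 * stats.t.sf(abs(t), dof))
    return SymptomNetwork(method=METHOD_SPEARMAN, state=state, W=W,
                          pvalues=pv, n_rows=ns)


def estimate_network(series: EsmSeries, state: str | None = None,
                     method: str = METHOD_REGRESSION,
                     standardize: bool = False,
                     include_trend: bool = True,
                     max_lag_minutes: int | None = None) -> SymptomNetwork:
    """Estimate one state's symptom network (``state=None`` pools all states).

    ``method`` is ``"regression"`` (the primary lagged-OLS network) or
    ``"spearman_partial"`` (the rank-based sensitivity network).
    """
    design = design_from_series(series, state=state,
                                max_lag_minutes=max_lag_minutes)
    if method == METHOD_REGRESSION:
        return _network_from_design(design, state, include_trend, standardize)
    if method == METHOD_SPEARMAN:
        if standardize:
            raise ConfigurationError(
                "standardize has no effect on rank-based networks"
            )
        return spearman_partial_from_design(design, state=state)
    raise ConfigurationError(f"unknown method '{method}'")


def spearman_partial_network(series: EsmSeries,
                             state: str | None = None) -> SymptomNetwork:
    """Convenience wrapper for the rank-based sensitivity network."""
    return estimate_network(series, state=state, method=METHOD_SPEARMAN)
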