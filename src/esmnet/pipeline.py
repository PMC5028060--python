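"""End-to-end orchestration: simulate/load -> describe -> networks -> centrality.

One :func:`run_pipeline` call produces a :class:`RunReport` holding every
artifact of the analysis (completion statistics, episode segmentation,
per-state descriptives and contrasts, one network per state and method, and
the centrality table of each estimable network).  :func:`export_report`
writes the report as plain CSV/JSON/GraphML files plus a manifest that
records the configuration verbatim and a content hash, so a rerun with the
same configuration and seed is byte-identical.

States with too few complete rows are reported as not estimable without
aborting the remaining states.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    DEFAULT_DOSE_STATE_MAP,
    STATES,
    SYMPTOMS,
    ConfigurationError,
    EsmError,
    EsmSeries,
    StateLabel,
    derive_states,
    read_esm_csv,
    segment_episodes,
    write_esm_csv,
)
from .centrality import centrality_table
from .descriptives import (
    beeps_per_day_anova,
    completion_stats,
    compare_states,
    day_level_series,
    state_summary,
)
from .networks import METHOD_REGRESSION, METHOD_SPEARMAN, estimate_network
from .simulate import GroundTruth, SyntheticConfig, simulate_series

log = logging.getLogger("esmnet")

_METHODS = (METHOD_REGRESSION, METHOD_SPEARMAN)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one data source applies: ``input_csv`` (an existing beep-level
    CSV) or ``synthetic`` (a generator configuration; the default when both
    are None).
    """

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    dose_state_map: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_STATE_MAP))
    states: tuple[str, ...] = STATES
    methods: tuple[str, ...] = _METHODS
    threshold: float = 0.0
    standardize: bool = False
    max_lag_minutes: int | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        d["states"] = list(self.states)
        d["methods"] = list(self.methods)
        d["dose_state_map"] = {str(k): v for k, v in self.dose_state_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "dose_state_map" in d:
            d["dose_state_map"] = {int(k): v for k, v in d["dose_state_map"].items()}
        for key in ("states", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunReport:
    """Everything one pipeline run computed."""

    config: RunConfig
    series: EsmSeries
    truth: GroundTruth | None
    completion: "object"
    episodes: list
    episode_summary: pd.DataFrame
    summary: "object"
    contrasts: pd.DataFrame
    day_series: pd.DataFrame
    beeps_anova: "object"
    networks: dict[tuple[str, str], "object"]
    failures: dict[tuple[str, str], str]
    centralities: dict[tuple[str, str], pd.DataFrame]
    version: str = __version__


def _contrast_table(series: EsmSeries) -> pd.DataFrame:
    """Welch contrasts of each relapse state against stable, per symptom."""
    rows = []
    for state in (StateLabel.IMPENDING_RELAPSE.value,
                  StateLabel.FULL_RELAPSE.value):
        for symptom in SYMPTOMS:
            try:
                c = compare_states(series, symptom, state,
                                   StateLabel.STABLE.value)
            except EsmError as exc:
                rows.append({"symptom": symptom, "state": state,
                             "reference": "stable", "error": str(exc)})
                continue
            rows.append({
                "symptom": symptom, "state": state, "reference": "stable",
                "n_state": c.n_a, "n_reference": c.n_b,
                "mean_state": c.mean_a, "mean_reference": c.mean_b,
                "statistic": c.statistic, "p_value": c.p_value,
                "direction": ("higher" if c.mean_a > c.mean_b else
                              "lower" if c.mean_a < c.mean_b else "equal"),
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis described by ``config``."""
    logging.basicConfig(level=config.log_level)
    truth = None
    if config.input_csv is not None:
        series = read_esm_csv(config.input_csv)
        log.info("loaded %s: %d beeps over %d days", config.input_csv,
                 len(series), series.n_days)
    else:
        syn = config.synthetic or SyntheticConfig()
        series, truth = simulate_series(syn, seed=config.seed)
        log.info("simulated %d beeps over %d days (seed %s)",
                 len(series), series.n_days, config.seed)
    series = derive_states(series, config.dose_state_map)

    completion = completion_stats(series)
    log.info("answered %d of %d beeps (%.1f%%)", completion.n_answered,
             completion.n_scheduled, 100 * completion.fraction)
    episodes, episode_summary = segment_episodes(series)
    summary = state_summary(series)
    contrasts = _contrast_table(series)
    day_series = day_level_series(series)
    beeps_anova = beeps_per_day_anova(series)

    networks, failures, centralities = {}, {}, {}
    for method in config.methods:
        for state in config.states:
            key = (method, state)
            try:
                net = estimate_network(
                    series, state=state, method=method,
                    standardize=(config.standardize
                                 if method == METHOD_REGRESSION else False),
                    max_lag_minutes=config.max_lag_minutes,
                )
            except EsmError as exc:
                failures[key] = str(exc)
                log.warning("network %s/%s not estimable: %s", method, state, exc)
                continue
            networks[key] = net
            centralities[key] = centrality_table(net, config.threshold)
            log.info("network %s/%s estimated from n=%s rows", method, state,
                     net.n_rows.tolist())
    return RunReport(
        config=config, series=series, truth=truth, completion=completion,
        episodes=episodes, episode_summary=episode_summary, summary=summary,
        contrasts=contrasts, day_series=day_series, beeps_anova=beeps_anova,
        networks=networks, failures=failures, centralities=centralities,
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default,
                               allow_nan=True))


def export_report(report: RunReport, out_dir) -> dict:
    """Write all artifacts of a run to ``out_dir``; returns the manifest.

    Layout: ``run_config.json``, ``series.csv`` (+ ``truth.json`` when
    simulated), ``completion.json``, ``episodes.csv``,
    ``episode_summary.csv``, ``state_summary.csv``, ``contrasts.csv``,
    ``day_series.csv``, ``beeps_per_day_anova.json``,
    ``networks/<method>_<state>.{json,graphml}``,
    ``centrality/<method>_<state>.csv`` and ``manifest.json`` with a SHA-256
    per file plus a combined content hash.
    """
    out = Path(out_dir)
    (out / "networks").mkdir(parents=True, exist_ok=True)
    (out / "centrality").mkdir(exist_ok=True)

    _write_json(out / "run_config.json", report.config.to_dict())
    write_esm_csv(report.series, out / "series.csv")
    if report.truth is not None:
        report.truth.to_json(out / "truth.json")
    _write_json(out / "completion.json", dataclasses.asdict(report.completion))
    pd.DataFrame([dataclasses.asdict(e) for e in report.episodes]).to_csv(
        out / "episodes.csv", index=False)
    report.episode_summary.to_csv(out / "episode_summary.csv")
    report.summary.table.to_csv(out / "state_summary.csv", index=False)
    report.contrasts.to_csv(out / "contrasts.csv", index=False)
    report.day_series.to_csv(out / "day_series.csv")
    _write_json(out / "beeps_per_day_anova.json", {
        "F": report.beeps_anova.F, "p_value": report.beeps_anova.p_value,
        "by_state": report.beeps_anova.by_state.reset_index()
        .to_dict(orient="list"),
    })
    for (method, state), net in sorted(report.networks.items()):
        stem = f"{method}_{state}"
        net.to_json(out / "networks" / f"{stem}.json")
        net.to_graphml(out / "networks" / f"{stem}.graphml")
        report.centralities[(method, state)].to_csv(
            out / "centrality" / f"{stem}.csv")
    if report.failures:
        _write_json(out / "not_estimable.json",
                    {f"{m}_{s}": msg for (m, s), msg in report.failures.items()})

    files = sorted(p for p in out.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    hashes = {str(p.relative_to(out)):
              hashlib.sha256(p.read_bytes()).hexdigest() for p in files}
    combined = hashlib.sha256(
        json.dumps(hashes, sort_keys=True).encode()).hexdigest()
    manifest = {"version": report.version, "content_hash": combined,
                "files": hashes}
    _write_json(out / "manifest.json", manifest)
    return manifest
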