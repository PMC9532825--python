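"""Replicate trials, apply the estimand strategies, aggregate table-style summaries.

A cell is one (design, shutdown start) combination; an experiment is a set
of cells sharing a design and replicate count.  Replicates are independent:
replicate ``r`` of cell ``c`` uses the RNG stream seeded with
``SeedSequence([master_seed, c, r])``, so results are bit-identical however
the loop is scheduled and any single replicate can be re-run in isolation.

Across-replicate statistics mirror the reporting of simulation tables in
the trial literature: the median and the 2.5th-97.5th percentile range
(type-7 linear interpolation), power as the rejection fraction of the
two-sided logrank test, with not-reached medians carried as ``+inf`` and
counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ShutdownConfig, TrialDesign
from .estimands import (
    STRATEGIES,
    AnalysisDataset,
    MonitoringRule,
    derive_exact_times,
    derive_hypothetical,
    derive_interval_dataset,
    derive_treatment_policy,
    determine_cutoff,
)
from .interval import ic_logrank, ic_median_bounds, ic_proportional_hazards, turnbull_npmle
from .survival import cox_hr, km_median, logrank_test
from .trial import simulate_trial

__all__ = [
    "ExperimentConfig",
    "ReplicationSummary",
    "run_replications",
    "run_cell",
    "summarize_metric",
    "compute_power",
    "render_tables",
]

_METRICS = (
    "median_pfs_control",
    "median_pfs_experimental",
    "hr",
    "n_events",
    "analysis_time_months",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    design: TrialDesign
    shutdown_starts: tuple[float, ...] = ()  # empty = no pandemic
    shutdown_duration: float = 6.0
    n_replicates: int = 2000
    master_seed: int = 0
    strategies: tuple[str, ...] = STRATEGIES
    horizon: float = 240.0
    compute_hr: bool = True
    ic_test: bool = True
    ic_hr: bool = False
    hypothetical_censor_on: str = "documented"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")

    def cells(self) -> list[ShutdownConfig]:
        if not self.shutdown_starts:
            return [ShutdownConfig()]
        return [
            ShutdownConfig(start=s, duration=self.shutdown_duration)
            for s in self.shutdown_starts
        ]


@dataclass
class ReplicationSummary:
    """Across-replicate aggregation for one cell (one shutdown start)."""

    shutdown: ShutdownConfig
    n_replicates: int
    raw: pd.DataFrame
    table: pd.DataFrame
    power: dict[str, float]
    n_failures: int = 0


def _exact_cutoff(trial: pd.DataFrame, target: int, horizon: float) -> tuple[float, bool]:
    cal = (
        trial["enrollment"].to_numpy(dtype=float)
        + trial["true_time"].to_numpy(dtype=float)
    )
    if target > len(cal):
        raise ValueError("target_events exceeds the number of patients")
    cutoff = float(np.partition(cal, target - 1)[target - 1])
    return (cutoff, True) if cutoff <= horizon else (horizon, False)


def _right_censored_row(ds: AnalysisDataset, compute_hr: bool) -> dict:
    d = ds.data
    t = d["time"].to_numpy(dtype=float)
    e = d["event"].to_numpy(dtype=bool)
    g = d["arm"].to_numpy()
    _, p = logrank_test(t, e, g)
    row = {
        "strategy": ds.strategy,
        "analysis_time_months": ds.cutoff_calendar,
        "target_reached": ds.target_reached,
        "n_events": ds.n_events,
        "p_value": p,
        "hr": cox_hr(t, e, g) if compute_hr else np.nan,
        "median_pfs_control": km_median(t[g == 0], e[g == 0]),
        "median_pfs_experimental": km_median(t[g == 1], e[g == 1]),
    }
    return row


def _interval_row(ds: AnalysisDataset, ic_test: bool, ic_hr: bool) -> dict:
    d = ds.data
    lo = d["left"].to_numpy(dtype=float)
    hi = d["right"].to_numpy(dtype=float)
    g = d["arm"].to_numpy()
    row = {
        "strategy": "interval",
        "analysis_time_months": ds.cutoff_calendar,
        "target_reached": ds.target_reached,
        "n_events": ds.n_events,
        "p_value": np.nan,
        "hr": np.nan,
    }
    if ic_test:
        _, row["p_value"] = ic_logrank(lo, hi, g, method="asymptotic")
    if ic_hr:
        row["hr"] = ic_proportional_hazards(lo, hi, g).hr_estimate
    for arm, name in ((0, "control"), (1, "experimental")):
        est = turnbull_npmle(lo[g == arm], hi[g == arm])
        bounds = ic_median_bounds(est)
        row[f"median_pfs_{name}_low"] = bounds.low
        row[f"median_pfs_{name}_high"] = bounds.high
    # midpoint-free convention: the right-censored median columns stay empty
    row["median_pfs_control"] = np.nan
    row["median_pfs_experimental"] = np.nan
    return row


def analyze_replicate(
    trial: pd.DataFrame, config: ExperimentConfig, shutdown: ShutdownConfig
) -> list[dict]:
    """All requested strategy analyses of one simulated trial."""
    design = config.design
    target = design.target_events
    rows: list[dict] = []

    need_documented = set(config.strategies) - {"exact_times"}
    if need_documented:
        cutoff, reached = determine_cutoff(
            trial, target, MonitoringRule.ALL_DOCUMENTED_EVENTS, config.horizon
        )

    if "exact_times" in config.strategies:
        c_exact, r_exact = _exact_cutoff(trial, target, config.horizon)
        ds = derive_exact_times(trial, c_exact, r_exact)
        rows.append(_right_censored_row(ds, config.compute_hr))
    if "treatment_policy" in config.strategies:
        ds = derive_treatment_policy(
            trial, cutoff, design, shutdown, reached, target_events=target
        )
        rows.append(_right_censored_row(ds, config.compute_hr))
    if "hypothetical" in config.strategies:
        ds = derive_hypothetical(
            trial,
            cutoff,
            design,
            shutdown,
            reached,
            target_events=target,
            censor_on=config.hypothetical_censor_on,
        )
        rows.append(_right_censored_row(ds, config.compute_hr))
    if "hypothetical_delayed" in config.strategies:
        c_del, r_del = determine_cutoff(
            trial,
            target,
            MonitoringRule.UNCENSORED_EVENTS_ONLY,
            config.horizon,
            shutdown,
            config.hypothetical_censor_on,
        )
        ds = derive_hypothetical(
            trial,
            c_del,
            design,
            shutdown,
            r_del,
            target_events=target,
            censor_on=config.hypothetical_censor_on,
            delayed=True,
        )
        rows.append(_right_censored_row(ds, config.compute_hr))
    if "interval" in config.strategies:
        ds = derive_interval_dataset(
            trial, cutoff, design, shutdown, reached, target_events=target
        )
        rows.append(_interval_row(ds, config.ic_test, config.ic_hr))
    return rows


def run_cell(
    config: ExperimentConfig, shutdown: ShutdownConfig, cell_index: int
) -> ReplicationSummary:
    """Run all replicates of one (design, shutdown) cell."""
    records: list[dict] = []
    failures = 0
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, cell_index, rep])
        )
        try:
            trial = simulate_trial(config.design, shutdown, rng)
            for row in analyze_replicate(trial, config, shutdown):
                row["replicate"] = rep
                records.append(row)
        except Exception:  # noqa: BLE001 - excluded with a count, must stay ~0
            failures += 1
    raw = pd.DataFrame.from_records(records)
    return ReplicationSummary(
        shutdown=shutdown,
        n_replicates=config.n_replicates,
        raw=raw,
        table=_aggregate(raw, config),
        power=_powers(raw, config.design.alpha_two_sided),
        n_failures=failures,
    )


def run_replications(config: ExperimentConfig) -> dict[float | None, ReplicationSummary]:
    """One :class:`ReplicationSummary` per shutdown start (``None`` = no pandemic)."""
    out: dict[float | None, ReplicationSummary] = {}
    for idx, shutdown in enumerate(config.cells()):
        key = shutdown.start if shutdown.enabled else None
        out[key] = run_cell(config, shutdown, idx)
    return out


def summarize_metric(values) -> tuple[float, float, float, int]:
    """(median, 2.5th pct, 97.5th pct, n_not_reached) with inf-aware order stats.

    Not-reached markers enter as ``+inf``; an order statistic landing on
    ``inf`` is reported as ``inf`` (not-reached), and the count of infinite
    values is returned separately.  Percentiles are type-7 (linear
    interpolation), the default of mainstream statistical software.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("summarize_metric requires at least one value")
    n_inf = int(np.isinf(v).sum())

    def q(p: float) -> float:
        h = (len(v) - 1) * p
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        f = h - lo
        if f == 0 or v[lo] == v[hi]:
            return float(v[lo])
        if np.isinf(v[hi]):
            return float("inf")
        return float(v[lo] + f * (v[hi] - v[lo]))

    return q(0.5), q(0.025), q(0.975), n_inf


def compute_power(p_values, alpha: float) -> float:
    """Fraction of replicates with a two-sided p-value below ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        return float("nan")
    return float(np.mean(p < alpha))


def _powers(raw: pd.DataFrame, alpha: float) -> dict[str, float]:
    return {
        strat: compute_power(sub["p_value"], alpha)
        for strat, sub in raw.groupby("strategy", sort=False)
    }


def _aggregate(raw: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    """Long-format table: one row per (strategy, metric)."""
    rows = []
    for strat, sub in raw.groupby("strategy", sort=False):
        metrics = [
            c
            for c in sub.columns
            if c.startswith("median_pfs") or c in ("hr", "n_events", "analysis_time_months")
        ]
        for metric in metrics:
            vals = sub[metric].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            med, lo, hi, n_inf = summarize_metric(vals)
            rows.append(
                {
                    "strategy": strat,
                    "metric": metric,
                    "median": med,
                    "pct_2_5": lo,
                    "pct_97_5": hi,
                    "n_median_not_reached": n_inf,
                }
            )
        rows.append(
            {
                "strategy": strat,
                "metric": "power",
                "median": compute_power(sub["p_value"], config.design.alpha_two_sided),
                "pct_2_5": np.nan,
                "pct_97_5": np.nan,
                "n_median_not_reached": 0,
            }
        )
        rows.append(
            {
                "strategy": strat,
                "metric": "n_target_unreached",
                "median": float((~sub["target_reached"].astype(bool)).sum()),
                "pct_2_5": np.nan,
                "pct_97_5": np.nan,
                "n_median_not_reached": 0,
            }
        )
    return pd.DataFrame(rows)


def render_tables(
    summaries: dict[float | None, ReplicationSummary], out_prefix: str
) -> tuple[str, str]:
    """Write the aggregated results as CSV and a readable text table.

    Returns the two file paths.  The CSV is long format with one record per
    (shutdown_start, strategy, metric) — re-parsing it reproduces the
    in-memory tables, and sweeping shutdown starts gives the data behind
    power/HR/median-vs-timing curves directly.
    """
    frames = []
    for start, summary in summaries.items():
        t = summary.table.copy()
        t.insert(0, "shutdown_start", np.nan if start is None else start)
        frames.append(t)
    combined = pd.concat(frames, ignore_index=True)
    csv_path = f"{out_prefix}.csv"
    txt_path = f"{out_prefix}.txt"
    combined.to_csv(csv_path, index=False)

    lines = []
    for start, summary in summaries.items():
        label = "no shutdown" if start is None else (
            f"shutdown [{start:g}, {summary.shutdown.end:g}) months"
        )
        lines.append(f"== {label} | {summary.n_replicates} replicates ==")
        for strat, sub in summary.table.groupby("strategy", sort=False):
            lines.append(f"  {strat}:")
            for _, r in sub.iterrows():
                if r["metric"] == "power":
                    lines.append(f"    power: {100 * r['median']:.1f}%")
                elif r["metric"] == "n_target_unreached":
                    if r["median"]:
                        lines.append(f"    target unreached in {int(r['median'])} replicates")
                else:
                    med = "NR" if np.isinf(r["median"]) else f"{r['median']:.1f}"
                    hi = "NR" if np.isinf(r["pct_97_5"]) else f"{r['pct_97_5']:.1f}"
                    lines.append(
                        f"    {r['metric']}: {med} [{r['pct_2_5']:.1f}-{hi}]"
                        + (
                            f" ({int(r['n_median_not_reached'])} not reached)"
                            if r["n_median_not_reached"]
                            else ""
                        )
                    )
        lines.append("")
    with open(txt_path, "w") as fh:
        fh.write("\n".join(lines))
    return csv_path, txt_path
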