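"""Analysis-ready datasets under each estimand strategy, and the event-driven cutoff.

Five strategies turn one simulated trial into an analysis dataset:

``exact_times``
    benchmark using the latent event times themselves (no assessment grid).
``treatment_policy``
    events ascribed to the time they are documented, shutdown ignored as an
    intercurrent event (intent-to-treat reading).
``hypothetical``
    events documented at the reopening evaluation are censored at the last
    assessment performed before the shutdown window, targeting a world
    without the shutdown.
``hypothetical_delayed``
    same censoring rule, but the analysis is triggered only once the target
    number of *uncensored* events is documented, restoring the event count
    at the price of a later cutoff.
``interval``
    censoring intervals (last negative assessment, documenting assessment]
    for an interval-censored analysis; shutdown-spanning intervals are
    naturally wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .design import ShutdownConfig, TrialDesign
from .trial import last_assessment_calendar

__all__ = [
    "STRATEGIES",
    "MonitoringRule",
    "AnalysisDataset",
    "hypothetical_flags",
    "determine_cutoff",
    "derive_exact_times",
    "derive_treatment_policy",
    "derive_hypothetical",
    "derive_interval_dataset",
]

STRATEGIES = (
    "exact_times",
    "treatment_policy",
    "hypothetical",
    "hypothetical_delayed",
    "interval",
)

#: default follow-up horizon (months) for delayed analyses
DEFAULT_HORIZON = 240.0


class MonitoringRule(str, Enum):
    """Which documented events count toward the analysis trigger."""

    ALL_DOCUMENTED_EVENTS = "all_documented_events"
    UNCENSORED_EVENTS_ONLY = "uncensored_events_only"


def hypothetical_flags(
    patients: pd.DataFrame, shutdown: ShutdownConfig, censor_on: str = "documented"
) -> np.ndarray:
    """Events the hypothetical strategy will censor as shutdown-affected.

    ``censor_on="documented"`` (default) flags every event documented at the
    reopening evaluation, i.e. whose regular detection scan was suppressed
    by the window.  ``censor_on="true"`` instead flags events whose latent
    time falls inside the window (a stricter literal reading of "events
    occurring during the shutdown"); the two differ for events arising just
    before the window whose detection scan was missed, and for events
    arising late in the window but detected at the first regular post-window
    scan.
    """
    if censor_on not in ("true", "documented"):
        raise ValueError("censor_on must be 'true' or 'documented'")
    if not shutdown.enabled:
        return np.zeros(len(patients), dtype=bool)
    if censor_on == "documented":
        return patients["via_reopening"].to_numpy(dtype=bool)
    true_cal = (
        patients["enrollment"].to_numpy(dtype=float)
        + patients["true_time"].to_numpy(dtype=float)
    )
    return (true_cal >= shutdown.start) & (true_cal < shutdown.end)


@dataclass
class AnalysisDataset:
    """Per-strategy analysis rows plus the cutoff they were frozen at.

    ``data`` has columns ``(arm, time, event)`` for right-censored
    strategies or ``(arm, left, right)`` (right may be ``inf``) for the
    interval strategy.  Times are months from randomization.
    """

    strategy: str
    cutoff_calendar: float
    data: pd.DataFrame
    target_reached: bool = True

    @property
    def n_events(self) -> int:
        if "event" in self.data:
            return int(self.data["event"].sum())
        return int(np.isfinite(self.data["right"]).sum())


def determine_cutoff(
    patients: pd.DataFrame,
    target_events: int,
    rule: MonitoringRule = MonitoringRule.ALL_DOCUMENTED_EVENTS,
    horizon: float = DEFAULT_HORIZON,
    shutdown: ShutdownConfig | None = None,
    censor_on: str = "documented",
) -> tuple[float, bool]:
    """Smallest calendar time at which the qualifying event count hits the target.

    Under :attr:`MonitoringRule.UNCENSORED_EVENTS_ONLY` only events that the
    hypothetical strategy will keep uncensored qualify (``shutdown`` and
    ``censor_on`` define that flag).  Returns ``(horizon, False)`` when the
    target is not reachable by ``horizon``.
    """
    if target_events < 1:
        raise ValueError("target_events must be >= 1")
    if target_events > len(patients):
        raise ValueError("target_events exceeds the number of patients")
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    doc = patients["documented_calendar"].to_numpy(dtype=float)
    if rule == MonitoringRule.UNCENSORED_EVENTS_ONLY:
        flags = hypothetical_flags(patients, shutdown or ShutdownConfig(), censor_on)
        doc = doc[~flags]
    if len(doc) < target_events:
        return horizon, False
    cutoff = float(np.partition(doc, target_events - 1)[target_events - 1])
    if cutoff > horizon:
        return horizon, False
    return cutoff, True


def _event_mask(
    enroll: np.ndarray,
    doc_cal: np.ndarray,
    cutoff: float,
    target_events: int | None,
    qualifying: np.ndarray | None = None,
) -> np.ndarray:
    """Events counted at the cutoff, holding the dataset at the design target.

    Documentation piles up at the reopening evaluation, so the target-th
    qualifying event can fall inside a calendar tie; events tied exactly at
    the cutoff beyond the target are then demoted to censored rows
    (arm-neutral deterministic tie-break: latest enrollment first), mirroring
    an analysis frozen at the prespecified event count.  ``qualifying``
    restricts the count (delayed-analysis monitoring); ``target_events=None``
    disables the cap.
    """
    event = doc_cal <= cutoff
    if target_events is None:
        return event
    counted = event if qualifying is None else (event & qualifying)
    excess = int(counted.sum()) - target_events
    if excess > 0:
        tied = np.flatnonzero(counted & (doc_cal == cutoff))
        if len(tied) >= excess:
            demote = tied[np.argsort(-enroll[tied], kind="stable")[:excess]]
            event[demote] = False
    return event


def _snap(x: np.ndarray) -> np.ndarray:
    """Round patient-scale times to 1e-9 months.

    Times from randomization are differences of calendar times; without
    rounding, float cancellation splits one grid time (e.g. 12.0) into
    several nearby endpoints, which corrupts tie handling and the Turnbull
    interval construction.
    """
    return np.round(x, 9)


def _reopen_eligible(
    enroll: np.ndarray,
    true_t: np.ndarray,
    via_reopen: np.ndarray,
    shutdown: ShutdownConfig,
) -> np.ndarray | None:
    """Whose record carries the reopening evaluation as an assessment.

    Only patients whose pending progression it documents: for everyone else
    the sites reopen and the regular scan schedule resumes, so censoring
    falls on regular (non-suppressed) scans.  This also keeps every
    censoring interval consistent with the latent event time — a patient
    whose progression arose between a suppressed scan and reopening but is
    documented at a later regular scan has no negative reopening assessment
    on record.
    """
    if not shutdown.enabled:
        return None
    return np.asarray(via_reopen, dtype=bool)


def _columns(patients: pd.DataFrame):
    return (
        patients["arm"].to_numpy(),
        patients["enrollment"].to_numpy(dtype=float),
        patients["true_time"].to_numpy(dtype=float),
        patients["documented_calendar"].to_numpy(dtype=float),
        patients["via_reopening"].to_numpy(dtype=bool),
    )


def derive_exact_times(
    patients: pd.DataFrame, cutoff: float, target_reached: bool = True
) -> AnalysisDataset:
    """Benchmark dataset on the latent event times (no assessment grid)."""
    arm, enroll, true_t, _, _ = _columns(patients)
    keep = enroll <= cutoff
    arm, enroll, true_t = arm[keep], enroll[keep], true_t[keep]
    event = enroll + true_t <= cutoff
    time = _snap(np.where(event, true_t, cutoff - enroll))
    data = pd.DataFrame({"arm": arm, "time": time, "event": event.astype(np.int8)})
    return AnalysisDataset("exact_times", cutoff, data, target_reached)


def derive_treatment_policy(
    patients: pd.DataFrame,
    cutoff: float,
    design: TrialDesign,
    shutdown: ShutdownConfig,
    target_reached: bool = True,
    target_events: int | None = None,
    strategy_name: str = "treatment_policy",
) -> AnalysisDataset:
    """Events at their documented times; others censored at the last assessment."""
    sub = patients[patients["enrollment"].to_numpy(dtype=float) <= cutoff]
    arm, enroll, true_t, doc_cal, via_reopen = _columns(sub)
    event = _event_mask(enroll, doc_cal, cutoff, target_events)
    last = last_assessment_calendar(
        enroll, doc_cal, cutoff, design, shutdown, strict=False,
        reopen_eligible=_reopen_eligible(enroll, true_t, via_reopen, shutdown),
    )
    censor_time = np.clip(np.nan_to_num(last - enroll, nan=0.0), 0.0, None)
    time = _snap(np.where(event, doc_cal - enroll, censor_time))
    data = pd.DataFrame({"arm": arm, "time": time, "event": event.astype(np.int8)})
    return AnalysisDataset(strategy_name, cutoff, data, target_reached)


def derive_hypothetical(
    patients: pd.DataFrame,
    cutoff: float,
    design: TrialDesign,
    shutdown: ShutdownConfig,
    target_reached: bool = True,
    target_events: int | None = None,
    censor_on: str = "documented",
    delayed: bool = False,
    strategy_name: str | None = None,
) -> AnalysisDataset:
    """Treatment-policy rows with shutdown-affected events censored pre-window.

    Flagged events (see :func:`hypothetical_flags`) become censored at the
    patient's last assessment strictly before the window (0 when there was
    none).  With ``delayed=True`` the event-count cap applies to the
    *qualifying* (unflagged) events, matching the uncensored-events-only
    monitoring that produced the cutoff.
    """
    if strategy_name is None:
        strategy_name = "hypothetical_delayed" if delayed else "hypothetical"
    sub = patients[patients["enrollment"].to_numpy(dtype=float) <= cutoff]
    arm, enroll, true_t, doc_cal, via_reopen = _columns(sub)
    flagged = hypothetical_flags(sub, shutdown, censor_on)

    event = _event_mask(
        enroll, doc_cal, cutoff, target_events,
        qualifying=(~flagged if delayed else None),
    )
    last = last_assessment_calendar(
        enroll, doc_cal, cutoff, design, shutdown, strict=False,
        reopen_eligible=_reopen_eligible(enroll, true_t, via_reopen, shutdown),
    )
    censor_time = np.clip(np.nan_to_num(last - enroll, nan=0.0), 0.0, None)
    time = np.where(event, doc_cal - enroll, censor_time)

    if shutdown.enabled:
        to_censor = flagged & event
        last_pre = last_assessment_calendar(
            enroll, doc_cal, shutdown.start, design, shutdown, strict=True
        )
        pre_time = np.clip(np.nan_to_num(last_pre - enroll, nan=0.0), 0.0, None)
        time = np.where(to_censor, pre_time, time)
        event = event & ~to_censor
    data = pd.DataFrame({"arm": arm, "time": _snap(time), "event": event.astype(np.int8)})
    return AnalysisDataset(strategy_name, cutoff, data, target_reached)


def derive_interval_dataset(
    patients: pd.DataFrame,
    cutoff: float,
    design: TrialDesign,
    shutdown: ShutdownConfig,
    target_reached: bool = True,
    target_events: int | None = None,
) -> AnalysisDataset:
    """Censoring intervals (last negative assessment, documenting assessment].

    Documented events contribute ``(previous assessment, documenting
    assessment]`` (0 when the documenting assessment was the first); patients
    undocumented at the cutoff contribute ``(last assessment by cutoff, inf)``.
    """
    sub = patients[patients["enrollment"].to_numpy(dtype=float) <= cutoff]
    arm, enroll, true_t, doc_cal, via_reopen = _columns(sub)
    event = _event_mask(enroll, doc_cal, cutoff, target_events)
    eligible = _reopen_eligible(enroll, true_t, via_reopen, shutdown)

    prev = last_assessment_calendar(
        enroll, doc_cal, doc_cal, design, shutdown, strict=True,
        reopen_eligible=eligible,
    )
    left_event = np.clip(np.nan_to_num(prev - enroll, nan=0.0), 0.0, None)

    last = last_assessment_calendar(
        enroll, doc_cal, cutoff, design, shutdown, strict=False,
        reopen_eligible=eligible,
    )
    left_cens = np.clip(np.nan_to_num(last - enroll, nan=0.0), 0.0, None)

    left = _snap(np.where(event, left_event, left_cens))
    right = _snap(np.where(event, doc_cal - enroll, np.inf))
    if np.any(right <= left):
        raise RuntimeError("internal consistency error: right <= left interval")
    data = pd.DataFrame({"arm": arm, "left": left, "right": right})
    return AnalysisDataset("interval", cutoff, data, target_reached)
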