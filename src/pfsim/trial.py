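"""Patient-level trial generation and the shutdown's effect on documentation.

A simulated trial is a :class:`pandas.DataFrame` with one row per patient:

======================  =======================================================
column                  meaning (all times in months)
======================  =======================================================
``arm``                 0 = control, 1 = experimental
``enrollment``          calendar time of randomization (after any shutdown
                        shift)
``true_time``           latent event time, from randomization
``detection_time``      scan-grid detection time absent any shutdown, from
                        randomization (first multiple of the scan interval at
                        or after ``true_time``)
``documented_time``     time at which the event is actually documented, from
                        randomization
``documented_calendar`` ``enrollment + documented_time``
``via_reopening``       True when the event was documented at the reopening
                        evaluation because the shutdown suppressed its regular
                        detection scan (or the event itself fell in the window)
======================  =======================================================

Progression can only be seen at a performed assessment, so documented times
are right-shifted proxies of the true times: without a shutdown the gap is
below one scan interval; with a shutdown it can grow to the window length
plus one interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ShutdownConfig, TrialDesign

__all__ = [
    "sample_accrual_times",
    "assign_arms",
    "sample_event_times",
    "grid_detection_time",
    "apply_shutdown",
    "simulate_trial",
    "assessment_times",
    "last_assessment_calendar",
]

#: tolerance used when snapping calendar times onto the per-patient scan grid
_GRID_TOL = 1e-9

ARM_CONTROL = 0
ARM_EXPERIMENTAL = 1


def sample_accrual_times(design: TrialDesign, rng: np.random.Generator) -> np.ndarray:
    """Enrollment calendar times: ``accrual_duration * Beta(a, b)`` draws."""
    return design.accrual_duration * rng.beta(
        design.accrual_shape_a, design.accrual_shape_b, size=design.n_patients
    )


def assign_arms(design: TrialDesign, rng: np.random.Generator) -> np.ndarray:
    """Balanced permuted arm assignment (exact counts per allocation ratio)."""
    n = design.n_patients
    n_exp = int(round(n * design.allocation_ratio / (1.0 + design.allocation_ratio)))
    arms = np.repeat(
        [ARM_CONTROL, ARM_EXPERIMENTAL], [n - n_exp, n_exp]
    ).astype(np.int8)
    rng.shuffle(arms)
    return arms


def sample_event_times(
    design: TrialDesign, arms: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exponential latent event times, proportional hazards across arms."""
    rate = np.where(
        arms == ARM_EXPERIMENTAL, design.experimental_rate, design.control_rate
    )
    return rng.exponential(1.0 / rate)


def grid_detection_time(true_time, scan_interval: float):
    """First positive multiple of ``scan_interval`` at or after ``true_time``.

    This is the scan at which the event would be documented in the absence
    of any shutdown (scans run every ``scan_interval`` months from
    randomization until documented progression).
    """
    if scan_interval <= 0:
        raise ValueError("scan_interval must be positive")
    t = np.asarray(true_time, dtype=float)
    if np.any(t < 0):
        raise ValueError("true_time must be non-negative")
    k = np.maximum(np.ceil(t / scan_interval - _GRID_TOL), 1.0)
    out = k * scan_interval
    return float(out) if np.isscalar(true_time) else out


def apply_shutdown(
    patients: pd.DataFrame, design: TrialDesign, shutdown: ShutdownConfig
) -> pd.DataFrame:
    """Shift accrual and re-document events affected by the shutdown window.

    * Enrollment at or after the window start is delayed by the window
      length (accrual is suspended, not re-drawn).
    * Scans falling inside ``[start, end)`` are not performed; the missed
      assessments are made up by a reopening evaluation at ``end``, so an
      event whose regular detection scan was suppressed is documented there
      (``via_reopening``).  An event whose detection scan falls after the
      window is documented at that scan as usual.
    """
    out = patients.copy()
    if not shutdown.enabled:
        return out
    start, end = shutdown.start, shutdown.end

    enroll = patients["enrollment"].to_numpy(dtype=float)
    enroll = np.where(enroll >= start, enroll + shutdown.duration, enroll)
    detect_cal = enroll + patients["detection_time"].to_numpy(dtype=float)

    affected = (detect_cal >= start) & (detect_cal < end)
    doc_cal = np.where(affected, end, detect_cal)

    out["enrollment"] = enroll
    out["documented_calendar"] = doc_cal
    out["documented_time"] = doc_cal - enroll
    out["via_reopening"] = affected
    return out


def simulate_trial(
    design: TrialDesign,
    shutdown: ShutdownConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Generate one complete trial; deterministic given the seed."""
    rng = np.random.default_rng(rng)
    shutdown = shutdown or ShutdownConfig()

    enroll = sample_accrual_times(design, rng)
    arms = assign_arms(design, rng)
    true_t = sample_event_times(design, arms, rng)
    detect_t = grid_detection_time(true_t, design.scan_interval)

    trial = pd.DataFrame(
        {
            "arm": arms,
            "enrollment": enroll,
            "true_time": true_t,
            "detection_time": detect_t,
            "documented_time": detect_t,
            "documented_calendar": enroll + detect_t,
            "via_reopening": np.zeros(design.n_patients, dtype=bool),
        }
    )
    return apply_shutdown(trial, design, shutdown)


def last_assessment_calendar(
    enrollment: np.ndarray,
    documented_calendar: np.ndarray,
    cutoff,
    design: TrialDesign,
    shutdown: ShutdownConfig,
    strict: bool = False,
    reopen_eligible: np.ndarray | None = None,
) -> np.ndarray:
    """Calendar time of each patient's last performed assessment by ``cutoff``.

    Assessments are the per-patient grid ``enrollment + k * scan_interval``
    (k >= 1) up to and including the documenting scan, minus scans inside the
    shutdown window, plus the reopening evaluation for patients enrolled
    before the window and still undocumented at reopening
    (``reopen_eligible`` restricts who received that make-up evaluation;
    default everyone).  With ``strict=True`` only assessments strictly
    before ``cutoff`` qualify (used for "last assessment prior to the
    shutdown" and "assessment preceding the documenting one").  Returns NaN
    where no assessment qualifies.
    """
    e = np.asarray(enrollment, dtype=float)
    doc = np.asarray(documented_calendar, dtype=float)
    c = np.broadcast_to(np.asarray(cutoff, dtype=float), e.shape)
    delta = design.scan_interval

    # assessments stop once the event is documented
    c_eff = np.minimum(c, doc)
    if strict:
        # strictness applies to the requested cutoff, not to documentation:
        # the documenting scan itself is performed
        k = np.where(
            c <= doc,
            np.ceil((c_eff - e) / delta - _GRID_TOL) - 1,
            np.floor((c_eff - e) / delta + _GRID_TOL),
        )
    else:
        k = np.floor((c_eff - e) / delta + _GRID_TOL)
    grid = np.where(k >= 1, e + k * delta, np.nan)

    if shutdown.enabled:
        s, r = shutdown.start, shutdown.end
        in_window = (grid >= s) & (grid < r)
        k_pre = np.ceil((s - e) / delta - _GRID_TOL) - 1
        pre = np.where(k_pre >= 1, e + k_pre * delta, np.nan)
        grid = np.where(in_window, pre, grid)
        # reopening evaluation, for pre-window enrollees undocumented at reopening
        reopen_ok = (
            (e < s)
            & (doc >= r)
            & ((r < c) if strict else (r <= c))
            & (r <= c_eff)
        )
        if reopen_eligible is not None:
            reopen_ok &= np.asarray(reopen_eligible, dtype=bool)
        reopen = np.where(reopen_ok, r, np.nan)
        grid = np.fmax(grid, reopen)
    return grid


def assessment_times(
    enrollment: float,
    documented_calendar: float,
    design: TrialDesign,
    shutdown: ShutdownConfig | None = None,
    reopen_eligible: bool = True,
) -> np.ndarray:
    """Calendar times of all assessments performed for one patient.

    ``reopen_eligible=False`` drops the reopening make-up evaluation (it is
    not performed for patients whose progression arose between their last
    suppressed scan and reopening but is documented at a later regular scan).
    """
    shutdown = shutdown or ShutdownConfig()
    delta = design.scan_interval
    k_max = int(np.floor((documented_calendar - enrollment) / delta + _GRID_TOL))
    cal = enrollment + delta * np.arange(1, k_max + 1)
    if shutdown.enabled:
        s, r = shutdown.start, shutdown.end
        cal = cal[(cal < s) | (cal >= r)]
        if reopen_eligible and enrollment < s and documented_calendar >= r:
            cal = np.union1d(cal, [r])
    return cal[cal <= documented_calendar + _GRID_TOL]
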