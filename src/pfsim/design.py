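"""Trial design constants and design arithmetic.

A two-arm randomized trial with an exponential time-to-progression in each
arm, staggered accrual following a scaled Beta distribution, periodic tumor
assessments on a per-patient grid, and an event-driven analysis trigger.
A :class:`ShutdownConfig` describes a calendar window during which accrual
and tumor assessments are suspended (e.g. a pandemic shutdown).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import special, stats

__all__ = [
    "TrialDesign",
    "ShutdownConfig",
    "schoenfeld_events",
    "accrual_fraction",
    "scenario_1",
    "scenario_2",
]


@dataclass(frozen=True)
class TrialDesign:
    """All design constants of one simulated trial.

    Parameters
    ----------
    n_patients : total sample size.
    median_pfs_control : true median PFS in the control arm, months.
    hazard_ratio : true hazard ratio, experimental vs control.
    accrual_duration : length of the accrual period, months.
    target_events : number of events that triggers the analysis.
    allocation_ratio : experimental:control allocation (1.0 = 1:1).
    accrual_shape_a, accrual_shape_b : Beta shape parameters of the accrual
        distribution; enrollment times are ``accrual_duration * Beta(a, b)``.
        The default ``a=1.5, b=1`` front-loads accrual toward the end
        (slower start).
    scan_interval : months between tumor assessments, counted from
        randomization.
    alpha_two_sided : two-sided type-I error of the logrank test.
    design_power : nominal power the target event count was sized for.
    """

    n_patients: int
    median_pfs_control: float
    hazard_ratio: float
    accrual_duration: float
    target_events: int
    allocation_ratio: float = 1.0
    accrual_shape_a: float = 1.5
    accrual_shape_b: float = 1.0
    scan_interval: float = 2.0
    alpha_two_sided: float = 0.05
    design_power: float = 0.90

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in (
            "median_pfs_control",
            "hazard_ratio",
            "accrual_duration",
            "allocation_ratio",
            "accrual_shape_a",
            "accrual_shape_b",
            "scan_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha_two_sided < 1:
            raise ValueError("alpha_two_sided must be in (0, 1)")
        if not 0 < self.design_power < 1:
            raise ValueError("design_power must be in (0, 1)")
        if not 1 <= self.target_events <= self.n_patients:
            raise ValueError("target_events must be in [1, n_patients]")

    @property
    def control_rate(self) -> float:
        """Exponential hazard rate of the control arm (per month)."""
        return math.log(2.0) / self.median_pfs_control

    @property
    def experimental_rate(self) -> float:
        return self.hazard_ratio * self.control_rate

    @property
    def median_pfs_experimental(self) -> float:
        """True median PFS implied in the experimental arm, months."""
        return self.median_pfs_control / self.hazard_ratio


@dataclass(frozen=True)
class ShutdownConfig:
    """Calendar window (months from accrual start) with no enrollment or scans.

    The window is half-open, ``[start, start + duration)``: an assessment
    scheduled exactly at ``start + duration`` is performed (that is the
    reopening evaluation).  ``duration == 0`` means no shutdown.
    """

    start: float = 0.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.duration < 0:
            raise ValueError("start and duration must be non-negative")

    @property
    def enabled(self) -> bool:
        return self.duration > 0

    @property
    def end(self) -> float:
        """Reopening time: first calendar instant with sites open again."""
        return self.start + self.duration


def schoenfeld_events(
    hazard_ratio: float,
    alpha_two_sided: float = 0.05,
    power: float = 0.90,
    allocation_ratio: float = 1.0,
) -> int:
    """Number of events required by Schoenfeld's formula (rounded up).

    ``D = (1 + r)^2 / r * (z_{1-a/2} + z_{power})^2 / (log HR)^2`` with
    allocation ratio ``r``.  With HR 0.70, alpha 0.05 and power 0.90 this
    gives 331 events; with HR 0.60, 162 events.
    """
    if hazard_ratio <= 0 or hazard_ratio == 1.0:
        raise ValueError("hazard_ratio must be positive and != 1")
    r = allocation_ratio
    z = stats.norm.ppf(1 - alpha_two_sided / 2.0) + stats.norm.ppf(power)
    d = (1 + r) ** 2 / r * z**2 / math.log(hazard_ratio) ** 2
    return math.ceil(d)


def accrual_fraction(t: float, design: TrialDesign) -> float:
    """Expected fraction of patients enrolled by calendar time ``t``.

    This is the CDF of the scaled Beta accrual distribution; with b = 1 it
    reduces to ``(t / accrual_duration) ** a``.
    """
    x = min(max(t / design.accrual_duration, 0.0), 1.0)
    return float(special.betainc(design.accrual_shape_a, design.accrual_shape_b, x))


def scenario_1() -> TrialDesign:
    """500 patients, control median 12 mo, HR 0.70, 12-mo accrual, 331 events."""
    return TrialDesign(
        n_patients=500,
        median_pfs_control=12.0,
        hazard_ratio=0.70,
        accrual_duration=12.0,
        target_events=331,
    )


def scenario_2() -> TrialDesign:
    """220 patients, control median 12 mo, HR 0.60, 6-mo accrual, 162 events."""
    return TrialDesign(
        n_patients=220,
        median_pfs_control=12.0,
        hazard_ratio=0.60,
        accrual_duration=6.0,
        target_events=162,
    )
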