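"""Isotonic-release trace processing and fiber-level quality control.

A force-clamp (isotonic) release steps the load on an activated fiber down to
a fraction of its isometric force Po; after a brief transient the fiber
shortens at constant velocity.  The velocity for each release is the negative
slope of a least-squares line fitted to the length channel over the last
100 ms of the 150 ms step, divided by the fiber's initial length (FL·s⁻¹).

A fiber's data are rejected when any of three rules trips: the isometric
force ran down by more than 10% across the release series, the sarcomere
length moved by more than 0.15 µm from its pre-activation set point, or the
Hill fit to the extracted (force, velocity) points has R² below 0.96.
Observations exactly at a threshold are accepted (the rules are strict
inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ReleaseTrace",
    "VelocityPoint",
    "QCThresholds",
    "QCResult",
    "extract_release_velocity",
    "apply_qc",
]

# single-release shortening above this fraction of initial length is flagged
SERIES_SHORTENING_CAP = 0.20


@dataclass
class ReleaseTrace:
    """One force-clamp release, sampled uniformly; t = 0 at clamp onset.

    Channels: time (s), force (µN), absolute fiber length (mm) and sarcomere
    length (µm). ``clamp_level`` records the commanded force as a fraction of
    the fiber's current Po when known (generator metadata).
    """

    time_s: np.ndarray
    force_uN: np.ndarray
    length_mm: np.ndarray
    sarcomere_um: np.ndarray
    clamp_level: float | None = None
    series: int | None = None
    index: int | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_uN = np.asarray(self.force_uN, dtype=float)
        self.length_mm = np.asarray(self.length_mm, dtype=float)
        self.sarcomere_um = np.asarray(self.sarcomere_um, dtype=float)
        n = self.time_s.size
        if n < 3:
            raise ValueError("trace needs at least 3 samples")
        for name in ("force_uN", "length_mm", "sarcomere_um"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length mismatch")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(dt) - np.min(dt) > 1e-6 * np.mean(dt) + 1e-12:
            raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def duration(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class VelocityPoint:
    """One (force, velocity) observation extracted from a release."""

    force: float  # µN, mean clamped force over the regression window
    velocity: float  # FL·s⁻¹, shortening positive
    regression_r2: float
    shortening_fraction: float  # total shortening over the step / initial length


@dataclass(frozen=True)
class QCThresholds:
    """Rejection thresholds; defaults are the standard skinned-fiber rules."""

    max_po_drop: float = 0.10  # fraction of initial Po
    max_sl_change: float = 0.15  # µm
    min_fit_r2: float = 0.96

    def __post_init__(self) -> None:
        if not (0 < self.max_po_drop <= 1 and self.max_sl_change > 0
                and 0 < self.min_fit_r2 <= 1):
            raise ValueError("QC thresholds out of range")


@dataclass(frozen=True)
class QCResult:
    accepted: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)
    po_drop_observed: float = 0.0
    sl_change_observed: float = 0.0
    fit_r2: float = 1.0


def extract_release_velocity(
    trace: ReleaseTrace,
    initial_length: float,
    step_duration: float = 0.150,
    regression_window: float = 0.100,
) -> VelocityPoint:
    """Extract shortening velocity from the tail of a force-clamp release.

    Fits a least-squares line to length vs. time over
    ``[step_duration − regression_window, step_duration]`` (measured from the
    first sample) and returns ``velocity = −slope / initial_length`` in
    FL·s⁻¹ together with the mean clamped force over the same window.
    """
    if initial_length <= 0:
        raise ValueError("initial_length must be > 0")
    if regression_window <= 0 or regression_window > step_duration:
        raise ValueError("regression_window must lie in (0, step_duration]")
    if trace.duration + 1e-9 < step_duration:
        raise ValueError(
            f"trace covers {trace.duration:.4f}s < step duration {step_duration}s"
        )
    t0 = trace.time_s[0]
    lo, hi = t0 + step_duration - regression_window, t0 + step_duration
    mask = (trace.time_s >= lo - 1e-12) & (trace.time_s <= hi + 1e-12)
    t = trace.time_s[mask]
    length = trace.length_mm[mask]
    if t.size < 3:
        raise ValueError("fewer than 3 samples in the regression window")

    ss_len = float(np.sum((length - length.mean()) ** 2))
    if ss_len < 1e-24:
        # constant length: zero velocity, the line fits the data exactly
        slope, r2 = 0.0, 1.0
    else:
        res = _sps.linregress(t, length)
        slope, r2 = float(res.slope), float(res.rvalue**2)

    force = float(np.mean(trace.force_uN[mask]))
    # total shortening over the step relative to initial length
    step_mask = trace.time_s <= hi + 1e-12
    l_step = trace.length_mm[step_mask]
    shortening = float((l_step[0] - l_step[-1]) / initial_length)
    if shortening > SERIES_SHORTENING_CAP:
        warnings.warn(
            f"release shortened {shortening:.1%} of initial length "
            f"(> {SERIES_SHORTENING_CAP:.0%} series cap)",
            stacklevel=2,
        )
    return VelocityPoint(
        force=force,
        velocity=-slope / initial_length,
        regression_r2=r2,
        shortening_fraction=shortening,
    )


def apply_qc(
    po_readings: Sequence[float],
    sarcomere_readings: Sequence[float],
    hill_fit_r2: float,
    thresholds: QCThresholds = QCThresholds(),
) -> QCResult:
    """Apply the three rejection rules to one fiber's experiment telemetry.

    ``po_readings`` are the per-series isometric force re-measurements (first
    entry = reference Po); ``sarcomere_readings`` the per-series sarcomere
    lengths (first entry = pre-activation set point).  Rules are strict: a
    drop of exactly 10%, a shift of exactly 0.15 µm or R² exactly 0.96 pass.
    """
    po = np.asarray(po_readings, dtype=float)
    sl = np.asarray(sarcomere_readings, dtype=float)
    if po.size < 2:
        raise ValueError("need at least two Po readings (initial + re-measurement)")
    if sl.size < 1:
        raise ValueError("need at least one sarcomere reading")
    if po[0] <= 0:
        raise ValueError("initial Po must be > 0")

    po_drop = float(1.0 - np.min(po) / po[0])
    sl_change = float(np.max(np.abs(sl - sl[0])))

    reasons = []
    if po_drop > thresholds.max_po_drop:
        reasons.append("po_drop")
    if sl_change > thresholds.max_sl_change:
        reasons.append("sl_change")
    if hill_fit_r2 < thresholds.min_fit_r2:
        reasons.append("fit_r2")
    return QCResult(
        accepted=not reasons,
        reasons=tuple(reasons),
        po_drop_observed=po_drop,
        sl_change_observed=sl_change,
        fit_r2=float(hill_fit_r2),
    )
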