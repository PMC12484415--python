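"""Closed-form Hill force-velocity mathematics for single muscle fibers.

The rectangular hyperbola (P + a)(V + b) = (Po + a) b relates the clamped
force P on a maximally activated fiber to its steady shortening velocity V.
``Po`` is the maximal isometric force (µN), ``a`` a force constant (µN) and
``b`` a velocity constant (fiber lengths per second, FL·s⁻¹).  Two derived
quantities dominate comparative work:

* ``Vmax = b·Po/a`` — the extrapolated unloaded shortening velocity, and
* ``a/Po`` — a dimensionless curvature index: a *low* a/Po means a sharply
  curved force-velocity relation (little force retained at speed), a high
  a/Po a flatter one.

When force is normalized to Po and velocity to Vmax the whole relation
collapses onto ``v(p) = k (1 − p) / (p + k)`` with ``k = a/Po``, so the
normalized power optimum is a function of curvature alone and has the closed
form ``v_opt = p_opt = sqrt(k (1 + k)) − k`` and ``w_max = v_opt²`` (in units
of Po·Vmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HillParameters",
    "FiberMorphology",
    "FiberDerived",
    "NormalizedOptimum",
    "velocity_at_force",
    "force_at_velocity",
    "normalized_power_optimum",
    "normalized_velocity",
    "normalized_power",
    "derive_fiber_parameters",
    "mean_group_curves",
    "percent_difference",
    "curvature_power_elevation",
]


@dataclass(frozen=True)
class HillParameters:
    """Hill hyperbola parameters for one fiber.

    Attributes
    ----------
    po : float
        Maximal isometric force, µN.
    a : float
        Hill force constant, µN.
    b : float
        Hill velocity constant, FL·s⁻¹.
    """

    po: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.po > 0 and self.a > 0 and self.b > 0):
            raise ValueError(
                f"Hill parameters must be strictly positive, got "
                f"po={self.po}, a={self.a}, b={self.b}"
            )

    @property
    def a_over_po(self) -> float:
        """Curvature index k = a/Po (dimensionless)."""
        return self.a / self.po

    @property
    def vmax(self) -> float:
        """Extrapolated unloaded shortening velocity b·Po/a, FL·s⁻¹."""
        return self.b * self.po / self.a


@dataclass(frozen=True)
class FiberMorphology:
    """Morphology of a single fiber segment.

    Attributes
    ----------
    fcsa : float
        Fiber cross-sectional area, µm² (circular cross-section assumed).
    fiber_length : float
        Segment length between attachments, mm.
    sarcomere_length : float
        Sarcomere length set before activation, µm.
    """

    fcsa: float
    fiber_length: float
    sarcomere_length: float = 2.6

    def __post_init__(self) -> None:
        if not (self.fcsa > 0 and self.fiber_length > 0 and self.sarcomere_length > 0):
            raise ValueError("fcsa, fiber_length and sarcomere_length must be > 0")


@dataclass(frozen=True)
class FiberDerived:
    """Quantities derived from a fiber's Hill parameters and morphology."""

    vmax: float  # FL·s⁻¹
    a_over_po: float  # dimensionless
    specific_tension: float  # N·cm⁻²
    max_power: float  # µW
    specific_power: float  # W·L⁻¹


@dataclass(frozen=True)
class NormalizedOptimum:
    """Optimum of the normalized power curve w(p) = p·k(1−p)/(p+k).

    ``v_opt`` and ``p_opt`` are the velocity (fraction of Vmax) and force
    (fraction of Po) at maximal power; they coincide by the symmetry of the
    normalized hyperbola. ``w_max`` is the peak power in units of Po·Vmax.
    """

    v_opt: float
    p_opt: float
    w_max: float


def velocity_at_force(params: HillParameters, force):
    """Shortening velocity (FL·s⁻¹, shortening positive) at a clamped force (µN).

    Solves the hyperbola for V: ``V(P) = b (Po − P) / (P + a)``.  Forces
    outside [0, Po] are outside the measured (concentric) domain and raise.
    Accepts scalars or arrays.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0) or np.any(f > params.po):
        raise ValueError(f"force must lie in [0, Po={params.po}]")
    v = params.b * (params.po - f) / (f + params.a)
    return float(v) if np.ndim(force) == 0 else v


def force_at_velocity(params: HillParameters, velocity):
    """Clamped force (µN) producing a given shortening velocity (FL·s⁻¹).

    Inverse of :func:`velocity_at_force`:
    ``P(V) = (Po + a) b / (V + b) − a``. Velocities above Vmax raise.
    """
    v = np.asarray(velocity, dtype=float)
    vmax = params.vmax
    if np.any(v < 0) or np.any(v > vmax * (1 + 1e-12)):
        raise ValueError(f"velocity must lie in [0, Vmax={vmax}]")
    p = (params.po + params.a) * params.b / (v + params.b) - params.a
    p = np.clip(p, 0.0, params.po)
    return float(p) if np.ndim(velocity) == 0 else p


def normalized_velocity(k: float, p):
    """Normalized hyperbola v(p) = k(1−p)/(p+k) for p in [0, 1]."""
    p = np.asarray(p, dtype=float)
    return k * (1.0 - p) / (p + k)


def normalized_power(k: float, p):
    """Normalized power w(p) = p·v(p), in units of Po·Vmax."""
    p = np.asarray(p, dtype=float)
    return p * normalized_velocity(k, p)


def normalized_power_optimum(k: float) -> NormalizedOptimum:
    """Closed-form optimum of the normalized power curve for curvature k = a/Po.

    ``v_opt = p_opt = sqrt(k(1+k)) − k`` and ``w_max = v_opt²``; the optimum
    approaches (0.5, 0.25) in the linear-relation limit k → ∞ and collapses
    toward zero for strongly curved relations (k → 0).
    """
    if not k > 0:
        raise ValueError(f"curvature k = a/Po must be > 0, got {k}")
    v_opt = float(np.sqrt(k * (1.0 + k)) - k)
    return NormalizedOptimum(v_opt=v_opt, p_opt=v_opt, w_max=v_opt * v_opt)


def derive_fiber_parameters(
    params: HillParameters, morph: FiberMorphology
) -> FiberDerived:
    """Derive Vmax, a/Po, specific tension, maximal power and specific power.

    Unit chain (exact contracts):

    * specific tension [N·cm⁻²] = (Po·1e-6 N) / (fcsa·1e-8 cm²) = 100·Po/fcsa
    * maximal power [µW] = Po[µN] · Vmax[FL·s⁻¹] · FL[mm] · w_max(a/Po) · 1e-3
      (FL·s⁻¹ × fiber length in mm gives mm·s⁻¹; µN·mm·s⁻¹ = 1e-3 µW)
    * specific power [W·L⁻¹] = 1e6 · max_power[µW] / (fcsa[µm²] · FL[mm])
      (fiber volume fcsa·FL is µm²·mm = 1e-12 L)
    """
    vmax = params.vmax
    k = params.a_over_po
    st = 100.0 * params.po / morph.fcsa
    w_max = normalized_power_optimum(k).w_max
    max_power = params.po * vmax * morph.fiber_length * w_max * 1e-3
    specific_power = 1e6 * max_power / (morph.fcsa * morph.fiber_length)
    return FiberDerived(
        vmax=vmax,
        a_over_po=k,
        specific_tension=st,
        max_power=max_power,
        specific_power=specific_power,
    )


def mean_group_curves(groups, n_points: int = 201) -> pd.DataFrame:
    """Sample absolute and normalized force-velocity / force-power curves.

    Parameters
    ----------
    groups : iterable of (label, po, vmax, a_over_po) or
        (label, po, vmax, a_over_po, fiber_length_mm)
        Group mean parameters; ``po`` may be a mean Po in µN or a mean
        specific tension (the absolute columns then carry that unit).
        ``fiber_length_mm`` converts FL·s⁻¹ to mm·s⁻¹ for absolute power
        and defaults to 1 mm (power per mm of fiber).
    n_points : int
        Number of force samples from 0 to Po inclusive.

    Returns
    -------
    DataFrame with columns ``group, p_norm, v_norm, w_norm, force_uN,
    velocity_fl_s, power_uW``.  The peak of ``w_norm`` within each group
    equals ``normalized_power_optimum(a_over_po).w_max`` up to sampling.
    """
    frames = []
    for grp in groups:
        label, po, vmax, k = grp[:4]
        fl_mm = grp[4] if len(grp) > 4 else 1.0
        if not (po > 0 and vmax > 0 and k > 0 and fl_mm > 0):
            raise ValueError(f"group {label!r}: po, vmax, a/Po, FL must be > 0")
        p_norm = np.linspace(0.0, 1.0, n_points)
        v_norm = normalized_velocity(k, p_norm)
        w_norm = p_norm * v_norm
        force = p_norm * po
        velocity = v_norm * vmax
        power = force * velocity * fl_mm * 1e-3  # µN · mm·s⁻¹ = 1e-3 µW
        frames.append(
            pd.DataFrame(
                {
                    "group": label,
                    "p_norm": p_norm,
                    "v_norm": v_norm,
                    "w_norm": w_norm,
                    "force_uN": force,
                    "velocity_fl_s": velocity,
                    "power_uW": power,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def percent_difference(value_a: float, value_b: float) -> float:
    """Percent by which ``value_a`` exceeds ``value_b``: 100·(a/b − 1)."""
    if not value_b > 0:
        raise ValueError(f"reference value must be > 0, got {value_b}")
    return 100.0 * (value_a / value_b - 1.0)


def curvature_power_elevation(
    k_a: float,
    k_b: float,
    vmax_a: float | None = None,
    vmax_b: float | None = None,
    normalization: str = "po_vmax",
) -> float:
    """Percent peak-power elevation of curve A over curve B due to curvature.

    Two constructions are exposed because the answer depends on the
    normalization of the power axis:

    * ``"po_vmax"`` — both curves normalized to their own Po·Vmax, so the
      comparison isolates curvature alone: 100·(w_max(k_a)/w_max(k_b) − 1).
    * ``"po_only"`` — force normalized to Po but velocity kept absolute
      (FL·s⁻¹), so each curve's peak is w_max(k)·Vmax and the elevation mixes
      curvature with the Vmax difference; requires ``vmax_a``/``vmax_b``.
    """
    wa = normalized_power_optimum(k_a).w_max
    wb = normalized_power_optimum(k_b).w_max
    if normalization == "po_vmax":
        return percent_difference(wa, wb)
    if normalization == "po_only":
        if vmax_a is None or vmax_b is None:
            raise ValueError("po_only normalization requires vmax_a and vmax_b")
        return percent_difference(wa * vmax_a, wb * vmax_b)
    raise ValueError(f"unknown normalization {normalization!r}")
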