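"""Hill force-velocity model fitting.

``HillModel`` holds one fiber's extracted (force, velocity) observations and
fits the rectangular hyperbola V = b (Po − P) / (P + a) by nonlinear least
squares in velocity space.  By default Po is fixed at the isometrically
measured value and only the Hill constants (a, b) are estimated
(``po_mode="fixed"``); ``po_mode="free"`` additionally estimates Po for
sensitivity checks.  ``fit()`` returns a :class:`HillFitResults` carrying the
estimates, their asymptotic standard errors, R², residuals and a
``summary()`` table; derived quantities (Vmax, a/Po, specific tension,
power) hang off the results object.

The (a, b) problem is separable: for any a, the optimal b is a linear
least-squares coefficient.  The fit therefore profiles b out, locates a by a
bounded one-dimensional search, and polishes (a, b) jointly with a bounded
Levenberg–Marquardt/TRF iteration, which makes the solution independent of
the starting point within the documented initialization box and exact on
noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .hill import (
    FiberMorphology,
    HillParameters,
    derive_fiber_parameters,
    normalized_power_optimum,
)
from .traces import VelocityPoint

__all__ = ["HillModel", "HillFitResults", "fit_hill", "vmax_from_fit"]


class HillModel:
    """Hill hyperbola model for one fiber's force-velocity data.

    Parameters
    ----------
    force : array-like
        Clamped forces, µN.
    velocity : array-like
        Extracted shortening velocities, FL·s⁻¹.
    po : float, optional
        Isometrically measured maximal force, µN.  Required for
        ``po_mode="fixed"``; used as the starting value when free.
    po_mode : {"fixed", "free"}
        Whether Po is pinned to the measured value (default) or estimated.
    loss_axis : {"velocity", "force"}
        Residual axis. The default minimizes velocity residuals, matching the
        observable actually derived from the traces.
    """

    def __init__(self, force, velocity, po: float | None = None,
                 po_mode: str = "fixed", loss_axis: str = "velocity"):
        self.force = np.asarray(force, dtype=float)
        self.velocity = np.asarray(velocity, dtype=float)
        if self.force.shape != self.velocity.shape or self.force.ndim != 1:
            raise ValueError("force and velocity must be 1-d arrays of equal length")
        if np.unique(self.force).size < 3:
            raise ValueError("need at least 3 points with distinct forces")
        if po_mode not in ("fixed", "free"):
            raise ValueError("po_mode must be 'fixed' or 'free'")
        if loss_axis not in ("velocity", "force"):
            raise ValueError("loss_axis must be 'velocity' or 'force'")
        if po_mode == "fixed":
            if po is None or po <= 0:
                raise ValueError("po_mode='fixed' requires a positive measured Po")
            if np.any(self.force >= po):
                raise ValueError("all clamped forces must be below the measured Po")
        self.po = po
        self.po_mode = po_mode
        self.loss_axis = loss_axis

    @classmethod
    def from_points(cls, points: Sequence[VelocityPoint], po_measured: float,
                    **kwargs) -> "HillModel":
        """Build the model from extracted :class:`VelocityPoint` records."""
        force = [p.force for p in points]
        velocity = [p.velocity for p in points]
        return cls(force, velocity, po=po_measured, **kwargs)

    # -- internals ---------------------------------------------------------

    def _profile_b(self, a: float, po: float) -> float:
        """Optimal b for given (a, Po): linear LS coefficient on g=(Po−P)/(P+a)."""
        g = (po - self.force) / (self.force + a)
        denom = float(g @ g)
        if denom <= 0:
            return 0.0
        return float((self.velocity @ g) / denom)

    def _sse_velocity(self, a: float, b: float, po: float) -> float:
        r = self.velocity - b * (po - self.force) / (self.force + a)
        return float(r @ r)

    def fit(self, a0: float | None = None, b0: float | None = None,
            max_iter: int = 10000, tol: float = 1e-12) -> "HillFitResults":
        """Fit the hyperbola; deterministic for identical inputs and options.

        Initialization defaults: a0 = 0.15·Po, b0 = 0.15·max(velocity);
        bounds a ∈ (0, 5·Po], b ∈ (0, 10·max(velocity)].
        """
        v_obs_max = float(np.max(self.velocity))
        if v_obs_max <= 0:
            raise ValueError("at least one positive velocity is required")
        po_ref = self.po if self.po is not None else float(np.max(self.force)) * 1.05
        a0 = 0.15 * po_ref if a0 is None else a0
        b0 = 0.15 * v_obs_max if b0 is None else b0
        a_hi, b_hi = 5.0 * po_ref, 10.0 * v_obs_max
        tiny = 1e-12

        if self.po_mode == "fixed" and self.loss_axis == "velocity":
            # profile out b, bracket a on a log grid, then bounded refinement
            log_grid = np.linspace(np.log(po_ref * 1e-4), np.log(a_hi), 80)
            sse_grid = [
                self._sse_velocity(np.exp(la), self._profile_b(np.exp(la), po_ref),
                                   po_ref)
                for la in log_grid
            ]
            la_best = log_grid[int(np.argmin(sse_grid))]
            res1 = optimize.minimize_scalar(
                lambda la: self._sse_velocity(
                    np.exp(la), self._profile_b(np.exp(la), po_ref), po_ref),
                bounds=(la_best - 1.0, la_best + 1.0),
                method="bounded",
                options={"xatol": 1e-14, "maxiter": max_iter},
            )
            a_init = float(np.exp(res1.x))
            b_init = self._profile_b(a_init, po_ref)
            x0 = np.array([a_init, max(b_init, tiny)])
        else:
            x0 = np.array([a0, b0])

        if self.po_mode == "fixed":
            def resid(x):
                a, b = x
                if self.loss_axis == "velocity":
                    return self.velocity - b * (po_ref - self.force) / (self.force + a)
                pred_f = (po_ref + a) * b / (self.velocity + b) - a
                return self.force - pred_f

            ls = optimize.least_squares(
                resid, x0, bounds=([tiny, tiny], [a_hi, b_hi]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_iter,
            )
            a_hat, b_hat = ls.x
            po_hat = po_ref
        else:
            po_lo = float(np.max(self.force)) * (1 + 1e-9)
            x0 = np.array([max(po_ref, po_lo * 1.01), x0[0], x0[1]])

            def resid(x):
                po, a, b = x
                if self.loss_axis == "velocity":
                    return self.velocity - b * (po - self.force) / (self.force + a)
                pred_f = (po + a) * b / (self.velocity + b) - a
                return self.force - pred_f

            ls = optimize.least_squares(
                resid, x0, bounds=([po_lo, tiny, tiny],
                                   [10 * po_ref, a_hi, b_hi]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_iter,
            )
            po_hat, a_hat, b_hat = ls.x

        params = HillParameters(po=float(po_hat), a=float(a_hat), b=float(b_hat))
        residuals = self.velocity - params.b * (params.po - self.force) / (
            self.force + params.a
        )
        sse = float(residuals @ residuals)
        ss_tot = float(np.sum((self.velocity - self.velocity.mean()) ** 2))
        if ss_tot > 0:
            r2 = 1.0 - sse / ss_tot
        else:
            r2 = 1.0 if sse < 1e-20 else 0.0

        n, p = self.velocity.size, ls.x.size
        cov = None
        if n > p:
            jtj = ls.jac.T @ ls.jac
            try:
                cov = np.linalg.inv(jtj) * sse / (n - p)
            except np.linalg.LinAlgError:
                cov = None
        return HillFitResults(
            model=self,
            params=params,
            r2=r2,
            residuals=residuals,
            n_points=n,
            converged=bool(ls.success),
            sse=sse,
            cov=cov,
        )


@dataclass
class HillFitResults:
    """Results of a Hill force-velocity fit."""

    model: HillModel
    params: HillParameters
    r2: float
    residuals: np.ndarray
    n_points: int
    converged: bool
    sse: float
    cov: np.ndarray | None = field(default=None, repr=False)

    # -- parameter accessors -------------------------------------------------

    @property
    def vmax(self) -> float:
        """Extrapolated unloaded shortening velocity b·Po/a, FL·s⁻¹."""
        return self.params.vmax

    @property
    def a_over_po(self) -> float:
        return self.params.a_over_po

    @property
    def bse(self) -> dict:
        """Asymptotic standard errors of the free parameters (NaN if singular)."""
        names = (["po"] if self.model.po_mode == "free" else []) + ["a", "b"]
        if self.cov is None:
            return {k: float("nan") for k in names}
        return {k: float(np.sqrt(self.cov[i, i])) for i, k in enumerate(names)}

    def predict(self, force):
        """Predicted shortening velocity at the given forces (µN)."""
        from .hill import velocity_at_force

        return velocity_at_force(self.params, force)

    def derive(self, morph: FiberMorphology):
        """Derived quantities (Vmax, a/Po, ST, power) for this fiber."""
        return derive_fiber_parameters(self.params, morph)

    def power_curve(self, n_points: int = 201):
        """Normalized force-velocity/power samples for this fiber's curvature."""
        from .hill import mean_group_curves

        return mean_group_curves(
            [("fiber", self.params.po, self.vmax, self.a_over_po)], n_points
        )

    def summary(self) -> str:
        """Plain-text summary table in the style of regression results."""
        opt = normalized_power_optimum(self.a_over_po)
        se = self.bse
        lines = [
            "Hill force-velocity fit",
            "=" * 46,
            f"{'n points':<28}{self.n_points:>18}",
            f"{'Po mode':<28}{self.model.po_mode:>18}",
            f"{'converged':<28}{str(self.converged):>18}",
            f"{'R^2 (velocity)':<28}{self.r2:>18.6f}",
            "-" * 46,
            f"{'Po [uN]':<20}{self.params.po:>12.3f}"
            + (f"  (se {se['po']:.3f})" if "po" in se else "  (measured)"),
            f"{'a [uN]':<20}{self.params.a:>12.4f}  (se {se['a']:.4f})",
            f"{'b [FL/s]':<20}{self.params.b:>12.6f}  (se {se['b']:.6f})",
            "-" * 46,
            f"{'Vmax [FL/s]':<28}{self.vmax:>18.4f}",
            f"{'a/Po':<28}{self.a_over_po:>18.4f}",
            f"{'w_max [Po*Vmax]':<28}{opt.w_max:>18.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the observations and fitted hyperbola (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = np.linspace(0, self.params.po, 200)
        ax.plot(self.model.force, self.model.velocity, "o", label="releases")
        ax.plot(f, self.predict(f), "-", label="Hill fit")
        ax.set_xlabel("force (µN)")
        ax.set_ylabel("velocity (FL·s⁻¹)")
        ax.legend()
        return ax


def fit_hill(points: Sequence[VelocityPoint], po_measured: float,
             po_mode: str = "fixed", loss_axis: str = "velocity",
             max_iter: int = 10000, tol: float = 1e-12) -> HillFitResults:
    """Fit the Hill hyperbola to extracted velocity points (functional API)."""
    model = HillModel.from_points(points, po_measured, po_mode=po_mode,
                                  loss_axis=loss_axis)
    return model.fit(max_iter=max_iter, tol=tol)


def vmax_from_fit(fit: HillFitResults) -> float:
    """Maximal shortening velocity b·Po/a from a fit, FL·s⁻¹."""
    return fit.vmax
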