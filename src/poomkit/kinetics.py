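"""Two-pool organic-carbon degradation kinetics with POOM positive feedback.

The model tracks organic matter deposited in marine sediments as two pools:
a labile, unoxidized pool ``g1`` that always degrades, and a pool ``g2`` of
partially oxidized organic matter (POOM) that degrades only while exposed to
oxygen.  While oxygen is present (``t <= t_ox``, the oxygen-exposure time),
oxidative metabolisms also convert ``g1`` into POOM at rate ``k12``::

    dg1/dt = -(k1 + k12) g1          t >= 0
    dg2/dt =  k12 g1 - k2 g2         0 <= t <= t_ox

with initial conditions ``g1(0) = (1 - a) g0`` and ``g2(0) = a g0``.  After
``t_ox`` the remaining material enters anoxic sediment: ``g1`` keeps decaying
(and is never preserved) while ``g2`` is frozen and ultimately buried.  Burial
efficiency is therefore ``g2(t_ox) / g0``.

The interesting regime is the positive feedback: when the POOM production rate
constant exceeds the threshold ``k* = a k2 / (1 - a)``, burial efficiency
*increases* with oxygen exposure up to a critical exposure time ``t_ox*`` —
more oxygen leads to more burial and hence more oxygen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "KineticTrajectory",
    "KineticsError",
    "RegimeError",
    "burial_efficiency_simple",
    "burial_efficiency",
    "burial_efficiency_derivative",
    "critical_rate",
    "critical_exposure_time",
    "integrate_kinetics",
    "classify_feedback",
]

#: Relative tolerance (in units of k1) below which the removable singularity
#: of the closed form at k2 = k1 + k12 is evaluated by its analytic limit.
DEGENERATE_RTOL = 1e-9


class KineticsError(ValueError):
    """Invalid kinetic parameters or domain violation."""


class RegimeError(KineticsError):
    """Operation requires the positive-feedback regime (k12 > k*)."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and initial partitioning of the two-pool model.

    Parameters
    ----------
    g0 : float
        Total organic carbon initially deposited (arbitrary mass units, > 0).
    a : float
        Initial POOM fraction ``g2(0)/g0``, in [0, 1].
    k1 : float
        Decay rate constant of the unoxidized pool (1/time, > 0).
    k2 : float
        Oxic decay rate constant of POOM (1/time, > 0).  The model assumes
        POOM is the more recalcitrant pool, i.e. ``k2 < k1``.
    k12 : float
        POOM production rate constant (1/time, >= 0); the integrated effect
        of oxidative metabolism plus mineral protection.
    allow_k2_ge_k1 : bool
        Lift the ``k2 < k1`` model assumption (the closed form itself does
        not require it).  Off by default.
    """

    g0: float
    a: float
    k1: float
    k2: float
    k12: float
    allow_k2_ge_k1: bool = False

    def __post_init__(self) -> None:
        if not self.g0 > 0:
            raise KineticsError(f"g0 must be positive, got {self.g0}")
        if not 0.0 <= self.a <= 1.0:
            raise KineticsError(f"a must lie in [0, 1], got {self.a}")
        if not self.k1 > 0:
            raise KineticsError(f"k1 must be positive, got {self.k1}")
        if not self.k2 > 0:
            raise KineticsError(f"k2 must be positive, got {self.k2}")
        if self.k12 < 0:
            raise KineticsError(f"k12 must be non-negative, got {self.k12}")
        if not self.allow_k2_ge_k1 and not self.k2 < self.k1:
            raise KineticsError(
                f"model assumes k2 < k1 (got k2={self.k2}, k1={self.k1}); "
                "pass allow_k2_ge_k1=True to override"
            )


@dataclass(frozen=True)
class KineticTrajectory:
    """Numerically integrated pool trajectories on a time grid."""

    times: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    t_ox: float

    @property
    def total(self) -> np.ndarray:
        return self.g1 + self.g2


def burial_efficiency_simple(a: float, k2: float, t_ox: float) -> float:
    """Burial efficiency of the two-pool model without POOM production.

    With ``k12 = 0`` the POOM pool simply decays while exposed to oxygen, so
    the fraction of deposited carbon that survives is ``a * exp(-k2 * t_ox)``.
    """
    if not 0.0 <= a <= 1.0:
        raise KineticsError(f"a must lie in [0, 1], got {a}")
    if not k2 > 0:
        raise KineticsError(f"k2 must be positive, got {k2}")
    if t_ox < 0:
        raise KineticsError(f"t_ox must be non-negative, got {t_ox}")
    return a * math.exp(-k2 * t_ox)


def _burial_efficiency_unchecked(p: KineticParams, t: float) -> float:
    # g2(t)/g0 = e^{-k2 t} [a + k12 (1-a) (e^{D t} - 1)/D],  D = k2 - k1 - k12.
    # The D -> 0 singularity is removable; the limit is (a + k12 (1-a) t).
    d = p.k2 - p.k1 - p.k12
    if abs(d) < DEGENERATE_RTOL * p.k1:
        inner = p.a + p.k12 * (1.0 - p.a) * t
    else:
        inner = p.a + p.k12 * (1.0 - p.a) * math.expm1(d * t) / d
    return math.exp(-p.k2 * t) * inner


def burial_efficiency(params: KineticParams, t_ox: float) -> float:
    """Exact burial efficiency ``g2(t_ox)/g0`` of the full model.

    Evaluates the closed-form solution of the oxic-phase equations.  At the
    removable singularity ``k2 = k1 + k12`` the analytic limit is used.
    """
    if t_ox < 0:
        raise KineticsError(f"t_ox must be non-negative, got {t_ox}")
    return _burial_efficiency_unchecked(params, t_ox)


def burial_efficiency_derivative(
    params: KineticParams, t_ox: float, step: float | None = None
) -> float:
    """Numeric d(burial efficiency)/d t_ox by central differences.

    The closed form is entire in ``t_ox``, so the centered stencil is applied
    even at ``t_ox = 0`` (using the analytic continuation to small negative
    times); this keeps the truncation error at ``O(step**2)`` rather than the
    ``O(step)`` of a one-sided stencil.  Default step is ``1e-6 / k1``.
    """
    if step is None:
        step = 1e-6 / params.k1
    lo = _burial_efficiency_unchecked(params, t_ox - step)
    hi = _burial_efficiency_unchecked(params, t_ox + step)
    return (hi - lo) / (2.0 * step)


def critical_rate(a: float, k2: float) -> float:
    """Threshold POOM production rate ``k* = a k2 / (1 - a)``.

    Positive feedback (burial efficiency increasing with oxygen exposure)
    requires ``k12 > k*``.
    """
    if not 0.0 <= a < 1.0:
        raise KineticsError(f"a must lie in [0, 1) for a finite threshold, got {a}")
    if not k2 > 0:
        raise KineticsError(f"k2 must be positive, got {k2}")
    return a * k2 / (1.0 - a)


def critical_exposure_time(params: KineticParams) -> float:
    """Critical oxygen-exposure time ``t_ox*`` maximizing burial efficiency.

    Solves ``d g2 / d t = 0`` for the closed form:

        t_ox* = log[ k2 (a k2 - a k1 - k12) / ((a - 1) k12 (k12 + k1)) ]
                / (k2 - k1 - k12)

    Only defined in the positive-feedback regime ``k12 > k*``; below the
    threshold burial efficiency is monotone non-increasing and there is no
    interior maximum.
    """
    p = params
    k_star = critical_rate(p.a, p.k2)
    if not p.k12 > k_star:
        raise RegimeError(
            f"no interior maximum: k12={p.k12} <= k*={k_star} "
            "(negative-feedback regime)"
        )
    d = p.k2 - p.k1 - p.k12
    arg = (p.k2 * (p.a * p.k2 - p.a * p.k1 - p.k12)) / (
        (p.a - 1.0) * p.k12 * (p.k12 + p.k1)
    )
    if abs(d) < DEGENERATE_RTOL * p.k1:
        # limit k2 -> k1 + k12 of the closed form: g2/g0 ~ e^{-k2 t}(a + c t),
        # stationary at t = 1/k2 - a/c with c = k12 (1 - a)
        c = p.k12 * (1.0 - p.a)
        return 1.0 / p.k2 - p.a / c
    return math.log(arg) / d


def integrate_kinetics(
    params: KineticParams,
    t_ox: float,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> KineticTrajectory:
    """Numerically integrate the piecewise ODE system on a time grid.

    For ``t <= t_ox`` the oxic equations run (decay of both pools plus
    conversion ``g1 -> g2``); for ``t > t_ox`` the system is anoxic: ``g2``
    is frozen at ``g2(t_ox)`` and ``g1`` keeps decaying at ``k1`` alone.
    Serves as the independent numerical route against the closed form.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise KineticsError("t_grid must be a 1-D array with at least 2 points")
    if t[0] != 0.0:
        raise KineticsError(f"t_grid must start at 0, got {t[0]}")
    if not np.all(np.diff(t) > 0):
        raise KineticsError("t_grid must be strictly increasing")
    if t_ox < 0:
        raise KineticsError(f"t_ox must be non-negative, got {t_ox}")

    p = params
    y0 = np.array([(1.0 - p.a) * p.g0, p.a * p.g0])

    def oxic(_t: float, y: np.ndarray) -> list[float]:
        g1, g2 = y
        return [-(p.k1 + p.k12) * g1, p.k12 * g1 - p.k2 * g2]

    def anoxic(_t: float, y: np.ndarray) -> list[float]:
        return [-p.k1 * y[0], 0.0]

    g1 = np.empty_like(t)
    g2 = np.empty_like(t)
    mask_ox = t <= t_ox

    if mask_ox.any():
        # include t=0 explicitly; solve_ivp needs a non-degenerate span
        t_eval = t[mask_ox]
        if t_eval[-1] > 0:
            sol = solve_ivp(
                oxic, (0.0, t_eval[-1]), y0, t_eval=t_eval,
                rtol=rtol, atol=atol, method="DOP853",
            )
            if not sol.success:  # pragma: no cover
                raise KineticsError(f"ODE integration failed: {sol.message}")
            g1[mask_ox], g2[mask_ox] = sol.y
        else:
            g1[mask_ox], g2[mask_ox] = y0[0], y0[1]

    if (~mask_ox).any():
        # state at the switch
        if t_ox > 0:
            sw = solve_ivp(
                oxic, (0.0, t_ox), y0, rtol=rtol, atol=atol, method="DOP853"
            )
            y_sw = sw.y[:, -1]
        else:
            y_sw = y0
        t_an = t[~mask_ox]
        sol = solve_ivp(
            anoxic, (t_ox, t_an[-1]), y_sw, t_eval=t_an,
            rtol=rtol, atol=atol, method="DOP853",
        )
        if not sol.success:  # pragma: no cover
            raise KineticsError(f"ODE integration failed: {sol.message}")
        g1[~mask_ox], g2[~mask_ox] = sol.y

    return KineticTrajectory(times=t, g1=g1, g2=g2, t_ox=t_ox)


def classify_feedback(params: KineticParams) -> str:
    """Classify the feedback regime of a parameter set.

    Returns ``"positive"`` iff ``k12 > k* = a k2 / (1 - a)`` (strict), else
    ``"negative"``; the boundary counts as negative.  With ``a = 1`` the
    threshold is unbounded, so the regime is always negative.
    """
    if params.a >= 1.0:
        return "negative"
    return "positive" if params.k12 > critical_rate(params.a, params.k2) else "negative"
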