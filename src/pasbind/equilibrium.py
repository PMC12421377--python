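"""One-site binding equilibria for direct and competition anisotropy assays.

A receptor ``R`` (mPSF in the motivating system) binds a fluorescent probe
``L`` with dissociation constant ``Kd1`` and, optionally, an unlabeled
competitor ``I`` with dissociation constant ``Kd2``.  All concentrations are
total concentrations in nM.  The module provides

* :func:`fraction_bound_direct` — the depletion-aware quadratic isotherm for
  a two-species (receptor + probe) system;
* :func:`solve_competitive` — the exact analytic solution of the
  three-species competitive equilibrium via the trigonometric form of the
  cubic mass-balance equation;
* :func:`numeric_equilibrium` — an independent brute-force bisection solver
  used as the numerical oracle for the analytic route.

The competitive mass balance eliminates the two complexes and leaves a cubic
in the free-receptor concentration ``R``::

    R^3 + a R^2 + b R + c = 0
    a = Kd1 + Kd2 + Lt + It - Rt
    b = Kd2 (Lt - Rt) + Kd1 (It - Rt) + Kd1 Kd2
    c = -Kd1 Kd2 Rt

which for physically meaningful inputs has exactly one root in ``[0, Rt]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EquilibriumSystem",
    "EquilibriumSolution",
    "fraction_bound_direct",
    "solve_competitive",
    "numeric_equilibrium",
    "free_receptor_competitive",
]


class EquilibriumDomainError(ValueError):
    """Raised when concentrations or dissociation constants are out of domain."""


@dataclass(frozen=True)
class EquilibriumSystem:
    """Total concentrations (nM) and Kds for one receptor/probe/competitor mix.

    ``competitor_total = 0`` encodes a direct-binding (two-species) system.
    """

    receptor_total: float
    probe_total: float
    kd_probe: float
    competitor_total: float = 0.0
    kd_competitor: float = np.inf

    def __post_init__(self) -> None:
        vals = (
            self.receptor_total,
            self.probe_total,
            self.competitor_total,
            self.kd_probe,
            self.kd_competitor,
        )
        for v in vals[:3]:
            if not np.isfinite(v) or v < 0:
                raise EquilibriumDomainError(
                    f"concentrations must be finite and >= 0, got {v!r}"
                )
        if not (self.kd_probe > 0) or not np.isfinite(self.kd_probe):
            raise EquilibriumDomainError("kd_probe must be finite and > 0")
        if not (self.kd_competitor > 0):
            raise EquilibriumDomainError("kd_competitor must be > 0")
        # kd_competitor may be +inf (non-binding competitor), but not nan
        if np.isnan(self.kd_competitor):
            raise EquilibriumDomainError("kd_competitor must not be NaN")


@dataclass(frozen=True)
class EquilibriumSolution:
    """Free receptor and bound fractions at equilibrium."""

    receptor_free: float
    fraction_probe_bound: float
    fraction_competitor_bound: float


def _check_nonneg_finite(**kwargs: float) -> None:
    for name, v in kwargs.items():
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise EquilibriumDomainError(f"{name} must be finite and >= 0, got {v!r}")


def fraction_bound_direct(receptor_total, probe_total, kd):
    """Fraction of probe bound in a receptor+probe system (quadratic isotherm).

    FB = ((Rt+Lt+Kd) - sqrt((Rt+Lt+Kd)^2 - 4 Rt Lt)) / (2 Lt)

    This accounts for probe depletion; the familiar hyperbola Rt/(Rt+Kd) is
    recovered in the limit ``probe_total -> 0``.  Accepts scalars or arrays
    (broadcast); returns the same shape.
    """
    _check_nonneg_finite(receptor_total=receptor_total, probe_total=probe_total)
    kd_arr = np.asarray(kd, dtype=float)
    if not np.all(np.isfinite(kd_arr)) or np.any(kd_arr <= 0):
        raise EquilibriumDomainError(f"kd must be finite and > 0, got {kd!r}")
    lt = np.asarray(probe_total, dtype=float)
    if np.any(lt <= 0):
        raise EquilibriumDomainError("probe_total must be > 0")
    rt = np.asarray(receptor_total, dtype=float)
    s = rt + lt + kd_arr
    disc = s * s - 4.0 * rt * lt
    # disc = (Rt-Lt+Kd)^2 + 4 Lt Kd > 0 always; clip guards rounding.
    # The complex concentration (s - sqrt(disc))/2 is rewritten as
    # 2 Rt Lt / (s + sqrt(disc)) to avoid cancellation when Lt << Kd.
    fb = 2.0 * rt / (s + np.sqrt(np.maximum(disc, 0.0)))
    fb = np.clip(fb, 0.0, 1.0)
    return fb if fb.ndim else float(fb)


def _mass_balance(r, rt, lt, it, kd1, kd2):
    """g(R) = R (1 + Lt/(Kd1+R) + It/(Kd2+R)) - Rt; strictly increasing in R."""
    with np.errstate(invalid="ignore"):
        comp = np.where(np.isinf(kd2), 0.0, it / (kd2 + r))
    return r * (1.0 + lt / (kd1 + r) + comp) - rt


def _newton_polish(r, rt, lt, it, kd1, kd2, iters: int = 3):
    """Refine a root of the mass balance; g' >= 1 so steps are well conditioned."""
    for _ in range(iters):
        g = _mass_balance(r, rt, lt, it, kd1, kd2)
        with np.errstate(invalid="ignore"):
            comp = np.where(np.isinf(kd2), 0.0, it * kd2 / (kd2 + r) ** 2)
        gprime = 1.0 + lt * kd1 / (kd1 + r) ** 2 + comp
        r = np.clip(r - g / gprime, 0.0, rt)
    return r


def free_receptor_competitive(rt, lt, it, kd1, kd2, *, clamp_tol: float = 1e-12):
    """Vectorised analytic free-receptor concentration for the ternary system.

    Solves the cubic mass balance in its trigonometric (three-real-root) form
    and selects the unique physical root in ``[0, Rt]``, then applies a short
    Newton polish on the monotone mass-balance function to remove the
    cancellation error of the closed form.  Degenerate systems (``a^2 - 3b
    <= 0``) fall back to bisection with a warning.

    All arguments broadcast; returns an array (or scalar) of free [R] in nM.
    """
    rt, lt, it, kd1, kd2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (rt, lt, it, kd1, kd2))
    )
    scalar = rt.ndim == 0
    rt = np.atleast_1d(rt).copy()
    lt, it, kd1, kd2 = (np.atleast_1d(x) for x in (lt, it, kd1, kd2))

    r = np.empty_like(rt)
    zero = rt == 0
    r[zero] = 0.0
    todo = ~zero

    # a non-binding competitor (Kd2 = inf) reduces to the two-species quadratic
    inf2 = todo & np.isinf(kd2)
    if np.any(inf2):
        s = rt[inf2] + lt[inf2] + kd1[inf2]
        bound = (s - np.sqrt(np.maximum(s * s - 4.0 * rt[inf2] * lt[inf2], 0.0))) / 2.0
        r[inf2] = np.clip(rt[inf2] - bound, 0.0, rt[inf2])
        todo = todo & ~inf2

    if np.any(todo):
        a = kd1[todo] + kd2[todo] + lt[todo] + it[todo] - rt[todo]
        b = (
            kd2[todo] * (lt[todo] - rt[todo])
            + kd1[todo] * (it[todo] - rt[todo])
            + kd1[todo] * kd2[todo]
        )
        c = -kd1[todo] * kd2[todo] * rt[todo]
        p = a * a - 3.0 * b
        degenerate = p <= 0
        ok = ~degenerate
        r_sub = np.empty_like(a)
        if np.any(ok):
            sq = np.sqrt(p[ok])
            arg = (-2.0 * a[ok] ** 3 + 9.0 * a[ok] * b[ok] - 27.0 * c[ok]) / (
                2.0 * sq**3
            )
            bad = np.abs(arg) > 1.0 + clamp_tol
            if np.any(bad):
                raise EquilibriumDomainError(
                    "arccos argument outside [-1, 1] beyond tolerance: "
                    f"max |arg| = {np.max(np.abs(arg)):.17g}"
                )
            theta = np.arccos(np.clip(arg, -1.0, 1.0))
            r_sub[ok] = -a[ok] / 3.0 + (2.0 / 3.0) * sq * np.cos(theta / 3.0)
        if np.any(degenerate):
            warnings.warn(
                "degenerate cubic (a^2 - 3b <= 0); falling back to bisection",
                RuntimeWarning,
                stacklevel=2,
            )
            idx = np.flatnonzero(todo)[degenerate]
            r_sub[degenerate] = _bisect_free_receptor(
                rt[idx], lt[idx], it[idx], kd1[idx], kd2[idx]
            )
        rt_sub = rt[todo]
        r_sub = np.clip(r_sub, 0.0, rt_sub)
        r[todo] = _newton_polish(r_sub, rt_sub, lt[todo], it[todo], kd1[todo], kd2[todo])

    return float(r[0]) if scalar else r


def _bisect_free_receptor(rt, lt, it, kd1, kd2, iters: int = 110):
    """Vectorised bisection for the mass-balance root on [0, Rt]."""
    lo = np.zeros_like(rt)
    hi = rt.astype(float).copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        g = _mass_balance(mid, rt, lt, it, kd1, kd2)
        high = g > 0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    return 0.5 * (lo + hi)


def _solution_from_r(system: EquilibriumSystem, r: float) -> EquilibriumSolution:
    fb_probe = r / (system.kd_probe + r) if system.probe_total > 0 else 0.0
    if system.competitor_total > 0 and np.isfinite(system.kd_competitor):
        fb_comp = r / (system.kd_competitor + r)
    else:
        fb_comp = 0.0
    return EquilibriumSolution(
        receptor_free=float(r),
        fraction_probe_bound=float(fb_probe),
        fraction_competitor_bound=float(fb_comp),
    )


def solve_competitive(system: EquilibriumSystem) -> EquilibriumSolution:
    """Exact equilibrium of one receptor with a probe and an unlabeled competitor.

    Returns the free receptor concentration and the bound fractions
    ``[RL]/Lt = R/(Kd1+R)`` and ``[RI]/It = R/(Kd2+R)``.
    """
    r = free_receptor_competitive(
        system.receptor_total,
        system.probe_total,
        system.competitor_total,
        system.kd_probe,
        system.kd_competitor,
    )
    return _solution_from_r(system, r)


def numeric_equilibrium(system: EquilibriumSystem) -> EquilibriumSolution:
    """Brute-force oracle: bisection on the monotone mass-balance g(R) on [0, Rt].

    g(0) <= 0 <= g(Rt) always brackets the unique root, so no failure mode
    exists for valid systems.  Terminates when |g| < 1e-12 * max(1, Rt) or the
    bracket is exhausted at machine precision.
    """
    rt = system.receptor_total
    if rt == 0:
        return _solution_from_r(system, 0.0)
    lt, it = system.probe_total, system.competitor_total
    kd1, kd2 = system.kd_probe, system.kd_competitor
    lo, hi = 0.0, float(rt)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:  # bracket exhausted at machine precision,
            break                   # so |g| is far below 1e-12 * max(1, Rt)
        g = _mass_balance(np.float64(mid), lt=lt, it=it, kd1=kd1, kd2=kd2, rt=rt)
        if g > 0:
            hi = mid
        else:
            lo = mid
    return _solution_from_r(system, 0.5 * (lo + hi))
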