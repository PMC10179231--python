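"""Three-compartment effect-site pharmacokinetics for intravenous bolus dosing.

The disposition model is the standard linear mammillary model with a central
compartment (volume ``v1``) exchanging drug with two peripheral compartments,
plus a first-order effect compartment of negligible volume linked to plasma by
``ke0``.  For a unit bolus the plasma concentration is a sum of three
exponentials

    Cp(t) = A exp(-l1 t) + B exp(-l2 t) + C exp(-l3 t),

where the exponents are the negated eigenvalues of the 3x3 disposition rate
matrix and A + B + C = 1/v1.  The effect-site response is the convolution of
Cp with ``ke0 exp(-ke0 t)``, again a finite sum of exponentials.  Because the
solution is closed-form, concentrations can be evaluated exactly at arbitrary
times — in particular as left limits "immediately before" a dose, which a
gridded ODE solution cannot deliver.  Multiple boluses superpose linearly.

Units are fixed throughout the package: minutes, micrograms, litres; a dose in
ug distributed in litres gives ng/mL directly (1 ug/L = 1 ng/mL).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PKParameters",
    "DoseEvent",
    "DosingHistory",
    "HybridDisposition",
    "ConcProfile",
    "hybrid_constants",
    "concentration_at",
    "simulate_profile",
]

#: relative eigenvalue spacing below which the closed form is treated as
#: degenerate and the micro-constants are nudged
_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class PKParameters:
    """Micro rate constants of the disposition model plus the effect-site
    equilibration constant.

    v1 is the central volume in litres; all k's are first-order rate
    constants in 1/min.  ``k12 = k13 = 0`` is allowed and collapses the model
    to one-compartment kinetics.
    """

    v1: float
    k10: float
    k12: float
    k21: float
    k13: float
    k31: float
    ke0: float

    def __post_init__(self) -> None:
        for name in ("v1", "k10", "k21", "k31", "ke0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PK parameter {name} must be strictly positive")
        for name in ("k12", "k13"):
            v = getattr(self, name)
            if not v >= 0 or not np.isfinite(v):
                raise ValueError(f"PK parameter {name} must be finite and >= 0")


@dataclass(frozen=True)
class DoseEvent:
    """A single intravenous fentanyl bolus.

    ``kind`` distinguishes the end-of-surgery bolus from patient-triggered
    PCA demands; only the latter generate MEC observations downstream.
    """

    time_min: float
    dose_ug: float
    kind: str = "pca_demand"

    _KINDS = ("initial_bolus", "pca_demand")

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_min):
            raise ValueError("dose time must be finite")
        if not self.dose_ug > 0:
            raise ValueError("dose must be > 0 ug")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")


@dataclass
class DosingHistory:
    """Timed bolus events for one subject, sorted by time."""

    subject_id: str
    events: list[DoseEvent] = field(default_factory=list)
    observation_end_min: float = 1440.0

    def __post_init__(self) -> None:
        times = [e.time_min for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("dose events must be sorted non-decreasing in time")

    @property
    def demand_events(self) -> list[DoseEvent]:
        return [e for e in self.events if e.kind == "pca_demand"]

    def cumulative_pca_ug(self) -> float:
        return sum(e.dose_ug for e in self.demand_events)


@dataclass(frozen=True)
class HybridDisposition:
    """Closed-form hybrid constants of the disposition + effect model.

    ``exponents`` (1/min) are the negated eigenvalues of the disposition rate
    matrix; ``plasma_coefs`` (1/L) the matching unit-impulse plasma
    coefficients.  ``effect_coefs`` pair with ``effect_exponents`` (the three
    disposition exponents plus ke0) so the unit-impulse effect-site response
    is ``sum(c_i * exp(-mu_i t))``.
    """

    exponents: np.ndarray
    plasma_coefs: np.ndarray
    effect_exponents: np.ndarray
    effect_coefs: np.ndarray


@dataclass
class ConcProfile:
    """Plasma/effect-site concentration curves for one subject (ng/mL)."""

    subject_id: str
    times: np.ndarray
    cp: np.ndarray
    ce: np.ndarray


def _rate_matrix(p: PKParameters) -> np.ndarray:
    """3x3 rate matrix of compartment amounts (central, periph-1, periph-2)."""
    return np.array(
        [
            [-(p.k10 + p.k12 + p.k13), p.k21, p.k31],
            [p.k12, -p.k21, 0.0],
            [p.k13, 0.0, -p.k31],
        ]
    )


def _perturbed(p: PKParameters, rel: float) -> PKParameters:
    """Nudge the micro constants apart to break an eigenvalue tie."""
    return PKParameters(
        v1=p.v1,
        k10=p.k10 * (1 + rel),
        k12=p.k12,
        k21=p.k21 * (1 - rel),
        k13=p.k13,
        k31=p.k31 * (1 + 2 * rel),
        ke0=p.ke0,
    )


def hybrid_constants(params: PKParameters) -> HybridDisposition:
    """Eigen-decompose the disposition system into hybrid constants.

    Exponents satisfy the trace identity ``sum(l) = k10+k12+k21+k13+k31``
    and the determinant identity ``l1*l2*l3 = k10*k21*k31``.  Nearly repeated
    eigenvalues (relative spacing < 1e-9, including collisions with ke0) are a
    measure-zero configuration; the constants are perturbed by ~1e-9 with a
    warning so the closed form stays usable.
    """
    K = _rate_matrix(params)
    lam, V = np.linalg.eig(K)
    lam2 = -lam.real  # mammillary model: eigenvalues real and negative
    idx = np.argsort(lam2)[::-1]
    lam2 = lam2[idx]
    V = V.real[:, idx]

    all_rates = np.sort(np.append(lam2, params.ke0))
    spacing = np.diff(all_rates) / np.maximum(all_rates[1:], 1e-300)
    if np.any(spacing < _DEGENERACY_RTOL):
        warnings.warn(
            "near-repeated disposition eigenvalues; perturbing rate constants "
            "to keep the closed-form solution well conditioned",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("degenerate eigenvalues for %s; applying 1e-9 perturbation", params)
        return hybrid_constants(_perturbed(params, 1e-9))

    # unit bolus: amounts a(t) = V exp(diag(-lam) t) V^-1 e1; Cp = a1/v1
    w = np.linalg.solve(V, np.array([1.0, 0.0, 0.0]))
    plasma_coefs = (V[0, :] * w) / params.v1

    ke0 = params.ke0
    # effect site: convolve each plasma mode with ke0 exp(-ke0 t)
    ce_coefs = ke0 * plasma_coefs / (ke0 - lam2)
    effect_exponents = np.append(lam2, ke0)
    effect_coefs = np.append(ce_coefs, -ce_coefs.sum())
    return HybridDisposition(
        exponents=lam2,
        plasma_coefs=plasma_coefs,
        effect_exponents=effect_exponents,
        effect_coefs=effect_coefs,
    )


def _unit_responses(hybrid: HybridDisposition, dt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plasma and effect-site response per ug at elapsed times ``dt >= 0``."""
    dt = np.asarray(dt, dtype=float)
    cp = np.exp(-np.outer(dt, hybrid.exponents)) @ hybrid.plasma_coefs
    ce = np.exp(-np.outer(dt, hybrid.effect_exponents)) @ hybrid.effect_coefs
    return cp, np.maximum(ce, 0.0)


def concentration_at(
    history: DosingHistory,
    params: PKParameters,
    t: float,
    site: str = "plasma",
    side: str = "pre",
    hybrid: HybridDisposition | None = None,
) -> float:
    """Exact concentration at time ``t`` by bolus superposition.

    ``side='pre'`` is the left limit (a bolus at exactly ``t`` excluded) —
    the convention used to read a MEC "immediately before" a demand;
    ``side='post'`` includes it.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    if site not in ("plasma", "effect"):
        raise ValueError("site must be 'plasma' or 'effect'")
    if side not in ("pre", "post"):
        raise ValueError("side must be 'pre' or 'post'")
    if hybrid is None:
        hybrid = hybrid_constants(params)
    total = 0.0
    for ev in history.events:
        if ev.time_min > t or (side == "pre" and ev.time_min == t):
            continue
        dt = np.array([t - ev.time_min])
        cp, ce = _unit_responses(hybrid, dt)
        total += ev.dose_ug * (cp[0] if site == "plasma" else ce[0])
    return float(total)


def simulate_profile(
    history: DosingHistory,
    params: PKParameters,
    grid: float = 1.0,
) -> ConcProfile:
    """Dense cp/ce curves on a regular grid plus exact values at event times.

    Event instants appear twice (pre then post jump) so the discontinuity in
    cp is represented exactly.  An empty history gives an all-zero profile.
    """
    if grid <= 0:
        raise ValueError("grid step must be > 0")
    hybrid = hybrid_constants(params)
    end = history.observation_end_min
    times = list(np.arange(0.0, end + grid / 2, grid))
    for ev in history.events:
        if 0 <= ev.time_min <= end:
            times.extend([ev.time_min, ev.time_min])
    times = np.array(sorted(times))

    cp = np.zeros_like(times)
    ce = np.zeros_like(times)
    seen: dict[float, int] = {}
    # at a duplicated event time the first copy is the left limit
    sides = np.empty(times.shape, dtype=object)
    for i, t in enumerate(times):
        k = seen.get(t, 0)
        seen[t] = k + 1
        sides[i] = "pre" if k == 0 else "post"

    for ev in history.events:
        mask_post = (times > ev.time_min) | ((times == ev.time_min) & (sides == "post"))
        dt = times[mask_post] - ev.time_min
        ucp, uce = _unit_responses(hybrid, dt)
        cp[mask_post] += ev.dose_ug * ucp
        ce[mask_post] += ev.dose_ug * uce
    return ConcProfile(subject_id=history.subject_id, times=times, cp=cp, ce=ce)


class SuperpositionState:
    """Running sum-of-exponentials state for incremental dosing simulation.

    Folds all past boluses into one weight per exponential mode, anchored at
    the most recent event time, so evaluating the effect-site (or plasma)
    curve costs O(#modes) regardless of how many doses have accrued.  Used by
    the closed-loop PCA generator where the curve is evaluated thousands of
    times.
    """

    def __init__(self, hybrid: HybridDisposition):
        self.h = hybrid
        self.t0 = 0.0
        self.w_cp = np.zeros_like(hybrid.plasma_coefs)
        self.w_ce = np.zeros_like(hybrid.effect_coefs)

    def add_dose(self, t: float, dose_ug: float) -> None:
        if t < self.t0:
            raise ValueError("doses must be added in time order")
        self._advance(t)
        self.w_cp = self.w_cp + dose_ug * self.h.plasma_coefs
        self.w_ce = self.w_ce + dose_ug * self.h.effect_coefs

    def _advance(self, t: float) -> None:
        dt = t - self.t0
        self.w_cp = self.w_cp * np.exp(-self.h.exponents * dt)
        self.w_ce = self.w_ce * np.exp(-self.h.effect_exponents * dt)
        self.t0 = t

    def ce(self, t: np.ndarray | float) -> np.ndarray | float:
        dt = np.asarray(t, dtype=float) - self.t0
        out = np.exp(-np.outer(np.atleast_1d(dt), self.h.effect_exponents)) @ self.w_ce
        out = np.maximum(out, 0.0)
        return float(out[0]) if np.isscalar(t) else out

    def cp(self, t: np.ndarray | float) -> np.ndarray | float:
        dt = np.asarray(t, dtype=float) - self.t0
        out = np.exp(-np.outer(np.atleast_1d(dt), self.h.exponents)) @ self.w_cp
        return float(out[0]) if np.isscalar(t) else out
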