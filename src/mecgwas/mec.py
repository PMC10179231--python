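"""Minimum-effective-concentration phenotypes from simulated dosing.

A patient presses the PCA button when analgesia has worn off, so the modeled
concentration immediately before each demand operationalizes that subject's
minimum effective concentration (MEC).  One (plasma, effect-site) MEC pair is
read per demand, the pairs are averaged over the 0-6 h, 0-12 h and 0-24 h
postoperative windows, and window means enter analysis as ln(1 + MEC) to pull
the right-skewed concentration scale toward normality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pk import DosingHistory, PKParameters, concentration_at, hybrid_constants

__all__ = ["MECRecord", "DEFAULT_WINDOWS_H", "extract_mec", "log_transform"]

#: postoperative averaging windows in hours
DEFAULT_WINDOWS_H = (6, 12, 24)

SITES = ("plasma", "effect")


@dataclass
class MECRecord:
    """Per-demand MEC observations and windowed phenotypes for one subject.

    ``demand_points`` holds (time_min, cp_pre, ce_pre) per PCA demand.
    ``window_means[(h, site)]`` is the arithmetic mean of the pre-demand
    concentrations over demands with 0 < t <= h*60, or None when the window
    contains no demand (missing, never zero).  ``log_values`` are
    ln(1 + mean) for every defined mean.
    """

    subject_id: str
    demand_points: list[tuple[float, float, float]] = field(default_factory=list)
    window_means: dict[tuple[int, str], float | None] = field(default_factory=dict)
    log_values: dict[tuple[int, str], float | None] = field(default_factory=dict)

    def n_demands(self, window_h: int) -> int:
        return sum(1 for t, _, _ in self.demand_points if 0 < t <= window_h * 60)


def log_transform(mec: float) -> float:
    """Analysis transform: ln(1 + MEC[ng/mL])."""
    if mec < 0:
        raise ValueError("MEC must be non-negative")
    return math.log1p(mec)


def extract_mec(
    history: DosingHistory,
    params: PKParameters,
    windows_h: tuple[int, ...] = DEFAULT_WINDOWS_H,
) -> MECRecord:
    """Read pre-demand concentrations and average them per window.

    Initial boluses shape the concentration field but contribute no MEC
    point.  Windows are half-open (0, h*60]: a demand at exactly the window
    bound belongs to it.  Pre-demand values are exact left limits of the
    closed-form curves.
    """
    hybrid = hybrid_constants(params)
    points: list[tuple[float, float, float]] = []
    demands = history.demand_events
    if demands:
        # vectorized superposition: dt[i, e] > 0 selects events strictly
        # before demand i, i.e. the left limit
        t_d = np.array([e.time_min for e in demands])
        t_e = np.array([e.time_min for e in history.events])
        dose = np.array([e.dose_ug for e in history.events])
        dt = t_d[:, None] - t_e[None, :]
        active = dt > 0
        dt = np.where(active, dt, 0.0)
        cp_resp = np.exp(-dt[..., None] * hybrid.exponents) @ hybrid.plasma_coefs
        ce_resp = np.exp(-dt[..., None] * hybrid.effect_exponents) @ hybrid.effect_coefs
        cp = (np.where(active, cp_resp, 0.0) * dose).sum(axis=1)
        ce = np.maximum((np.where(active, ce_resp, 0.0) * dose).sum(axis=1), 0.0)
        points = list(zip(t_d.tolist(), cp.tolist(), ce.tolist()))

    rec = MECRecord(subject_id=history.subject_id, demand_points=points)
    for h in windows_h:
        in_win = [(cp, ce) for t, cp, ce in points if 0 < t <= h * 60]
        for si, site in enumerate(SITES):
            if in_win:
                mean = float(np.mean([v[si] for v in in_win]))
                rec.window_means[(h, site)] = mean
                rec.log_values[(h, site)] = log_transform(mean)
            else:
                rec.window_means[(h, site)] = None
                rec.log_values[(h, site)] = None
    return rec
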