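"""Closed-form disposition model against independent oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mecgwas import (
    DoseEvent,
    DosingHistory,
    PKParameters,
    concentration_at,
    hybrid_constants,
    simulate_profile,
)
from mecgwas.pk import SuperpositionState, _rate_matrix

from conftest import random_history, random_params


def ode_concentrations(history, params, times):
    """Independent oracle: stiff integration of the 4-state linear system,
    with boluses applied as jumps in the central amount.  Values at event
    times are left limits."""
    p = params
    K = np.array(
        [
            [-(p.k10 + p.k12 + p.k13), p.k21, p.k31, 0.0],
            [p.k12, -p.k21, 0.0, 0.0],
            [p.k13, 0.0, -p.k31, 0.0],
            [p.ke0 / p.v1, 0.0, 0.0, -p.ke0],
        ]
    )
    f = lambda t, y: K @ y
    y = np.zeros(4)
    tcur = 0.0
    i = 0
    events = list(history.events)
    out = {}
    for tn in sorted({e.time_min for e in events} | {float(t) for t in times}):
        if tn > tcur:
            sol = solve_ivp(f, (tcur, tn), y, rtol=1e-12, atol=1e-15, method="LSODA")
            y = sol.y[:, -1]
            tcur = tn
        out[tn] = (y[0] / p.v1, y[3])
        while i < len(events) and events[i].time_min == tn:
            y[0] += events[i].dose_ug
            i += 1
    return out


class TestHybridConstants:
    def test_one_compartment_degeneracy(self, one_comp):
        h = hybrid_constants(one_comp)
        nz = np.abs(h.plasma_coefs) > 1e-15
        assert nz.sum() == 1
        assert h.exponents[nz][0] == pytest.approx(0.1)
        assert h.plasma_coefs[nz][0] == pytest.approx(0.1)  # 1/v1

    def test_unit_impulse_starts_at_inverse_volume(self, fentanyl):
        h = hybrid_constants(fentanyl)
        assert h.plasma_coefs.sum() == pytest.approx(1 / fentanyl.v1, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_trace_and_determinant_identities(self, seed):
        p = random_params(np.random.default_rng(seed))
        h = hybrid_constants(p)
        assert h.exponents.sum() == pytest.approx(
            p.k10 + p.k12 + p.k21 + p.k13 + p.k31, rel=1e-10)
        # independent oracle: determinant of the disposition rate matrix
        det = np.linalg.det(-_rate_matrix(p))
        assert np.prod(h.exponents) == pytest.approx(det, rel=1e-10)
        assert np.prod(h.exponents) == pytest.approx(p.k10 * p.k21 * p.k31, rel=1e-10)

    def test_effect_site_response_starts_at_zero(self, fentanyl):
        h = hybrid_constants(fentanyl)
        assert h.effect_coefs.sum() == pytest.approx(0.0, abs=1e-14)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PKParameters(v1=-1, k10=0.1, k12=0.1, k21=0.1, k13=0.1, k31=0.1, ke0=0.1)
        with pytest.raises(ValueError):
            PKParameters(v1=1, k10=0.0, k12=0.1, k21=0.1, k13=0.1, k31=0.1, ke0=0.1)

    def test_repeated_eigenvalues_perturbed_with_warning(self):
        # k12=k13=0 with k21 == k10 collides two modes
        p = PKParameters(v1=10, k10=0.1, k12=0.0, k21=0.1, k13=0.0, k31=0.01, ke0=0.5)
        with pytest.warns(RuntimeWarning):
            h = hybrid_constants(p)
        assert np.all(np.diff(np.sort(h.exponents)) > 0)


class TestConcentrationAt:
    def test_monoexponential_plasma(self, one_comp, bolus_history):
        # 100 ug in 10 L decaying at 0.1/min for 10 min
        c = concentration_at(bolus_history, one_comp, 10.0, "plasma", "pre")
        assert c == pytest.approx(10 * np.exp(-1), rel=1e-12)

    def test_biexponential_effect_site(self, one_comp, bolus_history):
        c = concentration_at(bolus_history, one_comp, 10.0, "effect", "pre")
        expected = 10 * (0.5 / 0.4) * (np.exp(-1) - np.exp(-5))
        assert c == pytest.approx(expected, rel=1e-12)
        assert c == pytest.approx(4.5143, abs=1e-4)

    def test_pre_excludes_bolus_at_t_post_includes(self, one_comp):
        h = DosingHistory("s", [DoseEvent(0.0, 100.0, "initial_bolus"), DoseEvent(30.0, 20.0)])
        pre = concentration_at(h, one_comp, 30.0, "plasma", "pre")
        post = concentration_at(h, one_comp, 30.0, "plasma", "post")
        assert post - pre == pytest.approx(20.0 / one_comp.v1, rel=1e-12)

    def test_two_boluses_superpose(self, fentanyl, rng):
        h1 = DosingHistory("a", [DoseEvent(0.0, 100.0, "initial_bolus")])
        h2 = DosingHistory("b", [DoseEvent(40.0, 60.0)])
        both = DosingHistory("c", [h1.events[0], h2.events[0]])
        for t in (10.0, 60.0, 200.0):
            for site in ("plasma", "effect"):
                assert concentration_at(both, fentanyl, t, site) == pytest.approx(
                    concentration_at(h1, fentanyl, t, site)
                    + concentration_at(h2, fentanyl, t, site),
                    rel=1e-12, abs=1e-15)

    def test_negative_time_rejected(self, one_comp, bolus_history):
        with pytest.raises(ValueError):
            concentration_at(bolus_history, one_comp, -1.0)


class TestSimulateProfile:
    def test_empty_history_all_zero(self, fentanyl):
        prof = simulate_profile(DosingHistory("s", [], 100.0), fentanyl, grid=10.0)
        assert np.all(prof.cp == 0) and np.all(prof.ce == 0)

    def test_agrees_with_concentration_at(self, fentanyl, rng):
        hist = random_history(rng, 6, horizon=300.0)
        prof = simulate_profile(hist, fentanyl, grid=20.0)
        event_times = {e.time_min for e in hist.events}
        for t, cp in zip(prof.times, prof.cp):
            if t not in event_times:
                assert cp == pytest.approx(
                    concentration_at(hist, fentanyl, float(t), "plasma"), rel=1e-12)

    def test_matches_ode_oracle(self, rng):
        params = random_params(rng)
        hist = random_history(rng, 8, horizon=400.0)
        ts = np.arange(7.0, 400.0, 23.0)
        oracle = ode_concentrations(hist, params, ts)
        for t in ts:
            cp_o, ce_o = oracle[float(t)]
            cp = concentration_at(hist, params, float(t), "plasma", "pre")
            ce = concentration_at(hist, params, float(t), "effect", "pre")
            assert cp == pytest.approx(cp_o, rel=1e-6)
            assert ce == pytest.approx(ce_o, rel=1e-6, abs=1e-12)

    def test_effect_site_lags_and_stays_below_plasma_peak(self, fentanyl, bolus_history):
        prof = simulate_profile(bolus_history, fentanyl, grid=0.25)
        i = int(np.argmax(prof.ce))
        assert 0 < i < len(prof.times) - 1  # interior maximum
        assert prof.times[i] > 0
        assert prof.ce.max() < prof.cp.max()

    def test_mass_nonnegative(self, rng):
        for _ in range(3):
            params = random_params(rng)
            prof = simulate_profile(random_history(rng, 10), params, grid=5.0)
            assert np.all(prof.cp >= 0) and np.all(prof.ce >= 0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 10_000))
def test_dose_proportionality(scale, seed):
    """Scaling every dose by c scales cp and ce by c (linearity)."""
    rng = np.random.default_rng(seed)
    params = random_params(rng)
    hist = random_history(rng, 5, horizon=300.0)
    scaled = DosingHistory(
        "s", [DoseEvent(e.time_min, e.dose_ug * scale, e.kind) for e in hist.events], 300.0)
    for t in (15.0, 150.0):
        for site in ("plasma", "effect"):
            a = concentration_at(hist, params, t, site)
            b = concentration_at(scaled, params, t, site)
            assert b == pytest.approx(scale * a, rel=1e-10, abs=1e-14)


def test_large_ke0_effect_tracks_plasma(one_comp, bolus_history):
    """ke0 -> inf collapses the effect-site lag away from dose instants."""
    fast = PKParameters(v1=10.0, k10=0.1, k12=0.0, k21=0.05, k13=0.0, k31=0.01, ke0=500.0)
    for t in (5.0, 30.0, 120.0):
        cp = concentration_at(bolus_history, fast, t, "plasma")
        ce = concentration_at(bolus_history, fast, t, "effect")
        assert ce == pytest.approx(cp, rel=5e-3)


def test_superposition_state_matches_direct_evaluation(fentanyl, rng):
    """Folded-mode incremental state equals event-by-event superposition."""
    hist = random_history(rng, 12, horizon=500.0)
    state = SuperpositionState(hybrid_constants(fentanyl))
    for e in hist.events:
        state.add_dose(e.time_min, e.dose_ug)
    t_last = hist.events[-1].time_min
    for t in np.linspace(t_last + 1, 500, 7):
        assert state.ce(float(t)) == pytest.approx(
            concentration_at(hist, fentanyl, float(t), "effect"), rel=1e-10)
        assert state.cp(float(t)) == pytest.approx(
            concentration_at(hist, fentanyl, float(t), "plasma"), rel=1e-10)
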