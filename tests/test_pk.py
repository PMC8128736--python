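"""PK engine: segment compilation, closed forms, ODE oracle, invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from iwspkpd.pk import (DosingEvent, PKParameters, compile_segments,
                        simulate_concentrations, simulate_state)

from conftest import random_pk_params, random_schedule


class TestCompileSegments:
    def test_single_long_infusion_constant_rate(self):
        sched = compile_segments([DosingEvent("m", 0.0, 336.0, duration=336.0)])
        assert np.allclose(sched.boundaries, [0.0, 336.0])
        assert np.allclose(sched.iv_rates, [1.0])  # 336 mg over 336 h

    def test_bolus_becomes_state_jump(self):
        sched = compile_segments([DosingEvent("m", 2.0, 5.0)])
        k = list(sched.boundaries).index(2.0)
        assert sched.iv_jumps[k] == 5.0
        assert np.all(sched.iv_rates == 0.0)

    def test_overlapping_infusions_sum(self):
        # 1 mg/h on [0,10] and on [5,15]: rates 1, 2, 1 -- brute-force
        # summation of indicator functions is the oracle
        events = [
            DosingEvent("m", 0.0, 10.0, duration=10.0),
            DosingEvent("m", 5.0, 10.0, duration=10.0),
        ]
        sched = compile_segments(events)
        assert np.allclose(sched.boundaries, [0.0, 5.0, 10.0, 15.0])
        assert np.allclose(sched.iv_rates, [1.0, 2.0, 1.0])
        for t, expected in [(2.0, 1.0), (7.0, 2.0), (12.0, 1.0)]:
            brute = sum(
                e.rate for e in events if e.time <= t < e.time + e.duration
            )
            assert brute == expected

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            DosingEvent("m", 0.0, -1.0, duration=1.0)


class TestClosedForms:
    def test_steady_state_equals_rate_over_clearance(self, one_comp):
        # C_ss = R / CL (here 1 mg/h / 10 L/h = 0.1 mg/L = 100 ng/mL)
        ev = [DosingEvent("drugA", 0.0, 1000.0, duration=1000.0)]
        prof = simulate_concentrations(ev, one_comp, 70.0, np.array([900.0, 999.0]))
        assert prof.values == pytest.approx(100.0, rel=1e-9)

    def test_bolus_monoexponential_decay(self, one_comp):
        grid = np.linspace(0.5, 48.0, 50)
        prof = simulate_concentrations([DosingEvent("drugA", 0.0, 5.0)],
                                       one_comp, 70.0, grid)
        kel = one_comp.CL / one_comp.V_c
        expected = 5.0 / one_comp.V_c * 1000.0 * np.exp(-kel * grid)
        np.testing.assert_allclose(prof.values, expected, rtol=1e-12)

    def test_allometric_scaling_of_steady_state(self, one_comp):
        # at 10 kg, CL scales by (10/70)^0.75 so C_ss rises accordingly
        ev = [DosingEvent("drugA", 0.0, 2000.0, duration=2000.0)]
        prof = simulate_concentrations(ev, one_comp, 10.0, np.array([1999.0]))
        cl10 = 10.0 * (10.0 / 70.0) ** 0.75
        assert prof.values[-1] == pytest.approx(1.0 / cl10 * 1000.0, rel=1e-8)


def _ode_oracle(events, params, weight, grid):
    """Independent adaptive-integrator solution of the same linear system."""
    sched = compile_segments(events)
    with_depot = sched.has_extravascular
    A = params.system_matrix(weight, with_depot=with_depot)
    n = A.shape[0]

    def rate_vec(t):
        k = np.searchsorted(sched.boundaries, t, side="right") - 1
        u = np.zeros(n)
        if 0 <= k < len(sched.iv_rates):
            u[0] = sched.iv_rates[k]
            if with_depot:
                u[-1] = params.F * sched.ev_rates[k]
        return u

    def rhs(t, x):
        return A @ x + rate_vec(t)

    pts = np.union1d(sched.boundaries, grid)
    pts = pts[pts <= grid[-1]]
    if pts[0] > 0:
        pts = np.concatenate([[0.0], pts])
    x = np.zeros(n)
    values = {}
    for i, t in enumerate(pts):
        k = np.searchsorted(sched.boundaries, t)
        if k < len(sched.boundaries) and np.isclose(sched.boundaries[k], t):
            x = x.copy()
            x[0] += sched.iv_jumps[k]
            if with_depot:
                x[-1] += params.F * sched.ev_jumps[k]
        values[t] = x[0]
        if i + 1 < len(pts):
            sol = solve_ivp(rhs, (t, pts[i + 1]), x, rtol=1e-11, atol=1e-13,
                            method="DOP853")
            x = sol.y[:, -1]
    scale = params.unit_scale / params.scaled(weight)["V_c"]
    return np.array([values[t] for t in grid]) * scale


@pytest.mark.parametrize("n_comp,with_depot", [(1, False), (2, False),
                                               (3, False), (2, True)])
def test_matches_adaptive_ode_oracle(n_comp, with_depot):
    """Piecewise-exact propagation agrees with an adaptive integrator."""
    rng = np.random.default_rng(100 + n_comp + 10 * with_depot)
    for _ in range(3):
        params = random_pk_params(rng, n_comp, with_depot=with_depot)
        events = random_schedule(rng, allow_ev=with_depot)
        grid = np.sort(rng.uniform(1.0, 150.0, size=25))
        weight = float(rng.uniform(5, 60))
        prof = simulate_concentrations(events, params, weight, grid)
        oracle = _ode_oracle(events, params, weight, grid)
        scale = max(oracle.max(), 1e-12)
        np.testing.assert_allclose(prof.values, oracle, rtol=1e-6,
                                   atol=1e-6 * scale)


class TestInvariants:
    def test_linearity_superposition(self, one_comp):
        rng = np.random.default_rng(7)
        events = random_schedule(rng, drug_id="drugA")
        doubled = [DosingEvent(e.drug_id, e.time, 2 * e.amount, e.duration, e.route)
                   for e in events]
        grid = np.linspace(1.0, 160.0, 80)
        a = simulate_concentrations(events, one_comp, 12.0, grid).values
        b = simulate_concentrations(doubled, one_comp, 12.0, grid).values
        np.testing.assert_allclose(b, 2 * a, rtol=1e-10)

    @pytest.mark.parametrize("n_comp", [1, 2, 3])
    def test_mass_conservation(self, n_comp):
        """input - eliminated == total amount in compartments (F = 1)."""
        rng = np.random.default_rng(40 + n_comp)
        params = random_pk_params(rng, n_comp)
        events = random_schedule(rng)
        grid = np.linspace(1.0, 200.0, 40)
        st = simulate_state(events, params, 20.0, grid)
        balance = st["input"] - st["eliminated"] - st["amounts"].sum(axis=1)
        total = max(st["input"].max(), 1.0)
        assert np.max(np.abs(balance)) < 1e-8 * total

    def test_rejects_bad_inputs(self, one_comp):
        ev = [DosingEvent("drugA", 0.0, 1.0, duration=1.0)]
        with pytest.raises(ValueError):
            simulate_concentrations(ev, one_comp, 0.0, np.array([1.0]))
        with pytest.raises(ValueError):
            simulate_concentrations(ev, one_comp, 10.0, np.array([2.0, 1.0]))

    def test_extravascular_requires_ka_and_applies_F(self):
        p = PKParameters(drug_id="d", CL=10.0, V_c=20.0, ka=1.0, F=0.5,
                         dose_unit="mg", concentration_unit="ng/mL")
        ev = [DosingEvent("d", 0.0, 10.0, route="extravascular")]
        grid = np.linspace(0.5, 72.0, 60)
        prof = simulate_concentrations(ev, p, 70.0, grid)
        st = simulate_state(ev, p, 70.0, grid)
        # only F * amount enters the system
        assert st["input"][-1] == pytest.approx(5.0)
        assert prof.values.max() > 0
        p_no_ka = PKParameters(drug_id="d", CL=10.0, V_c=20.0,
                               dose_unit="mg", concentration_unit="ng/mL")
        with pytest.raises(ValueError):
            simulate_concentrations(ev, p_no_ka, 70.0, grid)
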