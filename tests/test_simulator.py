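"""Integration behaviour, experiment designs, and solver-independence checks."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popguide import (
    CircuitSpec,
    ConsortiumParams,
    CultureState,
    ProductionParams,
    SimulationConfig,
    StrainParams,
    default_params,
    growth_matrix,
    rhs,
    scan_amp,
    scan_inoculum,
    simulate,
)
from popguide.simulator import DEFAULT_INIT


def rk4_integrate(params, init, t_end, h=0.001):
    """Fixed-step classical Runge-Kutta oracle, independent of solve_ivp."""
    n = int(round(t_end / h))
    y = init.as_array()
    ts = [0.0]
    ys = [y.copy()]
    for i in range(n):
        k1 = rhs(y, params)
        k2 = rhs(y + 0.5 * h * k1, params)
        k3 = rhs(y + 0.5 * h * k2, params)
        k4 = rhs(y + h * k3, params)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.maximum(y, 0.0)
        ts.append((i + 1) * h)
        ys.append(y.copy())
    return np.array(ts), np.array(ys)


class TestSimulate:
    def test_empty_inoculum_stays_flat(self, guider_params):
        init = CultureState(s=20.0, a=1.0, p=10.0, c=5.0)
        tc = simulate(guider_params, init, SimulationConfig(t_end=24.0))
        assert np.allclose(tc.states[:, 0], 0.0)
        assert np.allclose(tc.states[:, 1], 0.0)
        assert np.allclose(tc.channel("s"), 20.0)

    def test_commensal_dynamics(self, commensal_course):
        tc = commensal_course
        s = tc.channel("s")
        # alginate decreases monotonically until depletion
        assert np.all(np.diff(s) <= 1e-9)
        assert s[-1] < 1e-6
        # the consumer fraction starts at 0.8 and declines with time
        assert tc.ratio_e[0] == pytest.approx(0.8)
        assert tc.ratio_e[-1] < tc.ratio_e[0]

    def test_deterministic(self, guider_params, default_config):
        a = simulate(guider_params, DEFAULT_INIT, default_config)
        b = simulate(guider_params, DEFAULT_INIT, default_config)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.times, b.times)

    def test_circuit_neutral_without_ampicillin(self, default_config):
        """With no ampicillin the circuit leaves trajectories bit-identical."""
        runs = {}
        for mode in ("none", "constitutive", "guider"):
            tc = simulate(default_params(mode), DEFAULT_INIT, default_config)
            runs[mode] = tc.states
        assert np.array_equal(runs["none"], runs["guider"])
        assert np.array_equal(runs["none"], runs["constitutive"])

    def test_rk4_oracle_equivalence(self, guider_params):
        """Adaptive solver matches a fixed-step RK4 oracle on a 12-h run."""
        cfg = SimulationConfig(t_end=12.0, output_times=np.arange(0, 12.1, 2.0))
        init = dataclasses.replace(DEFAULT_INIT, c=5.0)
        tc = simulate(guider_params, init, cfg)
        ts, ys = rk4_integrate(guider_params, init, 12.0, h=0.001)
        for i, t in enumerate(tc.times):
            ref = ys[int(round(t / 0.001))]
            scale = np.maximum(np.abs(ref), 1e-6)
            assert np.all(np.abs(tc.states[i] - ref) / scale < 1e-4), \
                f"mismatch at t={t}"

    def test_grid_independence(self, guider_params):
        coarse = SimulationConfig(t_end=24.0, output_times=np.arange(0, 24.1, 6))
        fine = SimulationConfig(t_end=24.0, output_times=np.arange(0, 24.1, 3))
        a = simulate(guider_params, DEFAULT_INIT, coarse)
        b = simulate(guider_params, DEFAULT_INIT, fine)
        shared = np.isin(b.times, a.times)
        assert np.allclose(b.states[shared], a.states, rtol=1e-6, atol=1e-8)

    def test_exponential_limit(self):
        """Producer alone in substrate excess grows as exp(mu_max t) to 1%."""
        p = default_params("none")
        init = CultureState(x_v=0.5, s=1000.0)
        cfg = SimulationConfig(t_end=2.0, output_times=[0.0, 2.0])
        tc = simulate(p, init, cfg)
        assert tc.states[-1, 0] == pytest.approx(0.5 * np.exp(0.83 * 2.0),
                                                 rel=0.01)  # 2.6297

    def test_flux_bounds(self, commensal_course, commensal_params):
        """Acetate and product stay within their stoichiometric envelopes."""
        tc = commensal_course
        phi = commensal_params.producer.phi_a
        y_pa = commensal_params.production.y_pa
        consumed = tc.channel("s")[0] - tc.channel("s")
        assert np.all(tc.channel("a") <= phi * consumed + 1e-9)
        assert np.all(tc.channel("p") <= y_pa * phi * consumed + 1e-6)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(t_end=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(t_end=10.0, output_times=[0.0, 20.0])
        with pytest.raises(ValueError):
            SimulationConfig(t_end=10.0, output_times=[5.0, 5.0])


def _random_params(draw):
    producer = StrainParams(
        mu_max_primary=draw(st.floats(0.1, 1.2)),
        k_primary=draw(st.floats(0.1, 5.0)),
        y_x=draw(st.floats(0.1, 1.0)),
        phi_a=draw(st.floats(0.0, 1.0)),
        mu_max_ac=draw(st.floats(0.0, 0.5)),
        k_ac=draw(st.floats(0.1, 3.0)),
        k_rep=draw(st.floats(0.05, 3.0)),
        alpha_kill=draw(st.floats(0.0, 5.0)),
        k_kill=draw(st.floats(0.5, 30.0)),
    )
    consumer = StrainParams(
        mu_max_primary=draw(st.floats(0.02, 0.5)),
        k_primary=draw(st.floats(0.05, 2.0)),
        y_x=draw(st.floats(0.1, 1.0)),
        alpha_kill=draw(st.floats(0.0, 4.0)),
        k_kill=draw(st.floats(0.5, 30.0)),
    )
    production = ProductionParams(
        y_pa=draw(st.floats(0.0, 60.0)),
        k_pdeg=draw(st.floats(0.0, 0.01)),
        s_gate=draw(st.floats(0.1, 2.0)),
    )
    circuit = CircuitSpec(
        mode=draw(st.sampled_from(["none", "constitutive", "guider"])),
        beta_0=draw(st.floats(0.0, 0.3)),
        beta_1=draw(st.floats(0.3, 3.0)),
        k_p=draw(st.floats(5.0, 300.0)),
        n_hill=draw(st.floats(1.0, 4.0)),
        k_cat=draw(st.floats(0.0, 0.5)),
    )
    return ConsortiumParams(producer=producer, consumer=consumer,
                            production=production, circuit=circuit)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(data=st.data())
def test_trajectory_invariants_random_params(data):
    """Non-negativity and monotone substrate/antibiotic depletion hold for
    randomized valid parameter sets and inocula."""
    params = _random_params(data.draw)
    init = CultureState(
        x_v=data.draw(st.floats(0.0, 3.0)),
        x_e=data.draw(st.floats(0.0, 4.0)),
        s=data.draw(st.floats(0.5, 25.0)),
        a=data.draw(st.floats(0.0, 2.0)),
        p=data.draw(st.floats(0.0, 100.0)),
        c=data.draw(st.floats(0.0, 20.0)),
    )
    cfg = SimulationConfig(t_end=12.0, output_times=np.arange(0, 12.1, 2.0),
                           rel_tol=1e-7, abs_tol=1e-9)
    tc = simulate(params, init, cfg)
    # clipped output is exactly non-negative; raw excursions are bounded
    # by the solver's absolute tolerance
    assert np.all(tc.states >= 0.0)
    assert np.all(np.diff(tc.channel("s")) <= 1e-8)   # alginate only consumed
    assert np.all(np.diff(tc.channel("c")) <= 1e-8)   # ampicillin only degraded


class TestScanAmp:
    def test_zero_dose_equals_commensal(self, guider_params, commensal_params,
                                        default_config, commensal_course):
        courses, _ = scan_amp(guider_params, [0.0], DEFAULT_INIT, default_config)
        assert np.array_equal(courses[0.0].states, commensal_course.states)

    def test_summary_columns(self, guider_params, default_config):
        _, summary = scan_amp(guider_params, [0.0, 10.0], DEFAULT_INIT,
                              default_config)
        assert list(summary["amp_ugmL"]) == [0.0, 10.0]
        for col in ("final_P_mgL", "peak_A_gL", "final_OD", "final_ratio_E"):
            assert col in summary.columns

    def test_lethal_dose_shuts_down_production(self, guider_params,
                                               default_config):
        """A dose that nulls producer growth from t=0 leaves the titre near
        the contribution of the initial acetate pool (zero here)."""
        _, summary = scan_amp(guider_params, [2000.0], DEFAULT_INIT,
                              default_config)
        # producer collapses immediately: only the early trickle of acetate
        # from the dying producer can be converted
        assert summary["final_P_mgL"].iloc[0] < 25.0
        assert summary["consumed_S_gL"].iloc[0] < 2.0

    def test_negative_level_rejected(self, guider_params):
        with pytest.raises(ValueError):
            scan_amp(guider_params, [-1.0])


class TestScanInoculum:
    def test_no_producer_no_consumption(self, commensal_params, default_config):
        table = scan_inoculum(commensal_params, [(0.0, 2.0)],
                              DEFAULT_INIT, default_config)
        assert table["consumed_S_gL"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert table["final_P_mgL"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_reference_inocula_ranking(self, commensal_params, default_config):
        """The producer-heavy inoculum gives the worst titre; the spread
        across inocula is at least two-fold."""
        inocula = [(0.5, 4.0), (0.5, 1.0), (0.1, 2.4), (2.4, 0.1), (0.5, 2.0)]
        table = scan_inoculum(commensal_params, inocula, DEFAULT_INIT,
                              default_config)
        titres = table["final_P_mgL"]
        heavy = table[(table.X_V0 == 2.4) & (table.X_E0 == 0.1)]
        assert heavy["final_P_mgL"].iloc[0] == titres.min()
        assert titres.max() / max(titres.min(), 1e-9) >= 2.0

    def test_doubling_inoculum_doubles_early_biomass(self, commensal_params):
        cfg = SimulationConfig(t_end=1.0, output_times=[0.0, 1.0])
        t1 = scan_inoculum(commensal_params, [(0.25, 1.0)], DEFAULT_INIT, cfg)
        base = simulate(commensal_params,
                        CultureState(x_v=0.25, x_e=1.0, s=20.0), cfg)
        double = simulate(commensal_params,
                          CultureState(x_v=0.5, x_e=2.0, s=20.0), cfg)
        assert double.od_total[-1] == pytest.approx(2 * base.od_total[-1],
                                                    rel=0.02)
        assert t1 is not None

    def test_empty_inoculum_rejected(self, commensal_params):
        with pytest.raises(ValueError):
            scan_inoculum(commensal_params, [(0.0, 0.0)])


class TestGrowthMatrix:
    def test_shape_and_bounds(self, guider_params):
        hp = [0.0, 0.5, 2.0]
        amp = [0.0, 5.0, 20.0]
        mat = growth_matrix(guider_params, hp, amp)
        assert mat.shape == (len(hp), len(amp))
        assert (mat.to_numpy() >= -DEFAULT_INIT.od_total).all()

    def test_no_ampicillin_column_neutral(self, guider_params):
        mat = growth_matrix(guider_params, [0.0, 2.0], [0.0])
        col = mat[0.0]
        assert col.loc[0.0] == pytest.approx(col.loc[2.0], rel=1e-9)

    def test_basal_leak_floor_at_high_dose(self, guider_params):
        """Without 3-HP and with a near-zero leak, high-dose growth collapses
        to the unprotected minimum."""
        weak = dataclasses.replace(guider_params.circuit, beta_0=1e-4)
        p = guider_params.with_circuit(weak)
        mat = growth_matrix(p, [0.0], [50.0])
        assert mat.iloc[0, 0] < 0.5
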