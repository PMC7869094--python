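"""Bilinear neural dynamics, balloon hemodynamics, and the integrator."""

import numpy as np
import pandas as pd
import pytest

from audconn.dcm.forward import (
    StabilityError,
    integrate_and_sample,
    integrate_reference,
)
from audconn.dcm.model import (
    CONDITIONS,
    REGIONS_4,
    REGIONS_8,
    DCMParameters,
    HemodynamicParams,
    InputSet,
    bold_observation,
    condition_codes,
    effective_coupling,
    hemo_derivative,
    neural_derivative,
)


def make_inputs(n_runs=2, dt=0.05, seed=0, run_duration=192.0):
    rng = np.random.default_rng(seed)
    n_trials = int(run_duration // 8)
    rows = []
    for run in range(n_runs):
        order = rng.permutation(np.repeat(np.arange(4), 6))[:n_trials]
        for k, c in enumerate(order):
            rows.append({"onset": 8 * k + rng.uniform(0.4, 2.4),
                         "duration": 3.1, "trial_type": CONDITIONS[c],
                         "run": run})
    return InputSet.from_events(pd.DataFrame(rows), dt=dt,
                                run_duration=run_duration)


def demo_params(regions=REGIONS_8):
    p = DCMParameters.zeros(regions)
    p.C[:, 0] = 0.2
    p.B[0, 0, 0] = -0.47
    p.A[1, 0] = 0.2
    p.A[0, 1] = 0.1
    return p


class TestNeuralDerivative:
    def test_prior_self_decay(self):
        p = DCMParameters.zeros(REGIONS_8)
        z = np.linspace(-1, 1, 8)
        np.testing.assert_allclose(
            neural_derivative(z, np.zeros(4), p), -0.5 * z)

    def test_disinhibitory_self_modulation(self):
        # b = -0.47 on the self-connection, difficulty input on:
        # effective self rate -0.5 * exp(-0.47) ~ -0.3125 Hz (slower decay)
        p = DCMParameters.zeros(REGIONS_8)
        p.B[0, 0, 0] = -0.47
        u = np.array([0.0, 0.0, 1.0, 0.0])
        m = effective_coupling(p, u)
        assert m[0, 0] == pytest.approx(-0.5 * np.exp(-0.47))
        assert m[0, 0] == pytest.approx(-0.3125, abs=2e-4)
        assert m[0, 0] > -0.5
        np.testing.assert_allclose(np.diag(m)[1:], -0.5)

    def test_unit_drive_reaches_one_region(self):
        p = DCMParameters.zeros(REGIONS_8)
        p.C[3, 2] = 1.0
        dz = neural_derivative(np.zeros(8), np.array([0, 0, 1.0, 0]), p)
        assert dz[3] == 1.0
        assert np.count_nonzero(dz) == 1

    def test_self_connections_negative_for_all_conditions(self):
        rng = np.random.default_rng(0)
        p = DCMParameters.zeros(REGIONS_8)
        p.B = rng.normal(scale=0.5, size=p.B.shape)
        for u in np.vstack([np.zeros(4), condition_codes()]):
            assert np.all(np.diag(effective_coupling(p, u)) < 0)


class TestHemodynamics:
    HEMO = HemodynamicParams()

    def test_rest_is_fixed_point(self):
        h = np.array([0.0, 1.0, 1.0, 1.0])
        np.testing.assert_allclose(hemo_derivative(h, 0.0, self.HEMO), 0.0)
        assert bold_observation(h, self.HEMO) == pytest.approx(0.0)

    def test_positive_drive_raises_flow(self):
        h = np.array([0.0, 1.0, 1.0, 1.0])
        d = hemo_derivative(h, 0.5, self.HEMO)
        assert d[0] > 0            # vasodilatory signal rises first
        h2 = np.array([0.3, 1.0, 1.0, 1.0])
        assert hemo_derivative(h2, 0.5, self.HEMO)[1] > 0   # then inflow

    def test_deoxy_washout_raises_bold(self):
        h_low_q = np.array([0.0, 1.0, 1.0, 0.8])
        assert bold_observation(h_low_q, self.HEMO) > 0

    def test_nonpositive_state_rejected(self):
        with pytest.raises(ValueError):
            hemo_derivative(np.array([0.0, -1.0, 1.0, 1.0]), 0.0, self.HEMO)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            HemodynamicParams(E0=1.5)
        with pytest.raises(ValueError):
            HemodynamicParams(tau=-1.0)


class TestIntegrator:
    def test_zero_drive_is_flat(self):
        p = DCMParameters.zeros(REGIONS_8)
        ts = integrate_and_sample(p, make_inputs())
        np.testing.assert_allclose(ts.data, 0.0, atol=1e-12)

    def test_sampling_grid(self):
        inputs = make_inputs()
        ts = integrate_and_sample(demo_params(), inputs)
        assert ts.scans_per_run == 24
        assert ts.data.shape == (8, 48)
        np.testing.assert_allclose(np.diff(inputs.acquisition_times), 8.0)

    def test_step_halving_convergence(self):
        p = demo_params()
        y1 = integrate_and_sample(p, make_inputs(dt=0.05)).data
        y2 = integrate_and_sample(p, make_inputs(dt=0.025)).data
        assert np.abs(y1 - y2).max() / np.abs(y2).max() < 1e-4

    def test_kernel_matches_reference_integrator(self):
        # slow pure-numpy RK4 built on the public derivative functions
        p = demo_params(REGIONS_4)
        p.tau_scale = np.array([0.1, 0.0, -0.1, 0.05])
        p.kappa_scale = np.array([-0.05, 0.1, 0.0, 0.02])
        inputs = make_inputs(n_runs=1, dt=0.1, run_duration=64.0)
        y = integrate_and_sample(p, inputs).data
        ref = integrate_reference(p, inputs)
        np.testing.assert_allclose(y, ref, atol=1e-12)

    def test_near_linearity_for_small_drive(self):
        p = demo_params()
        inputs = make_inputs(n_runs=1)
        base = integrate_and_sample(p, inputs).data
        p2 = demo_params()
        p2.C = p.C * 1e-3
        small = integrate_and_sample(p2, inputs).data
        # superposition error vanishes as drive amplitude -> 0
        err_large = np.abs(base / np.abs(base).max()
                           - small / np.abs(small).max()).max()
        p3 = demo_params()
        p3.C = p.C * 1e-5
        tiny = integrate_and_sample(p3, inputs).data
        err_small = np.abs(small / np.abs(small).max()
                           - tiny / np.abs(tiny).max()).max()
        assert err_small < err_large
        assert err_small < 1e-3

    def test_unstable_parameters_raise(self):
        p = DCMParameters.zeros(REGIONS_4)
        p.A += 5.0 * (1 - np.eye(4))
        p.C[:, 0] = 1.0
        with pytest.raises(StabilityError, match="<-"):
            integrate_and_sample(p, make_inputs(n_runs=1))

    def test_impulse_response_peaks_3_to_7_s(self):
        # fine sampling of a single brief stimulus
        p = DCMParameters.zeros(("roi",))
        p.C = np.array([[1.0, 0, 0, 0]])
        ev = pd.DataFrame([{"onset": 1.0, "duration": 0.5,
                            "trial_type": CONDITIONS[0], "run": 0}])
        dt = 0.05
        inputs = InputSet.from_events(ev, dt=dt, run_duration=30.0,
                                      tr=0.2, scan_period=0.2)
        ts = integrate_and_sample(p, inputs)
        t = inputs.acquisition_times
        peak_t = t[np.argmax(ts.data[0])] - 1.0
        assert 3.0 <= peak_t <= 7.0

    def test_dissipative_return_to_rest(self):
        p = DCMParameters.zeros(("roi",))
        p.C = np.array([[0.5, 0, 0, 0]])
        ev = pd.DataFrame([{"onset": 1.0, "duration": 2.0,
                            "trial_type": CONDITIONS[0], "run": 0}])
        inputs = InputSet.from_events(ev, dt=0.05, run_duration=40.0,
                                      tr=0.4, scan_period=0.4)
        y = integrate_and_sample(p, inputs).data[0]
        assert np.abs(y).max() > 0.05
        assert np.abs(y[-5:]).max() < 0.02 * np.abs(y).max()


class TestContainers:
    def test_timeseries_csv_roundtrip(self, tmp_path):
        from audconn.dcm.model import ROITimeseries
        ts = integrate_and_sample(demo_params(REGIONS_4),
                                  make_inputs(n_runs=2, dt=0.1))
        path = tmp_path / "ts.csv"
        ts.to_csv(path)
        back = ROITimeseries.from_csv(path)
        assert back.regions == REGIONS_4
        assert back.n_runs == 2 and back.scans_per_run == 24
        np.testing.assert_allclose(back.data, ts.data, atol=1e-9)

    def test_parameter_json_roundtrip(self, tmp_path):
        p = demo_params()
        p.to_json(tmp_path / "p.json")
        q = DCMParameters.from_json(tmp_path / "p.json")
        np.testing.assert_allclose(q.A, p.A)
        np.testing.assert_allclose(q.B, p.B)
        np.testing.assert_allclose(q.C, p.C)
        assert q.regions == p.regions

    def test_inputs_regressors_zero_outside_trials(self):
        inputs = make_inputs(n_runs=1)
        u = inputs.regressors()
        active = inputs.cond_idx.ravel() > 0
        assert np.all(u[~active] == 0)
        assert np.abs(u[active, 0]).min() == 1.0
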