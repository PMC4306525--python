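"""Unit and property tests of the neural-mass source model and integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dcmerf.nmm as nmm
from dcmerf.nmm import (
    Edge,
    IntegrationDivergenceError,
    ModulationSite,
    NetworkModel,
    Source,
    SourceParameters,
    StimulusInput,
    compile_network,
    firing_rate,
    input_waveform,
    integrate,
    state_derivatives,
)
from dcmerf.synth import fixture_small


@pytest.fixture(scope="module")
def chain():
    model, stim, grid, _ = fixture_small(beta=0.3)
    return model, stim, grid


# ---------------------------------------------------------------------------
# activation and input
# ---------------------------------------------------------------------------


class TestFiringRate:
    def test_centred_at_zero(self):
        assert firing_rate(0.0, SourceParameters()) == pytest.approx(0.0, abs=1e-15)

    def test_saturation_limit(self):
        p = SourceParameters()
        expect = 1.0 - 1.0 / (1.0 + np.exp(p.rho1 * p.rho2))
        assert firing_rate(1e3, p) == pytest.approx(expect, rel=1e-12)

    def test_value_at_threshold(self):
        # direct evaluation: S(rho2) = 0.5 - 1/(1+e^2) for rho1=2, rho2=1
        p = SourceParameters(rho1=2.0, rho2=1.0)
        assert firing_rate(1.0, p) == pytest.approx(0.5 - 1.0 / (1.0 + np.e ** 2),
                                                    rel=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            firing_rate(np.nan, SourceParameters())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-8, 8), st.floats(-8, 8))
    def test_strictly_increasing_and_bounded(self, a, b):
        p = SourceParameters()
        fa, fb = firing_rate(a, p), firing_rate(b, p)
        assert -1.0 < fa < 1.0
        if a < b:
            assert fa <= fb
        if b - a > 1e-3:  # strict where the increment is float-resolvable
            assert fa < fb


class TestInputWaveform:
    def test_half_amplitude_at_onset(self):
        s = StimulusInput(onset_mean=200, onset_sd=16, amplitude=3.0)
        assert input_waveform(200.0, s) == pytest.approx(1.5, rel=1e-12)

    def test_vanishes_far_before_onset(self):
        s = StimulusInput(onset_mean=200, onset_sd=16, amplitude=1.0)
        assert input_waveform(-1e4, s) == pytest.approx(0.0, abs=1e-300)

    def test_one_sd_after_onset(self):
        # error-function oracle: Phi(1) ~ 0.8413
        from scipy.special import ndtr

        s = StimulusInput(onset_mean=200, onset_sd=16, amplitude=1.0)
        assert input_waveform(216.0, s) == pytest.approx(ndtr(1.0), rel=1e-12)

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            StimulusInput(onset_mean=200, onset_sd=0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-500, 500), st.floats(-500, 500))
    def test_non_decreasing(self, a, b):
        s = StimulusInput(onset_mean=100, onset_sd=20, amplitude=2.0)
        if a <= b:
            assert input_waveform(a, s) <= input_waveform(b, s) + 1e-15


# ---------------------------------------------------------------------------
# state derivatives
# ---------------------------------------------------------------------------


def _scalar_derivs(x, m0, m2, m4, m6, p: SourceParameters):
    """Independent scalar implementation of the 8-state kernel equations."""
    te, ti = p.tau_e / 1000.0, p.tau_i / 1000.0
    dx = np.empty(8)
    for (iv, m, H, tau) in ((0, m0, p.H_e, te), (2, m2, p.H_e, te),
                            (4, m4, p.H_e, te), (6, m6, p.H_i, ti)):
        dx[iv] = x[iv + 1]
        dx[iv + 1] = (H / tau) * m - (2.0 / tau) * x[iv + 1] - x[iv] / tau ** 2
    return dx


class TestStateDerivatives:
    def test_rest_is_fixed_point(self, chain):
        model, _, _ = chain
        S = len(model.sources)
        dx = state_derivatives(np.zeros((S, 8)), model, np.zeros(S))
        assert np.all(dx == 0.0)

    def test_zero_design_code_matches_unmodulated(self, chain):
        model, _, _ = chain
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.5, (3, 8))
        u = rng.normal(0, 1, 3)
        # condition 0 has design code 0 -> exp(beta*0) = 1
        dx_mod = state_derivatives(x, model, u, condition_index=0)
        from dataclasses import replace

        dx_plain = state_derivatives(x, replace(model, modulation=[]), u)
        np.testing.assert_array_equal(dx_mod, dx_plain)

    def test_single_source_matches_scalar_oracle(self):
        p = SourceParameters()
        model = NetworkModel(sources=[Source("A", "M", (0, 0, 0), 0, p)],
                             input_targets=["A"])
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (1, 8))
        drive = 2.5
        got = state_derivatives(x, model, np.array([drive]))
        sp = firing_rate(x[0, 2] - x[0, 6], p)
        expect = _scalar_derivs(
            x[0],
            m0=p.gamma1 * sp + drive,
            m2=p.gamma2 * firing_rate(x[0, 0], p),
            m4=p.gamma3 * sp,
            m6=p.gamma4 * firing_rate(x[0, 4], p),
            p=p,
        )
        np.testing.assert_allclose(got[0], expect, rtol=1e-12)

    def test_dimension_mismatch_rejected(self, chain):
        model, _, _ = chain
        with pytest.raises(ValueError):
            state_derivatives(np.zeros((2, 8)), model, np.zeros(3))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


class TestIntegrate:
    def test_zero_stimulus_stays_at_rest(self, chain):
        model, _, grid = chain
        stim = StimulusInput(onset_mean=50, onset_sd=16, amplitude=0.0)
        traj = integrate(model, stim, grid)
        assert np.all(traj.states == 0.0)

    def test_near_linear_amplitude_scaling(self, chain):
        model, _, grid = chain
        small = integrate(model, StimulusInput(50, 16, 0.01), grid).pyramidal_output
        double = integrate(model, StimulusInput(50, 16, 0.02), grid).pyramidal_output
        mask = np.abs(small) > 1e-3 * np.abs(small).max()
        ratio = double[mask] / small[mask]
        assert np.allclose(ratio, 2.0, rtol=0.02)

    def test_step_halving_converged(self, chain):
        model, stim, grid = chain
        a = integrate(model, stim, grid, dt_ms=1.0).pyramidal_output
        b = integrate(model, stim, grid, dt_ms=0.5).pyramidal_output
        assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 1e-6

    def test_deterministic(self, chain):
        model, stim, grid = chain
        a = integrate(model, stim, grid).states
        b = integrate(model, stim, grid).states
        np.testing.assert_array_equal(a, b)

    def test_monotone_gain_effect_on_top_source(self, chain):
        model, stim, grid = chain
        from dataclasses import replace

        peaks = []
        for mult in (1.0, 1.2, 1.5):
            srcs = [replace(s, params=replace(s.params, gamma2=s.params.gamma2 * mult))
                    if s.name == "PPC" else s for s in model.sources]
            traj = integrate(replace(model, sources=srcs), stim, grid)
            peaks.append(np.abs(traj.pyramidal_output[2]).max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_compiled_and_reference_paths_agree(self, chain):
        model, stim, grid = chain
        a = integrate(model, stim, grid, condition_index=2).states
        nmm._HAVE_NUMBA = False
        try:
            b = integrate(model, stim, grid, condition_index=2).states
        finally:
            nmm._HAVE_NUMBA = True
        np.testing.assert_allclose(a, b, atol=1e-12)

    @pytest.mark.filterwarnings("ignore:invalid value encountered")
    def test_divergence_reports_time(self, chain):
        # the saturating activation bounds the states for any finite gain, so
        # a non-finite drive is the reproducible way onto the error path
        model, stim, grid = chain
        with pytest.raises(IntegrationDivergenceError):
            integrate(model, StimulusInput(50, 16, np.inf), grid)


# ---------------------------------------------------------------------------
# model validation
# ---------------------------------------------------------------------------


class TestTrajectoryExport:
    def test_long_format_table_reproduces_pyramidal_output(self, chain):
        from dcmerf.nmm import trajectory_to_frame

        model, stim, grid = chain
        traj = integrate(model, stim, grid)
        df = trajectory_to_frame(traj)
        assert set(df.columns) == {"time_ms", "source", "population", "value"}
        ppc = df[(df.source == "PPC") & (df.population == "pyramidal")]
        np.testing.assert_allclose(ppc["value"].to_numpy(),
                                   traj.pyramidal_output[2], atol=1e-12)


class TestNetworkModel:
    def test_forward_edges_must_ascend(self):
        srcs = [Source("A", "M", (0, 0, 0), 0), Source("B", "M", (0, 0, 0), 1)]
        with pytest.raises(ValueError):
            NetworkModel(sources=srcs, forward=[Edge("B", "A")])

    def test_no_self_edges(self):
        srcs = [Source("A", "M", (0, 0, 0), 0)]
        with pytest.raises(ValueError):
            NetworkModel(sources=srcs, lateral=[Edge("A", "A")])

    def test_modulation_site_must_exist(self):
        srcs = [Source("A", "M", (0, 0, 0), 0)]
        with pytest.raises(ValueError):
            NetworkModel(sources=srcs, modulation=[ModulationSite("gamma2", "Z")])

    def test_condition_scaling_is_multiplicative_exponential(self, chain):
        model, _, _ = chain
        net = compile_network(model)
        g0, _ = net.condition_arrays(0)
        g2, _ = net.condition_arrays(2)
        i = model.source_index("PPC")
        assert g2[1, i] / g0[1, i] == pytest.approx(np.exp(0.3 * 2.0), rel=1e-12)
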