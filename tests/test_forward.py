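"""Tests of the lead-field projection, spatial modes and ERF containers."""

import numpy as np
import pytest

from dcmerf.forward import (
    ERFDataset,
    ERFParseError,
    LeadField,
    SpatialModes,
    baseline_correct,
    compute_spatial_modes,
    crop_erf,
    mode_reduce,
    project_to_sensors,
    read_erf,
    retained_variance,
    synthesize_lead_field,
    write_erf,
)
from dcmerf.inversion import ForwardProblem
from dcmerf.nmm import StimulusInput, integrate
from dcmerf.synth import study_network


def _erf(data, time=None, **kw):
    data = np.asarray(data, float)
    if time is None:
        time = np.arange(data.shape[2], dtype=float) * 5.0
    kw.setdefault("conditions", [f"c{i}" for i in range(data.shape[0])])
    return ERFDataset(data=data, fs_hz=200.0, time_ms=time, **kw)


class TestProjection:
    def test_zero_trajectory_gives_zero_sensors(self):
        lf = synthesize_lead_field(10, ["a", "b", "c"], seed=0)
        out = project_to_sensors(np.zeros((3, 40)), lf, ["a", "b", "c"])
        assert np.all(out == 0.0)

    def test_identity_lead_field_is_passthrough(self):
        lf = LeadField(matrix=np.eye(3), source_names=["a", "b", "c"])
        pyr = np.random.default_rng(0).normal(size=(3, 20))
        np.testing.assert_array_equal(project_to_sensors(pyr, lf), pyr)

    def test_matches_dense_product_oracle(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(10, 3))
        g = rng.normal(size=3)
        lf = LeadField(matrix=M, source_names=list("abc"), log_output_gain=g)
        pyr = rng.normal(size=(3, 25))
        np.testing.assert_allclose(project_to_sensors(pyr, lf),
                                   M @ np.diag(np.exp(g)) @ pyr, rtol=1e-12)

    def test_linearity_exact(self):
        rng = np.random.default_rng(2)
        lf = synthesize_lead_field(12, list("abc"), seed=3)
        X, Y = rng.normal(size=(2, 3, 30))
        lhs = project_to_sensors(2.5 * X - 1.5 * Y, lf)
        rhs = 2.5 * project_to_sensors(X, lf) - 1.5 * project_to_sensors(Y, lf)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_source_order_mismatch_rejected(self):
        lf = synthesize_lead_field(10, ["a", "b"], seed=0)
        with pytest.raises(ValueError):
            project_to_sensors(np.zeros((2, 5)), lf, ["b", "a"])


class TestSpatialModes:
    def test_rank_one_data_fully_captured_by_first_mode(self):
        u = np.linspace(-1, 1, 8)[:, None]
        X = u @ np.sin(np.linspace(0, 6, 50))[None, :]
        modes = compute_spatial_modes(X, 1)
        assert retained_variance(X, modes) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_sources_two_modes_capture_all(self):
        # variance bookkeeping: two orthogonal spatial patterns, n = 2
        t = np.linspace(0, 1, 60)
        A = np.zeros((6, 60))
        A[0] = np.sin(8 * t)
        A[3] = np.cos(5 * t)
        modes = compute_spatial_modes(A, 2)
        assert retained_variance(A, modes) == pytest.approx(1.0, abs=1e-12)

    def test_rows_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 120))
        m = compute_spatial_modes(X, 5)
        np.testing.assert_allclose(m.projection @ m.projection.T, np.eye(5),
                                   atol=1e-10)
        for row in m.projection:
            assert row[np.argmax(np.abs(row))] > 0
        m2 = compute_spatial_modes(X.copy(), 5)
        np.testing.assert_array_equal(m.projection, m2.projection)

    def test_too_many_modes_rejected(self):
        with pytest.raises(ValueError):
            compute_spatial_modes(np.zeros((4, 10)), 5)

    def test_eight_modes_capture_six_source_network(self):
        # noiseless bilateral six-source simulation through a 64-sensor field
        model = study_network(bilateral=True)
        stim = StimulusInput(onset_mean=200.0, onset_sd=16.0, amplitude=32.0)
        grid = np.arange(0.0, 501.0, 5.0)
        traj = integrate(model, stim, grid)
        lf = synthesize_lead_field(64, model.source_names, seed=11)
        X = project_to_sensors(traj, lf)
        modes = compute_spatial_modes(X, 8)
        assert retained_variance(X, modes) >= 0.99


class TestBaseline:
    def test_constant_channel_zeroed(self):
        d = _erf(np.full((1, 2, 20), 3.7), baseline_ms=(0.0, 50.0))
        out = baseline_correct(d)
        assert np.allclose(out.data, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        d = _erf(rng.normal(size=(2, 3, 40)), baseline_ms=(0.0, 50.0))
        once = baseline_correct(d)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-15)

    def test_subtracts_baseline_mean(self):
        data = np.zeros((1, 1, 20))
        data[0, 0, :4] = 3.2  # baseline window = first 4 samples
        data[0, 0, 4:] = 7.0
        d = _erf(data, time=np.arange(20.0) * 5 - 20.0, baseline_ms=(-20.0, -5.0))
        out = baseline_correct(d)
        assert out.data[0, 0, 0] == pytest.approx(0.0)
        assert out.data[0, 0, 10] == pytest.approx(7.0 - 3.2)

    def test_empty_baseline_window_rejected(self):
        d = _erf(np.zeros((1, 1, 10)))
        with pytest.raises(ValueError):
            baseline_correct(d)


class TestContainerIO:
    @pytest.mark.parametrize("suffix", ["", ".h5"])
    def test_lossless_round_trip(self, tmp_path, suffix):
        rng = np.random.default_rng(6)
        d = _erf(rng.normal(size=(3, 16, 51)), baseline_ms=(0.0, 25.0))
        p = write_erf(d, tmp_path / f"erf{suffix}")
        back = read_erf(p)
        np.testing.assert_array_equal(back.data, d.data)
        np.testing.assert_array_equal(back.time_ms, d.time_ms)
        assert back.conditions == d.conditions
        assert back.fs_hz == d.fs_hz
        assert tuple(back.baseline_ms) == d.baseline_ms
        assert back.channel_names == d.channel_names

    def test_missing_metadata_field_is_parse_error(self, tmp_path):
        d = _erf(np.zeros((1, 4, 10)))
        p = write_erf(d, tmp_path / "erf")
        import json

        meta = json.loads((p / "erf.json").read_text())
        del meta["fs_hz"]
        (p / "erf.json").write_text(json.dumps(meta))
        with pytest.raises(ERFParseError, match="fs_hz"):
            read_erf(p)

    def test_large_channel_count_shapes_preserved(self, tmp_path):
        d = _erf(np.zeros((1, 275, 101)), time=np.arange(101.0) * 5)
        back = read_erf(write_erf(d, tmp_path / "big"))
        assert back.data.shape == (1, 275, 101)


class TestModeReduce:
    def test_crop_and_project_shapes(self):
        rng = np.random.default_rng(7)
        time = np.arange(-100.0, 251.0, 5.0)
        d = _erf(rng.normal(size=(3, 16, len(time))), time=time,
                 baseline_ms=(-100.0, 0.0))
        modes = compute_spatial_modes(rng.normal(size=(16, 200)), 4)
        y = mode_reduce(d, modes, 0.0, 250.0)
        assert y.shape == (4, 51, 3)

    def test_mode_projection_preserves_model_ranking_noiseless(self, noiseless_problem):
        # evidence ordering true vs wrong-site model survives mode reduction
        from dataclasses import replace

        from dcmerf.inversion import default_priors, fit
        from dcmerf.nmm import ModulationSite

        problem, theta = noiseless_problem
        clean = problem.predict(theta)
        post_true = fit(problem, clean)
        wrong_model = replace(problem.model,
                              modulation=[ModulationSite("gamma2", "VC", 0.0)])
        wrong = ForwardProblem(wrong_model, problem.stim, problem.lead_field,
                               problem.modes, problem.grid_ms,
                               default_priors(wrong_model, problem.stim))
        post_wrong = fit(wrong, clean)
        assert post_true.free_energy > post_wrong.free_energy + 3.0
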