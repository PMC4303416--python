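"""Per-breath elastance estimation, normalisation, and surface assembly."""

import numpy as np
import pytest

from edrs import (
    ModelParams,
    breath_edrs,
    build_surface,
    compute_edrs_trace,
    detect_breaths,
    normalize_trajectory,
)
from edrs.errors import ConsistencyError, DegenerateBreathError, ParameterError
from edrs.segmentation import VolumeTrace


def _trace(paw, flow, volume, peep=0.0, **kwargs):
    params = ModelParams(**kwargs)
    vol = VolumeTrace(breath_index=0, volume=np.asarray(volume, dtype=float))
    return compute_edrs_trace(
        np.asarray(paw, dtype=float), np.asarray(flow, dtype=float),
        vol, peep, params,
    )


class TestEdrsTrace:
    def test_direct_substitution(self):
        # (15 - 5*0.5) / 0.25 = 50 cmH2O/L
        edrs, valid = _trace([15.0, 15.0], [0.5, 0.5], [0.25, 0.25], rrs=5.0)
        assert valid.all()
        np.testing.assert_allclose(edrs, 50.0)

    def test_zero_volume_at_onset_masked(self):
        edrs, valid = _trace([15, 15, 15], [0.5] * 3, [0.0, 0.2, 0.4])
        assert not valid[0]
        assert np.isnan(edrs[0])
        assert valid[1:].all()

    def test_all_zero_volume_degenerate(self):
        with pytest.raises(DegenerateBreathError):
            _trace([15, 15], [0.0, 0.0], [0.0, 0.0])

    def test_invalid_region_is_prefix(self, ps_noise_free):
        _, record, _ = ps_noise_free
        params = ModelParams()
        for breath in detect_breaths(record):
            _, valid, _ = breath_edrs(record, breath, params)
            first = np.argmax(valid)
            assert valid[first:].all() and not valid[:first].any()

    def test_passive_breath_recovers_constant_elastance(self, passive_session):
        cfg, record, _ = passive_session
        params = ModelParams(rrs=cfg.rrs_true)
        for breath in detect_breaths(record):
            edrs, valid, _ = breath_edrs(record, breath, params)
            np.testing.assert_allclose(edrs[valid], cfg.e_passive, atol=0.5)

    def test_spontaneous_breath_starts_negative(self, ps_noise_free):
        cfg, record, _ = ps_noise_free
        params = ModelParams(rrs=cfg.rrs_true)
        for breath in detect_breaths(record):
            edrs, valid, _ = breath_edrs(record, breath, params)
            assert edrs[valid][0] < 0.0

    def test_exact_recovery_of_analytic_truth(self, ps_noise_free, nava_noise_free):
        for cfg, record, truth in (ps_noise_free, nava_noise_free):
            params = ModelParams(rrs=cfg.rrs_true)
            for breath in detect_breaths(record):
                edrs, valid, _ = breath_edrs(record, breath, params)
                ref = truth.edrs_true[breath.onset : breath.end_insp]
                assert np.nanmax(np.abs(edrs[valid] - ref[valid])) < 1e-3

    def test_higher_assumed_resistance_shifts_edrs_down(self, ps_noise_free):
        cfg, record, _ = ps_noise_free
        for breath in detect_breaths(record):
            traces = {}
            for rrs in (1.0, 5.0, 10.0):
                edrs, valid, _ = breath_edrs(record, breath, ModelParams(rrs=rrs))
                traces[rrs] = (edrs, valid)
            valid = traces[1.0][1]
            flow = record.flow[breath.onset : breath.end_insp]
            sel = valid & (flow > 0)
            assert np.all(traces[1.0][0][sel] > traces[5.0][0][sel])
            assert np.all(traces[5.0][0][sel] > traces[10.0][0][sel])

    @pytest.mark.parametrize("scale", [0.5, 2.0, 7.3])
    def test_linearity_in_elastic_pressure(self, scale):
        paw = np.array([8.0, 12.0, 14.0])
        flow = np.array([0.4, 0.5, 0.3])
        vol = np.array([0.05, 0.15, 0.28])
        peep, rrs = 5.0, 5.0
        base, valid = _trace(paw, flow, vol, peep=peep, rrs=rrs)
        # scale the elastic pressure (paw - peep) and the resistive term alike
        scaled, _ = _trace(peep + scale * (paw - peep), scale * flow, vol,
                           peep=peep, rrs=rrs)
        np.testing.assert_allclose(scaled[valid], scale * base[valid])


class TestNormalisation:
    def test_constant_trace_preserved(self):
        edrs = np.full(37, 20.0)
        valid = np.ones(37, dtype=bool)
        traj = normalize_trajectory(edrs, valid, ti=0.9, params=ModelParams())
        assert traj.valid.all()
        np.testing.assert_allclose(traj.edrs, 20.0)
        assert traj.tau[0] == 0.0 and traj.tau[-1] == 1.0
        assert np.allclose(np.diff(traj.tau), traj.tau[1] - traj.tau[0])

    def test_linear_ramp_exact(self):
        m = 81
        x = np.linspace(0.0, 1.0, m)
        traj = normalize_trajectory(100.0 * x, np.ones(m, bool), 0.8, ModelParams())
        np.testing.assert_allclose(traj.edrs, 100.0 * traj.tau, atol=1e-12)

    def test_reparameterisation_invariance(self):
        # the same linear shape of t/ti sampled at ti=0.8 s and ti=1.6 s
        params = ModelParams()
        shape = lambda x: 5.0 + 40.0 * x
        trajs = []
        for ti in (0.8, 1.6):
            m = int(ti / 0.01) + 1
            x = np.linspace(0.0, 1.0, m)
            trajs.append(
                normalize_trajectory(shape(x), np.ones(m, bool), ti, params)
            )
        np.testing.assert_allclose(trajs[0].edrs, trajs[1].edrs, atol=1e-10)

    def test_invalid_prefix_stays_invalid_on_grid(self):
        m = 51
        valid = np.ones(m, bool)
        valid[:10] = False
        edrs = np.full(m, 30.0)
        edrs[:10] = np.nan
        traj = normalize_trajectory(edrs, valid, 0.5, ModelParams())
        first_tau = 10 / (m - 1)
        assert not traj.valid[traj.tau < first_tau - 1e-9].any()
        assert traj.valid[traj.tau >= first_tau].all()
        np.testing.assert_allclose(traj.edrs[traj.valid], 30.0)

    def test_fewer_than_two_valid_samples_rejected(self):
        valid = np.zeros(30, bool)
        valid[7] = True
        with pytest.raises(DegenerateBreathError):
            normalize_trajectory(np.zeros(30), valid, 0.5, ModelParams())


class TestSurface:
    def test_single_trajectory(self):
        traj = normalize_trajectory(np.full(20, 30.0), np.ones(20, bool),
                                    0.8, ModelParams())
        surface = build_surface([traj], "p", "PS")
        assert surface.n_breaths == 1

    def test_simulator_breaths_keep_acquisition_order(self, ps_noise_free):
        from edrs import analyze_session

        _, record, _ = ps_noise_free
        surface = analyze_session(record)
        idx = [t.breath_index for t in surface.trajectories]
        assert idx == sorted(idx)
        assert surface.n_breaths == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ConsistencyError):
            build_surface([], "p", "PS")

    def test_mixed_grid_sizes_rejected(self):
        a = normalize_trajectory(np.full(20, 1.0), np.ones(20, bool), 0.5,
                                 ModelParams(n_grid=50), breath_index=0)
        b = normalize_trajectory(np.full(20, 1.0), np.ones(20, bool), 0.5,
                                 ModelParams(n_grid=100), breath_index=1)
        with pytest.raises(ConsistencyError):
            build_surface([a, b], "p", "PS")


@pytest.mark.parametrize(
    "kwargs", [{"rrs": 0.0}, {"v_min_frac": 0.7}, {"n_grid": 5}]
)
def test_model_params_contract(kwargs):
    with pytest.raises(ParameterError):
        ModelParams(**kwargs)
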