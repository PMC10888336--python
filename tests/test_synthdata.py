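"""Generators: networks, spike cascades, calcium traces, frames, sweeps."""

import numpy as np
import pytest

from gelfun import synthdata
from gelfun.synthdata import (CalciumParams, RheoTruth, SpikeSimParams,
                              generate_network, generate_sweeps,
                              render_fluorescence, render_frames,
                              simulate_spikes)

from conftest import make_raster


class TestGenerateNetwork:
    def test_two_neurons_full_density_forces_complete(self):
        net = generate_network(2, density=1.0, n_communities=1, seed=0)
        assert net.adjacency[0, 1] == 1 and net.adjacency[1, 0] == 1
        assert net.adjacency[0, 0] == 0 and net.adjacency[1, 1] == 0

    def test_edge_count_within_binomial_bounds(self):
        net = generate_network(100, density=0.08, n_communities=4, seed=7)
        assert 640 <= net.n_edges <= 960  # 792 expected +/- 20%

    def test_deterministic_for_fixed_seed(self):
        a = generate_network(50, density=0.1, n_communities=3, seed=11)
        b = generate_network(50, density=0.1, n_communities=3, seed=11)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            generate_network(1, density=0.5)
        with pytest.raises(ValueError):
            generate_network(10, density=0.0)
        with pytest.raises(ValueError):
            generate_network(10, density=0.5, n_communities=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_structural_invariants(self, seed):
        net = generate_network(80, density=0.08, n_communities=4, seed=seed)
        assert np.all(np.diag(net.adjacency) == 0)
        # 80/20 excitatory/inhibitory split, exact at this size
        assert abs(net.excitatory_mask.mean() - 0.8) < 0.02
        # every community populated
        assert len(np.unique(net.community_labels)) == 4
        # positions inside the cylinder
        r = np.hypot(net.positions[:, 0], net.positions[:, 1])
        assert r.max() <= 3550.0 and np.abs(net.positions[:, 2]).max() <= 400.0

    def test_within_community_density_exceeds_between(self):
        net = generate_network(120, density=0.08, n_communities=4, seed=3)
        same = net.community_labels[:, None] == net.community_labels[None, :]
        off = ~np.eye(net.n_neurons, dtype=bool)
        p_in = net.adjacency[same & off].mean()
        p_out = net.adjacency[~same].mean()
        assert p_in > p_out

    def test_weights_nonneg_and_only_on_edges(self):
        net = generate_network(40, density=0.1, seed=5)
        assert np.all(net.weights >= 0)
        assert np.all((net.weights > 0) == (net.adjacency > 0))


class TestSimulateSpikes:
    def test_no_drive_gives_empty_raster(self, small_net):
        r = simulate_spikes(small_net, SpikeSimParams(
            duration=60, baseline_rate=0.0, coupling_scale=0.0, seed=0))
        assert r.n_events == 0

    def test_rejects_too_short_duration(self, small_net):
        with pytest.raises(ValueError):
            simulate_spikes(small_net, SpikeSimParams(duration=0.1, dt=1 / 33))

    def test_uncoupled_rate_near_baseline(self, small_net):
        p = SpikeSimParams(duration=900, baseline_rate=2.9 / 60,
                           coupling_scale=0.0, seed=1)
        r = simulate_spikes(small_net, p)
        rate = r.n_events / small_net.n_neurons / 900
        assert p.baseline_rate / 3 < rate < p.baseline_rate * 3

    def test_event_count_in_reported_regime(self):
        # ~2.9 activations/neuron/min, 100 neurons, 15 min -> ~4350 events
        net = generate_network(100, density=0.05, seed=2)
        p = SpikeSimParams(duration=900, baseline_rate=2.9 / 60,
                           coupling_scale=0.0, refractory=0.0, seed=3)
        r = simulate_spikes(net, p)
        mu = 4350
        assert abs(r.n_events - mu) < 5 * np.sqrt(mu)

    def test_directed_edge_shows_in_cross_correlogram(self, two_neuron_net):
        # brute-force histogram of pairwise spike-time differences
        p = SpikeSimParams(duration=900, dt=0.01, baseline_rate=0.5,
                           coupling_scale=0.9, transmission_delay=0.01,
                           refractory=0.0, seed=4)
        r = simulate_spikes(two_neuron_net, p)
        s0 = np.round(r.events[0] / p.dt).astype(int)
        s1 = np.round(r.events[1] / p.dt).astype(int)
        diffs = (s1[None, :] - s0[:, None]).ravel()
        counts = {lag: int((diffs == lag).sum()) for lag in (-1, 0, 1)}
        assert counts[1] > counts[0] and counts[1] > counts[-1]

    def test_refractory_enforced(self, small_net):
        p = SpikeSimParams(duration=300, baseline_rate=2.0,
                           coupling_scale=0.0, refractory=0.5, seed=5)
        r = simulate_spikes(small_net, p)
        for ev in r.events:
            if ev.size > 1:
                assert np.diff(ev).min() > 0.5 - 1e-9

    def test_sync_drive_raises_coactivation(self, small_net):
        from gelfun.fluoro import population_activity
        base = dict(duration=600, baseline_rate=2.9 / 60, coupling_scale=0.0)
        r_off = simulate_spikes(small_net, SpikeSimParams(**base, seed=6))
        r_on = simulate_spikes(small_net, SpikeSimParams(
            **base, sync_drive_rate=1 / 30, seed=6))
        f_off = population_activity(r_off).fraction_active.max()
        f_on = population_activity(r_on).fraction_active.max()
        assert f_on > f_off
        assert f_on >= 0.6  # drive recruits 60-90% of the network

    def test_deterministic(self, small_net):
        p = SpikeSimParams(duration=120, baseline_rate=0.1, seed=9)
        a = simulate_spikes(small_net, p)
        b = simulate_spikes(small_net, p)
        for x, y in zip(a.events, b.events):
            np.testing.assert_array_equal(x, y)


class TestRenderFluorescence:
    def test_empty_raster_constant_baseline(self):
        r = make_raster([[], []], duration=10)
        rec = render_fluorescence(r, CalciumParams(noise_sd=0, drift_amplitude=0))
        np.testing.assert_allclose(rec.F, 20.0)

    def test_single_spike_peak_amplitude(self):
        r = make_raster([[2.0]], duration=20)
        cal = CalciumParams(amplitude_per_spike=0.8, noise_sd=0, drift_amplitude=0)
        rec = render_fluorescence(r, cal)
        # peak = F0 * (1 + a), up to sampling of the kernel maximum
        expected = 20.0 * 1.8
        assert abs(rec.F.max() - expected) / expected < 0.02

    def test_two_far_spikes_equal_transients(self):
        r = make_raster([[5.0, 25.0]], duration=40)
        rec = render_fluorescence(r, CalciumParams(noise_sd=0, drift_amplitude=0))
        f = rec.F[0]
        fr = 33.0
        h1 = f[int(5 * fr):int(15 * fr)].max()
        h2 = f[int(25 * fr):int(35 * fr)].max()
        assert abs(h1 - h2) < 1e-9

    def test_rejects_bad_kinetics(self):
        with pytest.raises(ValueError):
            CalciumParams(rise_time=1.0, decay_time=0.5).validate()

    def test_noise_statistics(self):
        r = make_raster([[]], duration=60)
        rec = render_fluorescence(r, CalciumParams(noise_sd=0.5,
                                                   drift_amplitude=0, seed=1))
        assert abs(rec.F.std() - 0.5) < 0.05


class TestRenderFrames:
    def test_default_field_dimensions(self, two_neuron_net):
        r = make_raster([[], []], duration=1 / 33 * 2)
        rec = render_fluorescence(r, CalciumParams(noise_sd=0, drift_amplitude=0))
        stack = render_frames(rec, two_neuron_net)
        assert stack.shape[1:] == (1203, 1203)  # 7.1 mm / 5.9 um per px
        assert stack.dtype == np.uint8

    def test_single_spot_on_background(self):
        net = synthdata.GroundTruthNetwork(
            n_neurons=1, positions=np.zeros((1, 3)),
            adjacency=np.zeros((1, 1), int), weights=np.zeros((1, 1)),
            community_labels=np.zeros(1, int), excitatory_mask=np.ones(1, bool))
        r = make_raster([[]], duration=2 / 33)
        rec = render_fluorescence(r, CalciumParams(noise_sd=0, drift_amplitude=0))
        stack = render_frames(rec, net, field_mm=0.2, px_um=5.9)
        frame = stack[0]
        assert frame.max() > 0
        assert (frame > 0).sum() < frame.size * 0.2  # a localized spot

    def test_roi_mean_trace_recovers_activity(self):
        net = synthdata.GroundTruthNetwork(
            n_neurons=1, positions=np.zeros((1, 3)),
            adjacency=np.zeros((1, 1), int), weights=np.zeros((1, 1)),
            community_labels=np.zeros(1, int), excitatory_mask=np.ones(1, bool))
        r = make_raster([[1.0, 4.0, 7.0]], duration=10)
        rec = render_fluorescence(r, CalciumParams(noise_sd=0, drift_amplitude=0))
        stack = render_frames(rec, net, field_mm=0.1, px_um=5.9, gain=2.0)
        cy = cx = stack.shape[1] // 2
        trace = stack[:, cy - 2:cy + 3, cx - 2:cx + 3].mean(axis=(1, 2))
        rho = np.corrcoef(trace, rec.F[0])[0, 1]
        assert rho > 0.9

    def test_close_neurons_warn(self):
        net = synthdata.GroundTruthNetwork(
            n_neurons=2, positions=np.array([[0, 0, 0], [5.0, 0, 0]]),
            adjacency=np.zeros((2, 2), int), weights=np.zeros((2, 2)),
            community_labels=np.zeros(2, int), excitatory_mask=np.ones(2, bool))
        r = make_raster([[], []], duration=2 / 33)
        rec = render_fluorescence(r, CalciumParams(noise_sd=0, drift_amplitude=0))
        with pytest.warns(UserWarning, match="ROI width"):
            render_frames(rec, net, field_mm=0.1)

    def test_tiff_round_trip(self, tmp_path, two_neuron_net):
        from gelfun import io
        r = make_raster([[0.5], []], duration=1.0)
        rec = render_fluorescence(r, CalciumParams(noise_sd=0, drift_amplitude=0))
        stack = render_frames(rec, two_neuron_net, field_mm=0.2)
        p = tmp_path / "stack.tiff"
        io.write_tiff(p, stack)
        np.testing.assert_array_equal(io.read_tiff(p), stack)


class TestGenerateSweeps:
    def test_noise_free_plateau_exact(self):
        truth = RheoTruth(plateau_G1=200.0, noise_cv=0.0)
        df = generate_sweeps(truth, "frequency", grid={"omega": np.array([1.0])})
        # 1 rad/s is far below the 50 rad/s thickening onset
        assert df["G1_Pa"].iloc[0] == pytest.approx(200.0, rel=1e-3)
        assert df["G2_Pa"].iloc[0] == pytest.approx(20.0, rel=1e-3)

    def test_thickening_past_onset(self):
        truth = RheoTruth(plateau_G1=100.0, noise_cv=0.0)
        df = generate_sweeps(truth, "frequency")
        omega = df["omega_rad_s"].to_numpy()
        g1 = df["G1_Pa"].to_numpy()
        low = g1[omega < 10]
        assert np.all(np.abs(low / 100.0 - 1) < 0.05)
        assert g1[omega > 100].min() > 2 * 100.0

    def test_time_sweep_settles_at_truth(self):
        truth = RheoTruth(plateau_G1=150.0, transient_time_true=300.0,
                          noise_cv=0.0)
        df = generate_sweeps(truth, "time")
        from gelfun.rheo import detect_transient
        t_T, settled = detect_transient(df)
        assert settled
        assert abs(t_T - 300.0) <= 5.0  # one sample period

    def test_strain_sweep_slight_negative_trend(self):
        truth = RheoTruth(noise_cv=0.0)
        df = generate_sweeps(truth, "strain")
        from gelfun.rheo import check_lvr
        rep = check_lvr(df)
        assert -0.1 < rep["slope"] < 0
        assert not rep["moduli_cross"]

    def test_rejects_empty_grid_and_bad_test(self):
        with pytest.raises(ValueError):
            generate_sweeps(RheoTruth(), "frequency", grid={"omega": np.array([])})
        with pytest.raises(ValueError):
            generate_sweeps(RheoTruth(), "creep")

    def test_deterministic_and_noise_scale(self):
        truth = RheoTruth(plateau_G1=200.0, noise_cv=0.05, seed=4)
        a = generate_sweeps(truth, "frequency")
        b = generate_sweeps(truth, "frequency")
        assert a.equals(b)
        resid = np.log(a["G1_Pa"] / generate_sweeps(
            RheoTruth(plateau_G1=200.0, noise_cv=0.0), "frequency")["G1_Pa"])
        assert 0.02 < resid.std() < 0.10
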