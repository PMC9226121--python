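"""Izhikevich dynamics, synapse profiles, and wave propagation."""

import numpy as np
import pytest

import wavenav as wn
from wavenav.errors import ConfigurationError
from wavenav.wave_layer import FS, RS, NeuronArrays, V_REST


CFG = wn.SynapseConfig()


class TestSynapseProfiles:
    @pytest.mark.parametrize(
        "fn, d, expected",
        [
            (wn.synaptic_strength_ee, 1.0, 50.0),
            (wn.synaptic_strength_ee, 0.0, 0.0),   # no self-excitation
            (wn.synaptic_strength_ee, 2.0, 25.0),
            (wn.synaptic_strength_ee, 2.5, 0.0),   # beyond d_e
            (wn.synaptic_strength_ei, 1.0, 25.0),
            (wn.synaptic_strength_ei, 0.0, 0.0),
            (wn.synaptic_strength_ei, 3.0, 0.0),
        ],
    )
    def test_excitatory_profiles(self, fn, d, expected):
        assert fn(d, CFG) == pytest.approx(expected)

    def test_inhibitory_peak_at_zero_distance(self):
        assert wn.synaptic_strength_ie(0.0, CFG) == CFG.s_ie_max
        assert CFG.s_ie_max < 0

    def test_inhibitory_halves_at_distance_two(self):
        cfg = wn.SynapseConfig(d_s=2.0)
        assert wn.synaptic_strength_ie(2.0, cfg) == pytest.approx(
            cfg.s_ie_max / 2
        )

    def test_zero_beyond_inhibition_range(self):
        assert wn.synaptic_strength_ie(CFG.d_s + 0.5, CFG) == 0.0

    def test_negative_distance_rejected(self):
        for fn in (
            wn.synaptic_strength_ee,
            wn.synaptic_strength_ei,
            wn.synaptic_strength_ie,
        ):
            with pytest.raises(ConfigurationError):
                fn(-1.0, CFG)


class TestIzhikevichStep:
    def test_rest_is_fixed_point(self):
        params = NeuronArrays.uniform(1, RS)
        v = np.array([V_REST])
        u = params.b * v
        v2, u2, spiked = wn.izhikevich_step(v, u, params, np.zeros(1))
        assert not spiked.any()
        assert v2 == pytest.approx(v)
        assert u2 == pytest.approx(u)

    def test_suprathreshold_resets_to_c_and_bumps_u(self):
        params = NeuronArrays.uniform(1, RS)
        v = np.array([31.0])
        u = np.array([0.0])
        v2, u2, spiked = wn.izhikevich_step(v, u, params, np.zeros(1))
        assert spiked.all()
        assert v2[0] == RS.c
        # u is bumped by d after its own integration step
        assert u2[0] > u[0] + RS.d - 1.0

    def test_rs_spikes_within_100ms_at_dc25(self):
        params = NeuronArrays.uniform(1, RS)
        v = np.array([V_REST])
        u = params.b * v
        current = np.full(1, 25.0)
        for step in range(100):
            v, u, spiked = wn.izhikevich_step(v, u, params, current)
            if spiked.any():
                break
        assert spiked.any()

    def test_bad_dt_rejected(self):
        params = NeuronArrays.uniform(1, FS)
        with pytest.raises(ConfigurationError):
            wn.izhikevich_step(np.zeros(1), np.zeros(1), params, np.zeros(1), dt=0)


class TestSynapticInput:
    def test_silent_layer_has_only_dc_current(self, open41):
        center = open41.node_id(20, 20)
        layer = wn.WaveLayer(open41, stim_nodes=(center,))
        i_exc, i_inh = layer.gather_synaptic_input()
        assert i_exc[center] == CFG.I_dc
        i_exc[center] = 0.0
        assert not i_exc.any()
        assert not i_inh.any()

    def test_single_spike_drives_neighbor_with_peak_strength(self, open41):
        layer = wn.WaveLayer(open41)
        src = open41.node_id(10, 10)
        layer.spiked_exc[src] = True
        i_exc, i_inh = layer.gather_synaptic_input()
        assert i_exc[open41.node_id(11, 10)] == pytest.approx(50.0)
        assert i_exc[open41.node_id(12, 10)] == pytest.approx(25.0)
        assert i_exc[open41.node_id(11, 11)] == pytest.approx(50 / np.sqrt(2))
        assert i_exc[src] == 0.0  # no self-excitation
        assert i_inh[open41.node_id(11, 10)] == pytest.approx(25.0)

    def test_blocked_nodes_receive_and_send_nothing(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        m = wn.build_manifold(9, 9, mask)
        layer = wn.WaveLayer(m)
        layer.spiked_exc[m.node_id(3, 4)] = True
        i_exc, _ = layer.gather_synaptic_input()
        assert i_exc[m.node_id(4, 4)] == 0.0
        layer.spiked_exc[:] = False
        layer.spiked_exc[m.node_id(4, 4)] = True
        i_exc, i_inh = layer.gather_synaptic_input()
        assert not i_exc.any() and not i_inh.any()


class TestWavePropagation:
    def test_unstimulated_layer_stays_at_rest(self, open41):
        layer = wn.WaveLayer(open41)
        layer.run(100)
        assert np.isnan(layer.first_spike_exc).all()
        assert np.allclose(layer.v_exc, V_REST)

    def test_stimulated_center_emits_repeating_waves(self, wave300):
        layer, center = wave300
        # every excitatory neuron is eventually reached
        assert not np.isnan(layer.first_spike_exc).any()
        # the stimulated node spikes repeatedly (distinct emission bursts)
        times = [t for t, ids in layer.raster_exc if center in ids]
        bursts = 1 + sum(1 for a, b in zip(times, times[1:]) if b - a > 3)
        assert bursts >= 5

    def test_first_spike_times_nondecreasing_in_hops(self, wave300):
        layer, center = wave300
        from wavenav.analysis import first_spike_vs_bfs

        hops, times = first_spike_vs_bfs(layer, center)
        for h in range(int(hops.max())):
            assert times[hops == h].max() <= times[hops == h + 1].min() + 1e-9

    def test_blocked_ring_confines_activity(self):
        mask = np.zeros((21, 21), bool)
        mask[7:9, 7:15] = True
        mask[13:15, 7:15] = True
        mask[7:15, 7:9] = True
        mask[7:15, 13:15] = True
        m = wn.build_manifold(21, 21, mask)
        center = m.node_id(10, 10)  # inside the closed ring
        layer = wn.WaveLayer(m, stim_nodes=(center,))
        layer.run(150)
        spiked = ~np.isnan(layer.first_spike_exc)
        xs = spiked.reshape(21, 21)
        outside = np.ones((21, 21), bool)
        outside[7:15, 7:15] = False
        assert not xs[outside].any()
        assert xs[10, 10]

    def test_raster_rotation_symmetric_about_center(self, wave300):
        """Homogeneous dynamics preserve the grid's 4-fold symmetry."""
        layer, _ = wave300
        fs = layer.first_spike_exc.reshape(41, 41)
        assert np.array_equal(fs, np.rot90(fs))


class TestHeterogeneity:
    def test_phenotype_formulas_and_bounds(self):
        rng = np.random.default_rng(0)
        exc, inh = wn.randomize_neuron_params(500, rng)
        assert np.all((exc.c >= -65) & (exc.c <= -50))
        assert np.all((exc.d >= 2) & (exc.d <= 8))
        # c and d are driven by the same draw: c = -65 + 15 r^2, d = 8 - 6 r^2
        assert np.allclose((exc.c + 65) / 15, (8 - exc.d) / 6)
        assert np.all((inh.a >= 0.02) & (inh.a <= 0.1))
        assert np.all((inh.b >= 0.2) & (inh.b <= 0.25))
        assert np.allclose((inh.a - 0.02) / 0.08, (0.25 - inh.b) / 0.05)

    def test_phenotypes_reproducible_per_seed(self):
        a = wn.randomize_neuron_params(64, np.random.default_rng(7))
        b = wn.randomize_neuron_params(64, np.random.default_rng(7))
        assert np.array_equal(a[0].c, b[0].c)
        assert np.array_equal(a[1].a, b[1].a)

    def test_jitter_zero_fraction_is_identity(self, open41):
        w, _, _ = wn.build_synapses(open41, CFG)
        out = wn.jitter_synapses(w, np.random.default_rng(0), 0.0)
        assert (out != w).nnz == 0

    def test_jitter_bounds_and_sign(self, open41):
        _, _, w_ie = wn.build_synapses(open41, CFG)
        out = wn.jitter_synapses(w_ie, np.random.default_rng(1), 0.10)
        ratio = out.data / w_ie.data
        assert np.all((ratio >= 0.9) & (ratio <= 1.1))
        assert np.all(np.sign(out.data) == np.sign(w_ie.data))

    def test_jitter_reproducible_per_seed(self, open41):
        w, _, _ = wn.build_synapses(open41, CFG)
        a = wn.jitter_synapses(w, np.random.default_rng(3))
        b = wn.jitter_synapses(w, np.random.default_rng(3))
        assert (a != b).nnz == 0

    def test_heterogeneous_wave_still_reaches_whole_grid(self):
        m = wn.build_manifold(31, 31)
        layer = wn.WaveLayer(
            m,
            stim_nodes=(m.node_id(15, 15),),
            heterogeneity=wn.HeterogeneityConfig(enabled=True),
            rng=np.random.default_rng(0),
        )
        layer.run(200)
        assert (~np.isnan(layer.first_spike_exc)).mean() > 0.99
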