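"""Engine: construction contracts, scheduling, determinism, PRNG, recording."""

import numpy as np
import pytest

from hncsim import engine as eng
from hncsim import fixedpoint as fx
from hncsim import neuron as nrn

from conftest import brute_force_simulate, build_engine_network, random_small_network


class TestCreateConnect:
    def test_create_and_map(self):
        net = eng.Network()
        net.create(0, nrn.RS)
        assert net.map_neuron(0) == (0, 0)
        assert net.map_neuron(64) == (1, 0)
        assert net.map_neuron(1023) == (15, 63)

    def test_create_out_of_range(self):
        net = eng.Network()
        with pytest.raises(ValueError):
            net.create(net.config.n_m, nrn.RS)

    def test_duplicate_id(self):
        net = eng.Network()
        net.create(0, nrn.RS)
        with pytest.raises(ValueError):
            net.create(0, nrn.FS)

    def test_state_readback_roundtrip(self):
        net = eng.Network()
        net.create(3, nrn.RS, v0=-63.2, u0=-13.1)
        st = net.read_state(3)
        assert abs(st.v + 63.2) < 2 ** -23 and abs(st.u + 13.1) < 2 ** -23

    def test_streams_alternate(self):
        net = eng.Network()
        for i in range(5):
            net.create(i, nrn.RS)
        for t in range(1, 5):
            net.connect(0, t, 1.0, 0.5)
        s1, s2 = net.connectivity[0]
        assert [t.target for t in s1] == [1, 3]
        assert [t.target for t in s2] == [2, 4]
        assert all(t.stream == 1 for t in s1) and all(t.stream == 2 for t in s2)

    def test_delay_below_minimum_rejected(self):
        net = eng.Network()
        net.create(0, nrn.RS)
        net.create(1, nrn.RS)
        with pytest.raises(ValueError):
            net.connect(0, 1, 1.0, 0.05)

    def test_capacity_cap(self):
        cfg = eng.NodeConfig()
        net = eng.Network(cfg)
        for i in range(130):
            net.create(i, nrn.RS)
        for t in range(1, 129):
            net.connect(0, t, 1.0, 0.5)
        with pytest.raises(ValueError):
            net.connect(0, 129, 1.0, 0.5)


class TestTargetPacking:
    def test_roundtrip(self, rng):
        for _ in range(100):
            t = eng.SynapticTarget(
                stream=int(rng.integers(1, 3)),
                target=int(rng.integers(0, 1024)),
                weight=fx.encode(float(rng.uniform(-200, 200))),
                delay_steps=int(rng.integers(1, 65)))
            assert eng.unpack_target(eng.pack_target(t)) == t

    def test_padding_is_all_zero_and_ignored(self):
        assert eng.unpack_target(0) is None


class TestSimulate:
    def test_delayed_delivery(self):
        """A spike at k=10 through a 0.5 ms synapse arrives at k=15."""
        net = eng.Network()
        net.create(0, nrn.RS)
        net.create(1, nrn.RS)
        net.connect(0, 1, 2000.0, 0.5)  # strong enough to fire B on arrival
        stim = eng.StimulusSpec(pulse_schedule={10: [(0, 2000.0)]})
        res = net.simulate(30, stim)
        assert [(r.k, r.neuron) for r in res.records] == [(10, 0), (15, 1)]

    def test_workload_trace(self):
        net = eng.Network()
        net.create(0, nrn.RS)
        stim = eng.StimulusSpec(pulse_schedule={5: [(0, 2000.0)]})
        res = net.simulate(10, stim)
        assert res.workload_trace.sum() == len(res.records) == 1
        assert res.nu_bar_k_measured == pytest.approx(0.1)

    def test_deterministic_repeat(self, tmp_path, rng):
        neurons, conns, sched = random_small_network(rng)
        files = []
        for run in range(2):
            net = build_engine_network(neurons, conns)
            res = net.simulate(120, eng.StimulusSpec(pulse_schedule=sched))
            p = tmp_path / f"run{run}.spikes"
            eng.write_spikes(res.records, p)
            files.append(p.read_bytes())
        assert files[0] == files[1] and len(files[0]) > 0

    @pytest.mark.parametrize("arithmetic", ["float", "fixed"])
    def test_matches_brute_force_reference(self, rng, arithmetic):
        """Engine spike trains equal an independent dense-queue simulator."""
        n_nets = 10 if arithmetic == "fixed" else 25
        for _ in range(n_nets):
            neurons, conns, sched = random_small_network(rng)
            net = build_engine_network(neurons, conns)
            res = net.simulate(120, eng.StimulusSpec(pulse_schedule=sched),
                               arithmetic=arithmetic)
            got = [(r.k, r.neuron) for r in res.records]
            expect = brute_force_simulate(neurons, conns, 120, sched,
                                          arithmetic=arithmetic)
            assert got == expect

    def test_unit_relabelling_invariance(self, rng):
        """Shifting ids across processing units permutes, not perturbs, spikes."""
        neurons, conns, sched = random_small_network(rng, max_neurons=40)
        shift = eng.NodeConfig().n_p  # move every neuron one unit over
        neurons2 = {i + shift: v for i, v in neurons.items()}
        conns2 = [(s + shift, t + shift, w, d) for s, t, w, d in conns]
        sched2 = {k: [(n + shift, a) for n, a in v] for k, v in sched.items()}
        net1 = build_engine_network(neurons, conns)
        net2 = build_engine_network(neurons2, conns2)
        r1 = net1.simulate(150, eng.StimulusSpec(pulse_schedule=sched))
        r2 = net2.simulate(150, eng.StimulusSpec(pulse_schedule=sched2))
        assert r1.saturation_events == 0 and r2.saturation_events == 0
        assert ([(r.k, r.neuron + shift) for r in r1.records]
                == [(r.k, r.neuron) for r in r2.records])


class TestXnorShift:
    def test_same_seed_same_stream(self):
        s1 = s2 = 42
        for _ in range(100):
            s1, v1 = eng.xnorshift_next(s1)
            s2, v2 = eng.xnorshift_next(s2)
            assert (s1, v1) == (s2, v2)

    def test_mean_near_half(self):
        s, total = 987654321, 0.0
        n = 100_000
        for _ in range(n):
            s, v = eng.xnorshift_next(s)
            total += v
        assert 0.49 < total / n < 0.51

    def test_no_state_repeat_in_million_draws(self):
        s = 1
        seen = {s}
        for _ in range(1_000_000):
            s, _ = eng.xnorshift_next(s)
            assert s not in seen
            seen.add(s)

    def test_degenerate_seed_remapped(self):
        with pytest.warns(UserWarning):
            s, _ = eng.xnorshift_next(eng.XNORSHIFT_FIXED_POINT)
        assert s != eng.XNORSHIFT_FIXED_POINT


class TestSpikeFiles:
    def test_text_formatting(self, tmp_path):
        p = tmp_path / "s.spikes"
        eng.write_spikes([eng.SpikeRecord(k=10, neuron=7)], p)
        assert p.read_text() == "1.0 7\n"

    @pytest.mark.parametrize("fmt", ["text", "binary"])
    def test_roundtrip(self, tmp_path, rng, fmt):
        records = [eng.SpikeRecord(k=int(k), neuron=int(n))
                   for k, n in zip(sorted(rng.integers(0, 10**6, size=1000)),
                                   rng.integers(0, 1024, size=1000))]
        p = tmp_path / "s.spikes"
        eng.write_spikes(records, p, fmt=fmt)
        assert eng.read_spikes(p, fmt=fmt) == records

    def test_empty_file(self, tmp_path, fmt="text"):
        p = tmp_path / "e.spikes"
        eng.write_spikes([], p, fmt=fmt)
        assert eng.read_spikes(p, fmt=fmt) == []

    def test_malformed_line_reports_position(self, tmp_path):
        p = tmp_path / "bad.spikes"
        p.write_text("1.0 7\nnot a line\n")
        with pytest.raises(ValueError, match=":2"):
            eng.read_spikes(p)

    def test_network_files_roundtrip(self, tmp_path, rng):
        neurons, conns, _ = random_small_network(rng, max_neurons=16)
        net = build_engine_network(neurons, conns)
        net.to_files(tmp_path)
        net2 = eng.Network.from_files(tmp_path)
        assert net2.neurons.keys() == net.neurons.keys()
        for src in net.connectivity:
            got = [(t.target, t.weight.raw, t.delay_steps)
                   for lst in net2.connectivity[src] for t in lst]
            want = [(t.target, t.weight.raw, t.delay_steps)
                    for lst in net.connectivity[src] for t in lst]
            assert got == want
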