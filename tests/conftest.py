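"""Shared fixtures: an independent brute-force network simulator.

The reference simulator below deliberately shares no machinery with the
engine: delivery uses a dense map keyed by absolute target step, and the
neuron update is the scalar step function.  It serves as the oracle for
engine spike-train equivalence on small networks.
"""

from __future__ import annotations

import numpy as np
import pytest

from hncsim import engine as eng
from hncsim import fixedpoint as fx
from hncsim import neuron as nrn


def brute_force_simulate(neurons, conns, k_steps, pulse_schedule=None,
                         arithmetic="float"):
    """Straightforward reference simulation.

    neurons : dict id -> (IzhParams, v0, u0)
    conns   : list of (source, target, weight_pA, delay_steps)
    pulse_schedule : dict k -> [(neuron, pA), ...]
    Returns a list of (k, neuron) spike tuples in (k, id) order.
    """
    pulse_schedule = pulse_schedule or {}
    ids = sorted(neurons)
    # synaptic input accumulates as raw s16.23 integers, keyed by the
    # absolute delivery step (dense queue)
    pending: dict[tuple[int, int], list[int]] = {}
    out_lists = {}
    for src, tgt, w, d in conns:
        out_lists.setdefault(src, []).append((tgt, fx.encode(w).raw, d))

    if arithmetic == "fixed":
        state = {i: nrn.NeuronState(fx.decode(fx.encode(neurons[i][1])),
                                    fx.decode(fx.encode(neurons[i][2])))
                 for i in ids}
    else:
        state = {i: nrn.NeuronState(neurons[i][1], neurons[i][2]) for i in ids}
    spikes = []
    for k in range(k_steps):
        ext = {n: pa for n, pa in pulse_schedule.get(k, ())}
        fired = []
        for i in ids:
            ex_raw, inh_raw = pending.pop((k, i), (0, 0))
            state[i], sp = nrn.euler_step(
                state[i], neurons[i][0],
                i_ex=ex_raw / fx.SCALE, i_inh=inh_raw / fx.SCALE,
                i_ext=ext.get(i, 0.0), arithmetic=arithmetic)
            if sp:
                fired.append(i)
        for i in fired:
            spikes.append((k, i))
            for tgt, w_raw, d in out_lists.get(i, ()):
                cur = pending.setdefault((k + d, tgt), (0, 0))
                if w_raw >= 0:
                    pending[(k + d, tgt)] = (cur[0] + w_raw, cur[1])
                else:
                    pending[(k + d, tgt)] = (cur[0], cur[1] + w_raw)
    return spikes


def random_small_network(rng, k_rb=64, max_neurons=48, max_targets=8):
    """A random small network plus a spike-provoking pulse schedule."""
    n = int(rng.integers(4, max_neurons + 1))
    neurons = {}
    for i in range(n):
        p = nrn.RS if rng.random() < 0.8 else nrn.FS
        neurons[i] = (p, -70.0 + rng.uniform(-5, 5), -14.0 + rng.uniform(-2, 2))
    conns = []
    for src in range(n):
        n_tgt = int(rng.integers(0, max_targets + 1))
        for tgt in rng.integers(0, n, size=n_tgt):
            conns.append((src, int(tgt), float(rng.uniform(-15, 15)),
                          int(rng.integers(1, k_rb + 1))))
    schedule = {}
    for k in range(0, 120, 7):
        who = int(rng.integers(0, n))
        schedule[k] = [(who, 600.0)]
    return neurons, conns, schedule


def build_engine_network(neurons, conns, config=None):
    net = eng.Network(config or eng.NodeConfig())
    for i, (p, v0, u0) in sorted(neurons.items()):
        net.create(i, p, v0, u0)
    for src, tgt, w, d in conns:
        net.connect(src, tgt, w, d * net.config.d_min)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
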