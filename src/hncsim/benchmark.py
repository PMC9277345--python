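"""Two-population Izhikevich benchmark network and stimulus sweep.

The benchmark network consists of 1000 Izhikevich neurons: 800
excitatory regular-spiking (RS) and 200 inhibitory fast-spiking (FS)
cells.  Every neuron draws exactly ``K_in = 100`` incoming connections
without replacement; the excitatory population projects to both
populations while the inhibitory population projects only to excitatory
targets, so inhibitory neurons receive purely excitatory input.

Weight, delay and stimulus distributions of the published reference
network live in external supplementary material; the defaults here are
documented stand-ins in its lineage (Izhikevich-2003-style uniform
weights, a 1 ms minimum synaptic delay, and a sparse random-pulse
external drive) and every one of them can be overridden through
:class:`TwoPopSpec`.  Because the node caps a source neuron at 128
targets, in-degree sampling excludes sources that have reached that
capacity (a rare event affecting of order one percent of excitatory
sources).

Generation is deterministic per seed, down to byte-identical network
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import neuron as nrn
from .engine import Network, NodeConfig, StimulusSpec, TOTAL_CAPACITY


@dataclass(frozen=True)
class TwoPopSpec:
    """Generator parameters for the two-population benchmark network."""

    n_exc: int = 800
    n_inh: int = 200
    k_in: int = 100
    #: excitatory weights ~ U(0, w_exc_max] pA
    w_exc_max: float = 5.0
    #: inhibitory weights ~ U[-w_inh_max, 0) pA
    w_inh_max: float = 10.0
    #: excitatory delays ~ U{delay_min .. delay_max} ms on the 0.1 ms grid
    delay_min: float = 1.0
    delay_max: float = 6.4
    #: inhibitory delay, ms (fixed at the network's minimum synaptic delay)
    delay_inh: float = 1.0
    #: random input: one PRNG-chosen neuron per step receives this pulse (pA)
    pulse_amplitude: float = 1000.0
    v0: float = -70.0
    u0: float = -14.0

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh


def default_stimulus(spec: TwoPopSpec = TwoPopSpec(),
                     offset: float = 0.0) -> StimulusSpec:
    """The documented-default random-input drive plus a constant offset."""
    return StimulusSpec(offset=offset, pulse_amplitude=spec.pulse_amplitude,
                        pulse_count=1)


def build_two_pop(spec: TwoPopSpec = TwoPopSpec(), seed: int = 1,
                  config: NodeConfig | None = None) -> Network:
    """Build the benchmark network; deterministic per seed.

    Excitatory neurons occupy ids ``0..n_exc-1`` (RS parameters),
    inhibitory neurons the ids above (FS parameters).  Each target
    draws ``k_in`` distinct sources from its allowed source population
    (autapses excluded), skipping sources already at the node's
    128-target capacity.
    """
    cfg = config or NodeConfig(seed=seed)
    if spec.n_total > cfg.n_m:
        raise ValueError("network larger than node capacity")
    rng = np.random.default_rng(seed)
    net = Network(cfg)
    for i in range(spec.n_exc):
        net.create(i, nrn.RS, spec.v0, spec.u0, model="RS")
    for i in range(spec.n_exc, spec.n_total):
        net.create(i, nrn.FS, spec.v0, spec.u0, model="FS")

    n_delay_grid = int(round((spec.delay_max - spec.delay_min) / 0.1)) + 1

    def draw_sources(target: int, pool: np.ndarray) -> np.ndarray:
        allowed = pool[(pool != target)]
        allowed = allowed[[net.out_degree(int(s)) < TOTAL_CAPACITY
                           for s in allowed]]
        if len(allowed) < spec.k_in:
            raise ValueError(
                f"in-degree {spec.k_in} infeasible for target {target}: "
                f"only {len(allowed)} admissible sources")
        return rng.choice(allowed, size=spec.k_in, replace=False)

    exc_ids = np.arange(spec.n_exc)
    all_ids = np.arange(spec.n_total)
    for target in range(spec.n_total):
        # inhibitory targets receive only excitatory input
        pool = all_ids if target < spec.n_exc else exc_ids
        for src in draw_sources(target, pool):
            src = int(src)
            if src < spec.n_exc:
                w = spec.w_exc_max * (1.0 - rng.random())  # (0, w_exc_max]
                d = spec.delay_min + 0.1 * rng.integers(n_delay_grid)
            else:
                w = -spec.w_inh_max * (1.0 - rng.random())  # [-w_inh_max, 0)
                d = spec.delay_inh
            net.connect(src, target, w, round(d, 1))
    return net


def write_two_pop(out_dir, spec: TwoPopSpec = TwoPopSpec(), seed: int = 1) -> Network:
    """Generate and write ``neurons.csv``, ``connections.csv``, ``spec.json``."""
    net = build_two_pop(spec, seed)
    out = Path(out_dir)
    net.to_files(out)
    payload = {"seed": seed, **asdict(spec)}
    (out / "spec.json").write_text(json.dumps(payload, indent=2))
    return net


def sweep(net: Network, i_ext_values, t_bio: float, seed: int = 1,
          spec: TwoPopSpec = TwoPopSpec(), arithmetic: str = "fixed"):
    """Consecutive runs over a list of offset currents (pA).

    Each value runs ``t_bio`` seconds of biological time; returns a list
    of dicts with the offset, the measured mean rate nu_bar (spks/s),
    the per-step workload nu_bar_k, and the spike records.
    """
    h_s = net.config.h * 1e-3
    k_steps = int(round(t_bio / h_s))
    n = len(net.neurons)
    out = []
    for i_ext in i_ext_values:
        stim = default_stimulus(spec, offset=float(i_ext))
        res = net.simulate(k_steps, stim, arithmetic=arithmetic)
        total = len(res.records)
        nu_bar = total / (n * t_bio)
        out.append({"i_ext": float(i_ext),
                    "nu_bar": nu_bar,
                    "nu_bar_k": res.nu_bar_k_measured,
                    "result": res})
    return out
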