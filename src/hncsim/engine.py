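"""Node-level simulation kernel: Create / Connect / Simulate.

The node couples a time-driven neuron update with event-driven synaptic
delivery.  Each simulation step ``k`` (of width h = 0.1 ms):

1. every processing unit reads the accumulated synaptic input
   ``(i_ex, i_inh)`` for each of its neuron slots from its ring buffer
   and advances the Izhikevich state one forward-Euler step, adding any
   external stimulus current;
2. spikes are serialised in ascending (unit, slot) order into
   :class:`SpikeRecord` entries;
3. for every spike, the source neuron's full padded target packet is
   walked and each non-padding quadruple ``(s_ij, n_i, w_ij, d_ij)`` is
   delivered into the target's ring-buffer entry for step ``k + d``;
   deliveries always complete before step ``k + 1`` begins (the
   functional counterpart of the hardware's pipeline-restart rule);
4. the step's spike count is appended to the workload trace.

The run is fully deterministic given the network, the seed and the
stimulus.  Fixed-point accumulation is exact integer arithmetic, so
spike trains are invariant under relabelling neurons across processing
units as long as no saturation occurs (saturation events are counted and
reported).

A node hosts ``P`` processing units of ``N_P`` neurons; logical neuron
ids map block-wise onto (unit, slot).  Per source neuron the
connectivity store keeps two fixed-capacity target lists (one per data
stream), 64 quadruples each, mirroring the fixed-size 1 KiB presynaptic
packet the hardware streams from memory on every spike.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixedpoint as fx
from . import neuron as nrn
from .ringbuffer import RingBuffer, needs_restart


# ---------------------------------------------------------------------------
# PRNG: 32-bit XNOR-shift (complemented Marsaglia xorshift, triplet 13/17/5)
# ---------------------------------------------------------------------------

_M32 = 0xFFFFFFFF
#: unique fixed point of the XNOR-shift recurrence (the degenerate state)
XNORSHIFT_FIXED_POINT = 0x3FFFFFFF
DEFAULT_SEED = 0x12345678


def xnorshift_next(state: int) -> tuple[int, float]:
    """One step of the XNOR-shift PRNG; returns (state, uniform in [0,1)).

    A seed equal to the recurrence's fixed point would freeze the
    generator; it is remapped to a default seed with a warning.
    """
    state &= _M32
    if state == XNORSHIFT_FIXED_POINT:
        warnings.warn("degenerate XNOR-shift seed remapped to default",
                      stacklevel=2)
        state = DEFAULT_SEED
    state = ~(state ^ ((state << 13) & _M32)) & _M32
    state = ~(state ^ (state >> 17)) & _M32
    state = ~(state ^ ((state << 5) & _M32)) & _M32
    return state, state / 4294967296.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeConfig:
    """Hardware shape of one node (prototype: 16 units x 64 neurons)."""

    p: int = 16
    n_p: int = 64
    ds: int = 2
    h: float = 0.1          # ms
    d_min: float = 0.1      # ms, equals h
    k_rb: int = 64
    seed: int = DEFAULT_SEED

    @property
    def n_m(self) -> int:
        return self.p * self.n_p


#: per-source target-list capacity per stream and total (1 KiB packet of
#: 128 64-bit quadruples, split across the two streams)
STREAM_CAPACITY = 64
TOTAL_CAPACITY = 128


@dataclass(frozen=True)
class SynapticTarget:
    """Connectivity quadruple (s_ij, n_i, w_ij, d_ij)."""

    stream: int          # s_ij routing: 1 or 2 (0 is the padding code)
    target: int          # n_i
    weight: fx.Fixed40   # w_ij, pA
    delay_steps: int     # d_ij in units of d_min

    @property
    def restart(self) -> bool:
        return needs_restart(self.delay_steps)


_W_MASK = (1 << 32) - 1


def pack_target(t: SynapticTarget) -> int:
    """Pack a quadruple into one 64-bit item.

    Layout: bits 63-62 routing code (0 = padding), 61 restart flag,
    60-48 delay steps, 47-32 target id, 31-0 weight (s8.23, 32 bit).
    A padding item is all-zero.
    """
    w = t.weight.raw
    if not -(1 << 31) <= w < (1 << 31):
        raise ValueError("weight outside the packed s8.23 range (+-256 pA)")
    return ((t.stream & 0x3) << 62 | int(t.restart) << 61
            | (t.delay_steps & 0x1FFF) << 48 | (t.target & 0xFFFF) << 32
            | (w & _W_MASK))


def unpack_target(item: int) -> SynapticTarget | None:
    """Inverse of :func:`pack_target`; None for a padding item."""
    stream = (item >> 62) & 0x3
    if stream == 0:
        return None
    w = item & _W_MASK
    if w & (1 << 31):
        w -= 1 << 32
    return SynapticTarget(stream=stream, target=(item >> 32) & 0xFFFF,
                          weight=fx.Fixed40(w),
                          delay_steps=(item >> 48) & 0x1FFF)


@dataclass(frozen=True)
class SpikeRecord:
    """One recorded spike event (packs to 64 bits)."""

    k: int
    neuron: int
    node: int = 0


@dataclass
class StimulusSpec:
    """External stimulus for a run.

    offset : constant current (pA), scalar for all neurons or a mapping
        ``neuron id -> pA`` (per-population sweeps use this).
    pulse_amplitude : if nonzero, every step ``pulse_count`` neurons are
        drawn by the node's XNOR-shift PRNG and receive this current for
        one step — the documented-default "random input" protocol.
    pulse_schedule : optional mapping ``k -> [(neuron, pA), ...]`` of
        deterministic extra pulses (test instrumentation).
    """

    offset: float | dict = 0.0
    pulse_amplitude: float = 0.0
    pulse_count: int = 1
    pulse_schedule: dict = field(default_factory=dict)


@dataclass
class SimulationResult:
    records: list
    workload_trace: np.ndarray
    saturation_events: int
    restart_flags: int     # deliveries with d = d_min (performance accounting)

    @property
    def nu_bar_k_measured(self) -> float:
        return float(self.workload_trace.mean()) if len(self.workload_trace) else 0.0


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class Network:
    """A single-node network built through Create/Connect calls."""

    def __init__(self, config: NodeConfig = NodeConfig()):
        self.config = config
        self.neurons: dict[int, tuple[nrn.IzhParams, float, float]] = {}
        self.models: dict[int, str] = {}
        # per source: one list per data stream
        self.connectivity: dict[int, list[list[SynapticTarget]]] = {}
        self._out_count: dict[int, int] = {}

    # -- construction ------------------------------------------------------

    def create(self, logical_id: int, params: nrn.IzhParams,
               v0: float = -70.0, u0: float = -14.0,
               model: str = "custom") -> None:
        """Instantiate one neuron on the node (state encoded to s16.23)."""
        if not 0 <= logical_id < self.config.n_m:
            raise ValueError(
                f"neuron id {logical_id} outside node capacity {self.config.n_m}")
        if logical_id in self.neurons:
            raise ValueError(f"neuron id {logical_id} already created")
        self.neurons[logical_id] = (params, v0, u0)
        self.models[logical_id] = model

    def connect(self, source_id: int, target_id: int,
                weight: float, delay: float) -> None:
        """Create one synapse; delay in ms, a positive multiple of d_min.

        Targets are routed to the two data streams alternately per
        source, keeping the streams balanced.
        """
        if source_id not in self.neurons:
            raise ValueError(f"unknown source neuron {source_id}")
        if target_id not in self.neurons:
            raise ValueError(f"unknown target neuron {target_id}")
        steps = delay / self.config.d_min
        delay_steps = int(round(steps))
        if delay_steps < 1 or abs(steps - delay_steps) > 1e-9:
            raise ValueError(
                f"delay {delay} ms is not a positive multiple of "
                f"d_min = {self.config.d_min} ms")
        if delay_steps > self.config.k_rb:
            raise ValueError(
                f"delay {delay} ms exceeds the ring-buffer span "
                f"{self.config.k_rb * self.config.d_min} ms")
        n = self._out_count.get(source_id, 0)
        if n >= TOTAL_CAPACITY:
            raise ValueError(
                f"source {source_id} at target capacity ({TOTAL_CAPACITY})")
        stream = (n % self.config.ds) + 1
        lists = self.connectivity.setdefault(
            source_id, [[] for _ in range(self.config.ds)])
        lists[stream - 1].append(SynapticTarget(
            stream=stream, target=target_id,
            weight=fx.encode(weight), delay_steps=delay_steps))
        self._out_count[source_id] = n + 1

    def map_neuron(self, logical_id: int) -> tuple[int, int]:
        """Block mapping of a logical id to (processing unit, pipeline slot)."""
        if not 0 <= logical_id < self.config.n_m:
            raise ValueError(f"neuron id {logical_id} out of range")
        unit, slot = divmod(logical_id, self.config.n_p)
        return unit, slot

    def out_degree(self, source_id: int) -> int:
        return self._out_count.get(source_id, 0)

    # -- simulation --------------------------------------------------------

    def simulate(self, k_steps: int, stimulus: StimulusSpec | None = None,
                 arithmetic: str = "fixed",
                 record_trace_of: int | None = None) -> SimulationResult:
        """Run ``k_steps`` steps; returns spike records and workload trace.

        ``record_trace_of`` optionally records the (clamped) membrane
        trace of one neuron; the trace is attached to the result as
        ``v_trace``.
        """
        if arithmetic not in ("fixed", "float"):
            raise ValueError(f"unknown arithmetic {arithmetic!r}")
        stimulus = stimulus or StimulusSpec()
        cfg = self.config
        ids = np.array(sorted(self.neurons), dtype=np.int64)
        n = len(ids)
        if n == 0:
            return SimulationResult([], np.zeros(0), 0, 0)
        idx_of = {int(i): j for j, i in enumerate(ids)}

        params = [self.neurons[int(i)][0] for i in ids]
        v0 = np.array([self.neurons[int(i)][1] for i in ids])
        u0 = np.array([self.neurons[int(i)][2] for i in ids])
        counter = fx.SaturationCounter()

        fixed = arithmetic == "fixed"
        if fixed:
            v = fx.encode_array(v0)
            u = fx.encode_array(u0)
            ah = fx.encode_array([p.a * nrn.H_MS for p in params])
            b = fx.encode_array([p.b for p in params])
            c = fx.encode_array([p.c for p in params])
            d = fx.encode_array([p.d for p in params])
        else:
            v, u = v0.copy(), u0.copy()
            a_arr = np.array([p.a for p in params])
            b = np.array([p.b for p in params])
            c = np.array([p.c for p in params])
            d = np.array([p.d for p in params])

        # compiled per-source delivery arrays (S1 list order, then S2, ...)
        compiled: dict[int, tuple] = {}
        restart_total = 0
        for src, lists in self.connectivity.items():
            tgts = [t for lst in lists for t in lst]
            compiled[src] = (
                np.array([t.target for t in tgts], dtype=np.int64),
                np.array([t.delay_steps for t in tgts], dtype=np.int64),
                np.array([t.weight.raw for t in tgts], dtype=np.int64),
                np.array([t.weight.raw >= 0 for t in tgts], dtype=bool),
            )

        # external stimulus
        if isinstance(stimulus.offset, dict):
            offset = np.zeros(n)
            for nid, val in stimulus.offset.items():
                offset[idx_of[int(nid)]] = val
        else:
            offset = np.full(n, float(stimulus.offset))
        iext = fx.encode_array(offset) if fixed else offset.copy()
        amp = stimulus.pulse_amplitude
        amp_enc = fx.encode(amp).raw if (fixed and amp) else amp
        prng_state = cfg.seed

        rb = RingBuffer(cfg.k_rb, cfg.n_m)
        records: list[SpikeRecord] = []
        trace = [] if record_trace_of is not None else None
        trace_idx = idx_of[record_trace_of] if record_trace_of is not None else -1
        workload = np.zeros(k_steps, dtype=np.int64)

        for k in range(k_steps):
            # transient external pulses for this step
            pulses = []
            if amp:
                for _ in range(stimulus.pulse_count):
                    prng_state, uni = xnorshift_next(prng_state)
                    pulses.append(int(uni * n))
            for nid, pa in stimulus.pulse_schedule.get(k, ()):  # deterministic
                j = idx_of[int(nid)]
                pval = fx.encode(pa).raw if fixed else pa
                iext[j] += pval
                pulses.append((j, pval))
            for pj in pulses:
                if isinstance(pj, int):
                    iext[pj] += amp_enc

            # (1) read synaptic input, advance neuron states
            iex_row, iinh_row = rb.read_row(k)
            iex = iex_row[ids]
            iinh = iinh_row[ids]
            if fixed:
                v, u, spiked = nrn.euler_step_raw_v(
                    v, u, ah, b, c, d, iex, iinh, iext, counter)
            else:
                v, u, spiked = nrn.euler_step_float_v(
                    v, u, a_arr, b, c, d, iex / fx.SCALE, iinh / fx.SCALE, iext)

            # undo transient pulses
            for pj in pulses:
                if isinstance(pj, int):
                    iext[pj] -= amp_enc
                else:
                    iext[pj[0]] -= pj[1]

            if trace is not None:
                if spiked[trace_idx]:
                    trace.append(nrn.SPIKE_CUT_MV)
                else:
                    trace.append(float(v[trace_idx]) / (fx.SCALE if fixed else 1.0))

            # (2) serialise spikes in ascending (unit, slot) == id order
            sp_idx = np.nonzero(spiked)[0]
            workload[k] = len(sp_idx)
            if len(sp_idx) == 0:
                continue
            for j in sp_idx:
                records.append(SpikeRecord(k=k, neuron=int(ids[j])))

            # (3) deliver each firing source's target packet
            for j in sp_idx:
                src = int(ids[j])
                packet = compiled.get(src)
                if packet is None:
                    continue
                tg, dl, wr, exc = packet
                rb.write_batch(tg, dl, wr, exc, k, counter)
                restart_total += int(np.count_nonzero(dl == 1))

        result = SimulationResult(records, workload, counter.count, restart_total)
        if trace is not None:
            result.v_trace = np.asarray(trace)
        self._final_state = (ids, v, u, fixed)
        return result

    def read_state(self, logical_id: int) -> nrn.NeuronState:
        """State read-back: last simulated state, or the encoded initial state."""
        p, v0, u0 = self.neurons[logical_id]
        if getattr(self, "_final_state", None) is not None:
            ids, v, u, fixed = self._final_state
            j = int(np.searchsorted(ids, logical_id))
            if j < len(ids) and ids[j] == logical_id:
                s = fx.SCALE if fixed else 1.0
                return nrn.NeuronState(float(v[j]) / s, float(u[j]) / s)
        return nrn.NeuronState(fx.decode(fx.encode(v0)), fx.decode(fx.encode(u0)))

    # -- network files -----------------------------------------------------

    def to_files(self, out_dir) -> None:
        """Write ``neurons.csv`` and ``connections.csv``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [{"id": i, "model": self.models[i],
                 "a": p.a, "b": p.b, "c": p.c, "d": p.d, "v0": v0, "u0": u0}
                for i, (p, v0, u0) in sorted(self.neurons.items())]
        pd.DataFrame(rows).to_csv(out / "neurons.csv", index=False)
        crows = []
        for src in sorted(self.connectivity):
            lists = self.connectivity[src]
            # round-robin across streams restores creation order, so the
            # alternating routing reproduces the same stream split on reload
            n_conn = sum(len(lst) for lst in lists)
            iters = [iter(lst) for lst in lists]
            for i in range(n_conn):
                t = next(iters[i % len(lists)])
                crows.append({"source": src, "target": t.target,
                              "weight_pA": t.weight.value,
                              "delay_ms": t.delay_steps * self.config.d_min})
        pd.DataFrame(crows, columns=["source", "target", "weight_pA", "delay_ms"]
                     ).to_csv(out / "connections.csv", index=False)

    @classmethod
    def from_files(cls, net_dir, config: NodeConfig = NodeConfig()) -> "Network":
        net_dir = Path(net_dir)
        net = cls(config)
        neurons = pd.read_csv(net_dir / "neurons.csv")
        for _, r in neurons.iterrows():
            model = str(r["model"])
            params = nrn.PRESETS.get(model) or nrn.IzhParams(
                float(r["a"]), float(r["b"]), float(r["c"]), float(r["d"]))
            net.create(int(r["id"]), params, float(r["v0"]), float(r["u0"]),
                       model=model)
        conns = pd.read_csv(net_dir / "connections.csv")
        for _, r in conns.iterrows():
            net.connect(int(r["source"]), int(r["target"]),
                        float(r["weight_pA"]), float(r["delay_ms"]))
        return net


# ---------------------------------------------------------------------------
# Spike-record files
# ---------------------------------------------------------------------------

def write_spikes(records, path, fmt: str = "text", h: float = 0.1) -> None:
    """Write spike records; text lines are ``t_ms neuron_id`` with t = k*h."""
    path = Path(path)
    if fmt == "text":
        with open(path, "w") as f:
            for r in records:
                f.write(f"{r.k * h:.1f} {r.neuron}\n")
    elif fmt == "binary":
        packed = np.array(
            [(r.node & 0xFFFF) << 48 | (r.k & 0xFFFFFFFF) << 16
             | (r.neuron & 0xFFFF) for r in records], dtype="<u8")
        packed.tofile(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_spikes(path, fmt: str = "text", h: float = 0.1) -> list[SpikeRecord]:
    path = Path(path)
    if fmt == "text":
        records = []
        with open(path) as f:
            for lineno, line in enumerate(f, 1):
                if not line.strip():
                    continue
                try:
                    t_str, n_str = line.split()
                    t, nid = float(t_str), int(n_str)
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: malformed line {line!r}") from e
                records.append(SpikeRecord(k=int(round(t / h)), neuron=nid))
        return records
    if fmt == "binary":
        packed = np.fromfile(path, dtype="<u8")
        return [SpikeRecord(k=int((w >> 16) & 0xFFFFFFFF),
                            neuron=int(w & 0xFFFF),
                            node=int(w >> 48)) for w in packed]
    raise ValueError(f"unknown format {fmt!r}")


def save_config(config: NodeConfig, stimulus: StimulusSpec, path) -> None:
    data = {"p": config.p, "n_p": config.n_p, "ds": config.ds,
            "h": config.h, "d_min": config.d_min, "k_rb": config.k_rb,
            "seed": config.seed,
            "stimulus": {"offset": stimulus.offset,
                         "pulse_amplitude": stimulus.pulse_amplitude,
                         "pulse_count": stimulus.pulse_count}}
    Path(path).write_text(json.dumps(data, indent=2))


def load_config(path) -> tuple[NodeConfig, StimulusSpec]:
    data = json.loads(Path(path).read_text())
    stim = data.pop("stimulus", {})
    offset = stim.get("offset", 0.0)
    if isinstance(offset, dict):
        offset = {int(k): v for k, v in offset.items()}
    return (NodeConfig(**data),
            StimulusSpec(offset=offset,
                         pulse_amplitude=stim.get("pulse_amplitude", 0.0),
                         pulse_count=stim.get("pulse_count", 1)))
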