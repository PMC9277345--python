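"""Izhikevich neuron dynamics as computed by the node's ODE pipelines.

The membrane dynamics are

    dv/dt = 0.04 v^2 + 5 v + 140 - u + i_syn(t) + i_ext(t)
    du/dt = a (b v - u)
    if v >= 30 mV:  v <- c, u <- u + d

with i_syn = i_ex + i_inh (inhibitory input carries a negative sign).
Integration is explicit forward Euler at a fixed step of h = 0.1 ms, the
scheme the hardware pipeline realises.  The step is offered in two
arithmetics: ``float`` (double precision reference) and ``fixed``
(bit-faithful s16.23 pipeline emulation).

The fixed-point evaluation order is the documented pipeline reference:

    t1 = v*v; t2 = 0.04*t1; t3 = 5*v
    dv = h * (t2 + t3 + 140 - u + i_syn + i_ext)
    du = (a*h) * (b*v - u)

with all constants (0.04, 5, 140, h, a*h, b, 30, c, d) pre-encoded in
s16.23 and every ``*`` a truncating fixed-point multiply.  The threshold
test is applied to the post-update value within the same step; on a
spike the value reported for that step is clamped to the 30 mV peak.

An adaptive embedded Runge-Kutta 4(5) integration (scipy's ``RK45`` with
absolute tolerance 1e-6 and exact event location of the threshold
crossing) serves as the independent oracle for spike timing.
"""

from __future__ import annotations

from dataclasses import dataclass
import struct

import numpy as np
from scipy.integrate import solve_ivp

from . import fixedpoint as fx

H_MS = 0.1  #: integration step, ms
SPIKE_CUT_MV = 30.0

# pre-encoded model constants (raw s16.23)
_C_004 = fx.encode(0.04).raw
_C_5 = fx.encode(5.0).raw
_C_140 = fx.encode(140.0).raw
_C_H = fx.encode(H_MS).raw
_C_30 = fx.encode(SPIKE_CUT_MV).raw


@dataclass(frozen=True)
class IzhParams:
    """Izhikevich model parameters.

    a : recovery time scale (1/ms), b : recovery coupling, c : reset
    potential (mV), d : recovery increment on spike.
    """

    a: float
    b: float
    c: float
    d: float


#: regular spiking (excitatory) preset
RS = IzhParams(0.02, 0.2, -65.0, 8.0)
#: fast spiking (inhibitory) preset
FS = IzhParams(0.1, 0.2, -65.0, 2.0)

PRESETS = {"RS": RS, "FS": FS}


@dataclass(frozen=True)
class NeuronState:
    """Membrane potential v (mV) and recovery variable u."""

    v: float
    u: float


def threshold_reset(state: NeuronState, p: IzhParams) -> tuple[NeuronState, bool]:
    """The spike test/reset stage: if v >= 30 mV, v <- c and u <- u + d."""
    if state.v >= SPIKE_CUT_MV:
        return NeuronState(p.c, state.u + p.d), True
    return state, False


def euler_step(
    state: NeuronState,
    p: IzhParams,
    i_ex: float = 0.0,
    i_inh: float = 0.0,
    i_ext: float = 0.0,
    arithmetic: str = "float",
    counter: fx.SaturationCounter | None = None,
) -> tuple[NeuronState, bool]:
    """Advance one forward-Euler step of h = 0.1 ms.

    Returns the new state and a spike flag.  On a spike the returned
    state is the post-reset state; the membrane value to report for the
    step is the 30 mV peak (see :data:`SPIKE_CUT_MV`).
    """
    if arithmetic == "float":
        v, u = state.v, state.u
        i_syn = i_ex + i_inh
        dv = H_MS * (0.04 * v * v + 5.0 * v + 140.0 - u + i_syn + i_ext)
        du = H_MS * p.a * (p.b * v - u)
        v_new, u_new = v + dv, u + du
        if v_new >= SPIKE_CUT_MV:
            return NeuronState(p.c, u_new + p.d), True
        return NeuronState(v_new, u_new), False
    if arithmetic == "fixed":
        vr = fx.encode(state.v).raw
        ur = fx.encode(state.u).raw
        ver, uer, spk = _euler_step_raw_scalar(
            vr, ur, fx.encode(p.a * H_MS).raw, fx.encode(p.b).raw,
            fx.encode(p.c).raw, fx.encode(p.d).raw,
            fx.encode(i_ex).raw, fx.encode(i_inh).raw, fx.encode(i_ext).raw,
            counter,
        )
        return NeuronState(ver / fx.SCALE, uer / fx.SCALE), spk
    raise ValueError(f"unknown arithmetic {arithmetic!r}")


def _euler_step_raw_scalar(vr, ur, ah_r, b_r, c_r, d_r, iex_r, iinh_r, iext_r,
                           counter=None):
    """Scalar fixed-point pipeline on raw integers (exact arithmetic)."""
    m = lambda a, b: fx._saturate((a * b) >> fx.FRAC_BITS, counter)
    s = lambda a, b: fx._saturate(a + b, counter)
    t1 = m(vr, vr)
    t2 = m(_C_004, t1)
    t3 = m(_C_5, vr)
    acc = s(s(s(s(s(t2, t3), _C_140), -ur), s(iex_r, iinh_r)), iext_r)
    v_new = s(vr, m(_C_H, acc))
    t4 = s(m(b_r, vr), -ur)
    u_new = s(ur, m(ah_r, t4))
    if v_new >= _C_30:
        return c_r, s(u_new, d_r), True
    return v_new, u_new, False


def euler_step_raw_v(v_raw, u_raw, ah_raw, b_raw, c_raw, d_raw,
                     iex_raw, iinh_raw, iext_raw,
                     counter: fx.SaturationCounter | None = None):
    """Vectorised fixed-point Euler step on raw int64 arrays.

    Parameters are per-neuron raw arrays; returns ``(v_raw, u_raw,
    spiked_mask)`` with the reset already applied where spiked.
    Bit-identical to the scalar pipeline.
    """
    t1 = fx.mul_raw_v(v_raw, v_raw, counter)
    t2 = fx.mul_raw_v(_C_004, t1, counter)
    t3 = fx.mul_raw_v(_C_5, v_raw, counter)
    acc = fx.add_raw_v(
        fx.add_raw_v(
            fx.add_raw_v(
                fx.add_raw_v(fx.add_raw_v(t2, t3, counter), _C_140, counter),
                -u_raw, counter),
            fx.add_raw_v(iex_raw, iinh_raw, counter), counter),
        iext_raw, counter)
    v_new = fx.add_raw_v(v_raw, fx.mul_raw_v(_C_H, acc, counter), counter)
    t4 = fx.add_raw_v(fx.mul_raw_v(b_raw, v_raw, counter), -u_raw, counter)
    u_new = fx.add_raw_v(u_raw, fx.mul_raw_v(ah_raw, t4, counter), counter)
    spiked = v_new >= _C_30
    v_new = np.where(spiked, c_raw, v_new)
    u_new = np.where(spiked, fx.add_raw_v(u_new, d_raw, counter), u_new)
    return v_new, u_new, spiked


def euler_step_float_v(v, u, a, b, c, d, i_ex, i_inh, i_ext):
    """Vectorised double-precision Euler step; mirrors the fixed pipeline.

    The expression matches the scalar step term for term (identical
    floating-point association), so scalar and vector paths are
    bit-identical.
    """
    i_syn = i_ex + i_inh
    dv = H_MS * (0.04 * v * v + 5.0 * v + 140.0 - u + i_syn + i_ext)
    du = H_MS * a * (b * v - u)
    v_new, u_new = v + dv, u + du
    spiked = v_new >= SPIKE_CUT_MV
    v_new = np.where(spiked, c, v_new)
    u_new = np.where(spiked, u_new + d, u_new)
    return v_new, u_new, spiked


# ---------------------------------------------------------------------------
# Adaptive Runge-Kutta oracle
# ---------------------------------------------------------------------------

def rkf45_oracle(
    p: IzhParams,
    i_of_t,
    t_end: float,
    state0: NeuronState = NeuronState(-70.0, -14.0),
    abs_err: float = 1e-6,
):
    """Adaptive embedded RK4(5) reference integration with event handling.

    ``i_of_t`` maps time (ms) to the total input current.  Threshold
    crossings are located by the integrator's event machinery; at each
    event the reset rule is applied and integration restarts.  Returns
    ``(trajectory, spike_times)`` where trajectory is an ``(n, 3)`` array
    of ``(t, v, u)`` samples.
    """

    def rhs(t, y):
        v, u = y
        return [0.04 * v * v + 5.0 * v + 140.0 - u + i_of_t(t),
                p.a * (p.b * v - u)]

    def crossed(t, y):
        return y[0] - SPIKE_CUT_MV

    crossed.terminal = True
    crossed.direction = 1

    t0, y = 0.0, [state0.v, state0.u]
    spike_times: list[float] = []
    traj: list[np.ndarray] = []
    while t0 < t_end:
        sol = solve_ivp(rhs, (t0, t_end), y, method="RK45",
                        events=crossed, rtol=1e-8, atol=abs_err,
                        max_step=1.0)
        if not sol.success:
            raise RuntimeError(f"oracle integration failed: {sol.message}")
        traj.append(np.column_stack([sol.t, sol.y.T]))
        if sol.status == 1:  # threshold event
            t_sp = float(sol.t_events[0][0])
            spike_times.append(t_sp)
            u_sp = float(sol.y_events[0][0][1])
            t0, y = t_sp, [p.c, u_sp + p.d]
        else:
            break
    return np.concatenate(traj), np.asarray(spike_times)


def compare_spike_timing(euler_spikes, oracle_spikes, window: float = 2.0):
    """Greedy nearest matching of two sorted spike-time lists.

    Returns ``(max_offset, count_diff)`` where max_offset is the largest
    matched |Δt| (ms) and count_diff the number of unmatched spikes in
    either list.  ``window`` caps the offset at which two spikes still
    count as the same event.
    """
    a = list(map(float, euler_spikes))
    b = list(map(float, oracle_spikes))
    i = j = 0
    max_off = 0.0
    matched = 0
    while i < len(a) and j < len(b):
        dt = a[i] - b[j]
        if abs(dt) <= window:
            max_off = max(max_off, abs(dt))
            matched += 1
            i += 1
            j += 1
        elif dt > window:
            j += 1
        else:
            i += 1
    count_diff = (len(a) - matched) + (len(b) - matched)
    return max_off, count_diff


# ---------------------------------------------------------------------------
# Packed 128-bit state word
# ---------------------------------------------------------------------------

_MASK40 = (1 << 40) - 1


def pack_state_word(v: fx.Fixed40, u: fx.Fixed40, control: int = 0) -> bytes:
    """Pack (v, u) into the 128-bit state word.

    Layout: v in bits 0-39, u in bits 40-79, bits 80-119 zero, control
    byte in bits 120-127; serialised as two little-endian 64-bit words.
    """
    if not 0 <= control <= 0xFF:
        raise ValueError("control must fit one byte")
    word = (v.raw & _MASK40) | ((u.raw & _MASK40) << 40) | (control << 120)
    return struct.pack("<QQ", word & 0xFFFFFFFFFFFFFFFF, word >> 64)


def unpack_state_word(blob: bytes) -> tuple[fx.Fixed40, fx.Fixed40, int]:
    lo, hi = struct.unpack("<QQ", blob)
    word = lo | (hi << 64)
    def sext(r):
        return r - (1 << 40) if r & (1 << 39) else r
    v = fx.Fixed40(sext(word & _MASK40))
    u = fx.Fixed40(sext((word >> 40) & _MASK40))
    if (word >> 80) & _MASK40:
        raise ValueError("spare bits of state word not zero")
    return v, u, (word >> 120) & 0xFF
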