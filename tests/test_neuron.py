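"""Izhikevich dynamics: Euler step, fixed/float agreement, RK oracle."""

import numpy as np
import pytest

from hncsim import fixedpoint as fx
from hncsim import neuron as nrn


def run_single(params, k_steps, i_syn=0.0, arithmetic="float",
               state0=nrn.NeuronState(-70.0, -14.0)):
    st = state0
    spike_times = []
    for k in range(k_steps):
        st, sp = nrn.euler_step(st, params, i_ex=i_syn, arithmetic=arithmetic)
        if sp:
            spike_times.append((k + 1) * nrn.H_MS)
    return st, spike_times


class TestEulerStep:
    def test_rest_state_is_equilibrium_float(self):
        """(-70, -14) with zero input is exactly stationary in float mode."""
        st, sp = nrn.euler_step(nrn.NeuronState(-70.0, -14.0), nrn.RS)
        assert (st.v, st.u) == (-70.0, -14.0) and not sp

    def test_single_step_hand_computed(self):
        """From (-60, -12) with i_syn = 10: dv = 6.0 * h, du = 0."""
        st, sp = nrn.euler_step(nrn.NeuronState(-60.0, -12.0), nrn.RS, i_ex=10.0)
        assert st.v == pytest.approx(-59.4) and st.u == pytest.approx(-12.0)
        assert not sp

    def test_threshold_reset_rule(self):
        """At the check stage, v >= 30 resets to (c, u + d)."""
        st, sp = nrn.threshold_reset(nrn.NeuronState(31.0, -10.0), nrn.RS)
        assert sp and (st.v, st.u) == (-65.0, -2.0)
        st, sp = nrn.threshold_reset(nrn.NeuronState(29.9, -10.0), nrn.RS)
        assert not sp and st.v == 29.9

    def test_fixed_mode_equilibrium_drift(self):
        """Constant-encoding error drifts rest state < 0.01 mV over 1e5 steps."""
        v, u = fx.encode_array([-70.0]), fx.encode_array([-14.0])
        ah = fx.encode_array([nrn.RS.a * nrn.H_MS])
        b, c, d = (fx.encode_array([x]) for x in (nrn.RS.b, nrn.RS.c, nrn.RS.d))
        z = np.zeros(1, dtype=np.int64)
        for _ in range(100_000):
            v, u, sp = nrn.euler_step_raw_v(v, u, ah, b, c, d, z, z, z)
            assert not sp[0]
        assert abs(v[0] / fx.SCALE + 70.0) < 0.01

    def test_fixed_float_subthreshold_agreement(self, rng):
        """Per-step fixed/float difference stays within the analytic bound.

        The bound combines a few ulp of truncation with the s16.23
        representation errors of the constants h and 0.04, amplified by
        the drive term and by v^2 respectively; near equilibrium it
        collapses to a few ulp.
        """
        ulp = 2 ** -23
        err_h = abs(fx.decode(fx.encode(nrn.H_MS)) - nrn.H_MS)
        err_004 = abs(fx.decode(fx.encode(0.04)) - 0.04)
        err_ah = abs(fx.decode(fx.encode(nrn.RS.a * nrn.H_MS))
                     - nrn.RS.a * nrn.H_MS)
        for _ in range(200):
            v0 = float(rng.uniform(-75, 20))
            u0 = float(rng.uniform(-16, -2))
            i = float(rng.uniform(-5, 5))
            sf, _ = nrn.euler_step(nrn.NeuronState(v0, u0), nrn.RS, i_ex=i,
                                   arithmetic="float")
            sx, _ = nrn.euler_step(nrn.NeuronState(v0, u0), nrn.RS, i_ex=i,
                                   arithmetic="fixed")
            acc = 0.04 * v0 * v0 + 5.0 * v0 + 140.0 - u0 + i
            tol_v = 12 * ulp + abs(acc) * err_h + nrn.H_MS * v0 * v0 * err_004
            tol_u = 12 * ulp + abs(nrn.RS.b * v0 - u0) * err_ah
            assert abs(sx.v - sf.v) < tol_v
            assert abs(sx.u - sf.u) < tol_u


    def test_vector_fixed_step_matches_scalar(self, rng):
        vs = rng.uniform(-75, 25, size=64)
        us = rng.uniform(-16, 0, size=64)
        v, u = fx.encode_array(vs), fx.encode_array(us)
        ah = fx.encode_array(np.full(64, nrn.RS.a * nrn.H_MS))
        b = fx.encode_array(np.full(64, nrn.RS.b))
        c = fx.encode_array(np.full(64, nrn.RS.c))
        d = fx.encode_array(np.full(64, nrn.RS.d))
        z = np.zeros(64, dtype=np.int64)
        v1, u1, sp1 = nrn.euler_step_raw_v(v, u, ah, b, c, d, z, z, z)
        for i in range(64):
            vr, ur, sp = nrn._euler_step_raw_scalar(
                int(v[i]), int(u[i]), int(ah[i]), int(b[i]), int(c[i]),
                int(d[i]), 0, 0, 0)
            assert (vr, ur, sp) == (v1[i], u1[i], bool(sp1[i]))


class TestOracle:
    def test_rest_state_never_spikes(self):
        _, spikes = nrn.rkf45_oracle(nrn.RS, lambda t: 0.0, 1000.0)
        assert len(spikes) == 0

    def test_rs_periodic_at_10pa(self):
        """Constant 10 pA drives RS into a periodic spike train (23 in 1 s)."""
        _, spikes = nrn.rkf45_oracle(nrn.RS, lambda t: 10.0, 1000.0)
        assert len(spikes) == 23
        isi = np.diff(spikes[2:])
        assert isi.std() < 0.05 * isi.mean()

    def test_fs_spikes_at_least_as_fast_as_rs(self):
        _, rs = nrn.rkf45_oracle(nrn.RS, lambda t: 10.0, 500.0)
        _, fs = nrn.rkf45_oracle(nrn.FS, lambda t: 10.0, 500.0)
        assert len(fs) >= len(rs)

    def test_euler_count_matches_oracle(self):
        """Fixed-point Euler at h = 0.1 reproduces the oracle's spike count."""
        _, fixed_spikes = run_single(nrn.RS, 10_000, i_syn=10.0, arithmetic="fixed")
        _, float_spikes = run_single(nrn.RS, 10_000, i_syn=10.0, arithmetic="float")
        _, oracle_spikes = nrn.rkf45_oracle(nrn.RS, lambda t: 10.0, 1000.0)
        assert len(fixed_spikes) == len(float_spikes) == len(oracle_spikes)
        off, diff = nrn.compare_spike_timing(fixed_spikes, list(oracle_spikes),
                                             window=10.0)
        assert diff == 0
        assert off < 10.0  # phase drift of forward Euler stays sub-period


class TestCompareSpikes:
    def test_identical_lists(self):
        assert nrn.compare_spike_timing([1.0, 2.0], [1.0, 2.0]) == (0.0, 0)

    def test_shifted_lists(self):
        off, diff = nrn.compare_spike_timing([1.0, 2.0], [1.1, 2.1])
        assert off == pytest.approx(0.1) and diff == 0

    def test_unmatched_counted(self):
        off, diff = nrn.compare_spike_timing([1.0], [1.0, 500.0])
        assert diff == 1


class TestStateWord:
    def test_pack_roundtrip(self, rng):
        for _ in range(200):
            v = fx.Fixed40(int(rng.integers(fx.RAW_MIN, fx.RAW_MAX + 1)))
            u = fx.Fixed40(int(rng.integers(fx.RAW_MIN, fx.RAW_MAX + 1)))
            ctl = int(rng.integers(0, 256))
            blob = nrn.pack_state_word(v, u, ctl)
            assert len(blob) == 16
            assert nrn.unpack_state_word(blob) == (v, u, ctl)
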