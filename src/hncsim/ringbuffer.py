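"""Synaptic-delay ring buffer with valid-timestamp invalidation.

Synaptic transmission delays are realised by a circular buffer of
``K_RB`` segments x ``N_P`` slots (one slot per neuron of a processing
unit).  A weight arriving at step ``k`` with delay ``d`` steps is
accumulated in segment ``(k + d) mod K_RB``; entries carry a validity
stamp ``k_val = (k + d) >> log2(K_RB)`` so that stale entries from an
earlier buffer cycle are ignored on read without ever being cleared.
``K_RB`` must be a power of two for the stamp arithmetic to hold, and a
segment is re-addressed exactly every ``K_RB`` steps, bounding the
representable delay at ``K_RB * d_min`` with ``d_min = h = 0.1 ms``.

Excitatory and inhibitory inputs of static synapses are lumped into two
signed accumulator lanes per entry (raw s16.23 integers, so accumulation
is exact and commutative absent saturation).

Two hardware read-before-write hazards surface here only as bookkeeping:
:func:`needs_restart` flags minimum-delay deliveries (which force an ODE
pipeline restart, a cost accounted by the performance model — the
functional simulation always completes deliveries before the next step's
reads), and :func:`reorder_targets` separates multapse duplicates in a
target list so consecutive pipeline writes never address the same entry.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import fixedpoint as fx


class RingBuffer:
    """K_RB x N_P array of (i_ex, i_inh, k_val) accumulator entries."""

    def __init__(self, k_rb: int = 64, n_slots: int = 64):
        if k_rb < 2 or k_rb & (k_rb - 1):
            raise ValueError("K_RB must be a power of two >= 2")
        self.k_rb = k_rb
        self.n_slots = n_slots
        self.log2_k = k_rb.bit_length() - 1
        self.i_ex = np.zeros((k_rb, n_slots), dtype=np.int64)
        self.i_inh = np.zeros((k_rb, n_slots), dtype=np.int64)
        # stamp -1 marks never-written entries (real stamps are >= 0)
        self.k_val = np.full((k_rb, n_slots), -1, dtype=np.int64)

    # -- single-event interface --------------------------------------------

    def write(self, slot: int, delay_steps: int, weight: fx.Fixed40,
              sign: str, k: int,
              counter: fx.SaturationCounter | None = None) -> None:
        """Deliver one synaptic event arriving at step ``k``.

        ``sign`` is ``"exc"`` or ``"inh"``; the weight lands in the
        corresponding lane of the entry for step ``k + delay_steps``.
        A stale entry (wrong stamp) is overwritten, a current one
        accumulated into.
        """
        if not 1 <= delay_steps <= self.k_rb:
            raise ValueError(
                f"delay of {delay_steps} steps undeliverable (1..{self.k_rb})")
        if not 0 <= slot < self.n_slots:
            raise ValueError(f"slot {slot} out of range")
        if sign not in ("exc", "inh"):
            raise ValueError(f"sign must be 'exc' or 'inh', got {sign!r}")
        k_target = k + delay_steps
        seg = k_target % self.k_rb
        stamp = k_target >> self.log2_k
        if self.k_val[seg, slot] != stamp:
            self.i_ex[seg, slot] = 0
            self.i_inh[seg, slot] = 0
            self.k_val[seg, slot] = stamp
        lane = self.i_ex if sign == "exc" else self.i_inh
        lane[seg, slot] = fx._saturate(int(lane[seg, slot]) + weight.raw, counter)

    def read(self, slot: int, k: int) -> tuple[fx.Fixed40, fx.Fixed40]:
        """Accumulated (i_ex, i_inh) due at step ``k``; (0, 0) if stale.

        Non-destructive: invalidation is implicit through the stamp.
        """
        if not 0 <= slot < self.n_slots:
            raise ValueError(f"slot {slot} out of range")
        seg = k % self.k_rb
        if self.k_val[seg, slot] != k >> self.log2_k:
            return fx.Fixed40(0), fx.Fixed40(0)
        return (fx.Fixed40(int(self.i_ex[seg, slot])),
                fx.Fixed40(int(self.i_inh[seg, slot])))

    # -- batched interface used by the engine ------------------------------

    def write_batch(self, slots, delay_steps, weights_raw, excitatory, k: int,
                    counter: fx.SaturationCounter | None = None) -> None:
        """Vectorised delivery of many events arriving at the same step.

        All arrays are parallel; ``excitatory`` is a boolean mask
        selecting the lane.  Semantics match repeated :meth:`write`
        (stale entries are reset once before any accumulation; two
        deliveries can only share an entry if they share the stamp).
        """
        slots = np.asarray(slots, dtype=np.int64)
        delay_steps = np.asarray(delay_steps, dtype=np.int64)
        weights_raw = np.asarray(weights_raw, dtype=np.int64)
        excitatory = np.asarray(excitatory, dtype=bool)
        if delay_steps.size and (delay_steps.min() < 1 or delay_steps.max() > self.k_rb):
            raise ValueError("undeliverable delay in batch")
        k_target = k + delay_steps
        seg = k_target % self.k_rb
        stamp = k_target >> self.log2_k
        stale = self.k_val[seg, slots] != stamp
        if np.any(stale):
            self.i_ex[seg[stale], slots[stale]] = 0
            self.i_inh[seg[stale], slots[stale]] = 0
            self.k_val[seg[stale], slots[stale]] = stamp[stale]
        for lane, mask in ((self.i_ex, excitatory), (self.i_inh, ~excitatory)):
            if np.any(mask):
                np.add.at(lane, (seg[mask], slots[mask]), weights_raw[mask])
                sub = lane[seg[mask], slots[mask]]
                lane[seg[mask], slots[mask]] = fx.saturate_v(sub, counter)

    def read_row(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Raw (i_ex, i_inh) arrays over all slots due at step ``k``."""
        seg = k % self.k_rb
        valid = self.k_val[seg] == (k >> self.log2_k)
        return (np.where(valid, self.i_ex[seg], 0),
                np.where(valid, self.i_inh[seg], 0))

    def dump(self):
        """State dump as rows of (segment, slot, (i_ex, i_inh, k_val))."""
        rows = []
        for seg in range(self.k_rb):
            for slot in range(self.n_slots):
                if self.k_val[seg, slot] >= 0:
                    rows.append((seg, slot,
                                 (int(self.i_ex[seg, slot]),
                                  int(self.i_inh[seg, slot]),
                                  int(self.k_val[seg, slot]))))
        return rows


def needs_restart(delay_steps: int) -> bool:
    """True iff the delivery uses the minimum delay (d = d_min = h).

    Such a delivery targets the very next step's segment, which the ODE
    pipeline may already be fetching; the hardware then resets and
    restarts the pipeline.  Only the performance accounting consumes
    this flag — functional correctness never depends on it.
    """
    if delay_steps < 1:
        raise ValueError("delay must be >= 1 step")
    return delay_steps == 1


def reorder_targets(targets, min_gap: int = 4, key=None):
    """Separate duplicate (target, delay) items by at least ``min_gap``.

    Returns a permutation of ``targets`` in which any two items with the
    same key are at least ``min_gap`` positions apart when possible
    (greedy, stable: each position takes the earliest admissible item).
    If full separation is impossible a warning is emitted and the
    best-effort order is returned.  ``key`` extracts the conflict key;
    by default items are compared whole.
    """
    if key is None:
        key = lambda t: t
    pending = list(targets)
    out = []
    last_pos: dict = {}
    conflicts = 0
    while pending:
        placed = False
        for i, item in enumerate(pending):
            kk = key(item)
            if kk not in last_pos or len(out) - last_pos[kk] >= min_gap:
                out.append(pending.pop(i))
                last_pos[kk] = len(out) - 1
                placed = True
                break
        if not placed:  # impossible separation: take earliest, count it
            item = pending.pop(0)
            out.append(item)
            last_pos[key(item)] = len(out) - 1
            conflicts += 1
    if conflicts:
        warnings.warn(
            f"{conflicts} multapse duplicates could not be separated by "
            f"{min_gap} positions", stacklevel=2)
    return out
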