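"""40-bit signed fixed-point arithmetic in s16.23 format.

The neuron ODE pipelines of the compute node operate on a 40-bit signed
fixed-point data type with 16 integer and 23 fractional bits (s16.23);
a value is ``raw * 2**-23`` with ``raw`` a two's-complement integer in
``[-2**39, 2**39 - 1]``, i.e. values span ``[-65536, 65536 - 2**-23]``.

Design choices (the hardware datapath's rounding/overflow behaviour is
not publicly specified):

* overflow saturates (never wraps) and every saturation event can be
  counted, so higher layers can assert that a run was saturation-free;
* multiplication truncates toward -inf (plain arithmetic right shift of
  the full-precision product), the cheapest DSP datapath; a
  round-to-nearest mode is available for sensitivity studies;
* :func:`encode` rounds to nearest, ties to even, which minimises the
  representation error of model constants such as 0.04, 5 and 140.

Scalar operations work on :class:`Fixed40` wrappers with exact Python
integers.  The ``*_raw_v`` helpers operate on int64 numpy arrays of raw
values and are the fast path used by the simulation engine; they are
bit-compatible with the scalar operations (the vectorised multiply falls
back to exact integer arithmetic for the rare operands whose product
would not fit in 64 bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

INT_BITS = 16
FRAC_BITS = 23
TOTAL_BITS = 1 + INT_BITS + FRAC_BITS  # sign + integer + fraction = 40
SCALE = 1 << FRAC_BITS
RAW_MIN = -(1 << (TOTAL_BITS - 1))
RAW_MAX = (1 << (TOTAL_BITS - 1)) - 1

#: Conservative bound below which a signed 64-bit product cannot wrap.
_MUL_SAFE_PROD = float(1 << 62)


@dataclass
class SaturationCounter:
    """Counts saturation events; shared across operations of one run."""

    count: int = 0

    def hit(self, n: int = 1) -> None:
        self.count += n


@dataclass(frozen=True)
class Fixed40:
    """One s16.23 value, stored as its raw two's-complement integer."""

    raw: int

    def __post_init__(self) -> None:
        if not (RAW_MIN <= self.raw <= RAW_MAX):
            raise ValueError(f"raw value {self.raw} outside 40-bit range")

    @property
    def value(self) -> float:
        return self.raw / SCALE

    def __float__(self) -> float:
        return self.value

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Fixed40({self.raw}, value={self.value!r})"


def _saturate(raw: int, counter: SaturationCounter | None = None) -> int:
    if raw > RAW_MAX:
        if counter is not None:
            counter.hit()
        return RAW_MAX
    if raw < RAW_MIN:
        if counter is not None:
            counter.hit()
        return RAW_MIN
    return raw


def encode(x: float) -> Fixed40:
    """Encode a real number, round-to-nearest-even, saturating at the range ends."""
    if not math.isfinite(x):
        raise ValueError(f"cannot encode non-finite value {x!r}")
    # Round the exact product where possible: x * SCALE is exact for any
    # double (SCALE is a power of two), so banker's rounding on it is the
    # true nearest-even of x * 2**23.
    raw = round(x * SCALE)
    return Fixed40(_saturate(raw))


def decode(q: Fixed40) -> float:
    return q.raw / SCALE


def fx_add(a: Fixed40, b: Fixed40, counter: SaturationCounter | None = None) -> Fixed40:
    return Fixed40(_saturate(a.raw + b.raw, counter))


def fx_sub(a: Fixed40, b: Fixed40, counter: SaturationCounter | None = None) -> Fixed40:
    return Fixed40(_saturate(a.raw - b.raw, counter))


def fx_mul(
    a: Fixed40,
    b: Fixed40,
    counter: SaturationCounter | None = None,
    rounding: str = "truncate",
) -> Fixed40:
    """Full-precision product, shifted back by 23 bits.

    ``truncate`` (default) is an arithmetic right shift (floor);
    ``nearest`` adds half an LSB before the shift.
    """
    prod = a.raw * b.raw
    if rounding == "truncate":
        raw = prod >> FRAC_BITS
    elif rounding == "nearest":
        raw = (prod + (1 << (FRAC_BITS - 1))) >> FRAC_BITS
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return Fixed40(_saturate(raw, counter))


# ---------------------------------------------------------------------------
# Vectorised raw-integer helpers (int64 arrays of raw values)
# ---------------------------------------------------------------------------

def encode_array(x: np.ndarray) -> np.ndarray:
    """Vectorised encode: float array -> int64 raw array (nearest-even)."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot encode non-finite values")
    raw = np.rint(x * SCALE).astype(np.int64)
    return np.clip(raw, RAW_MIN, RAW_MAX)


def decode_array(raw: np.ndarray) -> np.ndarray:
    return np.asarray(raw, dtype=np.int64) / SCALE


def saturate_v(raw: np.ndarray, counter: SaturationCounter | None = None) -> np.ndarray:
    out = np.clip(raw, RAW_MIN, RAW_MAX)
    if counter is not None:
        counter.hit(int(np.count_nonzero(out != raw)))
    return out


def add_raw_v(a: np.ndarray, b: np.ndarray, counter: SaturationCounter | None = None) -> np.ndarray:
    # raw values are < 2**40 in magnitude, so int64 addition cannot wrap
    return saturate_v(a + b, counter)


def mul_raw_v(a, b, counter: SaturationCounter | None = None) -> np.ndarray:
    """Vectorised fx_mul on raw int64 arrays (truncating shift).

    Products of in-range state values fit int64; entries whose operands
    are large enough to overflow the 64-bit product are recomputed with
    exact Python integers, preserving bit-faithfulness near saturation.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    unsafe = np.abs(a).astype(np.float64) * np.abs(b).astype(np.float64) >= _MUL_SAFE_PROD
    with np.errstate(over="ignore"):
        raw = (a * b) >> FRAC_BITS
    if np.any(unsafe):
        au, bu = np.broadcast_arrays(a, b)
        idx = np.nonzero(np.broadcast_to(unsafe, au.shape))
        raw = np.array(np.broadcast_to(raw, au.shape))
        for i in zip(*idx):
            raw[i] = _saturate((int(au[i]) * int(bu[i])) >> FRAC_BITS, counter)
        safe_part = ~np.broadcast_to(unsafe, au.shape)
        clipped = np.clip(raw, RAW_MIN, RAW_MAX)
        if counter is not None:
            counter.hit(int(np.count_nonzero((clipped != raw) & safe_part)))
        return clipped
    return saturate_v(raw, counter)
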