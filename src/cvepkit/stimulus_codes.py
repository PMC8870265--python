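"""Binary stimulus code sets for cVEP stimulation.

A cVEP speller drives every target with the same maximal-length binary
sequence (m-sequence), circularly shifted by a target-specific number of
bits.  The m-sequence used here is 63 bits long (2**6 - 1), updated at
60 Hz, so one stimulation cycle lasts 1.05 s.  Because an m-sequence has
a two-valued cyclic autocorrelation (peak at lag 0, flat -1 elsewhere in
+/-1 encoding), shifted copies are nearly orthogonal and the evoked EEG
response identifies the attended target by its phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: The 63-bit m-sequence driving target 1, most-significant-bit first.
M_SEQUENCE_63 = "101011001101110110100100111000101111001010001100001000001111110"

#: Bits per second of the stimulus update.
BIT_UPDATE_RATE = 60.0

#: Seconds per stimulation cycle (63 bits at 60 Hz).
CYCLE_DURATION = 63 / 60.0


def _coerce_bits(code: Sequence[int] | str | np.ndarray) -> np.ndarray:
    """Validate and convert a binary code to a uint8 array of 0/1."""
    if isinstance(code, str):
        if not set(code) <= {"0", "1"}:
            bad = sorted(set(code) - {"0", "1"})
            raise ValueError(f"code contains non-binary symbols: {bad}")
        bits = np.frombuffer(code.encode("ascii"), dtype=np.uint8) - ord("0")
    else:
        bits = np.asarray(code)
        if bits.ndim != 1 or not np.isin(bits, (0, 1)).all():
            raise ValueError("code must be a 1-D sequence of 0/1 symbols")
        bits = bits.astype(np.uint8)
    return bits


@dataclass(frozen=True)
class CodeSet:
    """An m-sequence and the per-target circular shifts derived from it.

    Attributes
    ----------
    base_code : np.ndarray
        The bits of target 1's code, index 0 first.
    shifts : tuple of int
        Circular left-shift (in bits) for each target, target k at
        index k - 1.  Target 1 always has shift 0 under the default
        convention.
    bit_update_rate : float
        Stimulus update rate in Hz.
    cycle_duration : float
        Seconds per cycle; ``cycle_duration * bit_update_rate`` equals
        the code length.
    """

    base_code: np.ndarray
    shifts: tuple[int, ...]
    bit_update_rate: float = BIT_UPDATE_RATE
    cycle_duration: float = CYCLE_DURATION

    def __post_init__(self) -> None:
        bits = _coerce_bits(self.base_code)
        object.__setattr__(self, "base_code", bits)
        bits.setflags(write=False)
        n = bits.size
        if abs(self.cycle_duration * self.bit_update_rate - n) > 1e-9:
            raise ValueError(
                f"cycle_duration * bit_update_rate = "
                f"{self.cycle_duration * self.bit_update_rate} != code length {n}"
            )
        if len(set(s % n for s in self.shifts)) != len(self.shifts):
            raise ValueError("target shifts are not distinct modulo the code length")

    @property
    def n_targets(self) -> int:
        return len(self.shifts)

    @property
    def code_length(self) -> int:
        return int(self.base_code.size)

    def to_json(self) -> str:
        return json.dumps(
            {
                "base_code": "".join(str(int(b)) for b in self.base_code),
                "shifts": list(self.shifts),
                "bit_update_rate": self.bit_update_rate,
                "cycle_duration": self.cycle_duration,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "CodeSet":
        d = json.loads(payload)
        return cls(
            base_code=_coerce_bits(d["base_code"]),
            shifts=tuple(int(s) for s in d["shifts"]),
            bit_update_rate=float(d["bit_update_rate"]),
            cycle_duration=float(d["cycle_duration"]),
        )


def make_code_set(
    base_code: Sequence[int] | str | np.ndarray = M_SEQUENCE_63,
    n_targets: int = 32,
    convention: str = "uniform",
) -> CodeSet:
    """Build a :class:`CodeSet` with one circular shift per target.

    Parameters
    ----------
    base_code : binary sequence
        The code of target 1 (default: the 63-bit m-sequence).
    n_targets : int
        Number of targets; must not exceed the number of distinct
        shifts available at 2-bit spacing.
    convention : {"uniform", "literal"}
        "uniform" assigns shift ((k - 1) * 2) mod L to target k, so
        target 1 is the unshifted code and targets sit on a uniform
        2-bit grid.  "literal" assigns shift 0 to target 1 and
        (k * 2) mod L to targets k >= 2.

    Returns
    -------
    CodeSet
    """
    bits = _coerce_bits(base_code)
    n = bits.size
    if n != 63:
        raise ValueError(f"base_code must be 63 bits long, got {n}")
    if convention == "uniform":
        shifts = tuple(((k - 1) * 2) % n for k in range(1, n_targets + 1))
    elif convention == "literal":
        shifts = (0,) + tuple((k * 2) % n for k in range(2, n_targets + 1))
    else:
        raise ValueError(f"unknown shift convention: {convention!r}")
    if len(set(shifts)) != n_targets:
        raise ValueError(
            f"n_targets={n_targets} exceeds the distinct-shift capacity of a "
            f"{n}-bit code at 2-bit spacing under the {convention!r} convention"
        )
    return CodeSet(base_code=bits, shifts=shifts)


def code_for_target(cs: CodeSet, k: int) -> np.ndarray:
    """Return target k's code: the base code circularly left-rotated.

    "Left" moves symbols toward index 0, i.e. the bit at position
    ``shift`` becomes the first bit.
    """
    if not 1 <= k <= cs.n_targets:
        raise ValueError(f"target index k={k} outside 1..{cs.n_targets}")
    return np.roll(cs.base_code, -cs.shifts[k - 1])


def expand_to_samples(
    cs: CodeSet, k: int, sampling_rate: float, n_cycles: int = 2
) -> np.ndarray:
    """Expand target k's code to the EEG sample domain.

    Each bit is held for ``sampling_rate / bit_update_rate`` samples
    (the rates must divide evenly; no resampling is attempted), and the
    cycle is tiled ``n_cycles`` times.  At 600 Hz and 2 cycles the
    result has 1.05 * 600 * 2 = 1260 samples.
    """
    ratio = sampling_rate / cs.bit_update_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"sampling_rate {sampling_rate} is not an integer multiple of the "
            f"bit update rate {cs.bit_update_rate}"
        )
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    per_bit = int(round(ratio))
    one_cycle = np.repeat(code_for_target(cs, k), per_bit)
    return np.tile(one_cycle, n_cycles)


def lfsr_m_sequence(taps: Sequence[int] = (6, 1), seed_state: int = 0b111111) -> np.ndarray:
    """Generate a 63-bit m-sequence from a degree-6 Fibonacci LFSR.

    Parameters
    ----------
    taps : sequence of int
        Feedback tap positions (1-based, highest tap = register degree).
        (6, 1) is a primitive pair for degree 6 under this shift-right
        register orientation.
    seed_state : int
        Nonzero 6-bit initial register state.

    Returns
    -------
    np.ndarray
        The 63 output bits (register LSB per step).
    """
    degree = max(taps)
    if seed_state <= 0 or seed_state >= (1 << degree):
        raise ValueError("seed_state must be a nonzero state of the register")
    state = seed_state
    out = np.empty(2**degree - 1, dtype=np.uint8)
    for i in range(out.size):
        out[i] = state & 1
        fb = 0
        for t in taps:
            fb ^= (state >> (t - 1)) & 1
        state = (state >> 1) | (fb << (degree - 1))
    return out


def cyclic_autocorrelation(code: np.ndarray) -> np.ndarray:
    """Cyclic autocorrelation of a binary code in +/-1 encoding.

    For an m-sequence of length L this is two-valued: L at lag 0 and
    -1 at every other lag.
    """
    s = np.where(_coerce_bits(code).astype(int) == 1, 1, -1)
    n = s.size
    return np.array([int(np.dot(s, np.roll(s, -lag))) for lag in range(n)])


def validate_code_set(cs: CodeSet) -> dict:
    """Check m-sequence balance, autocorrelation and shift distinctness.

    Returns a dict of named boolean checks; raises nothing.
    """
    acf = cyclic_autocorrelation(cs.base_code)
    codes = [tuple(code_for_target(cs, k)) for k in range(1, cs.n_targets + 1)]
    n = cs.code_length
    return {
        "length_63": n == 63,
        "balanced": int(cs.base_code.sum()) == (n + 1) // 2,
        "two_valued_autocorrelation": acf[0] == n and bool((acf[1:] == -1).all()),
        "shifts_distinct": len(set(codes)) == cs.n_targets,
    }
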