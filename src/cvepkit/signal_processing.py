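"""Filter-bank decomposition of EEG trials.

Broadband cVEP responses carry target information in harmonics well
above the 60 Hz carrier's fundamental band, but the signal-to-noise
ratio decays with frequency.  The filter bank splits each trial into
overlapping band-pass sub-bands sharing one upper edge (60 Hz) with
rising lower edges (6, 14, 22, 30, 38 Hz), classifies in each sub-band,
and combines the per-band correlations with decaying weights

    a_k = alpha_k / sum(alpha),   alpha_k = k**-1.25 + 0.25.

Filtering is zero-phase (forward-reverse) 4th-order Butterworth so that
template/trial alignment is preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


def compute_subband_weights(n_subbands: int) -> np.ndarray:
    """Decaying sub-band combination weights a_k, k = 1..K.

    alpha_k = k**-1.25 + 0.25, normalized to sum to one.  For K = 5
    this yields (0.386, 0.207, 0.156, 0.132, 0.119) to 3 decimals.
    """
    if n_subbands < 1:
        raise ValueError("n_subbands must be >= 1")
    k = np.arange(1, n_subbands + 1, dtype=float)
    alpha = k ** -1.25 + 0.25
    return alpha / alpha.sum()


@dataclass(frozen=True)
class FilterBankSpec:
    """Band edges, filter order and combination weights of the bank."""

    low_cutoffs: tuple[float, ...] = (6.0, 14.0, 22.0, 30.0, 38.0)
    high_cutoff: float = 60.0
    filter_order: int = 4
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        lows = tuple(float(f) for f in self.low_cutoffs)
        object.__setattr__(self, "low_cutoffs", lows)
        if any(b <= a for a, b in zip(lows, lows[1:])):
            raise ValueError("low_cutoffs must be strictly increasing")
        if any(f >= self.high_cutoff for f in lows):
            raise ValueError("every low cutoff must lie below the high cutoff")
        w = self.weights or tuple(compute_subband_weights(len(lows)))
        w = tuple(float(x) for x in w)
        if len(w) != len(lows):
            raise ValueError("one weight per sub-band required")
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def n_subbands(self) -> int:
        return len(self.low_cutoffs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "low_cutoffs": list(self.low_cutoffs),
                "high_cutoff": self.high_cutoff,
                "filter_order": self.filter_order,
                "weights": list(self.weights),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "FilterBankSpec":
        d = json.loads(payload)
        return cls(
            low_cutoffs=tuple(d["low_cutoffs"]),
            high_cutoff=float(d["high_cutoff"]),
            filter_order=int(d["filter_order"]),
            weights=tuple(d.get("weights", ())),
        )


def _subband_sos(spec: FilterBankSpec, k: int, sampling_rate: float) -> np.ndarray:
    if not 1 <= k <= spec.n_subbands:
        raise ValueError(f"sub-band index k={k} outside 1..{spec.n_subbands}")
    if sampling_rate <= 2 * spec.high_cutoff:
        raise ValueError(
            f"band ({spec.low_cutoffs[k - 1]}, {spec.high_cutoff}) Hz outside "
            f"the Nyquist range at {sampling_rate} Hz"
        )
    return signal.butter(
        spec.filter_order,
        (spec.low_cutoffs[k - 1], spec.high_cutoff),
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def apply_subband(
    trial: np.ndarray, spec: FilterBankSpec, k: int, sampling_rate: float
) -> np.ndarray:
    """Zero-phase band-pass filter sub-band k along the last axis.

    Forward-reverse filtering cancels the phase response (the effective
    magnitude response is the Butterworth magnitude squared).  Edges are
    reflect-padded by one settling length before filtering because the
    trials are short and edge transients would bias the template
    correlations.
    """
    trial = np.asarray(trial, dtype=float)
    sos = _subband_sos(spec, k, sampling_rate)
    padlen = min(trial.shape[-1] - 1, 3 * (2 * sos.shape[0] + 1) * 4)
    return signal.sosfiltfilt(sos, trial, axis=-1, padtype="even", padlen=padlen)


def filter_bank(
    data: np.ndarray, spec: FilterBankSpec, sampling_rate: float
) -> np.ndarray:
    """Apply every sub-band to ``data`` (filtering the last axis).

    Returns an array with a new leading sub-band axis of length
    ``spec.n_subbands``; used to decompose whole trial tensors in one
    vectorized pass.
    """
    return np.stack(
        [apply_subband(data, spec, k, sampling_rate) for k in range(1, spec.n_subbands + 1)]
    )


def subband_magnitude_response(
    spec: FilterBankSpec, k: int, freqs: np.ndarray, sampling_rate: float
) -> np.ndarray:
    """Effective (two-pass) magnitude response of sub-band k at ``freqs``."""
    sos = _subband_sos(spec, k, sampling_rate)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=sampling_rate)
    return np.abs(h) ** 2
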