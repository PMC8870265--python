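"""Seeded synthetic multi-day cVEP EEG studies.

The generator emulates the structure the decoding pipeline assumes: a
subject-specific evoked impulse response (a difference-of-gammas kernel
with a 90-150 ms peak) convolved with the periodic stimulus code, mixed
into 16 channels through one occipitally concentrated spatial pattern,
plus coloured (1/f + white) noise with a small common-mode component.
Two sessions per subject are produced with independent multiplicative
session effects (amplitude gain, latency shift, kernel perturbation,
noise gain) so that a model trained on one day transfers imperfectly to
the other — the phenomenon the block-composition protocols quantify.

Everything is deterministic given (seed, config); no claim of
physiological realism is made beyond the template structure the
classifier exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import stats

from .stimulus_codes import CodeSet, expand_to_samples

#: Ratio of evoked power to noise power used by default.  Calibrated once
#: so that intra-session leave-one-block-out accuracy of the default
#: 10-subject study lands in the mid-90s (percent); see docs/methods.md.
DEFAULT_SNR_SCALE = 0.17


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level generative parameters (all rates in Hz, times in s)."""

    n_channels: int = 16
    n_targets: int = 32
    sampling_rate: float = 600.0
    n_cycles: int = 2
    blocks_per_session: int = 6
    kernel_duration: float = 0.25
    peak_latency_low: float = 0.09
    peak_latency_high: float = 0.15
    amplitude_sigma: float = 0.25      # log-normal(0, sigma) subject amplitude
    snr_scale: float = DEFAULT_SNR_SCALE
    latency_jitter_sd: float = 0.002   # per-trial latency jitter
    pink_fraction: float = 0.7         # fraction of noise power that is 1/f
    common_mode_amplitude: float = 0.1
    session_amplitude_sigma: float = 0.1   # log-normal(0, sigma) gain
    session_latency_sd: float = 0.005      # normal(0, sd) shift
    kernel_perturbation_sd: float = 0.15   # relative kernel noise
    session_noise_sigma: float = 0.1       # log-normal(0, sigma) noise gain

    def __post_init__(self) -> None:
        if self.snr_scale <= 0:
            raise ValueError("snr_scale must be > 0")
        if self.n_channels < 1 or self.n_targets < 1:
            raise ValueError("n_channels and n_targets must be >= 1")

    @property
    def samples_per_trial(self) -> int:
        return int(round(1.05 * self.sampling_rate * self.n_cycles))


@dataclass(frozen=True)
class SubjectModel:
    """One subject's evoked response model."""

    subject_id: int
    impulse_response: np.ndarray   # evoked kernel, amplitude vs lag
    mixing_vector: np.ndarray      # 16 per-channel weights, unit norm
    snr_scale: float               # evoked power / noise power
    latency_jitter_sd: float

    def __post_init__(self) -> None:
        if self.snr_scale <= 0:
            raise ValueError("snr_scale must be > 0")
        if not np.isfinite(self.impulse_response).all():
            raise ValueError("impulse_response must have finite energy")
        norm = np.linalg.norm(self.mixing_vector)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("mixing_vector must have unit Euclidean norm")


@dataclass(frozen=True)
class SessionEffect:
    """Day-to-day changes applied identically to all blocks of a session."""

    amplitude_gain: float = 1.0
    latency_shift: float = 0.0
    kernel_perturbation_sd: float = 0.0
    noise_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude_gain <= 0:
            raise ValueError("amplitude_gain must be > 0")
        if self.noise_gain < 0:
            raise ValueError("noise_gain must be >= 0")


IDENTITY_EFFECT = SessionEffect()


@dataclass(frozen=True)
class TrialTensor:
    """Trials of one subject-session, indexed (block, target, channel, sample)."""

    data: np.ndarray
    sampling_rate: float
    block_ids: tuple[int, ...]
    subject_id: int
    session_id: int

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be (block, target, channel, sample)")
        if len(self.block_ids) != self.data.shape[0]:
            raise ValueError("one block id per block required")
        if len(set(self.block_ids)) != len(self.block_ids):
            raise ValueError("block ids must be unique")

    @property
    def n_blocks(self) -> int:
        return self.data.shape[0]

    @property
    def n_targets(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]

    def block(self, block_id: int) -> np.ndarray:
        """The (target, channel, sample) array of one block by global id."""
        try:
            idx = self.block_ids.index(block_id)
        except ValueError:
            raise KeyError(f"block {block_id} not in tensor (has {self.block_ids})")
        return self.data[idx]

    def validate(self) -> None:
        """Enforce the study-shape invariants (32 targets, n = 1.05*FS*2)."""
        expected_n = int(round(1.05 * self.sampling_rate * 2))
        if self.n_targets != 32:
            raise ValueError(f"expected exactly 32 targets, got {self.n_targets}")
        if self.n_samples != expected_n:
            raise ValueError(
                f"trial length {self.n_samples} != 1.05 * {self.sampling_rate} * 2 "
                f"= {expected_n}"
            )


@dataclass(frozen=True)
class Study:
    """A collection of subject-session tensors sharing one code set."""

    tensors: dict[tuple[int, int], TrialTensor]
    code_set: CodeSet
    config: SimulationConfig
    seed: int | None = None

    @property
    def subjects(self) -> list[int]:
        return sorted({s for s, _ in self.tensors})

    @property
    def sessions(self) -> list[int]:
        return sorted({ses for _, ses in self.tensors})

    def tensor(self, subject: int, session: int) -> TrialTensor:
        return self.tensors[(subject, session)]

    def subject_blocks(self, subject: int) -> dict[int, np.ndarray]:
        """All of a subject's blocks keyed by global block id (1-12)."""
        out: dict[int, np.ndarray] = {}
        for (s, _), tensor in sorted(self.tensors.items()):
            if s != subject:
                continue
            for b in tensor.block_ids:
                out[b] = tensor.block(b)
        return out


# ---------------------------------------------------------------------------
# generative components
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, (np.random.Generator,)):
        return seed
    return np.random.default_rng(seed)


def _gamma_kernel(t: np.ndarray, peak: float, shape: float) -> np.ndarray:
    scale = peak / (shape - 1.0)
    k = stats.gamma.pdf(t, a=shape, scale=scale)
    return k / (np.abs(k).max() + 1e-300)


def make_kernel(
    peak_latency: float, sampling_rate: float, duration: float = 0.25
) -> np.ndarray:
    """Difference-of-gammas evoked kernel with its positive peak at
    ``peak_latency`` seconds, normalized to unit RMS."""
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    k = _gamma_kernel(t, peak_latency, 5.0) - 0.6 * _gamma_kernel(
        t, 1.6 * peak_latency, 7.0
    )
    return k / (np.sqrt(np.mean(k**2)) + 1e-300)


def sample_subject(seed, config: SimulationConfig | None = None) -> SubjectModel:
    """Draw a deterministic subject model from a seed.

    Peak latency is uniform on [peak_latency_low, peak_latency_high];
    the evoked amplitude (which sets the subject's SNR around the
    configured ``snr_scale``) is log-normal(0, amplitude_sigma).  The
    mixing vector is a posterior-channel Gaussian profile with random
    per-channel perturbations, unit-normalized.
    """
    config = config or SimulationConfig()
    rng = _rng(seed)
    subject_id = int(rng.integers(0, 2**31 - 1))
    peak = rng.uniform(config.peak_latency_low, config.peak_latency_high)
    kernel = make_kernel(peak, config.sampling_rate, config.kernel_duration)
    amplitude = float(rng.lognormal(mean=0.0, sigma=config.amplitude_sigma))
    c = np.arange(config.n_channels, dtype=float)
    # occipital electrodes sit at the high channel indices of the montage
    profile = np.exp(-((c - (config.n_channels - 3.0)) ** 2) / (2 * 2.5**2))
    profile = profile + 0.15 * rng.standard_normal(config.n_channels)
    mixing = profile / np.linalg.norm(profile)
    return SubjectModel(
        subject_id=subject_id,
        impulse_response=kernel,
        mixing_vector=mixing,
        snr_scale=config.snr_scale * amplitude**2,
        latency_jitter_sd=config.latency_jitter_sd,
    )


def sample_session_effect(seed, config: SimulationConfig | None = None) -> SessionEffect:
    """Draw one session's multiplicative drift from a seed."""
    config = config or SimulationConfig()
    rng = _rng(seed)
    return SessionEffect(
        amplitude_gain=float(rng.lognormal(0.0, config.session_amplitude_sigma)),
        latency_shift=float(rng.normal(0.0, config.session_latency_sd)),
        kernel_perturbation_sd=config.kernel_perturbation_sd,
        noise_gain=float(rng.lognormal(0.0, config.session_noise_sigma)),
    )


def _smooth(x: np.ndarray, width: int = 15) -> np.ndarray:
    win = np.hanning(width)
    win /= win.sum()
    return np.convolve(x, win, mode="same")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """1/f-power noise with unit RMS along the last axis."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** -0.5
    x = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / (rms + 1e-300)


def _trial_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, config: SimulationConfig
) -> np.ndarray:
    """Coloured per-channel noise plus a common-mode component, ~unit RMS."""
    pf = config.pink_fraction
    pink = _pink_noise(rng, (n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    noise = np.sqrt(pf) * pink + np.sqrt(1 - pf) * white
    cm = np.sqrt(pf) * _pink_noise(rng, (n_samples,)) + np.sqrt(
        1 - pf
    ) * rng.standard_normal(n_samples)
    noise = (noise + config.common_mode_amplitude * cm) / np.sqrt(
        1 + config.common_mode_amplitude**2
    )
    return noise


def _periodic_response(
    code_cycle: np.ndarray, kernel: np.ndarray, n_cycles: int
) -> np.ndarray:
    """Steady-state response: circular convolution of the (zero-mean)
    stimulus cycle with the evoked kernel, tiled over the trial."""
    n = code_cycle.size
    stim = code_cycle.astype(float) - code_cycle.mean()
    resp = np.fft.irfft(
        np.fft.rfft(stim) * np.fft.rfft(kernel, n=n), n=n
    )
    return np.tile(resp, n_cycles)


def simulate_session(
    subject: SubjectModel,
    effect: SessionEffect,
    cs: CodeSet,
    blocks: int,
    seed,
    config: SimulationConfig | None = None,
    session_id: int = 1,
    block_ids: tuple[int, ...] | None = None,
) -> TrialTensor:
    """Simulate one session: ``blocks`` passes over all targets.

    Each trial is mixing_vector (outer) the code-convolved, session-
    perturbed kernel response, circularly shifted by the session latency
    plus per-trial jitter, scaled by the session amplitude gain, plus
    coloured noise scaled to the subject's SNR.
    """
    config = config or SimulationConfig()
    if blocks < 1:
        raise ValueError("blocks must be >= 1")
    rng = _rng(seed)
    fs = config.sampling_rate
    if abs(fs / cs.bit_update_rate - round(fs / cs.bit_update_rate)) > 1e-9:
        raise ValueError("sampling rate incompatible with the code bit rate")
    n_targets = cs.n_targets
    n_samples = config.samples_per_trial

    kernel = subject.impulse_response.copy()
    if effect.kernel_perturbation_sd > 0:
        rms = np.sqrt(np.mean(kernel**2))
        pert = _smooth(rng.standard_normal(kernel.size))
        pert /= np.sqrt(np.mean(pert**2)) + 1e-300
        kernel = kernel + effect.kernel_perturbation_sd * rms * pert

    # per-target steady-state single-channel responses (n_targets, n)
    responses = np.stack(
        [
            _periodic_response(
                expand_to_samples(cs, k, fs, 1), kernel, config.n_cycles
            )
            for k in range(1, n_targets + 1)
        ]
    )
    evoked_power = float(np.mean(responses**2)) / config.n_channels
    noise_std = effect.noise_gain * np.sqrt(evoked_power / subject.snr_scale)
    shift_session = int(round(effect.latency_shift * fs))

    data = np.empty((blocks, n_targets, config.n_channels, n_samples))
    for b in range(blocks):
        for t in range(n_targets):
            jitter = (
                rng.normal(0.0, subject.latency_jitter_sd)
                if subject.latency_jitter_sd > 0
                else 0.0
            )
            shift = shift_session + int(round(jitter * fs))
            resp = np.roll(responses[t], shift)
            trial = effect.amplitude_gain * np.outer(subject.mixing_vector, resp)
            if noise_std > 0:
                trial = trial + noise_std * _trial_noise(
                    rng, config.n_channels, n_samples, config
                )
            data[b, t] = trial

    ids = block_ids or tuple(range(1, blocks + 1))
    if len(ids) != blocks:
        raise ValueError("block_ids length must equal blocks")
    return TrialTensor(
        data=data,
        sampling_rate=fs,
        block_ids=tuple(ids),
        subject_id=subject.subject_id,
        session_id=session_id,
    )


def simulate_study(
    n_subjects: int,
    cs: CodeSet,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> Study:
    """Simulate a full two-session study.

    Session 1 carries block ids 1..B, session 2 ids B+1..2B (B = blocks
    per session, 6 by default).  Each session draws an independent
    :class:`SessionEffect`.  Fully reproducible from (seed, config).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or SimulationConfig()
    b = config.blocks_per_session
    tensors: dict[tuple[int, int], TrialTensor] = {}
    for subj in range(1, n_subjects + 1):
        subject = sample_subject(np.random.SeedSequence([seed, subj, 0]), config)
        subject = replace(subject, subject_id=subj)
        for session in (1, 2):
            effect = sample_session_effect(
                np.random.SeedSequence([seed, subj, session]), config
            )
            ids = tuple(range(1, b + 1)) if session == 1 else tuple(
                range(b + 1, 2 * b + 1)
            )
            tensors[(subj, session)] = simulate_session(
                subject,
                effect,
                cs,
                blocks=b,
                seed=np.random.SeedSequence([seed, subj, session, 1]),
                config=config,
                session_id=session,
                block_ids=ids,
            )
    return Study(tensors=tensors, code_set=cs, config=config, seed=seed)
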