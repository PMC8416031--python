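"""Synthetic polysomnography nights with stage-dependent spectra and Markov dynamics.

Stage sequences follow a first-order Markov chain over W/N1/N2/N3/REM that
starts in Wake, has self-transition probability 0.9 in every stage, puts
about 5% of its stationary mass on N1 (deliberately rare, to exercise the
class-balance strategy) and forbids the physiologically unlikely direct
W -> N3 transition outright - a hard zero whose learned CRF transition score
should rank lowest among Wake's outgoing transitions.

Signals are sums of stage- and channel-specific oscillators with random
phase, Gaussian background noise, and scheduled bursts (sleep-spindle-like
12-14 Hz packets in N2, slow eye movements on EOG channels in REM), in
microvolts. N1 is spectrally intermediate between Wake and N2 so that it is
genuinely confusable, as it is in real recordings. Per-subject amplitude
jitter (+-10%) makes subject-independent cross-validation meaningful, and a
per-channel-epoch amplitude jitter (+-35%) makes amplitude statistics of
neighbouring stages overlap, so staging is learnable but not trivial.

The default montage is the AASM minimal one (one EEG, chin EMG, one EOG:
C4, EMG, LEOG); all six supported channels C4, EMG, LEOG, REOG, F4, O2 are
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np

from .io import Channel, Hypnogram, Recording, infer_modality
from .stages import N_STAGES, STAGES

__all__ = [
    "Oscillator",
    "Burst",
    "StageChannelProfile",
    "TransitionalProfile",
    "resolve_profile",
    "SynthConfig",
    "SynthNight",
    "DEFAULT_TRANSITIONS",
    "DEFAULT_CHANNELS",
    "default_profiles",
    "stationary_distribution",
    "sample_stage_sequence",
    "synthesize_epoch",
    "generate_night",
    "generate_dataset",
]

# Rows/columns ordered W, N1, N2, N3, REM. Every self-transition is 0.9, the
# W -> N3 entry is exactly 0, and the stationary mass of N1 is ~= 0.05.
DEFAULT_TRANSITIONS = np.array(
    [
        [0.900, 0.020, 0.060, 0.000, 0.020],
        [0.020, 0.900, 0.070, 0.000, 0.010],
        [0.012, 0.004, 0.900, 0.060, 0.024],
        [0.005, 0.000, 0.095, 0.900, 0.000],
        [0.046, 0.004, 0.050, 0.000, 0.900],
    ]
)

DEFAULT_CHANNELS = ("C4", "EMG", "LEOG")
ALL_CHANNELS = ("C4", "EMG", "LEOG", "REOG", "F4", "O2")


@dataclass(frozen=True)
class Oscillator:
    freq: float  # Hz
    amp: float  # microvolts


@dataclass(frozen=True)
class Burst:
    """A short enveloped oscillation placed at random offsets within an epoch.

    ``n_per_epoch`` is the Poisson mean of the burst count, so an epoch can
    lack bursts entirely (as real N2 epochs can lack visible spindles).
    """

    freq: float  # Hz
    amp: float  # microvolts
    duration: float  # seconds
    n_per_epoch: float


@dataclass(frozen=True)
class TransitionalProfile:
    """A stage whose epochs are random mixtures of two anchor stages.

    Each epoch draws lambda ~ U(lo, hi) and uses the lambda-interpolation of
    the two anchors' oscillator amplitudes and noise level (anchor bursts are
    dropped). Models transitional stages like N1, whose epochs range from
    Wake-like to N2-like.
    """

    between: tuple[str, str]
    lo: float = 0.15
    hi: float = 0.85


def resolve_profile(
    channel_profiles: dict, stage_name: str, lam: float | None
) -> StageChannelProfile:
    """Materialize a possibly-transitional profile for one epoch."""
    p = channel_profiles[stage_name]
    if not isinstance(p, TransitionalProfile):
        return p
    if lam is None:
        raise ValueError("transitional profile needs a mixing coefficient")
    a = channel_profiles[p.between[0]]
    b = channel_profiles[p.between[1]]
    oscillators = tuple(
        Oscillator(o.freq, (1.0 - lam) * o.amp) for o in a.oscillators
    ) + tuple(Oscillator(o.freq, lam * o.amp) for o in b.oscillators)
    noise = (1.0 - lam) * a.noise_std + lam * b.noise_std
    return StageChannelProfile(oscillators=oscillators, noise_std=noise, bursts=())


@dataclass(frozen=True)
class StageChannelProfile:
    oscillators: tuple[Oscillator, ...] = ()
    noise_std: float = 5.0  # microvolts
    bursts: tuple[Burst, ...] = ()

    def __post_init__(self) -> None:
        if self.noise_std < 0 or any(o.amp < 0 for o in self.oscillators):
            raise ValueError("amplitudes and noise std must be non-negative")


def _eeg_profiles(alpha_amp: float = 20.0) -> dict[str, StageChannelProfile]:
    return {
        "W": StageChannelProfile(
            oscillators=(Oscillator(10.0, alpha_amp), Oscillator(20.0, 5.0)),
            noise_std=10.0,
        ),
        # N1 is transitional: each epoch a random W/N2 mixture
        "N1": TransitionalProfile(between=("W", "N2")),
        "N2": StageChannelProfile(
            oscillators=(Oscillator(5.0, 14.0), Oscillator(2.0, 10.0)),
            noise_std=8.0,
            bursts=(Burst(13.0, 22.0, 1.0, 2.0),),  # sleep spindles (Poisson mean)
        ),
        "N3": StageChannelProfile(
            oscillators=(Oscillator(1.5, 60.0), Oscillator(5.0, 8.0)),
            noise_std=8.0,
        ),
        "REM": StageChannelProfile(
            oscillators=(Oscillator(6.0, 10.0), Oscillator(22.0, 4.0)),
            noise_std=9.0,
        ),
    }


def _emg_profiles() -> dict[str, StageChannelProfile]:
    # Chin tone decreases with depth; REM atonia is the hallmark. Adjacent
    # levels overlap once per-epoch jitter is applied.
    return {
        "W": StageChannelProfile(noise_std=20.0),
        "N1": TransitionalProfile(between=("W", "N2")),
        "N2": StageChannelProfile(noise_std=9.0),
        "N3": StageChannelProfile(noise_std=6.0),
        "REM": StageChannelProfile(noise_std=2.5),
    }


def _eog_profiles() -> dict[str, StageChannelProfile]:
    return {
        "W": StageChannelProfile(
            oscillators=(Oscillator(10.0, 8.0),), noise_std=10.0
        ),
        "N1": TransitionalProfile(between=("W", "N2")),
        "N2": StageChannelProfile(
            oscillators=(Oscillator(1.5, 10.0),), noise_std=8.0
        ),
        "N3": StageChannelProfile(
            oscillators=(Oscillator(1.5, 30.0),), noise_std=8.0  # delta crosstalk
        ),
        "REM": StageChannelProfile(
            oscillators=(Oscillator(0.5, 18.0),),
            noise_std=8.0,
            bursts=(Burst(0.8, 30.0, 2.0, 2.0),),  # slow eye movements
        ),
    }


def default_profiles() -> dict[str, dict[str, StageChannelProfile]]:
    """Stage -> channel -> profile for the six supported channels."""
    eeg_c4 = _eeg_profiles(alpha_amp=20.0)
    eeg_f4 = _eeg_profiles(alpha_amp=18.0)
    eeg_o2 = _eeg_profiles(alpha_amp=26.0)  # alpha is occipitally dominant
    emg = _emg_profiles()
    eog = _eog_profiles()
    by_channel = {
        "C4": eeg_c4,
        "F4": eeg_f4,
        "O2": eeg_o2,
        "EMG": emg,
        "LEOG": eog,
        "REOG": eog,
    }
    return {
        stage: {ch: by_channel[ch][stage] for ch in ALL_CHANNELS} for stage in STAGES
    }


@dataclass
class SynthConfig:
    """Study conditions for synthetic nights."""

    rate: float = 100.0  # Hz (100 or 250)
    n_epochs: int = 1140  # one standardized 9.5-h night
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    transitions: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    profiles: dict = field(default_factory=default_profiles)
    subject_jitter: float = 0.1  # +-10% per-subject amplitude scale
    epoch_jitter: float = 0.35  # +-35% per-channel-epoch amplitude scale

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.transitions.shape != (N_STAGES, N_STAGES):
            raise ValueError("transition matrix must be 5x5")
        if np.any(self.transitions < 0) or np.any(
            np.abs(self.transitions.sum(axis=1) - 1.0) > 1e-12
        ):
            raise ValueError("transition rows must be non-negative and sum to 1")
        unknown = set(self.channels) - set(ALL_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}; supported: {ALL_CHANNELS}")


@dataclass
class SynthNight:
    recording: Recording
    hypnogram: Hypnogram
    config: SynthConfig


def stationary_distribution(transitions: np.ndarray) -> np.ndarray:
    """Left eigenvector of the chain for eigenvalue 1, normalized to sum 1."""
    ev, V = np.linalg.eig(np.asarray(transitions, dtype=float).T)
    v = np.real(V[:, np.argmin(np.abs(ev - 1.0))])
    v = np.abs(v)
    return v / v.sum()


def sample_stage_sequence(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Markov chain of length n_epochs, started in Wake."""
    P = cfg.transitions
    seq = np.empty(cfg.n_epochs, dtype=np.int64)
    state = 0  # W
    for t in range(cfg.n_epochs):
        seq[t] = state
        state = int(rng.choice(N_STAGES, p=P[state]))
    return seq


def synthesize_epoch(
    stage: int,
    profile: StageChannelProfile,
    rate: float,
    rng: np.random.Generator,
    amp_scale: float = 1.0,
) -> np.ndarray:
    """One 30-s channel-epoch: oscillators (random phase) + noise + bursts."""
    n = int(30 * rate)
    t = np.arange(n) / rate
    x = rng.normal(0.0, profile.noise_std * amp_scale, n)
    for osc in profile.oscillators:
        phase = rng.uniform(0, 2 * np.pi)
        x += amp_scale * osc.amp * np.sin(2 * np.pi * osc.freq * t + phase)
    for burst in profile.bursts:
        dur = int(burst.duration * rate)
        if dur < 2 or dur > n:
            continue
        env = np.hanning(dur)
        tb = np.arange(dur) / rate
        for _ in range(int(rng.poisson(burst.n_per_epoch))):
            start = int(rng.integers(0, n - dur + 1))
            phase = rng.uniform(0, 2 * np.pi)
            x[start : start + dur] += (
                amp_scale * burst.amp * env * np.sin(2 * np.pi * burst.freq * tb + phase)
            )
    return x


def generate_night(
    cfg: SynthConfig,
    rng: np.random.Generator,
    subject_id: str = "S00",
    night_id: str = "N00",
    amp_scale: float = 1.0,
) -> SynthNight:
    stages = sample_stage_sequence(cfg, rng)
    n = int(30 * cfg.rate)
    start_time = datetime(2000, 1, 1, 23, 0)
    buffers = {ch: np.empty(stages.size * n) for ch in cfg.channels}
    channel_profiles = {
        ch: {stage: cfg.profiles[stage][ch] for stage in STAGES} for ch in cfg.channels
    }
    mix_bounds = {
        ch: p[STAGES[1]]
        for ch, p in channel_profiles.items()
        if isinstance(p[STAGES[1]], TransitionalProfile)
    }
    for t, stage in enumerate(stages):
        # depth of the transitional stage is a property of the epoch, shared
        # across channels
        lam = None
        if any(
            isinstance(channel_profiles[ch][STAGES[stage]], TransitionalProfile)
            for ch in cfg.channels
        ):
            bounds = next(iter(mix_bounds.values()), TransitionalProfile(("W", "N2")))
            lam = float(rng.uniform(bounds.lo, bounds.hi))
        for ch in cfg.channels:
            profile = resolve_profile(channel_profiles[ch], STAGES[stage], lam)
            # arousal level fluctuates epoch to epoch: amplitude statistics
            # of neighbouring stages overlap, as in real PSG
            scale = amp_scale * (
                1.0 + rng.uniform(-cfg.epoch_jitter, cfg.epoch_jitter)
            )
            buffers[ch][t * n : (t + 1) * n] = synthesize_epoch(
                stage, profile, cfg.rate, rng, scale
            )
    channels = [
        Channel(label=ch, samples=buffers[ch], rate=cfg.rate, modality=infer_modality(ch))
        for ch in cfg.channels
    ]
    rec = Recording(
        channels=channels, start_time=start_time, subject_id=subject_id, night_id=night_id
    )
    hyp = Hypnogram(stages=stages, start_time=start_time)
    return SynthNight(recording=rec, hypnogram=hyp, config=cfg)


def generate_dataset(
    cfg: SynthConfig,
    n_subjects: int,
    nights_per_subject: int = 1,
    seed=None,
) -> list[SynthNight]:
    """Synthetic corpus with per-subject amplitude jitter (deterministic per seed)."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    nights = []
    for s in range(n_subjects):
        scale = 1.0 + rng.uniform(-cfg.subject_jitter, cfg.subject_jitter)
        for k in range(nights_per_subject):
            nights.append(
                generate_night(
                    cfg,
                    rng,
                    subject_id=f"S{s:02d}",
                    night_id=f"S{s:02d}n{k}",
                    amp_scale=scale,
                )
            )
    return nights
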