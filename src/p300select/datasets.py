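"""Synthetic auditory-oddball EEG epoch datasets.

Emulates a virtual-sound direction-discrimination protocol: six stimulus
directions, each recorded in two sessions of 150 trials, with the session's
target direction presented on a fixed 20% of trials. Target trials carry a
P300-like positive deflection (a Gaussian bump peaking ~350 ms after
stimulus onset) on a configurable subset of informative channels, embedded
in independent per-channel 1/f-colored Gaussian noise. Epochs span
[-100, 1000) ms around stimulus onset.

Everything is generated directly as epoched data (no continuous recording
is synthesized), deterministically from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .montage import default_channel_names

__all__ = [
    "ProtocolSpec",
    "ErpSpec",
    "EpochDataset",
    "p300_template",
    "generate_session",
    "generate_dataset",
    "session_seeds",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Oddball stimulation protocol and acquisition geometry.

    Defaults reproduce the study design: 6 virtual-sound directions x 2
    sessions x 150 trials = 1800 trials, 20% targets per session, epochs
    of [-100, 1000) ms sampled at 250 Hz on a 64-channel montage.
    """

    n_directions: int = 6
    sessions_per_direction: int = 2
    trials_per_session: int = 150
    target_fraction: float = 0.20
    stimulus_ms: float = 300.0
    silence_ms: float = 800.0
    epoch_start_ms: float = -100.0
    epoch_end_ms: float = 1000.0
    fs: float = 250.0
    n_channels: int = 64

    def __post_init__(self) -> None:
        if self.n_directions < 1 or self.sessions_per_direction < 1:
            raise ValueError("protocol needs at least one direction and session")
        if not 0.0 < self.target_fraction < 1.0:
            raise ValueError("target_fraction must be in (0, 1)")
        n_targets = self.target_fraction * self.trials_per_session
        if abs(n_targets - round(n_targets)) > 1e-9:
            raise ValueError(
                "trials_per_session * target_fraction must be an integer "
                f"(got {n_targets})"
            )
        if self.epoch_end_ms <= self.epoch_start_ms:
            raise ValueError("epoch window is empty")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")

    @property
    def n_targets_per_session(self) -> int:
        return round(self.target_fraction * self.trials_per_session)

    @property
    def n_samples(self) -> int:
        """Samples per epoch over the half-open window [start, end)."""
        span_s = (self.epoch_end_ms - self.epoch_start_ms) / 1000.0
        return round(span_s * self.fs)

    @property
    def n_sessions(self) -> int:
        return self.n_directions * self.sessions_per_direction

    @property
    def n_trials_total(self) -> int:
        return self.n_sessions * self.trials_per_session

    def times_ms(self) -> np.ndarray:
        return self.epoch_start_ms + np.arange(self.n_samples) * 1000.0 / self.fs


@dataclass(frozen=True)
class ErpSpec:
    """Shape and noise model of the simulated event-related response.

    ``informative_channels`` are 0-based channel indices that receive the
    P300 bump on target trials; all other channels carry noise only. Noise
    is per-channel independent Gaussian, spectrally shaped to
    1/f**noise_color_exponent and scaled so each sample has standard
    deviation ``noise_sd`` (microvolts).
    """

    informative_channels: tuple[int, ...] = (30, 46, 10, 45)  # Pz, FCz, FC1, FC2
    p300_peak_ms: float = 350.0
    p300_width_ms: float = 120.0
    amplitude: float = 5.0
    latency_jitter_sd_ms: float = 0.0
    noise_sd: float = 10.0
    noise_color_exponent: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "informative_channels", tuple(int(c) for c in self.informative_channels)
        )
        if self.p300_width_ms <= 0:
            raise ValueError("p300_width_ms must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(c < 0 for c in self.informative_channels):
            raise ValueError("channel indices are 0-based and nonnegative")


@dataclass
class EpochDataset:
    """Epoched multi-channel EEG trials with per-trial metadata.

    ``data`` has shape (n_trials, n_channels, n_samples) in microvolts.
    ``labels`` are +1 (target) / -1 (nontarget); ``direction`` is the
    session's target direction (1-based); ``session`` is 1 or 2.
    ``trial_ids`` track provenance through subsetting, so disjointness of
    derived train/test splits is checkable.
    """

    data: np.ndarray
    labels: np.ndarray
    direction: np.ndarray
    session: np.ndarray
    fs: float
    t0_ms: float
    channel_names: tuple[str, ...]
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.direction = np.asarray(self.direction, dtype=np.int64)
        self.session = np.asarray(self.session, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        n = self.data.shape[0]
        for name, arr in (("labels", self.labels), ("direction", self.direction),
                          ("session", self.session)):
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != trial count {n}")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1/-1")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length mismatch")
        self.channel_names = tuple(self.channel_names)
        if self.trial_ids is None:
            self.trial_ids = np.arange(n, dtype=np.int64)
        else:
            self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
            if self.trial_ids.shape != (n,):
                raise ValueError("trial_ids length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def select(self, indices: np.ndarray) -> "EpochDataset":
        """Subset of trials, preserving original trial_ids."""
        idx = np.asarray(indices)
        return EpochDataset(
            data=self.data[idx],
            labels=self.labels[idx],
            direction=self.direction[idx],
            session=self.session[idx],
            fs=self.fs,
            t0_ms=self.t0_ms,
            channel_names=self.channel_names,
            trial_ids=self.trial_ids[idx],
        )

    def with_data(self, data: np.ndarray) -> "EpochDataset":
        """Same trials/metadata with replaced signal tensor."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("epochs", data=self.data)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("direction", data=self.direction)
            f.create_dataset("session", data=self.session)
            f.create_dataset("trial_ids", data=self.trial_ids)
            f.attrs["fs"] = self.fs
            f.attrs["t0_ms"] = self.t0_ms
            f.attrs["channel_names"] = list(self.channel_names)

    @classmethod
    def load(cls, path) -> "EpochDataset":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["epochs"][()],
                labels=f["labels"][()],
                direction=f["direction"][()],
                session=f["session"][()],
                fs=float(f.attrs["fs"]),
                t0_ms=float(f.attrs["t0_ms"]),
                channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
                trial_ids=f["trial_ids"][()] if "trial_ids" in f else None,
            )


def concat(datasets: list[EpochDataset]) -> EpochDataset:
    """Concatenate trial-wise; trial_ids are renumbered consecutively."""
    first = datasets[0]
    for d in datasets[1:]:
        if d.fs != first.fs or d.t0_ms != first.t0_ms \
                or d.channel_names != first.channel_names:
            raise ValueError("incompatible datasets")
    return EpochDataset(
        data=np.concatenate([d.data for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        direction=np.concatenate([d.direction for d in datasets]),
        session=np.concatenate([d.session for d in datasets]),
        fs=first.fs,
        t0_ms=first.t0_ms,
        channel_names=first.channel_names,
        trial_ids=None,
    )


def p300_template(
    times_ms: np.ndarray,
    peak_ms: float = 350.0,
    width_ms: float = 120.0,
    amplitude: float = 5.0,
) -> np.ndarray:
    """Unimodal positive deflection modelling the P300 on a time grid.

    A Gaussian bump ``amplitude * exp(-(t - peak)^2 / (2 width^2))``,
    rescaled so its maximum over the given grid equals ``amplitude``
    exactly (the grid rarely contains the continuous peak). Effectively
    zero beyond peak +- 3 widths.
    """
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    t = np.asarray(times_ms, dtype=np.float64)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times_ms must be strictly increasing")
    bump = np.exp(-0.5 * ((t - peak_ms) / width_ms) ** 2)
    peak = bump.max()
    if peak > 0 and amplitude > 0:
        bump = bump * (amplitude / peak)
    else:
        bump = np.zeros_like(bump)
    return bump


def _colored_noise(
    rng: np.random.Generator, shape: tuple[int, ...], exponent: float, fs: float
) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f**exponent power spectrum.

    White noise is shaped along the last axis in the frequency domain
    (circular filtering); gains are normalized analytically so the
    per-sample variance is exactly 1 in expectation. The DC gain is zero,
    so the noise is zero-mean over each epoch.
    """
    white = rng.standard_normal(shape)
    if exponent == 0:
        return white
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    # full-spectrum bin multiplicity: DC and (even-n) Nyquist appear once
    weight = np.full_like(gain, 2.0)
    weight[0] = 1.0
    if n % 2 == 0:
        weight[-1] = 1.0
    var_factor = float(np.sum(weight * gain**2) / n)
    gain /= np.sqrt(var_factor)
    spectrum = np.fft.rfft(white, axis=-1) * gain
    return np.fft.irfft(spectrum, n=n, axis=-1)


def generate_session(
    protocol: ProtocolSpec,
    erp: ErpSpec,
    target_direction: int,
    session_id: int,
    seed: int,
) -> EpochDataset:
    """One recording session: a fixed target direction, exact target count.

    Exactly ``round(target_fraction * trials_per_session)`` trials are
    targets, at seed-shuffled positions. The ERP template is added only on
    target trials and only on ``erp.informative_channels``; every
    trial/channel gets independent noise. Identical (specs, seed) give
    bit-identical output.
    """
    if not 1 <= target_direction <= protocol.n_directions:
        raise ValueError("target_direction out of range")
    if session_id < 1:
        raise ValueError("session_id is 1-based")
    for c in erp.informative_channels:
        if c >= protocol.n_channels:
            raise ValueError(
                f"informative channel {c} >= n_channels {protocol.n_channels}"
            )

    rng = np.random.default_rng(seed)
    n_trials = protocol.trials_per_session
    n_targets = protocol.n_targets_per_session
    labels = np.full(n_trials, -1, dtype=np.int64)
    labels[rng.permutation(n_trials)[:n_targets]] = 1

    times = protocol.times_ms()
    jitters = (
        rng.normal(0.0, erp.latency_jitter_sd_ms, size=n_targets)
        if erp.latency_jitter_sd_ms > 0
        else np.zeros(n_targets)
    )

    noise = erp.noise_sd * _colored_noise(
        rng,
        (n_trials, protocol.n_channels, protocol.n_samples),
        erp.noise_color_exponent,
        protocol.fs,
    )

    data = noise
    if erp.amplitude > 0 and erp.informative_channels:
        chans = list(erp.informative_channels)
        for k, trial in enumerate(np.flatnonzero(labels == 1)):
            bump = p300_template(
                times, erp.p300_peak_ms + jitters[k], erp.p300_width_ms, erp.amplitude
            )
            data[trial, chans, :] += bump

    return EpochDataset(
        data=data,
        labels=labels,
        direction=np.full(n_trials, target_direction, dtype=np.int64),
        session=np.full(n_trials, session_id, dtype=np.int64),
        fs=protocol.fs,
        t0_ms=protocol.epoch_start_ms,
        channel_names=default_channel_names(protocol.n_channels),
    )


def session_seeds(seed: int, n_sessions: int) -> list[int]:
    """Deterministic per-session sub-seeds derived from a master seed."""
    state = np.random.SeedSequence(seed).generate_state(n_sessions)
    return [int(s) for s in state]


def generate_dataset(protocol: ProtocolSpec, erp: ErpSpec, seed: int) -> EpochDataset:
    """Full multi-session dataset: every direction measured in every session.

    Sessions are generated independently with sub-seeds derived from
    ``seed`` and concatenated in (session, direction) order; with defaults
    this yields 6 x 2 = 12 sessions and 1800 trials.
    """
    seeds = session_seeds(seed, protocol.n_sessions)
    sessions = []
    k = 0
    for sess in range(1, protocol.sessions_per_direction + 1):
        for direction in range(1, protocol.n_directions + 1):
            sessions.append(
                generate_session(protocol, erp, direction, sess, seeds[k])
            )
            k += 1
    return concat(sessions)
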