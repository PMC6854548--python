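"""Synthetic MEG epochs and behavioural tables with known ground truth.

The generator emulates a whole-head magnetometer recording of a primed
semantic-decision task: epochs time-locked to the second word of a pair,
with three related conditions (taxonomic, strong thematic, weak
thematic) plus an unrelated condition.  Condition effects are injected
as oscillatory current dipoles with a Hann amplitude envelope; the
phase-locked fraction of each effect has constant phase across trials
(the "evoked" part) while the remainder gets an independent uniform
random phase per trial (the "induced" part).  Background activity comes
from many random interior dipoles with 1/f-shaped time courses, which
gives the sensor covariance the full-rank structure adaptive beamformers
require; white sensor noise is added on top.

Catch trials (the ~10% of trials that require an overt response) are
modelled only behaviourally, as per-participant reaction-time and
accuracy tables; the epochs carry an ``is_catch`` flag so loaders can
drop them from the MEG analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import (SensorArray, SphericalHeadModel, build_sensor_array,
                      dipole_field)

DEFAULT_CONDITIONS = ("taxonomic", "thematic_strong", "thematic_weak",
                      "unrelated")


@dataclass
class SimulationConfig:
    """Study-level parameters of the synthetic recording.

    Defaults mirror the recording they emulate: 248 magnetometers
    sampled at 678.17 Hz, 1500 ms epochs from -800 ms to +700 ms around
    second-word onset, 95 trials per related condition.  ``trial_scale``
    multiplies all trial counts for scaled-down runs.
    """

    sampling_rate: float = 678.17               # Hz
    epoch_window_ms: tuple[float, float] = (-800.0, 700.0)
    n_trials_per_condition: int = 95
    trial_scale: float = 1.0
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_participants: int = 20
    n_channels: int = 248
    helmet_radius: float = 0.12                 # m
    coverage_angle: float = 125.0               # deg
    head_radius: float = 0.09                   # m
    sensor_noise_sd: float = 2e-13              # T, white per sample
    n_noise_dipoles: int = 200
    noise_dipole_amp: float = 1e-8              # A·m RMS per dipole
    catch_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        if self.n_trials_scaled < 1:
            raise ValueError("n_trials per condition must be >= 1 after scaling")
        if self.n_samples < 2:
            raise ValueError("epoch must span at least 2 samples")

    @property
    def n_trials_scaled(self) -> int:
        return max(1, int(round(self.n_trials_per_condition * self.trial_scale)))

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window_ms
        return int(round((t1 - t0) / 1000.0 * self.sampling_rate))

    @property
    def times_ms(self) -> np.ndarray:
        t0 = self.epoch_window_ms[0]
        return t0 + np.arange(self.n_samples) * 1000.0 / self.sampling_rate

    def default_head(self) -> SphericalHeadModel:
        return SphericalHeadModel(center=np.zeros(3), radius=self.head_radius)

    def default_sensors(self) -> SensorArray:
        return build_sensor_array(self.n_channels, self.helmet_radius,
                                  self.coverage_angle, seed=self.seed)


@dataclass
class DipoleEffectSpec:
    """Ground-truth oscillatory source with condition-dependent amplitude.

    ``amplitude`` maps condition label -> dipole moment (A·m); absent
    conditions get zero.  ``phase_locked_fraction`` is the share of the
    amplitude whose carrier phase is identical on every trial.
    """

    location: np.ndarray                        # (3,) m head frame
    frequency_hz: float
    window_ms: tuple[float, float]
    amplitude: dict[str, float]
    phase_locked_fraction: float = 1.0
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.orientation = self.orientation / np.linalg.norm(self.orientation)
        if not 0.0 <= self.phase_locked_fraction <= 1.0:
            raise ValueError("phase_locked_fraction must be in [0, 1]")
        if any(a < 0 for a in self.amplitude.values()):
            raise ValueError("amplitudes must be >= 0")


@dataclass
class EpochsSet:
    """Epoched multichannel data for one participant."""

    data: np.ndarray            # (n_trials, n_channels, n_samples), tesla
    times_ms: np.ndarray        # (n_samples,)
    labels: np.ndarray          # (n_trials,) condition strings
    participant_id: str
    sensors: SensorArray
    sampling_rate: float
    is_catch: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("time axis length mismatch")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in epoch data")
        if self.is_catch is None:
            self.is_catch = np.zeros(self.data.shape[0], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "EpochsSet":
        return EpochsSet(data=self.data[mask], times_ms=self.times_ms,
                         labels=self.labels[mask],
                         participant_id=self.participant_id,
                         sensors=self.sensors,
                         sampling_rate=self.sampling_rate,
                         is_catch=self.is_catch[mask])

    def condition(self, label: str) -> "EpochsSet":
        return self.select(self.labels == label)


def _hann_envelope(times_ms: np.ndarray, window_ms: tuple[float, float]
                   ) -> np.ndarray:
    t0, t1 = window_ms
    env = np.zeros_like(times_ms)
    inside = (times_ms >= t0) & (times_ms <= t1)
    phase = (times_ms[inside] - t0) / (t1 - t0)
    env[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return env


def _one_over_f_noise(rng: np.random.Generator, n_series: int, n_samples: int
                      ) -> np.ndarray:
    """Unit-RMS rows with an approximately 1/f amplitude spectrum."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero] / freqs[nonzero][0])
    series = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(series ** 2, axis=1, keepdims=True))
    return series / rms


def _random_interior_dipoles(rng: np.random.Generator, head: SphericalHeadModel,
                             n: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform interior locations (avoiding centre/surface) with tangential moments."""
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = head.radius * 0.9 * rng.uniform(0.2, 1.0, size=n) ** (1 / 3)
    locs = head.center + u * radii[:, None]
    raw = rng.standard_normal((n, 3))
    radial = locs - head.center
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    tang = raw - np.sum(raw * radial, axis=1, keepdims=True) * radial
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return locs, tang


def simulate_epochs(config: SimulationConfig,
                    effects: list[DipoleEffectSpec],
                    head: SphericalHeadModel | None = None,
                    sensors: SensorArray | None = None,
                    ) -> tuple[list[EpochsSet], dict]:
    """Generate one :class:`EpochsSet` per participant, plus ground truth.

    Each trial is the sum of the forward-projected effect dipoles, the
    background dipole noise and white sensor noise.  Reproducible: the
    participant streams are spawned deterministically from ``config.seed``.
    """
    head = head or config.default_head()
    sensors = sensors or config.default_sensors()
    times = config.times_ms
    t_s = times / 1000.0
    nyquist = config.sampling_rate / 2.0

    for eff in effects:
        if eff.frequency_hz >= nyquist or eff.frequency_hz < 1.0:
            raise ValueError(
                f"effect frequency {eff.frequency_hz} Hz outside "
                f"[1, {nyquist:.1f}) Hz")
        t0, t1 = eff.window_ms
        w0, w1 = config.epoch_window_ms
        if t0 < w0 or t1 > w1:
            raise ValueError(f"effect window {eff.window_ms} outside epoch")

    # forward-project each effect dipole once
    effect_topos = [dipole_field(head, eff.location,
                                 eff.orientation, sensors)
                    for eff in effects]
    envelopes = [_hann_envelope(times, eff.window_ms) for eff in effects]

    root = np.random.default_rng(config.seed)
    part_seeds = root.integers(0, 2 ** 31 - 1, size=config.n_participants)

    n_trials = config.n_trials_scaled
    participants: list[EpochsSet] = []
    truth: dict = {"effects": effects, "participants": []}

    for p in range(config.n_participants):
        rng = np.random.default_rng(part_seeds[p])
        labels = np.repeat(config.conditions, n_trials)
        total = len(labels)
        data = np.zeros((total, sensors.n_channels, config.n_samples))

        # fixed evoked phase per effect (shared across trials and participants)
        for eff, topo, env in zip(effects, effect_topos, envelopes):
            plf = eff.phase_locked_fraction
            omega = 2.0 * np.pi * eff.frequency_hz
            evoked = env * np.cos(omega * t_s)
            for c_i, cond in enumerate(config.conditions):
                amp = eff.amplitude.get(cond, 0.0)
                if amp == 0.0:
                    continue
                sl = slice(c_i * n_trials, (c_i + 1) * n_trials)
                if plf > 0:
                    data[sl] += amp * plf * topo[:, None] * evoked[None, :]
                if plf < 1:
                    phases = rng.uniform(0, 2 * np.pi, size=n_trials)
                    induced = env[None, :] * np.cos(omega * t_s[None, :]
                                                    + phases[:, None])
                    data[sl] += (amp * (1 - plf)
                                 * topo[None, :, None] * induced[:, None, :])

        # background brain noise: fixed dipole positions per participant,
        # fresh 1/f time courses per trial
        noise_locs = noise_moms = None
        if config.n_noise_dipoles > 0 and config.noise_dipole_amp > 0:
            noise_locs, noise_moms = _random_interior_dipoles(
                rng, head, config.n_noise_dipoles)
            noise_topos = np.stack(
                [dipole_field(head, loc, mom, sensors)
                 for loc, mom in zip(noise_locs, noise_moms)])  # (d, ch)
            for tr in range(total):
                courses = _one_over_f_noise(rng, config.n_noise_dipoles,
                                            config.n_samples)
                data[tr] += config.noise_dipole_amp * (noise_topos.T @ courses)

        if config.sensor_noise_sd > 0:
            data += rng.normal(0.0, config.sensor_noise_sd, size=data.shape)

        n_catch = int(round(config.catch_fraction * total))
        is_catch = np.zeros(total, dtype=bool)
        if n_catch:
            is_catch[rng.choice(total, size=n_catch, replace=False)] = True

        pid = f"sub-{p + 1:02d}"
        participants.append(EpochsSet(data=data, times_ms=times,
                                      labels=labels, participant_id=pid,
                                      sensors=sensors,
                                      sampling_rate=config.sampling_rate,
                                      is_catch=is_catch))
        truth["participants"].append({
            "participant_id": pid, "seed": int(part_seeds[p]),
            "noise_dipole_locations": noise_locs,
        })
    return participants, truth


def reject_epochs(epochs: EpochsSet, amplitude_threshold: float
                  ) -> tuple[EpochsSet, dict]:
    """Drop trials whose peak |amplitude| on any channel exceeds the threshold.

    Automatic stand-in for visual artefact screening; returns the kept
    epochs and a report with the rejection fraction.
    """
    if not amplitude_threshold > 0:
        raise ValueError("amplitude_threshold must be > 0")
    peaks = np.max(np.abs(epochs.data), axis=(1, 2))
    keep = peaks <= amplitude_threshold
    report = {
        "participant_id": epochs.participant_id,
        "n_total": int(epochs.n_trials),
        "n_rejected": int(np.sum(~keep)),
        "rejection_fraction": float(np.mean(~keep)),
        "all_rejected": bool(not np.any(keep)),
    }
    return epochs.select(keep), report


def simulate_behaviour(n_participants: int,
                       condition_means: dict[str, tuple[float, float]],
                       sd_between: tuple[float, float] = (30.0, 0.03),
                       sd_within: tuple[float, float] = (20.0, 0.02),
                       n_catch: int = 29,
                       seed: int = 0,
                       poor_performer_indices: tuple[int, ...] = (),
                       poor_accuracy: float = 0.5) -> pd.DataFrame:
    """Catch-trial behavioural table: RT (ms) and accuracy per condition.

    ``condition_means`` maps condition -> (mean RT ms, mean accuracy).
    Each participant gets an additive offset drawn with SD ``sd_between``
    (shared across conditions) plus independent per-cell noise with SD
    ``sd_within``; accuracies are clipped to [0, 1].
    ``poor_performer_indices`` marks participants who perform near chance
    (accuracy centred on ``poor_accuracy`` in every condition), emulating
    the below-criterion participant the exclusion rule is meant to catch.
    """
    for cond, (rt, acc) in condition_means.items():
        if not 0.0 <= acc <= 1.0:
            raise ValueError(f"accuracy for {cond} must be in [0, 1]")
        if rt <= 0:
            raise ValueError(f"RT for {cond} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        off_rt = rng.normal(0.0, sd_between[0])
        off_acc = rng.normal(0.0, sd_between[1])
        poor = p in poor_performer_indices
        for cond, (rt, acc) in condition_means.items():
            mean_acc = poor_accuracy if poor else acc + off_acc
            rows.append({
                "participant": f"sub-{p + 1:02d}",
                "condition": cond,
                "rt_ms": max(1.0, rt + off_rt + rng.normal(0, sd_within[0])),
                "accuracy": float(np.clip(
                    mean_acc + rng.normal(0, sd_within[1]), 0.0, 1.0)),
                "n_catch": n_catch,
            })
    return pd.DataFrame(rows)
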