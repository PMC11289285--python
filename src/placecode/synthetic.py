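"""Ground-truth simulator for head-fixed treadmill calcium-imaging sessions.

The generator emulates the statistical structure the downstream analysis
assumes: a 180 cm circular belt with four 45 cm textures, locomotion at
~421 cm/min sampled at 15 frames/s, a sparse population in which a tuned
subpopulation follows a unimodal circular (von Mises shaped) rate profile

    lambda_i(x) = g * (B_i + A_i * exp(k_i * (cos(theta(x) - phi_i) - 1)))

with theta(x) = 2*pi*x/L, spikes drawn as Poisson counts per frame,
calcium as spikes convolved with a single-exponential kernel plus additive
Gaussian noise, and a global log-normal shared gain that induces positive
noise correlations. The multiplier ``g`` is the study's gain knob: the
adult-born-neuron manipulation is modelled as a multiplicative change of
all underlying rates.

Everything is deterministic given ``rng_seed``: each stochastic stage uses
its own named substream derived from the root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .errors import InvalidConfigError, InvalidInputError
from .session import PositionTrace, Session, reconstruct_position

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "simulate_trajectory",
    "simulate_session",
    "apply_gain",
]

# fixed stream ids so substreams stay decoupled when the code evolves
_STREAMS = {
    "trajectory": 1,
    "params": 2,
    "shared_gain": 3,
    "spikes": 4,
    "noise": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a simulated session.

    Units: belt/texture lengths in cm, speeds in cm/min (as commonly quoted
    for this preparation), rates in events/s, calcium amplitudes in ΔF/F,
    time constants in s.
    """

    n_neurons: int = 100
    n_laps: int = 21              # ~9 min of recording at 421 cm/min
    belt_length: float = 180.0
    n_textures: int = 4
    frame_rate: float = 15.0
    mean_speed: float = 421.0     # cm/min
    speed_jitter_sd: float = 23.0  # cm/min, slow (~2 s) fluctuation
    fraction_tuned: float = 0.5
    baseline_rate_range: tuple[float, float] = (0.02, 0.10)   # B, events/s
    amplitude_range: tuple[float, float] = (0.5, 1.5)         # A, events/s
    concentration_range: tuple[float, float] = (2.0, 8.0)     # k
    gain: float = 1.0             # g, dimensionless
    decay_tau: float = 1.0        # s, jRGECO1a-like single exponential
    spike_amplitude: float = 1.0  # ΔF/F per event
    noise_sd: float = 0.05        # additive ΔF/F noise
    shared_gain_sd: float = 0.2   # sd of the common multiplicative gain
    shared_gain_tau: float = 5.0  # s, correlation time of the shared gain
    f0: float = 100.0             # raw fluorescence baseline (a.u.)
    encoder_noise_sd: float = 0.0   # cm per telemetry sample
    encoder_gain_error: float = 0.0  # relative scale error of the encoder
    samples_per_frame: int = 1
    rng_seed: int = 0

    @property
    def texture_length(self) -> float:
        return self.belt_length / self.n_textures

    def validate(self) -> None:
        if self.n_laps < 1 or self.n_neurons < 1:
            raise InvalidConfigError("n_laps and n_neurons must be >= 1")
        if self.mean_speed <= 0 or self.frame_rate <= 0:
            raise InvalidConfigError("speed and frame rate must be positive")
        if not 0.0 <= self.fraction_tuned <= 1.0:
            raise InvalidConfigError("fraction_tuned must be in [0, 1]")
        if self.gain < 0:
            raise InvalidConfigError("gain must be >= 0")
        if self.noise_sd < 0 or self.decay_tau <= 0:
            raise InvalidConfigError("noise sd must be >= 0 and decay tau > 0")
        if self.shared_gain_sd < 0:
            raise InvalidConfigError("shared_gain_sd must be >= 0")
        for lo, hi in (self.baseline_rate_range, self.amplitude_range,
                       self.concentration_range):
            if lo < 0 or hi < lo:
                raise InvalidConfigError("parameter ranges must be 0 <= lo <= hi")
        if self.belt_length <= 0 or self.n_textures < 1:
            raise InvalidConfigError("belt_length > 0 and n_textures >= 1 required")


@dataclass
class SyntheticGroundTruth:
    """True generative parameters of a simulated session.

    Stored so that recovery tests can compare estimates against truth, and
    so the same config + seed regenerates the identical session.
    """

    baseline: np.ndarray        # B per neuron (events/s)
    amplitude: np.ndarray       # A per neuron (events/s); 0 for untuned
    concentration: np.ndarray   # k per neuron
    preferred_phase: np.ndarray  # phi per neuron (radians)
    tuned: np.ndarray           # bool per neuron
    spikes: np.ndarray          # latent counts, neurons x frames
    shared_gain: np.ndarray     # realised common multiplier per frame
    config: SyntheticConfig = field(repr=False)

    def __post_init__(self) -> None:
        if np.any(self.amplitude[~self.tuned] != 0):
            raise InvalidInputError("untuned neurons must have A = 0")


def simulate_trajectory(config: SyntheticConfig) -> PositionTrace:
    """Simulate locomotion and the telemetry streams that record it.

    The true speed fluctuates slowly (AR(1) with ~2 s correlation time,
    stationary sd ``speed_jitter_sd``) around ``mean_speed`` and is floored
    at zero. Telemetry consists of encoder increments — optionally corrupted
    by a relative gain error and per-sample Gaussian tick noise — plus RFID
    events fired whenever the *true* position crosses a texture boundary.

    The returned trace additionally carries ``true_position`` (unwrapped cm
    per sample) for validation against the reconstruction.
    """
    config.validate()
    dt = 1.0 / (config.frame_rate * config.samples_per_frame)
    speed_cms = config.mean_speed / 60.0
    jitter_cms = config.speed_jitter_sd / 60.0
    total = config.n_laps * config.belt_length

    rng = _rng(config.rng_seed, "trajectory")
    # generate in blocks until the required distance is covered
    rho = np.exp(-dt / 2.0)  # ~2 s speed correlation time
    innov_sd = np.sqrt(1.0 - rho**2)
    speeds: list[np.ndarray] = []
    z_last = rng.standard_normal()
    covered = 0.0
    est = int(np.ceil(total / (speed_cms * dt))) + 1
    while covered < total:
        z = np.empty(est)
        z[0] = rho * z_last + innov_sd * rng.standard_normal()
        eps = rng.standard_normal(est - 1)
        for i in range(1, est):
            z[i] = rho * z[i - 1] + innov_sd * eps[i - 1]
        z_last = z[-1]
        v = np.maximum(speed_cms + jitter_cms * z, 0.0)
        step = v * dt
        speeds.append(step)
        covered += float(step.sum())
        est = max(int(est * 0.2), 16)
    increments = np.concatenate(speeds)
    cum = np.cumsum(increments)
    n_samples = int(np.searchsorted(cum, total, side="left")) + 1
    n_samples = min(n_samples, increments.size)
    # trim to whole frames
    spf = config.samples_per_frame
    n_frames = max(n_samples // spf, 1)
    n_samples = n_frames * spf
    increments = increments[:n_samples]
    true_unwrapped = np.cumsum(increments)

    sample_times = (np.arange(n_samples) + 1) * dt
    frame_times = sample_times[spf - 1::spf]

    ticks = increments * (1.0 + config.encoder_gain_error)
    if config.encoder_noise_sd > 0:
        ticks = ticks + config.encoder_noise_sd * rng.standard_normal(n_samples)

    # RFID events at texture boundaries of the true position
    tex = config.texture_length
    boundary_idx = np.flatnonzero(
        np.diff(np.floor(true_unwrapped / tex), prepend=0.0) >= 1)
    events = []
    for s in boundary_idx:
        b = int(np.floor(true_unwrapped[s] / tex))
        tag = b % config.n_textures
        events.append((int(s), tag, (b * tex) % config.belt_length))

    trace = PositionTrace(
        ticks=ticks,
        sample_times=sample_times,
        frame_times=frame_times,
        rfid_events=events,
    )
    trace.true_position = true_unwrapped  # type: ignore[attr-defined]
    return trace


def _draw_parameters(config: SyntheticConfig):
    rng = _rng(config.rng_seed, "params")
    n = config.n_neurons
    n_tuned = int(round(config.fraction_tuned * n))
    tuned = np.zeros(n, dtype=bool)
    tuned[rng.permutation(n)[:n_tuned]] = True
    B = rng.uniform(*config.baseline_rate_range, size=n)
    A = np.where(tuned, rng.uniform(*config.amplitude_range, size=n), 0.0)
    k = rng.uniform(*config.concentration_range, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return B, A, k, phi, tuned


def _shared_gain(config: SyntheticConfig, n_frames: int) -> np.ndarray:
    """Log-normal AR(1) multiplier with mean 1 and sd ~ shared_gain_sd."""
    if config.shared_gain_sd == 0:
        return np.ones(n_frames)
    rng = _rng(config.rng_seed, "shared_gain")
    sigma_l = np.sqrt(np.log1p(config.shared_gain_sd**2))
    rho = np.exp(-1.0 / (config.frame_rate * config.shared_gain_tau))
    z = np.empty(n_frames)
    z[0] = rng.standard_normal()
    eps = rng.standard_normal(n_frames - 1)
    innov = np.sqrt(1.0 - rho**2)
    for i in range(1, n_frames):
        z[i] = rho * z[i - 1] + innov * eps[i - 1]
    return np.exp(sigma_l * z - 0.5 * sigma_l**2)


def expected_rate(
    config: SyntheticConfig,
    position: np.ndarray,
    B: np.ndarray,
    A: np.ndarray,
    k: np.ndarray,
    phi: np.ndarray,
) -> np.ndarray:
    """Noise-free rate lambda_i(x) (events/s), neurons x frames."""
    theta = 2.0 * np.pi * np.asarray(position) / config.belt_length
    prof = np.exp(k[:, None] * (np.cos(theta[None, :] - phi[:, None]) - 1.0))
    return config.gain * (B[:, None] + A[:, None] * prof)


def simulate_session(
    config: SyntheticConfig,
) -> tuple[Session, SyntheticGroundTruth]:
    """Simulate a full session and return it with its ground truth.

    The position fed to the rate model is the *reconstructed* position (the
    same code path real telemetry takes), so encoder imperfections propagate
    exactly as they would in an experiment.
    """
    config.validate()
    trace = simulate_trajectory(config)
    position, laps = reconstruct_position(trace, config.belt_length)
    n_frames = position.size

    B, A, k, phi, tuned = _draw_parameters(config)
    gain_trace = _shared_gain(config, n_frames)
    lam = expected_rate(config, position, B, A, k, phi) * gain_trace[None, :]

    spikes = _rng(config.rng_seed, "spikes").poisson(lam / config.frame_rate)

    gamma = np.exp(-1.0 / (config.frame_rate * config.decay_tau))
    calcium = lfilter([config.spike_amplitude], [1.0, -gamma],
                      spikes.astype(float), axis=1)
    noise = _rng(config.rng_seed, "noise").standard_normal(calcium.shape)
    dff = calcium + config.noise_sd * noise
    raw_f = config.f0 * (1.0 + dff)

    session = Session(
        dff=dff,
        raw_f=raw_f,
        frame_times=trace.frame_times,
        position=position,
        lap_index=laps,
        belt_length=config.belt_length,
        frame_rate=config.frame_rate,
        metadata={"rng_seed": config.rng_seed, "gain": config.gain,
                  "synthetic": True},
    )
    truth = SyntheticGroundTruth(
        baseline=B, amplitude=A, concentration=k, preferred_phase=phi,
        tuned=tuned, spikes=spikes, shared_gain=gain_trace, config=config,
    )
    session.metadata["config"] = truth.config  # enables apply_gain
    return session, truth


def apply_gain(session: Session, g: float) -> Session:
    """Re-simulate a synthetic session with all underlying rates scaled by g.

    The same root seed is reused, so tuning locations and widths — and, for
    ``g = 1``, the entire session — are unchanged; only the rate scale (and
    hence spiking, before the fixed additive-noise stage) differs.
    """
    if g < 0:
        raise InvalidInputError("gain must be >= 0")
    config: Optional[SyntheticConfig] = session.metadata.get("config")
    if config is None:
        raise InvalidInputError(
            "apply_gain requires a synthetic session carrying its config")
    new_cfg = replace(config, gain=config.gain * g)
    new_session, _ = simulate_session(new_cfg)
    return new_session
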