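"""Synthetic open-field fiber-photometry sessions with known ground truth.

The generator emulates the recording setup the analysis pipeline expects:
a mouse foraging in a 40 x 40 cm arena, video-tracked at 30 Hz, while a
dual-channel fiber-photometry system records a calcium-dependent signal
(473 nm) and an isosbestic control (405 nm) at 500 Hz.

The generative chain is

1. a semi-Markov behaviour sequence over five states (exploratory running,
   exploratory walking, grooming, rearing, still) with log-normal dwell
   times, tuned so the long-run occupancies match configured targets;
2. a neck trajectory whose speed follows a bounded mean-reverting process
   within each state's speed range, with wall reflection, tracking jitter
   and occasional low-likelihood dropout frames;
3. a latent cholinergic activity trace on the z-dF/F scale, linear in
   log2(speed) with behaviour offsets, a darkness term, per-animal and
   per-session random intercepts/slopes, and AR(1) noise;
4. an optical readout: the latent trace is scaled to dF/F units, convolved
   with a causal difference-of-exponentials calcium-indicator kernel
   (half-decay 1.69 s by default, matching jGCaMP7s), multiplied onto an
   exponentially bleaching 473 nm baseline, and contaminated with sparse
   motion artifacts shared (with a gain) between both channels plus white
   measurement noise.

Because the latent coefficients are configured, every downstream analysis
can be validated as a parameter-recovery problem.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.signal import fftconvolve, lfilter

from achdyn.kinematics import PoseTrack, log2_with_floor
from achdyn.photometry import RawPhotometry, process_session
from achdyn.tuning import AlignedSession

#: Behaviour states, in community-label order (labels files use the index).
STATES = ("still", "walk", "run", "groom", "rear")
STATE_NAMES = {
    "still": "still",
    "walk": "exploratory_walking",
    "run": "exploratory_running",
    "groom": "grooming",
    "rear": "rearing",
}
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

#: Open-field occupancies (fraction of time per behaviour); the printed
#: percentages (70.4 running, 26.2 walking, 2.1 rearing, 1.4 grooming) sum
#: to 100.1 from rounding and are renormalised here.
_RAW_OCC = {"run": 0.704, "walk": 0.262, "rear": 0.021, "groom": 0.014, "still": 0.0}
_OCC_SUM = sum(_RAW_OCC.values())
DEFAULT_OCCUPANCY = {k: v / _OCC_SUM for k, v in _RAW_OCC.items()}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class KernelParams:
    """Calcium-indicator impulse response: difference of exponentials.

    Only the half-decay time is reported for jGCaMP7s (1.69 s); the rise
    time constant is a free parameter with a typical slow-indicator default.
    """

    rise_tau: float = 0.2  # s
    half_decay: float = 1.69  # s, measured from the kernel peak


@dataclass
class BleachParams:
    baseline: float = 2.0  # a.u. at t=0
    tau_s: float = 600.0  # photobleaching time constant


@dataclass
class ArtifactParams:
    """Sparse motion transients shared across channels with gain ``channel_gain``."""

    rate_per_min: float = 2.0
    amplitude: float = 0.05  # a.u., typical magnitude on the 470 channel
    channel_gain: float = 0.8  # gamma: fraction appearing on the 405 channel
    decay_tau: float = 0.3  # s


@dataclass
class NoiseParams:
    """AR(1) latent noise: marginal SD ``sd`` (z-units), lag-1 coefficient ``ar_coef``."""

    ar_coef: float = 0.9
    sd: float = 0.5


@dataclass
class RandomEffectParams:
    """SDs of per-animal / per-session random intercepts and log-speed slopes."""

    animal_intercept_sd: float = 0.15
    animal_slope_sd: float = 0.03
    session_intercept_sd: float = 0.10
    session_slope_sd: float = 0.03


@dataclass
class Coefficients:
    """Fixed effects of the latent model, on the z-dF/F scale.

    Defaults follow the fitted open-field values: intercept -0.169 and
    log2(speed) slope 0.221; rearing offset 0.277 and grooming offset
    -0.211 relative to walking.  Darkness terms default to zero (the null
    finding); nonzero values are available for power studies.
    """

    beta0: float = -0.169
    beta_speed: float = 0.221
    beta_rear: float = 0.277
    beta_groom: float = -0.211
    beta_er: float = 0.0  # exploratory-running offset (walking = reference)
    beta_dark_slope: float = 0.0  # interaction log2(speed) x darkness
    beta_dark_main: float = 0.0  # main effect of darkness

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class SynthConfig:
    """All knobs of the synthetic-session generator."""

    session_duration: float = 300.0  # s
    photometry_rate: float = 500.0  # Hz
    frame_rate: float = 30.0  # Hz
    arena_size: tuple[float, float] = (40.0, 40.0)  # cm
    occupancy_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY)
    )
    #: cm/s range of the speed process per state; stationary states stay < 3
    speed_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "run": (10.0, 30.0),
            "walk": (3.0, 10.0),
            "groom": (0.2, 2.0),
            "rear": (0.2, 2.0),
            "still": (0.2, 2.0),
        }
    )
    #: median dwell time (s) per state for the log-normal dwell distribution
    dwell_medians: dict[str, float] = field(
        default_factory=lambda: {
            "run": 3.0,
            "walk": 2.0,
            "groom": 8.0,
            "rear": 2.0,
            "still": 4.0,
        }
    )
    dwell_sigma: float = 0.6  # log-normal shape parameter
    coeffs: Coefficients = field(default_factory=Coefficients)
    noise: NoiseParams = field(default_factory=NoiseParams)
    random_effects: RandomEffectParams = field(default_factory=RandomEffectParams)
    kernel: KernelParams = field(default_factory=KernelParams)
    bleach_470: BleachParams = field(default_factory=lambda: BleachParams(2.0, 600.0))
    bleach_405: BleachParams = field(default_factory=lambda: BleachParams(1.0, 500.0))
    artifact: ArtifactParams = field(default_factory=ArtifactParams)
    dff_scale: float = 0.03  # dF/F units per latent z-unit
    dff_offset: float = 0.05  # baseline dF/F level
    photometry_noise_sd: float = 0.01  # a.u. white noise per 500 Hz sample
    frame_noise_sd: float = 0.6  # z-units fast (white) readout noise at the frame clock
    speed_floor: float = 0.25  # cm/s, epsilon for log2
    tracking_jitter_sd: float = 0.05  # cm per coordinate
    dropout_prob: float = 0.02  # low-likelihood frame probability
    speed_tau: float = 0.5  # s, mean-reversion time of the speed process
    heading_diffusion: float = 1.5  # rad / sqrt(s)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.occupancy_targets.values())
        if abs(total - 1.0) > 0.01:
            raise ValueError(f"occupancy_targets sum to {total}, expected 1")
        if abs(total - 1.0) > 1e-9:
            self.occupancy_targets = {
                k: v / total for k, v in self.occupancy_targets.items()
            }
        for k in self.occupancy_targets:
            if k not in STATES:
                raise ValueError(f"unknown behaviour state {k!r}")
            if self.occupancy_targets[k] < 0:
                raise ValueError("occupancies must be non-negative")
            if self.occupancy_targets[k] > 0 and k not in self.speed_ranges:
                raise ValueError(f"state {k!r} has occupancy but no speed range")
        for k, (lo, hi) in self.speed_ranges.items():
            if not (0 <= lo < hi):
                raise ValueError(f"invalid speed range for state {k!r}")
        if self.kernel.half_decay <= 0 or self.kernel.rise_tau <= 0:
            raise ValueError("kernel parameters must be positive")
        if self.bleach_470.baseline < 0 or self.bleach_405.baseline < 0:
            raise ValueError("bleach baselines must be non-negative")
        if self.noise.sd < 0 or self.frame_noise_sd < 0 or self.photometry_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if min(self.arena_size) <= 0:
            raise ValueError("arena size must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.session_duration * self.frame_rate))


@dataclass
class BehaviorLabels:
    """Per-frame behaviour state (community index into :data:`STATES`)."""

    states: np.ndarray  # int per frame
    frame_rate: float
    #: (state index, n_frames) per drawn dwell, before same-state merging;
    #: the last draw may be truncated by the session end.
    drawn_bouts: list[tuple[int, int]] | None = None

    def __len__(self) -> int:
        return len(self.states)

    @property
    def names(self) -> np.ndarray:
        return np.asarray(STATES)[self.states]

    def indicator(self, state: str) -> np.ndarray:
        return (self.states == STATE_INDEX[state]).astype(float)

    def occupancy(self) -> dict[str, float]:
        return {s: float(np.mean(self.states == i)) for i, s in enumerate(STATES)}

    def bouts(self) -> list[tuple[int, int, int]]:
        """(state, start, length) runs of constant state."""
        changes = np.flatnonzero(np.diff(self.states)) + 1
        starts = np.concatenate([[0], changes])
        ends = np.concatenate([changes, [len(self.states)]])
        return [
            (int(self.states[a]), int(a), int(b - a)) for a, b in zip(starts, ends)
        ]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    latent: np.ndarray  # z-trace before the indicator kernel (frame clock)
    true_dff: np.ndarray  # dF/F after kernel, frame clock
    true_dff_samples: np.ndarray  # dF/F on the 500 Hz clock
    true_speed: np.ndarray  # cm/s per frame
    coeffs: Coefficients
    bleach_470: np.ndarray
    bleach_405: np.ndarray
    artifact: np.ndarray
    frame_times: np.ndarray
    kernel: np.ndarray


# ---------------------------------------------------------------------------
# indicator kernel


def calcium_kernel(
    rate: float, rise_tau: float = 0.2, half_decay: float = 1.69
) -> np.ndarray:
    """Causal difference-of-exponentials kernel, unit area, sampled at ``rate``.

    The decay time constant is solved numerically so that the half-decay
    time measured from the kernel peak equals ``half_decay``.
    """
    if half_decay <= 0 or rise_tau <= 0:
        raise ValueError("kernel parameters must be positive")

    def measured_half_decay(tau_d: float) -> float:
        t_p = np.log(tau_d / rise_tau) * rise_tau * tau_d / (tau_d - rise_tau)
        peak = np.exp(-t_p / tau_d) - np.exp(-t_p / rise_tau)

        def f(t):
            return np.exp(-t / tau_d) - np.exp(-t / rise_tau) - 0.5 * peak

        return brentq(f, t_p, t_p + 60.0 * tau_d) - t_p

    lo = rise_tau * 1.0001
    hi = max(10.0 * half_decay, 10.0 * rise_tau)
    tau_d = brentq(lambda td: measured_half_decay(td) - half_decay, lo, hi)
    dt = 1.0 / rate
    t_end = tau_d * np.log(1e4)  # truncate once the tail is < 1e-4 of scale
    t = np.arange(0.0, t_end, dt)
    h = np.exp(-t / tau_d) - np.exp(-t / rise_tau)
    return h / h.sum()


def kernel_half_decay(kernel: np.ndarray, rate: float) -> float:
    """Half-decay time (s) of a sampled kernel, from peak to half-peak,
    with linear interpolation between samples."""
    k = np.asarray(kernel, dtype=float)
    i_peak = int(np.argmax(k))
    half = k[i_peak] / 2.0
    below = np.nonzero(k[i_peak:] <= half)[0]
    if len(below) == 0:
        raise ValueError("kernel does not decay to half its peak")
    j = below[0]
    if j == 0:
        return 0.0
    k1, k0 = k[i_peak + j], k[i_peak + j - 1]
    frac = (k0 - half) / (k0 - k1)
    return (j - 1 + frac) / rate


# ---------------------------------------------------------------------------
# behaviour and trajectory


def simulate_behavior(config: SynthConfig, seed) -> BehaviorLabels:
    """Semi-Markov state sequence at the video frame rate.

    States are drawn i.i.d. with probabilities proportional to
    occupancy / expected dwell, and dwell times are log-normal with
    state-specific medians, so the expected time fraction per state equals
    the occupancy target.
    """
    rng = _rng(seed)
    n_frames = config.n_frames
    occ = config.occupancy_targets
    active = [s for s in STATES if occ.get(s, 0.0) > 0]
    if not active:
        raise ValueError("no behaviour state has positive occupancy")
    mean_dwell = {
        s: config.dwell_medians[s] * np.exp(config.dwell_sigma**2 / 2.0)
        for s in active
    }
    weights = np.array([occ[s] / mean_dwell[s] for s in active])
    weights /= weights.sum()
    states = np.empty(n_frames, dtype=np.int64)
    drawn: list[tuple[int, int]] = []
    pos = 0
    while pos < n_frames:
        s = active[rng.choice(len(active), p=weights)]
        dwell_s = config.dwell_medians[s] * np.exp(
            config.dwell_sigma * rng.standard_normal()
        )
        n = max(1, int(round(dwell_s * config.frame_rate)))
        states[pos : pos + n] = STATE_INDEX[s]
        drawn.append((STATE_INDEX[s], min(n, n_frames - pos)))
        pos += n
    return BehaviorLabels(
        states=states, frame_rate=config.frame_rate, drawn_bouts=drawn
    )


def sample_dwell_times(config: SynthConfig, state: str, n: int, seed) -> np.ndarray:
    """Direct draws from the configured dwell distribution (s), for oracles."""
    rng = _rng(seed)
    return config.dwell_medians[state] * np.exp(
        config.dwell_sigma * rng.standard_normal(n)
    )


def _fold(p: np.ndarray, width: float) -> np.ndarray:
    """Reflect coordinates into [0, width] (triangle-wave fold)."""
    m = np.mod(p, 2.0 * width)
    return np.where(m <= width, m, 2.0 * width - m)


def simulate_trajectory(
    labels: BehaviorLabels, config: SynthConfig, seed
) -> tuple[PoseTrack, np.ndarray]:
    """Neck trajectory and true per-frame speed.

    Within each bout, speed follows a mean-reverting process around a
    bout-specific target drawn uniformly from the state's speed range,
    clipped to that range; position integrates the speed along a diffusing
    heading and reflects at the arena walls.  The written pose track adds
    Gaussian tracking jitter and occasional low-likelihood dropout frames
    with inflated error.
    """
    rng = _rng(seed)
    n = len(labels)
    fr = config.frame_rate
    dt = 1.0 / fr
    w, h = config.arena_size

    lo = np.empty(n)
    hi = np.empty(n)
    target = np.empty(n)
    for state, start, length in labels.bouts():
        s_lo, s_hi = config.speed_ranges[STATES[state]]
        lo[start : start + length] = s_lo
        hi[start : start + length] = s_hi
        target[start : start + length] = rng.uniform(s_lo, s_hi)

    phi = np.exp(-dt / config.speed_tau)
    sd_u = 0.15 * (hi - lo)
    innov = np.sqrt(1.0 - phi**2) * sd_u * rng.standard_normal(n)
    u = lfilter([1.0], [1.0, -phi], innov)
    true_speed = np.clip(target + u, lo, hi)

    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    theta = theta0 + np.cumsum(
        config.heading_diffusion * np.sqrt(dt) * rng.standard_normal(n)
    )
    step = true_speed * dt
    x = rng.uniform(0.2 * w, 0.8 * w) + np.cumsum(step * np.cos(theta))
    y = rng.uniform(0.2 * h, 0.8 * h) + np.cumsum(step * np.sin(theta))
    x = _fold(x, w)
    y = _fold(y, h)

    jitter = config.tracking_jitter_sd
    obs_x = x + jitter * rng.standard_normal(n)
    obs_y = y + jitter * rng.standard_normal(n)
    likelihood = rng.uniform(0.95, 1.0, size=n)
    drop = rng.random(n) < config.dropout_prob
    likelihood[drop] = rng.uniform(0.0, 0.5, size=int(drop.sum()))
    obs_x[drop] += 3.0 * rng.standard_normal(int(drop.sum()))
    obs_y[drop] += 3.0 * rng.standard_normal(int(drop.sum()))

    pose = PoseTrack(
        time_s=np.arange(n) / fr, neck_x=obs_x, neck_y=obs_y, likelihood=likelihood
    )
    return pose, true_speed


# ---------------------------------------------------------------------------
# latent activity and optical readout


def simulate_latent(
    speed: np.ndarray,
    labels: BehaviorLabels,
    config: SynthConfig,
    lighting: str = "light",
    seed=0,
    intercept_offset: float = 0.0,
    slope_offset: float = 0.0,
) -> np.ndarray:
    """Latent cholinergic trace on the z-dF/F scale.

    latent = beta0 + (beta_speed + slope_offset + beta_dark_slope*I[dark])
             * log2(max(speed, eps))
             + beta_er*I[run] + beta_rear*I[rear] + beta_groom*I[groom]
             + beta_dark_main*I[dark] + intercept_offset + AR(1) noise.

    ``intercept_offset`` / ``slope_offset`` carry the summed animal and
    session random effects; cohort-level drivers draw them from
    ``config.random_effects``.
    """
    rng = _rng(seed)
    if len(speed) != len(labels):
        raise ValueError("speed and labels must be frame-aligned")
    c = config.coeffs
    is_dark = 1.0 if lighting == "dark" else 0.0
    ls = log2_with_floor(speed, config.speed_floor)
    slope = c.beta_speed + slope_offset + c.beta_dark_slope * is_dark
    latent = (
        c.beta0
        + intercept_offset
        + slope * ls
        + c.beta_er * labels.indicator("run")
        + c.beta_rear * labels.indicator("rear")
        + c.beta_groom * labels.indicator("groom")
        + c.beta_dark_main * is_dark
    )
    if config.noise.sd > 0:
        phi = config.noise.ar_coef
        warmup = 200
        eps = rng.standard_normal(len(speed) + warmup)
        innov = config.noise.sd * np.sqrt(1.0 - phi**2) * eps
        noise = lfilter([1.0], [1.0, -phi], innov)[warmup:]
        latent = latent + noise
    return latent


def render_photometry(
    latent: np.ndarray, config: SynthConfig, seed
) -> tuple[RawPhotometry, GroundTruth]:
    """Render the 500 Hz two-channel recording from a frame-clock latent trace.

    true dF/F = dff_offset + dff_scale * (latent (*) indicator kernel)
    F470(t) = B470 e^(-t/tau470) (1 + dF/F(t)) + m(t) + noise
    F405(t) = B405 e^(-t/tau405) + gamma m(t) + noise

    with m(t) a shared sparse motion-artifact process.  TTL frame times at
    the video frame rate are included in the returned raw recording.
    """
    rng = _rng(seed)
    latent = np.asarray(latent, dtype=float)
    n_frames = len(latent)
    fr = config.frame_rate
    prate = config.photometry_rate
    duration = n_frames / fr
    n_samp = int(round(duration * prate))
    t_samp = np.arange(n_samp) / prate
    frame_times = np.arange(n_frames) / fr

    kern = calcium_kernel(fr, config.kernel.rise_tau, config.kernel.half_decay)
    true_dff = config.dff_offset + config.dff_scale * np.convolve(latent, kern)[:n_frames]
    dff_samp = np.interp(t_samp, frame_times, true_dff)

    b470 = config.bleach_470.baseline * np.exp(-t_samp / config.bleach_470.tau_s)
    b405 = config.bleach_405.baseline * np.exp(-t_samp / config.bleach_405.tau_s)

    art = config.artifact
    m = np.zeros(n_samp)
    n_events = rng.poisson(art.rate_per_min * duration / 60.0)
    if n_events > 0 and art.amplitude > 0:
        event_idx = rng.integers(0, n_samp, size=n_events)
        amps = (
            art.amplitude
            * rng.uniform(0.5, 1.5, size=n_events)
            * rng.choice([-1.0, 1.0], size=n_events)
        )
        impulses = np.zeros(n_samp)
        np.add.at(impulses, event_idx, amps)
        t_dec = np.arange(0.0, 6.0 * art.decay_tau, 1.0 / prate)
        m = fftconvolve(impulses, np.exp(-t_dec / art.decay_tau))[:n_samp]

    noise_sd = config.photometry_noise_sd
    f470 = b470 * (1.0 + dff_samp) + m + noise_sd * rng.standard_normal(n_samp)
    f405 = b405 + art.channel_gain * m + noise_sd * rng.standard_normal(n_samp)

    raw = RawPhotometry(
        time_s=t_samp, f470=f470, f405=f405, ttl_frame_times=frame_times
    )
    truth = GroundTruth(
        latent=latent,
        true_dff=true_dff,
        true_dff_samples=dff_samp,
        true_speed=np.full(n_frames, np.nan),
        coeffs=config.coeffs,
        bleach_470=b470,
        bleach_405=b405,
        artifact=m,
        frame_times=frame_times,
        kernel=kern,
    )
    return raw, truth


# ---------------------------------------------------------------------------
# session- and cohort-level drivers


@dataclass
class SessionTruth:
    """Ground truth bundle for one simulated session."""

    labels: BehaviorLabels
    true_speed: np.ndarray
    latent: np.ndarray
    pose: PoseTrack
    intercept_offset: float
    slope_offset: float
    render: GroundTruth | None = None
    raw: RawPhotometry | None = None


def simulate_aligned_session(
    config: SynthConfig,
    seed,
    lighting: str = "light",
    animal_id: str = "a0",
    session_id: str = "s0",
    intercept_offset: float = 0.0,
    slope_offset: float = 0.0,
    response: str = "model",
) -> tuple[AlignedSession, SessionTruth]:
    """One synthetic session, already frame-aligned, at a chosen readout level.

    ``response`` selects what goes into the ``zdff`` column:

    - ``"model"``: the latent trace plus fast white readout noise (model
      scale, no indicator kernel) -- the right level for statistical
      parameter recovery, since the latent coefficients are defined on
      this scale;
    - ``"kernel"``: z-scored kernel-convolved latent plus white frame noise
      -- a cheap stand-in for the processed photometry readout, used for
      temporal-dynamics and causality experiments;
    - ``"photometry"``: the full optical render followed by the complete
      preprocessing chain (resampling, isosbestic correction, dF/F,
      z-scoring).

    The session's ``speed`` column is the generator's true speed; pose-based
    speed estimation is exercised by the file-level pipeline.
    """
    rng = _rng(seed)
    labels = simulate_behavior(config, rng)
    pose, true_speed = simulate_trajectory(labels, config, rng)
    latent = simulate_latent(
        true_speed,
        labels,
        config,
        lighting=lighting,
        seed=rng,
        intercept_offset=intercept_offset,
        slope_offset=slope_offset,
    )
    truth = SessionTruth(
        labels=labels,
        true_speed=true_speed,
        latent=latent,
        pose=pose,
        intercept_offset=intercept_offset,
        slope_offset=slope_offset,
    )
    n = len(latent)
    if response == "model":
        zdff = latent + config.frame_noise_sd * rng.standard_normal(n)
    elif response == "kernel":
        kern = calcium_kernel(
            config.frame_rate, config.kernel.rise_tau, config.kernel.half_decay
        )
        smoothed = np.convolve(latent, kern)[:n]
        noisy = smoothed + config.frame_noise_sd * rng.standard_normal(n)
        zdff = (noisy - noisy.mean()) / noisy.std(ddof=1)
    elif response == "photometry":
        raw, render = render_photometry(latent, config, rng)
        render.true_speed = true_speed
        truth.render = render
        truth.raw = raw
        zdff = process_session(raw).zdff
    else:
        raise ValueError(f"unknown response mode {response!r}")
    session = AlignedSession(
        animal_id=animal_id,
        session_id=session_id,
        lighting=lighting,
        frame_time=np.arange(n) / config.frame_rate,
        zdff=zdff,
        speed=true_speed,
        logspeed=log2_with_floor(true_speed, config.speed_floor),
        community=labels.states.copy(),
    )
    return session, truth


def _lighting_for(schedule, animal: int, session: int, n_sessions: int) -> str:
    if isinstance(schedule, str):
        if schedule in ("light", "dark"):
            return schedule
        if schedule == "alternate":
            # daily pattern light, dark, dark, light
            return ("light", "dark", "dark", "light")[session % 4]
        raise ValueError(f"unknown lighting schedule {schedule!r}")
    return schedule[animal][session]


def simulate_aligned_cohort(
    config: SynthConfig,
    n_animals: int,
    sessions_per_animal,
    seed,
    lighting_schedule="alternate",
    response: str = "model",
) -> tuple[list[AlignedSession], dict]:
    """A cohort of aligned sessions with per-animal/per-session random effects.

    ``sessions_per_animal`` is an int or a per-animal list.  Returns the
    sessions plus a truth dict with the drawn random effects.
    """
    if n_animals < 1:
        raise ValueError("need at least one animal")
    if isinstance(sessions_per_animal, int):
        sessions_per_animal = [sessions_per_animal] * n_animals
    if len(sessions_per_animal) != n_animals:
        raise ValueError("sessions_per_animal length must match n_animals")
    rng = _rng(seed)
    re = config.random_effects
    sessions: list[AlignedSession] = []
    truths = {}
    effects = {"animal": {}, "session": {}}
    for a in range(n_animals):
        animal_id = f"m{a:02d}"
        b0_a = re.animal_intercept_sd * rng.standard_normal()
        b1_a = re.animal_slope_sd * rng.standard_normal()
        effects["animal"][animal_id] = (b0_a, b1_a)
        for s in range(sessions_per_animal[a]):
            session_id = f"{animal_id}_s{s:03d}"
            b0_s = re.session_intercept_sd * rng.standard_normal()
            b1_s = re.session_slope_sd * rng.standard_normal()
            effects["session"][session_id] = (b0_s, b1_s)
            lighting = _lighting_for(
                lighting_schedule, a, s, sessions_per_animal[a]
            )
            sess, truth = simulate_aligned_session(
                config,
                rng,
                lighting=lighting,
                animal_id=animal_id,
                session_id=session_id,
                intercept_offset=b0_a + b0_s,
                slope_offset=b1_a + b1_s,
                response=response,
            )
            sessions.append(sess)
            truths[session_id] = truth
    return sessions, {"effects": effects, "truths": truths, "coeffs": config.coeffs}


def simulate_cohort(
    config: SynthConfig,
    n_animals: int,
    sessions_per_animal,
    lighting_schedule="alternate",
    seed: int = 0,
    outdir: str | Path = "cohort",
):
    """Write a full cohort to disk: photometry, pose, labels, ground truth
    and a manifest CSV.  Fully reproducible from the seed.

    Returns the manifest as a DataFrame.
    """
    import pandas as pd

    from achdyn import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(sessions_per_animal, int):
        sessions_per_animal = [sessions_per_animal] * n_animals
    rng = _rng(seed)
    rows = []
    for a in range(n_animals):
        animal_id = f"m{a:02d}"
        re = config.random_effects
        b0_a = re.animal_intercept_sd * rng.standard_normal()
        b1_a = re.animal_slope_sd * rng.standard_normal()
        for s in range(sessions_per_animal[a]):
            session_id = f"{animal_id}_s{s:03d}"
            b0_s = re.session_intercept_sd * rng.standard_normal()
            b1_s = re.session_slope_sd * rng.standard_normal()
            lighting = _lighting_for(lighting_schedule, a, s, sessions_per_animal[a])
            _, truth = simulate_aligned_session(
                config,
                rng,
                lighting=lighting,
                animal_id=animal_id,
                session_id=session_id,
                intercept_offset=b0_a + b0_s,
                slope_offset=b1_a + b1_s,
                response="photometry",
            )
            phot_path = outdir / f"{session_id}_photometry.csv"
            pose_path = outdir / f"{session_id}_pose.csv"
            labels_path = outdir / f"{session_id}_labels.csv"
            truth_path = outdir / f"{session_id}_truth.csv"
            io.write_photometry_csv(phot_path, truth.raw)
            io.write_dlc_pose_csv(pose_path, truth.pose)
            io.write_labels_csv(labels_path, truth.labels.states)
            io.write_truth_csv(truth_path, truth)
            rows.append(
                {
                    "animal_id": animal_id,
                    "session_id": session_id,
                    "lighting": lighting,
                    "photometry_path": phot_path.name,
                    "pose_path": pose_path.name,
                    "labels_path": labels_path.name,
                    "truth_path": truth_path.name,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def simulate_gc_table(
    n_animals: int = 5,
    sessions_per_animal: int = 20,
    intercept: float = 0.0063,
    direction_effect: float = 0.0,
    dark_effect: float = 0.0,
    interaction: float = 0.0,
    animal_sd: float = 0.001,
    session_sd: float = 0.0008,
    resid_sd: float = 0.0008,
    seed=0,
):
    """Synthetic per-session Granger-causality table for mixed-model studies.

    Two rows per session (one per direction), with configurable fixed
    effects and animal/session random intercepts.  With all effects zero
    this is the null for direction-effect calibration.
    """
    import pandas as pd

    rng = _rng(seed)
    rows = []
    for a in range(n_animals):
        b_a = animal_sd * rng.standard_normal()
        for s in range(sessions_per_animal):
            b_s = session_sd * rng.standard_normal()
            dark = 1.0 if s % 2 else 0.0
            for direction in (0.0, 1.0):  # 1 = ACh -> Speed
                gc = (
                    intercept
                    + direction_effect * direction
                    + dark_effect * dark
                    + interaction * direction * dark
                    + b_a
                    + b_s
                    + resid_sd * rng.standard_normal()
                )
                rows.append(
                    {
                        "animal_id": f"m{a:02d}",
                        "session_id": f"m{a:02d}_s{s:03d}",
                        "lighting": "dark" if dark else "light",
                        "direction": "ach_to_speed" if direction else "speed_to_ach",
                        "gc_nats": gc,
                    }
                )
    return pd.DataFrame(rows)
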