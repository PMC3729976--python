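"""Synthetic oddball-EEG generator.

Produces (a) pseudo-random oddball stimulus schedules with the classic
16:1:1 standard:deviant:target structure and at least two standards
immediately before every rare event, and (b) multi-channel epochs that
embody the oscillatory structure the analysis stages are designed to
detect:

* a deterministic P1–N1 evoked complex, identical across conditions;
* a theta burst whose per-trial phase is von Mises distributed with a
  condition-specific concentration but a condition-identical amplitude —
  phase reset without power change, so it moves inter-trial phase
  locking but not overall spectral power;
* an ongoing, random-phase alpha process that is multiplicatively
  attenuated after the stimulus with a condition-specific depth — an
  event-related desynchronization visible in induced but not evoked
  measures;
* 1/f ("pink") background noise.

All randomness is routed through per-event substreams of a single seed,
so generation is bit-reproducible and noise realizations do not depend
on which other events are rendered or on the phase-concentration
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import EpochSet
from .layout import gaussian_topography, standard_layout

__all__ = [
    "StimulusSchedule",
    "SimConfig",
    "EvokedComponent",
    "ThetaReset",
    "AlphaDesync",
    "NoiseSpec",
    "generate_schedule",
    "generate_epochs",
    "one_over_f_noise",
]


class ScheduleConstraintError(ValueError):
    """Raised when a requested schedule cannot satisfy its invariants."""


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

@dataclass
class StimulusSchedule:
    """Ordered oddball stimulus sequence.

    ``events`` is a list of ``(onset_ms, kind)`` with kind in
    ``{"standard", "deviant", "target"}`` and strictly increasing onsets.
    """

    events: list[tuple[float, str]]
    isi_range_ms: tuple[float, float]
    duration_ms: float

    @property
    def kinds(self) -> np.ndarray:
        return np.array([k for _, k in self.events], dtype=object)

    @property
    def onsets_ms(self) -> np.ndarray:
        return np.array([o for o, _ in self.events], dtype=float)

    def count(self, kind: str) -> int:
        return int(np.sum(self.kinds == kind))

    def indices(self, kind: str) -> np.ndarray:
        return np.flatnonzero(self.kinds == kind)

    def deviant_and_preceding_standard_indices(self) -> np.ndarray:
        """Event indices of every deviant and its immediately preceding
        standard, sorted.  Raises if a deviant has no preceding standard."""
        kinds = self.kinds
        out: list[int] = []
        for i in self.indices("deviant"):
            if i == 0 or kinds[i - 1] != "standard":
                raise ScheduleConstraintError(
                    f"deviant at event {i} is not preceded by a standard"
                )
            out.extend((i - 1, i))
        return np.unique(np.array(out, dtype=int))


def generate_schedule(
    n_deviants: int,
    ratio: tuple[int, int, int] = (16, 1, 1),
    isi_range_ms: tuple[float, float] = (612.0, 642.0),
    duration_ms: float = 200.0,
    seed: int | np.random.Generator = 0,
    min_standards_before: int = 2,
) -> StimulusSchedule:
    """Generate an oddball schedule with exact counts.

    Counts follow the ratio exactly: ``standards = n_deviants * s / d``
    and ``targets = n_deviants * t / d`` (must divide evenly).  Rare
    events (deviants and targets) are shuffled and dropped into the
    standard stream such that at least ``min_standards_before`` standards
    immediately precede every rare event.  ISIs are drawn uniformly on
    the integer-millisecond grid within ``isi_range_ms``; successive
    onsets are separated by stimulus duration plus ISI.
    """
    if n_deviants < 1:
        raise ValueError("n_deviants must be >= 1")
    s, d, t = ratio
    if min(s, d, t) < 1:
        raise ValueError("ratio components must be >= 1")
    if (n_deviants * s) % d or (n_deviants * t) % d:
        raise ScheduleConstraintError(
            f"ratio {ratio} does not yield integer counts for {n_deviants} deviants"
        )
    if isi_range_ms[0] > isi_range_ms[1]:
        raise ValueError("isi_range_ms must satisfy min <= max")
    n_standards = n_deviants * s // d
    n_targets = n_deviants * t // d
    n_rare = n_deviants + n_targets
    if n_standards < min_standards_before * n_rare:
        raise ScheduleConstraintError(
            f"{n_standards} standards cannot provide {min_standards_before} "
            f"standards before each of {n_rare} rare events"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rare = np.array(["deviant"] * n_deviants + ["target"] * n_targets, dtype=object)
    rng.shuffle(rare)
    # distribute standards into n_rare + 1 gaps; each gap preceding a rare
    # event gets at least min_standards_before
    extra = n_standards - min_standards_before * n_rare
    gap_extra = rng.multinomial(extra, np.full(n_rare + 1, 1.0 / (n_rare + 1)))
    kinds: list[str] = []
    for g in range(n_rare):
        kinds.extend(["standard"] * (min_standards_before + int(gap_extra[g])))
        kinds.append(str(rare[g]))
    kinds.extend(["standard"] * int(gap_extra[n_rare]))

    n_events = len(kinds)
    isis = rng.integers(
        int(round(isi_range_ms[0])), int(round(isi_range_ms[1])) + 1, size=n_events - 1
    ).astype(float)
    onsets = np.concatenate([[0.0], np.cumsum(duration_ms + isis)])
    events = [(float(o), k) for o, k in zip(onsets, kinds)]
    return StimulusSchedule(events=events, isi_range_ms=tuple(isi_range_ms), duration_ms=duration_ms)


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class EvokedComponent:
    """Deterministic evoked bump: Gaussian of given FWHM at a latency,
    scaled by a spatial topography.  ``conditions=None`` means the
    component is identical in every condition (the default)."""

    latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: np.ndarray | None = None
    conditions: tuple[str, ...] | None = None


@dataclass
class ThetaReset:
    """Stimulus-locked theta burst with condition-specific phase
    concentration (von Mises κ) and condition-identical amplitude."""

    freq_hz: float = 6.0
    phase_concentration_standard: float = 0.4
    phase_concentration_deviant: float = 8.0
    amplitude_uv: float = 4.0
    window_ms: tuple[float, float] = (50.0, 250.0)
    topography: np.ndarray | None = None


@dataclass
class AlphaDesync:
    """Ongoing random-phase alpha attenuated post-stimulus.

    ``relative_power_drop_*`` is the fractional power reduction inside
    ``window_ms`` (0 = none, 1 = complete suppression)."""

    freq_hz: float = 12.0
    relative_power_drop_standard: float = 0.35
    relative_power_drop_deviant: float = 0.6
    window_ms: tuple[float, float] = (300.0, 600.0)
    amplitude_uv: float = 3.0
    ramp_ms: float = 50.0
    topography: np.ndarray | None = None


@dataclass
class NoiseSpec:
    one_over_f_exponent: float = 1.0
    rms_uv: float = 5.0


@dataclass
class SimConfig:
    """All generator parameters; see module docstring for the model."""

    n_channels: int = 64
    sampling_rate_hz: float = 1000.0
    epoch_window_ms: tuple[float, float] = (-300.0, 600.0)
    evoked_components: list[EvokedComponent] = field(default_factory=list)
    theta_reset: ThetaReset = field(default_factory=ThetaReset)
    alpha_desync: AlphaDesync = field(default_factory=AlphaDesync)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_reset.phase_concentration_standard < 0:
            raise SimConfigError("phase_concentration_standard must be >= 0")
        if self.theta_reset.phase_concentration_deviant < 0:
            raise SimConfigError("phase_concentration_deviant must be >= 0")
        for name, drop in (
            ("relative_power_drop_standard", self.alpha_desync.relative_power_drop_standard),
            ("relative_power_drop_deviant", self.alpha_desync.relative_power_drop_deviant),
        ):
            if not 0.0 <= drop <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        if self.noise.rms_uv <= 0:
            raise SimConfigError("noise rms_uv must be > 0")
        lo, hi = self.epoch_window_ms
        for comp in self.evoked_components:
            if not lo <= comp.latency_ms <= hi:
                raise SimConfigError(
                    f"evoked component at {comp.latency_ms} ms outside epoch window {self.epoch_window_ms}"
                )
        tc = 0.5 * (self.theta_reset.window_ms[0] + self.theta_reset.window_ms[1])
        if not lo <= tc <= hi:
            raise SimConfigError("theta reset window outside epoch window")

    @classmethod
    def default(cls, seed: int = 0, n_channels: int = 64) -> "SimConfig":
        """The reference oddball simulation: P1–N1 evoked complex (all
        conditions), a sustained late deviant negativity (the slow part of
        the mismatch response, distinct from the theta-driven early
        phase), plus the theta-phase-reset / alpha-desynchronization
        structure."""
        return cls(
            n_channels=n_channels,
            seed=seed,
            evoked_components=[
                EvokedComponent(latency_ms=120.0, width_ms=60.0, amplitude_uv=3.0),
                EvokedComponent(latency_ms=180.0, width_ms=70.0, amplitude_uv=-4.0),
                EvokedComponent(
                    latency_ms=450.0,
                    width_ms=200.0,
                    amplitude_uv=-1.2,
                    conditions=("deviant",),
                ),
            ],
        )


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def _pink_noise(
    rng: np.random.Generator, shape: tuple[int, ...], exponent: float, rms: float
) -> np.ndarray:
    """Pink noise of the given shape (last axis = time).  Synthesized at
    the next fast FFT length and cropped, which keeps the series
    (circularly) stationary and the FFTs cheap."""
    from scipy.fft import next_fast_len

    n = shape[-1]
    nfast = next_fast_len(n, real=True)
    white = rng.standard_normal(shape[:-1] + (nfast,))
    return _shape_pink(white, exponent, rms)[..., :n] if nfast == n else _crop_renorm(
        _shape_pink(white, exponent, rms), n, rms
    )


def _crop_renorm(x: np.ndarray, n: int, rms: float) -> np.ndarray:
    x = x[..., :n]
    x = x - x.mean(axis=-1, keepdims=True)
    cur = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    cur[cur == 0] = 1.0
    return x * (rms / cur)


def _shape_pink(white: np.ndarray, exponent: float, rms: float) -> np.ndarray:
    """Impose a 1/f^exponent power spectrum on white series along the last
    axis and normalize each series to the exact target RMS."""
    from scipy.fft import irfft, rfft  # preserves single precision

    n = white.shape[-1]
    spec = rfft(white, axis=-1)
    k = np.arange(spec.shape[-1], dtype=float)
    k[0] = 1.0  # DC handled below
    scale = (k ** (-exponent / 2.0)).astype(white.dtype)
    scale[0] = 0.0  # zero mean
    x = irfft(spec * scale, n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    cur = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    cur[cur == 0] = 1.0
    return x * (rms / cur)


def one_over_f_noise(
    n_samples: int,
    exponent: float,
    rms_uv: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean noise with power spectral density ∝ 1/f^exponent and RMS
    equal to ``rms_uv`` (normalized exactly, well within the 1% contract).
    ``exponent=0`` gives white noise."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if rms_uv <= 0:
        raise ValueError("rms_uv must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _shape_pink(rng.standard_normal(n_samples), exponent, rms_uv)


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def _raised_cosine(t_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Hann bump spanning ``window`` (zero outside)."""
    lo, hi = window
    c, w = 0.5 * (lo + hi), hi - lo
    env = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t_ms - c) / w))
    env[(t_ms < lo) | (t_ms > hi)] = 0.0
    return env


def _desync_envelope(t_ms: np.ndarray, window: tuple[float, float], drop: float, ramp_ms: float) -> np.ndarray:
    """Amplitude envelope sqrt(1 − drop·w(t)) where w rises from 0 to 1
    over ``ramp_ms`` just before the window, is exactly 1 inside it, and
    falls back just after — so band power inside the window is exactly
    (1 − drop) times baseline."""
    lo, hi = window
    w = np.zeros_like(t_ms)
    w[(t_ms >= lo) & (t_ms <= hi)] = 1.0
    rise = (t_ms >= lo - ramp_ms) & (t_ms < lo)
    w[rise] = 0.5 * (1.0 + np.cos(np.pi * (lo - t_ms[rise]) / ramp_ms))
    fall = (t_ms > hi) & (t_ms <= hi + ramp_ms)
    w[fall] = 0.5 * (1.0 + np.cos(np.pi * (t_ms[fall] - hi) / ramp_ms))
    return np.sqrt(1.0 - drop * w)


def _von_mises_phase(rng: np.random.Generator, kappa: float) -> float:
    if not np.isfinite(kappa):
        return 0.0
    return float(rng.vonmises(0.0, kappa)) if kappa > 0 else float(rng.uniform(-np.pi, np.pi))


def generate_epochs(
    schedule: StimulusSchedule,
    config: SimConfig,
    include_targets: bool = False,
    event_subset: np.ndarray | None = None,
    dtype: type = np.float64,
) -> EpochSet:
    """Render one epoch per analyzed event of ``schedule``.

    By default targets are skipped (they are task events, not analyzed
    stimuli); pass ``include_targets=True`` to render them too, or
    ``event_subset`` (schedule event indices) to render only part of the
    block — e.g. deviants plus their preceding standards.  Each event has
    its own seed substream, so the same event yields the same voltages
    regardless of which other events are rendered.
    """
    names, positions = standard_layout(config.n_channels)
    topo_default = gaussian_topography(positions)
    fs = config.sampling_rate_hz
    lo, hi = config.epoch_window_ms
    n_times = int(round((hi - lo) * fs / 1000.0)) + 1
    t_ms = lo + np.arange(n_times) * 1000.0 / fs

    kinds = schedule.kinds
    if event_subset is None:
        keep = np.flatnonzero(kinds != "target") if not include_targets else np.arange(len(kinds))
    else:
        keep = np.asarray(event_subset, dtype=int)
        if not include_targets and np.any(kinds[keep] == "target"):
            raise ValueError("event_subset contains targets but include_targets=False")

    theta = config.theta_reset
    alpha = config.alpha_desync
    theta_topo = theta.topography if theta.topography is not None else topo_default
    alpha_topo = alpha.topography if alpha.topography is not None else topo_default
    theta_center = 0.5 * (theta.window_ms[0] + theta.window_ms[1])
    theta_env = _raised_cosine(t_ms, theta.window_ms)
    kappa = {
        "standard": theta.phase_concentration_standard,
        "deviant": theta.phase_concentration_deviant,
        "target": theta.phase_concentration_standard,
    }
    drop = {
        "standard": alpha.relative_power_drop_standard,
        "deviant": alpha.relative_power_drop_deviant,
        "target": alpha.relative_power_drop_standard,
    }
    desync_env = {
        k: _desync_envelope(t_ms, alpha.window_ms, v, alpha.ramp_ms) for k, v in drop.items()
    }

    # deterministic evoked waveforms per condition (channels x time)
    evoked = {k: np.zeros((config.n_channels, n_times)) for k in ("standard", "deviant", "target")}
    for comp in config.evoked_components:
        sd = comp.width_ms / 2.3548  # FWHM -> Gaussian sigma
        bump = comp.amplitude_uv * np.exp(-0.5 * ((t_ms - comp.latency_ms) / sd) ** 2)
        topo = comp.topography if comp.topography is not None else topo_default
        for k in comp.conditions or ("standard", "deviant", "target"):
            evoked[k] += topo[:, None] * bump[None, :]

    from scipy.fft import next_fast_len

    nfast = next_fast_len(n_times, real=True)
    streams = np.random.SeedSequence(config.seed).spawn(len(kinds))
    white = np.empty((len(keep), config.n_channels, nfast), dtype=dtype)
    theta_phase = np.empty(len(keep))
    alpha_phase = np.empty(len(keep))
    for j, ev in enumerate(keep):
        rng = np.random.default_rng(streams[ev])
        # fixed draw order: noise, alpha phase, theta phase — the von Mises
        # sampler's rejection count may depend on kappa, so it goes last
        white[j] = rng.standard_normal((config.n_channels, nfast), dtype=dtype)
        alpha_phase[j] = rng.uniform(-np.pi, np.pi)
        theta_phase[j] = _von_mises_phase(rng, kappa[kinds[ev]])
    data = _crop_renorm(
        _shape_pink(white, config.noise.one_over_f_exponent, config.noise.rms_uv),
        n_times,
        config.noise.rms_uv,
    )
    del white

    t_s = t_ms / 1000.0
    for j, ev in enumerate(keep):
        k = kinds[ev]
        data[j] += evoked[k]
        osc = theta.amplitude_uv * theta_env * np.cos(
            2.0 * np.pi * theta.freq_hz * (t_s - theta_center / 1000.0) + theta_phase[j]
        )
        data[j] += theta_topo[:, None] * osc[None, :]
        ongoing = alpha.amplitude_uv * np.cos(
            2.0 * np.pi * alpha.freq_hz * t_s + alpha_phase[j]
        ) * desync_env[k]
        data[j] += alpha_topo[:, None] * ongoing[None, :]

    return EpochSet(
        data=data,
        sampling_rate_hz=fs,
        t0_offset_ms=lo,
        condition=kinds[keep],
        channel_names=names,
        channel_positions=positions,
        event_ids=keep,
    )
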