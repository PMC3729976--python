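"""ERP difference-wave analysis with the consecutive-sample criterion.

The deviant-minus-standard difference waveform is tested sample-by-sample
with one-sample t-tests across subjects; an interval counts as a
significant epoch only if it sustains p < alpha for a minimum run of
consecutive samples.  That minimum run length is calibrated by Monte
Carlo simulation under a null of autocorrelation-matched Gaussian AR(1)
subject waves, so that the family-wise probability of any such run
appearing anywhere in the window by chance is at most alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

__all__ = [
    "DifferenceWave",
    "SignificanceEpochs",
    "difference_wave",
    "lowpass_40hz",
    "sequential_ttest",
    "estimate_lag1_autocorr",
    "calibrate_run_length",
    "significant_epochs",
    "detect_vmmn",
]


class CalibrationError(RuntimeError):
    pass


@dataclass
class DifferenceWave:
    """Deviant − standard waveforms: one per subject plus the group mean."""

    per_subject_waves: np.ndarray  # subjects x time, μV
    values: np.ndarray             # time, μV (subject mean)
    n_subjects: int


@dataclass
class SignificanceEpochs:
    runs: list[tuple[float, float]]  # (start_ms, end_ms)
    alpha: float
    min_run_samples: int
    autocorrelation: float | None = None


def difference_wave(standard_avg: np.ndarray, deviant_avg: np.ndarray) -> DifferenceWave:
    """Per-subject deviant − standard; group wave is the subject mean.

    Both inputs are ``subjects × time`` on the same time axis.
    """
    standard_avg = np.atleast_2d(np.asarray(standard_avg, dtype=float))
    deviant_avg = np.atleast_2d(np.asarray(deviant_avg, dtype=float))
    if standard_avg.shape != deviant_avg.shape:
        raise ValueError(
            f"subject/time mismatch: standard {standard_avg.shape} vs deviant {deviant_avg.shape}"
        )
    per = deviant_avg - standard_avg
    return DifferenceWave(per_subject_waves=per, values=per.mean(axis=0), n_subjects=per.shape[0])


def lowpass_40hz(wave: np.ndarray, sampling_rate_hz: float, cutoff_hz: float = 40.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (applied forward and
    backward), along the last axis."""
    if sampling_rate_hz <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    sos = signal.butter(4, cutoff_hz, btype="low", fs=sampling_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(wave, dtype=float), axis=-1)


def sequential_ttest(per_subject_waves: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Two-tailed one-sample t-test against zero at every time sample.

    Returns the per-sample p-values.  Samples where the across-subject
    variance is exactly zero are degenerate: p = 0 if the common value is
    nonzero, else 1.
    """
    x = np.asarray(per_subject_waves, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need >= 3 subjects")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degen = sd == 0
    p[degen] = np.where(mean[degen] != 0, 0.0, 1.0)
    return p


def estimate_lag1_autocorr(per_subject_waves: np.ndarray) -> float:
    """Mean over subjects of the lag-1 autocorrelation of each wave."""
    x = np.asarray(per_subject_waves, dtype=float)
    x = x - x.mean(axis=-1, keepdims=True)
    num = np.sum(x[..., 1:] * x[..., :-1], axis=-1)
    den = np.sum(x * x, axis=-1)
    return float(np.mean(num / den))


def _max_run_lengths(mask: np.ndarray) -> np.ndarray:
    """Longest run of True along the last axis, per row (vectorized)."""
    m = np.atleast_2d(mask)
    pad = np.zeros((m.shape[0], 1), dtype=int)
    d = np.diff(np.concatenate([pad, m.astype(int), pad], axis=1), axis=1)
    out = np.zeros(m.shape[0], dtype=int)
    starts_r, starts_c = np.nonzero(d == 1)
    ends_r, ends_c = np.nonzero(d == -1)
    lengths = ends_c - starts_c  # starts/ends pair up in order per row
    for r in range(m.shape[0]):
        sel = starts_r == r
        if sel.any():
            out[r] = lengths[sel].max()
    return out


def _simulate_null_max_runs(
    rho: float,
    n_samples: int,
    n_subjects: int,
    alpha: float,
    n_sim: int,
    rng: np.random.Generator,
    burn_in: int = 50,
) -> np.ndarray:
    """Max significant-run length in each of n_sim null experiments with
    Gaussian AR(1) subject waves of lag-1 autocorrelation rho."""
    eps = rng.standard_normal((n_sim, n_subjects, n_samples + burn_in))
    if rho != 0.0:
        x = signal.lfilter([1.0], [1.0, -rho], eps, axis=-1)
    else:
        x = eps
    x = x[..., burn_in:]
    p = sequential_ttest_batch(x)
    return _max_run_lengths(p < alpha)


def sequential_ttest_batch(x: np.ndarray) -> np.ndarray:
    """p-values for one-sample t-tests along axis 1 of (sims, subjects,
    samples); returns (sims, samples)."""
    n = x.shape[1]
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 1)


def calibrate_run_length(
    autocorr: float,
    n_samples: int,
    n_subjects: int,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
) -> int:
    """Smallest run length L such that, under the AR(1) null, the chance
    of >= L consecutive sub-alpha samples anywhere in the window is <= alpha.

    Estimated by Monte Carlo over ``n_sim`` replicate null experiments.
    """
    if not abs(autocorr) < 1:
        raise ValueError("|autocorr| must be < 1")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for a stable calibration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_runs = _simulate_null_max_runs(autocorr, n_samples, n_subjects, alpha, n_sim, rng)
    # P(max run >= L) as a function of L
    for L in range(1, n_samples + 1):
        if np.mean(max_runs >= L) <= alpha:
            return L
    raise CalibrationError(
        f"no run length up to {n_samples} controls the family-wise rate at {alpha}"
    )


def significant_epochs(
    p_values: np.ndarray,
    min_run: int,
    times_ms: np.ndarray,
    alpha: float = 0.05,
    autocorrelation: float | None = None,
) -> SignificanceEpochs:
    """Maximal runs of consecutive p < alpha samples of length >= min_run,
    reported in ms on the given time axis."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    mask = np.asarray(p_values) < alpha
    runs: list[tuple[float, float]] = []
    d = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if e - s >= min_run:
            runs.append((float(times_ms[s]), float(times_ms[e - 1])))
    return SignificanceEpochs(
        runs=runs, alpha=alpha, min_run_samples=min_run, autocorrelation=autocorrelation
    )


def detect_vmmn(
    standard_avg: np.ndarray,
    deviant_avg: np.ndarray,
    times_ms: np.ndarray,
    sampling_rate_hz: float,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    lowpass: bool = True,
) -> tuple[DifferenceWave, SignificanceEpochs]:
    """Full difference-wave procedure: 40 Hz low-pass, sequential t-tests,
    autocorrelation-matched run-length calibration, run detection."""
    dw = difference_wave(standard_avg, deviant_avg)
    waves = lowpass_40hz(dw.per_subject_waves, sampling_rate_hz) if lowpass else dw.per_subject_waves
    dw = DifferenceWave(waves, waves.mean(axis=0), dw.n_subjects)
    p = sequential_ttest(waves, alpha)
    rho = estimate_lag1_autocorr(waves)
    L = calibrate_run_length(rho, waves.shape[1], dw.n_subjects, alpha, n_sim, seed)
    return dw, significant_epochs(p, L, times_ms, alpha, autocorrelation=rho)
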