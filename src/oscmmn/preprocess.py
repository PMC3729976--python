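"""Epoch preprocessing: amplitude-threshold artifact rejection,
common-average re-referencing, baseline correction, ROI averaging.

Rejection is applied to raw amplitudes (before re-referencing) and the
threshold is a strict bound on absolute value: a sample at exactly the
threshold is kept.  No ocular regression or channel interpolation is
performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import CONDITIONS, EpochSet

__all__ = [
    "PreprocConfig",
    "RejectionReport",
    "reject_artifacts",
    "rereference_common_average",
    "baseline_correct",
    "roi_average",
    "preprocess",
]


class AllTrialsRejectedError(RuntimeError):
    pass


@dataclass
class PreprocConfig:
    reject_threshold_uv: float = 100.0
    baseline_window_ms: tuple[float, float] = (-300.0, 0.0)
    reference: str = "common_average"  # or "none"
    roi_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.reject_threshold_uv <= 0:
            raise ValueError("reject_threshold_uv must be > 0")
        if self.reference not in ("common_average", "none"):
            raise ValueError(f"unknown reference {self.reference!r}")


@dataclass
class RejectionReport:
    n_total: int
    n_rejected: int
    rejected_index: np.ndarray
    per_condition_fraction: dict[str, float]

    @property
    def fraction(self) -> float:
        return self.n_rejected / self.n_total if self.n_total else 0.0


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0) -> tuple[EpochSet, RejectionReport]:
    """Drop every trial containing any sample with |value| > threshold.

    Surviving trials are returned untouched.  Raises
    :class:`AllTrialsRejectedError` when nothing survives.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be > 0")
    bad = np.any(np.abs(epochs.data) > threshold_uv, axis=(1, 2))
    per_cond = {}
    for c in CONDITIONS:
        m = epochs.condition == c
        if m.any():
            per_cond[c] = float(bad[m].mean())
    report = RejectionReport(
        n_total=epochs.n_trials,
        n_rejected=int(bad.sum()),
        rejected_index=np.flatnonzero(bad),
        per_condition_fraction=per_cond,
    )
    if bad.all():
        raise AllTrialsRejectedError(
            f"all {epochs.n_trials} trials exceed ±{threshold_uv} μV"
        )
    return epochs.select_trials(~bad), report


def rereference_common_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean over channels from every channel."""
    if epochs.n_channels < 2:
        raise ValueError("common-average reference requires >= 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data)


def baseline_correct(epochs: EpochSet, window_ms: tuple[float, float] = (-300.0, 0.0)) -> EpochSet:
    """Subtract, per trial and channel, the mean over the baseline window."""
    t = epochs.times_ms
    mask = (t >= window_ms[0]) & (t <= window_ms[1])
    if not mask.any():
        raise ValueError(
            f"baseline window {window_ms} contains no samples of the epoch "
            f"time axis [{t[0]}, {t[-1]}] ms"
        )
    data = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=data)


def roi_average(epochs: EpochSet | np.ndarray, channels, channel_names=None) -> np.ndarray:
    """Pointwise mean over the named channels.

    Accepts an :class:`EpochSet` (returns trials × time) or a plain
    ``channels × time`` array with explicit ``channel_names``.
    """
    if isinstance(epochs, EpochSet):
        idx = [epochs.channel_index(c) for c in channels]
        return epochs.data[:, idx, :].mean(axis=1)
    if channel_names is None:
        raise ValueError("channel_names required for plain-array input")
    names = list(channel_names)
    missing = [c for c in channels if c not in names]
    if missing:
        raise KeyError(f"channels {missing} not present; available: {names}")
    idx = [names.index(c) for c in channels]
    return np.asarray(epochs)[idx, :].mean(axis=0)


def preprocess(epochs: EpochSet, config: PreprocConfig) -> tuple[EpochSet, RejectionReport]:
    """Standard chain: reject → (common-average) → baseline-correct."""
    out, report = reject_artifacts(epochs, config.reject_threshold_uv)
    if config.reference == "common_average":
        out = rereference_common_average(out)
    out = baseline_correct(out, config.baseline_window_ms)
    return out, report
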