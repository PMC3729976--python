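"""End-to-end orchestration: simulate (or load) an oddball study, run
preprocessing, the ERP difference-wave analysis, the three
time-frequency measures, and the cluster permutation statistics, and
render a figure report.

Every source of randomness is derived from the single configured seed
(per-subject substreams), so a pipeline run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cluster import (
    DEFAULT_BANDS,
    AdjacencyGraph,
    ClusterResult,
    band_test,
    build_adjacency,
    permutation_null,
)
from .containers import EpochSet
from .erp import detect_vmmn
from .layout import OCCIPITAL_ROI
from .preprocess import PreprocConfig, preprocess, roi_average
from .simulate import SimConfig, generate_epochs, generate_schedule
from .timefreq import (
    complex_demodulate,
    itpl,
    itpl_change,
    match_standard_trials,
    non_phase_locked_power_change,
    overall_power_change,
)

__all__ = ["PipelineConfig", "TFRParams", "StatsParams", "ERPParams", "run_pipeline", "render_report"]

MEASURES = ("overall", "induced", "itpl")


class PipelineConfigError(ValueError):
    def __init__(self, field_name: str, message: str) -> None:
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class TFRParams:
    fmin_hz: float = 4.0
    fmax_hz: float = 50.0
    fstep_hz: float = 2.0
    tstep_ms: float = 25.0
    bandwidth_hz: float = 4.0

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.fmin_hz, self.fmax_hz + 0.5 * self.fstep_hz, self.fstep_hz)


@dataclass
class StatsParams:
    n_permutations: int = 10000
    cluster_alpha: float = 0.01
    final_alpha: float = 0.05
    paired: bool = True
    tail_mode: str = "two_tailed"


@dataclass
class ERPParams:
    roi: tuple[str, ...] = OCCIPITAL_ROI
    alpha: float = 0.05
    n_sim: int = 1000


@dataclass
class PipelineConfig:
    n_subjects: int = 5
    n_deviants: int = 40
    ratio: tuple[int, int, int] = (16, 1, 1)
    matched_trials_only: bool = True
    sim: SimConfig | None = None
    # single-precision trial data (group statistics stay double)
    single_precision: bool = True
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    erp: ERPParams = field(default_factory=ERPParams)
    tfr: TFRParams = field(default_factory=TFRParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0

    def validate(self) -> None:
        sim = self.sim or SimConfig.default()
        if self.n_subjects < 3:
            raise PipelineConfigError("n_subjects", "need >= 3 subjects for group statistics")
        if self.tfr.fmax_hz >= sim.sampling_rate_hz / 2:
            raise PipelineConfigError(
                "tfr.fmax_hz",
                f"{self.tfr.fmax_hz} Hz is not below Nyquist ({sim.sampling_rate_hz / 2} Hz)",
            )
        if self.tfr.fmin_hz <= 0 or self.tfr.fstep_hz <= 0 or self.tfr.bandwidth_hz <= 0:
            raise PipelineConfigError("tfr", "fmin, fstep and bandwidth must be positive")
        if self.stats.n_permutations < 100:
            raise PipelineConfigError("stats.n_permutations", "must be >= 100")
        if not 0 < self.stats.cluster_alpha < 1:
            raise PipelineConfigError("stats.cluster_alpha", "must lie in (0, 1)")


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML mapping of the dataclass fields
    (unknown keys rejected with the offending name)."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    sections = {"preproc": PreprocConfig, "erp": ERPParams, "tfr": TFRParams, "stats": StatsParams}
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key, value in raw.items():
        if key not in valid:
            raise PipelineConfigError(key, "unknown configuration field")
        if key in sections and isinstance(value, dict):
            names = {f.name for f in dataclasses.fields(sections[key])}
            bad = set(value) - names
            if bad:
                raise PipelineConfigError(f"{key}.{sorted(bad)[0]}", "unknown configuration field")
            value = sections[key](**{k: tuple(v) if isinstance(v, list) else v for k, v in value.items()})
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_jsonable(dataclasses.asdict(config)), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _subject_data(config: PipelineConfig, sim_template: SimConfig, seed: int):
    """Simulate and preprocess one subject; return ROI waves and the
    per-measure (standard, deviant) maps."""
    rng = np.random.default_rng(seed)
    schedule = generate_schedule(
        config.n_deviants, config.ratio, seed=rng, min_standards_before=2
    )
    sim = dataclasses.replace(sim_template, seed=int(np.random.SeedSequence(seed).generate_state(1)[0] & 0x7FFFFFFF))
    subset = schedule.deviant_and_preceding_standard_indices() if config.matched_trials_only else None
    dtype = np.float32 if config.single_precision else np.float64
    epochs = generate_epochs(schedule, sim, event_subset=subset, dtype=dtype)
    clean, report = preprocess(epochs, config.preproc)

    deviants = clean.pick_condition("deviant")
    matched_standards, match_report = match_standard_trials(clean, schedule)

    roi = config.erp.roi
    erp_std = roi_average(matched_standards, roi).mean(axis=0)
    erp_dev = roi_average(deviants, roi).mean(axis=0)

    freqs = config.tfr.frequencies
    maps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tfr_std = complex_demodulate(matched_standards, freqs, config.tfr.tstep_ms, config.tfr.bandwidth_hz)
    tfr_dev = complex_demodulate(deviants, freqs, config.tfr.tstep_ms, config.tfr.bandwidth_hz)
    baseline = config.preproc.baseline_window_ms
    maps["overall"] = (
        overall_power_change(tfr_std, baseline).values.astype(np.float64),
        overall_power_change(tfr_dev, baseline).values.astype(np.float64),
    )
    maps["induced"] = (
        non_phase_locked_power_change(tfr_std, baseline).values.astype(np.float64),
        non_phase_locked_power_change(tfr_dev, baseline).values.astype(np.float64),
    )
    maps["itpl"] = (
        itpl_change(itpl(tfr_std), baseline).values.astype(np.float64),
        itpl_change(itpl(tfr_dev), baseline).values.astype(np.float64),
    )
    meta = {
        "rejection_fraction": report.fraction,
        "n_matched": match_report.n_matched,
        "times_ms": clean.times_ms,
        "latencies_ms": tfr_std.latencies_ms,
        "channel_names": clean.channel_names,
        "channel_positions": clean.channel_positions,
    }
    return erp_std, erp_dev, maps, meta


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis on a simulated multi-subject study.

    Returns a bundle dict with the ERP result, the three statistical
    maps with significance masks, band-test results, and a provenance
    record (seed, config hash, versions).
    """
    config.validate()
    t_start = time.perf_counter()
    sim_template = config.sim or SimConfig.default()
    master = np.random.SeedSequence(config.seed)
    subject_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in master.spawn(config.n_subjects)]

    erp_std, erp_dev = [], []
    subj_maps: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {m: [] for m in MEASURES}
    meta = None
    rejection = []
    log: list[dict] = []
    for s, seed in enumerate(subject_seeds):
        t0 = time.perf_counter()
        e_std, e_dev, maps, meta = _subject_data(config, sim_template, seed)
        erp_std.append(e_std)
        erp_dev.append(e_dev)
        for m in MEASURES:
            subj_maps[m].append(maps[m])
        rejection.append(meta["rejection_fraction"])
        log.append(
            {
                "stage": "subject",
                "subject": s,
                "rejection_fraction": meta["rejection_fraction"],
                "n_matched": meta["n_matched"],
                "runtime_s": round(time.perf_counter() - t0, 3),
            }
        )

    erp_seed = int(master.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
    dw, sig = detect_vmmn(
        np.array(erp_std),
        np.array(erp_dev),
        meta["times_ms"],
        sim_template.sampling_rate_hz,
        alpha=config.erp.alpha,
        n_sim=config.erp.n_sim,
        seed=erp_seed,
    )
    log.append({"stage": "erp", "n_runs": len(sig.runs), "min_run_samples": sig.min_run_samples})

    adjacency = build_adjacency(meta["channel_positions"])
    measures: dict[str, dict] = {}
    for i, m in enumerate(MEASURES):
        t0 = time.perf_counter()
        std_maps = np.array([pair[0] for pair in subj_maps[m]])
        dev_maps = np.array([pair[1] for pair in subj_maps[m]])
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7, i]))
        cluster = permutation_null(
            dev_maps,
            std_maps,
            adjacency,
            cluster_alpha=config.stats.cluster_alpha,
            n_permutations=config.stats.n_permutations,
            paired=config.stats.paired,
            seed=rng,
            final_alpha=config.stats.final_alpha,
            tail_mode=config.stats.tail_mode,
        )
        rng_b = np.random.default_rng(np.random.SeedSequence([config.seed, 11, i]))
        bands = band_test(
            dev_maps,
            std_maps,
            config.tfr.frequencies,
            adjacency,
            cluster_alpha=config.stats.cluster_alpha,
            n_permutations=config.stats.n_permutations,
            paired=config.stats.paired,
            seed=rng_b,
            final_alpha=config.stats.final_alpha,
            tail_mode=config.stats.tail_mode,
        )
        measures[m] = {
            "standard_maps": std_maps,
            "deviant_maps": dev_maps,
            "cluster": cluster,
            "bands": bands,
        }
        log.append(
            {
                "stage": f"stats.{m}",
                "n_clusters": len(cluster.clusters),
                "n_significant": len(cluster.significant_clusters),
                "runtime_s": round(time.perf_counter() - t0, 3),
            }
        )

    bundle = {
        "config": config,
        "provenance": {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "package_version": __version__,
            "numpy_version": np.__version__,
        },
        "erp": {
            "difference_wave": dw.values,
            "per_subject_waves": dw.per_subject_waves,
            "times_ms": meta["times_ms"],
            "runs_ms": sig.runs,
            "min_run_samples": sig.min_run_samples,
            "autocorrelation": sig.autocorrelation,
            "alpha": sig.alpha,
        },
        "frequencies_hz": config.tfr.frequencies,
        "latencies_ms": meta["latencies_ms"],
        "channel_names": meta["channel_names"],
        "adjacency": adjacency,
        "rejection_fractions": rejection,
        "measures": measures,
        "log": log,
        "runtime_s": round(time.perf_counter() - t_start, 3),
    }
    return bundle


def bundle_summary(bundle: dict) -> dict:
    """Machine-readable summary of a result bundle (JSON-serializable)."""
    out = {
        "provenance": bundle["provenance"],
        "erp": {
            "runs_ms": bundle["erp"]["runs_ms"],
            "min_run_samples": bundle["erp"]["min_run_samples"],
            "autocorrelation": bundle["erp"]["autocorrelation"],
        },
        "measures": {},
    }
    for m, res in bundle["measures"].items():
        cluster: ClusterResult = res["cluster"]
        out["measures"][m] = {
            "n_clusters": len(cluster.clusters),
            "significant": [
                {"summed_t": c.summed_t, "sign": c.sign, "p": c.monte_carlo_p, "n_cells": int(len(c.cells))}
                for c in cluster.significant_clusters
            ],
            "bands": {
                name: {
                    "n_significant": len(r.significant_clusters),
                    "min_p": min((c.monte_carlo_p for c in r.clusters), default=None),
                }
                for name, r in res["bands"].items()
            },
        }
    return _jsonable(out)


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_report(bundle: dict, outdir: str | Path, roi: tuple[str, ...] = OCCIPITAL_ROI) -> list[Path]:
    """Write the figure report: the ERP difference wave with significant
    runs shaded, and per measure the standard / deviant / masked
    difference maps averaged over the occipital ROI (non-significant
    difference cells masked).  Output is deterministic (fixed style, no
    timestamps); returns the manifest of written files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    save_kw = dict(dpi=110, metadata={"Software": "oscmmn"})

    # ERP panel
    fig, ax = plt.subplots(figsize=(7, 3.2))
    t = bundle["erp"]["times_ms"]
    ax.plot(t, bundle["erp"]["difference_wave"], color="k", lw=1.2)
    for lo, hi in bundle["erp"]["runs_ms"]:
        ax.axvspan(lo, hi, color="0.8", zorder=0)
    ax.axhline(0.0, color="0.6", lw=0.6)
    ax.set_xlabel("latency (ms)")
    ax.set_ylabel("deviant − standard (μV)")
    ax.set_title("difference waveform; shaded = significant epochs")
    fig.tight_layout()
    path = outdir / "erp_difference_wave.png"
    fig.savefig(path, **save_kw)
    plt.close(fig)
    written.append(path)

    names = list(bundle["channel_names"])
    roi_idx = [names.index(c) for c in roi if c in names]
    freqs = bundle["frequencies_hz"]
    lats = bundle["latencies_ms"]
    extent = [lats[0], lats[-1], freqs[0], freqs[-1]]

    for m, res in bundle["measures"].items():
        std = res["standard_maps"].mean(axis=0)[roi_idx].mean(axis=0)
        dev = res["deviant_maps"].mean(axis=0)[roi_idx].mean(axis=0)
        diff = dev - std
        sig = res["cluster"].mask[roi_idx].any(axis=0)
        masked = np.ma.masked_where(~sig, diff)
        fig, axes = plt.subplots(1, 3, figsize=(11, 3.0), sharey=True)
        vmax = max(np.abs(std).max(), np.abs(dev).max(), 1e-12)
        for ax, img, title in (
            (axes[0], std, "standard"),
            (axes[1], dev, "deviant"),
        ):
            ax.imshow(img, aspect="auto", origin="lower", extent=extent,
                      cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            ax.set_title(title)
            ax.set_xlabel("latency (ms)")
        dmax = max(np.abs(diff).max(), 1e-12)
        cmap = plt.get_cmap("RdBu_r").copy()
        cmap.set_bad("white")
        axes[2].imshow(masked, aspect="auto", origin="lower", extent=extent,
                       cmap=cmap, vmin=-dmax, vmax=dmax)
        n_sig = len(res["cluster"].significant_clusters)
        axes[2].set_title("difference (masked)" if n_sig else "no significant clusters")
        axes[2].set_xlabel("latency (ms)")
        axes[0].set_ylabel("frequency (Hz)")
        fig.suptitle(m)
        fig.tight_layout()
        path = outdir / f"tfr_{m}.png"
        fig.savefig(path, **save_kw)
        plt.close(fig)
        written.append(path)

    with open(outdir / "summary.json", "w") as f:
        json.dump(bundle_summary(bundle), f, indent=2, sort_keys=True)
    written.append(outdir / "summary.json")
    return written
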