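"""Full feature-comparison experiment.

Orchestrates the whole study on an annotated dataset: a random 50/50
train/test split of the seizures, training of the two eigenfeatures
(initial-5 s ``e_i`` and whole-seizure ``e_w``), per-feature median
threshold calibration, FP/FN/latency evaluation across scaled thresholds
for all seven features (five single bands plus ``u_i`` and ``u_w``),
stable-threshold-range ranking with first-rank counts, and the
training-set-size sensitivity sweep.

The non-seizure record is split in half by windows: the first half feeds
threshold calibration (the ``E_FP`` solver), the held-out second half is
what the reported FP rates are measured on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import AnnotatedDataset, SeizureAnnotation
from .detection import (DEFAULT_SCALES, PerformanceIndices, aggregate_ranks,
                        calibrate, evaluate_at_scales, stable_range)
from .pca import (EigenFeature, FeatureSignal, eigenvector_angle,
                  project_feature, subband_feature, train_eigenfeature)
from .subband import BAND_NAMES, BandEnergySeries, band_energy_series

__all__ = [
    "ExperimentConfig",
    "ComparisonReport",
    "FEATURE_NAMES",
    "split_train_test",
    "run_comparison",
    "sample_size_sweep",
    "render_report",
]

FEATURE_NAMES: tuple[str, ...] = BAND_NAMES + ("u_i", "u_w")


@dataclass
class ExperimentConfig:
    split_seed: int = 0
    train_fraction: float = 0.5
    features: tuple[str, ...] = FEATURE_NAMES
    scales: tuple[float, ...] = DEFAULT_SCALES
    fp_target: float = 0.05
    lat_target_s: float = 2.0
    fn_cutoff_s: float = 5.0
    initial_len_s: float = 5.0
    channel: int = 0
    sweep_sizes: tuple[int, ...] = (10, 20, 30, 50)
    sweep_repeats: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must lie in (0, 1)")
        if 1.0 not in self.scales:
            raise ValueError("the scale list must include 1.0 (Th_1 itself)")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


@dataclass
class ComparisonReport:
    feature_names: tuple[str, ...]
    performance: dict[str, dict[float, PerformanceIndices]]
    th1: dict[str, float]
    widths: np.ndarray              # (n_test_seizures, n_features)
    mean_ranks: np.ndarray
    rank_sds: np.ndarray
    first_rank_counts: np.ndarray
    e_initial: EigenFeature
    e_whole: EigenFeature
    angle_deg: float
    n_train: int
    n_test: int
    seed: int
    config_hash: str

    def rank_of(self, feature: str) -> float:
        return float(self.mean_ranks[self.feature_names.index(feature)])

    def firsts_of(self, feature: str) -> int:
        return int(self.first_rank_counts[self.feature_names.index(feature)])


def split_train_test(dataset: AnnotatedDataset, seed: int,
                     fraction: float = 0.5) -> AnnotatedDataset:
    """Tag each seizure train/test by uniform random partition (in place)."""
    pairs = [(ri, ai) for ri, rec in enumerate(dataset.records)
             for ai in range(len(rec.annotations))]
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least two seizures to split")
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"fraction {fraction} leaves one side empty for n={n}")
    order = np.random.default_rng(seed).permutation(n)
    for k, idx in enumerate(order):
        ri, ai = pairs[idx]
        dataset.records[ri].tags[ai] = "train" if k < n_train else "test"
    return dataset


def _seizure_series(dataset: AnnotatedDataset, cfg: ExperimentConfig
                    ) -> dict[str, list[tuple[BandEnergySeries, SeizureAnnotation]]]:
    out = {"train": [], "test": []}
    for rec in dataset.records:
        if not rec.annotations:
            continue
        series = band_energy_series(rec.recording, cfg.channel)
        for ann, tag in zip(rec.annotations, rec.tags):
            if tag in out:
                out[tag].append((series, ann))
    return out


def _nonseizure_halves(dataset: AnnotatedDataset, cfg: ExperimentConfig
                       ) -> tuple[BandEnergySeries, BandEnergySeries]:
    """Band series of the annotation-free record, split into calibration and
    held-out halves (by windows)."""
    free = [rec for rec in dataset.records if not rec.annotations]
    if not free:
        raise ValueError("dataset has no annotation-free (non-seizure) record")
    series = [band_energy_series(rec.recording, cfg.channel) for rec in free]
    energies = np.vstack([s.energies for s in series])
    starts = np.concatenate([s.window_starts_s for s in series])
    half = energies.shape[0] // 2
    if half == 0:
        raise ValueError("non-seizure record too short to split")
    mk = lambda sl: BandEnergySeries(energies[sl], starts[sl],
                                     series[0].window_len_s, series[0].hop_s,
                                     series[0].fs, series[0].band_names)
    return mk(slice(0, half)), mk(slice(half, None))


def _feature_signal(series: BandEnergySeries, name: str,
                    e_i: EigenFeature, e_w: EigenFeature) -> FeatureSignal:
    if name == "u_i":
        return project_feature(series, e_i, "u_i")
    if name == "u_w":
        return project_feature(series, e_w, "u_w")
    return subband_feature(series, name)


def run_comparison(dataset: AnnotatedDataset, cfg: ExperimentConfig | None = None,
                   seed: int | None = None) -> ComparisonReport:
    """Train, calibrate, and evaluate all seven features on one dataset."""
    cfg = cfg or ExperimentConfig()
    seed = cfg.split_seed if seed is None else seed
    split_train_test(dataset, seed, cfg.train_fraction)
    seiz = _seizure_series(dataset, cfg)
    cal_ns, held_ns = _nonseizure_halves(dataset, cfg)

    e_i = train_eigenfeature(seiz["train"], "initial_5s", cfg.initial_len_s)
    e_w = train_eigenfeature(seiz["train"], "whole", cfg.initial_len_s)

    performance: dict[str, dict[float, PerformanceIndices]] = {}
    th1: dict[str, float] = {}
    widths = np.zeros((len(seiz["test"]), len(cfg.features)))
    for j, name in enumerate(cfg.features):
        train_sigs = [(_feature_signal(s, name, e_i, e_w), a.onset_s)
                      for s, a in seiz["train"]]
        test_sigs = [(_feature_signal(s, name, e_i, e_w), a.onset_s)
                     for s, a in seiz["test"]]
        cal_sig = _feature_signal(cal_ns, name, e_i, e_w)
        held_sig = _feature_signal(held_ns, name, e_i, e_w)
        calib = calibrate(train_sigs, cal_sig, cfg.fp_target, cfg.lat_target_s,
                          cfg.scales)
        th1[name] = calib.th1
        performance[name] = evaluate_at_scales(test_sigs, held_sig, calib.th1,
                                               cfg.scales, cfg.fn_cutoff_s)
        for i, (sig, onset) in enumerate(test_sigs):
            widths[i, j] = stable_range(sig, onset, held_sig, cfg.fp_target,
                                        cfg.lat_target_s).width

    mean_ranks, rank_sds, firsts = aggregate_ranks(widths)
    return ComparisonReport(
        feature_names=tuple(cfg.features), performance=performance, th1=th1,
        widths=widths, mean_ranks=mean_ranks, rank_sds=rank_sds,
        first_rank_counts=firsts, e_initial=e_i, e_whole=e_w,
        angle_deg=eigenvector_angle(e_i.e, e_w.e),
        n_train=len(seiz["train"]), n_test=len(seiz["test"]),
        seed=seed, config_hash=cfg.config_hash)


def sample_size_sweep(dataset: AnnotatedDataset, cfg: ExperimentConfig | None = None,
                      seed: int = 0) -> dict[str, dict[int, dict[str, np.ndarray]]]:
    """Eigenvector stability vs training-set size.

    For each size, ``cfg.sweep_repeats`` random subsets of the training
    seizures (without replacement) are retrained; returns, per segment mode
    and size, the component-wise mean and sd of the dominant eigenvector.
    A size equal to the full pool with identical subsets gives sd 0.
    """
    cfg = cfg or ExperimentConfig()
    if not any(t == "train" for rec in dataset.records for t in rec.tags):
        split_train_test(dataset, cfg.split_seed, cfg.train_fraction)
    seiz = _seizure_series(dataset, cfg)["train"]
    pool = len(seiz)
    rng = np.random.default_rng(seed)
    out: dict[str, dict[int, dict[str, np.ndarray]]] = {
        "initial_5s": {}, "whole": {}}
    for size in cfg.sweep_sizes:
        if size > pool:
            raise ValueError(f"sweep size {size} exceeds training pool {pool}")
        vecs = {"initial_5s": [], "whole": []}
        for _ in range(cfg.sweep_repeats):
            idx = rng.choice(pool, size=size, replace=False)
            subset = [seiz[k] for k in idx]
            for mode in vecs:
                vecs[mode].append(
                    train_eigenfeature(subset, mode, cfg.initial_len_s).e)
        for mode in vecs:
            arr = np.vstack(vecs[mode])
            out[mode][size] = {"mean": arr.mean(axis=0),
                               "sd": arr.std(axis=0, ddof=0)}
    return out


def render_report(report: ComparisonReport, out_dir) -> list[Path]:
    """Write the report as CSV tables + model JSONs + a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for name in report.feature_names:
        for scale, perf in sorted(report.performance[name].items()):
            rows.append({"feature": name, "scale": scale,
                         "fp_pct": perf.fp_pct, "fn_pct": perf.fn_pct,
                         "mean_latency_s": perf.mean_latency_s})
    grid = out / "performance_grid.csv"
    pd.DataFrame(rows).to_csv(grid, index=False)
    written.append(grid)

    ranks = out / "rank_summary.csv"
    pd.DataFrame({"feature": report.feature_names,
                  "mean_rank": report.mean_ranks,
                  "rank_sd": report.rank_sds}).to_csv(ranks, index=False)
    written.append(ranks)

    firsts = out / "first_rank_counts.csv"
    pd.DataFrame({"feature": report.feature_names,
                  "first_ranks": report.first_rank_counts.astype(int)}
                 ).to_csv(firsts, index=False)
    written.append(firsts)

    for feat, fname in ((report.e_initial, "model_initial.json"),
                        (report.e_whole, "model_whole.json")):
        path = out / fname
        feat.to_json(path)
        written.append(path)

    manifest = out / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"seed": report.seed, "config_hash": report.config_hash,
                   "angle_deg": report.angle_deg, "th1": report.th1,
                   "n_train": report.n_train, "n_test": report.n_test},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(manifest)
    return written
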