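"""Threshold detection and its metrology.

A seizure is "detected" at the end of the first feature window at or above
threshold (a window's energy is only known once the window completes, so
the causal detection time is the window *end*).  Latency is the delay from
the annotated onset, clamped at zero when the crossing happens in the
window spanning the onset.  A seizure not detected within 5 s of onset
counts as a false negative; false positives are non-seizure windows whose
feature exceeds threshold (strict ``>``; detection uses ``≥``).

Threshold calibration follows the two-solver recipe: per training seizure,
the candidate threshold is the arithmetic mean of

* ``E_FP = 0.05`` — the smallest observed feature value whose non-seizure
  false-positive rate is ≤ 5%, and
* ``E_Lat = 2`` — the largest threshold still detecting within 2 s (the
  max feature value over windows ending within 2 s of onset),

and the operating threshold Th_1 is the median candidate across training
seizures (mean of the central two for even counts).  The gap between the
two solver outputs is the *stable threshold range*: how much noise margin
a feature leaves between "too many false alarms" and "too slow".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .pca import FeatureSignal

__all__ = [
    "DetectionOutcome",
    "PerformanceIndices",
    "ThresholdCalibration",
    "StableRange",
    "DEFAULT_SCALES",
    "detect_onset",
    "false_positive_rate",
    "threshold_for_fp",
    "threshold_for_latency",
    "calibrate",
    "evaluate_at_scales",
    "stable_range",
    "rank_features",
    "aggregate_ranks",
    "normalize_against_threshold",
]

#: Scale sweep around the median threshold Th_1.
DEFAULT_SCALES: tuple[float, ...] = (0.2, 0.5, 0.8, 1.0, 1.2, 1.5, 2.0)

FN_CUTOFF_S = 5.0


@dataclass
class DetectionOutcome:
    detected: bool
    detect_time_s: float | None
    latency_s: float | None
    is_fn: bool


@dataclass
class PerformanceIndices:
    fp_pct: float
    fn_pct: float
    mean_latency_s: float  # over non-FN detections only; NaN if none


@dataclass
class ThresholdCalibration:
    """Per-seizure (Th_FP, Th_Lat, candidate) triples and their median."""

    per_seizure: list[tuple[float, float, float]]
    th1: float
    scales: tuple[float, ...] = DEFAULT_SCALES

    @property
    def candidates(self) -> np.ndarray:
        return np.array([c for _, _, c in self.per_seizure])


@dataclass
class StableRange:
    low: float    # threshold at E_FP
    high: float   # threshold at E_Lat
    width: float = field(init=False)

    def __post_init__(self) -> None:
        self.width = max(0.0, self.high - self.low)


def detect_onset(sig: FeatureSignal, threshold: float, onset_s: float,
                 search_start_s: float | None = None,
                 fn_cutoff_s: float = FN_CUTOFF_S) -> DetectionOutcome:
    """First-crossing detection relative to an annotated onset.

    Windows whose end falls after ``search_start_s`` (default: the onset)
    are scanned in order for ``u_n ≥ threshold``.
    """
    if sig.n_windows == 0:
        raise ValueError("empty feature signal")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if search_start_s is None:
        search_start_s = onset_s
    ends = sig.window_ends_s
    eligible = np.nonzero(ends > search_start_s)[0]
    hits = eligible[sig.values[eligible] >= threshold]
    if hits.size == 0:
        return DetectionOutcome(False, None, None, True)
    t = float(ends[hits[0]])
    latency = max(0.0, t - onset_s)
    return DetectionOutcome(True, t, latency, latency > fn_cutoff_s)


def false_positive_rate(nonseizure_sig: FeatureSignal, threshold: float) -> float:
    """Percent of non-seizure windows with feature strictly above threshold."""
    if nonseizure_sig.n_windows == 0:
        raise ValueError("empty non-seizure signal")
    return 100.0 * float(np.count_nonzero(nonseizure_sig.values > threshold)
                         ) / nonseizure_sig.n_windows


def threshold_for_fp(nonseizure_sig: FeatureSignal,
                     target_fp: float = 0.05) -> float:
    """Smallest observed feature value with FP rate ≤ target.

    Candidates are the observed values themselves (an exact order
    statistic, not a continuous grid): the smallest value with at most
    ``target·W`` values strictly above it.  At the maximum observed value
    the strict-``>`` count is zero, so a solution always exists.
    """
    if not 0 < target_fp < 1:
        raise ValueError(f"target FP must be in (0, 1), got {target_fp}")
    u = nonseizure_sig.values
    if u.size == 0:
        raise ValueError("empty non-seizure signal")
    allowed = int(np.floor(target_fp * u.size))
    # k-th largest leaves k-1 values strictly above it (fewer under ties)
    order = np.sort(u)[::-1]
    return float(order[min(allowed, u.size - 1)])


def threshold_for_latency(seizure_sig: FeatureSignal, onset_s: float,
                          target_lat_s: float = 2.0) -> float:
    """Largest threshold that still detects within ``target_lat_s``.

    This is the max of u_n over windows ending in ``(onset, onset + target]``.
    """
    ends = seizure_sig.window_ends_s
    sel = (ends > onset_s) & (ends <= onset_s + target_lat_s + 1e-9)
    if not np.any(sel):
        raise ValueError(
            f"no window ends within ({onset_s}, {onset_s + target_lat_s}] s")
    return float(seizure_sig.values[sel].max())


def calibrate(train_seizure_sigs, nonseizure_sig: FeatureSignal,
              fp_target: float = 0.05, lat_target_s: float = 2.0,
              scales: tuple[float, ...] = DEFAULT_SCALES) -> ThresholdCalibration:
    """Median-of-candidates calibration over training seizures.

    ``train_seizure_sigs`` is a list of ``(FeatureSignal, onset_s)`` pairs.
    """
    train_seizure_sigs = list(train_seizure_sigs)
    if not train_seizure_sigs:
        raise ValueError("at least one training seizure required")
    th_fp = threshold_for_fp(nonseizure_sig, fp_target)
    per = []
    for sig, onset in train_seizure_sigs:
        th_lat = threshold_for_latency(sig, onset, lat_target_s)
        per.append((th_fp, th_lat, 0.5 * (th_fp + th_lat)))
    th1 = float(np.median([c for _, _, c in per]))
    return ThresholdCalibration(per, th1, tuple(scales))


def evaluate_at_scales(test_seizure_sigs, nonseizure_sig: FeatureSignal,
                       th1: float, scales: tuple[float, ...] = DEFAULT_SCALES,
                       fn_cutoff_s: float = FN_CUTOFF_S
                       ) -> dict[float, PerformanceIndices]:
    """FP/FN/latency at each multiple of the median threshold."""
    if th1 <= 0:
        raise ValueError(f"Th_1 must be positive, got {th1}")
    test_seizure_sigs = list(test_seizure_sigs)
    out: dict[float, PerformanceIndices] = {}
    for s in scales:
        th = s * th1
        fp = false_positive_rate(nonseizure_sig, th)
        latencies, n_fn = [], 0
        for sig, onset in test_seizure_sigs:
            res = detect_onset(sig, th, onset, fn_cutoff_s=fn_cutoff_s)
            if res.is_fn:
                n_fn += 1
            else:
                latencies.append(res.latency_s)
        fn_pct = 100.0 * n_fn / len(test_seizure_sigs) if test_seizure_sigs else 0.0
        mean_lat = float(np.mean(latencies)) if latencies else float("nan")
        out[s] = PerformanceIndices(fp, fn_pct, mean_lat)
    return out


def stable_range(seizure_sig: FeatureSignal, onset_s: float,
                 nonseizure_sig: FeatureSignal, fp_target: float = 0.05,
                 lat_target_s: float = 2.0) -> StableRange:
    """Threshold range from E_FP to E_Lat for one seizure; width ≥ 0."""
    low = threshold_for_fp(nonseizure_sig, fp_target)
    high = threshold_for_latency(seizure_sig, onset_s, lat_target_s)
    return StableRange(low, high)


def rank_features(widths: np.ndarray) -> np.ndarray:
    """Rank one seizure's per-feature stable-range widths (1 = widest).

    Ties receive the mean of the tied rank positions.
    """
    widths = np.asarray(widths, dtype=float)
    if widths.size < 2:
        raise ValueError("ranking needs at least two features")
    return rankdata(-widths, method="average")


def aggregate_ranks(per_seizure_widths: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean rank, rank SD, and first-rank counts across seizures.

    ``per_seizure_widths`` has shape ``(n_seizures, n_features)``.  A
    feature earns a first rank whenever its width equals the seizure's
    maximum (each member of a tie counts).
    """
    w = np.atleast_2d(np.asarray(per_seizure_widths, dtype=float))
    ranks = np.vstack([rank_features(row) for row in w])
    firsts = (w >= w.max(axis=1, keepdims=True) - 1e-12).sum(axis=0)
    return ranks.mean(axis=0), ranks.std(axis=0, ddof=0), firsts


def normalize_against_threshold(sig: FeatureSignal, th: float) -> FeatureSignal:
    """Feature scaled by its threshold: values > 1 flag FP windows."""
    if th <= 0:
        raise ValueError(f"threshold must be positive, got {th}")
    return FeatureSignal(sig.values / th, sig.window_starts_s,
                         sig.window_len_s, f"{sig.feature_name}_normalized")
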