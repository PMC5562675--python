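"""Dominant-eigenvector detection features.

The pooled second-moment matrix of the band-energy vectors over training
seizures,

    C = (1/N) Σ_n X_n X_nᵀ,

is eigendecomposed, C e = λ e, and the eigenvector with the largest
eigenvalue is the trained feature.  No mean is subtracted: the energy
vectors are far from zero-mean, and it is the principal *energy
direction*, not the principal variance direction, that characterizes the
ictal spectrum.  Two segment modes are compared: windows from the initial
5 s after onset (``e_i``) and windows spanning whole seizures (``e_w``).

The detection feature signal is the projection u_n = e · X_n.  Because C
is entrywise nonnegative, its dominant eigenvector admits an entrywise
nonnegative representative (Perron–Frobenius); the orientation chosen here
makes the largest-magnitude component positive.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import SeizureAnnotation
from .subband import BAND_NAMES, BandEnergySeries

__all__ = [
    "SecondMomentAccumulator",
    "EigenFeature",
    "FeatureSignal",
    "select_segment_windows",
    "accumulate_second_moment",
    "dominant_eigenvector",
    "project_feature",
    "subband_feature",
    "eigenvector_angle",
    "train_eigenfeature",
]

_TIE_TOL = 1e-10
_TOL_S = 1e-6  # window/annotation time comparisons


@dataclass
class SecondMomentAccumulator:
    """Running C = (1/N) Σ X_n X_nᵀ over nonnegative energy vectors."""

    dim: int = 5
    _sum: np.ndarray = field(init=False)
    count: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self._sum = np.zeros((self.dim, self.dim))

    def add(self, vectors: np.ndarray) -> "SecondMomentAccumulator":
        v = np.atleast_2d(np.asarray(vectors, dtype=float))
        if v.shape[1] != self.dim:
            raise ValueError(f"expected {self.dim}-component vectors, got {v.shape}")
        self._sum += v.T @ v
        self.count += v.shape[0]
        return self

    @property
    def matrix(self) -> np.ndarray:
        if self.count == 0:
            raise ValueError("no windows accumulated")
        return self._sum / self.count


@dataclass
class EigenFeature:
    """Unit-norm dominant eigenvector with its eigenvalue and provenance."""

    e: np.ndarray
    lam: float
    segment_mode: str  # "initial_5s" | "whole"
    n_windows: int = 0
    band_names: tuple[str, ...] = BAND_NAMES

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        norm = np.linalg.norm(self.e)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError(f"eigenvector must be unit norm, got ‖e‖={norm}")

    @property
    def dominant_band(self) -> str:
        return self.band_names[int(np.argmax(self.e))]

    def to_json(self, path=None, extra_config: dict | None = None) -> str:
        payload = {
            "bands": list(self.band_names),
            "e": [float(v) for v in self.e],
            "lambda": float(self.lam),
            "segment_mode": self.segment_mode,
            "n_windows": int(self.n_windows),
        }
        payload["config_hash"] = hashlib.sha256(
            json.dumps({**payload, **(extra_config or {})},
                       sort_keys=True).encode()).hexdigest()[:16]
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "EigenFeature":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.array(payload["e"]), payload["lambda"],
                   payload["segment_mode"], payload.get("n_windows", 0),
                   tuple(payload["bands"]))


@dataclass
class FeatureSignal:
    """A scalar detection feature aligned to band-energy windows."""

    values: np.ndarray
    window_starts_s: np.ndarray
    window_len_s: float
    feature_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts_s = np.asarray(self.window_starts_s, dtype=float)
        if self.values.shape != self.window_starts_s.shape:
            raise ValueError("values and window starts must align")

    @property
    def n_windows(self) -> int:
        return self.values.size

    @property
    def window_ends_s(self) -> np.ndarray:
        return self.window_starts_s + self.window_len_s


def select_segment_windows(series: BandEnergySeries, ann: SeizureAnnotation,
                           mode: str, initial_len_s: float = 5.0) -> np.ndarray:
    """Indices of windows fully inside the chosen seizure segment.

    ``initial_5s``: windows with ``start ≥ onset`` and
    ``start + window_len ≤ onset + initial_len_s``; ``whole``: likewise with
    the seizure offset as the right edge.  Partial windows are dropped.
    """
    if mode not in ("initial_5s", "whole"):
        raise ValueError(f"unknown segment mode {mode!r}")
    right = ann.onset_s + initial_len_s if mode == "initial_5s" else ann.offset_s
    starts = series.window_starts_s
    sel = (starts >= ann.onset_s - _TOL_S) & (
        starts + series.window_len_s <= right + _TOL_S)
    idx = np.nonzero(sel)[0]
    if idx.size == 0:
        raise ValueError(
            f"no whole {series.window_len_s} s window fits in segment "
            f"[{ann.onset_s}, {right}] s")
    return idx


def accumulate_second_moment(window_sets, dim: int = 5,
                             center: bool = False) -> SecondMomentAccumulator:
    """Pool windows from all training seizures into one second-moment matrix.

    ``window_sets`` is an iterable of ``(K_j, dim)`` arrays (one per
    seizure).  Set ``center=True`` to subtract the pooled mean first
    (sensitivity studies only; the default is the uncentered moment).
    """
    acc = SecondMomentAccumulator(dim)
    pooled = []
    for vs in window_sets:
        vs = np.atleast_2d(np.asarray(vs, dtype=float))
        pooled.append(vs)
    if not pooled or sum(v.shape[0] for v in pooled) == 0:
        raise ValueError("empty training pool")
    stacked = np.vstack(pooled)
    if center:
        stacked = stacked - stacked.mean(axis=0)
    acc.add(stacked)
    return acc


def dominant_eigenvector(C: np.ndarray, segment_mode: str = "whole",
                         n_windows: int = 0,
                         band_names: tuple[str, ...] = BAND_NAMES) -> EigenFeature:
    """Eigenpair of symmetric PSD ``C`` with the largest eigenvalue.

    Orientation makes the largest-magnitude component positive.  If the top
    two eigenvalues tie within 1e-10 (relative), a warning is raised and the
    smallest eigh index among the tied pairs is kept, deterministically.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"C must be square, got shape {C.shape}")
    if not np.allclose(C, C.T, atol=1e-10 * max(1.0, np.abs(C).max())):
        raise ValueError("C must be symmetric")
    vals, vecs = np.linalg.eigh(C)  # ascending
    scale = max(vals[-1], np.finfo(float).tiny)
    tied = np.nonzero(vals >= vals[-1] - _TIE_TOL * scale)[0]
    if tied.size > 1:
        warnings.warn(
            f"dominant eigenvalue is degenerate ({tied.size}-fold within "
            f"{_TIE_TOL:g} relative); keeping the lowest-index eigenpair",
            stacklevel=2)
    pick = int(tied.min())
    lam = float(vals[pick])
    e = vecs[:, pick]
    if e[np.argmax(np.abs(e))] < 0:
        e = -e
    return EigenFeature(e, lam, segment_mode, n_windows, band_names)


def project_feature(series: BandEnergySeries, feat: EigenFeature,
                    name: str | None = None) -> FeatureSignal:
    """u_n = e · X_n for every window."""
    if series.energies.shape[1] != feat.e.size:
        raise ValueError(
            f"dimension mismatch: series has {series.energies.shape[1]} bands, "
            f"eigenvector has {feat.e.size}")
    if name is None:
        name = "u_i" if feat.segment_mode == "initial_5s" else "u_w"
    return FeatureSignal(series.energies @ feat.e, series.window_starts_s,
                         series.window_len_s, name)


def subband_feature(series: BandEnergySeries, band_name: str) -> FeatureSignal:
    """Single-band comparator: u_n is one component of X_n."""
    return FeatureSignal(series.band(band_name), series.window_starts_s,
                         series.window_len_s, band_name)


def eigenvector_angle(e1: np.ndarray, e2: np.ndarray) -> float:
    """Axis angle between two feature vectors, in degrees ∈ [0°, 90°].

    Computed from the normalized dot product; the sign-free axis angle
    min(θ, 180° − θ) is reported since eigenvectors have no intrinsic sign.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    n1, n2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot take the angle with a zero vector")
    cos = np.clip(e1 @ e2 / (n1 * n2), -1.0, 1.0)
    theta = np.degrees(np.arccos(cos))
    return float(min(theta, 180.0 - theta))


def train_eigenfeature(series_and_anns, mode: str,
                       initial_len_s: float = 5.0,
                       center: bool = False) -> EigenFeature:
    """Train e_i or e_w from ``(BandEnergySeries, SeizureAnnotation)`` pairs."""
    window_sets = []
    for series, ann in series_and_anns:
        idx = select_segment_windows(series, ann, mode, initial_len_s)
        window_sets.append(series.energies[idx])
    acc = accumulate_second_moment(window_sets, center=center)
    return dominant_eigenvector(acc.matrix, mode, acc.count)
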