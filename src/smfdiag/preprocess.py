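"""Raw profile spectra -> cohort feature matrix (the serum metabolic fingerprint).

The chain is smooth -> baseline-correct -> local-maxima peak detection ->
cross-sample m/z alignment -> normalization -> cosine-similarity QC. Peak
absence after alignment is encoded as 0 (absence of an ion is informative in
LDI-MS and keeps the matrix dense for L1 models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "RawSpectrum",
    "PeakList",
    "FeatureMatrix",
    "smooth",
    "correct_baseline",
    "detect_peaks",
    "align_peaks",
    "normalize",
    "cosine_qc",
    "preprocess_spectrum",
    "build_feature_matrix",
]


@dataclass
class RawSpectrum:
    """One sample's profile spectrum: strictly increasing m/z axis + intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class PeakList:
    """Detected peaks of one sample: (mz, intensity, snr), mz ascending."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if np.any(np.diff(self.mz) < 0):
            raise ValueError("peak mz must be sorted ascending")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class FeatureMatrix:
    """Cohort table of aligned peak intensities (samples x m/z features)."""

    values: np.ndarray
    feature_mz: np.ndarray
    sample_ids: list[str]
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.values.shape != (len(self.sample_ids), len(self.feature_mz)):
            raise ValueError("values shape inconsistent with sample_ids/feature_mz")
        if np.any(np.diff(self.feature_mz) < 0):
            raise ValueError("feature_mz must be sorted ascending")
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length must match sample count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{m:.4f}" for m in self.feature_mz],
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, labels=None) -> "FeatureMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            feature_mz=np.asarray([float(c) for c in df.columns]),
            sample_ids=[str(i) for i in df.index],
            labels=list(labels) if labels is not None else None,
        )


def smooth(spectrum: RawSpectrum, window: int = 7, polyorder: int = 2) -> RawSpectrum:
    """Savitzky-Golay smoothing on the same axis, clipped at zero.

    ``window=1`` is an explicit pass-through. Otherwise the window must be odd,
    larger than ``polyorder`` and no longer than the spectrum.
    """
    if window == 1:
        return replace(spectrum)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if window > len(spectrum):
        raise ValueError("smoothing window exceeds spectrum length")
    sm = savgol_filter(spectrum.intensity, window, polyorder)
    return RawSpectrum(spectrum.mz, np.clip(sm, 0.0, None), spectrum.sample_id)


def correct_baseline(spectrum: RawSpectrum, half_window: int = 100) -> RawSpectrum:
    """Subtract a morphological (rolling min then max) baseline estimate.

    The opening with a window of ``2*half_window + 1`` points tracks any
    baseline that varies slowly relative to the window while passing under
    peaks that are narrow relative to it, so planted peak heights survive
    within a few percent.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    size = 2 * half_window + 1
    base = maximum_filter1d(
        minimum_filter1d(spectrum.intensity, size=size, mode="nearest"),
        size=size,
        mode="nearest",
    )
    corrected = np.clip(spectrum.intensity - base, 0.0, None)
    return RawSpectrum(spectrum.mz, corrected, spectrum.sample_id)


def _noise_floor(intensity: np.ndarray) -> tuple[float, float]:
    """Robust (floor, scale) of the signal-free bulk of a spectrum.

    Peaks occupy a small fraction of a profile spectrum, so the median and MAD
    of all points are dominated by noise; 1.4826 rescales MAD to a Gaussian
    sd. The floor (median) matters because non-negative detector noise leaves
    a positive offset after baseline correction; peak SNR is measured above
    it. If the MAD degenerates to 0 (more than half the points exactly equal),
    the positive points alone are retried.
    """
    med = float(np.median(intensity))
    scale = 1.4826 * float(np.median(np.abs(intensity - med)))
    if scale == 0:
        pos = intensity[intensity > med]
        # Retry on the above-median points only when they are plentiful
        # (half-clipped noise); in a noiseless spectrum the few positive
        # points are peaks, not noise, and the scale must stay 0.
        if len(pos) > 0.2 * len(intensity):
            scale = 1.4826 * float(np.median(np.abs(pos - np.median(pos))))
    return med, scale


def detect_peaks(
    spectrum: RawSpectrum,
    snr_min: float = 3.0,
    min_separation: float = 0.045,
) -> PeakList:
    """Strict local-maxima peak picking with an SNR floor.

    A peak is a point strictly above both neighbours (plateaus are resolved to
    their midpoint). Peaks closer than ``min_separation`` (Da) are thinned
    keeping the more intense. SNR = (height - noise floor) / noise scale, with
    floor and scale estimated robustly (median / scaled MAD) over the
    spectrum's signal-free bulk; when the scale is zero (noiseless input)
    every local maximum above the floor is kept.
    """
    n = len(spectrum)
    if n == 0:
        return PeakList(np.empty(0), np.empty(0), np.empty(0), spectrum.sample_id)
    step = float(np.median(np.diff(spectrum.mz))) if n > 1 else 1.0
    distance = max(1, int(np.ceil(min_separation / step)))
    floor, noise = _noise_floor(spectrum.intensity)
    height = floor + snr_min * noise if noise > 0 else floor + np.finfo(float).tiny
    idx, props = find_peaks(spectrum.intensity, height=height, distance=distance)
    if len(idx) == 0:
        return PeakList(np.empty(0), np.empty(0), np.empty(0), spectrum.sample_id)
    heights = props["peak_heights"]
    snr = (heights - floor) / noise if noise > 0 else np.full(len(idx), np.inf)
    return PeakList(spectrum.mz[idx], heights, snr, spectrum.sample_id)


def _split_cluster(mz: np.ndarray, start: int, stop: int, tol: float, bounds: list):
    """Split [start, stop) at its largest internal gaps until every piece has
    width <= tol (iterative; chained clusters can be very long)."""
    stack = [(start, stop)]
    while stack:
        a, b = stack.pop()
        if mz[b - 1] - mz[a] <= tol or b - a == 1:
            bounds.append((a, b))
            continue
        cut = a + 1 + int(np.argmax(np.diff(mz[a:b])))
        stack.append((cut, b))
        stack.append((a, cut))


def align_peaks(
    peaklists: Sequence[PeakList],
    tolerance: float = 0.1,
    labels: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """Cluster peak m/z across samples into features; absent peaks become 0.

    Single-linkage clustering: pooled peaks are chained wherever consecutive
    m/z gaps are <= ``tolerance``; chains wider than ``tolerance`` are split
    recursively at their largest internal gap. Each sample contributes at most
    one peak per feature (nearest to the feature center wins); the feature m/z
    is the intensity-weighted mean of its member peaks.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if len(peaklists) == 0:
        raise ValueError("need at least one PeakList")

    sample_ids = [pl.sample_id for pl in peaklists]
    all_mz = np.concatenate([pl.mz for pl in peaklists])
    all_int = np.concatenate([pl.intensity for pl in peaklists])
    all_sample = np.concatenate(
        [np.full(len(pl), i, dtype=np.int64) for i, pl in enumerate(peaklists)]
    )
    if len(all_mz) == 0:
        return FeatureMatrix(
            np.zeros((len(peaklists), 0)), np.empty(0), sample_ids,
            list(labels) if labels is not None else None,
        )

    order = np.argsort(all_mz, kind="stable")
    mz_s, int_s, samp_s = all_mz[order], all_int[order], all_sample[order]

    breaks = np.flatnonzero(np.diff(mz_s) > tolerance) + 1
    bounds: list[tuple[int, int]] = []
    for start, stop in zip(np.r_[0, breaks], np.r_[breaks, len(mz_s)]):
        _split_cluster(mz_s, start, stop, tolerance, bounds)

    n_feat = len(bounds)
    values = np.zeros((len(peaklists), n_feat))
    feature_mz = np.empty(n_feat)
    for f, (a, b) in enumerate(sorted(bounds)):
        w = int_s[a:b]
        m = mz_s[a:b]
        center = float(np.average(m, weights=w)) if w.sum() > 0 else float(m.mean())
        feature_mz[f] = center
        # nearest-to-center peak per sample
        dist = np.abs(m - center)
        for k in np.argsort(dist, kind="stable"):
            s = samp_s[a + k]
            if values[s, f] == 0.0:
                values[s, f] = w[k]
    return FeatureMatrix(
        values, feature_mz, sample_ids, list(labels) if labels is not None else None
    )


def normalize(matrix: FeatureMatrix, method: str = "tic") -> FeatureMatrix:
    """Row normalization of the feature matrix.

    ``tic``: each sample is scaled to unit total ion current, then rescaled by
    the cohort-median total so values stay on the raw intensity scale.
    ``none``: identity. All-zero rows are left as zeros with a warning.
    """
    if matrix.n_samples == 0 or matrix.n_features == 0:
        raise ValueError("matrix must be non-empty")
    if method == "none":
        return replace(matrix, values=matrix.values.copy())
    if method != "tic":
        raise ValueError(f"unknown normalization method: {method!r}")
    totals = matrix.values.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        warnings.warn(f"{zero.sum()} all-zero sample row(s) left unnormalized")
    median_total = np.median(totals[~zero]) if np.any(~zero) else 1.0
    scale = np.where(zero, 0.0, median_total / np.where(zero, 1.0, totals))
    return replace(matrix, values=matrix.values * scale[:, None])


def cosine_qc(matrix: FeatureMatrix, labels: Optional[Sequence[str]] = None) -> np.ndarray:
    """Per-sample cosine similarity to its own group's mean fingerprint.

    The group mean excludes the sample itself (leave-one-out), so identical
    rows score exactly 1 and a zero-norm row scores 0 (with a warning). Each
    group needs at least two samples.
    """
    labels = list(labels) if labels is not None else matrix.labels
    if labels is None:
        raise ValueError("labels required (argument or matrix.labels)")
    labels_arr = np.asarray(labels)
    X = matrix.values
    # Unit-normalize rows first so the score is invariant to per-sample
    # positive scaling (the group mean is a mean of directions, not of raw
    # rows). Zero-norm rows stay zero and score 0.
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if np.any(zero):
        for i in np.flatnonzero(zero):
            warnings.warn(f"zero-norm row for sample {matrix.sample_ids[i]}")
    U = X / np.where(zero, 1.0, norms)[:, None]
    scores = np.zeros(matrix.n_samples)
    for g in np.unique(labels_arr):
        idx = np.flatnonzero(labels_arr == g)
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        G = U[idx]
        total = G.sum(axis=0)
        for j, i in enumerate(idx):
            ref = total - G[j]  # leave-one-out mean direction (scale-free)
            num = float(G[j] @ ref)
            den = float(np.linalg.norm(G[j]) * np.linalg.norm(ref))
            scores[i] = num / den if den > 0 else 0.0
    return scores


def preprocess_spectrum(
    spectrum: RawSpectrum,
    smooth_window: int = 7,
    smooth_polyorder: int = 2,
    baseline_half_window: int = 100,
    snr_min: float = 3.0,
    min_separation: float = 0.045,
) -> PeakList:
    """smooth -> correct_baseline -> detect_peaks for one spectrum."""
    s = smooth(spectrum, smooth_window, smooth_polyorder)
    s = correct_baseline(s, baseline_half_window)
    return detect_peaks(s, snr_min=snr_min, min_separation=min_separation)


def filter_features(matrix: FeatureMatrix, min_fraction: float = 0.25) -> FeatureMatrix:
    """Drop features detected in fewer than ``min_fraction`` of samples.

    A single spectrum's local-maxima search at a moderate SNR threshold
    accepts some noise maxima (a 120,000-point profile offers tens of
    thousands of candidate maxima, so a 3-sigma rule alone cannot be clean);
    genuine peak species recur across samples while noise maxima land at
    random m/z, so cross-sample prevalence separates them.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    need = int(np.ceil(min_fraction * matrix.n_samples))
    keep = (matrix.values > 0).sum(axis=0) >= max(need, 1)
    return FeatureMatrix(
        matrix.values[:, keep],
        matrix.feature_mz[keep],
        matrix.sample_ids,
        matrix.labels,
    )


def build_feature_matrix(
    spectra: Iterable[RawSpectrum],
    labels: Optional[Sequence[str]] = None,
    tolerance: float = 0.1,
    norm_method: str = "tic",
    min_fraction: float = 0.25,
    **preprocess_kwargs,
) -> FeatureMatrix:
    """Full preprocessing of a cohort (streams spectra one at a time):
    per-spectrum smoothing/baseline/peak detection, cross-sample alignment,
    prevalence filtering, normalization."""
    peaklists = [preprocess_spectrum(s, **preprocess_kwargs) for s in spectra]
    matrix = align_peaks(peaklists, tolerance=tolerance, labels=labels)
    matrix = filter_features(matrix, min_fraction)
    return normalize(matrix, method=norm_method)
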