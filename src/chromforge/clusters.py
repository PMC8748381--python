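"""Summary traces and baseline segmentation of chromatograms.

Because nothing is known about the mixture a priori, peak picking runs on a
wavelength-agnostic summary trace: the maxplot (per-time maximum over all UV
channels) or the TIC (per-scan sum of MS intensities).  The trace is smoothed
by local polynomial regression (Savitzky-Golay); baseline stretches are
points whose smoothed value stays below a noise multiple for a minimum
number of consecutive samples, and the maximal non-baseline stretches in
between become peak clusters.  Composite clusters are split further at deep
interior valleys so each unit handed to curve resolution stays small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .chromio import Chromatogram, Detector

__all__ = [
    "SummaryTrace",
    "PeakCluster",
    "maxplot",
    "tic",
    "segment",
    "split_at_minima",
    "segment_chromatogram",
]


@dataclass
class SummaryTrace:
    time: np.ndarray
    value: np.ndarray
    kind: str  # "maxplot" | "tic"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("trace time/value length mismatch")


@dataclass
class PeakCluster:
    """A half-open index window [i_start, i_end) of one run's matrix."""

    run_id: str
    i_start: int
    i_end: int
    time: np.ndarray  # time slice
    submatrix: np.ndarray  # (i_end - i_start, n_channel)
    apex_times: list[float]
    noise_level: float

    def __post_init__(self) -> None:
        if self.i_start >= self.i_end:
            raise ValueError("empty cluster window")

    @property
    def n_points(self) -> int:
        return self.i_end - self.i_start


def maxplot(chrom: Chromatogram) -> SummaryTrace:
    """Per-time-point maximum over all wavelength channels, clipped at 0."""
    if chrom.detector is not Detector.UV:
        raise ValueError("maxplot is defined for UV data")
    value = np.clip(chrom.intensity.max(axis=1), 0.0, None)
    return SummaryTrace(chrom.time, value, "maxplot")


def tic(chrom: Chromatogram) -> SummaryTrace:
    """Total ion chromatogram: per-scan sum over all m/z channels."""
    if chrom.detector is not Detector.MS:
        raise ValueError("tic is defined for MS data")
    return SummaryTrace(chrom.time, chrom.intensity.sum(axis=1), "tic")


def _baseline_stats(ys: np.ndarray) -> tuple[float, float]:
    """Robust (level, noise) of the trace's quiescent floor.

    Peaks occupy a minority of samples, so the median of the smoothed trace
    sits on the baseline; the noise is 1.4826 x the median absolute negative
    deviation (the lower side is peak-free by construction).  Note a maxplot
    has a positive noise floor — the max of many noisy channels — which is
    exactly what the level term absorbs.
    """
    base = float(np.median(ys))
    neg = ys[ys <= base] - base
    if neg.size == 0:
        return base, 0.0
    sigma = 1.4826 * float(np.median(np.abs(neg)))
    return base, sigma


def segment(
    trace: SummaryTrace,
    chrom: Chromatogram,
    smooth_window: int = 11,
    noise_k: float = 3.0,
    min_points: int = 5,
    polyorder: int = 3,
) -> list[PeakCluster]:
    """Cut the trace into baseline-delimited peak clusters.

    Negative trace values are clipped to zero first.  Points whose smoothed
    value stays <= noise_k * noise for at least ``min_points`` consecutive
    samples are baseline; maximal non-baseline stretches become clusters.
    Apexes are local maxima of the smoothed trace where its second derivative
    is negative.  An all-baseline trace yields an empty list.
    """
    y = np.clip(trace.value, 0.0, None)
    if y.size <= smooth_window:
        raise ValueError("trace shorter than the smoothing window")
    win = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
    ys = savgol_filter(y, win, polyorder)
    d2 = savgol_filter(y, win, polyorder, deriv=2)
    base, noise = _baseline_stats(ys)
    # relative floor keeps numerically-tiny smoothing ripple out of the
    # cluster set when the data are (near) noiseless
    thr = base + max(noise_k * noise, 1e-4 * max(ys.max() - base, 0.0))

    below = ys <= thr
    baseline = np.zeros_like(below)
    # only stretches of >= min_points consecutive below-threshold samples
    # count as baseline
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_points:
                baseline[i:j] = True
            i = j
        else:
            i += 1

    clusters: list[PeakCluster] = []
    i = 0
    while i < n:
        if not baseline[i]:
            j = i
            while j < n and not baseline[j]:
                j += 1
            if j - i < min_points:
                # above-threshold excursions too short to be chromatographic
                # peaks at the advised >= 5 points/s sampling are noise blips
                i = j
                continue
            # pad by one point into the baseline so boundaries are baseline
            lo = max(i - 1, 0)
            hi = min(j + 1, n)
            apexes = _find_apexes(ys, d2, lo, hi, trace.time)
            if apexes:  # stretches with no resolvable apex are noise blips
                clusters.append(
                    PeakCluster(
                        run_id=chrom.run_id,
                        i_start=lo,
                        i_end=hi,
                        time=chrom.time[lo:hi],
                        submatrix=np.clip(chrom.intensity[lo:hi], 0.0, None),
                        apex_times=apexes,
                        noise_level=noise,
                    )
                )
            i = j
        else:
            i += 1
    return clusters


def _find_apexes(
    ys: np.ndarray, d2: np.ndarray, lo: int, hi: int, time: np.ndarray
) -> list[float]:
    apexes = []
    for i in range(max(lo, 1), min(hi, ys.size - 1)):
        if ys[i] >= ys[i - 1] and ys[i] > ys[i + 1] and d2[i] < 0:
            apexes.append(float(time[i]))
    return apexes


def split_at_minima(
    cluster: PeakCluster, trace: SummaryTrace, valley_ratio: float = 0.5
) -> list[PeakCluster]:
    """Split a composite cluster at deep interior valleys.

    A valley qualifies when the smoothed trace at an interior local minimum
    drops below ``valley_ratio`` times the smaller of the two adjacent apex
    heights.  Pieces tile the parent window exactly.
    """
    y = np.clip(trace.value[cluster.i_start : cluster.i_end], 0.0, None)
    n = y.size
    if n < 5:
        return [cluster]
    win = min(11, n - 1 if (n - 1) % 2 == 1 else n - 2)
    if win < 5:
        ys = y
    else:
        ys = savgol_filter(y, win, min(3, win - 1))

    # local maxima/minima of the smoothed slice
    cuts: list[int] = []
    i = 1
    while i < n - 1:
        if ys[i] < ys[i - 1] and ys[i] <= ys[i + 1]:
            left_apex = ys[:i].max()
            right_apex = ys[i + 1 :].max()
            lower = min(left_apex, right_apex)
            if lower > 0 and ys[i] < valley_ratio * lower:
                cuts.append(i)
        i += 1
    if not cuts:
        return [cluster]

    pieces: list[PeakCluster] = []
    bounds = [0] + cuts + [n]
    for a, b in zip(bounds, bounds[1:]):
        lo = cluster.i_start + a
        hi = cluster.i_start + b
        apexes = [t for t in cluster.apex_times if trace.time[lo] <= t < trace.time[hi - 1] + 1e-12]
        pieces.append(
            PeakCluster(
                run_id=cluster.run_id,
                i_start=lo,
                i_end=hi,
                time=cluster.time[a:b],
                submatrix=cluster.submatrix[a:b],
                apex_times=apexes,
                noise_level=cluster.noise_level,
            )
        )
    return pieces


def segment_chromatogram(
    chrom: Chromatogram,
    smooth_window: int = 11,
    noise_k: float = 3.0,
    min_points: int = 5,
    valley_ratio: float = 0.5,
) -> list[PeakCluster]:
    """maxplot/TIC -> segment -> split, in one call."""
    trace = maxplot(chrom) if chrom.detector is Detector.UV else tic(chrom)
    out: list[PeakCluster] = []
    for cl in segment(trace, chrom, smooth_window, noise_k, min_points):
        out.extend(split_at_minima(cl, trace, valley_ratio))
    return out
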