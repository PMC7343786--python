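"""Displacement waveforms derived from contour trajectories.

Six waveform sets feed the synchronisation analysis: the arterial wall
diameter (the most clearly cyclic vertical AWL–PWL distance), the radial and
longitudinal displacements of the plaque top and bottom surfaces, and the
per-pair plaque radial distances.  Plaque contours are trimmed 25 pixels at
each end so that only plaque tissue — and no adjacent normal wall — enters
the analysis; all series are high-pass filtered (4th-order Butterworth,
0.6 Hz cutoff, applied forward–backward so lags are not biased) to remove
baseline drift while leaving heart rates above ~40 bpm untouched; and the
cross-correlations downstream are confined to one average cardiac cycle,
whose length comes from the dominant frequency of the wall-diameter series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    DegenerateWaveformError,
    NoDominantFrequencyError,
    TooShortPlaqueError,
    TooShortSeriesError,
)
from .tracking import PixelTrajectory

__all__ = [
    "TimeSeries",
    "CycleWindow",
    "trim_plaque_edges",
    "wall_diameter",
    "radial_displacements",
    "longitudinal_displacements",
    "plaque_radial_distance",
    "highpass",
    "dominant_frequency",
]

KINDS = (
    "wall_diameter",
    "PTS_radial",
    "PTS_longitudinal",
    "PBS_radial",
    "PBS_longitudinal",
    "plaque_radial_distance",
)


@dataclass
class TimeSeries:
    """One displacement or distance waveform sampled at the frame rate."""

    values: np.ndarray
    frame_rate: float
    kind: str = "wall_diameter"
    units: str = "px"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a time series needs >= 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series values must be finite")

    def __len__(self) -> int:
        return self.values.size

    def replace(self, values: np.ndarray, **meta) -> "TimeSeries":
        return TimeSeries(
            values, self.frame_rate, self.kind, self.units, {**self.meta, **meta}
        )


@dataclass(frozen=True)
class CycleWindow:
    """One average cardiac cycle of the recording.

    ``length = round(frame_rate / f0)`` samples; ``start`` is the first
    usable wall-diameter minimum after the filter warm-up.
    """

    f0: float
    length: int
    start: int

    def slice(self) -> slice:
        return slice(self.start, self.start + self.length)


def trim_plaque_edges(traj: PixelTrajectory, n_trim: int = 25) -> PixelTrajectory:
    """Drop ``n_trim`` pixels from each end of a plaque surface contour.

    Raises :class:`TooShortPlaqueError` when fewer than one pixel would
    survive (pixel count <= 2 * n_trim).
    """
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    if n_trim == 0:
        return traj
    if traj.n_pixels <= 2 * n_trim:
        raise TooShortPlaqueError(
            f"{traj.name}: {traj.n_pixels} pixels cannot lose {n_trim} from "
            "each edge"
        )
    sl = slice(n_trim, traj.n_pixels - n_trim)
    return PixelTrajectory(traj.name, traj.rows[sl], traj.cols[sl], traj.frame_rate)


def _match_columns(a: PixelTrajectory, b: PixelTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Indices of vertically aligned pixel pairs (equal frame-1 column)."""
    ca, cb = a.initial_cols, b.initial_cols
    common, ia, ib = np.intersect1d(ca, cb, return_indices=True)
    return ia[np.argsort(common)], ib[np.argsort(common)]


def _cyclicity(values: np.ndarray, frame_rate: float, band: tuple[float, float]) -> float:
    """Fraction of (DC-free) periodogram power within +-1 bin of the in-band
    peak — the operational score for 'most clear cyclic motion'."""
    f, p = signal.periodogram(values - values.mean(), fs=frame_rate)
    f, p = f[1:], p[1:]
    total = p.sum()
    if total <= 0:
        return np.nan
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        return np.nan
    i = np.flatnonzero(mask)[np.argmax(p[mask])]
    return float(p[max(i - 1, 0) : i + 2].sum() / total)


def wall_diameter(
    awl: PixelTrajectory,
    pwl: PixelTrajectory,
    band: tuple[float, float] = (0.6, 3.0),
) -> TimeSeries:
    """The most clearly cyclic vertical AWL–PWL distance series.

    Per-frame radial distances are formed for every vertically aligned
    AWL–PWL pixel pair, and the pair whose periodogram concentrates the most
    power at its in-band peak is returned.  When every candidate is constant
    the cyclicity is undefined: the first series is returned with a
    ``cyclicity`` of NaN and a warning.
    """
    ia, ib = _match_columns(awl, pwl)
    if ia.size == 0:
        raise DegenerateWaveformError("AWL and PWL share no column")
    diam = np.abs(pwl.rows[ib] - awl.rows[ia])  # (pairs, frames)
    scores = np.array([_cyclicity(d, awl.frame_rate, band) for d in diam])
    if np.all(np.isnan(scores)):
        warnings.warn(
            "all wall-diameter candidates are constant; cyclicity undefined",
            stacklevel=2,
        )
        best = 0
    else:
        best = int(np.nanargmax(scores))
    return TimeSeries(
        diam[best],
        awl.frame_rate,
        kind="wall_diameter",
        meta={
            "column": int(awl.initial_cols[ia[best]]),
            "cyclicity": float(scores[best]) if not np.isnan(scores[best]) else np.nan,
        },
    )


def radial_displacements(traj: PixelTrajectory, kind: str) -> list[TimeSeries]:
    """Waveforms (ii)/(iv): per-pixel radial positions across frames."""
    return [
        TimeSeries(traj.rows[p], traj.frame_rate, kind=kind,
                   meta={"column": int(traj.initial_cols[p])})
        for p in range(traj.n_pixels)
    ]


def longitudinal_displacements(traj: PixelTrajectory, kind: str) -> list[TimeSeries]:
    """Waveforms (iii)/(v): per-pixel longitudinal positions across frames."""
    return [
        TimeSeries(traj.cols[p], traj.frame_rate, kind=kind,
                   meta={"column": int(traj.initial_cols[p])})
        for p in range(traj.n_pixels)
    ]


def plaque_radial_distance(
    pts: PixelTrajectory, pbs: PixelTrajectory
) -> list[TimeSeries]:
    """Waveform (vi): |PTS radial − PBS radial| per vertical pixel pair."""
    ia, ib = _match_columns(pts, pbs)
    if ia.size == 0:
        raise DegenerateWaveformError("PTS and PBS share no column")
    dist = np.abs(pts.rows[ia] - pbs.rows[ib])
    return [
        TimeSeries(dist[k], pts.frame_rate, kind="plaque_radial_distance",
                   meta={"column": int(pts.initial_cols[ia[k]])})
        for k in range(ia.size)
    ]


def highpass(ts: TimeSeries, cutoff: float = 0.6, order: int = 4) -> TimeSeries:
    """Zero-phase high-pass Butterworth filter.

    Applied forward–backward (``sosfiltfilt``) so the filter contributes no
    phase shift to the lag estimates; the effective magnitude response is
    the squared single-pass Butterworth response.
    """
    nyq = ts.frame_rate / 2.0
    if not (0 < cutoff < nyq):
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff, btype="highpass", fs=ts.frame_rate,
                        output="sos")
    # sosfiltfilt needs > 3 * (padlen) samples
    ntaps = 2 * (sos.shape[0] * 2 + 1)
    if len(ts) <= 3 * ntaps:
        raise TooShortSeriesError(
            f"series of {len(ts)} samples is shorter than the filter warm-up"
        )
    return ts.replace(signal.sosfiltfilt(sos, ts.values), highpassed=cutoff)


def dominant_frequency(
    ts: TimeSeries,
    band: tuple[float, float] = (0.6, 3.0),
    peak_factor: float = 10.0,
) -> CycleWindow:
    """Average cardiac cycle window from the wall-diameter periodogram.

    The dominant frequency is the in-band periodogram peak; it must stand
    ``peak_factor`` times above the median spectral level, otherwise there is
    no dominant cyclic component and :class:`NoDominantFrequencyError` is
    raised.  The window starts at the first local minimum of the series that
    leaves one full window of warm-up before it and one window after it.
    """
    fs = ts.frame_rate
    n = len(ts)
    if n < fs / band[0]:
        raise TooShortSeriesError("series shorter than one period at the band edge")
    f, p = signal.periodogram(ts.values - ts.values.mean(), fs=fs)
    f, p = f[1:], p[1:]
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any() or p.sum() <= 0:
        raise NoDominantFrequencyError("no spectral estimate inside the band")
    i = np.flatnonzero(mask)[np.argmax(p[mask])]
    floor = np.median(p)
    if floor > 0 and p[i] < peak_factor * floor:
        raise NoDominantFrequencyError(
            "in-band periodogram peak does not rise above the noise floor"
        )
    f0 = float(f[i])
    length = int(round(fs / f0))
    if length > n:
        raise NoDominantFrequencyError("cycle window longer than the recording")

    lo, hi = length, max(n - length, length + 1)
    v = ts.values
    start = None
    for k in range(max(lo, 1), min(hi, n - length)):
        if v[k] <= v[k - 1] and v[k] <= v[k + 1]:
            start = k
            break
    if start is None:
        seg_end = max(n - length, lo + 1)
        start = lo + int(np.argmin(v[lo:seg_end]))
    return CycleWindow(f0=f0, length=length, start=start)
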