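"""Cross-correlation phase-shift features of plaque motion.

Synchronisation between tissue areas is quantified with the mean-subtracted,
denominator-normalised cross-correlation

    r_d = sum_i (x(i) - m_x)(y(i-d) - m_y)
          / sqrt(sum_i (x(i) - m_x)^2) / sqrt(sum_i (y(i) - m_y)^2)

evaluated over all lags d = -(L-1) ... (L-1) of the windowed series (the
sequence is twice as long as the series, minus one).  The normalisation makes
the self-correlation equal 1 at lag 0; subtracting the means makes waveforms
from different subjects comparable.  From each correlation sequence two
measurements are read off: the sign of the maximum-absolute peak (positive =
in-phase motion, negative = a 180° phase opposition) and its absolute lag
``d_max`` in seconds, the phase shift.

Three correlation types are computed per plaque —

* CC1: plaque radial deformation against the wall diameter,
* CC2: radial displacements of the plaque top vs bottom surface,
* CC3: longitudinal displacements of top vs bottom surface —

and summarised into 24 features: per type, the synchronisation percentage
(fraction of pixel pairs with a positive peak) plus seven statistics of the
d_max distribution (max, min, mean, median, standard deviation, skewness,
excess kurtosis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FeatureExtractionError, UndefinedCorrelationError
from .tracking import PixelTrajectory
from .waveforms import (
    CycleWindow,
    TimeSeries,
    dominant_frequency,
    highpass,
    longitudinal_displacements,
    plaque_radial_distance,
    radial_displacements,
)

__all__ = [
    "CrossCorrelationSeries",
    "PeakMeasurement",
    "PlaqueFeatureVector",
    "FEATURE_NAMES",
    "cross_correlate",
    "peak_measurement",
    "synchronisation_percentage",
    "lag_statistics",
    "windowed",
    "estimate_pair_delay",
    "plaque_features",
]

CC_TYPES = ("CC1", "CC2", "CC3")
STAT_NAMES = ("max", "min", "mean", "median", "stdev", "skewness", "kurtosis")
FEATURE_NAMES = tuple(
    f"{s}_{cc}" for cc in CC_TYPES for s in ("sp",) + STAT_NAMES
)


@dataclass
class CrossCorrelationSeries:
    """Normalized cross-correlation over all lags of two windowed series."""

    r: np.ndarray  # (2L - 1,)
    lags: np.ndarray  # samples, -(L-1) ... (L-1)
    frame_rate: float
    cc_type: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.lags = np.asarray(self.lags, dtype=int)
        if self.r.shape != self.lags.shape:
            raise ValueError("r and lags must align")


@dataclass(frozen=True)
class PeakMeasurement:
    """Sign and absolute lag (s) of the maximum-|r| correlation peak."""

    sign: int
    d_max: float


def cross_correlate(
    x: TimeSeries, y: TimeSeries, cc_type: str = ""
) -> CrossCorrelationSeries:
    """Normalized cross-correlation of two equal-length series at all lags.

    Positive lag d means the second series is taken ``d`` samples earlier
    (``y(i - d)``).  Constant inputs make the normalising denominator zero
    and raise :class:`UndefinedCorrelationError`.
    """
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if x.frame_rate != y.frame_rate:
        raise ValueError("series must share a sampling rate")
    xc = x.values - x.values.mean()
    yc = y.values - y.values.mean()
    # one accumulation kernel (dot) for numerator and denominator, and a
    # single square root of the product: for x = y the lag-0 coefficient is
    # then exactly 1 in floating point (sqrt(s*s) == s, round-to-nearest)
    denom = np.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
    if denom <= 1e-30:
        raise UndefinedCorrelationError(
            "constant input: cross-correlation denominator is zero"
        )
    n = len(x)
    lags = np.arange(-(n - 1), n)
    num = np.empty(lags.size)
    for k, d in enumerate(lags):
        if d >= 0:
            num[k] = np.dot(xc[d:], yc[: n - d])
        else:
            num[k] = np.dot(xc[: n + d], yc[-d:])
    return CrossCorrelationSeries(num / denom, lags, x.frame_rate, cc_type)


def peak_measurement(cc: CrossCorrelationSeries) -> PeakMeasurement:
    """Sign and absolute lag of the maximum-absolute correlation peak.

    Ties in |r| are broken toward the smallest |lag| (favouring synchrony),
    then toward the positive lag.
    """
    a = np.abs(cc.r)
    top = a.max()
    if top <= 0:
        raise UndefinedCorrelationError("all-zero cross-correlation series")
    cand = np.flatnonzero(a >= top - 1e-12)
    order = np.lexsort((-cc.lags[cand], np.abs(cc.lags[cand])))
    i = cand[order[0]]
    sign = 1 if cc.r[i] > 0 else -1
    return PeakMeasurement(sign=sign, d_max=abs(int(cc.lags[i])) / cc.frame_rate)


def synchronisation_percentage(signs) -> float:
    """Percentage of positive peak signs over all PTS–PBS pairs."""
    signs = np.asarray(list(signs))
    if signs.size == 0:
        raise ValueError("empty sign list")
    return 100.0 * float(np.count_nonzero(signs > 0)) / signs.size


def lag_statistics(lags) -> dict[str, float]:
    """Seven histogram-based statistics of the d_max values (seconds).

    Standard deviation uses the n-1 (sample) convention; skewness and excess
    kurtosis are standardised central moments, defined as 0 for a constant
    sample.
    """
    lags = np.asarray(list(lags), dtype=float)
    if lags.size == 0:
        raise ValueError("empty lag list")
    if np.ptp(lags) == 0:
        sd = skew = kurt = 0.0
    else:
        sd = float(np.std(lags, ddof=1)) if lags.size > 1 else 0.0
        skew = float(stats.skew(lags, bias=True))
        kurt = float(stats.kurtosis(lags, fisher=True, bias=True))
    return {
        "max": float(lags.max()),
        "min": float(lags.min()),
        "mean": float(lags.mean()),
        "median": float(np.median(lags)),
        "stdev": sd,
        "skewness": skew,
        "kurtosis": kurt,
    }


def windowed(ts: TimeSeries, window: CycleWindow) -> TimeSeries:
    """Confine a series to the average cardiac cycle window."""
    sl = window.slice()
    if sl.stop > len(ts):
        raise ValueError("cycle window exceeds the series length")
    return ts.replace(ts.values[sl], window_start=window.start,
                      window_length=window.length)


def estimate_pair_delay(
    x: TimeSeries,
    y: TimeSeries,
    cutoff: float = 0.6,
    order: int = 4,
    band: tuple[float, float] = (0.6, 3.0),
) -> PeakMeasurement:
    """Phase shift between two displacement waveforms.

    Convenience wrapper running the per-pair pipeline: zero-phase high-pass,
    cycle-window estimation from the first series, windowing, normalized
    cross-correlation and peak measurement.
    """
    xf = highpass(x, cutoff, order)
    yf = highpass(y, cutoff, order)
    win = dominant_frequency(xf, band)
    return peak_measurement(cross_correlate(windowed(xf, win), windowed(yf, win)))


@dataclass
class PlaqueFeatureVector:
    """The 24 synchronisation features of one plaque, plus optional labels."""

    features: dict[str, float]
    labels: dict[str, str] = field(default_factory=dict)
    pair_signs: dict[str, np.ndarray] = field(default_factory=dict)
    pair_lags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.features)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")

    def to_array(self) -> np.ndarray:
        return np.array([self.features[k] for k in FEATURE_NAMES])

    def to_dict(self) -> dict[str, float]:
        return {k: self.features[k] for k in FEATURE_NAMES}


def _pair_series(
    pts: PixelTrajectory, pbs: PixelTrajectory
) -> dict[str, list[tuple[TimeSeries, TimeSeries]]]:
    """Waveform pairs per correlation type, matched by frame-1 column."""
    cols = np.intersect1d(pts.initial_cols, pbs.initial_cols)
    idx_t = {c: i for i, c in enumerate(pts.initial_cols)}
    idx_b = {c: i for i, c in enumerate(pbs.initial_cols)}
    t_rad = radial_displacements(pts, "PTS_radial")
    b_rad = radial_displacements(pbs, "PBS_radial")
    t_lon = longitudinal_displacements(pts, "PTS_longitudinal")
    b_lon = longitudinal_displacements(pbs, "PBS_longitudinal")
    dist = {s.meta["column"]: s for s in plaque_radial_distance(pts, pbs)}
    pairs: dict[str, list] = {"CC2": [], "CC3": [], "dist": []}
    for c in cols:
        it, ib = idx_t[c], idx_b[c]
        pairs["CC2"].append((t_rad[it], b_rad[ib]))
        pairs["CC3"].append((t_lon[it], b_lon[ib]))
        pairs["dist"].append(dist[c])
    return pairs


def plaque_features(
    wall: TimeSeries,
    pts: PixelTrajectory,
    pbs: PixelTrajectory,
    cutoff: float = 0.6,
    order: int = 4,
    band: tuple[float, float] = (0.6, 3.0),
    labels: dict[str, str] | None = None,
) -> PlaqueFeatureVector:
    """Assemble the 24-feature synchronisation vector of one plaque.

    Inputs are the representative wall-diameter series and the *trimmed*
    plaque top/bottom surface trajectories.  All waveforms are high-pass
    filtered, confined to one average cardiac cycle estimated from the wall
    diameter, cross-correlated per vertical pixel pair, and the peak signs
    and lags summarised per correlation type.  Pairs whose waveforms are
    constant (undefined correlation) are dropped; a type left with no valid
    pair raises :class:`FeatureExtractionError` naming it.
    """
    wall_f = highpass(wall, cutoff, order)
    win = dominant_frequency(wall_f, band)
    wall_w = windowed(wall_f, win)

    pairs = _pair_series(pts, pbs)
    signs: dict[str, list[int]] = {cc: [] for cc in CC_TYPES}
    lags: dict[str, list[float]] = {cc: [] for cc in CC_TYPES}

    def correlate_pair(a: TimeSeries, b: TimeSeries, cc: str) -> None:
        try:
            af = windowed(highpass(a, cutoff, order), win)
            bf = windowed(highpass(b, cutoff, order), win)
            pm = peak_measurement(cross_correlate(af, bf, cc))
        except UndefinedCorrelationError:
            return
        signs[cc].append(pm.sign)
        lags[cc].append(pm.d_max)

    # CC1: each plaque radial-distance series against the wall diameter
    for d in pairs["dist"]:
        try:
            df = windowed(highpass(d, cutoff, order), win)
            pm = peak_measurement(cross_correlate(df, wall_w, "CC1"))
        except UndefinedCorrelationError:
            continue
        signs["CC1"].append(pm.sign)
        lags["CC1"].append(pm.d_max)
    for a, b in pairs["CC2"]:
        correlate_pair(a, b, "CC2")
    for a, b in pairs["CC3"]:
        correlate_pair(a, b, "CC3")

    features: dict[str, float] = {}
    for cc in CC_TYPES:
        if not lags[cc]:
            raise FeatureExtractionError(f"no valid waveform pair for {cc}")
        features[f"sp_{cc}"] = synchronisation_percentage(signs[cc])
        for name, value in lag_statistics(lags[cc]).items():
            features[f"{name}_{cc}"] = value

    return PlaqueFeatureVector(
        features=features,
        labels=labels or {},
        pair_signs={cc: np.array(signs[cc]) for cc in CC_TYPES},
        pair_lags={cc: np.array(lags[cc]) for cc in CC_TYPES},
    )
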