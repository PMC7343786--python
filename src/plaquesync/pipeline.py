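"""End-to-end pipeline: image sequence + contours -> 24-feature vector.

Glue for the per-stage modules: track the four annotated interfaces, trim
the plaque contours, build the wall-diameter waveform, and compute the
synchronisation features.
"""

from __future__ import annotations

from .errors import TooShortPlaqueError
from .sync import PlaqueFeatureVector, plaque_features
from .tracking import ImageSequence, ROIContour, TrackerConfig, track_rois
from .waveforms import wall_diameter

__all__ = ["extract_plaque_features"]


def extract_plaque_features(
    seq: ImageSequence,
    contours: dict[str, ROIContour],
    cfg: TrackerConfig | None = None,
    n_trim: int = 25,
    cutoff: float = 0.6,
    order: int = 4,
    band: tuple[float, float] = (0.6, 3.0),
    labels: dict[str, str] | None = None,
) -> PlaqueFeatureVector:
    """Run tracking, waveform construction and feature extraction.

    ``contours`` must provide the four interfaces AWL, PWL, PTS and PBS
    annotated in the first frame.
    """
    missing = {"AWL", "PWL", "PTS", "PBS"} - set(contours)
    if missing:
        raise ValueError(f"missing contours: {sorted(missing)}")
    # plaque edges are trimmed before tracking: pixels are tracked
    # independently, so this is equivalent to trimming the trajectories
    # afterwards and skips the edge pixels the analysis discards anyway
    to_track = [contours["AWL"], contours["PWL"]]
    for name in ("PTS", "PBS"):
        c = contours[name]
        if c.pixels.shape[0] <= 2 * n_trim:
            raise TooShortPlaqueError(
                f"{name}: {c.pixels.shape[0]} pixels cannot lose {n_trim} "
                "from each edge"
            )
        sl = slice(n_trim, c.pixels.shape[0] - n_trim) if n_trim else slice(None)
        to_track.append(ROIContour(name, c.pixels[sl]))
    trajs = track_rois(seq, to_track, cfg)
    pts = trajs["PTS"]
    pbs = trajs["PBS"]
    wall = wall_diameter(trajs["AWL"], trajs["PWL"], band)
    return plaque_features(
        wall, pts, pbs, cutoff=cutoff, order=order, band=band, labels=labels
    )
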