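"""Grayscale normalisation and plaque echogenicity (GSM).

B-mode grayscale is scanner- and setting-dependent, so intensities are
linearly re-mapped against two physician-selected reference regions: the
median of a blood region becomes 0 and the median of an adventitia region
becomes 190, the standard normalisation for plaque characterisation.  The
plaque's grayscale median (GSM) is then computed in every frame inside the
region enclosed by the tracked top and bottom surface contours, averaged
over frames, and thresholded: plaques with GSM < 25 are echolucent
(dark, lipid-rich appearance), those with GSM >= 25 echogenic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon

from .errors import DegenerateRegionError, NormalisationError
from .tracking import ImageSequence, PixelTrajectory

__all__ = [
    "ReferenceRegions",
    "GSMResult",
    "normalise_grayscale",
    "plaque_gsm",
    "ECHOLUCENT_THRESHOLD",
]

ECHOLUCENT_THRESHOLD = 25.0
ADVENTITIA_TARGET = 190.0


@dataclass
class ReferenceRegions:
    """Frame-1 pixel sets for the blood and adventitia references."""

    blood: np.ndarray  # (K, 2) of (row, col)
    adventitia: np.ndarray  # (M, 2)

    def __post_init__(self) -> None:
        self.blood = np.atleast_2d(np.asarray(self.blood, dtype=int))
        self.adventitia = np.atleast_2d(np.asarray(self.adventitia, dtype=int))
        if self.blood.size == 0 or self.adventitia.size == 0:
            raise ValueError("reference regions must be non-empty")
        b = {tuple(p) for p in self.blood}
        a = {tuple(p) for p in self.adventitia}
        if b & a:
            raise ValueError("blood and adventitia regions must be disjoint")

    def medians(self, frame: np.ndarray) -> tuple[float, float]:
        mb = float(np.median(frame[self.blood[:, 0], self.blood[:, 1]]))
        ma = float(np.median(frame[self.adventitia[:, 0], self.adventitia[:, 1]]))
        return mb, ma


@dataclass(frozen=True)
class GSMResult:
    """Per-frame and overall plaque grayscale medians with the label."""

    per_frame: np.ndarray
    gsm: float
    label: str  # 'echolucent' or 'echogenic'


def normalise_grayscale(
    frame: np.ndarray,
    refs: ReferenceRegions,
    adventitia_target: float = ADVENTITIA_TARGET,
    clip: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Affine intensity map sending median(blood) -> 0, median(adventitia)
    -> ``adventitia_target`` (190), clipped to the 8-bit range."""
    frame = np.asarray(frame, dtype=float)
    mb, ma = refs.medians(frame)
    if ma <= mb:
        raise NormalisationError(
            f"adventitia median ({ma}) must exceed blood median ({mb})"
        )
    # divide before scaling: a pixel equal to the adventitia median maps to
    # exactly adventitia_target ((ma-mb)/(ma-mb) == 1 in floating point)
    out = (frame - mb) / (ma - mb) * adventitia_target
    return np.clip(out, *clip)


def _plaque_mask(
    shape: tuple[int, int],
    pts_rows: np.ndarray,
    pts_cols: np.ndarray,
    pbs_rows: np.ndarray,
    pbs_cols: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixels inside the polygon bounded by PTS (top, left-to-right) and PBS
    (bottom, right-to-left), contour positions rounded per frame."""
    poly_r = np.concatenate([np.round(pts_rows), np.round(pbs_rows[::-1])])
    poly_c = np.concatenate([np.round(pts_cols), np.round(pbs_cols[::-1])])
    return polygon(poly_r, poly_c, shape=shape)


def plaque_gsm(
    seq: ImageSequence,
    pts: PixelTrajectory,
    pbs: PixelTrajectory,
    refs: ReferenceRegions,
    min_pixels: int = 10,
) -> GSMResult:
    """Plaque GSM over the sequence and the echolucent/echogenic label.

    The affine normalisation is anchored on the reference-region medians of
    the first frame and applied to every frame; the plaque is located per
    frame from the tracked PTS/PBS contours, its GSM is the median of the
    normalised intensities inside, and the plaque GSM is the mean of the
    per-frame GSMs.
    """
    if pts.n_frames != seq.n_frames or pbs.n_frames != seq.n_frames:
        raise ValueError("trajectories must cover every frame of the sequence")
    mb, ma = refs.medians(seq.frames[0])
    if ma <= mb:
        raise NormalisationError(
            f"adventitia median ({ma}) must exceed blood median ({mb})"
        )
    per_frame = np.empty(seq.n_frames)
    for t in range(seq.n_frames):
        rr, cc = _plaque_mask(
            seq.shape, pts.rows[:, t], pts.cols[:, t], pbs.rows[:, t], pbs.cols[:, t]
        )
        if rr.size < min_pixels:
            raise DegenerateRegionError(
                f"plaque region has {rr.size} px (< {min_pixels}) in frame {t}"
            )
        norm = np.clip(
            (seq.frames[t, rr, cc] - mb) / (ma - mb) * ADVENTITIA_TARGET,
            0.0, 255.0,
        )
        per_frame[t] = np.median(norm)

    gsm = float(per_frame.mean())
    label = "echolucent" if gsm < ECHOLUCENT_THRESHOLD else "echogenic"
    return GSMResult(per_frame=per_frame, gsm=gsm, label=label)
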