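"""Synthetic phantoms for plaque motion-synchronisation analysis.

Clinical B-mode recordings of carotid plaques are not distributable, so this
module generates the three kinds of inputs the pipeline consumes, each with
known ground truth:

* displacement *waveform pairs* with a controllable phase delay between them
  (the quantity the synchronisation features must recover),
* speckle-textured *image sequences* in which the arterial walls and a plaque
  move with pulsatile, possibly phase-delayed waveforms, together with the
  exact trajectory of every annotated contour pixel, and
* labelled *cohort tables* of synchronisation features drawn from per-group
  distributions, for testing the statistical and classification stages.

The cardiac waveform is a sum of harmonics of a fundamental in the normal
resting heart-rate band with 1/k amplitude decay, normalised to unit peak.
Speckle is modelled as spatially correlated multiplicative noise on a
piecewise-constant tissue reflectivity map — adequate for block-matching
realism without acoustic simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import CohortSpecError, GenerationError, InvalidModelError
from .tracking import ImageSequence, PixelTrajectory, ROIContour
from .waveforms import TimeSeries

__all__ = [
    "MotionModel",
    "PhantomGeometry",
    "CohortSpec",
    "cardiac_waveform",
    "generate_waveform_pair",
    "generate_image_sequence",
    "generate_cohort",
    "write_image_sequence",
    "write_contours_csv",
    "write_trajectories_csv",
    "write_cohort_csv",
    "write_model_spec",
]


@dataclass(frozen=True)
class MotionModel:
    """Generative counterpart of the acquisition and physiology parameters.

    Defaults correspond to a resting subject imaged at 25 frames/s: a 0.9 Hz
    cardiac fundamental (54 bpm) with three harmonics, sub-millimetre radial
    and longitudinal excursions, slow low-amplitude baseline drift standing in
    for breathing/transducer motion, and small measurement noise.
    """

    fundamental_freq: float = 0.9  # Hz
    n_harmonics: int = 3
    radial_amp: float = 0.4  # mm, peak displacement
    longitudinal_amp: float = 0.25  # mm
    top_bottom_delay: float = 0.0  # s, PTS delayed relative to PBS
    wall_plaque_delay: float = 0.0  # s, plaque delayed relative to wall
    drift_amp: float = 0.05  # mm
    drift_freq: float = 0.2  # Hz, must stay below 0.3
    noise_sd: float = 0.01  # mm
    duration: float = 4.0  # s, >= 3 cardiac cycles
    frame_rate: float = 25.0  # frames/s
    seed: int = 0

    def validate(self) -> None:
        if self.fundamental_freq <= self.drift_freq:
            raise InvalidModelError(
                f"fundamental_freq ({self.fundamental_freq} Hz) must exceed "
                f"drift_freq ({self.drift_freq} Hz)"
            )
        if self.drift_freq >= 0.3:
            raise InvalidModelError("drift_freq must be < 0.3 Hz")
        if self.frame_rate <= 2 * self.fundamental_freq * self.n_harmonics:
            raise InvalidModelError(
                "frame_rate must exceed twice the highest harmonic frequency"
            )
        if self.duration < 3.0 / self.fundamental_freq:
            raise InvalidModelError(
                f"duration {self.duration} s is shorter than 3 cardiac cycles "
                f"({3.0 / self.fundamental_freq:.2f} s)"
            )
        if self.noise_sd < 0 or self.drift_amp < 0:
            raise InvalidModelError("noise_sd and drift_amp must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def cardiac_waveform(model: MotionModel, t: np.ndarray) -> np.ndarray:
    """Unit-peak pulsatile waveform: sum of harmonics with 1/k amplitude decay."""
    ks = np.arange(1, model.n_harmonics + 1)
    b = np.sum(
        np.cos(2 * np.pi * np.outer(ks, model.fundamental_freq * t)) / ks[:, None],
        axis=0,
    )
    return b / np.sum(1.0 / ks)


def generate_waveform_pair(
    model: MotionModel,
) -> tuple[TimeSeries, TimeSeries, float]:
    """Two pulsatile displacement waveforms, the second delayed.

    Returns ``(bottom, top, delay)`` where ``top`` is the same cardiac
    waveform delayed by ``model.top_bottom_delay`` seconds; each series gets
    its own drift-phase and noise realisation.  The returned delay is the
    ground truth for downstream lag recovery.
    """
    model.validate()
    rng = np.random.default_rng(model.seed)
    t = model.times()

    x = model.radial_amp * cardiac_waveform(model, t)
    y = model.radial_amp * cardiac_waveform(
        model, t - model.top_bottom_delay
    )
    for v in (x, y):
        phase = rng.uniform(0, 2 * np.pi)
        v += model.drift_amp * np.sin(2 * np.pi * model.drift_freq * t + phase)
        v += rng.normal(0.0, model.noise_sd, size=t.size)

    bottom = TimeSeries(x, model.frame_rate, kind="PBS_radial", units="mm")
    top = TimeSeries(y, model.frame_rate, kind="PTS_radial", units="mm")
    return bottom, top, model.top_bottom_delay


@dataclass(frozen=True)
class PhantomGeometry:
    """Layout and echo intensities of the simulated longitudinal section.

    Rows are the radial (depth) axis, columns the longitudinal axis.  A
    plaque protrudes from the posterior wall into the lumen: in depth order
    AWL < PTS < PBS <= PWL.  Intensities are on the 8-bit grayscale.
    """

    image_size: tuple[int, int] = (160, 160)  # (rows, cols)
    pixels_per_mm: float = 12.0
    awl_depth_mm: float = 3.0
    pwl_depth_mm: float = 10.0
    plaque_center_col_mm: float | None = None  # defaults to image centre
    plaque_extent_mm: float = 9.2
    pts_apex_depth_mm: float = 7.4
    pbs_depth_mm: float = 9.2
    min_thickness_mm: float = 0.3
    lumen_intensity: float = 15.0
    adventitia_intensity: float = 190.0
    plaque_intensity: float = 60.0
    wall_intensity: float = 120.0
    speckle_corr_px: float = 1.5
    speckle_strength: float = 0.35
    frame_noise_sd: float = 2.0

    def validate(self) -> None:
        h, w = self.image_size
        if not (0 < self.awl_depth_mm < self.pts_apex_depth_mm
                < self.pbs_depth_mm <= self.pwl_depth_mm):
            raise InvalidModelError(
                "depth ordering must satisfy AWL < PTS apex < PBS <= PWL"
            )
        if self.pwl_depth_mm * self.pixels_per_mm >= h - 1:
            raise InvalidModelError("posterior wall deeper than the image")
        if self.plaque_extent_mm * self.pixels_per_mm >= w:
            raise InvalidModelError("plaque wider than the image")
        if self.adventitia_intensity <= self.lumen_intensity:
            raise InvalidModelError("adventitia must be brighter than lumen")
        if self.min_thickness_mm <= 0:
            raise InvalidModelError("min_thickness_mm must be positive")

    # -- derived pixel-space quantities -------------------------------------

    @property
    def awl_row(self) -> float:
        return self.awl_depth_mm * self.pixels_per_mm

    @property
    def pwl_row(self) -> float:
        return self.pwl_depth_mm * self.pixels_per_mm

    @property
    def pbs_row(self) -> float:
        return self.pbs_depth_mm * self.pixels_per_mm

    def plaque_cols(self) -> np.ndarray:
        """Integer column indices spanned by the plaque."""
        w = self.image_size[1]
        center = (
            self.plaque_center_col_mm * self.pixels_per_mm
            if self.plaque_center_col_mm is not None
            else (w - 1) / 2.0
        )
        half = self.plaque_extent_mm * self.pixels_per_mm / 2.0
        lo = int(np.ceil(center - half))
        hi = int(np.floor(center + half))
        return np.arange(lo, hi + 1)

    def pts_row_profile(self, cols: np.ndarray) -> np.ndarray:
        """Plaque top surface depth (rows) per column: a parabolic cap."""
        pc = self.plaque_cols()
        center = (pc[0] + pc[-1]) / 2.0
        half = (pc[-1] - pc[0]) / 2.0
        xi = (np.asarray(cols, dtype=float) - center) / half
        bump = (self.pbs_depth_mm - self.pts_apex_depth_mm) * np.clip(
            1.0 - xi**2, 0.0, None
        )
        bump = np.maximum(bump, self.min_thickness_mm)
        return (self.pbs_depth_mm - bump) * self.pixels_per_mm


class _DisplacementField:
    """Analytic displacement field: piecewise linear in depth per column.

    Structures (anterior wall, plaque top/bottom surfaces, posterior wall)
    each follow the cardiac waveform with their own sign and delay; between
    structures the displacement interpolates linearly in depth so that the
    warped speckle deforms smoothly.  ``u(·, t=0) = 0`` by construction.
    """

    def __init__(self, model: MotionModel, geom: PhantomGeometry):
        self.model = model
        self.geom = geom
        h, w = geom.image_size
        self.h, self.w = h, w
        cols = np.arange(w)
        pc = geom.plaque_cols()
        in_plaque = (cols >= pc[0]) & (cols <= pc[-1])
        self.in_plaque = in_plaque
        # knot depths per column: 0, AWL, mid/top, mid/bottom, PWL, H-1
        mid_top = np.full(w, geom.awl_row + 0.45 * (geom.pwl_row - geom.awl_row))
        mid_bot = np.full(w, geom.awl_row + 0.55 * (geom.pwl_row - geom.awl_row))
        mid_top[in_plaque] = geom.pts_row_profile(cols[in_plaque])
        mid_bot[in_plaque] = geom.pbs_row
        self.knot_depths = np.stack(
            [
                np.zeros(w),
                np.full(w, geom.awl_row),
                mid_top,
                mid_bot,
                np.full(w, geom.pwl_row),
                np.full(w, h - 1.0),
            ]
        )  # (6, w)

    def _knot_values(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Radial and longitudinal displacement at the 6 knots, per column."""
        m, g = self.model, self.geom
        ppmm = g.pixels_per_mm

        def beta(delay: float) -> float:
            ts = np.array([t - delay, 0.0 - delay])
            b = cardiac_waveform(m, ts)
            return float(b[0] - b[1])

        a_r = m.radial_amp * ppmm
        a_l = m.longitudinal_amp * ppmm
        u_awl_r = +a_r * beta(0.0)
        u_pwl_r = -a_r * beta(0.0)
        u_pbs_r = -a_r * beta(m.wall_plaque_delay)
        u_pts_r = -a_r * beta(m.wall_plaque_delay + m.top_bottom_delay)
        u_wall_l = a_l * beta(0.0)
        u_pbs_l = a_l * beta(m.wall_plaque_delay)
        u_pts_l = a_l * beta(m.wall_plaque_delay + m.top_bottom_delay)

        w = self.w
        ur = np.empty((6, w))
        uc = np.empty((6, w))
        ur[0] = ur[1] = u_awl_r
        ur[4] = ur[5] = u_pwl_r
        uc[0] = uc[1] = u_wall_l
        uc[4] = uc[5] = u_wall_l
        # lumen mid-levels outside the plaque move with the average phase
        ur[2] = np.where(self.in_plaque, u_pts_r, 0.5 * (u_awl_r + u_pwl_r))
        ur[3] = np.where(self.in_plaque, u_pbs_r, 0.5 * (u_awl_r + u_pwl_r))
        uc[2] = np.where(self.in_plaque, u_pts_l, u_wall_l)
        uc[3] = np.where(self.in_plaque, u_pbs_l, u_wall_l)
        return ur, uc

    def grid(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Dense (h, w) radial and longitudinal displacement at time t."""
        ur_k, uc_k = self._knot_values(t)
        rows = np.arange(self.h, dtype=float)
        ur = np.empty((self.h, self.w))
        uc = np.empty((self.h, self.w))
        for c in range(self.w):
            ur[:, c] = np.interp(rows, self.knot_depths[:, c], ur_k[:, c])
            uc[:, c] = np.interp(rows, self.knot_depths[:, c], uc_k[:, c])
        return ur, uc

    def at(self, r: np.ndarray, c: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Displacement at arbitrary (sub-pixel) positions at time t."""
        ur_k, uc_k = self._knot_values(t)
        ci = np.clip(np.round(c).astype(int), 0, self.w - 1)
        ur = np.empty_like(np.asarray(r, dtype=float))
        uc = np.empty_like(ur)
        for i, (ri, cc) in enumerate(zip(np.atleast_1d(r), np.atleast_1d(ci))):
            ur.flat[i] = np.interp(ri, self.knot_depths[:, cc], ur_k[:, cc])
            uc.flat[i] = np.interp(ri, self.knot_depths[:, cc], uc_k[:, cc])
        return ur, uc

    def material_position(
        self, r0: np.ndarray, c0: np.ndarray, t: float, n_iter: int = 4
    ) -> tuple[np.ndarray, np.ndarray]:
        """Solve p = p0 + u(p, t) by fixed-point iteration.

        The rendered frames are produced by the backward warp
        ``I_t(p) = I_0(p - u(p, t))``, so the exact trajectory of the
        material point starting at p0 is the fixed point of this map.
        """
        r = np.asarray(r0, dtype=float).copy()
        c = np.asarray(c0, dtype=float).copy()
        for _ in range(n_iter):
            ur, uc = self.at(r, c, t)
            r = np.asarray(r0, dtype=float) + ur
            c = np.asarray(c0, dtype=float) + uc
        return r, c


def _reflectivity_map(geom: PhantomGeometry) -> np.ndarray:
    h, w = geom.image_size
    img = np.full((h, w), geom.lumen_intensity, dtype=float)
    rows = np.arange(h)[:, None]
    img[rows[:, 0] < geom.awl_row, :] = geom.wall_intensity
    img[rows[:, 0] >= geom.pwl_row, :] = geom.adventitia_intensity
    pc = geom.plaque_cols()
    pts = geom.pts_row_profile(pc)
    for c, pr in zip(pc, pts):
        top = int(np.ceil(pr))
        bot = int(np.floor(geom.pbs_row))
        img[top:bot, c] = geom.plaque_intensity
        img[bot:int(np.floor(geom.pwl_row)), c] = geom.wall_intensity
    return img


def generate_image_sequence(
    model: MotionModel, geom: PhantomGeometry
) -> tuple[ImageSequence, dict[str, PixelTrajectory], dict[str, ROIContour]]:
    """Speckle phantom sequence with ground-truth trajectories and contours.

    The first frame defines the annotated contours (AWL, PWL, PTS, PBS);
    subsequent frames are backward warps of the same speckle realisation by
    the analytic displacement field, plus per-frame sensor noise.  Returned
    trajectories are the exact material paths of the contour pixels under
    that warp, for validating the tracker.
    """
    model.validate()
    geom.validate()
    rng = np.random.default_rng(model.seed)
    h, w = geom.image_size

    base = _reflectivity_map(geom)
    speckle = ndimage.gaussian_filter(
        rng.standard_normal((h, w)), geom.speckle_corr_px
    )
    speckle /= max(speckle.std(), 1e-12)
    tissue = np.clip(base * (1.0 + geom.speckle_strength * speckle), 0, 255)

    max_disp = (
        max(model.radial_amp, model.longitudinal_amp) * geom.pixels_per_mm * 2.0
    )
    if (geom.awl_row - max_disp <= 0) or (geom.pwl_row + max_disp >= h - 1):
        raise GenerationError(
            "pulsatile displacement would carry tissue outside the image"
        )

    field = _DisplacementField(model, geom)
    times = model.times()
    frames = np.empty((times.size, h, w), dtype=float)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    for k, t in enumerate(times):
        if t == 0.0:
            warped = tissue
        else:
            ur, uc = field.grid(t)
            warped = ndimage.map_coordinates(
                tissue, [rr - ur, cc - uc], order=1, mode="nearest"
            )
        noise = rng.normal(0.0, geom.frame_noise_sd, size=(h, w))
        frames[k] = np.clip(warped + noise, 0, 255)

    seq = ImageSequence(frames, model.frame_rate, geom.pixels_per_mm)

    pc = geom.plaque_cols()
    pts_rows = np.round(geom.pts_row_profile(pc)).astype(int)
    contours = {
        "AWL": ROIContour("AWL", np.stack(
            [np.full(pc.size, int(round(geom.awl_row))), pc], axis=1)),
        "PWL": ROIContour("PWL", np.stack(
            [np.full(pc.size, int(round(geom.pwl_row))), pc], axis=1)),
        "PTS": ROIContour("PTS", np.stack([pts_rows, pc], axis=1)),
        "PBS": ROIContour("PBS", np.stack(
            [np.full(pc.size, int(round(geom.pbs_row))), pc], axis=1)),
    }

    trajectories = {}
    for name, contour in contours.items():
        r0 = contour.pixels[:, 0].astype(float)
        c0 = contour.pixels[:, 1].astype(float)
        rows_t = np.empty((r0.size, times.size))
        cols_t = np.empty_like(rows_t)
        for k, t in enumerate(times):
            if t == 0.0:
                rows_t[:, k], cols_t[:, k] = r0, c0
            else:
                rows_t[:, k], cols_t[:, k] = field.material_position(r0, c0, t)
        trajectories[name] = PixelTrajectory(name, rows_t, cols_t, model.frame_rate)

    return seq, trajectories, contours


@dataclass(frozen=True)
class CohortSpec:
    """Two-or-more labelled groups with per-feature normal distributions.

    ``feature_dists`` maps group label -> {feature name: (mean, sd)}.  All
    groups must declare the same feature set.
    """

    n_per_group: dict[str, int] = field(default_factory=dict)
    feature_dists: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_group) < 2:
            raise CohortSpecError("need at least 2 groups")
        if set(self.n_per_group) != set(self.feature_dists):
            raise CohortSpecError("groups of counts and distributions differ")
        feats = None
        for label, n in self.n_per_group.items():
            if n < 2:
                raise CohortSpecError(f"group {label!r} needs >= 2 samples")
            f = set(self.feature_dists[label])
            if feats is None:
                feats = f
            elif f != feats:
                raise CohortSpecError("groups declare different features")
            for name, (_, sd) in self.feature_dists[label].items():
                if sd < 0:
                    raise CohortSpecError(f"negative sd for {label}/{name}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a labelled feature table; reproducible for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label in sorted(spec.n_per_group):
        n = spec.n_per_group[label]
        dists = spec.feature_dists[label]
        block = {
            name: rng.normal(mu, sd, size=n) for name, (mu, sd) in sorted(dists.items())
        }
        df = pd.DataFrame(block)
        df["label"] = label
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


# -- serialisation -----------------------------------------------------------


def write_image_sequence(path: str | Path, seq: ImageSequence) -> None:
    """Write frames as an 8-bit grayscale multi-page TIFF."""
    import tifffile

    tifffile.imwrite(
        str(path), np.clip(np.round(seq.frames), 0, 255).astype(np.uint8)
    )


def write_contours_csv(path: str | Path, contours: dict[str, ROIContour]) -> None:
    rows = []
    for name, c in contours.items():
        for i, (r, col) in enumerate(c.pixels):
            rows.append({"roi": name, "pixel_index": i, "row": r, "col": col})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours_csv(path: str | Path) -> dict[str, ROIContour]:
    df = pd.read_csv(path)
    out = {}
    for name, grp in df.groupby("roi"):
        grp = grp.sort_values("pixel_index")
        out[str(name)] = ROIContour(str(name), grp[["row", "col"]].to_numpy())
    return out


def write_trajectories_csv(
    path: str | Path, trajectories: dict[str, PixelTrajectory]
) -> None:
    frames = []
    for name, tr in trajectories.items():
        p, t = tr.rows.shape
        idx = np.repeat(np.arange(p), t)
        frame = np.tile(np.arange(t), p)
        frames.append(
            pd.DataFrame(
                {
                    "roi": name,
                    "pixel_index": idx,
                    "frame": frame,
                    "row": tr.rows.ravel(),
                    "col": tr.cols.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def write_model_spec(path: str | Path, model: MotionModel) -> None:
    """Dump a motion model as YAML (or JSON if the suffix says so)."""
    d = dataclasses.asdict(model)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d))


def read_model_spec(path: str | Path) -> MotionModel:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return MotionModel(**d)
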