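"""Ground-truth mock motility videos for validating the image pipeline.

Rod-like fluorescent filaments of known length and speed are moved along
straight or constant-curvature paths, rendered as chains of point emitters
convolved with a Gaussian point-spread function on a noisy camera
background, and written out together with a per-frame truth table.  The
generator covers the failure modes the downstream quality control must
learn: filament crossings and irregular (jerky) motion.

Coordinates: image row-major, origin at the top-left pixel center, x along
columns and y along rows, physical positions in µm, 0-based pixel indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = [
    "FilamentSpec",
    "OpticsNoiseSpec",
    "build_paths",
    "render",
    "crossing_scenario",
    "write_stack",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = (
    "filament_id", "frame", "x_um", "y_um", "tip_x_um", "tip_y_um",
    "length_um", "velocity_um_s", "heading_rad", "curvature_per_um",
    "intensity_per_um", "overlap", "out_of_view", "label",
)


@dataclass(frozen=True)
class FilamentSpec:
    """One scripted filament: geometry, motion and brightness."""

    length_um: float
    velocity_um_s: float
    start_xy_um: tuple[float, float]
    heading_rad: float = 0.0
    curvature_per_um: float = 0.0  # 0 = straight path
    intensity_per_um: float = 2000.0
    label: str = "clean"
    #: per-frame heading jitter (rad, sd) for "irregular" motion scripts
    heading_jitter_rad: float = 0.0
    #: per-frame velocity jitter (fraction, sd) for irregular motion
    velocity_jitter_frac: float = 0.0

    def __post_init__(self):
        if self.length_um <= 0:
            raise ValueError("filament length must be positive")
        if self.velocity_um_s < 0:
            raise ValueError("velocity must be non-negative")


@dataclass(frozen=True)
class OpticsNoiseSpec:
    """Camera and photophysics parameters of the rendered videos."""

    psf_sigma_px: float = 0.9
    background_mean: float = 100.0
    background_sd: float = 5.0
    fluorophore_spacing_um: float = 0.05
    brightness_fluctuation_sd: float = 0.0  # fraction of emitter brightness
    brownian_sigma_um: float = 0.0          # per emitter per frame
    pixel_size_um: float = 0.08
    frame_rate: float = 30.0
    shape_px: tuple[int, int] = (512, 512)  # rows, cols

    def __post_init__(self):
        if self.psf_sigma_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("psf_sigma and pixel_size must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.shape_px[1] * self.pixel_size_um,
                self.shape_px[0] * self.pixel_size_um)


def _backbone(x, y, heading, length, curvature, n_points):
    """Backbone sample points of a rod whose center sits at (x, y).

    The rod lies along its path: straight, or bent with the path's constant
    curvature.  Returns (n_points, 2) positions in µm ordered tail -> tip.
    """
    s = np.linspace(-length / 2, length / 2, n_points)
    if abs(curvature) < 1e-9:
        px = x + s * math.cos(heading)
        py = y + s * math.sin(heading)
    else:
        r = 1.0 / curvature
        # arc through (x, y) with tangent `heading` at the center point
        cx = x - r * math.sin(heading)
        cy = y + r * math.cos(heading)
        ang = heading - math.pi / 2 * np.sign(curvature) + s * curvature
        px = cx + np.abs(r) * np.cos(ang) * np.sign(curvature)
        py = cy + np.abs(r) * np.sin(ang) * np.sign(curvature)
    return np.column_stack([px, py])


def build_paths(specs, duration_s, frame_rate, *,
                fov_um=(81.92, 81.92), seed: int = 0) -> pd.DataFrame:
    """Advance each filament along its scripted path; return the truth table.

    Motion is constant-speed along a straight line (curvature 0) or a
    constant-curvature arc; the tip is the backbone end that leads along the
    heading.  Frames at which the filament (partially) leaves the field of
    view are flagged ``out_of_view``; specs longer than the field diagonal
    are rejected.  Irregular-motion specs (nonzero jitter fields) evolve
    heading/speed with seeded per-frame perturbations.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_frames = int(round(duration_s * frame_rate))
    dt = 1.0 / frame_rate
    diag = math.hypot(*fov_um)
    rng = np.random.default_rng(seed)
    rows = []
    for fid, sp in enumerate(specs):
        if sp.length_um > diag:
            raise ValueError(
                f"filament {fid}: length {sp.length_um} um exceeds the "
                f"field-of-view diagonal {diag:.1f} um")
        x, y = sp.start_xy_um
        heading = sp.heading_rad
        for fr in range(n_frames):
            half = sp.length_um / 2
            tip = _backbone(x, y, heading, sp.length_um,
                            sp.curvature_per_um, 2)[-1]
            oov = not (half <= min(x, y)
                       and x <= fov_um[0] - half and y <= fov_um[1] - half)
            rows.append((fid, fr, x, y, tip[0], tip[1], sp.length_um,
                         sp.velocity_um_s, heading, sp.curvature_per_um,
                         sp.intensity_per_um, False, oov, sp.label))
            # advance to next frame
            v = sp.velocity_um_s
            if sp.velocity_jitter_frac > 0:
                v = max(0.0, v * (1 + rng.normal(0, sp.velocity_jitter_frac)))
            if sp.heading_jitter_rad > 0:
                heading += rng.normal(0, sp.heading_jitter_rad)
            step = v * dt
            if abs(sp.curvature_per_um) < 1e-9:
                x += step * math.cos(heading)
                y += step * math.sin(heading)
            else:
                # move along the arc: rotate the center point
                dheading = step * sp.curvature_per_um
                r = 1.0 / sp.curvature_per_um
                cx = x - r * math.sin(heading)
                cy = y + r * math.cos(heading)
                heading += dheading
                x = cx + r * math.sin(heading)
                y = cy - r * math.cos(heading)
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    _flag_overlaps(truth)
    truth.attrs["frame_rate"] = frame_rate
    truth.attrs["fov_um"] = tuple(fov_um)
    return truth


def _flag_overlaps(truth: pd.DataFrame, radius_um: float = 0.4) -> None:
    """Mark frames where two filament backbones come within ``radius_um``."""
    truth["overlap"] = False
    for fr, grp in truth.groupby("frame"):
        if len(grp) < 2:
            continue
        bbs = {}
        for _, r in grp.iterrows():
            bbs[r.name] = _backbone(r.x_um, r.y_um, r.heading_rad,
                                    r.length_um, r.curvature_per_um, 25)
        idx = list(bbs)
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                a, b = bbs[idx[i]], bbs[idx[j]]
                d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
                if d2.min() < radius_um ** 2:
                    truth.loc[[idx[i], idx[j]], "overlap"] = True


def render(truth: pd.DataFrame, optics: OpticsNoiseSpec, seed: int = 0):
    """Render a truth table into an image stack.

    Each filament is drawn as a chain of point emitters spaced
    ``fluorophore_spacing_um`` along the backbone, splatted bilinearly and
    convolved with a Gaussian PSF, on a background of mean
    ``background_mean`` with Gaussian read noise.  Optional per-emitter
    brightness fluctuation and Brownian jitter are applied per frame; the
    returned truth table carries the jittered centroid/tip positions.

    Returns ``(stack, truth_out)`` with ``stack`` a float array of shape
    (frames, rows, cols).
    """
    rng = np.random.default_rng(seed)
    n_frames = int(truth["frame"].max()) + 1
    rows_px, cols_px = optics.shape_px
    px = optics.pixel_size_um
    if px >= 1.0:  # a filament is ~0.2-1 um wide after PSF blur
        import warnings
        warnings.warn("pixel size >= 1 um/px: filaments are undersampled")
    stack = np.zeros((n_frames, rows_px, cols_px))
    truth_out = truth.copy()
    for fr in range(n_frames):
        img = np.zeros((rows_px, cols_px))
        sub = truth.loc[truth["frame"] == fr]
        for idx, r in sub.iterrows():
            n_em = max(2, int(round(r.length_um /
                                    optics.fluorophore_spacing_um)))
            pts = _backbone(r.x_um, r.y_um, r.heading_rad, r.length_um,
                            r.curvature_per_um, n_em)
            if optics.brownian_sigma_um > 0:
                pts = pts + rng.normal(0, optics.brownian_sigma_um,
                                       pts.shape)
            amp = np.full(n_em, r.intensity_per_um *
                          optics.fluorophore_spacing_um)
            if optics.brightness_fluctuation_sd > 0:
                amp = amp * np.clip(
                    rng.normal(1, optics.brightness_fluctuation_sd, n_em),
                    0, None)
            _splat(img, pts / px, amp)
            truth_out.loc[idx, ["x_um", "y_um"]] = pts.mean(axis=0)
            truth_out.loc[idx, ["tip_x_um", "tip_y_um"]] = pts[-1]
        if optics.psf_sigma_px > 0:
            img = gaussian_filter(img, optics.psf_sigma_px)
        img += optics.background_mean
        if optics.background_sd > 0:
            img += rng.normal(0, optics.background_sd, img.shape)
        stack[fr] = img
    return stack, truth_out


def _splat(img, pts_px, amp):
    """Bilinear splat of sub-pixel point emitters (x=col, y=row)."""
    x = pts_px[:, 0]
    y = pts_px[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0
    H, W = img.shape
    for dx, dy, w in ((0, 0, (1 - fx) * (1 - fy)), (1, 0, fx * (1 - fy)),
                      (0, 1, (1 - fx) * fy), (1, 1, fx * fy)):
        xi = x0 + dx
        yi = y0 + dy
        ok = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H)
        np.add.at(img, (yi[ok], xi[ok]), amp[ok] * w[ok])


def crossing_scenario(n: int, seed: int, *, frame_rate: float = 30.0,
                      duration_s: float = 5.0,
                      fov_um=(40.96, 40.96)) -> pd.DataFrame:
    """Scripted QC-training scenarios: clean, crossing, and irregular traces.

    Produces ``n`` crossing pairs (two filaments steered through a common
    point at mid-video, guaranteeing overlap frames), plus ``n`` clean and
    ``n`` irregular-motion filaments, each labelled for classifier
    training.  Deterministic for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        t = pd.DataFrame(columns=list(TRUTH_COLUMNS))
        t.attrs["frame_rate"] = frame_rate
        t.attrs["fov_um"] = tuple(fov_um)
        return t
    rng = np.random.default_rng(seed)
    cx, cy = fov_um[0] / 2, fov_um[1] / 2
    t_mid = duration_s / 2
    specs = []
    for _ in range(n):
        # two filaments aimed to arrive at a shared point at t_mid
        meet = (cx + rng.normal(0, 3), cy + rng.normal(0, 3))
        for k in range(2):
            heading = rng.uniform(0, 2 * math.pi)
            v = rng.uniform(0.4, 1.2)
            start = (meet[0] - v * t_mid * math.cos(heading),
                     meet[1] - v * t_mid * math.sin(heading))
            specs.append(FilamentSpec(
                length_um=rng.uniform(0.8, 2.5), velocity_um_s=v,
                start_xy_um=start, heading_rad=heading, label="crossing"))
    for _ in range(n):
        specs.append(FilamentSpec(
            length_um=rng.uniform(0.8, 2.5),
            velocity_um_s=rng.uniform(0.4, 1.2),
            start_xy_um=(rng.uniform(8, fov_um[0] - 8),
                         rng.uniform(8, fov_um[1] - 8)),
            heading_rad=rng.uniform(0, 2 * math.pi), label="clean"))
    for _ in range(n):
        specs.append(FilamentSpec(
            length_um=rng.uniform(0.8, 2.5),
            velocity_um_s=rng.uniform(0.3, 1.0),
            start_xy_um=(rng.uniform(8, fov_um[0] - 8),
                         rng.uniform(8, fov_um[1] - 8)),
            heading_rad=rng.uniform(0, 2 * math.pi),
            heading_jitter_rad=0.6, velocity_jitter_frac=0.8,
            label="irregular"))
    return build_paths(specs, duration_s, frame_rate, fov_um=fov_um,
                       seed=int(rng.integers(2 ** 31 - 1)))


def write_stack(path, stack) -> None:
    """Write a float stack as a 16-bit multi-page TIFF."""
    arr = np.clip(stack, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")
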