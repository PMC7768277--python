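"""Radial line-scan quantification of punctate organelle dispersion.

The dispersion of a punctate organelle signal (e.g. a Golgi marker)
around the nucleus is quantified per cell as follows:

1. A line scan is taken from the centroid of the nucleus to the cell
   periphery, repeated every degree (360 scans), sampling intensity at
   unit-pixel steps with bilinear interpolation.
2. A scan through a cargo-free sector of the cell is resampled onto each
   scan's normalized distance axis and subtracted (scaled background
   subtraction); negative values are clamped to zero.
3. Samples inside the nucleus are removed and each scan's remaining
   distances are mapped affinely so 0 is the nuclear membrane and 1 the
   cell periphery.
4. Pixels sampled by more than one scan near the centre are counted once
   (oversampling correction, under the circular-cell assumption).
5. Intensities are grouped into 20 normalized-distance bins of width
   0.05; within each bin only the top 200 pixels are kept and averaged,
   giving the cell's dispersion profile.

Profiles are compared across cells bin-by-bin (see
:mod:`punctaquant.stats`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

N_BINS_DEFAULT = 20
BIN_WIDTH_DEFAULT = 0.05
TOP_K_DEFAULT = 200


class GeometryError(ValueError):
    """Raised when cell/nucleus geometry violates the method's assumptions."""


@dataclass
class CellGeometry:
    """Nucleus centroid plus nucleus and cell boundaries as radius-per-angle.

    Radii are stored at 1-degree resolution and interpolated (period 360)
    for arbitrary angles. Angles follow the standard math convention
    (degrees counter-clockwise from +x) in pixel coordinates (x right,
    y down in the array sense; the convention only needs to be
    consistent between placement and scanning).
    """

    centroid: tuple[float, float]  # (x, y) pixels
    nucleus_radii: np.ndarray  # radius at angle k degrees, k = 0..359
    cell_radii: np.ndarray
    background_angle: float = 0.0  # deg, direction of a cargo-free sector

    def __post_init__(self) -> None:
        self.nucleus_radii = np.asarray(self.nucleus_radii, dtype=float)
        self.cell_radii = np.asarray(self.cell_radii, dtype=float)
        if self.nucleus_radii.shape != (360,) or self.cell_radii.shape != (360,):
            raise GeometryError("radii must be sampled at 360 one-degree steps")
        if np.any(self.nucleus_radii >= self.cell_radii):
            bad = int(np.argmax(self.nucleus_radii >= self.cell_radii))
            raise GeometryError(f"nucleus reaches the cell boundary at angle {bad} deg")
        if not 0.0 <= self.background_angle < 360.0:
            self.background_angle = self.background_angle % 360.0

    def _radius_at(self, radii: np.ndarray, angle_deg: float) -> float:
        a = np.asarray(angle_deg, dtype=float) % 360.0
        grid = np.arange(361.0)
        vals = np.concatenate([radii, radii[:1]])
        return float(np.interp(a, grid, vals))

    def nucleus_radius_at(self, angle_deg: float) -> float:
        return self._radius_at(self.nucleus_radii, angle_deg)

    def cell_radius_at(self, angle_deg: float) -> float:
        return self._radius_at(self.cell_radii, angle_deg)

    @classmethod
    def from_ellipses(
        cls,
        centroid: tuple[float, float],
        nucleus_axes: tuple[float, float],
        cell_axes: tuple[float, float],
        background_angle: float = 0.0,
    ) -> "CellGeometry":
        """Concentric-ellipse geometry (semi-axes in pixels)."""
        ang = np.radians(np.arange(360.0))

        def radii(a: float, b: float) -> np.ndarray:
            return 1.0 / np.sqrt((np.cos(ang) / a) ** 2 + (np.sin(ang) / b) ** 2)

        return cls(
            centroid=tuple(map(float, centroid)),
            nucleus_radii=radii(*nucleus_axes),
            cell_radii=radii(*cell_axes),
            background_angle=background_angle,
        )

    @classmethod
    def from_label_mask(cls, mask: np.ndarray, background_angle: float = 0.0) -> "CellGeometry":
        """Extract geometry from a label mask (0 outside, 1 cytoplasm, 2 nucleus).

        The centroid is the nucleus centre of mass; boundaries are found
        by casting a ray per degree and recording the last sample inside
        the nucleus (label 2) and inside the cell (label > 0).
        """
        mask = np.asarray(mask)
        if not np.any(mask == 2):
            raise GeometryError("label mask contains no nucleus (label 2)")
        cy, cx = ndimage.center_of_mass(mask == 2)
        h, w = mask.shape
        rmax = math.hypot(h, w)
        step = 0.25
        nuc = np.zeros(360)
        cell = np.zeros(360)
        for k in range(360):
            th = math.radians(k)
            dx, dy = math.cos(th), math.sin(th)
            r = 0.0
            last_nuc, last_cell = 0.0, 0.0
            while r <= rmax:
                x = int(round(cx + r * dx))
                y = int(round(cy + r * dy))
                if not (0 <= x < w and 0 <= y < h):
                    break
                v = mask[y, x]
                if v == 2:
                    last_nuc = r
                if v > 0:
                    last_cell = r
                r += step
            nuc[k] = last_nuc
            cell[k] = last_cell
        return cls((float(cx), float(cy)), nuc, cell, background_angle)

    def to_label_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the geometry as a label mask (0/1/2)."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        cx, cy = self.centroid
        dx, dy = xx - cx, yy - cy
        dist = np.hypot(dx, dy)
        ang = np.degrees(np.arctan2(dy, dx)) % 360.0
        grid = np.arange(361.0)
        rn = np.interp(ang, grid, np.concatenate([self.nucleus_radii, self.nucleus_radii[:1]]))
        rc = np.interp(ang, grid, np.concatenate([self.cell_radii, self.cell_radii[:1]]))
        out = np.zeros(shape, dtype=np.uint8)
        out[dist <= rc] = 1
        out[dist <= rn] = 2
        return out


@dataclass
class LinescanProfile:
    """One radial line scan: intensity sampled centroid -> cell boundary."""

    angle: float  # degrees
    distances: np.ndarray  # px from centroid, strictly increasing
    intensities: np.ndarray
    xs: np.ndarray = field(default=None)  # sample pixel coords (float)
    ys: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.distances) != len(self.intensities):
            raise ValueError("distances and intensities must have equal length")
        if len(self.distances) > 1 and not np.all(np.diff(self.distances) > 0):
            raise ValueError("distances must be strictly increasing")


@dataclass
class PixelSamples:
    """Masked, normalized samples from one or more line scans."""

    norm_dist: np.ndarray  # in [0, 1]
    intensity: np.ndarray
    px: np.ndarray  # integer pixel coords (containing unit cell)
    py: np.ndarray
    angle: np.ndarray  # source scan angle per sample
    xs: np.ndarray = None  # float sample coords (for centre-based dedup)
    ys: np.ndarray = None


@dataclass
class DispersionProfile:
    """Binned per-cell dispersion profile: 20 bins of normalized distance."""

    bin_lo: np.ndarray  # 0.00, 0.05, ..., 0.95
    mean_intensity: np.ndarray  # NaN where a bin is empty
    n_pixels: np.ndarray

    def __post_init__(self) -> None:
        self.bin_lo = np.asarray(self.bin_lo, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)

    @property
    def bin_centers(self) -> np.ndarray:
        width = self.bin_lo[1] - self.bin_lo[0] if len(self.bin_lo) > 1 else BIN_WIDTH_DEFAULT
        return self.bin_lo + width / 2.0

    def weighted_mean_distance(self) -> float:
        """Intensity-weighted mean normalized distance over non-missing bins."""
        ok = ~np.isnan(self.mean_intensity)
        w = self.mean_intensity[ok]
        if w.sum() <= 0:
            return float("nan")
        return float(np.sum(self.bin_centers[ok] * w) / np.sum(w))


def radial_linescans(
    image: np.ndarray, geometry: CellGeometry, n_angles: int = 360
) -> list[LinescanProfile]:
    """Sample intensity along radial lines from the nucleus centroid.

    One profile per angle (``n_angles`` equally spaced, starting at 0
    degrees), sampled at unit-pixel steps from the centroid to the cell
    boundary with bilinear interpolation.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cx, cy = geometry.centroid
    if not (0 <= cx < w and 0 <= cy < h):
        raise GeometryError(f"centroid ({cx:.1f}, {cy:.1f}) outside the {w}x{h} image")
    profiles = []
    for k in range(n_angles):
        ang = k * 360.0 / n_angles
        rc = geometry.cell_radius_at(ang)
        if rc < 2.0:
            raise GeometryError(f"cell boundary unresolvable at angle {ang:.1f} deg (radius {rc:.2f} px)")
        d = np.arange(0.0, math.floor(rc + 1e-9) + 1.0)
        xs = cx + d * math.cos(math.radians(ang))
        ys = cy + d * math.sin(math.radians(ang))
        vals = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")
        profiles.append(LinescanProfile(ang, d, vals, xs=xs, ys=ys))
    return profiles


def background_scan(image: np.ndarray, geometry: CellGeometry) -> LinescanProfile:
    """Line scan along the cargo-free direction, used for subtraction."""
    image = np.asarray(image, dtype=float)
    cx, cy = geometry.centroid
    ang = geometry.background_angle
    rc = geometry.cell_radius_at(ang)
    d = np.arange(0.0, math.floor(rc + 1e-9) + 1.0)
    xs = cx + d * math.cos(math.radians(ang))
    ys = cy + d * math.sin(math.radians(ang))
    vals = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")
    return LinescanProfile(ang, d, vals, xs=xs, ys=ys)


def subtract_background(
    profiles: list[LinescanProfile],
    background_profile: LinescanProfile,
    mode: str = "distance",
) -> list[LinescanProfile]:
    """Scaled background subtraction.

    ``"distance"`` (default): the background scan is resampled onto each
    target scan's normalized 0-1 distance axis (length scaling) and
    subtracted point-wise. ``"amplitude"``: additionally scales the
    resampled background by the least-squares coefficient of the target
    on it (clipped to >= 0). Negative results are clamped to zero.
    """
    if mode not in ("distance", "amplitude"):
        raise ValueError(f"mode must be 'distance' or 'amplitude', got {mode!r}")
    if len(background_profile.distances) < 2:
        raise GeometryError("background scan is degenerate (< 2 samples)")
    bg_norm = background_profile.distances / background_profile.distances[-1]
    out = []
    for p in profiles:
        if len(p.distances) < 2:
            out.append(p)
            continue
        t_norm = p.distances / p.distances[-1]
        bg = np.interp(t_norm, bg_norm, background_profile.intensities)
        if mode == "amplitude":
            denom = float(np.dot(bg, bg))
            scale = max(float(np.dot(p.intensities, bg)) / denom, 0.0) if denom > 0 else 0.0
            bg = scale * bg
        out.append(
            LinescanProfile(
                p.angle,
                p.distances,
                np.clip(p.intensities - bg, 0.0, None),
                xs=p.xs,
                ys=p.ys,
            )
        )
    return out


def mask_and_normalize(profile: LinescanProfile, geometry: CellGeometry) -> PixelSamples:
    """Drop nuclear samples and map distances to [0, 1].

    Samples at distance < nuclear radius (along this scan's angle) are
    removed; remaining distances are mapped affinely so the nuclear edge
    is 0 and the cell boundary 1.
    """
    rn = geometry.nucleus_radius_at(profile.angle)
    rc = geometry.cell_radius_at(profile.angle)
    if rn >= rc:
        raise GeometryError(f"nuclear radius >= cell radius at angle {profile.angle:.1f} deg")
    keep = profile.distances >= rn - 1e-9  # tolerate float jitter at the nuclear edge
    d = profile.distances[keep]
    norm = np.clip((d - rn) / (rc - rn), 0.0, 1.0)
    xs = profile.xs[keep] if profile.xs is not None else np.full(len(d), np.nan)
    ys = profile.ys[keep] if profile.ys is not None else np.full(len(d), np.nan)
    # pixel identity = containing unit cell [i, i+1); floor (unlike
    # round-half-even) commutes with quarter-turn rotations of the grid
    return PixelSamples(
        norm_dist=norm,
        intensity=profile.intensities[keep],
        px=np.floor(xs + 1e-6).astype(int),
        py=np.floor(ys + 1e-6).astype(int),
        angle=np.full(len(d), profile.angle),
        xs=xs,
        ys=ys,
    )


def correct_oversampling(samples: list[PixelSamples], method: str = "center") -> PixelSamples:
    """Count each integer pixel once across all scans.

    Scans converge near the centroid, so central pixels are sampled by
    many scans; under the circular-cell assumption each physical pixel
    should contribute once. ``method="mean"`` (default) merges the
    duplicate samples of a pixel by averaging their intensities and
    normalized distances. ``method="first"`` keeps the sample from the
    lowest scan angle. ``method="center"`` (default) keeps the sample
    nearest the pixel centre — sample-to-centre distances are preserved
    by grid rotations, so this choice, unlike the others, is stable
    under image rotation.
    """
    if method not in ("center", "mean", "first"):
        raise ValueError(f"method must be 'center', 'mean' or 'first', got {method!r}")
    if not samples:
        return PixelSamples(*(np.array([]) for _ in range(5)))
    ordered = sorted(samples, key=lambda s: float(s.angle[0]) if len(s.angle) else 0.0)
    nd = np.concatenate([s.norm_dist for s in ordered])
    it = np.concatenate([s.intensity for s in ordered])
    px = np.concatenate([s.px for s in ordered])
    py = np.concatenate([s.py for s in ordered])
    ang = np.concatenate([s.angle for s in ordered])
    if any(s.xs is None for s in ordered):  # coords unknown: centre of own pixel
        xs = px + 0.5
        ys = py + 0.5
    else:
        xs = np.concatenate([s.xs for s in ordered])
        ys = np.concatenate([s.ys for s in ordered])
    key = px.astype(np.int64) * 2**20 + py.astype(np.int64)
    uniq, first_idx, inverse, counts = np.unique(
        key, return_index=True, return_inverse=True, return_counts=True
    )
    if method == "first":
        first_idx.sort()
        return PixelSamples(nd[first_idx], it[first_idx], px[first_idx], py[first_idx], ang[first_idx])
    if method == "mean":
        nd_m = np.bincount(inverse, weights=nd) / counts
        it_m = np.bincount(inverse, weights=it) / counts
        return PixelSamples(nd_m, it_m, px[first_idx], py[first_idx], ang[first_idx])
    # 'center': per pixel keep the sample nearest that pixel's centre.
    # Sample-to-centre distances are preserved by grid rotations, so the
    # representative (unlike 'first') does not depend on scan ordering.
    d2 = (xs - px - 0.5) ** 2 + (ys - py - 0.5) ** 2
    order = np.lexsort((np.arange(len(d2)), d2))  # stable: distance, then scan order
    rep = np.full(len(uniq), -1, dtype=int)
    for i in order:
        g = inverse[i]
        if rep[g] < 0:
            rep[g] = i
    return PixelSamples(nd[rep], it[rep], px[rep], py[rep], ang[rep])


def bin_profile(
    samples: PixelSamples,
    bin_width: float = BIN_WIDTH_DEFAULT,
    top_k: int = TOP_K_DEFAULT,
) -> DispersionProfile:
    """Group samples into distance bins and average the top-k intensities.

    Bins are half-open [lo, lo + width) except the last, which includes
    1.0. Within each bin the ``top_k`` highest intensities are kept (all,
    if fewer); ties are resolved by sample order (stable sort). Empty
    bins are reported as NaN and excluded from downstream averaging.
    """
    d = np.asarray(samples.norm_dist, dtype=float)
    if len(d) and (d.min() < 0.0 or d.max() > 1.0):
        raise ValueError("normalized distances must lie in [0, 1]")
    n_bins = int(round(1.0 / bin_width))
    bin_lo = np.arange(n_bins) * bin_width
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    # snap values a float-epsilon below a bin edge onto the edge before flooring
    idx = np.minimum(np.floor(np.round(d / bin_width, 6)).astype(int), n_bins - 1)
    for b in range(n_bins):
        vals = samples.intensity[idx == b]
        if len(vals) == 0:
            continue
        order = np.argsort(-vals, kind="stable")[:top_k]
        kept = vals[order]
        means[b] = float(np.mean(kept))
        counts[b] = len(kept)
    return DispersionProfile(bin_lo, means, counts)


def dispersion_profile(
    image: np.ndarray,
    geometry: CellGeometry,
    n_angles: int = 360,
    bin_width: float = BIN_WIDTH_DEFAULT,
    top_k: int = TOP_K_DEFAULT,
    background: bool = True,
    background_mode: str = "distance",
    deduplicate: bool = True,
) -> DispersionProfile:
    """Full per-cell dispersion quantification.

    Deterministic composition: radial line scans -> scaled background
    subtraction -> nuclear masking and 0-1 normalization -> oversampling
    correction -> binning with top-k selection.
    """
    profiles = radial_linescans(image, geometry, n_angles=n_angles)
    if background:
        profiles = subtract_background(profiles, background_scan(image, geometry), mode=background_mode)
    samples = [mask_and_normalize(p, geometry) for p in profiles]
    if deduplicate:
        merged = correct_oversampling(samples)
    else:
        merged = PixelSamples(
            np.concatenate([s.norm_dist for s in samples]),
            np.concatenate([s.intensity for s in samples]),
            np.concatenate([s.px for s in samples]),
            np.concatenate([s.py for s in samples]),
            np.concatenate([s.angle for s in samples]),
        )
    return bin_profile(merged, bin_width=bin_width, top_k=top_k)


def average_profiles(cells: list[DispersionProfile]) -> dict:
    """Group mean +/- SEM per bin over cells with that bin non-missing.

    Returns a dict of arrays: ``bin_lo``, ``mean``, ``sem``, ``n_cells``.
    Requires at least two cells.
    """
    if len(cells) < 2:
        raise ValueError("need >= 2 cells to average profiles")
    bin_lo = cells[0].bin_lo
    mat = np.vstack([c.mean_intensity for c in cells])
    mask = ~np.isnan(mat)
    n = mask.sum(axis=0)
    vals = np.where(mask, mat, 0.0)
    mean = np.where(n > 0, vals.sum(axis=0) / np.maximum(n, 1), np.nan)
    resid = np.where(mask, mat - mean, 0.0)
    var = np.where(n > 1, (resid**2).sum(axis=0) / np.maximum(n - 1, 1), np.nan)
    sem = np.sqrt(var / np.maximum(n, 1))
    return {"bin_lo": bin_lo, "mean": mean, "sem": sem, "n_cells": n}
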