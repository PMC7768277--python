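"""Kymograph construction and per-punctum trajectory extraction.

A kymograph resamples a time-lapse stack along an axon path: each row is
one frame, each column one unit-pixel step along the path, so moving
puncta appear as sloped streaks. Trajectories are recovered by per-row
peak detection (sub-pixel parabolic refinement) followed by greedy
nearest-neighbour frame-to-frame linking — a deterministic, auditable
stand-in for manual kymograph tracing. Externally traced trajectories can
be imported as CSV instead (see :mod:`punctaquant.trajectory`).

Coordinate conventions: positions are micrometres from the start of the
axon path; pixel indices are 0-based; the ``soma_side`` flag records
which path end faces the cell body so that anterograde (away from soma)
can be distinguished from retrograde.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from punctaquant.trajectory import Trajectory


@dataclass
class AxonROI:
    """Axon path region of interest.

    Attributes
    ----------
    points : (N, 2) ndarray
        Ordered (x, y) pixel coordinates of the path; N >= 2.
    line_width : int
        Perpendicular averaging width in pixels (max is taken across it).
    soma_side : str
        Which path end faces the cell body: ``"start"`` or ``"end"``.
    pixel_size : float
        Micrometres per pixel.
    """

    points: np.ndarray
    line_width: int = 1
    soma_side: str = "start"
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise ValueError("ROI path needs >= 2 (x, y) points")
        if self.soma_side not in ("start", "end"):
            raise ValueError(f"soma_side must be 'start' or 'end', got {self.soma_side!r}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def length_px(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    @property
    def length_um(self) -> float:
        """Imaged axon length l in micrometres."""
        return self.length_px * self.pixel_size


@dataclass
class Kymograph:
    """Space-time intensity matrix: rows = frames, columns = path positions."""

    image: np.ndarray
    pixel_size: float  # um per column
    frame_interval: float  # s per row
    soma_side: str = "start"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        self.image = np.asarray(self.image, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.image.shape[0]

    @property
    def length_um(self) -> float:
        return self.image.shape[1] * self.pixel_size


def _resample_path(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at unit-pixel arclength steps.

    Returns (samples, normals); samples is (M, 2) x,y and normals the unit
    perpendicular at each sample.
    """
    seg = np.diff(points, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    s = np.arange(0.0, total + 1e-9, 1.0)
    x = np.interp(s, arclen, points[:, 0])
    y = np.interp(s, arclen, points[:, 1])
    samples = np.column_stack([x, y])
    # tangent by central differences, normal = rotate 90 deg
    tang = np.gradient(samples, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    tang /= norm[:, None]
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return samples, normals


def build_kymograph(
    stack: np.ndarray,
    roi: AxonROI,
    frame_interval: float,
    background_subtract: bool = False,
) -> Kymograph:
    """Sample each frame along the ROI path to build a kymograph.

    For every frame, intensity is sampled (bilinear) at unit-pixel steps
    along the path; across the perpendicular ``line_width`` the maximum is
    taken, so puncta slightly off-axis are still captured. With
    ``background_subtract`` each row's median is removed, making the
    result invariant to frame-wise constant offsets.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None, :, :]
    n_frames, h, w = stack.shape
    samples, normals = _resample_path(roi.points)

    offsets = np.arange(roi.line_width, dtype=float) - (roi.line_width - 1) / 2.0
    # coords[k] = samples + offsets[k] * normals ; shape (n_off, M, 2)
    coords = samples[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    xs, ys = coords[..., 0], coords[..., 1]
    if xs.min() < -0.5 or ys.min() < -0.5 or xs.max() > w - 0.5 or ys.max() > h - 0.5:
        bad = np.unravel_index(
            int(np.argmax((xs < -0.5) | (ys < -0.5) | (xs > w - 0.5) | (ys > h - 0.5))), xs.shape
        )
        raise ValueError(
            f"ROI path (with line width) leaves the image at sample point "
            f"({xs[bad]:.1f}, {ys[bad]:.1f}); image is {w}x{h}"
        )

    rows = np.empty((n_frames, samples.shape[0]))
    for f in range(n_frames):
        vals = ndimage.map_coordinates(stack[f], [ys.ravel(), xs.ravel()], order=1, mode="nearest")
        rows[f] = vals.reshape(xs.shape).max(axis=0)
    if background_subtract:
        rows -= np.median(rows, axis=1, keepdims=True)
    return Kymograph(rows, pixel_size=roi.pixel_size, frame_interval=frame_interval, soma_side=roi.soma_side)


def detect_puncta(row: np.ndarray, min_prominence: float, pixel_size: float = 1.0) -> np.ndarray:
    """Detect puncta in one kymograph row, sub-pixel refined.

    Local maxima with prominence >= ``min_prominence`` are refined by a
    3-point parabolic fit; returns positions in micrometres, ascending.
    An empty result is not an error.
    """
    row = np.asarray(row, dtype=float)
    if len(row) < 3:
        return np.array([])
    peaks, _ = signal.find_peaks(row, prominence=min_prominence)
    positions = []
    for p in peaks:
        if 0 < p < len(row) - 1:
            denom = row[p - 1] - 2 * row[p] + row[p + 1]
            delta = 0.5 * (row[p - 1] - row[p + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        positions.append((p + delta) * pixel_size)
    return np.array(sorted(positions))


class _Track:
    __slots__ = ("tid", "frames", "positions")

    def __init__(self, tid: int, frame: int, pos: float):
        self.tid = tid
        self.frames = [frame]
        self.positions = [pos]


def link_trajectories(
    detections: list[np.ndarray],
    max_step: float,
    max_gap: int = 0,
    frame_interval: float = 1.0,
    min_length: int = 2,
) -> list[Trajectory]:
    """Greedy nearest-neighbour linking of per-frame detections.

    Per frame transition, (track, detection) candidate pairs within
    ``max_step * n_frames_elapsed`` micrometres are assigned greedily in
    order of increasing distance, ties broken by lower position; each
    detection is used at most once (the assignment is a partial matching).
    Tracks unmatched for more than ``max_gap`` frames are closed; bridged
    gaps are filled by linear interpolation. Tracks shorter than
    ``min_length`` detections are discarded.
    """
    if max_step <= 0:
        raise ValueError("max_step must be > 0")
    active: list[_Track] = []
    done: list[_Track] = []
    next_id = 0
    for f, dets in enumerate(detections):
        dets = np.asarray(dets, dtype=float)
        # candidate pairs among tracks still within the gap window
        pairs = []
        for ti, tr in enumerate(active):
            elapsed = f - tr.frames[-1]
            for di, d in enumerate(dets):
                dist = abs(d - tr.positions[-1])
                if dist <= max_step * elapsed:
                    pairs.append((dist, d, ti, di))
        pairs.sort(key=lambda p: (p[0], p[1]))
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, d, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            active[ti].frames.append(f)
            active[ti].positions.append(float(d))
        for di, d in enumerate(dets):
            if di not in used_d:
                active.append(_Track(next_id, f, float(d)))
                next_id += 1
        still = []
        for tr in active:
            if f - tr.frames[-1] > max_gap:
                done.append(tr)
            else:
                still.append(tr)
        active = still
    done.extend(active)

    out: list[Trajectory] = []
    for tr in sorted(done, key=lambda t: t.tid):
        if len(tr.frames) < min_length:
            continue
        frames = np.arange(tr.frames[0], tr.frames[-1] + 1)
        positions = np.interp(frames, tr.frames, tr.positions)  # bridge gaps linearly
        out.append(
            Trajectory(
                punctum_id=tr.tid,
                frames=frames,
                times=frames * frame_interval,
                positions=positions,
            )
        )
    return out


def track_kymograph(
    kymo: Kymograph,
    min_prominence: float,
    max_step_um: float,
    max_gap: int = 2,
    min_length: int = 2,
) -> list[Trajectory]:
    """Detect puncta in every row and link them into trajectories."""
    detections = [detect_puncta(row, min_prominence, kymo.pixel_size) for row in kymo.image]
    return link_trajectories(
        detections,
        max_step=max_step_um,
        max_gap=max_gap,
        frame_interval=kymo.frame_interval,
        min_length=min_length,
    )
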