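"""Directed-run segmentation and axonal-transport statistics.

The central quantity is *flux*: the sum of distances travelled by all
moving puncta, standardized by the length of axon imaged and the movie
duration,

    flux = sum_i |d_i| / (l * t)      [min^-1]

where the ``d_i`` are individual run lengths (micrometres), ``l`` the
imaged axon length (micrometres) and ``t`` the movie duration (minutes).

A punctum is undergoing a *directed run* if a segment of its trajectory
covers >= ``run_threshold`` micrometres (default 2 um). The threshold is a
safe estimate of the diffusion limit: a passive cargo with diffusion
coefficient D has root-mean-squared displacement sqrt(2*D*t) in one
dimension, which for D = 0.01 um^2/s over t = 50 s is 1 um — directed
runs must exceed it. A run terminates when the punctum remains in the
same position (within ``stationary_eps``) for at least
``stationary_frames`` consecutive frames, or when its direction reverses.

Directionality is defined relative to the cell body: anterograde motion
points away from the soma-side end of the axon path, retrograde toward it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from punctaquant.trajectory import Trajectory

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"

#: defaults for the directed-run criterion
DEFAULT_RUN_THRESHOLD_UM = 2.0
DEFAULT_STATIONARY_FRAMES = 4
DEFAULT_STATIONARY_EPS_UM = 0.25  # ~1 camera pixel


def diffusion_limit(D: float, t: float) -> float:
    """Root-mean-squared displacement of a 1-D diffuser, sqrt(2*D*t).

    Parameters
    ----------
    D : float
        Diffusion coefficient, um^2/s. Must be >= 0.
    t : float
        Observation time, s. Must be > 0.

    Returns
    -------
    float
        RMS displacement in micrometres. Used to justify a directed-run
        distance threshold: displacements well above this value cannot be
        explained by diffusion.
    """
    if D < 0:
        raise ValueError(f"diffusion coefficient must be >= 0, got {D}")
    if t <= 0:
        raise ValueError(f"time must be > 0, got {t}")
    return math.sqrt(2.0 * D * t)


@dataclass
class RunSegment:
    """One directed run of one punctum."""

    punctum_id: int
    start_frame: int
    end_frame: int
    start_position: float  # um
    end_position: float  # um
    displacement: float  # um, signed (end - start)
    path_length: float  # um, sum of |frame-to-frame| steps
    duration: float  # s
    direction: str  # anterograde | retrograde

    @property
    def distance(self) -> float:
        """Unsigned run length |d| in micrometres."""
        return abs(self.displacement)


def classify_direction(displacement: float, soma_side: str = "start") -> str:
    """Classify a signed displacement as anterograde or retrograde.

    Positions are measured from the start of the axon path; anterograde
    motion points away from the soma. With the soma at the path start,
    positive displacement is anterograde; with the soma at the path end
    the convention flips.
    """
    if displacement == 0:
        raise ValueError("cannot classify zero displacement")
    if soma_side not in ("start", "end"):
        raise ValueError(f"soma_side must be 'start' or 'end', got {soma_side!r}")
    away_from_soma = displacement > 0 if soma_side == "start" else displacement < 0
    return ANTEROGRADE if away_from_soma else RETROGRADE


def _stationary_blocks(x: np.ndarray, eps: float, k: int) -> list[tuple[int, int]]:
    """Maximal index blocks where some k-frame window has position range <= eps.

    A window of k consecutive samples is stationary iff all pairwise
    displacements within it are <= eps, i.e. max - min <= eps. Overlapping
    and adjacent stationary windows are merged into maximal blocks,
    returned as inclusive (start, end) index pairs.
    """
    n = len(x)
    if n < k:
        return []
    starts = [i for i in range(n - k + 1) if np.ptp(x[i : i + k]) <= eps]
    if not starts:
        return []
    # merge windows that share at least one frame into maximal blocks
    merged: list[list[int]] = []
    for s in starts:
        e = s + k - 1
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _reversal_cuts(x: np.ndarray, i0: int, i1: int) -> list[int]:
    """Indices (within [i0, i1]) where a sustained direction reversal occurs.

    A reversal cut is placed at the local extremum index j when the steps
    j->j+1 and j+1->j+2 both carry the sign opposite to the current travel
    direction. Zero steps neither establish nor break a direction.
    """
    cuts = []
    cur_dir = 0
    j = i0
    while j < i1:
        s = np.sign(x[j + 1] - x[j])
        if s != 0:
            if cur_dir == 0:
                cur_dir = s
            elif s == -cur_dir:
                if j + 1 < i1 and np.sign(x[j + 2] - x[j + 1]) == s:
                    cuts.append(j)
                    cur_dir = s
        j += 1
    return cuts


def segment_runs(
    traj: Trajectory,
    run_threshold: float = DEFAULT_RUN_THRESHOLD_UM,
    stationary_frames: int = DEFAULT_STATIONARY_FRAMES,
    stationary_eps: float = DEFAULT_STATIONARY_EPS_UM,
    soma_side: str = "start",
    distance_mode: str = "net",
) -> list[RunSegment]:
    """Cut a trajectory into directed runs.

    The trajectory is cut at every stationarity event (>=
    ``stationary_frames`` consecutive frames whose positions all lie
    within ``stationary_eps`` of each other) and at every sustained
    direction reversal. Each inter-cut segment whose distance is >=
    ``run_threshold`` becomes one :class:`RunSegment`. ``distance_mode``
    selects the distance measure: ``"net"`` (default) uses the segment's
    net displacement, ``"path"`` the summed frame-to-frame path length.

    Returns a list of non-overlapping, time-ordered segments; a
    trajectory shorter than two frames yields an empty list.
    """
    if distance_mode not in ("net", "path"):
        raise ValueError(f"distance_mode must be 'net' or 'path', got {distance_mode!r}")
    x = np.asarray(traj.positions, dtype=float)
    t = np.asarray(traj.times, dtype=float)
    n = len(x)
    if n < 2:
        return []

    blocks = _stationary_blocks(x, stationary_eps, stationary_frames)

    # candidate stretches between stationary blocks (sharing block endpoints)
    bounds = [0]
    for s, e in blocks:
        bounds.extend([s, e])
    bounds.append(n - 1)
    stretches = []
    # pair up: stretch_k = [bounds[2k], bounds[2k+1]]
    for k in range(0, len(bounds) - 1, 2):
        a, b = bounds[k], bounds[k + 1]
        if b > a:
            stretches.append((a, b))

    block_ends = {e for _, e in blocks}
    block_starts = {s for s, _ in blocks}

    segments: list[RunSegment] = []
    for a, b in stretches:
        cuts = _reversal_cuts(x, a, b)
        edges = [a] + cuts + [b]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi <= lo:
                continue
            d = x[hi] - x[lo]
            path = float(np.sum(np.abs(np.diff(x[lo : hi + 1]))))
            dist = abs(d) if distance_mode == "net" else path
            if dist >= run_threshold and d != 0:
                t_start = _refine_start(x, t, lo, hi) if lo in block_ends else t[lo]
                t_end = _refine_end(x, t, lo, hi) if hi in block_starts else t[hi]
                if not t_end > t_start:  # refinement degenerate; fall back
                    t_start, t_end = t[lo], t[hi]
                segments.append(
                    RunSegment(
                        punctum_id=traj.punctum_id,
                        start_frame=int(traj.frames[lo]),
                        end_frame=int(traj.frames[hi]),
                        start_position=float(x[lo]),
                        end_position=float(x[hi]),
                        displacement=float(d),
                        path_length=path,
                        duration=float(t_end - t_start),
                        direction=classify_direction(float(d), soma_side),
                    )
                )
    return segments


def _refine_start(x: np.ndarray, t: np.ndarray, lo: int, hi: int) -> float:
    """Sub-frame estimate of when motion left a stationarity cut.

    The cut frame sits at the pause position, so the true run start lies
    between frames lo and lo+1; with locally constant velocity (estimated
    from the first fully interior step) the partial first step locates it.
    Falls back to the frame time when no interior step is available.
    """
    if hi < lo + 2:
        return float(t[lo])
    gap = t[lo + 2] - t[lo + 1]
    v_loc = (x[lo + 2] - x[lo + 1]) / gap if gap > 0 else 0.0
    first = x[lo + 1] - x[lo]
    if v_loc == 0 or np.sign(v_loc) != np.sign(first):
        return float(t[lo])
    delta = float(np.clip(first / v_loc, 0.0, t[lo + 1] - t[lo]))
    return float(t[lo + 1] - delta)


def _refine_end(x: np.ndarray, t: np.ndarray, lo: int, hi: int) -> float:
    """Mirror of :func:`_refine_start` for the run's terminal cut."""
    if hi < lo + 2:
        return float(t[hi])
    gap = t[hi - 1] - t[hi - 2]
    v_loc = (x[hi - 1] - x[hi - 2]) / gap if gap > 0 else 0.0
    last = x[hi] - x[hi - 1]
    if v_loc == 0 or np.sign(v_loc) != np.sign(last):
        return float(t[hi])
    delta = float(np.clip(last / v_loc, 0.0, t[hi] - t[hi - 1]))
    return float(t[hi - 1] + delta)


def compute_flux(runs: list[RunSegment], axon_length: float, duration_min: float) -> float:
    """Flux = sum |d_i| / (l * t) in events-per-minute.

    Parameters
    ----------
    runs : list of RunSegment
        Filter by ``direction`` first for per-direction flux.
    axon_length : float
        Imaged axon length l, micrometres.
    duration_min : float
        Movie duration t, minutes (the whole movie, not per-trajectory
        dwell time).
    """
    if axon_length <= 0:
        raise ValueError(f"axon length must be > 0, got {axon_length}")
    if duration_min <= 0:
        raise ValueError(f"duration must be > 0, got {duration_min}")
    total = sum(r.distance for r in runs)
    return total / (axon_length * duration_min)


def run_velocity(run: RunSegment) -> float:
    """Per-run velocity |d| / duration in um/s (pauses excluded by construction)."""
    if run.duration <= 0:
        raise ValueError(f"run duration must be > 0, got {run.duration}")
    return run.distance / run.duration


def qualifies_as_run(traj: Trajectory, run_threshold: float = DEFAULT_RUN_THRESHOLD_UM) -> bool:
    """Whole-trajectory run criterion under the net-displacement convention.

    True iff |net displacement| >= threshold; used to measure how often
    pure diffusion would be misclassified as directed motion.
    """
    return abs(traj.net_displacement) >= run_threshold


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(len(values))) if len(values) > 1 else float("nan")
    return mean, sem


@dataclass
class CategoryStats:
    """Flux / velocity / run-length block for one direction category."""

    flux: float  # min^-1
    velocity_mean: float  # um/s
    velocity_sem: float
    run_length_mean: float  # um
    run_length_sem: float
    n_runs: int


@dataclass
class TransportSummary:
    """Per-cell transport statistics in the standard table layout."""

    all_events: CategoryStats
    anterograde: CategoryStats
    retrograde: CategoryStats
    n_puncta: int
    n_runs: int
    axon_length: float  # um
    duration_min: float
    n_cells: int = 1

    def category(self, name: str) -> CategoryStats:
        return {"all": self.all_events, ANTEROGRADE: self.anterograde, RETROGRADE: self.retrograde}[name]


def _category_stats(runs: list[RunSegment], axon_length: float, duration_min: float) -> CategoryStats:
    vel = np.array([run_velocity(r) for r in runs])
    length = np.array([r.distance for r in runs])
    v_mean, v_sem = _mean_sem(vel)
    l_mean, l_sem = _mean_sem(length)
    return CategoryStats(
        flux=compute_flux(runs, axon_length, duration_min),
        velocity_mean=v_mean,
        velocity_sem=v_sem,
        run_length_mean=l_mean,
        run_length_sem=l_sem,
        n_runs=len(runs),
    )


def summarize_transport(
    trajectories: list[Trajectory],
    axon_length: float,
    duration_min: float,
    run_threshold: float = DEFAULT_RUN_THRESHOLD_UM,
    stationary_frames: int = DEFAULT_STATIONARY_FRAMES,
    stationary_eps: float = DEFAULT_STATIONARY_EPS_UM,
    soma_side: str = "start",
    distance_mode: str = "net",
) -> TransportSummary:
    """Segment every trajectory and aggregate flux/velocity/run length.

    Flux is reported per category (all, anterograde, retrograde); velocity
    and run length as mean +/- SEM across runs. Undefined statistics
    (no runs in a category) are reported as NaN.
    """
    runs: list[RunSegment] = []
    for traj in trajectories:
        runs.extend(
            segment_runs(
                traj,
                run_threshold=run_threshold,
                stationary_frames=stationary_frames,
                stationary_eps=stationary_eps,
                soma_side=soma_side,
                distance_mode=distance_mode,
            )
        )
    antero = [r for r in runs if r.direction == ANTEROGRADE]
    retro = [r for r in runs if r.direction == RETROGRADE]
    return TransportSummary(
        all_events=_category_stats(runs, axon_length, duration_min),
        anterograde=_category_stats(antero, axon_length, duration_min),
        retrograde=_category_stats(retro, axon_length, duration_min),
        n_puncta=len(trajectories),
        n_runs=len(runs),
        axon_length=axon_length,
        duration_min=duration_min,
    )


def percent_flux(treated: TransportSummary | float, control: TransportSummary | float) -> float:
    """Flux in treated cells normalized to controls (100%)."""
    t = treated.all_events.flux if isinstance(treated, TransportSummary) else float(treated)
    c = control.all_events.flux if isinstance(control, TransportSummary) else float(control)
    if c <= 0:
        raise ValueError("control flux must be > 0 to normalize")
    return 100.0 * t / c
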