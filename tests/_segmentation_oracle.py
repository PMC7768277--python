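"""Naive brute-force re-derivation of the run-segmentation semantics.

Kept deliberately simple (O(n^3) pairwise window checks, repeated
interval merging to fixpoint) and independent of the library's
vectorized implementation, so the two can be compared exhaustively.
"""

import numpy as np

from punctaquant.trajectory import Trajectory
from punctaquant.transport import segment_runs


def brute_segments(x, k, eps, thr):
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return []
    windows = []
    for i in range(n - k + 1):
        w = x[i : i + k]
        if all(abs(w[a] - w[b]) <= eps for a in range(k) for b in range(k)):
            windows.append([i, i + k - 1])
    # merge windows sharing at least one frame, to fixpoint
    merged = True
    while merged:
        merged = False
        out = []
        for w in sorted(windows):
            if out and w[0] <= out[-1][1]:
                out[-1][1] = max(out[-1][1], w[1])
                merged = True
            else:
                out.append(list(w))
        windows = out
    bounds = [0]
    for s, e in windows:
        bounds += [s, e]
    bounds.append(n - 1)
    stretches = [
        (bounds[i], bounds[i + 1])
        for i in range(0, len(bounds) - 1, 2)
        if bounds[i + 1] > bounds[i]
    ]
    segments = []
    for a, b in stretches:
        cuts = []
        cur = 0
        for j in range(a, b):
            s = np.sign(x[j + 1] - x[j])
            if s == 0:
                continue
            if cur == 0:
                cur = s
            elif s == -cur and j + 1 < b and np.sign(x[j + 2] - x[j + 1]) == s:
                cuts.append(j)
                cur = s
        edges = [a] + cuts + [b]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo and abs(x[hi] - x[lo]) >= thr and x[hi] != x[lo]:
                segments.append((lo, hi, x[hi] - x[lo]))
    return segments


def impl_segments(x, k, eps, thr):
    x = np.asarray(x, dtype=float)
    frames = np.arange(len(x))
    traj = Trajectory(0, frames, frames * 0.5, x)
    runs = segment_runs(traj, run_threshold=thr, stationary_frames=k, stationary_eps=eps)
    return [(r.start_frame, r.end_frame, r.displacement) for r in runs]
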