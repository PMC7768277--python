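"""Per-punctum trajectory container and CSV round-trip.

A trajectory is the time-ordered path of one punctum along the axon axis,
with positions measured in micrometres from the start of the axon path.
The CSV dialect (``punctum_id, frame, time_s, position_um``) is shared by
the simulator, the tracker and the metrics stage, so manually traced
kymograph paths can be imported unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CSV_COLUMNS = ["punctum_id", "frame", "time_s", "position_um"]


@dataclass
class Trajectory:
    """Time-ordered positions of one punctum along the axon.

    Attributes
    ----------
    punctum_id : int
        Identifier, unique within a cell/movie.
    frames : ndarray of int
        Frame indices, strictly increasing.
    times : ndarray of float
        Acquisition times in seconds, same length as ``frames``.
    positions : ndarray of float
        Position along the axon path in micrometres, measured from the
        start of the path.
    """

    punctum_id: int
    frames: np.ndarray
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if not (len(self.frames) == len(self.times) == len(self.positions)):
            raise ValueError("frames, times and positions must have equal length")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def net_displacement(self) -> float:
        """Signed end-to-start displacement in micrometres."""
        if len(self) == 0:
            return 0.0
        return float(self.positions[-1] - self.positions[0])


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into a long-format DataFrame (CSV dialect)."""
    if not trajectories:
        return pd.DataFrame(columns=CSV_COLUMNS)
    parts = [
        pd.DataFrame(
            {
                "punctum_id": t.punctum_id,
                "frame": t.frames,
                "time_s": t.times,
                "position_um": t.positions,
            }
        )
        for t in trajectories
    ]
    return pd.concat(parts, ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    bad = df[CSV_COLUMNS].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"trajectory table has missing values at data row {row}")
    out = []
    for pid, grp in df.groupby("punctum_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                punctum_id=int(pid),
                frames=grp["frame"].to_numpy(),
                times=grp["time_s"].to_numpy(),
                positions=grp["position_um"].to_numpy(),
            )
        )
    return out


def write_trajectories_csv(path, trajectories: list[Trajectory]) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False)


def read_trajectories_csv(path) -> list[Trajectory]:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # surface the offending line
        raise ValueError(f"malformed trajectory CSV {path}: {exc}") from exc
    return frame_to_trajectories(df)
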