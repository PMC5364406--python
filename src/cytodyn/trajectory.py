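"""Core trajectory container shared by every analysis stage.

A :class:`Trajectory` is a time-ordered sequence of 2D positions (µm) of a
single particle, indexed by integer frame numbers.  Frames may be missing
(fluorophore blinking, failed detections); time stamps always reflect true
wall-clock time so delay-dependent statistics remain correct across gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Positions of one tracked particle.

    Parameters
    ----------
    track_id : int
        Identifier, unique within one dataset.
    frames : ndarray of int
        Strictly increasing frame indices; gaps allowed.
    t : ndarray of float
        Time stamps in seconds, one per frame.
    x, y : ndarray of float
        Coordinates in µm.
    state : ndarray of str, optional
        Per-frame ground-truth labels from a simulator (e.g. ``"bound"`` /
        ``"unbound"`` or ``"fast"`` / ``"slow"``); absent for real data.
    """

    track_id: int
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    state: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frames)
        if not (len(self.t) == len(self.x) == len(self.y) == n):
            raise ValueError(
                f"track {self.track_id}: frames/t/x/y lengths differ "
                f"({n}/{len(self.t)}/{len(self.x)}/{len(self.y)})"
            )
        if n and np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")
        if self.state is not None:
            self.state = np.asarray(self.state)
            if len(self.state) != n:
                raise ValueError(f"track {self.track_id}: state length mismatch")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of xy positions in µm."""
        return np.column_stack([self.x, self.y])

    @property
    def dt(self) -> float:
        """Median frame interval in seconds (uniform for ungapped tracks)."""
        if len(self) < 2:
            raise ValueError("need >= 2 points for a frame interval")
        df = np.diff(self.frames)
        return float(np.median(np.diff(self.t) / df))

    @property
    def has_gaps(self) -> bool:
        return bool(len(self) >= 2 and np.any(np.diff(self.frames) != 1))

    @property
    def duration(self) -> float:
        """Total elapsed time in seconds."""
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def displacements(self) -> np.ndarray:
        """(n-1, 2) consecutive-sample displacement vectors in µm."""
        return np.diff(self.positions, axis=0)

    def path_length(self) -> float:
        """Total polyline length in µm."""
        return float(np.sum(np.hypot(*np.diff(self.positions, axis=0).T)))

    def slice(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory over a positional index range [start, stop)."""
        return Trajectory(
            track_id=self.track_id,
            frames=self.frames[start:stop],
            t=self.t[start:stop],
            x=self.x[start:stop],
            y=self.y[start:stop],
            state=None if self.state is None else self.state[start:stop],
        )
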