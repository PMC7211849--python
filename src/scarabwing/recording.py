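"""Containers for free-flight motion-capture landmark data.

A recording holds time-indexed 3D positions (millimetres) of three thorax
points, used to reconstruct the body reference frame, and seven wing
landmarks: three on the stiff leading edge (``wb`` wing base, ``mj``
marginal joint, ``wt`` wing tip) and four trailing-edge vein tips
(``RP``, ``MP``, ``CuA``, ``AA``) whose out-of-plane motion carries the
elastic-deformation signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

THORAX_LABELS: tuple[str, ...] = ("th1", "th2", "th3")
LEADING_EDGE_LABELS: tuple[str, ...] = ("wb", "mj", "wt")
TRAILING_EDGE_LABELS: tuple[str, ...] = ("RP", "MP", "CuA", "AA")
WING_LABELS: tuple[str, ...] = LEADING_EDGE_LABELS + TRAILING_EDGE_LABELS


@dataclass
class FlightRecording:
    """Time-synchronized 3D trajectories of thorax and wing landmarks.

    Parameters
    ----------
    times : (n,) array
        Frame times in seconds, strictly increasing, no gaps.
    thorax_points : dict
        Maps each label in :data:`THORAX_LABELS` to an ``(n, 3)`` array (mm).
    wing_points : dict
        Maps each label in :data:`WING_LABELS` to an ``(n, 3)`` array (mm).
    ground_truth : dict or None
        Optional generating angle/deflection series kept by the simulator
        so estimators can be validated against known commands.
    """

    times: np.ndarray
    thorax_points: dict[str, np.ndarray]
    wing_points: dict[str, np.ndarray]
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        n = self.times.shape[0]
        if n < 2:
            raise ValueError("recording needs at least two frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        missing = [l for l in THORAX_LABELS if l not in self.thorax_points]
        missing += [l for l in WING_LABELS if l not in self.wing_points]
        if missing:
            raise ValueError(f"missing landmark trajectories: {missing}")
        for d in (self.thorax_points, self.wing_points):
            for label, arr in d.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n, 3):
                    raise ValueError(
                        f"trajectory {label!r} has shape {arr.shape}, expected {(n, 3)}"
                    )
                d[label] = arr

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def frame_rate(self) -> float:
        """Mean sampling rate in Hz."""
        return (self.n_frames - 1) / (self.times[-1] - self.times[0])

    def wing_array(self, labels: tuple[str, ...] = WING_LABELS) -> np.ndarray:
        """Stack wing trajectories into an ``(n, len(labels), 3)`` array."""
        return np.stack([self.wing_points[l] for l in labels], axis=1)
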