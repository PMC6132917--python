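"""Core in-memory containers for the connectivity pipeline.

The pipeline moves a subject-session through three representations:
a regional BOLD time-series matrix (:class:`RoiTimeSeries`), the paired
rigid-body motion trace (:class:`MotionTrace`), and the Fisher-z functional
network (:class:`AdjacencyMatrix`).  All containers validate their invariants
on construction so that downstream graph code can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Column order of a motion-parameter file: three translations in mm followed
#: by three rotations in radians (the common realignment-output convention).
MOTION_COLUMNS = (
    "trans_x_mm",
    "trans_y_mm",
    "trans_z_mm",
    "rot_x_rad",
    "rot_y_rad",
    "rot_z_rad",
)


@dataclass
class RoiTimeSeries:
    """A frames x nodes matrix of regional signals.

    Parameters
    ----------
    values
        Real matrix, one row per acquired frame (volume), one column per
        atlas region.
    node_labels
        Region names, one per column.
    tr_seconds
        Sampling interval (repetition time); informational only.
    """

    values: np.ndarray
    node_labels: tuple[str, ...]
    tr_seconds: float = 2.15

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D frames x nodes matrix")
        self.node_labels = tuple(str(x) for x in self.node_labels)
        if len(self.node_labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.node_labels)} labels for {self.values.shape[1]} nodes"
            )
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 nodes")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class MotionTrace:
    """Frames x 6 rigid-body parameters: translations (mm), rotations (rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("motion trace must be a frames x 6 matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.values[:, 3:]


@dataclass
class AdjacencyMatrix:
    """Undirected weighted functional network (Fisher-z of Pearson r).

    Invariants enforced: symmetric to 1e-12, exactly zero diagonal, all
    entries finite.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isfinite(w).all():
            raise ValueError("adjacency contains non-finite weights")
        if np.abs(w - w.T).max(initial=0.0) > 1e-12:
            raise ValueError("adjacency is not symmetric (tolerance 1e-12)")
        if np.any(np.diagonal(w) != 0.0):
            raise ValueError("adjacency diagonal must be exactly zero")
        self.weights = w
        if not self.node_labels:
            self.node_labels = tuple(f"node{i}" for i in range(w.shape[0]))
        else:
            self.node_labels = tuple(str(x) for x in self.node_labels)
        if len(self.node_labels) != w.shape[0]:
            raise ValueError("label count does not match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]
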