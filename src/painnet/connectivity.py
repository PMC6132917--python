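"""From time series + motion to a scrubbed Fisher-z adjacency matrix.

The construction follows the standard resting-state recipe: discard the
initial non-equilibrium volumes, compute framewise displacement from the six
rigid-body parameters, scrub (exclude) frames whose incoming transition
exceeds a displacement threshold, correlate the surviving frames between every
pair of regions (Pearson), and Fisher-transform the correlations into an
undirected weighted network.  The scalar motion covariate used by the
statistical layer — mean absolute frame-to-frame head movement over the six
parameters — is computed here as well.

Rotations are expressed in radians and converted to arc length on a sphere of
``head_radius_mm`` (default 50 mm) wherever they are combined with
translations.
"""

from __future__ import annotations

from typing import overload

import numpy as np

from .types import AdjacencyMatrix, MotionTrace, RoiTimeSeries

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 1.5
DEFAULT_DROP_VOLUMES = 3


@overload
def drop_initial_volumes(ts: RoiTimeSeries, k: int = ...) -> RoiTimeSeries: ...
@overload
def drop_initial_volumes(ts: MotionTrace, k: int = ...) -> MotionTrace: ...


def drop_initial_volumes(ts, k: int = DEFAULT_DROP_VOLUMES):
    """Remove the first ``k`` frames (field-equilibrium volumes).

    Works on either a :class:`RoiTimeSeries` or a :class:`MotionTrace`; the
    caller is responsible for applying the same ``k`` to both members of a
    pair so they stay frame-aligned.

    Raises
    ------
    ValueError
        If no frames would remain (``frames <= k``).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    n = ts.n_frames
    if n <= k:
        raise ValueError(f"cannot drop {k} initial volumes from {n} frames")
    if isinstance(ts, RoiTimeSeries):
        return RoiTimeSeries(ts.values[k:], ts.node_labels, ts.tr_seconds)
    if isinstance(ts, MotionTrace):
        return MotionTrace(ts.values[k:])
    raise TypeError(f"unsupported input type {type(ts).__name__}")


def frame_displacement(
    motion: MotionTrace, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement (mm) at each frame-to-frame transition.

    FD at transition t is the sum of the absolute translation differences
    plus the absolute rotation differences converted to arc length on a
    sphere of ``head_radius_mm``:

        FD_t = sum_i |d trans_i| + sum_j |r * d rot_j|

    Returns an array of length ``frames - 1``.
    """
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames to compute displacement")
    d = np.diff(motion.values, axis=0)
    return np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)


def scrub_mask(
    displacement: np.ndarray,
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    drop_preceding: bool = False,
) -> np.ndarray:
    """Boolean retained-frame mask from framewise displacement.

    A transition with displacement strictly greater than ``threshold_mm``
    marks the latter frame of the pair as excluded (and, if
    ``drop_preceding``, the earlier frame too).  Displacement exactly at the
    threshold does not exclude.  Mask length is ``len(displacement) + 1``.
    """
    fd = np.asarray(displacement, dtype=float)
    if fd.ndim != 1:
        raise ValueError("displacement must be 1-D")
    if not np.isfinite(fd).all():
        raise ValueError("displacement contains non-finite values")
    mask = np.ones(fd.size + 1, dtype=bool)
    bad = fd > threshold_mm
    mask[1:][bad] = False
    if drop_preceding:
        mask[:-1][bad] = False
    return mask


def mean_motion(
    motion: MotionTrace, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> float:
    """Scalar motion covariate: mean absolute frame-to-frame movement.

    Per parameter, the mean absolute first difference across the scan;
    rotations are converted to mm via ``head_radius_mm`` so the six
    parameters are commensurable; the six per-parameter means are then
    averaged.
    """
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames to compute mean motion")
    d = np.abs(np.diff(motion.values, axis=0))
    d[:, 3:] *= head_radius_mm
    return float(d.mean(axis=0).mean())


def correlation_matrix(ts: RoiTimeSeries, mask: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between every pair of regions over retained frames.

    Parameters
    ----------
    ts
        Regional time series (post volume-discard).
    mask
        Boolean retained-frame mask of length ``ts.n_frames`` (from
        :func:`scrub_mask`); ``None`` retains every frame.

    Raises
    ------
    ValueError
        If fewer than 3 frames survive, or any region has zero variance over
        the retained frames (reported by label — silent NaN propagation into
        the graph metrics would be worse than failing here).
    """
    if mask is None:
        x = ts.values
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (ts.n_frames,):
            raise ValueError("mask length does not match frame count")
        x = ts.values[mask]
    if x.shape[0] < 3:
        raise ValueError(
            f"only {x.shape[0]} retained frames; need >= 3 for correlation"
        )
    sd = x.std(axis=0)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        names = ", ".join(ts.node_labels[i] for i in zero[:5])
        raise ValueError(f"zero-variance node(s) over retained frames: {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_transform(
    r: np.ndarray, node_labels: tuple[str, ...] | None = None
) -> AdjacencyMatrix:
    """Fisher z-transform a correlation matrix into an adjacency matrix.

    Off-diagonal entries become arctanh(r); the diagonal is set to zero
    (self-connections are not part of the network).  Off-diagonal |r| >= 1
    would map to +-infinity and is rejected, naming the offending pair.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    off = ~np.eye(r.shape[0], dtype=bool)
    bad = off & (np.abs(r) >= 1.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        if node_labels is not None:
            pair = f"({node_labels[i]}, {node_labels[j]})"
        else:
            pair = f"({i}, {j})"
        raise ValueError(f"|r| >= 1 between node pair {pair}; Fisher z undefined")
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    z = (z + z.T) / 2.0
    return AdjacencyMatrix(z, node_labels or ())


def subject_adjacency(
    ts: RoiTimeSeries,
    motion: MotionTrace,
    *,
    drop_volumes: int = DEFAULT_DROP_VOLUMES,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    drop_preceding: bool = False,
) -> tuple[AdjacencyMatrix, int, float]:
    """Full per-subject construction: discard, scrub, correlate, Fisher.

    Returns ``(adjacency, n_frames_retained, mean_motion)``.  The motion
    covariate is computed on the post-discard trace, before scrubbing, to
    summarize movement over the analyzed scan.
    """
    if motion.n_frames != ts.n_frames:
        raise ValueError(
            f"motion ({motion.n_frames}) and time series ({ts.n_frames}) "
            "frame counts differ"
        )
    ts = drop_initial_volumes(ts, drop_volumes)
    motion = drop_initial_volumes(motion, drop_volumes)
    fd = frame_displacement(motion, head_radius_mm)
    mask = scrub_mask(fd, fd_threshold_mm, drop_preceding)
    avg_motion = mean_motion(motion, head_radius_mm)
    r = correlation_matrix(ts, mask)
    adj = fisher_transform(r, ts.node_labels)
    return adj, int(mask.sum()), avg_motion
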