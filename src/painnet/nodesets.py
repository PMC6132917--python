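"""Named node sets over the 264-node whole-brain atlas ordering.

Three sets ship with the package: the 264-node whole brain, a 58-node default
mode network (DMN), and a 16-node pain network built from the positive-weight
regions of the neural pain signature (NPS).  Indices are 0-based positions
into the whole-brain node ordering.  The concrete index assignments for the
pain and DMN sets are documented placeholders (see ``data/*.json``): the
region names are known but their atlas indices are not part of this package's
inputs, so the sets are shipped as editable JSON and every computation is
index-set-generic — substituting the exact assignments changes no code.

Also provides optional sphere-ROI time-series extraction from a 4-D NIfTI
volume, for users bringing their own preprocessed data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .types import AdjacencyMatrix, RoiTimeSeries

PACKAGED_NODESETS = ("whole_brain", "dmn", "pain")


@dataclass(frozen=True)
class NodeSet:
    """A named, ordered set of node indices into the whole-brain ordering."""

    name: str
    indices: tuple[int, ...]
    n_total: int
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        idx = self.indices
        if len(set(idx)) != len(idx):
            raise ValueError(f"node set '{self.name}' has duplicate indices")
        if any(i < 0 or i >= self.n_total for i in idx):
            raise ValueError(
                f"node set '{self.name}' has indices outside [0, {self.n_total})"
            )
        if self.region_labels is not None and len(self.region_labels) != len(idx):
            raise ValueError("region_labels length does not match indices")

    def __len__(self) -> int:
        return len(self.indices)


def _from_dict(obj: dict) -> NodeSet:
    labels = obj.get("labels")
    return NodeSet(
        name=str(obj["name"]),
        indices=tuple(int(i) for i in obj["indices"]),
        n_total=int(obj["n_total"]),
        region_labels=tuple(labels) if labels else None,
    )


def load_nodeset(name_or_path: str | Path) -> NodeSet:
    """Load a packaged node set by name, or any set from a JSON file.

    Packaged names: ``whole_brain`` (264 nodes), ``dmn`` (58), ``pain`` (16).
    JSON schema: ``{"name": str, "n_total": int, "indices": [int],
    "labels": [str]?}``.
    """
    name = str(name_or_path)
    if name in PACKAGED_NODESETS:
        text = (
            resources.files("painnet").joinpath(f"data/{name}.json").read_text()
        )
        ns = _from_dict(json.loads(text))
        expected = {"whole_brain": 264, "dmn": 58, "pain": 16}[name]
        if len(ns) != expected:
            raise ValueError(
                f"packaged set '{name}' has {len(ns)} nodes, expected {expected}"
            )
        return ns
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(
            f"unknown node set '{name}': not one of {PACKAGED_NODESETS} "
            "and no such file"
        )
    return _from_dict(json.loads(path.read_text()))


def induced_subgraph(adj: AdjacencyMatrix, nodes: NodeSet) -> AdjacencyMatrix:
    """Restrict an adjacency matrix to a node set (edges among its members).

    Preserves the weight values and the node set's label order.
    """
    n = adj.n_nodes
    if any(i >= n for i in nodes.indices):
        raise ValueError(
            f"node set '{nodes.name}' indexes beyond the {n}-node adjacency"
        )
    idx = np.asarray(nodes.indices, dtype=int)
    sub = adj.weights[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, 0.0)
    labels = nodes.region_labels or tuple(adj.node_labels[i] for i in idx)
    return AdjacencyMatrix(sub, labels)


@dataclass(frozen=True)
class SphereRoi:
    """A spherical region of interest in world coordinates (mm)."""

    center: tuple[float, float, float]
    radius_mm: float = 5.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("sphere radius must be positive")


def extract_roi_timeseries(
    volume4d, rois: list[SphereRoi], tr_seconds: float | None = None
) -> RoiTimeSeries:
    """Mean sphere-ROI time series from a 4-D NIfTI image.

    A voxel belongs to an ROI when its world-space center lies within
    ``radius_mm`` of the ROI center (Euclidean distance through the image
    affine).  Each frame's ROI value is the mean over member voxels.

    Parameters
    ----------
    volume4d
        A ``nibabel`` image object or a path to a ``.nii``/``.nii.gz`` file.
    rois
        Sphere definitions; an ROI containing no voxel is an error (named).
    tr_seconds
        Override for the sampling interval; defaults to the header TR.
    """
    import nibabel as nib

    img = volume4d if hasattr(volume4d, "affine") else nib.load(str(volume4d))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, time)")
    affine = img.affine
    nx, ny, nz, nt = data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    world = (affine @ vox)[:3].T  # voxel centers in mm

    flat = data.reshape(-1, nt)
    series = np.empty((nt, len(rois)))
    labels = []
    for col, roi in enumerate(rois):
        d2 = ((world - np.asarray(roi.center)) ** 2).sum(axis=1)
        member = d2 <= roi.radius_mm**2
        if not member.any():
            label = roi.name or f"roi{col}"
            raise ValueError(f"sphere ROI '{label}' contains no voxel")
        series[:, col] = flat[member].mean(axis=0)
        labels.append(roi.name or f"roi{col}")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 1.0
    return RoiTimeSeries(series, tuple(labels), tr_seconds)
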