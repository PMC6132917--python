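"""Weighted global efficiency and betweenness centrality, from first principles.

Functional networks here are dense, undirected, weighted graphs whose weights
are Fisher-z correlations: a larger weight means a stronger functional
connection.  Following the usual convention for connection-strength graphs,
a weight ``w > 0`` maps to a path length ``1/w`` and non-positive weights map
to absent edges (length infinity); negative z-values can optionally be used
by magnitude instead (``negative_policy="abs"``).

Global efficiency (GE) is the mean over ordered node pairs of the inverse
shortest path length (1/inf = 0) — a measure of network integration.
Betweenness centrality (BC) of node v is the sum over node pairs (s, t) of
the fraction of shortest s-t paths passing through v, reported on the
unordered-pair scale for undirected graphs; high-BC nodes are the network's
hubs.  Because edge lengths are floating-point, equality of path lengths is
judged at a relative tolerance (default 1e-10) so shortest-path counts are
stable.

Shortest paths and path counts are computed with a Dijkstra sweep run in
lockstep across all sources (dense graphs make the O(n^2)-per-source scan the
right choice); BC is then accumulated through the standard dependency
identity  sigma_st(v) = sigma_sv * sigma_vt  whenever  d(s,v) + d(v,t) =
d(s,t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nodesets import NodeSet, induced_subgraph
from .types import AdjacencyMatrix

LENGTH_TIE_RTOL = 1e-10
NEGATIVE_POLICIES = ("zero", "abs")


def to_lengths(
    adj: AdjacencyMatrix | np.ndarray, negative_policy: str = "zero"
) -> np.ndarray:
    """Convert connection weights to path lengths (reciprocal of weight).

    ``negative_policy="zero"`` drops non-positive weights (length +inf);
    ``"abs"`` uses the weight magnitude.  The diagonal is 0.
    """
    if negative_policy not in NEGATIVE_POLICIES:
        raise ValueError(
            f"unknown negative_policy '{negative_policy}'; use one of "
            f"{NEGATIVE_POLICIES}"
        )
    w = adj.weights if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, float)
    if not np.isfinite(w).all():
        raise ValueError("weights must be finite")
    if negative_policy == "abs":
        w = np.abs(w)
    lengths = np.full_like(w, np.inf, dtype=float)
    pos = w > 0
    lengths[pos] = 1.0 / w[pos]
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_paths(
    lengths: np.ndarray, rtol: float = LENGTH_TIE_RTOL
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest path lengths and counts of distinct shortest paths.

    Runs one Dijkstra per source, vectorized so every source advances one
    settle step per iteration.  Two candidate path lengths are considered
    equal when they differ by at most ``rtol`` relative to their magnitude;
    equal-length alternatives accumulate into the path count.

    Returns ``(D, sigma)``: ``D[i, j]`` the minimal i-to-j length (inf if
    unreachable) and ``sigma[i, j]`` the number of distinct minimal paths
    (0 if unreachable, 1 on the diagonal).
    """
    L = np.asarray(lengths, dtype=float)
    n = L.shape[0]
    if L.ndim != 2 or L.shape[1] != n:
        raise ValueError("length matrix must be square")
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    settled = np.zeros((n, n), dtype=bool)
    rows = np.arange(n)
    for _ in range(n):
        frontier = np.where(settled, np.inf, D)
        u = np.argmin(frontier, axis=1)
        du = frontier[rows, u]
        active = np.isfinite(du)
        if not active.any():
            break
        settled[rows, u] = True
        nd = du[:, None] + L[u]  # candidate distance source->u->j
        nd[~active] = np.inf
        cand = ~settled & np.isfinite(nd)
        finite_d = np.isfinite(D)
        tol = rtol * np.maximum(np.abs(nd), np.where(finite_d, np.abs(D), 0.0))
        with np.errstate(invalid="ignore"):
            shorter = cand & (~finite_d | (nd < D - tol))
            equal = cand & finite_d & ~shorter & (np.abs(nd - D) <= tol)
        su = np.broadcast_to(sigma[rows, u][:, None], (n, n))
        D[shorter] = nd[shorter]
        sigma[shorter] = su[shorter]
        sigma[equal] += su[equal]
    return D, sigma


def global_efficiency(
    adj: AdjacencyMatrix | np.ndarray, negative_policy: str = "zero"
) -> float:
    """Mean inverse shortest path length over ordered node pairs.

    Unreachable pairs contribute 0.  Requires at least 2 nodes.
    """
    lengths = to_lengths(adj, negative_policy)
    n = lengths.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    D, _ = shortest_paths(lengths)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(D[off] > 0, 1.0 / D[off], 0.0)
    inv[~np.isfinite(D[off])] = 0.0
    return float(inv.mean())


def betweenness_centrality(
    adj: AdjacencyMatrix | np.ndarray,
    negative_policy: str = "zero",
    rtol: float = LENGTH_TIE_RTOL,
) -> np.ndarray:
    """Weighted betweenness centrality, unordered-pair scale.

    ``bc[v] = 1/2 * sum_{s != t, both != v} sigma_st(v) / sigma_st`` where
    ``sigma_st`` counts shortest s-t paths and ``sigma_st(v)`` those through
    v.  Endpoints are never intermediates.  Requires at least 3 nodes.
    """
    lengths = to_lengths(adj, negative_policy)
    n = lengths.shape[0]
    if n < 3:
        raise ValueError("betweenness centrality needs at least 3 nodes")
    D, sigma = shortest_paths(lengths, rtol)
    finite = np.isfinite(D)
    bc = np.zeros(n)
    for v in range(n):
        ok = finite & finite[:, v][:, None] & finite[v, :][None, :]
        total = D[:, v][:, None] + D[v, :][None, :]
        tol = rtol * np.maximum(np.abs(total), np.abs(np.where(finite, D, 0.0)))
        with np.errstate(invalid="ignore"):
            on_path = ok & (np.abs(total - D) <= tol)
        num = np.outer(sigma[:, v], sigma[v, :])
        denom = np.where(sigma > 0, sigma, 1.0)
        frac = np.where(on_path & (sigma > 0), num / denom, 0.0)
        frac[v, :] = 0.0
        frac[:, v] = 0.0
        np.fill_diagonal(frac, 0.0)
        bc[v] = 0.5 * frac.sum()
    return bc


def zscore_bc(bc: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Z-score a betweenness vector over the subject's whole-brain nodes.

    Population standard deviation (``ddof=0``) by default; ``ddof=1`` gives
    the sample-sd variant.  A zero-spread vector z-scores to all zeros.
    """
    bc = np.asarray(bc, dtype=float)
    if bc.size < 2:
        raise ValueError("z-scoring needs at least 2 nodes")
    sd = bc.std(ddof=ddof)
    if sd == 0:
        return np.zeros_like(bc)
    return (bc - bc.mean()) / sd


@dataclass
class TopologySummary:
    """Per subject-session topology: whole-brain GE plus per-network GE/z-BC.

    The whole brain gets GE only (whole-brain mean z-BC is identically zero
    by construction of the z-score, so it carries no information).
    """

    subject_id: str
    session: str
    ge_whole_brain: float
    subnetworks: dict[str, dict[str, float]] = field(default_factory=dict)
    n_frames_retained: int | None = None
    mean_motion: float | None = None

    def to_row(self) -> dict:
        row: dict = {
            "subject_id": self.subject_id,
            "session": self.session,
            "ge_whole_brain": self.ge_whole_brain,
        }
        for name, vals in self.subnetworks.items():
            row[f"ge_{name}"] = vals["ge"]
            row[f"bc_{name}"] = vals["mean_z_bc"]
        row["mean_motion"] = self.mean_motion
        row["n_frames_retained"] = self.n_frames_retained
        return row


def summarize(
    adj: AdjacencyMatrix,
    nodesets: dict[str, NodeSet] | list[NodeSet],
    *,
    subject_id: str = "",
    session: str = "",
    negative_policy: str = "zero",
    subnetwork_ge_mode: str = "induced",
    zscore_ddof: int = 0,
    n_frames_retained: int | None = None,
    mean_motion: float | None = None,
) -> TopologySummary:
    """Whole-brain GE plus GE and mean z-BC for each named subnetwork.

    BC is computed once on the whole-brain graph, z-scored over all of its
    nodes, and then averaged within each subnetwork.  (Computing and
    z-scoring BC within a subnetwork would force its mean to 0 identically.)
    Subnetwork GE uses the induced subgraph by default — paths confined to
    the subnetwork; ``subnetwork_ge_mode="restricted"`` instead averages the
    whole-brain inverse distances over subnetwork pairs.
    """
    if subnetwork_ge_mode not in ("induced", "restricted"):
        raise ValueError(f"unknown subnetwork_ge_mode '{subnetwork_ge_mode}'")
    if isinstance(nodesets, list):
        nodesets = {ns.name: ns for ns in nodesets}
    ge_wb = global_efficiency(adj, negative_policy)
    z = zscore_bc(betweenness_centrality(adj, negative_policy), ddof=zscore_ddof)
    if subnetwork_ge_mode == "restricted":
        D, _ = shortest_paths(to_lengths(adj, negative_policy))
    subnets: dict[str, dict[str, float]] = {}
    for name, ns in nodesets.items():
        if len(ns) == adj.n_nodes:
            ge = ge_wb
        elif subnetwork_ge_mode == "induced":
            ge = global_efficiency(induced_subgraph(adj, ns), negative_policy)
        else:
            idx = np.asarray(ns.indices, dtype=int)
            sub_d = D[np.ix_(idx, idx)]
            off = ~np.eye(len(ns), dtype=bool)
            with np.errstate(divide="ignore"):
                inv = np.where(sub_d[off] > 0, 1.0 / sub_d[off], 0.0)
            inv[~np.isfinite(sub_d[off])] = 0.0
            ge = float(inv.mean())
        subnets[name] = {
            "ge": ge,
            "mean_z_bc": float(z[np.asarray(ns.indices, dtype=int)].mean()),
        }
    return TopologySummary(
        subject_id=subject_id,
        session=session,
        ge_whole_brain=ge_wb,
        subnetworks=subnets,
        n_frames_retained=n_frames_retained,
        mean_motion=mean_motion,
    )
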