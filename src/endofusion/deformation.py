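"""Embedded deformation graph over the surfel map.

A sparse set of nodes, each carrying a local affine transform (a 3x3 matrix
``R`` and a translation ``t``), non-rigidly warps the dense surfel map: a
surfel blends the transforms of its k nearest nodes,

    phi(p) = sum_n  w_n(p) [ R_n (p - g_n) + g_n + t_n ]

with normals blended through the inverse-transpose of each ``R_n``.  The
raw influence weight of node ``n`` is ``(1 - ||p - g_n|| / d_max)^2`` where
``d_max`` is the distance to the (k+1)-nearest node; as these do not sum to
one in general they are explicitly renormalised, which makes the blend an
exact identity for a freshly built graph and exact for global rigid motions.

Node parameters are optimised by Gauss-Newton under three energies: a
rotation-pull term ``||R^T R - I||_F^2`` keeping the affine blocks close to
rotations, an as-rigid-as-possible regularisation along graph edges, and
soft point constraints from loop-closure correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from endofusion.surfels import SurfelMap

__all__ = [
    "DeformationGraph",
    "SurfaceConstraint",
    "build_graph",
    "influence_weights",
    "deform_points",
    "optimize_graph",
]


@dataclass
class SurfaceConstraint:
    """Soft constraint: the deformed ``source`` must land on ``target``."""

    source: np.ndarray
    target: np.ndarray
    weight: float = 1.0


@dataclass
class DeformationGraph:
    """Node set with per-node affine transforms and k-neighbour edges.

    ``positions`` are the node anchor points ``g_n``; ``edges[i]`` lists the
    k temporally-nearest other nodes of node i (directed edges).
    """

    positions: np.ndarray  # (N, 3)
    timestamps: np.ndarray  # (N,)
    edges: np.ndarray  # (N, k) int
    R: np.ndarray  # (N, 3, 3)
    t: np.ndarray  # (N, 3)
    k: int

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def copy(self) -> "DeformationGraph":
        return DeformationGraph(
            self.positions.copy(),
            self.timestamps.copy(),
            self.edges.copy(),
            self.R.copy(),
            self.t.copy(),
            self.k,
        )

    def to_dict(self) -> dict:
        """Plain-JSON form for debugging and fixtures."""
        return {
            "k": self.k,
            "positions": self.positions.tolist(),
            "timestamps": self.timestamps.tolist(),
            "edges": self.edges.tolist(),
            "R": self.R.tolist(),
            "t": self.t.tolist(),
        }

    @staticmethod
    def from_dict(d: dict) -> "DeformationGraph":
        return DeformationGraph(
            np.asarray(d["positions"], float),
            np.asarray(d["timestamps"], float),
            np.asarray(d["edges"], int),
            np.asarray(d["R"], float),
            np.asarray(d["t"], float),
            int(d["k"]),
        )


def build_graph(
    surfel_map: SurfelMap,
    *,
    node_count: int | None = None,
    node_spacing: int | None = None,
    k: int = 4,
    mask: np.ndarray | None = None,
) -> DeformationGraph:
    """Sample graph nodes by systematic subsampling of surfels in ``t_init``
    order; node neighbours are the k nearest nodes in that temporal ordering
    (ties broken by index), matching how fresh surface connects to surface
    mapped just before it.  ``mask`` restricts the candidate surfels (e.g.
    to the active set, so a loop closure warps only recent surface).
    """
    if mask is not None:
        subset = np.nonzero(mask)[0]
        n_surf = len(subset)
    else:
        subset = None
        n_surf = len(surfel_map)
    if n_surf == 0:
        raise ValueError("cannot build a graph over an empty map")
    t_init = surfel_map.t_init[subset] if subset is not None else surfel_map.t_init
    order = np.argsort(t_init, kind="stable")
    if subset is not None:
        order = subset[order]
    if node_count is None:
        if node_spacing is None:
            raise ValueError("give node_count or node_spacing")
        node_count = max(n_surf // node_spacing, 1)
    node_count = min(node_count, n_surf)
    if node_count < k + 2:
        raise ValueError(f"need at least {k + 2} nodes for k={k} (got {node_count})")
    pick = order[np.linspace(0, n_surf - 1, node_count).round().astype(int)]

    positions = surfel_map.positions[pick].copy()
    timestamps = surfel_map.t_init[pick].copy()
    n = node_count
    idx = np.arange(n)
    # k nearest in the temporal ordering == k nearest indices after sorting
    edges = np.empty((n, k), dtype=int)
    for i in range(n):
        d = np.abs(idx - i)
        d[i] = n + 1  # no self-edge
        edges[i] = np.argsort(d, kind="stable")[:k]
    return DeformationGraph(
        positions=positions,
        timestamps=timestamps,
        edges=edges,
        R=np.tile(np.eye(3), (n, 1, 1)),
        t=np.zeros((n, 3)),
        k=k,
    )


def influence_weights(
    points: np.ndarray, graph: DeformationGraph
) -> tuple[np.ndarray, np.ndarray]:
    """Influencing nodes and normalised weights for each query point.

    Returns ``(indices, weights)`` of shape (N, k): the k nearest nodes with
    raw weights ``(1 - d / d_max)^2`` (``d_max`` = distance to the
    (k+1)-nearest node), renormalised to sum to one.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    k = graph.k
    if graph.n_nodes < k + 1:
        raise ValueError("graph must have at least k+1 nodes")
    tree = cKDTree(graph.positions)
    dist, idx = tree.query(pts, k=k + 1)
    d_max = dist[:, k]
    if np.any(d_max <= 0):
        raise ValueError("degenerate geometry: point coincides with its "
                         "(k+1)-nearest node (d_max = 0)")
    raw = (1.0 - dist[:, :k] / d_max[:, None]) ** 2
    s = raw.sum(axis=1, keepdims=True)
    # all-zero raw weights cannot occur: dist[:, :k] < d_max strictly except
    # ties, where at least the nearest is < d_max or the point is degenerate
    w = np.where(s > 0, raw / np.maximum(s, 1e-300), 1.0 / k)
    return idx[:, :k], w


def deform_points(
    points: np.ndarray,
    graph: DeformationGraph,
    normals: np.ndarray | None = None,
    *,
    influence: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Apply the deformation to points (and optionally normals).

    Normals blend through ``R^-T`` and are renormalised; a singular node
    block raises.  Precomputed ``influence`` (from
    :func:`influence_weights`) may be passed to avoid re-querying.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx, w = influence if influence is not None else influence_weights(pts, graph)
    g = graph.positions[idx]  # (N, k, 3)
    R = graph.R[idx]  # (N, k, 3, 3)
    t = graph.t[idx]  # (N, k, 3)
    local = np.einsum("nkij,nkj->nki", R, pts[:, None, :] - g) + g + t
    out = np.einsum("nk,nki->ni", w, local)
    if normals is None:
        return out
    if np.any(np.abs(np.linalg.det(graph.R)) < 1e-12):
        raise np.linalg.LinAlgError("singular node transform in normal path")
    Rinv_T = np.transpose(np.linalg.inv(graph.R), (0, 2, 1))[idx]
    n_out = np.einsum("nk,nkij,nj->ni", w, Rinv_T, np.atleast_2d(normals))
    n_out /= np.maximum(np.linalg.norm(n_out, axis=1, keepdims=True), 1e-12)
    return out, n_out


# ---------------------------------------------------------------------------
# graph optimisation
# ---------------------------------------------------------------------------


def _energy_residuals(
    graph: DeformationGraph,
    constraints: list[SurfaceConstraint],
    infl: tuple[np.ndarray, np.ndarray],
    weights: tuple[float, float, float],
):
    """Stacked residual vector of the three energy terms (for reporting)."""
    w_rot, w_reg, w_con = weights
    res = []
    RtR = np.einsum("nji,njk->nik", graph.R, graph.R) - np.eye(3)
    res.append(np.sqrt(w_rot) * RtR.reshape(-1))
    gm = graph.positions[graph.edges]  # (N, k, 3)
    gn = graph.positions[:, None, :]
    pred = (
        np.einsum("nij,nkj->nki", graph.R, gm - gn)
        + gn
        + graph.t[:, None, :]
        - (gm + graph.t[graph.edges])
    )
    res.append(np.sqrt(w_reg) * pred.reshape(-1))
    src = np.array([c.source for c in constraints])
    tgt = np.array([c.target for c in constraints])
    cw = np.sqrt(np.array([c.weight for c in constraints]) * w_con)
    out = deform_points(src, graph, influence=infl)
    res.append((cw[:, None] * (out - tgt)).reshape(-1))
    return np.concatenate(res)


def optimize_graph(
    graph: DeformationGraph,
    constraints: list[SurfaceConstraint],
    *,
    w_rot: float = 1.0,
    w_reg: float = 10.0,
    w_con: float = 100.0,
    max_iterations: int = 10,
    tol: float = 1e-10,
) -> tuple[DeformationGraph, dict]:
    """Gauss-Newton optimisation of all node transforms.

    Minimises ``w_rot * E_rot + w_reg * E_reg + w_con * E_con`` over the
    stacked 12-parameter-per-node variables.  Only the rotation-pull term is
    nonlinear (quadratic in R), so convergence is fast.  Returns the updated
    graph and an info dict (energies, iterations, converged flag); the input
    graph is not modified.
    """
    if not constraints:
        raise ValueError("need at least one surface constraint")
    g = graph.copy()
    N, k = g.n_nodes, g.k
    n_par = 12 * N

    src = np.array([c.source for c in constraints])
    tgt = np.array([c.target for c in constraints])
    cw = np.array([c.weight for c in constraints], dtype=float)
    infl = influence_weights(src, g)
    i_idx, i_w = infl
    C = len(constraints)

    def pack_index(node, block):  # block 0..8 -> R row-major, 9..11 -> t
        return node * 12 + block

    energy_hist = []
    converged = False
    lam = 0.0
    E_prev = None
    for it in range(max_iterations):
        # --- residuals and sparse-ish Jacobian assembled densely (N small)
        r_all = []
        J = []

        # rotation-pull: r = sqrt(w_rot) * (R^T R - I), 9 residuals/node
        RtR = np.einsum("nji,njk->nik", g.R, g.R) - np.eye(3)
        r_rot = np.sqrt(w_rot) * RtR.reshape(N, 9)
        J_rot = np.zeros((N, 9, n_par))
        for a in range(3):  # residual row index of RtR
            for b in range(3):
                ridx = 3 * a + b
                for c in range(3):
                    # d(R^T R)_{ab} / dR_{ca} = R_{cb}; / dR_{cb} = R_{ca}
                    col_ca = pack_index(np.arange(N), 3 * c + a)
                    col_cb = pack_index(np.arange(N), 3 * c + b)
                    J_rot[np.arange(N), ridx, col_ca] += np.sqrt(w_rot) * g.R[:, c, b]
                    J_rot[np.arange(N), ridx, col_cb] += np.sqrt(w_rot) * g.R[:, c, a]
        r_all.append(r_rot.reshape(-1))
        J.append(J_rot.reshape(N * 9, n_par))

        # regularisation: r = sqrt(w_reg)*(R_n (g_m - g_n) + g_n + t_n - g_m - t_m)
        sw = np.sqrt(w_reg)
        gm = g.positions[g.edges]
        gn = g.positions[:, None, :]
        diff = gm - gn  # (N, k, 3)
        r_reg = sw * (
            np.einsum("nij,nkj->nki", g.R, diff) + gn + g.t[:, None, :] - gm - g.t[g.edges]
        )
        J_reg = np.zeros((N, k, 3, n_par))
        nn = np.arange(N)[:, None].repeat(k, axis=1)
        mm = g.edges
        for i in range(3):
            for j in range(3):
                J_reg[nn, np.arange(k)[None, :], i, pack_index(nn, 3 * i + j)] = (
                    sw * diff[..., j]
                )
            J_reg[nn, np.arange(k)[None, :], i, pack_index(nn, 9 + i)] = sw
            J_reg[nn, np.arange(k)[None, :], i, pack_index(mm, 9 + i)] = -sw
        r_all.append(r_reg.reshape(-1))
        J.append(J_reg.reshape(N * k * 3, n_par))

        # constraints: r = sqrt(w_con * cw) * (phi(src) - tgt)
        scw = np.sqrt(w_con * cw)
        gsrc = g.positions[i_idx]  # (C, k, 3)
        local = (
            np.einsum("ckij,ckj->cki", g.R[i_idx], src[:, None, :] - gsrc)
            + gsrc
            + g.t[i_idx]
        )
        phi = np.einsum("ck,cki->ci", i_w, local)
        r_con = scw[:, None] * (phi - tgt)
        J_con = np.zeros((C, 3, n_par))
        d = src[:, None, :] - gsrc  # (C, k, 3)
        cc = np.arange(C)[:, None].repeat(g.k, axis=1)
        kk = np.arange(g.k)[None, :].repeat(C, axis=0)
        for i in range(3):
            for j in range(3):
                np.add.at(
                    J_con,
                    (cc, i, pack_index(i_idx, 3 * i + j)),
                    (scw[:, None] * i_w) * d[..., j],
                )
            np.add.at(
                J_con, (cc, i, pack_index(i_idx, 9 + i)), scw[:, None] * i_w
            )
        r_all.append(r_con.reshape(-1))
        J.append(J_con.reshape(C * 3, n_par))

        r = np.concatenate(r_all)
        Jm = np.vstack(J)
        E = float(r @ r)
        energy_hist.append(E)
        if E_prev is not None and abs(E_prev - E) < tol * max(E_prev, 1.0):
            converged = True
            break
        E_prev = E

        H = Jm.T @ Jm
        grad = Jm.T @ r
        # damped GN with energy guard
        accepted = False
        for _ in range(6):
            try:
                delta = np.linalg.solve(H + (lam + 1e-12) * np.eye(n_par), -grad)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-8)
                continue
            g_try = g.copy()
            g_try.R = (g.R.reshape(N, 9) + delta.reshape(N, 12)[:, :9]).reshape(
                N, 3, 3
            )
            g_try.t = g.t + delta.reshape(N, 12)[:, 9:]
            r_try = _energy_residuals(g_try, constraints, infl, (w_rot, w_reg, w_con))
            if r_try @ r_try <= E:
                g = g_try
                lam = lam / 4.0 if lam > 1e-12 else 0.0
                accepted = True
                break
            lam = max(lam * 10.0, 1e-6)
        if not accepted:
            break

    info = {
        "energy": energy_hist[-1] if energy_hist else np.nan,
        "energy_history": energy_hist,
        "iterations": len(energy_hist),
        "converged": converged,
        "constraint_rms": float(
            np.sqrt(np.mean(np.sum((deform_points(src, g, influence=infl) - tgt) ** 2, axis=1)))
        ),
    }
    return g, info
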