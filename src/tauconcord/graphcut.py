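"""Binary MRF energy minimization by s-t minimum cut.

Solves the standard two-label labeling problem

    E(L) = sum_p U_p(L_p) + sum_{(p,q) in N} w_pq * [L_p != L_q]

exactly, via a single max-flow computation on the associated s-t graph
(source = foreground terminal). Capacities are scaled to 64-bit integers;
the returned energy is evaluated with the original float terms.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

__all__ = ["grid_edges", "solve_binary_mrf", "labeling_energy"]

_CAPACITY_SCALE = 10**6


def grid_edges(h: int, w: int, connectivity: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (p, q) of neighboring pixels on an h x w grid."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    idx = np.arange(h * w).reshape(h, w)
    pairs = [
        (idx[:, :-1].ravel(), idx[:, 1:].ravel()),
        (idx[:-1, :].ravel(), idx[1:, :].ravel()),
    ]
    if connectivity == 8:
        pairs.append((idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()))
        pairs.append((idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()))
    p = np.concatenate([a for a, _ in pairs])
    q = np.concatenate([b for _, b in pairs])
    return p, q


def labeling_energy(
    labels: np.ndarray,
    unary_bg: np.ndarray,
    unary_fg: np.ndarray,
    edges: tuple[np.ndarray, np.ndarray],
    weights: np.ndarray,
) -> float:
    """Energy of a flat binary labeling (True = foreground)."""
    lab = labels.ravel().astype(bool)
    e = float(np.where(lab, unary_fg.ravel(), unary_bg.ravel()).sum())
    p, q = edges
    e += float(weights[lab[p] != lab[q]].sum())
    return e


def solve_binary_mrf(
    unary_bg: np.ndarray,
    unary_fg: np.ndarray,
    edges: tuple[np.ndarray, np.ndarray],
    weights: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Globally minimize the binary Potts-type energy.

    Parameters are flat arrays: per-pixel costs of the background and
    foreground labels, neighbor index pairs, and non-negative pairwise
    weights (one per pair, counted once per unordered pair).

    Returns (labels, energy) with labels True = foreground; the energy is
    the float energy of the returned labeling.
    """
    unary_bg = np.asarray(unary_bg, dtype=float).ravel()
    unary_fg = np.asarray(unary_fg, dtype=float).ravel()
    n = unary_bg.size
    p, q = edges
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("pairwise weights must be non-negative")

    src, sink = n, n + 1
    # capacities must be non-negative; shifting both labels of a pixel by the
    # same constant changes every labeling's energy equally, so subtract the
    # per-pixel minimum before scaling
    shift = np.minimum(unary_bg, unary_fg)
    res_bg = unary_bg - shift
    res_fg = unary_fg - shift
    # a unary cost exceeding the sum of a pixel's incident pairwise weights
    # already forces that pixel's label in every optimum, so capping it there
    # (plus a strict margin) leaves the set of optimal labelings unchanged
    # while keeping capacities small enough for exact integer scaling
    incident = np.zeros(n)
    np.add.at(incident, p, w)
    np.add.at(incident, q, w)
    cap_limit = incident + 1.0
    res_bg = np.minimum(res_bg, cap_limit)
    res_fg = np.minimum(res_fg, cap_limit)
    # the max-flow backend computes in 32-bit integers; keep the total
    # capacity below that range
    total = float(res_bg.sum() + res_fg.sum() + 2.0 * w.sum())
    scale = min(_CAPACITY_SCALE, (2.0**31 - 1.0) / (total + 1.0))
    cap_bg = np.rint(res_bg * scale).astype(np.int64)
    cap_fg = np.rint(res_fg * scale).astype(np.int64)
    cap_w = np.rint(w * scale).astype(np.int64)

    # source->p cut when p labeled background contributes U_p(bg);
    # p->sink cut when p labeled foreground contributes U_p(fg)
    rows = np.concatenate([np.full(n, src), np.arange(n), p, q])
    cols = np.concatenate([np.arange(n), np.full(n, sink), q, p])
    data = np.concatenate([cap_bg, cap_fg, cap_w, cap_w])
    keep = data > 0
    graph = csr_matrix(
        (data[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2), dtype=np.int64
    )
    graph.sum_duplicates()

    result = maximum_flow(graph, src, sink)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    order, _ = breadth_first_order(residual, src, directed=True)
    reachable = np.zeros(n + 2, dtype=bool)
    reachable[order] = True
    labels = reachable[:n]

    energy = labeling_energy(labels, unary_bg, unary_fg, (p, q), w)
    return labels, energy
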