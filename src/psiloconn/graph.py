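"""Weighted whole-brain graph analysis.

Builds nonnegative weighted graphs from regional correlation matrices
(weights normalized by the maximum), thresholds them proportionally
(retaining the strongest 10-50% of edges in 1% steps), and quantifies
topology with small-world propensity (SWP) and its components — the
normalized deviations of the clustering coefficient (dC) and characteristic
path length (dL) from degree-matched lattice and random references — plus
nodal strength, weighted (Onnela) clustering, and the participation index
of a fixed modular partition.  Metrics are averaged across thresholds so
conclusions do not hinge on a single density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path


@dataclass
class GlobalGraphMetrics:
    clustering: float            # mean weighted clustering C
    path_length: float           # characteristic path length L (1/weight distances)
    delta_c: float               # (C_latt - C_obs) / (C_latt - C_rand), clipped to [0,1]
    delta_l: float               # (L_obs - L_rand) / (L_latt - L_rand), clipped to [0,1]
    swp: float                   # 1 - sqrt((dC^2 + dL^2)/2)
    connected: bool = True


@dataclass
class LocalGraphMetrics:
    strength: np.ndarray
    clustering: np.ndarray
    participation: np.ndarray
    labels: tuple[str, ...] = field(default=None)


def weighted_graph(values: np.ndarray, zero_negative: bool = True) -> np.ndarray:
    """Nonnegative symmetric weight matrix, zero diagonal, max weight 1.

    Negative correlations are set to zero (nonnegativity is required by the
    weighted clustering and SWP definitions).
    """
    W = np.array(values, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    W = np.nan_to_num(W, nan=0.0)
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    if zero_negative:
        W[W < 0] = 0.0
    mx = W.max()
    if mx <= 0:
        raise ValueError("graph has no positive weights")
    return W / mx


def is_connected(W: np.ndarray) -> bool:
    n_comp, _ = connected_components((W > 0).astype(np.int8), directed=False)
    return n_comp == 1


def proportional_threshold(W: np.ndarray, p: float) -> np.ndarray:
    """Keep the floor(p * E) largest-weight edges (E = positive-weight edges).

    Ties are broken deterministically by (weight descending, node pair
    ascending), so equal-weight graphs threshold reproducibly and edge sets
    are nested across increasing p.
    """
    if not 0 < p <= 1:
        raise ValueError("proportion must lie in (0, 1]")
    R = W.shape[0]
    iu = np.triu_indices(R, k=1)
    w = W[iu]
    pos = np.flatnonzero(w > 0)
    n_keep = int(np.floor(p * pos.size))
    order = np.lexsort((iu[1][pos], iu[0][pos], -w[pos]))
    keep = pos[order[:n_keep]]
    out = np.zeros_like(W)
    out[iu[0][keep], iu[1][keep]] = w[keep]
    return out + out.T


def onnela_clustering(W: np.ndarray) -> np.ndarray:
    """Per-node weighted clustering coefficient (Onnela geometric-mean form)."""
    mx = W.max()
    Wh = np.cbrt(W / mx) if mx > 0 else W.copy()
    num = np.diagonal(Wh @ Wh @ Wh)
    deg = (W > 0).sum(axis=1)
    denom = deg * (deg - 1)
    c = np.zeros(W.shape[0])
    ok = denom > 0
    c[ok] = num[ok] / denom[ok]
    return c


def char_path_length(W: np.ndarray) -> float:
    """Characteristic path length with distance 1/weight (inf if disconnected)."""
    with np.errstate(divide="ignore"):
        dist = np.where(W > 0, 1.0 / W, 0.0)
    D = shortest_path(dist, method="D", directed=False, unweighted=False)
    iu = np.triu_indices(W.shape[0], k=1)
    vals = D[iu]
    if np.isinf(vals).any():
        return float("inf")
    return float(vals.mean())


def lattice_reference(W: np.ndarray) -> np.ndarray:
    """Ring-lattice null: the observed weights reordered onto a ring lattice.

    Node pairs are ranked by circular distance (ties by index); the m edges
    receive the observed weights sorted descending, so the strongest weights
    sit on the shortest-range connections.
    """
    R = W.shape[0]
    iu = np.triu_indices(R, k=1)
    w = np.sort(W[iu])[::-1]
    m = int((w > 0).sum())
    ring = np.minimum(iu[1] - iu[0], R - (iu[1] - iu[0]))
    order = np.lexsort((iu[1], iu[0], ring))
    out = np.zeros_like(W)
    sel = order[:m]
    out[iu[0][sel], iu[1][sel]] = w[:m]
    return out + out.T


def random_references(W: np.ndarray, n_null: int = 20, seed: int = 0,
                      max_tries: int = 10) -> list[np.ndarray]:
    """Degree-sequence- and connectedness-preserving rewired nulls.

    Topology is randomized with connectivity-preserving double edge swaps;
    the observed weight multiset is then reshuffled onto the rewired edges.
    """
    if not is_connected(W):
        raise ValueError("input graph must be connected for null construction")
    R = W.shape[0]
    iu = np.triu_indices(R, k=1)
    weights = W[iu][W[iu] > 0]
    G0 = nx.from_numpy_array((W > 0).astype(float))
    m = G0.number_of_edges()
    rng = np.random.default_rng(seed)
    nulls = []
    for _ in range(n_null):
        ok = False
        for _try in range(max_tries):
            G = G0.copy()
            try:
                nx.connected_double_edge_swap(
                    G, nswap=max(4 * m, 10),
                    seed=int(rng.integers(2**31)))
            except nx.NetworkXError:
                continue
            if nx.is_connected(G):
                ok = True
                break
        if not ok:
            raise RuntimeError("rewiring failed to preserve connectedness")
        out = np.zeros_like(W)
        perm = rng.permutation(weights)
        for k, (i, j) in enumerate(G.edges()):
            out[i, j] = out[j, i] = perm[k]
        nulls.append(out)
    return nulls


def small_world_propensity(W: np.ndarray, n_null: int = 20, seed: int = 0
                           ) -> GlobalGraphMetrics:
    """SWP of a thresholded weighted graph against lattice/random references.

    dC = (C_latt - C_obs) / (C_latt - C_rand) and
    dL = (L_obs - L_rand) / (L_latt - L_rand), both clipped to [0, 1];
    SWP = 1 - sqrt((dC^2 + dL^2) / 2).  Degenerate normalizations
    (references coincide) yield NaN.
    """
    connected = is_connected(W)
    c_obs = float(onnela_clustering(W).mean())
    l_obs = char_path_length(W)
    if not connected:
        return GlobalGraphMetrics(c_obs, l_obs, np.nan, np.nan, np.nan, False)
    nulls = random_references(W, n_null=n_null, seed=seed)
    latt = lattice_reference(W)
    c_rand = float(np.mean([onnela_clustering(n_).mean() for n_ in nulls]))
    l_rand = float(np.mean([char_path_length(n_) for n_ in nulls]))
    c_latt = float(onnela_clustering(latt).mean())
    l_latt = char_path_length(latt)
    if not np.isfinite(l_latt) or abs(c_latt - c_rand) < 1e-12 \
            or abs(l_latt - l_rand) < 1e-12:
        return GlobalGraphMetrics(c_obs, l_obs, np.nan, np.nan, np.nan, connected)
    dc = np.clip((c_latt - c_obs) / (c_latt - c_rand), 0.0, 1.0)
    dl = np.clip((l_obs - l_rand) / (l_latt - l_rand), 0.0, 1.0)
    swp = 1.0 - np.sqrt((dc**2 + dl**2) / 2.0)
    return GlobalGraphMetrics(c_obs, l_obs, float(dc), float(dl), float(swp),
                              connected)


def louvain_partition(W: np.ndarray, seed: int = 0, n_restarts: int = 50
                      ) -> np.ndarray:
    """Modularity-maximizing module assignment (Louvain, best of restarts)."""
    G = nx.from_numpy_array(W)
    best, best_q = None, -np.inf
    for k in range(n_restarts):
        comms = nx.community.louvain_communities(G, weight="weight",
                                                 seed=seed + k)
        q = nx.community.modularity(G, comms, weight="weight")
        if q > best_q:
            best, best_q = comms, q
    part = np.empty(W.shape[0], dtype=int)
    for mod_id, nodes in enumerate(best):
        for v in nodes:
            part[v] = mod_id
    return part


def local_metrics(W: np.ndarray, partition: np.ndarray,
                  labels=None, participation: str = "coefficient"
                  ) -> LocalGraphMetrics:
    """Nodal strength, Onnela clustering, and participation index.

    ``participation="coefficient"`` uses the standard
    P_i = 1 - sum_s (kappa_is / k_i)^2; ``"ratio"`` uses the literal
    intermodule-strength / total-strength ratio.  Isolated nodes report
    strength 0, clustering 0, participation NaN.
    """
    partition = np.asarray(partition)
    if partition.shape[0] != W.shape[0]:
        raise ValueError("partition must cover all nodes")
    if participation not in ("coefficient", "ratio"):
        raise ValueError("participation must be 'coefficient' or 'ratio'")
    strength = W.sum(axis=1)
    clust = onnela_clustering(W)
    modules = np.unique(partition)
    kappa = np.stack([W[:, partition == s].sum(axis=1) for s in modules], axis=1)
    part = np.full(W.shape[0], np.nan)
    ok = strength > 0
    if participation == "coefficient":
        part[ok] = 1.0 - ((kappa[ok] / strength[ok, None])**2).sum(axis=1)
    else:
        own = kappa[np.arange(W.shape[0]), np.searchsorted(modules, partition)]
        part[ok] = (strength[ok] - own[ok]) / strength[ok]
    part[ok] = np.clip(part[ok], 0.0, 1.0)   # guard float round-off at 0 and 1
    return LocalGraphMetrics(strength, clust, part,
                             tuple(labels) if labels is not None else None)


DEFAULT_THRESHOLDS = np.round(np.arange(0.10, 0.501, 0.01), 2)


def threshold_average(values) -> float:
    """Mean across threshold evaluations, excluding flagged (NaN) thresholds."""
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).all():
        return float("nan")
    return float(np.nanmean(arr))


def analyze_graph(values: np.ndarray, partition: np.ndarray | None = None,
                  thresholds=DEFAULT_THRESHOLDS, n_null: int = 20,
                  seed: int = 0, labels=None):
    """Threshold sweep: per-threshold global and local metrics plus averages.

    Returns ``(global_df, local_mean)`` where ``global_df`` holds one row per
    threshold (NaN rows for disconnected/degenerate thresholds are excluded
    from the averages by ``threshold_average``) and ``local_mean`` the
    threshold-averaged LocalGraphMetrics.
    """
    import pandas as pd
    W = weighted_graph(values)
    if partition is None:
        partition = louvain_partition(W, seed=seed)
    rows, strengths, clusts, parts = [], [], [], []
    for k, p in enumerate(thresholds):
        Wt = proportional_threshold(W, float(p))
        if not is_connected(Wt):
            rows.append({"threshold": p, "clustering": np.nan,
                         "path_length": np.nan, "delta_c": np.nan,
                         "delta_l": np.nan, "swp": np.nan, "connected": False})
            strengths.append(np.full(W.shape[0], np.nan))
            clusts.append(np.full(W.shape[0], np.nan))
            parts.append(np.full(W.shape[0], np.nan))
            continue
        g = small_world_propensity(Wt, n_null=n_null, seed=seed + 1000 * k)
        loc = local_metrics(Wt, partition, labels)
        rows.append({"threshold": p, "clustering": g.clustering,
                     "path_length": g.path_length, "delta_c": g.delta_c,
                     "delta_l": g.delta_l, "swp": g.swp, "connected": g.connected})
        strengths.append(loc.strength)
        clusts.append(loc.clustering)
        parts.append(loc.participation)
    global_df = pd.DataFrame(rows)
    local_mean = LocalGraphMetrics(
        np.nanmean(np.stack(strengths), axis=0),
        np.nanmean(np.stack(clusts), axis=0),
        np.nanmean(np.stack(parts), axis=0),
        tuple(labels) if labels is not None else None)
    return global_df, local_mean
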