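"""Network-based statistic (NBS) with exchange blocks for a crossover design.

Edge-wise F statistics from a general linear model on per-session
difference matrices (post-minus-pre connectivity change), a primary
threshold that discards sub-threshold edges, connected-component extraction
on the surviving edges, and family-wise-error-corrected inference on
component extent against a permutation null of the maximum extent.
Permutations respect the paired crossover structure: for the treatment
contrast, condition labels are swapped only within each subject's pair of
sessions (exchange blocks of size two); for the subgroup-by-treatment
interaction, group labels are permuted between subjects while the
within-subject pairing stays intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import DiffMatrix


@dataclass
class EdgeGlmDesign:
    """Per-subject psilocybin and saline difference matrices plus group labels.

    ``psi`` and ``sal`` are n_subjects x R x R stacks aligned with
    ``subjects`` and ``groups``; ``contrast`` selects the treatment main
    effect or the subgroup-by-treatment interaction.
    """

    subjects: tuple[str, ...]
    groups: tuple[str, ...]
    psi: np.ndarray
    sal: np.ndarray
    labels: tuple[str, ...]
    contrast: str = "treatment"

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        self.sal = np.asarray(self.sal, dtype=float)
        n = len(self.subjects)
        if self.psi.shape != self.sal.shape or self.psi.shape[0] != n:
            raise ValueError("psi/sal stacks must be n_subjects x R x R and aligned")
        if len(self.groups) != n:
            raise ValueError("one group label per subject required")
        if self.contrast not in ("treatment", "interaction"):
            raise ValueError("contrast must be 'treatment' or 'interaction'")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return self.psi.shape[1]

    @classmethod
    def from_diff_matrices(cls, per_subject: dict[str, dict[str, DiffMatrix]],
                           groups: dict[str, str], contrast: str = "treatment"):
        """Build a design from {subject: {"psilocybin": DiffMatrix, "saline": ...}}."""
        subjects = tuple(sorted(per_subject))
        labels = per_subject[subjects[0]]["psilocybin"].labels
        psi = np.stack([per_subject[s]["psilocybin"].values for s in subjects])
        sal = np.stack([per_subject[s]["saline"].values for s in subjects])
        return cls(subjects, tuple(groups[s] for s in subjects), psi, sal,
                   labels, contrast)


@dataclass
class NbsParams:
    f_pt: float = 7.31          # primary threshold, F(1, 2n-2) upper 1% point at n=21
    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.f_pt <= 0:
            raise ValueError("primary threshold must be positive")
        if self.n_perm < 1:
            raise ValueError("need at least one permutation")


@dataclass
class NbsComponent:
    edges: list[tuple[int, int]]       # region index pairs (i < j)
    extent: int
    p_fwe: float = float("nan")

    def edge_labels(self, labels):
        return [(labels[i], labels[j]) for i, j in self.edges]


@dataclass
class NbsResult:
    components: list[NbsComponent]
    null_max_extent: np.ndarray
    f_values: np.ndarray               # R x R symmetric F map
    f_pt: float
    df: tuple[int, int]
    mean_effect: np.ndarray = field(default=None)  # R x R signed mean effect


def _edge_index(R: int):
    iu = np.triu_indices(R, k=1)
    return iu


def _treatment_f(D: np.ndarray, sst: np.ndarray, signs: np.ndarray,
                 n: int) -> np.ndarray:
    """One-way condition F on 2n observations from within-block sign flips.

    ``D`` is n x E per-subject (psi - sal) edge differences, ``sst`` the
    permutation-invariant total sum of squares of the 2n observations, and
    ``signs`` a K x n matrix of within-subject swaps.  df = (1, 2n - 2).
    """
    m = signs @ D / n                        # K x E condition mean difference
    ssb = n * m**2 / 2.0
    denom = sst[None, :] - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb * (2 * n - 2) / denom
    f[denom <= 1e-12 * np.maximum(sst[None, :], 1e-300)] = np.inf
    return f


def _interaction_f(D: np.ndarray, sst_d: np.ndarray, perm_groups: np.ndarray,
                   n1: int, n0: int) -> np.ndarray:
    """Two-group one-way F on per-subject differences; df = (1, n - 2)."""
    n = n1 + n0
    tot = D.sum(axis=0)                      # E
    t1 = perm_groups @ D                     # K x E  (group-1 sums)
    g1 = t1 / n1
    g0 = (tot[None, :] - t1) / n0
    gm = tot[None, :] / n
    ssb = n1 * (g1 - gm)**2 + n0 * (g0 - gm)**2
    denom = sst_d[None, :] - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb * (n - 2) / denom
    f[denom <= 1e-12 * np.maximum(sst_d[None, :], 1e-300)] = np.inf
    return f


def _edge_stack(design: EdgeGlmDesign):
    R = design.n_regions
    iu = _edge_index(R)
    psi = design.psi[:, iu[0], iu[1]]
    sal = design.sal[:, iu[0], iu[1]]
    return psi, sal, iu


def edge_f_statistics(design: EdgeGlmDesign) -> np.ndarray:
    """Observed per-edge F map (R x R symmetric, NaN diagonal).

    Treatment contrast: one-way F between the two condition groups of the
    2n difference-matrix observations, df (1, 2n-2).  Interaction contrast:
    one-way F between ADE and control on per-subject (psi - sal) responses,
    df (1, n-2).  Edges with zero residual variance report +inf.
    """
    psi, sal, iu = _edge_stack(design)
    n = design.n_subjects
    if n < 2:
        raise ValueError("need at least two subjects")
    R = design.n_regions
    if design.contrast == "treatment":
        obs = np.concatenate([psi, sal], axis=0)
        sst = ((obs - obs.mean(axis=0))**2).sum(axis=0)
        f = _treatment_f(psi - sal, sst, np.ones((1, n)), n)[0]
    else:
        D = psi - sal
        groups = np.asarray([g == "ADE" for g in design.groups], dtype=float)
        n1 = int(groups.sum())
        n0 = n - n1
        if n1 < 2 or n0 < 2:
            raise ValueError("interaction contrast needs >= 2 subjects per group")
        sst_d = ((D - D.mean(axis=0))**2).sum(axis=0)
        f = _interaction_f(D, sst_d, groups[None, :], n1, n0)[0]
    out = np.full((R, R), np.nan)
    out[iu] = f
    out[(iu[1], iu[0])] = f
    return out


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _components_from_edges(rows, cols, R):
    """Group suprathreshold edges into connected components; returns lists of edge ids."""
    uf = _UnionFind(R)
    for i, j in zip(rows, cols):
        uf.union(int(i), int(j))
    comp_edges: dict[int, list[int]] = {}
    for e, i in enumerate(rows):
        root = uf.find(int(i))
        comp_edges.setdefault(root, []).append(e)
    return list(comp_edges.values())


def extract_components(f_map: np.ndarray, threshold: float) -> list[NbsComponent]:
    """Connected components of the graph of edges with F above the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    R = f_map.shape[0]
    iu = _edge_index(R)
    f = f_map[iu]
    supra = np.flatnonzero(np.nan_to_num(f, nan=-np.inf) > threshold)
    rows, cols = iu[0][supra], iu[1][supra]
    comps = []
    for edge_ids in _components_from_edges(rows, cols, R):
        edges = [(int(rows[e]), int(cols[e])) for e in edge_ids]
        comps.append(NbsComponent(sorted(edges), len(edges)))
    return sorted(comps, key=lambda c: -c.extent)


def _max_extent(f_row: np.ndarray, threshold: float, iu, R: int) -> int:
    supra = np.flatnonzero(np.nan_to_num(f_row, nan=-np.inf) > threshold)
    if supra.size == 0:
        return 0
    rows, cols = iu[0][supra], iu[1][supra]
    return max(len(e) for e in _components_from_edges(rows, cols, R))


def nbs_permutation_test(design: EdgeGlmDesign, params: NbsParams = NbsParams()
                         ) -> NbsResult:
    """Full NBS: primary thresholding, components, max-extent permutation FWE.

    The attained p-values are Phipson-Smyth smoothed,
    p = (1 + #{null max extent >= observed extent}) / (n_perm + 1), so the
    smallest attainable p is 1/(n_perm + 1).
    """
    if params.n_perm + 1 < 1 / params.alpha:
        warnings.warn("n_perm too small to resolve the requested alpha", stacklevel=2)
    psi, sal, iu = _edge_stack(design)
    n = design.n_subjects
    R = design.n_regions
    rng = np.random.default_rng(params.seed)
    K = params.n_perm

    if design.contrast == "treatment":
        D = psi - sal
        obs = np.concatenate([psi, sal], axis=0)
        sst = ((obs - obs.mean(axis=0))**2).sum(axis=0)
        f_obs = _treatment_f(D, sst, np.ones((1, n)), n)[0]
        signs = rng.choice([-1.0, 1.0], size=(K, n))
        f_perm = _treatment_f(D, sst, signs, n)
        df = (1, 2 * n - 2)
    else:
        D = psi - sal
        groups = np.asarray([g == "ADE" for g in design.groups], dtype=float)
        n1, n0 = int(groups.sum()), n - int(groups.sum())
        sst_d = ((D - D.mean(axis=0))**2).sum(axis=0)
        f_obs = _interaction_f(D, sst_d, groups[None, :], n1, n0)[0]
        perms = np.stack([rng.permutation(groups) for _ in range(K)])
        f_perm = _interaction_f(D, sst_d, perms, n1, n0)
        df = (1, n - 2)

    f_map = np.full((R, R), np.nan)
    f_map[iu] = f_obs
    f_map[(iu[1], iu[0])] = f_obs
    components = extract_components(f_map, params.f_pt)

    null_max = np.fromiter(
        (_max_extent(f_perm[k], params.f_pt, iu, R) for k in range(K)),
        dtype=int, count=K)
    for comp in components:
        comp.p_fwe = (1 + int((null_max >= comp.extent).sum())) / (K + 1)

    mean_eff = np.full((R, R), np.nan)
    d_mean = D.mean(axis=0)
    mean_eff[iu] = d_mean
    mean_eff[(iu[1], iu[0])] = d_mean
    return NbsResult(components, null_max, f_map, params.f_pt, df, mean_eff)
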