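"""Inference layer: mixed ANOVA, permutation tests, FDR, correlations, clusters.

Per-session responses are post-minus-pre (TP2 - TP1) metric changes; the
two sessions (psilocybin, saline) of every subject enter a mixed
between(group) x within(treatment) ANOVA.  For the 2 x 2 design the
treatment main effect and the subgroup-by-treatment interaction both reduce
to tests on the per-subject session difference d_i = delta_psi - delta_sal:
the treatment effect tests the unweighted grand mean of d (Type-III style),
the interaction the group difference of d, each with F(1, n - 2).
Permutation analogues swap sessions within subjects (treatment) or permute
group labels between subjects (interaction).  Voxel-wise maps are
cluster-corrected by permutation of the maximum cluster extent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class RmAnovaResult:
    effect: str                  # "treatment" or "interaction"
    f: float
    df: tuple[int, int]
    p_param: float
    p_perm: float | None = None
    p_fdr: float | None = None
    n_perm: int | None = None


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p: float
    t: float


@dataclass
class Cluster:
    label: int
    extent: int
    p_fwe: float
    indices: tuple = field(default=None, repr=False)


@dataclass
class ClusterInference:
    clusters: list[Cluster]
    null_max_extent: np.ndarray
    cdt: float
    stat_map: np.ndarray
    label_map: np.ndarray


def delta_response(metric_tp2, metric_tp1):
    """Post-minus-pre response; inputs must be aligned (same index/order)."""
    import pandas as pd
    if isinstance(metric_tp2, pd.Series) and isinstance(metric_tp1, pd.Series):
        if not metric_tp2.index.equals(metric_tp1.index):
            raise ValueError("mismatched indices between TP2 and TP1 values")
        return metric_tp2 - metric_tp1
    a2, a1 = np.asarray(metric_tp2, dtype=float), np.asarray(metric_tp1, dtype=float)
    if a2.shape != a1.shape:
        raise ValueError("mismatched shapes between TP2 and TP1 values")
    return a2 - a1


def _effect_f_from_d(d: np.ndarray, groups: np.ndarray):
    """Treatment and interaction F(1, n-2) from per-subject session differences.

    ``groups`` is boolean (True = ADE).  Returns (f_treat, f_inter) using the
    unweighted-means (Type III) parameterization d = b0 + b1 * g, g in {-1, +1}.
    """
    n = d.size
    n1 = int(groups.sum())
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 subjects per group")
    m1 = d[groups].mean()
    m0 = d[~groups].mean()
    ss_res = ((d[groups] - m1)**2).sum() + ((d[~groups] - m0)**2).sum()
    mse = ss_res / (n - 2)
    c = 0.25 * (1.0 / n1 + 1.0 / n0)
    b0 = 0.5 * (m1 + m0)          # unweighted grand mean of d
    b1 = 0.5 * (m1 - m0)          # half the group difference
    with np.errstate(divide="ignore", invalid="ignore"):
        f_treat = b0**2 / (c * mse)
        f_inter = b1**2 / (c * mse)
    return float(f_treat), float(f_inter)


def rm_anova(delta_psi: np.ndarray, delta_sal: np.ndarray, groups
             ) -> dict[str, RmAnovaResult]:
    """Mixed between-within ANOVA of post-pre responses in a 2 x 2 design.

    ``delta_psi``/``delta_sal`` are per-subject TP2-TP1 responses under each
    treatment; ``groups`` the per-subject group labels ("ADE"/"control").
    Returns parametric results for the treatment main effect and the
    subgroup-by-treatment interaction, both F(1, n - 2).
    """
    delta_psi = np.asarray(delta_psi, dtype=float)
    delta_sal = np.asarray(delta_sal, dtype=float)
    if delta_psi.shape != delta_sal.shape:
        raise ValueError("each subject needs both sessions")
    g = np.asarray([str(x) == "ADE" for x in groups])
    n = delta_psi.size
    d = delta_psi - delta_sal
    f_treat, f_inter = _effect_f_from_d(d, g)
    df = (1, n - 2)
    return {
        "treatment": RmAnovaResult("treatment", f_treat, df,
                                   float(sps.f.sf(f_treat, *df))),
        "interaction": RmAnovaResult("interaction", f_inter, df,
                                     float(sps.f.sf(f_inter, *df))),
    }


def permutation_anova(delta_psi, delta_sal, groups, n_perm: int = 10000,
                      seed: int = 0) -> dict[str, RmAnovaResult]:
    """Permutation p-values for the mixed ANOVA effects.

    Treatment: within-subject session swaps (sign flips of d); interaction:
    group relabeling between subjects.  p-values are Phipson-Smyth smoothed.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values",
                      stacklevel=2)
    delta_psi = np.asarray(delta_psi, dtype=float)
    delta_sal = np.asarray(delta_sal, dtype=float)
    g = np.asarray([str(x) == "ADE" for x in groups])
    d = delta_psi - delta_sal
    n = d.size
    res = rm_anova(delta_psi, delta_sal, groups)
    rng = np.random.default_rng(seed)

    def _batch_f(x: np.ndarray, gb: np.ndarray):
        """Vectorized treatment/interaction F over rows of permuted d."""
        n1 = int(gb.sum())
        n0 = gb.size - n1
        m1 = x[:, gb].mean(axis=1)
        m0 = x[:, ~gb].mean(axis=1)
        ss_res = (((x[:, gb] - m1[:, None])**2).sum(axis=1)
                  + ((x[:, ~gb] - m0[:, None])**2).sum(axis=1))
        mse = ss_res / (gb.size - 2)
        c = 0.25 * (1.0 / n1 + 1.0 / n0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return ((0.5 * (m1 + m0))**2 / (c * mse),
                    (0.5 * (m1 - m0))**2 / (c * mse))

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    f_treat_null, _ = _batch_f(signs * d[None, :], g)
    # interaction: permuting group labels == permuting d against fixed labels
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    _, f_inter_null = _batch_f(d[perm_idx], g)
    res["treatment"].p_perm = (1 + int((f_treat_null >=
                               res["treatment"].f).sum())) / (n_perm + 1)
    res["interaction"].p_perm = (1 + int((f_inter_null >=
                                 res["interaction"].f).sum())) / (n_perm + 1)
    for r in res.values():
        r.n_perm = n_perm
    return res


def assumption_checks(cells: dict[str, np.ndarray]):
    """Shapiro-Wilk normality per cell and Bartlett variance homogeneity.

    Returns ``(shapiro_p, bartlett_p)`` with ``shapiro_p`` a dict per cell.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in cells.items()}
    for name, a in arrays.items():
        if a.size < 3:
            raise ValueError(f"cell {name!r} needs >= 3 values")
        if np.ptp(a) == 0:
            raise ValueError(f"cell {name!r} is constant")
    shapiro_p = {name: float(sps.shapiro(a).pvalue) for name, a in arrays.items()}
    bartlett_p = (float(sps.bartlett(*arrays.values()).pvalue)
                  if len(arrays) >= 2 else float("nan"))
    return shapiro_p, bartlett_p


def fdr_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment for m tests (m >= len(p)).

    When only a subset of the m performed tests is passed, the list is
    padded with ones, which reproduces the BH adjustment at family size m.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    m = k if m is None else int(m)
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of p-values {k}")
    padded = np.concatenate([p, np.ones(m - k)])
    _, adj, _, _ = multipletests(padded, method="fdr_bh")
    return adj[:k]


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p from the t approximation for n >= 10 and from exact
    enumeration of rank permutations below.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rho = float(sps.spearmanr(x, y).statistic)
    if n >= 10:
        p = float(sps.spearmanr(x, y).pvalue)
    else:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean()) / ry.std()
        perms = np.array(list(itertools.permutations(range(n))))
        null = (rx[perms] @ ry) / n
        p = float((np.abs(null) >= abs(rho) - 1e-12).mean())
    return CorrelationResult(rho, n, p, rho_to_t(rho, n))


def rho_to_t(rho: float, n: int) -> float:
    """t = |rho| / sqrt((1 - rho^2) / (n - 2)); |rho| = 1 maps to +inf."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if abs(rho) >= 1:
        return float("inf")
    return float(abs(rho) / np.sqrt((1 - rho**2) / (n - 2)))


def critical_threshold(alpha: float, df, dist: str = "t") -> float:
    """Upper-tail critical value of the t or F distribution, to two decimals.

    ``df`` is an int for t and a (dfn, dfd) pair for F.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if dist == "t":
        val = sps.t.ppf(1 - alpha, df)
    elif dist == "f":
        val = sps.f.ppf(1 - alpha, *df)
    else:
        raise ValueError("dist must be 't' or 'f'")
    return float(np.round(val, 2))


def normalized_relapse(baseline, relapse):
    """Relapse intake as percent of baseline: 100 * relapse / baseline."""
    baseline = np.asarray(baseline, dtype=float)
    relapse = np.asarray(relapse, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline intake must be positive")
    out = 100.0 * relapse / baseline
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# voxel-wise cluster-extent correction

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def _label_clusters(supra: np.ndarray, connectivity: int):
    structure = ndimage.generate_binary_structure(supra.ndim,
                                                  _STRUCTURES[connectivity])
    return ndimage.label(supra, structure=structure)


def _signflip_tmaps(maps2d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for sign-flipped subject maps; rows of ``signs`` are one flip each."""
    n = maps2d.shape[0]
    ss = (maps2d**2).sum(axis=0)
    mean = signs @ maps2d / n
    var = (ss[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def _rank_standardize(a: np.ndarray, axis=-1) -> np.ndarray:
    r = sps.rankdata(a, axis=axis)
    r = r - r.mean(axis=axis, keepdims=True)
    sd = r.std(axis=axis, keepdims=True)
    sd[sd == 0] = 1.0
    return r / sd


def cluster_correct(maps: np.ndarray, mask: np.ndarray, cdt: float,
                    n_perm: int = 1000, seed: int = 0,
                    covariate: np.ndarray | None = None,
                    connectivity: int = 6) -> ClusterInference:
    """Cluster-extent FWE correction of a voxel-wise statistic map.

    ``maps`` is n_subjects x X x Y x Z of per-subject (paired-difference)
    maps.  Without a covariate the statistic is the one-sample t across
    subjects and the null is built by sign-flipping subject maps; with a
    covariate the statistic is the Spearman rho of each voxel with the
    covariate transformed to t = |rho| * sqrt((n-2)/(1-rho^2)) and the null
    permutes the covariate.  Clusters are face-adjacent (6-connected) by
    default; 18 and 26 neighbourhoods are available.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    if not np.isfinite(cdt):
        raise ValueError("cluster-defining threshold must be finite")
    maps = np.asarray(maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = maps.shape[0]
    flat = maps[:, mask]                         # n x V
    rng = np.random.default_rng(seed)
    if covariate is None and 2**n < 100:
        warnings.warn("few subjects: permutation space smaller than 100",
                      stacklevel=2)

    def extents(stat_row):
        vol = np.zeros(mask.shape)
        vol[mask] = stat_row
        supra = (vol > cdt) & mask
        lab, nlab = _label_clusters(supra, connectivity)
        if nlab == 0:
            return 0, lab, np.array([], dtype=int)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, nlab + 1))
        return int(sizes.max()), lab, sizes.astype(int)

    if covariate is None:
        t_obs = _signflip_tmaps(flat, np.ones((1, n)))[0]
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        t_null = _signflip_tmaps(flat, signs)
    else:
        cov = np.asarray(covariate, dtype=float)
        if cov.size != n:
            raise ValueError("covariate must have one value per subject map")
        vox_ranks = _rank_standardize(flat, axis=0)          # n x V
        cov_rank = _rank_standardize(cov[None, :], axis=1)[0]
        rho_obs = cov_rank @ vox_ranks / n
        with np.errstate(divide="ignore", invalid="ignore"):
            t_obs = np.abs(rho_obs) * np.sqrt((n - 2) / np.maximum(1 - rho_obs**2,
                                                                   1e-12))
        perms = np.stack([rng.permutation(cov_rank) for _ in range(n_perm)])
        rho_null = perms @ vox_ranks / n
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.abs(rho_null) * np.sqrt(
                (n - 2) / np.maximum(1 - rho_null**2, 1e-12))

    _, lab_obs, sizes_obs = extents(t_obs)
    null_max = np.fromiter((extents(t_null[k])[0] for k in range(n_perm)),
                           dtype=int, count=n_perm)
    clusters = [
        Cluster(i + 1, int(sz),
                (1 + int((null_max >= sz).sum())) / (n_perm + 1))
        for i, sz in enumerate(sizes_obs)
    ]
    stat_map = np.full(mask.shape, np.nan)
    stat_map[mask] = t_obs
    return ClusterInference(sorted(clusters, key=lambda c: -c.extent),
                            null_max, cdt, stat_map, lab_obs)
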