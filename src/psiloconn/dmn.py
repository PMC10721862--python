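"""Default-mode-network connectivity and regional sample entropy.

The DMN here is the 12-region rodent network (OF, PL, IL, Cing1, Cing2, RS,
TempA, ParA, Aud1, Aud2, V1, CA1).  DMN connectivity is the mean Fisher-z
correlation over the 66 within-DMN region pairs; the within-DMN strength of
a region is the mean of its 11 edges to the rest of the network.  Signal
complexity is quantified with sample entropy, SampEn = -ln(A/B): the
negative log conditional probability that embedding vectors matching for m
points (within tolerance r, standardized Euclidean distance) still match
for m+1 points.  Lower values indicate a more regular signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .atlas import DMN_REGIONS
from .connectivity import ConnMatrix


@dataclass(frozen=True)
class SampEnParams:
    m: int = 3          # embedding dimension
    r: float = 0.2      # distance tolerance on the standardized embedding

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance must be positive")


def dmn_connectivity(conn: ConnMatrix, dmn=DMN_REGIONS):
    """Mean within-DMN connectivity and per-region within-DMN strength.

    Returns ``(mean_fc, strengths)`` with ``strengths`` a Series over the
    DMN regions; each region's strength is the mean of its edges to the 11
    other DMN regions, so the mean of the strengths equals ``mean_fc``.
    """
    missing = [lab for lab in dmn if lab not in conn.labels]
    if missing:
        raise KeyError(f"DMN region(s) missing from matrix: {missing}")
    idx = [conn.labels.index(lab) for lab in dmn]
    sub = conn.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.nan)
    strengths = pd.Series(np.nanmean(sub, axis=1), index=list(dmn))
    iu = np.triu_indices(len(dmn), k=1)
    mean_fc = float(np.nanmean(sub[iu]))
    return mean_fc, strengths


def _embed(x: np.ndarray, dim: int, m: int) -> np.ndarray:
    # N - m templates for both lengths keeps the A and B counts comparable
    return np.lib.stride_tricks.sliding_window_view(x, dim)[: x.size - m]


def sample_entropy(x: np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """SampEn of a 1-D series with standardized Euclidean template matching.

    The series is mean-subtracted; embedding vectors of lengths m and m+1
    are compared with the standardized Euclidean distance (each embedding
    coordinate divided by its across-template standard deviation), counting
    a match when the distance is at most r * sqrt(dim) — which keeps the
    conventional r = 0.2 scale.  Self-matches are excluded.  Constant
    series, or series with no length-m matches (B = 0), are flagged NaN.
    """
    x = np.asarray(x, dtype=float).ravel()
    m, r = params.m, params.r
    if x.size < m + 2:
        raise ValueError(f"series too short for m={m}")
    if np.ptp(x) == 0:
        warnings.warn("constant series: sample entropy undefined", stacklevel=2)
        return float("nan")
    x = x - x.mean()

    def _count(dim: int) -> int:
        X = _embed(x, dim, m)
        v = X.var(axis=0, ddof=1)
        v[v == 0] = 1.0
        d = cdist(X, X, metric="seuclidean", V=v)
        thr = r * np.sqrt(dim)
        return int((d <= thr).sum()) - X.shape[0]   # exclude self-matches

    B = _count(m)
    if B == 0:
        warnings.warn("no template matches at length m: SampEn undefined",
                      stacklevel=2)
        return float("nan")
    A = _count(m + 1)
    if A == 0:
        warnings.warn("no template matches at length m+1: SampEn infinite",
                      stacklevel=2)
        return float("inf")
    return float(-np.log(A / B))


def regional_entropy_roi(ts: np.ndarray, labels,
                         params: SampEnParams = SampEnParams()) -> pd.Series:
    """SampEn per region from a regions x frames matrix."""
    ts = np.asarray(ts, dtype=float)
    vals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, lab in enumerate(labels):
            vals[lab] = sample_entropy(ts[i], params)
    return pd.Series(vals)


def regional_entropy_volume(vol: np.ndarray, label_vol: np.ndarray,
                            region_names, params: SampEnParams = SampEnParams()
                            ) -> pd.Series:
    """Voxel-wise SampEn averaged within each labeled region.

    ``label_vol`` holds integer labels (0 = outside the mask); label k maps
    to ``region_names[k-1]``.  Empty regions are flagged NaN.
    """
    vol = np.asarray(vol, dtype=float)
    label_vol = np.asarray(label_vol)
    vals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, name in enumerate(region_names, start=1):
            sel = vol[label_vol == k]
            if sel.shape[0] == 0:
                vals[name] = float("nan")
                continue
            vals[name] = float(np.nanmean(
                [sample_entropy(v, params) for v in sel]))
    return pd.Series(vals)


def dmn_mean(per_region: pd.Series, dmn=DMN_REGIONS) -> float:
    """DMN summary: mean of the 12 regional values (not voxel-pooled)."""
    missing = [lab for lab in dmn if lab not in per_region.index]
    if missing:
        raise KeyError(f"DMN region(s) missing: {missing}")
    return float(per_region.loc[list(dmn)].mean())
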