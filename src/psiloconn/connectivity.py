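"""ROI connectivity matrices, difference matrices, and global brain connectivity.

Functional connectivity between regions is the Pearson correlation of their
band-passed time courses, variance-stabilized with the Fisher z transform
(atanh, with |r| clipped just below 1).  Per-session change is the
elementwise difference of the post- and pre-injection matrices.  Global
brain connectivity (GBC) is the voxel-wise mean Fisher-z correlation of each
gray-matter voxel with every other voxel in the mask, computed after
isotropic Gaussian smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

#: |r| is clipped here before atanh so perfect correlations stay finite
R_CLIP = 1.0 - 1e-7
Z_CLIP = float(np.arctanh(R_CLIP))

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass
class ConnMatrix:
    values: np.ndarray                # R x R Fisher z, NaN diagonal-excluded entries allowed
    labels: tuple[str, ...]
    epoch: str = ""                   # "TP1" or "TP2"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match matrix size")


@dataclass
class DiffMatrix:
    values: np.ndarray                # R x R, TP2 - TP1
    labels: tuple[str, ...]
    session: str = ""                 # "psilocybin" or "saline"


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def fc_matrix(ts: np.ndarray, labels=None, epoch: str = "") -> ConnMatrix:
    """Fisher-z Pearson correlation matrix of a regions x frames epoch.

    Constant regions cannot be correlated; their rows/columns are flagged
    NaN with a warning.  The diagonal is set to NaN (excluded from all
    downstream statistics).
    """
    ts = np.asarray(ts, dtype=float)
    R, T = ts.shape
    if T < 4:
        raise ValueError("need at least 4 frames")
    labels = tuple(labels) if labels is not None else tuple(f"r{i}" for i in range(R))
    sd = ts.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{constant.sum()} constant region(s) flagged missing",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts)
    z = _fisher_z(r)
    z[constant, :] = np.nan
    z[:, constant] = np.nan
    np.fill_diagonal(z, np.nan)
    return ConnMatrix(z, labels, epoch)


def diff_matrix(tp2: ConnMatrix, tp1: ConnMatrix, session: str = "") -> DiffMatrix:
    """Post-minus-pre difference matrix (antisymmetric under argument swap)."""
    if tp2.labels != tp1.labels:
        raise ValueError("connectivity matrices have mismatched region labels")
    return DiffMatrix(tp2.values - tp1.values, tp2.labels, session)


def smooth_volume(vol: np.ndarray, fwhm: float, voxel_size: float) -> np.ndarray:
    """Isotropic Gaussian smoothing of a 4D (X,Y,Z,T) volume, per frame.

    ``fwhm`` and ``voxel_size`` are in mm; sigma in voxels is
    fwhm / (2*sqrt(2*ln 2) * voxel_size).  fwhm = 0 is the identity.
    """
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    vol = np.asarray(vol, dtype=float)
    if fwhm == 0:
        return vol.copy()
    sigma = fwhm / (FWHM_TO_SIGMA * voxel_size)
    return gaussian_filter(vol, sigma=(sigma, sigma, sigma, 0.0), mode="constant")


def gbc_map(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Global brain connectivity: per-voxel mean Fisher-z correlation to the mask.

    ``vol`` is X x Y x Z x T, ``mask`` a boolean X x Y x Z.  Returns a 3D map,
    NaN outside the mask and for constant-signal voxels.
    """
    vol = np.asarray(vol, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least two voxels")
    X = vol[mask]                     # V x T
    V, T = X.shape
    if T < 4:
        raise ValueError("need at least 4 frames")
    sd = X.std(axis=1)
    ok = sd > 0
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1)
    norm[~ok] = 1.0
    U = Xc / norm[:, None]
    r = U @ U.T
    z = _fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z[~ok, :] = np.nan
    z[:, ~ok] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_other = np.maximum(ok.sum() - ok.astype(int), 1)
        vals = np.nansum(z, axis=1) / n_other
    vals[~ok] = np.nan
    out = np.full(mask.shape, np.nan)
    out[mask] = vals
    return out
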