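"""Motion scrubbing, confound regression, band-pass filtering, epoch split.

Covers the desk-scale tail of a resting-state preprocessing chain: framewise
displacement (FD) from six realignment parameters, replacement of
motion-flagged frames by cubic-spline interpolation, least-squares confound
regression, zero-phase band-pass filtering to 0.01-0.1 Hz, and the
positional split of each run into a pre-injection epoch (first 340 frames)
and a post-injection epoch (last 340 frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

EPOCH_LEN = 340


@dataclass(frozen=True)
class PreprocParams:
    fd_threshold: float = 0.05          # mm
    band: tuple[float, float] = (0.01, 0.1)   # Hz
    rotation_radius: float = 5.0        # mm, rat head
    max_flag_fraction: float = 0.10

    def __post_init__(self):
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 < low < high")


@dataclass(frozen=True)
class Epochs:
    """Pre/post-injection frame ranges (half-open, 0-based)."""
    tp1: tuple[int, int]
    tp2: tuple[int, int]

    def slice1(self) -> slice:
        return slice(*self.tp1)

    def slice2(self) -> slice:
        return slice(*self.tp2)


def framewise_displacement(motion: np.ndarray, radius: float = 5.0) -> np.ndarray:
    """Power-style FD: sum of absolute parameter differentials.

    ``motion`` is 6 x T (or T x 6): three translations in mm then three
    rotations in radians; rotations are converted to mm as arc length at the
    given head radius.  FD of the first frame is 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or 6 not in motion.shape:
        raise ValueError("motion trace must be 6 x T or T x 6")
    if motion.shape[0] != 6:
        motion = motion.T
    if motion.shape[1] < 2:
        raise ValueError("need at least two frames")
    d = np.abs(np.diff(motion, axis=1))
    fd = d[:3].sum(axis=0) + radius * d[3:].sum(axis=0)
    return np.concatenate([[0.0], fd])


def scrub_interpolate(ts: np.ndarray, fd: np.ndarray, threshold: float = 0.05,
                      max_flag_fraction: float = 0.10):
    """Replace motion-flagged frames by per-region cubic-spline interpolation.

    Frames with FD above ``threshold`` are re-estimated from the unflagged
    frames; flagged frames before the first (or after the last) unflagged
    frame take that nearest unflagged value, because splines extrapolate
    poorly.  Returns ``(cleaned, flags, warned)`` where ``warned`` records a
    flagged fraction above ``max_flag_fraction``.
    """
    ts = np.asarray(ts, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if ts.shape[-1] != fd.shape[0]:
        raise ValueError("time-series length and FD length differ")
    flags = fd > threshold
    if flags.all():
        raise ValueError("all frames flagged; nothing to interpolate from")
    frac = flags.mean()
    warned = frac > max_flag_fraction
    if warned:
        warnings.warn(f"flagged fraction {frac:.1%} exceeds {max_flag_fraction:.0%}",
                      stacklevel=2)
    if not flags.any():
        return ts.copy(), flags, warned
    good = np.flatnonzero(~flags)
    bad = np.flatnonzero(flags)
    out = ts.copy()
    if good.size >= 4:
        cs = CubicSpline(good, ts[..., good], axis=-1)
        out[..., bad] = cs(bad)
    else:  # too few anchors for a cubic spline: fall back to linear
        flat = out.reshape(-1, out.shape[-1])
        src = ts.reshape(-1, ts.shape[-1])
        for row in range(flat.shape[0]):
            flat[row, bad] = np.interp(bad, good, src[row, good])
    # nearest-neighbour extension at the boundaries
    before = bad[bad < good[0]]
    after = bad[bad > good[-1]]
    if before.size:
        out[..., before] = ts[..., good[0]][..., None] if ts.ndim > 1 else ts[good[0]]
    if after.size:
        out[..., after] = ts[..., good[-1]][..., None] if ts.ndim > 1 else ts[good[-1]]
    return out, flags, warned


def regress_confounds(ts: np.ndarray, regressors: np.ndarray | None = None) -> np.ndarray:
    """Residualize each region on an intercept plus the given confounds.

    ``regressors`` is T x k (k may be 0 or None, leaving plain demeaning).
    A rank-deficient design raises, naming the collinear columns.
    """
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[-1]
    if regressors is None or (hasattr(regressors, "size") and regressors.size == 0):
        X = np.ones((T, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != T:
            raise ValueError("regressor length does not match time series")
        X = np.column_stack([np.ones(T), regressors])
    if T <= X.shape[1]:
        raise ValueError("more design columns than frames")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(X, pivoting=True)
        diag = np.abs(np.diag(r))
        bad = sorted(int(piv[i]) - 1 for i in range(len(diag))
                     if diag[i] < 1e-10 * diag[0] and piv[i] > 0)
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    return ts - (X @ beta).T


def bandpass(ts: np.ndarray, band: tuple[float, float] = (0.01, 0.1),
             tr: float = 1.5, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    ts = np.asarray(ts, dtype=float)
    nyq = 0.5 / tr
    low, high = band
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} invalid for TR {tr} (Nyquist {nyq:g} Hz)")
    padlen = 3 * (2 * order + 1)  # sosfiltfilt default for a 2nd-order band sos
    if ts.shape[-1] <= padlen:
        raise ValueError("time series too short for the filter order")
    sos = butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    return sosfiltfilt(sos, ts, axis=-1)


def split_epochs(ts: np.ndarray, epoch_len: int = EPOCH_LEN) -> Epochs:
    """Positional pre/post epochs: first ``epoch_len`` and last ``epoch_len`` frames."""
    T = np.asarray(ts).shape[-1]
    if T < 2 * epoch_len:
        raise ValueError(f"need at least {2 * epoch_len} frames, got {T}")
    return Epochs((0, epoch_len), (T - epoch_len, T))


def preprocess_session(ts: np.ndarray, motion: np.ndarray,
                       params: PreprocParams = PreprocParams(),
                       tr: float = 1.5):
    """Full desk-scale chain: FD -> scrub -> confound regression -> band-pass.

    Motion parameters are the confounds.  Returns ``(clean_ts, epochs, flags)``.
    """
    fd = framewise_displacement(motion, params.rotation_radius)
    scrubbed, flags, _ = scrub_interpolate(ts, fd, params.fd_threshold,
                                           params.max_flag_fraction)
    resid = regress_confounds(scrubbed, np.asarray(motion, dtype=float).T
                              if np.asarray(motion).shape[0] == 6 else motion)
    filtered = bandpass(resid, params.band, tr)
    return filtered, split_epochs(filtered), flags
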