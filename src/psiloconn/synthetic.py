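"""Synthetic crossover cohort and session generator.

Emulates a pharmaco-fMRI crossover design: 15 alcohol-deprivation-effect
(ADE) rats and 6 controls, each scanned twice (psilocybin / saline) in
randomized order, with 44-region BOLD time series of 1450 frames at
TR 1.5 s.  Signals follow a linear latent-factor model: three band-limited
(0.01-0.1 Hz) community factors (DMN/cortical, sensorimotor, subcortical)
plus idiosyncratic noise.  Under psilocybin the post-injection segment
reduces the DMN/cortical factor loadings (an effect attenuated in ADE
animals proportionally to their relapse intensity) and couples the
hypothalamus and dorsal raphe to cortex through an extra shared factor.

The generator also produces six-parameter motion traces with occasional
spike displacements and, on request, small 4D voxel volumes whose voxels
inherit their region's signal — enough to exercise the voxel-wise global
connectivity and entropy pathways at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from . import atlas

#: study-condition defaults
N_ADE_DEFAULT = 15
N_CON_DEFAULT = 6
N_FRAMES_DEFAULT = 1450
TR_DEFAULT = 1.5
EPOCH_LEN = 340

#: factor loading shared by all regions on their community factor
BASE_LOADING = 0.8

#: drinking-intake distribution (g/kg): baseline mean/SD and the mean/SD of
#: the positive relapse increment above baseline
BASELINE_INTAKE_MEAN = 6.35
BASELINE_INTAKE_SD = 1.75
RELAPSE_INCREMENT_MEAN = 1.75
RELAPSE_INCREMENT_SD = 0.8

TREATMENTS = ("psilocybin", "saline")


class CohortError(ValueError):
    """Raised for invalid cohort specifications."""


@dataclass(frozen=True)
class Subject:
    id: str
    group: str                 # "ADE" or "control"
    session_order: str         # "psi-first" or "sal-first"
    baseline_intake: float     # g/kg; NaN for controls
    relapse_intake: float      # g/kg; NaN for controls

    @property
    def relapse_norm(self) -> float:
        """Relapse intake as percent of baseline (NaN for controls)."""
        if not np.isfinite(self.baseline_intake) or self.baseline_intake <= 0:
            return float("nan")
        return 100.0 * self.relapse_intake / self.baseline_intake


@dataclass(frozen=True)
class CohortDesign:
    subjects: tuple[Subject, ...]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(s) | {"relapse_norm": s.relapse_norm} for s in self.subjects]
        return pd.DataFrame(rows)

    @property
    def ade(self) -> tuple[Subject, ...]:
        return tuple(s for s in self.subjects if s.group == "ADE")


@dataclass(frozen=True)
class EffectSpec:
    """Treatment-effect parameters realized by the generator.

    dmn_drop          fractional reduction of DMN/cortical factor loadings
                      post-injection under psilocybin (dimensionless, >= 0)
    hub_gain          loading of the extra hub factor coupling HypR/DRN to
                      cortex post-injection under psilocybin
    blunting_beta     per-unit attenuation of dmn_drop with normalized
                      relapse above 100% (ADE animals only)
    noise_sd          idiosyncratic noise SD relative to unit-variance factors
    motion_spike_prob per-frame probability of a spike displacement
    motion_spike_amp  spike amplitude in mm
    """

    dmn_drop: float = 0.5
    hub_gain: float = 0.6
    blunting_beta: float = 2.0
    noise_sd: float = 1.0
    motion_spike_prob: float = 0.003
    motion_spike_amp: float = 0.2

    def __post_init__(self):
        if self.dmn_drop < 0 or self.hub_gain < 0:
            raise ValueError("dmn_drop and hub_gain must be non-negative")
        if self.blunting_beta < 0:
            raise ValueError("blunting_beta must be non-negative")
        if not 0 <= self.motion_spike_prob <= 1:
            raise ValueError("motion_spike_prob must be a probability")
        if self.motion_spike_amp < 0:
            raise ValueError("motion_spike_amp must be non-negative")

    def realized_drop(self, subject: Subject) -> float:
        """Per-subject DMN-loading drop after relapse blunting, clipped to >= 0."""
        drop = self.dmn_drop
        rn = subject.relapse_norm
        if subject.group == "ADE" and np.isfinite(rn):
            drop = self.dmn_drop * max(0.0, 1.0 - self.blunting_beta * (rn - 100.0) / 100.0)
        return max(0.0, drop)


@dataclass
class SyntheticSession:
    subject_id: str
    treatment: str
    roi_ts: np.ndarray                 # regions x frames
    motion: np.ndarray                 # 6 x frames (3 translations mm, 3 rotations rad)
    tr: float
    region_labels: tuple[str, ...]
    ground_truth: dict = field(default_factory=dict)
    voxel_volume: np.ndarray | None = None   # X x Y x Z x frames
    voxel_labels: np.ndarray | None = None   # X x Y x Z integer region labels (0 = outside)

    @property
    def n_frames(self) -> int:
        return self.roi_ts.shape[1]


def generate_cohort(n_ade: int = N_ADE_DEFAULT, n_con: int = N_CON_DEFAULT,
                    seed: int = 0) -> CohortDesign:
    """Draw a crossover cohort: group labels, session orders, drinking intakes.

    ADE animals get a baseline intake and a relapse intake strictly above
    baseline; controls carry no drinking values.  Session orders are assigned
    uniformly at random.  Deterministic for a fixed seed.
    """
    if n_ade < 0 or n_con < 0:
        raise CohortError("group sizes must be non-negative")
    if n_ade + n_con < 1:
        raise CohortError("cohort must contain at least one subject")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_ade + n_con):
        is_ade = i < n_ade
        order = "psi-first" if rng.random() < 0.5 else "sal-first"
        if is_ade:
            baseline = float(rng.normal(BASELINE_INTAKE_MEAN, BASELINE_INTAKE_SD))
            baseline = max(baseline, 1.0)
            increment = abs(float(rng.normal(RELAPSE_INCREMENT_MEAN, RELAPSE_INCREMENT_SD)))
            relapse = baseline + increment
            sid = f"ade{i + 1:02d}"
            group = "ADE"
        else:
            baseline = relapse = float("nan")
            sid = f"con{i - n_ade + 1:02d}"
            group = "control"
        subjects.append(Subject(sid, group, order, baseline, relapse))
    return CohortDesign(tuple(subjects), seed)


def _bandlimited_noise(rng: np.random.Generator, n_series: int, n_frames: int,
                       tr: float, band=(0.01, 0.1)) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the resting-state band."""
    x = rng.standard_normal((n_series, n_frames))
    nyq = 0.5 / tr
    sos = butter(2, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    y = sosfiltfilt(sos, x, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def make_motion(n_frames: int, spike_prob: float = 0.003, spike_amp: float = 0.2,
                seed: int = 0) -> np.ndarray:
    """Six-parameter motion trace: slow sub-threshold drift plus spike frames.

    Rows 0-2 are translations in mm, rows 3-5 rotations in radians.  Spikes
    are single-frame excursions on the first translation axis, so each spike
    raises the framewise displacement on the spike frame and the frame after.
    """
    if not 0 <= spike_prob <= 1:
        raise ValueError("spike_prob must lie in [0, 1]")
    if spike_amp < 0:
        raise ValueError("spike amplitude must be non-negative")
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(seed)
    # slow drift with frame-to-frame increments far below the 0.05 mm threshold
    drift = _bandlimited_noise(rng, 6, max(n_frames, 64), TR_DEFAULT,
                               band=(0.005, 0.02))[:, :n_frames]
    motion = drift * 0.01           # translations: ~0.01 mm scale
    motion[3:] *= 0.2 / 5.0         # rotations: keep radius*|drot| small (radius 5 mm)
    spikes = rng.random(n_frames) < spike_prob
    spikes[0] = False
    motion[0, spikes] += spike_amp
    return motion


def _community_index_map() -> list[tuple[np.ndarray, int]]:
    out = []
    for k, labels in enumerate(atlas.COMMUNITIES.values()):
        out.append((np.asarray(atlas.indices(labels)), k))
    return out


def simulate_session(subject: Subject, treatment: str, spec: EffectSpec | None = None,
                     seed: int = 0, n_frames: int = N_FRAMES_DEFAULT,
                     tr: float = TR_DEFAULT) -> SyntheticSession:
    """Simulate one scanning session for one subject.

    Signals are sums of a community factor (loading 0.8) and idiosyncratic
    band-limited noise.  Under psilocybin the final 340 frames (the
    post-injection epoch) scale the DMN/cortical loadings by ``1 - drop``
    with the subject's relapse-blunted drop, and add a shared hub factor to
    HypR/DRN (loading ``hub_gain``) and to cortical regions (loading
    ``hub_gain / 2``).  Under saline one generating model covers the whole run.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    spec = spec or EffectSpec()
    if n_frames < 2 * EPOCH_LEN:
        raise ValueError(f"n_frames must be >= {2 * EPOCH_LEN}")
    rng = np.random.default_rng(seed)
    R = atlas.N_REGIONS

    factors = _bandlimited_noise(rng, len(atlas.COMMUNITIES), n_frames, tr)
    hub_factor = _bandlimited_noise(rng, 1, n_frames, tr)[0]
    noise = _bandlimited_noise(rng, R, n_frames, tr) * spec.noise_sd

    loadings = np.full((R, n_frames), BASE_LOADING)
    post = slice(n_frames - EPOCH_LEN, n_frames)
    drop = spec.realized_drop(subject) if treatment == "psilocybin" else 0.0
    community_of = np.empty(R, dtype=int)
    for idx, k in _community_index_map():
        community_of[idx] = k
    dmn_cortical = np.asarray(atlas.indices(atlas.COMMUNITY_DMN_CORTICAL))
    hubs = np.asarray(atlas.indices(atlas.HUB_REGIONS))

    if treatment == "psilocybin":
        loadings[np.ix_(dmn_cortical, np.arange(n_frames)[post])] *= max(0.0, 1.0 - drop)

    ts = loadings * factors[community_of] + noise
    if treatment == "psilocybin" and spec.hub_gain > 0:
        ts[hubs[:, None], np.arange(n_frames)[post]] += spec.hub_gain * hub_factor[post]
        ts[dmn_cortical[:, None], np.arange(n_frames)[post]] += (
            0.5 * spec.hub_gain * hub_factor[post])

    motion = make_motion(n_frames, spec.motion_spike_prob, spec.motion_spike_amp,
                         seed=int(rng.integers(2**31)))
    gt = {
        "treatment": treatment,
        "dmn_drop_realized": drop,
        "hub_gain": spec.hub_gain if treatment == "psilocybin" else 0.0,
        "relapse_norm": subject.relapse_norm,
        "spec": asdict(spec),
    }
    return SyntheticSession(subject.id, treatment, ts, motion, tr,
                            atlas.REGIONS, gt)


def add_voxel_volume(session: SyntheticSession, shape=(16, 16, 8),
                     voxel_noise_sd: float = 0.5, seed: int = 0) -> SyntheticSession:
    """Attach a small 4D voxel grid whose voxels inherit their region's signal.

    Voxels are assigned to the 44 regions in contiguous flat-index blocks; a
    trailing remainder stays unlabeled (label 0, outside the gray-matter mask).
    Each in-mask voxel's time course is its region signal plus voxel noise.
    """
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(shape))
    R, T = session.roi_ts.shape
    per_region = n_vox // (R + 1)
    if per_region < 1:
        raise ValueError("grid too small to host all regions")
    labels_flat = np.zeros(n_vox, dtype=np.int32)
    for r in range(R):
        labels_flat[r * per_region:(r + 1) * per_region] = r + 1
    vol = np.zeros((n_vox, T))
    in_mask = labels_flat > 0
    vol[in_mask] = session.roi_ts[labels_flat[in_mask] - 1]
    vol[in_mask] += voxel_noise_sd * rng.standard_normal((in_mask.sum(), T))
    session.voxel_volume = vol.reshape(*shape, T)
    session.voxel_labels = labels_flat.reshape(shape)
    return session


def simulate_cohort_sessions(cohort: CohortDesign, spec: EffectSpec | None = None,
                             seed: int = 0, n_frames: int = N_FRAMES_DEFAULT,
                             tr: float = TR_DEFAULT):
    """Yield (subject, treatment, session) for every session of the cohort.

    Per-session seeds are spawned deterministically from ``seed``.
    """
    spec = spec or EffectSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cohort.subjects) * 2)
    k = 0
    for subject in cohort.subjects:
        order = (("psilocybin", "saline") if subject.session_order == "psi-first"
                 else ("saline", "psilocybin"))
        for treatment in order:
            sess_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            yield subject, treatment, simulate_session(
                subject, treatment, spec, seed=sess_seed, n_frames=n_frames, tr=tr)


# ---------------------------------------------------------------------------
# plain-text / NIfTI output

def write_roi_ts(session: SyntheticSession, path) -> None:
    df = pd.DataFrame(session.roi_ts, index=list(session.region_labels))
    df.to_csv(path, sep="\t", header=False, float_format="%.6g")


def write_motion(session: SyntheticSession, path) -> None:
    np.savetxt(path, session.motion.T, fmt="%.6g", delimiter="\t")


def write_cohort(cohort: CohortDesign, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def write_ground_truth(session: SyntheticSession, path) -> None:
    Path(path).write_text(json.dumps(session.ground_truth, indent=2))


def write_volume(session: SyntheticSession, vol_path, labels_path,
                 voxel_size_mm: float = 0.3) -> None:
    import nibabel as nib
    if session.voxel_volume is None:
        raise ValueError("session has no voxel volume; call add_voxel_volume first")
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(session.voxel_volume.astype(np.float32), affine), vol_path)
    nib.save(nib.Nifti1Image(session.voxel_labels.astype(np.int16), affine), labels_path)
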