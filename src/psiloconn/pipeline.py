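"""End-to-end helpers: simulate a cohort, preprocess, and tabulate responses.

These functions chain the generator, preprocessing, connectivity and DMN
modules into the tables the inference layer consumes: per-subject
post-minus-pre DMN responses under each treatment, per-subject difference
matrices for the network-based statistic, and the relapse covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import connectivity, dmn, preprocess, synthetic
from .atlas import DMN_REGIONS


@dataclass
class CohortAnalysis:
    """Per-subject session-level responses of one simulated cohort."""

    subjects: tuple[str, ...]
    groups: tuple[str, ...]
    relapse_norm: np.ndarray            # percent of baseline; NaN for controls
    dmn_delta: pd.DataFrame             # index subject, columns psilocybin/saline
    strength_delta: dict                # treatment -> DataFrame (subject x DMN region)
    diff_psi: np.ndarray                # n x R x R difference matrices
    diff_sal: np.ndarray
    labels: tuple[str, ...]

    @property
    def dmn_decrease(self) -> pd.Series:
        """Psilocybin-induced DMN FC decrease, Delta(sal) - Delta(psi)."""
        return self.dmn_delta["saline"] - self.dmn_delta["psilocybin"]


def session_responses(session: synthetic.SyntheticSession,
                      params: preprocess.PreprocParams = preprocess.PreprocParams(),
                      run_preprocess: bool = True):
    """Preprocess one session and compute epoch-wise connectivity summaries.

    Returns ``(diff, dmn_delta, strength_delta)``: the TP2-TP1 difference
    matrix, the change in mean DMN connectivity and the per-region change in
    within-DMN strength.
    """
    if run_preprocess:
        ts, epochs, _ = preprocess.preprocess_session(
            session.roi_ts, session.motion, params, session.tr)
    else:
        ts = session.roi_ts
        epochs = preprocess.split_epochs(ts)
    c1 = connectivity.fc_matrix(ts[:, epochs.slice1()], session.region_labels, "TP1")
    c2 = connectivity.fc_matrix(ts[:, epochs.slice2()], session.region_labels, "TP2")
    d = connectivity.diff_matrix(c2, c1, session.treatment)
    m1, s1 = dmn.dmn_connectivity(c1)
    m2, s2 = dmn.dmn_connectivity(c2)
    return d, m2 - m1, s2 - s1


def analyze_cohort(cohort: synthetic.CohortDesign,
                   spec: synthetic.EffectSpec | None = None,
                   seed: int = 0,
                   n_frames: int = synthetic.N_FRAMES_DEFAULT,
                   run_preprocess: bool = True) -> CohortAnalysis:
    """Simulate and analyze every session of a cohort."""
    spec = spec or synthetic.EffectSpec()
    subjects = tuple(s.id for s in cohort.subjects)
    groups = tuple(s.group for s in cohort.subjects)
    relapse = np.array([s.relapse_norm for s in cohort.subjects])
    R = len(synthetic.atlas.REGIONS)
    n = len(subjects)
    dmn_delta = pd.DataFrame(index=list(subjects),
                             columns=["psilocybin", "saline"], dtype=float)
    strength_delta = {
        t: pd.DataFrame(index=list(subjects), columns=list(DMN_REGIONS),
                        dtype=float)
        for t in synthetic.TREATMENTS
    }
    diff = {t: np.empty((n, R, R)) for t in synthetic.TREATMENTS}
    pos = {sid: k for k, sid in enumerate(subjects)}
    for subject, treatment, session in synthetic.simulate_cohort_sessions(
            cohort, spec, seed=seed, n_frames=n_frames):
        d, dm, ds = session_responses(session, run_preprocess=run_preprocess)
        dmn_delta.loc[subject.id, treatment] = dm
        strength_delta[treatment].loc[subject.id] = ds
        diff[treatment][pos[subject.id]] = np.nan_to_num(d.values, nan=0.0)
    return CohortAnalysis(subjects, groups, relapse, dmn_delta, strength_delta,
                          diff["psilocybin"], diff["saline"],
                          synthetic.atlas.REGIONS)
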