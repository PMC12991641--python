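"""Trial-wise response estimation with least-squares-separate (LSS) GLMs.

One GLM is fit per trial: the target trial gets its own HRF-convolved
regressor and all remaining trials of the same model kind share a second
one, which handles the collinearity of fast event-related designs better
than a single all-trials model. Two independent model families are kept per
phase: *cue* models (1 s cue boxcars; context onsets not modeled) and
*context* models (video-onset-to-cue-onset epochs; cue onsets not modeled) —
the design keeps CS type and context orthogonal, so neither family needs the
other's events. US onsets (acquisition/reversal only), six motion
parameters, white-matter and CSF mean signals, a cosine high-pass drift
basis, and an intercept enter as regressors of no interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fearrsa.design import CSType, Phase, PhaseDesign
from fearrsa.hrf import convolve_events, cosine_drift_basis
from fearrsa.synthetic_bold import CONFOUND_COLUMNS, VolumeGeometry

__all__ = [
    "GLMDesign",
    "BetaSeries",
    "build_lss_design",
    "estimate_lss_betas",
    "first_level_contrast",
]

MODEL_KINDS = ("cue", "context")


@dataclass
class GLMDesign:
    """A labeled design matrix for one LSS fit."""

    matrix: np.ndarray  # scans × regressors
    column_names: list[str]
    target_column: int

    def __post_init__(self) -> None:
        if len(self.column_names) != self.matrix.shape[1]:
            raise ValueError("column labels must match matrix width")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column labels must be unique")
        if not np.any(self.matrix[:, self.target_column]):
            raise ValueError("target column is all zero")


@dataclass
class BetaSeries:
    """Trial × voxel LSS coefficients with aligned trial metadata."""

    model_kind: str
    betas: np.ndarray  # trials × masked voxels
    metadata: pd.DataFrame
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if len(self.metadata) != self.betas.shape[0]:
            raise ValueError("metadata rows must match beta rows")

    def restrict_voxels(self, idx: np.ndarray) -> "BetaSeries":
        return BetaSeries(self.model_kind, self.betas[:, idx], self.metadata,
                          self.geometry)

    def select_trials(self, rows: np.ndarray) -> "BetaSeries":
        """Row subset (boolean or index array) with metadata kept aligned."""
        return BetaSeries(
            self.model_kind, self.betas[rows],
            self.metadata.iloc[rows].reset_index(drop=True), self.geometry,
        )

    def unreinforced(self) -> "BetaSeries":
        return self.select_trials(self.metadata["reinforced"].to_numpy() == 0)


def _event_regressors(
    design: PhaseDesign, model_kind: str, n_scans: int, tr: float
) -> np.ndarray:
    """Per-trial HRF-convolved regressors for one model family (scans × trials)."""
    R = np.empty((n_scans, len(design.trials)))
    for i, t in enumerate(design.trials):
        if model_kind == "cue":
            R[:, i] = convolve_events(
                [t.onset_cue], [t.onset_rating - t.onset_cue], n_scans, tr
            )
        else:
            R[:, i] = convolve_events(
                [t.onset_context], [t.onset_cue - t.onset_context], n_scans, tr
            )
    return R


def _nuisance_block(
    design: PhaseDesign,
    confounds: pd.DataFrame,
    n_scans: int,
    tr: float,
    drift_cutoff_s: float,
) -> tuple[np.ndarray, list[str]]:
    """US (no-interest), confound, drift, and intercept columns."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    us_onsets = [t.onset_us for t in design.trials if t.reinforced]
    if us_onsets:
        # impulse events: US delivery is effectively instantaneous
        cols.append(convolve_events(us_onsets, [0.0] * len(us_onsets), n_scans, tr))
        names.append("us")
    if len(confounds) != n_scans:
        raise ValueError(
            f"confound table has {len(confounds)} rows but volume has {n_scans} scans"
        )
    missing = [c for c in CONFOUND_COLUMNS if c not in confounds.columns]
    if missing:
        raise ValueError(f"confound table missing columns: {missing}")
    for c in CONFOUND_COLUMNS:
        cols.append(confounds[c].to_numpy(dtype=float))
        names.append(c)
    drift = cosine_drift_basis(n_scans, tr, drift_cutoff_s)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        names.append(f"drift{j + 1:02d}")
    cols.append(np.ones(n_scans))
    names.append("intercept")
    return np.column_stack(cols), names


def build_lss_design(
    design: PhaseDesign,
    target_trial: int,
    model_kind: str,
    confounds: pd.DataFrame,
    geometry: VolumeGeometry,
    n_scans: int | None = None,
    drift_cutoff_s: float = 128.0,
) -> GLMDesign:
    """Design matrix for the LSS model of one target trial.

    Columns: the target trial's regressor, one shared regressor for all other
    same-kind trials, then the nuisance block (US when present, 6 motion,
    WM, CSF, cosine drift, intercept).
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    idx = [t.trial_index for t in design.trials]
    if target_trial not in idx:
        raise ValueError(f"target trial {target_trial} not in design")
    if design.total_duration is None:
        raise ValueError("design has no onsets; call schedule_onsets first")
    if n_scans is None:
        n_scans = int(np.ceil(design.total_duration / geometry.tr))
    R = _event_regressors(design, model_kind, n_scans, geometry.tr)
    pos = idx.index(target_trial)
    others = R.sum(axis=1) - R[:, pos]
    N, nuisance_names = _nuisance_block(
        design, confounds, n_scans, geometry.tr, drift_cutoff_s
    )
    cols = [R[:, pos]]
    names = [f"target_trial_{target_trial:03d}"]
    if R.shape[1] > 1:
        cols.append(others)
        names.append("other_trials")
    matrix = np.column_stack(cols + [N])
    return GLMDesign(matrix=matrix, column_names=names + nuisance_names,
                     target_column=0)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the involved columns via the QR diagonal
        _, Rq = np.linalg.qr(X)
        diag = np.abs(np.diag(Rq))
        bad = [names[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank}/{X.shape[1]}); collinear columns: {bad}"
        )


def estimate_lss_betas(
    data: np.ndarray,
    design: PhaseDesign,
    confounds: pd.DataFrame,
    geometry: VolumeGeometry,
    model_kind: str,
    drift_cutoff_s: float = 128.0,
) -> BetaSeries:
    """Fit the full LSS beta series for one phase and model family.

    ``data`` is the masked time-series matrix (scans × voxels). Each trial's
    OLS fit records the target-trial coefficient per voxel; rows are ordered
    by trial index.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    n_scans = data.shape[0]
    trials = sorted(design.trials, key=lambda t: t.trial_index)
    ordered = PhaseDesign(design.phase, trials, design.seed, design.total_duration)
    R = _event_regressors(ordered, model_kind, n_scans, geometry.tr)
    total = R.sum(axis=1)
    N, nuis_names = _nuisance_block(ordered, confounds, n_scans, geometry.tr,
                                    drift_cutoff_s)
    betas = np.empty((len(trials), data.shape[1]))
    for i in range(len(trials)):
        cols = [R[:, i]]
        names = [f"target_trial_{trials[i].trial_index:03d}"]
        if len(trials) > 1:
            cols.append(total - R[:, i])
            names.append("other_trials")
        X = np.column_stack(cols + [N])
        _check_rank(X, names + nuis_names)
        coef, *_ = np.linalg.lstsq(X, data, rcond=None)
        betas[i] = coef[0]
    meta = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in trials],
            "cue_id": [t.cue_id for t in trials],
            "context_id": [t.context_id for t in trials],
            "cs_type": [t.cs_type.value for t in trials],
            "reinforced": [int(t.reinforced) for t in trials],
            "phase": [t.phase.value for t in trials],
        }
    )
    return BetaSeries(model_kind=model_kind, betas=betas, metadata=meta,
                      geometry=geometry)


def first_level_contrast(
    data: np.ndarray,
    design: PhaseDesign,
    confounds: pd.DataFrame,
    geometry: VolumeGeometry,
    condition_weights: dict[str, float],
    drift_cutoff_s: float = 128.0,
) -> np.ndarray:
    """Condition-wise GLM contrast map over masked voxels.

    One HRF-convolved column per CS type (cue events), the standard nuisance
    block, then the weighted sum of condition coefficients per voxel.
    """
    n_scans = data.shape[0]
    present = sorted({t.cs_type.value for t in design.trials})
    unknown = set(condition_weights) - set(present)
    if unknown:
        raise ValueError(f"weights reference unknown conditions: {sorted(unknown)}")
    cols, names = [], []
    for cond in present:
        onsets = [t.onset_cue for t in design.trials if t.cs_type.value == cond]
        durs = [t.onset_rating - t.onset_cue for t in design.trials
                if t.cs_type.value == cond]
        cols.append(convolve_events(onsets, durs, n_scans, geometry.tr))
        names.append(cond)
    N, nuis_names = _nuisance_block(design, confounds, n_scans, geometry.tr,
                                    drift_cutoff_s)
    X = np.column_stack(cols + [N])
    _check_rank(X, names + nuis_names)
    coef, *_ = np.linalg.lstsq(X, data, rcond=None)
    w = np.array([condition_weights.get(c, 0.0) for c in present])
    return w @ coef[: len(present)]
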