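"""BOLD-like synthetic data with planted representational structure.

Every trial's "true" multivoxel pattern is a weighted sum of components drawn
from a :class:`PatternBank`:

    pattern(t) = baseline
               + w_item  · P_item(cue_t)
               + w_cat   · P_valence(current valence of cue_t)
               + w_ctx   · P_context(context_t)
               + N(0, trial_noise_sd)

with phase- and CS-type-specific weights, so item stability, cue
generalization, context specificity, and cross-phase reinstatement all have
known ground truth. Voxel time series are the HRF-convolved event boxcars
scaled by these patterns, plus confound-loaded nuisance series, a slow linear
drift, and AR(1) Gaussian scan noise. Reuse flags control whether item and
valence-category patterns persist across phases (shared patterns → planted
reinstatement) or are drawn fresh per phase (independence null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fearrsa.design import CSType, Phase, PhaseDesign
from fearrsa.hrf import convolve_events

__all__ = [
    "VolumeGeometry",
    "PatternBank",
    "EffectSpec",
    "SyntheticDataset",
    "default_geometry",
    "default_effects",
    "null_effects",
    "make_pattern_bank",
    "compose_trial_patterns",
    "compose_context_patterns",
    "simulate_confounds",
    "synthesize_bold",
]

CONFOUND_COLUMNS = [
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
    "white_matter", "csf",
]


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid, isotropic voxel size (mm), brain mask, and TR (s)."""

    shape: tuple[int, int, int]
    mask: np.ndarray
    voxel_size_mm: float = 2.5
    tr: float = 2.53

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0 or self.tr <= 0:
            raise ValueError("voxel size and TR must be positive")
        if self.mask.shape != tuple(self.shape) or self.mask.dtype != bool:
            raise ValueError("mask must be a boolean array matching shape")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size_mm
        return a


def default_geometry(shape: tuple[int, int, int] = (18, 18, 12),
                     voxel_size_mm: float = 2.5, tr: float = 2.53) -> VolumeGeometry:
    """Desk-scale geometry: an ellipsoidal brain-like mask in a small grid."""
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    # semi-axes 1.15× the half-extent, clipped by the grid: ~2,400 in-mask
    # voxels at the default 18×18×12 shape
    mask = (((x - cx) / (1.15 * cx + 1e-9)) ** 2
            + ((y - cy) / (1.15 * cy + 1e-9)) ** 2
            + ((z - cz) / (1.15 * cz + 1e-9)) ** 2) <= 1.0
    return VolumeGeometry(shape=shape, mask=mask, voxel_size_mm=voxel_size_mm, tr=tr)


@dataclass
class PatternBank:
    """Per-voxel component patterns defined on the masked voxels.

    ``item[(key, cue_id)]``, ``valence[(key, 'threat'|'safe')]`` where ``key``
    is ``'base'`` for patterns shared across phases or a phase value for
    fresh per-phase patterns; ``context[context_id]``; plus a baseline.
    Patterns are mutually orthogonalized within the masked subspace.
    """

    baseline: np.ndarray
    item: dict[tuple[str, str], np.ndarray]
    valence: dict[tuple[str, str], np.ndarray]
    context: dict[str, np.ndarray]
    seed: int
    n_voxels: int

    def item_pattern(self, cue_id: str, key: str = "base") -> np.ndarray:
        return self.item[(key, cue_id)]

    def valence_pattern(self, valence: str, key: str = "base") -> np.ndarray:
        return self.valence[(key, valence)]


def make_pattern_bank(
    geometry: VolumeGeometry,
    seed: int,
    cue_ids: tuple[str, ...] = tuple(f"cue{i:02d}" for i in range(8)),
    context_ids: tuple[str, ...] = tuple(f"ctx{i:02d}" for i in range(16)),
    fresh_phases: tuple[Phase, ...] = (),
    orthogonalize: bool = True,
) -> PatternBank:
    """Draw the component patterns (Gaussian, optionally orthogonalized).

    The default request is 1 baseline + 8 item + 2 valence + 16 context = 27
    patterns; each phase listed in ``fresh_phases`` adds its own 8 item and 2
    valence patterns. Orthogonalization (QR of the Gaussian draw, scaled to
    unit voxel variance) requires at least as many masked voxels as patterns.
    """
    keys: list[tuple[str, ...]] = [("baseline",)]
    keys += [("item", "base", c) for c in cue_ids]
    keys += [("valence", "base", v) for v in ("threat", "safe")]
    keys += [("context", c) for c in context_ids]
    for ph in fresh_phases:
        ph = Phase(ph)
        keys += [("item", ph.value, c) for c in cue_ids]
        keys += [("valence", ph.value, v) for v in ("threat", "safe")]

    v = geometry.n_voxels
    k = len(keys)
    if orthogonalize and v < k:
        raise ValueError(f"mask has {v} voxels but {k} patterns requested")
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((v, k))
    if orthogonalize:
        Q, _ = np.linalg.qr(G)
        # fix signs for determinism across BLAS variants
        signs = np.sign(np.sum(Q * G, axis=0))
        signs[signs == 0] = 1.0
        P = Q * signs * np.sqrt(v)
    else:
        P = G
    bank = PatternBank(baseline=P[:, 0], item={}, valence={}, context={},
                       seed=seed, n_voxels=v)
    for j, key in enumerate(keys):
        if key[0] == "item":
            bank.item[(key[1], key[2])] = P[:, j]
        elif key[0] == "valence":
            bank.valence[(key[1], key[2])] = P[:, j]
        elif key[0] == "context":
            bank.context[key[1]] = P[:, j]
    return bank


def _phase_map(value, phases=tuple(Phase)) -> dict[Phase, float]:
    if isinstance(value, dict):
        return {Phase(k): float(v) for k, v in value.items()}
    return {p: float(value) for p in phases}


def _phase_cstype_map(value) -> dict[tuple[Phase, CSType], float]:
    if isinstance(value, dict):
        return {(Phase(p), CSType(c)): float(v) for (p, c), v in value.items()}
    return {(p, c): float(value) for p in Phase for c in CSType}


@dataclass
class EffectSpec:
    """Planted effect weights and noise parameters.

    ``w_item``/``w_cat`` map (phase, cs_type) to component weights, ``w_ctx``
    maps phase to the context-pattern weight. ``reuse_item``/``reuse_cat``
    say, per phase, whether that phase loads the shared ('base') patterns
    (True → cross-phase reinstatement is planted) or its own fresh ones.
    Noise: trial-level pattern jitter, AR(1) scan noise, linear drift, and
    confound loadings (motion / white matter / CSF regression weights).
    """

    w_item: dict[tuple[Phase, CSType], float]
    w_cat: dict[tuple[Phase, CSType], float]
    w_ctx: dict[Phase, float]
    baseline_amplitude: float = 1.0
    reuse_item: dict[Phase, bool] = field(
        default_factory=lambda: {p: True for p in Phase})
    reuse_cat: dict[Phase, bool] = field(
        default_factory=lambda: {p: True for p in Phase})
    trial_noise_sd: float = 0.3
    scan_noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.5
    motion_loading_sd: float = 0.2
    compartment_loading_sd: float = 0.2

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in (-1, 1)")
        for d in (self.w_item, self.w_cat):
            if not all(np.isfinite(list(d.values()))):
                raise ValueError("weights must be finite")


def default_effects(
    item_scale: float = 1.0,
    cat_scale: float = 1.0,
    ctx_scale: float = 1.0,
    **noise_overrides,
) -> EffectSpec:
    """Study-condition effect weights mirroring the planted findings.

    * cue generalization: valence-category weight higher for threat than safe
      cues in acquisition and reversal (CS+ > CS- generalization);
    * item stability: item weight raised in reversal for the cues whose
      contingency changed (CS-+, CS+-) relative to consistent cues;
    * context specificity: context weight higher in reversal than
      acquisition;
    * reinstatement: item and category patterns are shared across phases
      (reuse on), with test-phase weights reduced.
    """
    P, C = Phase, CSType
    w_cat = {}
    for p in Phase:
        for c in CSType:
            val = c.current_valence(p)
            if p in (P.ACQUISITION, P.REVERSAL):
                w_cat[(p, c)] = 0.6 if val == "threat" else 0.2
            else:
                w_cat[(p, c)] = 0.15  # generalization differences dissolve at test
    w_item = {}
    for p in Phase:
        for c in CSType:
            w = 0.5
            if p == P.REVERSAL and c in (C.CS_MP, C.CS_PM):
                w = 0.8  # contingency change boosts item-level coding
            if p in (P.TEST_NEW, P.TEST_OLD):
                w = 0.4
            w_item[(p, c)] = w
    w_ctx = {P.ACQUISITION: 0.4, P.REVERSAL: 0.8, P.TEST_NEW: 0.4, P.TEST_OLD: 0.4}
    return EffectSpec(
        w_item={k: item_scale * v for k, v in w_item.items()},
        w_cat={k: cat_scale * v for k, v in w_cat.items()},
        w_ctx={k: ctx_scale * v for k, v in w_ctx.items()},
        **noise_overrides,
    )


def null_effects(**noise_overrides) -> EffectSpec:
    """Fully null spec: no item, category, or context structure."""
    z_pc = {(p, c): 0.0 for p in Phase for c in CSType}
    z_p = {p: 0.0 for p in Phase}
    return EffectSpec(w_item=dict(z_pc), w_cat=dict(z_pc), w_ctx=z_p,
                      baseline_amplitude=0.0, **noise_overrides)


def compose_trial_patterns(
    design: PhaseDesign,
    bank: PatternBank,
    effects: EffectSpec,
    seed: int = 0,
) -> np.ndarray:
    """Ground-truth cue-event pattern matrix (trials × masked voxels).

    The valence component follows the phase's contingency semantics (e.g.
    CS-+ loads the safe pattern in acquisition but the threat pattern in
    reversal); reuse flags pick shared vs phase-specific component patterns.
    """
    rng = np.random.default_rng(seed)
    phase = design.phase
    item_key = "base" if effects.reuse_item.get(phase, True) else phase.value
    cat_key = "base" if effects.reuse_cat.get(phase, True) else phase.value
    T = len(design.trials)
    V = bank.n_voxels
    out = np.empty((T, V))
    for i, tr in enumerate(design.trials):
        pat = effects.baseline_amplitude * bank.baseline.copy()
        pat += effects.w_item[(phase, tr.cs_type)] * bank.item_pattern(tr.cue_id, item_key)
        val = tr.cs_type.current_valence(phase)
        pat += effects.w_cat[(phase, tr.cs_type)] * bank.valence_pattern(val, cat_key)
        pat += effects.w_ctx[phase] * bank.context[tr.context_id]
        if effects.trial_noise_sd > 0:
            pat = pat + rng.normal(0.0, effects.trial_noise_sd, size=V)
        out[i] = pat
    return out


def compose_context_patterns(
    design: PhaseDesign,
    bank: PatternBank,
    effects: EffectSpec,
    seed: int = 0,
) -> np.ndarray:
    """Ground-truth context-epoch pattern matrix (trials × masked voxels)."""
    rng = np.random.default_rng(seed)
    phase = design.phase
    T = len(design.trials)
    V = bank.n_voxels
    out = np.empty((T, V))
    for i, tr in enumerate(design.trials):
        pat = effects.baseline_amplitude * bank.baseline.copy()
        pat += effects.w_ctx[phase] * bank.context[tr.context_id]
        if effects.trial_noise_sd > 0:
            pat = pat + rng.normal(0.0, effects.trial_noise_sd, size=V)
        out[i] = pat
    return out


def simulate_confounds(n_scans: int, rng: np.random.Generator) -> pd.DataFrame:
    """Six random-walk motion parameters plus AR(1) WM and CSF mean signals."""
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(n_scans, 6)), axis=0)
    comp = np.empty((n_scans, 2))
    comp[0] = rng.normal(0.0, 1.0, size=2)
    for t in range(1, n_scans):
        comp[t] = 0.5 * comp[t - 1] + rng.normal(0.0, np.sqrt(1 - 0.25), size=2)
    return pd.DataFrame(np.column_stack([motion, comp]), columns=CONFOUND_COLUMNS)


@dataclass
class SyntheticDataset:
    """One phase of synthetic data: masked time series plus ground truth."""

    data: np.ndarray  # scans × masked voxels
    confounds: pd.DataFrame
    cue_patterns: np.ndarray  # trials × voxels, the planted cue-event patterns
    context_patterns: np.ndarray
    design: PhaseDesign
    effects: EffectSpec
    geometry: VolumeGeometry

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    def to_4d(self) -> np.ndarray:
        """Unmasked (x, y, z, t) array with zeros outside the mask."""
        out = np.zeros(self.geometry.shape + (self.n_scans,))
        out[self.geometry.mask] = self.data.T
        return out


def _ar1_noise(shape: tuple[int, int], rho: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """AR(1) noise with marginal standard deviation ``sd`` (scans × voxels)."""
    n, v = shape
    e = rng.standard_normal((n, v))
    if rho == 0.0 or sd == 0.0:
        return sd * e
    out = np.empty((n, v))
    out[0] = e[0]
    innov_sd = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + innov_sd * e[t]
    return sd * out


def synthesize_bold(
    design: PhaseDesign,
    cue_patterns: np.ndarray,
    context_patterns: np.ndarray,
    geometry: VolumeGeometry,
    effects: EffectSpec,
    seed: int,
    cue_duration: float = 1.0,
) -> SyntheticDataset:
    """Generate one phase's masked BOLD time series.

    Each voxel's series is the sum over trials of the HRF-convolved cue
    boxcar times the planted cue pattern, the analogous context-epoch
    response, confound series times per-voxel random loadings, a per-voxel
    linear drift, and AR(1) Gaussian noise. ``design`` must be scheduled.
    """
    if design.total_duration is None:
        raise ValueError("design has no onsets; call schedule_onsets first")
    rng = np.random.default_rng(seed)
    tr = geometry.tr
    n_scans = int(np.ceil(design.total_duration / tr))
    T = len(design.trials)
    V = geometry.n_voxels
    if cue_patterns.shape != (T, V) or context_patterns.shape != (T, V):
        raise ValueError("pattern matrices must be trials × masked voxels")

    R_cue = np.empty((n_scans, T))
    R_ctx = np.empty((n_scans, T))
    for i, trl in enumerate(design.trials):
        R_cue[:, i] = convolve_events([trl.onset_cue], [cue_duration], n_scans, tr)
        R_ctx[:, i] = convolve_events(
            [trl.onset_context], [trl.onset_cue - trl.onset_context], n_scans, tr
        )
    data = R_cue @ cue_patterns + R_ctx @ context_patterns

    confounds = simulate_confounds(n_scans, rng)
    loadings = np.vstack([
        rng.normal(0.0, effects.motion_loading_sd, size=(6, V)),
        rng.normal(0.0, effects.compartment_loading_sd, size=(2, V)),
    ])
    data += confounds.to_numpy() @ loadings

    if effects.drift_amplitude > 0:
        ramp = np.linspace(-0.5, 0.5, n_scans)[:, None]
        data += ramp * rng.uniform(-effects.drift_amplitude,
                                   effects.drift_amplitude, size=V)
    data += _ar1_noise((n_scans, V), effects.ar1_rho, effects.scan_noise_sd, rng)

    return SyntheticDataset(
        data=data, confounds=confounds, cue_patterns=cue_patterns,
        context_patterns=context_patterns, design=design, effects=effects,
        geometry=geometry,
    )
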