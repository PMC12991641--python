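"""End-to-end study orchestration, configuration, and file I/O.

A *study* is a simulated cohort run through the full analysis chain:

    design → ratings → synthetic BOLD → LSS beta series
           → searchlight metric maps → permutation cluster FWE
           → ROI extraction → reinstatement and linking mixed models

Volumetric artifacts are NIfTI-1 (nibabel), event and confound tables are
tab-separated, metric and result tables tidy CSV, configuration YAML. Every
stage is seeded from the config's base seed via a documented splitting rule,
so re-running a study with the same config reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from fearrsa import behavior as beh
from fearrsa import design as dsg
from fearrsa import inference as inf
from fearrsa import rsa as rsa_mod
from fearrsa import searchlight as sl
from fearrsa.design import CSType, Phase
from fearrsa.lss import BetaSeries, estimate_lss_betas
from fearrsa.synthetic_bold import (
    CONFOUND_COLUMNS,
    EffectSpec,
    SyntheticDataset,
    VolumeGeometry,
    compose_context_patterns,
    compose_trial_patterns,
    default_effects,
    default_geometry,
    make_pattern_bank,
    null_effects,
    synthesize_bold,
)

__all__ = [
    "StudyConfig",
    "RunManifest",
    "participant_seed",
    "simulate_participant",
    "lss_participant",
    "simulate_beta_participant",
    "simulate_linked_beta_participant",
    "standard_contrasts",
    "run_study",
    "write_map",
    "read_map",
    "write_beta_series",
    "read_beta_series",
]


# --------------------------------------------------------------------------
# configuration


@dataclass
class StudyConfig:
    """All study parameters; analysis defaults are the published constants."""

    # geometry
    grid_shape: tuple[int, int, int] = (18, 18, 12)
    voxel_size_mm: float = 2.5
    tr: float = 2.53
    # design
    n_trials_per_phase: int = 128
    reinforcement_rate: float = 0.5
    iti_bounds: tuple[float, float] = (7.0, 9.0)
    # planted effects
    effects_mode: str = "default"  # "default" | "null"
    item_scale: float = 1.0
    cat_scale: float = 1.0
    ctx_scale: float = 1.0
    trial_noise_sd: float = 0.3
    scan_noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.5
    motion_loading_sd: float = 0.2
    compartment_loading_sd: float = 0.2
    # cohort
    n_participants: int = 12
    base_seed: int = 0
    # analysis (published defaults)
    radius_mm: float = 5.0
    min_in_mask_frac: float = 0.5
    n_perm: int = 10_000
    cft_p: float = 0.001
    base_alpha: float = 0.05
    min_roi_volume_mm3: float = 1500.0
    connectivity: int = 26
    # io
    out_dir: str = "study_out"
    save_volumes: bool = False

    def validate(self) -> None:
        if self.effects_mode not in ("default", "null"):
            raise ValueError("effects_mode must be 'default' or 'null'")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not (0 < self.cft_p < 1 and 0 < self.base_alpha < 1):
            raise ValueError("cft_p and base_alpha must lie in (0, 1)")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.n_perm < 1 or self.min_roi_volume_mm3 < 0:
            raise ValueError("invalid analysis settings")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["iti_bounds"] = list(d["iti_bounds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "iti_bounds" in d:
            d["iti_bounds"] = tuple(d["iti_bounds"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        """Digest of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d.pop("save_volumes")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def geometry(self) -> VolumeGeometry:
        return default_geometry(self.grid_shape, self.voxel_size_mm, self.tr)

    def effects(self) -> EffectSpec:
        noise = dict(
            trial_noise_sd=self.trial_noise_sd,
            scan_noise_sd=self.scan_noise_sd,
            ar1_rho=self.ar1_rho,
            drift_amplitude=self.drift_amplitude,
            motion_loading_sd=self.motion_loading_sd,
            compartment_loading_sd=self.compartment_loading_sd,
        )
        if self.effects_mode == "null":
            return null_effects(**noise)
        return default_effects(self.item_scale, self.cat_scale, self.ctx_scale,
                               **noise)


def participant_seed(base_seed: int, participant_index: int, stream: int = 0) -> int:
    """Deterministic per-participant, per-stream seed below 2**31."""
    return (base_seed * 1_000_003 + participant_index * 10_007 + stream) % (2**31 - 1)


# --------------------------------------------------------------------------
# volumetric / tabular I/O


def write_map(arr: np.ndarray, geometry: VolumeGeometry, path) -> None:
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), geometry.affine())
    img.to_filename(str(path))


def read_map(path, geometry: VolumeGeometry | None = None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if geometry is not None:
        if data.shape[:3] != tuple(geometry.shape):
            raise ValueError(f"{path}: shape {data.shape[:3]} does not match "
                             f"configured grid {geometry.shape}")
        if not np.allclose(img.affine, geometry.affine(), atol=1e-4):
            raise ValueError(f"{path}: affine does not match configured geometry")
    return data


def write_beta_series(bs: BetaSeries, prefix) -> None:
    """Persist a beta series as 4D NIfTI (trial axis last) + TSV sidecar."""
    geom = bs.geometry
    vol = np.zeros(tuple(geom.shape) + (bs.betas.shape[0],), dtype=np.float32)
    vol[geom.mask] = bs.betas.T
    nib.Nifti1Image(vol, geom.affine()).to_filename(f"{prefix}.nii.gz")
    bs.metadata.to_csv(f"{prefix}.tsv", sep="\t", index=False)


def read_beta_series(prefix, geometry: VolumeGeometry, model_kind: str) -> BetaSeries:
    data = read_map(f"{prefix}.nii.gz", geometry)
    meta = pd.read_csv(f"{prefix}.tsv", sep="\t")
    betas = data[geometry.mask].T
    return BetaSeries(model_kind=model_kind, betas=betas, metadata=meta,
                      geometry=geometry)


def write_confounds(confounds: pd.DataFrame, path) -> None:
    confounds.to_csv(path, sep="\t", index=False)


def read_confounds(path, n_scans: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CONFOUND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing confound columns {missing}")
    if n_scans is not None and len(df) != n_scans:
        raise ValueError(f"{path}: {len(df)} rows but {n_scans} scans")
    return df


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class ParticipantData:
    """One participant's designs and per-phase synthetic datasets."""

    index: int
    spec: dsg.ExperimentSpec
    designs: dict[Phase, dsg.PhaseDesign]
    datasets: dict[Phase, SyntheticDataset]


def _spec_for(cfg: StudyConfig, participant: int) -> dsg.ExperimentSpec:
    spec = dsg.assign_counterbalancing(participant, seed=cfg.base_seed)
    return dataclasses.replace(
        spec,
        n_trials_per_phase=cfg.n_trials_per_phase,
        reinforcement_rate=cfg.reinforcement_rate,
        timing=dsg.Timing(iti_bounds=cfg.iti_bounds),
    )


def simulate_participant(cfg: StudyConfig, participant: int) -> ParticipantData:
    """Full BOLD simulation of one participant (all four phases)."""
    spec = _spec_for(cfg, participant)
    geom = cfg.geometry()
    effects = cfg.effects()
    bank = make_pattern_bank(
        geom, participant_seed(cfg.base_seed, participant, 1),
        cue_ids=spec.cue_ids,
        context_ids=tuple(spec.context_sets["A"] + spec.context_sets["B"]
                          + spec.context_sets["C"]),
    )
    designs: dict[Phase, dsg.PhaseDesign] = {}
    datasets: dict[Phase, SyntheticDataset] = {}
    for k, phase in enumerate(dsg.PHASE_ORDER):
        s = participant_seed(cfg.base_seed, participant, 10 + k)
        design = dsg.schedule_onsets(
            dsg.build_phase_design(spec, phase, seed=s), spec, seed=s + 1
        )
        cue_pat = compose_trial_patterns(design, bank, effects, seed=s + 2)
        ctx_pat = compose_context_patterns(design, bank, effects, seed=s + 3)
        datasets[phase] = synthesize_bold(design, cue_pat, ctx_pat, geom,
                                          effects, seed=s + 4)
        designs[phase] = design
    return ParticipantData(index=participant, spec=spec, designs=designs,
                           datasets=datasets)


def lss_participant(pdata: ParticipantData) -> dict[tuple[Phase, str], BetaSeries]:
    """Cue-model and context-model LSS beta series for every phase."""
    out = {}
    for phase, ds in pdata.datasets.items():
        for kind in ("cue", "context"):
            out[(phase, kind)] = estimate_lss_betas(
                ds.data, pdata.designs[phase], ds.confounds, ds.geometry, kind
            )
    return out


def simulate_beta_participant(
    cfg: StudyConfig,
    participant: int,
    beta_noise_sd: float = 1.0,
) -> dict[tuple[Phase, str], BetaSeries]:
    """Pattern-level shortcut: planted trial patterns plus estimation noise.

    Produces beta series directly from the ground-truth pattern generator
    with i.i.d. Gaussian noise standing in for GLM estimation error. The
    BOLD→LSS link itself is validated separately (exactly, against the
    normal-equations oracle), so repeated-cohort studies of the similarity
    metrics can skip it.
    """
    spec = _spec_for(cfg, participant)
    geom = cfg.geometry()
    effects = cfg.effects()
    bank = make_pattern_bank(
        geom, participant_seed(cfg.base_seed, participant, 1),
        cue_ids=spec.cue_ids,
        context_ids=tuple(spec.context_sets["A"] + spec.context_sets["B"]
                          + spec.context_sets["C"]),
    )
    out = {}
    for k, phase in enumerate(dsg.PHASE_ORDER):
        s = participant_seed(cfg.base_seed, participant, 10 + k)
        design = dsg.build_phase_design(spec, phase, seed=s)
        rng = np.random.default_rng(s + 5)
        meta = design.to_frame()[
            ["trial_index", "cue_id", "context_id", "cs_type", "reinforced", "phase"]
        ]
        for kind, composer, nseed in (
            ("cue", compose_trial_patterns, s + 2),
            ("context", compose_context_patterns, s + 3),
        ):
            pat = composer(design, bank, effects, seed=nseed)
            betas = pat + rng.normal(0.0, beta_noise_sd, size=pat.shape)
            out[(phase, kind)] = BetaSeries(kind, betas, meta.copy(), geom)
    return out


def simulate_linked_beta_participant(
    cfg: StudyConfig,
    participant: int,
    beta_noise_sd: float = 1.0,
    coupling: float = 0.6,
) -> dict[tuple[Phase, str], BetaSeries]:
    """Pattern-level cohort with a planted specificity–reinstatement link.

    Each participant gets a gain ``g = 1 + coupling * u`` (u ~ Uniform(-1, 1))
    that scales (a) the reversal context weight — so the reversal-minus-
    acquisition context-specificity difference varies across participants —
    and (b) the item weight of the newly threatening cue type (CS-+) in
    reversal and old-context test. Participants with more distinct reversal
    context coding therefore show stronger item reinstatement of the
    contingency-changed threat cues, while CS+- is uncoupled: the
    specificity × cue-type interaction of the linking model is planted.
    """
    rng = np.random.default_rng(participant_seed(cfg.base_seed, participant, 8))
    g = 1.0 + coupling * rng.uniform(-1.0, 1.0)
    base = cfg.effects()
    w_ctx = dict(base.w_ctx)
    w_ctx[Phase.REVERSAL] *= g
    w_item = dict(base.w_item)
    for ph in (Phase.REVERSAL, Phase.TEST_OLD):
        w_item[(ph, CSType.CS_MP)] *= g
    effects = dataclasses.replace(base, w_ctx=w_ctx, w_item=w_item)

    spec = _spec_for(cfg, participant)
    geom = cfg.geometry()
    bank = make_pattern_bank(
        geom, participant_seed(cfg.base_seed, participant, 1),
        cue_ids=spec.cue_ids,
        context_ids=tuple(spec.context_sets["A"] + spec.context_sets["B"]
                          + spec.context_sets["C"]),
    )
    out = {}
    for k, phase in enumerate(dsg.PHASE_ORDER):
        s = participant_seed(cfg.base_seed, participant, 10 + k)
        design = dsg.build_phase_design(spec, phase, seed=s)
        nrng = np.random.default_rng(s + 5)
        meta = design.to_frame()[
            ["trial_index", "cue_id", "context_id", "cs_type", "reinforced", "phase"]
        ]
        for kind, composer, nseed in (
            ("cue", compose_trial_patterns, s + 2),
            ("context", compose_context_patterns, s + 3),
        ):
            pat = composer(design, bank, effects, seed=nseed)
            betas = pat + nrng.normal(0.0, beta_noise_sd, size=pat.shape)
            out[(phase, kind)] = BetaSeries(kind, betas, meta.copy(), geom)
    return out


# --------------------------------------------------------------------------
# searchlight contrast catalog


@dataclass(frozen=True)
class ContrastSpec:
    """A group-level searchlight comparison and its alpha family."""

    name: str
    phase: Phase
    model_kind: str
    metric: str  # "generalization" | "stability" | "specificity_diff"
    groups_pos: frozenset[str] = frozenset()
    groups_neg: frozenset[str] = frozenset()
    family: str = "default"
    other_phase: Phase | None = None  # for specificity differences


def standard_contrasts() -> list[ContrastSpec]:
    """The study's searchlight comparisons, grouped into alpha families.

    Acquisition tests item stability and cue generalization for CS+ vs CS-
    (2 comparisons, alpha 0.025); reversal tests four CS-type comparisons
    (alpha 0.0125); context specificity compares reversal vs acquisition.
    """
    PP, PM, MP, MM = (c.value for c in
                      (CSType.CS_PP, CSType.CS_PM, CSType.CS_MP, CSType.CS_MM))
    A, R = Phase.ACQUISITION, Phase.REVERSAL
    return [
        ContrastSpec("acq_cue_generalization_csp_gt_csm", A, "cue",
                     "generalization", frozenset({PP, PM}), frozenset({MP, MM}),
                     "acquisition"),
        ContrastSpec("acq_item_stability_csp_gt_csm", A, "cue", "stability",
                     frozenset({PP, PM}), frozenset({MP, MM}), "acquisition"),
        ContrastSpec("rev_cue_generalization_cspp_gt_csmm", R, "cue",
                     "generalization", frozenset({PP}), frozenset({MM}),
                     "reversal"),
        ContrastSpec("rev_cue_generalization_threat_gt_safe", R, "cue",
                     "generalization", frozenset({PP, MP}), frozenset({PM, MM}),
                     "reversal"),
        ContrastSpec("rev_item_stability_change_gt_consistent", R, "cue",
                     "stability", frozenset({MP, PM}), frozenset({PP, MM}),
                     "reversal"),
        ContrastSpec("rev_item_stability_threat_gt_safe", R, "cue", "stability",
                     frozenset({PP, MP}), frozenset({PM, MM}), "reversal"),
        ContrastSpec("ctx_specificity_reversal_gt_acquisition", R, "context",
                     "specificity_diff", family="context", other_phase=A),
    ]


def participant_contrast_map(
    series: dict[tuple[Phase, str], BetaSeries],
    neighborhoods: sl.NeighborhoodSet,
    cspec: ContrastSpec,
) -> np.ndarray:
    """Evaluate one searchlight contrast for one participant."""
    bs = series[(cspec.phase, cspec.model_kind)].unreinforced()
    if cspec.metric == "generalization":
        metric = sl.generalization_contrast(
            bs, set(cspec.groups_pos), set(cspec.groups_neg) or None,
            restrict_unreinforced=False, name=cspec.name)
        return sl.run_searchlight(bs, neighborhoods, metric)
    if cspec.metric == "stability":
        metric = sl.stability_contrast(
            bs, set(cspec.groups_pos), set(cspec.groups_neg) or None,
            restrict_unreinforced=False, name=cspec.name)
        return sl.run_searchlight(bs, neighborhoods, metric)
    if cspec.metric == "specificity_diff":
        m1 = sl.run_searchlight(
            bs, neighborhoods, sl.specificity_metric(bs, False))
        bs0 = series[(cspec.other_phase, cspec.model_kind)].unreinforced()
        m0 = sl.run_searchlight(
            bs0, neighborhoods, sl.specificity_metric(bs0, False))
        return m1 - m0
    raise ValueError(f"unknown metric {cspec.metric!r}")


# --------------------------------------------------------------------------
# full study


@dataclass
class RunManifest:
    """Provenance of a study run."""

    config_hash: str
    base_seed: int
    software_version: str
    started: str
    finished: str = ""
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def add(self, path: Path) -> None:
        self.artifacts[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _checksum_add(manifest: RunManifest, path: Path) -> None:
    manifest.add(path)


def run_study(cfg: StudyConfig, use_full_bold: bool = True,
              beta_noise_sd: float = 1.0) -> RunManifest:
    """Run the complete simulated study and write all outputs.

    With ``use_full_bold`` the cohort goes through BOLD synthesis and LSS
    estimation; otherwise the pattern-level shortcut
    (:func:`simulate_beta_participant`) is used. Outputs under
    ``cfg.out_dir``: behavioral tables and tests, searchlight group maps,
    cluster/ROI tables, reinstatement metrics, linking-model results, a
    ground-truth recovery report, and the run manifest.
    """
    from fearrsa import __version__

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=cfg.hash(), base_seed=cfg.base_seed,
        software_version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    cfg.to_yaml(out / "config.yaml")
    geom = cfg.geometry()
    effects = cfg.effects()

    # ---- stage 1: cohort simulation (+ optional LSS) --------------------
    cohort: list[dict[tuple[Phase, str], BetaSeries]] = []
    designs_per_participant = []
    for i in range(cfg.n_participants):
        if use_full_bold:
            pdata = simulate_participant(cfg, i)
            designs_per_participant.append(pdata.designs)
            if cfg.save_volumes:
                pdir = out / "volumes" / f"sub-{i:03d}"
                pdir.mkdir(parents=True, exist_ok=True)
                for phase, ds in pdata.datasets.items():
                    write_map(ds.to_4d(), geom, pdir / f"{phase.value}_bold.nii.gz")
                    write_confounds(ds.confounds,
                                    pdir / f"{phase.value}_confounds.tsv")
                    dsg.write_events_tsv(pdata.designs[phase], pdata.spec,
                                         pdir / f"{phase.value}_events.tsv")
            cohort.append(lss_participant(pdata))
        else:
            cohort.append(simulate_beta_participant(cfg, i, beta_noise_sd))
            spec_i = _spec_for(cfg, i)
            designs_per_participant.append({
                ph: dsg.build_phase_design(
                    spec_i, ph, seed=participant_seed(cfg.base_seed, i, 10 + k))
                for k, ph in enumerate(dsg.PHASE_ORDER)
            })

    # ---- stage 2: behavior ----------------------------------------------
    params = beh.BehaviorModelParams(seed=participant_seed(cfg.base_seed, 0, 90))
    # ratings simulated per participant on their own designs
    rating_frames = []
    for i, designs in enumerate(designs_per_participant):
        p = dataclasses.replace(params,
                                seed=participant_seed(cfg.base_seed, i, 91))
        df = beh.simulate_expectancy(designs, p, 1)
        df["participant_id"] = f"sub-{i:03d}"
        rating_frames.append(df)
    ratings = pd.concat(rating_frames, ignore_index=True)
    ratings.to_csv(out / "ratings.tsv", sep="\t", index=False)
    summary = beh.summarize_expectancy(ratings)
    summary.to_csv(out / "ratings_summary.csv", index=False)
    bres = beh.analyze_expectancy(summary)
    pd.DataFrame(
        [{"term": t.term, "F": t.fstat, "df_num": t.df_num, "df_den": t.df_den,
          "p": t.pvalue} for t in bres.fixed_effects]
    ).to_csv(out / "behavior_fixed_effects.csv", index=False)
    bres.posthoc.to_csv(out / "behavior_posthoc.csv", index=False)

    # ---- stage 3: searchlight maps --------------------------------------
    neighborhoods = sl.build_neighborhoods(geom, cfg.radius_mm,
                                           cfg.min_in_mask_frac)
    contrasts = standard_contrasts()
    maps: dict[str, np.ndarray] = {}
    mapdir = out / "maps"
    mapdir.mkdir(exist_ok=True)
    for cspec in contrasts:
        stack = np.stack([
            participant_contrast_map(series, neighborhoods, cspec)
            for series in cohort
        ])
        maps[cspec.name] = stack
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gmean = np.nanmean(stack, axis=0)
        write_map(gmean, geom, mapdir / f"{cspec.name}_groupmean.nii.gz")

    # ---- stage 4: cluster FWE -------------------------------------------
    family_sizes: dict[str, int] = {}
    for c in contrasts:
        family_sizes[c.family] = family_sizes.get(c.family, 0) + 1
    cluster_rows = []
    sig_maps: dict[str, np.ndarray] = {}
    group_maps: dict[str, inf.GroupStatMap] = {}
    for cspec in contrasts:
        alpha = inf.bonferroni_alpha(cfg.base_alpha, family_sizes[cspec.family])
        gmap, cset = inf.cluster_fwe(
            maps[cspec.name], n_perm=cfg.n_perm, cft_p=cfg.cft_p, alpha=alpha,
            connectivity=cfg.connectivity,
            seed=participant_seed(cfg.base_seed, 0, 70),
            voxel_volume_mm3=geom.voxel_volume_mm3, contrast=cspec.name,
        )
        group_maps[cspec.name] = gmap
        write_map(gmap.tmap, geom, mapdir / f"{cspec.name}_tmap.nii.gz")
        t = cset.table()
        t["contrast"] = cspec.name
        t["alpha"] = alpha
        cluster_rows.append(t)
        sig = np.zeros(geom.shape, dtype=bool)
        for c in cset.significant():
            sig[tuple(c.voxels.T)] = True
        sig_maps[cspec.name] = sig
    clusters = (pd.concat(cluster_rows, ignore_index=True) if cluster_rows
                else pd.DataFrame())
    clusters.to_csv(out / "clusters.csv", index=False)

    # ---- stage 5: ROIs and reinstatement --------------------------------
    roiset = inf.extract_rois(sig_maps, geom, cfg.min_roi_volume_mm3,
                              cfg.connectivity)
    pd.DataFrame(
        [{"roi": n, "source": roiset.provenance[n], "n_voxels": int(m.sum()),
          "volume_mm3": float(m.sum() * geom.voxel_volume_mm3)}
         for n, m in roiset.rois.items()]
    ).to_csv(out / "rois.csv", index=False)

    roi_masks = dict(roiset.rois)
    roi_masks["whole_mask"] = geom.mask.copy()

    reinst_rows = []
    for roi_name, roi_mask in roi_masks.items():
        cols = np.flatnonzero(roi_mask[geom.mask])
        for src in (Phase.ACQUISITION, Phase.REVERSAL, Phase.TEST_NEW):
            for i, series in enumerate(cohort):
                a = series[(src, "cue")].unreinforced().restrict_voxels(cols)
                b = series[(Phase.TEST_OLD, "cue")].unreinforced()\
                    .restrict_voxels(cols)
                rsm = rsa_mod.build_rsm(a, b)
                for mode in ("item", "generalized"):
                    df = rsa_mod.reinstatement(
                        rsm, mode, restrict_unreinforced=False,
                        participant=f"sub-{i:03d}", region=roi_name)
                    df["source_phase"] = src.value
                    reinst_rows.append(df)
    reinst = pd.concat(reinst_rows, ignore_index=True)
    reinst.to_csv(out / "reinstatement.csv", index=False)

    lme_rows = []
    for roi_name in roi_masks:
        for mode in ("item", "generalized"):
            tab = reinst[(reinst.region == roi_name)
                         & (reinst.metric == f"{mode}_reinstatement")]
            tab = tab.rename(columns={"condition": "cs_type"})
            try:
                res = inf.roi_phase_lme(tab, ["source_phase", "cs_type"],
                                        family=f"{roi_name}/{mode}")
            except ValueError:
                continue
            t = res.table.copy()
            t["roi"] = roi_name
            t["mode"] = mode
            lme_rows.append(t)
    if lme_rows:
        pd.concat(lme_rows, ignore_index=True).to_csv(
            out / "reinstatement_lme.csv", index=False)

    # ---- stage 6: context specificity linking ---------------------------
    spec_roi = next(
        (n for n in roiset.rois
         if roiset.provenance[n] == "ctx_specificity_reversal_gt_acquisition"),
        None,
    )
    spec_mask = roiset.rois[spec_roi] if spec_roi else geom.mask
    cols = np.flatnonzero(spec_mask[geom.mask])
    spec_vals = []
    for i, series in enumerate(cohort):
        diffs = {}
        for ph in (Phase.ACQUISITION, Phase.REVERSAL):
            bs = series[(ph, "context")].unreinforced().restrict_voxels(cols)
            rsm = rsa_mod.build_rsm(bs)
            diffs[ph] = rsa_mod.context_specificity(
                rsm, restrict_unreinforced=False)["value"].iloc[0]
        spec_vals.append({"participant": f"sub-{i:03d}",
                          "specificity": diffs[Phase.REVERSAL]
                          - diffs[Phase.ACQUISITION]})
    spec_df = pd.DataFrame(spec_vals)
    spec_df.to_csv(out / "context_specificity.csv", index=False)

    link_rows = []
    changing = [CSType.CS_MP.value, CSType.CS_PM.value]
    for roi_name in roi_masks:
        for mode, src in (("generalized", Phase.ACQUISITION),
                          ("item", Phase.REVERSAL)):
            tab = reinst[(reinst.region == roi_name)
                         & (reinst.metric == f"{mode}_reinstatement")
                         & (reinst.source_phase == src.value)
                         & (reinst.condition.isin(changing))]
            merged = tab.rename(columns={"condition": "cs_type",
                                         "value": "reinstatement"}).merge(
                spec_df, on="participant")
            try:
                res = inf.specificity_reinstatement_lme(merged, mode)
            except ValueError:
                continue
            t = res.table.copy()
            t["roi"] = roi_name
            t["mode"] = mode
            t["source_phase"] = src.value
            link_rows.append(t)
    if link_rows:
        pd.concat(link_rows, ignore_index=True).to_csv(
            out / "specificity_linkage.csv", index=False)

    # ---- stage 7: ground-truth recovery report --------------------------
    report = {
        "effects_mode": cfg.effects_mode,
        "n_participants": cfg.n_participants,
        "group_mean_contrast": {
            name: float(np.nanmean(stack)) for name, stack in maps.items()
        },
        "significant_clusters": {
            name: int(sig.sum() > 0) for name, sig in sig_maps.items()
        },
        "n_rois": len(roiset.rois),
        "behavior_terms": {t.term: t.pvalue for t in bres.fixed_effects},
    }
    (out / "recovery_report.json").write_text(json.dumps(report, indent=2))

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            _checksum_add(manifest, f)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    return manifest
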