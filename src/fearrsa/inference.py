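"""Second-level inference: permutation cluster-FWE, ROIs, and linking models.

Group inference on participant searchlight maps is nonparametric: a
one-sample t map of the per-participant contrast values is thresholded at
the voxelwise level corresponding to the cluster-forming p (one-sided,
p < 0.001 by default), and the family-wise-error-corrected p of each
suprathreshold cluster is its size's rank in the permutation null
distribution of the *maximum* cluster size, built by randomly sign-flipping
whole participant maps (valid because per-participant contrasts are
exchangeable in sign under the null). The alpha against which cluster p
values are judged is Bonferroni-divided by the number of comparisons in the
phase's family (e.g. 0.05/2 = 0.025 when item stability and cue
generalization are both tested).

Surviving clusters become ROIs (connected components, minimum volume
1500 mm³; overlapping ROIs from different source maps resolved by keeping
the larger). ROI metric tables feed random-intercept mixed models
(Satterthwaite df) with FDR (Benjamini–Hochberg) correction across the
declared family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from fearrsa.lmm import (
    CoefTest,
    LMMResult,
    TermTest,
    anova_lmm,
    build_factorial_design,
    fit_random_intercept,
)
from fearrsa.synthetic_bold import VolumeGeometry

__all__ = [
    "GroupStatMap",
    "Cluster",
    "ClusterSet",
    "ROISet",
    "LinkageResult",
    "cluster_fwe",
    "bonferroni_alpha",
    "fdr_bh",
    "extract_rois",
    "roi_phase_lme",
    "specificity_reinstatement_lme",
]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


@dataclass
class GroupStatMap:
    """One-sample group t map over participant contrast maps."""

    tmap: np.ndarray
    defined: np.ndarray  # voxels where all participants have finite values
    n_participants: int
    contrast: str


@dataclass
class Cluster:
    label: int
    voxels: np.ndarray  # (k, 3) grid coordinates
    size: int
    volume_mm3: float
    peak_value: float
    p_fwe: float
    significant: bool


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    label_image: np.ndarray
    cluster_forming_p: float
    n_permutations: int
    alpha: float
    null_max_sizes: np.ndarray

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"label": c.label, "n_voxels": c.size, "volume_mm3": c.volume_mm3,
                 "peak": c.peak_value, "p_fwe": c.p_fwe,
                 "significant": c.significant}
                for c in self.clusters
            ]
        )


def bonferroni_alpha(base_alpha: float = 0.05, n_comparisons: int = 1) -> float:
    """Bonferroni-adjusted alpha: base_alpha / n_comparisons."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be ≥ 1")
    return base_alpha / n_comparisons


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p values."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float), method="bh")


def _tmap(stack: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0; 0/0 voxels become NaN."""
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = np.nan
    return t


def _max_cluster_size(supra: np.ndarray, struct: np.ndarray) -> int:
    lab, n = ndimage.label(supra, structure=struct)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def cluster_fwe(
    participant_maps: list[np.ndarray] | np.ndarray,
    n_perm: int = 10_000,
    cft_p: float = 0.001,
    alpha: float = 0.05,
    connectivity: int = 26,
    seed: int = 0,
    voxel_volume_mm3: float = 2.5**3,
    contrast: str = "contrast",
) -> tuple[GroupStatMap, ClusterSet]:
    """Cluster-level FWE by sign-flipping permutation (one-sided).

    ``participant_maps`` are voxel-aligned 3-D contrast maps (NaN where
    undefined). Degenerate voxels (zero across-participant variance) are
    excluded from the analysis rather than crashing the t map. p_fwe uses
    the +1-corrected rank, so it is never exactly zero.
    """
    import warnings as _w

    stack = np.asarray(participant_maps, dtype=float)
    if stack.ndim != 4 or stack.shape[0] < 2:
        raise ValueError("need ≥ 2 voxel-aligned participant maps")
    if n_perm < 100:
        _w.warn("n_perm < 100 gives a very coarse null", stacklevel=2)
    n = stack.shape[0]
    defined = np.isfinite(stack).all(axis=0)
    degenerate = defined & (stack.std(axis=0, ddof=1) == 0)
    if degenerate.any():
        _w.warn(f"{int(degenerate.sum())} zero-variance voxel(s) excluded",
                stacklevel=2)
        defined &= ~degenerate
    struct = _structure(connectivity)
    t_thresh = stats.t.ppf(1 - cft_p, df=n - 1)

    work = np.where(defined, stack, 0.0)
    tobs = _tmap(np.where(np.isfinite(stack), stack, 0.0))
    tobs[~defined] = np.nan
    supra = defined & (np.nan_to_num(tobs, nan=-np.inf) > t_thresh)
    lab, n_clus = ndimage.label(supra, structure=struct)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    flat = work[:, defined]  # participants × defined voxels
    grid = np.zeros_like(defined, dtype=bool)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        tp = _tmap(signs[:, None] * flat)
        grid[:] = False
        grid[defined] = tp > t_thresh
        null_max[p] = _max_cluster_size(grid, struct)

    clusters = []
    for lbl in range(1, n_clus + 1):
        vox = np.argwhere(lab == lbl)
        size = len(vox)
        p_fwe = (1 + int((null_max >= size).sum())) / (1 + n_perm)
        clusters.append(
            Cluster(
                label=lbl, voxels=vox, size=size,
                volume_mm3=size * voxel_volume_mm3,
                peak_value=float(np.nanmax(tobs[lab == lbl])),
                p_fwe=p_fwe, significant=p_fwe < alpha,
            )
        )
    gmap = GroupStatMap(tmap=tobs, defined=defined, n_participants=n,
                        contrast=contrast)
    cset = ClusterSet(clusters=clusters, label_image=lab, cluster_forming_p=cft_p,
                      n_permutations=n_perm, alpha=alpha, null_max_sizes=null_max)
    return gmap, cset


@dataclass
class ROISet:
    """Named, volume-filtered, overlap-resolved regions of interest."""

    rois: dict[str, np.ndarray] = field(default_factory=dict)  # name -> bool mask
    provenance: dict[str, str] = field(default_factory=dict)
    overlap_log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rois)


def extract_rois(
    thresholded_maps: dict[str, np.ndarray],
    geometry: VolumeGeometry,
    min_volume_mm3: float = 1500.0,
    connectivity: int = 26,
) -> ROISet:
    """Connected-component ROIs from boolean suprathreshold maps.

    Components smaller than ``min_volume_mm3`` are discarded. When ROIs from
    different source maps overlap, only the larger (by voxel count) is
    retained; each application of the rule is logged. An empty suprathreshold
    set yields an empty ROISet.
    """
    struct = _structure(connectivity)
    vv = geometry.voxel_volume_mm3
    candidates: list[tuple[str, str, np.ndarray]] = []
    for source, bmap in thresholded_maps.items():
        if bmap.shape != geometry.shape or bmap.dtype != bool:
            raise ValueError("thresholded maps must be boolean on the grid")
        lab, n = ndimage.label(bmap, structure=struct)
        for lbl in range(1, n + 1):
            m = lab == lbl
            if m.sum() * vv >= min_volume_mm3:
                candidates.append((source, f"{source}_roi{lbl:02d}", m))

    candidates.sort(key=lambda c: int(c[2].sum()), reverse=True)
    out = ROISet()
    for source, name, m in candidates:
        clash = None
        for kept_name, kept_mask in out.rois.items():
            if (m & kept_mask).any():
                clash = kept_name
                break
        if clash is not None:
            out.overlap_log.append(
                f"{name} ({int(m.sum())} vox) overlaps {clash} "
                f"({int(out.rois[clash].sum())} vox); larger kept"
            )
            continue
        out.rois[name] = m
        out.provenance[name] = source
    return out


@dataclass
class LinkageResult:
    """Mixed-model terms/coefficients with FDR-adjusted p values."""

    terms: list[TermTest]
    coefs: list[CoefTest]
    table: pd.DataFrame
    model: LMMResult
    descriptor: str
    singular: bool


def _terms_table(terms: list[TermTest], family: str) -> pd.DataFrame:
    df = pd.DataFrame(
        [{"term": t.term, "statistic": t.fstat, "df_num": t.df_num,
          "df_den": t.df_den, "p_raw": t.pvalue} for t in terms]
    )
    df["p_fdr"] = fdr_bh(df["p_raw"].to_numpy())
    df["family"] = family
    return df


def roi_phase_lme(
    metric_table: pd.DataFrame,
    factors: list[str],
    response: str = "value",
    group: str = "participant",
    interactions: bool = True,
    family: str = "roi",
) -> LinkageResult:
    """Factorial random-intercept LME on an ROI metric table.

    ``metric_table`` holds one row per participant × condition cell (e.g.
    phase-pair × CS type reinstatement values from one ROI). F tests use
    Satterthwaite df; p values are FDR-adjusted within the declared family.
    """
    if metric_table[group].nunique() < 2:
        raise ValueError("need ≥ 2 participants")
    if metric_table[response].std(ddof=0) == 0:
        raise ValueError("metric values are constant; no variance to model")
    model, terms = anova_lmm(metric_table, response, factors, group,
                             interactions=interactions)
    table = _terms_table(terms, family)
    return LinkageResult(terms=terms, coefs=model.coef_tests(), table=table,
                         model=model,
                         descriptor=f"{response} ~ {' * '.join(factors)} + (1|{group})",
                         singular=model.singular)


def specificity_reinstatement_lme(
    data: pd.DataFrame,
    mode: str,
    specificity_col: str = "specificity",
    reinstatement_col: str = "reinstatement",
    cs_type_col: str = "cs_type",
    group: str = "participant",
    family: str | None = None,
) -> LinkageResult:
    """Does reversal context specificity predict reinstatement, per cue type?

    Model: reinstatement ~ specificity * cs_type + (1 | participant), on the
    contingency-changing cue types (CS-+, CS+-). Reports the interaction F
    test and the per-cue-type simple slopes of specificity.
    """
    if mode not in ("item", "generalized"):
        raise ValueError("mode must be 'item' or 'generalized'")
    levels = sorted(data[cs_type_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 cue types, got {levels}")
    if data[group].nunique() < 2:
        raise ValueError("need ≥ 2 participants")
    X, names, term_cols = build_factorial_design(
        data, [cs_type_col], interactions=True, covariates=[specificity_col]
    )
    model = fit_random_intercept(
        data[reinstatement_col].to_numpy(dtype=float), X,
        data[group].to_numpy(), names,
    )
    terms = []
    for term, idx in term_cols.items():
        if term == "Intercept":
            continue
        L = np.zeros((len(idx), X.shape[1]))
        for r, c in enumerate(idx):
            L[r, c] = 1.0
        terms.append(model.term_ftest(L, term))
    # simple slopes: d reinstatement / d specificity at each cue-type level
    i_spec = names.index(specificity_col)
    i_int = names.index(f"{cs_type_col}[{levels[0]}]:{specificity_col}")
    slopes = []
    for lev, s in ((levels[0], 1.0), (levels[1], -1.0)):
        ell = np.zeros(X.shape[1])
        ell[i_spec] = 1.0
        ell[i_int] = s  # sum coding: level0 -> +1, level1 -> -1
        slopes.append(model.contrast_ttest(ell, f"slope[{lev}]"))
    table = _terms_table(terms, family or f"{mode}_reinstatement")
    return LinkageResult(
        terms=terms, coefs=model.coef_tests() + slopes, table=table, model=model,
        descriptor=(f"{reinstatement_col} ~ {specificity_col} * {cs_type_col} "
                    f"+ (1|{group}) [{mode}]"),
        singular=model.singular,
    )
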