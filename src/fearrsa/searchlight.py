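"""Searchlight mapping of pattern-similarity metrics.

A cubic ("square") neighborhood of half-width ``round(radius / voxel size)``
voxels — 5 mm radius at 2.5 mm voxels gives a 5×5×5 box of 125 voxels — is
placed at every in-mask center. A center is retained only if at least half
of its full ideal box (out-of-bounds positions counted as out-of-mask) lies
inside the analysis mask. At each retained center, trial patterns are
restricted to the in-mask member voxels, the local Fisher-z similarity
matrix is formed, and the metric (a weighted sum of pair-mask means, e.g.
"CS+ generalization − CS- generalization") is written to the map.

Evaluation is batched: centers are processed in chunks with padded member
index arrays, so per-center work is a batched matrix product rather than a
Python loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fearrsa.lss import BetaSeries
from fearrsa.synthetic_bold import VolumeGeometry

__all__ = [
    "NeighborhoodSet",
    "SearchlightMetric",
    "build_neighborhoods",
    "run_searchlight",
    "generalization_contrast",
    "stability_contrast",
    "specificity_metric",
    "reinstatement_metric",
]

_Z_CLIP = 1.0 - 1e-12


@dataclass
class NeighborhoodSet:
    """Retained searchlight centers and their member voxels.

    ``members``/``valid`` are padded (n_centers × box) arrays of masked-voxel
    column indices (−1 where padded) and validity flags; ``center_coords``
    holds the (i, j, k) grid position of each retained center.
    """

    center_coords: np.ndarray
    center_mask_index: np.ndarray
    members: np.ndarray
    valid: np.ndarray
    radius_mm: float
    min_in_mask_frac: float
    geometry: VolumeGeometry

    @property
    def n_centers(self) -> int:
        return len(self.center_coords)

    def member_indices(self, i: int) -> np.ndarray:
        """In-mask member columns of retained center ``i`` (unpadded)."""
        return self.members[i][self.valid[i]]


def build_neighborhoods(
    geometry: VolumeGeometry,
    radius_mm: float = 5.0,
    min_in_mask_frac: float = 0.5,
) -> NeighborhoodSet:
    """Cubic neighborhoods with the in-mask inclusion rule.

    The fraction's denominator is the full ideal box (2h+1)³, so a corner
    voxel whose box mostly leaves the volume is dropped like one whose box
    leaves the mask.
    """
    if radius_mm < geometry.voxel_size_mm:
        raise ValueError("radius must be at least one voxel")
    h = int(round(radius_mm / geometry.voxel_size_mm))
    offs = np.array(
        [(dx, dy, dz)
         for dx in range(-h, h + 1)
         for dy in range(-h, h + 1)
         for dz in range(-h, h + 1)]
    )
    box = len(offs)  # (2h+1)^3
    mask = geometry.mask
    shape = np.array(geometry.shape)
    # map grid position -> masked column index
    col_of = -np.ones(geometry.shape, dtype=np.int64)
    col_of[mask] = np.arange(mask.sum())

    centers = np.argwhere(mask)
    pos = centers[:, None, :] + offs[None, :, :]  # (N, box, 3)
    in_bounds = ((pos >= 0) & (pos < shape)).all(axis=2)
    posc = np.clip(pos, 0, shape - 1)
    cols = col_of[posc[..., 0], posc[..., 1], posc[..., 2]]
    valid = in_bounds & (cols >= 0)
    frac = valid.sum(axis=1) / box
    keep = frac >= min_in_mask_frac
    if not keep.any():
        raise ValueError("no centers satisfy the in-mask fraction rule")
    members = np.where(valid, cols, -1)[keep]
    return NeighborhoodSet(
        center_coords=centers[keep],
        center_mask_index=np.flatnonzero(keep),
        members=members,
        valid=valid[keep],
        radius_mm=radius_mm,
        min_in_mask_frac=min_in_mask_frac,
        geometry=geometry,
    )


@dataclass
class SearchlightMetric:
    """A metric as a weighted sum of pair-mask means over the local RSM."""

    name: str
    terms: list[tuple[float, np.ndarray]]  # (weight, Ta × Tb boolean mask)

    def __post_init__(self) -> None:
        for _, m in self.terms:
            if not m.any():
                raise ValueError(f"metric {self.name!r} has an empty pair mask")


def _meta_arrays(meta: pd.DataFrame):
    return (meta["cue_id"].to_numpy(), meta["cs_type"].to_numpy(),
            meta["context_id"].to_numpy(), meta["reinforced"].to_numpy() == 0)


def _restrict(mask, unre_a, unre_b, restrict):
    if restrict:
        mask = mask & unre_a[:, None] & unre_b[None, :]
    return mask


def generalization_contrast(
    series: BetaSeries,
    groups_pos: set[str],
    groups_neg: set[str] | None = None,
    restrict_unreinforced: bool = True,
    name: str = "cue_generalization_contrast",
) -> SearchlightMetric:
    """Mean different-item similarity within a category, optionally contrasted."""
    cue, typ, _, unre = _meta_arrays(series.metadata)
    terms = []
    for w, grp in ((1.0, groups_pos), (-1.0, groups_neg)):
        if grp is None:
            continue
        in_g = np.isin(typ, list(grp))
        m = in_g[:, None] & in_g[None, :] & (cue[:, None] != cue[None, :])
        m = _restrict(m, unre, unre, restrict_unreinforced)
        np.fill_diagonal(m, False)
        terms.append((w, m))
    return SearchlightMetric(name, terms)


def stability_contrast(
    series: BetaSeries,
    groups_pos: set[str],
    groups_neg: set[str] | None = None,
    restrict_unreinforced: bool = True,
    name: str = "item_stability_contrast",
) -> SearchlightMetric:
    """Mean same-item similarity of a cue group, optionally contrasted."""
    cue, typ, _, unre = _meta_arrays(series.metadata)
    terms = []
    for w, grp in ((1.0, groups_pos), (-1.0, groups_neg)):
        if grp is None:
            continue
        in_g = np.isin(typ, list(grp))
        m = in_g[:, None] & in_g[None, :] & (cue[:, None] == cue[None, :])
        m = _restrict(m, unre, unre, restrict_unreinforced)
        np.fill_diagonal(m, False)
        terms.append((w, m))
    return SearchlightMetric(name, terms)


def specificity_metric(
    series: BetaSeries,
    restrict_unreinforced: bool = True,
    name: str = "context_specificity",
) -> SearchlightMetric:
    """Within-context minus between-context mean similarity."""
    _, _, ctx, unre = _meta_arrays(series.metadata)
    same = ctx[:, None] == ctx[None, :]
    w_in = _restrict(same.copy(), unre, unre, restrict_unreinforced)
    np.fill_diagonal(w_in, False)
    w_bt = _restrict(~same, unre, unre, restrict_unreinforced)
    np.fill_diagonal(w_bt, False)
    return SearchlightMetric(name, [(1.0, w_in), (-1.0, w_bt)])


def reinstatement_metric(
    series_a: BetaSeries,
    series_b: BetaSeries,
    mode: str,
    cs_types: set[str] | None = None,
    restrict_unreinforced: bool = True,
    name: str | None = None,
) -> SearchlightMetric:
    """Cross-phase item or generalized reinstatement (optionally per CS type)."""
    if mode not in ("item", "generalized"):
        raise ValueError("mode must be 'item' or 'generalized'")
    cue_a, typ_a, _, unre_a = _meta_arrays(series_a.metadata)
    cue_b, typ_b, _, unre_b = _meta_arrays(series_b.metadata)
    same_type = typ_a[:, None] == typ_b[None, :]
    same_cue = cue_a[:, None] == cue_b[None, :]
    m = same_cue if mode == "item" else (same_type & ~same_cue)
    if cs_types is not None:
        m = m & np.isin(typ_a, list(cs_types))[:, None]
    m = _restrict(m, unre_a, unre_b, restrict_unreinforced)
    return SearchlightMetric(name or f"{mode}_reinstatement", [(1.0, m)])


def run_searchlight(
    series_a: BetaSeries,
    neighborhoods: NeighborhoodSet,
    metric: SearchlightMetric,
    series_b: BetaSeries | None = None,
    chunk_size: int = 128,
) -> np.ndarray:
    """Evaluate a metric at every retained center; NaN elsewhere.

    Returns a 3-D map on the geometry grid. A center where the metric is
    undefined (e.g. all selected pairs involve zero-variance local patterns)
    is NaN, not fatal.
    """
    geom = neighborhoods.geometry
    Xa = series_a.betas
    Xb = series_a.betas if series_b is None else series_b.betas
    within = series_b is None
    Ta, Tb = Xa.shape[0], Xb.shape[0]
    for _, m in metric.terms:
        if m.shape != (Ta, Tb):
            raise ValueError("metric masks must match the series trial counts")
    out = np.full(geom.shape, np.nan)
    coords = neighborhoods.center_coords
    vals = np.empty(neighborhoods.n_centers)

    masks = [(w, m) for w, m in metric.terms]
    for start in range(0, neighborhoods.n_centers, chunk_size):
        sl = slice(start, min(start + chunk_size, neighborhoods.n_centers))
        mem = neighborhoods.members[sl]
        val = neighborhoods.valid[sl]
        C, K = mem.shape
        w = val.astype(float)
        idx = np.where(val, mem, 0)
        A = Xa[:, idx.ravel()].reshape(Ta, C, K).transpose(1, 0, 2)
        B = A if within else Xb[:, idx.ravel()].reshape(Tb, C, K).transpose(1, 0, 2)
        nvox = w.sum(axis=1)[:, None]
        wa = w[:, None, :]
        Am = (A * wa).sum(axis=2) / nvox
        Ac = (A - Am[:, :, None]) * wa
        if within:
            Bc = Ac
        else:
            Bm = (B * wa).sum(axis=2) / nvox
            Bc = (B - Bm[:, :, None]) * wa
        G = Ac @ Bc.transpose(0, 2, 1)
        na = np.sqrt((Ac**2).sum(axis=2))
        nb = na if within else np.sqrt((Bc**2).sum(axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = G / (na[:, :, None] * nb[:, None, :])
        r = np.clip(r, -_Z_CLIP, _Z_CLIP)
        z = np.arctanh(r)
        v = np.zeros(C)
        undef = np.zeros(C, dtype=bool)
        for wgt, m in masks:
            zm = np.where(m[None, :, :], z, np.nan)
            finite = np.isfinite(zm)
            cnt = finite.reshape(C, -1).sum(axis=1)
            tot = np.where(finite, zm, 0.0).reshape(C, -1).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                term = tot / cnt
            undef |= cnt == 0
            v = v + wgt * np.where(cnt > 0, term, 0.0)
        v[undef] = np.nan
        vals[sl] = v

    out[coords[:, 0], coords[:, 1], coords[:, 2]] = vals
    return out
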