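"""Fisher-z representational similarity matrices and the masked metrics.

Every metric in the package is the mean of RSM entries selected by a boolean
pair mask:

* **item stability** — pairs of different presentations of the same item;
* **cue generalization** — pairs of different items sharing a CS type (or a
  coarser category such as CS+ = {CS++, CS+-} during acquisition);
* **context stability / generalization / specificity** — within-context
  pairs, between-context pairs, and their difference, on the context-model
  beta series;
* **item / generalized reinstatement** — cross-phase pairs of identical
  items / of different items of the same CS type.

RSM entries are Fisher r-to-z transformed Pearson correlations across
voxels. Analyses are restricted to unreinforced trials by default (any pair
touching a US-followed trial is excluded), so the shock response cannot
drive similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fearrsa.lss import BetaSeries

__all__ = [
    "RSM",
    "PairMask",
    "build_rsm",
    "make_pair_mask",
    "masked_mean",
    "item_stability",
    "cue_generalization",
    "context_stability",
    "context_generalization",
    "context_specificity",
    "reinstatement",
]

WITHIN_CATEGORIES = (
    "same_item",
    "same_cstype_different_item",
    "within_context",
    "between_context",
)
CROSS_CATEGORIES = (
    "cross_phase_same_item",
    "cross_phase_same_cstype_different_item",
)

_Z_CLIP = 1.0 - 1e-12  # |r| above this is numerically 1; keep atanh finite


@dataclass
class RSM:
    """Fisher-z similarity matrix with aligned row/column trial metadata."""

    z: np.ndarray
    row_meta: pd.DataFrame
    col_meta: pd.DataFrame
    within_phase: bool
    phase_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if self.z.shape != (len(self.row_meta), len(self.col_meta)):
            raise ValueError("matrix shape must match metadata")


@dataclass
class PairMask:
    """Boolean pair-selection mask congruent with an RSM."""

    mask: np.ndarray
    category: str
    restrict_unreinforced: bool

    @property
    def n_pairs(self) -> int:
        return int(self.mask.sum())


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale each pattern across voxels; flag zero-variance rows."""
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    sd = xc.std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    sd[~valid] = 1.0
    return xc / sd / np.sqrt(x.shape[1]), valid


def build_rsm(series_a: BetaSeries, series_b: BetaSeries | None = None) -> RSM:
    """Pairwise Fisher-z pattern similarity between trials.

    Entry (i, j) = atanh(Pearson r across voxels between pattern i of
    ``series_a`` and pattern j of ``series_b``). With ``series_b`` absent
    the matrix is the symmetric within-phase RSM with an undefined (NaN)
    diagonal. Zero-variance patterns yield NaN entries (excluded from every
    mask average) with a warning.
    """
    within = series_b is None
    if series_b is None:
        series_b = series_a
    if series_a.betas.shape[1] != series_b.betas.shape[1]:
        raise ValueError("both series must share the same voxel set")
    za, va = _standardize_rows(series_a.betas)
    zb, vb = _standardize_rows(series_b.betas)
    if not (va.all() and vb.all()):
        warnings.warn(
            f"{int((~va).sum() + (~vb).sum() * (not within))} zero-variance "
            "pattern(s); their similarities are undefined and excluded",
            stacklevel=2,
        )
    r = za @ zb.T
    r = np.clip(r, -_Z_CLIP, _Z_CLIP)
    z = np.arctanh(r)
    z[~va, :] = np.nan
    z[:, ~vb] = np.nan
    if within:
        np.fill_diagonal(z, np.nan)
    pa = series_a.metadata["phase"].iloc[0] if len(series_a.metadata) else ""
    pb = series_b.metadata["phase"].iloc[0] if len(series_b.metadata) else ""
    return RSM(z=z, row_meta=series_a.metadata.reset_index(drop=True),
               col_meta=series_b.metadata.reset_index(drop=True),
               within_phase=within, phase_pair=(pa, pb))


def make_pair_mask(
    rsm: RSM,
    category: str,
    restrict_unreinforced: bool = False,
) -> PairMask:
    """Boolean mask selecting exactly the pairs of one category.

    Within-phase categories require a square within-phase RSM (self-pairs
    are excluded; masks are symmetric); cross-phase categories require a
    rectangular one. With ``restrict_unreinforced`` any pair touching a
    reinforced trial is dropped.
    """
    if category in WITHIN_CATEGORIES:
        if not rsm.within_phase:
            raise ValueError(f"category {category!r} needs a within-phase RSM")
    elif category in CROSS_CATEGORIES:
        if rsm.within_phase:
            raise ValueError(f"category {category!r} needs a cross-phase RSM")
    else:
        raise ValueError(f"unknown category {category!r}")

    rm, cm = rsm.row_meta, rsm.col_meta
    cue_r = rm["cue_id"].to_numpy()[:, None]
    cue_c = cm["cue_id"].to_numpy()[None, :]
    type_r = rm["cs_type"].to_numpy()[:, None]
    type_c = cm["cs_type"].to_numpy()[None, :]
    ctx_r = rm["context_id"].to_numpy()[:, None]
    ctx_c = cm["context_id"].to_numpy()[None, :]

    if category in ("same_item", "cross_phase_same_item"):
        mask = cue_r == cue_c
    elif category in ("same_cstype_different_item",
                      "cross_phase_same_cstype_different_item"):
        mask = (type_r == type_c) & (cue_r != cue_c)
    elif category == "within_context":
        mask = ctx_r == ctx_c
    else:  # between_context
        mask = ctx_r != ctx_c

    if rsm.within_phase:
        np.fill_diagonal(mask, False)
    if restrict_unreinforced:
        ok_r = rm["reinforced"].to_numpy() == 0
        ok_c = cm["reinforced"].to_numpy() == 0
        mask = mask & ok_r[:, None] & ok_c[None, :]
    return PairMask(mask=mask, category=category,
                    restrict_unreinforced=restrict_unreinforced)


def masked_mean(rsm: RSM, mask: PairMask | np.ndarray) -> float:
    """Mean of the RSM entries under a mask, ignoring undefined entries."""
    m = mask.mask if isinstance(mask, PairMask) else mask
    if not m.any():
        raise ValueError("empty pair mask")
    vals = rsm.z[m]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("all selected pairs are undefined")
    return float(vals.mean())


def _metric_rows(rsm, pairs, participant=None, region=None, metric="", phase=None):
    rows = []
    for condition, mask in pairs:
        rows.append(
            {
                "participant": participant,
                "region": region,
                "phase": phase if phase is not None else rsm.phase_pair[0],
                "phase_pair": "-".join(rsm.phase_pair),
                "metric": metric,
                "condition": condition,
                "n_pairs": int(np.isfinite(rsm.z[mask]).sum()),
                "value": float(np.nanmean(np.where(mask, rsm.z, np.nan))),
            }
        )
    return pd.DataFrame(rows)


def item_stability(
    rsm: RSM,
    restrict_unreinforced: bool = True,
    participant=None,
    region=None,
) -> pd.DataFrame:
    """Mean same-item similarity, per cue and per CS type.

    A cue's value is the mean over all usable pairs of its presentations;
    a CS type's value is the mean of its two cues' values.
    """
    base = make_pair_mask(rsm, "same_item", restrict_unreinforced).mask
    cue_ids = rsm.row_meta["cue_id"].to_numpy()
    rows = []
    per_cue: dict[str, float] = {}
    for cue in sorted(set(cue_ids)):
        sel = base & (cue_ids[:, None] == cue)
        if not sel.any():
            raise ValueError(f"no usable same-item pairs for cue {cue!r}")
        per_cue[cue] = masked_mean(rsm, sel)
        rows.append((cue, sel))
    df = _metric_rows(rsm, rows, participant, region, "item_stability")
    df["level"] = "cue"
    type_of = dict(zip(rsm.row_meta["cue_id"], rsm.row_meta["cs_type"]))
    by_type: dict[str, list[float]] = {}
    for cue, v in per_cue.items():
        by_type.setdefault(type_of[cue], []).append(v)
    extra = pd.DataFrame(
        [
            {
                "participant": participant, "region": region,
                "phase": rsm.phase_pair[0], "phase_pair": "-".join(rsm.phase_pair),
                "metric": "item_stability", "condition": t,
                "n_pairs": np.nan, "value": float(np.mean(vs)), "level": "cs_type",
            }
            for t, vs in sorted(by_type.items())
        ]
    )
    return pd.concat([df, extra], ignore_index=True)


def cue_generalization(
    rsm: RSM,
    restrict_unreinforced: bool = True,
    groups: dict[str, set[str]] | None = None,
    participant=None,
    region=None,
) -> pd.DataFrame:
    """Mean different-item similarity within a CS type (or coarser category).

    ``groups`` may pool CS types (e.g. CS+ = {CS++, CS+-} during
    acquisition); by default each CS type is its own category. Pairs are
    different items whose types both belong to the category.
    """
    rm = rsm.row_meta
    types = rm["cs_type"].to_numpy()
    if groups is None:
        groups = {t: {t} for t in sorted(set(types))}
    cue_r = rm["cue_id"].to_numpy()[:, None]
    cue_c = rm["cue_id"].to_numpy()[None, :]
    unre = np.ones(len(rm), dtype=bool)
    if restrict_unreinforced:
        unre = rm["reinforced"].to_numpy() == 0
    rows = []
    for label, members in groups.items():
        in_g = np.isin(types, list(members))
        sel = in_g[:, None] & in_g[None, :] & (cue_r != cue_c)
        sel &= unre[:, None] & unre[None, :]
        np.fill_diagonal(sel, False)
        if not sel.any():
            raise ValueError(f"no usable generalization pairs for {label!r}")
        rows.append((label, sel))
    return _metric_rows(rsm, rows, participant, region, "cue_generalization")


def context_stability(rsm_context: RSM, restrict_unreinforced: bool = True,
                      participant=None, region=None) -> pd.DataFrame:
    """Mean within-context similarity on the context-model series."""
    m = make_pair_mask(rsm_context, "within_context", restrict_unreinforced)
    if not m.mask.any():
        raise ValueError("no within-context pairs")
    return _metric_rows(rsm_context, [("all", m.mask)], participant, region,
                        "context_stability")


def context_generalization(rsm_context: RSM, restrict_unreinforced: bool = True,
                           participant=None, region=None) -> pd.DataFrame:
    """Mean between-context similarity on the context-model series."""
    m = make_pair_mask(rsm_context, "between_context", restrict_unreinforced)
    if not m.mask.any():
        raise ValueError("single-context phase: no between-context pairs")
    return _metric_rows(rsm_context, [("all", m.mask)], participant, region,
                        "context_generalization")


def context_specificity(rsm_context: RSM, restrict_unreinforced: bool = True,
                        participant=None, region=None) -> pd.DataFrame:
    """Within-context minus between-context mean similarity (one value).

    Higher values mean more distinct context representations in the phase.
    Exactly equals context_stability − context_generalization.
    """
    if rsm_context.row_meta["context_id"].nunique() < 2:
        raise ValueError("context specificity needs ≥ 2 contexts in the phase")
    w = context_stability(rsm_context, restrict_unreinforced)["value"].iloc[0]
    b = context_generalization(rsm_context, restrict_unreinforced)["value"].iloc[0]
    return pd.DataFrame(
        [{
            "participant": participant, "region": region,
            "phase": rsm_context.phase_pair[0],
            "phase_pair": "-".join(rsm_context.phase_pair),
            "metric": "context_specificity", "condition": "all",
            "n_pairs": np.nan, "value": float(w - b),
        }]
    )


def reinstatement(
    rsm_cross: RSM,
    mode: str,
    restrict_unreinforced: bool = True,
    participant=None,
    region=None,
) -> pd.DataFrame:
    """Cross-phase reinstatement per CS type.

    ``mode='item'`` averages cross-phase same-item pairs (the same item's
    pattern recurring in a later phase); ``mode='generalized'`` averages
    cross-phase pairs of different items sharing a CS type (the category
    trace recurring).
    """
    if mode not in ("item", "generalized"):
        raise ValueError("mode must be 'item' or 'generalized'")
    category = ("cross_phase_same_item" if mode == "item"
                else "cross_phase_same_cstype_different_item")
    base = make_pair_mask(rsm_cross, category, restrict_unreinforced).mask
    types_r = rsm_cross.row_meta["cs_type"].to_numpy()
    rows = []
    for t in sorted(set(types_r)):
        sel = base & (types_r[:, None] == t)
        if not sel.any():
            raise ValueError(f"no usable {mode}-reinstatement pairs for {t!r}")
        rows.append((t, sel))
    return _metric_rows(rsm_cross, rows, participant, region,
                        f"{mode}_reinstatement")
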