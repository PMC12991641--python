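"""Cluster FWE, ROI extraction, FDR, and linking models."""

import numpy as np
import pandas as pd
import pytest

from fearrsa.inference import (
    bonferroni_alpha,
    cluster_fwe,
    extract_rois,
    fdr_bh,
    roi_phase_lme,
    specificity_reinstatement_lme,
)
from fearrsa.synthetic_bold import VolumeGeometry


def _geom(shape=(12, 12, 8)):
    return VolumeGeometry(shape=shape, mask=np.ones(shape, dtype=bool),
                          voxel_size_mm=2.5)


def test_bonferroni_values():
    assert bonferroni_alpha(0.05, 2) == pytest.approx(0.025)
    assert bonferroni_alpha(0.05, 4) == pytest.approx(0.0125)
    assert bonferroni_alpha(0.05, 1) == pytest.approx(0.05)
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


def test_fdr_bh_against_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(0)
    p = np.concatenate([rng.uniform(0, 0.01, 5), rng.uniform(0, 1, 20)])
    ours = fdr_bh(p)
    _, theirs, *_ = sm.multipletests(p, method="fdr_bh")
    assert np.allclose(ours, theirs, atol=1e-12)


def test_cluster_fwe_detects_planted_signal():
    shape = (12, 12, 8)
    rng = np.random.default_rng(1)
    region = np.zeros(shape, dtype=bool)
    region[3:8, 3:8, 2:6] = True
    stack = rng.normal(0, 1, (12,) + shape)
    stack[:, region] += 2.0
    gmap, cset = cluster_fwe(stack, n_perm=500, cft_p=0.001, alpha=0.05,
                             seed=0)
    sig = cset.significant()
    assert len(sig) >= 1
    big = max(sig, key=lambda c: c.size)
    hit = np.zeros(shape, dtype=bool)
    hit[tuple(big.voxels.T)] = True
    # the detected cluster overlaps the planted region substantially
    assert (hit & region).sum() / region.sum() > 0.5
    # permutation p respects the +1 correction lower bound
    assert big.p_fwe >= 1.0 / (cset.n_permutations + 1) - 1e-12


def test_cluster_fwe_controls_null():
    rng = np.random.default_rng(2)
    stack = rng.normal(0, 1, (10, 10, 10, 6))
    _, cset = cluster_fwe(stack, n_perm=300, cft_p=0.001, alpha=0.05, seed=3)
    assert len(cset.significant()) == 0


def test_cluster_table_columns():
    rng = np.random.default_rng(4)
    stack = rng.normal(0.8, 1, (12, 8, 8, 6))
    _, cset = cluster_fwe(stack, n_perm=200, cft_p=0.01, alpha=0.05, seed=1)
    t = cset.table()
    assert {"label", "n_voxels", "volume_mm3", "peak", "p_fwe",
            "significant"} <= set(t.columns)


def test_roi_volume_boundary():
    g = _geom((12, 12, 8))
    m95 = np.zeros(g.shape, dtype=bool)
    m95.flat[:95] = True  # 95 voxels × 15.625 = 1484.375 mm³ < 1500
    m96 = np.zeros(g.shape, dtype=bool)
    m96.flat[:96] = True  # 96 × 15.625 = 1500 mm³ exactly
    assert len(extract_rois({"a": m95}, g, 1500.0)) == 0
    rois = extract_rois({"a": m96}, g, 1500.0)
    assert len(rois) == 1
    (mask,) = rois.rois.values()
    assert mask.sum() == 96


def test_roi_overlap_keeps_larger():
    g = _geom((12, 12, 8))
    big = np.zeros(g.shape, dtype=bool)
    big[0:4, 0:6, 0:5] = True  # 120 voxels
    small = np.zeros(g.shape, dtype=bool)
    small[2:6, 0:6, 0:4] = True  # 96, overlapping big
    rois = extract_rois({"big_map": big, "small_map": small}, g, 1500.0)
    assert len(rois) == 1
    assert list(rois.provenance.values()) == ["big_map"]
    assert rois.overlap_log  # the resolution was logged


def test_roi_phase_lme_recovers_phase_effect():
    rng = np.random.default_rng(5)
    rows = []
    for p in range(10):
        b = rng.normal(0, 0.1)
        for ph_i, ph in enumerate(["acquisition", "reversal", "test_new"]):
            for cs in ["CS++", "CS--"]:
                rows.append(dict(participant=f"s{p}", source_phase=ph,
                                 cs_type=cs,
                                 value=0.3 * ph_i + b + rng.normal(0, 0.1)))
    res = roi_phase_lme(pd.DataFrame(rows), ["source_phase", "cs_type"])
    by = dict(zip(res.table.term, res.table.p_fdr))
    assert by["source_phase"] < 0.01
    assert by["cs_type"] > 0.01
    # FDR never decreases a raw p value
    assert (res.table.p_fdr >= res.table.p_raw - 1e-12).all()


def test_specificity_reinstatement_interaction():
    rng = np.random.default_rng(6)
    rows = []
    for p in range(16):
        spec = rng.normal(0, 1)
        b = rng.normal(0, 0.05)
        for cs, slope in (("CS-+", 0.5), ("CS+-", -0.1)):
            rows.append(dict(participant=f"s{p}", cs_type=cs,
                             specificity=spec,
                             reinstatement=slope * spec + b
                             + rng.normal(0, 0.1)))
    res = specificity_reinstatement_lme(pd.DataFrame(rows), "item")
    tab = res.table
    inter = tab[tab.term.str.contains(":")]
    assert len(inter) >= 1 and (inter.p_raw < 0.01).all()
    # simple slopes are reported per cue type
    slopes = [c for c in res.coefs if c.name.startswith("slope[")]
    assert len(slopes) == 2
    strong = [c for c in slopes if "CS-+" in c.name][0]
    assert strong.estimate == pytest.approx(0.5, abs=0.1)
    assert strong.pvalue < 0.001


def test_cluster_fwe_degenerate_voxels_warn():
    stack = np.random.default_rng(0).normal(0, 1, (6, 5, 5, 4))
    stack[:, 0, 0, 0] = 5.0  # constant across participants: t undefined
    with pytest.warns(UserWarning, match="excluded"):
        gmap, _ = cluster_fwe(stack, n_perm=100, cft_p=0.01, alpha=0.05,
                              seed=0)
    assert not gmap.defined[0, 0, 0]
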