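"""RSA metrics against brute-force pair enumeration and hand values."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fearrsa.design import CSType, Phase
from fearrsa.lss import BetaSeries
from fearrsa.rsa import (
    build_rsm,
    context_generalization,
    context_specificity,
    context_stability,
    cue_generalization,
    item_stability,
    make_pair_mask,
    masked_mean,
    reinstatement,
)

from conftest import make_toy_series


def brute_force_mean(bs_a, bs_b, select):
    """Oracle: mean Fisher-z over explicitly enumerated pairs."""
    within = bs_b is None
    b = bs_a if within else bs_b
    vals = []
    for i, ra in bs_a.metadata.iterrows():
        for j, rb in b.metadata.iterrows():
            if within and i == j:
                continue
            if select(ra, rb):
                r = np.corrcoef(bs_a.betas[i], b.betas[j])[0, 1]
                vals.append(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))
    return float(np.mean(vals))


def test_rsm_values_are_fisher_z(geom_small):
    bs = make_toy_series(geom_small, n_trials=6, seed=1)
    rsm = build_rsm(bs)
    r01 = np.corrcoef(bs.betas[0], bs.betas[1])[0, 1]
    assert rsm.z[0, 1] == pytest.approx(np.arctanh(r01))
    assert np.allclose(rsm.z, rsm.z.T, equal_nan=True)
    assert np.isnan(np.diag(rsm.z)).all()


def test_hand_computed_average():
    # two pairs with r = 0.3 and r = 0.5: mean Fisher z is
    # (atanh(0.3) + atanh(0.5)) / 2 = (0.309520 + 0.549306) / 2 = 0.429413
    z = (math.atanh(0.3) + math.atanh(0.5)) / 2
    assert z == pytest.approx((0.3095196 + 0.5493061) / 2, abs=1e-6)
    assert z == pytest.approx(0.4294129, abs=1e-6)


def test_pair_counts(geom_small):
    # 16 trials, 4 cues × 4 presentations, 4 contexts
    bs = make_toy_series(geom_small, n_trials=16, seed=0)
    rsm = build_rsm(bs)
    same_item = make_pair_mask(rsm, "same_item")
    # per cue: C(4,2)=6 unordered pairs → 12 ordered; 4 cues → 48
    assert same_item.n_pairs == 48
    within_ctx = make_pair_mask(rsm, "within_context")
    assert within_ctx.n_pairs == 48  # same layout for contexts
    between_ctx = make_pair_mask(rsm, "between_context")
    assert between_ctx.n_pairs == 16 * 15 - 48
    # unordered-count identities: C(8,2) = 28, C(16,2) = 120
    assert math.comb(8, 2) == 28 and math.comb(16, 2) == 120


@pytest.mark.parametrize("metric,select", [
    ("item_stability",
     lambda a, b: a.cue_id == b.cue_id),
    ("cue_generalization",
     lambda a, b: a.cs_type == b.cs_type and a.cue_id != b.cue_id),
    ("context_stability",
     lambda a, b: a.context_id == b.context_id),
    ("context_generalization",
     lambda a, b: a.context_id != b.context_id),
])
def test_metrics_match_enumeration_oracle(geom_small, metric, select):
    for seed in (0, 1, 2):
        bs = make_toy_series(geom_small, n_trials=24, seed=seed, n_cues=8,
                             n_contexts=4)
        rsm = build_rsm(bs)
        oracle = brute_force_mean(bs, None, select)
        if metric == "item_stability":
            df = item_stability(rsm, restrict_unreinforced=False)
            got = df[df.level == "cue"].value.mean()
            # cue-level means all have equal pair counts here, so the mean
            # of means equals the grand mean
        elif metric == "cue_generalization":
            df = cue_generalization(rsm, restrict_unreinforced=False)
            got = np.average(df.value, weights=df.n_pairs)
        elif metric == "context_stability":
            got = context_stability(rsm, restrict_unreinforced=False)\
                .value.iloc[0]
        else:
            got = context_generalization(rsm, restrict_unreinforced=False)\
                .value.iloc[0]
        assert got == pytest.approx(oracle, abs=1e-10)


def test_specificity_is_exact_decomposition(geom_small):
    bs = make_toy_series(geom_small, n_trials=16, seed=3)
    rsm = build_rsm(bs)
    w = context_stability(rsm, False).value.iloc[0]
    b = context_generalization(rsm, False).value.iloc[0]
    s = context_specificity(rsm, False).value.iloc[0]
    assert s == pytest.approx(w - b, abs=1e-12)


def test_reinstatement_matches_oracle(geom_small):
    a = make_toy_series(geom_small, n_trials=16, seed=4, n_cues=8,
                        phase=Phase.ACQUISITION)
    b = make_toy_series(geom_small, n_trials=16, seed=5, n_cues=8,
                        phase=Phase.TEST_OLD)
    rsm = build_rsm(a, b)
    assert not rsm.within_phase
    for mode, select in (
        ("item", lambda ra, rb: ra.cue_id == rb.cue_id),
        ("generalized",
         lambda ra, rb: ra.cs_type == rb.cs_type and ra.cue_id != rb.cue_id),
    ):
        df = reinstatement(rsm, mode, restrict_unreinforced=False)
        for cs in df.condition:
            oracle = brute_force_mean(
                a, b, lambda ra, rb, c=cs: select(ra, rb) and ra.cs_type == c)
            got = df[df.condition == cs].value.iloc[0]
            assert got == pytest.approx(oracle, abs=1e-10)


def test_restrict_unreinforced_drops_pairs(geom_small):
    bs = make_toy_series(geom_small, n_trials=16, seed=6, reinforced_every=4)
    rsm = build_rsm(bs)
    full = make_pair_mask(rsm, "same_item", restrict_unreinforced=False)
    restr = make_pair_mask(rsm, "same_item", restrict_unreinforced=True)
    assert restr.n_pairs < full.n_pairs
    ok = bs.metadata.reinforced.to_numpy() == 0
    assert not restr.mask[~ok].any() and not restr.mask[:, ~ok].any()


def test_cross_category_on_wrong_rsm_errors(geom_small):
    bs = make_toy_series(geom_small, n_trials=8, seed=0)
    rsm = build_rsm(bs)
    with pytest.raises(ValueError, match="cross-phase"):
        make_pair_mask(rsm, "cross_phase_same_item")
    with pytest.raises(ValueError, match="unknown"):
        make_pair_mask(rsm, "nonsense")


def test_zero_variance_pattern_warns(geom_small):
    bs = make_toy_series(geom_small, n_trials=8, seed=0)
    bs.betas[2] = 1.0  # constant pattern: correlation undefined
    with pytest.warns(UserWarning, match="zero-variance"):
        rsm = build_rsm(bs)
    assert np.isnan(rsm.z[2]).all()
    # metric averages simply skip the undefined pairs
    v = masked_mean(rsm, make_pair_mask(rsm, "same_item", False))
    assert np.isfinite(v)


def test_cue_generalization_pooling(geom_small):
    bs = make_toy_series(geom_small, n_trials=32, seed=7, n_cues=8)
    rsm = build_rsm(bs)
    pooled = cue_generalization(
        rsm, False,
        groups={"CS+": {CSType.CS_PP.value, CSType.CS_PM.value},
                "CS-": {CSType.CS_MP.value, CSType.CS_MM.value}})
    assert set(pooled.condition) == {"CS+", "CS-"}
    oracle = brute_force_mean(
        bs, None,
        lambda a, b: a.cs_type in ("CS++", "CS+-")
        and b.cs_type in ("CS++", "CS+-") and a.cue_id != b.cue_id)
    got = pooled[pooled.condition == "CS+"].value.iloc[0]
    assert got == pytest.approx(oracle, abs=1e-10)
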