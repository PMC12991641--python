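"""Synthetic pattern bank, effect specs, and BOLD generation."""

import dataclasses

import numpy as np
import pytest

from fearrsa.design import CSType, Phase, assign_counterbalancing, \
    build_phase_design, schedule_onsets
from fearrsa.synthetic_bold import (
    CONFOUND_COLUMNS,
    EffectSpec,
    VolumeGeometry,
    compose_context_patterns,
    compose_trial_patterns,
    default_effects,
    default_geometry,
    make_pattern_bank,
    null_effects,
    simulate_confounds,
    synthesize_bold,
)


def test_default_geometry_voxel_count():
    g = default_geometry()
    assert g.shape == (18, 18, 12)
    # desk-scale target: roughly 2,400 in-mask voxels
    assert 2200 <= g.n_voxels <= 2700
    assert g.voxel_volume_mm3 == pytest.approx(15.625)
    assert np.allclose(np.diag(g.affine()), [2.5, 2.5, 2.5, 1.0])


def test_pattern_bank_orthogonal_and_scaled(geom_small):
    bank = make_pattern_bank(geom_small, seed=1)
    pats = ([bank.baseline] + list(bank.item.values())
            + list(bank.valence.values()) + list(bank.context.values()))
    assert len(pats) == 27
    P = np.stack(pats)
    G = P @ P.T / geom_small.n_voxels
    assert np.allclose(G, np.eye(27), atol=1e-10)
    # deterministic in the seed
    bank2 = make_pattern_bank(geom_small, seed=1)
    assert np.allclose(bank.baseline, bank2.baseline)


def test_pattern_bank_too_few_voxels():
    g = VolumeGeometry(shape=(2, 2, 2), mask=np.ones((2, 2, 2), dtype=bool))
    with pytest.raises(ValueError, match="voxels"):
        make_pattern_bank(g, seed=0)


def test_effect_spec_validation():
    with pytest.raises(ValueError, match="ar1_rho"):
        default_effects(ar1_rho=1.5)


def test_default_effects_planted_directions():
    e = default_effects()
    A, R = Phase.ACQUISITION, Phase.REVERSAL
    # threat cues generalize more than safe cues in acquisition
    assert e.w_cat[(A, CSType.CS_PP)] > e.w_cat[(A, CSType.CS_MM)]
    # in reversal the *current* threat cues carry the larger weight
    assert e.w_cat[(R, CSType.CS_MP)] > e.w_cat[(R, CSType.CS_PM)]
    # contingency-changing cues get boosted item coding in reversal
    assert e.w_item[(R, CSType.CS_MP)] > e.w_item[(R, CSType.CS_PP)]
    # context coding stronger in reversal than acquisition
    assert e.w_ctx[R] > e.w_ctx[A]


def test_null_effects_zero_structure(geom_small):
    e = null_effects(trial_noise_sd=0.0)
    spec = assign_counterbalancing(0)
    spec = dataclasses.replace(spec, n_trials_per_phase=64)
    d = build_phase_design(spec, Phase.ACQUISITION, seed=0)
    bank = make_pattern_bank(
        geom_small, 0, cue_ids=spec.cue_ids,
        context_ids=tuple(spec.context_sets["A"] + spec.context_sets["B"]
                          + spec.context_sets["C"]))
    assert np.allclose(compose_trial_patterns(d, bank, e, seed=1), 0.0)


def test_composed_patterns_follow_weights(geom_small):
    spec = dataclasses.replace(assign_counterbalancing(0), n_trials_per_phase=64)
    d = build_phase_design(spec, Phase.ACQUISITION, seed=0)
    bank = make_pattern_bank(
        geom_small, 0, cue_ids=spec.cue_ids,
        context_ids=tuple(spec.context_sets["A"] + spec.context_sets["B"]
                          + spec.context_sets["C"]))
    e = default_effects(trial_noise_sd=0.0)
    P = compose_trial_patterns(d, bank, e, seed=1)
    t0 = d.trials[0]
    expected = (e.baseline_amplitude * bank.baseline
                + e.w_item[(d.phase, t0.cs_type)] * bank.item_pattern(t0.cue_id)
                + e.w_cat[(d.phase, t0.cs_type)]
                * bank.valence_pattern(t0.cs_type.current_valence(d.phase))
                + e.w_ctx[d.phase] * bank.context[t0.context_id])
    assert np.allclose(P[0], expected)
    C = compose_context_patterns(d, bank, e, seed=1)
    assert np.allclose(
        C[0], e.baseline_amplitude * bank.baseline
        + e.w_ctx[d.phase] * bank.context[t0.context_id])


def test_confound_table_columns():
    df = simulate_confounds(50, np.random.default_rng(0))
    assert list(df.columns) == CONFOUND_COLUMNS
    assert len(df) == 50


def test_synthesize_bold_shape_and_determinism(geom_small):
    spec = dataclasses.replace(assign_counterbalancing(0), n_trials_per_phase=64)
    d = schedule_onsets(build_phase_design(spec, Phase.TEST_NEW, seed=0), spec,
                        seed=1)
    bank = make_pattern_bank(
        geom_small, 0, cue_ids=spec.cue_ids,
        context_ids=tuple(spec.context_sets["A"] + spec.context_sets["B"]
                          + spec.context_sets["C"]))
    e = default_effects()
    ds1 = synthesize_bold(d, compose_trial_patterns(d, bank, e, 1),
                          compose_context_patterns(d, bank, e, 2),
                          geom_small, e, seed=9)
    ds2 = synthesize_bold(d, compose_trial_patterns(d, bank, e, 1),
                          compose_context_patterns(d, bank, e, 2),
                          geom_small, e, seed=9)
    n_scans = int(np.ceil(d.total_duration / geom_small.tr))
    assert ds1.data.shape == (n_scans, geom_small.n_voxels)
    assert np.array_equal(ds1.data, ds2.data)
    assert len(ds1.confounds) == n_scans
    vol = ds1.to_4d()
    assert vol.shape == tuple(geom_small.shape) + (n_scans,)
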