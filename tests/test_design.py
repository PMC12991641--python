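"""Design generation: exact printed counts, constraints, round trips."""

import numpy as np
import pandas as pd
import pytest

from fearrsa.design import (
    PHASE_ORDER,
    CSType,
    DesignError,
    Phase,
    assign_counterbalancing,
    build_phase_design,
    design_from_events,
    events_frame,
    read_events_tsv,
    schedule_onsets,
    write_events_tsv,
)


def test_spec_structure(spec0):
    assert len(spec0.cue_ids) == 8
    counts = pd.Series([t.value for t in spec0.cs_type_map.values()]).value_counts()
    assert sorted(counts) == [2, 2, 2, 2]
    all_ctx = sum((list(v) for v in spec0.context_sets.values()), [])
    assert len(set(all_ctx)) == 16
    assert len(spec0.phase_contexts(Phase.TEST_NEW)) == 8
    assert set(spec0.phase_contexts(Phase.TEST_OLD)) == set(
        spec0.context_sets["A"] + spec0.context_sets["B"]
    )


@pytest.mark.parametrize("phase", PHASE_ORDER)
def test_phase_counts(spec0, phase):
    d = build_phase_design(spec0, phase, seed=3)
    df = d.to_frame()
    assert len(df) == 128
    # 16 presentations per cue
    assert (df.groupby("cue_id").size() == 16).all()
    # uniform cue × context cells: 4 with 4 contexts, 2 with 8, 2 with 16
    cells = df.groupby(["cue_id", "context_id"]).size()
    n_ctx = df["context_id"].nunique()
    assert (cells == 128 // (8 * n_ctx)).all()
    expected_ctx = {Phase.ACQUISITION: 4, Phase.REVERSAL: 4,
                    Phase.TEST_NEW: 8, Phase.TEST_OLD: 8}
    assert n_ctx == expected_ctx[phase]


@pytest.mark.parametrize("phase", PHASE_ORDER)
def test_reinforcement_schedule(spec0, phase):
    d = build_phase_design(spec0, phase, seed=3)
    df = d.to_frame()
    for cs in CSType:
        sub = df[df.cs_type == cs.value]
        if cs.us_paired(phase):
            # 50% of the paired cues' trials carry the US
            assert sub.reinforced.sum() == len(sub) // 2
        else:
            assert sub.reinforced.sum() == 0
    assert df.iloc[0].reinforced == 0 and df.iloc[-1].reinforced == 0


def test_reinforcement_balanced_within_context(spec0):
    df = build_phase_design(spec0, Phase.ACQUISITION, seed=5).to_frame()
    paired = df[df.cs_type.isin([CSType.CS_PP.value, CSType.CS_PM.value])]
    per_cell = paired.groupby(["cue_id", "context_id"]).reinforced.sum()
    assert (per_cell == 2).all()  # 4 occurrences per cell, half reinforced


def test_no_long_cue_runs(spec0):
    df = build_phase_design(spec0, Phase.ACQUISITION, seed=3).to_frame()
    runs = (df.cue_id != df.cue_id.shift()).cumsum()
    assert df.groupby(runs).size().max() <= 2


def test_counterbalancing_rotates():
    maps = [assign_counterbalancing(i).cs_type_map for i in range(4)]
    # each cue takes different CS types over the rotation
    cue = sorted(maps[0])[0]
    assert len({m[cue] for m in maps}) > 1
    # the context pool is a fixed set, partitioned differently per participant
    pools = [
        frozenset(sum((list(v) for v in assign_counterbalancing(i).context_sets.values()), []))
        for i in range(4)
    ]
    assert len(set(pools)) == 1


def test_schedule_onsets_timing(spec0, acq_design):
    df = acq_design.to_frame()
    assert np.allclose(df.onset_cue - df.onset_context, 2.0)
    assert np.allclose(df.onset_rating - df.onset_cue, 1.0)
    itis = df.iti_duration.to_numpy()
    assert itis.min() >= 7.0 and itis.max() <= 9.0
    r = df[df.reinforced == 1]
    assert np.allclose(r.onset_us - r.onset_rating, 2.5)
    assert df[df.reinforced == 0].onset_us.isna().all()
    assert (np.diff(df.onset_context) > 0).all()
    assert acq_design.total_duration > df.onset_iti.iloc[-1]


def test_events_round_trip(tmp_path, spec0, acq_design):
    path = tmp_path / "events.tsv"
    write_events_tsv(acq_design, spec0, path)
    back = read_events_tsv(path)
    ref = events_frame(acq_design, spec0)
    pd.testing.assert_frame_equal(back, ref, check_exact=False, atol=1e-9)
    rebuilt = design_from_events(back)
    assert len(rebuilt) == len(acq_design)
    for a, b in zip(rebuilt.trials, acq_design.trials):
        assert (a.cue_id, a.context_id, a.cs_type, a.reinforced) == (
            b.cue_id, b.context_id, b.cs_type, b.reinforced
        )
        assert a.onset_cue == pytest.approx(b.onset_cue)


def test_indivisible_trial_count_rejected(spec0):
    import dataclasses

    bad = dataclasses.replace(spec0, n_trials_per_phase=96)
    with pytest.raises(DesignError):
        build_phase_design(bad, Phase.TEST_NEW, seed=0)


def test_current_valence_semantics():
    # CS-+ is safe in acquisition, threat from reversal onward
    assert CSType.CS_MP.current_valence(Phase.ACQUISITION) == "safe"
    assert CSType.CS_MP.current_valence(Phase.REVERSAL) == "threat"
    assert CSType.CS_MP.current_valence(Phase.TEST_OLD) == "threat"
    assert CSType.CS_PM.current_valence(Phase.ACQUISITION) == "threat"
    assert CSType.CS_PM.current_valence(Phase.TEST_NEW) == "safe"


def test_determinism(spec0):
    a = build_phase_design(spec0, Phase.REVERSAL, seed=9).to_frame()
    b = build_phase_design(spec0, Phase.REVERSAL, seed=9).to_frame()
    pd.testing.assert_frame_equal(a, b)
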