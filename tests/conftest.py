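import numpy as np
import pandas as pd
import pytest

from fearrsa.design import (
    CSType,
    Phase,
    PhaseDesign,
    TrialEvent,
    assign_counterbalancing,
    build_phase_design,
    schedule_onsets,
)
from fearrsa.lss import BetaSeries
from fearrsa.synthetic_bold import VolumeGeometry


@pytest.fixture(scope="session")
def spec0():
    """Default counterbalancing for participant 0 (128 trials per phase)."""
    return assign_counterbalancing(0)


@pytest.fixture(scope="session")
def acq_design(spec0):
    return schedule_onsets(
        build_phase_design(spec0, Phase.ACQUISITION, seed=11), spec0, seed=12
    )


@pytest.fixture(scope="session")
def geom_small():
    """Fully masked 6×6×4 grid (144 voxels) for fast pattern-level tests."""
    shape = (6, 6, 4)
    return VolumeGeometry(shape=shape, mask=np.ones(shape, dtype=bool))


def make_toy_series(
    geom,
    n_trials=16,
    seed=0,
    phase=Phase.ACQUISITION,
    model_kind="cue",
    n_cues=4,
    n_contexts=4,
    reinforced_every=0,
):
    """Random beta series with a simple factorial trial labeling."""
    rng = np.random.default_rng(seed)
    cs_cycle = [CSType.CS_PP, CSType.CS_PM, CSType.CS_MP, CSType.CS_MM]
    rows = []
    for i in range(n_trials):
        cue = f"cue{i % n_cues:02d}"
        rows.append(
            {
                "trial_index": i,
                "cue_id": cue,
                "context_id": f"ctx{i % n_contexts:02d}",
                "cs_type": cs_cycle[i % n_cues % 4].value,
                "reinforced": int(reinforced_every and i % reinforced_every == 0),
                "phase": phase.value,
            }
        )
    meta = pd.DataFrame(rows)
    betas = rng.standard_normal((n_trials, geom.n_voxels))
    return BetaSeries(model_kind=model_kind, betas=betas, metadata=meta,
                      geometry=geom)


def tiny_design(n_trials=8, tr_spacing=10.0, phase=Phase.ACQUISITION,
                reinforced=(), seed=0):
    """Small hand-built scheduled design (for LSS oracle tests)."""
    trials = []
    cs_cycle = [CSType.CS_PP, CSType.CS_PM, CSType.CS_MP, CSType.CS_MM]
    t = 2.0
    for i in range(n_trials):
        onset_ctx = t
        onset_cue = onset_ctx + 2.0
        onset_rating = onset_cue + 1.0
        is_r = i in reinforced
        onset_us = onset_rating + 2.5 if is_r else None
        trials.append(
            TrialEvent(
                phase=phase, trial_index=i, cue_id=f"cue{i % 4:02d}",
                cs_type=cs_cycle[i % 4], context_id=f"ctx{i % 2:02d}",
                reinforced=is_r, onset_context=onset_ctx, onset_cue=onset_cue,
                onset_rating=onset_rating, onset_us=onset_us,
                onset_iti=onset_rating + 2.5,
                iti_duration=tr_spacing - 5.5,
            )
        )
        t += tr_spacing
    return PhaseDesign(phase=phase, trials=trials, seed=seed,
                       total_duration=t + 16.0)
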