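"""Four-phase fear-conditioning experimental designs.

The paradigm has four phases run in order — fear acquisition, fear reversal,
test in new contexts (``test_new``), and test in the old acquisition/reversal
contexts (``test_old``). Eight cues are split into four contingency types of
two items each:

* ``CS++`` — US-paired during both acquisition and reversal,
* ``CS+-`` — US-paired during acquisition only (extinguished threat),
* ``CS-+`` — US-paired during reversal only (newly acquired threat),
* ``CS--`` — never US-paired.

US-paired cues are reinforced on 50% of their presentations; the test phases
contain no US. Contexts come in three sets: A (4 videos, acquisition),
B (4 videos, reversal), C (8 new videos, test_new); test_old re-uses A∪B.
Each phase holds 128 trials with the structure context video (2 s) → cue
(1 s) → expectancy rating (2.5 s) → optional US → jittered ITI (7–9 s); the
gap between cue offset and US makes this a trace-conditioning design.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "CSType",
    "Timing",
    "ExperimentSpec",
    "TrialEvent",
    "PhaseDesign",
    "DesignError",
    "assign_counterbalancing",
    "build_phase_design",
    "schedule_onsets",
    "events_frame",
    "write_events_tsv",
    "read_events_tsv",
]


class DesignError(ValueError):
    """Raised when a design request is infeasible or inconsistent."""


class Phase(str, enum.Enum):
    ACQUISITION = "acquisition"
    REVERSAL = "reversal"
    TEST_NEW = "test_new"
    TEST_OLD = "test_old"

    @property
    def has_us(self) -> bool:
        return self in (Phase.ACQUISITION, Phase.REVERSAL)


PHASE_ORDER = (Phase.ACQUISITION, Phase.REVERSAL, Phase.TEST_NEW, Phase.TEST_OLD)


class CSType(str, enum.Enum):
    CS_PP = "CS++"
    CS_PM = "CS+-"
    CS_MP = "CS-+"
    CS_MM = "CS--"

    def us_paired(self, phase: Phase) -> bool:
        """Whether this cue type is associated with the US in ``phase``."""
        if phase == Phase.ACQUISITION:
            return self in (CSType.CS_PP, CSType.CS_PM)
        if phase == Phase.REVERSAL:
            return self in (CSType.CS_PP, CSType.CS_MP)
        return False

    def current_valence(self, phase: Phase) -> str:
        """'threat' or 'safe' under the contingencies in force.

        Test phases carry no US; their nominal valence is taken from the most
        recent learning phase (reversal), which is what a lingering category
        trace would reflect. Generators weight it separately per phase, so a
        zero weight removes it entirely.
        """
        if phase == Phase.ACQUISITION:
            return "threat" if self in (CSType.CS_PP, CSType.CS_PM) else "safe"
        return "threat" if self in (CSType.CS_PP, CSType.CS_MP) else "safe"


@dataclass(frozen=True)
class Timing:
    """Within-trial event durations, in seconds."""

    context_duration: float = 2.0
    cue_duration: float = 1.0
    rating_duration: float = 2.5
    iti_bounds: tuple[float, float] = (7.0, 9.0)

    def __post_init__(self) -> None:
        lo, hi = self.iti_bounds
        if not (0 < lo <= hi):
            raise DesignError(f"invalid ITI bounds {self.iti_bounds}")


@dataclass(frozen=True)
class ExperimentSpec:
    """One participant's counterbalanced experimental specification."""

    cue_ids: tuple[str, ...]
    cs_type_map: dict[str, CSType]
    context_sets: dict[str, tuple[str, ...]]  # keys "A", "B", "C"
    timing: Timing = field(default_factory=Timing)
    reinforcement_rate: float = 0.5
    n_trials_per_phase: int = 128
    rating_scale: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        if len(self.cue_ids) != 8 or len(set(self.cue_ids)) != 8:
            raise DesignError("exactly 8 distinct cue ids required")
        counts = pd.Series([t.value for t in self.cs_type_map.values()]).value_counts()
        if set(self.cs_type_map) != set(self.cue_ids):
            raise DesignError("cs_type_map must cover exactly the cue ids")
        if sorted(counts) != [2, 2, 2, 2]:
            raise DesignError("each CS type must have exactly 2 cues")
        for name, size in (("A", 4), ("B", 4), ("C", 8)):
            if len(self.context_sets.get(name, ())) != size:
                raise DesignError(f"context set {name} must have {size} ids")
        all_ctx = list(itertools.chain.from_iterable(self.context_sets.values()))
        if len(set(all_ctx)) != 16:
            raise DesignError("context sets must hold 16 distinct ids")
        if not 0.0 <= self.reinforcement_rate <= 1.0:
            raise DesignError("reinforcement_rate must lie in [0, 1]")

    def phase_contexts(self, phase: Phase) -> tuple[str, ...]:
        """Context ids available in ``phase`` (A, B, C, or A∪B)."""
        table = {
            Phase.ACQUISITION: self.context_sets["A"],
            Phase.REVERSAL: self.context_sets["B"],
            Phase.TEST_NEW: self.context_sets["C"],
            Phase.TEST_OLD: self.context_sets["A"] + self.context_sets["B"],
        }
        return table[phase]

    def cues_of_type(self, cs_type: CSType) -> tuple[str, ...]:
        return tuple(c for c in self.cue_ids if self.cs_type_map[c] == cs_type)


@dataclass
class TrialEvent:
    """One trial: context video, cue, rating window, optional US, ITI."""

    phase: Phase
    trial_index: int
    cue_id: str
    cs_type: CSType
    context_id: str
    reinforced: bool
    onset_context: float | None = None
    onset_cue: float | None = None
    onset_rating: float | None = None
    onset_us: float | None = None
    onset_iti: float | None = None
    iti_duration: float | None = None


@dataclass
class PhaseDesign:
    """The ordered, labeled trial sequence of one phase."""

    phase: Phase
    trials: list[TrialEvent]
    seed: int
    total_duration: float | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """One row per trial with labels and (if scheduled) onsets."""
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "phase": t.phase.value,
                    "trial_index": t.trial_index,
                    "cue_id": t.cue_id,
                    "cs_type": t.cs_type.value,
                    "context_id": t.context_id,
                    "reinforced": int(t.reinforced),
                    "onset_context": t.onset_context,
                    "onset_cue": t.onset_cue,
                    "onset_rating": t.onset_rating,
                    "onset_us": t.onset_us,
                    "onset_iti": t.onset_iti,
                    "iti_duration": t.iti_duration,
                }
            )
        return pd.DataFrame(rows)


def _rotate(seq: tuple, k: int) -> tuple:
    k %= len(seq)
    return seq[k:] + seq[:k]


def assign_counterbalancing(participant_index: int, seed: int = 0) -> ExperimentSpec:
    """Counterbalanced cue→CS-type and context-set assignment.

    A Latin-square rotation over the participant index: the eight cues rotate
    through a fixed slot sequence of CS types (two slots per type), so that
    across any block of eight consecutive participants each cue serves each
    CS type exactly twice. The 16 context videos likewise rotate in steps of
    four before being partitioned into sets A (4), B (4), and C (8). ``seed``
    fixes the base orderings, so the whole schedule is reproducible from
    ``(participant_index, seed)``.
    """
    if participant_index < 0:
        raise DesignError("participant_index must be ≥ 0")
    rng = np.random.default_rng(seed)
    cues = tuple(f"cue{i:02d}" for i in range(8))
    contexts = tuple(f"ctx{i:02d}" for i in range(16))
    type_slots = [CSType.CS_PP, CSType.CS_PM, CSType.CS_MP, CSType.CS_MM] * 2
    rng.shuffle(type_slots)
    base_ctx = tuple(contexts[i] for i in rng.permutation(16))

    rotated_slots = _rotate(tuple(type_slots), participant_index)
    cs_type_map = {cue: rotated_slots[i] for i, cue in enumerate(cues)}
    ctx = _rotate(base_ctx, 4 * participant_index)
    context_sets = {"A": ctx[0:4], "B": ctx[4:8], "C": ctx[8:16]}
    return ExperimentSpec(cue_ids=cues, cs_type_map=cs_type_map, context_sets=context_sets)


def _assign_reinforcement(
    spec: ExperimentSpec, phase: Phase, cue: str, contexts: tuple[str, ...], reps: int, rng
) -> dict[str, list[bool]]:
    """Reinforced flags per context cell for one cue, at the spec's rate.

    US-paired cues are reinforced on ``reinforcement_rate`` of their
    presentations, balanced within each context cell when the cell count
    allows (keeps unreinforced trials evenly spread over contexts).
    """
    paired = phase.has_us and spec.cs_type_map[cue].us_paired(phase)
    if not paired:
        return {c: [False] * reps for c in contexts}
    n_pres = reps * len(contexts)
    n_reinforced = int(round(spec.reinforcement_rate * n_pres))
    per_cell, rem = divmod(n_reinforced, len(contexts))
    extra = set(rng.choice(len(contexts), size=rem, replace=False)) if rem else set()
    flags = {}
    for ci, c in enumerate(contexts):
        k = per_cell + (1 if ci in extra else 0)
        cell = [True] * k + [False] * (reps - k)
        rng.shuffle(cell)
        flags[c] = cell
    return flags


def build_phase_design(
    spec: ExperimentSpec,
    phase: Phase,
    seed: int,
    max_consecutive_cue: int = 2,
    max_attempts: int = 10_000,
) -> PhaseDesign:
    """Build one phase's pseudorandomized trial sequence.

    Every cue appears ``n_trials / 8`` times, distributed uniformly over the
    phase's contexts so that the CS-type × context contingency table is
    uniform by construction. US-paired cues (per-phase contingency semantics)
    are reinforced at the spec's rate. The order is a constrained shuffle,
    rejection-sampled until the first and last trials are unreinforced and no
    cue runs longer than ``max_consecutive_cue`` in a row.
    """
    phase = Phase(phase)
    contexts = spec.phase_contexts(phase)
    n_cues = len(spec.cue_ids)
    n_cells = n_cues * len(contexts)
    if spec.n_trials_per_phase % n_cells:
        raise DesignError(
            f"{spec.n_trials_per_phase} trials not divisible by "
            f"{n_cues} cues × {len(contexts)} contexts"
        )
    reps = spec.n_trials_per_phase // n_cells
    rng = np.random.default_rng(seed)

    pool: list[tuple[str, str, bool]] = []
    for cue in spec.cue_ids:
        flags = _assign_reinforcement(spec, phase, cue, contexts, reps, rng)
        for ctx in contexts:
            for r in flags[ctx]:
                pool.append((cue, ctx, r))

    any_reinforced = any(r for _, _, r in pool)
    for _ in range(max_attempts):
        order = rng.permutation(len(pool))
        seq = [pool[i] for i in order]
        if any_reinforced and (seq[0][2] or seq[-1][2]):
            continue
        runs_ok = True
        run = 1
        for prev, cur in itertools.pairwise(seq):
            run = run + 1 if cur[0] == prev[0] else 1
            if run > max_consecutive_cue:
                runs_ok = False
                break
        if runs_ok:
            break
    else:  # pragma: no cover - astronomically unlikely at sane sizes
        raise DesignError("could not satisfy ordering constraints; relax them")

    trials = [
        TrialEvent(
            phase=phase,
            trial_index=i,
            cue_id=cue,
            cs_type=spec.cs_type_map[cue],
            context_id=ctx,
            reinforced=r,
        )
        for i, (cue, ctx, r) in enumerate(seq)
    ]
    return PhaseDesign(phase=phase, trials=trials, seed=seed)


def schedule_onsets(design: PhaseDesign, spec: ExperimentSpec, seed: int) -> PhaseDesign:
    """Assign within-phase onsets (seconds from phase start) to every trial.

    Per trial: context video at t, cue at t+2 s, rating window at t+3 s, US
    (reinforced trials only) at rating offset — preserving the
    trace-conditioning gap between cue offset and US — then an ITI drawn
    uniformly from the spec's jitter bounds. Returns a new ``PhaseDesign``
    with ``total_duration`` set; the input is not modified.
    """
    rng = np.random.default_rng(seed)
    tm = spec.timing
    lo, hi = tm.iti_bounds
    t = 0.0
    trials = []
    for tr in design.trials:
        onset_context = t
        onset_cue = onset_context + tm.context_duration
        onset_rating = onset_cue + tm.cue_duration
        onset_iti = onset_rating + tm.rating_duration
        onset_us = onset_iti if tr.reinforced else None
        iti = float(rng.uniform(lo, hi))
        trials.append(
            replace(
                tr,
                onset_context=onset_context,
                onset_cue=onset_cue,
                onset_rating=onset_rating,
                onset_us=onset_us,
                onset_iti=onset_iti,
                iti_duration=iti,
            )
        )
        t = onset_iti + iti
    return PhaseDesign(
        phase=design.phase, trials=trials, seed=design.seed, total_duration=t
    )


_EVENT_COLUMNS = [
    "onset",
    "duration",
    "event_type",
    "cue_id",
    "context_id",
    "cs_type",
    "reinforced",
    "phase",
]


def events_frame(design: PhaseDesign, spec: ExperimentSpec) -> pd.DataFrame:
    """Long-format events table (one row per context/cue/rating/US event)."""
    if design.trials and design.trials[0].onset_context is None:
        raise DesignError("design has no onsets; call schedule_onsets first")
    tm = spec.timing
    rows = []
    for t in design.trials:
        common = {
            "cue_id": t.cue_id,
            "context_id": t.context_id,
            "cs_type": t.cs_type.value,
            "reinforced": int(t.reinforced),
            "phase": t.phase.value,
        }
        rows.append(
            {"onset": t.onset_context, "duration": tm.context_duration,
             "event_type": "context", **common}
        )
        rows.append(
            {"onset": t.onset_cue, "duration": tm.cue_duration,
             "event_type": "cue", **common}
        )
        rows.append(
            {"onset": t.onset_rating, "duration": tm.rating_duration,
             "event_type": "rating", **common}
        )
        if t.reinforced:
            rows.append(
                {"onset": t.onset_us, "duration": 0.0, "event_type": "us", **common}
            )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_events_tsv(design: PhaseDesign, spec: ExperimentSpec, path) -> None:
    events_frame(design, spec).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise DesignError(f"events table missing columns: {sorted(missing)}")
    return df


def design_from_events(events: pd.DataFrame) -> PhaseDesign:
    """Rebuild a scheduled PhaseDesign from a long-format events table."""
    phase = Phase(events["phase"].iloc[0])
    trials = []
    cue_rows = events[events.event_type == "cue"].sort_values("onset")
    ctx_rows = events[events.event_type == "context"].sort_values("onset")
    rat_rows = events[events.event_type == "rating"].sort_values("onset")
    us_rows = events[events.event_type == "us"]
    if not (len(cue_rows) == len(ctx_rows) == len(rat_rows)):
        raise DesignError("events table has unbalanced context/cue/rating rows")
    ends = list(ctx_rows["onset"].iloc[1:]) + [np.inf]
    for i, ((_, cue), (_, ctx), (_, rat), nxt) in enumerate(
        zip(cue_rows.iterrows(), ctx_rows.iterrows(), rat_rows.iterrows(), ends)
    ):
        onset_us = None
        if cue["reinforced"]:
            hits = us_rows[(us_rows.onset >= rat["onset"])
                           & (us_rows.onset < nxt)]["onset"]
            onset_us = float(hits.iloc[0]) if len(hits) else None
        onset_iti = rat["onset"] + rat["duration"]
        iti = (nxt - onset_iti) if np.isfinite(nxt) else None
        trials.append(
            TrialEvent(
                phase=phase, trial_index=i, cue_id=cue["cue_id"],
                cs_type=CSType(cue["cs_type"]), context_id=cue["context_id"],
                reinforced=bool(cue["reinforced"]),
                onset_context=float(ctx["onset"]), onset_cue=float(cue["onset"]),
                onset_rating=float(rat["onset"]), onset_us=onset_us,
                onset_iti=float(onset_iti),
                iti_duration=float(iti) if iti is not None else None,
            )
        )
    if trials and trials[-1].iti_duration is None:
        # last ITI is not recoverable from events; assume the jitter midpoint
        trials[-1].iti_duration = 8.0
    total = trials[-1].onset_iti + trials[-1].iti_duration if trials else 0.0
    return PhaseDesign(phase=phase, trials=trials, seed=-1, total_duration=total)
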