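"""Simulation and representational-similarity analysis of four-phase fear
acquisition, reversal, and test experiments.

The package generates the full experimental design of a trace fear-conditioning
paradigm (8 cues in 4 contingency types, 16 contexts, 50% reinforcement),
synthesizes BOLD-like volumes with planted item, valence-category, and context
pattern structure, estimates trial-wise responses with least-squares-separate
GLMs, and computes Fisher-z representational-similarity metrics (item
stability, cue generalization, context specificity, reinstatement) through
searchlight mapping, permutation cluster-level FWE inference, and
mixed-effects linking models.
"""

from fearrsa.design import (
    CSType,
    ExperimentSpec,
    Phase,
    PhaseDesign,
    TrialEvent,
    assign_counterbalancing,
    build_phase_design,
    schedule_onsets,
)

__version__ = "0.1.0"


def __getattr__(name):
    # StudyConfig / run_study live in fearrsa.pipeline; importing them lazily
    # keeps `import fearrsa` light (no nibabel/yaml import at package load)
    if name in ("StudyConfig", "run_study"):
        from fearrsa import pipeline

        return getattr(pipeline, name)
    raise AttributeError(f"module 'fearrsa' has no attribute {name!r}")


__all__ = [
    "StudyConfig",
    "run_study",
    "CSType",
    "ExperimentSpec",
    "Phase",
    "PhaseDesign",
    "TrialEvent",
    "assign_counterbalancing",
    "build_phase_design",
    "schedule_onsets",
    "__version__",
]
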