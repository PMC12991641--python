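"""US-expectancy ratings: simulation and group analysis.

After every cue, participants rate how likely a shock is on a 4-point Likert
scale. The generative model is deliberately minimal: a latent phase × CS-type
mean plus a participant random intercept plus trial-level Gaussian noise,
rounded and clipped onto the scale. This is enough to recover orderings and
interactions, which is all the group analysis tests.

The group analysis averages ratings per participant × phase × CS type (four
summary values per phase per participant), fits a random-intercept mixed
model with CS type, phase, and their interaction as fixed effects
(REML, Satterthwaite df), and runs paired Wilcoxon signed-rank post-hoc
tests, Bonferroni-corrected within each comparison family (CS-type pairs
within a phase; phase pairs across CS types).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fearrsa.design import CSType, Phase, PhaseDesign
from fearrsa.lmm import LMMResult, TermTest, anova_lmm

__all__ = [
    "BehaviorModelParams",
    "BehaviorResult",
    "default_expectancy_means",
    "simulate_expectancy",
    "summarize_expectancy",
    "analyze_expectancy",
]


@dataclass
class BehaviorModelParams:
    """Latent generative parameters for simulated US-expectancy ratings.

    ``mean_matrix`` maps (phase, cs_type) to the latent expectancy mean on
    the 1–4 scale; ``participant_sd`` scales a per-participant random
    intercept and ``noise_sd`` trial-level Gaussian noise.
    """

    mean_matrix: dict[tuple[Phase, CSType], float] = field(
        default_factory=lambda: default_expectancy_means()
    )
    participant_sd: float = 0.3
    noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participant_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be ≥ 0")


def default_expectancy_means() -> dict[tuple[Phase, CSType], float]:
    """Latent means mirroring the learned contingencies of the paradigm.

    During acquisition the two US-paired types (CS++, CS+-) are equivalent
    and high, the two unpaired types equivalent and low. During reversal the
    learned ordering is CS++ > CS+- > CS-+ > CS--, with overall expectancy
    highest. The US-free test phases keep a residual ordering at lower
    levels, test_old lowest.
    """
    P, C = Phase, CSType
    return {
        (P.ACQUISITION, C.CS_PP): 3.2, (P.ACQUISITION, C.CS_PM): 3.2,
        (P.ACQUISITION, C.CS_MP): 1.6, (P.ACQUISITION, C.CS_MM): 1.6,
        (P.REVERSAL, C.CS_PP): 3.6, (P.REVERSAL, C.CS_PM): 2.6,
        (P.REVERSAL, C.CS_MP): 2.2, (P.REVERSAL, C.CS_MM): 1.4,
        (P.TEST_NEW, C.CS_PP): 2.8, (P.TEST_NEW, C.CS_PM): 2.2,
        (P.TEST_NEW, C.CS_MP): 1.9, (P.TEST_NEW, C.CS_MM): 1.3,
        (P.TEST_OLD, C.CS_PP): 2.5, (P.TEST_OLD, C.CS_PM): 2.0,
        (P.TEST_OLD, C.CS_MP): 1.7, (P.TEST_OLD, C.CS_MM): 1.2,
    }


@dataclass
class BehaviorResult:
    """Fixed-effect F tests and Bonferroni-corrected Wilcoxon post-hocs."""

    fixed_effects: list[TermTest]
    posthoc: pd.DataFrame
    model: LMMResult | None
    singular: bool


def simulate_expectancy(
    designs: dict[Phase, PhaseDesign],
    params: BehaviorModelParams,
    n_participants: int,
) -> pd.DataFrame:
    """Simulate trial-wise ratings for a cohort.

    rating = clip(round(mean(phase, cs_type) + participant intercept +
    N(0, noise_sd)), 1, 4). One row per cue trial:
    (participant_id, phase, trial_index, cs_type, rating).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be ≥ 1")
    needed = {(Phase(p), t) for p in designs for t in CSType}
    missing = needed - set(params.mean_matrix)
    if missing:
        raise ValueError(f"mean_matrix missing cells: {sorted(str(m) for m in missing)}")
    rng = np.random.default_rng(params.seed)
    lo, hi = 1, 4
    rows = []
    for pi in range(n_participants):
        intercept = rng.normal(0.0, params.participant_sd)
        for phase, design in designs.items():
            phase = Phase(phase)
            for t in design.trials:
                latent = (
                    params.mean_matrix[(phase, t.cs_type)]
                    + intercept
                    + rng.normal(0.0, params.noise_sd)
                )
                rating = int(np.clip(np.round(latent), lo, hi))
                rows.append(
                    {
                        "participant_id": f"sub-{pi:03d}",
                        "phase": phase.value,
                        "trial_index": t.trial_index,
                        "cs_type": t.cs_type.value,
                        "rating": rating,
                    }
                )
    return pd.DataFrame(rows)


def summarize_expectancy(ratings: pd.DataFrame) -> pd.DataFrame:
    """Average ratings per participant × phase × CS type.

    Exactly four summary values per phase per participant; a missing cell is
    an explicit error (the design guarantees every cell is populated).
    """
    out = (
        ratings.groupby(["participant_id", "phase", "cs_type"], as_index=False)["rating"]
        .mean()
        .rename(columns={"rating": "mean_rating"})
    )
    participants = ratings["participant_id"].unique()
    phases = ratings["phase"].unique()
    for p, ph, ct in itertools.product(participants, phases, [t.value for t in CSType]):
        if not ((out.participant_id == p) & (out.phase == ph) & (out.cs_type == ct)).any():
            raise ValueError(f"missing rating cell: participant={p} phase={ph} cs_type={ct}")
    return out


def _wilcoxon_row(x: np.ndarray, y: np.ndarray, label: str) -> dict:
    d = x - y
    if np.allclose(d, 0.0):
        return {"pair": label, "statistic": np.nan, "p_raw": 1.0, "all_tied": True}
    stat, p = stats.wilcoxon(x, y, zero_method="wilcox", method="auto")
    return {"pair": label, "statistic": float(stat), "p_raw": float(p), "all_tied": False}


def analyze_expectancy(summary: pd.DataFrame) -> BehaviorResult:
    """Mixed-model ANOVA plus Wilcoxon post-hocs on the summary table.

    Fits mean_rating ~ cs_type * phase + (1 | participant) by REML with
    Satterthwaite denominator df. Post-hoc families: all CS-type pairs within
    each phase, and all phase pairs (collapsed over CS type); Bonferroni
    correction is applied within each family separately.
    """
    n_participants = summary["participant_id"].nunique()
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    import warnings as _warnings

    if np.ptp(summary["mean_rating"].to_numpy()) == 0.0:
        # constant ratings: the ANOVA is undefined, report inert tests
        model = None
        singular = True
        tests = [
            TermTest(term=t, fstat=np.nan, df_num=np.nan, df_den=np.nan,
                     pvalue=1.0)
            for t in ("cs_type", "phase", "cs_type:phase")
        ]
    else:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            model, tests = anova_lmm(
                summary, "mean_rating", ["cs_type", "phase"], "participant_id"
            )
        singular = model.singular

    rows = []
    pivot = summary.pivot_table(
        index="participant_id", columns=["phase", "cs_type"], values="mean_rating"
    )
    phases = sorted(summary["phase"].unique())
    cstypes = sorted(summary["cs_type"].unique())
    # family 1: CS-type pairs within each phase
    for ph in phases:
        fam = []
        for a, b in itertools.combinations(cstypes, 2):
            fam.append(
                _wilcoxon_row(
                    pivot[(ph, a)].to_numpy(), pivot[(ph, b)].to_numpy(),
                    f"{ph}: {a} vs {b}",
                )
            )
        m = len(fam)
        for r in fam:
            r["family"] = f"cs_type_within_{ph}"
            r["p_bonferroni"] = min(1.0, r["p_raw"] * m)
            rows.append(r)
    # family 2: phase pairs, collapsed over CS types
    by_phase = summary.pivot_table(
        index="participant_id", columns="phase", values="mean_rating", aggfunc="mean"
    )
    fam = []
    for a, b in itertools.combinations(phases, 2):
        fam.append(
            _wilcoxon_row(by_phase[a].to_numpy(), by_phase[b].to_numpy(), f"{a} vs {b}")
        )
    m = len(fam)
    for r in fam:
        r["family"] = "phase_pairs"
        r["p_bonferroni"] = min(1.0, r["p_raw"] * m)
        rows.append(r)

    posthoc = pd.DataFrame(rows)[
        ["family", "pair", "statistic", "p_raw", "p_bonferroni", "all_tied"]
    ]
    return BehaviorResult(
        fixed_effects=tests, posthoc=posthoc, model=model, singular=singular
    )
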