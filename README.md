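# fearrsa

Simulation and representational-similarity analysis (RSA) of a four-phase
context-dependent fear conditioning fMRI experiment — a complete,
planted-truth-validated pipeline from experimental design to group
inference.

The experiment it models: participants see 8 cue images (four contingency
types, two items each) embedded in 16 context videos across four phases —
**acquisition** (some cues predict an aversive outcome), **reversal** (half
the contingencies flip), **test_new** (novel contexts, no outcomes), and
**test_old** (return to the original contexts). The scientific questions
are representational: do threat cues generalize to each other more than
safe cues? Does item-specific coding sharpen for cues whose meaning
changed? Is context coding most distinct during reversal, and does that
context specificity predict later memory reinstatement?

Because no real data ships with a method like this, the package is built
around a synthetic-data generator that *plants* those effects at known
strengths, so every stage of the analysis can be validated against ground
truth: exact oracles for the estimators, recovery rates across simulated
cohorts for the inferences, and false-positive calibration under a null
generator. See [`docs/methods.md`](docs/methods.md) for the full model.

## Pipeline

1. **Design** (`fearrsa.design`) — balanced, counterbalanced trial
   schedules: 128 trials/phase, 50% reinforcement, exact cue × context
   balance, TSV event files.
2. **Behavior** (`fearrsa.behavior`) — simulated US-expectancy ratings;
   mixed ANOVA + Wilcoxon post-hocs.
3. **Synthetic BOLD** (`fearrsa.synthetic_bold`, `fearrsa.hrf`) —
   orthogonal item/valence/context pattern banks, double-gamma HRF,
   confounds, AR(1) noise.
4. **LSS beta series** (`fearrsa.lss`) — least-squares-separate per-trial
   GLMs for cue and context models.
5. **RSA** (`fearrsa.rsa`) — Fisher-z similarity metrics: item stability,
   cue generalization, context stability/generalization/specificity,
   cross-phase reinstatement.
6. **Searchlight** (`fearrsa.searchlight`) — batched cubic searchlights
   over the brain mask.
7. **Inference** (`fearrsa.inference`) — sign-flip permutation
   cluster-FWE, Bonferroni/FDR families, ROI extraction, and
   random-intercept mixed models with Satterthwaite degrees of freedom
   (validated against R's `lmerTest`).
8. **Pipeline** (`fearrsa.pipeline`, `fearrsa.cli`) — `StudyConfig`,
   seed management, NIfTI/TSV I/O, and the end-to-end `run_study`.

## Worked example

Run a small end-to-end study (6 participants, pattern-level simulation,
200 permutations — about 2 minutes):

```bash
fearrsa run-all --pattern-level --participants 6 --permutations 200 \
    --seed 42 --out scratch/demo
fearrsa report --study scratch/demo
```

which prints (abbreviated):

```json
{
  "group_mean_contrast": {
    "acq_cue_generalization_csp_gt_csm": 0.0812,
    "rev_item_stability_change_gt_consistent": 0.0773,
    "ctx_specificity_reversal_gt_acquisition": 0.2173,
    ...
  },
  "significant_clusters": { "ctx_specificity_reversal_gt_acquisition": 1, ... },
  "behavior_terms": { "cs_type": 5.9e-51, "phase": 3.6e-22, "cs_type:phase": 3.8e-18 }
}
```

All seven planted contrasts have positive group means, as generated. At
n = 6 only the strongest (context specificity) survives cluster-FWE
correction — smaller cohorts are honestly underpowered. The validation
studies (below) use n = 10–12, where all planted effects are recovered in
≥95% of cohorts.

The study directory also contains `behavior/` (ratings, ANOVA, post-hocs),
`searchlight/` (group metric maps), `inference/` (cluster tables,
significance masks, ROIs), `reinstatement/` (ROI reinstatement tables and
mixed-model results), and `manifest.json` (config hash + artifact
checksums; identical configs reproduce byte-identical tables).

### Stage-by-stage on disk

```bash
fearrsa init-config study.yaml                     # editable defaults
fearrsa simulate --participant 0 --out scratch/p0 --seed 7
fearrsa fit-lss --bold scratch/p0/acquisition_bold.nii.gz \
    --events scratch/p0/acquisition_events.tsv \
    --confounds scratch/p0/acquisition_confounds.tsv \
    --model-kind cue --out-prefix scratch/p0/acq_cue
fearrsa rsa --betas scratch/p0/acq_cue --model-kind cue \
    --metric cue_generalization --out scratch/p0/gen.csv
fearrsa searchlight --betas scratch/p0/acq_cue --model-kind cue \
    --metric generalization --groups-pos "CS++,CS+-" --groups-neg "CS-+,CS--" \
    --out scratch/p0/gen_map.nii.gz
fearrsa infer --maps m1.nii.gz --maps m2.nii.gz ... --out clusters.json \
    --comparisons 2
```

### Python API

```python
from fearrsa import StudyConfig, run_study

cfg = StudyConfig(n_participants=6, n_perm=200, base_seed=42,
                  out_dir="scratch/demo")
manifest = run_study(cfg, use_full_bold=False)  # True → full BOLD + LSS
```

## Validation

The test suite is oracle-first:

- **LSS** betas match brute-force normal equations to 1e-8 on randomized
  instances, and recover planted patterns exactly in the noiseless
  homogeneous case;
- **RSA** metrics match a brute-force pair-enumeration oracle on small
  random similarity matrices;
- **searchlight** values match whole-ROI metrics on the member voxels;
- the **mixed model** reproduces R `lmerTest` estimates, Satterthwaite
  degrees of freedom, and F statistics digit-for-digit on frozen datasets;
- **recovery**: across repeated simulated cohorts, the planted cue
  generalization, item stability, context specificity, and
  specificity × reinstatement linking effects are recovered in ≥95% of
  cohorts;
- **error control**: under a null generator, cluster-FWE rejections sit at
  the nominal 5% rate (within the binomial confidence band), as do the
  mixed-model term tests.

Reproduce:

```bash
python -m pytest -o addopts= -p no:cacheprovider -q     # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` runs the full-scale validation studies
(20 recovery cohorts at n = 12, 200 null cohorts, exact oracles) and
writes a JSON summary; it takes roughly 10 minutes.

## Layout

```
src/fearrsa/        package modules (design, behavior, hrf, synthetic_bold,
                    lss, rsa, searchlight, inference, lmm, pipeline, cli)
tests/              pytest suite, including tests/test_acceptance.py
scripts/acceptance.py   full-scale validation study runner
docs/methods.md     model, estimators, and design decisions in detail
```
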