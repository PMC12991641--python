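# Methods

This package simulates and analyzes a four-phase context-dependent fear
conditioning experiment at desk scale. Everything below — the design, the
generative model, the estimators, and the inference chain — is implemented
in `src/fearrsa/`; this note states the model precisely, explains the
numerical choices, and is candid about where the simulation is a deliberately
simplified stand-in for real fMRI.

## 1. Experimental design (`fearrsa.design`)

Four phases in fixed order: **acquisition**, **reversal**, **test_new**,
**test_old**, 128 trials each. Eight cue images are split into four
contingency (CS) types with two items each:

| CS type | acquisition | reversal | tests (carried valence) |
|---------|-------------|----------|-------------------------|
| CS++    | US-paired   | US-paired| threat |
| CS+-    | US-paired   | safe     | safe   |
| CS-+    | safe        | US-paired| threat |
| CS--    | safe        | safe     | safe   |

Sixteen context videos are partitioned into set A (4, acquisition), set B
(4, reversal), and set C (8, test_new); test_old reuses A∪B. Each phase
presents every cue 16 times, uniformly over that phase's contexts — 4
occurrences per cue × context cell in the 4-context phases, 2 in the
8-context phases. US-paired cue types are reinforced on exactly 50% of their
trials, balanced within each cue × context cell (2 of 4); first and last
trials of a phase are never reinforced, no cue repeats more than twice in a
row, and test phases deliver no US. Trial timing: context video 2 s → cue
1 s → rating window 2.5 s → US (reinforced trials only, at rating offset;
a trace interval separates cue offset and US) → ITI uniform on [7, 9] s.

Counterbalancing rotates the cue-to-CS-type assignment and the context
partition deterministically with participant index (Latin-square-style
rotation), so cohort-level confounds between specific images and conditions
cancel.

## 2. Behavioral model (`fearrsa.behavior`)

Trial-wise US-expectancy ratings on a 1-4 scale are generated as
`clip(round(mean(phase, cs_type) + participant_intercept + noise), 1, 4)`.
The default latent means encode acquisition of the +/- discrimination, its
reversal, and generalization to new contexts. Analysis: participant ×
phase × CS-type cell means, a `cs_type * phase` random-intercept mixed
ANOVA, and Wilcoxon signed-rank post-hocs Bonferroni-corrected within two
families (CS-type pairs within each phase; phase pairs).

## 3. Synthetic BOLD (`fearrsa.synthetic_bold`)

**Geometry.** An ellipsoidal "brain" mask in an 18 × 18 × 12 grid of 2.5 mm
isotropic voxels (≈2,500 in-mask voxels), TR 2.53 s. This is a package
choice to keep full studies tractable on a laptop; all analysis code is
resolution-agnostic.

**Pattern bank.** For each participant, one baseline, 8 item, 2 valence
(threat/safe), and 16 context patterns are drawn as Gaussian vectors over
the masked voxels and QR-orthogonalized (scaled to unit voxel variance).
Orthogonality makes planted effect sizes interpretable: every similarity
metric's expectation is a ratio of planted weights, uncontaminated by random
pattern overlap.

**Trial patterns.** The cue-event pattern of trial *t* in phase *p* is

```
baseline + w_item(p, cs) · P_item(cue) + w_cat(p, cs) · P_valence(v) + w_ctx(p) · P_context(ctx) + ε
```

where `v` is the cue's *current* valence under that phase's contingencies
(CS-+ loads the safe pattern in acquisition but the threat pattern from
reversal onward), and ε is i.i.d. trial noise. The context-epoch pattern
contains only baseline + context components. Default weights plant the
study's findings:

- `w_cat` = 0.6 (threat) vs 0.2 (safe) in acquisition and reversal, 0.15 in
  the tests → CS+ cues generalize more than CS- cues while contingencies are
  active;
- `w_item` = 0.5 everywhere, raised to 0.8 in reversal for the
  contingency-changing cues (CS-+, CS+-), lowered to 0.4 at test → item
  coding sharpens for cues whose meaning changed;
- `w_ctx` = 0.4 / 0.8 / 0.4 / 0.4 across phases → context coding is most
  distinct during reversal;
- item and valence patterns are shared across phases (reuse flags), so
  cross-phase reinstatement is planted; a `null` spec zeroes all structure.

**Time series.** Each voxel's series is the sum over trials of the
HRF-convolved cue boxcar (1 s) times its planted pattern value, the
analogous context-epoch (2 s) response, confound series (six random-walk
motion parameters, AR(1) WM and CSF signals) times per-voxel loadings, a
per-voxel linear drift, and AR(1) Gaussian scan noise. The HRF is the
canonical double-gamma (peak 6 s, undershoot 16 s, ratio 1:6), implemented
directly in `fearrsa.hrf` and shared verbatim between the generator and the
GLMs.

**What is deliberately not modeled:** spatial noise correlation,
physiological noise spectra, susceptibility dropout, motion-by-activation
interaction, nonlinear HRF saturation, and between-region heterogeneity.
The generator's purpose is planted-truth validation of the analysis chain,
not realism.

## 4. Trial-wise estimation: LSS (`fearrsa.lss`)

Each trial's response is estimated with a least-squares-separate GLM: the
target trial gets its own convolved regressor, all other same-family trials
share one, plus US impulse (conditioning phases), 6 motion + WM + CSF
confounds, a 128 s-cutoff cosine drift basis, and an intercept. Cue models
(1 s boxcars) and context models (video-onset-to-cue-onset epochs) are
separate families.

**Exactness and bias.** With noiseless data and *homogeneous* trial
amplitudes, LSS recovers planted patterns to machine precision (tested).
With heterogeneous amplitudes — the realistic case, and the default here —
the shared other-trials column is misspecified; the resulting misfit leaks
into the target beta mainly through its projection onto the confound and US
columns. The package treats this as a property of the method, not a bug:
per-trial correlation with the planted truth stays above 0.99 at the default
geometry (tested), and every downstream validation uses LSS outputs, biases
included. Estimation itself is verified against brute-force normal equations
to 1e-8 on randomized instances.

## 5. RSA metrics (`fearrsa.rsa`)

All metrics are means of Fisher-z-transformed Pearson correlations
(`atanh(r)`) over explicit pair masks, by default restricted to
unreinforced trials so US-evoked responses cannot masquerade as cue
similarity:

- **item stability** — same-item pairs, per cue, averaged to CS type;
- **cue generalization** — same-CS-type different-item pairs (optionally
  pooled, e.g. CS+ = {CS++, CS+-});
- **context stability / generalization / specificity** — within-context,
  between-context, and their difference (an exact decomposition);
- **item / generalized reinstatement** — cross-phase same-item or
  same-CS-type-different-item pairs, per CS type.

Every metric is tested against a brute-force pair-enumeration oracle.

## 6. Searchlight (`fearrsa.searchlight`)

Cubic searchlights of half-width `round(radius_mm / voxel_size)` (5 mm at
2.5 mm voxels → 125-voxel boxes). A center is retained when ≥50% of its
*ideal* box is in-mask — voxels lost to the volume edge count against the
fraction exactly like voxels outside the mask. Metric evaluation is batched:
local RSMs for 128 centers at a time via a single padded matrix product.
Searchlight values equal the corresponding whole-ROI metric computed on the
member voxels (tested center-by-center).

## 7. Group inference (`fearrsa.inference`)

One-sample t maps over participant contrast maps; one-sided cluster-forming
threshold p < 0.001; max-cluster-size null from sign-flipping permutations;
`p_fwe = (1 + #{null ≥ observed}) / (1 + n_perm)`; 26-connectivity.
Alpha families follow the comparison structure: 0.05/2 = 0.025 for the two
acquisition contrasts, 0.05/4 = 0.0125 for the four reversal contrasts.
ROIs are connected components of significant clusters with volume
≥ 1500 mm³ (96 voxels at 2.5 mm); overlapping ROIs from different source
maps keep the larger one (logged). Linking analyses are random-intercept
mixed models with Satterthwaite degrees of freedom (validated digit-for-digit
against R's lmerTest on frozen datasets) and Benjamini-Hochberg FDR within
declared families.

## 8. Study scales and validation studies

Problem sizes are package choices, selected so a full simulated study runs
in minutes:

- default study: 12 participants, 18 × 18 × 12 grid, 128 trials/phase;
- repeated-cohort recovery studies run at *beta-pattern level* (planted
  patterns + Gaussian estimation noise fed directly to RSA), because the
  BOLD → LSS link is verified separately and exactly;
- the specificity-reinstatement linking effect requires participant-level
  covariation, which fixed weights cannot produce: the linked cohort
  generator scales the reversal context weight and the CS-+ item weight
  jointly by a per-participant gain. A side effect is that the gain inflates
  reversal pattern variance and thereby *dilutes* the uncoupled CS+-
  reinstatement; the planted and tested signature is the simple-slope
  difference (CS-+ > CS+-), which is exactly what the interaction F tests;
- the null false-positive study uses a reduced grid and a 0.01
  cluster-forming threshold: at 0.001 on a small grid, max cluster sizes are
  concentrated on {0, 1, 2} and the test is ultra-conservative by
  discreteness alone. The analysis default remains 0.001.

## 9. Numerical choices

- correlations are clipped to |r| ≤ 1 − 1e-12 before `atanh`; zero-variance
  patterns yield NaN pairs that are excluded from mask means (warned);
- the REML profile is optimized on a log-variance-ratio grid with Brent
  refinement; boundary fits (τ² → 0) warn and coincide with OLS;
- QR sign conventions are fixed against the generating Gaussian draw so
  pattern banks are reproducible across BLAS implementations;
- all seeds derive from a single base seed via a documented splitting rule
  (`participant_seed`), and `run_study` with an identical config reproduces
  byte-identical metric tables.

## 10. Limitations

The simulation validates the *analysis machinery*, not biological claims.
Effect sizes are planted, noise is simplistic, and the geometry is far
smaller than a brain. Negative results at desk scale (e.g., a contrast
failing to reach cluster significance with 6 participants) say nothing
about the method at realistic scale; the acceptance studies therefore
report recovery *rates* across cohorts at stated sizes rather than single
runs.
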