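# Methods

`csfstage` implements a cerebrospinal-fluid (CSF) biomarker staging
pipeline for Alzheimer's disease: per-biomarker abnormality mixtures,
event-based inference of the order in which biomarkers become abnormal
(with support for multiple subtypes, each with its own ordering),
cross-validated model selection, per-subject staging, and the downstream
statistics that establish whether the resulting stages are clinically
useful.  Because the cohorts such analyses are run on are access-restricted,
the package ships a first-class synthetic-cohort generator that emulates
their statistical structure, so the entire pipeline is testable against
planted ground truth.

## The model

Each biomarker is a binary "event": it switches once, irreversibly, from a
normal to an abnormal regime.  Events occur in a fixed ordering
S = (s(1), ..., s(N)); a subject at stage k ∈ {0..N} has exactly the first
k events in the abnormal regime (stage 0 is the biomarker-negative stage).
Writing p_A(x_i) and p_N(x_i) for the abnormal/normal component densities
of subject measurement x_i, the stage-marginalized subject likelihood under
a uniform stage prior is

    P(x | S) = 1/(N+1) · Σ_{k=0}^{N} Π_{i≤k} p_A(x_{s(i)}) · Π_{i>k} p_N(x_{s(i)})

and a C-subtype model mixes subtype-specific orderings with fractions f_c:
P(x) = Σ_c f_c P(x | S_c).  All likelihood computations run in log space
(stable for N ≤ 20); zero densities are handled as -inf log-terms, and a
subject whose every stage term vanishes yields -inf with a warning.

Stage posteriors are proportional to f_c P(x | S_c, k); the MAP stage
breaks exact ties toward the lower stage (fewer abnormal calls), and
equal-likelihood orderings resolve lexicographically.

## Preprocessing

Raw biomarker values are z-scored against a biomarker-negative reference
group (by default the `reference_flag` column, otherwise cognitively
unimpaired amyloid-negative participants older than 60), and inverted where
raw abnormality is a decrease (the Aβ42/40 ratio) so that higher z always
means more abnormal.  Each biomarker's z-distribution is then modeled as a
two-component Gaussian mixture.  Component *densities* — not posterior
probabilities — feed the sequence likelihood: the mixing weight enters
every stage term as the same per-subject constant and cancels from all
ordering comparisons.

Two estimation details matter in practice:

- **Reference anchoring.** With a reference group available, the normal
  component's mean is pinned to the reference mean and reference subjects
  are treated as labeled normal observations; EM estimates the normal sd,
  the abnormal component and the weight.  A fully free EM (available via
  `anchor=None`) lets the normal component drift off the reference anchor,
  which is the main way adjacent events get misordered.  The normal sd is
  deliberately *not* pinned: the reference subsample's sd estimate carries
  ~10% sampling noise at n ≈ 60, and pinning it lets the abnormal
  component absorb the normal bulk.
- **Joint refinement.** Marginal per-biomarker two-Gaussian fits are weakly
  identified where the components overlap, and the residual density error
  is systematic: in cross-validated comparisons a second subtype ordering
  can absorb it and "generalize", so model selection hallucinates subtypes
  that are pure estimation artifacts (with exact generating densities the
  artifact vanishes identically).  The full fit therefore interleaves
  sequence estimation with mixture refinement: after the initial fit, each
  biomarker's components are re-estimated from the model's own per-event
  abnormality posteriors, which pool information across biomarkers through
  the subject's stage.  The sequence fit is warm-started between rounds
  (five by default) so that subtype structure found early — including a
  genuinely present minor subtype — is tracked rather than blurred away or
  rediscovered.  EM tolerance is 1e-6 per observation, at most 500
  iterations, with a component-sd floor of 0.05 z.

Analysis is complete-case: subjects missing any panel biomarker are
excluded from fitting and staging with a logged count.

## Ordering inference

Single subtype: 25 (default) random restarts of steepest-ascent
pairwise-swap hill climbing, followed by Metropolis–Hastings over orderings
(symmetric two-position swap proposal, 100,000 iterations, thinning 10 by
default; all reducible).  The retained samples estimate the positional
confusion matrix — the probability that each biomarker occupies each
sequence position — and support posterior-averaged out-of-sample
likelihoods.  More subtypes: hierarchical initialization (random bisection
of a cluster of the (C-1)-subtype solution, several trials), then EM
alternation of soft subject-to-subtype assignment and responsibility-
weighted ordering ascent until the total log-likelihood changes by less
than 1e-6 (at most 100 alternations), then joint MCMC with fractions held
at their EM estimates.  A seed is mandatory; all randomness flows through
one generator per fit.

`brute_force_ml_ordering` provides the exact argmax over all N!
permutations for N ≤ 8 and serves as the oracle for the stochastic search.

## Model selection

CVIC (cross-validation information criterion) is −2 × the summed held-out
log-likelihood over stratified k folds (k = 10 by default; folds stratified
by the MAP stage of a preliminary greedy full-data fit).  The entire
pipeline — z-scoring, mixtures with refinement, sequences — is refit inside
each training fold, so held-out subjects never influence any fitted
quantity; a `global_mixtures` switch reproduces the alternative convention
of fitting mixtures once on the full sample.  Held-out likelihood is
averaged over the retained ordering posterior: evaluating at a single
point-estimate ordering denies a one-subtype model its ordering
uncertainty while a multi-subtype mixture keeps averaging through its
components, which biases the comparison toward more subtypes.

The subtype count is the smallest C whose CVIC lies within ΔCVIC = 6 of the
minimum and whose median per-fold held-out log-likelihood is not worse than
any larger candidate's by more than 3 (the same slack expressed on the
log-likelihood rather than deviance scale).  ΔCVIC = 6 is the conventional
strong-evidence threshold on a deviance scale and operationalizes "similar
fit, lower complexity".

Biomarker-set optimization enumerates every subset of a declared removable
set (2^m candidates, subsets leaving fewer than two markers skipped) and
keeps the panel with minimal one-subtype CVIC.  Note that held-out
log-likelihoods of panels with different biomarker counts differ mostly by
the marginal entropy of the extra dimensions, so cross-size comparisons
systematically favor smaller panels; within a size class the comparison is
meaningful.  The procedure reproduces the published comparison convention
as-is.

## Validation statistics

- **Stage trajectories**: per-stage mean/sd and a tricube-weighted local
  linear smoother (span 0.75) over stage as a numeric axis; two-sided
  rank-sum tests on contiguous stage pairs, Benjamini–Hochberg adjusted
  over the pair family (groups with n < 2 skipped with a warning).
- **Dichotomous prediction**: rank-formulation AUC of the ordinal stage
  predictor; Youden-optimal stage cutoff (ties to the lowest stage);
  seeded percentile bootstrap CIs (2,000 resamples by default).
- **Ordinal prediction**: cumulative-logit proportional-odds model with
  stage as the sole predictor, fit by penalized ML (ridge 1e-4 engaged
  only when complete separation is detected, flagged in the result);
  per-stage category probabilities, modal category per stage, and a
  concordance index computed over all usable pairs with bootstrap CI.
  P(abnormal | z) of a fitted mixture is monotone in z over the clinically
  relevant range; when sd_A > sd_N it turns up again in the far-left tail,
  a property of any broad-vs-narrow Gaussian pair.
- **Longitudinal rates**: per-subject OLS slope of value on time; subjects
  with fewer than two usable visits excluded with a logged count.
- **Stage stability**: baseline × follow-up transition matrix with %
  stable / progressed / regressed and the share of progressors advancing
  exactly one stage.
- **Progression**: Kaplan–Meier curves with Greenwood CIs per stage group
  (0, 1–3, 4–5), median progression times, and a Cox proportional-hazards
  model (Efron ties) for the high (4–5) vs positive-low (1–3) contrast,
  optionally adjusted for age, sex and baseline clinical status.  Zero
  events in either compared group make the partial likelihood monotone;
  the hazard ratio is then reported as undefined rather than estimated.

## Synthetic cohorts

The generator plants: one ordering per subtype with subtype fractions; a
baseline stage distribution (default: the fractions 29.1 / 8.2 / 12.4 /
11.5 / 20.4 / 18.3% over stages 0–5 of a 426-subject cohort); biomarker
emissions on a latent abnormality z scale — normal component N(0,1),
abnormal N(3.0, 1.5²) per biomarker by default, a separation consistent
with the multi-sigma stage-wise group differences such panels show — mapped
to the raw scale with a signed affine map (negative sign for the decreasing
Aβ42/40 ratio); stage-linked outcomes (amyloid-PET positivity logistic in
stage − 1.5, tau-PET in stage − 3.5, steepness 4, so the Youden-optimal
cutoffs are stages 2 and 4 by construction; an ordinal diagnosis from a
noisy latent stage; continuous Centiloid/SUVR/cognitive values linear in
stage); progression hazards 0 / 0.02 / 0.15 per year for stage groups
0 / 1–3 / 4–5 with exponential event times and uniform censoring at 5
years (no stage-0 progressors, planted hazard ratio 7.5); follow-up visits
at 2.05 ± 0.22 years with stay / advance / regress probabilities
0.832 / 0.139 / 0.029, clipped at the stage bounds; and a reference flag on
half of the stage-0 subjects.

### Cohort table columns

One row per subject-visit; written/read as plain CSV (TSV for `.tsv`
paths).  A schema mapping can rename arbitrary source columns onto these
roles at read time.

| column | meaning |
|---|---|
| `subject_id` | unique subject identifier |
| `visit_time` | years from baseline (0 at baseline) |
| `Ab42_40`, `pT217_T217`, `pT205_T205`, `MTBR_tau243`, `np_tau` (+ optional `pT181_T181`, `pT231_T231`) | raw biomarker values |
| `age`, `sex`, `apoe4` | covariates (years; F/M; ε4-carrier 0/1) |
| `diagnosis` | CU− / CU+ / MCI+ / ADD+ |
| `amyloid_pet_status`, `centiloids` | amyloid-PET positivity (0/1) and Centiloid value |
| `tau_pet_status`, `tau_suvr` | tau-PET positivity (0/1) and SUVR |
| `cognitive_composite` | global cognitive composite (z) |
| `time_to_event`, `event` | years to clinical progression / censoring; event indicator |
| `reference_flag` | member of the z-score reference group |
| `truth_stage`, `truth_subtype` | planted ground truth (synthetic cohorts only) |

What the generator does **not** emulate: assay chemistry and platform
differences, covariate–biomarker confounding beyond stage, practice
effects, non-Gaussian tails, or informative missingness.  Passing tests
therefore demonstrate correctness of the algorithms under the model's own
assumptions, not robustness to real-data violations of them.

## Problem sizes and sampler settings used in the test suite

The test suite and the reproduction script run at reduced sampler settings
(typically 6 greedy start points, 500–2,000 MCMC iterations, 3-fold or
10-fold cross-validation) — sizes at which the stochastic search still
provably attains the exhaustive optimum on five-event problems, chosen so
the full battery (20-seed recoveries, 50-seed coverage, prevalence sweeps)
completes on a single CPU in minutes.

## Known limitations

- The joint mixture/sequence refinement is a generalized EM on the full
  model; it has no global-optimality guarantee, and with very weak
  separation it inherits the identifiability limits of the underlying
  two-Gaussian fits.
- Subtype fractions are held fixed during MCMC; ordering uncertainty is
  sampled, fraction uncertainty is not.
- Cross-size panel comparisons by raw CVIC are entropy-dominated (above).
- The proportional-odds model assumes a common stage coefficient across
  category thresholds; no covariates are included by default.
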