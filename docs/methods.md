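# Methods

## Model

The event-based model treats disease progression as a fixed sequence
*S = (s(1), …, s(N))* of biomarker-abnormality events shared by the whole
cohort. A subject at latent stage *k* ∈ {0, …, N} has experienced events
*s(1)…s(k)* and none of the later ones. Measurements are conditionally
independent given the stage, so the data likelihood of a sequence is

L(S) = ∏_j (N+1)⁻¹ Σ_k ∏_{i≤k} p(x_{s(i),j}|E) ∏_{i>k} p(x_{s(i),j}|¬E),

with a uniform prior over stages (no a priori staging information). All
likelihood computation is in the log domain: per-subject cumulative log-sums
over sequence positions and a log-sum-exp over stages make one sequence
evaluation O(J·N). The same J×(N+1) stage-wise log-joint kernel
(`sequence_inference.stage_log_joint`) drives both the sequence likelihood
and patient staging, so the two are consistent by construction rather than
by numerical agreement.

Assumptions worth keeping in mind: a single ordering for all subjects,
binary event status (no partial abnormality), conditional independence of
biomarkers given stage, and no missing measurements.

## Event distributions

Each biomarker's *p(x|E)* and *p(x|¬E)* are the components of a two-normal
mixture fitted to all subjects jointly by EM, with each component SD bounded
by the sample SD of the corresponding diagnostic group (normal ≤ SD of CN,
abnormal ≤ SD of AD). The bound is enforced by projection at each M-step;
because the weighted M-step objective is unimodal in the SD for a fixed
mean, clipping is the exact constrained maximiser and the observed-data
log-likelihood is non-decreasing across iterations (asserted in tests).
Initialisation is deterministic: normal component from the CN group mean,
abnormal from the AD group mean, weight from the CN fraction, plus a fixed
set of tail-anchored starting points (components anchored on the most-normal
/ most-abnormal data fractions) that guard against the coincident-components
local optimum when one component carries few subjects; the best final
constrained likelihood wins. The whole fit is reproducible bit-for-bit.

**Variance structure.** By default the two components share one SD, bounded
by the smaller of the two group SDs (which satisfies both per-component
bounds). The unequal-variance mixture is available (`sd_structure="free"`),
but it is weakly identified when the components overlap substantially: its
likelihood is then maximised by solutions that carve the data bulk with one
narrow component, which respect the SD bounds yet misplace both means, and
ordering recovery collapses. We verified this directly — on the default
synthetic cohort (2-SD separation) free-SD fits give median Kendall tau
≈ 0.5 against the generating order versus ≈ 0.98 for tied fits, while an
oracle with the true SDs gives ≈ 0.99 — so tied variances are the default
and the free structure is recommended only for well-separated biomarkers.

The mixing weight serves only fitting and descriptive cut points; the
sequence likelihood conditions on event status, with the stage prior taking
the weight's place. Densities are floored at 1e-300 before logs so extreme
outliers stay finite; at realistic values the floor is never active. The
cut point reported for a biomarker is the value between the component means
where the posterior probability of abnormality is 0.5 (mixing weight
included), solved by bracketed root finding; it is descriptive only — the
model never thresholds.

## Sequence search and uncertainty

`most_likely_sequence` runs greedy ascent from `n_starts` (default 10)
random permutations: all N(N−1)/2 pairwise swaps are evaluated per step and
the best strictly-improving swap applied, taking the lexicographically first
pair on ties, until a local optimum; the best optimum across starts is
returned. On problems small enough to enumerate (N ≤ 5) the result matches
the exhaustive argmax in all seeded tests.

`mcmc_sample` runs Metropolis sampling with a uniform random-transposition
proposal (symmetric, so the acceptance ratio is the bare likelihood ratio).
Defaults for full runs are 100,000 burn-in plus 1,000,000 retained samples;
the test profile uses 1,000 + 10,000. The positional variance matrix —
entry (event, position) is the fraction of retained samples with that event
at that position — is doubly stochastic by construction and is rendered with
events ordered by the ML sequence, greyscale 0 → white, 1 → black. With
hundreds of subjects the posterior over orderings is typically very
concentrated (likelihood ratios are products over subjects), so low MCMC
acceptance rates are expected and flagged only when literally zero.

`bootstrap_sequences` re-fits the event distributions and re-runs the search
on B (default 100) with-replacement resamples of subjects; replicates use
independent substreams of the master seed, so enlarging B extends rather
than reshuffles the replicate list. A resample with fewer than two CN or
two AD subjects (or a degenerate fit) is redrawn, with a cap on redraws.
Bootstrap diagrams absorb distribution-fit uncertainty and are at least as
diffuse as the MCMC diagrams on the same data (asserted on synthetic data).

## Staging and diagnostics

A subject's stage is the argmax of the N+1 stage log-joints (lowest stage on
ties — the conservative choice, avoiding inflated severity); the normalised
stage posterior is returned alongside. Longitudinal consistency flags a
subject only when the follow-up stage drops below baseline by more than an
uncertainty band: the band half-width at stage k is the smallest
neighbourhood of the event's ML position whose positional-variance mass
reaches `band_mass` (default 0.95). This band is this package's
operationalisation of sequence uncertainty, labelled as such in output; it
is not a formally derived model quantity.

Stage-threshold classification declares a subject positive when stage ≥ t,
sweeps t over 0..N+1, and reports the operating point maximising balanced
accuracy (mean of sensitivity and specificity; lowest threshold on ties,
favouring sensitivity). AUC is the Mann-Whitney rank statistic with ties
counted one half, identical to the trapezoid area under the swept ROC
points (asserted to 1e-12, and cross-checked against scikit-learn in
tests). Converter/stable cohort construction (follow-up windows, censoring)
is the caller's responsibility; the module is window-agnostic.

## Synthetic cohorts

`synthetic_data.generate_cohort` draws, per subject, a diagnostic label, a
true stage from the label's stage distribution, and then each biomarker
from its abnormal component if its sequence position is ≤ the stage, else
its normal component — exactly the generative reading of the model. The
defaults encode the study conditions the package is validated under:

- 14 events; identity ground-truth ordering; all events "increase".
- Component separation 2 SDs (means 0 and 2, both SDs 1) — a realistic
  overlap for CSF and volumetric markers; tests also use 3–8 SDs where a
  cleaner signal is the point.
- Group sizes CN 97 / MCI 135 / AD 68 (J = 300), mirroring the diagnostic
  proportions of a typical sporadic Alzheimer's cohort.
- Control contamination 1/3: that fraction of CN subjects is drawn from
  nonzero stages (uniform over stages 1–6, the presymptomatic range where
  CSF and atrophy-rate events live).
- Patient misdiagnosis 0.1: that fraction of AD-labelled subjects sits at
  stage 0; the rest concentrate on the last four stages with half at the
  final stage.
- MCI stages follow a triangular bump peaked at the middle stage.

All distributions are user-overridable, and `generate_staged_subjects`
places subjects at exact stages for staging checks. `generate_followup`
re-draws biomarkers at incremented stages (capped at N) for longitudinal
tests.

What the generator does **not** emulate: correlated noise across biomarkers
(the model's conditional-independence assumption is exactly true in the
synthetic data), subject-specific orderings, gradual sigmoid trajectories,
covariate effects, and missing data. Passing tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to their violation in real cohorts.

## Numerical and design choices

- Natural log for CSF tau transforms; volumes stored as percent of total
  intracranial volume (×100). Both only rescale the fitted mixtures.
- Amyloid subgrouping uses the raw pg/ml value (strictly < 192), not the
  transformed one.
- Missing biomarker values are unsupported; the reader either rejects
  (strict, default) or drops (lenient, logged) incomplete rows.
- Greedy tie-break: strict improvement required; equal-best swaps resolve to
  the lexicographically first pair. Stage ties resolve to the lowest stage;
  balanced-accuracy ties to the lowest threshold.
- Degenerate inputs: all-equal likelihood tables yield an arbitrary ordering
  with an explicit "fully degenerate" warning; identical mixture components
  make the cut point an error, not a number.
- Test problem sizes (e.g. 10 seeds × J = 300 for ordering recovery, 60,000
  MCMC samples for the sampling-accuracy check) were chosen to keep the
  whole suite at a few minutes while leaving comfortable Monte-Carlo margin.

## Known limitations

- A single ordering for the whole cohort; heterogeneous subgroups show up
  only as diffuse positional variance, not as alternative sequences.
- MCMC positional variance holds the fitted distributions fixed and so
  understates total uncertainty; the bootstrap overstates it. Read them as
  a bracket.
- The longitudinal-consistency band is a declared convention (see above).
- Cox proportional-hazards modelling of conversion is out of scope; the
  stage table export is designed so any survival package can consume it.
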