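# ebm-progression

An event-based model (EBM) of disease progression for sporadic-disease
cohorts. From a purely cross-sectional table of continuous biomarker
measurements with coarse diagnostic labels (CN / MCI / AD), the package
learns the maximum-likelihood *ordering* in which biomarkers become
abnormal — with no cut points and no a priori staging — quantifies the
uncertainty of that ordering, and assigns each subject a discrete disease
stage usable for classification and conversion prediction.

## The model

Disease progression is a sequence *S* of *N* events, where event *i* is the
transition of biomarker *i* from its normal to its abnormal distribution.
A subject at stage *k* has experienced exactly the first *k* events of *S*.
Given per-biomarker densities *p(x|E)* (abnormal) and *p(x|¬E)* (normal),
the likelihood of a sequence given measurements *x<sub>ij</sub>* for
subjects *j = 1..J* is

```
L(S) = ∏_j  Σ_{k=0}^{N}  P(k) ∏_{i≤k} p(x_{s(i),j} | E_{s(i)}) ∏_{i>k} p(x_{s(i),j} | ¬E_{s(i)})
```

with a uniform stage prior *P(k) = 1/(N+1)*. The two densities per
biomarker are components of a two-normal mixture fitted to **all** subjects
jointly — a sporadic-disease control group is contaminated by presymptomatic
cases, and the patient group by misdiagnoses, so neither group can be used
alone — under the weak constraint that each component SD not exceed the
sample SD of the corresponding diagnostic group (CN for normal, AD for
abnormal).

The maximum-likelihood sequence is found by multi-start greedy ascent over
pairwise swaps; its posterior is characterized by Metropolis MCMC over
permutations (positional variance diagrams) and cross-validated by subject
bootstrap. A subject's stage is the *k* maximizing the inner product above
under the ML sequence; the full stage posterior is also returned.

## Worked example

Synthetic cohorts with known ground truth are first-class citizens
(`ebm.synthetic_data`); they emulate a contaminated control group (a third
of CN subjects at nonzero stages) and a modestly misdiagnosed patient group:

```python
import numpy as np
from scipy.stats import kendalltau
from ebm import (SimulationScenario, generate_cohort, fit_all_biomarkers,
                 event_likelihoods, most_likely_sequence, mcmc_sample,
                 stage_subjects, stage_distribution, classify_by_stage)

sc = SimulationScenario(n_events=8, separation=2.0, seed=3)
ds, truth = generate_cohort(sc)                 # 300 subjects, hidden stages
dists = fit_all_biomarkers(ds)                  # constrained mixtures
lt = event_likelihoods(ds, dists)               # p(x|E), p(x|¬E) tables
ml = most_likely_sequence(lt, n_starts=10, seed=4)
post = mcmc_sample(lt, ml, n_samples=10_000, burn_in=1_000, seed=5)

print("recovered order:", post.ml_sequence.names(ds.biomarker_names))
stages = np.array([a.stage for a in stage_subjects(lt, post.ml_sequence)])
print(stage_distribution(stages, ds.diagnosis, sc.n_events).round(2))
keep = ds.diagnosis != "MCI"
report, _ = classify_by_stage(stages[keep], (ds.diagnosis == "AD")[keep].astype(int))
print(f"CN vs AD: threshold stage {report.threshold_stage}, "
      f"balanced accuracy {report.balanced_accuracy:.1f}%, AUC {report.auc:.3f}")
```

prints

```
recovered order: ['marker_02', 'marker_01', 'marker_03', 'marker_04', 'marker_05', 'marker_06', 'marker_07', 'marker_08']
         AD    CN   MCI
stage
0      0.04  0.42  0.01
1      0.00  0.14  0.04
2      0.00  0.24  0.15
3      0.03  0.04  0.17
4      0.01  0.07  0.24
5      0.13  0.03  0.17
6      0.12  0.04  0.11
7      0.28  0.01  0.07
8      0.38  0.00  0.04
CN vs AD: threshold stage 5, balanced accuracy 91.5%, AUC 0.944
```

At a 2-SD component separation the recovered ordering transposes only the
two earliest (hardest to distinguish) events — Kendall tau 0.929 against
the generating truth. The stage table shows the expected structure: CN
subjects concentrate at stage 0 (with a contaminated early-stage tail), AD
subjects at the final stages, MCI in between; thresholding stages separates
CN from AD with high balanced accuracy.

The same pipeline is scriptable from the shell:

```bash
ebm simulate --out runs/sim --seed 5 --n-events 8
ebm fit      --data runs/sim/cohort.csv --schema runs/sim/schema.yaml \
             --seed 1 --out runs/fit --plot
ebm stage    --data runs/sim/cohort.csv --schema runs/sim/schema.yaml \
             --fit-dir runs/fit --out runs/stage
ebm bootstrap --data runs/sim/cohort.csv --schema runs/sim/schema.yaml \
             -b 100 --seed 2 --out runs/boot
```

For real cohorts, `ebm.data_io` reads a CSV against a YAML schema mapping
columns to roles (id, diagnosis, visit, covariates, biomarkers with their
abnormality direction), applies the standard preprocessing (natural-log
transform of CSF tau measures; volumes as percent of total intracranial
volume), and selects population subgroups (amyloid+ is raw CSF amyloid-β
1-42 < 192 pg/ml; APOE+ is carriage of at least one APOE4 allele).

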