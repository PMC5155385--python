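# Methods

## The matching model

The engine computes, for a patient of age `a` (years, birth = 0, capped
at 120) and gender `g`, a posterior over every disease in the knowledge
base:

```
log score(d) = log prior(d; a, g) + Σ_i log L(o_i | d, a) [+ log L_acuity]
```

normalized by log-sum-exp. The model is naive Bayes: findings are
conditionally independent given the disease. No interaction structure is
modelled — curated content provides marginal frequencies and age
intervals per disease-finding pair, nothing pairwise.

**Prior.** Piecewise-constant incidence over contiguous half-open age
bins tiling [0, 120), times a per-gender multiplier. An unspecified
gender takes the mean of the multipliers. A weight of zero excludes the
disease at that age. Patient ages are capped at 120 inclusive; an age of
exactly 120 is clamped into the last bin so the documented cap is
usable.

**Temporal likelihoods.** Onset and disappearance are independent linear
CDF ramps across their closed intervals (a step when the interval is a
point). Disappearance is *not* conditioned on the sampled onset — the
curated data carry only interval endpoints, and a joint model would
invent information. The three branches:

* present, undated: `f · F_on(a) · (1 − F_off(a))`
* present at onset age `o`: `f · mass(F_on over o ± bin_width/2) · (1 − F_off(a))`
* absent: `1 − f · F_on(a) · (1 − F_off(a))`

Uncurated pairs use the background frequency `f0` with onset treated as
uniform over `[0, a]` (present with a dated onset: `f0 · bin_width / a`,
capped at `f0`).

**Acuity.** The timescale over which the illness emerged is a
six-class log-time scale (minutes=0 … years=5). An observed acuity
multiplies each disease's score by `acuity_match` on an exact class
match, `acuity_near` for an adjacent class, `acuity_far` otherwise;
diseases with unknown acuity take the neutral factor 1, so incomplete
curation of acuity never penalizes a disease.

### Engine parameters

| parameter | default | meaning |
|---|---|---|
| `eps_floor` | 1e-4 | floor on every likelihood factor; bounds the damage of one contradicted or mis-entered observation |
| `f0` | 0.005 | background presence probability for uncurated disease-finding pairs; sparse curation must not zero out a disease |
| `bin_width` | 0.25 yr | window for scoring a dated onset against the onset ramp; keeps onset likelihoods ≤ 1 |
| `acuity_match/near/far` | 1.0 / 0.5 / 0.1 | acuity-class match likelihoods |

None of these are estimated from data; all are configurable
(`EngineParams`, CLI flags, config file). Observations are sorted by
finding id before accumulation so the posterior is bit-identical under
any input permutation; differential ties break lexicographically by
disease id.

## Suggestions

One-step (myopic) value of information: for an unobserved finding, the
predictive presence probability is the posterior-weighted mixture of
per-disease presence probabilities, and the score is the expected drop
in posterior Shannon entropy (bits) over the present/absent branches,
clipped below at 0. Branch posteriors apply the same `eps_floor` as the
engine, so the lookahead matches what the engine would actually compute.
Bundles (findings sharing a `bundle_id`, e.g. the components of a
urinalysis) are scored over their joint 2^k outcome tree, k capped at 4
members (sorted by id) for tractability, at the summed member cost.

Usefulness = gain × urgency / cost, with urgency
`1 + w_t·E[treatability] + w_s·E[severity] + w_a·P(acuity ≤ days)`
under the current posterior (defaults w_t = 1.0, w_s = 0.5, w_a = 1.0;
the factors are those a clinician would prioritize by, the functional
form and weights are this package's choice). Findings whose onset ramp
has no mass by the patient's age are still scored — they can be
informative as pertinent negatives.

## Synthetic data

The generator emulates a mature multi-specialty curated database. Scale
defaults are the published ones: 5405 diseases, 22 findings per disease
on average (Poisson-distributed per disease, clipped to [1, n_findings]).
Unreported features use fixed plausible choices:

* finding vocabulary 800 (unknown for the real database); ~60/30/10%
  clinical/lab/imaging; log-normal costs floored at 0.1; ~6% flagged as
  core-checklist findings; roughly one finding in eight belongs to a
  bundle;
* frequencies Beta(2, 2) clipped to [0.01, 1] — mid-heavy, like curated
  "often/sometimes" grades;
* incidence log-normal(0, 1) across bins, creating rare-vs-common
  contrast; gender multipliers log-normal(0, 0.3);
* **age coherence:** each disease draws a typical manifestation age
  (uniform on [0, 60]); its incidence concentrates in a bin around that
  age (5% relative weight before, 20% after), and its findings' onset
  ages are Normal(manifestation age, 7 yr) with uniform ramp spans up to
  10 yr, 30% of associations carrying a later disappearance interval.
  Real curated content has this property — a childhood disease has
  childhood onsets — and without it simulated young patients are
  asymptomatic and carry no diagnostic signal;
* onset-interval widths are placeholders; their realistic distribution
  is not documented anywhere we know of.

`simulate_patient` is the generative mirror of the engine's model: age
from the disease's incidence profile, presence sampled per association
from its frequency and sampled onset/disappearance ages, onset ages
recorded, plus a Poisson(2) sample of curated-but-absent findings as
pertinent negatives (vignette negative density is undocumented; 2 is a
guess). `corrupt_profile` applies the four observed user-input error
modes independently per observation: onset dropped, finding omitted,
state flipped (misinterpretation also drops the onset), and spurious
findings drawn from outside the profile. All three operations take an
explicit seed and own their generator stream; identical seeds give
byte-identical artifacts (floats are canonically rounded to 6 decimals
at generation).

**What passing tests do and do not show.** The simulator samples from
the same family of temporal models the engine scores with, so the
generative-recovery experiment (true disease in the posterior top 5 in
≥ 90% of 500 noise-free simulations on a 200-disease KB) validates the
inference machinery, not real-world accuracy: real findings are
correlated, curation is biased and incomplete, and real vignettes are
not draws from the KB. Residual recovery failures are almost entirely
patients who present with zero positive findings (possible at ages
before the disease's typical onsets), where no engine could do better
than the prior.

## Evaluation

Diagnostic error: the differential contains neither the correct
diagnosis nor any of its categories (identifier equality after
case-insensitive normalization; no fuzzy matching — logs use tokens).
Relevance: |differential ∩ gold differential| / |differential|.
Change classification compares the paired baseline/aided error states.
Aggregation reports, per group (specialty, seniority, case, tester, all,
or cross-classifications): instance and error counts,
aided = baseline − fixed + added, percent of changes improving
(blank/NaN when a group made no changes), error rates, and the relative
decrease — all percentages rounded half-up to integers to match printed
reporting style (82.5 → 83). Workup lists run through the same
operations but carry no reference numbers.

`build_fixture_log` converts printed margin counts (baseline errors,
fixed, added — per tester group or per case) into a concrete 26-tester ×
8-case × 2-phase log by greedy allocation in tester-id order, validating
internal consistency (fixed ≤ baseline errors ≤ instances,
added ≤ correct instances). Aggregating such a log reproduces the
printed tables exactly; the per-instance allocation within a group is of
course not unique, which is why tester-level statistics (e.g. GEE Wald
magnitudes) computed from fixture logs are not meaningful reference
values.

**GEE.** `gee_logistic` fits a marginal logistic model for the clustered
binary error outcome via statsmodels (binomial family, exchangeable
working correlation with the moment estimate of the within-cluster
correlation, robust sandwich covariance). Wald = (β̂/SE)², referred to
χ²(1). Non-convergence and separation raise explicitly. Calibration is
validated by simulation: under a clustered null (26 clusters × 16
observations, random intercept σ = 0.8, marginal error rate ≈ 0.27) the
5%-level phase test rejects within the 3σ binomial band around 5% over
500 replicates (small-cluster sandwich variance is known to be slightly
liberal; observed rates sit near 6–8%), and the exchangeable correlation
estimate recovers a known beta-binomial correlation within ±0.05 at 200
clusters. With an independence working structure the coefficients equal
ordinary logistic regression to 1e-6.

## Problem sizes

The test suite and acceptance script use a 200-disease / 400-finding KB
for the recovery experiment (500 simulations), 50-disease KBs for
randomized property checks (1000 normalization cases), a 10-disease KB
for the exact-rational-arithmetic oracle, and 500 GEE replicates —
sizes chosen to exercise every code path at comfortable runtimes while
keeping Monte-Carlo bands tight enough to be meaningful.

## Known limitations

* Naive-Bayes independence; no finding co-occurrence model.
* Disappearance ramps independent of onset; no within-patient temporal
  correlation beyond the recorded onset age.
* Heritability is stored but does not modify the prior (no mechanism is
  documented for it); family-history evidence must be curated as an
  ordinary finding to count.
* The entropy-based suggestion score is this package's formalization of
  "useful in distinguishing diagnoses"; other engines may use different
  value-of-information metrics.
* The completeness audit reports both an any-association count and an
  above-near-zero-frequency count per checklist item, because curation
  workflows differ on whether a reviewed pertinent negative (frequency
  ≤ 0.01) counts as annotated.
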