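# tempdx

Temporal Bayesian differential diagnosis, next-test suggestion, and the
evaluation toolkit for before/after validation studies of diagnostic
decision support.

## The problem

Specialist diagnostic expertise is scarce — in pediatric rheumatology and
similar fields, most patients are first seen by generalists who must decide
what a presentation of, say, joint pain and fever could be and what to test
next. Diagnostic decision-support engines address this by matching a
patient's findings against a curated knowledge base of thousands of
diseases. Two things make that matching non-trivial:

* **Time.** A finding is evidence for a disease only at the right age:
  each disease-finding association carries a frequency and age intervals
  of onset and (when applicable) disappearance. A rash that appears at
  age 3 means something different from one appearing at 30.
* **Absence.** A *pertinent negative* — a finding explicitly recorded as
  absent — is evidence against diseases in which that finding is common
  at the patient's age.

## The model

For patient age $a$, gender $g$ and observations $o_1,\dots,o_n$, the
engine ranks diseases by a naive-Bayes posterior

$$P(d \mid \mathbf{o}) \propto \pi_d(a,g)\,\prod_{i=1}^{n} L(o_i \mid d, a),$$

where $\pi_d$ is the disease's incidence weight at age $a$ (piecewise
constant over age bins, scaled by a gender multiplier) and each
likelihood factor follows the temporal model of the finding in the
disease. With frequency $f$, onset interval $[o_{lo}, o_{hi}]$ and
disappearance interval $[d_{lo}, d_{hi}]$, the probability the finding
is present at age $a$ is

$$p(a) = f \cdot F_{on}(a) \cdot \bigl(1 - F_{off}(a)\bigr),$$

with $F_{on}, F_{off}$ linear ramps across their intervals. A present
finding contributes $p(a)$; a present finding with a recorded onset age
contributes $f$ times the onset-ramp mass in a small window around that
age; an absent finding contributes $1 - p(a)$. Findings with no curated
association fall back to a small background frequency $f_0$, and every
factor is floored at $\varepsilon$ so a single data-entry error cannot
zero out the correct disease. An observed *acuity of onset* (whether the
illness emerged over minutes, hours, days, weeks, months or years) is
matched against each disease's acuity class on that log-time scale.

On top of the posterior, the **suggestion** module scores every
unobserved finding (and test bundles such as a urinalysis panel) by the
expected reduction in posterior Shannon entropy, weighted by the
clinical urgency of the diseases in play (treatability, severity, and
mass on rapidly evolving diseases) and divided by the test's relative
cost.

The **evaluation** module implements the metrics used to validate such
engines in tester studies — diagnostic error (differential omits both
the correct diagnosis and its category), relevance (fraction of listed
diagnoses present in the expert gold standard), fixed/added-error change
classification, grouped error-rate tables with half-up-rounded
percentages, and a logistic GEE (exchangeable working correlation,
robust sandwich variance, Wald chi-square tests) for the clustered
binary error outcome. The **synthetic** module generates knowledge bases
at realistic scale (thousands of diseases averaging 22 findings each)
and simulates patients from a chosen disease, including the user-input
error modes observed in practice (onset ages dropped, findings omitted,
misinterpreted, or spuriously entered).

## Worked example

Generate a 200-disease synthetic knowledge base, simulate a patient from
disease `d0017`, and diagnose from the first recorded finding:

```bash
tempdx --seed 42 simulate kb --config sim.json --out kb.json
# tempdx: wrote kb.json: 200 diseases, 4508 associations
tempdx diagnose --kb kb.json --patient patient_first_visit.json --top 5
```

with `patient_first_visit.json` containing one undated present finding
for a 14-year-old boy:

```
rank  disease_id  posterior
1     d0088       0.394039
2     d0017       0.271574
3     d0082       0.07063
4     d0056       0.023735
5     d0106       0.0174929
```

A single undated finding leaves real uncertainty — the true disease sits
at rank 2 with posterior 0.27. Asking the engine what to check next:

```bash
tempdx suggest --kb kb.json --patient patient_first_visit.json --top 5
```

```
rank  target  gain_bits  urgency  cost  usefulness
1     f0096   0.299829   1.92474  0.13  4.43917
2     f0029   0.760835   1.92474  0.47  3.11576
3     f0126   0.499568   1.92474  0.33  2.91375
4     f0173   0.39457    1.92474  0.45  1.68765
5     f0186   0.343864   1.92474  0.41  1.61426
```

`f0029` would be the most informative single observation (0.76 bits),
but `f0096` is cheap enough to be the better first test per unit cost.
Adding the patient's second finding with its onset age drives the
posterior of `d0017` above 0.999: dated onsets are strong evidence.

Evaluation of a tester study, reproducing the grouped error tables from
a response log (here the built-in fixture log):

```bash
tempdx evaluate --fixture table4 --group-by seniority --gee
```

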