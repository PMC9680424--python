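# redeye

Dynamic Bayesian diagnosis and triage for red eye complaints.

Red eye is one of the most common eye presentations in primary and
emergency care, and the available decision aids are static flowcharts: every
patient gets the same questions in the same order, with no notion of how
likely each diagnosis currently is. `redeye` implements the alternative — a
sequential Bayesian engine that maintains a ranked differential diagnosis
and chooses each next question dynamically — together with the evaluation
statistics used to validate such engines against clinicians, and a
synthetic-patient generator so the whole pipeline can be exercised without
clinical data.

It is aimed at researchers studying clinical decision support and at
developers of knowledge-base-driven triage tools; the engine is fully
KB-agnostic and ships with an authored, editable red-eye knowledge base
covering 15 diagnoses (4 flagged urgent).

## The model

A patient is assumed to have exactly one diagnosis $d$ from the knowledge
base. Each questionnaire item $q$ is a binary finding with a per-diagnosis
conditional probability $P(\text{YES} \mid d)$, and findings are
conditionally independent given the diagnosis. After answers
$a_1, \dots, a_k$, the posterior over diagnoses is the naive-Bayes product

$$P(d \mid a_{1:k}) \propto \pi_d \prod_{i=1}^{k} P(a_i \mid d),$$

with $P(\text{NO} \mid d) = 1 - P(\text{YES} \mid d)$ and "I don't know"
carrying likelihood 1 for every diagnosis (no update). A conditional
probability of 0 or 1 acts as a hard rule-out.

After a fixed set of 3–4 opening questions, the next question is chosen by
**value of information**: for each eligible question, the engine computes
the total-variation distance $\tfrac12\sum_d |P(d\mid a, \cdot) - P(d\mid
\cdot)|$ between the current belief and the belief after a YES and after a
NO, and asks the question with the largest potential shift (an
expected-shift mode is also available). Prerequisite constraints (e.g.
corneal questions only after a positive fluorescein stain) and redundancy
rules (questions permanently dropped once another answer makes them
uninformative) shape the eligible set. The session stops when the top
posterior dominates the runner-up by a factor θ (default 5) while exceeding
an absolute floor (default 0.5), or when the bank is exhausted; sessions
that end with the belief essentially unchanged from the prior are flagged
low-confidence rather than silently reporting the prior's top diagnosis.

The evaluation layer scores batches of recorded cases the way validation
studies score them: top-1/2/3 accuracy against a gold-standard diagnosis,
referrer concordance, and urgency triage — a case is classified urgent iff
the top-ranked diagnosis carries the urgent flag — with sensitivity and
specificity carrying exact (Clopper–Pearson) 95% binomial confidence
intervals computed from beta quantiles.

## Worked example

Score the shipped 57-case concordance fixture (per-cluster counts of a
validation study of this style of engine):

```sh
$ redeye evaluate --fixture src/redeye/data/study_concordance.csv
...
Total | 57 | 40/57 | 39/57 | 43/57 | 46/57
overall%: referrer 70.2 | top1 68.4 | top2 75.4 | top3 80.7
```

Reading: referring physicians named the gold-standard diagnosis in 70.2% of
cases; the engine's top-ranked diagnosis matched in 68.4%, rising to 75.4%
within its top two and 80.7% within its top three suggestions.

From Python, run a recorded case and inspect the differential:

```python
>>> import redeye as re
>>> kb = re.load_default_kb()
>>> A = re.AnswerValue
>>> case = re.CaseRecord("c1", {"staining": A.YES, "opacity": A.YES,
...                             "contact_lens": A.YES})
>>> result = re.batch_diagnose(kb, [case])[0]
>>> result.top3
('corneal_ulcer', 'keratitis', 'endophthalmitis')
>>> result.advice
('Refer to Ophthalmology to rule out a corneal ulcer.',)
```

A positive fluorescein stain with a whitish opacity in a contact-lens
wearer drives corneal ulcer to rank 1 and fires the referral advice rule.

Other entry points: `redeye interview` (interactive terminal workup),
`redeye diagnose --cases file.csv` (batch), `redeye simulate` (synthetic
cases), `redeye validate-kb file.yaml` (schema/invariant checking with an
itemized report).

## Documentation

* `docs/methods.md` — the statistical model, question-selection policy,
  authored knowledge-base calibration, and known limitations.
* `docs/kb-schema.md` — the knowledge-base file format, field by field
  (machine-validated by `src/redeye/data/kb_schema.json`).
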