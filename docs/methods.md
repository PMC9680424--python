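# Methods

## Diagnostic model

The engine models a presentation as caused by exactly one diagnosis from
the knowledge base. Every questionnaire item is a binary finding; the KB
stores $P(\text{YES} \mid d)$ for each (question, diagnosis) pair, and
findings are assumed conditionally independent given the diagnosis (naive
Bayes). The belief starts at the normalized priors and each YES/NO answer
multiplies in its likelihood and renormalizes:

- YES: $P(d) \leftarrow P(d)\,P(\text{YES}\mid d) / Z$
- NO: $P(d) \leftarrow P(d)\,(1 - P(\text{YES}\mid d)) / Z$
- I don't know: no change (likelihood 1 for every diagnosis).

This makes the posterior a normalized product over the answered set —
order-independent, so batch replay of a recorded questionnaire and an
interactive session reach identical beliefs. Hard rule-outs are expressed
as conditional probabilities of exactly 0 or 1 rather than a separate flag;
an answer that zeroes every remaining diagnosis raises a contradiction
error at the library level, which the interactive and batch front-ends
downgrade to a logged skip so one inconsistent answer cannot destroy a
session.

Updates run in linear space with renormalization after every step.
Question banks in this domain are small (a few dozen items), so underflow
is not a practical concern; probability comparisons use a 1e-9 tolerance.

## Question selection

After the opening questions (asked verbatim in KB order), the engine
scores every eligible question by how far its answer could move the
belief, measured as total-variation distance
$d_a = \tfrac12 \sum_d |\text{post}_d(a) - \text{pre}_d|$ for
$a \in \{\text{YES}, \text{NO}\}$. Two aggregation modes are implemented,
selectable in KB settings:

- `max` (default): $\max(d_{\text{YES}}, d_{\text{NO}})$ — best-case
  discrimination, favouring questions with a decisive branch;
- `expected`: $\sum_a P(a)\,d_a$ with $P(a) = \sum_d \text{pre}_d
  P(a \mid d)$ — average-case discrimination.

Both are defensible readings of "ask the question with the highest
potential pre-test/post-test change"; `max` is the default because a
single decisive answer (e.g. a positive fluorescein stain) is exactly what
a clinician is hunting for. A branch that would contradict the whole
belief contributes 0 (it cannot be observed under the model). UNKNOWN is
excluded from scoring since it never changes the belief. Ties break by KB
declaration order, making selection fully deterministic. Lookahead beyond
one question, question costs, and entropy-based criteria are deliberately
out of scope.

Eligibility enforces two KB-declared constraint types: *prerequisites*
(pairs (question, answer) that must already hold — e.g. corneal-opacity
and contact-lens questions require a positive stain first) and *redundancy
triggers* (pairs whose occurrence permanently eliminates a question — a
positive stain retires the chronic-tearing question). Elimination is
evaluated idempotently against the answered set and survives later
contradicting answers.

## Stopping and confidence

The session stops when the top posterior is at least θ times the runner-up
**and** above an absolute floor, or when no eligible questions remain (or
the user quits). Defaults are θ = 5 and floor 0.5, both stored in the KB:
"heavily outweighs" is inherently a policy choice, and these values stop a
15-diagnosis workup only once one diagnosis holds a clear majority of the
posterior mass. On stopping, the state is flagged `low_confidence` when
the belief lies within total variation 0.05 of the prior: the answers
discriminated nothing, and the "top" diagnosis is merely the most
prevalent one. This flag is an intentional safeguard — an engine of this
kind otherwise reports an arbitrary top diagnosis on a findings-free case
— and it is surfaced, not silently resolved.

The rendered differential shows posterior × 100 to one decimal, a 0–10
bar, and an urgency marker; urgent diagnoses with nonzero posterior are
always rendered regardless of any top-N display cutoff, so critical
possibilities stay in view. The underlying belief always retains every
diagnosis.

## The default knowledge base

The shipped red-eye KB covers 15 diagnoses — from benign (conjunctivitis,
dry eye, subconjunctival blood) to sight-threatening (corneal ulcer, acute
angle-closure glaucoma, iritis, endophthalmitis; these four are flagged
urgent) — with 32 questions and 3 advice rules. Its priors follow an
emergency-department case mix (keratitis/abrasion, iritis and corneal
ulcer dominate), smoothed so no diagnosis starts at zero. External
pathologies that are usually clinically apparent (cellulitis, hordeolum,
chalazion, pingueculitis, trauma, penetrating injury) are not modelled;
the evaluation layer buckets such gold labels as "other", which is always
scored incorrect for the algorithm.

The conditional probabilities are **authored content**, not estimates from
patient data: they encode standard clinical cues (fluorescein staining,
whitish corneal opacity, contact-lens use, foreign-body sensation, pain
character and photophobia, pupil and corneal findings, intraocular
pressure, redness pattern, lid signs, discharge, tearing, itch, trauma and
surgical history, symptom duration) and were calibrated so that the KB
reproduces the qualitative behaviours a red-eye workup should show: a
positive stain prioritizes the ulcer workup and retires chronic tearing;
firm eye + abnormal pupil puts angle closure on top, and correcting both
to normal flips the case to keratitis/abrasion; removing a disputed stain
from a painful foreign-body-sensation case promotes scleritis into the
top two. Tests that pin these behaviours are KB-calibration tests — they
validate the authored content, not the engine, whose correctness is
established by the property tests (oracle equivalence, commutativity,
greedy optimality).

## Synthetic cases

The generator samples a gold diagnosis from a prevalence distribution
(defaults to the KB priors; an emergency-department mix mirroring the
57-case validation sample — 16 keratitis/abrasion, 13 iritis, 11 ulcer, 4
conjunctivitis, 4 scleritis, … — is built in), then answers every question
as Bernoulli($P(\text{YES} \mid d)$), flips each YES/NO answer with
probability `noise_rate`, and blanks it to UNKNOWN with probability
`unknown_rate`. Both rates default to 0 — a fully documented, fully
concordant questionnaire — and both are in [0, 1]; output is deterministic
given the seed. Referrer diagnoses are left unattempted: synthetic cases
exercise the algorithm, not referrer behaviour.

Because the generator uses the engine's own conditional-independence
assumption, recovery results measure engine correctness plus KB
separability, **not** clinical validity: real findings are correlated
(pain travels with photophobia; staining with foreign-body sensation), and
real answer probabilities are unknown. Under the authored KB the
generative and inferential models coincide, so the Bayes classifier is
optimal and zero-noise top-1 recovery on 1,000 cases sits at 96–97%,
degrading monotonically as noise rises — which is exactly what the
acceptance properties assert. Correlated symptom structure and referrer
simulation are out of scope.

## Evaluation statistics

Scoring conventions follow clinical validation practice: a referrer who
attempted no diagnosis is incorrect; "other" gold labels are always
algorithm-incorrect (the engine cannot name a diagnosis outside its KB).
Unrecognized diagnosis labels are collapsed into the "other" bucket when a
case file is read, so referrer scoring on such cases is conservative — a
referrer who correctly named an out-of-KB condition still scores incorrect
because the original label is discarded; count fixtures, which carry
per-cluster referrer counts directly, are unaffected.  Blank cells are
"I don't know"; blank questionnaire cells are "I don't know"; urgency
classification uses the top-1 diagnosis only (top-k urgency variants exist
in the API but are not part of the headline metrics). Sensitivity is
computed over gold-urgent cases, specificity over gold-non-urgent cases
("other" counts as non-urgent), and a zero denominator yields an undefined
metric, never 0.

Confidence intervals are exact Clopper–Pearson bounds from beta quantiles:
lower $= B^{-1}(\alpha/2;\,x,\,n-x+1)$ (0 when $x=0$), upper
$= B^{-1}(1-\alpha/2;\,x+1,\,n-x)$ (1 when $x=n$). The exact method is
used because, for the urgent-subset counts the shipped 57-case fixture
implies (20/26, 29/31, 22/26, 26/31), its bounds — and only its bounds,
among the standard interval methods — reproduce every printed interval of
the study this fixture comes from after integer rounding. The test suite
cross-checks the implementation against statsmodels' independent exact
interval for all $0 \le x \le n \le 40$.

Percentages are rounded half-up to one decimal and CI bounds half-up to
whole percents. One known print discrepancy: 29/31 = 93.548…% rounds to
93.5%, while the source study prints 93.6%; this package reports the
arithmetically correct 93.5% (the CI bounds, 79–99%, agree either way).

## Problem sizes

Property tests run on randomly generated knowledge bases up to 15
diagnoses × 30 questions with random answer sets (hundreds of states per
property), synthetic-recovery checks on 1,000 cases per condition, and the
CI cross-check over all count pairs with $n \le 40$ — sizes chosen to
cover the regime the shipped KB occupies while keeping the full suite
fast.

## Known limitations

- Conditional independence is assumed by both engine and generator;
  strongly correlated findings will make the posterior overconfident.
- The authored probabilities are plausibility-calibrated, not fitted;
  absolute posteriors should be read as suspicion scores, and any clinical
  use would require re-estimating the tables from data.
- Binary findings only; severity grading and multi-valued answers are not
  modelled.
- Greedy single-step question selection can be myopic when two questions
  are only jointly informative.
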