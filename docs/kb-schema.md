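# Knowledge-base file format

A knowledge base is a single YAML document (JSON also parses) with four
top-level keys: `diagnoses`, `questions`, `advice`, `settings`. A
JSON-Schema description ships at `src/redeye/data/kb_schema.json`;
`redeye validate-kb FILE` (or `redeye.validate_kb`) checks every invariant
below and reports all violations at once.

## `settings`

| field | type | default | meaning |
|---|---|---|---|
| `theta` | number ≥ 1 | 5.0 | dominance stop factor: stop once top posterior ≥ θ × runner-up |
| `posterior_stop` | number in [0, 1] | 0.5 | absolute posterior floor for the dominance stop |
| `voi_mode` | `max` \| `expected` | `max` | question-scoring mode (see methods note) |

## `diagnoses`

A list of mappings:

| field | type | required | meaning |
|---|---|---|---|
| `id` | string | yes | short stable identifier, unique in the KB |
| `name` | string | no (defaults to id) | display string |
| `urgent` | boolean | no (false) | requires rapid specialist referral; always kept visible in the rendered differential |
| `prior` | number ≥ 0 | no (1.0) | relative pre-test prevalence weight; renormalized to sum to 1 on load |

At least one diagnosis must have a positive prior.

## `questions`

A list of mappings, in the order used for opening-phase asking and
tie-breaking:

| field | type | required | meaning |
|---|---|---|---|
| `id` | string | yes | unique question identifier |
| `text` | string | yes | display string, phrased as a yes/no question |
| `answer_model` | mapping | yes | diagnosis id → P(YES \| diagnosis), decimal in [0, 1]; the special key `default` fills any unlisted diagnosis. Without a `default`, every diagnosis must be listed. 0 encodes a hard rule-out on YES, 1 a hard rule-out on NO |
| `opening` | boolean | no (false) | member of the fixed opening set, asked first in KB order |
| `prerequisites` | list of `[question-id, answer]` | no | all pairs must already hold in the answered set before this question is eligible; the prerequisite graph must be acyclic |
| `redundancy_triggers` | list of `[question-id, answer]` | no | any pair occurring in the answered set permanently eliminates this question |

Answers in pairs are `yes`, `no`, or `unknown`. All referenced question
ids must exist.

## `advice`

A list of management-advice rules; each fires at most once per session,
the moment its condition first holds:

| field | type | required | meaning |
|---|---|---|---|
| `id` | string | yes | unique rule identifier |
| `message` | string | yes | non-empty display string |
| `when.answers` | list of `[question-id, answer]` | no | conjunction over the answered set |
| `when.min_posterior` | single-entry mapping diagnosis-id → probability | no | additionally require the named diagnosis's posterior to reach the threshold |

## Example

```yaml
settings: {theta: 5.0, posterior_stop: 0.5, voi_mode: max}
diagnoses:
  - {id: ulcer, name: Corneal Ulcer, urgent: true, prior: 2}
  - {id: conj, name: Conjunctivitis, prior: 8}
questions:
  - id: staining
    text: "Is there corneal staining with fluorescein?"
    opening: true
    answer_model: {default: 0.05, ulcer: 0.85}
  - id: opacity
    text: "Is there a whitish corneal opacity?"
    prerequisites: [[staining, yes]]
    answer_model: {default: 0.02, ulcer: 0.9}
advice:
  - id: ulcer_referral
    message: "Refer to Ophthalmology to rule out a corneal ulcer."
    when:
      answers: [[staining, yes], [opacity, yes]]
```

Loading renormalizes priors and validates everything; serialization via
`redeye.save_kb` round-trips losslessly.
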