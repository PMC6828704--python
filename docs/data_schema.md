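# Input data schema

`dominet` consumes three plain-text inputs. All tables are UTF-8 CSV (or TSV
when the filename ends in `.tsv`/`.tab`) with a header row.

## Interaction table

One row per observed dyadic behavioural event.

| column | type | meaning |
|---|---|---|
| `session_id` | string | observation session the event belongs to; must exist in the session table |
| `order_index` | non-negative integer | within-session temporal order; unique per session |
| `initiator_id` | string | individual that initiated the behaviour; must differ from `recipient_id` |
| `recipient_id` | string | individual the behaviour was directed at |
| `behaviour_code` | string | key into the ethogram |
| `outcome` | `initiator_wins` / `recipient_wins` / `draw` / empty | required (non-empty) exactly when the ethogram classifies the code as agonistic; empty otherwise |

The behavioural category (`agonistic` / `affiliative` / `ambiguous`) is not
stored in the table; it is derived from the ethogram on read, so table and
ethogram can never disagree. Ambiguous records are accepted and retained but
excluded from every downstream computation. Draws count as interactions when
networks are built but contribute to neither Elo nor David's scores (a
half-credit Elo update is available via `EloConfig(draw_rule="half")`).

## Session table

One row per observation session.

| column | type | meaning |
|---|---|---|
| `session_id` | string | unique session identifier |
| `date` | ISO date (`YYYY-MM-DD`) | observation date; sessions are ordered by date |
| `duration_hours` | positive float | recording length; divides counts into interactions per hour |
| `individuals_present` | `;`-separated strings | roster for the session; every individual appearing in its records must be listed |

Individuals absent from a session (for example a bird temporarily removed
from the group) are simply left off that session's roster; per-session
analyses are restricted to present individuals, and consistency tests
between sessions with different rosters are skipped and reported.

## Ethogram

YAML (or JSON) mapping each behaviour code to a category, optionally with a
description:

```yaml
peck: agonistic
displace:
  category: agonistic
  description: approach causing the other bird to retreat
allopreen: affiliative
approach_unclear: ambiguous
```

Valid categories: `agonistic`, `affiliative`, `ambiguous`. Every code
appearing in an accepted interaction table must be present; an unknown code
is a validation error naming the code.

## Conventions

- Per-session summary statistics use the sample SD (ddof = 1); with a single
  session the SD is reported as NaN.
- `dominet simulate` emits exactly this schema plus a `ground_truth.json`
  with the latent abilities, true rankings and dyadic win probabilities.
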