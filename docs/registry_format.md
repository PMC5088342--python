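# Cohort XML dialect

`trialae` reads and writes trial adverse-event results in a small XML
dialect that mirrors the results section of ClinicalTrials.gov study
records, keeping exactly the fields the age-group analysis needs.  Real
registry records can be converted to this dialect by a thin external
script; the package itself never fetches data over the network.

## Structure

```xml
<?xml version="1.0" encoding="utf-8"?>
<cohort>
  <trial trial_id="T00001" sponsor_type="Industry" intervention="Drug X">
    <arm arm_id="A1" title="Treatment" enrolled="120" mean_age="47.5"
         overall_affected="33">
      <event term="Nausea" serious="false" subjects_affected="12"
             subjects_at_risk="120" soc="Gastrointestinal disorders"/>
      <event term="Cardiac arrest" serious="true" subjects_affected="1"
             subjects_at_risk="120"/>
    </arm>
    <arm arm_id="A2" title="Placebo" enrolled="118" mean_age="46.9"/>
  </trial>
</cohort>
```

The document is UTF-8; the root element is `<cohort>` with zero or more
`<trial>` children.

## Elements and attributes

### `<trial>`

| attribute | required | meaning |
| --- | --- | --- |
| `trial_id` | yes | identifier, unique per document |
| `sponsor_type` | no | free text (e.g. Industry, NIH) |
| `intervention` | no | free text |

A trial contains one or more `<arm>` children; `arm_id` values must be
unique within the trial.

### `<arm>`

| attribute | required | meaning |
| --- | --- | --- |
| `arm_id` | yes | identifier, unique within the trial |
| `title` | no | free text |
| `enrolled` | yes | positive integer, participants in the arm |
| `mean_age` | no | non-negative years; arms without it are excluded from age-group analyses |
| `overall_affected` | no | participants affected by at least one adverse event |

### `<event>`

| attribute | required | meaning |
| --- | --- | --- |
| `term` | yes | free-text adverse-event name |
| `serious` | yes | `true`/`false` (also accepts `1`/`0`, `yes`/`no`) |
| `subjects_affected` | yes | non-negative integer |
| `subjects_at_risk` | yes | positive integer; may differ from the arm's `enrolled`, as the registry allows |
| `soc` | no | pre-coded system organ class; when present and valid it wins over the term lookup table |

## Validation rules

Parsing validates every record; a violation is reported with the trial id
and field (by default the read aborts; with `skip_invalid=True` invalid
records are dropped, each with a logged diagnostic):

* `subjects_affected <= subjects_at_risk` for every event;
* `overall_affected <= enrolled`, and at least the largest
  `subjects_affected` among events whose denominator equals the arm's
  enrollment;
* event terms non-empty after trimming; arm ids unique; at least one arm
  per trial.

Writing is deterministic: the same records always serialize to the same
bytes, and `read_trial_records(write_trial_records(x))` returns records
equal to `x` field by field.
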