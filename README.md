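# wmltm

Simulation and measurement pipeline for a sequential object–color memory
paradigm with an immediate (working-memory, WM) probe test and a delayed
(long-term-memory, LTM) recognition test.

The package provides:

* **`wmltm.task_design`** — seeded generators for the WM session (120 trials:
  54/36/30 at set sizes 2/3/4, probe conditions split in thirds with halved
  sub-conditions, 336 unique studied items) and the LTM test (144 probes:
  48 new lures plus 32 studied items per origin set size, split 8/8/8/8 into
  re-paired, novel-color, previously-probed intact, and unprobed intact),
  plus a structural validator and CSV/JSON serialization.
* **`wmltm.response_model`** — an explicit multinomial-processing-tree
  observer (capacity `k`, guess-old rate, same-color guess bias, binding
  retention, novelty detection, LTM survival parameters) whose marginal
  old/new behavior reduces to `hit = p + (1 - p) · g` with
  `p = min(k/S, 1)`; cohort simulation with truncated-normal heterogeneity
  and per-participant seed substreams; three calibrated default age-group
  profiles.
* **`wmltm.estimators`** — guessing-corrected item-memory estimation
  `p = (h - f) / (1 - f)`, capacity `k = p · S`, implausible-value
  adjustment (k floored at 1; negative delayed proportions floored at 0),
  the per-participant LTM/WM transfer ratio, contingent binding-error
  scoring with all eligibility filters (object called old; novel-color
  probes excluded; delayed probes of WM-probed objects excluded; <5-trial
  cells flagged), same-color guess-bias rates, and summary tables.
* **`wmltm.inference`** — within-group standardization, a default-prior
  correlation Bayes factor (numerical integration over a stretched
  symmetric-beta prior on the correlation), and BIC-approximate Bayes
  factors for age / set-size / interaction effects with participant
  intercepts absorbed by within-participant centering.
* **`wmltm.pipeline`** — end-to-end orchestration
  (design → simulate → score → analyze) with full provenance (config +
  master seed reproduce every artifact) and a parameter-recovery experiment
  at realistic cohort sizes (43/39/42).

## CLI

```sh
wmltm design   --seed 1 --out out/                 # designs only
wmltm simulate --config configs/default.json --seed 1 --out out/
wmltm score    --in out/ --out out/scored/ [--pool-wm-lures] [--binding-include-all]
wmltm analyze  --in out/scored/ --out report.json [--prior-width 1.0]
wmltm run      --config configs/default.json --seed 1 --out out/   # all stages
wmltm recover  --seed 1 --replicates 50 --out recovery.json
```

`configs/default.json` holds the three default age-group profiles; edit the
per-parameter means/spreads or cohort sizes to define new cohorts.

Scoring consumes any long-format CSV with the columns
`participant_id, age_group, phase, probe_index, set_size, condition,
was_wm_probe, response, object_correct, fully_correct`
(`response` in `{SS, SD, DO}`), so externally collected data can be scored
after mapping onto this schema.

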