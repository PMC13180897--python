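# istroop

An engine for an **eye-tracking-based Stroop test**: a 3-minute,
examiner-free assessment of attention and frontal lobe function for
memory-clinic screening.  Instead of asking for spoken or written answers,
the test shows 16 short trials on a monitor — a color word or color patch
in the center, four candidate answers in the corners — and an infrared eye
tracker (50 Hz) records where the participant looks.  The score for a
trial is the **percentage of viewing time spent inside the region of
interest (ROI) over the correct option** during the 7-s presentation; the
per-trial percentages are averaged into condition scores and a total score
in [0, 100].  The continuous dwell percentage captures hesitation and
partial interference that a dichotomous correct/incorrect score cannot.

The package provides every stage as a library plus a thin CLI:

| module | what it does |
| --- | --- |
| `istroop.schedule` | generates and validates the 16-trial, 4-condition blocked stimulus program (word / reverse Stroop / color / Stroop; 7-s trials, 1-s ITI, 2-s block slide; per-condition correct colors a permutation of the palette; Latin-square corner balance) |
| `istroop.gaze` | gaze CSV I/O (`time_s,x,y,valid`) and half-open per-trial segmentation |
| `istroop.scoring` | ROI hit-testing and the dwell-percentage score with QC rules |
| `istroop.clinical` | MMSE / FAB / TMT / CDR / paper-Stroop containers and the standard cutoff classifiers (MMSE 28–30 / 24–27 / ≤23; FAB ≤11/18; CDR 0 / 0.5 / ≥1) |
| `istroop.stats` | Spearman (midranks), Mann–Whitney U (exact p by enumeration for small n), ROC/AUC with DeLong or bootstrap 95% CI |
| `istroop.simulate` | a generative memory-clinic cohort model — correlated latent traits, instrument scores, trialwise two-phase gaze streams — with an analytic expected-score oracle |
| `istroop.pipeline` | simulate/load → score → full validation battery → machine-readable report |

For a score `s` and cutoff-defined impairment labels, diagnostic accuracy
is summarised by the AUC–ROC, which equals the Mann–Whitney estimator
`U/(n₁·n₂) = P(s_impaired < s_control) + ½·P(tie)` (lower scores indicate
impairment).

## Worked example

```bash
istroop schedule --seed 1 --out schedule.json
istroop simulate --seed 1 --out-dir cohort/
istroop score --gaze cohort/gaze/sim01.csv --schedule cohort/schedule.json --out score.json
istroop analyze --cohort-dir cohort/ --out report.json
```

The `score` step prints, for one simulated participant,

```
total score 26.2 (0 trials failed QC)
```

meaning 26.2% of this participant's tracked viewing time fell on the
correct option, averaged over the 16 trials, with every trial passing the
minimum-valid-data check.  The same in Python, plus the cohort-level
condition means:

```python
import numpy as np
from istroop import Condition, generate_schedule, SimulationConfig, simulate_cohort, score_participant

schedule = generate_schedule(seed=1)
cohort = simulate_cohort(SimulationConfig(), schedule, seed=1)
result = score_participant(cohort[0].recording, schedule)
print(round(result.total_score, 1))          # 26.2

scores = [score_participant(p.recording, schedule) for p in cohort]
means = {c.value: round(float(np.nanmean([s.condition_scores[c] for s in scores])), 1)
         for c in Condition}
print(means)
# {'word': 38.1, 'reverse_stroop': 34.1, 'color': 40.5, 'stroop': 29.2}
```

The cohort condition profile shows the interference effect the task is
built around: the Stroop condition (respond to ink, ignore meaning) and
the reverse-Stroop condition score below their interference-free
counterparts (color and word).

`analyze` writes the full validation battery as JSON — nine Spearman
correlations (eye-tracking vs paper-based totals and per-condition scores,
FAB, TMT-A/B, MMSE), six Mann–Whitney group comparisons, and four ROC
analyses (FAB-defined frontal dysfunction, MMSE-defined dementia and
MCI+dementia screening, CDR-defined dementia), each with the n actually
used after per-analysis deletion of missing values.

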