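# kinectcpt

A scoring engine for the **motion-capture continuous performance test
(CPT)** — the go/no-go letter task in which the examinee raises the
dominant hand after every letter and must inhibit any movement when the
forbidden letter `X` appears.  Replacing the spacebar with the hand's
full 3-D trajectory lets the test measure not just *whether* a reaction
occurred, but when the movement started, how long it took to complete,
and — uniquely — *partial*, aborted reactions to no-go stimuli that a
keyboard cannot register.  The intended users are researchers in digital
phenotyping and objective ADHD assessment who need a reproducible,
scriptable scoring layer between raw skeletal-joint recordings and
psychometric analysis.

## What it computes

For a session scored against a stimulus schedule (60 letters / 12 no-go
in the 3-minute revised design; 360 letters in the legacy design):

* **RT** — reaction time: stimulus appearance to the detected movement
  onset of the hand raise (go trials).  Onset = first sustained
  vertical-velocity threshold crossing, backtracked to the movement
  start.
* **CT** — completion time: movement onset to the hand's return into the
  rest band.
* **Commission index** for each no-go trial:

  `CI = L(X window) / max(L(previous window), L(next window))`

  where `L` is the 3-D path length of the hand in a trial window — a
  continuous measure of failed inhibition (0 = perfect stillness,
  ~1 = full reaction), with the taxonomy correct inhibition / inhibited
  commission / commission cut at configurable thresholds.
* Event classes per trial (full reaction, omission, partial omission,
  multiple reaction, premature reaction, the commission triad, invalid).
* A participant summary: **median** of the 48 RTs and CTs and of the 12
  commission indices.
* **SWAN scale** scoring (18 items, 0–100 web format; factor means over
  items 1–9 / 10–15 / 16–18) and the predictors-by-factors Pearson (or
  Spearman) correlation report with two-sided p-values.

A synthetic-cohort simulator (minimum-jerk raises, shifted-lognormal RT
linked to latent traits, trait-linked omissions and no-go excursions)
makes the entire pipeline testable end to end without hardware; see
`docs/methods.md` for every model and threshold.

## Worked example

```python
from kinectcpt import (SimConfig, TraitProfile, generate_schedule,
                       score_session, simulate_participant,
                       summarize_participant)

sched = generate_schedule("revised-60", seed=7)           # 60 letters, 12 X
child = simulate_participant(sched, TraitProfile(inattention=30,
                                                 hyperactivity=40,
                                                 impulsivity=80),
                             SimConfig(seed=7), 7)
results = score_session(child.stream, child.session_schedule)
s = summarize_participant(results)
print(s.median_rt_s, s.median_ct_s, s.median_commission_index)
print({k: v for k, v in s.event_counts.items() if v})
```

prints

```
0.5 0.7666666666666657 0.4486512966201064
{'full_reaction': 46, 'omission': 2, 'commission': 3, 'inhibited_commission': 9}
```

A highly impulsive profile (80/100) reacts fast — median RT 0.50 s,
completing each raise in ~0.77 s — and inhibits poorly: its median
commission index is 0.45, with 3 of the 12 no-go trials scored as full
commissions and 9 as partial, aborted movements.  The two omissions
reflect the mild inattention trait.

The same flow is available from the shell:

```bash
cpt schedule --design revised-60 --seed 7 -o schedule.json
cpt simulate --n 30 --seed 7 --out cohort/
cpt score --schedule cohort/schedule.json --trajectory cohort/p000_trajectory.csv -o scored/
cpt correlate --summaries out/summaries.csv --swan out/swan.csv -o report.md
cpt run --out out/ --seed 7          # full pipeline + checksummed manifest
```

`cpt run` writes a `manifest.json` with a SHA-256 per artifact; an
identical config and seed reproduces the manifest byte for byte.

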