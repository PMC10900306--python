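# resptraj

Treatment-trajectory analysis for newly diagnosed asthma and COPD on
OMOP-shaped observational data.

Clinical guidelines (GINA for asthma, GOLD for COPD) recommend a stepwise
approach: start treatment at an intensity matched to the patient and step up
or down as control changes. How patients are actually treated after a new
diagnosis — what they start on, what they switch to, whether therapy is
escalated or de-escalated — can be read out of routinely collected
prescription (EHR) or dispensing (claims) records. `resptraj` implements
that readout as a reusable, tested pipeline for anyone doing
pharmacoepidemiological characterisation on data mapped to a class-level
subset of the OMOP common data model: epidemiologists, health-services
researchers, and students of treatment-pattern methods.

## What the pipeline computes

Input: four tables — `person`, `observation_period`,
`condition_occurrence`, `drug_exposure` — with drug exposures already mapped
to 14 respiratory drug classes (ICS, SABA, LABA, SAMA, LAMA, LTRA,
xanthines, systemic glucocorticoids, PDE4 inhibitors, biologics, and the
fixed combinations SABA-SAMA, LABA-LAMA, LABA-ICS, LABA-LAMA-ICS).

1. **Cohorts.** Two mutually exclusive new-diagnosis cohorts. A patient
   enters on the day of first diagnosis (index date), with first diagnosis
   inside 2010–2019, ≥ 365 days of prior observation, ≥ 1095 days of
   follow-up, age ≥ 18 (asthma) or ≥ 40 (COPD), and no diagnosis of the
   other disease on or before index.
2. **Drug eras.** Per patient and class, exposure records separated by at
   most 30 uncovered days are merged into continuous eras; eras shorter than
   5 days are dropped. Systemic glucocorticoid eras split by duration:
   < 30 days = steroid burst (an exacerbation marker), ≥ 30 days =
   maintenance therapy.
3. **Events and trajectories.** Overlapping eras of different classes are
   resolved pairwise: an overlap of ≥ 30 days, or one spanning the full
   duration of one era, becomes *combination therapy* (the union of the
   classes over the overlap); a shorter overlap is a *switch* (the earlier
   era is truncated where the later one starts). The ordered sequence of
   distinct event labels is the patient's treatment trajectory.
4. **Step classification.** Each patient's first transition is labelled
   step-up / step-down / switching / start or end of acute exacerbation /
   no follow-up treatment / other, by comparing event labels on a
   guideline-derived intensity ladder. Guideline conformance is the share of
   first transitions found in a strict transition set.
5. **Aggregation.** Trajectories occurring in ≥ 0.5% of the population are
   counted and drawn as a sunburst (ring *k* = *k*-th treatment); rarer ones
   pool into "other".

A seeded synthetic-data generator (`resptraj.synth`) emits the same four
tables with *planted* cohort membership, trajectories and transition types,
in either prescription style (contiguous records) or dispensing style
(~30-day fills with stochastic refill gaps), so every stage of the pipeline
can be checked against known ground truth.

> **Note on conformance numbers.** The intensity ladders and strict
> transition sets ship as editable YAML under `src/resptraj/data/`. They are
> class-level reconstructions of the GINA/GOLD step logic. Review and adapt
> them to your study before interpreting guideline-conformance output.

## Worked example

```python
import resptraj as rt

bundle = rt.make_toy_patient({
    "observation": (0, 1600),                 # days since 2009-01-01
    "conditions": [("asthma", 400)],          # first diagnosis -> index day
    "exposures": [("SABA", 410, 520), ("ICS", 450, 600)],
})
config = rt.RunConfig()
results = rt.run_pipeline(bundle, "asthma", config)
print(results["events.csv"])
print(results["transition_table.csv"].head(2))
```

```
  person_id  ordinal     label  start_day  end_day
0        T0        1      SABA        410      449
1        T0        2  ICS+SABA        450      520
2        T0        3       ICS        521      600
    category  n  percent
0    step_up  1    100.0
1  step_down  0      0.0
```

The SABA and ICS eras overlap for 71 days (≥ 30), so the overlap becomes a
loose combination event `ICS+SABA` flanked by the single-class remnants; the
trajectory is SABA → ICS+SABA → ICS, and the first transition (SABA at
ladder level 1 to ICS+SABA at level 2) is a step-up — 100% of this
one-patient cohort.

From the shell, the same round trip on synthetic data:

```bash
resptraj simulate --out data/ --seed 4
resptraj run --input data/ --cohort asthma --out out/
```

which writes `cohort.csv`, `attrition.csv`, `drug_eras.csv`, `events.csv`,
`trajectories.csv`, `transition_table.csv`, `trajectory_counts.csv`,
`first_line.csv`, `baseline.csv`, `summary.json`, `sunburst.json`,
`sunburst.html` and a checksum `manifest.csv`.

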