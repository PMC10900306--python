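# Methods

## Data model and time conventions

The pipeline consumes a minimal, class-level subset of the OMOP common data
model: `person` (id, birth year, sex), `observation_period` (one per
person), `condition_occurrence` (diagnosis concept + day) and
`drug_exposure` (drug class + closed day interval). Drug exposures are
assumed pre-mapped to 14 respiratory drug classes; source-vocabulary mapping
(SNOMED CT / RxNorm) is out of scope. Missing records are read as absence of
treatment.

Time is integer day indices relative to 2009-01-01 (one year before the
default study window opens). Intervals are closed `[start, end]`; duration
is `end − start + 1` days, which makes every "< 30 days" / "≥ 30 days" rule
an exact integer comparison and keeps the brute-force day-bitmap oracles in
the test suite trivial to state. "1 year" is 365 days, "3 years" 1095 days,
and age is index calendar year minus birth year — birth month is not in the
data model. A person has exactly one observation period; callers with
re-enrollment must pre-merge periods.

## Cohort construction

Two mutually exclusive new-diagnosis cohorts. Eligibility, applied in a
fixed precedence order so attrition reporting is deterministic:

1. index (first diagnosis) day inside the calendar window
   (2010-01-01 … 2019-12-31 by default);
2. age at index ≥ 18 (asthma) / ≥ 40 (COPD);
3. ≥ 365 days of observation before index;
4. ≥ 1095 days of observation after index;
5. no diagnosis of the other disease on or before index.

"No prior history" is evaluated at entry: a cross-diagnosis *after* index
does not remove a patient from a cohort (the asthma–COPD overlap population
is not analysed here). Each excluded person is tallied under the first
failing rule only.

## Drug eras

Per person and class, exposure intervals are unioned and neighbouring
intervals merged when the number of uncovered days between them
(`next_start − prev_end − 1`) is at most `era_gap_days` (30). The
`min_era_days` (5) filter is applied *after* merging, so short dispensing
fills that chain into a long era survive; the rule drops short eras, not
short records. Only exposure ending on or after the person's index day
contributes; an exposure straddling index is truncated at index
(`truncate_at_index`, on by default — switch it off to require post-index
starts instead).

Systemic glucocorticoid eras are relabelled by the *merged era's* duration:
`steroid_burst` below `steroid_maintenance_days` (30), `steroid_maintenance`
at or above it. The era, not the raw record, is the analysis unit.

## Event resolution (switching vs combination)

Eras of different classes can overlap. Two rules decide what an overlap
means:

- **combination therapy** — overlap ≥ `combination_overlap_days` (30), or
  the overlap spans the full duration of one of the two eras: a combination
  event carrying the union of the class sets is emitted over the overlap,
  and the non-overlapping remnants remain as events;
- **switching** — any shorter overlap: the earlier-starting event is
  truncated to the day before the later one starts (the later class wins
  the contested window).

Resolution is iterative pairwise: at each step the overlapping pair whose
overlap starts earliest is resolved (ties: the pair containing the longer
event, then alphabetical label order), and a combination event is itself
re-eligible to overlap others, which is how ≥ 3-class loose combinations
arise. The loop terminates because every step strictly reduces total
pairwise overlap; a generous iteration guard raises if that invariant were
ever violated. The "full duration" clause is evaluated against the current
(post-split) remnant, not the original era (`full_duration_uses_remnant`);
remnants shorter than `min_era_days` are dropped after resolution
(`drop_short_remnants`), reusing the 5-day rule symmetrically. Both choices
are config switches because observational-data conventions differ here and
no single reading is canonical.

After resolution, contiguous events with identical class sets are merged.
Non-contiguous repeats of the same class set stay separate events — they
collapse into one trajectory label downstream, but their day coverage stays
honest, which the day-level conservation test relies on.

Fixed-combination inhalers (e.g. `LABA-ICS`) are atomic labels distinct
from loose combinations; a loose combination renders as the alphabetical
`+`-join of its members (`ICS+SABA`, `LABA-ICS+LTRA`).

The trajectory is the ordered sequence of distinct event labels, truncated
at `max_trajectory_depth` (5) for aggregation — sunbursts beyond five rings
are unreadable; the cap is configurable.

## Step classification

The first transition of every treated patient is labelled with one of seven
categories, by precedence: no second treatment → *no follow-up*; a steroid
burst appearing → *start of acute exacerbation*; a burst disappearing →
*end of acute exacerbation*; otherwise the two labels are compared on a
disease-specific intensity ladder (higher → *step-up*, lower → *step-down*,
equal → *switching*), and anything unclassifiable is *other*. When both
sides contain a burst, the burst is stripped from both and the remaining
classes are compared; if a side is then empty or both sides coincide, the
transition is *other* — bursts mark exacerbations, not maintenance
intensity.

The ladders encode the GINA/GOLD step structure at drug-class granularity
(e.g. asthma: SABA-only rescue = 1, ICS or LTRA = 2, LABA-ICS = 3,
triple therapy = 4, biologics or maintenance steroids = 5). Doses are not
in the data model, so dose-based step distinctions (low/medium/high ICS)
cannot be expressed. Ladders and the strict transition sets used for
guideline conformance are YAML data files, not code; the shipped strict
sets are reconstructions and conformance output should not be interpreted
without reviewing them. A per-transition classification over whole
trajectories is emitted separately (`all_transitions.csv`) and never mixed
into the first-transition table.

## Aggregation and reporting

A trajectory is retained when its patient count is at least
`min_trajectory_fraction` (0.5%) of the population — the full cohort
including untreated patients by default (`population_includes_untreated`;
switchable to treated-only). The threshold applies to full trajectories
once, before plotting; per-node thresholds would filter twice. Retained
trajectories form a prefix tree (node count = patients whose trajectory
passes through that prefix); pooled rare trajectories appear as a single
first-ring "other" wedge (switchable off) — per-ring breakdowns of the pool
are not available by construction, since pooled sequences are not retained.
Conservation (retained + other + untreated = cohort size) is asserted on
every run, as is cohort disjointness.

The sunburst renderer writes a self-contained HTML file: a static SVG with
hover titles plus the node tree embedded as a JSON payload. Colours are
assigned to classes alphabetically from a fixed palette, so the mapping is
stable across runs; a loose-combination wedge is radially striped with each
member's colour. The renderer is deliberately dependency-free.

Baseline tables report n, % male (persons of unknown sex are excluded from
the denominator), mean age, mean Charlson Comorbidity Index (classic
weights, shipped as a data file) and per-comorbidity percentages with
lookback over all time before index — except lower respiratory tract
infections, restricted to the previous 365 days. Percentages are rounded
to 1 decimal throughout.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, with planted
ground truth per person: eligibility (and the single violated rule for
ineligible persons), the treatment trajectory, the planted event count, and
the broad category of the first transition.

- **Exposure styles.** Prescription style writes one contiguous record per
  class per event (EHR-like); dispensing style writes ~30-day fills whose
  refill gaps are drawn from a truncated normal clipped to
  `[0, era_gap_days]` (claims-like). The clipping guarantees that era
  merging reassembles each planted event exactly, so ground truth is an
  oracle rather than a hope.
- **Unambiguous planting.** Consecutive events are separated by gaps drawn
  with a floor of `era_gap_days + 1`, so planted switches can never merge;
  loose combinations are planted as co-extensive intervals, which the
  full-duration overlap clause resolves to a combination regardless of
  length. Steroid tokens are restricted to singleton events (a burst inside
  a longer multi-class event would split it and invalidate the planted
  label); burst events draw durations from 5–29 days, maintenance events
  are floored at 30.
- **Defaults.** Events last ~120 ± 30 days with inter-event gaps of
  ~90 ± 30 days and first treatment within 120 days of diagnosis — typical
  scales for chronic respiratory medication in claims/EHR data. Ages are
  drawn uniformly over 40 years above the disease minimum; sex is balanced;
  comorbidities are sampled independently at their configured marginal
  prevalences (joint structure is not modelled).
- **Infeasible scenarios** (event durations below the era minimum,
  inter-event gaps that could merge) are rejected before generation.

What passing on synthetic data does *not* show: robustness to irregular
real-world exposures (overlapping same-class records from multiple
prescribers, mid-era dose switches recorded as class re-starts, ambiguous
overlaps near the 30-day boundary), non-random missingness, or realistic
demographic/comorbidity joint distributions. The property tests on
randomized era layouts cover the rule mechanics beyond what the generator
plants, but real-data validation remains the user's job.

## Problem sizes and determinism

The shipped tests and the acceptance script run at n = 500–2000 persons —
large enough for the 3-standard-error recovery checks on planted fractions
to be meaningful, small enough to execute in seconds. All randomness flows
from explicit seeds (`numpy.random.default_rng`); identical seed and
configuration give byte-identical CSV/JSON/HTML outputs, which the test
suite asserts by hashing two independent runs.
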