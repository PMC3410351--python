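# Methods

## Data model

A courtship session is one male–female couple observed in a mating
chamber for up to `observation_cap_s` seconds (default 600) or until
copulation begins. The ethogram is bout-level: each event is one element
— orientation, wing vibration, licking, attempted copulation, copulation,
or a non-sexual encounter (NSE) — with start and end times in seconds.
NSEs are instantaneous (`end == start`). Times are carried as floats on a
centisecond grid and written with two decimals, so session CSVs
round-trip exactly.

Validation enforces: at most one copulation per session, and nothing
after it (the observation ends when copulation starts); bouts of the
*same* element may not overlap, while bouts of different elements may (a
male orients while singing) — this keeps per-element summed durations
well-defined and ≤ the total time; all events lie inside
`[0, total_time]`. The total observed time *T* is the copulation start
time if the couple copulated, else the cap. `ritual_time()` also offers
an alternative reading — time from the first courtship act (NSEs
excluded) to session end — but every downstream computation uses the
default, total observed time.

## Per-couple parameters and group comparison

Each couple yields eight features: orientation time, vibration time,
licking count, attempted-copulation (ATC) count, copulated flag, NSE
count, total time, and SFI = 1/(NSE + 1). The Boolean health label
(wild-type control vs. α-syn A30P) is the dependent variable.

Group summaries normalize per couple before averaging: time traits as
`100·t/T`, count traits as `100·count/T`. Dividing by each couple's own
*T* deliberately up-weights males that copulate quickly. Two deliberate
asymmetries: NSE is *not* time-normalized (it concentrates before any
sexual activity starts), and copulation is summed over the group rather
than averaged (it is binary per couple). Group means use compensated
summation (`math.fsum`) so summaries are exactly invariant under row
permutation.

The composite courtship score expresses each of six traits (orientation,
vibration, licking, ATC, copulation total, SFI) as percent of the control
group mean and averages them, so identical groups score exactly 100 and
scaling every trait by k scales the score by k. SFI, not raw NSE, is the
sixth trait so that every component increases with better courtship
performance. Reports print both the integer-rounded and full-precision
percentages; all internal arithmetic is unrounded (the one exception:
`copulation_reduction_pct` returns one decimal, matching how that
quantity is conventionally quoted).

## Climbing assay

A trial is one vial: `n_passed` of `n_flies` climbed ≥ 1 cm within 18 s
after tap-down. The genotype score is the pooled pass fraction — with
equal vial sizes this equals the per-vial average, and it is invariant to
how flies are partitioned into vials. The disease group's reduction is
`100·(1 − s_PD/s_ctrl)` with control anchored at 100 %. Day-6 vs day-21
comparisons are represented by an `age_days` column on trials; no aging
dynamics are modeled.

## Rule model

A `Condition` is an inclusive interval test `low ≤ feature ≤ high`
(inclusive on both ends; "3 to 5 times" includes 3 and 5). An
`exact_count` condition is the degenerate integer interval. A `Rule` is a
conjunction of one or more conditions predicting a label; a `RuleSet`
holds healthy-predicting rules with disjunction semantics treated as
necessary *and* sufficient: at least one conjunction holds ⇒ healthy,
none ⇒ sick.

`evaluate()` reports the two-sided success rate, the empirical
conditionals P(healthy | ≥1 condition holds) and P(sick | none holds),
and the improvement factor: the error of a chance guess at the given
class prior, `min(prior, 1 − prior)`, divided by the observed error
`1 − success`. At the default 0.5 prior this is `0.5/(1 − success)`,
strictly increasing in the success rate; a perfect classifier reports
`inf`, and the conditionals are `nan` when no vector hits (or misses) the
rule set.

The packaged reference rule set carries the published seven conditions
for the A30P screen verbatim, four of which test the NSE count on
pairwise-disjoint intervals (1–2, 3–5, 6–17, 35–51). The published
per-condition "average" annotations — some internally inconsistent — are
stored as free-text notes and never used in classification. Because the
raw 56-couple recordings behind that screen were never released, the
packaged evaluation cohort is a synthetic stand-in (construction, not
measurement) whose hit/miss pattern reproduces the published confusion
structure exactly: 23/28 healthy hits, 23/28 sick misses, success 46/56,
improvement 2.8.

## Rule mining

Candidate conditions are data-driven: for each feature, every interval
whose inclusive endpoints are observed values (for counts this is every
contiguous run of observed values; Booleans contribute only the two
singletons). This candidate set provably covers all distinguishable
intervals. On datasets larger than 64 rows, endpoints fall back to
equal-frequency quantile endpoints (8 bins) to bound the search;
`max_intervals_per_feature` overrides the bin count.

`mine_rules` enumerates every conjunction of candidate conditions on
distinct features up to `max_conjunction` (default 2) and keeps those
with empirical confidence ≥ `min_probability` (default 0.8, chosen to
bracket the reference screen's achieved 0.821) and support ≥
`min_support` (default 2), for both target labels. Support is the number
of covered cases *of the predicted class*, an absolute count — duplicating
every row doubles supports, so thresholds do not rescale with dataset
size. A qualifying conjunction is pruned when a proper sub-conjunction
qualifies for the same label with confidence at least as high.
Confidence comparisons use ordinary float division against the float
threshold; the test-suite oracle applies the identical comparison, making
agreement exact. Counting is vectorized as Boolean-matrix products
(conditions × rows per feature; integer matmuls for pairs); conjunctions
of size 3 loop over the first feature's conditions and are intended for
small candidate spaces. Mining is fully deterministic — fixed iteration
orders, no randomness. Exhaustive mode on a 56-row cohort legitimately
yields on the order of 10⁶ qualifying rules (continuous features
contribute ~1.6k intervals each); mine + selection completes in ~15 s.

`select_iff_ruleset` starts from the empty disjunction (everything
classified sick) and greedily adds the healthy-predicting rule that most
increases the two-sided success rate, breaking ties by higher support,
then fewer conditions, then a fixed lexical key; it stops when no
addition strictly improves. Greedy forward selection is not guaranteed
globally optimal in general, but matches exhaustive subset search on all
of the suite's small fixtures. If no rule beats the always-sick baseline
the selector raises rather than return an arbitrary set.

## Synthetic cohort generator

The generator emulates the summary statistics of the two-group design —
defaults: 28 couples per genotype, 600 s cap — without modeling courtship
dynamics (no ritual sequencing, no song structure, no female state).
Per couple:

* copulated ~ Bernoulli(p); copulating couples end at a Uniform(cap/2,
  cap) latency (300–600 s under defaults, covering the sub-600 ritual
  times the reference screen reports), others run to the cap;
* orientation and vibration fractions ~ Beta(mean·c, (1−mean)·c) with a
  shared concentration c = 50, giving a between-couple SD of ≈ 0.07 at a
  0.5 mean — the published means come with no dispersion information, so
  c is a free default, as are all second moments below;
* drawn time totals are realized as 2–20 s bouts (the final bout may be
  shorter) placed without within-element overlap, gaps split
  multinomially, all on the centisecond grid;
* licking and ATC counts ~ Poisson(norm_mean·T/100), so the `100·count/T`
  normalization recovers the configured norm in expectation regardless of
  copulation latency; bout lengths 0.3–1 s and 0.5–2 s;
* NSE ~ Poisson(nse_mean) instantaneous events at uniform times.

Default group parameters are the published screen's means: orientation
fractions 0.566/0.413, vibration 0.215/0.172, licking norms 3.4/2.006
(59 % of control), ATC norms 0.4/0.2028 (50.7 %), copulation
probabilities 11/28 and 8/28, NSE means 21/33 for control/A30P. Every
generated session passes full ethogram validation, and identical seeds
produce byte-identical CSVs.

What passing the recovery tests shows — and does not: at n = 2000 per
group every configured mean is recovered within 2 % relative, which
validates the pipeline's arithmetic end to end (generation → parameter
extraction → normalization → summary), not any claim about real flies.
Real recordings would have correlated traits, non-Poisson counts, and
ritual temporal structure the generator does not emulate; mined rule
intervals on synthetic cohorts are therefore data-dependent and not
comparable to the published intervals.

The climbing generator draws `n_passed ~ Binomial(10, p)` per vial. The
published comparison fixes only the 28 % relative reduction at day 21,
not absolute pass fractions; the defaults (0.9 control, 0.648 = 0.72·0.9
A30P) realize that reduction at a plausible control level.

## Problem sizes and determinism

The recovery checks use 2000 couples per group (sampling error ≈ 0.3–0.7 %
on the means, comfortably inside the 2 % band) and 500 vials × 10 flies
per group for climbing (SD of the recovered reduction ≈ 0.8 points
against the ±2-point band). Oracle-agreement checks run on ≤ 8-row
datasets where exhaustive enumeration is feasible. `scripts/acceptance.py`
derives its two generator seeds from the single `--seed` argument (seed
and seed + 1) so all randomness is caller-controlled.

## Known limitations

* Mining with `max_conjunction=3` on exhaustive endpoints is
  combinatorially heavy; use binned endpoints or small cohorts.
* Exhaustive mining returns very large rule lists by design ("all
  qualifying rules"); downstream consumers should rely on
  `select_iff_ruleset` rather than iterate the full list.
* Training-set success of a mined rule set is optimistic (the reference
  screen itself reports training performance); no cross-validation is
  provided.
* The evaluation cohort is synthetic; only its hit/miss pattern under
  the reference rule set is meaningful, and its relative-activity table
  is undefined (no copulations or ATCs), which the `report` command
  states explicitly.
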