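# Methods

## The statistic and its contract

A clonotype is a unique B-cell receptor rearrangement. Input rows are
collapsed onto the key **(normalized V gene, CDR3 nucleotide sequence)**;
CDR3-only keying is available via `clonotype_key="nt"` because repertoire
studies differ on whether the V segment is part of clonal identity, and the
choice changes the denominator. Multi-hit MiXCR V calls take the
first-listed (best-scoring) hit; allele suffixes (`*01`) and score
annotations are stripped. Rows that cannot form a key (empty CDR3,
unparseable V call) are dropped and tallied on the sample rather than
silently ignored.

Usage of gene *g* in a sample is the fraction of **clonotypes** carrying
*g*, never weighted by clone or read counts: one expanded clone is one
clonotype. Counts are still summed through the collapse so the tables
round-trip losslessly. Usage of an empty sample is an error, not zero, and
a patient with no USM sample is reported unassigned, not defaulted into a
group.

## ROC stratification

The classifier is `usage >= t -> predicted low complement`. The threshold
grid is every distinct observed usage plus a `+inf` sentinel (the
all-negative rule), so the curve runs from (0,0) to (1,1) and the
trapezoidal AUC equals the tie-corrected rank (Mann–Whitney) statistic;
this identity is asserted on random tied instances in the test suite. The
operating cutoff minimises the Euclidean distance to the (0,1) corner.
Ties are broken toward the lower threshold (the more sensitive operating
point). Youden's J argmax is computed alongside for diagnostics but is
never the selector — the two criteria can disagree. Usage exactly at the
cutoff is HIGH. Patients without complement data are excluded from ROC
fitting but still receive a group from the fitted cutoff. A preset cutoff
(e.g. the published 5.9%) can be supplied to `fit(cutoff=...)` to
reproduce downstream stages without refitting.

## Clinical instruments

* **SLEDAI-2K**: weighted sum over 24 descriptors (8 for the CNS/vascular
  block, 4 musculoskeletal/renal, 2 mucocutaneous/serositis/serology,
  1 constitutional/haematological; maximum 105). Unknown descriptor keys
  are errors naming the key.
* **LLDAS**: SLEDAI-2K ≤ 4 with no activity in major organ systems (renal,
  CNS, cardiopulmonary, vasculitis, fever), no haemolytic anaemia or GI
  activity, PGA ≤ 1, prednisolone ≤ 7.5 mg/day, and only standard
  maintenance immunosuppression. Missing inputs raise rather than return
  False.
* **SELENA-SLEDAI flare index**: severe when ΔSLEDAI > 12, a major-organ
  descriptor newly fires, prednisolone is increased beyond 0.5 mg/kg
  (absolute 30 mg/day fallback when body weight is unknown — the fallback
  is configurable and the caller should report its use), a new
  immunosuppressant / SLE hospitalisation occurs, or PGA > 2.5;
  mild/moderate when ΔSLEDAI is 3–12, a non-major descriptor newly fires,
  prednisolone rises below the severe threshold, or PGA rises by ≥ 1 while
  staying ≤ 2.5. The follow-up data the index is applied to rarely record
  which triggers fired, so the trigger sets are configuration
  (`FlareIndexConfig`) with the full published sets as defaults.
* **Low complement**: C3 or C4 strictly below the institutional lower
  limit. The limits are configuration; the defaults (C3 < 73 mg/dl,
  C4 < 11 mg/dl) are plausible institutional values, not published ones.
  A value exactly at the limit is not low.
* **Exclusions**: cyclophosphamide or rituximab within the past year, or
  prednisolone ≥ 21 mg/day (inclusive). Missing medication data never
  excludes; it is logged.

## Statistical battery

Mann–Whitney uses the exact null when the pooled sample is ≤ 10 without
ties, otherwise the tie-corrected normal approximation. Fisher's exact
two-sided p sums hypergeometric probabilities ≤ the observed table's.
Spearman uses midranks, with an exact full-permutation p for n ≤ 9 (n! ≤
362 880 permutations, vectorised) and the t-approximation above that.
Bonferroni families are explicit: all emitted subset pairs (10 for five
subsets) for the usage comparison, and the number of rows actually tested
for the group-comparison table; the family size is echoed in the run
manifest because published reports rarely state it. Missing data policy:
pairwise-complete for correlations, complete-case per model for the
regression (≥ 10 cases required), per-variable within-group denominators
for the tables.

The "multiple" regression fits each clinical outcome on **all five subset
usages jointly**, after z-scaling outcome and predictors, giving
standardised coefficients with t-based 95% CIs. Fitting one model per
subset is a defensible alternative reading; the joint model is the default
because that is what makes the regression multiple, and a univariable loop
is a one-line variation on the same function.

Report percentages use half-up rounding, one decimal at ≥ 10% and two
decimals (three significant figures) below 10% — the convention of
clinical cohort tables. Statistics are computed at full precision;
rounding is presentation only.

## Survival

Time origin is the baseline sampling visit (the data state no alternative
anchor). The analysis population is LLDAS achievers at baseline on the
named drug, concomitant therapy allowed; the event is the first flare of
mild/moderate or worse severity, with censoring at the last follow-up
visit. Kaplan–Meier and log-rank computations are delegated to lifelines;
censorings at an event time remain at risk for that time (standard
convention), and the test suite pins the product-limit and O−E/V
arithmetic to hand-computed fixtures plus a label-permutation oracle.

## Synthetic cohort generator

One latent activity score `a ~ N(0,1)` per patient drives everything —
the simplest structure that reproduces the full association pattern
(usage–complement, usage–serology, usage–SLEDAI, group-dependent flares).
Defaults and what they emulate:

* **Usage**: per-subset baseline IGHV4-34 frequency 7.4% (naïve), 6.6%
  (USM), with SM/DN/PB lower (3–4%), matching the observed ordering of
  subsets. The sample's focal-gene frequency is a Beta draw (the
  Dirichlet-multinomial marginal, concentration 150) around
  `sigmoid(logit(base) + 0.35·a)` — the 0.35 logit effect applies to USM
  only. Clonotype totals are negative-binomial (mean 400, shape 5,
  floor 50); the floor and mean are arbitrary study-design choices since
  cohort-level clonotype-count distributions are not published.
* **Labs**: C3 = 82 − 12a ± 14, C4 = 15 − 4a ± 4.5 mg/dl (so low
  complement concentrates at high activity); anti-dsDNA log-normal with a
  0.9·a log-shift; ESR, IgG up with activity; albumin, haemoglobin down.
* **SLEDAI items**: Bernoulli with logit-linear activity slope 0.9, except
  low complement and increased DNA binding, which are *derived from the
  simulated labs* so the clinical record is internally coherent.
* **Flares**: exponential first-flare time with hazard
  `0.35/yr · exp(0.5a) · HR^{1[u_USM ≥ 5.9%]}`, HR = 2.5, administrative
  censoring at 730 days.

CDR3 strings are random in-frame placeholders (Cys anchor, no stop
codons) with no biological motif content; V(D)J recombination biology,
somatic hypermutation and isotype structure are deliberately absent.
Passing tests therefore demonstrate that the *pipeline* recovers planted
effects of realistic size at the study's n — they say nothing about
whether real USM repertoires carry such effects.

The cohort-level draw materialises only the focal-gene count per sample;
the full clonotype table is realised lazily, conditioned on that count,
from a per-sample spawn of the master seed. Fixture files and the fast
usage matrix agree exactly, and any single sample is reproducible in
isolation.

## Numerical and design notes

* Cutoff ties and Youden ties both resolve toward the lower threshold;
  the tolerance for "tied" is 1e-12 on the distance/J scale.
* `assign_groups` treats NaN usage as unassigned; the partition
  HIGH + LOW + unassigned = n is asserted property-style.
* Pipeline outputs are written with a fixed float format so reruns with
  an unchanged config and seed are byte-identical; the manifest carries a
  SHA-256 of the canonical config JSON, the cutoff, Bonferroni family
  sizes, per-stage row counts and deduplicated warnings.
* Monte-Carlo problem sizes: recovery 200 replicates at n = 130 (the
  study's scale), Mann–Whitney null calibration 1000 replicates at n = 60,
  log-rank type-I calibration 2000 replicates at 40 + 40 with ~84% event
  probability. These sizes give standard errors comfortably inside the
  asserted tolerances (±2.5 and ±1.5 percentage points).

## Known limitations

* The published headline numbers (cutoff 5.9%, AUC 0.677, 76.2%/54.8%
  operating point, table p-values) belong to a cohort that is not
  redistributable; this package reproduces the *procedure* and the printed
  table arithmetic, and demonstrates recovery on synthetic cohorts only.
* The published sensitivity/specificity are not exactly consistent with
  the printed low-complement counts (49/64 = 76.6%), implying unreported
  missing-data denominators; no attempt is made to reproduce them.
* The flare index here classifies snapshot pairs; real SELENA scoring
  involves clinician judgement items that cannot be automated.
* CDR3-level biology (autoreactive AVY/NHS motifs, SHM) is out of scope.
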