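# ighvstrat

Stratification of systemic lupus erythematosus (SLE) patients by **IGHV4-34
clonotype usage in unswitched-memory (USM) B cells**.

IGHV4-34 is an intrinsically autoreactive immunoglobulin heavy-chain V-gene
segment. In SLE cohorts profiled by sorted-subset RNA-seq (naïve, USM,
switched-memory, double-negative B cells and plasmablasts), the fraction of
B-cell-receptor clonotypes carrying IGHV4-34 in the USM compartment tracks
disease activity. This package implements that analysis end to end for
anyone working with per-subset clonotype tables (AIRR Rearrangement TSV or
MiXCR clone-export TSV) and a linked clinical table:

1. **Usage** — for a sample with clonotype set *C* (clonotypes keyed by
   V gene + CDR3 nucleotide sequence), the usage of gene *g* is
   `u_g = |{c ∈ C : V(c) = g}| / |C|` — a count-unweighted fraction of
   clonotypes.
2. **Stratification** — the ROC of USM IGHV4-34 usage against the binary
   low-complement label (C3 or C4 below the institutional reference range);
   the operating cutoff `t*` minimises the distance to the top-left corner,
   `t* = argmin_t √((1−sens(t))² + (1−spec(t))²)`, and patients are assigned
   HIGH (`u ≥ t*`) or LOW groups.
3. **Association battery** — Mann–Whitney / Fisher-exact group comparison
   tables, Spearman correlations, Bonferroni adjustment, and multiple linear
   regression of a z-scaled clinical outcome on the five z-scaled subset
   usages jointly (standardised coefficients with 95% CIs).
4. **Flare-free survival** — Kaplan–Meier curves and the log-rank test
   between HIGH and LOW groups among patients in a lupus low disease
   activity state (LLDAS) on a given maintenance drug, with flares
   classified by the SELENA-SLEDAI flare index.
5. **Synthetic cohorts** — a generator in which a single latent
   disease-activity score couples USM IGHV4-34 usage (Dirichlet-multinomial
   repertoires), complement, anti-dsDNA, SLEDAI-2K items, PGA and flare
   hazard, so the whole pipeline is testable without access to patient data.

The clinical instruments (SLEDAI-2K weights, LLDAS criteria, SELENA-SLEDAI
flare triggers, cohort exclusion rules) are implemented in
`ighvstrat.clinical`.

## Worked example

```python
from ighvstrat import SimConfig, UsageStratification, simulate_cohort

cohort = simulate_cohort(SimConfig(n_patients=129), seed=1)
results = UsageStratification.from_cohort(cohort).fit()
print(results.summary())
```

```
Usage stratification                        (score >= cutoff -> predicted low complement)
==============================================================================
Gene / subset:        IGHV4-34 / USM
ROC n (pos/neg):      57 low-complement / 72 other
AUC:                     0.728
Cutoff (usage):          6.87%  (closest-to-corner)
Sensitivity at cutoff:  66.7%
Specificity at cutoff:  73.6%
Groups:               HIGH 57 / LOW 72 / unassigned 0
==============================================================================
```

The AUC of 0.728 says USM IGHV4-34 usage separates low-complement patients
from the rest clearly better than chance in this simulated cohort; the
6.87% cutoff is the usage value whose operating point (sens 66.7%,
spec 73.6%) lies closest to a perfect classifier. Downstream batteries hang
off the results object:

```python
rho, p = results.usage_correlation("c4")   # -> rho=-0.444, p=1.3e-07
table = results.compare_groups()           # Mann-Whitney / Fisher battery
reg = results.regression("c4")             # standardized subset coefficients
fs = results.flare_survival("tacrolimus")  # -> n=5, log-rank p=0.0389
```

In the same simulated cohort the HIGH group has median SLEDAI-2K 7 versus 2
in the LOW group, lower complement, higher anti-dsDNA, and a higher flare
rate among LLDAS achievers on tacrolimus — the qualitative pattern the
stratification is designed to surface.

Real data enter through `UsageStratification.from_fixture_dir(...)` (a
directory of `{patient}_{subset}.tsv` AIRR files plus `clinical.csv`) or
through `ighvstrat.repertoire.read_clonotype_table` for single files in
either dialect. A `ighvstrat` command-line tool runs the same stages
(`simulate`, `usage`, `stratify`, `associate`, `survive`, `report`, `all`)
with a YAML config and a reproducible run manifest.

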