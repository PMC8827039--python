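# Methods

This note documents the statistical model behind `pathlinc`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the package's known limitations. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## The inference chain

### Rank score

For regulator *i* and coding gene *j*, `r_ij` is the sample Pearson
correlation across all samples (tumor and control pooled by default;
`samples="tumor"` restricts it) and `p_ij` its two-sided p-value from
`t = r·sqrt((n-2)/(1-r²))` on `n-2` degrees of freedom. The rank score is

```
RS_ij = -log10(p_ij) · r_ij          (default, rs_sign="corrected")
RS_ij =  log10(p_ij) · r_ij          (rs_sign="paper")
```

The default sign puts strong positive correlates at the top, the GSEA
convention; the alternative keeps the literal published formula, whose
sign ranks them last, and is retained only for comparison. p-values are
floored at 1e-300 so RS stays finite at exact collinearity; genes with
zero variance are dropped (logged), and ties in RS break by gene id so
output order is deterministic.

### Enrichment score and RES

Walking down the RS-ranked list, a pathway member at position *j* adds
`|RS_j|^w / Σ_members |RS|^w` (weight `w = 1` by default) and a non-member
subtracts `1/(N - N_hit)`. The ES is the running-sum value of maximal
absolute deviation, signed, in [-1, 1]. The implementation evaluates the
running sum's extrema in closed form from the hit positions (the sum is
piecewise linear between hits); tests verify exact agreement with a direct
whole-list walk on hundreds of random instances.

A permutation p-value `p = (1 + b)/(n_perm + 1)` — `b` counting null
scores of the same sign at least as extreme — maps ES to the relative
enrichment score `RES = 1-2p` (ES > 0) or `2p-1` (ES < 0), with `RES = 0`
defined at the measure-zero case ES = 0 for continuity between branches.
With the default `n_perm = 999`, the smallest attainable p is 1/1000, so
the largest attainable |RES| is 0.998. Significance requires
`|RES| > 0.995` (lncRNA) or `|RES| > 0.990` (TF) — strict inequalities —
and BH-FDR < 0.05 computed within each regulator class (the two classes
use different cuts, implying class-wise families; `fdr_family="global"`
switches). The TF rule is applied to |RES|: the published top-TF table
lists strongly negative RES values (e.g. −0.991) among its top hits, so a
one-sided reading would contradict it.

### The permutation null, and why its calibration is a caveat

The default null (`null_scheme="gene_set"`) draws `n_perm` random member
sets of the observed size from the ranked list. This is a *competitive*
gene-set test, and it inherits the well-known property of that family:
when pathway members are co-expressed, their RS values move together, the
true set's |ES| is over-dispersed relative to random sets, and p-values
are anti-conservative. On synthetic null data (planted regulator loading
0, defaults otherwise) about 20–25% of regulator–pathway pairs clear the
full significance rule — far above nominal. The acceptance suite contains
a test asserting a ≤1% null call rate; it fails by design and documents
this measured rate.

The alternative (`null_scheme="regulator"`) permutes the regulator's
expression vector across samples and recomputes the entire ranking per
permutation, preserving the coding matrix's gene–gene correlation. It is
calibrated by construction — and it is the right tool for auditing — but
at 17 samples it has essentially no power at these thresholds: across 999
permutations the maximum chance correlation between a permuted regulator
and a pathway's shared expression axis reaches |r| ≈ 0.8, comparable to a
strongly loaded true regulator, so observed p-values bottom out near
0.01–0.1 and can never reach the p < 0.0025 that `|RES| > 0.995` demands.
At this design no single test is simultaneously calibrated and powered;
the package defaults to the powered, optimistic null that the thresholds
were designed around, and treats RES as a prioritisation score. Users
should validate top pairs orthogonally (the motivating study used RT–PCR
and immunohistochemistry for exactly this reason).

### Differential expression

Welch's unequal-variance t-test per gene on the log2 matrix, two-sided,
BH-adjusted over all tested genes; pass = `adj_p < 0.05` and
`|log2FC| > 1` (log2FC = tumor mean − control mean; both cuts strict).
Welch's t is this package's stated substitute for a moderated
(empirical-Bayes) test; an external DE table can be injected verbatim via
`read_de_table` / `--de-table`, so a limma `topTable` export can drive the
filter instead. Genes with zero variance in both groups are reported with
p = 1 and logged.

Power at the motivating design is intrinsically limited: with 12 vs 5
samples, unit residual SD and a 2-unit shift, the Welch statistic is
t ≈ 3.8 on ~7.5 df; under BH the attainable sensitivity is capped near
0.8 even when most genes are truly shifted (the threshold
`x ≤ 0.05·F(x)` solves at F ≈ 0.84, times ~0.97 for the fold-change gate).
The planted-recovery test asserts sensitivity ≥ 0.7 at exactly these
conditions, below that analytic cap; a moderated test would do somewhat
better by borrowing degrees of freedom across genes.

### Network assembly

The regulatory window of a lncRNA locus is the gene body plus 10 kb
upstream of the transcription start (strand-aware) and 0 bp downstream by
default, clamped at coordinate 0; all coordinates are 0-based half-open,
so a peak abutting a window does not overlap it. Peak–window overlap is
computed with an interval tree and verified against an all-pairs scan.
The funnel is: binding edges → candidate pairs (both members
pathway-significant) → final pairs (both members DE-passing;
`de_mode="either"` relaxes to at least one). A pair carries the union of
its members' significant pathways (a pair can affect several pathways and
a pathway several pairs), the peak count, and the lncRNA's DE statistics
— the convention the motivating study uses to annotate pairs.

## The synthetic-data generator

Each pathway *k* has a latent activity `z_k` per sample: standard normal
plus a tumor-group mean shift `pathway_shift` (default 2.0 — the pathways
are by premise differentially active in tumor, and the shift is set equal
to the planted DE effect). On the log2 scale:

* member gene  = `member_loading · z_k + ε`, `member_loading = 0.9`;
* planted regulator = `regulator_loading · z_k + ε + de_log2fc·1(tumor)`,
  defaults `regulator_loading = 0.6`, `de_log2fc = 2.0`;
* background genes and non-regulators = pure noise; `n_de_background`
  (default 100) background genes get a ±`de_log2fc` tumor shift with
  random sign, emulating the few hundred differentially expressed RNAs a
  real tumor cohort shows;
* `ε ~ N(0, noise_sd²)`, `noise_sd = 1.0`; every gene gets a constant
  baseline drawn from U(2, 10).

Defaults mirror the emulated study: 12 tumor + 5 control samples, 5
pathways × 30 members, 300 background genes, 40 lncRNAs, 15 TFs, 2
planted regulators per pathway per class. `member_loading`,
`pathway_shift` and the planted effect sizes were fixed a priori from the
power analysis above (so that a strongly loaded planted regulator is
recoverable through both the enrichment and the DE layer at this sample
size); they are conditions of the simulated experiment, not fitted
quantities.

Genomics: all lncRNA loci sit on one synthetic chromosome with 1 kb
bodies tiled at 21 kb spacing. That spacing is the smallest for which
default regulatory windows (body + 10 kb upstream) of neighbouring loci
are disjoint for every strand combination, so a planted peak — one 200 bp
peak centred in the bound lncRNA's body — is attributable to exactly one
lncRNA. Planted binding edges connect every planted TF × lncRNA pair
within a pathway; additionally a fraction `frac_bound_lncrnas` (default
0.5) of lncRNAs receives a peak from a random TF.

What the generator does **not** emulate: count-level noise (values are
emitted directly on the log2 scale, since every downstream statistic
operates there), batch effects, overlapping pathways, realistic genomic
coordinate distributions, multi-factor pathway structure, and
regulator–regulator correlation beyond shared pathway latents. Passing
recovery tests therefore show that the chain is implemented correctly and
has power under its own model assumptions — not that those assumptions
hold in any particular real dataset.

## Numerical and design choices

* p-floor 1e-300 for correlation p at |r| → 1; exact collinearity is
  detected with a 1e-14 tolerance on |r| (floating-point r can miss 1.0
  by one ulp).
* Expression TSVs are re-parsed through numpy's correctly-rounded float
  parser; pandas' fast parser is off by one ulp and would break the
  byte-level write→read→write round-trip guarantee every writer makes.
* RS ties break by gene id ascending; ssGSEA ties in per-sample ranking
  use average ranks with a gene-id tiebreak for the walk order.
* ssGSEA: per sample, genes are ordered by expression; the activity is the
  summed difference between the weighted hit CDF (weights = expression
  ranks, exponent 1 by default) and the miss CDF, then min–max rescaled
  per pathway to [-1, 1] across samples for reporting (`rescale=False`
  returns raw integrals).
* The p estimator `(1+b)/(n+1)` guarantees p > 0, hence |RES| < 1
  strictly and finite log-scores.
* Seeding: a single root seed fans out to named per-stage streams via
  `numpy.random.SeedSequence` spawn keys, so stage re-ordering never
  shifts another stage's draws; the manifest is byte-identical across
  runs with equal config and seed.
* Degenerate inputs: zero-variance genes are dropped from ranking; sets
  with no overlap are skipped and logged; genes flat in both groups get
  DE p = 1; TFs present in peak files but absent from the expression
  matrix are dropped with a warning (they can never be
  pathway-significant).
* Test problem sizes (≈500 genes, 55 regulators, 999 permutations) were
  chosen so the full suite exercises every stage at the study's sample
  size in well under five minutes.

## Limitations

* RES significance under the default competitive null is optimistic under
  member co-expression (measured above); treat the network as a ranked
  hypothesis list.
* Welch's t at 12v5 caps DE sensitivity near 0.8 for 2-unit shifts at
  unit noise; inject a moderated-test table for more power.
* Correlation is Pearson on log2 values across pooled groups; group-driven
  association and within-group co-variation are deliberately not
  separated (pooling is the method's definition, and the tumor shift is
  part of the biology it targets).
* The peak-to-gene rule is a fixed upstream window; enhancer-range
  interactions and chromatin context are out of scope.
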