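# Methods

This note documents the models behind `ithkit`, the defaults that matter,
what the synthetic generators do and do not emulate, and the design choices
made where the design was genuinely open.

## Heterogeneity scoring

**Genomic instability** is the absolute number of somatic variant calls per
sample: all SNVs plus insertions/deletions whose inserted/deleted length is
1–100 bp inclusive (`max_indel_len`, default 100). Longer indels are
excluded as likely structural events outside the score's intent.

**MATH** is `100 × MAD / median` over the sample's mutant-allele fractions,
with MAD scaled by the normal-consistency factor. Two choices deserve
emphasis:

- *The consistency constant.* The scale factor is stored as the
  conventional printed value **1.4826** (`MAD_SCALE`); the exact value
  1/Φ⁻¹(3/4) = 1.4826022… is available as
  `normal_consistency_constant()` and agrees with the stored constant to
  4 decimal places. The constant appears in both numerator conventions
  found in the literature ("scale the MAD" vs. "scale the median"); it is
  applied here to the MAD, the standard construction that makes the MAD an
  SD estimate in the normal limit. In the normal limit MATH therefore
  converges to 100·σ/μ (the coefficient of variation in percent), which the
  tests check at μ = 0.3, σ = 0.06 → MATH ≈ 20.
- *Minimum loci.* The MAD/median ratio is unstable on tiny mutation sets,
  so MATH is **undefined** (never imputed as 0) below `min_loci` fractions,
  default **5**. Variants with zero or missing depth contribute to the
  instability count (which is defined on calls) but not to the MAF vector
  (which is defined on fractions).

**Instability–ITH correlation** is the Pearson correlation between
log10(instability) and MATH, per cancer type. Samples with zero instability
are excluded rather than pseudocounted (log10(0) is undefined, and such
samples carry no MAF distribution either); fewer than 3 usable samples
yields a flagged undefined result. The even-length median is the mean of
the two central order statistics throughout.

## Mutation–ITH association

The **mutation matrix** is strictly binary: a sample–gene entry is 1 if at
least one retained variant falls in the gene. Binarization removes the
leverage a hypermutated gene would gain from multiplicity; no further
hypermutation handling is applied. Genes are optionally collapsed to 17
broad functional categories (epigenetic modifiers, genome integrity, RTK
signaling, …) by logical OR over member genes; the gene→category table
ships as an editable TSV resource (`resources/pathway_categories.tsv`)
compiled from the well-known pan-cancer significantly-mutated-gene
classification.

**Category models** regress heterogeneity on all category indicators
jointly (OLS, per cancer type). Constant columns are dropped with a warning
and their coefficients reported as undefined. The Benjamini–Hochberg family
is the set of coefficient p-values *within one cancer type's model* — each
model is displayed and interpreted per type, so the adjustment matches the
inference unit. R² and the model F-test p-value are reported alongside.

**LASSO driver discovery** standardizes the binary indicators (so
coefficients are comparable effect sizes per SD of mutation status) and
computes the coordinate-descent path over a 100-point log-spaced penalty
grid from the smallest all-zero penalty down to 10⁻³ of it. A gene's
*entry rank* is the grid point at which its coefficient first becomes
nonzero — the order of inclusion, read as relative importance. Ties at a
grid point break by larger absolute coefficient at entry, then gene name,
for determinism. The optimal penalty maximizes mean out-of-fold explained
variance over seeded K-fold CV (default 10 folds); the R² standard
deviation is the fold-wise dispersion at that penalty, and a model is
*significant* when mean R² exceeds zero by more than one SD. Genes mutated
in fewer than `min_mutated` (default 2) samples are excluded beforehand:
a single-sample indicator can absorb one residual exactly and corrupts the
path. Model evaluation predicts from the optimal-penalty coefficients and
reports the Pearson correlation of predicted vs observed heterogeneity.
The heterogeneity response is used on its raw (untransformed) MATH scale.

## Variant filtering cascade

Stages run in a canonical order — read support (alt ≥ 5 and depth ≥ 30,
both inclusive), known-germline removal (dbSNP members removed unless also
in COSMIC), SNV-only, then baseline-fixed removal — each recorded in a
report whose counts telescope exactly. The first three stages are
independent predicates, so the final survivor set is order-invariant; the
report is order-sensitive, hence the fixed canonical order. Variants with
undefined depth are removed in a dedicated, visible report stage.

The baseline rule removes a variant when it is present in the matched
earliest-timepoint sample **and** fixed there (baseline MAF ≥ 1, compared
with a 10⁻⁹ tolerance) — the conjunctive reading of "present in the
earliest replicate and with MAF equal to 1". Because exact fixation is
fragile under sequencing noise, the threshold is configurable
(`--baseline-maf 0.95` style relaxation); the disjunctive alternative
(remove on any baseline presence) can be emulated with
`--baseline-maf 0`. Database membership comes from ID sets or
pre-populated flags only; there is no network lookup.

## Subclonal clustering

The clustering input keeps variants supported by ≥ `min_reads` (default
**50**) reads in *every sample where observed*, aligned across samples by
(chrom, pos, ref, alt); "support" means total depth by default
(`count_mode="alt"` switches to alt-read support). Absent observations are
marked depth 0 and contribute nothing to the likelihood.

The model is a finite binomial mixture: variant *v* in sample *s*
contributes `alt(v,s) ~ Binomial(depth(v,s), p[k(v),s])`, with one center
per cluster per sample and mixture weights shared across samples. Fitting
is EM with the log-likelihood asserted non-decreasing each iteration;
defaults are 10 random restarts per K (centers initialized at observed VAF
vectors of randomly chosen variants plus small jitter), relative tolerance
10⁻⁶, 500 iterations max, K searched over 1…10 and chosen by minimal BIC
with `K·S + (K−1)` free parameters. Non-convergence returns the best fit
with a warning flag rather than an error.

This is a deliberate simplification of Dirichlet-process binomial
clustering with copy-number priors: centers are **allele fractions, not
cellular prevalences** (no copy-number or purity correction), and K is a
point estimate, not a posterior. The object consumed downstream — the
cluster × sample mean-VAF matrix — is preserved. Mean VAFs average
observed alt/depth over assigned variants; a cluster unobserved in a
sample yields an undefined (NaN) cell, never 0.

Sample dendrograms use average-linkage agglomerative clustering on a
pairwise-complete Euclidean distance: squared differences are summed over
cells defined in both samples and rescaled by (total cells / shared cells),
so sparsely shared pairs are not artificially close; a pair with no shared
cells gets the maximal-scale distance √K. Leaf order is made deterministic
by optimal leaf ordering on the same distances.

## Respirometry

Traces must present phases in assay order (baseline → oligomycin → FCCP →
rotenone+antimycin) with ≥3 baseline points. Parameters follow the assay
definitions literally: non-mitochondrial respiration is the mean post
rotenone/antimycin OCR; basal respiration is the **3rd baseline point**
(taken literally, not a mean — it is the last, most stabilized
pre-injection measurement) minus non-mitochondrial; maximal respiration is
the mean post-FCCP OCR minus non-mitochondrial; the spare capacity rate is
maximal − basal, enforced as an exact identity on the result type.
Oligomycin-phase values are stored for plotting but enter no formula, and
ATP-linked respiration is deliberately not derived (it is not in the
parameter set this pipeline reports). Protein normalization (OCR/µg)
happens once, guarded against double application, and commutes with
parameter derivation. Group comparisons use the pooled-variance unpaired
t-test by default (Welch via flag), matching the "Student's t-test"
convention of the assay analyses; basal-relative scaling of traces is a
plotting option only and never feeds parameter derivation.

## Synthetic data

The generators produce data with exactly the structure the estimators
assume, which is what makes the recovery tests sharp — and is also their
limitation:

- `simulate_tumor`: diploid, copy-neutral, heterozygous-only mutations, so
  expected MAF = purity × CCF/2 analytically; depth ~ Poisson(mean_depth)
  floored at 1 read; alt ~ Binomial(depth, MAF). No sequencing-error model,
  no selection, no copy-number events — MATH values on real tumors, where
  copy number distorts allele fractions, will be noisier than these tests
  suggest.
- `simulate_cohort`: heterogeneity = baseline + Σ effect·indicator +
  Normal noise, with independent per-gene mutation indicators. Real
  mutation co-occurrence structure (mutual exclusivity, subtype
  confounding) is not emulated, so LASSO recovery rates here are an upper
  bound.
- `simulate_timecourse`: serial samples (1/3/6-month analogs) from one
  lineage; each step appends new subclones (fresh private coordinates, CCF
  drawn from 0.2–0.4, 30 mutations each by default, 2 subclones per step)
  before reads are resampled, and a configurable number of variants at
  allele fraction exactly 1 persists across all timepoints to stand in for
  germinal variants. Alleles are a deterministic function of coordinate so
  the same locus aligns across samples. With gain 0, MATH stays within the
  generator's resampling noise band (empirically < 8 MATH units of drift at
  the default 100-mutation, 100× configuration); with gain 2 it rises
  monotonically across steps in ≳90% of seeds.
- `simulate_ocr_trace`: phase levels are the parameter formulas inverted
  (baseline at basal+non-mito, FCCP at maximal+non-mito, rotenone phase at
  non-mito), plus i.i.d. Normal noise; at zero noise derivation returns the
  input parameters exactly.

All generators are pure functions of (specification, seed) via
`numpy.random.default_rng`.

## Problem sizes

Default test and demonstration scales — 100-fixture oracle sweeps,
two-cluster mixtures of 200 variants at 1000×, LASSO cohorts of n = 300 ×
50 genes, 50-seed time-course sweeps — were chosen as the smallest sizes at
which the statistical properties under test (recovery rates, null false
positive rates, trend monotonicity) are stable, and run in seconds to a few
minutes on one CPU.

## Known limitations

- MAF-format read-count column names vary across dialects; the defaults
  (`t_ref_count`/`t_alt_count`) are a convention, overridable via
  `column_map`.
- Indels from "-"-allele MAF dialects are anchored with a placeholder `N`
  base (the true reference base would require the genome); deduplication
  and length logic are unaffected, but the anchor base is not real.
- The mixture stand-in does not reproduce posterior cluster counts of
  Dirichlet-process implementations, and no claim is made that it does.
- Survival analysis, copy-number estimation, read alignment and variant
  calling are upstream/out of scope; the pipeline starts at called
  variants with read counts.
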