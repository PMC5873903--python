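# Methods

## Problem setting

An arrayed transposon-insertion library stores one bacterial mutant per well
of a stack of 96-well plates. To map every insertion site to its well in a
single sequencing run, each well is assigned a binary codeword over 24
sequencing pools and the mutant is pipetted into exactly the pools whose bit
is 1 (combinatorial pooling, or group testing). Sequencing each pool then
reveals, for every insertion site, the set of pools it appears in — its
barcode — and an exact match of the barcode against the design recovers the
well. Downstream, the mapped library supports three analyses: saturation
(rarefaction), pathway-level essentiality prediction from genes that never
acquired an insertion, and validation of candidate genes from a
metagenome-wide association study (MGWA) of gene-family presence/absence
against host-colonization load.

## Pooling code

Codewords are constant-weight over 24 pools with weights restricted to
{10, 12, 14}. Because allowed weights differ by 2 and a single pool dropout
or gain changes the observed weight by exactly 1, any single-pool error
yields a weight outside the allowed set and the site is flagged rather than
mis-mapped. The code construction is ours: each weight class is enumerated
in colexicographic order (Gosper's hack) and the classes are interleaved
round-robin; a seeded permutation of pool positions is then applied
uniformly, giving reproducibly distinct but isomorphic codebooks per seed.
Two optional filters strengthen the code at the cost of capacity:

* `subset_free` — rejects any codeword that is a strict bitwise subset or
  superset of an accepted one. This prevents the silent failure mode in
  which a weight-12 barcode that loses two pools collides with an assigned
  weight-10 codeword.
* `min_distance` — enforces a minimum pairwise Hamming distance (4 is the
  useful setting; unfiltered constant-weight neighbours sit at distance 2).

Both default to off; the unconstrained capacity is C(24,10) + C(24,12) +
C(24,14) = 6,626,668 codewords, far above any practical library.
Uniqueness is enforced globally across plates, not per batch — necessary
because the final pools merge all plates, so a repeated codeword would be
undecodable.

The two-stage batch plan mirrors bench practice: plates are pooled five at
a time into intermediate sets of 24 pools, and final pool *i* merges all
intermediate pools *i*. The plan-execution round-trip (union of a well's
intermediate memberships equals its codeword) is asserted in tests.

## Decoding

Per site, per-pool read counts are thresholded at 50 reads (a count of
exactly 50 calls presence; the threshold phrase leaves the boundary open and
we adopt ≥). Barcode weight then classifies the site: weight in {10,12,14}
is a mapping candidate; weight 1–2 is treated as a sequencing artifact;
weight 0, 3–9, 11 or 13 as pool dropout / low coverage; weight above 14 as
suspected sister clones — two wells seeded from the same transposant, whose
pool patterns union into an over-weight barcode. Candidates are matched
exactly against the design; unmatched candidates are discarded rather than
error-corrected (a Hamming-distance-1 rescue exists behind a flag for
min-distance-4 designs but is off by default, matching the conservative
discard behaviour the analysis is built on). When two sites decode to the
same well, both are demoted to unmatched: a duplicate claim means at least
one of them is wrong and there is no evidence which.

## Synthetic data

The generators produce every pipeline input with known ground truth; all are
deterministic given their seed.

* **Annotation** — non-overlapping genes on one contig; gene lengths uniform
  on 300–1500 bp (mean ≈ 900 bp, a typical bacterial ORF-length spread),
  leftover sequence distributed multinomially among the gaps; pathway
  members drawn without replacement per pathway.
* **Library** — insertions uniform per base pair over non-essential gene
  space, or intergenic space with probability `intergenic_fraction`
  (default 0.15, matching a library in which ~85% of mapped mutants sit in
  ORFs); never inside a designated essential gene. Each mutant is a sister
  clone of an earlier one with probability `sister_clone_rate` (default
  0.02). Wells fill plate by plate in row-major A1..H12 order.
* **Pooled reads** — pools containing a mutant draw negative-binomial depths
  with mean `mean_depth` (default 200 reads, the depth scale the 50-read
  threshold is designed for) and dispersion α = 0.3 (variance m + αm²),
  zeroed independently with probability `dropout_p`; pools outside a site's
  union pattern draw Poisson(0.5) background (index bleed, far below
  threshold in expectation); sister-clone sites accumulate the sum over
  their wells; spurious sites (Poisson(rate × true sites) of them) light up
  1–2 random pools at full depth, emulating sequencing artifacts.
  "Noiseless" simulations set `dropout_p = 0`, `noise_mean = 0` **and**
  `dispersion = 0` (Poisson depth): with overdispersion left on, ~8% of
  positive pools fall below 50 reads at mean 200, which is a feature of the
  realistic regime, not of the noiseless identity.
* **Strain panel** — log CFU = baseline + Σ effects of OGs present +
  experiment effect N(0, sd²_exp) + strain effect N(0, sd²_strain) +
  residual; counts reported as round(exp(·)). Defaults mirror the study
  conditions: 41 strains, 3 experiments × 3 replicates, baseline 11.5
  natural-log units (≈10⁵ CFU per fly-pool homogenate), sd_experiment 0.5,
  sd_strain 0.8, sd_residual 0.7. The variance structure is what the
  association model assumes; the magnitudes are our choices (only the
  structure is dictated by the emulated experiment) and sit in the range
  where true effects of ~2 log units are detectable but not trivial.
* **Load table** — same structure with per-treatment fixed shifts against a
  control; default 3 experiments in triplicate, matching the validation
  experiments this emulates.

What the generators do **not** emulate: positional insertion bias of the
transposon, polar effects on downstream genes, CFU detection limits
(exposed as an optional left-censoring parameter, default off), pipetting
volume errors, and any fly biology beyond the stated variance structure.
Passing tests therefore demonstrate correctness of the decoding and
statistics under the stated noise model, not robustness to every artifact
of a real run.

## Enrichment statistics

Both pathway analyses (essentiality and top-MGWA-hit enrichment) share one
machinery. For each pathway a 2×2 table contrasts focal-set membership
inside vs outside the pathway (disjoint cells, pathway-vs-rest). The
Pearson chi-square statistic (no continuity correction) is assessed by
fixed-margin resampling: for a 2×2 the null table is determined by one
hypergeometric cell, B = 2000 draws by default, and p = (k + 1)/(B + 1)
where k counts resampled statistics ≥ the observed one (ties included, as
in R's `chisq.test(simulate.p.value=TRUE)`). The floor is 1/(B + 1) =
0.0005. Benjamini–Hochberg FDR is applied across the tested family.
Pathways below `min_count` (default 4; applied to pathway size for the
essentiality scan, and to both top-set and reference counts for the MGWA
scan) are excluded *before* testing, so they do not enter the FDR family.

**Direction call.** A pathway is labelled essential (or enriched) when its
focal fraction a/n exceeds a baseline rate. The natural baseline is the
genome-wide focal fraction A/G, but pathway-annotated genes are skewed
toward well-characterized core functions whose zero-insertion rate can sit
well below the genome-wide one; pathways falling between the two rates flip
label depending on the choice. The essentiality scan therefore defaults to
the annotated-gene baseline (zero-insertion rate among genes carrying at
least one pathway label), with `direction_background="genome"` available.

## Association model

Per orthologous group:

    log(CFU) = β₀ + β·presence + u_experiment + u_strain + ε

with independent zero-mean random effects for experiment and strain. The
crossed random effects are encoded as two variance components on a single
grouping (the standard statsmodels `MixedLM` construction); variance
components are constrained non-negative, and boundary fits are reported,
not errored. β is tested by a likelihood-ratio test between maximum-
likelihood fits of the nested models (χ²₁ reference); a Wald z-test is
available behind `test="wald"`. OGs with fewer than two strains in either
presence class are returned untested ("monomorphic"). Zero CFU counts are
replaced by 1 before taking natural logs and the replacement is logged.
Bonferroni correction multiplies each raw p by the number of OGs actually
tested; the top set for enrichment collects OGs with raw p < 0.001 (a flag
switches the cutoff to corrected p).

The mutant-load comparison fits log(CFU) on treatment fixed effects with a
random experiment intercept and reports each treatment's Wald contrast
against the control. With a single experiment the random effect is
inestimable and the function falls back to OLS with a loud warning.

## Numerical and testing choices

* Monte-Carlo tie handling uses a 1e-9 relative tolerance so an exact
  re-draw of the observed table counts toward k.
* Degenerate 2×2 tables (an empty margin) return statistic 0 and p = 1
  rather than NaN.
* Rarefaction averages over random orderings (default 100 permutations);
  tests check it against the closed form
  E[distinct after k] = Σ_g (1 − C(N−m_g, k)/C(N, k)).
* Calibration suites run at deliberately modest sizes chosen as a
  compromise between statistical resolution and runtime: 100 simulated
  panels for effect recovery (mean bias of β̂ under 0.1 at effect 2.0 with
  41 strains), 400 null panels for the type-I-error check (rejection rate
  at α = 0.05 inside the exact binomial 99% interval), 1000–2000
  permutations for rarefaction agreement.
* Decoder recovery at scale is checked on a 5,000-mutant noiseless library
  over a 53-plate design: 100% of well assignments must be recovered.

## Known limitations

* Essentiality is operational: a gene with zero insertions in a
  near-saturated library may instead be small, recently duplicated, or
  adjacent (polar) to an essential gene; a gene with one 3′-end insertion
  is binned non-essential even if only partially disabled.
* The exact-match decoder discards recoverable information when the design
  has minimum distance ≥ 4; the optional distance-1 rescue recovers most
  single-dropout sites at a quantifiable risk on subset-containing codebooks.
* The association model treats OGs independently; linked gene families on
  shared genomic backgrounds inflate the effective number of tests, and
  Bonferroni over OGs is conservative in the other direction.
* `MixedLM` variance components at the boundary (zero) make the LRT for β
  slightly conservative; the null-calibration test bounds the practical
  impact under the default design.
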