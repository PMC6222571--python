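# Methods

This note documents the models behind `acylqtl`, the calibrations and
numerical choices, and what the synthetic populations do and do not emulate.

## The cross being emulated

The package simulates an F2 mapping population from a cross between a
reference inbred (founder 0, "A" alleles) and a near-inbred mutant stock
(founder 1, "B" alleles). Five causal loci segregate
(`default_causal_loci()`):

| locus | chrom:pos | recessive allele from | effect when recessive |
|---|---|---|---|
| reduced-acylation (`aat1`) | 1:300,173,138 | mutant stock | acylation class switch; AC −23.3 mg/kg |
| intensifier (`in1`) | 7:88,000,000 | mutant stock | AC +105.4 mg/kg |
| colorless aleurone (`c1`) | 9:78,500,000 | reference line | AC −29.1 mg/kg |
| colored aleurone (`r1`) | 10:74,800,000 | reference line | AC −24.2 mg/kg |
| pericarp color (`p1`) | 1:48,000,000 | mutant stock | none (inert indicator) |

The reduced-acylation position is the candidate acyltransferase's start
coordinate on B73 RefGen_v3; the regulators' true genomic homes are known
but their exact coordinates are irrelevant to any package behaviour, so
they default to mid-arm positions on their chromosomes and are fully
configurable.

## Marker map

Markers (default 8,062) are allocated to the 10 chromosomes proportionally
to physical length (at least one each) and placed by sampling a
piecewise-uniform density in which the terminal regions — a total
`end_fraction = 0.2` of each chromosome, split between the two ends — have
`end_density_boost = 3`-fold elevated density, reflecting the euchromatic
bias of reduced-representation sequencing. The resulting mean adjacent gap
is ~256 kb and ~96% of gaps are under 1 Mb. The generator does **not**
emulate the sub-kilobase clustering of real GBS markers around restriction
sites (real panels have ~18% of close gaps under 1 kb; ours essentially
none) — spacing diagnostics report whatever map they are given.

## Meiosis

Gametes are formed under the standard no-interference model: the crossover
count per chromosome is Poisson with mean equal to the map length in
Morgans, and crossover positions are uniform on the genetic map. Genetic
positions are linear in bp at a single configurable rate, default
`cm_per_mb = 0.7` (a ~1,500 cM genome). Between any two positions at map
distance *d* cM this realises the Haldane recombination fraction
r = (1 − e^(−2d/100))/2, which the tests verify against the closed form.
Real maize recombination is concentrated toward chromosome ends; a uniform
rate slightly lengthens linkage blocks near the telomeric reduced-acylation
locus relative to real data.

Causal loci are simulated on the same gametes as the markers (they need not
coincide with a marker), so marker–locus linkage arises mechanically. A
`residual_founder_het = 0.05` fraction of markers is heterozygous in the
mutant-stock founder for a second minor allele; each F2 individual's F1
parent inherits one of the two stock alleles, which produces occasional
tri-allelic sites in the population, exercising the minor-allele pooling of
the numeric coding.

## Genotype coding and degradation

Raw calls are unordered allele pairs. At each marker the most frequent
allele in the population is the major allele (ties broken
lexicographically): major homozygote → 2, any heterozygote → 1, every other
homozygote → 0; MAF is the pooled-minor frequency folded to [0, 0.5].
Degradation masks entries as missing (Bernoulli `missing_rate`) and flips
surviving heterozygotes to a random homozygote of one of their two alleles
(`het_miscall_rate`), then recodes from the degraded calls; the recorded
causal truth is never degraded. Both rates default to 0 because the scans
emulate a post-imputation matrix; imputation itself is out of scope, and
downstream scans instead drop missing entries pairwise per marker.
Filtering order matches the original pipeline: sample filter (missing
fraction strictly greater than 0.80 excluded), MAF recomputed, then the MAF
filter (boundary value 0.05 kept).

## Phenotype model

Anthocyanin content: AC = max(baseline + Σ locus shifts, 0) × ε, with
ε ~ LogNormal(−σ²/2, σ), σ = `ac_noise_sigma` = 0.35 — unit-mean
multiplicative noise giving the right-skew seen in such populations.
The baseline of 89.0 mg/kg puts the expected population mean at
89.0 + (105.4 − 23.3 − 24.2 − 29.1)/4 ≈ 96.2 mg/kg, each recessive class
occupying ¼ of an F2.

Acylation percentage is bimodal: N(15.0, 5²) for reduced-acylation
homozygotes, N(70.8, 5²) otherwise, clipped to [0, 100]. No within-class
dispersions are published for the source cross; 5 percentage points keeps
the classes cleanly separated around the 50% classification cutoff while
leaving visible within-class spread, and is configurable (`acylation_sd`).

Peak areas are decomposed from AC and acylation %: total area is
proportional to AC through the external standard (1000 mg/kg ≡
`standard_total_area`), the acylated share equals the acylation fraction,
and fixed within-group composition weights split each share over the
eight-compound catalogue (cyanidin-dominant, as in purple maize). Because
the decomposition is exact, re-deriving traits from the generated peak
table recovers AC and acylation % to numerical precision — a round-trip the
tests assert.

Replicates: each of the two injections gets one multiplicative factor
1 + N(0, s²) applied to all its peaks (modelling injection-volume
variation, which cancels in acylation %). For a two-replicate CV the
statistic sd/mean has expectation s·√(2/π), so the generator sets
s = (target CV)·√(π/2) to make the population-mean CV equal the configured
3.09%. The factor pair is centred so replicate means reproduce the
generated areas exactly (the CV, a scale-free ratio, is unaffected).

Kernel-marker scores: the speckling score is 1 for individuals heterozygous
at `r1` (a selfed heterozygote's ear segregates speckled kernels under R1
imprinting; both homozygotes give uniform ears), and the colorless score is
the `c1` recessive indicator. The real study scored ears visually and
conditioned on pigmented kernels, which biases class proportions; the
generator does not model that conditioning.

## Scans and thresholds

The per-marker model is OLS of the trait on the numeric genotype code with
an intercept and any covariate markers; significance is the two-sided
t-test of the marker slope, df = n_used − rank. Three execution paths give
identical answers (verified against normal-equation oracles to 1e-10):
a fully vectorised masked simple regression (no covariates), a vectorised
Frisch–Waugh–Lovell projection (covariates, complete data), and a
per-marker least-squares loop (covariates with missing entries). Markers
monomorphic among the used samples, collinear with the covariate set, or
with fewer than three complete observations get p = 1 and a flag. Perfect
fits (zero residual) are floored at p = 1e-300 so −log10(p) stays finite.

The genome-wide threshold is Bonferroni α/n over the scanned markers
(−log10(0.05/8062) ≈ 5.2074). The relaxed exploratory threshold
(p < 1e-4) is just an alternative `Threshold` constructor. Stepwise
selection appends the top marker of each round to the covariate set while
it passes the per-test threshold, up to `max_qtl = 10` as a runaway guard;
ties on p break to the smaller (chromosome, position).

## Variance components

Each locus enters as a two-level random factor through its recessive-class
indicator. For every factor the Type-III sum of squares (full main-effects
projection minus the projection without that factor) and the residual SS
are equated to their expectations under the all-random model,
E[y'Qy] = Σ_g σ²_g·tr(Q Z_g Z_gᵀ) + σ²_e·tr(Q), and the linear system is
solved for the components — the method-of-moments estimator SAS labels
"Type 3". On balanced one-factor data this reduces to the classical
(MSB − MSW)/n oracle, which the tests assert. Negative solutions are
truncated to zero before proportions are formed (raw solutions retained);
an ill-conditioned system falls back to a sequential (Type-I)
decomposition with a logged warning. Interactions are not modelled. The
companion fixed-effects summary is one OLS fit of all indicators at once;
aliased (perfectly confounded) factors are reported, not silently dropped.

## Power simulation

For each subsample size, individuals are drawn without replacement
(independently across the 100 replicates, all streams derived from one
seed), the subsample is rescanned with no covariates, and the top marker is
classified: *detected* if Bonferroni-significant (n = all scanned markers)
and within 10 Mb of the known locus on its chromosome, *false positive* if
significant elsewhere, otherwise non-significant. Averaged −log10(p) is
conditioned on significant replicates; averaged distance on detected ones.

One subtlety is resolved explicitly: with discrete genotypes and small
subsamples, distant markers can carry bitwise-identical columns (no
recombinant gametes among those drawn), so the maximal significance is
attained by a *set* of tied markers that can span more than 10 Mb. A fixed
coordinate tie-break would then systematically point away from a causal
locus near a chromosome end and convert exact ties into spurious false
positives. "The most significant SNP" is ambiguous under a non-unique
maximum, so classification considers the whole argmax set: a replicate is
detected if any tied top marker on the true chromosome falls within the
window, and the reported distance is that of the nearest tied member. The
deterministic coordinate tie-break is retained wherever a single marker
must be named (stepwise selection, report rows). A window at least as long
as the genome classifies every significant replicate as detected, so false
positives are impossible by construction in that limit.

Under the default conditions the per-replicate detection probability at
subsample size 40 for the 25%-recessive binary trait is ~0.98–1.0 (the
rare miss is a linked cluster 11–16 Mb out that is strictly more
significant in that draw — the same mechanism that inflates false
positives at size 20), so 100-replicate detection percentages fluctuate in
the high 90s across seeds; the acceptance checks treat detection as
effectively complete (≥95%) rather than as a single-realization 100.

## Reproducibility and problem sizes

All randomness descends from one integer seed; each stage (marker map,
meiosis, degradation, phenotypes, power subsampling) draws from its own
stream derived by stable hashing of the stage name, so re-running one stage
never perturbs another. Seeded runs are bit-reproducible, and pipeline
outputs carry the seed and a configuration hash.

Problem sizes: the acceptance script and the simulation-backed acceptance
tests run the full study conditions (128 individuals × 8,062 markers,
100 replicates per subsample size — a few seconds per experiment thanks to
the vectorised scan). The general test suite uses an 800-marker population
for shared fixtures and 10-marker maps where only phenotypes matter;
Monte-Carlo checks (segregation, Haldane) use 10,000 individuals or 20,000
gametes with 3-standard-error bands.

## Known limitations

* Uniform within-chromosome recombination rate and no crossover
  interference; no sub-kb marker clustering around restriction sites.
* No sequence-level reads, variant calling or imputation modelling; the
  generator emits the post-imputation matrix directly (or a degraded one).
* The fixed-effects / variance-component stages consume true class
  indicators from the generator; the real study inferred one regulator's
  genotypes from its most significant SNP, so its published effect sizes
  carry an extra layer of inference noise not modelled here.
* Visual-scoring biases (sampling only pigmented kernels) are not modelled,
  so marker-gene class proportions follow Mendelian expectations rather
  than the published, conditioned ones.
* Identity/coverage homology screening of candidate proteins is out of
  scope; the motif filter assumes a pre-screened FASTA. The shipped
  candidate table is a documentation fixture, not a recomputation.
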