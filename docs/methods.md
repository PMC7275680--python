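# Methods

`fenclone` analyses how the clonal diversity and genetic variation of a
grid-sampled clonal plant respond to local environment. The intended setting
is a set of 1 m² plots scattered over a habitat (the motivating case is a
sedge in a high-alpine fen), each plot sampled at a fixed number of subplot
ramets and genotyped at a few codominant microsatellite loci, with per-plot
elevation and soil phosphorus/potassium measurements. This note documents
the models, the conventions, the numerical choices, and what the synthetic
generator does and does not emulate.

## Clone assignment and clonal diversity

Ramets with identical canonicalized allele pairs at every retained locus are
assigned to the same multilocus genotype (MLG), i.e. the same clone.
Matching is *exact*: no genotypic-distance tolerance for somatic mutation or
scoring error is offered. This is deliberate — with half a dozen loci and a
handful of alleles each, a distance threshold cannot be calibrated from the
data at hand, and the operational definition "same genotype = same clone" is
the standard one for this marker density.

Loci dominated by null alleles are removed before assignment:
`filter_null_loci` drops any locus whose fraction of samples with a missing
call strictly exceeds a threshold (default 0.03; a locus failing in 11 of
320 samples, 3.4 %, is removed). Samples that still carry a missing call at
a retained locus are excluded from clone assignment with reason "incomplete
genotype" but are kept for the allele-frequency statistics, which track a
per-locus sample count; this uses all available data without inventing
genotypes.

Clonal diversity per plot is genotypic richness R = (G − 1)/(N − 1) with G
the number of distinct MLGs and N the number of ramets. By default N is the
number of ramets *collected* (the design's subplot count), not the number
successfully genotyped; `n_for_r="genotyped"` switches the denominator. The
default matches how R is conventionally reported for fixed sampling grids
(a monoclonal plot scores 0.00, an all-distinct plot 1.00).

## Per-plot genetic variation

All indices are per-locus quantities averaged over retained loci, computed
over every sampled ramet (not one ramet per genet — the point of the design
is plot-level variation, and a genet-level recount would discard the
within-plot replication):

* Na — number of alleles with frequency > 0;
* Ne — effective number of alleles, 1/Σᵢpᵢ²;
* Ho — fraction of complete samples with two distinct alleles;
* He — *unbiased* expected heterozygosity, (2n/(2n−1))(1 − Σᵢpᵢ²), n the
  complete-sample count at the locus;
* F — fixation index, averaged per locus as (Heₗ − Hoₗ)/Heₗ using the
  *biased* Heₗ = 1 − Σpᵢ², over polymorphic loci only; undefined when no
  locus is polymorphic.

The asymmetry (unbiased He in the report, biased per-locus He inside F) is
intentional: it reproduces the behaviour of the summary software this field
routinely uses for codominant data, in which F = 1.00 exactly characterizes
a plot with allelic variation but no observed heterozygote. Loci with no
complete sample in a plot are skipped from that plot's means (the divisor is
the number of contributing loci) rather than propagating NaN. Rounding to
the two decimals of the report tables happens only at the presentation
layer.

All five indices are verified against an independent brute-force recount
(plain tallies, no shared code) to 1e−10 on randomized plots.

## Spatial detrending with Moran's Eigenvector Maps

Irregularly placed plots can carry spatial trends that masquerade as
environmental effects. The package removes them with MEMs: eigenvectors of
the doubly-centered spatial weighting matrix HWH (H = I − J/n), which form
an orthogonal, zero-mean basis of spatial patterns ordered by scale; the
Moran's I of eigenvector vₖ is (n/ΣW)·λₖ, an identity asserted in the tests
to 1e−8.

The spatial weighting matrix W is selected from a candidate grid: ten
distance thresholds evenly spaced between the longest minimum-spanning-tree
edge (the smallest threshold keeping the graph connected) and the maximum
pairwise distance, crossed with binary, linear (1 − d/D) and concave
(1 − (d/D)², D the maximum pairwise distance) weighting functions, plus
union-symmetrized k-nearest-neighbour graphs for k = 1..n/2 — 38 candidates
for 16 plots. The decay is scaled by D rather than by the threshold so that
edges sitting exactly at the threshold keep a positive weight; otherwise the
smallest sweep value would disconnect its own critical edge. The winning
candidate maximizes the adjusted R² of an all-MEM linear model, averaged
over the response variables, so one shared W serves the whole analysis;
ties break toward fewer MEMs, then grid order. When a candidate's full
basis leaves no residual degrees of freedom it is evaluated on its
positive-eigenvalue MEMs only.

Per response, MEMs (positive-eigenvalue ones by default — negative
eigenvalues encode fine-scale negative autocorrelation that is rarely a
"trend") are forward-selected in order of marginal R², each candidate tested
by permutation (default 999 permutations, seeded; p = (1+#≥obs)/(nperm+1)),
with a double stopping rule: stop at the first candidate with p > α
(default 0.05) or when the cumulative adjusted R² exceeds that of the
full-basis model. The detrended variable is the residual of an OLS fit on
the selected MEMs plus intercept; an empty selection is an explicit
passthrough. Only the response variables are detrended — elevation, P and K
enter the regression untouched.

## Robust Bayesian regression

Each (detrended) response is standardized (mean 0, sd 1, n−1 divisor) and
modelled as Student-t:

    yᵢ ~ t(ν, μᵢ, σ),  μᵢ = β₀ + β₁·elev + β₂·P + β₃·K

with standardized predictors. Priors: all β ~ Normal(0, precision 4) —
sd 0.5 on the standardized scale, which keeps coefficients near zero unless
the data insist; ν ~ 1 + Exponential(mean 29), spending prior mass on both
heavy-tailed and near-normal regimes; σ ~ Uniform(10⁻³, 10). The heavy
tails damp the influence of outlying plots (soil nutrients in small plots
are notoriously long-tailed). The intercept gets the same prior as the
slopes; with standardized data it is essentially zero anyway.

Sampling is adaptive Metropolis-within-Gibbs, vectorized across four
parallel chains with distinct sub-seeds: per-coordinate Gaussian random
walks for the β's, log-scale walks for σ (flat prior within bounds,
Jacobian-corrected) and ν−1 (exponential prior), proposal scales tuned
during 500 adaptation steps toward ~44 % acceptance, then 1,000 burn-in
steps and 20,000 saved draws in total (5,000 per chain). If the minimum
effective sample size over the four coefficients is below 10,000 the
thinning factor doubles and the schedule re-runs, capped at thin = 64
(beyond the cap a warning is recorded instead of looping forever). ESS uses
Geyer's initial-positive-sequence truncation of the autocorrelation (summed
over chains); convergence is monitored by the between/within-chain
Gelman–Rubin factor, flagged above 1.1. Correctness of the kernel is
established behaviourally: prior-only runs reproduce the Normal(0, 0.5)
prior sd within 0.02; planted-effect fits at n = 500 recover the truth and
agree with least squares; and 90 % HDIs cover true coefficients at 90 % ± 5 %
over 200 replicates.

Summaries per parameter: MPV (posterior mode; argmax of a Silverman-
bandwidth Gaussian KDE on a 512-point grid spanning the draw range, grid
ties breaking to the lower value, constant draws returning the constant),
90 % highest-density interval (shortest window of ⌈0.9·M⌉ sorted draws),
and PDist (% of draws above zero). Slope classification: *credible* when
the HDI excludes zero, *trend* when PDist > 90 or < 10, *none* otherwise.
σ and ν are reported as "scale" and "normality" without classification.
All nine responses (Ss, Sf, G, R, Na, Ne, Ho, He, F) are regressed;
constant or partially undefined responses are skipped with a warning.

## Synthetic fen generator

`simulate_fen` emulates the study design so every stage is testable with
known truth: 16 plots × 20 subplots by default, six loci with allele counts
(4, 4, 4, 1, 1, 1) (15 alleles in total, three loci monomorphic), allele
frequencies drawn once per locus from a symmetric Dirichlet (concentration
1). Plot coordinates are uniform in a 120 m box with 5 m minimum
separation. Elevation is Normal(2299.8 m, 0.25 m) — a fen spans well under
a metre of relief; log P and log K are bivariate normal (medians 20 and
950 mg/kg, log-sds 0.7 and 0.35, correlation 0.3), matching the order of
magnitude and right skew of poor-fen soils. The *true* clone count per plot
is G\* = min(S, 1 + Poisson(exp(a₀ + a_e·z_elev + a_P·z_P + a_K·z_K)))
with a₀ = ln 2 (mean G\* = 3 at zero effects) and default standardized
effects +0.6 for P and −0.6 for K, the qualitative pattern the analysis is
designed to detect; the subplot sequence is cut into G\* contiguous runs
(clonal patches along the sampling cross), each run a distinct founder
genotype, re-used across plots with probability 0.3. Null alleles are
injected at one monomorphic locus as missing calls with per-sample dropout
probability 11/320.

What the generator does *not* emulate: population-genetic realism (no
mutation, drift or pedigree; founder genotypes are i.i.d. draws), 2-D patch
geometry within plots (patches are runs along the sampling order, which is
all the pipeline can observe), environmental microstructure beyond one
optional smooth surface, and any dependence of heterozygosity on the
environment. Passing recovery tests therefore show that the pipeline
inverts its own observation model — clone counts are recovered exactly at
zero dropout, planted covariate signs are detected at realistic effect
sizes — not that the biological generating process is as simple as this.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed and is exactly reproducible
(identical seed → identical draws → byte-identical JSON artifacts); MEM
permutation tests default to seed 20200603, nperm 999. The test suite runs
its calibration experiments at deliberately chosen sizes — 20 replicates of
a 100-plot fen for sign recovery, 200 replicates of n = 100 regression fits
for HDI coverage, reduced MCMC schedules wherever only a rough posterior is
needed — sizes at which the Monte-Carlo error of the checked rates is small
relative to the asserted bands.

## Known limitations

* The bundled survey table carries only the per-plot indices, not the raw
  microsatellite scores or plot coordinates, so the worked example
  regresses raw (undetrended) values; with real spatial structure in the
  data the coefficients can differ from a detrended analysis (the
  regression tables make this visible through the elevation row).
* With 16 plots and three correlated predictors the regression is honest
  about uncertainty rather than powerful; the shrinkage prior (sd 0.5) is
  part of the model, and reported MPVs are pulled toward zero relative to
  least squares.
* Exact-match clone assignment treats any scoring error as a new clone;
  with noisy fragment calling G is an upper bound.
* The forward-selection p-values are conditional on the ranking by marginal
  R² and are somewhat anticonservative under the global null; the
  double stopping rule bounds, but does not remove, this effect.
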