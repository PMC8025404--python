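# Methods

This note documents the models behind `crossmosaic`, the defaults and
why they were chosen, and what the synthetic data can and cannot say
about real populations.

## Ancestral pools: Balding–Nichols frequencies

For each SNP a base frequency `p` is drawn uniformly on
`[maf_floor, 1 − maf_floor]` (default floor 0.05). Each pool's frequency
is then drawn from `Beta(p(1−F)/F, (1−p)(1−F)/F)`, so it has mean `p`
and variance `F·p(1−p)`, with `F` the pool's divergence parameter in
(0, 1). Two consequences shape the defaults:

- the expected Hudson Fst between two pools with the same `F` is `F`
  (ratio-of-sums estimator on the pool frequencies), so `F` is directly
  interpretable — the default 0.25–0.3 makes pools cleanly separable in
  a PCA, as distinct cattle ancestries are;
- a pool's expected heterozygosity is `(1 − F)` times the base-frequency
  heterozygosity, so ordering pools by divergence reproduces the
  empirical ordering of baseline heterozygosities across reference
  populations (zebu < African taurine < admixed indigenous < European
  taurine, a pattern driven in real arrays by SNP ascertainment bias).
  This is why no separate per-pool MAF-floor knob exists: one parameter
  controls both differentiation and spectrum.

Haplotypes are independent Bernoulli draws given the pool frequency —
there is deliberately **no within-pool linkage disequilibrium**, no
mutation, no selection and no inbreeding. See "What the simulation does
not emulate" below.

## Gametes, crosses and truth tracks

Recombination follows Haldane's model: crossover counts per chromosome
are Poisson with mean equal to the map length in Morgans, positions
uniform on the cM axis, no interference. The default map is uniform —
one 100 cM chromosome with the requested number of equally spaced SNPs;
multi-chromosome genomes are supported (`n_chrom`) and recommended
whenever per-individual realized proportions should concentrate (a
single chromosome gives whole-genome gametes with appreciable
probability, which is biologically right for one chromosome but not for
a 29-autosome genome).

A cross is specified by the breed-proportion recipes of its two parents.
Parents are realized recursively: a recipe with one pool at proportion 1
is a purebred (two haplotypes drawn from the pool without replacement);
any other recipe is split into two parental recipes averaging to it
(e.g. a 3/4:1/4 parent is the offspring of a purebred and an F1), which
terminates for any dyadic composition. Each offspring gets fresh,
independent parents. Truth tracks record the transmitted pool label at
every (site, haplotype) slot, so `true_breed_proportion` and
ancestral-origin heterozygosity are exact by construction.

All randomness flows from one master seed through named substreams
(`_rng.substream`), making every cohort bit-reproducible.

## Heterozygosity bounds: what is pointwise, what is an expectation

For breed-2 proportion `p`, the outer bound `upper(p) = 2·min(p, 1−p)`
holds **pointwise for every realized track**: with label counts
`n_AA, n_AB, n_BB`, `a = n_AB/n ≤ 2·min(p, 1−p)` is an identity.
The inner curve `lower(p) = 2p(1−p)` is the **expectation** under
inter-se mating, where the two transmitted gamete ancestries are
independent; a realized F2 whose two haplotypes happen to align their
ancestry blocks falls below it (at the extreme, identical mosaics give
`a = 0` at `p = 0.5`). On a finite genome such excursions are common —
roughly an eighth of simulated F2s on one 100 cM chromosome sit below
the curve at their own realized `p` — and they shrink, but do not
vanish, on multi-chromosome maps. Analyses should therefore treat the
green (inter-se) line as a reference expectation, not a hard floor; the
`below_lower` class in `classify_cross` flags individuals *clearly*
under it (beyond tolerance), which on real data indicates unmodelled
ancestry or close inbreeding rather than noise.

At `p = 0.5` the piecewise slope term `x` of the individual-het model is
ambiguous; the midparent form `x = H_F1 − (H_1 + H_2)/2` is used so the
upper envelope passes exactly through the F1 point `(0.5, H_F1)`. The
strictly one-sided forms miss that point whenever `H_1 ≠ H_2`; the
envelope is therefore continuous everywhere except for the slope kink
at 0.5.

## Supervised global ancestry

Per individual, the mixture weights `q` over K pools maximise the
binomial genotype likelihood under Hardy–Weinberg at the mixed frequency
`Σ_k q_k f_kj`. Optimisation is plain EM on the simplex, vectorised over
individuals; convergence at log-likelihood change < 1e−8 or 1,000
iterations. Pool frequencies are clipped to `[10⁻³, 1 − 10⁻³]` by
default: realized pool frequencies can be exactly 0/1, which would give
−∞ likelihoods (passing `clip=None` surfaces that as an error instead).
With 5,000 informative SNPs the estimator recovers purebreds at
`q ≥ 0.99` and F1s within ±0.03.

## Local ancestry: windowed haplotype-copying HMM

The decoder is a two-level simplification of hierarchical window-based
local-ancestry HMMs. The outer hidden chain runs over ancestral pools,
one state per window of `window_size = 12` SNPs, switching pools between
adjacent windows with probability `1 − exp(−switch_rate·d_cM)`
(`switch_rate = 0.01`/cM). The emission of a window under pool k is the
haplotype-copying likelihood of the window's alleles marginalised over
the pool's first `n_states = 15` founder haplotypes with per-site
`mismatch_rate`; decoding is Viterbi per chromosome. Keeping the
pool chain at window level (rather than a flat chain over
pool × founder states) is what gives pool switches their proper cost;
a flat chain prices a pool switch barely above a founder switch and
over-fragments the tracks.

`mismatch_rate` defaults to 0.03 — an order of magnitude above a
genotyping-error rate — because the copying emission must absorb
within-pool haplotype diversity relative to a 15-founder panel, not just
errors. With these defaults and pools at divergence 0.3, purebred
haplotypes are labelled correctly at >99% of sites and first-generation
backcross tracks at ~99%, with mean per-individual proportion error
below 0.01; accuracy degrades gracefully as divergence falls and is
uninformative (proportions near uniform over a cohort) for
indistinguishable pools. Three-way decoding of a two-way-admixed cohort
assigns the absent pool a small spurious share (<1% here; the same
failure mode appears with real reference panels, where closely related
pools bleed into each other).

## Imputation stand-ins

Sporadic missingness is filled with the site's modal genotype (ties →
heterozygote); this deliberately simple rule stands where a
pedigree/LD-aware tool would be used on real data, and is adequate only
for low missing rates.

Density imputation is a single-layer Li–Stephens model: each target
haplotype is a mosaic of reference haplotypes with copying switches at
`recomb_scale = 1` per cM (i.e. switch probability
`1 − exp(−d_cM/100)` across a gap) and emission error
`mismatch_rate = 0.001` at typed sites. Forward–backward runs over typed
sites only; posteriors at untyped sites follow from the exact
interpolation of the chain (messages relax toward uniform at rate
`exp(−recomb_scale·d/100)` across emission-free gaps), which is
algebraically identical to running the HMM over all sites but keeps
memory proportional to the typed-site count. Dosage is the
posterior-weighted reference allele, summed over the two haplotypes;
best-guess genotypes round dosages with half-integer ties to the
heterozygote. A frequency-only imputer (dosage = 2 × reference
frequency) is included as the chance-agreement baseline.

Accuracy metrics follow the imputation literature: the per-site Pearson
correlation of dosage against the true allele count is averaged
unweighted over sites (sites monomorphic in the validation truth are
excluded and counted; zero-variance dosages at polymorphic sites score
r = 0 by convention), and the pooled over-all-entries correlation is
reported alongside since the aggregation unit genuinely matters at low
accuracy. Allele-level concordance is `(2 − |best_guess − truth|)`
summed over entries divided by twice the comparisons; genotype-level
concordance is reported too. MAF bins default to edges
(0, .01, .05, .1, .2, .3, .4, .5), half-open with the last closed. The
frequency imputer makes the known artifact explicit: concordance ≥ 0.9
on MAF < 0.05 sites with correlation ≈ 0, declining across bins while
correlation stays flat — the reason correlation, not concordance, should
be read as imputation accuracy.

Scenario runs restrict the site universe to the target density panel,
type the sites of the starting panel (panels are nested random subsets
of the master site list, mirroring how commercial low-density arrays
nest in denser ones), and score the rest. k-fold cross-validation
splits target individuals reproducibly from the seed; each fold is
imputed with the remaining target individuals plus any external
reference cohorts.

## Problem sizes used by the test suite and acceptance script

Cohort sizes follow the analytic requirements of what they check:
200 F1 (an exact value needs no more), 2,000 F2 and 2,000 BC1 (standard
errors ≈ 0.004–0.007 against ±0.01 bands), 10⁴ mixed-pedigree
individuals for bound containment, 300 individuals × 5,000 SNPs for the
method-agreement check, and three seeds × three scenarios of
30 target / 50 reference individuals on 2,000 SNPs for the imputation
orderings. Maps are a single 100 cM chromosome unless concentration of
realized proportions matters, in which case ten chromosomes are used.

## What the simulation does not emulate

No within-pool LD (reference-panel haplotype structure is therefore
simpler than real panels, flattering the imputer at equal panel sizes);
no array ascertainment beyond the divergence-driven spectrum shift; no
real genetic map (uniform cM spacing); no genotyping error unless
injected via sporadic missingness; no phenotypes, so heterosis itself is
never estimated — only its genomic driver. Passing tests demonstrate
the estimators' correctness and internal consistency under these
conditions, not their field accuracy on real cattle data.
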