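# Methods

## The scientific problem

In severe inherited marrow-failure conditions (Fanconi anemia and related
formaldehyde-detoxification deficiencies), blood production persists for a
long time despite profound depletion of the stem-cell pool, and eventually
collapses into clonal hematopoiesis without any identifiable driver
mutation.  `clonedrift` implements the quantitative machinery needed to
study this regime: a closed-form attrition model tied to survival data, a
single-cell simulator of somatic-variant dynamics, ABC inference of
population-dynamic parameters from deep-WGS variant allele frequencies
(VAFs), and the somatic-variant filtering that makes such VAF data usable.
The operational unit throughout is the *blood-forming ancestor* (BFA): a
cell clone from which current granulocyte production derives, identified
purely from genomic data rather than immunophenotype.

## Attrition model (`clonedrift.attrition`)

Each of `N0` ancestors present at birth divides at rate `lambda` and is
lost (death or differentiation) at rate `delta`, with `delta > lambda`
(subcritical; `xi = lambda/delta < 1`).  Extinction of the whole pool is
identified with bone-marrow failure.  The pool survival probability is

    p_S(t) = 1 - [ (e^{(1-xi) delta t} - 1) / (e^{(1-xi) delta t} - xi) ]^{N0}

the `N0`-th power of the classical linear birth-death extinction
probability.  It is evaluated in log space (stable for `(1-xi) delta t`
well beyond 700).  Derived quantities: mean ancestor lifetime `1/delta`,
division-before-loss probability `xi/(1+xi)`, and extinction-time quantiles
by bracketed root finding (relative tolerance 1e-10).

**Bayesian fit.**  The model is fitted to a Kaplan-Meier curve (product-limit
estimate, computed by lifelines; censored animals reduce the risk set
without a step) assuming Gaussian observation noise with standard deviation
`sigma` on the survival steps, evaluated at event times only.  Priors are
uniform: `log10 N0` in (0,3), `delta` in (0.01,10) per week, `xi` in (0,1),
`sigma` in (0,1).  Sampling uses the emcee affine-invariant ensemble.  The
posterior has a curved ridge in `(delta, xi)` — the curve shape is mostly
set by the net decay rate `a = (1-xi) delta` — so the sampler works in the
decorrelated coordinates `(log10 N0, ln a, xi, ln sigma)` with the exact
Jacobian restoring the uniform priors on the natural scale.  Walkers start
in a dispersed ball around the differential-evolution MAP; defaults are 48
walkers, 2000 burn-in and 6000 retained steps, thinned evenly to 1000
draws.  Faithfulness is enforced by a test comparing the sampled marginals
of `(delta, xi)` against a dense-grid posterior (Kolmogorov-Smirnov
distance < 0.05 on the reduced two-parameter problem).  Effective sample
size below 100 triggers a diagnostic warning.

## Single-cell simulator (`clonedrift.clonesim`)

A population grows from one somatically unmutated founder by a pure-birth
(Yule) process at rate `lambda_e = 1`/week to the target size (the spectrum
is insensitive to `lambda_e`, which only sets the expansion clock), then
follows an exact Gillespie linear birth-death process: subcritical
attrition (`delta > lambda`) or critical homeostasis (`delta = lambda`).
Each division copies the mother's mutations to both daughters and mints
one novel integer index per daughter (infinite sites), so the per-division
mutation rate of the raw simulator is `mu = 2`; datasets needing a
different `mu <= 2` thin minted mutations binomially with probability
`mu/2`.  The state is a persistent lineage tree — each cell a node carrying
exactly one minted mutation — and the site frequency spectrum (SFS) is read
out by walking each living cell's ancestry; per-cell mutation vectors are a
derived view, never stored.  True VAFs are `n/(2N)` for a variant in `n` of
`N` cells (maximum 0.5: a heterozygous variant carried by every cell).

Sequencing noise: an observed VAF is drawn from a beta distribution with
mean equal to the true VAF and concentration equal to the read depth
(`alpha = vD`, `beta = (1-v)D`) — the paper-level statement names the beta
family but not a parameterization, so this mean/concentration choice is
isolated in one function.  Variant reads are the rounded product of
observed VAF and depth; fewer than 3 variant reads is below the detection
limit and the variant is dropped.

Cohorts use independent RNG substreams keyed `(master_seed, mouse_index)`,
so runs are reproducible and embarrassingly parallel.  A size-only
simulator (no mutation bookkeeping) serves the extinction-law and
population-size checks cheaply.

## SFS model and ABC inference (`clonedrift.scifer`)

The expected spectrum at absolute time `t` (clock starting at the founder;
the end of expansion `t_b = ln(N_ss)/lambda_exp` is identified with birth,
and sampling ages count from birth) is

    S_n(t) = integral_0^t  mu * lambda(tau) * N(tau) * p_n(tau, t)  d tau

with `lambda(tau)` and `N(tau)` piecewise between expansion and
homeostasis, and `p_n(tau, t)` the clone-size law of a variant arising at
`tau`.  During homeostasis that law is Kendall's critical birth-death
formula.  The key implementation device: the probability generating
function of every linear birth-death phase is a Moebius map, so phase
compositions (Yule expansion then critical homeostasis; supercritical
selected growth) remain in the two-parameter geometric-tail family
`p_0 = alpha`, `p_n = (1-alpha)(1-beta) beta^{n-1}` — giving closed-form
probabilities *and* closed-form tails `P(n >= m) = (1-alpha) beta^{m-1}`
for any phase sequence.  Composition is exact: `alpha` composes through the
pgf, means multiply, and `beta` follows from the mean identity.  This is
what makes the expected cumulative curve cheap enough for rejection ABC at
2x10^4 particles without per-particle simulation.

The expected *observed* cumulative curve bins clone sizes log-uniformly
(bin counts from tail differences, conserving total mass to 1e-6),
convolves each bin with the beta noise kernel, accounts for read-count
discretization (a variant clears grid VAF `g` iff its rounded read count
reaches `ceil(g*depth)`), and truncates below the detection limit.

**ABC.**  Rejection ABC draws particles from the published uniform priors
(`log10 mu` in (-2,3); `log10 lambda_ss` in (-2,1.5) per week (mouse) or
per year (human); `log10 N_ss` in (1,6); selected model adds `t_s` in
(0, sampling age) and `r` in (0,1)), evaluates each particle's expected
curve on a log-spaced 1/VAF grid covering [detection limit, 0.5], and
keeps the top 1% by distance.  The default distance is the RMS difference
of `log1p`-transformed cumulative counts: counts span three orders of
magnitude across the grid, and on the raw scale Poisson fluctuations of
the large counts at the detection limit (~300 +/- 17) swamp the
high-VAF bend (counts 1-30) that carries the population-size and
drift-timescale information; the log transform is the standard
variance-stabilizing choice for counts.  The raw-count RMS remains
available (`distance="rms"`).  Time units are tagged on priors and data;
mismatches raise immediately.

The neutral-drift fixation timescale — the expected time for one clone to
dominate the homeostatic pool by drift alone — is `T_fix =
N_ss/lambda_ss`; the package reports its posterior median and central
interval.

**Selected clone.**  A clone founded at `t_s` with advantage `r` grows as a
supercritical birth-death process (division `lambda_ss`, loss
`lambda_ss(1-r)`); its size at sampling is the survival-conditioned mean
`e^{r lambda_ss (t-t_s)}/(1 - alpha)`, capped at `N_ss` (conditioning is
appropriate because the clone is observed; the function is isolated so an
alternative growth law can be swapped in).  Variants carried by the clone
founder appear at VAF `clone_size/(2 N_ss)` — 0.5 at fixation; variants
arising inside the clone use the same phase machinery with the
supercritical law; the residual population contributes the neutral curve
scaled to its fraction.  Model choice between neutral drift and clonal
expansion compares median accepted distances, declaring clonal expansion
only when the relative improvement exceeds 0.2 (parsimony tie-break to
neutral).

A descriptive clone-age proxy, clonal-variant count divided by
`mu*lambda_ss`, is exposed as a convenience and flagged non-canonical.

## Variant filtering (`clonedrift.varfilter`)

The cascade mirrors the post-call curation of deep-WGS somatic calls in a
hybrid-strain mouse cohort:

- VAF = variant reads / (variant + reference reads); male X/Y variants are
  hemizygous and halved to a pseudo-diploid VAF.
- Background baseline: for each of the 96 pyrimidine-collapsed
  substitution-in-trinucleotide classes, the upper limit of the 95%
  percentile interval of background VAFs at 100 random sites per class
  across a panel of unrelated samples.  Pooling is per-(site, sample)
  observation by default; per-sample means behind a flag (the appropriate
  statistic is genuinely ambiguous; percentile intervals are robust to the
  zero-inflation of background VAFs).
- Recurrence filter: a candidate variant is removed iff its pileup VAF in
  any *other* sample strictly exceeds its class bound (ties kept); removal
  records the offending sample.
- Hard filters: fewer than 3 variant reads; SNP-database sites; repeat /
  simple-repeat / CNA / LOH regions.  Variant tables are 1-based, BED
  regions 0-based half-open; a position `p` overlaps `[s, e)` iff
  `s < p <= e`, and the boundary cases are unit-tested.
- Indels: any indel called in another animal's raw caller output is
  removed; survivors require confirmation by a second caller.
- LOH screening: germline heterozygous sites (coverage >= 10, mapping
  quality at the 60 maximum, median base quality 37, VAF strictly in
  (0.4, 0.6)) joined against tumor pileup VAFs; no segmentation here.
- Structural variants: a primary call is kept iff the confirming caller
  reports the same type with both breakpoints within 1000 bp; reporting
  further requires VAF > 0.2.

Every filter returns `(kept, removed-with-reason)` with
`kept + removed == input` exactly; filters are idempotent.

## Synthetic data (`clonedrift.synth`)

Generators emulate every input the pipeline consumes and write the
generating truth alongside.  Defaults mirror the fitted operating regime:
~100 ancestors at birth, mean lifetime 3 weeks (`delta = 1/3`/week),
division-before-loss 35-40% (`xi` 0.538-0.6), granulocyte depth 90x,
germline depth 30x.  The filter fixture plants private true somatics
(VAF >= 0.05), recurrent artifacts across >= 2 samples, and hard-filter
victims; background panel VAFs are drawn from a scaled Beta(0.5, 30) per
class — an explicit invention, as no generative model of the artifact
process is available.  What the generators do *not* emulate: mapping and
alignment artifacts at the read level, strand bias, context-dependent
sequencing error spectra, contamination, or a hierarchy of stem and
progenitor compartments.  Passing recovery tests therefore demonstrate
correctness of the inference machinery under the stated model, not
robustness to every failure mode of real sequencing data.

## Problem sizes and numerical choices

Simulation-backed tests use 100-1000 replicate pools (size-only where
mutations are not needed), 500 replicates for spectrum means, 1e5
replicates for the clone-size law, and 6000-20000 ABC particles; these
sizes keep Monte-Carlo error comfortably inside the asserted tolerances.
Quadrature of the spectrum integral uses Gauss-Legendre nodes split at the
phase boundary with node-doubling to a 1e-6 relative tolerance (a fixed
96-node rule on the ABC fast path).  Exponentials are clamped at 700 to
stay inside float64.  Ties in the cumulative VAF curve keep input order;
degenerate VAFs of 0 or 1 bypass beta sampling.  Extinct populations
propagate as flagged empty spectra.

## Known limitations

- Single well-mixed compartment; no stem/progenitor hierarchy, niche or
  spatial structure.
- One selected clone at most; no subclonal nesting beyond it.
- The attrition fit treats KM uncertainty as iid Gaussian on survival
  steps, ignoring the binomial correlation structure of the product-limit
  estimate.
- T_fix is weakly identified from a single 90x sample: the posterior is
  informative mostly through the curve's bend near the detection limit,
  and occasional datasets (population-size drift of the critical process
  is ~26% over a mouse lifetime) support a several-fold larger
  population; factor-two recovery holds in most but not all seeded
  replicates.
- The selected-clone growth law is a documented reconstruction
  (conditioned-mean, capped); subclonal structure inside the dominant
  clone is approximate.
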