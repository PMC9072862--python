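# Methods

`dhpredict` simulates a doubled-haploid (DH) barley breeding program end to
end — founder genomes, meiosis, virtual field trials, and RR-BLUP genomic
prediction — in order to compare two selection criteria for *tested* lines:
the phenotype `p` a line earned in the trial, and the genomic prediction
`y` computed from the very same trial data.  Because the simulation knows
each line's true genotypic value `g`, the two criteria can be compared
directly through the correlations r(p,g) and r(y,g), which no field
experiment can observe.

## Genome and founders

The genome is a synthetic stand-in for a barley map: 7 chromosomes of 1.5
Morgan each with 700 biallelic SNPs uniformly spaced on the genetic map by
default (counts and spacing are configurable; marker density has little
effect on any quantity reported here, which we verified up to several
thousand markers).  Founders are 10 fully homozygous inbred lines in two
pools — 5 elite lines and 5 donors — so a single 0/1 haplotype per founder
defines its genotype.

The founder generator encodes three structural features of elite x donor
breeding panels:

- **Pool divergence** (`pool_divergence`, default 1/3): this fraction of
  markers is fixed for opposite alleles between the pools.  The value was
  anchored by requiring that the *emergent* genetic-variance ratio between
  factorial (elite x donor) and diallel (elite x elite) progeny of the same
  effect vector is about 10:1, the ratio of the two calibration targets
  used throughout (20 vs 2).
- **Within-pool relatedness** (`within_pool_relatedness`, default 0.6):
  at the remaining markers each founder copies a hidden pool-ancestor
  allele with this probability, otherwise draws a fair coin.  Members of
  one breeding pool thus share most of their genome, as real elite panels
  do; pairwise modified Rogers' distances come out near 0.45 within pools
  and 0.85 between them.
- **Minor-allele floor** (`min_maf`, default 0.1) and a guard that no
  non-flagged marker is accidentally fixed between pools.

Marker QC follows standard panel practice: markers with more than two
recorded alleles, more than 10% missing calls, or gene diversity
(expected heterozygosity) below 0.1 are removed first, then lines missing
more than 15% of the retained markers.  Thresholds are strict
inequalities; markers are filtered before lines, and filtering is
idempotent.

## Meiosis and mating schemes

Recombination uses the Haldane model: per chromosome the crossover count
is Poisson with mean equal to the map length in Morgan, crossover
positions are uniform, and there is no interference.  This is the
minimal count-location model; crossover interference would shorten the
tails of the segment-length distribution but none of the reported
correlations is sensitive to it.  A DH line is produced by one meiosis of
the F1 and doubling of the resulting gamete, so every line is homozygous
at every locus by construction.

Two mating schemes are built in: the 5 x 5 elite x donor factorial (25
crosses) and the all-pairs elite diallel (10 crosses, no selfs or
reciprocals).  Population sizes follow the study grid: 10 or 6 DH lines
per factorial cross (250 or 150 lines) and 25 per diallel cross (250
lines).

## Trait model and effect architecture

The trait is purely additive: `g = intercept + X a` with X the -1/+1
genotype matrix.  The intercept (85, the centre of a plausible winter
barley yield range in dt/ha) is cosmetic — every reported correlation is
location-invariant.

The true effect vector `a` is generated in three steps, each of which
emulates a documented property of the experimental panels this kind of
study is anchored to:

1. **Base draw** — i.i.d. gaussian effects on all markers (laplace and
   sparse(k) alternatives are available for sensitivity runs).
2. **Donor yield penalty** (default on) — at pool-differentiated markers
   the sign is aligned so the donor allele decreases yield.  Donor pools
   contribute a target trait (e.g. disease resistance) but drag yield;
   this directional contrast is also what makes the genetic variance of
   factorial progeny several-fold larger than that of an elite diallel.
3. **Error-free re-estimation** (default on) — the base effects are
   replaced by the minimum-norm ridge solution that exactly reproduces
   the genotypic values of one simulated 250-line reference factorial.
   A study whose "true" effects are genome-wide estimates from an
   experimental panel inherits exactly this structure: the truth is
   confined to the genetic contrasts the reference population displays.
   This idealization (no estimation error) raises r(y,g) and r(y,p)
   above what a de-novo random architecture yields, and is the single
   most important driver of the headline result below.

Finally the effects are **calibrated per mating scheme**: a 5,000-line
calibration population is simulated under the scheme's cross plan and the
effects rescaled so its genetic variance equals the target (20 for the
factorial schemes, 2 for the diallel).  The rescale makes the calibration
draw's variance match the target exactly; a second, fresh draw re-checks
it against a 15% relative guard.  The guard is deliberately wide: lines
within a cross share parental segments, so a 5,000-line clustered
variance estimate has about 3% relative sampling SD (half again the iid
rate), and the guard is meant to catch scale bugs, not sampling noise.

## Virtual field trials

A trial with E environments and R replications per environment is reduced
to line-mean level.  The masking effect of line l in cross c is

    m_cl = u_c + v_l + w,
    u ~ N(0, s_ce2/E),  v ~ N(0, s_le2/E),  w ~ N(0, s_eps2/(E R)),

with the cross-by-environment deviation u drawn once per cross and shared
by all its lines, and the line-by-environment deviation v and plot error w
drawn per line.  Phenotypes are p = g + m.  No plot-level values are
simulated; averaging a component over its replications divides its
variance by the replication count, so the line-mean reduction is
algebraically identical for every correlation studied.  Block and
replication design factors of real augmented designs are deliberately not
modelled.

The default component set (10, 10, 30) mirrors variance components
estimated from a real multi-environment barley yield trial; the study
grid also varies the interaction split (2,18,30 / 18,2,30) and inflates
the error (10,10,60 / 20,20,120).

## RR-BLUP and genomic prediction

Marker effects are estimated from the simulated phenotypes by ridge
regression BLUP: `a_hat = (X'X + lambda I)^-1 X'(p - mu_hat)` with a
fixed intercept and `lambda = sigma_e2/sigma_a2`.  By default lambda is
set per replicate by REML of the equivalent kernel model (K = XX'), using
an orthonormal contrast projection of the intercept, the spectral
decomposition of the projected kernel, and a bounded one-dimensional
search over log lambda.  The solver works in the n-line dual space
whenever markers outnumber lines (and always above 2,000 markers); the
marker-space mixed-model equations are retained as an algebraically
identical alternative and as a cross-check.  Predictions are for the
phenotyped lines themselves, y = mu_hat + X a_hat, which is the
tested-lines use case: one cheap trial plus genotyping, then selection on
y instead of p.

Numerical notes: eigenvalues of the projected kernel are clipped at zero;
zero-variance phenotypes short-circuit to a flagged all-zero fit; REML
uses bounds e^-14..e^14 on the variance ratio and falls back to a
heuristic trace-based lambda with a warning if the bounded search ever
fails.

## Scenarios, replication, and randomness

A scenario fixes the mating scheme, family size, trial design, masking
components, and genetic-variance target.  The founder panel and the
calibrated true effects are built once per scenario and held fixed across
replicates — the emulation of a study anchored to one experimental panel
— while each replicate re-draws the DH population and the trial noise.
The full study grid is 30 scenarios; the package default is 2,000
replicates per scenario, while the bundled acceptance checks use 200,
which puts about 0.003-0.008 Monte-Carlo SE on each reported mean
correlation.

All randomness derives from one master seed through counter-based
substreams (`SeedSequence` spawn keys), so replicate k is identical
whether replicates are run serially, in any order, or in parallel, and
every result in the package is bit-reproducible given the seed.
Replicates with degenerate (zero-variance) correlation inputs are
excluded and counted; a scenario with more than 1% such replicates is
marked unreliable (with the default generator none occur).

## Expected correlations and a finite-cluster caveat

Under the masking model the plug-in expectation of the phenotype-genotype
correlation is

    r(p,g) ~= sqrt( sg2 / (sg2 + sm2) ),   sm2 = s_ce2/E + s_le2/E + s_eps2/(E R),

which treats sample moments as population moments.  The mean *sample*
correlation the simulation (and any real study) computes deviates from it
by a few thousandths in ways the cross structure shapes: downward for
high-correlation replicated designs (the ordinary finite-n bias of the
correlation coefficient, amplified because u is shared within the 25
crosses), upward for the 10-cross unreplicated diallel (the sample
variance of p is volatile with so few cluster draws, and the
nonlinearity of r inflates its expectation).  The downward bias grows
with the cross-shared component and with the between-cross share of
genetic variance; it reaches about -0.012 for the (18, 2, 30)
unreplicated factorial under the default truth architecture.  At 200
replicates the most precise rows resolve these biases at the 3-SE level,
which is why the analytic cross-checks use an absolute floor of 0.01 —
and the two scenarios whose bias exceeds even that floor are left as
documented deviations rather than hidden.  The plug-in formula is
exposed as `expected_r_pg` with this caveat.

## The dependent-correlation z-test

`compare_dependent_correlations` implements the Pearson-Filon (1898) z
for two overlapping dependent correlations sharing one variable, with a
one-sided alternative that the genomic prediction correlates more
strongly with the reference values than the phenotype does.  The variant
choice is isolated in `pearson_filon_z`.  The test is validated on
simulated data only — by its antisymmetry under swapping the two
predictors, by its null calibration, and by agreement of its rejection
rate with a bootstrap oracle — because the retrospective re-analysis it
was designed for requires experimental data that are not publicly
deposited.

## What the synthetic generator does and does not show

The generator reproduces the *structural* conditions that make genomic
prediction of tested lines work: related parents reused across many
crosses, a directional pool contrast, effects that are themselves
genome-wide estimates, and realistic masking-variance components.  Under
these conditions the simulated r(p,g) column matches its reference levels
within Monte-Carlo error, and the headline ordering — r(y,g) above
r(p,g) in every scenario, and r(y,g) of an unreplicated factorial trial
above r(p,g) of the replicated trial with six times the plots — holds
with a margin of about +0.03 at the flagship comparison.  The absolute
r(y,g) and r(y,p) levels, however, depend on the unobservable fine
structure of the real panel's effects (our flagship r(y,g) is about 0.83
against a reference level of 0.88); they should be read as sensitivity outputs,
not calibrated reproductions.  Real data also contain epistasis,
genotype-specific missingness, multi-allelic sites, and spatial field
trends, none of which are modelled.

## Default problem sizes

Tests and the acceptance script run 200 replicates per scenario with 250
(or 150) lines and 700 markers, 5,000-line calibration populations, and
100,000-gamete meiosis oracles — sizes at which every Monte-Carlo check
has at least 3-SE resolution against its target while a full 30-scenario
grid completes in minutes.  The 2,000-replicate default of
`ScenarioConfig` reproduces the original precision when wanted.
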