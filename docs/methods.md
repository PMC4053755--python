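# Methods

This note documents the models, estimators and numerical choices behind
`epistat`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Definitions and per-pair transforms

All growth rates are relative to wild type (g00 = 1) and are never
renormalized.  Log growth is G = log2(g); geometric epistasis is
E = G11 − G01 − G10 and traditional epistasis is e = g11 − g01·g10.  For
g11 > 0 the two always share a sign (e = g01·g10·(2^E − 1)), but e is
bounded below by −g01·g10 while E is unbounded; `traditional_lower_bound`
exposes the bound.  Synthetic-lethal doubles (g11 = 0) carry an explicit
E = −∞ sentinel; every moment computation excludes sentinels and reports
the lethal count separately.  Non-positive *single*-mutant growth rates
are treated the same way: the record survives the row filters (which
require only that singles be numeric and doubles be positive numbers) but
its pair is flagged lethal and never enters bins.

Sign epistasis: mutation A's conditional effect in B's background is
G11 − G10 (solo effect G01), and symmetrically.  A mutation "flips" when
its conditional effect has strictly opposite sign to its solo effect;
exact zeros never flip (a measure-zero event under noise, and the
convention avoids spurious positives on ties).  One flip is single sign
epistasis, two are reciprocal — for two deleterious singles, reciprocal
is equivalent to the double mutant being fitter than both singles, a
fitness valley.  The headline S(G, G) statistic counts single and
reciprocal together by default; a `reciprocal_only` switch restricts it
to valleys.

## Binning

Pairs are binned by (G01, G10) on exponential intervals [−2ⁿ, −2ⁿ⁻¹),
n = −7 … 0, left-closed right-open (the closed/open choice on edges is
measure-zero; one convention is fixed so tests can be bit-exact).  The
grid covers log growth −1 to −2⁻⁸, i.e. relative growth rates 0.5 to
0.997; a mirrored positive grid serves beneficial effects.  Mirror bins
(i, j) and (j, i) are pooled because the variance is symmetric in its two
arguments.  Per bin we report the count, mean and unbiased (n−1) variance
of E — with thousands of pairs per bin the estimator choice is
negligible, and the unbiased form is also correct for the small bins of
synthetic runs — plus the within-bin mean of each model basis (see
Fitting) and the 25th/75th percentiles of the variance over B = 1000
seeded bootstrap resamples.  Bins under 50 pairs are flagged low
confidence and excluded from fits by default.  Bootstrap generators are
derived deterministically per bin (documented in the docstrings) so that
an independently coded oracle can reproduce every draw.

The diagonal slice keeps pairs with |G01 − G10| ≤ 0.2·max(|G01|, |G10|)
(the denominator choice is ours) and assigns G = (G01 + G10)/2; finer
1-D bins (default two per octave) are available for diagonal variance
and sign-probability curves.

## Measurement-noise deconvolution

Reported uncertainties are interpreted as the standard error of the
reported value (for the generator: sample sd of the replicates divided by
√n_reps).  Mock datasets assume a world with no epistasis: singles keep
their reported values, doubles are set to g01·g10, and then *every*
growth rate is shifted by an independent Student's-t draw (df = 5 by
default, configurable — the heavy tail emulates occasional gross errors)
scaled so the shift's standard deviation equals the reported uncertainty.
Scaling to the sd rather than the t scale parameter is essential: it is
what makes variances add, var_obs ≈ var_bio + var_noise, independently of
the shift distribution (a gaussian-shift mode exists for robustness
checks, and changes recovered var_bio only within bootstrap error).  Each
gene's single-mutant shift is shared across all pairs referencing it in a
mock, mirroring how one measured fitness enters many pairs.  Shifted
values ≤ 0 are dropped by the same filters as real data.

Nine mocks are generated per analysis; the per-bin noise variance is
their across-mock mean, with the across-mock spread retained.  The
decomposition reports var_bio = max(var_obs − var_noise, 0), σ_bio =
√var_bio, the ratio var_obs/var_noise, and a per-bin `null_consistent`
flag: the excess var_obs − var_noise is compared against 1.645 combined
standard errors (bootstrap sd of var_obs from the interquartile spread,
IQR/1.349, plus the mock-ensemble standard error), a one-sided 5%
false-positive level.  Under a generator with no epistasis ~95% of bins
are expected to be flagged consistent; the corresponding suite check uses
a 90% threshold to leave room for the test's own false-positive rate.

## Fitting the scaling surface

Three variance models are implemented: the harmonic surface
var = 2c|G01·G10|/(|G01|+|G10|), the simpler var = c·√|G01·G10| (both
reduce to c|G| on the diagonal), and a per-slice Michaelis-Menten form
var(G10 | G01) = v|G10|/(K + |G10|) for slice diagnostics (v and K are
estimated per slice; symmetry implies K = |G01| and v ∝ |G01|, which the
tests verify on exact surfaces).

Two estimator details matter and are worth stating:

* **Within-bin basis averaging.**  The fitted models are linear in c, so
  the natural regressor for a bin is the within-bin *mean* of the
  per-pair basis f(G01, G10), not f evaluated at the bin-mean effects;
  the bases are concave and octave-wide bins make the latter noticeably
  biased.  `compute_bin_stats` therefore aggregates the per-pair basis.
* **Log-scale count weighting.**  The sampling error of a variance
  estimate is proportional to the variance itself, so least squares is
  performed on log var = log c + log f, where per-bin errors are
  approximately homoscedastic with variance (κ−1)/n and bin-count
  weights are inverse-variance optimal; c is then the count-weighted
  geometric mean of var/f.  Linear-scale weighted least squares
  (dominated by the few largest-effect bins, roughly doubling the
  estimator's spread under the default synthetic conditions) remains
  available via `scale="linear"`.

**Resolution cutoff.**  Genes with essentially wild-type fitness vastly
outnumber each deleterious octave, so single-mutant measurement scatter
fills the smallest-effect bins with pairs whose true effects — and hence
true epistasis variance — are far below the bin label, attenuating the
fitted coefficient.  The fit therefore uses only bins whose inner edge
clears the near-neutral band (taken as |G| ≤ 0.01, i.e. fitness within
~0.7% of wild type) by four times the median single-mutant log-growth
uncertainty computed from the reported sds.  This mirrors the practical
limit of such screens: below a few percent in growth-rate effect,
uncertainty prevents resolving which pairs interact.  The cutoff is
overridable (`fit_min_effect`), and beneficial-effect bins are always
excluded from the fit and reported separately, as their interactions are
consistently near zero.

Fits default to the noise-subtracted var_bio; a `fit_raw` switch fits the
unsubtracted variances.  The diagonal log-log scaling exponent (slope of
log var vs log |G|; 1 for the harmonic family, ≥ 2 for geometric-model
scaling) is estimated by count-weighted linear regression over the
diagonal bins above the resolution cutoff.  Its confidence interval
propagates each bin's own bootstrap variance uncertainty parametrically
(lognormal perturbation of the bin variances) when quantiles are
available — with only a handful of usable diagonal bins, resampling the
bins themselves gives badly discretized intervals — and falls back to
bin resampling otherwise.

## Fisher's geometric model

The FGM module uses the standard parameterization: phenotypes in n
dimensions (default 3), isotropic Gaussian mutation displacements
(per-coordinate sd 0.19), Gaussian fitness w = exp(−k·d²) with k = 1, and
the wild type at the optimum by default.  Mutations add in phenotype
space, so all epistasis comes from the curvature of log fitness; at the
optimum E = −2k·log2(e)·(δ1·δ2) exactly, which the 1-D closed-form test
exploits.

Two geometric facts shape what the module asserts.  First, conditioned on
equal single effects, var(E | G, G) ∝ G² exactly at the optimum — the
*lower bound* of the geometric-model regime, against the empirical
var ∝ |G|.  Second, for any radial fitness function and isotropic
mutations at the optimum, the sign-epistasis condition reduces to pure
geometry — the double mutant must land closer to the optimum than the
fitter single — so S(G, G) is scale-free (flat in |G|).  A literal
increase of S with |G| is therefore not realizable in this
parameterization, and moving the wild type off the optimum makes S
*decrease* while breaking the ≥ G² variance bound at small effects
(distant-from-gradient mutations of tiny net effect still interact).  The
contrast the package demonstrates is consequently directional: under the
empirical √|G| law the simulated S(G, G) falls significantly with |G|,
while under FGM it does not fall — opposite trends, matching the
qualitative disagreement between the two models of landscape ruggedness.
Off-optimum wild types are exposed via `wt_distance` for exploration
(there, conditioned deleterious pairs interact negatively on average).

## Synthetic data generator

The generator emulates the statistical structure of an SGA-style screen:

* **Single-mutant effects** (per gene): 79% near-neutral (G uniform in
  ±0.01), 19% deleterious with |G| log-uniform on [0.004, 1] (populating
  every default bin roughly evenly), 1% beneficial (G uniform up to
  +0.03), 1% lethal.  These shapes are pragmatic placeholders chosen to
  exercise the full grid, not claims about any particular organism.
* **Latent epistasis** per sampled pair: zero-mean, variance given by the
  configured surface (harmonic by default, c_true = 0.079) at the true
  effects, drawn from a standardized mixture of a Gaussian core and a
  negative-exponential tail (weight 0.05) — reproducing the heavy left
  tail of strong negative interactions seen in real screens.  Pairs of
  beneficial mutations get E = 0 unless enabled.  The double-mutant
  growth is g11 = g01·g10·2^E, with 1% of viable pairs made synthetic
  lethal.
* **Measurement**: multiplicative replicate noise (growth rates are
  colony-size ratios), per-replicate sd = 5% of the true value,
  t-distributed with df = 5.  Doubles are measured with 4 replicates;
  single-mutant fitnesses are given an effective 64 replicates because
  real screens pin them down with genome-wide control crosses — their
  uncertainty is much smaller than a double mutant's.  The reported
  value is the replicate mean and the reported sd the standard error of
  that mean, so the deconvolution stage faces realistic, noisy
  uncertainty estimates rather than oracle sds.

Everything derives from one seed; identical configs produce byte-identical
files.  The default problem sizes used by the test suite and the
reproduction script — 200,000 pairs over 1,500 genes for recovery runs,
100,000 for null and FGM runs — were chosen as the smallest sizes at
which every bin of the default grid is populated well enough for the
estimators' asymptotics to apply.

What the generator does *not* emulate: colony-plate spatial artifacts and
batch effects, correlated errors between a double mutant and its parent
singles, gene-specific (e.g. functional-module) interaction structure,
and any dependence of the E distribution's shape on position in the
(G01, G10) plane beyond its variance.  Passing tests therefore show that
the estimators recover the assumed statistical structure at realistic
noise levels — not that real screens satisfy that structure.

## Degenerate inputs and numerical conventions

Unparseable numeric fields become missing values, never zeros; rows are
dropped by explicitly logged filter rules (non-numeric singles, lethal /
negative / non-numeric doubles), and reciprocal query–array duplicates
are resolved by smallest mean reported uncertainty with lexicographic
tie-breaks, making deduplication order-independent.  All-zero variance
tables yield c = 0 with a degenerate-fit flag.  Empty bins are legal
everywhere.  Bootstrap resampling is chunked (200 resamples at a time) to
bound memory on large bins.  E values beyond ±8 in the generator are
clipped and counted.  Known limitations: the noise model assumes
independent errors across the three measurements of a pair (shared-batch
correlations would bias var_noise low), and the resolution cutoff assumes
the near-neutral band is denser than neighbouring deleterious octaves —
true for knockout screens, not necessarily for selected mutation panels.
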