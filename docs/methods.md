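# Methods

`microstab` analyses how soil microbial diversity and taxon asynchrony
relate to the temporal stability of ecosystem functions in a mesocosm
experiment, and ships a synthetic-experiment generator with known ground
truth so that every stage of the pipeline is testable without external
data.

## The experimental system being emulated

The reference design is a sieve-gradient soil biodiversity experiment:
grassland mesocosms are inoculated with soil passed through 5000, 100, 25
or 0 µm mesh (0 µm = sterilized inoculum), crossed with three soil origins
and five replicates — 60 mesocosms in all.  Four ecosystem functions
(plant biomass production, plant Shannon diversity, litter decomposition,
soil ¹³C assimilation) are measured at five harvests spaced 11 weeks
apart, alongside fungal and bacterial OTU tables from amplicon sequencing
of the soil.

## Statistics implemented

**Temporal stability** of a function in a mesocosm is the inverse
coefficient of variation, S = μ/σ, with μ and σ the mean and *sample* SD
(T−1 divisor; five harvests is a small sample) of the function over the
harvests.  S is invariant to positive rescaling of the function but not to
additive shifts — that is inherent to the CV.  A constant series (σ = 0)
is flagged degenerate and excluded from regressions rather than mapped to
+∞, keeping all downstream fits finite.

**Microbial diversity index**: fungal and bacterial richness (count of
taxa with abundance > 0; no rarefaction by default, an optional
column-normalization flag exists in the loader) are each rescaled to
[0, 1] *within each time point*, then averaged over groups and time
points.  Unit scaling of a constant vector returns 0.5 everywhere (with a
loud warning) so a degenerate time point does not delete mesocosms.

**Multifunctional stability** (averaging approach): each function's
stability column is rescaled to [0, 1] across mesocosms and the per-mesocosm
mean is taken.  It is therefore invariant to positive affine
transformations of any single function's stability.

**Multiple-threshold analysis**: for each threshold fraction t in
0.05…0.95 (1% steps, 91 values) the number of functions per mesocosm with
S ≥ t × (that function's maximum observed S) is counted and regressed on
the diversity index; the slope and Wald 95% CI are traced across the grid.
A threshold is "significant" when the CI excludes zero.  The summary
reports T_min and T_max (smallest/largest threshold with a significantly
positive slope) and R_mde (threshold of the steepest slope among the
significant ones).  The count model is negative-binomial with log link by
default; the source this emulates describes a "negative binomial with
logit link", which is self-contradictory, so a binomial(logit) model on
count/4 is available behind `family="binomial"`.  When the NB dispersion
collapses to the Poisson boundary (common with counts bounded by 4) the
fit falls back to the Poisson GLM — the exact NB limit — and the model
used is recorded per threshold.  No count GLMM tooling is available in the
Python stack, so origin and block enter these fits as fixed blocking
covariates; the slope contract is unchanged and the downgrade is logged.

**Taxon-level standardized effect sizes (SES)**: for each taxon at each
(function, harvest), the observed effect is the difference in mean
function value between mesocosms where the taxon is present (abundance
> 0) and absent.  The null reassigns the function values across mesocosms
uniformly at random (999 iterations by default; presence fixed), giving a
null mean and SD, and SES = (observed − null mean)/null SD.  A taxon is
significant when |SES| > 1.96 (the printed two-sided 5% constant; a z*
flag exists).  Taxa with fewer than 3 mesocosms on either side are
ineligible — one- or two-point group means make the null SD unstable.
Permutations run within each time point and across all mesocosms jointly
(no stratification by origin; a stratified null would be a sensitivity
analysis, not the default).  Each (taxon, function, time) test draws from
its own deterministic RNG substream derived from the master seed, so
results do not depend on evaluation order.

**Accumulation of affecting taxa**: for the sets of significantly
positive (or negative) taxa per function at a time — or per time for a
function — the curve reports, for each k, the mean over all C(K, k)
combinations of |union of k sets| / (total taxa observed).  If every item
has the same affecting set the curve is flat (slope 0); pairwise-disjoint
equal-size sets give slope 1 in units of the single-set proportion.
Slopes with uncertainty are estimated by beta-binomial regression (logit
link) — the mean is logit-linear in k with a common intraclass
overdispersion ρ, maximized numerically (Nelder–Mead from the empirical
logit line, three ρ starts; Wald CI from a finite-difference Hessian).  No
installed package offers beta-binomial *regression*, hence the hand-written
MLE around `scipy.stats.betabinom`; at the ρ→0 boundary the fit falls back
to the standard binomial GLM, and the exact-slope analytics (0 and 1) are
computed by OLS on the curve directly.

**Species stability and synchrony**: restricted to the taxa the SES step
flagged as positively supporting a function at any harvest.  Species
stability is the mean per-taxon CV⁻¹ of abundance over harvests (the
source is internally inconsistent between CV and CV⁻¹; CV⁻¹ is the
default, `use_cv=True` gives the other reading).  Synchrony is the mean
pairwise covariance of taxon abundance series after standardizing each to
mean 0 and SD 1 — i.e. the mean pairwise Pearson correlation, bounded in
[−1, 1].  The description "mean = 0, SE = 1" is read as SD = 1: an SE
scaling would rescale every series by the same √T and break the
covariance = correlation identity.  Taxa absent throughout a mesocosm or
with zero temporal variance are excluded (count logged).

**Association models**: per-mesocosm stability responses are regressed on
per-mesocosm predictors with random intercepts for block and for origin
nested within block (statsmodels MixedLM; an OLS-with-fixed-blocks
fallback engages on singular fits and is recorded).  The sterile contrast
enters an indicator for the 0 µm level *before* the continuous predictor
and reads both terms from a sequential (type-I) ANOVA, so the residual
predictor effect is explicitly conditional on the contrast; this
sequential test uses OLS with the blocking factors as fixed covariates to
keep the ordering interpretable.  Temporal autocorrelation structures are
not needed for these responses — stability is a single number per
mesocosm.

## The synthetic generator

`simulate` draws a full experiment from a `SimConfig`:

- **Design**: full factorial, mesocosm IDs M01…M60, sieve treatment as an
  ordered factor plus a log-linear numeric score log₂(mesh + 1) (sterile
  maps to 0), block assigned from the replicate index.
- **Communities**: each mesocosm carries a random subset of the regional
  pool of size round(retention × pool), fixed across harvests; the default
  retention (1.0, 0.85, 0.70, 0.42) yields a 58% taxon loss at the sterile
  level, inside the 55–60% band the sieve gradient is meant to emulate.
  Members get lognormal abundances per harvest (meanlog 2, sdlog 1);
  zero-inflation comes from the subset draw, not the abundance law, so
  richness and abundance are independently controllable.
- **Planted effects**: for each (function, harvest) a configured number of
  supporter taxa (default 8) is drawn.  In the default `rotating` mode the
  draws are independent across harvests — different taxa support a
  function at different times — and each supporter's expected abundance
  peaks at its assigned harvest (meanlog + 1.5).  `static` mode reuses one
  set per function.  `disjoint` and `identical` assignment modes exist for
  the accumulation analytics.  Supporters are positive by default
  (`p_negative=0` of effects are sign-flipped); negative effects are
  enabled by raising `p_negative`.
- **Functions**: value = baseline + scale_f × (effect_size × signed count
  of present supporters + Gaussian noise).  Baselines (20 g biomass, H′
  1.5, 400 mg litter, 5 min-scaled δ¹³C units) keep all values positive —
  the generator emits already-min-scaled carbon values, while the loader's
  `preprocess_carbon` handles raw negative δ¹³C.  The per-function scale
  (1, 0.1, 15, 0.3) expresses effect_size and noise_sd in units natural to
  each function so a single scalar drives functions of very different
  magnitudes.  A supporter absent from a mesocosm contributes nothing, so
  treatment → richness → function is causally linked.

Defaults: pool of 120 fungal + 200 bacterial taxa, effect_size 1.0,
noise_sd 0.25.  All generator laws and magnitudes are artifact choices
(the emulated experiment does not publish abundance distributions or
effect sizes); they are surfaced in the config rather than hard-coded.

### What the generator does and does not emulate

It reproduces the design geometry, the monotone richness gradient with a
>50% sterile loss, temporally rotating taxon→function effects, and a
diversity→stability link that arises mechanistically: at full retention
every harvest's supporters are present, so the function's supporter term
is nearly constant over time, while depauperate mesocosms miss a varying
subset of each harvest's supporters, raising temporal variance and
lowering the mean — the insurance effect in miniature.

It does **not** emulate: compositional (relative-abundance) sequencing
noise, taxon–taxon interactions, plant community dynamics (plant functions
are generated directly), or abundance-mediated function effects — planted
effects act through presence only, so relationships between *abundance*
stability/synchrony of supporters and function stability are not planted
and are typically absent in synthetic runs.  Passing tests therefore
demonstrate the correctness of the estimators and the recovery of
presence-based effects, not that real soil data will show any particular
pattern.  Note also that under the default gradient most taxa co-vary with
treatment, which itself drives the functions, so a large share of taxa is
flagged by the SES step; this presence–treatment confounding is a property
of gradient designs.  The uniform-retention configuration (all treatments
at equal retention) removes it, and there the flagged fraction of
non-supporters sits at the nominal 5%.

## Numerical choices and degenerate inputs

- Sample SD (ddof=1) everywhere a temporal SD is taken; permutation-null
  SD likewise.
- σ = 0 stability → degenerate flag, excluded from maxima, counts and
  regressions.
- Constant vectors in unit scaling → 0.5 with a warning.
- SES with null SD = 0 (constant function values) → degenerate flag, not
  an exception; ubiquitous/absent taxa → ineligible, recorded.
- Threshold fits that fail or do not converge → `converged=False` rows;
  the scan never aborts.
- Beta-binomial ρ estimated on the logit scale; ρ < 10⁻⁴ or a singular
  Hessian triggers the binomial fallback, reported in `method`.
- Ties in R_mde (equal steepest slopes) resolve to the first grid point,
  deterministic because the grid is ordered.

## Problem sizes

The analysis drivers use the full 60-mesocosm design with 320 taxa, five
harvests and 999 permutation iterations (~15 s for the complete SES
matrix).  The test suite exercises the same code paths on smaller pools
(25–80 taxa, 199–1999 iterations) and verifies the Monte-Carlo permutation
null against exhaustive enumeration at ≤10 mesocosms, where all C(n, k)
assignments can be listed.

## Known limitations

- Fixed community membership per mesocosm across harvests: richness is
  constant over time within a mesocosm, so the within-time-point scaling
  of the diversity index matters less than it would for real data.
- The mixed models use Wald inference; with three origins and five blocks
  the variance components are weakly identified, and the fallback to fixed
  blocking covariates is the honest alternative reported in `method`.
- No FDR control across the thousands of SES tests and no simultaneous
  inference across the 91 thresholds, matching the emulated analysis;
  interpret flagged sets accordingly.
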