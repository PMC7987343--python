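# microstab

Does losing soil microbial diversity destabilize ecosystem functioning
over time?  `microstab` is an analysis pipeline for mesocosm experiments
that cross a soil-biodiversity gradient (e.g. sieve treatments of
5000/100/25/0 µm inoculum) with repeated harvests, measuring fungal and
bacterial OTU tables alongside ecosystem functions such as plant biomass,
plant Shannon diversity, litter decomposition and soil ¹³C assimilation.
It is written for ecologists who want the full statistical chain — from
abundance tables to threshold curves — as tested, reusable code, with a
synthetic-experiment generator standing in for deposited data.

The pipeline computes, per mesocosm:

- **temporal stability** of each function, CV⁻¹ = μ/σ over harvests;
- a **microbial diversity index** (fungal and bacterial richness, each
  scaled to [0, 1] per time point, averaged);
- **multifunctional stability** (mean of unit-scaled per-function
  stabilities) and its **multiple-threshold analysis**: for thresholds
  t = 5%…95% of each function's maximum stability, the count of functions
  above t is regressed on diversity, yielding the significant band
  [T_min, T_max] and the steepest-slope threshold R_mde;
- **taxon-level standardized effect sizes**: SES = (Δ_obs − Δ̄_null)/s_null,
  where Δ_obs is the present-vs-absent difference in mean function value
  and the null permutes function values across mesocosms (999 iterations);
  |SES| > 1.96 flags a taxon as affecting the function at that harvest;
- **accumulation curves**: how the proportion of function-affecting taxa
  grows as more functions or more harvests are considered (slope 0 =
  fully shared taxa, slope 1 = fully distinct taxa), with beta-binomial
  slope estimates;
- **species stability** (mean per-taxon CV⁻¹) and **synchrony** (mean
  pairwise correlation of standardized abundance series, in [−1, 1]) of
  the supporter taxa, regressed against function stability with a
  sterile-treatment contrast.

See `docs/methods.md` for definitions, estimators and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a synthetic
experiment (60 mesocosms, 320 taxa, 5 harvests, rotating supporter taxa):

```bash
python analysis/01_simulate_experiment.py --seed 3
python analysis/02_stability_diversity.py
python analysis/03_threshold_scan.py
python analysis/04_taxon_effects.py
python analysis/05_species_stability_synchrony.py
```

Step 01 reports the design it generated:

```
wrote 4 tables to results/synthetic
  mesocosms: 60, harvests: 5, taxa: 320 (120 fungi, 200 bacteria)
  sterile treatment retains 134 taxa (58% loss)
  planted supporters per (function, time): 8 (rotating)
```

— the sterile (0 µm) level loses more than half the taxon pool, the
gradient the design is built to create.  Step 02 links diversity to
stability:

```
multifunctional_stability: slope +0.297 (p=6.4e-15, significant); after
sterile contrast, residual diversity effect p=2.2e-15
```

i.e. mesocosms with higher microbial diversity maintain more stable
functioning, and the relationship is not an artifact of the sterile
treatment alone (the residual effect stays significant after the contrast
absorbs it).  Step 03 summarizes the threshold scan:

```
diversity stabilizes multiple functions for thresholds in [0.05, 0.52];
the effect is steepest at 0.26 of maximum stability
```

so T_min = 0.05, T_max = 0.52 and R_mde = 0.26 for this synthetic run.
Step 04 flags taxa with |SES| > 1.96 and fits the accumulation slopes
(`+0.871 [0.714, 1.028]` across functions here: largely distinct taxa
support different functions, as planted).  Step 05 reports whether the
abundance stability and asynchrony of supporter taxa predict function
stability — in synthetic runs these are typically n.s., because planted
effects act through presence rather than abundance (see the limitations
section of `docs/methods.md`).

All tables land in `results/`; library functions behind every step live in
`src/microstab/` (`simulate`, `io`, `metrics`, `ses`, `threshold`,
`assoc`).

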