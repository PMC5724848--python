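# funcdyn

Dynamics of taxonomic and functional diversity in seasonal small-mammal
assemblages.

`funcdyn` is a reusable pipeline for a question community ecologists ask of
long-term trapping data: **what drives the functional diversity of an
assemblage through time — random sorting from the species pool,
environmental filtering, or species interactions?** It was built around the
setting of a multi-decadal seasonal monitoring program in two adjacent
tropical dry-forest habitats (an exposed upland forest and a more mesic
arroyo/riparian forest), but every stage is generic: any species × trait
table plus a seasonal abundance series and a seasonal climate series will
do.

## What it computes

1. **Functional trait space.** Mixed traits — several compositional
   categories (habitat use, vertical stratum, diet, temporal activity; each
   a proportion vector summing to 1 per species) plus mean individual
   biomass (g) — are combined into a species dissimilarity matrix **G** by
   a weighted Gower scheme:

       g_ij = Σ_k W_k · D_ijk / Σ_k W_k

   Biomass is log₁₀-transformed and scaled to unit SD (W = 1, D = |Δ|).
   Each compositional category is reduced by PCoA, retaining the leading
   axes explaining ≥ 75% of the variance; its Euclidean distance in those
   axes gets weight W_k = 1/s_k, where s_k is the retained variance share,
   so every trait contributes comparably regardless of dimensionality.
   **G** is summarised as an average-linkage dendrogram (Newick output);
   low merge heights flag functionally redundant species.

2. **Functional dispersion (FDis).** For every (year, season, habitat)
   assemblage, the weighted mean distance of species to their weighted
   centroid in a PCoA embedding of **G** (square-root corrected if
   non-Euclidean), under three weightings: occurrence (FDo), relative
   counts (FDn), and relative biomass (FDw). FDn, FDw ≤ FDo gaps measure
   functional evenness.

3. **Random-extinction null model.** Random removal orders over the full
   pool give, at every richness level r, the null distribution of FDis
   under random assembly (the richness–functional-diversity association,
   SFD). Deviations dFDo/dFDn/dFDw = observed − null mean at the observed
   richness separate extrinsic effects (filtering, limiting similarity)
   from pool composition. A saturation index (late-half marginal gain over
   early-half) quantifies intrinsic redundancy: ~1 linear/complementary,
   ~0 asymptotic/redundant.

4. **Autoregressive driver models.** Rates of change
   ΔS_t = log(S_t/S_{t−1}) and ΔdFD*_t are regressed, per season with
   habitats stacked, on current/previous-season precipitation,
   temperatures, a rainfall-anomaly dummy, habitat and its interactions,
   lagged biodiversity levels (the negative-feedback term), and log total
   captures as a sample-size covariate. Model choice is backward
   elimination then stepwise refinement under AICc; predictor importance is
   the partial determination coefficient R²_X = R² − R²₋X. Four responses ×
   two seasons give eight selected models.

5. **Synthetic study system.** A generator producing trait tables, seasonal
   climate, and multinomial capture counts with the structure above
   (13-species pool, one dominant ground-dwelling granivore at ~90%/~55% of
   captures by habitat, wet/dry rainfall contrast with one anomalous dry
   season, log-scale abundance dynamics with first-order negative
   feedback), so the whole pipeline is testable without field data.

## Worked example

```python
from funcdyn import *

traits, climate, abundance = simulate_dataset(SimulationConfig(seed=1))
fd = build_trait_space(traits)          # weighted Gower G
est = fd_series(abundance, fd)          # FDo/FDn/FDw per record
print(est.head(4).round(3).to_string(index=False))
```

```
 year season habitat  S  total_captures   FDo   FDn   FDw
 1990    dry  arroyo  9           120.0 0.459 0.393 0.419
 1990    dry  upland  7           171.0 0.444 0.142 0.164
 1990    wet  arroyo 11           153.0 0.448 0.428 0.439
 1990    wet  upland  8           381.0 0.452 0.121 0.123
```

FDo is similar across habitats (similar trait repertoires), but FDn/FDw
collapse in the upland records: one dominant species holds ~90% of
captures, so abundance-weighted dispersion is far below occurrence-based
dispersion — low functional evenness.

```python
curve = simulate_extinction_trajectories(fd, n_traj=1000, seed=1)
print(round(curve.pool_fdis, 4))                            # 0.4536
print(round(sfd_shape_summary(curve)["saturation_index"], 3))  # 0.043
dev = deviations(est, curve)
print(round(dev[dev.habitat == "upland"].dFDn.mean(), 3))   # -0.296
print(round(dev[dev.habitat == "arroyo"].dFDn.mean(), 3))   # -0.036
```

The saturation index near 0 says the null SFD is strongly asymptotic: the
pool is functionally redundant, and random species loss above ~5 species
barely moves FDis. The mean count-weighted deviations are negative in both
habitats — abundance is concentrated on a narrow trait subset — and an
order of magnitude stronger in the harsher upland habitat.

Running the whole pipeline:

```bash
funcdyn run-all --seed 1 --out-dir runs/demo
```

writes `dissimilarity_G.csv`, `dendrogram.nwk`, `fdis_series.csv`,
`null_curve.csv`, `deviations.csv`, `models.json`, `residuals.csv`,
`summary.json`, and `manifest.json`. The selected dry-season richness
model from that run, for example, is

```
ΔS_t = 0.707 − 0.253·HAB − 0.768·S_log,t−1 + 0.197·log N_t      R² = 0.52
```

with partial R²: lagged richness 0.33, sample size 0.42, habitat 0.15 —
first-order negative feedback (regulation) on richness, as every one of the
eight selected models shows for its own lagged level. `funcdyn simulate`,
`build-traits`, `fdis`, `nullmodel`, and `dynamics` expose the individual
stages on CSV inputs.

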