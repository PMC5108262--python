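# prwr — predicted rarity-weighted richness for site prioritization

Conservation planners rarely have species inventories for every site in a
planning area, yet prioritizing sites for species representation needs
exactly that knowledge. `prwr` implements a surrogate workflow for the
common situation where inventories exist for a *fraction* of sites:

1. **Score** the inventoried q% of sites by rarity-weighted richness,
   `RWR = Σᵢ 1/cᵢ`, summing over the species present at a site, where
   `cᵢ` is the number of sites species *i* occupies. Narrow-range species
   contribute large weights, so RWR concentrates on rarity hotspots.
2. **Model** RWR as a random-forest function of freely available
   environmental covariates (500 trees, out-of-bag error), after reducing
   the covariate pool to one representative variable per Kaiser-significant
   PCA factor (eigenvalue > 1 of the correlation matrix).
3. **Predict** PRWR — predicted RWR — for *every* site, including the
   uninventoried ones, and prioritize sites in PRWR order.
4. **Evaluate** the ranking with the Species Accumulation Index,

   `SAI = (S − R) / (O − R)`,

   where `S` is the number of species represented in the top-ranked sites,
   `O` the maximum achievable in as many sites (greedy/exact maximum
   coverage), and `R` the exact expectation for randomly chosen sites
   (hypergeometric). SAI = 1 means the surrogate matched optimal
   complementarity-based selection; 0 means it did no better than chance;
   the reported value is the mean over the top 5–50% landscape fractions.
   Replicate q% splits (default 100) give a mean SAI and a 95% percentile
   CI per inventory fraction q.

A virtual-landscape generator (Gaussian-niche species on latent
environmental gradients, with a tunable environment-vs-noise determinism
dial) provides ground-truthed data for testing every stage.

## Worked example

Simulate a 500-site landscape, score it, fit a PRWR model from a 20%
inventory, and evaluate the surrogate:

```console
$ prwr simulate --sites 500 --species 150 --gradients 4 --variables 10 --seed 7 --out demo
wrote 500 sites x 150 species landscape to demo

$ prwr score --occurrences demo/occurrences.csv --out demo/rwr.csv
wrote RWR for 500 sites to demo/rwr.csv

$ prwr fit --occurrences demo/occurrences.csv --env demo/environment.csv \
      --q 20 --seed 7 --out demo/prwr.csv
predictors: var01_g0, var06_g2, var08_g3, var04_g1
OOB MSE 0.49874  OOB R2 0.418
wrote PRWR for 500 sites to demo/prwr.csv

$ prwr evaluate --occurrences demo/occurrences.csv --scores demo/prwr.csv
mean SAI over top fractions (25, 50, 75, 100, 125, 150, 175, 200, 225, 250): 0.6966
```

The fit line says PCA retained four environmental factors and the forest
explains 42% of out-of-bag variance in subset RWR; the evaluation says
that, averaged over the top 5–50% of sites, ranking by PRWR was 70% as
effective as optimal selection at improving on random choice.

Sweeping the inventory fraction with replicate splits:

```console
$ prwr sweep --occurrences demo/occurrences.csv --env demo/environment.csv \
      --q 10,20,40 --replicates 10 --seed 7 --out demo/sweep
   q     mean   CI_low  CI_high  significant
10.0 0.721260 0.633154 0.841145         True
20.0 0.762551 0.668442 0.856597         True
40.0 0.789700 0.702008 0.847845         True
```

Surrogate efficiency is already significant at a 10% inventory and grows
with q. The output directory also receives `replicates.csv` (per-replicate
seed, OOB MSE, mean SAI) and `sai_vs_q.png` (SAI vs q with CI bars).

The same operations are available as a library
(`prwr.compute_rwr`, `prwr.fit_rwr_model`, `prwr.sai`,
`prwr.sweep`, ...); see the docstrings and `docs/methods.md`.

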