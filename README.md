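# nanodomain

Quantitative imaging analyses of nanoscale membrane-protein organization,
built for the question of how GPI-anchored proteins (GPI-APs) are arranged
at the apical surface of polarized epithelial cells: are they oligomerized,
are they spatially confined, and do perturbations (actin drugs, calcium
chelation) change that organization?  The package implements the three
complementary read-outs used for this question, each paired with a
synthetic-data generator that reproduces the statistical structure of the
corresponding experiment, so every stage is testable end to end without
microscope data.

1. **pc-STORM** — pair-correlation analysis of single-molecule localization
   tables.  The normalized radial pair correlation g(r) of each 4×4 µm ROI
   is fitted with two models:

   - random (isolated molecules, blinking overcounting only):

     g(r) = 1/(4πσ²ₛρ) · exp(−r²/4σ²ₛ) + 1

   - clustered: the same overcounting term plus
     (A·e^(−r/ξ) + 1) ⊛ 1/(4πσ²ₛ)·exp(−r²/4σ²ₛ),

   where σₛ is the localization error SD, ρ an effective localization
   density, ξ the cluster correlation length (diameter reported as 2ξ) and
   A the correlation amplitude at r = 0.  σₛ is estimated from an
   isolated-molecule reference and held fixed in the clustered fit.  A
   condition is called *clustered* when a two-sample Kolmogorov–Smirnov
   test finds the clustered model's fit-error distribution significantly
   (p ≤ 0.05) better than the random model's; cluster-size distributions
   are compared across conditions with a rank-sum (Wilcoxon) test.

2. **Number & brightness (N&B)** — moment analysis of 50-frame image time
   series.  Apparent brightness B = (Var − σ₀²)/(S·(mean − offset)) = 1 + ε
   per pixel, with detector calibration from the ⟨Var⟩ = S·⟨I⟩ + q line,
   photobleaching removed by a mean- and variance-preserving high-pass
   detrend, and pixels partitioned into monomer…hexamer classes via a
   K-means seeded from the monomer/dimer/trimer calibration curve.

3. **Time-gated FLIM** — per-pixel mean lifetime τ = Σᵢ Δtᵢ Iᵢ / Σᵢ Iᵢ with
   Δtᵢ = 2i − 1 ns over 5 or 10 sequential 2-ns gates (3×3 smoothing
   first); FRET between two proteins appears as a statistically
   significant *decrease* of the donor lifetime (two-tailed t-test).

## Layout

- `src/nanodomain/` — the library: `simulate` (generators), `paircorr`,
  `clusterfit`, `nandb`, `flim`, plus `io`/`config`/`pipelines`/`cli`
  glue.  A `nanodomain` console script exposes the generators and
  analyses as subcommands.
- `analysis/` — numbered drivers reproducing the study narrative on
  synthetic conditions; run them in order from the repository root.
- `docs/methods.md` — models, parameter choices and limitations.

## Worked example

```bash
python analysis/01_simulate_conditions.py --seed 1   # inputs -> scratch/synth/
python analysis/02_pcstorm_clustering.py             # tables -> results/
python analysis/03_nandb_oligomers.py
python analysis/04_flim_fret.py
```

The second script prints (seed 1):

```
sigma_s from isolated-molecule reference: 20.3 nm (n=12 ROIs)
control: clustered (KS p = 7.4e-07, 1774 localizations/um^2), diameter 70.9 nm (median 70.6)
egta: random (KS p = 0.787, 1796 localizations/um^2)
latrunculin: clustered (KS p = 0.000204, 1837 localizations/um^2), diameter 67.4 nm (median 66.4)
cluster sizes control vs latrunculin: rank-sum p = 0.419
```

i.e. the control and actin-perturbed conditions are confidently classified
as clustered with recovered domain diameters near the 67-nm ground truth
and no significant size shift between them, while the calcium-chelated
condition (generated without clusters) is classified random.  The N&B
driver recovers condition-mean brightness 1.200 / 1.140 / 1.051 for ground
truths 1.21 / 1.15 / 1.06 (the ~0.01 shortfall is the known small-sample
bias of the 50-frame per-pixel Var/mean estimator; see the methods note),
and the FLIM driver reports the donor gated lifetime dropping from
2.480 ± 0.001 to 2.410 ± 0.001 ns with the acceptor present — a FRET
verdict.

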