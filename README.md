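# woodgrad

Vertical wood-density gradients within trees, and how to stop them from
biasing biomass estimates.

## The problem

Tree aboveground biomass (AGB) is increasingly obtained by multiplying a
measured tree volume — from destructive sampling or terrestrial laser
scanning — by a wood density (WD) value, typically a species average from a
global database or a single basal measurement. But WD varies *vertically*
within a tree: in many (especially dense-wooded, shade-tolerant) tropical
trees it declines from the stump to the small branches, while light-wooded
pioneers stay flat or increase. Because the direction of the gradient is
correlated with basal WD itself, using a basal or database WD does not
average out across a stand — it produces a systematic bias of several
percent, directly propagated into carbon accounting.

`woodgrad` implements the full analysis chain for quantifying and removing
this bias from destructive-sampling campaigns:

* **fieldcalc** — laboratory formulas per wedge sample
  (`WD_i = m_d/v_f`, `MC_i = (m_d − m_f)/m_f`, `BV_i = v_f/m_f`),
  truncated-cone log volumes, compartment summaries and tree totals
  (`V_obs`, `AGB_obs`) over the six vertical compartments
  Stu, Ste_b, Ste, LB, MB, SB;
* **vwwd** — the volume-weighted wood density,
  `VWWD = Σ_c WD_c · V_c / V_obs`, the WD value for which
  `V_obs × VWWD = AGB_obs` holds exactly on volume-built trees;
* **profiles** — row-normalized WD profiles and their scaled
  (correlation-matrix) PCA: axis 1 opposes tree base to crown, so
  decreasing-profile trees score negative;
* **biascorr** — bias statistics
  (`b_i = 100·(AGB_est − AGB_obs)/AGB_obs`, `B = mean(b_i)`,
  `CV = 100·RMSE/MAGB_obs`) and the correction-model family
  `m1: VWWD ~ WD_Stu` … `m6: VWWD ~ WD_GWD + DBH + Sm`, with published
  reference coefficients, plus leave-one-site-out cross-validation;
* **grouping** — guild ANOVA with Tukey HSD, species × site variance
  partitioning, and Blomberg's K with a tip-randomization test for
  phylogenetic signal in the profile scores;
* **synthgen** — a synthetic-campaign generator whose default preset
  reproduces the regime observed in Central-African destructive data
  (roughly 83% of trees with decreasing profiles, mean small-branch
  deficit ≈ −13% of stump WD, gradient direction anticorrelated with
  basal WD).

## Worked example

```bash
woodgrad all --out demo_run --seed 7
```

runs the whole pipeline (simulate → process → convert → pca → fit →
crossval → group → physig → report) and prints the headline report. With
seed 7 the key numbers are:

```
"gradients":         frac_decreasing_trees_pct = 83.9, mean_gradient_pct = -13.8
"pca":               r_pc1_WD_Stu = -0.79
"bias_by_wd_source": WD_GWD:  B = +8.59%,  CV = 31.5%
                     WD_Stu:  B = +8.06%,  CV = 40.7%
                     VWWD:    B = +0.006%, CV = 0.1%
                     VWWD_m1: B = +0.27%,  CV = 10.6%
```

Reading: converting volumes with the database species WD inflates total
biomass by ~8.6% because decreasing profiles dominate; the exact
volume-weighted density removes the bias entirely (the residual 0.006% is
measurement noise on the weighed branches); and a simple linear correction
`VWWD = a + b·WD_Stu` fitted to the campaign brings the bias below half a
percent while needing only one basal measurement per tree.

Library use mirrors the CLI:

```python
from woodgrad import SimulationConfig, generate_dataset, process_tables, predict_vwwd

ds = generate_dataset(SimulationConfig(n_trees=200, seed=1))
comp, trees = process_tables(ds["samples"], ds["logs"], ds["trees"])
trees = trees.merge(ds["species"][["species_id", "WD_GWD"]], on="species_id")
trees["VWWD_hat"] = predict_vwwd("m5", trees)  # published preset coefficients
```

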