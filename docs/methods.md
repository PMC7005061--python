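# Methods

## The measurement chain

All internal units are g, cm, cm³ and g·cm⁻³ (tree heights and crown radii
in m). Per wedge sample the basic wood density is `WD_i = m_d / v_f`, the
moisture content `MC_i = (m_d − m_f) / m_f` and the fresh biomass-to-volume
ratio `BV_i = v_f / m_f`. `MC_i` is implemented exactly as this formula
reads, so it is negative (dry mass < fresh mass); validation checks
`MC_c ∈ (−1, 0]`. Compartment means `WD_c, MC_c, BV_c` are *unweighted*
arithmetic means over a compartment's samples — no volume weighting between
the two wedges, since there is no principled weight available from the
field protocol.

Field measurements convert as:

* weighed part: dry mass `= m_fresh · (1 + MC_c)`, fresh volume
  `= m_fresh · BV_c`;
* cone-measured log: fresh volume `= (π h / 3)(r1² + r1·r2 + r2²)`, dry
  mass `= V · WD_c`;
* directly supplied volume (irregular stumps whose cross-section was
  measured separately): dry mass `= V · WD_c`.

Tree totals sum compartment volumes and masses. The stump compartment is
mandatory (its `WD_c` is the basal density `WD_Stu` used by every
correction model); a missing stump is a hard error rather than an
imputation, because everything downstream conditions on it.

## The volume-weighted wood density

`VWWD = Σ_c WD_c · V_c / Σ_c V_c`. On a tree whose compartment masses are
built from volumes (cone-measured logs), `V_obs · VWWD = AGB_obs` holds to
machine precision — this identity is the reason VWWD is the right
volume-to-mass converter, and it is asserted at 1e−12 relative tolerance in
the tests. On weighed compartments the identity is only approximate: the
sample means `MC_c` and `BV_c` do not commute with the per-sample identity
`(1 + MC_i)/BV_i = WD_i` once measurement noise enters, leaving a residual
bias of order the squared noise (≈0.01% at the default 2% measurement
noise).

## Profile ordination

Profiles are compared shape-wise after row normalization. Two modes exist
because both are defensible readings of standard practice: dividing each
row by its mean (`row_mean_ratio`, the default — a flat profile maps to six
ones, and the normalized values keep the "percent of tree mean" reading)
and row-centring (`row_center`). Results are reported for the default;
both are tested.

The PCA is "scaled": columns standardized (SD with n−1), eigendecomposition
of the correlation matrix, scores = standardized matrix × eigenvectors.
Eigenvector signs are arbitrary in any eigensolver, so orientation is fixed
by convention: the small-branch (SB) loading is positive on axis 1 — hence
trees with relatively dense bases and light crowns (decreasing profiles)
score *negative* — and the stem (Ste) loading is positive on axis 2. This
makes scores stable across runs, row orders and BLAS builds.

A tree missing only the stem base (Ste_b) has it imputed as the mean of its
stump and stem WD before normalization (the stem base is physically
intermediate between the two), and the row is flagged. Trees missing any
other compartment are excluded with a warning rather than imputed: the
remaining compartments are not interpolatable from their neighbours with
any confidence.

## Bias statistics and the correction models

`b_i = 100 (AGB_est,i − AGB_obs,i)/AGB_obs,i`; `B = mean(b_i)`;
`RMSE = sqrt(mean((AGB_est − AGB_obs)²))`; `CV = 100 · RMSE / mean(AGB_obs)`.
Two distinct "residual error" quantities are kept apart by name:
`model_rse` (residual SE of the VWWD regression, g·cm⁻³, √(SSR/(n−p))) and
`agb_rmse` (the AGB-level formula above, g).

The model family m1–m6 regresses VWWD on basal WD (`WD_Stu`) or database
species WD (`WD_GWD`), optionally adding DBH and the stem-morphology index
`Sm = Ht/H`. Fits are unweighted OLS. AIC uses the Gaussian likelihood with
the error variance counted as a parameter (k = p + 1); the absolute level
depends on this convention but ΔAIC across the family does not, and ΔAIC is
the only quantity used for model comparison. Published reference
coefficients for all six models (from a large multi-site Central-African
destructive calibration) ship as presets for use on campaigns with no local
destructive data.

Model fits report both the apparent (fitting-set) B and CV and, through
`loso_crossval`, the leave-one-site-out versions: calibrate on all sites
but one, predict VWWD → AGB on the held-out site, report per-site and
pooled statistics.

## Grouping analyses

The guild analysis is a classical one-way fixed-effects ANOVA on axis-1
scores, with Tukey HSD pairwise comparisons computed directly from the
studentized range distribution (`scipy.stats.studentized_range`,
Tukey–Kramer SE for unequal group sizes) — for two groups this reduces
exactly to the pooled-variance t-test, which the tests assert to 1e−10.
The compact letter display uses the insert-and-absorb algorithm.

The species × site partition is a *sequential* (type-I) two-way ANOVA with
interaction, fit by least-squares projections of increasing design matrices
(intercept → +species → +site → +interaction), with degrees of freedom from
matrix ranks. Sequential SS is the right choice here because the question
is ordered — how much does species membership explain, and how much do
sites add on top. The analysis is restricted to species found in at least
`min_sites` (default 3) sites so the factors are genuinely crossed; if the
interaction has zero rank it is dropped with a warning. Variance fractions
are SS_term/SS_total.

Blomberg's K follows the standard variance-ratio construction: with C the
phylogenetic covariance matrix (shared root-to-MRCA branch length),
`â = (1'C⁻¹x)/(1'C⁻¹1)` the GLS mean,
`K = [(x−â)'(x−â) / (x−â)'C⁻¹(x−â)] / [(tr C − n/(1'C⁻¹1))]`
(both numerator and denominator ratios share the n−1 factor). K is
invariant to rescaling branch lengths or the trait; it equals 1 in
expectation under Brownian motion, and is *identically* 1 on a star
phylogeny (where the BM null coincides with iid — there is no signal to
detect there, which the tests assert as a property). Significance uses tip
randomization: p = (1 + #{K_rand at least as extreme})/(n_rand + 1),
default 999 shuffles. The default tail is *lower* (is the trait less
clustered on the tree than chance, i.e. overdispersed?); upper and
two-sided tails are available, since low-K situations can be read either
way and the choice should be explicit.

## The synthetic generator

The generator emulates a multi-site tropical destructive campaign, not any
particular dataset: 51 species spanning WD 0.22–1.02 g·cm⁻³ (the observed
tropical range), 822 trees over 6 sites by default, six compartments per
tree, two wedge samples per compartment, and field logs (trunk compartments
cone-measured, branches weighed) whose geometry integrates exactly to the
true compartment volumes.

The key structure is the gradient–basal-WD coupling. Per tree, the
stump-to-small-branch WD change is
`G = gradient_slope · (wd_pivot − WD_basal) + ε`, ε ~ N(0, slope_sd),
linear in compartment rank (an optional quadratic term, default 0, allows
the convex profiles seen in some dense-wood taxa). The default preset —
`gradient_slope = 0.45`, `wd_pivot = 0.36` g·cm⁻³, `slope_sd = 0.035`,
basal scatter 0.05, compartment noise 0.02, 2% measurement noise — was
chosen to place the simulated population in the empirically observed
regime: across seeds, ~82% of trees with decreasing profiles (seed-to-seed
range roughly 75–89%), mean small-branch deficit ≈ −13% of stump WD, and a
strong negative correlation (≈ −0.8) between axis-1 scores and `WD_Stu`.
Under this preset, database-WD conversion inflates biomass by ~7–9% — the
documented failure mode the correction models exist for.

Compartment volume fractions are Dirichlet-distributed around
(Stu 5%, Ste_b 5%, Ste 55%, LB 20%, MB 10%, SB 5%) — dominant-trunk trees —
with total volume from a form-factor allometry (0.35 × basal area ×
height). Species abundances are Dirichlet with concentration 4, so the
most-sampled species takes ~5–6% of trees, matching realistic campaign
evenness. Moisture contents are drawn in (−0.55, −0.25), guaranteeing dry
mass < fresh mass. An optional additive site intercept on basal WD exists
but defaults to 0 (no site effect), which is what the cross-validation
robustness checks assume. All randomness flows through per-stage substreams
of a single seed, so identical configs give byte-identical tables.

What the generator does *not* emulate: radial (pith-to-bark) gradients,
within-compartment vertical structure, measurement-protocol pathologies
(moisture loss before weighing, bark loss), phylogenetic signal in the
profiles (the simulated phylogeny is independent of the trait structure,
so the K observed on synthetic data reflects guild/WD clustering only as
far as it is phylogenetically random), and any 3-D geometry. Passing tests
therefore demonstrate the correctness and internal consistency of the
estimators and the bias-removal logic under the stated statistical regime —
not the field accuracy of any particular campaign.

Because the synthetic profiles are cleaner than field data (small
`slope_sd`), the m1–m6 fits reach R² ≈ 0.95–0.98 on synthetic campaigns,
higher than typical destructive datasets (≈0.8–0.9); the bias-removal
*structure* (several percent down to a few tenths of a percent) is the
meaningful comparison, not the R² level.

## Numerical choices and edge cases

* Correlation-matrix PCA via `numpy.linalg.eigh` (symmetric solver);
  eigenvalues clipped at 0; constant columns are a named error.
* Tukey p-values capped at 1; zero within-group variance handled
  explicitly (p = 1 for zero difference, 0 otherwise).
* `phylo_vcv` inverts C directly (tree sizes here are ≤ hundreds of tips);
  Brownian simulation adds 1e−12 jitter before Cholesky for degenerate
  ultrametric ties.
* Frustum volume validates h > 0 and non-negative radii; the cylinder and
  cone limits are exact.
* The pipeline's single seed fans out via `numpy.random.SeedSequence`
  substreams keyed per stage, so stages can be rerun in isolation with
  unchanged results.

## Problem sizes used in the test suite

The checked experiments run at desk scale, chosen to make the statistical
assertions stable: 500 trees for the conservation identity, 1000 for the
bias-removal hierarchy, 200 replicates × n = 800 for regression coverage,
50 random 20×6 fixtures for the PCA oracle, 200 Brownian replicates on a
50-tip tree plus 100 null shuffles × 199 randomizations for the K
calibration, and 800 trees over 6 sites for the leave-one-site-out check.
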