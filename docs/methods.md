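# Methods

This note documents the statistical model behind `tauconnect`, the design
choices that were genuinely open, the synthetic cohort the test suite runs
on, and what passing those tests does and does not establish.

## Matrices

Three P×P symmetric matrices share one container and one convention:
Fisher-Z scale (z = atanh r), zero diagonal, ROI order = atlas row order.

* **Functional connectivity (FC).** Pearson correlation of a subject's T×P
  ROI time series over all pairs, transformed, then averaged element-wise
  across a group's subjects *in Fisher-Z scale* (transform first, average
  second — the variance-stabilized scale is the right one for averaging
  correlations).
* **PET covariance.** For each ROI pair, the Spearman correlation across a
  group's subjects of the two ROIs' SUVR values (average ranks for ties,
  Pearson on ranks). Rank correlation is deliberate: a single extreme SUVR
  value in one subject or region cannot dominate an edge. The
  covariate-adjusted variant residualizes the rank-transformed SUVR on
  age, sex (coded F=0/M=1) and education — with intercept — and correlates
  the residuals. If a covariate absorbs all of a ROI's rank variance, that
  ROI's partial correlations are reported as 0 rather than undefined.

Correlations are clipped to |r| ≤ 1 − 1e-7 before atanh, so a perfect
correlation maps to z ≈ 8.4 instead of infinity; infinities would otherwise
poison every downstream regression. Group-level matrices carry provenance
(kind, group, n_subjects, adjusted_for).

## Edge association and the permutation null

Edges are the strict upper triangle in row-major order. The association
between two edge vectors is the OLS slope β of y on [1, x] (plus Euclidean
centroid distance as an extra column when distance adjustment is on), with
the *unadjusted* Pearson r always reported alongside. "Generalized linear
regression" here means Gaussian-identity OLS: the responses are Fisher-Z
edges and no other link is sensible.

The permutation null perturbs the connectivity matrix and recomputes β
identically:

* **node_relabel** (default): one random ROI permutation applied jointly to
  rows and columns. This preserves the matrix's value distribution and each
  edge's pairing structure, and is therefore the stricter null;
* **edge_shuffle**: upper-triangle values permuted freely.

p_exact = (1 + #{β_null ≥ β_obs}) / (n_perm + 1), right-tailed by default
because the substantive hypotheses are directional (positive association);
a two-sided variant ranks |β|. The add-one form can never return 0. For
small P an exhaustive mode enumerates all P! relabellings and reports the
plain enumeration fraction (identity included, so p ≥ 1/P!). Distance
covariates stay fixed under permutation — the null randomizes connectivity,
not geometry. Permutation slopes are computed by Frisch-Waugh-Lovell
residualization, which is algebraically identical to the full OLS
coefficient and verified against it in the tests.

Per-network associations use within-network edges only; a network with
fewer than 3 within edges is reported as skipped, not silently dropped.
No multiple-testing correction is applied across the seven networks by
default; the report includes a Bonferroni column where relevant for
transparency.

## Seed spreading

For seed s, the target uptake vector (group-mean SUVR over the P−1 other
ROIs) is regressed on conn[s, targets]; β_s is the seed's spreading weight.
The spreading signature is the Pearson correlation across seeds between
seed uptake and β_s. Rank-ordering ROIs by uptake is presentation only —
the regression itself is rank-free. Uptake is the AD group mean (the
group-level design); a subject-level variant is deliberately out of scope.
Seeds with degenerate (zero-variance) connectivity rows get NaN slopes and
are excluded pairwise rather than imputed. Because raw slopes depend on the
connectivity scale, seed reports also carry a standardized slope
(β · SD(x)/SD(y)). Ties at the uptake extremes break toward the lowest ROI
index, with a warning.

## Mediation

Three OLS equations with shared covariates Z: M ~ X + Z, Y ~ X + Z (total
effect c), Y ~ X + M + Z (direct effect c′, mediator effect b). The
indirect effect is the difference c − c′, which equals the product a·b
exactly in this linear shared-covariate setting (asserted to 1e-10 in the
tests). Inference is a nonparametric unit-resampling bootstrap (default
B = 1000, seeded) with percentile CIs — chosen over quasi-Bayesian
machinery because it is asymptotically equivalent for linear models,
simpler to verify, and fully reproducible. p_indirect is an add-one
smoothed two-sided bootstrap sign test. The proportion mediated
(c − c′)/c explodes near a null total effect, so it is withheld (flagged
unstable) when |c| < 1e-8 · SD(Y)/SD(X).

Two applications:

* **edge level** — units are edges; X = tau covariance, M = FC, Y = FDG
  covariance. Subject covariates are undefined per edge, so covariate
  control is delegated to matrix construction (partial-correlation
  matrices); the adjustment provenance is carried into the result.
* **hotspot level** — units are the P−1 target ROIs; X = group-mean tau
  SUVR, M = FC of each target to the tau hotspot, Y = per-ROI FDG Z-score
  (AD mean minus NC mean, in NC sample-SD units).

## Synthetic cohort generator

The generator is the package's test bed; its defaults are the study
conditions the suite runs under.

* **Connectome.** Block-structured correlation matrix over K networks:
  within-network level `w_within` = 0.5, between `w_between` = 0.1,
  projected to positive definite when needed (eigenvalue floor 1e-6,
  rescaled to unit diagonal). P = 40 parcels over K = 7 networks keeps
  every network with enough within-network edges at desk scale.
* **Time series.** T = 200 timepoints per subject drawn iid from
  N(0, FC) — no hemodynamics, autocorrelation, or motion artifacts.
* **Cohort sizes.** 22 NC / 57 AD, matching the clinical cohort scale the
  analysis design targets.
* **Tau.** AD: tau_ij = 1 + A·max(f_j, 0) + u_ij, where f is the
  connectome row of a configurable epicenter, A (`tau_amplitude` = 0.75)
  the spreading gain, and the residuals u across ROIs have correlation
  (1 − ρ)I + ρ·FC with one coupling dial ρ (`rho_tau` = 0.6) and scale
  σ_tau = 0.2. The epicenter's own profile value is 1, so it is the
  group-mean hotspot by construction. NC: 1 + unstructured noise.
* **FDG.** AD: fdg_ij = 2 − c′·(tau_ij − 1) − b·m_ij + e_ij with mediator
  m_ij = a·A·max(f_j, 0) + em_ij; defaults a = 0.8, b = 0.5, c′ = 0.4,
  σ_m = 0.2, σ_y = 0.15. The true proportion mediated is
  a·b/(a·b + c′) = 0.5. NC: 2 + unstructured noise.
* **Demographics** resemble a memory clinic (NC younger) but are
  independent of the PET model, so covariate adjustment is a no-op in
  expectation.

Two generator choices deserve emphasis. First, the mediator's systematic
part is the FC-to-epicenter profile itself and its noise em shares the
ρ-blended spatial correlation of the tau residuals. Both are needed for the
*measured*-mediator analyses to be identifiable: if FDG were built from the
realized tau values plus unstructured noise alone, FDG would be independent
of connectivity given tau, and both the edge-level and hotspot-level
mediations would correctly recover a proportion of ~0 no matter the
nominal a, b, c′. With this construction the hotspot-level mediator
(measured FC) carries the systematic part and the edge-level outcome (FDG
covariance) has a genuine connectivity channel. Second, all noise is
Gaussian; the Spearman stage makes the pipeline rank-robust anyway, and
Gaussianity keeps the ground truth analytic. A heavy-tail option is
deferred.

Recovery behaviour, measured by the suite: the proportion mediated is
recovered essentially unbiased from direct (X, M, Y) triplets (mean
absolute error < 0.05 at n = 2000 across a grid of path coefficients);
the hotspot-level recovery from a full simulated cohort is attenuated and
noisy (mean ≈ 0.42 vs truth 0.5 across replicates, single-cohort SD ≈ 0.3)
because the measured mediator is a noisy proxy on only P − 1 = 39 units and
is strongly collinear with tau uptake; the edge-level proportion
(≈ 0.3–0.4 across replicates) has no closed-form truth — it reflects the
relative strength of the connectivity channel in FDG covariance — but is
reliably inside (0, 1) with bootstrap CIs excluding zero.

## What the synthetic tests do and do not show

Passing the suite establishes that the estimators are internally correct
(exact agreement with brute-force oracles), that the permutation test is
calibrated under the generator's null (rejection rate within the binomial
99% band around 0.05 over 200 cohorts), that association strength responds
monotonically to the coupling dial, and that the full pipeline reproduces
the qualitative sign structure expected of a spreading pathology. It does
not validate the biological model on real data: real BOLD autocorrelation,
scanner effects, partial-volume residuals, spatially correlated noise and
demographic confounding are all absent from the generator, and real
covariance matrices need not match the block-plus-epicenter structure
assumed here.

## Numerical conventions and degenerate inputs

* ROI indices are 0-based internally, 1-based (`roi_id`) in files, reports
  and error messages.
* Matrices on disk are dense TSV with 17-significant-digit floats; readers
  parse with round-trip precision, so write→read is bit-exact.
* Constant time series, constant SUVR across subjects, zero NC FDG SD, and
  zero-variance regressors raise errors naming the offending ROI; constant
  extra covariates (e.g. all-equal distances) are dropped with a warning.
* Every stochastic routine takes an explicit seed (or Generator); the
  orchestrated run derives per-stage seeds from the cohort seed and echoes
  them into the report, making repeat runs byte-identical.
* Analyses on patient-group matrices default to the AD group — the group
  carrying pathology — with NC matrices still computed and emitted.

## Problem sizes in the checked runs

The acceptance script and the statistical tests run at P = 40, 22 NC /
57 AD, T = 200, with 199-permutation nulls for the 200-cohort calibration
study, 500 permutations for single-cohort association reports, 20
replicates per condition for the monotonicity and sign-structure checks,
and B = 200–1000 bootstrap draws for mediation CIs. These sizes were chosen
so the entire validation battery runs in minutes on a single core while
keeping every binomial/Monte-Carlo band meaningful.
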