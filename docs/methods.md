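# Methods

## Data model

The pipeline's universal input is a samples × metabolites matrix of
non-negative relative abundances with sample metadata (accession, group
D/W, species, ripening stage G/W/R, replicate) and metabolite metadata
(class primary/secondary). Missing cells are NaN; a literal 0 is a measured
"undetected" abundance, which matters because the two analysis branches
treat them differently (below). Tables are written with fixed column order
and 12 significant digits; the generator rounds its output to the same
precision, so write→read round-trips are bit-exact and full runs with the
same seed are byte-identical.

## STATIS

Each accession gives a t × p table (default t = 3 stage means over
replicates; t = 9 with `row_mode="stage_by_rep"`). Missing values are
zero-filled (undetected-equals-zero), values are log10(1 + x) transformed
(variance stabilization; zeros map to zero), columns are centered within
the table, and the table is scaled so ‖X Xᵀ‖_F = 1. Equal row masses 1/t.

The cross-product is S = X Xᵀ with no mass weighting inside the product;
masses enter only through the metric of the compromise eigen-analysis
(decompose M^{1/2} S M^{1/2}, M = diag(masses); row scores are
mass-weighted principal coordinates). For unit-norm PSD matrices the
elementwise inner product of two cross-products *is* the Rv coefficient.
The table weights α are the leading eigenvector of the inner-product
matrix C, normalized to unit Euclidean length (not sum-to-one) and
oriented non-negative; eigenvector signs are fixed by making the
largest-magnitude loading positive. Components are truncated at
eigenvalues above 1e−12.

With t = 3 centered rows, cross-products live in a very low-dimensional
cone, so Rv between any two tables is high (≳0.9) and contrasts are
relative: the meaningful pattern is *higher and tighter* domesticated
weights with the wild weights spread downward, not an absolute gap —
individual wild tables can align with the compromise, as happens in real
germplasm panels.

## Missingness filter and imputation

Metabolites with strictly more than 20% missing cells (over all samples
jointly) are excluded; the cutoff is configurable. Imputation is an
EM-style probabilistic low-rank fit in the Bayesian-PCA family: on log10
scale (offset = half the smallest positive observed value), missing cells
are initialized at column means and iterated to the rank-5 truncated-SVD
reconstruction of the completed, centered matrix until the relative change
of the imputed block falls below 1e−6 (default cap 500 iterations; a
non-converged fit returns the best estimate with a flag). Observed cells
are never altered. Acceptance is by known-truth RMSE against column-mean
imputation on low-rank data, which this construction beats essentially
always.

## Correlation networks and differential connectivity

Networks are built per stage and group from the filtered, imputed,
log10-scale data, treating the 7 accessions × 3 replicates = 21 samples
as exchangeable (the correlation sample unit of the emulated design).
Pairwise Pearson r gets two-sided p-values from the t transform with
n − 2 df; Benjamini–Hochberg runs over all metabolite pairs; edges are
pairs with q < 0.05. Constant metabolites have undefined correlations,
carry no edges, and are flagged. Density is edges over all possible pairs.

Differential connectivity per metabolite is the difference of
max-degree-normalized degrees, DC = deg_D/max_D − deg_W/max_W ∈ [−1, 1];
an empty network contributes normalized degree 0 for all nodes. Its null
distribution comes from reassigning whole accessions (all replicates
together) to the two groups, preserving the 7/7 split — this respects
within-accession correlation, which sample-level shuffling would break.
Empirical p-values use the add-one estimator (1 + #{|DC_b| ≥ |DC_obs|}) /
(B + 1), so p ≥ 1/(B+1) always, and are BH-adjusted across metabolites.

A structural consequence worth knowing: with only 7 + 7 exchangeable
units, permutations that nearly reproduce the true split (≥6 accessions
in place; about 3% of draws) partially reproduce any genuine group
difference, so the permutation p-value for a real signal has a floor well
above 1/(B+1) unless the wild samples are dispersed enough to dominate the
mixed-group correlations (see the generator notes). This is a property of
the design, not of the implementation.

Abundance differences use two-tailed Welch t-tests on log scale with BH
adjustment; direction is the sign of mean(D) − mean(W). Metabolites with
both q values below the threshold are classified into quadrants by
(sign(DC), direction): gain of connectivity with increased abundance in D
is top-right. The class association uses Pearson χ² with Yates continuity
correction on the 2 × 2 table (primary/secondary) × (gain/loss), either
over all metabolites with non-zero DC (always well-defined) or restricted
to significant DC (can degenerate; both are exported).

## Mixed-effect biomarker screen

Per metabolite: `log10(abundance) ~ stage + replicate + population` with a
random intercept for genotype (labels unique across populations, hence
nested), fitted by REML via statsmodels MixedLM. The population effect is
oriented as domesticated minus wild and tested with a t reference on
between-within degrees of freedom, df = n_genotypes − 2 — the appropriate
reference for a factor constant within genotypes; in the calibration
simulation (500 null fits, genotype variance present) the realized type-I
error is ≈0.035–0.05 at nominal 0.05. When the genotype variance collapses
the screen falls back to the fixed-effects-only OLS model and flags it;
constant responses fail cleanly. p-values are BH-adjusted across
metabolites; both raw-p and q-based significance counts are reported.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the emulated
study conditions: 7 + 7 accessions × 3 stages × 3 replicate pools, 43
primary + 87 secondary metabolites, 29 planted domestication biomarkers
(26 secondary, 3 primary) at 3 residual SDs, 5 wild-only hub metabolites,
structural co-regulation density targets 0.115 (domesticated) / 0.288
(wild secondary), and 4 primary + 6 secondary metabolites forced past the
20% missingness filter (the study's 43→39 and 87→81 attrition).

Abundances are multivariate normal on log10 scale and exponentiated
(lognormal marginals — positive and right-skewed, like MS intensities).
Components, per sample: a metabolite baseline N(3, 0.5²); a shared linear
G→W→R trend on a random half of the metabolites; the biomarker shift
(±half in each group); accession-stable and accession×stage random
offsets; a coherent per-accession×stage "secondary-metabolism activation"
scalar shifting all secondary metabolites together (this is what makes
wild tables genuinely heterogeneous in STATIS — independent per-metabolite
noise averages out over 130 columns); and correlated residual noise.

Correlation structure is built from disjoint equicorrelated cliques
("modules") at base_corr = 0.7 — positive semidefinite by construction.
Modules are shared between groups; the wild matrix coarsens the partition
by bounded pairwise merges (wild co-regulation is a superset), and each
hub — a singleton in the domesticated structure — joins one merged wild
module at hub_corr = 0.8. With equal density targets and no hubs the two
group matrices are identical, exactly the exchangeable global null the
calibration tests need. With `hub_mode="dedicated"` (no background
modules) the hubs instead form an explicit factor-model "program": a
mutually correlated hub core, one tight partner module per hub, and the
minimal cross terms the geometry forces. That geometry is worth stating:
any correlation matrix in which one node correlates at r with k partners
forces the partners' mean mutual correlation up to (k·r² − 1)/(k − 1)
(≈0.61 for k = 15, r = 0.8), so "a hub with uncorrelated partners" does
not exist; partners of a strong hub are themselves co-regulated.

Three noise choices are deliberate and load-bearing. First, accession
offsets are drawn with the same group correlation structure as replicate
noise; independent offsets would attenuate every planted correlation by
the accession-variance share. Second, accession-level variance shares are
kept small (≈10–15%); with only 7 accessions per group, a dominant
accession-level component makes the effective sample size for correlation
≈7 and the generator would no longer realize its planted correlations in
21-sample networks (the generator's contract is that the empirical
hub-partner correlation at large n is within ±0.1 of the planted value).
Third, wild noise is `wild_dispersion_scale` (default 3) times more
dispersed for secondary metabolites — the wild-variability pattern of
domestication panels. At high dispersion (5×, used in the hub power
analysis) wild samples dominate the pooled correlation of any mixed
accession subset, so permuted groups both express the wild structure and
the permutation null for differential connectivity collapses; at the
moderate default it does not, and few metabolites reach permutation
significance — both regimes are faithful to the permutation scheme, and
the power analysis documents its conditions.

Missingness combines a limit-of-detection mechanism (a configurable
fraction of planted missing cells drawn from each metabolite's bottom
quartile) with uniform missingness, at a planted total rate, plus the
forced high-missingness metabolites (35% of cells) that exercise the
filter.

What the generator does **not** emulate: chromatographic or batch
artifacts, pooling noise distinct from replicate noise, realistic
metabolite identities or pathway stoichiometry, non-lognormal marginals,
and missingness that is informative about group. Passing tests therefore
show the statistical machinery is correct and calibrated under the stated
design, not that real strawberry data would yield the study's specific
compound lists.

## Problem sizes and determinism

The test suite runs the calibration studies at the sizes stated in the
test docstrings: 20 global-null datasets at B = 200 for calibration, 20
seeds at B = 999 (pooled stages, 63 samples per group) for hub power, 500
null mixed-model fits, 20 imputation seeds; the acceptance script runs one
full default pipeline at B = 1,000. One master seed drives everything
through deterministically derived child seeds recorded in the run
manifest; identical config + seed reproduces every output file byte for
byte (the manifest's config hash excludes the output location).

## Known limitations

- The permutation floor with 7 + 7 accessions (above) bounds attainable
  q-values for genuinely group-specific structure at moderate dispersion.
- The between-within df approximation is conservative-to-nominal in the
  balanced design tested; strongly unbalanced designs may warrant a
  Satterthwaite or likelihood-ratio alternative.
- Density targets for the wild structure are approximated from below by
  the merge granularity of the module partition; achieved structural
  densities are recorded in the ground truth.
- Networks treat replicates as exchangeable samples; within-accession
  correlation mildly inflates edge counts equally in both groups (the
  permutation test is unaffected, as accessions move whole).
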