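# Methods

## The multifunctionality index

`soilmf` scores soil multifunctionality (SMF) with the *averaging* approach.
Given a plot × indicator table X (i indexes plots, j the 20 indicators of
the default scheme), each indicator is z-scored across plots,

    Z_ij = (X_ij − μ_j) / δ_j,

with μ_j and δ_j the across-plot mean and standard deviation. Indicators are
grouped into four soil functions — environmental regulation (MC, BD, TPO,
EC, pH), nutrient supply (AP, AK, NH4N, NO3N), nutrient storage (TC, TN, TP,
TK) and nutrient cycling (UE, AKP, CBH, NAG, BG, PPO, POD) — and each
function index F_if is the mean z-score of its indicators. The overall index
is the mean of all 20 z-scores,

    SMF_i = (1/20) Σ_j Z_ij = Σ_f (n_f / 20) F_if ,

so SMF is exactly the size-weighted mean of the four function indices (the
package asserts this identity numerically at 1e−12). Standardization forces
the across-plot mean of every z column — and hence of SMF — to zero, so SMF
is a *relative* score: it ranks plots within one survey and is not
comparable across surveys.

Choices worth knowing:

* δ_j is the sample SD (n−1 denominator). The definition admits either
  convention; ours is configurable via `ddof`.
* Indicators enter with their measured orientation. Bulk density or pH are
  *not* sign-flipped by default; a per-indicator `directions` map is
  available for users who consider some indicators "bad when high".
* A constant indicator column (δ_j = 0) is an error, never silently dropped.

Treatment comparisons use one-way ANOVA with Fisher's LSD post hoc tests:
pairwise t statistics on the pooled within-group mean square with N − g
degrees of freedom, unadjusted (that is what LSD is; a Holm-adjusted column
is always reported for users who want protection). Compact display letters
are the maximal cliques of the non-significance graph, so two treatments
share a letter iff they are not separated at α.

## Diversity and community statistics

Alpha diversity per sample: observed richness; Chao1
(S_obs + F1²/2F2, bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) when no
doubletons exist); Shannon entropy in nats (configurable base); and
Gini–Simpson 1 − Σp², oriented so larger = more diverse. Indices are
computed on raw counts by default — an optional `rarefy(depth, seed)` is
provided for sensitivity analysis, since results at very uneven depths can
be depth-driven.

Beta diversity: Bray–Curtis dissimilarity on raw counts, NMDS by non-metric
SMACOF with 20 restarts (restart 1 from the classical metric-MDS
configuration, the rest random Gaussian), reporting Kruskal stress-1

    stress = sqrt( Σ (d̂_ij − δ̂_ij)² / Σ d̂_ij² ),

where d̂ are configuration distances and δ̂ the isotonic (monotone,
ties-share-a-block) regression of d̂ on the dissimilarities. Stress is
recomputed by the package's own definition for every restart and the best
restart is returned, so the reported number does not depend on the internal
optimizer's convention.

Group location differences are tested with PerMANOVA: pseudo-F from sums of
squared distances (SS_total = Σ_{i<j} d²_ij / N, SS_within summed per group
with 1/n_g weights), label-permutation null. Relationships between distance
matrices use the Mantel test (Pearson correlation of lower triangles,
simultaneous row/column permutation of the second matrix, one-sided upper
tail). Both use the add-one p estimator p = (1 + #{perm ≥ obs}) / (1 + B),
which cannot return p = 0, and switch to exhaustive enumeration for small
designs (all N! label orders when N! ≤ 10,000 for PerMANOVA; N ≤ 7 for
Mantel), where the p-value is exact. Per-taxon group differences use the
tie-corrected Kruskal–Wallis H with a chi-square reference; a taxon with
all-identical values is flagged degenerate and reported as p = 1 rather
than failing the whole table.

## Driver attribution

The Mantel screen pairs a community-side distance (Euclidean over
standardized alpha-diversity indices, or any supplied distance matrix) with
one distance matrix per indicator (absolute difference of standardized
values). Which alpha index feeds the attribution stage is a genuine design
opening; the pipeline uses Shannon by default, configurable.

**Permutation importance.** The key-factor screen fits a bagged ensemble of
regression trees (default 500 trees, feature subset ⌈p/3⌉ per split,
seeded bootstrap). Importance of feature j is the across-tree mean increase
in out-of-bag MSE when j's out-of-bag values are shuffled, divided by the
response variance so the default retention cutoff (0.01) is scale-free.
Features *exceeding* the cutoff are retained — a rule of the form
"increase in MSE < 0.01 retains" would keep exactly the unimportant ones,
so the package treats the cutoff as a lower bound (the opposite convention
is available via `select_above=False`).

A caveat established while validating the screen: at survey-scale samples
(n ≈ 200, 10 features) the *null* distribution of this importance — the
canonical raw %IncMSE of random-forest practice — fluctuates by roughly
0.01–0.05 in the maximum across features. The fluctuation is
data-conditional: it persists no matter how many trees or permutation
repeats are averaged, and it is reproduced by the independent R
`randomForest` implementation on identical data. A fixed 0.01 cutoff
therefore admits occasional false positives on pure noise; users wanting a
protected selection should combine the cutoff with the reported per-feature
p-values (one-sided test of the per-tree increases) or raise the cutoff.

**Path model.** "SEM" here is recursive path analysis over observed
variables: every node of the DAG is a measured composite (diversity
indices, function indices, SMF), each endogenous node is fit by OLS on its
parents, and coefficients are standardized (columns z-scored before
fitting). There are no latent variables and no covariance-structure ML fit,
which keeps the effect decomposition exact: the direct effect of a source
on an outcome is its edge coefficient, the indirect effect is the sum over
all directed paths of length ≥ 2 of the coefficient products (computed via
the nilpotent power sum Σ B^k of the coefficient matrix), and total =
direct + indirect identically. Collinear parents (design condition number
> 1e8) are an error naming the equation.

The default DAG routes bacterial diversity to cycling, regulation and
storage, fungal diversity to cycling, cycling to supply and storage, and
the three function nodes storage, regulation and supply into SMF. The edge
set is fully configurable (YAML), since which non-significant edges belong
in the model is a modelling choice, not an estimate.

One structural fact matters for testing: with *zero* residual noise the
three parents of SMF are exact linear functions of the two exogenous
diversities, so the SMF equation is rank-deficient and the collinearity
error fires — exact noiseless recovery is only well-posed on the upstream
(diversity → function) subsystem. The tests exercise exactly that split.

## The synthetic study design

The generators emulate the field design the package was built around — a
monoculture pecan control (CK) and three understory intercropping systems
(CPS, CPH, CPL), three replicate plots each — whose plot-level measurements
are not public. They provide planted ground truth, not a forgery of any
real dataset.

* **Indicators**: multivariate normal around plausible orchard-Vertisol
  baselines (pH 7.9, TN 1.02 g kg⁻¹, AP 17.2 mg kg⁻¹, AK 178.7 mg kg⁻¹,
  …), within-treatment SD 8% of baseline, and exchangeable correlation
  ρ = 0.4 among indicators of the same function (functions share drivers);
  cross-function noise independent. Treatment effects are additive shifts
  in within-treatment SD units, so a planted shift is directly comparable
  to a z-score effect; defaults plant +0.74 (CPS), +0.55 (CPH) and −0.20
  (CPL) on all indicators. Note the mapping from a planted within-treatment
  shift s to the SMF scale: the shift itself adds between-treatment
  variance, inflating the standardizing SD by sqrt(1 + Σ(μ_t − μ̄)²/(n−1)),
  so the expected SMF contrast is s divided by that factor (≈ 0.70 for a
  lone +0.74 shift in the 12-plot design). The recovery tests use this
  closed form.
* **Communities**: Dirichlet-multinomial counts. A fixed mean profile gives
  each phylum its expected relative abundance exactly (fungal default
  dominated by Ascomycota 0.55 / Basidiomycota 0.38; bacterial default led
  by Proteobacteria 0.30 / Acidobacteria 0.225); per-treatment Dirichlet
  concentrations set replicate evenness; depths are log-normal with mean
  20,000 reads truncated at 1,000, matching typical amplicon yields.
* **Path data**: exogenous nodes standard normal, endogenous nodes linear
  in their parents plus Gaussian residual (default SD 0.3, n = 500). The
  output is flagged `attrs["standardized"]`; the path fitter honours the
  flag and skips re-scaling, because re-standardizing simulated columns
  would rescale planted coefficients by the endogenous SDs and make exact
  recovery impossible.

Each generator draws from its own RNG stream derived from (seed, operation
tag), so outputs are bit-reproducible and adding a generator never perturbs
another's stream.

What the generators deliberately do **not** emulate: sequencing error,
chimeras, taxonomy misassignment, compositional spatial structure,
non-normal indicator distributions, or indicator–diversity coupling (the
indicator and community generators are independent unless wired together
through the path generator). Passing tests therefore demonstrate that the
*estimators* recover planted truth under the stated design — not that real
pecan-orchard data satisfies the generating assumptions.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to make Monte-Carlo error small
relative to the asserted tolerance: 1,000 seeds for the SMF-contrast
recovery (±0.05 band), 400+ seeds for raw shift calibration, 100 seeds ×
300-tree forests for the importance screen's ranking behaviour, n = 500
for noisy path recovery (coefficient SEs ≈ 0.02–0.03 against a ±0.1 band).
Exhaustive permutation oracles run at N = 4 (Mantel, 24 orders) and N = 6
(PerMANOVA, 720 orders). NMDS uses tol 1e−6, max 300 iterations, 20
restarts. Ties in isotonic regression share a disparity block; permutation
counts default to 999.
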