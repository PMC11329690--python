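# Methods

This note documents the models and procedures implemented in `dietshift`,
the defaults they ship with, and the choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Footprint accounting

A person's daily impact in category c is the intake-weighted sum of
per-gram characterization factors, `impact_c(i) = Σ_f intake(i,f)·g_c(f)`.
Factor tables are stored per gram (LCA sources usually print per kg; the
reader converts at load and flags it in table metadata). GWP is reported
in kg CO₂-eq/day and land use in m²/day; the two eutrophication
categories are converted kg → g/day, the natural magnitude for a single
diet. Impacts are computed on raw intakes; energy adjustment applies only
to the analysis variables downstream, so footprint reports describe what
people actually ate. Report tables use survey-weighted means throughout
(an unweighted option exists for debugging).

Food-group contribution tables decompose each cluster's weighted mean
total exactly (the decomposition is an identity of the linear model, and
is enforced in tests to 1e-9 relative).

## Country adaptation of impact factors

LCI databases describe production in one country. The adaptation module
transfers them with two rules applied to the *characterized* impacts, not
to unit processes (the package has no process-level LCI database; the
contract preserves the decision logic of who gets which electricity mix):

* electricity substitution: `adapted = base − share·I_source + share·I_target`,
  where `share` is the food's electricity fraction of life-cycle impact
  and the target intensity is the European mix for imported foods and the
  domestic mix otherwise;
* feed substitution: a per-impact multiplicative factor for livestock foods.

Origin is classified from annual trade masses: imported iff
import/export > 1, with 0/0 defined as 0 (domestic) and x/0, x > 0 as +∞
(imported). The boundary ratio of exactly 1 is domestic, because imported
status requires the ratio to *exceed* 1. Adapted factors that would go
negative are physically impossible and are clipped at 0 with a warning.
Default intensities and shares are placeholders the user must override
with values for their own database.

## Diet quality (mBSDS)

The modified Baltic Sea Diet Score has eight components and range 0–22.
The implemented allocation is 7 quartile-scored components × 0–3 points
plus a 0/1 alcohol component; positive components score 0/1/2/3 upward
through the sex-specific quartiles (right-closed bins, ties to the lower
bin), red & processed meat scores reversed, and the alcohol point is
awarded when ethanol intake does not exceed 10 g/day (women) / 20 g/day
(men). Quartiles are computed on the survey-weighted distribution by
default, consistent with weighting elsewhere; externally supplied cut
points take precedence and are required when a component is constant in a
stratum (internal quartiles undefined). The 7×3+1 allocation is a
reconstruction consistent with the published component list and score
range; analysts wanting exact fidelity to the original score definition
should supply its cut points via `BsdsConfig.external_cutpoints`.

## Energy adjustment and standardization

The residual method regresses each variable on total energy by weighted
least squares and re-centers the residual at the value predicted at the
weighted mean energy: `x_adj = x − b(e − ē_w)`. The re-centering constant
is the conventional choice — it keeps original units and typical
non-negative values, and preserves the weighted mean exactly. The
adjusted variable has exactly zero weighted covariance with energy (a
machine-precision test). Survey weights enter every moment (the source
analyses apply non-response weights without stating exactly where; using
them consistently in all moment estimates is the coherent reading).
Standardization divides by the weighted *population* SD (denominator Σw,
not Σw−1); centering is left to the factor analysis. Total energy itself
is excluded from the adjusted active set (its own residual is a constant)
and instead projected as a supplementary variable.

## Weighted MFA

Multiple factor analysis is implemented from its definition: (1) for each
active group, the first eigenvalue λ₁ of the weighted PCA of the
(weighted-)centered group block; (2) columns divided by √λ₁; (3) weighted
PCA of the concatenation, with row weights as masses. This caps each
group's contribution to any axis at 1 and makes the first global
eigenvalue at most the number of groups (both asserted in tests). The
active groups are the energy-adjusted nutrients and the four
energy-adjusted impacts; food-group intakes, the mBSDS, energy,
protein-origin ratios, age/BMI/waist (quantitative) and sex, education,
income, municipality, smoking and physical activity (categorical) are
supplementary. Supplementary grouping is cosmetic — it does not affect
projection — so no grouping structure is imposed on them.

Quantitative projections are weighted correlations with dimension scores;
categorical projections are weighted barycenters with a v-test of the
barycenter against the origin using the dimension's eigenvalue as the
score variance. Eigendecomposition is exact (`numpy.linalg.eigh` on the
weighted covariance; the active matrix has ≤ ~50 columns, so no iterative
approximation is warranted). Eigenvector signs are arbitrary; each
dimension is oriented so its largest-|loading| variable loads positively,
which makes results identical across runs and platforms. Five dimensions
are retained by default (configurable); the retained count is a
conventional choice for this method family, and the downstream clustering
operates on the retained dimensions only.

## Clustering

Ward linkage is generalized to row masses: merging clusters A and B costs
`m_A m_B/(m_A+m_B)·‖c_A−c_B‖²` — exactly the weighted within-inertia
increase — with the Lance–Williams update
`D(A∪B,C) = [(m_A+m_C)D(A,C) + (m_B+m_C)D(B,C) − m_C D(A,B)]/(m_A+m_B+m_C)`.
Integer weights are therefore *exactly* equivalent to replicated
unit-weight rows (tested), and with unit weights the tree matches SciPy's
Ward linkage (heights up to the d²/2 convention). Ties break toward the
lowest merged index. The implementation holds the full dissimilarity
matrix and rescans it per merge (O(n³) in the worst case); at the
benchmark sizes used here (n = 1000) a tree builds in well under a
second, which is why no nearest-neighbor chain optimization was added.

The suggested cluster count maximizes the ratio of successive
between-inertia gains, gain(k)/gain(k+1), over the candidate range.
Structureless data also shows geometrically decaying gains, so the
"weak elbow" flag is relative: it is raised when the best ratio does not
exceed twice the median ratio across candidates. The suggestion is
advisory; the final k is the analyst's decision (interpretability counts),
and the pipeline accepts an explicit k.

Consolidation runs at most 10 weighted Lloyd iterations initialized at
the hierarchical cluster centroids — a consolidation, not a
re-clustering; a single deterministic initialization keeps the result
reproducible. The k-means objective is monotone from any start, so
consolidated within-inertia never exceeds the hierarchical cut's
(asserted). A cluster emptied by reassignment is re-seeded with the point
nearest its previous centroid, with a warning.

## Characterization

Quantitative v-test:
`v_k = (x̄_k − x̄)/√(s²/n_k · (N−n_k)/(N−1))` with s² the weighted
population variance; categorical v-test: the normal approximation of the
hypergeometric count deviation. Weights are normalized to mean 1 so the
effective n stays on the sample scale — a deliberate choice that keeps
|v| from being inflated or deflated by the weight scale (v is invariant
to rescaling all weights). The null calibration (≈5 % of |v| > 1.96 under
a global null) and a permutation cross-check are part of the test suite.

Post-hoc comparisons are Kruskal–Wallis (tie-corrected, via SciPy) with
Dunn's pairwise z tests computed from pooled ranks with the tie term
Σ(t³−t)/(12(N−1)), Bonferroni-adjusted by default (none/Holm available).
Rank tests run unweighted on raw values: rank statistics with survey
weights are ill-defined, and this is a documented limitation rather than
an approximation. Levene (mean-centered) and per-cluster Shapiro–Wilk are
diagnostics only — they document the heteroscedasticity and non-normality
that justify the non-parametric path. Categorical variables get an
omnibus chi-square and, when significant, Marascuilo-style pairwise
comparisons of the maximum proportion difference against
`√(χ²_{1−α/m, C−1})·√(p̂_i(1−p̂_i)/n_i + p̂_j(1−p̂_j)/n_j)` with m the
number of cluster pairs; C−1 degrees of freedom is used because the
comparison is over the C category proportions of a pair.

## Transition scenarios

Percentage change is `100(x̄_k − x̄)/x̄`, computed on energy-adjusted
impact means so it reflects dietary composition only. National annual
deltas are daily per-capita deltas × adult population × 365 (no leap
handling), with unit conversion to t or Mt; the adult population size is
a config parameter (default 4.3 million). Per-capita food changes are
(cluster − sample) g/day × 365/1000 per food group.

## Synthetic population

The generator emulates the statistical shape of FFQ survey data joined to
LCA factors; its defaults are the study conditions of the test suite.

* **Dimensionality**: 81 ingredient-level foods in 25 groups, 46 nutrient
  variables, 4 impact categories — matching the scale of national FFQ
  data linked to LCA databases.
* **Clusters**: five planted patterns with shares 16/38/18/24/4 %
  (plant-forward, average, high-fish "compromise", meat-leaning, heavy
  animal-source), expressed as log-scale shifts of food-group intake
  locations. Each cluster's expected energy is re-centered by a uniform
  log-offset to a mild level (0.98–1.25 × baseline): real diet patterns
  differ mainly in composition, and this keeps the planted signal from
  being removed by the energy adjustment. Every cluster pair differs by
  ≥ 3σ in log-intake on at least 5 foods (asserted in tests), with the
  separation placed on nutrient-salient groups (meats, fish, dairy,
  legumes, grains) so it survives the composition mapping into nutrient
  space — separation planted only on nutrient-poor foods would be
  invisible to the analysis by construction.
* **Intakes**: log-normal with σ = 0.30 per food, a per-person N(0, 0.2²)
  log-scale factor (energy–total-intake correlation) and a +0.12 male
  intake shift.
* **Nutrients**: `intakes @ composition` with 5 % multiplicative noise;
  the composition matrix uses per-group archetypes (protein in
  meat/fish/dairy/legumes, fiber and vitamin C in plants, n−3 fats in
  fish, ethanol only in alcoholic beverages, …) with fixed per-food
  jitter. Energy is exactly Σ intake × energy density (no noise), and
  total protein is exactly plant + animal protein after noise.
* **Impact factors**: uniform within per-group ranges whose orderings
  encode the qualitative structure (ruminant meat and dairy dominate
  GWP/land/marine eutrophication; farmed fish dominates freshwater
  eutrophication). Range magnitudes are calibrated analytically so the
  expected survey-weighted population means land at present-day Nordic
  adult-diet scales (6.23 kg CO₂-eq, 5.58 m², 5.84 g N-eq, 2.42 g P-eq
  per person-day); the calibration accounts for the log-normal variance
  inflation, the male intake shift and the weight–sex/age covariance.
* **Sociodemographics and weights**: per-cluster age/sex/education/
  income/lifestyle distributions loosely mirroring published cluster
  portraits (the compromise cluster older, more female, more educated;
  the heaviest cluster younger and predominantly male). Survey weights
  are inverse response propensities (logistic in age and sex; younger
  men respond least), normalized to mean 1 so weighted and unweighted n
  coincide.

What the generator does **not** emulate: real food-composition values,
portion-size conversion from FFQ frequencies, correlated measurement
error between foods, item non-response, or any spatial/temporal
structure. Passing tests therefore demonstrate that the statistical
machinery is correct and that recoverable structure is recovered — not
that any particular real population clusters this way.

## Problem sizes and numerical conventions

The recovery benchmark runs at n = 1000 persons × 5 seeds and the null
calibrations at 1000 variables × n = 500 (v-test) and 2000 replicates
(Levene) — sizes chosen so the whole suite completes in well under a
minute while keeping Monte-Carlo error small relative to the tolerances.
Accounting identities (contribution decomposition, inertia decomposition,
eigenvalue sum) are asserted at 1e-9 relative; orthogonality of adjusted
variables at 1e-8; hand oracles at 1e-9 absolute. Degenerate inputs are
errors, not silent results: zero-variance energy, constant score
components, constant active groups, single-cluster v-tests, all-tied
rank tests (reported as p = 1), empty report tables.

## Known limitations

* The LCI adaptation operates on characterized impacts, not unit
  processes; process-level substitution effects (e.g. electricity within
  feed within livestock) collapse into the additive share term.
* Post-hoc rank tests ignore survey weights (see above).
* The mBSDS point allocation is a reconstruction (see above).
* The elbow suggestion is a heuristic; on realistically diffuse data it
  can prefer a coarser cut than the planted k, which is why the final k
  is an explicit analyst decision.
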