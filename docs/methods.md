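# Methods

`redoxsar` models how the structure of an organic micropollutant decides
whether heterogeneous photocatalysis degrades it oxidatively (hydroxyl
radical, HO•) or reductively (superoxide, O₂•⁻). It covers the whole
chain from scavenger kinetics to a validated descriptor regression:
K-coefficient estimation, descriptor computation, GA-MLR subset
selection, internal/external validation, and the applicability domain.

## The K coefficient

Each compound is run under four conditions: no scavenger, +DMSO (quenches
HO• at k₁ = 6.6×10⁹ M⁻¹s⁻¹), +BQ (quenches O₂•⁻ at k₂ = 5.88×10¹⁰
M⁻¹s⁻¹), and both. With a 200-fold scavenger excess (10 mM vs 0.05 mM
substrate), the quenched pathway is treated as fully off. A trace covers
a dark adsorption period (negative times) and 20 min of irradiation;
extents are adsorption-corrected by referencing the pre-adsorption
concentration:

- adsorbed fraction `X_ads = (C_dark − C(0)) / C_dark`, clipped to [0, 1];
- bulk extent `X = (C(0) − C_end) / C_dark`, `C_end` the last sample at
  t ≤ 20 min.

The pathway split uses the **complement estimator** by default: the
extent measured under the *other* scavenger is the pathway's share
(M_HO = X_BQ, M_O₂ = X_DMSO). A **difference estimator**
(M_HO = X_none − X_DMSO, negatives clipped) is available for sensitivity
analysis; the two agree exactly when X_none = X_DMSO + X_BQ. Then
K = M_HO / M_O₂; a vanishing M_O₂ is reported as an
infinite-preference flag rather than a number.

## Response transformation

K spans more than two decades across the dataset (max/min ≈ 158), so
models are fitted to t = (K + 1)^(−1/2), a strictly decreasing bijection
of [0, ∞) onto (0, 1]. Any in-range prediction back-transforms to
K = t⁻² − 1 ≥ 0, so negative rate ratios are impossible by construction.
The functional form was fixed by checking which reading of the
(typographically ambiguous) printed transformation reproduces the
tabulated value pairs; (K+1)^(−1/2) reproduces all 30 within the
double-rounding bound below, 1/(K+1) does not.

Both the K column and the transformed column of the bundled table are
printed at 3 decimals. Since |dt/dK| ≤ 0.5 on K ≥ 0, a correct transform
of the printed K can differ from the printed t by up to
0.5·5×10⁻⁴ + 5×10⁻⁴ = 7.5×10⁻⁴; the loader validates pairs at that
bound. Three rows (DCF, 2,6-DMP, IBP) in fact deviate by 5.1–5.5×10⁻⁴,
i.e. beyond 5×10⁻⁴ but within the double-rounding bound.

## Structures

The bundled table carries curated parent SMILES for each CAS number:
salts are stripped to the neutral organic (diclofenac sodium, the HCl
salts of donepezil, omeprazole and vilazodone) because the descriptors
concern the organic moiety and multi-fragment graphs have no defined
topological distances. Tautomer/protonation-state enumeration is out of
scope. 2D descriptors use graphs; conformers replace the original
study's DFT-optimized geometries with seeded ETKDGv3 distance-geometry
embeddings refined by MMFF94 (UFF fallback), reproducible bit-for-bit
from the seed.

## Descriptors

Four families are implemented from their definitions:

- **MATS (Moran autocorrelation)** at lag k with atomic-property weights
  w: `MATS_k = [Δ_k⁻¹ Σ_{d(i,j)=k} (w_i−w̄)(w_j−w̄)] / [A⁻¹ Σ_i (w_i−w̄)²]`,
  Δ_k counting ordered pairs at topological distance k. Weights are
  carbon-scaled atomic mass, van der Waals volume, Sanderson
  electronegativity or polarizability; MATS is invariant to affine
  rescaling of the weights, so the scaling convention is immaterial.
  Empty lags and zero-variance weights return 0 to keep matrices dense.
  The autocorrelation runs over the **hydrogen-complete** graph by
  default. This choice (and the intersection-corrected atomic-volume
  table, e.g. H 6.709 ų, C 22.449 ų, O 11.494 ų) follows the
  conventions of the reference descriptor calculators; on this dataset
  the H-depleted alternative also flips the sign of the leading MATS4v
  coefficient of the five-variable model and roughly halves its
  explained variance, so the convention is not cosmetic.
- **3D-MoRSE**: `Mor_t = Σ_{i<j} w_i w_j sin(s r_ij)/(s r_ij)` with
  s = t−1 Å⁻¹ (the s = 0 term is w_i w_j), over all atoms including
  hydrogens. Because a single embedded conformer makes Mor values
  noticeably conformation-dependent, the pipeline reports the **mean
  over a seeded 50-member conformer ensemble**; the ensemble average is
  this package's stand-in for the single optimized geometry of the
  original workflow and substantially reduces seed-to-seed variance of
  downstream fit statistics.
- **CATS2D** pharmacophore-pair counts at lags 0–9 over five point
  types. D: O/N bearing ≥ 1 H. A: any O, plus H-free N outside nitro
  groups. P: positively charged atoms (nitro excluded) or basic
  aliphatic amines (not amide, anilinic, or S/P-adjacent). N: negatively
  charged atoms (nitro excluded) or the central atom of an acidic group
  (carboxylic C, sulfonic S, phosphonic P) — typing the central atom
  puts the –COOH donor–negative pair at lag 1, matching the 1/0
  dichotomy this descriptor shows on the dataset. L: C/S with only
  C/S/halogen/H neighbors. Counts are raw (not occurrence-scaled); lag 0
  counts atoms carrying both types.
- **2D atom pairs B0k[X−Y]**: presence/absence of elements X and Y at
  exact topological distance k on the heavy-atom graph.

Surrogate columns (for externally computed quantum-chemical descriptors)
pass through unchanged. A configurable screening grid (456 columns:
MATS lags 1–8 × 4 weights, MoRSE 32 signals × {u, v}, CATS2D 15 pairs ×
10 lags, B0k over {C,N,O,S,Cl,F} × k = 1–10) generalizes the five
descriptors of the selected model. Weighting schemes *i* (ionization)
and *s* (E-state) are omitted; nothing in the final model needs them.

## Matrix pre-processing

Near-duplicate columns are removed by a greedy scan in column order
(constant columns first, then the later member of any pair with
|r| ≥ 0.99), with a removal log. Normalization is per-column min–max
fitted on training rows only (constant columns map to 0; test rows may
fall outside [0, 1]); it is a wrapper over scikit-learn's MinMaxScaler
and round-trips exactly. Normalization makes coefficient magnitudes
comparable but leaves R²/Q² of OLS unchanged.

## Model building

Subsets of 1–5 descriptors (rule of thumb: ≥ 5 training compounds per
variable) are searched by a fixed-cardinality genetic algorithm:
tournament selection (size 3), uniform crossover repaired to constant
cardinality, per-gene mutation (default 0.20), elitism, defaults of 200
chromosomes × 2000 generations, exhaustive enumeration when the subset
space is smaller than one population. Fitness is leave-one-out Q²
(default; more protective against chance correlation) or training R².
The QUIK collinearity rule (any pairwise |r| ≥ 0.6 discards the subset)
applies during the search; the significance screen (model F-test p_M and
every slope t-test p_T below 0.05) applies after fitting, and surviving
models are ranked by fitness with lexicographic tie-breaks for
determinism. OLS fits and their standard errors/p-values come from
statsmodels. Predictions back-transform to K; t > 1 predictions are
flagged and clamped to K = 0.

Because the published coefficients are printed with n = 30 while the
model was selected on the 25-compound training set, the package exposes
both: `stepwise_build`/`GAMLRSelector` fit on training rows, and the
replication path refits the five fixed descriptors on all 30.

## Validation and applicability domain

- **Q²_LOO** via the leverage shortcut (deleted residual e_i/(1−h_ii)),
  with an explicit-refit fallback for exact-fit points;
  PRESS, S_PRESS = √(PRESS/(n−m−1)), S_DEP = √(PRESS/n).
- **Leave-many-out**: default 30% left out × 1000 iterations (the
  technique's parameters are a package choice; the source methodology
  does not fix them), scored against the retained-rows mean.
- **Y-scrambling**: default 300 permutations of the response with the
  subset fixed; under the null E[R²] ≈ m/(n−1), which the tests verify.
- **External validation**: R²_ext = 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)² on
  held-out rows.
- **Williams plot**: leverage h_ii = x_iᵀ(XᵀX)⁻¹x_i (training-fitted,
  intercept included) against standardized residuals e_i/s, with
  h* = 3(m+1)/n (n = training-set size even when test rows are
  projected) and ±3.0σ response-outlier limits, σ taken as the residual
  standard error s of the training fit (the customary reading where σ is
  otherwise undefined).

## Synthetic data

`gen_kinetics` emulates the scavenger experiment on the experimental
sampling grid (−20, −10, 0, 2.5, 5, 10, 15, 20 min): the dark period
removes an adsorbed fraction, the unscavenged arm decays first-order
with k_HO + k_O₂, the dual-scavenger arm is flat, and each
single-scavenger arm shows its pathway's branching share
k_j/(k_HO + k_O₂) of the unscavenged decay. This branching-share masking
makes X_none = X_DMSO + X_BQ hold exactly and the complement estimator
recover K = k_HO/k_O₂ at zero noise, which is what makes the generator a
usable oracle; a literal first-order mode (each arm decays with its
remaining rate constant) and a partial-suppression factor are kept as
configuration hooks. Noise is multiplicative Gaussian (default sd 0.02,
the scale of HPLC run-to-run variability) clipped at zero
concentration.

`gen_qsar` plants a sparse linear response in a matrix of equicorrelated
Gaussian columns min–max scaled to [0, 1] (like a normalized descriptor
matrix, and preserving correlations) plus Bernoulli 0/1 columns
mimicking atom-pair/CATS counts. Defaults mirror the modeling setting:
n = 30, p = 20, ≤ 5 active descriptors with coefficients of a few
tenths, intercept 0.55, response noise sd 0.05 (the scale of the fitted
model's residual error). The response stays in (0, 1] by construction;
clipping exists only as a noise guard and is counted in the returned
truth. What the generators do **not** emulate: real descriptor
distributions and their mutual correlations, surface chemistry
(adsorption isotherms, direct hole/electron oxidation), or partial
scavenging kinetics — so passing recovery tests demonstrate correctness
of the estimators, not field performance on real systems.

## Numerical choices and limitations

- Conformer ensembles: 50 members by default; the ensemble seed is
  recorded and reproduces coordinates exactly. The user seed maps to a
  strictly positive internal embedding seed because the embedding
  library derives per-conformer seeds multiplicatively (a zero base
  seed would silently collapse the ensemble onto one geometry).
- GA determinism: a single numpy Generator drives the whole search;
  equal-fitness subsets rank lexicographically.
- Degenerate inputs: zero-variance responses are rejected as degenerate
  fits; rank-deficient designs raise; h_ii = 1 points use explicit
  refits; infinite K (M_O₂ = 0) is a flag, not a number.
- The replication of the published five-variable model is approximate by
  construction: the original descriptors came from a commercial
  calculator on DFT geometries, and neither those geometries nor the
  exact calculator conventions are available. With the conventions
  above, the refitted model reproduces the published R²/Q² to within a
  few hundredths with all five coefficient signs matching; exact
  equality is not claimed.
- Quantum-chemical descriptors (E_HOMO, E_LUMO, dipole, ...) are not
  computed; surrogate columns can stand in for them in grid runs.
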