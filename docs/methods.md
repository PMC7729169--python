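# Methods

## Media and ion profiles

Media are defined as salt lists in mg/L. The packaged table holds the nine
MS-based formulations of the nutrition experiment: full MS, a macronutrient
dilution arm (1/2MSM, 1/4MSM, 1/8MSM, 0MSM scaling KNO₃, NH₄NO₃,
CaCl₂·2H₂O, MgSO₄·7H₂O, KH₂PO₄) and a micronutrient arm (1/2MSμ … 0MSμ
scaling MnSO₄·4H₂O, ZnSO₄·7H₂O, H₃BO₃, KI, Na₂MoO₄·2H₂O, CuSO₄·5H₂O,
CoCl₂·6H₂O). The iron source (Na₂EDTA + FeSO₄·7H₂O) is constant everywhere.
Ion concentrations are mg/L ÷ g/mol = mmol/L, summed over salts with their
stoichiometry; no speciation, chelation or charge-balance chemistry is
attempted. Na₂EDTA uses the anhydrous molar mass 336.21 g/mol — this is the
convention that reproduces the reported Na⁺ ≈ 0.223 mM of full MS (the
dihydrate does not). Boron is reported as BO₃³⁻ (1:1 from H₃BO₃) and
phosphate as H₂PO₄⁻ (1:1 from KH₂PO₄). Concentrations are carried in mM
internally; micronutrient-derived ions are displayed in μM.

The packaged media table stores the *printed* values of the published
formulation table, which are rounded (e.g. 1650/8 = 206.25 prints as 206.3).
Exact dilution arithmetic regenerates every printed cell after half-up
rounding at the cell's printed precision, and the pipeline's ion profiles
are computed from the printed values — this is what reproduces the reported
anchors (NH₄⁺ of 1/2MSM = 10.31 mM, Cu²⁺ of 1/2MSμ = 0.05 μM) to the digit.

Across the nine media 16 ions vary (K⁺, NO₃⁻, NH₄⁺, Ca²⁺, Cl⁻, Mg²⁺, SO₄²⁻,
H₂PO₄⁻, Mn²⁺, Zn²⁺, BO₃³⁻, I⁻, Na⁺, MoO₄²⁻, Cu²⁺, Co²⁺); Fe²⁺ and EDTA are
constant and excluded. All 16 are offered to the learner together with
genotype and subculture (both categorical), 18 candidate inputs in total.

## Classical statistics

Factorial ANOVA uses fixed effects with Type I sums of squares; the design
is balanced, so Type I equals Type III. On replicate-level data the full
genotype × medium × subculture model is fitted; on treatment means the full
crossing is saturated, so the model falls back to two-way interactions and
the three-way term becomes the residual. Count responses (PN, LN) are
analysed by ANOVA like the continuous ones — with ~20 replicates the
inference matches Poisson regression, and this keeps the pipeline uniform.
Tukey HSD pairwise comparisons (α = 0.01 by default) are summarized as a
compact letter display built by insert-and-absorb: starting from one letter
covering all groups, each significant pair splits the sets containing both
members and contained sets are absorbed, so two groups share a letter iff
they were never judged different. Normality is checked by a
Kolmogorov–Smirnov test of standardized within-group residuals against
N(0, 1) (KS as named, not Lilliefors-corrected), homoscedasticity by
Levene's test across groups.

## The neurofuzzy learner

Continuous inputs are affinely mapped to [0, 1] over their observed range;
constant columns are dropped. Each submodel is a tensor product of per-input
bases: order-2 B-splines on a clamped knot vector for continuous inputs
(triangular fuzzy sets, partition of unity) and one-hot indicators for
categorical inputs. Order 2 is fixed — it is what makes the bases read out
as Low/Mid/High fuzzy sets; "set density 2" is interpreted as the initial
two-set partition (knots at 0 and 1).

The structure search starts from the bias-only model and repeatedly
evaluates four move families: add a univariate submodel on an unused input;
merge two submodels into a tensor product (≤ 3 inputs); insert a knot at the
midpoint of the widest inter-knot interval of a continuous input (ties to
the lower interval, ≤ 15 knots per input); prune by deleting a submodel,
splitting a tensor submodel into its univariate marginals, or removing an
interior knot. Every candidate is ridge-fitted (λ = 10⁻⁶ on all
coefficients) and scored; the best strictly-improving candidate is accepted
(ties broken by score, then fewest parameters, then enumeration order, which
follows the candidate-input order); the search stops at the first iteration
with no improvement. Final submodels are ordered by drop-one criterion
contribution. Only CV fold assignment is stochastic; with SRM/MDL/BIC the
whole fit is deterministic, and per-output seeds are derived from the shared
seed and the output name so results do not depend on output order.

Parameter counting: p = Σ(basis sizes) + 2 − (number of submodels) — one
global bias plus all basis coefficients, with one constant-function
redundancy absorbed per submodel after the first (every spline basis spans
the constant). This bookkeeping reproduces the published df pairs, e.g. a
3×2 tensor plus a 2-set submodel gives p = 8 → df (7, 100) at n = 108, and a
single 3×2 tensor gives p = 7 → (6, 101). df₁ = p − 1, df₂ = n − p; the
f-ratio is computed from the unrounded R².

Criteria: SRM uses the guaranteed-risk form score = MSE / max(1 − √ε, 10⁻⁶)
with ε = C₁·[p(ln(2n/p) + 1) + C₂]/n and the published constants C₁ = 0.95,
C₂ = 4.8; the score is +∞ once the capacity term reaches 1, which is what
caps model size at n = 108. The exact SRM expression of the original
commercial implementation is unpublished; this Vapnik-style form is isolated
behind the criterion interface so alternatives are pluggable. MDL is
(n/2)·ln MSE + (p/2)·ln n, BIC n·ln MSE + p·ln n; CV is 5-fold held-out MSE
on folds stratified by genotype and fixed per search (so candidates are
compared on identical folds); LOOCV uses the closed-form ridge leave-one-out
residuals.

Quality gate per output: accepted iff train-set R² > 70% and the f-ratio
exceeds both 4 and the F critical value at α = 0.05; R² > 99.9% is rejected
as overfitting; an empty (bias-only) result is flagged uninformative.

## Rule extraction

Per submodel input, basis functions are labelled in knot order (2 sets →
Low/High; 3 → Low/Mid/High; more → Low/Mid1…/High); categorical inputs use
their level names. Each label combination is evaluated at its
characteristic point — the basis peaks, where the tensor activation is a
unit vector, so the value is simply the corresponding weight — plus the
model bias and the training-mean contribution of the other submodels. This
context value v is normalized against the model's fitted-value range to
m = (v − v_min)/(v_max − v_min), clipped to [0, 1]; the rule's consequent is
High with membership m when m ≥ 0.5 (ties to High, an arbitrary documented
choice), else Low with membership 1 − m, so the two memberships of any
combination sum to one. Normalizing against the whole model's fitted range
(rather than per submodel) makes dominant submodels saturate at 1.00 while
secondary submodels get sub-unit memberships, the pattern seen in practice.
A degenerate fitted range yields memberships of 0.5 and a flat-submodel
flag. Low/Mid/High boundaries reported in original units are the triangular
supports implied by the fitted knots.

## Synthetic data generator

The generator emulates the study conditions: 3 genotypes (BD, BH, BT) × the
nine packaged media × 4 subcultures, 108 treatments, six responses, Gaussian
noise with SD equal to `noise_fraction` (default 0.10) of each output's
deterministic signal range; with zero signal (pure-noise outputs) the scale
falls back to 1.0 so null datasets remain non-degenerate. The default emits
treatment means — the published degrees of freedom are only consistent with
training on the 108 means — and can emit replicate rows instead
(20 replicates by default). Counts (PN, LN) are rounded to non-negative
integers rather than drawn from a Poisson, consistent with the
ANOVA-on-counts choice. PN is gated to zero on the two zero-nutrient media
(no macronutrients or no micronutrients → no plantlet formation).

Planted surfaces mirror the reported interaction structure and directions:
genotype × Cu²⁺ on SL (copper toxic for BT, mildly positive otherwise) plus
a secondary monotone NH₄⁺ term; genotype × SO₄²⁻ × MoO₄²⁻ on RL, PN and AFW
(sulfate promotes growth in the macro arm, molybdate modulates it in the
micro arm with a BT mid-peak); subculture × Na⁺ on RL and PN (high Na⁺ high
response in every subculture); genotype × NH₄⁺ on LN (only BT profits);
genotype × Cu²⁺ × SO₄²⁻ plus monotone-negative MoO₄²⁻ on RFW. A crucial
design constraint is that each surface expresses its variance *on the actual
design support*: sulfate only falls in the macronutrient arm (where
molybdate stays at full strength), so a surface keyed to "low sulfate with
mid molybdate" would be invisible to any learner — the shipped surfaces put
genotype-dependent variation into each arm separately, with non-canceling
marginals so the stepwise search can reach the tensor terms. Amplitudes and
baselines are fixed once at the scale of the real measurements (SL ≈ 0–6 cm,
PN counts ≈ 0–25, RFW ≈ 0–0.1 g).

What the generator does **not** emulate: replicate-level heteroscedasticity,
epigenetic drift across subcultures, any mechanistic growth physiology, and
the unpublished empirical means of the original supplementary data. Passing
recovery tests therefore shows that the pipeline identifies planted
low-order interaction structure under design confounding and realistic
noise — not that it reproduces the original fitted surfaces.

## Recovery metrics and ion confounding

The dilution design scales whole salt groups jointly, so ion columns within
an arm are exactly or nearly collinear (H₂PO₄⁻ ∝ NH₄⁺; I⁻ ≈ Cu²⁺;
Na⁺ ≈ MoO₄²⁻ via the molybdate sodium). The planted ion is consequently not
identifiable from its proxies, and the recovery report counts a selected
input as recovering a planted input when their design columns correlate
with |r| ≥ 0.95 (factors require exact matches). Direction agreement
evaluates the trained model's partial dependence (input at its extremes,
other continuous inputs mid-range, averaged over factor levels), through the
proxy's correlation sign where a proxy was selected.

## Numerical choices and problem sizes

Ridge systems are solved by Cholesky on the (small) normal equations;
strict-improvement uses a relative tolerance of 10⁻¹² to avoid float-noise
loops. The test suite exercises the full pipeline at the study size
(n = 108, 18 candidate inputs, ~0.3 s per six-output training), the null
calibration at 50 seeds × 6 outputs, and signal-to-noise monotonicity at 8
seeds × 3 noise levels; the search-vs-enumeration equivalence check runs on
two-input instances at n = 30 with a 3-node cap, where the reachable
structure set (13 structures) is exhaustively enumerable and the SRM
capacity term still binds (at n = 8 every structure is infeasible under SRM,
and data-driven criteria degenerate to ridge interpolators there).

## Known limitations

- The SRM functional form and the membership normalization reconstruct
  unpublished proprietary behavior; both are validated behaviorally
  (capacity control, complementarity, saturation, direction fidelity), not
  against the original software's numeric output.
- The greedy search is not globally optimal in general; optimality is only
  asserted (and tested) on small enumerable instances.
- Rules are emitted per submodel, not for joint antecedents across
  submodels, and no rule simplification/merging is attempted.
- Spline order is fixed at 2; no order-adaptation moves.
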