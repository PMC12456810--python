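# Methods

## Markers

**Cycle entropy (static marker).** EMA prompts are partitioned by study day
into consecutive, non-overlapping 3-day blocks ("cycles") of
`cycle_length_days × prompts_per_day = 9` scheduled prompts; a trailing
partial block is discarded, so a 30-day protocol yields at most 10 cycles.
Within a cycle, every activity checked at an answered prompt contributes
one token; each missing prompt contributes one token to a single pooled
missing category. The tokens form a categorical distribution whose Shannon
entropy H (base 2, bits) is the cycle's static marker. A cycle is *valid*
when at most 2 of its 9 prompts are missing; H and the cycle symptom score
SC (arithmetic mean of the per-prompt five-item sums over answered prompts,
range 5–35) are computed only for valid cycles.

Base-2 logarithms are used throughout: the two-element worked example
(probabilities 5/9 and 4/9, H ≈ 0.991 "on a maximum possibility of 1") is
satisfied only in base 2.

With multi-select prompts the distribution's denominator is the *token*
count, not the prompt count, so probabilities always sum to 1; the
single-select case reduces to the familiar divide-by-9. A `prompts`
denominator mode (divide by prompt count, then renormalize) is available
for sensitivity analyses, since the original single-select worked example
does not disambiguate the two.

**State classification.** For each pair of consecutive valid cycles, the
direction of change of H and of SC — up (Δ > tol), down (Δ < −tol), flat
otherwise — is combined into one of nine states ordered UU, UF, UD, FU,
FF, FD, DU, DF, DD. The flat tolerances default to 1e-9: only (numerically)
exact ties count as flat. This is the least-assumptive reading of a
three-way up/flat/down split; wider flat bands are a config knob
(`flat_tol_H`, `flat_tol_SC`) for sensitivity analyses. The tiny nonzero
default absorbs float summation-order noise so that distributions with
identical probability multisets compare as ties.

Deltas are taken between consecutive *valid* cycles, skipping invalid ones
(`delta_gap_mode="skip"`), because inclusion requires only ≥ 3 cycles with
available data, not contiguity. A `strict` mode that breaks the state
sequence at gaps is provided; it drops cross-gap transitions.

**Per-participant chains.** Participants with ≥ 3 valid cycles (≥ 2
observable states) enter the dynamic analyses; the rest are reported in an
exclusions table. Observed state transitions are counted in a 9×9 matrix;
0.1 is added to every *count* cell before row normalization. Adding the
pseudocount before normalizing is the only order in which "attribute a
small probability (0.1) to all transitions, then normalize" leaves rows
summing to exactly 1. The smoothed matrix is strictly positive, hence
irreducible, so all expected hit times are finite.

**Hit times.** The expected first-hit time h(i → j) solves the linear
system h(i) = 1 + Σ_{k≠j} P(i,k) h(k) with h(j) = 0 (dense
`numpy.linalg.solve`; the system is nonsingular for strictly positive P).
MEHT(j) averages h(i → j) over all nine start states *including* the zero
self-hit term; `include_self_hit=False` excludes it. Self-hit is first-hit
(0), not expected return time. The matrix entropy MH sums the base-2
Shannon entropies of the nine rows (range 0 to 9·log₂9 ≈ 28.53).

**Group chains and random walk.** Group-level chains pool participants'
raw counts before smoothing (`aggregation="pool_counts"`), weighting
participants by their observed transitions and keeping the smoothing
semantics identical at both levels; averaging participants' smoothed
matrices is available as `average_P`. The random walk starts at state 1
(UU) and at each of the 100,000 steps draws u ~ U[0,1] and selects the
first state whose cumulative row probability is ≥ u (intervals closed on
the right, matching the printed example where u = 0.56 against cumulative
sums (0.2, 0.6, 1.0) selects state 2). Occupancy is the visit fraction
over the drawn states; for an irreducible chain it converges to the
stationary distribution (leading left eigenvector), which the tests use as
the analytic oracle.

## Statistical contracts

* **Within/between H–SC association.** SC (cycle level) is regressed on
  the participant's mean H (between-person) and the cycle's deviation from
  it (within-person) in a gamma log-link mixed model with a participant
  random intercept, estimated by maximum likelihood with Laplace
  approximation; a random slope of centered H is retained when the
  likelihood-ratio test favors it at p < .05. Estimation is delegated to
  lme4 (glmmTMB as fallback) through `Rscript`; the package owns the data
  preparation, the contract, the LRT decision rule, and reporting
  (mean ratios with Wald 95% CIs).
* **Marker–symptom associations.** Each interviewer-rated outcome
  (positive symptoms, reduced emotional experience, reduced emotional
  expression) is regressed on each of the 11 markers (mean H, MH, nine
  MEHTs) in separate gamma log-link GLMs — 33 models — adjusted for site,
  age, gender, ethnoracial group, educational attainment, and mean
  self-reported symptoms. BH-FDR is applied across the whole 33-model
  family. (A published description of this design counts "18 models per
  outcome"; the enumerated markers total 11 per outcome, and this package
  fits exactly those.)
* **Group differences.** Each marker is regressed on group in linear
  models: one model per marker with control as reference (yielding the
  bipolar-vs-control and schizophrenia-vs-control contrasts) and one on
  the clinical groups with bipolar as reference. FDR is applied within each
  contrast's marker family. Significance is p < .05 with the 95% CI
  excluding the null.
* **Attrition.** Included vs excluded participants are compared with
  Cramér's V (categorical) and |Spearman ρ| (continuous) against the
  inclusion indicator; values ≥ 0.10 are flagged. Constant variables are
  reported as undefined rather than zero.

BH adjustment is order-invariant, rank-preserving and dominating
(adjusted ≥ raw); it is *not* idempotent as an operator on p-value vectors
(re-adjusting already-adjusted values inflates them further), so the tests
assert the former properties.

## Synthetic cohort generator

The generator emulates the study protocol: 3 prompts/day × 30 days, the
39-activity catalog with 1–3 activities per answered prompt
(`multi_select_probs`, default (0.8, 0.15, 0.05) — the real frequency of
multi-checking is unreported, so it is a parameter rather than a constant),
five symptom items in 1..7 summing to 5–35, independent Bernoulli
per-prompt missingness (default rate 0.10, a typical adherence loss for
monthlong EMA protocols; a block mode drops whole days to mimic attrition
runs), and study-sized default groups of 45 controls / 192 bipolar / 153
schizophrenia.

Each participant's latent trajectory is a Markov chain over the nine states
drawn from the group's true matrix (initialized from its stationary
distribution). Realization is constructive: a per-participant **entropy
ladder** (compositions of the cycle's token total into activity piles,
deduplicated and sorted by entropy with ≥ 1e-6-bit gaps, piles capped at 9
so tokens can always be dealt to distinct prompts) and an integer ladder of
cycle symptom totals. An up label moves one rung up the respective ladder,
down one rung down, and flat reuses the previous cycle's realized multiset
exactly (contents permuted among equal-capacity prompts). Consequently, at
zero missingness the realized (ΔH, ΔSC) signs equal the latent labels
essentially always, and the latent trajectory is returned as ground truth
for recovery tests. If a trajectory demands a move past a ladder end
(e.g., an absorbing all-up chain over a long study), generation fails
loudly, naming the participant and cycle.

What the generator does **not** emulate: circadian prompt timing within
the three daily windows, informative (symptom-coupled) missingness,
response-style artifacts, activity autocorrelation beyond the cycle level,
and interview-rated scores that genuinely depend on behavior (the bundled
interviewer-score generator is a null generator unless an effect is
injected). Passing tests therefore demonstrate correctness of the
*pipeline* under known dynamics, not clinical validity on real data.
Missingness interacts with exact-tie flats: a single missing prompt
perturbs both the activity distribution and the SC mean, so latent "flat"
states are frequently reclassified under missingness — ground-truth
recovery tests run at `missingness_rate=0`, the clean regime.

## Numerical choices and test scales

Probability vectors are validated to sum to 1 within 1e-6 (inputs) and
produced to 1e-12 (smoothing). Stationary distributions come from the
eigendecomposition of Pᵀ with the eigenvector nearest eigenvalue 1,
made nonnegative and normalized. Random-walk and path simulation use
`numpy.searchsorted` on cumulative rows, reproducing the closed-on-the-
right inverse-CDF convention exactly; all randomness flows from explicit
seeds (cohort generation spawns one child stream per participant from a
single `SeedSequence`, the model layer uses named substreams per stage).

Simulation sizes in the test suite are the package's own choices to keep
the suite fast while leaving comfortable statistical margins: ground-truth
recovery uses 120 participants × 60 days; Monte-Carlo hit-time checks use
50,000 walks (≤ 2% relative tolerance ≈ 4 standard errors); stationarity
uses 100,000 steps at total-variation 0.01; the null model family runs 200
replicates of the 33-model family with acceptance band 2–8% raw rejections
(±3 SE around the nominal 5% allowing for within-outcome dependence);
group discrimination uses 60 + 60 participants and compares estimated
contrast signs only where the analytic MEHT separation exceeds 5 steps.

## Limitations

Per-participant chains rest on at most 9 transitions for a 30-day study,
so individual matrices are dominated by the 0.1-per-cell smoothing
(8.1 pseudo-observations versus ≤ 9 real ones); MEHT and MH are
correspondingly shrunk toward their uniform-chain values, and group
contrasts are attenuated relative to the analytic values of the true
chains (the tests therefore check sign structure, not magnitudes). The
flat category is measure-zero under exact-tie tolerances unless ties are
constructed, as the generator does; real data will populate flats only
with wider tolerances. The gamma GLM p-values are asymptotic; at the test
sample sizes they are mildly anti-conservative, which the type-I
acceptance band accommodates.
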