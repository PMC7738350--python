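# Methods

## The simulated system

The package simulates a variable-length cognitive-diagnostic computerized
adaptive test (CD-CAT) operating with a *miscalibrated* item bank. Two banks
exist side by side in every simulated session:

- the **true bank**, which generates the item responses, and
- the **calibrated bank** — the true bank plus additive zero-mean Gaussian
  calibration error — which is all the adaptive engine ever sees: it drives
  item selection, the posterior update, the termination decision, and the
  reported precision/information.

Every divergence between what the engine believes and what is actually true
is therefore attributable to calibration error alone; no estimation from
finite response samples is performed (that is a deliberate non-goal — the
error is the manipulated variable, not an estimate's by-product).

## Item response models

All three models are parameterized over binary attribute profiles
α ∈ {0,1}^K and a J×K binary Q-matrix:

| model | item response function | free parameters per item |
|---|---|---|
| DINA | (1−s)^η g^(1−η), η = ∏_k α_k^{q_k} | s, g |
| RRUM | π\* ∏_k r\*_k^{(1−α_k)q_k} | π\*, one r\* per required attribute |
| CRUM | logistic(δ0 + Σ_k δ_k α_k q_k) | δ0, one δ_k per required attribute |

The 2^K latent classes are enumerated by binary counting with attribute 1 as
the least-significant bit; this ordering is fixed across the package so that
posterior vectors, MAP indices and class-probability tables are comparable
everywhere. The (2^K × J) class-probability table is the single
computational cache from which response generation, Bayes updates, the MPWKL
selection index and the CDI are all derived.

## The synthetic generator and its defaults

The generator's defaults are the study conditions; they are not tuned per
run.

- **Q-matrix**: 20 copies of the 5 single-attribute rows, 14 copies of all
  10 pairs, 6 copies of all 10 triples → 300 items, the only composition of
  those three blocks consistent with a 300-item bank. Deterministic.
- **True parameters**: uniform within quality-stratified ranges —
  DINA s, g ~ U(0.05, 0.25) high / U(0.25, 0.45) low / U(0.05, 0.45) mix;
  RRUM π\* ~ U(0.75, 0.95) and r\* ~ U(0.05, 0.40) high, π\* ~ U(0.55, 0.75)
  and r\* ~ U(0.15, 0.50) low, unions for mix; CRUM δ0 ~ U(−3, −1.1) with
  full-mastery success probability p⁺ ~ U(0.85, 1.0) high, δ0 ~ U(−1.1, −0.2)
  with p⁺ ~ U(0.6, 0.85) low, unions for mix.
- **CRUM main effects** are not drawn directly: the total
  Σ_k δ_k = logit(p⁺) − δ0 is split across the item's required attributes by
  symmetric-Dirichlet proportions (an equal split is available via
  `crum_split="equal"`). The random split avoids every multi-attribute item
  having artificially identical effects; with the default ranges the total is
  always positive, so all main effects are positive and mastery can only
  help.
- **Examinees**: i.i.d. Bernoulli(0.5) mastery per attribute (so the uniform
  prior over the 2^K classes used by the engine matches the generating
  distribution exactly). Default N = 2000 at full scale.
- **Calibration error**: independent N(0, sd) per free parameter,
  sd ∈ {0, 0.1, 0.2, 0.3}, applied on each parameter's native scale —
  probability scale for DINA s/g and RRUM π\*/r\*, logit scale for CRUM δ.
  Perturbed probability-scale parameters are clipped to [0.01, 0.99]
  (configurable); CRUM parameters are unbounded and never clipped. No
  monotonicity repair is applied afterwards — a perturbed DINA item may have
  1−s < g, exactly as a badly calibrated operational bank might.

What the generator does **not** emulate: real calibration error is neither
independent across an item's parameters nor homoscedastic across items
(estimation error grows where information is scarce), attribute masteries in
real populations are positively correlated, and real Q-matrices are not
balanced block designs. Passing tests therefore demonstrate the behavior of
the adaptive machinery under the stated stochastic conditions, not
performance guarantees for any operational program.

## The adaptive loop

- **Prior**: uniform over the 2^K classes.
- **Selection**: modified posterior-weighted Kullback–Leibler index,
  MPWKL_j = π'A_jπ with A_j[d,c] the KL divergence between item j's
  Bernoulli response distributions under classes d and c (natural log;
  selection is invariant to the base). The A_j matrices are precomputed once
  per bank — contractually identical to on-the-fly evaluation. The first
  item is chosen at the uniform prior; no randomness enters selection.
- **Ties** (selection and MAP classification) break to the lowest index, so
  sessions are fully deterministic given the seeds.
- **Termination** is checked after each update: stop at the first step where
  max_c π_c ≥ ε (ε ∈ {0.7, 0.8}), else at 30 items. The uniform prior
  (max 1/32) can never trigger termination, so every session administers at
  least one item.
- **Responses** are Bernoulli draws from the true bank, one uniform variate
  per (examinee, step). The vectorized lockstep runner consumes a
  pregenerated (N × 30) uniform matrix and is test-verified to reproduce the
  scalar reference loop session by session; because both thresholds reuse
  the same matrix, per-examinee lengths are exactly paired and
  length(ε=0.8) ≥ length(ε=0.7) holds path-wise.

## Metrics

PCR and AACR compare MAP profiles to the truth at pattern and attribute
level. ATL is the mean variable length. RMP divides the summed maximum
posterior the engine reported by the same quantity rescored under true
parameters on the identical items and responses (uniform prior both times);
the rescoring runs through the identical update code path so that a
perfectly calibrated bank yields RMP = 1 *exactly*, not merely to rounding.
RTE does the analogue for test information: each examinee's administered
items' CDI summed under calibrated vs true parameters (same items, different
parameters); identity banks again give exactly 1.

The CDI of an item is the weighted average over ordered latent-class pairs
(u, v), u ≠ v, of the item's KL divergence KL_j(u‖v), with weights
1/hamming(α_u, α_v) normalized by the total weight — near-indistinguishable
class pairs count most. The weighting is configurable (`uniform` as the
alternative); because RTE is a same-items ratio and the normalizer is
item-independent, switching the weighting moves the reported RTE by well
under 1% (verified in `analysis/04`-adjacent exploration), so the choice is
immaterial to every conclusion.

Aggregation is per replication first (each replication contributes one PCR,
one RTE, …), then mean and SD (ddof = 1) across replications — the SD
columns of the summary tables are between-replication SDs.

## Seeding and reproducibility

All randomness derives from `SeedSequence([master_seed, purpose, labels…])`
with integer codes for purpose (bank / error / examinees / responses), model,
quality, error SD and replication. Consequences, all test-enforced: reruns
are bit-identical; results are independent of execution order and of
parallelization; within a replication index the true bank is shared across
error levels and thresholds and the examinees and response variates are
shared across *all* cells, so comparisons across error SD and ε are paired
comparisons.

## Problem sizes

Full scale is 2000 examinees × 25 replications per cell. The analysis
drivers, the test suite and the acceptance script run at a reduced scale of
500 examinees × 10 replications (smoke checks smaller still), which leaves
between-replication SEs of the reported means at a few percent of the
full-scale values while keeping the complete 72-cell grid re-runnable in
minutes on one core. Full scale remains a keyword away
(`run_grid(n_examinees=2000, n_replications=25)`).

## Numerical choices

- Clip bound [0.01, 0.99] for perturbed probability parameters: symmetric,
  minimal intervention, keeps every likelihood and KL term finite. It is the
  single most consequential free choice in the pipeline — see below.
- KL computations clip probabilities at 1e−12 as a guard; with validated
  banks the guard is inactive.
- Posterior renormalization after every update (enforced to 1e−10 in tests).
- Degenerate inputs rejected rather than repaired: empty Q-rows, parameters
  on the boundary, repeated administration of an item.

## Sensitivity of the efficiency ratios, and a known reproduction limit

The large-error RTE values are dominated by items whose perturbed parameters
hit the clip bound: a clipped item claims a per-item KL on the order of
log(1/clip) while its true discrimination is unchanged, and MPWKL selection
actively seeks those items out (a winner's-curse dynamic — the same
mechanism that shortens the tests). `analysis/04_clip_sensitivity.py`
quantifies this: tightening the clip from 1e−2 to 1e−5 leaves small-error
cells essentially unchanged but scales the DINA low-quality sd = 0.3 cell
from ≈15 to ≈36.

Reference results for this design report grid values (e.g. DINA low-quality
sd = 0.3 near 45, RRUM low-quality sd = 0.3 near 10) whose *pattern* this
implementation reproduces — orderings across models, qualities and error
levels, CRUM's near-flatness, RMP > 1 throughout — but whose largest
magnitudes it does not, under any single clip bound: bounds that raise the
DINA cells toward their reference values push the RRUM cells past theirs.
We conclude the original magnitudes depend on an out-of-range-parameter
policy that is not identifiable from the reported results, keep the
conservative default, and treat large-error RTEs as order-of-magnitude
quantities. The acceptance suite deliberately leaves the affected
comparisons failing rather than calibrating the clip bound against the
reference numbers.

## Known limitations

- No item-exposure control and no content balancing: the deterministic
  argmax concentrates administration on few items, which is faithful to the
  studied design but unrealistic operationally.
- Only MPWKL selection and only the posterior-threshold stopping rule are
  implemented; alternative selectors (PWKL, Shannon-entropy, mutual
  information) and fixed-length designs are out of scope.
- The three models are special cases of general frameworks (G-DINA/LCDM);
  the general models, and parameter estimation from response data, are out
  of scope.
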