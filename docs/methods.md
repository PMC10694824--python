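# Methods

## Measurement model

One excitation pulse reaches m emitter species. Species j holds M_j ≥ 1
identical emitters, each contributing a detected photon with probability
p_j ∈ (0, 1]; all emitters are assumed to fire independently. The detected
photon number per pulse is Y = Σ_j Y_j with Y_j ~ Binomial(M_j, p_j), so

    pr(Y = y | θ) = Σ_{y ∈ Y_y} Π_j C(M_j, y_j) p_j^{y_j} (1 − p_j)^{M_j − y_j},

where Y_y is the set of capped compositions of y (all ways to split y into
per-species parts y_j ≤ M_j). The package computes this PMF by sequential
discrete convolution of the per-species binomial vectors; the explicit
partition-sum form is retained as a brute-force oracle and the two are held
to 1e-10 agreement in the tests. Data from ν repeated pulses enter only
through the count histogram [C₀, …, C_N], giving the log-likelihood
ℓ(θ) = Σ_i C_i log pr(Y = i | θ), evaluated in log space so that large
total emitter numbers cannot underflow.

Background noise (dark counts, stray light, detector artifacts) is outside
the model, as is any spatial variation of the detection probability within
a species: the emitters of a species are treated as exchangeable. Both
restrictions mirror the physical setting the estimator targets — emitters
confined well within the focal volume — and anything beyond it (noise
convolution, per-emitter p) is future work, not a hidden assumption.

## Closed-form moments

The mean and central moments 2–3 of Y are cumulant-additive across species:

    μ₁ = Σ M_j p_j,
    μ₂ = Σ M_j p_j (1 − p_j),
    μ₃ = Σ M_j p_j (1 − p_j)(1 − 2 p_j).

The 4th central moment is *not* additive; it is assembled from the additive
4th cumulants plus the variance cross term:

    μ₄ = Σ M_j p_j (1 − p_j)(1 − 6 p_j (1 − p_j)) + 3 μ₂².

(Summing per-species 4th central moments is a tempting but wrong shortcut —
the property test comparing these formulas against the moments of the
computed PMF is what guards it.) Inverting the map, the first four moments
determine the power sums b_k = Σ_j M_j p_j^k:

    b₁ = μ₁,   b₂ = μ₁ − μ₂,   b₃ = (2μ₁ − 3μ₂ + μ₃)/2,
    b₄ = (6μ₁ − 11μ₂ + 3μ₂² + 6μ₃ − μ₄)/6.

## EM estimator

The complete data of a pulse are the per-species counts (y₁, …, y_m); only
the sum is observed. Writing w_y for the conditional probability of a
composition given its total under the current iterate, the E-step needs,
for each observed total i and species j, the conditional distribution of
y_j given Y = i. This is computed without enumerating compositions:
P(y_j = y | Y = i) ∝ pr_j(y) · rest_j(i − y), where rest_j is the
convolution of all other species' PMFs. Enumeration is kept as the test
oracle; the two agree to 1e-10.

The M-step is exact per species:

* p_j ← (Σ_i C_i E[y_j | Y = i]) / (M_j ν)  (closed form),
* M_j ← argmax over the integer range [max(support requirement), M_max] of
  the expected complete-data log-likelihood at the new p_j, with ties broken
  toward the smaller M.

Each iteration cannot decrease ℓ; the tests assert the monotone trace on
every run. Convergence is declared when max_j |Δp_j| < tol_p (default 1e-9)
with no emitter-count change, or when |Δℓ| < tol_ll (default 1e-10);
exceeding max_iter (default 10⁴) reports converged=False rather than
raising. Inside iterations p is clamped to [1e-12, 1 − 1e-12] to keep
logarithms finite.

Plain EM from an arbitrary start is unreliable here in an instructive way:
for one species the coordinate updates preserve M·p ≈ sample mean, so every
(M, mean/M) pair is a fixed point of the alternating scheme. The likelihood
ridge along constant M·p is exactly why the estimator searches over integer
combinations instead of trusting a single EM run.

## Moment-seeded combination search

Emitter counts are bounded integers, so all strictly increasing
m-combinations from {1, …, M_max} are enumerable (M_max defaults to
max(20, N)). For each combination the moment system Σ_j M_j p_jᵏ = b̂_k
(k = 1..m, b̂ from the sample moments) is solved for the detection
probabilities:

* m = 1: p = b̂₁/M.
* m = 2: elimination reduces the system to one quadratic; roots with
  |imaginary part| < 1e-8 are accepted as real.
* m ≥ 3: damped multi-start Newton iteration on the power-sum residual,
  48 fixed uniform starts per combination (one seeded generator, constant
  seed, so the search is reproducible independent of user RNG), steps
  clipped to ±0.25, 60 iterations, solutions kept when the residual is
  below 1e-9, de-duplicated at 1e-6.

Solutions with any component outside (0, 1] are discarded; a combination
with no admissible solution is skipped (as is any combination whose total
emitter count cannot cover the observed support — its likelihood is zero).
Every surviving seed is refined by fixed-M EM and the largest final
log-likelihood wins; ties break to the lexicographically smallest
combination, then the smallest seed, making the winner independent of
evaluation order. A final free-M polish of the winner is available
(`refine=True`) but off by default. Ground truths with two species of equal
emitter count are unreachable by a without-repetition pool; this is a known
limitation of the search design, not of the likelihood.

Two numerical accelerations keep the search cheap without touching what is
computed:

* **Batched two-phase EM.** All candidates iterate together in vectorized
  arrays. A loose pass (tol 1e-6, ≤1500 iterations) runs over everyone;
  full-tolerance refinement then continues only for candidates within 50
  log-likelihood units of the running best — once max |Δp| < 1e-6, the
  remaining ascent is O(ν·Δp²), so trailing candidates cannot overtake.
* **Guarded Aitken extrapolation.** EM converges linearly, often with rate
  near 1 for weakly separated species. Every 20 iterations the p-sequence
  is extrapolated geometrically; the jump is accepted per candidate only if
  it does not decrease that candidate's log-likelihood, preserving the
  ascent property. The batched path is tested for agreement with the plain
  per-candidate loop.

## Fisher information and Cramér–Rao bounds

The emitter count is an integer, so the PMF is relaxed to real M through
Γ-functions: C(M, y) → Γ(M+1)/(Γ(M−y+1)Γ(y+1)), which coincides with the
binomial coefficient at integer M. The scores are then

    ∂ log pr/∂M = ψ(M+1) − ψ(M−y+1) + log(1−p),
    ∂ log pr/∂p = y/p − (M−y)/(1−p),

with ψ the digamma function; both are validated against central finite
differences at relative 1e-6. Two information matrices are offered, in
parameter order [M₁, p₁, …, M_m, p_m]:

* **observed** (default): the information of the summed photon number — the
  statistic the detector records. Derivatives of L(i) = Σ_{Y_i} Π_j pr_j
  are obtained by convolving one species' score vector with the other
  species' PMFs.
* **as_printed**: score products of the joint composition probability
  summed over every tuple — the complete-data information, which dominates
  the observed one in the Loewner order (asserted in tests).

CRLB_ν = I⁻¹/ν. Singularity is declared when the reciprocal condition
number falls below machine epsilon: duplicated species (identical M and p)
produce an exactly rank-deficient matrix (~1e-27 reciprocal condition),
while legitimate three-species ground truths sit just above eps (~1e-15) —
ill-conditioned but meaningful. `required_nu` inverts the bound for the
experiments needed to reach a target relative precision and returns ∞ in
the singular case.

**Which bound do the RMSE curves approach?** The joint inverse-FIM diagonal
treats M as a free real parameter and is dominated by the strong M–p
anticorrelation along the constant-M·p ridge. The actual estimator returns
*integer* emitter counts, which lock onto the truth well before the p's
stop improving; from then on p̂ behaves like a known-M estimator, and its
RMSE approaches the inverse of the p-block of the FIM (for one species,
p(1−p)/(Mν)) — typically an order of magnitude below the joint bound. The
Monte-Carlo tables therefore carry both columns: `sqrt_crlb` (joint) and
`sqrt_crlb_cond` (p-block, emitter counts known). Convergence statements
("RMSE meets the bound at ν ≈ …") use the conditional column, because that
is the bound the estimator demonstrably tracks; with it, the one-, two- and
three-species studies reach the band at ν ≈ 10⁶, 10¹⁰ and 10¹³–10¹⁴
respectively.

## Synthetic data

`sample_histogram` offers two modes. `per_shot` draws one binomial per
species per pulse and bins the sums — the generative story verbatim —
and is guarded to ν ≤ 10⁷. `multinomial` (default) draws the whole
histogram in one multinomial step with the model PMF as cell
probabilities; since the estimator sees only [C₀…C_N], this is
statistically identical and reaches ν = 10¹⁴, the regime the three-species
study needs. The two modes are held to agreement by a chi-square test and
moment comparison. The generator emulates ideal PNRD statistics only: no
dead time, no crosstalk, no dark counts, no drift of p over the
measurement. Passing tests therefore demonstrate correctness of the
estimator under the stated model, not robustness to instrument artifacts.

## Monte-Carlo harness

For each ν on a grid, `run_mc` simulates `replicates` independent
histograms (default 100), fits each with the combination search, aligns
estimated species to the truth by the canonical ordering (ascending p, ties
by ascending M — the likelihood is label-symmetric, so a convention is
required), and tabulates per-parameter RMSE next to both √CRLB columns plus
the aMAPE of the emitter counts (mean absolute percentage error averaged
over replicates, then species). Replicate seeds are spawned from one
SeedSequence, making every table bit-reproducible from the single
configuration seed; fits that fail (no feasible seed candidate) are
excluded and counted. The EM stopping tolerance inside the harness is
floored at 1e-2/√ν — three orders of magnitude below the CRLB scale at that
ν — since iterating deeper cannot move any reported error statistic.

Study problem sizes: the single-species study runs 50 replicates on
ν = 10³…10⁷; the two-species study 100 replicates on 10⁶…10¹¹; the
three-species study 8 replicates on {10⁷, 10¹², 10¹³, 10¹⁴}. The
acceptance script uses 400 replicates for the two-species RMSE ratio,
because that ratio is driven by rare integer errors and benefits most from
extra replicates.

## Degenerate inputs and tie-breaks

* Histogram with all mass at zero photons: p updates to the clamp floor,
  the integer scan prefers the smallest admissible M (ties toward small M
  throughout).
* Observed photon number beyond any admissible support: the integer scan
  raises; the likelihood of an undersized mixture is −∞.
* p = 0 and p = 1 are admitted in PMF evaluation (point masses) but
  rejected in estimation parameters; Fisher information additionally
  requires p strictly inside (0, 1).
* Exact-PMF ("infinite data") histograms with fractional counts are
  accepted by every estimator path; they realize the ν → ∞ limit used in
  fixed-point and recovery tests.

## Known limitations

* m is assumed known; model selection over m (e.g. information criteria)
  is out of scope.
* Equal emitter counts across species are unreachable by the
  without-repetition combination pool.
* The moment system supplies at most four relations, capping the seeded
  search at m = 4 species; in practice run time and identifiability already
  bite at m = 3 (ν ≈ 10¹⁴ for CRLB-level precision).
* The CRLB uses a continuous relaxation of a discrete parameter; it guides
  rather than binds the integer part of the estimator (the integer RMSE
  can legitimately fall below it).
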