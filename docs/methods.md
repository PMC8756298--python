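# Methods

## Model

Expression of m genes across n independent samples is modeled as
multivariate Gaussian N(0, Σ) after the user's own normalization; the
package never transforms the data beyond mean-centering each gene column
(the σ^ii terms absorb scale, so no variance standardization is applied).
The estimand is the partial-correlation matrix
ρ_ij = −σ^ij/√(σ^ii σ^jj), whose support is the conditional-independence
graph. An edge is called when |ρ̂_ij| > 1e−8; exact zeros are produced by
soft-thresholding, so this cutoff only guards float noise.

## Joint estimator (space-lasso, space-log)

The loss is

f(ρ; σ) = ½ Σ_i w_i ‖Y_i − Σ_{j≠i} ρ_ij √(σ^jj/σ^ii) Y_j‖²
          + Σ_{i≠j} p(|ρ_ij|).

One value is stored per unordered pair; since the penalty sum runs over
ordered pairs, the effective per-pair penalty is 2·p(|ρ|). This keeps λ on
the ordered-sum scale (comparable to the original space convention) and the
reported objective matches that convention exactly.

**Coordinate update.** ρ_ij appears in both gene i's and gene j's
regressions, so the pair update aggregates both partial residuals:
c = w_i a⟨Y_j, r_i⟩ + w_j b⟨Y_i, r_j⟩ and V = w_i a²‖Y_j‖² + w_j b²‖Y_i‖²
with a = √(σ^jj/σ^ii), b = 1/a and r the partial residuals excluding the
pair; the closed-form minimizer is the soft threshold S(c, thr)/V. A
one-sided update would not minimize the joint loss.

**Active shooting.** One full sweep over all m(m−1)/2 pairs, then repeated
sweeps over the currently nonzero (active) pairs until the largest change is
≤ tol, then another full sweep; the solve stops when a full sweep is stable.
Defaults: tol = 1e−6, at most 1000 sweeps per inner solve (a warning is
logged and `converged=False` recorded if the cap is hit). Inner loops are
compiled with numba.

**Log penalty via LLA.** p(|ρ|; λ, τ) = λ log(|ρ|+τ) is concave in |ρ|, so
replacing it by its tangent at the current estimate gives a
majorize–minimize scheme: each iteration solves a weighted lasso with
per-pair levels 2λ/(|ρ̂^(k)_ij|+τ). Because coordinate descent never
increases the convex surrogate, the true objective is non-increasing across
LLA iterations regardless of how tightly the inner problem is solved. The
LLA is warm-started at the space-lasso solution at the same λ (one-step LLA
theory wants a consistent initial value; a zero start would make the first
iteration an ordinary lasso at λ/τ). Default 3 LLA iterations with early
stop when the support is unchanged and the largest entry moves < tol.

**σ^ii and weights.** σ̂^ii = 1/(mean squared residual of gene i's implied
regression), floored at 1e10 (warning) if a residual collapses. The lasso
phase alternates solve → update σ̂, w three times (the σ/weight schedule
depends only on the iteration index, never on the warm start, so
warm-started path fits equal cold-started ones); σ̂ and w are then held
fixed during LLA so the descent property refers to a single well-defined
objective. Weight schemes: uniform (w_i = 1), residual (w_i = σ̂^ii),
degree (w_i = current neighbor count, floored at 1 so isolated genes keep a
defined weight, computed from the previous iteration's support).

## Neighborhood selection (NS-lasso, NS-log)

Each gene is regressed on all others with penalty n·Σ_j p(|β_j|) — note the
n factor, which puts NS λ on a different scale from the joint estimator's.
NS-log applies the same LLA scheme per regression. Edges are formed by the
OR rule by default (edge if either direction selects; AND available as a
flag): OR is the convention most commonly benchmarked and maximizes power.
Edge weights are sign(β_ij)√(β_ij β_ji) when both directions agree; a sign
conflict yields no edge (logged); under OR a single nonzero coefficient is
reported as is.

## Tuning

extBIC = N log(RSS/N) + k log N + 2γ k log M, with γ = 0.5 by default
(mid-range of [0, 1], consistent when m grows with n); γ = 0 is plain BIC.
For the joint fit N = n·m, RSS is the weighted residual sum of squares,
k counts nonzero pairs (a support count, not an unbiased df estimate) and
M = m(m−1)/2; for one NS regression N = n, M = m−1, and each of the m
regressions selects its own (λ, τ) over the shared grid. The λ grid is 30
points log-spaced over [0.01·λ_max, λ_max], where λ_max is the smallest λ
whose fit is exactly empty (computed in closed form from the initial
inner products). τ is searched jointly with λ over multipliers
{1e−4, 1e−3, 1e−2, 1e−1} of the lasso solution's largest entry at that λ —
anchoring at the lasso scale keeps the grid meaningful across data scales.
Ties break toward the sparser model, then the larger λ. The truth-aware
"oracle" criterion (max F1 over the grid) is available for simulations as
an upper bound; for NS methods the oracle applies one shared (λ, τ) to all
regressions, since graph-level F1 does not decompose per gene.

## Simulator

Skeletons: BA growth from a single gene, each new gene attaching to
min(e, #old) distinct existing genes with probability proportional to
degree (uniform while all degrees are zero; sequential draws without
replacement with renormalization), giving exactly Σ_k min(e, k) edges; or
ER with independent edge probability p. Precision matrices put uniform
±[0.1, 0.4] magnitudes on edges, divide each row's off-diagonals by 1.5×
its absolute row sum, symmetrize by averaging and set the diagonal to 1 —
strict diagonal dominance guarantees positive definiteness (with a retry at
1.5× the boost as a safety net). Data are N(0, precision⁻¹) via the
precision's Cholesky factor, bit-reproducible given the seed.

What this emulates: exactly Gaussian, mean-zero, i.i.d. samples with a
known sparse conditional-independence structure and moderate, homogeneous
partial-correlation magnitudes. What it does not: heavy tails, count noise,
batch structure, confounders, or unfaithful near-cancelling magnitudes —
passing tests show correct recovery under the model's own assumptions, not
robustness to real RNA-seq artifacts (confounder removal is assumed done
upstream).

## Scenario runs and problem sizes

Batch runs fan out a master seed: replicate r draws its graph with
seed+r and its samples with seed+r+10⁶, so all methods see identical data
within a replicate; tables are bit-identical across reruns. The packaged
Monte Carlo study uses m=50, n=400 with 20 replicates in the test suite and
10 in the acceptance script — large enough for the method orderings
(log penalty: fewer false positives; space-log best on hub networks; NS-log
best on ER networks) to be stable, while keeping a full run on one core in
minutes. Exact error counts at m=100–300 depend on the unpublished
precision-magnitude scheme, so batch assertions target orderings and
replicate means, not figure-level values.

## Numerical choices and limitations

- Indices are 0-based internally, 1-based (g1…gm) in files.
- β-to-ρ symmetrization returns 0 on sign conflicts rather than guessing.
- ext_bic refuses k ≥ N (degenerate model); RSS is floored at 1e−300 before
  the log.
- The log-penalty problem is nonconvex: LLA converges to a stationary point
  that depends on the lasso warm start by design; different initializations
  can give different (valid) local solutions.
- m > n is supported by the penalized formulation, but the packaged study
  does not exercise it at scale.
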