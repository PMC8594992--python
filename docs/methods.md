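# Methods

## Problem and data model

The package discriminates β-thalassemia trait (βTT, the positive class)
from iron deficiency anemia (IDA) using four CBC indices: MCV (fl), MCH
(pg), Hb (g/dl), RDW (%). Records are rows of a CSV with header
`mcv,mch,hb,rdw,label`; predictors must be strictly positive and finite,
labels 0 (IDA) / 1 (βTT).

## Tree prior

A tree is generated recursively from the root: a node at depth `d` splits
with probability `α (1 + d)^(−β)`; conditional on splitting, the rule is
uniform over predictors that admit a split, then uniform over that
predictor's admissible split points. **Admissible split points are the gaps
between consecutive distinct observed values within the node that leave at
least `min_node_size` samples on each side**, represented numerically by
the gap midpoint. Identifying a rule with its gap makes "all possible
splits" a finite set, renders the prior a proper distribution over the
admissible tree space for a given training set (verified by exhaustive
enumeration in the tests: the prior sums to 1), and is invariant to
monotone jitter of the raw measurements. A node with no admissible split is
deterministically terminal and contributes no non-split factor.

Routing is `value ≤ threshold → left`, fixed project-wide.

`min_node_size` defaults to 10 = 2(p+1) with p = 4 predictors, so every
terminal logistic fit is well-posed.

## Node models and the integrated likelihood

Predictors are standardized to mean 0, SD 1 (denominator n−1) **on the
training set**; test data reuse the training location/scale. Each terminal
node fits a logistic regression on all four standardized predictors plus an
intercept, with prior `B ~ N(0, σ²I)`, σ = 20 by default. The split-rule
subset and the node-model subset are independently configurable; both
default to all four predictors.

The node marginal likelihood has no closed form; it is approximated by
Laplace: log posterior at the MAP + (p/2)·log 2π − ½·log det(−H), with the
MAP found by damped Newton (step halving up to 30 times on non-increase
beyond numerical noise; converged at gradient max-norm < 1e−8; the Gaussian
prior makes the objective strictly concave, so the optimum is unique and
finite even under complete separation). The negative-Hessian determinant is
computed by Cholesky factorization; a factorization failure is treated as a
proposal rejection. Accuracy: on random 1–2-coefficient nodes with n ≥ 20
the Laplace value is within 0.1 log units of adaptive quadrature of the
exact integral (test-suite property); the approximation error grows for
smaller blocks, which `min_node_size` keeps out of scope.

## Tree search

Metropolis–Hastings over tree space with move probabilities GROW 0.25,
PRUNE 0.25, CHANGE 0.40, SWAP 0.10 (configurable). Proposal ratios account
for the number of growable leaves, prunable internal nodes, splittable
predictors and admissible gaps, so the chain is exact: on an enumerable
12-sample toy space the visit frequencies match the brute-force posterior,
and with the likelihood disabled they match the analytic prior (both
within 3 Monte-Carlo SEs of thinned draws). A CHANGE/SWAP candidate whose
descendant rules become inadmissible (gap membership or `min_node_size`)
is rejected outright; an inapplicable move proposes the unchanged tree.

Chains start at the root-only tree. Restarts use independent sub-streams
spawned from the master seed (`SeedSequence([seed, restart])`), so runs are
bit-reproducible. The search result is the visited tree maximizing
log marginal + log prior, per restart. (α, β) are selected over
{0.5, 0.95} × {0.5, 1, 1.5, 2} by smallest training FNR; ties break toward
higher score, then fewer leaves.

Prediction is plug-in: each sample routes to its terminal node and gets
that node's MAP logistic probability; label βTT at probability ≥ 0.5
(threshold configurable). Per-iteration posterior-predictive averaging
over the chain is deliberately not implemented: a single selected tree
with plug-in coefficients is the documented, reproducible behavior.

Study-scale settings (8 restarts × 6000 iterations, full grid) are the
package defaults. The analysis drivers, test suite and acceptance script
run a scaled search (2–3 restarts × 200–400 iterations); on these cohorts
(n ≈ 600 training records, trees of 2–4 leaves) the chain's best tree
stabilizes within a few hundred iterations, and the scaled problem sizes
are stated where used.

## CART

Greedy growth maximizes the impurity decrease
`n·I(parent) − n_L·I(L) − n_R·I(R)` with Gini (`1 − Σ p²`) or entropy
(`−Σ p log p`, natural log — the base rescales but never reorders splits).
Defaults `min_split = 20`, `min_leaf = 7`, 10-fold CV mirror common
practice for this tool family. Ties in impurity decrease break to the
lowest predictor index, then the smallest threshold; leaf-label ties
resolve to βTT.

Weakest-link cost-complexity pruning collapses the internal node(s)
minimizing `g = (R(node) − R(branch)) / (|leaves| − 1)`. The sequence's
first element is the α = 0 optimum: when the grown tree carries branches
with zero risk improvement (positive impurity decrease but no
misclassification gain — common under 0–1 loss), any positive penalty
removes them, so they are collapsed into the first recorded step rather
than listed as a separate entry; each recorded subtree is verified against
exhaustive minimization of `R(T) + α|leaves|` over all pruned subtrees.
Subtree selection uses stratified k-fold CV at the geometric means of
consecutive α values and picks the minimum-CV-error subtree with no 1-SE
rule; ties go to the smaller tree.

## Evaluation battery

βTT is the positive class throughout. Proportion metrics carry
Clopper–Pearson exact 95% intervals (beta-quantile form; lower bound 0 at
0 successes, upper bound 1 at full successes). Youden's index takes the
interval obtained by summing the sensitivity and specificity bounds.
PLR/NLR carry Simel-style log-method intervals,
`exp(log LR ± z·SE)` with the standard diagnostic-likelihood-ratio
variance. Zero denominators yield an explicit undefined marker (NaN),
never silent infinities. Display rounding is half-away-from-zero:
percentages to integers, likelihood ratios to two decimals — the
convention that reproduces the benchmark table (174 of its 180 cells
exactly; the other six are internal inconsistencies of the source table,
itemized in `hemtree.benchmark.KNOWN_SOURCE_INCONSISTENCIES` with both
values).

AUC is the trapezoidal/Mann–Whitney statistic (ties ½), SE by DeLong's
structural components via midranks, CI Wald-truncated to [0, 1], with the
qualitative bands (> 0.9 excellent, > 0.8 very good, …). The paired DeLong
test uses the component covariance; identical score vectors return p = 1
exactly.

## Synthetic cohorts

The generator targets the published per-class descriptive statistics:
537 βTT / 370 IDA; medians (IQR widths) βTT MCV 62 (5.4), MCH 19.6 (1.8),
Hb 11 (1.6), RDW 15.7 (1.7); IDA MCV 72.2 (9.7), MCH 21.9 (4.2),
Hb 10.5 (2.6), RDW 15.7 (3.3). Each predictor is log-normal — positive
support and right skew are typical of hematology indices, and any
two-parameter positive family would fit the two published summaries; the
(μ, σ) solve the median/IQR equations exactly (closed form, verified
against distribution quantiles). Predictors are independent within class
by default; a Gaussian-copula correlation matrix is accepted but no
published dependence information exists to calibrate it. The train/test
split is stratified per class at a default fraction of 0.7 — the published
confusion-matrix column sums imply 376/537 and 259/370 training records,
i.e. 70/30, although the text says 2:1; both fractions are supported.

**What the generator does and does not emulate.** It reproduces class
sizes and per-predictor location/spread only. It does not reproduce the
real joint distribution: no MCV–MCH–RDW dependence, no analyzer
measurement structure, no tail behavior beyond log-normal. This caps the
attainable separation: a near-optimal classifier on the synthetic cohorts
reaches test AUC ≈ 0.93, whereas the real-data benchmark reports 0.94–0.98
— the real cohort is more separable than its published marginals imply.
Consequently, passing end-to-end tests demonstrate that the engines work
and that MCV dominates impurity-based splitting (CART roots on MCV in
20/20 generator seeds), not that the published AUCs are recovered.

A second consequence concerns the treed-logistic model specifically: since
every leaf carries a full four-predictor logistic model, a root-only tree
already captures the entire *linear* signal, and the marginally-preferred
first split is driven by residual interaction structure — which
independent marginals barely possess. On synthetic cohorts the BLTREED
first split is therefore not reliably MCV, unlike in the benchmark study
whose data evidently contained such structure. The acceptance suite states
this mirror property as the study reports it and documents the measured
shortfall rather than adjusting the generator.

Ground-truth recovery is tested separately with a treed-logistic
generator: data simulated from a known single-MCV-split tree with strong
node effects are reliably recovered by the search (root variable in ≥ 80%
of restarts; node coefficients within 3 SEs).

## Numerical and design notes

- Seeds: every stochastic operation takes an explicit seed or Generator;
  derived streams use `SeedSequence` spawning, never global state.
- The chain caches node marginals keyed by the node's row-index set, so
  repeated visits to the same partition cost nothing.
- `log det` via Cholesky; non-PD negative Hessians surface as rejections,
  not NaNs.
- The reported "log integrated likelihood" is the Laplace total as defined
  above (sign-indefinite because of the Laplace constants); no attempt is
  made to match alternative constant conventions.
- Degenerate inputs: zero-variance predictors fail standardization with a
  named diagnostic; single-class inputs are rejected by ROC/DeLong;
  samples with missing predictors are rejected at routing.

## Known limitations

- Plug-in (not fully Bayesian) prediction from a single selected tree.
- No categorical predictors, multiway splits, surrogate splits, case
  weights, or class priors/loss matrices.
- The synthetic cohort's marginal-only fidelity, as discussed above; the
  published headline AUCs are not reproducible without the patient data.
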