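# spacelog

Sparse partial-correlation estimation of gene–gene networks with a
nonconvex **log penalty**, together with lasso comparators,
neighborhood-selection baselines, extended-BIC tuning and a
simulation/evaluation harness.

## The problem

Given expression of *m* genes in *n* samples, assumed (after the user's own
normalization) to follow a multivariate Gaussian *N*(0, Σ), an edge between
genes *i* and *j* in the gene–gene network means conditional dependence given
all other genes — equivalently a nonzero entry of the concentration matrix
Σ⁻¹ = (σ^ij), or a nonzero partial correlation

ρᵢⱼ = −σ^ij / √(σ^ii σ^jj).

Because each gene satisfies the self-regression
Yᵢ = Σ_{j≠i} ρᵢⱼ √(σ^jj/σ^ii) Yⱼ + εᵢ, all partial correlations can be
estimated **jointly** by minimizing one penalized weighted least-squares loss
over the symmetric matrix ρ (the *space* framework):

    f(ρ; σ) = ½ Σᵢ wᵢ ‖Yᵢ − Σ_{j≠i} ρᵢⱼ √(σ^jj/σ^ii) Yⱼ‖² + Σ_{i≠j} p(|ρᵢⱼ|)

with p(|ρ|) = λ|ρ| (**space-lasso**) or the nonconvex
p(|ρ|) = λ log(|ρ| + τ) (**space-log**), which interpolates between L0- and
L1-like behavior and markedly reduces false positives, especially on
hub-dominated networks. The log penalty is minimized by Local Linear
Approximation (LLA): each iteration replaces p by its tangent at the current
estimate, yielding a weighted-lasso subproblem with per-pair penalty levels
λ/(|ρ̂⁽ᵏ⁾ᵢⱼ| + τ), solved by active-shooting coordinate descent. Per-gene
neighborhood-selection baselines (**NS-lasso**, **NS-log**) and three weight
schemes for the joint loss (uniform, residual-variance, degree) are included,
and (λ, τ) are selected by the extended BIC

    extBIC = N log(RSS/N) + k log N + 2γ k log M.

## Worked example

Simulate a hub-dominated (preferential-attachment) network of 50 genes,
sample 400 expression profiles, fit space-log with extBIC-selected (λ, τ),
and score the result against the known truth:

```bash
spacelog simulate --model ba --m 50 --n 400 --e 1 --seed 7 --out-prefix demo
# wrote demo.expr.tsv (400x50), 49 true edges
spacelog fit --input demo.expr.tsv --method space-log --auto \
         --out demo.spacelog.tsv --log-json demo.run.json
# space-log: 37 edges -> demo.spacelog.tsv
spacelog evaluate --truth demo.edges.tsv --estimate demo.spacelog.tsv \
         --out demo.report.json
# {"tp": 37, "fp": 0, "fn": 12, "fp_plus_fn": 12, "n_discoveries": 37,
#  "f1": 0.860..., "fdr": 0.0, "tpr": 0.755...}
```

Of the 49 true edges, space-log recovers 37 with **zero** false positives
(FDR 0): the log penalty trades a little power (TPR 0.76) for a clean edge
set. The edge list is a 3-column TSV sorted by |ρ̂| descending:

```
gene_i  gene_j  weight
g26     g47     0.5184...
g14     g49     -0.4984...
```

The same library surface is available in Python
(`spacelog.fit_space`, `spacelog.select_model`, `spacelog.run_scenario`, …).

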