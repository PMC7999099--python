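# ospca

Orthogonal smoothed principal component analysis for metabolome data with
time-course or rank-order sample structure.

## The problem

Metabolome experiments often measure samples along an ordered covariate —
incubation time in a metabolic-turnover study, taste rank in a food-quality
panel — possibly in several groups (strains, culture media) and with
replicate measurements. Ordinary PCA ignores that ordering; smoothed PCA
exploits it by penalizing rough score sequences, but its eigenvectors come
from a *generalized* eigenproblem, are not orthogonal, and carry no
statistical interpretation, so no metabolite can be declared significantly
associated with a smoothed component.

OS-PCA fixes this. Alongside the score `t = X w_x` it introduces an
auxiliary score `s = X w_y` and maximizes their covariance,

    max cov(t, s) = (1/n) w_x' X' X w_y
    s.t.  w_x' w_x = 1,   (1 - κ) w_y' w_y + κ (D s)'(D s) = w_y' P w_y = 1,

where `D` takes first or second differences of consecutive ordered samples
within each group and `κ ∈ [0, 1)` sets the smoothing strength
(`P = (1 - κ) I + κ X'D'DX`). Eliminating `w_y` yields an *ordinary*
symmetric eigenproblem,

    (1/n²) X'X P⁻¹ X'X w_x = λ w_x,

so the weight vectors are orthonormal, and on autoscaled data the loading
of metabolite p — the correlation `corr(s, x_p)` — is proportional to
`w_x,p`. Loadings are therefore plain correlation coefficients and can be
tested with the classical t-statistic `r √(n−2) / √(1−r²)` (df = n − 2),
followed by Benjamini–Hochberg FDR adjustment to select metabolites. At
κ = 0 the model reduces exactly to PCA. A repeated-measurement variant
runs the same algebra on the averaged matrix `M X`, where the
row-stochastic operator `M` maps replicate measurements to their
per-sample means.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from ospca import (SimulationSpec, simulate_metabolome, autoscale,
                   make_difference_matrix, fit_ospca, loading_test_table)

# 3 groups x 11 ordered timepoints, 60 metabolites, 10 on a smooth trend
data, design, truth = simulate_metabolome(SimulationSpec(seed=1))
X = autoscale(data)
D = make_difference_matrix(design, diff_order=2)
model = fit_ospca(X, D, kappa=0.999, k=5)

print("covariance contributions (%):",
      np.round(100 * model.contribution[:2], 2))
print("OS-PC1 auxiliary score vs order: rho = %.3f"
      % spearmanr(model.scores_s[:, 0], design.order).statistic)
table = loading_test_table(model, X, component=2)
print("significant at q<0.05:", (table.q < 0.05).sum(), "metabolites")
```

prints (seed 1):

```
covariance contributions (%): [41.01 35.25]
OS-PC1 auxiliary score vs order: rho = 0.332
significant at q<0.05: 11 metabolites
```

Here OS-PC1 captures the planted between-group contrast (its auxiliary
score barely tracks the time order, Spearman ρ = 0.33; its 41% is a
*covariance* contribution, not comparable with PCA's variance ratios)
while OS-PC2's auxiliary score follows the order almost perfectly
(ρ = 0.95). The loading test on OS-PC2 selects 11 metabolites at
q < 0.05, including all 10 planted trend metabolites.
The same workflow runs from the shell:

```sh
ospca simulate --seed 1 --out sim/
ospca run --data sim/data.csv --design sim/design.csv \
          --method ospca --kappa 0.999 --diff-order 2 \
          --test-component 2 --q 0.05 --out results/
```

which writes `scores_t.csv`, `scores_s.csv`, `weights_x.csv`,
`weights_y.csv`, `eigenvalues.csv` (with contribution ratios and their
basis), `loadings.csv` (r, t, df, p, q per metabolite) and a run
manifest. `--method ospca-rep` additionally writes `scores_avg.csv`, the
per-sample auxiliary scores shared by all replicates.

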