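# Methods

## Models

All four decompositions operate on an n × p matrix `X` of n measurements
(rows, sorted by group and then by an ordering covariate) by p
metabolites (columns), autoscaled per column. Variance is computed with
divisor n throughout, matching the `var(t) = (1/n) t't` convention the
eigenproblems are written in; the loading-as-correlation identity is
divisor-invariant, but score and eigenvalue magnitudes are not, so the
convention is applied consistently everywhere.

**PCA** — symmetric eigendecomposition of `(1/n) X'X`; contribution
ratios are eigenvalue fractions (variance basis).

**Smoothed PCA** — the variance objective under the mixed constraint
`(1-κ) w'w + κ (Dt)'(Dt) = 1`, i.e. the generalized eigenproblem
`(1/n) X'X w = λ P w` with `P = (1-κ) I + κ X'D'DX`. Solved with the
symmetric-definite generalized solver (`scipy.linalg.eigh(A, P)`), whose
eigenvectors return `P`-normalized, exactly the constraint. Smoothed-PC
eigenvectors are not orthogonal and have no correlation interpretation;
the package refuses loading tests for this model by design.

**OS-PCA** — maximize `cov(t, s) = (1/n) w_x'X'X w_y` under
`w_x'w_x = 1` and `w_y'P w_y = 1`. The stationarity conditions

    (1/n) X'X w_y = 2 λ_x w_x,    (1/n) X'X w_x = 2 λ_y P w_y

collapse to the ordinary symmetric eigenproblem
`(1/n²) X'X P⁻¹ X'X w_x = λ w_x` with `λ = 4 λ_x λ_y`. The
implementation forms `K = (1/n²) G P⁻¹ G` (`G = X'X`) through a Cholesky
factorization of `P`, symmetrizes it against floating-point asymmetry
and uses the symmetric eigensolver, which guarantees a real spectrum and
orthonormal `w_x` — the property that makes the whole construction
worthwhile. Each `w_y` is recovered as `P⁻¹ G w_x`, renormalized to
`w_y'P w_y = 1`, and sign-paired so that `cov(t, s) ≥ 0`; with that
normalization `cov(t_i, s_i) = √λ_i` and `λ_x = λ_y = √λ_i / 2`
identically, so both stationarity relations hold to machine precision by
construction (verified independently in the tests). Contribution ratios
are covariance fractions `cov(t_i, s_i) / Σ_j cov(t_j, s_j)` over the
full informative spectrum; outputs always carry a "variance" vs
"covariance" basis label because the two are not comparable.

**Repeated-measurement OS-PCA** — identical algebra with `G = X'M'MX`
and `Q = (1-κ) I + κ X'M'D'DMX`, where `M` (u × n, u replicate sets) is
the row-stochastic averaging operator and `D` is built on the collapsed
(one row per replicate set) design. Per-measurement scores `t = X w_x`
are kept; the auxiliary score is reported per replicate set as
`M s = M X w_y` — all repeats of a sample share it.

## Structure matrices

`D` slides the stencil [1, −1] (first differences) or [1, −2, 1]
(second differences) along consecutive order-sorted samples *within*
each group; no row straddles a group boundary, which is what produces
the (n − g) and (n − 2g) row counts. Differences are unweighted: the
penalty sees sample positions, not the numeric gaps of the covariate, so
log-spaced time grids are handled the same way as ranks. Groups with
fewer than diff_order + 1 samples contribute no rows (logged). Ties in
order are broken by input position (stable sort). Constant vectors are
always in `D`'s null space, and per-group linear-in-position vectors are
in `D⁽²⁾`'s.

## Scaling with replicates

With repeated measurements the object that must be autoscaled is the
averaged matrix `M X`: columns of `X` are shifted and scaled by the
column mean and (divisor-u) standard deviation of `M X`, making `M X`
exactly zero-mean/unit-variance while `X` retains small residual column
means. This is required for the repeated-measurement loading identity,
which needs `var(M x_p) = 1`; with all sets singletons it coincides with
ordinary autoscaling. Zero-variance columns are dropped with a warning.
Missing values are rejected at container construction — imputation is a
modelling decision the caller must make explicitly.

## Inference

Loadings are Pearson correlations: `corr(t, x_p)` for PCA,
`corr(s, x_p)` for OS-PCA, `corr(Ms, Mx_p)` for the repeated variant.
They are elementwise proportional to `w_x` with one positive constant,
so testing loadings is equivalent to ranking by `|w_x|` with calibrated
p-values attached. The t-test uses the number of rows entering the
correlation (n, or u for the repeated model) minus 2 as degrees of
freedom; tests are two-sided, since both positively and negatively
associated metabolites are of interest. FDR adjustment is
Benjamini–Hochberg (the metabolomics default), delegated to
statsmodels; the test suite checks it against an independent step-up
implementation. Caveat: the t-test treats `s` as fixed although it is
estimated from the same data, so p-values for a *data-driven* component
are approximate; the suite therefore calibrates type-I error on a fixed,
held-out score direction, where the null is exact, and separately checks
that all-null simulations yield few selections in practice.

## Tunable parameters

- `κ ∈ [0, 1)` — smoothing strength. No default and no automatic
  selection: it is a per-dataset modelling choice (strong smoothing
  ≈ 0.999 emphasizes order structure; mild ≈ 0.1 stays close to PCA),
  and the CLI requires it explicitly. `κ = 0.999` is numerically safe:
  the spectrum of `P` is bounded below by 1 − κ.
- `diff_order ∈ {1, 2}` — first differences penalize level changes,
  second differences penalize curvature and leave linear trends
  unpenalized; 2 is the CLI default.
- `k` — components retained, default `min(n − 1, p, 5)`; requests above
  the numerical rank are truncated with a warning.
- `q_threshold` — selection FDR level, default 0.05.

## Synthetic data

The generator emulates a turnover-style study: g groups × m ordered
covariate values × r replicates; a disjoint split of metabolites into a
trend set (loaded on a smooth latent curve), a group set (loaded on a
centered, equally spaced group contrast) and nulls; coefficients of
magnitude `effect_size` with random signs; i.i.d. Gaussian noise of sd
`noise_sd` on every entry; replicates share latents and differ only by
noise. Defaults: 3 groups, the 11 log-spaced incubation times
(0…7200 s) of a turnover experiment, 60 metabolites with 10 trend and 5
group metabolites, saturating-exponential trend, effect 1.0, noise sd
0.3. The trend curve is evaluated over the *rank position* of the
covariate, not its raw value: turnover time courses are sampled on
log-spaced grids precisely so the measured curve is smooth against
sample position, which is also the scale the unweighted difference
penalty acts on. A single `numpy` Generator seeded from `seed` drives
all randomness, making outputs bitwise reproducible.

What the generator does **not** emulate: bounded isotopomer ratios
(noise is Gaussian, not logit-bounded), heteroscedastic intensity noise,
missingness mechanisms, or correlated metabolite blocks beyond the two
planted latents. Passing recovery tests therefore demonstrates that the
estimator finds smooth planted structure under idealized noise — not
that it is robust to mass-spectrometry artifacts.

## Numerical choices

- `P`/`Q` are symmetrized after assembly and inverted via Cholesky;
  failure (possible only for κ pathologically close to 1 with degenerate
  data) raises with advice to lower κ.
- Components with eigenvalue below `1e-12` (relative to the largest) are
  treated as null space and truncated from the requested k.
- Sign convention: each (`w_x`, `w_y`) pair is flipped jointly so the
  largest-|·| element of `w_x` is positive — score directions are
  otherwise arbitrary, and joint flipping preserves `cov(t, s) ≥ 0`.
- Eigenvalues are returned in descending order; tie subspaces are
  ordered as the solver returns them (ties are measure-zero for real
  data and the simulator's conditions).
- All pipeline CSV output is printed at 10 significant digits with a
  self-describing `# method=… kappa=… diff_order=…` comment header.

## Design notes

- Selecting which component to test is the analyst's decision, as with
  any score-plot-driven workflow; the recovery diagnostics pick the
  component whose auxiliary score best rank-correlates with the ordering
  covariate, mirroring how a trend component is identified in practice.
- The recovery and monotonicity checks run at desk scale (33-sample,
  60-metabolite instances; 20–100 seeds), sizes at which every fit is a
  dense p × p eigenproblem and the whole suite completes in seconds.

## Known limitations

- No selection-effect correction for testing loadings of a data-driven
  component (documented caveat above).
- Unequal covariate spacing is deliberately not encoded as difference
  weights; if physical-time curvature matters, transform the covariate
  before analysis.
- No missing-value handling, Pareto/range scaling, log transforms, batch
  correction, kernel or supervised (PLS-family) variants.
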