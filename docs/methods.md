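# Methods

This note documents the statistical model, the Monte-Carlo design, and the
numerical choices behind `varscale`.

## 1. The scale-effect model

Consider a trait recorded as

    y_i = mu + a_i + e_i,

with additive genetic values a_i ~ N(0, sigma_u^2) and residuals
e_i ~ N(0, sigma_e^2), homoscedastic at baseline. The phenotypic SD is tied
to the mean through a coefficient of variation CV:

    sigma_p = CV * mu,
    sigma_u^2 = h2 * sigma_p^2,
    sigma_e^2 = (1 - h2) * sigma_p^2.

A *statistical scale effect* means the dispersion of a record tracks its own
magnitude: an individual whose realized record is y_i has elementwise scaled
standard deviations

    sigma_pi = CV * |y_i|,
    sigma_ei = sigma_pi * sqrt(1 - h2),
    sigma_ui = sigma_pi * sqrt(h2).

On the log-variance (multiplicative) scale commonly used for genetic
heterogeneity of environmental variance, the individual's environmental
"breeding value" is

    v_i = r * ln(sigma_ei^2 / sigma_e^2) = 2 r ln(sigma_ei / sigma_e),

where r in (0, 1] is the strength of the scale effect (r = 1 is the
full-strength effect). The trait breeding value rescaled to the individual's
own dispersion is

    u_i = a_i * sigma_ui / sigma_u.

Two summaries are studied on a population of such records:

- **rho = corr(u, v)**: the genetic correlation between the trait and its
  environmental variability *induced purely by the scale effect* — a
  spurious correlation in the sense that no variance-controlling gene
  exists in the generating model.
- **GCV ≈ sqrt(Var(v))**: the apparent genetic coefficient of variation of
  the environmental variance, the quantity usually reported as evidence of
  genetic heteroscedasticity.

### Small-CV limits

Writing w = 1 + CV·z_p with z_p standard normal, a delta-method expansion as
CV → 0 gives

    rho -> sqrt(h2),        GCV -> 2 r CV.

Both limits are exposed as closed forms (`small_cv_correlation_limit`,
`small_cv_gcv_limit`) and verified to 1% at CV = 0.01 by simulation.

### Negative records

For CV ≥ 0.35 a non-negligible fraction of records is negative (about 2.3%
of records at CV = 0.5, matching the normal tail beyond 2 SD). The model
needs a sign convention there. Two are implemented:

- **`fold_phenotype`** (default): sigma_pi = CV·|y_i| — the absolute value
  is taken at the phenotype, so all three scaled SDs are positive.
- **`flip_residual`**: sigma_pi = CV·y_i is kept signed (so sigma_ui is
  signed too) and only sigma_ei enters as |sigma_ei| where the log is
  formed.

The two conventions agree at printed precision for CV ≤ 0.25. At CV = 0.5
they differ visibly in rho (e.g. at h2 = 0.05: ≈ 0.140 folded vs ≈ 0.133
flipped; at h2 = 0.50: ≈ 0.41 folded vs ≈ 0.405 flipped). Published grids of
this model appear consistent with the flip convention at high CV; the folded
convention is this package's default because taking |y| at the phenotype is
the cleaner statement of "dispersion tracks magnitude". Both are available
via the `negative_handling` argument.

## 2. Monte-Carlo design

The study conditions are 10 replicates of 100,000 individuals per scenario,
mu = 100. Scenario grids: CV and h2 from 0.05 to 0.50 in steps of 0.05 for
the correlation grid (r = 1), and r from 0.05 to 1.00 in steps of 0.05
crossed with the same CVs for the GCV grid.

### Stream derivation

Randomness derives from `numpy.random.SeedSequence(seed,
spawn_key=(scenario_index, replicate_index))` feeding PCG64. Every
(scenario, replicate) pair has an independent, reproducible stream, and the
same replicate of the same scenario index sees the same stream regardless of
which parameters are varied — the basis of the shared-stream invariance
checks below.

### Rotation construction

Each replicate draws two iid N(0,1) vectors (z_p, z_w) and forms

    z_a = sqrt(h2) * z_p + sqrt(1 - h2) * z_w,
    z_e = sqrt(1 - h2) * z_p - sqrt(h2) * z_w,

an orthogonal rotation, so (z_a, z_e) are again iid N(0,1) and
y = mu + sigma_p * z_p exactly. Consequences, each verified by test:

- the phenotype (hence v, hence GCV) is identical across h2 values on a
  shared stream: GCV is *exactly* h2-invariant replicate-for-replicate;
- rho is exactly invariant to r (v is linear in r) and to mu (u, v depend on
  y only through y/mu) on shared streams, to better than 1e-10 relative.

### Exact floating-point identities

The baseline roots are computed in the same floating-point form as the
elementwise scaled SDs (sigma_p = cv*mu, sigma_e = sigma_p*sqrt(1-h2)), so a
record with |y| = mu yields sigma_ei / sigma_e == 1.0 bit-for-bit and
v == 0.0 exactly. v is computed as (2r)·ln(·), making v exactly linear in r
(one rounding), which the tests assert with exact array equality.

### Summaries and errors

Each replicate yields a Pearson correlation rho and a GCV
(sqrt of the ddof-1 sample variance of v). A scenario reports the mean over
replicates and SE = SD(replicates, ddof=1)/sqrt(m). Grid tables carry both,
plus the per-replicate long format; GCV cells above 0.69 (an implausibly
large apparent genetic CV of environmental variance) are flagged in the long
format.

## 3. Analytic oracles

All population moments reduce to one-dimensional integrals. With
w = 1 + CV·z and z standard normal, and a second independent standard
normal integrating out in closed form,

    E[u]   = sqrt(h2) * E[z |w|]
    E[u^2] = h2 * E[z^2 w^2] + (1 - h2) * E[w^2]
    E[u v] = sqrt(h2) * E[z |w| L(z)]
    E[v]   = E[L(z)],   E[v^2] = E[L(z)^2],
    L(z)   = 2 ln|w| (times r for GCV),

from which rho and GCV = r·2·sqrt(Var(ln|w|)) follow. (These moments use the
folded convention |w|; the oracle mirrors the simulator's default so the two
share one model.)

Numerically, ln|1 + CV·z| has a logarithmic singularity at z = −1/CV, which
enters the effective integration range once CV ≳ 0.3 and defeats
Gauss–Hermite quadrature (errors up to ~0.09 in GCV at CV = 0.5 at any node
count). The oracle therefore uses:

- **Gauss–Hermite** (scipy `roots_hermite`, default 128 nodes, with a
  doubled-node agreement check) for CV ≤ 0.125, where the singularity is
  ≥ 8 SDs out;
- **adaptive Gauss–Kronrod** (`scipy.integrate.quad`) for CV > 0.125, on
  panels split at the singularity with the substitution z = split ± t²,
  which removes the integrable log singularity (the Jacobian 2t vanishes
  where the log blows up). Tolerances 1e-13 absolute / 1e-11 relative.

A `QuadratureConvergenceWarning` is raised if the convergence check fails.
Against an independent 100-replicate Monte Carlo the oracle agrees to
< 0.5 SE at every cell checked, including CV = 0.5.

## 4. Data diagnostic

`quantile_bin_summary` sorts records, splits them into quantile bins
(remainder records going to the lowest bins), and reports n, mean, SD and CV
per bin. Under a pure scale effect the within-bin SD rises proportionally
with the bin mean while the CV stays flat — the fingerprint distinguishing a
scale effect from genuinely heteroscedastic genetics when inspecting real
trait data (`varscale bins data.csv`).

## 5. Known limitations

- The per-cell "mean within 4 SE of the oracle" consistency check uses an SE
  estimated from 10 replicates (9 degrees of freedom). The per-cell
  statistic is then a t9, and P(|t9| > 4) ≈ 0.3%, so over a 100-cell grid a
  correct implementation fails somewhere with probability ≈ 27%. The test
  suite implements the criterion literally and at its fixed seed one cell
  (CV = 0.50, h2 = 0.35) exceeds the band at z = 4.86; an independent
  100-replicate run agrees with the oracle at z = 0.45, confirming a
  sampling fluctuation, not a defect. The seed and the band were fixed
  before running and are deliberately left untouched.
- The expected maximum negative-record percentage at CV = 0.5 is ≈ 2.35%,
  i.e. on a rounding boundary: most seeds report 2.3 after rounding to one
  decimal, occasional seeds 2.4.
- The oracle covers the folded convention only; `flip_residual` is validated
  by simulation.
- No closed forms beyond the first-order small-CV limits are attempted; the
  quadrature oracle is the reference at finite CV.
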