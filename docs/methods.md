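# Methods

## Descriptors

A sigma-profile is the distribution of screening charge density over a
molecule's COSMO cavity: `p(sigma)*A` in Å² against `sigma` in e/Å²,
consumed here as two-column text files (comments `#`, whitespace or comma
separators). Files are accepted with any strictly increasing grid; the
typical open-database profiles carry 31 points over ±0.03 and other
counts between 31 and 61 parse without comment (outside that, with a
warning). No resampling is performed — the trapezoidal integration is
grid-agnostic.

The eight region areas `S1..S8` are trapezoidal integrals over a
partition of the sigma axis. The partition edges are configurable; the
default is eight equal-width intervals on [−0.03, +0.03] (width 0.0075),
which places the conventional hydrogen-bond threshold
|sigma| ≈ 0.0075–0.0082 at the S3/S4 and S5/S6 edges and reproduces the
standard grouping: S1–S2 strong donor, S3 weak donor, S4–S5 nonpolar,
S6 weak acceptor, S7–S8 strong acceptor. The negative-sigma end is the
donor side (an H^δ+ atom induces negative screening charge). Region
edges falling between grid points use linearly interpolated densities,
so the partition is exhaustive: ΣS_i equals the full-profile integral to
rounding error, a property the tests enforce at 1e−9 relative.

Units are carried as labels only; no conversions are applied. Mixture
descriptors are the mole-fraction weighted average of the constituent
descriptors. Compositions are expressed as an HBA:HBD molar ratio
(`1:n`) rescaled by `1 − x_cosolvent`; a mixture must contain exactly
one hydrogen-bond acceptor salt and at least one donor.

## Network and training

Inputs `(S1..S8, T[K])` and the target `log10(η/mPa·s)` are min–max
scaled to [−1, +1] using the training data's ranges (a constant feature
is widened by ±0.5 with a warning). Hidden layers apply
`tanh(W u + b)`; the output layer is affine. Working on `log η` rather
than `η` equalizes the error weight of thin and thick samples across
nearly four decades of viscosity.

Training minimizes `F = β E_D + α E_W` (`E_D` sum of squared scaled
residuals, `E_W` sum of squared weights) with a Levenberg–Marquardt
loop: solve `(2β JᵀJ + 2α I + μ I) δ = −g`, accept steps that lower F,
multiply μ by 10 on rejection and by 0.1 on acceptance. Under
`algorithm="bayesian_regularization"` (default) the hyperparameters are
re-estimated after every accepted step with the Gauss–Newton Hessian
`H = 2β JᵀJ + 2α I`:

    γ = N_w − 2α tr(H⁻¹),  α = γ / (2 E_W),  β = (N − γ) / (2 E_D)

starting from α = 0, β = 1; γ is clipped to (0, min(N_w, N)) and a
near-singular H falls back to a ridge-stabilized inverse with a
warning. `algorithm="l2"` keeps a fixed α (and β = 1), which is the
closed-form-checkable variant. Weights initialize from a symmetric
uniform distribution scaled by 1/√fan-in (biases zero), seeded — the
whole fit is bit-reproducible from (data, config, seed).

Stopping: the relative change of `E_D` stays below `tolerance`
(default 1e−9) for `patience` = 5 consecutive accepted steps, the
gradient vanishes, or no μ ≤ 1e10 yields descent. Exhausting
`max_iterations` (default 300) returns the model with
`metadata["converged"] = False` and a `ConvergenceWarning`; in practice
the benchmark fits sit at the noise floor well before the budget.

The Jacobian is assembled by per-sample backpropagation
(`tanh' = 1 − tanh²`) and verified against central finite differences;
the forward pass is verified against an independently composed matrix
expression at 1e−12 relative.

Architecture search trains every candidate (default: 1–25 one-layer
plus the 25×25 two-layer grid, 650 candidates) on the training split
and ranks by RMSE over the pooled train + test records; the selected
architecture is the one with the fewest parameters among candidates
within 1% relative RMSE of the best (both the pool and the tolerance
are arguments). Models serialize to a versioned JSON document and to a
flat per-neuron CSV weight table; both round-trip bit-exactly.

## Data splitting

Records are sorted ascending by `log η` (stable ties) and every 9th
sorted record — the 9th, 18th, … — becomes the external test set
(⌊N/9⌋ ≈ 11%), never touched during fitting. The remainder is randomly
divided with a seeded shuffle so the training set holds 80% of the
*total* records, leaving ≈ 9% as the internal test set. Systematic
sampling over the sorted response keeps the external set
distributionally representative; the suite checks its ECDF against the
full data within Kolmogorov distance 2k/N. Sorting is joint over all
systems.

## Metrics and cross-validation

`R² = 1 − SS_res/SS_tot` (about the mean experimental `log η`; reported
as NaN when the experimental vector is constant), `RMSE` in decades,
and `AARD = (100/n) Σ |Δ_i / log η_exp,i|`. AARD's denominator vanishes
at η = 1 mPa·s; points with `|log η_exp| ≤ 1e−9` are excluded from the
AARD sum and counted in the report (logged as a warning). The residual
band summary counts `|residual| ≤ band` with a closed boundary.

Leave-one-system-out CV retrains on all records outside one system
(composition family) and scores `R²` on the held-out system; `Q²` is
the unweighted mean over systems — holding out whole systems probes the
descriptors, since the held-out composition is genuinely unseen.
Systems with fewer than two records or a constant response are excluded
with a warning.

## Applicability domain

The Williams plot uses the scaled nine-feature training matrix without
an intercept column (`d* = 9`): `h_i = v_i (VᵀV)⁻¹ v_iᵀ` (pseudo-inverse
with a warning if rank-deficient), critical leverage `h* = 3(d*+1)/p`
(the factor is an argument), and standardized residuals
`SDR_i = r_i / s` with `s` the sample standard deviation of the
*training* residuals for all splits, so external points are judged on
the training error scale. A point is inside when `h < h*` and
`|SDR| < 3`; coverage is the percentage inside over every record.
Exactly zero residual spread (a literally perfect fit) is refused
rather than divided by. For response-free queries (the `predict`
command) only the leverage boundary applies.

## PaD sensitivity

Gradients of the output with respect to each input are exact chain-rule
derivatives through the scalers and tanh layers, returned on the
physical input scale (or the scaled scale on request) and verified
against finite differences at 1e−6 relative. Relative contributions
square the *scaled* gradients, sum over the records (training split by
default) and normalize to 100% — squaring follows the established PaD
practice and makes the ranking sign- and unit-independent. The default
subset is S1..S8 so the molecular descriptors are compared among
themselves; a flag includes the temperature. An all-zero gradient
subset is an error rather than a 0/0.

## Synthetic generator

The generator stands in for curated experimental tables and profile
databases. Profiles are sums of two to four Gaussian peaks on the
31-point ±0.03 grid: every compound has a nonpolar peak near sigma = 0;
donors add a peak beyond −0.0075, acceptors beyond +0.0075; the salt
carries a strong acceptor (chloride-like) peak; cosolvents are small
water-like molecules (total area ≈ 40–60 Å² against 150–300 for the DES
components).

Viscosities follow `log10 η = A(S) + B(S)/(T − T0(S))` with A, B, T0
affine in the mixture descriptors, coefficients drawn once per
configuration and recorded as ground truth (B floored at 50 K·decades,
T0 capped 40 K below the coldest measurement so the law has no
singularity in range). A final affine recalibration — folded exactly
into (A, B) — maps the noiseless response span onto the configured
window, by default log10 of 0.3862–4722 mPa·s, the span of the real
choline-chloride databases. Noise is multiplicative lognormal on η,
i.e. additive Gaussian on `log10 η`, default σ = 0.02 decades.

The default study has 20 pure-DES systems and 45 DES + cosolvent
systems on a 9-temperature grid (283.15–363.15 K): most cosolvent
systems cover a low-to-moderate dilution window and every fifth extends
to deep dilution, mirroring real studies where only a few systems reach
water-like viscosity — 1557 records, the same order as the ~1900-point
experimental compilations. An `n_points` cap truncates
deterministically.

What the generator does *not* emulate: real sigma-profile fine
structure (multiple donor peaks, shoulders), inter-laboratory scatter
and systematic offsets between sources, correlated measurement error
within a temperature series, and the heavy concentration of real
measurements in a few intensively studied systems. Passing tests
therefore demonstrate that the pipeline recovers a smooth
descriptor-driven law under realistic noise and leverage structure —
not that the specific chemistry of any real DES is captured.

## Problem sizes and numerical choices

The test suite trains small networks (9-2-1 … 9-8-1) on 150–400-record
studies and the reference 9-19-16-1 network on a 1500-record study;
LOSO runs use ≤ 20 systems with compact architectures. The acceptance
script uses the same 1500-record study plus a 15-system LOSO study.
These sizes keep every result at the intended noise floor while a full
run of suite plus script completes in well under a minute of CPU.

Other numerics: leverage solves use Cholesky/inverse with a
pseudo-inverse fallback; the SPD Levenberg–Marquardt solves fall back
to least squares on factorization failure; residual standard deviations
use ddof = 1; the grid-search tie-break prefers fewer parameters, then
lower RMSE, then grid order; `ratio_to_fractions` validates parts > 0
and cosolvent fraction in [0, 1).

## Known limitations

- Exact reproduction of a specific published weight set is possible
  only by importing its weight table, not by retraining: the reference
  implementation's initialization and stopping internals are not
  public.
- AARD on `log η` is intrinsically heavy-tailed when data approach
  η = 1 mPa·s; the ε-exclusion guards division by ~0 but a record very
  close to the crossing can still dominate the statistic.
- The applicability domain is the Williams plot only; no kNN-distance
  or bounding-box alternatives.
- No uncertainty quantification beyond the evidence-framework γ; no
  bootstrap confidence intervals.
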