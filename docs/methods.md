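# Methods

This note records the models implemented in `agesel`, the numerical choices
behind them, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Age-of-expression statistics

**REA** is the OLS slope of log expression on sample age, computed over all
samples of a gene (each replicate is a point; age-group means would give the
identical slope in a balanced design but discard information otherwise).
The log transform makes expression differences relative; when raw counts are
supplied they are transformed as log(count + pseudocount) with pseudocount
1 by default — the base and pseudocount only rescale REA by a constant, and
both are recorded/configurable.  REA is invariant under adding a constant to
a gene's log expression and scales as 1/c when ages are scaled by c.

**Early/late classes.**  The lower cutoff is the type-1 (inverse-ECDF)
empirical quantile of the lower percentile (default 10); the upper cutoff is
the mirrored type-1 quantile taken from the top of the distribution, so the
two tails are treated symmetrically (with n genes and default percentiles,
each tail captures ceil(n/10) genes when REA values are distinct).  Ties at
a cutoff fall into the extreme class, making the labels deterministic.

**ΔR_NS** uses unweighted arithmetic means of per-gene dN/dS within the
early and late classes; it is antisymmetric under swapping the classes and
bounded in [−2, 2], hitting an endpoint when one class mean is zero.

**τ** requires non-negative (linear-scale) per-tissue means; it is 0 for a
flat profile, 1 for single-tissue expression, undefined (error) for an
all-zero profile, and invariant under scaling all tissues by a constant.

**pN/pS** is (poly_N/sites_N)/(poly_S/sites_S).  Genes with poly_S = 0 get
NaN — an explicit "undefined" flag, never +inf — and are dropped listwise
from analyses that use pN/pS while remaining available elsewhere.

## Poisson random field model

Nonsynonymous mutations arise at total rate μN per gene, synonymous at μS;
a fraction α_m of nonsynonymous mutations are beneficial with homozygote
effect +s and the rest deleterious with −s; heterozygotes are intermediate
(additive); synonymous mutations are neutral; sites evolve without selective
interference.  Site counts of each class are then independent Poisson
variables (which is also exactly how the synthetic generator samples them).

Expected polymorphic-site counts in a sample of m copies:

- n_S = 4NₑμS · H_{m−1} (the neutral frequency-spectrum integral
  ∫ [1 − p^m − (1−p)^m]/p dp evaluates to the harmonic sum; the identity is
  asserted numerically for m = 2…50),
- n_B, n_D = 4NₑμN · {α_m, 1−α_m} · I(±γ; m) with
  I(γ; m) = ∫₀¹ [1 − e^{−γ(1−p)}]/[(1 − e^{−γ}) p(1−p)] · [1 − p^m − (1−p)^m] dp.

Expected fixed-site counts between two species separated by t_div (units of
2Nₑ generations): F_S = 4NₑμS(t_div + 1/m + 1) and
F_{B,D} = 4NₑμN{α_m, 1−α_m} · f(±x) · [t_div + G(m) + G(1)] where
f(x) = x/(1 − e^{−x}) is the relative fixation factor and
G(n) = ∫₀¹ x^{n−1} [1 − e^{−xₛ(1−u)}]/(xₛ(1−u)) du.  For t_div ≫ 1 the
dN/dS ratio simplifies to the closed form
μN/μS · [α_m f(x) + (1−α_m) f(−x)].

Both ratios are independent of the scale 4NₑμS (checked over six orders of
magnitude), collapse to μN/μS as s → 0, and are invariant under the mirror
relabelling (α_m, s) ↔ (1−α_m, −s).

**gamma_convention.**  The polymorphism integrals are implemented with
exponent γ = 4·Nₑs while the fixation factors and the divergence limit use
Nₑs — each form exactly as stated in its source equation.  The two scalings
are not mutually reconciled there, and this package deliberately does not
guess a reconciliation: the single parameter `ne_s` is on the fixation
(Nₑs) scale and the sojourn integrals receive 4·`ne_s`.  Consumers
comparing against other PRF software should check which convention that
software uses.  The Wright–Fisher oracle is made consistent with the
polymorphism equations by mapping `ne_s` to a per-generation homozygote
coefficient s_wf = 2·ne_s/N (the sojourn exponent of additive selection
with homozygote effect s is 2Ns).

**Quadrature.**  Public scalar functions use adaptive quadrature (QUADPACK,
relative tolerance 1e-11) with integrands written in 0/0-free form: the
sojourn integrand tends to m at p → 0 and 0 at p → 1, and for γ < 0 the
ratio is rewritten as e^{γp}(1 − e^{γ(1−p)})/(1 − e^{γ}) so no exponent is
ever positive (no overflow at strong selection).  Cohort-scale code uses a
vectorised composite Gauss–Legendre rule (16 nodes per panel, panels
dyadically refined toward both endpoints down to 2⁻¹²) that resolves the
boundary layers of width ~1/|γ|; the tests pin its agreement with the
adaptive route to <1e-10 for |γ| up to 400.  Below |Nₑs| = 1e-6 every
factor is a 0/0 form and second-order series take over:
I(γ; m) ≈ H_{m−1} + (γ/2)(m−1)/(m+1), G(n) ≈ 1/n − Nₑs/(2n(n+1)),
f(x) ≈ 1 + x/2 + x²/12.

**Wright–Fisher oracle.**  A discrete diploid simulator with independent
sites: Poisson mutation influx 2Nμ per class per generation, binomial
resampling after deterministic additive selection, hypergeometric
subsampling of m copies at intervals of 2N generations after a 20N-generation
burn-in.  Standard errors come from batch means (blocks of 5 epochs) with a
delta-method SE for the N/S ratio.  It refuses populations above N = 200 and
per-genome rates above 1 — outside that envelope the run time and the
diffusion comparison both degrade.  Agreement with the quadrature
predictions is asserted within 3 Monte-Carlo SE; at N = 100 the residual
discretisation bias (diffusion is only O(1/N)-exact) is well inside that
band at the simulation lengths used (~600 epochs).

## Inverting the model

μN/μS is estimated per gene as sites_N/sites_S (equal per-site rates).
Observed per-site pN/pS and dN/dS are rescaled by that ratio onto the
model's count-ratio scale, and the divergence observable defaults to the
t_div-free limit (no per-species divergence time is needed); the full
finite-t_div model is available via `InferenceOptions(t_div=...)`.

The estimator exploits the fact that, at fixed Nₑs, both expected ratios
are linear in α_m.  Each observation therefore defines α_m(Nₑs) explicitly,
and solving the system reduces to finding a root of their difference in one
dimension.  A 48-point log-spaced scan over Nₑs ∈ [1e-6, 100] brackets sign
changes, brentq polishes each root to machine precision, and a root with
α_m ∈ [0, 1] is an exact solution.  When none exists the observations lie
outside the model's attainable set and a bounded least-squares fit (squared
log residuals, deterministic 8×8 multi-start grid, L-BFGS-B refinement from
the two best cells) reports the minimal-residual estimate flagged
`no_solution`.  The objective is on the log scale because both ratios are
positive and span decades.

Diagnostics: `converged` means the log-residual norm is below 1e-6 (an
exact interior root, or a fallback that still matched the data);
`neutral_alpha_unidentifiable` is set whenever N̂ₑs < 1e-4, where α_m has no
leverage on either observable; `boundary` marks genes whose zero observation
was floored at half the smallest positive observed value of that column
(keeping the gene's rank information without a −inf log); `no_solution`
marks unattainable observations.  With Poisson counting noise a sizeable
minority of genes land slightly outside the attainable set; their
minimal-residual estimates are still reported and carry rank information —
the plant-recover tests pass with those genes included.  No uncertainty
quantification is attempted (the statistical properties of these per-gene
estimators are unknown); there is no pooling across genes.

## Gene lifespan walk

Fitness moves up with probability α and down otherwise; loss occurs at −k.
The first-passage PGF is the classic gambler's-ruin generating function
raised to the k-th power; it is evaluated in the cancellation-free form
[2(1−α)z/(1 + √(1 − 4α(1−α)z²))]^k, algebraically identical to the textbook
expression (rationalise the numerator).  V(1) = 1 for α ≤ ½ and
((1−α)/α)^k above.  The expected substitution count V′(1) reduces — because
√(1 − 4α(1−α)) = 1 − 2α on the α < ½ branch — to exactly k/(1−2α), which
the implementation reproduces to 1e-10 across the parameter grid and the
Monte-Carlo walker confirms within sampling error.  For α ≥ ½ the mean
diverges and a `DivergentMeanError` is raised.  The expected extinction
time is exposed in two forms: the small-α approximation
(k/(r_B+r_D))(1 + 2r_B/(r_B+r_D)) (finite for all α < 1) and the exact
composition k/((r_B+r_D)(1−2α)) (α < ½ only); both appear in the returned
pair, and the PGF dummy variable is named z to avoid colliding with the
selection coefficient.  The Monte-Carlo walker generates steps in blocks of
256 with a 10⁷-step cap and reports censoring — near α = ½ absorption times
are heavy-tailed.

## Synthetic cohorts

The generator plants exactly the structure the inference assumes, making
parameter recovery a clean test:

- REA_i ~ Normal(0, 1) by default (the empirical REA distribution is
  unknown; the shape is configurable, with a uniform alternative built in,
  and the unit-SD scale makes the map coefficients below directly
  interpretable).
- log expression = baseline + REA_i·age + Normal(0, 1), baseline ~
  Normal(5, 1.5) (log-normal expression levels), over 5 ages × 3 replicates
  (a whole-body design with three replicate pools at five adult ages);
  optional per-gene tissue offsets default to zero so the stated expression
  model holds exactly.
- Nₑs_i = exp(0.5 − 0.5·REA_i) — positive by construction, declining with
  REA (the selection-shadow direction); α_m,i = logistic(−2 + REA_i) ∈
  (0, 1), rising with REA.
- Site counts: Poisson draws around the forward-model expectations
  (polymorphism from the sojourn integrals; divergence from the full
  finite-t_div expressions at t_div = 10, i.e. divergence old enough that
  the t_div-free limit used by the default estimator is a good but not
  exact description — the deliberate, mild model mismatch keeps the
  plant-recover tests honest).  Defaults sites_N = 1000, sites_S = 300
  (a typical protein-coding gene with μN/μS ≈ 3.3), θ_S = 20 per gene,
  m = 40 sampled copies — counts large enough to be informative while
  staying safely below the site totals.
- Gene age ~ Exponential with mean equal to the walk model's approximate
  expected extinction time at rates r_B ∝ α_m·f(x), r_D ∝ (1−α_m)·f(−x)
  (k = 10): the simplest generative story consistent with the lifespan
  model, and finite for every gene because the small-α form is used.

Identical configuration (including the seed) gives byte-identical output.

**What passing tests do and do not show.**  The generator omits linkage and
interference, demography, per-gene mutation-rate variation, expression
measurement structure (batch, probe, library-size effects), circadian
sampling artefacts, and any GO/annotation structure; counts are Poisson by
construction, matching the inference model exactly.  Recovery on these
cohorts therefore validates the implementation and the statistical
identifiability of the planted maps — not the model's adequacy for any real
species.

## Problem sizes

The reference analyses use 2000-gene cohorts (the plant-recover check runs
20 seeds of those); null calibration uses 500 replicates of 150-gene
cohorts; the Wright–Fisher oracle runs 120,000 generations at N = 100 per
parameter set; Monte-Carlo walks use 10⁵ draws.  These sizes give
comfortable separation between signal and Monte-Carlo error for every
assertion made.

## Known limitations

- The two-point ±s effect distribution has no dominance parameter and no
  continuous DFE; the walk model has constant α and s along a gene's life.
- The exponent-convention tension described under `gamma_convention` is
  surfaced, not resolved.
- Per-gene estimates are point estimates; flags are the only uncertainty
  signal.
- The tissue "random factor" of mixed-model analyses is approximated by
  fixed per-tissue intercepts — identical for removing tissue means, but it
  does not shrink across tissues and changes the df accounting.
- `estimate_table` floors zero observations using the observed minimum of
  the column, which couples one gene's floor to the rest of the table;
  floored genes are flagged so they can be excluded.
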