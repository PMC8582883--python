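# Methods

## Model

`hetlogit` fits a four-category discrete-outcome model for crash injury
severity (no injury / minor / severe / fatal, with no injury as the
baseline because it is the most frequent outcome and anchoring the model
there stabilizes estimation).  Each severity level `i` of crash `k` has a
linear severity function

    F_ik = beta_ik' X_ik + eps_ik

with i.i.d. extreme-value disturbances, so that conditional on the
coefficients the outcome probabilities are multinomial logit with the
baseline's function fixed at zero.  Coefficients may be *random across
crashes*: a random coefficient realizes as

    beta_ik = beta + theta' Z_k + sigma * exp(omega' W_k) * gamma_k,
    gamma_k ~ N(0, 1),

so covariates `Z` shift its mean linearly (slopes `theta`) and covariates
`W` scale its standard deviation multiplicatively through the exponential
(slopes `omega`).  Only the normal mixing distribution is implemented;
it is the form retained in the empirical literature this model family
comes from, and supporting a single mixing family keeps the variance
heterogeneity interpretable.  The unconditional choice probability
integrates the logit kernel over the mixing distribution.

## Simulated likelihood and draws

The mixing integral is simulated: per crash, the logit kernel is averaged
over `R` standard-normal draws obtained from prime-base Halton
(radical-inverse) sequences pushed through the inverse normal CDF
(`scipy.special.ndtri`).  The default is `R = 200` draws per crash, a
standard operating point at which Halton sequences achieve the accuracy of
far larger pseudo-random samples.  Conventions the sequence itself does
not fix, chosen once and documented here:

- random slot `q` uses the `q`-th prime base (2, 3, 5, ...);
- the first 10 points of each sequence are discarded (`burn = 10`),
  removing the degenerate early run of small fractions;
- the per-slot stream is partitioned consecutively across crashes
  (crash `k` gets points `k·R+1 … (k+1)·R` after the burn-in), the
  partitioning used in standard treatments of simulated mixed logit;
- no scrambling or shifting.

There is no random state anywhere in the draw engine: the same settings
reproduce the bit-identical matrix, and the same draw block is used for
every candidate parameter vector during optimization (common draws), which
keeps the simulated objective smooth.  Simulation error at fixed
parameters decays with `R` overall but not strictly monotonically from one
doubling to the next; the test suite asserts the overall decay only.

## Estimation

The simulated log-likelihood is maximized with BFGS
(`scipy.optimize.minimize`).  The gradient is computed analytically from
the per-draw kernel probabilities; it is verified against central finite
differences in the test suite.  (Numeric-only gradients would work but
cost `2p` likelihood sweeps per iteration; the analytic score makes the
recovery and calibration studies run in minutes on one core.)

- Starting values: alternative-specific constants at their saturated
  log-odds, base SDs at 0.1, everything else 0.  The three-model ladder
  (no heterogeneity → heterogeneity in means → heterogeneity in means and
  variances) is fitted sequentially with warm starts: each restricted
  member initializes the next member's shared parameters by name.
- `sigma` is estimated unconstrained and reported in absolute value; its
  sign is not identified under normal mixing.
- Standard errors: inverse of the negative numerical Hessian (central
  differences of the analytic score, relative step `1e-5`); when that is
  singular or yields non-positive variances, a BHHH outer-product-of-scores
  fallback is used and recorded in `se_method`; if both fail, SEs are
  reported undefined with a warning.
- Convergence: optimizer success, or a sup-norm gradient below `1e-3` —
  BFGS occasionally reports precision loss at an otherwise converged
  point.  Non-convergence is always flagged on the results object.
- Retention screening follows the 90% two-tailed convention: parameters
  (including base SDs) with `|t| < 1.645` are flagged for removal; the
  screen reports, a human or config decides.

Degenerate cases: with no random slots the model collapses to closed-form
multinomial logit (`R` is ignored); utilities are max-stabilized before
exponentiation; simulated probabilities are floored at the smallest
positive double before the log; non-finite utilities (wild parameters
mid-line-search) return a large penalty rather than NaN.

## Model comparison and transfer tests

Fit metrics use the standard formulas against the constants-only
log-likelihood `LL0 = Σ n_i ln(n_i/n)`: McFadden `ρ² = 1 − LL/LL0`,
adjusted `ρ² = 1 − (LL−K)/LL0`, `AIC = 2K − 2LL`, `BIC = K ln n − 2LL`.
Published tables in this literature occasionally print metric values
mutually inconsistent with their own log-likelihoods; this package always
recomputes from the definitions above.

Two chi-square likelihood-ratio tests compare a pooled model with
period-specific ones:

- *separation*: `LR = −2[LL(pooled) − LL(a) − LL(b)]`,
  `df = K_a + K_b − K_pooled`;
- *transferability*: `LR = −2[LL(params_a on data_b) − LL(b)]`, `df` equal
  to the parameter count — the restricted likelihood pins the parameters
  at the other period's converged estimates.  (Descriptions of this test
  are sometimes worded ambiguously; this restricted-versus-refit form is
  the one that is chi-square under the null and yields a statistic of
  exactly zero when both fits see the same data.)  Note the convention
  treats the donor period's estimates as fixed values: with two
  equal-sized samples from the same process the statistic concentrates
  around twice its nominal df, so the test is strict by construction —
  the standard behaviour of this test as used in the applied literature.

Statistics negative beyond `1e-4` raise a diagnostics error (they signal a
non-converged restricted fit); smaller negatives are clipped to zero.

## Post-estimation

Marginal effects for a binary indicator are average discrete changes:
`mean_k [P(i | c←1) − P(i | c←0)]` over the estimation sample with all
other covariates at observed values, toggling the indicator everywhere it
appears — own slots and Z/W links alike.  Effects per covariate sum to
zero across the four levels by construction.  Effects are evaluated at the
point estimates only; no delta-method SEs (this mirrors how such tables
are usually reported).

Random-coefficient summaries at a covariate profile report the
conditional mean `beta + theta'Z`, the conditional SD
`sigma·exp(omega'W)`, and the share of the population with a negative
coefficient, `Φ(−mean/SD)`.  A second variance figure,
`sigma² + Σ omega·W`, is emitted as `additive_variance`: it is an additive
*reporting convention* seen in applied papers, not the model's conditional
variance, and is labelled as such.  Published shares in the source
literature for given (mean, SD) pairs do not always equal `Φ(−mean/SD)`;
this package always reports the recomputed value.

## Synthetic data generator

The generator draws indicator covariates as independent Bernoulli
variables, one `gamma` per crash and random slot from a seeded
pseudo-random normal stream (deliberately not Halton, so generation and
estimation draws are independent by construction), realizes coefficients
exactly per the model equation, and samples the outcome from the logit
probabilities at the realized coefficients.  The manifest records the
config, seed, realized `gamma`s and per-crash probabilities, making every
generated dataset fully reproducible and auditable.

The default configuration mirrors a fitted urban automobile–e-bicycle
crash model: 20 indicators with registry-typical frequencies (e.g. 0.79
road-segment crashes, 0.18 traffic control, visibility bands at 0.20/0.23)
and the mean–variance specification's coefficient values, including two
random visibility coefficients.  What the generator does **not** emulate:
covariate correlation (real crash indicators are correlated; here they are
independent by default), temporal or spatial structure, and any
registry-specific selection effects.  Passing recovery tests therefore
demonstrates the estimator is correct *under the model's own assumptions*,
not that the model is correct for any particular registry.

## Verification study sizes

Chosen as the package's own operating points:

- parameter recovery: 5 replicates of n = 5000 crashes at R = 200 draws
  for a model with one random slot, one mean link, one variance link and
  four fixed covariate slots; recovery is scored as the share of
  (parameter, replicate) pairs within 3 reported SEs of truth
  (target ≥ 90%).  The harness uses balanced ~0.5-prevalence link
  covariates — the information-maximizing design for binary indicators —
  and deliberately places several fixed covariates in the random slot's
  own severity function.  That within-cell utility variation is what
  identifies the normal mixture: with binary indicators only, a spec
  whose random-slot function holds nothing but the random coefficient
  and its links defines so few covariate cells that the degenerate
  latent-class boundary (mean, SD → ∞ at fixed ratio) can saturate the
  cell frequencies and weakly dominate the interior optimum — a property
  of that design, not of the estimator.  Fits whose parameters run
  beyond magnitude 1e3 are flagged non-converged for this reason.
- likelihood-ratio calibration: 50 replicates of two n = 500 periods
  under a shared fixed-coefficient process (8 parameters); the separation
  statistic's mean is compared with its df.  Power uses a +1.0 shift on
  one coefficient.
- oracle comparisons: closed-form MNL collapse to 1e−8 per evaluation;
  one-random-coefficient probabilities within 0.005 of a 64-node
  Gauss–Hermite quadrature.

## Known limitations

- No correlated random parameters (no Cholesky cross-terms) and no panel
  likelihood: each crash is one observation.
- Binary covariates only in v1; no continuous regressors or automatic
  interactions.
- Maximum simulated likelihood can, on samples where the mixture is
  weakly identified (sparse covariate cells, see above), converge to an
  alternate mode — near-zero base SD with inflated variance links, or
  the latent-class boundary; the ladder warm starts and the divergence
  flag mitigate but do not eliminate this.
- The retention screen and ladder are reporting/diagnostic tools; no
  automated specification search is performed.
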