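"""Post-estimation quantities.

Marginal effects for binary indicators (average discrete change in each
severity probability when an indicator toggles 0→1), normal-distribution
summaries of random coefficients under a covariate profile, and density
grids for plotting those distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import SEVERITY_LABELS
from .model import MixedLogit, MixedLogitResults


def marginal_effects(results: MixedLogitResults) -> pd.DataFrame:
    """Average discrete-change marginal effects for every covariate.

    For covariate ``c`` and severity level ``i`` the effect is the mean
    over crashes (and draws) of ``P(i | c=1) - P(i | c=0)`` with all
    other covariates at their observed values.  A covariate also acting
    through mean/variance heterogeneity links is toggled there too.  By
    construction each covariate's effects sum to zero across the four
    levels.  Covariates absent from the model yield structural-zero rows.

    Returns a DataFrame indexed by covariate with one column per
    severity label, plus an ``in_model`` flag.
    """
    model = results.model
    params = results.params_raw
    used = set(model.spec.covariates_used())
    rows = {}
    in_model = {}
    for cov in model.dataset.covariate_names:
        if cov not in used:
            rows[cov] = np.zeros(4)
            in_model[cov] = False
            continue
        p1 = _probabilities_with(model, params, cov, 1)
        p0 = _probabilities_with(model, params, cov, 0)
        rows[cov] = (p1 - p0).mean(axis=0)
        in_model[cov] = True
    out = pd.DataFrame.from_dict(rows, orient="index", columns=[SEVERITY_LABELS[c] for c in (1, 2, 3, 4)])
    out["in_model"] = pd.Series(in_model)
    return out


def _probabilities_with(model: MixedLogit, params: np.ndarray, cov: str, value: int) -> np.ndarray:
    counter = MixedLogit(
        model.dataset.with_covariate_set(cov, value),
        model.spec,
        draws=model.draws,
        n_draws=model.n_draws,
    )
    return counter.probabilities(params)


@dataclass(frozen=True)
class RandomParamSummary:
    """A random coefficient's normal distribution at a covariate profile.

    ``mean`` and ``sd`` are the conditional moments implied by the
    estimated model (``sd = sigma * exp(omega' W)``);
    ``share_below_zero`` is Φ(−mean/sd), the population share with a
    negative coefficient.  ``additive_variance`` is the additive
    reporting convention ``sigma² + Σ omega·W`` sometimes used to
    summarize variance heterogeneity — it is *not* the model's
    conditional variance (that is ``sd²``) and is emitted only for
    comparability with reports using that convention.
    """

    covariate: str
    severity: str
    profile: dict[str, float]
    mean: float
    sd: float
    share_below_zero: float
    additive_variance: float


def random_param_summary(
    results,
    covariate: str,
    severity,
    profile: Mapping[str, float] | None = None,
) -> RandomParamSummary:
    """Summarize a random coefficient's distribution at a Z/W profile.

    ``results`` may be a fitted :class:`MixedLogitResults` or a bare
    :class:`~hetlogit.spec.CoefficientSet`.  ``profile`` maps
    link-covariate names to 0/1 settings; unlisted links default to 0
    and entries naming covariates that are not links of this slot are
    ignored with a warning.
    """
    coeffs = results.coefficients if isinstance(results, MixedLogitResults) else results
    spec = coeffs.spec
    keys = [(r.slot.covariate, r.slot.severity) for r in spec.random_slots]
    from .spec import _as_code

    sev_code = _as_code(severity)
    if (covariate, sev_code) not in keys:
        raise ValueError(f"{covariate!r} at severity {severity!r} is not a random slot")
    q = keys.index((covariate, sev_code))
    rspec = spec.random_slots[q]
    profile = dict(profile or {})
    linked = set(rspec.mean_covariates) | set(rspec.variance_covariates)
    extra = sorted(set(profile) - linked)
    if extra:
        warnings.warn(f"profile entries ignored (not links of this slot): {extra}")
    mu = coeffs.random_mean(covariate, sev_code)
    for z in rspec.mean_covariates:
        mu += coeffs.theta(covariate, sev_code, z) * float(profile.get(z, 0))
    sigma = coeffs.random_sd(covariate, sev_code)
    wlin = 0.0
    add = sigma**2
    for w in rspec.variance_covariates:
        wval = float(profile.get(w, 0))
        wlin += coeffs.omega(covariate, sev_code, w) * wval
        add += coeffs.omega(covariate, sev_code, w) * wval
    sd = sigma * np.exp(wlin)
    share = float(norm.cdf(-mu / sd)) if sd > 0 else float(mu < 0)
    return RandomParamSummary(
        covariate=covariate,
        severity=SEVERITY_LABELS[sev_code],
        profile={k: float(v) for k, v in profile.items() if k in linked},
        mean=float(mu),
        sd=float(sd),
        share_below_zero=share,
        additive_variance=float(add),
    )


def density_curve(
    results,
    covariate: str,
    severity,
    profile: Mapping[str, float] | None = None,
    n_points: int = 201,
) -> tuple[np.ndarray, np.ndarray]:
    """Normal density of a random coefficient on a mean ± 4·SD grid.

    Returns ``(grid, density)``; a zero conditional SD degenerates to a
    single point mass ``([mean], [1.0])``.
    """
    s = random_param_summary(results, covariate, severity, profile)
    if s.sd == 0:
        return np.array([s.mean]), np.array([1.0])
    grid = np.linspace(s.mean - 4 * s.sd, s.mean + 4 * s.sd, n_points)
    return grid, norm.pdf(grid, loc=s.mean, scale=s.sd)
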