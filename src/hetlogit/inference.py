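"""Likelihood-ratio tests between fitted severity models.

Two tests decide whether a data subset (e.g. the peak traffic period)
warrants its own model:

* **separation** — compares a pooled fit against the two subset fits,
  ``LR = -2 [LL(pooled) - LL(a) - LL(b)]`` with
  ``df = K_a + K_b - K_pooled``;
* **transferability** — evaluates one subset's converged parameters on
  the other subset's data against a free refit on that data,
  ``LR = -2 [LL(params_a on b) - LL(b)]`` with df equal to the number
  of estimated parameters.

Both statistics are chi-square distributed under the null of a common
parameter structure; p-values use the upper-tail survival function.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .model import MixedLogitResults

#: LR statistics may come out very slightly negative through optimizer
#: slop; anything below this magnitude is clipped to zero, anything
#: beyond it raises, since it signals a non-converged restricted fit.
LR_TOLERANCE = 1e-4


class DiagnosticsError(RuntimeError):
    """An LR statistic is negative beyond optimizer tolerance."""


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    p_value: float
    kind: str  # separation | transferability | nested_ladder

    def significant(self, alpha: float = 0.01) -> bool:
        return self.p_value < alpha


def _check_stat(stat: float, kind: str, tol: float) -> float:
    if stat < -tol:
        raise DiagnosticsError(
            f"{kind} LR statistic is {stat:.6g} < 0 beyond tolerance; "
            "check convergence of the restricted fit"
        )
    return max(stat, 0.0)


def _require_same_structure(a: MixedLogitResults, b: MixedLogitResults) -> None:
    if a.spec.param_names != b.spec.param_names:
        raise ValueError("fits do not share the same parameter structure")


def lr_separation(
    overall: MixedLogitResults,
    part_a: MixedLogitResults,
    part_b: MixedLogitResults,
    tol: float = LR_TOLERANCE,
) -> LRTestResult:
    """Model separation test: should the two periods be modeled apart?

    All three fits must share the same variable structure; the overall
    fit must be on the union of the two parts' data.
    """
    _require_same_structure(overall, part_a)
    _require_same_structure(overall, part_b)
    if overall.nobs != part_a.nobs + part_b.nobs:
        raise ValueError(
            "overall fit must cover the union of the two parts "
            f"({overall.nobs} != {part_a.nobs} + {part_b.nobs})"
        )
    stat = -2.0 * (overall.llf - part_a.llf - part_b.llf)
    stat = _check_stat(stat, "separation", tol)
    df = part_a.n_params + part_b.n_params - overall.n_params
    return LRTestResult(stat, df, float(chi2.sf(stat, df)), "separation")


def lr_transferability(
    fit_a: MixedLogitResults,
    fit_b: MixedLogitResults,
    tol: float = LR_TOLERANCE,
) -> LRTestResult:
    """Parameter transferability test of a's estimates on b's data.

    ``fit_b`` is the same specification freely re-estimated on the
    other period's data; the restricted log-likelihood fixes the
    parameters at ``fit_a``'s converged values and evaluates them on
    b's data.  Identical data in both fits gives a statistic of zero.
    """
    _require_same_structure(fit_a, fit_b)
    ll_ab = fit_b.model.loglike(fit_a.params_raw)
    stat = _check_stat(-2.0 * (ll_ab - fit_b.llf), "transferability", tol)
    df = fit_a.n_params
    return LRTestResult(stat, df, float(chi2.sf(stat, df)), "transferability")


def lr_nested(restricted: MixedLogitResults, full: MixedLogitResults) -> LRTestResult:
    """LR test between two nested ladder members (e.g. means-only
    heterogeneity against means and variances)."""
    df = full.n_params - restricted.n_params
    if df < 1:
        raise ValueError("full model must have more parameters than restricted")
    stat = _check_stat(-2.0 * (restricted.llf - full.llf), "nested_ladder", LR_TOLERANCE)
    return LRTestResult(stat, df, float(chi2.sf(stat, df)), "nested_ladder")
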