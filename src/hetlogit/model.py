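"""Mixed (random-parameters) multinomial logit with heterogeneity in
means and variances, estimated by maximum simulated likelihood.

Model
-----
Crash ``k`` has a severity function for each level ``i``::

    F_ik = beta_ik' X_ik + eps_ik,      eps_ik iid extreme value,

with the baseline level's function constrained to zero.  A random
coefficient realizes, per crash and draw, as::

    beta_ik = beta + theta' Z_k + sigma * exp(omega' W_k) * gamma,
    gamma ~ N(0, 1),

so covariates Z shift the coefficient's mean and covariates W scale its
standard deviation.  The choice probability integrates the logit kernel
over the mixing distribution; it is simulated by averaging the kernel
over R standard-normal Halton draws per crash (common draws across all
candidate parameter vectors, which keeps the simulated objective smooth).

The log-likelihood gradient is computed analytically; standard errors
come from the inverse negative numerical Hessian at the optimum, with a
BHHH outer-product fallback when the Hessian is ill-conditioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .data import SEVERITY_CODES, SEVERITY_LABELS, CrashDataset
from .draws import DrawsMatrix, build_draws
from .spec import CoefficientSet, ModelSpec

_LL_PENALTY = -1e12
_PROB_FLOOR = np.finfo(np.float64).tiny


def realize_coefficients(
    params: CoefficientSet,
    record: Mapping[str, float],
    gamma: Sequence[float],
) -> dict[str, float]:
    """Realize every slot coefficient for one crash.

    ``record`` maps covariate name to its 0/1 value; ``gamma`` supplies
    one standard-normal deviate per random slot (declaration order).
    Fixed slots return their estimate unchanged; random slot ``q``
    returns ``beta_q + theta' Z + sigma_q * exp(omega' W) * gamma_q``.
    Setting ``gamma = 0`` yields the crash's conditional coefficient
    mean — e.g. a base mean of −2.117 with a mean-shift of −1.347 on an
    active link covariate realizes as −3.464.
    """
    spec = params.spec
    v = params.values
    out: dict[str, float] = {}
    for j, slot in enumerate(spec.fixed_slots):
        out[slot.name] = float(v[spec.sl_fixed.start + j])
    gamma = np.asarray(gamma, dtype=np.float64)
    if gamma.shape != (spec.n_random,):
        raise ValueError(f"expected {spec.n_random} gamma values")
    for q, r in enumerate(spec.random_slots):
        mean = v[spec.sl_rmean.start + q]
        for z in r.mean_covariates:
            mean += v[spec.theta_index(q, z)] * float(record[z])
        wlin = 0.0
        for w in r.variance_covariates:
            wlin += v[spec.omega_index(q, w)] * float(record[w])
        sigma = v[spec.sl_rsd.start + q]
        out[r.slot.name] = float(mean + sigma * np.exp(wlin) * gamma[q])
    return out


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit summary relative to the constants-only model.

    ``mcfadden_rho2 = 1 - LL/LL0``; the adjusted variant subtracts the
    parameter count from the numerator log-likelihood;
    ``aic = 2K - 2LL``; ``bic = K ln(n) - 2LL``.
    """

    mcfadden_rho2: float
    adjusted_rho2: float
    aic: float
    bic: float
    ll: float
    ll_null: float
    n_params: int
    n_obs: int


class MixedLogit:
    """Random-parameters multinomial logit model for a crash dataset.

    Parameters
    ----------
    dataset : CrashDataset
        Outcomes and binary covariates, one row per crash.
    spec : ModelSpec
        Which covariates enter which severity function, as fixed or
        random coefficients, with their heterogeneity links.
    n_draws : int
        Halton draws per crash for the simulated probabilities
        (default 200).  Ignored when the spec has no random slots, in
        which case probabilities are exact closed-form logit.
    burn : int
        Initial Halton points discarded per sequence (default 10).
    draws : DrawsMatrix, optional
        Pre-built draw matrix (must match ``n`` and the number of
        random slots); overrides ``n_draws``/``burn``.
    """

    def __init__(
        self,
        dataset: CrashDataset,
        spec: ModelSpec,
        n_draws: int = 200,
        burn: int = 10,
        draws: DrawsMatrix | None = None,
    ):
        spec.validate_against(dataset)
        self.dataset = dataset
        self.spec = spec
        self.n = dataset.n
        if spec.n_random == 0:
            self.draws = None
            self.n_draws = 1
        elif draws is not None:
            if draws.n != self.n or draws.n_random != spec.n_random:
                raise ValueError("supplied draws do not match dataset/spec")
            self.draws = draws
            self.n_draws = draws.n_draws
        else:
            self.draws = build_draws(self.n, n_draws, spec.n_random, burn)
            self.n_draws = n_draws
        self._build_design()
        self._cache_key: bytes | None = None
        self._cache_val: tuple[float, np.ndarray] | None = None

    # ------------------------------------------------------------------
    def _build_design(self) -> None:
        spec, ds = self.spec, self.dataset
        self._row_of = {code: code - 1 for code in SEVERITY_CODES}
        self._y_row = np.array([self._row_of[c] for c in ds.outcome])
        self._obs_idx = np.arange(self.n)
        # fixed part grouped by severity row
        cols: dict[int, list[int]] = {}
        for j, slot in enumerate(spec.fixed_slots):
            cols.setdefault(slot.severity, []).append(j)
        self._fixed_groups = []
        for sev, idxs in cols.items():
            X = np.column_stack([ds.covariate_array(spec.fixed_slots[j].covariate) for j in idxs])
            pidx = np.array([spec.sl_fixed.start + j for j in idxs])
            self._fixed_groups.append((self._row_of[sev], X, pidx))
        self._const_rows = np.array([self._row_of[l] for l in spec.nonbase_levels])
        # random slots
        self._rand = []
        for q, r in enumerate(spec.random_slots):
            x = ds.covariate_array(r.slot.covariate)
            Z = (
                np.column_stack([ds.covariate_array(z) for z in r.mean_covariates])
                if r.mean_covariates
                else np.empty((self.n, 0))
            )
            W = (
                np.column_stack([ds.covariate_array(w) for w in r.variance_covariates])
                if r.variance_covariates
                else np.empty((self.n, 0))
            )
            tidx = np.array([spec.theta_index(q, z) for z in r.mean_covariates], dtype=int)
            widx = np.array([spec.omega_index(q, w) for w in r.variance_covariates], dtype=int)
            self._rand.append(
                {
                    "row": self._row_of[r.slot.severity],
                    "x": x,
                    "Z": Z,
                    "W": W,
                    "theta_idx": tidx,
                    "omega_idx": widx,
                    "mean_idx": spec.sl_rmean.start + q,
                    "sd_idx": spec.sl_rsd.start + q,
                    "q": q,
                }
            )

    # ------------------------------------------------------------------
    def _utilities(self, params: np.ndarray) -> np.ndarray:
        """Utility array of shape (4 levels, n, R); baseline row is 0."""
        n, R = self.n, self.n_draws
        Vfix = np.zeros((4, n))
        Vfix[self._const_rows] += params[self.spec.sl_const][:, None]
        for row, X, pidx in self._fixed_groups:
            Vfix[row] += X @ params[pidx]
        V = np.broadcast_to(Vfix[:, :, None], (4, n, R)).copy()
        with np.errstate(over="ignore", invalid="ignore"):
            for rd in self._rand:
                mean = params[rd["mean_idx"]] + (
                    rd["Z"] @ params[rd["theta_idx"]] if rd["Z"].shape[1] else 0.0
                )
                wlin = rd["W"] @ params[rd["omega_idx"]] if rd["W"].shape[1] else np.zeros(n)
                scale = params[rd["sd_idx"]] * np.exp(wlin)
                gamma = self.draws.values[:, :, rd["q"]]
                coef = np.atleast_1d(mean)[:, None] + scale[:, None] * gamma
                V[rd["row"]] += coef * rd["x"][:, None]
        return V

    def _kernel(self, params: np.ndarray):
        """Per-draw choice probabilities; None signals non-finite utilities."""
        V = self._utilities(params)
        if not np.isfinite(V).all():
            return None
        Vmax = V.max(axis=0)
        with np.errstate(under="ignore"):
            E = np.exp(V - Vmax)
            P = E / E.sum(axis=0)
        return P  # (4, n, R)

    def probabilities(self, params: np.ndarray | CoefficientSet) -> np.ndarray:
        """Simulated choice probabilities, shape (n, 4), columns in
        severity-code order 1..4; each row sums to one."""
        params = self._vec(params)
        P = self._kernel(params)
        if P is None:
            raise FloatingPointError("non-finite utilities at these parameters")
        return P.mean(axis=2).T

    def per_draw_probabilities(self, params: np.ndarray | CoefficientSet) -> np.ndarray:
        """Per-draw probabilities, shape (n, R, 4)."""
        P = self._kernel(self._vec(params))
        if P is None:
            raise FloatingPointError("non-finite utilities at these parameters")
        return np.moveaxis(P, 0, 2)

    def _vec(self, params) -> np.ndarray:
        if isinstance(params, CoefficientSet):
            return params.values
        v = np.asarray(params, dtype=np.float64)
        if v.shape != (self.spec.n_params,):
            raise ValueError(f"expected {self.spec.n_params} parameters")
        return v

    # ------------------------------------------------------------------
    def _eval(self, params: np.ndarray, want_obs: bool = False):
        """Simulated log-likelihood, analytic score and (optionally) the
        per-observation score matrix."""
        n, R = self.n, self.n_draws
        P = self._kernel(params)
        p = self.spec.n_params
        if P is None:
            return _LL_PENALTY, np.zeros(p), np.zeros((n, p))
        Py = P[self._y_row, self._obs_idx, :]  # (n, R)
        Pbar = np.maximum(Py.mean(axis=1), _PROB_FLOOR)
        ll = float(np.log(Pbar).sum())
        # score: A_i(k,r) = B(k,r) * (1[i==y_k] - P_i(k,r)),
        # B = P_y / (R * Pbar); fixed-parameter scores need only sum_r A.
        B = Py / (R * Pbar[:, None])
        T = (B[None, :, :] * P).sum(axis=2)  # (4, n)
        Arow = -T
        Arow[self._y_row, self._obs_idx] += B.sum(axis=1)
        S = np.zeros((n, p))
        S[:, self.spec.sl_const] = Arow[self._const_rows].T
        for row, X, pidx in self._fixed_groups:
            S[:, pidx] = X * Arow[row][:, None]
        for rd in self._rand:
            a = Arow[rd["row"]] * rd["x"]
            S[:, rd["mean_idx"]] = a
            if rd["Z"].shape[1]:
                S[:, rd["theta_idx"]] = rd["Z"] * a[:, None]
            wlin = rd["W"] @ params[rd["omega_idx"]] if rd["W"].shape[1] else np.zeros(n)
            e = np.exp(wlin)
            gamma = self.draws.values[:, :, rd["q"]]
            ind = (self._y_row == rd["row"]).astype(np.float64)
            Aq = B * (ind[:, None] - P[rd["row"]])
            G = (Aq * gamma).sum(axis=1) * rd["x"] * e  # (n,)
            S[:, rd["sd_idx"]] = G
            if rd["W"].shape[1]:
                S[:, rd["omega_idx"]] = rd["W"] * (params[rd["sd_idx"]] * G)[:, None]
        grad = S.sum(axis=0)
        return ll, grad, (S if want_obs else None)

    def loglike(self, params: np.ndarray | CoefficientSet) -> float:
        """Simulated log-likelihood Σ_k ln P̂_k(outcome_k)."""
        return self._eval(self._vec(params))[0]

    def loglike_obs(self, params: np.ndarray | CoefficientSet) -> np.ndarray:
        """Per-crash log simulated probability of the observed outcome."""
        P = self._kernel(self._vec(params))
        if P is None:
            raise FloatingPointError("non-finite utilities at these parameters")
        Py = P[self._y_row, self._obs_idx, :].mean(axis=1)
        return np.log(np.maximum(Py, _PROB_FLOOR))

    def score(self, params: np.ndarray | CoefficientSet) -> np.ndarray:
        """Analytic gradient of the simulated log-likelihood."""
        return self._eval(self._vec(params))[1]

    def score_obs(self, params: np.ndarray | CoefficientSet) -> np.ndarray:
        """Per-observation score matrix, shape (n, n_params)."""
        return self._eval(self._vec(params), want_obs=True)[2]

    def loglike_null(self) -> float:
        """Constants-only log-likelihood at its analytic optimum,
        Σ_i n_i ln(n_i / n)."""
        counts = np.array(list(self.dataset.severity_counts().values()), dtype=float)
        pos = counts[counts > 0]
        return float(np.sum(pos * np.log(pos / self.n)))

    def start_params(self) -> np.ndarray:
        """Default starting values: constants at the saturated log odds
        versus the baseline, base SDs at 0.1, everything else 0."""
        x0 = np.zeros(self.spec.n_params)
        counts = self.dataset.severity_counts()
        nb = counts[self.spec.baseline]
        for i, lvl in enumerate(self.spec.nonbase_levels):
            x0[i] = np.log((counts[lvl] + 0.5) / (nb + 0.5))
        x0[self.spec.sl_rsd] = 0.1
        return x0

    # ------------------------------------------------------------------
    def _cached(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        key = x.tobytes()
        if key != self._cache_key:
            ll, grad, _ = self._eval(x)
            self._cache_key, self._cache_val = key, (ll, grad)
        return self._cache_val

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 1000,
        gtol: float = 1e-5,
    ) -> "MixedLogitResults":
        """Maximize the simulated log-likelihood (BFGS, analytic score).

        Non-convergence within the iteration cap is reported through
        ``converged=False`` on the results object, never silently.
        """
        x0 = np.asarray(start_params, dtype=float) if start_params is not None else self.start_params()
        # BFGS line searches can stall with "precision loss" on simulated
        # objectives; restarting from the stalled point with a fresh
        # Hessian approximation usually recovers
        for _ in range(3):
            res = optimize.minimize(
                lambda x: -self._cached(x)[0],
                x0,
                jac=lambda x: -self._cached(x)[1],
                method="BFGS",
                options={"gtol": gtol, "maxiter": maxiter},
            )
            if res.success or float(np.abs(res.jac).max()) < max(gtol * 100, 1e-3):
                break
            if np.allclose(res.x, x0):
                break
            x0 = res.x
        ll, grad, _ = self._eval(res.x)
        converged = bool(res.success) or float(np.abs(grad).max()) < max(gtol * 100, 1e-3)
        # indicator-only utilities beyond this magnitude signal a runaway
        # toward the degenerate latent-class boundary, not a usable optimum
        if float(np.abs(res.x).max()) > 1e3:
            converged = False
        cov, se_method = self._covariance(res.x)
        return MixedLogitResults(
            model=self,
            params=res.x.copy(),
            llf=ll,
            cov_params=cov,
            se_method=se_method,
            converged=converged,
            optimizer_message=str(res.message),
            n_iter=int(res.get("nit", -1)),
        )

    def _covariance(self, x: np.ndarray) -> tuple[np.ndarray, str]:
        p = self.spec.n_params
        H = np.empty((p, p))
        for j in range(p):
            h = 1e-5 * max(1.0, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            H[:, j] = (self._eval(xp)[1] - self._eval(xm)[1]) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(-H)
            if np.isfinite(cov).all() and (np.diag(cov) > 0).all():
                return cov, "hessian"
        except np.linalg.LinAlgError:
            pass
        # BHHH outer-product fallback
        S = self._eval(x, want_obs=True)[2]
        try:
            cov = np.linalg.inv(S.T @ S)
            if np.isfinite(cov).all() and (np.diag(cov) > 0).all():
                return cov, "bhhh"
        except np.linalg.LinAlgError:
            pass
        warnings.warn("singular Hessian and BHHH; standard errors undefined")
        return np.full((p, p), np.nan), "undefined"


class MixedLogitResults:
    """Estimation results: parameter estimates, standard errors,
    t-statistics, fit metrics and post-estimation reports.

    Base-SD parameters (``:sd`` suffix) are reported in absolute value;
    their sign is not identified under normal mixing.
    """

    def __init__(
        self,
        model: MixedLogit,
        params: np.ndarray,
        llf: float,
        cov_params: np.ndarray,
        se_method: str,
        converged: bool,
        optimizer_message: str = "",
        n_iter: int = -1,
    ):
        self.model = model
        self.spec = model.spec
        self.params_raw = params  # sigma possibly negative
        reported = params.copy()
        reported[model.spec.sl_rsd] = np.abs(reported[model.spec.sl_rsd])
        self.params = reported
        self.coefficients = CoefficientSet(model.spec, params.copy())
        self.llf = llf
        self.llnull = model.loglike_null()
        self.cov_params = cov_params
        self.bse = np.sqrt(np.diag(cov_params))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tvalues = self.params / self.bse
        self.se_method = se_method
        self.converged = converged
        self.optimizer_message = optimizer_message
        self.n_iter = n_iter
        self.nobs = model.n
        self.n_params = model.spec.n_params
        self.n_draws = model.n_draws

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.spec.param_names

    # ------------------------------------------------------------------
    def fit_metrics(self) -> FitMetrics:
        """McFadden ρ², adjusted ρ², AIC and BIC versus the
        constants-only log-likelihood."""
        ll, ll0, K, n = self.llf, self.llnull, self.n_params, self.nobs
        if ll0 == 0:
            raise ValueError("constants-only log-likelihood is zero; rho2 undefined")
        return FitMetrics(
            mcfadden_rho2=1.0 - ll / ll0,
            adjusted_rho2=1.0 - (ll - K) / ll0,
            aic=2.0 * K - 2.0 * ll,
            bic=K * np.log(n) - 2.0 * ll,
            ll=ll,
            ll_null=ll0,
            n_params=K,
            n_obs=n,
        )

    def retention_screen(self, confidence: float = 0.90) -> list[str]:
        """Names of parameters whose two-tailed t-statistic falls below
        the critical value at ``confidence`` (1.645 at 90%).  Parameters
        with undefined standard errors are reported as unscreenable."""
        zcrit = norm.ppf(0.5 + confidence / 2.0)
        flagged = []
        for name, t, se in zip(self.param_names, self.tvalues, self.bse):
            if not np.isfinite(se) or se <= 0:
                flagged.append(f"{name} (unscreenable: undefined SE)")
            elif abs(t) < zcrit:
                flagged.append(name)
        return flagged

    def summary(self) -> str:
        """Plain-text coefficient table with fit metrics."""
        m = self.fit_metrics()
        lines = [
            "Mixed logit with heterogeneity in means and variances",
            f"  observations: {self.nobs}   parameters: {self.n_params}   "
            f"draws: {self.n_draws}   converged: {self.converged}",
            f"  LL: {self.llf:.4f}   LL(constants): {self.llnull:.4f}   "
            f"rho2: {m.mcfadden_rho2:.4f}   AIC: {m.aic:.1f}   BIC: {m.bic:.1f}",
            f"  SE method: {self.se_method}",
            "-" * 72,
            f"{'parameter':<44}{'coef':>9}{'std err':>10}{'t':>8}",
            "-" * 72,
        ]
        for name, c, se, t in zip(self.param_names, self.params, self.bse, self.tvalues):
            lines.append(f"{name:<44}{c:>9.3f}{se:>10.3f}{t:>8.2f}")
        lines.append("-" * 72)
        return "\n".join(lines)

    def coefficient_table(self):
        """Coefficient table as a DataFrame (variable, coef, SE, t)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "coef": self.params,
                "std_err": self.bse,
                "t_stat": self.tvalues,
            }
        )

    # post-estimation, delegated ---------------------------------------
    def marginal_effects(self):
        from .effects import marginal_effects

        return marginal_effects(self)

    def random_param_summary(self, covariate: str, severity, profile=None):
        from .effects import random_param_summary

        return random_param_summary(self, covariate, severity, profile)

    def density_curve(self, covariate: str, severity, profile=None, n_points: int = 201):
        from .effects import density_curve

        return density_curve(self, covariate, severity, profile, n_points)


def fit_ladder(
    dataset: CrashDataset,
    spec: ModelSpec,
    n_draws: int = 200,
    burn: int = 10,
    **fit_kwargs,
) -> list[MixedLogitResults]:
    """Fit the three-model ladder (no heterogeneity, means only, means
    and variances) sequentially with warm starts.

    Each restricted model's estimates initialize the next model's
    shared parameters by name; new link parameters start at 0.
    """
    results: list[MixedLogitResults] = []
    prev: MixedLogitResults | None = None
    for member in spec.nested_ladder():
        model = MixedLogit(dataset, member, n_draws=n_draws, burn=burn)
        x0 = model.start_params()
        if prev is not None:
            lookup = dict(zip(prev.spec.param_names, prev.params_raw))
            for i, name in enumerate(member.param_names):
                if name in lookup:
                    x0[i] = lookup[name]
        results.append(model.fit(start_params=x0, **fit_kwargs))
        prev = results[-1]
    return results
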