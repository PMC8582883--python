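"""Simulated likelihood core: coefficient realization, probabilities,
log-likelihood and its analytic gradient, checked against independent
oracles (closed-form logit, statsmodels MNL, Gauss–Hermite quadrature)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.polynomial.hermite_e import hermegauss

import hetlogit as hl
from hetlogit.spec import CoefficientSet, CoefficientSlot, ModelSpec, RandomSlotSpec


# ----------------------------------------------------------------------
# coefficient realization
def _mean_link_spec(link):
    return ModelSpec(
        random_slots=[
            RandomSlotSpec(CoefficientSlot("vis", 3, "random"), mean_covariates=(link,))
        ]
    )


@pytest.mark.parametrize(
    "beta,theta,link,expected",
    [
        (-2.117, -1.347, "road_segments", -3.464),
        (-3.275, 1.626, "traffic_control", -1.649),
    ],
)
def test_conditional_mean_realization(beta, theta, link, expected):
    """At gamma=0 the realized coefficient is the conditional mean
    beta + theta * Z."""
    spec = _mean_link_spec(link)
    params = CoefficientSet.from_values(
        spec, means={("vis", 3): beta}, sds={("vis", 3): 1.0},
        thetas={("vis", 3, link): theta},
    )
    out = hl.realize_coefficients(params, {link: 1, "vis": 1}, [0.0])
    assert out["vis[severe]"] == pytest.approx(expected, abs=1e-12)


def test_fixed_slot_realizes_to_beta():
    spec = ModelSpec(fixed_slots=[CoefficientSlot("truck", 4)])
    params = CoefficientSet.from_values(spec, betas={("truck", 4): 0.8})
    out = hl.realize_coefficients(params, {"truck": 1}, [])
    assert out["truck[fatal]"] == 0.8


def test_zero_sigma_degenerates_to_fixed():
    spec = ModelSpec(random_slots=[RandomSlotSpec(CoefficientSlot("vis", 3, "random"))])
    params = CoefficientSet.from_values(spec, means={("vis", 3): -1.3})
    for g in (-2.0, 0.0, 3.0):
        out = hl.realize_coefficients(params, {"vis": 1}, [g])
        assert out["vis[severe]"] == pytest.approx(-1.3)


def test_variance_link_scales_sd_multiplicatively():
    spec = ModelSpec(
        random_slots=[
            RandomSlotSpec(
                CoefficientSlot("vis", 3, "random"), variance_covariates=("w",)
            )
        ]
    )
    params = CoefficientSet.from_values(
        spec, means={("vis", 3): 0.0}, sds={("vis", 3): 2.0},
        omegas={("vis", 3, "w"): 0.5},
    )
    out1 = hl.realize_coefficients(params, {"vis": 1, "w": 1}, [1.0])
    out0 = hl.realize_coefficients(params, {"vis": 1, "w": 0}, [1.0])
    assert out1["vis[severe]"] == pytest.approx(2.0 * np.exp(0.5))
    assert out0["vis[severe]"] == pytest.approx(2.0)


# ----------------------------------------------------------------------
# probabilities
def test_all_zero_parameters_give_uniform_probabilities(tiny_dataset):
    spec = ModelSpec([CoefficientSlot("truck", 3)])
    m = hl.MixedLogit(tiny_dataset, spec)
    P = m.probabilities(np.zeros(spec.n_params))
    assert np.allclose(P, 0.25)
    assert m.loglike(np.zeros(spec.n_params)) == pytest.approx(
        tiny_dataset.n * np.log(0.25)
    )


def test_per_draw_probabilities_normalize(mixed_dgp):
    sd = hl.generate(mixed_dgp)
    m = hl.MixedLogit(sd.dataset, mixed_dgp.spec, n_draws=20)
    P = m.per_draw_probabilities(mixed_dgp.true_params.values)
    assert np.allclose(P.sum(axis=2), 1.0, atol=1e-12)
    assert np.allclose(m.probabilities(mixed_dgp.true_params).sum(axis=1), 1.0, atol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.lists(st.floats(-8, 8), min_size=8, max_size=8))
def test_probability_normalization_any_parameters(vals):
    """Per-draw and averaged probabilities sum to one for arbitrary
    finite parameter vectors."""
    import pandas as pd

    spec = ModelSpec(
        fixed_slots=[CoefficientSlot("a", 2)],
        random_slots=[
            RandomSlotSpec(
                CoefficientSlot("r", 3, "random"),
                mean_covariates=("a",),
                variance_covariates=("a",),
            )
        ],
    )
    df = pd.DataFrame({"severity": [1, 2, 3, 4], "a": [0, 1, 0, 1], "r": [1, 1, 0, 1]})
    ds = hl.CrashDataset.from_dataframe(df, ["a", "r"])
    m = hl.MixedLogit(ds, spec, n_draws=10)
    P = m.per_draw_probabilities(np.array(vals))
    assert np.allclose(P.sum(axis=2), 1.0, atol=1e-12)


def test_sigma_collapse_matches_closed_form_mnl(mixed_dgp):
    """With sigma and all links at zero, the simulated probabilities
    equal the closed-form multinomial logit exactly."""
    sd = hl.generate(mixed_dgp)
    spec = mixed_dgp.spec
    v = mixed_dgp.true_params.values.copy()
    v[spec.sl_rsd] = 0.0
    v[spec.sl_theta] = 0.0
    v[spec.sl_omega] = 0.0
    m = hl.MixedLogit(sd.dataset, spec, n_draws=50)
    P = m.probabilities(v)
    # closed form on the same design
    ds = sd.dataset
    V = np.zeros((ds.n, 4))
    V[:, 1] = v[0]
    V[:, 2] = v[1] + v[spec.sl_rmean.start] * ds.covariate_array("xr")
    V[:, 3] = v[2] + v[spec.sl_fixed.start] * ds.covariate_array("truck")
    E = np.exp(V - V.max(axis=1, keepdims=True))
    Pref = E / E.sum(axis=1, keepdims=True)
    assert np.max(np.abs(P - Pref)) < 1e-10


def test_loglike_matches_statsmodels_mnl(mnl_dgp):
    """No-random-slot likelihood agrees with statsmodels' MNLogit at the
    statsmodels optimum, to 1e-8 per evaluation."""
    sm = pytest.importorskip("statsmodels.api")
    sd = hl.generate(mnl_dgp)
    ds = sd.dataset
    exog = np.column_stack(
        [np.ones(ds.n), ds.covariate_array("x1"), ds.covariate_array("x2")]
    )
    ref = sm.MNLogit(ds.outcome - 1, exog).fit(disp=0, method="newton", tol=1e-10)
    ref_params = np.asarray(ref.params)  # (k_exog, J-1), outcome j+1 vs baseline 0
    spec = mnl_dgp.spec
    v = np.zeros(spec.n_params)
    for j, sev in enumerate((2, 3, 4)):
        v[spec.nonbase_levels.index(sev)] = ref_params[0, j]
    fixed_keys = [(s.covariate, s.severity) for s in spec.fixed_slots]
    for row, cov in ((1, "x1"), (2, "x2")):
        for j, sev in enumerate((2, 3, 4)):
            v[spec.sl_fixed.start + fixed_keys.index((cov, sev))] = ref_params[row, j]
    m = hl.MixedLogit(ds, spec)
    assert m.loglike(v) == pytest.approx(ref.llf, abs=1e-8)
    # and our own optimizer reaches the same maximum
    res = m.fit(gtol=1e-7)
    assert res.llf == pytest.approx(ref.llf, abs=1e-6)


def test_simulated_probabilities_match_gauss_hermite():
    """One random coefficient: 200 Halton draws against a 64-node
    Gauss–Hermite quadrature oracle, max error below 0.005."""
    import pandas as pd

    spec = ModelSpec(random_slots=[RandomSlotSpec(CoefficientSlot("vis", 3, "random"))])
    n = 40
    rng = np.random.default_rng(2)
    df = pd.DataFrame(
        {"severity": rng.integers(1, 5, n), "vis": rng.binomial(1, 0.6, n)}
    )
    ds = hl.CrashDataset.from_dataframe(df, ["vis"])
    params = CoefficientSet.from_values(
        spec, constants={2: 0.4, 3: -0.2, 4: -0.8},
        means={("vis", 3): -1.5}, sds={("vis", 3): 2.2},
    )
    m = hl.MixedLogit(ds, spec, n_draws=200)
    P = m.probabilities(params)

    nodes, wts = hermegauss(64)
    wts = wts / wts.sum()
    x = ds.covariate_array("vis")
    V = np.zeros((4, n, 64))
    V[1] = params.constant(2)
    V[3] = params.constant(4)
    coef = -1.5 + 2.2 * nodes
    V[2] = params.constant(3) + coef[None, :] * x[:, None]
    E = np.exp(V - V.max(axis=0))
    Pq = (E / E.sum(axis=0)) @ wts
    assert np.max(np.abs(P - Pq.T)) < 0.005


def test_analytic_score_matches_finite_differences(mixed_dgp):
    sd = hl.generate(mixed_dgp)
    m = hl.MixedLogit(sd.dataset, mixed_dgp.spec, n_draws=40)
    x = mixed_dgp.true_params.values + 0.07
    g = m.score(x)
    gfd = np.empty_like(g)
    for j in range(len(x)):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        gfd[j] = (m.loglike(xp) - m.loglike(xm)) / (2 * h)
    assert np.max(np.abs(g - gfd)) < 1e-4
    # per-observation scores sum to the gradient
    assert np.allclose(m.score_obs(x).sum(axis=0), g, atol=1e-10)


def test_severity_relabeling_symmetry(mixed_dgp):
    """Swapping two non-baseline severities (data and parameters alike)
    leaves the likelihood invariant."""
    import pandas as pd

    sd = hl.generate(mixed_dgp)
    ds = sd.dataset
    spec = mixed_dgp.spec
    m = hl.MixedLogit(ds, spec, n_draws=30)
    ll = m.loglike(mixed_dgp.true_params.values)

    # swap severities 2 and 4 in outcomes and slot assignments
    swap = {2: 4, 4: 2, 1: 1, 3: 3}
    out2 = np.array([swap[c] for c in ds.outcome])
    ds2 = hl.CrashDataset(outcome=out2, covariates=ds.covariates, ids=ds.ids)
    spec2 = ModelSpec(
        [CoefficientSlot(s.covariate, swap[s.severity]) for s in spec.fixed_slots],
        [
            RandomSlotSpec(
                CoefficientSlot(r.slot.covariate, swap[r.slot.severity], "random"),
                r.mean_covariates,
                r.variance_covariates,
            )
            for r in spec.random_slots
        ],
    )
    true2 = CoefficientSet.from_values(
        spec2,
        constants={swap[2]: 1.0, swap[3]: -0.5, swap[4]: -1.0},
        betas={("truck", swap[4]): 0.8},
        means={("xr", swap[3]): -2.0},
        sds={("xr", swap[3]): 2.0},
        thetas={("xr", swap[3], "z"): 1.5},
        omegas={("xr", swap[3], "w"): 0.5},
    )
    m2 = hl.MixedLogit(ds2, spec2, n_draws=30)
    assert m2.loglike(true2.values) == pytest.approx(ll, abs=1e-10)


def test_draw_count_stability():
    """|LL(R) − LL(2R)| decays as the draw count grows (overall, not
    necessarily monotonically step to step)."""
    spec = ModelSpec(random_slots=[RandomSlotSpec(CoefficientSlot("xr", 3, "random"))])
    true = CoefficientSet.from_values(
        spec, constants={2: 0.5, 3: -0.3, 4: -0.8},
        means={("xr", 3): -1.5}, sds={("xr", 3): 2.0},
    )
    sd = hl.generate(
        hl.DGPConfig(n=300, covariate_probs={"xr": 0.5}, spec=spec, true_params=true, seed=7)
    )
    lls = {
        R: hl.MixedLogit(sd.dataset, spec, n_draws=R).loglike(true.values)
        for R in (50, 100, 200, 400, 800)
    }
    d = {R: abs(lls[R] - lls[2 * R]) for R in (50, 100, 200, 400)}
    assert d[400] < d[50]
    assert max(d[200], d[400]) < max(d[50], d[100])


def test_nonfinite_parameters_never_nan(tiny_dataset):
    spec = ModelSpec([CoefficientSlot("truck", 3)])
    m = hl.MixedLogit(tiny_dataset, spec)
    ll = m.loglike(np.array([1e4, -1e4, 5e3, 2e308 * 0 + 1e308]))
    assert np.isfinite(ll)
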