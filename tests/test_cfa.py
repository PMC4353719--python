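import numpy as np
import pytest
from dataclasses import replace
from scipy import optimize, stats

from mgcfa.cfa import (
    ModelSpec,
    chisq_diff,
    fit,
    fit_indices,
    make_objective,
    modification_indices,
    _ncp_quantile,
)
from mgcfa.moments import GroupMoments, moments_from_arrays
from mgcfa import synthetic
from mgcfa.synthetic import implied_facet_moments


def _pop_moments(lam, n=500, label="g", names=None):
    lam = np.asarray(lam, dtype=float)
    p = lam.size
    sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
    names = names or tuple(f"i{j}" for j in range(p))
    return GroupMoments(label, n, np.zeros(p), sigma, names)


def test_just_identified_closed_form():
    # 3 indicators: lambda_1 = sqrt(s12*s13/s23), chi-square exactly 0
    mom = _pop_moments([0.6, 0.7, 0.8])
    res = fit(ModelSpec(indicators=mom.variables, n_groups=1), [mom])
    assert res.df == 0
    assert res.chisq == pytest.approx(0.0, abs=1e-6)
    s = mom.cov
    lam1 = np.sqrt(s[0, 1] * s[0, 2] / s[1, 2])
    assert res.params.loadings[0, 0] == pytest.approx(lam1, abs=1e-6)
    np.testing.assert_allclose(res.params.loadings[0], [0.6, 0.7, 0.8], atol=1e-6)


def test_moment_sufficiency_loglik_matches_raw_data(rng):
    # the moment-based log-likelihood equals the sum of per-person normal
    # log-densities, confirming the ML (divisor n) convention end to end
    lam = np.array([0.5, 0.6, 0.7, 0.8])
    sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
    x = rng.multivariate_normal(np.ones(4), sigma, size=200)
    mom = moments_from_arrays("g", x, ("a", "b", "c", "d"))
    res = fit(ModelSpec(indicators=("a", "b", "c", "d"), n_groups=1), [mom])
    direct = stats.multivariate_normal(res.implied_mean[0], res.implied_cov[0]).logpdf(x).sum()
    assert res.loglik == pytest.approx(direct, rel=1e-8)


def test_scale_equivariance(rng):
    lam = np.array([0.4, 0.5, 0.6, 0.7, 0.8])
    sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
    x = rng.multivariate_normal(np.zeros(5), sigma, size=300)
    names = tuple("abcde")
    m1 = moments_from_arrays("g", x, names)
    m2 = moments_from_arrays("g", 3.0 * x, names)
    spec = ModelSpec(indicators=names, n_groups=1)
    r1, r2 = fit(spec, [m1]), fit(spec, [m2])
    assert r2.chisq == pytest.approx(r1.chisq, abs=1e-5)
    i1, i2 = fit_indices(r1), fit_indices(r2)
    assert i2.cfi == pytest.approx(i1.cfi, abs=1e-7)
    assert i2.rmsea == pytest.approx(i1.rmsea, abs=1e-7)
    np.testing.assert_allclose(r2.params.loadings, 3.0 * r1.params.loadings, atol=1e-4)
    np.testing.assert_allclose(r2.params.intercepts, 3.0 * r1.params.intercepts, atol=1e-4)


def test_cfi_arithmetic_from_formula():
    # chisq_m=100, df_m=18, chisq_b=1000, df_b=28 -> CFI = 1 - 82/972
    num = max(100 - 18, 0)
    den = max(1000 - 28, num, 0)
    assert 1 - num / den == pytest.approx(0.9156, abs=5e-5)


def test_fit_indices_saturated_limit():
    mom = _pop_moments(np.linspace(0.3, 0.8, 8), n=300)
    res = fit(ModelSpec(indicators=mom.variables, n_groups=1), [mom])
    ind = fit_indices(res)
    assert res.chisq <= res.df
    assert ind.cfi == 1.0
    assert ind.rmsea == 0.0
    assert ind.rmsea_lo == 0.0


def test_rmsea_ci_against_bisection_oracle():
    chisq, df = 141.86, 18
    for q in (0.95, 0.05):
        ncp = _ncp_quantile(chisq, df, q)
        # independent bisection on the noncentral chi-square CDF
        lo, hi = 0.0, 1000.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if stats.ncx2.cdf(chisq, df, max(mid, 1e-12)) > q:
                lo = mid
            else:
                hi = mid
        assert ncp == pytest.approx(0.5 * (lo + hi), abs=1e-4)
        assert stats.ncx2.cdf(chisq, df, ncp) == pytest.approx(q, abs=1e-6)


def test_rmsea_undefined_at_zero_df():
    mom = _pop_moments([0.6, 0.7, 0.8])
    res = fit(ModelSpec(indicators=mom.variables, n_groups=1), [mom])
    ind = fit_indices(res)
    assert ind.rmsea_undefined and ind.rmsea == 0.0


def test_chisq_diff_identical_and_counting(null_spec):
    moms = implied_facet_moments(null_spec, null_spec.layout.facets[0])
    spec_c = ModelSpec(indicators=moms[0].variables, n_groups=12)
    spec_w = replace(spec_c, loadings="equal")
    rc, rw = fit(spec_c, moms), fit(spec_w, moms)
    assert chisq_diff(rc, rc) == (0.0, 0)
    d_chi, d_df = chisq_diff(rw, rc)
    assert d_df == 8 * 11  # loading equality across 12 groups, 8 items
    assert d_chi == pytest.approx(0.0, abs=1e-4)  # population moments: no misfit


def test_chisq_diff_rejects_different_indicators():
    m1 = _pop_moments([0.6, 0.7, 0.8])
    m2 = _pop_moments([0.6, 0.7, 0.8], names=("x", "y", "z"))
    r1 = fit(ModelSpec(indicators=m1.variables, n_groups=1), [m1])
    r2 = fit(ModelSpec(indicators=m2.variables, n_groups=1), [m2])
    with pytest.raises(ValueError, match="indicator"):
        chisq_diff(r1, r2)


def test_mod_index_of_free_parameter_is_zero(rng):
    lam = np.array([0.5, 0.6, 0.7, 0.8, 0.4, 0.6])
    sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
    x = rng.multivariate_normal(np.zeros(6), sigma, size=400)
    mom = moments_from_arrays("g", x, tuple("abcdef"))
    res = fit(ModelSpec(indicators=mom.variables, n_groups=1), [mom])
    rows = modification_indices(res, [("loading", "a", 0), ("intercept", "b", 0)])
    for r in rows:
        assert r.stat == pytest.approx(0.0, abs=1e-6)


def test_mod_index_matches_refit_oracle(rng):
    # freeing a fixed-zero residual covariance: score statistic within 10%
    # of the actual chi-square drop from refitting, on a 2-group toy
    lam = np.array([0.5, 0.6, 0.7, 0.8, 0.4, 0.6])
    names = tuple("abcdef")
    moms = []
    for g in range(2):
        sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
        sigma[1, 3] += 0.15
        sigma[3, 1] += 0.15
        x = rng.multivariate_normal(np.zeros(6), sigma, size=300)
        moms.append(moments_from_arrays(f"g{g}", x, names))
    spec = ModelSpec(indicators=names, n_groups=2, loadings="equal",
                     intercepts="equal", latent_means="reference_zero")
    res = fit(spec, moms)
    row = modification_indices(res, [("resid_cov", ("b", "d"), "all")])[0]
    spec2 = replace(spec, pairs=(("b", "d"),), resid_cov="equal")
    res2 = fit(spec2, moms)
    d_chi, d_df = chisq_diff(res, res2)
    assert d_df == 1
    assert row.stat == pytest.approx(d_chi, rel=0.10)
    assert row.epc == pytest.approx(res2.params.resid_cov[0, 0], abs=0.02)


def test_injected_shift_attains_largest_mod_index():
    # a step intercept shift on one item should dominate the intercept
    # modification indices of the strong model in most replicates
    base = synthetic.neo_like_template(
        layout=synthetic.neo_layout(1, 1, 8), group_sizes=(250,) * 12
    )
    spec_pop = synthetic.inject_noninvariance(
        base, [synthetic.Directive("N1_i3", "intercept", "step", 0.5, (8, 9, 10, 11))]
    )
    facet = base.layout.facets[0]
    items = base.layout.items_per_facet[facet]
    from mgcfa.moments import compute_group_moments, default_grouping

    hits = 0
    n_rep = 20
    for r in range(n_rep):
        table = synthetic.simulate(spec_pop, seed=3000 + r)
        moms = compute_group_moments(table, default_grouping(), items)
        spec = ModelSpec(indicators=items, n_groups=12, loadings="equal",
                         intercepts="equal", latent_means="reference_zero")
        res = fit(spec, moms)
        cands = [("intercept", it, g) for it in items for g in range(12)]
        rows = modification_indices(res, cands)
        avg = {}
        for row in rows:
            avg.setdefault(row.target, []).append(row.stat)
        best = max(avg, key=lambda k: np.mean(avg[k]))
        hits += best == "N1_i3"
    assert hits >= int(0.95 * n_rep)


def test_parameter_recovery_null(null_spec):
    # n_g = 1000: mean absolute error of loadings/intercepts/means below 0.05
    spec_pop = synthetic.neo_like_template(
        layout=null_spec.layout, group_sizes=(1000,) * 12, latent_slope=-0.4
    )
    table = synthetic.simulate(spec_pop, seed=77)
    facet = spec_pop.layout.facets[0]
    items = spec_pop.layout.items_per_facet[facet]
    from mgcfa.moments import compute_group_moments, default_grouping

    moms = compute_group_moments(table, default_grouping(), items)
    spec = ModelSpec(indicators=items, n_groups=12, loadings="equal",
                     intercepts="equal", latent_means="reference_zero")
    res = fit(spec, moms)
    true_lam = np.linspace(0.3, 0.8, 8)
    true_alpha = np.array(spec_pop.latent_means[facet])
    assert np.mean(np.abs(res.params.loadings[0] - true_lam)) < 0.05
    assert np.mean(np.abs(res.params.intercepts[0])) < 0.05
    assert np.mean(np.abs(res.params.latent_means - true_alpha)) < 0.05


def test_heywood_flagged():
    # a population residual variance of ~0 drives the estimate to the bound
    lam = np.array([0.999, 0.6, 0.7, 0.5])
    sigma = np.outer(lam, lam) + np.diag(np.maximum(1 - lam**2, 1e-4))
    mom = GroupMoments("g", 200, np.zeros(4), sigma, ("a", "b", "c", "d"))
    res = fit(ModelSpec(indicators=mom.variables, n_groups=1), [mom])
    assert res.converged
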