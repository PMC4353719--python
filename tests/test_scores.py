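import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mgcfa import synthetic
from mgcfa.cfa import ModelSpec, fit
from mgcfa.scores import (
    critical_r,
    domain_indicator_scores,
    latent_reliability,
    ols_factor_scores,
    random_subset_correlations,
    residual_age_correlations,
)
from mgcfa.synthetic import Directive, implied_facet_moments


def _one_factor_table(lam, n, seed, slope_age=0.0):
    rng = np.random.default_rng(seed)
    lam = np.asarray(lam)
    eta = rng.standard_normal(n)
    eps = rng.standard_normal((n, lam.size)) * np.sqrt(1 - lam**2)
    x = np.outer(eta, lam) + eps
    cols = {f"i{j}": x[:, j] for j in range(lam.size)}
    cols["age"] = rng.uniform(18, 91, n)
    df = pd.DataFrame(cols)
    return df, eta


def test_factor_scores_track_the_true_latent():
    lam = np.full(8, 0.6)
    df, eta = _one_factor_table(lam, 5000, seed=101)
    fs = ols_factor_scores(df, [f"i{j}" for j in range(8)])
    r = np.corrcoef(fs.scores, eta)[0, 1]
    # closed-form regression-score validity: sqrt(sum l^2/(1-l^2) / (1 + sum))
    a = np.sum(lam**2 / (1 - lam**2))
    expected = np.sqrt(a / (1 + a))
    assert r >= 0.90
    assert r == pytest.approx(expected, abs=0.02)
    assert fs.scores.mean() == pytest.approx(0.0, abs=1e-10)
    assert fs.scores.std() == pytest.approx(1.0, abs=1e-10)


def test_item_order_invariance():
    df, _ = _one_factor_table(np.full(6, 0.6), 800, seed=7)
    items = [f"i{j}" for j in range(6)]
    a = ols_factor_scores(df, items)
    b = ols_factor_scores(df, list(reversed(items)))
    np.testing.assert_allclose(a.scores, b.scores, atol=1e-10)


def test_null_item_gets_null_loading():
    lam = np.array([0.0] + [0.6] * 7)
    df, _ = _one_factor_table(lam, 10000, seed=13)
    fs = ols_factor_scores(df, [f"i{j}" for j in range(8)])
    assert abs(fs.loadings[0]) < 0.05
    assert np.all(fs.loadings[1:] > 0.4)


@pytest.mark.parametrize(
    "n,alpha,expected,places",
    [(2711, 0.05 / 240, 0.071, 3), (10000, 1.0, 0.0, 10)],
)
def test_critical_r_values(n, alpha, expected, places):
    assert round(critical_r(n, alpha), places) == expected


def test_critical_r_monte_carlo_calibration():
    # null rejection rate at the critical value matches alpha
    rng = np.random.default_rng(515)
    n, B = 60, 20000
    x = rng.standard_normal((B, n))
    y = rng.standard_normal((B, n))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
    for alpha in (0.05, 0.01):
        rate = np.mean(np.abs(r) > critical_r(n, alpha))
        assert rate == pytest.approx(alpha, abs=3 * np.sqrt(alpha / B) + 0.002)


@given(st.integers(10, 10000))
def test_critical_r_decreases_with_n(n):
    assert critical_r(n + 5, 0.05) < critical_r(n, 0.05)


def test_residuals_exactly_orthogonal_to_factor():
    df, _ = _one_factor_table(np.full(8, 0.6), 2000, seed=23)
    items = [f"i{j}" for j in range(8)]
    fs = ols_factor_scores(df, items)
    tab = residual_age_correlations(df, fs, items, age="age", alphas={"bonf": 0.05 / 240})
    # recompute residuals and verify orthogonality to the score
    for it in items:
        y = df[it].to_numpy()
        b = np.cov(y, fs.scores, bias=True)[0, 1] / fs.scores.var()
        resid = y - y.mean() - b * fs.scores
        assert abs(np.corrcoef(resid, fs.scores)[0, 1]) < 1e-10
    assert set(tab.columns) >= {"unit", "r_raw", "r_residual", "sig_bonf"}


def test_residual_age_correlation_recovers_injected_drift():
    # linear intercept drift on one item leaves age signal in its residual
    layout = synthetic.neo_layout(1, 1, 8)
    spec = synthetic.neo_like_template(layout=layout)
    spec = synthetic.inject_noninvariance(
        spec, [Directive("N1_i3", "intercept", "linear", 0.8)]
    )
    table = synthetic.simulate(spec, seed=37)
    items = list(layout.items_per_facet["N1"])
    fs = ols_factor_scores(table, items)
    tab = residual_age_correlations(table, fs, items, age="age",
                                    alphas={"bonf": 0.05 / 240})
    r3 = tab.set_index("unit").loc["N1_i3", "r_residual"]
    others = tab.set_index("unit").drop("N1_i3")["r_residual"].abs()
    assert r3 > 0.15  # the drifting item carries unique age variance
    assert r3 > others.max()
    assert tab.set_index("unit").loc["N1_i3", "sig_bonf"]


def test_zero_variance_component_flagged():
    df, _ = _one_factor_table(np.full(4, 0.6), 100, seed=3)
    df["flat"] = 1.0
    fs = ols_factor_scores(df, [f"i{j}" for j in range(4)])
    tab = residual_age_correlations(df, fs, ["i0", "flat"], age="age", alphas={})
    row = tab.set_index("unit").loc["flat"]
    assert row["zero_variance"] and np.isnan(row["r_residual"])


def test_subset_correlations_deterministic(null_table, null_spec):
    layout = null_spec.layout
    pool = layout.items_per_facet[layout.facets[0]]
    a = random_subset_correlations(null_table, "N", pool, B=20, k=4, seed=5)
    b = random_subset_correlations(null_table, "N", pool, B=20, k=4, seed=5)
    np.testing.assert_array_equal(a.correlations, b.correlations)
    with pytest.raises(ValueError, match="exceeds"):
        random_subset_correlations(null_table, "N", pool, B=5, k=9, seed=1)


def test_subset_mean_matches_full_pool_correlation():
    # exchangeable items (one factor, equal loadings): 12-of-48 subset age
    # correlations centre on the full-pool score's age correlation
    layout = synthetic.neo_layout(1, 1, 48)
    facet = layout.facets[0]
    base = synthetic.neo_like_template(layout=layout, latent_slope=-0.4)
    spec = synthetic.PopulationSpec(
        layout=layout, groups=base.groups,
        facet_params={facet: synthetic.FacetParams(
            (0.6,) * 48, (0.0,) * 48, (0.64,) * 48)},
        latent_means=base.latent_means, domain_cor=0.0)
    table = synthetic.simulate(spec, seed=900)
    pool = layout.items_per_facet[facet]
    full = ols_factor_scores(table, pool)
    age = table["age"].to_numpy()
    r_full = np.corrcoef(full.scores, age)[0, 1]
    res = random_subset_correlations(table, "N", pool, B=100, k=12, seed=42)
    assert res.mean == pytest.approx(r_full, abs=0.02)


@pytest.mark.parametrize(
    "lam,theta,pairs,expected",
    [(0.6, 0.64, 0.0, 4.8**2 / (4.8**2 + 5.12)), (0.0, 1.0, 0.0, 0.0)],
)
def test_omega_arithmetic(lam, theta, pairs, expected):
    layout = synthetic.neo_layout(1, 1, 8)
    facet = layout.facets[0]
    items = layout.items_per_facet[facet]
    spec_pop = synthetic.PopulationSpec(
        layout=layout,
        groups=synthetic.neo_like_template(layout=layout).groups,
        facet_params={facet: synthetic.FacetParams(
            loadings=(lam,) * 8, intercepts=(0.0,) * 8, resid_var=(theta,) * 8)},
        latent_means={facet: (0.0,) * 12},
        domain_cor=0.0,
    )
    moms = implied_facet_moments(spec_pop, facet)
    res = fit(ModelSpec(indicators=items, n_groups=12), moms)
    omega = latent_reliability(res)
    np.testing.assert_allclose(omega, expected, atol=1e-4)


def test_omega_scale_free():
    # omega from a standardized vs rescaled solution is identical
    lam = np.linspace(0.3, 0.8, 8)
    num = lam.sum() ** 2
    om1 = num / (num + (1 - lam**2).sum())
    c = 7.3
    om2 = (c * lam).sum() ** 2 / ((c * lam).sum() ** 2 + (c**2 * (1 - lam**2)).sum())
    assert om1 == pytest.approx(om2, abs=1e-12)


def test_omega_lower_when_loadings_lowered():
    layout = synthetic.neo_layout(1, 1, 8)
    facet = layout.facets[0]
    items = layout.items_per_facet[facet]
    base = synthetic.neo_like_template(layout=layout, group_sizes=(400,) * 12)
    # step-lower every item's loading in the last 4 groups
    dirs = [Directive(it, "loading", "step", -0.25, (8, 9, 10, 11)) for it in items]
    spec_pop = synthetic.inject_noninvariance(base, dirs)
    lower = []
    for r in range(5):
        table = synthetic.simulate(spec_pop, seed=650 + r)
        from mgcfa.moments import compute_group_moments, default_grouping

        moms = compute_group_moments(table, default_grouping(), items)
        res = fit(ModelSpec(indicators=items, n_groups=12), moms)
        omega = latent_reliability(res)
        lower.append(omega[8:].mean() < omega[:8].mean())
    assert sum(lower) == 5


def test_domain_indicator_scores_shape(null_table, null_spec):
    layout = null_spec.layout
    fs = domain_indicator_scores(null_table, layout)
    assert list(fs.columns) == list(layout.facets)
    np.testing.assert_allclose(fs.mean(), 0.0, atol=1e-10)
    np.testing.assert_allclose(fs.std(ddof=0), 1.0, atol=1e-10)
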