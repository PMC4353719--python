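"""Factor scores and score-level analyses.

Factor scores are obtained by ordinary-least-squares (minimum-residual)
single-factor extraction from the item correlation matrix, with
regression-method (linear projection) scoring.  On top of that this module
provides: the critical correlation for a given two-sided alpha, item- and
facet-level residual-age correlations (each component residualized on its
unit's factor score by least squares), random-item-subset sensitivity of
domain-age correlations, and per-group latent reliability (coefficient
omega) from a fitted configural model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cfa import FitResult
from .instrument import InstrumentLayout

__all__ = [
    "FactorScores",
    "ols_factor_scores",
    "critical_r",
    "residual_age_correlations",
    "random_subset_correlations",
    "SubsetSensitivity",
    "latent_reliability",
    "domain_indicator_scores",
]


@dataclass
class FactorScores:
    """Standardized single-factor scores plus the extraction record."""

    scores: np.ndarray
    items: tuple[str, ...]
    loadings: np.ndarray  # standardized (correlation-metric) loadings


def _minres_loadings(R: np.ndarray) -> np.ndarray:
    """Single-factor minimum-residual loadings of a correlation matrix.

    Minimizes the sum of squared off-diagonal residuals
    ``sum_{j<k} (R_jk - l_j l_k)^2`` — the diagonal is ignored, which is
    what distinguishes this from a principal-component fit.  Deterministic:
    initialized from the first eigenvector.
    """
    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)
    w, v = np.linalg.eigh(R)
    lam0 = v[:, -1] * np.sqrt(max(w[-1], 1e-6))

    def obj(lam):
        res = (R - np.outer(lam, lam)) * off
        grad = -2.0 * (res @ lam) * 2.0  # d/dl_j sum_{j!=k} res_jk^2
        return float(np.sum(res**2)), grad

    sol = optimize.minimize(obj, lam0, jac=True, method="L-BFGS-B",
                            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000})
    if not np.all(np.isfinite(sol.x)):
        raise RuntimeError("minres factor extraction did not converge")
    lam = sol.x
    if lam.sum() < 0:
        lam = -lam
    return lam


def ols_factor_scores(table: pd.DataFrame, items: list[str] | tuple[str, ...]) -> FactorScores:
    """Regression-method scores from a minres single-factor solution.

    Items are standardized, a single factor is extracted from their
    correlation matrix by minimum residuals, and scores are the linear
    projection ``z R^-1 lambda``, restandardized to mean 0 / SD 1 over the
    scoring sample.  The factor is oriented so the sum of loadings is
    positive.  Deterministic and invariant to item order.
    """
    items = tuple(items)
    if len(items) < 3:
        raise ValueError("factor extraction needs at least 3 items")
    X = table.loc[:, list(items)].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd <= 0):
        bad = [items[j] for j in np.nonzero(sd <= 0)[0]]
        raise ValueError(f"zero-variance items: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    R = Z.T @ Z / Z.shape[0]
    lam = _minres_loadings(R)
    f = Z @ np.linalg.solve(R, lam)
    fsd = f.std()
    if fsd <= 0:
        raise RuntimeError("degenerate factor scores (zero variance)")
    f = (f - f.mean()) / fsd
    return FactorScores(scores=f, items=items, loadings=lam)


def critical_r(n: int, alpha_two_sided: float) -> float:
    """Smallest |r| significant at the given two-sided alpha with n observations.

    ``r* = t* / sqrt(t*^2 + n - 2)`` with ``t*`` the (1 - alpha/2) Student-t
    quantile at n - 2 degrees of freedom.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < alpha_two_sided <= 1:
        raise ValueError("alpha must be in (0, 1]")
    t = stats.t.ppf(1.0 - alpha_two_sided / 2.0, n - 2)
    return float(t / np.sqrt(t * t + n - 2))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    den = np.sqrt((xd @ xd) * (yd @ yd))
    if den <= 0:
        return np.nan
    return float((xd @ yd) / den)


def residual_age_correlations(
    table: pd.DataFrame,
    unit_scores: FactorScores,
    components: list[str] | tuple[str, ...],
    age: np.ndarray | str = "age",
    alphas: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Correlations of components with age before and after residualizing
    each component on its unit's factor score.

    Each component is regressed (with intercept) on the factor score; the
    least-squares residual is exactly orthogonal to the score, and its
    Pearson correlation with age isolates the component-specific age
    variance.  ``alphas`` maps flag names to two-sided alpha levels; each
    produces a boolean ``sig_<name>`` column (|residual r| above the
    critical value at that alpha).
    """
    if isinstance(age, str):
        age = table[age].to_numpy(dtype=float)
    f = unit_scores.scores
    n = len(f)
    alphas = alphas or {}
    crits = {name: critical_r(n, a) for name, a in alphas.items()}
    rows = []
    for comp in components:
        y = table[comp].to_numpy(dtype=float)
        if y.std() <= 0:
            row = {"unit": comp, "r_raw": np.nan, "r_residual": np.nan, "zero_variance": True}
            for name in alphas:
                row[f"sig_{name}"] = False
            rows.append(row)
            continue
        b = _pearson(y, f) * y.std() / f.std()
        resid = y - y.mean() - b * (f - f.mean())
        r_raw = _pearson(y, age)
        r_res = _pearson(resid, age)
        row = {"unit": comp, "r_raw": r_raw, "r_residual": r_res, "zero_variance": False}
        for name in alphas:
            row[f"sig_{name}"] = bool(abs(r_res) > crits[name])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SubsetSensitivity:
    """Distribution of age correlations over random item subsets of a domain."""

    domain: str
    B: int
    k: int
    correlations: np.ndarray
    mean: float
    q025: float
    q975: float

    def to_dict(self) -> dict:
        return {
            "domain": self.domain,
            "B": self.B,
            "k": self.k,
            "mean": self.mean,
            "q025": self.q025,
            "q975": self.q975,
        }


def random_subset_correlations(
    table: pd.DataFrame,
    domain: str,
    pool_items: list[str] | tuple[str, ...],
    age: np.ndarray | str = "age",
    B: int = 1000,
    k: int = 12,
    seed: int = 0,
) -> SubsetSensitivity:
    """Age correlations of B random k-item latent traits drawn from a domain.

    Each draw takes ``k`` distinct items from the domain's pool (default
    use: 12 of 48), extracts a single minres factor, computes
    regression-method scores, and correlates them with age.  Subset factors
    are sign-aligned to the full-pool factor so the quantile summary is not
    corrupted by arbitrary factor orientation.  Deterministic given seed.
    """
    pool = tuple(pool_items)
    if k > len(pool):
        raise ValueError(f"k={k} exceeds the pool of {len(pool)} items")
    if isinstance(age, str):
        age = table[age].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    full = ols_factor_scores(table, pool)
    rs = np.empty(B)
    for b in range(B):
        idx = rng.choice(len(pool), size=k, replace=False)
        sub = tuple(pool[i] for i in idx)
        fs = ols_factor_scores(table, sub)
        s = fs.scores
        if _pearson(s, full.scores) < 0:
            s = -s
        rs[b] = _pearson(s, age)
    return SubsetSensitivity(
        domain=domain,
        B=B,
        k=k,
        correlations=rs,
        mean=float(rs.mean()),
        q025=float(np.quantile(rs, 0.025)),
        q975=float(np.quantile(rs, 0.975)),
    )


def latent_reliability(fitres: FitResult) -> np.ndarray:
    """Coefficient omega of the latent scale per group, from a fitted model.

    ``omega_g = (sum_j lambda_jg)^2 /
    ((sum_j lambda_jg)^2 + sum_j theta_jjg + 2 sum_pairs theta_jkg)``.
    """
    lam = fitres.params.loadings
    thd = fitres.params.resid_var
    thp = fitres.params.resid_cov
    num = lam.sum(axis=1) ** 2
    den = num + thd.sum(axis=1) + 2.0 * (thp.sum(axis=1) if thp.size else 0.0)
    if np.any(den <= 0):
        raise ValueError("non-positive total variance in omega denominator")
    return num / den


def domain_indicator_scores(table: pd.DataFrame, layout: InstrumentLayout) -> pd.DataFrame:
    """Facet factor scores for every facet, as a domain indicator matrix.

    Returns one standardized factor-score column per facet (columns in
    layout order); slicing a domain's six facet columns yields the
    indicator matrix for that domain's latent model.
    """
    cols = {}
    for fac in layout.facets:
        cols[fac] = ols_factor_scores(table, layout.items_per_facet[fac]).scores
    return pd.DataFrame(cols, index=table.index)
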