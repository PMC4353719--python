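"""Single- and multi-group one-factor models by normal-theory maximum likelihood.

The model for group g with p indicators is

    x = tau_g + lambda_g * eta + eps,   eta ~ N(alpha_g, 1),  eps ~ N(0, Theta_g)

so the implied moments are ``Sigma_g = lambda_g lambda_g' + Theta_g`` and
``mu_g = tau_g + lambda_g alpha_g``, with the latent variance fixed at 1 in
every group for identification.  ``Theta_g`` is diagonal plus a small set of
user-specified residual-covariance pairs.  Estimation minimizes the
group-size-weighted ML discrepancy

    F = sum_g (n_g/N) [ ln|Sigma_g| - ln|S_g| + tr(S_g Sigma_g^-1) - p
                        + (xbar_g - mu_g)' Sigma_g^-1 (xbar_g - mu_g) ]

over the free parameters, with chi-square = N * F.  Cross-group equality
constraints are implemented by parameter sharing: one free scalar mapped
into several groups.  Modification indices are univariate score
(Lagrange-multiplier) statistics computed from the analytic gradient and
expected information at the constrained optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize, stats

from .moments import GroupMoments

__all__ = [
    "ModelSpec",
    "ParamTable",
    "FitResult",
    "FitIndices",
    "ModIndexRow",
    "fit",
    "fit_indices",
    "modification_indices",
    "chisq_diff",
    "make_objective",
]

_THETA_FLOOR = 1e-6  # Heywood guard: lower bound on residual variances
_RESTART_SEED = 20200615  # documented seed for jittered restarts


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Structure and constraint template of a one-factor model.

    ``loadings``/``intercepts``/``resid_var``/``resid_cov`` are each
    ``'free'`` (per group) or ``'equal'`` (across groups).  ``latent_means``
    is ``'zero'`` (fixed 0 in all groups) or ``'reference_zero'`` (fixed 0
    in the reference group, free elsewhere).  ``released_*`` lists items
    whose loading/intercept is freed per group despite an ``'equal'``
    template — the partial-invariance release list.
    """

    indicators: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...] = ()
    n_groups: int = 1
    loadings: str = "free"
    intercepts: str = "free"
    resid_var: str = "free"
    resid_cov: str = "free"
    latent_means: str = "zero"
    released_loadings: tuple[str, ...] = ()
    released_intercepts: tuple[str, ...] = ()
    reference: int = 0
    mean_structure: bool = True

    def __post_init__(self) -> None:
        if len(set(self.indicators)) != len(self.indicators):
            raise ValueError("duplicate indicator labels")
        for a, b in self.pairs:
            if a == b or a not in self.indicators or b not in self.indicators:
                raise ValueError(f"invalid residual-covariance pair ({a!r}, {b!r})")
        norm = {tuple(sorted(pr)) for pr in self.pairs}
        if len(norm) != len(self.pairs):
            raise ValueError("duplicate residual-covariance pairs")
        for fam, val in (
            ("loadings", self.loadings),
            ("intercepts", self.intercepts),
            ("resid_var", self.resid_var),
            ("resid_cov", self.resid_cov),
        ):
            if val not in ("free", "equal"):
                raise ValueError(f"{fam} must be 'free' or 'equal', got {val!r}")
        if self.latent_means not in ("zero", "reference_zero"):
            raise ValueError("latent_means must be 'zero' or 'reference_zero'")
        for it in self.released_loadings + self.released_intercepts:
            if it not in self.indicators:
                raise ValueError(f"released parameter names unknown item {it!r}")

    @property
    def p(self) -> int:
        return len(self.indicators)

    def with_release(self, family: str, item: str) -> "ModelSpec":
        """Copy of the spec with one more per-group release."""
        if family == "loading":
            return replace(self, released_loadings=self.released_loadings + (item,))
        if family == "intercept":
            return replace(self, released_intercepts=self.released_intercepts + (item,))
        raise ValueError(f"cannot release family {family!r}")


# ---------------------------------------------------------------------------
# parameter bookkeeping
#
# Atomic parameters per group, in fixed order:
#   lambda_1..p, tau_1..p, theta_11..pp, theta_(pairs), alpha
# Each atomic maps to a free-vector slot (shared slots implement equality
# constraints) or to a fixed value.


class _ParamMap:
    def __init__(self, spec: ModelSpec, moments: list[GroupMoments]):
        p, q, G = spec.p, len(spec.pairs), spec.n_groups
        self.spec = spec
        self.p, self.q, self.G = p, q, G
        self.m = 3 * p + q + 1  # atomics per group
        free_idx = np.full((G, self.m), -1, dtype=int)
        fixed = np.zeros((G, self.m))
        start: dict[int, list[float]] = {}
        lower: dict[int, float] = {}
        counter = 0

        def new_slot(val: float, lo: float = -np.inf) -> int:
            nonlocal counter
            k = counter
            counter += 1
            start[k] = [val]
            lower[k] = lo
            return k

        ref = spec.reference
        xbar_ref = moments[ref].mean
        var_g = np.array([np.diag(m.cov) for m in moments])  # (G, p)

        for j, item in enumerate(spec.indicators):
            # loadings
            if spec.loadings == "equal" and item not in spec.released_loadings:
                k = new_slot(0.5)
                free_idx[:, j] = k
            else:
                for g in range(G):
                    free_idx[g, j] = new_slot(0.5)
            # intercepts
            col = p + j
            if not spec.mean_structure:
                fixed[:, col] = 0.0
            elif spec.intercepts == "equal" and item not in spec.released_intercepts:
                k = new_slot(float(xbar_ref[j]))
                free_idx[:, col] = k
            else:
                for g in range(G):
                    free_idx[g, col] = new_slot(float(moments[g].mean[j]))
            # residual variances
            col = 2 * p + j
            if spec.resid_var == "equal":
                k = new_slot(float(var_g[:, j].mean()) / 2.0, lo=_THETA_FLOOR)
                free_idx[:, col] = k
            else:
                for g in range(G):
                    free_idx[g, col] = new_slot(float(var_g[g, j]) / 2.0, lo=_THETA_FLOOR)
        for t in range(q):
            col = 3 * p + t
            if spec.resid_cov == "equal":
                k = new_slot(0.0)
                free_idx[:, col] = k
            else:
                for g in range(G):
                    free_idx[g, col] = new_slot(0.0)
        col = 3 * p + q  # latent mean
        if not spec.mean_structure or spec.latent_means == "zero":
            fixed[:, col] = 0.0
        else:
            for g in range(G):
                if g != ref:
                    free_idx[g, col] = new_slot(0.0)

        self.free_idx = free_idx
        self.fixed = fixed
        self.n_free = counter
        self.x0 = np.array([float(np.mean(start[k])) for k in range(counter)])
        self.bounds = [(lower[k], np.inf) if np.isfinite(lower[k]) else (None, None)
                       for k in range(counter)]

    def expand(self, x: np.ndarray) -> np.ndarray:
        """Free vector -> (G, m) atomic values."""
        vals = self.fixed.copy()
        mask = self.free_idx >= 0
        vals[mask] = x[self.free_idx[mask]]
        return vals

    def collapse_grad(self, atom_grad: np.ndarray) -> np.ndarray:
        """(G, m) atomic gradient -> free-vector gradient (summing shared slots)."""
        g = np.zeros(self.n_free)
        mask = self.free_idx >= 0
        np.add.at(g, self.free_idx[mask], atom_grad[mask])
        return g

    def slices(self, vals_g: np.ndarray):
        p, q = self.p, self.q
        lam = vals_g[:p]
        tau = vals_g[p : 2 * p]
        thd = vals_g[2 * p : 3 * p]
        thp = vals_g[3 * p : 3 * p + q]
        alpha = vals_g[3 * p + q]
        return lam, tau, thd, thp, alpha


def _pair_indices(spec: ModelSpec) -> list[tuple[int, int]]:
    pos = {v: i for i, v in enumerate(spec.indicators)}
    return [(pos[a], pos[b]) for a, b in spec.pairs]


# ---------------------------------------------------------------------------
# discrepancy


def _implied(pm: _ParamMap, vals_g: np.ndarray, pidx) -> tuple[np.ndarray, np.ndarray]:
    lam, tau, thd, thp, alpha = pm.slices(vals_g)
    sigma = np.outer(lam, lam) + np.diag(thd)
    for t, (i, j) in enumerate(pidx):
        sigma[i, j] += thp[t]
        sigma[j, i] += thp[t]
    mu = tau + lam * alpha
    return sigma, mu


def make_objective(spec: ModelSpec, moments: list[GroupMoments]):
    """Return ``(f, param_map)`` with ``f(x) -> (F, grad)``.

    ``f`` evaluates the weighted ML discrepancy and its analytic gradient;
    non-positive-definite implied covariances get a large penalty value so
    line searches back off.
    """
    if len(moments) != spec.n_groups:
        raise ValueError(
            f"spec expects {spec.n_groups} groups, got {len(moments)} moment sets"
        )
    for m in moments:
        if tuple(m.variables) != tuple(spec.indicators):
            raise ValueError(
                f"group {m.label!r} variables do not match spec indicators"
            )
    pm = _ParamMap(spec, moments)
    pidx = _pair_indices(spec)
    N = sum(m.n for m in moments)
    w = np.array([m.n / N for m in moments])
    p = spec.p
    logdet_S = []
    for m in moments:
        sign, ld = np.linalg.slogdet(m.cov)
        if sign <= 0:
            raise ValueError(f"group {m.label!r}: sample covariance not positive definite")
        logdet_S.append(ld)
    mean_structure = spec.mean_structure

    def f(x: np.ndarray):
        vals = pm.expand(x)
        F = 0.0
        atom_grad = np.zeros_like(vals)
        for g, mom in enumerate(moments):
            sigma, mu = _implied(pm, vals[g], pidx)
            try:
                c = linalg.cholesky(sigma, lower=True)
            except linalg.LinAlgError:
                eigmin = float(np.linalg.eigvalsh(sigma)[0])
                return 1e10 * (1.0 + abs(eigmin)), np.zeros(pm.n_free)
            W = linalg.cho_solve((c, True), np.eye(p))
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            S = mom.cov
            d = (mom.mean - mu) if mean_structure else np.zeros(p)
            Wd = W @ d
            Fg = logdet - logdet_S[g] + float(np.sum(W * S)) - p + float(d @ Wd)
            F += w[g] * Fg
            # gradient pieces
            lam, tau, thd, thp, alpha = pm.slices(vals[g])
            Gm = W - W @ (S + np.outer(d, d)) @ W
            Glam = Gm @ lam
            ag = np.empty(pm.m)
            ag[:p] = 2.0 * Glam - 2.0 * alpha * Wd          # loadings
            ag[p : 2 * p] = -2.0 * Wd                        # intercepts
            ag[2 * p : 3 * p] = np.diag(Gm)                  # residual variances
            for t, (i, j) in enumerate(pidx):
                ag[3 * p + t] = 2.0 * Gm[i, j]               # residual covariances
            ag[3 * p + len(pidx)] = -2.0 * float(lam @ Wd)   # latent mean
            atom_grad[g] = w[g] * ag
        return F, pm.collapse_grad(atom_grad)

    return f, pm


# ---------------------------------------------------------------------------
# results


@dataclass
class ParamTable:
    """Estimated parameters per group plus the constraint structure applied."""

    indicators: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    loadings: np.ndarray        # (G, p)
    intercepts: np.ndarray      # (G, p)
    resid_var: np.ndarray       # (G, p)
    resid_cov: np.ndarray       # (G, q)
    latent_means: np.ndarray    # (G,)
    spec: ModelSpec

    def to_dict(self) -> dict:
        return {
            "indicators": list(self.indicators),
            "pairs": [list(pr) for pr in self.pairs],
            "loadings": self.loadings.tolist(),
            "intercepts": self.intercepts.tolist(),
            "resid_var": self.resid_var.tolist(),
            "resid_cov": self.resid_cov.tolist(),
            "latent_means": self.latent_means.tolist(),
        }


@dataclass
class FitResult:
    params: ParamTable
    F: float
    chisq: float
    df: int
    loglik: float
    n_free: int
    N: int
    converged: bool
    n_iter: int
    grad_norm: float
    heywood: bool
    implied_cov: list[np.ndarray]
    implied_mean: list[np.ndarray]
    spec: ModelSpec
    moments: list[GroupMoments]
    x: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "F": self.F,
            "chisq": self.chisq,
            "df": self.df,
            "loglik": self.loglik,
            "n_free": self.n_free,
            "N": self.N,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "heywood": self.heywood,
        }


class ConvergenceError(RuntimeError):
    """Optimization failed; carries the best result found so far."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


def _moment_count(spec: ModelSpec) -> int:
    p = spec.p
    per = p * (p + 3) // 2 if spec.mean_structure else p * (p + 1) // 2
    return spec.n_groups * per


def fit(
    spec: ModelSpec,
    moments: list[GroupMoments],
    x0: np.ndarray | None = None,
    max_restarts: int = 5,
) -> FitResult:
    """Minimize the ML discrepancy; raises :class:`ConvergenceError` on failure.

    ``x0`` warm-starts the optimizer (e.g. from the previous ladder level).
    Residual variances are bounded below at 1e-6; a bound hit is flagged as
    a Heywood case on the result rather than raised.
    """
    f, pm = make_objective(spec, moments)
    start = pm.x0 if x0 is None else np.asarray(x0, dtype=float)
    if start.shape != (pm.n_free,):
        raise ValueError(f"x0 has length {start.size}, expected {pm.n_free}")
    rng = np.random.default_rng(_RESTART_SEED)
    best = None
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            f,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=pm.bounds,
            options={"maxiter": 5000, "maxfun": 50000, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        gnorm = float(np.max(np.abs(res.jac)))
        if res.fun < 1e9 and (res.success or gnorm < 1e-5):
            best = res
            break
        # jittered restart
        start = pm.x0 + rng.normal(scale=0.1, size=pm.n_free)
        start = np.clip(start, [b[0] if b[0] is not None else -np.inf for b in pm.bounds], np.inf)
    res = best
    vals = pm.expand(res.x)
    p, q, G = pm.p, pm.q, pm.G
    lam = vals[:, :p]
    tau = vals[:, p : 2 * p]
    thd = vals[:, 2 * p : 3 * p]
    thp = vals[:, 3 * p : 3 * p + q]
    alpha = vals[:, 3 * p + q]
    pidx = _pair_indices(spec)
    implied = [_implied(pm, vals[g], pidx) for g in range(G)]
    N = sum(m.n for m in moments)
    F_val = float(res.fun)
    chisq = max(N * F_val, 0.0)
    df = _moment_count(spec) - pm.n_free
    # raw-data log-likelihood equivalent
    loglik = 0.0
    for g, mom in enumerate(moments):
        sigma, mu = implied[g]
        sign, ld = np.linalg.slogdet(sigma)
        W = np.linalg.inv(sigma)
        d = mom.mean - mu
        loglik += -0.5 * mom.n * (
            p * np.log(2 * np.pi) + ld + float(np.sum(W * mom.cov)) + float(d @ W @ d)
        )
    gnorm = float(np.max(np.abs(res.jac)))
    converged = bool(res.fun < 1e9 and (res.success or gnorm < 1e-5))
    result = FitResult(
        params=ParamTable(
            indicators=spec.indicators,
            pairs=spec.pairs,
            loadings=lam,
            intercepts=tau,
            resid_var=thd,
            resid_cov=thp,
            latent_means=alpha,
            spec=spec,
        ),
        F=F_val,
        chisq=chisq,
        df=df,
        loglik=float(loglik),
        n_free=pm.n_free,
        N=N,
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=gnorm,
        heywood=bool(np.any(thd <= _THETA_FLOOR * 1.01)),
        implied_cov=[s for s, _ in implied],
        implied_mean=[m for _, m in implied],
        spec=spec,
        moments=list(moments),
        x=res.x.copy(),
    )
    if not converged:
        raise ConvergenceError(
            f"optimizer did not converge (F={F_val:.6g}, grad={gnorm:.3g})", best=result
        )
    return result


# ---------------------------------------------------------------------------
# fit indices


@dataclass
class FitIndices:
    cfi: float
    rmsea: float
    rmsea_lo: float
    rmsea_hi: float
    baseline_chisq: float
    baseline_df: int
    rmsea_undefined: bool = False


def _baseline_chisq(moments: list[GroupMoments], mean_structure: bool) -> tuple[float, int]:
    """Independence baseline: free variances (and means), zero covariances.

    Per group the ML solution is the sample means and variances, so the
    discrepancy is available in closed form.
    """
    N = sum(m.n for m in moments)
    p = len(moments[0].variables)
    chisq = 0.0
    for m in moments:
        sign, ld = np.linalg.slogdet(m.cov)
        chisq += m.n * (float(np.sum(np.log(np.diag(m.cov)))) - ld)
    per = p * (p + 3) // 2 - 2 * p if mean_structure else p * (p + 1) // 2 - p
    return max(chisq, 0.0), len(moments) * per


def _ncp_quantile(chisq: float, df: int, q: float) -> float:
    """Noncentrality ncp with P(X2_df(ncp) <= chisq) = q (0 if none)."""
    if stats.ncx2.cdf(chisq, df, 1e-10) <= q:
        return 0.0
    hi = max(chisq, 1.0)
    while stats.ncx2.cdf(chisq, df, hi) > q:
        hi *= 2.0
        if hi > 1e8:
            break
    return float(optimize.brentq(lambda nc: stats.ncx2.cdf(chisq, df, nc) - q, 1e-10, hi))


def fit_indices(fitres: FitResult, moments: list[GroupMoments] | None = None) -> FitIndices:
    """CFI and RMSEA (with 90% noncentral-chi-square CI) for a fitted model.

    The baseline is the per-group independence model.  RMSEA carries the
    sqrt(G) multi-group multiplier.  With df = 0 the RMSEA is undefined and
    reported as 0 with a flag.
    """
    if moments is None:
        moments = fitres.moments
    G = len(moments)
    N = sum(m.n for m in moments)
    chisq_b, df_b = _baseline_chisq(moments, fitres.spec.mean_structure)
    num = max(fitres.chisq - fitres.df, 0.0)
    den = max(chisq_b - df_b, fitres.chisq - fitres.df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if fitres.df == 0:
        return FitIndices(cfi, 0.0, 0.0, 0.0, chisq_b, df_b, rmsea_undefined=True)
    scale = np.sqrt(G)
    rmsea = scale * np.sqrt(num / (fitres.df * N))
    ncp_lo = _ncp_quantile(fitres.chisq, fitres.df, 0.95)
    ncp_hi = _ncp_quantile(fitres.chisq, fitres.df, 0.05)
    lo = scale * np.sqrt(ncp_lo / (fitres.df * N))
    hi = scale * np.sqrt(ncp_hi / (fitres.df * N))
    return FitIndices(float(cfi), float(rmsea), float(lo), float(hi), chisq_b, df_b)


# ---------------------------------------------------------------------------
# modification indices (univariate score tests)


@dataclass
class ModIndexRow:
    family: str                 # 'loading' | 'intercept' | 'resid_var' | 'resid_cov'
    target: str | tuple[str, str]
    group: str                  # group label or 'all'
    stat: float
    epc: float
    skipped: bool = False


def _atomic_derivs(fitres: FitResult, g: int, extra_pairs: list[tuple[int, int]]):
    """Derivative matrices dSigma/datom (m', p, p) and dmu/datom (m', p)."""
    spec = fitres.spec
    p, q = spec.p, len(spec.pairs)
    pidx = _pair_indices(spec)
    lam = fitres.params.loadings[g]
    alpha = fitres.params.latent_means[g]
    m = 3 * p + q + 1
    mx = m + len(extra_pairs)
    Ds = np.zeros((mx, p, p))
    Dm = np.zeros((mx, p))
    for j in range(p):
        Ds[j, j, :] += lam
        Ds[j, :, j] += lam
        Dm[j, j] = alpha
        Dm[p + j, j] = 1.0
        Ds[2 * p + j, j, j] = 1.0
    for t, (i, j) in enumerate(pidx):
        Ds[3 * p + t, i, j] = 1.0
        Ds[3 * p + t, j, i] = 1.0
    Dm[3 * p + q] = lam
    for t, (i, j) in enumerate(extra_pairs):
        Ds[m + t, i, j] = 1.0
        Ds[m + t, j, i] = 1.0
    return Ds, Dm


def _score_info(fitres: FitResult, extra_pairs: list[tuple[int, int]]):
    """Per-group chi-square gradient and expected information over atomics."""
    spec = fitres.spec
    moments = fitres.moments
    p = spec.p
    grads, infos = [], []
    for g, mom in enumerate(moments):
        sigma = fitres.implied_cov[g]
        mu = fitres.implied_mean[g]
        W = np.linalg.inv(sigma)
        S = mom.cov
        d = (mom.mean - mu) if spec.mean_structure else np.zeros(p)
        Gm = W - W @ (S + np.outer(d, d)) @ W
        Wd = W @ d
        Ds, Dm = _atomic_derivs(fitres, g, extra_pairs)
        # gradient of n_g * F_g
        grad = mom.n * (np.einsum("ij,aij->a", Gm, Ds) - 2.0 * Dm @ Wd)
        # expected information of n_g * F_g
        T = np.einsum("ij,ajk,kl->ail", W, Ds, W)
        info = mom.n * (np.einsum("aij,bij->ab", T, Ds) + 2.0 * (Dm @ W @ Dm.T))
        grads.append(grad)
        infos.append(info)
    return grads, infos


def modification_indices(
    fitres: FitResult,
    candidates: list[tuple[str, object, object]],
) -> list[ModIndexRow]:
    """Score-test statistics for freeing each candidate constraint alone.

    Candidates are ``(family, target, group)`` with family in
    ``{'loading', 'intercept', 'resid_var', 'resid_cov'}``; ``group`` is a
    group index, or ``'all'`` for a single shared parameter added in every
    group (used for residual covariances fixed at zero).  Returns the score
    statistic and the expected parameter change for each candidate.
    """
    spec = fitres.spec
    pos = {v: i for i, v in enumerate(spec.indicators)}
    existing = {tuple(sorted((pos[a], pos[b]))) for a, b in spec.pairs}
    # collect extra derivative matrices needed for fixed-zero covariances
    extra_pairs: list[tuple[int, int]] = []
    extra_map: dict[tuple[int, int], int] = {}
    for fam, target, grp in candidates:
        if fam == "resid_cov":
            i, j = sorted((pos[target[0]], pos[target[1]]))
            if (i, j) not in existing and (i, j) not in extra_map:
                extra_map[(i, j)] = len(extra_pairs)
                extra_pairs.append((i, j))
    grads, infos = _score_info(fitres, extra_pairs)
    pm = _ParamMap(spec, fitres.moments)
    m_base = pm.m
    G = spec.n_groups
    p, q = spec.p, len(spec.pairs)

    # free-space score and information
    k = pm.n_free
    s_free = np.zeros(k)
    H = np.zeros((k, k))
    J_rows = []  # per group: (atom indices, free indices)
    for g in range(G):
        idx = pm.free_idx[g]
        mask = idx >= 0
        atoms = np.nonzero(mask)[0]
        fidx = idx[mask]
        J_rows.append((atoms, fidx))
        s_free[fidx] += grads[g][atoms]
        Ig = infos[g][np.ix_(atoms, atoms)]
        np.add.at(H, (fidx[:, None], fidx[None, :]), Ig)
    try:
        H_chol = linalg.cho_factor(H + 1e-10 * np.eye(k))
    except linalg.LinAlgError:
        H_chol = None

    def atom_col(fam: str, target, g: int) -> int | None:
        if fam == "loading":
            return pos[target]
        if fam == "intercept":
            return p + pos[target]
        if fam == "resid_var":
            return 2 * p + pos[target]
        if fam == "resid_cov":
            i, j = sorted((pos[target[0]], pos[target[1]]))
            if (i, j) in existing:
                t = [tuple(sorted((pos[a], pos[b]))) for a, b in spec.pairs].index((i, j))
                return 3 * p + t
            return m_base + extra_map[(i, j)]
        raise ValueError(f"unknown family {fam!r}")

    rows: list[ModIndexRow] = []
    for fam, target, grp in candidates:
        glist = list(range(G)) if grp == "all" else [int(grp)]
        s_c = 0.0
        H_cc = 0.0
        H_cf = np.zeros(k)
        for g in glist:
            col = atom_col(fam, target, g)
            s_c += grads[g][col]
            H_cc += infos[g][col, col]
            atoms, fidx = J_rows[g]
            H_cf[fidx] += infos[g][col, atoms]
        label = "all" if grp == "all" else fitres.moments[int(grp)].label
        if H_chol is None:
            rows.append(ModIndexRow(fam, target, label, np.nan, np.nan, skipped=True))
            continue
        Hi_cf = linalg.cho_solve(H_chol, H_cf)
        schur = H_cc - float(H_cf @ Hi_cf)
        s_adj = s_c - float(H_cf @ linalg.cho_solve(H_chol, s_free))
        if schur <= 1e-12:
            rows.append(ModIndexRow(fam, target, label, np.nan, np.nan, skipped=True))
            continue
        stat = 0.5 * s_adj * s_adj / schur
        epc = -s_adj / schur
        rows.append(ModIndexRow(fam, target, label, float(stat), float(epc)))
    return rows


# ---------------------------------------------------------------------------


def chisq_diff(restricted: FitResult, free: FitResult) -> tuple[float, int]:
    """Likelihood-ratio difference (delta chi-square, delta df) for nested fits."""
    if tuple(restricted.spec.indicators) != tuple(free.spec.indicators):
        raise ValueError("models are not nested: different indicator sets")
    d_chisq = restricted.chisq - free.chisq
    d_df = restricted.df - free.df
    if d_df < 0:
        raise ValueError("restricted model has fewer df than the free model")
    if d_chisq < -1e-6 * max(1.0, free.chisq):
        raise ValueError(
            f"restricted chi-square ({restricted.chisq:.4f}) below free "
            f"({free.chisq:.4f}): models not nested or not converged"
        )
    return float(max(d_chisq, 0.0)), int(d_df)
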