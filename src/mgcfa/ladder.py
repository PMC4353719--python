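"""The measurement-invariance ladder and its calibration.

Orchestrates baseline-model search (residual-covariance pairs added by
modification index until the single-group model fits), the
configural -> weak -> strong -> strict ladder of multi-group fits with
fit-change (delta-CFI) decisions, permutation calibration of the
delta-CFI criterion by shuffling group labels, and the stepwise
partial-invariance search that releases the loading or intercept with the
highest average modification index across groups.

Conventions follow the study design the package replays: the latent
variance is fixed at 1 in every group at every level; latent means are
fixed at 0 everywhere until the strong level, where all but the reference
(youngest) group's means are freed; the configural fit-change is measured
against the single-group full-sample model; residual covariances are
constrained equal across groups after a one-time check that this costs no
fit; delta-CFI is CFI(previous level) - CFI(current level).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cfa import (
    FitIndices,
    FitResult,
    ModelSpec,
    ConvergenceError,
    _ParamMap,
    fit,
    fit_indices,
    modification_indices,
)
from .moments import GroupMoments, GroupingScheme, compute_group_moments, pool_moments

__all__ = [
    "LadderThresholds",
    "LevelResult",
    "MIReport",
    "BaselineTrace",
    "build_baseline",
    "run_ladder",
    "partial_mi_search",
    "calibrate_thresholds",
    "CalibrationResult",
]

LEVELS = ("configural", "weak", "strong", "strict")


@dataclass(frozen=True)
class LadderThresholds:
    """Delta-CFI limits per ladder level.

    Defaults are the calibrated criteria: 0.03 for the configural step
    (measured against the single-group model) and 0.01 for the weak,
    strong, and strict steps.  ``use_rmsea_ci`` additionally reports the
    RMSEA confidence-interval-overlap verdict; it never gates decisions.
    """

    configural: float = 0.03
    weak: float = 0.01
    strong: float = 0.01
    strict: float = 0.01
    use_rmsea_ci: bool = True

    def limit(self, level: str) -> float:
        val = getattr(self, level)
        if val <= 0:
            raise ValueError(f"threshold for {level} must be > 0")
        return val


@dataclass
class LevelResult:
    level: str
    fit: FitResult
    indices: FitIndices
    delta_cfi: float | None
    ci_overlap: bool | None
    passed: bool | None

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "chisq": self.fit.chisq,
            "df": self.fit.df,
            "cfi": self.indices.cfi,
            "rmsea": self.indices.rmsea,
            "rmsea_ci": [self.indices.rmsea_lo, self.indices.rmsea_hi],
            "delta_cfi": self.delta_cfi,
            "ci_overlap": self.ci_overlap,
            "passed": self.passed,
        }


@dataclass
class MIReport:
    """Ladder of fits plus partial-invariance bookkeeping."""

    levels: list[LevelResult]
    single_group: LevelResult
    residcov_equal: bool
    residcov_delta_cfi: float | None
    released_loadings: list[tuple[str, float]] = field(default_factory=list)
    released_intercepts: list[tuple[str, float]] = field(default_factory=list)
    partial_weak: LevelResult | None = None
    partial_strong: LevelResult | None = None
    partial_weak_unattainable: bool = False
    partial_strong_unattainable: bool = False
    truncated_at: str | None = None
    error: str | None = None

    def level(self, name: str) -> LevelResult:
        for lv in self.levels:
            if lv.level == name:
                return lv
        raise KeyError(name)

    @property
    def latent_means(self) -> np.ndarray | None:
        """Latent group means from the (partial) strong model."""
        src = self.partial_strong
        if src is None:
            try:
                src = self.level("strong")
            except KeyError:
                return None
        return src.fit.params.latent_means.copy()

    def to_dict(self) -> dict:
        return {
            "single_group": self.single_group.to_dict(),
            "levels": [lv.to_dict() for lv in self.levels],
            "residcov_equal": self.residcov_equal,
            "residcov_delta_cfi": self.residcov_delta_cfi,
            "released_loadings": [[i, m] for i, m in self.released_loadings],
            "released_intercepts": [[i, m] for i, m in self.released_intercepts],
            "partial_weak": self.partial_weak.to_dict() if self.partial_weak else None,
            "partial_strong": self.partial_strong.to_dict() if self.partial_strong else None,
            "partial_weak_unattainable": self.partial_weak_unattainable,
            "partial_strong_unattainable": self.partial_strong_unattainable,
            "latent_means": None if self.latent_means is None else self.latent_means.tolist(),
            "truncated_at": self.truncated_at,
            "error": self.error,
        }


# ---------------------------------------------------------------------------
# warm starts


def _x0_from_params(spec: ModelSpec, moments: list[GroupMoments], params) -> np.ndarray:
    """Start vector for ``spec`` taken from another fit's parameter table.

    Shared slots get the across-group mean of the source values; parameters
    present in ``spec`` but not estimated before keep their defaults.
    """
    pm = _ParamMap(spec, moments)
    p, q, G = pm.p, pm.q, pm.G
    Gsrc = params.loadings.shape[0]
    vals = np.zeros((G, pm.m))
    for g in range(G):
        gs = min(g, Gsrc - 1)
        vals[g, :p] = params.loadings[gs]
        vals[g, p : 2 * p] = params.intercepts[gs]
        vals[g, 2 * p : 3 * p] = np.maximum(params.resid_var[gs], 1e-4)
        src_pairs = {tuple(sorted(pr)): t for t, pr in enumerate(params.pairs)}
        for t, pr in enumerate(spec.pairs):
            key = tuple(sorted(pr))
            if key in src_pairs:
                vals[g, 3 * p + t] = params.resid_cov[gs, src_pairs[key]]
        vals[g, 3 * p + q] = params.latent_means[gs]
    x0 = np.zeros(pm.n_free)
    cnt = np.zeros(pm.n_free)
    mask = pm.free_idx >= 0
    np.add.at(x0, pm.free_idx[mask], vals[mask])
    np.add.at(cnt, pm.free_idx[mask], 1.0)
    return x0 / np.maximum(cnt, 1.0)


def _fit_warm(spec: ModelSpec, moments: list[GroupMoments], prev: FitResult | None) -> FitResult:
    x0 = None
    if prev is not None:
        x0 = _x0_from_params(spec, moments, prev.params)
    try:
        return fit(spec, moments, x0=x0)
    except ConvergenceError:
        if x0 is not None:
            return fit(spec, moments)  # cold start fallback
        raise


# ---------------------------------------------------------------------------
# baseline search


@dataclass
class BaselineTrace:
    steps: list[dict]
    met_criteria: bool


def build_baseline(
    indicators: tuple[str, ...],
    moments_single_group: GroupMoments,
    cfi_min: float = 0.95,
    rmsea_max: float = 0.08,
    max_pairs: int = 5,
) -> tuple[ModelSpec, BaselineTrace]:
    """Single-group baseline model with a residual-covariance search.

    Starting from local independence, repeatedly frees the residual
    covariance with the largest modification index until the fit criteria
    (CFI >= ``cfi_min`` and RMSEA <= ``rmsea_max``) hold or ``max_pairs``
    pairs have been added.  Returns the augmented spec (single-group; the
    caller re-targets it at G groups) and a fit trace; if the criteria are
    unreachable the trace carries ``met_criteria=False``.
    """
    indicators = tuple(indicators)
    mom = [moments_single_group.subset(indicators)]
    spec = ModelSpec(indicators=indicators, n_groups=1)
    steps: list[dict] = []
    prev = None
    while True:
        res = _fit_warm(spec, mom, prev)
        prev = res
        ind = fit_indices(res)
        ok = ind.cfi >= cfi_min and ind.rmsea <= rmsea_max
        steps.append(
            {
                "pairs": [list(pr) for pr in spec.pairs],
                "chisq": res.chisq,
                "df": res.df,
                "cfi": ind.cfi,
                "rmsea": ind.rmsea,
                "met": ok,
            }
        )
        if ok or len(spec.pairs) >= max_pairs or res.df == 0:
            return spec, BaselineTrace(steps=steps, met_criteria=ok)
        existing = {tuple(sorted(pr)) for pr in spec.pairs}
        cands = [
            ("resid_cov", (a, b), "all")
            for i, a in enumerate(indicators)
            for b in indicators[i + 1 :]
            if (a, b) not in existing and (b, a) not in existing
        ]
        rows = [r for r in modification_indices(res, cands) if not r.skipped]
        if not rows:
            return spec, BaselineTrace(steps=steps, met_criteria=False)
        best = max(rows, key=lambda r: r.stat)
        spec = replace(spec, pairs=spec.pairs + (tuple(best.target),))


# ---------------------------------------------------------------------------
# the ladder


def _level_spec(baseline: ModelSpec, G: int, level: str, residcov_equal: bool) -> ModelSpec:
    common = dict(
        indicators=baseline.indicators,
        pairs=baseline.pairs,
        n_groups=G,
        resid_cov="equal" if residcov_equal else "free",
        released_loadings=baseline.released_loadings,
        released_intercepts=baseline.released_intercepts,
        reference=baseline.reference,
    )
    if level == "configural":
        return ModelSpec(loadings="free", intercepts="free", resid_var="free",
                         latent_means="zero", **common)
    if level == "weak":
        return ModelSpec(loadings="equal", intercepts="free", resid_var="free",
                         latent_means="zero", **common)
    if level == "strong":
        return ModelSpec(loadings="equal", intercepts="equal", resid_var="free",
                         latent_means="reference_zero", **common)
    if level == "strict":
        return ModelSpec(loadings="equal", intercepts="equal", resid_var="equal",
                         latent_means="reference_zero", **common)
    raise ValueError(f"unknown level {level!r}")


def _ci_overlap(a: FitIndices, b: FitIndices) -> bool:
    return a.rmsea_hi >= b.rmsea_lo and b.rmsea_hi >= a.rmsea_lo


def run_ladder(
    baseline: ModelSpec,
    group_moments: list[GroupMoments],
    thresholds: LadderThresholds = LadderThresholds(),
) -> MIReport:
    """Fit the full invariance ladder over the given groups.

    Fits, in order: the single-group full-sample model (pooled moments),
    configural, weak, strong, and strict.  Before the ladder proper, tests
    once whether residual covariances can be constrained equal across
    groups (retained when delta-CFI <= 0.01 and the RMSEA intervals
    overlap).  Any non-convergence truncates the report at that level.
    """
    G = len(group_moments)
    mom = [m.subset(baseline.indicators) for m in group_moments]
    pooled = pool_moments(mom)
    single_spec = replace(baseline, n_groups=1, loadings="free", intercepts="free",
                          resid_var="free", resid_cov="free", latent_means="zero",
                          released_loadings=(), released_intercepts=())
    try:
        single_fit = fit(single_spec, [pooled])
    except ConvergenceError as e:
        lv = LevelResult("single", e.best, fit_indices(e.best), None, None, None)
        return MIReport([], lv, False, None, truncated_at="single", error=str(e))
    single = LevelResult("single", single_fit, fit_indices(single_fit), None, None, None)

    # residual-covariance equality pre-step
    residcov_equal = True
    residcov_delta = None
    prev_fit = single_fit
    if baseline.pairs:
        try:
            cfg_free = _fit_warm(_level_spec(baseline, G, "configural", False), mom, single_fit)
            cfg_eq = _fit_warm(_level_spec(baseline, G, "configural", True), mom, cfg_free)
        except ConvergenceError as e:
            return MIReport([], single, False, None, truncated_at="configural", error=str(e))
        ind_free, ind_eq = fit_indices(cfg_free), fit_indices(cfg_eq)
        residcov_delta = ind_free.cfi - ind_eq.cfi
        residcov_equal = residcov_delta <= 0.01 and _ci_overlap(ind_free, ind_eq)
        cfg_fit = cfg_eq if residcov_equal else cfg_free
        prev_fit = cfg_fit

    levels: list[LevelResult] = []
    prev_indices = single.indices
    report = MIReport([], single, residcov_equal, residcov_delta)
    prev = single_fit
    for level in LEVELS:
        spec = _level_spec(baseline, G, level, residcov_equal)
        try:
            if level == "configural" and baseline.pairs:
                res = prev_fit  # reuse the pre-step fit
            else:
                res = _fit_warm(spec, mom, prev)
        except ConvergenceError as e:
            report.levels = levels
            report.truncated_at = level
            report.error = str(e)
            return report
        ind = fit_indices(res)
        delta = prev_indices.cfi - ind.cfi
        overlap = _ci_overlap(prev_indices, ind)
        passed = delta <= thresholds.limit(level)
        levels.append(LevelResult(level, res, ind, float(delta), overlap, passed))
        prev, prev_indices = res, ind
    report.levels = levels
    return report


# ---------------------------------------------------------------------------
# partial invariance search


def partial_mi_search(
    report: MIReport,
    level: str,
    thresholds: LadderThresholds = LadderThresholds(),
    max_release_frac: float = 0.5,
) -> MIReport:
    """Stepwise release of the loading/intercept with the highest average
    modification index across groups, until the level's delta-CFI passes.

    At the weak level loadings are candidates and the comparison model is
    the configural fit; at the strong level intercepts are candidates and
    the comparison is the (partial) weak fit.  A release frees the
    parameter in all groups simultaneously.  Ties break on the lowest item
    index.  If more than ``max_release_frac`` of the items are released
    without passing, the level is flagged unattainable.
    """
    if level not in ("weak", "strong"):
        raise ValueError("partial invariance is sought only at the weak or strong level")
    lv = report.level(level)
    if lv.passed:
        return report
    if level == "strong":
        weak_lv = report.partial_weak or report.level("weak")
        if not (weak_lv.passed or report.partial_weak is not None):
            raise ValueError("establish (partial) weak invariance before partial strong")
    family = "loading" if level == "weak" else "intercept"
    base_cfi = (
        report.single_group.indices.cfi
        if level == "weak"
        else (report.partial_weak or report.level("weak")).indices.cfi
    )
    spec = lv.fit.spec
    mom = lv.fit.moments
    G = len(mom)
    indicators = spec.indicators
    limit = thresholds.limit(level)
    max_releases = int(np.floor(len(indicators) * max_release_frac))
    cur_fit, cur_ind = lv.fit, lv.indices
    released: list[tuple[str, float]] = []
    while base_cfi - cur_ind.cfi > limit:
        if len(released) >= max_releases:
            if level == "weak":
                report.partial_weak_unattainable = True
            else:
                report.partial_strong_unattainable = True
            break
        done = set(
            spec.released_loadings if family == "loading" else spec.released_intercepts
        )
        cand_items = [it for it in indicators if it not in done]
        cands = [(family, it, g) for it in cand_items for g in range(G)]
        rows = modification_indices(cur_fit, cands)
        avg: dict[str, float] = {}
        for r in rows:
            if not r.skipped:
                avg.setdefault(r.target, []).append(r.stat)  # type: ignore[arg-type]
        if not avg:
            break
        means = {it: float(np.mean(v)) for it, v in avg.items() if len(v) == G}
        if not means:
            break
        # deterministic tie-break: highest mean, then lowest item index
        order = {it: i for i, it in enumerate(indicators)}
        best = min(means, key=lambda it: (-means[it], order[it]))
        spec = spec.with_release(family, best)
        cur_fit = _fit_warm(spec, mom, cur_fit)
        cur_ind = fit_indices(cur_fit)
        released.append((best, means[best]))
    partial = LevelResult(
        f"partial_{level}",
        cur_fit,
        cur_ind,
        float(base_cfi - cur_ind.cfi),
        None,
        base_cfi - cur_ind.cfi <= limit,
    )
    if level == "weak":
        report.partial_weak = partial
        report.released_loadings = released
    else:
        report.partial_strong = partial
        report.released_intercepts = released
    return report


def establish_partial_mi(report: MIReport, thresholds: LadderThresholds = LadderThresholds()) -> MIReport:
    """Run the partial search at the weak level, propagate the released
    loadings into the strong level, and search intercepts there.

    When partial weak releases loadings, the strong model is refitted with
    those releases before the intercept search, so the strong comparison
    is against the partially weak-invariant model.
    """
    if report.truncated_at is not None:
        return report
    report = partial_mi_search(report, "weak", thresholds)
    weak_lv = report.partial_weak or report.level("weak")
    strong_lv = report.level("strong")
    released = tuple(i for i, _ in report.released_loadings)
    if released:
        spec = replace(strong_lv.fit.spec, released_loadings=released)
        mom = strong_lv.fit.moments
        res = _fit_warm(spec, mom, strong_lv.fit)
        ind = fit_indices(res)
        delta = weak_lv.indices.cfi - ind.cfi
        strong_lv = LevelResult("strong", res, ind, float(delta), None,
                                delta <= thresholds.limit("strong"))
        # swap the refitted strong level into the report for the search
        report.levels = [strong_lv if lv.level == "strong" else lv for lv in report.levels]
    if not strong_lv.passed:
        report = partial_mi_search(report, "strong", thresholds)
    return report


# ---------------------------------------------------------------------------
# permutation calibration


@dataclass
class CalibrationResult:
    """Null delta-CFI distributions from group-label shuffles."""

    deltas: dict[str, np.ndarray]
    recommended: dict[str, float | None]
    n_shuffles: int
    grid: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "deltas": {k: v.tolist() for k, v in self.deltas.items()},
            "recommended": self.recommended,
            "n_shuffles": self.n_shuffles,
            "grid": list(self.grid),
        }


def calibrate_thresholds(
    table: pd.DataFrame,
    scheme: GroupingScheme,
    baseline: ModelSpec,
    n_shuffles: int,
    seed: int,
    thresholds: LadderThresholds = LadderThresholds(),
    grid: tuple[float, ...] = (0.01, 0.02, 0.03, 0.05),
    age_col: str = "age",
) -> CalibrationResult:
    """Null delta-CFI distributions by shuffling ages across persons.

    Each shuffle permutes the age column uniformly, forming pseudo groups
    of exactly the original sizes; the full ladder is run and the per-level
    delta-CFI recorded.  The recommended threshold per level is the
    smallest grid value with zero null exceedances (None if every grid
    value is exceeded).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    ages = table[age_col].to_numpy()
    deltas: dict[str, list[float]] = {lv: [] for lv in ("configural",) + LEVELS[1:]}
    for _ in range(n_shuffles):
        shuffled = table.copy()
        shuffled[age_col] = ages[rng.permutation(len(ages))]
        mom = compute_group_moments(shuffled, scheme, baseline.indicators, age_col=age_col)
        report = run_ladder(baseline, mom, thresholds)
        for lv in report.levels:
            deltas[lv.level].append(lv.delta_cfi)
    arrs = {k: np.asarray(v) for k, v in deltas.items()}
    recommended: dict[str, float | None] = {}
    for k, v in arrs.items():
        rec = None
        for t in grid:
            if v.size and np.all(v <= t):
                rec = t
                break
        recommended[k] = rec
    return CalibrationResult(arrs, recommended, n_shuffles, grid)
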