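"""End-to-end study orchestration.

``run_study`` replays the full design on a person x item table: per facet
a baseline-model search, residual-covariance equality check, the
invariance ladder, partial-invariance search, latent group means, and
per-group latent reliability; per domain the same ladder on facet factor
scores; then item- and facet-level residual-age correlations and
random-subset sensitivity.  One scale's failure never aborts the bundle —
the error is recorded and the pipeline continues, mirroring how scales
that fail even configural invariance are carried forward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .instrument import InstrumentLayout, neo_layout
from .ladder import (
    LadderThresholds,
    build_baseline,
    establish_partial_mi,
    run_ladder,
)
from .moments import GroupingScheme, compute_group_moments, default_grouping, pool_moments
from .scores import (
    domain_indicator_scores,
    latent_reliability,
    ols_factor_scores,
    random_subset_correlations,
    residual_age_correlations,
)

__all__ = ["RunConfig", "run_study", "summarize"]


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dumps accepts the bundle."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


@dataclass
class RunConfig:
    """What to run and with which settings."""

    layout: InstrumentLayout = field(default_factory=neo_layout)
    scheme: GroupingScheme = field(default_factory=default_grouping)
    thresholds: LadderThresholds = field(default_factory=LadderThresholds)
    cfi_min: float = 0.95
    rmsea_max: float = 0.08
    max_pairs: int = 5
    do_ladder: bool = True
    do_partial: bool = True
    do_residuals: bool = True
    do_subsets: bool = True
    do_reliability: bool = True
    subsets_B: int = 1000
    subsets_k: int = 12
    seed: int | None = None
    item_alpha: float | None = None   # default 0.05 / n_items
    facet_alpha: float | None = None  # default 0.05 / n_facets

    def validate(self) -> None:
        if self.do_subsets and self.seed is None:
            raise ValueError("a seed is mandatory when the subset analysis is enabled")


def _facet_analysis(table, cfg, facet):
    items = cfg.layout.items_per_facet[facet]
    moments = compute_group_moments(table, cfg.scheme, items)
    pooled = pool_moments(moments)
    baseline, trace = build_baseline(
        items, pooled, cfi_min=cfg.cfi_min, rmsea_max=cfg.rmsea_max, max_pairs=cfg.max_pairs
    )
    out = {"baseline": {"pairs": [list(p) for p in baseline.pairs],
                        "met_criteria": trace.met_criteria,
                        "trace": trace.steps}}
    if not cfg.do_ladder:
        return out
    report = run_ladder(baseline, moments, cfg.thresholds)
    if cfg.do_partial and report.truncated_at is None:
        report = establish_partial_mi(report, cfg.thresholds)
    out["ladder"] = report.to_dict()
    if cfg.do_reliability and report.truncated_at is None:
        cfg_fit = report.level("configural").fit
        out["reliability"] = latent_reliability(cfg_fit).tolist()
    return out


def _domain_analysis(facet_scores, ages, cfg, domain):
    facets = list(cfg.layout.facets_per_domain[domain])
    tab = facet_scores[facets].copy()
    tab["age"] = ages
    moments = compute_group_moments(tab, cfg.scheme, facets)
    pooled = pool_moments(moments)
    baseline, trace = build_baseline(
        facets, pooled, cfi_min=cfg.cfi_min, rmsea_max=cfg.rmsea_max, max_pairs=cfg.max_pairs
    )
    out = {"baseline": {"pairs": [list(p) for p in baseline.pairs],
                        "met_criteria": trace.met_criteria,
                        "trace": trace.steps}}
    if not cfg.do_ladder:
        return out
    report = run_ladder(baseline, moments, cfg.thresholds)
    if cfg.do_partial and report.truncated_at is None:
        report = establish_partial_mi(report, cfg.thresholds)
    out["ladder"] = report.to_dict()
    return out


def run_study(table: pd.DataFrame, config: RunConfig) -> dict:
    """Execute the full study on a person x item table; returns a JSON-able bundle."""
    cfg = config
    cfg.validate()
    layout = cfg.layout
    n_items = len(layout.items)
    n_facets = len(layout.facets)
    item_alpha = cfg.item_alpha if cfg.item_alpha is not None else 0.05 / n_items
    facet_alpha = cfg.facet_alpha if cfg.facet_alpha is not None else 0.05 / n_facets
    bundle: dict = {
        "config": {
            "n_items": n_items,
            "n_facets": n_facets,
            "n_domains": len(layout.domains),
            "groups": list(cfg.scheme.labels),
            "thresholds": {
                "configural": cfg.thresholds.configural,
                "weak": cfg.thresholds.weak,
                "strong": cfg.thresholds.strong,
                "strict": cfg.thresholds.strict,
            },
            "seed": cfg.seed,
            "item_alpha": item_alpha,
            "facet_alpha": facet_alpha,
        },
        "facets": {},
        "domains": {},
        "errors": {},
    }
    ages = table["age"].to_numpy(dtype=float)
    for facet in layout.facets:
        try:
            bundle["facets"][facet] = _facet_analysis(table, cfg, facet)
        except Exception as e:  # crash isolation: record and continue
            bundle["errors"][facet] = str(e)
    # facet factor scores, guarded per facet so one degenerate scale cannot
    # take down the domain-level and residual analyses of the others
    fscore_cols = {}
    for facet in layout.facets:
        try:
            fscore_cols[facet] = ols_factor_scores(
                table, layout.items_per_facet[facet]
            ).scores
        except Exception as e:
            bundle["errors"].setdefault(facet, str(e))
    fscores = pd.DataFrame(fscore_cols, index=table.index)
    for domain in layout.domains:
        try:
            missing = [f for f in layout.facets_per_domain[domain] if f not in fscores]
            if missing:
                raise ValueError(f"facet scores unavailable for {missing}")
            bundle["domains"][domain] = _domain_analysis(fscores, ages, cfg, domain)
        except Exception as e:
            bundle["errors"][domain] = str(e)
    if cfg.do_residuals:
        item_rows = []
        for facet in layout.facets:
            if facet not in fscores:
                continue
            items = layout.items_per_facet[facet]
            fs = ols_factor_scores(table, items)
            df = residual_age_correlations(
                table, fs, items, age=ages, alphas={"bonf": item_alpha}
            )
            df.insert(0, "facet", facet)
            item_rows.append(df)
        if item_rows:
            bundle["item_residual_age"] = pd.concat(
                item_rows, ignore_index=True).to_dict("records")
        facet_rows = []
        for domain in layout.domains:
            facets = list(layout.facets_per_domain[domain])
            if any(f not in fscores for f in facets):
                continue
            dom_scores = ols_factor_scores(fscores, facets)
            df = residual_age_correlations(
                fscores.assign(age=ages), dom_scores, facets, age=ages,
                alphas={"bonf": facet_alpha, "p01": 0.01},
            )
            df.insert(0, "domain", domain)
            facet_rows.append(df)
        if facet_rows:
            bundle["facet_residual_age"] = pd.concat(
                facet_rows, ignore_index=True).to_dict("records")
    if cfg.do_subsets:
        subs = {}
        for i, domain in enumerate(layout.domains):
            try:
                pool = layout.domain_items(domain)
                res = random_subset_correlations(
                    table, domain, pool, age=ages, B=cfg.subsets_B, k=cfg.subsets_k,
                    seed=int(np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31)),
                )
                subs[domain] = res.to_dict()
            except Exception as e:
                bundle["errors"][f"subsets:{domain}"] = str(e)
        bundle["subsets"] = subs
    return _jsonable(bundle)


def summarize(bundle: dict) -> str:
    """Plain-text per-scale summary of a study bundle."""
    if "facets" not in bundle or "config" not in bundle:
        raise ValueError("malformed bundle: missing 'facets' or 'config'")
    lines = []
    header = (f"{'scale':<10} {'level':<12} {'chisq':>10} {'df':>5} {'cfi':>7} "
              f"{'rmsea':>7} {'ci':>15} {'dCFI':>7} {'verdict':>8}")
    lines.append(header)
    lines.append("-" * len(header))

    def emit(name, analysis):
        lad = analysis.get("ladder")
        if lad is None:
            lines.append(f"{name:<10} (no ladder)")
            return
        rows = [lad["single_group"]] + lad["levels"]
        for lv in rows:
            delta = "" if lv["delta_cfi"] is None else f"{lv['delta_cfi']:7.4f}"
            verdict = "" if lv["passed"] is None else ("pass" if lv["passed"] else "FAIL")
            ci = f"[{lv['rmsea_ci'][0]:.3f};{lv['rmsea_ci'][1]:.3f}]"
            lines.append(
                f"{name:<10} {lv['level']:<12} {lv['chisq']:10.2f} {lv['df']:5d} "
                f"{lv['cfi']:7.4f} {lv['rmsea']:7.4f} {ci:>15} {delta:>7} {verdict:>8}"
            )
        nrl = len(lad["released_loadings"])
        nri = len(lad["released_intercepts"])
        lines.append(f"{name:<10} released loadings={nrl} intercepts={nri}")
        if lad["latent_means"] is not None:
            means = " ".join(f"{m:+.2f}" for m in lad["latent_means"])
            lines.append(f"{name:<10} latent means: {means}")

    for facet, analysis in bundle["facets"].items():
        emit(facet, analysis)
    for domain, analysis in bundle["domains"].items():
        emit(domain, analysis)
    if bundle.get("errors"):
        lines.append("errors:")
        for scale, msg in bundle["errors"].items():
            lines.append(f"  {scale}: {msg}")
    return "\n".join(lines)


def save_bundle(bundle: dict, path) -> None:
    Path(path).write_text(json.dumps(bundle, indent=1, sort_keys=True))
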