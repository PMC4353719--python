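"""Synthetic multi-group item-response data with controllable invariance violations.

The generator emulates the statistical structure the downstream analysis
assumes: a 240-item inventory (30 eight-item facets in 5 six-facet
domains) administered to 12 age groups of 150-310 persons.  Each facet is
a one-factor model — item = intercept + loading * latent + residual — with
the latent variance fixed at 1, optional residual-covariance pairs, and
group-specific latent means following a configurable age trajectory.
Facet latents within a domain share a common domain factor (correlation
``domain_cor``), so domain-level scoring and subset analyses operate on
realistically correlated facets.  Non-invariance directives perturb a
single item's loading or intercept by a step (listed groups only) or a
linear-in-group-index drift.

Items are generated continuous (normal); an optional 5-category
discretization by fixed thresholds exists but is off by default.  Ages are
uniform within each group's bracket, with no age-latent dependence within
a group beyond the group's latent mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .instrument import InstrumentLayout, neo_layout
from .moments import GroupMoments, default_grouping

__all__ = [
    "GroupDef",
    "FacetParams",
    "Directive",
    "PopulationSpec",
    "neo_like_template",
    "inject_noninvariance",
    "simulate",
    "implied_facet_moments",
    "TABLE1_SIZES",
    "write_spec",
    "read_spec",
]

# Group sizes of the 12 age groups of the emulated cohort (total 2711).
TABLE1_SIZES = (310, 299, 253, 269, 254, 208, 211, 191, 188, 193, 185, 150)

# fixed thresholds for the optional 5-category discretization (z-scale)
_LIKERT_CUTS = (-1.5, -0.5, 0.5, 1.5)


@dataclass(frozen=True)
class GroupDef:
    """One age group: label, size, and the real-age interval sampled."""

    label: str
    n: int
    age_lo: float
    age_hi: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if not self.age_hi > self.age_lo:
            raise ValueError(f"group {self.label!r}: empty age interval")


@dataclass(frozen=True)
class FacetParams:
    """One facet's measurement parameters (shared across groups before directives)."""

    loadings: tuple[float, ...]
    intercepts: tuple[float, ...]
    resid_var: tuple[float, ...]
    pairs: tuple[tuple[str, str, float], ...] = ()


@dataclass(frozen=True)
class Directive:
    """A controlled invariance violation on one item.

    ``pattern='step'`` adds ``magnitude`` to the parameter in the listed
    groups only; ``pattern='linear'`` adds
    ``magnitude * (g - reference) / (G - 1)`` in every group g.
    """

    item: str
    parameter: str  # 'loading' | 'intercept'
    pattern: str    # 'step' | 'linear'
    magnitude: float
    groups: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.parameter not in ("loading", "intercept"):
            raise ValueError(f"unknown parameter {self.parameter!r} (item {self.item!r})")
        if self.pattern not in ("step", "linear"):
            raise ValueError(f"unknown pattern {self.pattern!r} (item {self.item!r})")
        if not np.isfinite(self.magnitude):
            raise ValueError(f"non-finite magnitude for item {self.item!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """Generating model for a multi-group item-response population."""

    layout: InstrumentLayout
    groups: tuple[GroupDef, ...]
    facet_params: dict[str, FacetParams]
    latent_means: dict[str, tuple[float, ...]]  # facet -> alpha_g per group
    domain_cor: float = 0.4
    directives: tuple[Directive, ...] = ()
    reference: int = 0

    def __post_init__(self) -> None:
        G = len(self.groups)
        for fac in self.layout.facets:
            if fac not in self.facet_params:
                raise ValueError(f"missing parameters for facet {fac!r}")
            fp = self.facet_params[fac]
            p = len(self.layout.items_per_facet[fac])
            if not (len(fp.loadings) == len(fp.intercepts) == len(fp.resid_var) == p):
                raise ValueError(f"facet {fac!r}: parameter lengths do not match {p} items")
            if len(self.latent_means.get(fac, ())) != G:
                raise ValueError(f"facet {fac!r}: latent means must have one entry per group")
            if abs(self.latent_means[fac][self.reference]) > 1e-12:
                raise ValueError(f"facet {fac!r}: reference-group latent mean must be 0")
        if not 0.0 <= self.domain_cor < 1.0:
            raise ValueError("domain_cor must be in [0, 1)")
        items = set(self.layout.items)
        for d in self.directives:
            if d.item not in items:
                raise ValueError(f"directive names unknown item {d.item!r}")
            if d.pattern == "step" and any(g < 0 or g >= G for g in d.groups):
                raise ValueError(f"directive on {d.item!r}: group index out of range")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_params(self, facet: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-group loadings and intercepts (G, p) with directives applied."""
        fp = self.facet_params[facet]
        items = self.layout.items_per_facet[facet]
        G = self.n_groups
        lam = np.tile(np.asarray(fp.loadings, dtype=float), (G, 1))
        tau = np.tile(np.asarray(fp.intercepts, dtype=float), (G, 1))
        for d in self.directives:
            if d.item not in items:
                continue
            j = items.index(d.item)
            tgt = lam if d.parameter == "loading" else tau
            if d.pattern == "step":
                for g in d.groups:
                    tgt[g, j] += d.magnitude
            else:
                for g in range(G):
                    tgt[g, j] += d.magnitude * (g - self.reference) / (G - 1)
        return lam, tau

    def facet_theta(self, facet: str) -> np.ndarray:
        """Residual covariance matrix of a facet (same in every group)."""
        fp = self.facet_params[facet]
        items = self.layout.items_per_facet[facet]
        theta = np.diag(np.asarray(fp.resid_var, dtype=float))
        for a, b, v in fp.pairs:
            i, j = items.index(a), items.index(b)
            theta[i, j] = theta[j, i] = v
        return theta

    def validate(self) -> None:
        """Check every group's implied covariance is positive definite."""
        for fac in self.layout.facets:
            theta = self.facet_theta(fac)
            lam, _ = self.group_params(fac)
            for g in range(self.n_groups):
                sigma = np.outer(lam[g], lam[g]) + theta
                if np.linalg.eigvalsh(sigma)[0] <= 0:
                    raise ValueError(
                        f"facet {fac!r}, group {self.groups[g].label!r}: "
                        "implied covariance not positive definite"
                    )


def neo_like_template(
    layout: InstrumentLayout | None = None,
    group_sizes: tuple[int, ...] | None = None,
    latent_slope: float | dict[str, float] = 0.0,
    domain_cor: float = 0.4,
    residual_pairs: dict[str, tuple[tuple[str, str, float], ...]] | None = None,
) -> PopulationSpec:
    """Fully invariant default population: 240 items, 12 age groups.

    Group sizes default to the emulated cohort's (150-310 per group,
    total 2711).  Facet loadings are evenly spaced over [0.3, 0.8] with
    unit total variance (residuals ``1 - loading**2``) and zero intercepts.
    ``latent_slope`` (scalar or per facet) sets a linear latent trajectory:
    the latent mean of group g is ``slope * z_g`` where ``z_g`` is the
    standardized group mid-age, and the reference (youngest) group is
    shifted back to 0.
    """
    layout = layout or neo_layout()
    scheme = default_grouping()
    sizes = tuple(group_sizes) if group_sizes is not None else TABLE1_SIZES
    if len(sizes) != len(scheme.bins):
        raise ValueError(f"need {len(scheme.bins)} group sizes, got {len(sizes)}")
    groups = []
    for i, ((label, _, _), n) in enumerate(zip(scheme.bins, sizes)):
        lo, hi, _closed = scheme.edges(i)
        groups.append(GroupDef(label=label, n=n, age_lo=lo, age_hi=hi))
    G = len(groups)
    mids = np.array([(g.age_lo + g.age_hi) / 2 for g in groups])
    z = (mids - mids.mean()) / mids.std()
    facet_params: dict[str, FacetParams] = {}
    latent_means: dict[str, tuple[float, ...]] = {}
    pairs = residual_pairs or {}
    for fac in layout.facets:
        p = len(layout.items_per_facet[fac])
        lam = np.linspace(0.3, 0.8, p)
        facet_params[fac] = FacetParams(
            loadings=tuple(lam),
            intercepts=(0.0,) * p,
            resid_var=tuple(1.0 - lam**2),
            pairs=tuple(pairs.get(fac, ())),
        )
        slope = latent_slope.get(fac, 0.0) if isinstance(latent_slope, dict) else latent_slope
        alpha = slope * z
        alpha = alpha - alpha[0]  # reference group pinned at 0
        latent_means[fac] = tuple(float(a) for a in alpha)
    return PopulationSpec(
        layout=layout,
        groups=tuple(groups),
        facet_params=facet_params,
        latent_means=latent_means,
        domain_cor=domain_cor,
    )


def inject_noninvariance(
    spec: PopulationSpec, directives: list[Directive] | tuple[Directive, ...]
) -> PopulationSpec:
    """Copy of the population with additional invariance violations."""
    items = set(spec.layout.items)
    for d in directives:
        if d.item not in items:
            raise ValueError(f"directive names unknown item {d.item!r}")
    return replace(spec, directives=spec.directives + tuple(directives))


def implied_facet_moments(spec: PopulationSpec, facet: str) -> list[GroupMoments]:
    """Population moments of one facet's items, one per group.

    These are the exact generating moments; feeding them to the estimator
    as if they were sample moments yields chi-square 0 for a correctly
    specified model.
    """
    items = spec.layout.items_per_facet[facet]
    theta = spec.facet_theta(facet)
    lam, tau = spec.group_params(facet)
    out = []
    for g, gd in enumerate(spec.groups):
        alpha = spec.latent_means[facet][g]
        sigma = np.outer(lam[g], lam[g]) + theta
        mu = tau[g] + lam[g] * alpha
        out.append(GroupMoments(label=gd.label, n=gd.n, mean=mu, cov=sigma, variables=items))
    return out


def simulate(
    spec: PopulationSpec, seed: int, discretize: bool = False
) -> pd.DataFrame:
    """Draw a person x item response table from the population.

    For each person in group g the facet latents are
    ``eta_f = sqrt(rho) xi_dom + sqrt(1-rho) u_f + alpha_gf`` with
    independent standard-normal domain and facet draws; item j of facet f
    is ``tau_jg + lambda_jg eta_f + eps`` with facet residuals drawn from
    ``N(0, Theta_f)``.  Ages are uniform within the group bracket.  Three
    independent substreams (ages, latents, residuals) are spawned from the
    seed, so adding items does not perturb ages.  Deterministic given the
    spec and seed.
    """
    spec.validate()
    ss = np.random.SeedSequence(seed)
    rng_age, rng_lat, rng_res = (np.random.default_rng(s) for s in ss.spawn(3))
    layout = spec.layout
    facets = layout.facets
    rho = spec.domain_cor
    rows_age, rows_group = [], []
    blocks = []
    ids = []
    pid = 0
    for g, gd in enumerate(spec.groups):
        n = gd.n
        ages = rng_age.uniform(gd.age_lo, gd.age_hi, size=n)
        rows_age.append(ages)
        rows_group.extend([gd.label] * n)
        ids.extend(range(pid, pid + n))
        pid += n
        # latents: one domain factor per domain, one unique factor per facet
        xi = {d: rng_lat.standard_normal(n) for d in layout.domains}
        eta = {}
        for fac in facets:
            u = rng_lat.standard_normal(n)
            dom = layout.domain_of(fac)
            eta[fac] = (
                np.sqrt(rho) * xi[dom]
                + np.sqrt(1.0 - rho) * u
                + spec.latent_means[fac][g]
            )
        cols = []
        for fac in facets:
            items = layout.items_per_facet[fac]
            theta = spec.facet_theta(fac)
            lam, tau = spec.group_params(fac)
            L = np.linalg.cholesky(theta)
            eps = rng_res.standard_normal((n, len(items))) @ L.T
            x = tau[g] + np.outer(eta[fac], lam[g]) + eps
            cols.append(x)
        blocks.append(np.hstack(cols))
    data = np.vstack(blocks)
    if discretize:
        data = np.digitize(data, _LIKERT_CUTS) + 1.0
    table = pd.DataFrame(data, columns=list(layout.items))
    table.insert(0, "group", rows_group)
    table.insert(0, "age", np.concatenate(rows_age))
    table.insert(0, "id", ids)
    return table


# ---------------------------------------------------------------------------
# lossless round-trip of the population spec (JSON key-value config)


def write_spec(path, spec: PopulationSpec) -> None:
    doc = {
        "layout": {
            "domains": list(spec.layout.domains),
            "facets_per_domain": {d: list(v) for d, v in spec.layout.facets_per_domain.items()},
            "items_per_facet": {f: list(v) for f, v in spec.layout.items_per_facet.items()},
        },
        "groups": [
            {"label": g.label, "n": g.n, "age_lo": g.age_lo, "age_hi": g.age_hi}
            for g in spec.groups
        ],
        "facet_params": {
            f: {
                "loadings": list(fp.loadings),
                "intercepts": list(fp.intercepts),
                "resid_var": list(fp.resid_var),
                "pairs": [list(pr) for pr in fp.pairs],
            }
            for f, fp in spec.facet_params.items()
        },
        "latent_means": {f: list(v) for f, v in spec.latent_means.items()},
        "domain_cor": spec.domain_cor,
        "reference": spec.reference,
        "directives": [
            {
                "item": d.item,
                "parameter": d.parameter,
                "pattern": d.pattern,
                "magnitude": d.magnitude,
                "groups": list(d.groups),
            }
            for d in spec.directives
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_spec(path) -> PopulationSpec:
    with open(path) as fh:
        doc = json.load(fh)
    layout = InstrumentLayout(
        domains=tuple(doc["layout"]["domains"]),
        facets_per_domain={d: tuple(v) for d, v in doc["layout"]["facets_per_domain"].items()},
        items_per_facet={f: tuple(v) for f, v in doc["layout"]["items_per_facet"].items()},
    )
    return PopulationSpec(
        layout=layout,
        groups=tuple(
            GroupDef(g["label"], g["n"], g["age_lo"], g["age_hi"]) for g in doc["groups"]
        ),
        facet_params={
            f: FacetParams(
                loadings=tuple(fp["loadings"]),
                intercepts=tuple(fp["intercepts"]),
                resid_var=tuple(fp["resid_var"]),
                pairs=tuple((a, b, float(v)) for a, b, v in fp["pairs"]),
            )
            for f, fp in doc["facet_params"].items()
        },
        latent_means={f: tuple(v) for f, v in doc["latent_means"].items()},
        domain_cor=doc["domain_cor"],
        reference=doc["reference"],
        directives=tuple(
            Directive(d["item"], d["parameter"], d["pattern"], d["magnitude"], tuple(d["groups"]))
            for d in doc["directives"]
        ),
    )
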