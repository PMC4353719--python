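"""Instrument layout: the domain -> facet -> item hierarchy of a questionnaire.

The default template mirrors a five-domain personality inventory in which
each domain comprises six facets of eight items each (240 items, 30
facets).  Layouts are plain data: every item belongs to exactly one facet
and every facet to exactly one domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class InstrumentLayout:
    """Hierarchical item organisation of a questionnaire.

    Parameters
    ----------
    domains
        Ordered domain labels.
    facets_per_domain
        Mapping from each domain to its ordered facet labels.
    items_per_facet
        Mapping from each facet to its ordered item labels.
    """

    domains: tuple[str, ...]
    facets_per_domain: dict[str, tuple[str, ...]]
    items_per_facet: dict[str, tuple[str, ...]]
    _facet_of: dict[str, str] = field(init=False, repr=False, compare=False, default_factory=dict)
    _domain_of: dict[str, str] = field(init=False, repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.facets_per_domain) != set(self.domains):
            raise ValueError("facets_per_domain keys must equal domains")
        facet_of: dict[str, str] = {}
        domain_of: dict[str, str] = {}
        for dom in self.domains:
            for fac in self.facets_per_domain[dom]:
                if fac in domain_of:
                    raise ValueError(f"facet {fac!r} appears in more than one domain")
                domain_of[fac] = dom
        if set(self.items_per_facet) != set(domain_of):
            raise ValueError("items_per_facet keys must equal the set of facets")
        for fac, items in self.items_per_facet.items():
            for it in items:
                if it in facet_of:
                    raise ValueError(f"item {it!r} appears in more than one facet")
                facet_of[it] = fac
        object.__setattr__(self, "_facet_of", facet_of)
        object.__setattr__(self, "_domain_of", domain_of)

    @property
    def facets(self) -> tuple[str, ...]:
        return tuple(f for d in self.domains for f in self.facets_per_domain[d])

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(i for f in self.facets for i in self.items_per_facet[f])

    def facet_of(self, item: str) -> str:
        return self._facet_of[item]

    def domain_of(self, facet: str) -> str:
        return self._domain_of[facet]

    def domain_items(self, domain: str) -> tuple[str, ...]:
        """All items of a domain, in facet order."""
        return tuple(
            i for f in self.facets_per_domain[domain] for i in self.items_per_facet[f]
        )


def neo_layout(
    n_domains: int = 5,
    facets_per_domain: int = 6,
    items_per_facet: int = 8,
) -> InstrumentLayout:
    """Default template: 5 domains x 6 facets x 8 items = 240 items.

    Domains are labelled N, E, O, A, C; facets N1..N6 etc.; items
    ``<facet>_i1`` .. ``<facet>_i8``.
    """
    base = "NEOAC"
    if n_domains <= len(base):
        doms = tuple(base[:n_domains])
    else:
        doms = tuple(f"D{i + 1}" for i in range(n_domains))
    fpd = {d: tuple(f"{d}{j + 1}" for j in range(facets_per_domain)) for d in doms}
    ipf = {
        f: tuple(f"{f}_i{k + 1}" for k in range(items_per_facet))
        for d in doms
        for f in fpd[d]
    }
    return InstrumentLayout(domains=doms, facets_per_domain=fpd, items_per_facet=ipf)
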