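"""Degree-preserving network randomization and category enrichment.

The called interaction network is compared against a null ensemble produced
by random double-edge swaps, which preserve every node's degree exactly
while destroying higher-order structure.  Enrichment of edges within or
between node categories (e.g. host proteins targeted by viruses, cancer
census genes) is summarized by an empirical p-value with the standard
+1/(n+1) correction.  Homodimeric (self) edges are excluded from both the
observed statistic and the null, since a double-edge swap cannot preserve
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import canonical_pair

__all__ = [
    "InteractionNetwork",
    "EnrichmentResult",
    "rewire",
    "category_enrichment",
    "shared_target_enrichment",
]


@dataclass
class InteractionNetwork:
    """An undirected ORF interaction network with multi-label node categories."""

    categories: dict[str, set[str]]  # node -> category labels
    edges: set[tuple[str, str]]  # canonical pairs, no self-edges
    homodimers: set[str] = field(default_factory=set)

    @classmethod
    def from_edges(
        cls,
        pairs,
        categories: dict[str, set[str]] | None = None,
    ) -> "InteractionNetwork":
        edges: set[tuple[str, str]] = set()
        homodimers: set[str] = set()
        nodes: set[str] = set()
        for a, b in pairs:
            nodes.update((a, b))
            if a == b:
                homodimers.add(a)
            else:
                edges.add(canonical_pair(a, b))
        cats = {n: set() for n in nodes}
        if categories:
            for n, c in categories.items():
                cats.setdefault(n, set()).update(c)
        return cls(categories=cats, edges=edges, homodimers=homodimers)

    @property
    def nodes(self) -> set[str]:
        return set(self.categories)

    def degree_sequence(self) -> dict[str, int]:
        deg = {n: 0 for n in self.categories}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for n, c in self.categories.items():
            g.add_node(n, categories=sorted(c))
        g.add_edges_from(self.edges)
        return g


def rewire(
    network: InteractionNetwork,
    swaps_per_edge: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_swaps: int | None = None,
) -> InteractionNetwork:
    """Randomize by repeated double-edge swaps, preserving the degree sequence.

    Each step picks two distinct edges uniformly, exchanges endpoints (with
    a random pairing so both swap outcomes are equiprobable), and rejects
    swaps that would create a self-edge or a duplicate.  Runs until
    ``swaps_per_edge × |E|`` swaps (or ``n_swaps``, if given) are accepted,
    or gives up with a warning on networks with no valid swap (e.g. a
    triangle).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    edges = [list(e) for e in sorted(network.edges)]
    m = len(edges)
    if m < 2:
        warnings.warn("rewire: fewer than 2 edges; returning network unchanged")
        return InteractionNetwork(
            categories={n: set(c) for n, c in network.categories.items()},
            edges=set(network.edges),
            homodimers=set(network.homodimers),
        )
    edge_set = {tuple(sorted(e)) for e in edges}
    target = n_swaps if n_swaps is not None else swaps_per_edge * m
    accepted = 0
    attempts = 0
    max_attempts = max(1000, 200 * target)
    while accepted < target and attempts < max_attempts:
        attempts += 1
        i = int(rng.integers(0, m))
        j = int(rng.integers(0, m - 1))
        if j >= i:
            j += 1
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed: (a, c) and (b, d)
        if a == c or b == d:
            continue
        e1 = tuple(sorted((a, c)))
        e2 = tuple(sorted((b, d)))
        if e1 == e2 or e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(tuple(sorted((a, b))))
        edge_set.discard(tuple(sorted((c, d))))
        edge_set.update((e1, e2))
        edges[i] = list(e1)
        edges[j] = list(e2)
        accepted += 1
    if accepted < target:
        warnings.warn(
            f"rewire: accepted {accepted}/{target} swaps before giving up "
            "(network may admit no valid swap)"
        )
    return InteractionNetwork(
        categories={n: set(c) for n, c in network.categories.items()},
        edges=set(edge_set),
        homodimers=set(network.homodimers),
    )


@dataclass
class EnrichmentResult:
    statistic_name: str
    observed: int
    null_mean: float
    null_sd: float
    empirical_p: float
    n_rewired_networks: int
    z: float


def _null_distribution(
    network: InteractionNetwork,
    statistic,
    n_null: int,
    swaps_per_edge: int,
    seed: int,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.array(
        [statistic(rewire(network, swaps_per_edge, rng=rng).edges) for _ in range(n_null)]
    )


def _enrichment(
    network: InteractionNetwork,
    statistic,
    name: str,
    n_null: int,
    swaps_per_edge: int,
    seed: int,
) -> EnrichmentResult:
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    observed = statistic(network.edges)
    null = _null_distribution(network, statistic, n_null, swaps_per_edge, seed)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_null > 1 else 0.0
    p = (1 + int((null >= observed).sum())) / (1 + n_null)
    z = (observed - mean) / sd if sd > 0 else float("nan")
    return EnrichmentResult(
        statistic_name=name,
        observed=int(observed),
        null_mean=mean,
        null_sd=sd,
        empirical_p=p,
        n_rewired_networks=n_null,
        z=z,
    )


def category_enrichment(
    network: InteractionNetwork,
    category_a: str,
    category_b: str,
    n_null: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> EnrichmentResult:
    """Enrichment of edges joining category_a to category_b nodes.

    For ``category_a == category_b`` this counts edges with both endpoints
    in the category; otherwise edges with one endpoint in each.
    """
    cats = network.categories
    if not any(category_a in c for c in cats.values()):
        raise ValueError(f"no node carries category {category_a!r}")
    if not any(category_b in c for c in cats.values()):
        raise ValueError(f"no node carries category {category_b!r}")

    def stat(edges) -> int:
        n = 0
        for u, v in edges:
            cu, cv = cats[u], cats[v]
            if (category_a in cu and category_b in cv) or (
                category_b in cu and category_a in cv
            ):
                n += 1
        return n

    return _enrichment(
        network, stat, f"{category_a}-{category_b} edges", n_null, swaps_per_edge, seed
    )


def shared_target_enrichment(
    network: InteractionNetwork,
    annotations: dict[str, set[str]],
    n_null: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> EnrichmentResult:
    """Enrichment of edges whose endpoints share >= 1 annotation.

    The canonical use: pairs of host proteins each known to be targeted by a
    common viral protein.
    """
    if not annotations:
        raise ValueError("annotation map must be non-empty")

    def stat(edges) -> int:
        return sum(
            1
            for u, v in edges
            if annotations.get(u, set()) & annotations.get(v, set())
        )

    return _enrichment(
        network, stat, "shared-annotation edges", n_null, swaps_per_edge, seed
    )
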