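"""Cross-organ module conservation statistics.

Modules from different organs are compared by Jaccard similarity of their
member sets; overlap significance comes from a one-sided (upper-tail)
hypergeometric test with pooled BH correction over all inter-organ pairs.
Connected components of the resulting module similarity network spanning at
least two organs are "conservation groups" (labeled BC1, BC2, ... by
descending gene content); module triples with one module per organ and all
three pairwise edges present are triangle motifs, whose three-way overlap is
scored by fold enrichment against the chance expectation
``E[overlap] = n1 * n2 / N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd
from scipy import stats

from .community import GeneModule, ModuleCollection
from .errors import DataError
from .network import bh_adjust

__all__ = [
    "ModuleSimilarityEdge",
    "ConservationGroup",
    "ConservedSubgroup",
    "jaccard",
    "hypergeom_overlap_test",
    "build_similarity_network",
    "conservation_groups",
    "find_triangles",
    "three_way_subgroup",
    "similarity_edges_to_frame",
]

ModuleKey = tuple[str, int]  # (organ, module_id)


@dataclass(frozen=True)
class ModuleSimilarityEdge:
    module_a: ModuleKey
    module_b: ModuleKey
    jaccard: float
    overlap_k: int
    p: float
    q: float


@dataclass
class ConservationGroup:
    group_id: str
    member_modules: set[ModuleKey]
    organs_present: set[str]
    union_genes: set[str]


@dataclass
class ConservedSubgroup:
    triple: tuple[ModuleKey, ModuleKey, ModuleKey]
    core_genes: set[str]
    observed_overlap: int
    expected_overlap: float
    fold_enrichment: float | None
    p: float
    q: float | None = None

    @property
    def conserved(self) -> bool:
        return self.fold_enrichment is not None


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; undefined (error) when both sets are empty."""
    union = len(a | b)
    if union == 0:
        raise DataError("Jaccard undefined for two empty sets")
    return len(a & b) / union


def hypergeom_overlap_test(k: int, n1: int, n2: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, n1, n2)."""
    if not (0 <= k <= min(n1, n2) and 0 <= n1 <= N and 0 <= n2 <= N):
        raise DataError(
            f"inconsistent hypergeometric counts k={k}, n1={n1}, n2={n2}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, n1, n2))


def _background_size(
    coll_a: ModuleCollection, coll_b: ModuleCollection, background
) -> int:
    if isinstance(background, int):
        return background
    if background == "union":
        return len(coll_a.universe | coll_b.universe)
    if background == "intersection":
        return len(coll_a.universe & coll_b.universe)
    raise DataError(f"unknown background convention {background!r}")


def build_similarity_network(
    collections: list[ModuleCollection],
    q_threshold: float = 0.05,
    background="union",
) -> list[ModuleSimilarityEdge]:
    """Significant-overlap edges between modules of different organs.

    Every inter-organ module pair is tested; BH is pooled over all tests
    jointly; an edge is retained iff ``q <= q_threshold`` and it has at least
    one shared gene. ``background`` selects the universe size N for the
    hypergeometric test: "union" (default) or "intersection" of the two
    organs' network gene universes, or a fixed integer.
    """
    if len(collections) < 2:
        raise DataError("need modules from at least two organs")
    tests = []  # (key_a, key_b, jac, k, p)
    for coll_a, coll_b in combinations(collections, 2):
        if coll_a.organ == coll_b.organ:
            raise DataError("duplicate organ label in collections")
        N = _background_size(coll_a, coll_b, background)
        for ma in coll_a.modules:
            a = set(ma.members) if background != "intersection" else (
                set(ma.members) & coll_b.universe & coll_a.universe
            )
            for mb in coll_b.modules:
                b = set(mb.members) if background != "intersection" else (
                    set(mb.members) & coll_a.universe & coll_b.universe
                )
                k = len(a & b)
                jac = jaccard(a, b) if (a or b) else 0.0
                p = hypergeom_overlap_test(k, len(a), len(b), N)
                tests.append(
                    ((coll_a.organ, ma.module_id), (coll_b.organ, mb.module_id), jac, k, p)
                )
    if not tests:
        return []
    qvals = bh_adjust([t[4] for t in tests])
    edges = [
        ModuleSimilarityEdge(a, b, jac, k, p, float(q))
        for (a, b, jac, k, p), q in zip(tests, qvals)
        if q <= q_threshold and k >= 1
    ]
    return edges


def conservation_groups(
    edges: list[ModuleSimilarityEdge],
    collections: list[ModuleCollection],
) -> list[ConservationGroup]:
    """Connected components of the module similarity network.

    Components present in only one organ are excluded; groups are ordered by
    total (union) gene count descending and labeled BC1, BC2, ...
    """
    members_of = {
        (c.organ, m.module_id): set(m.members) for c in collections for m in c.modules
    }
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.module_a, e.module_b)
    groups = []
    for component in nx.connected_components(g):
        organs = {organ for organ, _ in component}
        if len(organs) < 2:
            continue
        union: set[str] = set()
        for key in component:
            union |= members_of.get(key, set())
        groups.append((component, organs, union))
    groups.sort(key=lambda t: (-len(t[2]), sorted(t[0])))
    return [
        ConservationGroup(f"BC{i + 1}", set(comp), organs, union)
        for i, (comp, organs, union) in enumerate(groups)
    ]


def find_triangles(
    group: ConservationGroup, edges: list[ModuleSimilarityEdge]
) -> list[tuple[ModuleKey, ModuleKey, ModuleKey]]:
    """All module triples in the group, one per distinct organ, with all
    three pairwise edges present; lexicographic by (organ, module_id)."""
    edge_set = {frozenset((e.module_a, e.module_b)) for e in edges}
    by_organ: dict[str, list[ModuleKey]] = {}
    for key in group.member_modules:
        by_organ.setdefault(key[0], []).append(key)
    organs = sorted(by_organ)
    triangles = []
    for o1, o2, o3 in combinations(organs, 3):
        for a in sorted(by_organ[o1]):
            for b in sorted(by_organ[o2]):
                if frozenset((a, b)) not in edge_set:
                    continue
                for c in sorted(by_organ[o3]):
                    if (
                        frozenset((a, c)) in edge_set
                        and frozenset((b, c)) in edge_set
                    ):
                        triangles.append((a, b, c))
    triangles.sort()
    return triangles


def three_way_subgroup(
    mod_a: GeneModule,
    mod_b: GeneModule,
    mod_c: GeneModule,
    N: int,
    pairing: str = "last",
) -> ConservedSubgroup:
    """Three-way conserved overlap of one module per organ.

    The intersection of two modules is computed first and its overlap with
    the third module is scored: with ``n1 = |A ∩ B|``, ``n2 = |C|`` and
    background ``N``, ``expected = n1*n2/N`` and
    ``fold = observed * N / (n1*n2)``. The core gene set ``A ∩ B ∩ C`` is
    identical under all three pairings; the reported statistics follow the
    configured pairing convention (default "last": the third module is the
    one from the lexicographically last organ). An empty pairwise
    intersection yields fold ``None`` (not conserved).
    """
    mods = sorted([mod_a, mod_b, mod_c], key=lambda m: m.organ)
    if len({m.organ for m in mods}) != 3:
        raise DataError("three-way subgroup needs modules from three distinct organs")
    if N < max(m.size for m in mods):
        raise DataError("background N smaller than a module size")
    if pairing not in {"last", "first"}:
        raise DataError(f"unknown pairing convention {pairing!r}")
    third = mods[2] if pairing == "last" else mods[0]
    pair = [m for m in mods if m is not third]
    inter = set(pair[0].members) & set(pair[1].members)
    core = inter & set(third.members)
    n1, n2 = len(inter), third.size
    expected = n1 * n2 / N
    if n1 == 0:
        return ConservedSubgroup(
            triple=tuple((m.organ, m.module_id) for m in mods),
            core_genes=core,
            observed_overlap=0,
            expected_overlap=expected,
            fold_enrichment=None,
            p=1.0,
        )
    fold = len(core) * N / (n1 * n2)
    p = hypergeom_overlap_test(len(core), n1, n2, N)
    return ConservedSubgroup(
        triple=tuple((m.organ, m.module_id) for m in mods),
        core_genes=core,
        observed_overlap=len(core),
        expected_overlap=expected,
        fold_enrichment=fold,
        p=p,
    )


def similarity_edges_to_frame(edges: list[ModuleSimilarityEdge]) -> pd.DataFrame:
    rows = [
        (
            e.module_a[0],
            e.module_a[1],
            e.module_b[0],
            e.module_b[1],
            e.jaccard,
            e.overlap_k,
            e.p,
            e.q,
        )
        for e in edges
    ]
    rows.sort()
    return pd.DataFrame(
        rows,
        columns=[
            "organ_a",
            "module_a",
            "organ_b",
            "module_b",
            "jaccard",
            "overlap_k",
            "p",
            "q",
        ],
    )
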