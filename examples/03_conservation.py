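"""Cross-organ module conservation: similarity network, groups, triangles.

Modules from different organs are linked when their gene overlap is
significant (one-sided hypergeometric, pooled BH); connected components are
conservation groups (BC1, BC2, ...) and module triples with all three
pairwise links are triangle motifs scored by fold enrichment
observed / (n1 * n2 / N).
"""

from organnet import (
    build_network,
    build_similarity_network,
    conservation_groups,
    default_config,
    find_triangles,
    generate_study,
    leiden_modules,
    spearman_all_pairs,
    three_way_subgroup,
)
from organnet.preprocess import preprocess

collections = []
for expr, samples, truth in generate_study(default_config(seed=42)):
    filtered, _ = preprocess(expr)
    net = build_network(spearman_all_pairs(filtered), organ=truth.organ)
    collections.append(leiden_modules(net, seed=42))

edges = build_similarity_network(collections, q_threshold=0.05)
groups = conservation_groups(edges, collections)
print(f"{len(edges)} significant similarity edges, {len(groups)} conservation groups")
by_organ = {c.organ: c for c in collections}
for group in groups:
    triangles = find_triangles(group, edges)
    print(f"{group.group_id}: {len(group.member_modules)} modules from "
          f"{sorted(group.organs_present)}, {len(group.union_genes)} genes, "
          f"{len(triangles)} triangle(s)")
    for tri in triangles:
        mods = [by_organ[o].module(m) for o, m in tri]
        sub = three_way_subgroup(*mods, N=len(by_organ[sorted(tri)[2][0]].universe))
        print(f"   triangle {tri}: core {sub.observed_overlap} genes, "
              f"expected {sub.expected_overlap:.2f}, "
              f"fold {sub.fold_enrichment:.1f}, p = {sub.p:.2e}")
# Fold enrichment far above 1 with tiny p means the three-way overlap is far
# larger than chance: a conserved cross-organ transcriptional program.
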