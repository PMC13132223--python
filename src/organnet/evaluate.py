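"""Ground-truth comparison helpers for simulated studies.

These utilities score pipeline output against the generator's planted
structure: adjusted Rand index of detected vs planted module memberships,
matching of detected modules to planted labels, and recovery of planted
cross-organ correspondences and trios in the similarity network.
"""

from __future__ import annotations

from itertools import combinations

from sklearn.metrics import adjusted_rand_score

from .community import ModuleCollection
from .conservation import ModuleSimilarityEdge
from .simulate import GroundTruth

__all__ = [
    "membership_ari",
    "match_modules",
    "planted_pair_recovery",
    "planted_trio_recovery",
]


def membership_ari(collection: ModuleCollection, truth: GroundTruth) -> float:
    """Adjusted Rand index between detected and planted memberships.

    Computed over the genes assigned to retained modules; planted labels for
    genes outside any module are 'background'.
    """
    detected = collection.membership()
    genes = sorted(detected)
    if not genes:
        return 0.0
    planted = [truth.membership.get(g, "background") for g in genes]
    found = [detected[g] for g in genes]
    return float(adjusted_rand_score(planted, found))


def match_modules(collection: ModuleCollection, truth: GroundTruth) -> dict[str, int]:
    """Best detected module for each planted label (max overlap count).

    Labels whose planted genes are absent from every detected module are
    omitted.
    """
    out: dict[str, int] = {}
    for label in truth.module_labels():
        members = truth.members(label)
        best, best_overlap = None, 0
        for m in collection.modules:
            overlap = len(members & m.members)
            if overlap > best_overlap:
                best, best_overlap = m.module_id, overlap
        if best is not None:
            out[label] = best
    return out


def planted_pair_recovery(
    edges: list[ModuleSimilarityEdge],
    collections: list[ModuleCollection],
    truths: list[GroundTruth],
) -> dict:
    """Fraction of planted cross-organ module pairs recovered as significant
    similarity edges (via max-overlap matching of detected modules)."""
    by_organ = {c.organ: c for c in collections}
    truth_by_organ = {t.organ: t for t in truths}
    matches = {
        organ: match_modules(by_organ[organ], truth_by_organ[organ])
        for organ in by_organ
    }
    edge_set = {frozenset((e.module_a, e.module_b)) for e in edges}
    total, hit, missing = 0, 0, []
    for corr in truths[0].correspondences:
        label = corr["label"]
        organs = [truths[i].organ for i in corr["organs"] if truths[i].organ in by_organ]
        for oa, ob in combinations(organs, 2):
            if label not in matches[oa] or label not in matches[ob]:
                total += 1
                missing.append((label, oa, ob))
                continue
            total += 1
            key = frozenset(((oa, matches[oa][label]), (ob, matches[ob][label])))
            if key in edge_set:
                hit += 1
            else:
                missing.append((label, oa, ob))
    return {
        "n_planted_pairs": total,
        "n_recovered": hit,
        "recovery_rate": hit / total if total else 0.0,
        "missing": missing,
    }


def planted_trio_recovery(
    triangles: list[tuple],
    collections: list[ModuleCollection],
    truths: list[GroundTruth],
) -> dict:
    """Fraction of planted three-organ trios present as triangle motifs."""
    by_organ = {c.organ: c for c in collections}
    truth_by_organ = {t.organ: t for t in truths}
    matches = {
        organ: match_modules(by_organ[organ], truth_by_organ[organ])
        for organ in by_organ
    }
    triangle_set = {frozenset(t) for t in triangles}
    total, hit, missing = 0, 0, []
    for corr in truths[0].correspondences:
        label = corr["label"]
        organs = [truths[i].organ for i in corr["organs"] if truths[i].organ in by_organ]
        for trio in combinations(organs, 3):
            total += 1
            if all(label in matches[o] for o in trio):
                key = frozenset((o, matches[o][label]) for o in trio)
                if key in triangle_set:
                    hit += 1
                    continue
            missing.append((label, trio))
    return {
        "n_planted_trios": total,
        "n_recovered": hit,
        "recovery_rate": hit / total if total else 0.0,
        "missing": missing,
    }
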