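"""Shared fixtures: simulated studies and their analyzed products.

The default study (3 organs, 2000 genes, 8 planted modules, 100 normal /
60 pathological samples, seed 42) is generated once per session and its
network/module/conservation analysis is cached for reuse across tests.
Smaller configurations are used where full scale adds nothing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from organnet.community import leiden_modules
from organnet.conservation import build_similarity_network, conservation_groups, find_triangles
from organnet.network import build_network, spearman_all_pairs
from organnet.preprocess import preprocess
from organnet.simulate import PlantedModule, SimConfig, default_config, generate_study


@pytest.fixture(scope="session")
def default_study():
    return generate_study(default_config(seed=42))


@pytest.fixture(scope="session")
def default_analysis(default_study):
    """Preprocess -> network -> Leiden -> conservation on the default study."""
    collections, truths, networks, filtered = [], [], {}, {}
    exprs, labels = {}, {}
    for expr, samples, truth in default_study:
        fexpr, _ = preprocess(expr)
        net = build_network(spearman_all_pairs(fexpr), organ=truth.organ)
        coll = leiden_modules(net, resolution=0.2, seed=42, min_size=10)
        collections.append(coll)
        truths.append(truth)
        networks[truth.organ] = net
        filtered[truth.organ] = fexpr
        exprs[truth.organ] = expr
        labels[truth.organ] = pd.Series(
            samples["label"].to_numpy(), index=samples["sample_id"].to_numpy()
        )
    edges = build_similarity_network(collections)
    groups = conservation_groups(edges, collections)
    triangles = [t for g in groups for t in find_triangles(g, edges)]
    return {
        "collections": collections,
        "truths": truths,
        "networks": networks,
        "filtered": filtered,
        "exprs": exprs,
        "labels": labels,
        "edges": edges,
        "groups": groups,
        "triangles": triangles,
    }


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A fast three-organ study for unit tests."""
    base = dict(
        n_organs=3,
        genes_total=400,
        module_specs=[
            PlantedModule("alpha", 20, 0.5, 1.5),
            PlantedModule("beta", 15, 0.5, 2.0),
            PlantedModule("gamma", 12, 0.5, 1.5),
        ],
        n_normal=40,
        n_pathological=24,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
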