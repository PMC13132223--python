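"""End-to-end pipeline driver.

Stage order: preprocess -> co-expression network -> Leiden modules ->
cross-organ conservation -> module eigengenes + Welch statistics ->
differential expression -> classification -> consensus feature ranking ->
feature-count sweep. Every output is a deterministic TSV/JSON file, and a
run manifest records the config snapshot, seeds, input digests and
per-stage outputs; re-running with the same inputs and config reproduces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from . import io
from .classify import ModelSpec, encode_labels, stratified_cv
from .community import leiden_modules
from .config import PipelineConfig
from .conservation import (
    build_similarity_network,
    conservation_groups,
    find_triangles,
    similarity_edges_to_frame,
    three_way_subgroup,
)
from .errors import OrgannetError
from .importance import (
    builtin_importance,
    consensus_across_organs,
    consensus_ranking,
    feature_sweep,
    permutation_importance,
    select_best_family,
    shap_importance,
)
from .network import (
    bh_adjust,
    build_network,
    edges_to_frame,
    spearman_all_pairs,
    topology_metrics,
)
from .preprocess import preprocess
from .stats import differential_expression, module_eigengene, welch_t
from .classify import build_model

log = logging.getLogger("organnet")

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(OrgannetError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    software_version: str
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, object] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "config": self.config,
            "software_version": self.software_version,
            "seed": self.seed,
            "input_digests": self.input_digests,
            "outputs": self.outputs,
            "counts": self.counts,
        }


def _pkg_version() -> str:
    try:
        return version("organnet")
    except PackageNotFoundError:
        return "unknown"


def _digest(expr: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(",".join(expr.index).encode())
    h.update(",".join(expr.columns).encode())
    h.update(expr.to_numpy().tobytes())
    return h.hexdigest()


def run_pipeline(
    datasets: list[tuple[pd.DataFrame, pd.DataFrame]],
    outdir: str | Path,
    config: PipelineConfig | None = None,
    signature_genes: list[str] | None = None,
) -> RunManifest:
    """Run every stage on a list of (expression, sample table) cohorts.

    With a single cohort the conservation stage is skipped (logged). When
    ``signature_genes`` is None the classification feature set is derived
    from the conservation analysis: the union of triangle-motif core genes
    across conservation groups (falling back to the largest group's gene
    union, then to all module genes).
    """
    config = (config or PipelineConfig()).validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.to_dict(), _pkg_version(), config.seed)

    organs, exprs, labels_by_organ = [], {}, {}
    for expr, samples in datasets:
        organ = str(samples["organ"].iloc[0])
        organs.append(organ)
        exprs[organ] = expr
        labels_by_organ[organ] = pd.Series(
            samples["label"].to_numpy(), index=samples["sample_id"].to_numpy()
        )
        manifest.input_digests[organ] = _digest(expr)

    def _out(name: str, key: str | None = None) -> Path:
        # manifest stores outdir-relative paths so identical runs into
        # different directories still produce identical manifests
        manifest.outputs[key or name] = name
        return outdir / name

    # --- per-organ network + module stages -------------------------------
    collections, networks, filtered = [], {}, {}
    for organ in organs:
        try:
            fexpr, report = preprocess(
                exprs[organ], config.mean_quantile, config.variance_fraction
            )
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"preprocess[{organ}]", e) from e
        filtered[organ] = fexpr
        io.write_expression(fexpr, _out(f"{organ}_filtered.tsv"))
        io.write_json(report.to_jsonable(), _out(f"{organ}_filter_report.json"))
        try:
            corr = spearman_all_pairs(fexpr)
            net = build_network(
                corr, config.r_threshold, config.q_threshold, organ=organ
            )
        except Exception as e:
            raise PipelineError(f"network[{organ}]", e) from e
        networks[organ] = net
        io.write_edge_list(edges_to_frame(net), _out(f"{organ}_edges.tsv"))
        io.write_json(
            topology_metrics(net).to_jsonable(), _out(f"{organ}_network_metrics.json")
        )
        try:
            coll = leiden_modules(
                net,
                resolution=config.resolution,
                seed=config.seed,
                min_size=config.min_module_size,
            )
        except Exception as e:
            raise PipelineError(f"modules[{organ}]", e) from e
        collections.append(coll)
        io.write_module_table(coll.to_frame(), _out(f"{organ}_modules.tsv"))
        manifest.counts[f"{organ}_n_network_nodes"] = net.number_of_nodes()
        manifest.counts[f"{organ}_n_network_edges"] = net.number_of_edges()
        manifest.counts[f"{organ}_n_modules"] = len(coll.modules)

    # --- conservation ----------------------------------------------------
    groups, edges, subgroups = [], [], []
    if len(organs) >= 2:
        try:
            edges = build_similarity_network(
                collections, config.conservation_q, config.background
            )
            groups = conservation_groups(edges, collections)
            by_organ = {c.organ: c for c in collections}
            raw_subgroups = []
            for group in groups:
                for tri in find_triangles(group, edges):
                    mods = [by_organ[o].module(m) for o, m in tri]
                    third_organ = sorted(tri)[2][0] if config.pairing == "last" else sorted(tri)[0][0]
                    N = len(by_organ[third_organ].universe)
                    raw_subgroups.append(
                        (group.group_id, three_way_subgroup(*mods, N=N, pairing=config.pairing))
                    )
            if raw_subgroups:
                qvals = bh_adjust([s.p for _, s in raw_subgroups])
                for (gid, s), q in zip(raw_subgroups, qvals):
                    s.q = float(q)
                    subgroups.append((gid, s))
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("conservation", e) from e
        io.write_edge_list(
            similarity_edges_to_frame(edges), _out("similarity_edges.tsv")
        )
        io.write_json(
            [
                {
                    "group_id": g.group_id,
                    "member_modules": sorted(map(list, g.member_modules)),
                    "organs_present": sorted(g.organs_present),
                    "n_union_genes": len(g.union_genes),
                    "union_genes": sorted(g.union_genes),
                }
                for g in groups
            ],
            _out("conservation_groups.json"),
        )
        io.write_json(
            [
                {
                    "group_id": gid,
                    "triple": [list(k) for k in s.triple],
                    "core_genes": sorted(s.core_genes),
                    "observed_overlap": s.observed_overlap,
                    "expected_overlap": s.expected_overlap,
                    "fold_enrichment": s.fold_enrichment,
                    "p": s.p,
                    "q": s.q,
                }
                for gid, s in subgroups
            ],
            _out("conserved_subgroups.json"),
        )
        manifest.counts["n_similarity_edges"] = len(edges)
        manifest.counts["n_conservation_groups"] = len(groups)
        manifest.counts["n_triangle_subgroups"] = len(subgroups)
    else:
        log.info("single cohort: conservation stage skipped")
        manifest.counts["conservation"] = "skipped (single cohort)"

    # --- eigengenes + Welch tests + DGE ----------------------------------
    eigengene_rows, test_rows = [], []
    for coll in collections:
        organ = coll.organ
        expr = exprs[organ]
        labels = labels_by_organ[organ].reindex(expr.columns)
        organ_tests = []
        for mod in coll.modules:
            try:
                profile = module_eigengene(expr, mod)
            except Exception as e:
                raise PipelineError(f"eigengene[{organ}:{mod.module_id}]", e) from e
            for sample, score in profile.scores.items():
                eigengene_rows.append((sample, organ, mod.module_id, score))
            normal = profile.scores[(labels == "normal").to_numpy()]
            path = profile.scores[(labels == "pathological").to_numpy()]
            res = welch_t(normal, path, groups=("normal", "pathological"))
            organ_tests.append(
                {
                    "organ": organ,
                    "module_id": mod.module_id,
                    "variance_explained": profile.variance_explained,
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p,
                }
            )
        if organ_tests:
            for row, q in zip(organ_tests, bh_adjust([r["p"] for r in organ_tests])):
                row["q"] = float(q)
        test_rows.extend(organ_tests)
        try:
            dge = differential_expression(filtered[organ], labels)
        except Exception as e:
            raise PipelineError(f"dge[{organ}]", e) from e
        dge.to_csv(
            _out(f"{organ}_dge.tsv"), sep="\t", index=False, float_format=io.FLOAT_FORMAT
        )
    pd.DataFrame(
        eigengene_rows, columns=["sample_id", "organ", "module_id", "score"]
    ).to_csv(_out("eigengenes.tsv"), sep="\t", index=False, float_format=io.FLOAT_FORMAT)
    io.write_json(test_rows, _out("eigengene_tests.json"))

    # --- signature derivation --------------------------------------------
    if signature_genes is None:
        derived: set[str] = set()
        for _, s in subgroups:  # union of triangle-motif cores (C1..Cn analog)
            derived |= s.core_genes
        if not derived and groups:
            derived = set(groups[0].union_genes)
        if not derived:
            for coll in collections:
                for m in coll.modules:
                    derived |= m.members
        signature_genes = sorted(derived)
    Path(_out("signature_genes.txt")).write_text(
        "\n".join(signature_genes) + "\n"
    )
    manifest.counts["n_signature_genes"] = len(signature_genes)

    # --- classification ---------------------------------------------------
    cls_results: dict[str, list] = {}
    for organ in organs:
        expr = exprs[organ]
        genes = [g for g in signature_genes if g in expr.index]
        X = expr.loc[genes].T
        y = encode_labels(labels_by_organ[organ].reindex(X.index))
        results = []
        for family in ("random_forest", "linear_svm", "l1_logistic"):
            spec = ModelSpec(
                family=family,
                n_estimators=config.trees,
                svm_c=config.svm_c,
                lasso_lambda=config.lasso_lambda,
                seed=config.seed,
            )
            try:
                results.append(
                    stratified_cv(
                        X, y, spec, k=config.folds, seed=config.seed,
                        cohort=organ, feature_set="signature",
                    )
                )
            except Exception as e:
                raise PipelineError(f"classify[{organ}:{family}]", e) from e
        cls_results[organ] = results
    io.write_json(
        {o: [r.to_jsonable() for r in rs] for o, rs in cls_results.items()},
        _out("classifier_results.json"),
    )

    # --- consensus importance + sweep ------------------------------------
    tables = {}
    for organ in organs:
        expr = exprs[organ]
        genes = [g for g in signature_genes if g in expr.index]
        X = expr.loc[genes].T
        y = encode_labels(labels_by_organ[organ].reindex(X.index))
        best = select_best_family(cls_results[organ])
        spec = ModelSpec(
            family=best,
            n_estimators=config.trees,
            svm_c=config.svm_c,
            lasso_lambda=config.lasso_lambda,
            seed=config.seed,
        )
        try:
            model = build_model(spec)
            model.fit(X.to_numpy(), y)
            tables[organ] = consensus_ranking(
                builtin_importance(model, X.columns),
                permutation_importance(
                    X, y, spec,
                    k=config.folds,
                    repeats=config.permutation_repeats,
                    seed=config.seed,
                ),
                shap_importance(model, X),
            )
        except Exception as e:
            raise PipelineError(f"importance[{organ}]", e) from e
        tables[organ].to_csv(
            _out(f"{organ}_importance.tsv"), sep="\t", float_format=io.FLOAT_FORMAT
        )
    try:
        combined = consensus_across_organs(tables, method=config.combine)
    except Exception as e:
        raise PipelineError("consensus", e) from e
    combined.to_csv(
        _out("consensus_importance.tsv"), sep="\t", float_format=io.FLOAT_FORMAT
    )

    sweep_frames = []
    for organ in organs:
        expr = exprs[organ]
        genes = [g for g in combined.index if g in expr.index]
        X = expr.loc[genes].T
        y = encode_labels(labels_by_organ[organ].reindex(X.index))
        grid = sorted({min(c, len(genes)) for c in config.sweep_grid})
        spec = ModelSpec(
            family="random_forest", n_estimators=config.trees, seed=config.seed
        )
        try:
            sweep = feature_sweep(
                X, y, combined, grid, spec, k=config.folds, seed=config.seed,
                cohort=organ,
            )
        except Exception as e:
            raise PipelineError(f"sweep[{organ}]", e) from e
        sweep.insert(0, "organ", organ)
        sweep_frames.append(sweep)
    pd.concat(sweep_frames, ignore_index=True).to_csv(
        _out("feature_sweep.tsv"), sep="\t", index=False, float_format=io.FLOAT_FORMAT
    )

    io.write_json(manifest.to_jsonable(), outdir / "manifest.json")
    return manifest
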