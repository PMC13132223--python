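"""Eigengenes, Welch statistics, and differential expression."""

import numpy as np
import pandas as pd
import pytest

from organnet.errors import DataError
from organnet.simulate import PlantedModule, SimConfig, generate_organ
from organnet.stats import (
    differential_expression,
    module_eigengene,
    pairwise_welch,
    welch_anova,
    welch_t,
)


def _expr(matrix, genes=None):
    matrix = np.asarray(matrix, dtype=float)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    return pd.DataFrame(
        matrix, index=genes, columns=[f"s{i}" for i in range(matrix.shape[1])]
    )


# ----------------------------------------------------------- module_eigengene
def test_identical_profiles_give_shared_zscore_and_full_variance():
    base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    X = _expr(np.tile(base, (4, 1)))
    prof = module_eigengene(X, list(X.index))
    z = (base - base.mean()) / base.std(ddof=1)
    # eigengene equals the shared z-profile up to overall scale
    scaled = prof.scores.to_numpy() / np.linalg.norm(prof.scores) * np.linalg.norm(z)
    assert np.allclose(scaled, z)
    assert prof.variance_explained == pytest.approx(1.0)


def test_two_orthogonal_genes_split_variance():
    rng = np.random.default_rng(0)
    a = rng.normal(size=400)
    b = rng.normal(size=400)
    a -= a.mean()
    b -= (b @ a) / (a @ a) * a + b.mean()  # exactly orthogonal
    X = _expr(np.vstack([a, b]))
    prof = module_eigengene(X, list(X.index))
    # SVD oracle on the z-scored matrix
    z = X.to_numpy()
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    s = np.linalg.svd(z.T, compute_uv=False)
    assert prof.variance_explained == pytest.approx(s[0] ** 2 / (s**2).sum(), abs=1e-12)
    assert prof.variance_explained == pytest.approx(0.5, abs=0.05)


def test_eigengene_invariant_to_gene_and_sample_order():
    rng = np.random.default_rng(1)
    X = _expr(rng.normal(size=(6, 30)) + rng.normal(size=30))
    prof = module_eigengene(X, list(X.index))
    perm = X.iloc[::-1, rng.permutation(30)]
    prof2 = module_eigengene(perm, list(perm.index))
    assert np.allclose(
        prof2.scores.reindex(prof.scores.index), prof.scores, atol=1e-9
    )


def test_eigengene_tracks_planted_factor():
    cfg = SimConfig(
        n_organs=1, genes_total=120,
        module_specs=[PlantedModule("m", 30, 0.5, 1.5)],
        n_normal=60, n_pathological=40, seed=21,
    )
    expr, _, truth = generate_organ(cfg, 0)
    prof = module_eigengene(expr, truth.members("m"))
    corr = np.corrcoef(prof.scores, truth.factors["m"])[0, 1]
    assert abs(corr) >= 0.95


def test_constant_gene_excluded_with_warning():
    X = _expr([[1, 2, 3, 4], [2, 4, 1, 3], [5, 5, 5, 5]])
    with pytest.warns(UserWarning, match="constant"):
        prof = module_eigengene(X, list(X.index))
    assert prof.n_genes_used == 2


def test_all_constant_module_rejected():
    X = _expr([[1, 1, 1, 1], [2, 2, 2, 2]])
    with pytest.raises(DataError):
        module_eigengene(X, list(X.index))


# ------------------------------------------------------------------- welch_t
def test_welch_t_hand_computation():
    # means 2 vs 5, each var 1: t = -3 / sqrt(2/3), Welch df = 4
    res = welch_t([1, 2, 3], [4, 5, 6])
    assert res.statistic == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-4)
    assert res.statistic == pytest.approx(-3.6742, abs=1e-4)
    assert res.df == pytest.approx(4.0)


def test_welch_t_identical_groups():
    res = welch_t([1, 2, 3], [1, 2, 3])
    assert res.statistic == 0.0
    assert res.p == pytest.approx(1.0)


def test_welch_t_zero_variance_conventions():
    assert welch_t([2, 2, 2], [2, 2, 2]).p == 1.0
    with pytest.raises(DataError):
        welch_t([2, 2, 2], [3, 3, 3])


def test_welch_reduces_to_student_under_equal_variance(rng):
    from scipy import stats as sps

    a = rng.normal(size=30)
    b = rng.normal(size=30)
    ours = welch_t(a, b)
    student = sps.ttest_ind(a, b, equal_var=True)
    # equal n: Welch's statistic equals Student's exactly
    assert ours.statistic == pytest.approx(student.statistic, abs=1e-12)


# --------------------------------------------------------------- welch_anova
def test_two_group_anova_is_squared_t(rng):
    a = rng.normal(0, 1, 25)
    b = rng.normal(0.5, 2, 40)
    f = welch_anova([a, b])
    t = welch_t(a, b)
    assert f.statistic == pytest.approx(t.statistic**2, abs=1e-10)
    assert f.p == pytest.approx(t.p, abs=1e-10)


def test_identical_groups_not_significant(rng):
    base = rng.normal(size=30)
    res = welch_anova([base, base + 1e-9 * rng.normal(size=30), base])
    assert res.p > 0.9


def test_shifted_group_detected(rng):
    groups = [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(2, 1, 50)]
    assert welch_anova(groups).p < 1e-6


def test_welch_anova_matches_pingouin(rng):
    import pingouin as pg

    data = {
        "g1": rng.normal(0, 1, 20),
        "g2": rng.normal(0.3, 2, 35),
        "g3": rng.normal(1, 0.5, 15),
    }
    ours = welch_anova(data)
    df = pd.DataFrame(
        [(k, v) for k, arr in data.items() for v in arr], columns=["grp", "val"]
    )
    ref = pg.welch_anova(data=df, dv="val", between="grp")
    assert ours.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
    assert ours.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)


# ------------------------------------------------------------- pairwise_welch
def test_two_groups_q_equals_p(rng):
    res = pairwise_welch({"a": rng.normal(size=10), "b": rng.normal(size=10)})
    assert len(res) == 1
    assert res[0].q == res[0].p


def test_identical_groups_no_discovery(rng):
    groups = {f"g{i}": rng.normal(size=40) for i in range(4)}
    res = pairwise_welch(groups)
    assert len(res) == 6
    assert all(r.q > 0.05 for r in res)


def test_lung_like_pattern_all_pathological_groups_detected(rng):
    """Normal vs three shifted pathological subgroups, reference design."""
    groups = {
        "normal": rng.normal(0, 1, 160),
        "rejection": rng.normal(2.0, 1.2, 24),
        "late_atrophy": rng.normal(1.5, 1.0, 36),
        "early_injury": rng.normal(1.0, 1.0, 16),
    }
    assert welch_anova(groups).p < 1e-10
    res = pairwise_welch(groups, reference="normal")
    assert len(res) == 3
    assert all(r.q < 0.05 for r in res)
    assert all(r.statistic < 0 for r in res)  # normal minus pathological


# --------------------------------------------------- differential_expression
def test_null_simulation_rare_discoveries(rng):
    X = _expr(rng.normal(size=(300, 40)))
    labels = pd.Series(
        ["normal"] * 20 + ["pathological"] * 20, index=X.columns
    )
    table = differential_expression(X, labels)
    assert (table["q"] < 0.05).mean() <= 0.05


def test_planted_module_upregulated():
    cfg = SimConfig(
        n_organs=1, genes_total=200,
        module_specs=[PlantedModule("cc", 24, 0.5, 1.5)],
        n_normal=60, n_pathological=40, seed=8,
    )
    expr, samples, truth = generate_organ(cfg, 0)
    labels = pd.Series(
        samples["label"].to_numpy(), index=samples["sample_id"].to_numpy()
    )
    table = differential_expression(expr, labels).set_index("gene_id")
    members = truth.members("cc")
    assert (table.loc[sorted(members), "q"] < 0.05).all()
    assert (table.loc[sorted(members), "log2fc"] > 0).all()


def test_constant_gene_flat_p():
    X = _expr([[3, 3, 3, 3]], genes=["flat"])
    labels = pd.Series(
        ["normal", "normal", "pathological", "pathological"], index=X.columns
    )
    table = differential_expression(X, labels)
    assert table.loc[0, "p"] == 1.0
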