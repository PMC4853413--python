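"""Group statistics: GLM against classical and statsmodels oracles, BH
step-up by hand, cluster topology fixtures, partial correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import fcdmap
from fcdmap import (
    PhantomSpec,
    NetworkSpec,
    bh_correct,
    extract_clusters,
    fdr_correct,
    make_phantom_grid,
    overlap_map,
    partial_correlation,
    regional_summary,
    simulate_cohort,
    voxelwise_glm,
)
from fcdmap.errors import InputError
from fcdmap.stats import correlation_report, ClusterTable
from conftest import block


def make_cohort(n_case, n_control, seed=0):
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": ["case"] * n_case + ["control"] * n_control,
        "age": rng.uniform(8, 30, n),
        "sex": rng.choice(["M", "F"], n),
    })


# ------------------------------------------------------------------- GLM


def test_identical_groups_give_zero_t():
    cohort = make_cohort(4, 4)
    one_map = np.random.default_rng(1).random((5, 5, 5))
    maps = np.stack([one_map] * 8)
    sm = voxelwise_glm(maps, cohort, np.ones((5, 5, 5), bool))
    assert (sm.t_map == 0).all()
    assert (sm.p_map == 1).all()


def test_glm_without_covariates_is_pooled_two_sample_t():
    rng = np.random.default_rng(2)
    cohort = make_cohort(9, 12)
    maps = rng.standard_normal((21, 4, 4, 4))
    sm = voxelwise_glm(maps, cohort, np.ones((4, 4, 4), bool), covariates=())
    t_ref, p_ref = sps.ttest_ind(maps[:9].reshape(9, -1),
                                 maps[9:].reshape(12, -1), axis=0)
    assert np.allclose(sm.t_map.ravel(), t_ref, atol=1e-10)
    assert np.allclose(sm.p_map.ravel(), p_ref, atol=1e-10)
    assert sm.df == 19


def test_glm_matches_statsmodels_at_single_voxel():
    import statsmodels.api as smapi

    rng = np.random.default_rng(3)
    cohort = make_cohort(10, 10, seed=3)
    maps = rng.standard_normal((20, 3, 3, 3))
    out = voxelwise_glm(maps, cohort, np.ones((3, 3, 3), bool))
    X = np.column_stack([
        np.ones(20),
        (cohort["group"] == "case").astype(float),
        cohort["age"],
        (cohort["sex"] == "M").astype(float),
    ])
    for idx in [(0, 0, 0), (1, 2, 1)]:
        fit = smapi.OLS(maps[(slice(None), *idx)], X).fit()
        assert np.isclose(out.t_map[idx], fit.tvalues[1], atol=1e-8)
        assert np.isclose(out.p_map[idx], fit.pvalues[1], atol=1e-8)
    assert out.df == 16  # n - 4


def test_constant_covariate_dropped_with_warning():
    cohort = make_cohort(5, 5)
    cohort["sex"] = "M"
    maps = np.random.default_rng(4).standard_normal((10, 3, 3, 3))
    with pytest.warns(UserWarning, match="sex"):
        sm = voxelwise_glm(maps, cohort, np.ones((3, 3, 3), bool))
    assert sm.df == 10 - 3  # intercept, group, age remain


def test_glm_recovers_planted_group_effect():
    """Cases couple at w = 0.4, controls at 0.8: network voxels show a
    clearly negative group t while background voxels stay near zero."""
    spec = PhantomSpec(
        grid_shape=(8, 8, 8),
        networks=[
            NetworkSpec("net", block(1, 2, 2, 2, 3, 2), 0.8,
                        "unilateral-left", group_effect=0.5),
            # keeps each subject's mean global degree (the normalization
            # denominator) well away from zero in both groups
            NetworkSpec("stable", block(1, 5, 5, 2, 2, 2), 0.8, "homotopic"),
        ],
        n_timepoints=200,
    )
    grid = make_phantom_grid(spec)
    study = simulate_cohort(
        grid, spec, 10, 10, seed=5,
        coupling_jitter={"net": (0.6, 1.0), "stable": (0.9, 1.0)},
    )
    stack = [
        fcdmap.fcd_maps_for_subject(vol, grid).g_norm
        for _, vol, _ in study.iter_subjects()
    ]
    sm = voxelwise_glm(np.stack(stack), study.cohort, grid.mask)
    members = tuple(spec.networks[0].member_voxels(spec.grid_shape).T)
    assert sm.t_map[members].mean() < -3
    off = np.ones(grid.shape, bool)
    off[members] = False
    assert abs(sm.t_map[off].mean()) < 1.0


# ---------------------------------------------------------------- BH / FDR


@pytest.mark.parametrize("p_in, expected", [
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([0.01, 0.04, 0.03, 0.02], [0.04, 0.04, 0.04, 0.04]),
    ([0.2], [0.2]),
    ([0.02, 0.5], [0.04, 0.5]),
])
def test_bh_step_up_hand_examples(p_in, expected):
    assert np.allclose(bh_correct(np.array(p_in)), expected, atol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_matches_statsmodels_and_bounds_raw(p_list):
    from statsmodels.stats.multitest import multipletests

    p = np.array(p_list)
    adj = bh_correct(p)
    _, adj_ref, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(adj, adj_ref, atol=1e-12)
    assert (adj >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()  # monotone along sorted raw p


def test_fdr_single_voxel_and_all_null():
    mask = np.zeros((3, 3, 3), bool)
    mask[1, 1, 1] = True
    p = np.ones((3, 3, 3))
    p[1, 1, 1] = 0.03
    sig, corrected = fdr_correct(p, mask, q=0.05)
    assert corrected[1, 1, 1] == pytest.approx(0.03)
    assert sig[1, 1, 1]

    sig, _ = fdr_correct(np.ones((3, 3, 3)), np.ones((3, 3, 3), bool))
    assert not sig.any()


# ---------------------------------------------------------------- clusters


@pytest.fixture
def grid10():
    spec = PhantomSpec(grid_shape=(10, 10, 10))
    return make_phantom_grid(spec)


def test_cube_survives_and_reports_peak(grid10):
    sig = np.zeros((10, 10, 10), bool)
    sig[2:5, 2:5, 2:5] = True
    t = np.zeros((10, 10, 10))
    t[sig] = -3.0
    t[3, 4, 2] = -9.0
    clusters = extract_clusters(sig, t, grid10, min_cluster_size=20)
    assert len(clusters) == 1
    row = clusters.table.iloc[0]
    assert row["size"] == 27
    assert (row.peak_i, row.peak_j, row.peak_k) == (3, 4, 2)
    assert np.allclose(
        [row.peak_x, row.peak_y, row.peak_z],
        grid10.world_coords(np.array([[3, 4, 2]]))[0],
    )
    assert row.peak_t == -9.0


def test_nineteen_voxel_blob_is_discarded(grid10):
    sig = np.zeros((10, 10, 10), bool)
    sig[2:5, 2:5, 2:4] = True  # 18 voxels
    sig[2, 2, 4] = True  # 19th
    assert sig.sum() == 19
    clusters = extract_clusters(sig, np.ones((10, 10, 10)), grid10)
    assert len(clusters) == 0


def test_edge_neighbors_merge_under_18_but_not_6_connectivity(grid10):
    """Two blobs touching only through an edge neighbor form one cluster
    at 18-connectivity and two at 6-connectivity."""
    sig = np.zeros((10, 10, 10), bool)
    sig[1:4, 1:4, 1:4] = True               # blob A, corner at (3,3,3)
    sig[4:7, 4:7, 3:6] = True               # blob B, corner at (4,4,3)
    t = np.ones((10, 10, 10))
    c18 = extract_clusters(sig, t, grid10, min_cluster_size=20, connectivity=18)
    c6 = extract_clusters(sig, t, grid10, min_cluster_size=20, connectivity=6)
    assert len(c18) == 1 and c18.table.iloc[0]["size"] == 54
    assert len(c6) == 2


def test_cluster_sizes_partition_surviving_voxels(grid10):
    rng = np.random.default_rng(6)
    sig = rng.random((10, 10, 10)) < 0.4
    clusters = extract_clusters(sig, np.ones((10, 10, 10)), grid10,
                                min_cluster_size=5)
    assert clusters.table["size"].sum() == (clusters.labels > 0).sum()
    for label in clusters.table["label"]:
        assert len(clusters.members(int(label))) >= 5


# ----------------------------------------------------------------- overlap


def test_overlap_categories():
    a = np.zeros((4, 4, 4), bool)
    a[:2] = True
    assert (overlap_map(a, a, a)[a] == 3).all()
    b = np.zeros_like(a)
    b[2:] = True
    ov = overlap_map(a, b, np.zeros_like(a))
    assert set(np.unique(ov)) == {1}
    counts = [(ov == k).sum() for k in (1, 2, 3)]
    assert sum(counts) == (a | b).sum()


# ------------------------------------------------------- regional summaries


def test_regional_summary_modes():
    cohort = make_cohort(2, 2)
    labels = np.zeros((5, 5, 5), int)
    labels[1:3, 1:3, 1] = 1
    labels[4, 4, 4] = 2
    table = pd.DataFrame({"label": [1, 2]})
    clusters = ClusterTable(table, labels)
    maps = np.zeros((4, 5, 5, 5))
    maps[:, 1:3, 1:3, 1] = np.arange(4)[:, None, None]
    maps[0, 1, 1, 1] = 10.0
    mean = regional_summary(maps, cohort, clusters, "mean")
    mx = regional_summary(maps, cohort, clusters, "max")
    assert (mx.values >= mean.values).all()
    assert mean.loc["s1", "cluster_1"] == 1.0  # constant within the region
    assert mx.loc["s0", "cluster_1"] == 10.0
    # singleton region: both modes equal the voxel value
    assert mean.loc["s2", "cluster_2"] == mx.loc["s2", "cluster_2"] == 0.0


# ------------------------------------------------- partial correlation


def test_partial_correlation_perfect_and_plain():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(40)
    cov = rng.standard_normal((40, 2))
    res = partial_correlation(x, x, cov)
    assert res.rho == pytest.approx(1.0)
    assert res.p == 0.0

    y = rng.standard_normal(40)
    plain = partial_correlation(x, y, None)
    r_ref, p_ref = sps.pearsonr(x, y)
    assert plain.rho == pytest.approx(r_ref, abs=1e-12)
    assert plain.p == pytest.approx(p_ref, abs=1e-10)
    assert plain.df == 38  # n - 2


def test_partial_correlation_df_accounting():
    """With age and sex controlled, df = n_complete - 4 (221 -> 217)."""
    rng = np.random.default_rng(8)
    x = rng.standard_normal(221)
    y = 0.3 * x + rng.standard_normal(221)
    cov = rng.standard_normal((221, 2))
    res = partial_correlation(x, y, cov)
    assert res.n == 221
    assert res.df == 217


def test_partial_correlation_matches_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(9)
    df = pd.DataFrame({
        "x": rng.standard_normal(60),
        "age": rng.uniform(8, 30, 60),
        "sex": rng.integers(0, 2, 60).astype(float),
    })
    df["y"] = -0.4 * df["x"] + 0.1 * df["age"] + rng.standard_normal(60)
    ref = pg.partial_corr(df, x="x", y="y", covar=["age", "sex"])
    res = partial_correlation(df["x"], df["y"], df[["age", "sex"]])
    assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


def test_partial_correlation_drops_incomplete_cases():
    rng = np.random.default_rng(10)
    x = rng.standard_normal(30)
    y = x + 0.5 * rng.standard_normal(30)
    x[3] = np.nan
    y[7] = np.nan
    cov = rng.standard_normal((30, 2))
    cov[11, 0] = np.nan
    res = partial_correlation(x, y, cov)
    assert res.n == 27
    assert res.df == 23


def test_partial_correlation_rejects_constant_residuals():
    cov = np.arange(20.0)
    with pytest.raises(InputError, match="undefined"):
        partial_correlation(2 * cov + 1, np.random.default_rng(0).random(20), cov)


def test_correlation_report_aligns_and_corrects():
    rng = np.random.default_rng(11)
    cohort = make_cohort(10, 10, seed=11)
    cohort["score"] = rng.standard_normal(20)
    values = 0.9 * cohort["score"].to_numpy() + 0.1 * rng.standard_normal(20)
    summaries = pd.DataFrame(
        {"cluster_1": values, "cluster_2": rng.standard_normal(20)},
        index=pd.Index(cohort["subject_id"], name="subject_id"),
    )
    # shuffled row order must not matter: alignment is by subject_id
    report = correlation_report(summaries.sample(frac=1, random_state=1),
                                cohort, "score")
    assert list(report["region"]) == ["cluster_1", "cluster_2"]
    assert report.loc[0, "rho"] > 0.8
    assert (report["p_bh"] >= report["p_raw"] - 1e-15).all()
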