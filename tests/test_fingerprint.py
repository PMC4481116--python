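"""Fingerprint matrix, clustering, grouped testing and post-hoc power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinomescreen import (
    PowerParams,
    ScreenError,
    bicluster,
    build_fingerprint,
    differential_panel,
    group_samples,
    posthoc_power,
    sample_correlations,
    ttest_two_sample,
)
from kinomescreen.errors import UndefinedStatisticError
from kinomescreen.fingerprint import GroupedProfiles
from kinomescreen.plate import ScreenSample
from kinomescreen.simulate import default_samples


def test_build_fingerprint_shape_and_order(default_run):
    dataset, _, scores = default_run
    m = build_fingerprint(dataset, scores)
    assert m.shape == (778, 7)
    assert not m.isna().any().any()
    assert list(m.index) == sorted(m.index)
    assert list(m.columns) == sorted(s.sample_id for s in dataset.samples)
    assert m.attrs["cell_class"]["MSC1A"] == "MSC"


def test_build_fingerprint_rejects_missing_pairs(default_run):
    dataset, _, scores = default_run
    with pytest.raises(ScreenError, match="missing"):
        build_fingerprint(dataset, scores.iloc[:-3])


def test_build_fingerprint_invariant_to_plate_order(small_sim):
    from kinomescreen import score_screen
    from kinomescreen.plate import ScreenDataset

    dataset, _ = small_sim
    shuffled = ScreenDataset(
        dataset.samples, dataset.layouts, list(reversed(dataset.plates))
    )
    m1 = build_fingerprint(dataset, score_screen(dataset))
    m2 = build_fingerprint(shuffled, score_screen(shuffled))
    assert np.allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-12)


def test_sample_correlations_limits_and_oracle():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
    m["b"] = m["a"]
    m["c"] = -m["a"]
    corr = sample_correlations(m)
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    assert np.allclose(corr, corr.T, atol=1e-12)
    assert np.allclose(np.diag(corr), 1.0)
    brute = np.corrcoef(m.to_numpy(), rowvar=False)
    assert np.allclose(corr.to_numpy(), brute, atol=1e-12)


def test_sample_correlations_constant_column_errors():
    m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.raises(UndefinedStatisticError, match="b"):
        sample_correlations(m)


def test_bicluster_identical_samples_merge_at_zero():
    rng = np.random.default_rng(1)
    base = rng.normal(size=20)
    m = pd.DataFrame(
        {"s1": base, "s2": base, "s3": rng.normal(size=20)}
    )
    res = bicluster(m, k_samples=2)
    pair_height = res.sample_linkage[0, 2]
    assert pair_height == pytest.approx(0.0, abs=1e-12)
    assert res.sample_clusters["s1"] == res.sample_clusters["s2"]
    assert res.sample_clusters["s1"] != res.sample_clusters["s3"]
    assert sorted(res.sample_order) == ["s1", "s2", "s3"]
    assert np.all(np.diff(res.sample_linkage[:, 2]) >= -1e-12)


def test_bicluster_invariant_to_row_permutation():
    rng = np.random.default_rng(2)
    m = pd.DataFrame(rng.normal(size=(30, 5)),
                     index=[f"g{i}" for i in range(30)],
                     columns=list("abcde"))
    perm = m.sample(frac=1.0, random_state=3)
    r1, r2 = bicluster(m, 2), bicluster(perm, 2)
    assert np.allclose(np.sort(r1.gene_linkage[:, 2]), np.sort(r2.gene_linkage[:, 2]))
    assert np.allclose(r1.sample_linkage[:, 2], r2.sample_linkage[:, 2])
    assert r1.sample_order == r2.sample_order
    assert r1.gene_order == r2.gene_order


def test_bicluster_recovers_planted_classes(default_run):
    dataset, _, scores = default_run
    m = build_fingerprint(dataset, scores)
    res = bicluster(m, k_samples=2)
    msc = {"MSC1A", "MSC1B", "MSC2"}
    labels = {res.sample_clusters[s] for s in msc}
    other = {res.sample_clusters[s] for s in set(m.columns) - msc}
    assert len(labels) == 1 and labels.isdisjoint(other)


def test_group_samples_reproduces_study_group_sizes():
    samples = default_samples()
    rng = np.random.default_rng(4)
    m = pd.DataFrame(
        rng.normal(size=(12, 7)), columns=[s.sample_id for s in samples]
    )
    groups = group_samples(m, samples)
    assert groups.sizes == {"MSC": 2, "fibroblast": 4}
    # same-donor preparations are averaged
    merged = groups.classes["MSC"]["MSC_D1"]
    assert np.allclose(merged, (m["MSC1A"] + m["MSC1B"]) / 2)


def test_group_samples_identity_without_shared_donors():
    samples = [
        ScreenSample("a", "MSC", "d1", "p1"),
        ScreenSample("b", "MSC", "d2", "p2"),
        ScreenSample("c", "fibroblast_primary", "d3", "p3"),
        ScreenSample("d", "fibroblast_line", "d4", "p4"),
    ]
    m = pd.DataFrame(np.random.default_rng(5).normal(size=(8, 4)),
                     columns=list("abcd"))
    groups = group_samples(m, samples)
    assert groups.sizes == {"MSC": 2, "fibroblast": 2}
    assert np.allclose(groups.classes["MSC"]["d1"], m["a"])


def test_ttest_hand_computed_example():
    t, p = ttest_two_sample([1.0, 1.2], [0.0, 0.1, -0.1, 0.2])
    # pooled variance 0.0175, df = 4
    assert t == pytest.approx(1.05 / np.sqrt(0.0175 * 0.75), abs=1e-12)
    assert t == pytest.approx(9.17, abs=0.01)
    assert 0 < p < 0.001


def test_ttest_identical_groups():
    t, p = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0, abs=1e-15)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_ttest_matches_scipy_oracle():
    rng = np.random.default_rng(6)
    for _ in range(50):
        a = rng.normal(size=int(rng.integers(2, 8)))
        b = rng.normal(size=int(rng.integers(2, 8)))
        t, p = ttest_two_sample(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_ttest_zero_pooled_variance_errors():
    with pytest.raises(UndefinedStatisticError):
        ttest_two_sample([1.0, 1.0], [1.0, 1.0])


def test_posthoc_power_null_and_saturation():
    params = PowerParams(alpha=0.05, n1=2, n2=4)
    assert posthoc_power(0.0, params) == 0.05
    assert posthoc_power(100.0, params) > 0.999


def test_posthoc_power_monotonicity():
    params = PowerParams()
    d_grid = [0.0, 0.5, 1.0, 2.0, 4.0]
    powers = [posthoc_power(d, params) for d in d_grid]
    assert all(b > a for a, b in zip(powers, powers[1:]))
    assert posthoc_power(2.0, PowerParams(n1=3, n2=4)) > posthoc_power(
        2.0, PowerParams(n1=2, n2=4)
    )
    assert posthoc_power(2.0, PowerParams(n1=2, n2=6)) > posthoc_power(
        2.0, PowerParams(n1=2, n2=4)
    )


def _grouped(A: np.ndarray, B: np.ndarray, genes) -> GroupedProfiles:
    return GroupedProfiles(
        {
            "MSC": pd.DataFrame(A, index=genes),
            "fibroblast": pd.DataFrame(B, index=genes),
        }
    )


def test_differential_panel_selection_and_clusters():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(100)]
    A = rng.normal(0, 0.2, size=(100, 2))
    B = rng.normal(0, 0.2, size=(100, 4))
    A[:5] -= 3.0  # much stronger kill in MSC
    B[5:10] -= 3.0  # much stronger kill in fibroblasts
    m = pd.DataFrame(np.column_stack([A, B]), index=genes)
    panel = differential_panel(m, _grouped(A, B, genes))
    top = panel.set_index("gene")
    for g in genes[:5]:
        assert top.loc[g, "selected"]
        assert top.loc[g, "cluster"] == "stronger_in_MSC"
    for g in genes[5:10]:
        assert top.loc[g, "selected"]
        assert top.loc[g, "cluster"] == "stronger_in_fibroblast"
    assert panel["p"].is_monotonic_increasing
    assert ((panel["power"] >= 0.05) & (panel["power"] <= 1.0)).all()
    sel = panel[panel["selected"]]
    assert (sel["p"] <= 0.05).all()
    # Benjamini-Hochberg selection is a subset of the uncorrected one
    bh = differential_panel(m, _grouped(A, B, genes), correction="bh")
    bh_sel = set(bh.loc[bh["selected"], "gene"])
    assert bh_sel <= set(sel["gene"])
    assert set(genes[:10]) <= bh_sel


def test_differential_panel_gene_with_equal_means_not_selected():
    genes = ["same", "diff"]
    A = np.array([[1.0, 1.1], [0.0, 0.1]])
    B = np.array([[1.0, 1.1, 0.9, 1.05], [2.0, 2.1, 1.9, 2.05]])
    panel = differential_panel(
        pd.DataFrame(np.column_stack([A, B]), index=genes),
        _grouped(A, B, genes),
    ).set_index("gene")
    assert not panel.loc["same", "selected"]
    assert panel.loc["diff", "selected"]


def test_differential_panel_invariant_to_gene_order_and_class_labels():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(40)]
    A = rng.normal(size=(40, 2))
    B = rng.normal(size=(40, 4))
    m = pd.DataFrame(np.column_stack([A, B]), index=genes)
    p1 = differential_panel(m, _grouped(A, B, genes)).set_index("gene")
    perm = list(reversed(genes))
    p2 = differential_panel(m.loc[perm], _grouped(A[::-1], B[::-1], perm)).set_index("gene")
    assert np.allclose(p1.loc[genes, "t"], p2.loc[genes, "t"], atol=1e-12)
    # swapping class labels flips t but not p / d / selection
    swapped = GroupedProfiles(
        {"fibroblast": pd.DataFrame(A, index=genes), "MSC": pd.DataFrame(B, index=genes)}
    )
    p3 = differential_panel(m, swapped).set_index("gene")
    assert np.allclose(p1.loc[genes, "t"], -p3.loc[genes, "t"], atol=1e-12)
    assert np.allclose(p1.loc[genes, "p"], p3.loc[genes, "p"], atol=1e-12)
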