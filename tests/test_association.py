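"""Architecture EMMs/contrasts, cell-type correlations, label propagation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metalspot import SpotLayout
from metalspot.association import (
    UNASSIGNED,
    celltype_metal_correlation,
    cluster_matrix,
    fit_architecture_model,
    propagate_labels,
)


def lattice_spots(n_side=6, pitch=100.0):
    xs, ys = np.meshgrid(np.arange(n_side) * pitch, np.arange(n_side) * pitch)
    n = n_side * n_side
    return SpotLayout(
        pd.DataFrame(
            {"spot_id": [f"s{i:02d}" for i in range(n)], "x_um": xs.ravel(), "y_um": ys.ravel()}
        ),
        pitch_um=pitch,
    )


class TestPropagateLabels:
    def test_fully_labelled_is_identity(self):
        spots = lattice_spots(3)
        labels = pd.Series(["a"] * 9, index=spots.spot_ids)
        out = propagate_labels(labels, spots)
        pd.testing.assert_series_equal(out, labels.rename("label"))

    def test_single_gap_takes_neighbour_majority(self):
        spots = lattice_spots(3)
        labels = pd.Series(["tumor"] * 9, index=spots.spot_ids)
        labels.iloc[4] = np.nan                     # centre spot unlabelled
        out = propagate_labels(labels, spots, k=4)
        assert out.iloc[4] == "tumor"

    def test_tie_breaks_lexicographically(self):
        spots = lattice_spots(3)
        labels = pd.Series(index=spots.spot_ids, dtype=object)
        # centre's 4-neighbours: two "interface", two "tumor"
        labels.iloc[1] = "interface"
        labels.iloc[7] = "interface"
        labels.iloc[3] = "tumor"
        labels.iloc[5] = "tumor"
        labels.iloc[0] = labels.iloc[2] = labels.iloc[6] = labels.iloc[8] = "serosa"
        out = propagate_labels(labels, spots, k=4)
        assert out.iloc[4] == "interface"

    def test_no_labels_at_all_rejected(self):
        spots = lattice_spots(2)
        with pytest.raises(ValueError):
            propagate_labels(pd.Series(index=spots.spot_ids, dtype=object), spots)

    def test_unassigned_count_never_increases(self):
        rng = np.random.default_rng(0)
        spots = lattice_spots(6)
        labels = pd.Series(
            rng.choice(["a", "b", np.nan], size=36, p=[0.2, 0.2, 0.6]),
            index=spots.spot_ids,
            dtype=object,
        )
        if labels.notna().sum() == 0:
            labels.iloc[0] = "a"
        out = propagate_labels(labels, spots, k=4)
        assert (out == UNASSIGNED).sum() <= labels.isna().sum()


class TestArchitectureModel:
    def test_identical_groups_null_contrast(self):
        gi = pd.DataFrame({"Cu": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
        labels = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        res = fit_architecture_model(gi, labels)
        row = res.contrasts.iloc[0]
        assert row["delta"] == pytest.approx(0.0)
        assert row["p_tukey"] == pytest.approx(1.0)

    def test_emm_difference_matches_pooled_t(self):
        # balanced groups, closed-form two-sample pooled t as the oracle
        rng = np.random.default_rng(0)
        n = 30
        a = rng.normal(1.0, 0.5, n)
        b = rng.normal(3.0, 0.5, n)
        gi = pd.DataFrame({"Cu": np.r_[a, b]}, index=[f"s{i}" for i in range(2 * n)])
        labels = pd.Series(["A"] * n + ["B"] * n, index=gi.index)
        res = fit_architecture_model(gi, labels)
        emm = res.emm.set_index("group")["emm"]
        assert emm["A"] == pytest.approx(a.mean())
        assert emm["B"] == pytest.approx(b.mean())
        row = res.contrasts.set_index(["group_a", "group_b"]).loc[("A", "B")]
        t_ref, _ = stats.ttest_ind(a, b)
        assert row["t"] == pytest.approx(t_ref)
        assert row["df"] == 2 * n - 2

    def test_emms_equal_group_means_unbalanced(self):
        rng = np.random.default_rng(1)
        sizes = {"tumor": 12, "interface": 7, "serosa": 25}
        vals, labs = [], []
        for g, n in sizes.items():
            vals.append(rng.normal(0, 1, n))
            labs += [g] * n
        gi = pd.DataFrame(
            {"Fe": np.concatenate(vals)}, index=[f"s{i}" for i in range(sum(sizes.values()))]
        )
        labels = pd.Series(labs, index=gi.index)
        res = fit_architecture_model(gi, labels)
        for g in sizes:
            expect = gi["Fe"][labels == g].mean()
            got = res.emm.query("group == @g")["emm"].iloc[0]
            assert got == pytest.approx(expect)

    def test_contrast_antisymmetry_exact(self):
        rng = np.random.default_rng(2)
        gi = pd.DataFrame({"Cu": rng.normal(size=30)}, index=[f"s{i}" for i in range(30)])
        labels = pd.Series(
            ["a"] * 10 + ["b"] * 10 + ["c"] * 10, index=gi.index
        )
        res = fit_architecture_model(gi, labels)
        c = res.contrasts.set_index(["group_a", "group_b"])
        for a, b in [("a", "b"), ("a", "c"), ("b", "c")]:
            assert c.loc[(a, b), "delta"] == -c.loc[(b, a), "delta"]
            assert c.loc[(a, b), "p_tukey"] == c.loc[(b, a), "p_tukey"]

    def test_tukey_p_matches_statsmodels(self):
        # dual route: statsmodels' Tukey HSD as the independent reference
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        vals = np.r_[rng.normal(0, 1, 15), rng.normal(0.8, 1, 15), rng.normal(2.0, 1, 15)]
        labs = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
        gi = pd.DataFrame({"Cu": vals}, index=[f"s{i}" for i in range(45)])
        res = fit_architecture_model(gi, pd.Series(labs, index=gi.index))
        ref = pairwise_tukeyhsd(vals, labs)
        ours = res.contrasts.set_index(["group_a", "group_b"])
        for (g1, g2), p_ref in zip(
            [("a", "b"), ("a", "c"), ("b", "c")], ref.pvalues
        ):
            assert ours.loc[(g1, g2), "p_tukey"] == pytest.approx(p_ref, abs=1e-6)

    def test_single_group_rejected(self):
        gi = pd.DataFrame({"Cu": [1.0, 2.0, 3.0]}, index=list("abc"))
        labels = pd.Series(["only"] * 3, index=gi.index)
        with pytest.raises(ValueError):
            fit_architecture_model(gi, labels)


class TestCellTypeCorrelation:
    def test_identical_column_gives_rho_one(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(50)]
        z = rng.normal(size=50)
        gi = pd.DataFrame({"Cu": z}, index=idx)
        props = pd.DataFrame({"Epithelial": z, "TCell": rng.normal(size=50)}, index=idx)
        res = celltype_metal_correlation(props, gi)
        assert res.rho.loc["Epithelial", "Cu"] == pytest.approx(1.0)

    def test_null_columns_rarely_exceed_015(self):
        # independence null at n = 500: |rho| < 0.15 for ~95% of draws
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(500)]
        gi = pd.DataFrame({"Cu": rng.normal(size=500)}, index=idx)
        hits = 0
        reps = 40
        for _ in range(reps):
            props = pd.DataFrame({"ct": rng.normal(size=500)}, index=idx)
            r = celltype_metal_correlation(props, gi).rho.iloc[0, 0]
            hits += abs(r) < 0.15
        assert hits / reps >= 0.95

    def test_constant_column_missing_rho(self):
        idx = [f"s{i}" for i in range(20)]
        gi = pd.DataFrame({"Cu": np.arange(20.0)}, index=idx)
        props = pd.DataFrame({"ct": np.ones(20)}, index=idx)
        res = celltype_metal_correlation(props, gi)
        assert np.isnan(res.rho.iloc[0, 0])
        assert res.p.iloc[0, 0] == 1.0

    def test_planted_coupling_is_largest_rho(self, small_dataset):
        # generator couples Macrophage proportions to the Cu field
        from metalspot import build_neighbors
        from metalspot.hotspot import gi_star

        ds = small_dataset
        graph = build_neighbors(ds.spots, radius_um=100.0)
        z, _ = gi_star(ds.spot_element_values["Cu"].to_numpy(), graph)
        gi = pd.DataFrame({"Cu": z}, index=ds.spot_element_values.index)
        res = celltype_metal_correlation(ds.cell_props, gi)
        assert res.rho["Cu"].idxmax() == "Macrophage"


class TestClusterMatrix:
    def test_duplicate_rows_adjacent(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=5)
        mat = np.vstack([a, rng.normal(size=5) + 10, a + 1e-12])
        order = cluster_matrix(mat)
        pos = {row: i for i, row in enumerate(order)}
        assert abs(pos[0] - pos[2]) == 1

    def test_separated_clusters_contiguous(self):
        rng = np.random.default_rng(1)
        lo = rng.normal(0, 0.1, (4, 6))
        hi = rng.normal(50, 0.1, (3, 6))
        order = cluster_matrix(np.vstack([lo, hi]))
        labels = [0 if i < 4 else 1 for i in order]
        # one switch between the two blocks in leaf order
        assert sum(a != b for a, b in zip(labels, labels[1:])) == 1

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(6, 4))
        order = cluster_matrix(mat)
        perm = rng.permutation(6)
        order_p = cluster_matrix(mat[perm])
        # same adjacency structure after mapping back through the permutation
        back = [perm[i] for i in order_p]
        pairs = {frozenset(p) for p in zip(order, order[1:])}
        pairs_p = {frozenset(p) for p in zip(back, back[1:])}
        assert len(pairs & pairs_p) >= len(pairs) - 2

    def test_single_row_identity(self):
        assert cluster_matrix(np.ones((1, 3))) == [0]
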