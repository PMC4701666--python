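"""Network construction, TOM, module detection, eigengenes, kIM."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cienet.network import (
    GREY,
    ModulePartition,
    Network,
    adjacency,
    classical_mds,
    cluster_modules,
    compute_eigengenes,
    eigengene_timecourse,
    kim,
    module_eigengene,
    module_overlap_score,
    pick_soft_threshold,
    scale_free_fit,
    select_deep_split,
    tom,
)


def _net_from_adjacency(a: np.ndarray) -> Network:
    ids = [f"g{i}" for i in range(a.shape[0])]
    adj = pd.DataFrame(a, index=ids, columns=ids)
    return Network(ids, 6, adj, None, pd.Series(a.sum(axis=1), index=ids))


def naive_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop oracle for the unsigned TOM formula."""
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestAdjacency:
    def test_analytic_values(self):
        x = np.vstack([np.arange(6.0), np.arange(6.0) * 2 + 1])  # cor = 1
        net = adjacency(pd.DataFrame(x), beta=6)
        assert net.adjacency.iloc[0, 1] == pytest.approx(1.0)
        assert net.adjacency.iloc[0, 0] == 0.0  # zero diagonal

    def test_negative_half_correlation(self):
        # construct two genes with cor exactly -0.5
        x1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x2 = np.array([-1.0, 0.0, 0.0, 1.0, -1.0, 1.0])
        r = np.corrcoef(x1, x2)[0, 1]
        net = adjacency(pd.DataFrame(np.vstack([x1, x2])), beta=6)
        assert net.adjacency.iloc[0, 1] == pytest.approx(abs(r) ** 6)

    def test_constant_gene_listed(self):
        x = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            adjacency(x, 6)


class TestSoftThreshold:
    def test_report_shape_and_monotone_connectivity(self, small_sim):
        em, _ = small_sim
        report = pick_soft_threshold(em, powers=(2, 4, 6, 8))
        assert list(report.index) == [2, 4, 6, 8]
        assert report["mean_k"].is_monotonic_decreasing

    def test_exact_power_law_degree_sequence_fits_well(self):
        # discrete degree sequence with counts exactly proportional to k^-2
        ks = np.arange(1, 11, dtype=float)
        counts = np.round(2000 * ks**-2.0).astype(int)
        k = np.repeat(ks, counts)
        r2, slope = scale_free_fit(k)
        assert r2 >= 0.95
        assert slope == pytest.approx(-2.0, abs=0.2)

    def test_heavy_tailed_sample_still_fits(self):
        rng = np.random.default_rng(0)
        k = rng.pareto(2.0, size=2000) + 1.0
        r2, slope = scale_free_fit(k)
        assert r2 >= 0.85
        assert slope < 0

    def test_degenerate_connectivity_flagged(self):
        r2, slope = scale_free_fit(np.full(100, 3.0))
        assert np.isnan(r2)


class TestTom:
    def test_isolated_pair_full_weight(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        t = tom(_net_from_adjacency(a)).tom.to_numpy()
        assert t[0, 1] == pytest.approx(1.0)  # (0+1)/(1+1-1)

    def test_no_edge_no_shared_neighbors(self):
        a = np.zeros((3, 3))
        a[1, 2] = a[2, 1] = 0.7
        t = tom(_net_from_adjacency(a)).tom.to_numpy()
        assert t[0, 1] == pytest.approx(0.0)

    def test_three_gene_hand_value(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        t = tom(_net_from_adjacency(a)).tom.to_numpy()
        # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert t[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [3, 4])
    @pytest.mark.parametrize("w", [0.2, 0.5, 0.9])
    def test_clique_closed_form(self, n, w):
        a = np.full((n, n), w)
        np.fill_diagonal(a, 0.0)
        t = tom(_net_from_adjacency(a)).tom.to_numpy()
        expected = ((n - 2) * w**2 + w) / ((n - 1) * w + 1 - w)
        off = t[~np.eye(n, dtype=bool)]
        assert np.allclose(off, expected, atol=1e-12)

    def test_matches_triple_loop_oracle_on_random_networks(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = rng.uniform(0, 1, size=(20, 20))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            t = tom(_net_from_adjacency(a)).tom.to_numpy()
            assert np.abs(t - naive_tom(a)).max() < 1e-12

    def test_range_and_symmetry(self, default_network):
        t = default_network.tom.to_numpy()
        assert (t >= 0).all() and (t <= 1).all()
        assert np.abs(t - t.T).max() == 0.0


class TestClusterModules:
    def test_two_perfect_blocks_fully_assigned(self):
        rng = np.random.default_rng(2)
        f1, f2 = rng.normal(size=24), rng.normal(size=24)
        rows = [f1 * s for s in rng.uniform(0.5, 2, 40)] + [f2 * s for s in rng.uniform(0.5, 2, 40)]
        vals = pd.DataFrame(rows, index=[f"g{i}" for i in range(80)])
        net = tom(adjacency(vals, 6))
        part = cluster_modules(net, 2, 30, expression=vals)
        assert len(part.modules) == 2
        assert part.n_grey == 0
        assert set(part.labels.iloc[:40].unique()) != set(part.labels.iloc[40:].unique())

    def test_iid_noise_mostly_grey(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.normal(size=(100, 48)), index=[f"n{i}" for i in range(100)])
        net = tom(adjacency(vals, 6))
        part = cluster_modules(net, 2, 30, expression=vals)
        assert part.n_grey >= 90

    def test_planted_module_recovery(self, normalized, default_sim, default_network):
        _, truth = default_sim
        part = cluster_modules(default_network, 2, 30, expression=normalized.values)
        ari = adjusted_rand_score(
            truth.module_labels.loc[part.labels.index], part.labels
        )
        assert ari >= 0.9

    def test_labels_follow_size_order(self, normalized, default_network):
        part = cluster_modules(default_network, 2, 30, expression=normalized.values)
        sizes = part.labels[part.labels != GREY].value_counts()
        assert list(sizes.index[:2]) == ["turquoise", "blue"]
        assert (sizes >= 30).all()

    def test_fewer_genes_than_min_size_all_grey(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(rng.normal(size=(10, 12)), index=[f"g{i}" for i in range(10)])
        net = tom(adjacency(vals, 6))
        part = cluster_modules(net, 2, 30)
        assert part.n_grey == 10

    def test_deterministic_given_input(self, normalized, default_network):
        p1 = cluster_modules(default_network, 2, 30, expression=normalized.values)
        p2 = cluster_modules(default_network, 2, 30, expression=normalized.values)
        assert p1.labels.equals(p2.labels)

    def test_invalid_deep_split_rejected(self, default_network):
        with pytest.raises(ValueError, match="deep_split"):
            cluster_modules(default_network, 7, 30)


@pytest.fixture(scope="module")
def block_data():
    rng = np.random.default_rng(3)
    rows, names = [], []
    for b in range(3):
        f = rng.normal(size=24)
        for i in range(40):
            rows.append(f + rng.normal(0, 0.05, 24))
            names.append(f"b{b}_{i}")
    vals = pd.DataFrame(rows, index=names)
    net = tom(adjacency(vals, 6))
    parts = {ds: cluster_modules(net, ds, 30, expression=vals) for ds in range(4)}
    return net, parts


class TestSelectDeepSplit:
    def test_well_separated_blocks_choose_deepest(self, block_data):
        net, parts = block_data
        assert select_deep_split(net, parts) == 3

    def test_single_module_partition_has_zero_overlap(self, block_data):
        net, _ = block_data
        coords = classical_mds(net.dissimilarity.to_numpy(), 2)
        labels = pd.Series("turquoise", index=net.adjacency.index)
        assert module_overlap_score(coords, labels) == {"turquoise": 0.0}

    def test_coincident_points_fully_overlap(self):
        coords = np.zeros((10, 2))
        labels = pd.Series(["a"] * 5 + ["b"] * 5)
        scores = module_overlap_score(coords, labels)
        # ties in distance: own centroid is not strictly closer, so no
        # misassignment by the strict < rule; degenerate MDS is instead
        # caught upstream by classical_mds
        with pytest.raises(ValueError, match="degenerate"):
            classical_mds(np.zeros((4, 4)), 2)
        assert set(scores) == {"a", "b"}


class TestEigengene:
    def test_identical_genes_explain_everything(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        vals = pd.DataFrame([profile, profile * 2 + 1, profile * 0.5 - 3],
                            index=["a", "b", "c"])
        eig, varexp = module_eigengene(vals, ["a", "b", "c"])
        assert varexp == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        r = np.corrcoef(eig, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_anticorrelated_halves_rank_one(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 2.0])
        vals = pd.DataFrame([profile, profile, -profile, -profile],
                            index=list("abcd"))
        eig, varexp = module_eigengene(vals, list("abcd"))
        assert varexp == pytest.approx(1.0)

    def test_orientation_positive_against_mean_profile(self, normalized, default_sim):
        _, truth = default_sim
        for mod in ("M4_biphasic", "M5_persistent"):
            genes = truth.module_gene_ids(mod)
            eig, _ = module_eigengene(normalized.values, genes)
            x = normalized.values.loc[genes].to_numpy()
            z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
            assert np.corrcoef(eig, z.mean(0))[0, 1] > 0

    def test_variance_explained_is_maximal_direction(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.normal(size=(15, 10)), index=[f"g{i}" for i in range(15)])
        eig, varexp = module_eigengene(vals, vals.index)
        x = vals.to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        total = (z**2).sum()
        for _ in range(200):
            v = rng.normal(size=10)
            v /= np.linalg.norm(v)
            assert ((z @ v) ** 2).sum() / total <= varexp + 1e-9


class TestKim:
    def test_pair_module_hand_values(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.8
        net = _net_from_adjacency(a)
        labels = pd.Series(["m", "m", GREY], index=net.adjacency.index)
        out = kim(net, ModulePartition(labels, 2, 2))
        assert out.loc["g0", "kim"] == pytest.approx(0.8)
        assert out.loc["g0", "scaled_kim"] == pytest.approx(1.0)
        assert out.loc["g2", "scaled_kim"] == 0.0  # grey

    def test_triangle_hand_values(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.9
        a[0, 2] = a[2, 0] = 0.1
        a[1, 2] = a[2, 1] = 0.1
        net = _net_from_adjacency(a)
        labels = pd.Series(["m", "m", "m"], index=net.adjacency.index)
        out = kim(net, ModulePartition(labels, 2, 3))
        assert np.allclose(out["kim"], [1.0, 1.0, 0.2])
        assert np.allclose(out["scaled_kim"], [1.0, 1.0, 0.2])

    def test_singleton_module_zero(self):
        a = np.zeros((2, 2))
        net = _net_from_adjacency(a)
        labels = pd.Series(["m", GREY], index=net.adjacency.index)
        out = kim(net, ModulePartition(labels, 2, 1))
        assert out.loc["g0", "kim"] == 0.0
        assert out.loc["g0", "scaled_kim"] == 0.0


class TestEigengeneTimecourse:
    def test_hand_computed_means_and_ses(self, small_sim):
        em, _ = small_sim
        md = em.metadata
        eig = pd.Series(np.arange(len(md), dtype=float), index=md.index)
        tc = eigengene_timecourse(eig, md)
        assert len(tc) == 8
        row = tc[(tc.treatment == "CIE") & (tc.timepoint == "0h")].iloc[0]
        sel = (md["treatment"] == "CIE") & (md["timepoint"] == "0h")
        vals = eig[sel.to_numpy()]
        assert row["mean"] == pytest.approx(vals.mean())
        assert row["se"] == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))

    def test_identical_values_zero_se(self, small_sim):
        em, _ = small_sim
        eig = pd.Series(2.5, index=em.metadata.index)
        tc = eigengene_timecourse(eig, em.metadata)
        assert (tc["se"] == 0).all()

    def test_biphasic_module_gap_pattern(self, normalized, default_sim, default_network):
        _, truth = default_sim
        part = cluster_modules(default_network, 2, 30, expression=normalized.values)
        part = compute_eigengenes(normalized.values, part)
        planted = set(truth.module_gene_ids("M4_biphasic"))
        best = max(part.modules, key=lambda m: len(planted & set(part.module_genes(m))))
        tc = eigengene_timecourse(part.eigengenes[best], normalized.metadata)
        piv = tc.pivot(index="timepoint", columns="treatment", values="mean")
        gap = (piv["CIE"] - piv["Ctrl"]).abs()
        assert set(gap.sort_values(ascending=False).index[:2]) == {"0h", "7d"}
        assert gap["72h"] < 0.5 * min(gap["0h"], gap["7d"])
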