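"""Complete-linkage agglomeration and the perturbation adjustment."""

import numpy as np
import pandas as pd
import pytest

from perturbkit import (
    PerturbationAdjuster,
    PVClusterer,
    PVPanelSpec,
    SubjectPanel,
    ValidationError,
    agglomerate,
    crude_rr,
    perturbation_adjusted_rr,
    pv_distance,
    simulate_panel,
    srr,
    stratified_perturbation_adjusted_rr,
)


class TestPVDistance:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 0, 1], [1, 0, 1], 0.0),
            ([0, 0, 0, 0], [1, 1, 1, 1], 1.0),
            ([1, 0, 1, 0], [1, 1, 0, 0], 0.5),
        ],
    )
    def test_examples(self, x, y, expected):
        assert pv_distance(np.array(x), np.array(y)) == expected

    def test_symmetry_and_mismatch(self):
        rng = np.random.default_rng(0)
        x, y = rng.integers(0, 2, 9), rng.integers(0, 2, 9)
        assert pv_distance(x, y) == pv_distance(y, x)
        with pytest.raises(ValidationError):
            pv_distance(x, y[:5])


def _oracle_complete_linkage(X, n_c):
    """Brute-force oracle: clusters as explicit sets; inter-cluster
    distance recomputed each step as the max pairwise profile distance;
    same lexicographic (min-member, min-member) tie-break."""
    clusters = [frozenset([i]) for i in range(len(X))]

    def dist(a, b):
        return max(pv_distance(X[i], X[j]) for i in a for j in b)

    while len(clusters) > 1 and min(len(c) for c in clusters) < n_c:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                ids = sorted((min(clusters[ai]), min(clusters[bi])))
                key = (dist(clusters[ai], clusters[bi]), ids[0], ids[1])
                if best is None or key < best[0]:
                    best = (key, ai, bi)
        _, ai, bi = best
        merged = clusters[ai] | clusters[bi]
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)]
        clusters.append(merged)
    labels = np.empty(len(X), dtype=int)
    for lab, c in enumerate(sorted(clusters, key=min)):
        for i in c:
            labels[i] = lab
    return labels


class TestAgglomerate:
    def test_nc_one_keeps_singletons(self):
        X = np.random.default_rng(0).integers(0, 2, (7, 3))
        asg = agglomerate(X, n_c=1)
        assert asg.n_clusters == 7
        assert asg.merge_trace == []

    def test_identical_rows_merge_first(self):
        X = np.array([[1, 0, 1], [0, 1, 1], [1, 0, 1], [0, 0, 0]])
        asg = agglomerate(X, n_c=2)
        assert asg.merge_trace[0][:2] == (0, 2)
        assert asg.merge_trace[0][2] == 0.0

    def test_two_separated_blocks_recovered(self):
        X = np.array(
            [[0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0],
             [1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 1]]
        )
        asg = agglomerate(X, n_c=3)
        assert asg.n_clusters == 2
        assert len(set(asg.labels[:3])) == 1 and len(set(asg.labels[3:])) == 1

    def test_small_n_below_nc_gives_single_cluster(self):
        X = np.random.default_rng(1).integers(0, 2, (5, 4))
        asg = agglomerate(X, n_c=10)
        assert asg.n_clusters == 1
        assert asg.sizes.tolist() == [5]

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n_c", [2, 3])
    def test_matches_bruteforce_oracle(self, seed, n_c):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        X = rng.integers(0, 2, (n, 4))
        got = agglomerate(X, n_c=n_c).labels
        want = _oracle_complete_linkage(X, n_c)
        assert np.array_equal(got, want)

    @pytest.mark.parametrize("seed", range(4))
    def test_merge_distances_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, (40, 6))
        trace = agglomerate(X, n_c=10).merge_trace
        dists = [t[2] for t in trace]
        assert np.all(np.diff(dists) >= -1e-12)

    def test_matches_scipy_on_tie_free_data(self):
        # continuous jittered profiles: no tied distances, so the merge
        # sequence is tie-break independent and scipy is a fair oracle
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        asg = agglomerate(X, n_c=6)
        condensed = pdist(X, "sqeuclidean") / X.shape[1]
        Z = linkage(condensed, method="complete")
        ref = fcluster(Z, t=asg.n_clusters, criterion="maxclust")
        # same partition up to label renaming
        pairs = {(a, b) for a in range(30) for b in range(30)
                 if asg.labels[a] == asg.labels[b]}
        ref_pairs = {(a, b) for a in range(30) for b in range(30)
                     if ref[a] == ref[b]}
        assert pairs == ref_pairs


class TestPerturbationAdjustment:
    def test_tiny_sample_falls_back_to_crude(self):
        e = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        d = np.array([1, 1, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        pv = np.random.default_rng(0).integers(0, 2, (12, 5))
        panel = SubjectPanel(e=e, d=d, pv=pv)
        rr, asg = perturbation_adjusted_rr(panel, n_c=20)
        assert asg.n_clusters == 1
        assert rr == pytest.approx(0.5 / (1 / 6))

    def test_noise_pvs_leave_crude_untouched_on_average(self, table2_neither):
        rng = np.random.default_rng(1)
        spec = PVPanelSpec(m_pv=100, mean=None, f_pv=0.0)
        diffs = []
        for _ in range(30):
            panel = simulate_panel(table2_neither, 200, spec, rng)
            rr, _ = perturbation_adjusted_rr(panel, n_c=20)
            crude = (panel.d[panel.e == 1].mean()) / (panel.d[panel.e == 0].mean())
            diffs.append(np.log(rr) - np.log(crude))
        assert np.mean(diffs) == pytest.approx(0.0, abs=0.05)

    def test_large_informative_panel_removes_bias(self, table1_positive):
        rng = np.random.default_rng(2)
        spec = PVPanelSpec(m_pv=2000, mean=None, f_pv=0.05)
        vals = []
        for _ in range(10):
            panel = simulate_panel(table1_positive, 200, spec, rng)
            vals.append(np.log(perturbation_adjusted_rr(panel, 20)[0]))
        log_s = np.log(srr(table1_positive))
        log_c = np.log(crude_rr(table1_positive))
        mean = np.mean(vals)
        assert abs(mean - log_s) < 0.35 * abs(log_c - log_s)

    def test_invalid_policies_agree_when_all_clusters_valid(self, table1_positive):
        panel = simulate_panel(
            table1_positive, 200, PVPanelSpec(m_pv=50, f_pv=0.05), rng=3
        )
        rr_drop, _ = perturbation_adjusted_rr(panel, 20, "drop")
        rr_merge, _ = perturbation_adjusted_rr(panel, 20, "merge")
        assert rr_drop == pytest.approx(rr_merge)

    def test_merge_policy_handles_degenerate_cluster(self):
        # one PV block holds only exposed subjects -> invalid under drop
        rng = np.random.default_rng(4)
        n = 60
        e = np.r_[np.ones(20, int), rng.integers(0, 2, 40)]
        d = rng.integers(0, 2, n)
        pv = np.zeros((n, 10), dtype=int)
        pv[:20] = 1
        panel = SubjectPanel(e=e, d=d, pv=pv)
        with pytest.warns(UserWarning):
            rr_drop, _ = perturbation_adjusted_rr(panel, n_c=15, invalid_policy="drop")
        rr_merge, _ = perturbation_adjusted_rr(panel, n_c=15, invalid_policy="merge")
        assert rr_drop > 0 and rr_merge > 0
        assert rr_merge != pytest.approx(rr_drop)


class TestEstimators:
    def test_clusterer_sklearn_interface(self):
        from sklearn.base import clone

        X = np.random.default_rng(0).integers(0, 2, (50, 8))
        est = PVClusterer(min_cluster_size=10)
        assert clone(est).get_params() == {"min_cluster_size": 10}
        labels = est.fit_predict(X)
        assert np.array_equal(labels, est.labels_)
        assert est.sizes_.min() >= 10
        assert est.assignment_.n_c == 10

    def test_adjuster_matches_function_wrapper(self, table1_positive):
        panel = simulate_panel(
            table1_positive, 150, PVPanelSpec(m_pv=40, f_pv=0.05), rng=5
        )
        est = PerturbationAdjuster(min_cluster_size=20)
        est.fit(panel.pv, np.column_stack([panel.e, panel.d]))
        rr, asg = perturbation_adjusted_rr(panel, n_c=20)
        assert est.adjusted_rr_ == pytest.approx(rr)
        assert np.array_equal(est.assignment_.labels, asg.labels)

    def test_adjuster_validates_y(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValidationError):
            PerturbationAdjuster().fit(X, np.zeros(10))
        with pytest.raises(ValidationError):
            PerturbationAdjuster().fit(X, np.full((10, 2), 2))


class TestStratifiedAdjustment:
    def test_constant_confounder_equals_plain(self, table1_positive):
        panel = simulate_panel(
            table1_positive, 150, PVPanelSpec(m_pv=30, f_pv=0.05), rng=6
        )
        with_conf = SubjectPanel(
            e=panel.e, d=panel.d, pv=panel.pv,
            confounders=pd.DataFrame({"MC": np.zeros(panel.n, dtype=int)}),
        )
        plain, _ = perturbation_adjusted_rr(panel, n_c=20)
        strat = stratified_perturbation_adjusted_rr(with_conf, n_c=20)
        assert strat == pytest.approx(plain)

    def test_measured_confounder_speeds_convergence(self, table1_positive):
        # U is a composite of a measured confounder (MC) and a true
        # unknown: strata 1..4 carry (MC,TU) = (1,1),(0,1),(1,0),(0,0).
        # Clustering within MC levels should land nearer the SRR than
        # clustering that ignores MC, at equal panel size.
        pop = table1_positive
        mc_of_u = np.array([1, 0, 1, 0])
        rng = np.random.default_rng(7)
        spec = PVPanelSpec(m_pv=200, mean=None, f_pv=0.05)
        log_s = np.log(srr(pop))
        plain, strat = [], []
        for _ in range(30):
            panel = simulate_panel(pop, 200, spec, rng)
            mc = mc_of_u[panel.truth()]
            with_conf = SubjectPanel(
                e=panel.e, d=panel.d, pv=panel.pv,
                confounders=pd.DataFrame({"MC": mc}),
            )
            plain.append(np.log(perturbation_adjusted_rr(panel, 20)[0]))
            strat.append(np.log(stratified_perturbation_adjusted_rr(with_conf, 20)))
        assert abs(np.mean(strat) - log_s) < abs(np.mean(plain) - log_s)

    def test_missing_confounders_rejected(self, table1_positive):
        panel = simulate_panel(
            table1_positive, 60, PVPanelSpec(m_pv=10, f_pv=0.05), rng=8
        )
        with pytest.raises(ValidationError):
            stratified_perturbation_adjusted_rr(panel, n_c=20)
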