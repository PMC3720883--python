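import numpy as np
import pytest

from metabonet import (
    CORE_REGIONS,
    core_analysis,
    hypometabolic_set_covariation,
    lobe_edge_counts,
    pearson_matrix,
    set_mean_abs_corr,
    top_k_edges,
)
from metabonet.atlas import LOBES
from metabonet.connectivity import ConnectivityMatrix


def _random_C(rng, n=90, n_subjects=60):
    return pearson_matrix(rng.normal(size=(n_subjects, n)))


class TestTopKEdges:
    def test_full_k_returns_all_pairs(self, rng):
        C = _random_C(rng)
        edges = top_k_edges(C, k=4005)
        assert len(edges) == 4005

    def test_k_one_is_max_pair(self, rng):
        C = _random_C(rng)
        top = top_k_edges(C, k=1).iloc[0]
        iu, ju = np.triu_indices(90, k=1)
        best = np.argmax(np.abs(C.r[iu, ju]))
        assert (top["region_a_index"], top["region_b_index"]) == (iu[best], ju[best])

    def test_matches_sort_oracle(self, rng):
        C = _random_C(rng, n=30)
        edges = top_k_edges(C, k=100)
        iu, ju = np.triu_indices(30, k=1)
        expected = np.sort(np.abs(C.r[iu, ju]))[::-1][:100]
        np.testing.assert_allclose(np.abs(edges["value"]), expected, atol=1e-12)

    def test_oversized_k_rejected(self, rng):
        with pytest.raises(ValueError, match="4005"):
            top_k_edges(_random_C(rng), k=4006)


class TestLobeEdgeCounts:
    def test_all_frontal_list(self, aal, rng):
        C = _random_C(rng)
        frontal = aal.lobe_indices("Frontal")
        import pandas as pd

        edges = pd.DataFrame(
            {
                "region_a_index": frontal[:-1],
                "region_b_index": frontal[1:],
                "value": 1.0,
                "rank": np.arange(1, len(frontal)),
            }
        )
        counts = lobe_edge_counts(edges, aal)
        assert counts["Frontal"] == len(frontal) - 1
        assert all(v == 0 for k, v in counts.items() if k != "Frontal")

    def test_toy_atlas_hand_counts(self, toy_atlas):
        import pandas as pd

        # edges: (A.L, A.R) intra-Frontal, (A.L, B.L) cross, (B.L, B.R) intra-Temporal
        edges = pd.DataFrame(
            {"region_a_index": [0, 0, 2], "region_b_index": [1, 2, 3]}
        )
        counts = lobe_edge_counts(edges, toy_atlas)
        assert counts["Frontal"] == 1
        assert counts["Temporal"] == 1

    def test_conservation_over_all_lobes(self, aal, rng):
        C = _random_C(rng)
        k = 500
        edges = top_k_edges(C, k=k)
        counts = lobe_edge_counts(edges, aal, lobes=LOBES)
        labels = aal.lobe_labels
        cross = sum(
            labels[a] != labels[b]
            for a, b in zip(edges["region_a_index"], edges["region_b_index"])
        )
        assert sum(counts.values()) + cross == k


class TestSetMeanAbsCorr:
    def test_two_region_set_single_pair(self, rng):
        C = _random_C(rng, n=10, n_subjects=30)
        assert set_mean_abs_corr(C, np.array([2, 7])) == pytest.approx(abs(C.r[2, 7]))

    def test_constant_matrix(self):
        r = np.full((12, 12), 0.5)
        np.fill_diagonal(r, 0.0)
        C = ConnectivityMatrix(r=r, n_subjects=20)
        assert set_mean_abs_corr(C, np.arange(5)) == pytest.approx(0.5)
        assert set_mean_abs_corr(C, np.arange(5), np.arange(6, 10)) == pytest.approx(0.5)

    def test_matches_enumeration_oracle(self, rng):
        C = _random_C(rng, n=20, n_subjects=40)
        a = np.array([0, 3, 7, 11])
        b = np.array([2, 5, 13])
        within = np.mean([
            abs(C.r[i, j]) for k, i in enumerate(a) for j in a[k + 1:]
        ])
        across = np.mean([abs(C.r[i, j]) for i in a for j in b])
        assert set_mean_abs_corr(C, a) == pytest.approx(within, abs=1e-12)
        assert set_mean_abs_corr(C, a, b) == pytest.approx(across, abs=1e-12)

    def test_invariances(self, rng):
        C = _random_C(rng, n=15, n_subjects=30)
        a = np.array([1, 4, 8, 12])
        v1 = set_mean_abs_corr(C, a)
        assert set_mean_abs_corr(C, a[::-1]) == pytest.approx(v1)
        flipped = ConnectivityMatrix(r=-C.r, n_subjects=C.n_subjects)
        assert set_mean_abs_corr(flipped, a) == pytest.approx(v1)

    def test_overlapping_sets_rejected(self, rng):
        C = _random_C(rng, n=10, n_subjects=30)
        with pytest.raises(ValueError, match="disjoint"):
            set_mean_abs_corr(C, np.array([1, 2, 3]), np.array([3, 4]))


class TestCoreAnalysis:
    def test_core_pair_count(self, aal):
        idx = aal.indices_of(CORE_REGIONS)
        assert len(idx) == 10  # 45 intra-Core pairs averaged
        # constant matrix: the mean over the 45 pairs equals the constant
        r = np.full((90, 90), 0.3)
        np.fill_diagonal(r, 0.0)
        C = ConnectivityMatrix(r=r, n_subjects=30)
        assert set_mean_abs_corr(C, idx) == pytest.approx(0.3)

    def test_identical_groups_null(self, aal, rng):
        mats = [_random_C(rng) for _ in range(5)]
        res = core_analysis({"NC": mats, "AD": mats}, aal)
        for name, (samples, kw) in res.items():
            assert kw.p == 1.0  # identical samples short-circuit

    def test_core_members_excluded_from_lobe_targets(self, aal, rng):
        core_idx = set(aal.indices_of(CORE_REGIONS))
        # SMA/PCL sit in Frontal, DCG in Limbic: the cross-set contrast must
        # not overlap (set_mean_abs_corr would raise on overlap)
        mats = [_random_C(rng) for _ in range(2)]
        res = core_analysis({"NC": mats}, aal)
        assert set(res) == {"Core-Core", "Core-Frontal", "Core-Limbic"}

    def test_planted_core_weakening_ordering(self, aal):
        # plant the whole intra-Core block at a group-specific level
        # (strongest in NC, weakest in AD) and require the per-bootstrap
        # Core-Core covariation means to recover that ordering
        from metabonet import CohortSpec, generate_cohort
        from metabonet.connectivity import BootstrapConfig, bootstrap_matrices
        from metabonet.preprocess import remove_confounds

        def core_block(level):
            return [
                (a, b, level)
                for i, a in enumerate(CORE_REGIONS)
                for b in CORE_REGIONS[i + 1:]
            ]

        orders = []
        for seed in range(8):
            spec = CohortSpec(
                n_subjects={"NC": 100, "MCI": 100, "AD": 100},
                seed=200 + seed,
                hypometabolic_regions={},
                extra_edges={
                    "NC": core_block(0.50),
                    "MCI": core_block(0.35),
                    "AD": core_block(0.20),
                },
            )
            cohort = generate_cohort(spec, aal)
            mats = {}
            for g in ("NC", "MCI", "AD"):
                res = remove_confounds(cohort.group_table(g))
                mats[g] = bootstrap_matrices(
                    res.values, BootstrapConfig(n_boot=6, seed=seed)
                )
            out = core_analysis(mats, aal)
            samples, _ = out["Core-Core"]
            means = {g: float(np.mean(s)) for g, s in samples.items()}
            orders.append(means["NC"] > means["MCI"] > means["AD"])
        assert np.mean(orders) >= 0.9


class TestHypometabolicSetCovariation:
    def test_all_regions_equals_whole_matrix_mean(self, rng):
        C = _random_C(rng, n=30)
        samples, _ = hypometabolic_set_covariation(
            {"NC": [C], "AD": [C]}, np.arange(30)
        )
        iu, ju = np.triu_indices(30, k=1)
        assert samples["NC"][0] == pytest.approx(np.abs(C.r[iu, ju]).mean())

    def test_small_set_rejected(self, rng):
        C = _random_C(rng, n=10, n_subjects=30)
        with pytest.raises(ValueError, match="at least 2"):
            hypometabolic_set_covariation({"NC": [C]}, np.array([4]))

    def test_planted_raised_covariance_ordering(self, aal):
        from metabonet import CohortSpec, generate_cohort
        from metabonet.connectivity import BootstrapConfig, bootstrap_matrices
        from metabonet.preprocess import remove_confounds

        region_set = ("HIP.L", "HIP.R", "PHG.L", "PHG.R", "PCG.L", "PCG.R")
        pairs = [
            (a, b, 0.65)
            for i, a in enumerate(region_set)
            for b in region_set[i + 1:]
        ]
        spec = CohortSpec(
            n_subjects={"NC": 60, "AD": 60},
            seed=33,
            hypometabolic_regions={},
            extra_edges={"AD": pairs},
        )
        cohort = generate_cohort(spec, aal)
        mats = {}
        for g in ("NC", "AD"):
            res = remove_confounds(cohort.group_table(g))
            mats[g] = bootstrap_matrices(res.values, BootstrapConfig(n_boot=8, seed=1))
        samples, kw = hypometabolic_set_covariation(
            mats, aal.indices_of(region_set)
        )
        assert np.mean(samples["AD"]) > np.mean(samples["NC"])
        assert kw.p < 0.05
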