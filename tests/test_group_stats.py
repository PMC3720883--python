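import numpy as np
import pytest

from metabonet import (
    attribute_curves,
    compare_auc,
    nbc_profile,
    pearson_matrix,
    select_hubs,
    sparsity_grid,
)
from metabonet.group_stats import AttributeCurve, NBCProfile, auc, connectivity_upper_bound

import oracles


def _matrices(rng, n_boot=4, n=20, n_subjects=40):
    return [pearson_matrix(rng.normal(size=(n_subjects, n))) for _ in range(n_boot)]


class TestAttributeCurves:
    def test_shape(self, rng):
        mats = _matrices(rng, n_boot=2)
        grid = sparsity_grid(0.5, 0.7, 0.1)
        curve = attribute_curves(mats, grid, "C")
        assert curve.values.shape == (2, 3)

    def test_identical_matrices_identical_rows(self, rng):
        C = _matrices(rng, n_boot=1)[0]
        curve = attribute_curves([C, C, C], sparsity_grid(0.5, 0.9, 0.1), "L")
        assert np.all(curve.values == curve.values[0])

    def test_global_efficiency_decreases_with_sparsity(self, rng):
        mats = _matrices(rng, n_boot=3, n=30)
        grid = sparsity_grid(0.5, 0.9, 0.05)
        curve = attribute_curves(mats, grid, "Eglob")
        diffs = np.diff(curve.values, axis=1)
        assert (diffs <= 1e-12).all()  # nested edge sets: efficiency cannot rise

    def test_unknown_metric_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown metric"):
            attribute_curves(_matrices(rng, 1), sparsity_grid(), "Q")


class TestAUC:
    def test_constant_curve(self):
        grid = sparsity_grid(0.5, 0.9, 0.02)
        curve = AttributeCurve("C", grid, np.ones((3, grid.size)))
        np.testing.assert_allclose(auc(curve), 0.4, atol=1e-12)

    def test_linear_curve_triangle_area(self):
        grid = sparsity_grid(0.5, 0.9, 0.02)
        vals = np.linspace(0, 1, grid.size)[None, :]
        np.testing.assert_allclose(auc(AttributeCurve("C", grid, vals)), 0.2, atol=1e-12)

    def test_matches_trapezoid_oracle(self, rng):
        grid = sparsity_grid(0.5, 0.9, 0.02)
        vals = rng.normal(size=(5, grid.size))
        expected = [oracles.trapezoid_oracle(grid, row) for row in vals]
        np.testing.assert_allclose(auc(AttributeCurve("x", grid, vals)), expected,
                                   atol=1e-12)

    def test_missing_values_need_interpolation_flag(self):
        grid = sparsity_grid(0.5, 0.9, 0.1)
        vals = np.ones((1, grid.size))
        vals[0, 2] = np.nan
        curve = AttributeCurve("L", grid, vals)
        with pytest.raises(ValueError, match="interpolate"):
            auc(curve)
        np.testing.assert_allclose(auc(curve, interpolate=True), 0.4, atol=1e-12)


class TestCompareAUC:
    def test_identical_samples_null(self, rng):
        x = rng.normal(size=300)
        res = compare_auc({"NC": x, "MCI": x, "AD": x})
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p > 0.9

    def test_all_tied_short_circuit(self):
        x = np.ones(10)
        res = compare_auc({"NC": x, "AD": x})
        assert res.p == 1.0
        assert res.post_hoc.empty

    def test_separated_groups_all_detected(self, rng):
        res = compare_auc({
            "NC": rng.normal(0.0, 0.01, 300),
            "MCI": rng.normal(0.5, 0.01, 300),
            "AD": rng.normal(1.0, 0.01, 300),
        })
        assert res.p < 1e-10
        assert res.post_hoc["significant"].all()

    def test_single_shifted_group(self, rng):
        hits = 0
        n_sims = 60
        for s in range(n_sims):
            r = np.random.default_rng(1000 + s)
            res = compare_auc({
                "NC": r.normal(0, 1, 300),
                "MCI": r.normal(0, 1, 300),
                "AD": r.normal(3, 1, 300),
            })
            ph = res.post_hoc.set_index(["group_a", "group_b"])["significant"]
            ok = (
                ph[("NC", "AD")] and ph[("MCI", "AD")] and not ph[("NC", "MCI")]
            )
            hits += ok
        assert hits / n_sims >= 0.95


def _block_matrices(rng, n_boot, hub=None, n=24, n_subjects=60, hub_r=0.6):
    """Bootstrap-like ensembles from a fixed covariance, optional hub region."""
    cov = np.full((n, n), 0.15)
    np.fill_diagonal(cov, 1.0)
    if hub is not None:
        others = [j for j in range(n) if j != hub]
        for j in others[: n // 2]:
            cov[hub, j] = cov[j, hub] = hub_r
    w, V = np.linalg.eigh(cov)
    cov = (V * np.clip(w, 1e-6, None)) @ V.T
    return [
        pearson_matrix(rng.multivariate_normal(np.zeros(n), cov, size=n_subjects))
        for _ in range(n_boot)
    ]


class TestNBCProfile:
    def test_upper_bound_monotone_connectivity(self, rng):
        mats = _matrices(rng, n_boot=3, n=20, n_subjects=30)
        grid = sparsity_grid(0.5, 0.9, 0.05)
        bound = connectivity_upper_bound({"NC": mats}, grid)
        assert bound in grid
        # beyond the bound some bootstrap graph fragments
        from metabonet import binarize, largest_component

        above = grid[grid > bound]
        if above.size:
            sizes = [largest_component(binarize(C, above[0]))[1] for C in mats]
            assert min(sizes) < 20

    def test_same_ensemble_never_flagged(self, rng, aal):
        mats = _matrices(rng, n_boot=6, n=20, n_subjects=40)
        grid = sparsity_grid(0.5, 0.6, 0.05)
        atlas20 = _toy_n_region_atlas(20)
        profile = nbc_profile({"NC": mats, "AD": mats}, grid, atlas20)
        assert not profile.flagged.any()

    def test_nbc_normalization_identity(self, rng):
        mats = _matrices(rng, n_boot=4, n=20, n_subjects=40)
        grid = sparsity_grid(0.5, 0.6, 0.05)
        atlas20 = _toy_n_region_atlas(20)
        profile = nbc_profile({"NC": mats}, grid, atlas20)
        # mean of b_i over regions is 1 at every (bootstrap, grid point)
        arr = profile.samples["NC"]
        np.testing.assert_allclose(arr.mean(axis=2), 1.0, atol=1e-10)

    def test_planted_hub_flagged_and_selected(self, rng):
        atlas24 = _toy_n_region_atlas(24)
        grid = sparsity_grid(0.5, 0.6, 0.05)
        null = _block_matrices(np.random.default_rng(1), 8)
        hubby = _block_matrices(np.random.default_rng(2), 8, hub=5)
        profile = nbc_profile({"NC": null, "AD": hubby}, grid, atlas24)
        hubs = select_hubs(profile)
        ad_hubs = hubs.loc[hubs["group"] == "AD", "region"].tolist()
        assert atlas24.abbreviations[5] in ad_hubs

    def test_no_connected_grid_point_errors(self, rng):
        mats = _matrices(rng, n_boot=2, n=30, n_subjects=30)
        with pytest.raises(ValueError, match="denser"):
            connectivity_upper_bound({"NC": mats}, np.array([0.97]))


def _toy_n_region_atlas(n):
    """Programmatic atlas with n regions (n even), alternating hemispheres."""
    import pandas as pd

    from metabonet.atlas import RegionAtlas, _validate_atlas

    rows = []
    lobes = ["Frontal", "Temporal", "Occipital", "Limbic", "Parietal"]
    for k in range(n // 2):
        for h in ("L", "R"):
            rows.append(
                dict(
                    abbreviation=f"R{k}.{h}",
                    name=f"region {k} {h}",
                    hemisphere=h,
                    lobe=lobes[k % len(lobes)],
                )
            )
    return RegionAtlas(_validate_atlas(pd.DataFrame(rows), expected_n=n))


class TestSelectHubs:
    def test_vertex_transitive_network_has_no_hubs(self, aal):
        import pandas as pd

        profile = NBCProfile(
            atlas=aal,
            grid_used=np.array([0.5]),
            upper_bound=0.5,
            mean_nbc=pd.DataFrame({"NC": np.ones(90)}, index=aal.abbreviations),
            p_corrected=np.ones((90, 1)),
            significant_fraction=np.zeros(90),
            flagged=np.zeros(90, dtype=bool),
        )
        assert select_hubs(profile).empty

    def test_threshold_strictly_exceeded(self, aal):
        import pandas as pd

        vals = np.ones(90)
        vals[3] = 1.5  # exactly at threshold: not a hub
        vals[7] = 1.6
        profile = NBCProfile(
            atlas=aal,
            grid_used=np.array([0.5]),
            upper_bound=0.5,
            mean_nbc=pd.DataFrame({"NC": vals}, index=aal.abbreviations),
            p_corrected=np.ones((90, 1)),
            significant_fraction=np.zeros(90),
            flagged=np.zeros(90, dtype=bool),
        )
        hubs = select_hubs(profile)
        assert hubs["region"].tolist() == [aal.abbreviations[7]]
        assert (hubs["mean_nbc"] > 1.5).all()
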