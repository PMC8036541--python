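"""dPCA / distance-PCA features, landscapes, barriers, cross-projection."""

import numpy as np
import pytest

import tigersim.conf_analysis as ca
from tigersim.constants import KB


class TestDpcaFeatures:
    def test_unit_circle_mapping(self):
        fm = ca.dpca_features([[0.0, 90.0, 180.0]])
        assert np.allclose(fm.raw, [[1, 0, 0, 1, -1, 0]], atol=1e-12)

    def test_periodicity(self):
        a = ca.dpca_features([[33.0, -140.0]])
        b = ca.dpca_features([[393.0, 220.0]])
        assert np.allclose(a.raw, b.raw, atol=1e-12)

    def test_column_count_doubles_angles(self):
        fm = ca.dpca_features(np.zeros((7, 5)))
        assert fm.raw.shape == (7, 10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ca.dpca_features(np.empty((0, 0)))


class TestDistanceFeatures:
    def test_pair_count(self, rng):
        frames = rng.normal(size=(4, 6, 3))
        fm = ca.interchain_distance_features(frames, [0, 1, 2], [3, 4, 5])
        assert fm.raw.shape == (4, 9)

    def test_zscore_normalization(self, rng):
        frames = rng.normal(size=(50, 6, 3))
        fm = ca.interchain_distance_features(frames, [0, 1, 2], [3, 4, 5])
        z = fm.normalized
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-10)

    def test_hand_computed_two_frame_fixture(self):
        frames = np.array(
            [
                [[0, 0, 0], [1, 0, 0], [0, 3, 0], [0, 0, 4]],
                [[0, 0, 0], [2, 0, 0], [6, 8, 0], [0, 5, 12]],
            ],
            dtype=float,
        )
        fm = ca.interchain_distance_features(frames, [0, 1], [2, 3], normalize=False)
        # manual Euclidean arithmetic
        expected = np.array([[3.0, 4.0, np.sqrt(1 + 9), np.sqrt(1 + 16)],
                             [10.0, 13.0, np.sqrt(16 + 64), np.sqrt(4 + 25 + 144)]])
        assert np.allclose(fm.raw, expected, atol=1e-12)

    def test_zero_variance_feature_flagged_and_kept(self):
        frames = np.zeros((5, 2, 3))
        frames[:, 1, 0] = 1.0  # constant distance
        fm = ca.interchain_distance_features(frames, [0], [1])
        assert fm.flags[0]
        assert np.allclose(fm.normalized, 0.0)  # scaled by 1, centred

    def test_empty_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            ca.interchain_distance_features(rng.normal(size=(3, 4, 3)), [], [1])

    def test_symmetrize_invariant_under_chain_relabeling(self, rng):
        frames = rng.normal(size=(6, 8, 3))
        a, b = [0, 1, 2, 3], [4, 5, 6, 7]
        fm_ab = ca.interchain_distance_features(frames, a, b, normalize=False,
                                                symmetrize=True)
        fm_ba = ca.interchain_distance_features(frames, b, a, normalize=False,
                                                symmetrize=True)
        # swapped labels reorder features as the transpose; symmetrised
        # matrices agree after that reordering
        n = len(a)
        swapped = fm_ba.raw.reshape(6, n, n).swapaxes(1, 2).reshape(6, -1)
        assert np.allclose(fm_ab.raw, swapped, atol=1e-12)


class TestFitPCA:
    def test_matches_eigendecomposition_oracle(self, rng):
        # brute-force covariance eigendecomposition on <= 6-feature instances
        for n_feat in (2, 4, 6):
            x = rng.normal(size=(300, n_feat)) @ rng.normal(size=(n_feat, n_feat))
            fm = ca.FeatureMatrix(raw=x)
            axes = ca.fit_pca(fm, n_components=n_feat)
            cov = np.cov(x, rowvar=False, ddof=1)
            evals, evecs = np.linalg.eigh(cov)
            order = np.argsort(evals)[::-1]
            assert np.allclose(axes.explained_variance, evals[order], rtol=1e-8)
            for k in range(n_feat):
                dot = abs(float(evecs[:, order[k]] @ axes.components[k]))
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_isotropic_gaussian_flat_spectrum(self, rng):
        x = rng.normal(size=(20000, 3))
        axes = ca.fit_pca(ca.FeatureMatrix(raw=x), 3)
        ev = axes.explained_variance
        assert ev.max() / ev.min() < 1.15  # equal within sampling error

    def test_rank_one_data(self, rng):
        t = rng.normal(size=(500, 1))
        x = t @ np.array([[1.0, -2.0, 0.5]]) + 1e-6 * rng.normal(size=(500, 3))
        axes = ca.fit_pca(ca.FeatureMatrix(raw=x), 3)
        assert axes.explained_variance[0] / axes.explained_variance.sum() > 0.999

    def test_full_basis_reconstructs_centered_data(self, rng):
        x = rng.normal(size=(40, 5))
        fm = ca.FeatureMatrix(raw=x)
        axes = ca.fit_pca(fm, 5)
        scores = ca.project(fm, axes)
        recon = scores @ axes.components + axes.mean
        assert np.allclose(recon, x, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        x = rng.normal(size=(100, 4)) * np.array([5.0, 1, 1, 1])
        axes = ca.fit_pca(ca.FeatureMatrix(raw=x), 2)
        for row in axes.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_many_components_rejected(self, rng):
        fm = ca.FeatureMatrix(raw=rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            ca.fit_pca(fm, 4)


class TestProject:
    def test_self_projection_consistency(self, rng):
        frames = rng.normal(size=(60, 6, 3))
        fm = ca.interchain_distance_features(frames, [0, 1, 2], [3, 4, 5])
        axes = ca.fit_pca(fm, 2)
        s1 = ca.project(fm, axes)
        s2 = ca.project(fm, axes)
        assert np.allclose(s1, s2, atol=1e-12)
        # fit-time scores: sklearn-equivalent transform of the same data
        centered = fm.normalized - axes.mean
        assert np.allclose(s1, centered @ axes.components.T, atol=1e-8)

    def test_constant_shift_projects_linearly(self, rng):
        x = rng.normal(size=(80, 4))
        fm = ca.FeatureMatrix(raw=x)
        axes = ca.fit_pca(fm, 2)
        shift = np.array([1.0, -0.5, 2.0, 0.0])
        s0 = ca.project(fm, axes)
        s1 = ca.project(ca.FeatureMatrix(raw=x + shift), axes)
        assert np.allclose(s1 - s0, shift @ axes.components.T, atol=1e-10)

    def test_projection_uses_reference_normalization(self, rng):
        # a second ensemble must be scaled by the *fitting* ensemble's stats
        frames = rng.normal(size=(50, 4, 3))
        fm = ca.interchain_distance_features(frames, [0, 1], [2, 3])
        axes = ca.fit_pca(fm, 2)
        other = ca.interchain_distance_features(
            frames * 3.0, [0, 1], [2, 3], normalize=False
        )
        scores = ca.project(other, axes)
        manual = ((other.raw - fm.mean) / fm.std - axes.mean) @ axes.components.T
        assert np.allclose(scores, manual, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        fm = ca.FeatureMatrix(raw=rng.normal(size=(30, 4)))
        axes = ca.fit_pca(fm, 2)
        with pytest.raises(ValueError):
            ca.project(ca.FeatureMatrix(raw=rng.normal(size=(5, 3))), axes)


class TestBoltzmannLandscape:
    def test_single_occupied_bin(self):
        scores = np.zeros((10, 2))
        land = ca.boltzmann_landscape(scores, bins=5)
        assert (~land.mask).sum() == 1
        assert np.nanmin(land.delta_g) == 0.0
        assert np.isnan(land.delta_g[land.mask]).all()

    def test_half_modal_bin_has_kt_ln2(self):
        # a bin holding half the modal probability sits kT ln 2 above it
        kt = KB * 300.0
        scores = np.concatenate(
            [np.tile([[0.5, 0.5]], (100, 1)), np.tile([[2.5, 2.5]], (50, 1))]
        )
        land = ca.boltzmann_landscape(scores, bins=3, kt=kt, axes_range=((0, 3), (0, 3)))
        dgs = np.sort(land.delta_g[~land.mask])
        assert dgs[0] == 0.0
        assert dgs[1] == pytest.approx(kt * np.log(2.0), rel=1e-12)
        assert kt * np.log(2.0) == pytest.approx(0.413, abs=0.005)

    def test_default_resolution_30x30(self, rng):
        land = ca.boltzmann_landscape(rng.normal(size=(500, 2)))
        assert land.probability.shape == (30, 30)
        assert land.probability.size == 900

    def test_probability_mass_conserved(self, rng):
        land = ca.boltzmann_landscape(rng.normal(size=(2000, 2)), bins=12)
        assert land.probability[~land.mask].sum() == pytest.approx(1.0, abs=1e-12)

    def test_imposed_range_drops_outside_frames(self, rng):
        scores = np.array([[0.5, 0.5], [0.6, 0.4], [5.0, 5.0]])
        land = ca.boltzmann_landscape(scores, bins=4, axes_range=((0, 1), (0, 1)))
        assert land.n_frames == 2
        assert land.n_total == 3

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            ca.boltzmann_landscape(rng.normal(size=(5, 1)))
        with pytest.raises(ValueError):
            ca.boltzmann_landscape(rng.normal(size=(5, 2)), bins=1)


def _make_landscape(dg_grid, kt=KB * 280.0):
    dg = np.asarray(dg_grid, dtype=float)
    mask = np.isnan(dg)
    p = np.where(mask, 0.0, np.exp(-dg / kt))
    p /= p.sum()
    nx, ny = dg.shape
    return ca.Landscape(
        edges_x=np.arange(nx + 1.0), edges_y=np.arange(ny + 1.0),
        probability=p, delta_g=dg, kt=kt, mask=mask, n_frames=1000, n_total=1000,
    )


class TestBarrierHeight:
    def test_same_bin_is_zero(self):
        land = _make_landscape([[0.0, 1.0], [1.0, 2.0]])
        assert ca.barrier_height(land, (0, 0), (0, 0)) == 0.0

    def test_single_path_three_bins(self):
        land = _make_landscape([[0.0], [2.0], [1.0]])
        assert ca.barrier_height(land, (0, 0), (2, 0)) == pytest.approx(2.0)
        assert ca.barrier_height(land, (2, 0), (0, 0)) == pytest.approx(1.0)

    def test_symmetry_up_to_endpoint_difference(self, rng):
        dg = rng.uniform(0, 4, (8, 8))
        dg[dg < 0.4] = np.nan
        dg = np.where(np.isnan(dg), np.nan, dg - np.nanmin(dg))
        land = _make_landscape(dg)
        unmasked = np.argwhere(~land.mask)
        a, b = map(tuple, unmasked[[0, -1]])
        try:
            fwd = ca.barrier_height(land, a, b)
            rev = ca.barrier_height(land, b, a)
        except ca.DisconnectedBasinsError:
            pytest.skip("random grid disconnected")
        assert fwd - rev == pytest.approx(
            land.delta_g[b] - land.delta_g[a], abs=1e-10
        )

    def test_matches_exhaustive_path_enumeration_on_small_grids(self, rng):
        # brute force: enumerate every simple 8-connected path by DFS
        def exhaustive(dg, a, b):
            nx, ny = dg.shape
            best = [np.inf]

            def dfs(cur, seen, peak):
                if peak >= best[0]:
                    return
                if cur == b:
                    best[0] = peak
                    return
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        nxt = (cur[0] + di, cur[1] + dj)
                        if (
                            (di or dj)
                            and 0 <= nxt[0] < nx
                            and 0 <= nxt[1] < ny
                            and nxt not in seen
                            and np.isfinite(dg[nxt])
                        ):
                            dfs(nxt, seen | {nxt}, max(peak, dg[nxt]))

            dfs(a, {a}, dg[a])
            return best[0] - dg[a]

        for trial in range(10):
            dg = rng.uniform(0, 5, (3, 4))
            if trial % 2:
                dg[rng.integers(3), rng.integers(4)] = np.nan
            dg = dg - np.nanmin(dg)
            land = _make_landscape(dg)
            unmasked = [tuple(ij) for ij in np.argwhere(~land.mask)]
            a, b = unmasked[0], unmasked[-1]
            expected = exhaustive(land.delta_g, a, b)
            if np.isinf(expected):
                with pytest.raises(ca.DisconnectedBasinsError):
                    ca.barrier_height(land, a, b)
            else:
                assert ca.barrier_height(land, a, b) == pytest.approx(expected, abs=1e-10)

    def test_matches_threshold_connectivity_oracle_on_10x10(self, rng):
        # independent oracle: binary search over dG thresholds with BFS
        def threshold_oracle(dg, a, b):
            finite = np.sort(dg[np.isfinite(dg)])

            def connected(t):
                ok = np.isfinite(dg) & (dg <= t)
                if not (ok[a] and ok[b]):
                    return False
                stack, seen = [a], {a}
                while stack:
                    ci, cj = stack.pop()
                    if (ci, cj) == b:
                        return True
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = ci + di, cj + dj
                            if (
                                (di or dj)
                                and 0 <= ni < dg.shape[0]
                                and 0 <= nj < dg.shape[1]
                                and ok[ni, nj]
                                and (ni, nj) not in seen
                            ):
                                seen.add((ni, nj))
                                stack.append((ni, nj))
                return False

            for t in finite:
                if connected(t):
                    return t - dg[a]
            return np.inf

        for _ in range(5):
            dg = rng.uniform(0, 6, (10, 10))
            dg[dg > 5.2] = np.nan
            dg = dg - np.nanmin(dg)
            land = _make_landscape(dg)
            unmasked = [tuple(ij) for ij in np.argwhere(~land.mask)]
            a = unmasked[3]
            b = unmasked[-4]
            expected = threshold_oracle(land.delta_g, a, b)
            if np.isinf(expected):
                with pytest.raises(ca.DisconnectedBasinsError):
                    ca.barrier_height(land, a, b)
            else:
                assert ca.barrier_height(land, a, b) == pytest.approx(expected, abs=1e-10)

    def test_masked_endpoint_rejected(self):
        land = _make_landscape([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError):
            ca.barrier_height(land, (0, 0), (0, 1))


class TestParameterRecovery:
    def test_two_basin_ddg_recovered(self, rng):
        # designed two-basin score distribution with ddG = 1.0 kcal/mol
        # between basin minima, recovered within 0.15 at 1e5 frames
        kt = KB * 280.0
        ddg = 1.0
        w2 = 1.0 / (1.0 + np.exp(ddg / kt))
        n = 100_000
        n2 = int(round(n * w2))
        basin1 = rng.normal(0, 0.45, size=(n - n2, 2)) + [-1.8, 0]
        basin2 = rng.normal(0, 0.45, size=(n2, 2)) + [1.8, 0]
        scores = np.vstack([basin1, basin2])
        land = ca.boltzmann_landscape(scores, bins=30, kt=kt,
                                      axes_range=((-3.6, 3.6), (-1.8, 1.8)))
        half = 15  # bins left of zero belong to basin 1
        dg1 = np.nanmin(land.delta_g[:half])
        dg2 = np.nanmin(land.delta_g[half:])
        assert (dg2 - dg1) == pytest.approx(ddg, abs=0.15)


class TestAxesSerialization:
    def test_roundtrip(self, rng):
        frames = rng.normal(size=(40, 4, 3))
        fm = ca.interchain_distance_features(frames, [0, 1], [2, 3])
        axes = ca.fit_pca(fm, 2)
        back = ca.PrincipalAxes.from_dict(axes.to_dict())
        assert np.allclose(back.components, axes.components)
        assert np.allclose(back.feature_std, axes.feature_std)
        s1, s2 = ca.project(fm, axes), ca.project(fm, back)
        assert np.allclose(s1, s2, atol=1e-12)
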