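"""Group spatial ICA, component thresholding, parcellation and matching."""

import numpy as np
import pytest

from metaconn import networks as nets
from metaconn import preproc as pre
from metaconn import synthio

from conftest import FIXTURE_SEEDS, make_roi_cohort


def _sparse_sources(rng, n_sources=2, V=500, width=60):
    """Disjoint zero-mean sparse spatial sources (strongly non-Gaussian)."""
    S = np.zeros((n_sources, V))
    for k in range(n_sources):
        sl = slice(100 * k, 100 * k + width)
        S[k, sl] = rng.choice([-1.5, 1.5], width) * rng.uniform(0.5, 1.0, width)
    return S


class TestConcatenate:
    def test_row_count_and_offsets(self):
        blocks = [np.ones((30, 50)) * k for k in range(3)]
        data, offsets, mask = nets.concatenate_group(blocks, demean=False)
        assert data.shape == (90, 50)
        assert offsets == [0, 30, 60]
        assert mask is None

    def test_order_swap_moves_blocks(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(10, 20)), rng.normal(size=(12, 20))
        d_ab, _, _ = nets.concatenate_group([a, b], demean=False)
        d_ba, _, _ = nets.concatenate_group([b, a], demean=False)
        np.testing.assert_allclose(d_ab[:10], d_ba[12:])
        np.testing.assert_allclose(d_ab[10:], d_ba[:12])

    def test_demean_removes_subject_means(self):
        rng = np.random.default_rng(1)
        blocks = [rng.normal(size=(8, 30)) + 5.0, rng.normal(size=(8, 30)) - 2.0]
        data, offsets, _ = nets.concatenate_group(blocks)
        np.testing.assert_allclose(data[:8].mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(data[8:].mean(axis=0), 0.0, atol=1e-12)

    def test_width_mismatch_raises(self):
        with pytest.raises(ValueError, match="same voxel"):
            nets.concatenate_group([np.ones((5, 10)), np.ones((5, 11))])


class TestGroupSpatialICA:
    @pytest.mark.parametrize("seed", range(5))
    def test_noiseless_two_source_recovery(self, seed):
        """Exact mixtures of two sparse orthogonal sources are recovered
        with |spatial r| > 0.99."""
        rng = np.random.default_rng(seed)
        S = _sparse_sources(rng)
        X = rng.normal(size=(40, 2)) @ S
        maps = nets.group_spatial_ica(X, n_components=2, seed=seed)
        for i in range(2):
            best = max(abs(np.corrcoef(maps.maps[i], S[j])[0, 1]) for j in range(2))
            assert best > 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2)) @ _sparse_sources(rng) + 0.01 * rng.normal(size=(30, 500))
        a = nets.group_spatial_ica(X, n_components=2, seed=7)
        b = nets.group_spatial_ica(X, n_components=2, seed=7)
        np.testing.assert_array_equal(a.maps, b.maps)
        np.testing.assert_array_equal(a.mixing, b.mixing)

    def test_maps_are_z_scored_and_skew_positive(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3)) @ np.abs(
            np.vstack([_sparse_sources(rng, 2), _sparse_sources(rng, 1)])
        )
        maps = nets.group_spatial_ica(X, n_components=3, seed=0)
        np.testing.assert_allclose(maps.maps.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(maps.maps.std(axis=1), 1.0, atol=1e-10)
        from scipy.stats import skew

        assert (skew(maps.maps, axis=1) >= -1e-12).all()

    def test_too_many_components_raises(self):
        with pytest.raises(ValueError, match="n_components"):
            nets.group_spatial_ica(np.ones((5, 10)), n_components=6)


class TestThresholdAndParcellate:
    @staticmethod
    def _maps_on_atlas(atlas, hot_rois, seed=0):
        rng = np.random.default_rng(seed)
        mask = atlas.brain_mask
        flat = np.isin(atlas.label_volume, hot_rois)[mask].astype(float) * 3.0
        flat += 0.1 * rng.normal(size=flat.size)
        m = (flat - flat.mean()) / flat.std()
        return nets.ComponentMaps(
            maps=m[None, :], n_components=1, mixing=np.zeros((1, 1)), seed=0, mask=mask
        )

    def test_above_max_threshold_empty(self):
        atlas = synthio.make_toy_atlas(4, (4, 4, 4), {"frontal": 2, "parietal": 2})
        maps = self._maps_on_atlas(atlas, [1])
        nm = nets.threshold_component(maps, 0, z=maps.maps.max() + 1)
        assert not nm.mask.any()

    def test_threshold_nesting(self):
        atlas = synthio.make_toy_atlas(4, (4, 4, 4), {"frontal": 2, "parietal": 2})
        maps = self._maps_on_atlas(atlas, [1, 3])
        tight = nets.threshold_component(maps, 0, z=1.5)
        loose = nets.threshold_component(maps, 0, z=1.0)
        assert (tight.mask <= loose.mask).all()

    def test_out_of_range_component_raises(self):
        atlas = synthio.make_toy_atlas(4, (4, 4, 4), {"frontal": 2, "parietal": 2})
        with pytest.raises(ValueError, match="out of range"):
            nets.threshold_component(self._maps_on_atlas(atlas, [1]), 3)

    def test_whole_roi_mask_parcellates_to_it(self):
        atlas = synthio.make_toy_atlas(6, (6, 6, 6), {"frontal": 3, "parietal": 3})
        mask = atlas.label_volume == 5
        assert nets.parcellate_mask(mask, atlas, min_fraction=0.5) == [5]

    def test_zero_fraction_keeps_any_overlap(self):
        atlas = synthio.make_toy_atlas(6, (6, 6, 6), {"frontal": 3, "parietal": 3})
        mask = np.zeros(atlas.shape, dtype=bool)
        mask[atlas.label_volume == 2] = True
        first_voxel = tuple(np.argwhere(atlas.label_volume == 4)[0])
        mask[first_voxel] = True
        assert nets.parcellate_mask(mask, atlas, min_fraction=0.0) == [2, 4]

    def test_fraction_agrees_with_voxel_counting(self):
        atlas = synthio.make_toy_atlas(5, (5, 5, 5), {"frontal": 3, "occipital": 2})
        rng = np.random.default_rng(7)
        mask = rng.random(atlas.shape) < 0.4
        got = nets.parcellate_mask(mask, atlas, min_fraction=0.35)
        expect = []
        for rid in atlas.roi_ids:
            inside = atlas.label_volume == rid
            if mask[inside].sum() / inside.sum() >= 0.35:
                expect.append(int(rid))
        assert got == expect


class TestMatchComponents:
    @staticmethod
    def _maps(arr):
        arr = np.asarray(arr, dtype=float)
        return nets.ComponentMaps(
            maps=arr, n_components=arr.shape[0],
            mixing=np.zeros((1, arr.shape[0])), seed=0,
        )

    def test_permutation_recovered(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(4, 100))
        perm = [2, 0, 3, 1]
        pairs = nets.match_components(self._maps(A), self._maps(A[perm]))
        mapping = {ia: ib for ia, ib, _ in pairs}
        for ib, ia in enumerate(perm):
            assert mapping[ia] == ib
        assert all(r == pytest.approx(1.0) for _, _, r in pairs)

    def test_sign_flip_reported(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(3, 80))
        pairs = nets.match_components(self._maps(A), self._maps(-A))
        assert all(r == pytest.approx(-1.0) for _, _, r in pairs)

    def test_assignment_beats_greedy(self):
        rng = np.random.default_rng(10)
        A, B = rng.normal(size=(5, 60)), rng.normal(size=(5, 60))
        pairs = nets.match_components(self._maps(A), self._maps(B))
        total = sum(abs(r) for _, _, r in pairs)
        corr = np.abs(np.corrcoef(A, B)[:5, 5:])
        greedy, used = 0.0, set()
        for i in range(5):
            j = max((j for j in range(5) if j not in used), key=lambda j: corr[i, j])
            used.add(j)
            greedy += corr[i, j]
        assert total >= greedy - 1e-12


class TestEndToEndNetworkIdentification:
    def test_motor_unit_recovered_majority_of_seeds(self):
        """On the default cohort the component matching the planted motor
        template parcellates to a set containing every motor region in a
        majority of the fixture seeds."""
        hits = 0
        for seed in FIXTURE_SEEDS:
            cohort = make_roi_cohort(seed, volumes=True, fmri_frames=30)
            atlas = cohort.atlas
            scans = [
                pre.global_mean_normalize(
                    pre.retain_frames(
                        pre.SubjectScan(
                            cohort.fpet_scans[s.subject_id], "fpet", s.subject_id,
                            brain_mask=atlas.brain_mask,
                        ),
                        30,
                    )
                )
                for s in cohort.group_subjects("PD")
            ]
            data, _, mask = nets.concatenate_group(scans)
            maps = nets.group_spatial_ica(data, n_components=10, seed=seed, mask=mask)
            motor = list(cohort.truth.motor_rois["PD"])
            template = np.isin(atlas.label_volume, motor)[mask].astype(float)
            rs = [abs(np.corrcoef(m, template)[0, 1]) for m in maps.maps]
            comp = int(np.argmax(rs))
            rois = nets.parcellate_mask(
                nets.threshold_component(maps, comp, z=1.0), atlas, 0.1
            )
            hits += set(motor) <= set(rois)
        assert hits >= 3
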