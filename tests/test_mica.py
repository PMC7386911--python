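"""Masked ICA, matching, model-order selection, specificity and segmentation."""
import itertools

import numpy as np
import pytest

from micacardio import mica
from micacardio.stats import dual_regression_maps
from micacardio.synthgen import PhantomSpec, make_phantom
from micacardio.types import ComponentSet, Mask, ReproducibilityCurve, TissuePriors, VolumeSeries


def _truth_in_mask(truth, mask):
    k = truth.source_maps.shape[0]
    return truth.source_maps.reshape(k, -1)[:, mask.data.ravel()]


class TestMaskedICA:
    def test_noiseless_sources_recovered(self, noiseless_phantom):
        _, (runs, mask, priors, truth) = noiseless_phantom
        comps = mica.masked_ica(runs, mask, 2, seed=1)
        corr = mica.crosscorr(
            comps, ComponentSet(maps=_zscore(_truth_in_mask(truth, mask)), mixing=[],
                                mask=mask, converged=True, seed=0)
        )
        _, matched, _ = mica.hungarian_match(corr)
        assert (matched > 0.99).all()
        assert comps.converged

    def test_same_seed_bit_identical(self, noiseless_phantom):
        _, (runs, mask, *_ ) = noiseless_phantom
        a = mica.masked_ica(runs, mask, 2, seed=3)
        b = mica.masked_ica(runs, mask, 2, seed=3)
        assert np.array_equal(a.maps, b.maps)
        for ma, mb in zip(a.mixing, b.mixing):
            assert np.array_equal(ma, mb)

    def test_oversized_k_raises(self):
        data = np.random.default_rng(1).standard_normal((4, 4, 2, 20))
        m = np.zeros((4, 4, 2), bool)
        m[:2, :2, 0] = True
        m[:2, :3, 1] = True  # 10-voxel mask
        mask = Mask(m, np.eye(4))
        run = VolumeSeries(data=data, tr=1.0, affine=np.eye(4))
        with pytest.raises(ValueError):
            mica.masked_ica([run], mask, mask.n_voxels + 1, seed=0)
        with pytest.raises(ValueError):
            mica.masked_ica([run], mask, 20, seed=0)  # k >= total volumes


def _zscore(maps):
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    return (maps - mu) / sd


class TestCrossCorr:
    def test_self_correlation_is_identity_diagonal(self, noiseless_phantom):
        _, (runs, mask, *_ ) = noiseless_phantom
        comps = mica.masked_ica(runs, mask, 2, seed=1)
        corr = mica.crosscorr(comps, comps)
        assert np.allclose(np.diag(corr), 1.0, atol=1e-12)

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(5)
        mask = Mask(np.ones((4, 4, 4), bool), np.eye(4))
        a = ComponentSet(maps=rng.standard_normal((2, 64)), mixing=[], mask=mask,
                         converged=True, seed=0)
        b = ComponentSet(maps=rng.standard_normal((3, 64)), mixing=[], mask=mask,
                         converged=True, seed=0)
        corr = mica.crosscorr(a, b)
        for i in range(2):
            for j in range(3):
                ref = np.corrcoef(a.maps[i], b.maps[j])[0, 1]
                assert abs(corr[i, j] - ref) < 1e-12

    def test_mask_mismatch_raises(self):
        m1 = Mask(np.ones((3, 3, 3), bool), np.eye(4))
        m2d = np.ones((3, 3, 3), bool)
        m2d[0, 0, 0] = False
        m2 = Mask(m2d, np.eye(4))
        a = ComponentSet(maps=np.zeros((1, 27)) + np.arange(27), mixing=[], mask=m1,
                         converged=True, seed=0)
        b = ComponentSet(maps=np.zeros((1, 26)) + np.arange(26), mixing=[], mask=m2,
                         converged=True, seed=0)
        with pytest.raises(ValueError):
            mica.crosscorr(a, b)


class TestHungarian:
    def test_diagonal_dominant_identity_assignment(self):
        corr = np.full((3, 3), 0.1)
        np.fill_diagonal(corr, [0.9, 0.8, 0.7])
        assignment, matched, signs = mica.hungarian_match(corr)
        assert list(assignment) == [0, 1, 2]
        assert np.allclose(matched, [0.9, 0.8, 0.7])

    def test_matches_exhaustive_search_4x4(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            corr = rng.uniform(-1, 1, size=(4, 4))
            assignment, matched, _ = mica.hungarian_match(corr)
            best = max(
                sum(abs(corr[i, p[i]]) for i in range(4))
                for p in itertools.permutations(range(4))
            )
            assert matched.sum() == pytest.approx(best, abs=1e-12)

    def test_negative_correlations_matched_by_magnitude(self):
        corr = np.array([[-0.95, 0.1], [0.1, -0.9]])
        assignment, matched, signs = mica.hungarian_match(corr)
        assert list(assignment) == [0, 1]
        assert (matched > 0).all()
        assert list(signs) == [-1.0, -1.0]

    def test_rectangular_input_leaves_rows_unmatched(self):
        corr = np.array([[0.9, 0.1], [0.1, 0.8], [0.5, 0.4]])
        assignment, matched, _ = mica.hungarian_match(corr)
        assert sorted(a for a in assignment if a >= 0) == [0, 1]
        assert (assignment == -1).sum() == 1


class TestReproducibility:
    def test_identical_subject_halves_reproduce_perfectly(self, noiseless_phantom):
        _, (runs, mask, *_ ) = noiseless_phantom
        # two subjects carrying bit-identical data: any half-split is an identity split
        twin = [
            VolumeSeries(data=runs[0].data.copy(), tr=runs[0].tr, affine=runs[0].affine,
                         run_id=f"twin{i}")
            for i in range(4)
        ]
        curve = mica.reproducibility(twin, mask, dims=[2], n_splits=1, seed=1,
                                     subjects=["a", "b", "c", "d"])
        assert curve.mean_r[0] > 0.999

    def test_split_randomness_is_run_order_invariant(self, noiseless_phantom):
        _, (runs, mask, *_ ) = noiseless_phantom
        quad = []
        rng = np.random.default_rng(8)
        for i in range(4):
            noisy = runs[i % 2].data + 0.2 * rng.standard_normal(runs[0].data.shape)
            quad.append(VolumeSeries(data=noisy, tr=1.25, affine=runs[0].affine, run_id=f"r{i}"))
        c1 = mica.reproducibility(quad, mask, dims=[2], n_splits=3, seed=5)
        c2 = mica.reproducibility(list(reversed(quad)), mask, dims=[2], n_splits=3, seed=5)
        assert c1.mean_r == c2.mean_r


class TestSelectDim:
    @staticmethod
    def _curve(entries, n_splits=10):
        dims = sorted(entries)
        return ReproducibilityCurve(
            dims=dims,
            mean_r=[entries[k][0] for k in dims],
            sd_r=[0.01] * len(dims),
            n_converged=[entries[k][1] for k in dims],
            n_splits=n_splits,
        )

    def test_argmax_mean_r(self):
        assert mica.select_dim(self._curve({8: (0.8, 10), 10: (0.7, 10)})) == 8

    def test_nonconverged_dimensionality_excluded(self):
        assert mica.select_dim(self._curve({8: (0.8, 10), 12: (0.9, 0)})) == 8

    def test_tie_breaks_to_smaller_dimensionality(self):
        assert mica.select_dim(self._curve({6: (0.8, 10), 8: (0.8, 10)})) == 6

    def test_no_eligible_dimensionality_raises(self):
        with pytest.raises(ValueError):
            mica.select_dim(self._curve({8: (0.8, 5)}), min_converged_frac=1.0)


class TestSpecificity:
    def _toy(self):
        """Two noiseless sources: one in a CSF pocket, one in grey matter."""
        grid = (10, 10, 6)
        mask = Mask(np.ones(grid, bool), np.eye(4))
        maps = np.zeros((2,) + grid)
        maps[0, 2:4, 2:4, 2:4] = 1.0  # CSF-locked
        maps[1, 6:9, 6:9, 2:4] = 1.0  # grey matter
        gm = np.zeros(grid)
        csf = np.zeros(grid)
        csf[:5] = 0.9
        gm[5:] = 0.9
        priors = TissuePriors(gm=gm, wm=np.zeros(grid), csf=csf, affine=np.eye(4))
        rng = np.random.default_rng(3)
        tc = rng.standard_normal((60, 2))
        data = np.einsum("kxyz,tk->xyzt", maps, tc)
        run = VolumeSeries(data=data + 1e-6 * rng.standard_normal(data.shape), tr=1.0,
                           affine=np.eye(4))
        comps = ComponentSet(maps=_zscore(maps.reshape(2, -1)), mixing=[], mask=mask,
                             converged=True, seed=0)
        return comps, [run], mask, priors

    def test_csf_component_scores_below_one(self):
        comps, runs, cuboid, priors = self._toy()
        scores = mica.specificity_scores(comps, runs, cuboid, priors)
        assert scores[0] < 1.0
        assert scores[1] > 1.0

    def test_zero_csf_activation_gives_infinite_sentinel(self):
        comps, runs, cuboid, priors = self._toy()
        priors.csf[:] = 0.0
        priors.gm[:] = 0.9
        scores = mica.specificity_scores(comps, runs, cuboid, priors)
        assert np.isinf(scores).all()


class TestFilterUnspecific:
    def test_low_outlier_excluded_by_mean_minus_sd(self):
        kept, excluded = mica.filter_unspecific(np.array([10.0, 10.0, 10.0, 1.0]))
        # mean 7.75, sd 4.5 -> threshold 3.25 -> only the score of 1 falls below
        assert excluded == [3]
        assert kept == [0, 1, 2]

    def test_equal_scores_keep_everything(self):
        kept, excluded = mica.filter_unspecific(np.array([5.0, 5.0, 5.0]))
        assert excluded == []

    def test_two_close_scores_keep_both(self):
        kept, excluded = mica.filter_unspecific(np.array([5.0, 4.99]))
        assert excluded == []

    def test_infinite_sentinel_mapped_to_max_finite(self):
        kept, excluded = mica.filter_unspecific(np.array([np.inf, 10.0, 10.0, 1.0]))
        assert excluded == [3]

    def test_iid_scores_rarely_exclude_more_than_half(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            scores = rng.uniform(1, 50, size=10)
            _, excluded = mica.filter_unspecific(scores)
            assert len(excluded) <= 5


class TestSegment:
    def test_noiseless_blobs_reproduce_partition(self, noiseless_phantom):
        spec, (runs, mask, priors, truth) = noiseless_phantom
        comps = mica.masked_ica(runs, mask, 2, seed=2)
        labels = mica.segment(comps, [0, 1])
        corr = mica.crosscorr(
            comps, ComponentSet(maps=_zscore(_truth_in_mask(truth, mask)), mixing=[],
                                mask=mask, converged=True, seed=0)
        )
        assignment, _, _ = mica.hungarian_match(corr)
        for true_idx in range(2):
            comp = list(assignment).index(true_idx)
            support = truth.source_maps[true_idx] > 0
            assert (labels.labels[support] == comp + 1).all()

    def test_single_component_labels_positive_voxels(self):
        mask = Mask(np.ones((3, 3, 1), bool), np.eye(4))
        maps = np.array([[1.0, -1.0, 2.0, -0.5, 0.0, 3.0, -2.0, 1.5, -1.0]])
        comps = ComponentSet(maps=maps, mixing=[], mask=mask, converged=True, seed=0)
        labels = mica.segment(comps, [0]).labels.ravel()
        assert np.array_equal(labels > 0, maps[0] > 0)

    def test_tie_goes_to_lowest_component(self):
        mask = Mask(np.ones((2, 1, 1), bool), np.eye(4))
        maps = np.array([[1.0, 0.5], [1.0, 2.0]])
        comps = ComponentSet(maps=maps, mixing=[], mask=mask, converged=True, seed=0)
        labels = mica.segment(comps, [0, 1]).labels.ravel()
        assert labels[0] == 1  # exact tie -> component 0 (label 1)
        assert labels[1] == 2

    def test_never_assigns_excluded_components(self, noiseless_phantom):
        _, (runs, mask, *_ ) = noiseless_phantom
        comps = mica.masked_ica(runs, mask, 2, seed=2)
        labels = mica.segment(comps, [1])
        assert set(np.unique(labels.labels)) <= {0, 2}


class TestMixtureThreshold:
    def test_pure_noise_rarely_survives(self):
        rng = np.random.default_rng(21)
        rates = []
        for seed in range(20):
            z = rng.standard_normal(2000)
            survived, _ = mica.mixture_threshold(z, seed=seed)
            rates.append(survived.mean())
        assert np.mean(rates) <= 0.01

    def test_shifted_voxels_detected(self):
        rng = np.random.default_rng(22)
        hit = []
        for seed in range(20):
            z = rng.standard_normal(2000)
            z[:200] += 5.0
            survived, _ = mica.mixture_threshold(z, seed=seed)
            hit.append(survived[:200].mean())
        assert np.mean(hit) >= 0.95

    def test_constant_map_falls_back(self):
        with pytest.warns(UserWarning):
            survived, _ = mica.mixture_threshold(np.zeros(100), seed=0)
        assert not survived.any()
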