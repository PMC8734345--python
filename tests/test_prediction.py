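"""Atlas forests, similarity selection, unary aggregation and CRF refinement."""

from __future__ import annotations

import numpy as np
import pytest

from kbplan import (
    AtlasCase,
    AtlasLibrary,
    CRFParams,
    ConvergenceError,
    DoseGrid,
    FeatureSpec,
    ImageVolume,
    StructureSet,
    crf_refine,
    extract_features,
    predict_unary,
    select_atlases,
    train_atlas_forests,
)
from kbplan.prediction import (
    ForestHyperparams,
    SimilarityRanking,
    UnaryPrediction,
    crf_energy,
    _grid_edges,
    geometry_descriptor,
    rank_by_descriptor,
)

SPEC = FeatureSpec()


class TestAtlasForests:
    def test_in_sample_fit_is_tight(self, tiny_library, tiny_forests):
        """A forest evaluated on its own training case reproduces the
        reference dose to within 5% of prescription (voxel-wise MAE)."""
        case = tiny_library.cases[0]
        fm = extract_features(case.image, case.structures, SPEC)
        pred = tiny_forests[case.case_id].predict(fm)
        target = case.dose.dose[fm.mask]
        mae = np.abs(pred - target).mean()
        assert mae <= 0.05 * case.dose.prescription_cGy

    def test_constant_dose_predicted_exactly(self, tiny_library):
        """A constant training target is reproduced exactly by the forest."""
        case = tiny_library.cases[0]
        flat = DoseGrid(dose=np.where(case.structures["External"], 1800.0, 0.0))
        lib = AtlasLibrary(cases=(AtlasCase(case_id="flat", image=case.image,
                                            structures=case.structures,
                                            dose=flat),))
        forests = train_atlas_forests(lib, SPEC)
        fm = extract_features(case.image, case.structures, SPEC)
        assert np.allclose(forests["flat"].predict(fm), 1800.0)

    def test_same_seed_trains_identical_forests(self, tiny_library):
        hyper = ForestHyperparams(n_trees=10, max_depth=8, seed=9)
        f1 = train_atlas_forests(tiny_library, SPEC, hyper)
        f2 = train_atlas_forests(tiny_library, SPEC, hyper)
        case = tiny_library.cases[1]
        fm = extract_features(case.image, case.structures, SPEC)
        p1 = f1[case.case_id].predict(fm)
        p2 = f2[case.case_id].predict(fm)
        assert np.array_equal(p1, p2)

    def test_column_mismatch_rejected(self, tiny_library, tiny_forests):
        case = tiny_library.cases[0]
        other_spec = FeatureSpec(smoothing_scales_mm=(3.0,))
        fm = extract_features(case.image, case.structures, other_spec)
        with pytest.raises(ValueError, match="columns"):
            tiny_forests[case.case_id].predict(fm)


class TestSelectAtlases:
    def test_self_similarity_ranks_first_with_maximal_score(self, tiny_library):
        case = tiny_library.cases[2]
        ranking = select_atlases(case.image, case.structures, tiny_library, k=1)
        assert ranking.entries[0][0] == case.case_id
        assert ranking.entries[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_k_equal_library_size_is_permutation(self, tiny_library):
        case = tiny_library.cases[0]
        ranking = select_atlases(case.image, case.structures, tiny_library,
                                 k=len(tiny_library))
        assert sorted(cid for cid, _ in ranking.entries) == sorted(tiny_library.ids)
        assert ranking.k_selected == len(tiny_library)

    def test_ranking_matches_brute_force_sort(self):
        """Hand-built descriptors: ranking equals an exhaustive sort of
        pairwise Euclidean distances, ties broken by insertion order."""
        rng = np.random.default_rng(12)
        descriptors = {f"c{i}": rng.normal(size=6) for i in range(5)}
        query = rng.normal(size=6)
        ranking = rank_by_descriptor(query, descriptors, k=3)
        brute = sorted(
            descriptors,
            key=lambda cid: (np.linalg.norm(descriptors[cid] - query),
                             list(descriptors).index(cid)),
        )
        assert [cid for cid, _ in ranking.entries] == brute
        scores = [s for _, s in ranking.entries]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_k_out_of_range_rejected(self, tiny_library):
        case = tiny_library.cases[0]
        with pytest.raises(ValueError):
            select_atlases(case.image, case.structures, tiny_library,
                           k=len(tiny_library) + 1)

    def test_missing_ptv_rejected(self, tiny_library):
        from kbplan import MissingStructureError

        case = tiny_library.cases[0]
        masks = {k: v for k, v in case.structures.masks.items()
                 if k != "PTVp_5400"}
        broken = StructureSet(masks=masks)
        with pytest.raises(MissingStructureError):
            select_atlases(case.image, broken, tiny_library, k=1)


def _toy_unary(mean, spread, shape):
    mask = np.ones(shape, dtype=bool)
    return UnaryPrediction(mean=np.asarray(mean, float),
                           spread=np.asarray(spread, float),
                           mask=mask, n_clipped=0)


class TestPredictUnary:
    def test_single_atlas_is_identity(self, tiny_library, tiny_forests):
        case = tiny_library.cases[0]
        fm = extract_features(case.image, case.structures, SPEC)
        ranking = select_atlases(case.image, case.structures, tiny_library, k=1)
        unary = predict_unary(fm, ranking, tiny_forests)
        direct = np.clip(tiny_forests[ranking.selected_ids[0]].predict(fm), 0, None)
        assert np.array_equal(unary.mean, direct)
        assert np.allclose(unary.spread, 0.0)

    def test_weighted_moments_match_hand_computation(self):
        """Three hand-set forest outputs at one voxel: the weighted mean and
        SD equal the closed-form weighted moments with softmax weights."""

        class _Stub:
            columns = ("f",)

            def __init__(self, value):
                self.value = value

            def predict(self, fm):
                return np.full(fm.values.shape[0], self.value)

        from kbplan.features import FeatureMatrix

        fm = FeatureMatrix(values=np.zeros((1, 1)), columns=("f",),
                           mask=np.ones((1, 1, 1), dtype=bool),
                           spacing=(1, 1, 1))
        forests = {"a": _Stub(100.0), "b": _Stub(200.0), "c": _Stub(400.0)}
        scores = {"a": -0.1, "b": -0.5, "c": -1.0}
        ranking = SimilarityRanking(
            entries=tuple(sorted(scores.items(), key=lambda kv: -kv[1])),
            k_selected=3)
        unary = predict_unary(fm, ranking, forests)
        s = np.array([scores[c] for c, _ in ranking.entries])
        w = np.exp(s - s.max())
        w /= w.sum()
        vals = np.array([forests[c].predict(fm)[0] for c, _ in ranking.entries])
        mean = (w * vals).sum()
        sd = np.sqrt((w * (vals - mean) ** 2).sum())
        assert unary.mean[0] == pytest.approx(mean, rel=1e-12)
        assert unary.spread[0] == pytest.approx(sd, rel=1e-12)

    def test_agreeing_forests_give_zero_spread(self, tiny_library, tiny_forests):
        case = tiny_library.cases[0]
        fm = extract_features(case.image, case.structures, SPEC)
        cid = tiny_library.ids[0]
        ranking = SimilarityRanking(entries=((cid, -0.1), (cid + "x", -0.2)),
                                    k_selected=1)
        unary = predict_unary(fm, ranking, tiny_forests)
        assert np.allclose(unary.spread, 0.0)


class TestCRF:
    def _image(self, shape, values=None):
        vals = np.zeros(shape) if values is None else values
        return ImageVolume(values=vals, spacing=(1.0, 1.0, 1.0))

    def test_lambda_zero_returns_unary(self):
        rng = np.random.default_rng(3)
        shape = (4, 4, 4)
        unary = _toy_unary(rng.uniform(0, 100, 64), rng.uniform(1, 5, 64), shape)
        result = crf_refine(unary, self._image(shape),
                            CRFParams(pairwise_weight=0.0))
        assert np.array_equal(result.dose.dose.ravel(), unary.mean)

    def test_constant_unary_is_fixed_point(self):
        shape = (4, 4, 4)
        unary = _toy_unary(np.full(64, 42.0), np.full(64, 2.0), shape)
        result = crf_refine(unary, self._image(shape),
                            CRFParams(pairwise_weight=0.5))
        assert np.allclose(result.dose.dose, 42.0, atol=1e-6)

    def test_chain_matches_dense_linear_solve(self):
        """1x1x8 voxel chain: CRF output equals the dense solution of
        (W + lambda L) d = W u computed by a brute-force dense solver."""
        shape = (1, 1, 8)
        rng = np.random.default_rng(7)
        u = rng.uniform(0, 100, 8)
        spread = rng.uniform(0.5, 4.0, 8)
        lam = 0.8
        unary = _toy_unary(u, spread, shape)
        params = CRFParams(pairwise_weight=lam, tolerance=1e-12,
                           max_iterations=500)
        result = crf_refine(unary, self._image(shape), params)
        w = 1.0 / (spread**2 + params.epsilon_cGy2)
        L = np.zeros((8, 8))
        for i in range(7):
            L[i, i] += 1; L[i + 1, i + 1] += 1
            L[i, i + 1] -= 1; L[i + 1, i] -= 1
        dense = np.linalg.solve(np.diag(w) + lam * L, w * u)
        assert np.allclose(result.dose.dose.ravel(), np.clip(dense, 0, None),
                           atol=1e-8)

    def test_energy_nonincreasing_per_iteration(self):
        rng = np.random.default_rng(5)
        shape = (6, 6, 6)
        unary = _toy_unary(rng.uniform(0, 5000, 216), rng.uniform(1, 300, 216),
                           shape)
        img = self._image(shape, rng.normal(0, 30, shape))
        result = crf_refine(unary, img, CRFParams(pairwise_weight=1e-4))
        diffs = np.diff(result.energies)
        assert np.all(diffs <= 1e-9 * max(result.energies[0], 1.0))

    def test_total_variation_reduced_with_uniform_appearance(self):
        """With uniform appearance weights and lambda > 0 the refined field
        is smoother: total variation does not increase."""
        rng = np.random.default_rng(8)
        shape = (5, 5, 5)
        u = rng.uniform(0, 1000, 125)
        unary = _toy_unary(u, np.full(125, 50.0), shape)
        img = self._image(shape)  # constant intensity -> uniform edge weights
        result = crf_refine(unary, img, CRFParams(pairwise_weight=1e-3))

        def tv(values):
            grid = values.reshape(shape)
            return sum(np.abs(np.diff(grid, axis=a)).sum() for a in range(3))

        assert tv(result.dose.dose.ravel()) <= tv(u) + 1e-9

    def test_nonconvergence_raises_with_residual(self):
        rng = np.random.default_rng(9)
        shape = (6, 6, 6)
        unary = _toy_unary(rng.uniform(0, 5000, 216), rng.uniform(1, 300, 216),
                           shape)
        with pytest.raises(ConvergenceError) as exc_info:
            crf_refine(unary, self._image(shape),
                       CRFParams(pairwise_weight=1.0, tolerance=1e-14,
                                 max_iterations=2))
        assert exc_info.value.residual > 0

    def test_appearance_weights_preserve_edges(self):
        """A strong intensity edge weakens the pairwise coupling across it,
        so a dose step across the edge survives refinement better than one
        inside a homogeneous region."""
        shape = (2, 1, 2)
        u = np.array([0.0, 0.0, 1000.0, 1000.0])
        spread = np.full(4, 100.0)
        intens_edge = np.array([[[0.0, 0.0]], [[500.0, 500.0]]])
        intens_flat = np.zeros(shape)
        lam = 1e-3
        r_edge = crf_refine(_toy_unary(u, spread, shape),
                            ImageVolume(values=intens_edge, spacing=(1, 1, 1)),
                            CRFParams(pairwise_weight=lam, appearance_scale=50.0))
        r_flat = crf_refine(_toy_unary(u, spread, shape),
                            ImageVolume(values=intens_flat, spacing=(1, 1, 1)),
                            CRFParams(pairwise_weight=lam, appearance_scale=50.0))
        step_edge = r_edge.dose.dose[1, 0, 0] - r_edge.dose.dose[0, 0, 0]
        step_flat = r_flat.dose.dose[1, 0, 0] - r_flat.dose.dose[0, 0, 0]
        assert abs(step_edge) > abs(step_flat)


class TestOrderingInvariance:
    def test_prediction_invariant_to_library_order(self, tiny_library):
        """Reversing the atlas library leaves predictions bit-identical when
        the same cases are selected (per-case seeds are id-derived)."""
        reversed_lib = AtlasLibrary(cases=tuple(reversed(tiny_library.cases)))
        f_fwd = train_atlas_forests(tiny_library, SPEC)
        f_rev = train_atlas_forests(reversed_lib, SPEC)
        case = tiny_library.cases[0]
        fm = extract_features(case.image, case.structures, SPEC)
        r_fwd = select_atlases(case.image, case.structures, tiny_library, k=2)
        r_rev = select_atlases(case.image, case.structures, reversed_lib, k=2)
        assert set(r_fwd.selected_ids) == set(r_rev.selected_ids)
        u_fwd = predict_unary(fm, r_fwd, f_fwd)
        u_rev = predict_unary(fm, r_rev, f_rev)
        assert np.array_equal(u_fwd.mean, u_rev.mean)
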