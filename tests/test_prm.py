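"""PRM scoring: identities, closed forms, bounds, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prmsrs as P
from prmsrs.preprocess import counters, preprocess_matrix
from prmsrs.prm import _shift_plan, _shifted_references

from conftest import shift_vector


def naive_prm(pixel, ref, alpha, max_shift=30):
    """Independent per-shift oracle: explicit loop, no shared kernels."""
    best, best_dx = -np.inf, None
    for k in range(-max_shift, max_shift + 1):
        shifted = np.zeros_like(ref)
        n = ref.size
        if k >= 0:
            shifted[k:] = ref[: n - k] if k else ref
        else:
            shifted[: n + k] = ref[-k:]
        val = float(np.dot(pixel, shifted)) - alpha * k**2
        # tie-break: smallest |k|, then negative
        if val > best + 1e-15 or (
            abs(val - best) <= 1e-15
            and (abs(k) < abs(best_dx) or (abs(k) == abs(best_dx) and k < best_dx))
        ):
            best, best_dx = val, k
    return best, best_dx


class TestPrmScore:
    def test_self_match_is_one_at_zero_shift(self, narrow_ref):
        for alpha in (0.0, 1e-4, 0.5):
            res = P.prm_score(narrow_ref, narrow_ref, P.PRMConfig(alpha=alpha))
            assert abs(res.score - 1.0) < 1e-9
            assert res.best_shift == 0.0

    @pytest.mark.parametrize("k", [-30, -21, -7, -1, 1, 7, 21, 30])
    def test_shift_closed_form(self, narrow_ref, grid, k):
        """pixel = ref displaced by k (support unclipped) => 1 - alpha*k^2."""
        pix = P.Spectrum(grid, shift_vector(narrow_ref.intensity, k),
                         P.Stage.UNIT_NORM)
        res = P.prm_score(pix, narrow_ref, P.PRMConfig(alpha=1e-4))
        assert abs(res.score - (1 - 1e-4 * k**2)) < 1e-9
        assert res.best_shift == k

    def test_zero_alpha_ignores_shift(self, narrow_ref, grid):
        pix = P.Spectrum(grid, shift_vector(narrow_ref.intensity, 13),
                         P.Stage.UNIT_NORM)
        res = P.prm_score(pix, narrow_ref, P.PRMConfig(alpha=0.0))
        assert abs(res.score - 1.0) < 1e-9

    def test_score_strictly_decreases_with_shift_magnitude(self, narrow_ref, grid):
        scores = []
        for k in range(0, 31):
            pix = P.Spectrum(grid, shift_vector(narrow_ref.intensity, k),
                             P.Stage.UNIT_NORM)
            scores.append(P.prm_score(pix, narrow_ref, P.PRMConfig(alpha=1e-4)).score)
        assert np.all(np.diff(scores) < 0)

    def test_penalty_monotone_in_alpha_and_limit(self, narrow_ref, grid, pcfg):
        rng = np.random.default_rng(5)
        pix = P.preprocess_pixel(P.Spectrum(grid, rng.uniform(0, 1, grid.size)), pcfg)
        alphas = [0.0, 1e-5, 1e-4, 1e-3, 1e-1, 10.0]
        scores = [P.prm_score(pix, narrow_ref, P.PRMConfig(alpha=a)).score for a in alphas]
        assert np.all(np.diff(scores) <= 1e-15)
        unshifted = float(np.dot(pix.intensity, narrow_ref.intensity))
        assert abs(scores[-1] - unshifted) < 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_score_bounded_in_unit_interval(self, seed):
        cfg = P.PreprocessConfig(grid_range=(2700, 2800))
        grid = cfg.grid()
        rng = np.random.default_rng(seed)
        pix = P.preprocess_pixel(P.Spectrum(grid, rng.uniform(0, 1, grid.size)), cfg)
        ref = P.preprocess_pixel(P.Spectrum(grid, rng.uniform(0, 1, grid.size)), cfg)
        res = P.prm_score(pix, ref, P.PRMConfig(alpha=1e-4))
        assert -1e-12 <= res.score <= 1 + 1e-12

    def test_matches_naive_oracle_on_random_spectra(self, pcfg, grid):
        rng = np.random.default_rng(6)
        for _ in range(5):
            pix = P.preprocess_pixel(P.Spectrum(grid, rng.uniform(0, 1, grid.size)), pcfg)
            ref = P.preprocess_pixel(P.Spectrum(grid, rng.uniform(0, 1, grid.size)), pcfg)
            res = P.prm_score(pix, ref, P.PRMConfig(alpha=1e-4))
            expect, expect_dx = naive_prm(pix.intensity, ref.intensity, 1e-4)
            assert abs(res.score - expect) < 1e-12
            assert res.best_shift == expect_dx

    def test_trace_is_exact_and_max_equals_score(self, narrow_ref, pcfg, grid):
        rng = np.random.default_rng(7)
        pix = P.preprocess_pixel(P.Spectrum(grid, rng.uniform(0, 1, grid.size)), pcfg)
        res = P.prm_score(pix, narrow_ref, P.PRMConfig(alpha=1e-4), keep_trace=True)
        assert res.per_shift_scores.size == 61
        assert abs(res.score - res.per_shift_scores.max()) < 1e-15
        j = np.where(res.shifts == res.best_shift)[0][0]
        assert res.per_shift_scores[j] == res.score

    def test_tie_break_prefers_small_then_negative_shift(self, grid):
        # pixel with spikes at +-2 of the reference spike: exact tie at
        # dx = -2 and +2; the negative shift must win
        j = grid.size // 2
        ref_i = np.zeros(grid.size)
        ref_i[j] = 1.0
        ref = P.Spectrum(grid, ref_i, P.Stage.UNIT_NORM)
        pix_i = np.zeros(grid.size)
        pix_i[j - 2] = pix_i[j + 2] = 1.0 / np.sqrt(2)
        pix = P.Spectrum(grid, pix_i, P.Stage.UNIT_NORM)
        res = P.prm_score(pix, ref, P.PRMConfig(alpha=0.0))
        assert res.best_shift == -2.0
        dx, _ = _shift_plan(P.PRMConfig(), grid)
        assert dx[0] == 0
        assert np.all(dx[1::2] < 0) and np.all(dx[2::2] > 0)

    def test_grid_mismatch_rejected(self, narrow_ref, pcfg):
        other_cfg = P.PreprocessConfig(grid_range=(2700, 3100))
        other = P.preprocess_pixel(
            P.make_reference([(1, 2900, 4)], other_cfg.grid()), other_cfg
        )
        with pytest.raises(P.GridMismatchError):
            P.prm_score(other, narrow_ref)


class TestShiftMechanics:
    def test_positive_shift_zero_pads_leading_side(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        shifted = _shifted_references(ref, np.array([0, 2, -1]))
        assert np.array_equal(shifted[0], ref)
        assert np.array_equal(shifted[1], [0, 0, 1, 2])  # trailing 3,4 trimmed
        assert np.array_equal(shifted[2], [2, 3, 4, 0])


class TestScoreStack:
    def test_affine_perturbed_pure_stack_scores_one(self, pcfg, grid):
        ref_raw = P.make_reference([(1.0, 2900, 4), (0.5, 2960, 5)], grid, "r")
        rng = np.random.default_rng(8)
        rows, cols = 4, 5
        data = np.empty((rows, cols, grid.size))
        for i in range(rows):
            for j in range(cols):
                a, b = rng.uniform(0.2, 3), rng.uniform(-1, 2)
                data[i, j] = a * ref_raw.intensity + b
        st_ = P.HyperspectralStack(data, grid)
        img = P.score_stack(st_, ref_raw, pcfg, P.PRMConfig(alpha=1e-4))
        assert np.all(np.abs(img.scores - 1.0) < 1e-9)
        assert np.all(img.best_shift == 0)

    def test_vectorized_equals_per_pixel_loop(self, pcfg):
        """Oracle equivalence on a seeded 8x8x75 random stack."""
        rng = np.random.default_rng(9)
        axis = 2700 + 6.0 * np.arange(75)
        data = rng.uniform(0, 1, (8, 8, 75))
        st_ = P.HyperspectralStack(data, axis)
        ref_raw = P.make_reference([(1.0, 2900, 4), (0.5, 2960, 5)], pcfg.grid(), "r")
        cfg = P.PRMConfig(alpha=1e-4)
        img = P.score_stack(st_, ref_raw, pcfg, cfg)
        ref = P.preprocess_pixel(ref_raw, pcfg)
        p, degenerate, _ = preprocess_matrix(st_.flat(), axis, pcfg)
        for idx in range(64):
            expect, expect_dx = naive_prm(p[idx], ref.intensity, 1e-4)
            r, c = divmod(idx, 8)
            assert abs(img.scores[r, c] - expect) < 1e-12
            assert img.best_shift[r, c] == expect_dx

    def test_chunked_execution_is_bit_identical(self, pcfg, library):
        spec = P.SimSpec(seed=10, shape=(8, 8), noise_sd=0.02, jitter_sd=3)
        stack, _ = P.make_stack(spec)
        one = P.score_stack_multi(stack, library, pcfg, n_chunks=1)
        four = P.score_stack_multi(stack, library, pcfg, n_chunks=4)
        for name in library.names:
            assert np.array_equal(one[name].scores, four[name].scores)
            assert np.array_equal(one[name].best_shift, four[name].best_shift)

    def test_constant_pixel_masked_others_scored(self, pcfg, grid, library):
        spec = P.SimSpec(seed=11, shape=(4, 4))
        stack, _ = P.make_stack(spec)
        stack.data[2, 2, :] = 5.0
        img = P.score_stack(stack, library["tag_like"], pcfg)
        assert img.mask[2, 2] and img.scores[2, 2] == 0
        assert not img.mask[0, 0] and img.scores[0, 0] > 0


class TestScoreStackMulti:
    def test_identical_references_give_identical_images(self, pcfg, grid):
        ref = P.preprocess_pixel(P.make_reference([(1, 2900, 6)], grid, "a"), pcfg)
        lib = P.ReferenceLibrary({"a": ref, "b": ref}, grid)
        spec = P.SimSpec(seed=12, shape=(4, 4), noise_sd=0.01)
        stack, _ = P.make_stack(spec)
        imgs = P.score_stack_multi(stack, lib, pcfg)
        assert np.array_equal(imgs["a"].scores, imgs["b"].scores)

    def test_preprocessing_runs_once_per_pixel_not_per_reference(self, pcfg, library):
        spec = P.SimSpec(seed=13, shape=(4, 4))
        stack, _ = P.make_stack(spec)
        counters["pixel_spectra_preprocessed"] = 0
        P.score_stack_multi(stack, library, pcfg)
        assert counters["pixel_spectra_preprocessed"] == 16

    def test_two_phase_argmax_recovers_partition(self, pcfg, library):
        spec = P.SimSpec(seed=14, shape=(8, 8), layout="two_phase")
        stack, truth = P.make_stack(spec)
        imgs = P.score_stack_multi(stack, library, pcfg)
        names = truth["names"]
        score_cube = np.stack([imgs[n].scores for n in names], axis=-1)
        assert np.array_equal(
            np.argmax(score_cube, axis=-1), np.argmax(truth["weights"], axis=-1)
        )

    def test_empty_library_rejected(self, pcfg, grid):
        spec = P.SimSpec(seed=15, shape=(2, 2))
        stack, _ = P.make_stack(spec)
        with pytest.raises(P.DimensionError):
            P.ReferenceLibrary({}, grid)


class TestPRMScorerEstimator:
    def test_sklearn_params_clone_roundtrip(self):
        from sklearn.base import clone

        s = P.PRMScorer(alpha=2e-4, max_shift=10)
        c = clone(s)
        assert c.get_params()["alpha"] == 2e-4
        c.set_params(alpha=1e-4)
        assert c.alpha == 1e-4

    def test_transform_scores_match_functional_path(self, pcfg, library):
        spec = P.SimSpec(seed=16, shape=(4, 4), noise_sd=0.01)
        stack, _ = P.make_stack(spec)
        scorer = P.PRMScorer(alpha=1e-4).fit(library)
        scores = scorer.transform(stack.flat(), wavenumbers=stack.axis)
        imgs = P.score_stack_multi(stack, library, pcfg)
        for j, name in enumerate(library.names):
            assert np.allclose(scores[:, j].reshape(4, 4), imgs[name].scores, atol=1e-12)
        assert list(scorer.get_feature_names_out()) == [
            f"prm_score_{n}" for n in library.names
        ]

    def test_fit_from_raw_array(self, grid):
        raw = np.stack([
            P.make_reference([(1, 2850, 5)], grid).intensity,
            P.make_reference([(1, 2935, 5)], grid).intensity,
        ])
        scorer = P.PRMScorer().fit(raw, wavenumbers=grid)
        scores = scorer.transform(raw, wavenumbers=grid)
        assert scores.shape == (2, 2)
        assert np.allclose(np.diag(scores), 1.0, atol=1e-9)
        assert scores[0, 1] < 0.9
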