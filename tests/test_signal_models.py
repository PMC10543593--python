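import numpy as np
import pytest

from drmm import (
    MODELS,
    AcquisitionGrid,
    FitConfig,
    SignalVolume,
    compute_aicc,
    fit_voxel_cascade,
    fit_volume,
    model_signal,
)
from drmm.signal_models import (
    InadmissibleModelError,
    normalized_model_signal,
)
from .conftest import rician_corrupt

#: one representative, well-separated parameter set per model
TRUE_PARAMS = {
    1: [1.3, 220.0],
    2: [0.5, 1.8, 150.0, 0.4],
    3: [0.4, 1.8, 60.0, 300.0, 0.5],
    4: [0.3, 1.2, 2.6, 70.0, 500.0, 0.35, 0.35],
    5: [0.3, 1.2, 2.6, 60.0, 220.0, 550.0, 0.35, 0.35],
}

NEST_CHAINS = [(1, 2), (2, 3), (2, 4), (3, 5), (4, 5)]


class TestModelSpecs:
    def test_parameter_counts(self):
        assert [MODELS[m].n_params for m in range(1, 6)] == [2, 4, 5, 7, 8]

    def test_pool_counts_and_t2_sharing(self):
        assert [MODELS[m].n_pools for m in range(1, 6)] == [1, 2, 2, 3, 3]
        assert MODELS[2].pool_t2_slot == (0, 0)  # both pools one T2
        assert MODELS[4].pool_t2_slot == (0, 0, 1)  # pools 1,2 share T2


class TestModelSignal:
    def test_monoexponential_point_value(self):
        # D=1, T2=100 at (TE=100, b=0): no diffusion term, e^{-1} relaxation
        grid = AcquisitionGrid(((100.0, 0.0), (57.0, 0.0)))
        sig = model_signal(MODELS[1], [1.0, 100.0], grid)
        idx = grid.points.index((100.0, 0.0))
        assert sig[idx] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_sum_of_fractions_at_origin_limit(self, grid16):
        # at b=0, TE -> 0 every pool decays by nothing: S/S0 -> sum f = 1
        grid = AcquisitionGrid(((1e-9, 0.0),))
        for m, params in TRUE_PARAMS.items():
            sig = model_signal(MODELS[m], params, grid)
            assert sig[0] == pytest.approx(1.0, abs=1e-9)

    def test_nesting_identity_model3_vs_model1(self, grid16):
        one = model_signal(MODELS[1], [0.9, 180.0], grid16)
        three = model_signal(MODELS[3], [0.9, 2.5, 180.0, 700.0, 1.0], grid16)
        np.testing.assert_allclose(three, one, atol=1e-12)

    def test_shared_t2_tying_model4(self, grid16):
        # model 4's first two pools read the same T2 slot
        p4 = [0.3, 1.2, 2.6, 90.0, 500.0, 0.3, 0.3]
        p5 = [0.3, 1.2, 2.6, 90.0, 90.0, 500.0, 0.3, 0.3]
        np.testing.assert_allclose(
            model_signal(MODELS[4], p4, grid16),
            model_signal(MODELS[5], p5, grid16),
            atol=1e-14,
        )

    def test_wrong_parameter_count(self, grid16):
        with pytest.raises(ValueError, match="expects 2 parameters"):
            model_signal(MODELS[1], [1.0, 100.0, 0.5], grid16)


class TestAicc:
    def test_worked_examples(self):
        # SSE = N makes the log term vanish, leaving the penalty alone
        assert compute_aicc(16.0, 16, 2) == pytest.approx(8.0, abs=1e-12)
        assert compute_aicc(16.0, 16, 8) == pytest.approx(48.0, abs=1e-12)

    def test_matches_independent_formula_on_random_inputs(self, rng):
        for _ in range(200):
            n = int(rng.integers(8, 64))
            p = int(rng.integers(1, n - 2))
            sse = float(rng.uniform(1e-8, 100.0))
            expected = n * np.log(sse / n) + 2 * (p + 1) * (
                1 + (p + 2) / (n - p - 2)
            )  # independent literal transcription
            assert compute_aicc(sse, n, p) == pytest.approx(expected, rel=1e-12)

    def test_perfect_fit_sentinel(self):
        assert compute_aicc(0.0, 16, 2) == float("-inf")

    def test_inadmissible_when_too_few_points(self):
        with pytest.raises(InadmissibleModelError):
            compute_aicc(1.0, 16, 14)

    def test_negative_sse_rejected(self):
        with pytest.raises(ValueError):
            compute_aicc(-1.0, 16, 2)


class TestCascadeFitting:
    def test_model1_recovery_tight(self, grid16):
        sig = normalized_model_signal(MODELS[1], TRUE_PARAMS[1], grid16)
        res = fit_voxel_cascade(sig, grid16, rng=np.random.default_rng(0))
        r1 = next(r for r in res if r.model_id == 1)
        np.testing.assert_allclose(r1.params, TRUE_PARAMS[1], rtol=1e-4)
        assert all(r.sse <= r1.sse + 1e-10 for r in res)

    def test_model3_recovery(self, grid16):
        sig = normalized_model_signal(MODELS[3], TRUE_PARAMS[3], grid16)
        res = fit_voxel_cascade(sig, grid16, rng=np.random.default_rng(0))
        r3 = next(r for r in res if r.model_id == 3)
        np.testing.assert_allclose(r3.params, TRUE_PARAMS[3], rtol=1e-2)
        assert r3.sse < 1e-12

    def test_constant_signal_degenerates_gracefully(self, grid16):
        res = fit_voxel_cascade(
            np.ones(16), grid16, rng=np.random.default_rng(0)
        )
        r1 = next(r for r in res if r.model_id == 1)
        cfg = FitConfig()
        assert r1.pools[0].d == pytest.approx(cfg.bounds.d[0], rel=0.05)
        assert r1.pools[0].t2 == pytest.approx(cfg.bounds.t2[1], rel=0.05)
        assert all(r.degenerate for r in res if r.model_id > 1)

    def test_pools_sorted_ascending_d(self, grid16, rng):
        clean = normalized_model_signal(MODELS[5], TRUE_PARAMS[5], grid16)
        noisy = rician_corrupt(clean, 0.02, rng)
        noisy /= noisy[grid16.reference_index]
        for r in fit_voxel_cascade(noisy, grid16, rng=np.random.default_rng(1)):
            d = [p.d for p in r.pools]
            assert d == sorted(d)
            assert sum(p.fraction for p in r.pools) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_rng(self, grid16, rng):
        clean = normalized_model_signal(MODELS[3], TRUE_PARAMS[3], grid16)
        noisy = rician_corrupt(clean, 0.03, rng)
        noisy /= noisy[grid16.reference_index]
        a = fit_voxel_cascade(noisy, grid16, rng=np.random.default_rng(7))
        b = fit_voxel_cascade(noisy, grid16, rng=np.random.default_rng(7))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.params, rb.params)
            assert ra.sse == rb.sse

    def test_signal_length_mismatch(self, grid16):
        with pytest.raises(ValueError, match="length"):
            fit_voxel_cascade(np.ones(10), grid16)

    def test_nesting_monotone_under_noise(self, grid16, rng):
        clean = normalized_model_signal(MODELS[5], TRUE_PARAMS[5], grid16)
        for i in range(5):
            noisy = rician_corrupt(clean, 0.03, rng)
            noisy /= noisy[grid16.reference_index]
            res = {
                r.model_id: r.sse
                for r in fit_voxel_cascade(noisy, grid16, rng=np.random.default_rng(i))
            }
            for lo, hi in NEST_CHAINS:
                assert res[hi] <= res[lo] + 1e-9


class TestFractionRecoveryUnderNoise:
    def test_model3_fraction_error_small_at_high_snr(self, grid16):
        """Median |f1 error| < 0.05 at SNR 200 over well-separated biexponentials.

        Biexponential fraction estimates from 16 points are variance-limited;
        this is the SNR regime where they become individually reliable.
        """
        rng = np.random.default_rng(42)
        cfg = FitConfig(model_ids=(1, 2, 3))
        errs = []
        for i in range(100):
            true = [
                rng.uniform(0.1, 1.0),
                rng.uniform(1.2, 3.0),
                rng.uniform(30, 150),
                rng.uniform(250, 700),
                rng.uniform(0.25, 0.75),
            ]
            clean = normalized_model_signal(MODELS[3], true, grid16)
            noisy = rician_corrupt(clean, 1.0 / 200, rng)
            noisy /= noisy[grid16.reference_index]
            res = fit_voxel_cascade(noisy, grid16, cfg, rng=np.random.default_rng(i))
            r3 = next(r for r in res if r.model_id == 3)
            errs.append(abs(r3.pools[0].fraction - true[4]))
        assert np.median(errs) < 0.05


class TestFitVolume:
    def _volume(self, grid, n=4):
        data = np.empty((n, 1, 1, grid.n_points))
        for i in range(n):
            data[i, 0, 0] = normalized_model_signal(
                MODELS[1], [0.5 + 0.3 * i, 100.0 + 40 * i], grid
            )
        return data

    def test_masked_voxels_are_nan(self, grid16):
        data = self._volume(grid16)
        mask = np.ones((4, 1, 1), dtype=bool)
        mask[2, 0, 0] = False
        vf = fit_volume(SignalVolume(data, mask=mask), grid16, FitConfig(model_ids=(1,)))
        amap = vf.aicc_map(1)
        assert np.isnan(amap[2, 0, 0])
        assert np.isfinite(amap[mask]).all()

    def test_empty_mask_raises(self, grid16):
        vol = SignalVolume(self._volume(grid16), mask=np.zeros((4, 1, 1), bool))
        with pytest.raises(ValueError, match="empty mask"):
            fit_volume(vol, grid16)

    def test_rerun_same_seed_bit_identical(self, grid16, rng):
        data = self._volume(grid16)
        data += rng.normal(0, 1e-3, data.shape)
        data /= data[..., [grid16.reference_index]]
        vol = SignalVolume(data)
        cfg = FitConfig(model_ids=(1, 2), seed=11)
        a = fit_volume(vol, grid16, cfg)
        b = fit_volume(vol, grid16, cfg)
        np.testing.assert_array_equal(a.sse_map(2), b.sse_map(2))
        for fa, fb in zip(a.fits, b.fits):
            for ra, rb in zip(fa, fb):
                np.testing.assert_array_equal(ra.params, rb.params)
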