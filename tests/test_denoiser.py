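import numpy as np
import pytest

from amri.denoiser import (
    BASELINE_LR,
    SS_LR,
    DenoiserConfig,
    build_model,
    denoise_volume,
    finetune_subject,
    ftd_term,
    mix_l,
    mix_l_ftd,
    sample_patches,
    train,
)
from amri.noise import NoiseModel, extract_native_noise
from amri.synthetic import PhantomSpec, make_phantom
from amri.volume import Volume


@pytest.fixture(scope="module")
def smoke_cfg():
    return DenoiserConfig(n_resblocks=3, filters=[16, 16, 16], epochs=2, batch=64,
                          ft_epochs=1, seed=3)


@pytest.fixture(scope="module")
def patch_pair():
    rng = np.random.default_rng(17)
    clean = rng.random((64, 64))
    noisy = np.clip(clean + rng.normal(0, 0.1, clean.shape), 0, None)
    return clean, noisy


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            DenoiserConfig(patch=60)
        with pytest.raises(ValueError):
            DenoiserConfig(alpha=1.2)
        with pytest.raises(ValueError):
            DenoiserConfig(beta=-0.1)
        with pytest.raises(ValueError):
            DenoiserConfig(kmask=128, patch=64)

    def test_table_learning_rates(self):
        assert BASELINE_LR == {"T1": 2.5e-4, "T2": 1e-4, "T2FLAIR": 1e-4,
                               "T2STAR": 2.5e-4, "DWI": 1e-4}
        assert SS_LR["T1"] == (1e-5, 1e-6)
        assert SS_LR["T2"] == (1e-5,)
        assert SS_LR["T2FLAIR"] == (1e-4,)
        assert SS_LR["DWI"] == (1e-5,)
        assert SS_LR["T2STAR"] is None
        # SS rates never exceed the corresponding baseline rate
        for c, rates in SS_LR.items():
            if rates is not None:
                assert all(r <= BASELINE_LR[c] for r in rates)


class TestLosses:
    def test_zero_at_identity(self, patch_pair):
        clean, _ = patch_pair
        assert mix_l(clean, clean) == pytest.approx(0.0, abs=1e-7)
        assert ftd_term(clean, clean) == 0.0
        cfg = DenoiserConfig()
        assert mix_l_ftd(clean, clean, cfg).total == pytest.approx(0.0, abs=1e-7)

    def test_alpha_zero_is_l1(self, patch_pair):
        clean, noisy = patch_pair
        assert mix_l(clean, noisy, alpha=0.0) == pytest.approx(
            np.abs(clean - noisy).mean(), rel=1e-6
        )

    def test_alpha_one_is_msssim_complement(self, patch_pair):
        """At alpha=1 the loss must equal 1 - MS-SSIM as computed by the
        metrics module (independent numpy code path)."""
        from amri.metrics import ms_ssim

        clean, noisy = patch_pair
        loss = mix_l(clean, noisy, alpha=1.0, scales=3, data_range=1.0)
        reference = ms_ssim(clean, noisy, data_range=1.0, scales=3)
        assert loss == pytest.approx(1.0 - reference, abs=1e-5)

    def test_default_alpha_is_084(self, patch_pair):
        clean, noisy = patch_pair
        cfg = DenoiserConfig(beta=0.0)
        expected = 0.84 * mix_l(clean, noisy, alpha=1.0) + 0.16 * mix_l(
            clean, noisy, alpha=0.0
        )
        assert mix_l_ftd(clean, noisy, cfg).total == pytest.approx(expected, rel=1e-5)

    def test_nyquist_checkerboard_escapes_mask(self):
        """A pure Nyquist-frequency difference lies outside the central
        16 x 16 k-space crop and contributes nothing."""
        base = np.full((64, 64), 0.5)
        i, j = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        checker = 0.1 * (-1.0) ** (i + j)
        assert ftd_term(base, base + checker, kmask=16) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_closed_form(self):
        """Only DC differs for a constant offset: with area-normalised
        spectra, RMS over k^2 coefficients is |c| / kmask."""
        c = 0.07
        a = np.zeros((64, 64))
        assert ftd_term(a, a + c, kmask=16) == pytest.approx(c / 16, rel=1e-9)

    def test_affine_in_beta(self, patch_pair):
        clean, noisy = patch_pair
        t0 = mix_l_ftd(clean, noisy, DenoiserConfig(beta=0.0)).total
        t1 = mix_l_ftd(clean, noisy, DenoiserConfig(beta=1.0)).total
        th = mix_l_ftd(clean, noisy, DenoiserConfig(beta=0.5)).total
        ftd = ftd_term(clean, noisy)
        assert t1 - t0 == pytest.approx(ftd, rel=1e-6)
        assert th == pytest.approx(t0 + 0.5 * ftd, rel=1e-6)

    @pytest.mark.parametrize("beta", [0.0, 0.01, 0.1, 1.0])
    def test_nonnegative_over_beta_grid(self, patch_pair, beta):
        clean, noisy = patch_pair
        assert mix_l_ftd(clean, noisy, DenoiserConfig(beta=beta)).total >= 0.0


class TestSamplePatches:
    def test_single_position_bounds(self, rng):
        sl = rng.random((64, 64))
        pn, pc = sample_patches([sl], [sl], 5, seed=0)
        for k in range(5):
            np.testing.assert_array_equal(pn[k], sl.astype(np.float32))
            np.testing.assert_array_equal(pc[k], sl.astype(np.float32))

    def test_deterministic(self, rng):
        sls = [rng.random((96, 96)) for _ in range(3)]
        a = sample_patches(sls, sls, 20, seed=4)
        b = sample_patches(sls, sls, 20, seed=4)
        np.testing.assert_array_equal(a[0], b[0])

    def test_undersized_slice_named(self, rng):
        with pytest.raises(ValueError, match="slice 0"):
            sample_patches([rng.random((32, 32))], [rng.random((32, 32))], 1, seed=0)

    def test_corner_distribution_uniform(self, rng):
        """Chi-square uniformity of sampled top-left corners at alpha=0.01."""
        from scipy import stats

        sl = rng.random((67, 67))  # 4x4 possible corners
        n = 10_000
        pn, _ = sample_patches([sl], [sl], n, seed=8)
        # recover each patch's corner by matching its first row in the slice
        counts = np.zeros((4, 4))
        candidates = {(r, c): sl[r, c : c + 64] for r in range(4) for c in range(4)}
        for k in range(n):
            for (r, c), row in candidates.items():
                if np.array_equal(pn[k, 0], row.astype(np.float32)):
                    counts[r, c] += 1
                    break
        counts = counts.ravel()
        assert counts.sum() == n
        chi2 = ((counts - n / 16) ** 2 / (n / 16)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=15)


class _IdentityStub:
    def predict_patches(self, patches):
        return np.asarray(patches)


class TestDenoiseVolume:
    def test_identity_stub_any_stride(self, t1_phantom):
        for stride in (16, 33, 64):
            out = denoise_volume(_IdentityStub(), t1_phantom, stride=stride)
            np.testing.assert_allclose(out.data, t1_phantom.data, rtol=1e-6)
        assert out.meta["denoised"] == "true"

    def test_nonoverlapping_tiling(self):
        data = np.random.default_rng(0).random((128, 128, 2)).astype(np.float32)
        v = Volume(data)
        out = denoise_volume(_IdentityStub(), v, stride=64)
        np.testing.assert_allclose(out.data, data, rtol=1e-6)

    def test_undersized_slice_rejected(self):
        v = Volume(np.zeros((32, 32, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="smaller than patch"):
            denoise_volume(_IdentityStub(), v)

    def test_invalid_stride(self, t1_phantom):
        with pytest.raises(ValueError):
            denoise_volume(_IdentityStub(), t1_phantom, stride=0)


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_sets(self):
        rng = np.random.default_rng(5)
        clean = rng.random((40, 64, 64)).astype(np.float32)
        noisy = np.clip(clean + rng.normal(0, 0.1, clean.shape), 0, None).astype(
            np.float32
        )
        return (noisy[:32], clean[:32]), (noisy[32:], clean[32:])

    def test_zero_epochs_returns_unchanged(self, tiny_sets, smoke_cfg):
        cfg = DenoiserConfig(**{**smoke_cfg.__dict__, "epochs": 0})
        model = build_model(cfg)
        before = model.state_dict()
        model, history = train(model, *tiny_sets, cfg)
        assert history == {"train": [], "val": []}
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_best_model_selection_bookkeeping(self, tiny_sets, smoke_cfg):
        model = build_model(smoke_cfg)
        model, history = train(model, *tiny_sets, smoke_cfg, lr=1e-3)
        assert len(history["val"]) == smoke_cfg.epochs
        from amri.denoiser import _eval_loss

        reloaded = _eval_loss(model, *tiny_sets[1], smoke_cfg)
        assert reloaded == pytest.approx(min(history["val"]), rel=1e-5)

    def test_beta_sweep_covers_grid(self, tiny_sets):
        from amri.denoiser import beta_sweep

        cfg = DenoiserConfig(n_resblocks=3, filters=[8, 8, 8], epochs=1, batch=16,
                             seed=2)
        out = beta_sweep(*tiny_sets, cfg, betas=(0.0, 1.0), lr=1e-4)
        assert set(out) == {0.0, 1.0}
        for _, history in out.values():
            assert len(history["val"]) == 1

    def test_finetune_lr_zero_keeps_weights(self, smoke_cfg):
        phantom = make_phantom(PhantomSpec(seed=61, background_sigma=0.06), "T1")
        block = extract_native_noise(phantom, seed=1)
        nm = NoiseModel(block=block, scale=1.0, target_snr=5.0)
        base = build_model(smoke_cfg)
        ss, _ = finetune_subject(base, phantom, nm, lr=0.0, cfg=smoke_cfg,
                                 n_patches=64)
        for k, v in ss.state_dict().items():
            np.testing.assert_array_equal(v, base.state_dict()[k])
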