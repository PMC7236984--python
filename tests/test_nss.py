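"""Unit and property tests for the NSS feature stack.

Vectorized MSCN/product/fit implementations are checked against the
loop-based oracles in ``_oracles.py`` on small images, the estimators
against known distributions, and the feature vector against its
documented layout.
"""

import numpy as np
import pytest
from scipy.stats import gennorm

from woodiqa import (
    DegenerateInputError,
    FEATURE_NAMES,
    TextureSpec,
    extract_features,
    extract_features_table,
    fit_aggd,
    fit_ggd,
    make_texture,
    mscn_transform,
    pairwise_products,
)
from woodiqa.nss import gaussian_window

from _oracles import (
    aggd_oracle,
    aggd_sample,
    ggd_oracle,
    mirror_products_oracle,
    mscn_oracle,
    products_oracle,
)


class TestMSCN:
    def test_window_sums_to_one(self):
        assert gaussian_window().sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_image_gives_zero_field(self):
        field = mscn_transform(np.full((32, 32), 77.0))
        assert np.allclose(field.mscn, 0.0)
        assert np.allclose(field.local_mean, 77.0)
        assert np.allclose(field.local_std, 0.0)

    def test_matches_loop_oracle_on_small_images(self, rng):
        for shape in [(8, 8), (12, 16), (16, 9)]:
            img = rng.uniform(0, 255, size=shape)
            field = mscn_transform(img)
            ref_mscn, ref_mu, ref_sd = mscn_oracle(img)
            np.testing.assert_allclose(field.mscn, ref_mscn, rtol=1e-9, atol=1e-12)
            np.testing.assert_allclose(field.local_mean, ref_mu, rtol=1e-9)
            np.testing.assert_allclose(field.local_std, ref_sd, rtol=1e-9, atol=1e-12)

    def test_approaches_affine_invariance_at_high_gain(self):
        # As the gain a grows, (aI+b) makes σ ≫ 1 and the +1 stabilizer
        # vanishes, so the field approaches (I − μ)/σ.
        img = make_texture(TextureSpec(width=128, height=128, seed=3))
        field = mscn_transform(img)
        limit = (img - field.local_mean) / np.where(
            field.local_std > 0, field.local_std, np.inf
        )
        errors = []
        for a in (1.0, 10.0, 100.0):
            m = mscn_transform(a * img + 5.0).mscn
            errors.append(np.abs(m - limit)[5:-5, 5:-5].mean())
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 2e-3

    def test_variance_normalisation_of_pure_noise(self, rng):
        # i.i.d. N(128, 20²): contrast normalisation brings the empirical
        # coefficient variance to the frozen Monte-Carlo value 0.719
        # (division by the locally-estimated σ̂, which is correlated with
        # the centred value, shrinks it below the naive (20/21)²).
        img = 128.0 + 20.0 * rng.standard_normal((512, 512))
        assert mscn_transform(img).mscn.var() == pytest.approx(0.719, abs=0.03)

    def test_rejects_undersized_or_bad_input(self):
        with pytest.raises(ValueError):
            mscn_transform(np.zeros((5, 40)))
        with pytest.raises(ValueError):
            mscn_transform(np.full((32, 32), np.nan))


class TestGGDFit:
    def test_gaussian_samples_recover_alpha_two(self, rng):
        params = fit_ggd(rng.standard_normal(100_000))
        assert 1.9 <= params.alpha <= 2.1
        assert 0.95 <= params.sigma2 <= 1.05

    def test_laplace_samples_recover_alpha_one(self, rng):
        params = fit_ggd(rng.laplace(scale=1.3, size=100_000))
        assert 0.95 <= params.alpha <= 1.05

    @pytest.mark.parametrize("alpha", [0.7, 1.5, 3.0])
    def test_round_trip_recovery(self, alpha, rng):
        x = gennorm.rvs(alpha, size=100_000, random_state=rng)
        fit = fit_ggd(x)
        assert fit.alpha == pytest.approx(alpha, rel=0.05)

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal(500)
        fit = fit_ggd(x)
        alpha_ref, sigma2_ref = ggd_oracle(x)
        assert fit.alpha == pytest.approx(alpha_ref, rel=1e-9)
        assert fit.sigma2 == pytest.approx(sigma2_ref, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_ggd(np.zeros(1000))
        with pytest.raises(DegenerateInputError):
            fit_ggd(np.ones(10))


class TestPairwiseProducts:
    def test_zero_field_gives_zero_products(self):
        products = pairwise_products(np.zeros((6, 6)))
        assert all(np.all(p == 0) for p in products.values())

    def test_two_by_two_by_hand(self):
        a, b, c, d = 2.0, 3.0, 5.0, 7.0
        products = pairwise_products(np.array([[a, b], [c, d]]))
        assert sorted(products["H1"].ravel()) == sorted([a * b, c * d])
        assert sorted(products["V1"].ravel()) == sorted([a * c, b * d])
        assert products["D1"].ravel().tolist() == [a * d]
        assert products["D2"].ravel().tolist() == [b * c]

    def test_matches_loop_oracle(self, rng):
        m = rng.standard_normal((9, 13))
        products = pairwise_products(m)
        ref = products_oracle(m)
        for key in ("H1", "V1", "D1", "D2"):
            np.testing.assert_allclose(products[key], ref[key], rtol=1e-9, atol=0)

    def test_mirror_orientations_carry_same_multisets(self, rng):
        # The value multisets of the four computed orientations equal
        # those of their mirrors, which is why only four are kept.
        for seed in range(20):
            img = make_texture(TextureSpec(width=48, height=48, seed=seed))
            m = mscn_transform(img).mscn
            fwd = pairwise_products(m)
            bwd = mirror_products_oracle(m)
            for a, b in [("H1", "H2"), ("V1", "V2"), ("D1", "D3"), ("D2", "D4")]:
                np.testing.assert_allclose(
                    np.sort(fwd[a].ravel()), np.sort(bwd[b].ravel()), rtol=0, atol=0
                )

    def test_undersized_field_rejected(self):
        with pytest.raises(ValueError):
            pairwise_products(np.zeros((1, 5)))


class TestAGGDFit:
    def test_symmetric_samples_give_balanced_scales_and_zero_eta(self, rng):
        half = rng.standard_normal(50_000)
        half = half[half != 0]
        x = np.concatenate([half, -half])
        fit = fit_aggd(x)
        assert fit.sigma_l2 == pytest.approx(fit.sigma_r2, rel=1e-9)
        assert fit.eta == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_recovery(self, rng):
        x = aggd_sample(nu=1.0, sigma_l=1.0, sigma_r=2.0, n=100_000, rng=rng)
        fit = fit_aggd(x)
        assert fit.nu == pytest.approx(1.0, rel=0.10)
        assert fit.sigma_l2 / fit.sigma_r2 == pytest.approx(0.25, rel=0.10)
        assert fit.eta > 0

    def test_eta_flips_sign_under_mirroring(self, rng):
        x = rng.gamma(2.0, size=5_000)  # all-positive, right-heavy
        fit_pos = fit_aggd(x)
        fit_neg = fit_aggd(-x)
        assert fit_pos.eta > 0 > fit_neg.eta
        assert fit_pos.eta == pytest.approx(-fit_neg.eta, rel=1e-9)
        assert fit_pos.nu == pytest.approx(fit_neg.nu, rel=1e-9)
        assert fit_pos.sigma_l2 == pytest.approx(fit_neg.sigma_r2, rel=1e-9)

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal(400) * np.where(rng.random(400) < 0.3, 0.5, 1.5)
        fit = fit_aggd(x)
        nu_ref, eta_ref, sl2_ref, sr2_ref = aggd_oracle(x)
        assert fit.nu == pytest.approx(nu_ref, rel=1e-9)
        assert fit.eta == pytest.approx(eta_ref, rel=1e-9)
        assert fit.sigma_l2 == pytest.approx(sl2_ref, rel=1e-9)
        assert fit.sigma_r2 == pytest.approx(sr2_ref, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_aggd(np.zeros(500))


class TestFeatureVector:
    def test_length_and_layout(self, small_texture):
        vec = extract_features(small_texture)
        assert vec.shape == (36,)
        assert len(FEATURE_NAMES) == 36
        # per scale: 2 GGD + 16 AGGD parameters
        for scale in (1, 2):
            block = [n for n in FEATURE_NAMES if n.startswith(f"s{scale}_")]
            assert len(block) == 18
            assert len([n for n in block if "ggd" not in n]) == 16
        assert FEATURE_NAMES[0] == "s1_ggd_alpha"
        assert FEATURE_NAMES[18] == "s2_ggd_alpha"

    def test_deterministic(self, small_texture):
        np.testing.assert_array_equal(
            extract_features(small_texture), extract_features(small_texture)
        )

    def test_texture_tails_heavier_than_noise(self, rng):
        texture = make_texture(TextureSpec(width=256, height=256, seed=1))
        noise = np.clip(128 + 20 * rng.standard_normal((256, 256)), 0, 255)
        alpha_texture = extract_features(texture)[0]
        alpha_noise = extract_features(noise)[0]
        assert alpha_texture < 2.0 < alpha_noise

    def test_table_columns(self, small_texture):
        table = extract_features_table({"a": small_texture, "b": small_texture})
        assert list(table.columns) == ["image_id"] + [f"f{i}" for i in range(1, 37)]
        assert len(table) == 2

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((10, 10)))


def test_distortion_separates_ggd_shape():
    """The MSCN GGD shape separates the distortion classes: white noise
    pushes α up towards the Gaussian/platykurtic regime on every
    fixture, while blur nudges it down; the class means keep a stable
    mb < reference < gwn ordering over 20 seeded textures."""
    from woodiqa import add_gaussian_noise, add_motion_blur

    alpha = lambda im: fit_ggd(mscn_transform(im).mscn).alpha  # noqa: E731
    rows = []
    for seed in range(20):
        img = make_texture(TextureSpec(width=128, height=128, seed=seed))
        a_ref = alpha(img)
        a_gwn = np.mean(
            [alpha(add_gaussian_noise(img, s, seed=seed * 100 + int(s))) for s in (10, 20, 30, 40, 50)]
        )
        a_mb = np.mean([alpha(add_motion_blur(img, s)) for s in (2, 4, 6, 8, 10)])
        assert a_gwn > a_ref  # noise Gaussianizes every fixture
        rows.append((a_ref, a_gwn, a_mb))
    mean_ref, mean_gwn, mean_mb = np.asarray(rows).mean(axis=0)
    assert mean_mb < mean_ref < mean_gwn
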