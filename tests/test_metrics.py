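"""Metric formula correctness: worked examples, axioms, oracles, limits."""

import numpy as np
import pytest
import skimage.color as skc

import oracles
from chromadiff import (
    DimensionMismatchError,
    GRAPHIC_ARTS,
    METRIC_NAMES,
    MetricParams,
    ParameterError,
    TEXTILES,
    cie00,
    cie76_lab,
    cie76_luv,
    cie94,
    cmc,
    compute_metric,
    delta_e_rgb,
    lab_to_lch,
    srgb_to_lab,
    srgb_to_luv,
)
from chromadiff.perturb import PerturbationSpec, reduce_channel


def _px(r, g, b):
    return np.array([[[r, g, b]]], dtype=np.uint8)


def _random_lab(rng, n):
    L = rng.uniform(0, 100, size=n)
    a = rng.uniform(-90, 90, size=n)
    b = rng.uniform(-90, 90, size=n)
    return np.stack([L, a, b], axis=-1)


class TestEuclideanRgb:
    def test_single_channel_step(self):
        assert delta_e_rgb(_px(10, 0, 0), _px(0, 0, 0))[0, 0] == pytest.approx(10.0)

    def test_maximal_corner_distance(self):
        d = delta_e_rgb(_px(255, 255, 255), _px(0, 0, 0))[0, 0]
        assert d == pytest.approx(255.0 * np.sqrt(3.0))

    def test_dimension_mismatch_raises(self, rng):
        a = rng.integers(0, 256, (4, 4, 3), dtype=np.uint8)
        b = rng.integers(0, 256, (4, 5, 3), dtype=np.uint8)
        with pytest.raises(DimensionMismatchError):
            delta_e_rgb(a, b)


class TestCie76:
    def test_pure_lightness_step(self):
        assert cie76_lab(np.array([50.0, 0, 0]), np.array([60.0, 0, 0])) == pytest.approx(10.0)
        assert cie76_luv(np.array([50.0, 0, 0]), np.array([60.0, 0, 0])) == pytest.approx(10.0)

    def test_white_vs_black_is_100(self):
        d = cie76_lab(srgb_to_lab(_px(255, 255, 255)), srgb_to_lab(_px(0, 0, 0)))
        assert d[0, 0] == pytest.approx(100.0, abs=1e-3)

    def test_luv_golden_fixture(self):
        # sRGB (255,0,0) vs (250,0,0), frozen from the scalar oracle chain.
        d = cie76_luv(srgb_to_luv(_px(255, 0, 0)), srgb_to_luv(_px(250, 0, 0)))
        assert d[0, 0] == pytest.approx(3.618680935037071, abs=1e-9)

    def test_cross_check_skimage_cie76(self, rng):
        lab1, lab2 = _random_lab(rng, 200), _random_lab(rng, 200)
        assert np.allclose(cie76_lab(lab1, lab2), skc.deltaE_cie76(lab1, lab2), atol=1e-10)


class TestCie94:
    def test_reduces_to_cie76_when_k1_k2_zero(self, rng):
        lab1, lab2 = _random_lab(rng, 500), _random_lab(rng, 500)
        p = MetricParams(k_1=0.0, k_2=0.0)
        assert np.allclose(cie94(lab1, lab2, p), cie76_lab(lab1, lab2), atol=1e-9)

    def test_golden_fixture_graphic_arts(self):
        # Frozen from the step-by-step scalar oracle.
        d = cie94(
            np.array([50.0, 2.6772, -79.7751]), np.array([50.0, 0.0, -82.7485]), GRAPHIC_ARTS
        )
        assert d == pytest.approx(1.373455869896799, abs=1e-9)

    def test_matches_scalar_oracle_on_random_pairs(self, rng):
        lab1, lab2 = _random_lab(rng, 300), _random_lab(rng, 300)
        got = cie94(lab1, lab2, TEXTILES)
        for i in range(300):
            exp = oracles.cie94_scalar(
                lab1[i], lab2[i], kL=2.0, k1=0.048, k2=0.014
            )
            assert got[i] == pytest.approx(exp, abs=1e-10)

    def test_symmetrized_variant_is_symmetric(self, rng):
        lab1, lab2 = _random_lab(rng, 200), _random_lab(rng, 200)
        p = MetricParams(cie94_symmetric=True)
        assert np.allclose(cie94(lab1, lab2, p), cie94(lab2, lab1, p), atol=1e-9)

    def test_nonpositive_params_rejected(self):
        with pytest.raises(ParameterError):
            MetricParams(k_L=0.0)
        with pytest.raises(ParameterError):
            MetricParams(k_1=-0.1)


# The canonical CIEDE2000 test-vector suite (34 Lab pairs with published
# reference differences), independently re-verified against a scalar
# implementation and skimage before freezing.
CIEDE2000_VECTORS = [
    ((50.0000, 2.6772, -79.7751), (50.0000, 0.0000, -82.7485), 2.0425),
    ((50.0000, 3.1571, -77.2803), (50.0000, 0.0000, -82.7485), 2.8615),
    ((50.0000, 2.8361, -74.0200), (50.0000, 0.0000, -82.7485), 3.4412),
    ((50.0000, -1.3802, -84.2814), (50.0000, 0.0000, -82.7485), 1.0000),
    ((50.0000, -1.1848, -84.8006), (50.0000, 0.0000, -82.7485), 1.0000),
    ((50.0000, -0.9009, -85.5211), (50.0000, 0.0000, -82.7485), 1.0000),
    ((50.0000, 0.0000, 0.0000), (50.0000, -1.0000, 2.0000), 2.3669),
    ((50.0000, -1.0000, 2.0000), (50.0000, 0.0000, 0.0000), 2.3669),
    ((50.0000, 2.4900, -0.0010), (50.0000, -2.4900, 0.0009), 7.1792),
    ((50.0000, 2.4900, -0.0010), (50.0000, -2.4900, 0.0010), 7.1792),
    ((50.0000, 2.4900, -0.0010), (50.0000, -2.4900, 0.0011), 7.2195),
    ((50.0000, 2.4900, -0.0010), (50.0000, -2.4900, 0.0012), 7.2195),
    ((50.0000, -0.0010, 2.4900), (50.0000, 0.0009, -2.4900), 4.8045),
    ((50.0000, -0.0010, 2.4900), (50.0000, 0.0010, -2.4900), 4.8045),
    ((50.0000, -0.0010, 2.4900), (50.0000, 0.0011, -2.4900), 4.7461),
    ((50.0000, 2.5000, 0.0000), (50.0000, 0.0000, -2.5000), 4.3065),
    ((50.0000, 2.5000, 0.0000), (73.0000, 25.0000, -18.0000), 27.1492),
    ((50.0000, 2.5000, 0.0000), (61.0000, -5.0000, 29.0000), 22.8977),
    ((50.0000, 2.5000, 0.0000), (56.0000, -27.0000, -3.0000), 31.9030),
    ((50.0000, 2.5000, 0.0000), (58.0000, 24.0000, 15.0000), 19.4535),
    ((50.0000, 2.5000, 0.0000), (50.0000, 3.1736, 0.5854), 1.0000),
    ((50.0000, 2.5000, 0.0000), (50.0000, 3.2972, 0.0000), 1.0000),
    ((50.0000, 2.5000, 0.0000), (50.0000, 1.8634, 0.5757), 1.0000),
    ((50.0000, 2.5000, 0.0000), (50.0000, 3.2592, 0.3350), 1.0000),
    ((60.2574, -34.0099, 36.2677), (60.4626, -34.1751, 39.4387), 1.2644),
    ((63.0109, -31.0961, -5.8663), (62.8187, -29.7946, -4.0864), 1.2630),
    ((61.2901, 3.7196, -5.3901), (61.4292, 2.2480, -4.9620), 1.8731),
    ((35.0831, -44.1164, 3.7933), (35.0232, -40.0716, 1.5901), 1.8645),
    ((22.7233, 20.0904, -46.6940), (23.0331, 14.9730, -42.5619), 2.0373),
    ((36.4612, 47.8580, 18.3852), (36.2715, 50.5065, 21.2231), 1.4146),
    ((90.8027, -2.0831, 1.4410), (91.1528, -1.6435, 0.0447), 1.4441),
    ((90.9257, -0.5406, -0.9208), (88.6381, -0.8985, -0.7239), 1.5381),
    ((6.7747, -0.2908, -2.4247), (5.8714, -0.0985, -2.2286), 0.6377),
    ((2.0776, 0.0795, -1.1350), (0.9033, -0.0636, -0.5514), 0.9082),
]


class TestCiede2000:
    @pytest.mark.parametrize("lab1,lab2,expected", CIEDE2000_VECTORS)
    def test_canonical_vectors(self, lab1, lab2, expected):
        assert cie00(np.array(lab1), np.array(lab2)) == pytest.approx(expected, abs=1e-4)

    def test_matches_scalar_oracle_on_random_pairs(self, rng):
        lab1, lab2 = _random_lab(rng, 500), _random_lab(rng, 500)
        got = cie00(lab1, lab2)
        for i in range(500):
            assert got[i] == pytest.approx(oracles.ciede2000_scalar(lab1[i], lab2[i]), abs=1e-10)

    def test_cross_check_skimage(self, rng):
        lab1, lab2 = _random_lab(rng, 500), _random_lab(rng, 500)
        assert np.allclose(cie00(lab1, lab2), skc.deltaE_ciede2000(lab1, lab2), atol=1e-8)

    def test_achromatic_pair_reduces_to_weighted_lightness(self):
        L1, L2 = 30.0, 70.0
        Lb = 0.5 * (L1 + L2)
        SL = 1 + 0.015 * (Lb - 50) ** 2 / np.sqrt(20 + (Lb - 50) ** 2)
        d = cie00(np.array([L1, 0.0, 0.0]), np.array([L2, 0.0, 0.0]))
        assert d == pytest.approx(abs(L2 - L1) / SL, abs=1e-12)


class TestCmc:
    def test_golden_fixture(self):
        # LCh of the blue CIEDE2000 pair 1, frozen from the scalar oracle.
        lch1 = lab_to_lch(np.array([50.0, 2.6772, -79.7751]))
        lch2 = lab_to_lch(np.array([50.0, 0.0, -82.7485]))
        assert cmc(lch1, lch2) == pytest.approx(1.7387361057261745, abs=1e-9)

    def test_achromatic_reference_sets_F_zero(self):
        # With C1 = 0: F = 0 so S_H = S_C; dH^2 vanishes too (chord through 0).
        lch1 = np.array([40.0, 0.0, 0.0])
        lch2 = np.array([45.0, 3.0, 120.0])
        SL = 0.040975 * 40 / (1 + 0.01765 * 40)
        SC = 0.638  # S_C at C1 = 0
        expected = np.sqrt((5.0 / (2 * SL)) ** 2 + (3.0 / SC) ** 2)
        assert cmc(lch1, lch2) == pytest.approx(expected, abs=1e-12)

    def test_low_lightness_branch(self):
        lch1 = np.array([10.0, 20.0, 100.0])
        lch2 = np.array([12.0, 20.0, 100.0])
        # L1 < 16 -> S_L = 0.511, only the lightness term survives.
        assert cmc(lch1, lch2) == pytest.approx(2.0 / (2 * 0.511), abs=1e-12)

    def test_matches_scalar_oracle_on_random_pairs(self, rng):
        lab1, lab2 = _random_lab(rng, 300), _random_lab(rng, 300)
        lch1, lch2 = lab_to_lch(lab1), lab_to_lch(lab2)
        got = cmc(lch1, lch2, MetricParams(l=1.0, c=1.0))
        for i in range(300):
            assert got[i] == pytest.approx(
                oracles.cmc_scalar(lch1[i], lch2[i], l=1.0, c=1.0), abs=1e-10
            )

    def test_cross_check_skimage(self, rng):
        lab1, lab2 = _random_lab(rng, 300), _random_lab(rng, 300)
        got = cmc(lab_to_lch(lab1), lab_to_lch(lab2), MetricParams(l=2.0, c=1.0))
        assert np.allclose(got, skc.deltaE_cmc(lab1, lab2, kL=2, kC=1), atol=1e-8)


class TestAxiomsAndDispatch:
    @pytest.mark.parametrize("name", METRIC_NAMES)
    def test_identity_of_indiscernibles_and_nonnegativity(self, name, rng):
        # 1000 random pixel pairs as two 1000 x 1 images.
        a = rng.integers(0, 256, size=(1000, 1, 3), dtype=np.uint8)
        b = rng.integers(0, 256, size=(1000, 1, 3), dtype=np.uint8)
        d_ab = compute_metric(name, a, b)
        assert (d_ab >= 0).all() and np.isfinite(d_ab).all()
        assert np.allclose(compute_metric(name, a, a), 0.0, atol=1e-12)

    @pytest.mark.parametrize("name", ["euclidean", "cie76lab", "cie76luv", "cie00"])
    def test_symmetric_metrics(self, name, rng):
        a = rng.integers(0, 256, size=(1000, 1, 3), dtype=np.uint8)
        b = rng.integers(0, 256, size=(1000, 1, 3), dtype=np.uint8)
        assert np.allclose(
            compute_metric(name, a, b), compute_metric(name, b, a), atol=1e-9
        )

    @pytest.mark.parametrize("name", ["cie94", "cmc"])
    def test_reference_anchored_metrics_are_asymmetric(self, name, rng):
        # Their weighting terms anchor on the first argument: swapping the
        # arguments changes the value on generic chromatic pairs.
        a = rng.integers(0, 256, size=(1000, 1, 3), dtype=np.uint8)
        b = rng.integers(0, 256, size=(1000, 1, 3), dtype=np.uint8)
        fwd = compute_metric(name, a, b)
        rev = compute_metric(name, b, a)
        assert np.abs(fwd - rev).max() > 1e-3

    def test_uniform_single_channel_offset(self):
        base = np.full((8, 9, 3), 100, dtype=np.uint8)
        shifted = base.copy()
        shifted[..., 1] += 5
        assert np.allclose(compute_metric("euclidean", base, shifted), 5.0)

    def test_unknown_metric_name(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        with pytest.raises(ParameterError, match="euclidean"):
            compute_metric("nope", img, img)

    @pytest.mark.parametrize("name", METRIC_NAMES)
    def test_pixelwise_block_diagonal(self, name, rng):
        # Concatenating image pairs concatenates their error matrices.
        a1 = rng.integers(0, 256, size=(6, 5, 3), dtype=np.uint8)
        b1 = rng.integers(0, 256, size=(6, 5, 3), dtype=np.uint8)
        a2 = rng.integers(0, 256, size=(6, 5, 3), dtype=np.uint8)
        b2 = rng.integers(0, 256, size=(6, 5, 3), dtype=np.uint8)
        joint = compute_metric(
            name, np.concatenate([a1, a2]), np.concatenate([b1, b2])
        )
        separate = np.concatenate(
            [compute_metric(name, a1, b1), compute_metric(name, a2, b2)]
        )
        assert np.allclose(joint, separate, atol=1e-12)

    def test_mean_euclidean_error_increases_with_fraction(self, rng):
        base = rng.integers(60, 256, size=(32, 32, 3), dtype=np.uint8)
        means = [
            compute_metric(
                "euclidean", base, reduce_channel(base, PerturbationSpec("R", f))
            ).mean()
            for f in (0.02, 0.05, 0.10)
        ]
        assert means[0] < means[1] < means[2]
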