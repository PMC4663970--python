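import numpy as np
import pytest

from emdkit import (
    EstimatorModel,
    FrontEnd,
    QuadrantWeights,
    apply_front_end,
    classes_to_quadrants,
    converging_3pt,
    correlation_classes,
    evaluate_model,
    hrc,
    kurtosis,
    poly_exponents,
    poly_features,
    predictor_matrix,
    quadrant_signals,
    weighted_quadrant,
)
from emdkit.models import CLASS_NAMES

# receptor-order reversal (1,2,3) -> (3,2,1) as a channel permutation
MIRROR_PERM = [4, 5, 2, 3, 0, 1]


class TestHRC:
    def test_mirror_antisymmetry(self, random_banks):
        assert np.allclose(hrc(random_banks[:, MIRROR_PERM], pair=(2, 3)), -hrc(random_banks))

    def test_static_scene_silences_output(self, kernels):
        # post-transient constant V: g-channels vanish, so the product is 0
        F = np.array([0.7, 0.0, 0.7, 0.0, 0.7, 0.0])
        assert hrc(F) == pytest.approx(0.0, abs=1e-15)

    def test_nonadjacent_pair_needs_flag(self, random_banks):
        with pytest.raises(ValueError):
            hrc(random_banks, pair=(1, 3))
        out = hrc(random_banks, pair=(1, 3), allow_nonadjacent=True)
        assert out.shape == (1000,)


class TestConverging3pt:
    def test_hand_arithmetic(self):
        F = np.array([2.0, 0.0, 1.0, 3.0, 0.0, 0.0])  # f1=2, g1=0, f2=1, g2=3
        assert converging_3pt(F, "squared") == pytest.approx(12.0)  # 2^2*3 - 1^2*0

    @pytest.mark.parametrize("variant", ["squared", "two-site"])
    def test_mirror_antisymmetry(self, random_banks, variant):
        fwd = converging_3pt(random_banks, variant)
        rev = converging_3pt(random_banks[:, MIRROR_PERM], variant, pair=(2, 3))
        assert np.allclose(rev, -fwd)

    @pytest.mark.parametrize("variant", ["squared", "two-site"])
    def test_odd_order_parity(self, random_banks, variant):
        """Order-3 correlators negate under global contrast inversion."""
        assert np.allclose(
            converging_3pt(-random_banks, variant), -converging_3pt(random_banks, variant)
        )

    def test_unknown_variant(self, random_banks):
        with pytest.raises(ValueError):
            converging_3pt(random_banks, "diagonal")


class TestQuadrants:
    def test_sum_reproduces_hrc(self, random_banks):
        Q = quadrant_signals(random_banks)
        assert np.allclose(Q.sum(axis=-1), hrc(random_banks), atol=1e-12)

    def test_each_quadrant_mirror_antisymmetric(self, random_banks):
        Q = quadrant_signals(random_banks)
        Qm = quadrant_signals(random_banks[:, MIRROR_PERM], pair=(2, 3))
        assert np.allclose(Qm, -Q)

    def test_all_positive_bank_fills_only_pp(self, rng):
        F = np.abs(rng.standard_normal((50, 6)))
        Q = quadrant_signals(F)
        assert np.allclose(Q[:, 1:], 0.0)
        assert np.allclose(Q[:, 0], hrc(F))

    def test_equal_weights_reproduce_hrc(self, random_banks):
        out = weighted_quadrant(random_banks, QuadrantWeights(1, 1, 1, 1))
        assert np.allclose(out, hrc(random_banks), atol=1e-12)

    def test_zero_weights(self, random_banks):
        assert np.allclose(weighted_quadrant(random_banks, np.zeros(4)), 0.0)

    def test_single_quadrant_on_positive_bank(self, rng):
        F = np.abs(rng.standard_normal((50, 6)))
        out = weighted_quadrant(F, np.array([1.0, 0.0, 0.0, 0.0]))
        assert np.allclose(out, hrc(F))


class TestCorrelationClasses:
    def test_even2_is_quarter_hrc(self, random_banks):
        C = correlation_classes(quadrant_signals(random_banks))
        assert np.allclose(C[:, CLASS_NAMES.index("even2")], hrc(random_banks) / 4.0)

    def test_roundtrip_bijection(self, random_banks):
        Q = quadrant_signals(random_banks)
        assert np.allclose(classes_to_quadrants(correlation_classes(Q)), Q, atol=1e-12)

    def test_parity_under_contrast_inversion(self, random_banks):
        """Inversion swaps (++)<->(--) and (+-)<->(-+): even-class values are
        invariant, odd-class values negate -- that is what the order of a
        correlation class means."""
        C = correlation_classes(quadrant_signals(random_banks))
        Ci = correlation_classes(quadrant_signals(-random_banks))
        even = [CLASS_NAMES.index(n) for n in ("even2", "even_gt2")]
        odd = [CLASS_NAMES.index(n) for n in ("odd", "odd_star")]
        assert np.allclose(Ci[:, even], C[:, even], atol=1e-12)
        assert np.allclose(Ci[:, odd], -C[:, odd], atol=1e-12)


class TestPolyFeatures:
    @pytest.mark.parametrize("arity,count", [(2, 14), (4, 69), (6, 209)])
    def test_predictor_counts(self, arity, count):
        assert len(poly_exponents(arity)) == count
        F = np.random.default_rng(0).standard_normal((5, 6))
        assert poly_features(F, arity).shape == (5, count)

    def test_bivariate_features_are_antisymmetrized(self, random_banks):
        feats = poly_features(random_banks, 2)
        feats_m = poly_features(random_banks[:, MIRROR_PERM], 2, pair=(2, 3))
        assert np.allclose(feats_m, -feats)

    def test_exponent_order_is_lexicographic(self):
        exps = poly_exponents(2)
        assert exps == sorted(exps)
        assert exps[0] == (0, 1)

    def test_hrc_special_case_arity2(self, random_banks):
        w = np.zeros(14)
        w[poly_exponents(2).index((1, 1))] = 1.0
        assert np.allclose(poly_features(random_banks, 2) @ w, hrc(random_banks))

    def test_hrc_special_case_arity4(self, random_banks):
        exps = poly_exponents(4)
        w = np.zeros(69)
        w[exps.index((1, 0, 0, 1))] = 1.0  # f1 * g2
        w[exps.index((0, 1, 1, 0))] = -1.0  # -g1 * f2
        assert np.allclose(poly_features(random_banks, 4) @ w, hrc(random_banks))

    def test_two_hrc_average_special_case_arity6(self, random_banks):
        exps = poly_exponents(6)
        w = np.zeros(209)
        w[exps.index((1, 0, 0, 1, 0, 0))] = 1.0
        w[exps.index((0, 1, 1, 0, 0, 0))] = -1.0
        w[exps.index((0, 0, 1, 0, 0, 1))] = 1.0
        w[exps.index((0, 0, 0, 1, 1, 0))] = -1.0
        expect = hrc(random_banks, (1, 2)) + hrc(random_banks, (2, 3))
        assert np.allclose(poly_features(random_banks, 6) @ w, expect)

    def test_arity_channel_mismatch(self, rng):
        with pytest.raises(ValueError):
            poly_features(rng.standard_normal((5, 4)), 6)
        with pytest.raises(ValueError):
            poly_features(rng.standard_normal((5, 6)), 3)


@pytest.fixture(scope="module")
def pool():
    return np.random.default_rng(8).lognormal(size=1_000_000)


class TestFrontEnd:
    def test_equalize_kurtosis(self, pool):
        assert kurtosis(FrontEnd("equalize").transform(pool)) == pytest.approx(1.8, abs=0.01)

    def test_median_binarize_kurtosis_exact(self, pool):
        out = FrontEnd("binarize", thresholds=(50.0,)).transform(pool)
        assert set(np.unique(out)) == {-1.0, 1.0}
        assert kurtosis(out) == pytest.approx(1.0, abs=1e-9)

    def test_gaussianize_kurtosis(self, pool):
        assert kurtosis(FrontEnd("gaussianize").transform(pool)) == pytest.approx(3.0, abs=0.05)

    def test_equalize_spans_unit_interval(self, rng):
        out = FrontEnd("equalize").transform(rng.standard_normal(1000))
        assert out.min() == pytest.approx(-1.0)
        assert out.max() == pytest.approx(1.0)

    def test_quartile_binarize_maps_outer_to_minus_one(self, rng):
        x = rng.standard_normal(100_000)
        out = FrontEnd("binarize", thresholds=(25.0, 75.0)).transform(x)
        lo, hi = np.percentile(x, [25, 75])
        assert np.all(out[(x < lo) | (x > hi)] == -1.0)
        assert np.all(out[(x > lo) & (x < hi)] == 1.0)

    def test_ties_share_rank(self):
        out = FrontEnd("equalize").transform(np.array([1.0, 2.0, 2.0, 3.0]))
        assert out[1] == out[2]

    def test_fit_apply_monotone_interpolation(self, rng):
        fe = FrontEnd("gaussianize").fit(rng.standard_normal(10_000))
        fresh = np.sort(rng.standard_normal(100))
        mapped = fe.apply(fresh)
        assert np.all(np.diff(mapped) >= 0)

    def test_pooled_transform_on_ensemble(self, small_ensemble):
        trans = apply_front_end(small_ensemble, FrontEnd("equalize"))
        assert trans.V.shape == small_ensemble.V.shape
        assert kurtosis(trans.pooled_values()) == pytest.approx(1.8, abs=0.01)

    def test_empty_pool_and_bad_kind(self):
        with pytest.raises(ValueError):
            FrontEnd("equalize").transform(np.array([]))
        with pytest.raises(ValueError):
            FrontEnd("sigmoid")


class TestEstimatorModel:
    def test_hrc_adapter_identity(self, random_banks):
        model = EstimatorModel("hrc", weights=np.array([1.0]))
        assert np.allclose(evaluate_model(model, random_banks), hrc(random_banks))

    def test_unset_weights_rejected(self, random_banks):
        with pytest.raises(ValueError):
            EstimatorModel("quadrant").evaluate(random_banks)

    def test_weight_count_checked(self, random_banks):
        with pytest.raises(ValueError):
            EstimatorModel("quadrant", weights=np.ones(3)).evaluate(random_banks)

    def test_json_roundtrip_exact(self, tmp_path, rng, random_banks):
        w = rng.standard_normal(69)
        model = EstimatorModel("poly4", weights=w, scale=0.123456789)
        model.save(tmp_path / "m.json")
        back = EstimatorModel.load(tmp_path / "m.json")
        assert back.architecture == "poly4"
        assert np.array_equal(back.weights, w)
        assert back.scale == model.scale
        assert np.array_equal(back.evaluate(random_banks), model.evaluate(random_banks))

    def test_unknown_architecture(self, random_banks):
        with pytest.raises(ValueError):
            predictor_matrix("fourier", random_banks)
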