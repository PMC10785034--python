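import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aqhia import satellite

from conftest import surface


def pixel(**kw):
    base = dict(
        lat=30.0,
        lon=-100.0,
        vcd=1e15,
        amf_orig=1.0,
        scattering_weights=np.ones(4),
        apriori=np.array([4e14, 3e14, 2e14, 1e14]),
        tropopause_layer=3,
        qa=0.9,
        cloud_fraction=0.1,
        sza=30.0,
    )
    base.update(kw)
    return satellite.RetrievalPixel(**base)


class TestFilterPixels:
    def test_vacuous_thresholds_keep_everything(self):
        pixels = [pixel(qa=0.1, cloud_fraction=0.9, sza=85.0), pixel()]
        assert len(satellite.filter_pixels(pixels, 0.0, 1.0, 90.0)) == 2

    def test_hand_counted_fixture(self):
        pixels = [pixel(qa=q) for q in (0.5, 0.6, 0.7)] + [pixel(qa=0.9) for _ in range(7)]
        kept = satellite.filter_pixels(pixels, qa_min=0.75, cf_max=0.3, sza_max=70.0)
        assert len(kept) == 7

    def test_impossible_qa_keeps_nothing(self):
        assert satellite.filter_pixels([pixel(), pixel()], qa_min=1.01) == []


class TestModelColumn:
    def test_equal_layers(self):
        assert satellite.model_column(np.full(3, 1e15), 2) == pytest.approx(3e15)

    def test_surface_layer_only(self):
        assert satellite.model_column(np.array([5e14, 9e14]), 0) == pytest.approx(5e14)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        prof = rng.uniform(1e13, 1e15, size=12)
        trop = 8
        want = 0.0
        for layer in range(trop + 1):
            want += prof[layer]
        assert satellite.model_column(prof, trop) == pytest.approx(want, rel=1e-15)

    def test_out_of_range_tropopause(self):
        with pytest.raises(ValueError, match="out of range"):
            satellite.model_column(np.ones(3), 3)


class TestRecomputeAmf:
    def test_unit_scattering_weights(self):
        p = pixel(scattering_weights=np.ones(4), amf_orig=1.3)
        model = np.array([5e14, 2e14, 1e14, 5e13])
        assert satellite.model_amf(p.scattering_weights, model, 3) == pytest.approx(1.0)
        assert satellite.recompute_amf(p, model) == pytest.approx(p.vcd * 1.3)

    def test_shape_invariance_model_proportional_to_apriori(self):
        sw = np.array([0.4, 0.7, 1.0, 1.3])
        ap = np.array([4e14, 3e14, 2e14, 1e14])
        amf0 = float(np.dot(sw, ap) / ap.sum())
        p = pixel(scattering_weights=sw, apriori=ap, amf_orig=amf0, vcd=2.2e15)
        assert satellite.recompute_amf(p, 3.7 * ap) == pytest.approx(2.2e15, rel=1e-12)

    def test_two_layer_hand_arithmetic(self):
        sw = np.array([0.5, 1.5])
        model = np.array([3e15, 1e15])
        p = pixel(scattering_weights=sw, apriori=np.array([1e15, 1e15]), tropopause_layer=1, vcd=1e15, amf_orig=1.0)
        amf = satellite.model_amf(sw, model, 1)
        assert amf == pytest.approx(0.75)
        assert satellite.recompute_amf(p, model) == pytest.approx(1e15 / 0.75, rel=1e-12)

    def test_slant_column_preserved(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(3, 12)
            sw = rng.uniform(0.1, 2.0, n)
            ap = rng.uniform(1e13, 1e15, n)
            trop = int(rng.integers(1, n))
            amf0 = float(np.dot(sw[: trop + 1], ap[: trop + 1]) / ap[: trop + 1].sum())
            p = pixel(scattering_weights=sw, apriori=ap, tropopause_layer=trop, amf_orig=amf0, vcd=float(rng.uniform(1e14, 5e15)))
            model = rng.uniform(1e13, 1e15, n)
            adj = satellite.recompute_amf(p, model)
            amf_m = satellite.model_amf(sw, model, trop)
            assert adj * amf_m == pytest.approx(p.vcd * p.amf_orig, rel=1e-12)

    def test_zero_model_column_rejected(self):
        with pytest.raises(ValueError, match="zero tropospheric column"):
            satellite.recompute_amf(pixel(), np.zeros(4))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            satellite.model_amf(np.array([-0.1, 1.0]), np.ones(2), 1)


class TestClassifySourceRegion:
    def test_dominant_mobile_is_urban(self):
        labels = satellite.classify_source_region({"mobile": np.array([[0.7]]), "point": np.array([[0.1]]), "og": np.array([[0.1]])})
        assert labels[0, 0] == "urban"

    def test_no_dominant_sector_is_other(self):
        labels = satellite.classify_source_region({"mobile": np.array([[0.4]]), "point": np.array([[0.4]]), "og": np.array([[0.1]])})
        assert labels[0, 0] == "other"

    def test_threshold_inclusive(self):
        labels = satellite.classify_source_region({"mobile": np.array([[0.2]]), "point": np.array([[0.6]]), "og": np.array([[0.2]])})
        assert labels[0, 0] == "point"

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            satellite.classify_source_region({"mobile": np.array([[1.2]])})
        with pytest.raises(ValueError, match="sum"):
            satellite.classify_source_region({"mobile": np.array([[0.6]]), "point": np.array([[0.6]])})

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0.51, 0.95))
    def test_raising_threshold_never_creates_labels(self, a, b, thr):
        total = a + b
        if total > 1:
            a, b = a / total, b / total
        fr = {"mobile": np.array([[a]]), "point": np.array([[b]]), "og": np.array([[max(0.0, 1 - a - b) * 0.5]])}
        lo = satellite.classify_source_region(fr, threshold=thr)
        hi = satellite.classify_source_region(fr, threshold=min(0.99, thr + 0.2))
        if lo[0, 0] == "other":
            assert hi[0, 0] == "other"
        # uniqueness: threshold > 0.5 admits at most one qualifying sector
        assert isinstance(lo[0, 0], str)


class TestRegionalChange:
    def test_identical_periods(self):
        cols = surface([[1e15, 2e15]])
        labels = np.array([["urban", "urban"]], dtype=object)
        assert satellite.regional_change(cols, cols, labels, "urban") == 0.0

    def test_uniform_halving(self):
        y1 = surface([[2e15, 4e15]])
        labels = np.array([["urban", "urban"]], dtype=object)
        assert satellite.regional_change(y1, y1 * 0.5, labels, "urban") == pytest.approx(-0.5)

    def test_three_cell_hand_case(self):
        y1 = surface([[10.0, 20.0, 99.0]])
        y2 = surface([[12.0, 24.0, 1.0]])
        labels = np.array([["urban", "urban", "other"]], dtype=object)
        assert satellite.regional_change(y1, y2, labels, "urban") == pytest.approx(36.0 / 30.0 - 1.0)

    def test_unknown_region_rejected(self):
        cols = surface([[1.0]])
        with pytest.raises(ValueError, match="no cells"):
            satellite.regional_change(cols, cols, np.array([["urban"]], dtype=object), "point")


class TestOdrFit:
    def test_perfect_line_slope_two(self):
        x = np.linspace(0, 10, 25)
        fit = satellite.odr_fit(x, 2 * x)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.slope_ci95[0] == pytest.approx(fit.slope_ci95[1])

    def test_identity_line(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        fit = satellite.odr_fit(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigenvector_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            x = rng.normal(0, rng.uniform(0.5, 3), n)
            y = rng.uniform(0.5, 3) * x + rng.normal(0, 1, n)
            fit = satellite.odr_fit(x, y)
            cov = np.cov(np.vstack([x, y]), bias=True)
            evals, evecs = np.linalg.eigh(cov)
            major = evecs[:, np.argmax(evals)]
            assert fit.slope == pytest.approx(major[1] / major[0], rel=1e-8)

    def test_symmetry_reciprocal_slopes(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 2, 80)
        y = 1.7 * x + rng.normal(0, 0.8, 80)
        assert satellite.odr_fit(x, y).slope == pytest.approx(1.0 / satellite.odr_fit(y, x).slope, rel=1e-8)

    def test_cross_check_against_odrpack(self):
        # independent iterative solver agrees with the closed form
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DeprecationWarning)
            import scipy.odr as sodr
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1.5, 60)
        y = 2.2 * x + 0.5 + rng.normal(0, 0.7, 60)
        fit = satellite.odr_fit(x, y)
        data = sodr.Data(x, y)
        model = sodr.Model(lambda b, xx: b[0] * xx + b[1])
        out = sodr.ODR(data, model, beta0=np.polyfit(x, y, 1), sstol=1e-13, partol=1e-13, maxit=200).run()
        assert fit.slope == pytest.approx(out.beta[0], rel=1e-5)
        assert fit.intercept == pytest.approx(out.beta[1], rel=1e-4, abs=1e-4)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            satellite.odr_fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="identical"):
            satellite.odr_fit(np.ones(5), np.ones(5))


class TestPixelCsvRoundTrip:
    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        pixels = [
            pixel(
                lat=float(rng.uniform(25, 45)),
                vcd=float(rng.uniform(1e14, 5e15)),
                scattering_weights=rng.uniform(0.1, 2, 4),
                apriori=rng.uniform(1e13, 1e15, 4),
            )
            for _ in range(5)
        ]
        frame = satellite.pixels_to_frame(pixels)
        back = satellite.frame_to_pixels(frame)
        for a, b in zip(pixels, back):
            assert a.vcd == b.vcd and a.lat == b.lat
            np.testing.assert_array_equal(a.scattering_weights, b.scattering_weights)
            np.testing.assert_array_equal(a.apriori, b.apriori)
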