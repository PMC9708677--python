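"""Perfusion volumetrics, lesion growth, overestimation, cube root."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ghostcore as g


def _maps(rcbf, tmax, spacing=(1.0, 1.0, 1.0)):
    brain = np.ones(np.shape(rcbf), dtype=bool)
    return g.PerfusionMaps(rcbf, tmax, brain, spacing)


class TestVolumeML:
    def test_unit_conversion(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        assert g.volume_ml(mask, (1, 1, 1)) == pytest.approx(1.0)

    def test_empty_mask(self):
        assert g.volume_ml(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1)) == 0.0

    def test_anisotropic_spacing(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        assert g.volume_ml(mask, (1, 2, 5)) == pytest.approx(0.01)

    def test_phantom_core_matches_truth(self, clean_phantom):
        maps = clean_phantom.perfusion
        assert g.compute_pcore(maps) == pytest.approx(clean_phantom.truth["pcore_ml"])


class TestThresholds:
    def test_uniform_normal_rcbf_gives_zero_core(self):
        maps = _maps(np.full((5, 5, 5), 50.0), np.zeros((5, 5, 5)))
        assert g.compute_pcore(maps) == 0.0

    def test_rcbf_boundary_inclusive(self):
        rcbf = np.full((5, 5, 5), 50.0)
        rcbf[0, 0, 0] = 20.0  # exactly at the threshold: counted
        maps = _maps(rcbf, np.zeros((5, 5, 5)))
        assert g.compute_pcore(maps) == pytest.approx(0.001)

    def test_tmax_boundary_inclusive(self):
        tmax = np.zeros((5, 5, 5))
        tmax[0, 0, 0] = 6.0
        maps = _maps(np.full((5, 5, 5), 100.0), tmax)
        hypo, _ = g.compute_penumbra(maps, 0.0)
        assert hypo == pytest.approx(0.001)

    def test_tmax_uniform_short_gives_zero_hypoperfusion(self):
        maps = _maps(np.full((5, 5, 5), 100.0), np.full((5, 5, 5), 3.0))
        hypo, pen = g.compute_penumbra(maps, 0.0)
        assert hypo == 0.0 and pen == 0.0

    def test_invalid_rcbf_threshold(self):
        maps = _maps(np.full((3, 3, 3), 50.0), np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            g.compute_pcore(maps, rcbf_threshold=0.0)

    def test_raising_rcbf_threshold_monotone(self, clean_phantom):
        maps = clean_phantom.perfusion
        vols = [g.compute_pcore(maps, t) for t in (5, 20, 50, 100)]
        assert vols == sorted(vols)

    def test_negative_penumbra_floored_with_warning(self, caplog):
        maps = _maps(np.full((5, 5, 5), 100.0), np.full((5, 5, 5), 3.0))
        with caplog.at_level("WARNING"):
            hypo, pen = g.compute_penumbra(maps, pcore_ml=10.0)
        assert pen == 0.0
        assert "floored" in caplog.text

    def test_penumbra_subtraction(self):
        tmax = np.zeros((20, 20, 20))
        tmax[:10] = 8.0  # 4 mL hypoperfused
        maps = _maps(np.full((20, 20, 20), 100.0), tmax)
        hypo, pen = g.compute_penumbra(maps, pcore_ml=1.5)
        assert hypo == pytest.approx(4.0)
        assert pen == pytest.approx(2.5)


class TestGrowthAndClassification:
    @pytest.mark.parametrize("fiv,pcore,expected", [
        (50.0, 30.0, 20.0),
        (10.0, 34.2, -24.2),
        (0.0, 0.0, 0.0),
    ])
    def test_lesion_growth(self, fiv, pcore, expected):
        assert g.lesion_growth(fiv, pcore) == pytest.approx(expected)

    def test_negative_volumes_rejected(self):
        with pytest.raises(ValueError):
            g.lesion_growth(-1.0, 5.0)

    @pytest.mark.parametrize("growth,expected", [
        (-10.0, False),   # boundary: strictly more negative than -10 required
        (-10.1, True),
        (18.4, False),
        (-300.0, True),
    ])
    def test_overestimation_strict_cutoff(self, growth, expected):
        assert g.classify_overestimation(growth) is expected

    def test_nonfinite_growth_rejected(self):
        with pytest.raises(ValueError):
            g.classify_overestimation(float("nan"))

    @given(st.floats(0, 300), st.floats(0, 300), st.floats(0, 300))
    def test_classification_monotone_in_pcore(self, fiv, p1, p2):
        """Larger predicted cores can only move toward overestimation."""
        lo, hi = sorted((p1, p2))
        if g.classify_overestimation(g.lesion_growth(fiv, lo)):
            assert g.classify_overestimation(g.lesion_growth(fiv, hi))


class TestCubicRoot:
    @pytest.mark.parametrize("x,expected", [(8.0, 2.0), (-8.0, -2.0), (0.0, 0.0)])
    def test_signed_values(self, x, expected):
        assert g.cubic_root_transform(x) == pytest.approx(expected)

    @given(st.floats(-1e6, 1e6))
    def test_odd_function(self, x):
        assert g.cubic_root_transform(-x) == pytest.approx(
            -g.cubic_root_transform(x), abs=1e-12)

    def test_vectorised(self):
        out = g.cubic_root_transform(np.array([27.0, -27.0]))
        np.testing.assert_allclose(out, [3.0, -3.0])


def test_end_to_end_phantom_volumeset_matches_truth(clean_phantom):
    b = clean_phantom
    maps = b.perfusion
    pcore = g.compute_pcore(maps)
    hypo, pen = g.compute_penumbra(maps, pcore)
    fiv = g.volume_ml(b.fiv_mask, b.admission_ct.spacing_mm)
    growth = g.lesion_growth(fiv, pcore)
    assert pcore == pytest.approx(b.truth["pcore_ml"])
    assert hypo == pytest.approx(b.truth["hypoperfusion_ml"])
    assert pen == pytest.approx(b.truth["penumbra_ml"])
    assert growth == pytest.approx(b.truth["lesion_growth_ml"])
    assert g.classify_overestimation(growth) == b.truth["overestimated"]
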