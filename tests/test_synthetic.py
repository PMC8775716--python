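import numpy as np
import pytest
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from fibrilmorph.errors import InvalidSpecError, PlacementError
from fibrilmorph.kinetics import boltzmann
from fibrilmorph.synthetic import (
    AfmBackground,
    AfmSimSpec,
    KineticSimSpec,
    ThermogramSimSpec,
    gen_afm_image,
    gen_kinetic_trace,
    gen_thermogram,
)
from tests.conftest import small_afm_spec


class TestKineticGenerator:
    def test_midpoint_value(self, t_grid):
        spec = KineticSimSpec(y1=0.0, y2=100.0, t_lag=64.80, t_half=80.30,
                              t_grid=np.array([0.0, 40.0, 80.30, 120.0, 200.0]))
        trace = gen_kinetic_trace(spec)
        assert trace.y[2] == pytest.approx(50.0, abs=1e-12)

    def test_plateau_asymptote(self):
        spec = KineticSimSpec(y1=0.0, y2=100.0, t_lag=10.0, t_half=20.0,
                              t_grid=np.array([0.0, 10.0, 20.0, 500.0, 1000.0]))
        trace = gen_kinetic_trace(spec)
        assert trace.y[-1] == pytest.approx(100.0, abs=1e-9)

    def test_value_at_lag_time(self):
        spec = KineticSimSpec(y1=5.0, y2=105.0, t_lag=30.0, t_half=50.0,
                              t_grid=np.array([0.0, 15.0, 30.0, 50.0, 100.0]))
        trace = gen_kinetic_trace(spec)
        expect = 5.0 + 100.0 / (1.0 + np.e**2)
        assert trace.y[2] == pytest.approx(expect, abs=1e-12)
        # ~ y1 + 0.1192 (y2 - y1)
        assert trace.y[2] == pytest.approx(5.0 + 11.92, abs=0.01)

    def test_noiseless_matches_model_everywhere(self, clean_trace):
        model = boltzmann(clean_trace.t, 0.0, 100.0, 80.3, 64.8)
        np.testing.assert_array_equal(clean_trace.y, model)

    def test_seed_reproducible(self, t_grid):
        spec = KineticSimSpec(y1=0.0, y2=1.0, t_lag=50.0, t_half=70.0,
                              t_grid=t_grid, noise_sd=0.1, seed=9)
        a, b = gen_kinetic_trace(spec), gen_kinetic_trace(spec)
        np.testing.assert_array_equal(a.y, b.y)

    def test_invalid_spec(self, t_grid):
        with pytest.raises(InvalidSpecError):
            KineticSimSpec(y1=0.0, y2=1.0, t_lag=70.0, t_half=70.0, t_grid=t_grid)


class TestThermogramGenerator:
    def test_integral_is_dh_cal(self, clean_thermogram):
        assert np.trapezoid(clean_thermogram.Cp, clean_thermogram.T) == pytest.approx(
            432.2, rel=0.01)

    def test_peak_at_td_when_enthalpies_equal(self, T_grid):
        tg = gen_thermogram(ThermogramSimSpec(
            T_d=66.0, dH_cal=400.0, dH_vH=400.0, T_grid=T_grid))
        assert abs(tg.T[np.argmax(tg.Cp)] - 66.0) <= 0.1

    def test_localized_transition(self, clean_thermogram):
        far = np.abs(clean_thermogram.T - 66.57) > 30.0
        # tails decay exponentially; ~5e-4 vs a ~50 kJ/mol/degC peak
        assert np.all(np.abs(clean_thermogram.Cp[far]) < 1e-3)

    def test_seed_reproducible(self, T_grid):
        spec = ThermogramSimSpec(T_d=66.0, dH_cal=400.0, dH_vH=450.0,
                                 T_grid=T_grid, noise_sd=0.5, seed=4)
        np.testing.assert_array_equal(gen_thermogram(spec).Cp, gen_thermogram(spec).Cp)


class TestAfmGenerator:
    def test_single_noiseless_fibril_apex(self):
        spec = small_afm_spec(populations=((3.7, 0.0, 1),))
        hmap, truth = gen_afm_image(spec)
        assert hmap.heights.max() == pytest.approx(3.7, abs=0.02)
        assert len(truth) == 1

    def test_population_means_within_2se(self):
        pops = ((2.6, 0.4, 40), (3.7, 0.8, 40), (6.1, 1.1, 40))
        spec = small_afm_spec(
            image_shape=(512, 512), populations=pops, seed=12,
            length_range=(100.0, 180.0), min_separation=20.0,
            fibril_width=(8.0, 0.0), max_tries=500,
        )
        _, truth = gen_afm_image(spec)
        heights = np.array([t["height"] for t in truth])
        labels = np.array([t["population"] for t in truth])
        for p, (mean, sd, count) in enumerate(pops):
            sample = heights[labels == p]
            assert len(sample) == count
            assert abs(sample.mean() - mean) <= 2.0 * sd / np.sqrt(count)

    def test_min_separation_respected(self, rough_afm):
        _, truth = rough_afm
        px = 4.0
        for i, a in enumerate(truth):
            for b in truth[i + 1:]:
                d, _ = cKDTree(a["path"].points).query(b["path"].points)
                assert d.min() * px >= 30.0 - 1e-6

    def test_centerline_lookup_recovers_height(self, clean_afm):
        hmap, truth = clean_afm
        for t in truth:
            pts = t["path"].points
            vals = map_coordinates(hmap.heights, [pts[:, 0], pts[:, 1]], order=1)
            # interior of the path sits at the fibril apex; bilinear lookup
            # between 4-nm pixels undershoots the crest by up to ~2%
            assert np.median(vals) == pytest.approx(t["height"], abs=0.1)

    def test_seed_reproducible(self):
        spec = small_afm_spec(seed=3, background=AfmBackground(roughness_sd=0.2))
        h1, _ = gen_afm_image(spec)
        h2, _ = gen_afm_image(spec)
        np.testing.assert_array_equal(h1.heights, h2.heights)

    def test_placement_error_names_population(self):
        # impossible request: many fibrils with huge separation
        spec = small_afm_spec(
            populations=((3.0, 0.0, 80),), min_separation=400.0, max_tries=5)
        with pytest.raises(PlacementError) as exc:
            gen_afm_image(spec)
        assert exc.value.population_index == 0

    def test_invalid_specs(self):
        with pytest.raises(InvalidSpecError):
            small_afm_spec(populations=((0.0, 0.1, 3),))
        with pytest.raises(InvalidSpecError):
            small_afm_spec(populations=((3.0, 0.1, 0),))
        with pytest.raises(InvalidSpecError):
            small_afm_spec(pixel_size=0.0)
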