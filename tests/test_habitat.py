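import math

import numpy as np
import pytest

from _oracles import brute_force_habitat
from reefhab.grids import GridSpec, Raster, aggregate_fraction, subdivide
from reefhab.habitat import (
    DEFAULT_LIMITS,
    EnvStack,
    ToleranceLimits,
    check_env_cell,
    habitat_area,
    max_reef_depth,
    predict_habitat,
)


def make_uniform_env(
    lat=(0.0, 2.0),
    lon=(0.0, 2.0),
    depth=10.0,
    par=1800.0,
    k490=0.05,
    t=25.0,
    s=35.0,
    no3=1.0,
    po4=0.1,
    omega=3.5,
):
    """Flat environment on a small three-resolution stack."""
    coarse = GridSpec(lat[0], lat[1], lon[0], lon[1], 1.0)
    mid = subdivide(coarse, 1 / 12).fine
    fine = subdivide(coarse, 1 / 120).fine
    return EnvStack(
        T=Raster.full(coarse, t),
        S=Raster.full(coarse, s),
        NO3=Raster.full(coarse, no3),
        PO4=Raster.full(coarse, po4),
        PAR=Raster.full(mid, par),
        K490=Raster.full(mid, k490),
        Z=Raster.full(fine, depth),
        omega=Raster.full(coarse, omega),
    )


class TestMaxReefDepth:
    def test_surface_irradiance_at_threshold(self):
        assert max_reef_depth(450.0, 0.05, 450.0) == 0.0

    def test_direct_evaluation(self):
        assert max_reef_depth(1800.0, 0.05, 450.0) == pytest.approx(math.log(4.0) / 0.05)
        assert max_reef_depth(1800.0, 0.05, 450.0) == pytest.approx(27.726, abs=1e-3)

    def test_subthreshold_surface_light(self):
        assert max_reef_depth(300.0, 0.05, 450.0) == 0.0

    def test_nonpositive_attenuation_rejected(self):
        with pytest.raises(ValueError):
            max_reef_depth(1800.0, 0.0, 450.0)

    def test_array_input_with_missing(self):
        z = max_reef_depth(np.array([1800.0, np.nan]), np.array([0.05, 0.05]), 450.0)
        assert z[0] > 0 and np.isnan(z[1])


class TestCheckEnvCell:
    def test_inside_envelope(self):
        assert check_env_cell(25.0, 35.0, 1.0, 0.1, 3.5, DEFAULT_LIMITS)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(T=20.0),
            dict(T=30.0),
            dict(S=28.0),
            dict(S=41.0),
            dict(NO3=5.0),
            dict(PO4=0.7),
            dict(omega=2.0),
        ],
    )
    def test_single_variable_out_of_range(self, kwargs):
        base = dict(T=25.0, S=35.0, NO3=1.0, PO4=0.1, omega=3.5)
        base.update(kwargs)
        assert not check_env_cell(
            base["T"], base["S"], base["NO3"], base["PO4"], base["omega"], DEFAULT_LIMITS
        )

    def test_bounds_are_inclusive(self):
        lim = DEFAULT_LIMITS
        assert check_env_cell(lim.t_min, 35.0, lim.no3_max, lim.po4_max, lim.omega_min, lim)

    def test_unchecked_omega_passes(self):
        assert check_env_cell(25.0, 35.0, 1.0, 0.1, None, DEFAULT_LIMITS)
        assert check_env_cell(25.0, 35.0, 1.0, 0.1, float("nan"), DEFAULT_LIMITS)

    def test_missing_climatology_fails_conservatively(self):
        assert not check_env_cell(float("nan"), 35.0, 1.0, 0.1, 3.5, DEFAULT_LIMITS)


class TestPredictHabitat:
    def test_uniform_suitable_world(self):
        env = make_uniform_env()  # Z_max = ln(4)/0.05 ≈ 27.7 m, depth 10 m
        res = predict_habitat(env, DEFAULT_LIMITS)
        assert res.fine_mask.values.all()
        assert (res.coarse_fraction.values == 1.0).all()

    def test_imin_raised_past_depth_kills_everything(self):
        env = make_uniform_env()
        # Z_max(1200) = ln(1.5)/0.05 ≈ 8.1 m < 10 m
        res = predict_habitat(env, DEFAULT_LIMITS.with_i_min(1200.0))
        assert not res.fine_mask.values.any()
        assert res.total_area_km2 == 0.0

    def test_envelope_gates_entire_block(self):
        env = make_uniform_env()
        env.PO4.values[0, 0] = 5.0  # one coarse cell fails phosphate
        res = predict_habitat(env, DEFAULT_LIMITS)
        assert not res.fine_mask.values[:120, :120].any()
        assert res.fine_mask.values[120:, :].all()

    def test_land_cells_never_suitable(self):
        env = make_uniform_env()
        env.Z.values[:60, :60] = -5.0
        res = predict_habitat(env, DEFAULT_LIMITS)
        assert not res.fine_mask.values[:60, :60].any()
        assert res.fine_mask.values[60:, 60:].all()

    def test_monotone_in_imin(self, small_world):
        env = small_world.env
        masks = [
            predict_habitat(env, DEFAULT_LIMITS.with_i_min(v)).fine_mask.values
            for v in (100.0, 300.0, 450.0, 600.0)
        ]
        for bigger, smaller in zip(masks, masks[1:]):
            assert not (smaller & ~bigger).any()  # raising I_min never adds cells

    def test_monotone_in_envelope_width(self, small_world):
        env = small_world.env
        tight = predict_habitat(env, DEFAULT_LIMITS).fine_mask.values
        wide_limits = ToleranceLimits(
            t_min=DEFAULT_LIMITS.t_min - 3,
            t_max=DEFAULT_LIMITS.t_max + 3,
            s_min=DEFAULT_LIMITS.s_min - 3,
            s_max=DEFAULT_LIMITS.s_max + 3,
            no3_max=DEFAULT_LIMITS.no3_max * 2,
            po4_max=DEFAULT_LIMITS.po4_max * 2,
            omega_min=DEFAULT_LIMITS.omega_min / 2,
            i_min=DEFAULT_LIMITS.i_min,
        )
        wide = predict_habitat(env, wide_limits).fine_mask.values
        assert not (tight & ~wide).any()

    def test_matches_brute_force_oracle(self, small_world):
        env = small_world.env
        limits = small_world.truth.limits
        res = predict_habitat(env, limits)
        expected = brute_force_habitat(env, limits)
        assert (res.fine_mask.values == expected).all()

    def test_fraction_equals_aggregate_of_mask(self, small_world):
        res = predict_habitat(small_world.env, small_world.truth.limits)
        frac = aggregate_fraction(res.fine_mask, small_world.env.coarse_spec)
        assert (res.coarse_fraction.values == frac.values).all()


class TestHabitatArea:
    def test_empty_mask(self):
        env = make_uniform_env()
        res = predict_habitat(env, DEFAULT_LIMITS.with_i_min(5000.0))
        assert habitat_area(res) == 0.0

    def test_fully_suitable_equatorial_block(self):
        env = make_uniform_env(lat=(0.0, 1.0), lon=(0.0, 1.0))
        res = predict_habitat(env, DEFAULT_LIMITS)
        assert res.fine_mask.values.all()
        assert habitat_area(res) == pytest.approx(12364.0, rel=1e-4)

    def test_additivity_over_disjoint_masks(self, small_world):
        res = predict_habitat(small_world.env, small_world.truth.limits)
        full = habitat_area(res)
        left = res.fine_mask.values.copy()
        left[:, left.shape[1] // 2 :] = False
        right = res.fine_mask.values.copy()
        right[:, : right.shape[1] // 2] = False
        spec = res.fine_mask.spec
        areas = spec.row_areas_km2()
        a = float((left.sum(axis=1) * areas).sum())
        b = float((right.sum(axis=1) * areas).sum())
        assert a + b == pytest.approx(full, rel=1e-12)

    def test_route_consistency_mask_vs_fraction(self, default_world):
        res = predict_habitat(default_world.env, default_world.truth.limits)
        coarse = default_world.env.coarse_spec
        via_fraction = float(
            (res.coarse_fraction.values * coarse.row_areas_km2()[:, None]).sum()
        )
        assert abs(via_fraction - res.total_area_km2) / res.total_area_km2 < 1e-3
        assert habitat_area(res) == pytest.approx(res.total_area_km2, rel=1e-12)
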