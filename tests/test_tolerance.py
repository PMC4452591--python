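import numpy as np
import pandas as pd
import pytest

from reefhab.grids import GridSpec, Raster, subdivide
from reefhab.habitat import DEFAULT_LIMITS
from reefhab.tolerance import derive_limits, rasterize_reefs
from reefhab.habitat import check_env_grid
from test_habitat import make_uniform_env


def fine_spec(lat=(0.0, 2.0), lon=(0.0, 2.0)):
    return GridSpec(lat[0], lat[1], lon[0], lon[1], 1.0 / 120.0)


class TestRasterizeReefs:
    def test_single_interior_vertex(self):
        spec = fine_spec()
        obs = rasterize_reefs([[(0.5041, 0.5041)]], spec)
        assert obs.fine_mask.values.sum() == 1
        assert obs.n_vertices_used == 1

    def test_four_vertices_in_four_adjacent_cells(self):
        spec = fine_spec()
        res = 1.0 / 120.0
        # one vertex in each cell of a 2x2 block of 30" cells
        base = 1.0  # shared corner of the four cells
        poly = [
            (base - res / 2, base - res / 2),
            (base - res / 2, base + res / 2),
            (base + res / 2, base - res / 2),
            (base + res / 2, base + res / 2),
        ]
        obs = rasterize_reefs([poly], spec)
        assert obs.fine_mask.values.sum() == 4

    def test_vertex_on_shared_edge_marks_one_cell(self):
        spec = fine_spec()
        obs = rasterize_reefs([[(1.0, 1.0)]], spec)  # exactly on a cell corner
        assert obs.fine_mask.values.sum() == 1

    def test_empty_polygon_list(self):
        obs = rasterize_reefs([], fine_spec())
        assert not obs.fine_mask.values.any()

    def test_out_of_domain_vertices_dropped(self):
        obs = rasterize_reefs([[(10.0, 10.0), (0.5, 0.5)]], fine_spec())
        assert obs.n_vertices_dropped == 1
        assert obs.fine_mask.values.sum() == 1

    def test_dataframe_input_matches_vertex_lists(self):
        spec = fine_spec()
        df = pd.DataFrame({"polygon_id": [0, 0], "lat": [0.3, 0.7], "lon": [0.3, 0.7]})
        a = rasterize_reefs(df, spec)
        b = rasterize_reefs([[(0.3, 0.3), (0.7, 0.7)]], spec)
        assert (a.fine_mask.values == b.fine_mask.values).all()

    def test_coarse_fraction_is_aggregate(self):
        spec = fine_spec()
        obs = rasterize_reefs([[(0.5, 0.5), (1.5, 1.5)]], spec)
        assert obs.coarse_fraction.values[0, 0] == pytest.approx(1.0 / 14400.0)
        assert obs.presence.sum() == 2


class TestDeriveLimits:
    def test_single_reef_cell_collapses_to_its_values(self):
        env = make_uniform_env(t=26.0, s=34.0, no3=0.8, po4=0.2, omega=3.1)
        obs = rasterize_reefs([[(0.5, 0.5)]], env.fine_spec)
        d = derive_limits(obs, env)
        assert (d.t_min, d.t_max) == (26.0, 26.0)
        assert (d.s_min, d.s_max) == (34.0, 34.0)
        assert d.no3_max == 0.8
        assert d.po4_max == 0.2
        assert d.omega_min == 3.1

    def test_recovers_planted_extremes_exactly(self, clean_world, default_world):
        for world in (clean_world, default_world):
            obs = rasterize_reefs(world.reefs, world.env.fine_spec, world.env.coarse_spec)
            d = derive_limits(obs, world.env)
            p = world.truth.limits
            assert (d.t_min, d.t_max) == (p.t_min, p.t_max)
            assert (d.s_min, d.s_max) == (p.s_min, p.s_max)
            assert d.no3_max == p.no3_max
            assert d.po4_max == p.po4_max
            assert d.omega_min == p.omega_min

    def test_monthly_range_from_known_series(self):
        env = make_uniform_env(t=25.0)
        obs = rasterize_reefs([[(0.5, 0.5)]], env.fine_spec)
        monthly = {"T": [Raster.full(env.coarse_spec, v) for v in (20.0, 25.0, 30.0)]}
        annual = derive_limits(obs, env)
        m = derive_limits(obs, env, time_scale="monthly", monthly=monthly)
        assert (annual.t_min, annual.t_max) == (25.0, 25.0)
        assert (m.t_min, m.t_max) == (20.0, 30.0)

    def test_scale_nesting_annual_within_monthly_within_weekly(self, default_world):
        w = default_world
        obs = rasterize_reefs(w.reefs, w.env.fine_spec, w.env.coarse_spec)
        annual = derive_limits(obs, w.env)
        monthly = derive_limits(obs, w.env, time_scale="monthly", monthly=w.monthly)
        weekly = derive_limits(
            obs, w.env, time_scale="weekly", monthly=w.monthly, weekly_t=w.weekly_t
        )
        assert weekly.t_min <= monthly.t_min <= annual.t_min
        assert annual.t_max <= monthly.t_max <= weekly.t_max
        assert annual.s_max <= monthly.s_max
        assert annual.no3_max <= monthly.no3_max

    def test_adding_reef_cells_never_narrows(self, default_world):
        w = default_world
        obs_all = rasterize_reefs(w.reefs, w.env.fine_spec, w.env.coarse_spec)
        half = w.reefs[w.reefs.polygon_id < w.reefs.polygon_id.median()]
        obs_half = rasterize_reefs(half, w.env.fine_spec, w.env.coarse_spec)
        d_half = derive_limits(obs_half, w.env)
        d_all = derive_limits(obs_all, w.env)
        assert d_all.t_min <= d_half.t_min and d_all.t_max >= d_half.t_max
        assert d_all.s_min <= d_half.s_min and d_all.s_max >= d_half.s_max
        assert d_all.no3_max >= d_half.no3_max
        assert d_all.po4_max >= d_half.po4_max

    def test_derived_limits_leave_no_env_attributable_fn(self, default_world):
        """Reef cells all pass the envelope under their own derived limits."""
        w = default_world
        obs = rasterize_reefs(w.reefs, w.env.fine_spec, w.env.coarse_spec)
        d = derive_limits(obs, w.env)
        ok, _ = check_env_grid(w.env, d.to_tolerance_limits(i_min=450.0))
        reef = obs.coarse_fraction.values > 0
        assert ok[reef].all()

    def test_empty_reef_mask_rejected(self):
        env = make_uniform_env()
        obs = rasterize_reefs([], env.fine_spec)
        with pytest.raises(ValueError):
            derive_limits(obs, env)

    def test_all_missing_variable_named_in_error(self):
        env = make_uniform_env()
        env.NO3.values[:] = np.nan
        env.NO3.missing[:] = True
        obs = rasterize_reefs([[(0.5, 0.5)]], env.fine_spec)
        with pytest.raises(ValueError, match="NO3"):
            derive_limits(obs, env)

    def test_quantile_trim_narrows_or_keeps(self, default_world):
        w = default_world
        obs = rasterize_reefs(w.reefs, w.env.fine_spec, w.env.coarse_spec)
        raw = derive_limits(obs, w.env)
        trimmed = derive_limits(obs, w.env, quantile_trim=0.05)
        assert trimmed.t_min >= raw.t_min and trimmed.t_max <= raw.t_max
        assert trimmed.no3_max <= raw.no3_max
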