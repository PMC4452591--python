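import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reefhab.grids import (
    EARTH_RADIUS_KM,
    GridSpec,
    Raster,
    aggregate_fraction,
    cell_area,
    lookup_coarse,
    nesting,
    subdivide,
)


class TestCellArea:
    def test_equatorial_one_degree_cell(self):
        # independent evaluation of the spherical zone formula
        expected = EARTH_RADIUS_KM**2 * math.radians(1.0) * math.sin(math.radians(1.0))
        assert cell_area(0.0, 1.0, 1.0) == pytest.approx(expected, rel=1e-14)
        assert cell_area(0.0, 1.0, 1.0) == pytest.approx(12364.0, rel=1e-4)

    def test_zero_longitude_width(self):
        assert cell_area(10.0, 11.0, 0.0) == 0.0

    def test_hemispheric_symmetry(self):
        assert cell_area(10.0, 11.0, 1.0) == pytest.approx(cell_area(-11.0, -10.0, 1.0), rel=1e-14)

    def test_reversed_latitudes_rejected(self):
        with pytest.raises(ValueError):
            cell_area(11.0, 10.0, 1.0)

    @pytest.mark.parametrize(
        "spec",
        [
            GridSpec(-40, 40, -180, 180, 1.0),
            GridSpec(-5, 5, 0, 20, 1.0 / 12.0),
            GridSpec(0, 2, 0, 3, 1.0 / 120.0),
        ],
    )
    def test_band_area_closure(self, spec):
        total = spec.row_areas_km2().sum() * spec.n_lon
        assert abs(total - spec.band_area_km2()) / spec.band_area_km2() < 1e-12


class TestGridSpec:
    def test_non_multiple_extent_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0, 1.5, 0, 2, 1.0)

    def test_latitude_band_enforced(self):
        with pytest.raises(ValueError):
            GridSpec(0, 45, 0, 10, 1.0)

    def test_half_open_cells(self):
        spec = GridSpec(0, 2, 0, 2, 1.0)
        assert spec.locate(0.0, 0.0) == (0, 0)
        assert spec.locate(1.0, 1.0) == (1, 1)  # shared edge -> owner cell
        assert spec.locate(2.0, 1.0) is None  # outer edge belongs to no cell
        assert spec.locate(1.999999, 0.5) == (1, 0)


class TestSubdivide:
    def test_five_minute_to_thirty_second(self):
        nest = subdivide(GridSpec(0, 1, 0, 1, 1 / 12), 1 / 120)
        assert nest.factor == 10
        assert nest.cells_per_block == 100

    def test_one_degree_to_thirty_second(self):
        nest = subdivide(GridSpec(0, 2, 0, 2, 1.0), 1 / 120)
        assert nest.cells_per_block == 14400

    def test_identity(self):
        nest = subdivide(GridSpec(0, 2, 0, 2, 1.0), 1.0)
        assert nest.factor == 1
        assert nest.block(1, 1) == (slice(1, 2), slice(1, 2))

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            subdivide(GridSpec(0, 1, 0, 1, 1 / 12), 1 / 18)

    def test_blocks_partition_domain(self):
        nest = subdivide(GridSpec(0, 2, 0, 3, 1.0), 1 / 12)
        seen = np.zeros(nest.fine.shape, dtype=int)
        for i in range(nest.coarse.n_lat):
            for j in range(nest.coarse.n_lon):
                seen[nest.block(i, j)] += 1
        assert (seen == 1).all()


class TestAggregateFraction:
    def setup_method(self):
        self.coarse = GridSpec(0, 2, 0, 2, 1.0)
        self.fine = subdivide(self.coarse, 1 / 12).fine

    def test_all_true_gives_one(self):
        frac = aggregate_fraction(Raster(self.fine, np.ones(self.fine.shape, bool)), self.coarse)
        assert (frac.values == 1.0).all()

    def test_all_false_gives_zero(self):
        frac = aggregate_fraction(Raster(self.fine, np.zeros(self.fine.shape, bool)), self.coarse)
        assert (frac.values == 0.0).all()

    def test_quarter_filled_block(self):
        coarse = GridSpec(0, 1, 0, 1, 1.0)
        fine = subdivide(coarse, 1 / 120).fine
        mask = np.zeros(fine.shape, dtype=bool)
        mask.ravel()[:3600] = True  # 3600 of 14400
        frac = aggregate_fraction(Raster(fine, mask), coarse)
        assert frac.values[0, 0] == 0.25

    def test_non_nesting_rejected(self):
        other = GridSpec(0, 2, 0, 3, 1.0)
        with pytest.raises(ValueError):
            aggregate_fraction(Raster(self.fine, np.zeros(self.fine.shape, bool)), other)

    @given(data=st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_added_true_cells(self, data):
        coarse = GridSpec(0, 2, 0, 2, 1.0)
        fine = subdivide(coarse, 1 / 4).fine
        bits = data.draw(st.lists(st.booleans(), min_size=64, max_size=64))
        a = np.array(bits, dtype=bool).reshape(fine.shape)
        extra = data.draw(st.lists(st.booleans(), min_size=64, max_size=64))
        b = a | np.array(extra, dtype=bool).reshape(fine.shape)
        fa = aggregate_fraction(Raster(fine, a), coarse).values
        fb = aggregate_fraction(Raster(fine, b), coarse).values
        assert (fb >= fa).all()


class TestLookupCoarse:
    def _fixture(self, missing_center=False, all_missing=False):
        coarse = GridSpec(0, 3, 0, 3, 1.0)
        vals = np.arange(9, dtype=float).reshape(3, 3)
        missing = np.zeros((3, 3), dtype=bool)
        if missing_center:
            missing[1, 1] = True
        if all_missing:
            missing[:] = True
        fine = subdivide(coarse, 1 / 12).fine
        return fine, Raster(coarse, vals, missing)

    def test_valid_enclosing_cell(self):
        fine, coarse = self._fixture()
        assert lookup_coarse(fine, 18, 18, coarse) == 4.0  # center of cell (1,1)

    def test_missing_cell_uses_nearest_neighbor(self):
        fine, coarse = self._fixture(missing_center=True)
        # fine cell near the bottom edge of the missing center cell: the
        # southern neighbor (value 1) is nearest
        assert lookup_coarse(fine, 12, 18, coarse) == 1.0
        # near the top edge the northern neighbor (value 7) wins
        assert lookup_coarse(fine, 23, 18, coarse) == 7.0

    def test_all_missing_neighborhood_reports_missing(self):
        fine, coarse = self._fixture(all_missing=True)
        assert math.isnan(lookup_coarse(fine, 18, 18, coarse))

    def test_outside_domain_rejected(self):
        fine = subdivide(GridSpec(0, 3, 0, 3, 1.0), 1 / 12).fine
        small = Raster(GridSpec(0, 1, 0, 1, 1.0), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            lookup_coarse(fine, 30, 30, small)


def test_nesting_requires_shared_extent():
    a = GridSpec(0, 2, 0, 2, 1.0)
    b = GridSpec(0, 2, 1, 3, 1 / 12)
    with pytest.raises(ValueError):
        nesting(a, b)
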