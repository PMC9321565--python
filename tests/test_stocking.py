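"""Carrying capacity, animal units, stocking density and its classification."""

import numpy as np
import pytest

from grasscap.grids import AnnualStack, Grid
from grasscap.stocking import (
    CLASS_LOW,
    CLASS_MEDIUM,
    CLASS_NODATA,
    CLASS_OVERSTOCKED,
    AnimalUnitParams,
    RSDClassScheme,
    animal_units,
    carrying_capacity,
    classify_rsd,
    mask_livestock_grazing,
    median_rsd_window,
    overstocked_year_fraction,
    rsd,
    rsd_min_cc,
)

from conftest import make_grid


def _cc_stack(values_per_year, au_like):
    years = list(range(2001, 2001 + len(values_per_year)))
    layers = [au_like.like(np.full(au_like.shape, v, dtype=float)) for v in values_per_year]
    return AnnualStack(years=years, layers=layers)


class TestCarryingCapacity:
    def test_productive_grassland_exceeds_100_au_per_km2(self):
        cc = carrying_capacity(make_grid([[500.0]]))
        # 500 g m⁻² → 5·10⁵ kg km⁻²; / (455 · 0.02 · 365)
        assert cc.values[0, 0] == pytest.approx(500_000 / 3321.5, rel=1e-12)
        assert cc.values[0, 0] == pytest.approx(150.53, abs=0.01)
        assert cc.values[0, 0] > 100

    def test_zero_agb_and_modest_agb(self):
        cc = carrying_capacity(make_grid([[0.0, 100.0]]))
        assert cc.values[0, 0] == 0.0
        assert cc.values[0, 1] == pytest.approx(30.106, abs=1e-3)

    def test_linear_in_agb_and_intake(self):
        agb = make_grid(np.random.default_rng(0).uniform(0, 600, (4, 4)))
        cc1 = carrying_capacity(agb).values
        cc2 = carrying_capacity(agb.like(agb.values * 2)).values
        assert np.allclose(cc2, 2 * cc1)
        half = carrying_capacity(agb, AnimalUnitParams(daily_intake_fraction=0.04)).values
        assert np.allclose(half, cc1 / 2)

    def test_invalid_intake_rejected(self):
        with pytest.raises(ValueError, match="intake"):
            AnimalUnitParams(daily_intake_fraction=0.0)


class TestAnimalUnits:
    def test_identity_factor(self):
        au = animal_units({"cattle": make_grid([[10.0]])}, {"cattle": 1.0})
        assert au.values[0, 0] == 10.0

    def test_weighted_sum_with_sheep(self):
        au = animal_units(
            {"cattle": make_grid([[10.0]]), "sheep": make_grid([[20.0]])},
            {"cattle": 1.0, "sheep": 0.125},
        )
        assert au.values[0, 0] == pytest.approx(12.5)

    def test_zero_headcounts_and_unknown_species(self):
        zero = animal_units({"cattle": make_grid([[0.0]])})
        assert zero.values[0, 0] == 0.0
        with pytest.raises(KeyError, match="yak"):
            animal_units({"yak": make_grid([[1.0]])})


class TestRSD:
    def test_ratios_and_degenerate_cells(self):
        au = make_grid([[15.0, 10.0, 0.0, 5.0, 0.0]])
        cc = make_grid([[30.0, 10.0, 25.0, 0.0, 0.0]])
        out = rsd(au, cc).values[0]
        assert out[0] == 0.5
        assert out[1] == 1.0
        assert out[2] == 0.0
        assert np.isposinf(out[3])  # stock on zero forage
        assert np.isnan(out[4])  # nothing to judge

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        au = make_grid(rng.uniform(0, 50, (3, 3)))
        cc = make_grid(rng.uniform(1, 100, (3, 3)))
        r1 = rsd(au, cc).values
        r2 = rsd(au.like(au.values * 3.7), cc.like(cc.values * 3.7)).values
        assert np.allclose(r1, r2)


class TestClassification:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.10, CLASS_LOW),
            (0.20, CLASS_MEDIUM),   # boundary belongs to medium
            (0.65, CLASS_MEDIUM),   # boundary belongs to medium
            (0.66, CLASS_OVERSTOCKED),
            (np.inf, CLASS_OVERSTOCKED),
            (np.nan, CLASS_NODATA),
        ],
    )
    def test_class_boundaries(self, value, expected):
        out = classify_rsd(make_grid([[value]]))
        assert out.values[0, 0] == expected

    def test_partition_every_defined_cell_gets_one_label(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1.5, (10, 10))
        vals[0, 0] = np.nan
        out = classify_rsd(make_grid(vals))
        defined = np.isfinite(vals)
        assert np.all(out.values[defined] >= 0)
        assert np.all(out.values[~defined] == CLASS_NODATA)
        counts = [(out.values == c).sum() for c in (0, 1, 2)]
        assert sum(counts) == defined.sum()

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            RSDClassScheme(low_max=0.7, med_max=0.65)


class TestWindowDiagnostics:
    def test_median_window_example(self):
        au = make_grid([[10.0]])
        stack = _cc_stack([10, 20, 30, 40, 50], au)
        out = median_rsd_window(au, stack, stack.years)
        assert out.values[0, 0] == pytest.approx(10 / 30)

    def test_median_window_constant_cc_equals_single_year_rsd(self):
        au = make_grid([[7.0]])
        stack = _cc_stack([20, 20, 20], au)
        out = median_rsd_window(au, stack, stack.years)
        assert out.values[0, 0] == pytest.approx(0.35)

    def test_median_window_empty_window_rejected(self):
        au = make_grid([[1.0]])
        with pytest.raises(ValueError, match="empty"):
            median_rsd_window(au, _cc_stack([1, 2], au), [])

    def test_min_cc_rsd_example_and_dominance(self):
        au = make_grid([[8.0]])
        stack = _cc_stack([10, 40], au)
        assert rsd_min_cc(au, stack).values[0, 0] == pytest.approx(0.8)
        rng = np.random.default_rng(3)
        au2 = make_grid(rng.uniform(0, 30, (6, 6)))
        layers = [au2.like(rng.uniform(5, 80, (6, 6))) for _ in range(5)]
        stack2 = AnnualStack(years=list(range(2001, 2006)), layers=layers)
        lo = median_rsd_window(au2, stack2, stack2.years).values
        hi = rsd_min_cc(au2, stack2).values
        assert np.all(hi >= lo - 1e-12)

    def test_overstocked_year_fraction(self):
        au = make_grid([[7.0, 0.0, 100.0]])
        years = [2001, 2002, 2003]
        layers = [au.like(np.array([[v, v, v]], dtype=float)) for v in (10, 10, 100)]
        stack = AnnualStack(years=years, layers=layers)
        out = overstocked_year_fraction(au, stack).values[0]
        assert out[0] == pytest.approx(2 / 3)  # 0.7, 0.7, 0.07
        assert out[1] == 0.0
        assert out[2] == 1.0


class TestLivestockGrazingMask:
    def test_identity_all_nodata_and_count(self):
        rng = np.random.default_rng(4)
        data = make_grid(rng.uniform(0, 10, (5, 5)))
        all_true = Grid(np.ones((5, 5), dtype=int), data.transform, data.crs, nodata=-1)
        all_false = Grid(np.zeros((5, 5), dtype=int), data.transform, data.crs, nodata=-1)
        assert np.array_equal(mask_livestock_grazing(data, all_true).values, data.values)
        assert np.all(np.isnan(mask_livestock_grazing(data, all_false).values))
        some = Grid((rng.random((5, 5)) < 0.5).astype(int), data.transform, data.crs, nodata=-1)
        out = mask_livestock_grazing(data, some)
        assert np.isfinite(out.values).sum() == some.values.sum()

    def test_geometry_mismatch_rejected(self):
        data = make_grid(np.ones((4, 4)))
        mask = Grid(np.ones((5, 5), dtype=int), data.transform, data.crs, nodata=-1)
        with pytest.raises(ValueError, match="mismatch"):
            mask_livestock_grazing(data, mask)
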