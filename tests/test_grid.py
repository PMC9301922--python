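"""Grid geometry, station QC, regridding and feature assembly."""

import io

import numpy as np
import pandas as pd
import pytest

from no2map import (
    GridField,
    GridSpec,
    QCConfig,
    daily_mean_from_hourly,
    regrid_area_weighted,
    sample_grid_at_stations,
)
from no2map.grid import EmptyTableError, apply_hourly_qc, read_station_table


def _hourly_df(values, station="S1", start="2019-01-01 00:00"):
    ts = pd.date_range(start, periods=len(values), freq="h")
    return pd.DataFrame(
        {
            "station_id": station,
            "city_id": "C1",
            "lat": 30.5,
            "lon": 110.5,
            "timestamp": ts,
            "value": values,
        }
    )


class TestGridSpec:
    def test_cell_count_and_centers(self):
        spec = GridSpec(30.0, 31.0, 110.0, 112.0, 0.25)
        assert (spec.n_lat, spec.n_lon) == (4, 8)
        assert spec.lats[0] == pytest.approx(30.125)
        assert spec.lons[-1] == pytest.approx(111.875)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(31.0, 30.0, 110.0, 111.0, 0.1)
        with pytest.raises(ValueError):
            GridSpec(30.0, 31.0, 110.0, 111.0, -0.1)
        with pytest.raises(ValueError):
            GridSpec(30.0, 31.0, 110.0, 111.0, 0.3)  # not a multiple

    def test_boundary_point_goes_to_lower_left_cell(self):
        spec = GridSpec(30.0, 31.0, 110.0, 111.0, 0.5)
        i, j = spec.cell_index(30.5, 110.5)  # interior cell boundary
        assert (i, j) == (0, 0)
        i, j = spec.cell_index(30.0, 110.0)  # domain minimum edge
        assert (i, j) == (0, 0)
        i, j = spec.cell_index(31.0, 111.0)  # domain maximum edge
        assert (i, j) == (1, 1)


class TestStationQC:
    def test_negative_value_dropped_and_counted(self):
        df = _hourly_df([35.0, -1.0, 12.0])
        out, report = apply_hourly_qc(df)
        assert len(out) == 2
        assert report.n_out_of_range == 1
        assert report.n_dropped == 1

    def test_valid_record_retained_unchanged(self):
        df = _hourly_df([35.0])
        out, _ = apply_hourly_qc(df)
        assert out.loc[0, "value"] == 35.0

    def test_stuck_run_of_identical_values_dropped(self):
        # 8 identical consecutive values trip the >= 6 stuck rule; the
        # distinct values around them survive
        df = _hourly_df([10.0] + [12.0] * 8 + [14.0])
        out, report = apply_hourly_qc(df)
        assert report.n_stuck == 8
        assert sorted(out["value"]) == [10.0, 14.0]

    def test_short_run_kept(self):
        df = _hourly_df([12.0] * 5)
        out, report = apply_hourly_qc(df)
        assert len(out) == 5 and report.n_stuck == 0

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("station_id,lat,lon,timestamp,value\nS1,30,110,2019-01-01,5\n")
        with pytest.raises(ValueError, match="city_id"):
            read_station_table(p)

    def test_empty_after_qc_signalled(self):
        with pytest.raises(EmptyTableError):
            apply_hourly_qc(_hourly_df([-5.0, 600.0]))

    def test_read_station_table_roundtrip(self, tmp_path):
        df = _hourly_df(list(np.linspace(10.0, 33.0, 24)))
        p = tmp_path / "st.csv"
        df.to_csv(p, index=False)
        out, report = read_station_table(p)
        assert len(out) == 24 and report.n_dropped == 0


class TestDailyAggregation:
    def test_constant_day_mean(self):
        daily = daily_mean_from_hourly(_hourly_df([20.0] * 24))
        assert len(daily) == 1
        assert daily.loc[0, "value"] == 20.0
        assert daily.loc[0, "n_hours"] == 24

    def test_below_min_hours_absent(self):
        daily = daily_mean_from_hourly(_hourly_df([20.0] * 12), min_hours=18)
        assert daily.empty

    def test_arithmetic_mean_with_low_threshold(self):
        daily = daily_mean_from_hourly(_hourly_df([10.0, 20.0, 30.0]), min_hours=3)
        assert daily.loc[0, "value"] == pytest.approx(20.0)

    @pytest.mark.parametrize("bad", [0, 25])
    def test_min_hours_bounds(self, bad):
        with pytest.raises(ValueError):
            daily_mean_from_hourly(_hourly_df([20.0]), min_hours=bad)


def _field(spec, values, mask=None, n_days=1):
    values = np.broadcast_to(values, (n_days,) + values.shape).copy()
    if mask is not None:
        mask = np.broadcast_to(mask, values.shape).copy()
    return GridField(
        spec=spec,
        dates=pd.date_range("2019-01-01", periods=n_days),
        values=values,
        mask=mask if mask is not None else np.zeros(values.shape, bool),
    )


class TestRegrid:
    def test_uniform_field_is_conserved(self):
        src = _field(GridSpec(30, 31, 110, 111, 0.1), np.full((10, 10), 3.7))
        out = regrid_area_weighted(src, GridSpec(30, 31, 110, 111, 0.25))
        assert np.allclose(out.values, 3.7)
        assert not out.mask.any()

    def test_equal_area_aggregation_at_equator(self):
        # 2x2 cells straddling the equator have equal areas by symmetry
        src = _field(GridSpec(-1, 1, -1, 1, 1.0), np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = regrid_area_weighted(src, GridSpec(-1, 1, -1, 1, 2.0))
        assert out.values[0, 0, 0] == pytest.approx(2.5)

    def test_matches_brute_force_overlap_oracle(self, rng):
        src_spec = GridSpec(30.0, 32.5, 110.0, 112.5, 0.5)  # 5x5
        dst_spec = GridSpec(30.4, 32.2, 110.1, 111.9, 0.6)  # 3x3, offset
        vals = rng.normal(size=(5, 5))
        src = _field(src_spec, vals)
        out = regrid_area_weighted(src, dst_spec)

        # brute force: loop over all rectangle pairs, integrate overlaps
        sle, slo = src_spec.lat_edges(), src_spec.lon_edges()
        dle, dlo = dst_spec.lat_edges(), dst_spec.lon_edges()
        expect = np.zeros((3, 3))
        for di in range(3):
            for dj in range(3):
                num = den = 0.0
                for si in range(5):
                    for sj in range(5):
                        la = max(dle[di], sle[si])
                        lb = min(dle[di + 1], sle[si + 1])
                        na = max(dlo[dj], slo[sj])
                        nb = min(dlo[dj + 1], slo[sj + 1])
                        if lb > la and nb > na:
                            w = (lb - la) * (nb - na) * np.cos(np.deg2rad((la + lb) / 2))
                            num += w * vals[si, sj]
                            den += w
                expect[di, dj] = num / den
        assert np.allclose(out.values[0], expect, rtol=1e-10, atol=0)

    def test_linearity(self, rng):
        spec = GridSpec(30, 31, 110, 111, 0.1)
        dst = GridSpec(30, 31, 110, 111, 0.25)
        mask = rng.random((10, 10)) < 0.3
        x = rng.normal(size=(10, 10))
        y = rng.normal(size=(10, 10))
        fx = _field(spec, x, mask)
        fy = _field(spec, y, mask)
        fz = _field(spec, 2.0 * x - 3.0 * y, mask)
        rx, ry, rz = (regrid_area_weighted(f, dst) for f in (fx, fy, fz))
        ok = ~rz.mask
        assert np.allclose(rz.values[ok], 2.0 * rx.values[ok] - 3.0 * ry.values[ok])

    def test_fully_masked_overlap_is_masked(self):
        spec = GridSpec(30, 31, 110, 111, 0.5)
        mask = np.array([[True, True], [False, False]])
        f = _field(spec, np.ones((2, 2)), mask)
        out = regrid_area_weighted(f, spec)  # same grid
        assert out.mask[0, 0, 0] and out.mask[0, 0, 1]
        assert not out.mask[0, 1, 0]

    def test_disjoint_domains_rejected(self):
        src = _field(GridSpec(30, 31, 110, 111, 0.5), np.ones((2, 2)))
        with pytest.raises(ValueError, match="disjoint"):
            regrid_area_weighted(src, GridSpec(40, 41, 110, 111, 0.5))


class TestNetCDFRoundTrip:
    def test_values_and_mask_survive_bit_exactly(self, tmp_path, rng):
        spec = GridSpec(30, 31, 110, 111, 0.25)
        vals = rng.normal(size=(3, 4, 4))
        mask = rng.random((3, 4, 4)) < 0.2
        f = GridField(
            spec=spec,
            dates=pd.date_range("2019-06-01", periods=3),
            values=np.where(mask, np.nan, vals),
            mask=mask,
            units="1e15 mol/cm2",
            name="trop_no2",
        )
        p = tmp_path / "f.nc"
        f.to_netcdf(p)
        g = GridField.from_netcdf(p)
        assert g.name == "trop_no2" and g.units == "1e15 mol/cm2"
        assert g.dates.equals(f.dates)
        assert np.array_equal(g.mask, f.mask)
        assert np.array_equal(g.values[~mask], vals[~mask])


class TestSampleAtStations:
    def _setup(self):
        spec = GridSpec(30, 31, 110, 111, 0.5)
        vals = np.arange(4.0).reshape(1, 2, 2)
        mask = np.zeros((1, 2, 2), bool)
        mask[0, 1, 1] = True
        grid = GridField(
            spec=spec,
            dates=pd.date_range("2019-01-01", periods=1),
            values=np.where(mask, np.nan, vals),
            mask=mask,
            name="col",
        )
        return spec, grid

    def _stations(self, lat, lon):
        return pd.DataFrame(
            {
                "station_id": ["S1"],
                "city_id": ["C1"],
                "lat": [lat],
                "lon": [lon],
                "date": [pd.Timestamp("2019-01-01")],
                "value": [10.0],
            }
        )

    def test_cell_center_returns_exact_value(self):
        _, grid = self._setup()
        rows = sample_grid_at_stations({"col": grid}, self._stations(30.25, 110.75))
        assert rows.loc[0, "col"] == 1.0
        assert not rows.loc[0, "incomplete"]

    def test_boundary_station_assigned_to_lower_left_cell(self):
        _, grid = self._setup()
        rows = sample_grid_at_stations({"col": grid}, self._stations(30.5, 110.5))
        assert rows.loc[0, "col"] == 0.0

    def test_masked_predictor_flags_row(self):
        _, grid = self._setup()
        rows = sample_grid_at_stations({"col": grid}, self._stations(30.75, 110.75))
        assert rows.loc[0, "incomplete"]

    def test_station_outside_domain_excluded_with_warning(self):
        _, grid = self._setup()
        with pytest.warns(UserWarning, match="outside"):
            rows = sample_grid_at_stations({"col": grid}, self._stations(35.0, 110.5))
        assert rows.empty
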