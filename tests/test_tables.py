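"""Commissioning tables: interpolation, placeholder fill, IO round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import protonmu as pm
from protonmu.tables import (
    ExtrapolationError,
    Grid1D,
    OCRGrid,
    RSFGrid,
    SmallFieldError,
    TableFormatError,
    TableLookupError,
    resample_ocr,
)


def brute_force_bilinear(x_axis, y_axis, values, xq, yq):
    """Independent oracle: locate the cell by scanning, interpolate by the
    textbook four-corner formula."""
    i = j = None
    for k in range(len(x_axis) - 1):
        if x_axis[k] <= xq <= x_axis[k + 1]:
            i = k
            break
    for k in range(len(y_axis) - 1):
        if y_axis[k] <= yq <= y_axis[k + 1]:
            j = k
            break
    assert i is not None and j is not None
    x1, x2 = x_axis[i], x_axis[i + 1]
    y1, y2 = y_axis[j], y_axis[j + 1]
    q11, q12 = values[i, j], values[i, j + 1]
    q21, q22 = values[i + 1, j], values[i + 1, j + 1]
    return (
        q11 * (x2 - xq) * (y2 - yq)
        + q21 * (xq - x1) * (y2 - yq)
        + q12 * (x2 - xq) * (yq - y1)
        + q22 * (xq - x1) * (yq - y1)
    ) / ((x2 - x1) * (y2 - y1))


class TestROF:
    def test_published_values_exact(self, published):
        assert published.lookup_rof(13) == 1.35
        assert published.lookup_rof(20) == 1.00
        assert published.lookup_rof(1) == 1.22

    def test_missing_option(self, published):
        with pytest.raises(TableLookupError):
            published.lookup_rof(99)


class TestSOBPF:
    @pytest.fixture()
    def grid_tables(self, published):
        published = pm.CommissioningTables.from_dict(published.to_dict())
        published.sobpf[20] = Grid1D(
            np.array([2.0, 3.0, 4.0, 6.0, 10.0]),
            np.array([1.08, 1.06, 1.05, 1.03, 1.0]),
        )
        return published

    def test_node_exactness_and_normalization(self, grid_tables):
        assert grid_tables.interp_sobpf(20, 3.0) == 1.06
        assert grid_tables.interp_sobpf(20, 10.0) == 1.0

    def test_midpoint_is_arithmetic_mean(self, grid_tables):
        assert grid_tables.interp_sobpf(20, 5.0) == pytest.approx((1.05 + 1.03) / 2)

    def test_no_silent_extrapolation(self, grid_tables):
        with pytest.raises(ExtrapolationError):
            grid_tables.interp_sobpf(20, 1.0)
        with pytest.raises(ExtrapolationError):
            grid_tables.interp_sobpf(20, 12.0)


class TestRSF:
    def test_published_cells_exact(self, published):
        assert published.interp_rsf(1, 25.0, 10.0) == pytest.approx(1.0)
        assert published.interp_rsf(1, 23.8, 10.0) == pytest.approx(0.9931)
        assert published.interp_rsf(13, 30.8, 5.0) == pytest.approx(1.0010)

    def test_bilinear_midpoint(self, published):
        # midway in range between the 23.8 and 25.0 rows at M = 10
        assert published.interp_rsf(1, 24.4, 10.0) == pytest.approx(0.99655)

    def test_placeholder_corner_flags_prediction(self, published):
        val, tainted = published.interp_rsf_flagged(20, 13.5, 14.0)
        assert tainted
        val, tainted = published.interp_rsf_flagged(20, 14.5, 10.0)
        assert not tainted

    def test_outside_rectangle_raises(self, published):
        with pytest.raises(ExtrapolationError):
            published.interp_rsf(1, 20.0, 10.0)

    def test_bilinear_matches_brute_force_oracle(self, rng):
        x = np.sort(rng.uniform(0, 10, 6))
        y = np.sort(rng.uniform(0, 10, 6))
        v = rng.uniform(0.8, 1.2, (6, 6))
        grid = RSFGrid(x, y, v)
        tables = pm.CommissioningTables(psi_o=1.0, rof={1: 1.0}, rsf={1: grid})
        for _ in range(1000):
            xq = rng.uniform(x[0], x[-1])
            yq = rng.uniform(y[0], y[-1])
            assert tables.interp_rsf(1, xq, yq) == pytest.approx(
                brute_force_bilinear(x, y, v, xq, yq), abs=1e-12
            )


class TestPlaceholderFill:
    def test_complete_row_is_untouched(self):
        grid = RSFGrid(np.array([10.0, 12.0]), np.array([2.0, 4.0, 6.0]),
                       np.ones((2, 3)))
        tables = pm.CommissioningTables(psi_o=1.0, rof={1: 1.0}, rsf={1: grid})
        before = grid.values.copy()
        tables.fill_rsf_placeholders(1)
        assert np.array_equal(grid.values, before)
        assert not grid.placeholder.any()

    def test_published_row_reproduced_within_tolerance(self, published):
        # refill the extrapolated cells of the shallow-range rows from the
        # measured cells only and compare to the printed placeholders
        tables = pm.CommissioningTables.from_dict(published.to_dict())
        grid = tables.rsf[20]
        mask = grid.placeholder.copy()
        grid.values[mask] = np.nan
        grid.placeholder[:] = False
        tables.fill_rsf_placeholders(20)
        assert grid.placeholder[0, 3] and grid.placeholder[0, 4]
        assert grid.values[0, 3] == pytest.approx(0.9196, abs=0.02)
        assert grid.values[0, 4] == pytest.approx(0.9251, abs=0.02)

    def test_exact_log_law_round_trip(self):
        m = np.array([2.0, 6.0, 10.0, 13.0, 14.5, 15.5])
        c0, c1 = 0.98, -0.017
        row_r = np.array([13.0, 15.5])
        values = np.vstack([c0 + c1 * np.log(m), np.ones_like(m)])
        grid = RSFGrid(row_r, m, values.copy())
        grid.values[0, m > 13.0] = 0.0
        tables = pm.CommissioningTables(psi_o=1.0, rof={1: 1.0}, rsf={1: grid})
        tables.fill_rsf_placeholders(1)
        assert grid.values[0] == pytest.approx(c0 + c1 * np.log(m), abs=1e-9)

    def test_too_few_points_raise(self):
        grid = RSFGrid(np.array([3.0, 6.0]), np.array([2.0, 3.0, 4.0, 5.0]),
                       np.ones((2, 4)))
        tables = pm.CommissioningTables(psi_o=1.0, rof={1: 1.0}, rsf={1: grid})
        with pytest.raises(ValueError, match=">= 3"):
            tables.fill_rsf_placeholders(1)


class TestOCR:
    def test_central_axis_is_unity_and_nodes_exact(self, noise_free_tables):
        assert noise_free_tables.interp_ocr(1, 0.0, 0.0) == pytest.approx(1.0)
        grid = noise_free_tables.ocr[1]
        assert noise_free_tables.interp_ocr(1, grid.x_axis[3], grid.y_axis[5]) == (
            pytest.approx(grid.values[3, 5])
        )

    def test_mirror_asymmetry_representable(self):
        # an asymmetric lateral profile: mirror points near the edge differ by 6%
        axis = np.linspace(-10, 10, 21)
        xg, yg = np.meshgrid(axis, axis, indexing="ij")
        values = 1.0 + 0.003 * xg  # linear tilt in x
        tables = pm.CommissioningTables(
            psi_o=1.0, rof={1: 1.0}, ocr={1: OCRGrid(axis, axis, values)}
        )
        left = tables.interp_ocr(1, -10.0, 0.0)
        right = tables.interp_ocr(1, 10.0, 0.0)
        assert left == pytest.approx(0.97)
        assert right == pytest.approx(1.03)

    def test_outside_extent(self, noise_free_tables):
        with pytest.raises(ExtrapolationError):
            noise_free_tables.interp_ocr(1, 25.0, 0.0)


class TestResample:
    def test_constant_grid_stays_constant(self):
        axis = np.arange(-3.0, 3.1, 1.0)
        grid = OCRGrid(axis, axis, np.ones((len(axis), len(axis))))
        fine = resample_ocr(grid)
        assert np.allclose(fine.values, 1.0)
        assert fine.x_axis[1] - fine.x_axis[0] == pytest.approx(0.05)
        assert fine.x_axis[0] == grid.x_axis[0]
        assert fine.x_axis[-1] == pytest.approx(grid.x_axis[-1])

    def test_bilinear_field_reproduced_exactly(self):
        axis = np.arange(-2.0, 2.1, 1.0)
        xg, yg = np.meshgrid(axis, axis, indexing="ij")
        plane = 1.0 + 0.01 * xg - 0.02 * yg + 0.003 * xg * yg
        fine = resample_ocr(OCRGrid(axis, axis, plane))
        fx, fy = np.meshgrid(fine.x_axis, fine.y_axis, indexing="ij")
        expect = 1.0 + 0.01 * fx - 0.02 * fy + 0.003 * fx * fy
        assert np.allclose(fine.values, expect, atol=1e-12)

    def test_non_uniform_grid_rejected(self):
        axis = np.array([0.0, 1.0, 3.0])
        grid = OCRGrid(axis, axis, np.ones((3, 3)))
        with pytest.raises(TableFormatError):
            resample_ocr(grid)


class TestFSF:
    def test_published_cells_exact(self, published):
        assert published.interp_fsf(1, pm.FieldSize.parse("3.5d")) == 0.687
        assert published.interp_fsf(13, pm.FieldSize.parse("10x10")) == 1.000
        assert published.interp_fsf(20, pm.FieldSize.parse("5x5")) == 1.003

    def test_group_fallback_to_nearest_measured_option(self, published):
        # option 7 has no measured FSF; nearest measured large option is 6
        direct = published.interp_fsf(6, pm.FieldSize.parse("5x5"))
        assert published.interp_fsf(7, pm.FieldSize.parse("5x5")) == direct

    def test_small_field_refused_without_override(self, published):
        tiny = pm.FieldSize.parse("2d")
        with pytest.raises(SmallFieldError, match="directly"):
            published.interp_fsf(20, tiny)
        value = published.interp_fsf(20, tiny, allow_small_field=True)
        assert value > 0


class TestGACF:
    def test_unity_at_calibration_angle(self, noise_free_tables):
        assert noise_free_tables.interp_gacf("large", 0.0) == pytest.approx(1.0)

    def test_group_deviations_match_machine_behaviour(self, noise_free_tables):
        small_150 = noise_free_tables.interp_gacf("small", 150.0)
        deep_135 = noise_free_tables.interp_gacf("deep", 135.0)
        assert 1.0 - small_150 == pytest.approx(0.036, abs=0.004)
        assert 1.0 - deep_135 == pytest.approx(0.023, abs=0.004)
        # maxima are where they should be
        angles = [a % 360 for a in range(-5, 186, 5)]
        small = [1 - noise_free_tables.interp_gacf("small", a) for a in angles]
        assert angles[int(np.argmax(small))] == 150.0

    def test_interpolation_across_the_wrap(self, noise_free_tables):
        v355 = noise_free_tables.interp_gacf("small", 355.0)
        v0 = noise_free_tables.interp_gacf("small", 0.0)
        v357 = noise_free_tables.interp_gacf("small", 357.5)
        assert min(v355, v0) <= v357 <= max(v355, v0)


class TestIO:
    def test_round_trip_identity(self, published, tmp_path):
        path = tmp_path / "tables.json"
        published.write(path)
        back = pm.CommissioningTables.read(path)
        assert back.to_dict() == published.to_dict()

    def test_four_decimal_export(self, noise_free_tables, tmp_path):
        path = tmp_path / "tables4.json"
        noise_free_tables.write(path, decimals=4)
        back = pm.CommissioningTables.read(path)
        v = back.interp_rsf(1, *_mid_rsf_node(back, 1))
        assert round(v, 4) == pytest.approx(v)

    def test_missing_rof_block_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"psi_o": 1.0}')
        with pytest.raises(TableFormatError, match="rof"):
            pm.CommissioningTables.read(path)

    def test_validate_flags_perturbed_reference(self, published):
        tables = pm.CommissioningTables.from_dict(published.to_dict())
        assert tables.validate() == []
        tables.rof[20] = 1.02
        warnings = tables.validate()
        assert any("calibration option" in w for w in warnings)

    def test_validate_flags_denormalized_rsf_row(self, published):
        tables = pm.CommissioningTables.from_dict(published.to_dict())
        tables.rsf[1].values[-1, 0] = 0.99
        assert any("largest R" in w for w in tables.validate())


def _mid_rsf_node(tables, option_id):
    grid = tables.rsf[option_id]
    return float(grid.r_axis[1]), float(grid.m_axis[1])


class TestInvariantsAfterPipeline:
    def test_normalizations_hold_on_campaign_tables(self, noise_free_tables):
        assert noise_free_tables.validate() == []
        assert noise_free_tables.lookup_rof(20) == pytest.approx(1.0)
        for oid, grid in noise_free_tables.sobpf.items():
            ref_m = pm.default_catalog().get(oid).rof_modulation
            assert noise_free_tables.interp_sobpf(oid, ref_m) == pytest.approx(1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_grid1d_interp_within_hull(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0, 10, 5))
        while np.any(np.diff(x) <= 0):
            x = np.sort(rng.uniform(0, 10, 5))
        v = rng.uniform(0.5, 1.5, 5)
        g = Grid1D(x, v)
        q = rng.uniform(x[0], x[-1])
        val = g.interp(q)
        assert v.min() - 1e-12 <= val <= v.max() + 1e-12
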