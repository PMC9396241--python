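"""Zonal geometry, resampling, and feature assembly."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tnepredict import errors
from tnepredict import oct_features as of


def brute_force_masks(rows, cols, extent=(6.0, 6.0)):
    """Independent oracle: per-pixel loop over centre distances."""
    masks = {z: np.zeros((rows, cols), dtype=bool) for z in of.ZONES}
    for i in range(rows):
        for j in range(cols):
            y = (i + 0.5) * extent[0] / rows - extent[0] / 2
            x = (j + 0.5) * extent[1] / cols - extent[1] / 2
            d = np.sqrt(x * x + y * y)
            for z, (lo, hi) in of.ZONE_RADII_MM.items():
                if lo <= d < hi:
                    masks[z][i, j] = True
    return masks


class TestResample:
    @pytest.mark.parametrize("shape", [(2, 2), (49, 768), (128, 512), (5, 9)])
    def test_constant_preserved(self, shape):
        out = of.resample_map(np.full(shape, 100.0), 128, 128)
        assert np.allclose(out, 100.0)

    def test_hand_evaluated_midpoint(self):
        # bilinear at the centre of [[0,1],[2,3]] is the mean of the corners
        out = of.resample_map(np.array([[0.0, 1.0], [2.0, 3.0]]), 3, 3)
        assert out[1, 1] == pytest.approx(1.5)

    def test_identity(self, rng):
        arr = rng.uniform(0, 50, size=(49, 768))
        assert np.allclose(of.resample_map(arr, 49, 768), arr)

    def test_degenerate_source_rejected(self):
        with pytest.raises(errors.ContractError):
            of.resample_map(np.ones((1, 5)), 10, 10)


class TestZoneMasks:
    def test_grid_centre_is_central(self):
        masks = of.etdrs_zone_masks(128, 128)
        # the four pixels nearest the geometric centre
        assert masks["central_1mm"][63:65, 63:65].all()

    @pytest.mark.parametrize("rows,cols", [(128, 128), (49, 768), (64, 100), (8, 8)])
    def test_matches_brute_force_enumeration(self, rows, cols):
        masks = of.etdrs_zone_masks(rows, cols)
        oracle = brute_force_masks(rows, cols)
        for z in of.ZONES:
            assert np.array_equal(masks[z], oracle[z])

    def test_masks_disjoint_and_union_is_disc(self):
        masks = of.etdrs_zone_masks(128, 128)
        total = sum(m.astype(int) for m in masks.values())
        assert total.max() == 1  # pairwise disjoint
        oracle = brute_force_masks(128, 128)
        union_oracle = oracle["central_1mm"] | oracle["para_1_3mm"] | oracle["peri_3_6mm"]
        assert np.array_equal(total.astype(bool), union_oracle)

    def test_central_pixel_count_approximates_disc_area(self):
        # 128 px over 6 mm -> radius 0.5 mm is ~10.67 px; ~pi r^2 ~ 357 px
        masks = of.etdrs_zone_masks(128, 128)
        n = int(masks["central_1mm"].sum())
        assert abs(n - np.pi * (0.5 / (6.0 / 128)) ** 2) < 15

    def test_bad_inputs_rejected(self):
        with pytest.raises(errors.ContractError):
            of.etdrs_zone_masks(4, 128)
        with pytest.raises(errors.ContractError):
            of.etdrs_zone_masks(128, 128, extent_mm=(0.0, 6.0))


class TestZonalSummaries:
    def test_zero_map_zero_volume(self):
        masks = of.etdrs_zone_masks(128, 128)
        assert of.zonal_volume(np.zeros((128, 128)), masks["central_1mm"], 1.0) == 0.0

    def test_uniform_field_closed_form(self):
        # 100 µm over the full 6x6 mm grid: 36 mm² x 0.1 mm = 3.6 mm³ = 3600 nl
        area = of.pixel_area_mm2(128, 128)
        full = np.ones((128, 128), dtype=bool)
        vol = of.zonal_volume(np.full((128, 128), 100.0), full, area)
        assert vol == pytest.approx(3600.0)

    @given(scale=st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=20)
    def test_volume_linearity(self, scale):
        rng = np.random.default_rng(3)
        arr = rng.uniform(0, 100, (32, 32))
        mask = of.etdrs_zone_masks(32, 32)["para_1_3mm"]
        v1 = of.zonal_volume(arr, mask, 0.01)
        v2 = of.zonal_volume(scale * arr, mask, 0.01)
        assert v2 == pytest.approx(scale * v1)

    def test_volume_additivity_over_zones(self, rng):
        arr = rng.uniform(0, 200, (49, 768))
        masks = of.etdrs_zone_masks(49, 768)
        area = of.pixel_area_mm2(49, 768)
        union = masks["central_1mm"] | masks["para_1_3mm"] | masks["peri_3_6mm"]
        parts = sum(of.zonal_volume(arr, masks[z], area) for z in of.ZONES)
        assert parts == pytest.approx(of.zonal_volume(arr, union, area))

    def test_mean_thickness(self):
        masks = of.etdrs_zone_masks(16, 16)
        m = masks["central_1mm"]
        arr = np.zeros((16, 16))
        idx = np.argwhere(m)
        arr[tuple(idx[: len(idx) // 2].T)] = 80.0
        # half the masked pixels at 0, half at 80 (even count on this grid)
        assert len(idx) % 2 == 0
        assert of.zonal_mean_thickness(arr, m) == pytest.approx(40.0)
        arr2 = arr.copy()
        arr2[~m] = 999.0  # values outside the mask are irrelevant
        assert of.zonal_mean_thickness(arr2, m) == of.zonal_mean_thickness(arr, m)

    def test_contract_errors(self):
        with pytest.raises(errors.ContractError):
            of.zonal_volume(np.zeros((4, 4)), np.zeros((5, 5), bool), 1.0)
        with pytest.raises(errors.ContractError):
            of.zonal_mean_thickness(np.zeros((4, 4)), np.zeros((4, 4), bool))


def _zonal(eye_id, label, value):
    return of.ZonalFeatures(
        eye_id=eye_id,
        visit_label=label,
        values={(b, z): value for b in of.BIOMARKERS for z in of.ZONES},
    )


class TestChangeAndAssembly:
    def test_change_is_elementwise_difference(self):
        m0, m1 = _zonal("e", "M0", 120.0), _zonal("e", "M1", 30.0)
        ch = of.change_features(m0, m1)
        assert all(v == pytest.approx(-90.0) for v in ch.values.values())
        # identical visits give zero change
        zero = of.change_features(m0, of.ZonalFeatures("e", "M1", dict(m0.values)))
        assert all(v == 0.0 for v in zero.values.values())

    def test_change_antisymmetry(self, rng):
        a = of.ZonalFeatures(
            "e", "M0",
            {(b, z): float(rng.uniform(0, 100)) for b in of.BIOMARKERS for z in of.ZONES},
        )
        b_ = of.ZonalFeatures(
            "e", "M1",
            {k: float(rng.uniform(0, 100)) for k in a.values},
        )
        fwd = of.change_features(a, b_)
        rev = of.change_features(
            of.ZonalFeatures("e", "M0", dict(b_.values)),
            of.ZonalFeatures("e", "M1", dict(a.values)),
        )
        for k in fwd.values:
            assert fwd.values[k] == pytest.approx(-rev.values[k])

    def test_eye_mismatch_rejected(self):
        with pytest.raises(errors.ContractError):
            of.change_features(_zonal("a", "M0", 1.0), _zonal("b", "M1", 1.0))

    def test_vector_has_45_imaging_and_50_total(self):
        fv = of.assemble_feature_vector(
            _zonal("e", "M0", 10.0), _zonal("e", "M1", 5.0), _zonal("e", "change", -5.0),
            bcva_m0=58, bcva_m1=63, age=75, sex="male",
        )
        assert len(fv.values) == 50
        imaging = [n for n in fv.names if not n.startswith(("bcva", "age", "sex"))]
        assert len(imaging) == 45
        assert fv.values[fv.names.index("bcva_change")] == pytest.approx(5.0)
        assert fv.values[fv.names.index("sex")] == 0.0

    def test_missing_entry_raises_not_imputes(self):
        m0 = _zonal("e", "M0", 10.0)
        broken = of.ZonalFeatures("e", "M1", dict(m0.values))
        broken.values[("IRF", "central_1mm")] = np.nan
        with pytest.raises(errors.MissingDataError):
            of.assemble_feature_vector(
                m0, broken, _zonal("e", "change", 0.0), 50, 50, 70, "female"
            )

    def test_name_value_alignment_survives_csv_round_trip(self, tmp_path):
        fv = of.assemble_feature_vector(
            _zonal("e1", "M0", 7.0), _zonal("e1", "M1", 3.0), _zonal("e1", "change", -4.0),
            bcva_m0=40, bcva_m1=45, age=80, sex="female",
        )
        df = of.feature_table([fv])
        of.write_feature_table(df, tmp_path / "f.csv", tmp_path / "s.json")
        back = of.read_feature_table(tmp_path / "f.csv")
        assert list(back.columns) == list(fv.names)
        assert np.allclose(back.loc["e1"].to_numpy(), fv.values)
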