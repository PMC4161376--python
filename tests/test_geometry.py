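"""Layout construction, design transforms, and screen classifiers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thumbkey as tk
from thumbkey.geometry import _SECTOR_LABELS, LayoutError, min_feasible_radius

from conftest import exact_letters_config

SCREEN = (51.0, 76.0)


class TestBaseLayout:
    def test_home_row_middle_key_is_g_and_centred(self, base_layout):
        g = base_layout.g_key
        assert g.x == pytest.approx(base_layout.screen_w / 2)
        home_row = [
            k
            for k in base_layout.keys
            if k.layer == "letters" and k.y == pytest.approx(base_layout.home_y)
        ]
        assert sorted(k.x for k in home_row)[len(home_row) // 2] == pytest.approx(g.x)

    def test_letters_layer_contents(self, base_layout):
        letters = {
            k.id for k in base_layout.keys if k.layer == "letters" and k.kind == "character"
        }
        assert letters == set("abcdefghijklmnopqrstuvwxyz")
        kinds = {k.kind for k in base_layout.keys if k.layer == "letters"}
        assert {"shift", "backspace", "function", "return", "spacebar-subkey"} <= kinds

    def test_spacebar_is_four_subkeys_sharing_one_id(self, base_layout):
        for layer in base_layout.layers:
            subs = base_layout.space_subkeys(layer)
            assert len(subs) == 4
            assert {k.id for k in subs} == {"space"}
            assert [k.sub for k in subs] == [0, 1, 2, 3]
            xs = [k.x for k in subs]
            assert xs == sorted(xs)

    def test_all_three_layers_present(self, base_layout):
        assert set(base_layout.layers) == {"letters", "numbers", "symbols"}

    def test_zero_width_key_rejected(self):
        cfg = exact_letters_config()
        cfg["key"]["width"] = 0.0
        with pytest.raises(LayoutError):
            tk.build_base_layout(cfg)

    def test_malformed_config_rejected(self):
        with pytest.raises(LayoutError):
            tk.build_base_layout({"screen": {"width": 51.0}})


class TestApplyDesign:
    @pytest.mark.parametrize(
        "l_level,height", [("bottom", 19.0), ("middle", 38.0), ("top", 57.0)]
    )
    def test_location_sets_g_height(self, base_layout, l_level, height):
        """L = bottom/middle/top puts the G centre 1/4, 1/2, 3/4 up the
        76 mm screen: 19, 38 and 57 mm."""
        out = tk.apply_design(base_layout, tk.DesignParams(l=l_level))
        g = out.g_key
        assert g.y == pytest.approx(height)
        assert g.x == pytest.approx(base_layout.g_key.x)

    def test_flat_unrotated_design_is_pure_vertical_shift(self, base_layout):
        out = tk.apply_design(base_layout, tk.DesignParams(l="top"))
        dy = 57.0 - base_layout.home_y
        for before, after in zip(base_layout.keys, out.keys):
            assert after.x == pytest.approx(before.x)
            assert after.y == pytest.approx(before.y + dy)

    def test_rotation_fixes_g_and_rotates_other_keys(self, base_layout):
        params = tk.DesignParams(o=30.0, l="middle")
        out = tk.apply_design(base_layout, params)
        g0, g1 = base_layout.g_key, out.g_key
        assert (g1.x, g1.y) == pytest.approx((g0.x, g0.y))
        phi = math.radians(30.0)
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        for before, after in zip(base_layout.keys, out.keys):
            expected = rot @ np.array([before.x - g0.x, before.y - g0.y])
            assert (after.x, after.y) == pytest.approx(
                (g0.x + expected[0], g0.y + expected[1])
            )

    @pytest.mark.parametrize("magnitude", [25.0, 60.0, 90.0])
    def test_curvature_sign_symmetry_on_home_row(self, base_layout, magnitude):
        """+R and -R displace home-row keys by mirror-image vertical offsets."""
        down = tk.apply_design(base_layout, tk.DesignParams(r=magnitude, l="middle"))
        up = tk.apply_design(base_layout, tk.DesignParams(r=-magnitude, l="middle"))
        hy = base_layout.home_y
        for k0, kd, ku in zip(base_layout.keys, down.keys, up.keys):
            if k0.layer == "letters" and k0.y == pytest.approx(hy):
                assert kd.y - hy == pytest.approx(-(ku.y - hy))
                assert kd.x == pytest.approx(ku.x)
                assert kd.y <= hy + 1e-9  # positive R curves down

    @pytest.mark.parametrize(
        "params",
        [
            tk.DesignParams(),
            tk.DesignParams(r=-20.0, o=-20.0, l="middle"),
            tk.DesignParams(r=90.0, o=60.0, l="top"),
            tk.DesignParams(r=-90.0, o=40.0, l="bottom"),
        ],
    )
    def test_key_count_and_sizes_invariant(self, base_layout, params):
        out = tk.apply_design(base_layout, params)
        assert len(out.keys) == len(base_layout.keys)
        for before, after in zip(base_layout.keys, out.keys):
            assert (after.width, after.height) == (before.width, before.height)
            assert (after.id, after.layer, after.kind, after.sub) == (
                before.id,
                before.layer,
                before.kind,
                before.sub,
            )

    def test_infeasible_curvature_names_minimum(self, base_layout):
        min_rho = min_feasible_radius(base_layout, positive=True)
        with pytest.raises(tk.InfeasibleCurvatureError, match="minimum feasible"):
            tk.apply_design(base_layout, tk.DesignParams(r=min_rho - 5.0))
        # feasible just above the bound
        tk.apply_design(base_layout, tk.DesignParams(r=min_rho + 0.1))

    def test_r_scale_changes_feasibility(self, base_layout):
        params = tk.DesignParams(r=10.0)
        with pytest.raises(tk.InfeasibleCurvatureError):
            tk.apply_design(base_layout, params)
        tk.apply_design(base_layout, params, r_scale=3.0)


class TestClassifyRegion:
    def test_corner_regions(self):
        assert tk.classify_region((45.0, 70.0), SCREEN) == 3  # top right
        assert tk.classify_region((45.0, 5.0), SCREEN) == 12  # bottom right
        assert tk.classify_region((5.0, 70.0), SCREEN) == 1
        assert tk.classify_region((5.0, 5.0), SCREEN) == 10

    def test_cell_centres_enumerate_all_regions(self):
        w, h = SCREEN
        got = [
            tk.classify_region(((c + 0.5) * w / 3, h - (r + 0.5) * h / 4), SCREEN)
            for r in range(4)
            for c in range(3)
        ]
        assert got == list(range(1, 13))

    def test_interior_boundaries_belong_to_upper_right_cell(self):
        assert tk.classify_region((17.0, 70.0), SCREEN) == 2  # on a column edge
        assert tk.classify_region((5.0, 19.0), SCREEN) == 7  # on a row edge

    def test_out_of_screen_points_clamp_to_nearest_cell(self):
        assert tk.classify_region((-3.0, 80.0), SCREEN) == 1
        assert tk.classify_region((60.0, -5.0), SCREEN) == 12

    def test_non_finite_point_rejected(self):
        with pytest.raises(ValueError):
            tk.classify_region((math.nan, 1.0), SCREEN)

    @given(
        x=st.floats(0.0, 51.0, exclude_max=True),
        y=st.floats(0.0, 76.0, exclude_max=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_every_screen_point_maps_to_exactly_one_region(self, x, y):
        region = tk.classify_region((x, y), SCREEN)
        assert 1 <= region <= 12
        # the region's cell actually contains the point
        col = (region - 1) % 3
        row_from_top = (region - 1) // 3
        assert col * 17.0 <= x < (col + 1) * 17.0 or (col == 2 and x >= 34.0)
        y_lo = (3 - row_from_top) * 19.0
        assert y_lo <= y < y_lo + 19.0 or (row_from_top == 0 and y >= 57.0)


class TestClassifyDirection:
    def test_axis_aligned_examples(self):
        assert tk.classify_direction((25, 10), (25, 30)) == "S to N"
        assert tk.classify_direction((10, 60), (30, 40)) == "NW to SE"
        assert tk.classify_direction((10, 10), (30, 10)) == "W to E"
        assert tk.classify_direction((10, 10), (30, 30)) == "SW to NE"

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            tk.classify_direction((1.0, 2.0), (1.0, 2.0))

    def test_sector_boundary_goes_clockwise(self):
        # (1, tan(22.5 deg)) computes to an angle of exactly 22.5 deg, the
        # E/NE boundary; clockwise of it is E ("W to E")
        d = (1.0, math.tan(math.radians(22.5)))
        assert math.degrees(math.atan2(d[1], d[0])) == 22.5
        assert tk.classify_direction((0, 0), d) == "W to E"

    @given(
        angle=st.integers(0, 359),
        radius=st.floats(0.1, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_opposite_displacements_share_an_axis(self, angle, radius):
        a = math.radians(angle)
        p, q = (0.0, 0.0), (radius * math.cos(a), radius * math.sin(a))
        fwd = tk.classify_direction(p, q)
        back = tk.classify_direction(q, p)
        flip = dict(zip(_SECTOR_LABELS, (_SECTOR_LABELS * 2)[4:12]))
        assert back == flip[fwd]

    @given(sector=st.integers(0, 7), jitter=st.floats(-20.0, 20.0))
    @settings(max_examples=100, deadline=None)
    def test_rotating_by_45_degrees_advances_one_sector(self, sector, jitter):
        a = math.radians(45.0 * sector + jitter)
        p = (0.0, 0.0)
        q = (math.cos(a), math.sin(a))
        q_rot = (math.cos(a + math.pi / 4), math.sin(a + math.pi / 4))
        k = _SECTOR_LABELS.index(tk.classify_direction(p, q))
        k_rot = _SECTOR_LABELS.index(tk.classify_direction(p, q_rot))
        assert k_rot == (k + 1) % 8


def test_export_layout_csv(base_layout, tmp_path):
    path = tmp_path / "layout.csv"
    tk.export_layout_csv(base_layout, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].startswith("layer,id,kind")
    assert len(lines) == len(base_layout.keys) + 1
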