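"""Sigma-profile parsing, region discretization and descriptor mixing."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import desvisc as dv
from desvisc.errors import ParseError, ValidationError
from desvisc.simulate import SIGMA_GRID_31, synthetic_profile


def make_profile_text(grid, dens, sep=" "):
    lines = ["# comment line"]
    lines += [f"{s}{sep}{a}" for s, a in zip(grid, dens)]
    return "\n".join(lines)


class TestParsing:
    def test_standard_31_point_file(self):
        dens = np.abs(np.sin(SIGMA_GRID_31 * 100)) * 10
        text = make_profile_text(SIGMA_GRID_31, dens)
        p = dv.parse_sigma_profile(io.StringIO(text), compound_id="glycerol")
        assert p.n_points == 31
        assert p.compound_id == "glycerol"
        assert p.sigma_grid[0] == -0.03 and p.sigma_grid[-1] == 0.03
        np.testing.assert_allclose(p.area_density, dens)

    def test_comma_separated_and_unsorted_rows(self):
        text = "0.0,2.0\n-0.01, 1.0\n0.01,3.0\n-0.02,0.5\n0.02,0.1"
        with pytest.warns(UserWarning, match="grid points"):
            p = dv.parse_sigma_profile(io.StringIO(text), compound_id="x")
        assert np.all(np.diff(p.sigma_grid) > 0)
        assert p.area_density[p.sigma_grid == 0.0] == 2.0

    def test_all_zero_area_profile_is_valid(self):
        text = make_profile_text(SIGMA_GRID_31, np.zeros(31))
        p = dv.parse_sigma_profile(io.StringIO(text), compound_id="void")
        assert p.total_area() == 0.0

    def test_roundtrip_write_parse_is_identical(self, tmp_path):
        grid = np.linspace(-0.03, 0.03, 51)
        prof = synthetic_profile("donor_rich", "c51", rng=7, grid=grid)
        path = tmp_path / "c51.txt"
        dv.write_sigma_profile(prof, str(path))
        back = dv.parse_sigma_profile(str(path))
        assert back.compound_id == "c51"
        np.testing.assert_array_equal(back.sigma_grid, prof.sigma_grid)
        np.testing.assert_array_equal(back.area_density, prof.area_density)

    def test_malformed_row_names_line_number(self):
        text = "-0.03 1.0\n-0.02 oops\n-0.01 1.0"
        with pytest.raises(ParseError, match="line 2"):
            dv.parse_sigma_profile(io.StringIO(text), compound_id="bad")

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ParseError, match="2 columns"):
            dv.parse_sigma_profile(
                io.StringIO("-0.03 1.0 9.9\n"), compound_id="bad"
            )

    def test_duplicate_sigma_rejected(self):
        text = "-0.01 1.0\n-0.01 2.0\n0.0 1.0\n0.01 1.0"
        with pytest.raises(ValidationError, match="strictly increasing"):
            dv.parse_sigma_profile(io.StringIO(text), compound_id="dup")

    def test_negative_density_rejected(self):
        text = "-0.02 1.0\n-0.01 -0.5\n0.0 1.0\n0.01 1.0"
        with pytest.raises(ValidationError, match="negative"):
            dv.parse_sigma_profile(io.StringIO(text), compound_id="neg")


class TestDiscretization:
    def test_zero_profile_gives_zero_descriptors(self):
        p = dv.SigmaProfile("z", SIGMA_GRID_31, np.zeros(31))
        d = dv.discretize_profile(p)
        np.testing.assert_array_equal(d.s, np.zeros(8))

    def test_triangular_profile_matches_fine_riemann_oracle(self):
        # piecewise-linear tent with its kink on a grid node: the
        # trapezoidal region areas must match brute-force quadrature
        dens = np.maximum(0.0, 1.0 - np.abs(SIGMA_GRID_31) / 0.03)
        p = dv.SigmaProfile("tent", SIGMA_GRID_31, dens)
        d = dv.discretize_profile(p)
        edges = np.linspace(-0.03, 0.03, 9)
        for i in range(8):
            xs = np.linspace(edges[i], edges[i + 1], 1_000_001)
            mid = (xs[:-1] + xs[1:]) / 2
            f = np.maximum(0.0, 1.0 - np.abs(mid) / 0.03)
            oracle = float(np.sum(f) * (xs[1] - xs[0]))
            assert d.s[i] == pytest.approx(oracle, rel=1e-9)

    def test_boundary_between_grid_points_interpolates(self):
        # constant density: every region area is width * density exactly,
        # even when edges fall between the grid nodes
        grid = np.linspace(-0.03, 0.03, 7)  # spacing 0.01
        p = dv.SigmaProfile("const", grid, np.full(7, 2.0))
        scheme = dv.RegionScheme(
            boundaries=np.array(
                [-0.03, -0.025, -0.012, -0.004, 0.0, 0.003, 0.011, 0.024, 0.03]
            )
        )
        d = dv.discretize_profile(p, scheme)
        widths = np.diff(scheme.boundaries)
        np.testing.assert_allclose(d.s, 2.0 * widths, rtol=1e-12)

    @pytest.mark.parametrize("seed", [0, 3, 9])
    @pytest.mark.parametrize("kind", ["nonpolar", "donor_rich", "water_like"])
    def test_region_areas_sum_to_total_area(self, seed, kind):
        p = synthetic_profile(kind, "c", rng=seed)
        d = dv.discretize_profile(p)
        assert d.total() == pytest.approx(p.total_area(), rel=1e-9)

    def test_scheme_wider_than_grid_rejected(self):
        grid = np.linspace(-0.02, 0.02, 21)
        p = dv.SigmaProfile("narrow", grid, np.ones(21))
        with pytest.raises(ValidationError, match="beyond the profile grid"):
            dv.discretize_profile(p)  # default scheme spans +/-0.03


class TestMixing:
    def test_identity_mixture_returns_pure_descriptors(self):
        a = dv.DescriptorVector(np.arange(1.0, 9.0))
        b = dv.DescriptorVector(np.ones(8))
        mix = dv.MixtureSpec(
            (dv.Component("a", 1.0, "hba"), dv.Component("b", 0.0, "hbd"))
        )
        out = dv.mix_descriptors({"a": a, "b": b}, mix)
        np.testing.assert_allclose(out.s, a.s)

    def test_two_component_weighted_average(self):
        a = dv.DescriptorVector(np.full(8, 2.0))
        b = dv.DescriptorVector(np.full(8, 4.0))
        mix = dv.MixtureSpec(
            (dv.Component("a", 0.25, "hba"), dv.Component("b", 0.75, "hbd"))
        )
        out = dv.mix_descriptors({"a": a, "b": b}, mix)
        np.testing.assert_allclose(out.s, np.full(8, 3.5))

    @settings(max_examples=30, derandomize=True)
    @given(
        x=st.floats(0.05, 0.95),
        y=st.floats(0.05, 0.95),
        seed=st.integers(0, 100),
    )
    def test_nested_mixing_equals_flat_average(self, x, y, seed):
        r = np.random.default_rng(seed)
        sa, sb, sc = (r.uniform(0, 10, 8) for _ in range(3))
        pure = {
            "a": dv.DescriptorVector(sa),
            "b": dv.DescriptorVector(sb),
            "c": dv.DescriptorVector(sc),
        }
        inner = dv.mix_descriptors(
            pure,
            dv.MixtureSpec(
                (dv.Component("a", x, "hba"), dv.Component("b", 1 - x, "hbd"))
            ),
        )
        outer = dv.mix_descriptors(
            {"ab": inner, "c": dv.DescriptorVector(sc)},
            dv.MixtureSpec(
                (
                    dv.Component("ab", y, "hba"),
                    dv.Component("c", 1 - y, "hbd"),
                )
            ),
        )
        flat = y * x * sa + y * (1 - x) * sb + (1 - y) * sc
        np.testing.assert_allclose(outer.s, flat, rtol=1e-12, atol=1e-12)

    def test_component_order_does_not_matter(self):
        pure = {
            "a": dv.DescriptorVector(np.arange(8.0)),
            "b": dv.DescriptorVector(np.arange(8.0)[::-1].copy()),
            "w": dv.DescriptorVector(np.full(8, 0.5)),
        }
        comps = (
            dv.Component("a", 0.3, "hba"),
            dv.Component("b", 0.5, "hbd"),
            dv.Component("w", 0.2, "cosolvent"),
        )
        fwd = dv.mix_descriptors(pure, dv.MixtureSpec(comps))
        rev = dv.mix_descriptors(pure, dv.MixtureSpec(comps[::-1]))
        np.testing.assert_allclose(fwd.s, rev.s)

    def test_missing_component_raises_lookup_error(self):
        mix = dv.MixtureSpec(
            (dv.Component("a", 0.5, "hba"), dv.Component("zz", 0.5, "hbd"))
        )
        with pytest.raises(KeyError, match="zz"):
            dv.mix_descriptors({"a": dv.DescriptorVector(np.ones(8))}, mix)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            dv.MixtureSpec(
                (dv.Component("a", 0.5, "hba"), dv.Component("b", 0.6, "hbd"))
            )


class TestRatioToFractions:
    def test_one_to_two_ratio(self):
        mix = dv.ratio_to_fractions(1, 2, 0)
        fr = mix.fractions()
        assert fr["ChCl"] == pytest.approx(1 / 3)
        assert fr["HBD"] == pytest.approx(2 / 3)

    def test_cosolvent_dilution(self):
        mix = dv.ratio_to_fractions(1, 2, 0.5, cosolvent_id="water")
        fr = mix.fractions()
        assert fr["ChCl"] == pytest.approx(1 / 6)
        assert fr["HBD"] == pytest.approx(1 / 3)
        assert fr["water"] == pytest.approx(0.5)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_one_to_three_gives_075_donor(self):
        mix = dv.ratio_to_fractions(1, 3, 0)
        assert mix.fractions()["HBD"] == pytest.approx(0.75)

    @pytest.mark.parametrize("args", [(-1, 2, 0), (1, 0, 0), (1, 2, 1.0)])
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValidationError):
            dv.ratio_to_fractions(*args)
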