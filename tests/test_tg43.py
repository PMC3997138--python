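"""tg43 + synthetic fields: geometry function, extraction, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import brachymc as b
from brachymc.fields import table_interpolator

L = 0.35


def test_geometry_function_closed_forms():
    assert b.geometry_function_line(1.0, 90.0, L) == pytest.approx(
        2 * np.arctan(0.175) / 0.35, rel=1e-12)
    assert b.geometry_function_line(1.0, 90.0, L) == pytest.approx(0.98999,
                                                                   abs=5e-5)
    assert b.geometry_function_line(1.0, 0.0, L) == pytest.approx(
        1.0 / (1.0 - 0.35**2 / 4), rel=1e-12)
    assert b.geometry_function_line(1.0, 0.0, L) == pytest.approx(1.03159,
                                                                  abs=5e-5)


def test_geometry_function_point_source_limit():
    for r, th in ((0.7, 35.0), (2.0, 90.0), (5.0, 140.0)):
        assert b.geometry_function_line(r, th, 1e-4) == pytest.approx(
            1.0 / r**2, rel=1e-6)


def test_geometry_function_matches_line_integral():
    """G equals the numerically integrated inverse-square of the line."""
    for r, th in ((1.0, 90.0), (1.0, 30.0), (2.0, 150.0), (0.5, 10.0)):
        rho = r * np.sin(np.radians(th))
        z = r * np.cos(np.radians(th))
        integ, _ = quad(lambda l: 1.0 / (rho**2 + (z - l) ** 2),
                        -L / 2, L / 2)
        assert b.geometry_function_line(r, th, L) == pytest.approx(
            integ / L, rel=1e-9)


def test_geometry_function_continuous_at_pole():
    near = b.geometry_function_line(1.0, 1e-4, L)
    axis = b.geometry_function_line(1.0, 0.0, L)
    assert near == pytest.approx(axis, rel=1e-6)


def test_geometry_function_rejects_points_inside_line():
    with pytest.raises(ValueError, match="r <= L/2"):
        b.geometry_function_line(0.1, 0.0, L)
    with pytest.raises(ValueError, match="theta"):
        b.geometry_function_line(1.0, 200.0, L)


@settings(max_examples=80, derandomize=True)
@given(st.floats(min_value=0.3, max_value=15.0),
       st.floats(min_value=0.0, max_value=180.0))
def test_geometry_function_positive_and_bounded(r, theta):
    val = b.geometry_function_line(r, theta, L)
    assert 0 < val <= 1.0 / (r**2 - L**2 / 4)


# ----- extraction round trips ----------------------------------------------


def test_tg43_composite_round_trip_machine_precision():
    g0 = lambda r: np.exp(-0.03 * (r - 1.0))  # noqa: E731
    f0 = lambda r, th: 1.0 - 0.35 * np.cos(np.radians(th)) ** 2  # noqa: E731
    profile = b.make_tg43_field(1.115, g0, f0, L, [0.5, 1.0, 2.0, 5.0, 10.0])
    g = b.radial_dose_function(profile, L)
    np.testing.assert_allclose(g["g"], g0(g["r_cm"].to_numpy()), atol=1e-10)
    pmap = b.make_tg43_field(1.115, g0, f0, L, [1.0, 5.0],
                             [5.0, 30.0, 90.0, 150.0, 179.0])
    f = b.anisotropy_function(pmap, L)
    expect = (f0(f["r_cm"], f["theta_deg"]) / f0(f["r_cm"], 90.0)).to_numpy()
    np.testing.assert_allclose(f["F"], expect, atol=1e-10)


def test_round_trip_on_published_reference_tables(reference_g, reference_f):
    """Splines through the published water tables survive extraction.

    Doubles as a transcription check of the bundled reference fixtures.
    """
    g_spline = table_interpolator(reference_g["r_cm"], reference_g["water"])
    water_f = reference_f[reference_f.medium == "water"]
    pivot = water_f.pivot(index="theta_deg", columns="r_cm", values="F")

    def f0(r, th):
        r_arr, th_arr = np.broadcast_arrays(np.asarray(r, float),
                                            np.asarray(th, float))
        out = np.empty(r_arr.shape)
        for i, (ri, ti) in enumerate(zip(r_arr.ravel(), th_arr.ravel())):
            col = pivot[ri] if ri in pivot.columns else None
            out.ravel()[i] = 1.0 if col is None else np.interp(ti, pivot.index,
                                                               col.to_numpy())
        return out

    radii = [0.5, 1.0, 2.0, 3.0, 5.0, 10.0]
    profile = b.make_tg43_field(1.115, g_spline, f0, L,
                                reference_g["r_cm"].to_numpy())
    g = b.radial_dose_function(profile, L)
    np.testing.assert_allclose(g["g"], reference_g["water"], atol=1e-10)
    pmap = b.make_tg43_field(1.115, g_spline, f0, L, radii,
                             sorted(water_f["theta_deg"].unique()))
    f = b.anisotropy_function(pmap, L)
    merged = f.merge(water_f, on=["r_cm", "theta_deg"])
    np.testing.assert_allclose(merged["F_x"], merged["F_y"], atol=1e-10)


def test_point_field_extraction():
    mu = 0.08
    profile = b.make_point_field(mu, 0.03, [0.5, 1.0, 4.0, 9.0])
    g = b.radial_dose_function(profile, L=1e-4)
    np.testing.assert_allclose(g["g"],
                               np.exp(-mu * (g["r_cm"].to_numpy() - 1.0)),
                               atol=1e-7)
    pmap = b.make_point_field(mu, 0.03, [1.0, 5.0], [10.0, 90.0, 170.0])
    f = b.anisotropy_function(pmap, L=1e-4)
    np.testing.assert_allclose(f["F"], 1.0, atol=1e-7)


def test_fields_are_pure_and_positive():
    a = b.make_point_field(0.1, 0.05, [1.0, 2.0]).kerma_per_history
    c = b.make_point_field(0.1, 0.05, [1.0, 2.0]).kerma_per_history
    np.testing.assert_array_equal(a, c)
    with pytest.raises(ValueError, match="positive"):
        b.make_tg43_field(1.0, lambda r: r - 1.5, lambda r, t: 1.0, L,
                          [0.5, 1.0])


def test_dose_rate_constant_identity_and_validation():
    assert b.dose_rate_constant(5.0, 5.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        b.dose_rate_constant(-1.0, 2.0)
    with pytest.raises(ValueError):
        b.dose_rate_constant(1.0, 0.0)


def test_radial_dose_function_requires_reference_bin():
    profile = b.make_point_field(0.1, 0.05, [2.0, 3.0])
    with pytest.raises(ValueError, match="1 cm"):
        b.radial_dose_function(profile)


def test_anisotropy_requires_90_degree_bin():
    pmap = b.make_point_field(0.1, 0.05, [1.0], [10.0, 40.0])
    with pytest.raises(ValueError, match="90"):
        b.anisotropy_function(pmap)


def test_dose_ratio_identity_and_grid_mismatch():
    prof = b.make_point_field(0.1, 0.05, [1.0, 2.0, 5.0])
    ratio = b.dose_ratio_curves(prof, prof)
    np.testing.assert_allclose(ratio["ratio"], 1.0, atol=1e-12)
    other = b.make_point_field(0.1, 0.05, [1.0, 2.0])
    with pytest.raises(ValueError, match="grid"):
        b.dose_ratio_curves(other, prof)


def test_air_kerma_strength_closed_form_and_invariance():
    """Bare point source, one line: S_K = E (mu_en/rho)_air / 4 pi."""
    spec = b.PhotonSpectrum(energies=np.array([0.3]),
                            intensities=np.array([1.0]))
    s_k, rel = b.compute_air_kerma_strength(None, spec, 150_000, seed=61)
    air = b.build_attenuation_table(b.load_material("dry_air"))
    exact = 0.3 * b.interpolate_mu(air, 0.3, "mu_en") / (4 * np.pi)
    assert s_k == pytest.approx(exact, rel=3 * rel + 1e-3)


def test_tg43_parameters_interpolation(reference_g, reference_f):
    water_f = reference_f[reference_f.medium == "water"].rename(
        columns={"F": "F"})
    params = b.TG43Parameters(
        medium="water", phantom_diameter=30.0, s_k_per_history=1.0,
        lambda_const=1.115,
        g_table=reference_g.rename(columns={"water": "g"})[["r_cm", "g"]],
        f_table=water_f)
    assert params.g(1.0) == pytest.approx(1.0)
    assert params.g(2.1) == pytest.approx(np.interp(
        2.1, reference_g["r_cm"], reference_g["water"]))
    assert params.anisotropy(1.0, 90.0) == pytest.approx(1.0)
    got = params.anisotropy(1.0, 30.0)
    ref = water_f[(water_f.r_cm == 1.0) & (water_f.theta_deg == 30.0)]["F"]
    assert got == pytest.approx(float(ref.iloc[0]))
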