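"""TG-43 parameter extraction from tallied kerma distributions.

Implements the AAPM TG-43 decomposition for a line source of active length
L: air-kerma strength S_K, dose-rate constant Lambda, radial dose function
g(r) and anisotropy function F(r, theta), with the line-source geometry
function

    G_L(r, theta) = beta / (L r sin theta),      beta = angle subtended
    G_L(r, 0)     = 1 / (r^2 - L^2/4)            on the source axis.

All dose inputs are per-history collision kerma from
:func:`brachymc.transport.run_transport`; every extracted quantity is a
ratio, so the per-history normalization cancels throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import PhotonSpectrum, build_attenuation_table, load_material
from .source import SourceGeometry
from .tallies import TallyResult, transverse_rings

_SIN_EPS = 1e-9


def geometry_function_line(r, theta, L: float = 0.35):
    """Line-source geometry function G_L(r, theta) in cm^-2.

    ``r`` in cm, ``theta`` in degrees (0..180), ``L`` the active length.
    Continuous through the on-axis limits; evaluating on the axis inside
    the line's axial extent (r <= L/2) raises.
    """
    r_arr = np.asarray(r, dtype=float)
    t_arr = np.asarray(theta, dtype=float)
    if np.any((t_arr < 0) | (t_arr > 180)):
        raise ValueError("theta must be within [0, 180] degrees")
    r_b, t_b = np.broadcast_arrays(r_arr, t_arr)
    t_rad = np.radians(t_b)
    sin_t = np.sin(t_rad)
    on_axis = sin_t < _SIN_EPS
    if np.any(on_axis & (r_b <= L / 2)):
        raise ValueError("geometry function undefined on-axis for r <= L/2")
    rho = r_b * sin_t
    z = r_b * np.cos(t_rad)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.arctan2(rho, z - L / 2) - np.arctan2(rho, z + L / 2)
        g_line = beta / (L * rho)
    g_axis = 1.0 / (r_b**2 - L**2 / 4)
    out = np.where(on_axis, g_axis, g_line)
    return float(out) if np.ndim(r) == 0 and np.ndim(theta) == 0 else out


def dose_rate_constant(dose_at_ref: float, s_k: float) -> float:
    """Lambda = D(1 cm, 90 deg) / S_K  (numerically cGy h^-1 U^-1)."""
    if dose_at_ref <= 0 or s_k <= 0:
        raise ValueError("dose and air-kerma strength must be positive")
    return dose_at_ref / s_k


def radial_dose_function(profile: TallyResult, L: float = 0.35) -> pd.DataFrame:
    """g(r) from a transverse-axis kerma profile.

    g(r) = [D(r)/D(1)] * [G_L(1, 90)/G_L(r, 90)], normalized exactly to 1
    at r = 1 cm; relative errors combine in quadrature (zero at 1 cm).
    """
    if profile.grid.kind != "rings":
        raise ValueError("radial_dose_function expects a ring tally")
    radii = profile.grid.r_centers
    at_ref = np.isclose(radii, 1.0, rtol=1e-6)
    if not at_ref.any():
        raise ValueError("transverse profile must include the r = 1 cm bin")
    d = profile.kerma_per_history
    rel = profile.rel_err
    j = int(np.flatnonzero(at_ref)[0])
    geom = geometry_function_line(radii, 90.0, L)
    g = (d / d[j]) * (geom[j] / geom)
    g_err = np.sqrt(rel**2 + rel[j] ** 2)
    g[j], g_err[j] = 1.0, 0.0
    return pd.DataFrame({"r_cm": radii, "g": g, "rel_err": g_err})


def anisotropy_function(polar_map: TallyResult, L: float = 0.35) -> pd.DataFrame:
    """F(r, theta) from an (r, theta) ring-tally map.

    F(r, theta) = [D(r, theta)/D(r, 90)] * [G_L(r, 90)/G_L(r, theta)],
    exactly 1 at theta = 90 for every radius.  Returns a long-format frame
    with columns r_cm, theta_deg, F, rel_err.
    """
    if polar_map.grid.kind != "rings":
        raise ValueError("anisotropy_function expects a ring tally")
    rc = polar_map.grid.r_centers
    tc = polar_map.grid.th_centers
    d = polar_map.kerma_per_history
    rel = polar_map.rel_err
    rows = []
    for r in np.unique(rc):
        sel = np.isclose(rc, r, rtol=1e-6)
        at90 = sel & np.isclose(tc, 90.0, atol=1e-9)
        if not at90.any():
            raise ValueError(f"polar map lacks a 90 deg bin at r = {r} cm")
        j = int(np.flatnonzero(at90)[0])
        geom = geometry_function_line(r, tc[sel], L)
        geom90 = geometry_function_line(r, 90.0, L)
        f_vals = (d[sel] / d[j]) * (geom90 / geom)
        f_err = np.sqrt(rel[sel] ** 2 + rel[j] ** 2)
        exact = np.isclose(tc[sel], 90.0, atol=1e-9)
        f_vals[exact], f_err[exact] = 1.0, 0.0
        for theta, fv, fe in zip(tc[sel], f_vals, f_err):
            rows.append((float(r), float(theta), float(fv), float(fe)))
    return pd.DataFrame(rows, columns=["r_cm", "theta_deg", "F", "rel_err"])


def dose_ratio_curves(profile_medium: TallyResult,
                      profile_water: TallyResult) -> pd.DataFrame:
    """Transverse dose ratio medium/water on a shared radial grid.

    Both profiles are per-history kerma from the same source model, so the
    ratio is already per unit air-kerma strength.
    """
    r_m = profile_medium.grid.r_centers
    r_w = profile_water.grid.r_centers
    if r_m.size != r_w.size or not np.allclose(r_m, r_w, rtol=1e-9):
        raise ValueError("profiles must share the same radial grid")
    ratio = profile_medium.kerma_per_history / profile_water.kerma_per_history
    rel = np.sqrt(profile_medium.rel_err**2 + profile_water.rel_err**2)
    return pd.DataFrame({"r_cm": r_m, "ratio": ratio, "rel_err": rel})


def compute_air_kerma_strength(source: SourceGeometry | None,
                               spectrum: PhotonSpectrum, n_histories: int,
                               seed: int, distances=(50.0, 100.0),
                               cutoff: float = 0.005):
    """Air-kerma strength per history, U = (MeV/g) cm^2 per history.

    Transports photons through the capsule into a vacuum world and scores
    air collision kerma in thin transverse rings at the given distances;
    S_K = K_air(d) * d^2 averaged over them.  In vacuum K d^2 must be
    distance-independent, so a >3 sigma disagreement raises (it flags a
    geometry bug rather than statistics).

    Returns ``(s_k, rel_err)``.
    """
    from .transport import PhantomSpec, run_transport

    air = build_attenuation_table(load_material("dry_air"))
    distances = np.asarray(distances, dtype=float)
    world = PhantomSpec(shape="sphere", diameter=2.0 * (distances.max() + 10.0),
                        medium=None)
    grid = transverse_rings(distances, theta_half=1.0, radial_half=0.5,
                            label="air_kerma", scoring_material=air)
    (res,) = run_transport(source, spectrum, world, [grid],
                           n_histories=n_histories, seed=seed, cutoff=cutoff)
    kd2 = res.kerma_per_history * distances**2
    sig = kd2 * res.rel_err
    if distances.size > 1:
        spread = abs(kd2[0] - kd2[-1])
        if spread > 3.0 * np.sqrt(sig[0] ** 2 + sig[-1] ** 2) and spread > 0:
            raise RuntimeError(
                "K*d^2 differs between scoring distances by more than 3 sigma; "
                "inverse-square invariance is violated")
    wgt = 1.0 / np.maximum(sig, 1e-300) ** 2
    s_k = float(np.sum(kd2 * wgt) / np.sum(wgt))
    rel = float(1.0 / np.sqrt(np.sum(wgt)) / s_k)
    return s_k, rel


@dataclass
class TG43Parameters:
    """Extracted TG-43 quantities for one medium/phantom combination."""

    medium: str
    phantom_diameter: float
    s_k_per_history: float
    lambda_const: float
    g_table: pd.DataFrame
    f_table: pd.DataFrame
    active_length: float = 0.35

    def __post_init__(self):
        if self.lambda_const <= 0:
            raise ValueError("dose-rate constant must be positive")

    def g(self, r):
        """Linear interpolation of g(r) between tabulated radii."""
        return np.interp(r, self.g_table["r_cm"], self.g_table["g"])

    def anisotropy(self, r, theta):
        """Bilinear interpolation of F(r, theta) between tabulated nodes."""
        from scipy.interpolate import RegularGridInterpolator

        pivot = self.f_table.pivot(index="r_cm", columns="theta_deg",
                                   values="F")
        interp = RegularGridInterpolator(
            (pivot.index.to_numpy(), pivot.columns.to_numpy()),
            pivot.to_numpy(), bounds_error=False, fill_value=None)
        pts = np.broadcast_arrays(np.asarray(r, float), np.asarray(theta, float))
        out = interp(np.stack([p.ravel() for p in pts], axis=-1))
        return float(out[0]) if np.ndim(r) == 0 and np.ndim(theta) == 0 \
            else out.reshape(pts[0].shape)
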