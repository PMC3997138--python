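"""Analytic stand-in dose fields and toy physics worlds.

These generators produce :class:`~brachymc.tallies.TallyResult`-shaped
objects from closed-form dose models (isotropic point source, TG-43
composite line-source field) and single-material toy worlds with constant
cross sections.  They make the TG-43 extraction stage and the transport
oracles testable without running the full simulation, and are deterministic
and pure in their parameters (no randomness, zero quoted uncertainty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .materials import AttenuationTable, Material
from .tallies import TallyGrid, TallyResult, polar_rings, transverse_rings
from .tg43 import geometry_function_line


def _result_from_values(grid: TallyGrid, values: np.ndarray) -> TallyResult:
    if np.any(values <= 0):
        raise ValueError("analytic fields must be strictly positive")
    return TallyResult(grid=grid, kerma_per_history=np.asarray(values, float),
                       rel_err=np.zeros(grid.n_bins), n_histories=0, seed=None)


@dataclass(frozen=True)
class AnalyticField:
    """A named closed-form dose field evaluated on a ring grid."""

    generator: str
    parameters: dict
    grid: TallyGrid
    values: np.ndarray = field(repr=False)

    def to_tally(self) -> TallyResult:
        return _result_from_values(self.grid, self.values)


def make_point_field(mu: float, mu_en_rho: float, radii,
                     thetas=None) -> TallyResult:
    """Exponentially attenuated isotropic point-source kerma field.

    D(r) = mu_en_rho * exp(-mu r) / (4 pi r^2); evaluated at ring centers.
    With ``thetas`` given, returns an (r, theta) polar map (isotropic, so
    the values depend on r only); otherwise a transverse profile.
    """
    if thetas is None:
        grid = transverse_rings(radii, label="point_field")
    else:
        grid = polar_rings(radii, thetas, label="point_field")
    r = grid.r_centers
    vals = mu_en_rho * np.exp(-mu * r) / (4.0 * np.pi * r**2)
    return _result_from_values(grid, vals)


def make_tg43_field(lambda0: float, g0: Callable, f0: Callable,
                    L: float, radii, thetas=None) -> TallyResult:
    """Composite TG-43 field D = Lambda0 * G_L/G_L(1,90) * g0(r) * F0(r,th).

    ``g0`` maps r -> g, ``f0`` maps (r, theta) -> F (vectorized or scalar).
    Feeding the result through the extraction stage must round-trip
    Lambda0, g0 and F0 to machine precision.
    """
    if thetas is None:
        grid = transverse_rings(radii, label="tg43_field")
    else:
        grid = polar_rings(radii, thetas, label="tg43_field")
    r = grid.r_centers
    th = grid.th_centers
    geom = geometry_function_line(r, th, L) / geometry_function_line(1.0, 90.0, L)
    g_vals = np.asarray(g0(r), dtype=float)
    f_vals = np.asarray(f0(r, th), dtype=float)
    vals = lambda0 * geom * g_vals * f_vals
    return _result_from_values(grid, vals)


def table_interpolator(x, y) -> Callable:
    """Monotone-safe (PCHIP) 1-D interpolant through a reference table."""
    from scipy.interpolate import PchipInterpolator

    return PchipInterpolator(np.asarray(x, float), np.asarray(y, float))


def make_toy_world(mu_pe: float, mu_incoh: float, mu_coh: float,
                   mu_en_over_rho: float | None = None,
                   density: float = 1.0,
                   energy_range=(1e-3, 2.0)) -> tuple[Material, AttenuationTable]:
    """Single-element toy medium with energy-independent coefficients.

    Enables the closed-form transport oracles: a pure absorber
    (``mu_incoh = mu_coh = 0``), a zero-attenuation scorer (all mu zero
    with a nonzero ``mu_en_over_rho``), or an everything-absorbed world
    (``mu_en_over_rho * density == mu_pe``).
    """
    if min(mu_pe, mu_incoh, mu_coh) < 0:
        raise ValueError("coefficients must be nonnegative")
    mat = Material(name="toy", density=density, composition={"H": 1.0})
    grid = np.array([energy_range[0], np.sqrt(energy_range[0] * energy_range[1]),
                     energy_range[1]])
    ones = np.ones_like(grid)
    if mu_en_over_rho is None:
        mu_en_over_rho = (mu_pe + mu_incoh) / density
    table = AttenuationTable(
        material=mat, energy_grid=grid,
        mu_photoelectric=mu_pe * ones, mu_incoherent=mu_incoh * ones,
        mu_coherent=mu_coh * ones, mu_en_over_rho=mu_en_over_rho * ones)
    return mat, table
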