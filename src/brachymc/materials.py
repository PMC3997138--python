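"""Materials, photon interaction-coefficient tables and the Ir-192 spectrum.

The bundled fixtures are per-element mass attenuation / energy-absorption
coefficient tables on a shared log energy grid (5 keV - 1.5 MeV) and the
Ir-192 photon line list.  Compound coefficients follow the mass-fraction
mixture rule; linear coefficients scale with density.  All interpolation is
log-log, exact at grid points, with no extrapolation outside the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .constants import MATERIALS

_DATA_DIR = Path(__file__).parent / "data"

_CHANNELS = ("total", "photoelectric", "incoherent", "coherent", "mu_en")
_CHANNEL_COLS = {
    "total": "mu_rho_total",
    "photoelectric": "mu_rho_pe",
    "incoherent": "mu_rho_incoh",
    "coherent": "mu_rho_coh",
    "mu_en": "mu_en_rho",
}


@dataclass(frozen=True)
class Material:
    """A scoring/transport medium: name, bulk density and composition.

    ``composition`` maps element symbols to mass fractions (summing to 1).
    """

    name: str
    density: float  # g/cm^3
    composition: dict[str, float]

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1"
            )


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete photon emission lines (energy in MeV, photons per decay)."""

    energies: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if e.shape != i.shape or e.ndim != 1 or e.size == 0:
            raise ValueError("energies and intensities must be matching 1-D arrays")
        if np.any(i <= 0):
            raise ValueError("all line intensities must be positive")
        if np.any(np.diff(e) <= 0):
            raise ValueError("lines must be sorted strictly ascending in energy")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "intensities", i)

    @property
    def lines(self) -> list[tuple[float, float]]:
        return list(zip(self.energies.tolist(), self.intensities.tolist()))

    @property
    def total_yield(self) -> float:
        """Photons emitted per decay (sum of line intensities)."""
        return float(self.intensities.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.intensities / self.intensities.sum()

    @property
    def mean_energy(self) -> float:
        """Intensity-weighted mean line energy (MeV)."""
        return float(np.average(self.energies, weights=self.intensities))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` line energies with probability proportional to intensity."""
        idx = rng.choice(self.energies.size, size=n, p=self.probabilities)
        return self.energies[idx]


class AttenuationTable:
    """Linear attenuation coefficients of one material on an energy grid.

    Stores the partial channels (photoelectric, incoherent, coherent) in
    cm^-1, their sum as the total, and the mass energy-absorption
    coefficient mu_en/rho in cm^2/g.  Lookups are log-log interpolated.
    """

    def __init__(self, material: Material, energy_grid: np.ndarray,
                 mu_photoelectric: np.ndarray, mu_incoherent: np.ndarray,
                 mu_coherent: np.ndarray, mu_en_over_rho: np.ndarray):
        self.material = material
        self.energy_grid = np.asarray(energy_grid, dtype=float)
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        self.mu_photoelectric = np.asarray(mu_photoelectric, dtype=float)
        self.mu_incoherent = np.asarray(mu_incoherent, dtype=float)
        self.mu_coherent = np.asarray(mu_coherent, dtype=float)
        self.mu_total = self.mu_photoelectric + self.mu_incoherent + self.mu_coherent
        self.mu_en_over_rho = np.asarray(mu_en_over_rho, dtype=float)
        self._log_e = np.log(self.energy_grid)
        self._logs = {
            "total": np.log(np.maximum(self.mu_total, 1e-300)),
            "photoelectric": np.log(np.maximum(self.mu_photoelectric, 1e-300)),
            "incoherent": np.log(np.maximum(self.mu_incoherent, 1e-300)),
            "coherent": np.log(np.maximum(self.mu_coherent, 1e-300)),
            "mu_en": np.log(np.maximum(self.mu_en_over_rho, 1e-300)),
        }

    def __call__(self, energy, channel: str = "total"):
        return interpolate_mu(self, energy, channel)


def interpolate_mu(table: AttenuationTable, energy, channel: str = "total"):
    """Log-log interpolate a coefficient; exact at grid points.

    ``channel`` is one of total | photoelectric | incoherent | coherent |
    mu_en.  Energies outside the table grid raise (no extrapolation).
    """
    if channel not in _CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; valid: {_CHANNELS}")
    e = np.asarray(energy, dtype=float)
    lo, hi = table.energy_grid[0], table.energy_grid[-1]
    if np.any(e < lo * (1 - 1e-12)) or np.any(e > hi * (1 + 1e-12)):
        raise ValueError(
            f"energy outside table range [{lo:g}, {hi:g}] MeV for "
            f"{table.material.name!r}"
        )
    out = np.exp(np.interp(np.log(np.clip(e, lo, hi)), table._log_e,
                           table._logs[channel]))
    return float(out) if np.ndim(energy) == 0 else out


def load_material(name: str) -> Material:
    """Return a bundled material by name.

    Valid names: water, cortical_bone, inflated_lung, polystyrene,
    stainless_steel, iridium, dry_air.  Tissues use ICRU-44 compositions.
    """
    try:
        density, comp = MATERIALS[name]
    except KeyError:
        valid = ", ".join(sorted(MATERIALS))
        raise ValueError(f"unknown material {name!r}; valid names: {valid}") from None
    return Material(name=name, density=density, composition=dict(comp))


@lru_cache(maxsize=None)
def _element_data(symbol: str) -> dict[str, np.ndarray]:
    path = _DATA_DIR / "elements" / f"{symbol}.csv"
    if not path.exists():
        raise ValueError(f"no bundled coefficient table for element {symbol!r}")
    raw = np.genfromtxt(path, delimiter=",", names=True)
    return {name: np.asarray(raw[name], dtype=float) for name in raw.dtype.names}


def bundled_energy_grid() -> np.ndarray:
    """The shared energy grid of the bundled elemental tables (MeV)."""
    return _element_data("O")["energy_MeV"].copy()


def build_attenuation_table(material: Material,
                            energy_grid: np.ndarray | None = None) -> AttenuationTable:
    """Assemble an :class:`AttenuationTable` via the mixture rule.

    Elemental mass coefficients are log-log interpolated onto
    ``energy_grid`` (default: the bundled grid), combined with the
    material's mass fractions, and scaled by density to linear
    coefficients.  The grid must lie within the bundled 5 keV - 1.5 MeV
    range.
    """
    grid = bundled_energy_grid() if energy_grid is None else np.asarray(energy_grid, float)
    ref = bundled_energy_grid()
    if grid[0] < ref[0] * (1 - 1e-12) or grid[-1] > ref[-1] * (1 + 1e-12):
        raise ValueError(
            f"requested grid [{grid[0]:g}, {grid[-1]:g}] MeV exceeds the "
            f"bundled coverage [{ref[0]:g}, {ref[-1]:g}] MeV"
        )
    cols = {c: np.zeros_like(grid) for c in _CHANNEL_COLS.values()}
    logg = np.log(grid)
    for sym, w in material.composition.items():
        data = _element_data(sym)
        log_e = np.log(data["energy_MeV"])
        for col in cols:
            vals = np.exp(np.interp(logg, log_e, np.log(np.maximum(data[col], 1e-300))))
            cols[col] += w * vals
    rho = material.density
    return AttenuationTable(
        material=material,
        energy_grid=grid,
        mu_photoelectric=rho * cols["mu_rho_pe"],
        mu_incoherent=rho * cols["mu_rho_incoh"],
        mu_coherent=rho * cols["mu_rho_coh"],
        mu_en_over_rho=cols["mu_en_rho"],
    )


@lru_cache(maxsize=1)
def ir192_spectrum() -> PhotonSpectrum:
    """The bundled Ir-192 photon line spectrum (gamma + fluorescence X rays).

    Beta emissions are excluded; line energies span 0.0089 - 1.0615 MeV.
    """
    raw = np.genfromtxt(_DATA_DIR / "ir192_lines.csv", delimiter=",", names=True)
    order = np.argsort(raw["energy_MeV"])
    return PhotonSpectrum(
        energies=np.asarray(raw["energy_MeV"], float)[order],
        intensities=np.asarray(raw["intensity"], float)[order],
    )
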