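"""Analog photon Monte Carlo with track-length collision-kerma scoring.

The simulation is the collision-kerma analogue of an MCNP F6 run: photons
are transported analogically (exponential free paths, interaction channel
chosen proportionally to the partial attenuation coefficients,
Klein-Nishina incoherent scattering, Thomson-law coherent redirection,
photoelectric absorption), electrons are assumed to deposit their energy on
the spot, and kerma is accumulated with a track-length estimator along
every flight segment.  Photons leaving the phantom are discarded; photons
falling below the energy cutoff are terminated.

Transport starts inside the source capsule: each primary is followed
analogically through the iridium core and steel capsule/cable segments, so
source self-absorption and capsule scatter are part of the analog game.
Once a photon has left the convex capsule envelope the capsule is no longer
modelled (re-entry of scattered photons into the 1.1 mm capsule is a
sub-0.1% effect at the tally radii used here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kleinnishina import sample_compton, sample_thomson_cosine
from .materials import AttenuationTable, Material, PhotonSpectrum, build_attenuation_table
from .source import (IRIDIUM, STEEL, SourceGeometry, isotropic_directions,
                     sample_emission, trace_batch)
from .tallies import TallyAccumulator, TallyGrid, TallyResult

__all__ = ["PhantomSpec", "run_transport", "sample_compton"]


@dataclass
class PhantomSpec:
    """Homogeneous phantom containing the source at its center.

    shape = "sphere" (diameter cm) or "cylinder" (diameter, height cm).
    ``medium=None`` gives a vacuum world (used for air-kerma strength runs),
    in which case a finite ``diameter`` still bounds the flight paths.
    """

    shape: str = "sphere"
    diameter: float = 30.0
    height: float | None = None
    medium: Material | None = None
    table: AttenuationTable | None = None

    def __post_init__(self):
        if self.shape not in ("sphere", "cylinder"):
            raise ValueError("shape must be 'sphere' or 'cylinder'")
        if self.shape == "cylinder" and self.height is None:
            raise ValueError("cylinder phantoms need a height")
        if self.diameter <= 0.5:
            raise ValueError("phantom must fully contain the source capsule")
        if self.medium is not None and self.table is None:
            self.table = build_attenuation_table(self.medium)

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    def boundary_distance(self, p: np.ndarray, d: np.ndarray) -> np.ndarray:
        """Distance to the phantom surface from interior points."""
        if self.shape == "sphere":
            b = np.einsum("ij,ij->i", p, d)
            c = np.einsum("ij,ij->i", p, p) - self.radius**2
            return -b + np.sqrt(np.maximum(b * b - c, 0.0))
        dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
        a = dx**2 + dy**2
        b = p[:, 0] * dx + p[:, 1] * dy
        c = p[:, 0] ** 2 + p[:, 1] ** 2 - self.radius**2
        with np.errstate(invalid="ignore", divide="ignore"):
            t_rad = np.where(a > 1e-18,
                             (-b + np.sqrt(np.maximum(b * b - a * c, 0.0))) / a,
                             np.inf)
            half_h = 0.5 * self.height
            t_ax = np.where(dz > 1e-18, (half_h - p[:, 2]) / dz,
                            np.where(dz < -1e-18, (-half_h - p[:, 2]) / dz, np.inf))
        return np.minimum(t_rad, t_ax)


class _MuLookup:
    """Fast vectorized log-log coefficient lookup for one material table."""

    def __init__(self, table: AttenuationTable, coherent: bool):
        self._log_e = np.log(table.energy_grid)
        tiny = 1e-300
        self._total = np.log(np.maximum(
            table.mu_total if coherent else
            table.mu_photoelectric + table.mu_incoherent, tiny))
        self._pe = np.log(np.maximum(table.mu_photoelectric, tiny))
        self._incoh = np.log(np.maximum(table.mu_incoherent, tiny))
        self._coh = np.log(np.maximum(table.mu_coherent, tiny))
        self._mu_en = np.log(np.maximum(table.mu_en_over_rho, tiny))

    def _interp(self, logs, e):
        return np.exp(np.interp(np.log(e), self._log_e, logs))

    def total(self, e):
        return self._interp(self._total, e)

    def channels(self, e):
        return (self._interp(self._pe, e), self._interp(self._incoh, e),
                self._interp(self._coh, e))

    def mu_en(self, e):
        return self._interp(self._mu_en, e)


def _rotate(d: np.ndarray, cos_t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vectors by polar angle arccos(cos_t), uniform azimuth."""
    n = d.shape[0]
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
    # orthonormal frame around each direction
    helper = np.zeros_like(d)
    near_z = np.abs(d[:, 2]) > 0.99
    helper[near_z, 0] = 1.0
    helper[~near_z, 2] = 1.0
    u = np.cross(helper, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    new = (cos_t[:, None] * d
           + sin_t[:, None] * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v))
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def _interact(e, d, mu_pe, mu_incoh, mu_coh, rng, cutoff, coherent):
    """One analog collision for each photon; returns survivors' (e, d, alive)."""
    mu_tot = mu_pe + mu_incoh + (mu_coh if coherent else 0.0)
    u = rng.random(e.size) * mu_tot
    is_pe = u < mu_pe
    is_incoh = ~is_pe & (u < mu_pe + mu_incoh)
    is_coh = ~is_pe & ~is_incoh
    alive = ~is_pe
    e_new = e.copy()
    d_new = d.copy()
    if is_incoh.any():
        e_sc, mu_sc = sample_compton(e[is_incoh], rng)
        e_new[is_incoh] = e_sc
        d_new[is_incoh] = _rotate(d[is_incoh], mu_sc, rng)
        alive[is_incoh] &= e_sc >= cutoff
    if is_coh.any():
        mu_sc = sample_thomson_cosine(int(is_coh.sum()), rng)
        d_new[is_coh] = _rotate(d[is_coh], mu_sc, rng)
    return e_new, d_new, alive


def _through_source(p, d, e, geometry, mu_by_mat, rng, cutoff, coherent,
                    max_gen: int = 200):
    """Analog transport inside the core/capsule; returns escapees."""
    out_p: list[np.ndarray] = []
    out_d: list[np.ndarray] = []
    out_e: list[np.ndarray] = []
    for _ in range(max_gen):
        if e.size == 0:
            break
        lengths, mats, t_env = trace_batch(p, d, geometry)
        e3 = np.broadcast_to(e[:, None], lengths.shape)
        mu = np.empty_like(lengths)
        for code in (IRIDIUM, STEEL):
            sel = mats == code
            if sel.any():
                mu[sel] = mu_by_mat[code].total(e3[sel])
        tau_cum = np.cumsum(lengths * mu, axis=1)
        xi = rng.exponential(size=e.size)
        escaped = xi >= tau_cum[:, -1]
        if escaped.any():
            out_p.append(p[escaped] + t_env[escaped, None] * d[escaped])
            out_d.append(d[escaped])
            out_e.append(e[escaped])
        stay = ~escaped
        if not stay.any():
            break
        # locate the collision segment and point for the interacting rest
        k = np.minimum(np.sum(tau_cum[stay] < xi[stay, None], axis=1), 2)
        rows = np.arange(k.size)
        seg_ends = np.cumsum(lengths[stay], axis=1)
        tau_prev = np.where(k > 0, tau_cum[stay][rows, np.maximum(k - 1, 0)], 0.0)
        seg_start = np.where(k > 0, seg_ends[rows, np.maximum(k - 1, 0)], 0.0)
        mu_k = mu[stay][rows, k]
        t_int = seg_start + (xi[stay] - tau_prev) / np.maximum(mu_k, 1e-300)
        p_int = p[stay] + t_int[:, None] * d[stay]
        e_s, d_s = e[stay], d[stay]
        # channel selection with the local material's partials
        mats_k = mats[stay][rows, k]
        mu_pe = np.empty_like(e_s)
        mu_ic = np.empty_like(e_s)
        mu_co = np.empty_like(e_s)
        for code in (IRIDIUM, STEEL):
            sel = mats_k == code
            if sel.any():
                mu_pe[sel], mu_ic[sel], mu_co[sel] = \
                    mu_by_mat[code].channels(e_s[sel])
        e_n, d_n, alive = _interact(e_s, d_s, mu_pe, mu_ic, mu_co, rng,
                                    cutoff, coherent)
        p, d, e = p_int[alive], d_n[alive], e_n[alive]
    else:
        raise RuntimeError("in-source transport failed to terminate")
    if not out_e:
        return np.empty((0, 3)), np.empty((0, 3)), np.empty(0)
    return (np.concatenate(out_p), np.concatenate(out_d), np.concatenate(out_e))


def run_transport(source: SourceGeometry | None, spectrum: PhotonSpectrum,
                  phantom: PhantomSpec, tallies: Sequence[TallyGrid],
                  n_histories: int, seed: int, *, coherent: bool = True,
                  cutoff: float = 0.005, n_batches: int = 40,
                  max_generations: int = 10_000) -> list[TallyResult]:
    """Run the analog simulation and return one TallyResult per grid.

    ``source=None`` emits from an isotropic point at the origin (no
    capsule), which the analytic-oracle tests rely on.  Results are
    bit-reproducible for a given (config, seed, n_batches).
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    if not tallies:
        raise ValueError("at least one tally grid is required")
    if cutoff >= float(np.max(spectrum.energies)):
        raise ValueError("cutoff energy is above every spectrum line")

    rng = np.random.default_rng(seed)
    vacuum = phantom.medium is None
    phantom_mu = None if vacuum else _MuLookup(phantom.table, coherent)

    mu_by_mat = None
    if source is not None:
        mu_by_mat = {
            IRIDIUM: _MuLookup(build_attenuation_table(source.core_material),
                               coherent),
            STEEL: _MuLookup(build_attenuation_table(source.capsule_material),
                             coherent),
        }

    # per-tally scoring mu_en/rho lookups (default: the phantom medium)
    score_lookups: list[_MuLookup | None] = []
    for grid in tallies:
        if grid.scoring_material is not None:
            score_lookups.append(_MuLookup(grid.scoring_material, coherent))
        else:
            if vacuum:
                raise ValueError(
                    "vacuum-world tallies need an explicit scoring_material")
            score_lookups.append(phantom_mu)

    accs = [TallyAccumulator(grid, n_batches) for grid in tallies]
    bounds = np.linspace(0, n_histories, n_batches + 1).astype(int)

    for batch in range(n_batches):
        n = int(bounds[batch + 1] - bounds[batch])
        if n == 0:
            continue
        if source is None:
            p = np.zeros((n, 3))
            d = isotropic_directions(n, rng)
            e = spectrum.sample(n, rng)
        else:
            em = sample_emission(source, spectrum, n, rng)
            p, d, e = _through_source(em.positions, em.directions, em.energies,
                                      source, mu_by_mat, rng, cutoff, coherent)
        for _ in range(max_generations):
            if e.size == 0:
                break
            t_bound = phantom.boundary_distance(p, d)
            if vacuum:
                s = t_bound
                leaving = np.ones(e.size, dtype=bool)
            else:
                mu_t = phantom_mu.total(e)
                s_free = rng.exponential(size=e.size) / mu_t
                leaving = s_free >= t_bound
                s = np.where(leaving, t_bound, s_free)
            for acc, look in zip(accs, score_lookups):
                w = e * look.mu_en(e)
                acc.score(batch, p, d, s, w)
            stay = ~leaving
            if not stay.any():
                break
            p = p[stay] + s[stay, None] * d[stay]
            mu_pe, mu_ic, mu_co = phantom_mu.channels(e[stay])
            e, d, alive = _interact(e[stay], d[stay], mu_pe, mu_ic, mu_co,
                                    rng, cutoff, coherent)
            p, d, e = p[alive], d[alive], e[alive]
        else:
            raise RuntimeError("phantom transport failed to terminate")

    return [acc.finalize(n_histories, seed) for acc in accs]
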