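"""Tally grids and track-length collision-kerma scoring.

Kerma is scored with the track-length estimator: every photon flight
segment adds  E * (mu_en/rho)(E) * chord / volume  to each bin it
traverses, giving collision kerma per history in MeV/g.  Uncertainties come
from history-batch statistics (one batch per transport chunk).

Grids exploit the azimuthal symmetry of the source + phantom: all bins are
full azimuthal rings (or spherical shells / 2-D cylindrical pixels).  Polar
angles are measured from the source axis; by default theta = 0 is the
proximal (cable) pole, matching the usual published table orientation for
this source, and can be flipped with ``theta_zero="tip"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .materials import AttenuationTable, Material


def radial_half_width(r: float) -> float:
    """Default ring half-thickness (cm): finer bins close to the source."""
    if r <= 1.0:
        return 0.025
    if r <= 5.0:
        return 0.05
    return 0.1


def polar_half_width(theta: float) -> float:
    """Default polar half-width (degrees): finer near the poles."""
    return 0.5 if (theta <= 10.0 or theta >= 170.0) else 2.5


@dataclass
class TallyGrid:
    """One tally: a set of azimuthal-ring bins, shells, or a 2-D matrix.

    kind = "rings":   bins are (r_lo, r_hi) x (th_lo, th_hi) rings,
    kind = "shells":  a contiguous radial-shell partition (full 4pi),
    kind = "matrix2d": cylindrical (radial x axial) pixels.
    """

    kind: str
    label: str = "tally"
    r_lo: np.ndarray | None = None
    r_hi: np.ndarray | None = None
    th_lo: np.ndarray | None = None
    th_hi: np.ndarray | None = None
    r_edges: np.ndarray | None = None       # shells
    rho_edges: np.ndarray | None = None     # matrix2d
    z_edges: np.ndarray | None = None       # matrix2d
    theta_zero: str = "cable"
    scoring_material: AttenuationTable | None = None
    r_nom: np.ndarray | None = None   # nominal ring radii (pre-clipping)
    th_nom: np.ndarray | None = None  # nominal polar angles (pre-clipping)

    def __post_init__(self):
        if self.kind not in ("rings", "shells", "matrix2d"):
            raise ValueError(f"unknown tally kind {self.kind!r}")
        if self.theta_zero not in ("cable", "tip"):
            raise ValueError("theta_zero must be 'cable' or 'tip'")
        if self.kind == "rings":
            for name in ("r_lo", "r_hi", "th_lo", "th_hi"):
                setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if np.any(self.r_hi <= self.r_lo) or np.any(self.th_hi <= self.th_lo):
                raise ValueError("ring bins must have positive extent")
            if self.r_nom is None:
                self.r_nom = 0.5 * (self.r_lo + self.r_hi)
            else:
                self.r_nom = np.asarray(self.r_nom, dtype=float)
            if self.th_nom is None:
                self.th_nom = 0.5 * (self.th_lo + self.th_hi)
            else:
                self.th_nom = np.asarray(self.th_nom, dtype=float)
        elif self.kind == "shells":
            self.r_edges = np.asarray(self.r_edges, dtype=float)
            if np.any(np.diff(self.r_edges) <= 0):
                raise ValueError("shell edges must be strictly increasing")
        else:
            self.rho_edges = np.asarray(self.rho_edges, dtype=float)
            self.z_edges = np.asarray(self.z_edges, dtype=float)
            if np.any(np.diff(self.rho_edges) <= 0) or np.any(np.diff(self.z_edges) <= 0):
                raise ValueError("matrix edges must be strictly increasing")

    # ----- derived geometry -------------------------------------------------

    @property
    def n_bins(self) -> int:
        if self.kind == "rings":
            return self.r_lo.size
        if self.kind == "shells":
            return self.r_edges.size - 1
        return (self.rho_edges.size - 1) * (self.z_edges.size - 1)

    @property
    def volumes(self) -> np.ndarray:
        """Bin volumes in cm^3 (full azimuth)."""
        if self.kind == "rings":
            tl = np.radians(self.th_lo)
            th = np.radians(self.th_hi)
            return (2.0 * np.pi / 3.0) * (self.r_hi**3 - self.r_lo**3) * (
                np.cos(tl) - np.cos(th))
        if self.kind == "shells":
            r = self.r_edges
            return (4.0 * np.pi / 3.0) * np.diff(r**3)
        area = np.pi * np.diff(self.rho_edges**2)
        return np.outer(area, np.diff(self.z_edges)).ravel()

    @property
    def r_centers(self) -> np.ndarray:
        if self.kind == "rings":
            return self.r_nom
        if self.kind == "shells":
            return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])
        raise ValueError("matrix2d grids have no radial centers")

    @property
    def th_centers(self) -> np.ndarray:
        if self.kind != "rings":
            raise ValueError("only ring grids have polar centers")
        return self.th_nom

    @property
    def axis_sign(self) -> float:
        """Sign mapping physical z to the grid's polar axis (+z = tip)."""
        return -1.0 if self.theta_zero == "cable" else 1.0


# ----- factory helpers ------------------------------------------------------


def transverse_rings(radii, theta_half: float = 2.5, label: str = "transverse",
                     scoring_material: AttenuationTable | None = None,
                     radial_half: float | None = None,
                     clip_radius: float | None = None) -> TallyGrid:
    """Thin rings on the transverse axis (theta = 90 deg) at given radii.

    ``clip_radius`` truncates bins at the phantom surface so that a ring
    centered on the boundary is normalized by its in-phantom volume only.
    """
    radii = np.asarray(radii, dtype=float)
    half = np.array([radial_half_width(r) for r in radii]) \
        if radial_half is None else np.full(radii.shape, radial_half)
    r_hi = radii + half
    if clip_radius is not None:
        r_hi = np.minimum(r_hi, clip_radius)
    return TallyGrid(
        kind="rings", label=label,
        r_lo=radii - half, r_hi=r_hi,
        th_lo=np.full(radii.shape, 90.0 - theta_half),
        th_hi=np.full(radii.shape, 90.0 + theta_half),
        scoring_material=scoring_material, r_nom=radii,
    )


def polar_rings(radii, thetas, theta_zero: str = "cable",
                label: str = "polar",
                clip_radius: float | None = None) -> TallyGrid:
    """Ring bins at each (r, theta) node of an anisotropy-function map."""
    radii = np.asarray(radii, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    rr, tt = [a.ravel() for a in np.meshgrid(radii, thetas, indexing="ij")]
    rh = np.array([radial_half_width(r) for r in rr])
    th = np.array([polar_half_width(t) for t in tt])
    r_hi = rr + rh
    if clip_radius is not None:
        r_hi = np.minimum(r_hi, clip_radius)
    return TallyGrid(
        kind="rings", label=label,
        r_lo=rr - rh, r_hi=r_hi,
        th_lo=np.clip(tt - th, 0.0, 180.0),
        th_hi=np.clip(tt + th, 0.0, 180.0),
        theta_zero=theta_zero, r_nom=rr, th_nom=tt,
    )


def radial_shells(r_edges, label: str = "shells") -> TallyGrid:
    """A contiguous full-sphere shell partition (for oracles/diagnostics)."""
    return TallyGrid(kind="shells", label=label, r_edges=r_edges)


def matrix2d(rho_edges, z_edges, label: str = "matrix2d") -> TallyGrid:
    """Cylindrical (radial x axial) pixel grid for 2-D dose matrices."""
    return TallyGrid(kind="matrix2d", label=label,
                     rho_edges=rho_edges, z_edges=z_edges)


# ----- scoring --------------------------------------------------------------


class TallyAccumulator:
    """Per-batch running sums of track-length kerma for one grid."""

    def __init__(self, grid: TallyGrid, n_batches: int):
        self.grid = grid
        self.sums = np.zeros((n_batches, grid.n_bins))

    def score(self, batch: int, p: np.ndarray, d: np.ndarray,
              s: np.ndarray, w: np.ndarray) -> None:
        """Score flight segments (start p, unit direction d, length s).

        ``w`` is the per-segment weight E * (mu_en/rho)(E) in MeV cm^2/g,
        already evaluated with this tally's scoring medium.
        """
        if s.size == 0:
            return
        if self.grid.kind == "rings":
            self._score_rings(batch, p, d, s, w)
        elif self.grid.kind == "shells":
            self._score_shells(batch, p, d, s, w)
        else:
            self._score_matrix(batch, p, d, s, w)

    # sphere-interval algebra: the set {t : |p + t d| < R} is a single
    # interval; chord in a shell is the outer interval minus the inner one.
    def _score_rings(self, batch, p, d, s, w):
        g = self.grid
        b = np.einsum("ij,ij->i", p, d)
        c = np.einsum("ij,ij->i", p, p)
        pz, dz = p[:, 2], d[:, 2]
        sign = g.axis_sign
        cos_hi = np.cos(np.radians(g.th_lo))  # cos decreases with theta
        cos_lo = np.cos(np.radians(g.th_hi))
        vols = g.volumes
        for j in range(g.n_bins):
            t_out = _sphere_interval(b, c, g.r_hi[j])
            if t_out is None:
                continue
            a0 = np.clip(t_out[0], 0.0, s)
            a1 = np.clip(t_out[1], 0.0, s)
            t_in = _sphere_interval(b, c, g.r_lo[j])
            if t_in is None:
                b0, b1 = a1, a1
            else:
                b0 = np.clip(t_in[0], a0, a1)
                b1 = np.clip(t_in[1], a0, a1)
                b1 = np.maximum(b0, b1)
            total = 0.0
            for lo, hi in ((a0, b0), (b1, a1)):
                ln = hi - lo
                mask = ln > 0.0
                if not mask.any():
                    continue
                tm = 0.5 * (lo + hi)
                zm = sign * (pz + tm * dz)
                rm = np.sqrt(np.maximum(c + tm * (2.0 * b + tm), 1e-300))
                mu = zm / rm
                ok = mask & (mu >= cos_lo[j] - 1e-12) & (mu <= cos_hi[j] + 1e-12)
                if ok.any():
                    total += float(np.sum(w[ok] * ln[ok]))
            self.sums[batch, j] += total / vols[j]

    def _score_shells(self, batch, p, d, s, w):
        g = self.grid
        b = np.einsum("ij,ij->i", p, d)
        c = np.einsum("ij,ij->i", p, p)
        vols = g.volumes
        prev = _chord_inside(b, c, g.r_edges[0], s)
        for j in range(g.n_bins):
            cur = _chord_inside(b, c, g.r_edges[j + 1], s)
            chord = cur - prev
            self.sums[batch, j] += float(np.sum(w * chord)) / vols[j]
            prev = cur

    def _score_matrix(self, batch, p, d, s, w, n_sub: int = 64):
        g = self.grid
        frac = (np.arange(n_sub) + 0.5) / n_sub
        t = s[:, None] * frac[None, :]
        x = p[:, 0, None] + t * d[:, 0, None]
        y = p[:, 1, None] + t * d[:, 1, None]
        z = g.axis_sign * (p[:, 2, None] + t * d[:, 2, None])
        rho = np.hypot(x, y)
        wt = np.broadcast_to((w * s / n_sub)[:, None], t.shape)
        ir = np.searchsorted(g.rho_edges, rho.ravel()) - 1
        iz = np.searchsorted(g.z_edges, z.ravel()) - 1
        nr, nz = g.rho_edges.size - 1, g.z_edges.size - 1
        ok = (ir >= 0) & (ir < nr) & (iz >= 0) & (iz < nz)
        flat = ir[ok] * nz + iz[ok]
        np.add.at(self.sums[batch], flat, wt.ravel()[ok] / g.volumes[flat])

    def finalize(self, n_histories: int, seed: int | None = None) -> "TallyResult":
        n_batches = self.sums.shape[0]
        per_batch = self.sums * n_batches / n_histories  # per-history, per batch
        mean = per_batch.mean(axis=0)
        if n_batches > 1:
            sem = per_batch.std(axis=0, ddof=1) / np.sqrt(n_batches)
        else:
            sem = np.full_like(mean, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(mean > 0, sem / mean, np.inf)
        return TallyResult(grid=self.grid, kerma_per_history=mean,
                           rel_err=rel, n_histories=n_histories, seed=seed)


def _sphere_interval(b, c, radius):
    disc = b * b - c + radius * radius
    pos = disc > 0.0
    if not pos.any():
        return None
    root = np.sqrt(np.maximum(disc, 0.0))
    t0 = np.where(pos, -b - root, 1.0)
    t1 = np.where(pos, -b + root, 0.0)
    return t0, t1


def _chord_inside(b, c, radius, s):
    iv = _sphere_interval(b, c, radius)
    if iv is None:
        return np.zeros_like(s)
    return np.maximum(np.clip(iv[1], 0.0, s) - np.clip(iv[0], 0.0, s), 0.0)


def intersect_bins(segment, grid: TallyGrid):
    """Exact (bin index, chord length) attribution of one flight segment.

    ``segment`` is ``(start, direction, length)``.  Works for ring and
    shell grids; chords over all returned bins sum to the in-grid path.
    """
    start, direction, length = segment
    p = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    acc = TallyAccumulator(grid, n_batches=1)
    # score with unit weight, then convert kerma-sums back to chords
    acc.score(0, p[None, :], d[None, :], np.array([float(length)]),
              np.array([1.0]))
    chords = acc.sums[0] * grid.volumes
    return [(int(j), float(chords[j])) for j in np.flatnonzero(chords > 1e-12)]


@dataclass
class TallyResult:
    """Per-bin collision kerma per history (MeV/g) with 1-sigma rel. error."""

    grid: TallyGrid
    kerma_per_history: np.ndarray
    rel_err: np.ndarray
    n_histories: int
    seed: int | None = None

    def value_at(self, r: float, theta: float | None = None,
                 return_err: bool = False):
        """Kerma in the bin whose center matches (r[, theta])."""
        if self.grid.kind == "rings":
            rc, tc = self.grid.r_centers, self.grid.th_centers
            sel = np.isclose(rc, r, rtol=1e-6, atol=1e-9)
            if theta is not None:
                sel &= np.isclose(tc, theta, rtol=1e-6, atol=1e-9)
            elif np.count_nonzero(sel) > 1:
                sel &= np.isclose(tc, 90.0, atol=1e-9)
        elif self.grid.kind == "shells":
            sel = np.isclose(self.grid.r_centers, r, rtol=1e-6, atol=1e-9)
        else:
            raise ValueError("value_at is not defined for matrix2d tallies")
        idx = np.flatnonzero(sel)
        if idx.size != 1:
            raise KeyError(f"no unique bin at r={r}, theta={theta}")
        j = int(idx[0])
        if return_err:
            return float(self.kerma_per_history[j]), float(self.rel_err[j])
        return float(self.kerma_per_history[j])

    def to_dataframe(self) -> pd.DataFrame:
        g = self.grid
        if g.kind == "rings":
            return pd.DataFrame({
                "r_cm": g.r_centers, "theta_deg": g.th_centers,
                "kerma_per_history_MeV_g": self.kerma_per_history,
                "rel_err": self.rel_err,
            })
        if g.kind == "shells":
            return pd.DataFrame({
                "r_lo_cm": g.r_edges[:-1], "r_hi_cm": g.r_edges[1:],
                "kerma_per_history_MeV_g": self.kerma_per_history,
                "rel_err": self.rel_err,
            })
        nr, nz = g.rho_edges.size - 1, g.z_edges.size - 1
        rho_c = np.repeat(0.5 * (g.rho_edges[:-1] + g.rho_edges[1:]), nz)
        z_c = np.tile(0.5 * (g.z_edges[:-1] + g.z_edges[1:]), nr)
        return pd.DataFrame({
            "rho_cm": rho_c, "z_cm": z_c,
            "kerma_per_history_MeV_g": self.kerma_per_history,
            "rel_err": self.rel_err,
        })

    def to_csv(self, path, metadata: dict | None = None) -> None:
        """Write the tally as CSV plus a JSON run-metadata sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {"label": self.grid.label, "kind": self.grid.kind,
                "n_histories": self.n_histories, "seed": self.seed}
        if metadata:
            meta.update(metadata)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
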