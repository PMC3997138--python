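"""Geometric model of the microSelectron HDR Ir-192 source.

The source sits at the origin with its symmetry axis along z.  The active
iridium core is a cylinder of length 0.35 cm and radius 0.03 cm.  It is
surrounded by a solid stainless-steel capsule of outer radius 0.055 cm with
a 0.025 cm distal end cap (toward +z) and, on the proximal side (toward
-z), a cap plus a 0.2 cm drive-cable stub of the same outer radius.  The
steel envelope therefore spans z in [-0.4, +0.2] cm.

Primary photons are emitted uniformly throughout the core volume with
isotropic directions and line energies drawn from the Ir-192 spectrum;
self-absorption is handled downstream by transporting each photon through
the traced core/capsule segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import Material, PhotonSpectrum, load_material

IRIDIUM = 0
STEEL = 1


@dataclass(frozen=True)
class SourceGeometry:
    """Dimensions (cm) and materials of core, capsule and cable stub."""

    active_length: float = 0.35
    active_radius: float = 0.03
    capsule_outer_radius: float = 0.055
    capsule_distal_cap_thickness: float = 0.025
    cable_length: float = 0.2
    cable_radius: float = 0.055
    core_material: Material = field(default_factory=lambda: load_material("iridium"))
    capsule_material: Material = field(
        default_factory=lambda: load_material("stainless_steel"))

    def __post_init__(self):
        if self.active_length <= 0:
            raise ValueError("active_length must be positive")
        if self.active_radius >= self.capsule_outer_radius:
            raise ValueError("active core must fit inside the capsule")

    @property
    def half_length(self) -> float:
        return 0.5 * self.active_length

    @property
    def z_distal(self) -> float:
        """Distal (+z) end of the steel envelope."""
        return self.half_length + self.capsule_distal_cap_thickness

    @property
    def z_proximal(self) -> float:
        """Proximal (-z) end of the steel envelope (cap + cable stub)."""
        return -(self.half_length + self.capsule_distal_cap_thickness
                 + self.cable_length)


@dataclass(frozen=True)
class EmissionBatch:
    """A batch of primary photons: positions (cm), unit directions, MeV."""

    positions: np.ndarray   # (n, 3)
    directions: np.ndarray  # (n, 3)
    energies: np.ndarray    # (n,)

    @property
    def count(self) -> int:
        return self.energies.size


def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit vectors uniform on the sphere."""
    mu = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - mu**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])


def sample_emission(geometry: SourceGeometry, spectrum: PhotonSpectrum,
                    n: int, rng: np.random.Generator) -> EmissionBatch:
    """Sample primary photons uniformly from the active core volume."""
    if n < 1:
        raise ValueError("need at least one history")
    r = geometry.active_radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    z = rng.uniform(-geometry.half_length, geometry.half_length, n)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return EmissionBatch(positions=pos,
                         directions=isotropic_directions(n, rng),
                         energies=spectrum.sample(n, rng))


def _cylinder_interval(p: np.ndarray, d: np.ndarray, radius: float,
                       z_lo: float, z_hi: float):
    """Parameter interval [t0, t1] where the ray is inside a finite cylinder.

    Vectorized over rays; empty intersections come back with t0 > t1.
    """
    px, py, pz = p[:, 0], p[:, 1], p[:, 2]
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    a = dx**2 + dy**2
    b = px * dx + py * dy
    c = px**2 + py**2 - radius**2
    big = 1e30
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = b**2 - a * c
        root = np.sqrt(np.maximum(disc, 0.0))
        tr0 = np.where(a > 1e-18, (-b - root) / a, np.where(c < 0, -big, big))
        tr1 = np.where(a > 1e-18, (-b + root) / a, np.where(c < 0, big, -big))
        miss = (a > 1e-18) & (disc <= 0.0)
        tr0 = np.where(miss, big, tr0)
        tr1 = np.where(miss, -big, tr1)
        tz0 = np.where(np.abs(dz) > 1e-18, (z_lo - pz) / dz, np.where(
            (pz >= z_lo) & (pz <= z_hi), -big, big))
        tz1 = np.where(np.abs(dz) > 1e-18, (z_hi - pz) / dz, np.where(
            (pz >= z_lo) & (pz <= z_hi), big, -big))
        swap = tz0 > tz1
        tz0, tz1 = np.where(swap, tz1, tz0), np.where(swap, tz0, tz1)
    return np.maximum(tr0, tz0), np.minimum(tr1, tz1)


def trace_batch(p: np.ndarray, d: np.ndarray, geometry: SourceGeometry):
    """Trace rays from inside the steel envelope to its surface.

    Returns ``(lengths, mats, t_exit)`` where ``lengths`` is (n, 3) segment
    lengths (zero-padded), ``mats`` the matching material codes (IRIDIUM /
    STEEL) and ``t_exit`` the distance to the envelope surface.  Segments
    are ordered along the ray and their lengths sum to ``t_exit``.
    """
    n = p.shape[0]
    g = geometry
    _, t_env = _cylinder_interval(p, d, g.capsule_outer_radius,
                                  g.z_proximal, g.z_distal)
    t_env = np.maximum(t_env, 0.0)
    c0, c1 = _cylinder_interval(p, d, g.active_radius,
                                -g.half_length, g.half_length)
    c0 = np.clip(c0, 0.0, t_env)
    c1 = np.clip(c1, 0.0, t_env)
    c1 = np.maximum(c0, c1)
    # breakpoints 0 <= c0 <= c1 <= t_env delimit at most three segments
    zeros = np.zeros(n)
    starts = np.stack([zeros, c0, c1], axis=1)
    ends = np.stack([c0, c1, t_env], axis=1)
    lengths = np.maximum(ends - starts, 0.0)
    mids = 0.5 * (starts + ends)
    mx = p[:, 0, None] + mids * d[:, 0, None]
    my = p[:, 1, None] + mids * d[:, 1, None]
    mz = p[:, 2, None] + mids * d[:, 2, None]
    in_core = ((mx**2 + my**2 <= g.active_radius**2)
               & (np.abs(mz) <= g.half_length))
    mats = np.where(in_core, IRIDIUM, STEEL)
    return lengths, mats, t_env


def trace_through_source(position, direction, geometry: SourceGeometry):
    """Ordered (material name, path length cm) segments from a core point.

    The ray starts at ``position`` (which must lie inside the active core)
    and is followed until it exits the capsule envelope.  Zero-length
    segments are dropped; consecutive same-material segments are merged.
    """
    p = np.atleast_2d(np.asarray(position, dtype=float))
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    g = geometry
    if (p[0, 0]**2 + p[0, 1]**2 > g.active_radius**2 * (1 + 1e-12)
            or abs(p[0, 2]) > g.half_length * (1 + 1e-12)):
        raise ValueError("position must lie inside the active core")
    lengths, mats, _ = trace_batch(p, d, g)
    names = {IRIDIUM: g.core_material.name, STEEL: g.capsule_material.name}
    out: list[tuple[str, float]] = []
    for length, mat in zip(lengths[0], mats[0]):
        if length <= 1e-12:
            continue
        name = names[int(mat)]
        if out and out[-1][0] == name:
            out[-1] = (name, out[-1][1] + float(length))
        else:
            out.append((name, float(length)))
    return out
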