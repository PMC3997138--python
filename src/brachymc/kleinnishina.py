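"""Klein-Nishina free-electron Compton cross sections and sampling.

All energies are in MeV, cross sections per electron in barn.  The sampler
draws the scattered-photon energy fraction from the exact Klein-Nishina
differential cross section with a simple rejection scheme and returns the
kinematically consistent scattering-angle cosine.
"""

from __future__ import annotations

import numpy as np

from .constants import ELECTRON_REST_MEV, R_E2_BARN

_TWO_PI_RE2 = 2.0 * np.pi * R_E2_BARN


def kn_total_cross_section(energy):
    """Total Klein-Nishina cross section per electron (barn).

    Closed form of the integrated KN formula; vectorized over `energy`.
    """
    a = np.asarray(energy, dtype=float) / ELECTRON_REST_MEV
    lg = np.log1p(2.0 * a)
    term1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - lg / a)
    term2 = lg / (2.0 * a)
    term3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    return _TWO_PI_RE2 * (term1 + term2 - term3)


def kn_dcs(energy, cos_theta):
    """Differential KN cross section dsigma/dOmega (barn/sr) per electron."""
    a = np.asarray(energy, dtype=float) / ELECTRON_REST_MEV
    mu = np.asarray(cos_theta, dtype=float)
    x = 1.0 / (1.0 + a * (1.0 - mu))  # E'/E
    return 0.5 * R_E2_BARN * x**2 * (x + 1.0 / x - (1.0 - mu**2))


def kn_energy_transfer_cross_section(energy, n_quad: int = 256):
    """Energy-transfer KN cross section per electron (barn).

    sigma_tr = integral of dsigma/dOmega * (1 - E'/E); evaluated by
    Gauss-Legendre quadrature over the scattering-angle cosine, which keeps
    this routine an independent cross-check of any closed form.
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    a = np.atleast_1d(np.asarray(energy, dtype=float)) / ELECTRON_REST_MEV
    mu = nodes[None, :]
    alpha = a[:, None]
    x = 1.0 / (1.0 + alpha * (1.0 - mu))
    dcs = 0.5 * R_E2_BARN * x**2 * (x + 1.0 / x - (1.0 - mu**2))
    integ = 2.0 * np.pi * np.sum(weights[None, :] * dcs * (1.0 - x), axis=1)
    return integ if np.ndim(energy) else float(integ[0])


def compton_scattered_energy(energy, cos_theta):
    """Compton kinematics: scattered photon energy for a given angle."""
    a = np.asarray(energy, dtype=float) / ELECTRON_REST_MEV
    return np.asarray(energy, dtype=float) / (1.0 + a * (1.0 - np.asarray(cos_theta)))


def sample_compton(energy, rng, max_iter: int = 256):
    """Sample scattered energy and angle cosine from the KN law.

    Parameters
    ----------
    energy : array-like, MeV (one entry per photon)
    rng : numpy Generator

    Returns
    -------
    (scattered_energy, cos_theta) arrays matching `energy`'s shape.

    Rejection sampling on the energy fraction x = E'/E in [1/(1+2a), 1]
    against h(x) = x + 1/x - 1 + cos^2(theta(x)), bounded by its value at
    x_min.  Efficiency is ~50-70% over the Ir-192 energy range.
    """
    e = np.atleast_1d(np.asarray(energy, dtype=float))
    a = e / ELECTRON_REST_MEV
    x_min = 1.0 / (1.0 + 2.0 * a)
    bound = x_min + 1.0 / x_min  # >= h(x) everywhere on [x_min, 1]
    x = np.empty_like(e)
    todo = np.ones(e.shape, dtype=bool)
    for _ in range(max_iter):
        n = int(todo.sum())
        if n == 0:
            break
        u = rng.random(n)
        v = rng.random(n)
        xm = x_min[todo]
        cand = xm + u * (1.0 - xm)
        mu_c = 1.0 - (1.0 / cand - 1.0) / a[todo]
        h = cand + 1.0 / cand - 1.0 + mu_c**2
        acc = v * bound[todo] <= h
        idx = np.flatnonzero(todo)
        x[idx[acc]] = cand[acc]
        todo[idx[acc]] = False
    else:  # pragma: no cover - rejection loop essentially always terminates
        raise RuntimeError("Compton rejection sampling failed to converge")
    cos_theta = 1.0 - (1.0 / x - 1.0) / a
    out_e = e * x
    if np.ndim(energy) == 0:
        return float(out_e[0]), float(cos_theta[0])
    return out_e, cos_theta


def sample_thomson_cosine(n, rng):
    """Sample angle cosines from the Thomson law p(mu) ~ 1 + mu^2."""
    out = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        mu = rng.uniform(-1.0, 1.0, m)
        acc = rng.random(m) * 2.0 <= 1.0 + mu**2
        idx = np.flatnonzero(todo)
        out[idx[acc]] = mu[acc]
        todo[idx[acc]] = False
    return out
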