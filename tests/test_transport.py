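"""transport_mc: analog transport, Compton sampling, tally plumbing."""

import numpy as np
import pytest
from scipy import stats

import brachymc as b
from brachymc.kleinnishina import (compton_scattered_energy, kn_dcs,
                                   kn_total_cross_section,
                                   kn_energy_transfer_cross_section)

SINGLE_LINE = b.PhotonSpectrum(energies=np.array([0.3]),
                               intensities=np.array([1.0]))


def _toy_phantom(mu_pe, mu_incoh, mu_coh, mu_en, diameter=30.0):
    mat, tab = b.make_toy_world(mu_pe, mu_incoh, mu_coh, mu_en_over_rho=mu_en)
    return b.PhantomSpec(shape="sphere", diameter=diameter, medium=mat,
                         table=tab)


def test_pure_absorber_matches_primary_kerma_oracle():
    """Point source in a pure absorber: K(r) = E mu_en e^{-mu r}/(4 pi r^2)."""
    mu, mu_en = 0.12, 0.04
    phantom = _toy_phantom(mu, 0.0, 0.0, mu_en)
    grid = b.transverse_rings([1.0, 3.0, 8.0])
    (res,) = b.run_transport(None, SINGLE_LINE, phantom, [grid],
                             n_histories=150_000, seed=21)
    for r in (1.0, 3.0, 8.0):
        val, err = res.value_at(r, return_err=True)
        exact = 0.3 * mu_en * np.exp(-mu * r) / (4 * np.pi * r**2)
        assert abs(val - exact) < 3 * err * val + 1e-12 * exact


def test_zero_attenuation_gives_inverse_square():
    phantom = _toy_phantom(0.0, 0.0, 0.0, 0.05)
    grid = b.transverse_rings([2.0, 10.0])
    (res,) = b.run_transport(None, SINGLE_LINE, phantom, [grid],
                             n_histories=100_000, seed=22)
    v2, e2 = res.value_at(2.0, return_err=True)
    v10, e10 = res.value_at(10.0, return_err=True)
    ratio = v2 / v10
    assert ratio == pytest.approx(25.0, rel=3 * np.hypot(e2, e10) + 5e-3)


def test_energy_conservation_in_total_absorber():
    """With mu_en = mu everywhere, the tallied kerma integrates to E."""
    mu = 0.5
    phantom = _toy_phantom(mu, 0.0, 0.0, mu, diameter=80.0)
    shells = b.radial_shells(np.linspace(0.0, 40.0, 81))
    (res,) = b.run_transport(None, SINGLE_LINE, phantom, [shells],
                             n_histories=40_000, seed=23)
    total = float(np.sum(res.kerma_per_history * shells.volumes))  # rho = 1
    assert total == pytest.approx(0.3, rel=0.02)


def test_compton_backscatter_kinematics():
    # E' = E / (1 + (E/m_e c^2)(1 - cos(theta)))
    assert compton_scattered_energy(0.662, -1.0) == pytest.approx(0.184, abs=5e-4)


def test_compton_sampler_thomson_limit():
    rng = np.random.default_rng(31)
    _, mu = b.sample_compton(np.full(200_000, 1e-4), rng)
    assert abs(mu.mean()) < 4 / np.sqrt(mu.size / 0.6)  # var(mu) = 3/5


def test_compton_sampler_matches_integrated_kn_pdf():
    """Empirical angle histogram at 0.3 MeV vs the numeric KN density."""
    rng = np.random.default_rng(32)
    energy = 0.3
    n = 400_000
    _, mu = b.sample_compton(np.full(n, energy), rng)
    edges = np.linspace(-1, 1, 51)
    counts, _ = np.histogram(mu, bins=edges)
    # expected bin probabilities by fine numerical integration of the DCS
    fine = np.linspace(-1, 1, 20_001)
    pdf = kn_dcs(energy, fine)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2
                                           * np.diff(fine))])
    cdf /= cdf[-1]
    probs = np.diff(np.interp(edges, fine, cdf))
    result = stats.chisquare(counts, f_exp=n * probs)
    assert result.pvalue > 0.01


def test_kn_total_cross_section_matches_numeric_integral():
    for energy in (0.05, 0.3, 1.0):
        mu = np.linspace(-1, 1, 40_001)
        numeric = 2 * np.pi * np.trapezoid(kn_dcs(energy, mu), mu)
        assert kn_total_cross_section(energy) == pytest.approx(numeric,
                                                               rel=1e-6)
        assert kn_energy_transfer_cross_section(energy) < numeric


def test_intersect_bins_single_and_split_segments():
    grid = b.radial_shells([0.0, 1.0, 2.0, 3.0])
    # fully inside one shell
    hits = b.intersect_bins(((1.1, 0, 0), (0, 0, 1), 0.2), grid)
    assert len(hits) == 1 and hits[0][0] == 1
    assert hits[0][1] == pytest.approx(0.2, abs=1e-9)
    # radial segment crossing two shells
    hits = b.intersect_bins(((0.5, 0, 0), (1, 0, 0), 1.0), grid)
    assert [j for j, _ in hits] == [0, 1]
    assert sum(c for _, c in hits) == pytest.approx(1.0, abs=1e-9)


def test_intersect_bins_matches_step_march():
    """Random segments: shell attribution equals a fine step-march."""
    rng = np.random.default_rng(5)
    edges = np.linspace(0.0, 5.0, 11)
    grid = b.radial_shells(edges)
    step = 1e-4
    for _ in range(200):
        p = rng.uniform(-2, 2, 3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        s = rng.uniform(0.1, 4.0)
        hits = dict(b.intersect_bins((p, d, s), grid))
        t = np.arange(step / 2, s, step)
        radii = np.linalg.norm(p[None, :] + t[:, None] * d[None, :], axis=1)
        idx = np.searchsorted(edges, radii) - 1
        inside = (idx >= 0) & (idx < len(edges) - 1)
        march = {int(j): float(c * step) for j, c in
                 zip(*np.unique(idx[inside], return_counts=True))}
        for j in set(hits) | set(march):
            assert hits.get(j, 0.0) == pytest.approx(march.get(j, 0.0),
                                                     abs=5 * step)


def test_seed_determinism_full_source_model():
    phantom = b.PhantomSpec(shape="sphere", diameter=30.0,
                            medium=b.load_material("water"))
    grid = b.transverse_rings([1.0, 5.0])
    runs = [b.run_transport(b.SourceGeometry(), b.ir192_spectrum(), phantom,
                            [grid], n_histories=30_000, seed=99)[0]
            for _ in range(2)]
    np.testing.assert_array_equal(runs[0].kerma_per_history,
                                  runs[1].kerma_per_history)
    np.testing.assert_array_equal(runs[0].rel_err, runs[1].rel_err)


def test_error_scales_as_inverse_sqrt_histories():
    phantom = _toy_phantom(0.02, 0.1, 0.0, 0.03)
    grid = b.transverse_rings([2.0, 5.0, 10.0])
    rel = {}
    for n in (40_000, 160_000):
        (res,) = b.run_transport(None, SINGLE_LINE, phantom, [grid],
                                 n_histories=n, seed=55)
        rel[n] = np.median(res.rel_err)
    ratio = rel[160_000] / rel[40_000]
    assert 0.35 < ratio < 0.65  # 1/sqrt(4) = 0.5 within 20-30% scatter


def test_medium_ordering_beyond_six_cm(water_run, bone_run, lung_run):
    """Deep kerma falls fastest in bone, then water, then lung."""
    profiles = {name: run[0] for name, run in
                (("water", water_run), ("bone", bone_run), ("lung", lung_run))}
    for r in (10.0, 15.0):
        decays = {name: prof.value_at(r) / prof.value_at(1.0)
                  for name, prof in profiles.items()}
        assert decays["bone"] < decays["water"] < decays["lung"]


def test_transport_input_validation():
    phantom = _toy_phantom(0.1, 0.0, 0.0, 0.1)
    with pytest.raises(ValueError, match="tally"):
        b.run_transport(None, SINGLE_LINE, phantom, [], 100, seed=1)
    with pytest.raises(ValueError, match="cutoff"):
        b.run_transport(None, SINGLE_LINE, phantom,
                        [b.transverse_rings([1.0])], 100, seed=1, cutoff=0.4)
    with pytest.raises(ValueError):
        b.PhantomSpec(shape="cube", diameter=30.0)
    with pytest.raises(ValueError, match="contain"):
        b.PhantomSpec(shape="sphere", diameter=0.3)


def test_rel_err_fields_are_sane(water_run):
    for res in water_run:
        assert np.all(res.kerma_per_history >= 0)
        finite = np.isfinite(res.rel_err)
        assert np.all(res.rel_err[finite] >= 0)
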