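"""Media, coefficient tables, spectra and eta/chi scaling factors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccbrachy import physics_data as pd
from ccbrachy.xs_build import ELEMENT_DATA


@pytest.mark.parametrize("symbol", sorted(ELEMENT_DATA))
def test_element_table_invariants(symbol):
    el = pd.get_element(symbol)
    el.validate()
    assert np.all(np.diff(el.energy_grid) > 0)
    assert np.all(el.muen_over_rho <= el.mu_over_rho * (1 + 1e-12))
    frac_sum = (el.frac_photoelectric + el.frac_incoherent + el.frac_coherent)
    np.testing.assert_allclose(frac_sum, 1.0, atol=1e-9)


def test_mixture_rule_water(water):
    h = pd.get_element("H")
    o = pd.get_element("O")
    np.testing.assert_allclose(
        water.mu_over_rho, 0.112 * h.mu_over_rho + 0.888 * o.mu_over_rho,
        rtol=1e-12)
    np.testing.assert_allclose(
        water.muen_over_rho, 0.112 * h.muen_over_rho + 0.888 * o.muen_over_rho,
        rtol=1e-12)


def test_single_element_medium_identity():
    m = pd.build_medium("oxygen", {"O": 100.0}, 1.141)
    o = pd.get_element("O")
    np.testing.assert_allclose(m.mu_over_rho, o.mu_over_rho, rtol=1e-14)
    np.testing.assert_allclose(m.muen_over_rho, o.muen_over_rho, rtol=1e-14)


def test_cortical_bone_definition(bone):
    assert bone.density == pytest.approx(1.92)
    assert sum(bone.composition.values()) == pytest.approx(1.0, abs=1e-12)
    assert bone.composition["Ca"] == pytest.approx(0.225, abs=1e-6)


def test_build_medium_errors():
    with pytest.raises(KeyError, match="Xx"):
        pd.build_medium("bad", {"Xx": 100.0}, 1.0)
    with pytest.raises(ValueError, match="sum"):
        pd.build_medium("bad", {"H": 50.0, "O": 49.0}, 1.0)
    with pytest.raises(ValueError, match="density"):
        pd.build_medium("bad", {"O": 100.0}, -1.0)


def test_spectral_average_degenerate_and_symmetry(water):
    sp1 = pd.PhotonSpectrum(np.array([0.3]), np.array([1.0]))
    mu, muen = pd.spectral_average(water, sp1)
    assert mu == pytest.approx(float(water.mu_at(0.3)), rel=1e-12)
    assert muen == pytest.approx(float(water.muen_at(0.3)), rel=1e-12)

    sp2 = pd.PhotonSpectrum(np.array([0.1, 0.5]), np.array([1.0, 1.0]))
    mu2, _ = pd.spectral_average(water, sp2)
    expected = 0.5 * (water.mu_at(0.1) + water.mu_at(0.5))
    assert mu2 == pytest.approx(float(expected), rel=1e-12)


def test_spectral_average_against_quadrature_oracle(bone):
    """Independent oracle: piecewise log-log interpolation by hand, summed
    over the packaged msc spectrum."""
    from ccbrachy.kernels import packaged_spectrum

    sp = packaged_spectrum("msc")
    # hand-rolled log-log interpolation (independent of Medium.mu_at)
    grid = np.log(bone.energy_grid)
    vals = np.log(bone.muen_over_rho)
    out = 0.0
    for e, w in zip(sp.energies, sp.weights):
        le = np.log(e)
        i = np.searchsorted(grid, le) - 1
        i = min(max(i, 0), len(grid) - 2)
        t = (le - grid[i]) / (grid[i + 1] - grid[i])
        out += w * np.exp(vals[i] * (1 - t) + vals[i + 1] * t)
    _, muen = pd.spectral_average(bone, sp)
    assert muen == pytest.approx(out, rel=1e-10)


@st.composite
def spectra(draw):
    n = draw(st.integers(2, 8))
    e = draw(st.lists(st.floats(2e-3, 1.4), min_size=n, max_size=n,
                      unique=True))
    w = draw(st.lists(st.floats(1e-3, 1.0), min_size=n, max_size=n))
    return pd.PhotonSpectrum(np.array(e), np.array(w))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(spectra())
def test_chi_eta_identities(sp):
    """chi/eta equals the medium-to-water ratio of muen/mu spectrum
    averages, and water is its own reference (eta = chi = 1)."""
    w = pd.water()
    b = pd.cortical_bone()
    assert pd.chi_factor(w, sp) == 1.0
    assert pd.eta_factor(w, sp) == 1.0
    chi = pd.chi_factor(b, sp)
    eta = pd.eta_factor(b, sp)
    mu_b, muen_b = pd.spectral_average(b, sp)
    mu_w, muen_w = pd.spectral_average(w, sp)
    assert chi / eta == pytest.approx((muen_b / mu_b) / (muen_w / mu_w),
                                      rel=1e-12)


def test_chi_bone_exceeds_eta_for_soft_spectrum(bone):
    """Photoelectric enhancement at low scattered energies makes the
    energy-absorption ratio exceed the attenuation ratio."""
    from ccbrachy.kernels import packaged_spectrum

    sp = packaged_spectrum("msc")
    assert pd.chi_factor(bone, sp) > pd.eta_factor(bone, sp) > 1.0


def test_chi_air_density_scale(air, ir_spectrum):
    chi = pd.chi_factor(air, ir_spectrum)
    assert 0.5e-3 < chi < 2e-3  # dominated by the ~1e-3 density ratio


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(1.1e-3, 1.45))
def test_interpolation_bounded_by_table(e):
    """Log-log interpolation never leaves the bracketing table values."""
    el = pd.get_element("Ca")
    i = np.searchsorted(el.energy_grid, e) - 1
    i = min(max(i, 0), len(el.energy_grid) - 2)
    lo = min(el.mu_over_rho[i], el.mu_over_rho[i + 1])
    hi = max(el.mu_over_rho[i], el.mu_over_rho[i + 1])
    v = el.mu_at(e)
    assert lo * (1 - 1e-12) <= v <= hi * (1 + 1e-12)


class TestFitCoeffsOverDistance:
    def test_monoenergetic_exact(self, water):
        sp = pd.PhotonSpectrum(np.array([0.3565]), np.array([1.0]))
        mu_eff, muen_eff = pd.fit_coeffs_over_distance(water, sp, (0.0, 10.0))
        assert mu_eff == pytest.approx(float(water.mu_at(0.3565)), rel=1e-9)
        assert muen_eff == pytest.approx(float(water.muen_at(0.3565)), rel=1e-9)

    def test_two_line_between_bruteforce(self, water):
        sp = pd.PhotonSpectrum(np.array([0.1, 0.6]), np.array([1.0, 1.0]))
        mu_eff, _ = pd.fit_coeffs_over_distance(water, sp, (0.0, 10.0))
        mu_lo = float(water.mu_at(0.6))
        mu_hi = float(water.mu_at(0.1))
        assert mu_lo < mu_eff < mu_hi
        # brute-force 1-D least squares oracle on a fine grid
        radii = np.linspace(0, 10, 11)
        we = sp.weights * sp.energies
        target = (we[None, :] * np.exp(-water.density * np.array(
            [water.mu_at(e) for e in sp.energies])[None, :] * radii[:, None])
        ).sum(axis=1) / we.sum()
        cand = np.linspace(mu_lo, mu_hi, 20001)
        sse = ((np.exp(-cand[None, :] * radii[:, None]) - target[:, None]) ** 2).sum(axis=0)
        assert mu_eff == pytest.approx(cand[np.argmin(sse)], abs=2e-4)

    def test_degenerate_range_point_spectrum(self, water):
        sp = pd.PhotonSpectrum(np.array([0.1, 0.6]), np.array([1.0, 1.0]))
        with pytest.warns(UserWarning, match="degenerate"):
            mu_eff, _ = pd.fit_coeffs_over_distance(water, sp, (5.0, 5.0))
        # oracle: single-depth hardened average
        we = sp.weights * sp.energies
        att = we * np.exp(-water.density * water.mu_at(sp.energies) * 5.0)
        att /= att.sum()
        expected = float(np.sum(att * water.mu_at(sp.energies)))
        assert mu_eff == pytest.approx(expected, rel=1e-9)


def test_media_library_roundtrip(tmp_path):
    media = pd.standard_media()
    path = tmp_path / "media.txt"
    pd.write_media_library(path, media)
    back = pd.load_media_library(path)
    assert set(back) == set(media)
    np.testing.assert_allclose(back["cortical_bone"].mu_over_rho,
                               media["cortical_bone"].mu_over_rho, rtol=1e-5)


def test_spectrum_validation():
    with pytest.raises(ValueError):
        pd.PhotonSpectrum(np.array([]), np.array([]))
    with pytest.raises(ValueError):
        pd.PhotonSpectrum(np.array([0.3]), np.array([-1.0]))
    with pytest.raises(ValueError):
        pd.PhotonSpectrum(np.array([5.0]), np.array([1.0]))  # above range


def test_ir192_spectrum_fixture(ir_spectrum):
    assert len(ir_spectrum.energies) >= 20
    assert ir_spectrum.energies.min() >= 0.06
    assert ir_spectrum.energies.max() <= 1.4
    assert ir_spectrum.weights.sum() == pytest.approx(1.0)
    assert 0.34 < ir_spectrum.mean_energy < 0.37
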