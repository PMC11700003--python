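"""Forced-interaction kernel generation, scatter spectra and the
bi-exponential fits."""

import numpy as np
import pytest

from ccbrachy import kernels as kn
from ccbrachy.constants import MEC2
from ccbrachy.physics_data import PhotonSpectrum, ir192_spectrum


def make_synthetic_tally(C, c, F, f, generation="msc"):
    """Exact bi-exponential tally: energy per (theta, r) bin from the
    closed-form integral of dOmega (C e^{-cr} + F e^{-fr})."""
    r_edges = kn._radial_edges()
    cos_edges = np.linspace(1.0, -1.0, kn.N_THETA + 1)
    dom = 2.0 * np.pi * (cos_edges[:-1] - cos_edges[1:])

    def cum(r):
        return C / c * (1 - np.exp(-c * r)) + F / f * (1 - np.exp(-f * r))

    per_r = cum(r_edges[1:]) - cum(r_edges[:-1])
    energy = dom[:, None] * per_r[None, :]
    absorbed = float(energy.sum())
    return kn.KernelTally(generation, r_edges, cos_edges, energy,
                          released=1.0, tallied=absorbed, escaped=1 - absorbed,
                          to_next_generation=0.0, n_histories=1, seed=0)


class TestFitting:
    def test_parameter_recovery_within_one_percent(self):
        tally = make_synthetic_tally(2.0, 0.1, 0.5, 0.5)
        fit = kn.fit_msc_biexponential(tally, shared_exponents=False,
                                       allow_buildup=False)
        # same parameters recovered in every cone
        np.testing.assert_allclose(fit.C, 2.0, rtol=0.01)
        np.testing.assert_allclose(fit.c, 0.1, rtol=0.01)
        np.testing.assert_allclose(fit.F, 0.5, rtol=0.01)
        np.testing.assert_allclose(fit.f, 0.5, rtol=0.01)

    def test_single_exponential_degenerate(self):
        tally = make_synthetic_tally(1.5, 0.12, 0.0, 1.0)
        fit = kn.fit_msc_biexponential(tally, shared_exponents=False,
                                       allow_buildup=False)
        # F vanishes or the pair degenerates with the correct summed kernel
        model = fit.evaluate(0.9, 3.0)
        truth = 1.5 * np.exp(-0.12 * 3.0)
        np.testing.assert_allclose(model, truth, rtol=0.02)

    def test_fit_integral_matches_tally(self):
        tally = make_synthetic_tally(2.0, 0.1, 0.5, 0.5)
        fit = kn.fit_msc_biexponential(tally, shared_exponents=False,
                                       allow_buildup=False)
        # closed-form absorbed fraction vs fitted kernel integral
        assert fit.kernel_integral() == pytest.approx(
            4 * np.pi * (2.0 / 0.1 + 0.5 / 0.5), rel=0.05)

    def test_closure_normalization(self):
        tally = make_synthetic_tally(2.0, 0.1, 0.5, 0.5)
        fit = kn.fit_msc_biexponential(tally, closure=1.0)
        assert fit.kernel_integral() == pytest.approx(1.0, rel=1e-12)

    def test_csv_roundtrip(self, tmp_path):
        fit = kn.fit_msc_biexponential(make_synthetic_tally(2.0, 0.1, 0.5, 0.5))
        path = tmp_path / "k.csv"
        fit.to_csv(path)
        back = kn.MscKernelFit.from_csv(path)
        np.testing.assert_allclose(back.C, fit.C, rtol=1e-6)
        np.testing.assert_allclose(back.f, fit.f, rtol=1e-6)
        assert back.generation == "msc"


class TestKernelGeneration:
    def test_1sc_energy_conservation_and_anisotropy(self, mono_spectrum):
        tally, spec = kn.generate_1sc_kernel(mono_spectrum, 100_000, seed=42)
        # deterministic bookkeeping: released = tallied + escaped + passed on
        balance = (tally.tallied + tally.escaped + tally.to_next_generation)
        assert balance == pytest.approx(tally.released, rel=1e-12)
        # Compton kinematic bounds for a 0.3565 MeV incident photon
        e0 = 0.3565
        e_min = e0 / (1 + 2 * e0 / MEC2)
        half_bin = 0.005
        assert spec.energies.min() >= e_min - half_bin
        assert spec.energies.max() <= e0 + half_bin
        # Klein-Nishina forward peaking: forward cones receive more energy
        n_half = kn.N_THETA // 2
        assert tally.energy[:n_half].sum() > tally.energy[n_half:].sum()

    def test_msc_conservation_and_softening(self):
        primary = ir192_spectrum()
        _, spec1 = kn.generate_1sc_kernel(primary, 100_000, seed=1)
        tally, spec2 = kn.generate_msc_kernel(spec1, 200_000, seed=2)
        # expectation-level closure of the descendant chain
        assert (tally.tallied + tally.escaped) == pytest.approx(
            tally.released, rel=2e-3)
        assert spec2.mean_energy < spec1.mean_energy

    def test_seed_reproducibility(self, mono_spectrum):
        t1, _ = kn.generate_1sc_kernel(mono_spectrum, 20_000, seed=9)
        t2, _ = kn.generate_1sc_kernel(mono_spectrum, 20_000, seed=9)
        np.testing.assert_array_equal(t1.energy, t2.energy)
        assert t1.released == t2.released

    def test_low_statistics_warning(self, mono_spectrum):
        with pytest.warns(UserWarning, match="histories"):
            kn.generate_1sc_kernel(mono_spectrum, 1000, seed=3)


class TestPackagedFixtures:
    @pytest.mark.parametrize("gen", ["1sc", "msc"])
    def test_kernel_invariants(self, gen):
        fit = kn.packaged_kernel(gen)
        assert (fit.c > 0).all() and (fit.f > 0).all()
        assert fit.solid_angles.sum() == pytest.approx(4 * np.pi, abs=1e-9)
        r = np.linspace(0, 40, 200)
        for i in range(0, kn.N_THETA, 7):
            vals = fit.C[i] * np.exp(-fit.c[i] * r) + fit.F[i] * np.exp(-fit.f[i] * r)
            assert (vals >= -1e-12).all()

    def test_msc_closure_and_spectra(self):
        assert kn.packaged_kernel("msc").kernel_integral() == pytest.approx(1.0, rel=1e-9)
        s1 = kn.packaged_spectrum("1sc")
        s2 = kn.packaged_spectrum("msc")
        assert s2.mean_energy < s1.mean_energy < ir192_spectrum().mean_energy
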