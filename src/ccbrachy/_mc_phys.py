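"""Shared numba photon-physics kernels: fine-grid coefficient lookup,
Klein-Nishina Compton sampling, Thomson (form-factor-free) Rayleigh
sampling and direction rotation.

Free-electron Klein-Nishina is used for Compton (no Doppler broadening or
impulse approximation); the engine and the Monte Carlo reference share the
same embedded coefficient tables, so the comparison between them isolates
the transport algorithm rather than cross-section fidelity.
"""

import numpy as np
from numba import njit

from .constants import E_CUTOFF, E_MAX, MEC2

#: number of points of the fine log-energy lookup grid
N_FINE = 1024


def build_medium_lookup(media):
    """Fine log-energy lookup tables for a list of media.

    Returns (ln_e0, dln, mu_rho, muen_rho, frac_pe, frac_incoh) where the
    coefficient arrays have shape (n_media, N_FINE).  The coherent fraction
    is the complement of the other two.
    """
    e = np.exp(np.linspace(np.log(E_CUTOFF), np.log(E_MAX), N_FINE))
    n = len(media)
    mu = np.empty((n, N_FINE))
    muen = np.empty((n, N_FINE))
    fpe = np.empty((n, N_FINE))
    finc = np.empty((n, N_FINE))
    for i, m in enumerate(media):
        mu[i] = m.mu_at(e)
        muen[i] = m.muen_at(e)
        # per-process fractions via the element mixture
        from .physics_data import get_element
        pe_part = np.zeros(N_FINE)
        inc_part = np.zeros(N_FINE)
        tot = np.zeros(N_FINE)
        for sym, w in m.composition.items():
            el = get_element(sym)
            mu_el = el.mu_at(e)
            pe_part += w * mu_el * np.interp(np.log(e), np.log(el.energy_grid),
                                             el.frac_photoelectric)
            inc_part += w * mu_el * np.interp(np.log(e), np.log(el.energy_grid),
                                              el.frac_incoherent)
            tot += w * mu_el
        fpe[i] = pe_part / tot
        finc[i] = inc_part / tot
    ln_e0 = np.log(E_CUTOFF)
    dln = (np.log(E_MAX) - ln_e0) / (N_FINE - 1)
    return ln_e0, dln, mu, muen, fpe, finc


@njit(cache=True, inline="always")
def lookup(table, im, ln_e0, dln, e):
    """Linear-in-ln(E) interpolation of ``table[im]`` at energy ``e``."""
    x = (np.log(e) - ln_e0) / dln
    if x <= 0.0:
        return table[im, 0]
    if x >= N_FINE - 1:
        return table[im, N_FINE - 1]
    i = int(x)
    f = x - i
    return table[im, i] * (1.0 - f) + table[im, i + 1] * f


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG state (distinct from NumPy's)."""
    np.random.seed(seed)


@njit(cache=True)
def sample_compton(e):
    """Sample a Klein-Nishina Compton scatter; returns (e_out, cos_theta).

    Standard two-density composition-rejection sampling of eps = E'/E.
    """
    a = e / MEC2
    eps_min = 1.0 / (1.0 + 2.0 * a)
    a1 = -np.log(eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        if np.random.random() * (a1 + a2) < a1:
            eps = eps_min * np.exp(a1 * np.random.random())
        else:
            eps = np.sqrt(eps_min * eps_min
                          + (1.0 - eps_min * eps_min) * np.random.random())
        t = (1.0 - eps) / (a * eps)
        sin2 = t * (2.0 - t)
        g = 1.0 - eps * sin2 / (1.0 + eps * eps)
        if np.random.random() <= g:
            cos_t = 1.0 - t
            return e * eps, cos_t


@njit(cache=True)
def sample_rayleigh_cos():
    """Thomson angular sampling (form-factor-free Rayleigh)."""
    while True:
        c = 2.0 * np.random.random() - 1.0
        if np.random.random() * 2.0 <= 1.0 + c * c:
            return c


@njit(cache=True)
def rotate_direction(d, cos_t, phi):
    """Rotate unit vector ``d`` by polar angle arccos(cos_t), azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    out = np.empty(3)
    if abs(d[2]) > 0.999999:
        sign = 1.0 if d[2] > 0.0 else -1.0
        out[0] = sin_t * cp
        out[1] = sign * sin_t * sp
        out[2] = sign * cos_t
    else:
        s = np.sqrt(1.0 - d[2] * d[2])
        out[0] = d[0] * cos_t + sin_t * (d[0] * d[2] * cp - d[1] * sp) / s
        out[1] = d[1] * cos_t + sin_t * (d[1] * d[2] * cp + d[0] * sp) / s
        out[2] = d[2] * cos_t - s * sin_t * cp
    norm = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2)
    out[0] /= norm
    out[1] /= norm
    out[2] /= norm
    return out


@njit(cache=True)
def sample_spectrum_line(energies, cum_weights):
    """Sample one line energy from a discrete spectrum (cum_weights[-1]=1)."""
    u = np.random.random()
    lo = 0
    hi = len(cum_weights) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cum_weights[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return energies[lo]
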