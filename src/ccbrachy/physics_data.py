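"""Media definitions, photon interaction coefficients, spectra and the
eta/chi heterogeneity scaling factors.

Coefficients live on a common ascending energy grid (1 keV - 1.5 MeV) and
are interpolated log-log off-grid.  Media are built from elemental mass
fractions with the mixture rule

    (mu/rho)_mix(E) = sum_k w_k (mu/rho)_k(E),

and the scaling factors relative to water are spectrum averages

    eta = (rho_m/rho_w) [mu_bar/rho]_m / [mu_bar/rho]_w
    chi = (rho_m/rho_w) [mu_bar_en/rho]_m / [mu_bar_en/rho]_w

where the bar denotes averaging over a given photon (fluence) spectrum.
``chi/eta`` converts the local energy absorption of a water kernel to the
actual medium; it equals one for water by construction.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import E_CUTOFF, E_MAX
from .xs_build import ELEMENT_DATA, build_element_tables

__all__ = [
    "ElementCoefficients",
    "Medium",
    "PhotonSpectrum",
    "ScalingFactors",
    "get_element",
    "build_medium",
    "spectral_average",
    "chi_factor",
    "eta_factor",
    "scaling_factors",
    "fit_coeffs_over_distance",
    "water",
    "cortical_bone",
    "air",
    "standard_media",
    "ir192_spectrum",
    "load_media_library",
    "write_media_library",
]


def loglog_interp(e_grid: np.ndarray, values: np.ndarray, e: np.ndarray | float):
    """Log-log linear interpolation, clamped to the table range.

    Monotone between bracketing grid points, so interpolated values never
    leave the bracketing table values.
    """
    e = np.asarray(e, dtype=float)
    le = np.log(np.clip(e, e_grid[0], e_grid[-1]))
    out = np.exp(np.interp(le, np.log(e_grid), np.log(values)))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# element tables


@dataclass(frozen=True)
class ElementCoefficients:
    """Photon interaction coefficients of a chemical element.

    ``mu_over_rho`` and ``muen_over_rho`` are mass attenuation and mass
    energy-absorption coefficients [cm^2/g] on ``energy_grid`` [MeV];
    ``frac_*`` are the per-process fractions of the total cross section.
    """

    symbol: str
    z: int
    atomic_mass: float
    energy_grid: np.ndarray
    mu_over_rho: np.ndarray
    muen_over_rho: np.ndarray
    frac_photoelectric: np.ndarray
    frac_incoherent: np.ndarray
    frac_coherent: np.ndarray

    def validate(self) -> None:
        if not np.all(np.diff(self.energy_grid) > 0):
            raise ValueError(f"{self.symbol}: energy grid not strictly increasing")
        if not np.all(self.mu_over_rho > 0) or not np.all(self.muen_over_rho > 0):
            raise ValueError(f"{self.symbol}: non-positive coefficient")
        if np.any(self.muen_over_rho > self.mu_over_rho * (1 + 1e-12)):
            raise ValueError(f"{self.symbol}: muen/rho exceeds mu/rho")
        s = self.frac_photoelectric + self.frac_incoherent + self.frac_coherent
        if np.any(np.abs(s - 1.0) > 1e-9):
            raise ValueError(f"{self.symbol}: process fractions do not sum to 1")

    def mu_at(self, e):
        return loglog_interp(self.energy_grid, self.mu_over_rho, e)

    def muen_at(self, e):
        return loglog_interp(self.energy_grid, self.muen_over_rho, e)


def _element_csv_dir():
    return resources.files("ccbrachy").joinpath("data/elements")


_ELEMENT_CACHE: dict[str, ElementCoefficients] = {}


def get_element(symbol: str) -> ElementCoefficients:
    """Return the embedded coefficient table for *symbol*."""
    if symbol in _ELEMENT_CACHE:
        return _ELEMENT_CACHE[symbol]
    if symbol not in ELEMENT_DATA:
        raise KeyError(f"unknown element {symbol!r}; embedded tables cover "
                       f"{sorted(ELEMENT_DATA)}")
    path = _element_csv_dir().joinpath(f"{symbol}.csv")
    if path.is_file():
        rows = []
        with path.open() as fh:
            rd = csv.reader(fh)
            for row in rd:
                if not row or row[0].startswith("#") or row[0].startswith("energy"):
                    continue
                rows.append([float(x) for x in row])
        arr = np.array(rows)
        z, a = ELEMENT_DATA[symbol]
        elem = ElementCoefficients(symbol, z, a, arr[:, 0], arr[:, 1], arr[:, 2],
                                   arr[:, 3], arr[:, 4], arr[:, 5])
    else:  # pragma: no cover - fixture normally shipped
        tab = build_element_tables()[symbol]
        z, a = ELEMENT_DATA[symbol]
        elem = ElementCoefficients(symbol, z, a, tab["energy"], tab["mu"],
                                   tab["muen"], tab["frac_pe"],
                                   tab["frac_incoh"], tab["frac_coh"])
    elem.validate()
    _ELEMENT_CACHE[symbol] = elem
    return elem


# ---------------------------------------------------------------------------
# media


@dataclass(frozen=True)
class Medium:
    """A material defined by elemental mass fractions and a bulk density.

    Mixture-rule coefficients share the common element energy grid.
    """

    name: str
    composition: dict[str, float]
    density: float  # g/cm^3
    energy_grid: np.ndarray = field(repr=False)
    mu_over_rho: np.ndarray = field(repr=False)
    muen_over_rho: np.ndarray = field(repr=False)

    def mu_at(self, e):
        """Mass attenuation coefficient [cm^2/g] at energy *e* [MeV]."""
        return loglog_interp(self.energy_grid, self.mu_over_rho, e)

    def muen_at(self, e):
        """Mass energy-absorption coefficient [cm^2/g] at *e* [MeV]."""
        return loglog_interp(self.energy_grid, self.muen_over_rho, e)

    def mu_linear_at(self, e):
        """Linear attenuation coefficient [1/cm] at *e* [MeV]."""
        return self.density * self.mu_at(e)


def build_medium(name: str, composition: dict[str, float], density: float) -> Medium:
    """Build a :class:`Medium` from elemental mass fractions.

    Fractions may be given in percent (summing to ~100) or as fractions
    (summing to ~1); they are normalized after the 1e-3 tolerance check.
    """
    if density <= 0:
        raise ValueError(f"{name}: density must be positive")
    total = sum(composition.values())
    scale = 100.0 if total > 50.0 else 1.0
    if abs(total / scale - 1.0) > 1e-3:
        raise ValueError(
            f"{name}: mass fractions sum to {total / scale:.5f}, outside 1 +/- 1e-3")
    fractions = {}
    for sym, w in composition.items():
        if w < 0 or w > scale:
            raise ValueError(f"{name}: fraction for {sym} outside [0, 1]")
        if sym not in ELEMENT_DATA:
            raise KeyError(
                f"{name}: unknown element {sym!r}; embedded tables cover "
                f"{sorted(ELEMENT_DATA)}")
        fractions[sym] = w / total
    elems = {sym: get_element(sym) for sym in fractions}
    grid = next(iter(elems.values())).energy_grid
    mu = sum(w * elems[sym].mu_over_rho for sym, w in fractions.items())
    muen = sum(w * elems[sym].muen_over_rho for sym, w in fractions.items())
    return Medium(name, fractions, float(density), grid, mu, muen)


def water() -> Medium:
    return build_medium("water", {"H": 11.2, "O": 88.8}, 1.00)


def cortical_bone() -> Medium:
    return build_medium(
        "cortical_bone",
        {"H": 3.4, "C": 15.5, "N": 4.2, "O": 43.5, "Na": 0.1, "Mg": 0.2,
         "P": 10.3, "S": 0.3, "Ca": 22.5},
        1.92,
    )


def air() -> Medium:
    return build_medium("air", {"N": 75.5, "O": 23.2, "Ar": 1.3}, 1.20e-3)


def standard_media() -> dict[str, Medium]:
    """The phantom media library: water, cortical bone and (dry) air."""
    return {m.name: m for m in (water(), cortical_bone(), air())}


# media library text format: one line per medium,
#   name density El:frac El:frac ...
def load_media_library(path) -> dict[str, Medium]:
    media = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        name, density = parts[0], float(parts[1])
        comp = {}
        for tok in parts[2:]:
            sym, frac = tok.split(":")
            comp[sym] = float(frac)
        media[name] = build_medium(name, comp, density)
    return media


def write_media_library(path, media: dict[str, Medium]) -> None:
    lines = ["# name density element:mass_fraction ..."]
    for m in media.values():
        comp = " ".join(f"{s}:{w:.6g}" for s, w in m.composition.items())
        lines.append(f"{m.name} {m.density:.6g} {comp}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# spectra


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete photon spectrum: bin energies [MeV] and normalized weights."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.size == 0:
            raise ValueError("empty spectrum")
        if np.any(w < 0):
            raise ValueError("negative spectrum weight")
        if np.any(e < E_CUTOFF) or np.any(e > E_MAX * (1 + 1e-12)):
            raise ValueError(f"spectrum energies outside [{E_CUTOFF}, {E_MAX}] MeV")
        s = w.sum()
        if s <= 0:
            raise ValueError("spectrum weights sum to zero")
        order = np.argsort(e)
        object.__setattr__(self, "energies", e[order])
        object.__setattr__(self, "weights", w[order] / s)

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))

    @classmethod
    def from_csv(cls, path) -> "PhotonSpectrum":
        rows = []
        with open(path) as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[0].startswith("energy"):
                    continue
                rows.append((float(row[0]), float(row[1])))
        arr = np.array(rows)
        return cls(arr[:, 0], arr[:, 1])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["energy_MeV", "weight"])
            for e, w in zip(self.energies, self.weights):
                wr.writerow([f"{e:.6e}", f"{w:.6e}"])


def ir192_spectrum() -> PhotonSpectrum:
    """The packaged bare-point Ir-192 emission line spectrum."""
    path = resources.files("ccbrachy").joinpath("data/ir192_spectrum.csv")
    with resources.as_file(path) as p:
        return PhotonSpectrum.from_csv(p)


# ---------------------------------------------------------------------------
# spectral averages and scaling factors


def spectral_average(medium: Medium, spectrum: PhotonSpectrum) -> tuple[float, float]:
    """Fluence-weighted (mu_bar/rho, mu_bar_en/rho) of *medium* over *spectrum*."""
    mu = medium.mu_at(spectrum.energies)
    muen = medium.muen_at(spectrum.energies)
    return (float(np.sum(spectrum.weights * mu)),
            float(np.sum(spectrum.weights * muen)))


def chi_factor(medium: Medium, spectrum: PhotonSpectrum,
               reference: Medium | None = None) -> float:
    """Linear energy-absorption ratio of *medium* to water over *spectrum*."""
    ref = reference if reference is not None else water()
    _, muen_m = spectral_average(medium, spectrum)
    _, muen_w = spectral_average(ref, spectrum)
    return (medium.density / ref.density) * muen_m / muen_w


def eta_factor(medium: Medium, spectrum: PhotonSpectrum,
               reference: Medium | None = None) -> float:
    """Linear attenuation ratio of *medium* to water over *spectrum*."""
    ref = reference if reference is not None else water()
    mu_m, _ = spectral_average(medium, spectrum)
    mu_w, _ = spectral_average(ref, spectrum)
    return (medium.density / ref.density) * mu_m / mu_w


@dataclass(frozen=True)
class ScalingFactors:
    """eta/chi pair of a medium for one scatter generation."""

    medium: str
    generation: str  # "prim" | "1sc" | "msc"
    eta: float
    chi: float

    def __post_init__(self):
        if self.generation not in ("prim", "1sc", "msc"):
            raise ValueError(f"invalid generation {self.generation!r}")
        if self.eta <= 0 or self.chi <= 0:
            raise ValueError("eta and chi must be positive")


def scaling_factors(medium: Medium, spectrum: PhotonSpectrum, generation: str,
                    reference: Medium | None = None) -> ScalingFactors:
    return ScalingFactors(medium.name, generation,
                          eta_factor(medium, spectrum, reference),
                          chi_factor(medium, spectrum, reference))


# ---------------------------------------------------------------------------
# distance-fitted effective coefficients


def fit_coeffs_over_distance(medium: Medium, spectrum: PhotonSpectrum,
                             radial_range: tuple[float, float] = (0.0, 10.0),
                             n_samples: int = 11) -> tuple[float, float]:
    """Effective (mu_bar/rho, mu_bar_en/rho) fitted over a radial range.

    A single-coefficient exponential exp(-mu_bar rho r) is least-squares
    fitted to the exact spectral primary energy-fluence attenuation
    sum_i w_i E_i exp(-mu_i rho r) sampled at *n_samples* radii, capturing
    beam hardening that a single-depth spectrum average ignores.  The
    effective mu_bar_en is the average of the per-radius hardened-spectrum
    muen averages over the same radii.
    """
    from scipy.optimize import minimize_scalar

    r0, r1 = radial_range
    if r1 < r0:
        raise ValueError("radial_range must be (min, max) with min <= max")
    if n_samples < 10:
        n_samples = 10
    e, w = spectrum.energies, spectrum.weights
    mu_lin = medium.density * medium.mu_at(e)

    if r1 == r0:
        warnings.warn("degenerate radial range; using the point spectrum at "
                      f"depth {r0:g} cm", stacklevel=2)
        att = w * e * np.exp(-mu_lin * r0)
        att /= att.sum()
        mu_eff = float(np.sum(att * medium.mu_at(e)))
        muen_eff = float(np.sum(att * medium.muen_at(e)))
        return mu_eff, muen_eff

    radii = np.linspace(r0, r1, n_samples)
    we = w * e  # primary energy-fluence weights
    target = (we[None, :] * np.exp(-mu_lin[None, :] * radii[:, None])).sum(axis=1)
    target /= we.sum()

    def sse(mu_eff_lin):
        return float(np.sum((np.exp(-mu_eff_lin * radii) - target) ** 2))

    lo, hi = mu_lin.min(), mu_lin.max()
    if hi - lo < 1e-14:  # monoenergetic: no hardening
        mu_eff_lin = float(mu_lin[0])
    else:
        res = minimize_scalar(sse, bounds=(0.5 * lo, 1.5 * hi), method="bounded",
                              options={"xatol": 1e-12})
        mu_eff_lin = float(res.x)

    # hardened-spectrum muen, averaged over the same radii
    muen = medium.muen_at(e)
    att = we[None, :] * np.exp(-mu_lin[None, :] * radii[:, None])
    muen_eff = float(np.mean(att @ muen / att.sum(axis=1)))
    return mu_eff_lin / medium.density, muen_eff
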