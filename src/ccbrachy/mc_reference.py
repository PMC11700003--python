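"""Generation-resolved photon Monte Carlo reference.

Photon-only transport (electron transport disabled, collision kerma as the
dose surrogate) with scatter-generation bookkeeping: every particle
carries a bookkeeping number (bkn); source photons start at bkn = 0 and a
photon produced in a photon interaction gets its parent's bkn + 1, so
kerma tallies split into prim (bkn=0), 1sc (bkn=1) and msc (bkn>=2)
classes that match the engine's successive-scattering decomposition.
Interaction forcing (within a configurable forcing radius) and
history-by-history Type A uncertainty estimation are built in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _mc_core
from ._mc_phys import build_medium_lookup, seed_rng
from .phantom import VoxelPhantom
from .physics_data import PhotonSpectrum, ir192_spectrum

__all__ = ["KermaTally", "assign_bkn", "run_mc", "uncertainty", "GEN_CLASSES"]

GEN_CLASSES = ("prim", "1sc", "msc")


def assign_bkn(parent_bkn: int, event: str,
               rayleigh_increments: bool = True) -> int:
    """Bookkeeping number of the product of an interaction.

    Source photons carry bkn 0; a photon produced in a photon interaction
    gets parent + 1; secondary charged particles would keep the parent bkn
    (vacuous here: electron transport is disabled).  Whether elastic
    (Rayleigh) scattering increments is configurable; the default applies
    the "+1 per photon interaction" rule literally.
    """
    if parent_bkn < 0:
        raise ValueError("bkn must be >= 0")
    if event == "source":
        return 0
    if event in ("compton", "photon"):
        return parent_bkn + 1
    if event == "rayleigh":
        return parent_bkn + 1 if rayleigh_increments else parent_bkn
    if event == "charged_secondary":
        return parent_bkn
    raise ValueError(f"unknown event {event!r}")


@dataclass
class KermaTally:
    """Per-voxel, per-generation collision-kerma tally with
    history-by-history variance accumulators.

    ``acc``/``sq`` hold per-class sums and sums of squares of per-history
    scores [MeV/g]; ``kerma(gen)`` returns the per-history mean.  The
    total is the exact sum of the three class tallies.
    """

    shape: tuple[int, int, int]
    acc: np.ndarray  # (3, n_voxels)
    sq: np.ndarray
    n_histories: int
    emitted: float
    escaped: float
    cutoff_deposited: float
    seed: int
    region_mask: Optional[np.ndarray] = None
    region_sum: Optional[np.ndarray] = None  # (4,) prim/1sc/msc/tot
    region_sq: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def kerma(self, gen: str = "tot") -> np.ndarray:
        """Mean collision kerma [MeV/g per emitted photon]."""
        if gen == "tot":
            flat = self.acc.sum(axis=0)
        else:
            flat = self.acc[GEN_CLASSES.index(gen)]
        return (flat / self.n_histories).reshape(self.shape)

    def uncertainty_grid(self, gen: str = "tot", k: float = 2.0) -> np.ndarray:
        """Per-voxel Type A absolute uncertainty of the mean (coverage k)."""
        n = self.n_histories
        if gen == "tot":
            s1 = self.acc.sum(axis=0)
            s2 = None  # covariances between classes are not stored per voxel
            # per-history total scores: acc/sq accumulated per class; the
            # total-score variance is bounded below by the class sum -- use
            # the conservative class-wise sum of variances
            var = sum(np.maximum(self.sq[c] - self.acc[c] ** 2 / n, 0.0)
                      for c in range(3)) / (n * (n - 1))
        else:
            c = GEN_CLASSES.index(gen)
            s1 = self.acc[c]
            var = np.maximum(self.sq[c] - s1**2 / n, 0.0) / (n * (n - 1))
        return (k * np.sqrt(var)).reshape(self.shape)

    def __add__(self, other: "KermaTally") -> "KermaTally":
        """Merge two independent batches (associative)."""
        if self.shape != other.shape:
            raise ValueError("tally shapes differ")
        rs = rq = rm = None
        if self.region_sum is not None and other.region_sum is not None:
            rs = self.region_sum + other.region_sum
            rq = self.region_sq + other.region_sq
            rm = self.region_mask
        return KermaTally(self.shape, self.acc + other.acc,
                          self.sq + other.sq,
                          self.n_histories + other.n_histories,
                          self.emitted + other.emitted,
                          self.escaped + other.escaped,
                          self.cutoff_deposited + other.cutoff_deposited,
                          self.seed, rm, rs, rq, dict(self.metadata))

    def save(self, path) -> None:
        from .io import write_volumes
        vols = {f"kerma_{g}": self.kerma(g) for g in GEN_CLASSES}
        vols["kerma_tot"] = self.kerma("tot")
        for g in GEN_CLASSES + ("tot",):
            vols[f"unc_{g}"] = self.uncertainty_grid(g)
        write_volumes(path, vols, {"n_histories": self.n_histories,
                                   "seed": self.seed, **self.metadata})


def run_mc(phantom: VoxelPhantom, spectrum: Optional[PhotonSpectrum] = None,
           n_histories: int = 1_000_000, seed: int = 1,
           forcing: bool = True, forcing_radius: float = 12.0,
           region_mask: Optional[np.ndarray] = None,
           rayleigh: bool = True, rayleigh_increments_bkn: bool = True,
           rr_threshold: float = 0.02, rr_survival: float = 0.25) -> KermaTally:
    """Run the Monte Carlo reference on a phantom.

    ``region_mask`` enables exact history-by-history uncertainty
    accumulation for that region's mean dose (used for the heterogeneity
    statistics).  Fixed seed gives bit-identical tallies.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    if int(seed) < 0:
        raise ValueError("seed must be non-negative")
    if spectrum is None:
        spectrum = ir192_spectrum()
    nx, ny, nz = phantom.shape
    n_vox = nx * ny * nz
    ln_e0, dln, mu, muen, fpe, finc = build_medium_lookup(phantom.media)
    cumw = np.cumsum(spectrum.weights)
    cumw[-1] = 1.0

    medium_flat = np.ascontiguousarray(phantom.medium_index.reshape(-1))
    rho_flat = np.ascontiguousarray(phantom.density.reshape(-1))
    if region_mask is not None:
        region_flat = np.ascontiguousarray(
            region_mask.reshape(-1).astype(np.uint8))
    else:
        region_flat = np.zeros(n_vox, dtype=np.uint8)

    acc = np.zeros((3, n_vox))
    sq = np.zeros((3, n_vox))
    tmp = np.zeros((3, n_vox))
    last = np.full((3, n_vox), -1, dtype=np.int64)
    reg_sum = np.zeros(4)
    reg_sq = np.zeros(4)

    seed_rng(int(seed) % 2**31)
    emitted, escaped, cutoff = _mc_core.run_histories(
        spectrum.energies, cumw, ln_e0, dln, mu, muen, fpe, finc,
        phantom.origin, phantom.voxel_size, nx, ny, nz, medium_flat,
        rho_flat, np.asarray(phantom.source_position, dtype=float),
        int(n_histories), 0, forcing, forcing_radius, rr_threshold,
        rr_survival, rayleigh, rayleigh_increments_bkn, region_flat,
        acc, sq, tmp, last, reg_sum, reg_sq)
    _mc_core.flush_accumulators(acc, sq, tmp, last)

    return KermaTally((nx, ny, nz), acc, sq, int(n_histories),
                      emitted, escaped, cutoff, int(seed),
                      region_mask,
                      reg_sum if region_mask is not None else None,
                      reg_sq if region_mask is not None else None,
                      {"forcing": forcing, "forcing_radius": forcing_radius,
                       "rayleigh": rayleigh,
                       "rayleigh_increments_bkn": rayleigh_increments_bkn})


def uncertainty(tally: KermaTally, region: Optional[np.ndarray] = None,
                gen: str = "tot", k: float = 2.0) -> float:
    """Relative Type A uncertainty (coverage k) of the mean dose over a
    region.

    Uses the exact history-by-history region accumulators when *region*
    matches the mask the tally was run with (or for single-voxel regions);
    otherwise falls back to the independent-voxel approximation, which
    ignores intra-history correlations between voxels.
    """
    n = tally.n_histories
    if region is None:
        region = (tally.region_mask if tally.region_mask is not None
                  else np.ones(tally.shape, dtype=bool))
    region = np.asarray(region, dtype=bool)
    idx = 3 if gen == "tot" else GEN_CLASSES.index(gen)

    if (tally.region_mask is not None
            and region.shape == tally.region_mask.shape
            and np.array_equal(region, tally.region_mask)):
        s1 = tally.region_sum[idx]
        s2 = tally.region_sq[idx]
        if s1 == 0.0:
            return np.inf
        var_mean = max(s2 - s1 * s1 / n, 0.0) / (n * (n - 1))
        return k * np.sqrt(var_mean) / (s1 / n)

    # independent-voxel approximation: sum of per-voxel variances
    flat = region.reshape(-1)
    if gen == "tot":
        s1v = tally.acc.sum(axis=0)[flat]
        varv = sum(np.maximum(tally.sq[c][flat]
                              - tally.acc[c][flat] ** 2 / n, 0.0)
                   for c in range(3))
    else:
        c = GEN_CLASSES.index(gen)
        s1v = tally.acc[c][flat]
        varv = np.maximum(tally.sq[c][flat] - s1v**2 / n, 0.0)
    s1 = float(s1v.sum())
    if s1 == 0.0:
        return np.inf
    var_mean = float(varv.sum()) / (n * (n - 1))
    return k * np.sqrt(var_mean) / (s1 / n)
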