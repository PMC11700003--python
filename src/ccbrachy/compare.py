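"""Figure-of-merit layer: percentage dose difference ratio maps
(Delta_gen), region statistics, histograms and profiles.

The figure of merit is Delta_gen = 100 (D_gen^test - D_gen^MC) / D_tot^MC
per voxel -- the denominator is always the TOTAL reference dose, so the
component maps satisfy Delta_tot = Delta_prim + Delta_1sc + Delta_msc
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as _stats

from .cc_engine import DoseComponents
from .mc_reference import KermaTally, uncertainty as _mc_uncertainty

__all__ = ["DeltaStats", "delta_map", "region_stats", "histogram", "profile",
           "delta_stats"]

GENS = ("prim", "1sc", "msc", "tot")


def delta_map(d_test: DoseComponents, d_mc: KermaTally, gen: str = "tot"):
    """Percentage dose difference ratio map for one generation.

    Voxels with zero total MC dose are masked (NaN) and counted in the
    returned mask's complement.
    """
    if gen not in GENS:
        raise ValueError(f"invalid generation {gen!r}")
    test = d_test.component(gen)
    ref = d_mc.kerma(gen)
    denom = d_mc.kerma("tot")
    if test.shape != denom.shape:
        raise ValueError("grids are not co-registered")
    valid = denom > 0
    out = np.full(test.shape, np.nan)
    out[valid] = 100.0 * (test[valid] - ref[valid]) / denom[valid]
    return out, valid


def region_stats(delta: np.ndarray, region: np.ndarray):
    """(mean, SD, median, skewness) of a Delta map over a region mask.

    Skewness is Fisher's standardized third moment; NaN (masked) voxels
    inside the region are excluded.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region mask")
    vals = np.asarray(delta)[region]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("region contains no valid voxels")
    sd = float(np.std(vals, ddof=0))
    skew = float(_stats.skew(vals, bias=True)) if sd > 0 else 0.0
    return float(np.mean(vals)), sd, float(np.median(vals)), skew


def histogram(delta: np.ndarray, region: Optional[np.ndarray] = None,
              bin_width: float = 0.5):
    """Delta histogram with fixed-width bins, normalized so that the
    integral sum(height * width) equals 100."""
    vals = np.asarray(delta)
    if region is not None:
        vals = vals[np.asarray(region, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    heights = 100.0 * counts / (counts.sum() * bin_width)
    return heights, edges


def profile(dose: np.ndarray, reference: np.ndarray, phantom,
            mask_source: bool = True):
    """Normalized dose profile along the +/-x axis through the source
    (y = z = 0 line), divided by a homogeneous-water reference dose at
    matched radii (the TG-43 surrogate).

    Returns (x_centers, dose/reference); the source voxel is masked NaN.
    """
    nx, ny, nz = phantom.shape
    jy, jz = ny // 2, nz // 2
    x = phantom.axis_centers(0)
    line = np.asarray(dose)[:, jy, jz].astype(float)
    ref = np.asarray(reference)[:, jy, jz].astype(float)
    out = np.full(nx, np.nan)
    ok = ref > 0
    out[ok] = line[ok] / ref[ok]
    if mask_source:
        out[np.argmin(np.abs(x - phantom.source_position[0]))] = np.nan
    return x, out


@dataclass
class DeltaStats:
    """Per-generation Delta maps and region statistics for one engine-MC
    comparison."""

    maps: dict = field(default_factory=dict)  # gen -> Delta grid
    stats: dict = field(default_factory=dict)  # gen -> (mean, sd, med, skew)
    mean_uncertainty: dict = field(default_factory=dict)  # gen -> k=2 rel. MC unc.
    n_region_voxels: int = 0
    mode: str = ""

    def to_rows(self, label: str = ""):
        rows = []
        for gen in GENS:
            m, sd, med, sk = self.stats[gen]
            rows.append({"case": label, "mode": self.mode, "gen": gen,
                         "mean": m, "sd": sd, "median": med, "skewness": sk,
                         "mc_unc_k2": self.mean_uncertainty.get(gen, np.nan)})
        return rows


def delta_stats(d_test: DoseComponents, d_mc: KermaTally,
                region: np.ndarray) -> DeltaStats:
    """Full Table-style statistics of the Delta distributions in a region.

    Also propagates the MC Type A (k=2) uncertainty of each region-mean
    Delta from the MC region uncertainty.
    """
    out = DeltaStats(mode=d_test.mode,
                     n_region_voxels=int(np.count_nonzero(region)))
    denom_mean = float(np.mean(d_mc.kerma("tot")[np.asarray(region, bool)]))
    for gen in GENS:
        dmap, _ = delta_map(d_test, d_mc, gen)
        out.maps[gen] = dmap
        out.stats[gen] = region_stats(dmap, region)
        # MC uncertainty on the mean Delta: relative k=2 uncertainty of the
        # region-mean MC component dose, expressed in Delta (%) units
        rel = _mc_uncertainty(d_mc, region, gen)
        comp_mean = float(np.mean(d_mc.kerma(gen)[np.asarray(region, bool)]))
        out.mean_uncertainty[gen] = 100.0 * rel * comp_mean / denom_mean
    return out
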