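"""Numba core of the generation-resolved photon Monte Carlo reference.

Photon histories random-walk on the voxel grid with exact per-voxel
raytraced free paths.  Collision kerma is scored with a track-length
estimator, w * E * (mu_en/rho) * l / V_voxel per traversed segment, into
the scatter-generation class of the photon's bookkeeping number
(prim: bkn=0, 1sc: bkn=1, msc: bkn>=2).  Interaction forcing splits each
flight into an analytically-scored escape branch and a collision branch
sampled from the truncated free-path distribution, which keeps the simple
track-length tally unbiased.  Type A uncertainties use history-by-history
accumulators.
"""

import numpy as np
from numba import njit

from ._mc_phys import (lookup, rotate_direction, sample_compton,
                       sample_rayleigh_cos, sample_spectrum_line)
from .constants import E_CUTOFF

_EPS = 1e-12


@njit(cache=True, inline="always")
def _score(cls, v, amount, h_id, acc, sq, tmp, last):
    if last[cls, v] != h_id:
        sq[cls, v] += tmp[cls, v] * tmp[cls, v]
        acc[cls, v] += tmp[cls, v]
        tmp[cls, v] = 0.0
        last[cls, v] = h_id
    tmp[cls, v] += amount


@njit(cache=True)
def _trace_segments(pos, d, origin, h, nx, ny, nz, medium_flat, rho_flat,
                    ln_e0, dln, mu_tab, e,
                    seg_vox, seg_len, seg_mu):
    """Walk from pos along d to the grid boundary; fill per-voxel segment
    buffers (voxel flat index, length, linear mu).  Returns (n_seg,
    tau_exit, t_exit)."""
    lo = origin
    hi0 = origin[0] + nx * h
    hi1 = origin[1] + ny * h
    hi2 = origin[2] + nz * h

    ix = int((pos[0] - origin[0]) / h)
    iy = int((pos[1] - origin[1]) / h)
    iz = int((pos[2] - origin[2]) / h)
    if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
        return 0, 0.0, 0.0

    step = np.empty(3, dtype=np.int64)
    t_max = np.empty(3)
    t_delta = np.empty(3)
    idx = np.empty(3, dtype=np.int64)
    idx[0], idx[1], idx[2] = ix, iy, iz
    for k in range(3):
        if d[k] > _EPS:
            step[k] = 1
            t_max[k] = ((idx[k] + 1) * h + origin[k] - pos[k]) / d[k]
            t_delta[k] = h / d[k]
        elif d[k] < -_EPS:
            step[k] = -1
            t_max[k] = (idx[k] * h + origin[k] - pos[k]) / d[k]
            t_delta[k] = -h / d[k]
        else:
            step[k] = 0
            t_max[k] = 1.0e300
            t_delta[k] = 1.0e300

    n_seg = 0
    tau = 0.0
    t_cur = 0.0
    while True:
        k_min = 0
        if t_max[1] < t_max[k_min]:
            k_min = 1
        if t_max[2] < t_max[k_min]:
            k_min = 2
        t_next = t_max[k_min]
        v = (idx[0] * ny + idx[1]) * nz + idx[2]
        dl = t_next - t_cur
        if dl > _EPS:
            mu_lin = rho_flat[v] * lookup(mu_tab, medium_flat[v], ln_e0, dln, e)
            seg_vox[n_seg] = v
            seg_len[n_seg] = dl
            seg_mu[n_seg] = mu_lin
            tau += mu_lin * dl
            n_seg += 1
        t_cur = t_next
        idx[k_min] += step[k_min]
        if idx[k_min] < 0 or idx[k_min] >= (nx if k_min == 0 else (ny if k_min == 1 else nz)):
            break
        t_max[k_min] += t_delta[k_min]
    return n_seg, tau, t_cur


@njit(cache=True)
def run_histories(energies, cumw, ln_e0, dln, mu_tab, muen_tab, fpe_tab,
                  finc_tab, origin, h, nx, ny, nz, medium_flat, rho_flat,
                  source, n_hist, hist_offset, forcing, forcing_radius,
                  rr_threshold, rr_survival, rayleigh_on, rayleigh_bkn,
                  region_flat, acc, sq, tmp, last, reg_sum, reg_sq):
    """Run n_hist histories; accumulators are updated in place.

    Returns (emitted, escaped, cutoff_deposited) energy sums [MeV].
    """
    inv_vol = 1.0 / (h * h * h)
    n_seg_max = 3 * (nx + ny + nz) + 6
    seg_vox = np.empty(n_seg_max, dtype=np.int64)
    seg_len = np.empty(n_seg_max)
    seg_mu = np.empty(n_seg_max)
    reg_tmp = np.zeros(4)

    emitted = 0.0
    escaped = 0.0
    cutoff_dep = 0.0

    for hh in range(n_hist):
        h_id = hist_offset + hh
        for c in range(4):
            reg_tmp[c] = 0.0
        e = sample_spectrum_line(energies, cumw)
        emitted += e
        # isotropic emission
        ct = 2.0 * np.random.random() - 1.0
        st = np.sqrt(max(0.0, 1.0 - ct * ct))
        phi = 2.0 * np.pi * np.random.random()
        d = np.empty(3)
        d[0] = st * np.cos(phi)
        d[1] = st * np.sin(phi)
        d[2] = ct
        pos = source.copy()
        w = 1.0
        bkn = 0

        while True:  # flights
            cls = bkn if bkn < 2 else 2
            n_seg, tau_exit, t_exit = _trace_segments(
                pos, d, origin, h, nx, ny, nz, medium_flat, rho_flat,
                ln_e0, dln, mu_tab, e, seg_vox, seg_len, seg_mu)
            if n_seg == 0:
                escaped += w * e
                break
            r_src = np.sqrt((pos[0] - source[0]) ** 2
                            + (pos[1] - source[1]) ** 2
                            + (pos[2] - source[2]) ** 2)
            use_forcing = forcing and (r_src < forcing_radius)

            if use_forcing:
                # split the flight into an analytically-scored escape
                # branch (weight w e^-tau_exit, traversing every segment)
                # and a collision branch sampled from the truncated
                # free-path distribution; segments upstream of the sampled
                # collision are traversed by both branches (total weight
                # w), downstream ones by the escape branch alone
                p_int = -np.expm1(-tau_exit)
                if p_int < 1e-12:
                    p_int = 1e-12
                w_col = w * p_int
                w_esc = w - w_col
                tau_s = -np.log(1.0 - np.random.random() * p_int)
            else:
                w_col = w
                w_esc = 0.0
                tau_s = -np.log(np.random.random())

            interacted = False
            tau_cum = 0.0
            t_int = 0.0
            v_int = seg_vox[0]
            for i in range(n_seg):
                v = seg_vox[i]
                mu_lin = seg_mu[i]
                muen_m = lookup(muen_tab, medium_flat[v], ln_e0, dln, e)
                seg_tau = mu_lin * seg_len[i]
                if (not interacted) and tau_cum + seg_tau >= tau_s and mu_lin > 0.0:
                    frac = (tau_s - tau_cum) / seg_tau
                    lpart = seg_len[i] * frac
                    # collision branch stops partway through this segment
                    amount = (w_col * lpart + w_esc * seg_len[i]) \
                        * e * muen_m * inv_vol
                    t_int += lpart
                    v_int = v
                    interacted = True
                else:
                    wseg = w if not interacted else w_esc
                    amount = wseg * e * muen_m * seg_len[i] * inv_vol
                    if not interacted:
                        tau_cum += seg_tau
                        t_int += seg_len[i]
                if amount != 0.0:
                    _score(cls, v, amount, h_id, acc, sq, tmp, last)
                    if region_flat[v]:
                        reg_tmp[cls] += amount
                        reg_tmp[3] += amount
                if interacted and w_esc == 0.0:
                    break

            if use_forcing:
                escaped += w_esc * e
                w = w_col
                if not interacted:
                    # floating-point drift past the last segment: collide
                    # at the end of the path
                    v_int = seg_vox[n_seg - 1]
                    t_int = t_exit
                    interacted = True
            if not interacted:
                # analog flight left the phantom
                escaped += w * e
                break

            pos[0] += t_int * d[0]
            pos[1] += t_int * d[1]
            pos[2] += t_int * d[2]

            # interaction
            im = medium_flat[v_int]
            f_pe = lookup(fpe_tab, im, ln_e0, dln, e)
            f_inc = lookup(finc_tab, im, ln_e0, dln, e)
            u = np.random.random()
            if u < f_pe:
                break  # photoelectric absorption ends the chain
            if u < f_pe + f_inc:
                e, cos_t = sample_compton(e)
                bkn += 1
            else:
                if not rayleigh_on:
                    break
                cos_t = sample_rayleigh_cos()
                if rayleigh_bkn:
                    bkn += 1
            if e < E_CUTOFF:
                cls = bkn if bkn < 2 else 2
                # local deposit [MeV/g]: w e / (rho V)
                amount = w * e * inv_vol / rho_flat[v_int]
                _score(cls, v_int, amount, h_id, acc, sq, tmp, last)
                if region_flat[v_int]:
                    reg_tmp[cls] += amount
                    reg_tmp[3] += amount
                cutoff_dep += w * e
                break
            d = rotate_direction(d, cos_t, 2.0 * np.pi * np.random.random())
            # Russian roulette on low weights
            if w < rr_threshold:
                if np.random.random() < rr_survival:
                    w /= rr_survival
                else:
                    break

        for c in range(4):
            reg_sum[c] += reg_tmp[c]
            reg_sq[c] += reg_tmp[c] * reg_tmp[c]

    return emitted, escaped, cutoff_dep


@njit(cache=True)
def flush_accumulators(acc, sq, tmp, last):
    """Fold any per-history temporaries still pending into acc/sq."""
    for c in range(acc.shape[0]):
        for v in range(acc.shape[1]):
            if tmp[c, v] != 0.0:
                sq[c, v] += tmp[c, v] * tmp[c, v]
                acc[c, v] += tmp[c, v]
                tmp[c, v] = 0.0
            last[c, v] = -1
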