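"""Numba core of the collapsed-cone line transport.

One call transports one direction: it builds the transport-line lattice,
accumulates the per-voxel total step length (Delta-l_max), then runs the
two-term exponential recursion along every line.  Per line and kernel
term, with x = eta_j c_theta dl_j,

    eps_j     = exp(-x)
    sigma_j   = S_j rho_j dOmega C_theta/c_theta * kappa_j
    dR_j      = sigma_j (1 - eps_j) / (eta_j c_theta)
    bracket_j = (1 - eps_j) R_{j-1} + sigma_j dl_j - dR_j
    deposit_j = [chi_j/eta_j] bracket_j            (corrected mode)
              = bracket_j                          (original mode)
    R_j       = R_{j-1} eps_j + dR_j [+ (1 - chi_j/eta_j) bracket_j]

kappa_j = V_voxel / (A_line * Delta-l_max,j) normalizes the per-line
release so the voxel's released energy is exact for the actual finite
lattice.  The recursion conserves energy exactly in both modes:
incoming + released = deposited + outgoing per step.
"""

import numpy as np
from numba import njit

from ._geometry import build_direction_lines


@njit(cache=True)
def transport_one_direction(d, origin, h, nx, ny, nz, spacing,
                            vox_buf, dl_buf, start_buf, dlmax_buf,
                            s_flat, rho_flat, eta_flat, chi_ratio_flat,
                            corrected, C_arr, c_arr, F_arr, f_arr,
                            C_avg, F_avg, dOmega, source, dose_flat):
    """Transport one direction; returns (released, deposited, exited,
    n_clamped)."""
    n_lines, n_steps = build_direction_lines(d, origin, h, nx, ny, nz,
                                             spacing, vox_buf, dl_buf,
                                             start_buf)
    for v in range(nx * ny * nz):
        dlmax_buf[v] = 0.0
    for j in range(n_steps):
        dlmax_buf[vox_buf[j]] += dl_buf[j]

    n_theta = len(C_arr)
    area = spacing * spacing
    vol = h * h * h
    released = 0.0
    deposited = 0.0
    exited = 0.0
    n_clamped = 0

    for line in range(n_lines):
        r_c = 0.0
        r_f = 0.0
        for j in range(start_buf[line], start_buf[line + 1]):
            v = vox_buf[j]
            dl = dl_buf[j]
            rho = rho_flat[v]
            eta = eta_flat[v]
            chir = chi_ratio_flat[v]
            s_val = s_flat[v]

            # polar angle of this transport direction relative to the local
            # incident (radial) direction
            iz = v % nz
            iy = (v // nz) % ny
            ix = v // (ny * nz)
            rx = origin[0] + (ix + 0.5) * h - source[0]
            ry = origin[1] + (iy + 0.5) * h - source[1]
            rz = origin[2] + (iz + 0.5) * h - source[2]
            rn = np.sqrt(rx * rx + ry * ry + rz * rz)
            if rn > 0.5 * h:
                cos_t = (d[0] * rx + d[1] * ry + d[2] * rz) / rn
                it = int((1.0 - cos_t) * 0.5 * n_theta)
                if it < 0:
                    it = 0
                elif it >= n_theta:
                    it = n_theta - 1
                amp_c = C_arr[it]
                amp_f = F_arr[it]
            else:
                # source voxel: the incident (radial) direction is
                # undefined; release with the 4pi-averaged amplitudes
                it = 0
                amp_c = C_avg
                amp_f = F_avg

            kappa = vol / (area * dlmax_buf[v])
            src_amp = s_val * rho * dOmega * kappa

            # --- C term ---
            cc = c_arr[it]
            x = eta * cc * dl
            one_m_eps = -np.expm1(-x)
            eps = 1.0 - one_m_eps
            sigma = src_amp * amp_c / cc
            d_r = sigma * one_m_eps / (eta * cc)
            bracket = one_m_eps * r_c + sigma * dl - d_r
            if bracket < 0.0:
                bracket = 0.0
                n_clamped += 1
            if corrected:
                dep = chir * bracket
                r_c = r_c * eps + d_r + (1.0 - chir) * bracket
            else:
                dep = bracket
                r_c = r_c * eps + d_r
            dose_flat[v] += dep * area / (rho * vol)
            deposited += dep * area
            released += sigma * dl * area

            # --- F term ---
            ff = f_arr[it]
            x = eta * ff * dl
            one_m_eps = -np.expm1(-x)
            eps = 1.0 - one_m_eps
            sigma = src_amp * amp_f / ff
            d_r = sigma * one_m_eps / (eta * ff)
            bracket = one_m_eps * r_f + sigma * dl - d_r
            # never clamp the F term: with a build-up kernel (negative F)
            # it legitimately carries a negative partial fluence that the
            # C term over-covers; only the net deposit is physical
            if corrected:
                dep = chir * bracket
                r_f = r_f * eps + d_r + (1.0 - chir) * bracket
            else:
                dep = bracket
                r_f = r_f * eps + d_r
            dose_flat[v] += dep * area / (rho * vol)
            deposited += dep * area
            released += sigma * dl * area

        exited += (r_c + r_f) * area
    return released, deposited, exited, n_clamped
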