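"""Independent pure-python reference implementations used as test oracles."""

import numpy as np


def line_recursion(steps, corrected):
    """Reference multiple-scatter line recursion for one kernel term.

    ``steps`` is a sequence of dicts with keys eta, chi_over_eta, rho, dl,
    sigma, c (per-step cone attenuation).  Returns (deposits, r_out,
    per-step conservation residuals) where deposits are the bracket-level
    energies (before the 1/(rho dlmax) dose conversion) and each residual
    is |incoming + released - deposited' - outgoing'| for the step.
    """
    r = 0.0
    deposits = []
    residuals = []
    for s in steps:
        x = s["eta"] * s["c"] * s["dl"]
        eps = np.exp(-x)
        d_r = s["sigma"] * (1.0 - eps) / (s["eta"] * s["c"])
        bracket = (1.0 - eps) * r + s["sigma"] * s["dl"] - d_r
        if corrected:
            dep = s["chi_over_eta"] * bracket
            r_new = r * eps + d_r + (1.0 - s["chi_over_eta"]) * bracket
        else:
            dep = bracket
            r_new = r * eps + d_r
        residuals.append(abs((r + s["sigma"] * s["dl"]) - (dep + r_new)))
        deposits.append(dep)
        r = r_new
    return np.array(deposits), r, np.array(residuals)
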