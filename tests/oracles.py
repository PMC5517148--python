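"""Independent reference implementations used as test oracles.

Deliberately naive (plain Python loops over every field square) and kept
separate from the package's code paths.
"""

import math

import numpy as np


def disc_weight(cx, cy, ix, iy, radius=3.5, sigma_frac=0.5):
    """Peak-normalized truncated-Gaussian weight of square (ix, iy)."""
    dx = ix + 0.5 - cx
    dy = iy + 0.5 - cy
    d2 = dx * dx + dy * dy
    if d2 > radius * radius:
        return 0.0
    sigma = sigma_frac * radius
    return math.exp(-d2 / (2.0 * sigma * sigma))


def brute_force_potential(terminal, field, others=(), C=0.0, sigma_frac=0.5):
    """Term-by-term evaluation of the guidance potential over all squares."""
    cx, cy = terminal.center
    num = 0.0
    den = 0.0
    for iy in range(field.height):
        for ix in range(field.width):
            w = disc_weight(cx, cy, ix, iy, terminal.radius, sigma_frac)
            if w == 0.0:
                continue
            Rf = 0.0
            Lf = 0.0
            for o in others:
                if o is terminal:
                    continue
                wo = disc_weight(o.center[0], o.center[1], ix, iy,
                                 o.radius, sigma_frac)
                Rf += wo * o.R_F
                Lf += wo * o.L_F
            if field.resident_R_f is not None:
                Rf += field.resident_R_f[iy, ix]
            if field.resident_L_f is not None:
                Lf += field.resident_L_f[iy, ix]
            num += terminal.L_F * w * (field.R_T[iy, ix]
                                       + terminal.R_F * w + C * Rf)
            den += terminal.R_F * w * (field.L_T[iy, ix]
                                       + terminal.L_F * w + C * Lf)
    if num <= 0.0 or den <= 0.0:
        return float("inf")
    return abs(math.log(num / den))


def weighted_history_coefficient(history, mu, h):
    """Linear-weight adaptation coefficient computed the long way."""
    padded = [0.0] * (h - len(history)) + list(history)
    num = sum((k + 1) * d for k, d in enumerate(padded))
    den = sum(range(1, h + 1))
    return 1.0 + math.log(1.0 + mu * num / den)
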