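"""Shared constructors for the test suite."""

import numpy as np

from ephmap import FiberTerminal, TargetField


def make_terminal(x=10.0, y=4.0, u=0.5, R=1.0, L=1.0, radius=3.5, **kw):
    return FiberTerminal(center=(x, y), origin_u=u, R_F0=R, L_F0=L,
                         R_F=R, L_F=L, radius=radius, **kw)


def random_micro_instance(rng):
    """Small random field + terminal population for oracle comparisons."""
    W = int(rng.integers(6, 12))
    H = int(rng.integers(4, 8))
    field = TargetField(
        width=W, height=H,
        L_T=rng.uniform(0.0, 4.0, size=(H, W)),
        R_T=rng.uniform(0.0, 4.0, size=(H, W)),
    )
    terms = [
        make_terminal(
            x=float(rng.uniform(1.0, W - 1.0)),
            y=float(rng.uniform(1.0, H - 1.0)),
            R=float(rng.uniform(0.2, 4.0)),
            L=float(rng.uniform(0.2, 4.0)),
        )
        for _ in range(int(rng.integers(1, 5)))
    ]
    C = float(rng.uniform(0.0, 2.0))
    return field, terms, C
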