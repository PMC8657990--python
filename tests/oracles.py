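"""Independent fixed-step RK4 reference integrator for the test suite.

Deliberately written from the chemistry, not from the package's rhs: a
plain-Python Runge–Kutta loop over the nine time-dependent species with
clamped O2.  Slow but simple; used only on short reference problems.
"""

from __future__ import annotations

import numpy as np


def rk4_reference(
    *,
    k_as: float,
    k_o2: float,
    k_probe: float,
    k_dim: float,
    k_nuc: float,
    as0: float,
    probe0: float,
    o2: float,
    nuc0: float = 0.0,
    t_end: float = 600.0,
    dt: float = 0.01,
    record_every: float = 1.0,
):
    """Integrate the competition network; returns (times, dict of arrays).

    Species: AS, HNO, ONOO, FlBA, FlOH, nucleophile, adduct, N2O, NO2.
    O2 is held constant at ``o2``.
    """

    def deriv(y):
        as_, hno, onoo, flba, floh, nuc, add, n2o, no2 = y
        r_rel = k_as * as_
        r_o2 = k_o2 * o2 * hno
        r_nuc = k_nuc * nuc * hno
        r_dim = k_dim * hno * hno
        r_pr = k_probe * flba * onoo
        return (
            -r_rel,
            r_rel - r_o2 - r_nuc - 2.0 * r_dim,
            r_o2 - r_pr,
            -r_pr,
            r_pr,
            -r_nuc,
            r_nuc,
            r_dim,
            r_pr,
        )

    y = (as0, 0.0, 0.0, probe0, 0.0, nuc0, 0.0, 0.0, 0.0)
    n_steps = int(round(t_end / dt))
    stride = max(1, int(round(record_every / dt)))
    times = [0.0]
    records = [y]
    for step in range(1, n_steps + 1):
        k1 = deriv(y)
        y2 = tuple(a + 0.5 * dt * b for a, b in zip(y, k1))
        k2 = deriv(y2)
        y3 = tuple(a + 0.5 * dt * b for a, b in zip(y, k2))
        k3 = deriv(y3)
        y4 = tuple(a + dt * b for a, b in zip(y, k3))
        k4 = deriv(y4)
        y = tuple(
            a + dt / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            for a, b1, b2, b3, b4 in zip(y, k1, k2, k3, k4)
        )
        if step % stride == 0:
            times.append(step * dt)
            records.append(y)
    arr = np.array(records)
    names = ("AS", "HNO", "ONOO", "FlBA", "FlOH", "nucleophile", "adduct", "N2O", "NO2")
    return np.array(times), {n: arr[:, i] for i, n in enumerate(names)}
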