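"""Independent brute-force oracles used only by the test suite."""

import numpy as np

from meltfit.models import KineticParams, unfolding_rate


def rk4_native_fraction(p: KineticParams, T: np.ndarray, max_hk: float = 0.05) -> np.ndarray:
    """Classic fixed-step 4th-order Runge–Kutta solve of
    dx_N/dT = −k_u(T)·x_N / v, substepped so each step satisfies
    h·k_u/v ≤ ``max_hk`` (the ODE turns stiff where the rate explodes).

    Deliberately independent of the closed-form path it checks.
    """

    def rhs(t: float, x: float) -> float:
        return -float(unfolding_rate(p, t)) * x / p.v

    x = 1.0
    out = [x]
    for i in range(T.size - 1):
        if x < 1e-15:  # fully unfolded; the ODE keeps x at 0
            out.append(0.0)
            continue
        h = T[i + 1] - T[i]
        k_end = float(unfolding_rate(p, T[i + 1])) / p.v
        nsub = min(10_000, max(1, int(np.ceil(h * k_end / max_hk))))
        hh = h / nsub
        t = float(T[i])
        for _ in range(nsub):
            k1 = rhs(t, x)
            k2 = rhs(t + hh / 2, x + hh / 2 * k1)
            k3 = rhs(t + hh / 2, x + hh / 2 * k2)
            k4 = rhs(t + hh, x + hh * k3)
            x = x + hh / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += hh
        out.append(x)
    return np.array(out)
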