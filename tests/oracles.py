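"""Independent numerical oracles used by the tests.

These deliberately avoid the package's closed-form code paths: the
decay chain is integrated as a stiff ODE in activity space, and organ
AUCs are computed by adaptive quadrature of the generating curves.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad, solve_ivp


def ode_chain_activities(chain, initial_activities_bq: dict, times_h) -> dict:
    """Integrate dA_i/dt = λ_i Σ_j b_ji A_j − λ_i A_i with Radau.

    Returns {nuclide: activities at times_h}. Handles the ~1e10/h decay
    constant of the fastest chain member via the implicit solver.
    """
    names = [n.name for n in chain.nuclides if not n.stable]
    lam = np.array([chain[n].lam for n in names])
    b = np.zeros((len(names), len(names)))
    for j, parent in enumerate(names):
        for daughter, frac in chain[parent].branches:
            if daughter in names:
                b[names.index(daughter), j] = frac
    a0 = np.array([initial_activities_bq.get(n, 0.0) for n in names])

    def rhs(_t, a):
        return lam * (b @ a) - lam * a

    times = np.atleast_1d(np.asarray(times_h, dtype=float))
    order = np.argsort(times)
    sol = solve_ivp(
        rhs,
        (0.0, max(times.max(), 1e-9)),
        a0,
        method="Radau",
        t_eval=times[order],
        rtol=1e-11,
        atol=1e-16 * max(a0.max(), 1.0),
    )
    assert sol.success
    out = np.empty_like(sol.y)
    out[:, order] = sol.y
    return {n: out[i] for i, n in enumerate(names)}


def quadrature_organ_auc(profile_fn, decay_lambda: float, t1: float, t2: float) -> float:
    """∫ profile(t)·e^{−λt} dt by adaptive quadrature."""
    val, err = quad(lambda t: profile_fn(t) * np.exp(-decay_lambda * t), t1, t2,
                    limit=200)
    assert err < 1e-8 * max(abs(val), 1.0)
    return val
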