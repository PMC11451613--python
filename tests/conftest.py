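"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's closed forms: the bound-state
survival is checked against direct ODE integration of the state master
equations and against Gillespie stochastic simulation of the same scheme.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spliceproof import KineticScheme

# rates behind the slow-tracking fit: Intermediate lifetime 9.1 s, A-complex
# lifetime 82 s, Ks = 0.15
K_OFF_INT = 1.0 / 9.1
K_OFF_A = 1.0 / 82.0
K_FWD2 = 0.15 * K_OFF_INT


@pytest.fixture(scope="session")
def slow_smt_scheme() -> KineticScheme:
    return KineticScheme(k_off_int=K_OFF_INT, k_fwd2=K_FWD2, k_off_A=K_OFF_A)


def ode_survival(scheme: KineticScheme, t_grid: np.ndarray) -> np.ndarray:
    """Master-equation oracle: integrate dP/dt for the Int -> A chain.

    P_int' = -(k_off_int + k_fwd2) P_int
    P_A'   = k_fwd2 P_int - k_off_A P_A
    S(t)   = P_int + P_A with P_int(0) = 1.
    """

    def rhs(_t, p):
        p_int, p_a = p
        return [
            -(scheme.k_off_int + scheme.k_fwd2) * p_int,
            scheme.k_fwd2 * p_int - scheme.k_off_A * p_a,
        ]

    sol = solve_ivp(
        rhs, (0.0, float(t_grid[-1])), [1.0, 0.0], t_eval=t_grid, rtol=1e-10, atol=1e-12
    )
    return sol.y.sum(axis=0)


def gillespie_bound_times(scheme: KineticScheme, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic-simulation oracle: total bound time entering at Intermediate."""
    lam = scheme.k_off_int + scheme.k_fwd2
    t_int = rng.exponential(1.0 / lam, size=n)
    goes_on = rng.random(n) < scheme.k_fwd2 / lam
    t_a = rng.exponential(1.0 / scheme.k_off_A, size=n) if scheme.k_off_A > 0 else np.zeros(n)
    return t_int + np.where(goes_on, t_a, 0.0)


def gillespie_state_occupancy(
    scheme: KineticScheme, n_events: int, rng: np.random.Generator
) -> np.ndarray:
    """Long-run time fractions in [U, E, Int, A] by explicit event simulation."""
    rates = {
        0: [(scheme.k_on_conc, 1)],
        1: [(scheme.k_off_E, 0), (scheme.k_fwd1, 2)],
        2: [(scheme.k_off_int, 0), (scheme.k_fwd2, 3)],
        3: [(scheme.k_off_A, 0)],
    }
    occ = np.zeros(4)
    state = 0
    for _ in range(n_events):
        out = rates[state]
        total = sum(r for r, _ in out)
        if total == 0:
            raise RuntimeError("absorbing state reached")
        occ[state] += rng.exponential(1.0 / total)
        u = rng.random() * total
        acc = 0.0
        for r, nxt in out:
            acc += r
            if u < acc:
                state = nxt
                break
    return occ / occ.sum()
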