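"""Independent reference implementations used only to validate simulators.

Every matrix here is rebuilt from the model definition rather than imported
from the package, and propagation is done by adaptive fine-step ODE
integration (or a dense linear solve for the steady-state lineshape), so
these share no code path with the production simulators.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

TWO_PI = 2.0 * np.pi
_IVP = dict(method="DOP853", rtol=1e-11, atol=1e-13)


def rates(p_E: float, k_ex: float) -> tuple[float, float]:
    return p_E * k_ex, (1.0 - p_E) * k_ex   # k_GE, k_EG


def ode_final(M: np.ndarray, v0: np.ndarray, t: float) -> np.ndarray:
    if t == 0:
        return np.asarray(v0, dtype=float)
    sol = solve_ivp(lambda _, y: M @ y, (0.0, t), np.asarray(v0, float),
                    t_eval=[t], **_IVP)
    assert sol.success
    return sol.y[:, 0]


def ir_two_state_ode(p_E, k_ex, R1_G, R1_E, G1_G, G1_E, delays, I_inf=1.0):
    kge, keg = rates(p_E, k_ex)
    pg = 1.0 - p_E
    r1g, r1e = R1_G + G1_G, R1_E + G1_E
    M = np.array([[0.0, 0.0, 0.0],
                  [2 * r1g * pg, -r1g - kge, keg],
                  [2 * r1e * p_E, kge, -r1e - keg]])
    v0 = np.array([0.5, -pg, -p_E])
    return I_inf * np.array([ode_final(M, v0, t)[1:].sum() for t in delays])


def _cest_matrix(p_E, k_ex, wG, wE, offset, B1, R1_G, R1_E, R2_G, R2_E):
    kge, keg = rates(p_E, k_ex)
    pg = 1.0 - p_E
    og = TWO_PI * (wG - offset)
    oe = TWO_PI * (wE - offset)
    w1 = TWO_PI * B1
    return np.array([
        [0, 0, 0, 0, 0, 0, 0],
        [0, -R2_G - kge, -og, w1, keg, 0, 0],
        [0, og, -R2_G - kge, 0, 0, keg, 0],
        [2 * R1_G * pg, -w1, 0, -R1_G - kge, 0, 0, keg],
        [0, kge, 0, 0, -R2_E - keg, -oe, w1],
        [0, 0, kge, 0, oe, -R2_E - keg, 0],
        [2 * R1_E * p_E, 0, 0, kge, -w1, 0, -R1_E - keg]], dtype=float)


def cest_ode(p_E, k_ex, wG, wE, offsets, refs, B1, t_cest,
             R1_G, R1_E, R2_G, R2_E):
    """Normalized CEST profile by direct ODE integration per offset."""
    v0 = np.array([0.5, 0, 0, 1.0 - p_E, 0, 0, p_E])

    def one(off):
        M = _cest_matrix(p_E, k_ex, wG, wE, off, B1, R1_G, R1_E, R2_G, R2_E)
        v = ode_final(M, v0, t_cest)
        return v[3] + v[6]

    raw = np.array([one(o) for o in np.atleast_1d(offsets)])
    ref = np.mean([one(o) for o in np.atleast_1d(refs)])
    return raw / ref


def cpmg_ode(p_E, k_ex, dw_hz, R2, T, nus):
    """R2,eff by ODE integration of each echo segment, conjugation pulses."""
    kge, keg = rates(p_E, k_ex)
    pg = 1.0 - p_E
    L = np.array([[-R2 - kge, keg],
                  [kge, -R2 - keg + 1j * TWO_PI * dw_hz]], dtype=complex)

    def seg(v, t):
        def rhs(_, y):
            z = y[:2] + 1j * y[2:]
            dz = L @ z
            return np.concatenate([dz.real, dz.imag])
        y0 = np.concatenate([v.real, v.imag])
        sol = solve_ivp(rhs, (0.0, t), y0, t_eval=[t], **_IVP)
        assert sol.success
        return sol.y[:2, 0] + 1j * sol.y[2:, 0]

    out = []
    for nu in np.atleast_1d(nus):
        n = int(round(nu * T))
        tau = T / (4.0 * n)
        v = np.array([pg, p_E], dtype=complex)
        for _ in range(n):
            v = seg(v, tau).conj()
            v = seg(v, 2 * tau).conj()
            v = seg(v, tau)
        out.append(-np.log(v[0].real / pg) / T)
    return np.array(out)


def exsy_ode(p_E, k_ex, R1_G, R1_E, mixing_times, scale=1.0):
    kge, keg = rates(p_E, k_ex)
    K = np.array([[-kge - R1_G, keg], [kge, -keg - R1_E]])
    out = np.empty((len(mixing_times), 2, 2))
    for i, t in enumerate(mixing_times):
        c0 = ode_final(K, [1.0 - p_E, 0.0], t)
        c1 = ode_final(K, [0.0, p_E], t)
        out[i] = scale * np.column_stack([c0, c1])
    return out


def lineshape_solve(p_E, k_ex, wG, wE, R2_G, R2_E, G2_G, G2_E, offsets,
                    scale=1.0):
    """Steady-state lineshape via an explicit dense matrix inverse."""
    kge, keg = rates(p_E, k_ex)
    out = np.empty(len(offsets))
    I0 = np.array([1.0 - p_E, p_E])
    for i, off in enumerate(offsets):
        M = np.array([
            [-R2_G - G2_G + 1j * TWO_PI * (wG - off) - kge, keg],
            [kge, -R2_E - G2_E + 1j * TWO_PI * (wE - off) - keg]],
            dtype=complex)
        out[i] = scale * abs(np.sum(np.linalg.inv(M) @ I0).real)
    return out


def amplitude_relative_error(calc: np.ndarray, oracle: np.ndarray) -> float:
    """Max deviation relative to the curve's amplitude scale."""
    return float(np.max(np.abs(calc - oracle)) / np.max(np.abs(oracle)))
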