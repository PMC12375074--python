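"""Bloch-McConnell forward models for two-site conformational exchange.

All observables measured on the loop probe — CEST profiles, CPMG relaxation
dispersion, EXSY build-up curves, inversion-recovery (optionally with
paramagnetic relaxation enhancement) and 1D lineshapes — are back-calculated
from a single two-site parameterization: a ground state G (open loop
conformation) and an excited state E (closed conformation) interconverting
as G <=> E with forward rate k_GE = p_E * k_ex and backward rate
k_EG = p_G * k_ex.

Unit conventions
----------------
All public interfaces take chemical shifts, offsets and B1 field strengths
in Hz; they are converted to angular frequency (rad/s) internally, where the
evolution matrices are defined.  Rates (k_ex, R1, R2, Gamma) are plain s^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ExchangeModel",
    "CESTSchedule",
    "CPMGSchedule",
    "EXSYSchedule",
    "IRSchedule",
    "SpectrumGrid",
    "simulate_ir_single",
    "simulate_ir_two_state",
    "simulate_cest",
    "simulate_cpmg",
    "simulate_cpmg_numeric",
    "simulate_exsy",
    "simulate_lineshape",
]

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExchangeModel:
    """Full two-site exchange parameterization for one sample condition.

    Parameters
    ----------
    p_E : float
        Population of the excited (closed) state, 0 <= p_E <= 1.
    k_ex : float
        Total exchange rate k_GE + k_EG in s^-1.
    omega_G, omega_E : float
        Chemical shifts of the two states in Hz on the observed-nucleus
        axis (converted to rad/s internally by the simulators).
    R1_G, R1_E, R2_G, R2_E : float
        Longitudinal / transverse relaxation rates per state (s^-1).
    Gamma1_G, Gamma1_E, Gamma2_G, Gamma2_E : float
        Optional paramagnetic contributions to R1/R2 per state (s^-1).
    """

    p_E: float
    k_ex: float
    omega_G: float = 0.0
    omega_E: float = 0.0
    R1_G: float = 1.0
    R1_E: float = 1.0
    R2_G: float = 10.0
    R2_E: float = 10.0
    Gamma1_G: float = 0.0
    Gamma1_E: float = 0.0
    Gamma2_G: float = 0.0
    Gamma2_E: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_E <= 1.0:
            raise ValueError(f"p_E must lie in [0, 1], got {self.p_E}")
        if self.k_ex < 0:
            raise ValueError(f"k_ex must be >= 0, got {self.k_ex}")
        for name in ("R1_G", "R1_E", "R2_G", "R2_E",
                     "Gamma1_G", "Gamma1_E", "Gamma2_G", "Gamma2_E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def p_G(self) -> float:
        return 1.0 - self.p_E

    @property
    def k_GE(self) -> float:
        """Forward rate G->E; detailed balance p_G*k_GE = p_E*k_EG holds."""
        return self.p_E * self.k_ex

    @property
    def k_EG(self) -> float:
        return (1.0 - self.p_E) * self.k_ex

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExchangeModel":
        return cls(**d)


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 0:
        a = a[None]
    if a.size == 0:
        raise ValueError(f"{name} must not be empty")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


@dataclass
class CESTSchedule:
    """Saturation-transfer acquisition grid.

    ``B1`` is the weak saturation field in Hz (nutation frequency); the
    saturation is applied for ``t_CEST`` seconds at every offset in
    ``offsets``, and intensities are normalized to the mean intensity at
    the far off-resonance ``reference_offsets``.
    """

    B1: float
    t_CEST: float
    offsets: np.ndarray
    reference_offsets: np.ndarray = field(
        default_factory=lambda: np.array([-10000.0, 10000.0]))

    def __post_init__(self) -> None:
        self.offsets = _as_array(self.offsets, "offsets")
        self.reference_offsets = _as_array(self.reference_offsets,
                                           "reference_offsets")
        if self.t_CEST <= 0:
            raise ValueError("t_CEST must be > 0")
        if self.B1 < 0:
            raise ValueError("B1 must be >= 0")
        if np.min(np.abs(self.reference_offsets)) < 2 * np.max(np.abs(self.offsets)):
            warnings.warn("reference offsets are less than 2x the largest "
                          "saturation offset; normalization may be biased")

    def to_dict(self) -> dict:
        return {"B1": self.B1, "t_CEST": self.t_CEST,
                "offsets": self.offsets.tolist(),
                "reference_offsets": self.reference_offsets.tolist()}


@dataclass
class CPMGSchedule:
    """Constant-time CPMG relaxation dispersion grid.

    Each pulse-train frequency nu_CPMG must pack an integer number of
    (tau - 180 - 2tau - 180 - tau) cycles into T_CPMG, i.e. T_CPMG*nu must
    be a whole number (an even number of refocusing pulses).  Off-grid
    values are rounded with a warning.
    """

    T_CPMG: float
    nu_CPMG: np.ndarray
    spectrometer_freq: float = 471.0  # MHz, for ppm <-> Hz conversion

    def __post_init__(self) -> None:
        if self.T_CPMG <= 0:
            raise ValueError("T_CPMG must be > 0")
        self.nu_CPMG = _as_array(self.nu_CPMG, "nu_CPMG")
        if np.any(self.nu_CPMG <= 0):
            raise ValueError("nu_CPMG values must be > 0")
        ncyc = self.nu_CPMG * self.T_CPMG
        if not np.allclose(ncyc, np.round(ncyc), atol=1e-9):
            warnings.warn("some nu_CPMG do not give an integer number of "
                          "CPMG cycles in T_CPMG; rounding")
            self.nu_CPMG = np.maximum(np.round(ncyc), 1) / self.T_CPMG

    @property
    def n_cycles(self) -> np.ndarray:
        return np.maximum(np.round(self.nu_CPMG * self.T_CPMG), 1).astype(int)

    def to_dict(self) -> dict:
        return {"T_CPMG": self.T_CPMG, "nu_CPMG": self.nu_CPMG.tolist(),
                "spectrometer_freq": self.spectrometer_freq}


@dataclass
class EXSYSchedule:
    """Longitudinal exchange (EXSY) mixing-time list and intensity scale."""

    mixing_times: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.mixing_times = _as_array(self.mixing_times, "mixing_times")
        if np.any(self.mixing_times < 0):
            raise ValueError("mixing times must be >= 0")
        if np.any(np.diff(self.mixing_times) <= 0):
            raise ValueError("mixing times must be strictly increasing")

    def to_dict(self) -> dict:
        return {"mixing_times": self.mixing_times.tolist(), "scale": self.scale}


@dataclass
class IRSchedule:
    """Inversion-recovery delay list and equilibrium intensity scale."""

    delays: np.ndarray
    I_inf: float = 1.0

    def __post_init__(self) -> None:
        self.delays = _as_array(self.delays, "delays")
        if np.any(self.delays < 0):
            raise ValueError("delays must be >= 0")
        if np.unique(self.delays).size < 3:
            warnings.warn("fewer than 3 distinct delays; R1 fitting will be "
                          "ill-determined")

    def to_dict(self) -> dict:
        return {"delays": self.delays.tolist(), "I_inf": self.I_inf}


@dataclass
class SpectrumGrid:
    """A digitized 1D spectrum: acquisition-axis offsets and intensities."""

    offsets: np.ndarray
    intensities: np.ndarray | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.offsets = _as_array(self.offsets, "offsets")
        d = np.diff(self.offsets)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("offsets must be strictly monotonic")
        if self.intensities is not None:
            self.intensities = _as_array(self.intensities, "intensities")
            if self.intensities.size != self.offsets.size:
                raise ValueError("intensities and offsets differ in length")


# ---------------------------------------------------------------------------
# inversion recovery
# ---------------------------------------------------------------------------

def simulate_ir_single(R1: float, schedule: IRSchedule) -> np.ndarray:
    """Mono-exponential inversion recovery I(t) = I_inf*(1 - 2*exp(-R1*t))."""
    if R1 < 0:
        raise ValueError(f"R1 must be >= 0, got {R1}")
    return schedule.I_inf * (1.0 - 2.0 * np.exp(-R1 * schedule.delays))


def ir_evolution_matrix(model: ExchangeModel) -> np.ndarray:
    """3x3 longitudinal evolution matrix on (E/2, Iz_G, Iz_E).

    The first component is the constant identity term carrying the thermal
    correction 2*(R1+Gamma1)*p that drives each state's z magnetization back
    to its equilibrium population.
    """
    r1g = model.R1_G + model.Gamma1_G
    r1e = model.R1_E + model.Gamma1_E
    kge, keg = model.k_GE, model.k_EG
    return np.array([
        [0.0, 0.0, 0.0],
        [2.0 * r1g * model.p_G, -r1g - kge, keg],
        [2.0 * r1e * model.p_E, kge, -r1e - keg],
    ])


def simulate_ir_two_state(model: ExchangeModel, schedule: IRSchedule) -> np.ndarray:
    """Inversion recovery of the exchanging two-state system (with PREs).

    Starting from inverted z magnetization (E/2, -p_G, -p_E), propagates
    the 3x3 longitudinal evolution matrix for each delay and returns the
    observable projection Iz_G + Iz_E scaled by the schedule's I_inf.
    Recovers to +I_inf as t -> inf.
    """
    M = ir_evolution_matrix(model)
    v0 = np.array([0.5, -model.p_G, -model.p_E])
    out = np.empty(schedule.delays.size)
    for i, t in enumerate(schedule.delays):
        vt = expm(M * t) @ v0
        if not np.all(np.isfinite(vt)):
            raise FloatingPointError(
                f"non-finite IR propagation at t={t}: model={model}")
        out[i] = vt[1] + vt[2]
    return schedule.I_inf * out


# ---------------------------------------------------------------------------
# CEST
# ---------------------------------------------------------------------------

def cest_evolution_matrix(model: ExchangeModel, offset_hz: float,
                          B1_hz: float) -> np.ndarray:
    """7x7 Bloch-McConnell matrix on (E/2, Ix_G, Iy_G, Iz_G, Ix_E, Iy_E, Iz_E).

    ``offset_hz`` is the saturation carrier position on the Hz axis; the
    per-state offsets entering the matrix are (state shift - carrier),
    converted to rad/s, so a saturation dip appears when the carrier sits
    on a state's resonance.  The B1 field is applied from y.
    """
    wg = TWO_PI * (model.omega_G - offset_hz)
    we = TWO_PI * (model.omega_E - offset_hz)
    w1 = TWO_PI * B1_hz
    r1g, r1e = model.R1_G, model.R1_E
    r2g, r2e = model.R2_G, model.R2_E
    kge, keg = model.k_GE, model.k_EG
    pg, pe = model.p_G, model.p_E
    return np.array([
        [0, 0, 0, 0, 0, 0, 0],
        [0, -r2g - kge, -wg, w1, keg, 0, 0],
        [0, wg, -r2g - kge, 0, 0, keg, 0],
        [2 * r1g * pg, -w1, 0, -r1g - kge, 0, 0, keg],
        [0, kge, 0, 0, -r2e - keg, -we, w1],
        [0, 0, kge, 0, we, -r2e - keg, 0],
        [2 * r1e * pe, 0, 0, kge, -w1, 0, -r1e - keg],
    ], dtype=float)


_CEST_PROJ = np.array([0, 0, 0, 1, 0, 0, 1], dtype=float)


def _cest_matrix_stack(model: ExchangeModel, offsets: np.ndarray,
                       B1: float) -> np.ndarray:
    """The 7x7 evolution matrix for every offset at once, shape (n, 7, 7)."""
    n = offsets.size
    Ms = np.zeros((n, 7, 7))
    Ms[:] = cest_evolution_matrix(model, 0.0, B1)
    wg = TWO_PI * (model.omega_G - offsets)
    we = TWO_PI * (model.omega_E - offsets)
    Ms[:, 1, 2], Ms[:, 2, 1] = -wg, wg
    Ms[:, 4, 5], Ms[:, 5, 4] = -we, we
    return Ms


def _cest_raw(model: ExchangeModel, offsets: np.ndarray, B1: float,
              t_cest: float) -> np.ndarray:
    """Propagate equilibrium magnetization for t_cest at every offset.

    Uses a stacked eigendecomposition of the evolution matrices (one LAPACK
    call for the whole offset grid); offsets whose eigenvector basis is
    ill-conditioned (near-defective matrix) fall back to the
    scaling-and-squaring matrix exponential.
    """
    v0 = np.array([0.5, 0, 0, model.p_G, 0, 0, model.p_E])
    Ms = _cest_matrix_stack(model, offsets, B1)
    lam, V = np.linalg.eig(Ms)
    with np.errstate(all="ignore"):
        b = np.broadcast_to((v0 + 0j)[:, None], (offsets.size, 7, 1))
        c = np.linalg.solve(V, b)[..., 0]
        vt = np.einsum("nij,nj->ni", V, c * np.exp(lam * t_cest))
    out = (vt.real @ _CEST_PROJ).astype(float)
    # fallback where the eigenbasis was numerically unusable
    bad = ~np.isfinite(out) | (np.abs(vt.imag @ _CEST_PROJ) > 1e-8)
    for i in np.flatnonzero(bad):
        out[i] = _CEST_PROJ @ (expm(Ms[i] * t_cest) @ v0)
    return out


def simulate_cest(model: ExchangeModel, schedule: CESTSchedule) -> np.ndarray:
    """Normalized CEST profile I(offset)/I(reference).

    Propagates equilibrium z magnetization under saturation for t_CEST at
    every offset and normalizes by the mean residual intensity at the far
    off-resonance reference offsets.
    """
    raw = _cest_raw(model, schedule.offsets, schedule.B1, schedule.t_CEST)
    ref = _cest_raw(model, schedule.reference_offsets, schedule.B1,
                    schedule.t_CEST).mean()
    if abs(ref) < 1e-12:
        raise ZeroDivisionError(
            "CEST normalization reference is ~0; reference offsets are "
            "saturating the spins")
    return raw / ref


# ---------------------------------------------------------------------------
# CPMG relaxation dispersion
# ---------------------------------------------------------------------------

def _transverse_L(model: ExchangeModel) -> np.ndarray:
    """Complex 2x2 free-precession matrix on (M+_G, M+_E), frame at omega_G."""
    dw = TWO_PI * (model.omega_E - model.omega_G)
    return np.array([
        [-model.R2_G - model.k_GE, model.k_EG],
        [model.k_GE, -model.R2_E - model.k_EG + 1j * dw],
    ], dtype=complex)


def _expm2(L: np.ndarray, t: float) -> np.ndarray:
    """Closed-form exp(L*t) for a 2x2 matrix via its eigenvalues."""
    tr = L[0, 0] + L[1, 1]
    s = np.sqrt(tr * tr - 4.0 * (L[0, 0] * L[1, 1] - L[0, 1] * L[1, 0]))
    lam1 = 0.5 * (tr + s)
    lam2 = 0.5 * (tr - s)
    I = np.eye(2, dtype=complex)
    if abs(s) < 1e-12 * max(1.0, abs(tr)):
        # defective / near-degenerate: first-order expansion about lam1
        return np.exp(lam1 * t) * (I + (L - lam1 * I) * t)
    e1, e2 = np.exp(lam1 * t), np.exp(lam2 * t)
    return (e1 * (L - lam2 * I) - e2 * (L - lam1 * I)) / s


def _matpow2(U: np.ndarray, n: int) -> np.ndarray:
    """U^n for a 2x2 matrix by binary exponentiation."""
    out = np.eye(2, dtype=complex)
    P = U.copy()
    while n:
        if n & 1:
            out = P @ out
        P = P @ P
        n >>= 1
    return out


def simulate_cpmg(model: ExchangeModel, schedule: CPMGSchedule,
                  assume_shared_R2: bool = True) -> np.ndarray:
    """Exact two-site single-quantum CPMG dispersion (Baldwin-type solution).

    For each nu_CPMG the constant-time echo train is n = T*nu repeats of
    (tau - 180 - 2tau - 180 - tau), tau = 1/(4 nu), with ideal pulses.
    The per-cycle propagator U = P(tau) conj(P(2tau)) P(tau) is built from
    closed-form 2x2 eigen-propagators and raised to the n-th power exactly;
    R2,eff = -(1/T_CPMG) ln(I/I0) where I is the ground-state signal and I0
    the reference intensity without the relaxation delay.

    When ``assume_shared_R2`` the intrinsic plateau rates of ground and
    excited state are tied (R2_G used for both).
    """
    m = model
    if assume_shared_R2 and model.R2_E != model.R2_G:
        m = ExchangeModel(**{**model.to_dict(), "R2_E": model.R2_G})
    L = _transverse_L(m)
    m0 = np.array([m.p_G, m.p_E], dtype=complex)
    T = schedule.T_CPMG
    out = np.empty(schedule.nu_CPMG.size)
    for i, n in enumerate(schedule.n_cycles):
        tau = T / (4.0 * n)
        P1 = _expm2(L, tau)
        U = P1 @ np.conj(_expm2(L, 2.0 * tau)) @ P1
        mT = _matpow2(U, int(n)) @ m0
        I = mT[0].real
        if I <= 0 or not np.isfinite(I):
            raise FloatingPointError(
                f"CPMG signal non-positive/overflowed at nu={schedule.nu_CPMG[i]}"
                f" (k_ex={m.k_ex})")
        out[i] = -np.log(I / m.p_G) / T
    return out


def simulate_cpmg_numeric(model: ExchangeModel, schedule: CPMGSchedule,
                          assume_shared_R2: bool = True) -> np.ndarray:
    """Oracle for :func:`simulate_cpmg`: explicit echo-train propagation.

    Steps each free-precession segment with scipy's matrix exponential and
    applies each ideal 180 pulse as complex conjugation of the transverse
    magnetization, one pulse at a time.
    """
    m = model
    if assume_shared_R2 and model.R2_E != model.R2_G:
        m = ExchangeModel(**{**model.to_dict(), "R2_E": model.R2_G})
    L = _transverse_L(m)
    T = schedule.T_CPMG
    out = np.empty(schedule.nu_CPMG.size)
    for i, n in enumerate(schedule.n_cycles):
        tau = T / (4.0 * n)
        Ptau = expm(L * tau)
        P2tau = expm(L * 2.0 * tau)
        v = np.array([m.p_G, m.p_E], dtype=complex)
        for _ in range(int(n)):
            v = Ptau @ v
            v = np.conj(v)          # ideal 180 pulse
            v = P2tau @ v
            v = np.conj(v)
            v = Ptau @ v
        I = v[0].real
        if I <= 0 or not np.isfinite(I):
            raise FloatingPointError(
                f"CPMG signal non-positive/overflowed at nu={schedule.nu_CPMG[i]}")
        out[i] = -np.log(I / m.p_G) / T
    return out


# ---------------------------------------------------------------------------
# EXSY
# ---------------------------------------------------------------------------

def exsy_rate_matrix(model: ExchangeModel) -> np.ndarray:
    """2x2 longitudinal exchange-relaxation matrix K."""
    return np.array([
        [-model.k_GE - model.R1_G, model.k_EG],
        [model.k_GE, -model.k_EG - model.R1_E],
    ])


def simulate_exsy(model: ExchangeModel, schedule: EXSYSchedule) -> np.ndarray:
    """EXSY auto/cross peak intensities vs mixing time.

    Returns an array of shape (n_mix, 2, 2) where element [t, i, j] is the
    intensity of magnetization that started in state j and is detected in
    state i after mixing time t:

        [[I_GG, I_EG], [I_GE, I_EE]] = S_EXSY * exp(K*t) * diag(p_G, p_E)
    """
    K = exsy_rate_matrix(model)
    P0 = np.diag([model.p_G, model.p_E])
    out = np.empty((schedule.mixing_times.size, 2, 2))
    for i, t in enumerate(schedule.mixing_times):
        out[i] = schedule.scale * (expm(K * t) @ P0)
    return out


# ---------------------------------------------------------------------------
# 1D lineshape
# ---------------------------------------------------------------------------

def simulate_lineshape(model: ExchangeModel, grid: SpectrumGrid,
                       use_pre: bool = False) -> np.ndarray:
    """Steady-state 1D two-site exchange lineshape.

    I(omega) = S * |Re(sum(M^-1 I0))| with the 2x2 complex matrix

        M = [[-R2_G (-Gamma2_G) + i(w_G - w) - k_GE,  k_EG],
             [k_GE, -R2_E (-Gamma2_E) + i(w_E - w) - k_EG]]

    (frequencies in rad/s); the Gamma2 terms are added when ``use_pre``.
    Vectorized over the spectrum axis via the closed-form 2x2 inverse.
    """
    g2g = model.Gamma2_G if use_pre else 0.0
    g2e = model.Gamma2_E if use_pre else 0.0
    if model.R2_G + g2g <= 0 or model.R2_E + g2e <= 0:
        raise ValueError("transverse decay must be > 0 for an invertible "
                         "lineshape matrix")
    w = TWO_PI * grid.offsets
    a = -model.R2_G - g2g - model.k_GE + 1j * (TWO_PI * model.omega_G - w)
    b = -model.R2_E - g2e - model.k_EG + 1j * (TWO_PI * model.omega_E - w)
    det = a * b - model.k_GE * model.k_EG
    bad = np.abs(det) < 1e-300
    if np.any(bad):
        raise np.linalg.LinAlgError(
            f"singular lineshape matrix at offset {grid.offsets[bad][0]} Hz")
    # sum of M^-1 @ (p_G, p_E)
    sigma = ((b - model.k_GE) * model.p_G + (a - model.k_EG) * model.p_E) / det
    return grid.scale * np.abs(sigma.real)
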