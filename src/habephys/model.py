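"""Two-compartment conductance-based model of a lateral habenula neuron
electrically coupled to a lumped non-neuronal (glial) compartment.

The neuron carries standard Na/K spike currents, a low-threshold T-type
Ca2+ current that de-inactivates during hyperpolarization, an SK current
gated by a first-order intracellular Ca2+ pool, an optional
hyperpolarization-activated (sag) current, and a slow adaptation K+
current that sets the strength of spike-frequency adaptation.  The glial
compartment is passive except for an optional T-type conductance (the
rebound trigger can sit post-junctionally) and a CNG-like cation
conductance gated by a slow variable ``s`` that charges while the glial
voltage is above a threshold and decays on a time scale of seconds.  The
two compartments are connected by an ohmic gap-junction conductance.

All voltages are in mV, times in ms, conductances in nS, capacitances in
pF, currents in pA and calcium in uM, so that C dV/dt = I holds without
unit factors.  Integration is fixed-step 4th-order Runge-Kutta.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


E_NA = 55.0
E_K = -90.0
E_CA = 120.0
E_H = -30.0

#: temperature-like speed-up applied to the Na/K gating rates
PHI_HH = 5.0


class SimulationDiverged(RuntimeError):
    """Raised when the integrator leaves the physiological voltage range."""


@dataclass
class ModelParams:
    """Conductances and kinetics of the neuron/glia pair.

    The defaults here are deliberately inert (passive membrane); use the
    named sets in :mod:`habephys.phenotypes` for the firing phenotypes.
    """

    # passive
    C_n: float = 25.0          # pF, neuron
    C_g: float = 40.0          # pF, glial compartment
    g_leak_n: float = 2.0      # nS
    g_leak_g: float = 18.0     # nS
    E_leak_n: float = -60.0    # mV
    E_leak_g: float = -80.0    # mV
    # spiking
    g_Na: float = 0.0          # nS
    g_K: float = 0.0           # nS
    g_adapt: float = 0.0       # nS, slow K+ adaptation current
    tau_adapt: float = 120.0   # ms
    p_Na_floor: float = 0.75   # slow Na+ availability at depolarized V
    # T-type Ca2+
    g_T: float = 0.0           # nS, neuronal T conductance
    g_T_glia: float = 0.0      # nS, glial (post-junctional) T conductance
    mT_half: float = -48.0     # mV, activation midpoint (neuron)
    mT_slope: float = 5.0      # mV
    hT_half: float = -67.0     # mV, inactivation midpoint
    hT_slope: float = 3.5      # mV
    tau_hT_depol: float = 80.0   # ms, inactivation when depolarized
    tau_hT_hyper: float = 1000.0  # ms, recovery when hyperpolarized
    mT_half_glia: float = -64.0  # mV, glial activation midpoint
    # glial T channels sit half-inactivated at the glial resting potential,
    # so only prior hyperpolarization (relayed through the gap junction)
    # primes the post-junctional trigger; tonic neuronal firing cannot
    hT_half_glia: float = -80.0  # mV, glial inactivation midpoint
    # SK (the glial pool is fed by Ca2+ carried through the T-type and
    # CNG-like conductances of that compartment)
    g_SK: float = 0.0          # nS
    g_SK_glia: float = 0.0     # nS
    K_Ca: float = 0.4          # uM, SK half-activation
    n_Hill: float = 4.0
    k_Ca: float = 2e-4         # uM per pA per ms of T-current influx
    tau_Ca: float = 80.0       # ms
    # sag
    g_H: float = 0.0           # nS
    # CNG-like plateau conductance (glial compartment)
    g_CNG: float = 0.0         # nS
    E_CNG: float = 0.0         # mV
    alpha_CNG: float = 8e-3    # 1/ms, activation rate above theta_CNG
    beta_CNG: float = 6e-4     # 1/ms, deactivation rate (1/beta ~ seconds)
    theta_CNG: float = -10.0   # mV, glial voltage threshold
    # coupling and noise
    g_gap: float = 0.0         # nS
    noise_sigma: float = 0.0   # pA, OU current noise amplitude
    noise_tau: float = 5.0     # ms
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "g_leak_n", "g_leak_g", "g_Na", "g_K", "g_adapt", "g_T",
            "g_T_glia", "g_SK", "g_SK_glia", "g_H", "g_CNG", "g_gap",
            "noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.C_n <= 0 or self.C_g <= 0:
            raise ValueError("capacitances must be > 0")
        if self.tau_Ca <= 0 or self.beta_CNG <= 0 or self.noise_tau <= 0:
            raise ValueError("tau_Ca, beta_CNG and noise_tau must be > 0")

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclass
class DrugCondition:
    """A named bath/internal condition mapped to a parameter transformation."""

    name: str
    scaling: dict = field(default_factory=dict)


#: fixed, documented parameter transformations for each named drug
DRUG_EFFECTS = {
    "control": {},
    "ttx": {"g_Na": 0.0},
    "apamin": {"g_SK": 0.0, "g_SK_glia": 0.0},
    "z944": {"g_T": 0.0, "g_T_glia": 0.0},
    "ni_high": {"g_T": 0.0, "g_T_glia": 0.0},
    # low Ni2+ mainly blocks the CNG-dependent plateau, with a mild
    # T-current reduction
    "ni_low": {"g_CNG": ("scale", 0.2), "g_T": ("scale", 0.8),
               "g_T_glia": ("scale", 0.8)},
    "lcd": {"g_CNG": 0.0},
    "carbenoxolone": {"g_gap": 0.0},
    "mfa": {"g_gap": 0.0},
    # BAPTA chelates Ca2+ so SK no longer sees it; the Ca pool itself is
    # left running
    "bapta": {"g_SK": 0.0, "g_SK_glia": 0.0},
    # 8-bromo-cGMP facilitates CNG gating: slower deactivation
    "br_cgmp": {"beta_CNG": ("scale", 0.5)},
}


def apply_drug(params: ModelParams, drug) -> ModelParams:
    """Return a new :class:`ModelParams` with the drug's effect applied.

    ``drug`` may be a name from :data:`DRUG_EFFECTS` or a
    :class:`DrugCondition`; the input parameters are never mutated.
    """
    if drug is None:
        return params
    if isinstance(drug, DrugCondition):
        name, extra = drug.name, drug.scaling
    else:
        name, extra = str(drug), {}
    if name not in DRUG_EFFECTS:
        raise ValueError(f"unknown drug condition: {name!r}")
    changes = {}
    for key, val in {**DRUG_EFFECTS[name], **extra}.items():
        if isinstance(val, tuple) and val[0] == "scale":
            changes[key] = getattr(params, key) * val[1]
        else:
            changes[key] = val
    return params.replace(**changes)


@dataclass
class StepProtocol:
    """A single square current step under current clamp."""

    hold_mV: Optional[float] = -60.0
    amp_pA: float = -100.0
    t_on: float = 0.5       # s
    t_off: float = 1.5      # s
    t_total: float = 7.0    # s
    dt: float = 0.025       # ms, integration step
    fs: float = 20000.0     # Hz, output sampling rate
    settle_s: float = 0.0   # lead-in discarded from the output

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0 <= self.t_on < self.t_off < self.t_total):
            raise ValueError("require 0 <= t_on < t_off < t_total")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def post_window_s(self) -> float:
        return self.t_total - self.t_off


@dataclass
class VoltageTrace:
    """A uniformly sampled current-clamp recording."""

    fs: float
    v_mV: np.ndarray
    i_pA: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v_mV = np.asarray(self.v_mV, dtype=float)
        self.i_pA = np.asarray(self.i_pA, dtype=float)
        if self.v_mV.shape != self.i_pA.shape:
            raise ValueError("v and i must have equal length")
        if not (np.isfinite(self.v_mV).all() and np.isfinite(self.i_pA).all()):
            raise ValueError("trace contains non-finite samples")

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.v_mV.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.v_mV.size / self.fs


@dataclass
class PairedTraces:
    """Simultaneous pre-junctional (neuron) and post-junctional traces."""

    pre: VoltageTrace
    post: VoltageTrace
    n_sweeps: int = 1

    def __post_init__(self) -> None:
        if self.pre.fs != self.post.fs or self.pre.v_mV.size != self.post.v_mV.size:
            raise ValueError("paired traces must share the time base")
        if not (1 <= self.n_sweeps <= 50):
            raise ValueError("sweep count must be within [1, 50]")


# ---------------------------------------------------------------------------
# gating functions (shared with the kernel; kept as plain math for numba)
# ---------------------------------------------------------------------------

def _mT_inf(v: float, half: float = -48.0, slope: float = 5.0) -> float:
    return 1.0 / (1.0 + math.exp(-(v - half) / slope))


def _hT_inf(v: float, half: float = -67.0, slope: float = 3.5) -> float:
    return 1.0 / (1.0 + math.exp((v - half) / slope))


def _z_inf(v: float) -> float:
    # spike-gated: z charges only while V is in the action-potential range
    return 1.0 / (1.0 + math.exp(-(v + 30.0) / 5.0))


def _p_inf(v: float, floor: float = 0.75) -> float:
    return floor + (1.0 - floor) / (1.0 + math.exp((v + 52.0) / 5.0))


def _r_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v + 80.0) / 6.0))


_P_FIELDS = (
    "C_n", "C_g", "g_leak_n", "g_leak_g", "E_leak_n", "E_leak_g",
    "g_Na", "g_K", "g_adapt", "tau_adapt", "g_T", "g_T_glia",
    "g_SK", "K_Ca", "n_Hill", "k_Ca", "tau_Ca", "g_H",
    "g_CNG", "E_CNG", "alpha_CNG", "beta_CNG", "theta_CNG", "g_gap",
    "mT_half", "mT_slope", "hT_half", "hT_slope",
    "tau_hT_depol", "tau_hT_hyper", "mT_half_glia", "g_SK_glia",
    "p_Na_floor", "hT_half_glia",
)


def _params_vector(p: ModelParams) -> np.ndarray:
    return np.array([getattr(p, f) for f in _P_FIELDS], dtype=np.float64)


# state vector layout:
#   0 V_n, 1 h_Na, 2 n_K, 3 h_T, 4 Ca, 5 z_adapt, 6 p_Na_slow, 7 r_H,
#   8 V_g, 9 h_T_glia, 10 s_CNG, 11 Ca_glia
N_STATE = 12


@njit(cache=True)
def _derivs(y, pv, i_inj, out):
    (C_n, C_g, g_leak_n, g_leak_g, E_leak_n, E_leak_g,
     g_Na, g_K, g_adapt, tau_adapt, g_T, g_T_glia,
     g_SK, K_Ca, n_Hill, k_Ca, tau_Ca, g_H,
     g_CNG, E_CNG, alpha_CNG, beta_CNG, theta_CNG, g_gap,
     mT_half, mT_slope, hT_half, hT_slope,
     tau_hT_depol, tau_hT_hyper, mT_half_g, g_SK_glia, p_floor,
     hT_half_g) = (
        pv[0], pv[1], pv[2], pv[3], pv[4], pv[5], pv[6], pv[7], pv[8],
        pv[9], pv[10], pv[11], pv[12], pv[13], pv[14], pv[15], pv[16],
        pv[17], pv[18], pv[19], pv[20], pv[21], pv[22], pv[23],
        pv[24], pv[25], pv[26], pv[27], pv[28], pv[29], pv[30], pv[31],
        pv[32], pv[33])

    V = y[0]
    h = y[1]
    n = y[2]
    hT = y[3]
    Ca = y[4]
    z = y[5]
    p_na = y[6]
    r = y[7]
    Vg = y[8]
    hTg = y[9]
    s = y[10]
    Cag = y[11]

    # --- Na/K gating (Wang-Buzsaki-style; m instantaneous) ---
    dv35 = V + 35.0
    if abs(dv35) < 1e-6:
        a_m = 1.0
    else:
        a_m = 0.1 * dv35 / (1.0 - math.exp(-dv35 / 10.0))
    b_m = 4.0 * math.exp(-(V + 60.0) / 18.0)
    m = a_m / (a_m + b_m)
    a_h = 0.07 * math.exp(-(V + 58.0) / 20.0)
    b_h = 1.0 / (1.0 + math.exp(-(V + 28.0) / 10.0))
    dv34 = V + 34.0
    if abs(dv34) < 1e-6:
        a_n = 0.1
    else:
        a_n = 0.01 * dv34 / (1.0 - math.exp(-dv34 / 10.0))
    b_n = 0.125 * math.exp(-(V + 44.0) / 80.0)

    # --- neuron currents ---
    I_Na = g_Na * m * m * m * h * p_na * (V - 55.0)
    I_K = g_K * n * n * n * n * (V + 90.0)
    mT = 1.0 / (1.0 + math.exp(-(V - mT_half) / mT_slope))
    I_T = g_T * mT * mT * hT * (V - 120.0)
    ca_n = Ca ** n_Hill
    I_SK = g_SK * ca_n / (ca_n + K_Ca ** n_Hill) * (V + 90.0)
    I_adapt = g_adapt * z * (V + 90.0)
    I_H = g_H * r * (V + 30.0)
    I_gap = g_gap * (V - Vg)
    I_leak = g_leak_n * (V - E_leak_n)

    out[0] = (-(I_leak + I_Na + I_K + I_T + I_SK + I_adapt + I_H + I_gap)
              + i_inj) / C_n
    out[1] = PHI_HH * (a_h * (1.0 - h) - b_h * h)
    out[2] = PHI_HH * (a_n * (1.0 - n) - b_n * n)
    hT_inf = 1.0 / (1.0 + math.exp((V - hT_half) / hT_slope))
    tau_hT = tau_hT_depol + (tau_hT_hyper - tau_hT_depol) \
        / (1.0 + math.exp((V + 70.0) / 5.0))
    out[3] = (hT_inf - hT) / tau_hT
    out[4] = -k_Ca * I_T - Ca / tau_Ca
    z_inf = 1.0 / (1.0 + math.exp(-(V + 30.0) / 5.0))
    out[5] = (z_inf - z) / tau_adapt
    p_inf = p_floor + (1.0 - p_floor) / (1.0 + math.exp((V + 52.0) / 5.0))
    out[6] = (p_inf - p_na) / 400.0
    r_inf = 1.0 / (1.0 + math.exp((V + 80.0) / 6.0))
    out[7] = (r_inf - r) / 200.0

    # --- glial compartment ---
    mTg = 1.0 / (1.0 + math.exp(-(Vg - mT_half_g) / mT_slope))
    I_Tg = g_T_glia * mTg * mTg * hTg * (Vg - 120.0)
    I_CNG = g_CNG * s * (Vg - E_CNG)
    cag_n = Cag ** n_Hill
    I_SKg = g_SK_glia * cag_n / (cag_n + K_Ca ** n_Hill) * (Vg + 90.0)
    I_leak_g = g_leak_g * (Vg - E_leak_g)
    out[8] = (-(I_leak_g + I_Tg + I_CNG + I_SKg) - g_gap * (Vg - V)) / C_g
    hTg_inf = 1.0 / (1.0 + math.exp((Vg - hT_half_g) / hT_slope))
    tau_hTg = tau_hT_depol + (tau_hT_hyper - tau_hT_depol) \
        / (1.0 + math.exp((Vg + 70.0) / 5.0))
    out[9] = (hTg_inf - hTg) / tau_hTg
    gate = 1.0 if Vg > theta_CNG else 0.0
    out[10] = alpha_CNG * gate * (1.0 - s) - beta_CNG * s
    out[11] = -k_Ca * (I_Tg + I_CNG) - Cag / tau_Ca
    return out


@njit(cache=True)
def _integrate(y0, pv, i_wave, dt, keep_every, n_keep, skip):
    """Fixed-step RK4; records every ``keep_every`` steps after ``skip``."""
    n_steps = i_wave.size
    y = y0.copy()
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    yt = np.empty(N_STATE)
    v_out = np.empty(n_keep)
    vg_out = np.empty(n_keep)
    kept = 0
    ok = True
    for step in range(n_steps):
        i_inj = i_wave[step]
        _derivs(y, pv, i_inj, k1)
        for j in range(N_STATE):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        _derivs(yt, pv, i_inj, k2)
        for j in range(N_STATE):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        _derivs(yt, pv, i_inj, k3)
        for j in range(N_STATE):
            yt[j] = y[j] + dt * k3[j]
        _derivs(yt, pv, i_inj, k4)
        for j in range(N_STATE):
            y[j] = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        # clamp bounded gates (and Ca >= 0) against round-off drift
        for j in (1, 2, 3, 5, 6, 7, 9, 10):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        if y[4] < 0.0:
            y[4] = 0.0
        if y[11] < 0.0:
            y[11] = 0.0
        if abs(y[0]) > 200.0 or abs(y[8]) > 200.0:
            ok = False
            break
        if step >= skip and (step - skip) % keep_every == 0 and kept < n_keep:
            v_out[kept] = y[0]
            vg_out[kept] = y[8]
            kept += 1
    return v_out, vg_out, kept, ok


# ---------------------------------------------------------------------------
# steady state / holding bias
# ---------------------------------------------------------------------------

def _glial_rest(p: ModelParams, v_n: float) -> float:
    """Glial resting potential given a fixed neuronal voltage (s = 0)."""

    def f(vg):
        mT = _mT_inf(vg, p.mT_half_glia, p.mT_slope)
        return (p.g_leak_g * (vg - p.E_leak_g)
                + p.g_T_glia * mT * mT
                * _hT_inf(vg, p.hT_half_glia, p.hT_slope) * (vg - E_CA)
                + p.g_gap * (vg - v_n))

    lo, hi = -130.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _hh_gate_inf(v: float):
    a_m = 1.0 if abs(v + 35.0) < 1e-6 else 0.1 * (v + 35.0) / (1 - math.exp(-(v + 35.0) / 10.0))
    b_m = 4.0 * math.exp(-(v + 60.0) / 18.0)
    a_h = 0.07 * math.exp(-(v + 58.0) / 20.0)
    b_h = 1.0 / (1.0 + math.exp(-(v + 28.0) / 10.0))
    a_n = 0.1 if abs(v + 34.0) < 1e-6 else 0.01 * (v + 34.0) / (1 - math.exp(-(v + 34.0) / 10.0))
    b_n = 0.125 * math.exp(-(v + 44.0) / 80.0)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)


def resting_state(p: ModelParams, v_n: float) -> np.ndarray:
    """State vector at the (quasi) fixed point for a held neuronal voltage."""
    m, h, n = _hh_gate_inf(v_n)
    hT = _hT_inf(v_n, p.hT_half, p.hT_slope)
    mT = _mT_inf(v_n, p.mT_half, p.mT_slope)
    i_T = p.g_T * mT * mT * hT * (v_n - E_CA)
    ca = max(0.0, -p.k_Ca * i_T * p.tau_Ca)
    vg = _glial_rest(p, v_n)
    mTg = _mT_inf(vg, p.mT_half_glia, p.mT_slope)
    hTg = _hT_inf(vg, p.hT_half_glia, p.hT_slope)
    i_Tg = p.g_T_glia * mTg * mTg * hTg * (vg - E_CA)
    ca_g = max(0.0, -p.k_Ca * i_Tg * p.tau_Ca)
    y = np.array([
        v_n, h, n, hT, ca, _z_inf(v_n), _p_inf(v_n, p.p_Na_floor), _r_inf(v_n),
        vg, hTg, 0.0, ca_g,
    ])
    return y


def holding_bias(p: ModelParams, hold_mV: float) -> float:
    """Constant bias current (pA) that balances the membrane at ``hold_mV``.

    Mirrors the experimental practice of manually holding the neuron near
    -60 mV with a steady current rather than a voltage clamp.
    """
    y = resting_state(p, hold_mV)
    v, ca, vg = y[0], y[4], y[8]
    h, n = y[1], y[2]
    m, _, _ = _hh_gate_inf(v)
    mT = _mT_inf(v, p.mT_half, p.mT_slope)
    i_na = p.g_Na * m ** 3 * h * y[6] * (v - E_NA)
    i_k = p.g_K * n ** 4 * (v - E_K)
    i_T = p.g_T * mT * mT * y[3] * (v - E_CA)
    ca_n = ca ** p.n_Hill
    i_sk = p.g_SK * ca_n / (ca_n + p.K_Ca ** p.n_Hill) * (v - E_K)
    i_adapt = p.g_adapt * y[5] * (v - E_K)
    i_h = p.g_H * y[7] * (v - E_H)
    i_gap = p.g_gap * (v - vg)
    i_leak = p.g_leak_n * (v - p.E_leak_n)
    return i_leak + i_na + i_k + i_T + i_sk + i_adapt + i_h + i_gap


def _ou_noise(n_steps: int, dt: float, sigma: float, tau: float,
              rng: np.random.Generator) -> np.ndarray:
    if sigma == 0.0:
        return np.zeros(n_steps)
    a = math.exp(-dt / tau)
    b = sigma * math.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n_steps)
    out = np.empty(n_steps)
    x = 0.0
    for k in range(n_steps):
        x = a * x + b * eps[k]
        out[k] = x
    return out


def _simulate_raw(params: ModelParams, protocol: StepProtocol,
                  drug=None, seed: Optional[int] = None):
    p = apply_drug(params, drug)
    dt = protocol.dt
    fs = protocol.fs
    step_per_sample = (1000.0 / fs) / dt
    keep_every = int(round(step_per_sample))
    if abs(step_per_sample - keep_every) > 1e-9 or keep_every < 1:
        raise ValueError("1/fs must be an integer multiple of dt")

    n_keep = int(round(protocol.t_total * fs))
    skip = int(round(protocol.settle_s * 1000.0 / dt))
    n_steps = skip + (n_keep - 1) * keep_every + 1

    if protocol.hold_mV is None:
        bias = 0.0
        y0 = resting_state(p, p.E_leak_n)
    else:
        bias = holding_bias(p, protocol.hold_mV)
        y0 = resting_state(p, protocol.hold_mV)

    t_steps = (np.arange(n_steps) - skip) * dt / 1000.0  # s, 0 at record start
    i_cmd = np.where((t_steps >= protocol.t_on) & (t_steps < protocol.t_off),
                     protocol.amp_pA, 0.0)
    rng = np.random.default_rng(p.seed if seed is None else seed)
    i_wave = i_cmd + bias + _ou_noise(n_steps, dt, p.noise_sigma,
                                      p.noise_tau, rng)

    pv = _params_vector(p)
    v, vg, kept, ok = _integrate(y0, pv, i_wave, dt, keep_every, n_keep, skip)
    if not ok:
        raise SimulationDiverged(
            "membrane potential left +/-200 mV; check parameters/dt")
    if kept != n_keep:  # pragma: no cover - defensive
        raise SimulationDiverged("integration ended early")
    i_out = i_cmd[skip::keep_every][:n_keep]
    return p, v, vg, i_out


def simulate_cell(params: ModelParams, protocol: StepProtocol,
                  drug=None, *, cell_id: str = "cell",
                  seed: Optional[int] = None,
                  return_both: bool = False):
    """Simulate the coupled pair and return the neuronal trace.

    With ``return_both=True`` (or via :func:`simulate_pair`) the glial
    trace is returned as well.  Deterministic for a fixed
    ``(params, protocol, drug, seed)``.
    """
    p, v, vg, i_out = _simulate_raw(params, protocol, drug, seed)
    drug_name = drug.name if isinstance(drug, DrugCondition) else (drug or "control")
    meta = {
        "cell_id": cell_id,
        "compartment": "neuron",
        "drug": drug_name,
        "seed": int(p.seed if seed is None else seed),
        "protocol": dataclasses.asdict(protocol),
    }
    neuron = VoltageTrace(fs=protocol.fs, v_mV=v, i_pA=i_out, meta=meta)
    if not return_both:
        return neuron
    glia = VoltageTrace(fs=protocol.fs, v_mV=vg, i_pA=np.zeros_like(vg),
                        meta={**meta, "compartment": "non_neuron"})
    return neuron, glia


def simulate_pair(params: ModelParams, protocol: StepProtocol,
                  drug=None, *, cell_id: str = "pair",
                  seed: Optional[int] = None) -> PairedTraces:
    """Double recording: current steps into the neuron, glia at rest."""
    neuron, glia = simulate_cell(params, protocol, drug, cell_id=cell_id,
                                 seed=seed, return_both=True)
    return PairedTraces(pre=neuron, post=glia)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Synthetic stand-in for a recorded cohort of LHb neurons."""

    group: str = "custom"
    n_cells: int = 50
    p_long: float = 0.3
    p_hf: float = 0.6
    jitter_sd: float = 0.08   # lognormal SD of multiplicative conductance jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_long <= 1.0 and 0.0 <= self.p_hf <= 1.0):
            raise ValueError("p_long and p_hf must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class CohortCell:
    cell_id: str
    group: str
    is_long: bool
    is_hf: bool
    params: ModelParams


_JITTERED = ("g_T", "g_T_glia", "g_SK", "g_CNG", "g_gap", "g_adapt",
             "g_Na", "g_K", "g_leak_n")


def make_cohort(config: CohortConfig) -> list:
    """Draw a labelled cohort of per-cell model parameters.

    Each cell is a long- or short-RDP phenotype (Bernoulli ``p_long``)
    crossed with an HF or LF firing phenotype (Bernoulli ``p_hf``); its
    conductances are jittered multiplicatively around the named defaults.
    """
    from . import phenotypes

    rng = np.random.default_rng(config.seed)
    cells = []
    for k in range(config.n_cells):
        is_long = bool(rng.random() < config.p_long)
        is_hf = bool(rng.random() < config.p_hf)
        base = phenotypes.cell_params(
            "long_rdp" if is_long else "short_rdp",
            "hf" if is_hf else "lf",
        )
        changes = {}
        for name in _JITTERED:
            val = getattr(base, name)
            if val > 0:
                changes[name] = val * float(
                    np.exp(rng.normal(0.0, config.jitter_sd)))
        changes["seed"] = int(rng.integers(0, 2 ** 31 - 1))
        cells.append(CohortCell(
            cell_id=f"{config.group}_{k:04d}", group=config.group,
            is_long=is_long, is_hf=is_hf, params=base.replace(**changes)))
    return cells


# ---------------------------------------------------------------------------
# dye-coupling ROI fixture
# ---------------------------------------------------------------------------

def make_roi_fixture(n_coupled: int, n_uncoupled: int, n_double_positive: int,
                     seed: int, margin_sd: float = 2.0):
    """Synthetic ROI intensity table exercising the dye-positivity criteria.

    Surround statistics are drawn per ROI; intended positives sit
    ``margin_sd`` surround-SDs beyond the criterion boundary (a margin of
    0 places them exactly on it, where the strict inequalities classify
    them negative).  Ground-truth labels are included.
    """
    import pandas as pd

    if min(n_coupled, n_uncoupled, n_double_positive) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    kinds = (["coupled"] * n_coupled + ["uncoupled"] * n_uncoupled
             + ["double_positive"] * n_double_positive)
    for i, kind in enumerate(kinds):
        nb_mu = float(rng.uniform(80, 120))
        nb_sd = float(rng.uniform(10, 25))
        ax_mu = float(rng.uniform(80, 120))
        ax_sd = float(rng.uniform(10, 25))
        if kind == "coupled":
            nb = nb_mu + (2.0 + margin_sd) * nb_sd
            ax = ax_mu + (0.5 - margin_sd) * ax_sd
        elif kind == "uncoupled":
            nb = nb_mu + (2.0 - margin_sd) * nb_sd
            ax = ax_mu + (0.5 - margin_sd) * ax_sd
        else:  # double positive: bright in both channels
            nb = nb_mu + (2.0 + margin_sd) * nb_sd
            ax = ax_mu + (0.5 + margin_sd) * ax_sd
        rows.append({
            "roi_id": f"roi_{i:03d}",
            "nb_mean": max(nb, 0.0),
            "alexa_mean": max(ax, 0.0),
            "nb_surround_mean": nb_mu,
            "nb_surround_sd": nb_sd,
            "alexa_surround_mean": ax_mu,
            "alexa_surround_sd": ax_sd,
            "is_recorded_cell": False,
            "true_label": kind,
        })
    cols = ["roi_id", "nb_mean", "alexa_mean", "nb_surround_mean",
            "nb_surround_sd", "alexa_surround_mean", "alexa_surround_sd",
            "is_recorded_cell", "true_label"]
    return pd.DataFrame(rows, columns=cols)
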