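"""Conductance-based definitions of the six cortical theta-oscillator models.

Each model is a Hodgkin-Huxley regular-spiking (RS) pyramidal cell, optionally
coupled to a somatostatin-like (SOM) interneuron that provides slow-decay
feedback synaptic inhibition.  Theta-timescale pacing comes from up to three
hyperpolarizing ("inhibitory") currents:

* ``I_m``    -- slow potassium (m-) current, voltage-gated, ~10-45 ms activation;
* ``I_inh``  -- SOM->RS synaptic inhibition, 0.25 ms rise / 50 ms decay;
* ``I_KSS``  -- super-slow calcium-activated potassium current, ~100 ms rise
  and ~500 ms decay, introducing a delta timescale.

The six models -- M, I, MI, MS, IS, MIS -- are named for the currents they
contain.  All other conductances are shared; only the leak conductance and the
tonic drive differ between models, so that each spikes tonically at 7 Hz.

Units: mV, ms; conductances and currents in the consistent mS/uA-per-area
scale conventional for single-compartment models (no conversion applied).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from numba import njit

MODEL_NAMES = ("M", "I", "MI", "MS", "IS", "MIS")

# -- fixed biophysical constants -------------------------------------------

E_NA = 40.0       # mV, RS sodium reversal
E_K = -80.0       # mV, RS potassium reversal
E_NAP = 50.0      # mV, persistent-sodium reversal
E_CA = 120.0      # mV, calcium reversal
E_NA_SOM = 50.0   # mV, SOM sodium reversal
E_K_SOM = -95.0   # mV, SOM potassium reversal
E_LEAK_SOM = -70.0
E_RS_TO_SOM = 0.0     # excitatory synapse reversal
E_SOM_TO_RS = -95.0   # inhibitory synapse reversal

TAU_R = 0.25          # ms, synaptic rise
TAU_D_RS_TO_SOM = 2.5   # ms, excitatory decay
TAU_D_SOM_TO_RS = 50.0  # ms, inhibitory decay

C_RS = 2.7   # capacitance; large, reflecting deep-layer pyramid size
C_SOM = 0.9

P_NOISE = 0.25     # noise proportion of the tonic drive
TAU_TRANS = 500.0  # ms, linear ramp-up of the tonic drive

# Calcium buffer: dCa/dt = -PHI_CA * I_Ca - Ca / TAU_CA.  First-order buffer
# in the hippocampal lineage of the I_KSS/I_Ca pair; PHI_CA and TAU_CA set the
# ~100 ms rise of I_KSS activation (its 500 ms decay is fixed by beta_q).
PHI_CA = 0.001     # concentration per (current * ms)
TAU_CA = 160.0     # ms

# temperature-corrected rate factor in tau_n (as printed: 3.3 * 3^((34-22)/10))
_TAUN_FACTOR = 3.3 * 3.0 ** 1.2

# Per-model entries: g_leak, g_m, g_KSS, g_app (tonic drive magnitude),
# and whether a SOM cell is present.  Drive magnitudes are set by the 7 Hz
# intrinsic-rate calibration (bisection on the F-I curve, mean rate over the
# final 5 s of 6 s noisy runs; see docs/methods.md) — the defining property
# of the model family is that every variant spikes tonically at 7 Hz.
_MODEL_TABLE = {
    #        g_leak   g_m     g_KSS   g_app    SOM
    "M":   (0.31, 1.4472, 0.0,    7.382, False),
    "MI":  (0.27, 1.4472, 0.0,    7.182, True),
    "I":   (0.78, 0.0,    0.0,    8.173, True),
    "IS":  (0.78, 0.0,    0.1512, 10.011, True),
    "MIS": (0.27, 1.4472, 0.1512, 9.091, True),
    "MS":  (0.27, 1.4472, 0.1512, 8.670, False),
}

_G_NA = 135.0
_G_KDR = 54.0
_G_NAP = 0.4307
_G_CA = 0.54
_G_NA_SOM = 100.0
_G_KDR_SOM = 80.0
_G_LEAK_SOM = 0.1
# Constant SOM holding current (no ramp, no noise).  Negative: it holds the
# highly excitable SOM cell just below threshold (~-79 mV), so the SOM spikes
# only when driven through the RS->SOM synapse, one-to-one with the RS cell.
_I_APP_SOM = -0.95
_G_RS_TO_SOM = 0.075
_G_SOM_TO_RS = 0.15

# state-vector layout (fixed 13 slots; SOM slots idle in single-cell models)
STATE_NAMES = (
    "V", "h", "m_KDR", "n", "m_NaP", "s_Ca", "q", "Ca",
    "V_SOM", "h_SOM", "m_KDR_SOM", "s_RS_SOM", "s_SOM_RS",
)
N_STATE = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}


class ConfigurationError(ValueError):
    """Raised for unknown model names or inconsistent parameters."""


@dataclass
class ModelConfig:
    """Full parameterization of one oscillator variant.

    Absent currents have conductance exactly zero; single-cell models (M, MS)
    have every SOM parameter zero.  ``g_app`` is the magnitude of the
    depolarizing tonic drive (the drive ramps up over ``tau_trans`` ms and
    carries a white-noise component of proportion ``p_noise``).
    """

    name: str
    C: float = C_RS
    g_Na: float = _G_NA
    g_KDR: float = _G_KDR
    g_leak: float = 0.0
    g_m: float = 0.0
    g_NaP: float = _G_NAP
    g_Ca: float = _G_CA
    g_KSS: float = 0.0
    g_app: float = 0.0
    E_leak: float = -65.0
    C_SOM: float = 0.0
    g_Na_SOM: float = 0.0
    g_KDR_SOM: float = 0.0
    g_leak_SOM: float = 0.0
    I_app_SOM: float = 0.0
    g_RS_SOM: float = 0.0
    g_SOM_RS: float = 0.0
    p_noise: float = P_NOISE
    tau_trans: float = TAU_TRANS
    phi_Ca: float = PHI_CA
    tau_Ca: float = TAU_CA

    @property
    def has_som(self) -> bool:
        return self.C_SOM > 0.0

    def to_array(self) -> np.ndarray:
        """Pack parameters into the flat float64 layout the integrator uses."""
        return np.array([
            self.C, self.g_Na, self.g_KDR, self.g_leak, self.E_leak,
            self.g_m, self.g_NaP, self.g_Ca, self.g_KSS,
            self.g_app, self.p_noise, self.tau_trans,
            self.C_SOM, self.g_Na_SOM, self.g_KDR_SOM, self.g_leak_SOM,
            self.I_app_SOM, self.g_RS_SOM, self.g_SOM_RS,
            self.phi_Ca, self.tau_Ca,
            1.0 if self.has_som else 0.0,
        ])

    # -- flat key-value (JSON) round trip ---------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def build_model(name: str, scale_gm: float = 1.0, scale_ginh: float = 1.0) -> ModelConfig:
    """Construct one of the six canonical configurations.

    ``scale_gm`` and ``scale_ginh`` multiply the m-current and SOM->RS
    inhibitory conductances (conductance-scaling sweeps); both default to 1.
    """
    if name not in _MODEL_TABLE:
        raise ConfigurationError(
            f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    if scale_gm <= 0 or scale_ginh <= 0:
        raise ConfigurationError("conductance scale factors must be positive")
    g_leak, g_m, g_kss, g_app, som = _MODEL_TABLE[name]
    cfg = ModelConfig(
        name=name,
        g_leak=g_leak,
        g_m=g_m * scale_gm,
        g_KSS=g_kss,
        g_app=g_app,
    )
    if som:
        cfg.C_SOM = C_SOM
        cfg.g_Na_SOM = _G_NA_SOM
        cfg.g_KDR_SOM = _G_KDR_SOM
        cfg.g_leak_SOM = _G_LEAK_SOM
        cfg.I_app_SOM = _I_APP_SOM
        cfg.g_RS_SOM = _G_RS_TO_SOM
        cfg.g_SOM_RS = _G_SOM_TO_RS * scale_ginh
    return cfg


# -- gating kinetics --------------------------------------------------------
#
# Rate-form variables (h, m_Na, m_KDR, s_Ca, q) are converted to
# steady-state/time-constant form via x_inf = alpha / (alpha + beta),
# tau = 1 / (alpha + beta).  Removable singularities (denominators of the
# form e^u - 1) are evaluated by their limits.

@njit(cache=True)
def _alpha_m_na(V):
    u = V + 16.0
    if abs(u) < 1e-7:
        return 1.0
    return 0.1 * u / (1.0 - math.exp(-u / 10.0))


@njit(cache=True)
def _beta_m_na(V):
    return 4.0 * math.exp(-(V + 41.0) / 18.0)


@njit(cache=True)
def m_na_inf(V):
    """Instantaneous RS fast-sodium activation."""
    a = _alpha_m_na(V)
    return a / (a + _beta_m_na(V))


@njit(cache=True)
def _alpha_h(V):
    return 0.07 * math.exp(-(V + 30.0) / 20.0)


@njit(cache=True)
def _beta_h(V):
    return 1.0 / (math.exp(-V / 10.0) + 1.0)


@njit(cache=True)
def _alpha_m_kdr(V):
    u = V + 20.0
    if abs(u) < 1e-7:
        return 0.1
    return 0.01 * u / (1.0 - math.exp(-u / 10.0))


@njit(cache=True)
def _beta_m_kdr(V):
    return 0.125 * math.exp(-(V + 30.0) / 80.0)


@njit(cache=True)
def n_inf(V):
    return 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))


@njit(cache=True)
def tau_n(V):
    return 1000.0 / (_TAUN_FACTOR * (math.exp((V + 35.0) / 40.0)
                                     + math.exp(-(V + 35.0) / 20.0)))


@njit(cache=True)
def m_nap_inf(V):
    return 1.0 / (1.0 + math.exp(-(V + 40.0) / 5.0))


TAU_M_NAP = 5.0  # ms


@njit(cache=True)
def _alpha_s_ca(V):
    return 1.6 / (1.0 + math.exp(-0.072 * (V - 65.0)))


@njit(cache=True)
def _beta_s_ca(V):
    u = V + 51.1
    if abs(u) < 1e-7:
        return 0.1
    return 0.02 * u / (math.exp(u / 5.0) - 1.0)


@njit(cache=True)
def _alpha_q(Ca):
    return min(0.1 * Ca, 1.0)


BETA_Q = 0.002  # /ms -> 500 ms decay of I_KSS activation


@njit(cache=True)
def m_na_som_inf(V):
    return 1.0 / (1.0 + math.exp((-V - 38.0) / 10.0))


@njit(cache=True)
def h_som_inf(V):
    return 1.0 / (1.0 + math.exp((V + 58.3) / 6.7))


@njit(cache=True)
def tau_h_som(V):
    return 0.225 + 1.125 / (1.0 + math.exp((V + 37.0) / 15.0))


@njit(cache=True)
def m_kdr_som_inf(V):
    return 1.0 / (1.0 + math.exp((-V - 27.0) / 11.5))


@njit(cache=True)
def tau_m_kdr_som(V):
    return 0.25 + 4.35 / (1.0 + math.exp(-abs(V + 10.0) / 10.0))


_GATE_RATE_FNS = {
    "h": (_alpha_h, _beta_h),
    "m_Na": (_alpha_m_na, _beta_m_na),
    "m_KDR": (_alpha_m_kdr, _beta_m_kdr),
    "s_Ca": (_alpha_s_ca, _beta_s_ca),
}


def gating_rates(variable: str, x: float) -> tuple[float, float]:
    """Steady state and time constant (ms) of a gating variable.

    ``x`` is the membrane potential in mV for voltage-gated variables, or the
    calcium concentration for ``q``.  Rate-form variables are converted via
    x_inf = alpha/(alpha+beta), tau = 1/(alpha+beta).
    """
    if variable in _GATE_RATE_FNS:
        a_fn, b_fn = _GATE_RATE_FNS[variable]
        a, b = a_fn(x), b_fn(x)
        return a / (a + b), 1.0 / (a + b)
    if variable == "n":
        return n_inf(x), tau_n(x)
    if variable == "m_NaP":
        return m_nap_inf(x), TAU_M_NAP
    if variable == "q":
        a = _alpha_q(x)
        return a / (a + BETA_Q), 1.0 / (a + BETA_Q)
    if variable == "h_SOM":
        return h_som_inf(x), tau_h_som(x)
    if variable == "m_KDR_SOM":
        return m_kdr_som_inf(x), tau_m_kdr_som(x)
    if variable == "m_Na_SOM":
        # instantaneous gate: steady state with zero lag
        return m_na_som_inf(x), 0.0
    raise ConfigurationError(f"unknown gating variable {variable!r}")


GATE_NAMES = ("h", "m_Na", "m_KDR", "n", "m_NaP", "s_Ca", "q",
              "h_SOM", "m_KDR_SOM", "m_Na_SOM")


def initial_state(config: ModelConfig, V0: float = -65.0,
                  V0_som: float = -70.0) -> np.ndarray:
    """Resting-ish state: gates at steady state for V0, Ca and synapses at 0."""
    y = np.zeros(N_STATE)
    y[IDX["V"]] = V0
    y[IDX["h"]] = gating_rates("h", V0)[0]
    y[IDX["m_KDR"]] = gating_rates("m_KDR", V0)[0]
    y[IDX["n"]] = n_inf(V0)
    y[IDX["m_NaP"]] = m_nap_inf(V0)
    y[IDX["s_Ca"]] = gating_rates("s_Ca", V0)[0]
    y[IDX["q"]] = 0.0
    y[IDX["Ca"]] = 0.0
    if config.has_som:
        y[IDX["V_SOM"]] = V0_som
        y[IDX["h_SOM"]] = h_som_inf(V0_som)
        y[IDX["m_KDR_SOM"]] = m_kdr_som_inf(V0_som)
    return y


@njit(cache=True)
def _rhs(y, p, I_stim, out):
    """Time derivatives of the full state vector.

    ``p`` is the ``ModelConfig.to_array()`` layout; ``I_stim`` is the
    time-varying applied current (tonic drive + pulse/speech input) delivered
    to the RS cell.  Currents with zero conductance contribute exactly zero.
    """
    (C, g_na, g_kdr, g_leak, e_leak, g_m, g_nap, g_ca, g_kss,
     _g_app, _p_noise, _tau_trans,
     c_som, g_na_som, g_kdr_som, g_leak_som, i_app_som,
     g_rs_som, g_som_rs, phi_ca, tau_ca, has_som) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
        p[11], p[12], p[13], p[14], p[15], p[16], p[17], p[18], p[19],
        p[20], p[21])

    V = y[0]
    h = y[1]
    m_kdr = y[2]
    n = y[3]
    m_nap = y[4]
    s_ca = y[5]
    q = y[6]
    ca = y[7]
    V_som = y[8]
    h_som = y[9]
    m_kdr_som = y[10]
    s_exc = y[11]   # RS -> SOM
    s_inh = y[12]   # SOM -> RS

    m_na = m_na_inf(V)
    i_na = g_na * m_na * m_na * m_na * h * (V - E_NA)
    i_kdr = g_kdr * m_kdr ** 4 * (V - E_K)
    i_leak = g_leak * (V - e_leak)
    i_m = g_m * n * (V - E_K)
    i_nap = g_nap * m_nap * (V - E_NAP)
    i_ca = g_ca * s_ca * s_ca * (V - E_CA)
    i_kss = g_kss * q * (V - E_K)
    i_inh = g_som_rs * s_inh * (V - E_SOM_TO_RS)

    out[0] = (I_stim - i_na - i_kdr - i_leak - i_m - i_nap
              - i_ca - i_kss - i_inh) / C

    a = _alpha_h(V)
    b = _beta_h(V)
    out[1] = (1.0 - h) * a - h * b
    a = _alpha_m_kdr(V)
    b = _beta_m_kdr(V)
    out[2] = (1.0 - m_kdr) * a - m_kdr * b
    out[3] = (n_inf(V) - n) / tau_n(V)
    out[4] = (m_nap_inf(V) - m_nap) / TAU_M_NAP
    # s_Ca and q integrate in steady-state/tau form (numerical stability)
    a = _alpha_s_ca(V)
    b = _beta_s_ca(V)
    out[5] = (a / (a + b) - s_ca) * (a + b)
    a = _alpha_q(ca)
    out[6] = (a / (a + BETA_Q) - q) * (a + BETA_Q)
    out[7] = -phi_ca * i_ca - ca / tau_ca

    if has_som > 0.0:
        m_na_s = m_na_som_inf(V_som)
        i_na_s = g_na_som * m_na_s ** 3 * h_som * (V_som - E_NA_SOM)
        i_kdr_s = g_kdr_som * m_kdr_som ** 4 * (V_som - E_K_SOM)
        i_leak_s = g_leak_som * (V_som - E_LEAK_SOM)
        i_exc = g_rs_som * s_exc * (V_som - E_RS_TO_SOM)
        out[8] = (i_app_som - i_na_s - i_kdr_s - i_leak_s - i_exc) / c_som
        out[9] = (h_som_inf(V_som) - h_som) / tau_h_som(V_som)
        out[10] = (m_kdr_som_inf(V_som) - m_kdr_som) / tau_m_kdr_som(V_som)
        out[11] = (-s_exc / TAU_D_RS_TO_SOM
                   + (1.0 - s_exc) / TAU_R * (1.0 + math.tanh(V / 10.0)))
        out[12] = (-s_inh / TAU_D_SOM_TO_RS
                   + (1.0 - s_inh) / TAU_R * (1.0 + math.tanh(V_som / 10.0)))
    else:
        out[8] = 0.0
        out[9] = 0.0
        out[10] = 0.0
        out[11] = 0.0
        out[12] = 0.0
    return out


def membrane_rhs(state: np.ndarray, config: ModelConfig,
                 I_stim: float = 0.0) -> np.ndarray:
    """Python-facing wrapper around the compiled right-hand side."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATE,):
        raise ConfigurationError(f"state must have shape ({N_STATE},)")
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state passed to membrane_rhs")
    out = np.empty(N_STATE)
    _rhs(state, config.to_array(), float(I_stim), out)
    return out
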