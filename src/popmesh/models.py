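"""Two-dimensional point-neuron models and their boundary rules.

A model is a deterministic vector field on a 2D state space (v, w) together
with threshold/reset metadata.  The *deterministic* field never includes
synaptic input: in the population-density method, noise enters exclusively
through jump transition matrices, so the fields here describe the noise-free
flow used to build state-space meshes.

The first coordinate is always the membrane potential ``v`` (except for the
Tsodyks-Markram synapse, where the state is (r, u)); the second coordinate is
the model's auxiliary variable: conductance, adaptation current, recovery
variable, or synaptic facilitation.  One-dimensional models (LIF, QIF, EIF)
are embedded in 2D with an identically-zero second field component.

Units are per-model and recorded in :attr:`NeuronModel.units`:

=============  =========================  =====================
model          v                          w
=============  =========================  =====================
cond           mV                         conductance / g_l (dimensionless)
adexp / eif    mV                         pA
fhn            dimensionless              dimensionless
lif / qif      threshold-normalised       unused
tm             r in [0, 1]                u in [0, 1]
=============  =========================  =====================

Time is in seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
from scipy.optimize import root

__all__ = [
    "NeuronModel",
    "TMSynapseParams",
    "conductance_field",
    "adexp_field",
    "fhn_field",
    "lif_field",
    "qif_field",
    "tm_synapse_field",
    "fhn_fixed_point",
    "tm_jump_rule",
    "get_model",
    "register_model",
    "COND_PARAMS",
    "ADEXP_PARAMS",
]

# Conductance-based model with first-order synaptic kinetics.
# tau_s is printed with an inconsistent unit in the source table; it is a
# synaptic *time* constant and is taken as 5 ms.
COND_PARAMS: dict[str, float] = {
    "tau_m": 0.020,   # membrane time constant (s)
    "E_r": -65.0,     # reset potential (mV)
    "E_l": -65.0,     # leak reversal potential (mV)
    "E_e": 0.0,       # excitatory synaptic reversal potential (mV)
    "tau_s": 0.005,   # synaptic time constant (s)
    "V_th": -55.0,    # threshold potential (mV)
}

# Adaptive-exponential integrate-and-fire constants (Brette-Gerstner set).
ADEXP_PARAMS: dict[str, float] = {
    "C_m": 281.0,     # membrane capacitance (pF)
    "g_l": 30.0,      # leak conductance (nS)
    "E_l": -70.6,     # leak reversal (mV)
    "V_T": -50.4,     # exponential threshold (mV)
    "Delta_T": 2.0,   # spike slope factor (mV)
    "tau_w": 0.144,   # adaptation time constant (s)
    "a": 4.0,         # subthreshold adaptation (nS)
    "b": 80.5,        # spike-triggered adaptation increment (pA)
    "I": 0.0,         # external current (pA)
}


@dataclass
class TMSynapseParams:
    """Tsodyks-Markram short-term plasticity constants (facilitating set)."""

    tau_rec: float = 0.1    # recovery time constant (s)
    tau_facil: float = 0.9  # facilitation time constant (s)
    U: float = 0.1          # utilisation constant
    A: float = 1.0          # maximal availability (amplitude units)

    def __post_init__(self):
        if min(self.tau_rec, self.tau_facil, self.U, self.A) <= 0 or self.U > 1:
            raise ValueError("TM parameters must be positive with U <= 1")


def conductance_field(p, params: dict | None = None) -> np.ndarray:
    """Drift of the conductance-based model with zero synaptic current.

    tau_m dV/dt = -(V - E_l) - g (V - E_e),  tau_s dg/dt = -g
    with the leak conductance normalised to 1 (g is in units of g_l).
    """
    c = COND_PARAMS if params is None else params
    p = np.asarray(p, dtype=float)
    V, g = p[..., 0], p[..., 1]
    dV = (-(V - c["E_l"]) - g * (V - c["E_e"])) / c["tau_m"]
    dg = -g / c["tau_s"]
    return np.stack([dV, dg], axis=-1)


def adexp_field(p, params: dict | None = None) -> np.ndarray:
    """Adaptive-exponential integrate-and-fire drift (V in mV, w in pA).

    C_m dV/dt = -g_l (V - E_l) + g_l Delta_T exp((V - V_T)/Delta_T) - w + I
    tau_w dw/dt = a (V - E_l) - w
    The pA/pF ratio is converted to mV/s (factor 1000).
    """
    c = ADEXP_PARAMS if params is None else params
    p = np.asarray(p, dtype=float)
    V, w = p[..., 0], p[..., 1]
    I_ion = (
        -c["g_l"] * (V - c["E_l"])
        + c["g_l"] * c["Delta_T"] * np.exp(
            np.minimum((V - c["V_T"]) / c["Delta_T"], 40.0)
        )
        - w
        + c["I"]
    )
    dV = 1000.0 * I_ion / c["C_m"]
    dw = (c["a"] * (V - c["E_l"]) - w) / c["tau_w"]
    return np.stack([dV, dw], axis=-1)


def eif_field(p, params: dict | None = None) -> np.ndarray:
    """Exponential integrate-and-fire: the AdExp field restricted to w = 0."""
    c = ADEXP_PARAMS if params is None else params
    p = np.asarray(p, dtype=float)
    V = p[..., 0]
    I_ion = (
        -c["g_l"] * (V - c["E_l"])
        + c["g_l"] * c["Delta_T"] * np.exp(
            np.minimum((V - c["V_T"]) / c["Delta_T"], 40.0)
        )
        + c["I"]
    )
    return np.stack([1000.0 * I_ion / c["C_m"], np.zeros_like(V)], axis=-1)


def fhn_field(p, I: float = 0.0) -> np.ndarray:
    """Fitzhugh-Nagumo field: dV/dt = V - V^3/3 - W + I, dW/dt = 0.08(V + 0.7 - 0.8 W).

    Time is in the model's dimensionless units (interpreted as seconds for
    simulation purposes).
    """
    p = np.asarray(p, dtype=float)
    V, W = p[..., 0], p[..., 1]
    dV = V - V ** 3 / 3.0 - W + I
    dW = 0.08 * (V + 0.7 - 0.8 * W)
    return np.stack([dV, dW], axis=-1)


def lif_field(p, tau: float = 0.05) -> np.ndarray:
    """Leaky integrate-and-fire drift dV/dt = -V/tau on a rescaled potential."""
    p = np.asarray(p, dtype=float)
    V = p[..., 0]
    return np.stack([-V / tau, np.zeros_like(V)], axis=-1)


def qif_field(p, tau: float = 0.01, I_c: float = 1.0) -> np.ndarray:
    """Quadratic integrate-and-fire drift dV/dt = (V^2 + I_c)/tau."""
    p = np.asarray(p, dtype=float)
    V = p[..., 0]
    return np.stack([(V ** 2 + I_c) / tau, np.zeros_like(V)], axis=-1)


def tm_synapse_field(p, params: TMSynapseParams | None = None) -> np.ndarray:
    """Deterministic part of the TM synapse: dr/dt=(1-r)/tau_rec, du/dt=-u/tau_facil."""
    c = params or TMSynapseParams()
    p = np.asarray(p, dtype=float)
    r, u = p[..., 0], p[..., 1]
    return np.stack([(1.0 - r) / c.tau_rec, -u / c.tau_facil], axis=-1)


def tm_jump_rule(centroids, params: TMSynapseParams | None = None) -> np.ndarray:
    """State-dependent presynaptic-spike jump h = (-u r, U (1 - u)).

    Evaluated at cell centroids when building a state-dependent transition
    matrix; the synaptic amplitude is G = A u r.
    """
    c = params or TMSynapseParams()
    cen = np.atleast_2d(np.asarray(centroids, dtype=float))
    r, u = cen[:, 0], cen[:, 1]
    return np.stack([-u * r, c.U * (1.0 - u)], axis=-1)


def fhn_fixed_point(I: float = 0.0, guess=(-1.0, -0.5)) -> np.ndarray:
    """Equilibrium of the Fitzhugh-Nagumo system by 2D root finding."""
    sol = root(lambda x: fhn_field(x, I=I), np.asarray(guess, float), tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"FHN fixed-point search failed: {sol.message}")
    return sol.x


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

@dataclass
class NeuronModel:
    """A 2D neuron model: drift field plus threshold/reset metadata.

    ``field`` maps an (..., 2) state array to an (..., 2) array of time
    derivatives (model units per second).  ``jump_dimension`` declares which
    coordinate synaptic jumps displace ('v', 'w' or 'state' for a
    state-dependent rule given by ``jump_rule``).  ``flow`` (optional) is the
    closed-form deterministic propagator ``flow(states, dt) -> states`` used
    by the exact event-driven Monte-Carlo path; ``time_to_threshold``
    (optional) returns the analytic time for each state to drift into the
    threshold, or inf.
    """

    name: str
    field: Callable[..., np.ndarray]
    params: dict = dc_field(default_factory=dict)
    tau: float | None = None
    threshold_v: float | None = None
    reset_v: float | None = None
    reset_w_increment: float = 0.0
    refractory: float = 0.0
    jump_dimension: str = "v"
    jump_rule: Callable[..., np.ndarray] | None = None
    units: tuple[str, str] = ("v", "w")
    flow: Callable[..., np.ndarray] | None = None
    time_to_threshold: Callable[..., np.ndarray] | None = None

    def __post_init__(self):
        if self.threshold_v is not None and self.reset_v is None:
            raise ValueError("a model with a threshold must define a reset")


def _make_cond(**over) -> NeuronModel:
    params = {**COND_PARAMS, **over}
    return NeuronModel(
        name="cond",
        field=lambda p: conductance_field(p, params),
        params=params,
        tau=params["tau_m"],
        threshold_v=params["V_th"],
        reset_v=params["E_r"],
        refractory=over.get("tau_ref", 0.0),
        jump_dimension="w",
        units=("mV", "g/g_l"),
    )


def _make_adexp(**over) -> NeuronModel:
    params = {**ADEXP_PARAMS, **over}
    return NeuronModel(
        name="adexp",
        field=lambda p: adexp_field(p, params),
        params=params,
        tau=params["C_m"] / params["g_l"] * 1e-3,
        threshold_v=over.get("threshold_v", -40.0),
        reset_v=over.get("reset_v", params["E_l"]),
        reset_w_increment=params["b"],
        jump_dimension="v",
        units=("mV", "pA"),
    )


def _make_eif(**over) -> NeuronModel:
    params = {**ADEXP_PARAMS, **over}
    return NeuronModel(
        name="eif",
        field=lambda p: eif_field(p, params),
        params=params,
        tau=params["C_m"] / params["g_l"] * 1e-3,
        threshold_v=over.get("threshold_v", -40.0),
        reset_v=over.get("reset_v", params["E_l"]),
        jump_dimension="v",
        units=("mV", "unused"),
    )


def _make_fhn(I: float = 0.0, **over) -> NeuronModel:
    return NeuronModel(
        name="fhn",
        field=lambda p: fhn_field(p, I=I),
        params={"I": I},
        jump_dimension="v",
        units=("V (dimensionless)", "W (dimensionless)"),
    )


def _lif_flow(tau):
    def flow(states, dt):
        out = np.array(states, dtype=float, copy=True)
        out[..., 0] *= np.exp(-np.asarray(dt) / tau)
        return out

    return flow


def _make_lif(tau: float = 0.05, threshold_v: float = 1.0, reset_v: float = 0.0,
              **over) -> NeuronModel:
    return NeuronModel(
        name="lif",
        field=lambda p: lif_field(p, tau=tau),
        params={"tau": tau},
        tau=tau,
        threshold_v=threshold_v,
        reset_v=reset_v,
        refractory=over.get("tau_ref", 0.0),
        jump_dimension="v",
        units=("V/theta", "unused"),
        flow=_lif_flow(tau),
    )


def _qif_flow(tau, I_c):
    s = np.sqrt(I_c)

    def flow(states, dt):
        out = np.array(states, dtype=float, copy=True)
        out[..., 0] = s * np.tan(
            s * np.asarray(dt) / tau + np.arctan(out[..., 0] / s)
        )
        return out

    return flow


def _qif_ttt(tau, I_c, threshold_v):
    s = np.sqrt(I_c)

    def ttt(states):
        V = np.asarray(states, dtype=float)[..., 0]
        return (tau / s) * (np.arctan(threshold_v / s) - np.arctan(V / s))

    return ttt


def _make_qif(tau: float = 0.01, I_c: float = 1.0, threshold_v: float = 10.0,
              reset_v: float = -10.0, **over) -> NeuronModel:
    if I_c <= 0:
        raise ValueError("the bursting QIF registry model requires I_c > 0")
    return NeuronModel(
        name="qif",
        field=lambda p: qif_field(p, tau=tau, I_c=I_c),
        params={"tau": tau, "I_c": I_c},
        tau=tau,
        threshold_v=threshold_v,
        reset_v=reset_v,
        refractory=over.get("tau_ref", 0.0),
        jump_dimension="v",
        units=("V (normalised)", "unused"),
        flow=_qif_flow(tau, I_c),
        time_to_threshold=_qif_ttt(tau, I_c, threshold_v),
    )


def _tm_flow(params: TMSynapseParams):
    def flow(states, dt):
        out = np.array(states, dtype=float, copy=True)
        dt = np.asarray(dt)
        out[..., 0] = 1.0 + (out[..., 0] - 1.0) * np.exp(-dt / params.tau_rec)
        out[..., 1] *= np.exp(-dt / params.tau_facil)
        return out

    return flow


def _make_tm(tau_rec: float = 0.1, tau_facil: float = 0.9, U: float = 0.1,
             A: float = 1.0, **over) -> NeuronModel:
    params = TMSynapseParams(tau_rec=tau_rec, tau_facil=tau_facil, U=U, A=A)
    return NeuronModel(
        name="tm",
        field=lambda p: tm_synapse_field(p, params),
        params={"tau_rec": tau_rec, "tau_facil": tau_facil, "U": U, "A": A},
        jump_dimension="state",
        jump_rule=lambda cen: tm_jump_rule(cen, params),
        units=("r", "u"),
        flow=_tm_flow(params),
    )


_REGISTRY: dict[str, Callable[..., NeuronModel]] = {
    "cond": _make_cond,
    "adexp": _make_adexp,
    "eif": _make_eif,
    "fhn": _make_fhn,
    "lif": _make_lif,
    "qif": _make_qif,
    "tm": _make_tm,
}


def register_model(name: str, factory: Callable[..., NeuronModel]) -> None:
    """Register a user model factory under ``name`` (overwrites silently)."""
    _REGISTRY[name] = factory


def get_model(name: str, **kwargs) -> NeuronModel:
    """Instantiate a registered model, optionally overriding parameters."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; known: {sorted(_REGISTRY)}"
        ) from None
    return factory(**kwargs)
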