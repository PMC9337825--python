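"""Ionic conductances of the model nociceptor and the capsaicin transducer.

Ten Hodgkin-Huxley-style conductances are used: four sodium currents
(TTX-sensitive fast, TTX-sensitive persistent, Na_v1.8, Na_v1.9), three
potassium currents (delayed rectifier, A-type with a -20 mV shift of both
gates, Kv7/M), the h-current, and low/high voltage-activated calcium
currents. Maximal densities and reversal potentials are fixed model
constants; gating kinetics follow the cited DRG/cerebellar formulations in
a uniform parametric form,

    x_inf(V) = 1 / (1 + exp(+-(V_half - V)/k))
    tau_x(V) = tau0 + tau1 * exp(-((V - c)/w)^2)   [ms]

with the sign chosen by gate polarity (activation vs. inactivation).

The capsaicin-like stimulus has two parts sharing one time gate:
a point conductance drive at each ending tip and a transducer conductance
g_Trans(x) = gbar_Trans * exp(-x/y), where x is the diffusion distance
from the stimulated nerve ending (zero on the ending itself, growing along
the fiber beyond it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GateKinetics",
    "ChannelModel",
    "CapsaicinStimulus",
    "default_channel_set",
    "default_density_map",
    "channel_current",
    "advance_gates",
    "transducer_density",
    "capsaicin_gate",
    "ChannelError",
    "E_NA",
    "E_K",
    "E_H",
    "E_CA",
]


class ChannelError(ValueError):
    """Invalid channel parameter or gate state."""


# reversal potentials (mV)
E_NA = 60.0
E_K = -85.0
E_H = -20.0
E_CA = 120.0  # fixed calcium reversal; no internal Ca dynamics
E_TRANS = 0.0  # nonselective cation (TRPV1-like)

# maximal conductance densities (S/cm^2)
GBAR = {
    "nav1p8": 0.02,
    "nav1p9": 0.00064,
    "nattxs": 0.0017,
    "nap": 0.00005,
    "kdr": 0.00083,
    "ka": 0.0015,
    "km": 0.00034,
    "h": 0.00033,
    "cal": 0.003,
    "cat": 0.001,
}

E_REV = {
    "nav1p8": E_NA,
    "nav1p9": E_NA,
    "nattxs": E_NA,
    "nap": E_NA,
    "kdr": E_K,
    "ka": E_K,
    "km": E_K,
    "h": E_H,
    "cal": E_CA,
    "cat": E_CA,
}


@dataclass(frozen=True)
class GateKinetics:
    """Voltage dependence of one first-order gating variable."""

    name: str
    inact: bool  # False: activation (increasing in V); True: inactivation
    vh: float  # half-activation voltage, mV
    k: float  # slope factor, mV
    tau0: float  # baseline time constant, ms
    tau1: float  # peak of the voltage-dependent component, ms
    tau_c: float  # center of the tau bell, mV
    tau_w: float  # width of the tau bell, mV

    def steady_state(self, v):
        v = np.asarray(v, dtype=float)
        if self.inact:
            return 1.0 / (1.0 + np.exp((v - self.vh) / self.k))
        return 1.0 / (1.0 + np.exp((self.vh - v) / self.k))

    def time_constant(self, v):
        v = np.asarray(v, dtype=float)
        return self.tau0 + self.tau1 * np.exp(-(((v - self.tau_c) / self.tau_w) ** 2))

    def as_row(self, power: int) -> list[float]:
        """Flat parameter row consumed by the integration kernel."""
        return [
            1.0 if self.inact else 0.0,
            self.vh,
            self.k,
            self.tau0,
            self.tau1,
            self.tau_c,
            self.tau_w,
            float(power),
        ]


@dataclass(frozen=True)
class ChannelModel:
    """One membrane conductance: density, reversal, and gating scheme."""

    name: str
    gbar: float  # S/cm^2
    e_rev: float  # mV
    gates: tuple[tuple[int, GateKinetics], ...] = ()  # (power, kinetics)
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ChannelError(f"channel {self.name!r}: gbar must be >= 0")
        for power, _ in self.gates:
            if power < 0:
                raise ChannelError(f"channel {self.name!r}: gate power must be >= 0")

    def open_fraction(self, gate_state) -> float:
        out = 1.0
        for (power, _), s in zip(self.gates, gate_state):
            out *= s**power
        return out


# -- gating kinetics --------------------------------------------------------
# Boltzmann midpoints/slopes and tau profiles per channel family; the A-type
# gates carry the -20 mV hyperpolarizing shift of both activation and
# inactivation built into their midpoints.

_KIN = {
    "nattxs_m": GateKinetics("nattxs_m", False, -40.0, 5.5, 0.06, 0.4, -45.0, 25.0),
    "nattxs_h": GateKinetics("nattxs_h", True, -44.0, 6.0, 2.0, 10.0, -55.0, 25.0),
    "nav1p8_m": GateKinetics("nav1p8_m", False, -16.0, 6.0, 0.1, 0.9, -25.0, 30.0),
    "nav1p8_h": GateKinetics("nav1p8_h", True, -35.0, 4.5, 1.0, 8.0, -35.0, 25.0),
    "nav1p9_m": GateKinetics("nav1p9_m", False, -25.0, 5.0, 3.0, 12.0, -50.0, 25.0),
    "nav1p9_h": GateKinetics("nav1p9_h", True, -60.0, 6.5, 150.0, 3000.0, -60.0, 25.0),
    "nap_m": GateKinetics("nap_m", False, -33.0, 6.0, 1.0, 3.0, -45.0, 20.0),
    "kdr_n": GateKinetics("kdr_n", False, -25.0, 12.0, 1.2, 8.0, -30.0, 25.0),
    "ka_a": GateKinetics("ka_a", False, -60.0, 15.0, 0.35, 1.2, -60.0, 30.0),
    "ka_b": GateKinetics("ka_b", True, -85.0, 7.0, 10.0, 40.0, -75.0, 30.0),
    "km_n": GateKinetics("km_n", False, -25.0, 8.0, 30.0, 250.0, -35.0, 30.0),
    "h_n": GateKinetics("h_n", True, -90.0, 7.0, 60.0, 300.0, -80.0, 30.0),
    "cat_m": GateKinetics("cat_m", False, -42.0, 6.5, 1.0, 4.0, -55.0, 20.0),
    "cat_h": GateKinetics("cat_h", True, -80.0, 5.5, 12.0, 40.0, -70.0, 20.0),
    "cal_m": GateKinetics("cal_m", False, -10.0, 6.0, 4.0, 6.0, -25.0, 20.0),
    "cal_h": GateKinetics("cal_h", True, -40.0, 6.0, 20.0, 40.0, -30.0, 30.0),
}

_GATING_SCHEME: dict[str, tuple[tuple[int, str], ...]] = {
    "nattxs": ((3, "nattxs_m"), (1, "nattxs_h")),
    "nav1p8": ((3, "nav1p8_m"), (1, "nav1p8_h")),
    "nav1p9": ((1, "nav1p9_m"), (1, "nav1p9_h")),
    "nap": ((1, "nap_m"),),
    "kdr": ((4, "kdr_n"),),
    "ka": ((4, "ka_a"), (1, "ka_b")),
    "km": ((1, "km_n"),),
    "h": ((1, "h_n"),),
    "cat": ((2, "cat_m"), (1, "cat_h")),
    "cal": ((2, "cal_m"), (1, "cal_h")),
}

_SOURCE_REF = {
    "nattxs": "TTX-sensitive fast Na (Herzog et al. 2001 family)",
    "nav1p8": "Na_v1.8 TTX-resistant (Baker 2005 family)",
    "nav1p9": "Na_v1.9 persistent TTX-resistant (Herzog et al. 2001 family)",
    "nap": "persistent Na (Baker 2005 family)",
    "kdr": "delayed-rectifier K (Herzog et al. 2001 family)",
    "ka": "A-type K, gates shifted -20 mV (Miyasho et al. 2001 family)",
    "km": "Kv7/M (Shah et al. 2008 family)",
    "h": "h-current (Shah et al. 2008; slope per Komagiri & Kitamura 2007)",
    "cal": "high-voltage-activated Ca",
    "cat": "low-voltage-activated Ca",
}


def _build_channel(name: str, gbar: float) -> ChannelModel:
    gates = tuple((p, _KIN[g]) for p, g in _GATING_SCHEME[name])
    return ChannelModel(name, gbar, E_REV[name], gates, _SOURCE_REF[name])


def default_channel_set(neuron_class: str = "generic") -> list[ChannelModel]:
    """All conductances for one neuron class at their fixed densities.

    The peptidergic class lacks Na_v1.9; everything else is identical.
    """
    if neuron_class not in {"generic", "peptidergic"}:
        raise ChannelError(f"unknown neuron class {neuron_class!r}")
    names = list(GBAR)
    if neuron_class == "peptidergic":
        names.remove("nav1p9")
    return [_build_channel(n, GBAR[n]) for n in names]


def default_density_map(neuron_class: str = "generic") -> dict[str, float]:
    """Channel-name -> density (S/cm^2) map for one neuron class."""
    return {ch.name: ch.gbar for ch in default_channel_set(neuron_class)}


def channel_current(channel: ChannelModel, gate_state, v: float) -> float:
    """Ohmic current density in mA/cm^2 at the given gate state and voltage."""
    for s in gate_state:
        if not 0.0 <= s <= 1.0:
            raise ChannelError(f"gate state {s} outside [0, 1]")
    return channel.gbar * channel.open_fraction(gate_state) * (v - channel.e_rev)


def advance_gates(channel: ChannelModel, gate_state, v: float, dt: float):
    """Exact-exponential relaxation of each gate toward its steady state."""
    if dt <= 0:
        raise ChannelError("dt must be positive")
    out = []
    for (power, kin), s in zip(channel.gates, gate_state):
        if not 0.0 <= s <= 1.0:
            raise ChannelError(f"gate state {s} outside [0, 1]")
        inf = float(kin.steady_state(v))
        tau = float(kin.time_constant(v))
        out.append(inf + (s - inf) * math.exp(-dt / tau))
    return out


# -- capsaicin-like stimulus ------------------------------------------------


@dataclass(frozen=True)
class CapsaicinStimulus:
    """Time-gated transducer drive mimicking puff-applied 1 uM capsaicin.

    The temporal gate is alpha(t) * beta(t): a bounded exponential
    activation factor alpha with fast rise ``tau_act_fast`` and calibrated
    amplitude ``alpha_max`` (the drive magnitude of the point-process
    equations is not recoverable in physical units and is calibrated so
    the control morphology fires a modest train; see docs/methods.md), and
    an exponential inactivation beta with time constant ``tau_beta``. The
    gate multiplies both the distributed transducer conductance and the
    ending point drive. ``tau_alpha`` stores the literal printed slow
    activation constant; with ``literal_tau_alpha=True`` it replaces the
    fast rise and ``alpha_max`` is ignored (the gate then peaks near
    tau_beta/tau_alpha ~ 2.4e-3).

    Spatially the transducer density is ``gbar_trans`` on the stimulated
    nerve ending itself (the application site, x = 0) and decays as
    exp(-x/y) with diffusion distance x along the fiber beyond the ending.
    """

    gbar_cap: float = 0.0007  # S/cm^2, ending point-drive strength (calibrated)
    gbar_trans: float = 0.0025  # S/cm^2, transducer density at the ending
    decay_constant_y: float = 7.04  # um, spatial decay beyond the ending
    tau_alpha: float = 1.0e6  # ms, printed slow activation constant
    tau_beta: float = 6500.0  # ms, inactivation time constant
    tau_act_fast: float = 50.0  # ms, fast activation rise
    alpha_max: float = 0.2  # dimensionless gate amplitude (calibrated)
    t_onset: float = 500.0  # ms
    t_puff: float = 2000.0  # ms
    e_trans: float = E_TRANS  # mV
    literal_tau_alpha: bool = False

    def __post_init__(self) -> None:
        if self.gbar_cap < 0 or self.gbar_trans < 0:
            raise ChannelError("stimulus conductances must be >= 0")
        if self.decay_constant_y <= 0:
            raise ChannelError("decay_constant_y must be positive")
        if self.tau_alpha <= 0 or self.tau_beta <= 0 or self.t_puff <= 0:
            raise ChannelError("time constants and t_puff must be positive")
        if not 0.0 <= self.alpha_max <= 1.0:
            raise ChannelError("alpha_max must lie in [0, 1]")


def transducer_density(x, stim: CapsaicinStimulus):
    """Transducer conductance density (S/cm^2) at diffusion distance x (um).

    g_Trans(x) = gbar_Trans * exp(-x / y); x is measured from the nerve
    ending (the application site), so x = 0 on the ending itself and the
    density is strictly decreasing with distance beyond it.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ChannelError("distance from the nerve ending must be >= 0")
    out = stim.gbar_trans * np.exp(-x / stim.decay_constant_y)
    return float(out) if out.ndim == 0 else out


def capsaicin_gate(t, stim: CapsaicinStimulus):
    """Dimensionless stimulus gate in [0, 1] at time(s) t (ms).

    Zero outside [t_onset, t_onset + t_puff]; inside, the product of the
    activation factor alpha(t) and inactivation beta(t) = exp(-(t-t0)/tau_beta).
    """
    t = np.asarray(t, dtype=float)
    rel = t - stim.t_onset
    if stim.literal_tau_alpha:
        tau_act, amp = stim.tau_alpha, 1.0
    else:
        tau_act, amp = stim.tau_act_fast, stim.alpha_max
    with np.errstate(over="ignore"):
        alpha = amp * (1.0 - np.exp(-np.clip(rel, 0.0, None) / tau_act))
        beta = np.exp(-np.clip(rel, 0.0, None) / stim.tau_beta)
    gate = alpha * beta
    gate = np.where((rel < 0) | (rel > stim.t_puff), 0.0, gate)
    return float(gate) if gate.ndim == 0 else gate


def kernel_gate_table(channels: list[ChannelModel]):
    """Flatten a channel set into kernel arrays.

    Returns (names, gate_params) where gate_params is one row per
    channel-gate: (inact, vh, k, tau0, tau1, tau_c, tau_w, power), plus a
    per-channel (gate_offset, n_gates, e_rev) description used by the
    discretizer.
    """
    rows: list[list[float]] = []
    desc = []
    for ch in channels:
        off = len(rows)
        for power, kin in ch.gates:
            rows.append(kin.as_row(power))
        desc.append((ch.name, off, len(ch.gates), ch.e_rev, ch.gbar))
    return np.asarray(rows, dtype=np.float64), desc
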