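"""Compartmental discretization and implicit integration of the branched cable.

The tree of sections is discretized into cylindrical compartments; the
membrane equation

    C_m dV/dt = -I_ion - I_axial + I_stim

is advanced with a backward-Euler step on voltage, staggered with
exact-exponential updates of the gating variables, and an O(N) Hines solve
of the tree-structured linear system (children eliminated into parents,
then back-substitution from the root). Gate steady states and relaxation
factors are pre-tabulated on a fine voltage grid per time step size, as
compartmental simulators conventionally do.

Units: mV, ms, uS, nA, nF; conductance densities enter in S/cm^2 and
geometry in um.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .channels import ChannelModel, _GATING_SCHEME, _KIN, _SOURCE_REF, E_REV
from .morphology import TerminalTreeSpec, validate_tree

__all__ = [
    "DiscretizedCable",
    "SimulationResult",
    "SpikeTrain",
    "discretize",
    "integrate",
    "detect_spikes",
    "NumericalError",
]

V_TABLE_MIN = -150.0
V_TABLE_MAX = 80.0
V_TABLE_STEP = 0.05
V_DIVERGE = 200.0  # mV, |V| beyond this aborts the run


class NumericalError(RuntimeError):
    """Integration diverged; carries the first offending compartment and time."""

    def __init__(self, msg: str, compartment: int | None = None, time_ms: float | None = None):
        super().__init__(msg)
        self.compartment = compartment
        self.time_ms = time_ms


@dataclass
class DiscretizedCable:
    """Flat compartment arrays for one morphology, kernel-ready."""

    tree: TerminalTreeSpec
    # per compartment
    parent: np.ndarray  # int32, -1 at root
    area: np.ndarray  # cm^2
    cm_nf: np.ndarray  # nF
    g_pas: np.ndarray  # uS
    e_pas: float
    g_axial: np.ndarray  # uS, coupling to parent (0 at root)
    section_id: list[str] = field(default_factory=list)  # per compartment
    position: np.ndarray | None = None  # center position along section [0,1]
    # channel instances
    inst_comp: np.ndarray | None = None
    inst_gmax: np.ndarray | None = None  # uS
    inst_erev: np.ndarray | None = None
    inst_goff: np.ndarray | None = None  # first gate index
    inst_ngate: np.ndarray | None = None
    # gates
    gate_comp: np.ndarray | None = None
    gate_kind: np.ndarray | None = None
    gate_pow: np.ndarray | None = None
    gate_params: np.ndarray | None = None  # (n_kinds, 7) kinetics rows
    gate_kind_names: list[str] = field(default_factory=list)
    # stimulus slots (filled by stimulation_protocols)
    stim_g: np.ndarray | None = None  # uS per compartment, scaled by gate wave
    stim_e: float = 0.0
    inj_amp: np.ndarray | None = None  # nA per compartment, scaled by inj wave

    @property
    def n_comp(self) -> int:
        return self.parent.size

    def comp_index(self, section_id: str, pos: float = 0.5) -> int:
        """Compartment whose center is nearest to ``pos`` along a section."""
        idx = [i for i, s in enumerate(self.section_id) if s == section_id]
        if not idx:
            raise KeyError(section_id)
        centers = self.position[idx]
        return idx[int(np.argmin(np.abs(centers - pos)))]


@dataclass
class SpikeTrain:
    times: np.ndarray  # ms

    @property
    def count(self) -> int:
        return self.times.size

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class SimulationResult:
    time: np.ndarray  # ms
    voltages: dict[str, np.ndarray]  # mV per recording site
    stimulus_trace: np.ndarray  # gate value per time point
    metadata: dict

    def spike_train(self, site: str, threshold: float = 0.0, refractory: float = 2.0) -> SpikeTrain:
        return detect_spikes(self, site, threshold, refractory)


def _gate_kind_registry(sections) -> tuple[list[str], np.ndarray]:
    """Unique gate kinds appearing in any section, with kinetics rows."""
    names: list[str] = []
    for sec in sections:
        for ch_name, dens in sec.channel_densities.items():
            if dens <= 0 or ch_name not in _GATING_SCHEME:
                continue
            for _, gname in _GATING_SCHEME[ch_name]:
                if gname not in names:
                    names.append(gname)
    rows = np.asarray([_KIN[n].as_row(1)[:7] for n in names], dtype=np.float64)
    if rows.size == 0:
        rows = np.zeros((0, 7), dtype=np.float64)
    return names, rows


def discretize(
    tree: TerminalTreeSpec,
    max_seg_len: float | None = None,
    *,
    refine: int = 1,
) -> DiscretizedCable:
    """Split every section into compartments and assemble kernel arrays.

    ``max_seg_len`` (um) forces at least length/max_seg_len compartments per
    section; ``refine`` multiplies every section's compartment count (used
    by convergence checks).
    """
    if max_seg_len is not None and max_seg_len <= 0:
        raise ValueError("max_seg_len must be positive")
    if refine < 1:
        raise ValueError("refine must be >= 1")
    validate_tree(tree)

    kind_names, kind_rows = _gate_kind_registry(tree.sections)
    kind_of = {n: i for i, n in enumerate(kind_names)}

    parent: list[int] = []
    area: list[float] = []
    cm_nf: list[float] = []
    g_pas: list[float] = []
    g_ax: list[float] = []
    sec_of_comp: list[str] = []
    pos: list[float] = []
    # half axial resistance (center to either end) per compartment, in Mohm
    half_r: list[float] = []

    inst_comp: list[int] = []
    inst_gmax: list[float] = []
    inst_erev: list[float] = []
    inst_goff: list[int] = []
    inst_ngate: list[int] = []
    gate_comp: list[int] = []
    gate_kind: list[int] = []
    gate_pow: list[int] = []

    # topological order: parents before children
    order: list = []
    stack = [s for s in tree.sections if s.parent is None]
    by_parent: dict[str | None, list] = {}
    for s in tree.sections:
        by_parent.setdefault(s.parent, []).append(s)
    while stack:
        s = stack.pop(0)
        order.append(s)
        stack.extend(sorted(by_parent.get(s.id, []), key=lambda x: x.id))

    last_comp_of: dict[str, int] = {}
    for sec in order:
        nseg = sec.n_segments * refine
        if max_seg_len is not None:
            nseg = max(nseg, math.ceil(sec.length / max_seg_len))
        l_cm = (sec.length / nseg) * 1e-4
        d_cm = sec.diameter * 1e-4
        a = math.pi * d_cm * l_cm  # cm^2
        cross = math.pi * (d_cm / 2.0) ** 2
        hr = sec.axial_resistivity * (l_cm / 2.0) / cross * 1e-6  # Mohm
        for j in range(nseg):
            ci = len(parent)
            if j == 0:
                if sec.parent is None:
                    parent.append(-1)
                    g_ax.append(0.0)
                else:
                    pi = last_comp_of[sec.parent]
                    parent.append(pi)
                    g_ax.append(1.0 / (hr + half_r[pi]))  # uS = 1/Mohm
            else:
                parent.append(ci - 1)
                g_ax.append(1.0 / (2.0 * hr))
            half_r.append(hr)
            area.append(a)
            cm_nf.append(sec.capacitance * a * 1e3)
            g_pas.append(a / sec.membrane_resistance * 1e6)
            sec_of_comp.append(sec.id)
            pos.append((j + 0.5) / nseg)
            for ch_name, dens in sorted(sec.channel_densities.items()):
                if dens <= 0 or ch_name not in _GATING_SCHEME:
                    continue
                inst_comp.append(ci)
                inst_gmax.append(dens * a * 1e6)  # uS
                inst_erev.append(E_REV[ch_name])
                inst_goff.append(len(gate_comp))
                scheme = _GATING_SCHEME[ch_name]
                inst_ngate.append(len(scheme))
                for p, gname in scheme:
                    gate_comp.append(ci)
                    gate_kind.append(kind_of[gname])
                    gate_pow.append(p)
        last_comp_of[sec.id] = len(parent) - 1

    n = len(parent)
    cable = DiscretizedCable(
        tree=tree,
        parent=np.asarray(parent, dtype=np.int64),
        area=np.asarray(area),
        cm_nf=np.asarray(cm_nf),
        g_pas=np.asarray(g_pas),
        e_pas=tree.e_pas,
        g_axial=np.asarray(g_ax),
        section_id=sec_of_comp,
        position=np.asarray(pos),
        inst_comp=np.asarray(inst_comp, dtype=np.int64),
        inst_gmax=np.asarray(inst_gmax),
        inst_erev=np.asarray(inst_erev),
        inst_goff=np.asarray(inst_goff, dtype=np.int64),
        inst_ngate=np.asarray(inst_ngate, dtype=np.int64),
        gate_comp=np.asarray(gate_comp, dtype=np.int64),
        gate_kind=np.asarray(gate_kind, dtype=np.int64),
        gate_pow=np.asarray(gate_pow, dtype=np.int64),
        gate_params=kind_rows,
        gate_kind_names=kind_names,
        stim_g=np.zeros(n),
        stim_e=0.0,
        inj_amp=np.zeros(n),
    )
    return cable


def _gate_tables(kind_rows: np.ndarray, dt: float):
    """Tabulate steady state and exact-exponential factor per gate kind."""
    v = np.arange(V_TABLE_MIN, V_TABLE_MAX + V_TABLE_STEP, V_TABLE_STEP)
    nk = kind_rows.shape[0]
    inf_tab = np.empty((nk, v.size))
    q_tab = np.empty((nk, v.size))
    for i in range(nk):
        inact, vh, k, tau0, tau1, tc, tw = kind_rows[i]
        if inact > 0.5:
            inf_tab[i] = 1.0 / (1.0 + np.exp((v - vh) / k))
        else:
            inf_tab[i] = 1.0 / (1.0 + np.exp((vh - v) / k))
        tau = tau0 + tau1 * np.exp(-(((v - tc) / tw) ** 2))
        q_tab[i] = 1.0 - np.exp(-dt / tau)
    return inf_tab, q_tab, v


@njit(cache=True, fastmath=True)
def _run_kernel(
    nsteps,
    dt,
    parent,
    g_ax,
    cm_dt,
    g_pas,
    e_pas,
    inst_comp,
    inst_gmax,
    inst_erev,
    inst_goff,
    inst_ngate,
    gate_comp,
    gate_kind,
    gate_pow,
    state,
    inf_tab,
    q_tab,
    v_min,
    dv_inv,
    nvtab,
    stim_g,
    stim_e,
    gate_wave,
    inj_amp,
    inj_wave,
    rec_idx,
    v,
    out,
):
    n = parent.size
    ninst = inst_comp.size
    d = np.empty(n)
    rhs = np.empty(n)
    i0c = np.empty(n, dtype=np.int64)
    frc = np.empty(n)
    # constant part of the diagonal: capacitance, leak, axial
    d_const = np.empty(n)
    for i in range(n):
        d_const[i] = cm_dt[i] + g_pas[i] + g_ax[i]
    for i in range(1, n):
        d_const[parent[i]] += g_ax[i]
    for k in range(nsteps):
        # 1) assemble the constant/leak/stimulus part of the system and
        #    locate each compartment's voltage in the gate tables
        sgate = gate_wave[k]
        iw = inj_wave[k]
        for i in range(n):
            d[i] = d_const[i]
            rhs[i] = cm_dt[i] * v[i] + g_pas[i] * e_pas
            if stim_g[i] > 0.0 and sgate > 0.0:
                gs = stim_g[i] * sgate
                d[i] += gs
                rhs[i] += gs * stim_e
            if inj_amp[i] != 0.0 and iw != 0.0:
                rhs[i] += inj_amp[i] * iw
            u = (v[i] - v_min) * dv_inv
            if u < 0.0:
                u = 0.0
            elif u > nvtab - 1.001:
                u = nvtab - 1.001
            i0c[i] = int(u)
            frc[i] = u - int(u)
        # 2) advance gates (exact exponential, tabulated) and add channel
        #    conductances, one fused pass over channel instances
        for j in range(ninst):
            c = inst_comp[j]
            i0 = i0c[c]
            fr = frc[c]
            op = 1.0
            off = inst_goff[j]
            for t in range(inst_ngate[j]):
                gi = off + t
                kk = gate_kind[gi]
                inf = inf_tab[kk, i0] * (1.0 - fr) + inf_tab[kk, i0 + 1] * fr
                q = q_tab[kk, i0] * (1.0 - fr) + q_tab[kk, i0 + 1] * fr
                s = state[gi] + (inf - state[gi]) * q
                state[gi] = s
                for _ in range(gate_pow[gi]):
                    op *= s
            gch = inst_gmax[j] * op
            d[c] += gch
            rhs[c] += gch * inst_erev[j]
        # 3) Hines solve (leaves -> root, then root -> leaves)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / d[i]
            d[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / d[0]
        if abs(v[0]) > 200.0:
            return k, 0
        for i in range(1, n):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / d[i]
            if abs(v[i]) > 200.0:
                return k, i
        for r in range(rec_idx.size):
            out[r, k + 1] = v[rec_idx[r]]
    return -1, -1


def integrate(
    cable: DiscretizedCable,
    stimuli=None,
    dt: float = 0.025,
    t_stop: float = 1000.0,
    record_sites: dict[str, int] | None = None,
    *,
    gate_wave: np.ndarray | None = None,
    inj_wave: np.ndarray | None = None,
    seed: int | None = None,
) -> SimulationResult:
    """Advance the cable from V = e_pas to ``t_stop`` ms in steps of ``dt``.

    ``record_sites`` maps site names to compartment indices (see
    :meth:`DiscretizedCable.comp_index`); defaults to the root compartment
    under the name ``"root"``. ``gate_wave``/``inj_wave`` are per-step
    scalars multiplying the attached conductance stimulus and current
    injection (typically produced by :mod:`nociterm.protocols`).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if stimuli is not None:
        from .protocols import attach_capsaicin  # pragma: no cover - convenience

        cable, gate_wave, _ = attach_capsaicin(cable, stimuli, dt=dt, t_stop=t_stop)
    nsteps = int(round(t_stop / dt))
    if record_sites is None:
        record_sites = {"root": 0}
    for name, idx in record_sites.items():
        if not 0 <= idx < cable.n_comp:
            raise KeyError(f"record site {name!r}: compartment {idx} does not exist")
    if gate_wave is None:
        gate_wave = np.zeros(nsteps)
    if inj_wave is None:
        inj_wave = np.zeros(nsteps)
    if gate_wave.size < nsteps or inj_wave.size < nsteps:
        raise ValueError("stimulus waveforms shorter than the simulation")

    inf_tab, q_tab, vgrid = _gate_tables(cable.gate_params, dt)
    v = np.full(cable.n_comp, cable.e_pas, dtype=np.float64)
    # gates start at steady state for the initial voltage
    state = np.empty(cable.gate_comp.size)
    for g in range(state.size):
        kin = _KIN[cable.gate_kind_names[cable.gate_kind[g]]]
        state[g] = float(kin.steady_state(cable.e_pas))

    rec_idx = np.asarray(list(record_sites.values()), dtype=np.int64)
    out = np.empty((rec_idx.size, nsteps + 1))
    out[:, 0] = v[rec_idx]
    cm_dt = cable.cm_nf / dt

    bad_step, bad_comp = _run_kernel(
        nsteps,
        dt,
        cable.parent,
        cable.g_axial,
        cm_dt,
        cable.g_pas,
        cable.e_pas,
        cable.inst_comp,
        cable.inst_gmax,
        cable.inst_erev,
        cable.inst_goff,
        cable.inst_ngate,
        cable.gate_comp,
        cable.gate_kind,
        cable.gate_pow,
        state,
        inf_tab,
        q_tab,
        V_TABLE_MIN,
        1.0 / V_TABLE_STEP,
        vgrid.size,
        cable.stim_g,
        cable.stim_e,
        np.ascontiguousarray(gate_wave[:nsteps], dtype=np.float64),
        cable.inj_amp,
        np.ascontiguousarray(inj_wave[:nsteps], dtype=np.float64),
        rec_idx,
        v,
        out,
    )
    if bad_step >= 0:
        raise NumericalError(
            f"voltage diverged (|V| > {V_DIVERGE} mV) in compartment {bad_comp} "
            f"(section {cable.section_id[bad_comp]!r}) at t = {bad_step * dt:.3f} ms",
            compartment=bad_comp,
            time_ms=bad_step * dt,
        )

    time = np.arange(nsteps + 1) * dt
    meta = {
        "dt": dt,
        "t_stop": t_stop,
        "n_comp": cable.n_comp,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "dt": dt,
                    "t_stop": t_stop,
                    "n_comp": cable.n_comp,
                    "neuron_class": cable.tree.neuron_class,
                    "n_endings": cable.tree.n_endings,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }
    wave_full = np.zeros(nsteps + 1)
    wave_full[1:] = gate_wave[:nsteps]
    return SimulationResult(
        time=time,
        voltages={name: out[r] for r, name in enumerate(record_sites)},
        stimulus_trace=wave_full,
        metadata=meta,
    )


def detect_spikes(
    result: SimulationResult,
    site: str,
    threshold: float = 0.0,
    refractory: float = 2.0,
) -> SpikeTrain:
    """Upward threshold crossings at a recorded site, with a refractory gap.

    Crossing times are linearly interpolated between samples, which makes
    spike-time comparisons insensitive to the sampling step.
    """
    if site not in result.voltages:
        raise KeyError(f"site {site!r} was not recorded")
    v = result.voltages[site]
    t = result.time
    above = v >= threshold
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return SpikeTrain(times=np.asarray(times))
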