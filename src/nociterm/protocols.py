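"""Assembly of nerve-ending stimulation and current-injection protocols.

The capsaicin-like protocol treats every stimulated nerve ending (free
endings and de novo branches) as the application site: the ending membrane
carries the full transducer density, which decays exponentially with axial
diffusion distance beyond the endings (integrated exactly per compartment),
plus a fixed-size point conductance drive at each ending tip. Both are
multiplied by the shared capsaicin time gate. Step-current protocols exist
for solver verification only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cable import DiscretizedCable, SimulationResult, integrate
from .channels import CapsaicinStimulus, capsaicin_gate
import math

from .morphology import BASELINE_ENDING_LENGTH, ENDING_ROLES

__all__ = [
    "ProtocolSpec",
    "attach_capsaicin",
    "run_capsaicin_protocol",
    "step_current_protocol",
    "run_step_protocol",
    "ProtocolError",
    "DEFAULT_RECORD_SITES",
]


class ProtocolError(ValueError):
    """Inconsistent protocol configuration."""


#: (name, section id, position) recorded by default: the distal end of the
#: central axon, i.e. the central terminal where output spikes are counted.
DEFAULT_RECORD_SITES = (("central_terminal", "central_axon", 1.0),)


@dataclass(frozen=True)
class ProtocolSpec:
    """A capsaicin-like stimulation run.

    ``t_onset`` inside ``stimulus`` is measured from the end of the
    settling period; the simulated span is ``settle + t_stop``.
    """

    stimulus: CapsaicinStimulus = field(default_factory=CapsaicinStimulus)
    stimulated_endings: tuple[str, ...] | None = None  # None = all endings
    record_sites: tuple[tuple[str, str, float], ...] = DEFAULT_RECORD_SITES
    t_stop: float = 4000.0  # ms, after settling
    settle: float = 500.0  # ms at zero stimulus before t = 0 of the protocol

    def __post_init__(self) -> None:
        if self.stimulus.t_onset + self.stimulus.t_puff > self.t_stop:
            raise ProtocolError("t_onset + t_puff must be <= t_stop")
        if self.settle < 0:
            raise ProtocolError("settle must be >= 0")


def _ending_sections(cable: DiscretizedCable, protocol: ProtocolSpec):
    tree = cable.tree
    if protocol.stimulated_endings is None:
        secs = [s for s in tree.sections if s.role_tag in ENDING_ROLES]
    else:
        secs = [tree.section(sid) for sid in protocol.stimulated_endings]
    if not secs:
        raise ProtocolError("stimulated ending set is empty")
    return secs


def _endpoint_distances(tree, ending_ids: set[str]) -> dict[str, tuple[float, float]]:
    """Per section, the axial distances (um) of its proximal and distal
    endpoints to the nearest stimulated ending (multi-source Dijkstra over
    the section graph; stimulated sections are distance-zero sources)."""
    import heapq

    node_of = {None: "@root"}
    for s in tree.sections:
        node_of[s.id] = s.id  # distal endpoint of each section
    edges: dict[str, list[tuple[str, float]]] = {n: [] for n in {"@root", *node_of.values()}}
    for s in tree.sections:
        a, b = node_of[s.parent], node_of[s.id]
        edges[a].append((b, s.length))
        edges[b].append((a, s.length))
    dist = {n: np.inf for n in edges}
    heap = []
    for s in tree.sections:
        if s.id in ending_ids:
            for n in (node_of[s.parent], node_of[s.id]):
                if dist[n] > 0.0:
                    dist[n] = 0.0
                    heap.append((0.0, n))
    heapq.heapify(heap)
    while heap:
        d, n = heapq.heappop(heap)
        if d > dist[n]:
            continue
        for m, w in edges[n]:
            nd = d + w
            if nd < dist[m]:
                dist[m] = nd
                heapq.heappush(heap, (nd, m))
    return {
        s.id: (dist[node_of[s.parent]], dist[node_of[s.id]]) for s in tree.sections
    }


def _transducer_compartment_conductance(
    cable: DiscretizedCable, stim: CapsaicinStimulus, ending_ids: set[str]
) -> np.ndarray:
    """Transducer conductance per compartment (uS).

    The density profile is quadratured on a fine arc-length grid per
    section and assigned to compartment centers with linear (hat-function)
    weights, which preserves both the total conductance and its first
    spatial moment. The attached drive is then nearly independent of the
    mesh, even though the decay length (7 um) is comparable to the default
    segment size.
    """
    y = stim.decay_constant_y
    dists = _endpoint_distances(cable.tree, ending_ids)
    nseg: dict[str, int] = {}
    first_comp: dict[str, int] = {}
    for i, sid in enumerate(cable.section_id):
        if sid not in nseg:
            first_comp[sid] = i
        nseg[sid] = nseg.get(sid, 0) + 1
    out = np.zeros(cable.n_comp)
    for s in cable.tree.sections:
        sid = s.id
        dp, dd = dists[sid]
        stimulated = sid in ending_ids
        if not stimulated and min(dp, dd) / y > 40.0:
            continue  # density is zero to machine precision
        n = nseg[sid]
        seg = s.length / n
        ds = min(0.05, seg / 8.0)
        m = max(int(math.ceil(s.length / ds)), 4)
        edgesq = np.linspace(0.0, s.length, m + 1)
        mid = 0.5 * (edgesq[:-1] + edgesq[1:])
        w = np.diff(edgesq)
        if stimulated:
            dens = np.ones_like(mid)
        else:
            x = np.minimum(dp + mid, dd + (s.length - mid))
            dens = np.exp(-x / y)
        g_fine = stim.gbar_trans * dens * math.pi * s.diameter * w * 1e-2  # uS
        centers = (np.arange(n) + 0.5) * seg
        idx = np.clip(np.searchsorted(centers, mid) - 1, 0, n - 2) if n > 1 else None
        base = first_comp[sid]
        if n == 1:
            out[base] += g_fine.sum()
        else:
            frac = np.clip((mid - centers[idx]) / seg, 0.0, 1.0)
            np.add.at(out, base + idx, g_fine * (1.0 - frac))
            np.add.at(out, base + idx + 1, g_fine * frac)
    return out


def attach_capsaicin(
    cable: DiscretizedCable,
    protocol: ProtocolSpec,
    dt: float = 0.025,
    t_stop: float | None = None,
):
    """Return (cable with stimulus conductances, gate wave, total duration).

    Every compartment of a stimulated nerve ending is at the application
    site (x = 0) and carries the full transducer density; compartments
    beyond the ending receive the exponentially decayed density
    ``transducer_density(x)`` with x the axial diffusion distance to the
    nearest stimulated ending. Densities convert to absolute conductances
    through compartment areas; the point drive is added at the tip
    compartment of every stimulated ending.
    """
    stim = protocol.stimulus
    duration = protocol.settle + (protocol.t_stop if t_stop is None else t_stop)
    sec_ids = {s.id: s for s in _ending_sections(cable, protocol)}
    stim_g = _transducer_compartment_conductance(cable, stim, set(sec_ids))
    # point process at each ending tip: absolute conductance referenced to
    # the class-baseline ending area, independent of discretization and of
    # the elongation condition; anchored at the true section end via a
    # Thevenin series correction for the center-to-end axial resistance,
    # so the attachment point does not move with the mesh
    ref_len = BASELINE_ENDING_LENGTH[cable.tree.neuron_class]
    nseg: dict[str, int] = {}
    for sid in cable.section_id:
        nseg[sid] = nseg.get(sid, 0) + 1
    for sid, sec in sec_ids.items():
        tip = cable.comp_index(sid, 1.0)
        ref_area = math.pi * sec.diameter * ref_len * 1e-8  # cm^2
        g_point = stim.gbar_cap * ref_area * 1e6  # uS at the section end
        seg_cm = sec.length / nseg[sid] * 1e-4
        cross = math.pi * (sec.diameter * 1e-4 / 2.0) ** 2
        hr_mohm = sec.axial_resistivity * (seg_cm / 2.0) / cross * 1e-6
        stim_g[tip] += g_point / (1.0 + g_point * hr_mohm)
    nsteps = int(round(duration / dt))
    t = (np.arange(nsteps) + 1) * dt  # end-of-step times
    gate_wave = capsaicin_gate(t - protocol.settle, stim)
    stimulated = replace(cable, stim_g=stim_g, stim_e=stim.e_trans)
    return stimulated, gate_wave, duration


def run_capsaicin_protocol(
    cable: DiscretizedCable,
    protocol: ProtocolSpec,
    dt: float = 0.025,
) -> SimulationResult:
    """Attach the protocol, resolve record sites, settle, and integrate."""
    stimulated, gate_wave, duration = attach_capsaicin(cable, protocol, dt=dt)
    sites = {
        name: cable.comp_index(sec, pos) for name, sec, pos in protocol.record_sites
    }
    return integrate(
        stimulated, dt=dt, t_stop=duration, record_sites=sites, gate_wave=gate_wave
    )


@dataclass(frozen=True)
class StepProtocol:
    section: str
    position: float = 0.5
    amplitude_pa: float = 0.0
    t_start: float = 100.0  # ms
    duration: float = 200.0  # ms
    t_stop: float = 500.0  # ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ProtocolError("duration must be positive")


def step_current_protocol(
    section: str,
    amplitude_pa: float,
    duration: float,
    *,
    position: float = 0.5,
    t_start: float = 100.0,
    t_stop: float | None = None,
) -> StepProtocol:
    """Square current injection at one site (solver verification only)."""
    return StepProtocol(
        section=section,
        position=position,
        amplitude_pa=amplitude_pa,
        t_start=t_start,
        duration=duration,
        t_stop=t_stop if t_stop is not None else t_start + duration + 200.0,
    )


def run_step_protocol(
    cable: DiscretizedCable,
    protocol: StepProtocol,
    dt: float = 0.025,
    record_sites: dict[str, int] | None = None,
) -> SimulationResult:
    comp = cable.comp_index(protocol.section, protocol.position)
    inj = np.zeros(cable.n_comp)
    inj[comp] = protocol.amplitude_pa * 1e-3  # nA
    nsteps = int(round(protocol.t_stop / dt))
    t = (np.arange(nsteps) + 1) * dt
    wave = ((t > protocol.t_start) & (t <= protocol.t_start + protocol.duration)).astype(float)
    stimulated = replace(cable, inj_amp=inj)
    if record_sites is None:
        record_sites = {"injection_site": comp}
    return integrate(
        stimulated, dt=dt, t_stop=protocol.t_stop, record_sites=record_sites, inj_wave=wave
    )
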