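"""SWC serialization of terminal-tree specs, with a JSON sidecar.

The standard 7-column SWC format (index, type, x, y, z, radius, parent)
carries topology and geometry: one node per section endpoint, chained from
a root soma node, laid out in a deterministic planar embedding (geometry is
electrically irrelevant; only lengths and radii matter). Role tags,
channel-density maps, passive overrides, and segment counts go in a JSON
sidecar keyed by section id, so read(write(tree)) reproduces the tree
specification exactly up to coordinate round-off.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from .morphology import (
    MorphologyError,
    SectionSpec,
    TerminalTreeSpec,
    validate_tree,
)

__all__ = ["write_swc", "read_swc", "save_tree", "load_tree", "SwcFormatError"]

SWC_TYPE = {
    "soma": 1,
    "central_axon": 2,
    "stem": 2,
    "peripheral_axon": 2,
    "distal_axon": 2,
    "propagation": 2,
    "navless_siz": 2,
    "free_ending": 2,
    "de_novo_branch": 2,
}


class SwcFormatError(MorphologyError):
    """Malformed SWC content (orphan nodes, cycles, multiple roots)."""


def write_swc(tree: TerminalTreeSpec) -> tuple[str, str]:
    """Serialize a tree to (swc_text, sidecar_json).

    Each section becomes one SWC node at its distal endpoint whose distance
    to the parent node equals the section length; the soma is the root
    node. The sidecar holds everything SWC cannot express.
    """
    validate_tree(tree)
    node_of: dict[str, int] = {}
    lines = ["# index type x y z radius parent"]
    # deterministic order: parents before children
    by_parent: dict[str | None, list[SectionSpec]] = {}
    for s in tree.sections:
        by_parent.setdefault(s.parent, []).append(s)
    queue = list(by_parent[None])
    order: list[SectionSpec] = []
    while queue:
        s = queue.pop(0)
        order.append(s)
        queue.extend(sorted(by_parent.get(s.id, []), key=lambda x: x.id))
    coords: dict[str, tuple[float, float]] = {}
    child_rank: dict[str, int] = {}
    for idx, sec in enumerate(order, start=1):
        node_of[sec.id] = idx
        if sec.parent is None:
            x = y = 0.0
            parent_idx = -1
        else:
            px, py = coords[sec.parent]
            rank = child_rank.get(sec.parent, 0)
            child_rank[sec.parent] = rank + 1
            theta = (rank % 7) * (math.pi / 8.0) - math.pi / 4.0
            x = px + sec.length * math.cos(theta)
            y = py + sec.length * math.sin(theta)
            parent_idx = node_of[sec.parent]
        coords[sec.id] = (x, y)
        lines.append(
            f"{idx} {SWC_TYPE[sec.role_tag]} {x:.4f} {y:.4f} 0.0000 "
            f"{sec.diameter / 2.0:.4f} {parent_idx}"
        )
    sidecar = {
        "neuron_class": tree.neuron_class,
        "n_endings": tree.n_endings,
        "ending_length": tree.ending_length,
        "branch_increase_pct": tree.branch_increase_pct,
        "elongation_target": tree.elongation_target,
        "e_pas": tree.e_pas,
        "sections": {
            sec.id: {
                "node": node_of[sec.id],
                "role_tag": sec.role_tag,
                "length": sec.length,
                "n_segments": sec.n_segments,
                "membrane_resistance": sec.membrane_resistance,
                "axial_resistivity": sec.axial_resistivity,
                "capacitance": sec.capacitance,
                "channel_densities": sec.channel_densities,
            }
            for sec in order
        },
    }
    return "\n".join(lines) + "\n", json.dumps(sidecar, indent=1)


def read_swc(swc_text: str, sidecar_json: str | None = None) -> TerminalTreeSpec:
    """Parse SWC text (+ optional sidecar) back into a tree spec.

    Without a sidecar, roles default to soma for the root and distal_axon
    elsewhere, with lengths taken from inter-node distances. Orphan nodes,
    cycles, and multiple roots raise :class:`SwcFormatError`.
    """
    nodes: dict[int, tuple[int, float, float, float, float, int]] = {}
    for ln in swc_text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 7:
            raise SwcFormatError(f"malformed SWC line: {ln!r}")
        idx, typ = int(parts[0]), int(parts[1])
        x, y, z, radius = map(float, parts[2:6])
        parent = int(parts[6])
        if idx in nodes:
            raise SwcFormatError(f"duplicate node index {idx}")
        nodes[idx] = (typ, x, y, z, radius, parent)
    if not nodes:
        raise SwcFormatError("empty SWC file")
    roots = [i for i, n in nodes.items() if n[5] == -1]
    if len(roots) != 1:
        raise SwcFormatError(f"expected exactly one root, found {len(roots)}")
    for i, n in nodes.items():
        if n[5] != -1 and n[5] not in nodes:
            raise SwcFormatError(f"orphan node {i} (parent {n[5]} missing)")
    # cycle check by walking up
    for i in nodes:
        seen = set()
        cur = i
        while cur != -1:
            if cur in seen:
                raise SwcFormatError(f"cycle through node {cur}")
            seen.add(cur)
            cur = nodes[cur][5]

    side = json.loads(sidecar_json) if sidecar_json else None
    sec_meta_by_node: dict[int, tuple[str, dict]] = {}
    if side:
        for sid, meta in side["sections"].items():
            sec_meta_by_node[meta["node"]] = (sid, meta)

    sections = []
    for idx in sorted(nodes):
        typ, x, y, z, radius, parent = nodes[idx]
        if side:
            sid, meta = sec_meta_by_node[idx]
            parent_sid = sec_meta_by_node[parent][0] if parent != -1 else None
            sections.append(
                SectionSpec(
                    id=sid,
                    parent=parent_sid,
                    length=meta["length"],
                    diameter=radius * 2.0,
                    n_segments=meta["n_segments"],
                    membrane_resistance=meta["membrane_resistance"],
                    axial_resistivity=meta["axial_resistivity"],
                    capacitance=meta["capacitance"],
                    channel_densities=dict(meta["channel_densities"]),
                    role_tag=meta["role_tag"],
                )
            )
        else:
            if parent == -1:
                length = radius * 2.0  # soma convention: length = diameter
            else:
                px, py, pz = nodes[parent][1:4]
                length = math.dist((x, y, z), (px, py, pz))
                if length <= 0:
                    raise SwcFormatError(f"zero-length segment at node {idx}")
            sections.append(
                SectionSpec(
                    id=f"n{idx}",
                    parent=None if parent == -1 else f"n{parent}",
                    length=length,
                    diameter=radius * 2.0,
                    n_segments=1,
                    role_tag="soma" if parent == -1 else "distal_axon",
                )
            )
    if side:
        tree = TerminalTreeSpec(
            sections=tuple(sections),
            neuron_class=side["neuron_class"],
            n_endings=side["n_endings"],
            ending_length=side["ending_length"],
            branch_increase_pct=side["branch_increase_pct"],
            elongation_target=side["elongation_target"],
            e_pas=side["e_pas"],
        )
        validate_tree(tree)
        return tree
    return TerminalTreeSpec(sections=tuple(sections), n_endings=0)


def save_tree(tree: TerminalTreeSpec, path: str | Path) -> None:
    """Write ``<path>.swc`` and ``<path>.json`` (sidecar)."""
    path = Path(path)
    swc, sidecar = write_swc(tree)
    path.with_suffix(".swc").write_text(swc)
    path.with_suffix(".json").write_text(sidecar)


def load_tree(path: str | Path) -> TerminalTreeSpec:
    """Read a tree written by :func:`save_tree`."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    return read_swc(
        path.with_suffix(".swc").read_text(),
        sidecar.read_text() if sidecar.exists() else None,
    )
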