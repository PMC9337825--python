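"""Nociceptor terminal-tree morphologies and structural-plasticity transforms.

The modeled neuron is a pseudo-unipolar C-fiber nociceptor: a soma-like
compartment on a stem axon that bifurcates at a T-junction into a peripheral
and a central axon. The peripheral axon fans out into terminal chains, each
ending in the ordered sequence

    distal_axon -> propagation -> navless_siz -> free_ending

where the spike initiation zone (SIZ) is a 25 um sodium-channel-free
("Na(v)less") compartment and the propagation compartment (50 um) carries
full sodium conductance. Inflammation-style structural plasticity is modeled
by two transforms: elongation of the free endings and addition of de novo
Na(v)less branches at the distal end of the propagation compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SectionSpec",
    "TerminalTreeSpec",
    "build_terminal_tree",
    "apply_elongation",
    "apply_branching",
    "validate_tree",
    "total_membrane_area",
    "MorphologyError",
    "SODIUM_CHANNELS",
    "NAVLESS_ROLES",
    "ENDING_ROLES",
    "BASELINE_ENDING_LENGTH",
    "DEFAULT_N_ENDINGS",
]


class MorphologyError(ValueError):
    """Invalid geometry, topology, or neuron-class parameter."""


#: channel names treated as sodium conductances (zeroed in Na(v)less sections)
SODIUM_CHANNELS = frozenset({"nav1p8", "nav1p9", "nattxs", "nap"})

#: role tags whose sections must carry zero sodium density
NAVLESS_ROLES = frozenset({"navless_siz", "free_ending", "de_novo_branch"})

#: role tags that behave as stimulated nerve endings (transducer targets)
ENDING_ROLES = frozenset({"free_ending", "de_novo_branch"})

ROLES = frozenset(
    {
        "soma",
        "stem",
        "peripheral_axon",
        "central_axon",
        "distal_axon",
        "propagation",
        "navless_siz",
        "free_ending",
        "de_novo_branch",
    }
)

# -- fixed geometry (um) ----------------------------------------------------
SOMA_DIAMETER = 25.0
BRANCH_DIAMETER = 0.25
SIZ_LENGTH = 25.0
PROPAGATION_LENGTH = 50.0
BASELINE_ENDING_LENGTH = {"generic": 32.0, "peptidergic": 26.0}
DEFAULT_N_ENDINGS = {"generic": 14, "peptidergic": 7}
STEM_LENGTH = 100.0
PERIPHERAL_AXON_LENGTH = 2000.0
CENTRAL_AXON_LENGTH = 2000.0
DISTAL_AXON_LENGTH = 250.0

# -- passive membrane -------------------------------------------------------
RM_DEFAULT = 10_000.0  # ohm cm^2
RA_DEFAULT = 150.0  # ohm cm
CM_DEFAULT = 1.0  # uF/cm^2
E_PAS_DEFAULT = -60.0  # mV
ENDING_RM_FACTOR = 4.0  # free endings: 4x somatic membrane resistance
ENDING_RA_FACTOR = 15.0  # free endings: 15x distal-axon axial resistivity

# -- discretization ---------------------------------------------------------
MAX_SEG_TERMINAL = 5.0  # um, propagation sections
MAX_SEG_ENDING = 2.0  # um, free endings and the Na(v)less SIZ
MAX_SEG_DISTAL = 10.0  # um, distal axons feeding the terminal chains
MAX_SEG_AXON = 25.0  # um, long axons


@dataclass(frozen=True)
class SectionSpec:
    """One unbranched cable section with geometry, passives, and densities."""

    id: str
    parent: str | None
    length: float  # um
    diameter: float  # um
    n_segments: int
    membrane_resistance: float = RM_DEFAULT  # ohm cm^2
    axial_resistivity: float = RA_DEFAULT  # ohm cm
    capacitance: float = CM_DEFAULT  # uF/cm^2
    channel_densities: dict[str, float] = field(default_factory=dict)
    role_tag: str = "peripheral_axon"

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise MorphologyError(
                f"section {self.id!r}: length and diameter must be positive"
            )
        if self.n_segments < 1:
            raise MorphologyError(f"section {self.id!r}: n_segments must be >= 1")
        if self.role_tag not in ROLES:
            raise MorphologyError(f"section {self.id!r}: unknown role {self.role_tag!r}")
        for name, g in self.channel_densities.items():
            if g < 0:
                raise MorphologyError(
                    f"section {self.id!r}: negative density for {name!r}"
                )
        if self.role_tag in NAVLESS_ROLES:
            for name in SODIUM_CHANNELS:
                if self.channel_densities.get(name, 0.0) != 0.0:
                    raise MorphologyError(
                        f"section {self.id!r} ({self.role_tag}) must have zero "
                        f"sodium density, got {name}"
                    )

    @property
    def area(self) -> float:
        """Lateral cylinder area in um^2."""
        return math.pi * self.diameter * self.length


@dataclass(frozen=True)
class TerminalTreeSpec:
    """A rooted tree of sections describing one model nociceptor."""

    sections: tuple[SectionSpec, ...]
    neuron_class: str = "generic"
    n_endings: int = 1
    ending_length: float = 32.0  # um, current free-ending length
    branch_increase_pct: float = 0.0
    elongation_target: float | None = None
    e_pas: float = E_PAS_DEFAULT  # mV

    def section(self, section_id: str) -> SectionSpec:
        for s in self.sections:
            if s.id == section_id:
                return s
        raise KeyError(section_id)

    def by_role(self, role: str) -> list[SectionSpec]:
        return [s for s in self.sections if s.role_tag == role]

    def children_of(self, section_id: str | None) -> list[SectionSpec]:
        return [s for s in self.sections if s.parent == section_id]


def _segments_for(length: float, role: str) -> int:
    if role in {"stem", "peripheral_axon", "central_axon"}:
        max_seg = MAX_SEG_AXON
    elif role == "distal_axon":
        max_seg = MAX_SEG_DISTAL
    elif role in {"free_ending", "navless_siz", "de_novo_branch"}:
        max_seg = MAX_SEG_ENDING
    else:
        max_seg = MAX_SEG_TERMINAL
    return max(1, math.ceil(length / max_seg))


def _make_section(
    sid: str,
    parent: str | None,
    length: float,
    role: str,
    densities: dict[str, float],
    diameter: float = BRANCH_DIAMETER,
) -> SectionSpec:
    dens = dict(densities)
    if role in NAVLESS_ROLES:
        for name in SODIUM_CHANNELS:
            dens[name] = 0.0
    rm = RM_DEFAULT
    ra = RA_DEFAULT
    if role in ENDING_ROLES:
        rm = RM_DEFAULT * ENDING_RM_FACTOR
        ra = RA_DEFAULT * ENDING_RA_FACTOR
    return SectionSpec(
        id=sid,
        parent=parent,
        length=length,
        diameter=diameter,
        n_segments=_segments_for(length, role),
        membrane_resistance=rm,
        axial_resistivity=ra,
        channel_densities=dens,
        role_tag=role,
    )


def build_terminal_tree(
    neuron_class: str = "generic",
    n_endings: int | None = None,
    branch_increase_pct: float = 0.0,
    elongation_target: float | None = None,
    *,
    ending_length: float | None = None,
    scale_propagation: bool = True,
) -> TerminalTreeSpec:
    """Construct a terminal-tree morphology for one neuron class.

    Parameters
    ----------
    neuron_class:
        ``"generic"`` (all Na_v1.8+ nociceptors; baseline ending 32 um,
        14 endings) or ``"peptidergic"`` (CGRP+; shorter 26 um endings,
        7 endings, no Na_v1.9 anywhere).
    n_endings:
        Number of terminal chains; defaults to the class default.
    branch_increase_pct:
        Percentage of de novo Na(v)less branches to add, relative to the
        number of endings (100 -> one branch per ending).
    elongation_target:
        If given, elongate every free ending to this length (um).
    ending_length:
        Override the baseline free-ending length (um).
    scale_propagation:
        When elongating, also scale propagation sections by the same
        percentage as the endings.
    """
    from .channels import default_density_map  # late import: avoid cycle

    if neuron_class not in BASELINE_ENDING_LENGTH:
        raise MorphologyError(f"unknown neuron class {neuron_class!r}")
    if n_endings is None:
        n_endings = DEFAULT_N_ENDINGS[neuron_class]
    if n_endings < 1:
        raise MorphologyError("n_endings must be >= 1")
    if branch_increase_pct < 0:
        raise MorphologyError("branch_increase_pct must be >= 0")
    base_len = BASELINE_ENDING_LENGTH[neuron_class] if ending_length is None else float(ending_length)
    if base_len <= 0:
        raise MorphologyError("ending_length must be positive")
    if elongation_target is not None and elongation_target < base_len:
        raise MorphologyError(
            "elongation_target must be >= the baseline ending length"
        )

    dens = default_density_map(neuron_class)

    sections: list[SectionSpec] = []
    soma = SectionSpec(
        id="soma",
        parent=None,
        length=SOMA_DIAMETER,
        diameter=SOMA_DIAMETER,
        n_segments=1,
        channel_densities=dict(dens),
        role_tag="soma",
    )
    sections.append(soma)
    sections.append(_make_section("stem", "soma", STEM_LENGTH, "stem", dens))
    # stem expands to peripheral and central axons at the T-junction
    sections.append(
        _make_section("peripheral_axon", "stem", PERIPHERAL_AXON_LENGTH, "peripheral_axon", dens)
    )
    sections.append(
        _make_section("central_axon", "stem", CENTRAL_AXON_LENGTH, "central_axon", dens)
    )
    for k in range(n_endings):
        sections.append(
            _make_section(f"distal_axon_{k}", "peripheral_axon", DISTAL_AXON_LENGTH, "distal_axon", dens)
        )
        sections.append(
            _make_section(f"propagation_{k}", f"distal_axon_{k}", PROPAGATION_LENGTH, "propagation", dens)
        )
        sections.append(
            _make_section(f"siz_{k}", f"propagation_{k}", SIZ_LENGTH, "navless_siz", dens)
        )
        sections.append(
            _make_section(f"ending_{k}", f"siz_{k}", base_len, "free_ending", dens)
        )

    tree = TerminalTreeSpec(
        sections=tuple(sections),
        neuron_class=neuron_class,
        n_endings=n_endings,
        ending_length=base_len,
        branch_increase_pct=0.0,
        elongation_target=None,
    )
    if branch_increase_pct > 0:
        tree = apply_branching(tree, branch_increase_pct)
    if elongation_target is not None:
        tree = apply_elongation(tree, elongation_target, scale_propagation=scale_propagation)
    validate_tree(tree)
    return tree


def apply_elongation(
    tree: TerminalTreeSpec, new_length: float, *, scale_propagation: bool = True
) -> TerminalTreeSpec:
    """Elongate every free ending to ``new_length`` um.

    When ``scale_propagation`` is true the propagation sections scale by
    the same ratio as the endings. De novo branches keep their baseline
    length (the condition percentages change branch numbers, not branch
    lengths). Section count is unchanged.
    """
    if new_length <= 0:
        raise MorphologyError("new_length must be positive")
    ratio = new_length / tree.ending_length
    out = []
    for s in tree.sections:
        if s.role_tag == "free_ending":
            s = replace(s, length=new_length, n_segments=_segments_for(new_length, s.role_tag))
        elif s.role_tag == "propagation" and scale_propagation:
            ln = s.length * ratio
            s = replace(s, length=ln, n_segments=_segments_for(ln, s.role_tag))
        out.append(s)
    return replace(
        tree,
        sections=tuple(out),
        ending_length=new_length,
        elongation_target=new_length,
    )


def apply_branching(tree: TerminalTreeSpec, increase_pct: float) -> TerminalTreeSpec:
    """Add de novo Na(v)less branches, round-robin one per ending.

    ``round(increase_pct/100 * n_endings)`` branches are attached at the
    distal end of the propagation sections (the junction with the SIZ/ending
    chain). Each branch has the class baseline ending length, carries zero
    sodium density, and uses free-ending passives.
    """
    if increase_pct < 0:
        raise MorphologyError("increase_pct must be >= 0")
    n_new = round(increase_pct / 100.0 * tree.n_endings)
    if n_new == 0:
        return replace(tree, branch_increase_pct=tree.branch_increase_pct + increase_pct)
    props = sorted(tree.by_role("propagation"), key=lambda s: s.id)
    existing = len(tree.by_role("de_novo_branch"))
    new_sections = list(tree.sections)
    template = tree.by_role("free_ending")[0]
    branch_len = BASELINE_ENDING_LENGTH[tree.neuron_class]
    for j in range(n_new):
        host = props[j % len(props)]
        sid = f"denovo_{existing + j}"
        new_sections.append(
            SectionSpec(
                id=sid,
                parent=host.id,
                length=branch_len,
                diameter=template.diameter,
                n_segments=_segments_for(branch_len, "de_novo_branch"),
                membrane_resistance=template.membrane_resistance,
                axial_resistivity=template.axial_resistivity,
                channel_densities=dict(template.channel_densities),
                role_tag="de_novo_branch",
            )
        )
    return replace(
        tree,
        sections=tuple(new_sections),
        branch_increase_pct=tree.branch_increase_pct + increase_pct,
    )


def validate_tree(tree: TerminalTreeSpec) -> None:
    """Check all structural invariants; raise :class:`MorphologyError` if violated."""
    ids = [s.id for s in tree.sections]
    if len(set(ids)) != len(ids):
        raise MorphologyError("duplicate section ids")
    id_set = set(ids)
    roots = [s for s in tree.sections if s.parent is None]
    if len(roots) != 1 or roots[0].role_tag != "soma":
        raise MorphologyError("tree must have exactly one root (the soma)")
    for s in tree.sections:
        if s.parent is not None and s.parent not in id_set:
            raise MorphologyError(f"section {s.id!r} has unknown parent {s.parent!r}")
    # acyclicity / connectedness: walk every section up to the root
    parent = {s.id: s.parent for s in tree.sections}
    for sid in ids:
        seen = set()
        cur: str | None = sid
        while cur is not None:
            if cur in seen:
                raise MorphologyError(f"cycle through section {cur!r}")
            seen.add(cur)
            cur = parent[cur]
    endings = tree.by_role("free_ending")
    if len(endings) != tree.n_endings:
        raise MorphologyError(
            f"expected {tree.n_endings} free endings, found {len(endings)}"
        )
    for e in endings:
        siz = tree.section(e.parent)
        if siz.role_tag != "navless_siz":
            raise MorphologyError(f"ending {e.id!r} not preceded by a SIZ section")
        prop = tree.section(siz.parent)
        if prop.role_tag != "propagation":
            raise MorphologyError(f"SIZ {siz.id!r} not preceded by a propagation section")
        if tree.section(prop.parent).role_tag != "distal_axon":
            raise MorphologyError(f"propagation {prop.id!r} not preceded by a distal axon")
    if tree.branch_increase_pct == 0 and tree.by_role("de_novo_branch"):
        raise MorphologyError("unexpected de novo branches at 0% branching")
    for s in tree.sections:
        if s.role_tag in NAVLESS_ROLES:
            for name in SODIUM_CHANNELS:
                if s.channel_densities.get(name, 0.0) != 0.0:
                    raise MorphologyError(f"sodium density on Na(v)less section {s.id!r}")
    if tree.neuron_class == "peptidergic":
        for s in tree.sections:
            if s.channel_densities.get("nav1p9", 0.0) != 0.0:
                raise MorphologyError(f"Na_v1.9 present in peptidergic section {s.id!r}")


def total_membrane_area(tree: TerminalTreeSpec) -> float:
    """Analytic membrane area of the whole tree in um^2 (lateral cylinders)."""
    return sum(s.area for s in tree.sections)
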