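"""Shared fixtures: small morphologies and discretized cables.

Simulation-bearing fixtures are session-scoped; the numba kernel is
compiled once and cached, so the first simulation in a session carries the
compilation cost.
"""

from __future__ import annotations

import numpy as np
import pytest

from nociterm import build_terminal_tree, discretize
from nociterm.morphology import SectionSpec, TerminalTreeSpec


@pytest.fixture(scope="session")
def generic_tree():
    return build_terminal_tree("generic")


@pytest.fixture(scope="session")
def small_tree():
    """Two-ending generic tree: cheap enough for repeated simulation."""
    return build_terminal_tree("generic", n_endings=2)


@pytest.fixture(scope="session")
def small_cable(small_tree):
    return discretize(small_tree)


@pytest.fixture(scope="session")
def single_chain_cable():
    return discretize(build_terminal_tree("generic", n_endings=1))


def make_passive_cable(length_um=500.0, diameter_um=0.25, n_segments=100,
                       rm=10_000.0, ra=150.0):
    """A single unbranched passive cable (no channels), sealed at both ends."""
    sec = SectionSpec(
        id="cable",
        parent=None,
        length=length_um,
        diameter=diameter_um,
        n_segments=n_segments,
        membrane_resistance=rm,
        axial_resistivity=ra,
        channel_densities={},
        role_tag="soma",  # root role; passive either way
    )
    tree = TerminalTreeSpec(sections=(sec,), n_endings=0)
    return _discretize_unvalidated(tree)


def _discretize_unvalidated(tree):
    """Discretize a bare test geometry, bypassing nociceptor-tree validation."""
    import nociterm.cable as cable_mod

    orig = cable_mod.validate_tree
    cable_mod.validate_tree = lambda t: None
    try:
        return cable_mod.discretize(tree)
    finally:
        cable_mod.validate_tree = orig


@pytest.fixture()
def passive_cable():
    return make_passive_cable()


@pytest.fixture()
def passive_compartment():
    """One isolated passive compartment (RC circuit)."""
    return make_passive_cable(length_um=50.0, diameter_um=10.0, n_segments=1)
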