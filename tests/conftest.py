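"""Shared fixtures: representative toy systems, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from egresslab import (ChannelSpec, ForceField, GateSpec, ToySystemSpec,
                       build_cage_system)


@pytest.fixture(scope="session")
def ff():
    return ForceField()


@pytest.fixture(scope="session")
def closed_cage():
    """Sealed cage: a fully buried binding site."""
    return build_cage_system(channels=[], seed=7)


@pytest.fixture(scope="session")
def drilled_cage():
    """One ungated 2.5 Å channel along +z."""
    return build_cage_system(
        channels=[ChannelSpec("2c", (0.0, 0.0, 1.0), 2.5)], seed=3)


@pytest.fixture(scope="session")
def two_channel_cage():
    """Wide (3.0 Å) channel along +z, narrow (1.2 Å) along +x."""
    return build_cage_system(
        channels=[ChannelSpec("wide", (0.0, 0.0, 1.0), 3.0),
                  ChannelSpec("narrow", (1.0, 0.0, 0.0), 1.2)],
        seed=8)


@pytest.fixture(scope="session")
def gated_cage():
    """One 2.5 Å channel occluded by a 4-bead revolving-door gate."""
    return build_cage_system(
        channels=[ChannelSpec("2c", (0.0, 0.0, 1.0), 2.5, gated=True)],
        gates=[GateSpec(channel_label="2c", barrier_height=2.0)], seed=1)


@pytest.fixture(scope="session")
def small_cage():
    """Small sealed cage for integrator statistics (cheap per step)."""
    return build_cage_system(cage_radius=6.0, n_shell_beads=45,
                             channels=[], seed=2)


@pytest.fixture(scope="session")
def free_ligand_spec():
    """A single free ligand bead: no receptor, no binding well."""
    return ToySystemSpec(
        roles=["ligand"], positions=np.zeros((1, 3)),
        vdw_radii=np.array([2.0]), masses=np.array([118.0]),
        bonds=[], dihedrals=[], anchors=[], exclusions=[],
        channels=[], gates=[], binding_well=(np.zeros(3), 0.0, 1.5),
        cage_radius=12.0)


@pytest.fixture(scope="session")
def well_only_spec():
    """Single ligand bead in a Gaussian binding well (no receptor)."""
    return ToySystemSpec(
        roles=["ligand"], positions=np.zeros((1, 3)),
        vdw_radii=np.array([2.0]), masses=np.array([118.0]),
        bonds=[], dihedrals=[], anchors=[], exclusions=[],
        channels=[], gates=[], binding_well=(np.zeros(3), 3.0, 1.5),
        cage_radius=12.0)
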