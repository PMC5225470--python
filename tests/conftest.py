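"""Shared fixtures: synthetic assemblies and their network models.

Everything is generated programmatically at test time; the expensive
480-node default tetramer and its spectrum are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from perturbnet import (Structure, TetramerSpec, build_network_model,
                        generate_c4_tetramer, pocket_centroid,
                        tetramer_pocket_force)
from perturbnet.structure import Residue
from perturbnet.synthetic import _helix_points, _rotation_z

SMALL_SPEC = TetramerSpec(
    n_residues_per_chain=50,
    helix_segments=((1, 22, 1.5), (29, 50, -1.5)),
    pocket_residues=(10, 12, 16, 30, 35, 40),
    seed=3,
)

KEYSTONE_POCKET = (3, 5, 7, 9, 11, 13)


def make_keystone_tetramer() -> Structure:
    """Hand-built C4 tetramer whose four upper arms are cross-braced by a
    single inter-subunit contact class (the "keystone").

    Each chain: a bottom helix (residues 1-14, the pocket region), a
    linker helix (15-26) and a short raised arm (27-34).  The arm radius
    and phase are chosen so each arm touches the next subunit's arm
    through exactly one residue pair; all other bracing is redundant.
    """
    bottom = _helix_points(14, np.array([7.0, 0.0]), 0.0, 1.5, phase=np.pi)
    ax2 = 9.5 * np.array([np.cos(np.deg2rad(22.5)), np.sin(np.deg2rad(22.5))])
    linker = _helix_points(12, ax2, bottom[-1, 2] + 1.0, 1.5, phase=np.pi / 2)
    ax3 = 9.6 * np.array([np.cos(np.deg2rad(42.0)), np.sin(np.deg2rad(42.0))])
    arm = _helix_points(8, ax3, linker[-1, 2] + 4.0, 1.5, phase=np.pi / 2)
    chain_a = np.vstack([bottom, linker, arm])
    coords = np.vstack([chain_a @ _rotation_z(k * np.pi / 2).T for k in range(4)])
    n = chain_a.shape[0]
    return Structure(
        Residue(cid, r + 1, "ALA", tuple(map(float, coords[ci * n + r])))
        for ci, cid in enumerate("ABCD")
        for r in range(n)
    )


@pytest.fixture(scope="session")
def small_tetramer() -> Structure:
    """200-node exact-C4 tetramer (50 residues/chain)."""
    return generate_c4_tetramer(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_model(small_tetramer):
    """(network, spectrum, covariance) for the 200-node tetramer."""
    return build_network_model(small_tetramer)


@pytest.fixture(scope="session")
def small_force(small_tetramer):
    return tetramer_pocket_force(small_tetramer, SMALL_SPEC.pocket_residues,
                                 pocket_centroid)


@pytest.fixture(scope="session")
def default_tetramer() -> Structure:
    """The 480-node default study tetramer (120 residues/chain, seed 1)."""
    return generate_c4_tetramer(TetramerSpec())


@pytest.fixture(scope="session")
def default_model(default_tetramer):
    return build_network_model(default_tetramer)


@pytest.fixture(scope="session")
def keystone_tetramer() -> Structure:
    return make_keystone_tetramer()


@pytest.fixture(scope="session")
def keystone_model(keystone_tetramer):
    return build_network_model(keystone_tetramer)
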