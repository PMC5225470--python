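"""Linear response theory perturbations of the elastic network.

LRT maps an applied force to the expected coordinate shift through the
equilibrium covariance of the unperturbed network:

    delta_r = beta * C * F

with C the Moore-Penrose pseudoinverse of the ANM Hessian, beta a
scalar force constant and F a 3N vector holding a unit force direction
on each perturbed residue and zeros elsewhere.  Two perturbations are
provided: a ligand-pocket force (directions from a ligand centre toward
each pocket Cα, mimicking pocket opening on (un)binding) and a
voltage-mimicking force (membrane-normal push on formally charged
residues).  Per-residue force vectors are normalised to equal length,
so all responses are shape-only, in arbitrary units; only ratios of
displacements are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enm import Covariance
from .structure import Structure

logger = logging.getLogger("perturbnet")


@dataclass
class ForceVector:
    F: np.ndarray       # (3N,), unit 3-vectors on target residues, 0 elsewhere
    beta: float         # force constant (arbitrary units); sign encodes push/pull
    description: str = ""
    normalized: bool = False  # set by the force constructors; enforces equal norms

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float).ravel()
        if self.beta == 0:
            raise ValueError("beta must be nonzero")
        if self.normalized:
            norms = np.linalg.norm(self.F.reshape(-1, 3), axis=1)
            nz = norms[norms > 1e-12]
            if nz.size and not np.allclose(nz, nz[0], atol=1e-9):
                raise ValueError("per-residue force norms must be equal")

    @property
    def target_nodes(self) -> np.ndarray:
        return np.nonzero(np.linalg.norm(self.F.reshape(-1, 3), axis=1) > 1e-12)[0]


@dataclass
class Response:
    delta_r: np.ndarray     # (3N,), arbitrary units
    magnitudes: np.ndarray  # (N,)
    force: ForceVector
    network_hash: str = ""


# ---------------------------------------------------------------------------
# force construction
# ---------------------------------------------------------------------------

def binding_pocket_force(structure: Structure, pocket, ligand_center,
                         beta: float = 1.0) -> ForceVector:
    """Equal-magnitude forces opening a ligand pocket.

    ``pocket`` lists (chain_id, residue_index) pairs; each listed
    residue receives the unit vector pointing from ``ligand_center``
    toward its Cα (beta > 0 pushes the pocket open, i.e. mimics ligand
    release / insertion pressure; flip beta's sign for the reverse).
    For a tetramer, call once per chain with that chain's ligand centre
    and sum the results with :func:`combine_forces`.
    """
    center = np.asarray(ligand_center, dtype=float).ravel()
    if center.shape != (3,):
        raise ValueError("ligand_center must be a 3-vector")
    if not pocket:
        raise ValueError("pocket must not be empty")
    F = np.zeros(3 * structure.n_nodes)
    for chain_id, res in pocket:
        i = structure.node_index(chain_id, res)
        d = structure.coords[i] - center
        nrm = np.linalg.norm(d)
        if nrm < 1e-9:
            raise ValueError(
                f"ligand centre coincides with Cα of {chain_id}:{res}; "
                "force direction undefined"
            )
        F[3 * i : 3 * i + 3] = d / nrm
    return ForceVector(F, beta, description=f"pocket force on {len(pocket)} residues",
                       normalized=True)


def combine_forces(*forces: ForceVector, description: str = "") -> ForceVector:
    """Sum force vectors with disjoint residue supports (same beta)."""
    if not forces:
        raise ValueError("no forces given")
    betas = {f.beta for f in forces}
    if len(betas) != 1:
        raise ValueError("cannot combine forces with different beta")
    total = np.sum([f.F for f in forces], axis=0)
    return ForceVector(total, forces[0].beta,
                       description or "; ".join(f.description for f in forces),
                       normalized=all(f.normalized for f in forces))


def tetramer_pocket_force(structure: Structure, pocket_residues, centroid_fn,
                          beta: float = 1.0) -> ForceVector:
    """Pocket force applied symmetrically to all four subunits.

    ``centroid_fn(structure, chain, pocket_residues)`` supplies each
    subunit's ligand-centre (for synthetic tetramers, the generated
    pseudo-ligand point; for real structures, the bound-ligand centre).
    """
    structure.require_tetramer()
    parts = []
    for chain in structure.chains:
        center = centroid_fn(structure, chain, pocket_residues)
        parts.append(binding_pocket_force(
            structure, [(chain, r) for r in pocket_residues], center, beta))
    return combine_forces(*parts,
                          description=f"C4 pocket force on residues {tuple(pocket_residues)}")


def voltage_force(structure: Structure, beta: float = 1.0,
                  axis=(0.0, 0.0, 1.0)) -> ForceVector:
    """Membrane-field surrogate: push formal charges along the field axis.

    Each residue with nonzero formal charge gets sign(charge) times the
    unit ``axis`` vector; magnitude per residue is 1 regardless of
    |charge|, matching the equal-length convention of the pocket force.
    """
    axis = np.asarray(axis, dtype=float).ravel()
    nrm = np.linalg.norm(axis)
    if axis.shape != (3,) or nrm < 1e-12:
        raise ValueError("axis must be a nonzero 3-vector")
    axis = axis / nrm
    charged = np.nonzero(structure.charges)[0]
    if charged.size == 0:
        raise ValueError("structure has no charged residues")
    F = np.zeros(3 * structure.n_nodes)
    for i in charged:
        F[3 * i : 3 * i + 3] = np.sign(structure.charges[i]) * axis
    return ForceVector(F, beta, description=f"voltage force on {charged.size} charges",
                       normalized=True)


# ---------------------------------------------------------------------------
# response
# ---------------------------------------------------------------------------

def lrt_response(covariance: Covariance, force: ForceVector,
                 network_hash: str | None = None) -> Response:
    """delta_r = beta * C * F (arbitrary units)."""
    C = covariance.matrix
    if force.F.shape[0] != C.shape[0]:
        raise ValueError(
            f"force length {force.F.shape[0]} != covariance dimension {C.shape[0]}"
        )
    if network_hash is not None and covariance.network_hash and \
            network_hash != covariance.network_hash:
        raise ValueError("covariance was built from a different network")
    delta = force.beta * (C @ force.F)
    mags = np.linalg.norm(delta.reshape(-1, 3), axis=1)
    return Response(delta, mags, force, covariance.network_hash)


def displacement_profile(response: Response, structure: Structure,
                         chain: str | None = None) -> pd.DataFrame:
    """Per-residue displacement magnitudes (arbitrary units)."""
    if response.magnitudes.shape[0] != structure.n_nodes:
        raise ValueError("response does not match structure size")
    df = pd.DataFrame({
        "chain": structure.chain_ids,
        "residue": structure.residue_indices,
        "magnitude": response.magnitudes,
    })
    if chain is not None:
        df = df[df["chain"] == chain].reset_index(drop=True)
    return df
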