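"""Anisotropic network model: contact map, Hessian, spectrum, covariance.

The protein is a mass-and-spring network on the Cα nodes.  The harmonic
potential is

    V = 1/2 * sum_(i,j in contacts) gamma_ij * (r_ij - r_ij0)^2

with ``r_ij0`` the equilibrium (input-structure) distance.  Two spring
classes are used: backbone-consecutive pairs ("covalent",
82 RT/A^2) and all other pairs within the cutoff ("noncovalent",
3.166 RT/A^2, the Miyazawa-Jernigan average interaction strength).
Temperature enters only through the RT unit of gamma; downstream
responses are reported in arbitrary units.

The Hessian of V at equilibrium has the familiar ANM block form: for a
contact (i, j) with separation vector d and distance r the off-diagonal
3x3 block is -(gamma/r^2) d d^T and the diagonal blocks accumulate the
negated sum of each row's off-diagonal blocks.  A connected network has
exactly six zero eigenvalues (rigid translations and rotations); the
Moore-Penrose pseudoinverse over the non-null modes is the mechanical
covariance matrix used by linear response theory.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

logger = logging.getLogger("perturbnet")

GAMMA_COVALENT = 82.0      # RT/A^2, backbone peptide bond
GAMMA_NONCOVALENT = 3.166  # RT/A^2, Miyazawa-Jernigan average
DEFAULT_CUTOFF = 10.0      # Angstrom


@dataclass(frozen=True)
class Contact:
    i: int          # node index, i < j
    j: int
    gamma: float    # RT/A^2
    kind: str       # "covalent" | "noncovalent"


@dataclass
class ElasticNetwork:
    structure: Structure
    contacts: list[Contact]
    cutoff: float

    def __post_init__(self) -> None:
        seen = set()
        for c in self.contacts:
            if not (0 <= c.i < c.j < self.structure.n_nodes):
                raise ValueError(f"bad contact indices ({c.i}, {c.j})")
            if (c.i, c.j) in seen:
                raise ValueError(f"duplicate contact ({c.i}, {c.j})")
            if c.gamma <= 0:
                raise ValueError("spring constants must be positive")
            seen.add((c.i, c.j))

    @property
    def n_nodes(self) -> int:
        return self.structure.n_nodes

    def content_hash(self) -> str:
        """Hash of coordinates and contact list; keys spectrum caches."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.structure.coords).tobytes())
        for c in self.contacts:
            h.update(f"{c.i},{c.j},{c.gamma:.6g},{c.kind};".encode())
        return h.hexdigest()[:16]

    def without_contacts(self, pairs) -> "ElasticNetwork":
        """Copy of the network with the given (i, j) springs removed."""
        drop = {(min(i, j), max(i, j)) for i, j in pairs}
        missing = drop - {(c.i, c.j) for c in self.contacts}
        if missing:
            raise KeyError(f"contacts not in network: {sorted(missing)}")
        kept = [c for c in self.contacts if (c.i, c.j) not in drop]
        return ElasticNetwork(self.structure, kept, self.cutoff)

    def to_tsv(self, path) -> None:
        s = self.structure
        with open(path, "w") as fh:
            fh.write("i\tj\tchain_i\tres_i\tchain_j\tres_j\tdistance\tgamma\tkind\n")
            for c in self.contacts:
                d = float(np.linalg.norm(s.coords[c.i] - s.coords[c.j]))
                fh.write(
                    f"{c.i}\t{c.j}\t{s.chain_ids[c.i]}\t{s.residue_indices[c.i]}"
                    f"\t{s.chain_ids[c.j]}\t{s.residue_indices[c.j]}"
                    f"\t{d:.10g}\t{c.gamma:.10g}\t{c.kind}\n"
                )


@dataclass
class Spectrum:
    """Eigendecomposition of the ANM Hessian (ascending eigenvalues)."""

    eigenvalues: np.ndarray   # (3N,), ascending
    eigenvectors: np.ndarray  # (3N, 3N), column k pairs with eigenvalues[k]
    null_count: int
    network_hash: str = ""

    @property
    def nonnull_values(self) -> np.ndarray:
        return self.eigenvalues[self.null_count:]

    @property
    def nonnull_vectors(self) -> np.ndarray:
        return self.eigenvectors[:, self.null_count:]

    @property
    def null_vectors(self) -> np.ndarray:
        return self.eigenvectors[:, : self.null_count]


@dataclass
class Covariance:
    """Moore-Penrose pseudoinverse of the Hessian (mechanical covariance)."""

    matrix: np.ndarray
    spectrum: Spectrum
    network_hash: str = ""


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_contact_map(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
                      gamma_covalent: float = GAMMA_COVALENT,
                      gamma_noncovalent: float = GAMMA_NONCOVALENT) -> ElasticNetwork:
    """Build the two-class spring network.

    A pair is a contact iff its distance is strictly below ``cutoff``
    or the two residues are backbone-consecutive in the same chain
    (residue indices differing by 1).  Backbone pairs are covalent
    regardless of distance; cross-chain pairs are never covalent.
    """
    if structure.n_nodes < 2:
        raise ValueError("need at least two nodes")
    coords = structure.coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")

    def is_backbone(i: int, j: int) -> bool:
        return (
            structure.chain_ids[i] == structure.chain_ids[j]
            and abs(int(structure.residue_indices[i]) - int(structure.residue_indices[j])) == 1
        )

    contacts: dict[tuple[int, int], Contact] = {}
    for i, j in pairs:
        i, j = int(min(i, j)), int(max(i, j))
        if np.linalg.norm(coords[i] - coords[j]) >= cutoff:
            continue  # strict inequality at the boundary
        if is_backbone(i, j):
            contacts[(i, j)] = Contact(i, j, gamma_covalent, "covalent")
        else:
            contacts[(i, j)] = Contact(i, j, gamma_noncovalent, "noncovalent")
    # backbone pairs beyond the cutoff are still covalently bonded
    for k in range(structure.n_nodes - 1):
        i, j = k, k + 1
        if (i, j) not in contacts and is_backbone(i, j):
            contacts[(i, j)] = Contact(i, j, gamma_covalent, "covalent")
    ordered = [contacts[k] for k in sorted(contacts)]
    return ElasticNetwork(structure, ordered, cutoff)


def build_hessian(network: ElasticNetwork) -> np.ndarray:
    """Dense 3N x 3N ANM Hessian (second derivative of V at equilibrium)."""
    n = network.n_nodes
    coords = network.structure.coords
    hess = np.zeros((3 * n, 3 * n))
    for c in network.contacts:
        d = coords[c.i] - coords[c.j]
        r2 = float(d @ d)
        if r2 == 0.0:
            raise ValueError(f"coincident nodes in contact ({c.i}, {c.j})")
        block = (c.gamma / r2) * np.outer(d, d)
        si, sj = slice(3 * c.i, 3 * c.i + 3), slice(3 * c.j, 3 * c.j + 3)
        hess[si, sj] -= block
        hess[sj, si] -= block
        hess[si, si] += block
        hess[sj, sj] += block
    return hess


def network_energy(network: ElasticNetwork, coords: np.ndarray) -> float:
    """Potential V at arbitrary node coordinates (N, 3).

    Equilibrium distances come from the network's structure; used as the
    finite-difference oracle for the analytic Hessian.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    ref = network.structure.coords
    v = 0.0
    for c in network.contacts:
        r = np.linalg.norm(coords[c.i] - coords[c.j])
        r0 = np.linalg.norm(ref[c.i] - ref[c.j])
        v += 0.5 * c.gamma * (r - r0) ** 2
    return float(v)


# ---------------------------------------------------------------------------
# Spectrum and covariance
# ---------------------------------------------------------------------------

def diagonalize(hessian: np.ndarray, tolerance_rel: float = 1e-8,
                require_rigid: bool = True, network_hash: str = "") -> Spectrum:
    """Full eigendecomposition of the (symmetric) Hessian.

    An eigenvalue counts as null iff it is below ``tolerance_rel`` times
    the largest eigenvalue.  A single rigid connected body has exactly
    six null modes (3 translations + 3 rotations); any other count
    signals a disconnected or mechanically floppy network and raises
    unless ``require_rigid`` is disabled (used internally by the
    switch-off screen to detect disconnecting removals).
    """
    hessian = np.asarray(hessian, dtype=float)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ValueError("hessian must be square")
    if not np.allclose(hessian, hessian.T, atol=1e-10):
        raise ValueError("hessian must be symmetric")
    from scipy.linalg import eigh

    vals, vecs = eigh(hessian)
    lam_max = float(vals[-1])
    if lam_max <= 0:
        raise ValueError("hessian has no positive eigenvalues")
    null_count = int(np.sum(vals < tolerance_rel * lam_max))
    if require_rigid and null_count != 6:
        raise ValueError(
            f"network not a single rigid-connected body: {null_count} null modes"
        )
    return Spectrum(vals, vecs, null_count, network_hash)


def pseudoinverse(spectrum: Spectrum) -> Covariance:
    """Mechanical covariance C = sum_k (1/lambda_k) v_k v_k^T over non-null modes."""
    if spectrum.null_count != 6:
        raise ValueError(
            f"covariance requires 6 null modes, got {spectrum.null_count}"
        )
    v = spectrum.nonnull_vectors
    inv = 1.0 / spectrum.nonnull_values
    mat = (v * inv) @ v.T
    return Covariance(mat, spectrum, spectrum.network_hash)


def build_network_model(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
                        gamma_covalent: float = GAMMA_COVALENT,
                        gamma_noncovalent: float = GAMMA_NONCOVALENT,
                        ) -> tuple[ElasticNetwork, Spectrum, Covariance]:
    """Convenience: contact map -> Hessian -> spectrum -> covariance."""
    net = build_contact_map(structure, cutoff, gamma_covalent, gamma_noncovalent)
    h = net.content_hash()
    spec = diagonalize(build_hessian(net), network_hash=h)
    return net, spec, pseudoinverse(spec)
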