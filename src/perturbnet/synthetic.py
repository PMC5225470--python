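"""Synthetic C4-symmetric tetramers for testing the whole pipeline.

Real tetrameric channel structures are not always redistributable, so
the generator builds toy tetramers that have the geometric features the
analysis relies on: four equal chains related by exact 90-degree
rotations about a common (z) axis, ~3.8 A consecutive-Cα spacing,
enough compactness that the 10 A contact graph forms one rigid body,
a six-residue "binding pocket" per subunit surrounding an interior
pseudo-ligand point, and formal-charge annotations for voltage-style
perturbations.

One chain is laid out as vertical helical segments (ideal 100-degree
twist per residue, consecutive spacing 3.8 A) joined by circular-arc
loops, the set of segment axes fanned around the symmetry axis so that
neighbouring helices of the same and of adjacent subunits fall within
contact range.  Coordinate jitter (sigma = 0.05 A, seeded) is applied
to chain A *before* symmetrisation, so the C4 symmetry of the output is
exact to machine precision — which keeps the eigenstructure's
degenerate/non-degenerate split clean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .structure import DEFAULT_CHARGES, Residue, Structure

logger = logging.getLogger("perturbnet")

CA_SPACING = 3.8        # A, consecutive Cα distance
HELIX_TWIST = np.deg2rad(100.0)  # per-residue rotation of an ideal helix
JITTER_SIGMA = 0.05     # A, pre-symmetrisation coordinate noise

#: 20-residue repeating pseudo-sequence (identical across chains); includes
#: charged residue types so voltage-style forces have targets.
SEQUENCE_PATTERN = [
    "ALA", "LEU", "SER", "GLY", "VAL", "ARG", "THR", "GLU", "PHE", "LYS",
    "ILE", "ASP", "MET", "TYR", "ASN", "GLN", "TRP", "HIS", "PRO", "CYS",
]

DEFAULT_POCKET = (40, 42, 46, 58, 67, 108)


def default_segments(n_residues_per_chain: int) -> tuple:
    """Two-helix layout (up, loop, down) scaled to the chain length.

    For the default 120-residue chain this is ((1, 55, 1.5), (66, 120, -1.5));
    other lengths keep the same proportions.
    """
    n = n_residues_per_chain
    up_end = max(2, round(n * 55 / 120))
    down_start = min(n - 1, round(n * 66 / 120))
    if down_start <= up_end:
        raise ValueError(f"chain of {n} residues too short for the default layout")
    return ((1, up_end, 1.5), (down_start, n, -1.5))


@dataclass
class TetramerSpec:
    """Recipe for one synthetic tetramer.

    ``helix_segments`` are (start, end, pitch) triples in 1-based residue
    indices; pitch is the signed per-residue rise in A (sign = direction
    along z).  Residues between segments form connecting loops.
    """

    n_residues_per_chain: int = 120
    helix_segments: tuple = ((1, 55, 1.5), (66, 120, -1.5))
    radius: float = 12.0
    pocket_residues: tuple = DEFAULT_POCKET
    seed: int = 1
    charge_spec: dict | None = None

    def validate(self) -> None:
        n = self.n_residues_per_chain
        if n < 20:
            raise ValueError("need at least 20 residues per chain")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not self.pocket_residues:
            raise ValueError("pocket must not be empty")
        for p in self.pocket_residues:
            if not 1 <= p <= n:
                raise ValueError(f"pocket residue {p} outside chain 1..{n}")
        segs = sorted(self.helix_segments)
        if not segs or segs[0][0] != 1 or segs[-1][1] != n:
            raise ValueError("helix segments must start at 1 and end at the chain end")
        prev_end = 0
        for a, b, pitch in segs:
            if a <= prev_end or b < a or abs(pitch) >= CA_SPACING:
                raise ValueError(f"bad helix segment ({a}, {b}, {pitch})")
            prev_end = b


# ---------------------------------------------------------------------------
# chain geometry
# ---------------------------------------------------------------------------

def _helix_points(n: int, axis_xy: np.ndarray, z0: float, pitch: float,
                  phase: float) -> np.ndarray:
    """Ideal helix: local radius set so consecutive spacing is CA_SPACING."""
    a = np.sqrt(CA_SPACING**2 - pitch**2) / (2.0 * np.sin(HELIX_TWIST / 2.0))
    t = np.arange(n)
    ang = phase + t * HELIX_TWIST
    pts = np.empty((n, 3))
    pts[:, 0] = axis_xy[0] + a * np.cos(ang)
    pts[:, 1] = axis_xy[1] + a * np.sin(ang)
    pts[:, 2] = z0 + t * pitch
    return pts


def _arc_points(p_from: np.ndarray, p_to: np.ndarray, n_pts: int) -> np.ndarray:
    """Circular-arc loop of ``n_pts`` interior residues joining two anchors.

    The arc length is (n_pts + 1) * CA_SPACING, bulging away from the
    chord in the vertical-most direction, so consecutive spacing stays
    near CA_SPACING and the loop rises over the helix tops.
    """
    chord = p_to - p_from
    c = float(np.linalg.norm(chord))
    if c < 1e-9:
        raise ValueError("loop anchors coincide")
    length = (n_pts + 1) * CA_SPACING
    if length <= c:  # anchors too far apart; fall back to straight spacing
        t = np.linspace(0, 1, n_pts + 2)[1:-1]
        return p_from + np.outer(t, chord)
    # half-angle psi of the arc: L/c = psi / sin(psi)
    ratio = length / c
    psi = brentq(lambda x: x / np.sin(x) - ratio, 1e-9, np.pi - 1e-9)
    rho = c / (2.0 * np.sin(psi))
    u = chord / c
    w = np.array([0.0, 0.0, 1.0]) - u[2] * u
    if np.linalg.norm(w) < 1e-6:  # vertical chord: bulge radially outward
        mid = 0.5 * (p_from + p_to)
        w = np.array([mid[0], mid[1], 0.0])
        if np.linalg.norm(w) < 1e-6:
            w = np.array([1.0, 0.0, 0.0])
    w /= np.linalg.norm(w)
    mid = 0.5 * (p_from + p_to)
    center = mid - w * rho * np.cos(psi)
    phi = -psi + 2.0 * psi * (np.arange(1, n_pts + 1) / (n_pts + 1))
    return center + rho * (np.outer(np.sin(phi), u) + np.outer(np.cos(phi), w))


def _build_chain(spec: TetramerSpec) -> np.ndarray:
    """Chain A backbone path before jitter and symmetrisation."""
    segs = sorted(spec.helix_segments)
    n_seg = len(segs)
    # fan the helix axes so all 4*n_seg helices of the tetramer are evenly
    # spaced around the symmetry axis
    sector = 2.0 * np.pi / (4 * n_seg)
    angles = (np.arange(n_seg) - (n_seg - 1) / 2.0) * sector
    pts = np.full((spec.n_residues_per_chain, 3), np.nan)
    z = 0.0
    prev_end_idx = None
    for k, (a, b, pitch) in enumerate(segs):
        axis_xy = spec.radius * np.array([np.cos(angles[k]), np.sin(angles[k])])
        if pitch < 0 and k > 0:
            z = pts[prev_end_idx, 2]  # descend from the previous height
        helix = _helix_points(b - a + 1, axis_xy, z, pitch, phase=np.pi + angles[k])
        pts[a - 1 : b] = helix
        if prev_end_idx is not None and a - prev_end_idx - 2 >= 0:
            n_loop = a - prev_end_idx - 2
            if n_loop > 0:
                pts[prev_end_idx + 1 : a - 1] = _arc_points(
                    pts[prev_end_idx], pts[a - 1], n_loop
                )
        prev_end_idx = b - 1
        z = pts[b - 1, 2]
    if np.any(np.isnan(pts)):
        raise RuntimeError("chain layout left unplaced residues")
    return pts


def _rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _contact_graph_connected(coords: np.ndarray, chain_len: int,
                             cutoff: float = 10.0) -> bool:
    from scipy.spatial import cKDTree

    n = coords.shape[0]
    pairs = cKDTree(coords).query_pairs(r=cutoff, output_type="ndarray")
    rows = list(pairs[:, 0])
    cols = list(pairs[:, 1])
    for i in range(n - 1):  # backbone always bonded within a chain
        if (i + 1) % chain_len != 0:
            rows.append(i)
            cols.append(i + 1)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_c4_tetramer(spec: TetramerSpec | None = None) -> Structure:
    """Build a jittered, exactly C4-symmetric four-chain Structure.

    Jitter is applied to chain A only; chains B, C, D are exact 90, 180
    and 270 degree rotations about z, so symmetry holds to machine
    precision.  If the 10 A contact graph of the result is not
    connected the tetramer is regenerated at a tighter ring radius
    (up to 5 attempts) before giving up.
    """
    spec = spec or TetramerSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    radius = spec.radius
    for attempt in range(5):
        trial = TetramerSpec(spec.n_residues_per_chain, spec.helix_segments,
                             radius, spec.pocket_residues, spec.seed,
                             spec.charge_spec)
        chain_a = _build_chain(trial)
        chain_a = chain_a + rng.normal(0.0, JITTER_SIGMA, chain_a.shape)
        blocks = [chain_a @ _rotation_z(k * np.pi / 2.0).T for k in range(4)]
        coords = np.vstack(blocks)
        if _contact_graph_connected(coords, spec.n_residues_per_chain):
            break
        logger.warning(
            "contact graph disconnected at radius %.2f A; retrying tighter", radius
        )
        radius *= 0.85
    else:
        raise RuntimeError("could not build a connected tetramer in 5 attempts")

    n = spec.n_residues_per_chain
    residues = []
    for ci, chain_id in enumerate("ABCD"):
        for r in range(1, n + 1):
            name = SEQUENCE_PATTERN[(r - 1) % len(SEQUENCE_PATTERN)]
            if spec.charge_spec is not None:
                charge = int(spec.charge_spec.get(r, 0))
            else:
                charge = DEFAULT_CHARGES.get(name, 0)
            xyz = coords[ci * n + r - 1]
            residues.append(
                Residue(chain_id, r, name, (float(xyz[0]), float(xyz[1]), float(xyz[2])),
                        charge)
            )
    return Structure(residues)


def pocket_centroid(structure: Structure, chain: str, pocket_residues) -> np.ndarray:
    """Pseudo-ligand position for one subunit's pocket.

    The arithmetic mean of the pocket Cα positions, displaced 2 A toward
    the C4 (z) axis so the point is interior to the assembly and never
    coincides with a Cα.  Stands in for the geometric centre of a bound
    ligand's heavy atoms, which does not exist at Cα resolution.
    """
    if not len(list(pocket_residues)):
        raise ValueError("pocket must contain at least one residue")
    idx = [structure.node_index(chain, r) for r in pocket_residues]
    center = structure.coords[idx].mean(axis=0)
    radial = np.array([center[0], center[1], 0.0])
    nrm = np.linalg.norm(radial)
    if nrm > 1e-9:
        center = center - 2.0 * radial / nrm
    return center


def write_pockets_tsv(structure: Structure, pocket_residues, path) -> None:
    """Per-chain pocket table with the pseudo-ligand centroid coordinates."""
    with open(path, "w") as fh:
        fh.write("chain\tresidues\tcx\tcy\tcz\n")
        for chain in structure.chains:
            c = pocket_centroid(structure, chain, pocket_residues)
            res = ",".join(str(r) for r in pocket_residues)
            fh.write(f"{chain}\t{res}\t{c[0]:.10g}\t{c[1]:.10g}\t{c[2]:.10g}\n")
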