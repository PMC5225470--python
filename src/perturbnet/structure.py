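"""Cα-level structure container and I/O.

A protein is represented at one node per residue, placed at the Cα
position.  Nodes are ordered by chain (in order of first appearance),
then by residue index; node ``i`` owns rows ``3i..3i+2`` of every 3N
vector used downstream (Hessian, eigenvectors, forces, displacements).
Residue numbering from the input PDB is preserved for reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("perturbnet")

#: formal charges at neutral pH, overridable per structure
DEFAULT_CHARGES = {"ARG": 1, "LYS": 1, "ASP": -1, "GLU": -1}


@dataclass(frozen=True)
class Residue:
    """One Cα node: identity, position and optional formal charge."""

    chain_id: str
    residue_index: int
    residue_name: str
    coord: tuple[float, float, float]
    charge: int = 0


class Structure:
    """Ordered collection of Cα nodes.

    Parameters
    ----------
    residues
        Iterable of :class:`Residue`. Stored sorted by chain (order of
        first appearance) then residue index; sorting is idempotent.
    """

    def __init__(self, residues: Iterable[Residue]):
        residues = list(residues)
        if not residues:
            raise ValueError("structure must contain at least one residue")
        chain_order: dict[str, int] = {}
        for r in residues:
            chain_order.setdefault(r.chain_id, len(chain_order))
        residues.sort(key=lambda r: (chain_order[r.chain_id], r.residue_index))
        seen: set[tuple[str, int]] = set()
        for r in residues:
            key = (r.chain_id, r.residue_index)
            if key in seen:
                raise ValueError(f"duplicate residue {r.chain_id}:{r.residue_index}")
            seen.add(key)
        self.residues: list[Residue] = residues
        self.coords = np.array([r.coord for r in residues], dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.chain_ids = [r.chain_id for r in residues]
        self.residue_indices = np.array([r.residue_index for r in residues], dtype=int)
        self.residue_names = [r.residue_name for r in residues]
        self.charges = np.array([r.charge for r in residues], dtype=int)
        self._index = {(r.chain_id, r.residue_index): i for i, r in enumerate(residues)}

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        """Chain ids in node order (each once)."""
        out: list[str] = []
        for c in self.chain_ids:
            if c not in out:
                out.append(c)
        return out

    def node_index(self, chain_id: str, residue_index: int) -> int:
        try:
            return self._index[(chain_id, residue_index)]
        except KeyError:
            raise KeyError(f"no residue {chain_id}:{residue_index}") from None

    def chain_slice(self, chain_id: str) -> slice:
        """Contiguous node range of one chain."""
        idx = [i for i, c in enumerate(self.chain_ids) if c == chain_id]
        if not idx:
            raise KeyError(f"no chain {chain_id}")
        return slice(idx[0], idx[-1] + 1)

    def chain_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.chain_ids:
            out[c] = out.get(c, 0) + 1
        return out

    def require_tetramer(self) -> None:
        """Assert 4 equal-length chains with identical residue-name sequences.

        Sequence identity (not coordinate identity) is the criterion:
        symmetric assemblies built by homology have identical sequences
        but generally asymmetric coordinates.
        """
        chains = self.chains
        if len(chains) != 4:
            raise ValueError(f"expected 4 chains, found {len(chains)}")
        seqs = []
        for c in chains:
            s = self.chain_slice(c)
            seqs.append(self.residue_names[s])
            if s.stop - s.start != len(self.residues) // 4:
                raise ValueError("chains have unequal lengths")
        for s in seqs[1:]:
            if s != seqs[0]:
                raise ValueError("chain residue-name sequences differ")

    def with_charges(self, charge_map: dict[str, int] | None = None) -> "Structure":
        """Return a copy with formal charges assigned by residue name."""
        cmap = DEFAULT_CHARGES if charge_map is None else charge_map
        return Structure(
            Residue(r.chain_id, r.residue_index, r.residue_name, r.coord,
                    cmap.get(r.residue_name, 0))
            for r in self.residues
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return (
            self.chain_ids == other.chain_ids
            and np.array_equal(self.residue_indices, other.residue_indices)
            and self.residue_names == other.residue_names
            and np.allclose(self.coords, other.coords, atol=5e-4)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Structure({self.n_nodes} residues, chains {self.chains})"


# ---------------------------------------------------------------------------
# PDB reading (Cα subset, MODEL 1, first ALTLOC, insertion codes rejected)
# ---------------------------------------------------------------------------

def read_pdb_calpha(path) -> Structure:
    """Read a PDB file into a Cα-only :class:`Structure`.

    Only MODEL 1 is used (a warning is logged if more models exist);
    for alternate locations the first ALTLOC encountered is kept;
    residues with insertion codes are rejected; HETATM records are
    ignored.  A standard residue without a CA atom is an error.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        struct = parser.get_structure("s", str(path))
    models = list(struct)
    if not models:
        raise ValueError(f"no models in {path}")
    if len(models) > 1:
        logger.warning("PDB %s has %d models; using MODEL 1 only", path, len(models))
    model = models[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag.strip():
                continue  # HETATM (waters, ligands) not part of the Cα network
            if icode.strip():
                raise ValueError(
                    f"insertion code {icode!r} at {chain.id}:{resseq} not supported"
                )
            if "CA" not in res:
                raise ValueError(
                    f"residue {chain.id}:{resseq} ({res.get_resname()}) lacks a CA atom"
                )
            ca = res["CA"]
            if ca.is_disordered():
                ca = ca.disordered_get_list()[0]  # keep first ALTLOC
            x, y, z = (float(v) for v in ca.get_coord())
            residues.append(Residue(chain.id, int(resseq), res.get_resname(), (x, y, z)))
    if not residues:
        raise ValueError(f"no parseable CA residues in {path}")
    return Structure(residues)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def write_pdb(structure: Structure, path, bfactors: Sequence[float] | None = None,
              charge_sidecar=None) -> None:
    """Write CA-only ATOM records.

    ``bfactors`` (per residue) are scaled to [0, 99.99] so per-residue
    displacement magnitudes can be colour-mapped in standard viewers.
    The PDB ATOM record has no formal-charge field at this precision;
    if any node carries a charge and ``charge_sidecar`` is given, the
    charges are preserved in a TSV sidecar.
    """
    if bfactors is not None:
        b = np.asarray(bfactors, dtype=float)
        if b.shape != (structure.n_nodes,):
            raise ValueError("bfactors length mismatch")
        peak = np.max(np.abs(b))
        b = np.zeros_like(b) if peak == 0 else np.abs(b) / peak * 99.99
    else:
        b = np.zeros(structure.n_nodes)

    lines = []
    serial = 0
    prev_chain = None
    for i, r in enumerate(structure.residues):
        if prev_chain is not None and r.chain_id != prev_chain:
            serial += 1
            lines.append(f"TER   {serial:5d}")
        serial += 1
        x, y, z = structure.coords[i]
        lines.append(
            f"ATOM  {serial:5d}  CA  {r.residue_name:<3s} {r.chain_id:1s}"
            f"{r.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b[i]:6.2f}"
            f"           C  "
        )
        prev_chain = r.chain_id
    serial += 1
    lines.append(f"TER   {serial:5d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    if charge_sidecar is not None and np.any(structure.charges != 0):
        with open(charge_sidecar, "w") as fh:
            fh.write("chain\tresidue\tcharge\n")
            for r in structure.residues:
                if r.charge:
                    fh.write(f"{r.chain_id}\t{r.residue_index}\t{r.charge}\n")


# ---------------------------------------------------------------------------
# Displacement / mode field export
# ---------------------------------------------------------------------------

def write_displacement_field(structure: Structure, vector, path,
                             format: str = "nmd", name: str = "field") -> None:
    """Export a 3N vector as arrows on the structure.

    ``nmd`` writes the normal-mode exchange format understood by common
    mode viewers (a ``coordinates`` line plus one ``mode`` line);
    ``tsv`` writes one row per residue with the 3-vector and its norm.
    """
    vec = np.asarray(vector, dtype=float).ravel()
    if vec.shape != (3 * structure.n_nodes,):
        raise ValueError(
            f"vector length {vec.shape[0]} != 3N = {3 * structure.n_nodes}"
        )
    if format == "nmd":
        with open(path, "w") as fh:
            fh.write("nmd\n")
            fh.write(f"name {name}\n")
            fh.write("resnames " + " ".join(structure.residue_names) + "\n")
            fh.write("chids " + " ".join(structure.chain_ids) + "\n")
            fh.write("resids " + " ".join(str(i) for i in structure.residue_indices) + "\n")
            fh.write("coordinates " + " ".join(f"{v:.3f}" for v in structure.coords.ravel()) + "\n")
            fh.write("mode 1 " + " ".join(f"{v:.10g}" for v in vec) + "\n")
    elif format == "tsv":
        arrows = vec.reshape(-1, 3)
        mags = np.linalg.norm(arrows, axis=1)
        with open(path, "w") as fh:
            fh.write("chain\tresidue\tdx\tdy\tdz\tmagnitude\n")
            for i, r in enumerate(structure.residues):
                dx, dy, dz = arrows[i]
                fh.write(
                    f"{r.chain_id}\t{r.residue_index}\t{dx:.10g}\t{dy:.10g}"
                    f"\t{dz:.10g}\t{mags[i]:.10g}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}")
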