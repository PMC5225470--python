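"""Contact switch-off screening.

The screen asks which individual residue-residue contacts matter for
the allosteric response: each noncovalent contact is switched off (its
spring constant set to zero), the LRT response is recomputed, and the
change in the per-residue displacement profile is measured.  To respect
the four-fold symmetry of the assembly, the four symmetry-related
copies of a contact are always removed together, so the unit of the
screen is a *contact class* (the orbit of one contact under the chain
permutation A->B->C->D->A).

Because LRT magnitudes carry arbitrary units, both the baseline and the
perturbed magnitude profiles are divided by the baseline's maximum
before comparison; a change threshold of 0.1 therefore means "10% of
the peak baseline displacement".  A class is significant when at least
``min_residues`` residues of *every* subunit change by more than the
threshold.

Removing m springs is a rank-m downdate of the Hessian,
H' = H - B B^T with B holding one scaled bond-direction column per
removed spring, so the perturbed response is obtained from the baseline
covariance by a Woodbury update:

    C' F = C F + C B (I_m - B^T C B)^{-1} B^T C F

which is exact whenever the removal leaves the network rigid; a
singular (I_m - B^T C B) signals that the removal disconnects the
network, in which case the class is flagged and not scored.  The slow
path (full rebuild and rediagonalisation) is retained for verification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enm import (Covariance, ElasticNetwork, build_hessian, diagonalize,
                  pseudoinverse)
from .lrt import ForceVector, Response, lrt_response
from .structure import Structure

logger = logging.getLogger("perturbnet")

DELTA_THRESHOLD = 0.1   # fraction of the peak baseline displacement
MIN_RESIDUES = 15       # per subunit
_SINGULAR_TOL = 1e-9    # Woodbury update matrix rank tolerance


@dataclass
class ContactClass:
    representative: tuple  # ((chain, res_i), (chain, res_j)), lexicographically least
    members: list          # [(i, j), ...] node-index pairs present in the network
    kind: str              # "intra-subunit" | "inter-subunit"

    @property
    def label(self) -> str:
        (c1, r1), (c2, r2) = self.representative
        return f"{c1}:{r1}-{c2}:{r2}"


@dataclass
class SwitchOffResult:
    response: Response | None
    disconnecting: bool


@dataclass
class SwitchOffRecord:
    contact_class: ContactClass
    delta_mags: np.ndarray | None   # per-residue |change| on the baseline-max scale
    subunit_counts: dict | None     # chain -> residues with |change| > threshold
    significant: bool
    disconnecting: bool = False

    @property
    def min_count(self) -> int:
        if self.subunit_counts is None:
            return -1
        return min(self.subunit_counts.values())


# ---------------------------------------------------------------------------
# symmetry classes
# ---------------------------------------------------------------------------

def enumerate_contact_classes(network: ElasticNetwork,
                              structure: Structure) -> list[ContactClass]:
    """Group noncovalent contacts into orbits of the C4 chain permutation.

    Covalent (backbone) springs are excluded: removing them models chain
    scission, not contact loss.  Each noncovalent contact lands in
    exactly one class; a class normally has four members (two for
    diagonal A-C/B-D contacts, whose orbit closes after two steps).  A
    missing symmetry mate (possible on non-ideal input) is logged and
    skipped.
    """
    structure.require_tetramer()
    chains = structure.chains
    succ = {chains[k]: chains[(k + 1) % 4] for k in range(4)}

    def image(node: int) -> int:
        return structure.node_index(succ[structure.chain_ids[node]],
                                    int(structure.residue_indices[node]))

    present = {(c.i, c.j) for c in network.contacts if c.kind == "noncovalent"}
    assigned: set[tuple[int, int]] = set()
    classes: list[ContactClass] = []
    for c in network.contacts:
        if c.kind != "noncovalent" or (c.i, c.j) in assigned:
            continue
        orbit: list[tuple[int, int]] = []
        i, j = c.i, c.j
        for _ in range(4):
            pair = (min(i, j), max(i, j))
            if pair not in orbit:
                orbit.append(pair)
            i, j = image(i), image(j)
        members = [p for p in orbit if p in present]
        for p in orbit:
            if p not in present:
                logger.warning("symmetry mate %s missing from contact map", p)
        assigned.update(members)

        def key(pair):
            a, b = pair
            return (structure.chain_ids[a], int(structure.residue_indices[a]),
                    structure.chain_ids[b], int(structure.residue_indices[b]))

        ia, ib = min(members, key=key)
        rep = ((structure.chain_ids[ia], int(structure.residue_indices[ia])),
               (structure.chain_ids[ib], int(structure.residue_indices[ib])))
        kind = ("intra-subunit"
                if structure.chain_ids[c.i] == structure.chain_ids[c.j]
                else "inter-subunit")
        classes.append(ContactClass(rep, members, kind))
    return classes


# ---------------------------------------------------------------------------
# perturbed responses
# ---------------------------------------------------------------------------

def _bond_columns(network: ElasticNetwork, members) -> tuple[np.ndarray, np.ndarray]:
    """B (3N x m) with H' = H - B B^T, plus the nonzero row indices."""
    coords = network.structure.coords
    gamma = {(c.i, c.j): c.gamma for c in network.contacts}
    n3 = 3 * network.n_nodes
    B = np.zeros((n3, len(members)))
    rows: set[int] = set()
    for col, (i, j) in enumerate(members):
        g = gamma[(min(i, j), max(i, j))]
        d = coords[i] - coords[j]
        u = np.sqrt(g) * d / np.linalg.norm(d)
        B[3 * i : 3 * i + 3, col] = u
        B[3 * j : 3 * j + 3, col] = -u
        rows.update(range(3 * i, 3 * i + 3))
        rows.update(range(3 * j, 3 * j + 3))
    return B, np.array(sorted(rows))


def switch_off_response(network: ElasticNetwork, clazz: ContactClass,
                        force: ForceVector, covariance: Covariance | None = None,
                        fast: bool = True) -> SwitchOffResult:
    """LRT response with one contact class removed.

    ``fast`` applies the Woodbury downdate to the baseline covariance
    (which must then be supplied); otherwise the perturbed network is
    rebuilt and rediagonalised from scratch.
    """
    if fast:
        if covariance is None:
            raise ValueError("fast path requires the baseline covariance")
        B, rows = _bond_columns(network, clazz.members)
        C = covariance.matrix
        CB = C[:, rows] @ B[rows, :]
        M = np.eye(len(clazz.members)) - B[rows, :].T @ CB[rows, :]
        eigs = np.linalg.eigvalsh(M)
        if eigs.min() < _SINGULAR_TOL:
            return SwitchOffResult(None, disconnecting=True)
        x = C @ force.F
        x_pert = force.beta * (x + CB @ np.linalg.solve(M, B[rows, :].T @ x[rows]))
        mags = np.linalg.norm(x_pert.reshape(-1, 3), axis=1)
        return SwitchOffResult(
            Response(x_pert, mags, force, covariance.network_hash), False)
    pert_net = network.without_contacts(clazz.members)
    hess = build_hessian(pert_net)
    spec = diagonalize(hess, require_rigid=False, network_hash=pert_net.content_hash())
    if spec.null_count != 6:
        return SwitchOffResult(None, disconnecting=True)
    return SwitchOffResult(lrt_response(pseudoinverse(spec), force), False)


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

def screen_contacts(network: ElasticNetwork, structure: Structure,
                    force: ForceVector, delta_threshold: float = DELTA_THRESHOLD,
                    min_residues: int = MIN_RESIDUES,
                    covariance: Covariance | None = None,
                    fast: bool = True) -> list[SwitchOffRecord]:
    """Switch off every contact class and rank by impact on the response.

    Records are sorted by the minimum per-subunit count of changed
    residues (descending), ties broken by the representative pair;
    disconnecting classes sort last and are never significant.
    """
    if covariance is None:
        spec = diagonalize(build_hessian(network),
                           network_hash=network.content_hash())
        covariance = pseudoinverse(spec)
    baseline = lrt_response(covariance, force)
    peak = float(baseline.magnitudes.max())
    if peak == 0.0:
        base_norm = baseline.magnitudes
        scale = 1.0
    else:
        base_norm = baseline.magnitudes / peak
        scale = peak

    classes = enumerate_contact_classes(network, structure)
    # partition check: every noncovalent contact in exactly one class
    covered: list = [p for cl in classes for p in cl.members]
    noncov = {(c.i, c.j) for c in network.contacts if c.kind == "noncovalent"}
    if len(covered) != len(set(covered)) or set(covered) != noncov:
        raise AssertionError("contact classes do not partition the noncovalent contacts")

    chain_nodes = {c: np.array([i for i, ch in enumerate(structure.chain_ids) if ch == c])
                   for c in structure.chains}
    records: list[SwitchOffRecord] = []
    for cl in classes:
        result = switch_off_response(network, cl, force, covariance, fast=fast)
        if result.disconnecting:
            logger.warning("switch-off of %s disconnects the network", cl.label)
            records.append(SwitchOffRecord(cl, None, None, False, disconnecting=True))
            continue
        delta = np.abs(result.response.magnitudes / scale - base_norm) \
            if peak else np.abs(result.response.magnitudes - base_norm)
        counts = {c: int(np.sum(delta[idx] > delta_threshold))
                  for c, idx in chain_nodes.items()}
        significant = min(counts.values()) >= min_residues
        records.append(SwitchOffRecord(cl, delta, counts, significant))

    def sort_key(rec: SwitchOffRecord):
        (c1, r1), (c2, r2) = rec.contact_class.representative
        return (-rec.min_count, c1, r1, c2, r2)

    records.sort(key=sort_key)
    return records


def screen_to_frame(records: list[SwitchOffRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "contact": rec.contact_class.label,
            "kind": rec.contact_class.kind,
            "n_members": len(rec.contact_class.members),
            "disconnecting": rec.disconnecting,
            "significant": rec.significant,
            "min_count": rec.min_count if not rec.disconnecting else np.nan,
        }
        if rec.subunit_counts:
            for c, v in rec.subunit_counts.items():
                row[f"count_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
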