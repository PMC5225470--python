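"""Symmetric contact switch-off: classes, fast updates, screening."""

import numpy as np
import pytest

from perturbnet import (ForceVector, build_contact_map, build_hessian,
                        diagonalize, enumerate_contact_classes, lrt_response,
                        pocket_centroid, pseudoinverse, screen_contacts,
                        switch_off_response, tetramer_pocket_force)
from perturbnet.structure import Residue, Structure
from perturbnet.switchoff import ContactClass

from conftest import KEYSTONE_POCKET, SMALL_SPEC


def square_tetramer(extra=()):
    """Minimal 4x2 tetramer: two residues per chain at the corners of a
    square prism; contact classes are enumerable by hand."""
    residues = []
    for k, cid in enumerate("ABCD"):
        ang = k * np.pi / 2
        x, y = 6.0 * np.cos(ang), 6.0 * np.sin(ang)
        residues.append(Residue(cid, 1, "ALA", (x, y, 0.0)))
        residues.append(Residue(cid, 2, "ALA", (x, y, 3.8)))
    return Structure(residues)


class TestClassEnumeration:
    def test_intra_subunit_orbit_spans_all_chains(self, small_model, small_tetramer):
        net, _, _ = small_model
        classes = enumerate_contact_classes(net, small_tetramer)
        intra = next(c for c in classes if c.kind == "intra-subunit")
        chains = {small_tetramer.chain_ids[i] for i, j in intra.members}
        assert chains == {"A", "B", "C", "D"}
        assert len(intra.members) == 4

    def test_inter_subunit_orbit_cycles_chain_pairs(self, small_model,
                                                    small_tetramer):
        net, _, _ = small_model
        classes = enumerate_contact_classes(net, small_tetramer)
        inter = next(c for c in classes if c.kind == "inter-subunit"
                     and len(c.members) == 4)
        pairs = {frozenset((small_tetramer.chain_ids[i], small_tetramer.chain_ids[j]))
                 for i, j in inter.members}
        assert pairs == {frozenset("AB"), frozenset("BC"),
                         frozenset("CD"), frozenset("DA")}

    def test_classes_partition_noncovalent_contacts(self, small_model,
                                                    small_tetramer):
        net, _, _ = small_model
        classes = enumerate_contact_classes(net, small_tetramer)
        members = [p for c in classes for p in c.members]
        noncov = {(c.i, c.j) for c in net.contacts if c.kind == "noncovalent"}
        assert len(members) == len(set(members))
        assert set(members) == noncov

    def test_covalent_contacts_excluded(self, small_model, small_tetramer):
        net, _, _ = small_model
        classes = enumerate_contact_classes(net, small_tetramer)
        members = {p for c in classes for p in c.members}
        cov_pairs = {(c.i, c.j) for c in net.contacts if c.kind == "covalent"}
        assert not members & cov_pairs

    def test_hand_countable_orbits_on_square_prism(self):
        """8 noncovalent contacts in 2 symmetric orbits -> exactly 2 classes."""
        s = square_tetramer()
        net = build_contact_map(s, cutoff=9.0)
        noncov = [c for c in net.contacts if c.kind == "noncovalent"]
        assert len(noncov) == 8  # adjacent-corner pairs at both heights
        classes = enumerate_contact_classes(net, s)
        assert len(classes) == 2
        assert all(len(c.members) == 4 for c in classes)

    def test_non_tetramer_rejected(self):
        s = Structure([Residue("A", 1, "ALA", (0, 0, 0)),
                       Residue("A", 2, "ALA", (3.8, 0, 0))])
        net = build_contact_map(s)
        with pytest.raises(ValueError):
            enumerate_contact_classes(net, s)


class TestSwitchOffResponse:
    def test_switch_back_on_restores_baseline(self, small_model, small_force):
        net, spectrum, cov = small_model
        baseline = lrt_response(cov, small_force)
        classes = enumerate_contact_classes(net, net.structure)
        # removing and re-adding the springs is the identity on the network
        restored = net.without_contacts(classes[0].members)
        assert len(restored.contacts) == len(net.contacts) - len(classes[0].members)
        again = lrt_response(pseudoinverse(diagonalize(build_hessian(net))),
                             small_force)
        assert np.allclose(again.delta_r, baseline.delta_r, atol=1e-10)

    def test_fast_update_matches_full_rebuild(self, small_model, small_tetramer,
                                              small_force):
        """Woodbury-updated responses equal full recomputation to 1e-8 of the
        peak magnitude on the 200-node fixture."""
        net, _, cov = small_model
        classes = enumerate_contact_classes(net, small_tetramer)
        sample = classes[:: max(1, len(classes) // 10)][:10]
        for cl in sample:
            fast = switch_off_response(net, cl, small_force, cov, fast=True)
            slow = switch_off_response(net, cl, small_force, fast=False)
            assert not fast.disconnecting and not slow.disconnecting
            peak = np.abs(slow.response.delta_r).max()
            diff = np.abs(fast.response.delta_r - slow.response.delta_r).max()
            assert diff < 1e-8 * peak

    def test_disconnecting_removal_flagged_on_both_paths(self):
        """Removing one of two tether classes leaves a rigid crown cluster
        hanging on four springs -- fewer constraints than its six rigid-body
        degrees of freedom.  The resulting rank deficiency must be flagged,
        never silently scored.

        Per chain: residues 1-2 form a braced base prism; residue 10 (no
        covalent link to residue 2) sits in a fully cross-braced crown that
        is held to the base only by two symmetric tether classes.
        """
        residues = []
        for k, cid in enumerate("ABCD"):
            ang = k * np.pi / 2
            rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            crown = 3.5 * np.array([np.cos(np.pi / 4), np.sin(np.pi / 4)])
            for idx, (x, y, z) in [(1, (4.0, 0.0, 0.0)), (2, (4.0, 0.0, 3.8)),
                                   (10, (crown[0], crown[1], 8.5))]:
                xx, yy = rot @ np.array([x, y])
                residues.append(Residue(cid, idx, "ALA", (float(xx), float(yy), z)))
        s = Structure(residues)
        net = build_contact_map(s, cutoff=8.2)
        spectrum = diagonalize(build_hessian(net))
        assert spectrum.null_count == 6  # baseline is rigid
        cov = pseudoinverse(spectrum)
        classes = enumerate_contact_classes(net, s)
        tethers = [c for c in classes
                   if {s.residue_indices[c.members[0][0]],
                       s.residue_indices[c.members[0][1]]} == {2, 10}]
        assert len(tethers) == 2  # exactly two crown-to-base tether classes
        force = ForceVector(np.zeros(3 * s.n_nodes), 1.0)
        force.F[0] = 1.0
        for tether in tethers:
            fast = switch_off_response(net, tether, force, cov, fast=True)
            slow = switch_off_response(net, tether, force, fast=False)
            assert fast.disconnecting and slow.disconnecting
            assert fast.response is None and slow.response is None


class TestScreen:
    def test_zero_force_nothing_significant(self, small_model, small_tetramer):
        net, _, cov = small_model
        force = ForceVector(np.zeros(3 * small_tetramer.n_nodes), 1.0)
        records = screen_contacts(net, small_tetramer, force, covariance=cov)
        assert all(not r.significant for r in records)

    def test_infinite_threshold_nothing_significant(self, small_model,
                                                    small_tetramer, small_force):
        net, _, cov = small_model
        records = screen_contacts(net, small_tetramer, small_force,
                                  delta_threshold=np.inf, covariance=cov)
        assert all(not r.significant for r in records)

    def test_monotone_in_thresholds(self, small_model, small_tetramer,
                                    small_force):
        net, _, cov = small_model
        base = screen_contacts(net, small_tetramer, small_force,
                               delta_threshold=0.02, min_residues=2,
                               covariance=cov)
        sig_base = {r.contact_class.label for r in base if r.significant}
        stricter_delta = screen_contacts(net, small_tetramer, small_force,
                                         delta_threshold=0.05, min_residues=2,
                                         covariance=cov)
        stricter_count = screen_contacts(net, small_tetramer, small_force,
                                         delta_threshold=0.02, min_residues=6,
                                         covariance=cov)
        assert sig_base  # the relaxed screen finds something to compare against
        for screened in (stricter_delta, stricter_count):
            sig = {r.contact_class.label for r in screened if r.significant}
            assert sig <= sig_base

    def test_counts_equal_across_subunits_for_symmetric_problem(
            self, small_model, small_tetramer, small_force):
        net, _, cov = small_model
        records = screen_contacts(net, small_tetramer, small_force,
                                  covariance=cov)
        for r in records[:25]:
            if r.subunit_counts:
                assert len(set(r.subunit_counts.values())) == 1

    def test_keystone_class_ranked_first(self, keystone_tetramer, keystone_model):
        """The single engineered inter-subunit brace between the four upper
        arms dominates the response change and must rank first."""
        net, _, cov = keystone_model
        s = keystone_tetramer
        force = tetramer_pocket_force(s, KEYSTONE_POCKET, pocket_centroid)
        classes = enumerate_contact_classes(net, s)
        arm_classes = [c for c in classes if c.kind == "inter-subunit"
                       and any(s.residue_indices[i] >= 27 or s.residue_indices[j] >= 27
                               for i, j in c.members)]
        assert len(arm_classes) == 1  # the keystone is unique by construction
        records = screen_contacts(net, s, force, covariance=cov)
        assert records[0].contact_class.label == arm_classes[0].label
        assert records[0].min_count > records[1].min_count

    def test_min_residues_zero_everything_significant(self, keystone_model,
                                                      keystone_tetramer):
        net, _, cov = keystone_model
        force = tetramer_pocket_force(keystone_tetramer, KEYSTONE_POCKET,
                                      pocket_centroid)
        records = screen_contacts(net, keystone_tetramer, force, min_residues=0,
                                  covariance=cov)
        assert all(r.significant for r in records if not r.disconnecting)
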