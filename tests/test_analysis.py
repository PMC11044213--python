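"""Residue elimination, segment detection, layers and interfaces."""

import numpy as np
import pytest

from fodm import (
    FixtureSpec, HydroProfile, SelectionError, classify_layers,
    eliminate_to_threshold, excess_deficit_segments, interface_residues,
    interface_status, kl_divergence, make_fixture, rd, select,
    uniform_profile,
)
from fodm.metrics import compute_profiles
from conftest import random_profile


def _pair(n, rng, spread=0.3):
    """A (T, O) pair with mild discrepancy; RD typically below 0.5."""
    t = random_profile(n, rng, kind="T")
    noise = 1.0 + spread * (rng.random(n) - 0.5)
    o = HydroProfile("O", t.values * noise / (t.values * noise).sum(), True)
    return t, o


class TestElimination:
    def test_noop_when_rd_already_below_threshold(self, rng):
        t, o = _pair(30, rng, spread=0.05)
        assert rd(o, t, uniform_profile(30)) < 0.5
        res = eliminate_to_threshold(t, o)
        assert res.eliminated == () and res.converged

    def test_single_discrepancy_residue_removed(self):
        # one residue carries the whole O-T mismatch by construction
        t = HydroProfile("T", np.array([0.3, 0.25, 0.2, 0.15, 0.06, 0.04]), True)
        o_raw = t.values.copy()
        o_raw[4] = 0.6  # inflate one low-T residue far above expectation
        o = HydroProfile("O", o_raw / o_raw.sum(), True)
        assert rd(o, t, uniform_profile(6)) >= 0.5
        res = eliminate_to_threshold(t, o)
        assert res.converged
        assert res.eliminated_indices[0] == 4
        assert res.final_status.rd < 0.5

    def test_final_rd_self_consistent(self, rng):
        model, _ = make_fixture(FixtureSpec("perturbed_micelle", 80, seed=2))
        t, o, _ = compute_profiles(model, tuple(r.key for r in model.residues))
        res = eliminate_to_threshold(t, o)
        # recompute from scratch on the survivors
        surv = list(res.surviving_indices)
        rd_again = rd(o.subset(surv), t.subset(surv), uniform_profile(len(surv)))
        assert rd_again == pytest.approx(res.final_status.rd, abs=1e-12)
        assert res.converged and rd_again < 0.5

    def test_terminates_within_n_minus_3(self, rng):
        t = random_profile(25, rng, kind="T")
        o = random_profile(25, rng)
        res = eliminate_to_threshold(t, o)
        assert len(res.eliminated) <= 25 - 3
        assert res.converged or len(res.surviving_indices) == 3

    def test_perturbation_patch_removed_first(self):
        for seed in (1, 2, 3):
            model, bounds = make_fixture(
                FixtureSpec("perturbed_micelle", 120, seed=seed))
            t, o, _ = compute_profiles(model, tuple(r.key for r in model.residues))
            res = eliminate_to_threshold(t, o)
            patch = range(int(bounds["patch_start"]), int(bounds["patch_stop"]))
            assert res.eliminated_indices, "patch must break the micelle"
            assert res.eliminated_indices[0] in patch


class TestSegments:
    def test_no_segments_when_o_equals_t(self, rng):
        t = random_profile(40, rng, kind="T")
        o = HydroProfile("O", t.values.copy(), True)
        assert excess_deficit_segments(t, o) == []

    def test_constructed_excess_run_detected(self):
        n = 40
        tol = 1.0 / (4 * n)
        t = uniform_profile(n)
        t = HydroProfile("T", t.values, True)
        o_raw = t.values.copy()
        o_raw[10:21] += 3 * tol  # inflate residues 10..20 well past tolerance
        o = HydroProfile("O", o_raw / o_raw.sum(), True)
        segs = excess_deficit_segments(t, o, min_len=3)
        excess = [s for s in segs if s.label == "excess"]
        assert len(excess) == 1
        assert excess[0].indices[0] == 10 and excess[0].indices[-1] == 20

    def test_segments_disjoint_ordered_and_consistent(self, rng):
        t = random_profile(60, rng, kind="T")
        o = random_profile(60, rng)
        segs = excess_deficit_segments(t, o, min_len=2)
        tol = 1.0 / (4 * 60)
        flagged = {i for i in range(60) if abs(o.values[i] - t.values[i]) > tol}
        seen = []
        for seg in segs:
            assert list(seg.indices) == sorted(seg.indices)
            assert not (set(seg.indices) & set(seen))
            assert set(seg.indices) <= flagged
            seen.extend(seg.indices)
        assert seen == sorted(seen)

    def test_min_len_filters_short_runs(self, rng):
        n = 30
        t = uniform_profile(n)
        o_raw = t.values.copy()
        o_raw[5] *= 3  # single-residue spike
        o = HydroProfile("O", o_raw / o_raw.sum(), True)
        assert excess_deficit_segments(t, o, min_len=3) == []
        short = excess_deficit_segments(t, o, min_len=1)
        assert any(s.label == "excess" and 5 in s.indices for s in short)


class TestLayers:
    def test_gap_case_unlabeled(self):
        n = 800  # 1/N = 0.00125 sits between the two thresholds
        u = uniform_profile(n)
        assert classify_layers(u, u) == []

    def test_direct_rules(self):
        t = HydroProfile("T", np.array([0.002, 0.0005, 0.002, 0.0012]), False)
        o = HydroProfile("O", np.array([0.0005, 0.0005, 0.002, 0.0012]), False)
        segs = classify_layers(t, o)
        labels = {i: s.label for s in segs for i in s.indices}
        assert labels[0] == "core_deficit"
        assert labels[1] == "surface_polar"
        assert labels[2] == "subsurface_conforming"
        assert 3 not in labels  # between thresholds: unlabeled

    def test_labels_pairwise_disjoint(self, rng):
        t = random_profile(500, rng, kind="T")
        o = random_profile(500, rng)
        segs = classify_layers(t, o)
        seen = set()
        for seg in segs:
            assert not (set(seg.indices) & seen)
            seen |= set(seg.indices)

    def test_bad_thresholds_rejected(self):
        u = uniform_profile(10)
        with pytest.raises(ValueError):
            classify_layers(u, u, t_low=0.01, t_high=0.001)


@pytest.fixture(scope="module")
def dimer():
    return make_fixture(FixtureSpec("engineered_dimer", 120, seed=2))


class TestInterface:
    def test_far_apart_chains_empty(self, dimer):
        model, _ = dimer
        ua, ub = select(model, "A"), select(model, "B")
        # drop the engineered contact residues: the rest are > 100 A apart
        far_a = [k for k in ua.members if k[1] != 1]
        far_b = [k for k in ub.members if k[1] != 1]
        from fodm import UnitSelection

        got = interface_residues(
            model, UnitSelection(tuple(far_a)), UnitSelection(tuple(far_b)), 5.0)
        assert got == ()

    def test_engineered_contact_found_exactly(self, dimer):
        model, bounds = dimer
        ua, ub = select(model, "A"), select(model, "B")
        got = interface_residues(model, ua, ub, 5.0)
        assert got == (("A", int(bounds["contact_seq_a"]), ""),)

    def test_monotone_in_cutoff(self, dimer):
        model, _ = dimer
        ua, ub = select(model, "A"), select(model, "B")
        prev: set = set()
        for cutoff in (3.0, 5.0, 8.0, 60.0, 130.0):
            cur = set(interface_residues(model, ua, ub, cutoff))
            assert prev <= cur
            prev = cur
        assert prev  # the largest cutoff reaches across the dimer

    def test_heavy_atom_superset_of_effective(self, dimer):
        model, _ = dimer
        ua, ub = select(model, "A"), select(model, "B")
        heavy = set(interface_residues(model, ua, ub, 20.0, basis="heavy_atom"))
        eff = set(interface_residues(model, ua, ub, 20.0, basis="effective_atom"))
        assert eff <= heavy

    def test_overlapping_units_rejected(self, dimer):
        model, _ = dimer
        ua = select(model, "A")
        with pytest.raises(SelectionError):
            interface_residues(model, ua, ua, 5.0)

    def test_interface_status_partition_and_identity(self, dimer):
        model, _ = dimer
        ua, ub = select(model, "A"), select(model, "B")
        span = tuple(r.key for r in model.residues)
        t, o, _ = compute_profiles(model, span)
        # interface == whole chain -> equals the chain's fragment status
        from fodm import fragment_status

        whole = interface_status(t, o, ua.members)
        frag = fragment_status(t, o, ua.members)
        assert whole.rd == pytest.approx(frag.rd, abs=1e-12)
        # P-P and no-P-P partition the chain
        iface = interface_residues(model, ua, ub, 12.0)
        assert iface
        comp_status = interface_status(t, o, iface, chain=ua.members,
                                       complement=True)
        assert comp_status.n_residues == len(ua.members) - len(iface)

    def test_hydrophobic_contact_raises_local_observed(self, dimer):
        # direction built into the fixture: the engineered contact pair is
        # maximally hydrophobic, so repainting it polar must lower the
        # observed hydrophobicity at the interface residue
        import copy

        from fodm.scales import get_scale

        model, _ = dimer
        ua, ub = select(model, "A"), select(model, "B")
        span = tuple(r.key for r in model.residues)
        t, o, _ = compute_profiles(model, span)
        iface = interface_residues(model, ua, ub, 5.0)
        idx = [t.keys.index(k) for k in iface]

        polar_model = copy.deepcopy(model)
        sc = get_scale()
        bottom = min(sc.values, key=sc.values.get)
        for key in (("A", 1, ""), ("B", 1, "")):
            polar_model[key].aa_type = bottom
        _, o_polar, _ = compute_profiles(polar_model, span)
        assert o.values[idx].mean() > o_polar.values[idx].mean()

        # and the interface status is computed from the same complex profiles
        # as its complement, over disjoint residue sets
        pp = interface_status(t, o, iface, label="P-P")
        nopp = interface_status(t, o, iface, chain=ua.members, complement=True)
        assert pp.n_residues + nopp.n_residues == len(ua.members)
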