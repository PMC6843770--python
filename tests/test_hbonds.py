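"""Hydrogen-bond detection, occupancy, and cross-model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heatdyn import synthetic as syn
from heatdyn.hbonds import (HBondCriterion, HBondOccupancy,
                            assign_donors_acceptors, compare_occupancies,
                            hbond_occupancy)
from heatdyn.io import AtomTable, Ensemble


def _ensemble(names, resnums, resnames, elements, coords):
    table = AtomTable.from_records(
        atom_names=names, residue_numbers=resnums, residue_names=resnames,
        chain_ids=["A"] * len(names), elements=elements)
    return Ensemble(table, np.asarray(coords, dtype=float))


def _brute_force_occupancy(ensemble, criterion, donors, acceptors):
    """Independent exhaustive frame-by-frame checker (oracle)."""
    out = {}
    X = ensemble.coords
    T = X.shape[0]
    for d, hyds in donors.items():
        for a in acceptors:
            if a == d:
                continue
            count = 0
            for t in range(T):
                dist = np.linalg.norm(X[t, a] - X[t, d])
                if dist > criterion.max_heavy_distance:
                    continue
                if criterion.distance_only:
                    count += 1
                    continue
                best = 0.0
                for h in hyds:
                    v1 = X[t, d] - X[t, h]
                    v2 = X[t, a] - X[t, h]
                    cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    best = max(best, np.degrees(np.arccos(
                        np.clip(cos, -1, 1))))
                if best >= criterion.angle_threshold:
                    count += 1
            if count:
                out[(d, a)] = count / T
    return out


class TestDonorAcceptorAssignment:
    def test_hydroxyl_is_donor_and_acceptor(self):
        # serine-like OG with HG at 0.96 A
        ens = _ensemble(["OG", "HG"], [1, 1], ["SER", "SER"], ["O", "H"],
                        [[[0, 0, 0], [0.96, 0, 0]]])
        donors, acceptors = assign_donors_acceptors(ens)
        assert list(donors) == [0]
        assert donors[0] == [1]
        assert 0 in acceptors

    def test_carbonyl_is_acceptor_only(self):
        ens = _ensemble(["O", "HX"], [1, 2], ["GLY", "GLY"], ["O", "H"],
                        [[[0, 0, 0], [5.0, 0, 0]]])  # H too far to be bonded
        donors, acceptors = assign_donors_acceptors(ens)
        assert donors == {}
        assert acceptors == [0]

    def test_carbon_is_neither(self):
        ens = _ensemble(["CA", "N", "H"], [1, 1, 1], ["ALA"] * 3,
                        ["C", "N", "H"],
                        [[[0, 0, 0], [1.5, 0, 0], [2.5, 0, 0]]])
        donors, acceptors = assign_donors_acceptors(ens)
        assert 0 not in acceptors and 0 not in donors

    def test_no_hydrogens_suggests_distance_only(self):
        ens = _ensemble(["N", "O"], [1, 2], ["GLY", "GLY"], ["N", "O"],
                        [[[0, 0, 0], [3.0, 0, 0]]])
        with pytest.raises(ValueError, match="distance-only"):
            assign_donors_acceptors(ens)


class TestOccupancy:
    def test_good_geometry_every_frame(self):
        coords = np.tile(syn._dha_coordinates(2.8, 170.0), (5, 1, 1))
        ens = _ensemble(["N", "H1", "O"], [1, 1, 2], ["DON", "DON", "ACC"],
                        ["N", "H", "O"], coords)
        occ = hbond_occupancy(ens)
        assert len(occ) == 1
        assert occ[0].occupancy == 1.0

    def test_distance_violation_never_counts(self):
        coords = np.tile(syn._dha_coordinates(3.4, 170.0), (5, 1, 1))
        ens = _ensemble(["N", "H1", "O"], [1, 1, 2], ["DON", "DON", "ACC"],
                        ["N", "H", "O"], coords)
        assert hbond_occupancy(ens) == []

    def test_generator_realized_fraction_recovered_exactly(self):
        spec = syn.HBondSeriesSpec(target_occupancy=0.7, n_frames=10_000,
                                   seed=13)
        ens = syn.make_hbond_ensemble(spec)
        occ = hbond_occupancy(ens)
        assert len(occ) == 1
        assert occ[0].occupancy == ens.metadata["realized_occupancy"]
        assert occ[0].count == ens.metadata["bound_frames"]

    def test_matches_brute_force_oracle_on_noisy_fixture(self):
        # 12-atom random system jittering around bonding distance
        rng = np.random.default_rng(3)
        names = ["N1", "H1", "O1", "N2", "H2", "O2", "C1", "C2",
                 "O3", "H3", "N3", "C3"]
        elements = [n[0] for n in names]
        base = rng.uniform(0, 6, size=(12, 3))
        # put hydrogens near their heavy partners
        for h, d in ((1, 0), (4, 3), (9, 8)):
            base[h] = base[d] + rng.normal(scale=0.3, size=3) * 0 + \
                np.array([1.0, 0, 0])
        coords = base[None] + rng.normal(scale=0.7, size=(1000, 12, 3))
        coords[:, 1] = coords[:, 0] + [1.0, 0, 0]   # keep D-H rigid
        coords[:, 4] = coords[:, 3] + [1.0, 0, 0]
        coords[:, 9] = coords[:, 8] + [1.0, 0, 0]
        ens = _ensemble(names, list(range(1, 13)), ["LIG"] * 12, elements,
                        coords)
        crit = HBondCriterion()
        donors, acceptors = assign_donors_acceptors(ens)
        oracle = _brute_force_occupancy(ens, crit, donors, acceptors)
        got = {}
        tbl = ens.atom_table.frame
        idx_of = {(r.chain_id, r.residue_number, r.atom_name): i
                  for i, r in tbl.iterrows()}
        for rec in hbond_occupancy(ens, crit):
            got[(idx_of[rec.donor], idx_of[rec.acceptor])] = rec.occupancy
        assert got == oracle
        assert len(got) > 0  # fixture actually exercises the criterion

    def test_monotonic_in_cutoffs(self):
        spec = syn.HBondSeriesSpec(target_occupancy=0.5, n_frames=500,
                                   seed=2, bound_geometry=(3.1, 150.0))
        ens = syn.make_hbond_ensemble(spec)

        def occ_of(dist, ang):
            crit = HBondCriterion(max_heavy_distance=dist,
                                  angle_threshold=ang)
            table = hbond_occupancy(ens, crit, include_zero=True)
            return table[0].occupancy if table else 0.0

        base = occ_of(3.3, 145.0)
        assert occ_of(3.6, 145.0) >= base      # looser distance
        assert occ_of(3.3, 120.0) >= base      # looser angle
        assert occ_of(3.0, 145.0) <= base      # tighter distance
        assert occ_of(3.3, 160.0) <= base      # tighter angle

    def test_rigid_motion_invariance(self, apply_rigid):
        spec = syn.HBondSeriesSpec(target_occupancy=0.6, n_frames=400,
                                   seed=6)
        ens = syn.make_hbond_ensemble(spec)
        moved = apply_rigid(ens, seed=9)
        occ0 = hbond_occupancy(ens)
        occ1 = hbond_occupancy(moved)
        assert [(o.donor, o.acceptor, o.occupancy) for o in occ0] == \
            [(o.donor, o.acceptor, o.occupancy) for o in occ1]

    def test_distance_only_mode_drops_angle_test(self):
        # good distance, terrible angle: only distance-only mode detects it
        coords = np.tile(syn._dha_coordinates(2.9, 100.0), (5, 1, 1))
        ens = _ensemble(["N", "H1", "O"], [1, 1, 2], ["DON", "DON", "ACC"],
                        ["N", "H", "O"], coords)
        assert hbond_occupancy(ens) == []
        occ = hbond_occupancy(ens, HBondCriterion(angle_threshold=None))
        assert occ and occ[0].occupancy == 1.0


def _table(pairs):
    return [HBondOccupancy(donor=("A", d, "N"), acceptor=("A", a, "O"),
                           occupancy=o, n_frames=100, count=round(o * 100))
            for d, a, o in pairs]


class TestCompareOccupancies:
    def test_identical_tables_give_empty_report(self):
        t = _table([(1, 2, 0.8)])
        rep = compare_occupancies([("wt", t), ("mut", t)], min_delta=0.01)
        assert len(rep) == 0

    def test_missing_pair_counts_as_zero(self):
        rep = compare_occupancies(
            [("wt", _table([(1, 2, 0.9)])), ("mut", _table([]))],
            min_delta=0.5)
        assert len(rep) == 1
        assert rep.iloc[0]["delta"] == pytest.approx(0.9)
        assert rep.iloc[0]["mut"] == 0.0

    def test_three_model_range(self):
        rep = compare_occupancies(
            [("a", _table([(1, 2, 0.2)])),
             ("b", _table([(1, 2, 0.5)])),
             ("c", _table([(1, 2, 0.9)]))], min_delta=0.5)
        assert len(rep) == 1
        assert rep.iloc[0]["delta"] == pytest.approx(0.7)

    def test_duplicate_labels_rejected(self):
        t = _table([(1, 2, 0.5)])
        with pytest.raises(ValueError, match="duplicate"):
            compare_occupancies([("x", t), ("x", t)])


@settings(deadline=None, max_examples=25)
@given(dist=st.floats(2.5, 4.0), ang=st.floats(100.0, 175.0))
def test_criterion_monotonicity_property(dist, ang):
    """Loosening either threshold can only keep or add detections."""
    spec = syn.HBondSeriesSpec(target_occupancy=0.5, n_frames=120, seed=1,
                               bound_geometry=(3.0, 155.0))
    ens = syn.make_hbond_ensemble(spec)

    def occ(d, a):
        table = hbond_occupancy(ens, HBondCriterion(d, a),
                                include_zero=True)
        return table[0].occupancy if table else 0.0

    assert occ(dist + 0.2, ang) >= occ(dist, ang)
    assert occ(dist, max(ang - 10, 1.0)) >= occ(dist, ang)
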