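"""Geometric hydrogen-bond detection against a brute-force oracle."""

import numpy as np
import pytest

from hgthermo.hbonds import (
    CATEGORIES,
    EnsembleHBondStats,
    Frame,
    HBondCriteria,
    classify_counts,
    count_cavity_waters,
    delta_on_binding,
    detect_hbonds,
)
from hgthermo.regions import CylinderRegion
from hgthermo.synthetic import ScenarioSpec, make_toy_complex

from conftest import random_water_frame


def brute_force_hbonds(frame, criteria=HBondCriteria()):
    """O(N^2) reference detector applying the same strict cuts."""
    def mi(v):
        if frame.box is None:
            return v
        return v - frame.box * np.round(v / frame.box)

    found = set()
    for heavy, hyd in frame.donors:
        for acc in frame.acceptors:
            if acc == heavy or frame.mol_ids[acc] == frame.mol_ids[heavy]:
                continue
            r = np.linalg.norm(mi(frame.coords[acc] - frame.coords[heavy]))
            if not (r < criteria.d_max):
                continue
            v1 = mi(frame.coords[heavy] - frame.coords[hyd])
            v2 = mi(frame.coords[acc] - frame.coords[hyd])
            cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            if angle > criteria.angle_min:
                found.add((heavy, hyd, acc))
    return found


def water_dimer(o_o_distance=2.8, dha_angle=165.0):
    """Donor water at origin donating (via H at +x) to an acceptor oxygen.

    The acceptor O is placed in the xy-plane so that the D-H-A angle is
    exactly ``dha_angle`` and |D...A| is exactly ``o_o_distance``.
    """
    oh = 0.9572
    d = o_o_distance
    a = np.deg2rad(dha_angle)
    h1 = np.array([oh, 0.0, 0.0])
    # H->A direction making angle `a` with H->D = (-1, 0, 0)
    ha_dir = np.array([-np.cos(a), np.sin(a), 0.0])
    # law of cosines: |DA|^2 = oh^2 + x^2 - 2*oh*x*cos(a) with x = |H-A|
    x = oh * np.cos(a) + np.sqrt(oh**2 * np.cos(a) ** 2 - oh**2 + d**2)
    acc_o = h1 + x * ha_dir
    h2 = np.array([-oh * 0.26, oh * 0.97, 0.0])  # second donor H, arbitrary
    acc_h = acc_o + np.array([0.0, 0.0, oh])
    coords = np.vstack([np.zeros(3), h1, h2, acc_o, acc_h, acc_o + np.array([oh, 0, 0.2])])
    return Frame(
        coords=coords,
        elements=["O", "H", "H", "O", "H", "H"],
        mol_labels=["water"] * 6,
        mol_ids=np.array([0, 0, 0, 1, 1, 1]),
        donors=[(0, 1), (0, 2), (3, 4), (3, 5)],
        acceptors=[0, 3],
    )


class TestDetectHbonds:
    def test_water_dimer_detected(self):
        frame = water_dimer(2.8, 165.0)
        bonds = detect_hbonds(frame)
        assert any(b.donor == 0 and b.acceptor == 3 for b in bonds)

    def test_distance_cut_strict(self):
        assert not any(
            b.donor == 0 for b in detect_hbonds(water_dimer(3.05, 165.0))
        )
        # exact boundary excluded
        assert not any(
            b.donor == 0 for b in detect_hbonds(water_dimer(3.0, 165.0))
        )

    def test_angle_cut_strict(self):
        assert not any(b.donor == 0 for b in detect_hbonds(water_dimer(2.8, 140.0)))
        assert not any(b.donor == 0 for b in detect_hbonds(water_dimer(2.8, 150.0)))

    @pytest.mark.parametrize("periodic", [False, True])
    def test_matches_bruteforce_on_random_frames(self, periodic):
        rng = np.random.default_rng(17)
        for _ in range(20):
            frame = random_water_frame(rng, n_waters=50, box=20.0, periodic=periodic)
            fast = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(frame)}
            assert fast == brute_force_hbonds(frame)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(23)
        frame = random_water_frame(rng, n_waters=40, box=15.0)
        n0 = len(detect_hbonds(frame))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = Frame(
            coords=frame.coords @ q.T + np.array([5.0, -3.0, 11.0]),
            elements=frame.elements,
            mol_labels=frame.mol_labels,
            mol_ids=frame.mol_ids,
            donors=frame.donors,
            acceptors=frame.acceptors,
        )
        assert len(detect_hbonds(moved)) == n0

    def test_periodic_wrap_invariance(self):
        rng = np.random.default_rng(29)
        frame = random_water_frame(rng, n_waters=40, box=15.0, periodic=True)
        n0 = {(b.donor, b.acceptor) for b in detect_hbonds(frame)}
        wrapped = Frame(
            coords=frame.coords + np.array([15.0, -30.0, 15.0]),
            elements=frame.elements,
            mol_labels=frame.mol_labels,
            mol_ids=frame.mol_ids,
            donors=frame.donors,
            acceptors=frame.acceptors,
            box=frame.box,
        )
        assert {(b.donor, b.acceptor) for b in detect_hbonds(wrapped)} == n0

    def test_annotation_invariant_enforced(self):
        with pytest.raises(ValueError, match="donor hydrogen"):
            Frame(
                coords=np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                elements=["O", "H"],
                mol_labels=["water", "water"],
                mol_ids=np.array([0, 0]),
                donors=[(0, 1)],
                acceptors=[0],
            )


class TestClassification:
    def test_all_water_bonds_are_ww(self):
        rng = np.random.default_rng(31)
        frame = random_water_frame(rng, n_waters=60, box=14.0)
        counts = classify_counts(detect_hbonds(frame), frame)
        assert counts["H-G"] == counts["H-W"] == counts["G-W"] == 0

    def test_constructed_complex_counts(self, spec):
        tc = make_toy_complex(spec, seed=0)
        counts = classify_counts(detect_hbonds(tc.bound), tc.bound)
        assert counts["H-G"] == spec.target_HG
        assert counts["G-W"] == spec.target_GW
        assert counts["H-W"] == spec.target_HW

    def test_counts_partition_bond_list(self):
        rng = np.random.default_rng(37)
        frame = random_water_frame(rng, n_waters=80, box=15.0)
        bonds = detect_hbonds(frame)
        assert sum(classify_counts(bonds, frame).values()) == len(bonds)


class TestDeltaOnBinding:
    def test_identical_composition_gives_zero(self):
        bound = EnsembleHBondStats({"H-G": 0, "H-W": 2.0, "G-W": 1.0, "W-W": 50.0}, 100)
        host = EnsembleHBondStats({"H-W": 2.0, "W-W": 30.0}, 60)
        guest = EnsembleHBondStats({"G-W": 1.0, "W-W": 20.0}, 40)
        t = delta_on_binding(bound, host, guest, bulk_rate_per_water=1.7)
        assert t.total == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "components,total",
        [((0.6, -0.7, -0.8, 3.1), 2.2), ((1.2, -1.2, -1.5, 4.2), 2.7)],
    )
    def test_printed_row_totals(self, components, total):
        hg, hw, gw, ww = components
        bound = EnsembleHBondStats(
            {"H-G": hg, "H-W": 10 + hw, "G-W": 5 + gw, "W-W": 100 + ww}, 100
        )
        host = EnsembleHBondStats({"H-W": 10.0, "W-W": 60.0}, 60)
        guest = EnsembleHBondStats({"G-W": 5.0, "W-W": 40.0}, 40)
        t = delta_on_binding(bound, host, guest)
        assert t.total == pytest.approx(total, abs=1e-9)

    def test_strict_matching_rejects_unbalanced(self):
        bound = EnsembleHBondStats({"W-W": 10.0}, 90)
        host = EnsembleHBondStats({"W-W": 8.0}, 60)
        guest = EnsembleHBondStats({"W-W": 4.0}, 40)
        with pytest.raises(ValueError, match="unbalanced"):
            delta_on_binding(bound, host, guest, matching="strict")

    def test_bulk_rate_credits_expelled_waters(self):
        bound = EnsembleHBondStats({"W-W": 10.0}, 90)
        host = EnsembleHBondStats({"W-W": 8.0}, 60)
        guest = EnsembleHBondStats({"W-W": 4.0}, 40)
        t = delta_on_binding(bound, host, guest, bulk_rate_per_water=1.5)
        assert t.dWW == pytest.approx(10.0 - 12.0 + 10 * 1.5)


class TestCavityWaters:
    cavity = CylinderRegion(center=(0, 0, 0), axis=(0, 0, 1), radius=4.0, half_height=3.0)

    def test_empty_cavity(self):
        rng = np.random.default_rng(41)
        frame = random_water_frame(rng, n_waters=10, box=30.0)
        far = Frame(
            coords=frame.coords + 50.0,
            elements=frame.elements,
            mol_labels=frame.mol_labels,
            mol_ids=frame.mol_ids,
            donors=frame.donors,
            acceptors=frame.acceptors,
        )
        assert count_cavity_waters(far, self.cavity) == 0

    def test_constructed_inside_outside_split(self):
        rng = np.random.default_rng(43)
        inside = rng.uniform(-1.5, 1.5, size=(5, 3))
        outside = rng.uniform(10, 15, size=(10, 3))
        coords, donors, acceptors, ids = [], [], [], []
        for i, o in enumerate(np.vstack([inside, outside])):
            base = 3 * i
            coords += [o, o + [0.96, 0, 0], o + [-0.24, 0.93, 0]]
            donors += [(base, base + 1), (base, base + 2)]
            acceptors.append(base)
            ids += [i] * 3
        frame = Frame(
            coords=np.array(coords),
            elements=["O", "H", "H"] * 15,
            mol_labels=["water"] * 45,
            mol_ids=np.array(ids),
            donors=donors,
            acceptors=acceptors,
        )
        assert count_cavity_waters(frame, self.cavity) == 5

    def test_bound_toy_complex_cavity_is_dry(self, spec):
        tc = make_toy_complex(spec, seed=2)
        assert count_cavity_waters(tc.bound, tc.cavity) == 0
        assert count_cavity_waters(tc.free_host, tc.cavity) == spec.n_cavity_waters
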