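"""Hydrogen-bond detection and classification tests on constructed geometries."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chitinmech import (
    HBondCriteria,
    MolecularFrame,
    SyntheticFrameSpec,
    classify_hbonds,
    detect_hbonds,
    generate_chain_frame,
    hbond_ratio_over_frames,
)


def build_frame(atoms, bonds=None):
    """atoms: list of (element, position, molecule_id, role)."""
    return MolecularFrame(
        positions=np.array([a[1] for a in atoms], dtype=float),
        masses=np.array([1.008 if a[0] == "H" else 15.999 for a in atoms]),
        elements=np.array([a[0] for a in atoms], dtype=object),
        molecule_ids=np.array([a[2] for a in atoms], dtype=int),
        roles=np.array([a[3] for a in atoms], dtype=object),
        bonds=bonds,
    )


def water_donating_to(acceptor_pos, da_distance, mol_id):
    """Water with one O–H aimed straight at an acceptor (angle 180°)."""
    acceptor = np.asarray(acceptor_pos, float)
    o_pos = acceptor - np.array([da_distance, 0.0, 0.0])
    h_pos = o_pos + np.array([0.96, 0.0, 0.0])
    h2_pos = o_pos + np.array([-0.24, 0.93, 0.0])
    return [
        ("O", o_pos, mol_id, "solvent"),
        ("H", h_pos, mol_id, "solvent"),
        ("H", h2_pos, mol_id, "solvent"),
    ]


class TestDetection:
    def test_textbook_geometry_scores_one_bond(self):
        atoms = [("O", [2.8, 0.0, 0.0], 0, "solute")] + water_donating_to([2.8, 0, 0], 2.8, 1)
        records = detect_hbonds(build_frame(atoms))
        assert len(records) == 1
        rec = records[0]
        assert rec.kind == "inter"
        assert rec.distance == pytest.approx(2.8)
        assert rec.angle == pytest.approx(180.0)

    def test_distance_cutoff_excludes(self):
        atoms = [("O", [4.2, 0.0, 0.0], 0, "solute")] + water_donating_to([4.2, 0, 0], 4.2, 1)
        assert detect_hbonds(build_frame(atoms)) == []

    def test_angle_cutoff_excludes(self):
        # acceptor perpendicular to the O–H direction: D–H···A angle = 90°
        atoms = [
            ("O", [0.96, 2.8, 0.0], 0, "solute"),
            ("O", [0.0, 0.0, 0.0], 1, "solvent"),
            ("H", [0.96, 0.0, 0.0], 1, "solvent"),
        ]
        assert detect_hbonds(build_frame(atoms)) == []

    def test_bridging_water_gives_two_inter_bonds(self):
        # water equidistant (3.0 Å) from two saccharide sites 4.5 Å apart
        a = np.array([0.0, 0.0, 0.0])
        c = np.array([4.5, 0.0, 0.0])
        o_pos = np.array([2.25, np.sqrt(9.0 - 2.25**2), 0.0])
        h1 = o_pos + 0.96 * (a - o_pos) / 3.0
        h2 = o_pos + 0.96 * (c - o_pos) / 3.0
        atoms = [
            ("O", a, 0, "solute"),
            ("O", c, 0, "solute"),
            ("O", o_pos, 1, "solvent"),
            ("H", h1, 1, "solvent"),
            ("H", h2, 1, "solvent"),
        ]
        records = detect_hbonds(build_frame(atoms))
        assert len(records) == 2
        assert all(r.kind == "inter" for r in records)
        assert {r.acceptor for r in records} == {0, 1}

    def test_rigid_motion_invariance(self):
        spec = SyntheticFrameSpec(n_units=8, compactness=0.3, bridge_waters=3, intra_hbonds=2, seed=4)
        frame = generate_chain_frame(spec)
        base = [(r.donor, r.hydrogen, r.acceptor) for r in detect_hbonds(frame)]
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = frame.transformed(rotation=rot, translation=[7.0, -3.0, 11.0])
        assert [(r.donor, r.hydrogen, r.acceptor) for r in detect_hbonds(moved)] == base

    def test_cutoff_monotonicity(self):
        spec = SyntheticFrameSpec(
            n_units=8, compactness=0.5, bridge_waters=2, bulk_waters=40, box_size=18.0, seed=6
        )
        frame = generate_chain_frame(spec)
        n_loose = len(detect_hbonds(frame, HBondCriteria(max_da_distance=4.0, min_dha_angle=130)))
        n_base = len(detect_hbonds(frame, HBondCriteria(max_da_distance=3.5, min_dha_angle=130)))
        n_tight_d = len(detect_hbonds(frame, HBondCriteria(max_da_distance=3.0, min_dha_angle=130)))
        n_tight_a = len(detect_hbonds(frame, HBondCriteria(max_da_distance=3.5, min_dha_angle=160)))
        assert n_tight_d <= n_base <= n_loose
        assert n_tight_a <= n_base

    def test_missing_bonding_information_errors(self):
        atoms = [
            ("O", [0.0, 0.0, 0.0], 0, "solute"),
            ("H", [3.0, 0.0, 0.0], 1, "solvent"),  # stray H, no heavy partner nearby
        ]
        with pytest.raises(ValueError, match="bond"):
            detect_hbonds(build_frame(atoms))


class TestClassification:
    def test_all_solute_frame_has_no_inter(self):
        spec = SyntheticFrameSpec(n_units=10, compactness=0.2, intra_hbonds=2, seed=3)
        records = detect_hbonds(generate_chain_frame(spec))
        intra, inter = classify_hbonds(records)
        assert inter == 0
        assert intra == 2

    def test_solute_without_donors_has_no_intra(self):
        spec = SyntheticFrameSpec(n_units=10, compactness=0.2, bridge_waters=4, seed=3)
        intra, inter = classify_hbonds(detect_hbonds(generate_chain_frame(spec)))
        assert intra == 0
        assert inter == 8

    def test_constructed_three_intra_six_inter(self):
        spec = SyntheticFrameSpec(n_units=10, compactness=0.2, bridge_waters=3, intra_hbonds=3, seed=8)
        records = detect_hbonds(generate_chain_frame(spec))
        assert classify_hbonds(records) == (3, 6)

    def test_counts_partition_solute_records(self):
        spec = SyntheticFrameSpec(
            n_units=10, compactness=0.4, bridge_waters=3, intra_hbonds=2,
            bulk_waters=30, box_size=20.0, seed=12,
        )
        records = detect_hbonds(generate_chain_frame(spec))
        intra, inter = classify_hbonds(records)
        solute_involving = [r for r in records if r.kind in ("intra", "inter")]
        assert intra + inter == len(solute_involving)


class TestRatioOverFrames:
    def test_duplicated_frames_keep_ratio(self):
        spec = SyntheticFrameSpec(n_units=10, compactness=0.2, bridge_waters=4, intra_hbonds=1, seed=5)
        frame = generate_chain_frame(spec)
        single = hbond_ratio_over_frames([frame])
        repeated = hbond_ratio_over_frames([frame] * 4)
        assert repeated.ratio == single.ratio

    def test_many_bridges_one_internal_bond(self):
        # 12 bridging waters → 24 intermolecular bonds against 1 intramolecular
        spec = SyntheticFrameSpec(
            n_units=13, compactness=0.1, bridge_waters=12, intra_hbonds=1, n_frames=3, seed=5
        )
        from chitinmech import generate_frame_series

        stats = hbond_ratio_over_frames(generate_frame_series(spec))
        assert stats.mean_intra == pytest.approx(1.0)
        assert stats.ratio == pytest.approx(24.0, abs=2.0)

    def test_zero_solvent_ratio_flagged_infinite(self):
        spec = SyntheticFrameSpec(n_units=10, compactness=0.2, seed=3)
        stats = hbond_ratio_over_frames([generate_chain_frame(spec)])
        assert stats.mean_inter == 0
        assert np.isinf(stats.ratio)
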