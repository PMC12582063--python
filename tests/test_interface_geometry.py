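"""interface_geometry: pockets, gate, H-bond energies, contacts."""

import numpy as np
import pytest

from helpers import dssp_energy_oracle
from lirscreen import fixture_forge
from lirscreen.fixture_forge import FixtureSpec, make_peptide_pose
from lirscreen.interface_geometry import (
    assign_pocket,
    count_backbone_hbonds,
    count_ca_contacts,
    dssp_hbond_energy,
    get_receptor_profile,
    hp0_gate_open,
    load_receptor_profiles,
)
from lirscreen.stretch_detector import Stretch
from lirscreen.structure_io import (
    PredictedComplex,
    Residue,
    add_backbone_hydrogens,
)

LC3B = get_receptor_profile("LC3B")


def _full_stretch(cx):
    n = len(cx.peptide)
    return Stretch(cx.model_id, 1, n, 90.0, 3.0)


def _rigid_transform(cx, seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50, 50, 3)

    def move(chain):
        return [
            Residue(r.name, r.index, {k: q @ v + t for k, v in r.atoms.items()})
            for r in chain
        ]

    return PredictedComplex(
        cx.model_id, move(cx.receptor), move(cx.peptide), cx.plddt, cx.pae
    )


def test_predicates_invariant_under_rigid_motion():
    cx = add_backbone_hydrogens(
        make_peptide_pose(FixtureSpec(label="can.LIR", seed=5))
    )
    s = _full_stretch(cx)
    ref = (
        assign_pocket(cx, s, LC3B, "HP0"),
        assign_pocket(cx, s, LC3B, "HP1"),
        assign_pocket(cx, s, LC3B, "HP2"),
        count_backbone_hbonds(cx, s, LC3B.beta2_range),
        count_ca_contacts(cx, s, LC3B.beta2_range),
    )
    for seed in range(5):
        moved = _rigid_transform(cx, seed)
        got = (
            assign_pocket(moved, s, LC3B, "HP0"),
            assign_pocket(moved, s, LC3B, "HP1"),
            assign_pocket(moved, s, LC3B, "HP2"),
            count_backbone_hbonds(moved, s, LC3B.beta2_range),
            count_ca_contacts(moved, s, LC3B.beta2_range),
        )
        assert got == ref


def test_first_engaging_residue_wins():
    b = fixture_forge._Builder(LC3B, "AAAEMAAASA", seed=0)
    b.place_pockets(gate_distance=10.0)
    b.engage("HP1", 7)
    # a second residue earlier in the stretch also reaches the pocket
    b.engage("HP1", 3)
    cx = b.build("two_engagers")
    got = assign_pocket(cx, _full_stretch(cx), LC3B, "HP1")
    assert got.residue == 3


def test_pocket_cutoffs_are_strict():
    spec = LC3B.hp1
    b = fixture_forge._Builder(LC3B, "AAAA", seed=0)
    b.place_pockets(gate_distance=10.0)
    a1 = b._rec(spec.anchor1).atoms["CA"]
    # place exactly at cutoff1 from anchor1 while within cutoff2 of anchor2
    a2 = b._rec(spec.anchor2).atoms["CA"]
    direction = np.array([0.0, 1.0, 0.0])
    b.peptide[0].atoms["CA"] = a1 + direction * spec.cutoff1
    cx = b.build("at_cutoff")
    assert np.linalg.norm(b.peptide[0].atoms["CA"] - a2) < spec.cutoff2
    assert not assign_pocket(cx, _full_stretch(cx), LC3B, "HP1").engaged
    b.peptide[0].atoms["CA"] = a1 + direction * (spec.cutoff1 - 0.05)
    cx = b.build("inside_cutoff")
    assert assign_pocket(cx, _full_stretch(cx), LC3B, "HP1").residue == 1


@pytest.mark.parametrize(
    "gate_distance,expected_open",
    [(8.5, False), (9.0, False), (9.05, True), (10.0, True)],
)
def test_hp0_gate_opens_strictly_above_nine_angstrom(gate_distance, expected_open):
    cx = make_peptide_pose(
        FixtureSpec(label="HP0-LIR", gate_distance=gate_distance)
    )
    assert hp0_gate_open(cx, LC3B.hp0_gate) is expected_open
    hp0 = assign_pocket(cx, _full_stretch(cx), LC3B, "HP0")
    assert hp0.gate_open is expected_open
    assert hp0.engaged is expected_open   # the fixture always reaches HP0


def test_glycine_gate_counts_as_open():
    cx = make_peptide_pose(FixtureSpec(label="HP0-LIR", gate_distance=8.0))
    gate_res = cx.receptor_by_index(LC3B.hp0_gate.sidechain_residue)
    assert not hp0_gate_open(cx, LC3B.hp0_gate)
    del gate_res.atoms["CB"]   # no sidechain left: nothing blocks the pocket
    assert hp0_gate_open(cx, LC3B.hp0_gate)


def test_hbond_energy_matches_literal_formula_on_random_geometry():
    rng = np.random.default_rng(12)
    for _ in range(100):
        n, h, c, o = rng.uniform(-5, 5, (4, 3))
        assert dssp_hbond_energy(n, h, c, o) == pytest.approx(
            dssp_energy_oracle(n, h, c, o)
        )


def _hbond_complex(n_bonds=2, energy_shift=0.0):
    """Receptor beta-2 acceptors with peptide donors in crafted geometry."""
    b = fixture_forge._Builder(LC3B, "AAAA", seed=0)
    lo, _ = LC3B.beta2_range
    b.craft_hbonds((2, 3, 4), [lo, lo + 1, lo + 2], n_bonds)
    return add_backbone_hydrogens(b.build("hb"))


def test_crafted_bonds_counted_and_cutoff_is_strict():
    cx = _hbond_complex(2)
    s = _full_stretch(cx)
    assert count_backbone_hbonds(cx, s, LC3B.beta2_range) == 2
    # crafted bonds sit near -2.9 kcal/mol: a stricter cutoff excludes them
    assert count_backbone_hbonds(cx, s, LC3B.beta2_range, energy_cutoff=-3.5) == 0
    assert count_backbone_hbonds(cx, s, LC3B.beta2_range, energy_cutoff=-1.0) == 2


def test_receptor_to_peptide_donation_also_counted():
    # swap roles: receptor residue donates into a peptide carbonyl
    b = fixture_forge._Builder(LC3B, "AAAA", seed=0)
    lo, _ = LC3B.beta2_range
    d = np.array([0.0, 0.0, -1.0])
    n_pos = np.array([25.0, 0.0, 12.0])
    donor = b._rec(lo + 1)
    prev = b._rec(lo)
    donor.atoms["N"] = n_pos
    prev.atoms["C"] = prev.atoms["O"] + d
    acc = b.peptide[2]
    acc.atoms["O"] = n_pos + 2.9 * d
    acc.atoms["C"] = n_pos + (2.9 + 1.23) * d
    cx = add_backbone_hydrogens(b.build("reverse"))
    assert count_backbone_hbonds(cx, _full_stretch(cx), LC3B.beta2_range) == 1


def test_hbonds_outside_receptor_range_ignored():
    cx = _hbond_complex(2)
    s = _full_stretch(cx)
    assert count_backbone_hbonds(cx, s, LC3B.uds_range) == 0


def test_ca_contact_cutoff_is_strict():
    b = fixture_forge._Builder(LC3B, "AAAA", seed=0)
    lo, _ = LC3B.beta2_range
    rec_ca = np.array([0.0, 0.0, -30.0])
    b._rec(lo).atoms["CA"] = rec_ca
    b.peptide[0].atoms["CA"] = rec_ca + np.array([5.0, 0.0, 0.0])
    cx = b.build("at5")
    assert count_ca_contacts(cx, _full_stretch(cx), LC3B.beta2_range) == 0
    b.peptide[0].atoms["CA"] = rec_ca + np.array([4.99, 0.0, 0.0])
    cx = b.build("inside5")
    assert count_ca_contacts(cx, _full_stretch(cx), LC3B.beta2_range) == 1


def test_ca_contacts_match_brute_force():
    rng = np.random.default_rng(5)
    for _ in range(100):
        b = fixture_forge._Builder(LC3B, "AAAAAA", seed=0)
        lo, hi = LC3B.beta2_range
        for idx in range(lo, hi + 1):
            b._rec(idx).atoms["CA"] = rng.uniform(-8, 8, 3)
        for p in b.peptide:
            p.atoms["CA"] = rng.uniform(-8, 8, 3)
        cx = b.build("rand")
        expected = sum(
            np.linalg.norm(p.atoms["CA"] - cx.receptor_by_index(i).atoms["CA"]) < 5.0
            for p in cx.peptide
            for i in range(lo, hi + 1)
        )
        assert count_ca_contacts(cx, _full_stretch(cx), LC3B.beta2_range) == expected


def test_receptor_profiles_cover_described_isoforms():
    profiles = load_receptor_profiles()
    assert {"LC3B", "GABARAP", "Atg8", "ATG8E", "ATG8CL", "SUMO2"} <= set(profiles)
    for name, p in profiles.items():
        if p.family == "LC3":
            assert p.hp0 and p.hp1 and p.hp2 and p.hp0_gate
            assert p.beta2_range and p.uds_range
        else:
            assert p.sim_groove_range
    assert profiles["LC3B"].hp0_gate.open_threshold == 9.0


def test_unknown_receptor_name_lists_alternatives():
    with pytest.raises(KeyError, match="available"):
        get_receptor_profile("NOPE")
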