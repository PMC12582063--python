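"""structure_io: file round-trips, PAE handling, minPAE, hydrogen placement."""

import json

import numpy as np
import pytest

from helpers import dssp_energy_oracle
from lirscreen.structure_io import (
    PredictedComplex,
    Residue,
    StructureError,
    add_backbone_hydrogens,
    compute_min_pae,
    load_pae_matrix,
    load_predicted_complex,
    peptide_min_pae,
    write_predicted_complex,
)


def _mini_complex(n_rec=5, n_pep=4, seed=0):
    rng = np.random.default_rng(seed)
    def chain(n, offset):
        return [
            Residue("ALA", i + 1, {"CA": rng.normal(size=3) + offset})
            for i in range(n)
        ]
    n = n_rec + n_pep
    pae = rng.uniform(0.5, 30.0, (n, n))
    return PredictedComplex(
        model_id="mini",
        receptor=chain(n_rec, 0.0),
        peptide=chain(n_pep, 20.0),
        plddt=rng.uniform(40, 100, n),
        pae=pae,
    )


def test_write_load_round_trip_preserves_coordinates_and_scores(
    tmp_path, lir_fixture_complex
):
    cx = lir_fixture_complex
    pdb, pae = tmp_path / "m.pdb", tmp_path / "m_pae.json"
    write_predicted_complex(cx, pdb, pae)
    back = load_predicted_complex(pdb, pae)
    assert len(back.receptor) == len(cx.receptor)
    assert len(back.peptide) == len(cx.peptide)
    for a, b in zip(cx.receptor + cx.peptide, back.receptor + back.peptide):
        assert a.name == b.name and a.index == b.index
        assert set(a.atoms) == set(b.atoms)
        for name in a.atoms:
            assert np.linalg.norm(a.atoms[name] - b.atoms[name]) < 1e-3
    assert np.allclose(cx.plddt, back.plddt, atol=0.01)
    assert np.allclose(cx.pae, back.pae, atol=0.005)


def test_min_pae_matches_brute_force_on_random_matrices():
    for seed in range(50):
        cx = _mini_complex(seed=seed)
        n = cx.pae.shape[0]
        for pos in range(n):
            expected = np.mean(
                sorted(cx.pae[i, pos] for i in range(n) if i != pos)[:3]
            )
            assert compute_min_pae(cx, pos) == pytest.approx(expected)


def test_min_pae_excludes_the_diagonal_self_entry():
    cx = _mini_complex()
    pae = np.full_like(cx.pae, 10.0)
    np.fill_diagonal(pae, 0.0)   # self-entries must not drag the mean down
    cx2 = PredictedComplex(
        "d", cx.receptor, cx.peptide, cx.plddt, pae
    )
    assert compute_min_pae(cx2, 0) == pytest.approx(10.0)


def test_min_pae_uses_columns_not_rows():
    cx = _mini_complex()
    pae = np.full_like(cx.pae, 20.0)
    pae[:, 2] = 4.0           # residue 2 scored: column
    pae[3, :] = 1.0           # residue 3 aligned: row must not matter ...
    pae[3, 2] = 4.0           # ... keep the column uniform
    cx2 = PredictedComplex("c", cx.receptor, cx.peptide, cx.plddt, pae)
    assert compute_min_pae(cx2, 2) == pytest.approx(4.0)
    assert compute_min_pae(cx2, 3) == pytest.approx(20.0)
    prof = peptide_min_pae(cx2)
    assert prof.shape == (len(cx2.peptide),)


def test_pae_length_mismatch_raises(tmp_path, lir_fixture_complex):
    cx = lir_fixture_complex
    pdb, pae = tmp_path / "m.pdb", tmp_path / "m_pae.json"
    write_predicted_complex(cx, pdb, pae)
    bad = tmp_path / "bad_pae.json"
    bad.write_text(json.dumps({"predicted_aligned_error": [[0.0, 1.0], [1.0, 0.0]]}))
    with pytest.raises(StructureError, match="mismatch"):
        load_predicted_complex(pdb, bad)


def test_missing_chain_raises(tmp_path, lir_fixture_complex):
    cx = lir_fixture_complex
    pdb, pae = tmp_path / "m.pdb", tmp_path / "m_pae.json"
    write_predicted_complex(cx, pdb, pae)
    with pytest.raises(StructureError, match="chain 'X'"):
        load_predicted_complex(pdb, pae, receptor_chain_id="X")


def test_pae_json_dialects(tmp_path):
    m = [[0.0, 2.0], [3.0, 0.0]]
    flat = tmp_path / "flat.json"
    flat.write_text(json.dumps({"pae": m}))
    ebi = tmp_path / "ebi.json"
    ebi.write_text(json.dumps([{"predicted_aligned_error": m}]))
    assert np.allclose(load_pae_matrix(flat), m)
    assert np.allclose(load_pae_matrix(ebi), m)
    empty = tmp_path / "none.json"
    empty.write_text(json.dumps({"something_else": m}))
    with pytest.raises(StructureError, match="no PAE field"):
        load_pae_matrix(empty)


def test_negative_pae_rejected():
    cx = _mini_complex()
    pae = np.array(cx.pae)
    pae[1, 2] = -0.5
    with pytest.raises(StructureError, match="non-negative"):
        PredictedComplex("n", cx.receptor, cx.peptide, cx.plddt, pae)


def test_plddt_outside_range_clamped_with_warning():
    cx = _mini_complex()
    plddt = np.array(cx.plddt)
    plddt[0] = 130.0
    with pytest.warns(UserWarning, match="clamping"):
        cx2 = PredictedComplex("p", cx.receptor, cx.peptide, plddt, cx.pae)
    assert cx2.plddt[0] == 100.0


def _backbone_chain(coords):
    out = []
    for i, (n, ca, c, o) in enumerate(coords, start=1):
        out.append(
            Residue("ALA", i, {
                "N": np.array(n, float), "CA": np.array(ca, float),
                "C": np.array(c, float), "O": np.array(o, float),
            })
        )
    return out


def test_amide_hydrogen_placed_anti_to_preceding_carbonyl():
    rec = _backbone_chain([
        ((0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0)),
        ((3.3, 0, 0), (4.3, 0, 0), (5.3, 0, 0), (5.3, 1, 0)),
    ])
    pep = _backbone_chain([((50, 0, 0), (51, 0, 0), (52, 0, 0), (52, 1, 0))])
    cx = PredictedComplex("h", rec, pep, np.full(3, 90.0), np.full((3, 3), 5.0))
    out = add_backbone_hydrogens(cx)
    assert "H" not in out.receptor[0].atoms            # chain N terminus
    assert "H" not in out.peptide[0].atoms
    h = out.receptor[1].atoms["H"]
    n = out.receptor[1].atoms["N"]
    # unit vector from the previous O to its C: (0, -1, 0)
    assert np.allclose(h, n + np.array([0.0, -1.0, 0.0]))
    assert np.linalg.norm(h - n) == pytest.approx(1.0)


def test_proline_gets_no_amide_hydrogen():
    rec = _backbone_chain([
        ((0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0)),
        ((3.3, 0, 0), (4.3, 0, 0), (5.3, 0, 0), (5.3, 1, 0)),
    ])
    pro = Residue("PRO", 2, dict(rec[1].atoms))
    rec = [rec[0], pro]
    pep = _backbone_chain([((50, 0, 0), (51, 0, 0), (52, 0, 0), (52, 1, 0))])
    cx = PredictedComplex("p", rec, pep, np.full(3, 90.0), np.full((3, 3), 5.0))
    out = add_backbone_hydrogens(cx)
    assert "H" not in out.receptor[1].atoms


def test_placed_hydrogen_reproduces_reference_bond_energy():
    """Collinear crafted N-H...O=C geometry scores about -2.9 kcal/mol."""
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([0.0, 0.0, -1.0])
    o = np.array([0.0, 0.0, -2.9])
    c = np.array([0.0, 0.0, -4.13])
    e = dssp_energy_oracle(n, h, c, o)
    assert -3.2 < e < -2.6


def test_residue_indices_must_strictly_increase():
    rec = [
        Residue("ALA", 1, {"CA": np.zeros(3)}),
        Residue("ALA", 1, {"CA": np.ones(3)}),
    ]
    pep = [Residue("ALA", 1, {"CA": np.full(3, 5.0)})]
    with pytest.raises(StructureError, match="strictly increasing"):
        PredictedComplex("i", rec, pep, np.full(3, 90.0), np.full((3, 3), 5.0))
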