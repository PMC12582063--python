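"""Shared constructors and independent oracles for the test suite."""

from __future__ import annotations

import gemmi
import numpy as np

from lirscreen.aggregator import ParentCall
from lirscreen.fragmenter import FragmentRecord
from lirscreen.interaction_classifier import InteractionCall
from lirscreen.interface_geometry import PocketAssignment
from lirscreen.stretch_detector import DetectionThresholds, Stretch


def write_single_chain(residues, path, plddt=90.0):
    """Write a list of Residue objects as a one-chain PDB file.

    ``plddt`` is a scalar applied to every residue or a per-residue sequence.
    """
    if np.isscalar(plddt):
        plddt = [float(plddt)] * len(residues)
    st = gemmi.Structure()
    st.name = "test"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res, b in zip(residues, plddt):
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.index, " ")
        for aname, xyz in res.atoms.items():
            at = gemmi.Atom()
            at.name = aname
            at.element = gemmi.Element(aname[0])
            at.pos = gemmi.Position(*map(float, xyz))
            at.b_iso = float(b)
            at.occ = 1.0
            gres.add_atom(at)
        chain.add_residue(gres)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def make_parent_call(
    parent_id="P1",
    start=1,
    end=16,
    state="WT",
    lc=16,
    stretch=(1, 4),
    label="can.LIR",
    engaged=None,
    plddt=None,
    minpae=None,
):
    """Fabricate a ParentCall without going through structure evaluation.

    ``stretch`` and ``engaged`` positions are fragment-local and 1-based, as
    the classifier reports them.
    """
    n = end - start + 1
    frag = FragmentRecord(parent_id, start, end, "A" * n, state, lc)
    s0, s1 = stretch
    m = s1 - s0 + 1
    pl = tuple(plddt) if plddt is not None else (90.0,) * m
    mp = tuple(minpae) if minpae is not None else (3.0,) * m
    st = Stretch(
        f"{parent_id}|{start}-{end}|{state}", s0, s1,
        float(np.mean(pl)), float(np.mean(mp)),
    )
    pockets = {
        pocket: PocketAssignment(pocket, pos)
        for pocket, pos in (engaged or {}).items()
    }
    call = InteractionCall(
        label=label,
        stretch=st,
        criteria_flags=(True, True, True, True),
        pockets=pockets,
        hbond_count=2,
        motif_string="",
    )
    return ParentCall(fragment=frag, call=call, plddt=pl, minpae=mp)


def stretch_oracle(plddt, minpae, thr: DetectionThresholds):
    """Brute-force stretch detection: enumerate every interval directly.

    Returns 0-based inclusive (start, end) pairs.  Independent of the
    vectorised implementation: plain Python loops and direct means.
    """
    L = len(plddt)

    def mean(arr, i, j):
        return sum(arr[i : j + 1]) / (j - i + 1)

    def qualifies(i, j):
        if j - i + 1 < thr.min_len:
            return False
        if mean(plddt, i, j) < thr.min_plddt:
            return False
        if mean(minpae, i, j) > thr.max_minpae:
            return False
        return any(
            plddt[k] >= thr.min_plddt and minpae[k] <= thr.max_minpae
            for k in range(i, j + 1)
        )

    qual = [(i, j) for i in range(L) for j in range(i, L) if qualifies(i, j)]
    maximal = [
        iv
        for iv in qual
        if not any(
            a <= iv[0] and iv[1] <= b and (a, b) != iv for (a, b) in qual
        )
    ]
    ivs = sorted(set(maximal))
    changed = True
    while changed:
        changed = False
        for a in range(len(ivs) - 1):
            (i1, j1), (i2, j2) = ivs[a], ivs[a + 1]
            if i2 <= j1:
                union = (min(i1, i2), max(j1, j2))
                if (
                    mean(plddt, *union) >= thr.min_plddt
                    and mean(minpae, *union) <= thr.max_minpae
                ):
                    keep = union
                elif mean(plddt, i2, j2) > mean(plddt, i1, j1):
                    keep = (i2, j2)
                else:
                    keep = (i1, j1)
                ivs[a : a + 2] = [keep]
                changed = True
                break
    return ivs


def dssp_energy_oracle(n, h, c, o):
    """Literal transcription of the electrostatic H-bond energy formula."""
    import math

    def d(a, b):
        return math.dist(tuple(a), tuple(b))

    return 0.084 * (1 / d(o, n) + 1 / d(c, h) - 1 / d(o, h) - 1 / d(c, n)) * 332
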