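"""Reading and writing AlphaFold-style predicted complexes.

A predicted complex couples a receptor chain (LC3/Atg8-family or SUMO) with a
peptide fragment, per-residue pLDDT confidence (stored in the B-factor column
by AlphaFold and AlphaPulldown) and a pairwise predicted-aligned-error (PAE)
matrix in the AlphaFold JSON dialect.  Structures are accepted in PDB or mmCIF
format via gemmi; pLDDT is always taken from the B-factor column regardless of
format.

The PAE matrix is oriented so that ``pae[i, j]`` is the expected error at
residue ``j`` when the prediction is aligned on residue ``i``; a residue's
confidence in the *scored* role therefore lives in its column.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "PredictedComplex",
    "StructureError",
    "load_predicted_complex",
    "write_predicted_complex",
    "load_pae_matrix",
    "compute_min_pae",
    "peptide_min_pae",
    "add_backbone_hydrogens",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised when a structure or PAE file violates the input contract."""


@dataclass
class Residue:
    """One residue: name, author index and heavy-atom (plus amide H) coordinates."""

    name: str                       # 3-letter code
    index: int                      # author residue number (1-based, from file)
    atoms: dict[str, np.ndarray]    # atom name -> xyz in Angstrom

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def heavy_atoms(self) -> dict[str, np.ndarray]:
        return {n: c for n, c in self.atoms.items() if not n.startswith("H")}

    def get(self, name: str) -> np.ndarray | None:
        return self.atoms.get(name)


@dataclass
class PredictedComplex:
    """Receptor + peptide chains with pLDDT and a PAE matrix.

    Residues are ordered receptor-first; ``plddt`` and the PAE axes follow that
    global order (length = total residue count).
    """

    model_id: str
    receptor: list[Residue]
    peptide: list[Residue]
    plddt: np.ndarray
    pae: np.ndarray
    model_rank: int = 1
    receptor_chain_id: str = "A"
    peptide_chain_id: str = "B"

    def __post_init__(self) -> None:
        n = len(self.receptor) + len(self.peptide)
        if not self.receptor or not self.peptide:
            raise StructureError("both chains must be non-empty")
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        if self.plddt.shape != (n,):
            raise StructureError(
                f"pLDDT length {self.plddt.shape} does not match residue count {n}"
            )
        if self.pae.shape != (n, n):
            raise StructureError(
                f"PAE/structure length mismatch: matrix {self.pae.shape}, {n} residues"
            )
        if np.any(self.pae < 0):
            raise StructureError("PAE values must be non-negative")
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            warnings.warn("pLDDT outside [0, 100]; clamping", stacklevel=2)
            self.plddt = np.clip(self.plddt, 0.0, 100.0)
        for chain in (self.receptor, self.peptide):
            idx = [r.index for r in chain]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise StructureError("residue indices must be strictly increasing")

    @property
    def n_residues(self) -> int:
        return len(self.receptor) + len(self.peptide)

    @property
    def peptide_offset(self) -> int:
        """Global position (0-based) of the first peptide residue."""
        return len(self.receptor)

    def peptide_plddt(self) -> np.ndarray:
        return self.plddt[self.peptide_offset:]

    def receptor_by_index(self, index: int) -> Residue:
        for r in self.receptor:
            if r.index == index:
                return r
        raise StructureError(f"receptor has no residue {index}")


def _chain_to_residues(chain: gemmi.Chain) -> tuple[list[Residue], list[float]]:
    residues, plddt = [], []
    for res in chain:
        atoms = {at.name: np.array([at.pos.x, at.pos.y, at.pos.z]) for at in res}
        ca = next((at for at in res if at.name == "CA"), None)
        b = ca.b_iso if ca is not None else res[0].b_iso
        residues.append(Residue(res.name, res.seqid.num, atoms))
        plddt.append(float(b))
    return residues, plddt


def load_structure_chain(
    structure_file: str | Path, chain_id: str | None = None
) -> tuple[list[Residue], np.ndarray]:
    """Read one chain (default: the first) of a PDB/mmCIF file.

    Returns the residues and the per-residue B-factor column interpreted as
    pLDDT.  Used for full-length single-protein structures in the occlusion
    analysis.
    """
    st = gemmi.read_structure(str(structure_file))
    st.setup_entities()
    model = st[0]
    if chain_id is None:
        chain = model[0]
    else:
        chains = {ch.name: ch for ch in model}
        if chain_id not in chains:
            raise StructureError(
                f"chain {chain_id!r} not found; available: {sorted(chains)}"
            )
        chain = chains[chain_id]
    residues, plddt = _chain_to_residues(chain)
    return residues, np.array(plddt)


def load_pae_matrix(pae_file: str | Path, key: str | None = None) -> np.ndarray:
    """Load a PAE matrix from an AlphaFold-dialect JSON file.

    Accepts the flat object form ``{"predicted_aligned_error": [[...]]}`` or
    ``{"pae": [[...]]}``, and the EBI list-of-objects wrapper.  ``key`` forces
    a specific field name for nonstandard dialects.
    """
    with open(pae_file) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        data = data[0]
    keys = (key,) if key else ("predicted_aligned_error", "pae")
    for k in keys:
        if k in data:
            return np.asarray(data[k], dtype=float)
    raise StructureError(
        f"no PAE field in {pae_file}; tried {keys}, found {sorted(data)}"
    )


def load_predicted_complex(
    structure_file: str | Path,
    pae_file: str | Path,
    receptor_chain_id: str = "A",
    peptide_chain_id: str = "B",
    pae_key: str | None = None,
    model_rank: int = 1,
) -> PredictedComplex:
    """Read a two-chain predicted structure plus its PAE matrix.

    The B-factor column is interpreted as per-residue pLDDT.  Chains other
    than the two named ones are ignored.  Raises :class:`StructureError` when
    a named chain is missing or when the PAE side does not equal the total
    residue count of the two chains.
    """
    st = gemmi.read_structure(str(structure_file))
    st.setup_entities()
    model = st[0]
    chains = {ch.name: ch for ch in model}
    for cid in (receptor_chain_id, peptide_chain_id):
        if cid not in chains:
            raise StructureError(
                f"chain {cid!r} not found in {structure_file}; "
                f"available chains: {sorted(chains)}"
            )
    receptor, b_rec = _chain_to_residues(chains[receptor_chain_id])
    peptide, b_pep = _chain_to_residues(chains[peptide_chain_id])
    pae = load_pae_matrix(pae_file, key=pae_key)
    n = len(receptor) + len(peptide)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise StructureError(f"PAE matrix is not square: {pae.shape}")
    if pae.shape[0] != n:
        raise StructureError(
            f"length mismatch: PAE side {pae.shape[0]} but {n} residues"
        )
    return PredictedComplex(
        model_id=Path(structure_file).stem,
        receptor=receptor,
        peptide=peptide,
        plddt=np.array(b_rec + b_pep),
        pae=pae,
        model_rank=model_rank,
        receptor_chain_id=receptor_chain_id,
        peptide_chain_id=peptide_chain_id,
    )


def write_predicted_complex(
    cx: PredictedComplex,
    structure_file: str | Path,
    pae_file: str | Path | None = None,
) -> None:
    """Write the complex as a PDB file (pLDDT in B-factors) and PAE JSON."""
    st = gemmi.Structure()
    st.name = cx.model_id
    model = gemmi.Model("1")
    pl = iter(cx.plddt)
    for cid, chain_res in (
        (cx.receptor_chain_id, cx.receptor),
        (cx.peptide_chain_id, cx.peptide),
    ):
        chain = gemmi.Chain(cid)
        for res in chain_res:
            b = float(next(pl))
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            for aname, xyz in res.atoms.items():
                at = gemmi.Atom()
                at.name = aname
                at.element = gemmi.Element(aname[0])
                at.pos = gemmi.Position(*map(float, xyz))
                at.b_iso = b
                at.occ = 1.0
                gres.add_atom(at)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(structure_file))
    if pae_file is not None:
        with open(pae_file, "w") as fh:
            json.dump(
                {"predicted_aligned_error": np.round(cx.pae, 3).tolist()}, fh
            )


def compute_min_pae(cx: PredictedComplex, position: int, k: int = 3) -> float:
    """minPAE of the residue at global ``position`` (0-based).

    The mean of the ``k`` lowest entries of the residue's PAE *column*, i.e.
    of the errors reported when the residue is used for scoring but not for
    aligning.  The diagonal self-entry is excluded.
    """
    n = cx.pae.shape[0]
    if not 0 <= position < n:
        raise StructureError(f"residue position {position} outside PAE matrix ({n})")
    if n < k + 1:
        raise StructureError(f"PAE side {n} too small for {k} off-diagonal values")
    col = np.delete(cx.pae[:, position], position)
    return float(np.mean(np.sort(col)[:k]))


def peptide_min_pae(cx: PredictedComplex, k: int = 3) -> np.ndarray:
    """Per-peptide-residue minPAE profile (fragment-local order)."""
    off = cx.peptide_offset
    return np.array(
        [compute_min_pae(cx, off + i, k=k) for i in range(len(cx.peptide))]
    )


def add_backbone_hydrogens(cx: PredictedComplex) -> PredictedComplex:
    """Return a copy with amide hydrogens placed on backbone nitrogens.

    Predicted structures carry no hydrogens, so the amide H needed for the
    DSSP hydrogen-bond energy is reconstructed: H sits 1.0 Angstrom from N
    along the unit vector from the preceding residue's carbonyl O to its C
    (the DSSP convention, anti to the preceding C=O).  Prolines and chain
    N-termini receive no H; residues with missing backbone atoms are skipped
    with a warning.  Heavy-atom coordinates are untouched.
    """
    def process(chain: list[Residue]) -> list[Residue]:
        out = []
        prev: Residue | None = None
        for res in chain:
            atoms = dict(res.atoms)
            if prev is not None and res.name != "PRO":
                n = atoms.get("N")
                c_prev, o_prev = prev.get("C"), prev.get("O")
                if n is None or c_prev is None or o_prev is None:
                    warnings.warn(
                        f"residue {res.name}{res.index}: backbone atoms missing, "
                        "no amide H placed",
                        stacklevel=3,
                    )
                else:
                    d = c_prev - o_prev
                    nrm = np.linalg.norm(d)
                    if nrm > 1e-9:
                        atoms["H"] = n + d / nrm
            out.append(Residue(res.name, res.index, atoms))
            prev = res
        return out

    return replace(cx, receptor=process(cx.receptor), peptide=process(cx.peptide))
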