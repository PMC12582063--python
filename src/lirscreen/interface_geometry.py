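"""Geometric predicates on the receptor-peptide interface.

Three families of measurements drive the interaction classifier:

* **Pocket engagement** -- a peptide residue engages one of the hydrophobic
  pockets (HP0/HP1/HP2) of an LC3/Atg8-family receptor when any of its heavy
  atoms lies within two anchor-specific distance cutoffs of the pocket's two
  anchor Calpha atoms.  HP0 additionally requires the pocket to be open, read
  off the displacement of a gate residue's sidechain.
* **Backbone hydrogen bonds** -- counted with the DSSP electrostatic model
  E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332 kcal/mol between an
  N-H donor and a C=O acceptor; a pair is a bond when E < -0.5 kcal/mol.
* **Calpha contacts** -- pairs of Calpha atoms closer than 5 Angstrom.

Receptor-specific residue numbers and cutoffs live in a packaged YAML table
(:func:`load_receptor_profiles`) covering LC3B, GABARAP, Atg8, ATG8E, ATG8CL
and SUMO2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .stretch_detector import Stretch
from .structure_io import PredictedComplex, Residue

__all__ = [
    "PocketSpec",
    "GateSpec",
    "ReceptorProfile",
    "PocketAssignment",
    "load_receptor_profiles",
    "get_receptor_profile",
    "assign_pocket",
    "hp0_gate_open",
    "dssp_hbond_energy",
    "count_backbone_hbonds",
    "count_ca_contacts",
]

HBOND_ENERGY_CUTOFF = -0.5   # kcal/mol, DSSP default
CA_CONTACT_CUTOFF = 5.0      # Angstrom


@dataclass(frozen=True)
class PocketSpec:
    anchor1: int
    cutoff1: float
    anchor2: int
    cutoff2: float


@dataclass(frozen=True)
class GateSpec:
    ca_residue: int
    sidechain_residue: int
    open_threshold: float = 9.0


@dataclass(frozen=True)
class ReceptorProfile:
    """Residue numbering and distance cutoffs for one receptor isoform."""

    name: str
    family: str                      # "LC3" or "SUMO"
    hp0: PocketSpec | None = None
    hp0_gate: GateSpec | None = None
    hp1: PocketSpec | None = None
    hp2: PocketSpec | None = None
    beta2_range: tuple[int, int] | None = None
    uds_range: tuple[int, int] | None = None
    sim_groove_range: tuple[int, int] | None = None

    def pocket(self, pocket_id: str) -> PocketSpec:
        spec = {"HP0": self.hp0, "HP1": self.hp1, "HP2": self.hp2}[pocket_id]
        if spec is None:
            raise ValueError(f"{self.name} has no pocket {pocket_id}")
        return spec


@dataclass(frozen=True)
class PocketAssignment:
    pocket: str                       # HP0 / HP1 / HP2
    residue: int | None               # fragment-local 1-based position, or None
    gate_open: bool | None = None     # HP0 only

    @property
    def engaged(self) -> bool:
        return self.residue is not None


def _parse_profile(name: str, raw: dict) -> ReceptorProfile:
    def pocket(key):
        p = raw.get(key)
        return PocketSpec(p["anchor1"], p["cutoff1"], p["anchor2"], p["cutoff2"]) if p else None

    gate = raw.get("hp0_gate")
    return ReceptorProfile(
        name=name,
        family=raw["family"],
        hp0=pocket("hp0"),
        hp0_gate=GateSpec(gate["ca_residue"], gate["sidechain_residue"],
                          gate["open_threshold"]) if gate else None,
        hp1=pocket("hp1"),
        hp2=pocket("hp2"),
        beta2_range=tuple(raw["beta2"]) if "beta2" in raw else None,
        uds_range=tuple(raw["uds"]) if "uds" in raw else None,
        sim_groove_range=tuple(raw["sim_groove"]) if "sim_groove" in raw else None,
    )


def load_receptor_profiles(path: str | Path | None = None) -> dict[str, ReceptorProfile]:
    """Load the receptor anchor tables (packaged defaults unless a path is given)."""
    if path is None:
        text = resources.files("lirscreen.data").joinpath("receptors.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {name: _parse_profile(name, entry) for name, entry in raw["receptors"].items()}


_PROFILE_CACHE: dict[str, ReceptorProfile] | None = None


def get_receptor_profile(name: str) -> ReceptorProfile:
    global _PROFILE_CACHE
    if _PROFILE_CACHE is None:
        _PROFILE_CACHE = load_receptor_profiles()
    try:
        return _PROFILE_CACHE[name]
    except KeyError:
        raise KeyError(
            f"unknown receptor {name!r}; available: {sorted(_PROFILE_CACHE)}"
        ) from None


# ---------------------------------------------------------------------------
# predicates

def _stretch_residues(cx: PredictedComplex, stretch: Stretch) -> list[Residue]:
    if stretch.end > len(cx.peptide):
        raise ValueError("stretch extends beyond peptide chain")
    return [cx.peptide[i] for i in stretch.local_range]


def _receptor_ca(cx: PredictedComplex, index: int) -> np.ndarray:
    res = cx.receptor_by_index(index)
    ca = res.get("CA")
    if ca is None:
        raise ValueError(f"receptor residue {index} has no CA atom")
    return ca


def hp0_gate_open(cx: PredictedComplex, gate: GateSpec) -> bool:
    """HP0 is open when the gate sidechain has swung away from the pocket.

    Measured as the minimum distance between the pocket Calpha and any
    non-hydrogen sidechain atom of the gate residue; open when strictly
    greater than the threshold (9.0 Angstrom by default).  A gate residue
    without sidechain atoms (glycine) leaves the pocket open.
    """
    ca = _receptor_ca(cx, gate.ca_residue)
    partner = cx.receptor_by_index(gate.sidechain_residue)
    side = [
        xyz
        for name, xyz in partner.heavy_atoms().items()
        if name not in ("N", "CA", "C", "O", "OXT")
    ]
    if not side:
        return True
    dmin = min(float(np.linalg.norm(xyz - ca)) for xyz in side)
    return dmin > gate.open_threshold


def assign_pocket(
    cx: PredictedComplex,
    stretch: Stretch,
    profile: ReceptorProfile,
    pocket_id: str,
) -> PocketAssignment:
    """First stretch residue (N to C) engaging the pocket, if any.

    A residue engages when any of its heavy atoms (backbone included) is
    within ``cutoff1`` of anchor1's Calpha and within ``cutoff2`` of anchor2's
    Calpha; comparisons are strict.  For HP0 the gate must additionally be
    open, otherwise no residue is assigned.
    """
    spec = profile.pocket(pocket_id)
    gate_open: bool | None = None
    if pocket_id == "HP0":
        if profile.hp0_gate is None:
            raise ValueError(f"{profile.name}: HP0 requires a gate definition")
        gate_open = hp0_gate_open(cx, profile.hp0_gate)
        if not gate_open:
            return PocketAssignment(pocket_id, None, gate_open=False)
    a1 = _receptor_ca(cx, spec.anchor1)
    a2 = _receptor_ca(cx, spec.anchor2)
    for pos, res in zip(stretch.local_range, _stretch_residues(cx, stretch)):
        coords = np.array(list(res.heavy_atoms().values()))
        if coords.size == 0:
            continue
        d1 = np.linalg.norm(coords - a1, axis=1)
        d2 = np.linalg.norm(coords - a2, axis=1)
        if np.any((d1 < spec.cutoff1) & (d2 < spec.cutoff2)):
            return PocketAssignment(pocket_id, pos + 1, gate_open=gate_open)
    return PocketAssignment(pocket_id, None, gate_open=gate_open)


def dssp_hbond_energy(
    donor_n: np.ndarray,
    donor_h: np.ndarray,
    acceptor_c: np.ndarray,
    acceptor_o: np.ndarray,
) -> float:
    """DSSP electrostatic H-bond energy in kcal/mol for one N-H...O=C pair."""
    r_on = np.linalg.norm(acceptor_o - donor_n)
    r_ch = np.linalg.norm(acceptor_c - donor_h)
    r_oh = np.linalg.norm(acceptor_o - donor_h)
    r_cn = np.linalg.norm(acceptor_c - donor_n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        return 0.0
    return float(0.084 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn) * 332)


def _hbond_pairs(
    donors: list[Residue], acceptors: list[Residue], cutoff: float
) -> int:
    count = 0
    for don in donors:
        n, h = don.get("N"), don.get("H")
        if n is None or h is None:
            # prolines and chain N-termini legitimately carry no amide H
            if n is None:
                warnings.warn(
                    f"residue {don.name}{don.index}: backbone N missing, "
                    "donor skipped",
                    stacklevel=3,
                )
            continue
        for acc in acceptors:
            c, o = acc.get("C"), acc.get("O")
            if c is None or o is None:
                warnings.warn(
                    f"residue {acc.name}{acc.index}: no C=O, acceptor skipped",
                    stacklevel=3,
                )
                continue
            if dssp_hbond_energy(n, h, c, o) < cutoff:
                count += 1
    return count


def count_backbone_hbonds(
    cx: PredictedComplex,
    stretch: Stretch,
    receptor_range: tuple[int, int],
    energy_cutoff: float = HBOND_ENERGY_CUTOFF,
) -> int:
    """Backbone H-bonds between the stretch and a receptor residue range.

    Both directions are counted (stretch N-H donating to receptor C=O and
    vice versa).  Amide hydrogens must have been placed beforehand
    (:func:`lirscreen.structure_io.add_backbone_hydrogens`); donors or
    acceptors with missing atoms are skipped with a warning.  The cutoff is
    strict: a pair at exactly the threshold energy is not counted.
    """
    lo, hi = receptor_range
    rec = [r for r in cx.receptor if lo <= r.index <= hi]
    pep = _stretch_residues(cx, stretch)
    return _hbond_pairs(pep, rec, energy_cutoff) + _hbond_pairs(rec, pep, energy_cutoff)


def count_ca_contacts(
    cx: PredictedComplex,
    stretch: Stretch,
    receptor_range: tuple[int, int],
    cutoff: float = CA_CONTACT_CUTOFF,
) -> int:
    """Number of (stretch Calpha, receptor-range Calpha) pairs below ``cutoff``."""
    lo, hi = receptor_range
    rec = [r.get("CA") for r in cx.receptor if lo <= r.index <= hi]
    pep = [r.get("CA") for r in _stretch_residues(cx, stretch)]
    rec = np.array([c for c in rec if c is not None])
    pep = np.array([c for c in pep if c is not None])
    if rec.size == 0 or pep.size == 0:
        return 0
    d = np.linalg.norm(pep[:, None, :] - rec[None, :, :], axis=2)
    return int(np.sum(d < cutoff))
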