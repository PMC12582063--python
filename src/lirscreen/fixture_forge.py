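"""Synthetic complexes, score profiles and full-length structures for testing.

The classifier consumes nothing but distances, backbone hydrogen-bond
geometry and per-residue confidence scores, so a minimal geometric scaffold
is the sufficient test surface: receptor residues sit on parking lines far
from the action, and only the atoms a predicate reads (anchor Calphas, the
HP0 gate sidechain, crafted donor/acceptor backbones, contact Calphas) are
placed deliberately.  Every fixture is self-validating -- feeding it through
stretch detection and classification must return the label it was built for
-- and deterministic under its seed (the seed only jitters parked atoms, so
predicates are unaffected).

Also provided: an end-to-end screen corpus for a synthetic 120-residue target
with one exposed canonical LIR and one buried decoy (fragment predictions,
phosphosites, full-length structure), and ideal helix/strand builders with
textbook backbone geometry for secondary-structure tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fragmenter import (
    FragmentRecord,
    TargetSequence,
    all_st_sites,
    apply_phosphomimetic,
    deduplicate_fragments,
    fragment_id,
    tile_sequence,
)
from .interface_geometry import ReceptorProfile, get_receptor_profile
from .structure_io import (
    ONE_TO_THREE,
    PredictedComplex,
    Residue,
    write_predicted_complex,
)

__all__ = [
    "FixtureSpec",
    "LABEL_RECIPES",
    "make_receptor_scaffold",
    "make_peptide_pose",
    "write_fixture",
    "generate_label_corpus",
    "synthetic_target",
    "make_screen_corpus",
    "make_full_length_structure",
    "build_backbone",
    "ideal_helix",
    "ideal_strand_pair",
    "fragment_file_stem",
]

# geometry of the crafted DSSP hydrogen bond: N-H...O=C collinear with
# |N-H| = 1.0, |H...O| = 1.9, |C=O| = 1.23 Angstrom -> E ~ -2.9 kcal/mol
_HB_NO = 2.9
_HB_CO = 1.23

_PARK_JITTER = 0.05


def fragment_file_stem(fid: str) -> str:
    """Filesystem-safe stem for a fragment id (``P1|5-20|WT`` -> ``P1_5-20_WT``)."""
    return fid.replace("|", "_")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe request for one synthetic complex.

    ``n_hbonds``/``n_contacts``/``gate_distance`` override the label's
    defaults for threshold sweeps; ``confident`` controls whether the peptide
    score profiles pass stretch detection at all.
    """

    label: str
    receptor: str = "LC3B"
    sequence: str | None = None
    gate_distance: float = 10.0
    n_hbonds: int | None = None
    n_contacts: int | None = None
    confident: bool = True
    seed: int = 0


class _Builder:
    """Mutable scaffold: receptor + peptide residues with parked atoms."""

    def __init__(self, profile: ReceptorProfile, sequence: str, seed: int = 0):
        self.profile = profile
        rng = np.random.default_rng(seed)

        def jitter() -> np.ndarray:
            return rng.uniform(-_PARK_JITTER, _PARK_JITTER, 3)

        indices = []
        for spec in (profile.hp0, profile.hp1, profile.hp2):
            if spec:
                indices += [spec.anchor1, spec.anchor2]
        if profile.hp0_gate:
            indices += [profile.hp0_gate.ca_residue, profile.hp0_gate.sidechain_residue]
        for rng_ in (profile.beta2_range, profile.uds_range, profile.sim_groove_range):
            if rng_:
                indices += list(rng_)
        n_rec = max(indices)
        self.receptor: list[Residue] = []
        for i in range(1, n_rec + 1):
            base = np.array([3.0 * i, -50.0, 0.0])
            park = np.array([3.0 * i, -80.0, 0.0])
            atoms = {
                "N": park + np.array([-0.5, 0.0, 0.0]) + jitter(),
                "CA": base + jitter(),
                "C": park + np.array([0.5, 0.0, 0.0]) + jitter(),
                "O": park + np.array([0.5, 1.23, 0.0]) + jitter(),
            }
            name = "GLY"
            if profile.hp0_gate and i == profile.hp0_gate.sidechain_residue:
                name = "ALA"
                atoms["CB"] = park + np.array([0.0, -1.5, 0.0]) + jitter()
            self.receptor.append(Residue(name, i, atoms))

        self.sequence = sequence
        self.peptide: list[Residue] = []
        for i, aa in enumerate(sequence, start=1):
            base = np.array([3.0 * i, 50.0, 0.0])
            park = np.array([3.0 * i, 80.0, 0.0])
            atoms = {
                "N": park + np.array([-0.5, 0.0, 0.0]) + jitter(),
                "CA": base + jitter(),
                "C": park + np.array([0.5, 0.0, 0.0]) + jitter(),
                "O": park + np.array([0.5, 1.23, 0.0]) + jitter(),
            }
            self.peptide.append(Residue(ONE_TO_THREE[aa], i, atoms))
        self._hb_slot = 0
        self._contact_slot: dict[int, float] = {}

    # -- receptor-side placement -------------------------------------------

    def _rec(self, index: int) -> Residue:
        return self.receptor[index - 1]

    def place_pockets(self, gate_distance: float) -> None:
        """Pin anchor Calphas (and the beta-2 strand) to the canonical local
        frame: HP1 at the origin, HP2 at +8 x, HP0 at -8 x."""
        p = self.profile
        coords = {
            p.hp1.anchor1: (0.0, 0.0, 0.0),
            p.hp1.anchor2: (0.0, 0.0, 6.0),
            p.hp2.anchor1: (8.0, 0.0, 0.0),
            p.hp2.anchor2: (8.0, 0.0, 6.0),
            p.hp0.anchor1: (-8.0, 0.0, 0.0),
            p.hp0.anchor2: (-8.0, 0.0, 4.0),
        }
        b = p.beta2_range[0]
        # x-spacing avoids any pair sitting exactly at the 5-Angstrom
        # contact cutoff, which would flip under rigid-motion round-off
        for offset, x in enumerate((-6.0, -3.0, 0.0, 4.3, 8.0, 11.0)):
            coords.setdefault(b + offset, (x, 0.0, 0.0))
        for index, xyz in coords.items():
            self._rec(index).atoms["CA"] = np.array(xyz)
        gate = p.hp0_gate
        self._rec(gate.sidechain_residue).atoms["CB"] = np.array(
            [-8.0, gate_distance, 0.0]
        )

    def place_groove(self) -> None:
        lo, hi = self.profile.sim_groove_range
        for offset, index in enumerate(range(lo, hi + 1)):
            self._rec(index).atoms["CA"] = np.array([3.0 * offset, 0.0, 0.0])

    # -- peptide-side placement --------------------------------------------

    def engage(self, pocket: str, pos: int) -> None:
        """Move the peptide residue's Calpha into the pocket's sweet spot."""
        site = {
            "HP1": (0.0, 3.0, 0.0),
            "HP2": (8.0, 3.0, 0.0),
            "HP0": (-8.0, 2.0, 0.0),
        }[pocket]
        self.peptide[pos - 1].atoms["CA"] = np.array(site)

    def craft_hbonds(
        self, donors: tuple[int, ...], acceptors: list[int], n: int
    ) -> None:
        """Create exactly ``n`` DSSP hydrogen bonds: peptide ``donors[k]``
        N-H donates to receptor ``acceptors[k]`` C=O, collinear geometry in a
        zone far from pockets and contact slots."""
        if n > min(len(donors), len(acceptors)):
            raise ValueError("not enough donor/acceptor slots for requested bonds")
        d = np.array([0.0, 0.0, -1.0])
        for k in range(n):
            slot = self._hb_slot
            self._hb_slot += 1
            n_pos = np.array([25.0 + 4.0 * slot, 0.0, 12.0])
            don = self.peptide[donors[k] - 1]
            prev = self.peptide[donors[k] - 2]
            don.atoms["N"] = n_pos
            prev.atoms["C"] = prev.atoms["O"] + d  # sets the amide-H direction
            acc = self._rec(acceptors[k])
            acc.atoms["O"] = n_pos + _HB_NO * d
            acc.atoms["C"] = n_pos + (_HB_NO + _HB_CO) * d

    def craft_contacts(self, pairs: list[tuple[int, int]]) -> None:
        """Place Calpha contacts: each (peptide pos, receptor index) pair at
        2 Angstrom, pairs isolated on a z = -15 rail 12 Angstrom apart."""
        used: dict[int, int] = {}
        for pep_pos, rec_index in pairs:
            if rec_index not in self._contact_slot:
                x = 12.0 * len(self._contact_slot)
                self._contact_slot[rec_index] = x
                self._rec(rec_index).atoms["CA"] = np.array([x, 0.0, -15.0])
            x = self._contact_slot[rec_index]
            side = used.get(rec_index, 0)
            used[rec_index] = side + 1
            y = 2.0 if side == 0 else -2.0
            self.peptide[pep_pos - 1].atoms["CA"] = np.array([x, y, -15.0])

    # -- assembly ----------------------------------------------------------

    def build(
        self,
        model_id: str,
        confident_region: set[int] | None = None,
        confident: bool = True,
    ) -> PredictedComplex:
        """Assemble the complex with score profiles.

        ``confident_region``: fragment-local positions given pLDDT 90 /
        column-PAE 3 (the rest 30/30, failing detection); None means the
        whole peptide is confident (or nothing, when ``confident`` is False).
        """
        n_rec, n_pep = len(self.receptor), len(self.peptide)
        n = n_rec + n_pep
        plddt = np.full(n, 90.0)
        pae = np.full((n, n), 20.0)
        if confident_region is None:
            confident_region = set(range(1, n_pep + 1)) if confident else set()
        for j in range(n_pep):
            good = (j + 1) in confident_region
            plddt[n_rec + j] = 90.0 if good else 30.0
            pae[:, n_rec + j] = 3.0 if good else 30.0
        return PredictedComplex(
            model_id=model_id,
            receptor=[Residue(r.name, r.index, dict(r.atoms)) for r in self.receptor],
            peptide=[Residue(r.name, r.index, dict(r.atoms)) for r in self.peptide],
            plddt=plddt,
            pae=pae,
        )


def make_receptor_scaffold(
    profile: ReceptorProfile, gate_distance: float = 10.0, seed: int = 0
) -> list[Residue]:
    """Receptor-only scaffold with anchors pinned (LC3 family) or the SIM
    groove placed (SUMO)."""
    b = _Builder(profile, "A", seed=seed)
    if profile.family == "LC3":
        b.place_pockets(gate_distance)
    else:
        b.place_groove()
    return b.receptor


# -- per-label recipes ------------------------------------------------------

@dataclass(frozen=True)
class _Recipe:
    sequence: str
    pockets: dict[str, int] = field(default_factory=dict)   # pocket -> pep pos
    donors: tuple[int, ...] = ()
    n_hbonds: int = 0
    contact_pocketless: bool = False     # leave anchors parked
    contact_range: str | None = None     # 'beta2' or 'uds'
    n_contacts: int = 0
    checks: tuple[tuple[int, str], ...] = ()   # (pos, allowed aa) feasibility


LABEL_RECIPES: dict[str, _Recipe] = {
    "can.LIR": _Recipe(
        "SAFEMLAASA", {"HP1": 3, "HP2": 6}, donors=(4, 5), n_hbonds=2,
        checks=((3, "WFY"), (6, "LIV")),
    ),
    "ap.LIR": _Recipe(
        "SALEMFAASA", {"HP2": 3, "HP1": 6}, donors=(4, 5), n_hbonds=2,
        checks=((6, "WFY"), (3, "LIV")),
    ),
    "HP0-LIR": _Recipe(
        "AFALAALAAS", {"HP0": 2, "HP2": 7},
        checks=((2, "WFY"), (4, "LIV"), (7, "LIV")),
    ),
    "2-HP-LIR": _Recipe(
        "SAAEMAAASA", {"HP1": 3, "HP2": 6},
        checks=((3, "ACDEGHKMNPQRST"), (6, "ACDEGHKMNPQRST")),
    ),
    "CLIR": _Recipe(
        "AAMLLAAASA", {"HP2": 5}, donors=(7, 8), n_hbonds=2,
        checks=((3, "LIVM"), (4, "LIVM"), (5, "LIV")),
    ),
    "sAIM": _Recipe(
        "ALAFAAAASA", {"HP1": 4}, checks=((2, "LIV"), (4, "WFY")),
    ),
    "[DE]W[DE]-LIR": _Recipe(
        "ADWEAAAASA", {"HP1": 3}, checks=((2, "DE"), (3, "W"), (4, "DE")),
    ),
    "lcLIR": _Recipe("AAAEAAAASA", {"HP1": 3}, checks=((3, "ACDEGHKMNPQRST"),)),
    "other@LDS": _Recipe(
        "AAAAAAAAAA", contact_pocketless=True, contact_range="beta2", n_contacts=5
    ),
    "UIM-like": _Recipe(
        "AAAAAAAAAA", contact_pocketless=True, contact_range="uds", n_contacts=5
    ),
    "other": _Recipe("AAAAAAAAAA", contact_pocketless=True),
    # dual-match fixture: satisfies both the CLIR and sAIM patterns; the
    # cascade order decides (CLIR first)
    "CLIR+sAIM": _Recipe(
        "LAFAMLLAAA", {"HP0": 3, "HP2": 7}, donors=(9, 10), n_hbonds=2,
        checks=((1, "LIV"), (3, "WFY"), (5, "LIVM"), (6, "LIVM"), (7, "LIV")),
    ),
    "SIM": _Recipe("AVIDLTAASA", donors=(5, 7, 9), n_hbonds=3),
}


def make_peptide_pose(spec: FixtureSpec) -> PredictedComplex:
    """Build a complex whose pipeline classification equals ``spec.label``.

    Raises ``ValueError`` for infeasible requests (unknown label, or a
    sequence override lacking the residues the target pattern needs).
    """
    profile = get_receptor_profile(spec.receptor)
    if profile.family == "SUMO":
        recipe = LABEL_RECIPES["SIM"]
        if spec.label not in ("SIM", "other"):
            raise ValueError(f"label {spec.label!r} not defined for SUMO receptors")
        n_hb = spec.n_hbonds
        if n_hb is None:
            n_hb = 3 if spec.label == "SIM" else 1
        seq = spec.sequence or recipe.sequence
        b = _Builder(profile, seq, seed=spec.seed)
        b.place_groove()
        lo, hi = profile.sim_groove_range
        b.craft_hbonds(recipe.donors, list(range(lo, hi + 1)), n_hb)
        return b.build(f"fixture_{spec.label}", confident=spec.confident)

    if spec.label not in LABEL_RECIPES:
        raise ValueError(
            f"unknown label {spec.label!r}; known: {sorted(LABEL_RECIPES)}"
        )
    recipe = LABEL_RECIPES[spec.label]
    seq = spec.sequence or recipe.sequence
    if len(seq) < len(recipe.sequence):
        raise ValueError("sequence override too short for this recipe")
    for pos, allowed in recipe.checks:
        if seq[pos - 1] not in allowed:
            raise ValueError(
                f"infeasible: label {spec.label!r} needs residue {pos} in "
                f"[{allowed}], got {seq[pos - 1]!r}"
            )
    b = _Builder(profile, seq, seed=spec.seed)
    if not recipe.contact_pocketless:
        b.place_pockets(spec.gate_distance)
        for pocket, pos in recipe.pockets.items():
            b.engage(pocket, pos)
        n_hb = recipe.n_hbonds if spec.n_hbonds is None else spec.n_hbonds
        if n_hb:
            lo, _hi = profile.beta2_range
            acceptors = [lo + 1, lo + 3, lo + 5, lo + 2]  # non-anchor beta2 first
            b.craft_hbonds(recipe.donors or (4, 5, 8, 9), acceptors, n_hb)
    elif recipe.contact_range:
        n_con = recipe.n_contacts if spec.n_contacts is None else spec.n_contacts
        lo, hi = (
            profile.beta2_range
            if recipe.contact_range == "beta2"
            else profile.uds_range
        )
        rec_indices = list(range(lo, hi + 1))
        pairs = [
            (p + 1, rec_indices[p % len(rec_indices)]) for p in range(n_con)
        ]
        b.craft_contacts(pairs)
    return b.build(f"fixture_{spec.label}", confident=spec.confident)


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> tuple[Path, Path]:
    """Materialise a fixture as PDB + PAE JSON in the dialect the loader reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cx = make_peptide_pose(spec)
    stem = spec.label.replace("[", "").replace("]", "").replace("/", "-")
    pdb = outdir / f"{stem}.pdb"
    pae = outdir / f"{stem}_pae.json"
    write_predicted_complex(cx, pdb, pae)
    return pdb, pae


def generate_label_corpus(outdir: str | Path, seed: int = 0) -> dict[str, tuple[Path, Path]]:
    """One on-disk fixture per classifier label (plus the precedence case)."""
    out = {}
    for label in LABEL_RECIPES:
        receptor = "SUMO2" if label == "SIM" else "LC3B"
        out[label] = write_fixture(
            FixtureSpec(label=label, receptor=receptor, seed=seed), outdir
        )
    out["other(SUMO)"] = write_fixture(
        FixtureSpec(label="other", receptor="SUMO2", seed=seed),
        Path(outdir) / "sumo_other",
    )
    return out


# -- end-to-end screen corpus ----------------------------------------------

@dataclass(frozen=True)
class PlantedMotif:
    """Ground truth for one planted canonical LIR in the synthetic target."""

    theta: int      # parent position of the HP1-binding aromatic
    gamma: int      # parent position of the HP2-binding aliphatic (theta + 3)
    buried: bool


def synthetic_target() -> tuple[TargetSequence, list[PlantedMotif]]:
    """A 120-residue target with one exposed canonical LIR (planted) and one
    canonical-looking decoy that the full-length structure buries."""
    seq = list("A" * 120)
    seq[14], seq[15], seq[16], seq[17] = "F", "E", "E", "I"   # decoy, 15-18
    seq[84], seq[85], seq[86], seq[87] = "W", "E", "E", "L"   # planted, 85-88
    for pos in (30, 60, 90, 110):
        seq[pos - 1] = "S"
    target = TargetSequence("SYN1", "".join(seq), phosphosites=all_st_sites("".join(seq)))
    motifs = [
        PlantedMotif(theta=15, gamma=18, buried=True),
        PlantedMotif(theta=85, gamma=88, buried=False),
    ]
    return target, motifs


def _grid_ball(inner: float, outer: float, spacing: float) -> np.ndarray:
    """Simple-cubic grid points with ``inner <= |p| <= outer``.

    With spacing 3.0 and a 1.5-Angstrom probe the occupied band is sealed:
    the worst void (a cube body centre) sits ~2.6 Angstrom from the nearest
    atoms, closer than the 3.2-Angstrom atom-plus-probe radius.
    """
    ax = np.arange(-outer, outer + spacing / 2, spacing)
    pts = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T
    r = np.linalg.norm(pts, axis=1)
    return pts[(r >= inner - 1e-6) & (r <= outer + 1e-6)]


def make_full_length_structure(
    target: TargetSequence,
    buried_range: tuple[int, int],
    path: str | Path,
    plddt: float = 90.0,
) -> Path:
    """Synthetic full-length structure: ``buried_range`` residues form a
    compact rod at the centre of a solid grid-ball atom cage built from the
    residues flanking them; everything else lies on an exposed extended rail.

    The cage starts at residue 2 so the chain-terminus surface caps of the
    depth engine stay on the exposed rail, never inside the cage.
    """
    lo, hi = buried_range
    cage = [i for i in range(max(2, lo - 25), min(len(target), hi + 25) + 1)
            if not lo <= i <= hi]
    cage_atoms = len(cage) * 4
    grid_pts = _grid_ball(3.0, 9.0, 3.0)
    if len(grid_pts) > cage_atoms:
        raise ValueError(
            f"cage too sparse: {cage_atoms} atoms for {len(grid_pts)} grid points"
        )
    residues = []
    pt = 0
    mid = (lo + hi) / 2
    for i, aa in enumerate(target.sequence, start=1):
        if lo <= i <= hi:
            center = np.array([(i - mid) * 1.2, 0.5, 0.0])
            atoms = {
                "N": center + np.array([-0.4, 0.0, 0.0]),
                "CA": center,
                "C": center + np.array([0.4, 0.0, 0.0]),
                "O": center + np.array([0.4, 0.5, 0.0]),
            }
        elif i in cage:
            atoms = {}
            for name in ("N", "CA", "C", "O"):
                atoms[name] = grid_pts[pt % len(grid_pts)]
                pt += 1
        else:
            base = np.array([60.0 + 3.5 * i, 0.0, 0.0])
            atoms = {
                "N": base + np.array([-1.2, 0.5, 0.0]),
                "CA": base,
                "C": base + np.array([1.2, 0.5, 0.0]),
                "O": base + np.array([1.2, 1.7, 0.0]),
            }
        residues.append(Residue(ONE_TO_THREE[aa], i, atoms))
    # single-chain write: reuse the complex writer with a one-residue stub
    # chain is not possible, so write via gemmi directly
    import gemmi

    st = gemmi.Structure()
    st.name = "full_length"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res in residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.index, " ")
        for aname, xyz in res.atoms.items():
            at = gemmi.Atom()
            at.name = aname
            at.element = gemmi.Element(aname[0])
            at.pos = gemmi.Position(*map(float, xyz))
            at.b_iso = float(plddt)
            at.occ = 1.0
            gres.add_atom(at)
        chain.add_residue(gres)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))
    return Path(path)


def make_screen_corpus(
    outdir: str | Path,
    seed: int = 0,
    lengths: tuple[int, ...] = (16, 36, 52),
) -> dict:
    """Materialise everything an end-to-end screen run needs.

    Writes the target FASTA, phosphosite list, full-length structure and one
    predicted complex (PDB + PAE JSON) per unique fragment.  Fragments fully
    containing a planted motif core get a canonical-LIR pose confined to the
    core; all other fragments get an unbound, low-confidence pose.  Returns
    the paths plus the ground truth.
    """
    outdir = Path(outdir)
    pred_dir = outdir / "predictions"
    pred_dir.mkdir(parents=True, exist_ok=True)
    target, motifs = synthetic_target()
    st_target = apply_phosphomimetic(target)

    fasta = outdir / "target.fasta"
    fasta.write_text(f">{target.id}\n{target.sequence}\n")
    sites = outdir / "phosphosites.tsv"
    sites.write_text(
        "".join(f"{target.id}\t{s}\n" for s in sorted(target.phosphosites))
    )
    full_length = outdir / "full_length.pdb"
    buried = next(m for m in motifs if m.buried)
    make_full_length_structure(target, (buried.theta - 2, buried.gamma + 2), full_length)

    unique: list[FragmentRecord] = []
    aliases: dict[str, str] = {}
    for length in lengths:
        wt = tile_sequence(target, length)
        stf = tile_sequence(st_target, length)
        uniq, alias = deduplicate_fragments(wt, stf)
        unique.extend(uniq)
        aliases.update(alias)

    for frag in unique:
        fid = fragment_id(frag)
        motif = next(
            (m for m in motifs if frag.contains(m.theta, m.gamma)), None
        )
        if motif is not None:
            theta_local = motif.theta - frag.start + 1
            spec = FixtureSpec(label="can.LIR", sequence=frag.sequence, seed=seed)
            b = _Builder(
                get_receptor_profile(spec.receptor), frag.sequence, seed=seed
            )
            b.place_pockets(spec.gate_distance)
            b.engage("HP1", theta_local)
            b.engage("HP2", theta_local + 3)
            lo, _ = get_receptor_profile(spec.receptor).beta2_range
            b.craft_hbonds((theta_local + 1, theta_local + 2), [lo + 1, lo + 3], 2)
            core = set(range(theta_local, theta_local + 4))
            cx = b.build(fragment_file_stem(fid), confident_region=core)
        else:
            spec = FixtureSpec(
                label="other", sequence=frag.sequence, confident=False, seed=seed
            )
            b = _Builder(
                get_receptor_profile(spec.receptor), frag.sequence, seed=seed
            )
            cx = b.build(fragment_file_stem(fid), confident=False)
        stem = fragment_file_stem(fid)
        write_predicted_complex(cx, pred_dir / f"{stem}.pdb", pred_dir / f"{stem}_pae.json")

    return {
        "target": target,
        "motifs": motifs,
        "fasta": fasta,
        "phosphosites": sites,
        "full_length": full_length,
        "predictions": pred_dir,
        "fragments": unique,
        "aliases": aliases,
        "receptor": "LC3B",
    }


# -- ideal backbone geometry (NeRF construction) ----------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8


def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural extension reference frame: position d given three anchors."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(
    n_res: int, phi: float, psi: float, omega: float = 180.0, name: str = "ALA"
) -> list[Residue]:
    """Poly-residue backbone with uniform dihedrals and textbook bond geometry."""
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    ns, cas, cs = [n0], [ca0], [c0]
    for _ in range(1, n_res):
        n = _place(ns[-1], cas[-1], cs[-1], _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca = _place(cas[-1], cs[-1], n, _BOND_N_CA, _ANGLE_C_N_CA, omega)
        c = _place(cs[-1], n, ca, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        ns.append(n)
        cas.append(ca)
        cs.append(c)
    residues = []
    for i in range(n_res):
        next_n = ns[i + 1] if i + 1 < n_res else None
        if next_n is not None:
            o = _place(ns[i], cas[i], cs[i], _BOND_C_O, _ANGLE_CA_C_O, psi + 180.0)
        else:
            o = _place(ns[i], cas[i], cs[i], _BOND_C_O, _ANGLE_CA_C_O, 0.0)
        residues.append(
            Residue(name, i + 1, {"N": ns[i], "CA": cas[i], "C": cs[i], "O": o})
        )
    return residues


def ideal_helix(n_res: int = 12) -> list[Residue]:
    """Ideal alpha helix (phi = -57, psi = -47)."""
    return build_backbone(n_res, phi=-57.0, psi=-47.0)


def ideal_strand_pair(n_res: int = 8) -> tuple[list[Residue], list[Residue]]:
    """Two flat antiparallel strands joined by an exact hydrogen-bond ladder.

    Even-index residues of both strands form collinear ring hydrogen bonds
    (N-H...O=C in both directions); the DSSP bridge rules then derive the
    intervening wide bridges from the same bonds, so interior residues read
    as extended strand.  Carbonyl oxygens alternate up/down along each chain
    to orient the reconstructed amide hydrogens of the ring residues toward
    the partner strand.  Residue numbering of the partner continues after the
    first strand with a gap (a deliberate chain break).
    """
    a = 3.4          # residue repeat along the strand axis
    y_b = 4.13       # partner backbone line; rings are 1.9-Angstrom H...O
    first, second = [], []
    for k in range(n_res):
        x = a * k
        ring = k % 2 == 0
        first.append(Residue("ALA", k + 1, {
            "N": np.array([x, 0.0, 0.0]),
            "CA": np.array([x + 1.1, 0.0, 0.0]),
            "C": np.array([x + 2.2, 0.0, 0.0]),
            "O": np.array([x + 2.2, 1.23 if ring else -1.23, 0.0]),
        }))
    for j in range(n_res):
        x = a * (n_res - 1 - j)   # partner runs antiparallel, pairs A[n-1-j]
        ring = (n_res - 1 - j) % 2 == 0
        second.append(Residue("ALA", n_res + 3 + j, {
            "N": np.array([x + 2.2, y_b, 0.0]),
            "CA": np.array([x + 1.1, y_b, 0.0]),
            "C": np.array([x, y_b, 0.0]),
            "O": np.array([x, y_b - 1.23 if ring else y_b + 1.23, 0.0]),
        }))
    return first, second
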