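"""Residue-depth and secondary-structure occlusion annotation.

A candidate motif found in a fragment is only useful if it is accessible in
the full-length protein.  Two occlusion proxies are computed on the predicted
full-length structure: residue depth (mean distance of a residue's atoms to
the nearest molecular-surface point, in nm) and simplified secondary
structure (helix/strand/other).  Both are assigned only to residues whose
full-length pLDDT reaches the mask threshold (default 70): low-confidence
regions are treated as disordered and get the depth of a fully exposed
residue (0.142 nm, the depth of a single energy-minimised glycine) when motif
averages are formed.  A motif whose mean depth over its residues exceeds
0.3 nm is flagged buried and excluded from ranked shortlists.

The default depth engine samples the solvent-accessible surface with a
1.5-Angstrom probe and measures depth to the probe-corrected (molecular)
surface; an adapter delegates to msms via Bio.PDB when that binary is on
PATH.  Masking can fragment the chain; each contiguous segment is surfaced
with additional probe points spawned at its N and C termini so artificial
chain breaks read as solvent-exposed.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, load_structure_chain

__all__ = [
    "FullLengthStructure",
    "OcclusionAnnotation",
    "load_full_length",
    "compute_residue_depth",
    "assign_secondary_structure",
    "annotate",
    "motif_mean_depth",
    "filter_accessible",
    "DEFAULT_DEPTH_NM",
    "MAX_MEAN_DEPTH_NM",
    "PLDDT_MASK",
]

log = logging.getLogger(__name__)

DEFAULT_DEPTH_NM = 0.142   # depth of a fully exposed (disordered) residue
MAX_MEAN_DEPTH_NM = 0.3    # motif accessibility cutoff
PLDDT_MASK = 70.0
PROBE_RADIUS = 1.5         # Angstrom

# van der Waals radii (Angstrom) by element for surface construction
_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.10}


@dataclass
class FullLengthStructure:
    """A single-chain full-length predicted structure with pLDDT."""

    path: Path | None
    residues: list[Residue]
    plddt: np.ndarray


@dataclass
class OcclusionAnnotation:
    """Per-residue occlusion annotation of a full-length structure."""

    depth_nm: np.ndarray          # NaN where unassigned
    secondary: list[str | None]   # 'H' / 'E' / '-' / None (unassigned)
    plddt_mask: float
    default_depth_nm: float = DEFAULT_DEPTH_NM

    def mean_depth(self, positions: list[int]) -> float:
        """Mean depth (nm) over 0-based residue positions; unassigned
        residues contribute the exposed-residue default."""
        vals = [
            self.default_depth_nm if np.isnan(self.depth_nm[p]) else self.depth_nm[p]
            for p in positions
        ]
        return float(np.mean(vals))


def load_full_length(path: str | Path, chain_id: str | None = None) -> FullLengthStructure:
    residues, plddt = load_structure_chain(path, chain_id)
    return FullLengthStructure(Path(path), residues, plddt)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True, as inclusive (start, end) index pairs."""
    out, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def _sample_surface(
    centers: np.ndarray,
    radii: np.ndarray,
    cap_centers: np.ndarray,
    probe: float,
    n_points: int,
) -> np.ndarray:
    """Points on the solvent-accessible surface, plus unconditional cap
    spheres at fragment termini."""
    unit = _fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(centers)
    r_max = float(expanded.max())
    surface = []
    for c, r in zip(centers, expanded):
        pts = c + unit * r
        neighbors = tree.query_ball_point(c, 2 * r_max)
        others = [k for k in neighbors if not np.allclose(centers[k], c)]
        keep = np.ones(len(pts), dtype=bool)
        for k in others:
            keep &= np.linalg.norm(pts - centers[k], axis=1) > expanded[k] - 1e-9
        surface.append(pts[keep])
    for c in cap_centers:
        # termini created by masking are treated as solvent-exposed: their
        # probe spheres contribute surface regardless of occlusion
        surface.append(c + unit * (1.7 + probe))
    return np.vstack([s for s in surface if len(s)])


def _builtin_depth(
    residues: list[Residue],
    mask: np.ndarray,
    probe: float,
    n_points: int,
) -> np.ndarray:
    depth = np.full(len(residues), np.nan)
    if not mask.any():
        return depth
    centers, radii, owner = [], [], []
    for i in np.nonzero(mask)[0]:
        for name, xyz in residues[i].heavy_atoms().items():
            centers.append(xyz)
            radii.append(_VDW.get(name[0], 1.70))
            owner.append(i)
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    owner = np.asarray(owner)
    caps = []
    for s, e in _segments(mask):
        for res, at in ((residues[s], "N"), (residues[e], "C")):
            xyz = res.get(at)
            if xyz is not None:
                caps.append(xyz)
    surface = _sample_surface(centers, radii, np.asarray(caps), probe, n_points)
    stree = cKDTree(surface)
    dist, _ = stree.query(centers)
    atom_depth = np.maximum(dist - probe, 0.0)   # to the molecular surface
    for i in np.unique(owner):
        depth[i] = atom_depth[owner == i].mean() / 10.0   # Angstrom -> nm
    return depth


def _msms_depth(fl: FullLengthStructure, mask: np.ndarray) -> np.ndarray:
    """Adapter: residue depth via the external msms surface engine."""
    from Bio.PDB import PDBParser
    from Bio.PDB.ResidueDepth import ResidueDepth

    parser = PDBParser(QUIET=True)
    model = parser.get_structure("fl", str(fl.path))[0]
    keep = {fl.residues[i].index for i in np.nonzero(mask)[0]}
    for chain in model:
        for res in list(chain):
            if res.id[1] not in keep:
                chain.detach_child(res.id)
    rd = ResidueDepth(model)
    depth = np.full(len(fl.residues), np.nan)
    by_index = {r.index: i for i, r in enumerate(fl.residues)}
    for (chain_id, res_id), (res_depth, _ca_depth) in rd.property_dict.items():
        i = by_index.get(res_id[1])
        if i is not None:
            depth[i] = res_depth / 10.0
    return depth


def compute_residue_depth(
    fl: FullLengthStructure,
    plddt_mask: float = PLDDT_MASK,
    probe: float = PROBE_RADIUS,
    n_points: int = 96,
    engine: str = "auto",
) -> np.ndarray:
    """Per-residue depth in nm; NaN where pLDDT is below the mask.

    ``engine``: ``"builtin"`` (sampled-surface implementation), ``"msms"``
    (Bio.PDB ResidueDepth adapter, requires the msms binary), or ``"auto"``
    (msms when available, builtin otherwise).
    """
    mask = fl.plddt >= plddt_mask
    if engine == "auto":
        engine = "msms" if shutil.which("msms") else "builtin"
        if engine == "builtin":
            log.info("msms not on PATH; using built-in sampled-surface depth")
    if engine == "msms":
        try:
            return _msms_depth(fl, mask)
        except Exception as exc:  # pragma: no cover - depends on external binary
            log.warning("msms depth failed (%s); falling back to builtin", exc)
    return _builtin_depth(fl.residues, mask, probe, n_points)


_SS_SIMPLIFY = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def assign_secondary_structure(
    fl: FullLengthStructure, plddt_mask: float = PLDDT_MASK
) -> list[str | None]:
    """Simplified DSSP secondary structure: 'H', 'E' or '-'; None when the
    residue's pLDDT is below the mask or its backbone is incomplete."""
    import warnings

    import mdtraj

    if fl.path is None:
        raise ValueError("secondary structure needs an on-disk structure file")
    with warnings.catch_warnings():
        # synthetic files carry a dummy CRYST1 record; the discarded unit
        # cell is irrelevant for DSSP
        warnings.filterwarnings("ignore", message=".*unit cell.*")
        traj = mdtraj.load(str(fl.path))
    ss = mdtraj.compute_dssp(traj, simplified=False)[0]
    by_index = {}
    for res, code in zip(traj.topology.residues, ss):
        by_index[res.resSeq] = code
    out: list[str | None] = []
    for res, pl in zip(fl.residues, fl.plddt):
        code = by_index.get(res.index)
        if pl < plddt_mask or code is None or code == "NA":
            out.append(None)
        else:
            out.append(_SS_SIMPLIFY.get(code, "-"))
    return out


def annotate(
    fl: FullLengthStructure,
    plddt_mask: float = PLDDT_MASK,
    engine: str = "auto",
) -> OcclusionAnnotation:
    """Depth + secondary structure in one pass."""
    depth = compute_residue_depth(fl, plddt_mask=plddt_mask, engine=engine)
    try:
        ss = assign_secondary_structure(fl, plddt_mask=plddt_mask)
    except Exception as exc:
        log.warning("secondary-structure assignment failed: %s", exc)
        ss = [None] * len(fl.residues)
    return OcclusionAnnotation(depth_nm=depth, secondary=ss, plddt_mask=plddt_mask)


def motif_mean_depth(
    annotation: OcclusionAnnotation, positions: list[int]
) -> float:
    """Mean depth (nm) of a motif given 0-based residue positions."""
    return annotation.mean_depth(positions)


def filter_accessible(groups, max_mean_depth: float = MAX_MEAN_DEPTH_NM):
    """Split motif groups into (accessible, buried) by mean residue depth.

    Each group must expose a ``mean_depth_nm`` attribute (None counts as
    accessible: no depth information available).  Idempotent.
    """
    accessible, buried = [], []
    for g in groups:
        d = getattr(g, "mean_depth_nm", None)
        (buried if d is not None and d > max_mean_depth else accessible).append(g)
    return accessible, buried
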