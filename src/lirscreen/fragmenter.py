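"""Fragment sequence generation for the structural screen.

Two schemes are provided.  Tiling covers a full protein with fixed-length
windows (default lengths 16/36/52) at 75% overlap; the final window is shifted
left if needed so it still has the nominal length.  The centered length scan
grows a 4-residue core motif symmetrically in 2-residue steps (one residue per
terminus) up to a maximum length, for probing the effect of fragment length on
a known motif.

Each scheme is run on the wild-type (WT) sequence and on a phosphomimetic (ST)
variant in which phosphorylatable serines/threonines are replaced by glutamate.
Windows without phosphosites yield identical WT/ST sequences; those ST
duplicates are dropped from the physical prediction set and recorded in an
alias table so downstream statistics still count both states.

All coordinates are 1-based inclusive, matching conventional residue numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

__all__ = [
    "TargetSequence",
    "FragmentRecord",
    "tile_sequence",
    "length_scan",
    "apply_phosphomimetic",
    "deduplicate_fragments",
    "read_fasta",
    "read_phosphosites",
    "write_fragment_fasta",
    "write_manifest",
    "read_manifest",
    "fragment_id",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TargetSequence:
    """A parent protein sequence with its known phosphosites.

    ``phosphosites`` are 1-based indices of serine/threonine residues; for
    proteins without large-scale phosphoproteomics data, pass
    ``all_st_sites(seq)`` to treat every S/T as a potential site.
    """

    id: str
    sequence: str
    phosphosites: frozenset[int] = frozenset()
    mutation_state: str = "WT"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        allowed = "ST" if self.mutation_state == "WT" else "STE"
        for site in self.phosphosites:
            if not 1 <= site <= len(self.sequence):
                raise ValueError(f"{self.id}: phosphosite {site} out of range")
            if self.sequence[site - 1] not in allowed:
                raise ValueError(
                    f"{self.id}: phosphosite {site} is "
                    f"{self.sequence[site - 1]}, not S/T"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def all_st_sites(sequence: str) -> frozenset[int]:
    """Every S/T position, for targets lacking experimental phosphosite data."""
    return frozenset(i + 1 for i, aa in enumerate(sequence) if aa in "ST")


@dataclass(frozen=True)
class FragmentRecord:
    """A windowed (possibly phosphomimetic) subsequence of a parent protein."""

    parent_id: str
    start: int                  # 1-based inclusive parent coordinates
    end: int
    sequence: str
    mutation_state: str         # "WT" or "ST"
    length_class: int           # nominal fragment length (16/36/52, or scan length)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("window size does not match sequence length")
        if self.mutation_state not in ("WT", "ST"):
            raise ValueError(f"bad mutation state {self.mutation_state!r}")

    @property
    def window(self) -> tuple[int, int]:
        return (self.start, self.end)

    def contains(self, start: int, end: int) -> bool:
        """Does this window fully cover parent residues [start, end]?"""
        return self.start <= start and end <= self.end


def fragment_id(frag: FragmentRecord) -> str:
    """Canonical fragment identifier, e.g. ``P40477|1070-1089|ST``."""
    return f"{frag.parent_id}|{frag.start}-{frag.end}|{frag.mutation_state}"


def tile_sequence(
    target: TargetSequence, length: int, overlap_fraction: float = 0.75
) -> list[FragmentRecord]:
    """Tile the parent with fixed-length windows at the given overlap.

    Windows start at 1, 1+step, ... with step = length * (1 - overlap); a
    window that would overrun the C terminus is replaced by one final window
    shifted left to end exactly at the last residue.  The union of windows
    covers the whole sequence.
    """
    L = len(target)
    if length > L:
        raise ValueError(f"fragment length {length} exceeds sequence length {L}")
    step_f = length * (1.0 - overlap_fraction)
    step = round(step_f)
    if step < 1 or abs(step - step_f) > 1e-9:
        raise ValueError(
            f"length {length} with overlap {overlap_fraction} gives non-integer "
            f"step {step_f}; choose a length divisible by "
            f"1/(1-overlap) (e.g. a multiple of 4 for 75% overlap)"
        )
    state = target.mutation_state
    frags = []
    start = 1
    while True:
        end = start + length - 1
        if end >= L:
            start = L - length + 1          # shift the last window to fit
            frags.append(_make(target, start, L, length, state))
            break
        frags.append(_make(target, start, end, length, state))
        start += step
    return frags


def _make(
    target: TargetSequence, start: int, end: int, length_class: int, state: str
) -> FragmentRecord:
    return FragmentRecord(
        parent_id=target.id,
        start=start,
        end=end,
        sequence=target.sequence[start - 1 : end],
        mutation_state=state,
        length_class=length_class,
    )


def length_scan(
    target: TargetSequence,
    core_start: int,
    core_end: int,
    max_length: int = 68,
) -> list[FragmentRecord]:
    """Centered length scan around a 4-residue core motif.

    Produces fragments of length 4, 6, 8, ..., ``max_length``, each extending
    the core by one residue per terminus per step; the first fragment is the
    bare core.  Flanks are truncated (with a warning) where they would cross a
    protein terminus, so boundary cores yield asymmetric fragments.
    """
    if core_end - core_start + 1 != 4:
        raise ValueError("core must be exactly 4 residues")
    L = len(target)
    if not (1 <= core_start and core_end <= L):
        raise ValueError("core outside sequence")
    state = target.mutation_state
    frags = []
    for flank in range(0, (max_length - 4) // 2 + 1):
        nominal = 4 + 2 * flank
        start = core_start - flank
        end = core_end + flank
        if start < 1 or end > L:
            warnings.warn(
                f"{target.id}: length-{nominal} fragment truncated at protein "
                "terminus",
                stacklevel=2,
            )
            start, end = max(1, start), min(L, end)
        frags.append(_make(target, start, end, nominal, state))
    return frags


def apply_phosphomimetic(target: TargetSequence) -> TargetSequence:
    """Return the ST variant: every listed phosphosite S/T mutated to E."""
    seq = list(target.sequence)
    for site in target.phosphosites:
        seq[site - 1] = "E"
    return replace(target, sequence="".join(seq), mutation_state="ST")


def deduplicate_fragments(
    wt: list[FragmentRecord], st: list[FragmentRecord]
) -> tuple[list[FragmentRecord], dict[str, str]]:
    """Drop ST fragments identical to their WT twin.

    Windows without phosphosites produce the same sequence in both states;
    only the WT fragment is kept for prediction, and the alias table maps the
    dropped ST fragment id to the WT id so that both logical mutation states
    share the one physical prediction.

    Returns ``(unique_fragments, aliases)``.
    """
    by_window = {(f.start, f.end, f.length_class): f for f in wt}
    unique = list(wt)
    aliases: dict[str, str] = {}
    for f in st:
        twin = by_window.get((f.start, f.end, f.length_class))
        if twin is not None and twin.sequence == f.sequence:
            aliases[fragment_id(f)] = fragment_id(twin)
        else:
            unique.append(f)
    return unique, aliases


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning {accession: sequence}.

    The accession is the first |-delimited token after '>' that looks like a
    plain id, or the whole first word (UniProt ``sp|P12345|NAME`` headers
    yield ``P12345``).
    """
    seqs: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                word = line[1:].split()[0]
                parts = word.split("|")
                current = parts[1] if len(parts) >= 3 and parts[0] in ("sp", "tr") else word
                seqs[current] = []
            elif current is not None:
                seqs[current].append(line)
    return {k: "".join(v).upper() for k, v in seqs.items()}


def read_phosphosites(path: str | Path) -> dict[str, frozenset[int]]:
    """Read a two-column TSV (accession, 1-based site index), dbPTM-style.

    Lines starting with '#' are skipped; extra columns are ignored.
    """
    sites: dict[str, set[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            acc, idx = parts[0], int(parts[1])
            sites.setdefault(acc, set()).add(idx)
    return {k: frozenset(v) for k, v in sites.items()}


def write_fragment_fasta(frags: list[FragmentRecord], path: str | Path) -> None:
    """Write prediction-ready multi-FASTA; headers carry provenance
    (``>parent|start-end|state``) so no sidecar file is needed downstream."""
    with open(path, "w") as fh:
        for f in frags:
            fh.write(f">{fragment_id(f)}\n{f.sequence}\n")


_MANIFEST_COLS = ["fragment_id", "parent_id", "start", "end",
                  "mutation_state", "length_class", "sequence", "alias_of"]


def write_manifest(
    frags: list[FragmentRecord],
    aliases: dict[str, str],
    path: str | Path,
) -> None:
    """TSV manifest of all logical fragments, including dedup aliases."""
    physical = {fragment_id(f): f for f in frags}
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLS) + "\n")
        for fid, f in physical.items():
            fh.write(
                f"{fid}\t{f.parent_id}\t{f.start}\t{f.end}\t{f.mutation_state}"
                f"\t{f.length_class}\t{f.sequence}\t-\n"
            )
        for alias, target in aliases.items():
            f = physical[target]
            parent, window, state = alias.split("|")
            fh.write(
                f"{alias}\t{parent}\t{f.start}\t{f.end}\t{state}"
                f"\t{f.length_class}\t{f.sequence}\t{target}\n"
            )


def read_manifest(path: str | Path) -> tuple[list[FragmentRecord], dict[str, str]]:
    """Inverse of :func:`write_manifest`: logical fragments + alias table."""
    frags, aliases = [], {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            frag = FragmentRecord(
                parent_id=row["parent_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                sequence=row["sequence"],
                mutation_state=row["mutation_state"],
                length_class=int(row["length_class"]),
            )
            frags.append(frag)
            if row["alias_of"] != "-":
                aliases[row["fragment_id"]] = row["alias_of"]
    return frags, aliases
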