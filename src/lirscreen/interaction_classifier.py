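"""Interaction-mode classification of confident stretches.

For LC3/Atg8-family receptors, four canonical-LIR criteria are evaluated:

  (i)   a stretch residue engages hydrophobic pocket 1 (HP1),
  (ii)  a stretch residue engages HP2,
  (iii) the stretch forms >= 2 backbone H-bonds with the receptor beta-2
        strand between HP1 and HP2,
  (iv)  the stretch carries the canonical Theta-X-X-Gamma motif (Theta in
        {W, F, Y}, Gamma in {L, I, V}) with Theta the HP1 residue and Gamma
        the HP2 residue.

All four criteria give ``can.LIR``.  One to three give a non-canonical LIR if
one of the described ncLIR patterns matches -- tested in a fixed order
(antiparallel ap.LIR, HP0-LIR, 2-HP-LIR, CLIR, sAIM, [DE]W[DE]-LIR), first
match wins -- and otherwise a low-confidence ``lcLIR``.  Zero criteria fall
back to proximity classes: ``other@LDS`` (>= 5 Calpha contacts with the
beta-2 strand), ``UIM-like`` (>= 5 Calpha contacts with the UIM-docking
site), or ``other``.

SUMO receptors use a single criterion: >= 2 backbone H-bonds with the
SIM-binding-groove beta strand give ``SIM``, anything else ``other``; whether
the stretch also matches the canonical Gamma-Gamma-X-Gamma / Gamma-X-Gamma-
Gamma SIM pattern is recorded as metadata only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .interface_geometry import (
    PocketAssignment,
    ReceptorProfile,
    assign_pocket,
    count_backbone_hbonds,
    count_ca_contacts,
)
from .stretch_detector import Stretch
from .structure_io import PredictedComplex

__all__ = ["InteractionCall", "LABELS", "NCLIR_ORDER", "classify_lir",
           "classify_sumo", "classify"]

THETA = set("WFY")
GAMMA = set("LIV")
GAMMA_M = set("LIVM")

NCLIR_ORDER = ("ap.LIR", "HP0-LIR", "2-HP-LIR", "CLIR", "sAIM", "[DE]W[DE]-LIR")

LABELS = (
    "can.LIR", *NCLIR_ORDER, "lcLIR", "other@LDS", "UIM-like", "other", "SIM",
)

_SIM_PATTERN = re.compile(r"(?=([LIV][LIV].[LIV]|[LIV].[LIV][LIV]))")

MIN_HBONDS = 2
MIN_CA_CONTACTS = 5


@dataclass(frozen=True)
class InteractionCall:
    """Classification of one confident stretch against one receptor."""

    label: str
    stretch: Stretch
    criteria_flags: tuple[bool, bool, bool, bool] | None   # (i)-(iv); None for SUMO
    pockets: dict[str, PocketAssignment]
    hbond_count: int
    motif_string: str
    canonical_sim: bool | None = None

    @property
    def engaged_residues(self) -> dict[str, int]:
        """Pocket -> fragment-local engaging residue, engaged pockets only."""
        return {p: a.residue for p, a in self.pockets.items() if a.engaged}


def _motif_string(seq: str, stretch: Stretch, engaged: set[int]) -> str:
    out = []
    for pos in range(stretch.start, stretch.end + 1):
        aa = seq[pos - 1]
        out.append(f"[{aa}]" if pos in engaged else aa.lower())
    return "".join(out)


def _peptide_seq(cx: PredictedComplex) -> str:
    return "".join(r.one_letter for r in cx.peptide)


def _aa(seq: str, pos: int | None) -> str | None:
    if pos is None or not 1 <= pos <= len(seq):
        return None
    return seq[pos - 1]


def _nclir_predicates(
    seq: str,
    flags: tuple[bool, bool, bool, bool],
    hp0: PocketAssignment,
    hp1: PocketAssignment,
    hp2: PocketAssignment,
):
    """Pattern predicates for each described non-canonical LIR class.

    Sequence positions are anchored on the pocket-engaging residues (e.g. the
    canonical spacing Theta-X-X-Gamma means the HP2 residue sits exactly three
    positions C-terminal of the HP1 residue).
    """
    c1, c2, c3, _ = flags

    def ap_lir() -> bool:
        # reversed canonical sequence Gamma-X-X-Theta: Theta (HP1) three
        # positions C-terminal of Gamma (HP2)
        return (
            c1 and c2 and c3
            and _aa(seq, hp1.residue) in THETA
            and _aa(seq, hp2.residue) in GAMMA
            and hp1.residue - hp2.residue == 3
        )

    def hp0_lir() -> bool:
        # Theta(HP0)-X-Gamma-X-X-Gamma(HP2); HP1 engagement not required
        return (
            hp0.engaged and c2
            and _aa(seq, hp0.residue) in THETA
            and _aa(seq, hp2.residue) in GAMMA
            and hp2.residue - hp0.residue == 5
            and _aa(seq, hp0.residue + 2) in GAMMA
        )

    def two_hp() -> bool:
        return c1 and c2

    def clir() -> bool:
        # Gamma/M-Gamma/M-Gamma(HP2): the two residues immediately N-terminal
        # of the HP2-engaging Gamma
        return (
            c2 and c3
            and _aa(seq, hp2.residue) in GAMMA
            and _aa(seq, hp2.residue - 1) in GAMMA_M
            and _aa(seq, hp2.residue - 2) in GAMMA_M
        )

    def saim() -> bool:
        # shuffled Gamma-X-Theta-X with Theta engaging HP0 or HP1
        for theta in (hp0.residue if hp0.engaged else None,
                      hp1.residue if hp1.engaged else None):
            if (
                theta is not None
                and _aa(seq, theta) in THETA
                and _aa(seq, theta - 2) in GAMMA
                and theta + 1 <= len(seq)
            ):
                return True
        return False

    def dwde() -> bool:
        # D/E-W-D/E with W engaging HP1
        return (
            c1
            and _aa(seq, hp1.residue) == "W"
            and _aa(seq, hp1.residue - 1) in ("D", "E")
            and _aa(seq, hp1.residue + 1) in ("D", "E")
        )

    return {
        "ap.LIR": ap_lir,
        "HP0-LIR": hp0_lir,
        "2-HP-LIR": two_hp,
        "CLIR": clir,
        "sAIM": saim,
        "[DE]W[DE]-LIR": dwde,
    }


def classify_lir(
    stretch: Stretch,
    cx: PredictedComplex,
    profile: ReceptorProfile,
    nclir_order: tuple[str, ...] = NCLIR_ORDER,
) -> InteractionCall:
    """Classify a stretch bound to an LC3/Atg8-family receptor.

    ``nclir_order`` exists so tests can demonstrate the order sensitivity of
    the non-canonical cascade; production code uses the default.
    """
    if profile.family != "LC3":
        raise ValueError(f"{profile.name} is not an LC3-family receptor")
    seq = _peptide_seq(cx)
    hp0 = assign_pocket(cx, stretch, profile, "HP0")
    hp1 = assign_pocket(cx, stretch, profile, "HP1")
    hp2 = assign_pocket(cx, stretch, profile, "HP2")
    hbonds = count_backbone_hbonds(cx, stretch, profile.beta2_range)

    c1 = hp1.engaged
    c2 = hp2.engaged
    c3 = hbonds >= MIN_HBONDS
    c4 = (
        c1 and c2
        and _aa(seq, hp1.residue) in THETA
        and _aa(seq, hp2.residue) in GAMMA
        and hp2.residue - hp1.residue == 3
    )
    flags = (c1, c2, c3, c4)
    pockets = {"HP0": hp0, "HP1": hp1, "HP2": hp2}
    engaged = {a.residue for a in pockets.values() if a.engaged}

    if all(flags):
        label = "can.LIR"
    elif any(flags):
        predicates = _nclir_predicates(seq, flags, hp0, hp1, hp2)
        label = next((n for n in nclir_order if predicates[n]()), "lcLIR")
    elif count_ca_contacts(cx, stretch, profile.beta2_range) >= MIN_CA_CONTACTS:
        label = "other@LDS"
    elif count_ca_contacts(cx, stretch, profile.uds_range) >= MIN_CA_CONTACTS:
        label = "UIM-like"
    else:
        label = "other"

    return InteractionCall(
        label=label,
        stretch=stretch,
        criteria_flags=flags,
        pockets=pockets,
        hbond_count=hbonds,
        motif_string=_motif_string(seq, stretch, engaged),
    )


def classify_sumo(
    stretch: Stretch, cx: PredictedComplex, profile: ReceptorProfile
) -> InteractionCall:
    """Classify a stretch bound to a SUMO receptor.

    Two or more backbone H-bonds with the SIM-groove beta strand make a SIM;
    canonical vs non-canonical SIM sequence is not distinguished for the
    label, but a match to the canonical Gamma-Gamma-X-Gamma / Gamma-X-Gamma-
    Gamma pattern is annotated.
    """
    if profile.family != "SUMO":
        raise ValueError(f"{profile.name} is not a SUMO receptor")
    seq = _peptide_seq(cx)
    hbonds = count_backbone_hbonds(cx, stretch, profile.sim_groove_range)
    stretch_seq = seq[stretch.start - 1 : stretch.end]
    return InteractionCall(
        label="SIM" if hbonds >= MIN_HBONDS else "other",
        stretch=stretch,
        criteria_flags=None,
        pockets={},
        hbond_count=hbonds,
        motif_string=stretch_seq.lower(),
        canonical_sim=bool(_SIM_PATTERN.search(stretch_seq)),
    )


def classify(
    stretch: Stretch, cx: PredictedComplex, profile: ReceptorProfile
) -> InteractionCall:
    """Dispatch on receptor family."""
    if profile.family == "SUMO":
        return classify_sumo(stretch, cx, profile)
    return classify_lir(stretch, cx, profile)
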