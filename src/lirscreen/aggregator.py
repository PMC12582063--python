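"""Cross-fragment aggregation of interaction calls into candidate motifs.

Stretches found in different fragments (any length class, either mutation
state) describe the same candidate motif when they predict the same
interaction type, engage the same pockets with the same parent residues, and
overlap by at least 3 residues; groups are closed under single linkage so the
result is independent of input order.

Per group the module computes:

* **relative occurrence** per (fragment length, mutation state): fragments
  containing the motif and forming the interaction, divided by all fragments
  containing it ("containing" = the window fully covers the representative
  pocket-engaging residues);
* **LO score** per mutation state: the length-weighted analogue, pooling all
  length classes -- sum of lengths of containing-and-forming fragments over
  the sum of lengths of containing fragments;
* **best core-motif pLDDT / minPAE**: per member, the best mean over every
  4-consecutive-residue window of the stretch; the group takes the maximum
  (pLDDT) respectively minimum (minPAE) over members;
* a ranking by per-class occurrence (WT+ST sum), longest class first.

The wild-type/phosphomimetic comparison marks a phosphosite as impactful when
the peak in one mutation state has no similar peak (grouping predicate) in
the same-window fragment of the other state, or the label changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragmenter import FragmentRecord, fragment_id
from .interaction_classifier import InteractionCall

__all__ = [
    "ParentCall",
    "MotifGroup",
    "MutationImpact",
    "group_motifs",
    "relative_occurrence",
    "lo_score",
    "best_core_scores",
    "rank_motifs",
    "impactful_mutations",
    "summarize",
]

MIN_GROUP_OVERLAP = 3


@dataclass(frozen=True)
class ParentCall:
    """One interaction call lifted into parent-protein coordinates for one
    logical fragment (dedup aliases expand to their own ParentCall)."""

    fragment: FragmentRecord
    call: InteractionCall
    plddt: tuple[float, ...]    # per stretch residue
    minpae: tuple[float, ...]

    @property
    def parent_range(self) -> tuple[int, int]:
        s = self.call.stretch
        off = self.fragment.start - 1
        return (s.start + off, s.end + off)

    @property
    def engaged_parent(self) -> frozenset[tuple[str, int]]:
        off = self.fragment.start - 1
        return frozenset(
            (p, pos + off) for p, pos in self.call.engaged_residues.items()
        )

    @property
    def label(self) -> str:
        return self.call.label

    @property
    def fragment_id(self) -> str:
        return fragment_id(self.fragment)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def _same_motif(a: ParentCall, b: ParentCall) -> bool:
    return (
        a.fragment.parent_id == b.fragment.parent_id
        and a.label == b.label
        and a.engaged_parent == b.engaged_parent
        and _overlap(a.parent_range, b.parent_range) >= MIN_GROUP_OVERLAP
    )


@dataclass
class MotifGroup:
    """A candidate motif: equivalent interaction calls pooled across fragments."""

    parent_id: str
    label: str
    engaged_parent: dict[str, int]
    members: list[ParentCall]
    occurrence: dict[tuple[int, str], float | None] = field(default_factory=dict)
    lo: dict[str, float | None] = field(default_factory=dict)
    best_core_plddt: float | None = None
    best_core_minpae: float | None = None
    mean_depth_nm: float | None = None
    buried: bool = False
    secondary: str | None = None

    @property
    def window(self) -> tuple[int, int]:
        """Motif span in parent coordinates (union of member stretches)."""
        return (
            min(m.parent_range[0] for m in self.members),
            max(m.parent_range[1] for m in self.members),
        )

    @property
    def representative_residues(self) -> tuple[int, int]:
        """Parent residue span a fragment must fully cover to 'contain' the
        motif: the pocket-engaging residues when pockets are engaged,
        otherwise the intersection of member stretches (or the shortest
        member when the intersection is empty)."""
        if self.engaged_parent:
            pos = sorted(self.engaged_parent.values())
            return (pos[0], pos[-1])
        lo = max(m.parent_range[0] for m in self.members)
        hi = min(m.parent_range[1] for m in self.members)
        if lo <= hi:
            return (lo, hi)
        shortest = min(
            self.members, key=lambda m: m.parent_range[1] - m.parent_range[0]
        )
        return shortest.parent_range

    @property
    def lo_mean(self) -> float | None:
        vals = [v for v in self.lo.values() if v is not None]
        return float(np.mean(vals)) if vals else None


def group_motifs(calls: list[ParentCall]) -> list[MotifGroup]:
    """Single-linkage grouping under the same-motif predicate.

    Transitive closure makes the result independent of call order; each call
    ends up in exactly one group.
    """
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _same_motif(calls[i], calls[j]):
                parent[find(i)] = find(j)
    clusters: dict[int, list[ParentCall]] = {}
    for i, c in enumerate(calls):
        clusters.setdefault(find(i), []).append(c)
    groups = []
    for members in clusters.values():
        rep = members[0]
        groups.append(
            MotifGroup(
                parent_id=rep.fragment.parent_id,
                label=rep.label,
                engaged_parent=dict(sorted(rep.engaged_parent)),
                members=sorted(
                    members, key=lambda m: (m.fragment_id, m.parent_range)
                ),
            )
        )
    groups.sort(key=lambda g: (g.parent_id, g.window))
    return groups


def _containing(
    group: MotifGroup, manifest: list[FragmentRecord]
) -> list[FragmentRecord]:
    lo, hi = group.representative_residues
    return [
        f
        for f in manifest
        if f.parent_id == group.parent_id and f.contains(lo, hi)
    ]


def relative_occurrence(
    group: MotifGroup, manifest: list[FragmentRecord]
) -> dict[tuple[int, str], float | None]:
    """Fraction of containing fragments that form the interaction, per
    (length class, mutation state).  None where no fragment of that class and
    state contains the motif."""
    containing = _containing(group, manifest)
    forming = {m.fragment_id for m in group.members}
    lengths = {f.length_class for f in manifest}
    states = {f.mutation_state for f in manifest}
    keys = sorted(
        ((lc, st) for lc in lengths for st in states),
        key=lambda k: (-k[0], k[1]),
    )
    out: dict[tuple[int, str], float | None] = {}
    for key in keys:
        cont = [f for f in containing if (f.length_class, f.mutation_state) == key]
        if not cont:
            out[key] = None
        else:
            out[key] = sum(fragment_id(f) in forming for f in cont) / len(cont)
    return out


def lo_score(
    group: MotifGroup, manifest: list[FragmentRecord]
) -> dict[str, float | None]:
    """Length-weighted fraction of occurrence per mutation state.

    Sum of the lengths of all fragments containing the motif and forming the
    interaction, divided by the sum of lengths of all containing fragments,
    pooled over length classes.  None where nothing contains the motif.
    """
    containing = _containing(group, manifest)
    forming = {m.fragment_id for m in group.members}
    out: dict[str, float | None] = {}
    for state in sorted({f.mutation_state for f in manifest}):
        cont = [f for f in containing if f.mutation_state == state]
        den = sum(f.length_class for f in cont)
        if den == 0:
            out[state] = None
        else:
            num = sum(f.length_class for f in cont if fragment_id(f) in forming)
            out[state] = num / den
    return out


def _best_window_mean(values: tuple[float, ...], best) -> float:
    """Best mean over every 4-consecutive-value window (full run if < 4)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        import warnings

        warnings.warn("motif shorter than 4 residues; using full motif",
                      stacklevel=3)
        return float(v.mean())
    means = np.convolve(v, np.ones(4) / 4, mode="valid")
    return float(best(means))


def best_core_scores(group: MotifGroup) -> tuple[float, float]:
    """(best core-motif pLDDT, best core-motif minPAE) over all members."""
    plddts = [_best_window_mean(m.plddt, np.max) for m in group.members]
    minpaes = [_best_window_mean(m.minpae, np.min) for m in group.members]
    return (max(plddts), min(minpaes))


def rank_motifs(groups: list[MotifGroup]) -> list[MotifGroup]:
    """Order by per-length-class occurrence, longest class first.

    The per-class score is the WT+ST sum of relative occurrences (None
    counting 0); ties break by parent id and ascending motif start.
    Occurrences must have been computed (see :func:`summarize`).
    """
    classes = sorted({lc for g in groups for (lc, _s) in g.occurrence}, reverse=True)

    def key(g: MotifGroup):
        per_class = tuple(
            -sum(
                v or 0.0
                for (lc, _s), v in g.occurrence.items()
                if lc == c
            )
            for c in classes
        )
        return (*per_class, g.parent_id, g.window[0])

    return sorted(groups, key=key)


@dataclass(frozen=True)
class MutationImpact:
    """A phosphomimetic mutation that changed a predicted peak."""

    parent_id: str
    window: tuple[int, int]          # fragment window containing the peak
    length_class: int
    motif_range: tuple[int, int]     # peak stretch in parent coordinates
    impact: str                      # appeared / disappeared / label-changed
    label_from: str
    label_to: str | None
    site: int                        # mutated parent position
    distance: int                    # residues from site to the motif (0 = inside)

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def _site_distance(site: int, motif: tuple[int, int]) -> int:
    lo, hi = motif
    if lo <= site <= hi:
        return 0
    return min(abs(site - lo), abs(site - hi))


def impactful_mutations(
    calls: list[ParentCall],
    phosphosites: dict[str, frozenset[int]],
) -> list[MutationImpact]:
    """Pairwise WT/ST comparison of peaks in fragments covering the same window.

    For every peak, the fragment of the alternative mutation state covering
    the same window is searched for a similar peak (grouping predicate).  A
    missing counterpart peak marks every phosphosite in the window as
    impactful (appeared/disappeared); a counterpart with the same pockets and
    overlap but a different label is a label change (reported once, from the
    WT side).  Peaks in windows with no alternative-state fragment are
    discarded.
    """
    by_window: dict[tuple, list[ParentCall]] = {}
    states: dict[tuple, set[str]] = {}
    for c in calls:
        f = c.fragment
        wkey = (f.parent_id, f.start, f.end, f.length_class)
        by_window.setdefault((*wkey, f.mutation_state), []).append(c)
        states.setdefault(wkey, set()).add(f.mutation_state)
    # windows present in both states, whether or not they produced calls,
    # must come from the manifest carried on the calls themselves; callers
    # pass calls expanded over dedup aliases, so both states are visible
    # whenever the window exists in both.
    impacts: list[MutationImpact] = []
    for c in calls:
        f = c.fragment
        wkey = (f.parent_id, f.start, f.end, f.length_class)
        other_state = "ST" if f.mutation_state == "WT" else "WT"
        counterparts = by_window.get((*wkey, other_state), [])
        sites = sorted(
            s for s in phosphosites.get(f.parent_id, ()) if f.start <= s <= f.end
        )
        if not sites:
            continue   # no alternative-state fragment existed: discarded
        similar = [
            o
            for o in counterparts
            if o.engaged_parent == c.engaged_parent
            and _overlap(o.parent_range, c.parent_range) >= MIN_GROUP_OVERLAP
        ]
        matched = [o for o in similar if o.label == c.label]
        if matched:
            continue
        if similar:
            if f.mutation_state != "WT":
                continue   # label changes reported once, from the WT side
            impact, label_to = "label-changed", similar[0].label
        else:
            impact = "disappeared" if f.mutation_state == "WT" else "appeared"
            label_to = None
        for site in sites:
            impacts.append(
                MutationImpact(
                    parent_id=f.parent_id,
                    window=(f.start, f.end),
                    length_class=f.length_class,
                    motif_range=c.parent_range,
                    impact=impact,
                    label_from=c.label,
                    label_to=label_to,
                    site=site,
                    distance=_site_distance(site, c.parent_range),
                )
            )
    impacts.sort(key=lambda m: (m.parent_id, m.window, m.motif_range, m.site))
    return impacts


def summarize(
    calls: list[ParentCall],
    manifest: list[FragmentRecord],
) -> list[MotifGroup]:
    """Group calls and fill in occurrence, LO and best-core statistics,
    returning groups in ranked order."""
    groups = group_motifs(calls)
    for g in groups:
        g.occurrence = relative_occurrence(g, manifest)
        g.lo = lo_score(g, manifest)
        g.best_core_plddt, g.best_core_minpae = best_core_scores(g)
    return rank_motifs(groups)
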