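"""aggregator: grouping, occurrence, LO score, ranking, mutation impacts."""

import itertools
import random

import pytest

from helpers import make_parent_call
from lirscreen.aggregator import (
    MutationImpact,
    best_core_scores,
    group_motifs,
    impactful_mutations,
    lo_score,
    relative_occurrence,
    summarize,
)
from lirscreen.fragmenter import FragmentRecord, fragment_id


def _frag(parent="P1", start=1, end=16, state="WT", lc=16):
    return FragmentRecord(parent, start, end, "A" * (end - start + 1), state, lc)


def _groups_key(groups):
    return sorted(
        (g.parent_id, g.label, tuple(sorted(g.engaged_parent.items())),
         tuple(sorted(m.fragment_id for m in g.members)))
        for g in groups
    )


def test_same_interaction_across_fragments_groups_together():
    a = make_parent_call(start=1, end=16, stretch=(5, 10),
                        engaged={"HP1": 5, "HP2": 8})
    b = make_parent_call(start=5, end=20, lc=16, stretch=(1, 6),
                        engaged={"HP1": 1, "HP2": 4})
    groups = group_motifs([a, b])
    assert len(groups) == 1
    assert groups[0].engaged_parent == {"HP1": 5, "HP2": 8}
    assert groups[0].window == (5, 10)
    assert groups[0].representative_residues == (5, 8)


def test_overlap_of_three_residues_required():
    # parent ranges [5,10] and [8,13] overlap by 3; [5,10] and [9,14] too,
    # but [5,10] and [11,16] only touch
    base = dict(engaged={})
    a = make_parent_call(start=1, end=16, stretch=(5, 10), **base)
    b = make_parent_call(start=5, end=20, stretch=(4, 9), **base)   # parent 8-13
    c = make_parent_call(start=9, end=24, stretch=(3, 8), **base)   # parent 11-18
    assert len(group_motifs([a, b])) == 1
    assert len(group_motifs([a, c])) == 2


def test_label_and_pockets_must_match_to_group():
    a = make_parent_call(stretch=(5, 10), engaged={"HP1": 5})
    b = make_parent_call(start=3, end=18, stretch=(3, 8),
                        engaged={"HP1": 3}, label="2-HP-LIR")
    c = make_parent_call(start=3, end=18, stretch=(3, 8), engaged={"HP1": 4})
    assert len(group_motifs([a, b])) == 2   # same pockets, different label
    assert len(group_motifs([a, c])) == 2   # same label, different pocket residue


def test_grouping_invariant_under_input_permutation():
    calls = [
        make_parent_call(start=1, end=16, stretch=(5, 10),
                        engaged={"HP1": 5, "HP2": 8}),
        make_parent_call(start=5, end=20, stretch=(1, 6),
                        engaged={"HP1": 1, "HP2": 4}),
        make_parent_call(start=9, end=24, stretch=(1, 4), engaged={}),
        make_parent_call(start=30, end=45, stretch=(2, 7),
                        engaged={"HP1": 33}, label="sAIM"),
    ]
    ref = _groups_key(group_motifs(calls))
    for perm in itertools.permutations(calls):
        assert _groups_key(group_motifs(list(perm))) == ref


def test_single_linkage_is_transitive():
    # a-b overlap, b-c overlap, a-c do not: still one group
    a = make_parent_call(start=1, end=16, stretch=(1, 6), engaged={})    # 1-6
    b = make_parent_call(start=1, end=16, stretch=(4, 10), engaged={})   # 4-10
    c = make_parent_call(start=1, end=16, stretch=(8, 14), engaged={})   # 8-14
    assert len(group_motifs([a, b, c])) == 1
    assert len(group_motifs([a, c])) == 2


def test_relative_occurrence_counts_containing_fragments():
    call16 = make_parent_call(start=1, end=16, stretch=(5, 8),
                             engaged={"HP1": 5, "HP2": 8})
    group = group_motifs([call16])[0]
    manifest = [
        _frag(start=1, end=16),                 # contains 5-8, forming
        _frag(start=5, end=20),                 # contains, not forming
        _frag(start=9, end=24),                 # does not contain
        _frag(start=1, end=16, state="ST"),     # contains, not forming
        _frag(start=1, end=36, lc=36),          # contains, not forming
    ]
    occ = relative_occurrence(group, manifest)
    assert occ[(16, "WT")] == pytest.approx(0.5)
    assert occ[(16, "ST")] == pytest.approx(0.0)
    assert occ[(36, "WT")] == pytest.approx(0.0)
    assert occ[(36, "ST")] is None


def test_lo_score_pools_length_classes_by_length():
    forming = [
        make_parent_call(start=1, end=16, stretch=(5, 8),
                        engaged={"HP1": 5, "HP2": 8}),
        make_parent_call(start=5, end=20, stretch=(1, 4),
                        engaged={"HP1": 1, "HP2": 4}),
    ]
    group = group_motifs(forming)
    assert len(group) == 1
    manifest = [
        _frag(start=1, end=16),
        _frag(start=5, end=20),
        _frag(start=1, end=36, lc=36),   # contains but does not form
    ]
    lo = lo_score(group[0], manifest)
    assert lo["WT"] == pytest.approx(32 / 68)


def test_occurrence_and_lo_match_brute_force_on_random_screens():
    rng = random.Random(424242)
    for _ in range(100):
        L = 60
        p = rng.randint(5, L - 10)
        engaged = {"HP1": p, "HP2": p + 3}
        manifest, calls = [], []
        for lc in (16, 36):
            starts = range(1, L - lc + 2, 4)
            for start in starts:
                for state in ("WT", "ST"):
                    f = _frag(start=start, end=start + lc - 1, state=state, lc=lc)
                    manifest.append(f)
                    if f.contains(p, p + 3) and rng.random() < 0.5:
                        calls.append(
                            make_parent_call(
                                start=f.start, end=f.end, state=state, lc=lc,
                                stretch=(p - f.start + 1, p + 3 - f.start + 1),
                                engaged={k: v - f.start + 1
                                         for k, v in engaged.items()},
                            )
                        )
        if not calls:
            continue
        groups = group_motifs(calls)
        assert len(groups) == 1
        g = groups[0]
        occ = relative_occurrence(g, manifest)
        lo = lo_score(g, manifest)
        forming_ids = {c.fragment_id for c in calls}
        for (lc, state), got in occ.items():
            cont = [f for f in manifest
                    if f.length_class == lc and f.mutation_state == state
                    and f.contains(p, p + 3)]
            if not cont:
                assert got is None
            else:
                want = sum(fragment_id(f) in forming_ids for f in cont) / len(cont)
                assert got == pytest.approx(want)
        for state, got in lo.items():
            cont = [f for f in manifest
                    if f.mutation_state == state and f.contains(p, p + 3)]
            den = sum(f.length_class for f in cont)
            num = sum(f.length_class for f in cont
                      if fragment_id(f) in forming_ids)
            assert got == pytest.approx(num / den)


def test_best_core_scores_use_best_four_residue_window():
    call = make_parent_call(
        stretch=(1, 8),
        plddt=(50, 60, 90, 90, 90, 90, 60, 50),
        minpae=(9, 9, 2, 2, 2, 2, 9, 9),
    )
    group = group_motifs([call])[0]
    plddt, minpae = best_core_scores(group)
    assert plddt == pytest.approx(90.0)
    assert minpae == pytest.approx(2.0)


def test_best_core_scores_extremise_over_members():
    a = make_parent_call(stretch=(1, 4), plddt=(80,) * 4, minpae=(4,) * 4,
                        engaged={"HP1": 2})
    b = make_parent_call(start=2, end=17, stretch=(1, 4), plddt=(95,) * 4,
                        minpae=(6,) * 4, engaged={"HP1": 1})
    group = group_motifs([a, b])
    assert len(group) == 1
    plddt, minpae = best_core_scores(group[0])
    assert plddt == pytest.approx(95.0)
    assert minpae == pytest.approx(4.0)


def test_short_motif_warns_and_uses_full_run():
    call = make_parent_call(stretch=(1, 3), plddt=(80, 90, 100),
                            minpae=(1, 2, 3))
    group = group_motifs([call])[0]
    with pytest.warns(UserWarning, match="shorter than 4"):
        plddt, minpae = best_core_scores(group)
    assert plddt == pytest.approx(90.0)
    assert minpae == pytest.approx(2.0)


def test_ranking_prefers_long_class_occurrence():
    def motif(p, form_in):
        calls = []
        for lc, start in form_in:
            calls.append(make_parent_call(
                start=start, end=start + lc - 1, lc=lc,
                stretch=(p - start + 1, p + 3 - start + 1),
                engaged={"HP1": p - start + 1},
            ))
        return calls

    manifest = [
        _frag(start=1, end=52, lc=52), _frag(start=1, end=36, lc=36),
        _frag(start=1, end=16, lc=16), _frag(start=17, end=32, lc=16),
        _frag(start=21, end=36, lc=16),
    ]
    # motif A forms only in the 52mer; motif B only in a 16mer
    calls = motif(5, [(52, 1)]) + motif(25, [(16, 21)])
    groups = summarize(calls, manifest)
    assert groups[0].representative_residues[0] == 5
    assert groups[1].representative_residues[0] == 25


def test_disappearing_peak_marks_sites_in_window():
    wt = make_parent_call(start=1, end=16, state="WT", stretch=(5, 8),
                         engaged={"HP1": 5})
    impacts = impactful_mutations([wt], {"P1": frozenset({7, 14, 30})})
    assert [(m.impact, m.site, m.distance) for m in impacts] == [
        ("disappeared", 7, 0),
        ("disappeared", 14, 6),
    ]


def test_appearing_peak_reported_from_st_side():
    st = make_parent_call(start=1, end=16, state="ST", stretch=(5, 8),
                         engaged={"HP1": 5})
    impacts = impactful_mutations([st], {"P1": frozenset({6})})
    assert [(m.impact, m.site) for m in impacts] == [("appeared", 6)]


def test_label_change_reported_once_from_wt():
    wt = make_parent_call(start=1, end=16, state="WT", stretch=(5, 8),
                         engaged={"HP1": 5}, label="can.LIR")
    st = make_parent_call(start=1, end=16, state="ST", stretch=(5, 8),
                         engaged={"HP1": 5}, label="2-HP-LIR")
    impacts = impactful_mutations([wt, st], {"P1": frozenset({5})})
    assert len(impacts) == 1
    assert impacts[0].impact == "label-changed"
    assert impacts[0].label_from == "can.LIR"
    assert impacts[0].label_to == "2-HP-LIR"


def test_stable_peak_in_both_states_is_not_impactful():
    wt = make_parent_call(start=1, end=16, state="WT", stretch=(5, 8),
                         engaged={"HP1": 5})
    st = make_parent_call(start=1, end=16, state="ST", stretch=(5, 8),
                         engaged={"HP1": 5})
    assert impactful_mutations([wt, st], {"P1": frozenset({6})}) == []


def test_peak_without_sites_in_window_is_ignored():
    wt = make_parent_call(start=1, end=16, state="WT", stretch=(5, 8),
                         engaged={"HP1": 5})
    assert impactful_mutations([wt], {"P1": frozenset({40})}) == []


def test_negative_impact_distance_rejected():
    with pytest.raises(ValueError, match="distance"):
        MutationImpact("P1", (1, 16), 16, (5, 8), "disappeared",
                       "can.LIR", None, 6, -1)


def test_summarize_fills_all_statistics():
    call = make_parent_call(stretch=(5, 8), engaged={"HP1": 5, "HP2": 8})
    groups = summarize([call], [_frag()])
    g = groups[0]
    assert g.occurrence[(16, "WT")] == 1.0
    assert g.lo["WT"] == 1.0
    assert g.best_core_plddt is not None
    assert g.lo_mean == pytest.approx(1.0)
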