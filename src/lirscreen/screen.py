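"""End-to-end orchestration of the fragment screen.

The screen takes a target sequence, tiles it into overlapping fragments in
both mutation states, evaluates one predicted complex per unique fragment
(stretch detection + interaction classification), lifts the calls to parent
coordinates, aggregates them into ranked motif groups, annotates occlusion on
the full-length structure, and runs the wild-type/phosphomimetic comparison.
Missing predictions are tolerated: they are logged to a gaps file and the
statistics simply see fewer fragments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import aggregator, occlusion
from .aggregator import MotifGroup, MutationImpact, ParentCall
from .fragmenter import (
    FragmentRecord,
    TargetSequence,
    all_st_sites,
    apply_phosphomimetic,
    deduplicate_fragments,
    fragment_id,
    read_fasta,
    read_phosphosites,
    tile_sequence,
    write_fragment_fasta,
    write_manifest,
)
from .fixture_forge import fragment_file_stem
from .interaction_classifier import classify
from .interface_geometry import get_receptor_profile
from .stretch_detector import DetectionThresholds, detect_stretches
from .structure_io import (
    add_backbone_hydrogens,
    load_predicted_complex,
    peptide_min_pae,
)

__all__ = ["ScreenConfig", "ScreenResult", "generate_fragments", "evaluate_predictions",
           "run_screen", "shortlist"]

log = logging.getLogger(__name__)

# labels with a structurally characterised interaction mode; shortlists are
# restricted to these (plus the occlusion filter)
KNOWN_MODE_LABELS = {
    "can.LIR", "ap.LIR", "HP0-LIR", "2-HP-LIR", "CLIR", "sAIM",
    "[DE]W[DE]-LIR", "SIM",
}


@dataclass
class ScreenConfig:
    """Tunable screen parameters (defaults match the published protocol)."""

    lengths: tuple[int, ...] = (16, 36, 52)
    overlap: float = 0.75
    states: tuple[str, ...] = ("WT", "ST")
    receptor: str = "LC3B"
    thresholds: DetectionThresholds = field(default_factory=DetectionThresholds)
    plddt_mask: float = occlusion.PLDDT_MASK
    max_mean_depth: float = occlusion.MAX_MEAN_DEPTH_NM
    receptor_chain: str = "A"
    peptide_chain: str = "B"
    all_phosphosites: bool = False   # treat every S/T as a phosphosite
    seed: int = 0


@dataclass
class ScreenResult:
    manifest: list[FragmentRecord]          # logical fragments (incl. aliases)
    aliases: dict[str, str]
    calls: list[ParentCall]                 # logical calls
    groups: list[MotifGroup]                # ranked
    impacts: list[MutationImpact]
    gaps: list[str]                         # fragment ids without predictions
    annotation: occlusion.OcclusionAnnotation | None = None

    def accessible_groups(self) -> list[MotifGroup]:
        return [g for g in self.groups if not g.buried]


def generate_fragments(
    target: TargetSequence, config: ScreenConfig
) -> tuple[list[FragmentRecord], dict[str, str]]:
    """Tile in both mutation states across all length classes; dedup."""
    st_target = apply_phosphomimetic(target)
    unique: list[FragmentRecord] = []
    aliases: dict[str, str] = {}
    for length in config.lengths:
        wt = tile_sequence(target, length, config.overlap)
        if "ST" in config.states:
            st = tile_sequence(st_target, length, config.overlap)
            uniq, alias = deduplicate_fragments(wt, st)
        else:
            uniq, alias = wt, {}
        unique.extend(uniq)
        aliases.update(alias)
    return unique, aliases


def _logical_manifest(
    unique: list[FragmentRecord], aliases: dict[str, str]
) -> list[FragmentRecord]:
    physical = {fragment_id(f): f for f in unique}
    logical = list(unique)
    for alias_id, target_id in aliases.items():
        f = physical[target_id]
        state = alias_id.rsplit("|", 1)[1]
        logical.append(
            FragmentRecord(
                parent_id=f.parent_id,
                start=f.start,
                end=f.end,
                sequence=f.sequence,
                mutation_state=state,
                length_class=f.length_class,
            )
        )
    return logical


def evaluate_predictions(
    unique: list[FragmentRecord],
    predictions_dir: str | Path,
    config: ScreenConfig,
) -> tuple[list[ParentCall], list[str]]:
    """Detect and classify stretches in every available fragment prediction.

    Expects ``<stem>.pdb`` (or ``.cif``) plus ``<stem>_pae.json`` per
    fragment, where the stem is the fragment id with '|' replaced by '_'.
    Returns physical calls and the list of fragment ids lacking predictions.
    """
    predictions_dir = Path(predictions_dir)
    profile = get_receptor_profile(config.receptor)
    calls: list[ParentCall] = []
    gaps: list[str] = []
    for frag in unique:
        fid = fragment_id(frag)
        stem = fragment_file_stem(fid)
        structure = next(
            (
                p
                for ext in (".pdb", ".cif")
                if (p := predictions_dir / f"{stem}{ext}").exists()
            ),
            None,
        )
        pae = predictions_dir / f"{stem}_pae.json"
        if structure is None or not pae.exists():
            gaps.append(fid)
            continue
        cx = load_predicted_complex(
            structure, pae, config.receptor_chain, config.peptide_chain
        )
        cx = add_backbone_hydrogens(cx)
        plddt = cx.peptide_plddt()
        minpae = peptide_min_pae(cx)
        for stretch in detect_stretches(plddt, minpae, fid, config.thresholds):
            call = classify(stretch, cx, profile)
            calls.append(
                ParentCall(
                    fragment=frag,
                    call=call,
                    plddt=tuple(plddt[stretch.start - 1 : stretch.end]),
                    minpae=tuple(minpae[stretch.start - 1 : stretch.end]),
                )
            )
    if gaps:
        log.warning("%d fragments had no prediction files", len(gaps))
    return calls, gaps


def _expand_aliases(
    calls: list[ParentCall],
    unique: list[FragmentRecord],
    aliases: dict[str, str],
) -> list[ParentCall]:
    """Duplicate each physical call for the dedup-aliased logical fragments."""
    by_target: dict[str, list[str]] = {}
    for alias_id, target_id in aliases.items():
        by_target.setdefault(target_id, []).append(alias_id)
    out = list(calls)
    for call in calls:
        for alias_id in by_target.get(call.fragment_id, ()):
            state = alias_id.rsplit("|", 1)[1]
            f = call.fragment
            alias_frag = FragmentRecord(
                parent_id=f.parent_id,
                start=f.start,
                end=f.end,
                sequence=f.sequence,
                mutation_state=state,
                length_class=f.length_class,
            )
            out.append(
                ParentCall(
                    fragment=alias_frag,
                    call=call.call,
                    plddt=call.plddt,
                    minpae=call.minpae,
                )
            )
    return out


def _annotate_groups(
    groups: list[MotifGroup],
    annotation: occlusion.OcclusionAnnotation,
    residues_index: dict[int, int],
    max_mean_depth: float,
) -> None:
    """Attach mean depth / burial flag / secondary structure per group, over
    the representative (pocket-engaging) residue span."""
    for g in groups:
        lo, hi = g.representative_residues
        positions = [residues_index[i] for i in range(lo, hi + 1) if i in residues_index]
        if not positions:
            continue
        g.mean_depth_nm = annotation.mean_depth(positions)
        g.buried = g.mean_depth_nm > max_mean_depth
        g.secondary = "".join(
            annotation.secondary[p] or "?" for p in positions
        )


def shortlist(groups: list[MotifGroup], n: int = 5) -> list[MotifGroup]:
    """Top candidate motifs: known interaction mode and not buried."""
    return [
        g for g in groups if g.label in KNOWN_MODE_LABELS and not g.buried
    ][:n]


def run_screen(
    config: ScreenConfig,
    fasta: str | Path,
    predictions_dir: str | Path,
    phosphosites: str | Path | None = None,
    full_length: str | Path | None = None,
    outdir: str | Path | None = None,
) -> ScreenResult:
    """Run the whole screen for every target in the FASTA file.

    ``phosphosites`` is a two-column TSV; when absent (or when
    ``config.all_phosphosites``) every S/T counts as a potential site.
    ``full_length`` enables the occlusion annotation.  ``outdir`` triggers
    report files (manifest, calls, motif table, shortlist, occlusion table,
    impact list, gaps, and a JSON-lines run log).
    """
    sequences = read_fasta(fasta)
    site_table = read_phosphosites(phosphosites) if phosphosites else {}
    all_unique: list[FragmentRecord] = []
    aliases: dict[str, str] = {}
    targets: dict[str, TargetSequence] = {}
    for acc, seq in sequences.items():
        if config.all_phosphosites or acc not in site_table:
            sites = all_st_sites(seq)
        else:
            sites = site_table[acc]
        target = TargetSequence(acc, seq, phosphosites=sites)
        targets[acc] = target
        unique, alias = generate_fragments(target, config)
        all_unique.extend(unique)
        aliases.update(alias)

    physical_calls, gaps = evaluate_predictions(all_unique, predictions_dir, config)
    logical_calls = _expand_aliases(physical_calls, all_unique, aliases)
    manifest = _logical_manifest(all_unique, aliases)
    groups = aggregator.summarize(logical_calls, manifest)

    annotation = None
    if full_length is not None:
        fl = occlusion.load_full_length(full_length)
        annotation = occlusion.annotate(fl, plddt_mask=config.plddt_mask)
        index = {r.index: i for i, r in enumerate(fl.residues)}
        _annotate_groups(groups, annotation, index, config.max_mean_depth)

    impacts = aggregator.impactful_mutations(
        logical_calls, {acc: t.phosphosites for acc, t in targets.items()}
    )
    result = ScreenResult(
        manifest=manifest,
        aliases=aliases,
        calls=logical_calls,
        groups=groups,
        impacts=impacts,
        gaps=gaps,
        annotation=annotation,
    )
    if outdir is not None:
        _write_reports(result, all_unique, config, Path(outdir))
    return result


# ---------------------------------------------------------------------------
# report files

def _write_reports(
    result: ScreenResult,
    unique: list[FragmentRecord],
    config: ScreenConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fragment_fasta(unique, outdir / "fragments.fasta")
    write_manifest(unique, result.aliases, outdir / "manifest.tsv")
    (outdir / "gaps.txt").write_text("".join(f"{g}\n" for g in result.gaps))

    with open(outdir / "calls.tsv", "w") as fh:
        fh.write(
            "fragment_id\tstretch\tparent_range\tlabel\tHP0\tHP1\tHP2"
            "\thbonds\tcriteria\tmotif\n"
        )
        for c in sorted(result.calls, key=lambda c: (c.fragment_id, c.parent_range)):
            s = c.call.stretch
            pockets = {p: a.residue for p, a in c.call.pockets.items()}
            flags = (
                "".join("1" if f else "0" for f in c.call.criteria_flags)
                if c.call.criteria_flags
                else "-"
            )
            pr = c.parent_range
            fh.write(
                f"{c.fragment_id}\t{s.start}-{s.end}\t{pr[0]}-{pr[1]}\t{c.label}"
                f"\t{pockets.get('HP0') or '-'}\t{pockets.get('HP1') or '-'}"
                f"\t{pockets.get('HP2') or '-'}\t{c.call.hbond_count}\t{flags}"
                f"\t{c.call.motif_string}\n"
            )

    classes = sorted(config.lengths, reverse=True)
    with open(outdir / "motifs.tsv", "w") as fh:
        occ_cols = "\t".join(f"occ_{lc}_{st}" for lc in classes for st in ("WT", "ST"))
        fh.write(
            "rank\tparent\twindow\tcore\tlabel\tengaged\t"
            f"{occ_cols}\tLO_WT\tLO_ST\tLO_mean\tbest_core_plddt\t"
            "best_core_minpae\tmean_depth_nm\tburied\tss\tn_members\n"
        )
        for rank, g in enumerate(result.groups, start=1):
            occ = "\t".join(
                _fmt(g.occurrence.get((lc, st)))
                for lc in classes
                for st in ("WT", "ST")
            )
            engaged = ",".join(f"{p}:{r}" for p, r in sorted(g.engaged_parent.items()))
            w, core = g.window, g.representative_residues
            fh.write(
                f"{rank}\t{g.parent_id}\t{w[0]}-{w[1]}\t{core[0]}-{core[1]}"
                f"\t{g.label}\t{engaged or '-'}\t{occ}"
                f"\t{_fmt(g.lo.get('WT'))}\t{_fmt(g.lo.get('ST'))}"
                f"\t{_fmt(g.lo_mean)}\t{_fmt(g.best_core_plddt)}"
                f"\t{_fmt(g.best_core_minpae)}\t{_fmt(g.mean_depth_nm)}"
                f"\t{int(g.buried)}\t{g.secondary or '-'}\t{len(g.members)}\n"
            )

    with open(outdir / "shortlist.tsv", "w") as fh:
        fh.write("parent\tcore\tlabel\tLO_mean\tmean_depth_nm\n")
        for g in shortlist(result.groups):
            core = g.representative_residues
            fh.write(
                f"{g.parent_id}\t{core[0]}-{core[1]}\t{g.label}"
                f"\t{_fmt(g.lo_mean)}\t{_fmt(g.mean_depth_nm)}\n"
            )

    with open(outdir / "impacts.tsv", "w") as fh:
        fh.write(
            "parent\twindow\tlength\tmotif\timpact\tlabel_from\tlabel_to"
            "\tsite\tdistance\n"
        )
        for m in result.impacts:
            fh.write(
                f"{m.parent_id}\t{m.window[0]}-{m.window[1]}\t{m.length_class}"
                f"\t{m.motif_range[0]}-{m.motif_range[1]}\t{m.impact}"
                f"\t{m.label_from}\t{m.label_to or '-'}\t{m.site}\t{m.distance}\n"
            )

    if result.annotation is not None:
        ann = result.annotation
        with open(outdir / "occlusion.tsv", "w") as fh:
            fh.write("position\tdepth_nm\tss\tassigned\n")
            for i, (d, ss) in enumerate(zip(ann.depth_nm, ann.secondary), start=1):
                assigned = not np.isnan(d)
                fh.write(
                    f"{i}\t{_fmt(None if not assigned else float(d))}"
                    f"\t{ss or '-'}\t{int(assigned)}\n"
                )

    with open(outdir / "run_log.jsonl", "w") as fh:
        fh.write(
            json.dumps(
                {
                    "event": "screen_complete",
                    "config": {
                        "lengths": list(config.lengths),
                        "overlap": config.overlap,
                        "receptor": config.receptor,
                        "min_len": config.thresholds.min_len,
                        "min_plddt": config.thresholds.min_plddt,
                        "max_minpae": config.thresholds.max_minpae,
                        "plddt_mask": config.plddt_mask,
                        "max_mean_depth": config.max_mean_depth,
                        "seed": config.seed,
                    },
                    "n_fragments": len(unique),
                    "n_calls": len(result.calls),
                    "n_groups": len(result.groups),
                    "n_gaps": len(result.gaps),
                }
            )
            + "\n"
        )


def _fmt(v: float | None) -> str:
    return "NA" if v is None else f"{v:.4g}"
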