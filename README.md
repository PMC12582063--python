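# lirscreen

Fragment-based structural screen for short linear motifs that bind
autophagy receptors (LIR/AIM motifs on the Atg8 family: LC3B, GABARAP,
Atg8, ATG8E, ATG8CL) or SUMO2 (SIM motifs), built on AlphaFold-Multimer
style predictions of receptor–fragment complexes.

The screen tiles a target sequence into overlapping fragments, expects one
predicted complex (structure + PAE matrix) per fragment, detects confidently
predicted peptide stretches, classifies the interaction mode from the
interface geometry, aggregates repeated observations of the same motif
across fragment lengths and phosphomimetic states, and filters candidates by
their accessibility in the full-length protein.

## Pipeline

1. **Fragmentation** (`fragmenter`) — tile the target into 16/36/52-mers at
   75 % overlap (the final window is shifted left to end at the C terminus),
   add phosphomimetic (S/T→E) variants of every window containing a
   phosphosite, and de-duplicate site-free windows against their wild-type
   twins.
2. **Stretch detection** (`stretch_detector`) — per peptide residue, pLDDT
   and minPAE (mean of the 3 lowest off-diagonal PAE column entries).
   A stretch is a maximal run of ≥ 4 residues with mean pLDDT ≥ 75 and mean
   minPAE ≤ 8, containing at least one residue that passes both cutoffs on
   its own.
3. **Interface geometry** (`interface_geometry`) — hydrophobic-pocket
   engagement (HP0 with its gate, HP1, HP2; the SUMO2 groove), DSSP-style
   backbone hydrogen-bond energies to the receptor β2 strand, and Cα
   contact counts.
4. **Classification** (`interaction_classifier`) — canonical LIR
   (Θ-X-X-Γ anchored in HP1/HP2 with ≥ 2 β2 hydrogen bonds), the
   non-canonical modes (ap.LIR, HP0-LIR, 2-HP-LIR, CLIR, sAIM,
   [DE]W[DE]-LIR) in a fixed cascade, lcLIR, localized binders (other@LDS,
   UIM-like) and SIM calls against SUMO2.
5. **Aggregation** (`aggregator`) — group the same motif observed in
   different fragments, compute relative occurrence per (length class,
   state), the length-weighted occurrence score (LO), best 4-residue core
   confidence, a ranked motif table and WT↔phosphomimetic impact calls.
6. **Occlusion** (`occlusion`) — residue depth (nm, probe-corrected
   molecular surface) and simplified secondary structure on the full-length
   prediction; motifs whose mean depth exceeds 0.3 nm are flagged buried and
   kept off the shortlist.

## Worked example

The package ships a fixture forge that builds a complete synthetic screen: a
120-residue target with one exposed canonical LIR (`WEEL` at 85–88) and one
decoy (`FEEI` at 15–18) that the full-length structure buries.

```console
$ lirscreen fixtures corpus --out corpus --seed 7
corpus for SYN1: 78 fragments -> corpus

$ lirscreen run --fasta corpus/target.fasta --predictions corpus/predictions \
      --sites corpus/phosphosites.tsv --full-length corpus/full_length.pdb \
      --out screen
2 motif groups from 40 calls (0 missing predictions) -> screen
```

`screen/motifs.tsv` ranks every motif group with its occurrence statistics
and occlusion annotation:

```text
rank  parent  window  core   label    engaged        LO_WT  LO_ST  mean_depth_nm  buried
1     SYN1    15-18   15-18  can.LIR  HP1:15,HP2:18  1      1      0.6554         1
2     SYN1    85-88   85-88  can.LIR  HP1:85,HP2:88  1      1      0.1617         0
```

`screen/shortlist.tsv` keeps only accessible motifs with a known interaction
mode — the buried decoy is excluded:

```text
parent  core   label    LO_mean  mean_depth_nm
SYN1    85-88  can.LIR  1        0.1617
```

Individual stages are available as subcommands. Classifying a single
predicted complex:

```console
$ lirscreen classify --structure can.LIR.pdb --pae can.LIR_pae.json
stretch  label    pockets        hbonds  motif
1-10     can.LIR  HP1:3,HP2:6    2       sa[F]em[L]aasa
```

(The motif string uppercases and brackets the pocket-anchoring residues.)

Run `lirscreen --help` for the full command list (`fragment`, `detect`,
`classify`, `occlusion`, `run`, `summarize`, `fixtures`).

## Using real predictions

`lirscreen fragment` writes `fragments.fasta` ready for batch prediction
against the receptor of interest. Name each model `<fragment_id>.pdb` (or
`.cif`) with `|` replaced by `_`, place the PAE matrix next to it as
`<fragment_id>_pae.json` (AlphaFold/ColabFold dialects are accepted), and
point `lirscreen run` at the directory. The receptor chain is `A` and the
peptide chain `B` by default.

## Testing

```sh
python -m pytest -q tests/
```

`scripts/acceptance.py --seed 1 --out results/acceptance.json` runs the main
computations end to end on synthetic data and writes the key quantities as
JSON.

See `docs/methods.md` for the scientific definitions and thresholds.
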