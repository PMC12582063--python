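# Methods

This document defines every quantity the screen computes and the thresholds
it applies. All residue indices are 1-based; fragment-local positions are
counted from the fragment's first residue.

## Fragmentation

A target of length *L* is tiled with fixed-length windows of 16, 36 and 52
residues at 75 % overlap (step = length / 4). Windows start at 1, 1 + step,
…; the final window is shifted left so that it ends exactly at residue *L*,
guaranteeing full coverage without overhang. A centered length scan
(length 4 → 68 in steps of 2 around a position of interest) is available for
follow-up mapping of a single motif.

For every annotated (or, by default, every) serine/threonine phosphosite,
a phosphomimetic fragment set is generated by substituting S/T → E. Windows
that contain no phosphosite are identical in both states; only the wild-type
copy is kept and the phosphomimetic twin is recorded as an alias, so each
unique sequence is predicted once but counted in both states during
aggregation.

## Per-residue confidence

* **pLDDT** is read from the B-factor column of the predicted model
  (clamped to [0, 100]).
* **minPAE** of a residue is the mean of the 3 lowest entries of its PAE
  *column* (the errors reported when the residue is scored against every
  possible alignment residue), excluding the diagonal self-entry. Using the
  column rather than the row scores the peptide residue in the frame of the
  receptor.

## Stretch detection

A *stretch* is a confidently predicted, receptor-associated run of peptide
residues. An interval qualifies when

* it is at least **4** residues long,
* its mean pLDDT is ≥ **75** and its mean minPAE is ≤ **8.0** (boundary
  values qualify), and
* it contains at least one *seed* residue that passes both cutoffs
  individually.

All maximal qualifying intervals are enumerated (vectorised over every
interval via 2-D prefix sums). Overlapping intervals are resolved
left-to-right: if their union still qualifies they are merged, otherwise the
interval with the higher mean pLDDT survives; the pass repeats until no
overlaps remain.

## Interface geometry

Receptor pocket definitions live in `src/lirscreen/data/receptors.yaml`.
Each hydrophobic pocket is anchored by two receptor Cα atoms with individual
distance cutoffs; a peptide residue *engages* a pocket when any of its heavy
atoms lies strictly within both cutoffs. The first stretch residue (N→C)
that engages is assigned to the pocket.

| Receptor | HP0 anchors (Å) | gate | HP1 anchors (Å) | HP2 anchors (Å) | β2 strand | UDS |
|----------|----------------|------|-----------------|-----------------|-----------|-----|
| LC3B | 7@4.50, 34@6.25 | 50 vs Cα 7 | 52@5.25, 108@9.75 | 54@4.75, 67@9.50 | 50–55 | 79–82 |
| GABARAP | 7@4.50, 34@6.25 | 49 vs Cα 7 | 51@5.25, 106@9.75 | 53@4.75, 66@9.50 | 49–54 | 78–81 |
| Atg8 | 6@4.50, 33@6.25 | 48 vs Cα 6 | 50@5.25, 105@9.75 | 52@4.75, 65@9.50 | 48–53 | 77–80 |
| ATG8E | 5@4.50, 32@6.25 | 47 vs Cα 5 | 49@5.25, 104@9.75 | 51@4.75, 64@9.50 | 47–52 | 76–79 |
| ATG8CL | 5@4.50, 32@6.25 | 47 vs Cα 5 | 49@5.25, 104@9.75 | 51@4.75, 64@9.50 | 47–52 | 76–79 |

SUMO2 exposes a single binding groove (residues 29–34).

**HP0 gate.** HP0 is only available when its gate sidechain has swung away:
the minimum distance between the pocket Cα and any heavy sidechain atom of
the gate residue must be strictly greater than **9.0 Å**. A gate residue
without sidechain atoms (glycine) leaves the pocket open.

**Backbone hydrogen bonds.** Amide hydrogens are placed geometrically
(H = N + unit(C<sub>prev</sub> − O<sub>prev</sub>); prolines and chain
N-termini carry none). A bond between donor (N, H) and acceptor (C, O) is
counted when the DSSP electrostatic energy

E = 0.084 · (1/r<sub>ON</sub> + 1/r<sub>CH</sub> − 1/r<sub>OH</sub> − 1/r<sub>CN</sub>) · 332 kcal/mol

is strictly below **−0.5 kcal/mol**. Both donation directions
(peptide→receptor and receptor→peptide) are counted against the β2 strand
(or the SUMO2 groove).

**Cα contacts.** The number of (stretch Cα, receptor-range Cα) pairs at a
distance strictly below **5.0 Å**.

## Interaction classification

Four criteria are evaluated for a stretch against an Atg8-family receptor:

1. *(i)* a residue engages HP1;
2. *(ii)* a residue engages HP2;
3. *(iii)* ≥ 2 backbone hydrogen bonds to the β2 strand;
4. *(iv)* the sequence pattern Θ-X-X-Γ with Θ ∈ {W, F, Y} engaging HP1 and
   Γ ∈ {L, I, V} engaging HP2 at spacing +3.

A stretch satisfying all four is a **can.LIR**. Otherwise the non-canonical
modes are tested in a fixed, order-sensitive cascade (first match wins):

| Label | Requirements |
|-------|--------------|
| ap.LIR | (i) ∧ (ii) ∧ (iii) with Θ in HP2 and Γ in HP1 (inverted orientation, HP1 residue = HP2 residue + 3) |
| HP0-LIR | HP0 engaged (gate open) ∧ (ii), Θ…Γ spacing +5 with an aliphatic at Θ+2 |
| 2-HP-LIR | (i) ∧ (ii) without the canonical pattern |
| CLIR | (ii) ∧ (iii) with an aliphatic Γ-Γ-Γ core (M allowed) ending in HP2 |
| sAIM | Γ two positions before Θ, Θ engaging HP0 or HP1 |
| [DE]W[DE]-LIR | (i) with a tryptophan in HP1 flanked by D/E on both sides |

A stretch engaging HP1 without any pattern match is an **lcLIR**
(low-complexity LIR). Without pocket engagement, ≥ 5 Cα contacts to the β2
strand yield **other@LDS**, ≥ 5 contacts to the UIM-docking site yield
**UIM-like**, and everything else is **other**. Against SUMO2, ≥ 2 backbone
hydrogen bonds to the groove yield **SIM** (the canonical
`[LIV][LIV]x[LIV]` / `[LIV]x[LIV][LIV]` pattern is reported as metadata but
not required).

## Aggregation

Calls are mapped back to parent coordinates. Two calls belong to the same
**motif group** when they share the parent, the label and the engaged parent
residues, and their stretches overlap by ≥ 3 parent residues
(single-linkage, so grouping is transitive and order-independent).

The span a fragment must fully cover to *contain* the motif is the engaged
residue span (or, for pocketless labels, the intersection of the member
stretches).

* **Relative occurrence** per (length class, state): forming fragments /
  containing fragments (None when nothing of that class and state contains
  the motif).
* **LO score** per state: Σ lengths of forming fragments / Σ lengths of
  containing fragments, pooled over length classes. Example: a motif formed
  by two 16-mers but missed by the one containing 36-mer scores
  32/68 ≈ 0.47.
* **Best core**: the best 4-residue sliding-window mean of pLDDT (max) and
  minPAE (min) over all member stretches.
* **Ranking**: by summed WT+ST occurrence, longest length class first.
* **Mutation impacts**: for each phosphosite inside a motif window, a peak
  present only in WT is *disappeared*, only in ST *appeared*, and a
  WT↔ST label change is reported once from the WT side.

## Occlusion

On the full-length prediction, residues with pLDDT < **70** are masked
(treated as disordered). For the remaining residues, depth is the mean
distance of a residue's heavy atoms to the probe-corrected molecular
surface, in nm. The surface is sampled with a 1.5 Å probe on a Fibonacci
sphere (96 directions per atom); termini of masked-out segments spawn
unconditional probe spheres so artificial chain breaks read as exposed.
Masked residues contribute the depth of a fully exposed residue
(**0.142 nm**) to motif means. A motif whose mean depth exceeds **0.3 nm**
is flagged buried and excluded from the shortlist. Simplified secondary
structure (H/E/−) is assigned with DSSP via mdtraj. When the external
`msms` binary is on PATH it is used for depth instead of the built-in
sampler.

## Thresholds at a glance

| Quantity | Threshold |
|----------|-----------|
| Stretch minimum length | 4 residues |
| Stretch mean pLDDT | ≥ 75 |
| Stretch mean minPAE | ≤ 8.0 |
| minPAE k | 3 lowest column entries |
| HP0 gate open | > 9.0 Å (strict) |
| H-bond energy | < −0.5 kcal/mol (strict) |
| β2 H-bonds for can.LIR / SIM | ≥ 2 |
| Cα contact distance | < 5.0 Å (strict) |
| Cα contacts for other@LDS / UIM-like | ≥ 5 |
| pLDDT occlusion mask | 70 |
| Exposed-residue default depth | 0.142 nm |
| Buried-motif cutoff | > 0.3 nm |
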