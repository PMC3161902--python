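# Methods

## Motif grammar

Conserved tRNase Z features are modeled as degenerate consensus patterns:
an uppercase letter must match exactly, `x` matches any residue (including
the unknown residue `X`, which matches *only* wildcards), and `[KL]`
matches any listed residue. A pattern matches a window if the number of
violated positions is at most the motif's mismatch budget. Scanning is
exhaustive over all windows (the vectorised scanner is tested against a
brute-force window enumeration), so no heuristic seeding can lose hits.

Default budgets: 0 mismatches for patterns of ≤ 6 positions, 1 for longer
ones (the 18-residue KL motif, the 7-residue EGxSxxG motif, and HEAT which
is explicitly allowed one substitution). The variant catalytic-assist
patterns follow the observed substitution spectra: `xExT` is modeled as
`[TMVL]E[SAMTCA]T` (invariant His replaced by Thr/Met/Val/Leu; Ala often
replaced by Ser, occasionally Met/Thr/Cys) and `HxH` as `H[TS]H` (Ser
mostly replaced by Thr; Thr substituted by His).

Motifs I, III, IV and V have no explicit residue-level consensus in the
family literature beyond an invariant Asp (I, IV) or conserved His
(III, V). The shipped catalog uses minimal anchored placeholders (`xxDx`,
`xHxx`, `xDxx`, `xHxx`) and restricts them by a *window*: their hit must
begin within 60–80 residues of the previously placed motif in a chain.
The window applies only when a preceding hit exists, so knocking out the
rank-1 motif does not spuriously erase Motif I from the evidence; window
sizes were chosen to span the longest flexible arm (62 aa) plus a linker,
so single-motif knockouts never cascade. These placeholders are
deliberately low-information; classification weight rests on the
explicitly specified motifs (His motif, arm motifs, PxKxRN/EGxSxxG,
HEAT/xExT, HST/HxH). The catalog file format is plain text and every
pattern, budget, rank and window is overridable.

Pseudo-motifs (the degenerate N-half remnants in long forms) reuse the
parent pattern with the mismatch budget raised by 2 and the catalytically
critical position *required* to mismatch, capturing "differs at critical
residues" rather than mere divergence.

## Chain assembly and classification

`find_motif_chain` selects, by dynamic programming over all candidate
hits, the maximum-coverage set of non-overlapping hits whose motif ranks
strictly increase along the sequence (the canonical N→C slot order:
PxKxRN/EGxSxxG, Motif I, Motif II, arm motif, Motif III, Motif IV,
HEAT/xExT, Motif V, HST/HxH). Ties are broken by fewer total mismatches,
then leftmost starts, making every output deterministic.

Form calling uses a banded size rule: S ≤ 450 aa, L ≥ 600 aa, AMBIGUOUS
between. The nominal size classes are 300–400 and 700–800 aa, but real
candidate inventories contain 425–445 aa short-like and 731 aa long-like
proteins; an ambiguous-length protein with a complete architecture is
resolved to the corresponding form (evidence-based override), otherwise
reported UNKNOWN.

The flexible arm is delineated as the segment between the end of the
Motif II hit and the start of the Motif III hit — the structural placement
of the exosite; the family texts do not state the arm's sequence position,
so the anchors are configurable. Arm typing: a KL-bearing, GP-free arm of
≤ 45 aa is TM-type; a GP-bearing arm is bacterial-type up to 58 aa and
eukaryotic-type beyond (cutoffs midway between the nominal ~30/~55/~62 aa
lengths).

Long forms are split at the start of the first complete C-half
architecture chain found scanning outward from the sequence midpoint
(fallback: the midpoint). The "eukaryotic GP arm in the N-half" condition
is implemented as a GP hit inside the N-half pseudo-architecture chain:
the pseudo-motifs are too degenerate to anchor an arm interval (there is
no pseudo Motif III), so GP presence is the operative evidence.

Decision table: a complete TM architecture → TM-type S; a complete
bacterial architecture → bacterial-type S (if both complete, fewer total
mismatches wins, a tie going to TM when the KL arm is present); a complete
C-half plus N-half GP → eukaryotic-type L; anything else of tRNase Z size
is a TLP, sub-typed S or L by the whole-protein form, with the missing
required motifs reported. PxKxRN absence alone is never used as TM
evidence — the TM call requires the EGxSxxG motif that occupies the
analogous position.

## CCA census

Annotated tRNA gene spans are assumed to *include* the discriminator N73
as their last base, so tRNA positions 74–76 are the first three
coding-strand bases downstream of the feature ('+': bases `[end, end+3)`;
'−': reverse complement of `[start−3, start)`). A
`--discriminator-excluded` flag shifts the window by one for annotation
conventions that stop before the discriminator. Categories partition all
non-truncated records: `CCA`; `CC*` (CCN); `C**` with second base ≠ C
(CNN); first base ≠ C (OTHER); windows clipped by a contig edge are
TRUNCATED, reported separately and excluded from totals by default.
Percent = round-half-up of 100 × (CCA+CCN+CNN)/total; this rounding
uniquely reproduces all 15 published per-genome percentages from their
printed counts. (The accompanying running text quotes 31% for
*A. thaliana* where the printed table gives 12/37 → 32; the package
follows the table.) GFF3 (1-based closed) and BED (0-based half-open) are
both normalized to internal 0-based half-open coordinates on read; RNA
letters are normalized to DNA.

## Conservation statistics

Pairwise identity/similarity use Needleman–Wunsch with linear gap penalty
(defaults match +1, mismatch 0, gap −1) and a deterministic traceback
(diagonal, then up, then left). Linear rather than affine gaps keeps the
optimum checkable against exhaustive enumeration of all alignments; an
affine mode is not provided. The percentage denominator defaults to
columns where neither sequence is gapped (selectable: shorter-sequence or
full-alignment length — the published pairwise tables do not state their
convention, so the choice is explicit). Similarity counts identical pairs
plus pairs sharing one of the widely used "strong" conservation groups
(STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW); the group set is a
parameter.

Logo matrices report per-column frequencies over the 20-letter alphabet
and IC = log2 20 − H (bits), with no small-sample correction. Neighbor
joining follows the standard Q-criterion agglomeration with ties broken by
the lexicographically smallest label pair (internal nodes labelled by
their smallest leaf), terminating with the three-point formulas; applied
to any additive matrix it provably recovers the generating topology, which
the tests exercise with random 8-taxon trees. Tree distances for the
clade check are p-distances (1 − identical fraction over gapless columns)
computed on each protein's concatenated motif regions.

## Synthetic data

The generators define the study conditions. Proteins are assembled from
uniformly sampled pattern instances placed in canonical order, joined by
4–12 residue linkers, with leader/tail padding to the type's nominal
length (TM-type S 320 aa with a 30 aa arm; bacterial-type S 340 aa with a
55 aa arm; eukaryotic-type L 880 aa with a 62 aa N-half arm and the
junction at half length). Linkers and wildcard fills are drawn from the
*safe composition* — the residues (F, Q, W with the default catalog) that
appear in no exact or set pattern position — so linkers can never complete
a motif by chance and planted-recovery tests are exact rather than
probabilistic. Knockouts either overwrite an instance with safe residues
(length-preserving delete) or mutate budget+1 anchored positions to Gln
(corrupt mode, echoing the naturally observed His→Gln TLP). Genomes plant
non-overlapping 70–90 bp genes separated by 6–30 bp, with each gene's
coding-strand post-discriminator trinucleotide sampled from its assigned
category and minus-strand genes realized by reverse complement. All
generators are deterministic per seed, and seeds are recorded in emitted
headers.

What the fixtures do *not* emulate: substitution/indel evolution, motif
divergence beyond the mismatch budgets, compositional bias of real
proteomes, introns/misannotation, or duplicated inverted-repeat tRNA
copies. Passing tests therefore demonstrate the correctness of the
scanning, chaining, decision and census machinery under the stated motif
grammar — not the sensitivity of the catalog on divergent real sequences,
where the placeholder Motif I/III/IV/V patterns and the unspecified
presence tolerance would dominate.

## Problem sizes and numerical choices

The test-suite and reproduction-script workloads are: a 200-protein
balanced panel (exact type recovery and exact missing sets), 1000 random
scanner-oracle cases (sequences ≤ 60 aa, patterns ≤ 8), 20 census genomes
of 20–200 genes, 40 alignment-enumeration cases (≤ 7 aa), 10 random
8-taxon NJ round-trips, and five 15-taxon clan replicates — sizes at which
the independent oracles are exact and the whole run completes in seconds.
Logo frequency rows are validated to 1e−9; NJ accepts matrices symmetric
to 1e−9 and requires an exactly zero diagonal. Internal coordinates are
0-based half-open everywhere.

## Known limitations

* Motif I/III/IV/V placeholder patterns are intentionally minimal; on real
  divergent sequences they should be refined from family alignments before
  the chain evidence is trusted.
* The mismatch tolerance implicitly used by human curators when calling a
  motif "present" in divergent species is unknown; the catalog makes it
  explicit but the defaults are a choice.
* The published 93%/95% identity/similarity for the closest sorghum/foxtail
  millet pair depends on fetching two database records and on alignment
  parameters; it is not recomputed here.
* Subcellular localization is bookkept (signal sequences and lengths), not
  predicted; localization is orthogonal to type and no typing rule uses it.
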