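"""Seeded generators of planted-structure fixtures.

Two substrates are emulated: (a) tRNase Z proteins of each type, assembled
from motif-consensus instances joined by linkers drawn from a "safe"
residue composition that cannot complete any catalog pattern by chance, so
planted-recovery tests are exact rather than probabilistic; (b) mini
chloroplast genomes with non-overlapping tRNA genes on both strands whose
post-discriminator trinucleotides follow a prescribed CCA/CCN/CNN/OTHER
mixture.  Every emitted artifact comes with a ground-truth object recording
the planted coordinates/categories, and identical spec + seed reproduces
identical bytes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .catalog import AA20, WILDCARD, MotifCatalog, MotifModel, default_catalog
from .census import TrnaGene

DNA = "ACGT"

# nominal sizes from the family's size classes and arm types
TYPE_DEFAULTS = {
    "TM_S": {"length": 320, "arm_length": 30},
    "BACTERIAL_S": {"length": 340, "arm_length": 55},
    "EUKARYOTIC_L": {"length": 880, "arm_length": 62},
}

_ARM_SLOT = "__ARM__"

# motif layout per type, N->C; the arm slot wraps the arm motif in padding
_LAYOUTS = {
    "TM_S": [
        "EGXSXXG",
        "MOTIF_I",
        "MOTIF_II",
        (_ARM_SLOT, "KL"),
        "MOTIF_III",
        "MOTIF_IV",
        "XEXT",
        "MOTIF_V",
        "HXH",
    ],
    "BACTERIAL_S": [
        "PXKXRN",
        "MOTIF_I",
        "MOTIF_II",
        (_ARM_SLOT, "GP"),
        "MOTIF_III",
        "MOTIF_IV",
        "HEAT",
        "MOTIF_V",
        "HST",
    ],
    "EUKARYOTIC_L_N": [
        "PSEUDO_PXKXRN",
        "PSEUDO_I",
        "PSEUDO_II",
        (_ARM_SLOT, "GP"),
    ],
    "EUKARYOTIC_L_C": [
        "PXKXRN",
        "MOTIF_I",
        "MOTIF_II",
        "MOTIF_III",
        "MOTIF_IV",
        "HEAT",
        "MOTIF_V",
        "HST",
    ],
}


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinSpec:
    ztype: str  # TM_S | BACTERIAL_S | EUKARYOTIC_L
    length: int | None = None
    arm_length: int | None = None
    knockouts: tuple[str, ...] = ()
    knockout_mode: str = "delete"  # delete | corrupt
    seed: int = 0

    def resolved(self) -> "ProteinSpec":
        if self.ztype not in TYPE_DEFAULTS:
            raise SyntheticSpecError(f"unknown ztype {self.ztype!r}")
        defaults = TYPE_DEFAULTS[self.ztype]
        return replace(
            self,
            length=self.length or defaults["length"],
            arm_length=self.arm_length or defaults["arm_length"],
        )


@dataclass(frozen=True)
class GenomeSpec:
    n_cca: int
    n_ccn: int
    n_cnn: int
    n_other: int
    minus_fraction: float = 0.5
    gene_length: tuple[int, int] = (70, 90)
    intergenic: tuple[int, int] = (6, 30)
    seq_id: str = "synthetic_cp"
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_cca + self.n_ccn + self.n_cnn + self.n_other

    def __post_init__(self) -> None:
        if min(self.n_cca, self.n_ccn, self.n_cnn, self.n_other) < 0:
            raise SyntheticSpecError("negative category count")
        if not 0.0 <= self.minus_fraction <= 1.0:
            raise SyntheticSpecError("minus_fraction outside [0, 1]")
        if self.n_genes == 0:
            raise SyntheticSpecError("empty genome spec")


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    category: str
    trinucleotide: str
    start: int
    end: int
    strand: str


@dataclass
class SyntheticTruth:
    """Planted coordinates / categories for one emitted artifact."""

    seed: int
    motifs: dict[str, tuple[int, int]] = field(default_factory=dict)
    junction: int | None = None
    knockouts: dict[str, tuple[int, int]] = field(default_factory=dict)
    genes: list[GeneTruth] = field(default_factory=list)


def safe_linker_alphabet(catalog: MotifCatalog | None = None) -> str:
    """Residues absent from every exact/set pattern position in the catalog.

    Linkers drawn from this composition can never complete a catalog motif
    by chance (any non-wildcard position would need an excluded residue).
    """
    catalog = catalog or default_catalog()
    used: set[str] = set()
    for model in catalog.entries.values():
        for spec in model.positions:
            used.update(spec)
    safe = "".join(res for res in AA20 if res not in used)
    if not safe:
        raise SyntheticSpecError("catalog leaves no safe linker residues")
    return safe


def sample_instance(model: MotifModel, rng: random.Random, safe: str) -> str:
    """One concrete instance of a motif pattern.

    Wildcards are filled from the safe composition.  Forced-mismatch
    positions (pseudo-motifs) get a safe residue, which by construction
    violates the parent spec there.
    """
    out = []
    forced = set(model.forced_mismatch_positions)
    for k, spec in enumerate(model.positions):
        if k in forced or spec == WILDCARD:
            out.append(rng.choice(safe))
        elif len(spec) == 1:
            out.append(spec)
        else:
            out.append(rng.choice(spec))
    return "".join(out)


def _linker(rng: random.Random, safe: str, length: int) -> str:
    return "".join(rng.choice(safe) for _ in range(length))


def _assemble(
    layout: list,
    arm_length: int,
    catalog: MotifCatalog,
    rng: random.Random,
    safe: str,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Core region: motif instances in canonical order joined by linkers."""
    parts: list[str] = []
    coords: dict[str, tuple[int, int]] = {}
    pos = 0

    def push(text: str, name: str | None = None) -> None:
        nonlocal pos
        if name is not None:
            coords[name] = (pos, pos + len(text))
        parts.append(text)
        pos += len(text)

    for i, slot in enumerate(layout):
        if i > 0 and not (isinstance(slot, tuple) or isinstance(layout[i - 1], tuple)):
            push(_linker(rng, safe, rng.randint(4, 12)))
        if isinstance(slot, tuple):
            _, arm_motif = slot
            inst = sample_instance(catalog.motif(arm_motif), rng, safe)
            if arm_length < len(inst):
                raise SyntheticSpecError(
                    f"arm length {arm_length} cannot hold {arm_motif}"
                )
            pad = arm_length - len(inst)
            left = pad // 2
            push(_linker(rng, safe, left))
            push(inst, arm_motif)
            push(_linker(rng, safe, pad - left))
        else:
            push(sample_instance(catalog.motif(slot), rng, safe), slot)
    return "".join(parts), coords


def _shift(coords: dict[str, tuple[int, int]], offset: int) -> dict[str, tuple[int, int]]:
    return {k: (s + offset, e + offset) for k, (s, e) in coords.items()}


def synth_protein(
    spec: ProteinSpec, catalog: MotifCatalog | None = None
) -> tuple[str, SyntheticTruth]:
    """Emit one synthetic protein plus its planted-motif ground truth."""
    catalog = catalog or default_catalog()
    spec = spec.resolved()
    rng = random.Random(spec.seed)
    safe = safe_linker_alphabet(catalog)

    if spec.ztype == "EUKARYOTIC_L":
        n_core, n_coords = _assemble(
            _LAYOUTS["EUKARYOTIC_L_N"], spec.arm_length, catalog, rng, safe
        )
        c_leader = _linker(rng, safe, rng.randint(3, 8))
        c_core, c_coords = _assemble(
            _LAYOUTS["EUKARYOTIC_L_C"], 0, catalog, rng, safe
        )
        n_target = spec.length // 2
        n_fill = n_target - len(n_core)
        c_fill = spec.length - n_target - len(c_leader) - len(c_core)
        if n_fill < 2 or c_fill < 1:
            raise SyntheticSpecError(
                f"length {spec.length} too short for an L-form layout"
            )
        n_leader = _linker(rng, safe, n_fill // 2)
        n_tail = _linker(rng, safe, n_fill - len(n_leader))
        c_tail = _linker(rng, safe, c_fill)
        sequence = n_leader + n_core + n_tail + c_leader + c_core + c_tail
        junction = n_target
        coords = _shift(n_coords, len(n_leader))
        coords.update(_shift(c_coords, junction + len(c_leader)))
    else:
        core, core_coords = _assemble(
            _LAYOUTS[spec.ztype], spec.arm_length, catalog, rng, safe
        )
        fill = spec.length - len(core)
        if fill < 2:
            raise SyntheticSpecError(
                f"length {spec.length} too short for a {spec.ztype} layout"
            )
        leader = _linker(rng, safe, fill // 2)
        tail = _linker(rng, safe, fill - len(leader))
        sequence = leader + core + tail
        junction = None
        coords = _shift(core_coords, len(leader))

    truth = SyntheticTruth(seed=spec.seed, motifs=coords, junction=junction)
    if spec.knockouts:
        sequence, truth = mutate_to_tlp(
            sequence,
            truth,
            list(spec.knockouts),
            mode=spec.knockout_mode,
            seed=spec.seed + 1,
            catalog=catalog,
        )
    return sequence, truth


def mutate_to_tlp(
    sequence: str,
    truth: SyntheticTruth,
    motifs: list[str],
    mode: str = "delete",
    seed: int = 0,
    catalog: MotifCatalog | None = None,
) -> tuple[str, SyntheticTruth]:
    """Destroy planted motif instances, keeping all other coordinates.

    delete: overwrite the instance with safe linker residues (length kept).
    corrupt: mutate max_mismatches+1 non-wildcard positions (critical
    residue first) to Gln, echoing the naturally observed His->Gln TLP.
    """
    if mode not in ("delete", "corrupt"):
        raise ValueError(f"unknown knockout mode {mode!r}")
    catalog = catalog or default_catalog()
    rng = random.Random(seed)
    safe = safe_linker_alphabet(catalog)
    seq = list(sequence)
    new_truth = SyntheticTruth(
        seed=truth.seed,
        motifs=dict(truth.motifs),
        junction=truth.junction,
        knockouts=dict(truth.knockouts),
        genes=list(truth.genes),
    )
    for name in motifs:
        if name not in new_truth.motifs:
            raise ValueError(f"motif {name!r} not planted in this protein")
        start, end = new_truth.motifs.pop(name)
        model = catalog.motif(name)
        if mode == "delete":
            seq[start:end] = _linker(rng, safe, end - start)
        else:
            anchored = [
                k for k, spec in enumerate(model.positions) if spec != WILDCARD
            ]
            crit = model.critical_position
            if crit in anchored:
                anchored.remove(crit)
                anchored.insert(0, crit)
            for k in anchored[: model.max_mismatches + 1]:
                seq[start + k] = "Q"
        new_truth.knockouts[name] = (start, end)
    return "".join(seq), new_truth


def synth_genome(
    spec: GenomeSpec,
) -> tuple[dict[str, str], list[TrnaGene], SyntheticTruth]:
    """Emit a mini genome, its tRNA gene annotations, and the planted truth.

    Each gene's coding-strand post-discriminator trinucleotide is drawn from
    its assigned category's string set; minus-strand genes are realized by
    reverse complement of the coding-strand plant.
    """
    rng = random.Random(spec.seed)
    categories = (
        ["CCA"] * spec.n_cca
        + ["CCN"] * spec.n_ccn
        + ["CNN"] * spec.n_cnn
        + ["OTHER"] * spec.n_other
    )
    rng.shuffle(categories)
    n = spec.n_genes
    n_minus = round(spec.minus_fraction * n)
    strands = ["-"] * n_minus + ["+"] * (n - n_minus)
    rng.shuffle(strands)

    def tri_for(category: str) -> str:
        if category == "CCA":
            return "CCA"
        if category == "CCN":
            return "CC" + rng.choice("CGT")
        if category == "CNN":
            return "C" + rng.choice("AGT") + rng.choice(DNA)
        return rng.choice("AGT") + rng.choice(DNA) + rng.choice(DNA)

    def random_dna(length: int) -> str:
        return "".join(rng.choice(DNA) for _ in range(length))

    parts: list[str] = []
    pos = 0
    genes: list[TrnaGene] = []
    truth = SyntheticTruth(seed=spec.seed)

    def push(text: str) -> None:
        nonlocal pos
        parts.append(text)
        pos += len(text)

    for idx, (category, strand) in enumerate(zip(categories, strands)):
        gap_len = max(rng.randint(*spec.intergenic), 4)
        gap = random_dna(gap_len)
        tri = tri_for(category)
        if strand == "-":
            # coding-strand downstream = revcomp of the 3 bases before start
            gap = gap[:-3] + str(Seq(tri).reverse_complement())
        push(gap)
        gene_id = f"trna{idx + 1:03d}"
        body = random_dna(rng.randint(*spec.gene_length))
        start = pos
        push(body)
        end = pos
        if strand == "+":
            push(tri)
        genes.append(TrnaGene(gene_id, spec.seq_id, start, end, strand))
        truth.genes.append(GeneTruth(gene_id, category, tri, start, end, strand))
    push(random_dna(10))
    return {spec.seq_id: "".join(parts)}, genes, truth


def random_additive_tree(
    n_taxa: int, seed: int = 0, branch_range: tuple[float, float] = (0.2, 1.0)
) -> tuple[list[str], list[list[float]], str]:
    """A random binary tree plus its exact additive distance matrix.

    Returns (labels, distances, newick).  Neighbor joining applied to the
    distances must recover the (unrooted) topology exactly; used as the
    round-trip oracle for tree construction.
    """
    if n_taxa < 3:
        raise SyntheticSpecError("need at least 3 taxa")
    rng = random.Random(seed)
    labels = [f"T{i + 1}" for i in range(n_taxa)]
    dist: dict[tuple[str, str], float] = {}
    # clusters: (newick, {leaf: distance to cluster root})
    clusters: list[tuple[str, dict[str, float]]] = [
        (label, {label: 0.0}) for label in labels
    ]
    while len(clusters) > 1:
        i, j = rng.sample(range(len(clusters)), 2)
        if i > j:
            i, j = j, i
        (nwk_a, depths_a) = clusters[i]
        (nwk_b, depths_b) = clusters[j]
        ba = rng.uniform(*branch_range)
        bb = rng.uniform(*branch_range)
        for x, dx in depths_a.items():
            for y, dy in depths_b.items():
                dist[tuple(sorted((x, y)))] = dx + ba + dy + bb
        merged = (
            f"({nwk_a}:{ba:.6f},{nwk_b}:{bb:.6f})",
            {
                **{x: dx + ba for x, dx in depths_a.items()},
                **{y: dy + bb for y, dy in depths_b.items()},
            },
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    newick = clusters[0][0] + ";"
    matrix = [
        [0.0 if a == b else dist[tuple(sorted((a, b)))] for b in labels]
        for a in labels
    ]
    return labels, matrix, newick


def reverse_complement_fixture(
    genome: dict[str, str], genes: list[TrnaGene]
) -> tuple[dict[str, str], list[TrnaGene]]:
    """Strand oracle: reverse-complement the genome and flip annotations."""
    flipped_genome = {
        seq_id: str(Seq(seq).reverse_complement()) for seq_id, seq in genome.items()
    }
    flipped_genes = []
    for g in genes:
        n = len(genome[g.seq_id])
        flipped_genes.append(
            TrnaGene(
                gene_id=g.gene_id,
                seq_id=g.seq_id,
                start=n - g.end,
                end=n - g.start,
                strand="-" if g.strand == "+" else "+",
            )
        )
    return flipped_genome, flipped_genes
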