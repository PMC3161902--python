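"""Pairwise conservation statistics, sequence-logo matrices, neighbor
joining, and targeting-signal bookkeeping.

The pairwise identity/similarity statistics use an optimal global alignment
(Needleman-Wunsch, linear gap penalty) with a deterministic traceback
(diagonal over up over left).  Similarity counts identical residue pairs
plus pairs sharing a "strong" conservation group.  Logo matrices carry
per-column residue frequencies and Shannon information content in bits.
Neighbor joining follows the standard agglomeration with a lexicographic
tie-break and emits Newick with branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .catalog import AA20

# widely used "strong" conservation groups (Clustal-style)
STRONG_GROUPS: tuple[str, ...] = (
    "STA",
    "NEQK",
    "NHQK",
    "NDEQ",
    "QHRK",
    "MILV",
    "MILF",
    "HY",
    "FYW",
)

GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_similar: int
    n_aligned_columns: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned strings differ in length")
        if not self.n_identical <= self.n_similar <= self.n_aligned_columns:
            raise AlignmentError("inconsistent column counts")


def _column_counts(
    aligned_a: str, aligned_b: str, groups: tuple[str, ...]
) -> tuple[int, int, int]:
    ident = simil = cols = 0
    group_sets = [set(g) for g in groups]
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == GAP or cb == GAP:
            continue
        cols += 1
        if ca == cb:
            ident += 1
            simil += 1
        elif any(ca in g and cb in g for g in group_sets):
            simil += 1
    return ident, simil, cols


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment with linear gap penalty.

    Equal-score traceback choices prefer the diagonal, then the up move
    (residue of ``a`` against a gap), then the left move.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=float)
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        ai = a[i - 1]
        prev = score[i - 1]
        row = score[i]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            row[j] = max(prev[j - 1] + s, prev[j] + gap, row[j - 1] + gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if score[i, j] == score[i - 1, j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP)
        out_b.append(b[j - 1])
        j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    ident, simil, cols = _column_counts(aligned_a, aligned_b, STRONG_GROUPS)
    return PairwiseAlignment(
        id_a=id_a,
        id_b=id_b,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score[n, m]),
        n_identical=ident,
        n_similar=simil,
        n_aligned_columns=cols,
    )


def percent_identity_similarity(
    alignment: PairwiseAlignment,
    groups: tuple[str, ...] = STRONG_GROUPS,
    denominator: str = "gapless",
) -> tuple[float, float]:
    """(identity %, similarity %) of a pairwise alignment, 1-decimal rounded.

    denominator: "gapless" (columns without gaps, default), "shorter"
    (shorter input length) or "full" (all alignment columns).
    """
    ident, simil, cols = _column_counts(alignment.aligned_a, alignment.aligned_b, groups)
    if denominator == "gapless":
        denom = cols
    elif denominator == "shorter":
        denom = min(
            len(alignment.aligned_a.replace(GAP, "")),
            len(alignment.aligned_b.replace(GAP, "")),
        )
    elif denominator == "full":
        denom = len(alignment.aligned_a)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise AlignmentError("zero aligned columns")
    return round(100 * ident / denom, 1), round(100 * simil / denom, 1)


@dataclass(frozen=True)
class LogoMatrix:
    """Per-column residue frequencies and information content (bits)."""

    alphabet: str
    frequencies: np.ndarray  # (columns, len(alphabet)), rows sum to 1
    information: np.ndarray  # (columns,), 0 <= IC <= log2(len(alphabet))

    def __post_init__(self) -> None:
        sums = self.frequencies.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")
        cap = np.log2(len(self.alphabet))
        if np.any(self.information < -1e-12) or np.any(self.information > cap + 1e-12):
            raise ValueError("information content out of [0, log2(alphabet)] bounds")


def logo_matrix(instances: list[str]) -> LogoMatrix:
    """Column frequencies and IC of equal-length motif instances.

    IC_col = log2(20) - H_col with H the Shannon entropy in bits; no
    small-sample correction is applied.
    """
    if not instances:
        raise ValueError("need at least one motif instance")
    length = len(instances[0])
    if any(len(s) != length for s in instances):
        raise ValueError("motif instances must all have equal length")
    index = {res: k for k, res in enumerate(AA20)}
    freqs = np.zeros((length, len(AA20)), dtype=float)
    for s in instances:
        for col, res in enumerate(s.upper()):
            if res not in index:
                raise ValueError(f"non-standard residue {res!r}")
            freqs[col, index[res]] += 1
    freqs /= len(instances)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.clip(np.log2(len(AA20)) - entropy, 0.0, np.log2(len(AA20)))
    return LogoMatrix(alphabet=AA20, frequencies=freqs, information=info)


class _Node:
    __slots__ = ("newick", "label")

    def __init__(self, newick: str, label: str):
        self.newick = newick  # subtree string without trailing branch length
        self.label = label  # smallest leaf label, for deterministic ties


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def nj_tree(distances, labels: list[str]) -> str:
    """Unrooted neighbor-joining tree in Newick form with branch lengths.

    Agglomeration follows the canonical Q-criterion; ties are broken by the
    lexicographically smallest (label, label) pair, labels of internal nodes
    being the smallest leaf label beneath them.
    """
    d = np.asarray(distances, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")

    nodes = [_Node(label, label) for label in labels]
    dist = d.copy()
    active = list(range(n))

    while len(active) > 3:
        r = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        na = len(active)
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (na - 2) * dist[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((nodes[i].label, nodes[j].label)))
                key = (q, pair_key)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (na - 2))
        lj = dij - li
        new_label = min(nodes[i].label, nodes[j].label)
        new_newick = (
            f"({nodes[i].newick}:{_fmt(li)},{nodes[j].newick}:{_fmt(lj)})"
        )
        # grow matrix by one row/col for the merged node
        k_new = dist.shape[0]
        grown = np.zeros((k_new + 1, k_new + 1), dtype=float)
        grown[:k_new, :k_new] = dist
        for k in active:
            if k in (i, j):
                continue
            dk = (dist[i, k] + dist[j, k] - dij) / 2
            grown[k_new, k] = grown[k, k_new] = dk
        dist = grown
        nodes.append(_Node(new_newick, new_label))
        active = [k for k in active if k not in (i, j)] + [k_new]

    i, j, k = active
    li = (dist[i, j] + dist[i, k] - dist[j, k]) / 2
    lj = (dist[i, j] + dist[j, k] - dist[i, k]) / 2
    lk = (dist[i, k] + dist[j, k] - dist[i, j]) / 2
    order = sorted([(nodes[i], li), (nodes[j], lj), (nodes[k], lk)], key=lambda t: t[0].label)
    inner = ",".join(f"{nd.newick}:{_fmt(ln)}" for nd, ln in order)
    return f"({inner});"


def p_distance_matrix(sequences: list[str], labels: list[str]) -> np.ndarray:
    """Pairwise p-distances (1 - identical fraction over gapless columns)."""
    n = len(sequences)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(sequences[i], sequences[j], id_a=labels[i], id_b=labels[j])
            if aln.n_aligned_columns == 0:
                raise AlignmentError(f"no aligned columns for {labels[i]}/{labels[j]}")
            d[i, j] = d[j, i] = 1.0 - aln.n_identical / aln.n_aligned_columns
    return d


@dataclass(frozen=True)
class TargetingSignal:
    """A printed N-terminal targeting signal with its declared length."""

    protein_id: str
    compartment: str  # C (chloroplast), M (mitochondrion), N (nucleus)
    sequence: str
    declared_length: int | None = None


def validate_signal(record: TargetingSignal) -> tuple[int, bool]:
    """Residue count of the signal and whether it matches the declared length."""
    if not record.sequence:
        raise ValueError(f"{record.protein_id}: empty signal sequence")
    for k, res in enumerate(record.sequence):
        if res not in AA20:
            raise ValueError(f"{record.protein_id}: non-standard residue at {k}")
    n = len(record.sequence)
    consistent = record.declared_length is None or n == record.declared_length
    return n, consistent


def load_signal_table(path: str | None = None) -> list[TargetingSignal]:
    """Load a targeting-signal TSV (default: the packaged transcription)."""
    import pandas as pd

    if path is None:
        src = resources.files("trz.data").joinpath("targeting_signals.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        TargetingSignal(
            protein_id=row.protein_id,
            compartment=row.compartment,
            sequence=row.sequence,
            declared_length=int(row.declared_length),
        )
        for row in df.itertuples()
    ]
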