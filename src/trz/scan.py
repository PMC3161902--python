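"""Mismatch-tolerant motif scanning and order-consistent chain assembly.

``scan_motif`` reports every window of a protein whose mismatch count
against a compiled consensus is within the motif's budget (exhaustive, so
it is equivalent to brute force over all windows).  ``find_motif_chain``
then selects, by dynamic programming, the maximum-coverage set of
non-overlapping hits whose motif ranks strictly increase along the
sequence — the formalisation of the observation that the conserved motifs
appear in the same relative order in every protein carrying them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .catalog import ALPHABET, UNKNOWN, WILDCARD, MotifCatalog, MotifModel


@dataclass(frozen=True)
class MotifHit:
    """One located motif instance (0-based half-open coordinates)."""

    motif_name: str
    start: int
    end: int
    matched: str
    mismatches: int


@dataclass
class MotifChain:
    """Order-consistent, non-overlapping motif hits on one protein."""

    protein_id: str
    hits: list[MotifHit]
    complete: bool
    architecture_tested: str
    missing: tuple[str, ...] = ()

    @property
    def total_mismatches(self) -> int:
        return sum(h.mismatches for h in self.hits)

    def hit(self, motif_name: str) -> MotifHit | None:
        for h in self.hits:
            if h.motif_name == motif_name:
                return h
        return None


class SequenceAlphabetError(ValueError):
    pass


@lru_cache(maxsize=256)
def _match_tables(positions: tuple[str, ...]) -> np.ndarray:
    """(pattern length, 128) booleans: does ASCII code c satisfy position k?

    Wildcards match every residue including the unknown 'X'; exact and set
    positions never match 'X'.
    """
    tables = np.zeros((len(positions), 128), dtype=bool)
    for k, spec in enumerate(positions):
        allowed = ALPHABET if spec == WILDCARD else spec
        for res in allowed:
            tables[k, ord(res)] = True
    return tables


_VALID = np.zeros(128, dtype=bool)
for _c in ALPHABET:
    _VALID[ord(_c)] = True


def _encode(sequence: str) -> np.ndarray:
    try:
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise SequenceAlphabetError(f"non-ASCII character in sequence: {exc}") from exc
    bad = np.nonzero(~_VALID[arr])[0]
    if bad.size:
        i = int(bad[0])
        raise SequenceAlphabetError(
            f"illegal residue {sequence[i]!r} at position {i}"
        )
    return arr


def scan_motif(sequence: str, model: MotifModel) -> list[MotifHit]:
    """All windows matching ``model`` within its mismatch budget.

    Hits are sorted by start (one window per start).  An empty or too-short
    sequence yields an empty list.
    """
    m = len(model)
    n = len(sequence)
    if n < m:
        return []
    arr = _encode(sequence)
    tables = _match_tables(model.positions)
    width = n - m + 1
    mismatches = np.zeros(width, dtype=np.int32)
    forced_ok = np.ones(width, dtype=bool)
    forced = set(model.forced_mismatch_positions)
    for k in range(m):
        match_k = tables[k][arr[k : k + width]]
        mismatches += ~match_k
        if k in forced:
            forced_ok &= ~match_k
    valid = (mismatches <= model.max_mismatches) & forced_ok
    return [
        MotifHit(
            motif_name=model.name,
            start=int(i),
            end=int(i) + m,
            matched=sequence[i : i + m],
            mismatches=int(mismatches[i]),
        )
        for i in np.nonzero(valid)[0]
    ]


@dataclass(frozen=True)
class _Candidate:
    hit: MotifHit
    rank: int
    window: int | None


def _chain_key(cov: int, mism: int, starts: tuple[int, ...]):
    # maximize coverage, then fewer mismatches, then leftmost starts
    return (-cov, mism, starts)


def find_motif_chain(
    sequence: str,
    catalog: MotifCatalog,
    architecture: str,
    protein_id: str = "",
) -> MotifChain:
    """Best rank-increasing, non-overlapping hit chain for one architecture.

    Ties between equal-coverage chains are broken by fewer total mismatches,
    then by leftmost starts.  A windowed motif's hit must begin within
    ``window`` residues of the previously placed hit's end; the constraint
    applies only when a preceding hit exists.
    """
    arch = catalog.architecture(architecture)
    candidates: list[_Candidate] = []
    for name in arch.members:
        model = catalog.motif(name)
        for hit in scan_motif(sequence, model):
            candidates.append(_Candidate(hit, model.rank, model.window))
    candidates.sort(key=lambda c: (c.hit.start, c.rank))

    # dp[i]: best chain ending at candidate i, as (coverage, mismatches,
    # starts, hit indices)
    n = len(candidates)
    best_cov = [0] * n
    best_mism = [0] * n
    best_prev = [-1] * n
    best_starts: list[tuple[int, ...]] = [()] * n
    for i, ci in enumerate(candidates):
        hi = ci.hit
        cov = hi.end - hi.start
        cur = (cov, hi.mismatches, (hi.start,), -1)
        for j in range(i):
            cj = candidates[j]
            hj = cj.hit
            if hj.end > hi.start or cj.rank >= ci.rank:
                continue
            if ci.window is not None and hi.start - hj.end > ci.window:
                continue
            cand = (
                best_cov[j] + cov,
                best_mism[j] + hi.mismatches,
                best_starts[j] + (hi.start,),
                j,
            )
            if _chain_key(cand[0], cand[1], cand[2]) < _chain_key(
                cur[0], cur[1], cur[2]
            ):
                cur = cand
        best_cov[i], best_mism[i], best_starts[i], best_prev[i] = (
            cur[0],
            cur[1],
            cur[2],
            cur[3],
        )

    if n == 0:
        required = arch.required
        return MotifChain(
            protein_id=protein_id,
            hits=[],
            complete=not required,
            architecture_tested=architecture,
            missing=tuple(required),
        )

    end = min(
        range(n), key=lambda i: _chain_key(best_cov[i], best_mism[i], best_starts[i])
    )
    hits: list[MotifHit] = []
    i = end
    while i != -1:
        hits.append(candidates[i].hit)
        i = best_prev[i]
    hits.reverse()

    present = {h.motif_name for h in hits}
    missing = tuple(m for m in arch.required if m not in present)
    chain = MotifChain(
        protein_id=protein_id,
        hits=hits,
        complete=not missing,
        architecture_tested=architecture,
        missing=missing,
    )
    _assert_sound(chain, catalog)
    return chain


def _assert_sound(chain: MotifChain, catalog: MotifCatalog) -> None:
    """Chain soundness: non-overlapping, start-sorted, rank-monotonic."""
    prev_end = -1
    prev_rank = -1
    for h in chain.hits:
        if h.start < prev_end:
            raise AssertionError(f"overlapping hits in chain for {chain.protein_id}")
        rank = catalog.motif(h.motif_name).rank
        if rank <= prev_rank:
            raise AssertionError(f"rank order violated in chain for {chain.protein_id}")
        prev_end, prev_rank = h.end, rank
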