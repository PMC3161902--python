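"""Degenerate consensus motif models and the tRNase Z motif catalog.

tRNase Z proteins are described in the literature by short degenerate
consensus strings (the metallo-beta-lactamase His motif ``HxHxDH``, the
flexible-arm ``GxPxGP``/``KLKxxYxxLxGxxIxxLK`` motifs, the catalytic-assist
``HEAT``/``HST`` motifs and their plant variants, ...).  This module turns
those strings into compiled :class:`MotifModel` objects and groups them into
a :class:`MotifCatalog` whose *architectures* record which motifs, in which
canonical N->C order, define each tRNase Z type.

Pattern notation: an uppercase letter is an exact residue, a lowercase
``x`` matches any residue (including the unknown residue ``X``), and a
bracketed set such as ``[KL]`` matches any listed residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

AA20 = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN = "X"
ALPHABET = AA20 + UNKNOWN

WILDCARD = ""  # internal marker for an any-residue position


class MotifPatternError(ValueError):
    """Malformed consensus pattern; carries the offending character index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} (pattern index {index})")
        self.index = index


class CatalogError(ValueError):
    """Inconsistent or malformed motif catalog."""


@dataclass(frozen=True)
class MotifModel:
    """A compiled degenerate consensus pattern.

    positions holds one spec per pattern position: ``""`` for a wildcard,
    a single residue for an exact match, several residues for a bracket set.

    forced_mismatch_positions marks positions that must *not* match the
    spec — used to model pseudo-motifs, whose catalytically critical
    residues are required to differ from the parent consensus.

    window, when set, caps the gap (in residues) between this motif and the
    previously placed motif in a chain; used for the low-information
    Motif I/III/IV/V placeholders.
    """

    name: str
    pattern: str
    positions: tuple[str, ...]
    max_mismatches: int
    rank: int = 0
    window: int | None = None
    forced_mismatch_positions: tuple[int, ...] = ()
    critical_position: int | None = None

    def __post_init__(self) -> None:
        if not self.positions:
            raise MotifPatternError("empty pattern", 0)
        if self.max_mismatches < 0:
            raise CatalogError(f"{self.name or self.pattern}: negative max_mismatches")
        if self.max_mismatches >= len(self.positions):
            raise CatalogError(
                f"{self.name or self.pattern}: max_mismatches "
                f"{self.max_mismatches} >= pattern length {len(self.positions)}"
            )
        for k in self.forced_mismatch_positions:
            if not 0 <= k < len(self.positions):
                raise CatalogError(f"{self.name}: forced position {k} out of range")
            if self.positions[k] == WILDCARD:
                raise CatalogError(
                    f"{self.name}: forced mismatch at wildcard position {k} is unsatisfiable"
                )

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, residue: str, k: int) -> bool:
        """Whether ``residue`` satisfies position ``k`` of the pattern."""
        spec = self.positions[k]
        return True if spec == WILDCARD else residue in spec

    def format(self) -> str:
        """Rebuild the consensus string; round-trips through compile_motif."""
        out = []
        for spec in self.positions:
            if spec == WILDCARD:
                out.append("x")
            elif len(spec) == 1:
                out.append(spec)
            else:
                out.append(f"[{spec}]")
        return "".join(out)


def compile_motif(
    pattern: str,
    max_mismatches: int,
    *,
    name: str = "",
    rank: int = 0,
    window: int | None = None,
    forced_mismatch_positions: tuple[int, ...] = (),
    critical_position: int | None = None,
) -> MotifModel:
    """Compile a degenerate consensus string into a :class:`MotifModel`.

    Raises :class:`MotifPatternError` naming the offending index for
    malformed brackets or characters outside the 20-letter alphabet / 'x'.
    """
    if not pattern:
        raise MotifPatternError("empty pattern", 0)
    positions: list[str] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "x":
            positions.append(WILDCARD)
            i += 1
        elif c == "[":
            j = pattern.find("]", i + 1)
            if j < 0:
                raise MotifPatternError("unclosed bracket", i)
            members = pattern[i + 1 : j]
            if not members:
                raise MotifPatternError("empty bracket set", i)
            for off, m in enumerate(members):
                if m not in AA20:
                    raise MotifPatternError(
                        f"illegal residue {m!r} in bracket set", i + 1 + off
                    )
            positions.append(members)
            i = j + 1
        elif c == "]":
            raise MotifPatternError("unmatched closing bracket", i)
        elif c in AA20:
            positions.append(c)
            i += 1
        else:
            raise MotifPatternError(f"illegal character {c!r}", i)
    return MotifModel(
        name=name,
        pattern=pattern,
        positions=tuple(positions),
        max_mismatches=max_mismatches,
        rank=rank,
        window=window,
        forced_mismatch_positions=forced_mismatch_positions,
        critical_position=critical_position,
    )


def format_motif(model: MotifModel) -> str:
    return model.format()


@dataclass(frozen=True)
class Architecture:
    """Required/optional motif names of one tRNase Z type, in canonical order."""

    name: str
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()

    @property
    def members(self) -> tuple[str, ...]:
        return self.required + self.optional


@dataclass
class MotifCatalog:
    """All motif models plus the per-type architecture tables."""

    entries: dict[str, MotifModel] = field(default_factory=dict)
    architectures: dict[str, Architecture] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, model in self.entries.items():
            if len(model) < 3:
                raise CatalogError(f"catalog motif {name} shorter than 3 positions")
        for arch in self.architectures.values():
            ranks = []
            for m in arch.members:
                if m not in self.entries:
                    raise CatalogError(
                        f"architecture {arch.name} references unknown motif {m}"
                    )
                ranks.append(self.entries[m].rank)
            req_ranks = [self.entries[m].rank for m in arch.required]
            if sorted(set(req_ranks)) != req_ranks:
                raise CatalogError(
                    f"architecture {arch.name}: required motif ranks must be a "
                    f"strict total order, got {req_ranks}"
                )

    def motif(self, name: str) -> MotifModel:
        try:
            return self.entries[name]
        except KeyError:
            raise CatalogError(f"unknown motif {name!r}") from None

    def architecture(self, name: str) -> Architecture:
        try:
            return self.architectures[name]
        except KeyError:
            raise CatalogError(f"unknown architecture {name!r}") from None


_OPT_RE = re.compile(r"^(window|critical|forced)=([0-9;]+)$")


def parse_catalog(text: str) -> MotifCatalog:
    """Parse the plain-text catalog format (see data/default_catalog.cfg)."""
    entries: dict[str, MotifModel] = {}
    architectures: dict[str, Architecture] = {}
    section: str | None = None
    arch_name: str | None = None
    arch_fields: dict[str, tuple[str, ...]] = {}

    def flush_arch() -> None:
        nonlocal arch_name, arch_fields
        if arch_name is not None:
            architectures[arch_name] = Architecture(
                name=arch_name,
                required=arch_fields.get("required", ()),
                optional=arch_fields.get("optional", ()),
            )
        arch_name, arch_fields = None, {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush_arch()
            header = line.strip("[]").strip()
            if header == "motifs":
                section = "motifs"
            elif header.startswith("architecture"):
                section = "architecture"
                arch_name = header.split(None, 1)[1].strip()
            else:
                raise CatalogError(f"line {lineno}: unknown section {header!r}")
            continue
        if section == "motifs":
            parts = line.split()
            if len(parts) < 4:
                raise CatalogError(f"line {lineno}: expected name pattern mm rank")
            name, pattern, mm_s, rank_s, *opts = parts
            kwargs: dict = {}
            for opt in opts:
                m = _OPT_RE.match(opt)
                if not m:
                    raise CatalogError(f"line {lineno}: bad option {opt!r}")
                key, val = m.groups()
                if key == "window":
                    kwargs["window"] = int(val)
                elif key == "critical":
                    kwargs["critical_position"] = int(val)
                else:
                    kwargs["forced_mismatch_positions"] = tuple(
                        int(v) for v in val.split(";")
                    )
            entries[name] = compile_motif(
                pattern, int(mm_s), name=name, rank=int(rank_s), **kwargs
            )
        elif section == "architecture":
            if "=" not in line:
                raise CatalogError(f"line {lineno}: expected key = names")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in ("required", "optional"):
                raise CatalogError(f"line {lineno}: unknown architecture key {key!r}")
            arch_fields[key] = tuple(val.split())
        else:
            raise CatalogError(f"line {lineno}: content outside any section")
    flush_arch()
    return MotifCatalog(entries=entries, architectures=architectures)


def load_catalog(source: str = "default") -> MotifCatalog:
    """Load a catalog from a file path, or the shipped default."""
    if source == "default":
        text = (
            resources.files("trz.data").joinpath("default_catalog.cfg").read_text()
        )
    else:
        with open(source) as fh:
            text = fh.read()
    return parse_catalog(text)


_DEFAULT: MotifCatalog | None = None


def default_catalog() -> MotifCatalog:
    """The shipped catalog (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_catalog("default")
    return _DEFAULT
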