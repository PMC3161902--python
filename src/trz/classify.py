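"""Form, flexible-arm and type classification of tRNase Z candidates.

The decision scheme distinguishes three enzyme types by motif architecture:

* TM-type tRNase Z(S): Motifs I-V plus the Gly-rich EGxSxxG motif, a short
  (~30 aa) flexible arm carrying the KL motif, and the xExT/HxH variants of
  the catalytic-assist motifs.  No PxKxRN.
* bacterial-type tRNase Z(S): Motifs I-V plus PxKxRN, a ~55 aa GP-motif arm,
  and the HEAT/HST motifs.
* eukaryotic-type tRNase Z(L): a tandem-duplicated protein whose N-half
  carries pseudo-motifs and a ~62 aa GP arm and whose C-half carries the
  full Motifs I-V + PxKxRN + HEAT + HST set.

Proteins of tRNase Z size that lack one or more required motifs are flagged
as tRNase Z-like proteins (TLPs), sub-typed S or L by length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .catalog import MotifCatalog, default_catalog
from .scan import MotifChain, find_motif_chain, scan_motif


class Form(str, Enum):
    S = "S"
    L = "L"
    AMBIGUOUS = "AMBIGUOUS"


class ZType(str, Enum):
    TM_S = "TM_S"
    BACTERIAL_S = "BACTERIAL_S"
    EUKARYOTIC_L = "EUKARYOTIC_L"
    TLP_S = "TLP_S"
    TLP_L = "TLP_L"
    UNKNOWN = "UNKNOWN"


class ArmType(str, Enum):
    TM = "TM"
    BACTERIAL = "BACTERIAL"
    EUKARYOTIC = "EUKARYOTIC"
    NONE = "NONE"


# form thresholds: the nominal size classes are 300-400 aa (short form) and
# 700-800 aa (long form); real candidate sets contain 425-445 aa short-like
# and 731 aa long-like proteins, hence the generous band.
S_MAX = 450
L_MIN = 600

# arm-length cutoffs sit midway between the nominal ~30/~55/~62 aa arms
TM_ARM_MAX = 45
BACTERIAL_ARM_MAX = 58


@dataclass(frozen=True)
class ArmRegion:
    """The flexible-arm (exosite) segment between Motif II and Motif III."""

    start: int
    end: int
    arm_type: ArmType
    has_gp: bool
    has_kl: bool
    flagged: bool = False  # anchors missing; arm undefined

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HalfSplit:
    """N/C-half decomposition of a long-form candidate."""

    split_index: int
    n_half_chain: MotifChain
    c_half_chain: MotifChain


@dataclass
class TypingResult:
    protein_id: str
    form: Form
    ztype: ZType
    evidence: dict
    missing_required: tuple[str, ...] = ()
    arm: ArmRegion | None = None

    def __post_init__(self) -> None:
        if self.ztype in (ZType.TM_S, ZType.BACTERIAL_S) and self.form != Form.S:
            raise AssertionError(f"{self.protein_id}: S-type with form {self.form}")
        if self.ztype == ZType.EUKARYOTIC_L and self.form != Form.L:
            raise AssertionError(f"{self.protein_id}: L-type with form {self.form}")
        if self.ztype in (ZType.TLP_S, ZType.TLP_L) and not self.missing_required:
            raise AssertionError(f"{self.protein_id}: TLP with empty missing set")


def classify_form(length: int, s_max: int = S_MAX, l_min: int = L_MIN) -> Form:
    """Size class: S for <= s_max aa, L for >= l_min aa, else AMBIGUOUS."""
    if length < 1:
        raise ValueError(f"non-positive protein length {length}")
    if length <= s_max:
        return Form.S
    if length >= l_min:
        return Form.L
    return Form.AMBIGUOUS


def delineate_arm(
    chain: MotifChain,
    sequence: str,
    catalog: MotifCatalog | None = None,
    n_anchor: str = "MOTIF_II",
    c_anchor: str = "MOTIF_III",
    tm_arm_max: int = TM_ARM_MAX,
    bacterial_arm_max: int = BACTERIAL_ARM_MAX,
) -> ArmRegion:
    """Arm = the segment between the His motif and Motif III hits.

    The arm type follows the KL/GP content and length: a KL-bearing arm of
    <= tm_arm_max aa is TM-type; a GP-bearing arm is bacterial-type up to
    bacterial_arm_max aa and eukaryotic-type beyond.
    """
    catalog = catalog or default_catalog()
    h2 = chain.hit(n_anchor)
    h3 = chain.hit(c_anchor)
    if h2 is None or h3 is None or h3.start < h2.end:
        return ArmRegion(0, 0, ArmType.NONE, False, False, flagged=True)
    start, end = h2.end, h3.start
    segment = sequence[start:end]
    has_gp = bool(scan_motif(segment, catalog.motif("GP")))
    has_kl = bool(scan_motif(segment, catalog.motif("KL")))
    length = end - start
    if has_kl and not has_gp and length <= tm_arm_max:
        arm_type = ArmType.TM
    elif has_gp and length <= bacterial_arm_max:
        arm_type = ArmType.BACTERIAL
    elif has_gp:
        arm_type = ArmType.EUKARYOTIC
    else:
        arm_type = ArmType.NONE
    return ArmRegion(start, end, arm_type, has_gp, has_kl)


def split_halves(
    sequence: str,
    catalog: MotifCatalog | None = None,
    c_architecture: str = "EUKARYOTIC_L_C",
    n_architecture: str = "EUKARYOTIC_L_N",
    protein_id: str = "",
) -> HalfSplit:
    """Split a long-form candidate at the start of its C-half architecture.

    The full architecture is scanned starting near the sequence midpoint,
    stepping outward; the split falls at the first placed motif of the first
    complete chain found (fallback: the midpoint).  Each half chain's
    coordinates are relative to its own half.
    """
    catalog = catalog or default_catalog()
    n = len(sequence)
    mid = n // 2
    split = mid
    max_off = n // 4
    offsets = [0]
    step = 10
    while step <= max_off:
        offsets.extend([-step, step])
        step += 10
    for off in offsets:
        origin = mid + off
        if origin <= 0 or origin >= n:
            continue
        chain = find_motif_chain(sequence[origin:], catalog, c_architecture)
        if chain.complete and chain.hits:
            split = origin + chain.hits[0].start
            break
    n_half_chain = find_motif_chain(
        sequence[:split], catalog, n_architecture, protein_id=protein_id
    )
    c_half_chain = find_motif_chain(
        sequence[split:], catalog, c_architecture, protein_id=protein_id
    )
    return HalfSplit(split, n_half_chain, c_half_chain)


def _presence_map(chain: MotifChain, catalog: MotifCatalog) -> dict[str, bool]:
    present = {h.motif_name for h in chain.hits}
    arch = catalog.architecture(chain.architecture_tested)
    return {name: name in present for name in arch.members}


def _arm_evidence(arm: ArmRegion | None) -> dict:
    if arm is None:
        return {}
    return {
        "arm_type": arm.arm_type.value,
        "arm_start": arm.start,
        "arm_end": arm.end,
        "arm_length": arm.length,
        "has_gp": arm.has_gp,
        "has_kl": arm.has_kl,
    }


def _classify_short(
    sequence: str, catalog: MotifCatalog, protein_id: str
) -> tuple[ZType, MotifChain, ArmRegion]:
    tm = find_motif_chain(sequence, catalog, "TM_S", protein_id=protein_id)
    bact = find_motif_chain(sequence, catalog, "BACTERIAL_S", protein_id=protein_id)
    if tm.complete and bact.complete:
        if tm.total_mismatches < bact.total_mismatches:
            best, ztype = tm, ZType.TM_S
        elif bact.total_mismatches < tm.total_mismatches:
            best, ztype = bact, ZType.BACTERIAL_S
        else:
            # tie: the KL arm is diagnostic of the TM type
            arm = delineate_arm(tm, sequence, catalog)
            if arm.has_kl:
                best, ztype = tm, ZType.TM_S
            else:
                best, ztype = bact, ZType.BACTERIAL_S
    elif tm.complete:
        best, ztype = tm, ZType.TM_S
    elif bact.complete:
        best, ztype = bact, ZType.BACTERIAL_S
    else:
        best = min(
            (tm, bact),
            key=lambda c: (len(c.missing), c.total_mismatches, c.architecture_tested),
        )
        ztype = ZType.TLP_S
    arm = delineate_arm(best, sequence, catalog)
    return ztype, best, arm


def classify_type(
    sequence: str,
    catalog: MotifCatalog | None = None,
    protein_id: str = "",
) -> TypingResult:
    """Classify one protein into form + type (or TLP) per the decision table."""
    if not sequence:
        raise ValueError("empty sequence")
    catalog = catalog or default_catalog()
    form = classify_form(len(sequence))

    if form == Form.AMBIGUOUS:
        # evidence-based override: a complete architecture resolves the form
        split = split_halves(sequence, catalog, protein_id=protein_id)
        gp_in_n = split.n_half_chain.hit("GP") is not None
        if split.c_half_chain.complete and gp_in_n:
            form = Form.L
        else:
            ztype, best, arm = _classify_short(sequence, catalog, protein_id)
            if ztype in (ZType.TM_S, ZType.BACTERIAL_S):
                form = Form.S
            else:
                evidence = {
                    "length": len(sequence),
                    "architecture": best.architecture_tested,
                    "motifs": _presence_map(best, catalog),
                    **_arm_evidence(arm),
                }
                return TypingResult(
                    protein_id=protein_id,
                    form=Form.AMBIGUOUS,
                    ztype=ZType.UNKNOWN,
                    evidence=evidence,
                    missing_required=best.missing,
                    arm=arm,
                )

    if form == Form.S:
        ztype, best, arm = _classify_short(sequence, catalog, protein_id)
        evidence = {
            "length": len(sequence),
            "architecture": best.architecture_tested,
            "motifs": _presence_map(best, catalog),
            **_arm_evidence(arm),
        }
        return TypingResult(
            protein_id=protein_id,
            form=Form.S,
            ztype=ztype,
            evidence=evidence,
            missing_required=best.missing if ztype == ZType.TLP_S else (),
            arm=arm,
        )

    # long form
    split = split_halves(sequence, catalog, protein_id=protein_id)
    gp_in_n = split.n_half_chain.hit("GP") is not None
    missing = list(split.c_half_chain.missing)
    if not gp_in_n:
        missing.append("GP")
    motifs = _presence_map(split.c_half_chain, catalog)
    motifs.update(_presence_map(split.n_half_chain, catalog))
    evidence = {
        "length": len(sequence),
        "architecture": split.c_half_chain.architecture_tested,
        "split_index": split.split_index,
        "motifs": motifs,
        "gp_in_n_half": gp_in_n,
    }
    if split.c_half_chain.complete and gp_in_n:
        ztype = ZType.EUKARYOTIC_L
        missing = []
    else:
        ztype = ZType.TLP_L
    return TypingResult(
        protein_id=protein_id,
        form=Form.L,
        ztype=ztype,
        evidence=evidence,
        missing_required=tuple(missing),
    )
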