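"""Karyotypes, chromosome fusions and bead-chain construction.

Chromosomes are represented as ordered lists of *segments*, each a
(source chromosome, bp interval, orientation) triple.  A wild-type
chromosome is a single forward segment covering itself; a fusion
chromosome concatenates the segments of its constituents.  Fusions are
described by :class:`FusionEvent` records (which end of which chromosome
is consumed, which centromere survives, how much junction sequence is
deleted) and applied by :func:`apply_fusion_plan`.

Bead chains discretise each segment independently into 3.2-kb beads
(ceiling rule, the final partial bead carrying the remainder), so fusing
chromosomes conserves bead counts exactly — fusion adds a connectivity
bond between existing junction beads rather than re-tiling the composite.
Junction beads lose their terminal/telomeric character; only the two free
ends of each chain are telomeres.

Genomic coordinates are 0-based half-open, in *model* coordinates: the
chromosome XII rDNA array is expanded from the two repeats of the
reference assembly to a configurable repeat count, so chromosome XII
positions downstream of the array are shifted accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "Segment",
    "ChromosomeSpec",
    "FusionEvent",
    "Karyotype",
    "BeadChain",
    "build_bead_chain",
    "apply_fusion_plan",
    "karyotype_summary",
    "wild_type_karyotype",
    "fusion_plan",
    "strain_karyotype",
    "simple_chromosome",
    "FC_STRAINS",
    "BP_PER_BEAD",
    "TELOMERIC_REGION_BP",
]

#: genomic content of one 30-nm bead, bp
BP_PER_BEAD = 3200
#: extent of the rigid, NE-attracted subtelomeric region at each free end, bp
TELOMERIC_REGION_BP = 20_000
#: length of one rDNA repeat unit, bp
RDNA_REPEAT_BP = 9100
#: rDNA repeat count reproducing the published 4062-bead wild-type genome
RDNA_REPEATS_DEFAULT = 101

# R64-1-1 chromosome lengths and centromere midpoints (bp).  The native
# chromosome XII rDNA interval (two repeat units in the assembly) is
# replaced at karyotype-build time by the modelled array.
_WT_TABLE: dict[str, tuple[int, int]] = {
    "I": (230_218, 151_524),
    "II": (813_184, 238_265),
    "III": (316_620, 114_443),
    "IV": (1_531_933, 449_766),
    "V": (576_874, 152_045),
    "VI": (270_161, 148_568),
    "VII": (1_090_940, 496_979),
    "VIII": (562_643, 105_645),
    "IX": (439_888, 355_687),
    "X": (745_751, 436_366),
    "XI": (666_816, 440_188),
    "XII": (1_078_177, 150_887),
    "XIII": (924_431, 268_090),
    "XIV": (784_333, 628_817),
    "XV": (1_091_291, 326_643),
    "XVI": (948_066, 555_957),
}
_RDNA_NATIVE_INTERVAL = (451_575, 468_931)  # chr XII, reference assembly


@dataclass(frozen=True)
class Segment:
    """A contiguous stretch of a source chromosome inside a (possibly fused) chain."""

    source: str
    start: int  # bp, half-open, source coordinates
    end: int
    forward: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ChromosomeSpec:
    """One chromosome (wild-type or fused composite) of a karyotype.

    ``centromere`` is (source chromosome, bp); ``rdna`` is
    (source chromosome, (start, end)) or None.  ``segments`` records the
    source composition in chain order.
    """

    name: str
    segments: list[Segment]
    centromere: tuple[str, int]
    rdna: Optional[tuple[str, tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("chromosome must contain at least one segment")
        src, pos = self.centromere
        if not any(s.source == src and s.start <= pos < s.end for s in self.segments):
            raise ValueError(f"centromere {src}:{pos} not contained in {self.name}")

    @property
    def length_bp(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def sources(self) -> list[str]:
        seen: list[str] = []
        for s in self.segments:
            if s.source not in seen:
                seen.append(s.source)
        return seen

    def arm_lengths_bp(self) -> tuple[int, int]:
        """Left and right arm lengths around the (single) centromere."""
        cen = self.centromere_offset_bp()
        return cen, self.length_bp - cen

    def centromere_offset_bp(self) -> int:
        """Centromere position in chain (composite) coordinates."""
        src, pos = self.centromere
        off = 0
        for s in self.segments:
            if s.source == src and s.start <= pos < s.end:
                return off + (pos - s.start if s.forward else s.end - 1 - pos)
            off += s.length
        raise AssertionError("centromere not found")  # guarded in __post_init__

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "segments": [
                {"source": s.source, "start": s.start, "end": s.end, "forward": s.forward}
                for s in self.segments
            ],
            "centromere": list(self.centromere),
            "rdna": None if self.rdna is None else [self.rdna[0], list(self.rdna[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChromosomeSpec":
        return cls(
            name=d["name"],
            segments=[Segment(**s) for s in d["segments"]],
            centromere=(d["centromere"][0], int(d["centromere"][1])),
            rdna=None if d.get("rdna") is None else (d["rdna"][0], tuple(d["rdna"][1])),
        )


def simple_chromosome(
    name: str,
    length_bp: int,
    centromere_bp: int,
    rdna_interval_bp: Optional[tuple[int, int]] = None,
) -> ChromosomeSpec:
    """A single-segment (unfused) chromosome."""
    if length_bp <= 0:
        raise ValueError("chromosome length must be positive")
    if not 0 < centromere_bp < length_bp:
        raise ValueError("centromere must lie strictly inside the chromosome")
    rdna = None
    if rdna_interval_bp is not None:
        lo, hi = rdna_interval_bp
        if not 0 <= lo < hi <= length_bp:
            raise ValueError("rDNA interval must lie within the chromosome")
        rdna = (name, (lo, hi))
    return ChromosomeSpec(
        name=name,
        segments=[Segment(name, 0, length_bp)],
        centromere=(name, centromere_bp),
        rdna=rdna,
    )


@dataclass(frozen=True)
class FusionEvent:
    """One end-to-end chromosome fusion.

    ``recipient_end`` / ``donor_end`` name the telomeres consumed by the
    junction; ``donor_orientation`` "reverted" flips the donor chain;
    ``deleted_bp_*`` trim junction sequence (default 0: only the telomere
    character is lost, no modelled bp).  ``retained_centromere`` names the
    source chromosome whose centromere survives on the composite.
    """

    recipient: str
    donor: str
    retained_centromere: str
    recipient_end: Literal["left", "right"] = "right"
    donor_end: Literal["left", "right"] = "left"
    donor_orientation: Literal["forward", "reverted"] = "forward"
    deleted_bp_recipient: int = 0
    deleted_bp_donor: int = 0

    def __post_init__(self) -> None:
        if self.recipient_end not in ("left", "right") or self.donor_end not in ("left", "right"):
            raise ValueError("chromosome ends must be 'left' or 'right'")
        if self.deleted_bp_recipient < 0 or self.deleted_bp_donor < 0:
            raise ValueError("deleted bp must be non-negative")


@dataclass
class Karyotype:
    """An ordered set of chromosomes plus the fusion plan that produced it."""

    chromosomes: list[ChromosomeSpec]
    plan: list[FusionEvent] = field(default_factory=list)
    name: str = "WT"

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_telomeres(self) -> int:
        return 2 * len(self.chromosomes)

    def chromosome(self, label: str) -> ChromosomeSpec:
        """Find the chromosome named ``label`` or containing it as a source."""
        for c in self.chromosomes:
            if c.name == label:
                return c
        for c in self.chromosomes:
            if label in c.sources:
                return c
        raise KeyError(f"no chromosome {label!r} in karyotype {self.name!r}")

    def build_chains(self, bp_per_bead: int = BP_PER_BEAD) -> list["BeadChain"]:
        return [build_bead_chain(c, bp_per_bead) for c in self.chromosomes]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "chromosomes": [c.to_dict() for c in self.chromosomes],
            "plan": [vars(e) | {} for e in self.plan],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Karyotype":
        return cls(
            chromosomes=[ChromosomeSpec.from_dict(c) for c in d["chromosomes"]],
            plan=[FusionEvent(**e) for e in d.get("plan", [])],
            name=d.get("name", "WT"),
        )


@dataclass
class BeadChain:
    """Discretised bead representation of one chromosome.

    Arrays are aligned per bead, in chain order.  ``src_start``/``src_end``
    are source-chromosome coordinates (half-open); ``comp_start``/``comp_end``
    are cumulative chain coordinates.  Flags mark centromere, free-end
    terminal beads, the 20-kb telomeric regions at free ends, and rDNA.
    """

    chromosome: str
    bp_per_bead: int
    source: np.ndarray  # dtype=object, source chromosome per bead
    src_start: np.ndarray
    src_end: np.ndarray
    comp_start: np.ndarray
    comp_end: np.ndarray
    is_centromere: np.ndarray
    is_terminal: np.ndarray
    is_telomeric: np.ndarray
    is_rdna: np.ndarray

    @property
    def n_beads(self) -> int:
        return len(self.src_start)

    @property
    def length_bp(self) -> int:
        return int(self.comp_end[-1])

    def bead_of_source_position(self, source: str, bp: int) -> int:
        """Chain index of the bead containing source position ``bp``."""
        hit = np.flatnonzero(
            (self.source == source) & (self.src_start <= bp) & (bp < self.src_end)
        )
        if hit.size == 0:
            raise KeyError(f"{source}:{bp} not present on chain {self.chromosome}")
        return int(hit[0])

    def beads_overlapping(self, source: str, start: int, end: int) -> np.ndarray:
        """Chain indices of beads overlapping [start, end) of ``source``."""
        return np.flatnonzero(
            (self.source == source) & (self.src_start < end) & (self.src_end > start)
        )

    def to_bed(self) -> str:
        """Bead annotations as BED: chain, chain-coords, source locus, flags."""
        lines = []
        for i in range(self.n_beads):
            flags = ",".join(
                n
                for n, a in (
                    ("CEN", self.is_centromere),
                    ("TEL", self.is_terminal),
                    ("SUBTEL", self.is_telomeric),
                    ("RDNA", self.is_rdna),
                )
                if a[i]
            )
            lines.append(
                f"{self.chromosome}\t{self.comp_start[i]}\t{self.comp_end[i]}\t"
                f"{self.source[i]}:{self.src_start[i]}-{self.src_end[i]}"
                f"{(';' + flags) if flags else ''}"
            )
        return "\n".join(lines) + "\n"


def _tile_segment(seg: Segment, bp_per_bead: int) -> tuple[np.ndarray, np.ndarray]:
    """Ceiling-rule bead tiling of one segment, returned in chain order."""
    n = math.ceil(seg.length / bp_per_bead)
    starts = seg.start + np.arange(n, dtype=np.int64) * bp_per_bead
    ends = np.minimum(starts + bp_per_bead, seg.end)
    if not seg.forward:
        starts, ends = starts[::-1].copy(), ends[::-1].copy()
    return starts, ends


def build_bead_chain(chrom: ChromosomeSpec, bp_per_bead: int = BP_PER_BEAD) -> BeadChain:
    """Discretise a chromosome into beads of ``bp_per_bead`` (default 3.2 kb).

    Each source segment is tiled independently with the ceiling rule (the
    last bead of a segment carries the remainder bp), so composite chains
    inherit exactly the beads of their constituents.
    """
    if bp_per_bead <= 0:
        raise ValueError("bp_per_bead must be positive")
    src_names: list[str] = []
    starts_l: list[np.ndarray] = []
    ends_l: list[np.ndarray] = []
    for seg in chrom.segments:
        s, e = _tile_segment(seg, bp_per_bead)
        starts_l.append(s)
        ends_l.append(e)
        src_names.extend([seg.source] * len(s))
    src_start = np.concatenate(starts_l)
    src_end = np.concatenate(ends_l)
    source = np.array(src_names, dtype=object)
    n = len(src_start)
    bead_len = src_end - src_start
    comp_end = np.cumsum(bead_len)
    comp_start = comp_end - bead_len
    total = int(comp_end[-1])

    is_centromere = np.zeros(n, dtype=bool)
    cen_src, cen_bp = chrom.centromere
    cen_idx = np.flatnonzero((source == cen_src) & (src_start <= cen_bp) & (cen_bp < src_end))
    if cen_idx.size != 1:
        raise ValueError(f"centromere of {chrom.name} maps to {cen_idx.size} beads")
    is_centromere[cen_idx[0]] = True

    is_terminal = np.zeros(n, dtype=bool)
    is_terminal[0] = is_terminal[-1] = True

    tel = min(TELOMERIC_REGION_BP, total)
    is_telomeric = (comp_start < tel) | (comp_end > total - tel)

    is_rdna = np.zeros(n, dtype=bool)
    if chrom.rdna is not None:
        r_src, (r_lo, r_hi) = chrom.rdna
        is_rdna = (source == r_src) & (src_start < r_hi) & (src_end > r_lo)

    return BeadChain(
        chromosome=chrom.name,
        bp_per_bead=bp_per_bead,
        source=source,
        src_start=src_start,
        src_end=src_end,
        comp_start=comp_start,
        comp_end=comp_end,
        is_centromere=is_centromere,
        is_terminal=is_terminal,
        is_telomeric=is_telomeric,
        is_rdna=is_rdna,
    )


def _trim_segments(segments: list[Segment], bp: int, end: Literal["left", "right"]) -> list[Segment]:
    """Remove ``bp`` of sequence from one end of a segment list (chain coords)."""
    if bp == 0:
        return list(segments)
    segs = list(segments)
    remaining = bp
    take_from = -1 if end == "right" else 0
    while remaining > 0:
        if not segs:
            raise ValueError("junction deletion removes an entire chromosome")
        seg = segs[take_from]
        if seg.length <= remaining:
            remaining -= seg.length
            segs.pop(take_from)
            continue
        # trim the chain-facing end of this segment
        trim_right_of_source = (end == "right") == seg.forward
        if trim_right_of_source:
            segs[take_from] = replace(seg, end=seg.end - remaining)
        else:
            segs[take_from] = replace(seg, start=seg.start + remaining)
        remaining = 0
    return segs


def _oriented(segments: list[Segment]) -> list[Segment]:
    """Reverse a segment list in place-order and flip orientations."""
    return [replace(s, forward=not s.forward) for s in reversed(segments)]


def apply_fusion_plan(karyotype: Karyotype, plan: Sequence[FusionEvent], name: str | None = None) -> Karyotype:
    """Apply a sequence of fusion events, returning the rearranged karyotype.

    Each event consumes one free end of the (possibly already fused) chain
    containing the recipient label and one free end of the donor chain,
    concatenates the two in the requested orientation minus any deleted
    junction sequence, and keeps the centromere of ``retained_centromere``.
    Reusing a consumed end, or fusing a chromosome with itself, is rejected.
    """
    chroms = {c.name: c for c in karyotype.chromosomes}
    consumed: set[tuple[str, str]] = set()  # (source chromosome, end) pairs used up

    def _find(label: str) -> ChromosomeSpec:
        if label in chroms:
            return chroms[label]
        for c in chroms.values():
            if label in c.sources:
                return c
        raise ValueError(f"fusion references unknown chromosome {label!r}")

    def _end_source(c: ChromosomeSpec, end: str) -> tuple[str, str]:
        seg = c.segments[0] if end == "left" else c.segments[-1]
        if end == "left":
            src_end = "left" if seg.forward else "right"
        else:
            src_end = "right" if seg.forward else "left"
        return (seg.source, src_end)

    for ev in plan:
        rec = _find(ev.recipient)
        don = _find(ev.donor)
        if rec is don:
            raise ValueError(f"cannot fuse {ev.recipient!r} with itself")
        for c, end in ((rec, ev.recipient_end), (don, ev.donor_end)):
            key = _end_source(c, end)
            if key in consumed:
                raise ValueError(f"chromosome end {key} already consumed by an earlier fusion")
        consumed.add(_end_source(rec, ev.recipient_end))
        consumed.add(_end_source(don, ev.donor_end))

        rec_segs = _trim_segments(rec.segments, ev.deleted_bp_recipient, ev.recipient_end)
        don_segs = list(don.segments)
        # orient the donor so its consumed end faces the junction
        junction_side: Literal["left", "right"]
        if ev.recipient_end == "right":
            junction_side = "left"
        else:
            junction_side = "right"
        # the consumed donor end must face the junction; this fixes the
        # donor orientation in the composite (the declarative
        # donor_orientation field is redundant given donor_end and is used
        # for readability/validation only)
        if ev.donor_end != junction_side:
            don_segs = _oriented(don_segs)
        don_segs = _trim_segments(don_segs, ev.deleted_bp_donor, junction_side)
        new_segs = rec_segs + don_segs if ev.recipient_end == "right" else don_segs + rec_segs

        if ev.retained_centromere == rec.centromere[0] or ev.retained_centromere in (
            rec.name,
        ):
            new_cen = rec.centromere
        elif ev.retained_centromere == don.centromere[0] or ev.retained_centromere in (
            don.name,
        ):
            new_cen = don.centromere
        else:
            raise ValueError(
                f"retained centromere {ev.retained_centromere!r} belongs to neither "
                f"{rec.name!r} nor {don.name!r}"
            )

        rdna = rec.rdna or don.rdna
        new_name = (
            f"{rec.name}:{don.name}" if ev.recipient_end == "right" else f"{don.name}:{rec.name}"
        )
        fused = ChromosomeSpec(name=new_name, segments=new_segs, centromere=new_cen, rdna=rdna)
        # the composite takes the recipient's slot so that global bead order
        # is preserved as far as possible across karyotypes
        order = list(chroms)
        pos = sum(1 for n in order[: order.index(rec.name)] if n != don.name)
        del chroms[rec.name]
        del chroms[don.name]
        items = list(chroms.items())
        items.insert(pos, (new_name, fused))
        chroms = dict(items)

    kname = name or (karyotype.name if not plan else f"{karyotype.name}+{len(plan)}fusions")
    return Karyotype(
        chromosomes=list(chroms.values()),
        plan=list(karyotype.plan) + list(plan),
        name=kname,
    )


def karyotype_summary(karyotype: Karyotype, bp_per_bead: int = BP_PER_BEAD) -> dict:
    """Chromosome, centromere, telomere and bead counts plus longest-arm length."""
    if not karyotype.chromosomes:
        return {
            "n_chromosomes": 0,
            "n_centromeres": 0,
            "n_telomeres": 0,
            "n_beads": 0,
            "longest_arm_bp": 0,
        }
    chains = karyotype.build_chains(bp_per_bead)
    longest_arm = max(max(c.arm_lengths_bp()) for c in karyotype.chromosomes)
    return {
        "n_chromosomes": karyotype.n_chromosomes,
        "n_centromeres": karyotype.n_chromosomes,
        "n_telomeres": karyotype.n_telomeres,
        "n_beads": int(sum(ch.n_beads for ch in chains)),
        "longest_arm_bp": int(longest_arm),
    }


def wild_type_karyotype(
    rdna_repeats: int = RDNA_REPEATS_DEFAULT, rdna_repeat_bp: int = RDNA_REPEAT_BP
) -> Karyotype:
    """The 16-chromosome haploid S. cerevisiae karyotype in model coordinates.

    The chromosome XII rDNA array is modelled as ``rdna_repeats`` tandem
    copies of a 9.1-kb unit in place of the two assembly repeats; the
    default repeat count (101, within the organism's 100-200 range) gives
    the published 4062-bead genome at 3.2 kb per bead.
    """
    chroms = []
    for name, (length, cen) in _WT_TABLE.items():
        if name == "XII":
            lo, hi = _RDNA_NATIVE_INTERVAL
            array = rdna_repeats * rdna_repeat_bp
            length = length - (hi - lo) + array
            chroms.append(simple_chromosome(name, length, cen, rdna_interval_bp=(lo, lo + array)))
        else:
            chroms.append(simple_chromosome(name, length, cen))
    return Karyotype(chromosomes=chroms, name="WT")


# Canonical fusion plans for the ten fusion-chromosome strains.  Each fusion
# joins the right end of the growing composite (chromosome IV is always the
# first recipient, consistent with TEL4R being consumed in every strain) to
# the left end of the next donor; the trailing label names the surviving
# centromere.
def _plan(*steps: tuple[str, str, str]) -> list[FusionEvent]:
    return [
        FusionEvent(recipient=r, donor=d, retained_centromere=keep) for r, d, keep in steps
    ]


FC_STRAINS: dict[str, list[FusionEvent]] = {
    "FC(IV:XII)CEN4": _plan(("IV", "XII", "IV")),
    "FC(IV:XII)CEN12": _plan(("IV", "XII", "XII")),
    "FC(IV:XV)CEN4": _plan(("IV", "XV", "IV")),
    "FC(IV:XV)CEN15": _plan(("IV", "XV", "XV")),
    "FC(IV:XV:V)CEN4": _plan(("IV", "XV", "IV"), ("IV", "V", "IV")),
    "FC(IV:XV:V)CEN5": _plan(("IV", "XV", "IV"), ("IV", "V", "V")),
    "FC(IV:XV:XVI)CEN4": _plan(("IV", "XV", "IV"), ("IV", "XVI", "IV")),
    "FC(IV:XV:XVI)CEN16": _plan(("IV", "XV", "IV"), ("IV", "XVI", "XVI")),
    "FC(IV:V:VII:XV)CEN4": _plan(("IV", "V", "IV"), ("IV", "VII", "IV"), ("IV", "XV", "IV")),
    "FC(IV:V:VII:XV)CEN7": _plan(("IV", "V", "IV"), ("IV", "VII", "VII"), ("IV", "XV", "VII")),
}


def fusion_plan(strain: str) -> list[FusionEvent]:
    """Canonical fusion plan for one of the named fusion-chromosome strains."""
    try:
        return list(FC_STRAINS[strain])
    except KeyError:
        raise KeyError(
            f"unknown strain {strain!r}; known strains: {sorted(FC_STRAINS)}"
        ) from None


def scaled_wild_type(scale: float = 0.1, **wt_kwargs) -> Karyotype:
    """A wild-type karyotype with all chromosome lengths scaled down.

    Keeps the 16-chromosome architecture (relative lengths, centromere
    positions and the rDNA interval scaled proportionally) while reducing
    the bead count, for ensemble runs at desk scale.  Intervals are
    rounded to whole beads to keep the discretisation faithful.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    wt = wild_type_karyotype(**wt_kwargs)
    chroms = []
    for c in wt.chromosomes:
        L = max(2 * BP_PER_BEAD, int(round(c.length_bp * scale)))
        cen = min(max(1, int(round(c.centromere[1] * scale))), L - 1)
        rdna = None
        if c.rdna is not None:
            lo, hi = c.rdna[1]
            lo, hi = int(round(lo * scale)), int(round(hi * scale))
            if hi > lo and hi <= L:
                rdna = (lo, hi)
        chroms.append(simple_chromosome(c.name, L, cen, rdna_interval_bp=rdna))
    return Karyotype(chromosomes=chroms, name=f"WT-scaled-{scale:g}")


def strain_karyotype(strain: str, **wt_kwargs) -> Karyotype:
    """Wild-type or named fusion-strain karyotype."""
    wt = wild_type_karyotype(**wt_kwargs)
    if strain in ("WT", "wt"):
        return wt
    return apply_fusion_plan(wt, fusion_plan(strain), name=strain)
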