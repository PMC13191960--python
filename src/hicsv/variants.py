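"""Domain types for SV breakpoints, copy-number segments, cSV events,
gene models, and mutation matrices."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval

SV_TYPES = ("DEL", "DUP", "INV", "TRA", "INS")
EVENT_CLASSES = ("ecDNA", "BFB", "CNC", "unknown", "linear")
_CLASS_BY_LOWER = {c.lower(): c for c in EVENT_CLASSES}


def normalize_event_class(label: str) -> str:
    try:
        return _CLASS_BY_LOWER[label.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown event class {label!r}; allowed: {', '.join(EVENT_CLASSES)}"
        ) from None


@dataclass(frozen=True)
class Breakpoint:
    """One SV junction with canonically ordered ends.

    Canonical order: (chrom1, pos1) <= (chrom2, pos2); strands travel with
    their end when the pair is swapped.
    """

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sv_type: str = ""

    def __post_init__(self) -> None:
        for s in (self.strand1, self.strand2):
            if s not in ("+", "-"):
                raise ValueError(f"unknown strand symbol {s!r}")
        if self.sv_type and self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")

    @staticmethod
    def make(
        chrom1: str, pos1: int, strand1: str,
        chrom2: str, pos2: int, strand2: str,
        sv_type: str | None = None,
    ) -> "Breakpoint":
        """Build a canonical breakpoint, inferring sv_type when not given.

        Inference rule (fixed convention): intra-chromosomal +/- -> DEL,
        -/+ -> DUP, +/+ or -/- -> INV; inter-chromosomal -> TRA.
        """
        if (chrom2, pos2) < (chrom1, pos1):
            chrom1, pos1, strand1, chrom2, pos2, strand2 = (
                chrom2, pos2, strand2, chrom1, pos1, strand1
            )
        if sv_type is None or sv_type == "":
            if chrom1 != chrom2:
                sv_type = "TRA"
            elif strand1 == strand2:
                sv_type = "INV"
            elif (strand1, strand2) == ("+", "-"):
                sv_type = "DEL"
            else:
                sv_type = "DUP"
        return Breakpoint(chrom1, pos1, strand1, chrom2, pos2, strand2, sv_type)


@dataclass(frozen=True)
class CopyNumberSegment:
    interval: GenomicInterval
    copy_number: float

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


class CopyNumberSegmentSet:
    """Per-sample absolute copy-number segments plus purity and ploidy.

    Segments are kept sorted and must not overlap within a chromosome.
    """

    def __init__(
        self,
        sample_id: str,
        segments: Iterable[CopyNumberSegment],
        purity: float = 1.0,
        ploidy: float = 2.0,
    ):
        if not 0 < purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if ploidy <= 0:
            raise ValueError("ploidy must be positive")
        segs = sorted(segments, key=lambda s: s.interval)
        for a, b in zip(segs, segs[1:]):
            if a.interval.chrom == b.interval.chrom and b.interval.start < a.interval.end:
                raise ValueError(
                    f"overlapping segments {a.interval} and {b.interval}"
                )
        self.sample_id = sample_id
        self.segments = segs
        self.purity = float(purity)
        self.ploidy = float(ploidy)

    def on_chrom(self, chrom: str) -> list[CopyNumberSegment]:
        return [s for s in self.segments if s.interval.chrom == chrom]

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


@dataclass
class AmpliconEvent:
    """One cSV call: class label plus ordered genomic segments with CN."""

    event_id: str
    sample_id: str
    event_class: str
    segments: list[tuple[GenomicInterval, float]]
    junctions: list[Breakpoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.event_class = normalize_event_class(self.event_class)
        if not self.segments:
            raise ValueError("event must have at least one segment")
        for _, cn in self.segments:
            if cn < 0:
                raise ValueError("segment copy number must be >= 0")
        self.segments = sorted(self.segments, key=lambda s: s[0])

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv, _ in self.segments:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.segments]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    chrom_type: str = "autosome"  # or "single_copy_sex"

    def __post_init__(self) -> None:
        if self.chrom_type not in ("autosome", "single_copy_sex"):
            raise ValueError(f"unknown chrom_type {self.chrom_type!r}")


class MutationMatrix:
    """Samples x variants binary presence matrix of deleterious mutations."""

    def __init__(
        self,
        sample_ids: Sequence[str],
        variant_ids: Sequence[str],
        presence: np.ndarray,
    ):
        presence = np.asarray(presence)
        if presence.shape != (len(sample_ids), len(variant_ids)):
            raise ValueError("presence matrix shape mismatch")
        if not np.isin(presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")
        self.sample_ids = list(sample_ids)
        self.variant_ids = list(variant_ids)
        self.presence = presence.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape
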