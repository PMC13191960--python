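"""Gene-level weighted copy number and ploidy-aware status calls.

Gene CN is the mean of overlapping segment CNs weighted by covered bp.
Status thresholds (strict inequalities, relative to tumor ploidy):

* weighted CN < 0.5 -> biallelic loss (takes precedence)
* autosome: gain if CN > ploidy x 1.95, loss if CN < ploidy x 0.5
* single-copy sex chromosome: gain if CN > ploidy x 0.8,
  loss if CN < ploidy x 0.3
* otherwise neutral (boundary equality is the non-call branch)
"""
from __future__ import annotations

from dataclasses import dataclass

from .variants import AmpliconEvent, CopyNumberSegmentSet, GeneModel

BIALLELIC_LOSS_CN = 0.5
GAIN_FACTOR = {"autosome": 1.95, "single_copy_sex": 0.8}
LOSS_FACTOR = {"autosome": 0.5, "single_copy_sex": 0.3}


@dataclass(frozen=True)
class GeneCNCall:
    gene_id: str
    weighted_cn: float
    status: str
    ploidy_used: float
    chrom_type: str


def gene_weighted_cn(segments: CopyNumberSegmentSet, gene: GeneModel) -> float | None:
    """Coverage-weighted mean CN over segments overlapping the gene span.

    Weights are renormalized over covered bp when segments only partially
    tile the transcript. Returns None (missing, not zero) with no overlap.
    """
    num = den = 0.0
    for seg in segments.on_chrom(gene.interval.chrom):
        ov = seg.interval.overlap_length(gene.interval)
        if ov > 0:
            num += seg.copy_number * ov
            den += ov
    if den == 0:
        return None
    return num / den


def call_cn_status(weighted_cn: float, ploidy: float, chrom_type: str) -> str:
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if chrom_type not in GAIN_FACTOR:
        raise ValueError(f"unknown chrom_type {chrom_type!r}")
    if weighted_cn < BIALLELIC_LOSS_CN:
        return "biallelic_loss"
    if weighted_cn > ploidy * GAIN_FACTOR[chrom_type]:
        return "gain"
    if weighted_cn < ploidy * LOSS_FACTOR[chrom_type]:
        return "loss"
    return "neutral"


def annotate_genes(
    segments: CopyNumberSegmentSet, genes: list[GeneModel]
) -> list[GeneCNCall]:
    """Weighted CN + status for every gene with segment coverage."""
    calls = []
    for gene in genes:
        wcn = gene_weighted_cn(segments, gene)
        if wcn is None:
            continue
        calls.append(
            GeneCNCall(gene.gene_id, wcn,
                       call_cn_status(wcn, segments.ploidy, gene.chrom_type),
                       segments.ploidy, gene.chrom_type)
        )
    return calls


def event_weighted_cn(event: AmpliconEvent) -> float:
    """Length-weighted mean CN over the event's segments."""
    total = sum(len(iv) for iv, _ in event.segments)
    if total == 0:
        raise ValueError("event has zero total segment length")
    return sum(cn * len(iv) for iv, cn in event.segments) / total
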