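"""Readers and writers for every text format the pipeline touches.

Dialects
--------
* copy-number segments: ``purple_tsv`` (columns ``chromosome  start  end
  copyNumber``, 1-based inclusive coordinates, optional ``#purity=`` /
  ``#ploidy=`` comment header) or ``bed`` (0-based half-open, CN in column 4).
* SV breakpoints: 10-column BEDPE (+ optional ``sv_type`` column 11);
  breakend positions are the 0-based ``start1``/``start2`` fields.
* cSV events: one row per segment with columns ``sample_id  event_id  class
  chrom  start  end  copy_number`` (0-based half-open; artifact-defined
  dialect, since classifier output is consumed, not produced).
* Hi-C: a ``bins`` table (chrom, start, end) plus a ``pixels`` table
  (bin1_id, bin2_id, count) with ``bin1_id <= bin2_id`` (upper triangle).
* peaks / genes / exclusion list: BED.
* expression: TSV, genes x samples; mutation matrix: TSV, samples x variants.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import ContactMatrix
from .genome import GenomeBins
from .intervals import GenomicInterval
from .variants import (
    AmpliconEvent,
    Breakpoint,
    CopyNumberSegment,
    CopyNumberSegmentSet,
    GeneModel,
    MutationMatrix,
    normalize_event_class,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- segments

def read_copy_segments(
    path: str | Path,
    dialect: str = "purple_tsv",
    sample_id: str | None = None,
    purity: float | None = None,
    ploidy: float | None = None,
) -> CopyNumberSegmentSet:
    """Read a per-sample copy-number segment table.

    ``purple_tsv`` coordinates are 1-based inclusive and converted to the
    internal 0-based half-open convention; ``bed`` is taken as-is.
    Purity/ploidy may come from ``#purity=``/``#ploidy=`` comment lines or the
    keyword arguments (arguments win).
    """
    path = Path(path)
    if dialect not in ("purple_tsv", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    meta: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    try:
                        meta[k.strip()] = float(v)
                    except ValueError:
                        pass
                continue
            fields = line.split("\t")
            if dialect == "purple_tsv" and fields[0] == "chromosome":
                continue  # header row
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                cn = float(fields[3])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {exc}") from None
            if dialect == "purple_tsv":
                start -= 1  # 1-based inclusive -> 0-based half-open
            rows.append(CopyNumberSegment(GenomicInterval(chrom, start, end), cn))
    pur = purity if purity is not None else meta.get("purity", 1.0)
    plo = ploidy if ploidy is not None else meta.get("ploidy", 2.0)
    return CopyNumberSegmentSet(sample_id or path.stem, rows, purity=pur, ploidy=plo)


def write_copy_segments(
    segset: CopyNumberSegmentSet, path: str | Path, dialect: str = "purple_tsv"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"#purity={segset.purity!r}\n#ploidy={segset.ploidy!r}\n")
        if dialect == "purple_tsv":
            fh.write("chromosome\tstart\tend\tcopyNumber\n")
            for s in segset:
                iv = s.interval
                fh.write(f"{iv.chrom}\t{iv.start + 1}\t{iv.end}\t{float(s.copy_number)!r}\n")
        elif dialect == "bed":
            for s in segset:
                iv = s.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{float(s.copy_number)!r}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# -------------------------------------------------------------- breakpoints

def read_breakpoints(path: str | Path) -> list[Breakpoint]:
    """Read a 10-column BEDPE (+ optional 11th sv_type column)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ParseError(f"{path}:{lineno}: expected >=10 BEDPE columns")
            try:
                bp = Breakpoint.make(
                    f[0], int(f[1]), f[8], f[3], int(f[4]), f[9],
                    sv_type=f[10] if len(f) > 10 else None,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            out.append(bp)
    return out


def write_breakpoints(breakpoints: list[Breakpoint], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, b in enumerate(breakpoints):
            fh.write(
                f"{b.chrom1}\t{b.pos1}\t{b.pos1 + 1}\t{b.chrom2}\t{b.pos2}\t"
                f"{b.pos2 + 1}\tbp{i}\t.\t{b.strand1}\t{b.strand2}\t{b.sv_type}\n"
            )


# ------------------------------------------------------------------ events

_EVENT_COLS = ["sample_id", "event_id", "class", "chrom", "start", "end", "copy_number"]


def read_events(path: str | Path) -> list[AmpliconEvent]:
    """Read cSV events from the one-row-per-segment TSV dialect."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(_EVENT_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    ndup = df.duplicated().sum()
    if ndup:
        warnings.warn(f"{path}: {ndup} duplicate event rows dropped")
        df = df.drop_duplicates()
    events = []
    for (sample_id, event_id), grp in df.groupby(["sample_id", "event_id"], sort=True):
        classes = {normalize_event_class(c) for c in grp["class"]}
        if len(classes) != 1:
            raise ParseError(f"{path}: event {event_id} has conflicting classes")
        segments = [
            (GenomicInterval(r.chrom, int(r.start), int(r.end)), float(r.copy_number))
            for r in grp.itertuples()
        ]
        events.append(
            AmpliconEvent(str(event_id), str(sample_id), classes.pop(), segments)
        )
    return events


def write_events(events: list[AmpliconEvent], path: str | Path) -> None:
    rows = []
    for e in events:
        for iv, cn in e.segments:
            rows.append(
                (e.sample_id, e.event_id, e.event_class, iv.chrom, iv.start, iv.end,
                 repr(float(cn)))
            )
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- Hi-C

def read_contact_matrix(
    bins_path: str | Path, pixels_path: str | Path
) -> ContactMatrix:
    """Assemble a symmetric ContactMatrix from bins + pixels text tables.

    Pixels store the upper triangle (``bin1_id <= bin2_id``); the lower
    triangle is mirrored. Bins without any pixel in their row/column are
    masked rather than treated as observed zeros.
    """
    bins_df = pd.read_csv(bins_path, sep="\t")
    chromsizes: dict[str, int] = {}
    widths = []
    for r in bins_df.itertuples():
        chromsizes[r.chrom] = max(chromsizes.get(r.chrom, 0), int(r.end))
        widths.append(int(r.end) - int(r.start))
    bin_size = max(widths) if widths else 10_000
    bins = GenomeBins(chromsizes, bin_size)
    if bins.n_bins != len(bins_df):
        raise ParseError(f"{bins_path}: bins do not tile the declared genome")
    px = pd.read_csv(pixels_path, sep="\t")
    b1 = px["bin1_id"].to_numpy(int)
    b2 = px["bin2_id"].to_numpy(int)
    cnt = px["count"].to_numpy(float)
    if (b1 > b2).any():
        bad = int(np.argmax(b1 > b2))
        raise ParseError(
            f"{pixels_path}: pixel row {bad} has bin1_id > bin2_id"
        )
    if len(b1) and (b1.min() < 0 or b2.max() >= bins.n_bins):
        raise ParseError(f"{pixels_path}: bin id out of range")
    if (cnt < 0).any():
        raise ParseError(f"{pixels_path}: negative count")
    upper = sp.coo_matrix((cnt, (b1, b2)), shape=(bins.n_bins, bins.n_bins))
    diag = sp.diags(upper.diagonal())
    full = upper + upper.T - diag
    return ContactMatrix(bins, full)


def write_contact_matrix(
    matrix: ContactMatrix, bins_path: str | Path, pixels_path: str | Path
) -> None:
    with open(bins_path, "w") as fh:
        fh.write("chrom\tstart\tend\n")
        for i in range(matrix.bins.n_bins):
            iv = matrix.bins.bin_interval(i)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    coo = sp.triu(matrix.values).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(pixels_path, "w") as fh:
        fh.write("bin1_id\tbin2_id\tcount\n")
        for i in order:
            fh.write(f"{coo.row[i]}\t{coo.col[i]}\t{float(coo.data[i])!r}\n")


# -------------------------------------------------------------- BED / genes

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genes(
    path: str | Path, sex_chroms: tuple[str, ...] = ("chrX", "chrY")
) -> list[GeneModel]:
    """Read gene models from 4-column BED (chrom, start, end, gene_id)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
                gene_id = f[3]
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            chrom_type = "single_copy_sex" if iv.chrom in sex_chroms else "autosome"
            out.append(GeneModel(gene_id, iv, chrom_type))
    return out


# ------------------------------------------------- expression / mutations

def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression table (first column = gene_id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_mutation_matrix(path: str | Path) -> MutationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MutationMatrix(list(df.index), list(df.columns), df.to_numpy())


def write_mutation_matrix(m: MutationMatrix, path: str | Path) -> None:
    pd.DataFrame(m.presence, index=m.sample_ids, columns=m.variant_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )
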