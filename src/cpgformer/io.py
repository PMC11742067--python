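"""File I/O: DMR tables, methylation-tagged BAM/SAM, posterior tables, FASTA.

Coordinates are 0-based half-open internally.  BED-like DMR tables are read
as-is; BAM/SAM records go through pysam (already 0-based in its API).
Methylation calls are taken exclusively from the per-base call string in
the ``XM`` tag (Bismark dialect: ``Z`` = methylated CpG, ``z`` =
unmethylated CpG, ``.`` = no call); no re-calling from the sequence.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
import pysam

from .types import GenomicRegion, MethylRead, PosteriorTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_dmr_table",
    "select_top_regions",
    "parse_methylation_bam",
    "write_methylation_bam",
    "write_posterior_table",
    "read_posterior_table",
    "read_table_reads",
    "write_table_reads",
    "fasta_segments",
]


# ---------------------------------------------------------------------------
# DMR tables


def read_dmr_table(path: Union[str, Path]) -> list[GenomicRegion]:
    """Load a BED-like tab-separated DMR table.

    Requires columns ``chr``/``chrom``, ``start``, ``end`` and
    ``areaStat`` (case-insensitive; a headerless 4-column file is accepted
    in that order).  Raises ``ValueError`` naming the offending line on
    malformed rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if not {"start", "end"} <= set(cols):
        # headerless file: positional columns
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "areaStat"], dtype=str,
        )
        cols = {c.lower(): c for c in df.columns}
    chrom_col = cols.get("chrom", cols.get("chr"))
    area_col = cols.get("areastat")
    if chrom_col is None or area_col is None:
        raise ValueError(f"{path}: expected chrom/start/end/areaStat columns")
    regions = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2 if cols.get("start") == "start" else i + 1
        try:
            regions.append(
                GenomicRegion(
                    chrom=str(getattr(row, chrom_col)),
                    start=int(getattr(row, cols["start"])),
                    end=int(getattr(row, cols["end"])),
                    area_stat=float(getattr(row, area_col)),
                    region_index=i,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {line_no}: {exc}") from exc
    return regions


def select_top_regions(
    regions: Sequence[GenomicRegion], n: int
) -> list[GenomicRegion]:
    """Keep the ``n`` regions with the largest areaStat score.

    Deterministic tie-break by (chrom, start).  Region indices are
    reassigned 0..n-1 in the selected order so they can feed the region
    embedding directly.
    """
    if n > len(regions):
        logger.warning(
            "requested top %d regions but only %d available; keeping all",
            n,
            len(regions),
        )
        n = len(regions)
    ranked = sorted(regions, key=lambda r: (-r.area_stat, r.chrom, r.start))[:n]
    return [
        GenomicRegion(r.chrom, r.start, r.end, r.area_stat, region_index=i)
        for i, r in enumerate(ranked)
    ]


def _assign_region(
    chrom: str, start: int, end: int, regions: Sequence[GenomicRegion]
) -> Optional[int]:
    """Region with the largest bp overlap; ties go to the lower start."""
    best, best_ov = None, 0
    for r in regions:
        if r.chrom != chrom:
            continue
        ov = r.overlap(start, end)
        if ov > best_ov or (ov == best_ov and ov > 0 and r.start < best.start):
            best, best_ov = r, ov
    return best.region_index if best is not None else None


# ---------------------------------------------------------------------------
# BAM/SAM with XM-dialect methylation calls


def parse_methylation_bam(
    path: Union[str, Path],
    regions: Sequence[GenomicRegion],
    on_missing_tag: str = "skip",
) -> Iterator[MethylRead]:
    """Stream reads overlapping ``regions`` from an XM-tagged BAM/SAM.

    CpG calls are extracted from ``Z``/``z`` symbols of the XM tag;
    unmapped reads are skipped.  Reads overlapping no region are skipped;
    a read spanning several regions is assigned to the one with the larger
    base-pair overlap (tie: lower start).  ``on_missing_tag`` is ``"skip"``
    (count and drop) or ``"error"``.
    """
    if on_missing_tag not in ("skip", "error"):
        raise ValueError("on_missing_tag must be 'skip' or 'error'")
    path = str(path)
    mode = "r" if path.endswith(".sam") else "rb"
    n_missing = 0
    seen: set[str] = set()
    with pysam.AlignmentFile(path, mode) as bam:
        has_index = bam.has_index()
        all_alns = None
        if not has_index:  # SAM without index: one full pass held in memory
            all_alns = [a for a in bam.fetch(until_eof=True) if not a.is_unmapped]
        for region in sorted(regions, key=lambda r: (r.chrom, r.start)):
            if has_index:
                it: Iterable = bam.fetch(region.chrom, region.start, region.end)
            else:
                it = (
                    a
                    for a in all_alns
                    if a.reference_name == region.chrom
                    and a.reference_start < region.end
                    and a.reference_end is not None
                    and a.reference_end > region.start
                )
            for aln in it:
                if aln.is_unmapped or aln.query_name in seen:
                    continue
                ridx = _assign_region(
                    aln.reference_name, aln.reference_start, aln.reference_end, regions
                )
                if ridx != region.region_index:
                    continue  # yielded from its best-overlap region only
                if not aln.has_tag("XM"):
                    if on_missing_tag == "error":
                        raise ValueError(f"read {aln.query_name} lacks the XM tag")
                    n_missing += 1
                    continue
                xm = aln.get_tag("XM")
                calls = [
                    (i, sym == "Z") for i, sym in enumerate(xm) if sym in "Zz"
                ]
                seen.add(aln.query_name)
                yield MethylRead(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    sequence=aln.query_sequence,
                    cpg_calls=calls,
                    strand="-" if aln.is_reverse else "+",
                    region_index=ridx,
                )
    if n_missing:
        logger.warning("skipped %d reads lacking the XM tag", n_missing)


def write_methylation_bam(
    path: Union[str, Path],
    reads: Sequence[MethylRead],
    chrom_sizes: dict,
) -> None:
    """Write reads as a coordinate-sorted, XM-tagged BAM (or SAM by suffix).

    The XM string carries ``Z``/``z`` at called CpGs and ``.`` elsewhere.
    A ``.bai`` index is created for BAM output.
    """
    path = str(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_sizes.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_sizes)}
    mode = "w" if path.endswith(".sam") else "wb"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for read in sorted(reads, key=lambda r: (tid[r.chrom], r.start)):
            a = pysam.AlignedSegment()
            a.query_name = read.read_id
            a.query_sequence = read.sequence
            a.flag = 16 if read.strand == "-" else 0
            a.reference_id = tid[read.chrom]
            a.reference_start = read.start
            a.mapping_quality = 42
            a.cigartuples = [(0, len(read.sequence))]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.sequence))
            xm = ["."] * len(read.sequence)
            for off, methylated in read.cpg_calls:
                xm[off] = "Z" if methylated else "z"
            a.set_tag("XM", "".join(xm))
            if read.cell_label is not None:
                a.set_tag("XC", read.cell_label)
            out.write(a)
    if mode == "wb":
        pysam.index(path)


# ---------------------------------------------------------------------------
# Plain-text read tables (simulator output / BAM-free interchange)

_TABLE_COLS = ["read_id", "chrom", "start", "strand", "region_index",
               "cell_label", "sequence", "cpg_calls"]


def write_table_reads(path: Union[str, Path], reads: Sequence[MethylRead]) -> None:
    """Write reads as TSV; cpg_calls serialised as ``offset:M|U`` pairs."""
    rows = []
    for r in reads:
        calls = ",".join(f"{o}:{'M' if m else 'U'}" for o, m in r.cpg_calls)
        rows.append([r.read_id, r.chrom, r.start, r.strand, r.region_index,
                     r.cell_label if r.cell_label is not None else ".",
                     r.sequence, calls])
    pd.DataFrame(rows, columns=_TABLE_COLS).to_csv(path, sep="\t", index=False)


def read_table_reads(path: Union[str, Path]) -> list[MethylRead]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    reads = []
    for row in df.itertuples(index=False):
        calls = []
        if row.cpg_calls:
            for item in row.cpg_calls.split(","):
                off, state = item.split(":")
                calls.append((int(off), state == "M"))
        reads.append(
            MethylRead(
                read_id=row.read_id,
                chrom=row.chrom,
                start=int(row.start),
                sequence=row.sequence,
                cpg_calls=calls,
                strand=row.strand,
                region_index=int(row.region_index),
                cell_label=None if row.cell_label == "." else row.cell_label,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Posterior tables


def write_posterior_table(path: Union[str, Path], table: PosteriorTable) -> None:
    """Write a posterior table as TSV with priors in a ``#`` header line."""
    with open(path, "w") as fh:
        prior_str = "\t".join(
            f"{c}={p:.10g}" for c, p in zip(table.cell_types, table.priors)
        )
        fh.write(f"# priors\t{prior_str}\n")
        cols = ["read_id", "region_index", *table.cell_types, "predicted_label"]
        table.frame[cols].to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_posterior_table(path: Union[str, Path]) -> PosteriorTable:
    """Inverse of :func:`write_posterior_table` (round-trip to ~1e-9)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# priors"):
            raise ValueError(f"{path}: missing '# priors' header line")
        pairs = [p.split("=") for p in first.strip().split("\t")[1:]]
        cell_types = [k for k, _ in pairs]
        priors = [float(v) for _, v in pairs]
        df = pd.read_csv(fh, sep="\t")
    if df.empty:
        df = pd.DataFrame(
            columns=["read_id", "region_index", *cell_types, "predicted_label"]
        )
        df["region_index"] = df["region_index"].astype(int)
    return PosteriorTable(df, cell_types, priors)


# ---------------------------------------------------------------------------
# FASTA corpus


def fasta_segments(
    path: Union[str, Path],
    segment_length: int = 510,
    drop_remainder: bool = True,
) -> list[str]:
    """Split every FASTA record into consecutive fixed-length segments.

    Used to build the masked-language-model pre-training corpus.  Segments
    shorter than ``segment_length`` at contig ends are dropped by default.
    """
    from pyfaidx import Fasta

    segments = []
    with Fasta(str(path), rebuild=False, build_index=True) as fa:
        for name in fa.keys():
            seq = str(fa[name][:]).upper()
            for i in range(0, len(seq) - segment_length + 1, segment_length):
                segments.append(seq[i : i + segment_length])
            if not drop_remainder and len(seq) % segment_length >= 3:
                segments.append(seq[len(seq) - (len(seq) % segment_length):])
    if not segments:
        raise ValueError(f"{path}: no segments of length {segment_length} found")
    return segments
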