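"""Tumor-specific variant filtering and splice-signal annotation.

Variant calling itself is upstream (the module consumes per-sample VCFs);
here a tumor variant survives when it has enough quality-filtered
supporting reads, the matched normal has coverage at the position, and
the matched normal's calls contain no variant there. Surviving calls are
then intersected with the donor/acceptor signal windows of the junction
library to flag variants that could disrupt splicing of a retained
intron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pysam

from .annotation import Junction

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "TSVCall",
    "read_vcf",
    "read_coverage_tsv",
    "CoverageTrack",
    "filter_tumor_specific",
    "annotate_splice_overlap",
]


@dataclass(frozen=True)
class VariantRecord:
    """One called variant; positions are 0-based."""

    contig: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    supporting_reads: int  # alt reads with base quality >= 20
    total_depth: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.supporting_reads > self.total_depth:
            raise ValueError("supporting reads cannot exceed depth")


@dataclass
class TSVCall:
    """A tumor-specific variant: covered but absent in the matched normal."""

    variant: VariantRecord
    normal_depth: int
    splice_site_hit: bool = False
    junction_id: str | None = None
    junction_side: str | None = None


class CoverageTrack:
    """Per-contig depth intervals (BED-graph style, 0-based half-open)."""

    def __init__(self, intervals: Sequence[tuple[str, int, int, int]]):
        self._by_contig: dict[str, list[tuple[int, int, int]]] = {}
        for contig, start, end, depth in intervals:
            self._by_contig.setdefault(contig, []).append((start, end, depth))
        for ivs in self._by_contig.values():
            ivs.sort()

    def depth_at(self, contig: str, pos: int) -> int:
        for start, end, depth in self._by_contig.get(contig, ()):
            if start <= pos < end:
                return depth
            if start > pos:
                break
        return 0


def read_coverage_tsv(path: str) -> CoverageTrack:
    """Read contig<TAB>start<TAB>end<TAB>depth intervals."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            contig, start, end, depth = line.split("\t")[:4]
            intervals.append((contig, int(start), int(end), int(depth)))
    return CoverageTrack(intervals)


def read_vcf(path: str, sample_id: str) -> list[VariantRecord]:
    """Read SNVs from a VCF 4.x file.

    Supporting-read counts are taken from the ``SRQ`` INFO field (alt
    reads at base quality >= 20) when present, otherwise from the alt
    component of the first sample's ``AD``; depth from ``DP``.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if alt is None:
                    continue
                dp = rec.info.get("DP", 0)
                if "SRQ" in rec.info:
                    srq = rec.info["SRQ"]
                    support = int(srq[0] if isinstance(srq, tuple) else srq)
                elif rec.samples and "AD" in rec.samples[0]:
                    support = int(rec.samples[0]["AD"][1])
                else:
                    raise ValueError(
                        f"{path}: record {rec.contig}:{rec.pos} lacks SRQ/AD"
                    )
                out.append(
                    VariantRecord(
                        contig=rec.contig,
                        pos=rec.pos - 1,
                        ref=rec.ref,
                        alt=str(alt),
                        sample_id=sample_id,
                        supporting_reads=support,
                        total_depth=int(dp),
                    )
                )
    return out


def filter_tumor_specific(
    tumor_variants: Sequence[VariantRecord],
    normal_variants: Sequence[VariantRecord],
    normal_coverage: CoverageTrack,
    min_reads: int = 3,
    min_baseq: int = 20,  # documented provenance of supporting_reads
) -> list[TSVCall]:
    """Keep tumor variants absent but covered in the matched normal.

    A variant survives iff it has >= ``min_reads`` quality-filtered
    supporting reads, the matched normal has >= 1x coverage at the
    position, and no normal call exists at that position (any allele).
    Raising ``min_reads`` can only shrink the result (monotone filter).
    """
    normal_positions = {(v.contig, v.pos) for v in normal_variants}
    calls: list[TSVCall] = []
    for v in tumor_variants:
        if v.supporting_reads < min_reads:
            continue
        depth = normal_coverage.depth_at(v.contig, v.pos)
        if depth < 1:
            continue
        if (v.contig, v.pos) in normal_positions:
            continue
        calls.append(TSVCall(variant=v, normal_depth=depth))
    return calls


def _signal_windows(
    j: Junction, donor_window: int, acceptor_window: int
) -> tuple[int, int] | None:
    """Genomic half-open interval of the splice-signal bases for ``j``.

    Donor signal: the first ``donor_window`` intronic bases after the
    exon (the GT dinucleotide at width 2); acceptor signal: the last
    ``acceptor_window`` intronic bases before the exon (the AG). Windows
    are computed in transcription orientation, so they flip ends on the
    minus strand.
    """
    if j.side == "donor":
        w = donor_window
        if w == 0:
            return None
        if j.strand == "+":
            return (j.intron_start, min(j.intron_start + w, j.intron_end))
        return (max(j.intron_end - w, j.intron_start), j.intron_end)
    w = acceptor_window
    if w == 0:
        return None
    if j.strand == "+":
        return (max(j.intron_end - w, j.intron_start), j.intron_end)
    return (j.intron_start, min(j.intron_start + w, j.intron_end))


def annotate_splice_overlap(
    tsv_calls: Sequence[TSVCall],
    junctions: Sequence[Junction],
    donor_window: int = 2,
    acceptor_window: int = 2,
) -> list[TSVCall]:
    """Flag tumor-specific variants falling in splice-signal windows.

    Each call is marked with the first junction whose donor/acceptor
    signal window contains the variant position.
    """
    windows: list[tuple[str, int, int, Junction]] = []
    for j in junctions:
        iv = _signal_windows(j, donor_window, acceptor_window)
        if iv is not None:
            windows.append((j.contig, iv[0], iv[1], j))
    windows.sort(key=lambda w: (w[0], w[1]))
    for call in tsv_calls:
        call.splice_site_hit = False
        call.junction_id = None
        call.junction_side = None
        for contig, lo, hi, j in windows:
            if contig == call.variant.contig and lo <= call.variant.pos < hi:
                call.splice_site_hit = True
                call.junction_id = j.junction_id
                call.junction_side = j.side
                break
    return list(tsv_calls)
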