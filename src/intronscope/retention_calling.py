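"""Retention-read classification and group-specific retention calling.

Round-2 alignments place reads that failed to map to the spliced
transcriptome onto the 202-bp junction library. A read is evidence of an
unspliced intron (a *retention read*) only when it is uniquely and
confidently mapped and cleanly covers a window centered on the
exon-intron switch point: MAPQ >= 30, full coverage of the 20-bp
boundary-centered window, at most two mismatches inside that window, and
no indel touching it.

A junction is a tumor-specific retention (TSR) when retention reads
support it in at least two tumor samples and not a single retention read
appears in any normal sample; normal-specific retention (NSR) is the
mirror image. The zero-in-the-other-group rule is absolute: it is the
contamination filter that makes the calls group-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import Junction

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

__all__ = [
    "JunctionAlignment",
    "RetentionMatrix",
    "GroupSpecificCallSet",
    "classify_retention_read",
    "read_junction_alignments",
    "call_sample_retentions",
    "call_group_specific",
    "map_calls_to_genes",
    "summarize_table1",
]


@dataclass
class JunctionAlignment:
    """One read aligned to a junction contig, reduced to what calling needs.

    ``mismatch_offsets`` are reference offsets on the junction contig;
    ``indel_intervals`` are reference intervals of deletions (half-open)
    and insertions (empty intervals ``(p, p)`` anchored at the insertion
    point).
    """

    read_id: str
    junction_id: str
    start_offset: int
    aligned_length: int
    mapq: int
    mismatch_offsets: tuple[int, ...] = ()
    indel_intervals: tuple[tuple[int, int], ...] = ()
    is_primary: bool = True
    is_unique: bool = True

    @property
    def end_offset(self) -> int:
        return self.start_offset + self.aligned_length

    @property
    def has_indel(self) -> bool:
        return bool(self.indel_intervals)

    @classmethod
    def from_pysam(
        cls, aln: pysam.AlignedSegment, junction_seq: str | None = None
    ) -> "JunctionAlignment":
        """Build from a mapped pysam record.

        Mismatch offsets come from the MD tag; when MD is absent the read
        is re-scored against ``junction_seq`` (required in that case).
        Uniqueness uses the NH tag when present (NH == 1), otherwise the
        secondary/supplementary flags alone.
        """
        if aln.is_unmapped:
            raise ValueError(f"read {aln.query_name} is unmapped")
        mismatches: list[int] = []
        if aln.has_tag("MD"):
            for _, rpos, ref_base in aln.get_aligned_pairs(with_seq=True):
                if rpos is not None and ref_base is not None and ref_base.islower():
                    mismatches.append(rpos)
        elif junction_seq is not None:
            qseq = aln.query_sequence or ""
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                if qseq[qpos].upper() != junction_seq[rpos].upper():
                    mismatches.append(rpos)
        else:
            raise ValueError(
                f"read {aln.query_name}: no MD tag and no junction sequence "
                "to re-score against"
            )
        indels: list[tuple[int, int]] = []
        rpos = aln.reference_start
        for op, length in aln.cigartuples or ():
            if op in (0, 7, 8):  # M, =, X
                rpos += length
            elif op == 2:  # D
                indels.append((rpos, rpos + length))
                rpos += length
            elif op == 3:  # N
                rpos += length
            elif op == 1:  # I
                indels.append((rpos, rpos))
        nh = aln.get_tag("NH") if aln.has_tag("NH") else None
        unique = not (aln.is_secondary or aln.is_supplementary)
        if nh is not None:
            unique = unique and nh == 1
        return cls(
            read_id=aln.query_name,
            junction_id=aln.reference_name,
            start_offset=aln.reference_start,
            aligned_length=aln.reference_end - aln.reference_start,
            mapq=aln.mapping_quality,
            mismatch_offsets=tuple(sorted(mismatches)),
            indel_intervals=tuple(indels),
            is_primary=not aln.is_secondary,
            is_unique=unique,
        )


def _indel_touches(interval: tuple[int, int], lo: int, hi: int) -> bool:
    s, e = interval
    if s == e:  # insertion anchored between s-1 and s
        return lo < s < hi
    return s < hi and e > lo


def classify_retention_read(
    alignment: JunctionAlignment,
    window: int = 20,
    min_mapq: int = 30,
    max_mismatch: int = 2,
    junction_length: int = 202,
) -> bool:
    """Decide whether one junction alignment counts as a retention read.

    True iff the read is primary and uniquely mapped with MAPQ >=
    ``min_mapq``, its aligned span fully covers the ``window``-bp region
    centered on the exon-intron switch point, at most ``max_mismatch``
    mismatches fall inside that region, and no indel touches it.
    """
    if window % 2:
        raise ValueError("window must be even")
    center = junction_length // 2
    lo, hi = center - window // 2, center + window // 2
    if not (alignment.is_primary and alignment.is_unique):
        return False
    if alignment.mapq < min_mapq:
        return False
    if alignment.start_offset > lo or alignment.end_offset < hi:
        return False
    window_mm = sum(lo <= m < hi for m in alignment.mismatch_offsets)
    if window_mm > max_mismatch:
        return False
    if any(_indel_touches(iv, lo, hi) for iv in alignment.indel_intervals):
        return False
    return True


def read_junction_alignments(
    sam_path: str, junction_seqs: Mapping[str, str] | None = None
) -> list[JunctionAlignment]:
    """Load mapped records from a round-2 SAM/BAM file.

    Unmapped and malformed records are skipped; the skip count is logged.
    """
    out: list[JunctionAlignment] = []
    skipped = 0
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                skipped += 1
                continue
            seq = junction_seqs.get(aln.reference_name) if junction_seqs else None
            try:
                out.append(JunctionAlignment.from_pysam(aln, seq))
            except ValueError:
                skipped += 1
    if skipped:
        logger.info("%s: skipped %d unmapped/malformed records", sam_path, skipped)
    return out


@dataclass
class RetentionMatrix:
    """Junction x sample retention-read counts plus group labels."""

    counts: pd.DataFrame  # junctions as index, samples as columns, int
    groups: pd.Series  # sample -> {tumor, normal}

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        bad = set(self.groups.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.counts.values < 0).any():
            raise ValueError("retention counts must be non-negative")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


def call_sample_retentions(
    alignments_by_sample: Mapping[str, Iterable[JunctionAlignment]],
    junction_ids: Sequence[str],
    groups: Mapping[str, str],
    window: int = 20,
    min_mapq: int = 30,
    max_mismatch: int = 2,
    junction_length: int = 202,
) -> RetentionMatrix:
    """Count classifier-passing reads per junction per sample.

    A junction is a per-sample retention event when its count is >= 1
    (no per-sample read minimum beyond existence; see
    :func:`call_group_specific` for the cross-sample rule).
    """
    known = set(junction_ids)
    samples = list(alignments_by_sample)
    counts = pd.DataFrame(
        0, index=pd.Index(junction_ids, name="junction_id"), columns=samples,
        dtype=int,
    )
    for sample, alignments in alignments_by_sample.items():
        for aln in alignments:
            if aln.junction_id not in known:
                raise ValueError(
                    f"sample {sample}: alignment to unknown junction "
                    f"{aln.junction_id!r}"
                )
            if classify_retention_read(
                aln, window=window, min_mapq=min_mapq,
                max_mismatch=max_mismatch, junction_length=junction_length,
            ):
                counts.at[aln.junction_id, sample] += 1
    return RetentionMatrix(counts, pd.Series(dict(groups)))


@dataclass
class GroupSpecificCallSet:
    """TSR/NSR junction calls and the derived gene-level sets.

    ``*_only_genes`` hold genes whose group-specific retentions are all
    from one group, before any expression filter; ``*_only_expressed``
    additionally intersect the expressed-gene filter when one was given;
    ``multi_*_genes`` are the expressed one-group genes with more than one
    retained intron (donor and acceptor calls of the same intron count
    once).
    """

    tsr_junctions: set[str] = field(default_factory=set)
    nsr_junctions: set[str] = field(default_factory=set)
    genes_with_tsr: set[str] = field(default_factory=set)
    genes_with_nsr: set[str] = field(default_factory=set)
    tsr_only_genes: set[str] = field(default_factory=set)
    nsr_only_genes: set[str] = field(default_factory=set)
    tsr_only_expressed: set[str] = field(default_factory=set)
    nsr_only_expressed: set[str] = field(default_factory=set)
    multi_tsr_genes: set[str] = field(default_factory=set)
    multi_nsr_genes: set[str] = field(default_factory=set)

    def validate(self) -> None:
        assert not (self.tsr_junctions & self.nsr_junctions)
        assert not (self.tsr_only_genes & self.nsr_only_genes)
        assert self.multi_tsr_genes <= self.tsr_only_expressed
        assert self.multi_nsr_genes <= self.nsr_only_expressed


def call_group_specific(
    matrix: RetentionMatrix,
    min_support_samples: int = 2,
    min_reads_per_sample: int = 1,
) -> GroupSpecificCallSet:
    """Call TSR/NSR junctions from the retention matrix.

    TSR: >= ``min_support_samples`` tumor samples each contributing >=
    ``min_reads_per_sample`` retention reads AND zero retention reads in
    every normal sample (any normal read disqualifies, whatever the
    per-sample minimum). NSR is symmetric.
    """
    tumor = matrix.samples(TUMOR)
    normal = matrix.samples(NORMAL)
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            "group-specific calling needs >= 2 samples per group "
            f"(got {len(tumor)} tumor, {len(normal)} normal)"
        )
    t = matrix.counts[tumor]
    n = matrix.counts[normal]
    t_support = (t >= min_reads_per_sample).sum(axis=1)
    n_support = (n >= min_reads_per_sample).sum(axis=1)
    t_any = t.sum(axis=1) > 0
    n_any = n.sum(axis=1) > 0
    tsr = matrix.counts.index[(t_support >= min_support_samples) & ~n_any]
    nsr = matrix.counts.index[(n_support >= min_support_samples) & ~t_any]
    out = GroupSpecificCallSet(tsr_junctions=set(tsr), nsr_junctions=set(nsr))
    out.validate()
    return out


def map_calls_to_genes(
    callset: GroupSpecificCallSet,
    junctions: Sequence[Junction],
    expression_filter: set[str] | None = None,
) -> GroupSpecificCallSet:
    """Populate gene-level sets from the junction-level calls.

    Every called junction must map to exactly one gene. Distinct retained
    introns per gene are counted by intron identity, so a donor and an
    acceptor call on the same intron contribute one retained intron.
    """
    by_id = {j.junction_id: j for j in junctions}
    for jid in callset.tsr_junctions | callset.nsr_junctions:
        if jid not in by_id:
            raise ValueError(f"called junction {jid!r} has no gene mapping")

    def gene_sets(jids: set[str]) -> tuple[set[str], dict[str, set]]:
        genes: set[str] = set()
        introns: dict[str, set] = {}
        for jid in jids:
            j = by_id[jid]
            genes.add(j.gene_id)
            introns.setdefault(j.gene_id, set()).add(j.intron_key)
        return genes, introns

    genes_t, introns_t = gene_sets(callset.tsr_junctions)
    genes_n, introns_n = gene_sets(callset.nsr_junctions)

    tsr_only = genes_t - genes_n
    nsr_only = genes_n - genes_t
    tsr_only_expr = tsr_only & expression_filter if expression_filter is not None else set(tsr_only)
    nsr_only_expr = nsr_only & expression_filter if expression_filter is not None else set(nsr_only)

    out = GroupSpecificCallSet(
        tsr_junctions=set(callset.tsr_junctions),
        nsr_junctions=set(callset.nsr_junctions),
        genes_with_tsr=genes_t,
        genes_with_nsr=genes_n,
        tsr_only_genes=tsr_only,
        nsr_only_genes=nsr_only,
        tsr_only_expressed=tsr_only_expr,
        nsr_only_expressed=nsr_only_expr,
        multi_tsr_genes={g for g in tsr_only_expr if len(introns_t[g]) >= 2},
        multi_nsr_genes={g for g in nsr_only_expr if len(introns_n[g]) >= 2},
    )
    out.validate()
    return out


def summarize_table1(callset: GroupSpecificCallSet) -> pd.DataFrame:
    """Five-row summary of group-specific retention calls per group.

    Rows: group-specific retentions (GSR), genes with GSR, genes whose
    GSRs all come from one group, the same after the expressed-gene
    filter, and the expressed one-group genes with more than one retained
    intron.
    """
    rows = {
        "group_specific_retentions": (
            len(callset.nsr_junctions), len(callset.tsr_junctions)
        ),
        "genes_with_gsr": (
            len(callset.genes_with_nsr), len(callset.genes_with_tsr)
        ),
        "group_specific_genes": (
            len(callset.nsr_only_genes), len(callset.tsr_only_genes)
        ),
        "group_specific_genes_expressed": (
            len(callset.nsr_only_expressed), len(callset.tsr_only_expressed)
        ),
        "group_specific_genes_expressed_multi": (
            len(callset.multi_nsr_genes), len(callset.multi_tsr_genes)
        ),
    }
    return pd.DataFrame(rows, index=[NORMAL, TUMOR]).T
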