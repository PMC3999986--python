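"""Gene models, non-overlapping exon selection, and junction derivation.

The junction library is the backbone of retention detection: every
exon-intron boundary of every retained (non-overlapping) exon is turned
into a 202-bp reference contig — 101 bp of exon plus 101 bp of intron on
the transcript strand — against which round-2 reads are aligned. A read
straddling the middle of such a contig is direct evidence that the intron
was not spliced out.

Coordinates are 0-based half-open internally; GTF input is converted from
1-based inclusive on the way in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

__all__ = [
    "GeneModel",
    "ExonRecord",
    "Junction",
    "load_gene_models",
    "select_nonoverlapping_exons",
    "derive_junctions",
    "write_junction_fasta",
    "read_junction_fasta",
    "write_junction_table",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One transcript of one gene, exons in transcription order.

    ``exons`` are genomic 0-based half-open intervals sorted 5'->3' along
    the transcript: ascending genomic start for ``+`` strand, descending
    for ``-``.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(
                    f"overlapping exons within transcript {self.transcript_id}"
                )

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals in transcription order."""
        genomic = sorted(self.exons)
        ivs = [(e1, s2) for (_, e1), (s2, _) in zip(genomic, genomic[1:])]
        return ivs if self.strand == "+" else ivs[::-1]

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junction_transcript_positions(self) -> list[int]:
        """Transcript coordinate of each exon-exon boundary, transcription order."""
        positions = []
        cum = 0
        for s, e in self.exons[:-1]:
            cum += e - s
            positions.append(cum)
        return positions


@dataclass(frozen=True)
class ExonRecord:
    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    ordinal: int  # 1-based position along the transcript, transcription order


@dataclass
class Junction:
    """One side of one exon-intron boundary with its flanking sequence.

    ``boundary_pos`` is the genomic coordinate of the boundary: for a
    plus-strand donor it is the first intronic base; in general it is the
    half-open split point of the genomic window. ``sequence`` is the
    2*flank window around the boundary written in transcript orientation
    (reverse-complemented for minus strand): donors read exon-then-intron,
    acceptors intron-then-exon, with the switch between offsets
    ``flank - 1`` and ``flank``.
    """

    junction_id: str
    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    boundary_pos: int
    side: str  # donor | acceptor
    intron_index_fwd: int
    intron_index_rev: int
    intron_length: int
    intron_start: int  # genomic interval of the adjoining intron
    intron_end: int
    flank: int
    sequence: str = field(repr=False, default="")

    def __post_init__(self) -> None:
        if self.side not in ("donor", "acceptor"):
            raise ValueError(f"side must be donor or acceptor, got {self.side!r}")
        if self.sequence and len(self.sequence) != 2 * self.flank:
            raise ValueError("sequence length must equal 2 * flank")

    @property
    def intron_key(self) -> tuple[str, int]:
        """Identity of the underlying intron; donor and acceptor share it."""
        return (self.transcript_id, self.intron_index_fwd)


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def load_gene_models(gtf: str | IO[str], genome: Fasta) -> list[GeneModel]:
    """Parse exon features from a GTF (ensembl dialect) into gene models.

    Exons are grouped per transcript, converted to 0-based half-open and
    ordered in transcription order. An exon on an unknown contig or out of
    contig bounds is a hard error naming the record. Single-exon
    transcripts are kept (they simply yield no junctions).
    """
    close = False
    if isinstance(gtf, str):
        gtf = open(gtf)
        close = True
    per_transcript: dict[str, dict] = {}
    try:
        for lineno, line in enumerate(gtf, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"GTF line {lineno}: expected 9 columns")
            contig, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            attr = _parse_gtf_attributes(attrs)
            try:
                gene_id, tx_id = attr["gene_id"], attr["transcript_id"]
            except KeyError as exc:
                raise ValueError(f"GTF line {lineno}: missing {exc} attribute")
            if contig not in genome:
                raise ValueError(
                    f"GTF line {lineno}: unknown contig {contig!r} "
                    f"(transcript {tx_id})"
                )
            start0, end0 = int(start) - 1, int(end)
            contig_len = len(genome[contig])
            if start0 < 0 or end0 > contig_len or start0 >= end0:
                raise ValueError(
                    f"GTF line {lineno}: exon {start}-{end} out of bounds for "
                    f"contig {contig!r} (length {contig_len}, transcript {tx_id})"
                )
            rec = per_transcript.setdefault(
                tx_id,
                {"gene_id": gene_id, "contig": contig, "strand": strand, "exons": []},
            )
            if rec["contig"] != contig or rec["strand"] != strand:
                raise ValueError(
                    f"transcript {tx_id}: exons on multiple contigs/strands"
                )
            rec["exons"].append((start0, end0))
    finally:
        if close:
            gtf.close()

    models = []
    for tx_id, rec in per_transcript.items():
        exons = sorted(rec["exons"])
        if rec["strand"] == "-":
            exons = exons[::-1]
        models.append(
            GeneModel(rec["gene_id"], tx_id, rec["contig"], rec["strand"], exons)
        )
    models.sort(key=lambda m: (m.contig, min(s for s, _ in m.exons), m.transcript_id))
    return models


def select_nonoverlapping_exons(models: Sequence[GeneModel]) -> list[ExonRecord]:
    """Keep exactly the exons that overlap no other exon on the genome.

    Overlap is assessed across all transcripts and genes; both members of
    any intersecting pair (>= 1 shared base) are discarded. Abutting
    half-open intervals do not overlap. Exact duplicate intervals from
    different transcripts also disqualify each other.
    """
    if not models:
        raise ValueError("need at least one gene model")
    records: list[ExonRecord] = []
    for m in models:
        for ordinal, (s, e) in enumerate(m.exons, 1):
            records.append(
                ExonRecord(m.contig, s, e, m.strand, m.gene_id, m.transcript_id, ordinal)
            )
    # sweep per contig: an exon survives iff no other interval intersects it
    keep: list[ExonRecord] = []
    by_contig: dict[str, list[ExonRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig, []).append(r)
    for contig_records in by_contig.values():
        contig_records.sort(key=lambda r: (r.start, r.end))
        n = len(contig_records)
        overlapped = [False] * n
        for i, r in enumerate(contig_records):
            j = i + 1
            while j < n and contig_records[j].start < r.end:
                overlapped[i] = True
                overlapped[j] = True
                j += 1
        keep.extend(r for i, r in enumerate(contig_records) if not overlapped[i])
    keep.sort(key=lambda r: (r.contig, r.start, r.transcript_id, r.ordinal))
    return keep


def derive_junctions(
    exon_set: Sequence[ExonRecord],
    models: Sequence[GeneModel],
    genome: Fasta,
    flank: int = 101,
    sides: str = "both",
) -> list[Junction]:
    """Emit donor/acceptor junctions for every retained exon boundary.

    A retained exon contributes a donor junction at its downstream
    (transcription-order) boundary if an intron follows it, and an
    acceptor junction at its upstream boundary if an intron precedes it.
    The 2*flank sequence is extracted symmetrically around the boundary
    and reverse-complemented for minus-strand transcripts so that the
    exon half always comes first. Boundaries whose window would run off
    the contig are skipped with a warning.

    ``sides`` restricts emission: "both" (default), "donor", "acceptor".
    """
    if flank <= 0:
        raise ValueError("flank must be >= 1")
    if sides not in ("both", "donor", "acceptor"):
        raise ValueError(f"invalid sides {sides!r}")
    retained = {
        (r.transcript_id, r.ordinal): r for r in exon_set
    }
    model_by_tx = {m.transcript_id: m for m in models}

    junctions: list[Junction] = []
    skipped = 0
    for (tx_id, ordinal), exon in sorted(retained.items()):
        model = model_by_tx[tx_id]
        n_introns = model.n_introns
        if n_introns == 0:
            continue
        introns = model.introns()  # transcription order
        contig_len = len(genome[model.contig])

        # (side, intron transcription index 1-based) pairs adjoining this exon
        adjoining = []
        if ordinal <= n_introns:
            adjoining.append(("donor", ordinal))
        if ordinal >= 2:
            adjoining.append(("acceptor", ordinal - 1))
        for side, idx in adjoining:
            if sides != "both" and side != sides:
                continue
            istart, iend = introns[idx - 1]
            if model.strand == "+":
                boundary = istart if side == "donor" else iend
            else:
                boundary = iend if side == "donor" else istart
            lo, hi = boundary - flank, boundary + flank
            if lo < 0 or hi > contig_len:
                skipped += 1
                logger.warning(
                    "skipping junction at %s:%d (%s %s): flank exceeds contig",
                    model.contig, boundary, tx_id, side,
                )
                continue
            seq = str(genome[model.contig][lo:hi])
            if model.strand == "-":
                seq = reverse_complement(seq)
            junction_id = f"{tx_id}|i{idx}|{side}"
            junctions.append(
                Junction(
                    junction_id=junction_id,
                    gene_id=model.gene_id,
                    transcript_id=tx_id,
                    contig=model.contig,
                    strand=model.strand,
                    boundary_pos=boundary,
                    side=side,
                    intron_index_fwd=idx,
                    intron_index_rev=n_introns - idx + 1,
                    intron_length=iend - istart,
                    intron_start=istart,
                    intron_end=iend,
                    flank=flank,
                    sequence=seq.upper(),
                )
            )
    if skipped:
        logger.info("skipped %d junctions with incomplete flanks", skipped)
    junctions.sort(key=lambda j: j.junction_id)
    return junctions


def write_junction_fasta(junctions: Sequence[Junction], path: str) -> None:
    """Write the junction library as FASTA.

    Header: ``junction_id|gene_id|side|intron_index_fwd|intron_length``
    with the junction id itself containing ``|``-separated transcript and
    intron index (round-trippable with :func:`read_junction_fasta`).
    """
    seen: set[str] = set()
    with open(path, "w") as fh:
        for j in junctions:
            if j.junction_id in seen:
                raise ValueError(f"duplicate junction id {j.junction_id!r}")
            seen.add(j.junction_id)
            header = "\t".join(
                [
                    j.junction_id,
                    j.gene_id,
                    j.side,
                    str(j.intron_index_fwd),
                    str(j.intron_index_rev),
                    str(j.intron_length),
                    j.contig,
                    j.strand,
                    str(j.boundary_pos),
                    str(j.intron_start),
                    str(j.intron_end),
                    str(j.flank),
                ]
            )
            fh.write(f">{header}\n")
            for i in range(0, len(j.sequence), 60):
                fh.write(j.sequence[i : i + 60] + "\n")


def read_junction_fasta(path: str) -> list[Junction]:
    """Parse a junction FASTA written by :func:`write_junction_fasta`."""
    junctions = []
    header: list[str] | None = None
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        (jid, gene, side, fwd, rev, ilen, contig, strand, bpos, istart, iend,
         flank) = header
        tx_id = jid.split("|")[0]
        junctions.append(
            Junction(
                junction_id=jid,
                gene_id=gene,
                transcript_id=tx_id,
                contig=contig,
                strand=strand,
                boundary_pos=int(bpos),
                side=side,
                intron_index_fwd=int(fwd),
                intron_index_rev=int(rev),
                intron_length=int(ilen),
                intron_start=int(istart),
                intron_end=int(iend),
                flank=int(flank),
                sequence="".join(seq_parts),
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:].split("\t")
                seq_parts = []
            elif line:
                seq_parts.append(line)
    flush()
    return junctions


def write_junction_table(junctions: Sequence[Junction], path: str) -> None:
    """BED-like TSV of junction boundaries plus ordinal columns."""
    with open(path, "w") as fh:
        fh.write(
            "#contig\tstart\tend\tjunction_id\tintron_length\tstrand"
            "\tgene_id\tside\tintron_index_fwd\tintron_index_rev\n"
        )
        for j in junctions:
            fh.write(
                f"{j.contig}\t{j.boundary_pos - 1}\t{j.boundary_pos}\t"
                f"{j.junction_id}\t{j.intron_length}\t{j.strand}\t"
                f"{j.gene_id}\t{j.side}\t{j.intron_index_fwd}\t"
                f"{j.intron_index_rev}\n"
            )
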