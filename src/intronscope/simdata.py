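"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the study design the pipeline targets: five
tumor/normal pairs of 101-bp Illumina-style reads over multi-exon genes,
with per-intron retention fractions that differ by group, negative-
binomial gene expression with planted fold changes, uniform sequencing
errors, and matched tumor/normal variant calls. Reads are emitted
pre-placed (SAM with correct CIGAR/MD/NM) so no external aligner is
needed; FASTQ is written alongside for optional integration with a real
aligner.

Everything is driven by one integer seed; regeneration with the same
config is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .annotation import (
    GeneModel,
    Junction,
    derive_junctions,
    load_gene_models,
    reverse_complement,
    select_nonoverlapping_exons,
    write_junction_fasta,
)

BASES = np.array(list("ACGT"))

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimReference",
    "CohortSim",
    "simulate_reference",
    "simulate_sample_alignments",
    "simulate_counts",
    "simulate_vcf_pair",
    "simulate_term_map",
]


@dataclass
class SimConfig:
    """Knobs of the generator; defaults are the emulated study design.

    Five tumor and five normal samples of 101-bp reads; intron lengths
    log-normal around a ~1.3-kb median as in human genes; NB expression
    with dispersion 0.1 and ~200 reads per gene per sample; 0.5% uniform
    base error. ``frac_tsr_introns`` of introns retain in tumors at rate
    ``rho_tumor`` (and never in normals); ``frac_nsr_introns`` mirror
    this in normals.
    """

    seed: int = 1
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (120, 300)
    intron_meanlog: float = 7.17  # median ~1300 bp
    intron_sdlog: float = 0.7
    min_intron: int = 60
    read_length: int = 101
    depth_per_gene: float = 200.0
    n_tumor: int = 5
    n_normal: int = 5
    frac_tsr_introns: float = 0.15
    frac_nsr_introns: float = 0.10
    rho_tumor: float = 0.2
    rho_normal: float = 0.2
    frac_de: float = 0.2
    log2_fc: float = 2.0
    nb_dispersion: float = 0.1
    error_rate: float = 0.005
    library_size_factors: dict | None = None
    retention_overrides: dict | None = None  # (tx, idx) -> (rho_t, rho_n)

    def sample_names(self) -> list[str]:
        return [f"T{i+1}" for i in range(self.n_tumor)] + [
            f"N{i+1}" for i in range(self.n_normal)
        ]

    def groups(self) -> dict[str, str]:
        return {
            s: ("tumor" if s.startswith("T") else "normal")
            for s in self.sample_names()
        }


@dataclass
class SimTruth:
    """Everything the generator planted, for recovery tests."""

    rho: dict = field(default_factory=dict)  # junction_id -> {tumor, normal}
    true_tsr_junctions: list = field(default_factory=list)
    true_nsr_junctions: list = field(default_factory=list)
    de_genes: dict = field(default_factory=dict)  # gene -> {direction, log2_fc}
    gene_means: dict = field(default_factory=dict)  # gene -> {sample: mu}
    library_factors: dict = field(default_factory=dict)
    enriched_terms: list = field(default_factory=list)
    true_tsvs: list = field(default_factory=list)  # dicts with contig/pos/alt...

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SimReference:
    genome_path: str
    gtf_path: str
    transcripts_path: str
    junctions_path: str
    models: list[GeneModel]
    junctions: list[Junction]
    transcript_seqs: dict[str, str]

    @property
    def transcript_to_gene(self) -> dict[str, str]:
        return {m.transcript_id: m.gene_id for m in self.models}

    @property
    def transcript_lengths(self) -> dict[str, int]:
        return {t: len(s) for t, s in self.transcript_seqs.items()}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def simulate_reference(config: SimConfig, out_dir: str) -> SimReference:
    """Write genome FASTA, GTF, transcript FASTA, and the junction library.

    Genes are laid out non-overlapping on one contig with 300-bp gaps,
    alternating strands, one transcript per gene; introns are log-normal
    with a floor of ``min_intron``.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    chunks: list[str] = []
    gtf_lines: list[str] = []
    tx_seqs: dict[str, str] = {}
    cursor = 300
    contig = "chr1"
    lo_e, hi_e = config.exons_per_gene
    for i in range(config.n_genes):
        gene_id, tx_id = f"G{i:04d}", f"TX{i:04d}"
        strand = "+" if i % 2 == 0 else "-"
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1,
                                 n_exons)
        intron_lens = np.maximum(
            np.rint(rng.lognormal(config.intron_meanlog, config.intron_sdlog,
                                  n_exons - 1)).astype(int),
            config.min_intron,
        )
        exons = []
        pos = cursor
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        gene_len = pos - cursor
        chunks.append(_random_seq(rng, cursor - sum(len(c) for c in chunks)))
        gene_seq = _random_seq(rng, gene_len)
        chunks.append(gene_seq)
        cursor = pos + 300

        genomic_exons = exons  # ascending
        spliced = "".join(
            gene_seq[s - genomic_exons[0][0]: e - genomic_exons[0][0]]
            for s, e in genomic_exons
        )
        tx_seqs[tx_id] = spliced if strand == "+" else reverse_complement(spliced)
        for s, e in genomic_exons:
            gtf_lines.append(
                f"{contig}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
            )
    genome_seq = "".join(chunks) + _random_seq(rng, 300)

    genome_path = os.path.join(out_dir, "genome.fa")
    with open(genome_path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(genome_seq), 60):
            fh.write(genome_seq[i: i + 60] + "\n")
    if os.path.exists(genome_path + ".fai"):
        os.remove(genome_path + ".fai")
    gtf_path = os.path.join(out_dir, "annotation.gtf")
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")
    tx_path = os.path.join(out_dir, "transcripts.fa")
    with open(tx_path, "w") as fh:
        for tx_id, seq in tx_seqs.items():
            fh.write(f">{tx_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")

    genome = Fasta(genome_path)
    models = load_gene_models(gtf_path, genome)
    exon_set = select_nonoverlapping_exons(models)
    junctions = derive_junctions(exon_set, models, genome, flank=config.read_length)
    junctions_path = os.path.join(out_dir, "junctions.fa")
    write_junction_fasta(junctions, junctions_path)
    return SimReference(
        genome_path, gtf_path, tx_path, junctions_path, models, junctions, tx_seqs
    )


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> tuple[str, list[int]]:
    """Substitute bases uniformly at ``error_rate``; returns (seq, offsets)."""
    if error_rate <= 0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), [int(i) for i in hits]


def _md_tag(ref: str, read: str) -> tuple[str, int]:
    """MD string and NM count for an all-match CIGAR alignment."""
    md = []
    run = 0
    nm = 0
    for r, q in zip(ref, read):
        if r == q:
            run += 1
        else:
            md.append(str(run))
            md.append(r)
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


def _sam_header(ref_names: Sequence[str], ref_lengths: Mapping[str, int]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(ref_lengths[n])} for n in ref_names],
    }


@dataclass
class CohortSim:
    round1_sams: dict[str, str]
    round2_sams: dict[str, str]
    fastqs: dict[str, str]
    truth: SimTruth
    config: SimConfig
    reference: SimReference


def _plant_retention(
    config: SimConfig, reference: SimReference, rng: np.random.Generator
) -> dict[tuple[str, int], tuple[float, float]]:
    """Assign (rho_tumor, rho_normal) to a subset of introns."""
    if config.retention_overrides is not None:
        return {k: tuple(v) for k, v in config.retention_overrides.items()}
    all_introns = sorted(
        {(m.transcript_id, i + 1) for m in reference.models
         for i in range(m.n_introns)}
    )
    rng.shuffle(all_introns)
    n_t = int(round(config.frac_tsr_introns * len(all_introns)))
    n_n = int(round(config.frac_nsr_introns * len(all_introns)))
    plan: dict[tuple[str, int], tuple[float, float]] = {}
    for key in all_introns[:n_t]:
        plan[key] = (config.rho_tumor, 0.0)
    for key in all_introns[n_t: n_t + n_n]:
        plan[key] = (0.0, config.rho_normal)
    return plan


def simulate_sample_alignments(
    config: SimConfig, reference: SimReference, out_dir: str
) -> CohortSim:
    """Emit round-1 (cDNA) and round-2 (junction) SAMs per sample.

    Each gene draws an NB read count per sample; each read retains a
    planted intron of its gene with the group's retention fraction
    (choosing donor or acceptor side evenly) or otherwise samples a
    position on the spliced transcript. All reads carry sequencing errors
    at the configured rate and exact CIGAR/MD/NM tags.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    plan = _plant_retention(config, reference, rng)
    junction_by_key: dict[tuple[str, int], dict[str, Junction]] = {}
    for j in reference.junctions:
        junction_by_key.setdefault(j.intron_key, {})[j.side] = j
    junction_lengths = {
        j.junction_id: len(j.sequence) for j in reference.junctions
    }

    truth = SimTruth()
    for key, (rt, rn) in plan.items():
        for side, j in junction_by_key.get(key, {}).items():
            truth.rho[j.junction_id] = {"tumor": rt, "normal": rn}
            if rt > 0 and rn == 0:
                truth.true_tsr_junctions.append(j.junction_id)
            if rn > 0 and rt == 0:
                truth.true_nsr_junctions.append(j.junction_id)
    truth.true_tsr_junctions.sort()
    truth.true_nsr_junctions.sort()

    genes = [m.gene_id for m in reference.models]
    de_pick = rng.random(len(genes)) < config.frac_de
    de_sign = rng.choice([1, -1], len(genes))
    for g, pick, sign in zip(genes, de_pick, de_sign):
        if pick:
            truth.de_genes[g] = {
                "direction": "up_in_tumor" if sign > 0 else "down_in_tumor",
                "log2_fc": float(sign * config.log2_fc),
            }

    lib = config.library_size_factors or {s: 1.0 for s in config.sample_names()}
    truth.library_factors = dict(lib)
    groups = config.groups()
    r_nb = 1.0 / config.nb_dispersion

    round1, round2, fastqs = {}, {}, {}
    model_by_gene = {m.gene_id: m for m in reference.models}
    for sample in config.sample_names():
        group = groups[sample]
        r1_path = os.path.join(out_dir, f"{sample}.round1.sam")
        r2_path = os.path.join(out_dir, f"{sample}.round2.sam")
        fq_path = os.path.join(out_dir, f"{sample}.fastq")
        tx_names = sorted(reference.transcript_seqs)
        j_names = sorted(junction_lengths)
        with pysam.AlignmentFile(
            r1_path, "wh", header=_sam_header(tx_names, reference.transcript_lengths)
        ) as r1, pysam.AlignmentFile(
            r2_path, "wh", header=_sam_header(j_names, junction_lengths)
        ) as r2, open(fq_path, "w") as fq:
            read_no = 0
            for gene_idx, m in enumerate(reference.models):
                mu = config.depth_per_gene * lib[sample]
                info = truth.de_genes.get(m.gene_id)
                if info and group == "tumor":
                    mu *= 2.0 ** info["log2_fc"]
                n_reads = int(rng.negative_binomial(r_nb, r_nb / (r_nb + mu)))
                truth.gene_means.setdefault(m.gene_id, {})[sample] = float(mu)

                gene_introns = [
                    (key, plan[key][0] if group == "tumor" else plan[key][1])
                    for key in plan
                    if key[0] == m.transcript_id
                ]
                gene_introns = [(k, r) for k, r in gene_introns if r > 0]
                rho_total = sum(r for _, r in gene_introns)
                tx_seq = reference.transcript_seqs[m.transcript_id]
                L = len(tx_seq)
                for _ in range(n_reads):
                    read_no += 1
                    name = f"{sample}.r{read_no}"
                    u = rng.random()
                    if u < rho_total:
                        # retention read on one side of one planted intron
                        acc = 0.0
                        for key, r in gene_introns:
                            acc += r
                            if u < acc:
                                break
                        sides = junction_by_key.get(key, {})
                        side = ("donor", "acceptor")[int(rng.integers(0, 2))]
                        if side not in sides:
                            side = next(iter(sides))
                        j = sides[side]
                        jl = len(j.sequence)
                        center = jl // 2
                        lo = center + 10 - config.read_length
                        hi = center - 10
                        start = int(rng.integers(max(lo, 0),
                                                 min(hi, jl - config.read_length) + 1))
                        ref_piece = j.sequence[start: start + config.read_length]
                        read, _ = _apply_errors(rng, ref_piece, config.error_rate)
                        md, nm = _md_tag(ref_piece, read)
                        _write_sam_read(r2, name, j.junction_id, start, read, md, nm)
                    else:
                        start = int(rng.integers(0, L - config.read_length + 1))
                        ref_piece = tx_seq[start: start + config.read_length]
                        read, _ = _apply_errors(rng, ref_piece, config.error_rate)
                        md, nm = _md_tag(ref_piece, read)
                        _write_sam_read(r1, name, m.transcript_id, start, read, md, nm)
                    fq.write(f"@{name}\n{read}\n+\n{'I' * len(read)}\n")
        round1[sample] = r1_path
        round2[sample] = r2_path
        fastqs[sample] = fq_path
    return CohortSim(round1, round2, fastqs, truth, config, reference)


def _write_sam_read(
    fh: pysam.AlignmentFile, name: str, ref: str, start: int,
    seq: str, md: str, nm: int, mapq: int = 42,
) -> None:
    a = pysam.AlignedSegment(fh.header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = 0
    a.reference_id = fh.header.references.index(ref)
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = f"{len(seq)}M"
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    a.set_tag("MD", md)
    a.set_tag("NM", nm)
    a.set_tag("NH", 1)
    fh.write(a)


def simulate_counts(
    config: SimConfig, n_genes: int | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Pure NB count matrix with planted fold changes and library factors.

    Gene base means are log-normal across genes so expression spans the
    realistic dynamic range; tumor samples multiply in the planted fold
    change. Returns (counts, truth).
    """
    rng = np.random.default_rng(config.seed + 2)
    n = n_genes if n_genes is not None else config.n_genes
    genes = [f"G{i:04d}" for i in range(n)]
    samples = config.sample_names()
    groups = config.groups()
    lib = config.library_size_factors or {s: 1.0 for s in samples}

    base = rng.lognormal(np.log(config.depth_per_gene), 1.0, n)
    de_pick = rng.random(n) < config.frac_de
    de_sign = rng.choice([1, -1], n)
    truth = SimTruth(library_factors=dict(lib))
    for g, pick, sign in zip(genes, de_pick, de_sign):
        if pick:
            truth.de_genes[g] = {
                "direction": "up_in_tumor" if sign > 0 else "down_in_tumor",
                "log2_fc": float(sign * config.log2_fc),
            }
    r_nb = 1.0 / config.nb_dispersion
    data = np.zeros((n, len(samples)), dtype=int)
    for sj, s in enumerate(samples):
        mu = base * lib[s]
        if groups[s] == "tumor":
            fc = np.where(
                de_pick, 2.0 ** (de_sign * config.log2_fc), 1.0
            )
            mu = mu * fc
        data[:, sj] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
        truth.gene_means.update(
            {g: {**truth.gene_means.get(g, {}), s: float(m)}
             for g, m in zip(genes, mu)}
        )
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"),
                          columns=samples)
    return counts, truth


def simulate_vcf_pair(
    config: SimConfig,
    reference: SimReference,
    out_dir: str,
    n_splice_tsv: int = 3,
    n_plain_tsv: int = 3,
) -> tuple[str, str, str, SimTruth]:
    """Plant variants and write tumor/normal VCFs plus a coverage track.

    Plants ``n_splice_tsv`` tumor-specific variants at donor +1 positions
    of junctions, ``n_plain_tsv`` deep-intronic tumor-specific variants,
    one germline variant (present in both VCFs), and one low-support
    tumor variant (2 reads). Returns (tumor_vcf, normal_vcf,
    coverage_tsv, truth).
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed + 3)
    genome = Fasta(reference.genome_path)
    contig = reference.junctions[0].contig
    donors = [j for j in reference.junctions if j.side == "donor"
              and j.intron_length > 120]
    rng.shuffle(donors)

    def alt_for(pos: int) -> tuple[str, str]:
        ref_base = str(genome[contig][pos]).upper()
        alt = next(b for b in "ACGT" if b != ref_base)
        return ref_base, alt

    planted: list[dict] = []
    used: set[int] = set()
    for j in donors[:n_splice_tsv]:
        pos = j.intron_start if j.strand == "+" else j.intron_end - 1
        if pos in used:
            continue
        used.add(pos)
        ref_base, alt = alt_for(pos)
        planted.append(
            {"pos": pos, "ref": ref_base, "alt": alt, "support": 5,
             "kind": "splice", "junction_id": j.junction_id}
        )
    for j in donors[n_splice_tsv: n_splice_tsv + n_plain_tsv]:
        pos = j.intron_start + j.intron_length // 2
        if pos in used:
            continue
        used.add(pos)
        ref_base, alt = alt_for(pos)
        planted.append(
            {"pos": pos, "ref": ref_base, "alt": alt, "support": 5,
             "kind": "plain", "junction_id": None}
        )
    extra = donors[n_splice_tsv + n_plain_tsv: n_splice_tsv + n_plain_tsv + 2]
    germline_pos = extra[0].intron_start + 30
    low_pos = extra[1].intron_start + 30
    g_ref, g_alt = alt_for(germline_pos)
    l_ref, l_alt = alt_for(low_pos)

    header = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n'
        '##INFO=<ID=SRQ,Number=1,Type=Integer,Description='
        '"Alt reads with base quality >= 20">\n'
        f"##contig=<ID={contig}>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )

    def vcf_line(pos: int, ref: str, alt: str, support: int, depth: int = 30) -> str:
        return (f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t60\tPASS\t"
                f"DP={depth};SRQ={support}\n")

    tumor_path = os.path.join(out_dir, "tumor.vcf")
    normal_path = os.path.join(out_dir, "normal.vcf")
    records = sorted(
        planted
        + [{"pos": germline_pos, "ref": g_ref, "alt": g_alt, "support": 8,
            "kind": "germline", "junction_id": None},
           {"pos": low_pos, "ref": l_ref, "alt": l_alt, "support": 2,
            "kind": "low_support", "junction_id": None}],
        key=lambda r: r["pos"],
    )
    with open(tumor_path, "w") as fh:
        fh.write(header)
        for r in records:
            fh.write(vcf_line(r["pos"], r["ref"], r["alt"], r["support"]))
    with open(normal_path, "w") as fh:
        fh.write(header)
        fh.write(vcf_line(germline_pos, g_ref, g_alt, 7))

    cov_path = os.path.join(out_dir, "normal_coverage.tsv")
    with open(cov_path, "w") as fh:
        fh.write(f"{contig}\t0\t{len(genome[contig])}\t30\n")

    truth = SimTruth()
    truth.true_tsvs = [
        {"contig": contig, "pos": r["pos"], "ref": r["ref"], "alt": r["alt"],
         "splice_site": r["kind"] == "splice", "junction_id": r["junction_id"]}
        for r in records if r["kind"] in ("splice", "plain")
    ]
    return tumor_path, normal_path, cov_path, truth


def simulate_retention_calibration(
    config: SimConfig,
    reference: SimReference,
    intron_key: tuple[str, int],
    rho: float,
    n_informative: int,
    out_dir: str,
    seed: int,
) -> tuple[str, str]:
    """Emit junction-informative reads for one intron at a known rate.

    Each of ``n_informative`` reads retains the intron with probability
    ``rho``: retention reads go to one side of the junction (covering the
    classification window), spliced reads to the transcript spanning the
    exon-exon boundary with >= 10 bp on each side. Retention abundance
    estimated from these files should recover ``rho`` up to binomial
    noise. Returns (round1_sam, round2_sam).
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    tx_id, idx = intron_key
    model = next(m for m in reference.models if m.transcript_id == tx_id)
    boundary = model.junction_transcript_positions()[idx - 1]
    sides = {
        j.side: j for j in reference.junctions if j.intron_key == intron_key
    }
    tx_seq = reference.transcript_seqs[tx_id]
    L = len(tx_seq)
    junction_lengths = {j.junction_id: len(j.sequence) for j in reference.junctions}
    r1_path = os.path.join(out_dir, f"calib_{tx_id}_{idx}.round1.sam")
    r2_path = os.path.join(out_dir, f"calib_{tx_id}_{idx}.round2.sam")
    tx_names = sorted(reference.transcript_seqs)
    j_names = sorted(junction_lengths)
    rl = config.read_length
    with pysam.AlignmentFile(
        r1_path, "wh", header=_sam_header(tx_names, reference.transcript_lengths)
    ) as r1, pysam.AlignmentFile(
        r2_path, "wh", header=_sam_header(j_names, junction_lengths)
    ) as r2:
        for i in range(n_informative):
            name = f"calib.r{i}"
            if rng.random() < rho:
                side = ("donor", "acceptor")[int(rng.integers(0, 2))]
                j = sides.get(side) or next(iter(sides.values()))
                jl = len(j.sequence)
                center = jl // 2
                start = int(rng.integers(max(center + 10 - rl, 0),
                                         min(center - 10, jl - rl) + 1))
                ref_piece = j.sequence[start: start + rl]
                read, _ = _apply_errors(rng, ref_piece, config.error_rate)
                md, nm = _md_tag(ref_piece, read)
                _write_sam_read(r2, name, j.junction_id, start, read, md, nm)
            else:
                lo = max(boundary + 10 - rl, 0)
                hi = min(boundary - 10, L - rl)
                start = int(rng.integers(lo, hi + 1))
                ref_piece = tx_seq[start: start + rl]
                read, _ = _apply_errors(rng, ref_piece, config.error_rate)
                md, nm = _md_tag(ref_piece, read)
                _write_sam_read(r1, name, tx_id, start, read, md, nm)
    return r1_path, r2_path


def simulate_term_map(
    rng: np.random.Generator,
    universe: Sequence[str],
    signal_genes: Sequence[str],
    n_terms: int = 30,
    term_size: int = 20,
    signal_fraction: float = 1.0,
) -> tuple[dict[str, tuple[str, set[str]]], str]:
    """Random term -> gene map with one planted enriched term.

    The planted term draws ``signal_fraction`` of its members from
    ``signal_genes`` (all of them by default — a clean positive control;
    at desk-scale universes a diluted term is barely distinguishable from
    the query's base rate); background terms are uniform over the
    universe. Returns (term_map, planted_term_id).
    """
    universe = list(universe)
    signal = [g for g in signal_genes if g in set(universe)]
    term_map: dict[str, tuple[str, set[str]]] = {}
    n_sig = min(int(round(signal_fraction * term_size)), len(signal))
    members = set(rng.choice(signal, n_sig, replace=False))
    others = [g for g in universe if g not in members]
    fill = rng.choice(others, term_size - len(members), replace=False)
    planted = "TERM_PLANTED"
    term_map[planted] = ("planted signal term", members | set(fill))
    for i in range(n_terms - 1):
        genes = set(rng.choice(universe, term_size, replace=False))
        term_map[f"TERM{i:03d}"] = (f"background term {i}", genes)
    return term_map, planted
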