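"""End-to-end orchestration: annotation through reports.

One :class:`RunConfig` drives every stage in sequence — junction library,
retention calling, expression/DE, characterization, enrichment, and
splice-variant filtering — and writes the report bundle: a call summary
table, gene lists, an enrichment table, the gene-list DE report, the
tumor-specific variant table, and a ranked candidate list, each stamped
with a config hash so reruns are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import __version__
from .annotation import (
    derive_junctions,
    load_gene_models,
    select_nonoverlapping_exons,
    write_junction_fasta,
    write_junction_table,
)
from .characterization import (
    FRAME_SHIFT,
    IntronRecord,
    classify_frame,
    compare_intron_sizes,
    gene_frame_class,
    position_distribution,
    frame_group_comparison,
    regulation_abundance_comparison,
    report_gene_list_de,
    retention_expression_trend,
    prioritize_candidates,
)
from .quant_de import (
    count_gene_reads,
    count_spanning_reads,
    de_exact_test,
    filter_expressed,
    retention_abundance,
    tmm_factors,
)
from .retention_calling import (
    call_group_specific,
    call_sample_retentions,
    map_calls_to_genes,
    read_junction_alignments,
    summarize_table1,
)
from .splice_variants import (
    annotate_splice_overlap,
    filter_tumor_specific,
    read_coverage_tsv,
    read_vcf,
)
from .stats_core import read_gmt, term_enrichment

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All paths, thresholds, and toggles for one pipeline run."""

    genome: str
    gtf: str
    sample_sheet: str  # TSV: sample_id, group, round1_sam, round2_sam
    out_dir: str
    transcripts: str | None = None
    term_map: str | None = None  # GMT
    gene_list: str | None = None  # one gene per line
    variant_sets: list[dict] = field(default_factory=list)
    # each: {tumor_vcf, normal_vcf, normal_coverage, patient}
    mapq: int = 30
    window: int = 20
    max_mismatch: int = 2
    min_support: int = 2
    min_reads_per_sample: int = 1
    tpm_threshold: float = 1.0
    alpha: float = 0.05
    flank: int = 101
    read_length: int = 101
    junction_sides: str = "both"
    correlation: str = "pearson"
    abundance_denominator: str = "spanning"  # or "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2:
            raise ValueError("window must be a positive even integer")
        if self.abundance_denominator not in ("spanning", "all"):
            raise ValueError("abundance_denominator must be spanning|all")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _read_sample_sheet(path: str) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "group", "round1_sam", "round2_sam"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return sheet


def _write_tsv(df: pd.DataFrame, path: str, config_hash: str, **kw: Any) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", **kw)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle into ``config.out_dir``.

    Returns a dict of in-memory results keyed by stage; any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.digest()
    bundle: dict[str, Any] = {"config_hash": chash}
    counts_log: dict[str, Any] = {}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    # ---- annotation ----
    name = stage("annotation")
    try:
        genome = Fasta(config.genome)
        models = load_gene_models(config.gtf, genome)
        exon_set = select_nonoverlapping_exons(models)
        junctions = derive_junctions(
            exon_set, models, genome, flank=config.flank,
            sides=config.junction_sides,
        )
        write_junction_fasta(junctions, os.path.join(config.out_dir, "junctions.fa"))
        write_junction_table(junctions, os.path.join(config.out_dir, "junctions.tsv"))
        counts_log[name] = {
            "models": len(models),
            "nonoverlapping_exons": len(exon_set),
            "junctions": len(junctions),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # ---- retention calling ----
    name = stage("retention_calling")
    try:
        sheet = _read_sample_sheet(config.sample_sheet)
        jseqs = {j.junction_id: j.sequence for j in junctions}
        aln_by_sample = {
            row.sample_id: read_junction_alignments(row.round2_sam, jseqs)
            for row in sheet.itertuples()
        }
        groups = dict(zip(sheet.sample_id, sheet.group))
        matrix = call_sample_retentions(
            aln_by_sample,
            [j.junction_id for j in junctions],
            groups,
            window=config.window,
            min_mapq=config.mapq,
            max_mismatch=config.max_mismatch,
            junction_length=2 * config.flank,
        )
        _write_tsv(matrix.counts, os.path.join(config.out_dir, "retention_matrix.tsv"),
                   chash)
        counts_log[name] = {
            "round2_reads": {s: len(a) for s, a in aln_by_sample.items()},
            "retention_reads": {
                s: int(matrix.counts[s].sum()) for s in matrix.counts.columns
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # ---- quantification / DE ----
    name = stage("quant_de")
    try:
        tx_to_gene = {m.transcript_id: m.gene_id for m in models}
        tx_lengths = {m.transcript_id: m.spliced_length() for m in models}
        expr = count_gene_reads(
            dict(zip(sheet.sample_id, sheet.round1_sam)),
            tx_to_gene, tx_lengths, read_length=config.read_length,
        )
        expressed = filter_expressed(expr.tpm, config.tpm_threshold)
        factors = tmm_factors(expr.counts)
        de = de_exact_test(
            expr.counts.loc[sorted(expressed)] if expressed else expr.counts,
            groups, factors, alpha=config.alpha,
        )
        _write_tsv(expr.counts, os.path.join(config.out_dir, "counts.tsv"), chash)
        _write_tsv(expr.tpm, os.path.join(config.out_dir, "tpm.tsv"), chash)
        de_df = pd.DataFrame([dataclasses.asdict(r) for r in de])
        _write_tsv(de_df, os.path.join(config.out_dir, "de_results.tsv"), chash,
                   index=False)
        counts_log[name] = {
            "genes": len(expr.counts), "expressed": len(expressed),
            "degs": int((de_df["adj_p"] < config.alpha).sum()) if len(de_df) else 0,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # ---- group-specific calls ----
    name = stage("group_calls")
    try:
        callset = call_group_specific(
            matrix, config.min_support, config.min_reads_per_sample
        )
        callset = map_calls_to_genes(callset, junctions, expressed)
        table1 = summarize_table1(callset)
        _write_tsv(table1, os.path.join(config.out_dir, "call_summary.tsv"), chash)
        gene_rows = (
            [{"gene_id": g, "class": "TSRG"} for g in sorted(callset.tsr_only_expressed)]
            + [{"gene_id": g, "class": "NSRG"} for g in sorted(callset.nsr_only_expressed)]
        )
        _write_tsv(pd.DataFrame(gene_rows, columns=["gene_id", "class"]),
                   os.path.join(config.out_dir, "gsr_genes.tsv"), chash, index=False)
        counts_log[name] = {
            "tsr": len(callset.tsr_junctions), "nsr": len(callset.nsr_junctions),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # ---- retention abundance ----
    name = stage("retention_abundance")
    try:
        by_id = {j.junction_id: j for j in junctions}
        tumor_samples = [s for s, g in groups.items() if g == "tumor"]
        gene_tsr_junctions: dict[str, list[str]] = {}
        for jid in callset.tsr_junctions:
            j = by_id[jid]
            if j.gene_id in callset.tsr_only_expressed:
                gene_tsr_junctions.setdefault(j.gene_id, []).append(jid)
        # boundary transcript positions per called intron (once per intron)
        model_by_tx = {m.transcript_id: m for m in models}
        span_targets: dict[str, set[int]] = {}
        intron_boundary: dict[tuple[str, int], int] = {}
        for jids in gene_tsr_junctions.values():
            for jid in jids:
                j = by_id[jid]
                positions = model_by_tx[j.transcript_id].junction_transcript_positions()
                pos = positions[j.intron_index_fwd - 1]
                intron_boundary[j.intron_key] = pos
                span_targets.setdefault(j.transcript_id, set()).add(pos)
        spanning: dict[tuple[str, int], int] = {}
        for row in sheet.itertuples():
            if groups[row.sample_id] != "tumor":
                continue
            per = count_spanning_reads(
                row.round1_sam, {t: sorted(p) for t, p in span_targets.items()}
            )
            for k, v in per.items():
                spanning[k] = spanning.get(k, 0) + v
        profiles = {}
        for gene, jids in gene_tsr_junctions.items():
            ret = int(matrix.counts.loc[jids, tumor_samples].to_numpy().sum())
            intron_keys = {by_id[jid].intron_key for jid in jids}
            if config.abundance_denominator == "spanning":
                spl = sum(
                    spanning.get((tx, intron_boundary[(tx, idx)]), 0)
                    for tx, idx in intron_keys
                )
            else:
                spl = int(expr.counts.loc[gene, tumor_samples].sum())
            profiles[gene] = retention_abundance(gene, ret, spl, len(intron_keys))
        prof_df = pd.DataFrame(
            [
                {
                    "gene_id": p.gene_id, "n_junctions": p.n_junctions,
                    "retention_reads": p.retention_reads,
                    "spliced_reads": p.spliced_reads, "R": p.R,
                }
                for p in profiles.values()
            ]
        )
        _write_tsv(prof_df, os.path.join(config.out_dir, "retention_abundance.tsv"),
                   chash, index=False)
        counts_log[name] = {"genes_profiled": len(profiles)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # ---- characterization ----
    name = stage("characterization")
    try:
        tsr_introns = {by_id[jid].intron_key for jid in callset.tsr_junctions}
        nsr_introns = {by_id[jid].intron_key for jid in callset.nsr_junctions}
        intron_records = []
        seen: set[tuple[str, int]] = set()
        for m in models:
            introns = m.introns()
            for idx, (s, e) in enumerate(introns, 1):
                key = (m.transcript_id, idx)
                if key in seen:
                    continue
                seen.add(key)
                if key in tsr_introns:
                    cls = "TSR"
                elif key in nsr_introns:
                    cls = "NSR"
                else:
                    cls = "other"
                intron_records.append(
                    IntronRecord(m.gene_id, e - s, idx, len(introns) - idx + 1, cls)
                )
        sizes = compare_intron_sizes(intron_records)
        pos_t = position_distribution(
            [r for r in intron_records if r.retention_class == "TSR"]
        )
        pos_n = position_distribution(
            [r for r in intron_records if r.retention_class == "NSR"]
        )
        frame_classes = {}
        fs_counts: dict[str, int] = {}
        for gene, jids in gene_tsr_junctions.items():
            lens = {by_id[jid].intron_key: by_id[jid].intron_length for jid in jids}
            frame_classes[gene] = gene_frame_class(list(lens.values()))
            fs_counts[gene] = sum(
                1 for L in lens.values() if classify_frame(L) == FRAME_SHIFT
            )
        mean_tpm = expr.tpm[tumor_samples].mean(axis=1).to_dict()
        frame_cmp = frame_group_comparison(profiles, frame_classes, mean_tpm)
        # per-gene retention counts across tumor samples for the trend
        ret_counts = pd.DataFrame(
            {
                s: {
                    g: int(matrix.counts.loc[jids, s].sum())
                    for g, jids in gene_tsr_junctions.items()
                }
                for s in tumor_samples
            }
        )
        trend = (
            retention_expression_trend(
                ret_counts, expr.tpm, tumor_samples, method=config.correlation
            )
            if len(ret_counts)
            else {"n_genes": 0}
        )
        reg_cmp = regulation_abundance_comparison(profiles, de)
        candidates = prioritize_candidates(fs_counts, de, alpha=config.alpha)
        _write_tsv(candidates, os.path.join(config.out_dir, "candidates.tsv"),
                   chash, index=False)
        if config.gene_list:
            with open(config.gene_list) as fh:
                wanted = [line.strip() for line in fh if line.strip()]
            gl_report = report_gene_list_de(de, wanted)
            _write_tsv(gl_report, os.path.join(config.out_dir, "gene_list_de.tsv"),
                       chash, index=False)
            bundle["gene_list_de"] = gl_report
        bundle.update(
            sizes=sizes, position_tumor=pos_t, position_normal=pos_n,
            frame_comparison=frame_cmp, trend=trend,
            regulation_comparison=reg_cmp, candidates=candidates,
            frame_classes=frame_classes,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # ---- enrichment ----
    name = stage("enrichment")
    try:
        if config.term_map:
            term_map = read_gmt(config.term_map)
            enr = term_enrichment(
                sorted(callset.tsr_only_expressed & expressed),
                sorted(expressed), term_map,
            )
            enr_df = pd.DataFrame([dataclasses.asdict(e) for e in enr])
            _write_tsv(enr_df, os.path.join(config.out_dir, "enrichment.tsv"),
                       chash, index=False)
            bundle["enrichment"] = enr
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # ---- splice variants ----
    name = stage("splice_variants")
    try:
        all_calls = []
        for vs in config.variant_sets:
            tv = read_vcf(vs["tumor_vcf"], vs.get("patient", "tumor"))
            nv = read_vcf(vs["normal_vcf"], vs.get("patient", "normal"))
            cov = read_coverage_tsv(vs["normal_coverage"])
            calls = filter_tumor_specific(tv, nv, cov)
            calls = annotate_splice_overlap(calls, junctions)
            all_calls.extend(calls)
        tsv_df = pd.DataFrame(
            [
                {
                    "contig": c.variant.contig, "pos": c.variant.pos,
                    "ref": c.variant.ref, "alt": c.variant.alt,
                    "sample": c.variant.sample_id,
                    "supporting_reads": c.variant.supporting_reads,
                    "normal_depth": c.normal_depth,
                    "splice_site_hit": c.splice_site_hit,
                    "junction_id": c.junction_id or "",
                }
                for c in all_calls
            ],
            columns=["contig", "pos", "ref", "alt", "sample",
                     "supporting_reads", "normal_depth", "splice_site_hit",
                     "junction_id"],
        )
        _write_tsv(tsv_df, os.path.join(config.out_dir, "tumor_specific_variants.tsv"),
                   chash, index=False)
        bundle["tsv_calls"] = all_calls
        counts_log[name] = {
            "tsv_calls": len(all_calls),
            "splice_site_hits": sum(c.splice_site_hit for c in all_calls),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    bundle.update(
        junctions=junctions, matrix=matrix, callset=callset, table1=table1,
        expression=expr, expressed=expressed, factors=factors, de=de,
        profiles=profiles,
    )
    log = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config_hash": chash,
        "stage_counts": counts_log,
    }
    with open(os.path.join(config.out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    bundle["run_log"] = log
    return bundle
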