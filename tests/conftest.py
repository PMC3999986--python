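"""Shared fixtures: tiny hand-built references and simulated cohorts."""

from __future__ import annotations

import os

import pytest
from pyfaidx import Fasta

from intronscope.simdata import (
    SimConfig,
    simulate_reference,
    simulate_sample_alignments,
)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 12-gene, 5v5 cohort at moderate depth, shared across tests."""
    out = str(tmp_path_factory.mktemp("small_cohort"))
    cfg = SimConfig(seed=7, n_genes=12, depth_per_gene=120)
    ref = simulate_reference(cfg, out)
    cohort = simulate_sample_alignments(cfg, ref, out)
    return cohort


@pytest.fixture(scope="session")
def acceptance_cohort(tmp_path_factory):
    """The 5v5, 50-gene, depth-200 cohort used by the recovery suite."""
    out = str(tmp_path_factory.mktemp("acceptance_cohort"))
    cfg = SimConfig(seed=20240301, n_genes=50, depth_per_gene=200)
    ref = simulate_reference(cfg, out)
    cohort = simulate_sample_alignments(cfg, ref, out)
    return cohort


@pytest.fixture()
def toy_genome(tmp_path):
    """A two-contig genome with a deterministic base pattern."""
    path = tmp_path / "toy.fa"
    seq1 = ("ACGT" * 300)[:1100]
    seq2 = ("TTGCA" * 100)[:480]
    with open(path, "w") as fh:
        fh.write(">chrA\n")
        for i in range(0, len(seq1), 60):
            fh.write(seq1[i : i + 60] + "\n")
        fh.write(">chrB\n")
        for i in range(0, len(seq2), 60):
            fh.write(seq2[i : i + 60] + "\n")
    return Fasta(str(path))


def write_gtf(path: str | os.PathLike, rows: list[tuple]) -> str:
    """rows: (contig, start1, end1, strand, gene_id, transcript_id)."""
    with open(path, "w") as fh:
        for contig, start, end, strand, gene, tx in rows:
            fh.write(
                f"{contig}\tsrc\texon\t{start}\t{end}\t.\t{strand}\t.\t"
                f'gene_id "{gene}"; transcript_id "{tx}";\n'
            )
    return str(path)
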