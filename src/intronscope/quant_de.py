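"""Expression quantification, normalization, differential expression, and
per-gene retention abundance.

Quantification is deliberately simple: uniquely mapped primary reads per
transcript, summed per gene (ambiguous multi-mappers are dropped rather
than redistributed). Between-sample normalization is trimmed mean of
M-values (TMM); the two-group test is an exact negative-binomial test
conditioned on the per-gene total with a single method-of-moments common
dispersion, followed by Benjamini-Hochberg adjustment.

Retention abundance for a gene pools its group-specifically retained
junctions: R = retention reads / (retention reads + spliced reads), where
spliced reads are indel-free round-1 cDNA reads spanning the corresponding
exon-exon boundary with at least 10 bp on each side. R is the fraction of
junction-informative transcripts that kept the intron.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from scipy.special import gammaln, logsumexp

from .stats_core import bh_adjust

logger = logging.getLogger(__name__)

UP = "up_in_tumor"
DOWN = "down_in_tumor"
NS = "ns"

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "GeneRetentionProfile",
    "count_gene_reads",
    "count_reads_per_transcript",
    "compute_tpm",
    "effective_lengths",
    "filter_expressed",
    "tmm_factors",
    "de_exact_test",
    "count_spanning_reads",
    "retention_abundance",
]


@dataclass
class ExpressionMatrix:
    counts: pd.DataFrame  # gene x sample, int
    lengths: pd.Series  # gene -> effective length (bp)
    tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.lengths.index)
        if missing:
            raise ValueError(f"genes without lengths: {sorted(missing)[:5]}")

    def with_tpm(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.counts, self.lengths, compute_tpm(self.counts, self.lengths)
        )


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2_fc: float
    p_value: float
    adj_p: float
    direction: str  # up_in_tumor | down_in_tumor | ns


@dataclass
class GeneRetentionProfile:
    """Pooled retention abundance for one gene.

    ``R`` is undefined (NaN, ``defined=False``) when no read of either
    kind covers the gene's retained junctions; such genes are excluded
    from downstream medians.
    """

    gene_id: str
    n_junctions: int
    retention_reads: int
    spliced_reads: int

    @property
    def defined(self) -> bool:
        return self.retention_reads + self.spliced_reads > 0

    @property
    def R(self) -> float:
        denom = self.retention_reads + self.spliced_reads
        if denom == 0:
            return float("nan")
        return self.retention_reads / denom


def effective_lengths(
    transcript_lengths: Mapping[str, int], read_length: int = 101
) -> pd.Series:
    """Effective length = length - read_length + 1, floored at 1."""
    return pd.Series(
        {t: max(int(L) - read_length + 1, 1) for t, L in transcript_lengths.items()}
    )


def count_reads_per_transcript(sam_path: str) -> dict[str, int]:
    """Uniquely mapped primary reads per reference transcript.

    Multi-mapping reads (NH > 1) are counted for nothing.
    """
    counts: dict[str, int] = {}
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.has_tag("NH") and aln.get_tag("NH") > 1:
                continue
            counts[aln.reference_name] = counts.get(aln.reference_name, 0) + 1
    return counts


def count_gene_reads(
    sam_by_sample: Mapping[str, str],
    transcript_to_gene: Mapping[str, str],
    transcript_lengths: Mapping[str, int],
    read_length: int = 101,
) -> ExpressionMatrix:
    """Build the gene x sample count matrix from round-1 cDNA alignments."""
    genes = sorted(set(transcript_to_gene.values()))
    samples = list(sam_by_sample)
    counts = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"),
                          columns=samples, dtype=int)
    for sample, path in sam_by_sample.items():
        for tx, n in count_reads_per_transcript(path).items():
            if tx not in transcript_to_gene:
                raise ValueError(f"transcript {tx!r} has no gene mapping")
            counts.at[transcript_to_gene[tx], sample] += n
    gene_lengths: dict[str, int] = {}
    for tx, g in transcript_to_gene.items():
        L = transcript_lengths[tx]
        gene_lengths[g] = max(gene_lengths.get(g, 0), L)
    lengths = effective_lengths(gene_lengths, read_length)
    return ExpressionMatrix(counts, lengths).with_tpm()


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled to 1e6."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("samples with zero counts: %s", list(counts.columns[zero]))
        totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def filter_expressed(tpm: pd.DataFrame, threshold: float = 1.0) -> set[str]:
    """Genes with TPM strictly above ``threshold`` in every sample."""
    return set(tpm.index[(tpm > threshold).all(axis=1)])


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float
) -> float:
    """One TMM factor (obs vs ref), doubly trimmed precision-weighted mean M."""
    n_obs, n_ref = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs, p_ref = obs / n_obs, ref / n_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[keep], a[keep], w[keep]
    if m.size == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not sel.any():
        return 1.0
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference column is the sample whose 75th count-fraction
    percentile is closest to the cohort mean, unless given explicitly.
    Genes with a zero in either member of a pair are ignored for that
    pair; per-gene log-ratios are trimmed by ``trim_m`` (each side) on M
    and ``trim_a`` on A, and averaged with delta-method precision
    weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError(
            f"all-zero samples: {list(counts.columns[lib == 0])}"
        )
    if ref_sample is None:
        q75 = (counts / lib).quantile(0.75, axis=0)
        ref_sample = (q75 - q75.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(dtype=float)
    factors = {}
    for s in counts.columns:
        if s == ref_sample:
            factors[s] = 1.0
        else:
            factors[s] = _tmm_pair(
                counts[s].to_numpy(dtype=float), ref, trim_m, trim_a
            )
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def _common_dispersion(
    pseudo: np.ndarray, group_idx: Sequence[np.ndarray]
) -> float:
    """Method-of-moments common NB dispersion from within-group residuals."""
    num = 0.0
    den = 0.0
    for idx in group_idx:
        if len(idx) < 2:
            continue
        sub = pseudo[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        ok = m > 0
        num += w * np.sum(v[ok] - m[ok])
        den += w * np.sum(m[ok] ** 2)
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def _exact_conditional_p(s1: int, t: int, a1: float, a2: float) -> float:
    """Two-sided exact p for S1 = s1 given S1 + S2 = t.

    S_k are sums of NB counts with shape a_k and a shared success
    probability, so the conditional law has the beta-binomial-type pmf
    C(k+a1-1, k) C(t-k+a2-1, t-k) / C(t+a1+a2-1, t), free of the mean.
    Two-sided by doubling the smaller tail, capped at 1.
    """
    if t == 0:
        return 1.0
    ks = np.arange(t + 1)
    logp = (
        gammaln(ks + a1) - gammaln(ks + 1)
        + gammaln(t - ks + a2) - gammaln(t - ks + 1)
    )
    logp -= logsumexp(logp)
    p = np.exp(logp)
    p_low = p[: s1 + 1].sum()
    p_high = p[s1:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def de_exact_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    factors: pd.Series | None = None,
    alpha: float = 0.05,
    dispersion: float | None = None,
    max_support: int = 2_000_000,
) -> list[DEResult]:
    """Two-group exact NB test with common dispersion and BH adjustment.

    Counts are rescaled to a common (geometric-mean) TMM-effective library
    size and rounded; per-gene group sums are then compared with an exact
    conditional test. A degenerate (<= 0) dispersion estimate falls back
    to the Poisson limit — the conditional law becomes binomial — with a
    logged warning. Direction is assigned only to genes significant at
    ``alpha`` after adjustment.
    """
    samples = list(counts.columns)
    glabels = pd.Series({s: groups[s] for s in samples})
    tumor = [s for s in samples if glabels[s] == "tumor"]
    normal = [s for s in samples if glabels[s] == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("need >= 2 samples in each group")
    if factors is None:
        factors = pd.Series(1.0, index=samples)
    lib = counts.sum(axis=0).astype(float) * factors.reindex(samples)
    target = float(np.exp(np.log(lib).mean()))
    scale = target / lib
    pseudo = counts.to_numpy(dtype=float) * scale.to_numpy()

    cols = {s: i for i, s in enumerate(samples)}
    idx_t = np.array([cols[s] for s in tumor])
    idx_n = np.array([cols[s] for s in normal])
    if dispersion is None:
        dispersion = _common_dispersion(pseudo, [idx_t, idx_n])
    poisson = dispersion <= 1e-8
    if poisson:
        logger.warning("degenerate dispersion estimate; using Poisson exact test")

    s_t = np.rint(pseudo[:, idx_t].sum(axis=1)).astype(np.int64)
    s_n = np.rint(pseudo[:, idx_n].sum(axis=1)).astype(np.int64)
    n1, n2 = len(idx_t), len(idx_n)
    mean_t = pseudo[:, idx_t].mean(axis=1)
    mean_n = pseudo[:, idx_n].mean(axis=1)
    log2fc = np.log2((mean_t + 0.5) / (mean_n + 0.5))

    pvals = np.ones(len(counts.index))
    for i, (s1, s2) in enumerate(zip(s_t, s_n)):
        t = int(s1 + s2)
        if t == 0:
            pvals[i] = 1.0
            continue
        if poisson:
            frac = n1 / (n1 + n2)
            p_low = stats.binom.cdf(s1, t, frac)
            p_high = stats.binom.sf(s1 - 1, t, frac)
            pvals[i] = min(1.0, 2.0 * min(p_low, p_high))
        else:
            if t > max_support:
                raise ValueError(
                    f"gene total {t} exceeds exact-test support cap"
                )
            pvals[i] = _exact_conditional_p(
                int(s1), t, n1 / dispersion, n2 / dispersion
            )

    adj = bh_adjust(pvals)
    results = []
    for gene, fc, p, ap in zip(counts.index, log2fc, pvals, adj):
        if ap < alpha:
            direction = UP if fc > 0 else DOWN
        else:
            direction = NS
        results.append(DEResult(gene, float(fc), float(p), float(ap), direction))
    return results


def count_spanning_reads(
    sam_path: str,
    boundary_positions: Mapping[str, Sequence[int]],
    pad: int = 10,
) -> dict[tuple[str, int], int]:
    """Count indel-free cDNA reads spanning exon-exon boundaries.

    ``boundary_positions`` maps a transcript id to the transcript
    coordinates of its exon-exon boundaries of interest; a read counts
    for a boundary when its aligned span covers ``[pos - pad, pos + pad)``
    and its alignment contains no insertion or deletion.
    """
    out = {
        (tx, pos): 0 for tx, ps in boundary_positions.items() for pos in ps
    }
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            tx = aln.reference_name
            if tx not in boundary_positions:
                continue
            if any(op in (1, 2) for op, _ in aln.cigartuples or ()):
                continue
            start, end = aln.reference_start, aln.reference_end
            for pos in boundary_positions[tx]:
                if start <= pos - pad and end >= pos + pad:
                    out[(tx, pos)] += 1
    return out


def retention_abundance(
    gene_id: str,
    retention_reads: int,
    spliced_reads: int,
    n_junctions: int,
) -> GeneRetentionProfile:
    """Assemble a gene's retention profile; R = ret / (ret + spliced)."""
    if n_junctions < 1:
        raise ValueError(f"{gene_id}: needs >= 1 retained junction")
    if retention_reads < 0 or spliced_reads < 0:
        raise ValueError("read counts must be non-negative")
    profile = GeneRetentionProfile(gene_id, n_junctions, retention_reads, spliced_reads)
    if not profile.defined:
        logger.warning("%s: retention abundance undefined (no covering reads)", gene_id)
    return profile
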