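"""Descriptive analyses of retained introns.

Covers the downstream portraits of the call set: intron size
distributions by retention class, ordinal position of retained introns
along transcripts (forward and reverse order), reading-frame
classification of retained introns and genes, the relationship between
retention and expression, and prioritization of candidate genes with
multiple frame-shift retentions that are over-expressed in tumors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quant_de import DEResult, GeneRetentionProfile, UP, DOWN
from .stats_core import binomial_test, wilcoxon_ranksum

logger = logging.getLogger(__name__)

IN_FRAME = "in_frame"
FRAME_SHIFT = "frame_shift"

__all__ = [
    "IntronRecord",
    "classify_frame",
    "compare_intron_sizes",
    "size_histogram",
    "position_distribution",
    "gene_frame_class",
    "frame_group_comparison",
    "retention_expression_trend",
    "regulation_abundance_comparison",
    "report_gene_list_de",
    "prioritize_candidates",
]


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    intron_length: int
    intron_index_fwd: int
    intron_index_rev: int
    retention_class: str  # TSR | NSR | other

    @property
    def frame(self) -> str:
        return classify_frame(self.intron_length)


def classify_frame(intron_length: int) -> str:
    """An intron whose length is a multiple of 3 preserves the frame."""
    if intron_length < 1:
        raise ValueError("intron length must be >= 1")
    return IN_FRAME if intron_length % 3 == 0 else FRAME_SHIFT


def size_histogram(
    lengths: Sequence[int], bin_width: int = 500, overflow: int = 10_000
) -> pd.Series:
    """Percentage of introns per right-open length bin, overflow pooled.

    Bins are ``[0, w), [w, 2w), ...`` up to ``overflow``; everything at or
    beyond ``overflow`` lands in one final bin.
    """
    lengths = np.asarray(lengths)
    edges = np.arange(0, overflow + bin_width, bin_width)
    counts, _ = np.histogram(lengths[lengths < overflow], bins=edges)
    over = int((lengths >= overflow).sum())
    labels = [f"[{a},{b})" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f">={overflow}")
    pct = 100.0 * np.asarray(list(counts) + [over]) / max(len(lengths), 1)
    return pd.Series(pct, index=labels, name="percent")


def compare_intron_sizes(
    introns: Sequence[IntronRecord],
    bin_width: int = 500,
    overflow: int = 10_000,
) -> dict:
    """Median intron size per retention class, pairwise tests, histograms.

    Compares TSR vs non-retained and NSR vs non-retained with the
    Wilcoxon rank-sum test; a class with no members is skipped with a
    warning.
    """
    by_class: dict[str, list[int]] = {"TSR": [], "NSR": [], "other": []}
    for r in introns:
        by_class.setdefault(r.retention_class, []).append(r.intron_length)
    medians = {
        c: float(np.median(v)) if v else float("nan") for c, v in by_class.items()
    }
    tests = {}
    for c in ("TSR", "NSR"):
        if not by_class[c] or not by_class["other"]:
            logger.warning("size comparison skipped for %s: empty class", c)
            continue
        p, _ = wilcoxon_ranksum(by_class[c], by_class["other"])
        tests[f"{c}_vs_other"] = p
    histograms = {
        c: size_histogram(v, bin_width, overflow)
        for c, v in by_class.items() if v
    }
    return {"medians": medians, "wilcoxon_p": tests, "histograms": histograms}


def position_distribution(
    introns: Sequence[IntronRecord], truncate_at: int = 10
) -> pd.DataFrame:
    """Percent of retained introns at each ordinal, forward and reverse.

    Percentages are computed over all retained introns (they sum to 100
    per orientation before display truncation); ordinals beyond
    ``truncate_at`` are pooled into a final ``>truncate_at`` row for
    display.
    """
    fwd = np.array([r.intron_index_fwd for r in introns])
    rev = np.array([r.intron_index_rev for r in introns])
    n = len(introns)
    rows = []
    for k in range(1, truncate_at + 1):
        rows.append(
            {
                "ordinal": str(k),
                "forward_pct": 100.0 * (fwd == k).sum() / max(n, 1),
                "reverse_pct": 100.0 * (rev == k).sum() / max(n, 1),
            }
        )
    rows.append(
        {
            "ordinal": f">{truncate_at}",
            "forward_pct": 100.0 * (fwd > truncate_at).sum() / max(n, 1),
            "reverse_pct": 100.0 * (rev > truncate_at).sum() / max(n, 1),
        }
    )
    return pd.DataFrame(rows).set_index("ordinal")


def gene_frame_class(retained_lengths: Sequence[int]) -> str:
    """Gene-level frame class from its retained introns.

    ``in_frame`` only when every retained intron preserves the frame; a
    single frame-shifting intron makes the gene ``frame_shift``.
    """
    if not retained_lengths:
        raise ValueError("gene has no retained introns")
    classes = {classify_frame(L) for L in retained_lengths}
    return IN_FRAME if classes == {IN_FRAME} else FRAME_SHIFT


def frame_group_comparison(
    profiles: Mapping[str, GeneRetentionProfile],
    frame_classes: Mapping[str, str],
    mean_tpm: Mapping[str, float] | None = None,
) -> dict:
    """Compare retention abundance (and expression) between frame classes.

    Genes are split by their frame class; medians of R and, when TPM is
    supplied, mean expression are compared with the Wilcoxon rank-sum
    test. With fewer than two populated classes the comparison is skipped.
    """
    r_by_class: dict[str, list[float]] = {IN_FRAME: [], FRAME_SHIFT: []}
    tpm_by_class: dict[str, list[float]] = {IN_FRAME: [], FRAME_SHIFT: []}
    for gene, cls in frame_classes.items():
        prof = profiles.get(gene)
        if prof is not None and prof.defined:
            r_by_class[cls].append(prof.R)
        if mean_tpm is not None and gene in mean_tpm:
            tpm_by_class[cls].append(mean_tpm[gene])
    out: dict = {
        "median_R": {
            c: float(np.median(v)) if v else float("nan")
            for c, v in r_by_class.items()
        },
        "mean_tpm": {
            c: float(np.mean(v)) if v else float("nan")
            for c, v in tpm_by_class.items()
        },
    }
    if r_by_class[IN_FRAME] and r_by_class[FRAME_SHIFT]:
        out["wilcoxon_p_R"], _ = wilcoxon_ranksum(
            r_by_class[IN_FRAME], r_by_class[FRAME_SHIFT]
        )
    else:
        logger.warning("frame comparison skipped: a frame class is empty")
    if tpm_by_class[IN_FRAME] and tpm_by_class[FRAME_SHIFT]:
        out["wilcoxon_p_tpm"], _ = wilcoxon_ranksum(
            tpm_by_class[IN_FRAME], tpm_by_class[FRAME_SHIFT]
        )
    return out


def retention_expression_trend(
    retention_counts: pd.DataFrame,
    tpm: pd.DataFrame,
    tumor_samples: Sequence[str],
    min_samples: int = 3,
    method: str = "pearson",
) -> dict:
    """Sign of the per-gene retention-vs-expression correlation in tumors.

    For each gene (rows shared by both tables) the correlation between
    retention read counts and TPM across tumor samples is computed;
    genes with fewer than ``min_samples`` tumor samples or zero variance
    in either variable are excluded. Reports the fraction of genes with a
    positive sign and an exact binomial test against 0.5.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr = sps.pearsonr if method == "pearson" else sps.spearmanr
    genes = [g for g in retention_counts.index if g in tpm.index]
    signs: dict[str, int] = {}
    for g in genes:
        x = retention_counts.loc[g, tumor_samples].to_numpy(dtype=float)
        y = tpm.loc[g, tumor_samples].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_samples:
            continue
        x, y = x[ok], y[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = corr(x, y)[0]
        signs[g] = 0 if r == 0 else (1 if r > 0 else -1)
    n_pos = sum(1 for s in signs.values() if s > 0)
    n_used = len(signs)
    p = binomial_test(n_pos, n_used, 0.5) if n_used else float("nan")
    return {
        "n_genes": n_used,
        "n_positive": n_pos,
        "fraction_positive": n_pos / n_used if n_used else float("nan"),
        "binomial_p": p,
        "signs": signs,
    }


def regulation_abundance_comparison(
    profiles: Mapping[str, GeneRetentionProfile],
    de_results: Sequence[DEResult],
) -> dict:
    """Median retention abundance of up- vs down-regulated retained genes.

    Non-significant genes are excluded; the two classes are compared with
    the Wilcoxon rank-sum test. Skipped with a warning when either class
    is empty.
    """
    r_up, r_down = [], []
    for res in de_results:
        prof = profiles.get(res.gene_id)
        if prof is None or not prof.defined:
            continue
        if res.direction == UP:
            r_up.append(prof.R)
        elif res.direction == DOWN:
            r_down.append(prof.R)
    out: dict = {
        "median_R_up": float(np.median(r_up)) if r_up else float("nan"),
        "median_R_down": float(np.median(r_down)) if r_down else float("nan"),
        "n_up": len(r_up),
        "n_down": len(r_down),
    }
    if r_up and r_down:
        out["wilcoxon_p"], _ = wilcoxon_ranksum(r_up, r_down)
    else:
        logger.warning("regulation comparison skipped: a direction class is empty")
    return out


def report_gene_list_de(
    de_results: Sequence[DEResult], gene_list: Sequence[str]
) -> pd.DataFrame:
    """DE rows restricted to a supplied gene list (one gene per line file).

    The returned frame carries ``n_up``/``n_down`` counts in ``attrs``.
    """
    wanted = set(gene_list)
    rows = [
        {
            "gene_id": r.gene_id,
            "log2_fc": r.log2_fc,
            "p_value": r.p_value,
            "adj_p": r.adj_p,
            "direction": r.direction,
        }
        for r in de_results
        if r.gene_id in wanted
    ]
    df = pd.DataFrame(
        rows, columns=["gene_id", "log2_fc", "p_value", "adj_p", "direction"]
    )
    df.attrs["n_up"] = int((df["direction"] == UP).sum()) if len(df) else 0
    df.attrs["n_down"] = int((df["direction"] == DOWN).sum()) if len(df) else 0
    return df


def prioritize_candidates(
    multi_frameshift_counts: Mapping[str, int],
    de_results: Sequence[DEResult],
    min_frameshift: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank genes with multiple frame-shift retentions that are up in tumor.

    ``multi_frameshift_counts`` maps gene -> number of distinct retained
    frame-shifting introns. A candidate needs >= ``min_frameshift`` such
    introns, direction up-in-tumor, and adjusted p < ``alpha``; output is
    sorted by adjusted p.
    """
    de_by_gene = {r.gene_id: r for r in de_results}
    rows = []
    for gene, n_fs in multi_frameshift_counts.items():
        res = de_by_gene.get(gene)
        if res is None or n_fs < min_frameshift:
            continue
        if res.direction == UP and res.adj_p < alpha:
            rows.append(
                {
                    "gene_id": gene,
                    "n_frameshift_retentions": n_fs,
                    "log2_fc": res.log2_fc,
                    "adj_p": res.adj_p,
                }
            )
    df = pd.DataFrame(
        rows, columns=["gene_id", "n_frameshift_retentions", "log2_fc", "adj_p"]
    )
    return df.sort_values("adj_p").reset_index(drop=True) if len(df) else df
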