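"""quant_de: TPM identities, TMM vs edgeR oracle, exact test, abundance."""

import numpy as np
import pandas as pd
import pysam
import pytest

from intronscope.quant_de import (
    compute_tpm,
    count_gene_reads,
    count_spanning_reads,
    de_exact_test,
    effective_lengths,
    filter_expressed,
    retention_abundance,
    tmm_factors,
)
from intronscope.simdata import SimConfig, simulate_counts


class TestTPM:
    def test_single_gene_gets_the_whole_million(self):
        tpm = compute_tpm(
            pd.DataFrame({"s": [50]}, index=["g"]), pd.Series({"g": 100})
        )
        assert tpm.at["g", "s"] == pytest.approx(1e6)

    def test_length_scaling_two_to_one(self):
        tpm = compute_tpm(
            pd.DataFrame({"s": [100, 100]}, index=["a", "b"]),
            pd.Series({"a": 100, "b": 200}),
        )
        assert tpm.at["a", "s"] / tpm.at["b", "s"] == pytest.approx(2.0)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 500, (40, 6)),
            index=[f"g{i}" for i in range(40)],
        )
        lengths = pd.Series(rng.integers(200, 3000, 40), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6)

    def test_effective_length_floor(self):
        el = effective_lengths({"t": 50}, read_length=101)
        assert el["t"] == 1


class TestFilterExpressed:
    def test_strict_threshold_everywhere(self):
        tpm = pd.DataFrame(
            {"s1": [0.9, 1.0, 5.0], "s2": [2.0, 3.0, 4.0]},
            index=["below", "boundary", "ok"],
        )
        assert filter_expressed(tpm) == {"ok"}


class TestTMM:
    def test_identical_columns_factor_one(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_pure_scaling_recovered_centered(self):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 500, 200)
        counts = pd.DataFrame({"a": base, "b": base * 2, "c": base})
        f = tmm_factors(counts)
        # composition unchanged: factors all ~1 after library-size division
        assert np.allclose(f, 1.0, atol=1e-6)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_geometric_mean_one_on_random_data(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.05, (300, 5)))
        f = tmm_factors(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, rel=1e-12)

    def test_matches_edger_reference_values(self):
        """Frozen oracle: Bioconductor edgeR calcNormFactors on this matrix."""
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(10, 10 / (10 + 200), size=(300, 6))
        counts[:, 2] = rng.negative_binomial(10, 10 / (10 + 600), size=300)
        df = pd.DataFrame(counts, columns=[f"S{i}" for i in range(6)])
        f = tmm_factors(df, ref_sample="S0")
        expected = [0.99769373, 1.00638699, 1.00555657,
                    1.02298187, 0.97795044, 0.99002565]
        assert np.allclose(f.to_numpy(), expected, atol=1e-7)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)


GROUPS = {f"T{i}": "tumor" for i in range(1, 6)} | {
    f"N{i}": "normal" for i in range(1, 6)
}


class TestExactTest:
    def test_all_zero_gene_gets_p_one(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(100, (20, 10)), columns=list(GROUPS)
        )
        counts.iloc[0] = 0
        res = de_exact_test(counts, GROUPS)
        assert res[0].p_value == 1.0
        assert res[0].direction == "ns"

    def test_planted_fold_change_detected_with_direction(self):
        cfg = SimConfig(seed=12, frac_de=0.3, n_genes=200, log2_fc=2.0)
        counts, truth = simulate_counts(cfg)
        res = de_exact_test(counts, cfg.groups(), tmm_factors(counts))
        by = {r.gene_id: r for r in res}
        hits = sum(
            by[g].adj_p < 0.05 and by[g].direction == info["direction"]
            for g, info in truth.de_genes.items()
        )
        assert hits / len(truth.de_genes) >= 0.9

    def test_bh_monotone_in_raw_p(self):
        cfg = SimConfig(seed=13, frac_de=0.2, n_genes=150)
        counts, _ = simulate_counts(cfg)
        res = de_exact_test(counts, cfg.groups())
        df = pd.DataFrame([(r.p_value, r.adj_p) for r in res], columns=["p", "ap"])
        df = df.sort_values("p")
        assert (df["ap"].diff().dropna() >= -1e-12).all()

    def test_small_group_rejected(self):
        counts = pd.DataFrame({"T1": [1], "T2": [2], "N1": [3]})
        with pytest.raises(ValueError):
            de_exact_test(counts, {"T1": "tumor", "T2": "tumor", "N1": "normal"})


class TestRetentionAbundance:
    def test_formula_arithmetic(self):
        p = retention_abundance("g", 5, 95, 1)
        assert p.R == pytest.approx(0.05)

    def test_zero_retention_reads(self):
        assert retention_abundance("g", 0, 40, 1).R == 0.0

    def test_undefined_when_no_reads(self):
        p = retention_abundance("g", 0, 0, 1)
        assert not p.defined and np.isnan(p.R)

    def test_monotone_in_retention_reads(self):
        rs = [retention_abundance("g", k, 50, 1).R for k in range(0, 100, 7)]
        assert all(a < b for a, b in zip(rs, rs[1:]))

    def test_no_junction_rejected(self):
        with pytest.raises(ValueError):
            retention_abundance("g", 1, 1, 0)


def write_sam(path, ref_lengths, reads):
    """reads: (name, ref, start, cigar, nh, secondary)."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": L} for n, L in ref_lengths.items()],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for name, ref, start, cigar, nh, secondary in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = name
            qlen = sum(
                int(n) for n, op in __import__("re").findall(r"(\d+)([MIS=X])", cigar)
            )
            a.query_sequence = "A" * qlen
            a.flag = 256 if secondary else 0
            a.reference_id = list(ref_lengths).index(ref)
            a.reference_start = start
            a.mapping_quality = 42
            a.cigarstring = cigar
            a.set_tag("NH", nh)
            fh.write(a)


class TestReadCounting:
    def test_unique_reads_counted_multimappers_dropped(self, tmp_path):
        sam = str(tmp_path / "s.sam")
        reads = [(f"r{i}", "tx1", 0, "50M", 1, False) for i in range(10)]
        reads += [("mm", "tx1", 0, "50M", 2, False), ("mm", "tx2", 0, "50M", 2, True)]
        write_sam(sam, {"tx1": 500, "tx2": 500}, reads)
        expr = count_gene_reads(
            {"s1": sam}, {"tx1": "gA", "tx2": "gB"}, {"tx1": 500, "tx2": 500},
            read_length=50,
        )
        assert expr.counts.at["gA", "s1"] == 10
        assert expr.counts.at["gB", "s1"] == 0

    def test_spanning_requires_pad_and_no_indel(self, tmp_path):
        sam = str(tmp_path / "s.sam")
        reads = [
            ("ok", "tx1", 85, "50M", 1, False),        # covers [85,135) around 100
            ("exact", "tx1", 90, "20M", 1, False),     # exactly [90,110)
            ("short", "tx1", 95, "10M", 1, False),     # too short
            ("off", "tx1", 91, "50M", 1, False),       # misses left pad by 1
            ("indel", "tx1", 80, "20M2D30M", 1, False),  # spans but has deletion
        ]
        write_sam(sam, {"tx1": 500}, reads)
        counts = count_spanning_reads(sam, {"tx1": [100]}, pad=10)
        assert counts[("tx1", 100)] == 2  # "ok" and "exact"


class TestCalibrationRecovery:
    @pytest.mark.parametrize("rho,depth", [(0.05, 500), (0.2, 500), (0.5, 200)])
    def test_abundance_recovers_planted_fraction(self, small_cohort, tmp_path,
                                                 rho, depth):
        """Mean R over replicate simulations hits the planted retention
        fraction within three Monte-Carlo standard errors."""
        from intronscope.retention_calling import (
            classify_retention_read, read_junction_alignments,
        )
        from intronscope.simdata import simulate_retention_calibration

        ref = small_cohort.reference
        key = ref.junctions[0].intron_key
        jseqs = {j.junction_id: j.sequence for j in ref.junctions}
        tx_id, idx = key
        model = next(m for m in ref.models if m.transcript_id == tx_id)
        pos = model.junction_transcript_positions()[idx - 1]
        n_rep = 5
        estimates = []
        for rep in range(n_rep):
            r1, r2 = simulate_retention_calibration(
                small_cohort.config, ref, key, rho, depth, str(tmp_path),
                seed=101 + rep,
            )
            ret = sum(
                classify_retention_read(a)
                for a in read_junction_alignments(r2, jseqs)
            )
            spl = count_spanning_reads(r1, {tx_id: [pos]})[(tx_id, pos)]
            estimates.append(retention_abundance("g", ret, spl, 1).R)
        se = np.sqrt(rho * (1 - rho) / (depth * n_rep))
        assert abs(np.mean(estimates) - rho) <= 3 * se
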