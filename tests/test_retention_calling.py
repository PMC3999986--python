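"""retention_calling: classifier, counting, and group-specific rules."""

import re

import numpy as np
import pandas as pd
import pytest

from intronscope.retention_calling import (
    GroupSpecificCallSet,
    JunctionAlignment,
    RetentionMatrix,
    call_group_specific,
    call_sample_retentions,
    classify_retention_read,
    map_calls_to_genes,
    summarize_table1,
)


def make_aln(**kw):
    base = dict(
        read_id="r1", junction_id="j1", start_offset=60, aligned_length=101,
        mapq=40, mismatch_offsets=(), indel_intervals=(),
        is_primary=True, is_unique=True,
    )
    base.update(kw)
    return JunctionAlignment(**base)


class TestClassifier:
    def test_clean_spanning_read_passes(self):
        assert classify_retention_read(make_aln())

    def test_mapq_just_below_threshold_fails(self):
        assert not classify_retention_read(make_aln(mapq=29))
        assert classify_retention_read(make_aln(mapq=30))

    def test_partial_window_coverage_fails(self):
        # span [92, 193): starts 1 bp inside the [91, 111) window
        assert not classify_retention_read(make_aln(start_offset=92))
        assert classify_retention_read(make_aln(start_offset=91))
        # right edge: span must reach offset 111
        assert not classify_retention_read(make_aln(start_offset=5, aligned_length=105))
        assert classify_retention_read(make_aln(start_offset=10, aligned_length=101))

    def test_window_mismatch_budget(self):
        assert classify_retention_read(make_aln(mismatch_offsets=(95, 100)))
        assert not classify_retention_read(make_aln(mismatch_offsets=(95, 100, 105)))
        # mismatches outside the window are free
        assert classify_retention_read(
            make_aln(mismatch_offsets=(61, 62, 63, 70, 120, 150))
        )

    def test_non_unique_or_secondary_fails(self):
        assert not classify_retention_read(make_aln(is_unique=False))
        assert not classify_retention_read(make_aln(is_primary=False))

    def test_indel_touching_window_fails(self):
        assert not classify_retention_read(make_aln(indel_intervals=((100, 102),)))
        assert not classify_retention_read(make_aln(indel_intervals=((95, 95),)))
        # deletion strictly outside the window is tolerated
        assert classify_retention_read(make_aln(indel_intervals=((70, 72),)))

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError):
            classify_retention_read(make_aln(), window=21)


# --- independent CIGAR/MD re-checker --------------------------------------

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Z]+)|([A-Z])")
_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


def oracle_check(cigar: str, md: str, start: int, mapq: int, unique: bool,
                 window=20, junction_length=202, max_mismatch=2) -> bool:
    """Re-derive the retention decision from raw CIGAR/MD strings."""
    center = junction_length // 2
    lo, hi = center - window // 2, center + window // 2
    if not unique or mapq < 30:
        return False
    # walk CIGAR for reference span and indel intervals
    rpos = start
    indels = []
    match_blocks = []
    for n, op in _CIGAR_TOKEN.findall(cigar):
        n = int(n)
        if op in "M=X":
            match_blocks.append((rpos, rpos + n))
            rpos += n
        elif op == "D":
            indels.append((rpos, rpos + n))
            rpos += n
        elif op == "N":
            rpos += n
        elif op == "I":
            indels.append((rpos, rpos))
    end = rpos
    if start > lo or end < hi:
        return False
    for s, e in indels:
        if (s == e and lo < s < hi) or (s != e and s < hi and e > lo):
            return False
    # walk MD for mismatch reference offsets (MD skips insertions)
    ref_off = start
    mism = []
    for num, dele, sub in _MD_TOKEN.findall(md):
        if num:
            ref_off += int(num)
        elif dele:
            ref_off += len(dele) - 1
        elif sub:
            mism.append(ref_off)
            ref_off += 1
    return sum(lo <= m < hi for m in mism) <= max_mismatch


def random_record(rng):
    """A random placed read with consistent CIGAR/MD and parsed fields."""
    read_len = 101
    start = int(rng.integers(0, 101))
    n_mm = int(rng.integers(0, 5))
    has_del = rng.random() < 0.25
    has_ins = rng.random() < 0.25
    # build blocks: optional deletion/insertion at random offsets
    del_at = int(rng.integers(10, 90)) if has_del else None
    del_len = int(rng.integers(1, 4)) if has_del else 0
    ins_at = int(rng.integers(10, 90)) if has_ins else None

    # reference consumed: read_len + del_len (insertions consume query only)
    cigar_parts = []
    indels = []
    qpos = 0
    rpos = start
    events = sorted(
        ([("D", del_at)] if has_del else []) + ([("I", ins_at)] if has_ins else [])
    , key=lambda e: e[1])
    last = 0
    ins_len = int(rng.integers(1, 4)) if has_ins else 0
    remaining = read_len - ins_len
    for kind, at in events:
        block = at - last
        if block <= 0:
            continue
        cigar_parts.append(f"{block}M")
        rpos += block
        last = at
        if kind == "D":
            cigar_parts.append(f"{del_len}D")
            indels.append((rpos, rpos + del_len))
            rpos += del_len
        else:
            cigar_parts.append(f"{ins_len}I")
            indels.append((rpos, rpos))
    tail = remaining - last
    cigar_parts.append(f"{tail}M")
    rpos += tail
    cigar = "".join(cigar_parts)
    aligned_length = rpos - start

    # mismatches at random match positions (reference offsets)
    match_offsets = []
    r = start
    for part in re.findall(r"(\d+)([MID])", cigar):
        n, op = int(part[0]), part[1]
        if op == "M":
            match_offsets.extend(range(r, r + n))
            r += n
        elif op == "D":
            r += n
    mism = sorted(
        rng.choice(match_offsets, size=min(n_mm, len(match_offsets)), replace=False)
    ) if n_mm else []

    # MD string: match runs with substitutions and deletions interleaved
    md = []
    run = 0
    mm_set = set(int(m) for m in mism)
    r = start
    for part in re.findall(r"(\d+)([MID])", cigar):
        n, op = int(part[0]), part[1]
        if op == "M":
            for pos in range(r, r + n):
                if pos in mm_set:
                    md.append(str(run))
                    md.append("A")
                    run = 0
                else:
                    run += 1
            r += n
        elif op == "D":
            md.append(str(run))
            md.append("^" + "C" * n)
            run = 0
            r += n
    md.append(str(run))
    mapq = int(rng.integers(0, 61))
    unique = bool(rng.random() < 0.8)
    aln = JunctionAlignment(
        read_id="r", junction_id="j", start_offset=start,
        aligned_length=aligned_length, mapq=mapq,
        mismatch_offsets=tuple(int(m) for m in mism),
        indel_intervals=tuple(indels), is_primary=True, is_unique=unique,
    )
    return aln, cigar, "".join(md), mapq, unique


class TestClassifierOracle:
    def test_randomized_records_agree_with_cigar_md_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(2000):
            aln, cigar, md, mapq, unique = random_record(rng)
            got = classify_retention_read(aln)
            want = oracle_check(cigar, md, aln.start_offset, mapq, unique)
            assert got == want, (cigar, md, aln)


class TestCounting:
    def test_pass_and_fail_reads_counted_correctly(self):
        alns = [make_aln(read_id=f"r{i}") for i in range(3)] + [
            make_aln(read_id="bad1", mapq=10),
            make_aln(read_id="bad2", start_offset=95),
        ]
        m = call_sample_retentions(
            {"T1": alns, "T2": []}, ["j1"], {"T1": "tumor", "T2": "normal"}
        )
        assert m.counts.at["j1", "T1"] == 3
        assert m.counts.at["j1", "T2"] == 0

    def test_unknown_junction_rejected(self):
        with pytest.raises(ValueError, match="zz"):
            call_sample_retentions(
                {"T1": [make_aln(junction_id="zz")]}, ["j1"], {"T1": "tumor"}
            )

    def test_simulated_counts_recover_exactly(self, small_cohort):
        """Classifier-passing read counts equal a direct re-count per SAM."""
        from intronscope.retention_calling import read_junction_alignments

        ref = small_cohort.reference
        jseqs = {j.junction_id: j.sequence for j in ref.junctions}
        sample = "T1"
        alns = read_junction_alignments(small_cohort.round2_sams[sample], jseqs)
        m = call_sample_retentions(
            {sample: alns, "N1": []},
            [j.junction_id for j in ref.junctions],
            {sample: "tumor", "N1": "normal"},
        )
        manual = {}
        for a in alns:
            if classify_retention_read(a):
                manual[a.junction_id] = manual.get(a.junction_id, 0) + 1
        for jid, n in manual.items():
            assert m.counts.at[jid, sample] == n
        assert m.counts[sample].sum() == sum(manual.values())


def matrix_from(rows, groups):
    counts = pd.DataFrame(rows).T
    counts.columns = list(groups)
    return RetentionMatrix(counts, pd.Series(groups))


GROUPS10 = {f"T{i}": "tumor" for i in range(1, 6)} | {
    f"N{i}": "normal" for i in range(1, 6)
}


class TestGroupSpecific:
    def test_two_tumor_samples_no_normal_reads_is_tsr(self):
        m = matrix_from({"j1": [2, 1, 0, 0, 0, 0, 0, 0, 0, 0]}, GROUPS10)
        cs = call_group_specific(m)
        assert cs.tsr_junctions == {"j1"}

    def test_single_sample_support_insufficient(self):
        m = matrix_from({"j1": [5, 0, 0, 0, 0, 0, 0, 0, 0, 0]}, GROUPS10)
        cs = call_group_specific(m)
        assert cs.tsr_junctions == set() and cs.nsr_junctions == set()

    def test_any_normal_read_disqualifies(self):
        m = matrix_from({"j1": [2, 1, 0, 0, 0, 1, 0, 0, 0, 0]}, GROUPS10)
        cs = call_group_specific(m)
        assert cs.tsr_junctions == set()

    def test_min_support_three_on_two_sample_junction(self):
        m = matrix_from({"j1": [2, 1, 0, 0, 0, 0, 0, 0, 0, 0]}, GROUPS10)
        cs = call_group_specific(m, min_support_samples=3)
        assert cs.tsr_junctions == set()

    def test_adding_normal_reads_only_shrinks_tsr(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(0.5, size=(30, 10))
        m = matrix_from(
            {f"j{i}": list(counts[i]) for i in range(30)}, GROUPS10
        )
        before = call_group_specific(m).tsr_junctions
        bumped = m.counts.copy()
        bumped.iloc[:10, 7] += 1  # add reads to a normal sample
        after = call_group_specific(RetentionMatrix(bumped, m.groups)).tsr_junctions
        assert after <= before

    def test_small_group_rejected(self):
        m = matrix_from({"j1": [1, 1, 0]}, {"T1": "tumor", "T2": "tumor", "N1": "normal"})
        with pytest.raises(ValueError, match="2 samples"):
            call_group_specific(m)


class TestGeneMapping:
    def test_mixed_gene_excluded_from_only_sets(self, small_cohort):
        juncs = small_cohort.reference.junctions
        gene = juncs[0].gene_id
        gene_juncs = [j for j in juncs if j.gene_id == gene]
        assert len(gene_juncs) >= 2
        cs = GroupSpecificCallSet(
            tsr_junctions={gene_juncs[0].junction_id},
            nsr_junctions={gene_juncs[1].junction_id},
        )
        out = map_calls_to_genes(cs, juncs)
        assert gene in out.genes_with_tsr and gene in out.genes_with_nsr
        assert gene not in out.tsr_only_genes

    def test_both_sides_of_one_intron_count_once(self, small_cohort):
        juncs = small_cohort.reference.junctions
        key = juncs[0].intron_key
        pair = [j for j in juncs if j.intron_key == key]
        assert len(pair) == 2
        cs = GroupSpecificCallSet(tsr_junctions={j.junction_id for j in pair})
        out = map_calls_to_genes(cs, juncs)
        assert out.multi_tsr_genes == set()  # one intron, two sides
        assert pair[0].gene_id in out.tsr_only_genes

    def test_expression_filter_applies_to_expressed_sets(self, small_cohort):
        juncs = small_cohort.reference.junctions
        j = juncs[0]
        cs = GroupSpecificCallSet(tsr_junctions={j.junction_id})
        out = map_calls_to_genes(cs, juncs, expression_filter=set())
        assert out.tsr_only_genes == {j.gene_id}
        assert out.tsr_only_expressed == set()

    def test_unmapped_junction_rejected(self):
        cs = GroupSpecificCallSet(tsr_junctions={"ghost"})
        with pytest.raises(ValueError, match="ghost"):
            map_calls_to_genes(cs, [])


class TestTable1:
    def test_empty_callset_all_zero(self):
        table = summarize_table1(GroupSpecificCallSet())
        assert (table.values == 0).all()

    def test_rows_monotone_by_subset(self, small_cohort):
        from intronscope.retention_calling import read_junction_alignments

        for cohort in (small_cohort,):
            ref = cohort.reference
            jseqs = {j.junction_id: j.sequence for j in ref.junctions}
            aln = {
                s: read_junction_alignments(p, jseqs)
                for s, p in cohort.round2_sams.items()
            }
            m = call_sample_retentions(
                aln, [j.junction_id for j in ref.junctions], cohort.config.groups()
            )
            cs = map_calls_to_genes(
                call_group_specific(m), ref.junctions
            )
            t = summarize_table1(cs)
            for col in t.columns:
                assert t.loc["group_specific_genes", col] <= t.loc["genes_with_gsr", col]
                assert (
                    t.loc["group_specific_genes_expressed_multi", col]
                    <= t.loc["group_specific_genes_expressed", col]
                    <= t.loc["group_specific_genes", col]
                )
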