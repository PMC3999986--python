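# Methods

## Model and procedure

The pipeline detects intron retention from the mapping geometry of short
reads. Reads are assumed to come in two rounds: round 1 against the
spliced transcriptome (cDNA), round 2 mapping the round-1 leftovers
against a library of exon–intron junction contigs. A read that aligns
across the exon/intron switch point of a junction contig can only come
from a transcript that failed to splice that intron.

**Junction library.** Exons that intersect any other exon (any overlap
≥ 1 bp, across all transcripts and genes, both members of a pair) are
removed so every junction assigns unambiguously to one gene. Each
remaining exon boundary adjoining an intron yields one contig per side:
`flank` bases of exon and `flank` of intron (default 101, matching the
read length), written in transcript orientation. Donor contigs read
exon→intron, acceptors intron→exon; the switch sits at the midpoint, so
the classifier below is side-symmetric. Boundaries whose window would
run off the contig are skipped rather than padded — padded sequence
would be fabricated reference.

**Retention-read classifier.** An alignment to a junction contig counts
as a retention read iff it is primary, uniquely mapped (NH == 1 when the
tag is present), has MAPQ ≥ 30, fully covers the 20-bp window centered
on the switch point, carries ≤ 2 mismatches inside that window, and no
insertion or deletion touches the window. Mismatch positions come from
the MD tag; reads without MD are re-scored against the junction
sequence. The indel rule extends the abundance step's indel exclusion to
calling, for consistency: a gapped alignment across the switch point is
evidence of something other than simple retention.

**Group-specific calls.** A junction is a tumor-specific retention (TSR)
iff ≥ `min_support` (default 2) tumor samples each have ≥
`min_reads_per_sample` (default 1) retention reads and **zero**
retention reads occur in any normal sample; normal-specific (NSR) is the
mirror image. The asymmetric absolute zero is the contamination filter:
genomic DNA or pre-mRNA carry-over in one sample cannot satisfy the
two-sample rule, and contamination across samples would appear in both
groups and void both calls. Consequences: the rule is monotone (adding
normal reads can only shrink the TSR set), and no coverage requirement
is imposed on the normals (a junction not expressed in normals can still
be a TSR; the expression filter below addresses this at the gene level).
A coverage-aware mode is deliberately not the default.

**Gene-level sets.** Genes with ≥ 1 TSR and no NSR are tumor-specific
retention genes (TSRGs), optionally intersected with the expressed set
(TPM > 1 in *every* sample — strict inequality). Donor and acceptor
calls on the same intron count as one retained intron for multiplicity
(a gene is "multi-TSR" only with ≥ 2 distinct retained introns), because
they are two observations of one splicing failure.

**Expression and differential expression.** Gene counts are uniquely
mapped primary reads summed over the gene's transcripts; ambiguous
multi-mappers are dropped rather than redistributed — an intentional
simplification that biases against genes with close paralogs but keeps
counting auditable. Effective length is transcript length − read length
+ 1 (floor 1). TPM follows the standard length-normalized rescaling to
1e6 per sample. Between-sample normalization is TMM with the standard
trims (30% on M, 5% on A) and delta-method precision weights; the
implementation was verified against Bioconductor edgeR's
`calcNormFactors` to 8 decimals on a seeded matrix, and those values are
frozen in the test suite. The two-group test is an exact conditional
negative-binomial test: counts are rescaled to the geometric-mean
TMM-effective library size, per-gene group sums are compared under the
conditional law P(S₁=k | S₁+S₂=t), which for NB sums with shapes a₁ =
n₁/φ, a₂ = n₂/φ is free of the mean. The common dispersion φ is a
method-of-moments estimate pooled over genes from within-group means and
variances; φ ≤ 0 falls back to the Poisson limit, where the conditional
law is binomial. Two-sided p doubles the smaller tail, capped at 1,
followed by Benjamini–Hochberg. Measured behavior at the default
simulation conditions: raw p < 0.05 fraction 0.065 and adjusted fraction
0.0005 over 2,000 null genes; direction + significance recovered for
100% of planted 4-fold changes at n = 5 vs 5, depth 200. The
tumor/normal pairing of patients is ignored (groups treated as
independent), matching the two-group design the test models.

**Retention abundance.** For a gene with called retentions,
R = Σ retention reads / (Σ retention reads + Σ spliced reads), pooled
over the gene's called introns and over tumor samples. Spliced reads are
round-1 cDNA reads that span the corresponding exon–exon boundary with
≥ 10 bp on each side (mirroring the half-window of the retention
classifier) and contain no indel. The denominator choice follows the
junction-spanning reading; `abundance_denominator: all` switches to all
gene-assigned reads for sensitivity analysis. R is undefined (flagged,
excluded from medians) when no read of either kind covers the junctions.

**Frame classification.** A retained intron is in-frame iff its length
≡ 0 (mod 3). A gene is in-frame only if *all* its retained introns are;
one frame-shifting intron makes the gene frame-shift (the conservative
rule; premature stop codons inside in-frame introns are not evaluated —
a known limitation). Candidate prioritization selects genes with ≥ 2
frame-shift retained introns, direction up-in-tumor, adjusted p < 0.05,
ranked by adjusted p.

**Retention–expression trend.** Per gene, the Pearson correlation
(Spearman by flag) between retention read counts and TPM across tumor
samples; genes with < 3 usable samples or zero variance are excluded,
and the fraction of positive signs is tested against 0.5 with an exact
binomial test. With five tumor samples per-gene signs are noisy; the
binomial aggregation is the meaningful statistic, not any single gene.

**Statistics.** Fisher's exact test is two-sided by the probability-mass
convention (one-sided variants available, since enrichment claims are
directional); hypergeometric over-representation is the upper tail
P[X ≥ k]; the rank-sum test uses mid-ranks with tie-corrected variance
and continuity correction, switching to full permutation enumeration for
n ≤ 12; BH is the standard step-up. Factorials are computed in log
space. Term enrichment ("classic" per-term testing, no ontology-graph
decorrelation) takes term → gene maps from GMT or two-column TSV; the
universe is the expressed-gene set.

**Splice variants.** Variant calling is upstream; the module consumes
per-sample VCFs (supporting reads at base quality ≥ 20 from the `SRQ`
INFO field or the alt `AD` component) plus a depth track for the matched
normal. A tumor variant survives with ≥ 3 supporting reads, ≥ 1×
normal coverage at the position, and no normal call there at any allele
frequency — only the matched normal is consulted. The splice "signal"
window defaults to the 2-bp donor/acceptor dinucleotides, computed in
transcription orientation (configurable; there is no canonical wider
definition).

## Synthetic data

The generator emulates the targeted study design: five tumor and five
normal samples, single-end 101-bp reads (the classifier operates per
aligned read, so paired-end adds no tested behavior), multi-exon genes
(2–8 exons, 120–300-bp exons), log-normal intron lengths (meanlog 7.17,
sdlog 0.7 → median ≈ 1.3 kb, floor 60 bp), NB expression with dispersion
0.1 and 200 reads/gene/sample, uniform base-error 0.005, 15% of introns
tumor-retained and 10% normal-retained at retention fraction 0.2, 20% of
genes differentially expressed at 4-fold. Reads are emitted pre-placed
as SAM with exact CIGAR/MD/NM — no aligner runs in tests — and FASTQ is
written alongside for optional real-aligner integration. All randomness
derives from one integer seed; regeneration is byte-identical.

A separate calibration mode emits only junction-informative reads
(retention with probability ρ, else spanning the exon–exon boundary), so
that the retention-abundance estimator's input matches its denominator
definition and R recovers ρ up to binomial noise.

What the simulator does **not** model: alignment ambiguity and mapping
error (reads are placed at their true origin with MAPQ 42), positional
or quality-score error profiles, fragment-length effects, paired-end
constraints, isoform mixtures beyond the retained/spliced dichotomy,
patient-level pairing of tumor and normal, and pre-mRNA/genomic
contamination. Passing recovery tests therefore demonstrates the
correctness of the decision rules and estimators given faithful
alignments — not robustness to aligner artifacts on real data.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; GTF converts at
  the boundary. Abutting exons (shared endpoint only) do not overlap.
- Exon overlap is assessed across genes, not just within; both members
  of any overlapping pair are dropped.
- Both junction sides are emitted per intron by default
  (`junction_sides: donor|acceptor` restricts).
- The exact conditional DE test enumerates the support (capped at 2×10⁶;
  larger totals raise rather than silently approximate). Two-sided by
  tail-doubling. Dispersion is a single common value — per-gene
  dispersions need more replicates than a five-pair design provides.
- Simulation sizes in tests (12–50 genes, depth 100–200, 2,000 null
  genes, 5 replicates per calibration cell) were chosen to make every
  recovery property measurable with Monte-Carlo error far below the
  asserted margins while keeping the suite fast.
- Degenerate inputs degrade loudly: empty strata skip comparisons with a
  warning, undefined R is flagged rather than NaN-propagated, all-zero
  samples are hard errors.

## Known limitations

- No isoform-level quantification; ambiguous reads are discarded, not
  redistributed by EM.
- The classifier requires the junction library flank to match read
  length for full-window coverage to be attainable by a single read.
- Gene-level frame classification ignores stop codons introduced by
  in-frame introns.
- The splice-signal window is the minimal dinucleotide; branch-point or
  polypyrimidine-tract variants are out of scope.
- Retention abundance pools junctions within a gene; per-junction
  abundance is available in the matrix but not summarized.
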