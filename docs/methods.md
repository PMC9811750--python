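# Methods

This note documents the models and procedures implemented in `scimeth`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## The simulator

### Genome and spike-ins

`simulate_genome` draws i.i.d. bases at a configurable GC fraction (default
0.42, a mammalian-like value) for the sample contigs, plus two spike-in
contigs: a 48,502 bp "lambda" contig (fully unmethylated conversion
control) and a 2,686 bp "pUC19" contig (fully CpG-methylated
overconversion control). The spike-ins are *random sequences with the real
lengths*: only their methylation role matters to any downstream computation,
so shipping or downloading the true sequences would add nothing. Random
i.i.d. sequence has no repeats, so alignment to the synthetic genome is
easier than to a real one; the aligner's uniqueness logic is therefore
additionally exercised on constructed multi-mapping cases in the tests.

### Methylomes

`simulate_methylomes` builds per-position methylation probabilities for each
cell type on both strands:

- CpG sites at `baseline_cpg` (default 0.8, a typical somatic global CpG
  level) outside DMRs;
- `n_dmrs` non-overlapping DMRs of `dmr_length` bp, each assigned
  round-robin to one cell type that is hypomethylated there (CpG 0.1) while
  all other types sit at 0.9 — the canonical cell-type DMR structure;
- all CpH sites (CHG + CHH, H ∈ {A,C,T}) at a global `cph_rate`. A scalar
  gives every type the same rate; a per-type sequence models the real
  situation in brain, where neurons carry several-fold more CpH methylation
  than glia. The end-to-end study conditions use per-type rates spread over
  0.5–3% for exactly this reason: 100 kb CpH bins are used as a clustering
  feature space *because* cell types differ in CpH, and a simulator in
  which CpH is identical across types would feed the embedding a feature
  block of pure noise (standardized to the same total variance as the CpG
  block) — measured to degrade cluster recovery substantially;
- lambda probability identically 0; pUC19 CpG probability identically 1
  and 0 elsewhere.

### Fragments and chemistry

Tagmented fragments are drawn uniformly over contigs (weighted by length)
with truncated-normal insert sizes (mean 250, sd 80, floor 30 bp).
Methylation states are sampled **once per fragment** (molecule level), so
the two mates of a pair always agree — as they must, both being copies of
one converted molecule.

The chemistry model has two modes:

- `enzymatic`: each unmethylated C reads as T with probability
  `conversion_rate` (default 0.999) and each methylated C erroneously reads
  as T with `overconversion_rate` (default 0.001–0.002).
- `bisulfite`: additionally,
  - *positional bias*: the non-conversion probability grows linearly with
    fractional position along the converting strand,
    `clip((1−conversion_rate) + slope·pos/L, 0, 1)`, producing the apparent
    5′→3′ rise of methylation that distinguishes bisulfite libraries. The
    linear form is a modelling choice — the phenomenon is reported as a
    monotone rise without a stated functional form — and the slope default
    is illustrative (0 disables it);
  - *survival bias*: candidate fragments are retained with probability
    proportional to `exp(survival_gamma · m)`, `m` being the fragment's
    methylated-cytosine fraction, modelling the over-representation of
    methylated fragments in bisulfite libraries. Rejection sampling uses
    acceptance probability `exp(gamma·(m−1)) = w/w_max` and draws until the
    requested fragment count survives, so the yield is exact and retention
    is proportional to `w`.

Enzymatic mode rejects non-zero bias parameters rather than silently
zeroing them.

### Run emission

Per molecule, one template strand (original-top or original-bottom) is
chosen equiprobably; read 1 is the template's 5′ end, read 2 the reverse
complement of its 3′ end (142 bp each by default, the NovaSeq layout).
Read-through past a short fragment fills with the P7 adapter, then the
linear-primer contaminant, then poly-A. `adapter_contamination_rate` is the
fraction of molecules forced to a sub-read-length insert — the mechanism
that produces adapter read-through — and the truth table records the
adapter onset per read. `polyg_rate` overwrites read 2 with G from a random
position > 60. I1 carries the i7 barcode; I2 is Tn5 (11 bp) + i5 (10 bp
NovaSeq dialect; 9 bp NextSeq selectable). Index errors are uniform
substitutions (no indels — matching Hamming-distance demultiplexing).
`duplication_rate` emits PCR duplicates at the converted-molecule level
(identical sequences, same fragment id). All randomness descends from one
master seed through `numpy.random.SeedSequence.spawn`.

**What the generator does not emulate:** sequencing quality-score error
models, indels, PCR family-size distributions beyond single duplication,
real genomic repeat structure, chimeric molecules, and empty/debris
barcodes inside `emit_run` (debris read-count structure is modelled
separately by `simulate_readcount_mixture`). Passing tests therefore
demonstrate correctness of the algorithms under clean-substitution-free
sequencing, not robustness to base-call errors.

## Demultiplexing

Each of the three indexes is matched independently against its whitelist;
a read pair is assigned iff every index has a unique best hit at Hamming
distance < 3. Ties at the minimum are rejected as ambiguous (cheaper than
risking cross-cell contamination; the original tooling's tie policy is
unknown). N counts as a mismatch against every base (N = N matches, but
whitelists contain no N, so an index with ≥ 3 Ns can never match).
Whitelists generated here enforce pairwise distance ≥ 5 =
2·(max_hamming−1)+1, which makes correction of up to two substitutions
unambiguous *by construction*. Note that three or more substitutions are
not guaranteed to be rejected by any decoder at this pairwise floor — three
errors can move a barcode within correction range of a different entry —
so the rejection guarantee is stated (and tested) for corrupted indexes at
distance ≥ 3 from every whitelist entry, which is the event the threshold
actually controls.

## Trimming

Pass 1 is TrimGalore-style: the longest read suffix matching a prefix of
the Illumina adapter `AGATCGGAAGAGC` with mismatch fraction ≤ 0.1 and
overlap ≥ 3 is removed. Strict idempotence of this pass holds only when
the trimmed read does not itself happen to end in a ≥ 3-base adapter
prefix; on random sequence such coincidences occur (probability ~1/64 per
read) and a second pass legitimately fires again — the behaviour of the
original tool as well.

Pass 2 removes read-through contaminants (the full P7 adapter, the linear
amplification primer, and the i7+poly-A+poly-G artifact) found *anywhere*:
the best occurrence and everything 3′ of it are clipped, up to two rounds.
Full occurrences use exact search with an `edlib` infix-alignment fallback
(edit distance ≤ ⌊0.1·len⌋ — edit distance rather than mismatch-only, a
superset that agrees on the error-free contaminants the generator emits);
partial occurrences running off the read's 3′ end are matched by
suffix-prefix overlap, without which contaminant onsets in the last ~30 bp
of a read escape detection. Reads shorter than 20 bp after trimming are
dropped, and dropping one mate drops the pair to keep streams synchronized.
Read 2 is finally hard-truncated to 60 bp. Contamination shorter than the
3-base stringency floor (1–2 terminal adapter bases) is undetectable in
principle and is left in place.

## Alignment

The reference is held as one global coordinate space (contigs separated by
N runs) with C→T and G→A images and sorted k-mer tables (seed length 12 by
default; the field's tools go as low as 9, and the parameter is exposed).
Each read is tried in four interpretations — as-is and reverse-complemented,
under the original-top (C→T) and original-bottom (G→A) rules — which is
what places both mates of molecules from either strand. Seeds are taken at
the read's start, middle and end; seeds hitting more than 200 loci are
skipped as repetitive. Candidate loci supported by ≥ 2 seeds are verified
first; single-seed candidates are verified only when no locus reaches two
votes (the situation for adapter chimeras, where only one anchored seed
survives).

Verification is against the raw reference under the asymmetric rule: on OT,
read T over reference C is a free conversion while read C over reference T
is a mismatch; symmetrically G/A on OB. A candidate scores +1 per match and
−2 per mismatch. End-to-end placement is accepted within a mismatch budget
of ⌊0.1·L⌋, but the best soft-clipped window (maximum-subarray over the
match profile; minimum window 25 bp, same mismatch fraction) wins whenever
it scores strictly higher — otherwise an untrimmed adapter tail can be
absorbed as in-budget mismatches at a shifted coordinate and corrupt the
methylation calls near read ends. A read is *unique* iff its best score
strictly beats every other candidate across all four interpretations;
multi-mappers are excluded from methylation extraction. Mates pair when on
the same contig and conversion strand with opposite orientations and an
implied insert in [30, 2000].

Deduplication operates on molecules (pairs or singles) keyed by (cell,
contig, leftmost start, conversion strand) — the molecule-level analogue of
start-position duplicate marking. The survivor is the most mismatch-free
copy, ties broken by read id. Pair-level keying is what makes the
deduplicated count equal the number of distinct true fragments.

## Methylation extraction

For each deduplicated molecule, reference-C positions covered under OT
(reference-G under OB, reported on the minus strand) contribute: read C
(resp. G) increments methylated and coverage, read T (resp. A) increments
coverage only, other bases are ignored. Overlapping mate segments count
once, first mate wins. Context and dinucleotide come from the strand-local
reference trinucleotide; cytosines without a defined context (contig edges)
are skipped, and an optional mappability mask restricts callable sites.
Calls are stored sparsely as (site index, methylated, coverage) against a
global site table and written as 8-column CGmap text.

## Cell QC

- Mapping efficiency = molecules aligned / read pairs assigned, per
  barcode; mapped bases = aligned window lengths (clipped bases excluded).
- Conversion efficiency = 100 × (1 − pooled 5mC level) over all lambda
  calls (so efficiency + lambda 5mC% = 100 identically); overconversion
  analogously over pUC19 CpG-context calls. Zero spike-in coverage yields
  "not computable" (None), distinct from 100%.
- Cell selection: barcodes under 100 unique molecules are removed; k-means
  (k = 3, seeded, n_init = 10) clusters the remaining log10 counts (read
  counts are multiplicative, hence the log scale); a normal fit to each
  cluster gives the highest-mean cluster's lower 95% bound
  (mean − 1.96·sd), and every barcode at or above that bound is retained.
  Which cluster is "the real cells" and whether the bound is one- or
  two-sided are interpretation knobs (`cluster_select`, `tail`) — the
  published description underdetermines both; highest-mean and two-sided
  are the defaults. If fewer than k distinct values remain, a single
  normal is fitted (identical counts ⇒ everything retained).
- The read-count mixture generator places debris/low/real populations at
  log10 means 2.0/2.9/3.8 (sd 0.22). The centres put about half of the
  debris barcodes under the 100-read filter while keeping three modes
  above it — the k = 3 clustering step models precisely this trimodal
  structure, so a mixture whose lower mode disappears entirely at the
  filter would leave k-means fitting a fiction.
- M-bias: pooled methylated/coverage per read position (position measured
  from the sequenced read's 5′ end, reverse-complement alignments mapped
  back accordingly) per context, with an equal-variance two-sample t-test
  comparing per-position levels of the first half vs second half of
  positions. Per-position levels are the test units; positions without
  coverage are excluded, and a half with fewer than two covered positions
  makes the test not computable. The retention bias acts on unmethylated
  cytosines, so detection power lives in the CH contexts (~99%
  unmethylated); CpG moves in the same direction but with ~20% of the
  lever arm.

## Feature matrices

All summaries are pooled ratios (Σmethylated/Σcoverage) — never means of
per-site levels — matching count-based extraction and remaining stable at
single-cell coverage. Metagene profiles flank each region (default ± 5 kb),
split the flanked interval into ⌈1/0.03⌉ = 34 fractional bins with edges
⌊i·L/34⌋ (widths differ by ≤ 1 bp and partition the interval exactly;
"equal width with a short last bin" would violate the partition property
for general L), reverse bins on minus-strand regions so bin 1 is always
5′, and pool across regions. Region summaries allow overlapping regions
(calls count in each). Genomic bins tile each contig from 0 in fixed
windows (100 kb default, CpH context default). `filter_and_impute` drops
features observed in < 20% of cells and fills remaining gaps with the
feature's observed mean — deterministic, and adequate for a non-negative
factorization input; iterative imputers would add stochasticity for little
benefit at these missingness levels.

## Cell typing

NMF (k = 12, NNDSVD-a initialization, coordinate descent, max_iter 2000,
tol 1e-9 — deep enough that an exactly rank-k matrix factorizes to < 1e-6
relative error) embeds each feature matrix; the two cell-factor matrices
are each scaled to unit total variance, multiplied by their weights
(default 1:1 — the published weighting is unstated) and concatenated.
t-SNE (perplexity 30, PCA init, seeded) standardizes its input to unit
total variance first: affinities are perplexity-calibrated and hence
scale-free in exact arithmetic, and standardizing makes the embedding
exactly invariant to a common rescaling of the weights instead of
invariant only up to gradient-descent round-off. DBSCAN with ε = 1.3 and
min_samples = 5 (ε is the published value; min_samples is this package's
default, exposed in config) clusters the 2-D embedding; noise cells are
excluded from pseudobulk, annotation, and the reported clustering metrics
— they are unassigned, not misassigned. At ~200 cells the embedding's
nearest-neighbour distances are ~0.5–1.0, which is the scale ε = 1.3
presumes.

Pseudobulk sums methylated/coverage site-wise over cluster members
(conservation is exact by construction). Cluster annotation pools each
annotation set's regions in each cluster's pseudobulk, z-scores each
annotation row across clusters, and labels by method: `lowest-z` (a
cluster takes the set holding its minimum z — hypomethylation marks
identity; ties flagged), `neuron-vs-nonneuron` (lower mean z over the
neuronal vs non-neuronal DMR sets), or `hierarchical` (average-linkage on
z columns with labels propagated from reference sets).

`depth_adjusted_comparison` fits OLS `level ~ group + log10(unique reads)`
per context and reports the group coefficient, its standard error and
two-sided p-value; it requires exactly two groups with ≥ 3 cells each.

## Problem sizes and determinism

The reference end-to-end study is 4 cell types × 50 cells at ~2,500–3,000
fragments per cell on a 2 Mb single-contig genome with 30 DMRs of 2 kb —
enough coverage for per-cell region levels (~3 fragments per region per
cell) while a full simulate-to-annotation run stays in the ten-minute
range on one CPU. Oracle comparisons use a 50 kb genome and 500 reads; the
M-bias null calibration uses 100 seeded runs of 400 fragments and the
detection case 50,000–100,000 fragments; regression calibration uses 500
null replicates at n = 200. Every stochastic step is seeded; repeated runs
with the same seed are bit-identical.

## Known limitations

- No indel handling anywhere (generator, trimmer semantics, aligner); the
  protocols' dominant artifacts are substitutions and read-through.
- The aligner is designed for desk-scale references (seed tables are held
  in memory; candidate verification is per-read Python/numpy); it is not a
  replacement for a production bisulfite mapper on a full mammalian
  genome.
- samtools-style pair-aware duplicate marking is simplified to
  molecule-start keying; orphan-rescue and mate-position subtleties are
  out of scope.
- The k-means cell-selection rule inherits the ambiguity of its published
  description; both interpretation knobs are exposed and defaulted.
- Mean imputation biases NMF factors toward feature means for cells with
  little coverage; at the simulated coverage (> 95% observed) the effect
  is negligible, at much sparser coverage it would not be.
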