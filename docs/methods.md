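# Methods

## Problem setting and model

The pipeline infers competing-endogenous-RNA (ceRNA) relationships from
bulk expression profiles observed across ordered physiological conditions
— canonically the bovine lactation cycle: dry period (≈ −50 d), early
lactation (≈ +10 d) and peak lactation (≈ +60 d), with cows as biological
replicates. The mechanistic model is miRNA sponging: a lncRNA carrying
miRNA response elements (MREs) titrates shared miRNAs away from their
mRNA targets, so lncRNA and mRNA abundances co-vary while the miRNA moves
opposite. Inference proceeds in two statistically distinct steps:

1. **Sharing enrichment.** For a (lncRNA, mRNA) pair, let N be the miRNA
   universe, K the number of miRNAs targeting the lncRNA, n the number
   targeting the mRNA, and c the number shared. Under the null that the
   mRNA's regulators are a uniform draw of n from N, the probability of
   sharing at least c is the upper hypergeometric tail
   P = Σ_{i=c}^{min(K,n)} C(K,i)·C(N−K,n−i)/C(N,n).
   The sum is evaluated in log space (log-gamma binomial coefficients
   combined by log-sum-exp), accurate to ~1e-15 against exact integer
   enumeration (verified over every parameter set with N ≤ 12, and
   against a 10⁵-draw urn simulation for N ≤ 500). Benjamini–Hochberg
   q-values are reported for every scored family of pairs; the retention
   gate defaults to raw P < 0.05, because that is the conventional form of
   the rule, with `cerna_gate="q"` switching the gate to q < α.
2. **Trend consistency.** Direction of change of every network member is
   classified over the pair's period span on log2 condition means:
   up/down when |Δlog2| exceeds `trend_epsilon`, else flat. A pair
   survives only if lncRNA and mRNA move in the same non-flat direction
   and at least one shared miRNA moves opposite. Shared miRNAs moving
   *with* the targets contradict sponging and are removed from the
   pair's shared set, after which c is reduced and P recomputed before
   the verdict. By default K and n keep their original values under this
   re-scoring (the dropped miRNA still targets both members; it merely
   fails the sponge pattern), which guarantees the re-scored P never
   decreases; `rescore="full"` shrinks K and n as well.

The hypergeometric statistic conditions on the node degrees but not on
candidacy: a pair only enters scoring when c ≥ 1, and for sparse tables a
minimal K = n = c = 1 candidate already has P = n/N, which is far below
0.05 whenever the universe is large. The raw-P gate therefore behaves
more like a sharing filter than a calibrated test on sparse inputs; the
package keeps the conventional behaviour and reports q alongside. Null-rate
statements in the test suite are accordingly made over *all*
lncRNA × mRNA pairs (non-candidates carrying P = 1), the denominator for
which super-uniformity of the tail probability actually holds.

### The universe N

The statistic defines N as the total miRNA count of the reference
genome without giving a number. Here N defaults to the number of distinct
miRNAs in the *unrestricted* supplied target table and can be pinned with
`n_total_mirnas`; the value in force is recorded in the run manifest.
Degrees K and n are counted over the differentially expressed miRNAs of
the comparison under scoring (the edge table is restricted to DE features
before pair building), mirroring a construction from DE regulatory pairs.

## Differential expression

Upstream tools for read-level DE testing (Cuffdiff, edgeR) operate on
alignments, which this package does not consume. The built-in stand-in is
a Welch two-sample t-test on log2(abundance + pseudocount) with a
per-group variance floor of 1e-8, so that two identical degenerate groups
give t = 0 and P = 1 rather than NaN. The test is deliberately pluggable:
`de_test(..., external_p=...)` accepts per-feature p-values computed by
any external tool, and the CLI exposes this as a TSV side-channel; the
package's contract is the thresholding logic, not the test itself.

Class gates follow the conventional rules: miRNAs need raw P below
`mirna_p` (0.05), linear |fold change| above `mirna_min_abs_fc` (2.0) and
a miRDeep2 score of at least `mirna_min_score` (1.0); mRNAs and lncRNAs
need BH q below `gene_q` (0.05), corrected within one comparison and one
feature class. Raw P is used for miRNAs as literally stated, with no
correction. A miRNA record without a miRDeep2 score passes the score gate
— the score applies to novel miRNA predictions; known miRBase entries
carry none. "Differentially expressed between at least two periods" is
the union of DE calls over the three pairwise comparisons.

Fold changes are log2((mean_b + pc)/(mean_a + pc)) on linear condition
means with pseudocount pc = 1.0 — standard for FPKM-scale data, and the
antisymmetry under swapping conditions is exact.

## Tunable parameters

| name | default | unit | rationale |
|---|---|---|---|
| `mirna_p` | 0.05 | prob. | conventional miRNA gate |
| `mirna_min_abs_fc` | 2.0 | linear FC | conventional miRNA gate |
| `mirna_min_score` | 1.0 | miRDeep2 score | conventional miRNA gate |
| `gene_q` | 0.05 | prob. | conventional mRNA/lncRNA gate (BH) |
| `lnc_min_len` / `lnc_min_exons` / `lnc_min_cov` | 200 / 2 / 3 | nt / exons / reads | conventional candidate filter |
| `cis_window_bp` | 100000 | bp | conventional cis window, inclusive boundary |
| `trans_min_abs_r` | 0.95 | — | conventional trans gate, strictly greater |
| `cerna_alpha` | 0.05 | prob. | conventional pair gate |
| `trend_epsilon` | 0.25 | log2 | below: "flat"; a quarter-doubling is small against the 2-fold DE gate; the one shared knob of the trend stage |
| `pseudocount` | 1.0 | abundance | log-transform and FC stabilizer |
| `coding_filter` | `all` | — | see below |
| `n_total_mirnas` | table universe | count | see above |

The coding-potential step is stated ambiguously in its source protocol
("predicted … by all of the four tools were filtered out" next to
"transcripts with no coding potential were selected"). Both readings are
implemented: `all` (default) removes only transcripts every tool calls
coding; `any` removes transcripts any tool calls coding. The mode in
force is logged; neither is asserted as the original intent. Transcript
length is the sum of exon lengths (mature length), the convention
coding-potential classifiers use, rather than genomic span.

Other conventions: genomic coordinates are 1-based inclusive throughout;
the cis window is symmetric and therefore strand-agnostic, with interval
gap ≤ window (overlap ⇒ gap 0, boundary inclusive); trans correlation is
Pearson on log2(x + pc) by default (`trans_scale="linear"` restores the
raw scale), with zero-variance profiles yielding no edge.

## The MRE scanner

miRanda/RNAhybrid are external tools; their output tables can be supplied
directly and bypass the scanner. The built-in scanner is an exact 7-mer
seed matcher: a site is a perfect target-sequence match to the reverse
complement of miRNA positions 2–8, no G:U wobble, no free energy, no
conservation. This captures canonical seed pairing only, and will neither
rank sites nor find the non-canonical sites hybridization tools report.
U/T are interchangeable on input; all reported positions are 1-based. The
scanner is verified exactly against a brute-force all-positions substring
search.

## Synthetic data generator

`generate_dataset` emulates a lactation-cycle study design: per-feature baseline
abundances 2^Normal(5, 1.5) (FPKM/TPM scale), replicate values equal to
the condition mean times 2^Normal(0, 0.25) multiplicative noise, three
conditions × three replicates. Planted structure: 20 sponge triplets whose
miRNA follows a random ±3 log2-step pattern over conditions and whose
lncRNA and mRNA follow the exact sign-flip; an additional 5% of each
class receives independent DE patterns (realistic decoys for the DE
stage); miRNA→target background edges are wired with Poisson out-degree
(mean 5). Background edges avoid planted-DE features: a random edge from
a planted miRNA onto another planted-DE feature would manufacture a pair
that genuinely satisfies the sponge pattern in the generated data while
being labelled false against the planted truth, making "precision"
unmeasurable. With this constraint the planted triplets are the
exhaustive set of sponge-consistent signals and recovery metrics are
exact. `generate_null_dataset` disables all planting and wires edges
fully uniformly. `n_decoy_triplets` optionally plants same-trend triplets
(miRNA moving with its targets) that must reach the candidate stage and
die at the trend filter. All randomness flows from a single PCG64
generator; a fixed seed reproduces every output bit-identically.

`generate_sequences` emits mature miRNA sequences and target sequences
consistent with an edge table: seed sites planted for every edge,
pairwise-distinct seed 7-mers, and non-edge sites scrubbed out of the
background by local mutation.

What the generator does **not** emulate: read-count mean–variance
structure (abundances are log-normal, not negative binomial — the
pipeline consumes abundances, not counts), length/GC biases, correlated
replicates, isoform structure, genomic clustering of features beyond a
simple cis placement, and partial or thermodynamically weighted miRNA
sites. Passing recovery tests therefore demonstrates the correctness of
the pipeline's logic and thresholds under its own model assumptions, not
performance on real sequencing data.

## Numerical choices

- Hypergeometric tail in log space; c = 0 short-circuits to exactly 1.
- BH via the standard step-up (statsmodels), cross-checked against an
  independently coded reference to 1e-12; candidate pairs are sorted by
  (lncRNA id, mRNA id) before correction so ties break deterministically.
- Welch variance floor 1e-8 on each group's sample variance.
- Float TSV round-trips are bit-exact (shortest-repr write, exact parse).
- Degenerate inputs: empty edge tables and empty networks are valid and
  produce valid empty outputs; conditions with fewer than two replicates
  are rejected before any statistic is computed.

## Problem sizes used in the shipped checks

The shipped tests and the reproduction script run the full pipeline at
500 mRNAs / 100 lncRNAs / 200 miRNAs over 20 seeds for recovery, 100
seeds of the same scale for null calibration, full hypergeometric
enumeration for N ≤ 12 plus a 10⁵-draw urn simulation for N ≤ 500, and
≥ 100 sequence fixtures for the scanner — sizes chosen so the whole suite
completes in about a minute on a single core while keeping Monte-Carlo
standard errors small relative to every margin tested.

## Known limitations

- The hypergeometric score ignores expression levels entirely; sharing
  is binary. Partial-correlation or conditional-mutual-information ceRNA
  scores are out of scope.
- The candidate definition (c ≥ 1) combined with a raw-P gate is
  anti-conservative on sparse tables (see above); users wanting a
  calibrated screen should use the q gate.
- Trend classification uses point estimates of condition means; with
  three replicates a direction near the epsilon boundary is noisy, and
  epsilon is a single global knob.
- The built-in DE test is a stand-in; for publication-grade DE calls,
  inject external p-values.
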