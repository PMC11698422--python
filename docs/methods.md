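# Methods

## The question and the measurement

Each analysis channel turns a matrix of per-sample observations into a
rooted binary dendrogram; concordance between two channels is measured on
the trees, not the matrices. For two dendrograms sharing `n` leaf labels,
with ranks `r_i` / `s_i` of label `i` in the two left-to-right leaf orders,

    entanglement = sum_i |r_i - s_i|^L  /  sum_i |i - (n + 1 - i)|^L .

The denominator is the statistic's value for an exact reversal, so the range
is [0, 1] regardless of `n` and `L`. The norm exponent `L` defaults to 1.5
(the convention of the R tanglegram ecosystem); it is the single most
consequential free constant and is exposed everywhere (`--L`). Because leaf
order is only defined up to rotations of internal nodes, entanglement is
reported both as observed and after untangling; both numbers are in every
report, since either may be the quantity of interest.

### Untangling

Rotating a node reverses which child block comes first but cannot change
topology. One-sided untangling (optimize tree B against fixed tree A) is
solved *exactly*: the shared leaves of any subtree occupy a contiguous block
of ranks, so with `cost(node, offset)` = minimal displacement sum when the
node's shared leaves occupy ranks `offset+1 …`, the recursion over the two
child orders is a dynamic program with O(n²) states. Two-sided untangling is
solved exactly when the smaller tree has ≤ 10 internal nodes (enumerate its
2^k rotation assignments, solve the other side by the DP — a true global
optimum over all rotation pairs); above that size it alternates exact
one-sided passes until a round yields no improvement (convergence tolerance
1e-12, capped at 25 rounds to rule out cycling). The alternation never
increases entanglement; this is asserted at run time.

## Tree construction

All builders share hand-written agglomerative engines rather than library
ones for one reason: determinism. Among pairs tied on the merge criterion,
the pair whose sorted representative labels (each cluster represented by its
lexicographically smallest leaf) is smallest merges first, and children are
ordered by representative label. R's `hclust` and scipy are input-order
dependent under ties, which matters here because zero-noise simulations are
tie-dense by design. scipy serves as an independent cross-check in the test
suite on tie-free inputs.

Height conventions: UPGMA stores merge distance / 2 (classical ultrametric;
cophenetic distance = 2 × LCA height recovers the merge distance), while
`hclust` with average/complete/ward.D stores the raw criterion, matching R.
ward.D applies the Ward Lance–Williams recurrence to the dissimilarities as
given, without requiring squared-Euclidean input. Newick round trips
preserve topology, heights (1e-9) and leaf order; parsing is delegated to
dendropy, with malformed input reported with a character offset. Non-binary
input trees are rejected unless left-leaning zero-length binarization is
requested.

Per-channel defaults (all config-exposed):

| channel | distance | linkage |
| --- | --- | --- |
| gSNV | 1 − identity-by-state | UPGMA |
| iSNV | depth-gated presence divergence | ward.D |
| gCNV | Euclidean on binned CN | ward.D |
| iCNV | Euclidean on smoothed scores | ward.D |
| transcript | 3-state ML distance on trinarized counts | UPGMA |

The linkage used on the IBS and transcript channels is not canonical in the
field; UPGMA is the default and a flag changes it.

## Channel details

**Trinarization.** Per sample, MED and SD are the median and standard
deviation of all that sample's values; a gene scores −1 iff value < MED −
SD, +1 iff value > MED + SD, 0 otherwise — strict inequalities, so boundary
values score 0. SD uses the n−1 denominator by default (`sd_mode`
records the choice in output metadata; the population variant is available).
The procedure is deliberately scale-agnostic (raw counts, CPM, log
microarray intensities); whether to log-transform first is the caller's
choice. A constant sample degenerates to a median split and warns. The
3-state distance is the ML distance under a symmetric 3-letter model,
d = −(2/3)·ln(1 − (3/2)p) with p the discordant-gene fraction, capped at
d_max = 5.0 where the log diverges (p ≥ 2/3); an uncorrected p-distance is
available for sensitivity analysis.

**SNV channels.** IBS uses pairwise-complete sites (no imputation); a pair
sharing no observed site is an error naming the pair. The RNA divergence is
a deliberate simplification of model-based read-count divergences: a site is
callable at total depth ≥ 3 and variant-present at alt/total ≥ 0.2, and the
divergence is the discordant fraction over mutually callable sites. The
interface takes alt/total count matrices so a likelihood-based estimator can
drop in without touching callers.

**iCNV.** Stages, in order: (1) drop genes with mean count < 0.1; (2)
normalize to the median library size, log2(x+1); (3) subtract the per-gene
reference mean — designated normal samples if given, else all samples; (4)
clamp at ±3 global SD; (5) centred moving average of 101 genes within each
chromosome, truncated at chromosome ends; (6) subtract each sample's median;
(7) zero values below 1.0 × residual SD, then re-centre so the per-sample
median invariant survives thresholding. The window (101) and denoise
threshold are package defaults, not claims of equivalence to any external
tool's unpublished defaults; no HMM state calling is performed — the
smoothed score profile *is* the inferred-CNV signal. Spatial spot counts are
summed within sections ("pseudo-bulking") before profiling.

**Binned gCNV.** Segment tables use 1-based inclusive coordinates. Bins of
1200 bp tile each chromosome from position 1 (half-open internally; the
terminal bin truncates, so a chromosome contributes ceil(length/bin) bins).
A bin takes the CN of the segment containing its midpoint (start + bin/2);
uncovered bins are missing. Calls: deletion at CN ≤ 1.5, amplification at
CN ≥ 2.5, both inclusive, relative to diploid 2 — the only reading of
"thresholds −1.5 / 2.5" consistent with non-negative copy numbers; log-ratio
thresholds can be substituted via config. Bins missing anywhere or called
identically in every sample are dropped; the surviving discordant-call
matrix is clustered (correlation distance, average linkage by default, with
a logged Euclidean fallback when a sample column has zero variance) and
bootstrap support is the fraction of row-resampled replicate trees
containing the same leaf set — plain bootstrap proportions, not multiscale
AU p-values. Correlation distances are rounded at 1e-12 so exact ties remain
ties under the deterministic tie-break.

## The simulator: what it emulates and what it does not

A clone tree is a random rooted binary topology over m clones; branches
carry Poisson numbers of events (floored at 1 in the presets so every clone
is separable in every channel). CNV events gain/lose one copy over a
contiguous run of genes (uniform length within bounds, confined to one
chromosome; CN floored at 0 with a logged clip); SNV events follow infinite
sites, each setting one unused site heterozygous. Trunk rates place shared
events on the root→MRCA edge — essential for tumour-vs-normal regimes,
where tumour units must be mutually closer than to normal tissue. Genes
live on 22 autosomes, evenly split, 10 kb each, back to back, so segment
and annotation files can be emitted.

Observations: single-cell DNA genotypes suffer allelic dropout (het →
random homozygote) and false positives; bulk/spatial units are
purity-weighted clone mixtures with real-valued CN and variants called at
expected dosage ≥ 0.1. RNA counts are negative binomial with mean
base_expr × (CN/2) × libsize and Var = μ + aμ² — dosage coupling is linear
in CN/2, which is the premise under test; per-gene base expression is
log-normal (median 6, σ = 0.6), chosen so that the MED ± SD thresholds are
crossed by a realistic minority of genes under single-copy events. Variant
site depths are Poisson at 30× scaled by host-gene dosage, alt reads
binomial. With *every* noise parameter at zero the observation path is
deterministic (rounded expectations): this is the acceptance backbone in
which all builders must recover the true partition exactly, and it is the
reason exact assertions (entanglement = 0.0, ARI = 1.0) are meaningful.

Study-regime presets: `sidr_like` (30 cells, 3 populations of 10/7/13,
≥ 1 CNV and SNV event per branch, rates 3/40); `bulk_a21_like` (7 bulk
samples, one dominant clone each, purity 0.75); `st_12section_like` (12
sections × 15 spots; 4 tumour sections at purity 0.6 with clone fractions
0.6/0.2/0.2 rotating the dominant clone, 8 near-normal at purity 0.02;
trunk rates 12/60). Every preset records its full parameterization in a
JSON manifest.

What the simulator does **not** emulate: read-level artefacts (alignment,
GC bias, doublets), splicing and transcript-level coverage bias,
allele-specific expression beyond the binomial model, CN-independent
transcriptional programs (a config hook exists for adding dosage-unrelated
expression noise), or real genome geometry. Passing tests therefore show
that the *pipeline logic* recovers planted structure under the stated noise
models — not that any channel would perform equivalently on real tissue.

## Numerical choices and limitations

- Heights and branch lengths are doubles; comparisons at 1e-9 absolute.
- All randomness flows through per-module streams derived from one master
  seed by SHA-256 hashing (< 2^31), so enabling a channel never perturbs
  another channel's draws and every run is reproducible bit-for-bit.
- Dendrogram cuts at k clusters undo the k−1 highest merges, ties resolved
  root-first; with tied heights other readings exist, and partition scores
  are only asserted on regimes where between-group merges dominate.
- The problem sizes in tests and presets (2200 genes, 240 sites, ≤ 30 cells,
  1000 bootstraps) were chosen as the smallest at which every regime's
  signal structure is comfortably expressed; all scale linearly if raised.
- Alternating untangling above the exact-size limit is a heuristic; it is
  guaranteed non-increasing but not globally optimal, and the brute-force
  optimality guarantee is asserted only at ≤ 6 leaves.
- The bootstrap treats bins as exchangeable units; correlated adjacent bins
  (as real segmentation produces) inflate support.
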