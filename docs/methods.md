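# Methods

This note documents the models, defaults and numerical choices behind
`paleometa`, in the order data flows through the package.

## Read simulation (`simdata`)

The simulator emulates an ancient-DNA metagenomic library at desk scale.
Each sample is defined by a `SampleDesign` (default 500,000 ancient +
500,000 modern fragments, 125-bp paired reads, per-base substitution error
rate 0.001) and a community of `SpeciesSpec` taxa. The default ten-sample
design uses microbial fractions (0.7, 0.7, 0.7, 0.5, 0.5, 0.5, 0.4, 0.3,
0.3, 0.3) and a 35-taxon panel of which 18 are ancient and 17 modern;
species names follow taxa commonly reported in ancient microbiome and
contamination-control work, but the genomes and taxon IDs are synthetic.

**Reference genomes** are i.i.d. nucleotide sequences at configurable GC
(default 0.5, microbial genomes 50 kb, host 200 kb). A random 200-kb
sequence has collision-free 31-mers with overwhelming probability, which
is what the unique-k-mer arithmetic tests rely on. Genome streams are
seeded by (genome seed, taxid), independent of iteration order.

**Fragment lengths** are log-normal: exp(Normal(loc, scale)) rounded to
integers and floored at `min_len` = 30 bp (below the k = 31 taxonomic
specificity floor a fragment is uninformative anyway). Ancient defaults
loc = 3.7424069808, scale = 0.2795148843 (median ≈ 42 bp, mean ≈ 44 bp)
reproduce fits to authentic ancient bacterial reads. Modern contaminants
are "moderately fragmented"; no published parameterization exists for
that phrase, so the package fixes loc = 5.0, scale = 0.25 (median
≈ 148 bp), a realistic modern library insert scale that cleanly separates
the read-length criterion without being degenerate.

**Damage** follows the Briggs picture with parameters
(nick_rate = 0.03, overhang_param = 0.4, ds_deam = 0.01, ss_deam = 0.3):

- single-strand overhang lengths at each end are geometric with
  P(j) = p·(1−p)^j, j ≥ 0 — blunt ends allowed;
- C→T at rate `ss_deam` inside the 5′ overhang; G→A at the same rate
  inside the 3′ overhang (the lesion is a C→T on the complementary
  strand);
- C→T at rate `ds_deam` in the double-stranded interior;
- nicks are modelled as an *additional* interior C→T opportunity at rate
  `nick_rate`·`ss_deam`; fragments are never split, which keeps truth
  fragment counts exact.

The analytic consequences used as test oracles: the 5′ C→T rate at
0-based position z is (1−p)^(z+1)·ss + [1−(1−p)^(z+1)]·(ds + (1−ds)·nick·ss)
(≈ 0.188 terminally at defaults), while the 3′ G→A rate is purely
(1−p)^(z+1)·ss because interior deamination only produces C→T.
Per-position events within one end are *correlated* through the shared
overhang length; window-level probabilities (e.g. the damaged-read
fraction) must marginalize over it rather than multiply marginal rates.

**Pools and the host.** The ancient fragment pool draws from
ancient-flagged taxa plus damaged host molecules; the modern pool draws
from modern taxa plus undamaged, modern-length host molecules. Within each
pool the host carries weight (1 − microbial_fraction) and taxa their
Dirichlet-assigned abundances (concentration 5), so a multinomial draw
makes per-pool totals exact (composition conservation). How the host share
splits across pools is not otherwise constrained; this symmetric choice is
the package's own.

**Outputs.** Reads are emitted as 4-line FASTQ (Phred+33, constant quality
"I"), R1 from the molecule's 5′ end and R2 from the reverse complement;
short inserts read through into the adapter (Illumina universal) and then
random fill. Sequencing errors are uniform substitutions applied once per
fragment (both reads inherit them); no indels. The truth SAM records one
alignment per fragment — the full damaged, error-bearing molecule at its
true coordinates, MAPQ 60, CIGAR all-M, NM and MD populated — and serves
as the package's stand-in for external-aligner output feeding the
authentication stage. Reproducibility: one master seed per sample;
per-species substreams are derived from (sample seed, CRC32(sample id),
taxid, pool), so results do not depend on species iteration order.

What the simulator does *not* emulate: real genome homology (no
cross-mapping between taxa, so simulated detection is easier than real
detection), quality-score structure, indels, GC bias, library duplicates.
Passing end-to-end tests therefore demonstrates correctness of the
statistics and the separation power of the score under the stated damage
model — not performance on real libraries.

## Screening (`screening`)

KrakenUniq-dialect reports (9 tab-separated columns: %, reads, taxReads,
kmers, dup, cov, taxID, rank, taxName; taxName indentation preserved) are
read and written losslessly. Candidate filtering keeps rows whose rank is
in `rank_keep` (default {"species"}; add "sequence"/"no rank" when
strain-level assemblies matter) with taxReads ≥ 200 and unique k-mers
≥ 1000. Both comparisons are **inclusive**; the convention is configurable
but fixed here because "at least N" reads naturally as ≥.

`count_unique_kmers_covered` counts distinct reference k-mers whose window
is fully contained in the union of read spans, with touching spans merged:
tiling reads recover every reference k-mer, isolated reads contribute
L − k + 1 windows each, and on a distinct-k-mer reference the count is
additive — 50 isolated 50-bp reads at k = 31 give exactly 50 × 20 = 1000.

Read-length filtering is strict (`length > 31 bp` by default — a literal
reading of "above", configurable). Adapter trimming removes the
rightmost-starting exact match of an adapter prefix (≥ `min_overlap`
bases, internal full occurrence or 3′ suffix overlap) and everything after
it; error-tolerant trimming is deliberately out of scope since the
simulator writes exact adapters.

## Authentication metrics (`authmetrics`)

Internally all coordinates are 0-based half-open; pysam handles the SAM
conversion. Reference bases per alignment come from the MD tag when
present, else from a supplied reference FASTA mapping. Only substitution
columns are tallied (insertions dropped, deletion columns skipped, NM kept
as reported) — the simulator emits no indels and, at aDNA read lengths,
real indels are rare.

- **Depth** = total aligned bases / reference length; **breadth** =
  fraction of positions covered ≥ 1×; **evenness** = local breadth within
  100 equal bins (last bin absorbs the remainder, mirroring windowed
  `samtools depth` post-processing). Breadth equals the bin-size-weighted
  mean of the per-bin values by construction.
- **Deamination profiles** count, per position from each end in molecule
  orientation (reverse-strand records flipped and complemented), C→T
  mismatches among reference-C sites (5′) and G→A among reference-G sites
  (3′), over a 15-position window; frequencies are NaN where no
  informative site exists.
- A read is **damaged** when it has ≥ 1 terminal C→T (5′) or G→A (3′)
  within a 5-bp window — the window is not standardized in damage-pattern
  tooling, so it is a parameter.
- **Edit-distance histograms** cover 0–10 mismatches (≥ 10 pooled), for
  all reads and the damaged subset.
- **Percent identity** = 100·(aligned length − NM)/aligned length, binned
  [80,85), [85,90), [90,95), [95,100]; ANI is summarized as the unweighted
  mean identity over assigned reads.
- **PMD score** is the per-read log-likelihood ratio of a damage model —
  deamination probability p_base + (p_max − p_base)·e^(−λz) at distance z
  from the relevant end — against a null in which every mismatch is a
  sequencing error at rate `err`. Defaults (λ = 0.5, p_max = 0.3,
  p_base = 0.01, err = 0.001) deliberately mirror the simulator's damage
  parameters so parameter recovery is testable end-to-end; they are not a
  restatement of any published tool's constants. Base qualities are not
  used.
- **Assigned-read counts** take primary alignments with MAPQ strictly
  above the threshold; the default `min_mapq = 0` reproduces the
  "uniquely mapped = MAPQ > 0" convention.

## Scoring (`scoring`)

Weights: evenness +2, deamination +1 per end, +1 each for edit distances
(all, damaged), read length, PMD, read count, identity — total 10. The
pass/fail criteria are this package's own calibration (they are commonly
tuned per project in practice):

| component | default criterion |
|---|---|
| deam5 / deam3 | terminal rate ≥ 0.05, ≥ 2× interior baseline (positions 8–12), ≥ 10 informative sites |
| evenness | breadth ≥ 0.8 × (1 − e^(−depth)) (Lander–Waterman expectation under random placement) and ≥ 40% of bins nonzero |
| edit_all | histogram mode at ≤ 1 and non-increasing over bins 0→3 allowing one inversion |
| edit_damaged | same shape, ≥ 20 damaged reads |
| read_length | median ≤ 100 bp |
| pmd | ≥ 10% of reads with PMD score > 3 |
| n_reads | ≥ 200 assigned reads |
| identity | mean identity ≥ 90% |

All thresholds and weights are config-overridable. The score is a sum of
independent indicator terms, hence monotone: improving one summary never
lowers the total.

## Benchmarking (`benchmark`)

Jaccard/IoU and F1 compare predicted and true taxon sets; both are defined
as 1.0 when both sets are empty (perfect vacuous agreement). Threshold
sweeps apply inclusive read-count cutoffs per sample and aggregate as
unweighted means with sample standard deviations. ROC curves and trapezoid
AUC come from scikit-learn, with equal scores grouped; the test suite
cross-checks the AUC against an independent pairwise-concordance
estimator. In score-based ROC, ancient-present taxa are positives and
modern-present taxa negatives.

## End-to-end driver (`cli`)

`run-all` chains the stages on synthetic data. Because the package wraps
no external classifier or aligner, the screening stage derives a
classifier-style report honestly from the truth alignments (assigned-read
counts and unique covered k-mers per taxon) and the metrics stage consumes
the truth SAM; any other SAM with NM/MD is equally accepted by the
library functions. Problem sizes default to a desk-scale run (2 samples,
5,000 + 5,000 fragments, 10 taxa) chosen so the whole loop completes in
seconds; the full ten-sample, 500,000 + 500,000-fragment design is a
config change. Output trees are byte-reproducible under a fixed seed: the
run log file omits timestamps (stderr logging keeps them) and images are
written without software/date metadata.

## Known limitations

- No cross-taxon homology in the synthetic genomes, so false-positive
  stacking (the phenomenon the breadth filter exists for) must be
  constructed explicitly in tests rather than emerging from alignment.
- Substitution-only error and damage model; no indels, no base-quality
  modelling, constant FASTQ qualities.
- The scoring criteria are heuristics calibrated on the simulator's
  defaults; real data typically require per-project threshold tuning.
- `nick_rate` never splits fragments; it only adds interior deamination
  opportunity.
- LCA classification, external database construction and wrapped tools
  are out of scope by design.
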