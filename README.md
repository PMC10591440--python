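# paleometa

A desk-scale toolkit for **ancient-metagenomics analysis**: simulating
damaged/fragmented ancient-DNA (aDNA) metagenomic samples with ground
truth, filtering k-mer–classifier reports by depth and breadth of
coverage, computing alignment-based validation/authentication metrics,
combining them into a 0–10 authentication score, and benchmarking
detection/authentication accuracy (Jaccard, F1, ROC).

It is aimed at researchers and method developers in palaeogenomics and
ancient microbiome analysis who want the *analytical core* of an ancient
pathogen/microbiome screening workflow — the filters, the damage
statistics and the scoring — as a testable Python library and CLI, without
multi-hundred-GB reference databases or wrapped external aligners.

## The science in brief

**Detection.** Depth of coverage alone (assigned reads, ≈ N·L_read /
L_genome) is a poor witness of microbial presence: cross-mapped reads stack
on conserved regions. Four reads of length L on a 4L genome give 1X depth
whether they stack (25% breadth) or tile (100% breadth). Candidate taxa are
therefore filtered on *both* a depth proxy (reads assigned directly to the
taxon, default ≥ 200) and a breadth proxy (unique reference k-mers covered,
default ≥ 1000). With k = 31 a 50-bp read holds 50 − 31 + 1 = 20 k-mer
windows, so 1000 unique k-mers correspond to ~50 non-overlapping reads —
the arithmetic behind the default.

**Authentication.** aDNA molecules are short (log-normal lengths, median
≈ 42 bp here) and carry post-mortem cytosine deamination: elevated C→T at
5′ read ends and G→A at 3′ ends (the complementary strand's C→T), modelled
Briggs-style with geometric single-strand overhangs, overhang deamination
rate 0.3, interior rate 0.01 and nick rate 0.03. Eight per-taxon summaries
are computed from SAM alignments — terminal deamination profiles, 100-bin
evenness of coverage, edit-distance histograms (all and damaged reads),
read lengths, per-read PMD log-likelihood-ratio scores, assigned-read
counts and percent identity/ANI — and each passing summary adds points:
+2 evenness, +1 per deaminated end, +1 for each of the rest, for a total
score in [0, 10]. High scores mean "present and ancient"; modern
contaminants typically plateau around 4–5 (present, not ancient).

## Worked example

Run the full simulate → screen → authenticate → score → benchmark loop at
reduced scale (2 samples, 5,000 ancient + 5,000 modern fragments each,
5 ancient + 5 modern species):

```sh
paleometa run-all --outdir demo --seed 1
```

which logs

```
INFO run-all: seed=1 n_samples=2 fragments=5000+5000
INFO simulate: sample1 (microbial fraction 0.70, 5000 + 5000 fragments)
INFO simulate: sample2 (microbial fraction 0.70, 5000 + 5000 fragments)
INFO screen: sample1 -> 10/10 candidate taxa
INFO metrics: sample1 -> 10 taxa
INFO screen: sample2 -> 9/10 candidate taxa
INFO metrics: sample2 -> 10 taxa
INFO score: 10 taxa x 2 samples
INFO benchmark: ROC AUC = 1.000 over 20 (sample, taxon) pairs
INFO run-all: done
```

and writes, among other artifacts, `demo/scores.tsv`:

```
taxon                       sample1  sample2
Campylobacter rectus             10       10
Clostridium botulinum            10       10
Enterococcus faecalis            10       10
Fusarium fujikuroi               10       10
Mycobacterium avium              10       10
Acanthamoeba castellanii          5        5
Aspergillus flavus                5        5
Brevibacterium aurantiacum        5        5
Burkholderia mallei               5        5
Lactococcus lactis                5        4
```

The five ancient-simulated taxa reach the maximal score of 10 (present:
even coverage, enough reads, high identity, clean edit distances; ancient:
terminal deamination at both ends, short fragments, PMD-positive reads,
damaged-read edit distances). The five modern contaminants stop at 4–5 —
they pass the presence-type criteria but fail every ancient-status
criterion — so the authentication score separates ancient from modern taxa
with ROC AUC 1.0 here. `demo/` also contains per-sample classifier-style
reports and candidate lists, per-taxon metrics (JSON/TSV plus nine-panel
figures), the score heatmap, the Jaccard/F1 threshold sweep and the ROC
table. Identical seeds give byte-identical output trees.

Other subcommands operate on individual artifacts, e.g.

```sh
paleometa screen-filter --report report.tsv --out candidates.tsv \
    --min-kmers 1000 --min-taxreads 200 --rank species
paleometa preprocess --fastq in.fastq --out trimmed.fastq \
    --adapter AGATCGGAAGAGC --min-len 31
```

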