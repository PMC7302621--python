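# phamlab

Comparative genomics of bacteriophage cohorts — the analysis style used for
collections of actinobacteriophages (e.g. phages of *Microbacterium*,
*Mycobacterium*, *Gordonia* hosts), where tens to hundreds of annotated
genomes are organized by shared gene content and nucleotide similarity.

Given a directory of annotated phage genomes (GenBank flat files, or FASTA
plus a gene table), phamlab:

- sorts all predicted proteins into **phamilies (phams)** — protein
  families built by pairwise Smith–Waterman alignment (BLOSUM62, gap
  11/1) with single-linkage closure over a link rule (default: ≥ 32.5%
  identity over an alignment covering ≥ 50% of the shorter protein);
- computes all-vs-all **gene-content similarity**
  `GCS(a,b) = 100 · ½ (|Pa∩Pb|/|Pa| + |Pa∩Pb|/|Pb|)` where `Px` is a
  phage's set of distinct phams, and its complement
  `gcd = 1 − GCS/100`;
- computes **ANI** by the classic fragment method (1,020-bp fragments,
  reciprocal best local alignments, 30% identity / 70% coverage filters)
  and a **MinHash nucleotide distance**
  `d = −(1/k)·ln(2j/(1+j))` from a bottom-sketch Jaccard estimate `j`
  over canonical k-mers (k = 21, sketch 1000);
- assigns **clusters** (connected components at GCS ≥ 35%, inclusive),
  **subclusters** (ANI components within clusters), and **singletons**;
- measures genetic isolation with **MaxGCDGap** — for each phage, the
  largest gap between consecutive sorted gcd values to all other phages,
  with a leading sentinel at 0;
- builds **genome networks** with edges where `gcd < 0.89` and
  nucleotide distance `< 0.42` (both strict);
- extracts intergenic regions and discovers **degenerate repeated
  motifs** (direct repeats, start-associated sequences, inverted
  repeats) with case-encoded consensi — uppercase = conserved in all
  occurrences, lowercase = conserved in ≥ 75% — and annotates each hit's
  distance to the next translation start;
- generates **synthetic cohorts** with planted clusters, divergence
  bands, and motifs, plus machine-readable truth tables, so the whole
  pipeline is testable without downloading data.

## Worked example

Simulate a small cohort with known structure, then run the full analysis:

```bash
phamlab simulate --seed 5 -o cohort/ --clusters 2 --cluster-size 3 --singletons 1
phamlab run cohort/ -o analysis/
```

`analysis/clusters.tsv` then contains (header comment abbreviated):

```
# clusters; config={'cluster_gcs_min': 35.0, ...}
phage_id    cluster  subcluster
synS_01     SINGLETON
synT1_01    C1
synT1_02    C1
synT1_03    C1
synT2_01    C2
synT2_02    C2
synT2_03    C2
```

The two planted clusters come back as C1 and C2 and the planted singleton
is labeled SINGLETON: within-cluster pairs share ~90% of their phams
(retention 0.9 in the simulator), far above the 35% cluster threshold,
while between-cluster pairs share none. The other outputs are the
genometrics table, the pham table and presence/absence matrix (TSV and
NEXUS for split-network software), the four pairwise matrices
(`gcs`/`gcd`/`ani`/`nucleotide_distance`), the MaxGCDGap table, the
network edge list, and motif reports (models TSV and hits GFF3).

The same stages are available individually (`phamlab metrics`, `phams`,
`distances`, `cluster`, `network`, `maxgcdgap`, `heatmap-order`,
`motif scan|discover|inverted`) and as library functions
(`phamlab.build_phams`, `phamlab.all_pairs`, `phamlab.assign_clusters`,
...).

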