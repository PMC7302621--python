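# Methods

## Scope and data model

phamlab organizes a cohort of annotated phage genomes by shared gene
content and nucleotide similarity. The unit of input is one genome: a DNA
sequence over {A,C,G,T,N} with an ordered list of genes (CDS with
amino-acid translations, tRNAs flagged separately). Coordinates are
0-based half-open internally and converted to 1-based inclusive in all
human-facing output (GenBank/GFF3 convention); the conversion is lossless
for single-interval features. Joined (multi-interval) CDS are collapsed
to their outer span with the translation kept from the record — adequate
for gene-content and intergenic work, and the phage records this tooling
targets are overwhelmingly single-interval. Genome termini class
(circularly permuted / cos extension / DTR) is metadata only and is never
inferred from sequence, since termini determination requires raw
sequencing reads, which are out of scope.

Genometrics: GC% is computed over unambiguous bases only (N excluded from
numerator and denominator) and rounded half away from zero to one
decimal, the convention used in published genometrics tables. Coding
density is the fraction of the genome covered by the union of gene
intervals.

## Phams (protein families)

All cohort proteins are compared all-vs-all with local Smith–Waterman
alignment (BLOSUM62, gap open 11 / extend 1; X accepted and scored 0).
Two proteins are linked when BLAST-style percent identity — identities
divided by alignment columns, gap columns included — is ≥ 32.5% and the
aligned residue columns cover ≥ 50% of the shorter protein. Phams are the
connected components of this link graph (single linkage, consistent with
established pham practice; chaining is an accepted property and is why a
protein can join a pham without directly aligning to every member).

Design notes:

- Gap-inclusive identity was chosen deliberately: with gap columns
  excluded, gappy chance alignments between unrelated proteins inflate
  identity and produce spurious links at an appreciable per-pair rate,
  which accumulates quadratically over a cohort; with the BLAST-style
  definition the spurious rate measured on random protein pairs of
  100–200 aa is below 10⁻⁴ while homologs at 50% amino-acid divergence
  still link comfortably.
- Pham ids are assigned deterministically (components ordered by their
  lexicographically smallest gene id), so results are invariant to
  genome and gene input order.
- Thresholds are parameters of `LinkRule` and are recorded in the
  resulting `PhamSet`; cohort-only phams will differ from phams computed
  against a large external database, so pham-derived quantities are
  comparable only within one build.

## Pairwise metrics

**Gene-content similarity.** GCS(a,b) = 100 · ½ (|Pa∩Pb|/|Pa| +
|Pa∩Pb|/|Pb|) over sets of distinct phams; gcd = 1 − GCS/100. A phage
with zero annotated genes has no defined GCS.

**ANI.** The classic fragment-based reciprocal method: the query is cut
into non-overlapping 1,020-bp fragments (trailing fragments ≥ 100 bp
kept), each fragment is aligned to the subject, fragments failing 30%
identity or 70% coverage are discarded, ANI(a→b) is the mean identity of
kept fragments, and the symmetrized value ½(ANI(a→b)+ANI(b→a)) is
reported. For speed, each fragment is first *placed* by semi-global edit
distance (edlib, infix mode) and then refined by Smith–Waterman (match 2,
mismatch −3, gap 5/2) inside the placed window plus a 100-bp margin; the
filters and identity are computed from the refined local alignment, with
gap columns included in the identity denominator (same rationale as for
proteins: without this, unrelated fragments pass the 30% filter through
gap-skipping). Unrelated genomes therefore yield ANI 0 (no fragment
passes), and a genome against itself yields exactly 100.

**Nucleotide distance.** A bottom-s MinHash sketch over canonical k-mers
(k = 21, s = 1000; canonical = lexicographic minimum of a k-mer and its
reverse complement; windows containing N skipped). K-mers are 2-bit
packed into 64-bit integers and hashed with a seeded splitmix64 finalizer.
The Jaccard estimate j uses the standard merged-bottom-sketch estimator,
and the distance is the Mash transform d = −(1/k)·ln(2j/(1+j)), capped at
1.0 when j = 0. With a sketch at least as large as the union of distinct
k-mers the estimate equals the exact Jaccard, which the tests exploit as
an oracle. The hash seed is an explicit parameter; distances are
deterministic given it.

## Taxonomy

Clusters are connected components of the graph with edges at GCS ≥ 35%
(threshold inclusive: a pair at exactly 35.0 is clustered). Components of
size 1 are singletons. Cluster naming is deterministic — C1, C2, … by
descending size, ties broken by smallest member id — with an optional
label map for EA/EB-style names.

Subclusters subdivide one cluster by connected components at ANI ≥ 75%.
The 75% default is a package choice (the cluster/subcluster literature
does not fix one); it sits between the within-subgroup (~98%) and
between-subgroup (~70%) ANI bands the synthetic generator plants, and is
surfaced prominently in `TaxonomyConfig`. A cluster whose ANI graph stays
connected receives no subcluster labels.

MaxGCDGap: for one phage, sort its gcd values to all other phages
ascending, prepend a sentinel 0 (the self-comparison), and report the
largest difference between consecutive values. The leading sentinel means
a phage whose nearest relative is at gcd 0.95 has MaxGCDGap ≥ 0.95; no
trailing sentinel at 1.0 is added (the metric measures isolation from the
nearest sampled relatives, not distance to a hypothetical maximally
distant phage). Both conventions exist in the wild; this one is fixed
here and configurable only by editing the sorted-value construction.

Genome networks: an edge joins two phages when gcd < 0.89 AND nucleotide
distance < 0.42, both strictly — a pair at exactly 0.89 or 0.42 gets no
edge. Components are reported for downstream layout tools; rendering is
out of scope.

Heatmap ordering reproduces the R `heatmap.2`-style display order:
pairwise Chebyshev ("maximum") distances between matrix rows,
single-linkage agglomeration, dendrogram leaf order.

Lifestyle markers: genes whose product text matches
integrase / (immunity) repressor patterns are flagged. This is explicitly
a marker report, not a lifestyle prediction: temperate phages can lack
identifiable repressors and integrase genes can serve lytic growth.

## Motif analysis

Motif matching is substitution-only Hamming distance over fixed-length
windows — no indels — matching how "departures" from a consensus are
counted positionally in phage motif work. Consensus strings accept IUPAC
degeneracy codes; N matches any base, and an N in the genome matches only
a consensus N. Intergenic regions are the maximal intervals covered by no
gene; the default search space for discovery is intergenic-only, because
the motifs of interest (direct repeats, start-associated sequences,
inverted repeats) live in intergenic gaps; whole-genome scanning is
available.

Direct-repeat discovery is a greedy, fully deterministic seed-and-refine:
every intergenic L-mer (forward strand, coordinate order) seeds a
candidate; windows within the mismatch budget are gathered; with at least
`min_copies` occurrences a case-encoded consensus is built (uppercase at
100% conservation, lowercase at ≥ 75%, N below) and re-scanned to a fixed
point (≤ 10 rounds). Because a seed one or two bases off the true repeat
frame can reach the copy threshold first, a frame-refinement step slides
the occurrence frame by up to ±3 bases and keeps the frame whose
consensus has the most informative columns (most non-N, then most
uppercase; ties prefer the smaller shift). Windows overlapping an emitted
model's occurrences are excluded from seeding further models, so shifted
variants of one repeat are not reported as separate models. Models are
sorted by copy number. Consensus column ties are broken alphabetically.

Inverted repeats: windows of arm + spacer + arm where the left arm and
the reverse complement of the right arm agree within the mismatch budget;
the spacer is unconstrained. The default geometry (arm 8, spacer 2) gives
an 18-bp site. Inverted repeats read identically on both strands, so hits
are reported once, on the forward strand.

Upstream distance: measured from the hit's 3′ end to the first base of
the start codon of the nearest downstream gene on the hit's strand, both
endpoints exclusive — a motif ending at position 100 (half-open) with a
gene starting at 121 is 21 bp upstream. Reverse-strand distances are
measured on the reverse complement. Hits overlapping a gene, or with no
gene start within 500 bp, are left unannotated. Published descriptions of
such ranges are not internally consistent at the ±1 level, so the
convention here is fixed and documented rather than matched to any one
table.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline must recover,
and nothing more:

- **Gene families** are random proteins (default gene length 300–600 bp,
  i.e. 100–200 aa) reverse-translated with codons weighted toward a GC
  target (default 0.63, the mid-range of high-GC actinobacteriophage
  genomes). Distinct families are unrelated by construction: a candidate
  protein that chance-aligns to an accepted family near the pham link
  rule (identity ≥ 27.5% over ≥ 40% of the shorter — a margin below the
  rule, so nucleotide mutation cannot push a pair over it) is resampled.
  Planted family structure is therefore exactly recoverable, and shared
  phams between clusters occur only through the explicit overlap
  parameter.
- **Clusters** sample a family template (default 12 families); members
  retain each family independently with probability `retention` (default
  0.9) and mutate their whole genome at a per-site substitution rate
  (default 0.01). The expected within-cluster GCS is ≈ 100·retention
  (the shared fraction ρ²T over ρT); the expected within-cluster ANI is
  ≈ 100·(1 − 2·rate). Spacer sequences belong to the template, so with
  retention 1 and rate 0 members are byte-identical and ANI is exactly
  100.
- **Subclusters** (optional) diverge from the cluster template at a
  shared between-subgroup rate (default 0.30 → between-subgroup ANI
  ≈ 70%, below the 75% subcluster threshold) while members stay at the
  within rate (ANI ≈ 98%). Protein-level divergence at these rates keeps
  phams linked across subgroups (via the template subgroup under single
  linkage), so the cluster holds together while ANI splits it.
- **Singletons** draw families disjoint from every cluster: GCS ≈ 0 and
  MaxGCDGap ≈ 1.
- **Motifs** are planted into intergenic spacers after mutation, ending
  a sampled offset upstream of a forward-strand gene start, each instance
  carrying at most the configured number of random departures; exact
  coordinates go into the truth table.
- Divergence is substitution-only (no indels or rearrangements), keeping
  ANI and sketch-distance targets analytic; gene gain/loss is modeled
  solely through family retention, which is precisely what GCS measures.

What the generator does *not* emulate: mosaicism and recombination,
horizontal exchange with an outside gene pool, codon-usage structure
beyond GC targeting, tRNA genes, or realistic genome sizes — synthetic
genomes are a few kbp with ~12–20 genes of 100–200 aa, a deliberately
scaled-down problem size chosen so the full pipeline (alignment-based
pham construction included) runs in seconds per cohort. Passing tests
therefore demonstrate the correctness of the algorithms and the
recoverability of planted structure under clean conditions, not
performance on real, mosaic phage genomes; on real cohorts the
continuum-of-diversity caveats of the cluster/singleton framework apply.

## Numerical and determinism notes

- Everything downstream of a seed is deterministic: one
  `numpy.random.Generator` threads through cohort generation; MinHash
  uses an explicit hash seed; motif discovery and pham numbering have no
  randomness; matrices are computed upper-triangle-only and mirrored, so
  symmetry is exact.
- Matrix TSVs are written to 3 decimals and round-trip losslessly at
  that precision; pipeline tables carry a `#` header comment naming the
  parameters that produced them.
- Degenerate inputs are rejected early with specific errors: empty
  proteins, all-N sequences (undefined GC), sequences shorter than k for
  sketching, phages with no phams (undefined GCS), single-genome inputs
  at the pairwise stage.
- The pipeline recomputes stages on each run rather than caching
  intermediates on content hashes; stages are instead re-runnable
  individually from files via the per-stage CLI subcommands, which keeps
  provenance explicit and the implementation simple at these problem
  sizes.

## Acceptance measurements

`scripts/acceptance.py --seed N --out file.json` regenerates the default
study cohort (4 planted clusters × 5 genomes + 2 singletons), a
3-subgroup cluster, divergence pairs (10–50 kbp), and a motif-planted
genome, runs the full pipeline on them, and reports: cluster/singleton
counts and recovery ARI, pham-vs-family recovery ARI, within/between
GCS, singleton MaxGCDGap, network component count, subcluster recovery,
ANI at a planted 5% substitution rate, sketch distance at 1%, the
MinHash-vs-exact-Jaccard error, and planted-motif recovery with
unplanted negative controls. All values are computed at run time from
the seed.
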