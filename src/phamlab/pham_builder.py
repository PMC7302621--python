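"""Pham (phamily) construction: protein families by single-linkage clustering.

Every predicted protein in the cohort is compared all-vs-all by local
(Smith-Waterman) alignment; two proteins are linked when percent identity
and coverage of the shorter protein both clear the link rule, and phams are
the connected components of the resulting graph. Single linkage matches
established pham practice and is a documented source of chaining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import PhageGenome

__all__ = [
    "LinkRule",
    "PairwiseProteinScore",
    "PhamSet",
    "make_aligner",
    "score_protein_pair",
    "build_phams",
    "presence_matrix",
    "pham_table",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class LinkRule:
    """Thresholds and scoring parameters that define a pham edge.

    Defaults follow the Phamerator lineage: BLOSUM62, gap open 11 / extend 1,
    link when identity >= 32.5% over a local alignment covering >= 50% of
    the shorter protein.
    """

    min_identity: float = 32.5  # percent over aligned columns
    min_coverage: float = 0.5  # aligned columns / length of shorter protein
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class PairwiseProteinScore:
    query_id: str
    subject_id: str
    percent_identity: float
    coverage: float
    raw_score: float

    def passes(self, rule: LinkRule) -> bool:
        return self.percent_identity >= rule.min_identity and self.coverage >= rule.min_coverage


def make_aligner(rule: LinkRule = LinkRule()) -> Align.PairwiseAligner:
    """Local protein aligner for the given link rule; X is scored 0."""
    matrix = substitution_matrices.load(rule.matrix)
    if "X" in matrix.alphabet:
        arr = np.array(matrix)
        xi = matrix.alphabet.index("X")
        arr[xi, :] = 0.0
        arr[:, xi] = 0.0
        matrix = substitution_matrices.Array(alphabet=matrix.alphabet, data=arr)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -rule.gap_open
    aligner.extend_gap_score = -rule.gap_extend
    return aligner


def _validate_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    bad = set(seq.upper()) - AA20 - {"X"}
    if bad:
        raise ValueError(f"{name}: invalid residues {sorted(bad)}")
    return seq.upper()


def score_protein_pair(
    a: str,
    b: str,
    rule: LinkRule = LinkRule(),
    aligner: Align.PairwiseAligner | None = None,
    query_id: str = "a",
    subject_id: str = "b",
) -> PairwiseProteinScore:
    """Best local alignment of two proteins with identity and coverage.

    Identity is BLAST-style percent identity over the aligned region
    (identities / alignment columns, gap columns included); coverage is the
    number of aligned residue columns divided by the shorter protein's
    length. Deterministic for fixed scoring parameters.
    """
    a = _validate_protein(a, query_id)
    b = _validate_protein(b, subject_id)
    if aligner is None:
        aligner = make_aligner(rule)
    alignments = aligner.align(a, b)
    if alignments.score <= 0:
        return PairwiseProteinScore(query_id, subject_id, 0.0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    # BLAST-style percent identity: gap columns count in the denominator
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return PairwiseProteinScore(query_id, subject_id, 0.0, 0.0, float(aln.score))
    identity = 100.0 * counts.identities / columns
    coverage = (counts.identities + counts.mismatches) / min(len(a), len(b))
    return PairwiseProteinScore(query_id, subject_id, identity, coverage, float(aln.score))


@dataclass
class PhamSet:
    """Partition of cohort proteins into phams.

    ``phams`` maps pham_id -> frozenset of gene ids; ``gene_to_pham`` is the
    reverse map; ``representative`` is the longest member of each pham.
    Singleton phams ("orphams") are permitted.
    """

    phams: dict[str, frozenset[str]]
    gene_to_pham: dict[str, str]
    representative: dict[str, str]
    gene_to_phage: dict[str, str]
    link_rule: LinkRule = field(default_factory=LinkRule)

    def __len__(self) -> int:
        return len(self.phams)

    def phams_of(self, phage_id: str) -> frozenset[str]:
        """Distinct phams with at least one member gene in ``phage_id``."""
        found = {
            self.gene_to_pham[g] for g, p in self.gene_to_phage.items() if p == phage_id
        }
        if not found and phage_id not in set(self.gene_to_phage.values()):
            raise KeyError(f"phage {phage_id} has no genes in this pham set")
        return frozenset(found)


def _cohort_proteins(genomes: list[PhageGenome]) -> list[tuple[str, str, str]]:
    """(gene_id, phage_id, translation) for every CDS, canonically ordered."""
    seen: dict[str, str] = {}
    out = []
    for genome in genomes:
        for g in genome.cds_genes:
            if g.gene_id in seen:
                raise ValueError(
                    f"gene id {g.gene_id} appears in both {seen[g.gene_id]} "
                    f"and {genome.phage_id}; gene ids must be cohort-unique"
                )
            seen[g.gene_id] = genome.phage_id
            out.append((g.gene_id, genome.phage_id, g.translation.upper()))
    out.sort(key=lambda t: t[0])
    return out


def build_phams(genomes: list[PhageGenome], rule: LinkRule = LinkRule()) -> PhamSet:
    """Partition all cohort proteins into phams by single-linkage closure.

    An edge joins two proteins when the link rule holds; phams are connected
    components. Pham ids are assigned deterministically: components sorted
    by their lexicographically smallest gene id and numbered pham_0001, ...
    Order of genomes or genes in the input does not affect the result.
    """
    proteins = _cohort_proteins(genomes)
    aligner = make_aligner(rule)
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(gid for gid, _, _ in proteins)
    for i in range(len(proteins)):
        gid_i, _, seq_i = proteins[i]
        for j in range(i + 1, len(proteins)):
            gid_j, _, seq_j = proteins[j]
            score = score_protein_pair(
                seq_i, seq_j, rule, aligner=aligner, query_id=gid_i, subject_id=gid_j
            )
            if score.passes(rule):
                graph.add_edge(gid_i, gid_j)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    width = max(4, len(str(len(components))))
    lengths = {gid: len(seq) for gid, _, seq in proteins}
    phams: dict[str, frozenset[str]] = {}
    gene_to_pham: dict[str, str] = {}
    representative: dict[str, str] = {}
    for k, members in enumerate(components, start=1):
        pham_id = f"pham_{k:0{width}d}"
        phams[pham_id] = frozenset(members)
        for gid in members:
            gene_to_pham[gid] = pham_id
        representative[pham_id] = max(members, key=lambda g: (lengths[g], g))
    return PhamSet(
        phams=phams,
        gene_to_pham=gene_to_pham,
        representative=representative,
        gene_to_phage={gid: pid for gid, pid, _ in proteins},
        link_rule=rule,
    )


def presence_matrix(phams: PhamSet, genomes: list[PhageGenome]) -> pd.DataFrame:
    """Binary phage x pham matrix: 1 iff the genome has >= 1 gene in the pham.

    In-genome paralogs still give a single 1.
    """
    built_from = set(phams.gene_to_phage.values())
    pham_ids = sorted(phams.phams)
    rows = []
    for genome in genomes:
        if genome.cds_genes and genome.phage_id not in built_from:
            raise ValueError(f"{genome.phage_id} was not part of this pham build")
        present = {phams.gene_to_pham[g.gene_id] for g in genome.cds_genes}
        rows.append([1 if p in present else 0 for p in pham_ids])
    return pd.DataFrame(rows, index=[g.phage_id for g in genomes], columns=pham_ids)


def pham_table(phams: PhamSet) -> pd.DataFrame:
    """Long-form table (pham_id, gene_id, phage_id), sorted for stable output."""
    rows = [
        (pham_id, gid, phams.gene_to_phage[gid])
        for pham_id, members in sorted(phams.phams.items())
        for gid in sorted(members)
    ]
    return pd.DataFrame(rows, columns=["pham_id", "gene_id", "phage_id"])
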