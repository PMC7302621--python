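"""Shared fixtures: handcrafted GenBank records and a reference synthetic cohort."""

from __future__ import annotations


import numpy as np
import pytest

from phamlab.genome_io import Gene, PhageGenome
from phamlab.pham_builder import PhamSet, build_phams
from phamlab.synthetic_cohort import CohortSpec, generate_cohort

SEQ_300 = ("ACGT" * 75)[:300]


def _origin_block(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    return "\n".join(lines)


# Hand-written record: forward CDS at 10..120 and reverse CDS at
# complement(150..270) in 1-based inclusive GenBank coordinates. The
# expected internal half-open coordinates, (9, 120) and (149, 270), were
# converted by hand.
GENBANK_TWO_CDS = (
    """\
LOCUS       TESTPHAGE                300 bp    DNA     linear   PHG 01-JAN-2024
DEFINITION  handcrafted coordinate-conversion fixture.
ACCESSION   TEST0001
VERSION     TEST0001.1
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
FEATURES             Location/Qualifiers
     source          1..300
                     /host="Microbacterium foliorum"
     CDS             10..120
                     /locus_tag="tp_001"
                     /product="hypothetical protein"
                     /translation="MAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA"
     CDS             complement(150..270)
                     /locus_tag="tp_002"
                     /product="terminase large subunit"
                     /translation="MKKKKKKKKKKKKKKKKKKKKKKKKKKKKKKKKKKKKKKK"
ORIGIN
"""
    + _origin_block(SEQ_300)
    + "\n//\n"
)

GENBANK_NO_FEATURES = (
    """\
LOCUS       EMPTYPHAGE               300 bp    DNA     linear   PHG 01-JAN-2024
DEFINITION  record with sequence but no features.
ACCESSION   TEST0002
VERSION     TEST0002.1
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
FEATURES             Location/Qualifiers
ORIGIN
"""
    + _origin_block(SEQ_300)
    + "\n//\n"
)


@pytest.fixture
def two_cds_gbk(tmp_path):
    path = tmp_path / "two_cds.gbk"
    path.write_text(GENBANK_TWO_CDS)
    return path


@pytest.fixture
def no_features_gbk(tmp_path):
    path = tmp_path / "empty.gbk"
    path.write_text(GENBANK_NO_FEATURES)
    return path


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_genome(
    phage_id: str = "toy",
    length: int = 300,
    genes: tuple = (),
    seed: int = 0,
    sequence: str | None = None,
) -> PhageGenome:
    """Small genome with genes given as (start, end, strand[, product]) tuples."""
    if sequence is None:
        sequence = random_dna(np.random.default_rng(seed), length)
    gene_objs = []
    for i, g in enumerate(genes, start=1):
        start, end, strand = g[:3]
        product = g[3] if len(g) > 3 else "hypothetical protein"
        aa = max(1, (end - start) // 3)
        gene_objs.append(
            Gene(f"{phage_id}_g{i:03d}", start, end, strand, product, "M" * aa)
        )
    return PhageGenome(phage_id=phage_id, sequence=sequence, genes=gene_objs)


def pham_set_from_dict(phage_phams: dict[str, set]) -> PhamSet:
    """Build a PhamSet directly from phage -> pham-id-set (for GCS oracles)."""
    phams: dict[str, set] = {}
    gene_to_pham = {}
    gene_to_phage = {}
    for phage, pham_ids in phage_phams.items():
        for k, pham in enumerate(sorted(pham_ids)):
            gid = f"{phage}_g{k}"
            phams.setdefault(str(pham), set()).add(gid)
            gene_to_pham[gid] = str(pham)
            gene_to_phage[gid] = phage
    return PhamSet(
        phams={p: frozenset(m) for p, m in phams.items()},
        gene_to_pham=gene_to_pham,
        representative={p: sorted(m)[0] for p, m in phams.items()},
        gene_to_phage=gene_to_phage,
    )


@pytest.fixture(scope="session")
def reference_cohort():
    """One 4-cluster + 2-singleton cohort with phams built, shared by tests."""
    spec = CohortSpec(seed=11)
    genomes, truth = generate_cohort(spec)
    phams = build_phams(genomes)
    return genomes, truth, phams
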