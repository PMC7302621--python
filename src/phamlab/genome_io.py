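"""Genome data model, GenBank/FASTA input, and per-genome genometrics.

Coordinates are 0-based half-open internally (Python/biopython convention);
anything written for human consumption is converted back to 1-based
inclusive (GenBank convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation

__all__ = [
    "Gene",
    "PhageGenome",
    "GenomeMetrics",
    "GenomeFormatError",
    "read_genbank",
    "read_fasta",
    "write_genbank",
    "compute_genometrics",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_nexus_binary",
]

TERMINI_CLASSES = ("circularly_permuted", "cos_ext", "DTR", "unknown")


class GenomeFormatError(ValueError):
    """Raised when an input file cannot be interpreted as a phage genome."""


@dataclass(frozen=True)
class Gene:
    """A single annotated gene (CDS or tRNA) on a phage genome.

    ``start``/``end`` are 0-based half-open genome coordinates.
    ``translation`` is the amino-acid sequence for CDS genes and empty for
    tRNA genes.
    """

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    product: str = ""
    translation: str = ""
    is_trna: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.is_trna and self.translation:
            raise ValueError(f"tRNA gene {self.gene_id} must not carry a translation")
        if not self.is_trna and not self.translation:
            raise ValueError(f"CDS gene {self.gene_id} requires a translation")


@dataclass
class PhageGenome:
    """One phage genome: sequence, ordered gene list, and metadata."""

    phage_id: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)
    termini_class: str = "unknown"
    termini_repeat_length: Optional[int] = None
    host: str = ""
    accession: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise GenomeFormatError(f"{self.phage_id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise GenomeFormatError(f"{self.phage_id}: non-ACGTN characters {sorted(bad)}")
        if self.termini_class not in TERMINI_CLASSES:
            raise ValueError(f"unknown termini class {self.termini_class!r}")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        for g in self.genes:
            if g.end > len(self.sequence):
                raise GenomeFormatError(
                    f"{self.phage_id}: gene {g.gene_id} extends beyond sequence "
                    f"({g.end} > {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_genes(self) -> list[Gene]:
        return [g for g in self.genes if not g.is_trna]

    @property
    def trna_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.is_trna]


@dataclass(frozen=True)
class GenomeMetrics:
    """Per-genome summary statistics (length, GC, gene counts, density)."""

    length_bp: int
    gc_percent: float
    cds_count: int
    trna_count: int
    coding_density: float
    regional_gc: tuple[tuple[int, int, float], ...] = ()


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_percent(seq: str, ndigits: int = 1) -> float:
    """GC% of ``seq`` ignoring N in numerator and denominator.

    Rounded half away from zero to ``ndigits`` decimals.
    """
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("GC content undefined: sequence has no unambiguous bases")
    return _round_half_up(100.0 * gc / acgt, ndigits)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def compute_genometrics(
    genome: PhageGenome,
    regions: Optional[Sequence[tuple[int, int]]] = None,
) -> GenomeMetrics:
    """Length, GC%, gene counts, coding density, and optional regional GC.

    Coding density is the fraction of the genome covered by the union of
    gene intervals. Requested regions are clipped to the genome before
    their GC is computed.
    """
    length = len(genome)
    covered = sum(e - s for s, e in _merge_intervals((g.start, g.end) for g in genome.genes))
    regional: list[tuple[int, int, float]] = []
    for s, e in regions or ():
        s2, e2 = max(0, s), min(length, e)
        if e2 <= s2:
            raise ValueError(f"region ({s}, {e}) is empty after clipping to the genome")
        regional.append((s2, e2, gc_percent(genome.sequence[s2:e2])))
    return GenomeMetrics(
        length_bp=length,
        gc_percent=gc_percent(genome.sequence),
        cds_count=len(genome.cds_genes),
        trna_count=len(genome.trna_genes),
        coding_density=covered / length,
        regional_gc=tuple(regional),
    )


# ---------------------------------------------------------------------------
# GenBank / FASTA input


def _feature_gene(feature, index: int, record_seq: str, phage_id: str) -> Gene:
    loc = feature.location
    if isinstance(loc, CompoundLocation):
        # Joined CDS collapsed to its outer span; translation kept from the
        # record so downstream protein work is unaffected.
        start = int(min(p.start for p in loc.parts))
        end = int(max(p.end for p in loc.parts))
    else:
        start, end = int(loc.start), int(loc.end)
    strand = "-" if loc.strand == -1 else "+"
    quals = feature.qualifiers
    gene_id = (
        quals.get("locus_tag", [None])[0]
        or quals.get("protein_id", [None])[0]
        or quals.get("gene", [None])[0]
        or f"{phage_id}_{index}"
    )
    product = quals.get("product", [""])[0]
    if feature.type == "tRNA":
        return Gene(gene_id, start, end, strand, product=product, is_trna=True)
    translation = quals.get("translation", [None])[0]
    if translation is None:
        warnings.warn(
            f"{phage_id}:{gene_id}: CDS without /translation; using conceptual "
            "translation (table 11)",
            stacklevel=2,
        )
        cds = feature.extract(Seq(record_seq))
        cds = cds[: len(cds) - len(cds) % 3]  # whole codons only
        translation = str(cds.translate(table=11)).rstrip("*").replace("*", "X")
    return Gene(gene_id, start, end, strand, product=product, translation=translation)


def read_genbank(path: str | Path) -> PhageGenome:
    """Read a single-record GenBank flat file into a :class:`PhageGenome`.

    Every CDS becomes a :class:`Gene` carrying its /translation (conceptual
    translation under the bacterial code if absent); tRNA features are
    flagged. Coordinates are converted to 0-based half-open.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenomeFormatError(f"{path}: {exc}") from exc
    seq = str(record.seq)
    if not seq or set(seq) == {"N"}:
        raise GenomeFormatError(f"{path}: record has no usable sequence")
    phage_id = record.name or record.id
    host = ""
    for feat in record.features:
        if feat.type == "source":
            host = feat.qualifiers.get("host", feat.qualifiers.get("lab_host", [""]))[0]
    genes = [
        _feature_gene(f, i, seq, phage_id)
        for i, f in enumerate(record.features, start=1)
        if f.type in ("CDS", "tRNA")
    ]
    return PhageGenome(
        phage_id=phage_id,
        sequence=seq,
        genes=genes,
        host=host,
        accession=record.id,
    )


def read_fasta(path: str | Path, gene_table: Optional[str | Path] = None) -> PhageGenome:
    """Read a single-record FASTA, optionally with a TSV gene table.

    The gene table columns are: gene_id, start (1-based inclusive), end,
    strand, translation. Without a table the genome carries no genes and
    only sequence-level operations apply.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise GenomeFormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise GenomeFormatError(
            f"{path}: {len(records)} records; supply one FASTA file per genome"
        )
    record = records[0]
    genes: list[Gene] = []
    if gene_table is not None:
        for line in Path(gene_table).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            gene_id, start, end, strand, translation = line.rstrip("\n").split("\t")
            genes.append(
                Gene(gene_id, int(start) - 1, int(end), strand, translation=translation)
            )
    return PhageGenome(phage_id=record.id, sequence=str(record.seq), genes=genes)


def write_genbank(genome: PhageGenome, path: str | Path) -> Path:
    """Write a genome as a GenBank flat file (round-trips through read_genbank)."""
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession or genome.phage_id,
        name=genome.phage_id[:16],
        description=f"{genome.phage_id} complete genome",
        annotations={"molecule_type": "DNA"},
    )
    source = SeqFeature(FeatureLocation(0, len(genome)), type="source")
    if genome.host:
        source.qualifiers["host"] = [genome.host]
    record.features.append(source)
    for g in genome.genes:
        feat = SeqFeature(
            FeatureLocation(g.start, g.end, strand=-1 if g.strand == "-" else 1),
            type="tRNA" if g.is_trna else "CDS",
        )
        feat.qualifiers["locus_tag"] = [g.gene_id]
        if g.product:
            feat.qualifiers["product"] = [g.product]
        if not g.is_trna:
            feat.qualifiers["translation"] = [g.translation]
        record.features.append(feat)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(record, str(path), "genbank")
    return path


# ---------------------------------------------------------------------------
# Matrix / NEXUS output


def write_matrix_tsv(matrix, path: str | Path, ndigits: int = 3) -> Path:
    """Write a labeled symmetric matrix as TSV (header row + label column).

    Values are printed to ``ndigits`` decimals; reading the file back gives
    identical labels and values at that precision.
    """
    labels = list(matrix.labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in matrix")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("\t".join([matrix.metric_name] + labels) + "\n")
        for label, row in zip(labels, matrix.values):
            fh.write("\t".join([label] + [f"{v:.{ndigits}f}" for v in row]) + "\n")
    return path


def read_matrix_tsv(path: str | Path):
    """Read a matrix written by :func:`write_matrix_tsv`."""
    import numpy as np

    from .pairwise_metrics import SymmetricMatrix

    lines = [ln for ln in Path(path).read_text().splitlines() if not ln.startswith("#")]
    header = lines[0].split("\t")
    metric_name, labels = header[0], header[1:]
    values = np.array([[float(v) for v in line.split("\t")[1:]] for line in lines[1:]])
    return SymmetricMatrix(labels=labels, values=values, metric_name=metric_name)


def write_nexus_binary(presence, path: str | Path) -> Path:
    """Write a phage x pham presence/absence matrix as a NEXUS characters block.

    ``presence`` is a pandas DataFrame with phage ids as index and pham ids
    as columns, entries 0/1. The output is readable by split-network
    software (SplitsTree-style standard datatype, symbols 0 1).
    """
    values = presence.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        raise ValueError("presence matrix must be strictly binary")
    taxa = [str(t) for t in presence.index]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate phage ids in presence matrix")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    width = max(len(t) for t in taxa)
    with path.open("w") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN TAXA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(taxa)};\n")
        fh.write("    TAXLABELS\n")
        for t in taxa:
            fh.write(f"        {t}\n")
        fh.write("    ;\nEND;\n\n")
        fh.write("BEGIN CHARACTERS;\n")
        fh.write(f"    DIMENSIONS NCHAR={presence.shape[1]};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
        fh.write("    MATRIX\n")
        for t, row in zip(taxa, values):
            fh.write(f"        {t:<{width}}  {''.join(str(int(v)) for v in row)}\n")
        fh.write("    ;\nEND;\n")
    return path


def with_termini(genome: PhageGenome, termini_class: str, repeat_length: int | None = None) -> PhageGenome:
    """Return a copy of ``genome`` with termini metadata attached.

    Termini class is metadata only — it is read from records or supplied by
    the caller, never inferred from sequence.
    """
    return replace(genome, termini_class=termini_class, termini_repeat_length=repeat_length)
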