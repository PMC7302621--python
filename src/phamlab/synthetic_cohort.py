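"""Synthetic phage cohorts with known ground truth.

The generator emulates the structure a comparative phage-genomics pipeline
has to recover: protein families shared within planted clusters, tunable
nucleotide divergence (targeting ANI bands), gene-content retention
(targeting GCS levels), intergenic spacers, and planted degenerate motifs
at controlled upstream offsets. Every stage of the pipeline can therefore
be tested offline against a machine-readable truth table.

Divergence is substitution-only: no indels or rearrangements, so ANI and
sketch-distance targets stay analytic. Gene gain/loss is modeled solely
through family retention, which is exactly what gene-content similarity
measures. Genomes are deliberately small (a few kbp); problem sizes are
documented in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .genome_io import Gene, PhageGenome, write_genbank
from .motif_finder import IUPAC, extract_intergenic

__all__ = [
    "PlantedMotifSpec",
    "CohortSpec",
    "CohortTruth",
    "generate_cohort",
    "mutate_sequence",
    "plant_motif",
    "write_cohort",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid, bacterial code, stop codons excluded
_CODONS: dict[str, list[str]] = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _codon = _b1 + _b2 + _b3
            _aa = str(Seq(_codon).translate(table=11))
            if _aa != "*":
                _CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class PlantedMotifSpec:
    """One motif to plant into intergenic spacers of every genome."""

    consensus: str
    copies: int
    max_mismatch: int = 0
    upstream_offset: tuple[int, int] = (20, 30)
    orientation: str = "direct"


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; ``seed`` is mandatory.

    Defaults describe a small cohort with clean cluster structure: four
    clusters of five genomes plus two singletons, ~90% within-cluster gene
    retention (GCS ~ 90%), no cross-cluster family overlap, and 1%
    per-member nucleotide substitution (within-cluster ANI ~ 98%).
    """

    seed: int
    n_clusters: int = 4
    cluster_sizes: Optional[Sequence[int]] = None  # default: 5 each
    n_singletons: int = 2
    families_per_cluster: int = 12
    families_per_singleton: int = 10
    family_universe_size: Optional[int] = None  # default: exactly as needed
    within_cluster_family_retention: float = 0.9
    cross_cluster_family_overlap: float = 0.0
    substitution_rate: float | Sequence[float] = 0.01  # per cluster member
    subclusters_per_cluster: int = 1
    between_subcluster_rate: float = 0.30  # targets between-subcluster ANI ~ 70%
    gene_length_range: tuple[int, int] = (300, 600)  # bp, rounded to codons
    intergenic_len_range: tuple[int, int] = (30, 80)
    planted_motifs: tuple[PlantedMotifSpec, ...] = ()
    gc_target: float = 0.63
    integrase_genomes: int = 0
    fraction_forward: float = 0.8

    def __post_init__(self) -> None:
        if self.cluster_sizes is None:
            self.cluster_sizes = tuple([5] * self.n_clusters)
        self.cluster_sizes = tuple(self.cluster_sizes)
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes must have n_clusters entries")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 1")
        for name in ("within_cluster_family_retention", "cross_cluster_family_overlap"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.within_cluster_family_retention == 0 and self.families_per_cluster > 0:
            raise ValueError("retention 0 with non-empty templates is infeasible")
        rates = self.substitution_rates
        if any(not 0 <= r < 1 for r in rates):
            raise ValueError("substitution rates must be in [0, 1)")

    @property
    def substitution_rates(self) -> tuple[float, ...]:
        if isinstance(self.substitution_rate, (int, float)):
            return tuple([float(self.substitution_rate)] * self.n_clusters)
        rates = tuple(float(r) for r in self.substitution_rate)
        if len(rates) != self.n_clusters:
            raise ValueError("substitution_rate must be scalar or one per cluster")
        return rates


@dataclass
class CohortTruth:
    """Ground truth emitted alongside a generated cohort."""

    gene_family: dict[str, str] = field(default_factory=dict)
    phage_cluster: dict[str, str] = field(default_factory=dict)  # SINGLETON_* for singletons
    phage_subcluster: dict[str, Optional[str]] = field(default_factory=dict)
    planted_motifs: list[dict] = field(default_factory=list)
    substitution_counts: dict[str, int] = field(default_factory=dict)
    integrase_genes: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Sequence-level helpers


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _random_protein(rng: np.random.Generator, length_aa: int) -> str:
    return "".join(np.array(list(AA20))[rng.integers(0, 20, size=length_aa)])


def _reverse_translate(rng: np.random.Generator, protein: str, gc: float) -> str:
    """Pick codons per residue, weighted toward the GC target."""
    out = []
    for aa in protein:
        codons = _CODONS[aa]
        gcs = np.array([(c.count("G") + c.count("C")) / 3 for c in codons])
        weights = np.exp(-8.0 * np.abs(gcs - gc))
        out.append(codons[rng.choice(len(codons), p=weights / weights.sum())])
    return "".join(out)


def mutate_sequence(
    seq: str, rate: float, rng: np.random.Generator | int
) -> tuple[str, int]:
    """Substitute each site independently with probability ``rate``.

    Substituted sites get a uniformly chosen *different* base. Returns the
    mutated sequence and the realized substitution count.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if rate == 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    sites = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in sites:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii"), int(len(sites))


def _instantiate_consensus(rng: np.random.Generator, consensus: str) -> str:
    """Concrete ACGT instance of a (possibly degenerate, case-encoded) consensus."""
    out = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in consensus")
        options = IUPAC[ch]
        out.append(options[rng.integers(0, len(options))])
    return "".join(out)


def plant_motif(
    genome: PhageGenome,
    consensus: str,
    copies: int,
    max_mismatch: int = 0,
    upstream_offset: tuple[int, int] = (20, 30),
    orientation: str = "direct",
    rng: np.random.Generator | int = 0,
    exclude_starts: Optional[set[int]] = None,
) -> tuple[PhageGenome, list[dict]]:
    """Write motif instances into intergenic spacers upstream of '+' genes.

    Each instance ends ``offset`` bp (sampled from ``upstream_offset``,
    inclusive) before the start codon of the gene that follows its spacer,
    and carries at most ``max_mismatch`` random departures from the
    (concretely instantiated) consensus. Returns the modified genome and
    truth entries with exact coordinates.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if orientation not in ("direct", "inverted"):
        raise ValueError("orientation must be 'direct' or 'inverted'")
    if copies == 0:
        return genome, []
    motif = _instantiate_consensus(rng, consensus)
    L = len(motif)
    fwd_gene_starts = {g.start for g in genome.genes if g.strand == "+"}
    usable = [
        r
        for r in extract_intergenic(genome)
        if r.end in fwd_gene_starts
        and len(r) >= upstream_offset[1] + L
        and r.start not in (exclude_starts or ())
    ]
    if len(usable) < copies:
        raise ValueError(
            f"{genome.phage_id}: only {len(usable)} spacers can host the motif, "
            f"need {copies}"
        )
    chosen = [usable[i] for i in sorted(rng.choice(len(usable), size=copies, replace=False))]
    if exclude_starts is not None:
        exclude_starts.update(r.start for r in chosen)
    seq = list(genome.sequence)
    truth = []
    for region in chosen:
        offset = int(rng.integers(upstream_offset[0], upstream_offset[1] + 1))
        end = region.end - offset
        start = end - L
        n_depart = int(rng.integers(0, max_mismatch + 1))
        instance = list(motif)
        for pos in rng.choice(L, size=n_depart, replace=False):
            current = instance[pos]
            others = [b for b in "ACGT" if b != current]
            instance[pos] = others[rng.integers(0, 3)]
        seq[start:end] = list("".join(instance))
        truth.append(
            {
                "phage_id": genome.phage_id,
                "start": int(start),
                "end": int(end),
                "strand": "+",
                "sequence": "".join(instance),
                "mismatches": n_depart,
                "upstream_offset": offset,
                "orientation": orientation,
            }
        )
    planted = PhageGenome(
        phage_id=genome.phage_id,
        sequence="".join(seq),
        genes=list(genome.genes),
        termini_class=genome.termini_class,
        host=genome.host,
        accession=genome.accession,
    )
    return planted, truth


# ---------------------------------------------------------------------------
# Cohort generation


def _translate_cds(cds: str) -> str:
    return str(Seq(cds).translate(table=11)).replace("*", "X")


def _assemble(
    phage_id: str,
    slots: list[dict],
    terminal_spacer: str,
) -> PhageGenome:
    """Concatenate spacer+gene slots into a genome with gene features."""
    parts: list[str] = []
    genes: list[Gene] = []
    cursor = 0
    for slot in slots:
        parts.append(slot["spacer"])
        cursor += len(slot["spacer"])
        cds = slot["cds"]
        start, end = cursor, cursor + len(cds)
        oriented = cds if slot["strand"] == "+" else str(Seq(cds).reverse_complement())
        parts.append(oriented)
        genes.append(
            Gene(
                gene_id=slot["gene_id"],
                start=start,
                end=end,
                strand=slot["strand"],
                product=slot["product"],
                translation=_translate_cds(cds),
            )
        )
        cursor = end
    parts.append(terminal_spacer)
    return PhageGenome(phage_id=phage_id, sequence="".join(parts), genes=genes)


def _refresh_translations(genome: PhageGenome) -> PhageGenome:
    """Recompute conceptual translations from the (possibly mutated) sequence."""
    genes = []
    for g in genome.genes:
        cds = genome.sequence[g.start : g.end]
        if g.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        genes.append(
            Gene(g.gene_id, g.start, g.end, g.strand, g.product, _translate_cds(cds), g.is_trna)
        )
    return PhageGenome(
        phage_id=genome.phage_id,
        sequence=genome.sequence,
        genes=genes,
        termini_class=genome.termini_class,
        host=genome.host,
        accession=genome.accession,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[PhageGenome], CohortTruth]:
    """Generate a cohort of phage genomes plus its ground truth.

    Gene families are random proteins reverse-translated toward the GC
    target; each planted cluster samples a family template, members retain
    families with the configured probability and mutate at the cluster's
    substitution rate; singletons draw exclusive families. Spacer sequences
    belong to the template, so unmutated members are nucleotide-identical
    over shared content. Motifs are planted into spacers afterwards, so
    planted instances carry exactly their recorded departures.

    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_shared = int(round(spec.cross_cluster_family_overlap * spec.families_per_cluster))
    n_exclusive = spec.families_per_cluster - n_shared
    needed = (
        n_shared
        + spec.n_clusters * n_exclusive
        + spec.n_singletons * spec.families_per_singleton
    )
    universe_size = spec.family_universe_size or needed
    if universe_size < needed:
        raise ValueError(
            f"family_universe_size {universe_size} < {needed} families required"
        )

    lo, hi = spec.gene_length_range
    # Families are unrelated by construction: a candidate protein that
    # chance-aligns near the default pham link rule (with a safety margin,
    # so nucleotide-level mutation cannot push it over) is resampled.
    from .pham_builder import LinkRule, make_aligner, score_protein_pair

    guard_rule = LinkRule()
    guard_aligner = make_aligner(guard_rule)

    def related(a: str, b: str) -> bool:
        s = score_protein_pair(a, b, guard_rule, aligner=guard_aligner)
        return s.percent_identity >= 27.5 and s.coverage >= 0.4

    families = []
    accepted_proteins: list[str] = []
    for k in range(universe_size):
        aa_len = max(10, int(rng.integers(lo, hi + 1)) // 3)
        for _ in range(20):
            protein = _random_protein(rng, aa_len)
            if not any(related(protein, other) for other in accepted_proteins):
                break
        else:
            raise RuntimeError("could not sample a dissimilar family protein")
        accepted_proteins.append(protein)
        families.append(
            {
                "family_id": f"fam_{k:04d}",
                "cds": _reverse_translate(rng, protein, spec.gc_target),
                "strand": "+" if rng.random() < spec.fraction_forward else "-",
            }
        )
    shared_pool = families[:n_shared]
    cursor = n_shared

    def spacer(length_range=spec.intergenic_len_range) -> str:
        return _random_dna(rng, int(rng.integers(length_range[0], length_range[1] + 1)), spec.gc_target)

    truth = CohortTruth()
    genomes: list[PhageGenome] = []
    rates = spec.substitution_rates

    for ci in range(spec.n_clusters):
        template = shared_pool + families[cursor : cursor + n_exclusive]
        cursor += n_exclusive
        template_spacers = [spacer() for _ in template]
        terminal = spacer()
        # subcluster templates: shared divergence from the cluster template
        sub_templates: list[list[str]] = []
        for si in range(spec.subclusters_per_cluster):
            if si == 0 or spec.subclusters_per_cluster == 1:
                sub_templates.append([f["cds"] for f in template])
            else:
                diverged = []
                for f in template:
                    mutated, _ = mutate_sequence(f["cds"], spec.between_subcluster_rate, rng)
                    diverged.append(mutated)
                sub_templates.append(diverged)
        cluster_label = f"T{ci + 1}"
        for mi in range(spec.cluster_sizes[ci]):
            phage_id = f"syn{cluster_label}_{mi + 1:02d}"
            si = mi % spec.subclusters_per_cluster
            retained = [
                i
                for i in range(len(template))
                if rng.random() < spec.within_cluster_family_retention
            ]
            if not retained:
                retained = [0]
            slots = []
            for gi, i in enumerate(retained):
                gene_id = f"{phage_id}_g{gi + 1:03d}"
                slots.append(
                    {
                        "gene_id": gene_id,
                        "cds": sub_templates[si][i],
                        "strand": template[i]["strand"],
                        "spacer": template_spacers[i],
                        "product": "hypothetical protein",
                    }
                )
                truth.gene_family[gene_id] = template[i]["family_id"]
            genome = _assemble(phage_id, slots, terminal)
            mutated, count = mutate_sequence(genome.sequence, rates[ci], rng)
            genome = PhageGenome(phage_id=phage_id, sequence=mutated, genes=genome.genes)
            used_spacers: set[int] = set()
            for motif_spec in spec.planted_motifs:
                genome, entries = plant_motif(
                    genome,
                    motif_spec.consensus,
                    motif_spec.copies,
                    motif_spec.max_mismatch,
                    motif_spec.upstream_offset,
                    motif_spec.orientation,
                    rng,
                    exclude_starts=used_spacers,
                )
                truth.planted_motifs.extend(entries)
            genome = _refresh_translations(genome)
            truth.substitution_counts[phage_id] = count
            truth.phage_cluster[phage_id] = cluster_label
            truth.phage_subcluster[phage_id] = (
                f"{cluster_label}.{si + 1}" if spec.subclusters_per_cluster > 1 else None
            )
            genomes.append(genome)

    for si in range(spec.n_singletons):
        phage_id = f"synS_{si + 1:02d}"
        template = families[cursor : cursor + spec.families_per_singleton]
        cursor += spec.families_per_singleton
        slots = []
        for gi, f in enumerate(template):
            gene_id = f"{phage_id}_g{gi + 1:03d}"
            slots.append(
                {
                    "gene_id": gene_id,
                    "cds": f["cds"],
                    "strand": f["strand"],
                    "spacer": spacer(),
                    "product": "hypothetical protein",
                }
            )
            truth.gene_family[gene_id] = f["family_id"]
        genome = _assemble(phage_id, slots, spacer())
        used_spacers = set()
        for motif_spec in spec.planted_motifs:
            genome, entries = plant_motif(
                genome,
                motif_spec.consensus,
                motif_spec.copies,
                motif_spec.max_mismatch,
                motif_spec.upstream_offset,
                motif_spec.orientation,
                rng,
                exclude_starts=used_spacers,
            )
            truth.planted_motifs.extend(entries)
        genome = _refresh_translations(genome)
        truth.substitution_counts[phage_id] = 0
        truth.phage_cluster[phage_id] = f"SINGLETON_{si + 1}"
        truth.phage_subcluster[phage_id] = None
        genomes.append(genome)

    if spec.integrase_genomes:
        if spec.integrase_genomes > len(genomes):
            raise ValueError("integrase_genomes exceeds cohort size")
        for genome in genomes[: spec.integrase_genomes]:
            g = genome.genes[-1]
            genome.genes[-1] = Gene(
                g.gene_id, g.start, g.end, g.strand, "serine integrase",
                g.translation, g.is_trna,
            )
            truth.integrase_genes.append((genome.phage_id, g.gene_id))

    return genomes, truth


def write_cohort(
    genomes: list[PhageGenome], truth: CohortTruth, outdir: str | Path
) -> Path:
    """Write per-genome GenBank files, a manifest TSV, and the truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "manifest.tsv").open("w") as fh:
        fh.write("phage_id\tfile\tlength_bp\tn_genes\ttrue_cluster\n")
        for g in genomes:
            path = outdir / f"{g.phage_id}.gbk"
            write_genbank(g, path)
            fh.write(
                f"{g.phage_id}\t{path.name}\t{len(g)}\t{len(g.genes)}\t"
                f"{truth.phage_cluster.get(g.phage_id, '')}\n"
            )
    (outdir / "truth.json").write_text(truth.to_json())
    with (outdir / "gene_families.tsv").open("w") as fh:
        fh.write("gene_id\tfamily_id\n")
        for gid, fam in sorted(truth.gene_family.items()):
            fh.write(f"{gid}\t{fam}\n")
    return outdir
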