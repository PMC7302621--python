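"""motif_finder: intergenic extraction, Hamming scans, discovery, consensi."""

import numpy as np
import pytest

from phamlab.genome_io import Gene, PhageGenome
from phamlab.motif_finder import (
    annotate_upstream_distance,
    build_consensus,
    discover_direct_repeats,
    extract_intergenic,
    find_inverted_repeats,
    reverse_complement,
    scan_motif,
    write_hits_gff3,
)

from conftest import make_genome, random_dna


def brute_force_scan(seq: str, consensus: str, max_mismatch: int):
    """Naive all-position Hamming scan (N in consensus matches anything)."""
    L = len(consensus)
    hits = []
    for pos in range(len(seq) - L + 1):
        mm = sum(
            1
            for s, c in zip(seq[pos : pos + L], consensus)
            if c != "N" and s != c
        )
        if mm <= max_mismatch:
            hits.append((pos, mm))
    return hits


class TestExtractIntergenic:
    def test_interval_arithmetic(self):
        genome = make_genome("t", 300, ((9, 120, "+"), (149, 270, "-")))
        regions = [(r.start, r.end) for r in extract_intergenic(genome)]
        assert regions == [(0, 9), (120, 149), (270, 300)]

    def test_fully_tiled_genome_has_none(self):
        genome = make_genome("t", 300, ((0, 150, "+"), (150, 300, "+")))
        assert extract_intergenic(genome) == []

    def test_overlapping_genes_merged(self):
        genome = make_genome("t", 300, ((10, 120, "+"), (100, 200, "-")))
        regions = [(r.start, r.end) for r in extract_intergenic(genome)]
        assert regions == [(0, 10), (200, 300)]

    def test_downstream_gene_resolved_per_strand(self):
        genome = make_genome("t", 300, ((50, 120, "-"), (149, 270, "+")))
        region = [r for r in extract_intergenic(genome) if r.start == 120][0]
        assert region.downstream_fwd == "t_g002"
        assert region.downstream_rev == "t_g001"

    def test_min_len_filter(self):
        genome = make_genome("t", 300, ((9, 120, "+"), (149, 270, "-")))
        regions = extract_intergenic(genome, min_len=20)
        assert [(r.start, r.end) for r in regions] == [(120, 149), (270, 300)]


class TestScanMotif:
    def test_zero_mismatch_equals_substring_search(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 2000)
        motif = seq[500:515]
        genome = PhageGenome(phage_id="t", sequence=seq)
        hits = scan_motif(genome, motif, max_mismatch=0, strands="fwd")
        naive = [p for p, _ in brute_force_scan(seq, motif, 0)]
        assert [h.start for h in hits] == naive
        assert 500 in naive

    @pytest.mark.parametrize("L,mm", [(13, 1), (18, 2)])
    def test_matches_brute_force_scan(self, L, mm):
        rng = np.random.default_rng(L * 10 + mm)
        seq = random_dna(rng, 5000)
        consensus = random_dna(rng, L)
        genome = PhageGenome(phage_id="t", sequence=seq)
        hits = scan_motif(genome, consensus, max_mismatch=mm, strands="fwd")
        assert [(h.start, h.mismatches) for h in hits] == brute_force_scan(
            seq, consensus, mm
        )

    def test_planted_sas_motif_found_exactly(self):
        """10 planted copies of the 13-bp start-associated consensus, <=1 mm."""
        rng = np.random.default_rng(3)
        motif = "GGGAAAGGACCCC"
        parts = []
        starts = []
        pos = 0
        for i in range(10):
            gap = random_dna(rng, 300)
            # avoid chance pre-existing near-matches in the random spacer
            while brute_force_scan(gap + motif[: len(gap) % 13], motif, 1):
                gap = random_dna(rng, 300)
            instance = list(motif)
            if i % 2:
                p = rng.integers(0, 13)
                instance[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[instance[p]]
            parts += [gap, "".join(instance)]
            pos += len(gap)
            starts.append(pos)
            pos += 13
        genome = PhageGenome(phage_id="t", sequence="".join(parts))
        hits = scan_motif(genome, motif, max_mismatch=1, strands="fwd")
        assert [h.start for h in hits] == starts

    def test_reverse_strand_hits_mirrored(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 3000)
        consensus = "GGGAAAGGACCCC"
        genome = PhageGenome(phage_id="t", sequence=seq)
        rc_genome = PhageGenome(phage_id="t", sequence=reverse_complement(seq))
        fwd = scan_motif(genome, consensus, max_mismatch=2)
        rc = scan_motif(rc_genome, consensus, max_mismatch=2)
        n = len(seq)
        mirrored = sorted((n - h.end, "-" if h.strand == "+" else "+") for h in rc)
        assert sorted((h.start, h.strand) for h in fwd) == mirrored

    def test_intergenic_search_space_respects_genes(self):
        rng = np.random.default_rng(5)
        motif = "GGGAAAGGACCCC"
        seq = random_dna(rng, 200) + motif + random_dna(rng, 200) + motif + random_dna(rng, 100)
        # first copy sits inside a gene, second in open space
        genome = PhageGenome(
            phage_id="t", sequence=seq,
            genes=[Gene("g1", 150, 300, "+", "", "M" * 50)],
        )
        hits = scan_motif(genome, motif, 0, search_space="intergenic", strands="fwd")
        assert [h.start for h in hits] == [413]

    def test_non_iupac_consensus_rejected(self):
        genome = make_genome("t", 100)
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif(genome, "ACGTQ", 0)


class TestBuildConsensus:
    def test_identical_occurrences_all_uppercase(self):
        assert build_consensus(["ACGT"] * 5) == "ACGT"

    def test_nine_of_twelve_is_lowercase(self):
        column = ["A"] * 9 + ["C"] * 3
        occurrences = [b + "GGG" for b in column]
        assert build_consensus(occurrences)[0] == "a"

    def test_six_of_twelve_is_n(self):
        column = ["G"] * 6 + ["A"] * 3 + ["C"] * 3
        occurrences = [b + "TTT" for b in column]
        assert build_consensus(occurrences)[0] == "N"

    def test_tie_broken_alphabetically(self):
        occurrences = ["ATTT", "CTTT"]  # A and C tie at 50%
        assert build_consensus(occurrences, partial_frac=0.5)[0] == "a"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            build_consensus(["ACGT", "ACG"])


def _spacer_genome(phage_id, rng, n_spacers=14, spacer_len=60, gene_len=300):
    """Genome alternating genes and wide spacers, for planting."""
    parts, genes = [], []
    pos = 0
    for i in range(n_spacers):
        parts.append(random_dna(rng, spacer_len))
        pos += spacer_len
        genes.append(Gene(f"{phage_id}_g{i+1:02d}", pos, pos + gene_len, "+", "",
                          "M" * (gene_len // 3)))
        parts.append(random_dna(rng, gene_len))
        pos += gene_len
    return PhageGenome(phage_id=phage_id, sequence="".join(parts), genes=genes)


def _plant(genome, motif, positions_in_spacers, mm_each=0, rng=None):
    """Overwrite the start of the chosen intergenic regions with the motif."""
    regions = extract_intergenic(genome)
    seq = list(genome.sequence)
    starts = []
    for idx in positions_in_spacers:
        r = regions[idx]
        instance = list(motif)
        if mm_each and rng is not None:
            p = rng.integers(0, len(motif))
            instance[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[instance[p]]
        seq[r.start : r.start + len(motif)] = instance
        starts.append(r.start)
    return (
        PhageGenome(phage_id=genome.phage_id, sequence="".join(seq),
                    genes=list(genome.genes)),
        starts,
    )


class TestDiscoverDirectRepeats:
    def test_recovers_planted_twelve_copy_motif(self):
        rng = np.random.default_rng(6)
        motif = "TAGACTCTAGGTGTAAGC"  # 18 bp
        genome = _spacer_genome("t", rng)
        genome, starts = _plant(genome, motif, range(12), mm_each=1, rng=rng)
        models = discover_direct_repeats(genome, length=18, min_copies=5, max_mismatch=2)
        assert len(models) == 1
        model = models[0]
        assert model.copy_number == 12
        assert sorted(h.start for h in model.occurrences) == sorted(starts)
        assert model.consensus.upper() == motif

    def test_no_models_in_unplanted_random_sequence(self):
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            genome = PhageGenome(phage_id=f"r{seed}", sequence=random_dna(rng, 5000))
            models = discover_direct_repeats(
                genome, length=18, min_copies=5, max_mismatch=1, search_space="whole"
            )
            assert models == []

    def test_two_planted_motifs_stay_separate(self):
        rng = np.random.default_rng(7)
        motif_a = "TAGACTCTAGGTGTAAGC"
        motif_b = "CCGGTTAACCGGTTAACG"
        genome = _spacer_genome("t", rng)
        genome, starts_a = _plant(genome, motif_a, range(6))
        genome, starts_b = _plant(genome, motif_b, range(6, 12))
        models = discover_direct_repeats(genome, length=18, min_copies=5, max_mismatch=2)
        assert len(models) == 2
        found = {m.consensus.upper(): {h.start for h in m.occurrences} for m in models}
        assert found[motif_a] == set(starts_a)
        assert found[motif_b] == set(starts_b)

    def test_rescan_with_own_consensus_recovers_occurrences(self):
        rng = np.random.default_rng(8)
        motif = "GATTACAGATTACAGATT"
        genome = _spacer_genome("t", rng)
        genome, _ = _plant(genome, motif, range(8), mm_each=1, rng=rng)
        models = discover_direct_repeats(genome, length=18, min_copies=5, max_mismatch=2)
        assert models
        model = models[0]
        hits = scan_motif(genome, model.consensus, model.max_mismatch,
                          search_space="intergenic", strands="fwd")
        assert {h.start for h in model.occurrences} <= {h.start for h in hits}


class TestInvertedRepeats:
    def test_consensus_structure_hit(self):
        """The arm-NN-arm inverted site is found with zero arm mismatches."""
        rng = np.random.default_rng(9)
        site = "GATCAACC" + "AT" + "GGTTGATC"
        seq = random_dna(rng, 500) + site + random_dna(rng, 500)
        genome = PhageGenome(phage_id="t", sequence=seq)
        hits = find_inverted_repeats(genome, arm=8, spacer=2, max_mismatch=0,
                                     search_space="whole")
        assert any(h.start == 500 and h.mismatches == 0 for h in hits)

    def test_poly_a_arms(self):
        seq = "GCGCGC" + "AAAAAAAA" + "TT" + "TTTTTTTT" + "GCGCGC"
        genome = PhageGenome(phage_id="t", sequence=seq)
        hits = find_inverted_repeats(genome, arm=8, spacer=2, max_mismatch=0,
                                     search_space="whole")
        assert any(h.start == 6 for h in hits)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        seq = random_dna(rng, 10000)
        genome = PhageGenome(phage_id="t", sequence=seq)
        hits = find_inverted_repeats(genome, arm=5, spacer=2, max_mismatch=1,
                                     search_space="whole")
        expected = []
        for pos in range(len(seq) - 12 + 1):
            left = seq[pos : pos + 5]
            right = seq[pos + 7 : pos + 12]
            mm = sum(x != y for x, y in zip(left, reverse_complement(right)))
            if mm <= 1:
                expected.append((pos, mm))
        assert [(h.start, h.mismatches) for h in hits] == expected

    def test_arm_minimum_enforced(self):
        genome = make_genome("t", 100)
        with pytest.raises(ValueError, match="arm"):
            find_inverted_repeats(genome, arm=3)


class TestUpstreamDistance:
    def test_hand_computed_distance(self):
        """Motif ending at 100 with a '+' gene starting at 121 is 21 bp upstream."""
        genome = make_genome("t", 400, ((121, 301, "+"),))
        hits = scan_motif(genome, genome.sequence[87:100], 0,
                          search_space="whole", strands="fwd")
        hit = [h for h in hits if h.end == 100][0]
        annotated = annotate_upstream_distance([hit], genome)
        assert annotated[0].upstream_distance == 21

    def test_hit_inside_gene_not_annotated(self):
        genome = make_genome("t", 400, ((50, 350, "+"),))
        hits = scan_motif(genome, genome.sequence[100:113], 0,
                          search_space="whole", strands="fwd")
        hit = [h for h in hits if h.start == 100][0]
        assert annotate_upstream_distance([hit], genome)[0].upstream_distance is None

    def test_no_gene_within_window(self):
        genome = make_genome("t", 2000, ((1600, 1900, "+"),))
        hits = scan_motif(genome, genome.sequence[0:13], 0,
                          search_space="whole", strands="fwd")
        hit = [h for h in hits if h.start == 0][0]
        assert annotate_upstream_distance([hit], genome, window=500)[0].upstream_distance is None

    def test_reverse_strand_distance(self):
        """For a '-' hit the distance runs from the hit start back to the gene end."""
        genome = make_genome("t", 400, ((50, 200, "-"),))
        motif = reverse_complement(genome.sequence[225:238])
        hits = scan_motif(genome, motif, 0, search_space="whole")
        hit = [h for h in hits if h.start == 225 and h.strand == "-"][0]
        assert annotate_upstream_distance([hit], genome)[0].upstream_distance == 25

    def test_planted_offset_round_trip(self):
        from phamlab.synthetic_cohort import plant_motif

        rng = np.random.default_rng(11)
        genome = _spacer_genome("t", rng)
        planted, truth = plant_motif(genome, "TAGACTCTAGGTGTAAGC", copies=5,
                                     upstream_offset=(25, 25), rng=rng)
        hits = scan_motif(planted, "TAGACTCTAGGTGTAAGC", 0,
                          search_space="intergenic", strands="fwd")
        annotated = annotate_upstream_distance(hits, planted)
        by_start = {h.start: h for h in annotated}
        for entry in truth:
            assert by_start[entry["start"]].upstream_distance == 25


class TestGff3Output:
    def test_one_based_coordinates_and_attributes(self, tmp_path):
        genome = make_genome("t", 400, ((121, 301, "+"),))
        hits = scan_motif(genome, genome.sequence[87:100], 0,
                          search_space="whole", strands="fwd")
        hits = annotate_upstream_distance(hits, genome)
        path = write_hits_gff3(hits, tmp_path / "hits.gff3", model_id="m1")
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        fields = [ln.split("\t") for ln in lines[1:] if ln.startswith("t")]
        target = [f for f in fields if f[3] == "88" and f[4] == "100"]
        assert target and "upstream_distance=21" in target[0][8]
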