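"""Intergenic regions and degenerate repeated-motif discovery.

Motif matching is substitution-only (Hamming distance over fixed-length
windows, no indels), matching how "departures" from a consensus are
counted in phage motif descriptions. Consensi are case-encoded: uppercase
positions are conserved in every occurrence, lowercase positions in at
least ``partial_frac`` of them, and positions below that are written N.
Discovery is deterministic: seeds are processed in genome coordinate order
and nothing is randomized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .genome_io import Gene, PhageGenome

__all__ = [
    "IntergenicRegion",
    "MotifHit",
    "MotifModel",
    "extract_intergenic",
    "scan_motif",
    "discover_direct_repeats",
    "find_inverted_repeats",
    "build_consensus",
    "annotate_upstream_distance",
    "reverse_complement",
    "write_hits_gff3",
    "model_summary",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IntergenicRegion:
    """A maximal genome interval covered by no gene (0-based half-open)."""

    phage_id: str
    start: int
    end: int
    downstream_fwd: Optional[str] = None  # nearest '+' gene starting at/after end
    downstream_rev: Optional[str] = None  # nearest '-' gene ending at/before start

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start``/``end`` are forward-strand coordinates."""

    phage_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mismatches: int
    sequence: str = ""  # motif-oriented (reverse-complemented for '-' hits)
    upstream_distance: Optional[int] = None


@dataclass
class MotifModel:
    """A discovered motif: case-encoded consensus plus its occurrences."""

    consensus: str
    length: int
    max_mismatch: int
    orientation: Literal["direct", "inverted"]
    occurrences: list[MotifHit] = field(default_factory=list)
    full_frac: float = 1.0
    partial_frac: float = 0.75

    @property
    def copy_number(self) -> int:
        return len(self.occurrences)


# ---------------------------------------------------------------------------
# Intergenic extraction


def extract_intergenic(genome: PhageGenome, min_len: int = 1) -> list[IntergenicRegion]:
    """Maximal intervals of the genome not covered by any gene.

    The union of gene intervals is subtracted from [0, L); regions shorter
    than ``min_len`` are dropped. The nearest downstream gene is resolved
    per strand ('+': first gene starting at or after the region end;
    '-': last gene ending at or before the region start).
    """
    length = len(genome)
    covered: list[tuple[int, int]] = []
    for g in sorted(genome.genes, key=lambda g: (g.start, g.end)):
        if covered and g.start <= covered[-1][1]:
            covered[-1] = (covered[-1][0], max(covered[-1][1], g.end))
        else:
            covered.append((g.start, g.end))
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for s, e in covered:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        gaps.append((cursor, length))
    fwd_starts = sorted((g.start, g.gene_id) for g in genome.genes if g.strand == "+")
    rev_ends = sorted((g.end, g.gene_id) for g in genome.genes if g.strand == "-")
    regions = []
    for s, e in gaps:
        if e - s < min_len:
            continue
        down_fwd = next((gid for start, gid in fwd_starts if start >= e), None)
        down_rev = next((gid for end, gid in reversed(rev_ends) if end <= s), None)
        regions.append(IntergenicRegion(genome.phage_id, s, e, down_fwd, down_rev))
    return regions


# ---------------------------------------------------------------------------
# Hamming scanning

_BASE_IDX = np.full(256, 4, dtype=np.int64)  # N and anything odd -> column 4
for _i, _b in enumerate("ACGT"):
    _BASE_IDX[ord(_b)] = _i


def _consensus_table(consensus: str) -> np.ndarray:
    """(L, 5) boolean table: allowed[i, base] for ACGT plus N-in-genome."""
    table = np.zeros((len(consensus), 5), dtype=bool)
    for i, ch in enumerate(consensus.upper()):
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in consensus")
        for b in IUPAC[ch]:
            table[i, "ACGT".index(b)] = True
        if ch == "N":
            table[i, 4] = True  # N in the genome only matches a consensus N
    return table


def _mismatch_counts(seq: str, table: np.ndarray) -> np.ndarray:
    """Hamming mismatches of every length-L window of ``seq`` vs the table."""
    L = table.shape[0]
    codes = _BASE_IDX[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if len(codes) < L:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    matched = table[np.arange(L)[None, :], windows]
    return L - matched.sum(axis=1)


def _search_segments(
    genome: PhageGenome, search_space: str, min_len: int
) -> list[tuple[int, str]]:
    """(offset, sequence) segments to scan for the requested search space."""
    if search_space == "whole":
        return [(0, genome.sequence)]
    if search_space == "intergenic":
        return [
            (r.start, genome.sequence[r.start : r.end])
            for r in extract_intergenic(genome, min_len=min_len)
        ]
    raise ValueError(f"unknown search_space {search_space!r}")


def scan_motif(
    genome: PhageGenome,
    consensus: str,
    max_mismatch: int = 0,
    search_space: Literal["intergenic", "whole"] = "whole",
    strands: Literal["fwd", "both"] = "both",
) -> list[MotifHit]:
    """All windows within ``max_mismatch`` Hamming distance of the consensus.

    Case is ignored; N (and other IUPAC degeneracies) in the consensus
    match their base sets. Overlapping hits are reported. Reverse-strand
    hits are matched against the reverse complement and reported at their
    forward-strand coordinates with strand '-'.
    """
    consensus = consensus.upper()
    if len(consensus) < 4:
        raise ValueError("consensus must be at least 4 bp")
    table = _consensus_table(consensus)
    L = len(consensus)
    hits: list[MotifHit] = []
    for offset, segment in _search_segments(genome, search_space, min_len=L):
        counts = _mismatch_counts(segment, table)
        for pos in np.nonzero(counts <= max_mismatch)[0]:
            start = offset + int(pos)
            hits.append(
                MotifHit(
                    genome.phage_id, start, start + L, "+",
                    int(counts[pos]), segment[pos : pos + L],
                )
            )
        if strands == "both":
            rc = reverse_complement(segment)
            counts = _mismatch_counts(rc, table)
            for pos in np.nonzero(counts <= max_mismatch)[0]:
                start = offset + len(segment) - int(pos) - L
                hits.append(
                    MotifHit(
                        genome.phage_id, start, start + L, "-",
                        int(counts[pos]), rc[pos : pos + L],
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Consensus building


def build_consensus(
    occurrences: Sequence[str], full_frac: float = 1.0, partial_frac: float = 0.75
) -> str:
    """Case-encoded consensus of aligned equal-length occurrence sequences.

    Per column the majority base (ties broken alphabetically) is written
    uppercase when its frequency reaches ``full_frac``, lowercase when it
    reaches ``partial_frac``, and N otherwise.
    """
    if len(occurrences) < 2:
        raise ValueError("need at least 2 occurrences")
    lengths = {len(s) for s in occurrences}
    if len(lengths) != 1:
        raise ValueError(f"occurrences have unequal lengths {sorted(lengths)}")
    n = len(occurrences)
    out = []
    for column in zip(*(s.upper() for s in occurrences)):
        counts = {b: column.count(b) for b in "ACGT"}
        top = max(counts.values())
        best = sorted(b for b, c in counts.items() if c == top)[0]
        freq = top / n
        if freq >= full_frac:
            out.append(best)
        elif freq >= partial_frac:
            out.append(best.lower())
        else:
            out.append("N")
    return "".join(out)


# ---------------------------------------------------------------------------
# Direct-repeat discovery


def discover_direct_repeats(
    genomes: PhageGenome | Iterable[PhageGenome],
    length: int = 18,
    min_copies: int = 3,
    max_mismatch: int = 2,
    search_space: Literal["intergenic", "whole"] = "intergenic",
    full_frac: float = 1.0,
    partial_frac: float = 0.75,
    max_rounds: int = 10,
) -> list[MotifModel]:
    """Greedy seed-and-refine discovery of repeated degenerate motifs.

    Every L-mer of the search space (forward strand, genome coordinate
    order) seeds a candidate: windows within ``max_mismatch`` are gathered,
    and if there are at least ``min_copies`` a case-encoded consensus is
    built and re-scanned to a fixed point (at most ``max_rounds`` rounds).
    Models whose occurrence sets duplicate an earlier model are dropped;
    results are sorted by copy number (descending).
    """
    if length < 8:
        raise ValueError("length must be >= 8")
    if min_copies < 3:
        raise ValueError("min_copies must be >= 3")
    if isinstance(genomes, PhageGenome):
        genomes = [genomes]
    genomes = list(genomes)

    windows: list[tuple[str, int, str]] = []  # (phage_id, start, sequence)
    for genome in genomes:
        for offset, segment in _search_segments(genome, search_space, min_len=length):
            for pos in range(len(segment) - length + 1):
                windows.append((genome.phage_id, offset + pos, segment[pos : pos + length]))

    if not windows:
        return []
    codes = _BASE_IDX[
        np.frombuffer(
            "".join(w[2] for w in windows).upper().encode("ascii"), dtype=np.uint8
        )
    ].reshape(len(windows), length)
    positions = np.arange(length)[None, :]

    def gather(consensus: str) -> np.ndarray:
        table = _consensus_table(consensus)
        matched = table[positions, codes]
        return np.nonzero((length - matched.sum(axis=1)) <= max_mismatch)[0]

    pos_index = {(w[0], w[1]): i for i, w in enumerate(windows)}

    def converge(occ_idx: np.ndarray, consensus: str) -> tuple[np.ndarray, str]:
        for _ in range(max_rounds):
            new_idx = gather(consensus)
            if len(new_idx) < min_copies:
                break
            new_consensus = build_consensus(
                [windows[i][2] for i in new_idx], full_frac, partial_frac
            )
            if np.array_equal(new_idx, occ_idx) and new_consensus == consensus:
                break
            occ_idx, consensus = new_idx, new_consensus
        return occ_idx, consensus

    def frame_quality(consensus: str) -> tuple[int, int]:
        return (
            sum(c != "N" for c in consensus),
            sum(c.isupper() for c in consensus),
        )

    models: list[MotifModel] = []
    seen_occurrence_sets: set[frozenset[tuple[str, int]]] = set()
    claimed: set[tuple[str, int]] = set()
    for seed_idx, (phage_id, start, seed) in enumerate(windows):
        if (phage_id, start) in claimed or "N" in seed:
            continue
        occ_idx = gather(seed)
        if len(occ_idx) < min_copies:
            continue
        consensus = build_consensus([windows[i][2] for i in occ_idx], full_frac, partial_frac)
        occ_idx, consensus = converge(occ_idx, consensus)
        if len(occ_idx) < min_copies:
            continue
        # frame refinement: a seed one or two bases off the true repeat frame
        # can converge first; slide the frame and keep the most informative
        # consensus (most non-N, then most fully conserved columns)
        best = (frame_quality(consensus), 0)
        for shift in (-3, -2, -1, 1, 2, 3):
            shifted = [
                pos_index.get((windows[i][0], windows[i][1] + shift)) for i in occ_idx
            ]
            if any(j is None for j in shifted):
                continue
            quality = frame_quality(
                build_consensus([windows[j][2] for j in shifted], full_frac, partial_frac)
            )
            if (quality, -abs(shift)) > (best[0], -abs(best[1])):
                best = (quality, shift)
        if best[1] != 0:
            occ_idx = np.array(
                [pos_index[(windows[i][0], windows[i][1] + best[1])] for i in occ_idx]
            )
            consensus = build_consensus(
                [windows[i][2] for i in occ_idx], full_frac, partial_frac
            )
            occ_idx, consensus = converge(occ_idx, consensus)
        if len(occ_idx) < min_copies:
            continue
        coords = frozenset((windows[i][0], windows[i][1]) for i in occ_idx)
        if coords in seen_occurrence_sets:
            continue
        seen_occurrence_sets.add(coords)
        # claim every window overlapping an occurrence so shifted variants of
        # this model do not seed near-duplicate models
        for pid, pos in coords:
            claimed.update((pid, s) for s in range(pos - length + 1, pos + length))
        table = _consensus_table(consensus)
        occurrences = []
        for i in occ_idx:
            pid, pos, seq = windows[i]
            occ_codes = _BASE_IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            mm = int(length - table[np.arange(length), occ_codes].sum())
            occurrences.append(MotifHit(pid, pos, pos + length, "+", mm, seq))
        models.append(
            MotifModel(
                consensus=consensus,
                length=length,
                max_mismatch=max_mismatch,
                orientation="direct",
                occurrences=occurrences,
                full_frac=full_frac,
                partial_frac=partial_frac,
            )
        )
    models.sort(key=lambda m: (-m.copy_number, m.occurrences[0].start))
    return models


# ---------------------------------------------------------------------------
# Inverted repeats


def find_inverted_repeats(
    genome: PhageGenome,
    arm: int = 8,
    spacer: int = 2,
    max_mismatch: int = 0,
    search_space: Literal["intergenic", "whole"] = "intergenic",
) -> list[MotifHit]:
    """Windows arm + spacer + arm where the arms are reverse-complementary.

    Mismatches are counted between the left arm and the reverse complement
    of the right arm; the spacer is unconstrained. The default geometry
    (arm 8, spacer 2) gives an 18-bp site. Inverted repeats read the same
    on both strands, so hits are reported once, on '+'.
    """
    if arm < 4:
        raise ValueError("arm must be >= 4")
    if spacer < 0:
        raise ValueError("spacer must be >= 0")
    total = 2 * arm + spacer
    hits: list[MotifHit] = []
    for offset, segment in _search_segments(genome, search_space, min_len=total):
        seq = segment.upper()
        for pos in range(len(seq) - total + 1):
            left = seq[pos : pos + arm]
            right = seq[pos + arm + spacer : pos + total]
            rc_right = reverse_complement(right)
            mm = sum(
                1
                for x, y in zip(left, rc_right)
                if x == "N" or y == "N" or x != y
            )
            if mm <= max_mismatch:
                start = offset + pos
                hits.append(
                    MotifHit(
                        genome.phage_id, start, start + total, "+", mm,
                        seq[pos : pos + total],
                    )
                )
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# Upstream distance


def annotate_upstream_distance(
    hits: Sequence[MotifHit], genome: PhageGenome, window: int = 500
) -> list[MotifHit]:
    """Attach the distance from each hit to the next translation start.

    For a '+' hit the distance runs from the hit end to the start of the
    first '+' gene at or after it; for a '-' hit it is measured on the
    reverse complement (hit start back to the end of the nearest '-'
    gene). Hits overlapping a gene, or with no start within ``window`` bp,
    get no annotation. Both endpoints are exclusive: a motif ending at 100
    with a gene starting at 121 is 21 bp upstream.
    """
    fwd_starts = sorted(g.start for g in genome.genes if g.strand == "+")
    rev_ends = sorted(g.end for g in genome.genes if g.strand == "-")
    intervals = [(g.start, g.end) for g in genome.genes]

    def overlaps_gene(h: MotifHit) -> bool:
        return any(h.start < e and h.end > s for s, e in intervals)

    out = []
    for h in hits:
        distance: Optional[int] = None
        if not overlaps_gene(h):
            if h.strand == "+":
                nxt = next((s for s in fwd_starts if s >= h.end), None)
                if nxt is not None and nxt - h.end <= window:
                    distance = nxt - h.end
            else:
                prv = next((e for e in reversed(rev_ends) if e <= h.start), None)
                if prv is not None and h.start - prv <= window:
                    distance = h.start - prv
        out.append(replace(h, upstream_distance=distance))
    return out


# ---------------------------------------------------------------------------
# Output


def write_hits_gff3(
    hits: Sequence[MotifHit], path: str | Path, model_id: str = "motif", feature_type: str = "sequence_motif"
) -> Path:
    """Write hits as GFF3 (1-based inclusive coordinates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(hits, start=1):
            attrs = [f"ID={model_id}_{i}", f"mismatches={h.mismatches}", f"model={model_id}"]
            if h.upstream_distance is not None:
                attrs.append(f"upstream_distance={h.upstream_distance}")
            fh.write(
                "\t".join(
                    [
                        h.phage_id, "phamlab", feature_type,
                        str(h.start + 1), str(h.end), ".", h.strand, ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    return path


def model_summary(models: Sequence[MotifModel]):
    """Summary table (one row per model) for discovered motifs."""
    import pandas as pd

    rows = [
        (f"model_{i}", m.consensus, m.length, m.orientation, m.copy_number, m.max_mismatch)
        for i, m in enumerate(models, start=1)
    ]
    return pd.DataFrame(
        rows,
        columns=["model_id", "consensus", "length", "orientation", "copies", "max_mismatch"],
    )
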