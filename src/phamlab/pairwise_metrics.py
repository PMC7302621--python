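"""All-vs-all genome comparisons.

Three complementary metrics:

* gene-content similarity/dissimilarity (GCS/GCD) over shared phams:
  GCS = 100 * 1/2 (|Pa & Pb|/|Pa| + |Pa & Pb|/|Pb|), GCD = 1 - GCS/100;
* fragment-based reciprocal average nucleotide identity (ANI): the query is
  chopped into 1020-bp fragments, each placed in the subject and refined by
  local alignment, fragments failing 30% identity / 70% coverage filters
  are discarded, and the two directions are averaged;
* sketch-based nucleotide distance: bottom-s MinHash over canonical k-mers
  with the Mash transform d = -(1/k) ln(2j/(1+j)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np
from Bio import Align

from .genome_io import PhageGenome
from .pham_builder import PhamSet

__all__ = [
    "SymmetricMatrix",
    "AniParams",
    "SketchParams",
    "gene_content_similarity",
    "gene_content_dissimilarity",
    "ani",
    "nucleotide_distance",
    "minhash_sketch",
    "all_pairs",
    "long_form",
]


@dataclass
class SymmetricMatrix:
    """Labeled all-vs-all matrix for one metric."""

    labels: list[str]
    values: np.ndarray
    metric_name: str
    parameters: dict = field(default_factory=dict)

    SELF_VALUES = {"gcs": 100.0, "gcd": 0.0, "ani": 100.0, "nucleotide_distance": 0.0}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix is not symmetric within 1e-9")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != n:
            raise ValueError("duplicate labels")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: list[str]) -> "SymmetricMatrix":
        idx = [self._index[lab] for lab in labels]
        return SymmetricMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            metric_name=self.metric_name,
            parameters=dict(self.parameters),
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class AniParams:
    """Fragment-based ANI parameters (classic 1020-bp reciprocal method)."""

    fragment_length: int = 1020
    step: int = 1020
    min_identity: float = 0.3  # fraction, over aligned columns
    min_coverage: float = 0.7  # aligned columns / fragment length
    min_terminal_fragment: int = 100  # shorter trailing fragments are dropped
    placement_margin: int = 100  # bp of slack around the edlib placement

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise ValueError("fragment_length must be >= 100")
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class SketchParams:
    """MinHash sketch parameters (canonical k-mers, bottom-s sketch)."""

    k: int = 21
    sketch_size: int = 1000
    seed: int = 42

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 32:
            raise ValueError("k must be in [1, 32]")
        if self.sketch_size < 1:
            raise ValueError("sketch_size must be >= 1")


# ---------------------------------------------------------------------------
# Gene content


def gene_content_similarity(a: str, b: str, phams: PhamSet) -> float:
    """GCS percent: averaged shared-pham fraction across both genomes."""
    pa, pb = phams.phams_of(a), phams.phams_of(b)
    if not pa or not pb:
        raise ValueError(f"GCS undefined: {a if not pa else b} has no phams")
    shared = len(pa & pb)
    return 100.0 * 0.5 * (shared / len(pa) + shared / len(pb))


def gene_content_dissimilarity(a: str, b: str, phams: PhamSet) -> float:
    """GCD = 1 - GCS/100, a dissimilarity in [0, 1]."""
    return 1.0 - gene_content_similarity(a, b, phams) / 100.0


# ---------------------------------------------------------------------------
# Fragment ANI


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def _fragments(seq: str, params: AniParams) -> list[str]:
    if len(seq) <= params.fragment_length:
        return [seq]
    out = []
    for start in range(0, len(seq), params.step):
        frag = seq[start : start + params.fragment_length]
        if len(frag) >= min(params.min_terminal_fragment, params.fragment_length):
            out.append(frag)
    return out


def _directional_ani(query: str, subject: str, params: AniParams, aligner) -> float:
    kept: list[float] = []
    for frag in _fragments(query, params):
        hit = edlib.align(frag, subject, mode="HW", task="locations")
        locations = hit.get("locations") or []
        if not locations or hit["editDistance"] < 0:
            continue
        loc_start, loc_end = locations[0]
        w0 = max(0, loc_start - params.placement_margin)
        w1 = min(len(subject), loc_end + 1 + params.placement_margin)
        window = subject[w0:w1]
        alignments = aligner.align(frag, window)
        if alignments.score <= 0:
            continue
        counts = alignments[0].counts()
        aligned = counts.identities + counts.mismatches
        cols = aligned + counts.gaps  # BLAST-style: gap columns count
        if cols == 0:
            continue
        identity = counts.identities / cols
        coverage = aligned / len(frag)
        if identity >= params.min_identity and coverage >= params.min_coverage:
            kept.append(identity)
    if not kept:
        return 0.0
    return 100.0 * float(np.mean(kept))


def ani(
    a: PhageGenome | str,
    b: PhageGenome | str,
    params: AniParams = AniParams(),
) -> float:
    """Symmetrized fragment-based ANI (percent) between two genomes.

    Each genome is chopped into non-overlapping fragments which are placed
    in the other genome (semi-global edit distance) and refined by local
    alignment; fragments failing the identity/coverage filters are dropped.
    Returns 1/2 (ANI(a->b) + ANI(b->a)); 0 when no fragment passes in either
    direction.
    """
    sa = a.sequence if isinstance(a, PhageGenome) else str(a).upper()
    sb = b.sequence if isinstance(b, PhageGenome) else str(b).upper()
    if not sa or not sb:
        raise ValueError("ANI undefined for empty sequences")
    aligner = _nt_aligner()
    return 0.5 * (
        _directional_ani(sa, sb, params, aligner) + _directional_ani(sb, sa, params, aligner)
    )


# ---------------------------------------------------------------------------
# MinHash nucleotide distance

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_SPLITMIX_1 = np.uint64(0x9E3779B97F4A7C15)
_SPLITMIX_2 = np.uint64(0xBF58476D1CE4E5B9)
_SPLITMIX_3 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray, seed: int) -> np.ndarray:
    z = (x ^ np.uint64(seed)) + _SPLITMIX_1
    z = (z ^ (z >> np.uint64(30))) * _SPLITMIX_2
    z = (z ^ (z >> np.uint64(27))) * _SPLITMIX_3
    return z ^ (z >> np.uint64(31))


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Distinct canonical k-mers of ``seq`` as 2-bit packed uint64 codes.

    Canonical = numeric (equivalently lexicographic) minimum of a k-mer and
    its reverse complement; windows containing N are skipped.
    """
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    fwd_bases = np.where(valid, codes, 0).astype(np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(fwd_bases, k)
    fwd = (win * powers).sum(axis=1, dtype=np.uint64)
    rc_bases = (np.uint64(3) - fwd_bases)[::-1]
    rc_win = np.lib.stride_tricks.sliding_window_view(rc_bases, k)
    rc_all = (rc_win * powers).sum(axis=1, dtype=np.uint64)
    rc = rc_all[::-1]  # rc[i] = revcomp of the k-mer starting at i
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    canon = np.minimum(fwd[ok], rc[ok])
    return np.unique(canon)


def minhash_sketch(seq: str, params: SketchParams = SketchParams()) -> np.ndarray:
    """Sorted bottom-``sketch_size`` hash values over canonical k-mers."""
    hashes = _splitmix64(_canonical_kmer_codes(seq.upper(), params.k), params.seed)
    hashes = np.unique(hashes)
    return hashes[: params.sketch_size]


def _sketch_jaccard(ha: np.ndarray, hb: np.ndarray, s: int) -> float:
    union = np.unique(np.concatenate([ha, hb]))[:s]
    both = np.intersect1d(ha, hb, assume_unique=True)
    shared = np.isin(union, both, assume_unique=True).sum()
    return float(shared) / len(union)


def mash_distance(jaccard: float, k: int) -> float:
    """Mash transform of a Jaccard estimate; capped at 1.0 for j = 0."""
    if jaccard <= 0.0:
        return 1.0
    return min(1.0, -math.log(2.0 * jaccard / (1.0 + jaccard)) / k)


def nucleotide_distance(
    a: PhageGenome | str,
    b: PhageGenome | str,
    params: SketchParams = SketchParams(),
) -> float:
    """MinHash nucleotide distance between two genomes (fraction in [0, 1]).

    Bottom-sketch Jaccard estimate over canonical k-mers, transformed by
    d = -(1/k) ln(2j/(1+j)). Deterministic for a fixed hash seed.
    """
    sa = a.sequence if isinstance(a, PhageGenome) else str(a).upper()
    sb = b.sequence if isinstance(b, PhageGenome) else str(b).upper()
    ha = minhash_sketch(sa, params)
    hb = minhash_sketch(sb, params)
    return mash_distance(_sketch_jaccard(ha, hb, params.sketch_size), params.k)


# ---------------------------------------------------------------------------
# All-vs-all


def all_pairs(
    genomes: list[PhageGenome],
    metric: str,
    phams: Optional[PhamSet] = None,
    params: AniParams | SketchParams | None = None,
) -> SymmetricMatrix:
    """Compute an all-vs-all :class:`SymmetricMatrix` for one metric.

    ``metric`` is one of ``gcs``, ``gcd``, ``ani``, ``nucleotide_distance``.
    Only the upper triangle is computed and mirrored; the diagonal is set to
    the metric's analytic self-value.
    """
    if len(genomes) < 2:
        raise ValueError("all_pairs requires at least 2 genomes")
    labels = [g.phage_id for g in genomes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate phage ids")
    if metric not in SymmetricMatrix.SELF_VALUES:
        raise ValueError(f"unknown metric {metric!r}")

    if metric in ("gcs", "gcd"):
        if phams is None:
            raise ValueError(f"metric {metric!r} requires a PhamSet")
        pham_sets = {lab: phams.phams_of(lab) for lab in labels}

        def pairfn(i: int, j: int) -> float:
            pa, pb = pham_sets[labels[i]], pham_sets[labels[j]]
            if not pa or not pb:
                raise ValueError("GCS undefined for a phage with no phams")
            shared = len(pa & pb)
            gcs = 100.0 * 0.5 * (shared / len(pa) + shared / len(pb))
            return gcs if metric == "gcs" else 1.0 - gcs / 100.0

        parameters = {"link_rule": phams.link_rule}
    elif metric == "ani":
        ani_params = params or AniParams()

        def pairfn(i: int, j: int) -> float:
            return ani(genomes[i], genomes[j], ani_params)

        parameters = {"params": ani_params}
    else:
        sketch_params = params or SketchParams()
        sketches = [minhash_sketch(g.sequence, sketch_params) for g in genomes]

        def pairfn(i: int, j: int) -> float:
            return mash_distance(
                _sketch_jaccard(sketches[i], sketches[j], sketch_params.sketch_size),
                sketch_params.k,
            )

        parameters = {"params": sketch_params}

    n = len(labels)
    values = np.full((n, n), SymmetricMatrix.SELF_VALUES[metric], dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pairfn(i, j)
    return SymmetricMatrix(labels=labels, values=values, metric_name=metric, parameters=parameters)


def long_form(gcd: SymmetricMatrix, nd: SymmetricMatrix):
    """Long-form pair table (phage_a, phage_b, gcd, nucleotide_distance).

    The input for genomic similarity plots; one row per unordered pair.
    """
    import pandas as pd

    if gcd.labels != nd.labels:
        raise ValueError("matrices must share labels in the same order")
    rows = [
        (a, b, gcd.value(a, b), nd.value(a, b))
        for i, a in enumerate(gcd.labels)
        for b in gcd.labels[i + 1 :]
    ]
    return pd.DataFrame(rows, columns=["phage_a", "phage_b", "gcd", "nucleotide_distance"])
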