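"""Marker location, pairwise K80 distances and cross-marker identity
regression.

Marker genes are located by exact-word seeding followed by local alignment
(protein queries are scanned against all six reading-frame translations);
distances come from pairwise global alignments under the K80 substitution
model, with gapped and ambiguous columns excluded.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .core_io import GenomeRecord, reverse_complement

# Affine gap convention: a gap of length L costs GAP_OPEN + L * GAP_EXTEND.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = 4.0
GAP_EXTEND = 1.0

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_CONCRETE = set("ACGT")


class SaturatedDistanceError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MarkerHit:
    genome_id: str
    marker_name: str
    start: int  # 0-based, forward strand
    end: int  # half-open
    strand: str
    score: float
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid hit coordinates")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("hit sequence length inconsistent with coordinates")


@dataclasses.dataclass(frozen=True)
class PairwiseDistance:
    id_a: str
    id_b: str
    p_identity: float
    P: float  # transition proportion
    Q: float  # transversion proportion
    d_k80: float | None  # None when saturated
    n_sites: int

    @property
    def saturated(self) -> bool:
        return self.d_k80 is None

    @property
    def pair_key(self) -> tuple[str, str]:
        return tuple(sorted((self.id_a, self.id_b)))


@dataclasses.dataclass
class MarkerComparison:
    marker_x: str
    marker_y: str
    slope: float
    intercept: float
    r2: float
    n_pairs: int
    n_dropped: int
    x_identity: np.ndarray
    y_identity: np.ndarray


# --------------------------------------------------------------------------
# Pairwise alignment


def _nucleotide_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_pair(a: str, b: str) -> tuple[str, str, float]:
    """Global affine-gap alignment; returns (aligned_a, aligned_b, score).

    Scoring: match +1, mismatch -1, a gap of length L costs 4 + L.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _nucleotide_aligner("global")
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


# --------------------------------------------------------------------------
# K80 distance


def compute_k80(aligned_a: str, aligned_b: str, id_a: str = "a", id_b: str = "b") -> PairwiseDistance:
    """K80 distance from an aligned pair.

    Columns with a gap or ambiguity code in either row are excluded.  When
    the log arguments are non-positive the pair is reported saturated
    (``d_k80 = None``) but retained with its identity.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    n = ts = tv = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in _CONCRETE or y not in _CONCRETE:
            continue
        n += 1
        if x == y:
            continue
        if frozenset((x, y)) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable (ungapped, unambiguous) columns")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    d: float | None
    if w1 <= 0 or w2 <= 0:
        d = None
    else:
        d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return PairwiseDistance(id_a, id_b, 1.0 - P - Q, P, Q, d, n)


def distance_pair(a: str, b: str, id_a: str = "a", id_b: str = "b") -> PairwiseDistance:
    """Align two unaligned sequences and compute their K80 distance."""
    aligned_a, aligned_b, _ = align_pair(a, b)
    return compute_k80(aligned_a, aligned_b, id_a, id_b)


def pairwise_distances(sequences: Mapping[str, str]) -> list[PairwiseDistance]:
    """All-vs-all K80 distances for a set of homologous sequences."""
    ids = sorted(sequences)
    out = []
    for i, ida in enumerate(ids):
        for idb in ids[i + 1 :]:
            out.append(distance_pair(sequences[ida], sequences[idb], ida, idb))
    return out


def trim_alignment_columns(
    msa: Sequence[str], start_col: int, end_col: int
) -> list[str]:
    """Slice every row of an alignment to a 1-based inclusive column range."""
    if not msa:
        return []
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment rows have unequal width")
    if not (1 <= start_col <= end_col <= width):
        raise ValueError(
            f"column interval [{start_col}, {end_col}] out of range for width {width}"
        )
    return [row[start_col - 1 : end_col] for row in msa]


# --------------------------------------------------------------------------
# Marker location (seed-and-extend)


def _seed_diagonals(query: str, target: str, k: int) -> list[int]:
    """Approximate alignment start offsets from exact k-mer seed matches,
    clustered by diagonal."""
    index: dict[str, list[int]] = {}
    for qpos in range(len(query) - k + 1):
        index.setdefault(query[qpos : qpos + k], []).append(qpos)
    diagonals: set[int] = set()
    for tpos in range(len(target) - k + 1):
        for qpos in index.get(target[tpos : tpos + k], ()):
            diagonals.add(tpos - qpos)
    if not diagonals:
        return []
    clustered: list[int] = []
    for d in sorted(diagonals):
        if not clustered or d - clustered[-1] > max(30, k):
            clustered.append(d)
    return clustered


def _alignment_stats(alignment) -> tuple[int, int, int, int, int]:
    """(matches, aligned_cols, t_start, t_end, q_aligned) of a local alignment."""
    rows = str(alignment[0]), str(alignment[1])
    matches = sum(
        1 for x, y in zip(*rows) if x == y and x != "-"
    )
    cols = sum(1 for x, y in zip(*rows) if x != "-" and y != "-")
    blocks = alignment.aligned
    t_start = int(blocks[0][0][0])
    t_end = int(blocks[0][-1][1])
    q_aligned = int(sum(b[1] - b[0] for b in blocks[1]))
    return matches, cols, t_start, t_end, q_aligned


def _nucleotide_candidates(
    query: str, target: str, min_identity: float, min_coverage: float
) -> list[tuple[int, int, float, float]]:
    """Candidate (start, end, score, identity) spans of query on target."""
    k = min(12, max(6, len(query) // 8))
    aligner = _nucleotide_aligner("local")
    pad = max(20, len(query) // 10)
    out = []
    for diag in _seed_diagonals(query, target, k):
        w_start = max(0, diag - pad)
        w_end = min(len(target), diag + len(query) + pad)
        window = target[w_start:w_end]
        alignments = aligner.align(window, query)
        if len(alignments) == 0:
            continue
        alignment = alignments[0]
        matches, cols, t0, t1, q_aligned = _alignment_stats(alignment)
        if cols == 0:
            continue
        identity = matches / cols
        coverage = q_aligned / len(query)
        if identity >= min_identity and coverage >= min_coverage:
            out.append((w_start + t0, w_start + t1, float(alignment.score), identity))
    return out


def _protein_candidates(
    query: str, target: str, min_identity: float, min_coverage: float
) -> list[tuple[int, int, float, float]]:
    """Protein query scanned against 3 forward reading frames of target;
    returns nucleotide spans."""
    k = 4
    aligner = _protein_aligner()
    out = []
    for frame in range(3):
        sub = target[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        trans = str(Seq(sub).translate())
        trans = trans.replace("*", "X")
        pad = max(10, len(query) // 10)
        for diag in _seed_diagonals(query, trans, k):
            w_start = max(0, diag - pad)
            w_end = min(len(trans), diag + len(query) + pad)
            window = trans[w_start:w_end]
            alignments = aligner.align(window, query)
            if len(alignments) == 0:
                continue
            alignment = alignments[0]
            matches, cols, t0, t1, q_aligned = _alignment_stats(alignment)
            if cols == 0:
                continue
            identity = matches / cols
            coverage = q_aligned / len(query)
            if identity >= min_identity and coverage >= min_coverage:
                nt_start = frame + 3 * (w_start + t0)
                nt_end = frame + 3 * (w_start + t1)
                out.append((nt_start, nt_end, float(alignment.score), identity))
    return out


def locate_marker(
    genome: GenomeRecord,
    query: str,
    is_protein: bool = False,
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
    marker_name: str = "marker",
) -> list[MarkerHit]:
    """Locate a marker gene on both strands of a genome.

    Returns non-overlapping hits passing the identity and coverage
    thresholds, best score first; the hit count is the copy number.
    """
    if not query:
        raise ValueError("query must be non-empty")
    if not (0 <= min_identity <= 1 and 0 <= min_coverage <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    seq = genome.sequence
    candidates: list[tuple[int, int, str, float]] = []
    finder = _protein_candidates if is_protein else _nucleotide_candidates
    for strand in "+-":
        target = seq if strand == "+" else reverse_complement(seq)
        for start, end, score, _ident in finder(query, target, min_identity, min_coverage):
            if strand == "-":
                start, end = len(seq) - end, len(seq) - start
            candidates.append((start, end, strand, score))
    candidates.sort(key=lambda c: (-c[3], c[0]))
    hits: list[MarkerHit] = []
    for start, end, strand, score in candidates:
        if any(start < h.end and h.start < end for h in hits):
            continue
        hits.append(
            MarkerHit(genome.id, marker_name, start, end, strand, score, seq[start:end])
        )
    return hits


def single_copy_fraction(hits_per_genome: Mapping[str, Sequence[MarkerHit]]) -> float:
    """Fraction of genomes carrying exactly one hit of the marker."""
    if not hits_per_genome:
        raise ValueError("empty genome set")
    single = sum(1 for hits in hits_per_genome.values() if len(hits) == 1)
    return single / len(hits_per_genome)


# --------------------------------------------------------------------------
# Cross-marker regression


def compare_markers(
    dist_x: Iterable[PairwiseDistance],
    dist_y: Iterable[PairwiseDistance],
    marker_x: str = "x",
    marker_y: str = "y",
    use_k80_similarity: bool = False,
) -> MarkerComparison:
    """OLS of marker-y identity on marker-x identity over shared genome pairs.

    Pairs are joined on the unordered (id_a, id_b) key; pairs absent from
    either set are dropped and counted.  With ``use_k80_similarity`` the
    regression runs on exp(-d_k80) instead of raw p-identity (saturated
    pairs are then dropped too).
    """

    def value(d: PairwiseDistance) -> float | None:
        if use_k80_similarity:
            return None if d.d_k80 is None else math.exp(-d.d_k80)
        return d.p_identity

    xmap = {d.pair_key: value(d) for d in dist_x}
    ymap = {d.pair_key: value(d) for d in dist_y}
    shared = [
        k for k in xmap.keys() & ymap.keys() if xmap[k] is not None and ymap[k] is not None
    ]
    n_dropped = len(xmap.keys() | ymap.keys()) - len(shared)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared genome pairs, got {len(shared)}"
        )
    shared.sort()
    x = np.array([xmap[k] for k in shared])
    y = np.array([ymap[k] for k in shared])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return MarkerComparison(
        marker_x, marker_y, float(slope), float(intercept), r2, len(shared), n_dropped, x, y
    )


def map_identity(comparison: MarkerComparison, x_identity: float) -> float:
    """Predicted marker-y identity at a given marker-x identity, clipped to
    [0, 1]."""
    if not np.isfinite(comparison.slope):
        raise ValueError("comparison is not fitted")
    return float(np.clip(comparison.intercept + comparison.slope * x_identity, 0.0, 1.0))
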