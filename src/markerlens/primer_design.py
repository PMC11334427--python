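"""Degenerate primer design from protein orthologue alignments.

The protein alignment is back-translated codon-by-codon into a nucleotide
alignment, gap-free windows are collapsed to minimal-covering IUPAC
consensus strings, and forward/reverse candidates are paired under product
length, melting temperature and %GC constraints.  Tm uses the Wallace rule
on expected base counts, which handles degenerate codes naturally.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .core_io import IUPAC_SETS, reverse_complement

# minimal IUPAC code for each non-empty base set
_SET_TO_CODE = {frozenset(s): c for c, s in IUPAC_SETS.items()}


class GapInWindowError(ValueError):
    """Signals a consensus window overlapping an alignment gap."""


@dataclasses.dataclass
class CodonAlignment:
    """Nucleotide alignment mirroring a protein alignment codon-for-codon."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("rows have unequal width")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("codon alignment width must be divisible by 3")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclasses.dataclass(frozen=True)
class PrimerCandidate:
    start_col: int  # 0-based alignment column
    iupac: str
    degeneracy: int
    gc_fraction: float
    tm: float
    conservation: float

    def __len__(self) -> int:
        return len(self.iupac)


@dataclasses.dataclass(frozen=True)
class PrimerPair:
    fwd: PrimerCandidate
    rev: PrimerCandidate  # positions refer to the alignment; sequence below
    rev_synthesized: str  # reverse complement of the reverse window consensus
    product_length: int
    combined_degeneracy: int


def back_translate(
    protein_msa: Sequence[tuple[str, str]], cds_map: Mapping[str, str]
) -> CodonAlignment:
    """Replace each aligned amino acid by its source codon; '-' -> '---'.

    Each CDS must have length 3x its row's ungapped protein length and
    translate to that protein under the standard code (terminal stop codons
    are tolerated and trimmed).
    """
    ids, rows = [], []
    for rid, prot in protein_msa:
        if rid not in cds_map:
            raise ValueError(f"row {rid!r}: no CDS provided")
        cds = cds_map[rid].upper().replace("U", "T")
        ungapped = prot.replace("-", "")
        if len(cds) == 3 * (len(ungapped) + 1) and cds[-3:] in ("TAA", "TAG", "TGA"):
            cds = cds[:-3]
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"row {rid!r}: CDS length {len(cds)} inconsistent with "
                f"{len(ungapped)} residues"
            )
        translated = str(Seq(cds).translate())
        if translated != ungapped:
            raise ValueError(f"row {rid!r}: CDS does not translate to protein row")
        out = []
        pos = 0
        for aa in prot:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds[pos : pos + 3])
                pos += 3
        ids.append(rid)
        rows.append("".join(out))
    return CodonAlignment(ids, rows)


def consensus_degenerate(
    columns: Sequence[str], min_base_frequency: float = 0.0
) -> str:
    """Minimal IUPAC consensus of an alignment slice (one string per row).

    A base is covered when its column frequency exceeds
    ``min_base_frequency`` (default 0 covers every observed base).  Any gap
    in the slice raises :class:`GapInWindowError`.
    """
    if not columns:
        raise ValueError("empty slice")
    width = len(columns[0])
    out = []
    n_rows = len(columns)
    for j in range(width):
        col = [row[j].upper() for row in columns]
        if "-" in col:
            raise GapInWindowError(f"gap in consensus window at column {j}")
        observed: set[str] = set()
        for base in set(col):
            if base not in IUPAC_SETS:
                raise ValueError(f"invalid nucleotide {base!r}")
            freq = col.count(base) / n_rows
            if freq > min_base_frequency:
                observed |= IUPAC_SETS[base]
        if not observed:  # everything fell below the frequency floor
            observed = set().union(*(IUPAC_SETS[b] for b in set(col)))
        out.append(_SET_TO_CODE[frozenset(observed)])
    return "".join(out)


def primer_metrics(iupac: str) -> tuple[int, float, float]:
    """(degeneracy, expected GC fraction, Wallace-rule Tm in Celsius).

    Each code contributes its expected GC content; Tm = 2*(A+T) + 4*(G+C)
    on expected counts.
    """
    if not iupac:
        raise ValueError("empty primer")
    degeneracy = 1
    exp_gc = 0.0
    for code in iupac.upper():
        if code not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {code!r}")
        s = IUPAC_SETS[code]
        degeneracy *= len(s)
        exp_gc += len(s & {"G", "C"}) / len(s)
    n = len(iupac)
    gc_fraction = exp_gc / n
    tm = 2.0 * (n - exp_gc) + 4.0 * exp_gc
    return degeneracy, gc_fraction, tm


def _window_conservation(
    columns: Sequence[str], consensus: str
) -> float:
    """Fraction of rows matching the consensus with zero mismatches."""
    ok = 0
    for row in columns:
        if all(row[j].upper() in IUPAC_SETS[consensus[j]] for j in range(len(consensus))):
            ok += 1
    return ok / len(columns)


def scan_windows(
    codon_aln: CodonAlignment,
    window_len: int = 21,
    max_degeneracy: int = 512,
    min_conservation: float = 1.0,
    min_base_frequency: float = 0.0,
) -> list[PrimerCandidate]:
    """All gap-free windows whose consensus passes the degeneracy and
    conservation thresholds, sorted by (degeneracy, -conservation, start)."""
    if window_len > codon_aln.width:
        raise ValueError("window longer than alignment")
    candidates = []
    for start in range(codon_aln.width - window_len + 1):
        slice_rows = [row[start : start + window_len] for row in codon_aln.rows]
        try:
            consensus = consensus_degenerate(slice_rows, min_base_frequency)
        except GapInWindowError:
            continue
        degeneracy, gc, tm = primer_metrics(consensus)
        if degeneracy > max_degeneracy:
            continue
        conservation = _window_conservation(slice_rows, consensus)
        if conservation < min_conservation:
            continue
        candidates.append(
            PrimerCandidate(start, consensus, degeneracy, gc, tm, conservation)
        )
    candidates.sort(key=lambda c: (c.degeneracy, -c.conservation, c.start_col))
    return candidates


def select_pairs(
    candidates: Sequence[PrimerCandidate],
    product_range: tuple[int, int],
    max_dtm: float = 5.0,
    max_dgc: float = 0.1,
) -> list[PrimerPair]:
    """Ordered forward/reverse pairs with in-range product length and
    matched Tm and %GC, sorted by combined degeneracy.

    Product length is the outer span on the alignment:
    ``rev.start - fwd.start + len(rev)``.
    """
    lo, hi = product_range
    pairs = []
    for fwd in candidates:
        for rev in candidates:
            product = rev.start_col - fwd.start_col + len(rev)
            if not (lo <= product <= hi):
                continue
            if rev.start_col < fwd.start_col + len(fwd):
                continue
            if abs(fwd.tm - rev.tm) > max_dtm:
                continue
            if abs(fwd.gc_fraction - rev.gc_fraction) > max_dgc:
                continue
            pairs.append(
                PrimerPair(
                    fwd,
                    rev,
                    reverse_complement(rev.iupac),
                    product,
                    fwd.degeneracy * rev.degeneracy,
                )
            )
    pairs.sort(key=lambda p: (p.combined_degeneracy, p.fwd.start_col, p.rev.start_col))
    return pairs
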