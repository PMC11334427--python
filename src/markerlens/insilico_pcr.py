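"""Degenerate-primer matching and in-silico PCR.

A genome position matches a primer position iff the genome code's base set
is a subset of the primer code's set — so an ``N`` in the genome never
silently matches a concrete primer base.  Mismatches are counted uniformly
along the primer with a per-primer allowance, and product length is the
outer 5'->5' span including both primer footprints (``inner_span=True``
switches to the insert-only convention).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import pandas as pd

from .core_io import (
    IUPAC_SETS,
    GenomeRecord,
    normalize_sequence,
    reverse_complement,
)


@dataclasses.dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC primer, written 5'->3'."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.iupac)
        object.__setattr__(self, "iupac", seq)
        bad = set(seq) - set(IUPAC_SETS)
        if not seq or bad:
            raise ValueError(f"primer {self.name!r}: invalid IUPAC string {self.iupac!r}")

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def degeneracy(self) -> int:
        deg = 1
        for code in self.iupac:
            deg *= len(IUPAC_SETS[code])
        return deg

    def expand(self) -> list[str]:
        """All concrete sequences the primer denotes (use only for small
        degeneracies)."""
        pools = [sorted(IUPAC_SETS[c]) for c in self.iupac]
        return ["".join(p) for p in itertools.product(*pools)]


@dataclasses.dataclass(frozen=True)
class AmpliconHit:
    genome_id: str
    fwd_start: int
    rev_end: int
    product_length: int
    mismatches_fwd: int
    mismatches_rev: int
    orientation: str  # '+' forward primer on plus strand, '-' on minus


def iupac_match(primer_code: str, genome_code: str) -> bool:
    """True iff the genome code's base set is covered by the primer code's."""
    try:
        p = IUPAC_SETS[primer_code.upper()]
        g = IUPAC_SETS[genome_code.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None
    return g <= p


def count_mismatches(primer: DegeneratePrimer | str, window: str) -> int:
    """Number of primer positions whose code fails to cover the genome base."""
    pattern = primer.iupac if isinstance(primer, DegeneratePrimer) else normalize_sequence(primer)
    window = normalize_sequence(window)
    if len(window) != len(pattern):
        raise ValueError(
            f"window length {len(window)} != primer length {len(pattern)}"
        )
    return sum(
        0 if iupac_match(p, g) else 1 for p, g in zip(pattern, window)
    )


def _scan_sites(pattern: str, genome: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (start, mismatches) where pattern matches genome within budget."""
    L = len(pattern)
    psets = [IUPAC_SETS[c] for c in pattern]
    out = []
    for start in range(len(genome) - L + 1):
        mism = 0
        for off in range(L):
            if IUPAC_SETS[genome[start + off]] <= psets[off]:
                continue
            mism += 1
            if mism > max_mismatch:
                break
        else:
            out.append((start, mism))
    return out


def find_amplicons(
    genome: GenomeRecord | str,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    min_len: int,
    max_len: int,
    max_mismatch: int = 6,
    inner_span: bool = False,
) -> list[AmpliconHit]:
    """Predicted PCR products for a primer pair on both genome strands.

    On the plus strand the forward primer matches directly and the reverse
    primer's reverse complement matches downstream; the minus-strand case is
    the mirror image.  The mismatch budget applies per primer.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    if isinstance(genome, GenomeRecord):
        gid, seq = genome.id, genome.sequence
    else:
        gid, seq = "", normalize_sequence(genome)

    hits: list[AmpliconHit] = []
    fwd_pat = fwd.iupac
    rev_rc = reverse_complement(rev.iupac)
    # plus orientation: fwd ... revcomp(rev)
    fwd_sites = _scan_sites(fwd_pat, seq, max_mismatch)
    rev_sites = _scan_sites(rev_rc, seq, max_mismatch)
    for fstart, fmm in fwd_sites:
        for rstart, rmm in rev_sites:
            rev_end = rstart + len(rev_rc)
            if rstart < fstart + len(fwd_pat):
                continue
            product = rev_end - fstart
            length = product - (0 if not inner_span else len(fwd_pat) + len(rev_rc))
            if min_len <= length <= max_len:
                hits.append(
                    AmpliconHit(gid, fstart, rev_end, length, fmm, rmm, "+")
                )
    # minus orientation: rev ... revcomp(fwd) on the plus strand
    rev_pat = rev.iupac
    fwd_rc = reverse_complement(fwd_pat)
    rev_sites = _scan_sites(rev_pat, seq, max_mismatch)
    fwd_sites = _scan_sites(fwd_rc, seq, max_mismatch)
    for rstart, rmm in rev_sites:
        for fstart, fmm in fwd_sites:
            fwd_end = fstart + len(fwd_rc)
            if fstart < rstart + len(rev_pat):
                continue
            product = fwd_end - rstart
            length = product - (0 if not inner_span else len(fwd_pat) + len(rev_pat))
            if min_len <= length <= max_len:
                hits.append(
                    AmpliconHit(gid, rstart, fwd_end, length, fmm, rmm, "-")
                )
    hits.sort(key=lambda h: (h.fwd_start, h.rev_end, h.orientation))
    return hits


def taxonomic_coverage(
    genomes: Sequence[GenomeRecord],
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    min_len: int,
    max_len: int,
    max_mismatch: int = 6,
) -> pd.DataFrame:
    """Per-(order, family) fraction of species representatives amplified.

    Each genome is taken as one species representative; a species counts as
    hit when at least one in-range amplicon passes the mismatch budget.
    """
    if not genomes:
        raise ValueError("empty genome set")
    rows: dict[tuple[str, str], list[int]] = {}
    for genome in genomes:
        if genome.taxonomy is None:
            raise ValueError(f"genome {genome.id!r} lacks taxonomy")
        key = (genome.taxonomy.name_at("order"), genome.taxonomy.name_at("family"))
        hit = bool(
            find_amplicons(genome, fwd, rev, min_len, max_len, max_mismatch)
        )
        n_species, n_hit = rows.get(key, [0, 0])
        rows[key] = [n_species + 1, n_hit + int(hit)]
    records = [
        {
            "order": order,
            "family": family,
            "n_species": n_species,
            "n_hit": n_hit,
            "coverage": n_hit / n_species,
        }
        for (order, family), (n_species, n_hit) in sorted(rows.items())
    ]
    return pd.DataFrame.from_records(records)


def extract_inner_region(
    read: str,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    max_mismatch: int = 6,
) -> str | None:
    """Sequence strictly between the primers of an amplicon-oriented read.

    The forward primer is located on the read and the reverse primer as its
    reverse complement downstream; ``None`` when either primer is missing
    within the mismatch budget.  Of multiple candidate sites the outermost
    ones (earliest forward, latest reverse) are used.
    """
    seq = normalize_sequence(read)
    fwd_sites = _scan_sites(fwd.iupac, seq, max_mismatch)
    if not fwd_sites:
        return None
    rev_rc = reverse_complement(rev.iupac)
    rev_sites = _scan_sites(rev_rc, seq, max_mismatch)
    fstart = fwd_sites[0][0]
    inner_start = fstart + len(fwd.iupac)
    rev_sites = [s for s, _ in rev_sites if s >= inner_start]
    if not rev_sites:
        return None
    return seq[inner_start : rev_sites[-1]]


# Published primer pairs used throughout the examples and demo pipeline.
DNAK_FWD = DegeneratePrimer("F_Ru_45_65", "YGTNGCNGTNATGGARGGCGG")
DNAK_REV = DegeneratePrimer("R_Ru_154_174", "NGCCTGNCKYTTTGCVACCTG")
GYRB_FWD = DegeneratePrimer("F_La_334_354", "GGHGGAGGATAYAAGGTATCC")
GYRB_REV = DegeneratePrimer("R_La_816_836", "TRTANGAATCRTTRTGCTGC")
DNAK_WINDOW = (75, 150)
GYRB_WINDOW = (800, 1100)
DEFAULT_MAX_MISMATCH = 6


def read_primers_tsv(path) -> dict[str, DegeneratePrimer]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    primers = {}
    for _, row in frame.iterrows():
        role = row.get("role", row["name"])
        primers[role] = DegeneratePrimer(row["name"], row["sequence"])
    return primers


def write_amplicons_tsv(path, hits: Iterable[AmpliconHit]) -> None:
    frame = pd.DataFrame([dataclasses.asdict(h) for h in hits])
    if frame.empty:
        frame = pd.DataFrame(
            columns=[f.name for f in dataclasses.fields(AmpliconHit)]
        )
    frame.to_csv(path, sep="\t", index=False)
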