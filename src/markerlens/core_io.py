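"""Shared I/O, domain types and conventions.

Coordinates are 0-based, half-open, on the forward strand throughout the
package; reverse-strand features carry forward-strand coordinates plus a
strand flag.  Sequences are normalized to upper case on input and ``U`` is
mapped to ``T``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

# Canonical GTDB-style rank prefixes, domain through species.
RANK_PREFIXES: tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

# IUPAC nucleotide codes -> the set of concrete bases each denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class TaxonomyParseError(ValueError):
    """Raised for taxonomy strings with unknown rank prefixes."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Upper-case a sequence and map RNA ``U`` to ``T``."""
    return seq.upper().replace("U", "T")


def validate_nucleotides(seq: str, *, allow_gap: bool = False) -> None:
    allowed = set(IUPAC_SETS)
    if allow_gap:
        allowed.add("-")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"invalid nucleotide code(s): {sorted(bad)}")


@dataclasses.dataclass(frozen=True)
class TaxonomyLabel:
    """Seven-rank GTDB-style taxonomy label; names may be empty."""

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValueError("taxonomy must carry exactly 7 ranks")
        for (prefix, _), expected in zip(self.ranks, RANK_PREFIXES):
            if prefix != expected:
                raise ValueError(
                    f"rank prefix {prefix!r} out of order (expected {expected!r})"
                )

    def name_at(self, rank: str) -> str:
        """Name at a rank given as a prefix ('g__'), letter ('g') or word ('genus')."""
        idx = _rank_index(rank)
        return self.ranks[idx][1]

    def render(self) -> str:
        return ";".join(prefix + name for prefix, name in self.ranks)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _rank_index(rank: str) -> int:
    rank = rank.lower()
    if rank in RANK_NAMES:
        return RANK_NAMES.index(rank)
    key = rank[0] + "__" if len(rank) == 1 else rank
    if key in RANK_PREFIXES:
        return RANK_PREFIXES.index(key)
    raise ValueError(f"unknown taxonomic rank {rank!r}")


def parse_taxonomy(label: str) -> TaxonomyLabel:
    """Parse a semicolon-separated rank-prefixed string into 7 ranks.

    Missing trailing ranks are filled with empty names.  Ranks must appear
    in canonical order; unknown prefixes raise :class:`TaxonomyParseError`.
    """
    names = {prefix: "" for prefix in RANK_PREFIXES}
    last_idx = -1
    for field in label.split(";"):
        field = field.strip()
        if not field:
            continue
        prefix = field[:3]
        if prefix not in RANK_PREFIXES:
            raise TaxonomyParseError(f"unknown rank prefix in field {field!r}")
        idx = RANK_PREFIXES.index(prefix)
        if idx <= last_idx:
            raise TaxonomyParseError(f"rank {prefix!r} out of canonical order")
        last_idx = idx
        names[prefix] = field[3:]
    return TaxonomyLabel(tuple((p, names[p]) for p in RANK_PREFIXES))


def render_taxonomy(label: TaxonomyLabel) -> str:
    return label.render()


@dataclasses.dataclass(frozen=True)
class GenomeRecord:
    id: str
    sequence: str
    taxonomy: TaxonomyLabel | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: sequence must be non-empty")
        validate_nucleotides(self.sequence)


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file.

    Sequences are upper-cased with ``U`` mapped to ``T``.  Sequence data
    before the first header raises :class:`FastaParseError` naming the line.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before first header"
                    )
                chunks.append(normalize_sequence(line))
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, str]], width: int = 80
) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genomes(
    fasta_path: str | Path, taxonomy_path: str | Path | None = None
) -> list[GenomeRecord]:
    """Read genomes from FASTA, optionally joined with a taxonomy TSV."""
    tax: dict[str, TaxonomyLabel] = {}
    if taxonomy_path is not None:
        table = read_taxonomy_tsv(taxonomy_path)
        tax = dict(table)
    return [
        GenomeRecord(rid, seq, tax.get(rid)) for rid, seq in read_fasta(fasta_path)
    ]


# --------------------------------------------------------------------------
# BMI

BMI_CATEGORIES = ("lean", "overweight", "obese")
UNDERWEIGHT_FLAG = "underweight-excluded"


def classify_bmi(bmi: float) -> str:
    """Classify BMI (kg/m^2) into lean [18.5, 25), overweight [25, 30),
    obese [30, inf).  Values below 18.5 are flagged for exclusion."""
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be positive and finite, got {bmi!r}")
    if bmi < 18.5:
        return UNDERWEIGHT_FLAG
    if bmi < 25.0:
        return "lean"
    if bmi < 30.0:
        return "overweight"
    return "obese"


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    bmi: float
    city: str
    sex: str = ""
    age: float = float("nan")

    @property
    def bmi_category(self) -> str:
        return classify_bmi(self.bmi)


# --------------------------------------------------------------------------
# Count matrices

class CountMatrix:
    """Integer count matrix, samples in rows, ASVs in columns."""

    def __init__(
        self,
        sample_ids: Sequence[str],
        asv_ids: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(sample_ids), len(asv_ids)):
            raise ValueError(
                f"count matrix shape {counts.shape} inconsistent with "
                f"{len(sample_ids)} samples x {len(asv_ids)} ASVs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(asv_ids)) != len(asv_ids):
            raise ValueError("duplicate ASV ids")
        self.sample_ids = list(sample_ids)
        self.asv_ids = list(asv_ids)
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def asv_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def select_samples(self, keep: Sequence[bool]) -> "CountMatrix":
        keep = np.asarray(keep, dtype=bool)
        ids = [s for s, k in zip(self.sample_ids, keep) if k]
        return CountMatrix(ids, self.asv_ids, self.counts[keep])

    def select_asvs(self, keep: Sequence[bool]) -> "CountMatrix":
        keep = np.asarray(keep, dtype=bool)
        ids = [a for a, k in zip(self.asv_ids, keep) if k]
        return CountMatrix(self.sample_ids, ids, self.counts[:, keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.asv_ids == other.asv_ids
            and np.array_equal(self.counts, other.counts)
        )


def read_counts_tsv(path: str | Path) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_frame(frame)


def write_counts_tsv(path: str | Path, matrix: CountMatrix) -> None:
    frame = matrix.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_taxonomy_tsv(path: str | Path) -> list[tuple[str, TaxonomyLabel]]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    id_col, label_col = frame.columns[:2]
    return [
        (row[id_col], parse_taxonomy(row[label_col])) for _, row in frame.iterrows()
    ]


def write_taxonomy_tsv(
    path: str | Path, items: Iterable[tuple[str, TaxonomyLabel]], id_col: str = "asv_id"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"{id_col}\ttaxonomy\n")
        for rid, label in items:
            fh.write(f"{rid}\t{label.render()}\n")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, bmi, city, sex, age) and derive
    bmi_category.  Underweight samples (BMI < 18.5) are dropped, mirroring
    the cohort exclusion rule."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "bmi", "city"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"metadata missing required column(s): {sorted(missing)}")
    frame = frame[frame["bmi"] >= 18.5].reset_index(drop=True)
    frame["bmi_category"] = frame["bmi"].map(classify_bmi)
    return frame


def write_metadata_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Config and RNG

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def make_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Canonical RNG constructor; pass generators through unchanged."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
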