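"""Synthetic fixtures: K80-evolved marker genomes with controlled primer
sites, hurdle-structured diversity cohorts, and negative-binomial count
cohorts.  Every generator emits a truth table sufficient to score the
downstream stage that consumes it.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_io import (
    CountMatrix,
    GenomeRecord,
    IUPAC_SETS,
    TaxonomyLabel,
    make_rng,
    parse_taxonomy,
    reverse_complement,
)
from .insilico_pcr import DegeneratePrimer

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclasses.dataclass(frozen=True)
class MarkerSpec:
    """A simulated marker locus: length, relative substitution rate and
    transition/transversion ratio."""

    name: str
    length: int
    rate_multiplier: float = 1.0
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.length < 60:
            raise ValueError("marker length must be >= 60 bp")
        if self.rate_multiplier < 0:
            raise ValueError("rate_multiplier must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


@dataclasses.dataclass(frozen=True)
class PrimerSitePlan:
    """Where a primer pair binds inside a marker and how many mismatches to
    inject per taxon.

    The forward site starts at ``fwd_offset`` within the marker; the reverse
    primer's reverse complement ends at ``fwd_offset + product_length``, so
    the outer amplicon span equals ``product_length``.  ``mismatches`` maps
    taxon index -> (fwd, rev) counts; taxa not listed get (0, 0).
    """

    fwd: DegeneratePrimer
    rev: DegeneratePrimer
    product_length: int
    fwd_offset: int = 0
    mismatches: Mapping[int, tuple[int, int]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.product_length < len(self.fwd) + len(self.rev):
            raise ValueError("product_length shorter than the two primer footprints")


def k80_site_probabilities(distance: float, kappa: float) -> tuple[float, float, float]:
    """(identity, transition, per-transversion) site probabilities at branch
    length ``distance`` expected substitutions/site."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    e2 = np.exp(-2.0 * distance * (kappa + 1.0) / (kappa + 2.0))
    e4 = np.exp(-4.0 * distance / (kappa + 2.0))
    p_same = 0.25 + 0.25 * e4 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4  # each of the two transversion targets
    return float(p_same), float(p_ts), float(p_tv)


def evolve_k80(ancestor: str, distance: float, kappa: float = 2.0, seed=None) -> str:
    """Evolve a sequence along a branch of ``distance`` substitutions/site
    under K80, site-independently."""
    rng = make_rng(seed)
    p_same, p_ts, p_tv = k80_site_probabilities(distance, kappa)
    codes = np.array([_BASE_INDEX[b] for b in ancestor])
    # transition partner: A<->G (0<->2), C<->T (1<->3)
    ts_partner = np.array([2, 3, 0, 1])
    # the two transversion targets of each base, fixed order
    tv1 = np.array([1, 0, 1, 0])  # A->C, C->A, G->C, T->A
    tv2 = np.array([3, 2, 3, 2])  # A->T, C->G, G->T, T->G
    u = rng.random(codes.size)
    out = codes.copy()
    ts = u >= p_same
    out[ts] = ts_partner[codes[ts]]
    v1 = u >= p_same + p_ts
    out[v1] = tv1[codes[v1]]
    v2 = u >= p_same + p_ts + p_tv
    out[v2] = tv2[codes[v2]]
    return "".join(_BASES[out])


def random_sequence(length: int, seed=None) -> str:
    rng = make_rng(seed)
    return "".join(rng.choice(_BASES, size=length))


def _realize_primer_site(
    primer: DegeneratePrimer, n_mismatches: int, rng: np.random.Generator
) -> tuple[str, int]:
    """Draw one concrete binding site for ``primer`` and flip
    ``n_mismatches`` bases at non-degenerate positions."""
    site = [rng.choice(sorted(IUPAC_SETS[c])) for c in primer.iupac]
    concrete = [i for i, c in enumerate(primer.iupac) if len(IUPAC_SETS[c]) == 1]
    if n_mismatches > len(concrete):
        raise ValueError(
            f"cannot inject {n_mismatches} mismatches: primer {primer.name!r} "
            f"has only {len(concrete)} non-degenerate positions"
        )
    for pos in rng.choice(concrete, size=n_mismatches, replace=False):
        site[pos] = rng.choice([b for b in "ACGT" if b != site[pos]])
    return "".join(site), n_mismatches


@dataclasses.dataclass
class MarkerGenomeSim:
    genomes: list[GenomeRecord]
    truth: pd.DataFrame  # genome_id, marker, start, end, strand, divergence, mm_fwd, mm_rev
    ancestors: dict[str, str]


_DEFAULT_TAXONOMY_TEMPLATE = (
    "d__Bacteria;p__Bacillota_A;c__Clostridia;o__Oscillospirales;"
    "f__Oscillospiraceae;g__Genus{i};s__Genus{i} sp{i:03d}"
)


def simulate_marker_genomes(
    n_taxa: int,
    divergences: Sequence[float] | float,
    specs: Sequence[MarkerSpec],
    background_length: int = 5000,
    primer_plans: Mapping[str, PrimerSitePlan] | None = None,
    seed=None,
    taxonomy_template: str = _DEFAULT_TAXONOMY_TEMPLATE,
) -> MarkerGenomeSim:
    """Simulate genomes each carrying one copy of every marker.

    Marker ``i`` of taxon ``t`` is evolved from a shared random ancestor to
    branch length ``divergences[t] * specs[i].rate_multiplier``.  Where a
    :class:`PrimerSitePlan` is given for a marker, the primer sites are
    overwritten post-evolution with a concrete realization carrying exactly
    the requested number of mismatches, so thresholds are exactly testable.
    Markers are embedded at random positions and strands in random
    background sequence; the truth table records coordinates and injected
    mismatch counts.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = make_rng(seed)
    if np.isscalar(divergences):
        divergences = [float(divergences)] * n_taxa
    if len(divergences) != n_taxa:
        raise ValueError("divergences must have one entry per taxon")
    if any(d < 0 for d in divergences):
        raise ValueError("divergences must be >= 0")
    primer_plans = primer_plans or {}
    total_marker = sum(s.length for s in specs)
    if background_length < total_marker + len(specs):
        raise ValueError(
            f"background_length {background_length} too small for "
            f"{total_marker} bp of markers"
        )

    ancestors = {s.name: random_sequence(s.length, rng) for s in specs}
    genomes: list[GenomeRecord] = []
    rows: list[dict] = []
    for t in range(n_taxa):
        markers: list[tuple[str, str, str]] = []  # (name, seq, strand)
        for spec in specs:
            seq = evolve_k80(
                ancestors[spec.name], divergences[t] * spec.rate_multiplier,
                spec.kappa, rng,
            )
            plan = primer_plans.get(spec.name)
            mm_f = mm_r = None
            if plan is not None:
                if plan.fwd_offset + plan.product_length > spec.length:
                    raise ValueError(
                        f"primer plan for {spec.name!r} exceeds marker length"
                    )
                mm_f, mm_r = plan.mismatches.get(t, (0, 0))
                fsite, _ = _realize_primer_site(plan.fwd, mm_f, rng)
                rsite, _ = _realize_primer_site(plan.rev, mm_r, rng)
                o = plan.fwd_offset
                end = o + plan.product_length
                seq = (
                    seq[:o]
                    + fsite
                    + seq[o + len(fsite) : end - len(rsite)]
                    + reverse_complement(rsite)
                    + seq[end:]
                )
            strand = "+" if rng.random() < 0.5 else "-"
            markers.append((spec.name, seq, strand))
            rows.append(
                {
                    "genome_id": f"g{t:03d}",
                    "marker": spec.name,
                    "strand": strand,
                    "divergence": divergences[t] * spec.rate_multiplier,
                    "mm_fwd": mm_f,
                    "mm_rev": mm_r,
                }
            )
        # carve the background into len(specs)+1 chunks and interleave
        slack = background_length - total_marker
        cuts = np.sort(rng.integers(0, slack + 1, size=len(specs)))
        background = random_sequence(background_length - total_marker, rng)
        pieces: list[str] = []
        pos = 0
        prev = 0
        row_iter = iter(rows[-len(specs):])
        for (name, mseq, strand), cut in zip(markers, cuts):
            pieces.append(background[prev:cut])
            pos += cut - prev
            row = next(row_iter)
            row["start"] = pos
            row["end"] = pos + len(mseq)
            pieces.append(mseq if strand == "+" else reverse_complement(mseq))
            pos += len(mseq)
            prev = cut
        pieces.append(background[prev:])
        taxonomy = parse_taxonomy(taxonomy_template.format(i=t))
        genomes.append(GenomeRecord(f"g{t:03d}", "".join(pieces), taxonomy))
    truth = pd.DataFrame(rows)[
        ["genome_id", "marker", "start", "end", "strand", "divergence", "mm_fwd", "mm_rev"]
    ]
    return MarkerGenomeSim(genomes, truth, ancestors)


# --------------------------------------------------------------------------
# Diversity cohorts


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a hurdle-structured diversity cohort.

    Presence is Bernoulli on the logit scale (intercept ``a0``, BMI slope
    ``a1``); the positive part is Gamma with log-scale mean ``b0 + b1*bmi``
    and shape ``gamma_shape``.  ``city_effects`` maps city -> (presence,
    positive-part) offsets.
    """

    n_samples: int
    a0: float
    a1: float
    b0: float
    b1: float
    gamma_shape: float = 5.0
    bmi_range: tuple[float, float] = (18.5, 40.0)
    city_levels: tuple[str, ...] = ("CityA", "CityB")
    city_effects: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=dict
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")


def simulate_diversity_cohort(
    spec: CohortSpec, seed=None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw (metadata, per-sample Shannon) under the hurdle model.

    BMI is uniform over ``bmi_range`` and cities are assigned in balanced
    rotation.  Returns a metadata frame (sample_id, bmi, city, sex, age,
    bmi_category) and the Shannon vector in nats.
    """
    rng = make_rng(spec.seed if seed is None else seed)
    n = spec.n_samples
    bmi = rng.uniform(*spec.bmi_range, size=n)
    cities = [spec.city_levels[i % len(spec.city_levels)] for i in range(n)]
    a_off = np.array([spec.city_effects.get(c, (0.0, 0.0))[0] for c in cities])
    b_off = np.array([spec.city_effects.get(c, (0.0, 0.0))[1] for c in cities])
    p_present = expit(spec.a0 + spec.a1 * bmi + a_off)
    present = rng.random(n) < p_present
    mean = np.exp(spec.b0 + spec.b1 * bmi + b_off)
    shannon = np.where(
        present,
        rng.gamma(spec.gamma_shape, mean / spec.gamma_shape, size=n),
        0.0,
    )
    from .core_io import classify_bmi

    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(n)],
            "bmi": bmi,
            "city": cities,
            "sex": [("F", "M")[i % 2] for i in range(n)],
            "age": rng.integers(18, 63, size=n),
        }
    )
    meta["bmi_category"] = meta["bmi"].map(classify_bmi)
    return meta, shannon


# --------------------------------------------------------------------------
# Count cohorts


@dataclasses.dataclass
class CountCohortSim:
    table: CountMatrix
    metadata: pd.DataFrame
    taxonomy: list[tuple[str, TaxonomyLabel]]
    fold_changes: np.ndarray  # per-ASV obese-vs-lean mean ratio (truth)


_ASV_TAXONOMY_TEMPLATE = (
    "d__Bacteria;p__Bacillota_A;c__Clostridia;o__Oscillospirales;"
    "f__Oscillospiraceae;g__Genus{g};s__"
)


def simulate_count_cohort(
    n_samples: int,
    n_asvs: int,
    richness_slope: float = 0.0,
    fold_changes: Sequence[float] | float = 1.0,
    library_size: tuple[float, float] = (2.0e4, 0.25),
    dispersion: float = 0.5,
    n_genera: int = 3,
    presence_logit0: float = 3.0,
    seed=None,
) -> CountCohortSim:
    """Negative-binomial ASV counts across a BMI-stratified cohort.

    Per-category means scale by ``fold_changes`` (lean 1x, overweight
    sqrt(fc), obese fc); a sample/ASV presence indicator with BMI slope
    ``richness_slope`` (logit scale, centered at BMI 29) thins richness;
    library sizes are lognormal (mean, sigma).  Counts are gamma-Poisson
    with dispersion ``alpha`` so Var = mu + alpha*mu^2.
    """
    if n_asvs < 2:
        raise ValueError("need at least 2 ASVs")
    rng = make_rng(seed)
    fc = np.broadcast_to(np.asarray(fold_changes, dtype=float), (n_asvs,)).copy()
    if (fc <= 0).any():
        raise ValueError("fold changes must be positive")

    bmi = rng.uniform(18.5, 40.0, size=n_samples)
    cities = [("CityA", "CityB")[i % 2] for i in range(n_samples)]
    from .core_io import classify_bmi

    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(n_samples)],
            "bmi": bmi,
            "city": cities,
            "sex": [("F", "M")[i % 2] for i in range(n_samples)],
            "age": rng.integers(18, 63, size=n_samples),
        }
    )
    meta["bmi_category"] = meta["bmi"].map(classify_bmi)
    cat_power = meta["bmi_category"].map(
        {"lean": 0.0, "overweight": 0.5, "obese": 1.0}
    ).to_numpy()

    base_w = rng.lognormal(0.0, 1.0, size=n_asvs)
    base_w /= base_w.sum()
    libs = rng.lognormal(np.log(library_size[0]), library_size[1], size=n_samples)

    mult = fc[None, :] ** cat_power[:, None]
    mu = libs[:, None] * base_w[None, :] * mult
    mu *= (libs[:, None] / mu.sum(axis=1, keepdims=True))
    p_present = expit(presence_logit0 + richness_slope * (bmi - 29.0))
    present = rng.random((n_samples, n_asvs)) < p_present[:, None]
    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    counts = rng.poisson(lam) * present

    asv_ids = [f"asv{j:04d}" for j in range(n_asvs)]
    taxonomy = [
        (asv_ids[j], parse_taxonomy(_ASV_TAXONOMY_TEMPLATE.format(g=j % n_genera)))
        for j in range(n_asvs)
    ]
    table = CountMatrix(list(meta["sample_id"]), asv_ids, counts)
    return CountCohortSim(table, meta, taxonomy, fc)
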