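"""Alpha-diversity vs phenotype: count filtering, rarefaction, taxon-subset
Shannon indices, identity clustering, the two-part (hurdle) GLM against BMI
with a city covariate, and Benjamini-Hochberg FDR.

Order of operations is fixed as filter -> rarefy (whole table, global
minimum depth) -> subset -> Shannon; ``per_subset_rarefaction`` switches to
rarefying within each taxon subset instead.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import CountMatrix, TaxonomyLabel, make_rng
from .marker_survey import align_pair


@dataclasses.dataclass
class ASVTable:
    """Count matrix plus per-ASV taxonomy and optional representative
    sequences."""

    matrix: CountMatrix
    taxonomy: dict[str, TaxonomyLabel]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        missing = [a for a in self.matrix.asv_ids if a not in self.taxonomy]
        if missing:
            raise ValueError(f"taxonomy missing for ASV(s): {missing[:5]}")

    def restrict(self, matrix: CountMatrix) -> "ASVTable":
        keep = set(matrix.asv_ids)
        seqs = (
            {a: s for a, s in self.sequences.items() if a in keep}
            if self.sequences is not None
            else None
        )
        return ASVTable(matrix, {a: self.taxonomy[a] for a in matrix.asv_ids}, seqs)


@dataclasses.dataclass
class FilterResult:
    table: "ASVTable | CountMatrix"
    dropped_samples: list[str]
    dropped_asvs: list[str]


DEFAULT_MIN_TOTAL = 100


def filter_min_counts(table, min_total: int = DEFAULT_MIN_TOTAL) -> FilterResult:
    """Drop samples then ASVs with totals below ``min_total`` ("less than"
    is exclusive: a total of exactly ``min_total`` is kept)."""
    matrix = table.matrix if isinstance(table, ASVTable) else table
    keep_samples = matrix.sample_sums() >= min_total
    if not keep_samples.any():
        raise ValueError("all samples fall below the count threshold")
    dropped_samples = [s for s, k in zip(matrix.sample_ids, keep_samples) if not k]
    matrix = matrix.select_samples(keep_samples)
    keep_asvs = matrix.asv_sums() >= min_total
    dropped_asvs = [a for a, k in zip(matrix.asv_ids, keep_asvs) if not k]
    matrix = matrix.select_asvs(keep_asvs)
    out = table.restrict(matrix) if isinstance(table, ASVTable) else matrix
    return FilterResult(out, dropped_samples, dropped_asvs)


def rarefy(table, depth: int | None = None, seed=None):
    """Subsample every sample without replacement to a common depth
    (default: the smallest sample total)."""
    matrix = table.matrix if isinstance(table, ASVTable) else table
    sums = matrix.sample_sums()
    if depth is None:
        depth = int(sums.min())
    if (sums < depth).any():
        low = [s for s, t in zip(matrix.sample_ids, sums) if t < depth]
        raise ValueError(f"depth {depth} exceeds sample total(s) for {low[:5]}")
    rng = make_rng(seed)
    out = np.empty_like(matrix.counts)
    for i, row in enumerate(matrix.counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    rarefied = CountMatrix(matrix.sample_ids, matrix.asv_ids, out)
    return table.restrict(rarefied) if isinstance(table, ASVTable) else rarefied


def shannon(counts: Sequence[float]) -> float:
    """Shannon index in nats; 0 when at most one taxon has counts."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        return 0.0
    p = c[c > 0] / total
    if p.size <= 1:
        return 0.0
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(matrix: CountMatrix) -> pd.Series:
    return pd.Series(
        [shannon(row) for row in matrix.counts], index=matrix.sample_ids, name="shannon"
    )


def subset_shannon(table: ASVTable, rank: str, name: str) -> pd.Series:
    """Per-sample Shannon over the ASVs labelled ``name`` at ``rank``;
    samples with no subset counts get H = 0 (the hurdle's zero class)."""
    keep = [table.taxonomy[a].name_at(rank) == name for a in table.matrix.asv_ids]
    if not any(keep):
        raise ValueError(f"no ASV labelled {name!r} at rank {rank!r}")
    return shannon_per_sample(table.matrix.select_asvs(keep))


# --------------------------------------------------------------------------
# Identity clustering


@dataclasses.dataclass
class ClusterAssignment:
    threshold: float
    assignment: dict[str, str]  # ASV id -> centroid ASV id
    centroids: list[str]


def _pair_identity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    aligned_a, aligned_b, _ = align_pair(a, b)
    # gap columns count as differences, so distinct sequences never reach 1.0
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    return matches / len(aligned_a)


def greedy_cluster(
    sequences: Mapping[str, str],
    abundances: Mapping[str, float],
    threshold: float,
) -> ClusterAssignment:
    """Greedy centroid clustering at a global-alignment identity threshold.

    Sequences are processed by decreasing total abundance (ties broken by
    id); each joins the first centroid with identity >= threshold, else
    founds a new cluster.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    order = sorted(sequences, key=lambda a: (-abundances.get(a, 0.0), a))
    centroids: list[str] = []
    assignment: dict[str, str] = {}
    for asv in order:
        for centroid in centroids:
            ident = _pair_identity(sequences[asv], sequences[centroid])
            if ident >= threshold:
                assignment[asv] = centroid
                break
        else:
            centroids.append(asv)
            assignment[asv] = asv
    return ClusterAssignment(threshold, assignment, centroids)


def collapse_table(table: ASVTable, clusters: ClusterAssignment) -> ASVTable:
    """Sum member counts into their centroid columns."""
    matrix = table.matrix
    frame = matrix.to_frame()
    grouped = frame.T.groupby(
        [clusters.assignment[a] for a in matrix.asv_ids], sort=False
    ).sum().T
    # order clusters by first member appearance so identity clustering
    # preserves the original column order exactly
    col_order, seen = [], set()
    for a in matrix.asv_ids:
        c = clusters.assignment[a]
        if c not in seen:
            seen.add(c)
            col_order.append(c)
    grouped = grouped[col_order]
    new_matrix = CountMatrix.from_frame(grouped)
    seqs = (
        {c: table.sequences[c] for c in new_matrix.asv_ids}
        if table.sequences is not None
        else None
    )
    return ASVTable(new_matrix, {c: table.taxonomy[c] for c in new_matrix.asv_ids}, seqs)


# --------------------------------------------------------------------------
# Hurdle GLM


@dataclasses.dataclass
class HurdleFit:
    taxon: str
    rank: str
    marker: str
    model: str  # "glm.bin" | "glm.cont"
    beta_bmi: float | None
    se: float | None
    p: float | None
    fdr: float | None
    n_obs: int
    converged: bool
    note: str = ""


def _design_matrix(
    metadata: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "bmi": metadata["bmi"].astype(float)})
    X.index = metadata.index
    for cov in covariates:
        col = metadata[cov]
        if pd.api.types.is_numeric_dtype(col):
            X[cov] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                X[f"{cov}[{level}]"] = (col.astype(str) == level).astype(float)
    return X


_SEPARATION_BETA = 30.0


def fit_hurdle(
    shannon_values: pd.Series | Sequence[float],
    metadata: pd.DataFrame,
    covariates: Sequence[str] = ("city",),
    taxon: str = "",
    rank: str = "",
    marker: str = "",
) -> tuple[HurdleFit, HurdleFit]:
    """Two-part association of Shannon diversity with continuous BMI.

    glm.bin: 1{H>0} ~ BMI + covariates, binomial/logit.  glm.cont: H on the
    H>0 subset, Gamma with log link, dispersion from Pearson residuals.
    Wald tests on the BMI coefficient.  Degenerate inputs (all zero / all
    positive / too few positives) and quasi-separation are flagged, not
    raised.
    """
    h = np.asarray(shannon_values, dtype=float)
    if len(h) != len(metadata):
        raise ValueError("response and metadata length mismatch")
    if len(h) < 10:
        raise ValueError("need at least 10 samples")
    X = _design_matrix(metadata.reset_index(drop=True), covariates)
    present = (h > 0).astype(float)

    def _flagged(model: str, n: int, note: str) -> HurdleFit:
        return HurdleFit(taxon, rank, marker, model, None, None, None, None, n, False, note)

    # binary part
    if present.min() == present.max():
        fit_bin = _flagged(
            "glm.bin", len(h), "non-estimable: response all zero or all positive"
        )
    else:
        res = sm.GLM(present, X, family=sm.families.Binomial()).fit(
            maxiter=100, tol=1e-8
        )
        beta, se = float(res.params["bmi"]), float(res.bse["bmi"])
        p = float(res.pvalues["bmi"])
        converged = bool(res.converged) and abs(res.params).max() < _SEPARATION_BETA
        note = "" if converged else "quasi-separation or non-convergence"
        fit_bin = HurdleFit(
            taxon, rank, marker, "glm.bin", beta, se, p, None, len(h), converged, note
        )

    # continuous part
    pos = h > 0
    n_pos = int(pos.sum())
    if n_pos < X.shape[1] + 2:
        fit_cont = _flagged(
            "glm.cont", n_pos, "non-estimable: too few positive observations"
        )
    else:
        res = sm.GLM(
            h[pos],
            X.iloc[np.flatnonzero(pos)],
            family=sm.families.Gamma(link=sm.families.links.Log()),
        ).fit(maxiter=100, tol=1e-8, scale="X2")
        beta, se = float(res.params["bmi"]), float(res.bse["bmi"])
        p = float(res.pvalues["bmi"])
        converged = bool(res.converged)
        fit_cont = HurdleFit(
            taxon, rank, marker, "glm.cont", beta, se, p, None, n_pos, converged,
            "" if converged else "non-convergence",
        )
    return fit_bin, fit_cont


# --------------------------------------------------------------------------
# FDR


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values: sort, multiply by m/rank, take the
    cumulative minimum from the largest down, cap at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def adjust_fdr(
    pvalues: Sequence[float], groups: Sequence | None = None
) -> np.ndarray:
    """BH adjustment, applied within each declared family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if groups is None:
        return benjamini_hochberg(p)
    codes = pd.factorize(pd.Series(list(groups), dtype=object))[0]
    out = np.empty_like(p)
    for g in np.unique(codes):
        mask = codes == g
        out[mask] = benjamini_hochberg(p[mask])
    return out


DEFAULT_FDR_ALPHA = 0.20


# --------------------------------------------------------------------------
# End-to-end per-taxon scan and clustering sensitivity


def analyze_diversity(
    table: ASVTable,
    metadata: pd.DataFrame,
    taxa: Sequence[tuple[str, str]],
    marker: str = "amplicon",
    min_total: int = DEFAULT_MIN_TOTAL,
    depth: int | None = None,
    seed=0,
    covariates: Sequence[str] = ("city",),
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
    do_rarefy: bool = True,
) -> pd.DataFrame:
    """filter -> rarefy -> per-taxon subset Shannon -> hurdle GLM -> BH-FDR.

    FDR families are (marker, rank, model).  Returns one row per taxon per
    model part.
    """
    filtered = filter_min_counts(table, min_total).table
    if do_rarefy:
        filtered = rarefy(filtered, depth, seed)
    meta = (
        metadata.set_index("sample_id")
        .loc[filtered.matrix.sample_ids]
        .reset_index()
    )
    fits: list[HurdleFit] = []
    for rank, name in taxa:
        h = subset_shannon(filtered, rank, name)
        fits.extend(
            fit_hurdle(h, meta, covariates, taxon=name, rank=rank, marker=marker)
        )
    frame = pd.DataFrame([dataclasses.asdict(f) for f in fits])
    frame["fdr"] = np.nan
    testable = frame["p"].notna()
    if testable.any():
        frame.loc[testable, "fdr"] = adjust_fdr(
            frame.loc[testable, "p"].to_numpy(),
            list(
                zip(
                    frame.loc[testable, "marker"],
                    frame.loc[testable, "rank"],
                    frame.loc[testable, "model"],
                )
            ),
        )
    frame["significant"] = frame["fdr"] < fdr_alpha
    return frame


def sensitivity_suite(
    table: ASVTable,
    metadata: pd.DataFrame,
    taxa: Sequence[tuple[str, str]],
    thresholds: Iterable[float] = (1.0, 0.97, 0.90, 0.85),
    marker: str = "amplicon",
    seed=0,
    **analyze_kwargs,
) -> dict[float, pd.DataFrame]:
    """Re-run the diversity scan after collapsing ASVs at each identity
    threshold."""
    if table.sequences is None:
        raise ValueError("representative sequences required for clustering")
    abundances = dict(zip(table.matrix.asv_ids, table.matrix.asv_sums()))
    results = {}
    for t in thresholds:
        clusters = greedy_cluster(table.sequences, abundances, t)
        collapsed = collapse_table(table, clusters)
        results[t] = analyze_diversity(
            collapsed, metadata, taxa, marker=marker, seed=seed, **analyze_kwargs
        )
    return results
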