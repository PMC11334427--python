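"""Differential ASV abundance across BMI categories.

Median-of-ratios size factors and a per-ASV negative-binomial GLM with a
Wald test on the category contrast.  Dispersion is estimated per ASV by
maximum likelihood (method-of-moments start, floored at 1e-8); there is no
dispersion or fold-change shrinkage, so this is a plain NB analogue of the
usual shrinkage-based pipelines — noted in every output header.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .core_io import CountMatrix
from .amplicon_diversity import benjamini_hochberg

DISPERSION_FLOOR = 1e-8
_DISPERSION_CEIL = 1e4


def size_factors(matrix: CountMatrix, allow_fallback: bool = False) -> np.ndarray:
    """Median-of-ratios normalization factors, one per sample.

    Reference set: ASVs with strictly positive counts in every sample; each
    sample's factor is the median of its counts divided by the reference
    ASVs' geometric means.  With no all-positive ASV the fallback (enabled
    by flag) uses per-ASV geometric means over the positive entries only.
    """
    counts = matrix.counts.astype(float)
    all_positive = (counts > 0).all(axis=0)
    if all_positive.any():
        ref = counts[:, all_positive]
        log_geo = np.log(ref).mean(axis=0)
        factors = np.exp(np.median(np.log(ref) - log_geo, axis=1))
    elif allow_fallback:
        with np.errstate(divide="ignore"):
            logs = np.where(counts > 0, np.log(counts), np.nan)
        log_geo = np.nanmean(logs, axis=0)
        ratios = logs - log_geo
        factors = np.exp(np.nanmedian(ratios, axis=1))
    else:
        raise ValueError(
            "no ASV has positive counts in every sample; pass "
            "allow_fallback=True to use the positive-entry pseudo-reference"
        )
    if not (np.isfinite(factors).all() and (factors > 0).all()):
        raise ValueError("size factors must be positive and finite")
    return factors


# --------------------------------------------------------------------------
# Negative-binomial GLM with ML dispersion


def _nb_negloglik(alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    r = 1.0 / alpha
    return float(
        -np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _mom_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    return float(np.clip(num / den if den > 0 else DISPERSION_FLOOR,
                         DISPERSION_FLOOR, _DISPERSION_CEIL))


def fit_nb_glm(
    y: np.ndarray, X: np.ndarray | pd.DataFrame, offset: np.ndarray, max_outer: int = 10
):
    """NB GLM (log link) with dispersion profiled by maximum likelihood.

    Alternates GLM fits at fixed dispersion with 1-D ML updates of the
    dispersion given the fitted means.  Returns (results, alpha).
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        mu = pois.mu
        alpha = _mom_alpha(y, mu)
        for _ in range(max_outer):
            res = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit(maxiter=100)
            mu = res.mu
            opt = optimize.minimize_scalar(
                lambda la: _nb_negloglik(np.exp(la), y, mu),
                bounds=(np.log(DISPERSION_FLOOR), np.log(_DISPERSION_CEIL)),
                method="bounded",
                options={"xatol": 1e-6},
            )
            new_alpha = float(np.exp(opt.x))
            if abs(np.log(new_alpha) - np.log(alpha)) < 1e-4:
                alpha = new_alpha
                break
            alpha = new_alpha
        res = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit(maxiter=100)
    return res, alpha


@dataclasses.dataclass
class DifferentialAbundanceResult:
    asv_id: str
    base_mean: float
    log2_fold_change: float | None
    se: float | None
    wald_p: float | None
    fdr: float | None
    converged: bool
    note: str = ""


def nb_wald_test(
    matrix: CountMatrix,
    factors: np.ndarray,
    condition: Sequence[str],
    contrast: tuple[str, str],
    extra_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-ASV NB Wald test of ``contrast[0]`` vs reference ``contrast[1]``.

    The model is count ~ condition with offset log(size factor); the Wald
    statistic tests the contrast coefficient (log2 scale in the output).
    ASVs with all-zero counts in both contrast levels are excluded with a
    reason; BH-FDR is computed across the tested ASVs.
    """
    condition = pd.Series(list(condition), dtype=str)
    if len(condition) != len(matrix.sample_ids):
        raise ValueError("condition length must match sample count")
    level_a, level_b = contrast
    levels = sorted(condition.unique())
    for lvl in contrast:
        if lvl not in levels:
            raise ValueError(f"contrast level {lvl!r} absent from condition")
        if (condition == lvl).sum() < 3:
            raise ValueError(f"contrast level {lvl!r} has fewer than 3 samples")
    # reference = contrast[1]; dummies for the remaining levels
    ordered = [level_b] + [l for l in levels if l != level_b]
    X = pd.DataFrame({"const": np.ones(len(condition))})
    for lvl in ordered[1:]:
        X[lvl] = (condition == lvl).astype(float)
    if extra_covariates is not None:
        X = pd.concat([X, extra_covariates.reset_index(drop=True)], axis=1)
    offset = np.log(np.asarray(factors, dtype=float))
    in_contrast = condition.isin(contrast).to_numpy()

    results: list[DifferentialAbundanceResult] = []
    norm = matrix.counts / np.asarray(factors)[:, None]
    for j, asv in enumerate(matrix.asv_ids):
        y = matrix.counts[:, j].astype(float)
        base_mean = float(norm[:, j].mean())
        if y[in_contrast].sum() == 0:
            results.append(
                DifferentialAbundanceResult(
                    asv, base_mean, None, None, None, None, False,
                    "excluded: all-zero in both contrast levels",
                )
            )
            continue
        try:
            res, _alpha = fit_nb_glm(y, X, offset)
            beta = float(res.params[level_a])
            se = float(res.bse[level_a])
            z = beta / se
        except Exception as exc:
            results.append(
                DifferentialAbundanceResult(
                    asv, base_mean, None, None, None, None, False, f"fit failed: {exc}"
                )
            )
            continue
        p = 2.0 * float(stats.norm.sf(abs(z)))
        results.append(
            DifferentialAbundanceResult(
                asv, base_mean, beta / np.log(2.0), se / np.log(2.0), p, None,
                bool(res.converged),
            )
        )
    frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
    tested = frame["wald_p"].notna()
    frame["fdr"] = np.nan
    if tested.any():
        frame.loc[tested, "fdr"] = benjamini_hochberg(
            frame.loc[tested, "wald_p"].to_numpy()
        )
    return frame


def run_contrasts(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    category_col: str = "bmi_category",
    allow_fallback: bool = True,
) -> dict[tuple[str, str], pd.DataFrame]:
    """All pairwise category contrasts (FDR within each contrast)."""
    factors = size_factors(matrix, allow_fallback=allow_fallback)
    condition = metadata.set_index("sample_id").loc[matrix.sample_ids, category_col]
    levels = sorted(condition.unique())
    out = {}
    for a, b in itertools.combinations(levels, 2):
        out[(a, b)] = nb_wald_test(matrix, factors, condition, (a, b))
    return out
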