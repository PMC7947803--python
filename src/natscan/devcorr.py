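"""Developmental-correlation analysis of sense-antisense pairs.

Each feature's normalized expression is regressed on age (days) by OLS,
judged by the model F-test.  When the three-age fit fails the test, a
fallback fit on the two older ages (P14, P56) is attempted.  A pair is
classified by the signs of the two final slopes: matching signs imply a
positive developmental correlation, mismatched signs a negative one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LinearFitResult",
    "PairClassification",
    "fit_linear_model",
    "classify_pair",
    "summarize_quadrants",
]

FALLBACK_AGES = (14, 56)


@dataclass(frozen=True)
class LinearFitResult:
    feature_id: str
    tissue: str
    slope: float
    intercept: float
    f_pvalue: float  # NaN when undefined
    n_points: int
    used_fallback: bool
    fit_ok: bool


@dataclass(frozen=True)
class PairClassification:
    gene_id: str
    contig_id: str
    tissue: str
    klass: str  # positive | negative | flat | unfit


def _ols(values: np.ndarray, ages: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, F-test p) of value on age.

    For simple regression the model F-test coincides with the slope t-test.
    """
    X = sm.add_constant(ages.astype(float))
    fit = sm.OLS(values.astype(float), X).fit()
    p = float(fit.f_pvalue) if fit.f_pvalue is not None else math.nan
    return float(fit.params[1]), float(fit.params[0]), p


def fit_linear_model(
    values: Sequence[float],
    ages: Sequence[float],
    alpha: float = 0.05,
    feature_id: str = "",
    tissue: str = "",
) -> LinearFitResult:
    """Fit expression on age with the two-age fallback.

    The full fit uses every sample; if its F-test p >= alpha (or is
    undefined), the fit is repeated on samples at the fallback ages (P14
    and P56) only.  ``fit_ok`` is True iff the final p < alpha.  Constant
    values or fewer than two distinct ages leave the feature unfit.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.shape != a.shape:
        raise ValueError("values and ages must have equal length")
    if len(v) < 3 or len(np.unique(a)) < 2:
        raise ValueError("need >=3 samples spanning >=2 distinct ages")

    def _attempt(vals: np.ndarray, ags: np.ndarray) -> tuple[float, float, float]:
        if np.allclose(vals, vals[0]) or len(np.unique(ags)) < 2:
            return 0.0, float(vals[0]) if len(vals) else 0.0, math.nan
        return _ols(vals, ags)

    slope, intercept, p = _attempt(v, a)
    used_fallback = False
    n_points = len(v)

    if not (p < alpha):  # failed or undefined -> fallback on older ages
        mask = np.isin(a, FALLBACK_AGES)
        if mask.sum() >= 2 and len(np.unique(a[mask])) >= 2:
            slope, intercept, p = _attempt(v[mask], a[mask])
            used_fallback = True
            n_points = int(mask.sum())

    fit_ok = bool(p < alpha) if not math.isnan(p) else False
    return LinearFitResult(
        feature_id=feature_id,
        tissue=tissue,
        slope=slope,
        intercept=intercept,
        f_pvalue=p,
        n_points=n_points,
        used_fallback=used_fallback,
        fit_ok=fit_ok,
    )


def classify_pair(
    gene_fit: LinearFitResult, contig_fit: LinearFitResult
) -> PairClassification:
    """Slope-sign classification of a sense-antisense pair (same tissue).

    unfit if either fit failed; flat if either final slope is exactly
    zero; positive when slope signs match, negative when they differ.
    """
    if gene_fit.tissue != contig_fit.tissue:
        raise ValueError(
            f"tissue mismatch: {gene_fit.tissue!r} vs {contig_fit.tissue!r}"
        )
    if not (gene_fit.fit_ok and contig_fit.fit_ok):
        klass = "unfit"
    elif gene_fit.slope == 0.0 or contig_fit.slope == 0.0:
        klass = "flat"
    elif (gene_fit.slope > 0) == (contig_fit.slope > 0):
        klass = "positive"
    else:
        klass = "negative"
    return PairClassification(
        gene_id=gene_fit.feature_id,
        contig_id=contig_fit.feature_id,
        tissue=gene_fit.tissue,
        klass=klass,
    )


def summarize_quadrants(
    pairs: Iterable[PairClassification],
) -> pd.DataFrame:
    """Counts per class per tissue; rows sum to the number of input pairs."""
    classes = ["positive", "negative", "flat", "unfit"]
    tallies: dict[str, dict[str, int]] = {}
    for p in pairs:
        row = tallies.setdefault(p.tissue, {k: 0 for k in classes})
        row[p.klass] += 1
    df = pd.DataFrame.from_dict(tallies, orient="index", dtype=int)
    if df.empty:
        df = pd.DataFrame(columns=classes, dtype=int)
    df = df.reindex(columns=classes, fill_value=0)
    df.index.name = "tissue"
    return df.sort_index()
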