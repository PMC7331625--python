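"""Shannon-diversity estimators and Nei's gene diversity for allele counts.

All entropies are in nats (natural logarithm).  The plug-in estimator
``h_mle`` is the classical -sum(p ln p) with sample frequencies; it is
negatively biased in small samples because unsampled alleles inflate the
frequencies of those seen.  Three corrections are provided:

``h_zahl``
    Jackknife bias correction: ``n*H - (n-1)*mean(H_{-i})`` where ``H_{-i}``
    is the plug-in entropy with one gene copy removed.
``h_chao_shen``
    Coverage-adjusted Horvitz-Thompson estimator.  Sample frequencies are
    shrunk by the Good-Turing coverage ``C = 1 - f1/n`` (``f1`` singletons)
    and each term is inflated by the probability the allele is seen at all.
    When every allele is a singleton the coverage is zero and the estimator
    is undefined: this raises :class:`ChaoShenFailure`, a first-class
    signal that batch drivers record as a missing value.
``h_chao2013``
    Harmonic-number series estimator with a singleton/doubleton tail
    correction governed by the Good-Turing ratio ``A``.

``gene_diversity`` (expected heterozygosity, ``1 - sum(p^2)``) serves as the
conventional population-genetic reference measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .popdata import AlleleCounts

METRICS = ("H_MLE", "H_Z", "H_CS", "H_Chao", "Hs")

__all__ = [
    "METRICS",
    "ChaoShenFailure",
    "EstimateRecord",
    "h_mle",
    "h_zahl",
    "h_chao_shen",
    "h_chao2013",
    "gene_diversity",
    "estimate_all",
]


class ChaoShenFailure(ArithmeticError):
    """Chao-Shen estimator undefined: zero estimated sample coverage
    (every allele a singleton, f1 == n)."""


@dataclass(frozen=True)
class EstimateRecord:
    """One estimator value with provenance.

    ``value`` is ``None`` only for the Chao-Shen estimator's defined
    failure mode.  ``sample_size`` is an integer number of genotypes or the
    string ``"parametric"`` for whole-population values.
    """

    metric: str
    value: float | None
    locus: str
    population: str
    sample_size: int | str
    replicate: int
    resample: int | None = None


def _counts(c) -> np.ndarray:
    """Coerce an AlleleCounts or positive-count vector to int64 array."""
    if isinstance(c, AlleleCounts):
        return c.counts
    arr = np.asarray(c, dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("counts must be a non-empty 1-d vector")
    if np.any(arr < 1):
        raise ValueError("allele counts must be strictly positive")
    return arr


def h_mle(c) -> float:
    """Plug-in (maximum-likelihood) Shannon entropy, -sum p ln p."""
    x = _counts(c)
    n = x.sum()
    p = x / n
    return float(-np.sum(xlogy(p, p)))


def h_zahl(c) -> float:
    """Zahl's jackknife entropy, ``n*H - (n-1)*mean leave-one-out H``.

    Leave-outs are grouped by allele (removing any copy of allele i yields
    the same configuration), which equals the literal n-fold average.
    """
    x = _counts(c)
    n = int(x.sum())
    if n < 2:
        raise ValueError("Zahl jackknife requires at least 2 gene copies")
    h_full = h_mle(x)
    # H_{-i} = ln(n-1) - (S - g(x_i))/(n-1), S = sum x ln x,
    # g(x) = x ln x - (x-1) ln(x-1); weighting by x_i/n and summing:
    s = float(np.sum(xlogy(x, x)))
    g = xlogy(x, x) - xlogy(x - 1, x - 1)
    h_loo_mean = np.log(n - 1) - (n * s - float(np.sum(x * g))) / (n * (n - 1))
    return float(n * h_full - (n - 1) * h_loo_mean)


def h_chao_shen(c) -> float:
    """Chao-Shen coverage-adjusted Horvitz-Thompson entropy.

    Raises
    ------
    ChaoShenFailure
        If all alleles are singletons (estimated coverage zero).
    """
    x = _counts(c)
    n = int(x.sum())
    f1 = int(np.count_nonzero(x == 1))
    if f1 == n:
        raise ChaoShenFailure(
            f"all {n} gene copies are singletons: estimated coverage is 0"
        )
    coverage = 1.0 - f1 / n
    p_adj = coverage * x / n
    detect = 1.0 - (1.0 - p_adj) ** n  # P(allele enters the sample)
    return float(np.sum(-xlogy(p_adj, p_adj) / detect))


def h_chao2013(c) -> float:
    """Chao, Wang & Jost's series entropy with Good-Turing tail correction.

    The main term sums ``(x_i/n) * (H_{n-1} - H_{x_i - 1})`` with harmonic
    numbers ``H_m``; the tail term adds the contribution of unseen alleles
    estimated from singletons (f1) and doubletons (f2) through
    ``A = 2 f2 / ((n-1) f1 + 2 f2)`` (with the usual f2 = 0 and f1 = 0
    fallbacks).
    """
    x = _counts(c)
    n = int(x.sum())
    if n < 2:
        raise ValueError("estimator requires at least 2 gene copies")
    f1 = int(np.count_nonzero(x == 1))
    f2 = int(np.count_nonzero(x == 2))
    # cumulative harmonic numbers: harm[m] = 1 + 1/2 + ... + 1/m, harm[0] = 0
    harm = np.concatenate(([0.0], np.cumsum(1.0 / np.arange(1, n))))
    main = float(np.sum(x / n * (harm[n - 1] - harm[x - 1])))
    if f1 == 0:
        return main
    if f2 > 0:
        a = 2.0 * f2 / ((n - 1.0) * f1 + 2.0 * f2)
    else:
        a = 2.0 / ((n - 1.0) * (f1 - 1.0) + 2.0)
    if a >= 1.0:  # degenerate: tail mass estimate vanishes
        return main
    r = np.arange(1, n)
    series = float(np.sum((1.0 - a) ** r / r))
    tail = f1 / n * (1.0 - a) ** (1 - n) * (-np.log(a) - series)
    return main + tail


def gene_diversity(c) -> float:
    """Nei's gene diversity (expected heterozygosity), 1 - sum p^2."""
    x = _counts(c)
    p = x / x.sum()
    return float(1.0 - np.sum(p * p))


_FUNCS = {
    "H_MLE": h_mle,
    "H_Z": h_zahl,
    "H_CS": h_chao_shen,
    "H_Chao": h_chao2013,
    "Hs": gene_diversity,
}


def estimate_all(
    c,
    metrics=METRICS,
    *,
    locus: str = "",
    population: str = "",
    sample_size: int | str = 0,
    replicate: int = 0,
    resample: int | None = None,
) -> list[EstimateRecord]:
    """Evaluate the requested metrics on one counts vector.

    A Chao-Shen failure is recorded as a missing value without aborting the
    other metrics.
    """
    if not metrics:
        raise ValueError("metrics must be non-empty")
    unknown = [m for m in metrics if m not in _FUNCS]
    if unknown:
        raise ValueError(f"unknown metric(s): {unknown}; choose from {METRICS}")
    records = []
    for m in metrics:
        try:
            value = _FUNCS[m](c)
        except ChaoShenFailure:
            value = None
        records.append(
            EstimateRecord(
                metric=m,
                value=value,
                locus=locus,
                population=population,
                sample_size=sample_size,
                replicate=replicate,
                resample=resample,
            )
        )
    return records
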