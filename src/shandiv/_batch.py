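"""Vectorised estimator evaluation on stacks of count vectors.

The resampling experiment evaluates each estimator tens of millions of
times, so the per-vector functions in :mod:`.estimators` are too slow to
call in a Python loop.  This module recomputes the same formulas on a
``(m, k)`` matrix of allele counts (rows = resamples, columns = allele
states, zeros = unobserved states) in a handful of array operations per
metric.  All rows must share one total ``n``; tests assert bitwise-level
agreement with the scalar implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

__all__ = ["batch_estimates"]


def batch_estimates(counts: np.ndarray, metrics) -> dict[str, np.ndarray]:
    """Evaluate metrics row-wise on a matrix of allele counts.

    Parameters
    ----------
    counts
        Integer array ``(m, k)``; zero entries mean "state not observed"
        and are ignored.  Every row must sum to the same ``n >= 2``.
    metrics
        Iterable drawn from ``estimators.METRICS``.

    Returns
    -------
    dict mapping metric name to a float array of length ``m``.  For
    ``H_CS``, rows where every observed allele is a singleton are NaN
    (the estimator's defined failure mode).
    """
    x = np.asarray(counts, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("counts must be 2-d (resamples x allele states)")
    totals = x.sum(axis=1)
    n = int(totals[0])
    if not np.all(totals == n):
        raise ValueError("all rows must have the same number of gene copies")
    if n < 2:
        raise ValueError("need at least 2 gene copies per row")

    p = x / n
    f1 = (x == 1).sum(axis=1)
    out: dict[str, np.ndarray] = {}

    if "H_MLE" in metrics or "H_Z" in metrics:
        hmle = -xlogy(p, p).sum(axis=1)
    if "H_MLE" in metrics:
        out["H_MLE"] = hmle
    if "Hs" in metrics:
        out["Hs"] = 1.0 - (p * p).sum(axis=1)
    if "H_Z" in metrics:
        s = xlogy(x, x).sum(axis=1)
        xm1 = np.maximum(x - 1.0, 0.0)  # zero cells would give xlogy(-1, -1)
        g = xlogy(x, x) - xlogy(xm1, xm1)
        loo = np.log(n - 1.0) - (n * s - (x * g).sum(axis=1)) / (n * (n - 1.0))
        out["H_Z"] = n * hmle - (n - 1.0) * loo
    if "H_CS" in metrics:
        coverage = 1.0 - f1 / n
        p_adj = coverage[:, None] * p
        detect = 1.0 - (1.0 - p_adj) ** n
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(p_adj > 0, -xlogy(p_adj, p_adj) / detect, 0.0)
        hcs = terms.sum(axis=1)
        hcs[f1 == n] = np.nan
        out["H_CS"] = hcs
    if "H_Chao" in metrics:
        out["H_Chao"] = _chao2013_rows(x, n, f1)
    unknown = set(metrics) - set(out)
    if unknown:
        raise ValueError(f"unknown metric(s): {sorted(unknown)}")
    return out


def _chao2013_rows(x: np.ndarray, n: int, f1: np.ndarray) -> np.ndarray:
    f2 = (x == 2).sum(axis=1)
    harm = np.concatenate(([0.0], np.cumsum(1.0 / np.arange(1, n))))
    xi = x.astype(np.int64)
    main = (x / n * (harm[n - 1] - harm[np.maximum(xi - 1, 0)])).sum(axis=1)

    a = np.ones_like(main)
    has_f2 = (f1 > 0) & (f2 > 0)
    no_f2 = (f1 > 0) & (f2 == 0)
    a[has_f2] = 2.0 * f2[has_f2] / ((n - 1.0) * f1[has_f2] + 2.0 * f2[has_f2])
    a[no_f2] = 2.0 / ((n - 1.0) * (f1[no_f2] - 1.0) + 2.0)

    tail = np.zeros_like(main)
    active = (f1 > 0) & (a < 1.0)
    if np.any(active):
        aa = a[active]
        r = np.arange(1, n)
        series = ((1.0 - aa[:, None]) ** r / r).sum(axis=1)
        tail[active] = (
            f1[active] / n * (1.0 - aa) ** (1 - n) * (-np.log(aa) - series)
        )
    return main + tail
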