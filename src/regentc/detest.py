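"""Temporal differential-expression testing.

Each gene's log-scale profile is regressed on a natural-cubic-spline basis
of time and compared to a time-independent (intercept-only) null by a
likelihood-ratio test: ``lrt = n * ln(RSS0 / RSS1)`` referred to a
chi-squared distribution with ``df`` degrees of freedom. Q-values are
Benjamini-Hochberg, and the dynamic-gene cutoff is calibrated from the
spike-in transcripts (``factor * min spike-in qval``, capped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from regentc.core import SpikeInSet, TimeCourseMatrix


@dataclass(frozen=True)
class SplineSpec:
    """Natural-spline basis specification (df columns, intercept excluded)."""

    df: int = 3

    def __post_init__(self) -> None:
        if self.df < 2:
            raise ValueError("spline df must be >= 2")


@dataclass
class DETestResult:
    gene_id: str
    lrt_stat: float
    pval: float
    qval: float = float("nan")
    dynamic: bool = False
    is_spikein: bool = False


@dataclass(frozen=True)
class CutoffPolicy:
    """cutoff = min(factor * min spike-in qval, cap)."""

    factor: float = 10.0
    cap: float = 1.0

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if not 0 < self.cap <= 1:
            raise ValueError("cap must be in (0, 1]")


def spline_knots(times: Iterable[float], spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Boundary + interior knots: min/max of the distinct times plus df-1
    interior knots at quantiles of the distinct times."""
    uniq = np.unique(np.asarray(list(times), dtype=float))
    needed = spec.df + 2
    if uniq.size < needed:
        raise ValueError(
            f"need at least {needed} distinct time points for df={spec.df}, "
            f"got {uniq.size}"
        )
    probs = np.linspace(0, 1, spec.df + 1)  # boundary + df-1 interior
    knots = np.quantile(uniq, probs)
    if np.unique(knots).size != knots.size:
        raise ValueError("degenerate (duplicated) knots from time quantiles")
    return knots


def natural_spline_basis(
    times: Iterable[float],
    spec: SplineSpec = SplineSpec(),
    knots: np.ndarray | None = None,
) -> np.ndarray:
    """Natural-cubic-spline basis: df columns, linear beyond boundary knots.

    Knots default to :func:`spline_knots` of the given times; pass ``knots``
    to evaluate the same basis at other points. Uses the truncated-power
    natural basis: N_1(x) = x and, for interior knots xi_k,
    N_{k+1}(x) = d_k(x) - d_{K-1}(x) with
    d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k).
    """
    x = np.asarray(list(times), dtype=float)
    if knots is None:
        knots = spline_knots(x, spec)
    else:
        knots = np.asarray(knots, dtype=float)
        if knots.size != spec.df + 1:
            raise ValueError(f"expected {spec.df + 1} knots, got {knots.size}")

    K = knots.size  # df + 1

    def d(k: int, v: np.ndarray) -> np.ndarray:
        num = np.clip(v - knots[k], 0, None) ** 3 - np.clip(v - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k, x) - d(K - 2, x))
    return np.column_stack(cols)


def lrt_dynamic_test(
    profile: Sequence[float],
    times: Sequence[float],
    spec: SplineSpec = SplineSpec(),
    basis: np.ndarray | None = None,
) -> tuple[float, float]:
    """Spline-vs-constant likelihood-ratio test for one gene.

    Returns (lrt_stat, pval). ``basis`` may be precomputed for the same
    ``times`` to avoid rebuilding it per gene.
    """
    y = np.asarray(profile, dtype=float)
    if basis is None:
        basis = natural_spline_basis(times, spec)
    n = y.size
    p1 = spec.df + 1
    if n <= p1:
        raise ValueError(f"need more than {p1} samples, got {n}")
    X = np.column_stack([np.ones(n), basis])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ coef) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss0 <= 0:
        return 0.0, 1.0
    if rss1 <= max(1e-12 * rss0, 1e-300):
        warnings.warn("zero residual sum of squares under the full model")
        return float("inf"), 0.0
    stat = max(n * np.log(rss0 / rss1), 0.0)
    pval = float(stats.chi2.sf(stat, spec.df))
    return stat, pval


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving in p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_de(
    matrix: TimeCourseMatrix,
    paradigm: str,
    spec: SplineSpec = SplineSpec(),
    spikeins: SpikeInSet | None = None,
) -> list[DETestResult]:
    """Test every gene of one paradigm's samples; BH-adjust across all rows.

    The matrix must be on the log scale. Spike-in rows are tested and
    adjusted together with the genes (they calibrate the cutoff) but are
    flagged so that dynamic-gene calls can exclude them.
    """
    if matrix.scale != "log":
        raise ValueError(f"run_de expects log-scale values, got {matrix.scale!r}")
    sub = matrix.subset_paradigm(paradigm)
    times = sub.times
    basis = natural_spline_basis(times, spec)
    n = times.size
    X = np.column_stack([np.ones(n), basis])
    # shared design: hat-matrix residuals for all genes at once
    Q, _ = np.linalg.qr(X)
    Y = sub.values
    resid1 = Y - (Y @ Q) @ Q.T
    rss1 = np.sum(resid1**2, axis=1)
    rss0 = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)

    spike_set = set(spikeins.spikein_ids) if spikeins is not None else set()
    results = []
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rss1 > 0, rss0 / np.maximum(rss1, 1e-300), np.inf)
    for i, gene in enumerate(sub.gene_ids):
        if rss0[i] <= 0:
            stat, pval = 0.0, 1.0
        elif rss1[i] <= max(1e-12 * rss0[i], 1e-300):
            stat, pval = float("inf"), 0.0
        else:
            stat = max(n * float(np.log(ratio[i])), 0.0)
            pval = float(stats.chi2.sf(stat, spec.df))
        results.append(
            DETestResult(
                gene_id=gene, lrt_stat=stat, pval=pval, is_spikein=gene in spike_set
            )
        )
    qvals = bh_adjust([r.pval for r in results])
    for r, q in zip(results, qvals):
        r.qval = float(q)
    return results


def spikein_cutoff(
    results: Sequence[DETestResult],
    spikeins: SpikeInSet,
    policy: CutoffPolicy = CutoffPolicy(),
) -> float:
    """Significance cutoff calibrated from the spike-in q-values."""
    spike_ids = set(spikeins.spikein_ids)
    qvals = [r.qval for r in results if r.gene_id in spike_ids]
    if not qvals:
        raise ValueError("no spike-ins present among the test results")
    return float(min(policy.factor * min(qvals), policy.cap))


def call_dynamic_genes(results: Sequence[DETestResult], cutoff: float) -> set[str]:
    """Genes (excluding spike-ins) with qval < cutoff; updates dynamic flags."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    dynamic = set()
    for r in results:
        r.dynamic = (not r.is_spikein) and r.qval < cutoff
        if r.dynamic:
            dynamic.add(r.gene_id)
    return dynamic


def results_to_frame(results: Sequence[DETestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "lrt_stat": [r.lrt_stat for r in results],
            "pval": [r.pval for r in results],
            "qval": [r.qval for r in results],
            "dynamic": [r.dynamic for r in results],
            "is_spikein": [r.is_spikein for r in results],
        }
    )
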