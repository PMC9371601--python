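"""Cascade classification under translation inhibition.

Each gene's control (untreated) and cycloheximide time courses are
correlated over their shared time grid; genes whose treated profile tracks
the control (r >= threshold) are called translation independent — the
putative first tier of the expression cascade. Per-cluster summaries are
averaged on the Fisher-z (atanh) scale, on which mean values above 1 are
possible, and back-transformed for reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from regentc.core import TimeCourseMatrix
from regentc.modules import ClusterAssignment

_R_CLAMP = 1.0 - 1e-12


@dataclass
class CascadeResult:
    gene_id: str
    r: float
    z: float
    label: str = "unclassified"
    cluster: int | None = None
    classifiable: bool = True


def profile_correlation(control: Sequence[float], treated: Sequence[float]) -> float:
    """Pearson correlation of two aligned profiles (length >= 3, nonconstant)."""
    x = np.asarray(control, dtype=float)
    y = np.asarray(treated, dtype=float)
    if x.size != y.size:
        raise ValueError("profiles have different lengths")
    if x.size < 3:
        raise ValueError("need at least 3 shared time points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r: float) -> float:
    """atanh of a correlation, clamped away from +-1 so the value is finite."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    return float(np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP)))


def correlate_paradigms(
    matrix: TimeCourseMatrix,
    genes: Sequence[str],
    control_paradigm: str = "sucrose",
    treated_paradigm: str = "sucrose_chx",
) -> list[CascadeResult]:
    """Correlate each gene's replicate-averaged profiles between two paradigms.

    The matrix should be replicate-averaged and on the log scale; profiles
    are aligned on the intersection of the two time grids. Genes with a
    constant profile in either paradigm are returned unclassifiable.
    """
    control = matrix.subset_paradigm(control_paradigm)
    treated = matrix.subset_paradigm(treated_paradigm)
    shared = sorted(set(control.times) & set(treated.times))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared time points between paradigms")
    c_idx = [int(np.nonzero(control.times == t)[0][0]) for t in shared]
    t_idx = [int(np.nonzero(treated.times == t)[0][0]) for t in shared]

    out = []
    for gene in genes:
        x = control.row(gene)[c_idx]
        y = treated.row(gene)[t_idx]
        try:
            r = profile_correlation(x, y)
        except ValueError:
            out.append(
                CascadeResult(gene_id=gene, r=float("nan"), z=float("nan"), classifiable=False)
            )
            continue
        out.append(CascadeResult(gene_id=gene, r=r, z=fisher_z(r)))
    return out


def classify_translation_independence(
    results: Sequence[CascadeResult], threshold: float = 0.8
) -> list[CascadeResult]:
    """Label each classifiable result: r >= threshold -> translation_independent."""
    if not -1.0 < threshold < 1.0:
        raise ValueError("threshold must be in (-1, 1)")
    for res in results:
        if not res.classifiable:
            continue
        res.label = (
            "translation_independent" if res.r >= threshold else "translation_dependent"
        )
    return list(results)


def cluster_correlation_summary(
    results: Sequence[CascadeResult],
    assignment: ClusterAssignment | Mapping[str, int],
) -> pd.DataFrame:
    """Per-cluster count, mean Fisher-z, and back-transformed tanh(mean z).

    Empty clusters are simply absent from the output. Unclassifiable genes
    are excluded.
    """
    cluster_of = (
        assignment.cluster_of if isinstance(assignment, ClusterAssignment) else assignment
    )
    by_cluster: dict[int, list[float]] = {}
    for res in results:
        if not res.classifiable:
            continue
        if res.gene_id not in cluster_of:
            raise ValueError(f"classifiable gene {res.gene_id!r} has no cluster")
        res.cluster = int(cluster_of[res.gene_id])
        by_cluster.setdefault(res.cluster, []).append(res.z)
    rows = []
    for cluster in sorted(by_cluster):
        zs = np.array(by_cluster[cluster])
        rows.append(
            {
                "cluster": cluster,
                "n": zs.size,
                "mean_z": float(zs.mean()),
                "mean_r_backtransformed": float(np.tanh(zs.mean())),
            }
        )
    return pd.DataFrame(rows)


def results_to_frame(results: Sequence[CascadeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "cluster": [r.cluster if r.cluster is not None else 0 for r in results],
            "r": [r.r for r in results],
            "z": [r.z for r in results],
            "label": [r.label for r in results],
        }
    )
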