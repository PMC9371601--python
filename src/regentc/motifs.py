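"""Motif scanning, target prediction, and cross-set overlap statistics.

Motifs are fixed-length patterns of literal bases and bracketed character
classes (e.g. ``TTT[GC][GC]CGC`` for the E2F promoter element bound
upstream, ``TGTA[CTAG]ATA`` for the Pumilio response element bound to
3'UTRs). Scanning reports every window, overlapping hits included; ``N``
never matches. Also here: the generic overlap statistics used to compare
gene sets (Fisher's exact test, one-proportion z-test, chance-overlap
baseline) and reciprocal-best-hit pairing from a similarity score table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from regentc.core import SequenceRegion

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str
    region_kind: str

    def __post_init__(self) -> None:
        if self.region_kind not in ("upstream", "utr3"):
            raise ValueError(f"unknown region kind {self.region_kind!r}")
        compile_motif(self.pattern)  # validate eagerly


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    region_kind: str
    start: int  # 0-based, forward-strand coordinate of leftmost matched base
    match: str
    strand: str = "forward"


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")


def compile_motif(pattern: str) -> list[frozenset[str]]:
    """Expand a bracket pattern into per-position allowed-base sets."""
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            end = pattern.find("]", i)
            if end == -1:
                raise ValueError(f"unbalanced '[' at offset {i} in {pattern!r}")
            inner = pattern[i + 1 : end]
            if not inner:
                raise ValueError(f"empty character class at offset {i} in {pattern!r}")
            for j, ch_inner in enumerate(inner):
                if ch_inner not in _BASES:
                    raise ValueError(
                        f"illegal base {ch_inner!r} at offset {i + 1 + j} in {pattern!r}"
                    )
            positions.append(frozenset(inner))
            i = end + 1
        elif ch == "]":
            raise ValueError(f"unbalanced ']' at offset {i} in {pattern!r}")
        elif ch in _BASES:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(f"illegal base {ch!r} at offset {i} in {pattern!r}")
    if not positions:
        raise ValueError("empty motif pattern")
    return positions


def _scan_forward(positions: Sequence[frozenset[str]], sequence: str) -> list[int]:
    L = len(positions)
    return [
        start
        for start in range(len(sequence) - L + 1)
        if all(sequence[start + k] in positions[k] for k in range(L))
    ]


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def scan_sequence(
    motif: MotifPattern, region: SequenceRegion, scan_reverse: bool = False
) -> list[MotifHit]:
    """All (overlapping) hits of the motif in the region, forward strand by
    default; with ``scan_reverse`` the reverse complement is scanned too and
    hits are reported with forward-strand start coordinates."""
    positions = compile_motif(motif.pattern)
    L = len(positions)
    seq = region.sequence
    hits = [
        MotifHit(
            gene_id=region.gene_id,
            region_kind=region.kind,
            start=s,
            match=seq[s : s + L],
            strand="forward",
        )
        for s in _scan_forward(positions, seq)
    ]
    if scan_reverse:
        rc = reverse_complement(seq)
        n = len(seq)
        for s in _scan_forward(positions, rc):
            fwd_start = n - s - L
            hits.append(
                MotifHit(
                    gene_id=region.gene_id,
                    region_kind=region.kind,
                    start=fwd_start,
                    match=seq[fwd_start : fwd_start + L],
                    strand="reverse",
                )
            )
    return hits


def scan_regions(
    motif: MotifPattern, regions: Iterable[SequenceRegion], scan_reverse: bool = False
) -> list[MotifHit]:
    """Scan the motif over every region of its bound kind."""
    hits: list[MotifHit] = []
    for region in regions:
        if region.kind == motif.region_kind:
            hits.extend(scan_sequence(motif, region, scan_reverse=scan_reverse))
    return hits


def predict_targets(
    hits: Iterable[MotifHit], dynamic: Iterable[str], motif: MotifPattern
) -> set[str]:
    """Dynamic genes with >=1 hit in the motif's bound region kind."""
    dynamic = set(dynamic)
    return {
        h.gene_id for h in hits if h.region_kind == motif.region_kind and h.gene_id in dynamic
    }


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [h.gene_id for h in hits],
            "region_kind": [h.region_kind for h in hits],
            "start": [h.start for h in hits],
            "match": [h.match for h in hits],
            "strand": [h.strand for h in hits],
        }
    )


# -- overlap statistics -------------------------------------------------------


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p (point-probability rule, fixed margins)."""
    _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")
    return float(p)


def one_proportion_ztest(k: int, n: int, p0: float) -> tuple[float, float]:
    """Normal-approximation test of k/n against null proportion p0."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    z = (k / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), p


def expected_overlap_fraction(n_marked: int, n_total: int) -> float:
    """Chance probability that a random gene carries the mark."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_marked <= n_total:
        raise ValueError("n_marked must lie in [0, n_total]")
    return n_marked / n_total


def reciprocal_best_hits(scores: pd.DataFrame) -> set[tuple[str, str]]:
    """Mutual-argmax pairs from a (idA, idB, score) table.

    Ties within a row or column argmax are broken toward the
    lexicographically smallest partner id, so output is deterministic.
    """
    required = {"idA", "idB", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"score table missing columns {sorted(required - set(scores.columns))}")
    if scores.duplicated(subset=["idA", "idB"]).any():
        dupes = scores[scores.duplicated(subset=["idA", "idB"], keep=False)]
        raise ValueError(f"duplicate (idA, idB) entries:\n{dupes}")
    if not np.all(np.isfinite(scores["score"].to_numpy(dtype=float))):
        raise ValueError("scores must be finite")

    def best_partner(frame: pd.DataFrame, by: str, partner: str) -> dict[str, str]:
        out: dict[str, str] = {}
        for key, group in frame.groupby(by, sort=False):
            top = group[group["score"] == group["score"].max()]
            out[str(key)] = str(top[partner].min())
        return out

    best_b = best_partner(scores, "idA", "idB")
    best_a = best_partner(scores, "idB", "idA")
    return {(a, b) for a, b in best_b.items() if best_a.get(b) == a}
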