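"""Domain types, I/O, normalization, replicate averaging, and row z-scoring.

The central carrier is :class:`TimeCourseMatrix`: a gene x sample table of
expression values with per-sample metadata (paradigm, time in minutes,
replicate) and an explicit ``scale`` flag that downstream stages check so
that raw counts are never, e.g., z-scored by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Recognized experimental paradigms.
PARADIGMS = ("sucrose", "posterior_half", "anterior_half", "sucrose_chx")

#: Recognized value scales, in the order they are produced by the pipeline.
SCALES = ("raw_counts", "normalized", "log", "zscore")

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SampleMeta:
    """Identity and design coordinates of one sequenced sample."""

    sample_id: str
    paradigm: str
    time_min: int
    replicate: int

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(
                f"unknown paradigm {self.paradigm!r} for sample {self.sample_id!r}; "
                f"expected one of {PARADIGMS}"
            )
        if self.time_min < 0:
            raise ValueError(f"negative time_min for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1 for sample {self.sample_id!r}")


@dataclass
class TimeCourseMatrix:
    """Gene x sample expression table with sample metadata and a scale flag."""

    gene_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray
    scale: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene_ids: {dupes}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in metadata")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in matrix")
        if self.scale in ("raw_counts", "normalized") and np.any(self.values < 0):
            raise ValueError(f"negative values not allowed on scale {self.scale!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_min for s in self.samples], dtype=float)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, keep: Sequence[bool] | Sequence[int]) -> "TimeCourseMatrix":
        idx = np.arange(len(self.samples))[np.asarray(keep)]
        return TimeCourseMatrix(
            gene_ids=list(self.gene_ids),
            samples=[self.samples[i] for i in idx],
            values=self.values[:, idx].copy(),
            scale=self.scale,
        )

    def subset_paradigm(self, paradigm: str) -> "TimeCourseMatrix":
        if paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {paradigm!r}")
        mask = [s.paradigm == paradigm for s in self.samples]
        if not any(mask):
            raise ValueError(f"no samples with paradigm {paradigm!r}")
        return self.subset_samples(mask)

    def subset_genes(self, gene_ids: Sequence[str]) -> "TimeCourseMatrix":
        idx = [self.gene_index(g) for g in gene_ids]
        return TimeCourseMatrix(
            gene_ids=list(gene_ids),
            samples=list(self.samples),
            values=self.values[idx, :].copy(),
            scale=self.scale,
        )


@dataclass(frozen=True)
class SpikeInSet:
    """Spike-in control rows and their nominal relative concentrations."""

    spikein_ids: tuple[str, ...]
    nominal_level: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid in self.spikein_ids:
            level = self.nominal_level.get(sid, 1.0)
            if level <= 0:
                raise ValueError(f"non-positive nominal level for spike-in {sid!r}")

    def check_against(self, matrix: TimeCourseMatrix) -> None:
        missing = sorted(set(self.spikein_ids) - set(matrix.gene_ids))
        if missing:
            raise ValueError(f"spike-in ids absent from matrix: {missing}")


@dataclass(frozen=True)
class SequenceRegion:
    """A non-coding region (upstream or 3'UTR) attached to a gene."""

    gene_id: str
    kind: str
    sequence: str
    coords: tuple[int, int] | None = None  # 0-based, half-open; informational

    def __post_init__(self) -> None:
        if self.kind not in ("upstream", "utr3"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for gene {self.gene_id!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"invalid characters {sorted(bad)} in region of gene {self.gene_id!r}"
            )


# -- file I/O -----------------------------------------------------------------


def read_counts_table(path: str | Path, meta_path: str | Path) -> TimeCourseMatrix:
    """Read a counts TSV plus its sample-metadata TSV into a matrix.

    The counts file has a header row of sample ids and gene ids in the first
    column. The metadata file has columns sample_id, paradigm, time_min and
    replicate; an optional leading ``# scale=...`` comment records the scale
    (defaulting to ``raw_counts``).
    """
    scale = "raw_counts"
    meta_path = Path(meta_path)
    with open(meta_path) as fh:
        header_comments = []
        for line in fh:
            if line.startswith("#"):
                header_comments.append(line[1:].strip())
            else:
                break
    for comment in header_comments:
        if comment.startswith("scale="):
            scale = comment.split("=", 1)[1].strip()

    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "paradigm", "time_min", "replicate"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata missing columns {sorted(required - set(meta.columns))}")
    meta_by_id = {row.sample_id: row for row in meta.itertuples(index=False)}

    table = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip"
    )
    gene_ids = [str(g) for g in table.index]
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise ValueError(f"duplicate gene_id {g!r} in {path}")
        seen.add(g)

    samples = []
    for col in table.columns:
        if col not in meta_by_id:
            raise ValueError(f"sample column {col!r} has no metadata row")
        row = meta_by_id[col]
        samples.append(
            SampleMeta(
                sample_id=str(col),
                paradigm=str(row.paradigm),
                time_min=int(row.time_min),
                replicate=int(row.replicate),
            )
        )

    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(table.columns):
            for i, g in enumerate(gene_ids):
                try:
                    float(table.iat[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {table.iat[i, j]!r} at gene {g!r}, "
                        f"sample {col!r}"
                    ) from None
        values = table.astype(float).to_numpy()
    return TimeCourseMatrix(gene_ids=gene_ids, samples=samples, values=values, scale=scale)


def write_counts_table(
    matrix: TimeCourseMatrix, path: str | Path, meta_path: str | Path
) -> None:
    """Write counts + metadata TSVs readable by :func:`read_counts_table`.

    Values are written with full ``repr`` precision so the round trip is exact.
    """
    if not matrix.gene_ids:
        raise ValueError("refusing to write a matrix with no genes")
    matrix.validate()
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format=None)

    with open(meta_path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        fh.write("sample_id\tparadigm\ttime_min\treplicate\n")
        for s in matrix.samples:
            fh.write(f"{s.sample_id}\t{s.paradigm}\t{s.time_min}\t{s.replicate}\n")


def read_fasta_regions(path: str | Path, kind: str) -> list[SequenceRegion]:
    """Read a FASTA file of per-gene regions; record ids are gene ids."""
    regions = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {record.id!r} contains invalid characters {sorted(bad)}"
            )
        regions.append(SequenceRegion(gene_id=record.id, kind=kind, sequence=seq))
    return regions


def write_fasta_regions(regions: Iterable[SequenceRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for region in regions:
            fh.write(f">{region.gene_id}\n{region.sequence}\n")


def read_spikein_ids(path: str | Path) -> SpikeInSet:
    """Read a plain-text spike-in id list (one id per line)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return SpikeInSet(spikein_ids=tuple(ids))


# -- transforms ---------------------------------------------------------------


def normalize(
    matrix: TimeCourseMatrix,
    method: str = "cpm",
    spikeins: SpikeInSet | None = None,
) -> TimeCourseMatrix:
    """Column-normalize raw counts.

    ``cpm`` scales each column to sum 1e6; ``median_ratio`` uses the median of
    per-gene ratios to the geometric-mean reference column (genes containing
    any zero are excluded from the reference); ``spikein`` equalizes the
    summed spike-in signal across columns.
    """
    if matrix.scale != "raw_counts":
        raise ValueError(f"normalize expects raw_counts, got scale {matrix.scale!r}")
    values = matrix.values
    colsums = values.sum(axis=0)
    if np.any(colsums == 0):
        bad = [matrix.sample_ids[j] for j in np.nonzero(colsums == 0)[0]]
        raise ValueError(f"all-zero columns: {bad}")

    if method == "cpm":
        factors = colsums / 1e6
    elif method == "median_ratio":
        positive = np.all(values > 0, axis=1)
        if not np.any(positive):
            raise ValueError("median_ratio: no gene is positive in every column")
        ref = np.exp(np.mean(np.log(values[positive]), axis=1))
        factors = np.median(values[positive] / ref[:, None], axis=0)
    elif method == "spikein":
        if spikeins is None:
            raise ValueError("spikein normalization requires a SpikeInSet")
        spikeins.check_against(matrix)
        idx = [matrix.gene_index(g) for g in spikeins.spikein_ids]
        spike_sums = values[idx, :].sum(axis=0)
        if np.any(spike_sums == 0):
            bad = [matrix.sample_ids[j] for j in np.nonzero(spike_sums == 0)[0]]
            raise ValueError(f"no spike-in counts in columns: {bad}")
        factors = spike_sums / spike_sums.mean()
    else:
        raise ValueError(f"unknown normalization method {method!r}")

    out = values / factors[None, :]
    return TimeCourseMatrix(
        gene_ids=list(matrix.gene_ids),
        samples=list(matrix.samples),
        values=out,
        scale="normalized",
    )


def log_transform(matrix: TimeCourseMatrix, pseudocount: float = 1.0) -> TimeCourseMatrix:
    """Natural-log transform: value -> ln(value + pseudocount)."""
    if matrix.scale not in ("raw_counts", "normalized"):
        raise ValueError(f"log_transform expects counts, got scale {matrix.scale!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return TimeCourseMatrix(
        gene_ids=list(matrix.gene_ids),
        samples=list(matrix.samples),
        values=np.log(matrix.values + pseudocount),
        scale="log",
    )


def average_replicates(matrix: TimeCourseMatrix) -> TimeCourseMatrix:
    """Collapse replicates: one column per (paradigm, time_min), mean value.

    Output columns are ordered by paradigm (in :data:`PARADIGMS` order) then
    time, and carry replicate=1.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for j, s in enumerate(matrix.samples):
        groups.setdefault((s.paradigm, s.time_min), []).append(j)
    keys = sorted(groups, key=lambda k: (PARADIGMS.index(k[0]), k[1]))
    cols = []
    samples = []
    for paradigm, t in keys:
        cols.append(matrix.values[:, groups[(paradigm, t)]].mean(axis=1))
        samples.append(
            SampleMeta(
                sample_id=f"{paradigm}_t{t}", paradigm=paradigm, time_min=t, replicate=1
            )
        )
    return TimeCourseMatrix(
        gene_ids=list(matrix.gene_ids),
        samples=samples,
        values=np.column_stack(cols),
        scale=matrix.scale,
    )


def zscore_rows(matrix: TimeCourseMatrix) -> TimeCourseMatrix:
    """Z-score each row: mean 0, sample (n-1 denominator) standard deviation 1."""
    if matrix.values.shape[1] < 2:
        raise ValueError("zscore_rows requires at least 2 columns")
    sd = matrix.values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = [matrix.gene_ids[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance rows cannot be z-scored: {bad}")
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    return TimeCourseMatrix(
        gene_ids=list(matrix.gene_ids),
        samples=list(matrix.samples),
        values=centered / sd[:, None],
        scale="zscore",
    )
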