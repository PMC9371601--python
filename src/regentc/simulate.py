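"""Synthetic experiment generator with planted ground truth.

Emulates the statistical structure of a four-series regeneration time
course: sucrose-shock, posterior-half and anterior-half regeneration plus a
sucrose+cycloheximide series. Dynamic genes belong to one of six modules
(combinations of paradigms in which they respond) and to one of five
temporal archetype clusters; counts are negative-binomial around a
baseline times an exponentiated log-fold-change profile. Spike-ins have
constant means. Non-coding regions are uniform-random sequence with motif
instances planted only for designated target genes, and rejection-sampled
motif-free everywhere else so that planted labels are exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from regentc.core import (
    SampleMeta,
    SequenceRegion,
    SpikeInSet,
    TimeCourseMatrix,
)
from regentc.modules import MODULE_LABELS

DEFAULT_TIME_GRIDS: dict[str, tuple[int, ...]] = {
    "sucrose": (0, 30, 60, 90, 120, 180, 240, 300, 360, 420),
    "sucrose_chx": (0, 30, 60, 90, 120, 180, 240, 300, 360, 420),
    "posterior_half": (0, 60, 90, 120, 180, 360, 420),
    "anterior_half": (0, 60, 90, 120, 180, 360, 420),
}

#: Paradigms (other than the cycloheximide mirror) in which each module's
#: dynamic component is active.
MODULE_PARADIGMS: dict[str, tuple[str, ...]] = {
    "OA_specific": ("sucrose", "posterior_half"),
    "sucrose_specific": ("sucrose",),
    "posterior_specific": ("posterior_half",),
    "anterior_specific": ("anterior_half",),
    "bisection_specific": ("posterior_half", "anterior_half"),
    "general": ("sucrose", "posterior_half", "anterior_half"),
}

#: Gaussian-bump centers (minutes) for archetype clusters 2..5.
CLUSTER_CENTERS = {2: 90.0, 3: 150.0, 4: 240.0, 5: 330.0}
CLUSTER_WIDTH = 60.0

E2F_PATTERN = "TTT[GC][GC]CGC"
PUM_PATTERN = "TGTA[CTAG]ATA"


def _default_genes_per_cell() -> dict[tuple[str, int], int]:
    sizes = {
        "OA_specific": 10,
        "sucrose_specific": 6,
        "posterior_specific": 6,
        "anterior_specific": 6,
        "bisection_specific": 6,
        "general": 6,
    }
    return {(m, c): n for m, n in sizes.items() for c in range(1, 6)}


def _default_chx_attenuation() -> dict[int, float]:
    # Cluster 1 loses its repression, late clusters lose their upregulation;
    # cluster-2 genes are the early (translation-independent enriched) wave.
    return {1: 0.1, 2: 1.0, 3: 0.1, 4: 0.1, 5: 0.1}


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical configs give identical output."""

    seed: int = 0
    time_grids: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TIME_GRIDS)
    )
    replicates: int = 3
    genes_per_cell: dict[tuple[str, int], int] = field(
        default_factory=_default_genes_per_cell
    )
    n_background: int = 800
    baseline_mean: float = 200.0
    amplitude_logfc: float = 2.0
    nb_dispersion: float = 0.1
    n_spikeins: int = 40
    chx_attenuation: dict[int, float] = field(default_factory=_default_chx_attenuation)
    early_fraction_cluster2: float = 0.5
    region_length: int = 500
    #: Cluster whose genes carry a planted upstream E2F site / a planted
    #: 3'UTR Pumilio site (within the OA_specific module).
    e2f_target_cluster: int = 3
    pum_target_cluster: int = 4

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.baseline_mean <= 0 or self.amplitude_logfc <= 0:
            raise ValueError("baseline_mean and amplitude_logfc must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_background < 0 or self.n_spikeins < 0:
            raise ValueError("gene counts must be non-negative")
        if not 0.0 <= self.early_fraction_cluster2 <= 1.0:
            raise ValueError("early_fraction_cluster2 must be in [0, 1]")
        for (module, cluster), n in self.genes_per_cell.items():
            if module not in MODULE_LABELS:
                raise ValueError(f"unknown module label {module!r}")
            if cluster not in range(1, 6):
                raise ValueError(f"cluster index {cluster} out of range 1..5")
            if n < 0:
                raise ValueError("genes_per_cell counts must be non-negative")
        for paradigm, grid in self.time_grids.items():
            if len(grid) < 2:
                raise ValueError(f"time grid for {paradigm!r} too short")
        for cluster, mult in self.chx_attenuation.items():
            if mult < 0:
                raise ValueError(f"negative attenuation for cluster {cluster}")


@dataclass
class GroundTruth:
    """Planted labels: the oracle for every recovery test downstream."""

    module: dict[str, str | None]
    cluster: dict[str, int | None]
    translation_independent: dict[str, bool]
    planted_motifs: dict[str, frozenset[str]]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.module)

    def dynamic_in(self, paradigm: str) -> set[str]:
        """Genes whose dynamic component is active in the given paradigm."""
        out = set()
        for gene, module in self.module.items():
            if module is not None and paradigm in MODULE_PARADIGMS[module]:
                out.add(gene)
        return out

    def module_genes(self, module: str) -> set[str]:
        return {g for g, m in self.module.items() if m == module}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.gene_ids:
            rows.append(
                {
                    "gene_id": gene,
                    "module": self.module[gene] or "none",
                    "cluster": self.cluster[gene] or 0,
                    "translation_independent": self.translation_independent[gene],
                    "motifs": ",".join(sorted(self.planted_motifs[gene])) or "none",
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroundTruth":
        frame = pd.read_csv(path, sep="\t")
        module = {}
        cluster = {}
        indep = {}
        motifs = {}
        for row in frame.itertuples(index=False):
            gene = str(row.gene_id)
            module[gene] = None if row.module == "none" else str(row.module)
            cluster[gene] = None if row.cluster == 0 else int(row.cluster)
            indep[gene] = bool(row.translation_independent)
            motifs[gene] = (
                frozenset() if row.motifs == "none" else frozenset(str(row.motifs).split(","))
            )
        return cls(module, cluster, indep, motifs)


def archetype_profile(cluster: int, times: Iterable[float], amplitude: float = 2.0) -> np.ndarray:
    """Mean log-fold-change of an archetype cluster at the given times.

    Cluster 1 holds ``amplitude`` through 30 min then decays smoothly to
    below 0.05*amplitude by 420 min (a repression-release shape: expression
    starts high and falls). Clusters 2-5 are Gaussian bumps of height
    ``amplitude`` centered at 90/150/240/330 min with width 60 min.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ValueError("empty time list")
    if cluster == 1:
        tau = (420.0 - 30.0) / 3.0  # exp(-3) = 0.0498 < 0.05 at t=420
        out = np.where(times <= 30.0, amplitude, amplitude * np.exp(-(times - 30.0) / tau))
        return out.astype(float)
    if cluster in CLUSTER_CENTERS:
        center = CLUSTER_CENTERS[cluster]
        return amplitude * np.exp(-((times - center) ** 2) / (2.0 * CLUSTER_WIDTH**2))
    raise ValueError(f"cluster must be in 1..5, got {cluster}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mean + dispersion*mean^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[TimeCourseMatrix, SpikeInSet, GroundTruth]:
    """Generate the four-series count matrix, spike-ins, and planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples: list[SampleMeta] = []
    for paradigm in ("sucrose", "posterior_half", "anterior_half", "sucrose_chx"):
        for t in config.time_grids[paradigm]:
            for rep in range(1, config.replicates + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{paradigm}_t{t}_r{rep}",
                        paradigm=paradigm,
                        time_min=t,
                        replicate=rep,
                    )
                )

    # -- assemble gene roster and truth labels --------------------------------
    module: dict[str, str | None] = {}
    cluster: dict[str, int | None] = {}
    indep: dict[str, bool] = {}
    motifs: dict[str, frozenset[str]] = {}
    gene_ids: list[str] = []

    counter = 0
    for mod in MODULE_LABELS:
        for clu in range(1, 6):
            n = config.genes_per_cell.get((mod, clu), 0)
            for _ in range(n):
                counter += 1
                gene = f"g{counter:05d}"
                gene_ids.append(gene)
                module[gene] = mod
                cluster[gene] = clu
                indep[gene] = False
                planted = set()
                if mod == "OA_specific" and clu == config.e2f_target_cluster:
                    planted.add("E2F_upstream")
                if mod == "OA_specific" and clu == config.pum_target_cluster:
                    planted.add("PUM_utr3")
                motifs[gene] = frozenset(planted)
    for _ in range(config.n_background):
        counter += 1
        gene = f"g{counter:05d}"
        gene_ids.append(gene)
        module[gene] = None
        cluster[gene] = None
        indep[gene] = False
        motifs[gene] = frozenset()

    # Flag a deterministic fraction of every cluster-2 cell translation
    # independent (first ceil(f*n) genes of the cell, so identical configs
    # give identical flags).
    for mod in MODULE_LABELS:
        cell = [g for g in gene_ids if module[g] == mod and cluster[g] == 2]
        n_indep = int(round(config.early_fraction_cluster2 * len(cell)))
        for gene in cell[:n_indep]:
            indep[gene] = True

    spike_ids = tuple(f"ERCC_{i:03d}" for i in range(1, config.n_spikeins + 1))
    # geometric concentration ladder, as in a spike-in mix
    nominal = {sid: 2.0 ** (i % 8) for i, sid in enumerate(spike_ids)}

    all_ids = gene_ids + list(spike_ids)

    # -- mean matrix ----------------------------------------------------------
    means = np.empty((len(all_ids), len(samples)), dtype=float)
    times_by_sample = np.array([s.time_min for s in samples], dtype=float)
    paradigm_by_sample = [s.paradigm for s in samples]

    profile_cache: dict[tuple[int, str], np.ndarray] = {}

    def profile_for(clu: int, paradigm: str) -> np.ndarray:
        key = (clu, paradigm)
        if key not in profile_cache:
            grid = np.asarray(config.time_grids[paradigm], dtype=float)
            profile_cache[key] = archetype_profile(clu, grid, config.amplitude_logfc)
        return profile_cache[key]

    col_of_time = {
        paradigm: {t: i for i, t in enumerate(config.time_grids[paradigm])}
        for paradigm in config.time_grids
    }

    for i, gene in enumerate(gene_ids):
        mod = module[gene]
        if mod is None:
            means[i, :] = config.baseline_mean
            continue
        clu = cluster[gene]
        active = MODULE_PARADIGMS[mod]
        row = np.full(len(samples), config.baseline_mean)
        for j, s in enumerate(samples):
            paradigm = paradigm_by_sample[j]
            if paradigm == "sucrose_chx":
                if "sucrose" not in active:
                    continue
                mult = 1.0 if indep[gene] else config.chx_attenuation.get(clu, 1.0)
                prof = profile_for(clu, "sucrose_chx")
            elif paradigm in active:
                mult = 1.0
                prof = profile_for(clu, paradigm)
            else:
                continue
            k = col_of_time[paradigm][s.time_min]
            row[j] = config.baseline_mean * np.exp(mult * prof[k])
        means[i, :] = row

    for i, sid in enumerate(spike_ids):
        means[len(gene_ids) + i, :] = config.baseline_mean * nominal[sid]

    counts = _nb_draw(rng, means, config.nb_dispersion)

    matrix = TimeCourseMatrix(
        gene_ids=all_ids, samples=samples, values=counts.astype(float), scale="raw_counts"
    )
    spikeins = SpikeInSet(spikein_ids=spike_ids, nominal_level=nominal)
    truth = GroundTruth(module, cluster, indep, motifs)
    return matrix, spikeins, truth


# -- sequence simulation ------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _sample_motif_instance(rng: np.random.Generator, pattern: str) -> str:
    from regentc.motifs import compile_motif

    choices = compile_motif(pattern)
    return "".join(sorted(pos)[rng.integers(0, len(pos))] for pos in choices)


def _count_hits(sequence: str, pattern: str) -> int:
    from regentc.motifs import MotifPattern, scan_sequence

    region = SequenceRegion(gene_id="_tmp", kind="upstream", sequence=sequence)
    motif = MotifPattern(name="_tmp", pattern=pattern, region_kind="upstream")
    return len(scan_sequence(motif, region))


def simulate_regions(truth: GroundTruth, config: SimulationConfig) -> list[SequenceRegion]:
    """Generate one upstream and one 3'UTR region per gene.

    Planted genes get exactly the designated motif in the designated region
    kind; every other (region, motif-bound-to-that-kind) combination is
    rejection-sampled to contain no occurrence of either motif, so that a
    brute-force scan reproduces the planted labels exactly.
    """
    min_len = 8  # both default motifs expand to 8 nt
    if config.region_length < min_len:
        raise ValueError(
            f"region_length {config.region_length} shorter than motif length {min_len}"
        )
    rng = np.random.default_rng(config.seed + 1)
    regions: list[SequenceRegion] = []

    def motif_free_seq() -> str:
        while True:
            seq = _random_seq(rng, config.region_length)
            if _count_hits(seq, E2F_PATTERN) == 0 and _count_hits(seq, PUM_PATTERN) == 0:
                return seq

    def planted_seq(pattern: str, other: str) -> str:
        while True:
            seq = motif_free_seq()
            instance = _sample_motif_instance(rng, pattern)
            offset = int(rng.integers(0, config.region_length - len(instance) + 1))
            seq = seq[:offset] + instance + seq[offset + len(instance):]
            # planting may create a spurious occurrence of the other motif
            if _count_hits(seq, other) == 0:
                return seq

    for gene in truth.gene_ids:
        planted = truth.planted_motifs[gene]
        if "E2F_upstream" in planted:
            upstream = planted_seq(E2F_PATTERN, PUM_PATTERN)
        else:
            upstream = motif_free_seq()
        if "PUM_utr3" in planted:
            utr3 = planted_seq(PUM_PATTERN, E2F_PATTERN)
        else:
            utr3 = motif_free_seq()
        regions.append(SequenceRegion(gene_id=gene, kind="upstream", sequence=upstream))
        regions.append(SequenceRegion(gene_id=gene, kind="utr3", sequence=utr3))
    return regions


def simulate_score_table(
    n_pairs: int, n_decoys: int, seed: int = 0
) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Pairwise similarity scores with planted reciprocal-best-hit pairs.

    True pairs (a_i, b_i) score strictly above everything else and are each
    other's unique maxima. Decoys score against true partners above the
    decoy-decoy band, so no decoy can be a mutual best hit; recovery of the
    truth by RBH is therefore exact by construction.
    """
    if n_pairs < 0 or n_decoys < 0:
        raise ValueError("n_pairs and n_decoys must be non-negative")
    rng = np.random.default_rng(seed)
    a_true = [f"a{i:03d}" for i in range(n_pairs)]
    b_true = [f"b{i:03d}" for i in range(n_pairs)]
    a_decoy = [f"adk{i:03d}" for i in range(n_decoys)]
    b_decoy = [f"bdk{i:03d}" for i in range(n_decoys)]

    rows = []
    for i, a in enumerate(a_true):
        for j, b in enumerate(b_true):
            score = 100.0 + i if i == j else float(rng.uniform(10, 20))
            rows.append((a, b, score))
        for b in b_decoy:
            rows.append((a, b, float(rng.uniform(10, 20))))
    for a in a_decoy:
        for b in b_true:
            rows.append((a, b, float(rng.uniform(30, 40))))
        for b in b_decoy:
            rows.append((a, b, float(rng.uniform(1, 10))))

    table = pd.DataFrame(rows, columns=["idA", "idB", "score"])
    truth = {(a_true[i], b_true[i]) for i in range(n_pairs)}
    return table, truth
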