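"""Planted-truth synthetic data: genomes with known SSRs and coverages,
and diploid genotype tables drawn under Hardy–Weinberg equilibrium.

The genome generator emulates the input of a genome-survey marker
pipeline: assembled contigs of a few hundred bp to a few kb carrying
perfect di/tri/tetra-nucleotide repeats at recorded coordinates, with
per-contig mean read depths.  Background sequence is i.i.d. uniform over
{A,C,G,T} and is scrubbed of *unplanned* repeats that would qualify under
the detection thresholds, so detector precision and recall can be scored
exactly against the planted truth.  Planted repeats are guaranteed
maximal (the flanking bases break the period) and consist of complete
motif copies.

The genotype generator emulates the validation study design — by default
11 diploid individuals — drawing two independent allele copies per
individual per marker from configured allele frequencies on a repeat-unit
lattice (allele j of marker m has size ``base + period·j``), applying
per-call missingness, and optionally adding Gaussian size noise to
produce a raw-sizes table for the binning step.

All generators are deterministic under a fixed seed; one global seed fans
out to per-component streams via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import (
    DEFAULT_MIN_REPEATS,
    SSRLocus,
    canonical_motif,
    find_perfect_ssrs,
)
from .io import Contig, GenotypeTable

__all__ = [
    "GenomeSimConfig",
    "PlantSpec",
    "GenotypeSimConfig",
    "MarkerSimSpec",
    "simulate_genome",
    "simulate_genotypes",
    "validation_study_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Motif-class mix skewed toward the classes that dominate grass genomes
#: (AG among di-, CCG among tri-, AAAT among tetra-nucleotides).
DEFAULT_MOTIF_WEIGHTS: Mapping[str, float] = {
    "AG": 0.25, "AC": 0.08, "AT": 0.05, "CG": 0.01,
    "CCG": 0.20, "AAG": 0.08, "AGG": 0.05, "ACC": 0.04, "AAC": 0.03, "ACT": 0.02,
    "AAAT": 0.10, "AAAG": 0.05, "AGAT": 0.03, "ACAT": 0.01,
}

#: Mean complete-copy counts per period: about six copies for
#: di-nucleotide runs and about three for tri-/tetra-nucleotide runs.
DEFAULT_MEAN_REPEATS: Mapping[int, float] = {2: 6.0, 3: 3.3, 4: 3.3}


@dataclass
class PlantSpec:
    """One repeat to plant: motif (as spelled) and complete-copy count."""

    motif: str
    repeat_count: int

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.period * self.repeat_count


@dataclass
class GenomeSimConfig:
    """Parameters of the synthetic contig set.

    ``loci_per_contig`` is the Poisson mean of planted repeats per contig.
    Coverage is lognormal (median ≈ e^``coverage_log_mean``); the default
    spread puts contigs on both sides of the 10× and 100× selection tiers.
    """

    n_contigs: int = 20
    min_length: int = 500
    max_length: int = 2000
    motif_class_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_WEIGHTS)
    )
    mean_repeats: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_REPEATS)
    )
    min_repeats: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    loci_per_contig: float = 2.0
    coverage_log_mean: float = 3.4  # ln-scale; median ≈ 30×
    coverage_log_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.max_length < self.min_length:
            raise ValueError("contig length bounds invalid")
        weights = list(self.motif_class_weights.values())
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("motif weights must be non-negative and not all zero")


def _random_background(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _scrub_background(
    rng: np.random.Generator, seq: np.ndarray, min_repeats: Mapping[int, int]
) -> np.ndarray:
    """Mutate bases until no qualifying repeat survives in the background."""
    for _ in range(100):
        contig = Contig(id="_bg", sequence=seq.tobytes().decode("ascii"))
        found = find_perfect_ssrs(contig, min_repeats)
        if not found:
            return seq
        for loc in found:
            mid = (loc.start + loc.end) // 2
            old = seq[mid]
            choices = _BASES[_BASES != old]
            seq[mid] = rng.choice(choices)
    raise RuntimeError("failed to scrub background sequence of chance repeats")


def _sample_motif_variant(rng: np.random.Generator, motif_class: str) -> str:
    """A random class member (rotation and/or reverse complement)."""
    comp = str.maketrans("ACGT", "TGCA")
    rc = motif_class.translate(comp)[::-1]
    base = motif_class if rng.random() < 0.5 else rc
    shift = int(rng.integers(0, len(base)))
    return base[shift:] + base[:shift]


def _plant_into(
    rng: np.random.Generator,
    seq: np.ndarray,
    start: int,
    plant: PlantSpec,
) -> None:
    """Write a repeat at ``start`` and break the period at both flanks."""
    motif_bytes = np.frombuffer(plant.motif.encode("ascii"), dtype=np.uint8)
    run = np.tile(motif_bytes, plant.repeat_count)
    end = start + plant.length
    seq[start:end] = run
    if start > 0:  # left extension continues the run iff seq[start-1] == motif[-1]
        banned = motif_bytes[-1]
        choices = _BASES[_BASES != banned]
        seq[start - 1] = rng.choice(choices)
    if end < len(seq):  # right extension continues iff seq[end] == motif[0]
        banned = motif_bytes[0]
        choices = _BASES[_BASES != banned]
        seq[end] = rng.choice(choices)


def simulate_contig(
    rng: np.random.Generator,
    contig_id: str,
    length: int,
    plants: Sequence[PlantSpec],
    min_repeats: Mapping[int, int] = DEFAULT_MIN_REPEATS,
    max_tries: int = 50,
) -> tuple[Contig, list[SSRLocus]]:
    """One contig with the given repeats planted at random positions.

    Planted repeats are placed non-overlapping with at least 10 bp of
    clearance between them and 1 bp from the contig ends; after planting,
    the contig is re-scanned and regenerated until the detected loci equal
    the planted truth exactly.

    Raises
    ------
    ValueError
        If the contig is too short to hold the requested repeats.
    """
    margin = 10
    needed = sum(p.length + margin for p in plants) + margin
    if needed > length:
        raise ValueError(
            f"contig {contig_id!r} of {length} bp too short for {len(plants)} plant(s) "
            f"needing ~{needed} bp"
        )
    for _ in range(max_tries):
        seq = _scrub_background(rng, _random_background(rng, length), min_repeats)
        truth: list[SSRLocus] = []
        cursor = 1
        free = length - 1 - needed
        starts = []
        for plant in plants:
            gap = int(rng.integers(0, max(free, 1)))
            free -= gap
            start = cursor + margin + gap
            starts.append(start)
            cursor = start + plant.length
        for plant, start in zip(plants, starts):
            _plant_into(rng, seq, start, plant)
            truth.append(
                SSRLocus(
                    contig_id=contig_id,
                    start=start,
                    end=start + plant.length,
                    period=plant.period,
                    motif_observed=plant.motif,
                    motif_class=canonical_motif(plant.motif),
                    repeat_count=plant.repeat_count,
                )
            )
        contig = Contig(id=contig_id, sequence=seq.tobytes().decode("ascii"))
        detected = find_perfect_ssrs(contig, min_repeats)
        truth.sort(key=lambda loc: (loc.start, loc.period))
        if detected == truth:
            return contig, truth
    raise RuntimeError(f"could not realize clean plants in contig {contig_id!r}")


def simulate_genome(config: GenomeSimConfig) -> tuple[list[Contig], list[SSRLocus]]:
    """Contig set with planted-truth loci and simulated coverages.

    Returns ``(contigs, truth)``: every truth locus qualifies under the
    configured thresholds and the background carries no other qualifying
    repeat, so a perfect detector achieves 100% recall and precision.
    Byte-identical output under the same config (including seed).
    """
    root = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(config.n_contigs + 1)]
    cov_rng = streams[-1]
    classes = sorted(config.motif_class_weights)
    weights = np.array([config.motif_class_weights[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    contigs: list[Contig] = []
    truth: list[SSRLocus] = []
    for i in range(config.n_contigs):
        rng = streams[i]
        length = int(rng.integers(config.min_length, config.max_length + 1))
        n_plants = int(rng.poisson(config.loci_per_contig))
        plants = []
        for _ in range(n_plants):
            cls = classes[int(rng.choice(len(classes), p=weights))]
            variant = _sample_motif_variant(rng, cls)
            p = len(variant)
            floor = config.min_repeats[p]
            extra_mean = max(config.mean_repeats[p] - floor, 0.05)
            count = floor + int(rng.poisson(extra_mean))
            plants.append(PlantSpec(motif=variant, repeat_count=count))
        contig, contig_truth = simulate_contig(
            rng, f"contig{i + 1:04d}", length, plants, config.min_repeats
        )
        contig.coverage = float(
            np.round(cov_rng.lognormal(config.coverage_log_mean, config.coverage_log_sigma), 1)
        )
        contigs.append(contig)
        truth.extend(contig_truth)
    return contigs, truth


# ---------------------------------------------------------------------------
# diploid genotypes under Hardy–Weinberg


@dataclass
class MarkerSimSpec:
    """Per-marker truth: allele sizes ``base_size + period·j`` with
    frequencies ``freqs[j]`` (must sum to 1)."""

    name: str
    period: int
    base_size: int
    freqs: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.freqs) < 1:
            raise ValueError(f"{self.name}: need at least one allele")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: frequencies sum to {sum(self.freqs)}")
        if self.period not in (2, 3, 4):
            raise ValueError(f"{self.name}: period must be 2, 3 or 4")

    @property
    def allele_sizes(self) -> list[int]:
        return [self.base_size + self.period * j for j in range(len(self.freqs))]


@dataclass
class GenotypeSimConfig:
    """Study design for the genotype simulator (default: 11 individuals,
    the size of a small validation panel of germplasm accessions)."""

    markers: Sequence[MarkerSimSpec]
    n_individuals: int = 11
    missing_rate: float = 0.0
    size_noise_sd: float = 0.0  # bp, Gaussian, applied to the raw-sizes table
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.size_noise_sd < 0:
            raise ValueError("size_noise_sd must be >= 0")


def simulate_genotypes(
    config: GenotypeSimConfig,
) -> tuple[GenotypeTable, pd.DataFrame, dict[str, dict[int, float]]]:
    """Diploid genotypes under Hardy–Weinberg from known frequencies.

    Each individual draws two independent allele copies per marker;
    missingness hits whole calls at ``missing_rate``.  Returns
    ``(clean_table, raw_sizes, truth)`` where ``raw_sizes`` is a
    sample/marker/size1/size2 frame with Gaussian noise of
    ``size_noise_sd`` bp added (equal to the clean sizes when the sd is 0)
    and ``truth`` maps marker → {allele size → frequency}.
    """
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    individuals = [f"ind{i + 1:03d}" for i in range(config.n_individuals)]
    markers = [m.name for m in config.markers]
    calls: dict[tuple[str, str], tuple[float, float] | None] = {}
    raw_rows = []
    truth: dict[str, dict[int, float]] = {}
    for spec in config.markers:
        sizes = spec.allele_sizes
        truth[spec.name] = dict(zip(sizes, [float(p) for p in spec.freqs]))
        probs = np.asarray(spec.freqs, dtype=float)
        draws = rng.choice(len(sizes), size=(config.n_individuals, 2), p=probs)
        missing = rng.random(config.n_individuals) < config.missing_rate
        noise = rng.normal(0.0, config.size_noise_sd, size=(config.n_individuals, 2))
        for i, ind in enumerate(individuals):
            if missing[i]:
                calls[(ind, spec.name)] = None
                raw_rows.append({"sample": ind, "marker": spec.name,
                                 "size1": np.nan, "size2": np.nan})
                continue
            a, b = sizes[draws[i, 0]], sizes[draws[i, 1]]
            calls[(ind, spec.name)] = (float(min(a, b)), float(max(a, b)))
            ra, rb = sorted((a + noise[i, 0], b + noise[i, 1]))
            raw_rows.append({"sample": ind, "marker": spec.name,
                             "size1": round(ra, 3), "size2": round(rb, 3)})
    table = GenotypeTable(individuals, markers, calls)
    raw = pd.DataFrame(raw_rows, columns=["sample", "marker", "size1", "size2"])
    return table, raw, truth


def validation_study_config(
    n_markers: int = 10, n_individuals: int = 11, seed: int = 0,
    missing_rate: float = 0.05, size_noise_sd: float = 0.15,
) -> GenotypeSimConfig:
    """A validation-study-like preset: mostly di-nucleotide markers with
    2–8 alleles per marker drawn from a symmetric Dirichlet spectrum."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    periods = [2] * max(1, round(n_markers * 0.8)) + [3, 4]
    specs = []
    for i in range(n_markers):
        period = periods[i % len(periods)]
        k = int(rng.integers(2, 9))
        freqs = rng.dirichlet(np.full(k, 2.0))
        base = int(rng.integers(100, 320))
        specs.append(
            MarkerSimSpec(
                name=f"Sim{i + 1:04d}", period=period, base_size=base,
                freqs=(freqs / freqs.sum()).tolist(),
            )
        )
    return GenotypeSimConfig(
        markers=specs, n_individuals=n_individuals,
        missing_rate=missing_rate, size_noise_sd=size_noise_sd, seed=seed,
    )
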