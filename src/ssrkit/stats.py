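"""Marker descriptive statistics: allele frequencies, He, Ho, PIC,
allele-frequency classes, size concordance, transferability and the
attrition arithmetic of marker-development pipelines.

Formulas
--------
For a marker with allele frequencies ``p_i`` estimated by direct counting
(two allele copies per genotyped diploid individual, missing calls
excluded from the denominator):

* expected heterozygosity (Nei's gene diversity)
  ``He = 1 − Σ p_i²``
* observed heterozygosity
  ``Ho = (# individuals with two distinct alleles) / (# genotyped)``
* polymorphism information content (Botstein)
  ``PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²``

These are the plain (sample-size–uncorrected) estimators; under them
``0 ≤ PIC ≤ He < 1`` always holds, with equality at 0 exactly for a
monomorphic marker.

Alleles are classified by frequency as rare (p < 0.05), intermediate
(0.05 ≤ p ≤ 0.30) or abundant (p > 0.30); the boundaries are assigned to
the intermediate class so the three classes partition the alleles.

Attrition arithmetic chains per-step loss rates multiplicatively, rounding
half-up at each step, forward (how many loci survive) or backward (how
many inputs are needed to end with a target count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .io import AmplificationTable, GenotypeTable
from .panels import MarkerDef

__all__ = [
    "AlleleFrequencies",
    "MarkerStatsRow",
    "AttritionModel",
    "NoDataError",
    "allele_frequencies",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "pic",
    "classify_allele_frequencies",
    "AlleleClassCounts",
    "marker_summary",
    "aggregate_stats",
    "size_concordance",
    "transferability",
    "attrition_forward",
    "attrition_required",
    "round_half_up",
    "truncate",
]


class NoDataError(ValueError):
    """Raised when a marker has no non-missing calls ("no_data")."""


@dataclass(frozen=True)
class AlleleFrequencies:
    """Allele-frequency spectrum of one marker.

    ``freqs`` maps allele size (bp) to its relative frequency p_i over the
    2·``n_genotyped`` allele copies observed; frequencies are positive and
    sum to 1.
    """

    marker: str
    freqs: Mapping[float, float]
    n_genotyped: int

    def __post_init__(self) -> None:
        if self.n_genotyped < 1:
            raise ValueError(f"{self.marker}: n_genotyped < 1")
        if any(p <= 0 for p in self.freqs.values()):
            raise ValueError(f"{self.marker}: non-positive frequency")
        if abs(sum(self.freqs.values()) - 1.0) > 1e-9:
            raise ValueError(f"{self.marker}: frequencies sum to {sum(self.freqs.values())}")


@dataclass
class MarkerStatsRow:
    """One line of the per-marker descriptive-statistics table."""

    marker: str
    allele_count: int
    size_range: tuple[float, float] | None
    he: float
    ho: float
    pic: float
    polymorphic: bool
    no_data: bool = False


@dataclass(frozen=True)
class AttritionModel:
    """Ordered development steps with the fraction of loci lost at each."""

    step_names: tuple[str, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.step_names) != len(self.rates):
            raise ValueError("step_names and rates must have equal length")
        if any(not 0 <= r < 1 for r in self.rates):
            raise ValueError("each attrition rate must be in [0, 1)")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the display convention for percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    out = Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)
    return float(out)


def truncate(value: float, ndigits: int) -> float:
    """Truncation toward zero at ``ndigits`` decimals (3-decimal displays)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_DOWN))


def _round_half_up_int(value: float) -> int:
    return int(math.floor(value + 0.5))


# ---------------------------------------------------------------------------
# frequencies and diversity statistics


def allele_frequencies(geno: GenotypeTable, marker: str) -> AlleleFrequencies:
    """Direct-count allele frequencies over non-missing calls.

    Each genotyped individual contributes two allele copies (homozygotes
    contribute the same size twice); missing calls are excluded from the
    denominator entirely.
    """
    calls = geno.calls_for_marker(marker)
    if not calls:
        raise NoDataError(f"marker {marker!r}: no_data (all calls missing)")
    counts: dict[float, int] = {}
    for a, b in calls:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * len(calls)
    freqs = {size: c / total for size, c in sorted(counts.items())}
    return AlleleFrequencies(marker=marker, freqs=freqs, n_genotyped=len(calls))


def expected_heterozygosity(f: AlleleFrequencies) -> float:
    """Nei gene diversity He = 1 − Σ p_i² (0 for a monomorphic marker)."""
    return 1.0 - sum(p * p for p in f.freqs.values())


def observed_heterozygosity(geno: GenotypeTable, marker: str) -> float:
    """Fraction of genotyped individuals whose two alleles differ."""
    calls = geno.calls_for_marker(marker)
    if not calls:
        raise NoDataError(f"marker {marker!r}: no_data (all calls missing)")
    return sum(1 for a, b in calls if a != b) / len(calls)


def pic(f: AlleleFrequencies) -> float:
    """Botstein polymorphism information content.

    PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²; always ≤ He, 0 iff monomorphic.
    """
    ps = list(f.freqs.values())
    sum_sq = sum(p * p for p in ps)
    cross = 0.0
    for i in range(len(ps)):
        for j in range(i + 1, len(ps)):
            cross += 2.0 * ps[i] ** 2 * ps[j] ** 2
    return 1.0 - sum_sq - cross


# ---------------------------------------------------------------------------
# allele-frequency classes


@dataclass
class AlleleClassCounts:
    """Pooled rare/intermediate/abundant allele counts and fractions."""

    counts: dict[str, int]
    fractions: dict[str, float]
    total: int


def classify_allele_frequencies(
    freq_db: Iterable[AlleleFrequencies],
    rare_below: float = 0.05,
    abundant_above: float = 0.30,
) -> AlleleClassCounts:
    """Pool alleles across markers into frequency classes.

    rare: p < ``rare_below``; abundant: p > ``abundant_above``; the closed
    interval in between (boundaries included) is intermediate, making the
    classes a total partition.  Fractions are over the pooled allele count.
    """
    counts = {"rare": 0, "intermediate": 0, "abundant": 0}
    for f in freq_db:
        for p in f.freqs.values():
            if p < rare_below:
                counts["rare"] += 1
            elif p > abundant_above:
                counts["abundant"] += 1
            else:
                counts["intermediate"] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no alleles to classify")
    fractions = {k: v / total for k, v in counts.items()}
    return AlleleClassCounts(counts=counts, fractions=fractions, total=total)


# ---------------------------------------------------------------------------
# per-marker summary table


def marker_summary(
    geno: GenotypeTable, markers: Sequence[MarkerDef] | Sequence[str] | None = None
) -> list[MarkerStatsRow]:
    """One statistics row per marker: allele count, size range, He, Ho, PIC.

    A marker whose calls are all missing yields a flagged ``no_data`` row
    (statistics zero, excluded from aggregates) rather than aborting the
    table.  ``polymorphic`` means at least two distinct alleles observed.
    """
    if markers is None:
        names = list(geno.markers)
    else:
        names = [m.name if isinstance(m, MarkerDef) else m for m in markers]
    rows: list[MarkerStatsRow] = []
    for name in names:
        try:
            f = allele_frequencies(geno, name)
        except NoDataError:
            rows.append(
                MarkerStatsRow(
                    marker=name, allele_count=0, size_range=None,
                    he=0.0, ho=0.0, pic=0.0, polymorphic=False, no_data=True,
                )
            )
            continue
        sizes = sorted(f.freqs)
        rows.append(
            MarkerStatsRow(
                marker=name,
                allele_count=len(sizes),
                size_range=(sizes[0], sizes[-1]),
                he=expected_heterozygosity(f),
                ho=observed_heterozygosity(geno, name),
                pic=pic(f),
                polymorphic=len(sizes) >= 2,
            )
        )
    return rows


def aggregate_stats(rows: Sequence[MarkerStatsRow]) -> dict[str, float]:
    """Aggregate report over markers with data.

    Keys: ``n_markers``, ``n_polymorphic``, ``total_alleles``,
    ``mean_alleles_per_polymorphic``, ``mean_he``, ``mean_ho``,
    ``mean_pic``, ``min_pic``, ``max_pic``.
    """
    usable = [r for r in rows if not r.no_data]
    if not usable:
        raise ValueError("no markers with data")
    poly = [r for r in usable if r.polymorphic]
    out: dict[str, float] = {
        "n_markers": len(usable),
        "n_polymorphic": len(poly),
        "total_alleles": sum(r.allele_count for r in usable),
        "mean_he": sum(r.he for r in usable) / len(usable),
        "mean_ho": sum(r.ho for r in usable) / len(usable),
        "mean_pic": sum(r.pic for r in usable) / len(usable),
        "min_pic": min(r.pic for r in usable),
        "max_pic": max(r.pic for r in usable),
    }
    if poly:
        out["mean_alleles_per_polymorphic"] = sum(r.allele_count for r in poly) / len(poly)
    return out


# ---------------------------------------------------------------------------
# size concordance and transferability


@dataclass(frozen=True)
class SizeConcordance:
    contains: bool
    within_tolerance: bool


def size_concordance(
    expected: int, observed_range: tuple[float, float], tolerance_fraction: float = 0.10
) -> SizeConcordance:
    """Compare an observed allele-size range with the designed product size.

    ``contains``: expected size falls inside the observed range.
    ``within_tolerance``: both range endpoints lie inside
    ``[expected·(1−t), expected·(1+t)]``.
    """
    if not 0 < tolerance_fraction < 1:
        raise ValueError("tolerance_fraction must be in (0, 1)")
    lo, hi = observed_range
    if lo > hi:
        raise ValueError(f"invalid range {observed_range}")
    contains = lo <= expected <= hi
    within = expected * (1 - tolerance_fraction) <= lo and hi <= expected * (1 + tolerance_fraction)
    return SizeConcordance(contains=contains, within_tolerance=within)


def transferability(amp: AmplificationTable) -> dict[str, float]:
    """Per-species percentage of markers that amplified.

    100 × successes / total markers, reported to one decimal with
    round-half-up; invariant under permutation of marker order.
    """
    n = len(amp.markers)
    if n == 0:
        raise ValueError("no markers in amplification table")
    out = {}
    for sp in amp.species:
        hits = sum(1 for m in amp.markers if amp.amplified[(m, sp)])
        out[sp] = round_half_up(100.0 * hits / n, 1)
    return out


# ---------------------------------------------------------------------------
# attrition arithmetic


def attrition_forward(start: int, model: AttritionModel) -> list[int]:
    """Expected surviving counts after each step.

    ``count_k = round_half_up(count_{k−1} · (1 − rate_k))``; the returned
    chain includes the starting count, so its length is ``len(rates) + 1``.
    """
    if start < 0:
        raise ValueError("start must be >= 0")
    chain = [start]
    for rate in model.rates:
        chain.append(_round_half_up_int(chain[-1] * (1.0 - rate)))
    return chain


def attrition_required(target: int, model: AttritionModel) -> list[int]:
    """Inputs needed at each step to end with ``target`` survivors.

    Applied from the last step backward:
    ``input_k = round_half_up(output_k / (1 − rate_k))``.  The returned
    chain runs forward (first-step input … target), matching the shape of
    :func:`attrition_forward`; the two are inverse up to ±1 per step.
    """
    if target < 0:
        raise ValueError("target must be >= 0")
    chain = [target]
    for rate in reversed(model.rates):
        chain.append(_round_half_up_int(chain[-1] / (1.0 - rate)))
    chain.reverse()
    return chain


# ---------------------------------------------------------------------------
# table output


def write_marker_stats(rows: Sequence[MarkerStatsRow], path) -> None:
    """Statistics CSV: marker, allele count, size range, He, Ho, PIC, flags."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["marker", "allele_no", "size_min", "size_max", "he", "ho", "pic",
             "polymorphic", "no_data"]
        )
        for r in rows:
            lo, hi = r.size_range if r.size_range else ("", "")
            writer.writerow(
                [r.marker, r.allele_count, lo, hi,
                 f"{r.he:.3f}", f"{r.ho:.3f}", f"{r.pic:.3f}",
                 int(r.polymorphic), int(r.no_data)]
            )


def write_frequency_db(freq_db: Sequence[AlleleFrequencies], path) -> None:
    """Frequency-database CSV: marker, allele size, frequency, n genotyped."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["marker", "allele_size", "frequency", "n_genotyped"])
        for f in freq_db:
            for size, p in f.freqs.items():
                writer.writerow([f.marker, f"{size:g}", f"{p:.6f}", f.n_genotyped])
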