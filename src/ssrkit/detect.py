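"""Perfect microsatellite (SSR) detection and cataloguing.

Finds every maximal perfect di-, tri- and tetra-nucleotide repeat in
assembled contigs and classifies each by its canonical motif, the
representative obtained by taking the lexicographically smallest string
(A < C < G < T) over all rotations of the motif and of its reverse
complement.  GA, CT and TC therefore all belong to class AG; the three
most frequent classes in a grass genome survey of this kind are typically
AG, CCG and AAAT.

A repeat is *perfect* when no mismatch, indel or N interrupts the tandem
copies; any such interruption terminates the run (runs are split at N,
never silently bridged).  A run expressible at several periods is reported
once, at the smallest period, which is enforced by requiring the motif to
be primitive (AT yes, ATAT no).  Reported spans are maximal — extending
them by one base on either side breaks perfection — and include a trailing
partial motif copy when present, while ``repeat_count`` counts complete
copies only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .io import Contig

__all__ = [
    "SSRLocus",
    "CatalogSummary",
    "DEFAULT_MIN_REPEATS",
    "canonical_motif",
    "is_primitive",
    "find_perfect_ssrs",
    "summarize_catalog",
]

#: Minimum number of complete motif copies for a run to be reported,
#: per motif period.  Configurable; these defaults keep di-nucleotide
#: runs of at least five copies and tri/tetra runs of at least three.
DEFAULT_MIN_REPEATS: Mapping[int, int] = {2: 5, 3: 3, 4: 3}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_PERIODS = (2, 3, 4)


class MotifError(ValueError):
    """Raised for motifs outside the supported alphabet or non-primitive motifs."""


@dataclass(frozen=True)
class SSRLocus:
    """A perfect tandem repeat occurrence on a contig.

    Coordinates are 0-based half-open in contig space.  ``motif_observed``
    is the motif as spelled at the start of the span; ``motif_class`` is its
    canonical label; ``repeat_count`` counts complete copies (the span may
    additionally cover a trailing partial copy).
    """

    contig_id: str
    start: int
    end: int
    period: int
    motif_observed: str
    motif_class: str
    repeat_count: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CatalogSummary:
    """Aggregate counts over a locus catalog (per period and per canonical class)."""

    counts_by_period: dict[int, int] = field(default_factory=dict)
    counts_by_class: dict[str, int] = field(default_factory=dict)
    mean_repeats_by_period: dict[int, float] = field(default_factory=dict)
    total: int = 0


def is_primitive(motif: str) -> bool:
    """True when no proper divisor period generates the motif (ATAT → False)."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical class label for a primitive 2–4 bp motif.

    The label is the lexicographic minimum (A < C < G < T) over all
    rotations of the motif and all rotations of its reverse complement,
    so the classification is invariant under phase shift and strand flip.
    Idempotent: ``canonical_motif(canonical_motif(m)) == canonical_motif(m)``.

    Raises
    ------
    MotifError
        If the motif contains characters outside {A,C,G,T}, has length
        outside 2–4, or is non-primitive (e.g. "AA", "ATAT").
    """
    if not 2 <= len(motif) <= 4:
        raise MotifError(f"motif length must be 2-4, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise MotifError(f"motif {motif!r} contains characters outside ACGT")
    if not is_primitive(motif):
        raise MotifError(f"motif {motif!r} is not primitive")
    rc = motif.translate(_COMPLEMENT)[::-1]
    candidates = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(candidates)


def find_perfect_ssrs(
    contig: "Contig",
    min_repeats: Mapping[int, int] | None = None,
) -> list[SSRLocus]:
    """All maximal perfect di/tri/tetra-nucleotide repeats in one contig.

    Parameters
    ----------
    contig:
        Sequence record; the sequence must be uppercase over {A,C,G,T,N}.
    min_repeats:
        Minimum complete-copy count per period ``{2: ..., 3: ..., 4: ...}``;
        defaults to :data:`DEFAULT_MIN_REPEATS`.

    Returns
    -------
    list of SSRLocus sorted by span start (then period).  Runs containing
    N are split at the N.  A run reportable at several periods appears once
    at the smallest qualifying period (motif primitivity enforces this).
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    for p in _VALID_PERIODS:
        if p not in min_repeats:
            raise ValueError(f"min_repeats must define period {p}")
    seq = contig.sequence
    n = len(seq)
    loci: list[SSRLocus] = []
    if n == 0:
        return loci
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    not_n = arr != ord("N")
    for p in _VALID_PERIODS:
        if n < p + 1:
            continue
        eq = (arr[p:] == arr[:-p]) & not_n[p:] & not_n[:-p]
        padded = np.concatenate(([0], eq.astype(np.int8), [0]))
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)  # exclusive, in eq coordinates
        for a, b in zip(run_starts, run_ends):
            run_len = int(b - a) + p  # bases covered by the perfect run
            count = run_len // p
            if count < min_repeats[p]:
                continue
            motif = seq[a : a + p]
            if not is_primitive(motif):
                continue  # reported at a smaller period instead
            if "N" in seq[a : a + run_len]:  # unreachable at sane minima; guard
                continue
            loci.append(
                SSRLocus(
                    contig_id=contig.id,
                    start=int(a),
                    end=int(a) + run_len,
                    period=p,
                    motif_observed=motif,
                    motif_class=canonical_motif(motif),
                    repeat_count=count,
                )
            )
    loci.sort(key=lambda loc: (loc.start, loc.period))
    return loci


def find_perfect_ssrs_in_contigs(
    contigs: Iterable["Contig"],
    min_repeats: Mapping[int, int] | None = None,
) -> list[SSRLocus]:
    """Concatenated per-contig detection, preserving contig order."""
    out: list[SSRLocus] = []
    for contig in contigs:
        out.extend(find_perfect_ssrs(contig, min_repeats))
    return out


def summarize_catalog(loci: Iterable[SSRLocus]) -> CatalogSummary:
    """Partition a locus catalog by period and canonical class.

    ``mean_repeats_by_period`` averages complete-copy counts; periods with
    no loci are absent from the mapping rather than carrying NaN.
    """
    summary = CatalogSummary()
    repeat_sums: dict[int, int] = {}
    for loc in loci:
        summary.counts_by_period[loc.period] = summary.counts_by_period.get(loc.period, 0) + 1
        summary.counts_by_class[loc.motif_class] = (
            summary.counts_by_class.get(loc.motif_class, 0) + 1
        )
        repeat_sums[loc.period] = repeat_sums.get(loc.period, 0) + loc.repeat_count
        summary.total += 1
    summary.mean_repeats_by_period = {
        p: repeat_sums[p] / summary.counts_by_period[p] for p in repeat_sums
    }
    return summary
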