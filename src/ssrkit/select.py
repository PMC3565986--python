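"""Coverage-tiered contig/locus selection and primer-candidate preparation.

The survey design selects loci in two tiers: a broad catalog on contigs
longer than 200 bp with at least 10× mean read depth (tier 1), and a
validation set on contigs that additionally reach 100× (tier 2).  Length
is compared strictly (>), coverage inclusively (≥).  Retained loci are
turned into primer-design candidates by extracting flanking sequence, and
candidates are exported as Boulder-IO records, the key=value input format
of the Primer3 family of design tools (design itself is delegated to
those tools).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .detect import SSRLocus
from .io import Contig

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "PrimerCandidate",
    "CandidateRejected",
    "filter_contigs",
    "select_loci",
    "extract_candidate",
    "extract_candidates",
    "export_primer3_records",
    "estimate_tm",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for the two selection tiers.

    Defaults are the survey's: contigs > 200 bp, tier-1 depth ≥ 10×,
    tier-2 depth ≥ 100×; 150 bp of flank is extracted around each locus
    for primer design, with a 50 bp hard minimum on either side.
    """

    min_contig_length: int = 200
    min_coverage_tier1: float = 10.0
    min_coverage_tier2: float = 100.0
    flank_length: int = 150
    min_flank_length: int = 50

    def __post_init__(self) -> None:
        if not (self.min_coverage_tier2 >= self.min_coverage_tier1 >= 0):
            raise ValueError("require min_coverage_tier2 >= min_coverage_tier1 >= 0")
        if self.flank_length <= 0 or self.min_flank_length <= 0:
            raise ValueError("flank lengths must be positive")


@dataclass(frozen=True)
class PrimerCandidate:
    """Template around one SSR locus, ready for primer design.

    ``target_span`` locates the repeat within ``template`` (0-based
    half-open); ``flank_lengths`` gives the actual left/right flank sizes
    after truncation at contig ends.
    """

    locus: SSRLocus
    template: str
    target_span: tuple[int, int]
    flank_lengths: tuple[int, int]


class CandidateRejected(ValueError):
    """Candidate extraction failed; ``reason`` is machine-readable.

    Reason codes: ``flank_too_short``, ``ambiguous_flank`` (N in a flank),
    ``ssr_in_flank`` (another detected repeat overlaps a flank).
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


def passes_tier(contig: Contig, config: SelectionConfig, tier: int) -> bool:
    """One-line boundary predicate: strict > on length, inclusive ≥ on depth."""
    if contig.coverage is None:
        return False
    threshold = config.min_coverage_tier1 if tier == 1 else config.min_coverage_tier2
    return contig.length > config.min_contig_length and contig.coverage >= threshold


def filter_contigs(
    contigs: Iterable[Contig], config: SelectionConfig, tier: int
) -> list[Contig]:
    """Contigs passing the requested selection tier, input order preserved.

    Contigs with unknown coverage are excluded with a logged warning —
    depth is part of the criterion and unknown is not zero.
    """
    if tier not in (1, 2):
        raise ValueError(f"tier must be 1 or 2, got {tier}")
    kept = []
    for contig in contigs:
        if contig.coverage is None:
            logger.warning("contig %s: coverage unknown, excluded from tier %d", contig.id, tier)
            continue
        if passes_tier(contig, config, tier):
            kept.append(contig)
    return kept


def select_loci(loci: Iterable[SSRLocus], contigs: Iterable[Contig]) -> list[SSRLocus]:
    """Loci lying on the retained contigs, in stable input order."""
    retained = {c.id for c in contigs}
    out = []
    for loc in loci:
        if loc.contig_id in retained:
            out.append(loc)
    return out


def extract_candidate(
    locus: SSRLocus,
    contig: Contig,
    flank_length: int = 150,
    min_flank_length: int = 50,
    other_loci: Sequence[SSRLocus] = (),
) -> PrimerCandidate:
    """Cut the repeat plus up to ``flank_length`` bases of flank on each side.

    Flanks are truncated at contig ends; a candidate is rejected when either
    truncated flank is shorter than ``min_flank_length``, contains N, or
    overlaps another detected repeat in ``other_loci`` (primer specificity).

    Raises
    ------
    CandidateRejected
        With reason ``flank_too_short``, ``ambiguous_flank`` or ``ssr_in_flank``.
    """
    if locus.contig_id != contig.id:
        raise ValueError(f"locus on {locus.contig_id!r}, contig is {contig.id!r}")
    left_start = max(0, locus.start - flank_length)
    right_end = min(contig.length, locus.end + flank_length)
    left_len = locus.start - left_start
    right_len = right_end - locus.end
    if left_len < min_flank_length or right_len < min_flank_length:
        raise CandidateRejected(
            "flank_too_short", f"flanks {left_len}/{right_len} < {min_flank_length}"
        )
    left = contig.sequence[left_start : locus.start]
    right = contig.sequence[locus.end : right_end]
    if "N" in left or "N" in right:
        raise CandidateRejected("ambiguous_flank", "N in flanking sequence")
    for other in other_loci:
        if other.contig_id != contig.id or other.span == locus.span:
            continue
        if other.start < locus.start and other.end > left_start:
            raise CandidateRejected("ssr_in_flank", f"overlaps locus at {other.span}")
        if other.end > locus.end and other.start < right_end:
            raise CandidateRejected("ssr_in_flank", f"overlaps locus at {other.span}")
    template = left + contig.sequence[locus.start : locus.end] + right
    return PrimerCandidate(
        locus=locus,
        template=template,
        target_span=(left_len, left_len + locus.length),
        flank_lengths=(left_len, right_len),
    )


def extract_candidates(
    loci: Sequence[SSRLocus],
    contigs: Iterable[Contig],
    flank_length: int = 150,
    min_flank_length: int = 50,
) -> tuple[list[PrimerCandidate], list[tuple[SSRLocus, str]]]:
    """Batch extraction; returns (candidates, [(rejected locus, reason), ...])."""
    by_id = {c.id: c for c in contigs}
    candidates: list[PrimerCandidate] = []
    rejected: list[tuple[SSRLocus, str]] = []
    for locus in loci:
        contig = by_id.get(locus.contig_id)
        if contig is None:
            raise KeyError(f"locus at {locus.span} references unknown contig {locus.contig_id!r}")
        try:
            candidates.append(
                extract_candidate(
                    locus, contig, flank_length, min_flank_length, other_loci=loci
                )
            )
        except CandidateRejected as exc:
            rejected.append((locus, exc.reason))
    return candidates, rejected


def export_primer3_records(
    candidates: Iterable[PrimerCandidate],
    product_size_range: tuple[int, int] = (100, 350),
) -> str:
    """Boulder-IO records (KEY=value lines, ``=`` terminator) for primer design.

    One record per candidate; ``SEQUENCE_TARGET`` marks the repeat so the
    design tool places primers in the flanks.  Ids are derived from the
    locus coordinates and unique within the export.
    """
    lo, hi = product_size_range
    records = []
    for cand in candidates:
        loc = cand.locus
        start, length = cand.target_span[0], cand.target_span[1] - cand.target_span[0]
        records.append(
            "\n".join(
                [
                    f"SEQUENCE_ID={loc.contig_id}_{loc.start}_{loc.end}",
                    f"SEQUENCE_TEMPLATE={cand.template}",
                    f"SEQUENCE_TARGET={start},{length}",
                    f"PRIMER_PRODUCT_SIZE_RANGE={lo}-{hi}",
                    "=",
                ]
            )
        )
    return "\n".join(records) + ("\n" if records else "")


def estimate_tm(primer: str, method: str = "wallace") -> float:
    """Advisory primer melting temperature (°C) by a textbook rule.

    ``wallace``: 2(A+T) + 4(G+C).  ``gc_content``: 64.9 + 41·(G+C − 16.4)/L.
    These sanity-check marker tables; they are not a nearest-neighbor
    thermodynamic model and primer design itself is delegated.
    """
    primer = primer.upper().replace(" ", "")
    if not 10 <= len(primer) <= 40:
        raise ValueError(f"primer length {len(primer)} outside 10-40")
    if set(primer) - set("ACGT"):
        raise ValueError("primer contains characters outside ACGT")
    gc = primer.count("G") + primer.count("C")
    at = len(primer) - gc
    if method == "wallace":
        return 2.0 * at + 4.0 * gc
    if method == "gc_content":
        return 64.9 + 41.0 * (gc - 16.4) / len(primer)
    raise ValueError(f"unknown Tm method {method!r}; use 'wallace' or 'gc_content'")
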