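"""Readers and writers for every external format the pipeline touches.

Conventions (fixed for bit-exact interchange):

* FASTA for contigs in; a two-column tab-separated sidecar table supplies
  per-contig mean read depth (assembler coverage is not portably encoded
  in FASTA headers; an optional ``cov=`` header token parser is provided).
* Tab-separated locus catalogs with 0-based half-open spans; GFF3 output
  uses 1-based inclusive coordinates and feature type ``microsatellite``.
* Comma-separated genotype, marker, statistics, amplification and panel
  tables; UTF-8 throughout; missing genotype calls are empty fields, never
  0 or ".".
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .detect import SSRLocus

logger = logging.getLogger(__name__)

__all__ = [
    "Contig",
    "GenotypeTable",
    "AmplificationTable",
    "FormatError",
    "read_contigs",
    "read_coverage_table",
    "parse_coverage_token",
    "write_contigs",
    "read_genotypes",
    "write_genotypes",
    "write_locus_catalog",
    "read_locus_catalog",
    "write_catalog_summary",
    "read_amplification",
    "write_amplification",
    "read_raw_sizes",
    "write_raw_sizes",
]

CATALOG_DIALECTS = ("tsv", "gff3")
_CATALOG_COLUMNS = ("contig_id", "start", "end", "period", "motif", "motif_class", "repeat_count")


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class Contig:
    """Assembled consensus sequence with its mean read depth.

    ``coverage`` is ``None`` when unknown (absent from the sidecar table) —
    deliberately distinct from 0, which is a legal depth.
    """

    id: str
    sequence: str
    coverage: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise FormatError(f"contig {self.id!r}: characters outside ACGTN: {bad}")
        if self.coverage is not None and self.coverage < 0:
            raise FormatError(f"contig {self.id!r}: negative coverage {self.coverage}")

    @property
    def length(self) -> int:
        return len(self.sequence)


class GenotypeTable:
    """Diploid allele-size calls, individuals × markers.

    Each non-missing call is an unordered pair of strictly positive allele
    sizes in base pairs (homozygotes repeat one size).  Missing calls are
    stored as ``None``; a half-call (one allele present, one absent) is
    rejected at parse time.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        markers: Sequence[str],
        calls: Mapping[tuple[str, str], tuple[float, float] | None],
    ) -> None:
        self.individuals = list(individuals)
        self.markers = list(markers)
        self.calls: dict[tuple[str, str], tuple[float, float] | None] = {}
        for ind in self.individuals:
            for marker in self.markers:
                call = calls.get((ind, marker))
                if call is not None:
                    a, b = call
                    if a <= 0 or b <= 0:
                        raise FormatError(
                            f"non-positive allele size for {ind!r}/{marker!r}: {call}"
                        )
                    call = (min(a, b), max(a, b))
                self.calls[(ind, marker)] = call

    def get(self, individual: str, marker: str) -> tuple[float, float] | None:
        return self.calls[(individual, marker)]

    def calls_for_marker(self, marker: str) -> list[tuple[float, float]]:
        """Non-missing calls for one marker, in individual order."""
        if marker not in self.markers:
            raise KeyError(f"unknown marker {marker!r}")
        out = []
        for ind in self.individuals:
            call = self.calls[(ind, marker)]
            if call is not None:
                out.append(call)
        return out

    def n_missing(self, marker: str | None = None) -> int:
        keys = (
            self.calls
            if marker is None
            else [(ind, marker) for ind in self.individuals]
        )
        return sum(1 for k in keys if self.calls[k] is None)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.markers == other.markers
            and self.calls == other.calls
        )


@dataclass
class AmplificationTable:
    """Cross-species PCR amplification success matrix (marker × species).

    Every (marker, species) cell is present and boolean — a marker that
    failed to amplify is an explicit ``False``, never an absent entry.
    """

    markers: list[str]
    species: list[str]
    amplified: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for marker in self.markers:
            for sp in self.species:
                if (marker, sp) not in self.amplified:
                    raise FormatError(f"missing amplification cell ({marker!r}, {sp!r})")


# ---------------------------------------------------------------------------
# contigs + coverage


def read_coverage_table(path) -> dict[str, float]:
    """Two-column (contig id, mean depth) tab-separated sidecar table."""
    coverage: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            cid, depth = fields
            if cid == "contig_id" and lineno == 1:
                continue  # optional header
            try:
                value = float(depth)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric coverage {depth!r}"
                ) from None
            if not math.isfinite(value) or value < 0:
                raise FormatError(f"{path}: line {lineno}: invalid coverage {value}")
            coverage[cid] = value
    return coverage


_COV_TOKEN = re.compile(r"\bcov(?:erage)?=([0-9]+(?:\.[0-9]+)?)")


def parse_coverage_token(description: str) -> float | None:
    """Optional helper: pull a ``cov=12.3`` token out of a FASTA header."""
    m = _COV_TOKEN.search(description)
    return float(m.group(1)) if m else None


def read_contigs(fasta_path, coverage_path=None) -> list[Contig]:
    """Read contigs from FASTA, attaching coverage from a sidecar table.

    Contigs absent from the coverage table get ``coverage=None`` (unknown)
    and a logged warning; FASTA order is preserved.  Duplicate FASTA ids
    are an error.
    """
    coverage = read_coverage_table(coverage_path) if coverage_path is not None else {}
    contigs: list[Contig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in seen:
            raise FormatError(f"{fasta_path}: duplicate contig id {record.id!r}")
        seen.add(record.id)
        cov = coverage.get(record.id)
        if coverage_path is not None and cov is None:
            logger.warning("contig %s has no entry in %s; coverage unknown", record.id, coverage_path)
        contigs.append(Contig(id=record.id, sequence=str(record.seq), coverage=cov))
    return contigs


def write_contigs(contigs: Iterable[Contig], fasta_path, coverage_path=None) -> None:
    """Write contigs to FASTA and (optionally) their coverage sidecar table."""
    contigs = list(contigs)
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for contig in contigs:
            fh.write(f">{contig.id}\n")
            for i in range(0, len(contig.sequence), 70):
                fh.write(contig.sequence[i : i + 70] + "\n")
    if coverage_path is not None:
        with open(coverage_path, "w", encoding="utf-8") as fh:
            fh.write("contig_id\tcoverage\n")
            for contig in contigs:
                if contig.coverage is not None:
                    fh.write(f"{contig.id}\t{contig.coverage:g}\n")


# ---------------------------------------------------------------------------
# genotypes


def _parse_allele(value: str, lineno: int, path) -> float | None:
    value = value.strip()
    if value == "":
        return None
    try:
        size = float(value)
    except ValueError:
        raise FormatError(f"{path}: line {lineno}: non-numeric allele size {value!r}") from None
    if size <= 0:
        raise FormatError(f"{path}: line {lineno}: non-positive allele size {size}")
    return size


def read_genotypes(path) -> GenotypeTable:
    """Long-format CSV with columns sample, marker, allele1, allele2.

    Both allele fields empty denotes a missing call; exactly one empty is a
    half-call and rejected.  Sample and marker order follow first appearance.
    """
    individuals: list[str] = []
    markers: list[str] = []
    calls: dict[tuple[str, str], tuple[float, float] | None] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"sample", "marker", "allele1", "allele2"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            sample, marker = row["sample"], row["marker"]
            a = _parse_allele(row["allele1"], lineno, path)
            b = _parse_allele(row["allele2"], lineno, path)
            if (a is None) != (b is None):
                raise FormatError(
                    f"{path}: line {lineno}: half-call for {sample!r}/{marker!r} "
                    "(exactly one allele field empty)"
                )
            if sample not in individuals:
                individuals.append(sample)
            if marker not in markers:
                markers.append(marker)
            calls[(sample, marker)] = None if a is None else (a, b)
    return GenotypeTable(individuals, markers, calls)


def _format_size(size: float) -> str:
    return f"{int(size)}" if float(size).is_integer() else f"{size:g}"


def write_genotypes(table: GenotypeTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "marker", "allele1", "allele2"])
        for ind in table.individuals:
            for marker in table.markers:
                call = table.calls[(ind, marker)]
                if call is None:
                    writer.writerow([ind, marker, "", ""])
                else:
                    writer.writerow([ind, marker, _format_size(call[0]), _format_size(call[1])])


# ---------------------------------------------------------------------------
# locus catalogs (TSV and GFF3)


def write_locus_catalog(loci: Iterable[SSRLocus], path, dialect: str = "tsv") -> None:
    """Write a locus catalog.

    ``tsv`` uses 0-based half-open spans; ``gff3`` emits 1-based inclusive
    coordinates, feature type ``microsatellite`` and attributes carrying
    motif, canonical class, period and complete-copy count.  Both dialects
    round-trip losslessly through :func:`read_locus_catalog`.
    """
    loci = list(loci)
    if dialect == "tsv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(_CATALOG_COLUMNS)
            for loc in loci:
                writer.writerow(
                    [loc.contig_id, loc.start, loc.end, loc.period,
                     loc.motif_observed, loc.motif_class, loc.repeat_count]
                )
    elif dialect == "gff3":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("##gff-version 3\n")
            for i, loc in enumerate(loci, start=1):
                attrs = (
                    f"ID=ssr{i};motif={loc.motif_observed};motif_class={loc.motif_class};"
                    f"period={loc.period};repeat_count={loc.repeat_count}"
                )
                fh.write(
                    "\t".join(
                        [loc.contig_id, "ssrkit", "microsatellite",
                         str(loc.start + 1), str(loc.end), ".", "+", ".", attrs]
                    )
                    + "\n"
                )
    else:
        raise FormatError(
            f"unknown catalog dialect {dialect!r}; supported: {', '.join(CATALOG_DIALECTS)}"
        )


def read_locus_catalog(path, dialect: str = "tsv") -> list[SSRLocus]:
    if dialect == "tsv":
        loci = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                loci.append(
                    SSRLocus(
                        contig_id=row["contig_id"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        period=int(row["period"]),
                        motif_observed=row["motif"],
                        motif_class=row["motif_class"],
                        repeat_count=int(row["repeat_count"]),
                    )
                )
        return loci
    if dialect == "gff3":
        loci = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise FormatError(f"{path}: GFF3 line has {len(fields)} columns, expected 9")
                attrs = dict(item.split("=", 1) for item in fields[8].split(";") if item)
                loci.append(
                    SSRLocus(
                        contig_id=fields[0],
                        start=int(fields[3]) - 1,
                        end=int(fields[4]),
                        period=int(attrs["period"]),
                        motif_observed=attrs["motif"],
                        motif_class=attrs["motif_class"],
                        repeat_count=int(attrs["repeat_count"]),
                    )
                )
        return loci
    raise FormatError(
        f"unknown catalog dialect {dialect!r}; supported: {', '.join(CATALOG_DIALECTS)}"
    )


def write_catalog_summary(summary, path) -> None:
    """One CSV row per canonical class: period, count, fraction of total."""
    class_periods = {cls: len(cls) for cls in summary.counts_by_class}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["motif_class", "period", "count", "fraction"])
        for cls in sorted(summary.counts_by_class, key=lambda c: (len(c), c)):
            count = summary.counts_by_class[cls]
            frac = count / summary.total if summary.total else 0.0
            writer.writerow([cls, class_periods[cls], count, f"{frac:.6f}"])


# ---------------------------------------------------------------------------
# amplification matrices and raw fragment sizes


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def read_amplification(path) -> AmplificationTable:
    """Wide CSV: first column ``marker``, one boolean column per species."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[0] != "marker" or len(header) < 2:
            raise FormatError(f"{path}: expected header 'marker,<species>,...'")
        species = header[1:]
        markers: list[str] = []
        amplified: dict[tuple[str, str], bool] = {}
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise FormatError(f"{path}: line {lineno}: wrong column count")
            marker = row[0]
            markers.append(marker)
            for sp, cell in zip(species, row[1:]):
                token = cell.strip().lower()
                if token in _TRUE:
                    amplified[(marker, sp)] = True
                elif token in _FALSE:
                    amplified[(marker, sp)] = False
                else:
                    raise FormatError(f"{path}: line {lineno}: non-boolean cell {cell!r}")
    return AmplificationTable(markers=markers, species=species, amplified=amplified)


def write_amplification(table: AmplificationTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["marker"] + table.species)
        for marker in table.markers:
            writer.writerow(
                [marker] + ["1" if table.amplified[(marker, sp)] else "0" for sp in table.species]
            )


def read_raw_sizes(path) -> pd.DataFrame:
    """Raw (pre-binning) fragment sizes: sample, marker, size1, size2.

    Empty size fields denote missing; returned as NaN in a pandas frame so
    the binning step can pass missing calls through unchanged.
    """
    df = pd.read_csv(path, dtype={"sample": str, "marker": str})
    required = {"sample", "marker", "size1", "size2"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    half = df["size1"].isna() != df["size2"].isna()
    if half.any():
        raise FormatError(f"{path}: half-call at data row(s) {list(df.index[half])}")
    if ((df[["size1", "size2"]] <= 0).any()).any():
        raise FormatError(f"{path}: non-positive fragment size")
    return df


def write_raw_sizes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.3f")
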