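"""Bundled reference data: the validated ruzigrass marker panels and the
headline counts of the genome-survey marker-development study they come
from.

The toolkit ships the published table of the 30 most informative
ruzigrass (*Brachiaria ruziziensis*) microsatellite markers — 11 multiplex
panels with primer sequences, dye labels, observed allele-size ranges and
per-marker descriptive statistics (allele number, He, Ho, PIC) from
genotyping 11 accessions — as a worked-example input.  Two Ho entries in
the printed source lost their decimal point ("1000"); they are transcribed
as 1.000.

``RUZIGRASS_SURVEY`` collects the study's printed counts (loci detected
per coverage tier, primer pairs tested, polymorphism and transferability
outcomes) used by the attrition and transferability worked examples.
Per-species amplification counts are back-calculated from the printed
percentages of 198 polymorphic markers; each percentage determines the
count uniquely.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .panels import MarkerDef

__all__ = ["load_ruzigrass_top30", "ruzigrass_top30_markers", "RUZIGRASS_SURVEY"]

#: Headline counts of the ruzigrass genome-survey marker study.
RUZIGRASS_SURVEY: dict = {
    # perfect SSR loci detected per selection tier
    "loci_all_contigs": 139_098,
    "loci_10x_by_period": {2: 3_919, 3: 72_902, 4: 8_746},  # contigs >200 bp, ≥10×
    "loci_100x": 1_135,
    "loci_selected_for_primers": 500,
    # validation outcomes on 11 accessions
    "primer_pairs_tested": 269,
    "markers_genotyped": 239,
    "markers_polymorphic": 198,
    "total_alleles": 835,
    # of the 198 polymorphic markers:
    "expected_size_in_range": 139,  # observed range contains the designed size
    "within_10pct_of_expected": 190,  # both range endpoints within ±10%
    # cross-species amplification successes out of 198 polymorphic markers
    "transfer_counts": {
        "B. brizantha cv. Marandu": 180,
        "B. brizantha cv. Piata": 134,
        "B. brizantha cv. Xaraes": 174,
        "B. decumbens cv. Basilisk": 184,
        "B. humidicola cv. Tupi": 85,
    },
}


def load_ruzigrass_top30() -> pd.DataFrame:
    """The 30-marker multiplex-panel table as a DataFrame.

    Columns: panel, marker, dye, forward_primer, reverse_primer,
    allele_no, size_min, size_max, he, ho, pic.
    """
    path = files("ssrkit").joinpath("data/ruzigrass_top30_markers.csv")
    with path.open("rb") as fh:
        return pd.read_csv(fh)


def ruzigrass_top30_markers() -> list[MarkerDef]:
    """The same table as :class:`~ssrkit.panels.MarkerDef` objects.

    The source table does not record motif periods or designed product
    sizes for these markers, so ``period`` and ``expected_size`` are left
    unset; observed size ranges and PIC values are attached.
    """
    df = load_ruzigrass_top30()
    return [
        MarkerDef(
            name=row.marker,
            forward_primer=row.forward_primer,
            reverse_primer=row.reverse_primer,
            dye=row.dye,
            observed_size_range=(int(row.size_min), int(row.size_max)),
            pic=float(row.pic),
        )
        for row in df.itertuples()
    ]
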