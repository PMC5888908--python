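"""Curated reference table of the novel *Drosophila suzukii* RNA viruses.

The packaged TSV transcribes the published summary of the 18 newly
described viruses: provisional name, GenBank accession(s), best-hit
taxon, genome class, longest assembled contig, the sampling pools in
which each virus was detected, and the RT-PCR (cDNA) / PCR (nuclear DNA)
validation outcomes.  Sample labels are normalized to Location+Year
tokens; the Beult virus row, published with "Japan" and no year, is
recorded as Japan2016, the single Japanese collection year.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .strand import GENOME_CLASSES

__all__ = ["CuratedVirusRecord", "load_table1", "tally_by_class"]

_ACCESSION_PREFIX = "MF"


@dataclass(frozen=True)
class CuratedVirusRecord:
    name: str
    accessions: tuple[str, ...]
    taxon: str
    genome_class: str
    longest_contig_kb: float
    samples_detected: tuple[str, ...]
    rtpcr_positive: bool
    dnapcr_positive: bool


def load_table1() -> list[CuratedVirusRecord]:
    """Load the packaged novel-virus table as validated records."""
    with resources.files("virosift.data").joinpath("novel_viruses.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    expected = {
        "name",
        "accessions",
        "taxon",
        "genome_class",
        "longest_contig_kb",
        "samples",
        "rtpcr_positive",
        "dnapcr_positive",
    }
    if set(df.columns) != expected:
        raise ValueError(f"fixture columns {sorted(df.columns)} != {sorted(expected)}")
    records = []
    for row in df.itertuples():
        if row.genome_class not in GENOME_CLASSES:
            raise ValueError(f"bad genome class {row.genome_class!r} for {row.name!r}")
        accessions = tuple(row.accessions.split(","))
        if not all(a.startswith(_ACCESSION_PREFIX) for a in accessions):
            raise ValueError(f"unexpected accession format in {accessions}")
        records.append(
            CuratedVirusRecord(
                name=row.name,
                accessions=accessions,
                taxon=row.taxon,
                genome_class=row.genome_class,
                longest_contig_kb=float(row.longest_contig_kb),
                samples_detected=tuple(row.samples.split(",")),
                rtpcr_positive=row.rtpcr_positive == "true",
                dnapcr_positive=row.dnapcr_positive == "true",
            )
        )
    return records


def tally_by_class(records) -> dict[str, int]:
    """Count records per genome class; counts partition the record set."""
    tally = {cls: 0 for cls in GENOME_CLASSES}
    for rec in records:
        cls = getattr(rec, "genome_class", None)
        if cls not in tally:
            raise ValueError(f"unknown genome class {cls!r}")
        tally[cls] += 1
    return tally
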