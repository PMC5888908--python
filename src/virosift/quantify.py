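"""Abundance normalization, detection thresholding, and the clustered
log10 abundance matrix.

Raw per-(virus, sample) read counts are expressed as reads per kilobase
of target per million non-ribosomal library reads:

    normalized = count * 1e9 / (target_length_nt * non_rrna_total)

A detection threshold (default 0.5 reads/kb/million, inclusive) guards
against spurious signals from low-level species contamination, barcode
switching between co-sequenced libraries, and cross-mapping to close
relatives.  Detected values are displayed on a log10 scale with rows and
columns ordered by agglomerative hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "DETECTION_THRESHOLD",
    "AbundanceCell",
    "AbundanceMatrix",
    "normalize",
    "apply_threshold",
    "abundance_cells",
    "build_matrix",
    "read_counts_table",
    "read_samples_table",
]

DETECTION_THRESHOLD = 0.5  # reads per kb per million non-rRNA reads


@dataclass(frozen=True)
class AbundanceCell:
    virus: str
    sample: str
    raw_count: int
    target_length_nt: int
    non_rrna_total: int
    normalized: float
    detected: bool


@dataclass
class AbundanceMatrix:
    """Log10 abundance matrix with clustering-derived row/column orders.

    ``values`` holds log10(normalized) for detected cells and NaN for
    undetected ones; ``clustering_values`` is the same matrix with
    undetected cells imputed at the clustering floor (one decade, by
    default, below the smallest detected value).
    """

    values: pd.DataFrame
    clustering_values: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None

    @property
    def ordered(self) -> pd.DataFrame:
        return self.values.loc[self.row_order, self.col_order]


def normalize(raw_count: float, target_length_nt: int, non_rrna_total: int) -> float:
    """Reads per kb of target per million non-rRNA reads."""
    if target_length_nt <= 0:
        raise ValueError("target_length_nt must be positive")
    if non_rrna_total <= 0:
        raise ValueError("non_rrna_total must be positive")
    if raw_count < 0:
        raise ValueError("raw_count must be non-negative")
    return raw_count * 1e9 / (target_length_nt * non_rrna_total)


def apply_threshold(normalized: float, threshold: float = DETECTION_THRESHOLD) -> bool:
    """Detected iff normalized abundance reaches the threshold (inclusive)."""
    if normalized < 0:
        raise ValueError("normalized abundance must be non-negative")
    return normalized >= threshold


def abundance_cells(
    counts: Mapping[tuple[str, str], int],
    target_lengths: Mapping[str, int],
    non_rrna_totals: Mapping[str, int],
    threshold: float = DETECTION_THRESHOLD,
) -> list[AbundanceCell]:
    """Build normalized, thresholded cells from summed (virus, sample) counts.

    ``counts`` maps (virus, sample) to the read count already summed over
    the virus's segments; ``target_lengths`` maps virus to its summed
    segment length in nt.  Every (virus, sample) combination over the
    observed viruses and samples is emitted, absent counts as zero.
    """
    viruses = sorted({v for v, _ in counts} | set(target_lengths))
    samples = sorted({s for _, s in counts} | set(non_rrna_totals))
    cells = []
    for virus in viruses:
        length = target_lengths[virus]
        for sample in samples:
            total = non_rrna_totals[sample]
            raw = int(counts.get((virus, sample), 0))
            norm = normalize(raw, length, total)
            cells.append(
                AbundanceCell(
                    virus, sample, raw, length, total, norm, apply_threshold(norm, threshold)
                )
            )
    return cells


def build_matrix(
    cells: Sequence[AbundanceCell],
    distance: str = "euclidean",
    method: str = "complete",
    floor_decades: float = 1.0,
) -> AbundanceMatrix:
    """Assemble the log10 abundance matrix and cluster rows and columns.

    Undetected cells are exported as missing (NaN) but, for distance
    computation only, imputed at ``floor_decades`` below the smallest
    detected log10 value, so fully undetected rows cluster together at
    the floor rather than being dropped.  Axes with fewer than two
    entries keep their (sorted) identity order.
    """
    if not cells:
        empty = pd.DataFrame()
        return AbundanceMatrix(empty, empty.copy(), [], [], None, None)
    records = pd.DataFrame(
        {
            "virus": [c.virus for c in cells],
            "sample": [c.sample for c in cells],
            "log10": [
                np.log10(c.normalized) if c.detected else np.nan for c in cells
            ],
        }
    )
    mat = records.pivot_table(
        index="virus", columns="sample", values="log10", aggfunc="first", dropna=False
    ).sort_index(axis=0).sort_index(axis=1)
    if not np.isfinite(mat.to_numpy()).any():
        clust = mat.fillna(0.0)
        return AbundanceMatrix(
            mat, clust, list(mat.index), list(mat.columns), None, None
        )
    floor = np.nanmin(mat.to_numpy()) - floor_decades
    clust = mat.fillna(floor)

    def _order(frame: pd.DataFrame) -> tuple[list, np.ndarray | None]:
        labels = list(frame.index)
        if len(labels) < 2:
            return labels, None
        z = linkage(pdist(frame.to_numpy(), metric=distance), method=method)
        return [labels[i] for i in leaves_list(z)], z

    row_order, row_z = _order(clust)
    col_order, col_z = _order(clust.T)
    return AbundanceMatrix(mat, clust, row_order, col_order, row_z, col_z)


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read a stranded counts TSV (sample, reference, strand, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "reference": str, "strand": str})
    expected = {"sample", "reference", "strand", "count"}
    if not expected <= set(df.columns):
        raise ValueError(f"counts table must have columns {sorted(expected)}")
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    bad = set(df["strand"]) - {"+", "-", "−"}
    if bad:
        raise ValueError(f"strand must be '+' or '-', got {sorted(bad)}")
    df["strand"] = df["strand"].replace({"−": "-"})
    return df


def read_samples_table(path: str | Path) -> pd.DataFrame:
    """Read a samples TSV (sample, total_reads, rrna_fraction) and derive
    the non-rRNA denominator."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    expected = {"sample", "total_reads", "rrna_fraction"}
    if not expected <= set(df.columns):
        raise ValueError(f"samples table must have columns {sorted(expected)}")
    if ((df["rrna_fraction"] < 0) | (df["rrna_fraction"] >= 1)).any():
        raise ValueError("rrna_fraction must be in [0, 1)")
    df["non_rrna_total"] = (
        df["total_reads"] * (1.0 - df["rrna_fraction"])
    ).round().astype(int)
    if (df["non_rrna_total"] <= 0).any():
        raise ValueError("non-rRNA totals must be positive")
    return df


def sum_counts_by_virus(
    counts: pd.DataFrame, virus_of_reference: Mapping[str, str]
) -> dict[tuple[str, str], int]:
    """Sum stranded counts over strands and segments to (virus, sample) totals.

    References absent from ``virus_of_reference`` (e.g. host markers) are
    ignored.
    """
    out: dict[tuple[str, str], int] = {}
    for row in counts.itertuples():
        virus = virus_of_reference.get(row.reference)
        if virus is None:
            continue
        key = (virus, row.sample)
        out[key] = out.get(key, 0) + int(row.count)
    return out
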