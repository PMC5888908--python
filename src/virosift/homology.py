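"""Best-hit triage of tabular homology-search results and novelty calling.

Contigs are classified from a BLAST/DIAMOND ``outfmt 6``-style table: for
each contig a single top hit is retained (smallest e-value under a
threshold, ties broken by larger bitscore then lexicographic subject id),
and a contig is called viral iff that top hit falls in the ``virus``
subject category.  Candidate viruses grouped by best-hit taxon are called
*known* when their polymerase identity to a published virus exceeds a
strict threshold (default >95%), otherwise *novel*.

Subject categories come from a separate two-column map (subject id ->
category) rather than being parsed out of subject identifiers, because
database taxonomy strings drift between releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HitRecord",
    "VirusCandidate",
    "SUBJECT_CATEGORIES",
    "best_hit",
    "best_hits_by_contig",
    "classify_viral",
    "pairwise_aa_identity",
    "novelty_call",
    "group_candidates",
    "read_hit_table",
    "write_candidate_table",
]

SUBJECT_CATEGORIES = (
    "virus",
    "prokaryote",
    "protist",
    "fungus",
    "nematode",
    "hymenopteran",
    "dipteran",
    "other",
)

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "evalue",
    "bitscore",
    "subject_category",
]

GAP_CHARS = frozenset("-−.")


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular protein homology search."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    evalue: float
    bitscore: float
    subject_category: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not 0 <= self.pident <= 100:
            raise ValueError("pident must be in [0, 100]")


@dataclass
class VirusCandidate:
    name: str
    taxon_group: str
    genome_class: str | None
    contig_ids: list[str] = field(default_factory=list)
    longest_contig_kb: float = 0.0
    novelty: str = "novel"


def best_hit(
    hits: Sequence[HitRecord], evalue_threshold: float = 0.01
) -> HitRecord | None:
    """Select the single top hit for one contig.

    Returns the hit with the smallest e-value among those with
    ``evalue <= evalue_threshold``; ties are broken by larger bitscore,
    then lexicographically smaller subject id.  Returns None when no hit
    passes the threshold.
    """
    if not hits:
        return None
    qids = {h.qseqid for h in hits}
    if len(qids) > 1:
        raise ValueError(f"hits span multiple contigs: {sorted(qids)}")
    passing = [h for h in hits if h.evalue <= evalue_threshold]
    if not passing:
        return None
    return min(passing, key=lambda h: (h.evalue, -h.bitscore, h.sseqid))


def best_hits_by_contig(
    hits: Iterable[HitRecord], evalue_threshold: float = 0.01
) -> dict[str, HitRecord]:
    """Apply :func:`best_hit` per contig; contigs with no passing hit are absent."""
    by_contig: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_contig.setdefault(h.qseqid, []).append(h)
    out = {}
    for qid, rows in by_contig.items():
        top = best_hit(rows, evalue_threshold)
        if top is not None:
            out[qid] = top
    return out


def classify_viral(best_hits: Mapping[str, HitRecord | None]) -> set[str]:
    """Contigs whose top hit exists and is a virus. Only the top hit counts."""
    return {
        qid
        for qid, hit in best_hits.items()
        if hit is not None and hit.subject_category == "virus"
    }


def pairwise_aa_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identity over mutually non-gapped columns of an alignment.

    Both inputs must be equal-length aligned strings; '-' (ASCII or
    unicode minus) marks gaps.  Columns where either sequence is gapped
    are excluded from the denominator.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    comparable = 0
    matches = 0
    for a, b in zip(aligned_a.upper(), aligned_b.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        comparable += 1
        if a == b:
            matches += 1
    if comparable == 0:
        raise ValueError("no mutually non-gapped columns to compare")
    return 100.0 * matches / comparable


def novelty_call(identity_to_best_known: float, threshold: float = 95.0) -> str:
    """'known' iff identity strictly exceeds the threshold, else 'novel'."""
    if not 0 <= identity_to_best_known <= 100:
        raise ValueError("identity must be in [0, 100]")
    return "known" if identity_to_best_known > threshold else "novel"


def group_candidates(
    best_hits: Mapping[str, HitRecord],
    contig_lengths: Mapping[str, int],
    taxon_of_subject: Mapping[str, str] | None = None,
    identity_to_known: Mapping[str, float] | None = None,
    genome_class_of_taxon: Mapping[str, str] | None = None,
    novelty_threshold: float = 95.0,
) -> list[VirusCandidate]:
    """Group viral contigs into candidates by their best-hit taxon.

    ``taxon_of_subject`` maps subject ids to taxon labels (defaults to the
    subject id itself); ``identity_to_known`` gives, per taxon group, the
    polymerase identity to the closest published virus used for the
    novelty call (absent -> treated as novel).
    """
    taxon_of_subject = taxon_of_subject or {}
    identity_to_known = identity_to_known or {}
    genome_class_of_taxon = genome_class_of_taxon or {}
    viral = classify_viral(best_hits)
    groups: dict[str, VirusCandidate] = {}
    for qid in sorted(viral):
        hit = best_hits[qid]
        taxon = taxon_of_subject.get(hit.sseqid, hit.sseqid)
        cand = groups.setdefault(
            taxon,
            VirusCandidate(
                name=taxon,
                taxon_group=taxon,
                genome_class=genome_class_of_taxon.get(taxon),
            ),
        )
        cand.contig_ids.append(qid)
        kb = contig_lengths.get(qid, 0) / 1000.0
        cand.longest_contig_kb = max(cand.longest_contig_kb, kb)
    for taxon, cand in groups.items():
        ident = identity_to_known.get(taxon)
        cand.novelty = (
            novelty_call(ident, novelty_threshold) if ident is not None else "novel"
        )
    return [groups[t] for t in sorted(groups)]


def read_hit_table(
    path: str | Path, category_map: str | Path | Mapping[str, str] | None = None
) -> list[HitRecord]:
    """Read an outfmt-6-compatible TSV into HitRecords.

    The file either carries a trailing ``subject_category`` column or the
    category is looked up per subject id in ``category_map`` (a mapping or
    a two-column TSV of subject id and category).
    """
    df = pd.read_csv(path, sep="\t")
    if "subject_category" not in df.columns:
        if category_map is None:
            raise ValueError(
                "hit table lacks subject_category and no category map given"
            )
        if not isinstance(category_map, Mapping):
            cm = pd.read_csv(
                category_map, sep="\t", header=None, names=["sseqid", "category"]
            )
            category_map = dict(zip(cm["sseqid"], cm["category"]))
        df["subject_category"] = df["sseqid"].map(category_map)
        if df["subject_category"].isna().any():
            missing = df.loc[df["subject_category"].isna(), "sseqid"].unique()
            raise ValueError(f"subjects missing from category map: {missing[:5]}")
    return [
        HitRecord(
            qseqid=str(r.qseqid),
            sseqid=str(r.sseqid),
            pident=float(r.pident),
            length=int(r.length),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
            subject_category=str(r.subject_category),
        )
        for r in df.itertuples()
    ]


def write_candidate_table(candidates: Sequence[VirusCandidate], path: str | Path) -> None:
    """Write the candidate table TSV (name, taxon, class, longest contig, contigs)."""
    rows = [
        {
            "name": c.name,
            "taxon": c.taxon_group,
            "genome_class": c.genome_class or "",
            "longest_contig_kb": round(c.longest_contig_kb, 3),
            "n_contigs": len(c.contig_ids),
            "contigs": ",".join(c.contig_ids),
            "novelty": c.novelty,
        }
        for c in candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
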