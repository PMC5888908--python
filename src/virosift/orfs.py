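"""Six-frame ORF discovery and contig triage.

Assembled metatranscriptomic contigs are frequently partial genome
fragments, so the default ORF convention here is *stop-to-stop*: an ORF is
a maximal stop-codon-free codon run in one of the six reading frames,
including terminal runs that lack a bounding stop codon.  An AUG-anchored
mode is available via ``require_start=True`` for callers that want
conventional start-to-stop genes.

Triage follows a two-gate rule typical of virus-discovery pipelines:
contigs shorter than a minimum nucleotide length are excluded outright,
and of the remainder only contigs whose longest ORF reaches a minimum
codon count are retained for homology search.  Annotation of individual
ORFs within a retained contig applies a minimum amino-acid length, with
short ORFs rescued by similarity evidence and short nested ORFs
disregarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

__all__ = [
    "Orf",
    "ContigTriageResult",
    "AnnotationCall",
    "find_orfs",
    "translate",
    "triage_contig",
    "annotate_orfs",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # TAA, TAG, TGA
_VALID_CHARS = frozenset("ACGTN")

FRAME_ORDER = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"sequence contains characters outside ACGTN: {sorted(bad)!r}"
        )
    return seq


def translate(codons: str) -> str:
    """Translate a frame-aligned nucleotide string with the standard code.

    Codons containing N (or any codon absent from the standard table that
    is not a stop) translate to ``X``.  Stop codons translate to ``*``.
    """
    if len(codons) % 3:
        raise ValueError("length must be a multiple of 3")
    out = []
    for i in range(0, len(codons), 3):
        codon = codons[i : i + 3]
        if codon in _STOP_CODONS:
            out.append("*")
        else:
            out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


@dataclass(frozen=True, order=True)
class Orf:
    """A stop-free codon run located on the forward strand.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand regardless of frame sign; for negative frames the
    translation reads from ``end`` leftwards.
    """

    contig_id: str
    frame: int
    start: int
    end: int
    translation: str

    @property
    def length_codons(self) -> int:
        return (self.end - self.start) // 3

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF span must be a multiple of 3")
        if len(self.translation) != self.length_codons:
            raise ValueError("translation length must equal codon count")


@dataclass(frozen=True)
class ContigTriageResult:
    contig_id: str
    length_nt: int
    longest_orf_codons: int
    retained: bool
    concatenated_translation: str


@dataclass(frozen=True)
class AnnotationCall:
    orf: Orf
    annotated: bool
    reason: str  # long_enough | short_non_similar | nested_disregarded | similarity_rescue


def _runs_in_frame(seq: str, offset: int, min_codons: int, require_start: bool):
    """Yield (start_nt, end_nt, translation) runs on `seq` in one frame.

    Coordinates are relative to `seq` itself; the caller maps them back to
    the forward strand.  Runs are maximal stop-free stretches; terminal
    runs without a closing stop are included.
    """
    n_codons = (len(seq) - offset) // 3
    run_start = 0  # codon index where current run began
    i = 0
    while i <= n_codons:
        at_end = i == n_codons
        codon = None if at_end else seq[offset + 3 * i : offset + 3 * i + 3]
        if at_end or codon in _STOP_CODONS:
            if i > run_start:
                s, e = run_start, i
                if require_start:
                    # anchor at the first ATG within the run
                    anchor = None
                    for j in range(s, e):
                        if seq[offset + 3 * j : offset + 3 * j + 3] == "ATG":
                            anchor = j
                            break
                    s = anchor if anchor is not None else None
                if s is not None and e - s >= min_codons:
                    nt_s = offset + 3 * s
                    nt_e = offset + 3 * e
                    yield nt_s, nt_e, translate(seq[nt_s:nt_e])
            run_start = i + 1
        i += 1


def find_orfs(
    sequence: str,
    min_codons: int = 1,
    contig_id: str = "",
    require_start: bool = False,
) -> list[Orf]:
    """Find ORFs in all six reading frames.

    Parameters
    ----------
    sequence : str
        Nucleotide sequence over ``ACGTN`` (case-insensitive).
    min_codons : int
        Minimum ORF length in codons (>= 1).
    contig_id : str
        Label stored on each returned :class:`Orf`.
    require_start : bool
        If True, ORFs are anchored at the first AUG of each stop-free run
        instead of spanning the whole run.

    Returns
    -------
    list of Orf sorted by frame (+1,+2,+3,-1,-2,-3) then forward start.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    seq = _check_sequence(sequence)
    length = len(seq)
    orfs: list[Orf] = []
    rc = _revcomp(seq)
    for sign, strand_seq in ((1, seq), (-1, rc)):
        for offset in range(3):
            frame = sign * (offset + 1)
            for s, e, aa in _runs_in_frame(
                strand_seq, offset, min_codons, require_start
            ):
                if sign == 1:
                    start, end = s, e
                else:
                    start, end = length - e, length - s
                orfs.append(Orf(contig_id, frame, start, end, aa))
    orfs.sort(key=lambda o: (FRAME_ORDER.index(o.frame), o.start))
    return orfs


def triage_contig(
    contig_id: str,
    sequence: str,
    min_length_nt: int = 500,
    min_orf_codons: int = 150,
    require_start: bool = False,
) -> ContigTriageResult:
    """Apply the length and longest-ORF retention gates to one contig.

    Contigs shorter than ``min_length_nt`` are excluded before any ORF
    analysis.  Otherwise the contig is retained iff its longest six-frame
    ORF reaches ``min_orf_codons``; the concatenated translation joins all
    ORF translations ordered by frame then start, which is the protein
    input handed to the downstream homology search.
    """
    seq = _check_sequence(sequence)
    if len(seq) < min_length_nt:
        return ContigTriageResult(contig_id, len(seq), 0, False, "")
    orfs = find_orfs(seq, min_codons=1, contig_id=contig_id, require_start=require_start)
    longest = max((o.length_codons for o in orfs), default=0)
    retained = longest >= min_orf_codons
    concat = "".join(o.translation for o in orfs)
    return ContigTriageResult(contig_id, len(seq), longest, retained, concat)


def _nested_within_larger(orf: Orf, others: Iterable[Orf]) -> bool:
    for other in others:
        if other is orf or other == orf:
            continue
        if (
            other.start <= orf.start
            and orf.end <= other.end
            and other.length_codons > orf.length_codons
        ):
            return True
    return False


def annotate_orfs(
    orfs: Sequence[Orf],
    similarity_evidence: Mapping[Orf, bool] | None = None,
    min_aa: int = 100,
    nested_max_aa: int = 200,
) -> list[AnnotationCall]:
    """Decide which ORFs of one contig would be annotated on a genome map.

    An ORF is annotated iff it is at least ``min_aa`` amino acids long and
    is not a sub-``nested_max_aa`` ORF fully nested (forward-strand
    interval containment) within a larger one — unless similarity evidence
    to a known protein rescues it.
    """
    similarity_evidence = similarity_evidence or {}
    calls = []
    for orf in orfs:
        aa_len = orf.length_codons
        similar = bool(similarity_evidence.get(orf, False))
        nested = aa_len < nested_max_aa and _nested_within_larger(orf, orfs)
        if aa_len >= min_aa and not nested:
            calls.append(AnnotationCall(orf, True, "long_enough"))
        elif similar:
            calls.append(AnnotationCall(orf, True, "similarity_rescue"))
        elif aa_len < min_aa:
            calls.append(AnnotationCall(orf, False, "short_non_similar"))
        else:
            calls.append(AnnotationCall(orf, False, "nested_disregarded"))
    return calls
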