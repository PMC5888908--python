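"""Contamination and artifact diagnostics.

Three screens that separate genuine infections from artifacts of
multiplexed metatranscriptomics:

* **Cross-mapping** — reads from an abundant virus aligning to a close
  relative's genome can fabricate a low-level detection of the relative.
  For an ordered pair of references the screen reports the fraction of
  reads mapped to the first that also align to the second; the fraction
  is directional, so both orientations are reported.
* **COI profiling** — read counts over a species-discriminating
  cytochrome oxidase I region reveal pooled individuals of the wrong
  species (misidentification) or library cross-contamination.
* **EVE classification** — RNA viruses produce no DNA intermediate, so a
  virus detectable in the DNA fraction is likely an endogenous viral
  element (EVE) rather than an active infection.

A heuristic barcode-switching note flags viruses detected just above
threshold in one library while present at a much higher level (default
ratio >= 100x) in a co-sequenced library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CrossMapReport",
    "CoiProfile",
    "EveCall",
    "crossmap",
    "coi_profile",
    "eve_classify",
    "barcode_switch_notes",
]

CALL_ACTIVE = "active_infection_candidate"
CALL_EVE = "putative_eve"
CALL_NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class CrossMapReport:
    ref_a: str
    ref_b: str
    n_mapped_a: int
    n_shared: int
    shared_fraction: float
    flagged: bool


@dataclass(frozen=True)
class CoiProfile:
    sample: str
    species_fractions: dict[str, float]
    contaminants: list[str]


@dataclass(frozen=True)
class EveCall:
    virus: str
    rna_detected: bool
    dna_detected: bool
    call: str


def crossmap(
    read_assignments: pd.DataFrame,
    ref_a: str,
    ref_b: str,
    flag_threshold: float = 0.05,
) -> CrossMapReport:
    """Fraction of reads mapped to ``ref_a`` that also align to ``ref_b``.

    ``read_assignments`` lists one (read_id, reference) row per alignment;
    a read aligning to both references contributes to the shared count.
    The measure is directional: swap the arguments for the reverse view.
    A reference absent from the table yields a zero-mapped report with a
    warning rather than an error.
    """
    expected = {"read_id", "reference"}
    if not expected <= set(read_assignments.columns):
        raise ValueError(f"assignments need columns {sorted(expected)}")
    reads_a = set(
        read_assignments.loc[read_assignments["reference"] == ref_a, "read_id"]
    )
    if not reads_a:
        warnings.warn(f"no reads mapped to {ref_a!r}", stacklevel=2)
        return CrossMapReport(ref_a, ref_b, 0, 0, 0.0, False)
    reads_b = set(
        read_assignments.loc[read_assignments["reference"] == ref_b, "read_id"]
    )
    shared = len(reads_a & reads_b)
    fraction = shared / len(reads_a)
    return CrossMapReport(
        ref_a, ref_b, len(reads_a), shared, fraction, fraction >= flag_threshold
    )


def coi_profile(
    coi_counts: Mapping[str, int],
    focal_species: str,
    contam_threshold: float = 0.005,
    sample: str = "",
) -> CoiProfile:
    """Species composition of COI-mapped reads and the contaminant list.

    Fractions are normalized over all species with counts; any species
    other than the focal one whose fraction reaches ``contam_threshold``
    is listed as a contaminant.
    """
    if any(v < 0 for v in coi_counts.values()):
        raise ValueError("COI counts must be non-negative")
    total = sum(coi_counts.values())
    if total == 0:
        raise ValueError("all COI counts are zero")
    fractions = {sp: n / total for sp, n in coi_counts.items() if n > 0}
    contaminants = sorted(
        sp
        for sp, f in fractions.items()
        if sp != focal_species and f >= contam_threshold
    )
    return CoiProfile(sample, fractions, contaminants)


def eve_classify(rna_detected: bool, dna_detected: bool, virus: str = "") -> EveCall:
    """Classify a virus from its RNA- and DNA-fraction detections.

    Detection in the DNA fraction implies an endogenous viral element;
    RNA-only detection marks a candidate active infection.
    """
    if dna_detected:
        call = CALL_EVE
    elif rna_detected:
        call = CALL_ACTIVE
    else:
        call = CALL_NOT_DETECTED
    return EveCall(virus, bool(rna_detected), bool(dna_detected), call)


def barcode_switch_notes(
    normalized: Mapping[tuple[str, str], float],
    co_sequenced: Iterable[tuple[str, str]],
    threshold: float = 0.5,
    near_factor: float = 4.0,
    ratio: float = 100.0,
) -> list[dict]:
    """Flag detections plausibly explained by barcode switching.

    A virus detected in one library within ``near_factor`` of the
    detection threshold, while a co-sequenced library carries it at
    >= ``ratio`` times that level, is noted as a possible index-hopping
    artifact.  ``normalized`` maps (virus, sample) to normalized
    abundance; ``co_sequenced`` lists unordered library pairs run on the
    same flow cell.  Heuristic only: notes inform review, they do not
    change detection calls.
    """
    notes = []
    pairs = set()
    for a, b in co_sequenced:
        pairs.add((a, b))
        pairs.add((b, a))
    for (virus, sample), value in sorted(normalized.items()):
        if not threshold <= value < threshold * near_factor:
            continue
        for (recv, src) in pairs:
            if recv != sample:
                continue
            source_value = normalized.get((virus, src), 0.0)
            if source_value >= value * ratio:
                notes.append(
                    {
                        "virus": virus,
                        "sample": sample,
                        "normalized": value,
                        "co_sequenced_sample": src,
                        "co_sequenced_normalized": source_value,
                        "note": "possible barcode switching",
                    }
                )
    return notes
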