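"""Synthetic multi-sample virome datasets with known ground truth.

The generator plants a configurable set of viruses — each with a genome
class (+ssRNA, −ssRNA, dsRNA), one or more genome segments, a
positive-sense read polarity, and per-sample abundances expressed
directly in reads per kb per million non-rRNA reads — into a background
of host contigs, and emits every file the triage/quantification/strand/
diagnostics stages consume, together with a truth table.

Modeling choices (see the methods note for discussion):

* Segment read totals are Poisson with mean
  ``abundance × length_kb × non_rrna_total / 1e6``; positive-strand
  counts are Binomial(total, polarity_fraction).  No overdispersion by
  default — only the normalization / threshold / CI logic downstream is
  under test.
* Library cross-contamination is modeled as barcode switching only: a
  small fraction of each co-sequenced library's reads (per strand) is
  copied into the receiving library.
* Genome sequences are random nucleotides with a planted stop-free codon
  run of at least 150 codons, so every viral contig survives the ORF
  retention gate; no attempt is made to mimic real viral sequence
  composition.

The default scenario emulates the structure of a five-pool field study:
one native-range pool and four invasive-range pools, planted viruses of
all three genome classes spanning widespread/high-abundance to
single-pool/low-depth to sub-threshold trace, a host COI marker for the
strand baseline, COI species contamination in two pools, and reciprocal
barcode switching between the two libraries sequenced together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .homology import HitRecord
from .quantify import DETECTION_THRESHOLD
from .strand import GENOME_CLASSES, MIN_DEPTH

__all__ = [
    "DEFAULT_SEED",
    "VirusModel",
    "SampleModel",
    "Scenario",
    "SyntheticDataset",
    "generate_genomes",
    "generate_host_contigs",
    "simulate_counts",
    "simulate_coi",
    "simulate_hits",
    "generate_dataset",
    "default_scenario",
]

DEFAULT_SEED = 20180329

_STOPS = ("TAA", "TAG", "TGA")
_HOST_COI_REF = "host_COI"


@dataclass(frozen=True)
class VirusModel:
    """A planted virus: genome organisation, polarity, and abundances.

    ``per_sample_abundance`` is in reads per kb per million non-rRNA
    reads — the same unit the quantification stage reports — so planted
    values round-trip directly through normalization.
    ``identity_to_known`` is the percent amino-acid identity of the
    polymerase to the closest published virus, driving the novelty call.
    """

    name: str
    genome_class: str
    segment_lengths: tuple[int, ...]
    polarity_fraction: float
    per_sample_abundance: Mapping[str, float]
    identity_to_known: float = 75.0

    def __post_init__(self) -> None:
        if self.genome_class not in GENOME_CLASSES:
            raise ValueError(f"unknown genome class {self.genome_class!r}")
        if not self.segment_lengths:
            raise ValueError("segment_lengths must be non-empty")
        if any(l < 500 for l in self.segment_lengths):
            raise ValueError("segment lengths must be >= 500 nt")
        if not 0 < self.polarity_fraction <= 1:
            raise ValueError("polarity_fraction must be in (0, 1]")
        if any(a < 0 for a in self.per_sample_abundance.values()):
            raise ValueError("abundances must be non-negative")

    @property
    def segment_ids(self) -> tuple[str, ...]:
        return tuple(f"{self.name}|seg{i + 1}" for i in range(len(self.segment_lengths)))

    @property
    def total_length_nt(self) -> int:
        return sum(self.segment_lengths)


@dataclass(frozen=True)
class SampleModel:
    """One sequencing pool: library size, rRNA content, and co-sequenced
    libraries from which barcode-switched reads leak in."""

    sample_id: str
    total_reads: int
    rrna_fraction: float
    contamination_sources: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.rrna_fraction < 1:
            raise ValueError("rrna_fraction must be in [0, 1)")
        if self.non_rrna_total <= 0:
            raise ValueError("non-rRNA total must be positive")
        for src, rate in self.contamination_sources:
            if not 0 <= rate <= 0.05:
                raise ValueError(f"switch rate {rate} outside [0, 0.05] ({src})")

    @property
    def non_rrna_total(self) -> int:
        return int(round(self.total_reads * (1.0 - self.rrna_fraction)))


@dataclass
class Scenario:
    """Declarative description of one synthetic study."""

    viruses: list[VirusModel]
    samples: list[SampleModel]
    n_host_contigs: int = 20
    decoy_fraction: float = 0.5
    host_polarity: float = 0.99
    host_coi_depth: int = 50_000
    coi_species_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    coi_depth: int = 10_000
    focal_species: str = "D. suzukii"
    eve_elements: list[str] = field(default_factory=list)
    seed: int = DEFAULT_SEED


@dataclass
class SyntheticDataset:
    contigs: list[SeqRecord]
    hits: list[HitRecord]
    counts: pd.DataFrame
    coi: pd.DataFrame
    samples: pd.DataFrame
    detection: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every stage input plus the truth JSON; returns the paths."""
        from Bio import SeqIO

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs": outdir / "contigs.fasta",
            "hits": outdir / "hits.tsv",
            "counts": outdir / "counts.tsv",
            "coi": outdir / "coi.tsv",
            "samples": outdir / "samples.tsv",
            "detection": outdir / "detection.tsv",
            "genome_classes": outdir / "genome_classes.tsv",
            "truth": outdir / "truth.json",
        }
        SeqIO.write(self.contigs, paths["contigs"], "fasta")
        pd.DataFrame(
            [
                {
                    "qseqid": h.qseqid,
                    "sseqid": h.sseqid,
                    "pident": h.pident,
                    "length": h.length,
                    "evalue": h.evalue,
                    "bitscore": h.bitscore,
                    "subject_category": h.subject_category,
                }
                for h in self.hits
            ]
        ).to_csv(paths["hits"], sep="\t", index=False)
        self.counts.to_csv(paths["counts"], sep="\t", index=False)
        self.coi.to_csv(paths["coi"], sep="\t", index=False)
        self.samples.to_csv(paths["samples"], sep="\t", index=False)
        self.detection.to_csv(paths["detection"], sep="\t", index=False)
        pd.DataFrame(
            [
                {"virus": v["name"], "genome_class": v["genome_class"]}
                for v in self.truth["viruses"]
            ]
        ).to_csv(paths["genome_classes"], sep="\t", index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        return paths


def _random_orf_codons(rng: np.random.Generator, n_codons: int) -> str:
    """A stop-free random codon string of n_codons codons."""
    bases = "ACGT"
    out = []
    while len(out) < n_codons:
        codon = "".join(rng.choice(list(bases), size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_genomes(models: Sequence[VirusModel], seed: int) -> list[SeqRecord]:
    """Generate one contig per virus segment, deterministic for a seed.

    Each segment is random nucleotide sequence with a planted stop-free
    codon run of >= 150 codons in frame +1, so it passes the default ORF
    retention gate.
    """
    rng = np.random.default_rng(seed)
    records = []
    for model in models:
        for seg_id, length in zip(model.segment_ids, model.segment_lengths):
            seq = list(_random_sequence(rng, length))
            n_codons = length // 3
            orf_codons = min(n_codons, max(160, int(0.7 * n_codons)))
            max_start_codon = n_codons - orf_codons
            start = 3 * int(rng.integers(0, max_start_codon + 1))
            orf = _random_orf_codons(rng, orf_codons)
            seq[start : start + len(orf)] = orf
            records.append(
                SeqRecord(Seq("".join(seq)), id=seg_id, description=f"planted {model.genome_class}")
            )
    return records


def generate_host_contigs(
    n: int, seed: int, length_range: tuple[int, int] = (600, 3000)
) -> list[SeqRecord]:
    """Random host background contigs (no planted ORF guarantee)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        records.append(
            SeqRecord(
                Seq(_random_sequence(rng, length)),
                id=f"host_contig_{i + 1}",
                description="host background",
            )
        )
    return records


def simulate_counts(
    models: Sequence[VirusModel],
    samples: Sequence[SampleModel],
    seed: int,
    host_polarity: float = 0.99,
    host_coi_depth: int = 50_000,
) -> pd.DataFrame:
    """Stranded per-(sample, reference) read counts.

    Per segment and sample the total count is
    Poisson(abundance × length_kb × non_rrna_total / 1e6), split into
    strands by Binomial(total, polarity_fraction).  Barcode switching
    then copies Binomial(source_count, switch_rate) reads per strand
    from each contamination source into the receiving sample.  A host
    COI reference with mean depth ``host_coi_depth`` is included for the
    strand baseline; set it to 0 to omit.
    """
    rng = np.random.default_rng(seed)
    base: dict[str, dict[str, tuple[int, int]]] = {}
    for sample in samples:
        per_ref: dict[str, tuple[int, int]] = {}
        millions = sample.non_rrna_total / 1e6
        for model in models:
            abundance = float(model.per_sample_abundance.get(sample.sample_id, 0.0))
            for seg_id, length in zip(model.segment_ids, model.segment_lengths):
                mean = abundance * (length / 1000.0) * millions
                total = int(rng.poisson(mean)) if mean > 0 else 0
                pos = int(rng.binomial(total, model.polarity_fraction)) if total else 0
                per_ref[seg_id] = (pos, total - pos)
        if host_coi_depth > 0:
            total = int(rng.poisson(host_coi_depth))
            pos = int(rng.binomial(total, host_polarity)) if total else 0
            per_ref[_HOST_COI_REF] = (pos, total - pos)
        base[sample.sample_id] = per_ref

    final = {sid: dict(refs) for sid, refs in base.items()}
    for sample in samples:
        for source_id, rate in sample.contamination_sources:
            for ref, (src_pos, src_neg) in base.get(source_id, {}).items():
                add_pos = int(rng.binomial(src_pos, rate)) if src_pos else 0
                add_neg = int(rng.binomial(src_neg, rate)) if src_neg else 0
                if add_pos or add_neg:
                    pos, neg = final[sample.sample_id].get(ref, (0, 0))
                    final[sample.sample_id][ref] = (pos + add_pos, neg + add_neg)

    rows = []
    for sample in samples:
        for ref in sorted(final[sample.sample_id]):
            pos, neg = final[sample.sample_id][ref]
            if pos == 0 and neg == 0:
                continue
            rows.append({"sample": sample.sample_id, "reference": ref, "strand": "+", "count": pos})
            rows.append({"sample": sample.sample_id, "reference": ref, "strand": "-", "count": neg})
    return pd.DataFrame(rows, columns=["sample", "reference", "strand", "count"])


def simulate_coi(
    samples: Sequence[SampleModel],
    species_fractions: Mapping[str, Mapping[str, float]],
    focal_species: str,
    depth: int,
    seed: int,
    positive_fraction: float = 0.99,
) -> pd.DataFrame:
    """Multinomial COI species counts per sample, split by strand.

    ``species_fractions[sample]`` gives contaminant species fractions;
    the focal species receives the remainder.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample in samples:
        contam = dict(species_fractions.get(sample.sample_id, {}))
        focal_frac = 1.0 - sum(contam.values())
        if focal_frac <= 0:
            raise ValueError(f"contaminant fractions exceed 1 in {sample.sample_id}")
        species = [focal_species] + sorted(contam)
        probs = [focal_frac] + [contam[s] for s in sorted(contam)]
        counts = rng.multinomial(depth, probs)
        for sp, n in zip(species, counts):
            if n == 0:
                continue
            pos = int(rng.binomial(n, positive_fraction))
            rows.append({"sample": sample.sample_id, "species": sp, "strand": "+", "count": pos})
            rows.append({"sample": sample.sample_id, "species": sp, "strand": "-", "count": int(n) - pos})
    return pd.DataFrame(rows, columns=["sample", "species", "strand", "count"])


def simulate_hits(
    contigs: Sequence[SeqRecord],
    models: Sequence[VirusModel],
    decoy_fraction: float,
    seed: int,
) -> list[HitRecord]:
    """A DIAMOND-style tabular result for the planted contigs.

    Every viral contig receives a virus-category best hit (e-value well
    under 0.01) whose percent identity equals the model's
    ``identity_to_known``; the first viral contig additionally gets an
    equal-e-value, lower-bitscore second hit to exercise tie-breaking.
    A ``decoy_fraction`` of host contigs receive a strong non-viral
    (dipteran) hit — the first of those also carries a weaker viral hit,
    so only-top-hit semantics are exercised — and the rest receive no
    hit at all.
    """
    if not 0 <= decoy_fraction <= 1:
        raise ValueError("decoy_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_name = {m.name: m for m in models}
    hits: list[HitRecord] = []
    first_viral = True
    host_ids = []
    for rec in contigs:
        name = rec.id.split("|")[0]
        model = by_name.get(name)
        if model is None:
            host_ids.append(rec.id)
            continue
        evalue = 10.0 ** float(rng.uniform(-80, -20))
        bitscore = float(np.round(rng.uniform(150, 900), 1))
        hits.append(
            HitRecord(
                qseqid=rec.id,
                sseqid=f"rel_{name}",
                pident=float(model.identity_to_known),
                length=max(50, len(rec.seq) // 3 // 2),
                evalue=evalue,
                bitscore=bitscore,
                subject_category="virus",
            )
        )
        if first_viral:
            hits.append(
                HitRecord(
                    qseqid=rec.id,
                    sseqid=f"alt_rel_{name}",
                    pident=float(model.identity_to_known) - 5.0,
                    length=max(50, len(rec.seq) // 3 // 3),
                    evalue=evalue,
                    bitscore=bitscore - 30.0,
                    subject_category="virus",
                )
            )
            first_viral = False
    n_decoy = int(round(decoy_fraction * len(host_ids)))
    for i, cid in enumerate(host_ids):
        if i >= n_decoy:
            continue  # no hit at all
        evalue = 10.0 ** float(rng.uniform(-60, -10))
        hits.append(
            HitRecord(
                qseqid=cid,
                sseqid=f"dmel_protein_{i + 1}",
                pident=float(np.round(rng.uniform(85, 99), 1)),
                length=120,
                evalue=evalue,
                bitscore=float(np.round(rng.uniform(100, 600), 1)),
                subject_category="dipteran",
            )
        )
        if i == 0:
            # weaker secondary viral hit: must not flip the classification
            hits.append(
                HitRecord(
                    qseqid=cid,
                    sseqid="spurious_viral_subject",
                    pident=30.0,
                    length=60,
                    evalue=max(evalue * 1e4, 1e-6),
                    bitscore=45.0,
                    subject_category="virus",
                )
            )
    return hits


def _expected_truth(scenario: Scenario, threshold: float, min_depth: int) -> dict:
    """Ground-truth expectations derived from planted parameters alone."""
    non_rrna = {s.sample_id: s.non_rrna_total for s in scenario.samples}
    viruses = []
    detections: dict[str, list[str]] = {s.sample_id: [] for s in scenario.samples}
    for model in scenario.viruses:
        expected_total = sum(
            model.per_sample_abundance.get(sid, 0.0)
            * (model.total_length_nt / 1000.0)
            * (non_rrna[sid] / 1e6)
            for sid in non_rrna
        )
        if expected_total < min_depth:
            verdict = "inconclusive_low_depth"
        elif model.genome_class == "plus_ss_rna":
            verdict = "replication_supported" if model.polarity_fraction < 1 else "not_supported"
        elif model.genome_class == "minus_ss_rna":
            verdict = "replication_supported" if model.polarity_fraction > 0 else "not_supported"
        else:
            verdict = (
                "replication_supported" if 0 < model.polarity_fraction < 1 else "not_supported"
            )
        for sid in non_rrna:
            if model.per_sample_abundance.get(sid, 0.0) >= threshold:
                detections[sid].append(model.name)
        viruses.append(
            {
                "name": model.name,
                "genome_class": model.genome_class,
                "segments": dict(zip(model.segment_ids, model.segment_lengths)),
                "total_length_nt": model.total_length_nt,
                "polarity_fraction": model.polarity_fraction,
                "identity_to_known": model.identity_to_known,
                "novelty": "known" if model.identity_to_known > 95 else "novel",
                "per_sample_abundance": dict(model.per_sample_abundance),
                "expected_total_reads": expected_total,
                "expected_verdict": verdict,
            }
        )
    return {
        "seed": scenario.seed,
        "detection_threshold": threshold,
        "min_depth": min_depth,
        "focal_species": scenario.focal_species,
        "host_polarity": scenario.host_polarity,
        "coi_species_fractions": {k: dict(v) for k, v in scenario.coi_species_fractions.items()},
        "viruses": viruses,
        "expected_detections": {k: sorted(v) for k, v in detections.items()},
        "viral_contigs": sorted(
            seg for m in scenario.viruses for seg in m.segment_ids
        ),
        "eve_elements": sorted(scenario.eve_elements),
    }


def generate_dataset(
    scenario: Scenario,
    seed: int | None = None,
    detection_threshold: float = DETECTION_THRESHOLD,
    min_depth: int = MIN_DEPTH,
) -> SyntheticDataset:
    """Generate the full dataset (all stage inputs + truth) for a scenario.

    ``seed`` overrides the scenario's seed; sub-stages derive independent
    child seeds so the dataset is deterministic end to end.
    """
    seed = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_genomes, s_host, s_counts, s_coi, s_hits = [
        int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(5)
    ]
    viral_contigs = generate_genomes(scenario.viruses, s_genomes)
    host_contigs = generate_host_contigs(scenario.n_host_contigs, s_host)
    contigs = viral_contigs + host_contigs
    counts = simulate_counts(
        scenario.viruses,
        scenario.samples,
        s_counts,
        host_polarity=scenario.host_polarity,
        host_coi_depth=scenario.host_coi_depth,
    )
    coi = simulate_coi(
        scenario.samples,
        scenario.coi_species_fractions,
        scenario.focal_species,
        scenario.coi_depth,
        s_coi,
    )
    hits = simulate_hits(contigs, scenario.viruses, scenario.decoy_fraction, s_hits)
    truth = _expected_truth(scenario, detection_threshold, min_depth)
    truth["host_contigs"] = [r.id for r in host_contigs]
    det_rows = [
        {
            "virus": v["name"],
            "rna_detected": any(
                v["name"] in names for names in truth["expected_detections"].values()
            ),
            "dna_detected": False,
        }
        for v in truth["viruses"]
    ]
    det_rows += [
        {"virus": name, "rna_detected": True, "dna_detected": True}
        for name in scenario.eve_elements
    ]
    detection = pd.DataFrame(det_rows, columns=["virus", "rna_detected", "dna_detected"])
    samples_df = pd.DataFrame(
        [
            {
                "sample": s.sample_id,
                "total_reads": s.total_reads,
                "rrna_fraction": s.rrna_fraction,
            }
            for s in scenario.samples
        ]
    )
    return SyntheticDataset(contigs, hits, counts, coi, samples_df, detection, truth)


def default_scenario(seed: int = DEFAULT_SEED) -> Scenario:
    """The default five-pool study used by the end-to-end tests.

    Planted abundances are either comfortably above the 0.5 reads/kb/
    million detection threshold (>= 4, i.e. >= 8x) or a trace at 0.1x,
    so expected detection status is unambiguous under Poisson sampling;
    pooled read depths are either well past or far below the 2000-read
    verdict floor for the same reason.  Polarity fractions follow the
    class-typical ranges seen in strand-specific resequencing: +ssRNA
    near 1, −ssRNA 0.15–0.49, dsRNA mid-range.
    """
    samples = [
        SampleModel("Japan2016", 6_250_000, 0.20, (("UK2016", 0.0002),)),
        SampleModel("France2013", 5_000_000, 0.04),
        SampleModel("UK2014", 6_000_000, 0.25),
        SampleModel("UK2015", 7_000_000, 0.30),
        SampleModel("UK2016", 5_500_000, 0.18, (("Japan2016", 0.0002),)),
    ]
    all_samples = {s.sample_id: 120.0 for s in samples}
    viruses = [
        # widespread, bipartite, high depth in every pool
        VirusModel("sobemo_like", "plus_ss_rna", (2000, 1000), 0.97, all_samples, 90.9),
        # invasive-range only
        VirusModel(
            "hepe_virga_like",
            "plus_ss_rna",
            (12000,),
            0.95,
            {"France2013": 20.0, "UK2014": 20.0, "UK2015": 20.0, "UK2016": 20.0},
            62.0,
        ),
        # native-range only, negative-sense
        VirusModel("chu_like", "minus_ss_rna", (10500,), 0.30, {"Japan2016": 60.0}, 55.0),
        VirusModel("phasma_like", "minus_ss_rna", (7300,), 0.45, {"UK2015": 70.0}, 70.0),
        # segmented dsRNA at verdict-grade depth
        VirusModel(
            "reo_like", "ds_rna", (4200, 3800, 3000), 0.60, {"UK2014": 50.0}, 58.0
        ),
        # detected but below the 2000-read verdict floor
        VirusModel("toti_like", "ds_rna", (1600,), 0.70, {"UK2015": 15.0}, 65.0),
        VirusModel("noda_like", "plus_ss_rna", (1600,), 1.0, {"Japan2016": 4.0}, 68.0),
        # trace planted at 0.1x the detection threshold: must stay absent
        VirusModel(
            "trace_tombus_like",
            "plus_ss_rna",
            (3000,),
            0.95,
            {"UK2014": 0.05, "UK2016": 0.05},
            72.0,
        ),
        # near-identical to a published virus: novelty call must be 'known'
        VirusModel(
            "known_picorna_like", "plus_ss_rna", (9000,), 0.92, {"UK2016": 60.0}, 99.2
        ),
    ]
    coi = {
        "Japan2016": {"D. immigrans": 0.013},
        "UK2015": {"D. melanogaster": 0.0074},
    }
    return Scenario(
        viruses=viruses,
        samples=samples,
        coi_species_fractions=coi,
        eve_elements=["integrated_rhabdo_element"],
        seed=seed,
    )
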