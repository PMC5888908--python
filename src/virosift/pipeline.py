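"""End-to-end orchestration of the post-assembly virome pipeline.

Stages run in discovery order — contig triage, homology classification,
abundance quantification, strand-polarity replication inference,
contamination/EVE diagnostics — each gated on the presence of its input
files, so a partial configuration degrades gracefully: omitting the
counts table, for instance, skips quantification and the strand stage
but leaves triage untouched.  Every applied threshold is logged and
echoed into the report so a run is self-documenting, and outputs are
deterministic for a fixed configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import diagnostics as dx
from . import homology, orfs, quantify, strand

logger = logging.getLogger("virosift")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, parameters, and output location for one pipeline run.

    Any input path left as None disables the stages that need it.
    Parameter defaults are the study-standard values: 500 nt minimum
    contig length, 150-codon ORF retention, e-value 0.01, >95% novelty
    identity, 0.5 reads/kb/million detection threshold, 95% CIs, and a
    2000-read verdict floor.
    """

    out_dir: str = "virosift_out"
    contigs: str | None = None
    hits: str | None = None
    category_map: str | None = None
    counts: str | None = None
    samples: str | None = None
    coi: str | None = None
    detection: str | None = None
    genome_classes: str | None = None

    min_length_nt: int = 500
    min_orf_codons: int = 150
    evalue_threshold: float = 0.01
    novelty_threshold: float = 95.0
    detection_threshold: float = quantify.DETECTION_THRESHOLD
    ci_level: float = 0.95
    min_depth: int = strand.MIN_DEPTH
    clustering_distance: str = "euclidean"
    clustering_linkage: str = "complete"
    floor_decades: float = 1.0
    contam_threshold: float = 0.005
    crossmap_flag_threshold: float = 0.05
    barcode_ratio: float = 100.0
    focal_species: str = "D. suzukii"
    host_references: tuple[str, ...] = ("host_COI",)
    co_sequenced: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "co_sequenced" in raw:
            raw["co_sequenced"] = tuple(tuple(p) for p in raw["co_sequenced"])
        if "host_references" in raw:
            raw["host_references"] = tuple(raw["host_references"])
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.detection_threshold:
            raise ValueError("detection_threshold must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        for name in ("contigs", "hits", "category_map", "counts", "samples", "coi", "detection", "genome_classes"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input {name!r} not found: {path}")


def _virus_of_reference(references, host_references) -> dict[str, str]:
    """Map segment references to viruses by the `virus|segN` convention;
    references without a segment separator map to themselves."""
    out = {}
    for ref in references:
        if ref in host_references:
            continue
        out[ref] = ref.split("|")[0]
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; return the report.

    The report (also written to ``<out_dir>/report.json``) summarizes
    candidates, per-sample detections, strand verdicts, diagnostics, and
    the applied parameters.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages_run": [],
    }

    retained_ids: set[str] | None = None
    contig_lengths: dict[str, int] = {}

    # --- contig triage -------------------------------------------------
    if config.contigs is not None:
        logger.info(
            "triage: min_length_nt=%d min_orf_codons=%d",
            config.min_length_nt,
            config.min_orf_codons,
        )
        records = list(SeqIO.parse(config.contigs, "fasta"))
        results = []
        orf_rows = []
        for rec in records:
            seq = str(rec.seq)
            contig_lengths[rec.id] = len(seq)
            res = orfs.triage_contig(
                rec.id, seq, config.min_length_nt, config.min_orf_codons
            )
            results.append(res)
            if res.retained:
                for orf in orfs.find_orfs(seq, min_codons=1, contig_id=rec.id):
                    orf_rows.append(
                        {
                            "contig_id": rec.id,
                            "frame": orf.frame,
                            "start": orf.start,
                            "end": orf.end,
                            "length_codons": orf.length_codons,
                        }
                    )
        retained_ids = {r.contig_id for r in results if r.retained}
        pd.DataFrame(
            [
                {
                    "contig_id": r.contig_id,
                    "length_nt": r.length_nt,
                    "longest_orf_codons": r.longest_orf_codons,
                    "retained": r.retained,
                }
                for r in results
            ]
        ).to_csv(out / "triage.tsv", sep="\t", index=False)
        pd.DataFrame(orf_rows).to_csv(out / "orfs.tsv", sep="\t", index=False)
        report["triage"] = {
            "n_contigs": len(results),
            "n_retained": len(retained_ids),
            "retained": sorted(retained_ids),
        }
        report["stages_run"].append("triage")
    else:
        logger.info("triage skipped: no contigs input")

    # --- homology classification --------------------------------------
    if config.hits is not None:
        logger.info("classify: evalue_threshold=%g", config.evalue_threshold)
        hit_records = homology.read_hit_table(config.hits, config.category_map)
        if retained_ids is not None:
            hit_records = [h for h in hit_records if h.qseqid in retained_ids]
        best = homology.best_hits_by_contig(hit_records, config.evalue_threshold)
        viral = homology.classify_viral(best)
        identity = {}
        for qid in viral:
            taxon = best[qid].sseqid
            identity[taxon] = max(identity.get(taxon, 0.0), best[qid].pident)
        candidates = homology.group_candidates(
            best,
            contig_lengths,
            identity_to_known=identity,
            novelty_threshold=config.novelty_threshold,
        )
        homology.write_candidate_table(candidates, out / "candidates.tsv")
        report["classification"] = {
            "n_viral_contigs": len(viral),
            "viral_contigs": sorted(viral),
            "candidates": [
                {
                    "name": c.name,
                    "taxon": c.taxon_group,
                    "contigs": c.contig_ids,
                    "longest_contig_kb": round(c.longest_contig_kb, 3),
                    "novelty": c.novelty,
                }
                for c in candidates
            ],
        }
        report["stages_run"].append("classify")
    else:
        logger.info("classify skipped: no hits input")

    # --- quantification ------------------------------------------------
    normalized_map: dict[tuple[str, str], float] = {}
    counts_df = None
    if config.counts is not None and config.samples is not None:
        logger.info("quantify: detection_threshold=%g", config.detection_threshold)
        counts_df = quantify.read_counts_table(config.counts)
        samples_df = quantify.read_samples_table(config.samples)
        non_rrna = dict(zip(samples_df["sample"], samples_df["non_rrna_total"]))
        ref_to_virus = _virus_of_reference(
            counts_df["reference"].unique(), set(config.host_references)
        )
        counts_map = quantify.sum_counts_by_virus(counts_df, ref_to_virus)
        seg_lengths: dict[str, int] = {}
        if config.contigs is not None:
            for ref, virus in ref_to_virus.items():
                if ref in contig_lengths:
                    seg_lengths[virus] = seg_lengths.get(virus, 0) + contig_lengths[ref]
        lengths = {
            v: seg_lengths[v]
            for v in {virus for virus, _ in counts_map}
            if v in seg_lengths
        }
        dropped = {virus for virus, _ in counts_map} - set(lengths)
        if dropped:
            logger.warning(
                "no contig lengths for %s; excluded from quantification",
                sorted(dropped),
            )
            counts_map = {
                (v, s): n for (v, s), n in counts_map.items() if v in lengths
            }
        cells = quantify.abundance_cells(
            counts_map, lengths, non_rrna, config.detection_threshold
        )
        pd.DataFrame(
            [
                {
                    "virus": c.virus,
                    "sample": c.sample,
                    "raw_count": c.raw_count,
                    "normalized": round(c.normalized, 6),
                    "detected": c.detected,
                }
                for c in cells
            ]
        ).to_csv(out / "abundance.tsv", sep="\t", index=False)
        matrix = quantify.build_matrix(
            [c for c in cells],
            distance=config.clustering_distance,
            method=config.clustering_linkage,
            floor_decades=config.floor_decades,
        )
        matrix.ordered.to_csv(out / "abundance_matrix.tsv", sep="\t")
        normalized_map = {(c.virus, c.sample): c.normalized for c in cells}
        detections = {
            sample: sorted(
                c.virus for c in cells if c.sample == sample and c.detected
            )
            for sample in sorted({c.sample for c in cells})
        }
        report["quantification"] = {
            "detections": detections,
            "row_order": matrix.row_order,
            "col_order": matrix.col_order,
        }
        report["stages_run"].append("quantify")
    else:
        logger.info("quantify skipped: counts and samples inputs required")

    # --- strand / replication -----------------------------------------
    if counts_df is not None:
        logger.info("strand: ci_level=%g min_depth=%d", config.ci_level, config.min_depth)
        ref_to_virus = _virus_of_reference(
            counts_df["reference"].unique(), set(config.host_references)
        )
        refs_of_virus: dict[str, list[str]] = {}
        for ref, virus in ref_to_virus.items():
            refs_of_virus.setdefault(virus, []).append(ref)
        classes: dict[str, str] = {}
        if config.genome_classes is not None:
            gc = pd.read_csv(config.genome_classes, sep="\t")
            classes = dict(zip(gc["virus"], gc["genome_class"]))
        summaries = strand.summarize_strands(
            counts_df, refs_of_virus, classes, config.ci_level, config.min_depth
        )
        baseline = strand.host_baseline(
            counts_df, config.host_references, config.ci_level
        )
        strand.write_strand_table(
            summaries + ([baseline] if baseline else []), out / "strand.tsv"
        )
        report["strand"] = {
            "verdicts": {s.virus: s.verdict for s in summaries},
            "host_baseline": (
                {
                    "p_hat": baseline.p_hat,
                    "ci_low": baseline.ci_low,
                    "ci_high": baseline.ci_high,
                    "n_total": baseline.n_total,
                }
                if baseline
                else None
            ),
        }
        report["stages_run"].append("strand")

    # --- diagnostics ----------------------------------------------------
    diag: dict = {}
    if config.coi is not None:
        coi_df = pd.read_csv(config.coi, sep="\t")
        profiles = {}
        for sample, grp in coi_df.groupby("sample"):
            counts = grp.groupby("species")["count"].sum().to_dict()
            prof = dx.coi_profile(
                counts, config.focal_species, config.contam_threshold, str(sample)
            )
            profiles[str(sample)] = {
                "fractions": {k: round(v, 6) for k, v in prof.species_fractions.items()},
                "contaminants": prof.contaminants,
            }
        diag["coi"] = profiles
    if config.detection is not None:
        det = pd.read_csv(config.detection, sep="\t")
        calls = [
            dx.eve_classify(bool(r.rna_detected), bool(r.dna_detected), str(r.virus))
            for r in det.itertuples()
        ]
        diag["eve_calls"] = {c.virus: c.call for c in calls}
    if normalized_map and config.co_sequenced:
        diag["barcode_switch_notes"] = dx.barcode_switch_notes(
            normalized_map,
            config.co_sequenced,
            threshold=config.detection_threshold,
            ratio=config.barcode_ratio,
        )
    if diag:
        report["diagnostics"] = diag
        report["stages_run"].append("diagnose")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
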