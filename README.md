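# virosift

Post-assembly triage for metatranscriptomic virus discovery.

Shotgun sequencing of total RNA from pooled field-collected insects (here:
the invasive fruit pest *Drosophila suzukii*) yields a de novo assembly in
which novel RNA viruses hide among tens of thousands of host and microbial
contigs. `virosift` implements the computations that turn that assembly —
plus a tabular homology search and stranded read-mapping summaries — into a
curated virome:

1. **ORF-based contig triage** — contigs shorter than 500 nt are excluded;
   the remainder are scanned in all six reading frames for maximal
   stop-free codon runs (stop-to-stop convention, terminal runs included)
   and retained only if the longest ORF reaches 150 codons. Annotation
   rules for genome maps (≥100 aa, sub-200-aa fully nested ORFs
   disregarded, similarity rescue) are included.
2. **Best-hit viral classification** — a single top hit per contig from a
   DIAMOND/BLAST `outfmt 6` table (e-value ≤ 0.01; ties by bitscore, then
   subject id); a contig is viral iff its top hit is a virus. Candidates
   grouped by best-hit taxon are *known* when polymerase amino-acid
   identity to a published virus strictly exceeds 95%, *novel* otherwise.
3. **Abundance quantification** — counts are normalized to reads per kb of
   target per million non-rRNA library reads,
   `count · 10⁹ / (length_nt · non_rrna_total)`, with an inclusive
   detection threshold of 0.5 and a row/column-clustered log₁₀ abundance
   matrix (complete linkage, Euclidean distance).
4. **Strand-polarity replication inference** — the positive-sense read
   fraction p̂ = k/n with a binomial 95% CI on the logit scale,
   `logit(p̂) ± z·√(1/k + 1/(n−k))` (Clopper–Pearson at the k ∈ {0, n}
   boundaries). Replication is supported when the CI excludes the
   no-replication null (p = 1 for +ssRNA, p = 0 for −ssRNA; both strands
   for dsRNA) at ≥ 2000 mapped reads; shallower summaries are
   inconclusive. A host COI gene provides the transcriptional baseline.
5. **Contamination / EVE diagnostics** — directional cross-mapping
   fractions between close relatives, COI-based species-contamination
   profiles, a barcode-switching heuristic for marginal detections in
   co-sequenced libraries, and the RNA-vs-DNA-fraction rule: an RNA virus
   detectable in nuclear DNA is a putative endogenous viral element (EVE),
   not an active infection.

A synthetic virome generator plants viruses of known genome class,
abundance, and strand polarity into multi-sample datasets with host
background, rRNA fractions, COI contamination, and barcode switching —
with a machine-readable truth table — so the entire chain is testable
without any external data. The curated table of the 18 published novel
*D. suzukii* viruses ships as a package fixture.

## Worked example

Generate the default five-pool synthetic study and run every stage:

```sh
virosift simulate --out data
virosift run-all --config config.yaml   # config lists the files in data/
```

`out/strand.tsv` then contains, among others:

```
virus         genome_class  n_pos  n_total  p_hat     ci_low    ci_high   verdict
chu_like      minus_ss_rna    983     3180  0.309119  0.293292  0.325408  replication_supported
sobemo_like   plus_ss_rna    8391     8647  0.970394  0.966605  0.973765  replication_supported
noda_like     plus_ss_rna      33       33  1.0       0.894237  1.0       inconclusive_low_depth
host                       247491   249989  0.990008  0.989610  0.990390  baseline
```

The planted negative-sense virus shows ~31% positive reads — far from the
p = 0 expected without replication, so replication is supported; the pure
positive-sense virus at 33 reads stays inconclusive (depth < 2000). In
`out/abundance.tsv` the same virus is detected only in its planted pool
(e.g. `chu_like Japan2016 3180 reads → 60.57 reads/kb/million, detected`),
and `out/report.json` reproduces the planted truth exactly: detection
flags, viral contig set, novelty calls, COI contaminants, and the one
planted EVE.

`virosift fixtures` prints the curated-table tallies:

```
records        18
plus_ss_rna    10
minus_ss_rna    5
ds_rna          3
```

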