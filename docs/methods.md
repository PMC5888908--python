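# Methods

## ORF model

An ORF is a maximal stop-codon-free codon run in one of the six reading
frames (standard genetic code, table 1). The default is the
**stop-to-stop** convention rather than AUG-anchored, because assembled
viral contigs are frequently partial: 5′-truncated polymerase fragments
would otherwise be lost. For the same reason terminal runs without a
bounding stop codon count as ORFs. An AUG-anchored mode
(`find_orfs(..., require_start=True)`, anchoring at the first AUG of each
run) is provided for callers that want conventional genes. Codons
containing `N` translate to `X` and never terminate a run — a codon that
*could* be a stop (`TAN`) is treated as non-stop, which errs toward
keeping sequence in a discovery setting. Coordinates are 0-based
half-open on the forward strand; frames −1..−3 are counted from the first
position of the reverse complement. The concatenated translation of a
retained contig joins ORFs by frame (+1, +2, +3, −1, −2, −3) then start
coordinate; the order only affects the downstream search input, never
retention.

Triage gates: minimum contig length 500 nt (applied before ORF analysis)
and minimum longest-ORF length 150 codons. Annotation gates: ≥100 aa,
with ORFs of <200 aa fully nested (forward-strand interval containment)
inside a larger ORF disregarded, and similarity evidence rescuing either
failure. Nesting is checked against ORFs of the same contig only.

## Homology triage

One top hit per contig: smallest e-value among hits with e-value ≤ 0.01
(inclusive). The tie-break — larger bitscore, then lexicographically
smaller subject id — is a determinism choice; tabular search output
carries no further ranking signal. A contig is viral iff its top hit is
in the `virus` subject category; a lower-ranked viral hit never
classifies. Subject categories are supplied as a separate two-column map
because database taxonomy drifts between releases.

"Amino-acid similarity" for the novelty rule is implemented as percent
identity over mutually non-gapped aligned columns (gap columns excluded
from the denominator); a substitution-matrix similarity mode is
deliberately not the default, as identity is reproducible without fixing
a matrix. The novelty threshold is strict: a candidate is *known* only
when identity exceeds 95%; 95.0% exactly remains novel.

## Quantification

Normalized abundance is reads per kb of target per million non-rRNA
reads. The non-rRNA denominator is taken from the samples table as
given, not recomputed from mappings, and is not corrected for
virus-mapped reads. Multi-segment viruses are quantified by summing
counts over segments against the summed segment length. The detection
threshold (0.5, the published choice) is applied **inclusively**; the
source material does not state inclusivity, and a boundary value is
treated as evidence rather than noise.

For the clustered matrix, detected cells are log₁₀-transformed;
undetected cells are exported as missing but imputed, for distance
computation only, at `floor_decades` (default 1.0) below the smallest
detected value — a defined floor keeps fully undetected rows clustered
together without inventing a finite log of zero. Clustering is
agglomerative with Euclidean distance and complete linkage (the common
heatmap default), both configurable; leaf orders follow the standard
dendrogram convention (lower-index child first).

## Strand-polarity replication inference

With strand-specific libraries, reads of the sense opposite to the
encapsidated genome evidence a replication intermediate. The binomial CI
for the positive-sense fraction uses the Wald interval on the logit
scale, matching a logit-parameterized binomial GLM: SE =
√(1/k + 1/(n−k)), back-transformed through the inverse logit. At k = 0
or k = n the logit SE is undefined, so the exact Clopper–Pearson
interval is substituted; no other boundary correction is applied.

Verdict rules: the no-replication null is p = 1 for +ssRNA and p = 0 for
−ssRNA; replication is supported when the CI excludes the null at
adequate depth. Below `min_depth` (default 2000 reads — the depth at
which pure-positive +ssRNA summaries stop being attributable to sampling
alone) every verdict is `inconclusive_low_depth`. dsRNA viruses package
both strands and no published null exists; the rule used here — both
strands observed at adequate depth — is an extrapolation of this
package, reported with the CI for descriptive use. Counts are pooled
over samples and segments per virus; the host COI gene is summarized
identically as a baseline.

## Diagnostics

Cross-mapping is quantified as the fraction of reads mapped to reference
A that also align to reference B — directional, so both orientations are
reported; any co-alignment counts (no preferential-region analysis).
The flag threshold (0.05) and the COI contaminant threshold (0.005,
inclusive) are package defaults chosen to flag fraction magnitudes that
in practice warrant review; the source analyses report raw fractions and
reason qualitatively. The barcode-switching note is a heuristic:
a virus detected within 4× of the detection threshold in one library
while a co-sequenced library carries it at ≥100× that level is noted,
never re-called. The EVE rule is exact: RNA viruses produce no DNA
intermediate, so DNA-fraction detection implies an endogenous element;
RNA-only detection marks a candidate active infection.

## Synthetic virome generator

The generator emulates a five-pool field study (one native-range, four
invasive-range pools; library sizes 5–7 M reads with rRNA fractions
0.04–0.30, giving ~4.5–5 M non-rRNA reads each). Planted viruses cover
all three genome classes, multi-segment genomes, widespread and
single-pool distributions, a trace planted at 0.1× the detection
threshold, a low-depth virus below the verdict floor, and one
near-identical (99.2%) to a "published" virus so the novelty call is
exercised in both directions. Polarity fractions follow the
class-typical ranges observed in strand-specific resequencing of insect
viromes: +ssRNA 0.92–1.0, −ssRNA 0.30–0.45 (within the 15–49% band),
dsRNA 0.6–0.7; the host marker is 0.99 positive.

Segment read totals are **Poisson** with mean
`abundance × length_kb × non_rrna_total/10⁶` — abundances are planted
directly in reads/kb/million so they round-trip through normalization —
and positive-strand counts are Binomial(total, polarity). A negative
binomial would add realism (biological replicate overdispersion) but
only the normalization/threshold/CI logic is under test, and Poisson
keeps planted expectations analytic. Contamination is barcode switching
only: per strand, Binomial(source count, switch rate) reads are copied
from each co-sequenced library (rate 2×10⁻⁴ by default, within the
per-mille range reported for patterned flow cells). Genome sequences are
random nucleotides with a planted stop-free run of ≥150 codons (70% of
the segment, ≥160 codons) — no codon-usage or compositional realism, so
passing tests demonstrate correctness of the *computations*, not
performance on real sequence data. Hit tables assign each viral contig a
strong virus-category hit whose percent identity equals the planted
identity-to-known; host contigs receive dipteran decoy hits or none.

Planted abundances are deliberately either ≥8× the detection threshold
or ≤0.1× it, and pooled depths either well past or far below the
2000-read verdict floor, so the truth table's expected flags are
unambiguous under Poisson sampling (flip probabilities ≲10⁻⁶) for any
seed. The default scenario seed is 20180329; all sub-stages derive
independent child seeds from one `SeedSequence`, so datasets are
deterministic end to end.

What the generator does not model: read-level FASTQ simulation,
alignment error, sequence evolution, rRNA identification, or real viral
genome architecture. Conclusions about real-data sensitivity (e.g. to
mapping ambiguity between close relatives) cannot be drawn from these
tests; the cross-mapping diagnostic exists precisely because the real
pipeline inherits that ambiguity from its upstream mapper.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 1000 random sequences of
30–3000 nt for ORF-oracle equivalence; 10 000 replicates at p = 0.3,
n = 200 for CI coverage; and the default scenario (9 viruses, 5 pools,
~5 M non-rRNA reads per pool, 32 contigs) for end-to-end recovery —
sizes at which every expectation is analytically checkable while the
whole suite runs in seconds. Ties in clustering distances are avoided in
test fixtures because agglomerative leaf order is convention-dependent
under ties. Division-by-zero states are rejected as input errors
(zero-length targets, empty libraries, all-zero COI counts, n = 0
intervals) rather than propagated as NaN.

## Known limitations

- The dsRNA replication rule is an extrapolation (see above).
- Percent identity stands in for "similarity" in the novelty rule; with
  a substitution matrix the 95% boundary would shift for borderline
  pairs.
- The barcode-switching note and the diagnostic thresholds are
  heuristics with package-chosen defaults; they surface candidates for
  review and must not be read as calls.
- The curated-table loader normalizes sample labels to Location+Year;
  the one published row listing "Japan" without a year is recorded as
  Japan2016, the single Japanese collection year.
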