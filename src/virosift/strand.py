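"""Replication inference from stranded read counts.

Strand-specific RNA-seq lets the replication state of an RNA virus be
read off the polarity of its mapped reads.  A virus that is merely
present as encapsidated genomic RNA shows only genome-sense reads: all
positive-sense for a +ssRNA virus, all negative-sense for a −ssRNA
virus.  Active replication produces the complementary strand
(replication intermediate), so observing a positive-sense read fraction
whose confidence interval excludes the no-replication null (p = 1 for
+ssRNA, p = 0 for −ssRNA) supports replication.  dsRNA viruses package
both strands; for them the presence of both polarities at depth is
reported as supporting, an extrapolation documented in the methods note.

Intervals are binomial 95% CIs computed on the logit scale,

    logit(p̂) ± z · sqrt(1/k + 1/(n−k)),   p̂ = k/n,

back-transformed through the inverse logit; at the boundaries k ∈ {0, n}
where the logit SE is undefined the exact Clopper–Pearson interval is
used instead.  Low-depth summaries (default < 2000 mapped reads) are
declared inconclusive rather than negative, because a +ssRNA virus at
low depth can lack negative-sense reads by sampling alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "GENOME_CLASSES",
    "MIN_DEPTH",
    "StrandSummary",
    "logit_ci",
    "replication_verdict",
    "summarize_strands",
    "host_baseline",
]

GENOME_CLASSES = ("plus_ss_rna", "minus_ss_rna", "ds_rna")
MIN_DEPTH = 2000

VERDICT_SUPPORTED = "replication_supported"
VERDICT_NOT_SUPPORTED = "not_supported"
VERDICT_LOW_DEPTH = "inconclusive_low_depth"


@dataclass(frozen=True)
class StrandSummary:
    virus: str
    genome_class: str | None
    n_pos: int
    n_total: int
    p_hat: float
    ci_low: float
    ci_high: float
    verdict: str = ""


def logit_ci(n_pos: int, n_total: int, level: float = 0.95) -> tuple[float, float]:
    """Binomial CI for the positive-sense fraction, logit parameterization.

    Falls back to the exact (Clopper–Pearson) interval at p̂ ∈ {0, 1}.
    """
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not 0 <= n_pos <= n_total:
        raise ValueError("n_pos must be in [0, n_total]")
    if n_pos == 0 or n_pos == n_total:
        lo, hi = proportion_confint(n_pos, n_total, alpha=1 - level, method="beta")
        return float(lo), float(hi)
    p = n_pos / n_total
    se = np.sqrt(1.0 / n_pos + 1.0 / (n_total - n_pos))
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = expit(logit(p) - z * se), expit(logit(p) + z * se)
    return float(lo), float(hi)


def replication_verdict(
    summary: StrandSummary, min_depth: int = MIN_DEPTH
) -> str:
    """Verdict on active replication for one virus.

    The no-replication null is p = 1 for +ssRNA and p = 0 for −ssRNA;
    replication is supported when the CI excludes the null and depth is
    adequate.  dsRNA viruses are called supported when both strands are
    observed at adequate depth.  Depth below ``min_depth`` is always
    inconclusive.
    """
    if summary.n_total < min_depth:
        return VERDICT_LOW_DEPTH
    cls = summary.genome_class
    if cls == "plus_ss_rna":
        excludes_null = summary.ci_high < 1.0 and summary.n_pos < summary.n_total
        return VERDICT_SUPPORTED if excludes_null else VERDICT_NOT_SUPPORTED
    if cls == "minus_ss_rna":
        excludes_null = summary.ci_low > 0.0 and summary.n_pos > 0
        return VERDICT_SUPPORTED if excludes_null else VERDICT_NOT_SUPPORTED
    if cls == "ds_rna":
        both = 0 < summary.n_pos < summary.n_total
        return VERDICT_SUPPORTED if both else VERDICT_NOT_SUPPORTED
    return VERDICT_NOT_SUPPORTED


def _strand_totals(
    counts: pd.DataFrame, references: Sequence[str]
) -> tuple[int, int]:
    sub = counts[counts["reference"].isin(references)]
    n_pos = int(sub.loc[sub["strand"] == "+", "count"].sum())
    n_total = int(sub["count"].sum())
    return n_pos, n_total


def summarize_strands(
    counts: pd.DataFrame,
    references_of_virus: Mapping[str, Sequence[str]],
    genome_class_of_virus: Mapping[str, str],
    level: float = 0.95,
    min_depth: int = MIN_DEPTH,
) -> list[StrandSummary]:
    """Per-virus strand summaries pooled over samples and segments.

    ``counts`` is the stranded counts table (sample, reference, strand,
    count); ``references_of_virus`` maps each virus to its segment
    reference names.  Viruses with zero mapped reads are skipped.
    """
    summaries = []
    for virus in sorted(references_of_virus):
        n_pos, n_total = _strand_totals(counts, references_of_virus[virus])
        if n_total == 0:
            continue
        p_hat = n_pos / n_total
        lo, hi = logit_ci(n_pos, n_total, level)
        summ = StrandSummary(
            virus, genome_class_of_virus.get(virus), n_pos, n_total, p_hat, lo, hi
        )
        summaries.append(
            StrandSummary(
                virus,
                summ.genome_class,
                n_pos,
                n_total,
                p_hat,
                lo,
                hi,
                replication_verdict(summ, min_depth),
            )
        )
    return summaries


def host_baseline(
    counts: pd.DataFrame,
    host_references: Sequence[str] = ("host_COI",),
    level: float = 0.95,
) -> StrandSummary | None:
    """Strand summary for the host marker gene (e.g. COI), pooled over samples.

    The host gene sets the expected positive-sense fraction for an
    abundantly transcribed non-viral template; virus fractions are read
    against it.  Returns None (with a warning) when no host counts exist.
    """
    n_pos, n_total = _strand_totals(counts, list(host_references))
    if n_total == 0:
        warnings.warn(
            "no reads mapped to the host marker; baseline omitted", stacklevel=2
        )
        return None
    lo, hi = logit_ci(n_pos, n_total, level)
    return StrandSummary(
        "host", None, n_pos, n_total, n_pos / n_total, lo, hi, "baseline"
    )


def write_strand_table(summaries: Sequence[StrandSummary], path) -> None:
    pd.DataFrame(
        [
            {
                "virus": s.virus,
                "genome_class": s.genome_class or "",
                "n_pos": s.n_pos,
                "n_total": s.n_total,
                "p_hat": round(s.p_hat, 6),
                "ci_low": round(s.ci_low, 6),
                "ci_high": round(s.ci_high, 6),
                "verdict": s.verdict,
            }
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False)
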