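"""Per-class CNV summaries, gene-content annotation, and size comparisons.

Produces the per-class feature table (counts, carriers, calls/subject,
size statistics in Mb, genes per call with a 50 kb breakpoint flank,
proportion of large calls and of deletions) and a Wilcoxon rank-sum
test for between-class size differences.

The rank-sum test is self-contained because its contract is explicit:
midranks for ties, exact enumeration of the permutation distribution
when both samples have <= 10 observations, and a tie-corrected,
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as _sps

from .genomic import CnvCall, CnvClass, CnvClassification, GenomicInterval

__all__ = [
    "GeneRecord",
    "GeneIndex",
    "genes_in_cnv",
    "summarize_by_class",
    "RankSumResult",
    "rank_sum_test",
    "compare_sizes",
    "SUMMARY_ROWS",
]

#: exact-enumeration cutoff for the rank-sum test (per-sample size)
_EXACT_N = 10


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval


class GeneIndex:
    """Per-chromosome interval index over gene loci."""

    def __init__(self, genes: Sequence[GeneRecord]):
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.interval.chrom, IntervalTree())
            tree.addi(g.interval.start, g.interval.end, g.gene_id)

    def overlapping(self, interval: GenomicInterval) -> list[str]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(interval.start, interval.end)})


def genes_in_cnv(
    call: CnvCall,
    genes: Sequence[GeneRecord] | GeneIndex,
    flank_bp: int = 50_000,
) -> tuple[int, list[str]]:
    """Genes intersecting the call extended by ``flank_bp`` on each side.

    The flanked query interval is clamped at position 0.  Each gene_id is
    counted once regardless of how many records it has.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    iv = call.interval
    query = GenomicInterval(iv.chrom, max(0, iv.start - flank_bp), iv.end + flank_bp)
    if isinstance(genes, GeneIndex):
        ids = genes.overlapping(query)
    else:
        ids = sorted(
            {g.gene_id for g in genes if g.interval.intersection_length(query) > 0}
        )
    return len(ids), ids


SUMMARY_ROWS = [
    "n_cnvs",
    "n_patients",
    "cnvs_per_subject",
    "mean_size_mb",
    "median_size_mb",
    "min_size_mb",
    "max_size_mb",
    "genes_per_cnv",
    "prop_large",
    "prop_deletion",
]

#: classes whose calls/subject row divides by the whole cohort rather
#: than by carriers of the class (matching the published arithmetic)
_COHORT_DENOMINATOR = {"common", "overall"}


def summarize_by_class(
    calls: Sequence[CnvCall],
    classifications: Sequence[CnvClassification],
    genes: Sequence[GeneRecord] | GeneIndex,
    n_subjects: int,
    flank_bp: int = 50_000,
) -> pd.DataFrame:
    """Per-class CNV feature table (rows = statistics, columns = classes).

    Columns are the classes present among ``classifications`` (in the
    order common, familial, de_novo, unique_unresolved) plus ``overall``.
    ``cnvs_per_subject`` divides by the cohort size for the common and
    overall columns and by per-class carrier counts otherwise, and
    ``prop_large`` uses a strict > 1 Mb cut.
    """
    if len(calls) != len(classifications):
        raise ValueError("calls and classifications must have equal length")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")

    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    rows = []
    for call, cls in zip(calls, classifications):
        if call.call_id != cls.call_id:
            raise ValueError(f"call/classification mismatch at {call.call_id!r}")
        n_genes, _ = genes_in_cnv(call, index, flank_bp)
        rows.append(
            {
                "klass": cls.klass.value,
                "subject_id": call.subject_id,
                "size_mb": call.size_mb,
                "n_genes": n_genes,
                "is_deletion": call.state.value == "deletion",
            }
        )
    df = pd.DataFrame(rows)

    order = [
        k.value
        for k in (
            CnvClass.COMMON,
            CnvClass.FAMILIAL,
            CnvClass.DE_NOVO,
            CnvClass.UNIQUE_UNRESOLVED,
        )
        if not df.empty and (df["klass"] == k.value).any()
    ]
    table = {}
    for label in order + ["overall"]:
        sub = df if label == "overall" else df[df["klass"] == label]
        n_cnvs = len(sub)
        n_patients = n_subjects if label == "overall" else sub["subject_id"].nunique()
        denom = n_subjects if label in _COHORT_DENOMINATOR else n_patients
        sizes = sub["size_mb"].to_numpy()
        table[label] = {
            "n_cnvs": float(n_cnvs),
            "n_patients": float(n_patients),
            "cnvs_per_subject": n_cnvs / denom if denom else math.nan,
            "mean_size_mb": float(np.mean(sizes)) if n_cnvs else math.nan,
            "median_size_mb": float(np.median(sizes)) if n_cnvs else math.nan,
            "min_size_mb": float(np.min(sizes)) if n_cnvs else math.nan,
            "max_size_mb": float(np.max(sizes)) if n_cnvs else math.nan,
            "genes_per_cnv": float(sub["n_genes"].mean()) if n_cnvs else math.nan,
            "prop_large": float((sizes > 1.0).mean()) if n_cnvs else math.nan,
            "prop_deletion": float(sub["is_deletion"].mean()) if n_cnvs else math.nan,
        }
    return pd.DataFrame(table, index=SUMMARY_ROWS)


class RankSumResult(NamedTuple):
    statistic: float  # rank sum of the first sample
    pvalue: float
    method: str  # "exact" or "normal"


def _exact_ranksum_pvalue(ranks2: np.ndarray, n1: int, w2: int) -> float:
    """Two-sided exact p over all size-n1 subsets of the pooled ranks.

    ``ranks2`` holds doubled midranks (integers), ``w2`` the doubled
    observed rank sum.  Counts of subset sums are built by dynamic
    programming, which is equivalent to full enumeration of the
    C(n, n1) assignments.
    """
    n = len(ranks2)
    total = int(ranks2.sum())
    dp = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    dp[0, 0] = 1
    for v in ranks2:
        v = int(v)
        for k in range(n1, 0, -1):
            dp[k, v:] += dp[k - 1, : total + 1 - v]
    dist = dp[n1]
    e2 = n1 * (n + 1)  # doubled expectation of the rank sum
    sums = np.arange(total + 1)
    obs_dev = abs(w2 - e2)
    mask = np.abs(sums - e2) >= obs_dev
    return float(dist[mask].sum() / dist.sum())


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Wilcoxon rank-sum test (two-sided), midranks for ties.

    Exact permutation enumeration when both samples have <= 10 values;
    otherwise a normal approximation with tie correction and a 0.5
    continuity correction.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = _sps.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())

    if n1 <= _EXACT_N and n2 <= _EXACT_N:
        ranks2 = np.rint(2 * ranks).astype(np.int64)  # midranks are multiples of 1/2
        p = _exact_ranksum_pvalue(ranks2, n1, int(round(2 * w)))
        return RankSumResult(w, p, "exact")

    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankSumResult(w, 1.0, "normal")
    z = max(0.0, abs(w - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(_sps.norm.sf(z)))
    return RankSumResult(w, p, "normal")


def compare_sizes(sizes_a: Sequence[float], sizes_b: Sequence[float]) -> RankSumResult:
    """Between-class CNV size comparison (Wilcoxon rank-sum, two-sided)."""
    return rank_sum_test(sizes_a, sizes_b)
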