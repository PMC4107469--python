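"""Subject grouping by CNV class and per-phenotype prevalence comparison.

Subjects are partitioned by the "worst" CNV they carry: any de novo
call puts a subject in the de novo group; a familial call without a de
novo call gives familial-only; everyone else is common-only.  Subjects
carrying both a de novo and a familial call are flagged so that the
familial-vs-common contrast can exclude them.

Each phenotype feature is compared between two groups with a two-sided
Fisher exact test on the abnormal/normal x groupA/groupB table, and
p-values are adjusted per contrast with the Benjamini-Hochberg step-up.
The Fisher p-value is computed by exact hypergeometric enumeration with
integer weights, so the "probability at most that of the observed
table" comparison is made with a 1e-7 relative tolerance on exact
integers rather than on floats.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic import CnvClass
from .phenotypes import PhenotypeMatrix

__all__ = [
    "SubjectGrouping",
    "group_subjects",
    "fisher_exact_2x2",
    "bh_adjust",
    "prevalence_comparison",
]

GROUP_DE_NOVO = "de_novo"
GROUP_FAMILIAL_ONLY = "familial_only"
GROUP_COMMON_ONLY = "common_only"

#: relative tolerance for the <= comparison of table probabilities,
#: applied on integer weights as w <= w_obs * (1 + 1e-7)
_FISHER_TOL_NUM = 10_000_001
_FISHER_TOL_DEN = 10_000_000


@dataclass(frozen=True)
class SubjectGrouping:
    """Partition of subjects into de_novo / familial_only / common_only."""

    group_of: Mapping[str, str]
    dual_carriers: frozenset[str]

    def members(self, group: str) -> list[str]:
        return sorted(s for s, g in self.group_of.items() if g == group)

    @property
    def sizes(self) -> dict[str, int]:
        out = {GROUP_DE_NOVO: 0, GROUP_FAMILIAL_ONLY: 0, GROUP_COMMON_ONLY: 0}
        for g in self.group_of.values():
            out[g] += 1
        return out


def group_subjects(
    call_classes: Mapping[str, Iterable[CnvClass | str]],
    subjects: Sequence[str] | None = None,
    unresolved_as_familial: bool = False,
) -> SubjectGrouping:
    """Group subjects by the classes of their calls.

    ``call_classes`` maps subject id to the classes of that subject's
    calls (subjects with no calls may be listed with an empty sequence or
    supplied via ``subjects``, and land in common_only).  Unresolved
    unique calls count as familial only when ``unresolved_as_familial``
    is set; by default they do not promote a subject out of common_only.
    """
    all_subjects = set(call_classes)
    if subjects is not None:
        all_subjects |= set(subjects)
    familial_like = {CnvClass.FAMILIAL.value}
    if unresolved_as_familial:
        familial_like.add(CnvClass.UNIQUE_UNRESOLVED.value)

    group_of: dict[str, str] = {}
    dual: set[str] = set()
    for subj in all_subjects:
        classes = {
            c.value if isinstance(c, CnvClass) else str(c)
            for c in call_classes.get(subj, ())
        }
        has_dn = CnvClass.DE_NOVO.value in classes
        has_fam = bool(classes & familial_like)
        if has_dn:
            group_of[subj] = GROUP_DE_NOVO
            if has_fam:
                dual.add(subj)
        elif has_fam:
            group_of[subj] = GROUP_FAMILIAL_ONLY
        else:
            group_of[subj] = GROUP_COMMON_ONLY
    return SubjectGrouping(group_of=group_of, dual_carriers=frozenset(dual))


def fisher_exact_2x2(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability is at most that of the observed table
    (relative tolerance 1e-7).  A table with a zero margin has a single
    attainable configuration and returns 1.0.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    flat = [int(v) for v in arr.ravel()]
    if any(int(v) != float(v) for v in np.asarray(arr, dtype=float).ravel()):
        raise ValueError("table entries must be integers")
    if any(v < 0 for v in flat):
        raise ValueError("table entries must be non-negative")
    a, b, c, d = flat
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    qualifying = sum(
        w for w in weights if w * _FISHER_TOL_DEN <= w_obs * _FISHER_TOL_NUM
    )
    return float(qualifying / comb(r1 + r2, c1))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def prevalence_comparison(
    matrix: PhenotypeMatrix,
    grouping: SubjectGrouping,
    contrast: tuple[str, str] = (GROUP_DE_NOVO, GROUP_COMMON_ONLY),
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-feature prevalence comparison between two subject groups.

    Builds the abnormal/normal x group 2x2 table per feature, applies the
    Fisher exact test, and BH-adjusts across all features of the
    contrast.  ``exclude`` removes subjects (e.g. dual de novo + familial
    carriers for the familial contrast) from both columns.  Subjects in a
    group but absent from the matrix are ignored.
    """
    group_a, group_b = contrast
    excluded = set(exclude)
    in_matrix = set(matrix.subjects)
    subj_a = [s for s in grouping.members(group_a) if s in in_matrix and s not in excluded]
    subj_b = [s for s in grouping.members(group_b) if s in in_matrix and s not in excluded]
    if not subj_a or not subj_b:
        raise ValueError(
            f"empty group after exclusion: {group_a} n={len(subj_a)}, "
            f"{group_b} n={len(subj_b)}"
        )
    n_a, n_b = len(subj_a), len(subj_b)
    data_a = matrix.data.loc[subj_a]
    data_b = matrix.data.loc[subj_b]

    records = []
    for feature in matrix.features:
        k_a = int(data_a[feature].sum())
        k_b = int(data_b[feature].sum())
        p = fisher_exact_2x2([[k_a, k_b], [n_a - k_a, n_b - k_b]])
        records.append(
            {
                "feature": feature,
                "n_a": n_a,
                "abnormal_a": k_a,
                "prevalence_a": k_a / n_a,
                "n_b": n_b,
                "abnormal_b": k_b,
                "prevalence_b": k_b / n_b,
                "p_value": p,
            }
        )
    out = pd.DataFrame(records).set_index("feature")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out.attrs["contrast"] = contrast
    out.attrs["excluded"] = sorted(excluded)
    return out
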