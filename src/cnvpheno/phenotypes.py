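"""Coarse/fine binary phenotype matrices, prevalence filtering, and scoring.

Phenotypes follow a two-level dysmorphology ontology: fine features
(secondary categories) nest inside coarse categories (primary
categories).  A subject's coarse value is the logical OR of the fine
features in that category.  Features present in almost no or almost
all subjects carry no contrast and are removed by a prevalence filter.
Per-subject abnormality burden and a configurable five-item checklist
score (De Vries score) summarise phenotype severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeOntology",
    "PhenotypeMatrix",
    "RubricItem",
    "DeVriesRubric",
    "aggregate_coarse",
    "filter_by_prevalence",
    "abnormality_counts",
    "de_vries_score",
    "score_cohort",
    "default_rubric",
]


@dataclass(frozen=True)
class PhenotypeOntology:
    """Mapping of fine feature ids to coarse category ids.

    ``coarse_order`` fixes the declared order of coarse categories for
    output; categories absent from a matrix are simply not emitted.
    """

    fine_to_coarse: Mapping[str, str]
    coarse_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        order = tuple(self.coarse_order) if self.coarse_order else tuple(
            dict.fromkeys(self.fine_to_coarse.values())
        )
        object.__setattr__(self, "coarse_order", order)

    @property
    def coarse_categories(self) -> tuple[str, ...]:
        return self.coarse_order

    def coarse_of(self, fine_id: str) -> str:
        try:
            return self.fine_to_coarse[fine_id]
        except KeyError:
            raise KeyError(f"fine feature {fine_id!r} is not in the ontology") from None


@dataclass
class PhenotypeMatrix:
    """Binary subjects x features matrix at one ontology level.

    ``data`` is a pandas DataFrame with subject ids as index and feature
    ids as columns; values are 0/1 with no missing cells (the readers
    map explicit unknown markers to 0 before construction).
    """

    data: pd.DataFrame
    level: str = "fine"

    def __post_init__(self) -> None:
        if self.level not in ("fine", "coarse"):
            raise ValueError(f"level must be 'fine' or 'coarse', got {self.level!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate subject id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("phenotype matrix values must be 0 or 1")
        self.data = self.data.astype(np.int8)

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data.index)

    def subset(self, subjects: Sequence[str]) -> "PhenotypeMatrix":
        return PhenotypeMatrix(self.data.loc[list(subjects)], level=self.level)


def aggregate_coarse(
    matrix: PhenotypeMatrix, ontology: PhenotypeOntology
) -> PhenotypeMatrix:
    """OR-aggregate a fine matrix into its coarse categories.

    A coarse category is abnormal for a subject iff at least one of its
    fine features present in the matrix is abnormal.  Only categories
    with >= 1 fine feature in the matrix appear in the output.
    """
    if matrix.level != "fine":
        raise ValueError("aggregate_coarse expects a fine-level matrix")
    unmapped = [f for f in matrix.features if f not in ontology.fine_to_coarse]
    if unmapped:
        raise KeyError(f"fine feature {unmapped[0]!r} is not in the ontology")
    groups: dict[str, list[str]] = {}
    for f in matrix.features:
        groups.setdefault(ontology.coarse_of(f), []).append(f)
    cols = {}
    for coarse in ontology.coarse_order:
        if coarse in groups:
            cols[coarse] = matrix.data[groups[coarse]].max(axis=1)
    # categories not in the declared order still aggregate, after it
    for coarse, fines in groups.items():
        if coarse not in cols:
            cols[coarse] = matrix.data[fines].max(axis=1)
    return PhenotypeMatrix(pd.DataFrame(cols, index=matrix.data.index), level="coarse")


def filter_by_prevalence(
    matrix: PhenotypeMatrix, lo: float = 0.05, hi: float = 0.95
) -> tuple[PhenotypeMatrix, pd.DataFrame]:
    """Drop features present in < lo or > hi of subjects.

    Keeps features with ``lo*N <= count <= hi*N`` (N = subject count); for
    N = 78 and the default band that removes counts below 4 and above 74.
    Returns the reduced matrix and a report of removed features with their
    counts and the side of the band they fell on.
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError("require 0 <= lo < hi <= 1")
    n = matrix.n_subjects
    counts = matrix.data.sum(axis=0)
    keep = (counts >= lo * n) & (counts <= hi * n)
    removed = pd.DataFrame(
        {
            "feature": counts.index[~keep],
            "count": counts[~keep].astype(int).to_numpy(),
            "prevalence": (counts[~keep] / n).to_numpy() if n else np.nan,
            "reason": np.where(counts[~keep] < lo * n, "below_min", "above_max"),
        }
    ).reset_index(drop=True)
    reduced = PhenotypeMatrix(matrix.data.loc[:, keep], level=matrix.level)
    return reduced, removed


def abnormality_counts(matrix: PhenotypeMatrix) -> tuple[pd.Series, float]:
    """Per-subject abnormal-feature counts and the cohort median."""
    if matrix.n_subjects == 0 or not matrix.features:
        raise ValueError("phenotype matrix must be non-empty")
    counts = matrix.data.sum(axis=1).astype(int)
    return counts, float(np.median(counts.to_numpy()))


@dataclass(frozen=True)
class RubricItem:
    """One checklist item.

    Counting item (``threshold`` None): contributes
    ``min(cap, weight * n_hits)`` where n_hits is the number of abnormal
    features among ``features``.  Threshold item: contributes ``weight``
    (capped) iff ``n_hits >= threshold`` — used for the ">= 2 facial
    dysmorphic features" item.
    """

    name: str
    features: tuple[str, ...]
    weight: int = 1
    cap: int = 2
    threshold: int | None = None

    def __post_init__(self) -> None:
        if self.weight < 0 or self.cap < 0:
            raise ValueError("weight and cap must be >= 0")
        if self.threshold is not None and self.threshold < 1:
            raise ValueError("threshold must be >= 1 when set")

    def score(self, present: Collection[str]) -> int:
        hits = sum(1 for f in self.features if f in present)
        if self.threshold is not None:
            return min(self.cap, self.weight) if hits >= self.threshold else 0
        return min(self.cap, self.weight * hits)


@dataclass(frozen=True)
class DeVriesRubric:
    items: tuple[RubricItem, ...]
    total_cap: int = 9

    def __post_init__(self) -> None:
        if self.total_cap < 0:
            raise ValueError("total_cap must be >= 0")

    def item_hits(self, present: Collection[str]) -> dict[str, int]:
        return {
            item.name: sum(1 for f in item.features if f in present)
            for item in self.items
        }


def de_vries_score(
    subject_features: Collection[str] | pd.Series, rubric: DeVriesRubric
) -> int:
    """Checklist score for one subject: capped sum of capped item scores."""
    if isinstance(subject_features, pd.Series):
        present = set(subject_features.index[subject_features.astype(bool)])
    else:
        present = set(subject_features)
    return min(rubric.total_cap, sum(item.score(present) for item in rubric.items))


def score_cohort(matrix: PhenotypeMatrix, rubric: DeVriesRubric) -> pd.Series:
    """De Vries score per subject of a fine-level matrix."""
    scores = {
        subj: de_vries_score(matrix.data.loc[subj], rubric)
        for subj in matrix.subjects
    }
    return pd.Series(scores, name="de_vries_score", dtype=int)


def default_rubric(bindings: Mapping[str, Sequence[str]]) -> DeVriesRubric:
    """Build the default five-item rubric from feature-id bindings.

    ``bindings`` maps item names to the fine feature ids realising each
    item: family_history (weight 1, cap 1), prenatal_growth_retardation
    (weight 2, cap 2), postnatal_growth_abnormalities (weight 1 per
    feature, cap 2), facial_dysmorphism (>= 2 designated facial features
    scores 2), congenital_anomalies (weight 1 per feature, cap 2).
    """
    spec = {
        "family_history": dict(weight=1, cap=1),
        "prenatal_growth_retardation": dict(weight=2, cap=2),
        "postnatal_growth_abnormalities": dict(weight=1, cap=2),
        "facial_dysmorphism": dict(weight=2, cap=2, threshold=2),
        "congenital_anomalies": dict(weight=1, cap=2),
    }
    missing = set(spec) - set(bindings)
    if missing:
        raise KeyError(f"rubric bindings missing items: {sorted(missing)}")
    items = tuple(
        RubricItem(name=name, features=tuple(bindings[name]), **kw)
        for name, kw in spec.items()
    )
    return DeVriesRubric(items=items, total_cap=9)
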