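"""Genomic intervals, CNV calls, and database-overlap classification.

A copy-number call is compared against a study-attributed database of
population variants (a DGV-style catalogue plus internal controls from
cognitively normal subjects).  A call whose interval is *completely*
covered by the union of overlapping database records is labelled
``common`` when that union is backed by at least two distinct population
studies, or by any internal-control record.  Every other call is
*unique* (rare) and is resolved into ``de_novo`` / ``familial`` /
``unique_unresolved`` from parental-testing evidence.

Coordinates are 0-based half-open (BED convention) throughout; the
on-disk dialects in :mod:`cnvpheno.io` convert 1-based inclusive tables
on read.  Coverage is computed in integer bases, so the "complete
overlap" test (coverage exactly 1.0) is exact, not a float comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "CnvState",
    "InheritanceEvidence",
    "RecordSource",
    "CnvClass",
    "CnvCall",
    "VariantRecord",
    "VariantDatabase",
    "ClassificationPolicy",
    "CnvClassification",
    "normalize_chrom",
    "coverage_fraction",
    "classify_cnv",
    "classify_cohort",
    "resolve_inheritance",
    "filter_calls_by_probes",
]


class CnvState(str, Enum):
    """Copy-number state of a call or database record."""

    DELETION = "deletion"
    DUPLICATION = "duplication"
    #: database records of unreported state; not valid for calls
    UNKNOWN = "unknown"


class InheritanceEvidence(str, Enum):
    """Outcome of secondary (FISH/qPCR) parental testing for a unique call."""

    ABSENT_IN_BOTH_PARENTS = "absent_in_both_parents"
    PRESENT_IN_A_PARENT = "present_in_a_parent"
    UNTESTED = "untested"


class RecordSource(str, Enum):
    POPULATION_DB = "population_db"
    INTERNAL_CONTROL = "internal_control"


class CnvClass(str, Enum):
    COMMON = "common"
    DE_NOVO = "de_novo"
    FAMILIAL = "familial"
    UNIQUE_UNRESOLVED = "unique_unresolved"


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix; comparison afterwards is exact."""
    name = name.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if not name:
        raise ValueError("empty chromosome name")
    return name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CnvCall:
    """One subject's copy-number call.

    ``probe_count`` is the number of consecutive array probes supporting
    the call; ``None`` means unknown (such calls pass the probe filter).
    """

    call_id: str
    subject_id: str
    interval: GenomicInterval
    state: CnvState
    probe_count: int | None = None
    inheritance_evidence: InheritanceEvidence = InheritanceEvidence.UNTESTED

    def __post_init__(self) -> None:
        if self.state not in (CnvState.DELETION, CnvState.DUPLICATION):
            raise ValueError(f"call state must be deletion or duplication, got {self.state}")
        if self.probe_count is not None and self.probe_count < 0:
            raise ValueError("probe_count must be >= 0 or None")

    @property
    def size(self) -> int:
        return self.interval.length

    @property
    def size_mb(self) -> float:
        return self.interval.length / 1e6


@dataclass(frozen=True)
class VariantRecord:
    """A population-database or internal-control variant."""

    interval: GenomicInterval
    study_id: str
    source: RecordSource = RecordSource.POPULATION_DB
    state: CnvState = CnvState.UNKNOWN

    def __post_init__(self) -> None:
        if self.source is RecordSource.POPULATION_DB and not self.study_id:
            raise ValueError("population_db records require a non-empty study_id")


class VariantDatabase:
    """Study-attributed population variants with per-chromosome interval indexes."""

    def __init__(self, records: Iterable[VariantRecord]):
        self._records: list[VariantRecord] = list(records)
        self._trees: dict[str, IntervalTree] = {}
        for rec in self._records:
            tree = self._trees.setdefault(rec.interval.chrom, IntervalTree())
            tree.addi(rec.interval.start, rec.interval.end, rec)

    def __len__(self) -> int:
        return len(self._records)

    @property
    def records(self) -> Sequence[VariantRecord]:
        return tuple(self._records)

    @property
    def chromosomes(self) -> frozenset[str]:
        return frozenset(self._trees)

    def overlapping(self, interval: GenomicInterval) -> list[VariantRecord]:
        """All records with a nonzero intersection with ``interval``.

        Identical (interval, study, source) duplicates are collapsed, so a
        study contributing the same record twice is counted once.
        Returned in deterministic (coordinate, study) order.
        """
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(interval.start, interval.end)}
        return sorted(
            hits,
            key=lambda r: (r.interval.start, r.interval.end, r.study_id, r.source.value),
        )


@dataclass(frozen=True)
class ClassificationPolicy:
    """Tunable aspects of the common/unique rule.

    match_state
        Require database records to match the call's deletion/duplication
        state (records of unknown state always count).  Off by default:
        catalogue records of the era mix states.
    borderline_to_common
        Route calls with union coverage in [0.5, 1.0) that meet the
        study-support condition to ``common`` instead of unique.  Off by
        default, which preserves the strict complete-overlap rule.
    """

    match_state: bool = False
    borderline_to_common: bool = False


@dataclass(frozen=True)
class CnvClassification:
    call_id: str
    klass: CnvClass
    coverage: float
    supporting_studies: int
    internal_control_hit: bool
    borderline: bool


def _contributing_records(
    call: CnvCall, db: VariantDatabase, policy: ClassificationPolicy
) -> list[VariantRecord]:
    hits = db.overlapping(call.interval)
    if policy.match_state:
        hits = [r for r in hits if r.state in (CnvState.UNKNOWN, call.state)]
    return [r for r in hits if r.interval.intersection_length(call.interval) > 0]


def _union_covered_bases(call_iv: GenomicInterval, records: Sequence[VariantRecord]) -> int:
    segments = sorted(
        (max(r.interval.start, call_iv.start), min(r.interval.end, call_iv.end))
        for r in records
    )
    covered = 0
    cur_start = cur_end = None
    for s, e in segments:
        if cur_end is None:
            cur_start, cur_end = s, e
        elif s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def coverage_fraction(
    call: CnvCall,
    db: VariantDatabase,
    policy: ClassificationPolicy = ClassificationPolicy(),
) -> tuple[float, list[VariantRecord]]:
    """Fraction of the call covered by the union of overlapping db records.

    Returns ``(fraction, contributing_records)`` where the contributing
    records are exactly those with nonzero intersection with the call.
    A chromosome absent from the database yields 0.0 without error.
    """
    records = _contributing_records(call, db, policy)
    covered = _union_covered_bases(call.interval, records)
    return covered / call.interval.length, records


def resolve_inheritance(evidence: InheritanceEvidence) -> CnvClass:
    """Map parental-testing evidence of a unique call to its class."""
    if evidence is InheritanceEvidence.ABSENT_IN_BOTH_PARENTS:
        return CnvClass.DE_NOVO
    if evidence is InheritanceEvidence.PRESENT_IN_A_PARENT:
        return CnvClass.FAMILIAL
    return CnvClass.UNIQUE_UNRESOLVED


def classify_cnv(
    call: CnvCall,
    db: VariantDatabase,
    policy: ClassificationPolicy = ClassificationPolicy(),
) -> CnvClassification:
    """Apply the common/unique rule to a single call.

    ``common`` requires the call's interval to be completely covered by
    the union of contributing records AND that union to be supported by
    >= 2 distinct population studies or >= 1 internal-control record.
    Non-common calls are resolved by :func:`resolve_inheritance`;
    ``borderline`` flags coverage in [0.5, 1.0), the range the binary
    rule leaves unnamed.
    """
    records = _contributing_records(call, db, policy)
    covered = _union_covered_bases(call.interval, records)
    length = call.interval.length
    coverage = covered / length

    studies = {r.study_id for r in records if r.source is RecordSource.POPULATION_DB}
    internal_hit = any(r.source is RecordSource.INTERNAL_CONTROL for r in records)
    supported = len(studies) >= 2 or internal_hit
    borderline = covered < length and 2 * covered >= length

    if covered == length and supported:
        klass = CnvClass.COMMON
    elif policy.borderline_to_common and borderline and supported:
        klass = CnvClass.COMMON
    else:
        klass = resolve_inheritance(call.inheritance_evidence)

    return CnvClassification(
        call_id=call.call_id,
        klass=klass,
        coverage=coverage,
        supporting_studies=len(studies),
        internal_control_hit=internal_hit,
        borderline=borderline,
    )


def classify_cohort(
    calls: Sequence[CnvCall],
    db: VariantDatabase,
    policy: ClassificationPolicy = ClassificationPolicy(),
) -> list[CnvClassification]:
    return [classify_cnv(call, db, policy) for call in calls]


def filter_calls_by_probes(
    calls: Sequence[CnvCall], min_probes: int = 3
) -> list[CnvCall]:
    """Retain calls supported by >= ``min_probes`` probes (unknown passes)."""
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    return [c for c in calls if c.probe_count is None or c.probe_count >= min_probes]


def calls_by_subject(
    calls: Sequence[CnvCall], classifications: Sequence[CnvClassification]
) -> Mapping[str, list[CnvClass]]:
    """Per-subject list of call classes, pairing calls with their classifications."""
    if len(calls) != len(classifications):
        raise ValueError("calls and classifications must have equal length")
    out: dict[str, list[CnvClass]] = {}
    for call, cls in zip(calls, classifications):
        if call.call_id != cls.call_id:
            raise ValueError(f"call/classification mismatch at {call.call_id!r}")
        out.setdefault(call.subject_id, []).append(cls.klass)
    return out
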