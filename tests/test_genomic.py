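"""Interval coverage and the common/unique/de-novo/familial rule."""

from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvpheno.genomic import (
    ClassificationPolicy,
    CnvCall,
    CnvClass,
    CnvState,
    GenomicInterval,
    InheritanceEvidence,
    RecordSource,
    VariantDatabase,
    VariantRecord,
    classify_cnv,
    coverage_fraction,
    filter_calls_by_probes,
    normalize_chrom,
    resolve_inheritance,
)


def _call(chrom="1", start=100, end=200, evidence=InheritanceEvidence.UNTESTED):
    return CnvCall(
        "c1", "s1", GenomicInterval(chrom, start, end), CnvState.DELETION,
        probe_count=5, inheritance_evidence=evidence,
    )


def _rec(chrom="1", start=0, end=1, study="A", source=RecordSource.POPULATION_DB):
    return VariantRecord(GenomicInterval(chrom, start, end), study, source)


class TestGenomicInterval:
    def test_rejects_empty_and_inverted(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 1)

    def test_chrom_normalization(self):
        assert normalize_chrom("chr1") == "1"
        assert normalize_chrom("X") == "X"
        with pytest.raises(ValueError):
            normalize_chrom("chr")


class TestCoverageFraction:
    @pytest.mark.parametrize(
        "records, expected",
        [
            ([(100, 200)], 1.0),  # identical record covers fully
            ([(150, 300)], 0.5),  # half covered
            ([(100, 160), (150, 200)], 1.0),  # union of two closes the gap
            ([(100, 160), (170, 200)], 0.9),  # union with a 10 bp hole
            ([], 0.0),
        ],
    )
    def test_union_coverage(self, records, expected):
        db = VariantDatabase([_rec("1", s, e) for s, e in records])
        frac, contributing = coverage_fraction(_call(), db)
        assert frac == pytest.approx(expected)
        assert len(contributing) == len(records)

    def test_unknown_chromosome_returns_zero(self):
        db = VariantDatabase([_rec("2", 100, 200)])
        frac, contributing = coverage_fraction(_call("1"), db)
        assert frac == 0.0 and contributing == []

    @given(st.data())
    def test_matches_per_base_oracle(self, data):
        """Union coverage equals a per-base membership count."""
        start = data.draw(st.integers(0, 500))
        end = data.draw(st.integers(start + 1, start + 400))
        call = _call("1", start, end)
        n_rec = data.draw(st.integers(0, 8))
        intervals = [
            (s := data.draw(st.integers(0, 900)), data.draw(st.integers(s + 1, 1000)))
            for _ in range(n_rec)
        ]
        db = VariantDatabase(
            [_rec("1", s, e, study=f"st{i}") for i, (s, e) in enumerate(intervals)]
        )
        frac, _ = coverage_fraction(call, db)
        covered = {
            pos
            for s, e in intervals
            for pos in range(max(s, start), min(e, end))
        }
        assert frac == pytest.approx(len(covered) / (end - start))

    @given(st.data())
    def test_monotone_in_records(self, data):
        """Adding records never decreases coverage."""
        intervals = data.draw(
            st.lists(
                st.tuples(st.integers(0, 300), st.integers(1, 100)), min_size=1, max_size=6
            )
        )
        records = [_rec("1", s, s + l, study=f"st{i}") for i, (s, l) in enumerate(intervals)]
        call = _call("1", 50, 250)
        fracs = [
            coverage_fraction(call, VariantDatabase(records[: k + 1]))[0]
            for k in range(len(records))
        ]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestClassifyCnv:
    def test_two_studies_full_coverage_is_common(self):
        db = VariantDatabase([_rec("1", 100, 200, "A"), _rec("1", 100, 200, "B")])
        cls = classify_cnv(_call(), db)
        assert cls.klass is CnvClass.COMMON
        assert cls.coverage == 1.0
        assert cls.supporting_studies == 2
        assert not cls.borderline

    def test_partial_coverage_resolves_by_inheritance(self):
        db = VariantDatabase([_rec("1", 100, 140, "A"), _rec("1", 100, 140, "B")])
        cls = classify_cnv(_call(evidence=InheritanceEvidence.ABSENT_IN_BOTH_PARENTS), db)
        assert cls.klass is CnvClass.DE_NOVO
        assert cls.coverage == pytest.approx(0.4)
        assert not cls.borderline

    def test_single_study_full_coverage_is_not_common(self):
        db = VariantDatabase([_rec("1", 50, 300, "A")])
        cls = classify_cnv(_call(evidence=InheritanceEvidence.PRESENT_IN_A_PARENT), db)
        assert cls.klass is CnvClass.FAMILIAL
        assert cls.coverage == 1.0
        assert cls.supporting_studies == 1
        assert not cls.borderline

    def test_internal_control_alone_suffices(self):
        db = VariantDatabase(
            [_rec("1", 50, 300, "internal", RecordSource.INTERNAL_CONTROL)]
        )
        cls = classify_cnv(_call(), db)
        assert cls.klass is CnvClass.COMMON
        assert cls.internal_control_hit

    def test_duplicate_records_count_one_study(self):
        db = VariantDatabase([_rec("1", 100, 200, "A"), _rec("1", 100, 200, "A")])
        cls = classify_cnv(_call(), db)
        assert cls.supporting_studies == 1
        assert cls.klass is not CnvClass.COMMON

    def test_borderline_flag_and_policy_routing(self):
        db = VariantDatabase([_rec("1", 100, 170, "A"), _rec("1", 100, 170, "B")])
        cls = classify_cnv(_call(), db)
        assert cls.borderline and cls.klass is CnvClass.UNIQUE_UNRESOLVED
        routed = classify_cnv(
            _call(), db, ClassificationPolicy(borderline_to_common=True)
        )
        assert routed.klass is CnvClass.COMMON

    def test_state_matching_policy(self):
        del_rec = VariantRecord(
            GenomicInterval("1", 100, 200), "A", state=CnvState.DUPLICATION
        )
        db = VariantDatabase([del_rec, _rec("1", 100, 200, "B")])
        strict = classify_cnv(_call(), db, ClassificationPolicy(match_state=True))
        assert strict.supporting_studies == 1  # dup record ignored for a deletion call
        loose = classify_cnv(_call(), db)
        assert loose.supporting_studies == 2

    def test_empty_database_yields_unique(self):
        cls = classify_cnv(_call(), VariantDatabase([]))
        assert cls.coverage == 0.0
        assert cls.klass is CnvClass.UNIQUE_UNRESOLVED

    def test_deterministic(self, study):
        call = study.calls[0]
        first = classify_cnv(call, study.db)
        assert all(classify_cnv(call, study.db) == first for _ in range(3))

    def test_partition_over_cohort(self, study, classified):
        """Every call gets exactly one class; class counts conserve the total."""
        assert len(classified) == len(study.calls)
        counts = Counter(c.klass for c in classified)
        assert sum(counts.values()) == len(study.calls)


class TestResolveInheritance:
    @pytest.mark.parametrize(
        "evidence, expected",
        [
            (InheritanceEvidence.ABSENT_IN_BOTH_PARENTS, CnvClass.DE_NOVO),
            (InheritanceEvidence.PRESENT_IN_A_PARENT, CnvClass.FAMILIAL),
            (InheritanceEvidence.UNTESTED, CnvClass.UNIQUE_UNRESOLVED),
        ],
    )
    def test_mapping(self, evidence, expected):
        assert resolve_inheritance(evidence) is expected


class TestProbeFilter:
    def test_threshold_and_unknown(self):
        calls = [
            CnvCall(f"c{i}", "s", GenomicInterval("1", 0, 10), CnvState.DELETION, pc)
            for i, pc in enumerate([2, 3, 5, None])
        ]
        kept = filter_calls_by_probes(calls, 3)
        assert [c.call_id for c in kept] == ["c1", "c2", "c3"]
        assert filter_calls_by_probes(calls, 1) == calls
        with pytest.raises(ValueError):
            filter_calls_by_probes(calls, 0)
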