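"""File dialects, run configuration, and the end-to-end pipeline.

On-disk conventions
-------------------
* CNV-call and variant-database TSVs are 1-based inclusive (matching the
  coordinate style of published CNV tables) and are converted to 0-based
  half-open intervals on read; writers convert back.
* Gene annotation is BED4 (already 0-based half-open).
* Phenotypes are a subjects x features TSV of {0,1,NA}; NA is mapped to
  absent (0) and the count is logged.  The ontology is a two-column TSV
  (fine_id, coarse_id).
* The De Vries rubric is a YAML block naming feature ids per item.
* Floating-point TSV output is at 4 significant digits; the JSON run
  summary keeps full precision and contains no timestamps so reruns with
  the same seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, clustering
from .association import (
    GROUP_COMMON_ONLY,
    GROUP_DE_NOVO,
    GROUP_FAMILIAL_ONLY,
    group_subjects,
    prevalence_comparison,
)
from .characterize import (
    GeneIndex,
    GeneRecord,
    compare_sizes,
    summarize_by_class,
)
from .clustering import characterize_clusters, select_k
from .genomic import (
    ClassificationPolicy,
    CnvCall,
    CnvClass,
    CnvClassification,
    CnvState,
    GenomicInterval,
    InheritanceEvidence,
    RecordSource,
    VariantDatabase,
    VariantRecord,
    calls_by_subject,
    classify_cohort,
    filter_calls_by_probes,
    normalize_chrom,
)
from .phenotypes import (
    DeVriesRubric,
    PhenotypeMatrix,
    PhenotypeOntology,
    RubricItem,
    abnormality_counts,
    aggregate_coarse,
    filter_by_prevalence,
    score_cohort,
)
from .simulate import SyntheticStudy

__all__ = [
    "InputError",
    "RunConfig",
    "read_cnv_calls",
    "write_cnv_calls",
    "read_variant_db",
    "write_variant_db",
    "read_genes",
    "write_genes",
    "read_phenotype_matrix",
    "read_ontology",
    "read_phenotypes",
    "write_phenotype_matrix",
    "write_ontology",
    "read_rubric",
    "write_rubric",
    "write_study",
    "run_pipeline",
    "OUTPUT_FILES",
]

logger = logging.getLogger("cnvpheno")

_FLOAT_FMT = "%.4g"

_STATE_ALIASES = {
    "del": CnvState.DELETION,
    "deletion": CnvState.DELETION,
    "dup": CnvState.DUPLICATION,
    "duplication": CnvState.DUPLICATION,
    "unknown": CnvState.UNKNOWN,
    "na": CnvState.UNKNOWN,
}

_INHERITANCE_ALIASES = {
    "de_novo": InheritanceEvidence.ABSENT_IN_BOTH_PARENTS,
    "absent_in_both_parents": InheritanceEvidence.ABSENT_IN_BOTH_PARENTS,
    "parental": InheritanceEvidence.PRESENT_IN_A_PARENT,
    "present_in_a_parent": InheritanceEvidence.PRESENT_IN_A_PARENT,
    "untested": InheritanceEvidence.UNTESTED,
    "na": InheritanceEvidence.UNTESTED,
}


class InputError(ValueError):
    """Malformed input file content."""


def _read_tsv(path: Path | str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df


def _parse_int(value: str, what: str, path: Path | str, line: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise InputError(f"{path}, line {line}: {what} {value!r} is not an integer") from None


def read_cnv_calls(path: Path | str) -> list[CnvCall]:
    """Read the CNV-call TSV (1-based inclusive coordinates on disk).

    Required columns: subject_id, chrom, start, end, state, probe_count,
    inheritance.  ``state`` is del/dup (case-insensitive); ``inheritance``
    is de_novo/parental/untested/NA; probe_count NA means unknown.
    """
    df = _read_tsv(
        path, ["subject_id", "chrom", "start", "end", "state", "probe_count", "inheritance"]
    )
    calls = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        start = _parse_int(row.start, "start", path, line)
        end = _parse_int(row.end, "end", path, line)
        if start >= end or start < 1:
            raise InputError(
                f"{path}, line {line}: invalid 1-based coordinates {start}-{end}"
            )
        state_key = row.state.strip().lower()
        if state_key not in ("del", "dup", "deletion", "duplication"):
            raise InputError(f"{path}, line {line}: unknown state {row.state!r}")
        inh_key = row.inheritance.strip().lower()
        if inh_key not in _INHERITANCE_ALIASES:
            raise InputError(f"{path}, line {line}: unknown inheritance {row.inheritance!r}")
        probe_raw = row.probe_count.strip()
        probe = None if probe_raw.upper() in ("", "NA") else _parse_int(
            probe_raw, "probe_count", path, line
        )
        call_id = getattr(row, "call_id", "") or f"call_{i + 1:05d}"
        calls.append(
            CnvCall(
                call_id=call_id,
                subject_id=row.subject_id,
                interval=GenomicInterval(normalize_chrom(row.chrom), start - 1, end),
                state=_STATE_ALIASES[state_key],
                probe_count=probe,
                inheritance_evidence=_INHERITANCE_ALIASES[inh_key],
            )
        )
    return calls


def write_cnv_calls(calls: Sequence[CnvCall], path: Path | str) -> None:
    rows = [
        {
            "call_id": c.call_id,
            "subject_id": c.subject_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start + 1,
            "end": c.interval.end,
            "state": "del" if c.state is CnvState.DELETION else "dup",
            "probe_count": "NA" if c.probe_count is None else c.probe_count,
            "inheritance": {
                InheritanceEvidence.ABSENT_IN_BOTH_PARENTS: "de_novo",
                InheritanceEvidence.PRESENT_IN_A_PARENT: "parental",
                InheritanceEvidence.UNTESTED: "untested",
            }[c.inheritance_evidence],
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variant_db(path: Path | str) -> VariantDatabase:
    """Read the variant-database TSV (1-based inclusive coordinates)."""
    df = _read_tsv(path, ["chrom", "start", "end", "study_id", "source", "state"])
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        start = _parse_int(row.start, "start", path, line)
        end = _parse_int(row.end, "end", path, line)
        if start >= end or start < 1:
            raise InputError(
                f"{path}, line {line}: invalid 1-based coordinates {start}-{end}"
            )
        source_key = row.source.strip().lower()
        if source_key not in ("population_db", "internal_control"):
            raise InputError(f"{path}, line {line}: unknown source {row.source!r}")
        state_key = row.state.strip().lower()
        if state_key not in _STATE_ALIASES:
            raise InputError(f"{path}, line {line}: unknown state {row.state!r}")
        records.append(
            VariantRecord(
                interval=GenomicInterval(normalize_chrom(row.chrom), start - 1, end),
                study_id=row.study_id,
                source=RecordSource(source_key),
                state=_STATE_ALIASES[state_key],
            )
        )
    return VariantDatabase(records)


def write_variant_db(db: VariantDatabase, path: Path | str) -> None:
    rows = [
        {
            "chrom": r.interval.chrom,
            "start": r.interval.start + 1,
            "end": r.interval.end,
            "study_id": r.study_id,
            "source": r.source.value,
            "state": {
                CnvState.DELETION: "del",
                CnvState.DUPLICATION: "dup",
                CnvState.UNKNOWN: "unknown",
            }[r.state],
        }
        for r in db.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes(path: Path | str) -> list[GeneRecord]:
    """Read BED4 gene annotation (0-based half-open, no header)."""
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputError(f"{path}, line {line_no}: BED4 requires 4 columns")
            start = _parse_int(parts[1], "start", path, line_no)
            end = _parse_int(parts[2], "end", path, line_no)
            if start >= end or start < 0:
                raise InputError(f"{path}, line {line_no}: invalid BED interval")
            genes.append(
                GeneRecord(parts[3], GenomicInterval(normalize_chrom(parts[0]), start, end))
            )
    return genes


def write_genes(genes: Sequence[GeneRecord], path: Path | str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_id}\n")


def read_phenotype_matrix(path: Path | str) -> tuple[PhenotypeMatrix, int]:
    """Read the subjects x features phenotype TSV.

    Cells are {0,1,NA}; NA is mapped to absent and the number of such
    cells is returned alongside the matrix (and logged).
    """
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise InputError(f"{path}: duplicate feature column {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path}: duplicate subject id {dup!r}")
    cleaned = df.apply(lambda col: col.str.strip())
    na_mask = cleaned.isin(["NA", "na", ""])
    bad = ~(na_mask | cleaned.isin(["0", "1"]))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise InputError(
            f"{path}: invalid phenotype value {df.iloc[r, c]!r} "
            f"(subject {df.index[r]!r}, feature {df.columns[c]!r})"
        )
    n_na = int(na_mask.to_numpy().sum())
    if n_na:
        logger.info("phenotype matrix %s: %d NA cells mapped to absent", path, n_na)
    values = cleaned.where(~na_mask, "0").astype(np.int8)
    return PhenotypeMatrix(values, level="fine"), n_na


def read_ontology(path: Path | str) -> PhenotypeOntology:
    """Read the two-column (fine_id, coarse_id) ontology TSV."""
    df = _read_tsv(path, ["fine_id", "coarse_id"])
    if df["fine_id"].duplicated().any():
        dup = df["fine_id"][df["fine_id"].duplicated()].iloc[0]
        raise InputError(f"{path}: fine feature {dup!r} mapped more than once")
    order = tuple(dict.fromkeys(df["coarse_id"]))
    return PhenotypeOntology(dict(zip(df["fine_id"], df["coarse_id"])), order)


def read_phenotypes(
    matrix_path: Path | str, ontology_path: Path | str
) -> tuple[PhenotypeMatrix, PhenotypeOntology, int]:
    """Read and cross-validate the phenotype matrix and its ontology."""
    matrix, n_na = read_phenotype_matrix(matrix_path)
    ontology = read_ontology(ontology_path)
    unmapped = [f for f in matrix.features if f not in ontology.fine_to_coarse]
    if unmapped:
        raise InputError(
            f"{matrix_path}: feature {unmapped[0]!r} is absent from the ontology"
        )
    return matrix, ontology, n_na


def write_phenotype_matrix(matrix: PhenotypeMatrix, path: Path | str) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="subject_id")


def write_ontology(ontology: PhenotypeOntology, path: Path | str) -> None:
    pd.DataFrame(
        {"fine_id": list(ontology.fine_to_coarse), "coarse_id": list(ontology.fine_to_coarse.values())}
    ).to_csv(path, sep="\t", index=False)


def read_rubric(path: Path | str) -> DeVriesRubric:
    """Read a De Vries rubric YAML (items with features/weight/cap/threshold)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        items = tuple(
            RubricItem(
                name=item["name"],
                features=tuple(item["features"]),
                weight=int(item.get("weight", 1)),
                cap=int(item.get("cap", 2)),
                threshold=item.get("threshold"),
            )
            for item in doc["items"]
        )
        return DeVriesRubric(items=items, total_cap=int(doc.get("total_cap", 9)))
    except (KeyError, TypeError) as exc:
        raise InputError(f"{path}: malformed rubric ({exc})") from exc


def write_rubric(rubric: DeVriesRubric, path: Path | str) -> None:
    doc = {
        "total_cap": rubric.total_cap,
        "items": [
            {
                "name": it.name,
                "features": list(it.features),
                "weight": it.weight,
                "cap": it.cap,
                **({"threshold": it.threshold} if it.threshold is not None else {}),
            }
            for it in rubric.items
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


STUDY_FILES = {
    "calls": "calls.tsv",
    "variant_db": "variant_db.tsv",
    "genes": "genes.bed",
    "phenotypes": "phenotypes.tsv",
    "ontology": "ontology.tsv",
    "rubric": "rubric.yaml",
    "truth_calls": "truth_calls.tsv",
    "truth_subjects": "truth_subjects.tsv",
    "generator_config": "generator_config.yaml",
}


def write_study(study: SyntheticStudy, outdir: Path | str) -> dict[str, Path]:
    """Write a synthetic study to the pipeline input dialects plus truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in STUDY_FILES.items()}
    write_cnv_calls(study.calls, paths["calls"])
    write_variant_db(study.db, paths["variant_db"])
    write_genes(study.genes, paths["genes"])
    write_phenotype_matrix(study.matrix, paths["phenotypes"])
    write_ontology(study.ontology, paths["ontology"])
    write_rubric(study.rubric, paths["rubric"])
    pd.DataFrame(
        {
            "call_id": list(study.truth.call_classes),
            "true_class": [k.value for k in study.truth.call_classes.values()],
        }
    ).to_csv(paths["truth_calls"], sep="\t", index=False)
    subj_rows = []
    for subj, cluster in study.truth.subject_clusters.items():
        row = {"subject_id": subj, "true_cluster": cluster}
        row.update(
            {f"hits_{k}": v for k, v in study.truth.rubric_hits.get(subj, {}).items()}
        )
        subj_rows.append(row)
    pd.DataFrame(subj_rows).to_csv(paths["truth_subjects"], sep="\t", index=False)
    cfg = study.config.to_dict()
    cfg["seed_used"] = study.seed
    with open(paths["generator_config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


@dataclass
class RunConfig:
    """Paths and policy flags for an end-to-end pipeline run."""

    calls: Path
    variant_db: Path
    genes: Path
    phenotypes: Path
    ontology: Path
    outdir: Path
    rubric: Path | None = None
    min_probes: int = 3
    match_state: bool = False
    borderline_to_common: bool = False
    unresolved_as_familial: bool = False
    prevalence_lo: float = 0.05
    prevalence_hi: float = 0.95
    flank_bp: int = 50_000
    k_min: int = 2
    k_max: int = 10
    restarts: int = 100
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("calls", "variant_db", "genes", "phenotypes", "ontology", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.rubric is not None:
            self.rubric = Path(self.rubric)
        for name in ("calls", "variant_db", "genes", "phenotypes", "ontology"):
            if not Path(getattr(self, name)).exists():
                raise InputError(f"input file does not exist: {getattr(self, name)}")
        if self.rubric is not None and not self.rubric.exists():
            raise InputError(f"rubric file does not exist: {self.rubric}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


OUTPUT_FILES = [
    "classifications.tsv",
    "subject_groups.tsv",
    "cnv_class_summary.tsv",
    "cnv_class_summary.json",
    "size_comparisons.tsv",
    "phenotype_filter_report.tsv",
    "subject_burden.tsv",
    "association_de_novo_vs_common.tsv",
    "association_familial_vs_common.tsv",
    "cluster_assignments.tsv",
    "calinski_trace.tsv",
    "heatmap_matrix.tsv",
    "cluster_characterization.tsv",
    "run_summary.json",
    "run.log",
]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all output tables.

    Stages: probe filter -> classification -> subject grouping ->
    per-class summary and size tests -> coarse aggregation and
    prevalence filtering -> burden and De Vries scores -> both
    prevalence contrasts at both ontology levels -> K selection,
    clustering and cluster characterization.  Returns the run summary
    (also written as JSON); any stage failure raises with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "stages": {}}
    stage = "read_inputs"
    try:
        calls = read_cnv_calls(config.calls)
        db = read_variant_db(config.variant_db)
        genes = read_genes(config.genes)
        matrix, ontology, n_na = read_phenotypes(config.phenotypes, config.ontology)
        rubric = read_rubric(config.rubric) if config.rubric else None
        summary["stages"][stage] = {
            "n_calls": len(calls),
            "n_db_records": len(db),
            "n_genes": len(genes),
            "n_subjects": matrix.n_subjects,
            "n_fine_features": len(matrix.features),
            "n_na_cells": n_na,
        }
        logger.info("inputs: %s", summary["stages"][stage])

        stage = "probe_filter"
        filtered = filter_calls_by_probes(calls, config.min_probes)
        summary["stages"][stage] = {
            "min_probes": config.min_probes,
            "n_calls_in": len(calls),
            "n_calls_kept": len(filtered),
        }

        stage = "classify"
        policy = ClassificationPolicy(
            match_state=config.match_state,
            borderline_to_common=config.borderline_to_common,
        )
        classifications = classify_cohort(filtered, db, policy)
        assert len(classifications) == len(filtered), "calls in != calls classified"
        class_counts = {k.value: 0 for k in CnvClass}
        for c in classifications:
            class_counts[c.klass.value] += 1
        summary["stages"][stage] = {"class_counts": class_counts}
        logger.info("classification counts: %s", class_counts)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "call_id": c.call_id,
                        "subject_id": call.subject_id,
                        "klass": c.klass.value,
                        "coverage": c.coverage,
                        "supporting_studies": c.supporting_studies,
                        "internal_control_hit": c.internal_control_hit,
                        "borderline": c.borderline,
                    }
                    for call, c in zip(filtered, classifications)
                ]
            ),
            outdir / "classifications.tsv",
            index=False,
        )

        stage = "group_subjects"
        per_subject = calls_by_subject(filtered, classifications)
        call_subjects = set(per_subject)
        matrix_subjects = set(matrix.subjects)
        if not call_subjects <= matrix_subjects:
            logger.warning(
                "%d call subjects absent from the phenotype matrix",
                len(call_subjects - matrix_subjects),
            )
        grouping = group_subjects(
            per_subject,
            subjects=sorted(matrix_subjects),
            unresolved_as_familial=config.unresolved_as_familial,
        )
        summary["stages"][stage] = {
            "sizes": grouping.sizes,
            "dual_carriers": sorted(grouping.dual_carriers),
            "unresolved_as_familial": config.unresolved_as_familial,
        }
        logger.info("group sizes: %s", grouping.sizes)
        _write_tsv(
            pd.DataFrame(
                {
                    "subject_id": list(grouping.group_of),
                    "group": list(grouping.group_of.values()),
                    "dual_carrier": [
                        s in grouping.dual_carriers for s in grouping.group_of
                    ],
                }
            ).sort_values("subject_id"),
            outdir / "subject_groups.tsv",
            index=False,
        )

        stage = "summarize_classes"
        summary_table = summarize_by_class(
            filtered, classifications, genes, matrix.n_subjects, config.flank_bp
        )
        _write_tsv(summary_table, outdir / "cnv_class_summary.tsv")
        (outdir / "cnv_class_summary.json").write_text(
            json.dumps(json.loads(summary_table.to_json()), indent=2, sort_keys=True)
        )
        sizes_by_class: dict[str, list[float]] = {}
        for call, c in zip(filtered, classifications):
            sizes_by_class.setdefault(c.klass.value, []).append(call.size_mb)
        size_tests = []
        pairs = [
            (CnvClass.DE_NOVO.value, CnvClass.COMMON.value),
            (CnvClass.FAMILIAL.value, CnvClass.COMMON.value),
            (CnvClass.DE_NOVO.value, CnvClass.FAMILIAL.value),
        ]
        for a, b in pairs:
            if sizes_by_class.get(a) and sizes_by_class.get(b):
                res = compare_sizes(sizes_by_class[a], sizes_by_class[b])
                size_tests.append(
                    {
                        "class_a": a,
                        "class_b": b,
                        "n_a": len(sizes_by_class[a]),
                        "n_b": len(sizes_by_class[b]),
                        "statistic": res.statistic,
                        "p_value": res.pvalue,
                        "method": res.method,
                    }
                )
        _write_tsv(pd.DataFrame(size_tests), outdir / "size_comparisons.tsv", index=False)
        summary["stages"][stage] = {"size_tests": size_tests}

        stage = "phenotype_processing"
        coarse = aggregate_coarse(matrix, ontology)
        fine_f, fine_removed = filter_by_prevalence(
            matrix, config.prevalence_lo, config.prevalence_hi
        )
        coarse_f, coarse_removed = filter_by_prevalence(
            coarse, config.prevalence_lo, config.prevalence_hi
        )
        fine_removed.insert(0, "level", "fine")
        coarse_removed.insert(0, "level", "coarse")
        _write_tsv(
            pd.concat([coarse_removed, fine_removed], ignore_index=True),
            outdir / "phenotype_filter_report.tsv",
            index=False,
        )
        fine_counts, fine_median = abnormality_counts(fine_f)
        coarse_counts, coarse_median = abnormality_counts(coarse_f)
        burden = pd.DataFrame(
            {"coarse_abnormalities": coarse_counts, "fine_abnormalities": fine_counts}
        )
        scores = None
        if rubric is not None:
            scores = score_cohort(matrix, rubric)
            burden["de_vries_score"] = scores
        _write_tsv(burden, outdir / "subject_burden.tsv")
        summary["stages"][stage] = {
            "n_coarse_total": len(coarse.features),
            "n_coarse_retained": len(coarse_f.features),
            "n_fine_total": len(matrix.features),
            "n_fine_retained": len(fine_f.features),
            "median_coarse_abnormalities": coarse_median,
            "median_fine_abnormalities": fine_median,
            "median_de_vries_score": (
                float(np.median(scores)) if scores is not None else None
            ),
        }
        logger.info("phenotypes: %s", summary["stages"][stage])

        stage = "prevalence_contrasts"
        contrasts = {
            "association_de_novo_vs_common.tsv": (
                (GROUP_DE_NOVO, GROUP_COMMON_ONLY),
                frozenset(),
            ),
            "association_familial_vs_common.tsv": (
                (GROUP_FAMILIAL_ONLY, GROUP_COMMON_ONLY),
                grouping.dual_carriers,
            ),
        }
        contrast_summary = {}
        for fname, (contrast, exclude) in contrasts.items():
            frames = []
            for level, mat in (("coarse", coarse_f), ("fine", fine_f)):
                n_a = len(
                    [s for s in grouping.members(contrast[0]) if s not in exclude]
                )
                n_b = len(
                    [s for s in grouping.members(contrast[1]) if s not in exclude]
                )
                if n_a == 0 or n_b == 0:
                    logger.warning(
                        "skipping %s/%s contrast at %s level: empty group "
                        "(n_a=%d, n_b=%d)",
                        *contrast,
                        level,
                        n_a,
                        n_b,
                    )
                    contrast_summary[f"{fname}:{level}"] = "skipped_empty_group"
                    continue
                table = prevalence_comparison(mat, grouping, contrast, exclude)
                table.insert(0, "level", level)
                frames.append(table.reset_index())
                contrast_summary[f"{fname}:{level}"] = {
                    "n_features": len(table),
                    "n_q_lt_05": int((table["q_value"] < 0.05).sum()),
                }
            out = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(
                    columns=["level", "feature", "n_a", "abnormal_a", "prevalence_a",
                             "n_b", "abnormal_b", "prevalence_b", "p_value", "q_value"]
                )
            )
            _write_tsv(out, outdir / fname, index=False)
        summary["stages"][stage] = contrast_summary

        stage = "clustering"
        if len(fine_f.features) < 2 or fine_f.n_subjects < 4:
            logger.warning("skipping clustering: matrix too small after filtering")
            summary["stages"][stage] = "skipped_matrix_too_small"
            for fname in (
                "cluster_assignments.tsv",
                "calinski_trace.tsv",
                "heatmap_matrix.tsv",
                "cluster_characterization.tsv",
            ):
                _write_tsv(pd.DataFrame(), outdir / fname, index=False)
        else:
            k_max = min(config.k_max, fine_f.n_subjects - 1)
            result = select_k(
                fine_f,
                k_range=range(config.k_min, k_max + 1),
                restarts=config.restarts,
                seed=config.seed,
            )
            character = characterize_clusters(fine_f, result)
            # heat-map-ready ordering: subjects by cluster, features by prevalence
            feature_order = (
                fine_f.data.mean(axis=0).sort_values(ascending=False).index
            )
            assignments = result.assignments.sort_values(kind="mergesort")
            _write_tsv(
                pd.DataFrame(
                    {
                        "cluster": assignments,
                        "abnormality_count": character.counts.reindex(assignments.index),
                    }
                ),
                outdir / "cluster_assignments.tsv",
            )
            _write_tsv(
                pd.DataFrame(
                    {
                        "k": list(result.per_k_ch),
                        "calinski_index": list(result.per_k_ch.values()),
                    }
                ),
                outdir / "calinski_trace.tsv",
                index=False,
            )
            heatmap = fine_f.data.loc[assignments.index, feature_order]
            _write_tsv(heatmap, outdir / "heatmap_matrix.tsv")
            if character.feature_table is not None:
                _write_tsv(
                    character.feature_table, outdir / "cluster_characterization.tsv"
                )
            else:
                _write_tsv(
                    pd.DataFrame(), outdir / "cluster_characterization.tsv", index=False
                )
            summary["stages"][stage] = {
                "chosen_k": result.chosen_k,
                "restarts": result.restarts,
                "k_range": [config.k_min, k_max],
                "per_k_calinski": {
                    str(k): (v if np.isfinite(v) else "inf")
                    for k, v in result.per_k_ch.items()
                },
                "cluster_mean_counts": {
                    k: float(v) for k, v in character.mean_counts.items()
                },
                "count_test_p": [
                    float(p) for p in character.count_tests["p_value"]
                ],
                "n_features_q_lt_05": (
                    int((character.feature_table["q_value"] < 0.05).sum())
                    if character.feature_table is not None
                    else None
                ),
            }
            logger.info("clustering: %s", summary["stages"][stage])

        stage = "write_summary"
        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
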