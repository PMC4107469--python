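"""Seeded generator of a full synthetic study with known ground truth.

Emulates the shape of a deeply phenotyped intellectual-disability
cohort: a study-attributed population-variant database, per-subject CNV
calls with known common / de novo / familial classes, a gene
annotation, and a binary fine-phenotype matrix with two planted subject
clusters of differing abnormality burden.  Defaults reproduce the
published cohort shape (78 subjects; ~6 common calls/subject; 21 de
novo calls in 18 carriers and 27 familial calls in 22 carriers with 2
dual carriers; per-class log-normal size distributions with
median/mean 0.14/0.42, 0.43/0.70 and 2.46/3.14 Mb; deletion
proportions 0.59, 0.30 and 0.67; cluster burden means 28 vs 13 abnormal
features out of 80 fine features in 32 coarse categories).

Common calls are placed inside "common template" regions that the
database covers completely with records from >= 2 distinct studies (or
an internal control), so the classifier recovers the planted class by
construction; unique calls are rejection-sampled to keep database
coverage below 0.5.  Everything is deterministic given (config, seed):
each generator draws from its own fixed seed stream, so the database
and the calls can be generated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic import (
    ClassificationPolicy,
    CnvCall,
    CnvClass,
    CnvState,
    GenomicInterval,
    InheritanceEvidence,
    RecordSource,
    VariantDatabase,
    VariantRecord,
    coverage_fraction,
)
from .characterize import GeneRecord
from .phenotypes import DeVriesRubric, PhenotypeMatrix, PhenotypeOntology, default_rubric

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "lognormal_params",
    "generate_variant_db",
    "generate_cohort_cnvs",
    "generate_genes",
    "generate_phenotypes",
    "generate_study",
]

# fixed per-generator seed-stream offsets so (config, seed) fully
# determines every artifact independently of call order
_STREAM_TEMPLATES = 10
_STREAM_DB = 11
_STREAM_CNVS = 12
_STREAM_PHENOTYPES = 13
_STREAM_GENES = 14


def lognormal_params(median_mb: float, mean_mb: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and mean (Mb).

    mu = ln(median); sigma = sqrt(2 ln(mean/median)).
    """
    if not 0 < median_mb <= mean_mb:
        raise ValueError("require 0 < median <= mean")
    return math.log(median_mb), math.sqrt(2.0 * math.log(mean_mb / median_mb))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shape parameters; defaults emulate the published cohort."""

    n_subjects: int = 78
    # cohort CNV structure
    common_calls_per_subject: float = 6.14  # Poisson mean (479/78)
    n_de_novo_calls: int = 21
    n_de_novo_carriers: int = 18
    n_familial_calls: int = 27
    n_familial_carriers: int = 22
    n_dual_carriers: int = 2
    # per-class size distributions: (median Mb, mean Mb)
    size_common: tuple[float, float] = (0.14, 0.42)
    size_familial: tuple[float, float] = (0.43, 0.70)
    size_de_novo: tuple[float, float] = (2.46, 3.14)
    min_call_bp: int = 10_000
    # per-class deletion proportions
    del_prop_common: float = 0.59
    del_prop_familial: float = 0.30
    del_prop_de_novo: float = 0.67
    probe_count_range: tuple[int, int] = (3, 60)
    # genome model
    n_chromosomes: int = 22
    chrom_length: int = 100_000_000
    # variant database
    n_templates: int = 300
    n_studies: int = 12
    internal_control_fraction: float = 0.15
    n_decoy_records: int = 60
    template_size: tuple[float, float] = (0.3, 1.0)  # (median, mean) Mb
    # gene annotation
    n_genes: int = 15_000
    gene_mean_length: int = 30_000
    # phenotypes: two planted clusters over n_fine binary features
    n_fine: int = 80
    n_coarse: int = 32
    cluster_sizes: tuple[int, int] = (40, 38)
    burden_means: tuple[float, float] = (28.0, 13.0)
    n_differential: int = 20
    prevalence_high: float = 0.85
    prevalence_low: float = 0.10
    #: cluster-independent prevalences of the rubric-bound features,
    #: chosen to emulate a severely affected cohort (checklist-based
    #: enrolment); they give an expected De Vries score around 5
    rubric_prevalence: tuple[tuple[str, float], ...] = (
        ("family_history_of_id", 0.60),
        ("prenatal_growth_retardation", 0.40),
        ("microcephaly", 0.30),
        ("short_stature", 0.30),
        ("macrocephaly", 0.30),
        ("tall_stature", 0.30),
        ("facial_01", 0.60),
        ("facial_02", 0.60),
        ("facial_03", 0.60),
        ("facial_04", 0.60),
        ("congenital_anomaly_01", 0.40),
        ("congenital_anomaly_02", 0.40),
    )
    max_placement_retries: int = 200
    seed: int = 1

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.n_subjects:
            raise ValueError("cluster sizes must sum to n_subjects")
        if self.n_dual_carriers > min(self.n_de_novo_carriers, self.n_familial_carriers):
            raise ValueError("dual carriers cannot exceed either carrier group")
        if self.n_de_novo_calls < self.n_de_novo_carriers:
            raise ValueError("need >= 1 de novo call per carrier")
        if self.n_familial_calls < self.n_familial_carriers:
            raise ValueError("need >= 1 familial call per carrier")
        if (
            self.n_familial_carriers - self.n_dual_carriers
            > self.n_subjects - self.n_de_novo_carriers
        ):
            raise ValueError(
                "not enough non-de-novo subjects for the familial-only carriers"
            )
        for p in self.baseline_prevalences:
            if not 0 <= p <= 1:
                raise ValueError(
                    "burden means are unreachable with the configured "
                    "differential-feature profile (baseline prevalence outside [0,1])"
                )

    @property
    def subject_ids(self) -> list[str]:
        return [f"s{i:03d}" for i in range(1, self.n_subjects + 1)]

    @property
    def baseline_prevalences(self) -> tuple[float, float]:
        """Shared-feature prevalence per cluster, solved from the burden means.

        The expected abnormality burden decomposes into the fixed
        rubric-feature part, the differential part, and the shared
        baseline, which absorbs whatever is left so that the planted
        burden means hold exactly in expectation.
        """
        rubric_sum = sum(p for _, p in self.rubric_prevalence)
        n_shared = self.n_fine - self.n_differential - len(self.rubric_prevalence)
        if n_shared <= 0:
            raise ValueError("no shared features left for the baseline solve")
        high = (
            self.burden_means[0]
            - rubric_sum
            - self.n_differential * self.prevalence_high
        ) / n_shared
        low = (
            self.burden_means[1]
            - rubric_sum
            - self.n_differential * self.prevalence_low
        ) / n_shared
        return high, low

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth for every generated call and subject."""

    call_classes: dict[str, CnvClass] = field(default_factory=dict)
    subject_clusters: dict[str, int] = field(default_factory=dict)
    rubric_hits: dict[str, dict[str, int]] = field(default_factory=dict)


def _sample_templates(config: GeneratorConfig, seed: int) -> list[GenomicInterval]:
    """Common-template regions; identical for the db and the call generator."""
    rng = np.random.default_rng([seed, _STREAM_TEMPLATES])
    mu, sigma = lognormal_params(*config.template_size)
    templates = []
    for _ in range(config.n_templates):
        size = int(rng.lognormal(mu, sigma) * 1e6)
        size = max(config.min_call_bp * 2, min(size, config.chrom_length // 4))
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        start = int(rng.integers(0, config.chrom_length - size))
        templates.append(GenomicInterval(chrom, start, start + size))
    return templates


def generate_variant_db(config: GeneratorConfig, seed: int) -> VariantDatabase:
    """Study-attributed variant database built around common templates.

    Every template is fully covered either by records from >= 2 distinct
    population studies or (for a configurable fraction) by an
    internal-control record, so calls placed inside a template satisfy
    the common rule.  Additional single-study decoy records exercise the
    "one study is not enough" branch.
    """
    templates = _sample_templates(config, seed)
    rng = np.random.default_rng([seed, _STREAM_DB])
    studies = [f"study_{i:02d}" for i in range(1, config.n_studies + 1)]
    states = [CnvState.DELETION, CnvState.DUPLICATION, CnvState.UNKNOWN]
    records: list[VariantRecord] = []
    n_internal = int(round(config.internal_control_fraction * len(templates)))
    for i, template in enumerate(templates):
        if i < n_internal:
            records.append(
                VariantRecord(
                    interval=template,
                    study_id="internal",
                    source=RecordSource.INTERNAL_CONTROL,
                    state=states[rng.integers(0, 3)],
                )
            )
        else:
            n_sup = int(rng.integers(2, 4))  # 2 or 3 supporting studies
            chosen = rng.choice(len(studies), size=n_sup, replace=False)
            for j in chosen:
                records.append(
                    VariantRecord(
                        interval=template,
                        study_id=studies[j],
                        source=RecordSource.POPULATION_DB,
                        state=states[rng.integers(0, 3)],
                    )
                )
    # single-study decoys: fully cover a region but lack the 2-study support
    mu, sigma = lognormal_params(*config.template_size)
    for _ in range(config.n_decoy_records):
        size = max(config.min_call_bp, int(rng.lognormal(mu, sigma) * 1e6))
        size = min(size, config.chrom_length // 4)
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        start = int(rng.integers(0, config.chrom_length - size))
        records.append(
            VariantRecord(
                interval=GenomicInterval(chrom, start, start + size),
                study_id=studies[int(rng.integers(0, len(studies)))],
                source=RecordSource.POPULATION_DB,
                state=states[rng.integers(0, 3)],
            )
        )
    return VariantDatabase(records)


def _multi_carrier_counts(n_calls: int, n_carriers: int) -> list[int]:
    """Distribute calls over carriers: everyone >= 1, extras spread 1-at-a-time."""
    counts = [1] * n_carriers
    extra = n_calls - n_carriers
    i = 0
    while extra > 0:
        counts[i % n_carriers] += 1
        extra -= 1
        i += 1
    return counts


def _place_unique_call(
    rng: np.random.Generator,
    config: GeneratorConfig,
    db: VariantDatabase,
    size: int,
) -> GenomicInterval:
    """Interval with database union coverage < 0.5, by rejection sampling."""
    probe = CnvState.DELETION
    for _ in range(config.max_placement_retries):
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        start = int(rng.integers(0, config.chrom_length - size))
        iv = GenomicInterval(chrom, start, start + size)
        call = CnvCall("probe", "probe", iv, probe)
        frac, _ = coverage_fraction(call, db)
        if frac < 0.5:
            return iv
    raise RuntimeError(
        "could not place a unique call with db coverage < 0.5; "
        "use a larger genome or fewer/smaller database records"
    )


def generate_cohort_cnvs(
    config: GeneratorConfig, db: VariantDatabase, seed: int
) -> tuple[list[CnvCall], SyntheticTruth]:
    """Per-subject CNV calls with planted classes.

    ``db`` must come from :func:`generate_variant_db` with the same
    (config, seed) so the two generators agree on the template regions.
    """
    templates = _sample_templates(config, seed)
    rng = np.random.default_rng([seed, _STREAM_CNVS])
    subjects = config.subject_ids

    dn_idx = rng.choice(config.n_subjects, size=config.n_de_novo_carriers, replace=False)
    dn_carriers = [subjects[i] for i in sorted(dn_idx)]
    dual = list(rng.choice(dn_carriers, size=config.n_dual_carriers, replace=False))
    non_dn = [s for s in subjects if s not in set(dn_carriers)]
    fam_only_n = config.n_familial_carriers - config.n_dual_carriers
    fam_idx = rng.choice(len(non_dn), size=fam_only_n, replace=False)
    fam_carriers = sorted(dual) + [non_dn[i] for i in sorted(fam_idx)]

    class_specs = {
        CnvClass.DE_NOVO: (
            dn_carriers,
            _multi_carrier_counts(config.n_de_novo_calls, config.n_de_novo_carriers),
            config.size_de_novo,
            config.del_prop_de_novo,
            InheritanceEvidence.ABSENT_IN_BOTH_PARENTS,
        ),
        CnvClass.FAMILIAL: (
            fam_carriers,
            _multi_carrier_counts(config.n_familial_calls, config.n_familial_carriers),
            config.size_familial,
            config.del_prop_familial,
            InheritanceEvidence.PRESENT_IN_A_PARENT,
        ),
    }

    calls: list[CnvCall] = []
    truth = SyntheticTruth()
    counter = 0

    def _next_id() -> str:
        nonlocal counter
        counter += 1
        return f"cnv_{counter:05d}"

    template_lengths = np.array([t.length for t in templates])
    mu_c, sigma_c = lognormal_params(*config.size_common)
    lo_p, hi_p = config.probe_count_range
    for subject in subjects:
        n_common = int(rng.poisson(config.common_calls_per_subject))
        for _ in range(n_common):
            size = max(config.min_call_bp, int(rng.lognormal(mu_c, sigma_c) * 1e6))
            fits = np.flatnonzero(template_lengths >= size)
            if fits.size == 0:  # clamp to the largest template
                t_i = int(template_lengths.argmax())
                size = int(template_lengths[t_i])
            else:
                t_i = int(fits[rng.integers(0, fits.size)])
            template = templates[t_i]
            start = template.start + int(
                rng.integers(0, template.length - size + 1)
            )
            state = (
                CnvState.DELETION
                if rng.random() < config.del_prop_common
                else CnvState.DUPLICATION
            )
            call = CnvCall(
                call_id=_next_id(),
                subject_id=subject,
                interval=GenomicInterval(template.chrom, start, start + size),
                state=state,
                probe_count=int(rng.integers(lo_p, hi_p + 1)),
                inheritance_evidence=InheritanceEvidence.UNTESTED,
            )
            calls.append(call)
            truth.call_classes[call.call_id] = CnvClass.COMMON

    for klass, (carriers, counts, size_mm, del_prop, evidence) in class_specs.items():
        mu, sigma = lognormal_params(*size_mm)
        for subject, n_calls in zip(carriers, counts):
            for _ in range(n_calls):
                size = max(config.min_call_bp, int(rng.lognormal(mu, sigma) * 1e6))
                size = min(size, config.chrom_length // 4)
                iv = _place_unique_call(rng, config, db, size)
                state = (
                    CnvState.DELETION
                    if rng.random() < del_prop
                    else CnvState.DUPLICATION
                )
                call = CnvCall(
                    call_id=_next_id(),
                    subject_id=subject,
                    interval=iv,
                    state=state,
                    probe_count=int(rng.integers(lo_p, hi_p + 1)),
                    inheritance_evidence=evidence,
                )
                calls.append(call)
                truth.call_classes[call.call_id] = klass
    return calls, truth


def generate_genes(config: GeneratorConfig, seed: int) -> list[GeneRecord]:
    """Uniformly placed gene loci with exponential lengths (floor 200 bp)."""
    rng = np.random.default_rng([seed, _STREAM_GENES])
    genes = []
    for i in range(config.n_genes):
        length = max(200, int(rng.exponential(config.gene_mean_length)))
        length = min(length, config.chrom_length // 10)
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        start = int(rng.integers(0, config.chrom_length - length))
        genes.append(
            GeneRecord(f"g{i + 1:05d}", GenomicInterval(chrom, start, start + length))
        )
    return genes


#: fine features bound to the De Vries rubric items; these are the first
#: features of the synthetic ontology so scores are always computable
RUBRIC_BINDINGS = {
    "family_history": ["family_history_of_id"],
    "prenatal_growth_retardation": ["prenatal_growth_retardation"],
    "postnatal_growth_abnormalities": [
        "microcephaly",
        "short_stature",
        "macrocephaly",
        "tall_stature",
    ],
    "facial_dysmorphism": ["facial_01", "facial_02", "facial_03", "facial_04"],
    "congenital_anomalies": ["congenital_anomaly_01", "congenital_anomaly_02"],
}


def _fine_feature_names(config: GeneratorConfig) -> list[str]:
    named = [f for feats in RUBRIC_BINDINGS.values() for f in feats]
    if config.n_fine < len(named):
        raise ValueError(f"n_fine must be >= {len(named)} to fit the rubric features")
    generic = [f"fine_{i:03d}" for i in range(len(named) + 1, config.n_fine + 1)]
    return named + generic


def generate_phenotypes(
    config: GeneratorConfig, seed: int
) -> tuple[PhenotypeMatrix, PhenotypeOntology, DeVriesRubric, SyntheticTruth]:
    """Binary fine-phenotype matrix with two planted clusters.

    Features are independent Bernoulli given the subject's cluster:
    ``n_differential`` features have prevalence ``prevalence_high`` in
    cluster 1 vs ``prevalence_low`` in cluster 2; the remaining shared
    features get per-cluster baselines solved so that the expected
    abnormality burdens equal ``burden_means``.  The ontology maps the
    fine features into ``n_coarse`` categories in contiguous blocks, and
    the first features realise the De Vries rubric bindings.
    """
    rng = np.random.default_rng([seed, _STREAM_PHENOTYPES])
    features = _fine_feature_names(config)
    subjects = config.subject_ids
    n1, _ = config.cluster_sizes
    clusters = np.array([1] * n1 + [2] * (config.n_subjects - n1))

    # differential features are the last n_differential; rubric-bound
    # features keep their own cluster-independent prevalences
    n_diff = config.n_differential
    base_high, base_low = config.baseline_prevalences
    prev = np.empty((2, config.n_fine))
    prev[0, :] = base_high
    prev[1, :] = base_low
    prev[0, config.n_fine - n_diff :] = config.prevalence_high
    prev[1, config.n_fine - n_diff :] = config.prevalence_low
    col_of = {f: i for i, f in enumerate(features)}
    for name, p in config.rubric_prevalence:
        prev[:, col_of[name]] = p

    draws = rng.random((config.n_subjects, config.n_fine))
    values = (draws < prev[clusters - 1]).astype(np.int8)
    matrix = PhenotypeMatrix(
        pd.DataFrame(values, index=pd.Index(subjects, name="subject_id"), columns=features),
        level="fine",
    )

    coarse_names = [f"coarse_{i:02d}" for i in range(1, config.n_coarse + 1)]
    fine_to_coarse = {
        f: coarse_names[i * config.n_coarse // config.n_fine]
        for i, f in enumerate(features)
    }
    ontology = PhenotypeOntology(fine_to_coarse, tuple(coarse_names))
    rubric = default_rubric(RUBRIC_BINDINGS)

    truth = SyntheticTruth()
    for subj, lab in zip(subjects, clusters):
        truth.subject_clusters[subj] = int(lab)
        present = set(matrix.data.columns[matrix.data.loc[subj].astype(bool)])
        truth.rubric_hits[subj] = rubric.item_hits(present)
    return matrix, ontology, rubric, truth


@dataclass
class SyntheticStudy:
    config: GeneratorConfig
    seed: int
    db: VariantDatabase
    calls: list[CnvCall]
    genes: list[GeneRecord]
    matrix: PhenotypeMatrix
    ontology: PhenotypeOntology
    rubric: DeVriesRubric
    truth: SyntheticTruth


def generate_study(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> SyntheticStudy:
    """Generate the complete synthetic study (db, calls, genes, phenotypes)."""
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else seed
    db = generate_variant_db(config, seed)
    calls, cnv_truth = generate_cohort_cnvs(config, db, seed)
    genes = generate_genes(config, seed)
    matrix, ontology, rubric, pheno_truth = generate_phenotypes(config, seed)
    truth = SyntheticTruth(
        call_classes=cnv_truth.call_classes,
        subject_clusters=pheno_truth.subject_clusters,
        rubric_hits=pheno_truth.rubric_hits,
    )
    return SyntheticStudy(
        config=config,
        seed=seed,
        db=db,
        calls=calls,
        genes=genes,
        matrix=matrix,
        ontology=ontology,
        rubric=rubric,
        truth=truth,
    )
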