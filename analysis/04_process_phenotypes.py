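"""Phenotype-matrix processing: aggregation, filtering, burden, De Vries.

OR-aggregates fine features into coarse categories, removes features
with < 5% or > 95% prevalence at each level independently, computes
per-subject abnormality counts, and scores the five-item De Vries
checklist.  Writes ``results/phenotype_filter_report.tsv`` and
``results/subject_burden.tsv``.
"""

import numpy as np
import pandas as pd

import cnvpheno.io as pio
from _cohort import RESULTS, ensure_cohort
from cnvpheno.phenotypes import (
    abnormality_counts,
    aggregate_coarse,
    filter_by_prevalence,
    score_cohort,
)


def main() -> None:
    paths = ensure_cohort()
    matrix, ontology, _ = pio.read_phenotypes(paths["phenotypes"], paths["ontology"])
    rubric = pio.read_rubric(paths["rubric"])

    coarse = aggregate_coarse(matrix, ontology)
    fine_f, fine_removed = filter_by_prevalence(matrix)
    coarse_f, coarse_removed = filter_by_prevalence(coarse)
    fine_removed.insert(0, "level", "fine")
    coarse_removed.insert(0, "level", "coarse")
    RESULTS.mkdir(exist_ok=True)
    pd.concat([coarse_removed, fine_removed], ignore_index=True).to_csv(
        RESULTS / "phenotype_filter_report.tsv", sep="\t", index=False,
        float_format="%.4g",
    )

    fine_counts, fine_median = abnormality_counts(fine_f)
    coarse_counts, coarse_median = abnormality_counts(coarse_f)
    scores = score_cohort(matrix, rubric)
    pd.DataFrame(
        {
            "coarse_abnormalities": coarse_counts,
            "fine_abnormalities": fine_counts,
            "de_vries_score": scores,
        }
    ).to_csv(RESULTS / "subject_burden.tsv", sep="\t")

    print(f"coarse features: {len(coarse.features)} -> {len(coarse_f.features)} after filter")
    print(f"fine features:   {len(matrix.features)} -> {len(fine_f.features)} after filter")
    print(f"median abnormalities/subject: coarse {coarse_median}, fine {fine_median}")
    print(f"median De Vries score: {np.median(scores)}"
          f" ({(scores >= 3).mean():.0%} of subjects score >= 3)")


if __name__ == "__main__":
    main()
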