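"""Per-phenotype prevalence comparison across CNV groups.

Groups subjects by their CNV classes (de novo / familial-only /
common-only), then compares each retained phenotype's prevalence
between groups with Fisher's exact test and BH correction: de novo vs
common-only, and familial-only vs common-only with the two dual
de novo + familial carriers excluded.  Writes
``results/association_<contrast>.tsv`` at both ontology levels.
"""

import pandas as pd

import cnvpheno.io as pio
from _cohort import RESULTS, ensure_cohort
from cnvpheno.association import group_subjects, prevalence_comparison
from cnvpheno.genomic import calls_by_subject, classify_cohort
from cnvpheno.phenotypes import aggregate_coarse, filter_by_prevalence


def main() -> None:
    paths = ensure_cohort()
    calls = pio.read_cnv_calls(paths["calls"])
    db = pio.read_variant_db(paths["variant_db"])
    matrix, ontology, _ = pio.read_phenotypes(paths["phenotypes"], paths["ontology"])
    classifications = classify_cohort(calls, db)
    grouping = group_subjects(
        calls_by_subject(calls, classifications), subjects=matrix.subjects
    )
    print(f"group sizes: {grouping.sizes}; dual carriers: {sorted(grouping.dual_carriers)}")

    fine_f, _ = filter_by_prevalence(matrix)
    coarse_f, _ = filter_by_prevalence(aggregate_coarse(matrix, ontology))
    RESULTS.mkdir(exist_ok=True)
    for name, contrast, exclude in (
        ("de_novo_vs_common", ("de_novo", "common_only"), frozenset()),
        ("familial_vs_common", ("familial_only", "common_only"), grouping.dual_carriers),
    ):
        frames = []
        for level, mat in (("coarse", coarse_f), ("fine", fine_f)):
            table = prevalence_comparison(mat, grouping, contrast, exclude)
            table.insert(0, "level", level)
            frames.append(table.reset_index())
            n_sig = int((table["q_value"] < 0.05).sum())
            print(f"{name} ({level}): {len(table)} features tested, "
                  f"{n_sig} with q < 0.05")
        pd.concat(frames, ignore_index=True).to_csv(
            RESULTS / f"association_{name}.tsv", sep="\t", index=False,
            float_format="%.4g",
        )


if __name__ == "__main__":
    main()
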