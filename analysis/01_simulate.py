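"""Generate the synthetic study cohort used by all downstream scripts.

Writes a 78-subject cohort with the configured shape — ~6 common CNV
calls per subject, 21 de novo calls in 18 carriers, 27 familial calls
in 22 carriers (2 dual carriers), a study-attributed variant database,
a gene annotation, and an 80-feature binary phenotype matrix with two
planted clusters — plus the ground-truth files, to
``results/synthetic_cohort/``.
"""

import pandas as pd

from _cohort import COHORT_DIR, SEED, ensure_cohort


def main() -> None:
    paths = ensure_cohort()
    calls = pd.read_csv(paths["calls"], sep="\t")
    truth = pd.read_csv(paths["truth_calls"], sep="\t")
    pheno = pd.read_csv(paths["phenotypes"], sep="\t", index_col=0)
    print(f"cohort written to {COHORT_DIR} (seed {SEED})")
    print(f"  {len(calls)} CNV calls in {calls['subject_id'].nunique()} subjects")
    print(f"  planted classes: {truth['true_class'].value_counts().to_dict()}")
    print(f"  phenotypes: {pheno.shape[0]} subjects x {pheno.shape[1]} fine features")


if __name__ == "__main__":
    main()
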