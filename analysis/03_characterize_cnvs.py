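"""Per-class CNV feature summary and between-class size comparison.

Builds the per-class table (counts, carriers, calls/subject, size
statistics, genes per call with a 50 kb flank, proportion > 1 Mb,
proportion of deletions) and tests the size differences between
classes with the Wilcoxon rank-sum test.  Writes
``results/cnv_class_summary.tsv`` and ``results/size_comparisons.tsv``.
"""

import pandas as pd

import cnvpheno.io as pio
from _cohort import RESULTS, ensure_cohort
from cnvpheno.characterize import compare_sizes, summarize_by_class
from cnvpheno.genomic import classify_cohort


def main() -> None:
    paths = ensure_cohort()
    calls = pio.read_cnv_calls(paths["calls"])
    db = pio.read_variant_db(paths["variant_db"])
    genes = pio.read_genes(paths["genes"])
    pheno = pd.read_csv(paths["phenotypes"], sep="\t", index_col=0)
    classifications = classify_cohort(calls, db)

    table = summarize_by_class(calls, classifications, genes, len(pheno))
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "cnv_class_summary.tsv", sep="\t", float_format="%.4g")
    print(table.round(3).to_string())

    sizes = {}
    for call, c in zip(calls, classifications):
        sizes.setdefault(c.klass.value, []).append(call.size_mb)
    rows = []
    for a, b in [("de_novo", "common"), ("familial", "common"), ("de_novo", "familial")]:
        res = compare_sizes(sizes[a], sizes[b])
        rows.append({"class_a": a, "class_b": b, "statistic": res.statistic,
                     "p_value": res.pvalue, "method": res.method})
        print(f"size {a} vs {b}: rank-sum p = {res.pvalue:.3g}")
    pd.DataFrame(rows).to_csv(RESULTS / "size_comparisons.tsv", sep="\t",
                              index=False, float_format="%.4g")


if __name__ == "__main__":
    main()
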