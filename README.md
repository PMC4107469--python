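# cnvpheno

Rule-based copy-number-variant (CNV) classification and deep-phenotype
association analysis for intellectual-disability (ID) cohorts.

Chromosome-microarray screening of subjects with ID yields a mix of CNV
calls: abundant polymorphisms shared with the general population, rarer
variants inherited from a parent, and rare *de novo* events. This package
implements the full analysis pipeline that connects those CNV classes to
deeply phenotyped subjects:

1. **CNV classification.** A call is **common** when its interval is
   *completely* covered by the union of population-database records
   supported by ≥ 2 distinct studies — or by an internal-control record
   from cognitively normal subjects. Every other call is **unique** and
   resolved by parental testing into **de novo** (absent in both
   parents), **familial** (present in a parent), or unresolved.
   Coverage is computed in integer bases over a per-chromosome interval
   index, so "complete overlap" is exact.
2. **CNV characterization.** Per-class feature tables (counts, carriers,
   calls/subject, size statistics in Mb, genes within 50 kb of the
   breakpoints, proportion > 1 Mb, proportion of deletions) and
   between-class size comparisons with the Wilcoxon rank-sum test
   (exact permutation enumeration for small samples; tie- and
   continuity-corrected normal approximation otherwise).
3. **Phenotype processing.** Binary subjects × features matrices on a
   two-level dysmorphology ontology (fine features nested in coarse
   categories, in the style of the Winter-Baraitser Dysmorphology
   Database). Coarse values are the OR of their fine features; features
   present in < 5% or > 95% of subjects are filtered out; per-subject
   abnormality burden and a configurable five-item De Vries checklist
   score summarize severity.
4. **Association.** Subjects are grouped by their CNV classes
   (de novo / familial-only / common-only, with dual carriers flagged),
   and each phenotype's prevalence is compared between groups with a
   two-sided Fisher exact test (full hypergeometric enumeration) and
   Benjamini–Hochberg FDR correction per contrast.
5. **Clustering.** Subjects are clustered on the filtered fine-feature
   matrix with restarted Lloyd k-means; the number of clusters K is
   selected by the Calinski–Harabasz index
   CH(K) = (B/(K−1)) / (W/(n−K)), and clusters are characterized by
   burden difference and per-feature prevalence tests.
6. **Synthetic cohorts.** A seeded generator produces a complete study —
   variant database, calls with known classes, gene annotation, and a
   phenotype matrix with two planted clusters — so every stage is
   testable end to end against known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic cohort (78 subjects, seed 1) and write their tables
under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_classify_cnvs.py
python analysis/03_characterize_cnvs.py
python analysis/04_process_phenotypes.py
python analysis/05_test_associations.py
python analysis/06_cluster_phenotypes.py
```

Classification recovers every planted class and the carrier structure
partitions the cohort 18 / 20 / 40:

```
classified 500 calls: Counter({'common': 452, 'familial': 27, 'de_novo': 21})
agreement with planted classes: 100.0%
...
group sizes: {'de_novo': 18, 'familial_only': 20, 'common_only': 40}
```

The per-class summary shows the planted size hierarchy — de novo calls
(median 2.6 Mb here) are far larger than common ones (0.13 Mb),
rank-sum p = 4.3e-13 — and the clustering stage selects K = 2 and
recovers the planted high- and low-burden clusters exactly:

```
Calinski trace: K=2: 23.7, K=3: 13.4, K=4: 9.5, ...
selected K = 2
mean abnormal features/subject by cluster: cluster_1: 27.9, cluster_2: 12.6
between-cluster burden rank-sum p = 2.77e-14
20 / 79 features more prevalent in one cluster (q < 0.05)
agreement with planted clusters: ARI = 1.000
```

No phenotype differs significantly between CNV groups after FDR
correction (none was planted), while the clusters — defined on the
phenotypes — separate as expected.

The same pipeline runs on real data through the CLI, given a call
table, variant database, gene BED, phenotype matrix and ontology in
the documented TSV dialects (see `docs/methods.md`):

```sh
cnvpheno run --calls calls.tsv --db dgv.tsv --genes genes.bed \
    --phenotypes phenotypes.tsv --ontology ontology.tsv \
    --rubric rubric.yaml --outdir out/
```

## Layout

- `src/cnvpheno/` — the library: `genomic` (intervals, database,
  classification rule), `characterize` (per-class summaries, rank-sum
  test), `phenotypes` (ontology, filtering, De Vries), `association`
  (grouping, Fisher, BH), `clustering` (k-means, Calinski index),
  `simulate` (synthetic cohorts), `io` (file dialects and the
  end-to-end pipeline), `cli`.
- `analysis/` — the numbered narrative drivers shown above.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — models, conventions, parameter defaults and
  limitations.
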