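# Methods

## CNV classification

A CNV call is an interval on a chromosome with a deletion/duplication
state, a supporting-probe count, and parental-testing evidence. The
population-variant database holds study-attributed records (a DGV-style
catalogue) plus internal-control records from cognitively normal
subjects, indexed per chromosome with an interval tree.

**Common rule.** For a call `c`, the *coverage fraction* is
`|union of (r ∩ c) over overlapping records r| / |c|`, computed in
integer bases so that completeness (coverage = 1.0) is an exact integer
comparison, not a float test. The call is **common** iff coverage is
exactly 1.0 **and** the contributing records include ≥ 2 distinct
population studies or ≥ 1 internal-control record. "≥ 2 studies" counts
distinct study identifiers among all contributing records: the studies
jointly cover the call; no single study must contain it alone.
Duplicated records (same interval, study and source) collapse to one
before counting. Internal-control support is accepted on its own,
also under the joint-union-coverage reading.

**Unique calls.** Every non-common call is unique and resolved by
evidence: absent in both parents → *de novo*; present in a parent →
*familial*; untested → *unresolved*. The binary common/unique rule
names only coverage < 0.5 ("overlapped partially or not at all") and
coverage 1.0; the gap in between is kept as unique but flagged
`borderline` (coverage in [0.5, 1.0)), and a policy switch can route
borderline, study-supported calls to common instead. Deletion/
duplication state matching between call and record is off by default —
catalogue records of the relevant era mix and omit states — and can be
switched to strict matching.

Coordinates are 0-based half-open (BED convention) in memory. The
on-disk call and variant-database TSVs are 1-based inclusive (the
convention of published CNV coordinate tables) and converted on read;
gene annotation is BED4 and read as-is. Chromosome names are normalized
by stripping any `chr` prefix. A filter retaining calls supported by
≥ 3 consecutive probes (unknown counts pass) is applied before
classification.

## Per-class characterization

For each class and overall: number of calls; number of carriers;
calls/subject — divided by the whole cohort for common and overall but
by per-class carriers for familial and de novo, matching the
convention of published per-class CNV tables; mean/median/min/max size
in Mb; genes per call, counting each gene once if its locus intersects
the call extended by a 50 kb flank on each side (clamped at zero);
proportion of calls strictly > 1 Mb; proportion of deletions. Medians
use the midpoint rule for even counts. TSV output rounds to 4
significant digits; JSON keeps full precision.

**Size comparison.** Two-sided Wilcoxon rank-sum test with midranks for
ties. When both samples have ≤ 10 observations the permutation
distribution of the rank sum is enumerated exactly (dynamic programming
over doubled midranks, equivalent to enumerating all C(n, n1)
assignments; two-sided p = P(|W − E[W]| ≥ observed)). Otherwise a
normal approximation with tie-corrected variance
`n1·n2/12 · ((n+1) − Σ(t³−t)/(n(n−1)))` and a 0.5 continuity
correction is used. The exact and approximate branches agree within
0.02 at 10-vs-10 (verified in the test suite).

## Phenotype processing

Phenotypes are binary (abnormal/normal) fine features nested in coarse
categories by a two-column ontology. Explicit `NA` cells are mapped to
normal on read and counted in the log: the downstream binary analysis
has no missing-data treatment, so unknowns are conservatively treated
as unobserved abnormalities. A subject's coarse value is the OR of the
category's fine features. The prevalence filter keeps features with
`0.05·N ≤ count ≤ 0.95·N`; at N = 78 this removes features in fewer
than 4 or more than 74 subjects. Filtering is applied to the fine and
coarse matrices independently (the fine filter never drives the coarse
one), and is idempotent.

**De Vries score.** The five-item checklist is configurable as a YAML
rubric binding item names to feature ids. Default weights/caps follow
the structure of the original checklist: family history of ID (1,
cap 1); prenatal-onset growth retardation (2, cap 2); postnatal growth
abnormalities — microcephaly, short stature, macrocephaly, tall
stature — (1 each, cap 2); ≥ 2 designated facial dysmorphic features
(2, cap 2, threshold predicate); other dysmorphism/congenital
anomalies (1 each, cap 2); total cap 9. The score is
`min(total_cap, Σᵢ min(capᵢ, scoreᵢ))`, monotone in the feature set.
Because the exact weighting used for published cohort medians is not
restated in primary reports, rubric-dependent medians should be read
as rubric-relative; the rubric ships as configuration, not code.

## Association analysis

Subjects partition by their classified calls: ≥ 1 de novo call →
*de novo* group; otherwise ≥ 1 familial call → *familial-only*;
otherwise *common-only* (including subjects with no calls). Subjects
with both de novo and familial calls are flagged as dual carriers;
they stay in the de novo group for the de-novo-vs-common contrast and
are excluded entirely from the familial-vs-common contrast. Unresolved
unique calls do not promote a subject out of common-only unless a
config flag says otherwise (logged either way).

Per feature, the 2×2 abnormal/normal × group table is tested with a
two-sided **Fisher exact test**: the hypergeometric probabilities of
all tables with the observed margins are enumerated with exact integer
weights, and the p-value sums those with probability ≤ that of the
observed table, the comparison made at 1e-7 relative tolerance (on
integers, so ties are exact). Degenerate margins give p = 1.
**Benjamini–Hochberg** step-up adjustment is applied per contrast
across the feature set analyzed at that level (coarse and fine
separately, not pooled across contrasts). Both primitives are verified
exhaustively against independent oracles (scipy's implementation for
all 2×2 tables with total ≤ 40; statsmodels for BH), and the realized
false-discovery proportion under a simulated global null at the cohort's
group sizes stays below the nominal 0.05 level.

## Clustering

Rows of the filtered fine matrix are clustered as raw 0/1 vectors
under Euclidean distance — no scaling, weighting or dimensionality
reduction. Lloyd's algorithm initializes centroids at K distinct data
rows drawn uniformly; 100 restarts by default (seed 1), keeping the
lowest within-cluster sum of squares; WSS is asserted non-increasing
across iterations. An emptied cluster is re-seeded at the point
farthest from its current centroid, keeping K fixed as the index
requires; the repair loops because one repair can empty another
cluster. K is scanned over 2..min(10, n−1) — the published optimum in
this problem sits well inside that bracket — and chosen to maximize
CH(K) = (B/(K−1)) / (W/(n−K)), with ties to the smallest K and an
infinity sentinel when W = 0. The scan range and restart count are not
standardized in the literature, so both are recorded in output
metadata. Selected clusters are characterized by per-subject burden
(Wilcoxon rank-sum between clusters) and, at K = 2, per-feature
prevalence (Fisher + BH).

## Synthetic cohort generator

The generator emulates the shape of a deeply phenotyped ID cohort so
the pipeline can be exercised end to end with known truth. Defaults:
78 subjects; common calls Poisson(6.14)/subject; 21 de novo calls in
18 carriers and 27 familial calls in 22 carriers, 2 dual carriers
(extras spread one at a time over carriers, e.g. familial multi-
carriers get 3, 3 and 2 calls); per-class log-normal sizes solved from
target (median m, mean μ) as `mu = ln m`, `sigma = sqrt(2 ln(μ/m))` —
common 0.14/0.42 Mb, familial 0.43/0.70 Mb, de novo 2.46/3.14 Mb —
with a 10 kb floor; deletion proportions 0.59 / 0.30 / 0.67.

The genome is 22 synthetic autosomes of 100 Mb; no real coordinates
are used. The database is built from ~300 "common template" regions,
each fully covered by records from 2–3 distinct studies (a 15%
fraction instead carries an internal-control record), plus
single-study decoy records that exercise the insufficient-support
branch. Common calls are placed inside templates, so the classifier
provably labels them common; unique calls are rejection-sampled until
database coverage < 0.5. Genes (15,000, exponential lengths, mean
30 kb) are placed uniformly.

Phenotypes are independent Bernoulli draws given the subject's planted
cluster (40 vs 38 subjects): 20 differential features at prevalence
0.85 vs 0.10, twelve rubric-bound features at fixed cluster-independent
prevalences chosen to emulate a checklist-enrolled (severe) cohort —
giving a cohort median De Vries score of 5 — and the remaining shared
features at a baseline solved so the expected abnormality burdens equal
28 vs 13 per subject exactly. With these defaults the planted clusters
are separated by ≈ 4.6 within-cluster standard deviations along the
mean-difference direction, so k-means recovery is essentially
deterministic (ARI ≈ 1 across seeds).

All three generators draw from fixed, independent seed streams, so
(config, seed) fully determines every artifact and the database and
calls can be regenerated independently yet consistently.

**What the generator does not model** — and hence what passing tests do
not show about real data: feature–feature correlation within subjects
(real dysmorphology features co-occur), linkage/recurrence structure of
real CNV loci, genome-build coordinates, phenotype measurement error,
and any planted CNV-class/phenotype association (the association stage
is validated under the null plus artificial planted contrasts). The
empirical proportion of large (> 1 Mb) de novo calls implied by the
fitted log-normal (≈ 0.90) is higher than values reported from real
cohorts (≈ 0.7): a two-parameter log-normal matched to the published
median and mean cannot simultaneously match a published tail
proportion, and the median/mean parameterization was kept.

## Problem sizes and determinism

Tests run the study at its native scale (78 subjects, ~500 calls) plus
scaled checks chosen for statistical stability: 500 calls/class for
size-statistic recovery (medians within 20%), ~1,000 calls for
classifier throughput, 200 replicates for the FDR null, 20 seeds for
cluster recovery. All randomness flows through numpy Generators seeded
explicitly; reruns with the same seed produce byte-identical outputs
(the JSON run summary contains no timestamps).
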