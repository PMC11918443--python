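# Methods

This note records the statistical model behind `adstage`, the design
choices made where the procedure was genuinely open, and what the
synthetic-cohort experiments do and do not establish.

## Statistical primitives

Expression matrices are genes × samples. Counts are converted to TPM by
per-sample scaling to 10⁶ (dividing by gene length first when lengths are
known). The clustering transform is `X = log2(TPM + 1) − C`, with per-gene
`C` chosen so each gene's mean over the included individuals is zero; all
individual-level clustering operates on `X`.

Two-group comparisons use Welch's *t* (unequal variances,
Welch–Satterthwaite degrees of freedom, two-tailed); three-group
comparisons use one-way ANOVA. Degenerate inputs follow explicit
conventions: zero variance in every group with equal means gives p = 1,
with unequal means the p → 0 limit (flagged by a warning). Multiple
testing is controlled by Benjamini–Hochberg; the significance threshold is
FDR < 0.1 throughout, a deliberately permissive level for a
hypothesis-generating screen. Pearson correlation of a constant vector is
defined as 0, which is what produces the spike at zero in
expression–promoter correlation histograms for genes whose promoters never
carry a mark.

Size factors follow the median-of-ratios construction: the reference is
the per-gene geometric mean over samples (genes with any zero excluded),
and a sample's factor is a quantile (median, or first/third quartile) of
its per-gene count ratios to the reference. The low-expression filter
drops a gene only when its mean TPM is below 0.1 in *all three* stage
groups (the alternative reading, overall mean < 0.1, is available via
`mode="overall"`), and always drops spike-in identifiers (prefix `ERCC-`
by default).

## Exact r×c Fisher test

The two-sided p-value is the total multivariate-hypergeometric probability
(margins fixed) of all tables whose probability does not exceed the
observed table's, with relative tolerance 1e-7 to absorb round-off. This
probability-mass ordering is the convention of the major statistical
environments and is required to reproduce published values. Enumeration is
a recursive margin-constrained fill with a log-factorial cache; a guard
refuses problems whose composition bound exceeds 1e8 tables (the largest
table of interest here, 3×3 with n = 82, enumerates in well under a
second). The 2×2 closed form uses the hypergeometric distribution directly
and agrees with the enumerator exactly on the shared domain.

## Clustering

Hierarchical clustering is UPGMA (group-average) on correlation distance
`1 − r`. Ties in the merge sequence are broken by the lexicographically
smallest pair of cluster ids, which makes dendrograms platform-independent;
a float-level symmetrisation guards against `corrcoef` asymmetry. A
first-branch cluster counts as *enriched* for a clinical group when it
holds strictly more than 2/3 of the group's members and the 2×2 Fisher
exact p-value of cluster × group membership is below 0.05.

The k-means cluster number is selected by an explicit elbow rule: the k
maximising the second difference `SSE(k−1) − 2·SSE(k) + SSE(k+1)` of the
best-of-50 k-means SSE curve (k-means++ initialisation, a fixed seed
stream per call). When the smallest k already has zero SSE it is chosen;
grids without an interior point fall back to the largest k with a warning.
An explicit rule is needed because an "elbow read off a plot" is not
reproducible.

## Gene-set search and substages

Directional selection keeps genes with mean TPM higher in the later group
at p ≤ P_up plus genes lower at p ≤ P_down; thresholds are inclusive.
Separation scans cluster only the two compared groups' individuals,
re-centred on the selected genes; a cell with fewer than two genes cannot
define a correlation distance and never separates. The named sets are
built only from these operations: the majority-MCI (M-NA) set from the
omnibus grid, the NCI-vs-AD sets from the two backend grids, and the union
sets by absorbing the largest p-ordered candidate prefix that preserves
complete separation (scanned from the full list downwards).

In synthetic mode the count-scale backend is Welch's *t* on
counts-per-million. Because the per-gene *t* statistic is scale-invariant,
this backend orders genes almost identically to the TPM backend even with
unequal gene lengths; the two grids therefore act as near-replicates
rather than as genuinely independent evidence. A plugin slot accepts any
per-gene p-value producer (e.g. a negative-binomial likelihood-ratio test)
for real-data runs, where the two backends do differ.

AD subgroup discovery cuts the AD-only dendrogram into three, tests the
up-in-AD genes across the three subgroups by ANOVA (FDR < 0.1), clusters
the significant genes' standardised AD profiles by elbow k-means, and
types each gene cluster from its sorted per-subgroup centroid: deviant-low
(CA-like) when the lower gap exceeds half the range, deviant-high
(CB-like) when the upper gap does (factor configurable). Each AD
individual is then labelled from their own mean expression of the CA and
CB clusters — high/low by a two-means split of each score — giving HH, LL,
and HL. Labelling individuals directly from their CA/CB scores, rather
than through the three-cut, is deliberate: the three-cut can be distorted
by MCI-proximal bridge variance while the per-individual scores are not.

Deviation counting marks, for each individual and each pairwise grid cell
in which *both* groups' enriched clusters formed, whether the individual
sat inside the other group's cluster, summing over both backends (2 × 25
cells per pair). Classification uses elbow k-means on the counts — 1-D for
NCI (k ∈ {1,2,3}) and AD, 2-D (toward-NCI, toward-AD) for the MCI majority
— with clusters labelled from their centroids: the cluster nearest the
origin (or with centroid norm < 0.5 counts) is typical, the rest are
NCI-proximal or AD-proximal by dominant axis. Omnibus deviators (MCI
members outside the MCI-enriched cluster in any omnibus cell) are set
aside as MCI_NCI_AD before the k-means.

## Epigenome analysis

Peaks are regions with fold-change-over-control strictly above 5; the
boundary value is excluded. Interval arithmetic is 0-based half-open
throughout (BED convention); the Jaccard coefficient is intersection
length over union length, 0 when the union is empty, and is verified in
the tests against both a per-basepair bitmap oracle and `bedtools
jaccard`. Individuals are typed by clustering the rows of the Jaccard
matrix (self-similarity entries retained; Euclidean distance, UPGMA): the
larger first-branch side is Typical, and when the hierarchical-cut elbow
selects three clusters the Typical side splits at its top merge into
Typical1/Typical2. Promoters are the 1 kbp upstream of the TSS,
strand-aware and clipped at chromosome bounds; promoter marker density
divides the overlap by the nominal 1000 bp even for clipped promoters.

## Progression networks

Individuals are embedded with all principal components (an orthogonal,
distance-preserving rotation, kept for reproducibility) on the union of
the M-NA set with one NCI-vs-AD set, and joined in a symmetric
union-of-kNN graph with n_neighbors = 2, the minimum, so only the tightest
neighbourhood relations survive. Connection confidence between substages
is the observed number of inter-partition edges divided by the count
expected if the inter-partition edges were placed uniformly over unordered
partition pairs in proportion to size products — the partition-graph
abstraction idea in its simplest form. Confidences are *not* clipped:
genuine adjacencies typically exceed 1, and capping them at 1 provably
collapses the pruning rule (keep confidence > 2 × the maximum NCI–AD
confidence) into an empty graph whenever any NCI–AD pair reaches half the
cap. When the NCI–AD maximum is zero, all positive edges are kept — there
is no shortcut level to prune against. Networks from the two gene-set
unions are intersected (minimum confidence on common edges) and cross-stage
edges oriented NCI → MCI → AD.

On the default synthetic cohort the detailed 12-node network is sparse:
the NCI-proximal and AD-proximal bridge substages abut in expression
space, so the NCI–AD pruning floor is high. The coarse 6-node network
reliably shows the two planted routes (through the MCI majority, and
through the doubly-deviant bridge).

## The synthetic cohort generator

The generator plants, in log2-TPM space, a cohort of 25 NCI / 29 MCI / 28
AD individuals over 2000 genes with seven gene modules: the majority-MCI
programme (150 up + 150 down, effect 2.6 log2), the NCI→AD programme (60
up + 40 down, effect 2.0), the AD-subgroup contrasts (70 CA-like and 90
CB-like genes, effect 2.4; CA low in exactly the LL subgroup, CB high in
exactly the HH subgroup), and 1440 null genes. Counts are negative
binomial (dispersion 0.2) around length-weighted means with log-normal
library sizes (σ = 0.15) and per-gene, per-individual log2 noise
(σ = 0.3); TPM is recovered by length-corrected per-sample scaling.

Three structural choices make the planted truth recoverable by the
procedure itself, and are worth stating because each was forced by a
geometric argument:

* **Bridge weights exceed one half.** A bridge individual planted exactly
  midway between two flank profiles always falls on the signature-group
  side of the first-branch boundary, because that boundary is the
  group-size-weighted mean of the flank profiles and the signature group
  is the smaller one. Symmetric 0.5 bridges therefore never deviate.
  Stage bridges use weight 0.62 toward the destination flank
  (MCI_NCI_AD keeps the symmetric 0.5 between NCI and AD).
* **Stages share graded programmes.** Typical MCI carries the NCI→AD
  programme at weight 0.4 and the subgroup modules at the mean AD level,
  and NCI and pure-AD individuals share a background 0.25 of the MCI
  programme. Without the shared levels, module contrasts that should be
  invisible to a given comparison (e.g. the MCI programme in NCI-vs-AD
  tests) become significant through the bridge individuals alone, and the
  search steps entangle.
* **AD bridges mix module families independently** (MCI-programme
  engagement 0.45, NCI→AD retreat 0.55, subgroup identity loss only
  0.25), so an AD_HH_MCI individual still reads as HH to the subgroup
  analysis while deviating toward MCI in the pairwise grids.

Epigenome tracks place jittered copies (Gaussian shift σ = 40 bp, drop
probability 0.1) of 240 template peaks on a 3 × 1 Mbp genome — one or two
overlapping "typical" templates plus a disjoint "untypical" template —
and, on the CB-like genes' promoters, peaks whose presence probability
and width increase with the individual's planted expression, so the
expression–promoter-density correlation is positive by construction.
APOE genotypes assign each individual exactly one carrier class (APOE2:
any ε2; APOE3: ε3/ε3; APOE4: any ε4) and never emit ε2 together with ε4.

**Known limitation.** Planted MCI_NCI individuals sit, by construction, on
the same geometric boundary in the omnibus clustering as in the pairwise
NCI-vs-MCI cells: the event "deviates toward NCI" and the event "ejected
from the omnibus MCI cluster" nearly coincide, so the procedure routes
most planted MCI_NCI individuals to MCI_NCI_AD. This is the dominant
residual confusion behind a median detailed-substage adjusted Rand index
of ≈ 0.93 rather than ≈ 1. Deviation counts are also more bimodal than in
real cohorts (individuals mostly deviate in many cells or none), because
the grid cells are highly correlated when every module gene has a similar
effect size.

What passing the synthetic tests shows: the pipeline recovers planted
substage structure, controls its type-I error, and its network stage
recovers planted progression chains. What it does not show: performance on
real cohorts, where within-group variance structure, library artefacts,
batch effects, and the count-model mismatch of the *t*-test are all
harsher than anything planted here.

## Problem sizes

The default test and acceptance runs use cohorts of 82 individuals × 2000
genes, five independent cohort seeds for recovery medians, 2500 null genes
for calibration, 125 label-permuted grid cells for the null separation
check, and five planted chains (six nodes × 14 individuals, 10 features)
for the network check.
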