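# adstage

Transcriptome-defined substages of dementia cohorts and adjacency networks
of disease progression.

Cohort studies of late-onset Alzheimer's disease typically label each
individual with one of three clinical stages — no cognitive impairment
(NCI), mild cognitive impairment (MCI), and Alzheimer's disease (AD) — yet
brain expression profiles within each stage are strikingly heterogeneous.
`adstage` implements a complete analysis that stratifies such a cohort into
finer, transcriptome-defined substages and then infers which substages are
adjacent along the course of the disease:

1. **Threshold-grid gene-set search.** For a pair of clinical groups,
   per-gene tests (Welch's *t* on TPM, or a count-scale backend; one-way
   ANOVA for three groups) are thresholded on a grid of p-value cutoffs
   `(P_up, P_down)` applied separately to genes up- and down-regulated in
   the later group. A grid cell is *separating* when group-average
   (UPGMA) clustering with correlation distance `d(i,j) = 1 − r(x_i, x_j)`
   on `X = log2(TPM+1) − C` (per-gene `C` centres each gene across
   individuals) splits the two groups perfectly at the first dendrogram
   branch.
2. **Substage classification.** Individuals deviating from their own
   group's enriched cluster (a cluster holding > 2/3 of the group with a
   2×2 Fisher exact p < 0.05) are counted across all grid cells; k-means
   with an elbow rule on the deviation counts splits each stage into
   typical and bridge substages (12 in total, e.g. `MCI_NCI_AD`,
   `AD_HL_MCI`). AD is further divided into HH / LL / HL subgroups from
   two discovered gene clusters (CA: low in exactly one subgroup; CB: high
   in exactly one subgroup).
3. **Epigenome similarity typing.** Genome-wide peak tracks (fold change
   over control > 5) are compared between individuals with the interval
   Jaccard coefficient; clustering the Jaccard profiles types each
   individual's genome-wide distribution as typical or untypical, and
   promoter (1 kbp upstream) marker densities are correlated with
   expression per gene.
4. **Exact r×c Fisher tests** by full enumeration over tables with fixed
   margins, for substage–epigenotype and substage–APOE association tables.
5. **Progression networks.** Individuals are embedded by full-rank PCA,
   joined in a union-of-2-nearest-neighbour graph, and substage-to-substage
   connection confidence is the observed/expected inter-partition edge
   count. Connections weaker than twice the strongest direct NCI–AD
   confidence are pruned (progression is assumed to pass through MCI), the
   networks from two independent gene-set unions are intersected, and
   cross-stage edges are oriented NCI → MCI → AD.

A first-class synthetic-cohort generator (`adstage.synthetic`) plants all
of this structure — stage signatures, bridge individuals, AD subgroups,
matching epigenome tracks, APOE genotypes — so the whole pipeline is
testable without access to restricted cohort data. Real tables (TSV
expression matrices, BED/bedGraph tracks) are supported through
`adstage.io_formats`.

## Worked example

```python
from adstage.pipeline import PipelineConfig, run_all
from adstage.synthetic import CohortSpec

result = run_all(PipelineConfig(spec=CohortSpec(), seed=1))
print(result.assignment.detailed.value_counts())
print(result.networks["coarse"]["oriented"])
```

The synthetic cohort holds 25 NCI, 29 MCI, and 28 AD individuals over 2000
genes. With seed 1 the pipeline prints:

```
NCI_Typical    22
MCI_Typical    17
MCI_NCI_AD      9
AD_LL           9
AD_HH           8
AD_HL           6
NCI_MCI         3
MCI_AD          3
AD_HL_MCI       2
AD_HH_MCI       2
AD_LL_MCI       1
```

i.e. the majority of each stage is typical, while bridge individuals
(planted intermediates) are routed to the NCI-proximal, AD-proximal, or
doubly-deviant substages. The coarse progression network at the same seed
is

```
    node_a     node_b  confidence  direction
     AD_HH      AD_HL    1.968382 undirected
     AD_HL      AD_LL    1.968382 undirected
 MCI_Major      AD_HL    3.936765    forward
 MCI_Major      AD_LL    1.574706    forward
MCI_NCI_AD      AD_LL    3.499346    forward
       NCI MCI_NCI_AD    4.199216    forward
```

showing two NCI→AD routes: through the majority-MCI programme into the
AD_HL/AD_LL subgroups, and through the doubly-deviant MCI_NCI_AD bridge
directly into AD_LL. Confidence is the observed/expected inter-partition
edge ratio of the 2-NN graph; `forward` edges point along clinical stage
order.

The exact Fisher test is also exposed on the command line:

```sh
$ adstage fisher --table "6,4,3;0,0,4"
p = 0.0432773
```

Other subcommands (`simulate`, `degscan`, `substage`, `epigenome`,
`network`, `all`) wrap the corresponding library stages; see
`adstage --help`.

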