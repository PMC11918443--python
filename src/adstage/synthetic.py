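"""Synthetic cohorts with planted substage structure.

The generator emulates a dementia cohort of three clinical stages (25 NCI,
29 MCI, 28 AD individuals by default) carrying planted gene modules:

* ``mna_up`` / ``mna_down`` — genes shifted up/down in the typical-MCI
  expression programme (the majority-MCI signature);
* ``na_up`` / ``na_down`` — genes shifted up/down in all AD substages
  relative to NCI;
* ``ca_like`` — genes low in exactly one AD subgroup (the LL subgroup);
* ``cb_like`` — genes high in exactly one AD subgroup (the HH subgroup);
* ``null`` — unaffected genes.

Bridge substages (NCI_MCI, MCI_NCI, MCI_AD, MCI_NCI_AD, AD_*_MCI) receive
mean profiles that are convex mixtures of the two flanking pure-substage
profiles, planting individuals intermediate between stages; the mixture
weights lean toward the destination stage so bridges genuinely straddle
the clustering boundaries (see the per-weight field comments).  Counts are
negative binomial around length-weighted per-gene log-normal means with
per-sample library-size spread; TPM is recovered by length-corrected
per-sample scaling to 1e6.

Matching epigenome peak tracks place jittered copies of shared peak
templates ("typical" individuals; optionally two sub-templates) or of a
disjoint template ("untypical"), plus promoter peaks on ``cb_like`` genes
whose presence and width grow with the individual's planted expression, so
the expression-promoter-density correlation is positive by construction.

The synthetic genome is 3 chromosomes of 1 Mbp: gene promoters tile the low
coordinates of every chromosome and background peak templates occupy the
high coordinates, keeping the two signals separable and small enough for
brute-force interval oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epigenome import IntervalSet
from .io_formats import ExpressionCohort
from .substages import BRIDGE_FLANKS, PURE_SUBSTAGES, STAGE_OF_SUBSTAGE

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "generate_cohort",
    "generate_epigenome",
    "generate_genotypes",
    "synthetic_annotation",
    "generate_progression_chain",
]

MODULES = ("mna_up", "mna_down", "na_up", "na_down", "ca_like", "cb_like", "null")
STAGE_PREFIX = {"NCI": "N", "MCI": "M", "AD": "A"}
AD_PURE = ("AD_HH", "AD_HL", "AD_LL")

_DEFAULT_FRACTIONS = {
    "NCI": {"NCI_Typical": 22 / 25, "NCI_MCI": 3 / 25},
    "MCI": {"MCI_Typical": 17 / 29, "MCI_NCI": 4 / 29,
            "MCI_AD": 3 / 29, "MCI_NCI_AD": 5 / 29},
    "AD": {"AD_HH": 7 / 28, "AD_HH_MCI": 3 / 28,
           "AD_LL": 6 / 28, "AD_LL_MCI": 4 / 28,
           "AD_HL": 5 / 28, "AD_HL_MCI": 3 / 28},
}

_DEFAULT_MODULE_SIZES = {
    "mna_up": 150, "mna_down": 150, "na_up": 60, "na_down": 40,
    "ca_like": 70, "cb_like": 90, "null": 1440,
}


def _default_effects():
    # the majority-MCI programme is the dominant cohort structure, and the
    # subgroup-defining CA-like contrast must survive dilution by the
    # MCI-proximal AD bridges, so both run slightly hotter than the rest
    eff = {m: 2.0 for m in MODULES if m != "null"}
    eff["mna_up"] = eff["mna_down"] = 2.6
    eff["ca_like"] = eff["cb_like"] = 2.4
    return eff


@dataclass
class CohortSpec:
    """Parameters of a planted synthetic cohort."""

    n_per_stage: dict = field(default_factory=lambda: {"NCI": 25, "MCI": 29, "AD": 28})
    substage_fractions: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in _DEFAULT_FRACTIONS.items()})
    n_genes: int = 2000
    module_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_MODULE_SIZES))
    effect_log2: dict = field(default_factory=_default_effects)
    noise_sd_log2: float = 0.3
    libsize_sigma: float = 0.15
    nb_dispersion: float = 0.2
    bridge_weight: float = 0.6       # stage-bridge weight on the destination flank
    ad_mci_mna_weight: float = 0.45  # AD_*_MCI: MCI-programme (mna) engagement
    ad_mci_na_weight: float = 0.55   # AD_*_MCI: retreat along the NCI->AD axis
    ad_mci_subgroup_weight: float = 0.25  # AD_*_MCI: loss of subgroup (ca/cb) identity
    nia_bridge_weight: float = 0.5   # NCI/AD-symmetric MCI_NCI_AD bridge
    mci_na_weight: float = 0.4       # partial NCI->AD axis engagement in typical MCI
    mci_subgroup_engagement: float = 1.0  # typical-MCI level of the subgroup
                                          # (ca/cb) modules, as a fraction of the
                                          # mean AD level: these genes rise early
                                          # in progression and only then
                                          # differentiate among AD subgroups
    background_mna_weight: float = 0.25  # shared baseline of the MCI programme
                                         # in NCI and pure-AD individuals
    baseline_log2_range: tuple = (1.0, 6.0)
    mean_library_size: float = 300_000.0
    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000})
    seed: int = 0

    def validate(self) -> None:
        for stage, n in self.n_per_stage.items():
            if n <= 0:
                raise ValueError(f"n_per_stage[{stage}] must be positive")
            fr = self.substage_fractions.get(stage)
            if not fr:
                raise ValueError(f"substage_fractions missing stage {stage}")
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"substage_fractions[{stage}] must sum to 1")
            for sub in fr:
                if STAGE_OF_SUBSTAGE.get(sub) != stage:
                    raise ValueError(f"substage {sub} does not belong to stage {stage}")
        unknown = set(self.module_sizes) - set(MODULES)
        if unknown:
            raise ValueError(f"unknown module(s) in module_sizes: {sorted(unknown)}")
        if sum(self.module_sizes.values()) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if any(v < 0 for v in self.module_sizes.values()):
            raise ValueError("module sizes must be non-negative")
        if self.noise_sd_log2 < 0 or self.libsize_sigma < 0 or self.nb_dispersion < 0:
            raise ValueError("noise parameters must be non-negative")
        for w in (self.bridge_weight, self.ad_mci_mna_weight,
                  self.ad_mci_na_weight, self.ad_mci_subgroup_weight,
                  self.nia_bridge_weight, self.mci_na_weight,
                  self.background_mna_weight):
            if not 0 <= w <= 1:
                raise ValueError("mixture weights must lie in [0, 1]")

    def with_effects(self, value: float) -> "CohortSpec":
        return replace(self, effect_log2={m: value for m in self.effect_log2})


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    substage: pd.Series           # individual -> detailed substage
    module: pd.Series             # gene -> module name
    planted_log2_mean: pd.DataFrame  # genes x individuals, before noise

    def stage(self) -> pd.Series:
        return self.substage.map(STAGE_OF_SUBSTAGE)


def _integer_counts(fracs: dict, n: int) -> dict:
    """Largest-remainder rounding of fractions to counts summing to n."""
    raw = {k: v * n for k, v in fracs.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = n - sum(base.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - base[k]), k))
    for k in order[:rem]:
        base[k] += 1
    return {k: v for k, v in base.items() if v > 0}


def _module_assignment(spec: CohortSpec) -> pd.Series:
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    modules = []
    for m in MODULES:
        modules.extend([m] * spec.module_sizes.get(m, 0))
    modules.extend(["null"] * (spec.n_genes - len(modules)))
    return pd.Series(modules, index=pd.Index(genes, name="gene_id"), name="module")


def _substage_profiles(spec: CohortSpec, module: pd.Series) -> pd.DataFrame:
    """Per-gene log2 offsets for every detailed substage."""
    e = {m: spec.effect_log2.get(m, 0.0) for m in MODULES}
    delta = pd.DataFrame(0.0, index=module.index, columns=list(PURE_SUBSTAGES))
    delta.loc[module == "mna_up", "MCI_Typical"] = e["mna_up"]
    delta.loc[module == "mna_down", "MCI_Typical"] = -e["mna_down"]
    # every stage shares a background level of the MCI programme, so the
    # majority-MCI signature is a graded programme rather than an on/off
    # switch and carries no NCI-vs-AD contrast
    wb = spec.background_mna_weight
    for sub in ("NCI_Typical",) + AD_PURE:
        delta.loc[module == "mna_up", sub] = wb * e["mna_up"]
        delta.loc[module == "mna_down", sub] = -wb * e["mna_down"]
    for sub in AD_PURE:
        delta.loc[module == "na_up", sub] = e["na_up"]
        delta.loc[module == "na_down", sub] = -e["na_down"]
    # typical MCI partially engages the NCI->AD programme (disease progression)
    delta.loc[module == "na_up", "MCI_Typical"] = spec.mci_na_weight * e["na_up"]
    delta.loc[module == "na_down", "MCI_Typical"] = -spec.mci_na_weight * e["na_down"]
    # CA-like: low in exactly one subgroup (LL); CB-like: high in exactly one (HH)
    delta.loc[module == "ca_like", ["AD_HH", "AD_HL"]] = e["ca_like"]
    delta.loc[module == "ca_like", "AD_LL"] = 0.25 * e["ca_like"]
    delta.loc[module == "cb_like", "AD_HH"] = e["cb_like"]
    delta.loc[module == "cb_like", ["AD_HL", "AD_LL"]] = 0.25 * e["cb_like"]
    # typical MCI carries the subgroup modules at (a fraction of) the mean AD
    # level: these genes rise early in progression and only afterwards
    # differentiate among the AD subgroups
    for m in ("ca_like", "cb_like"):
        mask = module == m
        delta.loc[mask, "MCI_Typical"] = (
            spec.mci_subgroup_engagement
            * delta.loc[mask, list(AD_PURE)].mean(axis=1))

    ad_mean = delta[list(AD_PURE)].mean(axis=1)
    is_sub = module.isin(["ca_like", "cb_like"]).to_numpy()
    is_mna = module.isin(["mna_up", "mna_down"]).to_numpy()
    for sub, (a, b) in BRIDGE_FLANKS.items():
        col_a = ad_mean if a == "AD" else delta[a]
        col_b = ad_mean if b == "AD" else delta[b]
        if sub == "MCI_NCI_AD":
            w = np.full(len(module), spec.nia_bridge_weight)
        elif sub.startswith("AD_"):
            # AD bridges mix module families independently: they engage the
            # MCI programme, retreat along the NCI->AD axis, and keep most of
            # their subgroup (ca/cb) identity so the AD-only clustering still
            # recognises their subgroup
            w = np.full(len(module), spec.ad_mci_na_weight)
            w[is_mna] = spec.ad_mci_mna_weight
            w[is_sub] = spec.ad_mci_subgroup_weight
        else:
            w = np.full(len(module), spec.bridge_weight)
        delta[sub] = (1 - w) * col_a + w * col_b
    return delta


def _assign_substages(spec: CohortSpec, rng: np.random.Generator) -> pd.Series:
    rows = {}
    for stage in ("NCI", "MCI", "AD"):
        n = spec.n_per_stage[stage]
        counts = _integer_counts(spec.substage_fractions[stage], n)
        labels = [sub for sub, c in sorted(counts.items()) for _ in range(c)]
        labels = list(rng.permutation(labels))
        ids = [f"{STAGE_PREFIX[stage]}{i + 1}" for i in range(n)]
        rows.update(dict(zip(ids, labels)))
    return pd.Series(rows, name="substage")


def generate_cohort(spec: CohortSpec):
    """Generate an :class:`ExpressionCohort` and its :class:`CohortTruth`."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x0C0C]))
    module = _module_assignment(spec)
    substage = _assign_substages(spec, rng)
    delta = _substage_profiles(spec, module)

    lo, hi = spec.baseline_log2_range
    base = rng.uniform(lo, hi, size=spec.n_genes)
    planted = base[:, None] + delta[substage.to_numpy()].to_numpy()
    planted = pd.DataFrame(planted, index=module.index, columns=substage.index)

    log2_mean = planted.to_numpy() + rng.normal(
        0.0, spec.noise_sd_log2, size=planted.shape)
    mu = np.power(2.0, log2_mean)  # abundance on the TPM scale
    lib = np.exp(rng.normal(0.0, spec.libsize_sigma, size=planted.shape[1]))
    lengths = rng.uniform(500.0, 5000.0, size=planted.shape[0])
    weights = mu * (lengths / lengths.mean())[:, None]  # read counts follow length
    scale = spec.mean_library_size / weights.mean(axis=0).mean() / planted.shape[0]
    mean_counts = weights * lib[None, :] * scale
    if spec.nb_dispersion > 0:
        r = 1.0 / spec.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean_counts))
    else:
        counts = rng.poisson(mean_counts)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=module.index,
                             columns=substage.index)
    cohort = ExpressionCohort.from_counts(counts_df, substage.map(STAGE_OF_SUBSTAGE),
                                          gene_lengths=lengths)
    truth = CohortTruth(substage=substage, module=module, planted_log2_mean=planted)
    return cohort, truth


# ---------------------------------------------------------------------------
# synthetic genome and epigenome tracks

_SLOT = 1000           # promoter slot size (one gene per slot)
_GENE_REGION_END = 667_000
_TEMPLATE_REGION = (700_000, 999_000)
_TEMPLATE_SLOT = 1000
_PEAK_WIDTH = 400


def synthetic_annotation(spec: CohortSpec) -> pd.DataFrame:
    """Gene annotation for the synthetic genome (gene_id, chrom, strand, tss).

    Genes tile slots of 1 kbp in the low region of each chromosome; strand
    alternates, with the promoter of the gene in slot k always the window
    [1000k, 1000(k+1)): a + gene has its TSS at the window end, a - gene at
    the window start.
    """
    chroms = sorted(spec.chrom_lengths)
    if not chroms:
        raise ValueError("chromosome model missing (empty chrom_lengths)")
    slots_per_chrom = _GENE_REGION_END // _SLOT
    rows = []
    for i in range(spec.n_genes):
        chrom = chroms[i % len(chroms)]
        slot = i // len(chroms)
        if slot >= slots_per_chrom:
            raise ValueError("too many genes for the synthetic genome")
        strand = "+" if i % 2 == 0 else "-"
        tss = (slot + 1) * _SLOT if strand == "+" else slot * _SLOT
        rows.append((f"G{i:04d}", chrom, strand, tss))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])


def _template_slots(spec: CohortSpec):
    slots = []
    for chrom in sorted(spec.chrom_lengths):
        start, end = _TEMPLATE_REGION
        end = min(end, spec.chrom_lengths[chrom])
        for pos in range(start, end - _PEAK_WIDTH, _TEMPLATE_SLOT):
            slots.append((chrom, pos))
    return slots


def _jittered(template, rng, jitter_sd, drop_prob, chrom_lengths):
    records = []
    for chrom, pos in template:
        if rng.random() < drop_prob:
            continue
        shift = int(round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
        s = max(0, pos + shift)
        e = min(chrom_lengths[chrom], s + _PEAK_WIDTH)
        if s < e:
            records.append((chrom, s, e))
    return records


def generate_epigenome(spec: CohortSpec, truth: CohortTruth,
                       typical_fraction: float = 0.75, n_templates: int = 2,
                       jitter_sd: float = 40.0, drop_prob: float = 0.1,
                       n_template_peaks: int = 240, n_swap: int = 60,
                       coupling: bool = True):
    """Per-individual peak tracks plus the planted typing.

    Returns ``(tracks, planted_typing)`` where ``tracks`` maps individual to
    :class:`IntervalSet` and ``planted_typing`` is the Typical1/Typical2/
    Untypical (or Typical/Untypical) label each individual was generated
    from.
    """
    if not 0 < typical_fraction < 1:
        raise ValueError("typical_fraction must lie in (0, 1)")
    if n_templates not in (1, 2):
        raise ValueError("n_templates must be 1 or 2")
    if not spec.chrom_lengths:
        raise ValueError("chromosome model missing (empty chrom_lengths)")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xE19]))
    slots = _template_slots(spec)
    if len(slots) < 2 * n_template_peaks:
        raise ValueError("synthetic genome too small for the peak templates")
    order = rng.permutation(len(slots))
    t1 = [slots[i] for i in order[:n_template_peaks]]
    untypical = [slots[i] for i in order[n_template_peaks:2 * n_template_peaks]]
    spare = [slots[i] for i in order[2 * n_template_peaks:]]
    templates = {"Typical1": t1}
    if n_templates == 2:
        n_swap = min(n_swap, len(spare), n_template_peaks)
        templates["Typical2"] = t1[n_swap:] + spare[:n_swap]
    templates["Untypical"] = untypical

    individuals = list(truth.substage.index)
    n_typ = max(1, int(round(typical_fraction * len(individuals))))
    order = [str(i) for i in rng.permutation(individuals)]
    typing = {}
    for k, ind in enumerate(order):
        if k >= n_typ:
            typing[ind] = "Untypical"
        elif n_templates == 2:
            typing[ind] = "Typical1" if k % 2 == 0 else "Typical2"
        else:
            typing[ind] = "Typical1"
    planted = pd.Series(typing).loc[individuals]
    if n_templates == 1:
        planted = planted.replace({"Typical1": "Typical"})

    annot = synthetic_annotation(spec)
    cb_genes = truth.module.index[truth.module == "cb_like"]
    cb_annot = annot.set_index("gene_id").loc[cb_genes]
    planted_expr = truth.planted_log2_mean.loc[cb_genes]
    span = planted_expr.max(axis=1) - planted_expr.min(axis=1)
    span[span == 0] = 1.0
    z = planted_expr.sub(planted_expr.min(axis=1), axis=0).div(span, axis=0)

    tracks = {}
    for ind in individuals:
        template = templates[typing[ind]]
        records = _jittered(template, rng, jitter_sd, drop_prob,
                            spec.chrom_lengths)
        if coupling:
            for gene, row in cb_annot.iterrows():
                zi = float(z.loc[gene, ind])
                if rng.random() < 0.02 + 0.96 * zi:
                    length = 50 + int(round(950 * zi))
                    w0 = row.tss - _SLOT if row.strand == "+" else row.tss
                    records.append((row.chrom, w0, w0 + length))
        tracks[ind] = IntervalSet.from_records(records)
    return tracks, planted


def generate_genotypes(truth: CohortTruth, carrier_probs=None,
                       seed: int = 0, homozygous_prob: float = 0.1) -> pd.DataFrame:
    """APOE genotypes consistent with exactly one carrier class each.

    By construction no individual carries both the e2 and e4 alleles.
    """
    if carrier_probs is None:
        carrier_probs = {"APOE2": 0.15, "APOE3": 0.65, "APOE4": 0.20}
    probs = np.array([carrier_probs.get(c, 0.0)
                      for c in ("APOE2", "APOE3", "APOE4")])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("carrier probabilities must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA90E]))
    rows = []
    for ind in truth.substage.index:
        cls = ("APOE2", "APOE3", "APOE4")[rng.choice(3, p=probs)]
        if cls == "APOE3":
            alleles = ("e3", "e3")
        else:
            var = "e2" if cls == "APOE2" else "e4"
            alleles = (var, var) if rng.random() < homozygous_prob else (var, "e3")
        rows.append((ind, alleles[0], alleles[1], cls))
    return pd.DataFrame(rows, columns=["individual", "allele1", "allele2",
                                       "carrier_class"]).set_index("individual")


def generate_progression_chain(n_nodes: int = 6, n_per_node: int = 14,
                               n_features: int = 10, spacing: float = 3.0,
                               noise_sd: float = 1.0, seed: int = 0):
    """Blobs of individuals along a linear progression axis.

    Returns ``(X, labels, stage_of_node)`` with X features x individuals;
    node t sits at distance ``spacing * t`` along a fixed unit direction.
    Used to test that partition-connectivity pruning recovers a planted
    chain.  Node names follow the disease axis: the first third of nodes is
    NCI, the middle MCI, the last AD.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC4A1]))
    direction = np.zeros(n_features)
    direction[0] = 1.0
    cols, labels = [], {}
    names = [f"S{t}" for t in range(n_nodes)]
    stage_of_node = {}
    for t, name in enumerate(names):
        third = t * 3 // n_nodes
        stage_of_node[name] = ("NCI", "MCI", "AD")[third]
        centre = direction * spacing * t
        for j in range(n_per_node):
            ind = f"{name}_{j}"
            cols.append(centre + rng.normal(0.0, noise_sd, n_features))
            labels[ind] = name
    X = pd.DataFrame(np.array(cols).T,
                     index=[f"f{k}" for k in range(n_features)],
                     columns=list(labels))
    return X, pd.Series(labels), stage_of_node
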