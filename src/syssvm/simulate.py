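"""Synthetic tumor-cohort generator.

Produces every input the pipeline consumes — somatic variant, copy-number and
structural-variant tables, a systems-level property table with controlled
missingness, known-cancer-gene labels, pathway gene sets inducing planted
patient clusters, a tissue-expression table and a germline variant table —
with known ground truth, so the whole method is testable without any external
data.

A planted subset of "cancer-like" genes (known cancer genes used for training
plus helper genes to be recovered) is drawn from shifted systems-level
property distributions: longer genes with more domains, higher interaction
degree and betweenness, more miRNA regulators, broader expression, hub
status, ohnolog retention and older evolutionary origin. Cancer-like genes
are also recurrently altered (higher per-patient damage rate) and their
alterations are biased toward copy-number gains, mirroring a gain-dominated
adenocarcinoma cohort. Continuous shifts are ``feature_shift`` standard
deviations; boolean and ordinal separations come from planted-vs-background
probability tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alterations import (
    Consequence,
    CopyNumberSegment,
    GeneInterval,
    SmallVariant,
    StructuralVariant,
    SVType,
)
from .features import CHROMATIN_STATES, EVOLUTIONARY_ORIGINS, SYSTEMS_PROPERTY_COLUMNS
from .germline import GermlineVariant, SiteGenotypeStats
from .pathways import GeneSetCollection


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults define the study conditions."""

    n_patients: int = 50
    n_genes: int = 2000
    n_known_cancer_genes: int = 50
    n_planted_helpers: int = 50
    damaged_genes_per_patient: float = 80.0  # Poisson mean
    cancer_gene_damage_weight: float = 3.0  # recurrence bias of cancer-like genes
    feature_shift: float = 1.0  # sd units on continuous systems-level properties
    gain_fraction_cancer: float = 0.55  # alteration-type mix: cancer-like genes
    gain_fraction_background: float = 0.20
    missingness: float = 0.05
    unexpressed_fraction: float = 0.05
    # pathway / clustering structure
    n_pathways: int = 40
    pathway_size: tuple[int, int] = (10, 30)
    n_planted_clusters: int = 3
    cluster_pathway_rate: float = 0.85
    background_pathway_rate: float = 0.02
    # germline structure
    n_germline_variants: int = 500
    n_predisposition_genes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_genes, self.n_known_cancer_genes,
               self.n_planted_helpers) <= 0:
            raise ValueError("counts must be positive")
        if self.n_known_cancer_genes + self.n_planted_helpers > self.n_genes:
            raise ValueError("planted genes exceed the gene universe")
        for p in (self.gain_fraction_cancer, self.gain_fraction_background,
                  self.missingness, self.unexpressed_fraction,
                  self.cluster_pathway_rate, self.background_pathway_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")


@dataclass
class SyntheticCohort:
    """All module inputs plus ground-truth labels for one synthetic cohort."""

    spec: CohortSpec
    gene_ids: list[str]
    known_cancer_genes: list[str]
    planted_helpers: list[str]
    gene_intervals: list[GeneInterval]
    properties: pd.DataFrame  # raw systems-level table, NaN = missing
    variants: list[SmallVariant]
    segments: list[CopyNumberSegment]
    svs: list[StructuralVariant]
    expression: pd.Series  # gene -> normal-tissue expression
    gene_sets: GeneSetCollection
    pathway_levels: dict[str, int]
    true_clusters: pd.Series  # sample -> planted cluster label
    germline_variants: list[GermlineVariant]
    germline_site_stats: dict[str, SiteGenotypeStats]
    predisposition_genes: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.spec.n_patients)]

    @property
    def cancer_like_genes(self) -> set[str]:
        return set(self.known_cancer_genes) | set(self.planted_helpers)


# (background mean, background sd); cancer-like mean += feature_shift * sd
_CONTINUOUS_PARAMS = {
    "gene_length": (2500.0, 1500.0),
    "domain_count": (3.0, 2.0),
    "ppi_degree": (15.0, 12.0),
    "ppi_betweenness": (5e-4, 5e-4),
    "mirna_count": (3.0, 3.0),
    "expression_breadth": (16.0, 8.0),
}
_CONTINUOUS_MIN = {
    "gene_length": 150.0,
    "domain_count": 0.0,
    "ppi_degree": 0.0,
    "ppi_betweenness": 0.0,
    "mirna_count": 0.0,
    "expression_breadth": 0.0,
}
# planted-vs-background probability tables for boolean properties
_BOOLEAN_PROBS = {  # (background, cancer-like)
    "is_duplicated": (0.50, 0.10),
    "is_ohnolog": (0.25, 0.70),
    "ppi_hub": (0.10, 0.50),
}
# ordered old -> young; cancer-like genes skew old
_ORIGIN_PROBS_BG = np.array([0.10, 0.15, 0.10, 0.25, 0.15, 0.15, 0.10])
_ORIGIN_PROBS_CANCER = np.array([0.35, 0.30, 0.15, 0.12, 0.05, 0.02, 0.01])
_CHROMATIN_PROBS_BG = np.array([0.10, 0.10, 0.20, 0.10, 0.10, 0.15, 0.10, 0.15])
_CHROMATIN_PROBS_CANCER = np.array([0.22, 0.16, 0.25, 0.10, 0.08, 0.09, 0.05, 0.05])

# properties with missing entries in real annotation (length/duplication/ohnolog complete)
_MISSING_ELIGIBLE = [
    "domain_count", "ppi_degree", "ppi_betweenness", "ppi_hub", "mirna_count",
    "expression_breadth", "chromatin_state", "evolutionary_origin",
]


def _generate_properties(
    spec: CohortSpec, gene_ids: list[str], cancer_like: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(gene_ids)
    cols: dict[str, object] = {}
    for name, (mu, sd) in _CONTINUOUS_PARAMS.items():
        x = rng.normal(mu, sd, size=n)
        x[cancer_like] += spec.feature_shift * sd
        x = np.maximum(x, _CONTINUOUS_MIN[name])
        if name in ("domain_count", "ppi_degree", "mirna_count", "expression_breadth"):
            x = np.round(x)
        if name == "expression_breadth":
            x = np.minimum(x, 30)
        cols[name] = x
    for name, (p_bg, p_cl) in _BOOLEAN_PROBS.items():
        p = np.where(cancer_like, p_cl, p_bg)
        cols[name] = rng.random(n) < p
    origin = np.empty(n, dtype=object)
    chromatin = np.empty(n, dtype=object)
    for i in range(n):
        op = _ORIGIN_PROBS_CANCER if cancer_like[i] else _ORIGIN_PROBS_BG
        cp = _CHROMATIN_PROBS_CANCER if cancer_like[i] else _CHROMATIN_PROBS_BG
        origin[i] = EVOLUTIONARY_ORIGINS[rng.choice(len(op), p=op)]
        chromatin[i] = CHROMATIN_STATES[rng.choice(len(cp), p=cp)]
    cols["evolutionary_origin"] = origin
    cols["chromatin_state"] = chromatin
    props = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    props = props[SYSTEMS_PROPERTY_COLUMNS]
    # plant missingness (real annotation is complete only for length,
    # duplication and ohnolog status)
    for col in _MISSING_ELIGIBLE:
        mask = rng.random(n) < spec.missingness
        if mask.any():
            props[col] = props[col].astype(object)
            props.loc[mask, col] = None
    return props


def _damaging_small_variant(
    sample: str, gene: str, kind: str, rng: np.random.Generator, gof: bool = False
) -> SmallVariant:
    vaf = float(rng.uniform(0.15, 0.8))
    if kind == "truncating":
        choices = [Consequence.STOPGAIN, Consequence.STOPLOSS, Consequence.FRAMESHIFT]
        cons = choices[int(rng.choice(3, p=[0.55, 0.05, 0.40]))]
        indel = int(rng.integers(1, 4)) if cons == Consequence.FRAMESHIFT else 0
        return SmallVariant(sample, gene, cons, vaf, indel_length=indel, gof_flag=gof)
    if kind == "non_truncating":
        votes = int(rng.integers(5, 8))
        func = tuple(i < votes for i in range(7))
        cons_votes = int(rng.integers(0, 4))
        cons = tuple(i < cons_votes for i in range(3))
        return SmallVariant(sample, gene, Consequence.NONSYNONYMOUS, vaf,
                            functional_calls=func, conservation_calls=cons, gof_flag=gof)
    if kind == "splicing":
        votes = int(rng.integers(1, 3))
        return SmallVariant(sample, gene, Consequence.SPLICING, vaf,
                            splicing_calls=tuple(i < votes for i in range(2)), gof_flag=gof)
    raise ValueError(kind)


def _passenger_small_variant(sample: str, gene: str, rng: np.random.Generator) -> SmallVariant:
    vaf = float(rng.uniform(0.15, 0.6))
    if rng.random() < 0.6:
        return SmallVariant(sample, gene, Consequence.SILENT, vaf)
    # sub-threshold nonsynonymous: at most 4/7 functional, at most 1/3 conservation
    fv = int(rng.integers(0, 5))
    cv = int(rng.integers(0, 2))
    return SmallVariant(
        sample, gene, Consequence.NONSYNONYMOUS, vaf,
        functional_calls=tuple(i < fv for i in range(7)),
        conservation_calls=tuple(i < cv for i in range(3)),
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort, deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_cancer_like = spec.n_known_cancer_genes + spec.n_planted_helpers
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    planted_idx = rng.choice(spec.n_genes, size=n_cancer_like, replace=False)
    known = sorted(gene_ids[i] for i in planted_idx[: spec.n_known_cancer_genes])
    helpers = sorted(gene_ids[i] for i in planted_idx[spec.n_known_cancer_genes:])
    cancer_like = np.zeros(spec.n_genes, dtype=bool)
    cancer_like[planted_idx] = True

    properties = _generate_properties(spec, gene_ids, cancer_like, rng)

    # gene intervals on a synthetic genome: 5 chromosomes, 100 kb spacing
    lengths = properties["gene_length"].to_numpy()
    intervals = []
    for i, g in enumerate(gene_ids):
        chrom = f"chr{i % 5 + 1}"
        start = (i // 5) * 100_000
        intervals.append(GeneInterval(g, chrom, start, start + int(max(lengths[i], 150))))
    interval_by_gene = {iv.gene_id: iv for iv in intervals}

    samples = [f"S{i:04d}" for i in range(spec.n_patients)]
    ploidies = rng.choice([2.0, 2.0, 2.0, 3.0, 4.0], size=spec.n_patients)

    # planted patient clusters and their signature pathways
    cluster_of = pd.Series(
        (np.arange(spec.n_patients) % spec.n_planted_clusters) + 1, index=samples,
        name="cluster",
    )
    lo, hi = spec.pathway_size
    pathway_sets: dict[str, frozenset[str]] = {}
    pathway_levels: dict[str, int] = {}
    pathway_cluster: dict[str, int] = {}
    for p in range(spec.n_pathways):
        name = f"PW{p:03d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(spec.n_genes, size=size, replace=False)
        pathway_sets[name] = frozenset(gene_ids[i] for i in members)
        pathway_levels[name] = 3 + int(rng.integers(0, 3))
        pathway_cluster[name] = p % spec.n_planted_clusters + 1
    gene_sets = GeneSetCollection(
        sets=pathway_sets, levels=pathway_levels,
        universe=frozenset(gene_ids),
    )

    weights = np.where(cancer_like, spec.cancer_gene_damage_weight, 1.0)
    weights = weights / weights.sum()
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    variants: list[SmallVariant] = []
    segments: list[CopyNumberSegment] = []
    svs: list[StructuralVariant] = []

    for si, sample in enumerate(samples):
        ploidy = float(ploidies[si])
        n_dmg = max(5, int(rng.poisson(spec.damaged_genes_per_patient)))
        n_dmg = min(n_dmg, spec.n_genes)
        chosen = set(rng.choice(spec.n_genes, size=n_dmg, replace=False, p=weights))
        # cluster signal: perturb the cluster's signature pathways
        for pw, members in pathway_sets.items():
            cl = pathway_cluster[pw]
            rate = (
                spec.cluster_pathway_rate
                if cl == int(cluster_of[sample])
                else spec.background_pathway_rate
            )
            if rng.random() < rate:
                pick = sorted(members)[int(rng.integers(0, len(members)))]
                chosen.add(gene_index[pick])
        for gi in sorted(chosen):
            gene = gene_ids[gi]
            p_gain = (
                spec.gain_fraction_cancer if cancer_like[gi]
                else spec.gain_fraction_background
            )
            rest = 1.0 - p_gain
            kinds = ["gain", "loss", "truncating", "non_truncating", "splicing", "sv"]
            probs = np.array(
                [p_gain, 0.05 * rest / 0.95, 0.25 * rest / 0.95,
                 0.50 * rest / 0.95, 0.07 * rest / 0.95, 0.13 * rest / 0.95]
            )
            probs = probs / probs.sum()
            kind = kinds[int(rng.choice(len(kinds), p=probs))]
            gof = bool(cancer_like[gi] and rng.random() < 0.05)
            iv = interval_by_gene[gene]
            if kind == "gain":
                cn = ploidy + float(rng.integers(1, 5))
                segments.append(CopyNumberSegment(
                    sample, iv.chrom, max(0, iv.start - 1000), iv.end + 1000,
                    absolute_cn=cn, sample_ploidy=ploidy,
                ))
            elif kind == "loss":
                segments.append(CopyNumberSegment(
                    sample, iv.chrom, max(0, iv.start - 1000), iv.end + 1000,
                    absolute_cn=0.0, sample_ploidy=ploidy,
                ))
            elif kind == "sv":
                sv_types = list(SVType)
                svs.append(StructuralVariant(
                    sample, gene, sv_types[int(rng.integers(0, len(sv_types)))]
                ))
            else:
                variants.append(_damaging_small_variant(sample, gene, kind, rng, gof=gof))
        # passenger mutations (silent / sub-threshold), ~30% of the damage count
        n_pass = int(rng.poisson(0.3 * n_dmg))
        for gi in rng.choice(spec.n_genes, size=n_pass, replace=True, p=weights):
            variants.append(_passenger_small_variant(sample, gene_ids[int(gi)], rng))

    # normal-tissue expression; planted genes always expressed
    expr = np.round(rng.lognormal(mean=2.0, sigma=1.0, size=spec.n_genes), 3)
    background_idx = np.flatnonzero(~cancer_like)
    n_off = int(spec.unexpressed_fraction * spec.n_genes)
    off = rng.choice(background_idx, size=min(n_off, len(background_idx)), replace=False)
    expr[off] = 0.0
    expression = pd.Series(expr, index=pd.Index(gene_ids, name="gene_id"), name="expression")

    germline_variants, site_stats, predisposition = _generate_germline(spec, gene_ids, samples, rng)

    return SyntheticCohort(
        spec=spec,
        gene_ids=gene_ids,
        known_cancer_genes=known,
        planted_helpers=helpers,
        gene_intervals=intervals,
        properties=properties,
        variants=variants,
        segments=segments,
        svs=svs,
        expression=expression,
        gene_sets=gene_sets,
        pathway_levels=pathway_levels,
        true_clusters=cluster_of,
        germline_variants=germline_variants,
        germline_site_stats=site_stats,
        predisposition_genes=predisposition,
    )


def _generate_germline(
    spec: CohortSpec, gene_ids: list[str], samples: list[str], rng: np.random.Generator
) -> tuple[list[GermlineVariant], dict[str, SiteGenotypeStats], list[str]]:
    predisposition = sorted(
        gene_ids[i] for i in rng.choice(
            len(gene_ids), size=min(spec.n_predisposition_genes, len(gene_ids)),
            replace=False,
        )
    )
    variants: list[GermlineVariant] = []
    stats: dict[str, SiteGenotypeStats] = {}
    n_samples = max(len(samples), 10)
    for i in range(spec.n_germline_variants):
        site = f"V{i:05d}"
        sample = samples[int(rng.integers(0, len(samples)))]
        # a quarter of sites fall in predisposition genes to exercise flagging
        if rng.random() < 0.25:
            gene = predisposition[int(rng.integers(0, len(predisposition)))]
        else:
            gene = gene_ids[int(rng.integers(0, len(gene_ids)))]
        depth = int(rng.integers(30, 150))
        het = rng.random() < 0.7
        if het:
            vaf = float(np.clip(rng.normal(0.5, np.sqrt(0.25 / depth)), 0.0, 1.0))
            if rng.random() < 0.10:  # artefactual outliers
                vaf = float(rng.uniform(0.05, 0.30))
        else:
            vaf = float(rng.uniform(0.95, 1.0))
            if rng.random() < 0.05:
                vaf = float(rng.uniform(0.70, 0.94))
        # reference / cohort MAF structure: mostly concordant, some inflated
        if rng.random() < 0.6:  # rare
            maf_ref = float(rng.uniform(0.0, 0.009))
            maf_cohort = float(np.clip(maf_ref + rng.normal(0, 0.002), 0.0, 1.0))
        else:  # common
            maf_ref = float(rng.uniform(0.02, 0.4))
            maf_cohort = float(np.clip(maf_ref * rng.uniform(0.7, 1.3), 0.0, 1.0))
        if rng.random() < 0.08:  # cohort-inflated artefact
            maf_cohort = float(rng.uniform(0.11, 0.35))
            maf_ref = float(rng.uniform(0.0, 0.001))
        maf_exac = maf_ref
        maf_1kg = float(np.clip(maf_ref * rng.uniform(0.8, 1.2), 0.0, 1.0))
        # site genotype statistics, occasionally with excess heterozygosity
        p_minor = max(min(maf_cohort, 1.0 - maf_cohort), 1.0 / (2 * n_samples))
        hw_het = 2.0 * p_minor * (1.0 - p_minor)
        p_het = float(np.clip(
            hw_het * (rng.uniform(2.5, 4.0) if rng.random() < 0.07 else rng.uniform(0.6, 1.1)),
            0.0, 1.0,
        ))
        stats[site] = SiteGenotypeStats(p_het=p_het, p_major=1.0 - p_minor, p_minor=p_minor)
        r = rng.random()
        if r < 0.15:
            truncating = [Consequence.STOPGAIN, Consequence.STOPLOSS, Consequence.FRAMESHIFT]
            cons = truncating[int(rng.integers(0, 3))]
            func = None
        elif r < 0.75:
            cons = Consequence.NONSYNONYMOUS
            votes = int(rng.integers(0, 8))
            func = tuple(j < votes for j in range(7))
        else:
            cons = Consequence.SILENT
            func = tuple(False for _ in range(7))
        variants.append(GermlineVariant(
            sample_id=sample, gene_id=gene,
            genotype="het" if het else "hom",
            vaf=vaf, depth=depth, consequence=cons, functional_calls=func,
            maf_cohort=maf_cohort, maf_exac=maf_exac, maf_1kg=maf_1kg,
            site_id=site,
        ))
    return variants, stats, predisposition


def generate_block_profiles(
    n_samples: int = 60,
    n_clusters: int = 3,
    pathways_per_cluster: int = 12,
    within_rate: float = 0.85,
    noise_rate: float = 0.02,
    seed: int = 0,
) -> tuple[dict[str, frozenset[str]], pd.Series]:
    """Block-structured perturbation profiles with planted cluster labels.

    Each cluster owns a disjoint pathway pool; a sample perturbs each pathway
    of its own pool with probability ``within_rate`` and any foreign pathway
    with probability ``noise_rate``, giving high within-block and low
    between-block Jaccard similarity.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    labels = pd.Series(
        (np.arange(n_samples) % n_clusters) + 1, index=samples, name="cluster"
    )
    pools = {
        c + 1: [f"PW{c}_{j:02d}" for j in range(pathways_per_cluster)]
        for c in range(n_clusters)
    }
    profiles: dict[str, frozenset[str]] = {}
    for s in samples:
        own = int(labels[s])
        chosen = set()
        for c, pool in pools.items():
            rate = within_rate if c == own else noise_rate
            for pw in pool:
                if rng.random() < rate:
                    chosen.add(pw)
        if not chosen:  # guarantee a non-empty profile
            chosen.add(pools[own][0])
        profiles[s] = frozenset(chosen)
    return profiles, labels


def generate_worked_fixture(seed: int = 7) -> SyntheticCohort:
    """Tiny hand-checkable cohort: 4 patients, 40 genes."""
    spec = CohortSpec(
        n_patients=4, n_genes=40, n_known_cancer_genes=8, n_planted_helpers=6,
        damaged_genes_per_patient=12.0, n_pathways=6, pathway_size=(10, 14),
        n_planted_clusters=2, n_germline_variants=40, n_predisposition_genes=5,
        seed=seed,
    )
    return generate_cohort(spec)
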