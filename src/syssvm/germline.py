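"""Germline variant filtration cascade.

Four filters applied in order, each with a machine-readable drop reason:

1. VAF plausibility — heterozygous calls deviating from 50% by more than
   z = 2.6 binomial standard deviations (sd = sqrt(0.25/depth)), and
   homozygous calls with VAF below 95%, are removed.
2. Cohort-MAF inflation — variants with cohort MAF > 10% that exceed
   sqrt(10 x MAF_reference) against either reference panel are removed.
3. Heterozygosity excess — sites with a heterozygote proportion above the
   Hardy-Weinberg-motivated bound 1.04 - sqrt(1.04 - 3.74 p_A p_a) are
   removed.
4. Rare damaging retention — survivors are kept only if damaging
   (frameshift/stopgain/stoploss, or >=5 of 7 functional predictors) and
   rare (MAF < 1% in both reference panels); patients carrying a retained
   variant in a predisposition gene are flagged.

All inequalities are strict, exactly as stated; no filter mutates its input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .alterations import (
    Consequence,
    N_FUNCTIONAL_PREDICTORS,
    FUNCTIONAL_MIN_VOTES,
    TRUNCATING_CONSEQUENCES,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GermlineVariant:
    sample_id: str
    gene_id: str
    genotype: str  # "het" | "hom"
    vaf: float
    depth: int
    consequence: Consequence
    functional_calls: tuple[bool, ...] | None = None
    maf_cohort: float = 0.0
    maf_exac: float = 0.0
    maf_1kg: float = 0.0
    site_id: str | None = None  # joins site-level genotype statistics

    def __post_init__(self) -> None:
        if self.genotype not in ("het", "hom"):
            raise ValueError("genotype must be 'het' or 'hom'")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must be in [0,1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for f in ("maf_cohort", "maf_exac", "maf_1kg"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0,1]")
        object.__setattr__(self, "consequence", Consequence(self.consequence))
        if self.functional_calls is not None:
            calls = tuple(bool(c) for c in self.functional_calls)
            if len(calls) != N_FUNCTIONAL_PREDICTORS:
                raise ValueError(
                    f"functional_calls must have {N_FUNCTIONAL_PREDICTORS} entries"
                )
            object.__setattr__(self, "functional_calls", calls)


@dataclass(frozen=True)
class SiteGenotypeStats:
    """Per-site heterozygote proportion and allele frequencies."""

    p_het: float
    p_major: float
    p_minor: float

    def __post_init__(self) -> None:
        if abs(self.p_major + self.p_minor - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")
        if not 0.0 <= self.p_het <= 1.0:
            raise ValueError("p_het must be in [0,1]")


def site_stats_from_counts(
    n_het: int, n_hom_alt: int, n_samples: int
) -> SiteGenotypeStats:
    """Site statistics from cohort genotype counts at one site."""
    if n_samples < 1 or n_het + n_hom_alt > n_samples:
        raise ValueError("invalid genotype counts")
    alt = (n_het + 2 * n_hom_alt) / (2 * n_samples)
    p_minor = min(alt, 1.0 - alt)
    return SiteGenotypeStats(
        p_het=n_het / n_samples, p_major=1.0 - p_minor, p_minor=p_minor
    )


def filter_vaf(
    v: GermlineVariant, z: float = 2.6, hom_min: float = 0.95
) -> tuple[bool, str | None]:
    """VAF plausibility filter; returns (keep, reason)."""
    if v.genotype == "het":
        sd = math.sqrt(0.25 / v.depth)
        if abs(v.vaf - 0.5) > z * sd:
            return False, "het_vaf_outlier"
    else:
        if v.vaf < hom_min:
            return False, "hom_vaf_low"
    return True, None


def maf_inflation_threshold(maf_reference: float) -> float:
    """Cohort-MAF ceiling relative to a reference panel: sqrt(10 x MAF_ref)."""
    return math.sqrt(10.0 * maf_reference)


def filter_maf_inflation(
    v: GermlineVariant, maf_max: float = 0.10
) -> tuple[bool, str | None]:
    """Drop variants with inflated cohort MAF vs either reference panel.

    Missing reference MAFs are treated as 0 (any cohort MAF above
    ``maf_max`` is then inflated).
    """
    if v.maf_cohort > maf_max and (
        v.maf_cohort > maf_inflation_threshold(v.maf_exac)
        or v.maf_cohort > maf_inflation_threshold(v.maf_1kg)
    ):
        return False, "maf_inflated"
    return True, None


def het_excess_threshold(p_major: float, p_minor: float) -> float:
    """Maximum heterozygote proportion consistent with Hardy-Weinberg."""
    radicand = 1.04 - 3.74 * p_major * p_minor
    if radicand < 0:
        logger.warning("heterozygosity-excess radicand clipped at 0")
        radicand = 0.0
    return 1.04 - math.sqrt(radicand)


def filter_het_excess(s: SiteGenotypeStats) -> tuple[bool, str | None]:
    """Drop sites whose heterozygote proportion exceeds the HW bound."""
    if s.p_het > het_excess_threshold(s.p_major, s.p_minor):
        return False, "het_excess"
    return True, None


def is_germline_damaging(v: GermlineVariant) -> bool:
    """Truncating consequence, or >=5/7 function-based predictor votes."""
    if v.consequence in TRUNCATING_CONSEQUENCES:
        return True
    if v.functional_calls is None:
        return False
    return sum(v.functional_calls) >= FUNCTIONAL_MIN_VOTES


def select_rare_damaging(
    variants: Sequence[GermlineVariant],
    predisposition_genes: set[str],
    maf_max: float = 0.01,
) -> tuple[list[GermlineVariant], pd.DataFrame]:
    """Retain rare damaging variants and flag predisposition carriers.

    A variant is retained iff damaging and with MAF below ``maf_max`` in both
    reference panels. Returns the retained variants and a per-patient table
    with the predisposition flag (>=1 retained variant in a predisposition
    gene).
    """
    if not predisposition_genes:
        logger.warning("empty predisposition gene list; no patients will be flagged")
    retained = [
        v
        for v in variants
        if is_germline_damaging(v) and v.maf_exac < maf_max and v.maf_1kg < maf_max
    ]
    flags: dict[str, bool] = {}
    for v in variants:
        flags.setdefault(v.sample_id, False)
    for v in retained:
        if v.gene_id in predisposition_genes:
            flags[v.sample_id] = True
    table = pd.DataFrame(
        {"sample_id": sorted(flags), "predisposition": [flags[s] for s in sorted(flags)]}
    )
    return retained, table


def apply_germline_filters(
    variants: Sequence[GermlineVariant],
    site_stats: Mapping[str, SiteGenotypeStats] | None = None,
    predisposition_genes: set[str] | None = None,
    z: float = 2.6,
    hom_min: float = 0.95,
    maf_inflation_max: float = 0.10,
    rare_max: float = 0.01,
) -> tuple[list[GermlineVariant], pd.DataFrame, pd.DataFrame]:
    """Run the full cascade in order; returns (retained, drops, patient flags).

    ``site_stats`` maps ``site_id`` to cohort genotype statistics; variants
    without statistics skip the heterozygosity-excess filter. The drops table
    carries one reason code per removed variant.
    """
    surviving: list[GermlineVariant] = []
    drops: list[dict] = []

    def drop(v: GermlineVariant, reason: str) -> None:
        drops.append(
            {"sample_id": v.sample_id, "gene_id": v.gene_id,
             "site_id": v.site_id or "", "reason": reason}
        )

    for v in variants:
        keep, reason = filter_vaf(v, z=z, hom_min=hom_min)
        if not keep:
            drop(v, reason)
            continue
        keep, reason = filter_maf_inflation(v, maf_max=maf_inflation_max)
        if not keep:
            drop(v, reason)
            continue
        if site_stats is not None and v.site_id in site_stats:
            keep, reason = filter_het_excess(site_stats[v.site_id])
            if not keep:
                drop(v, reason)
                continue
        surviving.append(v)

    retained, flags = select_rare_damaging(
        surviving, predisposition_genes or set(), maf_max=rare_max
    )
    retained_ids = {id(v) for v in retained}
    for v in surviving:
        if id(v) not in retained_ids:
            drop(v, "not_rare_damaging")
    drops_frame = pd.DataFrame(
        drops, columns=["sample_id", "gene_id", "site_id", "reason"]
    )
    return retained, drops_frame, flags
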