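"""End-to-end cohort prioritization: alterations -> features -> ensemble -> consensus.

Convenience layer tying the modules together for in-memory cohorts (real or
synthetic). Each step is the public API of its module; nothing here adds
behaviour beyond composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import alterations as alt
from . import features as feat
from . import model as mdl
from .simulate import SyntheticCohort

__all__ = [
    "PrioritizationResult",
    "prioritize_cohort",
    "build_feature_matrix",
    "helper_recovery",
    "holdout_known_gene_scores",
]


def build_feature_matrix(
    cohort: SyntheticCohort,
    vaf_min: float = 0.10,
    max_indel: int = 5,
    schema: feat.FeatureSchema = feat.DEFAULT_SCHEMA,
) -> tuple[pd.DataFrame, feat.ScalingParams]:
    """Scaled 34-feature matrix of all damaged (sample, gene) pairs."""
    variants = alt.filter_variants(cohort.variants, vaf_min=vaf_min, max_indel=max_indel)
    profiles = alt.build_molecular_profiles(
        variants, cohort.segments, cohort.svs, cohort.gene_intervals
    )
    frame = alt.profiles_to_frame(profiles)
    imputed = feat.impute_missing(cohort.properties, set(cohort.known_cancer_genes), schema)
    matrix = feat.assemble_feature_matrix(frame, imputed, schema)
    return feat.scale_features(matrix)


@dataclass
class PrioritizationResult:
    matrix: pd.DataFrame
    scaling: feat.ScalingParams
    best_sets: list[mdl.BestModelSet]
    helper_lists: list[frozenset[str]]
    scores_by_config: dict[tuple, pd.DataFrame]
    consensus: mdl.ConsensusResult

    @property
    def modal_scores(self) -> pd.DataFrame:
        """Score table of the configuration behind the modal helper list."""
        for bs in self.best_sets:
            key = bs.key()
            scores = self.scores_by_config[key]
            if mdl.helper_union(mdl.topk_per_sample(scores)) == self.consensus.modal_list:
                return scores
        return next(iter(self.scores_by_config.values()))


def prioritize_cohort(
    cohort: SyntheticCohort,
    n_iter: int = 300,
    checkpoint_every: int = 100,
    repeats: int = 5,
    grid: dict | None = None,
    seed: int = 0,
    k: int = 10,
    use_expression_filter: bool = True,
) -> PrioritizationResult:
    """Run the full prioritization on a cohort bundle.

    Trains on the known-cancer-gene vectors, scores all other damaged genes
    per patient under every selected best-model set, and tallies the
    cohort-level helper lists into a consensus.
    """
    scaled, params = build_feature_matrix(cohort)
    if grid is None:
        grid = mdl.small_grid()
    records = mdl.cv_grid_search(
        scaled, cohort.known_cancer_genes, grid=grid, n_iter=n_iter, seed=seed
    )
    best = mdl.select_best_models(
        records, checkpoint_every=checkpoint_every, repeats=repeats, seed=seed
    )
    genes = scaled.index.get_level_values("gene_id")
    known = set(cohort.known_cancer_genes)
    train = scaled[genes.isin(known)]
    predict = scaled[~genes.isin(known)]
    expr = cohort.expression if use_expression_filter else None
    lists, distinct = mdl.score_with_model_sets(best, train, predict, expression=expr, k=k)
    consensus = mdl.consensus_helpers(lists)
    return PrioritizationResult(
        matrix=scaled, scaling=params, best_sets=best,
        helper_lists=lists, scores_by_config=distinct, consensus=consensus,
    )


def helper_recovery(
    scores: pd.DataFrame, planted_helpers: set[str], k: int = 10
) -> tuple[float, float]:
    """(mean per-sample top-k precision, random-selection baseline).

    The baseline is the per-sample fraction of scored genes that are planted
    helpers — the expected top-k precision of a random ranking.
    """
    topk = mdl.topk_per_sample(scores, k=k)
    precision = float(np.mean(
        [len(set(g) & planted_helpers) / len(g) for g in topk.values()]
    ))
    baselines = []
    for _, sub in scores.groupby(level="sample_id"):
        genes = set(sub.index.get_level_values("gene_id"))
        baselines.append(len(genes & planted_helpers) / len(genes))
    return precision, float(np.mean(baselines))


def holdout_known_gene_scores(
    matrix: pd.DataFrame,
    known_genes: list[str],
    best: mdl.BestModelSet,
    cancer_like: set[str],
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Validation-mode check: held-out known cancer genes vs background.

    Holds out one third of the known cancer genes, trains the best-model set
    on the rest, scores everything else (held-out knowns included), and
    returns the one-sided rank-sum p that held-out known genes score above
    genes outside the cancer-like set.
    """
    train_genes, heldout = mdl.split_training(known_genes, seed)
    genes = matrix.index.get_level_values("gene_id")
    train = matrix[genes.isin(set(train_genes))]
    predict = matrix[~genes.isin(set(train_genes))]
    scores = mdl.train_and_score(best, train, predict)
    pg = scores.index.get_level_values("gene_id")
    held_scores = scores.loc[pg.isin(set(heldout)), "combined_score"]
    background = scores.loc[~pg.isin(cancer_like), "combined_score"]
    _, p = mannwhitneyu(held_scores, background, alternative="greater")
    return float(p), scores
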