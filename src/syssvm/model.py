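"""One-class SVM ensemble: grid search, model selection, scoring, consensus, RFE.

The classifiers are trained on the feature vectors of known cancer genes only
(novelty detection, no negative class). Four kernels — linear, radial,
sigmoid, polynomial — are tuned by iterated three-fold cross-validation: at
each iteration the known cancer genes are split 2/3 train / 1/3 test and each
candidate configuration is scored by its sensitivity, the fraction of
held-out known-cancer-gene vectors predicted as members. At every checkpoint
of ``checkpoint_every`` iterations the best configuration per kernel is the
one maximizing the median sensitivity over all iterations seen so far (ties:
minimum variance, then grid order); the walk over checkpoints is repeated
with shuffled iteration orders, yielding ``repeats * n_iter /
checkpoint_every`` best-model sets (500 at the documented full scale of
10,000 iterations, checkpoint 100, 5 repeats).

Each best-model set then trains the four kernels on the full known-gene set
and scores every altered (sample, gene) vector: per kernel, the cohort-wide
percentile of the decision value; combined score = mean of the four
percentiles; genes are ranked per sample. The per-sample top-k genes are the
candidate helpers, and the modal cohort-level list across the best-model sets
is the final prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import OneClassSVM

logger = logging.getLogger(__name__)

KERNELS = ("linear", "radial", "sigmoid", "polynomial")
_SKLEARN_KERNEL = {"linear": "linear", "radial": "rbf", "sigmoid": "sigmoid", "polynomial": "poly"}


class ConsensusTieError(RuntimeError):
    """Two distinct helper lists are tied for the modal position."""


@dataclass(frozen=True, order=True)
class KernelConfig:
    """One kernel plus its hyperparameters."""

    kernel: str
    nu: float
    gamma: float | None = None
    degree: int | None = None
    coef0: float | None = None

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must be in (0, 1]")

    def estimator(self) -> OneClassSVM:
        kwargs: dict = {"kernel": _SKLEARN_KERNEL[self.kernel], "nu": self.nu}
        if self.kernel != "linear":
            kwargs["gamma"] = self.gamma if self.gamma is not None else "scale"
        if self.kernel == "polynomial":
            kwargs["degree"] = self.degree if self.degree is not None else 3
        if self.kernel in ("polynomial", "sigmoid"):
            kwargs["coef0"] = self.coef0 if self.coef0 is not None else 0.0
        return OneClassSVM(**kwargs)

    def label(self) -> str:
        parts = [self.kernel, f"nu={self.nu:g}"]
        if self.gamma is not None:
            parts.append(f"gamma={self.gamma:g}")
        if self.degree is not None:
            parts.append(f"degree={self.degree}")
        if self.coef0 is not None:
            parts.append(f"coef0={self.coef0:g}")
        return ",".join(parts)


NU_GRID = (0.01, 0.05, 0.1, 0.2, 0.3)
GAMMA_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
DEGREE_GRID = (2, 3, 4)
COEF0_GRID = (0.0, 1.0)


def default_grid() -> dict[str, list[KernelConfig]]:
    """Documented default hyperparameter grid (230 configurations)."""
    grid: dict[str, list[KernelConfig]] = {k: [] for k in KERNELS}
    for nu in NU_GRID:
        grid["linear"].append(KernelConfig("linear", nu))
        for gamma in GAMMA_GRID:
            grid["radial"].append(KernelConfig("radial", nu, gamma=gamma))
            for coef0 in COEF0_GRID:
                grid["sigmoid"].append(KernelConfig("sigmoid", nu, gamma=gamma, coef0=coef0))
                for degree in DEGREE_GRID:
                    grid["polynomial"].append(
                        KernelConfig("polynomial", nu, gamma=gamma, degree=degree, coef0=coef0)
                    )
    return grid


def small_grid() -> dict[str, list[KernelConfig]]:
    """Desk-scale grid (12 configurations) for quick runs and CI."""
    grid: dict[str, list[KernelConfig]] = {k: [] for k in KERNELS}
    for nu in (0.05, 0.2):
        grid["linear"].append(KernelConfig("linear", nu))
        for gamma in (0.01, 0.1):
            grid["radial"].append(KernelConfig("radial", nu, gamma=gamma))
        grid["sigmoid"].append(KernelConfig("sigmoid", nu, gamma=0.01, coef0=0.0))
        for degree in (2, 3):
            grid["polynomial"].append(
                KernelConfig("polynomial", nu, gamma=0.01, degree=degree, coef0=0.0)
            )
    return grid


def split_training(
    training_genes: Sequence[str], seed: int | np.random.Generator
) -> tuple[list[str], list[str]]:
    """Seeded 2/3 train / 1/3 test partition of the known cancer genes."""
    genes = sorted(set(training_genes))
    n = len(genes)
    if n < 3:
        raise ValueError("need at least 3 training genes to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = math.ceil(2 * n / 3)
    train = [genes[i] for i in perm[:n_train]]
    test = [genes[i] for i in perm[n_train:]]
    return train, test


@dataclass
class CVRecords:
    """Sensitivity records of a grid search, plus the grid that produced them."""

    sensitivities: dict[str, np.ndarray]  # kernel -> (n_configs, n_iter)
    grid: dict[str, list[KernelConfig]]
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kernel in KERNELS:
            sens = self.sensitivities[kernel]
            for ci, cfg in enumerate(self.grid[kernel]):
                for it in range(self.n_iter):
                    rows.append(
                        {
                            "kernel": kernel,
                            "config": cfg.label(),
                            "iteration": it,
                            "sensitivity": sens[ci, it],
                        }
                    )
        return pd.DataFrame(rows)


def cv_grid_search(
    matrix: pd.DataFrame,
    training_genes: Sequence[str],
    grid: Mapping[str, Sequence[KernelConfig]] | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
) -> CVRecords:
    """Iterated three-fold cross-validation over the hyperparameter grid.

    ``matrix`` is the scaled feature matrix indexed by (sample_id, gene_id).
    Each iteration splits the known cancer genes 2/3 / 1/3; every
    configuration is trained on the train-gene vectors and its sensitivity is
    the member fraction among the test-gene vectors. Degenerate folds (no
    vectors on either side) are resampled and logged.
    """
    if grid is None:
        grid = default_grid()
    grid = {k: list(v) for k, v in grid.items()}
    for kernel in KERNELS:
        if not grid.get(kernel):
            raise ValueError(f"grid has no configurations for kernel {kernel!r}")

    genes = matrix.index.get_level_values("gene_id").to_numpy()
    known = sorted(set(training_genes) & set(genes))
    if len(known) < 3:
        raise ValueError("fewer than 3 known cancer genes present in the matrix")
    gene_rows: dict[str, np.ndarray] = {}
    order = np.argsort(genes, kind="stable")
    sorted_genes = genes[order]
    values = matrix.to_numpy(dtype=float)
    for g in known:
        lo = np.searchsorted(sorted_genes, g, side="left")
        hi = np.searchsorted(sorted_genes, g, side="right")
        gene_rows[g] = order[lo:hi]

    rng = np.random.default_rng(seed)
    sens = {k: np.zeros((len(grid[k]), n_iter)) for k in KERNELS}
    for it in range(n_iter):
        for _attempt in range(100):
            train_g, test_g = split_training(known, rng)
            tr_idx = np.concatenate([gene_rows[g] for g in train_g])
            te_idx = np.concatenate([gene_rows[g] for g in test_g]) if test_g else np.array([], int)
            if len(tr_idx) and len(te_idx):
                break
            logger.info("degenerate fold at iteration %d resampled", it)
        X_tr = values[tr_idx]
        X_te = values[te_idx]
        for kernel in KERNELS:
            for ci, cfg in enumerate(grid[kernel]):
                est = cfg.estimator()
                est.fit(X_tr)
                sens[kernel][ci, it] = float(np.mean(est.predict(X_te) == 1))
    return CVRecords(sensitivities=sens, grid=grid, n_iter=n_iter)


@dataclass(frozen=True)
class BestModelSet:
    """One tuned configuration per kernel, selected at a CV checkpoint."""

    models: tuple[tuple[str, KernelConfig], ...]  # ordered (kernel, config)
    checkpoint: int
    repeat: int

    @property
    def configs(self) -> dict[str, KernelConfig]:
        return dict(self.models)

    def key(self) -> tuple:
        """Hyperparameter identity, ignoring checkpoint/repeat provenance."""
        return tuple(cfg for _, cfg in self.models)


def select_best_models(
    records: CVRecords,
    checkpoint_every: int = 100,
    repeats: int = 5,
    seed: int = 0,
) -> list[BestModelSet]:
    """Checkpointed best-model selection with shuffled repeats.

    At each checkpoint the winning configuration per kernel maximizes the
    median sensitivity over all iterations seen so far in the (seeded)
    shuffled order; ties go to minimum variance, then grid order. Returns
    ``repeats * n_iter / checkpoint_every`` best-model sets.
    """
    n_iter = records.n_iter
    if n_iter % checkpoint_every != 0:
        raise ValueError("checkpoint_every must divide n_iter")
    n_checkpoints = n_iter // checkpoint_every
    rng = np.random.default_rng(seed)
    out: list[BestModelSet] = []
    for rep in range(repeats):
        order = rng.permutation(n_iter)
        for cp in range(1, n_checkpoints + 1):
            prefix = order[: cp * checkpoint_every]
            chosen = []
            for kernel in KERNELS:
                S = records.sensitivities[kernel][:, prefix]
                med = np.median(S, axis=1)
                var = np.var(S, axis=1)
                best = np.flatnonzero(med == med.max())
                if len(best) > 1:
                    sub = best[var[best] == var[best].min()]
                    best = sub
                chosen.append((kernel, records.grid[kernel][int(best[0])]))
            out.append(BestModelSet(models=tuple(chosen), checkpoint=cp, repeat=rep))
    return out


def train_and_score(
    best: BestModelSet,
    train_matrix: pd.DataFrame,
    predict_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Train the four tuned kernels and score every prediction vector.

    Per kernel: the decision value of each (sample, gene) vector and its
    cohort-wide percentile (average rank / n). The combined score is the mean
    of the four percentiles; genes are ranked 1..n per sample by descending
    combined score, ties broken by gene id.
    """
    if list(train_matrix.columns) != list(predict_matrix.columns):
        raise ValueError("training and prediction matrices must share the feature schema")
    X_tr = train_matrix.to_numpy(dtype=float)
    X_pr = predict_matrix.to_numpy(dtype=float)
    n = len(predict_matrix)
    scores = pd.DataFrame(index=predict_matrix.index)
    pct_cols = []
    for kernel, cfg in best.models:
        est = cfg.estimator()
        est.fit(X_tr)
        dv = est.decision_function(X_pr)
        pct = rankdata(dv, method="average") / n
        scores[f"decision_{kernel}"] = dv
        scores[f"percentile_{kernel}"] = pct
        pct_cols.append(f"percentile_{kernel}")
    scores["combined_score"] = scores[pct_cols].mean(axis=1)
    scores = rank_scores(scores)
    return scores


def rank_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """(Re)assign per-sample ranks 1..n by descending combined score.

    Equal combined scores are broken lexicographically by gene id, so ranks
    are always a permutation of 1..n within each sample.
    """
    scores = scores.copy()
    frame = scores.reset_index()
    frame = frame.sort_values(
        ["sample_id", "combined_score", "gene_id"], ascending=[True, False, True]
    )
    frame["rank"] = frame.groupby("sample_id").cumcount() + 1
    frame = frame.set_index(["sample_id", "gene_id"])
    return frame.loc[scores.index]  # preserve original row order


def filter_expressed(
    scores: pd.DataFrame, expression: pd.Series, threshold: float = 0.0
) -> pd.DataFrame:
    """Drop genes not expressed in the reference tissue, then re-rank.

    Genes with expression <= ``threshold`` and genes missing from the table
    are removed (the latter logged).
    """
    genes = scores.index.get_level_values("gene_id")
    missing = sorted(set(genes) - set(expression.index))
    if missing:
        logger.warning(
            "%d gene(s) absent from the expression table removed: %s",
            len(missing), ", ".join(missing[:10]),
        )
    expr = expression.reindex(genes).to_numpy()
    keep = np.isfinite(expr) & (expr > threshold)
    return rank_scores(scores[keep])


def topk_per_sample(scores: pd.DataFrame, k: int = 10) -> dict[str, list[str]]:
    """Top-``k`` genes per sample by rank (all genes when fewer than k)."""
    if "rank" not in scores.columns:
        scores = rank_scores(scores)
    out: dict[str, list[str]] = {}
    frame = scores.reset_index()[["sample_id", "gene_id", "rank"]]
    for sample, sub in frame.groupby("sample_id"):
        sub = sub.sort_values("rank")
        out[str(sample)] = sub["gene_id"].head(k).tolist()
    return out


def helper_union(topk: Mapping[str, Sequence[str]]) -> frozenset[str]:
    """Cohort-level helper candidate list: union of per-sample top-k genes."""
    out: set[str] = set()
    for genes in topk.values():
        out.update(genes)
    return frozenset(out)


@dataclass
class ConsensusResult:
    """Occurrence counts of distinct cohort-level helper lists."""

    counts: list[tuple[frozenset[str], int]]  # sorted by count desc
    n_lists: int

    @property
    def modal_list(self) -> frozenset[str]:
        return self.counts[0][0]

    @property
    def modal_count(self) -> int:
        return self.counts[0][1]

    @property
    def modal_frequency(self) -> float:
        return self.modal_count / self.n_lists

    @property
    def frequencies(self) -> list[float]:
        return [c / self.n_lists for _, c in self.counts]

    @property
    def core(self) -> frozenset[str]:
        core = set(self.counts[0][0])
        for s, _ in self.counts[1:]:
            core &= s
        return frozenset(core)


def consensus_helpers(lists: Sequence[Iterable[str]]) -> ConsensusResult:
    """Tally distinct helper lists (set equality) across best-model runs."""
    if not lists:
        raise ValueError("need at least one helper list")
    counts: dict[frozenset[str], int] = {}
    for lst in lists:
        key = frozenset(lst)
        counts[key] = counts.get(key, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    if len(ordered) > 1 and ordered[0][1] == ordered[1][1]:
        raise ConsensusTieError(
            f"two distinct lists tie for the modal position with {ordered[0][1]} "
            f"occurrences each out of {len(lists)}; resolve manually"
        )
    return ConsensusResult(counts=ordered, n_lists=len(lists))


def _svm_feature_weights(cfg: KernelConfig, X: np.ndarray) -> np.ndarray:
    est = cfg.estimator()
    est.fit(X)
    # coefficient-weighted sum of support vectors; exact for the linear
    # kernel and applied unchanged as the approximation for the others
    w = est.dual_coef_ @ est.support_vectors_
    return np.asarray(w).ravel()


def rfe_rank_features(
    best: BestModelSet, train_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Recursive feature elimination ranking per kernel.

    At each round the model is retrained on the remaining features, the
    weight w of each feature is the product of the SVM coefficients with the
    support vectors, and the feature with the smallest w**2 is removed
    (first index on ties). The first feature removed receives the worst rank
    (n features), the last survivor rank 1.
    """
    features = list(train_matrix.columns)
    if len(features) < 2:
        raise ValueError("RFE needs at least 2 features")
    rows = []
    for kernel, cfg in best.models:
        remaining = list(features)
        n = len(features)
        rank = n
        while remaining:
            X = train_matrix[remaining].to_numpy(dtype=float)
            w = _svm_feature_weights(cfg, X)
            w2 = w**2
            i = int(np.argmin(w2))
            rows.append(
                {"kernel": kernel, "feature": remaining[i], "w": w[i], "rank": rank}
            )
            remaining.pop(i)
            rank -= 1
    return pd.DataFrame(rows, columns=["kernel", "feature", "w", "rank"])


def score_with_model_sets(
    best_sets: Sequence[BestModelSet],
    train_matrix: pd.DataFrame,
    predict_matrix: pd.DataFrame,
    expression: pd.Series | None = None,
    k: int = 10,
) -> tuple[list[frozenset[str]], dict[tuple, pd.DataFrame]]:
    """Score the cohort under every best-model set and collect helper lists.

    Identical hyperparameter sets are trained once; returns the per-set
    cohort helper lists (one per input set, duplicates preserved for the
    consensus tally) and the score table per distinct configuration.
    """
    distinct: dict[tuple, pd.DataFrame] = {}
    lists: list[frozenset[str]] = []
    for bs in best_sets:
        key = bs.key()
        if key not in distinct:
            scores = train_and_score(bs, train_matrix, predict_matrix)
            if expression is not None:
                scores = filter_expressed(scores, expression)
            distinct[key] = scores
        lists.append(helper_union(topk_per_sample(distinct[key], k=k)))
    return lists, distinct
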