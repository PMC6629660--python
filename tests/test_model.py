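"""Grid-search CV, checkpointed model selection, scoring, consensus and RFE."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from syssvm.model import (
    BestModelSet,
    ConsensusTieError,
    CVRecords,
    KernelConfig,
    consensus_helpers,
    cv_grid_search,
    default_grid,
    filter_expressed,
    helper_union,
    rank_scores,
    rfe_rank_features,
    select_best_models,
    small_grid,
    split_training,
    topk_per_sample,
    train_and_score,
)

KERNELS = ("linear", "radial", "sigmoid", "polynomial")


def matrix_from(values, samples, genes, n_features=4):
    idx = pd.MultiIndex.from_arrays([samples, genes], names=["sample_id", "gene_id"])
    return pd.DataFrame(np.asarray(values, dtype=float), index=idx,
                        columns=[f"f{i}" for i in range(n_features)])


def blob_matrix(seed=0, n_known=12, n_other=40, shift=4.0):
    """Known genes in a tight cluster, background far away."""
    rng = np.random.default_rng(seed)
    rows, samples, genes = [], [], []
    for i in range(n_known):
        rows.append(rng.normal(shift, 0.5, size=4))
        samples.append(f"S{i % 4}")
        genes.append(f"CG{i:02d}")
    for i in range(n_other):
        rows.append(rng.normal(0.0, 1.0, size=4))
        samples.append(f"S{i % 4}")
        genes.append(f"BG{i:02d}")
    return matrix_from(rows, samples, genes), [f"CG{i:02d}" for i in range(n_known)]


def test_split_training_sizes_and_determinism():
    genes = [f"G{i}" for i in range(476)]
    train, test = split_training(genes, seed=3)
    assert (len(train), len(test)) == (318, 158)  # ceil(2*476/3)
    assert set(train).isdisjoint(test) and set(train) | set(test) == set(genes)
    assert split_training(genes, seed=3) == (train, test)
    train6, test6 = split_training([f"G{i}" for i in range(6)], seed=0)
    assert (len(train6), len(test6)) == (4, 2)
    with pytest.raises(ValueError):
        split_training(["a", "b"], seed=0)


def test_grid_sizes():
    g = default_grid()
    assert [len(g[k]) for k in KERNELS] == [5, 25, 50, 150]
    s = small_grid()
    assert sum(len(v) for v in s.values()) == 12


def test_cv_single_point_grid_record_shape():
    matrix, known = blob_matrix()
    grid = {k: [v[0]] for k, v in small_grid().items()}
    records = cv_grid_search(matrix, known, grid=grid, n_iter=2, seed=0)
    for k in KERNELS:
        assert records.sensitivities[k].shape == (1, 2)
        assert np.all((records.sensitivities[k] >= 0) & (records.sensitivities[k] <= 1))


def test_cv_easy_blob_reaches_high_sensitivity():
    """Held-out members of a well-sampled planted cluster are recognized.

    With a loose nu the one-class boundary encloses nearly all of a
    distribution it was trained on, so CV sensitivity on an easy blob is high.
    """
    sens = []
    for seed in range(5):
        matrix, known = blob_matrix(seed=seed, n_known=150)
        grid = {
            "linear": [KernelConfig("linear", 0.05)],
            "radial": [KernelConfig("radial", 0.05, gamma=0.01)],
            "sigmoid": [KernelConfig("sigmoid", 0.05, gamma=0.01, coef0=0.0)],
            "polynomial": [KernelConfig("polynomial", 0.05, gamma=0.01, degree=2, coef0=0.0)],
        }
        records = cv_grid_search(matrix, known, grid=grid, n_iter=4, seed=seed)
        sens.append(records.sensitivities["radial"].mean())
    assert np.mean(sens) >= 0.9


def fake_records(sens_by_kernel, grid, n_iter):
    return CVRecords(
        sensitivities={k: np.asarray(v, dtype=float) for k, v in sens_by_kernel.items()},
        grid=grid, n_iter=n_iter,
    )


def one_config_grid():
    return {
        "linear": [KernelConfig("linear", 0.1)],
        "radial": [KernelConfig("radial", 0.1, gamma=0.1)],
        "sigmoid": [KernelConfig("sigmoid", 0.1, gamma=0.1, coef0=0.0)],
        "polynomial": [KernelConfig("polynomial", 0.1, gamma=0.1, degree=2, coef0=0.0)],
    }


def test_select_best_models_counts_and_single_config():
    grid = one_config_grid()
    n_iter = 10_000
    rng = np.random.default_rng(0)
    sens = {k: rng.uniform(size=(1, n_iter)) for k in KERNELS}
    best = select_best_models(fake_records(sens, grid, n_iter), 100, 5, seed=0)
    assert len(best) == 500
    assert len({b.key() for b in best}) == 1  # single-config grid: all identical


def test_select_best_models_median_then_variance_tiebreak():
    grid = one_config_grid()
    # two linear configs with equal medians; lower variance must win
    grid["linear"] = [KernelConfig("linear", 0.1), KernelConfig("linear", 0.2)]
    sens = {k: np.full((1, 4), 0.5) for k in KERNELS}
    sens["linear"] = np.array(
        [
            [0.75, 0.85, 0.85, 0.75],  # median 0.8, low variance
            [0.60, 1.00, 1.00, 0.60],  # median 0.8, high variance
        ]
    )
    best = select_best_models(fake_records(sens, grid, 4), checkpoint_every=4,
                              repeats=1, seed=0)
    assert len(best) == 1
    assert best[0].configs["linear"].nu == 0.1
    # flipped variances flip the winner
    sens["linear"] = sens["linear"][::-1]
    best = select_best_models(fake_records(sens, grid, 4), 4, 1, seed=0)
    assert best[0].configs["linear"].nu == 0.2


def test_select_best_models_grid_order_breaks_full_ties():
    grid = one_config_grid()
    grid["linear"] = [KernelConfig("linear", 0.1), KernelConfig("linear", 0.2)]
    sens = {k: np.full((1, 4), 0.5) for k in KERNELS}
    sens["linear"] = np.full((2, 4), 0.7)
    best = select_best_models(fake_records(sens, grid, 4), 4, 1, seed=0)
    assert best[0].configs["linear"].nu == 0.1


def test_select_best_models_requires_divisible_checkpoint():
    grid = one_config_grid()
    sens = {k: np.zeros((1, 10)) for k in KERNELS}
    with pytest.raises(ValueError):
        select_best_models(fake_records(sens, grid, 10), checkpoint_every=3, repeats=1, seed=0)


def single_set(grid=None):
    grid = grid or one_config_grid()
    return BestModelSet(models=tuple((k, grid[k][0]) for k in KERNELS), checkpoint=1, repeat=0)


def test_scores_percentiles_combined_and_ranks():
    matrix, known = blob_matrix(seed=1)
    genes = matrix.index.get_level_values("gene_id")
    train = matrix[genes.isin(known)]
    predict = matrix[~genes.isin(known)]
    scores = train_and_score(single_set(), train, predict)
    n = len(scores)
    for k in KERNELS:
        # percentile is the cohort-wide average rank of the decision value
        expected = rankdata(scores[f"decision_{k}"], method="average") / n
        assert np.allclose(scores[f"percentile_{k}"], expected)
    pct = scores[[f"percentile_{k}" for k in KERNELS]]
    assert np.allclose(scores["combined_score"], pct.mean(axis=1))
    assert scores["combined_score"].between(0, 1).all()
    for _, sub in scores.groupby(level="sample_id"):
        assert sorted(sub["rank"]) == list(range(1, len(sub) + 1))


def test_rank_ties_broken_lexicographically():
    idx = pd.MultiIndex.from_tuples(
        [("S1", "GB"), ("S1", "GA"), ("S1", "GC")], names=["sample_id", "gene_id"]
    )
    scores = pd.DataFrame({"combined_score": [0.5, 0.5, 0.9]}, index=idx)
    ranked = rank_scores(scores)
    assert ranked.loc[("S1", "GC"), "rank"] == 1
    assert ranked.loc[("S1", "GA"), "rank"] == 2
    assert ranked.loc[("S1", "GB"), "rank"] == 3


def test_filter_expressed_drops_silent_and_missing_genes():
    idx = pd.MultiIndex.from_tuples(
        [("S1", "G1"), ("S1", "G2"), ("S1", "G3")], names=["sample_id", "gene_id"]
    )
    scores = pd.DataFrame({"combined_score": [0.9, 0.8, 0.7]}, index=idx)
    expr = pd.Series({"G1": 5.0, "G2": 0.0})  # G3 missing
    kept = filter_expressed(scores, expr)
    assert list(kept.index.get_level_values("gene_id")) == ["G1"]
    assert kept["rank"].tolist() == [1]
    all_on = filter_expressed(scores, pd.Series({"G1": 1.0, "G2": 1.0, "G3": 1.0}))
    assert len(all_on) == 3


def test_topk_returns_all_when_fewer_than_k():
    idx = pd.MultiIndex.from_tuples(
        [("S1", f"G{i}") for i in range(7)], names=["sample_id", "gene_id"]
    )
    scores = rank_scores(pd.DataFrame({"combined_score": np.linspace(1, 0, 7)}, index=idx))
    topk = topk_per_sample(scores, k=10)
    assert len(topk["S1"]) == 7
    assert topk["S1"][0] == "G0"


def test_consensus_reported_counts_and_core():
    A = frozenset({"g1", "g2", "g3"})
    B = frozenset({"g1", "g2", "g4"})
    C = frozenset({"g1", "g5"})
    lists = [A] * 207 + [B] * 161 + [C] * 43 + [frozenset({"g9", str(i)}) for i in range(89)]
    result = consensus_helpers(lists)
    assert result.n_lists == 500
    assert result.modal_list == A
    assert result.modal_count == 207
    assert result.modal_frequency == pytest.approx(0.414)
    top3 = {s: c for s, c in result.counts[:3]}
    assert top3 == {A: 207, B: 161, C: 43}
    assert frozenset.intersection(A, B, C) == frozenset({"g1"})
    assert consensus_helpers([A] * 5).modal_frequency == 1.0


def test_consensus_modal_tie_is_an_error():
    with pytest.raises(ConsensusTieError):
        consensus_helpers([frozenset({"a"}), frozenset({"b"})])


def test_rfe_eliminates_smallest_weight_first():
    rng = np.random.default_rng(0)
    # training cloud stretched along (3, 1): the linear one-class weight
    # vector points that way, so feature f1 has the smaller w^2
    base = rng.normal(0, 0.05, size=(40, 2))
    X = base + np.array([3.0, 1.0])
    train = matrix_from(X, [f"S{i%4}" for i in range(40)],
                        [f"CG{i:02d}" for i in range(40)], n_features=2)
    ranking = rfe_rank_features(single_set(), train)
    linear = ranking[ranking["kernel"] == "linear"].set_index("feature")
    assert linear.loc["f1", "rank"] == 2  # eliminated first = worst rank
    assert linear.loc["f0", "rank"] == 1


def test_rfe_ranks_are_a_permutation_per_kernel():
    matrix, known = blob_matrix(seed=2)
    genes = matrix.index.get_level_values("gene_id")
    ranking = rfe_rank_features(single_set(), matrix[genes.isin(known)])
    for k in KERNELS:
        sub = ranking[ranking["kernel"] == k]
        assert sorted(sub["rank"]) == [1, 2, 3, 4]
        assert set(sub["feature"]) == {"f0", "f1", "f2", "f3"}
    with pytest.raises(ValueError):
        rfe_rank_features(single_set(), matrix[genes.isin(known)][["f0"]])


def test_cv_and_selection_deterministic_under_seed():
    matrix, known = blob_matrix(seed=3)
    grid = small_grid()
    a = cv_grid_search(matrix, known, grid=grid, n_iter=6, seed=42)
    b = cv_grid_search(matrix, known, grid=grid, n_iter=6, seed=42)
    for k in KERNELS:
        assert np.array_equal(a.sensitivities[k], b.sensitivities[k])
    sa = select_best_models(a, 2, 3, seed=7)
    sb = select_best_models(b, 2, 3, seed=7)
    assert [s.key() for s in sa] == [s.key() for s in sb]


def test_helper_union_is_cohort_level():
    assert helper_union({"S1": ["a", "b"], "S2": ["b", "c"]}) == frozenset({"a", "b", "c"})
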