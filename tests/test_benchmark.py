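import itertools

import numpy as np
import pytest

from causalde import (
    GeneEffectTable,
    SimConfig,
    compute_ari,
    compute_asw,
    compute_fpr_tpr,
    run_benchmark,
)
from causalde.simulate import SimTruth


def _truth(de_mask, groups=None, n=None):
    p = len(de_mask)
    n = n or 10
    return SimTruth(
        de_mask=np.asarray(de_mask, bool),
        true_lfc=np.zeros(p),
        true_tau=np.zeros(p),
        U_true=np.zeros((n, 1)),
        group_labels=np.zeros(n, int) if groups is None else np.asarray(groups),
        pi_true=np.full(n, 0.5),
    )


def _table(p_values):
    m = len(p_values)
    return GeneEffectTable.from_arrays(
        [f"g{i}" for i in range(m)],
        np.zeros(m), np.ones(m), np.zeros(m),
        np.asarray(p_values, float), np.asarray(p_values, float),
        np.zeros(m, bool), np.zeros(m, bool),
    )


def ari_pair_counting(a, b):
    """Brute-force adjusted Rand index via the pair-counting formula."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, 1)
    n11 = np.sum(same_a[iu] & same_b[iu])
    n00 = np.sum(~same_a[iu] & ~same_b[iu])
    n10 = np.sum(same_a[iu] & ~same_b[iu])
    n01 = np.sum(~same_a[iu] & same_b[iu])
    total = n * (n - 1) / 2
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def silhouette_direct(X, labels):
    """Direct silhouette computation from its definition."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    svals = []
    for i in range(len(X)):
        own = labels == labels[i]
        a = dist[i, own & (np.arange(len(X)) != i)].mean()
        b = min(
            dist[i, labels == lab].mean() for lab in np.unique(labels) if lab != labels[i]
        )
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


class TestFprTpr:
    def test_all_rejected(self):
        truth = _truth([True] * 6 + [False] * 4)
        fpr, tpr = compute_fpr_tpr(_table(np.zeros(10)), truth)
        assert (fpr, tpr) == (1.0, 1.0)

    def test_perfect_rejections(self):
        de = np.array([True] * 6 + [False] * 4)
        p = np.where(de, 0.001, 0.9)
        fpr, tpr = compute_fpr_tpr(_table(p), _truth(de))
        assert (fpr, tpr) == (0.0, 1.0)

    def test_hand_counted_toy(self):
        # 6 DE, 4 null; reject 4 DE and 1 null at level 0.1
        de = np.array([True] * 6 + [False] * 4)
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.5, 0.6, 0.05, 0.9, 0.8, 0.7])
        fpr, tpr = compute_fpr_tpr(_table(p), _truth(de))
        assert fpr == pytest.approx(1 / 4)
        assert tpr == pytest.approx(4 / 6)

    def test_nan_rates_for_empty_sets(self):
        fpr, tpr = compute_fpr_tpr(_table([0.5, 0.5]), _truth([True, True]))
        assert np.isnan(fpr) and tpr == 0.0


class TestARI:
    def test_true_scores_recover_labels(self, rng):
        groups = rng.integers(0, 3, 90)
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        U = centers[groups] + 0.3 * rng.standard_normal((90, 2))
        truth = _truth([False], groups=groups, n=90)
        assert compute_ari(U, truth) == 1.0

    def test_shuffled_labels_near_zero(self, rng):
        n = 1000
        groups = rng.integers(0, 4, n)
        U = rng.standard_normal((n, 3))
        truth = _truth([False], groups=groups, n=n)
        assert abs(compute_ari(U, truth)) < 0.05

    def test_matches_pair_counting_oracle(self, rng):
        from sklearn.metrics import adjusted_rand_score

        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 4, 30)
        assert adjusted_rand_score(a, b) == pytest.approx(
            ari_pair_counting(a, b), abs=1e-10
        )

    def test_relabeling_invariance(self, rng):
        groups = rng.integers(0, 3, 60)
        U = np.eye(3)[groups] * 5 + 0.1 * rng.standard_normal((60, 3))
        t1 = _truth([False], groups=groups, n=60)
        t2 = _truth([False], groups=(groups + 1) % 3, n=60)
        assert compute_ari(U, t1) == pytest.approx(compute_ari(U, t2))


class TestASW:
    def test_perfect_separation_limit(self, rng):
        groups = np.repeat([0, 1], 15)
        X = np.where(groups[:, None] == 0, 0.0, 1000.0) + 1e-6 * rng.standard_normal(
            (30, 5)
        )
        truth = _truth([False], groups=groups, n=30)
        assert compute_asw(np.abs(X), truth) > 0.95

    def test_random_labels_near_half(self, rng):
        n = 300
        groups = rng.integers(0, 3, n)
        X = np.abs(rng.standard_normal((n, 10)))
        truth = _truth([False], groups=groups, n=n)
        assert abs(compute_asw(X, truth) - 0.5) < 0.05

    def test_translation_invariance(self, rng):
        groups = np.repeat([0, 1, 2], 10)
        X = np.abs(rng.standard_normal((30, 6))) + groups[:, None]
        t = _truth([False], groups=groups, n=30)
        a = compute_asw(X, t, log_transform=False)
        b = compute_asw(X + 7.0, t, log_transform=False)
        assert a == pytest.approx(b, abs=1e-10)

    def test_matches_direct_silhouette(self, rng):
        from sklearn.metrics import silhouette_score

        X = rng.standard_normal((30, 4))
        labels = rng.integers(0, 3, 30)
        assert silhouette_score(X, labels) == pytest.approx(
            silhouette_direct(X, labels), abs=1e-10
        )


class TestHarness:
    def test_deterministic_and_tidy(self):
        cfgs = [SimConfig(n=120, p=60, seed=77, n_groups=2)]
        t1 = run_benchmark(cfgs, n_reps=1, rank=2)
        t2 = run_benchmark(cfgs, n_reps=1, rank=2)
        assert len(t1) == 4  # |grid| x n_reps x 4 metrics
        assert sorted(t1.metric) == ["ari", "asw", "fpr", "tpr"]
        assert (t1.value == t2.value).all()

    def test_does_not_mutate_configs(self):
        cfg = SimConfig(n=120, p=60, seed=78, n_groups=2)
        before = repr(cfg)
        run_benchmark([cfg], n_reps=1, rank=0)
        assert repr(cfg) == before

    def test_row_count_grid(self):
        cfgs = [
            SimConfig(n=100, p=50, seed=79, n_groups=2),
            SimConfig(n=100, p=50, seed=80, n_groups=2),
        ]
        out = run_benchmark(cfgs, n_reps=2, rank=0)
        assert len(out) == 2 * 2 * 4
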