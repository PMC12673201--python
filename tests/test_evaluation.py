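"""ROC/AUC, Youden operating point, DeLong test, observer-study machinery."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from stenosisnet import (
    ScoredSet,
    delong_test,
    delong_variance,
    group_average_roc,
    mann_whitney_auc,
    roc_curve,
    select_observer_cases,
    youden_operating_point,
)


def pairwise_auc_oracle(scores, labels):
    """Brute-force enumeration over all positive x negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_scan_oracle(scores, labels):
    """Exhaustive threshold scan for the Youden point (rule: score > t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    best = (-np.inf, None)
    for t in np.unique(scores):
        sens = np.mean(scores[labels == 1] > t)
        spec = np.mean(scores[labels == 0] <= t)
        j = sens + spec - 1
        if j > best[0] + 1e-15:
            best = (j, t)
    return best[1]


def random_scored(rng, n=30, discrete=False):
    labels = rng.integers(0, 2, size=n)
    while labels.min() == labels.max():
        labels = rng.integers(0, 2, size=n)
    if discrete:
        scores = rng.integers(0, 6, size=n) / 5.0
    else:
        scores = rng.random(n)
    return scores, labels


class TestAuc:
    def test_perfect_separation(self):
        assert mann_whitney_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert mann_whitney_auc([0.5] * 6, [1, 1, 0, 0, 0, 1]) == 0.5

    @pytest.mark.parametrize("discrete", [False, True])
    def test_matches_pairwise_oracle(self, rng, discrete):
        for _ in range(20):
            scores, labels = random_scored(rng, 30, discrete)
            assert mann_whitney_auc(scores, labels) == pytest.approx(
                pairwise_auc_oracle(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self, rng):
        for _ in range(10):
            scores, labels = random_scored(rng, 50, discrete=True)
            assert mann_whitney_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores, labels = random_scored(rng, 40)
        a = mann_whitney_auc(scores, labels)
        b = mann_whitney_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_label_swap_maps_auc_to_complement(self, rng):
        scores, labels = random_scored(rng, 40)
        a = mann_whitney_auc(scores, labels)
        b = mann_whitney_auc(scores, 1 - labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([0.1, 0.2], [1, 1])


class TestRocCurve:
    def test_sensitivity_specificity_monotone_in_threshold(self, rng):
        scores, labels = random_scored(rng, 60, discrete=True)
        roc = roc_curve(scores, labels)
        assert np.all(np.diff(roc.sensitivity) <= 1e-15)
        assert np.all(np.diff(roc.specificity) >= -1e-15)

    def test_auc_equals_trapezoid_over_roc_points(self, rng):
        scores, labels = random_scored(rng, 50, discrete=True)
        roc = roc_curve(scores, labels)
        fpr = np.concatenate([[1.0], 1 - roc.specificity, [0.0]])
        tpr = np.concatenate([[1.0], roc.sensitivity, [0.0]])
        trap = -np.trapezoid(tpr, fpr)
        assert roc.auc == pytest.approx(trap, abs=1e-12)


class TestYouden:
    def test_perfect_separation_lowest_threshold(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        t, sens, spec, acc = youden_operating_point(roc)
        assert sens == 1.0 and spec == 1.0 and acc == 1.0
        assert t == 0.2  # lowest threshold achieving J = 1 under ">" rule

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            scores, labels = random_scored(rng, 40, discrete=True)
            roc = roc_curve(scores, labels)
            assert roc.youden_threshold == youden_scan_oracle(scores, labels)

    def test_argmax_contract(self, rng):
        scores, labels = random_scored(rng, 40)
        roc = roc_curve(scores, labels)
        j = roc.sensitivity + roc.specificity - 1
        j_at = roc.youden_sensitivity + roc.youden_specificity - 1
        assert j_at >= j.max() - 1e-12


class TestDelong:
    def test_identical_scores_give_z0_p1(self, rng):
        scores, labels = random_scored(rng, 40)
        ids = np.arange(40).astype(str)
        a = ScoredSet(ids, labels, scores)
        with pytest.warns(UserWarning, match="zero variance"):
            auc_a, auc_b, z, p = delong_test(a, ScoredSet(ids, labels, scores.copy()))
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_swapping_sets_negates_z_preserves_p(self, rng):
        scores, labels = random_scored(rng, 60)
        ids = np.arange(60).astype(str)
        a = ScoredSet(ids, labels, scores)
        b = ScoredSet(ids, labels, np.clip(scores + rng.normal(0, 0.3, 60), 0, 1))
        auc_a, auc_b, z_ab, p_ab = delong_test(a, b)
        auc_b2, auc_a2, z_ba, p_ba = delong_test(b, a)
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)
        assert (auc_a, auc_b) == (auc_a2, auc_b2)

    def test_mismatched_cases_rejected(self, rng):
        scores, labels = random_scored(rng, 20)
        a = ScoredSet(np.arange(20).astype(str), labels, scores)
        b = ScoredSet(np.arange(1, 21).astype(str), labels, scores)
        with pytest.raises(ValueError, match="support"):
            delong_test(a, b)

    def test_variance_matches_stratified_bootstrap(self):
        """DeLong single-AUC variance vs a 2000-replicate stratified bootstrap
        on a 40+40 synthetic set (within 15% relative)."""
        rng = np.random.default_rng(7)
        pos = rng.normal(1.0, 1.0, 40)
        neg = rng.normal(0.0, 1.0, 40)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 40 + [0] * 40)
        v_delong = delong_variance(scores, labels)
        boots = []
        for _ in range(2000):
            bp = rng.choice(pos, 40, replace=True)
            bn = rng.choice(neg, 40, replace=True)
            boots.append(
                mann_whitney_auc(np.concatenate([bp, bn]), labels)
            )
        v_boot = np.var(boots, ddof=1)
        assert abs(v_delong - v_boot) / v_boot < 0.15

    def test_variance_order_of_magnitude_sanity(self, rng):
        # balanced random scores: var(AUC) ~ 1/(4 * min(n_pos, n_neg)) scale
        scores = rng.random(100)
        labels = np.array([0, 1] * 50)
        v = delong_variance(scores, labels)
        closed = 1.0 / (4 * 50)
        assert closed / 10 < v < closed * 10


@pytest.fixture(scope="module")
def pooled():
    rng = np.random.default_rng(11)
    n_pos, n_neg = 84, 867
    scores = np.concatenate([
        rng.beta(5, 2, n_pos),  # positives score high
        rng.beta(2, 5, n_neg),
    ])
    labels = np.array([1] * n_pos + [0] * n_neg)
    ids = np.array([f"seg{i:04d}" for i in range(n_pos + n_neg)])
    return ScoredSet(ids, labels, scores)


class TestObserverSelection:
    def test_returns_requested_class_counts(self, pooled):
        sel = select_observer_cases(pooled, 40, 40, tolerance=0.02, seed=0)
        chosen = np.isin(pooled.case_ids, sel.case_ids)
        assert chosen.sum() == 80
        assert pooled.labels[chosen].sum() == 40

    def test_subset_auc_within_tolerance(self, pooled):
        sel = select_observer_cases(pooled, 40, 40, tolerance=0.02, seed=1)
        assert sel.within_tolerance
        assert abs(sel.subset_auc - sel.full_auc) <= 0.02

    def test_vacuous_tolerance_accepts_first_draw(self, pooled):
        sel = select_observer_cases(pooled, 40, 40, tolerance=1.0, seed=2)
        assert sel.n_draws == 1

    def test_insufficient_class_members_rejected(self, pooled):
        with pytest.raises(ValueError):
            select_observer_cases(pooled, 100, 40, seed=0)

    def test_selection_is_seeded(self, pooled):
        a = select_observer_cases(pooled, 40, 40, seed=3)
        b = select_observer_cases(pooled, 40, 40, seed=3)
        assert np.array_equal(np.sort(a.case_ids), np.sort(b.case_ids))


class TestGroupAverageRoc:
    def _reader(self, rng, labels, noise):
        scores = np.clip(labels + rng.normal(0, noise, labels.size), 0, 1)
        return ScoredSet(np.arange(labels.size).astype(str), labels, scores)

    def test_single_reader_mean_equals_own_auc(self, rng):
        labels = np.array([0, 1] * 20)
        r = self._reader(rng, labels, 0.4)
        _, _, aucs, mean_auc = group_average_roc([r])
        assert mean_auc == aucs[0] == roc_curve(r.scores, r.labels).auc

    def test_mean_auc_is_arithmetic_mean(self, rng):
        labels = np.array([0, 1] * 25)
        readers = [self._reader(rng, labels, n) for n in (0.3, 0.6)]
        _, _, aucs, mean_auc = group_average_roc(readers)
        assert mean_auc == pytest.approx(aucs.mean())

    def test_averaged_curve_between_member_curves(self, rng):
        labels = np.array([0, 1] * 25)
        readers = [self._reader(rng, labels, n) for n in (0.3, 0.5, 0.8)]
        grid, mean_tpr, _, _ = group_average_roc(readers)
        member = [group_average_roc([r])[1] for r in readers]
        lo = np.min(member, axis=0)
        hi = np.max(member, axis=0)
        assert np.all(mean_tpr >= lo - 1e-12) and np.all(mean_tpr <= hi + 1e-12)

    def test_case_support_mismatch_rejected(self, rng):
        labels = np.array([0, 1] * 10)
        a = self._reader(rng, labels, 0.3)
        b = ScoredSet(np.arange(1, 21).astype(str), labels, a.scores)
        with pytest.raises(ValueError, match="same cases"):
            group_average_roc([a, b])
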