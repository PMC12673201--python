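"""ROC analysis, Youden operating point, DeLong test and observer-study tools.

Conventions, fixed so results on discrete score sets are reproducible:

* decision rule: a case is called positive when score > threshold (ties at
  the threshold are negative);
* AUC is the Mann-Whitney pairwise estimate with ties counted 1/2, which
  equals the trapezoidal area under the empirical ROC;
* the Youden operating point maximizes J = sensitivity + specificity - 1,
  breaking ties toward the lowest threshold (favoring sensitivity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)


@dataclass
class ScoredSet:
    """Per-case scores (probabilities or reader ratings) with binary labels."""

    case_ids: np.ndarray
    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.case_ids = np.asarray(self.case_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.case_ids) == len(self.labels) == len(self.scores)):
            raise ValueError("case_ids, labels and scores must have equal length")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary")

    @classmethod
    def from_dataframe(cls, df, id_col="segment_id", label_col="label", score_col="score"):
        return cls(df[id_col].to_numpy(), df[label_col].to_numpy(), df[score_col].to_numpy())

    def sorted_by_id(self) -> "ScoredSet":
        order = np.argsort(self.case_ids)
        return ScoredSet(self.case_ids[order], self.labels[order], self.scores[order])


@dataclass
class RocResult:
    """Empirical ROC with its AUC and Youden operating point."""

    thresholds: np.ndarray  # sorted unique scores, ascending
    sensitivity: np.ndarray  # P(score > t | positive), per threshold
    specificity: np.ndarray  # P(score <= t | negative), per threshold
    auc: float
    n_pos: int
    n_neg: int
    youden_threshold: float = field(default=np.nan)
    youden_sensitivity: float = field(default=np.nan)
    youden_specificity: float = field(default=np.nan)
    youden_accuracy: float = field(default=np.nan)


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC analysis needs at least one case of each class")
    return pos, neg


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the probability a positive outscores a negative (ties = 1/2)."""
    pos, neg = _split_scores(scores, labels)
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2)
                 / (pos.size * neg.size))


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC over all unique score thresholds, with Youden point."""
    pos, neg = _split_scores(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    roc = RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=mann_whitney_auc(scores, labels),
        n_pos=pos.size,
        n_neg=neg.size,
    )
    t, se, sp, acc = youden_operating_point(roc)
    roc.youden_threshold = t
    roc.youden_sensitivity = se
    roc.youden_specificity = sp
    roc.youden_accuracy = acc
    return roc


def youden_operating_point(roc: RocResult) -> tuple[float, float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1 (lowest on ties)."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-15)[0])
    se = float(roc.sensitivity[best])
    sp = float(roc.specificity[best])
    acc = (se * roc.n_pos + sp * roc.n_neg) / (roc.n_pos + roc.n_neg)
    return float(roc.thresholds[best]), se, sp, float(acc)


def _placements(scores, labels):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos, neg = _split_scores(scores, labels)
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single empirical AUC."""
    v10, v01 = _placements(scores, labels)
    var10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    var01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return float(var10 / v10.size + var01 / v01.size)


def delong_test(scores_a: ScoredSet, scores_b: ScoredSet):
    """Paired DeLong comparison of two correlated AUCs on the same cases.

    Returns (auc_a, auc_b, z, p) with a two-sided normal p-value. If the
    variance of the AUC difference is zero (e.g. identical score sets), z = 0
    and p = 1 with a warning.
    """
    a = scores_a.sorted_by_id()
    b = scores_b.sorted_by_id()
    if not (np.array_equal(a.case_ids, b.case_ids) and np.array_equal(a.labels, b.labels)):
        raise ValueError("both score sets must cover the same (case, label) support")

    v10a, v01a = _placements(a.scores, a.labels)
    v10b, v01b = _placements(b.scores, b.labels)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var_diff <= 0 or not np.isfinite(var_diff):
        warnings.warn("zero variance of the AUC difference; returning z = 0, p = 1")
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


@dataclass
class ObserverSelection:
    """Result of the stratified observer-study case draw."""

    case_ids: np.ndarray
    subset_auc: float
    full_auc: float
    n_draws: int
    within_tolerance: bool


def _stratified_draw(rng, scores, ids, n_wanted):
    """Draw n_wanted ids stratified over score deciles (largest remainder)."""
    edges = np.quantile(scores, np.linspace(0, 1, 11))
    strata = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, 9)
    groups = [np.flatnonzero(strata == s) for s in range(10)]
    sizes = np.array([g.size for g in groups], dtype=float)
    exact = n_wanted * sizes / sizes.sum()
    alloc = np.floor(exact).astype(int)
    rema = exact - alloc
    for s in np.argsort(-rema):
        if alloc.sum() >= n_wanted:
            break
        if alloc[s] < sizes[s]:
            alloc[s] += 1
    # spill any residue (strata exhausted) into strata with room
    while alloc.sum() < n_wanted:
        room = np.flatnonzero(alloc < sizes)
        alloc[room[np.argmax(sizes[room] - alloc[room])]] += 1
    chosen = []
    for g, k in zip(groups, alloc):
        if k > 0:
            chosen.append(rng.choice(g, size=min(k, g.size), replace=False))
    return ids[np.concatenate(chosen)]


def select_observer_cases(
    pooled: ScoredSet,
    n_pos: int,
    n_neg: int,
    tolerance: float = 0.02,
    seed: int = 0,
    max_draws: int = 10_000,
) -> ObserverSelection:
    """Select an observer-study subset whose AUC matches the full set.

    Draws n_pos positives and n_neg negatives by stratified random sampling
    over score deciles within each class, repeating (seeded) until the AUC of
    the subset is within ``tolerance`` of the full-set AUC; if ``max_draws``
    is reached the best-matching draw is returned.
    """
    labels, scores, ids = pooled.labels, pooled.scores, pooled.case_ids
    if (labels == 1).sum() < n_pos or (labels == 0).sum() < n_neg:
        raise ValueError("not enough cases in one of the classes")
    full_auc = mann_whitney_auc(scores, labels)
    rng = np.random.default_rng(seed)

    pos_mask = labels == 1
    best: tuple[float, np.ndarray] | None = None
    for draw in range(1, max_draws + 1):
        sel_pos = _stratified_draw(rng, scores[pos_mask], ids[pos_mask], n_pos)
        sel_neg = _stratified_draw(rng, scores[~pos_mask], ids[~pos_mask], n_neg)
        sel = np.concatenate([sel_pos, sel_neg])
        mask = np.isin(ids, sel)
        sub_auc = mann_whitney_auc(scores[mask], labels[mask])
        gap = abs(sub_auc - full_auc)
        if best is None or gap < abs(best[0] - full_auc):
            best = (sub_auc, sel)
        if gap <= tolerance:
            return ObserverSelection(sel, sub_auc, full_auc, draw, True)
    logger.warning("observer-case search hit the %d-draw cap", max_draws)
    return ObserverSelection(best[1], best[0], full_auc, max_draws, False)


def group_average_roc(readers: list[ScoredSet], n_grid: int = 201):
    """Reader-group ROC: mean AUC and vertically averaged curve.

    All readers must rate the same cases. The averaged curve is the mean
    sensitivity at each false-positive rate on a common grid (linear
    interpolation of each reader's empirical ROC).
    """
    if not readers:
        raise ValueError("at least one reader required")
    ref = readers[0].sorted_by_id()
    for r in readers[1:]:
        rs = r.sorted_by_id()
        if not (np.array_equal(ref.case_ids, rs.case_ids)
                and np.array_equal(ref.labels, rs.labels)):
            raise ValueError("all readers must rate the same cases")

    fpr_grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    aucs = []
    for r in readers:
        roc = roc_curve(r.scores, r.labels)
        aucs.append(roc.auc)
        fpr = 1.0 - roc.specificity
        tpr = roc.sensitivity
        order = np.argsort(fpr, kind="stable")
        fpr_pts = np.concatenate([[0.0], fpr[order][::1], [1.0]])
        tpr_pts = np.concatenate([[0.0], tpr[order][::1], [1.0]])
        # enforce monotone non-decreasing TPR along increasing FPR
        srt = np.argsort(fpr_pts, kind="stable")
        tprs.append(np.interp(fpr_grid, fpr_pts[srt], np.maximum.accumulate(tpr_pts[srt])))
    mean_tpr = np.mean(tprs, axis=0)
    return fpr_grid, mean_tpr, np.asarray(aucs), float(np.mean(aucs))
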