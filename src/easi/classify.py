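"""Binary classification of labeled score sets and of EASI residuals.

Two layers live here.  The threshold layer turns a set of labeled similarity
or dissimilarity scores into confusion matrices, ROC and precision-recall
curves, and the conservative "zero false positive" operating point used in
forensic reporting.  The supervised layer fits a stepwise binary logistic
regression on EASI residual vectors, the classifier that resolves the target
compound from diastereomers sharing every fragment channel.

Conventions, fixed for determinism:

* similarity polarity predicts positive when ``score >= threshold``;
  dissimilarity polarity when ``score <= threshold`` (inclusive on the
  positive side in both cases);
* ROC AUC is integrated by the trapezoid rule over all distinct thresholds,
  which makes it exactly the Mann-Whitney probability that a random
  positive/negative pair is ordered correctly, with ties counted 1/2;
* the logistic model is oriented so that *high* probability means "not the
  target compound": the target is called when p < threshold (default 0.5),
  and the p == threshold boundary is classified negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .glm import PredictionRecord

__all__ = [
    "ScoreSet",
    "ConfusionCounts",
    "ROCCurve",
    "PRCurve",
    "ResidualLogit",
    "confusion_at_threshold",
    "roc_curve",
    "pr_curve",
    "zero_fp_threshold",
    "fit_residual_logit_stepwise",
    "classify_logit",
]

POLARITIES = ("similarity", "dissimilarity")


@dataclass(frozen=True)
class ScoreSet:
    """Labeled scores plus the polarity that maps score to 'positive'."""

    ids: tuple[str, ...]
    truth: tuple[str, ...]
    scores: np.ndarray
    polarity: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if not (len(self.ids) == len(self.truth) == len(self.scores)):
            raise ValueError("ids, truth and scores must have equal length")
        bad = set(self.truth) - {"known_positive", "known_negative"}
        if bad:
            raise ValueError(f"scored spectra must be KP or KN, got {sorted(bad)}")

    @property
    def is_positive(self) -> np.ndarray:
        return np.array([t == "known_positive" for t in self.truth])

    def _oriented(self) -> np.ndarray:
        """Scores flipped so that higher always means more positive."""
        return self.scores if self.polarity == "similarity" else -self.scores

    def require_both_classes(self) -> None:
        pos = self.is_positive
        if not pos.any() or pos.all():
            raise ValueError("need at least one known positive and one known negative")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts with the usual derived rates."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def fpr(self) -> float:
        return 1.0 - self.tnr

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


@dataclass(frozen=True)
class ROCCurve:
    """(threshold, tpr, fpr) sweep and its trapezoid area."""

    points: tuple[tuple[float, float, float], ...]
    auc: float


@dataclass(frozen=True)
class PRCurve:
    """(threshold, recall, precision) sweep; zero-prediction points omitted."""

    points: tuple[tuple[float, float, float], ...]


def confusion_at_threshold(scores: ScoreSet, threshold: float) -> ConfusionCounts:
    """Confusion counts at one decision threshold (inclusive positive side)."""
    if scores.polarity == "similarity":
        called = scores.scores >= threshold
    else:
        called = scores.scores <= threshold
    pos = scores.is_positive
    return ConfusionCounts(
        tp=int(np.sum(called & pos)),
        tn=int(np.sum(~called & ~pos)),
        fp=int(np.sum(called & ~pos)),
        fn=int(np.sum(~called & pos)),
    )


def _sweep(scores: ScoreSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct thresholds (original units, most strict first) with cumulative
    TP and FP counts at each."""
    oriented = scores._oriented()
    pos = scores.is_positive
    order = np.argsort(-oriented, kind="stable")
    o_sorted = oriented[order]
    p_sorted = pos[order]
    distinct_idx = np.nonzero(np.diff(o_sorted, append=np.nan))[0]
    cum_tp = np.cumsum(p_sorted)[distinct_idx]
    cum_fp = np.cumsum(~p_sorted)[distinct_idx]
    thresholds = o_sorted[distinct_idx]
    if scores.polarity == "dissimilarity":
        thresholds = -thresholds
    return thresholds, cum_tp, cum_fp


def roc_curve(scores: ScoreSet) -> ROCCurve:
    """ROC sweep over all distinct scores plus a predict-nothing sentinel.

    The trapezoid-rule area equals the Mann-Whitney pairwise probability
    (ties counted 1/2) that a random known positive outscores a random known
    negative in the positive direction.
    """
    scores.require_both_classes()
    thresholds, cum_tp, cum_fp = _sweep(scores)
    n_pos = int(scores.is_positive.sum())
    n_neg = len(scores.scores) - n_pos
    sentinel = np.inf if scores.polarity == "similarity" else -np.inf
    tpr = np.concatenate([[0.0], cum_tp / n_pos])
    fpr = np.concatenate([[0.0], cum_fp / n_neg])
    points = tuple(
        (float(t), float(r), float(f))
        for t, r, f in zip(np.concatenate([[sentinel], thresholds]), tpr, fpr)
    )
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=points, auc=auc)


def pr_curve(scores: ScoreSet) -> PRCurve:
    """Precision-recall sweep over all distinct thresholds.

    Precision is undefined when nothing is predicted positive, so the
    predict-nothing sentinel point is omitted.
    """
    scores.require_both_classes()
    thresholds, cum_tp, cum_fp = _sweep(scores)
    n_pos = int(scores.is_positive.sum())
    points = []
    for t, tp, fp in zip(thresholds, cum_tp, cum_fp):
        if tp + fp == 0:
            continue
        points.append((float(t), float(tp / n_pos), float(tp / (tp + fp))))
    return PRCurve(points=tuple(points))


def zero_fp_threshold(scores: ScoreSet) -> tuple[float, ConfusionCounts]:
    """The most permissive threshold that admits no false positives.

    Placed at the midpoint between the extreme known-negative score and the
    nearest known-positive score on the admissible side (similarity: just
    above the largest KN; dissimilarity: just below the smallest KN).  When
    no positive lies on the admissible side the threshold sits immediately
    beyond the extreme negative and the true-positive count is 0.
    """
    scores.require_both_classes()
    pos = scores.is_positive
    if scores.polarity == "similarity":
        kn_extreme = float(scores.scores[~pos].max())
        admissible = scores.scores[pos][scores.scores[pos] > kn_extreme]
        threshold = (
            (kn_extreme + float(admissible.min())) / 2.0
            if admissible.size
            else float(np.nextafter(kn_extreme, np.inf))
        )
    else:
        kn_extreme = float(scores.scores[~pos].min())
        admissible = scores.scores[pos][scores.scores[pos] < kn_extreme]
        threshold = (
            (kn_extreme + float(admissible.max())) / 2.0
            if admissible.size
            else float(np.nextafter(kn_extreme, -np.inf))
        )
    return threshold, confusion_at_threshold(scores, threshold)


# ---------------------------------------------------------------------------
# Stepwise logistic regression on EASI residuals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidualLogit:
    """Stepwise logistic model on residual channels.

    Oriented so the fitted probability is that of the *negative* class: a
    query is called the target compound when p < ``threshold``.  ``method``
    records whether plain maximum likelihood sufficed or the ridge-penalised
    fallback was used (complete separation makes unpenalised ML diverge).
    """

    selected: tuple[int, ...]
    intercept: float
    coefficients: Mapping[int, float]
    threshold: float = 0.5
    method: str = "mle"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", {int(k): float(v) for k, v in self.coefficients.items()}
        )
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if set(self.coefficients) != set(self.selected):
            raise ValueError("coefficients must cover exactly the selected channels")


def _logit_fit(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.0, max_iter: int = 100
) -> tuple[np.ndarray, float, bool]:
    """Newton/IRLS logistic fit, optionally ridge-penalised (intercept free).

    Returns ``(beta, unpenalised log-likelihood, converged)``.  Under
    complete separation with ``alpha = 0`` the likelihood climbs toward 0
    while the coefficients diverge; the iteration cap keeps everything
    finite and the caller detects the condition.
    """
    n, p = X.shape
    Xc = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.concatenate([[0.0], np.full(p, alpha)])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Xc @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = Xc.T @ (y - mu) - pen * beta
        if np.max(np.abs(grad)) < 1e-9:
            converged = True
            break
        H = (Xc * w[:, None]).T @ Xc + np.diag(pen + 1e-10)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps for stability
        norm = np.max(np.abs(step))
        if norm > 20.0:
            step *= 20.0 / norm
        beta = beta + step
    eta = np.clip(Xc @ beta, -35, 35)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-15, 1 - 1e-15)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return beta, ll, converged


def fit_residual_logit_stepwise(
    records: Sequence[PredictionRecord],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    threshold: float = 0.5,
    ridge_alpha: float = 1.0,
) -> ResidualLogit:
    """Bidirectional stepwise logistic regression on EASI residual channels.

    Channels enter on the smallest likelihood-ratio p-value below
    ``p_enter`` and leave when their LR p-value exceeds ``p_remove``
    (likelihood-ratio rather than Wald tests: they remain directional under
    separation).  If the final maximum-likelihood fit shows complete
    separation — perfect training classification with diverging
    coefficients — it is refit with a ridge penalty of ``ridge_alpha`` and
    tagged ``"ridge"``.

    Requires residual records of both truth classes; the response is coded
    1 for known negatives, so low fitted probability means "target compound".
    """
    truths = {r.truth for r in records}
    if truths - {"known_positive", "known_negative"}:
        raise ValueError("records must carry known_positive/known_negative truths")
    if len(truths) < 2:
        raise ValueError("need residual records of both truth classes")
    channels = records[0].channels
    if any(r.channels != channels for r in records):
        raise ValueError("all records must share one panel")
    R = np.array([r.residuals for r in records], dtype=float)
    y = np.array([1.0 if r.truth == "known_negative" else 0.0 for r in records])
    n = len(y)

    usable = [i for i in range(len(channels)) if R[:, i].std() > 0]
    cols = {channels[i]: R[:, i] for i in usable}

    def design(sel: list[int]) -> np.ndarray:
        return np.column_stack([cols[c] for c in sel]) if sel else np.empty((n, 0))

    selected: list[int] = []
    _, ll_cur, _ = _logit_fit(design(selected), y)
    seen: set[frozenset[int]] = {frozenset()}

    while True:
        changed = False
        best_p, best_c, best_ll = None, None, None
        for c in cols:
            if c in selected:
                continue
            _, ll_new, _ = _logit_fit(design(selected + [c]), y)
            lr = max(2.0 * (ll_new - ll_cur), 0.0)
            pval = float(stats.chi2.sf(lr, 1))
            if best_p is None or pval < best_p:
                best_p, best_c, best_ll = pval, c, ll_new
        if best_p is not None and best_p < p_enter:
            trial = frozenset(selected + [best_c])
            if trial not in seen:
                selected.append(best_c)
                ll_cur = best_ll
                seen.add(trial)
                changed = True
        while selected:
            worst_p, worst_c, worst_ll = None, None, None
            for c in selected:
                others = [s for s in selected if s != c]
                _, ll_wo, _ = _logit_fit(design(others), y)
                lr = max(2.0 * (ll_cur - ll_wo), 0.0)
                pval = float(stats.chi2.sf(lr, 1))
                if worst_p is None or pval > worst_p:
                    worst_p, worst_c, worst_ll = pval, c, ll_wo
            if worst_p is not None and worst_p > p_remove:
                trial = frozenset(s for s in selected if s != worst_c)
                if trial in seen:
                    break
                selected.remove(worst_c)
                ll_cur = worst_ll
                seen.add(trial)
                changed = True
            else:
                break
        if not changed:
            break

    X = design(selected)
    beta, ll, converged = _logit_fit(X, y)
    method = "mle"
    if selected:
        eta = beta[0] + X @ beta[1:]
        # complete separation: the unpenalised MLE does not exist (the
        # likelihood climbs toward 0 as coefficients diverge), so any
        # "converged" fit there is an artifact of numerical clipping
        perfect = np.all((eta > 0) == (y == 1.0))
        if perfect or not converged or np.max(np.abs(beta)) > 30.0:
            beta, _, _ = _logit_fit(X, y, alpha=ridge_alpha)
            method = "ridge"
    return ResidualLogit(
        selected=tuple(selected),
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(selected, beta[1:])},
        threshold=threshold,
        method=method,
    )


def classify_logit(
    model: ResidualLogit, record: PredictionRecord
) -> tuple[float, str]:
    """Apply a fitted residual logit to one prediction record.

    Returns ``(probability, predicted_class)``; the probability is that of
    the negative class, so p < threshold calls the target compound and the
    exact boundary p == threshold is classified ``known_negative``.
    """
    chan_index = {c: i for i, c in enumerate(record.channels)}
    missing = [c for c in model.selected if c not in chan_index]
    if missing:
        raise ValueError(f"record lacks residual channels {missing}")
    eta = model.intercept + sum(
        model.coefficients[c] * record.residuals[chan_index[c]] for c in model.selected
    )
    prob = float(1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700))))
    label = "known_positive" if prob < model.threshold else "known_negative"
    return prob, label
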