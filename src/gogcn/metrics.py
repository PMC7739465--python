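"""Evaluation metrics for multi-label protein function prediction.

Term-centric metrics (AUC, AUPRC, PR50) are computed per selected term
over proteins and macro-averaged; protein-centric metrics (Fmax, Smin)
are computed per protein over terms and aggregated across a threshold
grid.

Fmax is the maximum over thresholds θ of the harmonic mean of the
averaged precision and recall, where the averages run over m(θ), the set
of proteins with at least one prediction at or above θ (a flag switches
recall to the all-protein CAFA convention). Smin is the minimum over θ of
``sqrt(ru(θ)² + mi(θ)²)`` where remaining uncertainty ``ru`` sums the
information content of true-but-unpredicted terms and misinformation
``mi`` sums the IC of predicted-but-untrue terms, both averaged over all
proteins; it measures, in IC units, how far the prediction sits from the
truth on the ontology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Default threshold grid: 0.00 to 1.00 in steps of 0.01.
DEFAULT_GRID = np.round(np.arange(101) / 100.0, 2)


def term_auc(labels, scores) -> float:
    """Rank-based AUC for one term; ties count one half.

    Equals the fraction of (positive, negative) pairs ranked concordantly,
    via the Mann-Whitney statistic.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _descending_order(scores: np.ndarray) -> np.ndarray:
    # stable sort on negated scores: ties keep input order
    return np.argsort(-scores, kind="stable")


def term_auprc(labels, scores) -> float:
    """Average precision for one term (mean precision at each positive's rank).

    Ties are broken by descending score then input order; no interpolation.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("AUPRC needs at least one positive")
    order = _descending_order(scores)
    hits = labels[order] == 1
    ranks = np.flatnonzero(hits) + 1  # 1-based rank of each positive
    precisions = np.cumsum(hits)[hits.nonzero()] / ranks
    return float(precisions.mean())


def term_pr50(labels, scores) -> float:
    """Precision at the smallest rank cutoff where recall reaches 50%."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("PR50 needs at least one positive")
    order = _descending_order(scores)
    hits = (labels[order] == 1).astype(float)
    tp = np.cumsum(hits)
    recall = tp / n_pos
    k = int(np.argmax(recall >= 0.5))  # first crossing
    return float(tp[k] / (k + 1))


def _macro(metric, truth: np.ndarray, scores: np.ndarray, need_negative: bool):
    """Macro-average a per-term metric, skipping degenerate columns."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    values = []
    skipped = 0
    for j in range(truth.shape[1]):
        col = truth[:, j]
        if col.sum() == 0 or (need_negative and col.sum() == len(col)):
            skipped += 1
            continue
        values.append(metric(col, scores[:, j]))
    if not values:
        raise ValueError("no term has the class support the metric requires")
    if skipped:
        logger.info("macro average skipped %d degenerate terms", skipped)
    return float(np.mean(values)), len(values)


def macro_auc(truth, scores) -> float:
    return _macro(term_auc, truth, scores, need_negative=True)[0]


def macro_auprc(truth, scores) -> float:
    return _macro(term_auprc, truth, scores, need_negative=False)[0]


def macro_pr50(truth, scores) -> float:
    return _macro(term_pr50, truth, scores, need_negative=False)[0]


def fmax(
    truth,
    scores,
    grid=DEFAULT_GRID,
    cafa_recall: bool = False,
) -> tuple[float, float]:
    """Protein-centric maximum F-measure over a threshold grid.

    Returns ``(Fmax, θ*)``. At each θ, per-protein precision and recall are
    averaged over m(θ), the proteins with at least one score ≥ θ; with
    ``cafa_recall=True`` recall is instead averaged over all proteins.
    Thresholds where m(θ) is empty or precision+recall is zero are skipped;
    if every threshold is degenerate the result is ``(nan, nan)``.
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if truth.shape != scores.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape}, scores {scores.shape}")
    n = truth.shape[0]
    true_counts = truth.sum(axis=1)
    best_f, best_theta = -np.inf, np.nan
    for theta in grid:
        pred = scores >= theta
        pred_counts = pred.sum(axis=1)
        covered = pred_counts > 0
        m = int(covered.sum())
        if m == 0:
            continue
        tp = (pred & (truth == 1)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(covered, tp / np.maximum(pred_counts, 1), 0.0)
            r_i = np.where(true_counts > 0, tp / np.maximum(true_counts, 1), 0.0)
        p = p_i[covered].sum() / m
        r = r_i.sum() / n if cafa_recall else r_i[covered].sum() / m
        if p + r == 0:
            continue
        f = 2 * p * r / (p + r)
        if f > best_f:
            best_f, best_theta = f, theta
    if not np.isfinite(best_f):
        logger.warning("Fmax undefined: no threshold yields any prediction")
        return float("nan"), float("nan")
    return float(best_f), float(best_theta)


def smin(truth, scores, ic, grid=DEFAULT_GRID) -> tuple[float, float]:
    """Minimum IC-weighted semantic distance over a threshold grid.

    Returns ``(Smin, θ*)``; ``ic`` must align with the term columns.
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    ic = np.asarray(ic, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if ic.shape != (truth.shape[1],):
        raise ValueError(
            f"IC vector shape {ic.shape} does not match {truth.shape[1]} terms"
        )
    n = truth.shape[0]
    is_true = truth == 1
    best_s, best_theta = np.inf, np.nan
    for theta in grid:
        pred = scores >= theta
        ru = (np.where(pred & ~is_true, ic, 0.0).sum(axis=1)).sum() / n
        mi = (np.where(is_true & ~pred, ic, 0.0).sum(axis=1)).sum() / n
        s = float(np.hypot(ru, mi))
        if s < best_s:
            best_s, best_theta = s, theta
    return float(best_s), float(best_theta)


@dataclass
class EvalReport:
    """Macro term-centric and protein-centric scores for one prediction set."""

    auc: float
    auprc: float
    pr50: float
    fmax: float
    fmax_threshold: float
    smin: float
    smin_threshold: float
    n_proteins: int
    n_terms: int
    n_terms_scored: int
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy(), repr=False)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auprc": self.auprc,
            "pr50": self.pr50,
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "smin": self.smin,
            "smin_threshold": self.smin_threshold,
            "n_proteins": self.n_proteins,
            "n_terms": self.n_terms,
            "n_terms_scored": self.n_terms_scored,
        }

    def summary(self) -> str:
        lines = [
            "Evaluation report",
            "-----------------",
            f"proteins: {self.n_proteins}   terms: {self.n_terms} "
            f"(scored: {self.n_terms_scored})",
            f"macro AUC:   {self.auc:.4f}",
            f"macro AUPRC: {self.auprc:.4f}",
            f"macro PR50:  {self.pr50:.4f}",
            f"Fmax: {self.fmax:.4f} at threshold {self.fmax_threshold:.2f}",
            f"Smin: {self.smin:.4f} at threshold {self.smin_threshold:.2f}",
        ]
        return "\n".join(lines)


def evaluate(
    truth,
    scores,
    ic,
    grid=DEFAULT_GRID,
    cafa_recall: bool = False,
) -> EvalReport:
    """Compute the full metric panel on probability scores."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    auc, n_scored = _macro(term_auc, truth, scores, need_negative=True)
    auprc = macro_auprc(truth, scores)
    pr = macro_pr50(truth, scores)
    f, f_theta = fmax(truth, scores, grid=grid, cafa_recall=cafa_recall)
    s, s_theta = smin(truth, scores, ic, grid=grid)
    return EvalReport(
        auc=auc,
        auprc=auprc,
        pr50=pr,
        fmax=f,
        fmax_threshold=f_theta,
        smin=s,
        smin_threshold=s_theta,
        n_proteins=truth.shape[0],
        n_terms=truth.shape[1],
        n_terms_scored=n_scored,
        grid=np.asarray(grid, dtype=float),
    )
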