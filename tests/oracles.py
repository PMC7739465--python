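"""Brute-force reference implementations, kept deliberately naive.

Everything here is plain loops over pairs, thresholds, proteins and
terms, independent of the vectorized code paths it checks.
"""

import math

import numpy as np


def reachable_ancestors(edges, term):
    """Transitive parents of ``term`` by repeated scanning of the edge set."""
    parents = {}
    for child, parent, _rel in edges:
        parents.setdefault(child, set()).add(parent)
    out, frontier = set(), {term}
    while frontier:
        nxt = set()
        for t in frontier:
            for p in parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    nxt.add(p)
        frontier = nxt
    return out


def reachable_descendants(edges, term):
    flipped = {(p, c, r) for c, p, r in edges}
    return reachable_ancestors(flipped, term)


def pairwise_auc(labels, scores):
    """Concordant-pair fraction with ties counted one half."""
    pos = [s for lab, s in zip(labels, scores) if lab == 1]
    neg = [s for lab, s in zip(labels, scores) if lab == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def rankwalk_auprc(labels, scores):
    """Mean precision at each positive's rank, input order breaking ties."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    tp, precisions = 0, []
    for rank, i in enumerate(order, start=1):
        if labels[i] == 1:
            tp += 1
            precisions.append(tp / rank)
    return sum(precisions) / len(precisions)


def rankwalk_pr50(labels, scores):
    """Precision at the first rank where recall reaches one half."""
    n_pos = sum(1 for lab in labels if lab == 1)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    tp = 0
    for rank, i in enumerate(order, start=1):
        if labels[i] == 1:
            tp += 1
        if tp / n_pos >= 0.5:
            return tp / rank
    raise AssertionError("unreachable: recall always reaches 1")


def threshold_fmax(truth, scores, grid, cafa_recall=False):
    """Nested-loop Fmax over the grid; returns (fmax, theta)."""
    n, t = len(truth), len(truth[0])
    best, best_theta = float("-inf"), float("nan")
    for theta in grid:
        ps, rs_m, rs_all, m = [], [], [], 0
        for i in range(n):
            pred = [1 if scores[i][j] >= theta else 0 for j in range(t)]
            npred = sum(pred)
            tp = sum(1 for j in range(t) if pred[j] and truth[i][j])
            ntrue = sum(truth[i])
            r_i = tp / ntrue if ntrue else 0.0
            rs_all.append(r_i)
            if npred > 0:
                m += 1
                ps.append(tp / npred)
                rs_m.append(r_i)
        if m == 0:
            continue
        p = sum(ps) / m
        r = sum(rs_all) / n if cafa_recall else sum(rs_m) / m
        if p + r == 0:
            continue
        f = 2 * p * r / (p + r)
        if f > best:
            best, best_theta = f, theta
    return best, best_theta


def threshold_smin(truth, scores, ic, grid):
    """Nested-loop Smin over the grid; returns (smin, theta)."""
    n, t = len(truth), len(truth[0])
    best, best_theta = float("inf"), float("nan")
    for theta in grid:
        ru = mi = 0.0
        for i in range(n):
            for j in range(t):
                pred = scores[i][j] >= theta
                if pred and not truth[i][j]:
                    ru += ic[j]
                if truth[i][j] and not pred:
                    mi += ic[j]
        s = math.hypot(ru / n, mi / n)
        if s < best:
            best, best_theta = s, theta
    return best, best_theta


def random_eval_instance(rng, max_proteins=5, max_terms=6):
    """A random truth/scores pair where every protein has a true term."""
    n = int(rng.integers(1, max_proteins + 1))
    t = int(rng.integers(1, max_terms + 1))
    truth = (rng.random((n, t)) < 0.4).astype(int)
    for i in range(n):
        if truth[i].sum() == 0:
            truth[i, rng.integers(0, t)] = 1
    scores = np.round(rng.random((n, t)), 2)  # grid-aligned score ties occur
    return truth, scores
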