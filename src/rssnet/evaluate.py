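"""Benchmark metrics and the classical tests used to summarize results.

AUROC is the Mann-Whitney probability that a positive outscores a
negative (ties count one half); AUPRC is the step-wise integral of the
precision-recall curve.  FPR/FDR evaluate gene prioritization at a P1
cutoff.  The binomial and two-proportion tail tests are computed in log
space so that probabilities far below 1e-300 remain exact.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from sklearn import metrics as _skm

from .datatypes import ValidationError

LN10 = np.log(10.0)


def roc_prc_eval(pos_scores, neg_scores) -> dict:
    """AUROC, AUPRC and the underlying curves for two score samples."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be non-empty")
    y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
    s = np.r_[pos, neg]
    fpr, tpr, _ = _skm.roc_curve(y, s)
    prec, rec, _ = _skm.precision_recall_curve(y, s)
    return {
        "auroc": float(_skm.roc_auc_score(y, s)),
        "auprc": float(_skm.average_precision_score(y, s)),
        "roc": (fpr, tpr),
        "prc": (rec, prec),
    }


def fpr_fdr_eval(p1, labels, cutoff: float = 0.9) -> dict:
    """False positive rate and false discovery rate at P1 >= cutoff.

    Undefined ratios (no negatives / no calls) are reported as None.
    """
    p1 = np.asarray(p1, dtype=float)
    labels = np.asarray(labels).astype(bool)
    called = p1 >= cutoff
    fp = int(np.sum(called & ~labels))
    negatives = int(np.sum(~labels))
    ncalled = int(called.sum())
    return {
        "fpr": fp / negatives if negatives else None,
        "fdr": fp / ncalled if ncalled else None,
        "n_called": ncalled,
        "n_true": int(labels.sum()),
    }


def binomial_test_one_sided(k: int, n: int, p0: float,
                            log10: bool = False) -> float:
    """Exact upper tail P(X >= k), X ~ Binomial(n, p0), in log space."""
    if not (0 <= k <= n):
        raise ValidationError("require 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValidationError("require p0 in (0, 1)")
    if k == 0:
        return 0.0 if log10 else 1.0
    ks = np.arange(k, n + 1)
    log_tail = logsumexp(stats.binom.logpmf(ks, n, p0))
    return log_tail / LN10 if log10 else float(np.exp(log_tail))


def two_proportion_test_one_sided(k1: int, n1: int, k2: int, n2: int,
                                  continuity: bool = True,
                                  log10: bool = False) -> float:
    """One-sided pooled two-proportion test of p1 > p2.

    Chi-square with 1 df made one-sided via the signed normal deviate,
    with a continuity correction by default; tail computed in log space.
    """
    if min(k1, k2) < 0 or k1 > n1 or k2 > n2:
        raise ValidationError("invalid counts")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    d = p1 - p2
    if continuity:
        d -= np.sign(d) * 0.5 * (1 / n1 + 1 / n2)
    z = d / se if se > 0 else 0.0
    log_tail = stats.norm.logsf(z)
    return log_tail / LN10 if log10 else float(np.exp(log_tail))
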