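"""Early-recognition metrics for virtual screening.

A screening model is judged by how many actives it puts at the very top of
its ranked list, because only a tiny fraction of predictions can be tested
experimentally.  Four metrics capture this:

- ranged logAUC: area under the ROC curve with FPR on a log10 axis
  restricted to [0.001, 0.1], normalized by the log-width.  Perfect
  ranking = 1; a random ranking ~ 0.0215.
- BEDROC: exponentially weighted early-recognition score in [0, 1],
  defined through the Robust Initial Enhancement (RIE) statistic.
- EF_k (enrichment factor): active fraction in the top k over the global
  active fraction; random expectation 1.
- DCG_k (discounted cumulative gain): actives in the top k discounted by
  log2(rank + 1); the undiscounted CG_k is returned alongside.

All metrics depend only on the induced ranking.  Ties are broken
deterministically: score descending, then stable input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sklearn.metrics

__all__ = [
    "RankedResult", "RocCurve", "roc_curve", "ranged_log_auc",
    "bedroc", "enrichment_factor", "dcg", "compute_all_metrics",
    "METRIC_NAMES", "RANDOM_LOGAUC",
]

METRIC_NAMES = ("logauc_0.001_0.1", "bedroc", "ef_100", "dcg_100")

#: logAUC of the diagonal (random) ROC over [0.001, 0.1]:
#: integral of x dlog10(x) over the range divided by the log-width.
RANDOM_LOGAUC = (0.1 - 0.001) / np.log(10.0) / 2.0


@dataclass
class RankedResult:
    """Predicted activity scores paired with true labels for a test set."""

    ids: np.ndarray
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ids, scores, labels must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def __len__(self):
        return len(self.scores)

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    def _require_both_classes(self, metric: str):
        if self.n_actives == 0 or self.n_actives == len(self):
            raise ValueError(
                f"{metric} requires at least one active and one inactive"
            )

    def ranked_labels(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Labels ordered by score descending.

        Ties are broken by stable input order, or shuffled under ``rng``
        when given (used by the tie-averaging metric mode).
        """
        if rng is None:
            order = np.argsort(-self.scores, kind="stable")
        else:
            jitter = rng.permutation(len(self.scores))
            order = np.lexsort((jitter, -self.scores))
        return self.labels[order]


def _tie_average(fn, r: "RankedResult", tie_policy: str, n_shuffles: int = 10,
                 tie_seed: int = 0):
    """Apply a ranked-labels metric under the requested tie policy.

    ``stable``: deterministic order (score desc, then input order).
    ``shuffle-average``: mean over seeded shuffles of tie blocks.
    """
    if tie_policy == "stable":
        return fn(r.ranked_labels())
    if tie_policy == "shuffle-average":
        rng = np.random.default_rng(tie_seed)
        return float(np.mean([fn(r.ranked_labels(rng))
                              for _ in range(n_shuffles)]))
    raise ValueError(f"unknown tie policy {tie_policy!r}")


@dataclass
class RocCurve:
    """Threshold-sweep ROC: (FPR, TPR) from (0,0) to (1,1), nondecreasing."""

    fpr: np.ndarray
    tpr: np.ndarray


def roc_curve(r: RankedResult) -> RocCurve:
    """Descending-score sweep; tied scores advance as one block."""
    r._require_both_classes("roc_curve")
    fpr, tpr, _ = sklearn.metrics.roc_curve(
        r.labels, r.scores, drop_intermediate=False
    )
    return RocCurve(fpr=fpr, tpr=tpr)


def ranged_log_auc(r: RankedResult, fpr_lo: float = 0.001,
                   fpr_hi: float = 0.1, n_grid: int = 10_001) -> float:
    """Normalized area under TPR d(log10 FPR) over [fpr_lo, fpr_hi].

    TPR is interpolated linearly in FPR between ROC vertices (the curve is
    extended from (0, 0), so FPRs below the empirical minimum are covered);
    the integral is a trapezoid rule on a dense log-uniform grid augmented
    with every curve vertex inside the range, divided by the log-width.
    """
    if not (0.0 < fpr_lo < fpr_hi <= 1.0):
        raise ValueError("need 0 < fpr_lo < fpr_hi <= 1")
    curve = roc_curve(r)
    fpr, tpr = curve.fpr, curve.tpr
    if fpr[0] > 0.0:
        fpr, tpr = np.r_[0.0, fpr], np.r_[0.0, tpr]

    # integrate segment by segment in sweep order; vertical segments
    # (equal FPR) have zero measure on the FPR axis and contribute nothing
    grid = np.logspace(np.log10(fpr_lo), np.log10(fpr_hi), n_grid)
    area = 0.0
    for k in range(len(fpr) - 1):
        x0, x1 = fpr[k], fpr[k + 1]
        y0, y1 = tpr[k], tpr[k + 1]
        a, b = max(x0, fpr_lo), min(x1, fpr_hi)
        if a >= b or x1 == x0:
            continue
        inner = grid[(grid > a) & (grid < b)]
        xs = np.concatenate([[a], inner, [b]])
        ys = y0 + (y1 - y0) * (xs - x0) / (x1 - x0)
        area += np.trapezoid(ys, np.log10(xs))
    return float(area / (np.log10(fpr_hi) - np.log10(fpr_lo)))


def bedroc(r: RankedResult, alpha: float = 20.0,
           tie_policy: str = "stable") -> float:
    """Boltzmann-enhanced discrimination of ROC.

    BEDROC = (RIE - RIE_min) / (RIE_max - RIE_min) with
    RIE = sum over actives of exp(-alpha * rank_i / N), normalized by the
    expectation for uniformly placed actives; RIE_max/min place all
    actives at the very top/bottom.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    r._require_both_classes("bedroc")

    def from_ranked(ranked: np.ndarray) -> float:
        N = len(ranked)
        n = int(ranked.sum())
        ranks = np.nonzero(ranked)[0] + 1  # 1-based
        denom = (n / N) * (1.0 - np.exp(-alpha)) / (np.expm1(alpha / N))
        rie = np.exp(-alpha * ranks / N).sum() / denom
        top = np.arange(1, n + 1)
        bottom = np.arange(N - n + 1, N + 1)
        rie_max = np.exp(-alpha * top / N).sum() / denom
        rie_min = np.exp(-alpha * bottom / N).sum() / denom
        return float((rie - rie_min) / (rie_max - rie_min))

    return _tie_average(from_ranked, r, tie_policy)


def enrichment_factor(r: RankedResult, cutoff: int = 100,
                      tie_policy: str = "stable") -> float:
    """EF_k = (actives in top k / k) / (actives / N); random expectation 1."""
    N = len(r)
    if N < cutoff:
        raise ValueError(f"enrichment cutoff {cutoff} exceeds data set size {N}")
    r._require_both_classes("enrichment_factor")
    n = r.n_actives

    def from_ranked(ranked):
        return float((int(ranked[:cutoff].sum()) / cutoff) / (n / N))

    return _tie_average(from_ranked, r, tie_policy)


def dcg(r: RankedResult, cutoff: int = 100,
        tie_policy: str = "stable") -> tuple[float, float]:
    """(DCG_k, CG_k): discounted and plain active counts in the top k.

    Relevance is 1 for actives, 0 for inactives; rank i starts at 1 and
    the discount is 1/log2(i + 1).
    """
    N = len(r)
    if N < cutoff:
        raise ValueError(f"DCG cutoff {cutoff} exceeds data set size {N}")
    i = np.arange(1, cutoff + 1)

    dcg_val = _tie_average(
        lambda ranked: float((ranked[:cutoff] / np.log2(i + 1)).sum()),
        r, tie_policy)
    cg_val = _tie_average(lambda ranked: float(ranked[:cutoff].sum()),
                          r, tie_policy)
    cg_val = int(cg_val) if float(cg_val).is_integer() else cg_val
    return dcg_val, cg_val


def compute_all_metrics(r: RankedResult, alpha: float = 20.0,
                        cutoff: int = 100, fpr_lo: float = 0.001,
                        fpr_hi: float = 0.1) -> dict:
    """The standard four-metric report for one (model, data set, split)."""
    dcg_val, _cg = dcg(r, cutoff)
    return {
        f"logauc_{fpr_lo}_{fpr_hi}": ranged_log_auc(r, fpr_lo, fpr_hi),
        "bedroc": bedroc(r, alpha),
        f"ef_{cutoff}": enrichment_factor(r, cutoff),
        f"dcg_{cutoff}": dcg_val,
    }
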