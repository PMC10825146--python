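"""Evaluation statistics: classification, reconstruction/translation fidelity,
latent-space separation, and the GSEA rank distance between profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

__all__ = [
    "ConfusionCounts",
    "EffectSize",
    "classification_metrics",
    "pearson_global",
    "spearman_per_sample",
    "sign_accuracy",
    "r2_per_gene",
    "cosine_distance",
    "cohens_d",
    "enrichment_score",
    "gsea_distance",
    "latent_separation_report",
]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest confusion counts."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @classmethod
    def from_labels(cls, pred, true, n_classes: int) -> "ConfusionCounts":
        pred = np.asarray(pred)
        true = np.asarray(true)
        tp = np.zeros(n_classes, dtype=int)
        fp = np.zeros(n_classes, dtype=int)
        tn = np.zeros(n_classes, dtype=int)
        fn = np.zeros(n_classes, dtype=int)
        for k in range(n_classes):
            tp[k] = np.sum((pred == k) & (true == k))
            fp[k] = np.sum((pred == k) & (true != k))
            fn[k] = np.sum((pred != k) & (true == k))
            tn[k] = np.sum((pred != k) & (true != k))
        return cls(tp, fp, tn, fn)


def classification_metrics(pred_labels, true_labels, n_classes: int) -> dict[str, float]:
    """Accuracy and (micro-)F1 in one-vs-rest accounting.

    For K > 2 the micro-F1 of summed per-class counts is reported; the binary
    case reduces to the usual single-positive-class formulas.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    c = ConfusionCounts.from_labels(pred, true, n_classes)
    if n_classes == 2:
        tp, fp, tn, fn = c.tp[1], c.fp[1], c.tn[1], c.fn[1]
        accuracy = (tp + tn) / (tp + tn + fp + fn)
        denom = tp + 0.5 * (fp + fn)
        f1 = tp / denom if denom > 0 else 0.0
    else:
        accuracy = (c.tp.sum() + c.tn.sum()) / (c.tp.sum() + c.tn.sum() + c.fp.sum() + c.fn.sum())
        denom = c.tp.sum() + 0.5 * (c.fp.sum() + c.fn.sum())
        f1 = c.tp.sum() / denom if denom > 0 else 0.0
    return {"accuracy": float(accuracy), "f1": float(f1)}


def pearson_global(Y_hat, Y) -> float:
    """Single Pearson correlation over all flattened entries."""
    a = np.asarray(Y_hat, dtype=float).ravel()
    b = np.asarray(Y, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.corrcoef(a, b)[0, 1])


def spearman_per_sample(Y_hat, Y) -> float:
    """Average over samples of the per-row Spearman rank correlation
    (average ranks on ties)."""
    A = np.atleast_2d(np.asarray(Y_hat, dtype=float))
    B = np.atleast_2d(np.asarray(Y, dtype=float))
    if A.shape != B.shape:
        raise ValueError("shape mismatch")
    rs = [spearmanr(A[i], B[i]).statistic for i in range(A.shape[0])]
    return float(np.mean(rs))


def sign_accuracy(Y_hat, Y, tol: float = 1e-6) -> float:
    """Fraction of entries whose regulation sign agrees, counting entries with
    |value| <= tol in both matrices as agreeing 'true zeros'."""
    A = np.asarray(Y_hat, dtype=float)
    B = np.asarray(Y, dtype=float)
    if A.shape != B.shape:
        raise ValueError("shape mismatch")
    true_zero = (np.abs(A) <= tol) & (np.abs(B) <= tol)
    tp = (A > tol) & (B > tol)
    tn = (A < -tol) & (B < -tol)
    return float((true_zero | tp | tn).sum() / A.size)


def r2_per_gene(stat_hat, stat_true) -> float:
    """Coefficient of determination R^2 = 1 - RSS/TSS for per-gene statistics."""
    a = np.asarray(stat_hat, dtype=float).ravel()
    b = np.asarray(stat_true, dtype=float).ravel()
    rss = np.sum((a - b) ** 2)
    tss = np.sum((b - b.mean()) ** 2)
    if tss == 0:
        raise ValueError("zero total sum of squares: ground truth is constant")
    return float(1.0 - rss / tss)


def cosine_distance(z1, z2) -> float:
    """1 - cosine similarity: 0 for identical directions, 2 for opposite."""
    a = np.asarray(z1, dtype=float).ravel()
    b = np.asarray(z2, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(a, b) / (na * nb))


@dataclass
class EffectSize:
    """Cohen's d with pooled standard deviation; antisymmetric under swap."""

    d: float
    n1: int
    n2: int
    mean1: float
    mean2: float
    s1: float
    s2: float


def cohens_d(dist1, dist2) -> EffectSize:
    x = np.asarray(dist1, dtype=float)
    y = np.asarray(dist2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 + n2 <= 2:
        raise ValueError("need more than two observations in total")
    s1, s2 = x.std(ddof=1), y.std(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return EffectSize(d=float((x.mean() - y.mean()) / pooled), n1=n1, n2=n2,
                      mean1=float(x.mean()), mean2=float(y.mean()),
                      s1=float(s1), s2=float(s2))


# ---------------------------------------------------------------------------
# GSEA rank distance
# ---------------------------------------------------------------------------

def enrichment_score(in_set: np.ndarray) -> float:
    """Unweighted running-sum enrichment score of a gene set in a ranking.

    ``in_set`` is a boolean vector ordered by the ranking (best first).  Hits
    step +1/|S|, misses step -1/(N-|S|); the score is the running-sum value of
    maximum absolute deviation (signed).
    """
    in_set = np.asarray(in_set, dtype=bool)
    n = in_set.size
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a proper non-empty subset of the universe")
    steps = np.where(in_set, 1.0 / n_hit, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _es_one_direction(scores_from: np.ndarray, scores_in: np.ndarray, t: int) -> float:
    """Combined ES of the top-t and bottom-t genes of one profile inside the
    other profile's ranking; identity => +1, reversal => -1."""
    order_from = np.argsort(-scores_from)  # best first
    top = set(order_from[:t])
    bottom = set(order_from[-t:])
    order_in = np.argsort(-scores_in)
    es_up = enrichment_score(np.fromiter((g in top for g in order_in), bool, len(order_in)))
    es_down = enrichment_score(np.fromiter((g in bottom for g in order_in), bool, len(order_in)))
    return (es_up - es_down) / 2.0


def gsea_distance(rank_A, rank_B, thresholds=(100, 250, 500)) -> float:
    """Rank-based distance between two profiles over one feature universe.

    For each threshold t the top-t and bottom-t genes of each profile are
    scored by their running-sum enrichment in the other profile's ranking;
    the per-threshold distance is 1 - (ES_AinB + ES_BinA)/2 and the average
    over thresholds is returned.  0 means the most up- and down-regulated
    genes coincide; 2 means the rankings are reversed.  Thresholds larger
    than half the universe are rejected; for small universes the default
    threshold list is scaled down proportionally (relative to 1000 genes).
    """
    a = np.asarray(rank_A, dtype=float).ravel()
    b = np.asarray(rank_B, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("profiles must share one feature universe")
    n = a.size
    thresholds = [int(t) for t in thresholds]
    if n < 1000 and thresholds == [100, 250, 500]:
        thresholds = sorted({max(1, int(round(t * n / 1000))) for t in thresholds})
    for t in thresholds:
        if t > n / 2:
            raise ValueError(f"threshold {t} must not exceed half the gene count ({n})")
        if t < 1:
            raise ValueError("thresholds must be positive")
    dists = []
    for t in thresholds:
        es_ab = _es_one_direction(a, b, t)
        es_ba = _es_one_direction(b, a, t)
        dists.append(1.0 - (es_ab + es_ba) / 2.0)
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# Latent-space separation report
# ---------------------------------------------------------------------------

def latent_separation_report(embeddings, metadata, n_random_pairs: int = 1000,
                             seed: int = 0) -> dict:
    """Cosine-distance distributions for random pairs vs structured pairs.

    ``metadata`` is a sequence of dicts (or SampleRecords) with ``system``,
    ``condition`` and optionally ``replicate_group`` per sample.  Categories
    with fewer than two pairs are reported as absent (None).  Returns the
    distance distributions and the Cohen's d of each category against random
    pairs (negative d means the category's pairs are closer than random).
    """
    Z = np.asarray(embeddings, dtype=float)
    n = Z.shape[0]
    rng = np.random.default_rng(seed)

    def get(s, key):
        if isinstance(s, dict):
            return s.get(key)
        if key == "condition":
            cond = getattr(s, "condition", None)
            return cond.as_tuple() if cond is not None else None
        return getattr(s, key, None)

    def dist_of(pairs):
        return np.array([cosine_distance(Z[i], Z[j]) for i, j in pairs])

    random_pairs = [(i, j) for i, j in zip(rng.integers(0, n, n_random_pairs),
                                           rng.integers(0, n, n_random_pairs)) if i != j]
    categories: dict[str, list[tuple[int, int]]] = {
        "same_system": [], "same_condition": [], "replicate": []}
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = metadata[i], metadata[j]
            if get(si, "system") is not None and get(si, "system") == get(sj, "system"):
                categories["same_system"].append((i, j))
            if get(si, "condition") is not None and get(si, "condition") == get(sj, "condition"):
                categories["same_condition"].append((i, j))
            rg = get(si, "replicate_group")
            if rg is not None and rg == get(sj, "replicate_group"):
                categories["replicate"].append((i, j))

    rand_d = dist_of(random_pairs)
    report: dict = {"random": {"distances": rand_d, "n": len(rand_d)}}
    for name, pairs in categories.items():
        if len(pairs) < 2:
            report[name] = None
            continue
        if len(pairs) > n_random_pairs:
            sel = rng.choice(len(pairs), size=n_random_pairs, replace=False)
            pairs = [pairs[k] for k in sel]
        dd = dist_of(pairs)
        report[name] = {"distances": dd, "n": len(dd),
                        "cohens_d_vs_random": cohens_d(dd, rand_d).d}
    return report
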