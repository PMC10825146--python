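"""Model interpretation: integrated-gradient attribution, selection of
important latent variables (k-means rule and likelihood-ratio tests), and the
serology feature-identification pipeline."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .autodiff import Tensor
from .metrics import enrichment_score
from .model import TranslatorModel

__all__ = [
    "ImportanceResult",
    "LRTResult",
    "read_gmt",
    "integrated_gradients",
    "kmeans_importance_split",
    "lrt_latent",
    "select_protective_latents",
    "rank_cross_system_features",
    "build_feature_network",
    "percentile_rank_summary",
    "preranked_enrichment",
]


@dataclass
class ImportanceResult:
    """Integrated-gradient scores.

    ``scores`` has shape (n_samples, n_features) or (n_features,) when
    averaged across samples.  The baseline is the zero vector; attribution
    satisfies completeness (sum of scores = F(x) - F(0)) up to the
    step-count discretization error.
    """

    scores: np.ndarray
    baseline: np.ndarray
    n_steps: int
    averaged: bool
    target: Optional[int] = None

    def mean_over_samples(self) -> "ImportanceResult":
        if self.averaged:
            return self
        return ImportanceResult(self.scores.mean(axis=0), self.baseline,
                                self.n_steps, True, self.target)


def _alphas(n_steps: int, method: str) -> tuple[np.ndarray, np.ndarray]:
    if method == "left":
        a = np.arange(n_steps) / n_steps
        w = np.full(n_steps, 1.0 / n_steps)
    elif method == "midpoint":
        a = (np.arange(n_steps) + 0.5) / n_steps
        w = np.full(n_steps, 1.0 / n_steps)
    elif method == "trapezoid":
        a = np.linspace(0.0, 1.0, n_steps + 1)
        w = np.full(n_steps + 1, 1.0 / n_steps)
        w[0] = w[-1] = 0.5 / n_steps
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return a, w


def integrated_gradients(F: Callable[[Tensor], Tensor], x, target_index: Optional[int] = None,
                         n_steps: int = 50, method: str = "left",
                         average_samples: bool = False) -> ImportanceResult:
    """Riemann approximation of the path-integral attribution from a zero
    baseline:  score_i = x_i * \\int_0^1 dF(a x)/dx_i da.

    ``F`` maps a Tensor of shape (n, d) to per-sample outputs of shape (n,)
    or (n, K); with a 2-D output ``target_index`` selects the column.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    alphas, weights = _alphas(n_steps, method)
    grad_acc = np.zeros_like(x)
    for a, w in zip(alphas, weights):
        xt = Tensor(a * x, requires_grad=True)
        out = F(xt)
        if out.data.ndim == 2 and out.data.shape[1] > 1:
            if target_index is None:
                raise ValueError("target_index required for a multi-output map")
            out = out[:, target_index]
        out.sum().backward()
        grad_acc += w * xt.grad
    scores = x * grad_acc
    res = ImportanceResult(scores=scores, baseline=np.zeros(x.shape[1]),
                           n_steps=n_steps, averaged=False, target=target_index)
    return res.mean_over_samples() if average_samples else res


def kmeans_importance_split(abs_scores, seed: int = 0, n_restarts: int = 10,
                            ) -> tuple[np.ndarray, float]:
    """Split latent variables into important / unimportant by 3-means.

    Scores are clustered (on their absolute values) into three clusters; the
    highest-centroid cluster is treated as a small cluster of outliers, the
    lowest as the unimportant bulk, and the middle one as important.  The
    threshold is the midpoint between the highest score in the unimportant
    cluster and the lowest score in the important cluster; everything at or
    above it (middle cluster plus outliers) is returned as important.
    """
    from sklearn.cluster import KMeans

    s = np.abs(np.asarray(abs_scores, dtype=float)).ravel()
    if np.unique(s).size < 3:
        raise ValueError("no separation: need at least 3 distinct score values")
    km = KMeans(n_clusters=3, n_init=n_restarts, random_state=seed).fit(s.reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    order = np.argsort(centroids)  # low (unimportant), mid (important), high (outliers)
    lab = km.labels_
    low, mid = order[0], order[1]
    hi_unimportant = s[lab == low].max()
    lo_important = s[lab == mid].min()
    threshold = (hi_unimportant + lo_important) / 2.0
    important = np.flatnonzero(s >= threshold)
    return important, float(threshold)


@dataclass
class LRTResult:
    """Per-latent-variable likelihood-ratio test of the protection term."""

    lrt: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    t_protection: np.ndarray


def _design(cols: list[np.ndarray]) -> np.ndarray:
    n = cols[0].size
    return np.column_stack([np.ones(n)] + cols)


def _gauss_loglik(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = y.size
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return ll, beta, resid


def lrt_latent(Z, protection, vaccination, species) -> LRTResult:
    """LRT of `latent_i ~ protection + vaccination + species` against the
    nested model without protection; 1-df chi-square p-values with
    Benjamini-Hochberg adjustment, plus the t-value of the protection term.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    prot = np.asarray(protection, dtype=float)
    vacc = np.asarray(vaccination, dtype=float)
    spec = np.asarray(species, dtype=float)
    names = ["protection", "vaccination", "species"]
    cols = [prot, vacc, spec]
    for i in range(3):
        for j in range(i + 1, 3):
            ci, cj = cols[i], cols[j]
            if np.std(ci) > 0 and np.std(cj) > 0:
                if abs(np.corrcoef(ci, cj)[0, 1]) > 1 - 1e-10:
                    raise ValueError(f"collinear covariates: {names[i]} and {names[j]}")
    n = prot.size
    X_a = _design(cols)
    X_0 = _design(cols[1:])
    if n <= X_a.shape[1]:
        raise ValueError("need more samples than coefficients")
    df_resid = n - X_a.shape[1]
    xtx_inv = np.linalg.pinv(X_a.T @ X_a)
    lrt = np.zeros(Z.shape[1])
    tval = np.zeros(Z.shape[1])
    for j in range(Z.shape[1]):
        y = Z[:, j]
        ll_a, beta_a, resid_a = _gauss_loglik(y, X_a)
        ll_0, *_ = _gauss_loglik(y, X_0)
        lrt[j] = max(0.0, 2.0 * (ll_a - ll_0))
        sigma2_hat = float(resid_a @ resid_a) / df_resid
        se = np.sqrt(max(sigma2_hat * xtx_inv[1, 1], 1e-300))
        tval[j] = beta_a[1] / se
    p = stats.chi2.sf(lrt, df=1)
    p = np.where(lrt == 0.0, 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return LRTResult(lrt=lrt, p=p, p_adj=p_adj, t_protection=tval)


def select_protective_latents(lrt: LRTResult, ig_scores, pct_threshold: float = 10.0,
                              alpha: float = 0.05) -> np.ndarray:
    """Latent variables that are FDR-significant for protection AND carry a
    high integrated-gradient importance with agreeing sign.

    ``ig_scores`` holds signed per-latent scores with shape (n_folds,
    n_latent) or (n_latent,).  Importance is expressed per fold as a
    percentage of that fold's maximum absolute score, averaged across folds;
    a variable is kept when this average is >= ``pct_threshold``, its
    FDR-adjusted p < ``alpha`` and the sign of its mean score agrees with the
    sign of the protection t-value.
    """
    ig = np.atleast_2d(np.asarray(ig_scores, dtype=float))
    pct = 100.0 * np.abs(ig) / np.abs(ig).max(axis=1, keepdims=True)
    avg_pct = pct.mean(axis=0)
    mean_score = ig.mean(axis=0)
    keep = ((lrt.p_adj < alpha)
            & (avg_pct >= pct_threshold)
            & (np.sign(mean_score) == np.sign(lrt.t_protection))
            & (mean_score != 0))
    return np.flatnonzero(keep)


def rank_cross_system_features(model: TranslatorModel, dataset, important_latents,
                               source_system: str, *, target_system: Optional[str] = None,
                               target_features: Optional[Sequence[int]] = None,
                               n_steps: int = 50, bonferroni: bool = True,
                               encoder_input: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Score every source-system feature by its integrated-gradient control of
    the important latent variables (or, for cross-system scoring, of selected
    translated target features), averaged across that system's samples.

    Returns a table with the signed mean score per (feature, target),
    percentage scores relative to the maximum magnitude and a >=20% flag.
    When the dataset carries protection labels and targets are latents, a
    Wilcoxon rank-sum p-value (Bonferroni-adjusted) between protected and
    unprotected samples is attached per feature.
    """
    important_latents = list(important_latents)
    if not important_latents and target_features is None:
        raise ValueError("important_latents must be non-empty")
    X = np.asarray(dataset.matrix, float) if encoder_input is None else encoder_input
    rows = []
    if target_features is not None:
        if target_system is None:
            raise ValueError("target_system required when scoring target features")

        def make_F(feat):
            def F(xt):
                out = model.translate(xt, source_system, target_system)
                out = out[0] if isinstance(out, tuple) else out
                return out[:, int(feat)]
            return F

        targets = [("feature", int(f), make_F(f)) for f in target_features]
    else:
        def make_L(lat):
            def F(xt):
                return model.encode(xt, source_system)[:, int(lat)]
            return F

        targets = [("latent", int(l), make_L(l)) for l in important_latents]

    model.eval()
    for kind, tgt, F in targets:
        res = integrated_gradients(F, X, n_steps=n_steps, average_samples=True)
        for j, score in enumerate(res.scores):
            rows.append({"feature": dataset.feature_ids[j], "target_kind": kind,
                         "target": tgt, "score": float(score)})
    table = pd.DataFrame(rows)
    max_abs = table["score"].abs().max()
    table["pct"] = 100.0 * table["score"].abs() / (max_abs if max_abs > 0 else 1.0)
    table["ge20"] = table["pct"] >= 20.0

    prot = np.array([getattr(s, "protection", None) for s in dataset.samples])
    if target_features is None and any(p is not None for p in prot):
        mask = prot == "protected"
        pvals = []
        for j in range(X.shape[1]):
            a, b = X[mask, j], X[~mask, j]
            if a.size < 2 or b.size < 2:
                pvals.append(np.nan)
                continue
            pvals.append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        pvals = np.asarray(pvals, dtype=float)
        if bonferroni:
            pvals = np.minimum(pvals * X.shape[1], 1.0)
        pmap = dict(zip(dataset.feature_ids, pvals))
        table["wilcoxon_p"] = table["feature"].map(pmap)
    return table


def build_feature_network(pair_scores: pd.DataFrame, recon_r, fold_sd,
                          magnitude_threshold: float = 10.0,
                          recon_threshold: float = 0.75) -> pd.DataFrame:
    """Filter source->target feature pairs into a high-confidence network.

    Four criteria, applied in order over the table of mean importance scores:
    (1) the source feature's reconstruction Pearson r >= ``recon_threshold``
    (inclusive); (2) the pair's across-fold importance standard deviation is
    in the bottom quartile of all input pairs; (3) the raw signed importance
    has magnitude > ``magnitude_threshold``; (4) the pair's |importance| is in
    the top quartile of the pairs that passed (1)-(3).
    """
    if len(pair_scores) == 0:
        return pair_scores.copy()
    df = pair_scores.copy()
    recon_r = pd.Series(recon_r)
    sd = np.asarray(fold_sd, dtype=float)
    if sd.shape[0] != len(df):
        raise ValueError("fold_sd must align with pair_scores rows")
    df["_sd"] = sd
    q25_sd = df["_sd"].quantile(0.25)
    keep = (df["source"].map(recon_r) >= recon_threshold) \
        & (df["_sd"] <= q25_sd) \
        & (df["score"].abs() > magnitude_threshold)
    survivors = df[keep]
    if len(survivors) == 0:
        return survivors.drop(columns="_sd")
    q75 = survivors["score"].abs().quantile(0.75)
    out = survivors[survivors["score"].abs() >= q75]
    return out.drop(columns="_sd").reset_index(drop=True)


def percentile_rank_summary(scores, categories) -> pd.Series:
    """Median percentile rank of features per category.

    Percentile ranks are computed over all features from the given (mean
    importance) scores; the median within each category is returned.
    """
    s = np.asarray(scores, dtype=float)
    cats = list(categories)
    if len(cats) != s.size:
        raise ValueError("scores and categories must align")
    if any(c is None or (isinstance(c, float) and np.isnan(c)) for c in cats):
        raise ValueError("unknown (missing) category label")
    pr = 100.0 * (stats.rankdata(s) - 0.5) / s.size
    return pd.Series(pr).groupby(pd.Series(cats)).median()


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def preranked_enrichment(importance_scores: pd.Series, gene_sets: dict[str, Sequence[str]],
                         n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Running-sum enrichment of gene sets in an importance ranking, with
    gene-label permutation p-values (two-sided on |ES|)."""
    if isinstance(importance_scores, dict):
        importance_scores = pd.Series(importance_scores)
    genes = np.asarray(importance_scores.index)
    vals = importance_scores.to_numpy(dtype=float)
    order = np.argsort(-vals)
    ranked = genes[order]
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        member_set = set(members) & set(genes)
        if len(member_set) < 2:
            warnings.warn(f"gene set {name!r} overlaps the universe in <2 genes; skipped",
                          stacklevel=2)
            continue
        hits = np.isin(ranked, list(member_set))
        es = enrichment_score(hits)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = enrichment_score(rng.permutation(hits))
        pval = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
        rows.append({"set": name, "size": len(member_set), "es": es, "p": pval})
    return pd.DataFrame(rows, columns=["set", "size", "es", "p"])
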