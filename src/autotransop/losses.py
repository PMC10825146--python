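"""Every term of the training objective, plus the weighted combinations.

The objective couples: reconstruction (MSE for z-scored profiles, negative
binomial negative log-likelihood for counts), alignment of same-condition
embeddings across systems (Euclidean distance minimized, cosine similarity
maximized), a Jensen-Shannon mutual-information bound estimated by Discr1
over the in-batch mask of positives, a prior term scored by Discr2 against a
uniform [0,1] reference, classifier cross-entropies, and L2 penalties.  All
functions operate on autodiff Tensors when given Tensors (for training) and
return plain floats when given plain arrays (for analysis and testing).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .autodiff import Tensor, softplus

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "sample_prior",
    "prior_loss",
    "mi_loss",
    "pair_alignment_losses",
    "recon_loss_mse",
    "recon_loss_nb",
    "classifier_entropy",
    "l2_penalty",
    "total_loss",
]

_LN2 = float(np.log(2.0))


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=float)), False


def _ret(t: Tensor, any_tensor: bool):
    return t if any_tensor else t.item()


@dataclass
class LossWeights:
    """Non-negative weights for each objective term (lambda)."""

    recon: float = 1.0
    distance: float = 1.0
    mi: float = 1.0
    prior: float = 1.0
    cosine: float = 1.0
    enc: tuple[float, float] = (1.0, 1.0)
    dec: tuple[float, float] = (1.0, 1.0)
    l2_class: tuple[float, ...] = ()
    classifier: tuple[float, ...] = ()
    adverse: float = 1.0
    trained_effect: float = 1.0

    def validate(self):
        for f in fields(self):
            v = getattr(self, f.name)
            vals = v if isinstance(v, tuple) else (v,)
            if any(x < 0 for x in vals):
                raise ValueError(f"negative loss weight {f.name}")
        return self


@dataclass
class LossBreakdown:
    """All computed loss parts for one step/epoch, as plain floats."""

    L_recon: float = 0.0
    L_distance: float = 0.0
    L_cosine: float = 0.0
    L_MI: float = 0.0
    E_p: float = 0.0
    E_q: float = 0.0
    L_prior: float = 0.0
    entropy: tuple[float, ...] = ()
    entropy_adverse: float = 0.0
    L2_encoder: tuple[float, float] = (0.0, 0.0)
    L2_decoder: tuple[float, float] = (0.0, 0.0)
    L2_classifier: tuple[float, ...] = ()
    L2_trained_effect: float = 0.0
    total: float = 0.0

    def as_dict(self) -> dict[str, float]:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                for i, x in enumerate(v):
                    out[f"{f.name}_{i}"] = float(x)
            else:
                out[f.name] = float(v)
        return out


def sample_prior(n: int, latent_dim: int, rng: np.random.Generator) -> np.ndarray:
    """Reference embeddings v_i ~ Uniform[0, 1] per latent coordinate."""
    return rng.uniform(0.0, 1.0, size=(n, latent_dim))


def prior_loss(discr2_scores_v, discr2_scores_z):
    """Mean over the batch of log D(v_i) + log(1 - D(z_g_i)) (natural log)."""
    sv, tv = _as_tensor(discr2_scores_v)
    sz, tz = _as_tensor(discr2_scores_z)
    if sv.data.size != sz.data.size:
        raise ValueError("score lists must have equal length")
    for s in (sv.data, sz.data):
        if np.any(s <= 0.0) or np.any(s >= 1.0):
            raise ValueError("discriminator scores must lie strictly in (0, 1)")
    out = (sv.log() + (1.0 - sz).log()).mean()
    return _ret(out, tv or tz)


def mi_loss(pair_scores, mask):
    """Jensen-Shannon MI bound terms over a batch's mask of positives.

    E_p averages ln2 - softplus(-D) over positive pairs; E_q averages
    softplus(-D) + D - ln2 over off-diagonal negative pairs (self-pairs are
    excluded from the negatives); the loss is -(E_p - E_q).  Returns
    ``(L_MI, E_p, E_q)``.
    """
    D, is_t = _as_tensor(pair_scores)
    mask = np.asarray(mask, dtype=float)
    if mask.shape != D.data.shape:
        raise ValueError("mask and score matrix shapes differ")
    if not np.all((mask == 0) | (mask == 1)):
        raise ValueError("mask must be binary")
    off_diag = 1.0 - np.eye(mask.shape[0])
    neg = (1.0 - mask) * off_diag
    n_pos, n_neg = mask.sum(), neg.sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("batch mask has no positive (or no negative) pairs; "
                         "skip the MI term for this batch")
    sp_negD = softplus(-D)
    E_p = ((_LN2 - sp_negD) * Tensor(mask)).sum() * (1.0 / n_pos)
    E_q = ((sp_negD + D - _LN2) * Tensor(neg)).sum() * (1.0 / n_neg)
    L_MI = -(E_p - E_q)
    if is_t:
        return L_MI, E_p, E_q
    return L_MI.item(), E_p.item(), E_q.item()


def pair_alignment_losses(Z, positive_pairs, squared: bool = False):
    """(L_distance, L_cosine): mean Euclidean distance (squared by flag) and
    mean cosine similarity over positive pairs.  The cosine term is
    *subtracted* in the total loss, i.e. maximized."""
    Zt, is_t = _as_tensor(Z)
    pairs = list(positive_pairs)
    if not pairs:
        raise ValueError("at least one positive pair is required")
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    norms = np.linalg.norm(Zt.data, axis=1)
    if np.any(norms[ii] == 0) or np.any(norms[jj] == 0):
        raise ValueError("zero-norm embedding in a positive pair: cosine undefined")
    A, B = Zt[ii], Zt[jj]
    diff = A - B
    sq = (diff**2).sum(axis=1)
    dist = sq if squared else (sq + 1e-12) ** 0.5
    L_distance = dist.mean()
    dot = (A * B).sum(axis=1)
    na = ((A**2).sum(axis=1)) ** 0.5
    nb = ((B**2).sum(axis=1)) ** 0.5
    L_cosine = (dot / (na * nb)).mean()
    if is_t:
        return L_distance, L_cosine
    return L_distance.item(), L_cosine.item()


def recon_loss_mse(X, X_hat):
    """Sum of squared errors per sample, averaged across samples."""
    Xt, tx = _as_tensor(X)
    Xh, th = _as_tensor(X_hat)
    if Xt.data.shape != Xh.data.shape:
        raise ValueError("shape mismatch between data and reconstruction")
    n = Xt.data.shape[0] if Xt.data.ndim > 1 else 1
    out = ((Xt - Xh) ** 2).sum() * (1.0 / n)
    return _ret(out, tx or th)


def recon_loss_nb(counts, mean, dispersion):
    """Negative-binomial negative log-likelihood, summed per sample and
    averaged across samples.

    Parameterization: mean mu > 0 and inverse-dispersion theta > 0 with
    Var = mu + mu^2/theta;
    log pmf(k) = lgamma(k+theta) - lgamma(theta) - lgamma(k+1)
                 + theta log(theta/(theta+mu)) + k log(mu/(theta+mu)).
    """
    k = np.asarray(counts, dtype=float)
    if np.any(k < 0) or not np.allclose(k, np.round(k)):
        raise ValueError("counts must be non-negative integers")
    mu, tm = _as_tensor(mean)
    th, tt = _as_tensor(dispersion)
    if np.any(mu.data <= 0) or np.any(th.data <= 0):
        raise ValueError("mean and dispersion must be positive")
    from scipy.special import gammaln

    kt = Tensor(k)
    log_theta_mu = (th + mu).log()
    ll = ((kt + th).lgamma() - th.lgamma() - Tensor(gammaln(k + 1.0))
          + th * (th.log() - log_theta_mu) + kt * (mu.log() - log_theta_mu))
    n = k.shape[0] if k.ndim > 1 else 1
    out = -(ll.sum()) * (1.0 / n)
    return _ret(out, tm or tt)


def classifier_entropy(probs, labels):
    """Mean cross-entropy (natural log) between predicted class probabilities
    and integer labels."""
    P, is_t = _as_tensor(probs)
    labels = np.asarray(labels, dtype=int)
    n, k = P.data.shape
    if labels.shape[0] != n:
        raise ValueError("labels length must match probability rows")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label index out of range")
    picked = P[(np.arange(n), labels)]
    out = -(picked.log().mean())
    return _ret(out, is_t)


def l2_penalty(params) -> "Tensor | float":
    """Sum of squares of the given parameter tensors/arrays."""
    total = None
    any_t = False
    for p in params:
        t, it = _as_tensor(p)
        any_t = any_t or it
        term = (t**2).sum()
        total = term if total is None else total + term
    if total is None:
        total = Tensor(0.0)
    return _ret(total, any_t)


def total_loss(parts: LossBreakdown, w: LossWeights, variant: str = "v1"):
    """Weighted combination of the parts.

    basic = l_recon*L_recon + l_distance*L_distance + l_MI*L_MI
            + l_prior*L_prior + sum_i l_enc_i*L2_enc_i + sum_i l_dec_i*L2_dec_i
            + sum_i l_L2class_i*L2_class_i + sum_i l_class_i*entropy_i
            - l_cosine*L_cosine
    v2 adds  - l_adverse*entropy_adverse + l_trained_effect*L2_trained_effect.
    v3 carries its system classifier inside the entropy_i sum.
    """
    w.validate()
    total = (w.recon * parts.L_recon + w.distance * parts.L_distance
             + w.mi * parts.L_MI + w.prior * parts.L_prior
             - w.cosine * parts.L_cosine)
    for lam, val in zip(w.enc, parts.L2_encoder):
        total = total + lam * val
    for lam, val in zip(w.dec, parts.L2_decoder):
        total = total + lam * val
    n_class = len(parts.entropy)
    l2c = w.l2_class if w.l2_class else (1.0,) * len(parts.L2_classifier)
    lcl = w.classifier if w.classifier else (1.0,) * n_class
    if len(l2c) < len(parts.L2_classifier) or len(lcl) < n_class:
        raise ValueError("fewer classifier weights than classifier terms")
    for lam, val in zip(l2c, parts.L2_classifier):
        total = total + lam * val
    for lam, val in zip(lcl, parts.entropy):
        total = total + lam * val
    if variant == "v2":
        total = total - w.adverse * parts.entropy_adverse \
            + w.trained_effect * parts.L2_trained_effect
    return total
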