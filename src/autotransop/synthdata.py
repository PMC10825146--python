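"""Synthetic two-system datasets with shared condition effects.

The generator emulates the statistical structure the translation framework
assumes: each experimental condition c has a true latent state u_c drawn once;
each biological system s observes it through its own feature map,

    x = W_s g(u_c) + b_s + eps,   eps ~ Normal(0, noise_sd^2),

with disjoint feature spaces across systems (no 1-to-1 homology), an additive
system effect b_s, and optional nonlinearity g.  A chosen fraction of
conditions is observed in both systems ("paired conditions"); those anchors
are what the framework uses to align its global latent space.  Count mode
replaces the Gaussian observation with negative-binomial draws; serology mode
replaces conditions with per-sample protection labels and plants a known set
of protection-informative features in each species.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import ConditionKey, OmicsDataset, SampleRecord

__all__ = ["SynthConfig", "generate_paired_bulk", "generate_counts", "generate_serology"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    Defaults describe the benchmark used throughout the test-suite: 300
    conditions, half of them observed in both systems, 50/80 disjoint
    features driven by a 10-dimensional true latent state, unit-scale
    system offsets and measurement noise about a quarter of the signal
    scale (profiles are O(1), z-score-like).
    """

    n_conditions: int = 300
    paired_fraction: float = 0.5
    n_features_a: int = 50
    n_features_b: int = 80
    latent_dim_true: int = 10
    system_effect_scale: float = 1.0
    noise_sd: float = 0.25
    nonlinearity: str = "none"  # {"none", "tanh"}
    mode: str = "zscore"  # {"zscore", "count", "serology"}
    nb_dispersion: float = 3.0
    protection_effect: float = 1.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction must be in [0, 1]")
        if self.nonlinearity not in ("none", "tanh"):
            raise ValueError("nonlinearity must be 'none' or 'tanh'")
        if self.mode not in ("zscore", "count", "serology"):
            raise ValueError("mode must be one of zscore/count/serology")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def _g(cfg: SynthConfig, u: np.ndarray) -> np.ndarray:
    return np.tanh(u) if cfg.nonlinearity == "tanh" else u


def _loading(rng: np.random.Generator, d: int, p: int) -> np.ndarray:
    # 1/sqrt(d) scaling keeps outputs O(1)
    return rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, p))


def generate_paired_bulk(cfg: SynthConfig):
    """Two-system bulk datasets plus the generating ground truth.

    Returns ``(ds_a, ds_b, truth)`` where ``truth`` holds the condition
    latents ``u`` (keyed by condition name), the loadings ``W_a/W_b``, system
    offsets ``b_a/b_b`` and the list of shared condition names.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.latent_dim_true
    names = [f"cond{i:04d}" for i in range(cfg.n_conditions)]
    U = rng.normal(size=(cfg.n_conditions, d))
    W = {"A": _loading(rng, d, cfg.n_features_a), "B": _loading(rng, d, cfg.n_features_b)}
    b = {"A": rng.normal(0.0, cfg.system_effect_scale, size=cfg.n_features_a),
         "B": rng.normal(0.0, cfg.system_effect_scale, size=cfg.n_features_b)}

    n_shared = int(round(cfg.paired_fraction * cfg.n_conditions))
    shared = names[:n_shared]
    rest = names[n_shared:]
    only_a = rest[::2]
    only_b = rest[1::2]
    cond_of = {"A": shared + only_a, "B": shared + only_b}

    datasets = {}
    for sys_label, p in (("A", cfg.n_features_a), ("B", cfg.n_features_b)):
        rows, samples = [], []
        for cname in cond_of[sys_label]:
            u = U[names.index(cname)]
            clean = _g(cfg, u) @ W[sys_label] + b[sys_label]
            for r in range(cfg.n_replicates):
                x = clean + rng.normal(0.0, cfg.noise_sd, size=p)
                rows.append(x)
                samples.append(SampleRecord(
                    sample_id=f"{sys_label}_{cname}_r{r}", system=sys_label,
                    condition=ConditionKey(cname), tas=1.0,
                    n_replicates=cfg.n_replicates, n_passed_qc=cfg.n_replicates))
        datasets[sys_label] = OmicsDataset(
            matrix=np.asarray(rows), samples=samples,
            feature_ids=[f"{sys_label.lower()}_gene{j}" for j in range(p)], mode="zscore")

    truth = {"u": {n: U[i] for i, n in enumerate(names)}, "W_a": W["A"], "W_b": W["B"],
             "b_a": b["A"], "b_b": b["B"], "shared_conditions": shared}
    return datasets["A"], datasets["B"], truth


def generate_counts(cfg: SynthConfig) -> OmicsDataset:
    """Negative-binomial count dataset for one system.

    Per-gene means come from the bulk construction, exponentiated
    (mu = exp(W g(u) + b)); counts are drawn from a gamma-Poisson mixture
    with inverse-dispersion theta = ``nb_dispersion`` so that
    Var = mu + mu^2/theta.  Cell-type labels are attached round-robin.
    """
    if cfg.mode != "count":
        raise ValueError("generate_counts requires cfg.mode == 'count'")
    bulk_cfg = replace(cfg, mode="zscore")
    ds_a, _, truth = generate_paired_bulk(bulk_cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    # clean per-sample means; noise enters only through the NB draw
    clean = np.asarray([
        _g(cfg, truth["u"][s.condition.perturbagen]) @ truth["W_a"] + truth["b_a"]
        for s in ds_a.samples
    ])
    mu = np.exp(np.clip(clean, -10, 6))
    counts = sample_nb(mu, cfg.nb_dispersion, rng)
    celltypes = ["type%d" % (i % 3) for i in range(len(ds_a.samples))]
    samples = [replace_celltype(s, ct) for s, ct in zip(ds_a.samples, celltypes)]
    return OmicsDataset(matrix=counts, samples=samples,
                        feature_ids=ds_a.feature_ids, mode="count")


def sample_nb(mu: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and variance mu + mu^2/theta (mu=0 -> 0)."""
    if theta <= 0:
        raise ValueError("dispersion must be positive")
    lam = rng.gamma(shape=theta, scale=np.asarray(mu) / theta)
    return rng.poisson(lam)


def replace_celltype(s: SampleRecord, ct: str) -> SampleRecord:
    return SampleRecord(sample_id=s.sample_id, system=s.system, condition=s.condition,
                        n_replicates=s.n_replicates, n_passed_qc=s.n_passed_qc,
                        is_outlier=s.is_outlier, tas=s.tas, celltype=ct)


def generate_serology(cfg: SynthConfig):
    """Two-species serology panels with a planted protection factor.

    Each species observes ``n_conditions`` subjects (exactly half protected).
    A dedicated protection latent shifts a planted subset (20%) of features in
    each species by ``protection_effect``; the remaining latent variation is
    nuisance.  Feature spaces are disjoint.  Returns
    ``(ds_human, ds_nhp, truth)`` with the planted feature names per species.
    """
    if cfg.mode != "serology":
        raise ValueError("generate_serology requires cfg.mode == 'serology'")
    rng = np.random.default_rng(cfg.seed)
    d = cfg.latent_dim_true
    datasets, planted = {}, {}
    for species, p in (("human", cfg.n_features_a), ("nhp", cfg.n_features_b)):
        n = cfg.n_conditions
        n_prot = n // 2
        prot = np.array([1] * n_prot + [0] * (n - n_prot))
        rng.shuffle(prot)
        vacc = rng.integers(0, 2, size=n)
        W = _loading(rng, d, p)
        b = rng.normal(0.0, cfg.system_effect_scale, size=p)
        n_planted = max(1, p // 5)
        idx = rng.choice(p, size=n_planted, replace=False)
        w_prot = np.zeros(p)
        w_prot[idx] = 1.0
        U = rng.normal(size=(n, d))
        clean = _g(cfg, U) @ W + b
        X = clean + np.outer(prot, cfg.protection_effect * w_prot)
        X = X + rng.normal(0.0, cfg.noise_sd, size=X.shape)
        feats = [f"{species}_feat{j}" for j in range(p)]
        samples = [SampleRecord(
            sample_id=f"{species}_s{i}", system=species, condition=ConditionKey(f"subj{i}"),
            protection="protected" if prot[i] else "unprotected",
            vaccination="vaccinated" if vacc[i] else "placebo") for i in range(n)]
        datasets[species] = OmicsDataset(matrix=X, samples=samples,
                                         feature_ids=feats, mode="serology")
        planted[species] = [feats[j] for j in sorted(idx)]
    truth = {"planted_features": planted}
    return datasets["human"], datasets["nhp"], truth
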