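"""Training orchestration for the three framework variants, cross-validation
folds, and the globality evaluation.

All parts of the framework are trained simultaneously with one adaptive
optimizer; variant v2 additionally alternates framework steps with steps that
update only the adverse system classifier, and the prior discriminator always
gets its own alternating update so that it keeps discriminating embeddings
from the uniform reference.  Batches are sampled condition-wise so that both
members of a paired condition co-occur in the batch (the mask of positives is
built per batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, cat, no_grad
from .losses import (LossBreakdown, LossWeights, classifier_entropy, l2_penalty,
                     mi_loss, pair_alignment_losses, prior_loss, recon_loss_mse,
                     recon_loss_nb, sample_prior)
from .metrics import classification_metrics, pearson_global
from .model import TranslatorModel
from .nn import SGD, Adam
from .preprocess import (OmicsDataset, PairIndex, build_pair_index,
                         combine_datasets, log_transform_counts)

__all__ = ["ModelConfig", "FoldPlan", "make_folds", "train",
           "pretrain_adverse", "evaluate_globality", "translation_benchmark"]

_TABLE_DEFAULTS = {
    # study mode: (latent, enc hidden, dec hidden, batch, epochs, lr)
    "l1000_978": (292, [640, 384], [384, 640], 512, 1000, 1e-3),
    "l1000_10086": (1024, [4096, 2048, 1024, 512], [512, 1024, 2048, 4096], 512, 1000, 1e-3),
    "lung_fibrosis": (512, [4096, 2048, 1024, 512], [512, 768, 2048, 4096], 1024, 200, 1e-3),
    "serology": (32, [64], [64], 50, 2000, 1e-3),
}


@dataclass
class ModelConfig:
    """Architecture + optimization settings.

    ``for_study_mode`` returns the published defaults per study mode (e.g.
    978-gene mode: latent 292, encoder [640, 384], batch 512, 1000 epochs,
    learning rate 0.001; serology: latent 32, batch 50, 2000 epochs).
    """

    latent_dim: int = 16
    encoder_hidden: tuple[int, ...] = (64,)
    decoder_hidden: tuple[int, ...] = (64,)
    batch_size: int = 128
    epochs: int = 100
    learning_rate: float = 1e-3
    dropout: float = 0.1
    variant: str = "v1"
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    optimizer: str = "adam"  # or "sgd"
    count_mode: bool = False
    mi_hidden: int = 64
    prior_hidden: int = 64
    adverse_hidden: tuple[int, ...] = (32,)
    classifier_specs: dict = field(default_factory=dict)  # name -> (hidden, label_key)
    adverse_pretrain_frac: float = 0.1
    adverse_ratio: int = 1  # classifier steps per framework step
    prior_sign: float = 1.0
    covariate_mode: str = "additive"
    use_celltype_vectors: bool = False

    @classmethod
    def for_study_mode(cls, mode: str, **overrides) -> "ModelConfig":
        latent, enc, dec, batch, epochs, lr = _TABLE_DEFAULTS[mode]
        base = cls(latent_dim=latent, encoder_hidden=tuple(enc), decoder_hidden=tuple(dec),
                   batch_size=batch, epochs=epochs, learning_rate=lr)
        return replace(base, **overrides)


@dataclass
class FoldPlan:
    """Condition-keyed cross-validation folds.

    Every sample appears in exactly one validation fold, and a condition's
    samples (in both systems) always share a fold, so paired conditions are
    hidden from training together.
    """

    k: int
    fold_of_condition: dict
    fold_of_sample: dict[str, np.ndarray]  # system label -> fold id per sample

    def val_indices(self, system: str, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample[system] == fold)

    def train_indices(self, system: str, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample[system] != fold)


def make_folds(data_a: OmicsDataset, data_b: OmicsDataset, k: int = 10,
               seed: int = 0) -> FoldPlan:
    conds = sorted({s.condition.as_tuple() for s in data_a.samples}
                   | {s.condition.as_tuple() for s in data_b.samples})
    if k > len(conds):
        raise ValueError(f"k={k} exceeds the number of conditions ({len(conds)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(conds))
    fold_of_condition = {conds[idx]: i % k for i, idx in enumerate(order)}
    fold_of_sample = {}
    for label, ds in (("A", data_a), ("B", data_b)):
        fold_of_sample[label] = np.array(
            [fold_of_condition[s.condition.as_tuple()] for s in ds.samples])
    return FoldPlan(k=k, fold_of_condition=fold_of_condition, fold_of_sample=fold_of_sample)


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

_LABEL_KEYS = ("system", "celltype", "protection", "vaccination")


def _labels_for(samples, key: str) -> tuple[np.ndarray, list]:
    vals = []
    for s in samples:
        v = getattr(s, key, None)
        vals.append("?" if v is None else str(v))
    classes = sorted(set(vals))
    return np.array([classes.index(v) for v in vals]), classes


class _BatchPlan:
    """Condition-wise batch sampler over the concatenated (A then B) dataset."""

    def __init__(self, ds_a: OmicsDataset, ds_b: OmicsDataset, batch_size: int):
        self.offset_b = ds_a.n_samples
        self.by_condition: dict[tuple, list[int]] = {}
        for i, s in enumerate(ds_a.samples):
            self.by_condition.setdefault(s.condition.as_tuple(), []).append(i)
        for j, s in enumerate(ds_b.samples):
            self.by_condition.setdefault(s.condition.as_tuple(), []).append(self.offset_b + j)
        self.conditions = sorted(self.by_condition)
        self.batch_size = batch_size

    def _valid(self, batch: list[int]):
        # batch-norm needs >= 2 rows per system; drop a singleton side
        a = [i for i in batch if i < self.offset_b]
        b = [i for i in batch if i >= self.offset_b]
        if len(a) == 1:
            a = []
        if len(b) == 1:
            b = []
        out = a + b
        return out if len(out) >= 2 else None

    def batches(self, rng: np.random.Generator):
        order = rng.permutation(len(self.conditions))
        batch: list[int] = []
        for idx in order:
            batch.extend(self.by_condition[self.conditions[idx]])
            if len(batch) >= self.batch_size:
                checked = self._valid(batch)
                if checked:
                    yield checked
                batch = []
        checked = self._valid(batch)
        if checked:
            yield checked


def _clamp_scores(t: Tensor, eps: float = 1e-7) -> Tensor:
    np.clip(t.data, eps, 1.0 - eps, out=t.data)
    return t


def _build_model(ds_a: OmicsDataset, ds_b: OmicsDataset, cfg: ModelConfig) -> TranslatorModel:
    systems = ["A", "B"]
    celltypes = sorted({s.celltype for s in list(ds_a.samples) + list(ds_b.samples)
                        if s.celltype is not None})
    specs = {}
    for name, (hidden, key) in cfg.classifier_specs.items():
        _, classes = _labels_for(list(ds_a.samples) + list(ds_b.samples), key)
        specs[name] = (tuple(hidden), len(classes))
    model = TranslatorModel(
        systems, {"A": ds_a.n_features, "B": ds_b.n_features},
        cfg.latent_dim, cfg.encoder_hidden, cfg.decoder_hidden,
        variant=cfg.variant, dropout=cfg.dropout, count_mode=cfg.count_mode,
        mi_hidden=cfg.mi_hidden, prior_hidden=cfg.prior_hidden,
        classifier_specs=specs, adverse_hidden=cfg.adverse_hidden,
        celltypes=celltypes if cfg.use_celltype_vectors else None,
        covariate_mode=cfg.covariate_mode, seed=cfg.seed)
    model.feature_ids = {"A": list(ds_a.feature_ids), "B": list(ds_b.feature_ids)}
    return model


def _framework_params(model: TranslatorModel):
    """All parameters except the adverse classifier and prior discriminator."""
    excluded = set()
    if model.variant == "v2":
        excluded |= {id(p) for p in model.adverse_classifier.parameters()}
    excluded |= {id(p) for p in model.prior_discriminator.parameters()}
    return [p for p in model.parameters() if id(p) not in excluded]


def _encoder_inputs(ds: OmicsDataset, count_mode: bool) -> np.ndarray:
    return log_transform_counts(ds.matrix) if count_mode else np.asarray(ds.matrix, float)


def _forward_losses(model, batch, Xa, Xb, Ya, Yb, offset_b, pairs_set, labels, cfg,
                    rng, w: LossWeights, include_recon=True, include_classifiers=True,
                    include_adverse=True):
    """One batch forward pass; returns (total Tensor, LossBreakdown)."""
    idx_a = [i for i in batch if i < offset_b]
    idx_b = [i - offset_b for i in batch if i >= offset_b]
    zs, sys_rows = [], []
    if idx_a:
        zs.append(model.encode(Tensor(Xa[idx_a]), "A"))
        sys_rows += [("A", i) for i in idx_a]
    if idx_b:
        zs.append(model.encode(Tensor(Xb[idx_b]), "B"))
        sys_rows += [("B", j + offset_b) for j in idx_b]
    z = cat(zs, axis=0) if len(zs) > 1 else zs[0]
    batch_order = [g for _, g in sys_rows]
    n = len(batch_order)

    parts = LossBreakdown()
    total = Tensor(0.0)

    # reconstruction
    if include_recon:
        recon_terms = []
        pos = 0
        for sys_label, idx, Y in (("A", idx_a, Ya), ("B", idx_b, Yb)):
            if not idx:
                continue
            z_sys = z[np.arange(pos, pos + len(idx))]
            pos += len(idx)
            z_dec = model.compose(z_sys, sys_label) if model.variant == "v2" else z_sys
            out = model.decode(z_dec, sys_label)
            if cfg.count_mode:
                mean_t, disp_t = out[0], out[1]
                recon_terms.append(recon_loss_nb(Y[idx], mean_t, disp_t))
            else:
                recon_terms.append(recon_loss_mse(Tensor(Y[idx]), out))
        n_a, n_b = len(idx_a), len(idx_b)
        L_recon = sum(r * (m / n) for r, m in zip(recon_terms, [x for x in (n_a, n_b) if x]))
        parts.L_recon = L_recon.item()
        total = total + w.recon * L_recon

    # alignment + MI over in-batch positives
    local_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                   if (batch_order[i], batch_order[j]) in pairs_set]
    if local_pairs:
        L_dist, L_cos = pair_alignment_losses(z, local_pairs)
        parts.L_distance, parts.L_cosine = L_dist.item(), L_cos.item()
        total = total + w.distance * L_dist - w.cosine * L_cos
        mask = np.zeros((n, n))
        for i, j in local_pairs:
            mask[i, j] = mask[j, i] = 1.0
        if mask.sum() and (1 - mask - np.eye(n)).sum() > 0:
            D = model.mi_estimator(z)
            L_MI, E_p, E_q = mi_loss(D, mask)
            parts.L_MI, parts.E_p, parts.E_q = L_MI.item(), E_p.item(), E_q.item()
            total = total + w.mi * L_MI

    # prior term (encoder side; sign flag per configuration)
    v = sample_prior(n, model.latent_dim, rng)
    with no_grad():
        d_v = model.prior_discriminator(Tensor(v))
    d_z = _clamp_scores(model.prior_discriminator(z))
    L_prior = prior_loss(_clamp_scores(Tensor(d_v.data)), d_z)
    parts.L_prior = L_prior.item()
    total = total + w.prior * cfg.prior_sign * L_prior

    # task classifiers
    if include_classifiers and model.classifiers:
        ents, l2cs = [], []
        for name, clf in model.classifiers.items():
            key = cfg.classifier_specs.get(name, ((), "system"))[1]
            y = labels[key][batch_order]
            z_in = z
            if model.variant == "v2":
                # classify in the composed space
                comp = []
                pos = 0
                for sys_label, idx in (("A", idx_a), ("B", idx_b)):
                    if idx:
                        comp.append(model.compose(z[np.arange(pos, pos + len(idx))], sys_label))
                        pos += len(idx)
                z_in = cat(comp, axis=0) if len(comp) > 1 else comp[0]
            probs = _clamp_scores(clf.proba(z_in))
            ent = classifier_entropy(probs, y)
            ents.append(ent)
            l2cs.append(l2_penalty(clf.parameters()))
        lcl = w.classifier if w.classifier else (1.0,) * len(ents)
        l2c = w.l2_class if w.l2_class else (1.0,) * len(l2cs)
        for lam, e in zip(lcl, ents):
            total = total + lam * e
        for lam, r in zip(l2c, l2cs):
            total = total + lam * r
        parts.entropy = tuple(e.item() for e in ents)
        parts.L2_classifier = tuple(r.item() for r in l2cs)

    # adverse classifier penalty (v2): encoder is rewarded for fooling it;
    # the adverse parameters are simply not in the framework optimizer
    if model.variant == "v2" and include_adverse:
        probs = _clamp_scores(model.adverse_classifier.proba(z))
        ent_adv = classifier_entropy(probs, labels["system"][batch_order])
        parts.entropy_adverse = ent_adv.item()
        total = total - w.adverse * ent_adv
        vec_params = (list(model.system_vectors.values())
                      + list(getattr(model, "celltype_vectors", {}).values())) \
            if model.covariate_mode == "additive" else \
            [p for net in model.system_nets.values() for p in net.parameters()]
        l2_te = l2_penalty(vec_params)
        parts.L2_trained_effect = l2_te.item()
        total = total + w.trained_effect * l2_te

    # L2 of encoders/decoders
    l2_enc = [l2_penalty(model.encoders[s].parameters()) for s in model.systems]
    l2_dec = [l2_penalty(model.decoders[s].parameters()) for s in model.systems]
    for lam, t in zip(w.enc, l2_enc):
        total = total + lam * t
    for lam, t in zip(w.dec, l2_dec):
        total = total + lam * t
    parts.L2_encoder = tuple(t.item() for t in l2_enc)
    parts.L2_decoder = tuple(t.item() for t in l2_dec)
    parts.total = total.item()
    return total, parts, z, batch_order


def _discr2_step(model, z_data: np.ndarray, rng, opt) -> None:
    """Prior discriminator's own update: learn to tell prior from embeddings."""
    v = sample_prior(z_data.shape[0], model.latent_dim, rng)
    d_v = _clamp_scores(model.prior_discriminator(Tensor(v)))
    d_z = _clamp_scores(model.prior_discriminator(Tensor(z_data)))
    loss = -prior_loss(d_v, d_z)
    opt.zero_grad()
    loss.backward()
    opt.step()


def _adverse_step(model, z_data: np.ndarray, y: np.ndarray, opt) -> None:
    probs = _clamp_scores(model.adverse_classifier.proba(Tensor(z_data)))
    loss = classifier_entropy(probs, y)
    opt.zero_grad()
    loss.backward()
    opt.step()


def _make_optimizer(params, cfg: ModelConfig):
    if cfg.optimizer == "sgd":
        return SGD(params, lr=cfg.learning_rate)
    return Adam(params, lr=cfg.learning_rate)


# ---------------------------------------------------------------------------
# public training entry points
# ---------------------------------------------------------------------------

def train(data_a: OmicsDataset, data_b: OmicsDataset, pairs: Optional[PairIndex],
          cfg: ModelConfig, model: Optional[TranslatorModel] = None,
          ) -> tuple[TranslatorModel, list[LossBreakdown]]:
    """Train a TranslatorModel; returns (model, per-epoch loss trace).

    ``pairs`` indexes the concatenated sample list (A first, then B); when
    None it is built from the data.  Training is seed-deterministic given
    fixed thread settings.
    """
    if cfg.batch_size < 2:
        raise ValueError("batch size must be at least 2 (batch normalization)")
    align_on = (cfg.weights.distance > 0 or cfg.weights.cosine > 0 or cfg.weights.mi > 0)
    if pairs is None:
        pairs = build_pair_index(combine_datasets(data_a, data_b))
    if align_on and not pairs.positive_pairs:
        raise ValueError("alignment losses are active but there are no positive pairs")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = _build_model(data_a, data_b, cfg)
    if cfg.variant == "v2" and cfg.adverse_pretrain_frac > 0:
        pretrain_adverse(model, data_a, data_b, pairs, cfg,
                         epochs=max(1, int(cfg.adverse_pretrain_frac * cfg.epochs)))

    Xa = _encoder_inputs(data_a, cfg.count_mode)
    Xb = _encoder_inputs(data_b, cfg.count_mode)
    Ya, Yb = np.asarray(data_a.matrix, float), np.asarray(data_b.matrix, float)
    all_samples = list(data_a.samples) + list(data_b.samples)
    labels = {key: _labels_for(all_samples, key)[0] for key in _LABEL_KEYS}
    pairs_set = {(a, b) for a, b in pairs.positive_pairs}
    pairs_set |= {(b, a) for a, b in pairs.positive_pairs}
    plan = _BatchPlan(data_a, data_b, cfg.batch_size)

    main_opt = _make_optimizer(_framework_params(model), cfg)
    d2_opt = _make_optimizer(model.prior_discriminator.parameters(), cfg)
    adv_opt = (_make_optimizer(model.adverse_classifier.parameters(), cfg)
               if cfg.variant == "v2" else None)

    trace: list[LossBreakdown] = []
    model.train()
    for _epoch in range(cfg.epochs):
        epoch_parts: list[LossBreakdown] = []
        for batch in plan.batches(rng):
            total, parts, z, order = _forward_losses(
                model, batch, Xa, Xb, Ya, Yb, data_a.n_samples, pairs_set,
                labels, cfg, rng, cfg.weights)
            main_opt.zero_grad()
            total.backward()
            main_opt.step()
            z_frozen = z.data.copy()
            _discr2_step(model, z_frozen, rng, d2_opt)
            if cfg.variant == "v2":
                for _ in range(cfg.adverse_ratio):
                    _adverse_step(model, z_frozen, labels["system"][order], adv_opt)
            epoch_parts.append(parts)
        trace.append(_mean_breakdown(epoch_parts, cfg))
    model.eval()
    return model, trace


def _mean_breakdown(parts: list[LossBreakdown], cfg: ModelConfig) -> LossBreakdown:
    if not parts:
        return LossBreakdown()
    keys = parts[0].as_dict().keys()
    avg = {k: float(np.mean([p.as_dict()[k] for p in parts])) for k in keys}
    out = LossBreakdown()
    for f in ("L_recon", "L_distance", "L_cosine", "L_MI", "E_p", "E_q", "L_prior",
              "entropy_adverse", "L2_trained_effect", "total"):
        setattr(out, f, avg.get(f, 0.0))
    out.entropy = tuple(avg[k] for k in sorted(avg) if k.startswith("entropy_")
                        and k != "entropy_adverse")
    out.L2_encoder = (avg["L2_encoder_0"], avg["L2_encoder_1"])
    out.L2_decoder = (avg["L2_decoder_0"], avg["L2_decoder_1"])
    out.L2_classifier = tuple(avg[k] for k in sorted(avg) if k.startswith("L2_classifier_"))
    return out


def pretrain_adverse(model: TranslatorModel, data_a: OmicsDataset, data_b: OmicsDataset,
                     pairs: Optional[PairIndex], cfg: ModelConfig, epochs: int,
                     ) -> TranslatorModel:
    """Pre-train encoders + discriminators + adverse classifier (v2 only).

    Decoders and task classifiers are untouched; after pretraining the adverse
    classifier can already tell the systems apart in the global space.
    """
    if model.variant != "v2":
        raise ValueError("adverse pretraining applies to variant v2 only")
    if epochs == 0:
        return model
    if pairs is None:
        pairs = build_pair_index(combine_datasets(data_a, data_b))
    rng = np.random.default_rng(cfg.seed + 1)
    Xa = _encoder_inputs(data_a, cfg.count_mode)
    Xb = _encoder_inputs(data_b, cfg.count_mode)
    Ya, Yb = np.asarray(data_a.matrix, float), np.asarray(data_b.matrix, float)
    all_samples = list(data_a.samples) + list(data_b.samples)
    labels = {key: _labels_for(all_samples, key)[0] for key in _LABEL_KEYS}
    pairs_set = {(a, b) for a, b in pairs.positive_pairs}
    pairs_set |= {(b, a) for a, b in pairs.positive_pairs}
    plan = _BatchPlan(data_a, data_b, cfg.batch_size)

    enc_params = [p for s in model.systems for p in model.encoders[s].parameters()]
    enc_params += model.mi_estimator.parameters()
    enc_opt = _make_optimizer(enc_params, cfg)
    d2_opt = _make_optimizer(model.prior_discriminator.parameters(), cfg)
    adv_opt = _make_optimizer(model.adverse_classifier.parameters(), cfg)

    model.train()
    for _epoch in range(epochs):
        for batch in plan.batches(rng):
            total, parts, z, order = _forward_losses(
                model, batch, Xa, Xb, Ya, Yb, data_a.n_samples, pairs_set,
                labels, cfg, rng, cfg.weights,
                include_recon=False, include_classifiers=False, include_adverse=False)
            enc_opt.zero_grad()
            total.backward()
            enc_opt.step()
            z_frozen = z.data.copy()
            _discr2_step(model, z_frozen, rng, d2_opt)
            _adverse_step(model, z_frozen, labels["system"][order], adv_opt)
    return model


def evaluate_globality(model: TranslatorModel, data_a: OmicsDataset,
                       data_b: OmicsDataset, seed: int = 0,
                       count_mode: Optional[bool] = None) -> dict:
    """Probe how much system identity survives in each latent space.

    Fits a logistic-regression probe to classify the system from frozen
    embeddings, separately on the global space and (for v2) the composed
    space, with a held-out split; reports accuracy and F1 per space.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    cm = model.count_mode if count_mode is None else count_mode
    Xa = _encoder_inputs(data_a, cm)
    Xb = _encoder_inputs(data_b, cm)
    report: dict = {}
    spaces = {"global": False}
    if model.variant == "v2":
        spaces["composed"] = True
    y = np.array([0] * data_a.n_samples + [1] * data_b.n_samples)
    for name, composed in spaces.items():
        Z = np.vstack([model.embed(Xa, "A", composed=composed),
                       model.embed(Xb, "B", composed=composed)])
        Ztr, Zte, ytr, yte = train_test_split(Z, y, test_size=0.3, random_state=seed,
                                              stratify=y)
        probe = LogisticRegression(max_iter=2000).fit(Ztr, ytr)
        report[name] = classification_metrics(probe.predict(Zte), yte, 2)
    return report


def translation_benchmark(model: TranslatorModel, data_a: OmicsDataset,
                          data_b: OmicsDataset, test_conditions: Sequence,
                          count_mode: bool = False) -> dict:
    """Translation fidelity on held-out paired conditions, against the
    no-model baseline.

    The model translates each held-out source profile into the target feature
    space and is scored by global Pearson r against the observed target
    profile of the same condition.  The baseline uses the source profile
    itself as the prediction; with disjoint feature spaces this is evaluated
    on index-matched columns (the first min(p_A, p_B) features).
    """
    test_set = {t if isinstance(t, tuple) else (t, "", "") for t in test_conditions}
    idx_a = {s.condition.as_tuple(): i for i, s in enumerate(data_a.samples)}
    idx_b = {s.condition.as_tuple(): i for i, s in enumerate(data_b.samples)}
    common = sorted(set(idx_a) & set(idx_b) & test_set)
    if not common:
        raise ValueError("no shared test conditions between the systems")
    Xa = _encoder_inputs(data_a, count_mode)[np.array([idx_a[c] for c in common])]
    Yb = np.asarray(data_b.matrix, float)[np.array([idx_b[c] for c in common])]
    model.eval()
    with no_grad():
        pred = model.translate(Tensor(Xa), "A", "B")
        pred = pred[0].data if isinstance(pred, tuple) else pred.data
    r_model = pearson_global(pred, Yb)
    p = min(data_a.n_features, data_b.n_features)
    Xa_raw = np.asarray(data_a.matrix, float)[np.array([idx_a[c] for c in common])]
    r_direct = pearson_global(Xa_raw[:, :p], Yb[:, :p])
    return {"r_model": r_model, "r_direct": r_direct, "n_conditions": len(common)}
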