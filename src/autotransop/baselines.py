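"""Comparison methods: the DeepCellState-style shared-encoder autoencoder and
its three variations, the principal-component (TransCompR-style) translator,
the per-gene slope-1 penalized regression (FIT-style), and direct translation.

All of these require a shared (homolog-matched) feature space between the two
systems, unlike the main framework.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, no_grad
from .losses import recon_loss_mse
from .nn import Adam, Dropout, Linear, Module
from .preprocess import OmicsDataset, PairIndex, build_pair_index, combine_datasets

__all__ = [
    "DCSSpec",
    "DCSModel",
    "dcs_train",
    "dcs_translate",
    "TransCompRTranslator",
    "transcompr_fit",
    "transcompr_translate",
    "FITTranslator",
    "fit_fit",
    "fit_translate",
    "direct_translate",
]


def _check_shared_features(ds_a: OmicsDataset, ds_b: OmicsDataset):
    if list(ds_a.feature_ids) != list(ds_b.feature_ids):
        raise ValueError("this method depends on a 1-1 mapping: the two systems "
                         "must share one feature space")


# ---------------------------------------------------------------------------
# DeepCellState-style autoencoder
# ---------------------------------------------------------------------------

@dataclass
class DCSSpec:
    """Shared encoder + two decoders with input dropout and L1 latent penalty.

    variant 'original' keeps the additive skip connection from the
    input-dropout layer to the output layer; mod1 removes it; mod2 and mod3
    additionally penalize the latent distance of same-condition pairs, and
    mod2 also penalizes direct cross-system translation error.
    """

    variant: str = "original"
    latent_dim: int = 16
    encoder_hidden: tuple[int, ...] = (64,)
    decoder_hidden: tuple[int, ...] = (64,)
    input_dropout: float = 0.5
    l1_latent: float = 1e-4
    distance_weight: float = 1.0
    translation_weight: float = 1.0
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("original", "mod1", "mod2", "mod3"):
            raise ValueError("variant must be original/mod1/mod2/mod3")

    @property
    def has_skip(self) -> bool:
        return self.variant == "original"

    @property
    def has_distance(self) -> bool:
        return self.variant in ("mod2", "mod3")

    @property
    def has_translation_error(self) -> bool:
        return self.variant == "mod2"


class DCSModel(Module):
    """One shared encoder, two system decoders; leaky-ReLU hidden layers and a
    tanh output; optional linear skip path from the dropped input."""

    def __init__(self, n_features: int, systems: Sequence[str], spec: DCSSpec):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.systems = list(systems)
        self.input_drop = Dropout(spec.input_dropout, rng)
        sizes = [n_features] + list(spec.encoder_hidden)
        self.enc_layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.enc_out = Linear(sizes[-1], spec.latent_dim, rng)
        self.decoders = {}
        self.skips = {}
        dsizes = [spec.latent_dim] + list(spec.decoder_hidden)
        for s in systems:
            layers = [Linear(a, b, rng) for a, b in zip(dsizes[:-1], dsizes[1:])]
            layers.append(Linear(dsizes[-1], n_features, rng))
            self.decoders[s] = layers
            if spec.has_skip:
                self.skips[s] = Linear(n_features, n_features, rng)
        self.n_features = n_features

    def parameters(self):
        params = [p for l in self.enc_layers for p in l.parameters()]
        params += self.enc_out.parameters()
        for layers in self.decoders.values():
            for l in layers:
                params.extend(l.parameters())
        for skip in self.skips.values():
            params.extend(skip.parameters())
        return params

    def encode(self, x: Tensor, training: bool) -> tuple[Tensor, Tensor]:
        self.input_drop.training = training
        dropped = self.input_drop(x)
        h = dropped
        for l in self.enc_layers:
            h = l(h).leaky_relu()
        return self.enc_out(h).leaky_relu(), dropped

    def decode(self, z: Tensor, dropped: Tensor, system: str) -> Tensor:
        h = z
        layers = self.decoders[system]
        for l in layers[:-1]:
            h = l(h).leaky_relu()
        pre = layers[-1](h)
        if self.spec.has_skip:
            pre = pre + self.skips[system](dropped)
        return pre.tanh()

    def forward(self, x: Tensor, system: str, training: bool = False):
        z, dropped = self.encode(x, training)
        return self.decode(z, dropped, system), z


def dcs_train(data_a: OmicsDataset, data_b: OmicsDataset, spec: DCSSpec,
              pairs: Optional[PairIndex] = None) -> DCSModel:
    """Train a DeepCellState-style model on the concatenated systems."""
    _check_shared_features(data_a, data_b)
    if pairs is None:
        pairs = build_pair_index(combine_datasets(data_a, data_b))
    model = DCSModel(data_a.n_features, ["A", "B"], spec)
    rng = np.random.default_rng(spec.seed + 1)
    X = np.vstack([np.asarray(data_a.matrix, float), np.asarray(data_b.matrix, float)])
    system_of = np.array([0] * data_a.n_samples + [1] * data_b.n_samples)
    pair_arr = np.array(pairs.positive_pairs, dtype=int).reshape(-1, 2)
    opt = Adam(model.parameters(), lr=spec.learning_rate)
    n = X.shape[0]
    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, spec.batch_size):
            batch = order[lo: lo + spec.batch_size]
            if batch.size < 2:
                continue
            total = Tensor(0.0)
            zs = {}
            for s_id, s_label in ((0, "A"), (1, "B")):
                rows = batch[system_of[batch] == s_id]
                if rows.size == 0:
                    continue
                xt = Tensor(X[rows])
                out, z = model.forward(xt, s_label, training=True)
                total = total + recon_loss_mse(xt, out)
                total = total + spec.l1_latent * ((z * z + 1e-12) ** 0.5).sum()
                zs.update({int(r): (z[np.array([k])], s_label) for k, r in enumerate(rows)})
            if spec.has_distance and pair_arr.size:
                in_batch = [(i, j) for i, j in pair_arr if int(i) in zs and int(j) in zs]
                if in_batch:
                    d = Tensor(0.0)
                    for i, j in in_batch:
                        zi, _ = zs[int(i)]
                        zj, _ = zs[int(j)]
                        d = d + (((zi - zj) ** 2).sum() + 1e-12) ** 0.5
                    total = total + spec.distance_weight * d * (1.0 / len(in_batch))
            if spec.has_translation_error and pair_arr.size:
                in_batch = [(i, j) for i, j in pair_arr if int(i) in zs and int(j) in zs]
                if in_batch:
                    t = Tensor(0.0)
                    for i, j in in_batch:
                        zi, _ = zs[int(i)]
                        tgt_label = "B" if system_of[int(j)] == 1 else "A"
                        pred = model.decode(zi, Tensor(np.zeros((1, model.n_features))),
                                            tgt_label)
                        t = t + recon_loss_mse(Tensor(X[[int(j)]]), pred)
                    total = total + spec.translation_weight * t * (1.0 / len(in_batch))
            opt.zero_grad()
            total.backward()
            opt.step()
    return model


def dcs_translate(model: DCSModel, X, source: str, target: str) -> np.ndarray:
    """Encode with the shared encoder, decode with the target decoder."""
    del source  # the encoder is shared; kept for interface symmetry
    X = np.atleast_2d(np.asarray(X, dtype=float))
    with no_grad():
        xt = Tensor(X)
        z, dropped = model.encode(xt, training=False)
        out = model.decode(z, dropped, target)
    return out.data


# ---------------------------------------------------------------------------
# Principal-component-space translator (TransCompR-style)
# ---------------------------------------------------------------------------

@dataclass
class TransCompRTranslator:
    pca: object
    regressor: object
    target_mean: np.ndarray
    n_components: int


def transcompr_fit(data_a: OmicsDataset, data_b: OmicsDataset, n_components: int,
                   regressor: str = "linear", seed: int = 0) -> TransCompRTranslator:
    """Fit the target system's principal-component space and a regression from
    PC scores back to target profiles.

    Translation projects a source profile into the target's PC space (the
    shared latent space) and regresses from there to the target feature
    profile.  ``n_components=0`` degenerates to predicting the target mean.
    """
    from sklearn.decomposition import PCA
    from sklearn.linear_model import LinearRegression
    from sklearn.neural_network import MLPRegressor

    _check_shared_features(data_a, data_b)
    Xb = np.asarray(data_b.matrix, float)
    if n_components > min(Xb.shape):
        raise ValueError("n_components exceeds min(n_samples, n_features) of the target")
    if n_components == 0:
        return TransCompRTranslator(pca=None, regressor=None,
                                    target_mean=Xb.mean(axis=0), n_components=0)
    pca = PCA(n_components=n_components, random_state=seed).fit(Xb)
    scores = pca.transform(Xb)
    if regressor == "mlp":
        reg = MLPRegressor(hidden_layer_sizes=(64,), max_iter=2000,
                           random_state=seed).fit(scores, Xb)
    else:
        reg = LinearRegression().fit(scores, Xb)
    return TransCompRTranslator(pca=pca, regressor=reg, target_mean=Xb.mean(axis=0),
                                n_components=n_components)


def transcompr_translate(translator: TransCompRTranslator, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if translator.n_components == 0:
        return np.tile(translator.target_mean, (X.shape[0], 1))
    scores = translator.pca.transform(X)
    return np.asarray(translator.regressor.predict(scores))


# ---------------------------------------------------------------------------
# Per-gene slope-1 penalized regression (FIT-style)
# ---------------------------------------------------------------------------

@dataclass
class FITTranslator:
    slope: np.ndarray
    intercept: np.ndarray
    penalty: float


def fit_fit(data_a: OmicsDataset, data_b: OmicsDataset, penalty: float = 1.0,
            pairs: Optional[PairIndex] = None) -> FITTranslator:
    """Per-gene linear regression between homolog genes of paired conditions,
    ridge-penalized toward slope 1 and intercept 0.

    Minimizes sum_i (y_i - (a x_i + b))^2 + penalty * ((a-1)^2 + b^2) per
    gene.  penalty -> infinity recovers the identity map; penalty = 0 is
    ordinary least squares.
    """
    _check_shared_features(data_a, data_b)
    if pairs is None:
        pairs = build_pair_index(combine_datasets(data_a, data_b))
    if not pairs.positive_pairs:
        raise ValueError("no paired conditions available to fit the per-gene model")
    na = data_a.n_samples
    src_rows, tgt_rows = [], []
    for i, j in pairs.positive_pairs:
        a_idx, b_idx = (i, j) if i < na else (j, i)
        src_rows.append(a_idx)
        tgt_rows.append(b_idx - na)
    Xa = np.asarray(data_a.matrix, float)[src_rows]
    Xb = np.asarray(data_b.matrix, float)[tgt_rows]
    n, p = Xa.shape
    slope = np.empty(p)
    intercept = np.empty(p)
    lam = float(penalty)
    for g in range(p):
        x, y = Xa[:, g], Xb[:, g]
        # normal equations of the penalized quadratic
        A = np.array([[np.sum(x * x) + lam, np.sum(x)],
                      [np.sum(x), n + lam]])
        rhs = np.array([np.sum(x * y) + lam, np.sum(y)])
        a, b = np.linalg.solve(A, rhs)
        slope[g], intercept[g] = a, b
    return FITTranslator(slope=slope, intercept=intercept, penalty=lam)


def fit_translate(translator: FITTranslator, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X * translator.slope + translator.intercept


def direct_translate(X, source_features: Optional[Sequence[str]] = None,
                     target_features: Optional[Sequence[str]] = None) -> np.ndarray:
    """Use the source profile unchanged as the target prediction."""
    if source_features is not None and target_features is not None:
        if list(source_features) != list(target_features):
            raise ValueError("direct translation requires a shared feature space")
    return np.asarray(X, dtype=float).copy()
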