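"""Network components of the translation framework.

A TranslatorModel always couples exactly two biological systems.  Each system
has its own encoder and decoder (no weight sharing); a shared latent module
shapes the global space through a mutual-information estimator (Discr1) and a
prior discriminator (Discr2).  Variant v2 adds trainable covariate vectors
(system and, optionally, cell type) producing the composed space from which
the decoders sample, plus an adversarially trained system classifier on the
global space.  Variant v3 adds a cooperatively trained system classifier on
the global space instead.
"""

from __future__ import annotations

import json
import warnings
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import MLP, Linear, Module

__all__ = [
    "Encoder",
    "Decoder",
    "MIEstimator",
    "PriorDiscriminator",
    "Classifier",
    "TranslatorModel",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-8


class Encoder(Module):
    """System-specific encoder: FC blocks ending in a bias-free projection.

    In count mode the (log-transformed) input is first multiplied elementwise
    by a trainable per-gene scaling vector.
    """

    def __init__(self, n_features: int, hidden: Sequence[int], latent_dim: int,
                 dropout: float, rng: np.random.Generator, count_mode: bool = False):
        self.count_mode = count_mode
        if count_mode:
            self.gene_scale = Tensor(np.ones(n_features), requires_grad=True)
        self.net = MLP(n_features, list(hidden), latent_dim, dropout, rng, out_bias=False)
        self.n_features, self.latent_dim = n_features, latent_dim

    def __call__(self, x: Tensor) -> Tensor:
        if self.count_mode:
            x = x * self.gene_scale
        return self.net(x)


class Decoder(Module):
    """System-specific decoder; in count mode it emits (mean, dispersion) heads.

    Positivity of both count heads is enforced with softplus plus a small
    floor; the NB variance is mean + mean^2 / dispersion.
    """

    def __init__(self, latent_dim: int, hidden: Sequence[int], n_features: int,
                 dropout: float, rng: np.random.Generator, count_mode: bool = False):
        self.count_mode = count_mode
        out = 2 * n_features if count_mode else n_features
        self.net = MLP(latent_dim, list(hidden), out, dropout, rng, out_bias=False)
        self.n_features, self.latent_dim = n_features, latent_dim

    def __call__(self, z: Tensor):
        out = self.net(z)
        if not self.count_mode:
            return out
        p = self.n_features
        mean = out[:, :p].softplus() + _EPS
        dispersion = out[:, p:].softplus() + _EPS
        return mean, dispersion


class MIEstimator(Module):
    """Discr1: pairwise score matrix for Jensen-Shannon MI estimation.

    Both embeddings pass through the same three FC+ReLU layers plus one
    fully-connected skip connection; the score of an ordered pair is the inner
    product of the two transformed embeddings.
    """

    def __init__(self, latent_dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(latent_dim, hidden, rng)
        self.fc2 = Linear(hidden, hidden, rng)
        self.fc3 = Linear(hidden, hidden, rng)
        self.skip = Linear(latent_dim, hidden, rng)

    def transform(self, z: Tensor) -> Tensor:
        h = self.fc3(self.fc2(self.fc1(z).relu()).relu()).relu()
        return h + self.skip(z)

    def __call__(self, z: Tensor) -> Tensor:
        h = self.transform(z)
        return h @ h.T


class PriorDiscriminator(Module):
    """Discr2: scalar probability that an embedding comes from the prior."""

    def __init__(self, latent_dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(latent_dim, hidden, rng)
        self.fc2 = Linear(hidden, hidden, rng)
        self.fc3 = Linear(hidden, 1, rng)

    def __call__(self, z: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(z).relu()).relu()).sigmoid()


class Classifier(Module):
    """Fully-connected classifier; ``proba`` applies the final softmax."""

    def __init__(self, latent_dim: int, hidden: Sequence[int], n_classes: int,
                 rng: np.random.Generator):
        sizes = [latent_dim] + list(hidden)
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.out = Linear(sizes[-1], n_classes, rng)
        self.n_classes = n_classes

    def logits(self, z: Tensor) -> Tensor:
        for layer in self.layers:
            z = layer(z).relu()
        return self.out(z)

    def proba(self, z: Tensor) -> Tensor:
        logits = self.logits(z)
        m = np.max(logits.data, axis=1, keepdims=True)
        e = (logits - Tensor(m)).exp()
        return e / e.sum(axis=1, keepdims=True)

    __call__ = proba


class CovariateNet(Module):
    """Intermediate network alternative to additive covariate vectors."""

    def __init__(self, latent_dim: int, hidden: Sequence[int], rng: np.random.Generator):
        sizes = [latent_dim] + list(hidden) + [latent_dim]
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, z: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            z = layer(z).relu()
        return self.layers[-1](z)


class TranslatorModel(Module):
    """Two coupled autoencoders sharing a global latent space.

    Parameters are created from explicit sizes; training orchestration lives
    in :mod:`autotransop.train`.
    """

    def __init__(self, systems: Sequence[str], n_features: dict[str, int],
                 latent_dim: int, encoder_hidden: Sequence[int],
                 decoder_hidden: Sequence[int], *, variant: str = "v1",
                 dropout: float = 0.1, count_mode: bool = False,
                 mi_hidden: int = 64, prior_hidden: int = 64,
                 classifier_specs: Optional[dict[str, tuple[Sequence[int], int]]] = None,
                 adverse_hidden: Sequence[int] = (32,), n_systems_classes: int = 2,
                 celltypes: Optional[Sequence[str]] = None,
                 covariate_mode: str = "additive", seed: int = 0):
        if len(systems) != 2:
            raise ValueError("the framework always models exactly two systems")
        if variant not in ("v1", "v2", "v3"):
            raise ValueError("variant must be one of v1/v2/v3")
        rng = np.random.default_rng(seed)
        self.systems = list(systems)
        self.variant = variant
        self.count_mode = count_mode
        self.latent_dim = latent_dim
        self.covariate_mode = covariate_mode
        self.encoders = {s: Encoder(n_features[s], encoder_hidden, latent_dim,
                                    dropout, rng, count_mode) for s in systems}
        self.decoders = {s: Decoder(latent_dim, decoder_hidden, n_features[s],
                                    dropout, rng, count_mode) for s in systems}
        self.mi_estimator = MIEstimator(latent_dim, mi_hidden, rng)
        self.prior_discriminator = PriorDiscriminator(latent_dim, prior_hidden, rng)
        self.classifiers = {name: Classifier(latent_dim, hid, k, rng)
                            for name, (hid, k) in (classifier_specs or {}).items()}
        self.feature_ids: dict[str, list[str]] = {}
        if variant == "v2":
            self.adverse_classifier = Classifier(latent_dim, adverse_hidden,
                                                 n_systems_classes, rng)
            if covariate_mode == "additive":
                self.system_vectors = {s: Tensor(np.zeros(latent_dim), requires_grad=True)
                                       for s in systems}
                self.celltype_vectors = {c: Tensor(np.zeros(latent_dim), requires_grad=True)
                                         for c in (celltypes or [])}
            else:
                self.system_nets = {s: CovariateNet(latent_dim, adverse_hidden, rng)
                                    for s in systems}
        elif variant == "v3" and "system" not in self.classifiers:
            self.classifiers["system"] = Classifier(latent_dim, adverse_hidden,
                                                    n_systems_classes, rng)

    # -- forward contracts -------------------------------------------------
    def _check_system(self, system: str):
        if system not in self.systems:
            raise ValueError(f"unknown system {system!r}; model has {self.systems}")

    def encode(self, X, system: str) -> Tensor:
        """Global embeddings z_g for a batch from one system."""
        self._check_system(system)
        X = X if isinstance(X, Tensor) else Tensor(np.atleast_2d(np.asarray(X, dtype=float)))
        if X.shape[1] != self.encoders[system].n_features:
            raise ValueError(f"input has {X.shape[1]} features; system {system!r} "
                             f"expects {self.encoders[system].n_features}")
        return self.encoders[system](X)

    def compose(self, z_g: Tensor, system: str, celltype: Optional[str] = None) -> Tensor:
        """Composed embeddings z_c = z_g + covariate vectors (v2 only)."""
        if self.variant != "v2":
            raise ValueError("compose() is only defined for variant v2")
        self._check_system(system)
        z_g = z_g if isinstance(z_g, Tensor) else Tensor(np.atleast_2d(z_g))
        if self.covariate_mode == "additive":
            z_c = z_g + self.system_vectors[system]
            if celltype is not None:
                if celltype not in self.celltype_vectors:
                    raise ValueError(f"unknown cell type {celltype!r}")
                z_c = z_c + self.celltype_vectors[celltype]
            return z_c
        return self.system_nets[system](z_g)

    def decode(self, z, system: str):
        """Reconstruction in zscore mode; (mean, dispersion, variance) in count
        mode, with variance = mean + mean^2 / dispersion."""
        self._check_system(system)
        z = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
        if not np.isfinite(z.data).all():
            raise ValueError("non-finite latent embedding passed to decode()")
        out = self.decoders[system](z)
        if self.count_mode:
            mean, dispersion = out
            variance = mean + mean**2 / dispersion
            return mean, dispersion, variance
        return out

    def translate(self, X, source: str, target: str):
        """Predict the target-system profile of a source-system sample.

        v1/v3 decode the global embedding with the target decoder; v2 first
        adds the target system's covariate vector (composed space).
        """
        self._check_system(source)
        self._check_system(target)
        if source == target:
            warnings.warn("source == target: translate() returns the reconstruction",
                          stacklevel=2)
        z = self.encode(X, source)
        if self.variant == "v2":
            z = self.compose(z, target)
        return self.decode(z, target)

    def embed(self, X, system: str, composed: bool = False) -> np.ndarray:
        """Deterministic evaluation-mode embeddings as a plain array."""
        self.eval()
        with no_grad():
            z = self.encode(X, system)
            if composed:
                z = self.compose(z, system)
        return z.data


def save_checkpoint(model: TranslatorModel, path: str, config: Optional[dict] = None):
    """Single-file archive of weights + provenance + feature id lists."""
    meta = {
        "systems": model.systems, "variant": model.variant,
        "latent_dim": model.latent_dim, "count_mode": model.count_mode,
        "feature_ids": model.feature_ids, "config": config or {},
    }
    arrays = model.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str, model: TranslatorModel) -> TranslatorModel:
    """Load weights into a compatibly constructed model, validating feature ids."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    if meta["systems"] != model.systems or meta["variant"] != model.variant:
        raise ValueError("checkpoint does not match the model's systems/variant")
    if model.feature_ids and meta["feature_ids"] and meta["feature_ids"] != model.feature_ids:
        raise ValueError("checkpoint feature ids do not match the model")
    model.load_state_arrays(arrays)
    model.feature_ids = {k: list(v) for k, v in meta["feature_ids"].items()}
    return model
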