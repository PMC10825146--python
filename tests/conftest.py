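"""Shared fixtures: small synthetic datasets and trained models.

Training fixtures are session-scoped so the expensive fits happen once.
"""

from __future__ import annotations

import numpy as np
import pytest

import autotransop as at


def small_weights(**overrides) -> at.LossWeights:
    """Loss weights used by the small training runs in this suite."""
    base = dict(recon=1.0, distance=1.0, cosine=1.0, mi=0.1, prior=1e-3,
                enc=(1e-6, 1e-6), dec=(1e-6, 1e-6))
    base.update(overrides)
    return at.LossWeights(**base)


@pytest.fixture(scope="session")
def bulk_small():
    """Two-system bulk data: 60 conditions, half paired, 20/30 features."""
    cfg = at.SynthConfig(n_conditions=60, paired_fraction=0.5, n_features_a=20,
                         n_features_b=30, latent_dim_true=6, seed=7)
    ds_a, ds_b, truth = at.generate_paired_bulk(cfg)
    return cfg, ds_a, ds_b, truth


@pytest.fixture(scope="session")
def trained_v1(bulk_small):
    _, ds_a, ds_b, _ = bulk_small
    cfg = at.ModelConfig(latent_dim=8, encoder_hidden=(24,), decoder_hidden=(24,),
                         batch_size=64, epochs=60, learning_rate=1e-3, dropout=0.1,
                         weights=small_weights(), seed=7)
    model, trace = at.train(ds_a, ds_b, None, cfg)
    return model, trace, cfg


@pytest.fixture(scope="session")
def trained_v2(bulk_small):
    _, ds_a, ds_b, _ = bulk_small
    cfg = at.ModelConfig(latent_dim=8, encoder_hidden=(24,), decoder_hidden=(24,),
                         batch_size=64, epochs=60, learning_rate=1e-3, dropout=0.1,
                         variant="v2", seed=7,
                         weights=small_weights(adverse=0.2, trained_effect=1e-4,
                                               classifier=(1.0,), l2_class=(1e-6,)),
                         classifier_specs={"system": ((16,), "system")})
    model, trace = at.train(ds_a, ds_b, None, cfg)
    return model, trace, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_records():
    """Five records of which exactly two satisfy every quality predicate."""
    mk = at.SampleRecord
    key = at.ConditionKey
    return [
        # keeper: 5 replicates, 3 passed (>= ceil(5/2)=3), tas 0.5
        mk("s1", "A", key("drug1", "1uM", "24h"), n_replicates=5, n_passed_qc=3, tas=0.5),
        # dropped: only 3 replicates ("more than three" fails)
        mk("s2", "A", key("drug2", "1uM", "24h"), n_replicates=3, n_passed_qc=3, tas=0.9),
        # dropped: QC 2 of 6 (< ceil(6/2)=3)
        mk("s3", "A", key("drug3", "1uM", "24h"), n_replicates=6, n_passed_qc=2, tas=0.9),
        # keeper: boundary TAS exactly at threshold
        mk("s4", "B", key("drug4", "1uM", "24h"), n_replicates=4, n_passed_qc=4, tas=0.3),
        # dropped: flagged outlier
        mk("s5", "B", key("drug5", "1uM", "24h"), n_replicates=8, n_passed_qc=8,
           tas=0.9, is_outlier=True),
    ]
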