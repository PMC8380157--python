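import numpy as np
import pytest

import fdgnet as fg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_backbone_config(**overrides):
    """Smallest trainable architecture: 32^3 grid, minimal channel widths."""
    base = dict(conv_channels=(2, 3, 3, 4, 4, 4), input_shape=(32, 32, 32),
                attention_ratio=2, conv6_padding="same", dropout_rate=0.0)
    base.update(overrides)
    return fg.BackboneConfig(**base)


@pytest.fixture
def tiny_cfg():
    return tiny_backbone_config()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small separable phantom cohort on the 32^3 grid (6 subjects/class)."""
    cfg = fg.PhantomConfig(shape=(32, 32, 32), noise_sd=0.1,
                           scans_per_subject=2, seed=77)
    return fg.generate_cohort(cfg, 6)


def grouped_split(data, n_test, n_verif, seed=0):
    """Subject-stratified (train, verification, test) split helper."""
    by = {}
    for sid, lab in sorted(data.subjects().items()):
        by.setdefault(lab, []).append(sid)
    rng = np.random.default_rng(seed)
    train, verif, test = [], [], []
    for lab in sorted(by):
        sids = by[lab]
        perm = [sids[i] for i in rng.permutation(len(sids))]
        test += perm[:n_test]
        verif += perm[n_test:n_test + n_verif]
        train += perm[n_test + n_verif:]
    return data.subset(train), data.subset(verif), data.subset(test)
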