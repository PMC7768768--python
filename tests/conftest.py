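"""Shared fixtures.

The expensive session-scoped fixtures train full-scale models once and are
shared by the acceptance tests; everything else is cheap and local.
"""

from __future__ import annotations

import numpy as np
import pytest

import bilatnet as bn
from bilatnet.lesion import trajectory_extras
from bilatnet.measures import target_rdm

LEXICON_SEED = 0
DEV_PRESENTATIONS = 300_000


@pytest.fixture(scope="session")
def inventory():
    return bn.build_inventory(LEXICON_SEED)


@pytest.fixture(scope="session")
def lexicon(inventory):
    return bn.generate_lexicon(inventory, LEXICON_SEED)


def make_toy_state(n_left=3, n_right=3, cross_density=0.0, seed=0, **kw):
    cfg = bn.NetworkConfig(n_left=n_left, n_right=n_right,
                           cross_density=cross_density, seed=seed, **kw)
    return bn.init_network(cfg)


@pytest.fixture
def toy_state():
    return make_toy_state()


def _train_intact(lexicon, seed, log_extras=None, eval_every=0,
                  n_left=60, n_right=30, n=DEV_PRESENTATIONS):
    cfg = bn.NetworkConfig(n_left=n_left, n_right=n_right, seed=seed)
    state = bn.init_network(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    return bn.train(state, lexicon, n, eval_every=eval_every, rng=rng,
                    log_extras=log_extras)


@pytest.fixture(scope="session")
def intact_logged(lexicon):
    """Fully developed 60/30 models (seeds 1-3) with checkpointed measures.

    Checkpoints every 10K presentations record accuracy, pathway output
    activations, and per-layer RSA scores over the developmental period.
    """
    tgt = target_rdm(lexicon)
    out = {}
    for seed in (1, 2, 3):
        ref = bn.init_network(bn.NetworkConfig(n_left=60, n_right=30, seed=seed))
        extras = trajectory_extras(lexicon, ref, tgt)
        state, log = _train_intact(lexicon, seed, log_extras=extras,
                                   eval_every=10_000)
        out[seed] = (state, log)
    return out


@pytest.fixture(scope="session")
def intact_extra(lexicon):
    """Two more developed 60/30 models (seeds 4-5), no checkpoint series."""
    return {seed: _train_intact(lexicon, seed)[0] for seed in (4, 5)}
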