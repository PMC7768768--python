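"""Frequency-weighted training, accuracy scoring, and periodic evaluation.

Training presents one word at a time, sampled i.i.d. by the lexicon's
log-frequency presentation probabilities, and applies an online weight
update after every presentation.  Accuracy is whole-item: each production
tick's output vector is decoded to the nearest inventory phoneme
(Euclidean distance over the 25 features, ties broken by inventory order)
and the item counts as correct only if all three decoded phonemes match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import train_block
from .lexicon import Lexicon, PhonemeInventory, encode_words
from .network import NetworkState, forward_batch

EVAL_EVERY_DEFAULT = 5000


@dataclass
class AccuracyReport:
    accuracy_hf: float  # percent
    accuracy_lf: float
    accuracy_nw: float
    word_correct: np.ndarray  # (200,) bool, lexicon order
    nonword_correct: np.ndarray  # (25,) bool

    @property
    def accuracy_words(self) -> float:
        return 100.0 * float(self.word_correct.mean())

    @property
    def accuracy_overall(self) -> float:
        n = len(self.word_correct) + len(self.nonword_correct)
        return 100.0 * (self.word_correct.sum() + self.nonword_correct.sum()) / n


@dataclass
class TrainingLog:
    """Checkpointed accuracy/loss time series over a training run."""

    checkpoints: list[dict] = field(default_factory=list)

    def add(self, **fields) -> None:
        if self.checkpoints and fields["presentations"] <= self.checkpoints[-1]["presentations"]:
            raise ValueError("presentation counts must be strictly increasing")
        self.checkpoints.append(fields)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.checkpoints)

    def series(self, key: str) -> np.ndarray:
        return np.array([c[key] for c in self.checkpoints])


def decode_outputs(outputs: np.ndarray, inventory: PhonemeInventory) -> np.ndarray:
    """Map output vectors to nearest-phoneme indices.

    ``outputs`` has shape (..., 25); returns integer indices into the
    inventory, ties resolved toward the earliest inventory entry (argmin).
    """
    P = inventory.feature_matrix()  # (n_phon, 25)
    flat = outputs.reshape(-1, P.shape[1])
    # squared Euclidean distance; the ||out||^2 term is constant per row
    d2 = (flat**2).sum(1, keepdims=True) - 2.0 * flat @ P.T + (P**2).sum(1)
    return d2.argmin(axis=1).reshape(outputs.shape[:-1])


def score_word(outputs: np.ndarray, target: tuple[str, str, str],
               inventory: PhonemeInventory) -> bool:
    """Whole-word correctness for one item's three production outputs."""
    idx = decode_outputs(np.asarray(outputs), inventory)
    symbols = inventory.symbols
    return all(symbols[i] == t for i, t in zip(idx, target))


def _score_batch(state: NetworkState, feats: np.ndarray,
                 inventory: PhonemeInventory) -> np.ndarray:
    """Whole-item correctness flags for a batch of encoded triples."""
    _, _, out = forward_batch(state, feats)
    prod = out[3:].transpose(1, 0, 2)  # (B, 3, 25)
    decoded = decode_outputs(prod, inventory)
    target = decode_outputs(feats, inventory)  # exact rows -> their own index
    return (decoded == target).all(axis=1)


def evaluate(state: NetworkState, lexicon: Lexicon) -> AccuracyReport:
    """Score all words and nonwords; pure (no weight changes)."""
    inv = lexicon.inventory
    wfeats = encode_words(lexicon.word_triples(), inv)
    nfeats = encode_words(lexicon.nonwords, inv)
    wc = _score_batch(state, wfeats, inv)
    nc = _score_batch(state, nfeats, inv)
    hf, lf = lexicon.hf_indices, lexicon.lf_indices
    return AccuracyReport(
        accuracy_hf=100.0 * float(wc[hf].mean()),
        accuracy_lf=100.0 * float(wc[lf].mean()),
        accuracy_nw=100.0 * float(nc.mean()),
        word_correct=wc, nonword_correct=nc,
    )


def train(state: NetworkState, lexicon: Lexicon, n_presentations: int,
          eval_every: int = EVAL_EVERY_DEFAULT,
          rng: np.random.Generator | int | None = None,
          log_extras=None, presentations_offset: int = 0,
          gain_schedule=None) -> tuple[NetworkState, TrainingLog]:
    """Train for ``n_presentations`` word presentations, in place.

    Words are sampled i.i.d. from the lexicon's presentation probabilities.
    The log records an evaluation at presentation 0, every ``eval_every``
    presentations, and at the end.  ``log_extras(state)``, if given, returns
    a dict of extra fields recorded at each checkpoint (e.g. RSA scores).
    ``gain_schedule(p)``, if given, is called before each presentation
    block with the current presentation count (used for the recovery gain
    ramp).  ``presentations_offset`` only shifts the counts written to the
    log (e.g. recovery runs continuing a developmental clock).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    inv = lexicon.inventory
    feats = encode_words(lexicon.word_triples(), inv)  # (200, 3, 25)
    probs = lexicon.presentation_probs
    log = TrainingLog()

    def checkpoint(p: int, mean_loss: float) -> None:
        rep = evaluate(state, lexicon)
        row = dict(
            presentations=p + presentations_offset,
            accuracy_hf=rep.accuracy_hf, accuracy_lf=rep.accuracy_lf,
            accuracy_nw=rep.accuracy_nw,
            accuracy_words=rep.accuracy_words,
            accuracy_overall=rep.accuracy_overall,
            mean_loss=mean_loss,
        )
        if log_extras is not None:
            row.update(log_extras(state))
        log.add(**row)

    if gain_schedule is not None:
        gain_schedule(0)  # the initial checkpoint reflects the schedule's start
    checkpoint(0, float("nan"))
    done = 0
    while done < n_presentations:
        block = min(eval_every - (done % eval_every) if eval_every else n_presentations,
                    n_presentations - done)
        if gain_schedule is not None:
            # split the block so the schedule is applied at its boundaries
            block = min(block, gain_schedule(done))
        idx = rng.choice(len(probs), size=block, p=probs)
        loss_sum = train_block(state, idx, feats)
        done += block
        if eval_every and (done % eval_every == 0 or done == n_presentations):
            checkpoint(done, loss_sum / block)
    if eval_every == 0 or (n_presentations == 0):
        pass
    elif log.checkpoints[-1]["presentations"] != n_presentations + presentations_offset:
        checkpoint(done, float("nan"))
    return state, log
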