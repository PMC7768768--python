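"""Model "neuroimaging" proxies.

All measurements are pure: they run forward trials without touching the
weights.  Two laterality measures mirror the ones used on fMRI data:

* functional contribution — correlate the output patterns produced with
  one pathway's input silenced against the full model's output patterns
  (a proxy for effective connectivity);
* output unit activation — the mean output-layer activation attributable
  to one pathway, isolated the same way (a proxy for BOLD amplitude).

Both are combined into a laterality index (L - R) / (L + R); positive
means left-dominant.  Representational similarity analysis (RSA) compares
a hidden layer's representational dissimilarity matrix (RDM; pairwise
1 - Pearson over word patterns) to the target phonological RDM.
"""

from __future__ import annotations

import warnings

import numpy as np

from .lexicon import Lexicon, PhonemeInventory, encode_words
from .network import NetworkState, forward_batch

PRODUCTION_TICKS = slice(3, 6)


def _word_features(lexicon: Lexicon) -> np.ndarray:
    return encode_words(lexicon.word_triples(), lexicon.inventory)


def pathway_output_patterns(state: NetworkState, lexicon: Lexicon,
                            side: str) -> np.ndarray:
    """Output patterns with the *opposite* pathway's input silenced.

    Returns a (n_words, 3 * n_io) matrix: per word, the concatenated
    output activations over the three production ticks.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    silence = "right" if side == "left" else "left"
    return _output_patterns(state, lexicon, silence)


def _output_patterns(state: NetworkState, lexicon: Lexicon,
                     silence: str = "none") -> np.ndarray:
    feats = _word_features(lexicon)
    _, _, out = forward_batch(state, feats, silence=silence)
    prod = out[PRODUCTION_TICKS]  # (3, n_words, n_io)
    return prod.transpose(1, 0, 2).reshape(feats.shape[0], -1)


def functional_contribution(state: NetworkState, lexicon: Lexicon,
                            side: str) -> float:
    """Correlation of one pathway's output patterns with the full model's."""
    part = pathway_output_patterns(state, lexicon, side).ravel()
    full = _output_patterns(state, lexicon).ravel()
    if part.std() == 0.0 or full.std() == 0.0:
        warnings.warn("degenerate (zero-variance) output pattern; "
                      "functional contribution reported as 0")
        return 0.0
    return float(np.corrcoef(part, full)[0, 1])


def mean_output_activation(state: NetworkState, lexicon: Lexicon,
                           side: str) -> float:
    """Mean output activation attributable to one pathway."""
    return float(pathway_output_patterns(state, lexicon, side).mean())


def laterality_index(left: float, right: float) -> float:
    """(L - R) / (L + R); positive = left-lateralized."""
    total = left + right
    if total == 0:
        raise ValueError("laterality index undefined for L + R = 0")
    return (left - right) / total


def mean_hidden_activation(state: NetworkState, lexicon: Lexicon,
                           layer: str, subset: str = "all_live") -> float:
    """Mean activation of one hidden layer over all words and all 6 ticks.

    ``subset`` selects ``all_live`` units, the ``perilesional`` (surviving)
    units of a lesioned layer, or the ``lesioned`` (dead) units.
    """
    feats = _word_features(lexicon)
    h1, h2, _ = forward_batch(state, feats)
    acts = (h1 if layer.endswith("1") else h2)[:, :, state.layer_slice(layer)]
    alive = state.layer_alive(layer).astype(bool)
    if subset == "all_live":
        sel = alive
    elif subset == "perilesional":
        if layer not in state.lesioned_layers:
            raise ValueError(f"layer {layer} has not been lesioned")
        sel = alive
    elif subset == "lesioned":
        if layer not in state.lesioned_layers:
            raise ValueError(f"layer {layer} has not been lesioned")
        sel = ~alive
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if not sel.any():
        raise ValueError(f"empty unit subset {subset!r} for layer {layer}")
    return float(acts[:, :, sel].mean())


def compute_rdm(patterns: np.ndarray) -> np.ndarray:
    """Representational dissimilarity matrix, 1 - Pearson over rows."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[0] < 2:
        raise ValueError("need at least 2 items for an RDM")
    sd = patterns.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"zero-variance pattern for item {bad}")
    rdm = 1.0 - np.corrcoef(patterns)
    np.fill_diagonal(rdm, 0.0)
    return rdm


def rsa_score(model_rdm: np.ndarray, target_rdm: np.ndarray) -> float:
    """Pearson correlation of the two RDMs' lower triangles."""
    if model_rdm.shape != target_rdm.shape:
        raise ValueError("RDM dimensions do not match")
    iu = np.tril_indices_from(model_rdm, k=-1)
    a, b = model_rdm[iu], target_rdm[iu]
    if a.std() == 0.0 or b.std() == 0.0:  # degenerate RDM (e.g. silenced layer)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def hidden_patterns_for_rsa(state: NetworkState, lexicon: Lexicon,
                            layer: str, ticks: slice = PRODUCTION_TICKS
                            ) -> np.ndarray:
    """Per-word live-unit activations of one hidden layer, production ticks.

    Returns a (n_words, 3 * n_live) matrix (concatenation over ticks).
    """
    feats = _word_features(lexicon)
    h1, h2, _ = forward_batch(state, feats)
    acts = (h1 if layer.endswith("1") else h2)[ticks][:, :, state.layer_slice(layer)]
    alive = state.layer_alive(layer).astype(bool)
    acts = acts[:, :, alive]
    return acts.transpose(1, 0, 2).reshape(feats.shape[0], -1)


def target_rdm(lexicon: Lexicon, use_model_outputs: bool = False,
               state: NetworkState | None = None) -> np.ndarray:
    """RDM over the words' target phonological patterns.

    By default the target patterns are the ground-truth feature sequences
    (3 x 25 concatenated per word); with ``use_model_outputs`` the model's
    own produced output patterns are used instead.
    """
    if use_model_outputs:
        if state is None:
            raise ValueError("state required when use_model_outputs=True")
        return compute_rdm(_output_patterns(state, lexicon))
    feats = _word_features(lexicon)
    return compute_rdm(feats.reshape(feats.shape[0], -1))


def layer_rsa_scores(state: NetworkState, lexicon: Lexicon,
                     tgt: np.ndarray | None = None) -> dict[str, float]:
    """RSA score of every hidden layer against the target RDM."""
    if tgt is None:
        tgt = target_rdm(lexicon)
    scores = {}
    for layer in ("LH1", "RH1", "LH2", "RH2"):
        try:
            pats = hidden_patterns_for_rsa(state, lexicon, layer)
            scores[layer] = rsa_score(compute_rdm(pats), tgt)
        except ValueError:  # fully lesioned layer: no live units / zero rows
            scores[layer] = float("nan")
    return scores


def weight_statistics(state: NetworkState,
                      reference: NetworkState) -> tuple[float, float]:
    """(mean |w|, mean |w - w_ref|) over live weight entries.

    Entries into or out of dead units are excluded, as are structurally
    absent entries (outside block or sparsity masks).
    """
    if state.config.n_left != reference.config.n_left or \
            state.config.n_right != reference.config.n_right:
        raise ValueError("architectures do not match")
    from .network import _block_diag_mask
    nh = state.nh
    diag = _block_diag_mask(state.config.n_left, state.config.n_right)
    a1 = state.alive1.astype(bool)
    a2 = state.alive2.astype(bool)
    masks = {
        "W_in": np.outer(a1, np.ones(state.config.n_io, bool)),
        "C_ctx": diag & np.outer(a1, a1),
        "C_cross": state.M_cross1.astype(bool) & np.outer(a1, a1),
        "W_mid": diag & np.outer(a2, a1),
        "X_cross": state.M_cross2.astype(bool) & np.outer(a2, a2),
        "W_out": np.outer(np.ones(state.config.n_io, bool), a2),
        "b1": a1, "b2": a2, "b_out": np.ones(state.config.n_io, bool),
    }
    w_sum = d_sum = n = 0.0
    ref_blocks = reference.weight_blocks()
    for name, W in state.weight_blocks().items():
        m = masks[name]
        w_sum += np.abs(W[m]).sum()
        d_sum += np.abs(W[m] - ref_blocks[name][m]).sum()
        n += m.sum()
    return w_sum / n, d_sum / n


def rdm_to_csv(rdm: np.ndarray, word_ids: list, path) -> None:
    """Write an RDM as a square CSV with word-id header row and column."""
    import pandas as pd
    pd.DataFrame(rdm, index=word_ids, columns=word_ids).to_csv(path)


def rdm_from_csv(path) -> np.ndarray:
    import pandas as pd
    return pd.read_csv(path, index_col=0).to_numpy()
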