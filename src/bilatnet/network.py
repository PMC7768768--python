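"""The bilateral simple recurrent network (SRN).

Two parallel processing pathways — "left" and "right" — each with two
hidden layers (H1, H2), connect a shared 25-unit phonological input layer
to a shared 25-unit phonological output layer.  Each H1 layer has an Elman
context: a copy of its own previous-tick activations fed back as extra
input.  Optionally, sparse homotopic cross-connections link LH1<->RH1 and
LH2<->RH2.

A repetition trial spans six time ticks: the three input phonemes are
presented at ticks 1-3, and the model must produce them back at ticks 4-6
(input is the zero vector during production).  Hidden units use a gained
logistic activation a = sigma(g * net); g is normally 1 and is lowered to
model inefficient (e.g., perilesional) processing.  Lesioned units are
clamped to zero activation and receive no weight updates.

Internally the left and right pathways are stored in single concatenated
weight arrays with structural masks enforcing the pathway separation (no
feedforward connections cross between pathways; cross-connections exist
only where their sparsity mask allows).  Cross-connections are recurrent
like the Elman context: at tick t they deliver the contralateral layer's
activation from tick t-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

N_IO = 25
TOTAL_HIDDEN = 90  # n_left + n_right in every study configuration
N_TICKS = 6
N_INPUT_TICKS = 3

LAYERS = ("LH1", "RH1", "LH2", "RH2")


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and learning hyperparameters.

    ``n_left``/``n_right`` are the units per hidden layer on each side
    (H1 and H2 have the same count within a side).  ``cross_density`` is
    the fraction of homotopic cross-connections present, drawn once at
    initialization; ``cross_constraint`` is "free" or "negative_only".
    ``backprop`` selects "truncated" (per-tick gradients, the Elman context
    treated as constant input) or "bptt" (gradients flow through the
    context copies across the six ticks).
    """

    n_left: int = 60
    n_right: int = 30
    n_io: int = N_IO
    cross_density: float = 0.0
    cross_constraint: str = "free"
    learning_rate: float = 0.0005
    init_range: float = 0.5
    seed: int = 0
    backprop: str = "bptt"

    def __post_init__(self):
        if self.n_left < 0 or self.n_right < 0:
            raise ValueError("unit counts must be nonnegative")
        if not 0.0 <= self.cross_density <= 1.0:
            raise ValueError("cross_density must be in [0, 1]")
        if self.cross_constraint not in ("free", "negative_only"):
            raise ValueError("cross_constraint must be 'free' or 'negative_only'")
        if self.backprop not in ("truncated", "bptt"):
            raise ValueError("backprop must be 'truncated' or 'bptt'")


@dataclass
class NetworkState:
    """All weights, masks, gains, and lesion state of the bilateral SRN.

    Hidden layers are stored concatenated: units ``[0:n_left]`` are the
    left pathway, ``[n_left:]`` the right, identically for H1 and H2.
    """

    config: NetworkConfig
    W_in: np.ndarray    # (nh, n_io)   input -> H1 (both sides)
    C_ctx: np.ndarray   # (nh, nh)     Elman context -> H1, block-diagonal
    C_cross: np.ndarray  # (nh, nh)    H1 cross-connections, off-diagonal blocks
    M_cross1: np.ndarray  # boolean sparsity mask for C_cross
    W_mid: np.ndarray   # (nh, nh)     H1 -> H2, block-diagonal
    X_cross: np.ndarray  # (nh, nh)    H2 cross-connections, off-diagonal blocks
    M_cross2: np.ndarray  # boolean sparsity mask for X_cross
    W_out: np.ndarray   # (n_io, nh)   H2 -> output
    b1: np.ndarray      # (nh,)
    b2: np.ndarray      # (nh,)
    b_out: np.ndarray   # (n_io,)
    alive1: np.ndarray  # (nh,) float 0/1 lesion mask for H1
    alive2: np.ndarray  # (nh,) float 0/1 lesion mask for H2
    g1: np.ndarray      # (nh,) per-unit gain for H1
    g2: np.ndarray      # (nh,) per-unit gain for H2
    lesioned_layers: dict = field(default_factory=dict)  # layer -> dead index array

    @property
    def nh(self) -> int:
        return self.config.n_left + self.config.n_right

    @property
    def left(self) -> slice:
        return slice(0, self.config.n_left)

    @property
    def right(self) -> slice:
        return slice(self.config.n_left, self.nh)

    def layer_slice(self, layer: str) -> slice:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        return self.left if layer.startswith("L") else self.right

    def layer_alive(self, layer: str) -> np.ndarray:
        return (self.alive1 if layer.endswith("1") else self.alive2)[self.layer_slice(layer)]

    def has_cross(self) -> bool:
        return bool(self.M_cross1.any() or self.M_cross2.any())

    def weight_blocks(self) -> dict[str, np.ndarray]:
        """Named views of every trainable array (weights and biases)."""
        return {
            "W_in": self.W_in, "C_ctx": self.C_ctx, "C_cross": self.C_cross,
            "W_mid": self.W_mid, "X_cross": self.X_cross, "W_out": self.W_out,
            "b1": self.b1, "b2": self.b2, "b_out": self.b_out,
        }

    def copy(self) -> "NetworkState":
        return NetworkState(
            config=self.config,
            **{k: v.copy() for k, v in self.weight_blocks().items()},
            M_cross1=self.M_cross1.copy(), M_cross2=self.M_cross2.copy(),
            alive1=self.alive1.copy(), alive2=self.alive2.copy(),
            g1=self.g1.copy(), g2=self.g2.copy(),
            lesioned_layers={k: v.copy() for k, v in self.lesioned_layers.items()},
        )

    def checksum(self) -> float:
        """Cheap fingerprint of all trainable arrays (for purity checks)."""
        return float(sum(np.abs(v).sum() + (v**3).sum()
                         for v in self.weight_blocks().values()))


@dataclass
class TrialActivations:
    """Per-tick activations for one trial: arrays of shape (6, n_units)."""

    lh1: np.ndarray
    rh1: np.ndarray
    lh2: np.ndarray
    rh2: np.ndarray
    output: np.ndarray  # (6, n_io)


def _block_diag_mask(n_left: int, n_right: int) -> np.ndarray:
    nh = n_left + n_right
    m = np.zeros((nh, nh), dtype=bool)
    m[:n_left, :n_left] = True
    m[n_left:, n_left:] = True
    return m


def init_network(config: NetworkConfig) -> NetworkState:
    """Initialize weights i.i.d. uniform in [-init_range, +init_range].

    Cross-connection sparsity masks are drawn once from the config seed,
    each direction independently at ``cross_density``.  Gains start at 1,
    lesion masks all-alive, contexts are zeroed at every trial start.
    """
    cfg = config
    nh = cfg.n_left + cfg.n_right
    rng = np.random.default_rng(cfg.seed)
    r = cfg.init_range

    def U(*shape):
        return rng.uniform(-r, r, size=shape)

    diag = _block_diag_mask(cfg.n_left, cfg.n_right)
    off = ~diag
    M1 = off & (rng.random((nh, nh)) < cfg.cross_density)
    M2 = off & (rng.random((nh, nh)) < cfg.cross_density)

    W_in = U(nh, cfg.n_io)
    C_ctx = U(nh, nh) * diag
    C_cross = U(nh, nh) * M1
    W_mid = U(nh, nh) * diag
    X_cross = U(nh, nh) * M2
    W_out = U(cfg.n_io, nh)

    if cfg.cross_constraint == "negative_only":
        np.minimum(C_cross, 0.0, out=C_cross)
        np.minimum(X_cross, 0.0, out=X_cross)

    return NetworkState(
        config=cfg, W_in=W_in, C_ctx=C_ctx, C_cross=C_cross, M_cross1=M1,
        W_mid=W_mid, X_cross=X_cross, M_cross2=M2, W_out=W_out,
        b1=np.zeros(nh), b2=np.zeros(nh), b_out=np.zeros(cfg.n_io),
        alive1=np.ones(nh), alive2=np.ones(nh),
        g1=np.ones(nh), g2=np.ones(nh),
    )


def set_layer_gain(state: NetworkState, layer: str, g: float) -> NetworkState:
    """Set the logistic gain of one hidden layer (in place; returns state)."""
    if not 0.0 <= g <= 1.0:
        raise ValueError("gain must be in [0, 1]")
    sl = state.layer_slice(layer)
    (state.g1 if layer.endswith("1") else state.g2)[sl] = g
    return state


def _silence_mask(state: NetworkState, silence: str) -> np.ndarray | None:
    """Per-H1-unit multiplier zeroing the input->H1 drive of one side."""
    if silence == "none":
        return None
    if silence not in ("left", "right"):
        raise ValueError("silence must be 'none', 'left' or 'right'")
    m = np.ones(state.nh)
    m[state.layer_slice("LH1" if silence == "left" else "RH1")] = 0.0
    return m


def forward_batch(state: NetworkState, features: np.ndarray,
                  silence: str = "none"):
    """Run trials for a batch of items, non-destructively.

    Parameters
    ----------
    features
        Array of shape (B, 3, n_io); row t is presented at tick t+1, the
        zero vector at ticks 4-6.
    silence
        "left"/"right" zeroes the input->H1 drive of that side for this
        run only (the Elman context and biases remain active).

    Returns
    -------
    h1, h2 : arrays (6, B, nh);  out : array (6, B, n_io)
    """
    B = features.shape[0]
    if features.shape[1:] != (N_INPUT_TICKS, state.config.n_io):
        raise ValueError(
            f"features must be (B, {N_INPUT_TICKS}, {state.config.n_io}), "
            f"got {features.shape}")
    nh = state.nh
    smask = _silence_mask(state, silence)
    has_c1 = state.M_cross1.any()
    has_c2 = state.M_cross2.any()

    h1s = np.empty((N_TICKS, B, nh))
    h2s = np.empty((N_TICKS, B, nh))
    outs = np.empty((N_TICKS, B, state.config.n_io))
    h1_prev = np.zeros((B, nh))
    h2_prev = np.zeros((B, nh))
    for t in range(N_TICKS):
        if t < N_INPUT_TICKS:
            inp = features[:, t, :] @ state.W_in.T
            if smask is not None:
                inp *= smask
        else:
            inp = 0.0
        net1 = inp + h1_prev @ state.C_ctx.T + state.b1
        if has_c1:
            net1 += h1_prev @ state.C_cross.T
        h1 = sigmoid(state.g1 * net1) * state.alive1
        net2 = h1 @ state.W_mid.T + state.b2
        if has_c2:
            net2 += h2_prev @ state.X_cross.T
        h2 = sigmoid(state.g2 * net2) * state.alive2
        out = sigmoid(h2 @ state.W_out.T + state.b_out)
        h1s[t], h2s[t], outs[t] = h1, h2, out
        h1_prev, h2_prev = h1, h2
    return h1s, h2s, outs


def forward_trial(state: NetworkState, features: np.ndarray,
                  silence: str = "none") -> TrialActivations:
    """Run a single six-tick repetition trial (pure, no weight changes)."""
    if features.shape != (N_INPUT_TICKS, state.config.n_io):
        raise ValueError(
            f"features must be ({N_INPUT_TICKS}, {state.config.n_io}), "
            f"got {features.shape}")
    h1, h2, out = forward_batch(state, features[None, :, :], silence)
    L, R = state.left, state.right
    return TrialActivations(
        lh1=h1[:, 0, L], rh1=h1[:, 0, R],
        lh2=h2[:, 0, L], rh2=h2[:, 0, R],
        output=out[:, 0, :],
    )


def cross_entropy_loss(outputs: np.ndarray, targets: np.ndarray,
                       eps: float = 1e-12) -> float:
    """Summed cross-entropy over the production ticks.

    ``outputs``: (3, n_io) activations at ticks 4-6; ``targets``: the
    word's three feature rows.
    """
    a = np.clip(outputs, eps, 1.0 - eps)
    return float(-(targets * np.log(a) + (1.0 - targets) * np.log(1.0 - a)).sum())


def _project_cross(state: NetworkState) -> None:
    """Re-impose the sparsity mask and sign constraint on cross weights."""
    state.C_cross *= state.M_cross1
    state.X_cross *= state.M_cross2
    if state.config.cross_constraint == "negative_only":
        np.minimum(state.C_cross, 0.0, out=state.C_cross)
        np.minimum(state.X_cross, 0.0, out=state.X_cross)


def compute_gradients(state: NetworkState,
                      features: np.ndarray) -> tuple[float, dict]:
    """Loss and per-block gradients for one repetition trial.

    The target at ticks 4-6 is the word's own feature sequence (repetition
    task); cross-entropy error is accumulated over the three production
    ticks.  With ``backprop="truncated"`` the Elman context and cross
    inputs are treated as constant inputs at each tick (no gradient across
    the copy); with "bptt" the gradient flows backward through the
    context/cross copies over the six ticks.  Gradients for structurally
    masked entries are reported dense; callers re-impose the masks.
    """
    cfg = state.config
    nh = state.nh
    has_c1 = state.M_cross1.any()
    has_c2 = state.M_cross2.any()

    W_in, C_ctx, C_cross = state.W_in, state.C_ctx, state.C_cross
    W_mid, X_cross, W_out = state.W_mid, state.X_cross, state.W_out
    b1, b2, b_out = state.b1, state.b2, state.b_out
    g1, g2 = state.g1, state.g2
    alive1, alive2 = state.alive1, state.alive2

    # -- forward, storing per-tick activations ---------------------------
    h1s = np.zeros((N_TICKS + 1, nh))  # index t holds activation of tick t (1-based)
    h2s = np.zeros((N_TICKS + 1, nh))
    outs = np.empty((N_TICKS + 1, cfg.n_io))
    for t in range(1, N_TICKS + 1):
        net1 = C_ctx @ h1s[t - 1] + b1
        if t <= N_INPUT_TICKS:
            net1 += W_in @ features[t - 1]
        if has_c1:
            net1 += C_cross @ h1s[t - 1]
        h1s[t] = sigmoid(g1 * net1) * alive1
        net2 = W_mid @ h1s[t] + b2
        if has_c2:
            net2 += X_cross @ h2s[t - 1]
        h2s[t] = sigmoid(g2 * net2) * alive2
        if t > N_INPUT_TICKS:
            outs[t] = sigmoid(W_out @ h2s[t] + b_out)

    loss = cross_entropy_loss(outs[N_INPUT_TICKS + 1:], features)

    # -- backward --------------------------------------------------------
    gW_in = np.zeros_like(W_in)
    gC_ctx = np.zeros_like(C_ctx)
    gC_cross = np.zeros_like(C_cross) if has_c1 else None
    gW_mid = np.zeros_like(W_mid)
    gX_cross = np.zeros_like(X_cross) if has_c2 else None
    gW_out = np.zeros_like(W_out)
    gb1 = np.zeros(nh)
    gb2 = np.zeros(nh)
    gb_out = np.zeros(cfg.n_io)

    bptt = cfg.backprop == "bptt"
    d_h1_next = np.zeros(nh)  # gradient reaching h1[t] via its context use at t+1
    d_h2_next = np.zeros(nh)
    first_tick = 1 if bptt else N_INPUT_TICKS + 1
    for t in range(N_TICKS, first_tick - 1, -1):
        h1, h2 = h1s[t], h2s[t]
        if t > N_INPUT_TICKS:
            d_out = outs[t] - features[t - N_INPUT_TICKS - 1]
            gW_out += np.outer(d_out, h2)
            gb_out += d_out
            d_h2 = W_out.T @ d_out
        else:
            d_h2 = np.zeros(nh)
        if bptt:
            d_h2 += d_h2_next
        d_h2 *= g2 * h2 * (1.0 - h2)
        gW_mid += np.outer(d_h2, h1)
        gb2 += d_h2
        if has_c2:
            gX_cross += np.outer(d_h2, h2s[t - 1])

        d_h1 = W_mid.T @ d_h2
        if bptt:
            d_h1 += d_h1_next
        d_h1 *= g1 * h1 * (1.0 - h1)
        if t <= N_INPUT_TICKS:
            gW_in += np.outer(d_h1, features[t - 1])
        gC_ctx += np.outer(d_h1, h1s[t - 1])
        gb1 += d_h1
        if has_c1:
            gC_cross += np.outer(d_h1, h1s[t - 1])

        if bptt:
            d_h1_next = C_ctx.T @ d_h1
            if has_c1:
                d_h1_next += C_cross.T @ d_h1
            d_h2_next = X_cross.T @ d_h2 if has_c2 else np.zeros(nh)

    grads = {"W_in": gW_in, "C_ctx": gC_ctx, "W_mid": gW_mid,
             "W_out": gW_out, "b1": gb1, "b2": gb2, "b_out": gb_out}
    if has_c1:
        grads["C_cross"] = gC_cross
    if has_c2:
        grads["X_cross"] = gX_cross
    return loss, grads


def train_step(state: NetworkState, features: np.ndarray,
               lr: float | None = None) -> float:
    """One word presentation: forward trial, backprop, single weight update.

    Gradients are accumulated over the six ticks (see
    :func:`compute_gradients`) and applied once, by plain gradient descent.
    Dead (lesioned) units receive no updates — their activations and error
    terms are clamped to zero, so their gradient blocks vanish.  Cross
    weights are re-projected onto their mask and sign constraint, and the
    block-diagonal arrays onto their structural mask (the dense outer
    products put gradient on structurally absent entries), after the
    update.  Returns the trial's cross-entropy loss.
    """
    cfg = state.config
    if lr is None:
        lr = cfg.learning_rate
    loss, grads = compute_gradients(state, features)
    blocks = state.weight_blocks()
    for name, g in grads.items():
        blocks[name] -= lr * g
    if "C_cross" in grads or "X_cross" in grads:
        _project_cross(state)
    diag = _block_diag_mask(cfg.n_left, cfg.n_right)
    state.C_ctx *= diag
    state.W_mid *= diag
    return loss


# -- checkpointing -------------------------------------------------------

def save_checkpoint(state: NetworkState, path: str | Path,
                    rng_state: dict | None = None) -> None:
    """Save all weights, masks, gains, and config to one ``.npz`` file."""
    cfg = state.config
    arrays = {k: v for k, v in state.weight_blocks().items()}
    arrays.update(
        M_cross1=state.M_cross1, M_cross2=state.M_cross2,
        alive1=state.alive1, alive2=state.alive2,
        g1=state.g1, g2=state.g2,
    )
    for layer, dead in state.lesioned_layers.items():
        arrays[f"dead_{layer}"] = dead
    import json
    meta = {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}
    if rng_state is not None:
        meta["rng_state"] = rng_state
    arrays["_meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8).copy()
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> NetworkState:
    import json
    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        meta.pop("rng_state", None)
        cfg = NetworkConfig(**meta)
        lesioned = {
            k[len("dead_"):]: z[k] for k in z.files if k.startswith("dead_")
        }
        state = NetworkState(
            config=cfg,
            W_in=z["W_in"], C_ctx=z["C_ctx"], C_cross=z["C_cross"],
            M_cross1=z["M_cross1"], W_mid=z["W_mid"], X_cross=z["X_cross"],
            M_cross2=z["M_cross2"], W_out=z["W_out"],
            b1=z["b1"], b2=z["b2"], b_out=z["b_out"],
            alive1=z["alive1"], alive2=z["alive2"],
            g1=z["g1"], g2=z["g2"], lesioned_layers=lesioned,
        )
    return state
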