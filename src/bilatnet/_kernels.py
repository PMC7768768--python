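"""Compiled inner training loop.

Online per-presentation weight updates cannot be batched, so the training
loop is a tight scalar loop; this module provides a numba-compiled kernel
that performs a block of presentations in place.  It implements exactly
the same forward/backward arithmetic as :func:`bilatnet.network.train_step`
(which remains the readable, finite-difference-checked reference); the two
paths agree up to floating-point summation order, and an equivalence test
holds them together.  If numba is unavailable the trainer falls back to
the reference implementation.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco


@njit(cache=False)
def _train_block_jit(idx, feats, W_in, C_ctx, C_cross, M1, W_mid, X_cross,
                     M2, W_out, b1, b2, b_out, alive1, alive2, g1, g2,
                     n_left, lr, has_c1, has_c2, bptt, neg_only):
    """Run len(idx) presentations in place; returns summed trial loss."""
    nh = W_in.shape[0]
    nio = W_in.shape[1]
    T = 6
    TI = 3
    h1s = np.zeros((T + 1, nh))
    h2s = np.zeros((T + 1, nh))
    outs = np.zeros((T + 1, nio))
    gW_in = np.zeros_like(W_in)
    gC_ctx = np.zeros_like(C_ctx)
    gC_cross = np.zeros_like(C_cross)
    gW_mid = np.zeros_like(W_mid)
    gX_cross = np.zeros_like(X_cross)
    gW_out = np.zeros_like(W_out)
    gb1 = np.zeros(nh)
    gb2 = np.zeros(nh)
    gb_out = np.zeros(nio)
    total_loss = 0.0

    for p in range(idx.shape[0]):
        F = feats[idx[p]]
        # forward
        h1s[0, :] = 0.0
        h2s[0, :] = 0.0
        for t in range(1, T + 1):
            net1 = np.dot(C_ctx, h1s[t - 1]) + b1
            if t <= TI:
                net1 += np.dot(W_in, F[t - 1])
            if has_c1:
                net1 += np.dot(C_cross, h1s[t - 1])
            for i in range(nh):
                h1s[t, i] = alive1[i] / (1.0 + np.exp(-g1[i] * net1[i]))
            net2 = np.dot(W_mid, h1s[t]) + b2
            if has_c2:
                net2 += np.dot(X_cross, h2s[t - 1])
            for i in range(nh):
                h2s[t, i] = alive2[i] / (1.0 + np.exp(-g2[i] * net2[i]))
            if t > TI:
                neto = np.dot(W_out, h2s[t]) + b_out
                for k in range(nio):
                    outs[t, k] = 1.0 / (1.0 + np.exp(-neto[k]))

        for t in range(TI + 1, T + 1):
            for k in range(nio):
                a = outs[t, k]
                if a < 1e-12:
                    a = 1e-12
                elif a > 1.0 - 1e-12:
                    a = 1.0 - 1e-12
                tau = F[t - TI - 1, k]
                total_loss -= tau * np.log(a) + (1.0 - tau) * np.log(1.0 - a)

        # backward
        gW_in[:, :] = 0.0
        gC_ctx[:, :] = 0.0
        gW_mid[:, :] = 0.0
        gW_out[:, :] = 0.0
        gb1[:] = 0.0
        gb2[:] = 0.0
        gb_out[:] = 0.0
        if has_c1:
            gC_cross[:, :] = 0.0
        if has_c2:
            gX_cross[:, :] = 0.0
        d_h1_next = np.zeros(nh)
        d_h2_next = np.zeros(nh)
        d_out = np.zeros(nio)
        first_tick = 1 if bptt else TI + 1
        for t in range(T, first_tick - 1, -1):
            if t > TI:
                for k in range(nio):
                    d_out[k] = outs[t, k] - F[t - TI - 1, k]
                for k in range(nio):
                    dk = d_out[k]
                    gb_out[k] += dk
                    for j in range(nh):
                        gW_out[k, j] += dk * h2s[t, j]
                d_h2 = np.dot(W_out.T, d_out)
            else:
                d_h2 = np.zeros(nh)
            if bptt:
                d_h2 += d_h2_next
            for i in range(nh):
                a = h2s[t, i]
                d_h2[i] *= g2[i] * a * (1.0 - a)
            for i in range(nh):
                di = d_h2[i]
                gb2[i] += di
                for j in range(nh):
                    gW_mid[i, j] += di * h1s[t, j]
            if has_c2:
                for i in range(nh):
                    di = d_h2[i]
                    for j in range(nh):
                        gX_cross[i, j] += di * h2s[t - 1, j]

            d_h1 = np.dot(W_mid.T, d_h2)
            if bptt:
                d_h1 += d_h1_next
            for i in range(nh):
                a = h1s[t, i]
                d_h1[i] *= g1[i] * a * (1.0 - a)
            for i in range(nh):
                di = d_h1[i]
                gb1[i] += di
                for j in range(nh):
                    gC_ctx[i, j] += di * h1s[t - 1, j]
            if has_c1:
                for i in range(nh):
                    di = d_h1[i]
                    for j in range(nh):
                        gC_cross[i, j] += di * h1s[t - 1, j]
            if t <= TI:
                for i in range(nh):
                    di = d_h1[i]
                    for k in range(nio):
                        gW_in[i, k] += di * F[t - 1, k]
            if bptt:
                d_h1_next = np.dot(C_ctx.T, d_h1)
                if has_c1:
                    d_h1_next += np.dot(C_cross.T, d_h1)
                if has_c2:
                    d_h2_next = np.dot(X_cross.T, d_h2)
                else:
                    d_h2_next[:] = 0.0

        # update; block-structure masks re-imposed
        W_in -= lr * gW_in
        W_out -= lr * gW_out
        b1 -= lr * gb1
        b2 -= lr * gb2
        b_out -= lr * gb_out
        for i in range(nh):
            lo = 0 if i < n_left else n_left
            hi = n_left if i < n_left else nh
            for j in range(lo, hi):
                C_ctx[i, j] -= lr * gC_ctx[i, j]
                W_mid[i, j] -= lr * gW_mid[i, j]
        if has_c1:
            for i in range(nh):
                for j in range(nh):
                    if M1[i, j]:
                        w = C_cross[i, j] - lr * gC_cross[i, j]
                        if neg_only and w > 0.0:
                            w = 0.0
                        C_cross[i, j] = w
        if has_c2:
            for i in range(nh):
                for j in range(nh):
                    if M2[i, j]:
                        w = X_cross[i, j] - lr * gX_cross[i, j]
                        if neg_only and w > 0.0:
                            w = 0.0
                        X_cross[i, j] = w
    return total_loss


def train_block(state, idx: np.ndarray, feats: np.ndarray,
                lr: float | None = None) -> float:
    """Apply ``len(idx)`` presentations to ``state`` in place.

    ``feats`` is the (n_words, 3, n_io) encoded lexicon and ``idx`` the
    presentation order.  Uses the compiled kernel when numba is present,
    otherwise the reference ``train_step`` loop.  Returns the summed loss.
    """
    from .network import train_step

    cfg = state.config
    if lr is None:
        lr = cfg.learning_rate
    if not HAVE_NUMBA:
        return float(sum(train_step(state, feats[i], lr=lr) for i in idx))
    return float(_train_block_jit(
        np.ascontiguousarray(idx, dtype=np.int64),
        np.ascontiguousarray(feats),
        state.W_in, state.C_ctx, state.C_cross, state.M_cross1,
        state.W_mid, state.X_cross, state.M_cross2, state.W_out,
        state.b1, state.b2, state.b_out, state.alive1, state.alive2,
        state.g1, state.g2, cfg.n_left, lr,
        bool(state.M_cross1.any()), bool(state.M_cross2.any()),
        cfg.backprop == "bptt", cfg.cross_constraint == "negative_only",
    ))
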