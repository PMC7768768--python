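"""Graded lesioning and the retraining (recovery) protocol.

A lesion removes a random proportion of a hidden layer's units (they are
clamped to zero activation and receive no further updates) and adds
one-time Gaussian noise to every weight into and out of the layer,
including those of surviving ("perilesional") units.  The standard
severity scheme pairs damage proportions 0.1..1.0 with noise levels
0.1..1.0.

Recovery re-exposes the lesioned model to the same training environment.
During the first 10,000 presentations the lesioned layer's units relearn
"inefficiently": their logistic gain follows a step ramp g = 0, 0.1, ...,
1.0, advancing every 1,000 presentations (gain 1.0 from 10,000 onward).
The trajectory records accuracy, per-pathway output activation, hidden
activations split into lesioned/perilesional populations, RSA scores, and
weight statistics at every checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .measures import (
    layer_rsa_scores,
    mean_hidden_activation,
    mean_output_activation,
    target_rdm,
    weight_statistics,
)
from .network import LAYERS, NetworkState, set_layer_gain
from .training import TrainingLog, train

RAMP_STEP_PRESENTATIONS = 1000
RAMP_STEPS = 10  # gain reaches 1.0 after RAMP_STEPS * RAMP_STEP_PRESENTATIONS
RECOVERY_PRESENTATIONS = 100_000
RECOVERY_EVAL_EVERY = 1000


@dataclass(frozen=True)
class LesionSpec:
    """One lesion condition: which layer, how many units, how much noise.

    ``noise_sd`` is the scale of the one-time additive Gaussian
    perturbation of the weights into and out of the layer.  Severity
    levels quoted for this manipulation are ambiguous between a
    standard-deviation and a variance reading; ``noise_as`` selects
    whether the value v is used as the standard deviation ("sd", default)
    or as a variance ("variance", i.e. sd = sqrt(v)).
    """

    layer: str  # "LH1" | "RH1"
    proportion: float
    noise_sd: float
    seed: int = 0
    noise_as: str = "sd"

    def __post_init__(self):
        if self.layer not in ("LH1", "RH1"):
            raise ValueError("lesions target LH1 or RH1")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise scale must be nonnegative")
        if self.noise_as not in ("sd", "variance"):
            raise ValueError("noise_as must be 'sd' or 'variance'")

    @property
    def sd(self) -> float:
        return self.noise_sd if self.noise_as == "sd" else float(np.sqrt(self.noise_sd))


@dataclass
class RecoveryTrajectory:
    """Checkpoint time series over a retraining run."""

    condition: str
    checkpoints: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.checkpoints)
        df.insert(0, "condition", self.condition)
        return df

    def series(self, key: str) -> np.ndarray:
        return np.array([c[key] for c in self.checkpoints])

    def to_csv(self, path, seed=None) -> None:
        df = self.to_frame()
        if seed is not None:
            df.insert(1, "seed", seed)
        df.to_csv(path, index=False)


def apply_lesion(state: NetworkState, spec: LesionSpec) -> NetworkState:
    """Lesion a hidden layer in place (returns the same state).

    A uniformly random subset of floor(proportion * n_live) currently live
    units is marked dead, and Gaussian noise of standard deviation
    ``spec.sd`` is added once to all structurally present weights into and
    out of the layer (biases excluded).  Dead units' weights are frozen by
    the zero-activation clamp; the lesion RNG is independent of training.
    """
    sl = state.layer_slice(spec.layer)
    alive = state.alive1  # lesionable layers are H1 only
    live_idx = np.flatnonzero(alive[sl] > 0) + sl.start
    if live_idx.size == 0:
        raise ValueError(f"layer {spec.layer} is already fully dead")
    rng = np.random.default_rng(spec.seed)
    n_dead = int(np.floor(spec.proportion * live_idx.size))
    dead = rng.choice(live_idx, size=n_dead, replace=False)
    dead.sort()
    alive[dead] = 0.0
    state.lesioned_layers[spec.layer] = dead

    sd = spec.sd
    if sd > 0:
        idx = np.arange(sl.start, sl.stop)
        # into the layer: input, context, cross, bias-side rows
        state.W_in[idx, :] += rng.normal(0, sd, (idx.size, state.config.n_io))
        state.C_ctx[idx, :] += rng.normal(0, sd, (idx.size, state.nh))
        # out of the layer: H1->H2 feedforward and H1 cross/context columns
        state.W_mid[:, idx] += rng.normal(0, sd, (state.nh, idx.size))
        state.C_ctx[:, idx] += rng.normal(0, sd, (state.nh, idx.size))
        if state.M_cross1.any():
            state.C_cross[idx, :] += rng.normal(0, sd, (idx.size, state.nh))
            state.C_cross[:, idx] += rng.normal(0, sd, (state.nh, idx.size))
        # re-impose structural masks and sign constraints
        from .network import _block_diag_mask, _project_cross
        diag = _block_diag_mask(state.config.n_left, state.config.n_right)
        state.C_ctx *= diag
        state.W_mid *= diag
        _project_cross(state)
    return state


def ramp_gain(presentations: int) -> float:
    """Gain of the lesioned layer at a given point in recovery."""
    return min(1.0, (presentations // RAMP_STEP_PRESENTATIONS) / RAMP_STEPS)


def trajectory_extras(lexicon: Lexicon, reference: NetworkState,
                      tgt_rdm=None):
    """Build a ``log_extras`` callback recording the recovery measures."""
    if tgt_rdm is None:
        tgt_rdm = target_rdm(lexicon)

    def extras(state: NetworkState) -> dict:
        row = {
            "out_act_left": mean_output_activation(state, lexicon, "left"),
            "out_act_right": mean_output_activation(state, lexicon, "right"),
        }
        for layer in LAYERS:
            if layer in state.lesioned_layers:
                row[f"hidden_act_{layer}_perilesional"] = (
                    mean_hidden_activation(state, lexicon, layer, "perilesional")
                    if state.layer_alive(layer).any() else float("nan"))
                row[f"hidden_act_{layer}_lesioned"] = mean_hidden_activation(
                    state, lexicon, layer, "lesioned")
            else:
                row[f"hidden_act_{layer}"] = mean_hidden_activation(
                    state, lexicon, layer, "all_live")
        for layer, score in layer_rsa_scores(state, lexicon, tgt_rdm).items():
            row[f"rsa_{layer}"] = score
        mean_w, mean_dw = weight_statistics(state, reference)
        row["mean_abs_weight"] = mean_w
        row["mean_abs_dweight"] = mean_dw
        return row

    return extras


def activation_extras(lexicon: Lexicon):
    """Lightweight ``log_extras``: pathway output activations only."""

    def extras(state: NetworkState) -> dict:
        return {
            "out_act_left": mean_output_activation(state, lexicon, "left"),
            "out_act_right": mean_output_activation(state, lexicon, "right"),
        }

    return extras


def retrain(state: NetworkState, lexicon: Lexicon,
            n_presentations: int = RECOVERY_PRESENTATIONS,
            ramp: bool = True,
            eval_every: int = RECOVERY_EVAL_EVERY,
            rng=None,
            reference: NetworkState | None = None,
            presentations_offset: int = 0,
            condition: str = "",
            extras=None) -> tuple[NetworkState, RecoveryTrajectory]:
    """Re-expose a lesioned model to its learning environment.

    Identical sampling and update regime as development training; the
    lesioned layer's gain follows the step ramp (unless ``ramp=False``,
    the ablation control).  ``reference`` is the pre-lesion snapshot used
    for the weight-change measure (defaults to the state at entry).
    The first checkpoint is at 0 presentations, immediately post-lesion.
    ``extras`` overrides the per-checkpoint measurement callback (default:
    the full :func:`trajectory_extras` battery).
    """
    if reference is None:
        reference = state.copy()
    lesioned = list(state.lesioned_layers)

    schedule = None
    if ramp and lesioned:
        def schedule(p: int) -> int:
            g = ramp_gain(p)
            for layer in lesioned:
                set_layer_gain(state, layer, g)
            if g >= 1.0:
                return n_presentations
            return RAMP_STEP_PRESENTATIONS - (p % RAMP_STEP_PRESENTATIONS)

    if extras is None:
        extras = trajectory_extras(lexicon, reference)
    state, log = train(state, lexicon, n_presentations,
                       eval_every=eval_every, rng=rng, log_extras=extras,
                       presentations_offset=presentations_offset,
                       gain_schedule=schedule)
    for layer in lesioned:  # leave the state with normal gain
        set_layer_gain(state, layer, 1.0)
    traj = RecoveryTrajectory(condition=condition, checkpoints=log.checkpoints)
    return state, traj


def standard_lesion_levels() -> list[tuple[float, float]]:
    """The ten paired (proportion, noise) severity levels."""
    return [(round(0.1 * k, 1), round(0.1 * k, 1)) for k in range(1, 11)]


def severity_group(proportion: float) -> str:
    if proportion <= 0.3:
        return "mild"
    if proportion <= 0.6:
        return "moderate"
    return "severe"
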