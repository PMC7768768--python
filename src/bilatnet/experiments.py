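"""Reproducible runners for the four studies, plus the statistics helpers.

Each runner trains (or reuses) models over a seed list and returns tidy
DataFrames; nothing is read from global state, so a runner's output is
fully determined by its configuration.  The four studies:

1. capacity sweep — five left/right capacity splits; laterality indices
   vs. the capacity asymmetry index;
2. lesion severity sweep — graded LH1/RH1 lesions, recovered accuracy;
3. recovery time-course — the four lesion conditions, with
   acute/subacute/chronic phase contrasts of pathway output activation;
4. interconnectivity — the same recovery conditions at several homotopic
   cross-connection densities, free or negative-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lesion import (
    LesionSpec,
    apply_lesion,
    retrain,
    severity_group,
    trajectory_extras,
)
from .lexicon import Lexicon, build_inventory, generate_lexicon
from .measures import (
    functional_contribution,
    laterality_index,
    mean_hidden_activation,
    mean_output_activation,
    target_rdm,
)
from .network import NetworkConfig, init_network
from .training import train

CAPACITY_PAIRS = [(15, 75), (30, 60), (45, 45), (60, 30), (75, 15)]
LESION_CONDITIONS = [  # (layer, proportion == noise level), Fig-3 conventions
    ("LH1", 0.2, "left_mild"),
    ("LH1", 0.5, "left_moderate"),
    ("LH1", 0.8, "left_severe"),
    ("RH1", 0.8, "right_severe"),
]
DEV_PRESENTATIONS = 300_000
RECOVERY_PRESENTATIONS = 100_000


@dataclass
class PhaseBins:
    """Recovery phases in presentations-into-retraining (half-open)."""

    acute: tuple[int, int] = (0, 1000)
    subacute: tuple[int, int] = (1000, 5000)
    chronic: tuple[int, int] = (5000, 40000)

    def __post_init__(self):
        spans = [self.acute, self.subacute, self.chronic]
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if b != c or a >= b or c >= d:
                raise ValueError("phase bins must be contiguous, ordered, "
                                 "non-overlapping")

    def items(self):
        return [("acute", self.acute), ("subacute", self.subacute),
                ("chronic", self.chronic)]


@dataclass
class ExperimentConfig:
    name: str = "experiment"
    capacity_pairs: list = field(default_factory=lambda: list(CAPACITY_PAIRS))
    lesion_conditions: list = field(default_factory=lambda: list(LESION_CONDITIONS))
    densities: list = field(default_factory=lambda: [0.0, 0.3, 0.7])
    cross_constraint: str = "free"
    seeds: list = field(default_factory=lambda: [1, 2, 3])
    dev_presentations: int = DEV_PRESENTATIONS
    recovery_presentations: int = RECOVERY_PRESENTATIONS
    dev_eval_every: int = 5000
    recovery_eval_every: int = 1000
    lexicon_seed: int = 0
    phase_bins: PhaseBins = field(default_factory=PhaseBins)
    output_dir: str | None = None

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("seed list must be nonempty")
        for cond in self.lesion_conditions:
            if cond[0] not in ("LH1", "RH1"):
                raise ValueError(f"unknown lesion layer {cond[0]!r}")

    def make_lexicon(self) -> Lexicon:
        inv = build_inventory(self.lexicon_seed)
        return generate_lexicon(inv, self.lexicon_seed)

    def write_manifest(self) -> None:
        if self.output_dir is None:
            return
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        d = asdict(self)
        d["phase_bins"] = {k: list(v) for k, v in self.phase_bins.items()}
        from . import __version__
        d["package_version"] = __version__
        (out / f"{self.name}_manifest.json").write_text(json.dumps(d, indent=1))


def _maybe_write(df: pd.DataFrame, config: ExperimentConfig, stem: str) -> None:
    if config.output_dir is not None:
        Path(config.output_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(config.output_dir) / f"{config.name}_{stem}.csv",
                  index=False)


def _train_intact(lexicon: Lexicon, n_left: int, n_right: int, seed: int,
                  n_presentations: int, eval_every: int = 0,
                  log_extras=None, cross_density: float = 0.0,
                  cross_constraint: str = "free"):
    """Develop one intact model; training RNG derived from the seed."""
    cfg = NetworkConfig(n_left=n_left, n_right=n_right, seed=seed,
                        cross_density=cross_density,
                        cross_constraint=cross_constraint)
    state = init_network(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    return train(state, lexicon, n_presentations, eval_every=eval_every,
                 rng=rng, log_extras=log_extras)


def run_capacity_sweep(config: ExperimentConfig):
    """Study 1: laterality follows capacity asymmetry.

    Returns (models DataFrame, correlations dict).  Correlations are
    Pearson r between the capacity asymmetry index (nL-nR)/(nL+nR) and the
    laterality index from each measure, pooled over all (pair, seed)
    models.
    """
    lexicon = config.make_lexicon()
    rows = []
    for n_left, n_right in config.capacity_pairs:
        for seed in config.seeds:
            state, log = _train_intact(lexicon, n_left, n_right, seed,
                                       config.dev_presentations)
            fc_l = functional_contribution(state, lexicon, "left")
            fc_r = functional_contribution(state, lexicon, "right")
            oa_l = mean_output_activation(state, lexicon, "left")
            oa_r = mean_output_activation(state, lexicon, "right")
            final = log.checkpoints[-1]
            rows.append(dict(
                n_left=n_left, n_right=n_right, seed=seed,
                asymmetry_index=laterality_index(n_left, n_right),
                li_functional=laterality_index(fc_l, fc_r),
                li_output_activation=laterality_index(oa_l, oa_r),
                fc_left=fc_l, fc_right=fc_r,
                out_act_left=oa_l, out_act_right=oa_r,
                hidden_act_LH1=mean_hidden_activation(state, lexicon, "LH1"),
                hidden_act_RH1=mean_hidden_activation(state, lexicon, "RH1"),
                accuracy_hf=final["accuracy_hf"],
                accuracy_lf=final["accuracy_lf"],
                accuracy_nw=final["accuracy_nw"],
            ))
    df = pd.DataFrame(rows)
    corr = {
        "r_functional": pearson_r(df.asymmetry_index, df.li_functional)[0],
        "r_output_activation": pearson_r(df.asymmetry_index,
                                         df.li_output_activation)[0],
    }
    _maybe_write(df, config, "capacity_sweep")
    config.write_manifest()
    return df, corr


def capacity_anova(df: pd.DataFrame) -> pd.DataFrame:
    """Word-type x model-type repeated-measures ANOVA over seeds."""
    from statsmodels.stats.anova import AnovaRM
    long = df.melt(
        id_vars=["n_left", "n_right", "seed"],
        value_vars=["accuracy_hf", "accuracy_lf", "accuracy_nw"],
        var_name="word_type", value_name="accuracy")
    long["model_type"] = long.n_left.astype(str) + "/" + long.n_right.astype(str)
    res = AnovaRM(long, "accuracy", "seed",
                  within=["word_type", "model_type"],
                  aggregate_func="mean").fit()
    return res.anova_table


def run_lesion_sweep(config: ExperimentConfig,
                     levels: list[float] | None = None,
                     intact_states: dict | None = None):
    """Study 2: recovered accuracy as a function of lesion severity.

    ``levels`` are the paired (proportion = noise) values; default the
    standard ten 0.1..1.0.  ``intact_states`` may supply pre-trained
    60/30 models keyed by seed (they are copied, never mutated).
    """
    if levels is None:
        levels = [round(0.1 * k, 1) for k in range(1, 11)]
    lexicon = config.make_lexicon()
    rows = []
    for seed in config.seeds:
        if intact_states is not None and seed in intact_states:
            intact = intact_states[seed]
        else:
            intact, _ = _train_intact(lexicon, 60, 30, seed,
                                      config.dev_presentations)
        from .training import evaluate
        rep = evaluate(intact, lexicon)
        rows.append(dict(side="intact", level=0.0, group="intact", seed=seed,
                         accuracy_words=rep.accuracy_words,
                         accuracy_nw=rep.accuracy_nw,
                         accuracy_overall=rep.accuracy_overall))
        for side in ("LH1", "RH1"):
            for level in levels:
                st = intact.copy()
                apply_lesion(st, LesionSpec(
                    side, level, level,
                    seed=_derived_seed(seed, side, level)))
                st, traj = retrain(
                    st, lexicon, config.recovery_presentations,
                    eval_every=config.recovery_presentations,
                    rng=np.random.default_rng(
                        np.random.SeedSequence(
                            [seed, 2, int(round(level * 10)),
                             0 if side == "LH1" else 1])),
                    condition=f"{side}_{level}")
                fin = traj.checkpoints[-1]
                rows.append(dict(
                    side=side, level=level, group=severity_group(level),
                    seed=seed, accuracy_words=fin["accuracy_words"],
                    accuracy_nw=fin["accuracy_nw"],
                    accuracy_overall=fin["accuracy_overall"]))
    df = pd.DataFrame(rows)
    _maybe_write(df, config, "lesion_sweep")
    config.write_manifest()
    return df


def _derived_seed(seed: int, side: str, level: float) -> int:
    return int(np.random.SeedSequence(
        [seed, 3, 0 if side == "LH1" else 1,
         int(round(level * 10))]).generate_state(1)[0] % (2**31))


def run_recovery_timecourse(config: ExperimentConfig,
                            intact_states: dict | None = None):
    """Study 3 (and the per-density part of study 4).

    For every lesion condition x seed: the full recovery trajectory; then
    phase-mean pathway output activations and paired-across-seeds phase
    contrasts (Bonferroni-corrected).

    Returns (trajectories DataFrame, phase-means DataFrame,
    contrasts DataFrame).
    """
    lexicon = config.make_lexicon()
    traj_frames = []
    phase_rows = []
    for seed in config.seeds:
        if intact_states is not None and seed in intact_states:
            intact = intact_states[seed]
        else:
            intact, _ = _train_intact(lexicon, 60, 30, seed,
                                      config.dev_presentations)
        pre = intact
        tgt = target_rdm(lexicon)
        for layer, level, condition in config.lesion_conditions:
            st = intact.copy()
            apply_lesion(st, LesionSpec(
                layer, level, level, seed=_derived_seed(seed, layer, level)))
            st, traj = retrain(
                st, lexicon, config.recovery_presentations,
                eval_every=config.recovery_eval_every,
                rng=np.random.default_rng(
                    np.random.SeedSequence([seed, 4, int(round(level * 10)),
                                            0 if layer == "LH1" else 1])),
                reference=pre, condition=condition)
            tf = traj.to_frame()
            tf.insert(1, "seed", seed)
            traj_frames.append(tf)
            row = dict(condition=condition, seed=seed)
            for phase, (lo, hi) in config.phase_bins.items():
                sel = tf[(tf.presentations > lo) & (tf.presentations <= hi)]
                row[f"left_{phase}"] = sel.out_act_left.mean()
                row[f"right_{phase}"] = sel.out_act_right.mean()
            phase_rows.append(row)
    trajectories = pd.concat(traj_frames, ignore_index=True)
    phases = pd.DataFrame(phase_rows)
    contrasts = phase_contrasts(phases)
    _maybe_write(trajectories, config, "recovery_trajectories")
    _maybe_write(phases, config, "recovery_phases")
    _maybe_write(contrasts, config, "recovery_phase_contrasts")
    config.write_manifest()
    return trajectories, phases, contrasts


def phase_contrasts(phases: pd.DataFrame) -> pd.DataFrame:
    """Paired tests across seeds for the two phase transitions, per side.

    For each condition: (subacute - acute) and (chronic - subacute) of the
    left and right pathway output activations, paired t-tests over seeds,
    Bonferroni-corrected within condition (4 tests).
    """
    rows = []
    for condition, grp in phases.groupby("condition", sort=False):
        tests = []
        for side in ("left", "right"):
            for a, b, name in (("acute", "subacute", "subacute_minus_acute"),
                               ("subacute", "chronic", "chronic_minus_subacute")):
                x = grp[f"{side}_{b}"].to_numpy()
                y = grp[f"{side}_{a}"].to_numpy()
                t, p = paired_t(x, y)
                tests.append(dict(condition=condition, side=side,
                                  contrast=name, mean_diff=float(np.mean(x - y)),
                                  t=t, p=p))
        padj = bonferroni([d["p"] for d in tests])
        for d, pa in zip(tests, padj):
            d["p_bonferroni"] = pa
            rows.append(d)
    return pd.DataFrame(rows)


def run_interconnectivity(config: ExperimentConfig):
    """Study 4: repeat development + recovery across cross-densities.

    Returns (trajectories DataFrame, cross-weight summary DataFrame).
    A density of 0 reproduces the baseline runner exactly (the same seeds
    give bit-identical models).
    """
    lexicon = config.make_lexicon()
    traj_frames = []
    weight_rows = []
    for density in config.densities:
        for seed in config.seeds:
            state, _ = _train_intact(
                lexicon, 60, 30, seed, config.dev_presentations,
                cross_density=density,
                cross_constraint=config.cross_constraint)
            cw = np.concatenate([state.C_cross[state.M_cross1],
                                 state.X_cross[state.M_cross2]])
            if cw.size:
                weight_rows.append(dict(
                    density=density, seed=seed, n_cross=cw.size,
                    mean_cross=float(cw.mean()),
                    mean_abs_cross=float(np.abs(cw).mean()),
                    frac_near_zero=float((np.abs(cw) < 0.1).mean()),
                    max_cross=float(cw.max())))
            pre = state
            for layer, level, condition in config.lesion_conditions:
                st = state.copy()
                apply_lesion(st, LesionSpec(
                    layer, level, level,
                    seed=_derived_seed(seed, layer, level)))
                st, traj = retrain(
                    st, lexicon, config.recovery_presentations,
                    eval_every=config.recovery_eval_every,
                    rng=np.random.default_rng(
                        np.random.SeedSequence([seed, 4,
                                                int(round(level * 10)),
                                                0 if layer == "LH1" else 1])),
                    reference=pre, condition=condition)
                tf = traj.to_frame()
                tf.insert(0, "density", density)
                tf.insert(2, "seed", seed)
                traj_frames.append(tf)
    trajectories = pd.concat(traj_frames, ignore_index=True)
    weights = pd.DataFrame(weight_rows)
    _maybe_write(trajectories, config, "interconnectivity_trajectories")
    _maybe_write(weights, config, "interconnectivity_cross_weights")
    config.write_manifest()
    return trajectories, weights


def correlate_measures(frame: pd.DataFrame,
                       min_checkpoints: int = 10) -> pd.DataFrame:
    """Correlations of accuracy with activation and RSA measures.

    ``frame`` is a trajectory/log DataFrame with checkpoints (pooled
    across seeds if a ``seed`` column is present).  Returns one row per
    measure with Pearson r, p, and a significance star column; zero-
    variance series are flagged as undefined rather than reported as 0.
    """
    if len(frame) < min_checkpoints:
        raise ValueError(f"need at least {min_checkpoints} checkpoints, "
                         f"got {len(frame)}")
    measure_cols = {
        "L output unit act": "out_act_left",
        "R output unit act": "out_act_right",
        "L RSA H2": "rsa_LH2",
        "R RSA H2": "rsa_RH2",
        "L RSA H1": "rsa_LH1",
        "R RSA H1": "rsa_RH1",
    }
    acc = frame["accuracy_overall"].to_numpy(dtype=float)
    rows = []
    for label, col in measure_cols.items():
        if col not in frame:
            continue
        v = frame[col].to_numpy(dtype=float)
        ok = np.isfinite(acc) & np.isfinite(v)
        if ok.sum() < 3 or np.std(acc[ok]) == 0 or np.std(v[ok]) == 0:
            rows.append(dict(measure=label, r=float("nan"), p=float("nan"),
                             stars="undefined", n=int(ok.sum())))
            continue
        r, p = pearson_r(acc[ok], v[ok])
        stars = "***" if p < 0.001 else "*" if p < 0.05 else ""
        rows.append(dict(measure=label, r=r, p=p, stars=stars, n=int(ok.sum())))
    return pd.DataFrame(rows)


# -- statistics helpers ---------------------------------------------------

def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p."""
    r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test; t = 0, p = 1 for identical samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.allclose(x, y):
        return 0.0, 1.0
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def bonferroni(p_list) -> list[float]:
    """Bonferroni adjustment, clipped at 1."""
    n = len(p_list)
    return [min(1.0, float(p) * n) for p in p_list]
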