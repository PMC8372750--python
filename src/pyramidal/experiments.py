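"""Train / freeze / test protocols and parameter sweeps.

Both experiments follow the same arc: train a neuron with all adaptation
active (weights, biases, gains, running averages) on a long input
stream, then freeze every adaptive variable and evaluate on an
independent test batch drawn from the same fixed geometry.

* Alignment: the test metric is the Pearson correlation rho[I_p, I_d]
  between the realized proximal and distal currents — how well Hebbian
  learning aligned the basal read-out with the apical teaching signal.
* Classification: two independent neurons receive the same basal input,
  each apically driven by one component of the one-hot target; at test
  time the apical input is turned off and the neuron with the higher
  rate predicts the class.

:func:`sweep` runs full factorial grids over the distraction scale
``s``, the distractor count ``n_dist``, the neuron model and the
plasticity rule, and summarizes each ``n_dist`` row by the sum of the
seed-averaged metric over ``s`` (the "sigma over s" bar of the
heatmap figures).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .adaptation import BCMParams, HebbParams, HomeostasisParams, HomeostasisState
from .model_core import TransferParams, compartment_rate, point_rate, sigmoid
from .synthetic_inputs import (
    AlignmentTaskSpec,
    ClassificationTaskSpec,
    alignment_batch,
    classification_batch,
)

logger = logging.getLogger(__name__)

MODELS = ("compartment", "point")
RULES = ("hebb", "bcm")

__all__ = [
    "TrainConfig",
    "AlignmentRun",
    "ClassificationRun",
    "SweepResult",
    "default_plasticity",
    "run_alignment",
    "run_classification",
    "pearson",
    "sweep",
    "cell_seed",
]


def default_plasticity(
    rule: str, model: str, transfer: TransferParams
) -> HebbParams | BCMParams:
    """Reference plasticity parameters for a model/rule combination.

    The BCM threshold is fixed at the midpoint (1 + alpha)/2 between the
    plateau and burst rates for the compartment model, and slides as the
    running mean of y**2 for the point model, where no plateau midpoint
    exists.
    """
    if rule == "hebb":
        return HebbParams()
    if rule == "bcm":
        if model == "compartment":
            return BCMParams(
                threshold_mode="fixed", theta_M_fixed=(1.0 + transfer.alpha) / 2.0
            )
        return BCMParams(threshold_mode="sliding")
    raise ValueError(f"unknown rule {rule!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Everything a single train/freeze/test run needs besides the task.

    ``seed`` drives the weight initialization and the train/test sample
    draws (the task geometry has its own seed in the task spec).
    ``apical_off`` selects how the distal drive is silenced during
    classification testing: ``"clamp"`` pins I_d three units below the
    distal threshold (and drops the I_d term for the point model);
    ``"zero_signal"`` feeds x_d = 0 through the frozen gain and bias.
    """

    model: str = "compartment"
    rule: str = "hebb"
    T_train: int = 1_000_000
    T_test: int = 20_000
    transfer: TransferParams = field(default_factory=TransferParams)
    homeo: HomeostasisParams = field(default_factory=HomeostasisParams)
    plast: HebbParams | BCMParams | None = None
    seed: int = 0
    apical_off: str = "clamp"
    engine: str = "fused"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if self.T_train < 1 or self.T_test < 1:
            raise ValueError("T_train and T_test must be >= 1")
        if self.apical_off not in ("clamp", "zero_signal"):
            raise ValueError("apical_off must be 'clamp' or 'zero_signal'")

    def plasticity(self) -> HebbParams | BCMParams:
        return (
            self.plast
            if self.plast is not None
            else default_plasticity(self.rule, self.model, self.transfer)
        )


@dataclass
class AlignmentRun:
    """Outcome of one alignment run: the test correlation plus the
    final adaptation state and end-of-training current statistics
    (mean/variance over the last window of training steps)."""

    rho: float
    weights: np.ndarray
    homeo: HomeostasisState
    train_stats: dict[str, float]


@dataclass
class ClassificationRun:
    """Outcome of one classification run.

    ``accuracy`` is measured apical-off; ``rho_on`` holds each neuron's
    correlation rho[I_p, I_d] on an apical-ON frozen batch (the
    alignment metric reused as a supplementary learning measure).
    """

    accuracy: float
    rho_on: tuple[float, float]
    weights: tuple[np.ndarray, np.ndarray]
    homeo: tuple[HomeostasisState, HomeostasisState]
    train_stats: tuple[dict[str, float], dict[str, float]]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; 0 (with a warning) if either series
    has zero variance, so degenerate runs score as unaligned rather
    than erroring out."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("pearson needs two equal-length 1-d series of length >= 2")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("zero-variance series: correlation undefined, reporting 0")
        return 0.0
    return float(stats.pearsonr(x, y).statistic)


def _train(xp, xd, cfg: TrainConfig, w0) -> _engine.Trajectory:
    runner = _engine.fused_train if cfg.engine == "fused" else _engine.stepwise_train
    return runner(
        xp,
        xd,
        w0,
        model=cfg.model,
        rule=cfg.rule,
        transfer=cfg.transfer,
        homeo_params=cfg.homeo,
        plast_params=cfg.plasticity(),
    )


def _frozen_currents(xp, xd, homeo: HomeostasisState, w):
    I_p = homeo.n_p * (xp @ w) - homeo.b_p
    I_d = homeo.n_d * xd - homeo.b_d
    return I_p, I_d


def _train_window_stats(traj: _engine.Trajectory, window: int = 10_000) -> dict:
    sl = slice(-min(window, traj.I_p.size), None)
    return {
        "I_p_mean": float(traj.I_p[sl].mean()),
        "I_p_var": float(traj.I_p[sl].var()),
        "I_d_mean": float(traj.I_d[sl].mean()),
        "I_d_var": float(traj.I_d[sl].var()),
    }


def _run_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n)]


def run_alignment(spec: AlignmentTaskSpec, cfg: TrainConfig) -> AlignmentRun:
    """Train on the alignment task, then measure rho[I_p, I_d] frozen.

    Weights start i.i.d. N(0, 1/N) so the initial proximal current is of
    order one; training runs with all adaptation active; the test batch
    is an independent draw from the same geometry, evaluated with every
    adaptive variable frozen.
    """
    w_seed, train_seed, test_seed = _run_seeds(cfg.seed, 3)
    rng = np.random.default_rng(w_seed)
    w0 = rng.standard_normal(spec.N) / np.sqrt(spec.N)

    xp, xd = alignment_batch(spec, cfg.T_train, train_seed)
    traj = _train(xp, xd, cfg, w0)

    xp_test, xd_test = alignment_batch(spec, cfg.T_test, test_seed)
    I_p, I_d = _frozen_currents(xp_test, xd_test, traj.homeo, traj.plast.w)
    return AlignmentRun(
        rho=pearson(I_p, I_d),
        weights=traj.plast.w,
        homeo=traj.homeo,
        train_stats=_train_window_stats(traj),
    )


def _apical_off_rates(I_p: np.ndarray, cfg: TrainConfig, homeo: HomeostasisState):
    if cfg.apical_off == "clamp":
        if cfg.model == "compartment":
            I_d = np.full_like(I_p, cfg.transfer.theta_d - 3.0)
            return compartment_rate(I_p, I_d, cfg.transfer)
        return sigmoid(I_p - cfg.transfer.theta_point)
    # zero_signal: x_d = 0 through the frozen gain and bias
    I_d = np.full_like(I_p, -homeo.b_d)
    rate = compartment_rate if cfg.model == "compartment" else point_rate
    return rate(I_p, I_d, cfg.transfer)


def run_classification(
    spec: ClassificationTaskSpec, cfg: TrainConfig
) -> ClassificationRun:
    """Train the two-neuron one-hot classifier, then test apical-off.

    The two output neurons share the basal input stream but are fully
    independent otherwise (separate weights, homeostasis and plasticity
    state); neuron k is apically driven by the one-hot component x_d,k.
    At test time adaptation is frozen and the apical drive silenced; the
    neuron with the higher rate predicts the class (ties, a measure-zero
    event, go to class 0). The per-neuron correlation rho[I_p, I_d] is
    also measured on the same frozen batch with the apical drive ON.
    """
    w0_seed, w1_seed, train_seed, test_seed = _run_seeds(cfg.seed, 4)
    xp, _, xd0, xd1 = classification_batch(spec, cfg.T_train, train_seed)

    trajs = []
    for w_seed, xd in ((w0_seed, xd0), (w1_seed, xd1)):
        rng = np.random.default_rng(w_seed)
        w0 = rng.standard_normal(spec.N) / np.sqrt(spec.N)
        trajs.append(_train(xp, xd, cfg, w0))

    xp_t, labels, xd0_t, xd1_t = classification_batch(spec, cfg.T_test, test_seed)
    rates = []
    rho_on = []
    for traj, xd_t in zip(trajs, (xd0_t, xd1_t)):
        I_p, I_d = _frozen_currents(xp_t, xd_t, traj.homeo, traj.plast.w)
        rates.append(_apical_off_rates(I_p, cfg, traj.homeo))
        rho_on.append(pearson(I_p, I_d))
    pred = (rates[1] > rates[0]).astype(int)
    return ClassificationRun(
        accuracy=float(np.mean(pred == labels)),
        rho_on=(rho_on[0], rho_on[1]),
        weights=(trajs[0].plast.w, trajs[1].plast.w),
        homeo=(trajs[0].homeo, trajs[1].homeo),
        train_stats=(_train_window_stats(trajs[0]), _train_window_stats(trajs[1])),
    )


def cell_seed(master_seed: int, *parts) -> int:
    """Stable per-cell seed derived from the master seed and the cell
    coordinates, so any sweep cell can be reproduced in isolation."""
    key = ":".join(str(p) for p in (master_seed, *parts)).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "little") % (
        2**31
    )


@dataclass
class SweepResult:
    """Tidy grid of scalar outcomes from a factorial sweep.

    ``table`` has one row per (model, rule, s, n_dist, seed) cell with
    columns task/metric/value; failed cells carry NaN.
    """

    table: pd.DataFrame
    metric: str

    def seed_mean(self) -> pd.DataFrame:
        """Seed-averaged metric per (model, rule, n_dist, s)."""
        return (
            self.table.groupby(["model", "rule", "n_dist", "s"])["value"]
            .mean()
            .reset_index()
        )

    def sigma_over_s(self) -> pd.DataFrame:
        """Sum of the seed-averaged metric over the s grid, per
        (model, rule, n_dist) — the bar-plot summary of a heatmap row."""
        m = self.seed_mean()
        out = (
            m.groupby(["model", "rule", "n_dist"])["value"]
            .sum()
            .reset_index()
            .rename(columns={"value": "sigma_acc"})
        )
        return out


def sweep(
    task: str,
    s_values,
    ndist_values,
    models=MODELS,
    rules=RULES,
    seeds=(0,),
    *,
    N: int = 100,
    T_train: int = 1_000_000,
    T_test: int = 20_000,
    sigma_a: float = 0.25,
    transfer: TransferParams | None = None,
    homeo: HomeostasisParams | None = None,
    apical_off: str = "clamp",
    engine: str = "fused",
) -> SweepResult:
    """Full factorial sweep over (s, n_dist, model, rule, seed).

    ``task`` is ``"alignment"`` (metric: pearson_rho) or
    ``"classification"`` (metric: accuracy). Each cell draws its own
    geometry and samples from :func:`cell_seed`; a failing cell is
    logged and recorded as NaN rather than aborting the sweep.
    """
    if task not in ("alignment", "classification"):
        raise ValueError(f"task must be 'alignment' or 'classification', got {task!r}")
    if not (len(list(s_values)) and len(list(ndist_values)) and len(list(seeds))):
        raise ValueError("s_values, ndist_values and seeds must be nonempty")
    transfer = transfer if transfer is not None else TransferParams()
    homeo = homeo if homeo is not None else HomeostasisParams()
    metric = "pearson_rho" if task == "alignment" else "accuracy"

    rows = []
    for model in models:
        for rule in rules:
            for n_dist in ndist_values:
                for s in s_values:
                    for seed in seeds:
                        cs = cell_seed(seed, task, model, rule, s, n_dist)
                        try:
                            cfg = TrainConfig(
                                model=model,
                                rule=rule,
                                T_train=T_train,
                                T_test=T_test,
                                transfer=transfer,
                                homeo=homeo,
                                seed=cs,
                                apical_off=apical_off,
                                engine=engine,
                            )
                            if task == "alignment":
                                spec = AlignmentTaskSpec.create(N, n_dist, s, seed=cs)
                                value = run_alignment(spec, cfg).rho
                            else:
                                spec = ClassificationTaskSpec.create(
                                    N, n_dist, s, seed=cs, sigma_a=sigma_a
                                )
                                value = run_classification(spec, cfg).accuracy
                        except Exception:
                            logger.exception(
                                "sweep cell failed: %s %s %s s=%s n_dist=%s seed=%s",
                                task, model, rule, s, n_dist, seed,
                            )
                            value = np.nan
                        rows.append(
                            {
                                "task": task,
                                "model": model,
                                "rule": rule,
                                "s": float(s),
                                "n_dist": int(n_dist),
                                "seed": int(seed),
                                "metric": metric,
                                "value": value,
                            }
                        )
    return SweepResult(table=pd.DataFrame(rows), metric=metric)
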