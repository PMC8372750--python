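"""Stateful per-timestep update rules.

Dual homeostasis keeps the proximal and distal input currents

    I_p(t) = n_p(t) * w(t) . x_p(t) - b_p(t)
    I_d(t) = n_d(t) * x_d(t)        - b_d(t)

near preset mean and variance targets by adapting the biases ``b`` and
gains ``n``; two local plasticity rules (a Linsker-style Hebbian rule with
trailing-average reference levels, and a BCM rule) adapt the basal
weights ``w``.

All step functions are pure: they take a state, return a new state, and
never mutate their arguments. Within one simulated timestep the
composition order is: rate evaluation, plasticity, bias step, gain step;
trailing averages consumed inside a step are the values from before that
step's sample is folded in. The fused training loop in
:mod:`pyramidal._engine` replays exactly this composition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HomeostasisParams",
    "HomeostasisState",
    "HebbParams",
    "BCMParams",
    "PlasticityState",
    "running_average_step",
    "bias_step",
    "gain_step",
    "hebbian_step",
    "bcm_step",
    "init_homeostasis_state",
    "init_plasticity_state",
]


@dataclass(frozen=True)
class HomeostasisParams:
    """Rates and targets of the dual homeostatic controller.

    ``mu_b`` adapts the biases toward the mean-current targets
    ``I_p_target`` / ``I_d_target``; ``mu_n`` adapts the gains toward the
    variance targets ``V_p_target`` / ``V_d_target``; ``mu_av`` is the
    rate of the low-pass current averages used by the gain rule.
    Defaults are the reference operating point: zero-mean currents with
    variance 0.25, i.e. fluctuations of order 0.5 around threshold.
    """

    mu_b: float = 1e-3
    mu_n: float = 1e-4
    mu_av: float = 5e-3
    I_p_target: float = 0.0
    I_d_target: float = 0.0
    V_p_target: float = 0.25
    V_d_target: float = 0.25

    def __post_init__(self) -> None:
        for name in ("mu_b", "mu_n", "mu_av"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.V_p_target <= 0 or self.V_d_target <= 0:
            raise ValueError("variance targets must be positive")


@dataclass(frozen=True)
class HomeostasisState:
    """Biases, gains and low-pass current averages for one neuron."""

    b_p: float = 0.0
    b_d: float = 0.0
    n_p: float = 1.0
    n_d: float = 1.0
    Itilde_p: float = 0.0
    Itilde_d: float = 0.0


@dataclass(frozen=True)
class HebbParams:
    """Hebbian rule parameters: learning rate, decay, averaging rate.

    The proportional decay ``epsilon * w`` bounds the weights; ``mu_av``
    sets the timescale of the trailing pre/post averages that act as
    activity reference levels.
    """

    mu_w: float = 5e-5
    epsilon: float = 0.1
    mu_av: float = 5e-3

    def __post_init__(self) -> None:
        if self.mu_w <= 0 or self.epsilon <= 0:
            raise ValueError("mu_w and epsilon must be positive")


@dataclass(frozen=True)
class BCMParams:
    """BCM rule parameters.

    ``threshold_mode='fixed'`` pins the LTP/LTD threshold at
    ``theta_M_fixed`` — for the compartment model the natural choice is
    the midpoint (1 + alpha) / 2 between the plateau and burst rates, so
    potentiation requires coincident apical drive. ``'sliding'`` uses the
    Law–Cooper running average of y**2 (rate ``mu_av``), appropriate for
    the point model where no such midpoint exists.
    """

    mu_w: float = 5e-5
    epsilon: float = 0.1
    threshold_mode: str = "fixed"
    theta_M_fixed: float = 0.65
    mu_av: float = 5e-3

    def __post_init__(self) -> None:
        if self.mu_w <= 0 or self.epsilon <= 0:
            raise ValueError("mu_w and epsilon must be positive")
        if self.threshold_mode not in ("fixed", "sliding"):
            raise ValueError(
                f"threshold_mode must be 'fixed' or 'sliding', got {self.threshold_mode!r}"
            )


@dataclass(frozen=True)
class PlasticityState:
    """Basal weights plus the trailing averages the rules reference.

    ``theta_M_sliding`` is only consulted by the sliding-threshold BCM
    variant; it is carried (and updated) regardless so that state objects
    are interchangeable between rules.
    """

    w: np.ndarray
    xtilde_p: np.ndarray
    ytilde: float
    theta_M_sliding: float = 0.0

    def __post_init__(self) -> None:
        if self.w.shape != self.xtilde_p.shape:
            raise ValueError("w and xtilde_p must have the same length")


def running_average_step(avg, sample, mu_av: float):
    """One step of the low-pass filter ``(1 - mu) * avg + mu * sample``.

    A convex combination for ``mu_av`` in (0, 1]; a constant sample
    stream is approached geometrically at rate ``1 - mu_av``.
    """
    if not 0.0 < mu_av <= 1.0:
        raise ValueError(f"mu_av must lie in (0, 1], got {mu_av}")
    avg = np.asarray(avg, dtype=float)
    sample = np.asarray(sample, dtype=float)
    if avg.shape != sample.shape:
        raise ValueError("avg and sample must have the same shape")
    out = (1.0 - mu_av) * avg + mu_av * sample
    return out if out.ndim else float(out)


def bias_step(
    state: HomeostasisState, I_p: float, I_d: float, params: HomeostasisParams
) -> HomeostasisState:
    """Move each bias so the mean current approaches its target.

    ``b += mu_b * (I - I_target)``: a current above target raises the
    (subtractive) bias, pulling the realized mean down, and vice versa.
    """
    return replace(
        state,
        b_p=state.b_p + params.mu_b * (I_p - params.I_p_target),
        b_d=state.b_d + params.mu_b * (I_d - params.I_d_target),
    )


def gain_step(
    state: HomeostasisState, I_p: float, I_d: float, params: HomeostasisParams
) -> HomeostasisState:
    """Synaptic-scaling step toward the variance targets.

    ``n += mu_n * (V_target - (I - Itilde)**2)`` nudges each gain by the
    gap between the target variance and the instantaneous squared
    deviation from the running mean; then the running means are updated.
    Gains are clamped at >= 0 (the rule is sign-symmetric in n and could
    otherwise settle at a negative scaling).
    """
    n_p = state.n_p + params.mu_n * (params.V_p_target - (I_p - state.Itilde_p) ** 2)
    n_d = state.n_d + params.mu_n * (params.V_d_target - (I_d - state.Itilde_d) ** 2)
    return replace(
        state,
        n_p=max(n_p, 0.0),
        n_d=max(n_d, 0.0),
        Itilde_p=running_average_step(state.Itilde_p, I_p, params.mu_av),
        Itilde_d=running_average_step(state.Itilde_d, I_d, params.mu_av),
    )


def hebbian_step(
    pstate: PlasticityState, x_p: np.ndarray, y: float, params: HebbParams
) -> PlasticityState:
    """Hebbian update with trailing-average reference levels.

    ``w_i += mu_w * [(x_i - xtilde_i)(y - ytilde) - epsilon * w_i]``:
    pre and post are counted as active when above their own trailing
    averages, and the proportional decay prevents runaway growth. The
    weight update uses the averages from before this step's sample is
    folded in; the averages are advanced afterwards.
    """
    x_p = np.asarray(x_p, dtype=float)
    if x_p.shape != pstate.w.shape:
        raise ValueError(f"x_p has shape {x_p.shape}, expected {pstate.w.shape}")
    dw = (x_p - pstate.xtilde_p) * (y - pstate.ytilde) - params.epsilon * pstate.w
    return replace(
        pstate,
        w=pstate.w + params.mu_w * dw,
        xtilde_p=running_average_step(pstate.xtilde_p, x_p, params.mu_av),
        ytilde=running_average_step(pstate.ytilde, y, params.mu_av),
    )


def bcm_step(
    pstate: PlasticityState, x_p: np.ndarray, y: float, params: BCMParams
) -> PlasticityState:
    """BCM update ``w_i += mu_w * [y (y - theta_M) x_i - epsilon * w_i]``.

    Post-rates above the threshold ``theta_M`` potentiate active inputs
    (LTP), rates below depress them (LTD). In sliding mode the threshold
    tracks the running mean of ``y**2`` and is advanced after the weight
    update, at rate ``mu_av``.
    """
    x_p = np.asarray(x_p, dtype=float)
    if x_p.shape != pstate.w.shape:
        raise ValueError(f"x_p has shape {x_p.shape}, expected {pstate.w.shape}")
    theta_M = (
        pstate.theta_M_sliding
        if params.threshold_mode == "sliding"
        else params.theta_M_fixed
    )
    dw = y * (y - theta_M) * x_p - params.epsilon * pstate.w
    return replace(
        pstate,
        w=pstate.w + params.mu_w * dw,
        theta_M_sliding=running_average_step(
            pstate.theta_M_sliding, y * y, params.mu_av
        ),
    )


def init_homeostasis_state(first_I_p: float, first_I_d: float) -> HomeostasisState:
    """Fresh state with biases 0, gains 1 and running averages seeded
    from the first observed currents (avoids a transient from an
    arbitrary zero start)."""
    return HomeostasisState(
        Itilde_p=float(first_I_p), Itilde_d=float(first_I_d)
    )


def init_plasticity_state(
    w: np.ndarray, first_x_p: np.ndarray, first_y: float
) -> PlasticityState:
    """Fresh plasticity state with trailing averages seeded from the
    first observed sample; the sliding BCM threshold starts at y**2."""
    w = np.asarray(w, dtype=float)
    return PlasticityState(
        w=w.copy(),
        xtilde_p=np.asarray(first_x_p, dtype=float).copy(),
        ytilde=float(first_y),
        theta_M_sliding=float(first_y) ** 2,
    )
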