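"""Training-loop engines.

The per-timestep dynamics are inherently sequential (every update reads
state written by the previous step), so the hot path is a fused,
numba-compiled loop. A pure-Python reference that literally composes the
step functions from :mod:`pyramidal.adaptation` and the transfer
functions from :mod:`pyramidal.model_core` is kept alongside; the test
suite asserts the two trajectories agree, so the compiled loop is never
the sole definition of the dynamics.

Within one timestep both engines apply, in order: current composition,
rate evaluation, plasticity, bias step, gain step. Trailing averages
consumed by a rule are the pre-step values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .adaptation import (
    BCMParams,
    HebbParams,
    HomeostasisParams,
    HomeostasisState,
    PlasticityState,
    bcm_step,
    bias_step,
    gain_step,
    hebbian_step,
    init_homeostasis_state,
    init_plasticity_state,
)
from .model_core import TransferParams, compartment_rate, point_rate

MODEL_COMPARTMENT = 0
MODEL_POINT = 1
RULE_HEBB = 0
RULE_BCM_FIXED = 1
RULE_BCM_SLIDING = 2


@dataclass
class Trajectory:
    """Recorded currents and rates plus the final adaptation state."""

    I_p: np.ndarray
    I_d: np.ndarray
    y: np.ndarray
    homeo: HomeostasisState
    plast: PlasticityState


@njit(cache=False)
def _train_loop(
    xp,
    xd,
    w,
    hs,  # [b_p, b_d, n_p, n_d, Itilde_p, Itilde_d]
    xt,
    ps,  # [ytilde, theta_M_sliding]
    theta_p0,
    theta_p1,
    theta_d,
    alpha,
    theta_point,
    mu_b,
    mu_n,
    mu_av,
    I_p_target,
    I_d_target,
    V_p_target,
    V_d_target,
    mu_w,
    epsilon,
    theta_M_fixed,
    model_id,
    rule_id,
    plastic,
    adapt,
    seed_averages,
    Ip_out,
    Id_out,
    y_out,
):
    T = xp.shape[0]
    N = xp.shape[1]
    for t in range(T):
        x = xp[t]
        I_p = hs[2] * np.dot(w, x) - hs[0]
        I_d = hs[3] * xd[t] - hs[1]
        if model_id == MODEL_COMPARTMENT:
            sp0 = 1.0 / (1.0 + np.exp(-4.0 * (I_p - theta_p0)))
            sp1 = 1.0 / (1.0 + np.exp(-4.0 * (I_p - theta_p1)))
            gate = 1.0 / (1.0 + np.exp(-4.0 * (I_d - theta_d)))
            y = alpha * sp0 * (1.0 - gate) + gate * sp1
        else:
            y = 1.0 / (1.0 + np.exp(-4.0 * (I_p + I_d - theta_point)))
        Ip_out[t] = I_p
        Id_out[t] = I_d
        y_out[t] = y

        if t == 0 and seed_averages:
            hs[4] = I_p
            hs[5] = I_d
            for i in range(N):
                xt[i] = x[i]
            ps[0] = y
            ps[1] = y * y

        if plastic:
            if rule_id == RULE_HEBB:
                for i in range(N):
                    w[i] = w[i] + mu_w * (
                        (x[i] - xt[i]) * (y - ps[0]) - epsilon * w[i]
                    )
                for i in range(N):
                    xt[i] = (1.0 - mu_av) * xt[i] + mu_av * x[i]
                ps[0] = (1.0 - mu_av) * ps[0] + mu_av * y
            else:
                theta_M = ps[1] if rule_id == RULE_BCM_SLIDING else theta_M_fixed
                for i in range(N):
                    w[i] = w[i] + mu_w * (y * (y - theta_M) * x[i] - epsilon * w[i])
                ps[1] = (1.0 - mu_av) * ps[1] + mu_av * (y * y)

        if adapt:
            hs[0] = hs[0] + mu_b * (I_p - I_p_target)
            hs[1] = hs[1] + mu_b * (I_d - I_d_target)
            n_p = hs[2] + mu_n * (V_p_target - (I_p - hs[4]) ** 2)
            n_d = hs[3] + mu_n * (V_d_target - (I_d - hs[5]) ** 2)
            hs[2] = n_p if n_p > 0.0 else 0.0
            hs[3] = n_d if n_d > 0.0 else 0.0
            hs[4] = (1.0 - mu_av) * hs[4] + mu_av * I_p
            hs[5] = (1.0 - mu_av) * hs[5] + mu_av * I_d


def fused_train(
    xp: np.ndarray,
    xd: np.ndarray,
    w0: np.ndarray,
    *,
    model: str,
    rule: str | None,
    transfer: TransferParams,
    homeo_params: HomeostasisParams,
    plast_params: HebbParams | BCMParams | None,
    homeo_state: HomeostasisState | None = None,
    plast_state: PlasticityState | None = None,
    plastic: bool = True,
    adapt: bool = True,
) -> Trajectory:
    """Run the compiled training loop over a `(T, N)` input batch.

    When ``homeo_state``/``plast_state`` are None, biases start at 0,
    gains at 1, and all trailing averages are seeded from the first
    observed sample; otherwise the loop continues from the given state.
    ``plastic=False`` freezes the weights, ``adapt=False`` freezes
    biases, gains and running averages (a fully frozen call just records
    the currents and rates).
    """
    xp = np.ascontiguousarray(xp, dtype=float)
    xd = np.ascontiguousarray(xd, dtype=float)
    T, N = xp.shape
    if xd.shape != (T,):
        raise ValueError(f"xd has shape {xd.shape}, expected ({T},)")
    w = np.asarray(w0, dtype=float).copy()
    if w.shape != (N,):
        raise ValueError(f"w0 has shape {w.shape}, expected ({N},)")

    model_id = {"compartment": MODEL_COMPARTMENT, "point": MODEL_POINT}[model]
    if plastic:
        if isinstance(plast_params, HebbParams):
            rule_id = RULE_HEBB
            theta_M_fixed = 0.0
        elif isinstance(plast_params, BCMParams):
            rule_id = (
                RULE_BCM_SLIDING
                if plast_params.threshold_mode == "sliding"
                else RULE_BCM_FIXED
            )
            theta_M_fixed = plast_params.theta_M_fixed
        else:
            raise TypeError("plast_params must be HebbParams or BCMParams")
        mu_w, epsilon, mu_av_w = (
            plast_params.mu_w,
            plast_params.epsilon,
            plast_params.mu_av,
        )
    else:
        rule_id, theta_M_fixed = RULE_HEBB, 0.0
        mu_w = epsilon = 0.0
        mu_av_w = homeo_params.mu_av
    # Hebb/BCM trailing averages run at the plasticity mu_av, homeostatic
    # running means at the homeostasis mu_av; the reference set uses one
    # shared value, which is what both engines assume.
    if plastic and not np.isclose(mu_av_w, homeo_params.mu_av):
        raise ValueError("plasticity and homeostasis mu_av must agree")

    seed_averages = homeo_state is None and plast_state is None
    if (homeo_state is None) != (plast_state is None):
        raise ValueError("pass both homeo_state and plast_state, or neither")
    if homeo_state is None:
        hs = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        xt = np.zeros(N)
        ps = np.array([0.0, 0.0])
    else:
        hs = np.array(
            [
                homeo_state.b_p,
                homeo_state.b_d,
                homeo_state.n_p,
                homeo_state.n_d,
                homeo_state.Itilde_p,
                homeo_state.Itilde_d,
            ]
        )
        xt = np.asarray(plast_state.xtilde_p, dtype=float).copy()
        ps = np.array([plast_state.ytilde, plast_state.theta_M_sliding])

    Ip_out = np.empty(T)
    Id_out = np.empty(T)
    y_out = np.empty(T)
    _train_loop(
        xp,
        xd,
        w,
        hs,
        xt,
        ps,
        transfer.theta_p0,
        transfer.theta_p1,
        transfer.theta_d,
        transfer.alpha,
        transfer.theta_point,
        homeo_params.mu_b,
        homeo_params.mu_n,
        homeo_params.mu_av,
        homeo_params.I_p_target,
        homeo_params.I_d_target,
        homeo_params.V_p_target,
        homeo_params.V_d_target,
        mu_w,
        epsilon,
        theta_M_fixed,
        model_id,
        rule_id,
        plastic,
        adapt,
        seed_averages,
        Ip_out,
        Id_out,
        y_out,
    )
    homeo = HomeostasisState(
        b_p=hs[0], b_d=hs[1], n_p=hs[2], n_d=hs[3], Itilde_p=hs[4], Itilde_d=hs[5]
    )
    plast = PlasticityState(w=w, xtilde_p=xt, ytilde=ps[0], theta_M_sliding=ps[1])
    return Trajectory(I_p=Ip_out, I_d=Id_out, y=y_out, homeo=homeo, plast=plast)


def stepwise_train(
    xp: np.ndarray,
    xd: np.ndarray,
    w0: np.ndarray,
    *,
    model: str,
    rule: str | None,
    transfer: TransferParams,
    homeo_params: HomeostasisParams,
    plast_params: HebbParams | BCMParams | None,
    homeo_state: HomeostasisState | None = None,
    plast_state: PlasticityState | None = None,
    plastic: bool = True,
    adapt: bool = True,
) -> Trajectory:
    """Reference loop composed from the public step functions.

    Semantically identical to :func:`fused_train`; used as its oracle.
    """
    xp = np.asarray(xp, dtype=float)
    xd = np.asarray(xd, dtype=float)
    T, N = xp.shape
    rate = compartment_rate if model == "compartment" else point_rate

    hstate = homeo_state
    pstate = plast_state
    w = np.asarray(w0, dtype=float).copy()
    Ip_out = np.empty(T)
    Id_out = np.empty(T)
    y_out = np.empty(T)
    for t in range(T):
        x = xp[t]
        if pstate is not None:
            w = pstate.w
        n_p = hstate.n_p if hstate is not None else 1.0
        n_d = hstate.n_d if hstate is not None else 1.0
        b_p = hstate.b_p if hstate is not None else 0.0
        b_d = hstate.b_d if hstate is not None else 0.0
        I_p = n_p * float(np.dot(w, x)) - b_p
        I_d = n_d * xd[t] - b_d
        y = rate(I_p, I_d, transfer)
        Ip_out[t], Id_out[t], y_out[t] = I_p, I_d, y
        if hstate is None:
            hstate = init_homeostasis_state(I_p, I_d)
        if pstate is None:
            pstate = init_plasticity_state(w, x, y)
        if plastic:
            if isinstance(plast_params, HebbParams):
                pstate = hebbian_step(pstate, x, y, plast_params)
            else:
                pstate = bcm_step(pstate, x, y, plast_params)
        if adapt:
            hstate = bias_step(hstate, I_p, I_d, homeo_params)
            hstate = gain_step(hstate, I_p, I_d, homeo_params)
    return Trajectory(I_p=Ip_out, I_d=Id_out, y=y_out, homeo=hstate, plast=pstate)
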