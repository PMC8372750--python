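"""Stateless neural transfer functions.

Two rate models are implemented:

* a two-compartment model of a cortical pyramidal neuron, in which the
  proximal (basal) current ``I_p`` alone can drive the cell onto a reduced
  plateau of height ``alpha``, while coincident distal (apical) input
  ``I_d`` unlocks the full, burst-like rate of 1;
* a classical point neuron that simply sums the two currents.

Both are pure functions of their inputs; all adaptation state lives in
:mod:`pyramidal.adaptation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TransferParams", "sigmoid", "compartment_rate", "point_rate"]


@dataclass(frozen=True)
class TransferParams:
    """Thresholds and plateau level of the transfer functions.

    Parameters
    ----------
    theta_p0
        Proximal threshold of the low-rate (plateau) branch. With distal
        input below ``theta_d``, proximal drive above this threshold
        yields at most the plateau rate ``alpha``.
    theta_p1
        Proximal threshold of the high-rate (burst) branch, active when
        distal input is suprathreshold. Must satisfy
        ``theta_p1 < theta_p0`` for the rate to be non-decreasing in the
        distal current.
    theta_d
        Distal threshold separating the plateau and burst regimes.
    alpha
        Plateau rate in (0, 1): the maximal rate attainable from proximal
        drive alone, as a fraction of the burst-regime maximum of 1.
    theta_point
        Threshold of the point-neuron comparison model. Defaults to 0,
        which places the operating point at the steepest part of the
        sigmoid once bias homeostasis has centred the currents.
    """

    theta_p0: float = 0.0
    theta_p1: float = -1.0
    theta_d: float = 0.0
    alpha: float = 0.3
    theta_point: float = 0.0

    def __post_init__(self) -> None:
        if not self.theta_p1 < self.theta_p0:
            raise ValueError(
                f"theta_p1 ({self.theta_p1}) must be < theta_p0 ({self.theta_p0})"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")


def sigmoid(x):
    """Logistic activation ``1 / (1 + exp(-4 x))``.

    The factor 4 sets the slope at the origin to 1. Strictly increasing,
    with ``sigmoid(0) == 0.5`` and ``sigmoid(-x) == 1 - sigmoid(x)``.
    """
    x = np.asarray(x, dtype=float)
    _check_finite(x, "x")
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-4.0 * x))
    return out if out.ndim else float(out)


def compartment_rate(I_p, I_d, params: TransferParams = TransferParams()):
    """Firing rate of the two-compartment neuron, in [0, 1].

    ``y = alpha * s(I_p - theta_p0) * (1 - s(I_d - theta_d))
    + s(I_d - theta_d) * s(I_p - theta_p1)`` with ``s`` the
    :func:`sigmoid`. Three regimes emerge: silence for subthreshold
    proximal drive, a plateau near ``alpha`` for proximal drive alone,
    and rates near 1 when proximal and distal input coincide.
    """
    I_p = np.asarray(I_p, dtype=float)
    I_d = np.asarray(I_d, dtype=float)
    _check_finite(I_p, "I_p")
    _check_finite(I_d, "I_d")
    gate = sigmoid(I_d - params.theta_d)
    y = params.alpha * sigmoid(I_p - params.theta_p0) * (1.0 - gate) + gate * sigmoid(
        I_p - params.theta_p1
    )
    y = np.asarray(y)
    return y if y.ndim else float(y)


def point_rate(I_p, I_d, params: TransferParams = TransferParams()):
    """Firing rate of the point neuron: ``sigmoid(I_p + I_d - theta_point)``.

    Fully symmetric in its two inputs; the comparison model without
    dendritic coincidence detection.
    """
    I_p = np.asarray(I_p, dtype=float)
    I_d = np.asarray(I_d, dtype=float)
    _check_finite(I_p, "I_p")
    _check_finite(I_d, "I_d")
    return sigmoid(I_p + I_d - params.theta_point)
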