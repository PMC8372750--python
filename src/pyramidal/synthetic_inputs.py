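"""Input-stream generators for the two learning tasks.

Both tasks share one geometric motif: a fixed random unit vector ``a``
in the N-dimensional basal input space defines the direction that
carries the apical teaching signal, and an ``N_dist``-dimensional
orthonormal "distraction" subspace — orthogonal to ``a`` and internally
orthogonal — carries variance scaled by a factor ``s`` that competes
with ``a`` for the attention of Hebbian plasticity.

* Alignment task: basal inputs are i.i.d. uniform on [0, 1]; the apical
  target is the linear read-out ``x_d = a . x_p`` of the raw samples;
  the centred component of ``x_p`` inside the distraction subspace is
  then rescaled by ``s``.
* Classification task: two Gaussian clusters at ``b ± a/2`` (within-class
  spread ``sigma_a`` along ``a``, spread ``s`` along each distractor),
  with one-hot apical targets signalling the class.

All generators are deterministic given (spec, seed, T). The fixed
geometry (a, b, basis) is drawn once from the spec's own seed; batches
take an independent seed so train and test phases share the geometry
but not the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignmentTaskSpec",
    "ClassificationTaskSpec",
    "make_orthonormal_distractors",
    "alignment_batch",
    "classification_batch",
    "batch_to_frame",
]


def _unit_vector(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)


def make_orthonormal_distractors(
    a: np.ndarray, n_dist: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw an orthonormal basis of ``n_dist`` directions orthogonal to ``a``.

    i.i.d. Gaussian vectors are projected into the orthogonal complement
    of the unit vector ``a`` and orthonormalized by QR. Returns an
    ``(N, n_dist)`` matrix ``B`` with ``B.T @ B = I`` and ``B.T @ a = 0``.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    if not 0 <= n_dist <= n - 1:
        raise ValueError(f"n_dist must lie in [0, {n - 1}], got {n_dist}")
    if n_dist == 0:
        return np.zeros((n, 0))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = rng.standard_normal((n, n_dist))
    g -= np.outer(a, a @ g)
    q, r = np.linalg.qr(g)
    # fix the sign convention so the basis is unique given the draws
    q *= np.sign(np.diag(r))
    return q


@dataclass(frozen=True)
class AlignmentTaskSpec:
    """Fixed geometry of the unsupervised alignment task.

    ``a`` is the unit read-out vector of the apical target,
    ``distraction_basis`` the (N, N_dist) orthonormal distractor set and
    ``s`` the factor by which the centred distractor-subspace component
    of the basal input is rescaled. ``center_rescale`` selects whether
    the rescaling is applied about the input mean 0.5 (default: ``s``
    then scales the distraction variance without shifting the input
    mean) or about the raw origin.
    """

    N: int
    a: np.ndarray
    distraction_basis: np.ndarray
    s: float
    seed: int
    center_rescale: bool = True

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.a) - 1.0) > 1e-12:
            raise ValueError("a must be a unit vector")
        _check_basis(self.a, self.distraction_basis)
        if self.s < 0:
            raise ValueError("s must be >= 0")

    @property
    def n_dist(self) -> int:
        return self.distraction_basis.shape[1]

    @classmethod
    def create(
        cls, N: int, n_dist: int, s: float, seed: int, center_rescale: bool = True
    ) -> "AlignmentTaskSpec":
        """Draw the random geometry (a, distractor basis) from ``seed``."""
        rng = np.random.default_rng(seed)
        a = _unit_vector(N, rng)
        basis = make_orthonormal_distractors(a, n_dist, rng)
        return cls(
            N=N, a=a, distraction_basis=basis, s=s, seed=seed,
            center_rescale=center_rescale,
        )


@dataclass(frozen=True)
class ClassificationTaskSpec:
    """Fixed geometry of the two-cluster classification task.

    Cluster centres sit at ``b - a/2`` and ``b + a/2``; ``sigma_a`` is
    the within-class standard deviation along the separating normal
    ``a`` and ``s`` the standard deviation along each distractor
    direction.
    """

    N: int
    b: np.ndarray
    a: np.ndarray
    distraction_basis: np.ndarray
    s: float
    seed: int
    sigma_a: float = 0.25

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.a) - 1.0) > 1e-12:
            raise ValueError("a must be a unit vector")
        _check_basis(self.a, self.distraction_basis)
        if self.sigma_a <= 0:
            raise ValueError("sigma_a must be positive")

    @property
    def n_dist(self) -> int:
        return self.distraction_basis.shape[1]

    @classmethod
    def create(
        cls, N: int, n_dist: int, s: float, seed: int, sigma_a: float = 0.25
    ) -> "ClassificationTaskSpec":
        rng = np.random.default_rng(seed)
        b = rng.uniform(0.0, 1.0, N)
        a = _unit_vector(N, rng)
        basis = make_orthonormal_distractors(a, n_dist, rng)
        return cls(
            N=N, b=b, a=a, distraction_basis=basis, s=s, seed=seed, sigma_a=sigma_a
        )


def _check_basis(a: np.ndarray, basis: np.ndarray) -> None:
    if basis.shape[0] != a.shape[0]:
        raise ValueError("basis rows must match len(a)")
    if basis.shape[1] > a.shape[0] - 1:
        raise ValueError("at most N-1 distractor directions fit orthogonal to a")
    if basis.size:
        gram = basis.T @ basis
        if not np.allclose(gram, np.eye(basis.shape[1]), atol=1e-10):
            raise ValueError("distraction basis is not orthonormal")
        if not np.allclose(basis.T @ a, 0.0, atol=1e-10):
            raise ValueError("distraction basis is not orthogonal to a")


def alignment_batch(
    spec: AlignmentTaskSpec, T: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``T`` timesteps of the alignment task.

    Raw basal samples are i.i.d. uniform on [0, 1] per afferent. The
    apical target ``x_d = a . x_p`` is read out from the raw samples, so
    it stays reconstructable at every ``s``; afterwards the component of
    ``x_p`` inside the distraction subspace (centred at the distribution
    mean 0.5 unless ``spec.center_rescale`` is off) is rescaled by
    ``s``. Returns ``(x_p, x_d)`` of shapes (T, N) and (T,).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    xp = rng.uniform(0.0, 1.0, (T, spec.N))
    xd = xp @ spec.a
    B = spec.distraction_basis
    if B.shape[1]:
        center = 0.5 if spec.center_rescale else 0.0
        proj = (xp - center) @ B
        xp = xp + (spec.s - 1.0) * proj @ B.T
    return xp, xd


def classification_batch(
    spec: ClassificationTaskSpec, T: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``T`` timesteps of the classification task.

    Each sample is ``x_p = b + a (c + sigma_a z) + s B zdist`` with the
    class variable ``c`` drawn from {-0.5, +0.5} equiprobably and all
    ``z`` standard normal, fresh every step. The one-hot apical targets
    are ``x_d1 = H((x_p - b) . a)`` and ``x_d0 = 1 - x_d1`` with the
    Heaviside convention ``H(0) = 0``; because of the within-class noise
    they follow the realized side of the hyperplane, not ``c``.

    Returns ``(x_p, labels, x_d0, x_d1)`` where ``labels`` is the class
    index in {0, 1} implied by the targets. Draw order from the batch
    seed is fixed: c, then zeta_a, then zeta_dist.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    c = rng.choice((-0.5, 0.5), size=T)
    zeta_a = rng.standard_normal(T)
    xp = spec.b + np.outer(c + spec.sigma_a * zeta_a, spec.a)
    B = spec.distraction_basis
    if B.shape[1]:
        zeta_dist = rng.standard_normal((T, B.shape[1]))
        xp = xp + spec.s * zeta_dist @ B.T
    score = (xp - spec.b) @ spec.a
    xd1 = (score > 0.0).astype(float)
    xd0 = 1.0 - xd1
    labels = xd1.astype(int)
    return xp, labels, xd0, xd1


def batch_to_frame(xp: np.ndarray, target: np.ndarray, target_name: str = "x_d"):
    """Tidy DataFrame view of a generated batch, for CSV export."""
    import pandas as pd

    T, N = xp.shape
    df = pd.DataFrame(xp, columns=[f"x_p_{i + 1}" for i in range(N)])
    df.insert(0, "t", np.arange(T))
    df[target_name] = target
    return df
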