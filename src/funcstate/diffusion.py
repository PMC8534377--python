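"""Laplacian spectral machinery, heat-kernel propagator and emergent functional states.

Diffusion of a field phi on a weighted undirected network obeys
``d(phi)/d(tau) = -L phi`` with the combinatorial Laplacian
``L = diag(K) - W``. Its solution is carried by the propagator
``U(tau) = exp(-tau L)``, which for undirected networks is symmetric and
doubly stochastic. The emergent functional state at scale tau is the
propagator rescaled by the initial field amount ``phi0`` with the diagonal
removed: ``W~_ij(tau) = phi0 * U_ij(tau) * (1 - delta_ij)`` — a network whose
links encode pairwise flow exchange within propagation time tau.

All tau-dependent quantities reuse one full symmetric eigendecomposition of
``L`` (O(N^3) once, O(N^2) per tau), appropriate for the N <= ~500 networks
this package targets.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .errors import DisconnectedError, FuncstateError, ValidationError
from .networks import WeightedNetwork

__all__ = [
    "SpectralDecomposition",
    "FunctionalState",
    "InitialDistribution",
    "decompose",
    "propagator",
    "functional_state",
    "rescaled_tau_grid",
]

#: eigenvalues below this fraction of the largest count as zero modes
ZERO_EIGENVALUE_REL_THRESHOLD = 1e-10
#: propagator entries more negative than this indicate a numerical bug
NEGATIVE_ENTRY_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class SpectralDecomposition:
    """Full eigendecomposition of the combinatorial Laplacian.

    ``eigenvalues`` are sorted ascending with ``eigenvalues[0] ~ 0``;
    ``eigenvectors[:, l]`` is the orthonormal eigenvector of ``eigenvalues[l]``.
    """

    laplacian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    node_labels: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.eigenvalues)

    @property
    def zero_threshold(self) -> float:
        lam_max = float(self.eigenvalues[-1])
        return ZERO_EIGENVALUE_REL_THRESHOLD * max(lam_max, 1.0)

    @property
    def n_components(self) -> int:
        """Number of connected components = multiplicity of the zero eigenvalue."""
        return int(np.count_nonzero(self.eigenvalues < self.zero_threshold))

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1

    @property
    def lambda2(self) -> float:
        """Second-smallest Laplacian eigenvalue (algebraic connectivity)."""
        return float(self.eigenvalues[1])

    @property
    def diffusion_time(self) -> float:
        """tau_d = 1/lambda_2, the scale at which the slowest nontrivial mode
        has decayed to 1/e; defined only for connected networks."""
        if not self.is_connected:
            raise DisconnectedError("diffusion time undefined (lambda_2 = 0)")
        return 1.0 / self.lambda2


def decompose(net: WeightedNetwork) -> SpectralDecomposition:
    """Eigendecompose ``L = diag(K) - W`` of a weighted network.

    Disconnection is recorded (extra zero modes), not fatal.
    """
    lap = np.diag(net.strengths) - net.weights
    eigvals, eigvecs = scipy.linalg.eigh(lap)
    eigvals = np.clip(eigvals, 0.0, None)  # L is PSD; clip eigh round-off
    # snap zero modes to exactly 0 so extreme-tau limits are exact instead of
    # amplifying the ~1e-15 residual (e^{-tau*residual} drifts at tau >> 1)
    threshold = ZERO_EIGENVALUE_REL_THRESHOLD * max(float(eigvals[-1]), 1.0)
    eigvals[eigvals < threshold] = 0.0
    return SpectralDecomposition(lap, eigvals, eigvecs, net.node_labels)


def propagator(dec: SpectralDecomposition, tau: float) -> np.ndarray:
    """Heat kernel ``U(tau) = V diag(e^{-tau lambda}) V^T``.

    Symmetric and doubly stochastic (the Laplacian has zero row sums).
    Entries negative only by floating-point noise are clipped to zero;
    larger negatives raise, since exp(-tau L) is provably nonnegative.
    """
    if tau < 0:
        raise ValidationError(f"tau must be >= 0, got {tau}")
    v = dec.eigenvectors
    u = (v * np.exp(-tau * dec.eigenvalues)) @ v.T
    u = (u + u.T) / 2.0
    worst = u.min()
    if worst < -NEGATIVE_ENTRY_TOL:
        raise FuncstateError(
            f"propagator entry {worst} below -{NEGATIVE_ENTRY_TOL}: internal inconsistency"
        )
    return np.clip(u, 0.0, None)


@dataclasses.dataclass(frozen=True)
class InitialDistribution:
    """Diagonal of the initial-condition operator Pi, ``Pi_ii = phi_i / phi0``.

    Fractions are nonnegative and sum to 1: the total field phi0 is split
    across sources instead of each node emitting a full phi0.
    """

    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if np.any(f < 0):
            raise ValidationError("initial distribution has negative entries")
        if not np.isclose(f.sum(), 1.0, rtol=0, atol=1e-10):
            raise ValidationError(f"initial distribution sums to {f.sum()}, not 1")


@dataclasses.dataclass(frozen=True)
class FunctionalState:
    """Emergent functional network at scale tau.

    ``matrix`` is ``phi0 * Pi U(tau)`` with the diagonal zeroed; symmetric
    whenever the initial distribution is uniform (Pi = I).
    """

    tau: float
    phi0: float
    matrix: np.ndarray
    node_labels: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def functional_strengths(self) -> np.ndarray:
        """k_i = sum_j W~_ij, total flow node i exchanges within tau."""
        return self.matrix.sum(axis=1)

    @property
    def mean_strength(self) -> float:
        """k-bar = (1/N) sum_ij W~_ij; rises from 0 toward phi0*(N-1)/N with tau."""
        return float(self.matrix.sum() / self.n_nodes)

    @property
    def symmetrized(self) -> np.ndarray:
        """(W~ + W~^T)/2 — the matrix handed to community detection when Pi != I."""
        return (self.matrix + self.matrix.T) / 2.0

    def to_network(self, min_weight: float = 0.0) -> WeightedNetwork:
        """Export as a WeightedNetwork, optionally thresholding small links."""
        m = self.symmetrized.copy()
        np.fill_diagonal(m, 0.0)
        if min_weight > 0:
            m[m < min_weight] = 0.0
        return WeightedNetwork(self.node_labels, m)


def functional_state(
    dec: SpectralDecomposition,
    tau: float,
    phi0: float = 1.0,
    pi: InitialDistribution | None = None,
) -> FunctionalState:
    """Build the emergent functional state ``phi0 * Pi U(tau)`` (diagonal zeroed).

    With ``pi=None`` the initial condition is uniform (Pi = I) and the state
    is symmetric. ``phi0`` is a pure scale: every strength is proportional
    to it, so curves are reported in units of phi0.
    """
    if tau <= 0:
        raise ValidationError(f"tau must be > 0, got {tau}")
    if phi0 <= 0:
        raise ValidationError(f"phi0 must be > 0, got {phi0}")
    u = propagator(dec, tau)
    if pi is not None:
        if len(pi.fractions) != dec.n_nodes:
            raise ValidationError("initial distribution length does not match network size")
        u = pi.fractions[:, None] * u
    m = phi0 * u
    np.fill_diagonal(m, 0.0)
    return FunctionalState(tau=tau, phi0=phi0, matrix=m, node_labels=dec.node_labels)


def rescaled_tau_grid(
    dec: SpectralDecomposition,
    ratio_min: float = 1e-10,
    ratio_max: float = 10.0,
    n_points: int = 100,
) -> list[tuple[float, float]]:
    """Log-spaced grid of rescaled scales ``r = tau/tau_d`` paired with ``tau = r * tau_d``.

    Rescaling by the diffusion time makes scales comparable across networks;
    it requires connectivity (tau_d finite).
    """
    if not dec.is_connected:
        raise DisconnectedError("diffusion time undefined (lambda_2 = 0)")
    if not (0 < ratio_min < ratio_max):
        raise ValidationError(f"need 0 < ratio_min < ratio_max, got ({ratio_min}, {ratio_max})")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    tau_d = dec.diffusion_time
    ratios = np.logspace(np.log10(ratio_min), np.log10(ratio_max), n_points)
    return [(float(r), float(r * tau_d)) for r in ratios]
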