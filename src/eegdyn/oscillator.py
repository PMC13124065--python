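"""Connectome-coupled phase-oscillator network and its state-space analysis.

The model is a network of N phase oscillators with a synaptically derived
coupling function:

    dtheta_i/dt = omega * (1 - a cos(theta_i)
                           + (1 - cos(theta_i)) * (K/N) * sum_j w_ij cos(theta_j)
                           + Q eta_i(t))

where omega = 2 pi f (f = 10 Hz), `a` controls the stability of the locked
state (stability decreases as `a` grows), K scales the global coupling
through the symmetric nonnegative connectome weights w_ij (normalized by
their 95th off-diagonal percentile), and eta_i is white Gaussian noise of
strength Q. Between the fully suppressed (low a and/or K) and saturated
(high a and/or K) regimes lies a metastable regime of transient, recurring
partially synchronized network states; the same sliding-window CCorr +
correlation-distance pipeline used for EEG quantifies this switching, and
k-medoids clustering of the distance matrix identifies the recurring states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .dynamics import PSDMatrix, default_tau_grid, jl_grid, psd_matrix
from .phase import SyncSeries, phases_to_sync

logger = logging.getLogger(__name__)


def synthetic_connectome(n_nodes: int = 10, seed: int = 7,
                         density: float = 0.8) -> np.ndarray:
    """Synthetic symmetric tractography-like weight matrix.

    Log-normal weights (heavy-tailed, like streamline counts), zero diagonal,
    symmetric; a stand-in for an atlas-derived connectome, usable wherever a
    whitespace-delimited weight matrix would be loaded.
    """
    rng = np.random.default_rng(seed)
    W = rng.lognormal(mean=0.0, sigma=1.0, size=(n_nodes, n_nodes))
    mask = rng.random((n_nodes, n_nodes)) < density
    W = W * mask
    W = np.triu(W, 1)
    W = W + W.T
    return W


def load_connectome(path) -> np.ndarray:
    """Load a whitespace-delimited nonnegative square weight matrix."""
    W = np.loadtxt(path)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("connectome must be a square matrix")
    if (W < 0).any():
        raise ValueError("connectome weights must be nonnegative")
    return W


def normalize_connectome(W_raw: np.ndarray) -> np.ndarray:
    """Divide weights by the 95th percentile of the off-diagonal entries.

    The diagonal is structurally zero in a connectome, so the percentile is
    taken over off-diagonal entries only (linear interpolation).
    """
    W_raw = np.asarray(W_raw, dtype=float)
    if W_raw.ndim != 2 or W_raw.shape[0] != W_raw.shape[1]:
        raise ValueError("connectome must be square")
    if (W_raw < 0).any():
        raise ValueError("weights must be nonnegative")
    off = W_raw[~np.eye(W_raw.shape[0], dtype=bool)]
    scale = np.percentile(off, 95)
    if scale <= 0:
        raise ValueError("connectome has no positive off-diagonal weight")
    return W_raw / scale


@dataclass
class OscParams:
    """Simulation settings; defaults follow the 10-node, 10-Hz configuration."""

    W: np.ndarray
    a: float = 0.5
    K: float = 2.0
    f: float = 10.0
    Q: float = 0.01
    dt: float = 0.001
    duration: float = 11.0
    transient: float = 1.0
    output_rate: float = 250.0
    noise_mode: str = "sqrt_dt"  # "sqrt_dt" (Euler-Maruyama) | "per_step"
    seed: int | None = None
    theta0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        N = self.W.shape[0]
        if self.W.shape != (N, N):
            raise ValueError("W must be square")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if (self.W < 0).any() or np.abs(np.diag(self.W)).max() > 0:
            raise ValueError("W must be nonnegative with zero diagonal")
        if self.dt <= 0 or self.duration <= self.transient:
            raise ValueError("need dt > 0 and duration > transient")
        ratio = 1.0 / (self.dt * self.output_rate)
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("1/dt must be an integer multiple of output_rate")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.f


@dataclass
class PhaseTrajectories:
    """Simulated node phases on the output grid (wrapped on export)."""

    theta: np.ndarray  # (n_nodes, n_samples), unwrapped
    rate: float

    @property
    def n_nodes(self) -> int:
        return self.theta.shape[0]

    @property
    def wrapped(self) -> np.ndarray:
        return np.angle(np.exp(1j * self.theta))


def simulate(params: OscParams) -> PhaseTrajectories:
    """Euler(-Maruyama) integration of the phase network.

    Deterministic drift steps dt * omega * (...); the noise increment is
    omega*Q*sqrt(dt)*N(0,1) per node per step in the default "sqrt_dt" SDE
    convention, or omega*Q*dt*N(0,1) in the literal "per_step" mode. The
    transient is discarded and phases are subsampled to ``output_rate``.
    """
    rng = np.random.default_rng(params.seed)
    N = params.n_nodes
    omega = params.omega
    n_steps = int(round(params.duration / params.dt))
    keep_from = int(round(params.transient / params.dt))
    stride = int(round(1.0 / (params.dt * params.output_rate)))

    if params.theta0 is not None:
        theta = np.asarray(params.theta0, dtype=float).copy()
        if theta.shape != (N,):
            raise ValueError("theta0 must have one phase per node")
    else:
        theta = rng.uniform(-np.pi, np.pi, size=N)

    if params.noise_mode == "sqrt_dt":
        noise_scale = omega * params.Q * np.sqrt(params.dt)
    elif params.noise_mode == "per_step":
        noise_scale = omega * params.Q * params.dt
    else:
        raise ValueError(f"unknown noise_mode {params.noise_mode!r}")

    KoverN = params.K / N
    out = np.empty((N, (n_steps - keep_from + stride - 1) // stride))
    oi = 0
    for step in range(n_steps):
        if step >= keep_from and (step - keep_from) % stride == 0:
            out[:, oi] = theta
            oi += 1
        cos_t = np.cos(theta)
        drift = omega * (1.0 - params.a * cos_t
                         + (1.0 - cos_t) * (KoverN * (params.W @ cos_t)))
        theta = theta + params.dt * drift
        if params.Q > 0:
            theta = theta + noise_scale * rng.standard_normal(N)
        if not np.all(np.isfinite(theta)):
            raise FloatingPointError(f"non-finite phase at step {step}")
    return PhaseTrajectories(theta=out[:, :oi], rate=params.output_rate)


def sim_sync_pipeline(
    traj: PhaseTrajectories,
    window_s: float = 1.0,
    step_s: float = 0.1,
) -> tuple[SyncSeries, PSDMatrix]:
    """Sliding CCorr (on the raw phases, no wavelet) and the distance matrix.

    Defaults: 1-s windows in 100-ms steps, the partly overlapping convention
    used for the simulation analyses.
    """
    L = int(round(window_s * traj.rate))
    step = int(round(step_s * traj.rate))
    ss = phases_to_sync(traj.wrapped, traj.rate, L, step)
    return ss, psd_matrix(ss)


class KMedoids(ClusterMixin, BaseEstimator):
    """Partitioning-around-medoids on a precomputed distance matrix.

    Voronoi-style iteration: assign each point to its nearest medoid, then
    re-pick each cluster's medoid as the member minimizing the within-cluster
    distance sum; the total cost is nonincreasing and iteration stops when the
    medoid set is stable. Initial medoids come either from ``init_medoids`` or
    a seeded greedy farthest-point heuristic.
    """

    def __init__(self, n_clusters: int = 3, init_medoids=None,
                 max_iter: int = 300, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.init_medoids = init_medoids
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a precomputed symmetric distance matrix X."""
        D = np.asarray(X, dtype=float)
        n = D.shape[0]
        if D.ndim != 2 or D.shape != (n, n):
            raise ValueError("X must be a square distance matrix")
        k = self.n_clusters
        if k < 1 or k > n:
            raise ValueError(f"n_clusters={k} outside 1..{n}")

        if self.init_medoids is not None:
            medoids = np.asarray(self.init_medoids, dtype=int)
            if medoids.size != k or medoids.min() < 0 or medoids.max() >= n:
                raise ValueError("init_medoids must be k valid window indices")
        else:
            medoids = self._greedy_init(D, k)

        for _ in range(self.max_iter):
            labels = np.argmin(D[medoids], axis=0)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                medoids = new_medoids
                break
            medoids = new_medoids
        labels = np.argmin(D[medoids], axis=0)
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = float(D[medoids[labels], np.arange(n)].sum())
        return self

    def _greedy_init(self, D: np.ndarray, k: int) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        first = int(rng.integers(D.shape[0]))
        medoids = [first]
        while len(medoids) < k:
            d_to_set = D[medoids].min(axis=0)
            d_to_set[medoids] = -np.inf
            medoids.append(int(np.argmax(d_to_set)))
        return np.asarray(medoids)

    def predict(self, X):
        """Nearest-medoid labels for distance rows X (n_samples x n_fitted)."""
        check_is_fitted(self, "medoid_indices_")
        D = np.asarray(X, dtype=float)
        return np.argmin(D[:, self.medoid_indices_], axis=1)


def kmedoids_cluster(psd: PSDMatrix, k: int, init_medoids=None,
                     seed: int | None = None, freq_index: int = 0) -> KMedoids:
    """Cluster window networks with k-medoids on the correlation distances."""
    D = psd.distances[freq_index]
    if np.isnan(D).any():
        raise ValueError("distance matrix contains flagged windows; drop them "
                         "before clustering")
    if k < 2:
        raise ValueError("need k >= 2 clusters")
    return KMedoids(n_clusters=k, init_medoids=init_medoids,
                    random_state=seed).fit(D)


def medoid_embedding(psd: PSDMatrix, medoids, freq_index: int = 0) -> np.ndarray:
    """Coordinates 1 - D[t, m_k] of every window relative to each medoid.

    A medoid's own-axis coordinate is exactly 1 (its self-distance is 0).
    """
    D = psd.distances[freq_index]
    medoids = np.asarray(medoids, dtype=int)
    if medoids.min() < 0 or medoids.max() >= D.shape[0]:
        raise IndexError("medoid index out of range")
    return 1.0 - D[:, medoids]


DEFAULT_A_GRID = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95, 1.0)
DEFAULT_K_GRID = (0.0, 0.1, 1.0, 2.0, 5.0, 10.0, 100.0)


def parameter_sweep(
    W: np.ndarray,
    a_grid=DEFAULT_A_GRID,
    K_grid=DEFAULT_K_GRID,
    n_seeds: int = 1,
    base_seed: int = 0,
    taus: np.ndarray | None = None,
    **param_overrides,
) -> pd.DataFrame:
    """Per-(a, K, seed) jump-length statistics, tidy table.

    Each cell runs simulate -> sliding CCorr -> distance matrix -> jump-length
    grid over tau in [1, 2] s (100-ms steps by default) and reports mu/sigma/
    kurtosis averaged over tau. Failed cells are logged and marked.
    """
    if taus is None:
        taus = default_tau_grid(step_s=0.1, tau_min=1.0, tau_max=2.0)
    rows = []
    for a in a_grid:
        for K in K_grid:
            for s in range(n_seeds):
                seed = base_seed + s
                try:
                    params = OscParams(W=W, a=a, K=K, seed=seed,
                                       **param_overrides)
                    traj = simulate(params)
                    _, psd = sim_sync_pipeline(traj)
                    grid = jl_grid(psd, taus=taus)
                    rows.append({
                        "a": a, "K": K, "seed": seed, "failed": False,
                        "mu_jl": float(np.nanmean(grid.mean)),
                        "sigma_jl": float(np.nanmean(grid.sd)),
                        "k_jl": float(np.nanmean(grid.kurtosis)),
                    })
                except Exception as err:  # noqa: BLE001 - sweep keeps going
                    logger.error("sweep cell a=%g K=%g seed=%d failed: %s",
                                 a, K, seed, err)
                    rows.append({"a": a, "K": K, "seed": seed, "failed": True,
                                 "mu_jl": np.nan, "sigma_jl": np.nan,
                                 "k_jl": np.nan})
    return pd.DataFrame(rows)
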