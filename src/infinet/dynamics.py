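"""Three-state spin cascade: asynchronous Monte Carlo dynamics.

Each node i carries a spin sigma_i in {-1, 0, +1} (blue / white / red).
Nodes in the pinned red (blue) set keep sigma = +1 (-1) forever.  At each
sweep the variable (non-pinned) nodes are visited once, in a freshly drawn
random permutation, and each visited node adopts the sign of its local field

    Z_i = sum_{j != i} (S~_ij + S~_ji) sigma_j ,

keeping its previous spin when Z_i = 0.  Updates are asynchronous: a new
spin value is immediately visible to later updates within the same sweep.
A realization runs up to ``tau_max`` sweeps (default 100) with early exit
once a full sweep changes nothing; an ensemble of R realizations yields the
per-node red-outcome fraction fr(i) and its average fr over variable nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from infinet._kernels import sweep_csr
from infinet.network import NodePanel, TransitionMatrices


class PinnedNodeError(ValueError):
    """Raised when an update would touch a permanently pinned node."""


def _as_csr64(W: sp.spmatrix) -> sp.csr_matrix:
    W = sp.csr_matrix(W, dtype=np.float64)
    W.sort_indices()
    return W


@dataclass
class SpinConfiguration:
    """Per-node spins plus the permanently pinned red/blue sets."""

    spins: np.ndarray  # int8, values in {-1, 0, +1}
    fixed_red: np.ndarray
    fixed_blue: np.ndarray

    def __post_init__(self) -> None:
        self.spins = np.asarray(self.spins, dtype=np.int8)
        self.fixed_red = np.asarray(self.fixed_red, dtype=np.int64)
        self.fixed_blue = np.asarray(self.fixed_blue, dtype=np.int64)
        if np.intersect1d(self.fixed_red, self.fixed_blue).size:
            raise ValueError("pinned red and blue sets must be disjoint")

    @classmethod
    def initial(
        cls,
        N: int,
        fixed_red: Sequence[int],
        fixed_blue: Sequence[int],
        initial_blues: Sequence[int] = (),
        initial_reds: Sequence[int] = (),
    ) -> "SpinConfiguration":
        """White everywhere except pinned values and initial +-1 seeds.

        Initial blues/reds are *variable*: they may flip later.  They must
        not overlap the pinned sets.
        """
        fixed_red = np.asarray(fixed_red, dtype=np.int64)
        fixed_blue = np.asarray(fixed_blue, dtype=np.int64)
        initial_blues = np.asarray(initial_blues, dtype=np.int64)
        initial_reds = np.asarray(initial_reds, dtype=np.int64)
        pinned = np.union1d(fixed_red, fixed_blue)
        for arr, what in ((initial_blues, "initial blue"), (initial_reds, "initial red")):
            if np.intersect1d(arr, pinned).size:
                raise PinnedNodeError(
                    f"{what} nodes overlap the permanently pinned sets"
                )
        spins = np.zeros(N, dtype=np.int8)
        spins[initial_blues] = -1
        spins[initial_reds] = 1
        spins[fixed_red] = 1
        spins[fixed_blue] = -1
        return cls(spins=spins, fixed_red=fixed_red, fixed_blue=fixed_blue)

    @property
    def pinned(self) -> np.ndarray:
        return np.union1d(self.fixed_red, self.fixed_blue)

    def variable_nodes(self) -> np.ndarray:
        """Sorted indices of the non-pinned nodes."""
        return np.setdiff1d(np.arange(self.spins.size), self.pinned)

    def is_pinned(self, i: int) -> bool:
        return bool(np.isin(i, self.fixed_red).any() or np.isin(i, self.fixed_blue).any())

    def copy(self) -> "SpinConfiguration":
        return SpinConfiguration(
            spins=self.spins.copy(),
            fixed_red=self.fixed_red.copy(),
            fixed_blue=self.fixed_blue.copy(),
        )


def local_field(W: sp.spmatrix, spins: np.ndarray, i: int) -> float:
    """Z_i = sum_j W_ij sigma_j over all neighbors, pinned and variable.

    Cost is proportional to the degree of i (sparse row dot product).
    The diagonal of W is zero by construction, so j = i never contributes.
    """
    W = _as_csr64(W) if not sp.isspmatrix_csr(W) else W
    lo, hi = W.indptr[i], W.indptr[i + 1]
    return float(W.data[lo:hi] @ spins[W.indices[lo:hi]])


def update_node(
    state: SpinConfiguration, W: sp.spmatrix, i: int
) -> SpinConfiguration:
    """Asynchronously update one variable node in place (and return state)."""
    if state.is_pinned(i):
        raise PinnedNodeError(f"node {i} is permanently pinned and cannot be updated")
    z = local_field(W, state.spins, i)
    if z > 0:
        state.spins[i] = 1
    elif z < 0:
        state.spins[i] = -1
    return state


def sweep(
    state: SpinConfiguration, W: sp.spmatrix, order: np.ndarray
) -> tuple[SpinConfiguration, int]:
    """Apply one asynchronous sweep along ``order``.

    ``order`` must be a permutation of exactly the variable (non-pinned)
    nodes.  Returns the state and the number of spins that changed.
    """
    order = np.asarray(order, dtype=np.int64)
    expected = state.variable_nodes()
    if not np.array_equal(np.sort(order), expected):
        if np.intersect1d(order, state.pinned).size:
            raise PinnedNodeError("sweep order touches permanently pinned nodes")
        raise ValueError("sweep order is not a permutation of the variable nodes")
    W = _as_csr64(W)
    n_changed = sweep_csr(W.indptr, W.indices, W.data, state.spins, order)
    return state, int(n_changed)


@dataclass
class RealizationResult:
    """Outcome of a single realization (one full iteration to tau_max)."""

    final_spins: SpinConfiguration
    tau_last: int  # first sweep index (1-based) after which nothing changed
    converged: bool  # False if no zero-change sweep occurred within tau_max
    initial_blues: np.ndarray
    red_trajectory: np.ndarray  # red count among variable nodes, per sweep


def run_realization(
    W: sp.spmatrix,
    fixed_red: Sequence[int],
    fixed_blue: Sequence[int],
    initial_blues: Sequence[int] = (),
    tau_max: int = 100,
    rng: np.random.Generator | int | None = None,
    initial_reds: Sequence[int] = (),
) -> RealizationResult:
    """Run one realization: random-permutation sweeps until convergence.

    Starts from pinned values, sigma = -1 on ``initial_blues`` (+1 on
    ``initial_reds``), sigma = 0 elsewhere.  A fresh permutation of the
    variable nodes is drawn from ``rng`` for every sweep.  The run exits
    early when a full sweep changes no spin; ``tau_last`` records that sweep
    (the trajectory keeps the converged value afterwards).  Deterministic
    given the generator state.
    """
    W = _as_csr64(W)
    N = W.shape[0]
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    state = SpinConfiguration.initial(
        N, fixed_red, fixed_blue, initial_blues=initial_blues, initial_reds=initial_reds
    )
    var = state.variable_nodes()
    traj = np.zeros(tau_max, dtype=np.int64)
    tau_last = tau_max
    converged = False
    spins = state.spins
    for tau in range(1, tau_max + 1):
        order = rng.permutation(var) if var.size else var
        n_changed = sweep_csr(W.indptr, W.indices, W.data, spins, order)
        traj[tau - 1] = np.count_nonzero(spins[var] == 1)
        if n_changed == 0:
            tau_last = tau
            converged = True
            traj[tau:] = traj[tau - 1]
            break
    return RealizationResult(
        final_spins=state,
        tau_last=tau_last,
        converged=converged,
        initial_blues=np.asarray(initial_blues, dtype=np.int64),
        red_trajectory=traj,
    )


@dataclass
class SimulationConfig:
    """Parameters of a realization ensemble.

    - ``tau_max``: sweeps per realization (default 100).
    - ``R``: number of independent realizations.
    - ``n_b``: how many of the panel's blue nodes are pinned (a prefix of
      the panel order); None pins them all.
    - ``candidate_set``: nodes eligible as initial blues under random
      placement; None means all variable nodes.
    - ``n_ib``: number of initial (non-pinned) blue nodes per realization.
    - ``placement``: "random_in_set" draws ``n_ib`` distinct candidates per
      realization; "fixed_configuration" uses ``configuration`` every time.
    - ``seed``: master seed; realization r uses the independent substream
      SeedSequence(seed, spawn_key=(r,)), so results do not depend on
      execution order.
    """

    R: int = 1000
    tau_max: int = 100
    n_b: int | None = None
    candidate_set: np.ndarray | None = None
    n_ib: int = 0
    placement: str = "random_in_set"
    configuration: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.placement not in ("random_in_set", "fixed_configuration"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.candidate_set is not None:
            self.candidate_set = np.asarray(self.candidate_set, dtype=np.int64)
        self.configuration = tuple(int(i) for i in self.configuration)


@dataclass
class OutcomeStats:
    """Aggregated outcome of an ensemble of realizations."""

    fr_per_node: np.ndarray  # fraction of red outcomes per node
    blue_frac_per_node: np.ndarray
    fr_mean: float  # average of fr_per_node over the variable nodes
    Nv: int
    variable_nodes: np.ndarray
    fr_trajectory: np.ndarray  # network-average red fraction per sweep
    white_stable_count: int  # nodes never red and never blue across all R
    tau_last: np.ndarray  # per-realization convergence sweep
    realization_fr: np.ndarray  # per-realization mean red fraction (variable nodes)
    realization_blues: list  # per-realization initial-blue node arrays
    R: int = 0
    config: SimulationConfig | None = field(default=None, repr=False)


def simulate(
    matrices: TransitionMatrices,
    panel: NodePanel,
    config: SimulationConfig,
) -> OutcomeStats:
    """Run R independent realizations and aggregate outcome statistics.

    The dynamics use the symmetric coupling W = S~ + S~^T built from the
    dangling-preserving matrix S~ (never the uniform-fixed S).
    """
    W = _as_csr64(matrices.W)
    N = W.shape[0]
    fixed_red = np.asarray(panel.fixed_red, dtype=np.int64)
    fixed_blue = np.asarray(panel.fixed_blue, dtype=np.int64)
    if config.n_b is not None:
        if config.n_b > fixed_blue.size:
            raise ValueError(
                f"n_b={config.n_b} exceeds the panel's {fixed_blue.size} blue nodes"
            )
        fixed_blue = fixed_blue[: config.n_b]
    pinned = np.union1d(fixed_red, fixed_blue)
    var = np.setdiff1d(np.arange(N), pinned)
    Nv = var.size

    if config.placement == "fixed_configuration":
        configuration = np.asarray(config.configuration, dtype=np.int64)
        if np.intersect1d(configuration, pinned).size:
            raise PinnedNodeError("fixed configuration overlaps pinned nodes")
        candidates = None
        n_ib = configuration.size
    else:
        candidates = config.candidate_set if config.candidate_set is not None else var
        if np.intersect1d(candidates, pinned).size:
            raise ValueError("candidate set contains permanently pinned nodes")
        n_ib = config.n_ib
        if n_ib > candidates.size:
            raise ValueError(
                f"n_ib={n_ib} exceeds the candidate set size {candidates.size}"
            )
        configuration = None

    red_counts = np.zeros(N, dtype=np.int64)
    blue_counts = np.zeros(N, dtype=np.int64)
    traj_sum = np.zeros(config.tau_max, dtype=np.float64)
    tau_last = np.zeros(config.R, dtype=np.int64)
    realization_fr = np.zeros(config.R, dtype=np.float64)
    realization_blues: list[np.ndarray] = []

    for r in range(config.R):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(r,))
        rng = np.random.default_rng(ss)
        if configuration is not None:
            blues = configuration
        elif n_ib:
            blues = rng.choice(candidates, size=n_ib, replace=False)
        else:
            blues = np.empty(0, dtype=np.int64)
        res = run_realization(
            W, fixed_red, fixed_blue,
            initial_blues=blues, tau_max=config.tau_max, rng=rng,
        )
        spins = res.final_spins.spins
        red_counts += spins == 1
        blue_counts += spins == -1
        traj_sum += res.red_trajectory
        tau_last[r] = res.tau_last
        realization_fr[r] = res.red_trajectory[-1] / Nv if Nv else 0.0
        realization_blues.append(np.sort(blues))

    fr_per_node = red_counts / config.R
    blue_frac = blue_counts / config.R
    fr_mean = float(fr_per_node[var].sum() / Nv) if Nv else 0.0
    white_stable = int(np.count_nonzero((red_counts == 0) & (blue_counts == 0)))
    return OutcomeStats(
        fr_per_node=fr_per_node,
        blue_frac_per_node=blue_frac,
        fr_mean=fr_mean,
        Nv=Nv,
        variable_nodes=var,
        fr_trajectory=traj_sum / (config.R * Nv) if Nv else traj_sum,
        white_stable_count=white_stable,
        tau_last=tau_last,
        realization_fr=realization_fr,
        realization_blues=realization_blues,
        R=config.R,
        config=config,
    )
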