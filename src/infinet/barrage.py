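"""Erdös-barrage construction and ranking of blue repressor placements.

The Erdös set of a pinned red hub is the set of nodes at symmetrized-graph
distance 1 from the hub (a direct or inverse link to a hub node).  Placing
a few initially blue nodes inside this set is the most effective way to
block the red cascade; candidates are ranked by the network-averaged red
outcome frc obtained when a candidate (or a configuration of candidates)
is the initial blue seed — the lower frc, the better the barrage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from infinet.dynamics import OutcomeStats, SimulationConfig, simulate
from infinet.network import NodePanel, TransitionMatrices


def erdos_set(
    W: sp.spmatrix,
    hub: Sequence[int],
    exclude: Sequence[int] = (),
) -> np.ndarray:
    """Nodes with a symmetrized coupling to the hub (Erdös number one).

    Returns, in ascending order, every node i not in ``hub`` or ``exclude``
    with W_ij > 0 for some hub node j.  ``exclude`` normally holds the
    pinned blue panel (the default behavior; pass ``exclude=()`` to keep
    panel-blue neighbors in the set).
    """
    hub = np.asarray(hub, dtype=np.int64)
    if hub.size == 0:
        raise ValueError("hub set must be nonempty")
    W = sp.csr_matrix(W)
    neighbors: set[int] = set()
    for j in hub:
        lo, hi = W.indptr[j], W.indptr[j + 1]
        cols = W.indices[lo:hi][W.data[lo:hi] > 0]
        neighbors.update(int(c) for c in cols)
    neighbors.difference_update(int(j) for j in hub)
    neighbors.difference_update(int(j) for j in np.asarray(exclude, dtype=np.int64))
    return np.array(sorted(neighbors), dtype=np.int64)


@dataclass
class BarrageRanking:
    """Candidates ranked by conditional red outcome frc (ascending).

    ``kfr_order`` lists candidate *positions* (indices into ``candidates``)
    sorted by increasing frc, ties by ascending node index; the 1-based rank
    of candidate at position p is ``kfr_rank[p]``.
    """

    candidates: np.ndarray
    frc: np.ndarray
    kfr_order: np.ndarray
    support_counts: np.ndarray

    @property
    def kfr_rank(self) -> np.ndarray:
        ranks = np.empty(self.candidates.size, dtype=np.int64)
        ranks[self.kfr_order] = np.arange(1, self.candidates.size + 1)
        return ranks

    def ranked(self) -> list[tuple[int, int, float, int]]:
        """Rows (Kfr, node, frc, support) in rank order."""
        return [
            (k + 1, int(self.candidates[p]), float(self.frc[p]),
             int(self.support_counts[p]))
            for k, p in enumerate(self.kfr_order)
        ]


@dataclass
class ConfigurationOutcome:
    """Network-averaged red outcome for one initial-blue configuration.

    ``frc_value`` is None when the estimate is undefined (support below the
    minimum threshold in conditional mode).
    """

    configuration: tuple[int, ...]
    frc_value: float | None
    n_ib: int
    support: int

    @property
    def defined(self) -> bool:
        return self.frc_value is not None


def rank_single_blue(
    candidates: Sequence[int],
    matrices: TransitionMatrices,
    panel: NodePanel,
    base_config: SimulationConfig,
) -> BarrageRanking:
    """Rank candidates by frc(i): the mean red outcome with i as the single
    initial blue node (fixed position, n_ib = 1).

    Each candidate run derives its own seed from the base seed so candidate
    order does not affect any estimate.
    """
    candidates = np.asarray(candidates, dtype=np.int64)
    if candidates.size == 0:
        raise ValueError("candidate set is empty")
    frc = np.empty(candidates.size, dtype=np.float64)
    for p, c in enumerate(candidates):
        seed = int(
            np.random.SeedSequence(
                entropy=base_config.seed, spawn_key=(int(c), 1)
            ).generate_state(1)[0] % (2**31)
        )
        cfg = replace(
            base_config,
            placement="fixed_configuration",
            configuration=(int(c),),
            candidate_set=None,
            n_ib=1,
            seed=seed,
        )
        frc[p] = simulate(matrices, panel, cfg).fr_mean
    kfr_order = np.lexsort((candidates, frc))
    return BarrageRanking(
        candidates=candidates,
        frc=frc,
        kfr_order=kfr_order,
        support_counts=np.full(candidates.size, base_config.R, dtype=np.int64),
    )


def conditional_frc(
    stats: OutcomeStats,
    query: int | Sequence[int],
    mode: str = "contains",
    min_support: int = 100,
) -> ConfigurationOutcome:
    """Post-hoc conditional estimate of frc from a random-placement ensemble.

    Averages the realization-level mean red fraction over the realizations
    whose initial-blue set contains the query node(s) (``mode="contains"``)
    or exactly equals the query configuration (``mode="exact"``).  When the
    support falls below ``min_support`` the outcome is flagged undefined
    rather than reported as a number.
    """
    if mode not in ("contains", "exact"):
        raise ValueError(f"unknown conditioning mode {mode!r}")
    query_arr = np.atleast_1d(np.asarray(query, dtype=np.int64))
    q = np.sort(query_arr)
    hits = []
    for r, blues in enumerate(stats.realization_blues):
        if mode == "exact":
            match = np.array_equal(blues, q)
        else:
            match = np.isin(q, blues).all()
        if match:
            hits.append(r)
    support = len(hits)
    value = float(stats.realization_fr[hits].mean()) if support >= min_support else None
    return ConfigurationOutcome(
        configuration=tuple(int(i) for i in query_arr),
        frc_value=value,
        n_ib=q.size,
        support=support,
    )


def evaluate_all_subsets(
    optimal_set: Sequence[int],
    matrices: TransitionMatrices,
    panel: NodePanel,
    base_config: SimulationConfig,
) -> list[ConfigurationOutcome]:
    """Run every subset of a small node set as a fixed configuration.

    Returns 2^k outcomes (including the empty baseline), ordered by subset
    size then lexicographically.
    """
    optimal_set = [int(i) for i in optimal_set]
    k = len(optimal_set)
    if k > 12:
        raise ValueError(f"set of size {k} exceeds the 2^k evaluation limit (k <= 12)")
    outcomes = []
    for size in range(k + 1):
        for combo in itertools.combinations(sorted(optimal_set), size):
            seed = int(
                np.random.SeedSequence(
                    entropy=base_config.seed, spawn_key=(2,) + combo
                ).generate_state(1)[0] % (2**31)
            )
            cfg = replace(
                base_config,
                placement="fixed_configuration",
                configuration=combo,
                candidate_set=None,
                n_ib=len(combo),
                seed=seed,
            )
            st = simulate(matrices, panel, cfg)
            outcomes.append(
                ConfigurationOutcome(
                    configuration=combo,
                    frc_value=st.fr_mean,
                    n_ib=len(combo),
                    support=st.R,
                )
            )
    return outcomes


def select_optimal_group(rankings: Sequence[BarrageRanking], k: int) -> np.ndarray:
    """Pick the k candidates with the smallest summed Kfr positions.

    A rank-sum heuristic over rankings obtained at several n_ib values;
    all rankings must share the same candidate set.  Ties break by
    ascending node index.
    """
    if not rankings:
        raise ValueError("at least one ranking is required")
    base = rankings[0].candidates
    for rk in rankings[1:]:
        if not np.array_equal(np.sort(rk.candidates), np.sort(base)):
            raise ValueError("rankings do not share a candidate set")
    if k > base.size:
        raise ValueError(f"k={k} exceeds the {base.size} candidates")
    rank_sum = np.zeros(base.size, dtype=np.int64)
    for rk in rankings:
        # align candidate order with the first ranking
        pos = {int(c): p for p, c in enumerate(rk.candidates)}
        rank_sum += rk.kfr_rank[[pos[int(c)] for c in base]]
    order = np.lexsort((base, rank_sum))
    return np.sort(base[order[:k]])
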