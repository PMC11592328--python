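"""Independent oracles: dense-matrix dynamics and exact order enumeration.

These deliberately re-implement the spin update with plain dense numpy
loops, independent of the package's sparse kernel, so that agreement is a
genuine cross-check and not a tautology.
"""

from itertools import permutations

import numpy as np


def dense_local_field(Wd: np.ndarray, spins: np.ndarray, i: int) -> float:
    z = 0.0
    for j in range(Wd.shape[0]):
        if j != i:
            z += Wd[i, j] * spins[j]
    return z


def dense_sweep(Wd: np.ndarray, spins: np.ndarray, order) -> int:
    changed = 0
    for i in order:
        z = dense_local_field(Wd, spins, i)
        if z > 0:
            new = 1
        elif z < 0:
            new = -1
        else:
            new = spins[i]
        if new != spins[i]:
            spins[i] = new
            changed += 1
    return changed


def enumerate_outcomes(
    Wd: np.ndarray,
    init_spins: np.ndarray,
    variable: np.ndarray,
    tau_max: int,
) -> dict[tuple, float]:
    """Exact distribution over final states after tau_max random-order sweeps.

    Equivalent to averaging over all (Nv!)^tau_max sweep-order sequences,
    but propagates a probability measure over distinct states instead of
    expanding the sequence tree.
    """
    perms = list(permutations(variable.tolist()))
    p0 = 1.0 / len(perms)
    dist = {tuple(int(s) for s in init_spins): 1.0}
    for _ in range(tau_max):
        new: dict[tuple, float] = {}
        for state, p in dist.items():
            for order in perms:
                spins = np.array(state, dtype=np.int64)
                dense_sweep(Wd, spins, order)
                key = tuple(int(s) for s in spins)
                new[key] = new.get(key, 0.0) + p * p0
        dist = new
    return dist


def exact_fr_per_node(dist: dict[tuple, float], n: int) -> np.ndarray:
    fr = np.zeros(n)
    for state, p in dist.items():
        fr += p * (np.array(state) == 1)
    return fr
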