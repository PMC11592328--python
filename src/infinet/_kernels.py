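"""Numba-compiled inner loop of the asynchronous spin dynamics.

A single compiled kernel performs one asynchronous sweep over a given node
order on the CSR representation of the symmetric coupling W = S~ + S~^T.
Every code path of the package (low-level ``sweep`` API and the realization
engine) goes through this one kernel, so there is a single dynamics
implementation.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def sweep_csr(indptr, indices, data, spins, order):  # pragma: no cover - compiled
    """One asynchronous sweep: update spins along ``order`` in place.

    For each node i in order, the local field Z_i = sum_j W_ij * sigma_j is
    evaluated on the *current* spins (updates are immediately visible to
    later nodes in the same sweep) and sigma_i becomes sign(Z_i), unchanged
    when Z_i == 0.  Returns the number of spins that changed value.
    """
    n_changed = 0
    for k in range(order.size):
        i = order[k]
        z = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            z += data[p] * spins[indices[p]]
        if z > 0.0:
            new = np.int8(1)
        elif z < 0.0:
            new = np.int8(-1)
        else:
            new = spins[i]
        if new != spins[i]:
            spins[i] = new
            n_changed += 1
    return n_changed
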