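"""JIT-compiled double-edge-swap kernel for degree-preserving rewiring."""

import numba
import numpy as np


@numba.njit(cache=True)
def double_edge_swap(A, u, v, e1, e2, orient):  # pragma: no cover - jitted
    """Attempt a sequence of Maslov-Sneppen swaps in place.

    ``A`` is a symmetric uint8 adjacency; (``u``, ``v``) list the current
    edges; attempt t proposes replacing edges e1[t]=(a,b) and e2[t]=(c,d)
    (optionally with c,d transposed) by (a,c) and (b,d).  Proposals that
    would create a self-loop or a duplicate edge are rejected, which keeps
    the degree sequence exactly.
    """
    for t in range(e1.shape[0]):
        p, q = e1[t], e2[t]
        if p == q:
            continue
        a, b = u[p], v[p]
        c, d = u[q], v[q]
        if orient[t] == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if A[a, c] == 1 or A[b, d] == 1:
            continue
        A[a, b] = 0
        A[b, a] = 0
        A[c, d] = 0
        A[d, c] = 0
        A[a, c] = 1
        A[c, a] = 1
        A[b, d] = 1
        A[d, b] = 1
        u[p], v[p] = a, c
        u[q], v[q] = b, d
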