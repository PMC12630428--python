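"""Exact counterfactual prevalences by enumeration of the binary DAG.

Given conditional success-probability functions for the intermediate
confounders L (given exposure, baseline confounders C, and earlier L), the
mediators M (given exposure, C, L, earlier M), and an outcome mean function
(given exposure, C, L, M), this module computes counterfactual outcome means

    p(x_d, x_m) = E_C [ sum_L P(L | x_d, C) sum_M  Ptilde(M | x_m, C)
                        E(Y | x_d, C, L, M) ]

where Ptilde(M | x_m, C) = sum_L' P(L' | x_m, C) P(M | x_m, C, L') is the
mediator-block distribution marginalized over an independent draw of the
intermediate confounders under x_m — the randomized interventional analogue
of natural effects.  The expectation over C runs over supplied rows
(optionally weighted), so only the post-exposure block needs to be binary.

There is no simulation error: this is the oracle the Monte-Carlo g-formula
is checked against.
"""

from __future__ import annotations

from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np

ProbFn = Callable[[str, Mapping[str, np.ndarray | float]], np.ndarray]


def enumerate_prevalences(
    prob: ProbFn,
    outcome_mean: ProbFn,
    c_data: Mapping[str, np.ndarray],
    exposure: str,
    l_names: Sequence[str],
    m_names: Sequence[str],
    outcome: str,
    scenarios: Sequence[tuple[int, int]],
    weights: np.ndarray | None = None,
    chunk_size: int = 4096,
) -> dict[tuple[int, int], float]:
    """Exact p(x_direct, x_mediator) for each requested scenario.

    ``prob(name, ctx)`` must return P(name = 1 | ctx) for binary L/M
    variables; ``outcome_mean(name, ctx)`` the conditional outcome mean.
    ``ctx`` maps variable names to scalars or arrays over the C-row chunk.
    """
    names = list(c_data)
    n = len(np.asarray(c_data[names[0]])) if names else 1
    w = np.ones(n) / n if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()

    l_configs = list(product((0.0, 1.0), repeat=len(l_names)))
    m_configs = list(product((0.0, 1.0), repeat=len(m_names)))
    x_values = sorted({x for sc in scenarios for x in sc})

    totals = {sc: 0.0 for sc in scenarios}
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        ctx_c = {name: np.asarray(c_data[name])[sl] for name in names}
        w_chunk = w[sl]
        m = len(w_chunk)

        # P(L = config | x, C) for both exposure values, shape (m, n_lconfigs)
        p_l: dict[int, np.ndarray] = {}
        for x in x_values:
            cols = []
            for lconf in l_configs:
                p = np.ones(m)
                ctx = dict(ctx_c)
                ctx[exposure] = float(x)
                for j, lname in enumerate(l_names):
                    pj = np.broadcast_to(prob(lname, ctx), (m,))
                    p = p * (pj if lconf[j] == 1.0 else 1.0 - pj)
                    ctx[lname] = lconf[j]
                cols.append(p)
            p_l[x] = np.column_stack(cols) if cols else np.ones((m, 1))

        # Ptilde(M = config | x, C): marginalized over an independent L draw
        p_m: dict[int, np.ndarray] = {}
        for x in x_values:
            cols = []
            for mconf in m_configs:
                acc = np.zeros(m)
                for li, lconf in enumerate(l_configs):
                    ctx = dict(ctx_c)
                    ctx[exposure] = float(x)
                    for j, lname in enumerate(l_names):
                        ctx[lname] = lconf[j]
                    pm = np.ones(m)
                    for k, mname in enumerate(m_names):
                        pk = np.broadcast_to(prob(mname, ctx), (m,))
                        pm = pm * (pk if mconf[k] == 1.0 else 1.0 - pk)
                        ctx[mname] = mconf[k]
                    acc += p_l[x][:, li] * pm
                cols.append(acc)
            p_m[x] = np.column_stack(cols) if cols else np.ones((m, 1))

        # E(Y | x_d, C, L, M) for each (L, M) configuration
        y_val: dict[int, np.ndarray] = {}
        for x in sorted({sc[0] for sc in scenarios}):
            grid = np.empty((m, len(l_configs), len(m_configs)))
            for li, lconf in enumerate(l_configs):
                for mi, mconf in enumerate(m_configs):
                    ctx = dict(ctx_c)
                    ctx[exposure] = float(x)
                    for j, lname in enumerate(l_names):
                        ctx[lname] = lconf[j]
                    for k, mname in enumerate(m_names):
                        ctx[mname] = mconf[k]
                    grid[:, li, mi] = np.broadcast_to(outcome_mean(outcome, ctx), (m,))
            y_val[x] = grid

        for sc in scenarios:
            x_d, x_m = sc
            # sum over L (drawn under x_d, feeds Y) and M (marginal under x_m)
            per_row = np.einsum("il,im,ilm->i", p_l[x_d], p_m[x_m], y_val[x_d])
            totals[sc] += float(per_row @ w_chunk)
    return totals
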