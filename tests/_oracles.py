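"""Straight-line reference implementations used as independent oracles.

Deliberately written with nested loops and no shared code with the
package: these are the ground truth the vectorised pipeline is checked
against.
"""

import math

import numpy as np


def brute_pearson(u, v):
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    num = sum((u[i] - mu) * (v[i] - mv) for i in range(n))
    du = math.sqrt(sum((u[i] - mu) ** 2 for i in range(n)))
    dv = math.sqrt(sum((v[i] - mv) ** 2 for i in range(n)))
    if du == 0 or dv == 0:
        return 0.0
    return max(-1.0, min(1.0, num / (du * dv)))


def brute_force_score(q_ids, q_rows, p_ids, p_rows, beta, threshold):
    """Correlation -> strict filter -> overlap masking -> weighted row-max
    mean, all with plain loops."""
    N, M = len(q_ids), len(p_ids)
    if N == 0 or M == 0:
        return 0.0
    C = [[brute_pearson(q_rows[k], p_rows[l]) for l in range(M)] for k in range(N)]
    for k in range(N):
        for l in range(M):
            if not C[k][l] > threshold:
                C[k][l] = 0.0
    for l in range(M):
        if p_ids[l] in q_ids:
            k_match = q_ids.index(p_ids[l])
            for k in range(N):
                C[k][l] = 0.0
            C[k_match][l] = 1.0
    total = 0.0
    for k in range(N):
        best = 0.0
        for l in range(M):
            value = C[k][l]
            if p_ids[l] in q_ids and q_ids.index(p_ids[l]) == k:
                value = beta * C[k][l]
            if value > best:
                best = value
        total += best
    return total / N


def random_instance(rng):
    """Random (query, pathway) encodings with overlaps and near-duplicate
    rows so both the filter and the overlap mask fire."""
    N = int(rng.integers(1, 9))
    M = int(rng.integers(1, 9))
    d = int(rng.integers(3, 17))
    names = [f"G{i}" for i in range(N + M)]
    q_ids = names[:N]
    q = rng.standard_normal((N, d))
    p_ids, p_rows = [], []
    for l in range(M):
        kind = rng.random()
        if kind < 0.3:  # exact overlap: same gene, same vector
            k = int(rng.integers(0, N))
            p_ids.append(q_ids[k])
            p_rows.append(q[k].copy())
        elif kind < 0.6:  # near-duplicate: passes the 0.9 filter often
            k = int(rng.integers(0, N))
            p_ids.append(names[N + l])
            p_rows.append(q[k] + 0.05 * rng.standard_normal(d))
        else:
            p_ids.append(names[N + l])
            p_rows.append(rng.standard_normal(d))
    seen, ids, rows = set(), [], []
    for ident, row in zip(p_ids, p_rows):
        if ident in seen:
            continue
        seen.add(ident)
        ids.append(ident)
        rows.append(row)
    return q_ids, q, ids, np.array(rows)
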