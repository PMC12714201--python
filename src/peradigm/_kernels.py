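"""Numba kernels: CBOW word2vec training and without-replacement sampling.

Both are single-threaded and fully deterministic given their seeds: all
stochasticity comes from numba's per-kernel np.random state, and CBOW
vector initialization is seeded outside.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sample_means(values: np.ndarray, n: int, n_reps: int, seed: int) -> np.ndarray:
    """Means of n_reps independent size-n without-replacement samples.

    Rejection sampling keeps each replicate O(n) for n << pool; a partial
    Fisher-Yates shuffle handles dense draws (n > pool/2).
    """
    np.random.seed(seed)
    pool = values.shape[0]
    out = np.empty(n_reps)
    if n * 2 <= pool:
        taken = np.zeros(pool, dtype=np.uint8)
        picked = np.empty(n, dtype=np.int64)
        for r in range(n_reps):
            total = 0.0
            count = 0
            while count < n:
                j = np.random.randint(pool)
                if taken[j] == 0:
                    taken[j] = 1
                    picked[count] = j
                    total += values[j]
                    count += 1
            out[r] = total / n
            for k in range(n):
                taken[picked[k]] = 0
    else:
        idx = np.arange(pool)
        for r in range(n_reps):
            total = 0.0
            for k in range(n):
                j = k + np.random.randint(pool - k)
                tmp = idx[k]
                idx[k] = idx[j]
                idx[j] = tmp
                total += values[idx[k]]
            out[r] = total / n
    return out


@njit(cache=True)
def _train_epochs(
    tokens: np.ndarray,  # int32 concatenated sentences
    offsets: np.ndarray,  # int64 sentence boundaries, len = n_sent + 1
    syn0: np.ndarray,  # (V, d) input vectors, updated in place
    syn1: np.ndarray,  # (V, d) output vectors, updated in place
    neg_table: np.ndarray,  # int32 unigram^0.75 sampling table
    window: int,
    negative: int,
    epochs: int,
    alpha0: float,
    alpha_min: float,
    seed: int,
) -> None:
    np.random.seed(seed)
    d = syn0.shape[1]
    n_sent = offsets.shape[0] - 1
    total = epochs * tokens.shape[0]
    processed = 0
    neu1 = np.empty(d, dtype=np.float32)
    neu1e = np.empty(d, dtype=np.float32)
    tbl = neg_table.shape[0]
    for _ in range(epochs):
        for s in range(n_sent):
            lo = offsets[s]
            hi = offsets[s + 1]
            for t in range(lo, hi):
                alpha = alpha0 - (alpha0 - alpha_min) * (processed / total)
                processed += 1
                target = tokens[t]
                a = t - window if t - window > lo else lo
                b = t + window + 1 if t + window + 1 < hi else hi
                cn = 0
                for j in range(d):
                    neu1[j] = 0.0
                for c in range(a, b):
                    if c == t:
                        continue
                    wc = tokens[c]
                    for j in range(d):
                        neu1[j] += syn0[wc, j]
                    cn += 1
                if cn == 0:
                    continue
                inv = 1.0 / cn
                for j in range(d):
                    neu1[j] *= inv
                    neu1e[j] = 0.0
                for k in range(negative + 1):
                    if k == 0:
                        w = target
                        label = 1.0
                    else:
                        w = neg_table[np.random.randint(tbl)]
                        if w == target:
                            continue
                        label = 0.0
                    f = 0.0
                    for j in range(d):
                        f += neu1[j] * syn1[w, j]
                    if f > 8.0:
                        g = (label - 1.0) * alpha
                    elif f < -8.0:
                        g = label * alpha
                    else:
                        g = (label - 1.0 / (1.0 + np.exp(-f))) * alpha
                    for j in range(d):
                        neu1e[j] += g * syn1[w, j]
                        syn1[w, j] += g * neu1[j]
                for c in range(a, b):
                    if c == t:
                        continue
                    wc = tokens[c]
                    for j in range(d):
                        syn0[wc, j] += neu1e[j] * inv
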