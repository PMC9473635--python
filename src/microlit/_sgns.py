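"""Numba kernel for skip-gram with negative sampling.

Single-threaded, explicitly seeded (64-bit LCG), float32 throughout: two
runs with the same encoded corpus and seed produce bitwise-identical
vectors. The update rule is the classic SGNS gradient step with a dynamic
(uniformly shrunk) context window and a linearly decaying learning rate.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LCG_MULT = 6364136223846793005
_LCG_INC = 1442695040888963407
_MAX_EXP = 6.0


@njit(cache=True)
def _next(state):
    return state * _LCG_MULT + _LCG_INC


@njit(cache=True)
def _rand31(state):
    # top bits of an LCG are the well-mixed ones
    return (state >> 33) & 0x7FFFFFFF


@njit(cache=True)
def train_sgns(data, offsets, syn0, syn1, table, window, negative,
               alpha0, min_alpha, epochs, seed):
    """Train in place.

    data: int32 token ids, all documents concatenated
    offsets: int64 document boundaries (len = n_docs + 1)
    syn0: float32 (V, D) input vectors -- the published embedding
    syn1: float32 (V, D) output (context) vectors
    table: int32 negative-sampling table (unigram^0.75)
    """
    dim = syn0.shape[1]
    n_table = len(table)
    total = np.int64(len(data)) * epochs
    if total == 0:
        return
    state = _next(np.int64(seed))
    neu1e = np.zeros(dim, dtype=np.float32)
    processed = np.int64(0)
    for _ in range(epochs):
        for d in range(len(offsets) - 1):
            start = offsets[d]
            end = offsets[d + 1]
            for pos in range(start, end):
                alpha = alpha0 * (1.0 - processed / total)
                if alpha < min_alpha:
                    alpha = min_alpha
                processed += 1
                center = data[pos]
                state = _next(state)
                shrink = _rand31(state) % window
                lo = pos - (window - shrink)
                hi = pos + (window - shrink) + 1
                if lo < start:
                    lo = start
                if hi > end:
                    hi = end
                for pos2 in range(lo, hi):
                    if pos2 == pos:
                        continue
                    ctx = data[pos2]
                    for k in range(dim):
                        neu1e[k] = 0.0
                    for neg in range(negative + 1):
                        if neg == 0:
                            target = center
                            label = 1.0
                        else:
                            state = _next(state)
                            target = table[_rand31(state) % n_table]
                            if target == center:
                                continue
                            label = 0.0
                        f = 0.0
                        for k in range(dim):
                            f += syn0[ctx, k] * syn1[target, k]
                        if f > _MAX_EXP:
                            g = (label - 1.0) * alpha
                        elif f < -_MAX_EXP:
                            g = label * alpha
                        else:
                            g = (label - 1.0 / (1.0 + math.exp(-f))) * alpha
                        gf = np.float32(g)
                        for k in range(dim):
                            neu1e[k] += gf * syn1[target, k]
                        for k in range(dim):
                            syn1[target, k] += gf * syn0[ctx, k]
                    for k in range(dim):
                        syn0[ctx, k] += neu1e[k]
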