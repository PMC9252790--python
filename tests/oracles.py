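"""Independent brute-force oracles for HMM scoring, used only by tests.

The oracles enumerate hidden-state paths explicitly (depth-first over the
sparse transition structure) instead of running any dynamic-programming
recursion, so they are an independent check of the forward-backward
implementation.
"""

from __future__ import annotations

import numpy as np

from varbind.models import FirstOrderTFFM, encode_sequence


def _emission(m: FirstOrderTFFM, state: int, t: int, codes) -> float:
    """Emission probability of state (0=background, 1..L=motif) at position t."""
    c = codes[t]
    if t == 0:
        if c >= 4:
            return 0.25
        if state == 0:
            return float(m.background_emission[c])
        row = m.background_emission @ m.motif_conditional[state - 1]
        return float(row[c])
    p = codes[t - 1]
    table = m.background_conditional if state == 0 else m.motif_conditional[state - 1]
    row = table[p] if p < 4 else m.background_emission @ table
    return 0.25 if c >= 4 else float(row[c])


def _successors(m: FirstOrderTFFM, state: int):
    L = m.length
    if state == 0:
        yield 0, m.background_self_transition
        if m.motif_entry > 0:
            yield 1, m.motif_entry
    elif state < L:
        yield state + 1, 1.0
    else:
        yield 0, 1.0


def enumerate_paths(m: FirstOrderTFFM, seq: str):
    """Yield (path, probability) over all valid complete-occurrence paths.

    Paths start in the background state and must finish in the background
    state or exactly at the final motif position.
    """
    codes = encode_sequence(seq)
    T = codes.size
    L = m.length

    def walk(t, state, prob, path):
        prob = prob * _emission(m, state, t, codes)
        if prob == 0.0:
            return
        path = path + (state,)
        if t == T - 1:
            if state in (0, L):
                yield path, prob
            return
        for nxt, tp in _successors(m, state):
            yield from walk(t + 1, nxt, prob * tp, path)

    yield from walk(0, 0, 1.0, ())


def brute_posterior(m: FirstOrderTFFM, seq: str) -> np.ndarray:
    """Posterior that a motif occurrence ends at each position, by explicit
    enumeration of hidden-state paths."""
    T = len(seq)
    total = 0.0
    end_mass = np.zeros(T)
    for path, prob in enumerate_paths(m, seq):
        total += prob
        for t, state in enumerate(path):
            if state == m.length:
                end_mass[t] += prob
    return end_mass / total if total > 0 else end_mass


def brute_likelihood(m: FirstOrderTFFM, seq: str) -> float:
    return float(sum(prob for _, prob in enumerate_paths(m, seq)))
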