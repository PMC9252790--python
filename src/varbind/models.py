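"""Motif binding models: position weight matrices and TF flexible models.

Two families of transcription-factor binding models are implemented:

* **PWM** — the classical position weight matrix, a log2-odds matrix
  derived from a position count matrix (PCM) of aligned binding sites.
  Window scores are min/max-normalized so every window scores in [0, 1],
  the consensus scores exactly 1 and the anti-consensus exactly 0.

* **TFFM** — transcription factor flexible models, hidden Markov models
  whose emissions depend on the previous nucleotide and therefore capture
  adjacent-position dependencies that PWMs ignore.  Both the *first-order*
  flavour (one state per motif position, previous-base-conditional
  emissions) and the *detailed* flavour (each position decomposed into four
  per-nucleotide states whose transition probabilities carry the
  first-order emissions) are supported.  TFFMs are scored with the
  forward–backward algorithm; the per-window score is the posterior
  probability that the window is a complete motif occurrence, which again
  lies in [0, 1].

All models carry ``tf_name``, ``model_id`` and ``source`` metadata so that
per-model results can be grouped per transcription factor downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BASES",
    "BackgroundDistribution",
    "PositionCountMatrix",
    "PositionWeightMatrix",
    "FirstOrderTFFM",
    "DetailedTFFM",
    "ModelError",
    "encode_sequence",
    "reverse_complement",
    "pcm_to_pwm",
    "information_content",
    "tffm_posterior_scores",
    "sequence_likelihood",
    "build_detailed_from_first_order",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

N_CODE = 4  # code used for N / any unrecognized IUPAC symbol


class ModelError(ValueError):
    """Raised for invalid model definitions or scoring inputs."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(seq), N_CODE, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[raw == ord(base)] = idx
    return out


def decode_sequence(codes: Sequence[int]) -> str:
    return "".join(BASES[c] if c < 4 else "N" for c in codes)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Background distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackgroundDistribution:
    """Genomic background nucleotide distribution (order A, C, G, T)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ModelError("background needs exactly four probabilities")
        if np.any(p <= 0):
            raise ModelError("background probabilities must all be positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ModelError("background probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    @classmethod
    def human(cls) -> "BackgroundDistribution":
        # ~41% GC, the genome-wide human composition used by default.
        return cls(np.array([0.295, 0.205, 0.205, 0.295]))

    @classmethod
    def uniform(cls) -> "BackgroundDistribution":
        return cls(np.full(4, 0.25))

    def __getitem__(self, base: str) -> float:
        return float(self.probs[_BASE_INDEX[base]])


DEFAULT_BACKGROUND = BackgroundDistribution.human()


# ---------------------------------------------------------------------------
# Count and weight matrices
# ---------------------------------------------------------------------------


@dataclass
class PositionCountMatrix:
    """Raw base counts per motif position (rows A, C, G, T)."""

    counts: np.ndarray
    tf_name: str = ""
    model_id: str = ""
    source: str = "custom"

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise ModelError("counts must be a 4 x L matrix with L >= 1")
        if np.any(c < 0):
            raise ModelError("counts must be non-negative")
        if not np.any(c.sum(axis=0) > 0):
            raise ModelError("at least one column must have positive total")
        self.counts = c

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def frequencies(self, pseudocount_scale: float = 0.0,
                    background: BackgroundDistribution | None = None) -> np.ndarray:
        """Column base frequencies with an optional background-weighted pseudocount."""
        bg = (background or BackgroundDistribution.uniform()).probs
        totals = self.counts.sum(axis=0)
        if np.any(totals + pseudocount_scale <= 0):
            raise ModelError("degenerate motif column")
        k = float(pseudocount_scale)
        return (self.counts + k * bg[:, None]) / (totals + k)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


class PositionWeightMatrix:
    """Log2-odds matrix with cached score extrema for [0, 1] normalization."""

    kind = "PWM"

    def __init__(self, weights: np.ndarray, background: BackgroundDistribution,
                 tf_name: str = "", model_id: str = "", source: str = "custom"):
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 4 or w.shape[1] < 1:
            raise ModelError("weights must be a 4 x L matrix")
        self.weights = w
        self.background = background
        self.tf_name = tf_name
        self.model_id = model_id
        self.source = source
        self.min_score = float(w.min(axis=0).sum())
        self.max_score = float(w.max(axis=0).sum())
        # 5th row: expected weight under the background, used for N bases.
        self._ext = np.vstack([w, background.probs @ w])

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=0))

    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmin(axis=0))

    def raw_window_score(self, window: str) -> float:
        codes = encode_sequence(window)
        if codes.size != self.length:
            raise ModelError(
                f"window length {codes.size} != motif length {self.length}")
        return float(self._ext[codes, np.arange(self.length)].sum())

    def window_score(self, window: str) -> float:
        """Normalized score in [0, 1]: (raw - min) / (max - min)."""
        raw = self.raw_window_score(window)
        if self.max_score - self.min_score <= 0:
            return 0.5  # constant-score (degenerate) model
        val = (raw - self.min_score) / (self.max_score - self.min_score)
        return float(min(1.0, max(0.0, val)))

    def window_scores(self, codes: np.ndarray, starts: np.ndarray) -> np.ndarray:
        """Vectorized normalized scores for windows beginning at ``starts``."""
        starts = np.asarray(starts, dtype=np.int64)
        if starts.size == 0:
            return np.empty(0)
        L = self.length
        # sum per-window with the same pairwise reduction as the cached
        # extrema, so a consensus window scores exactly 1.0
        vals = self._ext[codes[starts[:, None] + np.arange(L)], np.arange(L)]
        raw = vals.sum(axis=1)
        span = self.max_score - self.min_score
        if span <= 0:
            return np.full(starts.shape, 0.5)
        return np.clip((raw - self.min_score) / span, 0.0, 1.0)


def pcm_to_pwm(pcm: PositionCountMatrix,
               background: BackgroundDistribution | None = None,
               pseudocount_scale: float | None = None) -> PositionWeightMatrix:
    """Convert a count matrix to a log2-odds weight matrix.

    ``weights[b, i] = log2(((counts[b, i] + k * bg[b]) / (N_i + k)) / bg[b])``
    where ``N_i`` is the column total.  By default the pseudocount ``k`` is
    the square root of the column total; pass an explicit non-negative
    constant to override.
    """
    bg = background or DEFAULT_BACKGROUND
    totals = pcm.counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ModelError(f"degenerate motif column in model {pcm.model_id!r}")
    if pseudocount_scale is None:
        k = np.sqrt(totals)
    else:
        if pseudocount_scale < 0:
            raise ModelError("pseudocount_scale must be >= 0")
        k = np.full_like(totals, float(pseudocount_scale))
    freq = (pcm.counts + k * bg.probs[:, None]) / (totals + k)
    if np.any(freq <= 0):
        raise ModelError(
            f"zero probability in model {pcm.model_id!r}; use a pseudocount")
    weights = np.log2(freq / bg.probs[:, None])
    return PositionWeightMatrix(weights, bg, tf_name=pcm.tf_name,
                                model_id=pcm.model_id, source=pcm.source)


def information_content(pcm: PositionCountMatrix,
                        pseudocount_scale: float = 0.0) -> np.ndarray:
    """Per-column information content in bits: ``2 + sum_b p log2 p``."""
    freq = pcm.frequencies(pseudocount_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(np.where(freq > 0, freq, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return np.clip(ic, 0.0, 2.0)


# ---------------------------------------------------------------------------
# TFFMs
# ---------------------------------------------------------------------------


def _check_rows_stochastic(mat: np.ndarray, what: str) -> None:
    if np.any(mat < -1e-12):
        raise ModelError(f"negative probability in {what}")
    if np.any(np.abs(mat.sum(axis=-1) - 1.0) > 1e-9):
        raise ModelError(f"rows of {what} must sum to 1")


@dataclass
class FirstOrderTFFM:
    """First-order TFFM: one HMM state per motif position.

    Each motif state emits a nucleotide with probabilities conditional on
    the previously emitted base (``motif_conditional[i][prev][cur]``);
    position 0 conditions on the last background base.  A single background
    state emits with ``background_conditional[prev][cur]`` (marginal
    ``background_emission`` at the first sequence position), loops with
    probability ``background_self_transition`` and enters the motif with
    probability ``motif_entry``.  The motif chain is deterministic and
    returns to the background after the final position; a motif occurrence
    must therefore be complete to count, and sequences are required to end
    in the background state or exactly at the final motif position.
    """

    background_emission: np.ndarray
    background_conditional: np.ndarray
    motif_conditional: np.ndarray  # (L, 4, 4)
    background_self_transition: float = 0.9
    motif_entry: float = 0.1
    tf_name: str = ""
    model_id: str = ""
    source: str = "custom"

    kind = "TFFM_first"

    def __post_init__(self):
        self.background_emission = np.asarray(self.background_emission, float)
        self.background_conditional = np.asarray(self.background_conditional, float)
        self.motif_conditional = np.asarray(self.motif_conditional, float)
        if self.background_emission.shape != (4,):
            raise ModelError("background_emission must have four entries")
        _check_rows_stochastic(self.background_emission[None, :], "background emission")
        if self.background_conditional.shape != (4, 4):
            raise ModelError("background_conditional must be 4 x 4")
        _check_rows_stochastic(self.background_conditional, "background conditional")
        if self.motif_conditional.ndim != 3 or self.motif_conditional.shape[1:] != (4, 4) \
                or self.motif_conditional.shape[0] < 1:
            raise ModelError("motif_conditional must be (L, 4, 4) with L >= 1")
        _check_rows_stochastic(self.motif_conditional, "motif conditional")
        if not (0 < self.background_self_transition < 1):
            raise ModelError("background_self_transition must be in (0, 1)")
        if not (0 <= self.motif_entry < 1):
            raise ModelError("motif_entry must be in [0, 1)")
        if self.background_self_transition + self.motif_entry > 1 + 1e-12:
            raise ModelError("background_self_transition + motif_entry must be <= 1")

    @property
    def length(self) -> int:
        return self.motif_conditional.shape[0]

    def _ext_tables(self):
        """Emission tables extended with an N row/column (uniform substitution).

        An N at the emitting position contributes 0.25; an N as the
        conditioning base averages the conditional rows weighted by the
        background marginal.
        """
        bg = self.background_emission

        def extend(table):  # table (..., 4, 4) -> (..., 5, 5)
            marg = np.einsum("p,...pc->...c", bg, table)
            t5 = np.concatenate([table, marg[..., None, :]], axis=-2)
            n_col = np.full(t5.shape[:-1] + (1,), 0.25)
            return np.concatenate([t5, n_col], axis=-1)

        return extend(self.background_conditional), extend(self.motif_conditional)

    def window_scores(self, codes: np.ndarray, starts: np.ndarray) -> np.ndarray:
        """Posterior probability that each window is a complete motif hit.

        The score of the window starting at ``s`` is the forward–backward
        posterior of the full motif path on the local subsequence
        ``codes[s-1 : s+L]`` (one background context base plus the window).
        Exactly two state paths are consistent with a complete occurrence
        or none at all — all-background and background-then-motif — so the
        posterior reduces to ``M / (M + B)`` with ``M`` the motif-path and
        ``B`` the background-path probability.  The score is a function of
        the local window string only, which makes it strand- and
        context-stable for scanning.
        """
        starts = np.asarray(starts, dtype=np.int64)
        if starts.size == 0:
            return np.empty(0)
        L = self.length
        bc5, mc5 = self._ext_tables()
        prev = np.where(starts > 0, codes[np.maximum(starts - 1, 0)], N_CODE)
        log_m = np.log(self.motif_entry) if self.motif_entry > 0 else -np.inf
        log_b = L * np.log(self.background_self_transition)
        m = np.full(starts.shape, log_m)
        b = np.full(starts.shape, log_b)
        with np.errstate(divide="ignore"):
            for i in range(L):
                cur = codes[starts + i]
                m = m + np.log(mc5[i][prev, cur])
                b = b + np.log(bc5[prev, cur])
                prev = cur
        # posterior = e^m / (e^m + e^b), computed stably
        diff = b - m
        out = np.where(np.isneginf(m), 0.0, 1.0 / (1.0 + np.exp(np.clip(diff, -700, 700))))
        return out


@dataclass
class DetailedTFFM:
    """Detailed TFFM: four states per motif position plus four background states.

    State order: background A, C, G, T then position-1 A..T, position-2
    A..T, ...  A state for nucleotide ``b`` deterministically emits ``b``;
    all emission structure of the first-order model lives in the
    row-stochastic ``transition`` matrix.  ``initial`` is the start
    distribution over the four background states.
    """

    motif_length: int
    transition: np.ndarray
    initial: np.ndarray
    tf_name: str = ""
    model_id: str = ""
    source: str = "custom"

    kind = "TFFM_detailed"

    def __post_init__(self):
        L = self.motif_length
        n = 4 + 4 * L
        self.transition = np.asarray(self.transition, float)
        self.initial = np.asarray(self.initial, float)
        if L < 1:
            raise ModelError("motif length must be >= 1")
        if self.transition.shape != (n, n):
            raise ModelError(f"transition matrix must be {n} x {n}")
        if np.any(self.transition < -1e-12):
            raise ModelError("negative probability in transition matrix")
        sums = self.transition.sum(axis=1)
        if np.any(sums > 1 + 1e-9):
            raise ModelError("transition rows must sum to at most 1")
        # motif rows are exactly stochastic; background rows may carry
        # implicit termination mass (mirrors the first-order model where
        # background_self_transition + motif_entry may be < 1)
        if np.any(np.abs(sums[4:] - 1.0) > 1e-9):
            raise ModelError("motif-state transition rows must sum to 1")
        if self.initial.shape != (4,):
            raise ModelError("initial distribution must cover the 4 background states")
        _check_rows_stochastic(self.initial[None, :], "initial distribution")

    @property
    def length(self) -> int:
        return self.motif_length

    def state_base(self, state: int) -> int:
        return state % 4

    def _blocks(self):
        T = self.transition
        L = self.motif_length
        bg = T[0:4, 0:4]                      # background -> background
        entry = T[0:4, 4:8]                   # background -> position 1
        steps = [T[4 * i:4 * i + 4, 4 * i + 4:4 * i + 8] for i in range(1, L)]
        return bg, entry, steps

    def window_scores(self, codes: np.ndarray, starts: np.ndarray) -> np.ndarray:
        """Local complete-occurrence posterior, as for the first-order model.

        Emissions are deterministic, so given the observed bases both the
        all-background and the motif path are unique state sequences whose
        probabilities are products of transition entries.  N bases
        marginalize over the four background states with weight 0.25.
        """
        starts = np.asarray(starts, dtype=np.int64)
        if starts.size == 0:
            return np.empty(0)
        L = self.motif_length
        bg, entry, steps = self._blocks()

        def ext(block):  # add N row (initial-weighted average) and N column (mean/4...)
            marg = self.initial @ block
            b5 = np.vstack([block, marg])
            n_col = b5.sum(axis=1, keepdims=True) * 0.25
            return np.hstack([b5, n_col])

        bg5 = ext(bg)
        entry5 = ext(entry)
        steps5 = [ext(s) for s in steps]
        prev = np.where(starts > 0, codes[np.maximum(starts - 1, 0)], N_CODE)
        with np.errstate(divide="ignore"):
            cur = codes[starts]
            m = np.log(entry5[prev, cur])
            b = np.log(bg5[prev, cur])
            prev2 = cur
            for i in range(1, L):
                cur = codes[starts + i]
                m = m + np.log(steps5[i - 1][prev2, cur])
                b = b + np.log(bg5[prev2, cur])
                prev2 = cur
        diff = b - m
        return np.where(np.isneginf(m), 0.0,
                        1.0 / (1.0 + np.exp(np.clip(diff, -700, 700))))


TFFM = FirstOrderTFFM | DetailedTFFM
MotifModel = PositionWeightMatrix | FirstOrderTFFM | DetailedTFFM


def build_detailed_from_first_order(m: FirstOrderTFFM) -> DetailedTFFM:
    """Decompose a first-order TFFM into its detailed (per-nucleotide) form.

    Transition probabilities of the detailed model carry the emission
    probabilities of the first-order model, so both models assign identical
    likelihoods to every sequence.
    """
    L = m.length
    n = 4 + 4 * L
    T = np.zeros((n, n))
    p_self = m.background_self_transition
    p_entry = m.motif_entry
    for a in range(4):
        for b in range(4):
            T[a, b] = p_self * m.background_conditional[a, b]
            T[a, 4 + b] = p_entry * m.motif_conditional[0, a, b]
    # leftover (1 - p_self - p_entry) is implicit termination mass, as in
    # the first-order model
    for i in range(1, L):
        for a in range(4):
            for b in range(4):
                T[4 * i + a, 4 * (i + 1) + b] = m.motif_conditional[i, a, b]
    for a in range(4):
        for b in range(4):
            T[4 * L + a, b] = m.background_conditional[a, b]
    return DetailedTFFM(motif_length=L, transition=T,
                        initial=m.background_emission.copy(),
                        tf_name=m.tf_name, model_id=m.model_id + ".detailed"
                        if m.model_id else "", source=m.source)


# ---------------------------------------------------------------------------
# Forward-backward
# ---------------------------------------------------------------------------


def _hmm_parts(model: TFFM, codes: np.ndarray):
    """Return (initial, transition, emission matrix e[t, state]) for a sequence.

    Emissions conditional on the previous *observed* base are folded into a
    position-dependent emission vector, so standard forward–backward
    applies.  N bases use the uniform substitution.
    """
    T_len = codes.size
    if isinstance(model, FirstOrderTFFM):
        L = model.length
        n = 1 + L
        bc5, mc5 = model._ext_tables()
        init = np.zeros(n)
        init[0] = 1.0
        trans = np.zeros((n, n))
        trans[0, 0] = model.background_self_transition
        trans[0, 1] = model.motif_entry
        for i in range(1, L):
            trans[i, i + 1] = 1.0
        trans[L, 0] = 1.0
        emis = np.zeros((T_len, n))
        bg5 = np.append(model.background_emission, 0.25)
        for t in range(T_len):
            cur = codes[t]
            c = cur if cur < 4 else 4
            if t == 0:
                emis[t, 0] = bg5[c]
                # motif states unreachable at t=0 (start in background)
                for i in range(L):
                    emis[t, 1 + i] = 0.25 if c == 4 else float(
                        (model.background_emission @ model.motif_conditional[i])[c])
            else:
                p = codes[t - 1]
                pp = p if p < 4 else 4
                emis[t, 0] = bc5[pp, c]
                for i in range(L):
                    emis[t, 1 + i] = mc5[i][pp, c]
        final_mask = np.zeros(n, bool)
        final_mask[0] = True
        final_mask[L] = True
        return init, trans, emis, final_mask
    elif isinstance(model, DetailedTFFM):
        L = model.motif_length
        n = 4 + 4 * L
        init = np.zeros(n)
        init[0:4] = model.initial
        trans = model.transition
        emis = np.zeros((T_len, n))
        states_base = np.arange(n) % 4
        for t in range(T_len):
            c = codes[t]
            if c >= 4:
                emis[t, :] = 0.25
            else:
                emis[t, :] = (states_base == c).astype(float)
        final_mask = np.zeros(n, bool)
        final_mask[0:4] = True
        final_mask[4 * L:4 * L + 4] = True
        return init, trans, emis, final_mask
    raise ModelError(f"not a TFFM: {type(model).__name__}")


def _forward_backward(init, trans, emis, final_mask):
    """Scaled forward–backward conditioned on ending in an allowed state.

    Returns per-position posterior state probabilities (T x n) and the
    log-likelihood of the sequence (paths ending mid-motif excluded).
    """
    T_len, n = emis.shape
    alpha = np.zeros((T_len, n))
    scale = np.zeros(T_len)
    a = init * emis[0]
    s = a.sum()
    if s == 0:
        return np.zeros((T_len, n)), -np.inf
    alpha[0] = a / s
    scale[0] = s
    for t in range(1, T_len):
        a = (alpha[t - 1] @ trans) * emis[t]
        s = a.sum()
        if s == 0:
            return np.zeros((T_len, n)), -np.inf
        alpha[t] = a / s
        scale[t] = s
    beta = np.zeros((T_len, n))
    beta[-1] = final_mask.astype(float)
    for t in range(T_len - 2, -1, -1):
        beta[t] = (trans @ (beta[t + 1] * emis[t + 1])) / scale[t + 1]
    norm = float(alpha[-1] @ beta[-1])
    if norm == 0:
        return np.zeros((T_len, n)), -np.inf
    gamma = alpha * beta / norm
    loglik = float(np.log(scale).sum() + np.log(norm))
    return gamma, loglik


def tffm_posterior_scores(model: TFFM, sequence: str) -> np.ndarray:
    """Posterior probability, per position, that a motif occurrence ends there.

    Computed with the forward–backward algorithm over the whole sequence,
    conditioning on valid terminations (the chain must finish in the
    background state or exactly at the last motif position — a binding
    site cannot be truncated by the sequence end).  For detailed models the
    four per-nucleotide sub-states of the final position are summed.
    """
    codes = encode_sequence(sequence)
    L = model.length
    if codes.size < L:
        import warnings
        warnings.warn("sequence shorter than the motif; no positions scored")
        return np.empty(0)
    if isinstance(model, FirstOrderTFFM) and model.motif_entry == 0:
        return np.zeros(codes.size)
    init, trans, emis, final_mask = _hmm_parts(model, codes)
    gamma, _ = _forward_backward(init, trans, emis, final_mask)
    if isinstance(model, FirstOrderTFFM):
        post = gamma[:, L]
    else:
        post = gamma[:, 4 * L:4 * L + 4].sum(axis=1)
    return np.clip(post, 0.0, 1.0)


def sequence_likelihood(model: TFFM, sequence: str) -> float:
    """Likelihood of a sequence under a TFFM (complete-occurrence paths only)."""
    codes = encode_sequence(sequence)
    init, trans, emis, final_mask = _hmm_parts(model, codes)
    _, loglik = _forward_backward(init, trans, emis, final_mask)
    return float(np.exp(loglik)) if np.isfinite(loglik) else 0.0
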