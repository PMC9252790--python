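"""Variant-effect scanning: WT/MT window maxima and the signed joint score.

For every motif model the scanner evaluates a sliding window whose start
offset runs from ``-window_halfwidth`` to ``+window_halfwidth`` nucleotides
around the variant location, on both the reference ("wild-type", WT) and
the variant ("mutated", MT) sequence and on both strands.  The highest
normalized window scores (0 <= WT, MT <= 1) are combined into a signed
joint score

    S = 2 / (1 + 2**(-2 F)) - 1

    F = -(1 - MT + a) / (1 - WT + a) + 1   if WT >  MT
    F =  (1 - WT + a) / (1 - MT + a) - 1   if WT <= MT

with pseudocount ``a`` (default 0.1) keeping the denominators positive.
S runs from -1 (likely binding-site loss) to +1 (likely gain); the
inverted scores ``1 - WT`` / ``1 - MT`` enter the ratio because model
scores correlate with whether binding is possible at all, and the ratio
reacts most strongly near the top of the score range.

Per transcription factor, the joint scores of the individual models are
averaged; when both TFFMs and PWMs are available, only the TFFMs enter
the combined prediction by default.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .models import MotifModel, encode_sequence, reverse_complement

__all__ = [
    "Variant",
    "SequencePair",
    "ScanConfig",
    "ScanOutcome",
    "TFPrediction",
    "ScanError",
    "joint_score",
    "best_window_score",
    "scan_variant",
    "combine_per_tf",
    "variant_to_sequence_pair",
    "category_label",
]

_VARIANT_RE = re.compile(
    r"^(?P<chrom>[\w.]+):(?P<pos>\d+)(?P<ref>[ACGTacgt]+)>(?P<alt>[ACGTacgt]+)$")


class ScanError(ValueError):
    """Raised for unanalysable variants or invalid scan inputs."""


@dataclass(frozen=True)
class Variant:
    """A DNA variant: chromosome, 1-based position, ref and alt allele."""

    chrom: str
    pos: int  # 1-based position of the first ref base
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ScanError("variant position must be 1-based and positive")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or not re.fullmatch("[ACGT]+", allele):
                raise ScanError(f"{name} allele must be non-empty A/C/G/T")
        if self.ref == self.alt:
            raise ScanError("ref and alt alleles must differ")

    @classmethod
    def from_string(cls, text: str) -> "Variant":
        """Parse chromosomal notation like ``1:160001799G>C``."""
        m = _VARIANT_RE.match(text.strip())
        if not m:
            raise ScanError(f"cannot parse variant notation: {text!r}")
        return cls(m["chrom"], int(m["pos"]), m["ref"].upper(), m["alt"].upper())

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class SequencePair:
    """Reference and mutated sequence with the variant anchor position.

    ``variant_offset`` is the 0-based index of the first variant base
    within ``wt_seq``; windows are anchored there in each sequence's own
    coordinate frame.
    """

    wt_seq: str
    mt_seq: str
    variant_offset: int
    ref: str = ""
    alt: str = ""

    @classmethod
    def from_sequences(cls, wt_seq: str, mt_seq: str) -> "SequencePair":
        """Build a pair from two raw sequences, deriving the differing span."""
        wt, mt = wt_seq.upper(), mt_seq.upper()
        if wt == mt:
            raise ScanError("sequences are identical; no variant to analyse")
        lead = 0
        while lead < min(len(wt), len(mt)) and wt[lead] == mt[lead]:
            lead += 1
        trail = 0
        while (trail < min(len(wt), len(mt)) - lead
               and wt[len(wt) - 1 - trail] == mt[len(mt) - 1 - trail]):
            trail += 1
        off = lead
        ref = wt[lead:len(wt) - trail]
        alt = mt[lead:len(mt) - trail]
        if not ref or not alt:  # pure indel: left-anchor on the shared base
            if lead == 0:
                raise ScanError("indel at the very start of the sequence "
                                "cannot be left-anchored")
            off = lead - 1
            ref = wt[off:len(wt) - trail]
            alt = mt[off:len(mt) - trail]
        return cls(wt, mt, off, ref=ref, alt=alt)

    @classmethod
    def from_variant(cls, variant: Variant, wt_seq: str, variant_offset: int) -> "SequencePair":
        wt = wt_seq.upper()
        end = variant_offset + len(variant.ref)
        if wt[variant_offset:end] != variant.ref:
            raise ScanError(
                f"reference allele does not match genome at {variant}")
        mt = wt[:variant_offset] + variant.alt + wt[end:]
        return cls(wt, mt, variant_offset, ref=variant.ref, alt=variant.alt)


@dataclass
class ScanConfig:
    """Scan parameters.

    window_halfwidth: largest window-start offset evaluated on either side
        of the variant (nucleotides).
    alpha: pseudocount of the joint-score ratio.
    tffm_only_default: combine per-TF predictions from TFFMs only when any
        TFFM is available for that factor.
    both_strands: score the reverse strand as well.
    max_variants: cap on the number of variants accepted from a VCF.
    """

    window_halfwidth: int = 15
    alpha: float = 0.1
    tffm_only_default: bool = True
    both_strands: bool = True
    max_variants: int = 10000

    def __post_init__(self):
        if self.window_halfwidth < 1:
            raise ScanError("window_halfwidth must be >= 1")
        if self.alpha <= 0:
            raise ScanError("alpha must be > 0")


@dataclass
class ScanOutcome:
    """Per-model result: WT and MT maxima, joint score, best windows."""

    model_id: str
    tf_name: str
    model_kind: str  # PWM | TFFM_first | TFFM_detailed
    source: str
    WT: float
    MT: float
    S: float
    best_wt_offset: int | None
    best_wt_strand: str | None
    best_mt_offset: int | None
    best_mt_strand: str | None


@dataclass
class TFPrediction:
    """Combined per-transcription-factor prediction."""

    tf_name: str
    combined_S: float
    n_models_used: int
    tffm_only_used: bool
    outcomes: list[ScanOutcome] = field(default_factory=list)


def joint_score(WT, MT, alpha: float = 0.1):
    """Signed joint score S in (-1, 1) from the WT and MT window maxima.

    Accepts scalars or numpy arrays.  S is exactly 0 when WT == MT,
    negative when the reference scores higher (predicted loss of binding)
    and positive when the variant scores higher (predicted gain).
    """
    wt = np.asarray(WT, dtype=float)
    mt = np.asarray(MT, dtype=float)
    if np.any((wt < 0) | (wt > 1) | (mt < 0) | (mt > 1)):
        raise ScanError("WT and MT scores must lie in [0, 1]")
    if alpha <= 0:
        raise ScanError("alpha must be > 0")
    loss = -(1.0 - mt + alpha) / (1.0 - wt + alpha) + 1.0
    gain = (1.0 - wt + alpha) / (1.0 - mt + alpha) - 1.0
    F = np.where(wt > mt, loss, gain)
    S = 2.0 / (1.0 + np.exp2(-2.0 * F)) - 1.0
    if np.isscalar(WT) and np.isscalar(MT):
        return float(S)
    return S


def category_label(S: float) -> str:
    """Cosmetic loss/gain bin for display; the raw S is always reported."""
    mag = abs(S)
    if mag < 0.2:
        return "neutral"
    strength = "weak" if mag < 0.5 else ("moderate" if mag < 0.8 else "strong")
    direction = "loss" if S < 0 else "gain"
    return f"{strength}_{direction}"


@dataclass(frozen=True)
class WindowHit:
    score: float
    offset: int | None  # window start relative to the variant start
    strand: str | None


def _window_starts(variant_offset: int, seq_len: int, L: int,
                   start_range: tuple[int, int]) -> np.ndarray:
    lo = max(0, variant_offset + start_range[0])
    hi = min(seq_len - L, variant_offset + start_range[1])
    if hi < lo:
        return np.empty(0, dtype=np.int64)
    return np.arange(lo, hi + 1, dtype=np.int64)


def _scores_both_strands(model: MotifModel, codes: np.ndarray,
                         rc_codes: np.ndarray, starts: np.ndarray,
                         both_strands: bool):
    """Scores for windows at ``starts`` on + and (optionally) - strand."""
    n = codes.size
    L = model.length
    plus = model.window_scores(codes, starts)
    if not both_strands:
        return [("+", plus)]
    rc_starts = n - L - starts
    minus = model.window_scores(rc_codes, rc_starts)
    return [("+", plus), ("-", minus)]


def best_window_score(model: MotifModel, seq: str, variant_offset: int,
                      cfg: ScanConfig | None = None,
                      start_range: tuple[int, int] | None = None) -> WindowHit:
    """Maximum model score over windows around the variant anchor.

    Windows whose start offset relative to ``variant_offset`` lies within
    ``start_range`` (default ``[-window_halfwidth, +window_halfwidth]``)
    and that fit entirely inside the sequence are evaluated on both
    strands.  Ties are broken by smallest absolute offset, then by the
    smaller signed offset, forward strand first, so results are
    deterministic.
    """
    cfg = cfg or ScanConfig()
    if start_range is None:
        start_range = (-cfg.window_halfwidth, cfg.window_halfwidth)
    codes = encode_sequence(seq)
    starts = _window_starts(variant_offset, codes.size, model.length, start_range)
    if starts.size == 0:
        warnings.warn(f"no scorable window for model {model.model_id} "
                      f"at offset {variant_offset}")
        return WindowHit(0.0, None, None)
    rc_codes = encode_sequence(reverse_complement(seq)) if cfg.both_strands else codes
    return _best_hit(model, codes, rc_codes, variant_offset, start_range,
                     cfg.both_strands)


def _best_hit(model, codes, rc_codes, variant_offset, start_range, both_strands):
    starts = _window_starts(variant_offset, codes.size, model.length, start_range)
    if starts.size == 0:
        return WindowHit(0.0, None, None)
    offsets = starts - variant_offset
    candidates = []
    for s_idx, (strand, scores) in enumerate(
            _scores_both_strands(model, codes, rc_codes, starts, both_strands)):
        candidates.append((scores, offsets, strand, s_idx))
    # pick max score; ties -> smallest |offset|, then signed offset, then '+'
    best_key = None
    best = None
    for scores, offs, strand, s_idx in candidates:
        for i in range(offs.size):
            key = (-float(scores[i]), abs(int(offs[i])), int(offs[i]), s_idx)
            if best_key is None or key < best_key:
                best_key = key
                best = WindowHit(float(scores[i]), int(offs[i]), strand)
    return best


def scan_variant(pair: SequencePair, models: Sequence[MotifModel],
                 cfg: ScanConfig | None = None) -> list[ScanOutcome]:
    """Score every model on the WT and MT sequence and derive joint scores.

    Windows are anchored at the variant start in each sequence's own
    coordinate frame.  Deletions longer than twice the window halfwidth
    abolish every scorable placement of a binding site and are rejected.
    """
    cfg = cfg or ScanConfig()
    if not models:
        raise ScanError("no models supplied")
    if pair.ref and pair.alt:
        deletion = len(pair.ref) - len(pair.alt)
        if deletion > 2 * cfg.window_halfwidth:
            raise ScanError(
                "deletion abolishes complete TFBS; not analysable "
                f"(deletion of {deletion} nt exceeds {2 * cfg.window_halfwidth} nt)")
    start_range = (-cfg.window_halfwidth, cfg.window_halfwidth)
    wt_codes = encode_sequence(pair.wt_seq)
    mt_codes = encode_sequence(pair.mt_seq)
    wt_rc = encode_sequence(reverse_complement(pair.wt_seq))
    mt_rc = encode_sequence(reverse_complement(pair.mt_seq))
    outcomes = []
    for model in models:
        wt_hit = _best_hit(model, wt_codes, wt_rc, pair.variant_offset,
                           start_range, cfg.both_strands)
        mt_hit = _best_hit(model, mt_codes, mt_rc, pair.variant_offset,
                           start_range, cfg.both_strands)
        S = joint_score(wt_hit.score, mt_hit.score, cfg.alpha)
        outcomes.append(ScanOutcome(
            model_id=model.model_id, tf_name=model.tf_name,
            model_kind=model.kind, source=model.source,
            WT=wt_hit.score, MT=mt_hit.score, S=S,
            best_wt_offset=wt_hit.offset, best_wt_strand=wt_hit.strand,
            best_mt_offset=mt_hit.offset, best_mt_strand=mt_hit.strand))
    return outcomes


def combine_per_tf(outcomes: Iterable[ScanOutcome],
                   tffm_only: bool = True) -> list[TFPrediction]:
    """Average per-model joint scores into one prediction per factor.

    With ``tffm_only`` (the default) and at least one TFFM outcome for a
    factor, only TFFM joint scores enter the average; otherwise all models
    contribute.
    """
    by_tf: dict[str, list[ScanOutcome]] = {}
    for o in outcomes:
        by_tf.setdefault(o.tf_name, []).append(o)
    predictions = []
    for tf_name, group in by_tf.items():
        if not group:
            continue
        tffms = [o for o in group if o.model_kind != "PWM"]
        use_tffm_only = bool(tffm_only and tffms)
        selected = tffms if use_tffm_only else group
        combined = float(np.mean([o.S for o in selected]))
        predictions.append(TFPrediction(
            tf_name=tf_name, combined_S=combined,
            n_models_used=len(selected), tffm_only_used=use_tffm_only,
            outcomes=group))
    predictions.sort(key=lambda p: (-abs(p.combined_S), p.tf_name))
    return predictions


def variant_to_sequence_pair(variant: Variant, genome: Mapping[str, object],
                             cfg: ScanConfig | None = None,
                             max_model_length: int = 1) -> SequencePair:
    """Extract the sequence context a scan needs from an indexed genome.

    The wild-type sequence covers
    ``[pos - halfwidth - (Lmax - 1), pos + |ref| - 1 + halfwidth + (Lmax - 1)]``
    (1-based inclusive, clipped at the chromosome ends) so that every
    window in the +-halfwidth start range is fully scorable for the
    longest selected model.  ``genome`` may be a plain dict of strings or a
    ``pyfaidx.Fasta``-like object.
    """
    cfg = cfg or ScanConfig()
    chrom_seq = _chrom_sequence(genome, variant.chrom)
    if chrom_seq is None:
        raise ScanError(f"unknown chromosome {variant.chrom!r}")
    n = len(chrom_seq)
    pad = cfg.window_halfwidth + max(1, max_model_length) - 1
    start0 = max(0, variant.pos - 1 - pad)  # 0-based inclusive
    end0 = min(n, variant.pos - 1 + len(variant.ref) + pad)  # 0-based exclusive
    if variant.pos - 1 + len(variant.ref) > n:
        raise ScanError(f"variant {variant} lies beyond the chromosome end")
    wt = str(chrom_seq[start0:end0]).upper()
    return SequencePair.from_variant(variant, wt, variant.pos - 1 - start0)


def _chrom_sequence(genome, chrom: str):
    """Fetch a chromosome from dict-like or pyfaidx-like genomes, tolerating
    a 'chr' prefix mismatch."""
    names = [chrom, f"chr{chrom}"]
    if chrom.startswith("chr"):
        names.append(chrom[3:])
    for name in names:
        try:
            return genome[name]
        except KeyError:
            continue
    return None
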