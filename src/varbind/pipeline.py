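"""End-to-end analysis: variants + genome + models -> per-TF predictions."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

from .filters import FilterConfig, apply_model_filters
from .io import AnnotatedVariant, KnownSiteIndex, VariantResult
from .models import (
    BackgroundDistribution,
    DetailedTFFM,
    FirstOrderTFFM,
    MotifModel,
    PositionCountMatrix,
    pcm_to_pwm,
)
from .scan import (
    ScanConfig,
    ScanError,
    SequencePair,
    TFPrediction,
    Variant,
    combine_per_tf,
    scan_variant,
    variant_to_sequence_pair,
)

__all__ = ["prepare_models", "analyse_pair", "analyse_variant",
           "analyse_variants", "load_genome"]


def prepare_models(raw_models: Sequence,
                   background: BackgroundDistribution | None = None,
                   pseudocount_scale: float | None = None) -> list[MotifModel]:
    """Convert raw models to scorable form (PCMs become PWMs)."""
    out: list[MotifModel] = []
    for m in raw_models:
        if isinstance(m, PositionCountMatrix):
            out.append(pcm_to_pwm(m, background, pseudocount_scale))
        elif isinstance(m, (FirstOrderTFFM, DetailedTFFM)):
            out.append(m)
        else:
            out.append(m)  # already scorable (e.g. a PWM)
    return out


def load_genome(path: str | Path):
    """Open a FASTA as an indexed, lazily-read genome."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def analyse_pair(pair: SequencePair, models: Sequence[MotifModel],
                 cfg: ScanConfig | None = None,
                 tffm_only: bool | None = None) -> list[TFPrediction]:
    """Scan one sequence pair and combine outcomes per transcription factor."""
    cfg = cfg or ScanConfig()
    outcomes = scan_variant(pair, models, cfg)
    if tffm_only is None:
        tffm_only = cfg.tffm_only_default
    return combine_per_tf(outcomes, tffm_only)


def analyse_variant(variant: Variant, genome: Mapping, models: Sequence[MotifModel],
                    cfg: ScanConfig | None = None,
                    known_sites: KnownSiteIndex | None = None,
                    filter_cfg: FilterConfig | None = None,
                    tffm_only: bool | None = None) -> VariantResult:
    """Analyse a single variant against a genome; errors are captured
    per-variant rather than aborting a batch."""
    cfg = cfg or ScanConfig()
    hits = known_sites.query(variant.chrom, variant.pos) if known_sites else []
    selected = list(models)
    if filter_cfg is not None:
        selected = apply_model_filters(selected, known_sites, variant, filter_cfg)
    if not selected:
        warnings.warn(f"no models selected for {variant}; no predictions")
        return VariantResult(variant, [], hits)
    lmax = max(m.length for m in selected)
    try:
        pair = variant_to_sequence_pair(variant, genome, cfg, lmax)
        predictions = analyse_pair(pair, selected, cfg, tffm_only)
    except ScanError as exc:
        return VariantResult(variant, [], hits, error=str(exc))
    return VariantResult(variant, predictions, hits)


def analyse_variants(variants: Sequence[Variant | AnnotatedVariant],
                     genome: Mapping, models: Sequence[MotifModel],
                     cfg: ScanConfig | None = None,
                     known_sites: KnownSiteIndex | None = None,
                     filter_cfg: FilterConfig | None = None,
                     tffm_only: bool | None = None) -> list[VariantResult]:
    cfg = cfg or ScanConfig()
    if len(variants) > cfg.max_variants:
        raise ScanError(f"{len(variants)} variants exceed the "
                        f"{cfg.max_variants} variant cap")
    results = []
    for v in variants:
        variant = v.variant if isinstance(v, AnnotatedVariant) else v
        results.append(analyse_variant(variant, genome, models, cfg,
                                       known_sites, filter_cfg, tffm_only))
    return results
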