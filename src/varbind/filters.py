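"""Variant- and model-level filters mirroring the interactive search modes.

Variant filters act on VCF annotations: candidate-gene vicinity, custom
genomic regions, sequencing depth, homozygosity and population allele
frequency (from a user-supplied INFO field).  Model filters restrict which
motif models are evaluated for a given variant: by model kind, source,
explicit TF list, or to factors with a known binding site overlapping the
variant position.

All filters are conjunctive, so their application order does not matter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io import AnnotatedVariant, KnownSiteIndex, FormatError, normalize_chrom
from .scan import Variant

__all__ = [
    "FilterConfig",
    "GeneRecord",
    "read_gene_table",
    "apply_variant_filters",
    "apply_model_filters",
]


@dataclass(frozen=True)
class GeneRecord:
    """Gene span (0-based half-open) with strand for vicinity filtering."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


def read_gene_table(path: str | Path) -> dict[str, GeneRecord]:
    """Read a gene-coordinate table: BED6 or a TSV with a header line.

    The TSV header must contain ``gene``/``name``, ``chrom``, ``start``,
    ``end`` and optionally ``strand``; coordinates are 0-based half-open
    in both layouts.
    """
    genes: dict[str, GeneRecord] = {}
    with open(path) as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    if not rows:
        raise FormatError(f"{path}: empty gene table")
    header = [c.strip().lower() for c in rows[0]]
    if "start" in header and ("gene" in header or "name" in header):
        name_col = header.index("gene") if "gene" in header else header.index("name")
        cols = {c: header.index(c) for c in ("chrom", "start", "end")}
        strand_col = header.index("strand") if "strand" in header else None
        for r in rows[1:]:
            rec = GeneRecord(r[name_col], r[cols["chrom"]],
                             int(r[cols["start"]]), int(r[cols["end"]]),
                             r[strand_col] if strand_col is not None else "+")
            genes[rec.name] = rec
    else:  # BED: chrom start end name [score] [strand]
        for r in rows:
            if len(r) < 4:
                raise FormatError(f"{path}: BED gene table needs >= 4 columns")
            genes[r[3]] = GeneRecord(r[3], r[0], int(r[1]), int(r[2]),
                                     r[5] if len(r) > 5 else "+")
    return genes


@dataclass
class FilterConfig:
    """Active filters; ``None`` / empty means a filter is off.

    ``regions`` are (chrom, start, end) 0-based half-open intervals.  A
    variant passes the positional filter if it falls inside any region OR
    within the flank of any candidate gene.  ``flank_upstream`` /
    ``flank_downstream`` default to 5 kb / 1 kb around the annotated gene
    span (strand-aware).  The allele-frequency filter keeps variants with
    AF <= ``max_allele_freq`` (boundary inclusive); variants lacking an AF
    annotation are kept and flagged.
    """

    regions: list[tuple[str, int, int]] = field(default_factory=list)
    candidate_genes: list[str] = field(default_factory=list)
    flank_upstream: int = 5000
    flank_downstream: int = 1000
    min_depth: int | None = None
    homozygous_only: bool = False
    max_allele_freq: float | None = None
    known_tfbs_only: bool = False
    model_kinds: set[str] = field(default_factory=set)  # subset of kinds
    sources: set[str] = field(default_factory=set)
    tf_names: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.flank_upstream < 0 or self.flank_downstream < 0:
            raise ValueError("gene flanks must be >= 0")
        if self.max_allele_freq is not None and not (0 <= self.max_allele_freq <= 1):
            raise ValueError("max_allele_freq must lie in [0, 1]")


def _gene_window(gene: GeneRecord, up: int, down: int) -> tuple[int, int]:
    if gene.strand == "-":
        return gene.start - down, gene.end + up
    return gene.start - up, gene.end + down


def _passes_position(v: Variant, cfg: FilterConfig,
                     gene_table: dict[str, GeneRecord] | None) -> bool:
    if not cfg.regions and not cfg.candidate_genes:
        return True
    pos0 = v.pos - 1
    chrom = normalize_chrom(v.chrom)
    for (c, s, e) in cfg.regions:
        if normalize_chrom(c) == chrom and s <= pos0 < e:
            return True
    for name in cfg.candidate_genes:
        gene = gene_table[name]  # presence validated by caller
        if normalize_chrom(gene.chrom) != chrom:
            continue
        s, e = _gene_window(gene, cfg.flank_upstream, cfg.flank_downstream)
        if s <= pos0 < e:
            return True
    return False


def apply_variant_filters(variants: Sequence[AnnotatedVariant],
                          cfg: FilterConfig,
                          gene_table: dict[str, GeneRecord] | None = None
                          ) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Keep variants passing every active filter; returns (kept, counts).

    The counts dictionary logs how many variants each filter removed.
    """
    if cfg.candidate_genes:
        if gene_table is None:
            raise FormatError("candidate_genes filter needs a gene table")
        missing = sorted(set(cfg.candidate_genes) - set(gene_table))
        if missing:
            raise FormatError(
                "candidate genes absent from gene table: " + ", ".join(missing))
    counts = {"input": len(variants), "position": 0, "depth": 0,
              "homozygosity": 0, "allele_freq": 0, "kept": 0}
    kept: list[AnnotatedVariant] = []
    for av in variants:
        if not _passes_position(av.variant, cfg, gene_table):
            counts["position"] += 1
            continue
        if cfg.min_depth is not None and (av.depth is not None
                                          and av.depth < cfg.min_depth):
            counts["depth"] += 1
            continue
        if cfg.homozygous_only and av.homozygous is False:
            counts["homozygosity"] += 1
            continue
        if cfg.max_allele_freq is not None:
            if av.allele_freq is None:
                if "af_missing" not in av.flags:
                    av.flags.append("af_missing")
            elif av.allele_freq > cfg.max_allele_freq:
                counts["allele_freq"] += 1
                continue
        kept.append(av)
    counts["kept"] = len(kept)
    return kept, counts


def apply_model_filters(models: Sequence, known_sites: KnownSiteIndex | None,
                        variant: Variant, cfg: FilterConfig) -> list:
    """Models selected for one variant: kind/source/TF intersection, and
    optionally only factors with a known site overlapping the variant."""
    selected = list(models)
    if cfg.model_kinds:
        selected = [m for m in selected if m.kind in cfg.model_kinds]
    if cfg.sources:
        selected = [m for m in selected if m.source in cfg.sources]
    if cfg.tf_names:
        selected = [m for m in selected if m.tf_name in cfg.tf_names]
    if cfg.known_tfbs_only:
        if known_sites is None:
            raise FormatError("known_tfbs_only filter needs known-site tracks")
        bound = known_sites.tf_names_at(variant.chrom, variant.pos)
        selected = [m for m in selected if m.tf_name in bound]
    return selected
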