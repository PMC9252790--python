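"""Readers and writers for the standard formats the tool touches.

Formats supported:

* **VCF 4.x** (plain or bgzipped, via pysam) for variant input, with
  per-record depth / genotype / allele-frequency annotations when present.
* **JASPAR PFM** text (via Bio.motifs) for position count matrices.
* A documented **JSON model dialect** covering PCMs and both TFFM
  flavours (see :func:`write_models_json`), round-trip safe.
* **TFFM XML** in a strict GHMM-style dialect (states / discrete
  emissions / transitions elements); anything unrecognized is a hard
  error, never a silent default.
* **BED3+** known-TFBS interval tracks with the TF name in column 4.
* The **TSV results report** (complete table, per-model table, summary).

Coordinate conventions: BED is 0-based half-open; VCF and chromosomal
notation are 1-based.  Conversions happen here and nowhere else.
Chromosome names are normalized by stripping a ``chr`` prefix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from lxml import etree

from .models import (
    DetailedTFFM,
    FirstOrderTFFM,
    ModelError,
    PositionCountMatrix,
)
from .scan import ScanConfig, TFPrediction, Variant, category_label

__all__ = [
    "AnnotatedVariant",
    "KnownSite",
    "KnownSiteIndex",
    "VariantResult",
    "FormatError",
    "read_vcf",
    "read_known_sites",
    "read_models",
    "write_models_json",
    "write_tffm_xml",
    "write_report",
    "normalize_chrom",
]


class FormatError(ValueError):
    """Raised for malformed or unsupported input files."""


def normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedVariant:
    """A variant plus the per-record annotations the filters understand."""

    variant: Variant
    depth: int | None = None
    homozygous: bool | None = None
    allele_freq: float | None = None
    flags: list[str] = field(default_factory=list)


def read_vcf(path: str | Path, max_variants: int = 10000,
             af_field: str = "AF") -> list[AnnotatedVariant]:
    """Read variants from a VCF 4.x file (plain or gzipped).

    Multi-allelic records are expanded to one variant per ALT allele;
    symbolic and structural ALTs are skipped with a warning.  More than
    ``max_variants`` resulting variants is an error naming the cap.
    """
    import pysam

    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if alt is None or not alt.isalpha() or \
                        not set(alt.upper()) <= set("ACGT"):
                    warnings.warn(
                        f"skipping symbolic/structural ALT {alt!r} at "
                        f"{rec.chrom}:{rec.pos}")
                    continue
                if rec.ref is None or not set(rec.ref.upper()) <= set("ACGT"):
                    warnings.warn(
                        f"skipping record with non-ACGT REF at {rec.chrom}:{rec.pos}")
                    continue
                try:
                    variant = Variant(rec.chrom, rec.pos, rec.ref.upper(),
                                      alt.upper())
                except ValueError as exc:
                    raise FormatError(
                        f"malformed VCF record at {rec.chrom}:{rec.pos}: {exc}"
                    ) from exc
                out.append(AnnotatedVariant(
                    variant,
                    depth=_record_depth(rec),
                    homozygous=_record_homozygous(rec, alt),
                    allele_freq=_record_af(rec, alt, af_field)))
                if len(out) > max_variants:
                    raise FormatError(
                        f"VCF exceeds the {max_variants} variant cap; "
                        "restrict the input or raise --max-variants")
    return out


def _record_depth(rec) -> int | None:
    if "DP" in rec.info:
        val = rec.info["DP"]
        return int(val[0] if isinstance(val, tuple) else val)
    for sample in rec.samples.values():
        if "DP" in sample and sample["DP"] is not None:
            return int(sample["DP"])
    return None


def _record_homozygous(rec, alt: str) -> bool | None:
    try:
        alt_index = list(rec.alts).index(alt) + 1
    except (ValueError, TypeError):
        return None
    for sample in rec.samples.values():
        gt = sample.get("GT")
        if gt and None not in gt:
            return all(g == alt_index for g in gt)
    return None


def _record_af(rec, alt: str, af_field: str) -> float | None:
    if af_field not in rec.info:
        return None
    val = rec.info[af_field]
    if isinstance(val, tuple):
        try:
            idx = list(rec.alts).index(alt)
            return float(val[idx]) if idx < len(val) else None
        except (ValueError, TypeError):
            return None
    return float(val)


# ---------------------------------------------------------------------------
# Known TFBS intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KnownSite:
    """An experimentally supported binding interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    tf_name: str
    source: str = "custom"

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError("known site needs start < end")
        if not self.tf_name:
            raise FormatError("known site needs a TF name")


class KnownSiteIndex:
    """Point-queryable interval index of known binding sites."""

    def __init__(self, sites: Iterable[KnownSite] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for site in sites:
            self.add(site)

    def add(self, site: KnownSite) -> None:
        tree = self._trees.setdefault(normalize_chrom(site.chrom), IntervalTree())
        tree.addi(site.start, site.end, site)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, chrom: str, pos: int) -> list[KnownSite]:
        """All sites overlapping a 1-based genomic position."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos - 1)]
        hits.sort(key=lambda s: (s.tf_name, s.source, s.start, s.end))
        return hits

    def tf_names_at(self, chrom: str, pos: int) -> set[str]:
        return {s.tf_name for s in self.query(chrom, pos)}


def read_known_sites(paths) -> KnownSiteIndex:
    """Read BED3+ tracks (TF name in column 4) into one interval index.

    ``paths`` is an iterable of paths or ``(path, source_label)`` pairs;
    a bare path uses its file stem as the source label.  Records with
    ``start >= end`` are rejected with a warning.
    """
    index = KnownSiteIndex()
    for entry in paths:
        if isinstance(entry, (tuple, list)):
            path, source = entry
        else:
            path, source = entry, Path(entry).stem
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise FormatError(
                        f"{path}:{lineno}: BED needs >= 4 columns (TF name in col 4)")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
                if start >= end:
                    warnings.warn(f"{path}:{lineno}: start >= end, record rejected")
                    continue
                index.add(KnownSite(fields[0], start, end, fields[3], source))
    return index


# ---------------------------------------------------------------------------
# Motif models: JASPAR PFM, JSON dialect, TFFM XML
# ---------------------------------------------------------------------------


RawModel = PositionCountMatrix | FirstOrderTFFM | DetailedTFFM


def read_models(paths, source: str | None = None) -> list[RawModel]:
    """Read motif models from files or directories, auto-detecting formats.

    Detection is by content: ``>`` starts a JASPAR PFM file, ``{`` or
    ``[`` the JSON dialect, ``<`` the TFFM XML dialect.  Duplicate model
    ids are an error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    files: list[Path] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            files.extend(sorted(q for q in p.iterdir() if q.is_file()))
        else:
            files.append(p)
    models: list[RawModel] = []
    for f in files:
        text = f.read_text()
        head = text.lstrip()[:1]
        if head == ">" or _looks_like_pfm(text):
            models.extend(_read_jaspar_pfm(f, source))
        elif head in "{[":
            models.extend(read_models_json(f, source))
        elif head == "<":
            models.append(read_tffm_xml(f, source))
        else:
            raise FormatError(f"{f}: unrecognized model format")
    seen: set[str] = set()
    for m in models:
        if m.model_id in seen:
            raise FormatError(f"duplicate model id {m.model_id!r}")
        seen.add(m.model_id)
    return models


def _looks_like_pfm(text: str) -> bool:
    lines = [l for l in text.splitlines() if l.strip()]
    return len(lines) == 4 and all(l.lstrip()[:1] in "ACGT0123456789" for l in lines)


def _read_jaspar_pfm(path: Path, source: str | None) -> list[PositionCountMatrix]:
    from Bio import motifs

    with open(path) as fh:
        try:
            parsed = motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse JASPAR PFM: {exc}") from exc
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        try:
            pcm = PositionCountMatrix(
                counts,
                tf_name=(m.name or m.matrix_id or path.stem),
                model_id=(m.matrix_id or m.name or path.stem),
                source=source or "JASPAR")
        except ModelError as exc:
            raise FormatError(f"{path}: invalid PFM {m.matrix_id}: {exc}") from exc
        out.append(pcm)
    return out


# --- JSON dialect ----------------------------------------------------------


def model_to_dict(model: RawModel) -> dict:
    meta = {"model_id": model.model_id, "tf_name": model.tf_name,
            "source": model.source}
    if isinstance(model, PositionCountMatrix):
        return {"kind": "PCM", "counts": model.counts.tolist(), **meta}
    if isinstance(model, FirstOrderTFFM):
        return {"kind": "TFFM_first",
                "background_emission": model.background_emission.tolist(),
                "background_conditional": model.background_conditional.tolist(),
                "motif_conditional": model.motif_conditional.tolist(),
                "background_self_transition": model.background_self_transition,
                "motif_entry": model.motif_entry, **meta}
    if isinstance(model, DetailedTFFM):
        return {"kind": "TFFM_detailed", "motif_length": model.motif_length,
                "initial": model.initial.tolist(),
                "transition": model.transition.tolist(), **meta}
    raise FormatError(f"cannot serialize {type(model).__name__}")


def model_from_dict(d: dict, source: str | None = None) -> RawModel:
    kind = d.get("kind")
    meta = dict(tf_name=d.get("tf_name", ""), model_id=d.get("model_id", ""),
                source=source or d.get("source", "custom"))
    try:
        if kind == "PCM":
            return PositionCountMatrix(np.array(d["counts"], float), **meta)
        if kind == "TFFM_first":
            return FirstOrderTFFM(
                background_emission=np.array(d["background_emission"], float),
                background_conditional=np.array(d["background_conditional"], float),
                motif_conditional=np.array(d["motif_conditional"], float),
                background_self_transition=float(d["background_self_transition"]),
                motif_entry=float(d["motif_entry"]), **meta)
        if kind == "TFFM_detailed":
            return DetailedTFFM(
                motif_length=int(d["motif_length"]),
                initial=np.array(d["initial"], float),
                transition=np.array(d["transition"], float), **meta)
    except (KeyError, ModelError) as exc:
        raise FormatError(
            f"invalid model {d.get('model_id', '?')!r}: {exc}") from exc
    raise FormatError(f"unknown model kind {kind!r}")


def read_models_json(path: str | Path, source: str | None = None) -> list[RawModel]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict) and "models" in data:
        data = data["models"]
    if isinstance(data, dict):
        data = [data]
    return [model_from_dict(d, source) for d in data]


def write_models_json(models: Sequence[RawModel], path: str | Path) -> None:
    payload = {"format": "varbind-models", "version": 1,
               "models": [model_to_dict(m) for m in models]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# --- TFFM XML (GHMM-style dialect) ----------------------------------------


def write_tffm_xml(model: FirstOrderTFFM | DetailedTFFM, path: str | Path) -> None:
    """Write a TFFM as GHMM-style XML (states / discrete emissions / transitions)."""
    root = etree.Element("mixture")
    hmm = etree.SubElement(root, "HMM", name=model.model_id or "tffm",
                           tf=model.tf_name, source=model.source,
                           kind=("first_order" if isinstance(model, FirstOrderTFFM)
                                 else "detailed"))
    etree.SubElement(hmm, "alphabet").text = "ACGT"
    fmt = lambda vals: ", ".join(f"{v:.12g}" for v in np.asarray(vals).ravel())
    if isinstance(model, FirstOrderTFFM):
        st = etree.SubElement(hmm, "state", id="0", initial="1")
        etree.SubElement(st, "discrete", order="0").text = fmt(model.background_emission)
        etree.SubElement(st, "discrete", order="1").text = fmt(model.background_conditional)
        for i in range(model.length):
            st = etree.SubElement(hmm, "state", id=str(i + 1))
            etree.SubElement(st, "discrete", order="1").text = fmt(model.motif_conditional[i])
        _add_transition(hmm, 0, 0, model.background_self_transition)
        _add_transition(hmm, 0, 1, model.motif_entry)
        for i in range(1, model.length):
            _add_transition(hmm, i, i + 1, 1.0)
        _add_transition(hmm, model.length, 0, 1.0)
    else:
        n = 4 + 4 * model.motif_length
        for s in range(n):
            attrs = {"id": str(s)}
            if s < 4:
                attrs["initial"] = f"{model.initial[s]:.12g}"
            st = etree.SubElement(hmm, "state", **attrs)
            onehot = np.zeros(4)
            onehot[s % 4] = 1.0
            etree.SubElement(st, "discrete", order="0").text = fmt(onehot)
        for a in range(n):
            for b in range(n):
                if model.transition[a, b] > 0:
                    _add_transition(hmm, a, b, model.transition[a, b])
    Path(path).write_bytes(etree.tostring(root, pretty_print=True,
                                          xml_declaration=True, encoding="UTF-8"))


def _add_transition(hmm, source: int, target: int, prob: float) -> None:
    tr = etree.SubElement(hmm, "transition", source=str(source), target=str(target))
    etree.SubElement(tr, "probability").text = f"{prob:.12g}"


def read_tffm_xml(path: str | Path, source: str | None = None):
    """Read a TFFM from the GHMM-style XML dialect, validating strictly."""
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: not well-formed XML: {exc}") from exc
    hmm = root.find("HMM") if root.tag == "mixture" else root
    if hmm is None or hmm.tag != "HMM":
        raise FormatError(f"{path}: expected a <mixture><HMM> document")
    kind = hmm.get("kind")
    meta = dict(model_id=hmm.get("name", Path(path).stem),
                tf_name=hmm.get("tf", ""),
                source=source or hmm.get("source", "custom"))
    alphabet = hmm.findtext("alphabet", "").strip()
    if alphabet != "ACGT":
        raise FormatError(f"{path}: unsupported alphabet {alphabet!r}")
    states: dict[int, dict] = {}
    transitions: dict[tuple[int, int], float] = {}
    for el in hmm:
        if el.tag == "alphabet":
            continue
        if el.tag == "state":
            sid = int(el.get("id"))
            entry = {"initial": float(el.get("initial", 0.0)), "discrete": {}}
            for d in el:
                if d.tag != "discrete":
                    raise FormatError(f"{path}: unexpected <{d.tag}> in state {sid}")
                order = int(d.get("order", 0))
                vals = np.array([float(v) for v in d.text.replace(",", " ").split()])
                entry["discrete"][order] = vals
            states[sid] = entry
        elif el.tag == "transition":
            s, t = int(el.get("source")), int(el.get("target"))
            p = el.findtext("probability")
            if p is None:
                raise FormatError(f"{path}: transition {s}->{t} missing probability")
            transitions[(s, t)] = float(p)
        else:
            raise FormatError(f"{path}: unexpected element <{el.tag}>")
    try:
        if kind == "first_order":
            return _first_order_from_xml(states, transitions, meta)
        if kind == "detailed":
            return _detailed_from_xml(states, transitions, meta)
    except (KeyError, ModelError) as exc:
        raise FormatError(f"{path}: invalid TFFM: {exc}") from exc
    raise FormatError(f"{path}: unknown or missing TFFM kind {kind!r}")


def _first_order_from_xml(states, transitions, meta) -> FirstOrderTFFM:
    n_states = len(states)
    L = n_states - 1
    if L < 1 or sorted(states) != list(range(n_states)):
        raise ModelError("first-order TFFM needs states 0..L")
    bg = states[0]
    mc = np.stack([states[i + 1]["discrete"][1].reshape(4, 4) for i in range(L)])
    for i in range(1, L):
        if abs(transitions.get((i, i + 1), 0.0) - 1.0) > 1e-9:
            raise ModelError(f"motif chain transition {i}->{i + 1} must be 1")
    if abs(transitions.get((L, 0), 0.0) - 1.0) > 1e-9:
        raise ModelError("final motif state must return to background")
    return FirstOrderTFFM(
        background_emission=bg["discrete"][0],
        background_conditional=bg["discrete"][1].reshape(4, 4),
        motif_conditional=mc,
        background_self_transition=transitions.get((0, 0), 0.0),
        motif_entry=transitions.get((0, 1), 0.0), **meta)


def _detailed_from_xml(states, transitions, meta) -> DetailedTFFM:
    n = len(states)
    if n < 8 or n % 4 != 0 or sorted(states) != list(range(n)):
        raise ModelError("detailed TFFM needs 4 + 4L consecutive states")
    L = n // 4 - 1
    for sid, st in states.items():
        emis = st["discrete"].get(0)
        if emis is None or emis.shape != (4,) or \
                abs(emis[sid % 4] - 1.0) > 1e-9 or abs(emis.sum() - 1.0) > 1e-9:
            raise ModelError(f"state {sid} must deterministically emit base {sid % 4}")
    T = np.zeros((n, n))
    for (s, t), p in transitions.items():
        if not (0 <= s < n and 0 <= t < n):
            raise ModelError(f"transition {s}->{t} outside the state space")
        T[s, t] = p
    initial = np.array([states[i]["initial"] for i in range(4)])
    return DetailedTFFM(motif_length=L, initial=initial, transition=T, **meta)


# ---------------------------------------------------------------------------
# Results report
# ---------------------------------------------------------------------------


@dataclass
class VariantResult:
    """All predictions for one variant, plus known-site annotation."""

    variant: Variant
    predictions: list[TFPrediction] = field(default_factory=list)
    known_sites: list[KnownSite] = field(default_factory=list)
    error: str | None = None

    def known_sources_for(self, tf_name: str) -> list[str]:
        return sorted({s.source for s in self.known_sites if s.tf_name == tf_name})


MAIN_COLUMNS = ["variant", "chrom", "pos", "ref", "alt", "tf_name",
                "combined_S", "category", "n_models_used", "tffm_only",
                "known_tfbs", "known_sources"]
MODEL_COLUMNS = ["variant", "tf_name", "model_id", "model_kind", "source",
                 "WT", "MT", "S", "wt_offset", "wt_strand", "mt_offset",
                 "mt_strand"]


def _fmt(x) -> str:
    if x is None:
        return "."
    if isinstance(x, float):
        return f"{x:.6f}"
    if isinstance(x, bool):
        return "1" if x else "0"
    return str(x)


def write_report(results: Sequence[VariantResult], out_prefix: str | Path,
                 cfg: ScanConfig | None = None,
                 filter_summary: dict | None = None) -> dict[str, Path]:
    """Write the complete TSV report, the per-model table and a summary.

    Output is deterministic: variants keep their input order and within a
    variant the factors are sorted by decreasing ``|combined_S|`` (name as
    tie-break).  Returns the paths written.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    main_path = out_prefix.with_suffix(".tsv")
    model_path = out_prefix.with_suffix(".models.tsv")
    summary_path = out_prefix.with_suffix(".summary.tsv")

    main_lines = ["\t".join(MAIN_COLUMNS)]
    model_lines = ["\t".join(MODEL_COLUMNS)]
    n_rows = 0
    for res in results:
        v = res.variant
        if res.error:
            continue
        for pred in res.predictions:  # already sorted by |combined_S|
            sources = res.known_sources_for(pred.tf_name)
            main_lines.append("\t".join(_fmt(x) for x in [
                str(v), v.chrom, v.pos, v.ref, v.alt, pred.tf_name,
                pred.combined_S, category_label(pred.combined_S),
                pred.n_models_used, pred.tffm_only_used,
                bool(sources), ";".join(sources) if sources else None]))
            n_rows += 1
            for o in sorted(pred.outcomes, key=lambda o: o.model_id):
                model_lines.append("\t".join(_fmt(x) for x in [
                    str(v), o.tf_name, o.model_id, o.model_kind, _model_source(o),
                    o.WT, o.MT, o.S, o.best_wt_offset, o.best_wt_strand,
                    o.best_mt_offset, o.best_mt_strand]))
    if n_rows == 0:
        main_lines.append("# no results after filtering")
    main_path.write_text("\n".join(main_lines) + "\n")
    model_path.write_text("\n".join(model_lines) + "\n")

    summary = {"n_variants": len(results),
               "n_variants_failed": sum(1 for r in results if r.error),
               "n_rows": n_rows}
    if cfg is not None:
        summary.update(window_halfwidth=cfg.window_halfwidth, alpha=cfg.alpha,
                       tffm_only_default=cfg.tffm_only_default,
                       both_strands=cfg.both_strands)
    if filter_summary:
        summary.update(filter_summary)
    summary_lines = ["key\tvalue"] + [f"{k}\t{_fmt(v)}" for k, v in summary.items()]
    for res in results:
        if res.error:
            summary_lines.append(f"error:{res.variant}\t{res.error}")
    summary_path.write_text("\n".join(summary_lines) + "\n")
    return {"main": main_path, "models": model_path, "summary": summary_path}


def _model_source(outcome) -> str:
    return getattr(outcome, "source", ".") or "."
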