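"""Deterministic synthetic fixtures: models, genomes, planted sites, variants.

Everything the scanner consumes can be generated here from a single seed,
so the whole pipeline builds and tests without downloading any external
motif database or genome.  The generator emulates:

* motif count matrices with tunable per-column conservation,
* first-order TFFMs whose emissions depend on the previous base with a
  tunable dependency strength (0 = PWM-equivalent, 1 = maximally
  position-coupled),
* a background genome with planted consensus occurrences on both strands,
  "near-consensus" sites one base short of perfect, and engineered
  neutral zones,
* a VCF of variants with known expected effect directions: loss variants
  destroy a planted consensus at its most informative column, gain
  variants complete a near-consensus, neutral variants change a base
  whose local context provably leaves every model's best window score
  unchanged.

The neutral construction deserves a note: the variant sits in a
two-base-period tandem repeat that already carries the alternate allele in
the equivalent repeat phase 14 nt downstream.  Within the +-15 window
range every window string readable in the mutated sequence is also
readable in the reference (shifted by 14 nt) and vice versa, on both
strands, for any motif up to 12 nt.  Best-window maxima are therefore
*identical* between the two alleles and the joint score is exactly zero
for every model — a repeat-mediated "the allele already exists nearby"
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    BASES,
    BackgroundDistribution,
    DEFAULT_BACKGROUND,
    FirstOrderTFFM,
    PositionCountMatrix,
    build_detailed_from_first_order,
    information_content,
    reverse_complement,
)

__all__ = [
    "FixtureSpec",
    "make_pcm",
    "make_tffm",
    "make_tffm_for_pcm",
    "make_model_set",
    "make_genome_with_sites",
    "make_disrupting_vcf",
    "make_known_sites_bed",
    "write_fixture_dir",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Largest motif the engineered neutral zones are valid for; with the
# +-15 window range and a 14-nt repeat displacement, window reads of
# length L+1 <= 14 can never straddle both the variant and its
# pre-mutated repeat copy.
MAX_MOTIF_LENGTH = 12
_NEUTRAL_SHIFT = 14       # displacement of the pre-mutated repeat copy
_NEUTRAL_UNIT = 2         # tandem repeat period (divides the shift)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic replicate.

    Defaults are sized for fast, fully-deterministic test fixtures: a
    handful of factors with motifs of 6-10 bp (typical eukaryotic core
    motif lengths), moderate previous-base dependency, and a genome just
    large enough to hold well-separated planted features.
    """

    seed: int = 0
    n_tfs: int = 5
    motif_length: tuple[int, int] = (6, 10)
    dependency_strength: float = 0.3
    genome_length: int = 6000
    n_planted_sites: int = 3
    n_variants: int = 9
    concentration: float = 12.0
    chrom: str = "chrS"

    def __post_init__(self):
        lo, hi = self.motif_length
        if not (2 <= lo <= hi <= MAX_MOTIF_LENGTH):
            raise ValueError(
                f"motif lengths must lie in [2, {MAX_MOTIF_LENGTH}]")
        if min(self.n_tfs, self.n_planted_sites, self.n_variants,
               self.genome_length) < 1:
            raise ValueError("all fixture counts must be >= 1")
        if not 0 <= self.dependency_strength <= 1:
            raise ValueError("dependency_strength must lie in [0, 1]")

    @property
    def n_neutral(self) -> int:
        return max(1, self.n_variants - 2 * self.n_planted_sites)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def make_pcm(seed: int, length: int, concentration: float = 12.0,
             total: float = 100.0, tf_name: str = "", model_id: str = "",
             source: str = "synthetic") -> PositionCountMatrix:
    """Random count matrix around a random consensus.

    ``concentration`` controls conservation: 0 gives near-uniform columns
    (information content ~ 0 bits), large values approach one-hot columns
    (2 bits).
    """
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=length)
    counts = np.empty((4, length))
    for i in range(length):
        base = np.ones(4)
        base[consensus[i]] += concentration
        jitter = rng.gamma(30.0, 1.0 / 30.0, size=4)
        p = base * jitter
        p /= p.sum()
        counts[:, i] = p * total
    return PositionCountMatrix(counts, tf_name=tf_name,
                               model_id=model_id or f"SYN{seed % 10**6:06d}",
                               source=source)


def make_tffm(seed: int, length: int, dependency_strength: float,
              background: BackgroundDistribution | None = None,
              self_transition: float = 0.999, motif_entry: float = 0.001,
              tf_name: str = "", model_id: str = "",
              source: str = "synthetic") -> FirstOrderTFFM:
    """Random first-order TFFM with tunable previous-base dependency.

    At strength 0 every conditional row within a position is identical,
    so the model is exactly a PWM in HMM form; at strength 1 the rows are
    (floored) one-hot distributions on bases permuted by the previous
    base, i.e. maximally different.
    """
    rng = np.random.default_rng(seed)
    bg = (background or DEFAULT_BACKGROUND).probs
    s = float(dependency_strength)
    mc = np.empty((length, 4, 4))
    for i in range(length):
        p = rng.dirichlet(np.full(4, 0.8) + 4.0 * _onehot(rng.integers(0, 4)))
        for prev in range(4):
            q = np.full(4, 0.005)
            q[(int(np.argmax(p)) + prev) % 4] += 1.0 - 4 * 0.005
            row = (1.0 - s) * p + s * q
            mc[i, prev] = row / row.sum()
    bc = np.tile(bg, (4, 1))
    return FirstOrderTFFM(background_emission=bg.copy(),
                          background_conditional=bc,
                          motif_conditional=mc,
                          background_self_transition=self_transition,
                          motif_entry=motif_entry, tf_name=tf_name,
                          model_id=model_id or f"SYNT{seed % 10**6:06d}",
                          source=source)


def _onehot(i: int) -> np.ndarray:
    v = np.zeros(4)
    v[i] = 1.0
    return v


def make_tffm_for_pcm(pcm: PositionCountMatrix, seed: int,
                      dependency_strength: float = 0.3,
                      background: BackgroundDistribution | None = None,
                      self_transition: float = 0.999, motif_entry: float = 0.001,
                      model_id: str = "", source: str = "synthetic"
                      ) -> FirstOrderTFFM:
    """First-order TFFM sharing a count matrix's consensus and marginals.

    Conditional rows modulate the PCM column frequencies by a
    previous-base-specific factor while pinning the consensus base's
    modulation to 1, so the consensus stays the per-row argmax and planted
    consensus sites score highly under both model families.
    """
    rng = np.random.default_rng(seed)
    bg = (background or DEFAULT_BACKGROUND).probs
    freq = pcm.frequencies(pseudocount_scale=1.0)
    s = float(dependency_strength)
    L = pcm.length
    cons = pcm.counts.argmax(axis=0)
    mc = np.empty((L, 4, 4))
    for i in range(L):
        for prev in range(4):
            mod = 1.0 - s * rng.uniform(0.0, 0.5, size=4)
            mod[cons[i]] = 1.0
            row = freq[:, i] * mod
            mc[i, prev] = row / row.sum()
    bc = np.tile(bg, (4, 1))
    return FirstOrderTFFM(background_emission=bg.copy(),
                          background_conditional=bc, motif_conditional=mc,
                          background_self_transition=self_transition,
                          motif_entry=motif_entry, tf_name=pcm.tf_name,
                          model_id=model_id or (pcm.model_id + ".tffm"),
                          source=source)


def make_model_set(spec: FixtureSpec) -> tuple[list, dict]:
    """One PCM + first-order TFFM (+ detailed TFFM for every other factor)
    per transcription factor; returns (models, per-TF metadata)."""
    seeds = _child_seeds(spec.seed, 3 * spec.n_tfs)
    rng = np.random.default_rng(spec.seed + 1)
    lo, hi = spec.motif_length
    models: list = []
    meta: dict[str, dict] = {}
    for i in range(spec.n_tfs):
        tf = f"TF{i:02d}"
        L = int(rng.integers(lo, hi + 1))
        pcm = make_pcm(seeds[3 * i], L, spec.concentration, tf_name=tf,
                       model_id=f"VB{i:03d}.pcm")
        tffm = make_tffm_for_pcm(pcm, seeds[3 * i + 1],
                                 spec.dependency_strength,
                                 model_id=f"VB{i:03d}.tffm")
        entry = {"pcm": pcm, "tffm": tffm, "consensus": pcm.consensus(),
                 "length": L}
        models.extend([pcm, tffm])
        if i % 2 == 0:
            detailed = build_detailed_from_first_order(tffm)
            models.append(detailed)
            entry["detailed"] = detailed
        meta[tf] = entry
    return models, meta


@dataclass
class _Feature:
    kind: str          # "site" | "near_site" | "neutral"
    tf: str
    pos: int           # site start (0-based) or neutral variant position
    strand: str = "+"
    length: int = 0
    mismatch_col: int = 0
    ref: str = ""
    alt: str = ""


def make_genome_with_sites(spec: FixtureSpec, meta: dict | None = None
                           ) -> tuple[dict[str, str], pd.DataFrame]:
    """Background genome with planted consensus sites, near-sites and
    neutral zones; returns ({chrom: sequence}, truth table).

    The truth table records, per planted feature: kind, TF, 0-based
    genomic start, strand, and for near-sites the mismatched motif column.
    """
    if meta is None:
        _, meta = make_model_set(spec)
    rng = np.random.default_rng(spec.seed + 2)
    bg = DEFAULT_BACKGROUND.probs
    lmax = max(entry["length"] for entry in meta.values())
    zone_halfwidth = 16 + lmax
    seq = rng.choice(list(BASES), size=spec.genome_length, p=bg)

    n_features = 2 * spec.n_planted_sites + spec.n_neutral
    margin = zone_halfwidth + 20
    slot = 2 * zone_halfwidth + 10
    needed = 2 * margin + n_features * slot
    if spec.genome_length < needed:
        raise ValueError(f"genome_length {spec.genome_length} too small for "
                         f"{n_features} features (need >= {needed})")
    positions = [margin + j * slot + int(rng.integers(0, 6))
                 for j in range(n_features)]
    rng.shuffle(positions)

    tf_names = list(meta)
    features: list[_Feature] = []
    idx = 0
    for j in range(spec.n_planted_sites):
        for kind in ("site", "near_site"):
            tf = tf_names[j % len(tf_names)]
            entry = meta[tf]
            L = entry["length"]
            cons = entry["consensus"]
            strand = "+" if rng.random() < 0.5 else "-"
            ic = information_content(entry["pcm"], 1.0)
            col = int(np.argmax(ic))
            planted = cons
            if kind == "near_site":
                worst = BASES[int(entry["pcm"].counts[:, col].argmin())]
                planted = cons[:col] + worst + cons[col + 1:]
            stamp = planted if strand == "+" else reverse_complement(planted)
            start = positions[idx]
            idx += 1
            seq[start:start + L] = list(stamp)
            features.append(_Feature(kind, tf, start, strand, L, col))
    for _ in range(spec.n_neutral):
        pos = positions[idx]
        idx += 1
        unit = rng.choice(list(BASES), size=_NEUTRAL_UNIT)
        for q in range(pos - zone_halfwidth, pos + zone_halfwidth + 1):
            seq[q] = unit[(q - pos) % _NEUTRAL_UNIT]
        ref = str(unit[0])
        alt = str(rng.choice([b for b in BASES if b != ref]))
        seq[pos + _NEUTRAL_SHIFT] = alt  # pre-mutated repeat copy
        features.append(_Feature("neutral", ".", pos, "+", 0, 0, ref, alt))

    genome = {spec.chrom: "".join(seq)}
    truth = pd.DataFrame([{
        "kind": f.kind, "tf": f.tf, "chrom": spec.chrom, "start": f.pos,
        "strand": f.strand, "length": f.length, "mismatch_col": f.mismatch_col,
        "ref": f.ref, "alt": f.alt} for f in features])
    truth = truth.sort_values("start", kind="stable").reset_index(drop=True)
    return genome, truth


def make_disrupting_vcf(truth: pd.DataFrame, genome: dict[str, str],
                        meta: dict, spec: FixtureSpec
                        ) -> tuple[str, pd.DataFrame]:
    """VCF text plus an expected-direction table for the planted features.

    Per full site: one SNV at the maximum-information column replacing the
    consensus base with the least-favoured base (expected S < 0).  Per
    near-site: the SNV completing the consensus (expected S > 0).  Per
    neutral zone: the engineered repeat SNV (expected S = 0 exactly).
    """
    rows = []
    for _, f in truth.iterrows():
        chrom_seq = genome[f["chrom"]]
        if f["kind"] == "neutral":
            pos0, ref, alt, sign = f["start"], f["ref"], f["alt"], 0
        else:
            entry = meta[f["tf"]]
            pcm, L = entry["pcm"], entry["length"]
            col = int(f["mismatch_col"])
            cons_base = BASES[int(pcm.counts[:, col].argmax())]
            worst_base = BASES[int(pcm.counts[:, col].argmin())]
            offset = col if f["strand"] == "+" else L - 1 - col
            pos0 = int(f["start"]) + offset
            if f["kind"] == "site":  # destroy the consensus
                ref, alt, sign = cons_base, worst_base, -1
            else:  # near_site: restore the consensus
                ref, alt, sign = worst_base, cons_base, +1
            if f["strand"] == "-":
                ref, alt = _COMP[ref], _COMP[alt]
        assert chrom_seq[pos0] == ref, "truth table out of sync with genome"
        rows.append({"chrom": f["chrom"], "pos": pos0 + 1, "ref": ref,
                     "alt": alt, "tf": f["tf"], "expected_sign": sign,
                     "kind": f["kind"]})
    expected = pd.DataFrame(rows).sort_values(["chrom", "pos"],
                                              kind="stable").reset_index(drop=True)
    lines = ["##fileformat=VCFv4.2"]
    for chrom, seq in genome.items():
        lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, r in expected.iterrows():
        lines.append(f"{r['chrom']}\t{r['pos']}\t{r['kind']}{i}\t"
                     f"{r['ref']}\t{r['alt']}\t.\tPASS\t.")
    return "\n".join(lines) + "\n", expected


def make_known_sites_bed(truth: pd.DataFrame, pad: int = 200) -> str:
    """BED4 text of ChIP-seq-like intervals (a few hundred bases) around
    the planted full sites."""
    lines = []
    for _, f in truth.iterrows():
        if f["kind"] != "site":
            continue
        start = max(0, int(f["start"]) - pad)
        end = int(f["start"]) + int(f["length"]) + pad
        lines.append(f"{f['chrom']}\t{start}\t{end}\t{f['tf']}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_fixture_dir(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete fixture set (FASTA, VCF, BED, models, truth tables)."""
    from .io import write_models_json, write_tffm_xml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models, meta = make_model_set(spec)
    genome, truth = make_genome_with_sites(spec, meta)
    vcf_text, expected = make_disrupting_vcf(truth, genome, meta, spec)

    paths = {
        "fasta": outdir / "genome.fa",
        "vcf": outdir / "variants.vcf",
        "known_sites": outdir / "known_sites.bed",
        "models": outdir / "models.json",
        "truth": outdir / "truth.tsv",
        "expected": outdir / "expected.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    paths["vcf"].write_text(vcf_text)
    paths["known_sites"].write_text(make_known_sites_bed(truth))
    write_models_json(models, paths["models"])
    first_tffm = next(m for m in models if isinstance(m, FirstOrderTFFM))
    xml_path = outdir / f"{first_tffm.model_id}.xml"
    write_tffm_xml(first_tffm, xml_path)
    paths["tffm_xml"] = xml_path
    truth.to_csv(paths["truth"], sep="\t", index=False)
    expected.to_csv(paths["expected"], sep="\t", index=False)
    return paths
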