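"""Synthetic two-genotype methylome generator.

Generates, deterministically per seed: random genomes, gene/TE annotations,
per-cytosine methylation call tables for two genotypes (A and B) with
planted DMRs of known location and effect size, and MeDIP-like peak and
coverage tracks — so every pipeline stage is testable without external
data.

Model sketch
------------
* Cytosine positions and contexts (CG/CHG/CHH, both strands) are derived
  from the actual simulated sequence, so context ratios emerge from base
  composition.
* Each site's true methylation level is drawn from a context-specific Beta
  mixture; sites inside TEs use an elevated mixture, sites within 2 kb of a
  Gypsy TE get an extra CG/CHG boost, and a V-shaped dip is applied around
  each TSS and TTS. Per genotype and context the genome-wide mean is then
  normalised exactly to the configured value (defaults CG 0.38/0.36,
  CHG 0.25/0.24, CHH 0.05/0.04 for A/B). The CG mixture is bimodal, placing
  roughly 40% of observed site levels below 0.2 and 48% above 0.6 at the
  default depth.
* Genotype B's true level is a deterministic mean-matching transform of
  A's (identical when the configured means are equal — the null
  construction), except inside planted DMRs, where the two genotypes are
  re-drawn as a low/high pair separated by exactly ``dmr_delta``.
* Observed counts: depth ~ NegBin(mean, size) per genotype and site,
  methylated reads ~ Binomial(depth, true level).
* MeDIP: expected pull-down coverage per window is a baseline plus a term
  proportional to the summed methylation of the window's cytosines
  (capturing both methylation level and cytosine density); Poisson noise;
  peaks are runs of windows whose coverage clears a genome-wide
  significance threshold over the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .io import (AnnotationSet, MethylomeTable, RegionSet,
                 write_cytosine_report, write_chrom_lengths, write_regions,
                 write_bedgraph)

logger = logging.getLogger(__name__)

_A, _C, _G, _T = 0, 1, 2, 3
_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions
    the generator emulates (two tetraploid switchgrass genotypes profiled
    by WGBS at moderate depth)."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.46
    # annotation
    n_genes: int = 250
    exons_per_gene: float = 4.0
    n_tes: int = 350
    te_class_mix: dict = field(default_factory=lambda: {
        "LTR/Copia": 0.3, "LTR/Gypsy": 0.3, "LINE": 0.2, "DNA": 0.2})
    intronic_te_fraction: float = 0.2
    gene_mean_len: float = 1800.0
    te_mean_len: float = 1100.0
    # methylation (genotype A, genotype B genome-wide mean per context)
    mean_levels: dict = field(default_factory=lambda: {
        "CG": (0.38, 0.36), "CHG": (0.25, 0.24), "CHH": (0.05, 0.04)})
    depth_mean: float = 20.0
    depth_size: float | None = 5.0  # NegBin dispersion; None = fixed depth
    # mean depth shrinks to (1 - bias * level): methylated repeat-derived
    # fragments map uniquely less often, so heavily methylated sites run
    # shallower — the mechanism that lets the read-weighted genome mean sit
    # below the unweighted per-site mean, as bisulfite studies report
    depth_meth_bias: float = 0.49
    # planted profile shapes
    tss_dip_bp: int = 200
    tss_dip_floor: float = 0.15
    gypsy_flank_boost: float = 0.25
    # planted DMRs
    n_dmrs: int = 100
    dmr_width: int = 300
    dmr_context: str = "CG"
    dmr_delta: float = 0.5
    dmr_min_sites: int = 8
    dmr_hyper_fraction: float = 0.5
    # MeDIP
    medip_window: int = 200
    medip_background: float = 5.0
    medip_scale: float = 2.0

    def __post_init__(self) -> None:
        for ctx, (ma, mb) in self.mean_levels.items():
            if not (0 <= ma <= 1 and 0 <= mb <= 1):
                raise ValueError(f"mean level for {ctx} outside [0,1]")
        if self.dmr_delta < 0 or self.dmr_delta > 1:
            raise ValueError("dmr_delta must lie in [0,1]")


# ---------------------------------------------------------------------------
# Beta-mixture parameters per context. Components are (a, b) Beta shapes;
# weights differ between non-TE ("base") and TE site classes. The CG base
# weights and high component were calibrated once so the default
# configuration reproduces the emulation targets (weighted CG mean 0.38 with
# ~40% of observed site levels < 0.2 and ~48% > 0.6 at NegBin depth 20);
# CHG/CHH were set analytically to their target means and left alone.
# ---------------------------------------------------------------------------

MIXTURES: dict[str, dict] = {
    "CG": {
        "components": [(0.5, 18.0), (2.0, 3.0), (80.0, 5.2)],
        "base": (0.515, 0.0, 0.485),
        "te": (0.03, 0.02, 0.95),
    },
    "CHG": {
        "components": [(0.4, 9.6), (2.0, 3.0), (6.0, 3.0)],
        "base": (0.52, 0.36, 0.12),
        "te": (0.20, 0.35, 0.45),
    },
    "CHH": {
        "components": [(0.3, 12.0), (1.5, 6.0), (5.0, 3.0)],
        "base": (0.92, 0.07, 0.01),
        "te": (0.72, 0.23, 0.05),
    },
}


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig
                    ) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Random nucleotide sequences at the configured GC fraction.

    Returns ({chrom: uint8 base codes (A,C,G,T = 0..3)}, chrom lengths).
    """
    if config.chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    rng = _rng(config, 1)
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {}
    for i in range(config.n_chroms):
        chrom = f"Chr{i + 1:02d}"
        seqs[chrom] = rng.choice(4, size=config.chrom_length, p=p).astype(np.uint8)
    return seqs, {c: len(s) for c, s in seqs.items()}


def write_fasta(seqs: dict[str, np.ndarray], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, codes in seqs.items():
            fh.write(f">{chrom}\n")
            text = "".join(_BASES[codes])
            for i in range(0, len(text), width):
                fh.write(text[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _gene_structure(rng: np.random.Generator, chrom: str, start: int,
                    length: int, strand: str, gene_id: str,
                    mean_exons: float) -> tuple[dict, list[dict]]:
    """One gene with exon/intron/UTR structure (coordinates 0-based)."""
    end = start + length
    n_exons = 1 + rng.poisson(max(mean_exons - 1, 0))
    n_exons = min(n_exons, max(1, length // 240))
    # alternate exon/intron lengths from a Dirichlet split with floors
    n_seg = 2 * n_exons - 1
    w = rng.dirichlet(np.full(n_seg, 1.5))
    floors = np.where(np.arange(n_seg) % 2 == 0, 60, 80)  # exon/intron minima
    free = length - floors.sum()
    seg = (floors + np.floor(w * free)).astype(int)
    seg[-1] += length - seg.sum()
    bounds = start + np.concatenate([[0], np.cumsum(seg)])
    exons = [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2)]

    gene = {"chrom": chrom, "start": start, "end": end, "strand": strand,
            "gene_id": gene_id}
    subs = []
    # UTRs: fractions of the terminal exons, orientation by strand
    first, last = exons[0], exons[-1]
    utr5_len = max(20, int(0.25 * (first[1] - first[0])))
    utr3_len = max(20, int(0.3 * (last[1] - last[0])))
    if strand == "+":
        utr5 = (first[0], first[0] + utr5_len)
        utr3 = (last[1] - utr3_len, last[1])
    else:
        utr5 = (last[1] - utr5_len, last[1])
        utr3 = (first[0], first[0] + utr3_len)
    subs.append({"feature": "five_prime_UTR", "start": utr5[0], "end": utr5[1]})
    subs.append({"feature": "three_prime_UTR", "start": utr3[0], "end": utr3[1]})
    for es, ee in exons:
        cs, ce = es, ee
        for us, ue in (utr5, utr3):
            if us <= cs < ue:
                cs = ue
            if us < ce <= ue:
                ce = us
        if cs < ce:
            subs.append({"feature": "CDS", "start": cs, "end": ce})
    for i in range(len(exons) - 1):
        subs.append({"feature": "intron", "start": exons[i][1],
                     "end": exons[i + 1][0]})
    for s in subs:
        s.update({"chrom": chrom, "strand": strand, "gene_id": gene_id})
    return gene, subs


def simulate_annotation(config: SimulationConfig,
                        genome: tuple[dict[str, np.ndarray], dict[str, int]]
                        ) -> AnnotationSet:
    """Non-overlapping genes with exon/intron/UTR structure plus TEs
    (intergenic, and intronic in a configurable fraction of genes), with
    class labels drawn from the configured mix."""
    _, chrom_lengths = genome
    rng = _rng(config, 2)
    chroms = list(chrom_lengths)
    genes, subs, tes = [], [], []

    # genes: slot placement guarantees non-overlap
    per_chrom = np.full(len(chroms), config.n_genes // len(chroms))
    per_chrom[:config.n_genes % len(chroms)] += 1
    gid = 0
    gene_slots: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, n_here in zip(chroms, per_chrom):
        length = chrom_lengths[chrom]
        if n_here == 0:
            continue
        slot = length // n_here
        for k in range(n_here):
            glen = int(np.clip(rng.lognormal(np.log(config.gene_mean_len), 0.35),
                               min(700, slot // 3), slot - 200))
            if glen + 100 > slot:
                raise ValueError("requested genes exceed genome capacity")
            offset = rng.integers(50, slot - glen - 50)
            start = k * slot + int(offset)
            strand = "+" if rng.random() < 0.5 else "-"
            gene, sub = _gene_structure(rng, chrom, start, glen, strand,
                                        f"gene_{gid:05d}", config.exons_per_gene)
            genes.append(gene)
            subs.extend(sub)
            gene_slots[chrom].append((start, start + glen))
            gid += 1

    # intronic TEs: one per selected gene, dropped into a random intron
    te_classes = list(config.te_class_mix)
    te_probs = np.array([config.te_class_mix[c] for c in te_classes], dtype=float)
    te_probs /= te_probs.sum()
    tid = 0
    gene_ids_with_introns: dict[str, list[dict]] = {}
    for s in subs:
        if s["feature"] == "intron":
            gene_ids_with_introns.setdefault(s["gene_id"], []).append(s)
    for gene in genes:
        if rng.random() >= config.intronic_te_fraction:
            continue
        introns = gene_ids_with_introns.get(gene["gene_id"])
        if not introns:
            continue
        intron = introns[int(rng.integers(len(introns)))]
        room = intron["end"] - intron["start"] - 20
        if room < 80:
            continue
        tlen = int(rng.integers(80, min(room, 800) + 1))
        tstart = intron["start"] + 10 + int(rng.integers(room - tlen + 1))
        tes.append({"chrom": gene["chrom"], "start": tstart,
                    "end": tstart + tlen, "strand": ".",
                    "te_id": f"te_{tid:05d}",
                    "te_class": te_classes[int(rng.choice(len(te_classes), p=te_probs))]})
        tid += 1

    # intergenic TEs fill the remaining requested count
    n_intergenic = config.n_tes - tid
    if n_intergenic < 0:
        raise ValueError("intronic TEs alone exceed n_tes")
    gaps = []
    for chrom in chroms:
        occupied = sorted(gene_slots[chrom])
        prev = 0
        for s, e in occupied + [(chrom_lengths[chrom], chrom_lengths[chrom])]:
            if s - prev > 600:
                gaps.append((chrom, prev, s))
            prev = max(prev, e)
    if not gaps:
        raise ValueError("no intergenic room for TEs")
    gap_sizes = np.array([g[2] - g[1] for g in gaps], dtype=float)
    placed = 0
    cursor = {i: gaps[i][1] + 100 for i in range(len(gaps))}
    order = rng.permutation(len(gaps))
    attempts = 0
    while placed < n_intergenic:
        attempts += 1
        if attempts > 50 * config.n_tes:
            raise ValueError("requested TEs exceed genome capacity")
        i = int(rng.choice(len(gaps), p=gap_sizes / gap_sizes.sum()))
        chrom, gs, ge = gaps[i]
        pos = cursor[i] + int(rng.integers(0, 200))
        room = ge - pos - 100
        if room < 100:
            continue
        tlen = int(np.clip(rng.lognormal(np.log(config.te_mean_len), 0.5),
                           100, min(room, 5000)))
        tes.append({"chrom": chrom, "start": pos, "end": pos + tlen,
                    "strand": ".", "te_id": f"te_{tid:05d}",
                    "te_class": te_classes[int(rng.choice(len(te_classes), p=te_probs))]})
        cursor[i] = pos + tlen + 50
        tid += 1
        placed += 1

    gene_df = pd.DataFrame(genes)
    sub_df = pd.DataFrame(subs)[["chrom", "start", "end", "strand",
                                 "gene_id", "feature"]]
    te_df = pd.DataFrame(tes)[["chrom", "start", "end", "strand",
                               "te_id", "te_class"]]
    return AnnotationSet(gene_df, sub_df, te_df, chrom_lengths)


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """Write genes (gene/mRNA/exon-equivalent sub-features) and TEs as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in annotation.genes.itertuples(index=False):
            fh.write(f"{g.chrom}\tmethgrass_sim\tgene\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.1"
            fh.write(f"{g.chrom}\tmethgrass_sim\tmRNA\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n")
            sub = annotation.subfeatures[
                annotation.subfeatures["gene_id"] == g.gene_id]
            # exons = gene span minus introns
            introns = sub[sub["feature"] == "intron"].sort_values("start")
            prev = g.start
            for intron in introns.itertuples(index=False):
                if intron.start > prev:
                    fh.write(f"{g.chrom}\tmethgrass_sim\texon\t{prev + 1}\t"
                             f"{intron.start}\t.\t{g.strand}\t.\tParent={mid}\n")
                prev = intron.end
            if g.end > prev:
                fh.write(f"{g.chrom}\tmethgrass_sim\texon\t{prev + 1}\t{g.end}"
                         f"\t.\t{g.strand}\t.\tParent={mid}\n")
            for s in sub[sub["feature"] != "intron"].itertuples(index=False):
                fh.write(f"{s.chrom}\tmethgrass_sim\t{s.feature}\t{s.start + 1}"
                         f"\t{s.end}\t.\t{s.strand}\t.\tParent={mid}\n")
        for t in annotation.tes.itertuples(index=False):
            fh.write(f"{t.chrom}\tmethgrass_sim\ttransposable_element\t"
                     f"{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
                     f"ID={t.te_id};class={t.te_class}\n")


# ---------------------------------------------------------------------------
# methylome pair
# ---------------------------------------------------------------------------

def cytosine_sites(codes: np.ndarray) -> pd.DataFrame:
    """Cytosine positions (1-based), strands and contexts from a sequence.

    Plus strand: C followed by G -> CG; C,H,G -> CHG; else CHH. Minus
    strand mirrors with preceding bases. Cytosines too close to the
    sequence edge to define a context are skipped.
    """
    n = len(codes)
    plus = np.flatnonzero(codes[:n - 2] == _C)
    nxt1 = codes[plus + 1]
    nxt2 = codes[plus + 2]
    ctx_plus = np.where(nxt1 == _G, "CG", np.where(nxt2 == _G, "CHG", "CHH"))
    minus = np.flatnonzero(codes[2:] == _G) + 2
    prv1 = codes[minus - 1]
    prv2 = codes[minus - 2]
    ctx_minus = np.where(prv1 == _C, "CG", np.where(prv2 == _C, "CHG", "CHH"))
    df = pd.DataFrame({
        "pos": np.concatenate([plus + 1, minus + 1]),
        "strand": np.concatenate([np.full(len(plus), "+"),
                                  np.full(len(minus), "-")]),
        "context": np.concatenate([ctx_plus, ctx_minus]),
    })
    return df.sort_values(["pos", "strand"]).reset_index(drop=True)


def _feature_masks(annotation: AnnotationSet, config: SimulationConfig
                   ) -> dict[str, dict[str, np.ndarray]]:
    """Per-chromosome boolean TE mask, Gypsy-flank mask and TSS/TTS dip
    multiplier array."""
    masks: dict[str, dict[str, np.ndarray]] = {}
    for chrom, length in annotation.chrom_lengths.items():
        te = np.zeros(length, dtype=bool)
        gypsy_flank = np.zeros(length, dtype=bool)
        dip = np.ones(length, dtype=np.float32)
        masks[chrom] = {"te": te, "gypsy_flank": gypsy_flank, "dip": dip}
    for t in annotation.tes.itertuples(index=False):
        masks[t.chrom]["te"][t.start:t.end] = True
    for t in annotation.tes.itertuples(index=False):
        if t.te_class != "LTR/Gypsy":
            continue
        arr = masks[t.chrom]["gypsy_flank"]
        arr[max(0, t.start - 2000):t.start] = True
        arr[t.end:t.end + 2000] = True
    for chrom in masks:
        masks[chrom]["gypsy_flank"] &= ~masks[chrom]["te"]
    w = config.tss_dip_bp
    floor = config.tss_dip_floor
    ramp = floor + (1 - floor) * np.abs(np.arange(-w, w + 1)) / w
    for g in annotation.genes.itertuples(index=False):
        dip = masks[g.chrom]["dip"]
        for anchor in (g.start, g.end - 1):
            lo = max(0, anchor - w)
            hi = min(len(dip), anchor + w + 1)
            seg = ramp[lo - (anchor - w): (2 * w + 1) - ((anchor + w + 1) - hi)]
            dip[lo:hi] = np.minimum(dip[lo:hi], seg)
    return masks


def _draw_levels(rng: np.random.Generator, context: np.ndarray,
                 in_te: np.ndarray, gypsy_flank: np.ndarray,
                 dip: np.ndarray, gypsy_flank_boost: float = 0.25) -> np.ndarray:
    """True levels for genotype A from the context/site-class mixtures."""
    levels = np.empty(len(context), dtype=float)
    for ctx, mix in MIXTURES.items():
        sel = context == ctx
        if not sel.any():
            continue
        comps = mix["components"]
        for class_name, class_mask in (("base", sel & ~in_te),
                                       ("te", sel & in_te)):
            m = class_mask
            if not m.any():
                continue
            weights = np.array(mix[class_name])
            comp_idx = rng.choice(len(comps), size=int(m.sum()), p=weights)
            a = np.array([comps[i][0] for i in comp_idx])
            b = np.array([comps[i][1] for i in comp_idx])
            levels[m] = rng.beta(a, b)
        if ctx in ("CG", "CHG"):
            boost = sel & gypsy_flank
            levels[boost] = 1 - (1 - levels[boost]) * (1 - gypsy_flank_boost)
    levels *= dip
    return np.clip(levels, 0.0, 1.0)


def _mean_transform(levels: np.ndarray, current: float, target: float) -> np.ndarray:
    """Deterministic monotone transform taking the mean from ``current`` to
    ``target`` while staying in [0,1]: scale toward 0 when decreasing, scale
    the complement toward 1 when increasing. Identity when equal."""
    if np.isclose(current, target):
        return levels.copy()
    if target < current:
        return levels * (target / current)
    return 1 - (1 - levels) * ((1 - target) / (1 - current))


def _expected_weighted_mean(levels: np.ndarray, bias: float) -> float:
    """Read-weighted mean implied by the depth model E[d] ∝ (1 - bias*p)."""
    w = 1 - bias * levels
    return float((w * levels).sum() / w.sum())


def _normalize_weighted(levels: np.ndarray, target: float, bias: float,
                        tol: float = 1e-10) -> np.ndarray:
    """Monotone-rescale ``levels`` so the *expected read-weighted* mean under
    the biased-depth model equals ``target`` (bisection on the transform's
    target site mean; exact up to ``tol``)."""
    current = _expected_weighted_mean(levels, bias)
    if abs(current - target) < tol:
        return levels.copy()
    lo, hi = 0.0, 1.0
    site_mean = float(levels.mean())
    for _ in range(80):
        mid = (lo + hi) / 2
        cand = _mean_transform(levels, site_mean, mid)
        got = _expected_weighted_mean(cand, bias)
        if abs(got - target) < tol:
            break
        if got < target:
            lo = mid
        else:
            hi = mid
    return cand


def _place_dmrs(rng: np.random.Generator, sites: pd.DataFrame,
                chrom_lengths: dict[str, int], config: SimulationConfig
                ) -> pd.DataFrame:
    """Plant non-overlapping DMR windows with enough context sites each."""
    chroms = list(chrom_lengths)
    probs = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    pos_by_chrom = {
        c: sites.loc[(sites["chrom"] == c) &
                     (sites["context"] == config.dmr_context), "pos"].to_numpy()
        for c in chroms}
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    attempts = 0
    while len(rows) < config.n_dmrs:
        attempts += 1
        if attempts > 500 * max(config.n_dmrs, 1):
            raise ValueError("could not place requested DMRs (site density too low)")
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        start = int(rng.integers(0, chrom_lengths[chrom] - config.dmr_width))
        end = start + config.dmr_width
        if any(s < end + 200 and start < e + 200 for s, e in placed[chrom]):
            continue
        pos = pos_by_chrom[chrom]
        n_sites = int(np.searchsorted(pos, end, side="right") -
                      np.searchsorted(pos, start + 1, side="left"))
        if n_sites < config.dmr_min_sites:
            continue
        direction = "hyper" if rng.random() < config.dmr_hyper_fraction else "hypo"
        placed[chrom].append((start, end))
        rows.append({"chrom": chrom, "start": start, "end": end,
                     "name": f"dmr_{len(rows):04d}", "strand": ".",
                     "direction": direction, "context": config.dmr_context,
                     "delta": config.dmr_delta})
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_methylome_pair(config: SimulationConfig,
                            genome: tuple[dict[str, np.ndarray], dict[str, int]],
                            annotation: AnnotationSet
                            ) -> tuple[MethylomeTable, MethylomeTable, RegionSet]:
    """Two genotypes' per-cytosine call tables plus the planted-DMR truth set."""
    seqs, chrom_lengths = genome
    rng = _rng(config, 3)
    masks = _feature_masks(annotation, config)

    frames = []
    for chrom, codes in seqs.items():
        sites = cytosine_sites(codes)
        sites.insert(0, "chrom", chrom)
        frames.append(sites)
    sites = pd.concat(frames, ignore_index=True)

    pos0 = sites["pos"].to_numpy() - 1
    in_te = np.empty(len(sites), dtype=bool)
    gypsy_flank = np.empty(len(sites), dtype=bool)
    dip = np.empty(len(sites), dtype=np.float32)
    for chrom in chrom_lengths:
        idx = (sites["chrom"] == chrom).to_numpy()
        p = pos0[idx]
        in_te[idx] = masks[chrom]["te"][p]
        gypsy_flank[idx] = masks[chrom]["gypsy_flank"][p]
        dip[idx] = masks[chrom]["dip"][p]

    context = sites["context"].to_numpy()
    level_a = _draw_levels(rng, context, in_te, gypsy_flank, dip,
                           config.gypsy_flank_boost)
    level_b = np.empty_like(level_a)
    bias = config.depth_meth_bias
    for ctx, (ma, mb) in config.mean_levels.items():
        sel = context == ctx
        level_a[sel] = _normalize_weighted(level_a[sel], ma, bias)
        level_b[sel] = _normalize_weighted(level_a[sel], mb, bias)

    # plant DMRs: low/high pair separated by exactly delta
    if config.n_dmrs > 0:
        truth_df = _place_dmrs(rng, sites, chrom_lengths, config)
        delta = config.dmr_delta
        for dmr in truth_df.itertuples(index=False):
            sel = ((sites["chrom"] == dmr.chrom).to_numpy() &
                   (pos0 >= dmr.start) & (pos0 < dmr.end) &
                   (context == dmr.context))
            # DMRs flip between a near-unmethylated and a methylated state:
            # the low side sits close to 0 and the high side exactly delta above
            low = (1 - delta) * rng.beta(0.5, 12.0, size=int(sel.sum()))
            if dmr.direction == "hyper":
                level_a[sel] = low
                level_b[sel] = low + delta
            else:
                level_a[sel] = low + delta
                level_b[sel] = low
        truth = RegionSet(truth_df, source="planted_dmrs")
    else:
        truth = RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]),
                          source="planted_dmrs")

    def observe(levels: np.ndarray, stage: int, sample_id: str) -> MethylomeTable:
        obs_rng = _rng(config, stage)
        mean_depth = config.depth_mean * (1 - config.depth_meth_bias * levels)
        if config.depth_size is None:
            depth = np.full(len(levels), int(config.depth_mean))
        else:
            size = config.depth_size
            depth = obs_rng.negative_binomial(size, size / (size + mean_depth))
        n_meth = obs_rng.binomial(depth, levels)
        df = pd.DataFrame({
            "chrom": sites["chrom"], "pos": sites["pos"],
            "strand": sites["strand"], "n_meth": n_meth,
            "n_unmeth": depth - n_meth, "context": context})
        return MethylomeTable(df, sample_id=sample_id)

    table_a = observe(level_a, 4, "genotypeA")
    table_b = observe(level_b, 5, "genotypeB")
    return table_a, table_b, truth


# ---------------------------------------------------------------------------
# MeDIP
# ---------------------------------------------------------------------------

def simulate_medip(config: SimulationConfig, table_a: MethylomeTable,
                   table_b: MethylomeTable, chrom_lengths: dict[str, int]
                   ) -> dict[str, RegionSet]:
    """MeDIP-like coverage and peaks per genotype from the methylomes.

    Expected window coverage = background + scale * (summed observed site
    levels in the window); Poisson noise; a window is peak-worthy when its
    coverage clears both 1.5x the genome median and a Poisson tail test
    (p < 1e-6) against the median; adjacent peak windows merge.
    """
    out: dict[str, RegionSet] = {}
    win = config.medip_window
    for tag, table, stage in (("a", table_a, 6), ("b", table_b, 7)):
        rng = _rng(config, stage)
        cov_frames = []
        peak_frames = []
        for chrom, length in chrom_lengths.items():
            n_win = int(np.ceil(length / win))
            signal = np.zeros(n_win)
            sub = table.df[table.df["chrom"] == chrom]
            depth = (sub["n_meth"] + sub["n_unmeth"]).to_numpy()
            ok = depth > 0
            lev = np.zeros(len(sub))
            lev[ok] = sub["n_meth"].to_numpy()[ok] / depth[ok]
            widx = (sub["pos"].to_numpy() - 1) // win
            np.add.at(signal, widx, lev)
            lam = config.medip_background + config.medip_scale * signal
            cov = rng.poisson(lam)
            starts = np.arange(n_win) * win
            ends = np.minimum(starts + win, length)
            cov_frames.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": ends,
                "score": cov.astype(float)}))
        cov_df = pd.concat(cov_frames, ignore_index=True)
        med = max(float(np.median(cov_df["score"])), 1.0)
        is_peak = ((cov_df["score"] > 1.5 * med) &
                   (poisson.sf(cov_df["score"] - 1, med) < 1e-6))
        peaks = cov_df[is_peak]
        if len(peaks):
            from ._intervals import merge_intervals
            merged = merge_intervals(peaks[["chrom", "start", "end"]])
        else:
            merged = pd.DataFrame(columns=["chrom", "start", "end"])
        out[f"coverage_{tag}"] = RegionSet(cov_df, source="medip_coverage")
        out[f"peaks_{tag}"] = RegionSet(merged, source="medip_peaks")
    return out


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    seqs: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    annotation: AnnotationSet
    table_a: MethylomeTable
    table_b: MethylomeTable
    truth: RegionSet
    medip: dict[str, RegionSet]


def simulate_study(config: SimulationConfig, with_medip: bool = True
                   ) -> SimulatedStudy:
    genome = simulate_genome(config)
    annotation = simulate_annotation(config, genome)
    table_a, table_b, truth = simulate_methylome_pair(config, genome, annotation)
    medip = simulate_medip(config, table_a, table_b, genome[1]) if with_medip else {}
    return SimulatedStudy(config, genome[0], genome[1], annotation,
                          table_a, table_b, truth, medip)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write FASTA, GFF3, two cytosine reports, truth BED, peaks and
    coverage bedGraphs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(study.seqs, outdir / "genome.fa")
    write_gff3(study.annotation, outdir / "annotation.gff3")
    write_chrom_lengths(study.chrom_lengths, outdir / "chrom_lengths.tsv")
    write_cytosine_report(study.table_a, outdir / "genotypeA.CX_report.txt")
    write_cytosine_report(study.table_b, outdir / "genotypeB.CX_report.txt")
    write_regions(study.truth, outdir / "planted_dmrs.bed",
                  extra_columns=study.truth.df[["direction", "context", "delta"]]
                  if "direction" in study.truth.df.columns else None)
    for tag in ("a", "b"):
        if f"peaks_{tag}" in study.medip:
            write_regions(study.medip[f"peaks_{tag}"],
                          outdir / f"genotype{tag.upper()}.peaks.bed")
            write_bedgraph(study.medip[f"coverage_{tag}"],
                           outdir / f"genotype{tag.upper()}.coverage.bedGraph")
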