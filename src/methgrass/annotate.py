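"""Assign regions to genomic features and test feature overrepresentation.

Feature categories and precedence (highest wins when a region overlaps
several): TE > CDS > UTR (5' then 3') > intron > promoter > upstream_2kb >
downstream_2kb > intergenic. The promoter is the 1 kb immediately 5' of the
TSS; upstream_2kb is the remaining 1-2 kb band; downstream_2kb is the 2 kb
past the TES — all strand-aware (strandless genes are treated as plus).

Overrepresentation uses a hypergeometric tail on a genome tiling: the
genome is cut into ``tile_bp`` windows, each labelled by the same
precedence, and for each category the test asks whether region-overlapped
tiles hit that category more often than a uniform draw of the same number
of tiles would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from . import _intervals
from .io import AnnotationSet, RegionSet
from .dmr import bh_adjust

logger = logging.getLogger(__name__)

# lowest to highest precedence (later paints over earlier on the tile map)
CATEGORIES = ("intergenic", "downstream_2kb", "upstream_2kb", "promoter",
              "intron", "three_prime_UTR", "five_prime_UTR", "CDS", "TE")
PRECEDENCE = {cat: i for i, cat in enumerate(CATEGORIES)}


def category_intervals(annotation: AnnotationSet, promoter_bp: int = 1000,
                       flank_bp: int = 2000) -> dict[str, pd.DataFrame]:
    """Interval lists per category (intergenic is implicit)."""
    genes = annotation.genes
    plus = (genes["strand"] != "-").to_numpy()
    tss = np.where(plus, genes["start"], genes["end"])
    tes = np.where(plus, genes["end"], genes["start"])

    def band(anchor, lo_off, hi_off, upstream: bool):
        # offsets measured 5'-ward (upstream) or 3'-ward of the anchor
        sign = -1 if upstream else 1
        a = anchor + sign * np.where(plus, lo_off, -lo_off)
        b = anchor + sign * np.where(plus, hi_off, -hi_off)
        start = np.minimum(a, b)
        end = np.maximum(a, b)
        df = pd.DataFrame({"chrom": genes["chrom"], "start": start, "end": end})
        df["start"] = df["start"].clip(lower=0)
        for chrom, length in annotation.chrom_lengths.items():
            sel = df["chrom"] == chrom
            df.loc[sel, "end"] = df.loc[sel, "end"].clip(upper=length)
        return df[df["start"] < df["end"]].reset_index(drop=True)

    sub = annotation.subfeatures
    out = {
        "TE": annotation.tes[["chrom", "start", "end"]],
        "CDS": sub[sub["feature"] == "CDS"][["chrom", "start", "end"]],
        "five_prime_UTR": sub[sub["feature"] == "five_prime_UTR"][["chrom", "start", "end"]],
        "three_prime_UTR": sub[sub["feature"] == "three_prime_UTR"][["chrom", "start", "end"]],
        "intron": sub[sub["feature"] == "intron"][["chrom", "start", "end"]],
        "promoter": band(tss, 0, promoter_bp, upstream=True),
        "upstream_2kb": band(tss, promoter_bp, flank_bp, upstream=True),
        "downstream_2kb": band(tes, 0, flank_bp, upstream=False),
    }
    return {k: v.reset_index(drop=True) for k, v in out.items()}


def assign_features(regions: RegionSet, annotation: AnnotationSet,
                    promoter_bp: int = 1000, flank_bp: int = 2000) -> pd.DataFrame:
    """One category per region by precedence; >= 1 bp overlap makes a
    category a candidate. Returns the region columns plus ``category`` and
    an ``overlap_<category>`` bp column per candidate category."""
    rdf = regions.df
    unknown = set(rdf["chrom"]) - set(annotation.chrom_lengths)
    if unknown:
        raise ValueError(f"regions on unknown chromosomes: {sorted(unknown)}")
    cats = category_intervals(annotation, promoter_bp, flank_bp)
    out = rdf[["chrom", "start", "end", "name"]].copy()
    chosen = np.full(len(rdf), "intergenic", dtype=object)
    best_rank = np.full(len(rdf), -1, dtype=int)
    for cat, intervals in cats.items():
        bp = _intervals.overlap_bp(rdf, intervals) if len(intervals) else \
            np.zeros(len(rdf), dtype=np.int64)
        out[f"overlap_{cat}"] = bp
        rank = PRECEDENCE[cat]
        take = (bp >= 1) & (rank > best_rank)
        chosen[take] = cat
        best_rank[take] = rank
    out["category"] = chosen
    return out


def _tile_labels(annotation: AnnotationSet, tile_bp: int,
                 promoter_bp: int = 1000, flank_bp: int = 2000
                 ) -> dict[str, np.ndarray]:
    """Per-chromosome tile label codes; a tile overlapping a category by
    >= 1 bp is a candidate and the highest precedence wins."""
    cats = category_intervals(annotation, promoter_bp, flank_bp)
    labels: dict[str, np.ndarray] = {}
    for chrom, length in annotation.chrom_lengths.items():
        n_tiles = int(np.ceil(length / tile_bp))
        labels[chrom] = np.zeros(n_tiles, dtype=np.int8)  # 0 = intergenic
    for cat in CATEGORIES[1:]:  # paint in increasing precedence
        code = PRECEDENCE[cat]
        merged = cats[cat]
        for row in merged.itertuples(index=False):
            arr = labels.get(row.chrom)
            if arr is None:
                continue
            lo = int(row.start) // tile_bp
            hi = int(np.ceil(row.end / tile_bp))
            arr[lo:hi] = np.maximum(arr[lo:hi], code)
    return labels


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed: int
    expected: float
    p_value: float
    q_value: float
    background_fraction: float


def enrichment_test(regions: RegionSet, annotation: AnnotationSet,
                    tile_bp: int = 100, promoter_bp: int = 1000,
                    flank_bp: int = 2000) -> list[EnrichmentResult]:
    """One-sided (overrepresentation) hypergeometric test per category.

    N = total tiles, K = tiles labelled with the category, n = tiles
    overlapped by any region, k = overlapped tiles with the label;
    p = P(X >= k). Categories with K = 0 are skipped with a warning. BH
    q-values across the tested categories are reported alongside raw p.
    """
    if not len(regions):
        raise ValueError("assignments non-empty required")
    labels = _tile_labels(annotation, tile_bp, promoter_bp, flank_bp)
    hit: dict[str, np.ndarray] = {c: np.zeros(len(a), dtype=bool)
                                  for c, a in labels.items()}
    for row in regions.df.itertuples(index=False):
        arr = hit.get(row.chrom)
        if arr is None:
            continue
        arr[int(row.start) // tile_bp:int(np.ceil(row.end / tile_bp))] = True

    all_labels = np.concatenate([labels[c] for c in sorted(labels)])
    all_hit = np.concatenate([hit[c] for c in sorted(labels)])
    N = len(all_labels)
    n = int(all_hit.sum())
    rows = []
    for cat in CATEGORIES:
        code = PRECEDENCE[cat]
        K = int((all_labels == code).sum())
        if K == 0:
            logger.warning("category %s covers no tiles; skipped", cat)
            continue
        k = int((all_hit & (all_labels == code)).sum())
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((cat, k, n * K / N, p, K / N))
    q = bh_adjust(np.array([r[3] for r in rows]))
    return [EnrichmentResult(cat, k, exp, p, float(qi), bg)
            for (cat, k, exp, p, bg), qi in zip(rows, q)]


def nearest_te(regions: RegionSet, annotation: AnnotationSet) -> pd.DataFrame:
    """Nearest TE per region: class, distance (0 when overlapping, ties to
    the leftmost TE) and TE length. Chromosomes without TEs give missing
    distance."""
    idx, dist = _intervals.nearest_interval(regions.df, annotation.tes)
    tes = annotation.tes
    rows = []
    for k, (j, d) in enumerate(zip(idx, dist)):
        region = regions.df.iloc[k]
        if j < 0:
            rows.append((region["chrom"], region["start"], region["end"],
                         None, np.nan, np.nan))
        else:
            te = tes.loc[j]
            rows.append((region["chrom"], region["start"], region["end"],
                         te["te_class"], int(d), int(te["end"] - te["start"])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "te_class",
                                       "distance", "te_length"])


def genes_near(regions: RegionSet, annotation: AnnotationSet,
               max_dist: int = 2000) -> list[str]:
    """IDs of genes whose span lies within ``max_dist`` bp of any region
    (0 when overlapping; the bound is inclusive), de-duplicated and sorted."""
    found: set[str] = set()
    rdf = regions.df
    for chrom, genes in annotation.genes.groupby("chrom"):
        sub = rdf[rdf["chrom"] == chrom]
        if not len(sub):
            continue
        rs = sub["start"].to_numpy()
        re_ = sub["end"].to_numpy()
        for g in genes.itertuples(index=False):
            dists = np.where(rs >= g.end, rs - g.end,
                             np.where(re_ <= g.start, g.start - re_, 0))
            if (dists <= max_dist).any():
                found.add(g.gene_id)
    return sorted(found)


def genes_near_by_direction(merged_dmrs: dict[str, RegionSet],
                            annotation: AnnotationSet,
                            max_dist: int = 2000) -> dict[str, list[str]]:
    """Per-direction gene lists for merged hyper/hypo DMR sets."""
    return {direction: genes_near(rs, annotation, max_dist)
            for direction, rs in merged_dmrs.items()}
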