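"""Weighted methylation statistics: global, per-feature, per-window, paired.

The central quantity is the *weighted* methylation level of a site set,

    level = sum(n_meth) / sum(n_meth + n_unmeth),

i.e. read-count-weighted, not the mean of per-site levels. It is robust to
uneven depth and additive over disjoint site sets (numerators and
denominators pool).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _intervals
from .io import CONTEXTS, AnnotationSet, MethylomeTable, RegionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MethylationLevel:
    """Weighted level over a site set; ``level`` is NaN when no reads."""

    level: float
    n_sites: int
    total_meth_reads: int
    total_reads: int

    @property
    def missing(self) -> bool:
        return self.total_reads == 0


@dataclass(frozen=True)
class LevelDistribution:
    bin_edges: tuple[float, ...]
    proportions: tuple[float, ...]
    context: str
    min_depth: int
    n_sites: int


@dataclass(frozen=True)
class PairedComparison:
    context: str
    mean_diff: float
    p_value: float
    n_pairs: int
    note: str = ""


def _pool(n_meth: np.ndarray, depth: np.ndarray) -> MethylationLevel:
    total = int(depth.sum())
    meth = int(n_meth.sum())
    level = meth / total if total > 0 else float("nan")
    return MethylationLevel(level, int(len(n_meth)), meth, total)


def _sites_in_regions(df: pd.DataFrame, regions: RegionSet | pd.DataFrame) -> np.ndarray:
    """Mask of cytosines (1-based pos) falling in the union of regions."""
    rdf = regions.df if isinstance(regions, RegionSet) else regions
    mask = np.zeros(len(df), dtype=bool)
    if not len(rdf):
        return mask
    merged = _intervals.merge_intervals(rdf[["chrom", "start", "end"]])
    pos0 = df["pos"].to_numpy() - 1  # 0-based site coordinate
    for chrom, grp in merged.groupby("chrom"):
        idx = np.flatnonzero((df["chrom"] == chrom).to_numpy())
        if not len(idx):
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        p = pos0[idx]
        j = np.searchsorted(starts, p, side="right") - 1
        inside = (j >= 0) & (p < ends[np.clip(j, 0, None)])
        mask[idx] = inside
    return mask


def weighted_level(table: MethylomeTable, context: str | None = None,
                   regions: RegionSet | None = None,
                   min_depth: int = 1) -> MethylationLevel:
    """Weighted methylation level over sites of ``context`` with depth >=
    ``min_depth``, optionally restricted to the union of ``regions``.

    No qualifying site yields a missing level (NaN), not zero.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    df = table.subset(context=context, min_depth=min_depth)
    if regions is not None:
        df = df[_sites_in_regions(df, regions)]
    if not len(df):
        return MethylationLevel(float("nan"), 0, 0, 0)
    return _pool(df["n_meth"].to_numpy(),
                 (df["n_meth"] + df["n_unmeth"]).to_numpy())


def level_distribution(table: MethylomeTable, context: str,
                       bin_edges: tuple[float, ...] = (0.2, 0.6),
                       min_depth: int = 5) -> LevelDistribution:
    """Proportions of per-site observed levels per bin.

    With the default edges the bins are [0, 0.2), [0.2, 0.6], (0.6, 1]:
    "low" is strictly below the first edge and "high" strictly above the
    last, the middle bin is closed. With more edges, interior bins after the
    second are half-open (e_i, e_{i+1}].
    """
    edges = tuple(bin_edges)
    if any(not (0 < e < 1) for e in edges) or list(edges) != sorted(set(edges)):
        raise ValueError("bin_edges must be strictly increasing within (0,1)")
    df = table.subset(context=context, min_depth=min_depth)
    if not len(df):
        raise ValueError("no sites")
    depth = (df["n_meth"] + df["n_unmeth"]).to_numpy()
    levels = df["n_meth"].to_numpy() / depth
    counts = [int((levels < edges[0]).sum()),
              int(((levels >= edges[0]) & (levels <= edges[1])).sum())]
    prev = edges[1]
    for e in edges[2:]:
        counts.append(int(((levels > prev) & (levels <= e)).sum()))
        prev = e
    counts.append(int((levels > prev).sum()))
    total = len(levels)
    return LevelDistribution(edges, tuple(c / total for c in counts),
                             context, min_depth, total)


_FEATURE_NAMES = ("TE", "promoter", "CDS", "UTR", "intron", "gene")


def _feature_instances(annotation: AnnotationSet, feature: str,
                       promoter_bp: int = 1000) -> pd.DataFrame:
    """Instances of a feature as [chrom, start, end, instance_id] rows.

    CDS/UTR/intron pool all segments of a gene into one instance; the
    promoter is the ``promoter_bp`` immediately 5' of the TSS (strand-aware).
    """
    if feature == "TE":
        df = annotation.tes.rename(columns={"te_id": "instance_id"})
        return df[["chrom", "start", "end", "instance_id"]]
    if feature == "gene":
        df = annotation.genes.rename(columns={"gene_id": "instance_id"})
        return df[["chrom", "start", "end", "instance_id"]]
    if feature == "promoter":
        g = annotation.genes
        plus = g["strand"] != "-"
        start = np.where(plus, g["start"] - promoter_bp, g["end"])
        end = np.where(plus, g["start"], g["end"] + promoter_bp)
        df = pd.DataFrame({"chrom": g["chrom"], "start": start, "end": end,
                           "instance_id": g["gene_id"]})
        df["start"] = df["start"].clip(lower=0)
        for chrom, length in annotation.chrom_lengths.items():
            sel = df["chrom"] == chrom
            df.loc[sel, "end"] = df.loc[sel, "end"].clip(upper=length)
        return df[df["start"] < df["end"]]
    if feature in ("CDS", "intron"):
        sub = annotation.subfeatures
        df = sub[sub["feature"] == feature]
    elif feature == "UTR":
        sub = annotation.subfeatures
        df = sub[sub["feature"].isin(["five_prime_UTR", "three_prime_UTR"])]
    else:
        raise ValueError(f"unknown feature {feature!r}; valid: {_FEATURE_NAMES}")
    return df.rename(columns={"gene_id": "instance_id"})[
        ["chrom", "start", "end", "instance_id"]]


@dataclass
class FeatureLevels:
    feature: str
    context: str
    levels: pd.DataFrame  # instance_id, level, n_sites, total_meth, total_reads
    n_omitted: int        # instances with no qualifying site


def feature_levels(table: MethylomeTable, annotation: AnnotationSet,
                   feature: str, context: str | None = None,
                   min_depth: int = 1) -> FeatureLevels:
    """One weighted level per feature instance (violin-plot export).

    Instances without qualifying sites are omitted and counted in
    ``n_omitted``.
    """
    inst = _feature_instances(annotation, feature)
    df = table.subset(context=context, min_depth=min_depth)
    rows = []
    n_omitted = 0
    pos0_all = df["pos"].to_numpy() - 1
    meth_all = df["n_meth"].to_numpy()
    depth_all = (df["n_meth"] + df["n_unmeth"]).to_numpy()
    by_chrom = {chrom: np.flatnonzero((df["chrom"] == chrom).to_numpy())
                for chrom in inst["chrom"].unique()}
    for instance_id, grp in inst.groupby("instance_id", sort=False):
        meth = reads = nsites = 0
        for row in grp.itertuples(index=False):
            idx = by_chrom.get(row.chrom)
            if idx is None or not len(idx):
                continue
            p = pos0_all[idx]
            lo = np.searchsorted(p, row.start, side="left")
            hi = np.searchsorted(p, row.end, side="left")
            sel = idx[lo:hi]
            meth += int(meth_all[sel].sum())
            reads += int(depth_all[sel].sum())
            nsites += hi - lo
        if reads == 0:
            n_omitted += 1
            continue
        rows.append((instance_id, meth / reads, nsites, meth, reads))
    out = pd.DataFrame(rows, columns=["instance_id", "level", "n_sites",
                                      "total_meth", "total_reads"])
    return FeatureLevels(feature, context or "all", out, n_omitted)


def window_track(table: MethylomeTable, context: str,
                 chrom_lengths: dict[str, int], window_size: int = 100_000,
                 min_depth: int = 1) -> RegionSet:
    """Tiling-window weighted levels per chromosome as a scored RegionSet.

    Windows lacking qualifying sites carry a missing (NaN) score; the result
    is exportable as bedGraph (missing windows skipped on write).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    df = table.subset(context=context, min_depth=min_depth)
    out = []
    for chrom, length in chrom_lengths.items():
        edges = np.arange(0, length, window_size)
        n_win = len(edges)
        meth = np.zeros(n_win)
        reads = np.zeros(n_win)
        sub = df[df["chrom"] == chrom]
        if len(sub):
            widx = (sub["pos"].to_numpy() - 1) // window_size
            np.add.at(meth, widx, sub["n_meth"].to_numpy())
            np.add.at(reads, widx, (sub["n_meth"] + sub["n_unmeth"]).to_numpy())
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(reads > 0, meth / np.where(reads > 0, reads, 1), np.nan)
        out.append(pd.DataFrame({
            "chrom": chrom, "start": edges,
            "end": np.minimum(edges + window_size, length), "score": score}))
    return RegionSet(pd.concat(out, ignore_index=True), source="windows")


def subgenome_pair_comparison(pair_table: pd.DataFrame,
                              gene_levels: pd.DataFrame) -> dict[str, PairedComparison]:
    """Paired comparison of homeologous gene pairs between subgenomes.

    ``pair_table``: two columns of gene IDs (subgenome A member, B member).
    ``gene_levels``: DataFrame indexed by gene ID with one column per
    context holding that gene's weighted level (NaN = unmeasured).

    Per context the result holds the mean paired difference (B - A), a
    two-sided paired t-test p-value and the number of complete pairs. Pairs
    with identical levels everywhere give mean difference 0 and the note
    ``"no difference"`` (p undefined when the variance is 0).
    """
    a_ids = pair_table.iloc[:, 0].to_numpy()
    b_ids = pair_table.iloc[:, 1].to_numpy()
    unknown = [g for g in np.concatenate([a_ids, b_ids])
               if g not in gene_levels.index]
    if unknown:
        raise KeyError(f"gene IDs not resolvable: {sorted(set(unknown))[:5]}")
    out: dict[str, PairedComparison] = {}
    for context in gene_levels.columns:
        la = gene_levels.loc[a_ids, context].to_numpy(dtype=float)
        lb = gene_levels.loc[b_ids, context].to_numpy(dtype=float)
        complete = ~(np.isnan(la) | np.isnan(lb))
        n = int(complete.sum())
        if n < 2:
            raise ValueError(f"insufficient pairs for context {context}")
        diff = lb[complete] - la[complete]
        mean_diff = float(diff.mean())
        if np.allclose(diff.std(ddof=1), 0.0):
            p = float("nan") if mean_diff == 0 else 0.0
            note = "no difference" if mean_diff == 0 else "constant shift"
        else:
            p = float(sps.ttest_rel(lb[complete], la[complete]).pvalue)
            note = ""
        out[context] = PairedComparison(context, mean_diff, p, n, note)
    return out


def gene_body_levels(table: MethylomeTable, annotation: AnnotationSet,
                     min_depth: int = 1) -> pd.DataFrame:
    """Per-gene weighted level for every context, indexed by gene ID."""
    out = {}
    for context in CONTEXTS:
        fl = feature_levels(table, annotation, "gene", context=context,
                            min_depth=min_depth)
        out[context] = fl.levels.set_index("instance_id")["level"]
    return pd.DataFrame(out).reindex(annotation.genes["gene_id"])
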