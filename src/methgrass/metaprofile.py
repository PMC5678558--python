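"""Scaled-body + fixed-flank methylation metaprofiles for genes and TEs.

Each region contributes its cytosines to fixed-width flank bins (default
20 x 100 bp on each side) and to ``body_bins`` equal fractions of its own
length. Pooling is count-based per bin (sum of methylated reads over sum of
reads), so region order never matters and deep regions weigh more, matching
the weighted-level convention elsewhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotationSet, MethylomeTable, RegionSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MetaProfile:
    """Pooled counts per bin; levels are NaN where a bin saw no reads."""

    upstream_meth: np.ndarray
    upstream_reads: np.ndarray
    body_meth: np.ndarray
    body_reads: np.ndarray
    downstream_meth: np.ndarray
    downstream_reads: np.ndarray
    flank_bp: int
    flank_bin_bp: int
    n_regions: int
    context: str

    def _levels(self, meth: np.ndarray, reads: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(reads > 0, meth / np.where(reads > 0, reads, 1), np.nan)

    @property
    def upstream(self) -> np.ndarray:
        return self._levels(self.upstream_meth, self.upstream_reads)

    @property
    def body(self) -> np.ndarray:
        return self._levels(self.body_meth, self.body_reads)

    @property
    def downstream(self) -> np.ndarray:
        return self._levels(self.downstream_meth, self.downstream_reads)

    @property
    def levels(self) -> np.ndarray:
        """Upstream, body, downstream bins concatenated 5' to 3'."""
        return np.concatenate([self.upstream, self.body, self.downstream])

    def to_frame(self) -> pd.DataFrame:
        n_up = len(self.upstream)
        n_body = len(self.body)
        n_down = len(self.downstream)
        segment = ["upstream"] * n_up + ["body"] * n_body + ["downstream"] * n_down
        return pd.DataFrame({
            "segment": segment,
            "bin": list(range(n_up)) + list(range(n_body)) + list(range(n_down)),
            "level": self.levels,
            "meth_reads": np.concatenate([self.upstream_meth, self.body_meth,
                                          self.downstream_meth]),
            "total_reads": np.concatenate([self.upstream_reads, self.body_reads,
                                           self.downstream_reads]),
        })


def profile(table: MethylomeTable, regions: RegionSet, context: str,
            flank_bp: int = 2000, body_bins: int = 20, flank_bin_bp: int = 100,
            strand_aware: bool = True, min_depth: int = 1) -> MetaProfile:
    """Metaprofile of ``context`` methylation over ``regions``.

    Flanks are fixed ``flank_bin_bp`` bins covering ``flank_bp`` on each
    side; the body is ``body_bins`` equal fractions of each region (a site at
    offset o in a region of length L lands in bin floor(body_bins * o / L)).
    Minus-strand regions are reversed when ``strand_aware`` so bin 0 is
    always the 5' end.
    """
    if not len(regions):
        raise ValueError("regions must be non-empty")
    if flank_bp % flank_bin_bp:
        raise ValueError("flank_bp must be divisible by flank_bin_bp")
    n_flank = flank_bp // flank_bin_bp
    n_total = 2 * n_flank + body_bins

    df = table.subset(context=context, min_depth=min_depth)
    pos0 = df["pos"].to_numpy() - 1
    meth = df["n_meth"].to_numpy()
    reads = meth + df["n_unmeth"].to_numpy()
    chrom_idx = {chrom: np.flatnonzero((df["chrom"] == chrom).to_numpy())
                 for chrom in regions.df["chrom"].unique()}

    pooled_meth = np.zeros(n_total)
    pooled_reads = np.zeros(n_total)
    n_used = 0
    for row in regions.df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        length = end - start
        if length <= 0:
            raise ValidationError(f"zero-length region {row.chrom}:{start}-{end}")
        idx = chrom_idx.get(row.chrom)
        n_used += 1
        if idx is None or not len(idx):
            continue
        p = pos0[idx]
        lo = np.searchsorted(p, start - flank_bp, side="left")
        hi = np.searchsorted(p, end + flank_bp, side="left")
        sel = idx[lo:hi]
        if not len(sel):
            continue
        off = pos0[sel] - start
        bins = np.empty(len(sel), dtype=np.int64)
        up = off < 0
        down = off >= length
        body = ~(up | down)
        bins[up] = (off[up] + flank_bp) // flank_bin_bp
        bins[body] = n_flank + (body_bins * off[body]) // length
        bins[down] = n_flank + body_bins + (off[down] - length) // flank_bin_bp
        if strand_aware and row.strand == "-":
            bins = n_total - 1 - bins
        np.add.at(pooled_meth, bins, meth[sel])
        np.add.at(pooled_reads, bins, reads[sel])

    return MetaProfile(pooled_meth[:n_flank], pooled_reads[:n_flank],
                       pooled_meth[n_flank:n_flank + body_bins],
                       pooled_reads[n_flank:n_flank + body_bins],
                       pooled_meth[n_flank + body_bins:],
                       pooled_reads[n_flank + body_bins:],
                       flank_bp, flank_bin_bp, n_used, context)


DEFAULT_TE_CLASSES = ("LTR/Copia", "LTR/Gypsy", "LINE", "DNA")


def te_class_profiles(table: MethylomeTable, annotation: AnnotationSet,
                      classes: tuple[str, ...] = DEFAULT_TE_CLASSES,
                      context: str = "CG", **kwargs) -> dict[str, MetaProfile]:
    """One metaprofile per TE class; classes absent from the annotation are
    skipped with a warning. TEs are profiled strand-agnostically unless the
    annotation provides strands."""
    out: dict[str, MetaProfile] = {}
    for te_class in classes:
        regions = annotation.te_regions(te_class)
        if not len(regions):
            logger.warning("TE class %s absent from annotation; skipped", te_class)
            continue
        stranded = set(regions.df["strand"]) - {"."} != set()
        kw = {"strand_aware": stranded, **kwargs}
        out[te_class] = profile(table, regions, context, **kw)
    return out


def genes_without_intronic_tes(annotation: AnnotationSet) -> RegionSet:
    """Gene bodies whose introns overlap no TE (any overlap >= 1 bp excludes)."""
    from . import _intervals

    introns = annotation.subfeatures[annotation.subfeatures["feature"] == "intron"]
    if len(introns) and len(annotation.tes):
        hit = _intervals.overlap_any(introns, annotation.tes)
        excluded = set(introns.loc[hit, "gene_id"])
    else:
        excluded = set()
    keep = annotation.genes[~annotation.genes["gene_id"].isin(excluded)]
    out = keep.rename(columns={"gene_id": "name"})[
        ["chrom", "start", "end", "name", "strand"]]
    return RegionSet(out.copy(), source="genes_without_intronic_tes")


def plot_profile(profiles: dict[str, MetaProfile], path: str | None = None,
                 title: str = ""):
    """Minimal line-plot helper (one line per labelled profile)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    for label, prof in profiles.items():
        ax.plot(prof.levels, label=label)
    n_flank = len(next(iter(profiles.values())).upstream)
    n_body = len(next(iter(profiles.values())).body)
    ax.axvline(n_flank - 0.5, color="grey", lw=0.5)
    ax.axvline(n_flank + n_body - 0.5, color="grey", lw=0.5)
    ax.set_ylabel("methylation level")
    ax.set_title(title)
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
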