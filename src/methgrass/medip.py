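"""MeDIP-seq peak summaries and BS-seq/MeDIP concordance.

MeDIP-seq pulls down methylated fragments with an anti-methylcytosine
antibody, yielding coverage peaks without single-base resolution. The
analyses here summarise peak density per chromosome, find peaks common to
two genotypes, score peak regions with single-base (BS-seq) weighted
levels, and ask whether BS-derived DMRs agree in direction with
differential MeDIP peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _intervals, stats as mstats
from .io import CONTEXTS, MethylomeTable, RegionSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# peak density
# ---------------------------------------------------------------------------

def peak_density(peaks: RegionSet, annotated: np.ndarray,
                 chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Per-chromosome peak counts and per-Mb densities.

    ``annotated`` is a boolean per peak (e.g. assigned to a promoter or
    genic category by :func:`methgrass.annotate.assign_features`).
    """
    annotated = np.asarray(annotated, dtype=bool)
    if len(annotated) != len(peaks):
        raise ValueError("annotated flag length mismatch")
    df = peaks.df.assign(annotated=annotated)
    counts = df.groupby("chrom").agg(total_peaks=("start", "size"),
                                     annotated_peaks=("annotated", "sum"))
    rows = []
    for chrom, length in chrom_lengths.items():
        total = int(counts["total_peaks"].get(chrom, 0))
        ann = int(counts["annotated_peaks"].get(chrom, 0))
        rows.append({"chrom": chrom, "total_peaks": total,
                     "annotated_peaks": ann, "length_mb": length / 1e6})
    return density_table(pd.DataFrame(rows))


def density_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add per-Mb densities to a [chrom, total_peaks, annotated_peaks,
    length_mb] table. Densities are reported to 2 decimals (numpy
    round-half-even) alongside the unrounded values."""
    out = counts.copy()
    out["total_per_mb"] = out["total_peaks"] / out["length_mb"]
    out["annotated_per_mb"] = out["annotated_peaks"] / out["length_mb"]
    out["total_per_mb_2dp"] = np.round(out["total_per_mb"], 2)
    out["annotated_per_mb_2dp"] = np.round(out["annotated_per_mb"], 2)
    return out


# ---------------------------------------------------------------------------
# common peaks
# ---------------------------------------------------------------------------

def common_peaks(peaks_a: RegionSet, peaks_b: RegionSet,
                 min_overlap_bp: int = 1) -> RegionSet:
    """Intersection intervals where an A peak and a B peak overlap by at
    least ``min_overlap_bp``; each merged overlap is reported once. The
    operation is symmetric in its arguments."""
    inter = _intervals.intersect_intervals(
        peaks_a.df[["chrom", "start", "end"]],
        peaks_b.df[["chrom", "start", "end"]],
        min_overlap_bp=min_overlap_bp)
    if len(inter):
        inter = _intervals.merge_intervals(inter)
    return RegionSet(inter, source="common_peaks")


# ---------------------------------------------------------------------------
# BS-seq levels over peak regions
# ---------------------------------------------------------------------------

def region_methylation(bs_table: MethylomeTable, regions: RegionSet,
                       min_depth: int = 1) -> pd.DataFrame:
    """Per-region weighted level per context (heat-map matrix export).

    Rows follow ``regions``; a region with no qualifying sites of a context
    carries NaN there.
    """
    rdf = regions.df
    out = {ctx: np.full(len(rdf), np.nan) for ctx in CONTEXTS}
    for context in CONTEXTS:
        df = bs_table.subset(context=context, min_depth=min_depth)
        for chrom, grp in df.groupby("chrom"):
            idx = np.flatnonzero((rdf["chrom"] == chrom).to_numpy())
            if not len(idx):
                continue
            pos0 = grp["pos"].to_numpy() - 1
            meth = grp["n_meth"].to_numpy()
            reads = meth + grp["n_unmeth"].to_numpy()
            cmeth = np.concatenate([[0], np.cumsum(meth)])
            creads = np.concatenate([[0], np.cumsum(reads)])
            lo = np.searchsorted(pos0, rdf["start"].to_numpy()[idx], side="left")
            hi = np.searchsorted(pos0, rdf["end"].to_numpy()[idx], side="left")
            m = cmeth[hi] - cmeth[lo]
            r = creads[hi] - creads[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                out[context][idx] = np.where(r > 0, m / np.maximum(r, 1), np.nan)
    mat = pd.DataFrame(out)
    mat.insert(0, "chrom", rdf["chrom"].to_numpy())
    mat.insert(1, "start", rdf["start"].to_numpy())
    mat.insert(2, "end", rdf["end"].to_numpy())
    return mat


@dataclass(frozen=True)
class RegionComparison:
    context: str
    mean_diff: float  # mean(B - A)
    p_value: float
    n_pairs: int


def compare_genotype_regions(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                             paired: bool = True) -> dict[str, RegionComparison]:
    """Per-context t-test of region methylation between two genotypes.

    Matrices must share region rows (as produced by
    :func:`region_methylation` on the same RegionSet). ``mean_diff`` is
    mean(B - A); the default test is paired two-sided.
    """
    if len(matrix_a) != len(matrix_b):
        raise ValueError("matrices must share region rows")
    out: dict[str, RegionComparison] = {}
    for context in CONTEXTS:
        a = matrix_a[context].to_numpy(dtype=float)
        b = matrix_b[context].to_numpy(dtype=float)
        complete = ~(np.isnan(a) | np.isnan(b))
        n = int(complete.sum())
        if n < 2:
            raise ValueError(f"<2 complete pairs for context {context}")
        if paired:
            diff = b[complete] - a[complete]
            if np.allclose(diff.std(ddof=1), 0):
                p = float("nan") if np.allclose(diff, 0) else 0.0
            else:
                p = float(sps.ttest_rel(b[complete], a[complete]).pvalue)
        else:
            p = float(sps.ttest_ind(b[complete], a[complete]).pvalue)
        out[context] = RegionComparison(context, float((b[complete] - a[complete]).mean()),
                                        p, n)
    return out


# ---------------------------------------------------------------------------
# DMR / MeDIP concordance
# ---------------------------------------------------------------------------

def coverage_mean(track: RegionSet, regions: RegionSet) -> np.ndarray:
    """Interval-weighted mean of bedGraph values over each region.

    Only covered bases contribute; a region with no covered base gets NaN.
    """
    tdf = track.df.dropna(subset=["score"])
    out = np.full(len(regions), np.nan)
    for chrom, grp in tdf.groupby("chrom"):
        idx = np.flatnonzero((regions.df["chrom"] == chrom).to_numpy())
        if not len(idx):
            continue
        ss = grp["start"].to_numpy()
        se = grp["end"].to_numpy()
        val = grp["score"].to_numpy(dtype=float)
        for k in idx:
            qs = int(regions.df["start"].iloc[k])
            qe = int(regions.df["end"].iloc[k])
            lo = np.searchsorted(se, qs, side="right")
            hi = np.searchsorted(ss, qe, side="left")
            if hi <= lo:
                continue
            seg_s = np.maximum(ss[lo:hi], qs)
            seg_e = np.minimum(se[lo:hi], qe)
            w = (seg_e - seg_s).clip(min=0)
            if w.sum() > 0:
                out[k] = float(np.average(val[lo:hi], weights=w))
    return out


@dataclass
class ConcordanceReport:
    per_dmr: pd.DataFrame          # direction, chrom, start, end, signal_a, signal_b
    mean_signal: pd.DataFrame      # direction x (signal_a, signal_b, n, n_missing)
    concordant_hyper: int          # hyper DMRs overlapping B-upregulated peaks
    concordant_hypo: int           # hypo DMRs overlapping A-upregulated peaks


def dmr_peak_concordance(dmrs: dict[str, RegionSet], track_a: RegionSet,
                         track_b: RegionSet, diff_peaks_a: RegionSet,
                         diff_peaks_b: RegionSet) -> ConcordanceReport:
    """Per-DMR MeDIP signal means per genotype plus direction-concordant
    overlap counts (hyper DMRs vs B-upregulated peaks, hypo DMRs vs
    A-upregulated peaks; >= 1 bp overlap)."""
    frames = []
    missing_rows = []
    for direction in ("hyper", "hypo"):
        rs = dmrs[direction]
        sig_a = coverage_mean(track_a, rs)
        sig_b = coverage_mean(track_b, rs)
        df = rs.df[["chrom", "start", "end"]].copy()
        df["direction"] = direction
        df["signal_a"] = sig_a
        df["signal_b"] = sig_b
        frames.append(df)
        complete = ~(np.isnan(sig_a) | np.isnan(sig_b))
        missing_rows.append({
            "direction": direction,
            "signal_a": float(np.nanmean(sig_a[complete])) if complete.any() else np.nan,
            "signal_b": float(np.nanmean(sig_b[complete])) if complete.any() else np.nan,
            "n": int(complete.sum()),
            "n_missing": int((~complete).sum()),
        })
    per_dmr = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    hyper_hits = _intervals.overlap_any(dmrs["hyper"].df, diff_peaks_b.df) \
        if len(dmrs["hyper"]) and len(diff_peaks_b) else np.zeros(0, dtype=bool)
    hypo_hits = _intervals.overlap_any(dmrs["hypo"].df, diff_peaks_a.df) \
        if len(dmrs["hypo"]) and len(diff_peaks_a) else np.zeros(0, dtype=bool)
    return ConcordanceReport(per_dmr, pd.DataFrame(missing_rows),
                             int(hyper_hits.sum()), int(hypo_hits.sum()))
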