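"""Sorted-sweep interval primitives shared across modules.

All coordinates are 0-based half-open. Inputs are plain DataFrames with
``chrom``/``start``/``end`` columns; helpers return DataFrames or numpy
arrays so callers can wrap them in their own domain types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def merge_intervals(df: pd.DataFrame, book_ended: bool = True) -> pd.DataFrame:
    """Union of intervals per chromosome; touching intervals merge if
    ``book_ended``. Returns [chrom, start, end] sorted."""
    out = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            joins = s <= cur_e if book_ended else s < cur_e
            if joins:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64}, errors="ignore")


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame,
                        min_overlap_bp: int = 1) -> pd.DataFrame:
    """Piecewise intersection of two interval sets (each merged first)."""
    a = merge_intervals(a) if len(a) else a
    b = merge_intervals(b) if len(b) else b
    out = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])) if len(a) and len(b) else []:
        ga = a[a["chrom"] == chrom]
        gb = b[b["chrom"] == chrom]
        ia = ib = 0
        sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
        sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
        while ia < len(sa) and ib < len(sb):
            s = max(sa[ia], sb[ib])
            e = min(ea[ia], eb[ib])
            if e - s >= min_overlap_bp:
                out.append((chrom, int(s), int(e)))
            if ea[ia] <= eb[ib]:
                ia += 1
            else:
                ib += 1
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def overlap_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: overlaps (>=1 bp) any subject interval."""
    result = np.zeros(len(query), dtype=bool)
    if not len(subject):
        return result
    merged = merge_intervals(subject, book_ended=False)
    for chrom, grp in merged.groupby("chrom"):
        idx = np.flatnonzero((query["chrom"] == chrom).to_numpy())
        if not len(idx):
            continue
        qs = query["start"].to_numpy()[idx]
        qe = query["end"].to_numpy()[idx]
        ss = grp["start"].to_numpy()
        se = grp["end"].to_numpy()
        # subject interval j overlaps [qs,qe) iff ss[j] < qe and se[j] > qs
        j = np.searchsorted(ss, qe, side="left") - 1  # last ss < qe
        hit = (j >= 0) & (se[np.clip(j, 0, None)] > qs)
        # a subject starting before qe may end before qs; scan back is not
        # needed because subjects are merged/disjoint: se is increasing.
        result[idx] = hit
    return result


def overlap_bp(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Total overlapped bp per query row against the merged subject set."""
    result = np.zeros(len(query), dtype=np.int64)
    if not len(subject):
        return result
    merged = merge_intervals(subject, book_ended=False)
    for chrom, grp in merged.groupby("chrom"):
        idx = np.flatnonzero((query["chrom"] == chrom).to_numpy())
        if not len(idx):
            continue
        ss = grp["start"].to_numpy()
        se = grp["end"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(se - ss)])
        for k in idx:
            qs = int(query["start"].iloc[k])
            qe = int(query["end"].iloc[k])
            lo = np.searchsorted(se, qs, side="right")
            hi = np.searchsorted(ss, qe, side="left")
            if hi <= lo:
                continue
            total = cum[hi] - cum[lo]
            total -= max(0, qs - ss[lo])
            total -= max(0, se[hi - 1] - qe)
            result[k] = total
    return result


def gap_distance(qs: int, qe: int, ss: int, se: int) -> int:
    """Bases separating two half-open intervals; 0 when they overlap."""
    if ss >= qe:
        return ss - qe
    if se <= qs:
        return qs - se
    return 0


def nearest_interval(query: pd.DataFrame, subject: pd.DataFrame
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest subject interval per query row.

    Returns (index into ``subject``, distance bp). Overlap gives distance 0;
    ties are broken toward the leftmost subject (smallest start, then the
    earlier row). Queries on chromosomes without subjects get index -1 and
    distance -1.
    """
    nearest_idx = np.full(len(query), -1, dtype=np.int64)
    nearest_dist = np.full(len(query), -1, dtype=np.int64)
    for chrom, grp in subject.groupby("chrom"):
        idx = np.flatnonzero((query["chrom"] == chrom).to_numpy())
        if not len(idx):
            continue
        grp = grp.sort_values(["start", "end"])
        ss = grp["start"].to_numpy()
        se = grp["end"].to_numpy()
        rows = grp.index.to_numpy()
        for k in idx:
            qs = int(query["start"].iloc[k])
            qe = int(query["end"].iloc[k])
            dists = np.where(ss >= qe, ss - qe,
                             np.where(se <= qs, qs - se, 0))
            best = int(np.min(dists))
            j = int(np.flatnonzero(dists == best)[0])  # leftmost tie
            nearest_idx[k] = rows[j]
            nearest_dist[k] = best
    return nearest_idx, nearest_dist
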