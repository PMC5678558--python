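"""Differential methylation inference between two genotypes.

Pipeline: per-cytosine two-sided Fisher exact tests on sites covered by at
least ``min_depth`` reads in *both* genotypes -> Benjamini-Hochberg FDR
within each context -> DMCs (q < 0.05) -> single-linkage clustering of DMCs
closer than ``max_gap`` bp (same chromosome, context and direction) ->
clusters with >= ``min_dmcs`` members spanning >= ``min_span`` bp become
DMRs when the genotypes' weighted levels over the region differ by more
than the context threshold (0.4 / 0.2 / 0.1 for CG / CHG / CHH) ->
per-context DMRs merged across contexts within each direction.

Direction convention: *hyper* means higher methylation in genotype B,
*hypo* higher in genotype A (in the motivating two-ecotype comparison,
B = VS16 upland, A = AP13 lowland).

The Fisher p-value is computed vectorised from the hypergeometric pmf
(sum of the probabilities of all tables with the observed margins that are
no more probable than the observed table, with a 1e-7 relative tolerance on
the comparison to absorb floating-point rounding); per-site calls to a
generic implementation would be orders of magnitude too slow for the ~1e6
cytosines a genome-wide screen tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from . import _intervals
from .io import CONTEXTS, MethylomeTable, RegionSet

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}
_REL_TOL = 1e-7


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact_vector(a_meth: np.ndarray, a_unmeth: np.ndarray,
                        b_meth: np.ndarray, b_unmeth: np.ndarray,
                        chunk: int = 65536) -> np.ndarray:
    """Two-sided Fisher exact p for 2x2 tables [[am, au], [bm, bu]], vectorised.

    Conditional on the margins, the first cell follows a hypergeometric law;
    the two-sided p sums hypergeometric probabilities <= the observed
    table's (within relative tolerance 1e-7). Zero-depth margins raise.
    """
    am = np.asarray(a_meth, dtype=np.int64)
    au = np.asarray(a_unmeth, dtype=np.int64)
    bm = np.asarray(b_meth, dtype=np.int64)
    bu = np.asarray(b_unmeth, dtype=np.int64)
    if (am < 0).any() or (au < 0).any() or (bm < 0).any() or (bu < 0).any():
        raise ValueError("counts must be non-negative")
    n1 = am + au
    n2 = bm + bu
    if (n1 == 0).any() or (n2 == 0).any():
        raise ValueError("zero-depth margin; caller must filter such sites")
    total = n1 + n2
    k_total = am + bm
    p = np.empty(len(am), dtype=float)
    for lo_i in range(0, len(am), chunk):
        sl = slice(lo_i, lo_i + chunk)
        M, n, K, x = total[sl], n1[sl], k_total[sl], am[sl]
        lo = np.maximum(0, K - n2[sl])
        hi = np.minimum(n, K)
        width = int((hi - lo).max()) + 1
        k = lo[:, None] + np.arange(width)[None, :]
        valid = k <= hi[:, None]
        pmf = hypergeom.pmf(np.where(valid, k, 0), M[:, None], n[:, None],
                            K[:, None])
        obs = hypergeom.pmf(x, M, n, K)
        extreme = valid & (pmf <= obs[:, None] * (1 + _REL_TOL))
        p[sl] = np.where(extreme, pmf, 0.0).sum(axis=1)
    p[p >= 1 - 1e-10] = 1.0  # full-support sums are exactly 1 in exact math
    return np.clip(p, np.finfo(float).tiny, 1.0)


def test_dmc(a_meth: int, a_unmeth: int, b_meth: int, b_unmeth: int) -> float:
    """Two-sided Fisher exact p-value for one cytosine's 2x2 count table."""
    return float(fisher_exact_vector(np.array([a_meth]), np.array([a_unmeth]),
                                     np.array([b_meth]), np.array([b_unmeth]))[0])


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values (monotone, bounded by 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DMC calling
# ---------------------------------------------------------------------------

def call_dmcs(table_a: MethylomeTable, table_b: MethylomeTable,
              min_depth: int = 5, fdr_alpha: float = 0.05,
              per_context_fdr: bool = True,
              return_tested: bool = False):
    """Per-cytosine Fisher tests and FDR on sites deep enough in both samples.

    Only sites present with depth >= ``min_depth`` in BOTH genotypes are
    tested. BH adjustment is applied separately within each context by
    default (``per_context_fdr=False`` pools all contexts). Returns the DMC
    DataFrame (q < ``fdr_alpha``) with per-genotype counts, levels, p, q and
    direction; with ``return_tested`` also the full tested table.
    """
    merged = pd.merge(table_a.df, table_b.df,
                      on=["chrom", "pos", "strand", "context"],
                      suffixes=("_a", "_b"), how="inner")
    depth_a = merged["n_meth_a"] + merged["n_unmeth_a"]
    depth_b = merged["n_meth_b"] + merged["n_unmeth_b"]
    tested = merged[(depth_a >= min_depth) & (depth_b >= min_depth)].reset_index(drop=True)
    if not len(tested):
        logger.warning("no common sites with depth >= %d in both genotypes", min_depth)
        empty = tested.assign(p_value=[], q_value=[], level_a=[], level_b=[],
                              direction=[])
        return (empty, tested) if return_tested else empty

    tested["level_a"] = tested["n_meth_a"] / (tested["n_meth_a"] + tested["n_unmeth_a"])
    tested["level_b"] = tested["n_meth_b"] / (tested["n_meth_b"] + tested["n_unmeth_b"])
    tested["p_value"] = fisher_exact_vector(
        tested["n_meth_a"].to_numpy(), tested["n_unmeth_a"].to_numpy(),
        tested["n_meth_b"].to_numpy(), tested["n_unmeth_b"].to_numpy())
    tested["q_value"] = np.nan
    if per_context_fdr:
        for context in tested["context"].unique():
            sel = (tested["context"] == context).to_numpy()
            tested.loc[sel, "q_value"] = bh_adjust(tested.loc[sel, "p_value"].to_numpy())
    else:
        tested["q_value"] = bh_adjust(tested["p_value"].to_numpy())

    dmcs = tested[tested["q_value"] < fdr_alpha].copy()
    dmcs["direction"] = np.where(dmcs["level_b"] > dmcs["level_a"], "hyper", "hypo")
    dmcs = dmcs.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return (dmcs, tested) if return_tested else dmcs


# ---------------------------------------------------------------------------
# clustering and DMR filtering
# ---------------------------------------------------------------------------

def cluster_dmcs(dmcs: pd.DataFrame, max_gap: int = 100,
                 split_direction: bool = True) -> pd.DataFrame:
    """Single-linkage clustering of DMCs within chromosome/context(/direction).

    Consecutive DMCs with positional gap strictly below ``max_gap`` join one
    cluster; strand is ignored. Returns one row per cluster:
    [chrom, first_pos, last_pos (1-based inclusive), context, direction,
    n_dmcs, span_bp] with span_bp = last_pos - first_pos + 1.
    """
    if not len(dmcs):
        return pd.DataFrame(columns=["chrom", "first_pos", "last_pos", "context",
                                     "direction", "n_dmcs", "span_bp"])
    keys = ["chrom", "context"] + (["direction"] if split_direction else [])
    rows = []
    for key, grp in dmcs.sort_values("pos").groupby(keys, sort=False):
        pos = np.unique(grp["pos"].to_numpy())  # strand-collapsed positions
        breaks = np.flatnonzero(np.diff(pos) >= max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        key = key if isinstance(key, tuple) else (key,)
        for s, e in zip(starts, ends):
            n_dmcs = int(((grp["pos"] >= pos[s]) & (grp["pos"] <= pos[e])).sum())
            rows.append((*key, int(pos[s]), int(pos[e]), n_dmcs))
    cols = keys + ["first_pos", "last_pos", "n_dmcs"]
    out = pd.DataFrame(rows, columns=[*keys, "first_pos", "last_pos", "n_dmcs"])
    if not split_direction:
        out["direction"] = "mixed"
    out["span_bp"] = out["last_pos"] - out["first_pos"] + 1
    return out[["chrom", "first_pos", "last_pos", "context", "direction",
                "n_dmcs", "span_bp"]].sort_values(
        ["chrom", "first_pos"]).reset_index(drop=True)


def _region_level(df: pd.DataFrame, chrom: str, first_pos: int, last_pos: int,
                  context: str, which: str) -> tuple[int, int]:
    """Pooled (meth, reads) for one genotype over [first_pos, last_pos]."""
    sub = df[(df["chrom"] == chrom) & (df["context"] == context)]
    pos = sub["pos"].to_numpy()
    lo = np.searchsorted(pos, first_pos, side="left")
    hi = np.searchsorted(pos, last_pos, side="right")
    sel = sub.iloc[lo:hi]
    meth = int(sel[f"n_meth_{which}"].sum())
    reads = meth + int(sel[f"n_unmeth_{which}"].sum())
    return meth, reads


def call_dmrs(clusters: pd.DataFrame, table_a: MethylomeTable,
              table_b: MethylomeTable, min_dmcs: int = 4, min_span: int = 50,
              thresholds: dict[str, float] | None = None, min_depth: int = 5,
              dmc_positions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Filter DMC clusters into DMRs.

    Keeps clusters with >= ``min_dmcs`` members AND span >= ``min_span`` bp,
    recomputes each genotype's weighted level over *all* context sites with
    depth >= ``min_depth`` in the cluster span (pass ``dmc_positions`` —
    the DMC table — to restrict the region level to DMC sites instead), and
    retains the cluster as a DMR iff |level_b - level_a| strictly exceeds
    the context threshold. Output columns: chrom, start, end (0-based
    half-open), context, n_dmcs, span_bp, level_a, level_b, diff, direction.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    kept = clusters[(clusters["n_dmcs"] >= min_dmcs) &
                    (clusters["span_bp"] >= min_span)]

    def prep(table: MethylomeTable, which: str) -> pd.DataFrame:
        df = table.subset(min_depth=min_depth).copy()
        return df.rename(columns={"n_meth": f"n_meth_{which}",
                                  "n_unmeth": f"n_unmeth_{which}"})

    if dmc_positions is not None:
        keys = dmc_positions[["chrom", "pos", "strand", "context"]]
        df_a = prep(table_a, "a").merge(keys, on=["chrom", "pos", "strand", "context"])
        df_b = prep(table_b, "b").merge(keys, on=["chrom", "pos", "strand", "context"])
    else:
        df_a = prep(table_a, "a")
        df_b = prep(table_b, "b")
    df_a = df_a.sort_values(["chrom", "context", "pos"])
    df_b = df_b.sort_values(["chrom", "context", "pos"])

    rows = []
    for row in kept.itertuples(index=False):
        meth_a, reads_a = _region_level(df_a, row.chrom, row.first_pos,
                                        row.last_pos, row.context, "a")
        meth_b, reads_b = _region_level(df_b, row.chrom, row.first_pos,
                                        row.last_pos, row.context, "b")
        assert reads_a > 0 and reads_b > 0, "cluster span contains its own DMCs"
        level_a = meth_a / reads_a
        level_b = meth_b / reads_b
        diff = level_b - level_a
        if abs(diff) > thresholds[row.context]:
            rows.append((row.chrom, row.first_pos - 1, row.last_pos, row.context,
                         row.n_dmcs, row.span_bp, level_a, level_b, diff,
                         "hyper" if diff > 0 else "hypo"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                       "n_dmcs", "span_bp", "level_a",
                                       "level_b", "diff", "direction"])


def merge_contexts(dmrs: pd.DataFrame) -> dict[str, RegionSet]:
    """Union per-context DMRs across contexts within each direction.

    Overlapping or book-ended intervals merge; directions never mix.
    """
    out: dict[str, RegionSet] = {}
    for direction in ("hyper", "hypo"):
        sub = dmrs[dmrs["direction"] == direction]
        if not len(sub):
            out[direction] = RegionSet(pd.DataFrame(
                columns=["chrom", "start", "end"]), source=f"dmrs_{direction}")
            continue
        merged = _intervals.merge_intervals(sub[["chrom", "start", "end"]],
                                            book_ended=True)
        merged["name"] = [f"{direction}_dmr_{i}" for i in range(len(merged))]
        out[direction] = RegionSet(merged, source=f"dmrs_{direction}")
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline with a funnel summary
# ---------------------------------------------------------------------------

@dataclass
class DMRResult:
    dmcs: pd.DataFrame
    clusters: pd.DataFrame
    dmrs: pd.DataFrame
    merged: dict[str, RegionSet]
    funnel: pd.DataFrame


def dmr_pipeline(table_a: MethylomeTable, table_b: MethylomeTable,
                 min_depth: int = 5, fdr_alpha: float = 0.05,
                 max_gap: int = 100, min_dmcs: int = 4, min_span: int = 50,
                 thresholds: dict[str, float] | None = None) -> DMRResult:
    """Full DMC -> cluster -> DMR -> merge pipeline with a per-context funnel
    (tested sites, raw p < alpha, DMCs, qualifying clusters, DMRs)."""
    dmcs, tested = call_dmcs(table_a, table_b, min_depth=min_depth,
                             fdr_alpha=fdr_alpha, return_tested=True)
    clusters = cluster_dmcs(dmcs, max_gap=max_gap)
    dmrs = call_dmrs(clusters, table_a, table_b, min_dmcs=min_dmcs,
                     min_span=min_span, thresholds=thresholds,
                     min_depth=min_depth)
    merged = merge_contexts(dmrs)
    qual = clusters[(clusters["n_dmcs"] >= min_dmcs) &
                    (clusters["span_bp"] >= min_span)]
    rows = []
    for context in CONTEXTS:
        rows.append({
            "context": context,
            "sites_tested": int((tested["context"] == context).sum()),
            "sites_p_lt_alpha": int(((tested["context"] == context) &
                                     (tested["p_value"] < fdr_alpha)).sum()),
            "dmcs": int((dmcs["context"] == context).sum()),
            "clusters_kept": int((qual["context"] == context).sum()),
            "dmrs": int((dmrs["context"] == context).sum()),
        })
    return DMRResult(dmcs, clusters, dmrs, merged, pd.DataFrame(rows))
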