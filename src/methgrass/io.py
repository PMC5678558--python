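"""Domain types and readers/writers for the external formats the pipeline touches.

Conventions
-----------
* Intervals are stored 0-based half-open (BED-native).
* Per-cytosine positions are stored 1-based (as in Bismark cytosine/CX
  reports) and converted to intervals only at overlap time, via
  :func:`cytosine_interval`.
* The ``CpG`` context label used by Bismark is normalised to ``CG``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

TE_CLASSES = (
    "LTR/Copia",
    "LTR/Gypsy",
    "LINE",
    "SINE",
    "DNA",
    "RC/Helitron",
    "other",
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when parsed records violate a structural invariant."""


# ---------------------------------------------------------------------------
# coordinate conversion (centralised: the only place 1-based becomes 0-based)
# ---------------------------------------------------------------------------

def gff_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based closed GFF3 span to 0-based half-open."""
    return start_1based - 1, end_1based


def cytosine_interval(pos_1based: int) -> tuple[int, int]:
    """The 0-based half-open interval covered by a 1-based cytosine."""
    return pos_1based - 1, pos_1based


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineCall:
    """One cytosine's methylation evidence in one sample."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValidationError(f"negative read count at {self.chrom}:{self.pos}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        return self.n_meth / self.depth if self.depth else float("nan")


_METHYLOME_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]


class MethylomeTable:
    """Indexed collection of per-cytosine calls for one sample.

    Backed by a :class:`pandas.DataFrame` sorted by (chrom, pos, strand);
    the (chrom, pos, strand) key is unique.
    """

    def __init__(self, df: pd.DataFrame, sample_id: str = "",
                 n_filtered_depth: int = 0, n_rejected: int = 0):
        missing = [c for c in _METHYLOME_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"methylome table missing columns {missing}")
        df = df[_METHYLOME_COLUMNS].sort_values(
            ["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValidationError("duplicate (chrom, pos, strand) keys")
        self.df = df
        self.sample_id = sample_id
        self.n_filtered_depth = n_filtered_depth
        self.n_rejected = n_rejected

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[CytosineCall]:
        for row in self.df.itertuples(index=False):
            yield CytosineCall(row.chrom, int(row.pos), row.strand,
                               row.context, int(row.n_meth), int(row.n_unmeth))

    @property
    def depth(self) -> np.ndarray:
        return (self.df["n_meth"] + self.df["n_unmeth"]).to_numpy()

    def subset(self, context: str | None = None, min_depth: int = 0,
               chroms: Iterable[str] | None = None) -> pd.DataFrame:
        """View of the underlying frame restricted by context/depth/chromosome."""
        df = self.df
        mask = np.ones(len(df), dtype=bool)
        if context is not None:
            if context not in CONTEXTS:
                raise ValueError(f"unknown context {context!r}; valid: {CONTEXTS}")
            mask &= (df["context"] == context).to_numpy()
        if min_depth > 0:
            mask &= self.depth >= min_depth
        if chroms is not None:
            mask &= df["chrom"].isin(list(chroms)).to_numpy()
        return df[mask]

    @classmethod
    def from_calls(cls, calls: Iterable[CytosineCall], sample_id: str = "") -> "MethylomeTable":
        rows = [(c.chrom, c.pos, c.strand, c.n_meth, c.n_unmeth, c.context)
                for c in calls]
        df = pd.DataFrame(rows, columns=_METHYLOME_COLUMNS)
        return cls(df, sample_id=sample_id)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


_REGION_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class RegionSet:
    """Generic scored intervals (peaks, DMRs, windows).

    Backed by a DataFrame with BED6-shaped columns, sorted by (chrom, start, end).
    """

    def __init__(self, df: pd.DataFrame, source: str = "regions"):
        df = df.copy()
        for col, default in (("name", None), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[_REGION_COLUMNS + [c for c in df.columns if c not in _REGION_COLUMNS]]
        bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
        if len(bad):
            r = bad.iloc[0]
            raise ValidationError(
                f"invalid interval {r['chrom']}:{r['start']}-{r['end']}")
        self.df = df.sort_values(["chrom", "start", "end"],
                                 kind="mergesort").reset_index(drop=True)
        self.source = source

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            score = None if pd.isna(row.score) else float(row.score)
            name = None if row.name in (None, "", ".") or pd.isna(row.name) else str(row.name)
            yield GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  str(row.strand), score, name)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval],
                       source: str = "regions") -> "RegionSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
                for iv in intervals]
        df = pd.DataFrame(rows, columns=_REGION_COLUMNS)
        return cls(df, source=source)

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())


class AnnotationSet:
    """Genes with derived sub-features, TEs with classes, and chromosome sizes.

    ``genes``: DataFrame [chrom, start, end, strand, gene_id]
    ``subfeatures``: DataFrame [chrom, start, end, strand, gene_id, feature]
        with feature in {CDS, five_prime_UTR, three_prime_UTR, intron}, taken
        from one representative (longest) transcript per gene.
    ``tes``: DataFrame [chrom, start, end, strand, te_id, te_class]
    ``chrom_lengths``: mapping chromosome -> length (bp)
    """

    SUBFEATURES = ("CDS", "five_prime_UTR", "three_prime_UTR", "intron")

    def __init__(self, genes: pd.DataFrame, subfeatures: pd.DataFrame,
                 tes: pd.DataFrame, chrom_lengths: Mapping[str, int]):
        self.genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.subfeatures = subfeatures.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.tes = tes.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.chrom_lengths = dict(chrom_lengths)
        self._validate()

    def _validate(self) -> None:
        if len(self.subfeatures):
            spans = self.genes.set_index("gene_id")[["start", "end"]]
            sub = self.subfeatures
            gs = spans.reindex(sub["gene_id"])
            outside = (sub["start"].to_numpy() < gs["start"].to_numpy()) | \
                      (sub["end"].to_numpy() > gs["end"].to_numpy())
            if outside.any():
                row = sub[outside].iloc[0]
                raise ValidationError(
                    f"sub-feature {row['feature']} of {row['gene_id']} "
                    f"[{row['start']},{row['end']}) lies outside its gene span")
        if len(self.tes) and not self.tes["te_class"].isin(TE_CLASSES).all():
            bad = sorted(set(self.tes["te_class"]) - set(TE_CLASSES))
            raise ValidationError(f"unknown TE classes {bad}")

    def te_regions(self, te_class: str | None = None) -> RegionSet:
        df = self.tes if te_class is None else self.tes[self.tes["te_class"] == te_class]
        out = df.rename(columns={"te_id": "name"})[["chrom", "start", "end", "name", "strand"]]
        return RegionSet(out.copy(), source="tes")

    def gene_regions(self) -> RegionSet:
        out = self.genes.rename(columns={"gene_id": "name"})[
            ["chrom", "start", "end", "name", "strand"]]
        return RegionSet(out.copy(), source="genes")


# ---------------------------------------------------------------------------
# Bismark cytosine / CX report
# ---------------------------------------------------------------------------

_CX_NAMES = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]
_CONTEXT_ALIASES = {"CpG": "CG", "CG": "CG", "CHG": "CHG", "CHH": "CHH"}


def read_cytosine_report(path: str | Path, min_depth: int = 0,
                         sample_id: str | None = None) -> MethylomeTable:
    """Read a Bismark-style per-cytosine report (7 tab-separated columns).

    Rows with total depth below ``min_depth`` are dropped (counted in
    ``MethylomeTable.n_filtered_depth``). Malformed lines raise
    :class:`ParseError` naming the 1-based line number; an empty file yields
    an empty table.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    try:
        df = pd.read_csv(path, sep="\t", names=_CX_NAMES, header=None,
                         dtype={"chrom": str, "strand": str, "context": str, "tri": str},
                         comment=None)
    except pd.errors.EmptyDataError:
        return MethylomeTable(pd.DataFrame(columns=_METHYLOME_COLUMNS),
                              sample_id=sample_id)
    if df.shape[1] != len(_CX_NAMES):
        raise ParseError(f"{path}: expected 7 tab-separated columns")

    for col in ("pos", "n_meth", "n_unmeth"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != np.floor(converted)) | (converted < 0)
        if col == "pos":
            bad |= converted < 1
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"{path}:{line}: non-integer or negative {col!r} field")
        df[col] = converted.astype(np.int64)

    ctx = df["context"].map(_CONTEXT_ALIASES)
    if ctx.isna().any():
        line = int(np.flatnonzero(ctx.isna().to_numpy())[0]) + 1
        raise ParseError(f"{path}:{line}: unknown context "
                         f"{df['context'].iloc[line - 1]!r}")
    df["context"] = ctx
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise ParseError(f"{path}:{line}: strand must be '+' or '-'")

    n_in = len(df)
    depth = (df["n_meth"] + df["n_unmeth"]).to_numpy()
    keep = depth >= min_depth
    table = MethylomeTable(df.loc[keep, _METHYLOME_COLUMNS], sample_id=sample_id,
                           n_filtered_depth=int(n_in - keep.sum()))
    logger.info("%s: %d rows read, %d kept (depth >= %d), 0 rejected",
                path, n_in, len(table), min_depth)
    return table


def write_cytosine_report(table: MethylomeTable, path: str | Path) -> None:
    """Write a 7-column Bismark-style report (CG labelled CpG, as Bismark does)."""
    df = table.df.copy()
    df["context_out"] = df["context"].map({"CG": "CpG", "CHG": "CHG", "CHH": "CHH"})
    df["tri"] = df["context_out"].map({"CpG": "CGN", "CHG": "CHG", "CHH": "CHH"})
    df[["chrom", "pos", "strand", "n_meth", "n_unmeth", "context_out", "tri"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TE_FEATURE_TYPES = {"transposable_element", "repeat_region", "transposon_fragment"}
_GFF_NAMES = ["seqid", "source", "type", "start", "end", "score", "strand",
              "phase", "attributes"]


def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def _canonical_te_class(raw: str | None) -> str:
    if raw is None:
        return "other"
    raw = raw.strip()
    lowered = raw.lower()
    aliases = {
        "ltr/copia": "LTR/Copia", "copia": "LTR/Copia",
        "ltr/gypsy": "LTR/Gypsy", "gypsy": "LTR/Gypsy",
        "line": "LINE", "sine": "SINE",
        "dna": "DNA", "dna transposon": "DNA",
        "rc/helitron": "RC/Helitron", "helitron": "RC/Helitron",
    }
    return aliases.get(lowered, raw if raw in TE_CLASSES else "other")


def read_gff3(path: str | Path, te_path: str | Path | None = None) -> AnnotationSet:
    """Read gene and TE annotation from GFF3 into an :class:`AnnotationSet`.

    Genes carry gene/mRNA/exon/CDS/UTR hierarchies; one representative
    (longest) mRNA per gene supplies sub-features, and introns are the mRNA
    span minus its exons. TE features (types ``transposable_element`` /
    ``repeat_region``) carry a ``class`` attribute; a missing class maps to
    ``other`` with a logged warning. ``##sequence-region`` pragmas populate
    chromosome lengths. A second file (e.g. a repeat annotation) may be
    supplied via ``te_path``.
    """
    paths = [Path(path)] + ([Path(te_path)] if te_path is not None else [])
    chrom_lengths: dict[str, int] = {}
    records: list[dict] = []
    for p in paths:
        with open(p) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        chrom_lengths[parts[1]] = int(parts[3])
                    continue
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ParseError(f"{p}:{lineno}: expected 9 columns")
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{p}:{lineno}: non-integer coordinates") from exc
                if start1 < 1 or end1 < start1:
                    raise ParseError(f"{p}:{lineno}: invalid span {start1}-{end1}")
                start, end = gff_to_internal(start1, end1)
                records.append({
                    "chrom": fields[0], "type": fields[2], "start": start,
                    "end": end, "strand": fields[6],
                    "attrs": _parse_attributes(fields[8]), "line": lineno,
                })

    genes, tes, mrnas, children = [], [], {}, {}
    for rec in records:
        ftype = rec["type"]
        attrs = rec["attrs"]
        if ftype == "gene":
            genes.append({"chrom": rec["chrom"], "start": rec["start"],
                          "end": rec["end"], "strand": rec["strand"],
                          "gene_id": attrs.get("ID", f"gene_{len(genes)}")})
        elif ftype == "mRNA":
            mrnas[attrs.get("ID")] = {**rec, "parent": attrs.get("Parent")}
        elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
            parent = attrs.get("Parent")
            children.setdefault(parent, []).append(rec)
        elif ftype in _TE_FEATURE_TYPES:
            raw = attrs.get("class") or attrs.get("Class") or attrs.get("classification")
            if raw is None:
                logger.warning("TE at %s:%d-%d has no class attribute; using 'other'",
                               rec["chrom"], rec["start"], rec["end"])
            tes.append({"chrom": rec["chrom"], "start": rec["start"],
                        "end": rec["end"], "strand": rec["strand"],
                        "te_id": attrs.get("ID", f"te_{len(tes)}"),
                        "te_class": _canonical_te_class(raw)})

    gene_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "gene_id"])
    te_df = pd.DataFrame(tes, columns=["chrom", "start", "end", "strand", "te_id", "te_class"])

    # one representative (longest) transcript per gene
    rep: dict[str, dict] = {}
    for mrna in mrnas.values():
        gid = mrna["parent"]
        if gid is None:
            continue
        if gid not in rep or (mrna["end"] - mrna["start"]) > (rep[gid]["end"] - rep[gid]["start"]):
            rep[gid] = mrna

    sub_rows = []
    mrna_ids = {id(m): mid for mid, m in mrnas.items()}
    for gid, mrna in rep.items():
        mid = mrna_ids[id(mrna)]
        kids = children.get(mid, [])
        for rec in kids:
            if rec["start"] < mrna["start"] or rec["end"] > mrna["end"]:
                raise ValidationError(
                    f"child {rec['type']} [{rec['start']},{rec['end']}) outside "
                    f"mRNA {mid} span [{mrna['start']},{mrna['end']})")
            if rec["type"] != "exon":
                sub_rows.append({"chrom": rec["chrom"], "start": rec["start"],
                                 "end": rec["end"], "strand": rec["strand"],
                                 "gene_id": gid, "feature": rec["type"]})
        exons = sorted((r["start"], r["end"]) for r in kids if r["type"] == "exon")
        if not exons:  # fall back: CDS+UTRs act as exons for intron derivation
            exons = sorted((r["start"], r["end"]) for r in kids)
        prev_end = None
        for start, end in exons:
            if prev_end is not None and start > prev_end:
                sub_rows.append({"chrom": mrna["chrom"], "start": prev_end,
                                 "end": start, "strand": mrna["strand"],
                                 "gene_id": gid, "feature": "intron"})
            prev_end = end if prev_end is None else max(prev_end, end)

    sub_df = pd.DataFrame(sub_rows, columns=["chrom", "start", "end", "strand",
                                             "gene_id", "feature"])
    for chrom in pd.concat([gene_df["chrom"], te_df["chrom"]]).unique():
        chrom_lengths.setdefault(chrom, int(max(
            gene_df.loc[gene_df["chrom"] == chrom, "end"].max() if len(gene_df) else 0,
            te_df.loc[te_df["chrom"] == chrom, "end"].max() if len(te_df) else 0)))
    return AnnotationSet(gene_df, sub_df, te_df, chrom_lengths)


# ---------------------------------------------------------------------------
# BED family
# ---------------------------------------------------------------------------

def read_regions(path: str | Path, dialect: str = "bed",
                 source: str | None = None) -> RegionSet:
    """Read a BED / narrowPeak / bedGraph file (0-based half-open).

    narrowPeak preserves the score column (5th) in ``score``; bedGraph
    preserves its value column. ``start >= end`` raises with the line number.
    """
    path = Path(path)
    if dialect not in ("bed", "narrowPeak", "bedGraph"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#",
                          dtype={0: str})
    except pd.errors.EmptyDataError:
        return RegionSet(pd.DataFrame(columns=_REGION_COLUMNS),
                         source=source or dialect)
    ncol = raw.shape[1]
    df = pd.DataFrame({"chrom": raw[0].astype(str),
                       "start": raw[1].astype(np.int64),
                       "end": raw[2].astype(np.int64)})
    if dialect == "bedGraph":
        if ncol < 4:
            raise ParseError(f"{path}: bedGraph needs 4 columns")
        df["score"] = raw[3].astype(float)
    else:
        df["name"] = raw[3].astype(str) if ncol > 3 else None
        if ncol > 4:
            score = pd.to_numeric(raw[4], errors="coerce")
            df["score"] = score
        if ncol > 5:
            df["strand"] = raw[5].astype(str)

    bad = (df["start"] >= df["end"]) | (df["start"] < 0)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ParseError(f"{path}:{line}: start >= end")
    return RegionSet(df, source=source or dialect)


def write_regions(regions: RegionSet, path: str | Path,
                  extra_columns: pd.DataFrame | None = None) -> None:
    """Write BED6(+extras); round-trips through :func:`read_regions`."""
    df = regions.df[_REGION_COLUMNS].copy()
    df["name"] = df["name"].fillna(".")
    df["score"] = df["score"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    df["strand"] = df["strand"].fillna(".")
    if extra_columns is not None:
        if len(extra_columns) != len(df):
            raise ValidationError("extra_columns length mismatch")
        df = pd.concat([df, extra_columns.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(regions: RegionSet, path: str | Path) -> None:
    """Write chrom/start/end/value lines; missing scores are skipped."""
    df = regions.df[["chrom", "start", "end", "score"]].dropna(subset=["score"])
    df.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column name<TAB>length table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_lengths(chrom_lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
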