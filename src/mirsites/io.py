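"""Typed readers and writers for the external formats the pipeline touches.

Every genomic coordinate inside the package is 0-based half-open; 1-based
formats (GTF-like annotations, TargetScan UTR positions) are converted at the
boundary. Parsers are lossless: duplicate site records are retained and
de-duplication is left to the matrix builder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mirsites")

CONSERVED = "conserved"
NONCONSERVED = "nonconserved"
CATEGORIES = (CONSERVED, NONCONSERVED)

#: Column order of the generic site-table dialect (TSV with header).
SITE_COLUMNS = [
    "gene_id",
    "mirna_id",
    "species_id",
    "category",
    "context_score",
    "utr_start",
    "utr_end",
]


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Normalize a set of 0-based half-open intervals: sort and merge overlaps.

    Abutting intervals (10,20)+(20,30) are merged into (10,30) as well, so the
    result is strictly non-overlapping and non-adjacent.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    for start, end in ivs:
        if start >= end:
            raise FormatError(f"interval has start >= end: ({start}, {end})")
    merged = [list(ivs[0])]
    for start, end in ivs[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteRecord:
    """One predicted miRNA site in a gene's 3'UTR.

    ``context_score`` is the site-efficacy score (more negative = stronger
    predicted repression). Optional ``utr_start``/``utr_end`` locate the site
    within the 3'UTR, 0-based half-open.
    """

    gene_id: str
    mirna_id: str
    species_id: str
    category: str
    context_score: float
    utr_start: int | None = None
    utr_end: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_id or not self.mirna_id:
            raise ValueError("gene_id and mirna_id must be nonempty")
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if (self.utr_start is None) != (self.utr_end is None):
            raise ValueError("utr_start and utr_end must be given together")
        if self.utr_start is not None and not self.utr_start < self.utr_end:
            raise ValueError("utr_start must be < utr_end")


@dataclass
class GeneAnnotation:
    """Gene model in one coordinate convention: 0-based half-open on ``chrom``.

    ``tss`` is the transcription start *base*; for minus-strand genes it is the
    rightmost transcript coordinate (span end - 1). ``span`` is the full
    transcript extent, introns included; when absent it defaults to the hull of
    the TSS and all annotated intervals.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    utr3_intervals: list[tuple[int, int]] = field(default_factory=list)
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        self.utr3_intervals = merge_intervals(self.utr3_intervals)
        self.cds_intervals = merge_intervals(self.cds_intervals)
        if self.span is None:
            points = [self.tss, self.tss + 1]
            for s, e in self.utr3_intervals + self.cds_intervals:
                points += [s, e]
            self.span = (min(points), max(points))

    @property
    def utr3_length(self) -> int:
        return total_length(self.utr3_intervals)

    @property
    def cds_length(self) -> int:
        return total_length(self.cds_intervals)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression intensities on a linear scale."""

    data: pd.DataFrame  # index: gene_id, columns: sample_id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene rows in expression matrix: {dups[:5]}")
        if self.data.isna().any().any():
            raise FormatError("expression matrix contains missing values (ragged rows?)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


class ScoreTrack:
    """Per-base scores as sorted, non-overlapping intervals keyed by chromosome.

    Conservation scores live in [0, 1]; bases outside the intervals are
    *uncovered*, not zero.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame[["chrom", "start", "end", "score"]].copy()
        if (frame["start"] >= frame["end"]).any():
            raise FormatError("track interval with start >= end")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=True):
            if not sub["start"].is_monotonic_increasing:
                logger.info("track intervals on %s unsorted; sorting internally", chrom)
                sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise FormatError(f"overlapping track intervals on {chrom}")
            self._by_chrom[str(chrom)] = (starts, ends, sub["score"].to_numpy(dtype=float))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, scores) arrays for one chromosome (empty if absent)."""
        if chrom not in self._by_chrom:
            z = np.empty(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return self._by_chrom[chrom]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms:
            starts, ends, scores = self._by_chrom[chrom]
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "score": scores}))
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end", "score"])
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat element (e.g. LTR, SINE) as a 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    repeat_class: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("repeat start must be < end")


@dataclass
class GeneSet:
    """A named set of gene ids (TF lists, tissue-specific lists, CLIP targets)."""

    name: str
    members: set[str]

    def restricted(self, universe: Iterable[str]) -> "GeneSet":
        return GeneSet(self.name, self.members & set(universe))


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

_TARGETSCAN_MAP = {
    "gene_id": ("Gene Symbol", "Gene ID"),
    "mirna_id": ("miRNA",),
    "species_id": ("Species ID",),
    "category": ("Site category",),
    "context_score": ("context+ score",),
    "utr_start": ("UTR start",),
    "utr_end": ("UTR end",),
}

_MIRANDA_MAP = {
    "gene_id": ("gene_symbol",),
    "mirna_id": ("mirna_name",),
    "species_id": ("species",),
    "category": ("category",),
    "context_score": ("mirsvr_score",),
    "utr_start": ("utr_start",),
    "utr_end": ("utr_end",),
}

_GENERIC_MAP = {c: (c,) for c in SITE_COLUMNS}

_DIALECTS = {"targetscan": _TARGETSCAN_MAP, "miranda": _MIRANDA_MAP, "generic-tsv": _GENERIC_MAP}

#: Sites with mirSVR score above this (i.e. weaker) are dropped for the
#: miranda dialect. The cutoff defining a "good" mirSVR score is not a
#: community constant; override per data release.
DEFAULT_MIRSVR_CUTOFF = -0.1


def _pick(columns: Sequence[str], candidates: Sequence[str]) -> str | None:
    for c in candidates:
        if c in columns:
            return c
    return None


def parse_site_frame(
    path: str | Path,
    dialect: str = "generic-tsv",
    category: str | None = None,
    mirsvr_cutoff: float = DEFAULT_MIRSVR_CUTOFF,
) -> pd.DataFrame:
    """Read a site table into a DataFrame with the generic columns.

    This is the bulk fast path; :func:`parse_site_table` wraps it into
    :class:`SiteRecord` objects. ``category`` supplies the site category for
    single-category files (TargetScan ships conserved and nonconserved sites
    as separate downloads). For the ``miranda`` dialect, rows with mirSVR
    score above ``mirsvr_cutoff`` (weaker than the cutoff) are dropped.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    colmap = _DIALECTS[dialect]
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = pd.DataFrame(index=raw.index)
    for target in ("gene_id", "mirna_id", "species_id"):
        col = _pick(raw.columns, colmap[target])
        if col is None:
            raise FormatError(f"missing mandatory column {colmap[target][0]!r} in {path}")
        out[target] = raw[col]
    cat_col = _pick(raw.columns, colmap["category"])
    if cat_col is not None:
        out["category"] = raw[cat_col]
    elif category is not None:
        out["category"] = category
    else:
        raise FormatError(
            f"missing mandatory column {colmap['category'][0]!r} in {path} "
            "(pass category=... for single-category files)"
        )
    score_col = _pick(raw.columns, colmap["context_score"])
    if score_col is None:
        raise FormatError(f"missing mandatory column {colmap['context_score'][0]!r} in {path}")
    scores = pd.to_numeric(raw[score_col], errors="coerce")
    bad = scores.isna() | (raw[score_col].str.strip() == "")
    if bad.any():
        # +2: 1-based line numbering plus the header line
        line = int(bad.idxmax()) + 2
        raise FormatError(f"non-numeric score {raw[score_col][bad.idxmax()]!r} at line {line} of {path}")
    out["context_score"] = scores.astype(float)
    for target in ("utr_start", "utr_end"):
        col = _pick(raw.columns, colmap[target])
        out[target] = pd.to_numeric(raw[col], errors="coerce") if col is not None else np.nan
    if dialect == "targetscan" and out["utr_start"].notna().any():
        # TargetScan UTR positions are 1-based inclusive
        out["utr_start"] = out["utr_start"] - 1
    invalid = ~out["category"].isin(CATEGORIES)
    if invalid.any():
        raise FormatError(f"invalid site category {out['category'][invalid.idxmax()]!r} in {path}")
    if dialect == "miranda":
        n0 = len(out)
        out = out[out["context_score"] <= mirsvr_cutoff].reset_index(drop=True)
        logger.info("miranda dialect: %d of %d rows pass mirSVR cutoff %.3g", len(out), n0, mirsvr_cutoff)
    return out


def frame_to_records(frame: pd.DataFrame) -> list[SiteRecord]:
    records = []
    for row in frame.itertuples(index=False):
        has_pos = row.utr_start is not None and not pd.isna(row.utr_start)
        records.append(
            SiteRecord(
                gene_id=str(row.gene_id),
                mirna_id=str(row.mirna_id),
                species_id=str(row.species_id),
                category=str(row.category),
                context_score=float(row.context_score),
                utr_start=int(row.utr_start) if has_pos else None,
                utr_end=int(row.utr_end) if has_pos else None,
            )
        )
    return records


def records_to_frame(records: Iterable[SiteRecord]) -> pd.DataFrame:
    rows = [
        (r.gene_id, r.mirna_id, r.species_id, r.category, r.context_score,
         np.nan if r.utr_start is None else r.utr_start,
         np.nan if r.utr_end is None else r.utr_end)
        for r in records
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def parse_site_table(path: str | Path, dialect: str = "generic-tsv", **kwargs) -> list[SiteRecord]:
    """Parse a site table into :class:`SiteRecord` objects (see parse_site_frame)."""
    return frame_to_records(parse_site_frame(path, dialect, **kwargs))


def write_site_table(records: Iterable[SiteRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write sites in the generic-tsv dialect (the round-trip partner of the parser)."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    out = frame.copy()
    for col in ("utr_start", "utr_end"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _parse_bed12(path: str | Path) -> list[GeneAnnotation]:
    names = ["chrom", "start", "end", "name", "score", "strand", "thick_start",
             "thick_end", "rgb", "block_count", "block_sizes", "block_starts"]
    raw = pd.read_csv(path, sep="\t", header=None, names=names, dtype=str, comment="#")
    anns = []
    for row in raw.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        thick_s, thick_e = int(row.thick_start), int(row.thick_end)
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        cds = [(max(s, thick_s), min(e, thick_e)) for s, e in exons if s < thick_e and e > thick_s]
        if row.strand == "+":
            utr3 = [(max(s, thick_e), e) for s, e in exons if e > thick_e]
            tss = start
        else:
            utr3 = [(s, min(e, thick_s)) for s, e in exons if s < thick_s]
            tss = end - 1
        anns.append(GeneAnnotation(
            gene_id=str(row.name), chrom=str(row.chrom), strand=str(row.strand),
            tss=tss, utr3_intervals=utr3, cds_intervals=cds, span=(start, end),
        ))
    return anns


def _parse_gtf_like(path: str | Path) -> list[GeneAnnotation]:
    spans: dict[str, tuple[str, str, int, int]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    utr3: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = parts[:9]
            start, end = int(start1) - 1, int(end1)  # 1-based inclusive -> 0-based half-open
            if start >= end:
                raise FormatError(f"line {lineno}: start >= end after coordinate conversion")
            gene_id = None
            for token in attrs.split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gene_id = token.split(None, 1)[1].strip().strip('"')
            if gene_id is None:
                raise FormatError(f"line {lineno}: missing gene_id attribute")
            if gene_id not in spans and gene_id not in order:
                order.append(gene_id)
            if feature == "transcript":
                spans[gene_id] = (chrom, strand, start, end)
            elif feature == "CDS":
                cds.setdefault(gene_id, []).append((start, end))
            elif feature == "three_prime_utr":
                utr3.setdefault(gene_id, []).append((start, end))
    anns = []
    for gene_id in order:
        if gene_id not in spans:
            raise FormatError(f"gene {gene_id} has no transcript feature")
        chrom, strand, start, end = spans[gene_id]
        tss = start if strand == "+" else end - 1
        anns.append(GeneAnnotation(
            gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
            utr3_intervals=utr3.get(gene_id, []), cds_intervals=cds.get(gene_id, []),
            span=(start, end),
        ))
    return anns


def parse_annotation(path: str | Path, format: Literal["bed12-like", "gtf-like"] = "gtf-like") -> list[GeneAnnotation]:
    """Read gene annotations; all output intervals are 0-based half-open.

    ``gtf-like`` input is 1-based inclusive with transcript / CDS /
    three_prime_utr features carrying a ``gene_id`` attribute. For
    minus-strand genes the TSS is the rightmost transcript base.
    """
    if format == "bed12-like":
        return _parse_bed12(path)
    if format == "gtf-like":
        return _parse_gtf_like(path)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotation(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write annotations in the gtf-like dialect (round-trip partner of the parser)."""
    with open(path, "w") as fh:
        for ann in annotations:
            rows = [("transcript", ann.span[0], ann.span[1])]
            rows += [("CDS", s, e) for s, e in ann.cds_intervals]
            rows += [("three_prime_utr", s, e) for s, e in ann.utr3_intervals]
            for feature, start, end in rows:
                fh.write(
                    f"{ann.chrom}\tmirsites\t{feature}\t{start + 1}\t{end}\t.\t{ann.strand}\t.\t"
                    f'gene_id "{ann.gene_id}";\n'
                )


# ---------------------------------------------------------------------------
# expression / tracks / repeats / gene sets
# ---------------------------------------------------------------------------

def parse_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene_id). Duplicates and ragged rows error."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.index = data.index.astype(str)
    return ExpressionMatrix(data)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def parse_track(path: str | Path) -> ScoreTrack:
    """Read a bedGraph (chrom, start, end, score; no header)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["chrom", "start", "end", "score"])
    return ScoreTrack(frame)


def write_track(track: ScoreTrack, path: str | Path) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False)


_RMSK_ALIASES = {
    "chrom": ("chrom", "genoName"),
    "start": ("start", "genoStart"),
    "end": ("end", "genoEnd"),
    "repeat_class": ("class", "repClass", "repeat_class"),
}


def parse_repeats(path: str | Path) -> list[RepeatAnnotation]:
    """Read repeat annotations (TSV with header; rmsk column names accepted)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = {}
    for target, aliases in _RMSK_ALIASES.items():
        col = _pick(raw.columns, aliases)
        if col is None:
            raise FormatError(f"missing mandatory column {aliases[0]!r} in {path}")
        cols[target] = col
    return [
        RepeatAnnotation(str(r[cols["chrom"]]), int(r[cols["start"]]), int(r[cols["end"]]),
                         str(r[cols["repeat_class"]]))
        for _, r in raw.iterrows()
    ]


def write_repeats(repeats: Iterable[RepeatAnnotation], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.chrom, r.start, r.end, r.repeat_class) for r in repeats],
        columns=["chrom", "start", "end", "class"],
    )
    frame.to_csv(path, sep="\t", index=False)


def parse_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set: one id per line; duplicates collapse silently."""
    members = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                members.add(line)
    return GeneSet(name or Path(path).stem, members)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(gene_set.members):
            fh.write(gene_id + "\n")


def parse_bed_loci(path: str | Path) -> pd.DataFrame:
    """Read a BED file of loci (chrom, start, end, name) into a DataFrame."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"])
    if (frame["start"] >= frame["end"]).any():
        raise FormatError("BED interval with start >= end")
    return frame


def write_bed_loci(loci: pd.DataFrame, path: str | Path) -> None:
    loci[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)
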