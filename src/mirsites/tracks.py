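"""Conservation aggregation, repeat overlap, 3'UTR length and co-localization.

Conservation means are length-weighted over the intersection of the query
intervals with the track's covered bases; uncovered bases are excluded from
the denominator (score tables only cover aligned bases), so a half-covered
interval averages only its covered part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneAnnotation, RepeatAnnotation, ScoreTrack, merge_intervals
from .stats import TestResult, spearman, wilcoxon_rank_sum

logger = logging.getLogger("mirsites")

DEFAULT_REPEAT_CLASSES = frozenset({"LTR", "SINE"})


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def mean_conservation(
    track: ScoreTrack, intervals: Sequence[tuple[int, int]], chrom: str
) -> float | None:
    """Length-weighted mean track score over ``intervals``; None if uncovered."""
    ivs = merge_intervals(intervals)
    starts, ends, scores = track.segments(chrom)
    weighted = 0.0
    covered = 0
    for q_start, q_end in ivs:
        lo = int(np.searchsorted(ends, q_start, side="right"))
        hi = int(np.searchsorted(starts, q_end, side="left"))
        for i in range(lo, hi):
            overlap = min(q_end, ends[i]) - max(q_start, starts[i])
            if overlap > 0:
                weighted += overlap * scores[i]
                covered += overlap
    if covered == 0:
        return None
    return weighted / covered


@dataclass
class ConservationSummary:
    gene_id: str
    utr3_mean: float | None
    cds_mean: float | None
    utr3_len: int
    cds_len: int


def conservation_summaries(
    track: ScoreTrack, annotations: Iterable[GeneAnnotation]
) -> list[ConservationSummary]:
    """Per-gene mean conservation over 3'UTR and CDS intervals."""
    out = []
    for ann in annotations:
        out.append(ConservationSummary(
            ann.gene_id,
            mean_conservation(track, ann.utr3_intervals, ann.chrom) if ann.utr3_intervals else None,
            mean_conservation(track, ann.cds_intervals, ann.chrom) if ann.cds_intervals else None,
            ann.utr3_length,
            ann.cds_length,
        ))
    return out


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

@dataclass
class RepeatFlag:
    gene_id: str
    has_ltr_sine: bool
    overlap_bp: int


def flag_repeat_overlap(
    annotation: GeneAnnotation,
    repeats: Iterable[RepeatAnnotation],
    classes: frozenset[str] | set[str] = DEFAULT_REPEAT_CLASSES,
) -> RepeatFlag:
    """Whether any class-matching repeat overlaps the gene's 3'UTR by >= 1 bp."""
    overlap = 0
    for rep in repeats:
        if rep.repeat_class not in classes or rep.chrom != annotation.chrom:
            continue
        for s, e in annotation.utr3_intervals:
            overlap += max(0, min(e, rep.end) - max(s, rep.start))
    return RepeatFlag(annotation.gene_id, overlap >= 1, overlap)


def repeat_flags(
    annotations: Iterable[GeneAnnotation],
    repeats: Sequence[RepeatAnnotation],
    classes: frozenset[str] | set[str] = DEFAULT_REPEAT_CLASSES,
) -> dict[str, RepeatFlag]:
    by_chrom: dict[str, list[RepeatAnnotation]] = {}
    for rep in repeats:
        if rep.repeat_class in classes:
            by_chrom.setdefault(rep.chrom, []).append(rep)
    return {
        ann.gene_id: flag_repeat_overlap(ann, by_chrom.get(ann.chrom, ()), classes)
        for ann in annotations
    }


def stratified_count_medians(
    counts: Mapping[str, int] | pd.Series,
    flags: Mapping[str, RepeatFlag] | Mapping[str, bool],
    within: Iterable[str] | None = None,
) -> dict:
    """Median distinct-miRNA counts for repeat-flagged vs unflagged genes.

    Restricted to the ``within`` gene set when given (e.g. Q4 only); the
    two-sided Wilcoxon rank-sum p quantifies the difference.
    """
    counts = pd.Series(counts, dtype=float)
    flag_map = {g: (f.has_ltr_sine if isinstance(f, RepeatFlag) else bool(f)) for g, f in flags.items()}
    genes = [g for g in counts.index if g in flag_map]
    if within is not None:
        scope = set(within)
        genes = [g for g in genes if g in scope]
    with_rep = [counts[g] for g in genes if flag_map[g]]
    without_rep = [counts[g] for g in genes if not flag_map[g]]
    if not with_rep or not without_rep:
        raise ValueError("both repeat strata must be nonempty")
    test: TestResult = wilcoxon_rank_sum(with_rep, without_rep)
    return {
        "median_with": float(np.median(with_rep)),
        "median_without": float(np.median(without_rep)),
        "n_with": len(with_rep),
        "n_without": len(without_rep),
        "wilcoxon_p": test.p_value,
    }


# ---------------------------------------------------------------------------
# 3'UTR length
# ---------------------------------------------------------------------------

def utr_length_vs_counts(
    annotations: Iterable[GeneAnnotation], counts: Mapping[str, int] | pd.Series
) -> tuple[pd.DataFrame, float | None]:
    """Per-gene (3'UTR length, distinct-miRNA count) table plus Spearman rho."""
    counts = pd.Series(counts, dtype=float)
    rows = []
    dropped = 0
    for ann in annotations:
        if not ann.utr3_intervals or ann.gene_id not in counts.index:
            dropped += 1
            continue
        rows.append((ann.gene_id, ann.utr3_length, counts[ann.gene_id]))
    if dropped:
        logger.info("utr_length_vs_counts: %d genes without UTR annotation or count dropped", dropped)
    table = pd.DataFrame(rows, columns=["gene_id", "utr3_length", "count"])
    rho = None
    if len(table) >= 3:
        rho = spearman(table["utr3_length"], table["count"])
    return table, rho


# ---------------------------------------------------------------------------
# miRNA co-localization
# ---------------------------------------------------------------------------

@dataclass
class ColocalizationResult:
    pairs: set[tuple[str, str]]  # (mirna_id, gene_id)

    @property
    def n_mirnas(self) -> int:
        return len({m for m, _ in self.pairs})

    @property
    def n_genes(self) -> int:
        return len({g for _, g in self.pairs})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.pairs), columns=["mirna_id", "gene_id"])


def colocalize_mirnas(
    mirna_loci: pd.DataFrame,
    annotations: Iterable[GeneAnnotation],
    window: int = 20_000,
) -> ColocalizationResult:
    """miRNA loci within +/-window of a gene's full span (introns included).

    A pair (m, g) is reported iff the locus interval intersects
    [span_start - window, span_end + window) on the same chromosome, so a
    locus starting exactly ``window`` bases upstream is included.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pairs: set[tuple[str, str]] = set()
    loci_by_chrom = {str(c): sub for c, sub in mirna_loci.groupby("chrom")}
    for ann in annotations:
        sub = loci_by_chrom.get(ann.chrom)
        if sub is None:
            continue
        lo = max(0, ann.span[0] - window)
        hi = ann.span[1] + window
        hit = (sub["start"] < hi) & (sub["end"] > lo)
        for name in sub.loc[hit, "name"]:
            pairs.add((str(name), ann.gene_id))
    return ColocalizationResult(pairs)
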