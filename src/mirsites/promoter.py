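"""Promoter-sequence proxies for intrinsic transcriptional noise.

Two sequence features of the +/-1 kb window around the TSS stand in for
nucleosome occupancy and hence promoter-driven expression noise: the GC
fraction, and the ratio of nucleosome-favoring dinucleotides (GC, CG, GG) to
nucleosome-disfavoring ones (AA, CA, AC). Dinucleotides are counted over all
overlapping length-2 windows; windows containing N are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

from .io import GeneAnnotation

logger = logging.getLogger("mirsites")

FAVORING = frozenset({"GC", "CG", "GG"})
DISFAVORING = frozenset({"AA", "CA", "AC"})


@dataclass
class PromoterFeatures:
    gene_id: str
    gc_fraction: float | None
    fav_count: int
    disfav_count: int

    @property
    def dinuc_ratio(self) -> float | None:
        """favoring/disfavoring count ratio; None (undefined) when disfavoring = 0."""
        if self.disfav_count == 0:
            return None
        return self.fav_count / self.disfav_count


def promoter_window(
    annotation: GeneAnnotation, chrom_length: int, flank: int = 1000
) -> tuple[int, int]:
    """The [tss - flank, tss + flank) interval, clipped to the chromosome."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if not 0 <= annotation.tss < chrom_length:
        raise ValueError(
            f"TSS {annotation.tss} of {annotation.gene_id} outside chromosome of length {chrom_length}"
        )
    return max(0, annotation.tss - flank), min(chrom_length, annotation.tss + flank)


def gc_content(sequence: str) -> float | None:
    """(G + C) / (A + C + G + T); N bases are excluded. None for all-N input."""
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return None
    return (seq.count("G") + seq.count("C")) / acgt


def dinucleotide_counts(sequence: str) -> tuple[int, int]:
    """(favoring, disfavoring) dinucleotide counts over overlapping windows."""
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    fav = disfav = 0
    for i in range(len(seq) - 1):
        dinuc = seq[i : i + 2]
        if "N" in dinuc:
            continue
        if dinuc in FAVORING:
            fav += 1
        elif dinuc in DISFAVORING:
            disfav += 1
    return fav, disfav


def promoter_features(gene_id: str, sequence: str) -> PromoterFeatures:
    fav, disfav = dinucleotide_counts(sequence)
    return PromoterFeatures(gene_id, gc_content(sequence), fav, disfav)


def features_from_sequences(sequences: Mapping[str, str]) -> list[PromoterFeatures]:
    """Features for promoter sequences keyed by gene id (already sense-oriented)."""
    return [promoter_features(g, s) for g, s in sequences.items()]


def extract_promoters(
    genome: Mapping[str, str],
    annotations: Iterable[GeneAnnotation],
    flank: int = 1000,
    strand_mode: str = "sense",
) -> dict[str, str]:
    """Cut +/-flank promoter windows out of a genome, keyed by gene id.

    With ``strand_mode="sense"`` (default) minus-strand promoters are
    reverse-complemented so that counting happens on the transcribed strand;
    ``strand_mode="plus"`` keeps the reference strand as stored.
    """
    if strand_mode not in ("sense", "plus"):
        raise ValueError(f"strand_mode must be 'sense' or 'plus', got {strand_mode!r}")
    out: dict[str, str] = {}
    for ann in annotations:
        if ann.chrom not in genome:
            logger.info("chromosome %s of %s not in genome; skipped", ann.chrom, ann.gene_id)
            continue
        chrom_seq = genome[ann.chrom]
        start, end = promoter_window(ann, len(chrom_seq), flank)
        seq = chrom_seq[start:end]
        if strand_mode == "sense" and ann.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[ann.gene_id] = seq
    return out


def features_table(features: Iterable[PromoterFeatures]) -> pd.DataFrame:
    """Per-gene TSV-ready table; undefined values become NaN."""
    rows = [
        (f.gene_id,
         float("nan") if f.gc_fraction is None else f.gc_fraction,
         f.fav_count, f.disfav_count,
         float("nan") if f.dinuc_ratio is None else f.dinuc_ratio)
        for f in features
    ]
    return pd.DataFrame(rows, columns=["gene_id", "gc_fraction", "fav", "disfav", "ratio"])
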