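"""Cross-species normalized site counts and distance-ordered trajectories.

Species carry different numbers of annotated miRNAs, so raw distinct-miRNA
counts are not comparable across species; each gene's count is normalized to
the mean count over all genes with an orthologous 3'UTR in that species, which
forces the per-species mean of normalized counts to 1. Gene groups (the
reference quartiles) are fixed on the reference species and propagated through
the ortholog map; the trend of a group's mean normalized count against the
distance rank is summarized by a Spearman correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .interaction import InteractionMatrix
from .stats import spearman

logger = logging.getLogger("mirsites")


@dataclass
class SpeciesPanel:
    """Ordered species matrices with distance ranks (reference has rank 0)."""

    reference_species: str
    species: list[tuple[str, int]]  # (species_id, distance_rank)
    matrices: dict[str, InteractionMatrix]
    #: (reference gene id, species id) -> gene id in that species; identity when empty
    ortholog_map: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = [r for _, r in self.species]
        if len(set(ranks)) != len(ranks):
            raise ValueError("distance ranks must be unique")
        by_id = dict(self.species)
        if by_id.get(self.reference_species) != 0:
            raise ValueError("reference species must have distance rank 0")
        missing = [s for s, _ in self.species if s not in self.matrices]
        if missing:
            raise ValueError(f"species without a matrix: {missing}")
        self.species = sorted(self.species, key=lambda sr: sr[1])

    def ortholog(self, ref_gene: str, species_id: str) -> str:
        if not self.ortholog_map:
            return ref_gene
        return self.ortholog_map.get((ref_gene, species_id), ref_gene if species_id == self.reference_species else None)


def normalized_counts(matrix: InteractionMatrix, nonzero_only: bool = False) -> pd.Series:
    """Per-gene distinct-miRNA count divided by the species' mean count.

    The normalization mean is over *all* genes in the matrix (genes with an
    orthologous 3'UTR), so the output averages to 1; ``nonzero_only`` divides
    by the mean over genes with >= 1 site instead.
    """
    counts = matrix.counts.astype(float)
    denom_counts = counts[counts > 0] if nonzero_only else counts
    if len(denom_counts) == 0 or denom_counts.mean() == 0:
        raise ValueError(f"species {matrix.species_id}: all-zero matrix, cannot normalize")
    return counts / denom_counts.mean()


def group_trajectory(
    panel: SpeciesPanel,
    gene_group: Iterable[str],
    nonzero_only: bool = False,
) -> pd.DataFrame:
    """Mean normalized count of a reference gene group in each species.

    Returned ordered by distance rank with columns (species_id, distance_rank,
    mean_normalized, n). Group members without an ortholog in a species are
    excluded from that species' mean (counts logged); a species where the whole
    group is absent gets NaN.
    """
    group = sorted(set(gene_group))
    rows = []
    for species_id, rank in panel.species:
        norm = normalized_counts(panel.matrices[species_id], nonzero_only)
        members = [panel.ortholog(g, species_id) for g in group]
        members = [m for m in members if m is not None and m in norm.index]
        if len(members) < len(group):
            logger.info("species %s: %d of %d group members missing", species_id,
                        len(group) - len(members), len(group))
        if members:
            rows.append((species_id, rank, float(norm.loc[members].mean()), len(members)))
        else:
            rows.append((species_id, rank, float("nan"), 0))
    return pd.DataFrame(rows, columns=["species_id", "distance_rank", "mean_normalized", "n"])


def trend_statistic(trajectory: pd.DataFrame) -> float | None:
    """Spearman correlation of (distance rank, group mean); +1 = increase with distance."""
    valid = trajectory.dropna(subset=["mean_normalized"])
    if len(valid) < 3:
        raise ValueError("trend statistic needs >= 3 non-missing species points")
    return spearman(valid["distance_rank"], valid["mean_normalized"])


def read_ortholog_map(path: str | Path) -> dict[tuple[str, str], str]:
    """TSV {ref_gene_id, species_id, gene_id} -> mapping keyed by (ref gene, species)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"ref_gene_id", "species_id", "gene_id"}
    if not required <= set(frame.columns):
        raise ValueError(f"ortholog map needs columns {sorted(required)}")
    return {
        (row.ref_gene_id, row.species_id): row.gene_id
        for row in frame.itertuples(index=False)
    }


def read_species_config(path: str | Path) -> tuple[str, list[tuple[str, int]]]:
    """YAML with reference_species and an ordered species: [{id, distance_rank}] list."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    species = [(str(s["id"]), int(s["distance_rank"])) for s in cfg["species"]]
    return str(cfg["reference_species"]), species
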