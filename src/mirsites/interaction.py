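"""Binary gene x miRNA interaction matrices and gene stratification.

The per-gene statistic everywhere downstream is the *distinct-miRNA count*:
several sites for one miRNA in a 3'UTR collapse to a single incidence, while
one site shared by several miRNAs counts once per miRNA. Genes are stratified
into quartile groups (Q1 below the 25th percentile of counts, Q4 above the
75th) and into 20 equal-size rank bins (vigintiles) for trend plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CONSERVED, NONCONSERVED, SiteRecord, records_to_frame

logger = logging.getLogger("mirsites")


def _as_frame(records: Iterable[SiteRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


# ---------------------------------------------------------------------------
# score-percentile filtering
# ---------------------------------------------------------------------------

def filter_sites_by_percentile(
    records: Iterable[SiteRecord] | pd.DataFrame,
    pct_conserved: float = 50.0,
    pct_nonconserved: float = 75.0,
    direction: str = "strength",
) -> pd.DataFrame:
    """Keep only the strongest predicted sites, per category independently.

    Weak sites are removed by thresholding at the given percentile of score
    *strength* (the negated context score, so that larger = stronger predicted
    repression): a site survives iff its strength is >= the category's
    percentile threshold, ties at the threshold kept. The threshold is the
    higher-interpolation quantile of the observed strengths, so with pct=50
    the strongest half is retained exactly on distinct scores.

    ``direction="raw"`` thresholds the context score as printed instead, for
    score conventions where larger raw values mean stronger sites.
    """
    frame = _as_frame(records)
    if direction not in ("strength", "raw"):
        raise ValueError(f"direction must be 'strength' or 'raw', got {direction!r}")
    for pct in (pct_conserved, pct_nonconserved):
        if not 0 <= pct <= 100:
            raise ValueError(f"percentile out of [0, 100]: {pct}")
    if frame.empty:
        return frame.copy()
    keep = np.zeros(len(frame), dtype=bool)
    for category, pct in ((CONSERVED, pct_conserved), (NONCONSERVED, pct_nonconserved)):
        mask = (frame["category"] == category).to_numpy()
        if not mask.any():
            logger.info("no %s sites; percentile filter is a no-op for that category", category)
            continue
        strength = frame.loc[mask, "context_score"].to_numpy(dtype=float)
        if direction == "strength":
            strength = -strength
        threshold = np.quantile(strength, pct / 100.0, method="higher")
        kept = strength >= threshold
        keep[np.flatnonzero(mask)[kept]] = True
        logger.info("category %s: %d of %d sites pass the %.0fth strength percentile",
                    category, int(kept.sum()), int(mask.sum()), pct)
    other = ~frame["category"].isin((CONSERVED, NONCONSERVED)).to_numpy()
    if other.any():
        raise ValueError("records contain categories outside the conserved/nonconserved enum")
    return frame[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# binary matrix
# ---------------------------------------------------------------------------

@dataclass
class InteractionMatrix:
    """Binary gene x miRNA incidence for one species, with per-gene counts."""

    species_id: str
    incidence: pd.DataFrame  # index: gene_id, columns: mirna_id, int8 entries in {0,1}

    def __post_init__(self) -> None:
        if self.incidence.index.has_duplicates:
            raise ValueError("duplicate gene ids in incidence matrix")
        vals = self.incidence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.incidence.columns)

    @property
    def counts(self) -> pd.Series:
        """Distinct-miRNA count per gene (row sums of the incidence)."""
        return self.incidence.sum(axis=1).astype(int)

    def to_records(self) -> pd.DataFrame:
        """Re-expand incidence into one generic site row per (gene, miRNA) pair."""
        genes, mirnas = np.nonzero(self.incidence.to_numpy())
        return pd.DataFrame({
            "gene_id": self.incidence.index.to_numpy()[genes],
            "mirna_id": self.incidence.columns.to_numpy()[mirnas],
            "species_id": self.species_id,
            "category": CONSERVED,
            "context_score": -1.0,
            "utr_start": np.nan,
            "utr_end": np.nan,
        })

    def write(self, path: str | Path, counts_path: str | Path | None = None) -> None:
        self.incidence.to_csv(path, sep="\t", index_label="gene_id")
        if counts_path is not None:
            self.counts.rename("distinct_mirnas").to_csv(counts_path, sep="\t", index_label="gene_id")


def build_binary_matrix(
    records: Iterable[SiteRecord] | pd.DataFrame,
    species_id: str,
    gene_universe: Sequence[str] | None = None,
    mirna_universe: Sequence[str] | None = None,
) -> InteractionMatrix:
    """Collapse site records into a binary incidence matrix.

    incidence[g, m] = 1 iff at least one record links gene g to miRNA m.
    Genes of ``gene_universe`` without any site get an all-zero row (they
    still take part in stratification).
    """
    frame = _as_frame(records)
    if not frame.empty:
        species = frame["species_id"].unique()
        if len(species) > 1 or (len(species) == 1 and species[0] != species_id):
            raise ValueError(f"records carry species {sorted(species)}, expected {species_id!r}")
    pairs = frame[["gene_id", "mirna_id"]].drop_duplicates()
    genes = pd.Index(sorted(set(pairs["gene_id"]) | set(gene_universe or [])), name="gene_id")
    mirnas = pd.Index(sorted(set(pairs["mirna_id"]) | set(mirna_universe or [])), name="mirna_id")
    inc = np.zeros((len(genes), len(mirnas)), dtype=np.int8)
    inc[genes.get_indexer(pairs["gene_id"]), mirnas.get_indexer(pairs["mirna_id"])] = 1
    return InteractionMatrix(species_id, pd.DataFrame(inc, index=genes, columns=mirnas))


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def nearest_rank_percentile(values: Sequence[float], pct: float) -> float:
    """Classic nearest-rank percentile: the value at 1-based rank ceil(pct/100 * n)."""
    arr = np.sort(np.asarray(values, dtype=float))
    if len(arr) == 0:
        raise ValueError("empty input")
    rank = int(np.ceil(pct / 100.0 * len(arr)))
    return float(arr[max(rank, 1) - 1])


@dataclass
class StratifiedGenes:
    """Quartile-group and vigintile assignments on the distinct-miRNA counts."""

    q25_threshold: float
    q75_threshold: float
    q1_set: set[str]
    q4_set: set[str]
    vigintile: dict[str, int] = field(default_factory=dict)


def assign_quartile_groups(counts: Mapping[str, int] | pd.Series) -> StratifiedGenes:
    """Split genes at the nearest-rank 25th/75th count percentiles.

    Q1 holds genes with counts strictly below the 25th percentile, Q4 genes
    strictly above the 75th (the "less than" / "more than" reading). With
    constant counts both sets are empty and a warning is logged.
    """
    counts = pd.Series(counts, dtype=float)
    if len(counts) < 8:
        raise ValueError("quartile stratification needs >= 8 genes")
    q25 = nearest_rank_percentile(counts.to_numpy(), 25.0)
    q75 = nearest_rank_percentile(counts.to_numpy(), 75.0)
    q1 = set(counts.index[counts < q25])
    q4 = set(counts.index[counts > q75])
    if counts.nunique() == 1:
        logger.warning("constant distinct-miRNA counts: quartile groups are empty")
    return StratifiedGenes(q25, q75, q1, q4)


def assign_vigintiles(counts: Mapping[str, int] | pd.Series, n_bins: int = 20) -> dict[str, int]:
    """Rank genes by count and split into ``n_bins`` contiguous bins (1..20).

    Bin sizes differ by at most one (earlier bins take the remainder); ties in
    counts are broken by gene id so the assignment is deterministic.
    """
    counts = pd.Series(counts)
    if len(counts) < n_bins:
        raise ValueError(f"vigintile assignment needs >= {n_bins} genes, got {len(counts)}")
    order = sorted(counts.index, key=lambda g: (counts[g], g))
    sizes = np.full(n_bins, len(order) // n_bins, dtype=int)
    sizes[: len(order) % n_bins] += 1
    assignment: dict[str, int] = {}
    pos = 0
    for bin_index, size in enumerate(sizes, start=1):
        for gene_id in order[pos : pos + size]:
            assignment[gene_id] = bin_index
        pos += size
    return assignment


def binned_means(
    vigintile_map: Mapping[str, int],
    x_per_gene: Mapping[str, float] | pd.Series,
    y_per_gene: Mapping[str, float] | pd.Series,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Arithmetic means of x and y within each vigintile, ordered by bin.

    Genes missing either value are excluded from that bin's means (count
    logged); a bin with no complete gene gets NaN means and n = 0.
    """
    x = pd.Series(x_per_gene, dtype=float)
    y = pd.Series(y_per_gene, dtype=float)
    rows = []
    n_dropped = 0
    bins = pd.Series(vigintile_map)
    for bin_index in range(1, n_bins + 1):
        genes = bins.index[bins == bin_index]
        sub_x = x.reindex(genes)
        sub_y = y.reindex(genes)
        complete = sub_x.notna() & sub_y.notna()
        n_dropped += int((~complete).sum())
        if complete.any():
            rows.append((bin_index, float(sub_x[complete].mean()),
                         float(sub_y[complete].mean()), int(complete.sum())))
        else:
            rows.append((bin_index, np.nan, np.nan, 0))
    if n_dropped:
        logger.info("binned_means: %d genes lacked a value and were excluded", n_dropped)
    return pd.DataFrame(rows, columns=["bin", "mean_x", "mean_y", "n"])
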