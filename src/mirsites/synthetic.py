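"""Seeded synthetic inputs with planted class structure.

The generator emulates the study conditions end-to-end: a panel of genes on
one synthetic chromosome, a quarter of them "regulatory", with a shared latent
per-gene noise level that drives promoter GC content, expression variability
and (together with the class) the 3'UTR site rate — so site counts, CV and GC
are mutually correlated through class and noise without asserting causality.

Cross-species tables treat the reference species as the *derived* state of a
selective-inclusion history: a species at distance rank d retains ancestral
sites that the reference lineage's non-regulatory genes shed (extra distinct
miRNAs at rate ``gain_rate`` per rank) and lacks sites the reference lineage's
regulatory genes acquired (per-site survival exp(-loss_rate * d)). Group mean
normalized counts therefore rise with distance for low-count genes and fall
for high-count genes. Species diverge independently from the reference (star
topology); distances enter only as ranks.

All outputs are byte-identical across runs with the same config: every
generator derives its own stream from (seed, stream id).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    RepeatAnnotation,
    ScoreTrack,
    write_annotation,
    write_bed_loci,
    write_expression,
    write_gene_set,
    write_repeats,
    write_site_table,
    write_track,
)

CHROM = "chrS1"

# stream ids for per-generator RNGs (never reuse across generators)
_STREAM_LABELS = 1
_STREAM_GENOME = 2
_STREAM_SITES = 3
_STREAM_EXPRESSION = 4
_STREAM_TRACKS = 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters encoding the planted relationships.

    Site rates are pre-filter means of distinct miRNAs per gene; the planted
    per-gene rate is ``rate_class * (1 + site_noise_slope * (noise_g - 0.5))``
    with the latent noise drawn uniformly in (0.05, 0.45) for non-regulatory
    and (0.55, 0.95) for regulatory genes, so the site count correlates with
    noise within class as well as between classes.
    ``gain_rate``/``loss_rate`` are per distance-rank unit (see the module
    docstring for their orientation).
    """

    seed: int = 0
    n_genes: int = 2000
    n_mirnas: int = 300
    n_samples: int = 100
    n_species: int = 10
    frac_regulatory: float = 0.25
    site_rate_reg: float = 55.0
    site_rate_nonreg: float = 12.0
    site_noise_slope: float = 1.0
    noise_gc_slope: float = 0.3
    cv_base: float = 0.2
    cv_slope: float = 0.8
    cons_utr_reg: float = 0.8
    cons_utr_nonreg: float = 0.4
    cons_cds_reg: float = 0.5
    cons_cds_nonreg: float = 0.8
    gain_rate: float = 0.15
    loss_rate: float = 0.12
    repeat_prob_reg: float = 0.6
    repeat_prob_nonreg: float = 0.17
    coloc_prob_reg: float = 0.1
    promoter_flank: int = 1000
    chrom_length: int | None = None  # cap; auto-sized when None

    def __post_init__(self) -> None:
        for name in ("frac_regulatory", "noise_gc_slope", "repeat_prob_reg",
                     "repeat_prob_nonreg", "coloc_prob_reg", "cons_utr_reg",
                     "cons_utr_nonreg", "cons_cds_reg", "cons_cds_nonreg"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.frac_regulatory < 1:
            raise ValueError("frac_regulatory must be in (0, 1)")
        for name in ("site_rate_reg", "site_rate_nonreg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("gain_rate", "loss_rate", "cv_base"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return dataclasses.replace(self, seed=seed)

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """All coupling parameters off: class and noise drive nothing."""
        defaults = dict(
            seed=seed,
            site_rate_reg=25.0, site_rate_nonreg=25.0,
            site_noise_slope=0.0, noise_gc_slope=0.0, cv_slope=0.0,
            gain_rate=0.0, loss_rate=0.0,
            cons_utr_reg=0.5, cons_utr_nonreg=0.5,
            cons_cds_reg=0.5, cons_cds_nonreg=0.5,
            repeat_prob_reg=0.3, repeat_prob_nonreg=0.3,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def gene_ids(config: SyntheticConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def mirna_ids(config: SyntheticConfig) -> list[str]:
    width = len(str(config.n_mirnas))
    return [f"miR-{i:0{width}d}" for i in range(1, config.n_mirnas + 1)]


def species_ladder(config: SyntheticConfig) -> list[tuple[str, int]]:
    """Reference species 'ref' at rank 0, then sp1..sp{k-1} at ranks 1..k-1."""
    return [("ref", 0)] + [(f"sp{d}", d) for d in range(1, config.n_species)]


def plant_gene_classes(config: SyntheticConfig) -> tuple[pd.Series, pd.Series]:
    """(labels, noise): regulatory flags (deterministic count) and latent noise.

    Exactly round(frac_regulatory * n_genes) genes are regulatory; the latent
    noise is uniform in (0.55, 0.95) for regulatory and (0.05, 0.45) for
    non-regulatory genes.
    """
    rng = _rng(config, _STREAM_LABELS)
    genes = gene_ids(config)
    n_reg = int(round(config.frac_regulatory * config.n_genes))
    flags = np.zeros(config.n_genes, dtype=bool)
    flags[rng.permutation(config.n_genes)[:n_reg]] = True
    labels = pd.Series(flags, index=genes, name="regulatory")
    u = rng.uniform(0.05, 0.45, size=config.n_genes)
    noise = pd.Series(np.where(flags, u + 0.5, u), index=genes, name="noise")
    return labels, noise


# ---------------------------------------------------------------------------
# genome, annotations, promoters
# ---------------------------------------------------------------------------

def generate_genome_and_annotations(
    config: SyntheticConfig, labels: pd.Series, noise: pd.Series
) -> tuple[list[GeneAnnotation], dict[str, str], dict[str, int]]:
    """Non-overlapping gene models on one chromosome plus sense-strand promoters.

    Each gene carries one CDS interval (~1.5 kb) and one 3'UTR interval at its
    3' end, drawn longer on average for regulatory genes (log-normal, means
    ~1.2 kb vs ~0.6 kb). The promoter sequence spans 2 * promoter_flank bases
    with per-base GC probability 0.4 + noise_gc_slope * noise_g.
    """
    if config.n_genes < 40:
        raise ValueError("need >= 40 genes for quartile/vigintile stratification")
    rng = _rng(config, _STREAM_GENOME)
    genes = gene_ids(config)
    annotations: list[GeneAnnotation] = []
    promoters: dict[str, str] = {}
    cursor = config.promoter_flank + 100
    bases_strong = np.array(list("GC"))
    bases_weak = np.array(list("AT"))
    window = 2 * config.promoter_flank
    for gene_id in genes:
        cursor += int(rng.integers(2000, 5001))
        strand = "+" if rng.random() < 0.5 else "-"
        cds_len = int(np.clip(rng.lognormal(np.log(1500), 0.3), 300, 8000))
        utr_mean = 1200.0 if labels[gene_id] else 600.0
        utr_len = int(np.clip(rng.lognormal(np.log(utr_mean), 0.5), 60, 12000))
        start = cursor
        if strand == "+":
            cds = (start, start + cds_len)
            utr3 = (cds[1], cds[1] + utr_len)
            span = (start, utr3[1])
            tss = start
        else:
            utr3 = (start, start + utr_len)
            cds = (utr3[1], utr3[1] + cds_len)
            span = (start, cds[1])
            tss = span[1] - 1
        cursor = span[1]
        annotations.append(GeneAnnotation(gene_id, CHROM, strand, tss,
                                          [utr3], [cds], span))
        gc_p = 0.4 + config.noise_gc_slope * noise[gene_id]
        strong = rng.random(window) < gc_p
        picks = rng.integers(0, 2, size=window)
        seq = np.where(strong, bases_strong[picks], bases_weak[picks])
        promoters[gene_id] = "".join(seq)
    # tail reserved for background miRNA loci placed away from any gene
    chrom_length = cursor + 300_000 + 30_000 * max(10, config.n_genes // 100)
    if config.chrom_length is not None:
        if config.chrom_length < chrom_length:
            raise ValueError(
                f"genes do not fit in chrom_length={config.chrom_length}; "
                f"need >= {chrom_length} (use a larger chromosome)"
            )
        chrom_length = config.chrom_length
    return annotations, promoters, {CHROM: chrom_length}


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

def _score_frame(rng: np.random.Generator, pairs: pd.DataFrame, species_id: str) -> pd.DataFrame:
    """Attach duplicates, categories and context scores to (gene, miRNA) pairs."""
    n_extra = rng.poisson(0.3 * len(pairs))
    if n_extra and len(pairs):
        dup_idx = rng.integers(0, len(pairs), size=n_extra)
        pairs = pd.concat([pairs, pairs.iloc[dup_idx]], ignore_index=True)
    n = len(pairs)
    out = pairs.copy()
    out["species_id"] = species_id
    out["category"] = np.where(rng.random(n) < 0.7, "conserved", "nonconserved")
    out["context_score"] = -np.round(0.02 + rng.gamma(2.0, 0.12, size=n), 4)
    out["utr_start"] = np.nan
    out["utr_end"] = np.nan
    return out


def generate_sites(
    config: SyntheticConfig, labels: pd.Series, noise: pd.Series
) -> tuple[dict[str, pd.DataFrame], dict[tuple[str, str], str]]:
    """Per-species site tables (generic columns) plus an identity ortholog map.

    Reference gene g gets Poisson(rate_class * (1 + site_noise_slope *
    (noise_g - 0.5))) distinct miRNAs with random duplicate records. A species at rank d keeps each
    regulatory-gene site with probability exp(-loss_rate * d) and adds
    Poisson(gain_rate * d) extra distinct miRNAs to each non-regulatory gene.
    """
    rng = _rng(config, _STREAM_SITES)
    genes = np.array(gene_ids(config))
    mirnas = np.array(mirna_ids(config))
    reg = labels.reindex(genes).to_numpy()
    rates = np.where(reg, config.site_rate_reg, config.site_rate_nonreg)
    rates = rates * (1.0 + config.site_noise_slope * (noise.reindex(genes).to_numpy() - 0.5))
    k = np.minimum(rng.poisson(rates), config.n_mirnas)
    ref_gene_col = np.repeat(genes, k)
    ref_mirna_col = np.concatenate(
        [rng.choice(mirnas, size=kk, replace=False) for kk in k]
    ) if k.sum() else np.empty(0, dtype=mirnas.dtype)
    ref_pairs = pd.DataFrame({"gene_id": ref_gene_col, "mirna_id": ref_mirna_col})
    if ref_pairs.empty:
        raise ValueError("site rates produced an empty reference matrix")

    tables: dict[str, pd.DataFrame] = {}
    ortholog_map: dict[tuple[str, str], str] = {}
    is_reg_pair = labels.reindex(ref_pairs["gene_id"]).to_numpy()
    nonreg_genes = genes[~reg]
    for species_id, rank in species_ladder(config):
        if rank == 0:
            pairs = ref_pairs
        else:
            survive = np.ones(len(ref_pairs), dtype=bool)
            if config.loss_rate > 0:
                p_keep = np.exp(-config.loss_rate * rank)
                survive[is_reg_pair] = rng.random(int(is_reg_pair.sum())) < p_keep
            pairs = ref_pairs[survive]
            gains = rng.poisson(config.gain_rate * rank, size=len(nonreg_genes))
            if gains.sum():
                gain_gene = np.repeat(nonreg_genes, gains)
                gain_mirna = mirnas[rng.integers(0, config.n_mirnas, size=int(gains.sum()))]
                pairs = pd.concat(
                    [pairs, pd.DataFrame({"gene_id": gain_gene, "mirna_id": gain_mirna})],
                    ignore_index=True,
                )
            pairs = pairs.drop_duplicates(ignore_index=True)
        table = _score_frame(rng, pairs.reset_index(drop=True), species_id)
        if table.empty:
            raise ValueError(f"species {species_id}: rates produced an empty matrix")
        tables[species_id] = table
        for g in genes:
            ortholog_map[(g, species_id)] = g
    return tables, ortholog_map


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: SyntheticConfig, labels: pd.Series, noise: pd.Series
) -> ExpressionMatrix:
    """Log-normal genes x samples intensities with planted per-gene sigma.

    sigma_g = cv_base + cv_slope * noise_g on the log scale; the log-mean is
    uniform in [3, 7], so all intensities are positive.
    """
    if config.n_samples < 10:
        raise ValueError("need >= 10 samples")
    rng = _rng(config, _STREAM_EXPRESSION)
    genes = gene_ids(config)
    sigma = config.cv_base + config.cv_slope * noise.reindex(genes).to_numpy()
    if (sigma < 0).any():
        raise ValueError("planted sigma must be >= 0 for every gene")
    mu = rng.uniform(3.0, 7.0, size=config.n_genes)
    values = rng.lognormal(mean=mu[:, None], sigma=np.maximum(sigma, 1e-12)[:, None],
                           size=(config.n_genes, config.n_samples))
    samples = [f"s{j:03d}" for j in range(1, config.n_samples + 1)]
    return ExpressionMatrix(pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                                         columns=samples))


# ---------------------------------------------------------------------------
# tracks, repeats, miRNA loci
# ---------------------------------------------------------------------------

def generate_tracks_and_repeats(
    config: SyntheticConfig,
    annotations: list[GeneAnnotation],
    labels: pd.Series,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[ScoreTrack, list[RepeatAnnotation], pd.DataFrame]:
    """Conservation track, LTR/SINE repeats and miRNA loci with planted class bias.

    Conservation is drawn per ~50 bp segment around the class mean (sd 0.08,
    clipped to [0, 1]) over UTR and CDS intervals only; other bases stay
    uncovered. Repeats of length ~150 bp are dropped into 3'UTRs with
    class-dependent probability (plus LINE decoys). One miRNA locus lands
    inside a regulatory gene's span with probability coloc_prob_reg;
    background loci sit in the gene-free chromosome tail.
    """
    rng = _rng(config, _STREAM_TRACKS)
    seg_rows = []
    repeats: list[RepeatAnnotation] = []
    loci_rows = []
    n_loci = 0
    for ann in annotations:
        is_reg = bool(labels[ann.gene_id])
        for intervals, mean in (
            (ann.utr3_intervals, config.cons_utr_reg if is_reg else config.cons_utr_nonreg),
            (ann.cds_intervals, config.cons_cds_reg if is_reg else config.cons_cds_nonreg),
        ):
            for s, e in intervals:
                edges = np.arange(s, e, 50)
                ends = np.minimum(edges + 50, e)
                scores = np.clip(rng.normal(mean, 0.08, size=len(edges)), 0.0, 1.0)
                seg_rows.append(pd.DataFrame(
                    {"chrom": ann.chrom, "start": edges, "end": ends, "score": scores}))
        p_rep = config.repeat_prob_reg if is_reg else config.repeat_prob_nonreg
        utr_s, utr_e = ann.utr3_intervals[0]
        if utr_e - utr_s > 40 and rng.random() < p_rep:
            rep_len = min(150, (utr_e - utr_s) - 10)
            offset = int(rng.integers(utr_s, utr_e - rep_len + 1))
            rep_class = "LTR" if rng.random() < 0.5 else "SINE"
            repeats.append(RepeatAnnotation(ann.chrom, offset, offset + rep_len, rep_class))
        if rng.random() < 0.1:  # decoy class, must not flag
            repeats.append(RepeatAnnotation(ann.chrom, ann.span[0], ann.span[0] + 120, "LINE"))
        if is_reg and rng.random() < config.coloc_prob_reg:
            pos = int(rng.integers(ann.span[0], ann.span[1] - 80))
            n_loci += 1
            loci_rows.append((ann.chrom, pos, pos + 80, f"mir-syn-{n_loci:03d}"))
    last_end = max(ann.span[1] for ann in annotations)
    for i in range(max(10, config.n_genes // 100)):
        pos = last_end + 100_000 + 30_000 * i
        n_loci += 1
        loci_rows.append((CHROM, pos, pos + 80, f"mir-syn-{n_loci:03d}"))
    track = ScoreTrack(pd.concat(seg_rows, ignore_index=True))
    loci = pd.DataFrame(loci_rows, columns=["chrom", "start", "end", "name"])
    if chrom_sizes is not None and (loci["end"] > chrom_sizes[CHROM]).any():
        raise ValueError("background loci exceed the chromosome; enlarge chrom_length")
    return track, repeats, loci


# ---------------------------------------------------------------------------
# full dataset / bundle on disk
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    labels: pd.Series
    noise: pd.Series
    annotations: list[GeneAnnotation]
    promoters: dict[str, str]
    chrom_sizes: dict[str, int]
    site_tables: dict[str, pd.DataFrame]
    ortholog_map: dict[tuple[str, str], str]
    species: list[tuple[str, int]]
    expression: ExpressionMatrix
    track: ScoreTrack
    repeats: list[RepeatAnnotation]
    mirna_loci: pd.DataFrame

    @property
    def tf_set(self) -> GeneSet:
        """The planted regulatory genes, exported as the TF-like gene set."""
        return GeneSet("tf_genes", set(self.labels.index[self.labels]))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """All input types in memory, mutually consistent, fully seeded."""
    labels, noise = plant_gene_classes(config)
    annotations, promoters, chrom_sizes = generate_genome_and_annotations(config, labels, noise)
    site_tables, ortholog_map = generate_sites(config, labels, noise)
    expression = generate_expression(config, labels, noise)
    track, repeats, loci = generate_tracks_and_repeats(config, annotations, labels, chrom_sizes)
    return SyntheticDataset(
        config=config, labels=labels, noise=noise, annotations=annotations,
        promoters=promoters, chrom_sizes=chrom_sizes, site_tables=site_tables,
        ortholog_map=ortholog_map, species=species_ladder(config),
        expression=expression, track=track, repeats=repeats, mirna_loci=loci,
    )


def write_bundle(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the complete input bundle and return a manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    site_paths = {}
    for species_id, table in dataset.site_tables.items():
        p = outdir / f"sites_{species_id}.tsv"
        write_site_table(table, p)
        site_paths[species_id] = str(p)
    manifest["sites"] = site_paths

    p = outdir / "species.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump({
            "reference_species": "ref",
            "species": [{"id": s, "distance_rank": r} for s, r in dataset.species],
        }, fh, sort_keys=False)
    manifest["species_config"] = str(p)

    p = outdir / "orthologs.tsv"
    pd.DataFrame(
        [(g, s, t) for (g, s), t in sorted(dataset.ortholog_map.items())],
        columns=["ref_gene_id", "species_id", "gene_id"],
    ).to_csv(p, sep="\t", index=False)
    manifest["ortholog_map"] = str(p)

    p = outdir / "expression.tsv"
    write_expression(dataset.expression, p)
    manifest["expression"] = str(p)

    p = outdir / "promoters.fasta"
    with open(p, "w") as fh:
        for gene_id in sorted(dataset.promoters):
            seq = dataset.promoters[gene_id]
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    manifest["promoters"] = str(p)

    p = outdir / "annotations.gtf"
    write_annotation(dataset.annotations, p)
    manifest["annotations"] = str(p)

    p = outdir / "chrom.sizes"
    with open(p, "w") as fh:
        for chrom, size in sorted(dataset.chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")
    manifest["chrom_sizes"] = str(p)

    p = outdir / "conservation.bedgraph"
    write_track(dataset.track, p)
    manifest["conservation"] = str(p)

    p = outdir / "repeats.tsv"
    write_repeats(dataset.repeats, p)
    manifest["repeats"] = str(p)

    p = outdir / "mirna_loci.bed"
    write_bed_loci(dataset.mirna_loci, p)
    manifest["mirna_loci"] = str(p)

    p = outdir / "tf_genes.txt"
    write_gene_set(dataset.tf_set, p)
    manifest["tf_set"] = str(p)

    p = outdir / "labels.tsv"
    pd.DataFrame({
        "gene_id": dataset.labels.index,
        "regulatory": dataset.labels.to_numpy().astype(int),
        "noise": dataset.noise.reindex(dataset.labels.index).to_numpy(),
    }).to_csv(p, sep="\t", index=False)
    manifest["labels"] = str(p)

    return manifest
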