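"""Stage orchestration: run the full analysis from a flat config file.

Stages run in dependency order (matrix -> stratify -> promoter / expression /
tracks -> gene-set tests -> cross-species); every stage writes its table under
``outdir`` and contributes to one machine-readable report. Stages whose inputs
are absent are recorded as SKIPPED, never silently dropped, and each filter
logs records in/out so dropped-gene accounting is visible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import interaction, io, promoter, species, stats, tracks, variability

logger = logging.getLogger("mirsites")

REPORT_SCHEMA_VERSION = 1

ALL_STAGES = (
    "matrix", "stratify", "promoter", "expression", "conservation",
    "repeats", "colocalize", "enrichment", "cross_species",
)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_FORMAT_ERROR = 3


@dataclass
class RunConfig:
    """Input paths and parameters for one pipeline run."""

    outdir: str
    sites: dict[str, str] = field(default_factory=dict)  # species_id -> path
    species_config: str | None = None
    ortholog_map: str | None = None
    expression: str | None = None
    promoters: str | None = None  # promoter FASTA keyed by gene_id
    genome: str | None = None  # genome FASTA (promoters cut via annotations)
    annotations: str | None = None
    annotation_format: str = "gtf-like"
    conservation: str | None = None
    repeats: str | None = None
    mirna_loci: str | None = None
    tf_set: str | None = None

    dialect: str = "generic-tsv"
    site_category: str | None = None
    mirsvr_cutoff: float = io.DEFAULT_MIRSVR_CUTOFF
    pct_conserved: float = 50.0
    pct_nonconserved: float = 75.0
    percentile_direction: str = "strength"
    flank: int = 1000
    coloc_window: int = 20_000
    strand_mode: str = "sense"
    log2_expression: bool = False
    nonzero_only_normalization: bool = False
    repeat_classes: tuple[str, ...] = ("LTR", "SINE")
    figures: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "repeat_classes" in raw:
            raw["repeat_classes"] = tuple(raw["repeat_classes"])
        if "outdir" not in raw:
            raise ValueError("config must set outdir")
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = list(self.sites.values()) + [
            p for p in (self.species_config, self.ortholog_map, self.expression,
                        self.promoters, self.genome, self.annotations,
                        self.conservation, self.repeats, self.mirna_loci, self.tf_set)
            if p is not None
        ]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValueError(f"referenced input paths do not exist: {missing}")


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _maybe_float(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


class Pipeline:
    """Holds intermediate state shared between stages of one run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.report: dict[str, Any] = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "parameters": {
                "pct_conserved": config.pct_conserved,
                "pct_nonconserved": config.pct_nonconserved,
                "percentile_direction": config.percentile_direction,
                "flank": config.flank,
                "coloc_window": config.coloc_window,
                "strand_mode": config.strand_mode,
                "log2_expression": config.log2_expression,
                "seed": config.seed,
            },
            "stages": {},
        }
        self.annotations: list[io.GeneAnnotation] | None = None
        self.matrix: interaction.InteractionMatrix | None = None
        self.counts: pd.Series | None = None
        self.strata: interaction.StratifiedGenes | None = None
        self.vigintile: dict[str, int] | None = None

    # -- helpers ------------------------------------------------------------

    def _skip(self, stage: str, reason: str) -> None:
        logger.info("stage %s SKIPPED: %s", stage, reason)
        self.report["stages"][stage] = {"status": "SKIPPED", "reason": reason}

    def _done(self, stage: str, **results) -> None:
        self.report["stages"][stage] = {"status": "complete", **results}

    def _reference_species(self) -> str:
        if self.config.species_config:
            ref, _ = species.read_species_config(self.config.species_config)
            return ref
        if len(self.config.sites) == 1:
            return next(iter(self.config.sites))
        raise ValueError("cannot determine reference species: set species_config")

    def _load_annotations(self) -> list[io.GeneAnnotation] | None:
        if self.annotations is None and self.config.annotations:
            self.annotations = io.parse_annotation(self.config.annotations,
                                                  self.config.annotation_format)
        return self.annotations

    def _filtered_frame(self, path: str) -> pd.DataFrame:
        frame = io.parse_site_frame(path, self.config.dialect,
                                    category=self.config.site_category,
                                    mirsvr_cutoff=self.config.mirsvr_cutoff)
        return interaction.filter_sites_by_percentile(
            frame, self.config.pct_conserved, self.config.pct_nonconserved,
            self.config.percentile_direction)

    def _vigintile_spearman(self, values: pd.Series) -> tuple[pd.DataFrame, float | None]:
        binned = interaction.binned_means(self.vigintile, values, self.counts)
        ok = binned.dropna(subset=["mean_x", "mean_y"])
        rho = stats.spearman(ok["mean_y"], ok["mean_x"]) if len(ok) >= 3 else None
        return binned, rho

    # -- stages -------------------------------------------------------------

    def stage_matrix(self) -> None:
        if not self.config.sites:
            self._skip("matrix", "no site tables configured")
            return
        ref = self._reference_species()
        if ref not in self.config.sites:
            raise ValueError(f"no site table for reference species {ref!r}")
        filtered = self._filtered_frame(self.config.sites[ref])
        anns = self._load_annotations()
        universe = [a.gene_id for a in anns] if anns else None
        self.matrix = interaction.build_binary_matrix(filtered, ref, gene_universe=universe)
        self.counts = self.matrix.counts
        self.matrix.write(self.outdir / "matrix_ref.tsv", self.outdir / "counts_ref.tsv")
        self._done("matrix", species=ref, n_genes=len(self.matrix.gene_ids),
                   n_mirnas=len(self.matrix.mirna_ids),
                   n_filtered_sites=int(len(filtered)),
                   mean_count=float(self.counts.mean()))

    def stage_stratify(self) -> None:
        if self.counts is None:
            self._skip("stratify", "matrix stage did not run")
            return
        self.strata = interaction.assign_quartile_groups(self.counts)
        self.vigintile = interaction.assign_vigintiles(self.counts)
        self.strata.vigintile = self.vigintile
        pd.DataFrame({
            "gene_id": self.counts.index,
            "count": self.counts.to_numpy(),
            "vigintile": [self.vigintile[g] for g in self.counts.index],
            "quartile_group": [
                "Q1" if g in self.strata.q1_set else ("Q4" if g in self.strata.q4_set else "mid")
                for g in self.counts.index
            ],
        }).to_csv(self.outdir / "stratification.tsv", sep="\t", index=False)
        self._done("stratify", q25_threshold=self.strata.q25_threshold,
                   q75_threshold=self.strata.q75_threshold,
                   n_q1=len(self.strata.q1_set), n_q4=len(self.strata.q4_set))

    def stage_promoter(self) -> None:
        if self.vigintile is None:
            self._skip("promoter", "stratification unavailable")
            return
        if self.config.promoters:
            seqs = _read_fasta(self.config.promoters)
        elif self.config.genome and self.annotations is not None:
            seqs = promoter.extract_promoters(_read_fasta(self.config.genome),
                                              self.annotations, self.config.flank,
                                              self.config.strand_mode)
        else:
            self._skip("promoter", "no promoter FASTA or genome+annotations configured")
            return
        feats = promoter.features_from_sequences(seqs)
        table = promoter.features_table(feats).set_index("gene_id")
        table.to_csv(self.outdir / "promoter_features.tsv", sep="\t")
        n_undefined = int(table["ratio"].isna().sum())
        if n_undefined:
            logger.info("promoter: %d genes with undefined dinucleotide ratio excluded", n_undefined)
        gc_binned, gc_rho = self._vigintile_spearman(table["gc_fraction"])
        ratio_binned, ratio_rho = self._vigintile_spearman(table["ratio"])
        gc_binned.to_csv(self.outdir / "vigintile_gc.tsv", sep="\t", index=False)
        ratio_binned.to_csv(self.outdir / "vigintile_dinuc_ratio.tsv", sep="\t", index=False)
        self._done("promoter", n_genes=len(table), n_undefined_ratio=n_undefined,
                   vigintile_spearman_gc=_maybe_float(gc_rho),
                   vigintile_spearman_dinuc_ratio=_maybe_float(ratio_rho))

    def stage_expression(self) -> None:
        if self.vigintile is None or self.strata is None:
            self._skip("expression", "stratification unavailable")
            return
        if not self.config.expression:
            self._skip("expression", "no expression matrix configured")
            return
        matrix = io.parse_expression(self.config.expression)
        cv_table = variability.expression_cv(matrix, self.config.log2_expression)
        cv_table.to_csv(self.outdir / "expression_cv.tsv", sep="\t", index=False)
        cv = cv_table.set_index("gene_id")["cv"]
        comparison = variability.group_cv_comparison(cv, self.strata.q1_set, self.strata.q4_set)
        binned, rho = self._vigintile_spearman(cv)
        binned.to_csv(self.outdir / "vigintile_cv.tsv", sep="\t", index=False)
        self._done("expression", n_genes=len(cv_table),
                   vigintile_spearman_cv=_maybe_float(rho), **comparison)

    def stage_conservation(self) -> None:
        if self.vigintile is None:
            self._skip("conservation", "stratification unavailable")
            return
        anns = self._load_annotations()
        if not self.config.conservation or anns is None:
            self._skip("conservation", "no conservation track or annotations configured")
            return
        track = io.parse_track(self.config.conservation)
        summaries = tracks.conservation_summaries(track, anns)
        table = pd.DataFrame(
            [(s.gene_id, _maybe_float(s.utr3_mean), _maybe_float(s.cds_mean),
              s.utr3_len, s.cds_len) for s in summaries],
            columns=["gene_id", "utr3_mean", "cds_mean", "utr3_len", "cds_len"],
        ).set_index("gene_id")
        table.to_csv(self.outdir / "conservation.tsv", sep="\t")
        utr_binned, utr_rho = self._vigintile_spearman(table["utr3_mean"].astype(float))
        cds_binned, cds_rho = self._vigintile_spearman(table["cds_mean"].astype(float))
        utr_binned.to_csv(self.outdir / "vigintile_utr_conservation.tsv", sep="\t", index=False)
        cds_binned.to_csv(self.outdir / "vigintile_cds_conservation.tsv", sep="\t", index=False)
        length_table, length_rho = tracks.utr_length_vs_counts(anns, self.counts)
        length_table.to_csv(self.outdir / "utr_length_vs_counts.tsv", sep="\t", index=False)
        self._done("conservation",
                   vigintile_spearman_utr=_maybe_float(utr_rho),
                   vigintile_spearman_cds=_maybe_float(cds_rho),
                   spearman_utr_length_vs_count=_maybe_float(length_rho))

    def stage_repeats(self) -> None:
        if self.strata is None:
            self._skip("repeats", "stratification unavailable")
            return
        anns = self._load_annotations()
        if not self.config.repeats or anns is None:
            self._skip("repeats", "no repeat annotations configured")
            return
        reps = io.parse_repeats(self.config.repeats)
        flags = tracks.repeat_flags(anns, reps, frozenset(self.config.repeat_classes))
        flag_series = pd.Series({g: f.has_ltr_sine for g, f in flags.items()})
        pd.DataFrame({
            "gene_id": flag_series.index, "has_ltr_sine": flag_series.to_numpy().astype(int),
            "overlap_bp": [flags[g].overlap_bp for g in flag_series.index],
        }).to_csv(self.outdir / "repeat_flags.tsv", sep="\t", index=False)
        q1 = [g for g in self.strata.q1_set if g in flag_series.index]
        q4 = [g for g in self.strata.q4_set if g in flag_series.index]
        frac_q1 = float(flag_series.reindex(q1).mean()) if q1 else None
        frac_q4 = float(flag_series.reindex(q4).mean()) if q4 else None
        overall = tracks.stratified_count_medians(self.counts, flags)
        try:
            within_q4 = tracks.stratified_count_medians(self.counts, flags,
                                                        within=self.strata.q4_set)
        except ValueError as exc:
            within_q4 = {"error": str(exc)}
        self._done("repeats", frac_ltr_sine_q1=frac_q1, frac_ltr_sine_q4=frac_q4,
                   overall=overall, within_q4=within_q4)

    def stage_colocalize(self) -> None:
        anns = self._load_annotations()
        if not self.config.mirna_loci or anns is None:
            self._skip("colocalize", "no miRNA loci or annotations configured")
            return
        loci = io.parse_bed_loci(self.config.mirna_loci)
        result = tracks.colocalize_mirnas(loci, anns, self.config.coloc_window)
        result.to_frame().to_csv(self.outdir / "colocalization_pairs.tsv", sep="\t", index=False)
        self._done("colocalize", n_mirnas=result.n_mirnas, n_genes=result.n_genes,
                   n_pairs=len(result.pairs), n_loci=int(len(loci)))

    def stage_enrichment(self) -> None:
        if self.strata is None:
            self._skip("enrichment", "stratification unavailable")
            return
        if not self.config.tf_set:
            self._skip("enrichment", "no TF gene set configured")
            return
        tf = io.parse_gene_set(self.config.tf_set, "tf").restricted(self.counts.index)
        universe_n = len(self.counts)
        results = {}
        for group_name, group, tail in (
            ("q4", self.strata.q4_set, "greater"),
            ("q1", self.strata.q1_set, "less"),
        ):
            overlap = len(tf.members & group)
            test = stats.hypergeometric_enrichment(universe_n, len(tf.members),
                                                   len(group), overlap, tail)
            results[f"tf_{group_name}_{tail}"] = {
                "overlap": overlap, "group_size": len(group),
                "set_size": len(tf.members), "p_value": test.p_value,
            }
        tf_counts = self.counts.reindex(sorted(tf.members)).dropna()
        non_tf_counts = self.counts.drop(index=list(tf.members), errors="ignore")
        ranksum = stats.wilcoxon_rank_sum(tf_counts, non_tf_counts, tail="greater")
        results["tf_vs_nontf_ranksum"] = {"p_value": ranksum.p_value,
                                          "statistic": ranksum.statistic}
        self._done("enrichment", universe_n=universe_n, **results)

    def stage_cross_species(self) -> None:
        if self.strata is None:
            self._skip("cross_species", "stratification unavailable")
            return
        if not self.config.species_config or len(self.config.sites) < 3:
            self._skip("cross_species", "needs species_config and >= 3 per-species site tables")
            return
        ref, ladder = species.read_species_config(self.config.species_config)
        ortho = species.read_ortholog_map(self.config.ortholog_map) if self.config.ortholog_map else {}
        matrices = {}
        for species_id, _rank in ladder:
            if species_id not in self.config.sites:
                raise ValueError(f"no site table for species {species_id!r}")
            filtered = self._filtered_frame(self.config.sites[species_id])
            # universe: every reference gene with an ortholog in this species,
            # so zero-count orthologs enter the normalization mean
            if ortho:
                universe = [ortho[(g, species_id)] for g in self.matrix.gene_ids
                            if (g, species_id) in ortho]
            elif species_id == ref:
                universe = self.matrix.gene_ids
            else:
                universe = None
            matrices[species_id] = interaction.build_binary_matrix(
                filtered, species_id, gene_universe=universe)
        panel = species.SpeciesPanel(ref, ladder, matrices, ortho)
        results = {}
        for name, group in (("q1", self.strata.q1_set), ("q4", self.strata.q4_set)):
            traj = species.group_trajectory(panel, group,
                                            self.config.nonzero_only_normalization)
            traj.to_csv(self.outdir / f"trajectory_{name}.tsv", sep="\t", index=False)
            results[f"trend_{name}"] = _maybe_float(species.trend_statistic(traj))
        self._done("cross_species", n_species=len(ladder), **results)

    def write_figures(self) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        panels = [
            ("vigintile_cv.tsv", "mean CV of expression", "fig_vigintile_cv.png"),
            ("vigintile_gc.tsv", "mean promoter GC fraction", "fig_vigintile_gc.png"),
            ("vigintile_dinuc_ratio.tsv", "mean fav/disfav dinucleotide ratio",
             "fig_vigintile_dinuc_ratio.png"),
            ("vigintile_utr_conservation.tsv", "mean 3'UTR conservation",
             "fig_vigintile_utr_conservation.png"),
            ("vigintile_cds_conservation.tsv", "mean CDS conservation",
             "fig_vigintile_cds_conservation.png"),
        ]
        for table_name, ylabel, fig_name in panels:
            path = self.outdir / table_name
            if not path.exists():
                continue
            table = pd.read_csv(path, sep="\t")
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.scatter(table["mean_y"], table["mean_x"], s=18)
            ax.set_xlabel("mean distinct-miRNA count (vigintile)")
            ax.set_ylabel(ylabel)
            fig.tight_layout()
            fig.savefig(self.outdir / fig_name, dpi=120)
            plt.close(fig)

    def run(self, stages: tuple[str, ...] | list[str] | None = None) -> dict:
        self.config.validate_paths()
        selected = tuple(stages) if stages else ALL_STAGES
        unknown = set(selected) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in ALL_STAGES:  # dependency order is fixed
            if stage in selected or stage in ("matrix", "stratify"):
                getattr(self, f"stage_{stage}")()
        if self.config.figures:
            self.write_figures()
        report_path = self.outdir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("report written to %s", report_path)
        return self.report


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the configured stages and return (and write) the report."""
    return Pipeline(config).run(stages)


def recover_planted_signals(dataset) -> dict:
    """Core analyses on an in-memory synthetic dataset, without file I/O.

    Filters each species' sites, builds matrices over the full gene universe,
    stratifies the reference counts and returns the headline statistics: the
    hypergeometric enrichment of the planted regulatory set in Q4, the
    vigintile-level Spearman of counts against expression CV and promoter GC
    (with one-sided p-values), and the distance trends of the Q1/Q4 mean
    normalized counts. Used by validation studies over many seeds.
    """
    universe = list(dataset.labels.index)
    matrices = {
        sp: interaction.build_binary_matrix(
            interaction.filter_sites_by_percentile(table), sp, gene_universe=universe)
        for sp, table in dataset.site_tables.items()
    }
    reference = next(s for s, rank in dataset.species if rank == 0)
    counts = matrices[reference].counts
    strata = interaction.assign_quartile_groups(counts)
    vigintile = interaction.assign_vigintiles(counts)

    cv = variability.expression_cv(dataset.expression).set_index("gene_id")["cv"]
    gc = pd.Series({g: promoter.gc_content(s) for g, s in dataset.promoters.items()},
                   dtype=float)
    out: dict[str, Any] = {"counts": counts, "strata": strata}
    for name, values in (("cv", cv), ("gc", gc)):
        binned = interaction.binned_means(vigintile, values, counts)
        ok = binned.dropna(subset=["mean_x", "mean_y"])
        test = stats.spearman_test(ok["mean_y"], ok["mean_x"], tail="greater")
        out[f"vigintile_spearman_{name}"] = test.statistic
        out[f"vigintile_spearman_{name}_p"] = test.p_value

    tf = dataset.tf_set.members & set(universe)
    overlap = len(tf & strata.q4_set)
    out["q4_enrichment_p"] = stats.hypergeometric_enrichment(
        len(universe), len(tf), len(strata.q4_set), overlap, "greater").p_value

    panel = species.SpeciesPanel(reference, list(dataset.species), matrices)
    for name, group, tail in (("q1", strata.q1_set, "greater"),
                              ("q4", strata.q4_set, "less")):
        traj = species.group_trajectory(panel, group)
        out[f"trend_{name}"] = species.trend_statistic(traj)
        out[f"trend_{name}_p"] = stats.spearman_test(
            traj["distance_rank"], traj["mean_normalized"], tail=tail).p_value
    return out
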