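"""End-to-end orchestration from one config, with a consistency-checked summary.

Stages run sequentially: simulate or load count reports -> per-individual
mCG calling -> CMC/DMC classification -> DMR detection and gene
association -> feature enrichment and metagene profiling -> optional
extrapolation from fixation observations.  The summary report is the
machine-readable surface: JSON plus TSV, with every printed total
re-derivable from the stage output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotation import GenomeAnnotation
from .calling import CallingParams, MethylationCallSet, SiteCountTable, call_mcg, coverage_summary
from .compare import ClassificationParams, ComparativeCallSet, GroupDesign, classify_all
from .dmr import ClusterParams, associate_genes, category_counts, extrapolate_fixed, find_dmc_clusters, write_dmr_bed
from .enrichment import assign_features, chi_square_2x2, feature_contingency, metagene_profile

logger = logging.getLogger("methyldiff")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Inputs and per-stage parameters for one pipeline run.

    Either ``simulation`` (a SimulationParams) or ``count_reports`` +
    ``design_file`` + ``annotation_gff3`` must be provided.
    """

    outdir: str = "methyldiff_out"
    seed: int = 0
    simulation: Optional[object] = None  # SimulationParams
    count_reports: dict[str, str] = field(default_factory=dict)  # individual -> path
    design_file: Optional[str] = None
    annotation_gff3: Optional[str] = None
    te_bed: Optional[str] = None
    smrna_bed: Optional[str] = None
    calling: CallingParams = field(default_factory=CallingParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    enrichment_features: tuple[str, ...] = ("intron", "TE")
    enrichment_reference: str = "CDS"
    # report-only extrapolation inputs (n_tested, n_fixed, n_general); None skips
    fixation_observations: Optional[tuple[int, int, int]] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        from .simulate import SimulationParams

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("outdir", "seed", "design_file", "annotation_gff3",
                    "te_bed", "smrna_bed", "enrichment_reference"):
            if key in raw:
                kwargs[key] = raw[key]
        if "count_reports" in raw:
            kwargs["count_reports"] = dict(raw["count_reports"])
        if "enrichment_features" in raw:
            kwargs["enrichment_features"] = tuple(raw["enrichment_features"])
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            for tup_key in ("exons_per_gene", "gene_length_range"):
                if tup_key in sim:
                    sim[tup_key] = tuple(sim[tup_key])
            kwargs["simulation"] = SimulationParams(**sim)
        if "calling" in raw:
            kwargs["calling"] = CallingParams(**raw["calling"])
        if "classification" in raw:
            kwargs["classification"] = ClassificationParams(**raw["classification"])
        if "clustering" in raw:
            kwargs["clustering"] = ClusterParams(**raw["clustering"])
        if "fixation_observations" in raw and raw["fixation_observations"]:
            kwargs["fixation_observations"] = tuple(raw["fixation_observations"])
        config = cls(**kwargs)
        for key, p in config.count_reports.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"count report for {key!r} not found: {p}")
        for key in ("design_file", "annotation_gff3", "te_bed", "smrna_bed"):
            p = getattr(config, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} not found: {p}")
        return config


def dmc_ratio(n_dmc_a: int, n_dmc_b: int) -> float:
    """Ratio of group-A to group-B DMC counts (report-only entry point)."""
    if n_dmc_b <= 0:
        raise ValueError("n_dmc_b must be positive")
    return n_dmc_a / n_dmc_b


@dataclass
class SummaryReport:
    per_sample: dict[str, dict]
    universe_size: int
    n_cmc: int
    n_dmc_a: int
    n_dmc_b: int
    group_a: str
    group_b: str
    dmc_ratio: Optional[float]
    n_dmrs: int
    dmr_categories: dict[str, int]
    enrichment: list[dict]
    extrapolation: Optional[dict] = None
    fixation: Optional[dict] = None

    @property
    def gene_related_dmrs(self) -> int:
        return sum(v for k, v in self.dmr_categories.items() if k != "intergenic")

    def check_consistency(self) -> None:
        if self.n_dmc_a + self.n_dmc_b > self.universe_size:
            raise ValueError("more DMCs than universe sites")
        if sum(self.dmr_categories.values()) < self.n_dmrs:
            raise ValueError(
                "category counts cannot cover the DMRs (each DMR carries "
                "at least one category)")
        if self.dmc_ratio is not None and self.n_dmc_b > 0:
            expect = self.n_dmc_a / self.n_dmc_b
            if abs(self.dmc_ratio - expect) > 1e-9:
                raise ValueError("dmc_ratio inconsistent with DMC counts")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_related_dmrs"] = self.gene_related_dmrs
        d["version"] = __version__
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        rows = [("universe_size", self.universe_size),
                ("n_cmc", self.n_cmc),
                (f"n_dmc_{self.group_a}", self.n_dmc_a),
                (f"n_dmc_{self.group_b}", self.n_dmc_b),
                ("dmc_ratio", "" if self.dmc_ratio is None else f"{self.dmc_ratio:.2f}"),
                ("n_dmrs", self.n_dmrs),
                ("gene_related_dmrs", self.gene_related_dmrs)]
        rows += [(f"n_dmrs_{k}", v) for k, v in self.dmr_categories.items()]
        for e in self.enrichment:
            rows.append((f"chi2_{e['feature']}_vs_{e['reference']}",
                         f"{e['statistic']:.4g} (p={e['p_value']:.3g})"))
        if self.extrapolation:
            rows.append(("extrapolated_fixed", self.extrapolation["fixed"]))
            rows.append(("extrapolated_general", self.extrapolation["general"]))
        with open(path, "w") as fh:
            for key, value in rows:
                fh.write(f"{key}\t{value}\n")


def summarize_counts(comparative: ComparativeCallSet, dmrs, enrichment: list[dict],
                     extrapolation: Optional[dict] = None,
                     per_sample: Optional[dict] = None,
                     fixation: Optional[dict] = None) -> SummaryReport:
    """Assemble the report from stage outputs and run its consistency checks."""
    report = SummaryReport(
        per_sample=per_sample or {},
        universe_size=comparative.universe_size,
        n_cmc=comparative.n_cmc,
        n_dmc_a=comparative.n_dmc_a,
        n_dmc_b=comparative.n_dmc_b,
        group_a=comparative.design.group_a,
        group_b=comparative.design.group_b,
        dmc_ratio=(comparative.n_dmc_a / comparative.n_dmc_b
                   if comparative.n_dmc_b else None),
        n_dmrs=len(dmrs),
        dmr_categories=category_counts(dmrs),
        enrichment=enrichment,
        extrapolation=extrapolation,
        fixation=fixation,
    )
    report.check_consistency()
    return report


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Run every stage, writing outputs under ``config.outdir``.

    A stage failure aborts with the failing stage named; outputs written so
    far are kept next to a FAILED marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------------
        stage = "simulate" if config.simulation is not None else "load"
        if config.simulation is not None:
            from .simulate import simulate_annotation, simulate_cohort, write_cohort

            params = dataclasses.replace(config.simulation, seed=config.seed)
            logger.info("simulating cohort: %s", params)
            annotation = simulate_annotation(params)
            truth, tables = simulate_cohort(annotation, params)
            design = truth.design
            write_cohort(outdir / "simulated", annotation, truth, tables)
        else:
            design = GroupDesign.from_tsv(config.design_file)
            annotation = GenomeAnnotation.from_gff3(
                config.annotation_gff3, te_bed=config.te_bed,
                smrna_bed=config.smrna_bed)
            tables = {
                ind: SiteCountTable.read_tsv(path, individual=ind)
                for ind, path in config.count_reports.items()
            }

        # ---- calling ------------------------------------------------------
        stage = "call"
        callsets: dict[str, MethylationCallSet] = {}
        per_sample: dict[str, dict] = {}
        for ind, table in tables.items():
            cs = call_mcg(table, config.calling)
            cs.to_bed(outdir / f"{ind}.calls.bed")
            cov = coverage_summary(table)
            callsets[ind] = cs
            per_sample[ind] = {
                "n_mcg": len(cs.methylated),
                "n_tested": len(cs.covered),
                "mean_depth_per_strand": cov.mean_depth_per_strand,
                "covered_fraction": cov.covered_fraction,
            }
            logger.info("%s: %d mCGs of %d tested sites", ind,
                        len(cs.methylated), len(cs.covered))

        # ---- classification ----------------------------------------------
        stage = "compare"
        comparative = classify_all(callsets, design, config.classification)
        comparative.write_beds(outdir)
        logger.info("universe %d: %d CMC, %d/%d DMC",
                    comparative.universe_size, comparative.n_cmc,
                    comparative.n_dmc_a, comparative.n_dmc_b)

        # ---- DMRs ---------------------------------------------------------
        stage = "dmr"
        dmcs = comparative.dmc_table()
        dmrs = find_dmc_clusters(dmcs, config.clustering)
        dmrs = associate_genes(dmrs, annotation, config.clustering)
        write_dmr_bed(dmrs, outdir / "dmrs.bed")

        # ---- enrichment + profile ----------------------------------------
        stage = "enrich"
        universe = frozenset(zip(comparative.df["chrom"], comparative.df["pos"],
                                 comparative.df["strand"]))
        class_sites = {
            cls: comparative.sites_of_class(cls)
            for cls in ("CMC", "DMC_A", "DMC_B")
        }
        interesting = class_sites["CMC"] | class_sites["DMC_A"] | class_sites["DMC_B"]
        labels = assign_features(interesting, annotation, config.clustering.flank)
        enrichment_rows = []
        for feature in config.enrichment_features:
            try:
                table = feature_contingency(comparative, labels, feature,
                                            config.enrichment_reference)
                statistic, p_value = chi_square_2x2(table)
                enrichment_rows.append({
                    "feature": feature, "reference": config.enrichment_reference,
                    "table": table.table, "odds_ratio": table.odds_ratio,
                    "statistic": statistic, "p_value": p_value,
                })
            except Exception as exc:  # an empty cell on tiny runs is not fatal
                logger.warning("enrichment %s vs %s skipped: %s", feature,
                               config.enrichment_reference, exc)
        pd.DataFrame(enrichment_rows).to_csv(outdir / "enrichment.tsv",
                                             sep="\t", index=False)

        stage = "profile"
        profile = metagene_profile(class_sites, annotation,
                                   universe_sites=universe,
                                   flank=config.clustering.flank)
        profile.to_tsv(outdir / "metagene.tsv")

        # ---- extrapolation ------------------------------------------------
        stage = "extrapolate"
        extrapolation = None
        if config.fixation_observations is not None:
            n_tested, n_fixed, n_general = config.fixation_observations
            if n_tested > len(dmrs):
                logger.warning(
                    "extrapolation skipped: %d regions tested but only %d "
                    "DMRs found", n_tested, len(dmrs))
            else:
                fixed, general = extrapolate_fixed(len(dmrs), n_tested,
                                                   n_fixed, n_general)
                extrapolation = {"n_total_dmrs": len(dmrs), "n_tested": n_tested,
                                 "n_fixed_observed": n_fixed,
                                 "n_general_observed": n_general,
                                 "fixed": fixed, "general": general}

        stage = "report"
        report = summarize_counts(comparative, dmrs, enrichment_rows,
                                  extrapolation=extrapolation,
                                  per_sample=per_sample)
        report.to_json(outdir / "summary.json")
        report.to_tsv(outdir / "summary.tsv")
        (outdir / "run.log").write_text(
            f"methyldiff {__version__}\nseed={config.seed}\n"
            f"calling={config.calling}\nclassification={config.classification}\n"
            f"clustering={config.clustering}\n")
        return report
    except PipelineError:
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise PipelineError(stage, exc) from exc
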