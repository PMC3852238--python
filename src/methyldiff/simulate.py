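"""Synthetic two-group bisulfite cohorts with known epigenomic ground truth.

The generator emulates the statistical structure of a sparse invertebrate
CpG methylome sequenced at low per-strand depth: ~0.1% of CG sites
methylated, 4-6x coverage per strand, 67-81% of cytosines covered, partial
methylation levels below 1 (cell-type mixture), a small bisulfite
conversion-failure background measurable at non-CG cytosines, within-group
epiallele variability, and a planted set of group-fixed differences (both
isolated differentially methylated cytosines and small clusters that the
region-detection stage should recover).

Sites are drawn as a positional catalogue rather than from an explicit
random sequence: CpG dinucleotides at a fixed per-bp density (both strand
cytosines emitted as separate records) and a representative subsample of
non-CG cytosines whose only role is to carry the conversion-failure
background.  Methylation truth is planted per CpG dinucleotide and applied
symmetrically to both strand records.

Randomness is organised as one master seed with fixed substreams
(annotation, truth planting, one per individual), so adding an individual
to a cohort never perturbs the data of earlier individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationError, Gene, GenomeAnnotation
from .calling import SiteCountTable
from .compare import GroupDesign

__all__ = [
    "SimulationParams",
    "TrueEpigenome",
    "SizingError",
    "simulate_annotation",
    "simulate_cohort",
    "simulate_amplicon_reads",
    "write_cohort",
]


class SizingError(ValueError):
    """Genome too small to place the requested features."""


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study.

    Defaults are the study conditions the downstream rules assume: a 3 + 4
    two-group cohort, 0.1% of CG sites methylated, 5x mean per-strand depth,
    75% of cytosines covered at all, 0.5% conversion failure, 80% partial
    methylation at truly methylated sites, and an epipolymorphism rate of
    0.3 (per-individual dropout of group-level methylation).
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    n_genes: int = 120
    exons_per_gene: tuple[int, int] = (2, 6)
    gene_length_range: tuple[int, int] = (1000, 4000)
    te_fraction: float = 0.10
    smrna_loci: int = 30
    n_group_a: int = 3
    n_group_b: int = 4
    group_a_name: str = "domesticated"
    group_b_name: str = "wild"
    mcg_density: float = 0.001
    planted_dmc_fraction: float = 0.05
    planted_direction_bias: float = 0.5  # probability a planted difference is group-A-fixed
    planted_dmr_count: int = 5
    epipolymorphism_rate: float = 0.3
    mean_coverage_per_strand: float = 5.0
    covered_fraction: float = 0.75
    conversion_failure_rate: float = 0.005
    partial_methylation_level: float = 0.8
    cg_dinucleotide_density: float = 1.0 / 16.0
    noncg_site_density: float = 0.02
    seed: int = 0

    def validate(self, for_comparison: bool = False) -> None:
        fractions = {
            "te_fraction": self.te_fraction,
            "mcg_density": self.mcg_density,
            "planted_dmc_fraction": self.planted_dmc_fraction,
            "planted_direction_bias": self.planted_direction_bias,
            "epipolymorphism_rate": self.epipolymorphism_rate,
            "covered_fraction": self.covered_fraction,
            "conversion_failure_rate": self.conversion_failure_rate,
            "partial_methylation_level": self.partial_methylation_level,
            "cg_dinucleotide_density": self.cg_dinucleotide_density,
            "noncg_site_density": self.noncg_site_density,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_length and n_chromosomes must be positive")
        if self.n_genes < 0 or self.smrna_loci < 0 or self.planted_dmr_count < 0:
            raise ValueError("feature counts must be non-negative")
        if self.mean_coverage_per_strand <= 0:
            raise ValueError("mean_coverage_per_strand must be positive")
        lo, hi = self.exons_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("exons_per_gene range must satisfy 1 <= lo <= hi")
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("need at least one individual per group")
        if for_comparison and (self.n_group_a < 3 or self.n_group_b < 3):
            raise ValueError(
                "CMC/DMC classification needs >=3 individuals per group; "
                f"got {self.n_group_a} and {self.n_group_b}"
            )

    def individual_ids(self) -> tuple[list[str], list[str]]:
        a = [f"dome{i + 1}" for i in range(self.n_group_a)]
        b = [f"wild{i + 1}" for i in range(self.n_group_b)]
        return a, b

    def design(self) -> GroupDesign:
        a, b = self.individual_ids()
        return GroupDesign({self.group_a_name: a, self.group_b_name: b})


@dataclass
class TrueEpigenome:
    """Planted ground truth: site catalogue, per-CpG labels, per-individual states.

    ``sites`` lists every emitted cytosine record (both strands of each CpG,
    plus non-CG cytosines, dinuc_id == -1).  ``dinucs`` carries one row per
    CpG dinucleotide with its group-level label in {unmethylated, conserved,
    fixed_a, fixed_b} and a cluster id (>= 0 for planted DMC clusters).
    ``membership`` is the post-epipolymorphism truth: one boolean column per
    individual over dinucleotides.
    """

    sites: pd.DataFrame
    dinucs: pd.DataFrame
    membership: pd.DataFrame
    design: GroupDesign
    params: SimulationParams

    def methylated_sites(self, individual: str) -> frozenset:
        member = self.membership[individual]
        meth_dinucs = set(member.index[member])
        cg = self.sites[self.sites["dinuc_id"].isin(meth_dinucs)]
        return frozenset(zip(cg["chrom"], cg["pos"], cg["strand"]))

    def labelled_sites(self, label: str) -> frozenset:
        """All strand-level CG site keys whose dinucleotide carries ``label``."""
        ids = set(self.dinucs.index[self.dinucs["label"] == label])
        cg = self.sites[self.sites["dinuc_id"].isin(ids)]
        return frozenset(zip(cg["chrom"], cg["pos"], cg["strand"]))

    def realized_labels(self) -> pd.Series:
        """Per-dinucleotide label after noise: planted label where the
        realized pattern is intact, 'polymorphic' where epipolymorphism
        removed it from at least one individual that should carry it."""
        a_ids = self.design.group_a_individuals
        b_ids = self.design.group_b_individuals
        out = self.dinucs["label"].copy()
        expect = {
            "conserved": a_ids + b_ids,
            "fixed_a": a_ids,
            "fixed_b": b_ids,
        }
        for label, individuals in expect.items():
            mask = self.dinucs["label"] == label
            if mask.any():
                intact = self.membership.loc[mask, individuals].all(axis=1)
                out.loc[mask & ~intact.reindex(out.index, fill_value=True)] = "polymorphic"
        return out

    def to_tsv(self, path) -> None:
        df = self.dinucs.copy()
        for ind in self.membership.columns:
            df[f"methylated_in_{ind}"] = self.membership[ind]
        df.to_csv(path, sep="\t", index_label="dinuc_id")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(params: SimulationParams) -> GenomeAnnotation:
    """Place genes, TEs and smRNA loci on a synthetic genome.

    Genes never overlap each other; TE intervals may overlap genes (and thus
    introns), mirroring real annotations.  Deterministic given the seed.
    """
    params.validate()
    rng = _rng(params.seed, 0)

    base = params.genome_length // params.n_chromosomes
    rem = params.genome_length - base * params.n_chromosomes
    chromosomes = {
        f"chr{i + 1}": base + (1 if i < rem else 0)
        for i in range(params.n_chromosomes)
    }
    chrom_names = list(chromosomes)

    # genes, round-robin across chromosomes
    genes: list[Gene] = []
    per_chrom = [params.n_genes // params.n_chromosomes] * params.n_chromosomes
    for i in range(params.n_genes % params.n_chromosomes):
        per_chrom[i] += 1
    glo, ghi = params.gene_length_range
    elo, ehi = params.exons_per_gene
    gene_no = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        if n_here == 0:
            continue
        clen = chromosomes[chrom]
        lengths = rng.integers(glo, ghi + 1, size=n_here)
        free = clen - int(lengths.sum())
        if free < 0:
            raise SizingError(
                f"cannot place {n_here} genes totalling {lengths.sum()} bp "
                f"on {chrom} ({clen} bp); enlarge the genome or reduce n_genes"
            )
        offsets = np.sort(rng.integers(0, free + 1, size=n_here))
        starts = offsets + np.concatenate([[0], np.cumsum(lengths[:-1])])
        strands = rng.choice(np.array(["+", "-"]), size=n_here)
        for j in range(n_here):
            gene_no += 1
            start, length = int(starts[j]), int(lengths[j])
            n_exons = int(rng.integers(elo, ehi + 1))
            n_exons = max(1, min(n_exons, (length + 1) // 2))
            n_cuts = 2 * n_exons - 2
            cuts = np.sort(rng.choice(np.arange(1, length), size=n_cuts, replace=False))
            bounds = np.concatenate([[0], cuts, [length]])
            exons = [
                (start + int(bounds[k]), start + int(bounds[k + 1]))
                for k in range(0, len(bounds) - 1, 2)
            ]
            genes.append(
                Gene(f"gene{gene_no:05d}", chrom, str(strands[j]),
                     start, start + length, exons)
            )

    # TEs: draw lengths until the target fraction of bp is reached
    te_intervals = []
    target = int(round(params.te_fraction * params.genome_length))
    placed = 0
    while placed < target:
        length = int(rng.integers(200, 2001))
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        clen = chromosomes[chrom]
        length = min(length, clen)
        start = int(rng.integers(0, clen - length + 1))
        te_intervals.append((chrom, start, start + length))
        placed += length

    smrna_intervals = []
    for _ in range(params.smrna_loci):
        length = int(rng.integers(80, 151))
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        clen = chromosomes[chrom]
        if clen < length:
            raise SizingError(f"chromosome {chrom} too small for an smRNA locus")
        start = int(rng.integers(0, clen - length + 1))
        smrna_intervals.append((chrom, start, start + length))

    ann = GenomeAnnotation(
        chromosomes=chromosomes,
        genes=genes,
        te_intervals=sorted(te_intervals),
        smrna_intervals=sorted(smrna_intervals),
    )
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# site catalogue and truth
# ---------------------------------------------------------------------------

def _site_catalogue(annotation: GenomeAnnotation, params: SimulationParams,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample CpG dinucleotide and non-CG cytosine positions per chromosome."""
    dinuc_rows = []
    noncg_rows = []
    for chrom, clen in annotation.chromosomes.items():
        n_cg = int(round(clen * params.cg_dinucleotide_density))
        n_cg = min(n_cg, max(0, (clen - 1) // 2))
        if n_cg > 0:
            n_cand = min(clen - 1, int(n_cg * 1.3) + 8)
            cand = np.sort(rng.choice(clen - 1, size=n_cand, replace=False))
            keep = np.diff(cand, prepend=-2) >= 2
            pos = cand[keep][:n_cg]
        else:
            pos = np.array([], dtype=int)
        dinuc_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))

        n_noncg = int(round(clen * params.noncg_site_density))
        if n_noncg > 0:
            occupied = np.zeros(clen, dtype=bool)
            occupied[pos] = True
            occupied[pos + 1] = True
            cand = rng.choice(clen, size=min(clen, int(n_noncg * 1.5) + 8), replace=False)
            cand = cand[~occupied[cand]][:n_noncg]
            cand.sort()
            noncg_rows.append(pd.DataFrame({
                "chrom": chrom,
                "pos": cand,
                "strand": rng.choice(np.array(["+", "-"]), size=len(cand)),
                "context": rng.choice(np.array(["CHG", "CHH"]), size=len(cand), p=[0.3, 0.7]),
            }))

    dinucs = pd.concat(dinuc_rows, ignore_index=True)
    dinucs.index.name = "dinuc_id"

    plus = pd.DataFrame({
        "chrom": dinucs["chrom"], "pos": dinucs["pos"], "strand": "+",
        "context": "CG", "dinuc_id": dinucs.index,
    })
    minus = plus.copy()
    minus["pos"] = minus["pos"] + 1
    minus["strand"] = "-"
    parts = [plus, minus]
    if noncg_rows:
        noncg = pd.concat(noncg_rows, ignore_index=True)
        noncg["dinuc_id"] = -1
        parts.append(noncg)
    sites = pd.concat(parts, ignore_index=True)
    sites = sites.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return dinucs, sites


def _plant_truth(dinucs: pd.DataFrame, params: SimulationParams,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Assign group-level labels per CpG dinucleotide.

    Baseline methylation at rate mcg_density; planted_dmr_count clusters of
    3 consecutive dinucleotides (span <= 200 bp) made group-fixed; of the
    remaining methylated dinucleotides, planted_dmc_fraction made group-fixed
    singletons, the rest conserved.
    """
    n = len(dinucs)
    labels = np.full(n, "unmethylated", dtype=object)
    cluster_id = np.full(n, -1, dtype=int)
    meth = rng.random(n) < params.mcg_density

    # candidate anchors for planted clusters: 3 dinucs spanning <= 200 bp
    pos = dinucs["pos"].to_numpy()
    chrom = dinucs["chrom"].to_numpy()
    if n >= 3:
        span_ok = (pos[2:] - pos[:-2] <= 200) & (chrom[2:] == chrom[:-2])
        candidates = np.flatnonzero(span_ok)
    else:
        candidates = np.array([], dtype=int)
    order = rng.permutation(len(candidates))
    chosen: list[int] = []
    for idx in candidates[order]:
        if len(chosen) >= params.planted_dmr_count:
            break
        if all(abs(int(pos[idx]) - int(pos[c])) > 600 or chrom[idx] != chrom[c]
               for c in chosen):
            chosen.append(int(idx))
    if params.planted_dmr_count > 0 and len(chosen) < params.planted_dmr_count:
        raise SizingError(
            f"could only seat {len(chosen)} of {params.planted_dmr_count} planted "
            "DMC clusters; enlarge the genome or raise cg_dinucleotide_density"
        )
    for k, anchor in enumerate(sorted(chosen)):
        direction = "fixed_a" if rng.random() < params.planted_direction_bias else "fixed_b"
        sl = slice(anchor, anchor + 3)
        labels[sl] = direction
        cluster_id[sl] = k
        meth[sl] = True

    single = meth & (labels == "unmethylated")
    single_idx = np.flatnonzero(single)
    fixed_draw = rng.random(len(single_idx)) < params.planted_dmc_fraction
    dir_draw = rng.random(len(single_idx)) < params.planted_direction_bias
    labels[single_idx[fixed_draw & dir_draw]] = "fixed_a"
    labels[single_idx[fixed_draw & ~dir_draw]] = "fixed_b"
    labels[single_idx[~fixed_draw]] = "conserved"

    out = dinucs.copy()
    out["label"] = labels
    out["cluster_id"] = cluster_id
    return out


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1, by inverse transform."""
    lo = math.exp(-lam)
    u = rng.uniform(lo, 1.0, size=size)
    return stats.poisson.ppf(u, lam).astype(np.int64)


def simulate_cohort(
    annotation: GenomeAnnotation, params: SimulationParams
) -> tuple[TrueEpigenome, dict[str, SiteCountTable]]:
    """Generate the ground-truth epigenome and one count table per individual.

    Per individual and cytosine record: coverage is Bernoulli(covered_fraction);
    covered records get a zero-truncated Poisson(mean_coverage_per_strand)
    depth; the methylated-read count is Binomial(depth, p) with p equal to
    partial_methylation_level where the individual's truth is methylated and
    conversion_failure_rate elsewhere (all non-CG cytosines are unmethylated
    in truth).
    """
    params.validate()
    truth_rng = _rng(params.seed, 1)
    dinucs_raw, sites = _site_catalogue(annotation, params, truth_rng)
    dinucs = _plant_truth(dinucs_raw, params, truth_rng)

    design = params.design()
    a_ids, b_ids = params.individual_ids()
    individuals = a_ids + b_ids
    group_of = {i: "a" for i in a_ids} | {i: "b" for i in b_ids}

    label = dinucs["label"].to_numpy()
    baseline = {
        "a": (label == "conserved") | (label == "fixed_a"),
        "b": (label == "conserved") | (label == "fixed_b"),
    }

    dinuc_ids = sites["dinuc_id"].to_numpy()
    is_cg = dinuc_ids >= 0
    n_sites = len(sites)

    membership = {}
    tables: dict[str, SiteCountTable] = {}
    for idx, ind in enumerate(individuals):
        rng_i = _rng(params.seed, 2, idx)
        member = baseline[group_of[ind]].copy()
        flip = rng_i.random(len(member)) < params.epipolymorphism_rate
        member &= ~flip
        membership[ind] = member

        site_member = np.zeros(n_sites, dtype=bool)
        site_member[is_cg] = member[dinuc_ids[is_cg]]

        covered = rng_i.random(n_sites) < params.covered_fraction
        depth = np.zeros(n_sites, dtype=np.int64)
        n_cov = int(covered.sum())
        if n_cov:
            depth[covered] = _zero_truncated_poisson(
                rng_i, params.mean_coverage_per_strand, n_cov)
        p = np.where(site_member, params.partial_methylation_level,
                     params.conversion_failure_rate)
        m = rng_i.binomial(depth, p)

        df = sites[["chrom", "pos", "strand", "context"]].copy()
        df["count_methylated"] = m
        df["count_total"] = depth
        tables[ind] = SiteCountTable(df, individual=ind)

    truth = TrueEpigenome(
        sites=sites,
        dinucs=dinucs,
        membership=pd.DataFrame(membership, index=dinucs.index),
        design=design,
        params=params,
    )
    return truth, tables


def write_cohort(outdir, annotation: GenomeAnnotation, truth: TrueEpigenome,
                 tables: dict[str, SiteCountTable]) -> None:
    """Serialize a simulated cohort: count TSVs, GFF3 + BED tracks, truth, design."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation.to_gff3(outdir / "annotation.gff3")
    annotation.write_te_bed(outdir / "te.bed")
    annotation.write_smrna_bed(outdir / "smrna.bed")
    truth.to_tsv(outdir / "truth.tsv")
    truth.design.to_tsv(outdir / "design.tsv")
    for ind, table in tables.items():
        table.to_tsv(outdir / f"{ind}.counts.tsv")


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------

def simulate_amplicon_reads(
    target: str,
    cg_levels: dict[int, float],
    n_reads: int,
    rng: np.random.Generator,
    conversion_failure_rate: float = 0.0,
) -> list[str]:
    """Bisulfite-converted reads over an amplicon target.

    ``cg_levels`` maps 0-based positions of cytosines of interest (typically
    CpG cytosines on the forward strand) to their true methylation level;
    every other C converts to T except for conversion failures.
    """
    target = target.upper()
    c_positions = [i for i, b in enumerate(target) if b == "C"]
    reads = []
    for _ in range(n_reads):
        bases = list(target)
        for i in c_positions:
            p = cg_levels.get(i, conversion_failure_rate)
            if rng.random() >= p:
                bases[i] = "T"
        reads.append("".join(bases))
    return reads
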