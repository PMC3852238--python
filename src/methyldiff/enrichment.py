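"""Genomic-feature assignment, 2x2 enrichment tests, and metagene profiles.

Sites are multi-labelled over {CDS, intron, upstream, downstream, TE,
smRNA, intergenic}: within one gene model CDS takes precedence over intron,
flanks are strand-aware, TE and smRNA labels are independent of genic
labels, and a site is intergenic exactly when it carries no other label.
Enrichment of DMCs relative to CMCs in a feature versus a reference feature
(CDS by default) is tested with a Pearson chi-square on the 2x2 table,
without continuity correction unless asked for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import GenomeAnnotation
from .calling import Site
from .compare import ComparativeCallSet

FEATURES = ("CDS", "intron", "upstream", "downstream", "TE", "smRNA", "intergenic")


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# feature assignment
# ---------------------------------------------------------------------------

def _build_trees(annotation: GenomeAnnotation, flank: int) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {
        name: {} for name in ("gene", "upstream", "downstream", "TE", "smRNA")
    }

    def add(track: str, chrom: str, start: int, end: int, payload) -> None:
        if start < end:
            trees[track].setdefault(chrom, IntervalTree()).addi(start, end, payload)

    for gene in annotation.genes:
        add("gene", gene.chrom, gene.start, gene.end, gene)
        add("upstream", gene.chrom, *annotation.upstream_flank(gene, flank), gene.gene_id)
        add("downstream", gene.chrom, *annotation.downstream_flank(gene, flank), gene.gene_id)
    for chrom, s, e in annotation.te_intervals:
        add("TE", chrom, s, e, None)
    for chrom, s, e in annotation.smrna_intervals:
        add("smRNA", chrom, s, e, None)
    return trees


def assign_features(sites: Iterable[Site], annotation: GenomeAnnotation,
                    flank: int = 2000) -> pd.DataFrame:
    """Multi-label feature assignment; one boolean column per feature,
    indexed by (chrom, pos, strand)."""
    trees = _build_trees(annotation, flank)
    site_list = list(sites)
    out = np.zeros((len(site_list), len(FEATURES)), dtype=bool)
    col = {name: i for i, name in enumerate(FEATURES)}
    for row, (chrom, pos, _strand) in enumerate(site_list):
        genic = False
        for iv in trees["gene"].get(chrom, IntervalTree())[pos]:
            gene = iv.data
            in_exon = any(s <= pos < e for s, e in gene.exons)
            out[row, col["CDS" if in_exon else "intron"]] = True
            genic = True
        hit_up = bool(trees["upstream"].get(chrom, IntervalTree())[pos])
        hit_down = bool(trees["downstream"].get(chrom, IntervalTree())[pos])
        hit_te = bool(trees["TE"].get(chrom, IntervalTree())[pos])
        hit_sm = bool(trees["smRNA"].get(chrom, IntervalTree())[pos])
        out[row, col["upstream"]] = hit_up
        out[row, col["downstream"]] = hit_down
        out[row, col["TE"]] = hit_te
        out[row, col["smRNA"]] = hit_sm
        if not (genic or hit_up or hit_down or hit_te or hit_sm):
            out[row, col["intergenic"]] = True
    index = pd.MultiIndex.from_tuples(site_list, names=["chrom", "pos", "strand"])
    return pd.DataFrame(out, index=index, columns=list(FEATURES))


# ---------------------------------------------------------------------------
# contingency + chi-square
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows (feature, reference), columns (DMC, CMC)."""

    feature: str
    reference: str
    table: tuple[tuple[int, int], tuple[int, int]]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.table, dtype=float)

    def validate(self) -> None:
        arr = self.as_array()
        if (arr < 0).any():
            raise EnrichmentError("contingency counts must be non-negative")
        for i, row_name in enumerate((self.feature, self.reference)):
            if arr[i].sum() == 0:
                raise EnrichmentError(
                    f"empty row for {row_name!r}: no DMCs or CMCs carry this label")

    @property
    def odds_ratio(self) -> float:
        (a, b), (c, d) = self.table
        if b == 0 or c == 0:
            return float("inf") if a * d > 0 else float("nan")
        return (a * d) / (b * c)


def feature_contingency(comparative: ComparativeCallSet, labels: pd.DataFrame,
                        feature: str, reference: str = "CDS") -> ContingencyTable:
    """DMC/CMC counts in ``feature`` vs ``reference``; both DMC directions pooled."""
    if feature == reference:
        raise EnrichmentError("feature and reference must differ")
    for name in (feature, reference):
        if name not in labels.columns:
            raise EnrichmentError(f"unknown feature {name!r}")
    dmc = comparative.sites_of_class("DMC_A") | comparative.sites_of_class("DMC_B")
    cmc = comparative.sites_of_class("CMC")

    def count(sites: frozenset, name: str) -> int:
        idx = labels.index.intersection(list(sites))
        return int(labels.loc[idx, name].sum())

    table = ContingencyTable(
        feature=feature, reference=reference,
        table=(
            (count(dmc, feature), count(cmc, feature)),
            (count(dmc, reference), count(cmc, reference)),
        ),
    )
    table.validate()
    return table


def chi_square_2x2(table: ContingencyTable | Iterable[Iterable[float]],
                   yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 degree of freedom.

    No continuity correction by default (the tables this pipeline produces
    have large cells); set ``yates=True`` to apply it.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise EnrichmentError("need a 2x2 table")
    if (arr < 0).any():
        raise EnrichmentError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise EnrichmentError("zero marginal: the chi-square test is undefined")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# metagene profile
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Ordered positional bins over gene bodies and fixed-width flanks.

    Bin order: upstream (farthest first), body (5' to 3' in 20 fractional
    bins), downstream.  ``counts`` has one row per class; ``densities``
    divides counts by the number of universe sites per bin when a universe
    was supplied, and repeats the raw counts otherwise.
    """

    counts: pd.DataFrame
    densities: pd.DataFrame
    universe_counts: Optional[pd.Series]
    n_genes_used: int
    n_genes_skipped: int
    n_flank_bins: int
    body_bins: int

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.body_bins

    def to_tsv(self, path) -> None:
        rows = []
        for cls in self.counts.index:
            for b in range(self.n_bins):
                rows.append({
                    "class": cls, "bin": b, "segment": self.segment(b),
                    "count": int(self.counts.loc[cls].iloc[b]),
                    "density": float(self.densities.loc[cls].iloc[b]),
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def segment(self, b: int) -> str:
        if b < self.n_flank_bins:
            return "upstream"
        if b < self.n_flank_bins + self.body_bins:
            return "body"
        return "downstream"

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        x = np.arange(self.n_bins)
        for cls in self.densities.index:
            ax.plot(x, self.densities.loc[cls].to_numpy(), label=str(cls))
        for edge in (self.n_flank_bins, self.n_flank_bins + self.body_bins):
            ax.axvline(edge - 0.5, color="grey", lw=0.5)
        ax.set_xlabel("bin (upstream | body | downstream)")
        ax.set_ylabel("methylation density")
        ax.legend(fontsize=8)
        return ax


def _site_bin(pos: int, gene, flank: int, body_bins: int, flank_bin_bp: int
              ) -> Optional[int]:
    """Strand-aware bin index of a position relative to one gene, or None."""
    n_flank_bins = flank // flank_bin_bp
    length = gene.end - gene.start
    if gene.strand == "+":
        if pos < gene.start:  # upstream
            d = gene.start - pos
            if d > flank:
                return None
            return (flank - d) // flank_bin_bp
        if pos >= gene.end:  # downstream
            d = pos - (gene.end - 1)
            if d > flank:
                return None
            return n_flank_bins + body_bins + (d - 1) // flank_bin_bp
        frac = (pos - gene.start) / length
    else:
        if pos >= gene.end:  # upstream of a minus-strand gene
            d = pos - (gene.end - 1)
            if d > flank:
                return None
            return (flank - d) // flank_bin_bp
        if pos < gene.start:  # downstream
            d = gene.start - pos
            if d > flank:
                return None
            return n_flank_bins + body_bins + (d - 1) // flank_bin_bp
        frac = (gene.end - 1 - pos) / length
    return n_flank_bins + min(int(frac * body_bins), body_bins - 1)


def metagene_profile(class_sites: Mapping[str, Iterable[Site]],
                     annotation: GenomeAnnotation,
                     universe_sites: Optional[Iterable[Site]] = None,
                     flank: int = 2000, body_bins: int = 20,
                     flank_bin_bp: int = 100) -> MetageneProfile:
    """Positional distribution of sites across genes and flanks.

    Every site falling within a gene's body or its ``flank``-bp up/down
    regions contributes to one bin per such gene (multi-gene multiplicity
    is kept, matching per-gene averaging).  Genes shorter than ``body_bins``
    bp are skipped and counted.  With ``universe_sites`` (typically the
    jointly covered CG sites) densities are count / universe count per bin.
    """
    if flank % flank_bin_bp != 0:
        raise ValueError("flank must be a multiple of flank_bin_bp")
    n_flank_bins = flank // flank_bin_bp
    n_bins = 2 * n_flank_bins + body_bins

    genes = [g for g in annotation.genes if g.length >= body_bins]
    n_skipped = len(annotation.genes) - len(genes)
    span_tree: dict[str, IntervalTree] = {}
    for gene in genes:
        lo = max(0, gene.start - flank)
        hi = min(annotation.chromosomes[gene.chrom], gene.end + flank)
        span_tree.setdefault(gene.chrom, IntervalTree()).addi(lo, hi, gene)

    def bin_counts(sites: Iterable[Site]) -> np.ndarray:
        counts = np.zeros(n_bins, dtype=np.int64)
        for chrom, pos, _strand in sites:
            tree = span_tree.get(chrom)
            if tree is None:
                continue
            for iv in tree[pos]:
                b = _site_bin(pos, iv.data, flank, body_bins, flank_bin_bp)
                if b is not None:
                    counts[b] += 1
        return counts

    counts = pd.DataFrame(
        {cls: bin_counts(sites) for cls, sites in class_sites.items()}
    ).T
    counts.index.name = "class"

    universe_counts = None
    if universe_sites is not None:
        universe_counts = pd.Series(bin_counts(universe_sites))
        denom = universe_counts.to_numpy().astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(denom > 0, counts.to_numpy() / denom, 0.0)
        densities = pd.DataFrame(dens, index=counts.index, columns=counts.columns)
    else:
        densities = counts.astype(float)

    return MetageneProfile(
        counts=counts, densities=densities, universe_counts=universe_counts,
        n_genes_used=len(genes), n_genes_skipped=n_skipped,
        n_flank_bins=n_flank_bins, body_bins=body_bins,
    )
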