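"""Per-individual mCG calling from bisulfite cytosine count reports.

A CG site is called methylated when its methylated-read count is improbably
high under a binomial background model: the per-read false-methylation
probability (bisulfite conversion failure plus sequencing error) is
estimated from non-CG cytosines — which are essentially unmethylated in the
organisms this pipeline targets — and each CG site's one-sided binomial
tail probability is corrected across all tested sites with
Benjamini-Hochberg.  Sites at adjusted value <= fdr_q are methylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

Site = tuple[str, int, str]  # (chrom, 0-based pos, strand)

_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_total"]

ERROR_RATE_FLOOR = 1e-4


class CountTableError(ValueError):
    pass


class SiteCountTable:
    """Per-cytosine methylated/total read counts for one individual.

    In memory positions are 0-based; the TSV dialect on disk is 1-based
    (chrom, pos, strand, context, count_methylated, count_total), matching
    the cytosine reports of standard bisulfite aligners.  Rows with zero
    coverage are allowed and define the cytosine universe for coverage
    summaries.
    """

    def __init__(self, df: pd.DataFrame, individual: str = "sample",
                 validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.individual = individual
        if validate:
            self.validate()

    def validate(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise CountTableError(f"missing columns: {missing}")
        m = self.df["count_methylated"].to_numpy()
        t = self.df["count_total"].to_numpy()
        if (m < 0).any() or (m > t).any():
            raise CountTableError("need 0 <= count_methylated <= count_total")
        bad = ~self.df["context"].isin(["CG", "CHG", "CHH"])
        if bad.any():
            raise CountTableError(
                f"unknown context values: {sorted(self.df.loc[bad, 'context'].unique())}")
        if self.df.duplicated(["chrom", "pos", "strand"]).any():
            raise CountTableError("(chrom, pos, strand) must be unique")

    def __len__(self) -> int:
        return len(self.df)

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["pos"] = out["pos"] + 1
        out.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def read_tsv(cls, path, individual: Optional[str] = None,
                 dialect: str = "methyldiff") -> "SiteCountTable":
        """Read a cytosine report.

        ``dialect='methyldiff'``: chrom, pos(1-based), strand, context,
        count_methylated, count_total.  ``dialect='cx'``: the common aligner
        CX-report order chrom, pos, strand, count_methylated,
        count_unmethylated, context[, trinucleotide].
        """
        if dialect == "methyldiff":
            df = pd.read_csv(path, sep="\t", header=None, names=_COLUMNS)
        elif dialect == "cx":
            df = pd.read_csv(
                path, sep="\t", header=None,
                names=["chrom", "pos", "strand", "count_methylated",
                       "count_unmethylated", "context", "tri"],
                usecols=range(6),
            )
            df["count_total"] = df["count_methylated"] + df["count_unmethylated"]
            df = df[_COLUMNS]
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        df["pos"] = df["pos"].astype(int) - 1
        name = individual if individual is not None else str(path)
        return cls(df, individual=name)


@dataclass(frozen=True)
class CallingParams:
    error_rate: Optional[float] = None  # estimated from non-CG sites when None
    fdr_q: float = 0.01
    min_depth: int = 1
    merge_strands: bool = False

    def validate(self) -> None:
        if self.error_rate is not None and not 0.0 < self.error_rate < 1.0:
            raise ValueError("error_rate must lie in (0, 1)")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class MethylationCallSet:
    """Called mCG sites of one individual, with the tested-coverage universe."""

    individual: str
    methylated: frozenset
    covered: frozenset
    params: CallingParams
    table: pd.DataFrame = field(repr=False, default=None)  # per tested site: counts, q_value, called

    def __post_init__(self):
        if not self.methylated <= self.covered:
            raise ValueError("methylated sites must be a subset of covered sites")

    def to_bed(self, path) -> None:
        out = self.table.copy()
        out["start"] = out["pos"]
        out["end"] = out["pos"] + 1
        out[["chrom", "start", "end", "strand", "count_methylated",
             "count_total", "q_value", "called"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def read_bed(cls, path, individual: str, params: Optional[CallingParams] = None
                 ) -> "MethylationCallSet":
        df = pd.read_csv(path, sep="\t")
        df["pos"] = df["start"]
        sites = list(zip(df["chrom"], df["pos"], df["strand"]))
        called = df["called"].astype(bool)
        return cls(
            individual=individual,
            methylated=frozenset(s for s, c in zip(sites, called) if c),
            covered=frozenset(sites),
            params=params or CallingParams(),
            table=df,
        )


def estimate_error_rate(counts: SiteCountTable, min_background_reads: int = 1000,
                        floor: float = ERROR_RATE_FLOOR) -> float:
    """Per-read false-methylation probability from the non-CG background.

    Non-CG cytosines are treated as truly unmethylated, so their pooled
    methylated/total read ratio estimates conversion failure plus error.
    The estimate is clamped to at least ``floor`` to keep the binomial
    test proper when the background is spotless.
    """
    noncg = counts.df[counts.df["context"] != "CG"]
    total = int(noncg["count_total"].sum())
    if total == 0:
        raise CountTableError(
            "no non-CG reads to estimate the error rate from; "
            "supply error_rate explicitly")
    if total < min_background_reads:
        raise CountTableError(
            f"only {total} non-CG background reads (< {min_background_reads}); "
            "supply error_rate explicitly or lower min_background_reads")
    rate = float(noncg["count_methylated"].sum()) / total
    return min(max(rate, floor), 1.0 - floor)


def _merge_cg_strands(cg: pd.DataFrame) -> pd.DataFrame:
    """Pool the two strand records of each CpG onto the dinucleotide start."""
    cg = cg.copy()
    cg["dinuc_pos"] = np.where(cg["strand"] == "+", cg["pos"], cg["pos"] - 1)
    merged = (
        cg.groupby(["chrom", "dinuc_pos"], as_index=False)[
            ["count_methylated", "count_total"]].sum()
    )
    merged["pos"] = merged["dinuc_pos"]
    merged["strand"] = "+"
    merged["context"] = "CG"
    return merged[_COLUMNS]


def call_mcg(counts: SiteCountTable, params: CallingParams) -> MethylationCallSet:
    """Binomial-against-background mCG calling with BH-FDR across sites.

    Tests every CG record with count_total >= min_depth; the covered set of
    the result is exactly the tested universe.  With ``merge_strands`` the
    two strand records of a CpG are pooled and called once at the
    dinucleotide start on the '+' strand.
    """
    params.validate()
    error_rate = params.error_rate
    if error_rate is None:
        error_rate = estimate_error_rate(counts)
    if error_rate >= 0.5:
        raise ValueError(
            f"error_rate {error_rate} >= 0.5: background this noisy cannot "
            "support one-sided methylation calls")

    cg = counts.df[counts.df["context"] == "CG"]
    if params.merge_strands:
        cg = _merge_cg_strands(cg)
    tested = cg[cg["count_total"] >= params.min_depth].reset_index(drop=True)
    if len(tested) == 0:
        empty = pd.DataFrame(columns=_COLUMNS + ["p_value", "q_value", "called"])
        return MethylationCallSet(counts.individual, frozenset(), frozenset(),
                                  params, empty)

    m = tested["count_methylated"].to_numpy()
    t = tested["count_total"].to_numpy()
    # one-sided upper tail: P(X >= m) under Binomial(t, error_rate)
    pvals = stats.binom.sf(m - 1, t, error_rate)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    called = (qvals <= params.fdr_q) & (m > 0)

    out = tested.copy()
    out["p_value"] = pvals
    out["q_value"] = qvals
    out["called"] = called

    sites = list(zip(out["chrom"], out["pos"], out["strand"]))
    methylated = frozenset(s for s, c in zip(sites, called) if c)
    return MethylationCallSet(counts.individual, methylated, frozenset(sites),
                              params, out)


@dataclass(frozen=True)
class CoverageSummary:
    mean_depth_per_strand: float
    covered_fraction: float


def coverage_summary(counts: SiteCountTable,
                     n_cytosine_sites: Optional[int] = None) -> CoverageSummary:
    """Mean per-strand depth and the fraction of cytosines with any read.

    The cytosine universe is the table's rows (reports should enumerate
    zero-coverage sites); pass ``n_cytosine_sites`` to use an external
    universe size instead.
    """
    n = n_cytosine_sites if n_cytosine_sites is not None else len(counts.df)
    if n == 0:
        return CoverageSummary(0.0, 0.0)
    total = float(counts.df["count_total"].sum())
    covered = int((counts.df["count_total"] > 0).sum())
    return CoverageSummary(total / n, covered / n)
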