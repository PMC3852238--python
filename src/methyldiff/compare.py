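"""Cross-group CMC/DMC classification by methylation presence across individuals.

The rule is presence/absence, not level-based: over CG sites covered in both
groups, a site methylated in at least ``min_methylated_in`` individuals of
one group but in no more than ``max_methylated_out`` of the other is a
group-specific differentially methylated cytosine (DMC); a site methylated
in at least ``min_methylated_in`` individuals of both groups is a conserved
methylated cytosine (CMC).  Defaults (3, 1) suit a 3 + 4 cohort.

Two readings of "covered in both groups" are supported.  ``literal``: any
individual of each group covers the site (uncovered individuals count as
unmethylated).  ``strict`` (default): at least ``min_methylated_in``
individuals per group cover the site, so absence of a call is backed by
actual coverage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import MethylationCallSet, Site

CLASSES = ("CMC", "DMC_A", "DMC_B", "unclassified")


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class GroupDesign:
    """Mapping of individuals to exactly two ordered groups."""

    groups: Mapping[str, Sequence[str]]

    def __post_init__(self):
        if len(self.groups) != 2:
            raise DesignError(f"need exactly two groups, got {list(self.groups)}")
        ids = [i for members in self.groups.values() for i in members]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise DesignError(f"duplicate individual ids: {dupes}")
        for name, members in self.groups.items():
            if len(members) < 3:
                raise DesignError(
                    f"group {name!r} has {len(members)} individuals; the "
                    "classification thresholds require at least 3 per group")

    @property
    def group_a(self) -> str:
        return next(iter(self.groups))

    @property
    def group_b(self) -> str:
        return list(self.groups)[1]

    @property
    def group_a_individuals(self) -> list[str]:
        return list(self.groups[self.group_a])

    @property
    def group_b_individuals(self) -> list[str]:
        return list(self.groups[self.group_b])

    @property
    def individuals(self) -> list[str]:
        return self.group_a_individuals + self.group_b_individuals

    def swapped(self) -> "GroupDesign":
        a, b = self.group_a, self.group_b
        return GroupDesign({b: self.groups[b], a: self.groups[a]})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for group, members in self.groups.items():
                for ind in members:
                    fh.write(f"{ind}\t{group}\n")

    @classmethod
    def from_tsv(cls, path) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", header=None, names=["individual", "group"])
        groups: dict[str, list[str]] = {}
        for r in df.itertuples():
            groups.setdefault(str(r.group), []).append(str(r.individual))
        return cls(groups)


@dataclass(frozen=True)
class ClassificationParams:
    min_methylated_in: int = 3
    max_methylated_out: int = 1
    eligibility: str = "strict"  # or "literal"

    def validate(self) -> None:
        if not self.min_methylated_in > self.max_methylated_out >= 0:
            raise ValueError("need min_methylated_in > max_methylated_out >= 0")
        if self.eligibility not in ("strict", "literal"):
            raise ValueError(f"unknown eligibility mode {self.eligibility!r}")


def classify_site(methylated_in_a: int, covered_in_a: int,
                  methylated_in_b: int, covered_in_b: int,
                  params: ClassificationParams = ClassificationParams()) -> str:
    """Classify one jointly covered site from per-group methylated counts."""
    if methylated_in_a > covered_in_a or methylated_in_b > covered_in_b:
        raise ValueError("methylated count exceeds covered count")
    k, x = params.min_methylated_in, params.max_methylated_out
    if methylated_in_a >= k and methylated_in_b <= x:
        return "DMC_A"
    if methylated_in_b >= k and methylated_in_a <= x:
        return "DMC_B"
    if methylated_in_a >= k and methylated_in_b >= k:
        return "CMC"
    return "unclassified"


def _check_design(callsets: Mapping[str, MethylationCallSet],
                  design: GroupDesign) -> None:
    missing = [i for i in design.individuals if i not in callsets]
    if missing:
        raise DesignError(f"no call set for designed individuals: {missing}")


def _site_counts(callsets: Mapping[str, MethylationCallSet],
                 individuals: Iterable[str]) -> pd.DataFrame:
    """Per-site covered / methylated individual counts for one group."""
    frames = []
    for ind in individuals:
        cs = callsets[ind]
        if not cs.covered:
            continue
        df = pd.DataFrame(list(cs.covered), columns=["chrom", "pos", "strand"])
        keys = list(zip(df["chrom"], df["pos"], df["strand"]))
        df["covered"] = 1
        df["methylated"] = [k in cs.methylated for k in keys]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "covered", "methylated"])
    both = pd.concat(frames, ignore_index=True)
    return both.groupby(["chrom", "pos", "strand"], as_index=False)[
        ["covered", "methylated"]].sum()


def joint_coverage_universe(callsets: Mapping[str, MethylationCallSet],
                            design: GroupDesign,
                            params: ClassificationParams = ClassificationParams()
                            ) -> frozenset:
    """Sites eligible for classification under the chosen coverage reading."""
    params.validate()
    _check_design(callsets, design)
    need = 1 if params.eligibility == "literal" else params.min_methylated_in
    cov_a = _site_counts(callsets, design.group_a_individuals)
    cov_b = _site_counts(callsets, design.group_b_individuals)
    a = cov_a[cov_a["covered"] >= need]
    b = cov_b[cov_b["covered"] >= need]
    sites_a = set(zip(a["chrom"], a["pos"], a["strand"]))
    sites_b = set(zip(b["chrom"], b["pos"], b["strand"]))
    return frozenset(sites_a & sites_b)


@dataclass
class ComparativeCallSet:
    """Per-site classes over the joint-coverage universe, with totals."""

    df: pd.DataFrame  # chrom, pos, strand, m_a, c_a, m_b, c_b, cls
    design: GroupDesign
    params: ClassificationParams

    @property
    def n_cmc(self) -> int:
        return int((self.df["cls"] == "CMC").sum())

    @property
    def n_dmc_a(self) -> int:
        return int((self.df["cls"] == "DMC_A").sum())

    @property
    def n_dmc_b(self) -> int:
        return int((self.df["cls"] == "DMC_B").sum())

    @property
    def n_dmc(self) -> int:
        return self.n_dmc_a + self.n_dmc_b

    @property
    def universe_size(self) -> int:
        return len(self.df)

    @property
    def dmc_ratio(self) -> float:
        """Group-A : group-B DMC count ratio (nan when no group-B DMCs)."""
        return self.n_dmc_a / self.n_dmc_b if self.n_dmc_b else float("nan")

    def sites_of_class(self, cls: str) -> frozenset:
        sub = self.df[self.df["cls"] == cls]
        return frozenset(zip(sub["chrom"], sub["pos"], sub["strand"]))

    def dmc_table(self) -> pd.DataFrame:
        """Sorted DMC sites with direction column ('A' or 'B'), for clustering."""
        sub = self.df[self.df["cls"].isin(["DMC_A", "DMC_B"])].copy()
        sub["direction"] = sub["cls"].str[-1]
        return sub[["chrom", "pos", "strand", "direction"]].sort_values(
            ["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)

    def write_beds(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = {
            "CMC": "cmc.bed",
            "DMC_A": f"dmc_{self.design.group_a}.bed",
            "DMC_B": f"dmc_{self.design.group_b}.bed",
        }
        for cls, fname in names.items():
            sub = self.df[self.df["cls"] == cls].sort_values(
                ["chrom", "pos", "strand"])
            with open(outdir / fname, "w") as fh:
                for r in sub.itertuples():
                    fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{cls}\t0\t{r.strand}\n")

    def summary(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "n_cmc": self.n_cmc,
            f"n_dmc_{self.design.group_a}": self.n_dmc_a,
            f"n_dmc_{self.design.group_b}": self.n_dmc_b,
            "dmc_ratio": self.dmc_ratio,
        }


def classify_all(callsets: Mapping[str, MethylationCallSet],
                 design: GroupDesign,
                 params: ClassificationParams = ClassificationParams()
                 ) -> ComparativeCallSet:
    """Apply the presence/absence rule over the joint-coverage universe."""
    params.validate()
    _check_design(callsets, design)
    need = 1 if params.eligibility == "literal" else params.min_methylated_in
    cov_a = _site_counts(callsets, design.group_a_individuals).rename(
        columns={"covered": "c_a", "methylated": "m_a"})
    cov_b = _site_counts(callsets, design.group_b_individuals).rename(
        columns={"covered": "c_b", "methylated": "m_b"})
    df = cov_a.merge(cov_b, on=["chrom", "pos", "strand"], how="inner")
    df = df[(df["c_a"] >= need) & (df["c_b"] >= need)].reset_index(drop=True)

    k, x = params.min_methylated_in, params.max_methylated_out
    m_a = df["m_a"].to_numpy()
    m_b = df["m_b"].to_numpy()
    cls = pd.Series("unclassified", index=df.index, dtype=object)
    cls[(m_a >= k) & (m_b <= x)] = "DMC_A"
    cls[(m_b >= k) & (m_a <= x)] = "DMC_B"
    cls[(m_a >= k) & (m_b >= k)] = "CMC"
    df["cls"] = cls
    df = df[["chrom", "pos", "strand", "m_a", "c_a", "m_b", "c_b", "cls"]]
    return ComparativeCallSet(df, design, params)
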