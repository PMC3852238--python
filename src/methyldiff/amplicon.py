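"""Amplicon bisulfite validation: read matching, site levels, fixation test.

Reads from targeted bisulfite PCR (with per-read individual ids already
assigned by barcode demultiplexing upstream) are matched to their target
region by local alignment in bisulfite space (both read and target with
C -> T applied), per-cytosine methylation states are read off at
reference-C positions (C = methylated, T = converted), and per-site
methylation levels are the ratio of methylated to covering reads, either
per individual or pooled per sample set.

A region is informative when enough new individuals of each group have
covering data; a differential cluster is called fixed when at least
``fixation_min_consistent_per_group`` individuals per group have every
tested site on the expected side of the level thresholds.

Matching is forward-strand: reads from the opposite bisulfite strand are
supported by listing that strand's target sequence as its own entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import Align, SeqIO


@dataclass(frozen=True)
class FixationParams:
    min_read_len: int = 100
    min_new_group_a: int = 3
    min_new_group_b: int = 2
    fixation_min_consistent_per_group: int = 2
    level_threshold_low: float = 0.2
    level_threshold_high: float = 0.5

    def validate(self) -> None:
        if not 0.0 <= self.level_threshold_low < self.level_threshold_high <= 1.0:
            raise ValueError("need 0 <= low < high <= 1 for level thresholds")
        if self.min_read_len < 1:
            raise ValueError("min_read_len must be >= 1")


@dataclass
class AmpliconRead:
    read_id: str
    individual: str
    sequence: str


@dataclass
class AmpliconReadSet:
    """Target sequences plus individually labelled reads."""

    targets: dict[str, str]
    reads: list[AmpliconRead] = field(default_factory=list)

    def validate(self) -> None:
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("region ids must be unique")
        for read in self.reads:
            if set(read.sequence.upper()) - set("ACGTN"):
                raise ValueError(f"read {read.read_id}: non-nucleotide characters")

    @classmethod
    def from_fasta(cls, targets_fasta, reads_fasta,
                   individual_map: Optional[Mapping[str, str]] = None
                   ) -> "AmpliconReadSet":
        """Targets and reads from FASTA/FASTQ.

        The individual of each read comes from ``individual_map`` (read id ->
        individual) when given, otherwise from a ``individual=`` key in the
        description, otherwise the part of the read id before the first '/'.
        """
        targets = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(targets_fasta), "fasta")}
        fmt = "fastq" if str(reads_fasta).endswith(("fastq", "fq")) else "fasta"
        reads = []
        for rec in SeqIO.parse(str(reads_fasta), fmt):
            if individual_map and rec.id in individual_map:
                ind = individual_map[rec.id]
            elif "individual=" in rec.description:
                ind = rec.description.split("individual=")[1].split()[0]
            else:
                ind = rec.id.split("/")[0]
            reads.append(AmpliconRead(rec.id, ind, str(rec.seq).upper()))
        rs = cls(targets, reads)
        rs.validate()
        return rs


@dataclass
class MatchedReads:
    """Per-read per-reference-C methylation states after target assignment."""

    states: pd.DataFrame  # read_id, individual, region, pos, methylated (bool)
    n_unmatched: int
    targets: dict[str, str]

    def covered_individuals(self, region: str) -> frozenset:
        sub = self.states[self.states["region"] == region]
        return frozenset(sub["individual"].unique())


def _bisulfite_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def cg_positions(target: str) -> list[int]:
    """0-based positions of the C of each CpG on the forward strand."""
    target = target.upper()
    return [i for i in range(len(target) - 1) if target[i:i + 2] == "CG"]


def match_reads(readset: AmpliconReadSet,
                params: FixationParams = FixationParams()) -> MatchedReads:
    """Assign each read to its best target and score reference-C positions.

    Alignment happens with C -> T applied to both sequences so that
    methylation differences do not penalise the match; matches whose
    aligned target span is shorter than ``min_read_len`` are discarded.
    """
    params.validate()
    readset.validate()
    aligner = _bisulfite_aligner()
    t_space = {rid: seq.upper().replace("C", "T")
               for rid, seq in readset.targets.items()}

    rows = []
    n_unmatched = 0
    for read in readset.reads:
        read_seq = read.sequence.upper()
        r_space = read_seq.replace("C", "T")
        best = None
        for region, tseq in t_space.items():
            alignments = aligner.align(tseq, r_space)
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            if best is None or aln.score > best[1].score:
                best = (region, aln)
        if best is None:
            n_unmatched += 1
            continue
        region, aln = best
        t_blocks, r_blocks = aln.aligned
        matched_len = int(sum(e - s for s, e in t_blocks))
        if matched_len < params.min_read_len:
            n_unmatched += 1
            continue
        target_seq = readset.targets[region].upper()
        for (ts, te), (rs, _re) in zip(t_blocks, r_blocks):
            for off in range(te - ts):
                tpos = ts + off
                if target_seq[tpos] != "C":
                    continue
                base = read_seq[rs + off]
                if base == "C":
                    rows.append((read.read_id, read.individual, region, tpos, True))
                elif base == "T":
                    rows.append((read.read_id, read.individual, region, tpos, False))
                # other bases: ambiguous, not scored
    states = pd.DataFrame(
        rows, columns=["read_id", "individual", "region", "pos", "methylated"])
    return MatchedReads(states=states, n_unmatched=n_unmatched,
                        targets=dict(readset.targets))


def site_levels(matched: MatchedReads, grouping: str = "individual",
                sample_sets: Optional[Mapping[str, str]] = None,
                cg_only: bool = True) -> pd.DataFrame:
    """Per-site methylation levels: methylated reads / covering reads.

    ``grouping='individual'`` reports one row per (region, pos, individual);
    ``grouping='sample_set'`` pools individuals through ``sample_sets``
    (individual -> set id) before taking the ratio.  With ``cg_only`` the
    sites are restricted to CpG cytosines of each target.
    """
    df = matched.states
    if cg_only:
        keep = pd.Series(False, index=df.index)
        for region, target in matched.targets.items():
            cgs = set(cg_positions(target))
            mask = (df["region"] == region) & df["pos"].isin(cgs)
            keep |= mask
        df = df[keep]
    if grouping == "individual":
        df = df.assign(unit=df["individual"])
    elif grouping == "sample_set":
        if sample_sets is None:
            raise ValueError("sample_sets mapping required for grouping='sample_set'")
        df = df.assign(unit=df["individual"].map(sample_sets))
        df = df[df["unit"].notna()]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    grouped = df.groupby(["region", "pos", "unit"], as_index=False).agg(
        n_methylated=("methylated", "sum"), n_covering=("methylated", "size"))
    grouped["level"] = grouped["n_methylated"] / grouped["n_covering"]
    return grouped


def region_informative(covered_individuals: Iterable[str],
                       design: Mapping[str, str],
                       params: FixationParams = FixationParams(),
                       roster: Optional[Iterable[str]] = None) -> str:
    """'fully_covered' | 'informative' | 'insufficient' for one region.

    ``design`` maps each new individual to 'a' or 'b' (or the two group
    names in the order A, B).  ``roster`` is the full set of expected
    individuals; when given and all are covered the region is fully_covered.
    """
    params.validate()
    covered = set(covered_individuals)
    labels = sorted(set(design.values()))
    if set(labels) <= {"a", "b"}:
        a_label, b_label = "a", "b"
    elif len(labels) == 2:
        a_label, b_label = labels[0], labels[1]
    else:
        raise ValueError("design must map individuals to exactly two groups")
    n_a = sum(1 for i in covered if design.get(i) == a_label)
    n_b = sum(1 for i in covered if design.get(i) == b_label)
    if roster is not None and set(roster) <= covered:
        return "fully_covered"
    if n_a >= params.min_new_group_a and n_b >= params.min_new_group_b:
        return "informative"
    return "insufficient"


def fixation_test(levels: pd.DataFrame, expected_direction: str,
                  design: Mapping[str, str],
                  params: FixationParams = FixationParams(),
                  status: Optional[str] = None) -> str:
    """'fixed' | 'not_fixed' | 'insufficient' for one region's cluster.

    ``levels`` holds per-individual rows (columns unit, level) for the
    tested sites of one region.  ``expected_direction`` is 'a_hypo' (group A
    expected unmethylated, group B methylated) or 'a_hyper'.  An individual
    is consistent when every one of its tested sites lies on the expected
    side: level <= low threshold in its hypo group, level >= high threshold
    in its hyper group.
    """
    params.validate()
    if status == "insufficient":
        return "insufficient"
    if expected_direction not in ("a_hypo", "a_hyper"):
        raise ValueError("expected_direction must be 'a_hypo' or 'a_hyper'")
    labels = sorted(set(design.values()))
    if set(labels) <= {"a", "b"}:
        a_label, b_label = "a", "b"
    else:
        a_label, b_label = labels[0], labels[1]
    hypo_label = a_label if expected_direction == "a_hypo" else b_label

    consistent = {a_label: 0, b_label: 0}
    for unit, sub in levels.groupby("unit"):
        group = design.get(str(unit))
        if group is None or len(sub) == 0:
            continue
        lv = sub["level"]
        if group == hypo_label:
            ok = bool((lv <= params.level_threshold_low).all())
        else:
            ok = bool((lv >= params.level_threshold_high).all())
        if ok:
            consistent[group] += 1
    need = params.fixation_min_consistent_per_group
    if consistent[a_label] >= need and consistent[b_label] >= need:
        return "fixed"
    return "not_fixed"


def fixation_report(region_results: Mapping[str, str]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(region, outcome) for region, outcome in region_results.items()],
        columns=["region", "outcome"])
    return df.sort_values("region").reset_index(drop=True)
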