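"""Gene-catalog abundance profiling and nonparametric group comparison.

Reads are assigned to catalog gene families by k-mer plurality voting,
samples with shallow sequencing are dropped, counts are normalized to counts
per million (CPM) against each sample's *total* read count, and disease
groups (nonIBD, UC, CD) are compared pairwise with two-sided Mann-Whitney U
tests, unadjusted by default.  A Shapiro-Wilk normality report accompanies
each comparison set, documenting why a rank test is used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("gudgar.abundance")

GROUPS = ("nonIBD", "UC", "CD")
#: gene subsets matching the two reported screens: the E. coli-homolog set
#: and the alternative aldolase alone
GENE_SUBSET_PRESETS = {
    "homolog_set": ("gudD", "garD", "garR", "garL"),
    "gudL_only": ("gudL",),
}


@dataclass
class CountMatrix:
    """Samples x gene-family counts with library sizes and group labels."""

    counts: pd.DataFrame  # rows: samples, columns: families, ints >= 0
    library_size: pd.Series  # total reads per sample (mapped + unmapped)
    group: pd.Series  # per-sample label in GROUPS

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not self.counts.index.equals(self.library_size.index) or not self.counts.index.equals(
            self.group.index
        ):
            raise ValueError("counts, library_size and group must share the sample index")
        too_big = self.counts.sum(axis=1) > self.library_size
        if too_big.any():
            raise ValueError(
                f"catalog counts exceed library size for {list(self.counts.index[too_big])}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "library_size", self.library_size)
        out.to_csv(counts_path, sep="\t", index_label="sample_id")
        meta = pd.DataFrame(
            {"group": self.group, "library_size": self.library_size}
        )
        meta.to_csv(metadata_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, metadata_path: str | Path) -> "CountMatrix":
        tab = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
        meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
        lib = tab.pop("library_size")
        return cls(counts=tab, library_size=lib, group=meta["group"])


# ---------------------------------------------------------------------------
# k-mer read assignment


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class KmerIndex:
    k: int
    kmer_to_families: dict[str, frozenset]

    @classmethod
    def build(
        cls, catalog: Sequence[tuple[str, str]], family_of: Mapping[str, str], k: int = 21
    ) -> "KmerIndex":
        if k % 2 == 0:
            raise ValueError("k must be odd")
        index: dict[str, set[str]] = {}
        for gene_id, seq in catalog:
            fam = family_of[gene_id]
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], set()).add(fam)
        return cls(k=k, kmer_to_families={km: frozenset(v) for km, v in index.items()})


@dataclass
class AssignmentDiagnostics:
    n_assigned: int = 0
    n_unassigned: int = 0
    n_too_short: int = 0


def assign_reads(
    reads: Iterable[tuple[str, str]],
    index: KmerIndex,
    min_frac: float = 0.5,
) -> tuple[dict[str, int], AssignmentDiagnostics]:
    """Assign each read to the family holding a strict plurality of its k-mers.

    Both strands of the read are considered (the better-matching strand
    votes).  A read is assigned when the top family's matching k-mers are a
    strict plurality and at least *min_frac* of the read's k-mers; ties and
    sub-threshold votes leave the read unassigned.  Reads shorter than k are
    tallied separately.
    """
    k = index.k
    counts: dict[str, int] = {}
    diag = AssignmentDiagnostics()
    for _, seq in reads:
        seq = seq.upper()
        if len(seq) < k:
            diag.n_too_short += 1
            continue
        n_kmers = len(seq) - k + 1
        best_votes: dict[str, int] | None = None
        for strand_seq in (seq, _revcomp(seq)):
            votes: dict[str, int] = {}
            for i in range(n_kmers):
                fams = index.kmer_to_families.get(strand_seq[i : i + k])
                if fams:
                    for fam in fams:
                        votes[fam] = votes.get(fam, 0) + 1
            if best_votes is None or (
                votes and max(votes.values(), default=0) > max(best_votes.values(), default=0)
            ):
                best_votes = votes
        votes = best_votes or {}
        if not votes:
            diag.n_unassigned += 1
            continue
        top = max(votes.values())
        winners = [fam for fam, v in votes.items() if v == top]
        if len(winners) != 1 or top < min_frac * n_kmers:
            diag.n_unassigned += 1
            continue
        counts[winners[0]] = counts.get(winners[0], 0) + 1
        diag.n_assigned += 1
    return counts, diag


def profile_samples(
    sample_reads: Mapping[str, Sequence[tuple[str, str]]],
    index: KmerIndex,
    groups: Mapping[str, str],
    min_frac: float = 0.5,
    library_sizes: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Assign every sample's reads and assemble a CountMatrix.

    Library size defaults to the number of reads in the sample (every read in
    a synthetic FASTQ is 'sequenced'); pass *library_sizes* to override with
    the true totals when the input is a pre-filtered subset.
    """
    families: set[str] = set()
    per_sample: dict[str, dict[str, int]] = {}
    libs: dict[str, int] = {}
    for sample, reads in sample_reads.items():
        counts, _ = assign_reads(reads, index, min_frac=min_frac)
        per_sample[sample] = counts
        families.update(counts)
        libs[sample] = (
            library_sizes[sample] if library_sizes is not None else len(reads)
        )
    samples = sorted(per_sample)
    fams = sorted(families)
    mat = pd.DataFrame(
        [[per_sample[s].get(f, 0) for f in fams] for s in samples],
        index=samples,
        columns=fams,
    )
    return CountMatrix(
        counts=mat,
        library_size=pd.Series([libs[s] for s in samples], index=samples),
        group=pd.Series([groups[s] for s in samples], index=samples),
    )


# ---------------------------------------------------------------------------
# filtering and normalization


def filter_samples(matrix: CountMatrix, min_total_reads: int = 5_000_000) -> CountMatrix:
    """Drop samples whose library size is strictly below *min_total_reads*."""
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    keep = matrix.library_size >= min_total_reads
    if not keep.any():
        raise ValueError("every sample fell below the read-count threshold")
    return CountMatrix(
        counts=matrix.counts.loc[keep],
        library_size=matrix.library_size.loc[keep],
        group=matrix.group.loc[keep],
    )


def cpm_normalize(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million of *total* sample reads: counts / library_size * 1e6."""
    if (matrix.library_size <= 0).any():
        raise ValueError("zero library size")
    return matrix.counts.div(matrix.library_size, axis=0) * 1e6


# ---------------------------------------------------------------------------
# Mann-Whitney


@dataclass(frozen=True)
class TestResult:
    comparison: tuple[str, str]
    U: float  # rank statistic of the first-named group
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" or "normal_approx"


def mann_whitney(
    groupA_values: Sequence[float], groupB_values: Sequence[float], comparison=("A", "B")
) -> TestResult:
    """Two-sided Mann-Whitney U test; U is the statistic of the first group.

    The exact rank-sum null distribution is used when n1*n2 <= 10,000 and the
    pooled values carry no ties; otherwise the normal approximation with
    tie-corrected variance and continuity correction applies.
    """
    a = np.asarray(groupA_values, dtype=float)
    b = np.asarray(groupB_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = (a.size * b.size <= 10_000) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        comparison=tuple(comparison),
        U=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        n1=int(a.size),
        n2=int(b.size),
        method="exact" if exact else "normal_approx",
    )


# ---------------------------------------------------------------------------
# group comparison

COMPARISONS = (("CD", "nonIBD"), ("UC", "nonIBD"), ("UC", "CD"))


def compare_groups(
    cpm: pd.DataFrame,
    groups: pd.Series,
    gene_subset: Sequence[str] | str | None = None,
) -> tuple[list[TestResult], dict[str, tuple[float, float]]]:
    """Pairwise Mann-Whitney tests on per-sample summed CPM of a gene subset.

    *gene_subset* may be a list of families, a preset name ("homolog_set",
    "gudL_only"), or None for all families.  Returns the three pairwise test
    results (p-values unadjusted, mirroring the no-correction choice of the
    source analysis) and a per-group Shapiro-Wilk (W, p) normality report.
    Comparisons with a group of fewer than 2 samples are skipped with a
    warning.
    """
    if isinstance(gene_subset, str):
        if gene_subset not in GENE_SUBSET_PRESETS:
            raise ValueError(f"unknown gene-subset preset {gene_subset!r}")
        gene_subset = GENE_SUBSET_PRESETS[gene_subset]
    if gene_subset is None:
        gene_subset = list(cpm.columns)
    missing = [g for g in gene_subset if g not in cpm.columns]
    if missing:
        raise ValueError(f"families absent from the CPM matrix: {missing}")
    values = cpm[list(gene_subset)].sum(axis=1)

    normality: dict[str, tuple[float, float]] = {}
    for g in GROUPS:
        x = values[groups == g]
        if len(x) >= 3 and len(np.unique(x)) > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                W, p = stats.shapiro(x)
            normality[g] = (float(W), float(p))

    results: list[TestResult] = []
    for g1, g2 in COMPARISONS:
        x1, x2 = values[groups == g1], values[groups == g2]
        if len(x1) < 2 or len(x2) < 2:
            logger.warning("skipping %s vs %s: fewer than 2 samples in a group", g1, g2)
            continue
        results.append(mann_whitney(x1, x2, comparison=(g1, g2)))
    return results, normality


def holm_adjust(results: Sequence[TestResult]) -> list[TestResult]:
    """Optional Holm step-down adjustment of a comparison set's p-values."""
    order = sorted(range(len(results)), key=lambda i: results[i].p_two_sided)
    m = len(results)
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min((m - rank) * results[i].p_two_sided, 1.0))
        adjusted[i] = running
    return [
        TestResult(
            comparison=r.comparison,
            U=r.U,
            p_two_sided=adjusted[i],
            n1=r.n1,
            n2=r.n2,
            method=r.method,
        )
        for i, r in enumerate(results)
    ]


def write_results(
    results: Sequence[TestResult],
    normality: Mapping[str, tuple[float, float]],
    path: str | Path,
    adjusted: bool = False,
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# p_values: {'holm-adjusted' if adjusted else 'unadjusted'}\n")
        for g, (W, p) in normality.items():
            fh.write(f"# shapiro_wilk\t{g}\tW={W:.5f}\tp={p:.4g}\n")
        fh.write("group1\tgroup2\tn1\tn2\tU\tp\tmethod\n")
        for r in results:
            fh.write(
                f"{r.comparison[0]}\t{r.comparison[1]}\t{r.n1}\t{r.n2}\t"
                f"{r.U:.6g}\t{r.p_two_sided:.6g}\t{r.method}\n"
            )
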