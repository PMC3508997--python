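"""Expression co-correlation of duplicate groups against control groups.

For every duplicate group and every eligible expression dataset, Pearson
correlations (two-sided test) are computed between each pair of member
genes; a group's score is the proportion of those tests that are significant
at level alpha.  The same procedure applied to co-localised non-duplicated
genes and to randomly drawn genes provides the two control distributions,
and class means are compared with Welch's t-test.

Dataset eligibility mirrors the filters applied to public expression series:
at least 3 samples, every group member present, and no member profile that
is entirely missing or constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneIndex

__all__ = [
    "ExpressionDataset",
    "PairCorrelation",
    "GroupCorrelation",
    "ComparisonResult",
    "read_expression",
    "filter_datasets",
    "pairwise_pearson",
    "proportion_significant",
    "sample_control_groups",
    "compare_proportions",
    "compare_classes",
]

#: Default cap on group size for the expression analysis; expression data for
#: larger groups is typically too incomplete to test meaningfully.
MAX_GROUP_SIZE_EXPRESSION = 5


@dataclass
class ExpressionDataset:
    """One expression experiment: a genes x samples matrix, NaN = missing."""

    dataset_id: str
    matrix: pd.DataFrame  # rows: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.matrix.shape[0] < 1 or self.matrix.shape[1] < 1:
            raise ValueError(f"dataset {self.dataset_id}: empty matrix")
        if self.matrix.columns.duplicated().any():
            raise ValueError(f"dataset {self.dataset_id}: duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class PairCorrelation:
    dataset_id: str
    gene_a: str
    gene_b: str
    r: float
    p: float


@dataclass
class GroupCorrelation:
    """Per-group correlation outcome.

    proportion_significant is the pooled fraction of significant tests over
    all (pair x dataset) combinations; None when no test could be run or the
    group was skipped (see skipped_reason).  per_pair_proportions holds, for
    each gene pair, the fraction of datasets in which it was significant.
    """

    group_id: str
    records: list[PairCorrelation] = field(default_factory=list)
    n_tests: int = 0
    n_significant: int = 0
    n_skipped_pairs: int = 0
    proportion_significant: float | None = None
    per_pair_proportions: dict[tuple[str, str], float] = field(default_factory=dict)
    skipped_reason: str | None = None


@dataclass
class ComparisonResult:
    """Welch t-test comparisons between group-class proportion lists."""

    class_proportions: dict[str, list[float]]
    tests: dict[tuple[str, str], tuple[float, float]]  # (t, p) per class pair


def read_expression(path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    """Read a tab-delimited genes x samples matrix (first column gene ids).

    Empty cells and ``NA`` are treated as missing.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    return ExpressionDataset(
        dataset_id=dataset_id or Path(path).stem, matrix=frame.astype(float)
    )


def _profile_unusable(profile: pd.Series) -> bool:
    values = profile.dropna()
    return len(values) == 0 or values.nunique() <= 1


def filter_datasets(
    members: Iterable[str],
    datasets: Sequence[ExpressionDataset],
) -> list[ExpressionDataset]:
    """Datasets eligible for a group: >=3 samples, all members present,
    and no member profile entirely missing or constant."""
    members = list(members)
    eligible = []
    for ds in datasets:
        if ds.n_samples < 3:
            continue
        if not all(g in ds.matrix.index for g in members):
            continue
        if any(_profile_unusable(ds.matrix.loc[g]) for g in members):
            continue
        eligible.append(ds)
    return eligible


def pairwise_pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float] | None:
    """Pearson r and two-sided p-value between two expression profiles.

    Missing entries are removed pairwise-complete.  Returns None (the pair is
    skipped and counted by the caller) when fewer than 3 complete
    observations remain or either profile is constant; the p-value otherwise
    comes from the t distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def proportion_significant(
    group_id: str,
    members: Iterable[str],
    datasets: Sequence[ExpressionDataset],
    alpha: float = 0.05,
    max_group_size: int | None = MAX_GROUP_SIZE_EXPRESSION,
) -> GroupCorrelation:
    """Proportion of significant pairwise correlations for one gene group.

    Tests every member pair in every eligible dataset and pools: proportion =
    significant tests / valid tests.  Groups above *max_group_size* are
    skipped with a reason, as are groups with no eligible dataset.
    """
    members = sorted(set(members))
    result = GroupCorrelation(group_id=group_id)
    if max_group_size is not None and len(members) > max_group_size:
        result.skipped_reason = (
            f"group size {len(members)} exceeds cap {max_group_size}"
        )
        return result
    if len(members) < 2:
        result.skipped_reason = "fewer than 2 member genes"
        return result
    eligible = filter_datasets(members, datasets)
    if not eligible:
        result.skipped_reason = "no eligible expression dataset"
        return result

    per_pair_counts: dict[tuple[str, str], list[int]] = {}
    for ds in eligible:
        for a, b in combinations(members, 2):
            out = pairwise_pearson(ds.matrix.loc[a].values, ds.matrix.loc[b].values)
            if out is None:
                result.n_skipped_pairs += 1
                continue
            r, p = out
            result.records.append(PairCorrelation(ds.dataset_id, a, b, r, p))
            result.n_tests += 1
            sig = int(p < alpha)
            result.n_significant += sig
            per_pair_counts.setdefault((a, b), []).append(sig)
    if result.n_tests:
        result.proportion_significant = result.n_significant / result.n_tests
        result.per_pair_proportions = {
            pair: sum(v) / len(v) for pair, v in per_pair_counts.items()
        }
    else:
        result.skipped_reason = "no valid correlation test"
    return result


def sample_control_groups(
    index: GeneIndex,
    exclude: Iterable[str],
    kind: str,
    sizes: Sequence[int],
    seed: int | np.random.Generator = 0,
) -> list[set[str]]:
    """Draw control gene groups matched in size to the duplicate groups.

    ``kind='colocalised'`` samples runs of consecutive-rank genes none of
    which belongs to a duplicate group; ``kind='random'`` samples uniformly,
    without replacement within a group, from all non-duplicated genes.
    Reproducible for a fixed seed.
    """
    if kind not in {"colocalised", "random"}:
        raise ValueError(f"unknown control kind {kind!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excluded = set(exclude)
    eligible = [g.gene_id for g in index if g.gene_id not in excluded]
    if not sizes:
        return []
    if len(eligible) < max(sizes):
        raise ValueError("not enough non-duplicated genes to sample controls")

    groups: list[set[str]] = []
    if kind == "random":
        for size in sizes:
            pick = rng.choice(len(eligible), size=size, replace=False)
            groups.append({eligible[i] for i in pick})
        return groups

    # colocalised: runs of adjacent ranks avoiding excluded genes
    runs: list[list[str]] = []
    for genes in index.chromosomes.values():
        current: list[str] = []
        for g in genes:
            if g.gene_id in excluded:
                if current:
                    runs.append(current)
                current = []
            else:
                current.append(g.gene_id)
        if current:
            runs.append(current)
    for size in sizes:
        candidates = [
            (ri, start)
            for ri, run in enumerate(runs)
            for start in range(len(run) - size + 1)
        ]
        if not candidates:
            raise ValueError(
                f"no run of {size} consecutive non-duplicated genes available"
            )
        ri, start = candidates[rng.integers(len(candidates))]
        groups.append(set(runs[ri][start : start + size]))
    return groups


def compare_proportions(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t-test between proportion lists.

    Degenerate inputs (both classes constant) are resolved directly: equal
    means give (0, 1), unequal means (inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_classes(
    class_proportions: Mapping[str, Sequence[float]],
) -> ComparisonResult:
    """Welch t-tests between every pair of group classes.

    Typical classes are ``duplicated``, ``colocalised_nondup`` and
    ``random``; each maps to the list of per-group proportions of
    significant correlations (or of semantic-similarity means).
    """
    labels = sorted(class_proportions)
    tests = {
        (a, b): compare_proportions(class_proportions[a], class_proportions[b])
        for a, b in combinations(labels, 2)
    }
    return ComparisonResult(
        class_proportions={k: list(v) for k, v in class_proportions.items()},
        tests=tests,
    )
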