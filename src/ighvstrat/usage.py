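"""V-gene usage statistics.

Usage of a gene in a sample is the fraction of *clonotypes* carrying that
gene — the number of clonotypes using the gene divided by the total number
of clonotypes in the sample. It is deliberately unweighted by clone/read
counts: a hugely expanded clone contributes exactly one clonotype.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .association import bonferroni, mann_whitney
from .errors import UndefinedStatisticError
from .repertoire import BCellSubset, RepertoireSample

__all__ = ["UsageResult", "compute_usage", "usage_by_gene", "usage_matrix", "compare_subsets"]

DEFAULT_GENE = "IGHV4-34"


@dataclass(frozen=True)
class UsageResult:
    """Clonotype-usage fraction of one gene in one (patient, subset) sample."""

    patient_id: str
    subset: BCellSubset
    gene: str
    usage: float
    n_clonotypes: int


def compute_usage(sample: RepertoireSample, gene: str = DEFAULT_GENE) -> UsageResult:
    """Fraction of clonotypes in ``sample`` whose V gene is ``gene``.

    Raises :class:`UndefinedStatisticError` on an empty sample — usage of
    nothing is undefined, not zero.
    """
    n = len(sample)
    if n == 0:
        raise UndefinedStatisticError(
            f"usage undefined for empty sample {sample.patient_id}/{sample.subset}"
        )
    k = sum(1 for c in sample.clonotypes if c.v_gene == gene)
    return UsageResult(sample.patient_id, sample.subset, gene, k / n, n)


def usage_by_gene(sample: RepertoireSample) -> pd.Series:
    """Usage fraction for every gene present in the sample (sums to 1)."""
    n = len(sample)
    if n == 0:
        raise UndefinedStatisticError("usage undefined for empty sample")
    counts = sample.gene_clonotype_counts()
    return pd.Series({g: k / n for g, k in counts.items()}, name="usage")


def usage_matrix(
    samples: Iterable[RepertoireSample], gene: str = DEFAULT_GENE
) -> pd.DataFrame:
    """Long-format usage table: one row per available (patient, subset).

    Missing subsets yield absent rows, never zeros. A duplicated
    (patient, subset) pair is an error.
    """
    rows = []
    seen: set[tuple[str, BCellSubset]] = set()
    for sample in samples:
        key = (sample.patient_id, sample.subset)
        if key in seen:
            raise ValueError(f"duplicate sample for patient={key[0]} subset={key[1]}")
        seen.add(key)
        res = compute_usage(sample, gene)
        rows.append(
            {
                "patient_id": res.patient_id,
                "subset": res.subset.value,
                "gene": res.gene,
                "usage": res.usage,
                "n_clonotypes": res.n_clonotypes,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "subset", "gene", "usage", "n_clonotypes"])


@dataclass(frozen=True)
class SubsetComparison:
    """Rank-sum comparison of usage between two B-cell subsets."""

    subset_a: str
    subset_b: str
    n_a: int
    n_b: int
    statistic: float
    p_raw: float
    p_adj: float


def compare_subsets(matrix: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons of usage across subsets.

    Bonferroni family size m = number of comparisons actually emitted
    (10 for five subsets). Subsets with fewer than two observations are
    skipped with a warning and m reduced accordingly.
    """
    groups = {
        subset: sub["usage"].to_numpy()
        for subset, sub in matrix.groupby("subset", sort=False)
    }
    usable = {}
    for subset, values in groups.items():
        if len(values) < 2:
            warnings.warn(
                f"subset {subset} has <2 observations; skipped from pairwise comparisons",
                stacklevel=2,
            )
        else:
            usable[subset] = values
    if len(usable) < 2:
        raise UndefinedStatisticError("need >=2 subsets with >=2 observations each")
    order = [s.value for s in BCellSubset if s.value in usable]
    order += [s for s in usable if s not in order]
    pairs = list(itertools.combinations(order, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        stat, p = mann_whitney(usable[a], usable[b])
        rows.append(
            SubsetComparison(a, b, len(usable[a]), len(usable[b]), stat, p,
                             float(bonferroni([p], m)[0]))
        )
    return pd.DataFrame([r.__dict__ for r in rows])
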