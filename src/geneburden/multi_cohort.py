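"""Per-cohort counting, overlap exclusion, and combined-sample testing.

Replication across cohorts is done by naive count pooling: carrier and
total counts from pairwise-disjoint cohorts are summed element-wise and a
single one-sided exact test is run on the pooled 2x2 table. Disjointness
is the caller's responsibility and is supported two ways: an explicit
overlapping-sample-id set, or dropping entire cohorts that feed another
dataset (``subsumed_by`` in a registry). Stratified alternatives (e.g.
Cochran-Mantel-Haenszel) are deliberately out of scope — pooling keeps the
arithmetic identical to the published-table convention this package exists
to replay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association_stats import (
    BurdenResult,
    TwoByTwo,
    burden_counts,
    result_from_table,
    single_variant_test,
)
from .cohort_data import GenotypeMatrix, VariantSite
from .errors import ConfigError


@dataclass(frozen=True)
class CohortCounts:
    """Carrier/total counts for one label (gene or variant) in one cohort."""

    cohort_id: str
    label: str
    a: int
    n1: int
    b: int
    n2: int

    def __post_init__(self) -> None:
        TwoByTwo(self.a, self.n1, self.b, self.n2)  # validates invariants

    @property
    def table(self) -> TwoByTwo:
        return TwoByTwo(self.a, self.n1, self.b, self.n2)


def count_cohort(
    matrix: GenotypeMatrix,
    sites: list[VariantSite],
    label: str,
    cohort_id: str,
    denominators: str = "per_site",
) -> CohortCounts:
    """Build CohortCounts from genotypes.

    ``denominators="per_site"`` (single-variant convention, requires exactly
    one site): totals are per-site non-missing counts. ``"group"`` (burden
    convention): totals are group sizes, observations are (sample, site)
    carrier pairs.
    """
    if denominators == "per_site":
        if len(sites) != 1:
            raise ConfigError("per_site denominators require exactly one site")
        r = single_variant_test(matrix, sites[0])
        t = r.table
    elif denominators == "group":
        t = burden_counts(matrix, sites, gene=label)
    else:
        raise ConfigError(f"unknown denominators mode {denominators!r}")
    return CohortCounts(cohort_id=cohort_id, label=label,
                        a=t.a, n1=t.n1, b=t.b, n2=t.n2)


def exclude_overlap(
    matrix: GenotypeMatrix,
    sites: list[VariantSite],
    overlap_ids,
    label: str,
    cohort_id: str,
    denominators: str = "per_site",
) -> CohortCounts:
    """Recompute a cohort's counts after removing overlapping subjects.

    ``overlap_ids`` is a set of sample ids present in another dataset the
    cohort will be pooled with; the retained subjects are recounted from
    genotypes (an empty set reproduces the full-cohort counts).
    """
    overlap = set(overlap_ids)
    keep = np.array([s.sample_id not in overlap for s in matrix.samples], dtype=bool)
    return count_cohort(matrix.subset_samples(keep), sites, label, cohort_id,
                        denominators=denominators)


def samples_in_cohorts(samples, cohort_ids) -> set[str]:
    """Sample ids belonging to any of the named cohorts — the id set to
    exclude when whole cohorts are subsumed by another dataset."""
    wanted = set(cohort_ids)
    return {s.sample_id for s in samples if s.cohort_id in wanted}


def combine_counts(parts: list[CohortCounts]) -> CohortCounts:
    """Element-wise sum of disjoint cohorts' counts (associative,
    commutative). Duplicate cohort ids are rejected as a disjointness
    guard; labels must agree."""
    if not parts:
        raise ConfigError("combine_counts needs at least one cohort")
    ids = [p.cohort_id for p in parts]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicate cohort ids in combination: {ids}")
    labels = {p.label for p in parts}
    if len(labels) != 1:
        raise ConfigError(f"cannot combine different labels: {sorted(labels)}")
    return CohortCounts(
        cohort_id="+".join(ids), label=parts[0].label,
        a=sum(p.a for p in parts), n1=sum(p.n1 for p in parts),
        b=sum(p.b for p in parts), n2=sum(p.n2 for p in parts),
    )


def combined_test(parts: list[CohortCounts], m: int = 1) -> BurdenResult:
    """Pool disjoint cohorts and run the one-sided exact test + Woolf CI."""
    pooled = combine_counts(parts)
    return result_from_table(pooled.label, pooled.table, m_genes=m)
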