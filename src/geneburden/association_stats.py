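"""Exact one-sided 2x2 inference and burden counting.

The collapsing (burden) test reduces each gene to a 2x2 table::

              qualifying obs    subjects
    cases          a               n1
    controls       b               n2

and asks whether qualifying-variant observations are enriched in cases.
Significance is the one-sided Fisher exact (upper-tail hypergeometric)
probability of observing >= a case observations given the margins; effect
size is the unconditional sample odds ratio on the carriers vs non-carriers
cells with a Woolf (log-scale) confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .cohort_data import GenotypeMatrix, VariantSite, MISSING
from .errors import DegenerateDataError

Z_95 = 1.959964  # two-sided 95% normal quantile

#: how a carrier genotype contributes to the aggregated count
COUNT_RULES = ("per_site", "alleles", "per_sample")


@dataclass(frozen=True)
class TwoByTwo:
    """Qualifying observations and group totals: (a/n1 cases, b/n2 controls)."""

    a: int
    n1: int
    b: int
    n2: int

    def __post_init__(self) -> None:
        for name, value in (("a", self.a), ("n1", self.n1), ("b", self.b), ("n2", self.n2)):
            if int(value) != value or value < 0:
                raise DegenerateDataError(f"{name} must be a non-negative integer: {value}")
        if self.a > self.n1 or self.b > self.n2:
            raise DegenerateDataError(
                f"cell exceeds its margin: a={self.a}/n1={self.n1}, b={self.b}/n2={self.n2}"
            )


@dataclass(frozen=True)
class BurdenResult:
    """Test outcome for one gene or variant."""

    label: str
    table: TwoByTwo
    p_one_sided: float
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_bonferroni: float
    n_qualifying_sites: int = 0


def _log_hypergeom_pmf(k: np.ndarray, big_n: int, big_k: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(N, K, n) via log-factorials."""

    def lchoose(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    return lchoose(big_k, k) + lchoose(big_n - big_k, n - k) - lchoose(big_n, n)


def fisher_one_sided(t: TwoByTwo) -> float:
    """Upper-tail one-sided Fisher exact p for enrichment in cases.

    Sums hypergeometric point masses P(X >= a) with X the number of the
    a+b qualifying observations that fall in the case group, conditioning
    on all margins. Computed with log-factorials (gammaln) and a log-sum-exp
    reduction; relative accuracy is ~1e-14. A table with no observations
    (a+b = 0) carries no signal and returns 1.
    """
    total = t.a + t.b
    if total == 0:
        return 1.0
    big_n = t.n1 + t.n2
    k = np.arange(t.a, min(t.n1, total) + 1)
    logs = _log_hypergeom_pmf(k, big_n, total, t.n1)
    m = logs.max()
    p = float(np.exp(m) * np.exp(logs - m).sum())
    return min(p, 1.0)


def odds_ratio_woolf(
    t: TwoByTwo, z: float = Z_95
) -> tuple[float, float, float] | None:
    """Sample odds ratio with Woolf (log-scale) confidence interval.

    Cells are (a, n1-a, b, n2-b): carriers vs non-carriers. The interval is
    exp(ln OR +/- z * sqrt(1/a + 1/(n1-a) + 1/b + 1/(n2-b))). Any zero cell
    leaves OR and CI undefined (returns None); no continuity correction is
    applied.
    """
    a, b = t.a, t.b
    c, d = t.n1 - t.a, t.n2 - t.b
    if min(a, b, c, d) == 0:
        return None
    log_or = np.log(a) + np.log(d) - np.log(b) - np.log(c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (float(np.exp(log_or)),
            float(np.exp(log_or - z * se)),
            float(np.exp(log_or + z * se)))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p: min(1, m * p)."""
    if m < 1:
        raise DegenerateDataError(f"m must be >= 1, got {m}")
    return min(1.0, m * p)


def _site_columns(matrix: GenotypeMatrix, sites: list[VariantSite]) -> np.ndarray:
    index = {s.key: j for j, s in enumerate(matrix.sites)}
    try:
        return np.array([index[s.key] for s in sites], dtype=int)
    except KeyError as exc:
        raise KeyError(f"qualifying site not in matrix: {exc.args[0]}") from None


def burden_counts(
    matrix: GenotypeMatrix,
    qualifying: list[VariantSite],
    gene: str = "",
    count_rule: str = "per_site",
) -> TwoByTwo:
    """Aggregate qualifying-variant observations into a 2x2 table.

    Count rules (``per_site`` is the default and the one used throughout):

    * ``per_site`` — one observation per (sample, qualifying site) pair with
      a carrier genotype; a homozygote counts once per site, a sample
      carrying two qualifying sites counts twice.
    * ``alleles`` — observations are alternate-allele copies (homozygote
      counts 2).
    * ``per_sample`` — a sample counts at most once per gene (carrier
      collapsing in the strict CAST sense).

    Denominators are the post-QC group sizes. A count exceeding its group
    size raises, signalling that the chosen rule is inappropriate for the
    data (cannot happen with ``per_sample``; with rare variants it is not
    expected under the others either).
    """
    if count_rule not in COUNT_RULES:
        raise DegenerateDataError(f"unknown count_rule {count_rule!r}")
    case = matrix.case_mask
    if qualifying:
        cols = _site_columns(matrix, qualifying)
        calls = matrix.calls[:, cols]
        carrier = calls >= 1
        if count_rule == "per_site":
            per_sample = carrier.sum(axis=1)
        elif count_rule == "alleles":
            per_sample = np.where(carrier, calls, 0).sum(axis=1)
        else:
            per_sample = carrier.any(axis=1).astype(int)
        a = int(per_sample[case].sum())
        b = int(per_sample[~case].sum())
    else:
        a = b = 0
    return TwoByTwo(a=a, n1=int(case.sum()), b=b, n2=int((~case).sum()))


def gene_burden_test(
    matrix: GenotypeMatrix,
    qualifying: list[VariantSite],
    gene: str,
    m_genes: int = 1,
    count_rule: str = "per_site",
) -> BurdenResult:
    """Full burden test for one gene: count, exact p, OR/CI, Bonferroni."""
    table = burden_counts(matrix, qualifying, gene, count_rule=count_rule)
    return result_from_table(gene, table, m_genes=m_genes,
                             n_qualifying_sites=len(qualifying))


def single_variant_test(
    matrix: GenotypeMatrix, site: VariantSite, m_tests: int = 1
) -> BurdenResult:
    """One-sided exact test for a single site.

    Unlike the gene-level burden, denominators are the per-site non-missing
    call counts in each group (samples not called at the site are not
    at-risk observations for it).
    """
    j = matrix.site_index(site.key)
    calls = matrix.calls[:, j]
    case = matrix.case_mask
    called = calls != MISSING
    carrier = calls >= 1
    table = TwoByTwo(
        a=int((carrier & case).sum()), n1=int((called & case).sum()),
        b=int((carrier & ~case).sum()), n2=int((called & ~case).sum()),
    )
    label = site.rsid or f"{site.chrom}:{site.pos}:{site.ref}>{site.alt}"
    return result_from_table(label, table, m_genes=m_tests, n_qualifying_sites=1)


def result_from_table(
    label: str, table: TwoByTwo, m_genes: int = 1, n_qualifying_sites: int = 0
) -> BurdenResult:
    """Assemble a BurdenResult from an already-built 2x2 table."""
    p = fisher_one_sided(table)
    woolf = odds_ratio_woolf(table)
    or_, lo, hi = woolf if woolf is not None else (None, None, None)
    return BurdenResult(
        label=label, table=table, p_one_sided=p,
        odds_ratio=or_, ci_low=lo, ci_high=hi,
        p_bonferroni=bonferroni(p, m_genes),
        n_qualifying_sites=n_qualifying_sites,
    )


def replay_table(rows, m: int = 1) -> list[BurdenResult]:
    """Batch mode over (label, a, n1, b, n2) rows.

    Lets any published 2x2 table be re-tested directly, without genotypes.
    ``rows`` is an iterable of 5-tuples or of dicts with those keys.
    """
    results = []
    for row in rows:
        if isinstance(row, dict):
            label, a, n1, b, n2 = (row["label"], row["a"], row["n1"], row["b"], row["n2"])
        else:
            label, a, n1, b, n2 = row
        table = TwoByTwo(a=int(a), n1=int(n1), b=int(b), n2=int(n2))
        results.append(result_from_table(str(label), table, m_genes=m))
    return results
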