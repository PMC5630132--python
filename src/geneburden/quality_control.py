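"""Call-rate QC: sample filtering, per-group site filtering, coverage summary.

Ordering is fixed and deliberate: samples are filtered first on the full
site set (a sample must be genotyped for >= threshold of *all* assayed
variants), then sites are filtered on the reduced matrix, requiring the
call rate to reach the threshold within cases AND within controls
separately. All comparisons are inclusive (a rate of exactly 0.95 passes
a 0.95 threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_data import GenotypeMatrix, GeneTarget
from .errors import EmptyCohortError, ConfigError


@dataclass
class QcReport:
    """What QC did: in/out dimensions, removals with their call rates,
    and per-gene coverage percentages."""

    n_samples_in: int = 0
    n_samples_out: int = 0
    n_sites_in: int = 0
    n_sites_out: int = 0
    removed_samples: list[tuple[str, float]] = field(default_factory=list)
    removed_sites: list[tuple[tuple[str, int, str, str], float, float]] = field(default_factory=list)
    per_gene_coverage: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Removed-entity table for the TSV report."""
        rows = [{"kind": "sample", "key": sid, "call_rate_cases": rate,
                 "call_rate_controls": rate} for sid, rate in self.removed_samples]
        rows += [{"kind": "site", "key": f"{c}:{p}:{r}>{a}",
                  "call_rate_cases": rc, "call_rate_controls": ro}
                 for (c, p, r, a), rc, ro in self.removed_sites]
        return pd.DataFrame(rows, columns=["kind", "key", "call_rate_cases", "call_rate_controls"])

    def summary_lines(self) -> list[str]:
        return [
            f"samples: {self.n_samples_in} in, {self.n_samples_out} retained, "
            f"{len(self.removed_samples)} removed",
            f"sites: {self.n_sites_in} in, {self.n_sites_out} retained, "
            f"{len(self.removed_sites)} removed",
        ]


def _check_threshold(threshold: float) -> None:
    if not (0.0 <= threshold <= 1.0):
        raise ConfigError(f"call-rate threshold must be in [0, 1]: {threshold}")


def filter_samples_by_call_rate(
    matrix: GenotypeMatrix, threshold: float = 0.95
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples genotyped for < threshold of all sites (inclusive >=)."""
    _check_threshold(threshold)
    if matrix.n_samples == 0:
        raise EmptyCohortError("matrix has no samples")
    if matrix.n_sites == 0:
        rates = np.ones(matrix.n_samples)
    else:
        rates = matrix.called().mean(axis=1)
    keep = rates >= threshold
    if not keep.any():
        raise EmptyCohortError(
            f"sample call-rate filter at {threshold} removed every sample"
        )
    report = QcReport(
        n_samples_in=matrix.n_samples, n_samples_out=int(keep.sum()),
        n_sites_in=matrix.n_sites, n_sites_out=matrix.n_sites,
        removed_samples=[(matrix.samples[i].sample_id, float(rates[i]))
                         for i in np.flatnonzero(~keep)],
    )
    return matrix.subset_samples(keep), report


def filter_variants_by_group_call_rate(
    matrix: GenotypeMatrix, threshold: float = 0.95
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop sites whose call rate is < threshold in cases or in controls.

    Rates are computed on the matrix as given, i.e. after sample filtering
    when used in the standard order.
    """
    _check_threshold(threshold)
    case = matrix.case_mask
    n_cases, n_controls = int(case.sum()), int((~case).sum())
    if n_cases == 0 or n_controls == 0:
        raise EmptyCohortError(
            f"need both groups non-empty: {n_cases} cases, {n_controls} controls"
        )
    called = matrix.called()
    rate_cases = called[case, :].mean(axis=0) if matrix.n_sites else np.ones(0)
    rate_controls = called[~case, :].mean(axis=0) if matrix.n_sites else np.ones(0)
    keep = (rate_cases >= threshold) & (rate_controls >= threshold)
    report = QcReport(
        n_samples_in=matrix.n_samples, n_samples_out=matrix.n_samples,
        n_sites_in=matrix.n_sites, n_sites_out=int(keep.sum()),
        removed_sites=[(matrix.sites[j].key, float(rate_cases[j]), float(rate_controls[j]))
                       for j in np.flatnonzero(~keep)],
    )
    return matrix.subset_sites(keep), report


def run_qc(
    matrix: GenotypeMatrix,
    sample_threshold: float = 0.95,
    site_threshold: float = 0.95,
    targets: list[GeneTarget] | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Samples first, then per-group sites; merged report.

    If ``targets`` is given, the report also carries per-gene coverage of
    the retained sites.
    """
    filtered, sample_report = filter_samples_by_call_rate(matrix, sample_threshold)
    filtered, site_report = filter_variants_by_group_call_rate(filtered, site_threshold)
    report = QcReport(
        n_samples_in=matrix.n_samples, n_samples_out=filtered.n_samples,
        n_sites_in=matrix.n_sites, n_sites_out=filtered.n_sites,
        removed_samples=sample_report.removed_samples,
        removed_sites=site_report.removed_sites,
    )
    if targets is not None:
        report.per_gene_coverage = gene_coverage_summary(
            matrix, targets, {s.key for s in filtered.sites}
        )
    return filtered, report


def gene_coverage_summary(
    matrix: GenotypeMatrix,
    targets: list[GeneTarget],
    retained_sites,
) -> dict[str, tuple[float, float]]:
    """Percent of targeted coding positions represented by retained sites.

    For each gene: 100 x (targeted positions overlapped by a retained
    site's reference span) / (total targeted positions), reported for
    cases and controls. ``retained_sites`` is a set of site keys applied
    to both groups, or a ``(cases_set, controls_set)`` pair when the two
    groups retain different sites. Sites assigned to no target interval
    are excluded from the numerator with a warning.
    """
    if isinstance(retained_sites, tuple) and len(retained_sites) == 2 \
            and not isinstance(retained_sites[0], str):
        retained_by_group = (set(retained_sites[0]), set(retained_sites[1]))
    else:
        both = set(retained_sites)
        retained_by_group = (both, both)

    site_by_key = {s.key: s for s in matrix.sites}
    target_by_gene = {t.gene: t for t in targets}
    out: dict[str, tuple[float, float]] = {}
    for gene, target in target_by_gene.items():
        denom = target.n_positions()
        pcts = []
        for retained in retained_by_group:
            covered: set[tuple[str, int]] = set()
            for key in retained:
                site = site_by_key.get(key)
                if site is None or site.gene not in ("", gene):
                    continue
                span = [(site.chrom, p) for p in range(site.pos, site.pos + len(site.ref))
                        if target.contains(site.chrom, p)]
                if not span and (site.gene == gene):
                    warnings.warn(
                        f"site {key} assigned to {gene} lies outside its target intervals",
                        stacklevel=2,
                    )
                covered.update(span)
            pcts.append(100.0 * len(covered) / denom if denom else 0.0)
        out[gene] = (pcts[0], pcts[1])
    return out
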