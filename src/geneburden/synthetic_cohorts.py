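"""Synthetic multi-cohort case-control studies with known ground truth.

The generator emulates a targeted-sequencing candidate-gene design: a
panel of genes, each carrying a handful of rare qualifying sites
(disrupting/missense, reference-panel MAF <= 0.01 or novel) plus some
non-qualifying sites (synonymous, or missense too common to pass the MAF
filter), in a case-control sample drawn from several cohorts.

Carrier model
-------------
Each subject carries at most one qualifying variant per gene (heterozygous)
— the singleton-dominated spectrum typical of rare-variant panels. The
gene-level carrier probability is ``carrier_freq_controls`` in controls;
in cases the carrier *odds* are multiplied by the configured odds ratio:

    p_case = cf * OR / (1 - cf + cf * OR)

The carrier's site is drawn from a skewed (Dirichlet) weight vector so a
few sites recur and the rest are near-singletons. Non-qualifying sites get
independent Hardy-Weinberg genotypes at their panel frequency.

Missingness is MCAR from two rates (per-sample and per-site, combined
independently per call), with an optional extra rate in cases to exercise
differential-missingness QC. All randomness flows from the single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .association_stats import gene_burden_test
from .cohort_data import (
    CASE,
    CONTROL,
    CONSEQUENCE_DISRUPTING,
    CONSEQUENCE_MISSENSE,
    CONSEQUENCE_OTHER,
    MISSING,
    GeneTarget,
    GenotypeMatrix,
    QualifyingRule,
    SampleRecord,
    VariantSite,
    write_gene_targets,
    write_phenotype_table,
    write_vcf_genotypes,
)
from .errors import ConfigError
from .quality_control import run_qc
from .qualifying_variants import select_qualifying

#: raw annotation strings the generator emits, by class
_DISRUPTING_STRINGS = ("stop-gained", "frameshift", "splice-donor", "splice-acceptor")
_OTHER_RARE_STRING = "coding-synonymous"
_COMMON_MISSENSE_STRING = "missense"


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth parameters for one gene."""

    gene: str
    carrier_freq_controls: float
    odds_ratio: float = 1.0
    n_qualifying_sites: int = 8
    n_nonqualifying_sites: int = 3

    def case_carrier_freq(self) -> float:
        cf = self.carrier_freq_controls
        p = cf * self.odds_ratio / (1.0 - cf + cf * self.odds_ratio)
        if p >= 1.0:
            raise ConfigError(
                f"{self.gene}: carrier_freq {cf} x OR {self.odds_ratio} "
                f"implies case carrier probability >= 1"
            )
        return p


def default_gene_panel() -> list[GeneSpec]:
    """A 13-gene amyloid-pathway-style panel.

    Control carrier frequencies and odds ratios span the range seen in
    candidate-gene burden studies of this design: mostly null genes
    (OR near 1), a couple of moderate risk genes (OR 2-3.5) and one strong
    one (OR ~6) with very rare carriers. Frequencies are per 1700 controls.
    """
    rows = [
        # gene, control carriers per 1700, OR, n qualifying sites
        ("APP", 19, 0.85, 12), ("PSEN1", 6, 3.49, 16), ("PSEN2", 46, 0.86, 18),
        ("TREM2", 52, 2.04, 10), ("APH1A", 1, 0.90, 2), ("APH1B", 6, 2.57, 8),
        ("BACE1", 15, 1.20, 12), ("CASP3", 3, 1.20, 4), ("CASP8", 4, 5.93, 8),
        ("GSK3A", 4, 1.13, 4), ("GSK3B", 3, 1.20, 4), ("NCSTN", 32, 0.96, 16),
        ("PSENEN", 1, 0.90, 2),
    ]
    return [GeneSpec(gene=g, carrier_freq_controls=k / 1700.0, odds_ratio=orr,
                     n_qualifying_sites=nq) for g, k, orr, nq in rows]


def default_cohort_splits() -> list[tuple[str, float]]:
    return [("NIA-LOAD", 0.30), ("NCRAD", 0.09), ("NACC", 0.17),
            ("NIMH", 0.21), ("ACT", 0.13), ("WashU", 0.10)]


@dataclass
class SimulationConfig:
    """Full parameterisation of a synthetic multi-cohort study.

    Defaults reproduce the scale of a large targeted-sequencing burden
    study: 1886 cases vs 1700 controls across six cohorts, the 13-gene
    panel of :func:`default_gene_panel`, and modest MCAR missingness
    (2% per sample, 1% per site).
    """

    seed: int = 0
    n_cases: int = 1886
    n_controls: int = 1700
    genes: list[GeneSpec] = field(default_factory=default_gene_panel)
    per_sample_missing_rate: float = 0.02
    per_site_missing_rate: float = 0.01
    case_extra_missing_rate: float = 0.0
    cohort_splits: list[tuple[str, float]] = field(default_factory=default_cohort_splits)

    def __post_init__(self) -> None:
        for name in ("per_sample_missing_rate", "per_site_missing_rate",
                     "case_extra_missing_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ConfigError(f"{name} must be in [0, 1): {rate}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError("need at least one case and one control")
        total = sum(f for _, f in self.cohort_splits)
        if self.cohort_splits and abs(total - 1.0) > 1e-9:
            raise ConfigError(f"cohort fractions must sum to 1, got {total}")
        for spec in self.genes:
            if not (0.0 <= spec.carrier_freq_controls < 1.0):
                raise ConfigError(
                    f"{spec.gene}: carrier_freq_controls out of [0, 1)"
                )
            if spec.odds_ratio <= 0:
                raise ConfigError(f"{spec.gene}: odds_ratio must be > 0")
            spec.case_carrier_freq()  # raises if probability >= 1


@dataclass
class SimTruth:
    """Ground truth recorded alongside the generated study."""

    gene_case_carriers: dict[str, int]
    gene_control_carriers: dict[str, int]
    variant_carrier_probs: dict[str, tuple[float, float]]  # key str -> (control, case)
    n_masked_calls: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimulatedStudy:
    matrix: GenotypeMatrix
    annotation: dict[tuple[str, int, str, str], tuple[str, str, float | None]]
    targets: list[GeneTarget]
    truth: SimTruth

    @property
    def samples(self) -> list[SampleRecord]:
        return self.matrix.samples


def _make_samples(config: SimulationConfig, rng: np.random.Generator) -> list[SampleRecord]:
    n = config.n_cases + config.n_controls
    statuses = [CASE] * config.n_cases + [CONTROL] * config.n_controls
    if config.cohort_splits:
        ids = [c for c, _ in config.cohort_splits]
        probs = np.array([f for _, f in config.cohort_splits])
        cohorts = rng.choice(ids, size=n, p=probs / probs.sum())
    else:
        cohorts = np.array(["discovery"] * n)
    width = len(str(n))
    return [SampleRecord(sample_id=f"S{i + 1:0{width}d}", cohort_id=str(cohorts[i]),
                         status=statuses[i]) for i in range(n)]


_BASES = np.array(list("ACGT"))


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def simulate_cohort(config: SimulationConfig) -> SimulatedStudy:
    """Generate one study: genotypes, annotation, targets and truth.

    Deterministic under ``config.seed``; see the module docstring for the
    generative model.
    """
    rng = np.random.default_rng(config.seed)
    samples = _make_samples(config, rng)
    case_mask = np.array([s.is_case for s in samples])
    n = len(samples)

    sites: list[VariantSite] = []
    annotation: dict[tuple[str, int, str, str], tuple[str, str, float | None]] = {}
    targets: list[GeneTarget] = []
    columns: list[np.ndarray] = []
    truth = SimTruth({}, {}, {}, 0)

    for g_idx, spec in enumerate(config.genes):
        base = 1_000_000 * (g_idx + 1)
        chrom = str(g_idx % 22 + 1)
        n_sites_gene = spec.n_qualifying_sites + spec.n_nonqualifying_sites
        positions = base + 10 * np.arange(1, n_sites_gene + 1)
        targets.append(GeneTarget.from_raw(
            spec.gene, [(chrom, base, int(positions[-1]) + 50)]
        ))

        # qualifying sites: skewed weights -> singleton-rich spectrum
        nq = spec.n_qualifying_sites
        weights = rng.dirichlet(np.full(nq, 0.5)) if nq > 1 else np.ones(max(nq, 1))
        p_control = spec.carrier_freq_controls
        p_case = spec.case_carrier_freq()
        is_carrier = np.where(case_mask,
                              rng.random(n) < p_case,
                              rng.random(n) < p_control)
        carrier_site = rng.choice(nq, size=n, p=weights) if nq else np.zeros(n, int)

        truth.gene_case_carriers[spec.gene] = int((is_carrier & case_mask).sum())
        truth.gene_control_carriers[spec.gene] = int((is_carrier & ~case_mask).sum())

        for i in range(nq):
            ref, alt = _draw_alleles(rng)
            pos = int(positions[i])
            if rng.random() < 0.2:
                raw = str(rng.choice(_DISRUPTING_STRINGS))
                consequence = CONSEQUENCE_DISRUPTING
            else:
                raw = "missense"
                consequence = CONSEQUENCE_MISSENSE
            # half the rare sites are absent from the reference panel (novel)
            panel_af = None if rng.random() < 0.5 else float(
                10 ** rng.uniform(-4, np.log10(0.01))
            )
            site = VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt,
                               gene=spec.gene, consequence=consequence,
                               panel_af=panel_af)
            sites.append(site)
            annotation[site.key] = (spec.gene, raw, panel_af)
            columns.append((is_carrier & (carrier_site == i)).astype(np.int8))
            truth.variant_carrier_probs["|".join(map(str, site.key))] = (
                float(p_control * weights[i]), float(p_case * weights[i]),
            )

        # non-qualifying sites: synonymous (any AF) or too-common missense
        for i in range(spec.n_nonqualifying_sites):
            ref, alt = _draw_alleles(rng)
            pos = int(positions[nq + i])
            if rng.random() < 0.5:
                raw, consequence = _OTHER_RARE_STRING, CONSEQUENCE_OTHER
                panel_af = float(10 ** rng.uniform(-4, np.log10(0.05)))
            else:
                raw, consequence = _COMMON_MISSENSE_STRING, CONSEQUENCE_MISSENSE
                panel_af = float(rng.uniform(0.02, 0.2))
            site = VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt,
                               gene=spec.gene, consequence=consequence,
                               panel_af=panel_af)
            sites.append(site)
            annotation[site.key] = (spec.gene, raw, panel_af)
            columns.append(rng.binomial(2, panel_af, size=n).astype(np.int8))

    calls = (np.stack(columns, axis=1) if columns
             else np.empty((n, 0), dtype=np.int8))

    # MCAR missingness: per-sample and per-site rates combine independently
    if calls.size:
        sample_rate = np.full(n, config.per_sample_missing_rate)
        sample_rate[case_mask] = 1 - (1 - sample_rate[case_mask]) * (
            1 - config.case_extra_missing_rate
        )
        p_miss = 1 - np.outer(1 - sample_rate,
                              np.full(calls.shape[1], 1 - config.per_site_missing_rate))
        mask = rng.random(calls.shape) < p_miss
        calls = np.where(mask, np.int8(MISSING), calls)
        truth.n_masked_calls = int(mask.sum())

    matrix = GenotypeMatrix(samples=samples, sites=sites, calls=calls)
    return SimulatedStudy(matrix=matrix, annotation=annotation,
                          targets=targets, truth=truth)


def write_simulated_study(study: SimulatedStudy, directory) -> dict[str, str]:
    """Emit the study as VCF + phenotype TSV + annotation TSV + BED + truth
    JSON, all readable by :mod:`geneburden.cohort_data`."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {name: os.path.join(directory, fname) for name, fname in [
        ("vcf", "study.vcf"), ("phenotypes", "phenotypes.tsv"),
        ("annotation", "annotation.tsv"), ("targets", "targets.bed"),
        ("truth", "truth.json"),
    ]}
    write_vcf_genotypes(study.matrix, paths["vcf"])
    write_phenotype_table(study.samples, paths["phenotypes"])
    with open(paths["annotation"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tconsequence\tpanel_af\n")
        for (chrom, pos, ref, alt), (gene, raw, af) in study.annotation.items():
            af_str = "" if af is None else f"{af:.6g}"
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{gene}\t{raw}\t{af_str}\n")
    write_gene_targets(study.targets, paths["targets"])
    with open(paths["truth"], "w") as fh:
        fh.write(study.truth.to_json())
    return paths


@dataclass
class GeneSimResult:
    """Per-gene Monte-Carlo outcome over replicates."""

    p_values: np.ndarray
    odds_ratios: np.ndarray  # NaN where undefined (zero cell)

    def rejection_rate(self, alpha: float = 0.05) -> float:
        return float((self.p_values <= alpha).mean())

    def mc_se(self, alpha: float = 0.05) -> float:
        r = self.rejection_rate(alpha)
        return float(np.sqrt(r * (1 - r) / len(self.p_values))) or float(
            np.sqrt(0.25 / len(self.p_values))
        )

    def median_odds_ratio(self) -> float:
        defined = self.odds_ratios[~np.isnan(self.odds_ratios)]
        return float(np.median(defined)) if defined.size else float("nan")


def simulate_and_test(
    config: SimulationConfig,
    replicates: int,
    alpha: float = 0.05,
    rule: QualifyingRule = QualifyingRule(),
    sample_threshold: float = 0.95,
    site_threshold: float = 0.95,
    count_rule: str = "per_site",
) -> dict[str, GeneSimResult]:
    """Run the full pipeline (QC -> qualifying selection -> burden test)
    on ``replicates`` fresh studies and collect per-gene p-values and
    odds-ratio estimates. Replicate seeds are spawned from ``config.seed``.
    """
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    seeds = np.random.SeedSequence(config.seed).generate_state(replicates) % (2**31)
    p_vals = {spec.gene: np.empty(replicates) for spec in config.genes}
    ors = {spec.gene: np.full(replicates, np.nan) for spec in config.genes}
    for r, seed in enumerate(seeds):
        rep_config = SimulationConfig(
            seed=int(seed), n_cases=config.n_cases, n_controls=config.n_controls,
            genes=config.genes,
            per_sample_missing_rate=config.per_sample_missing_rate,
            per_site_missing_rate=config.per_site_missing_rate,
            case_extra_missing_rate=config.case_extra_missing_rate,
            cohort_splits=config.cohort_splits,
        )
        study = simulate_cohort(rep_config)
        filtered, _ = run_qc(study.matrix, sample_threshold, site_threshold)
        qualifying = select_qualifying(
            filtered.sites, rule, retained_sites={s.key for s in filtered.sites}
        )
        for spec in config.genes:
            result = gene_burden_test(
                filtered, qualifying.get(spec.gene, []), spec.gene,
                count_rule=count_rule,
            )
            p_vals[spec.gene][r] = result.p_one_sided
            if result.odds_ratio is not None:
                ors[spec.gene][r] = result.odds_ratio
    return {g: GeneSimResult(p_values=p_vals[g], odds_ratios=ors[g])
            for g in p_vals}
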