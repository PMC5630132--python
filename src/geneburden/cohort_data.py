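"""Core data model and file I/O for case-control genotype studies.

Conventions
-----------
* Genotype calls are alternate-allele counts ``{0, 1, 2}`` with ``-1`` for a
  missing call, stored as a dense ``int8`` samples x sites matrix.
* Internal coordinates are 1-based inclusive (VCF ``POS`` convention); BED
  input (0-based, half-open) is converted on read and back on write.
* Multi-allelic VCF records are split into one site per alternate allele;
  a genotype carrying a *different* alternate allele counts 0 at that site.
* A reference-panel frequency absent from the annotation is kept as ``None``
  at read time; the qualifying filter decides what "absent" means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputFormatError

MISSING: int = -1

CASE = "case"
CONTROL = "control"

#: tokens accepted in phenotype files, normalised case-insensitively
_STATUS_TOKENS = {
    "case": CASE, "ca": CASE, "1": CASE, "affected": CASE,
    "control": CONTROL, "co": CONTROL, "0": CONTROL, "unaffected": CONTROL,
}

CONSEQUENCE_DISRUPTING = "disrupting"
CONSEQUENCE_MISSENSE = "missense"
CONSEQUENCE_OTHER = "other"
CONSEQUENCES = (CONSEQUENCE_DISRUPTING, CONSEQUENCE_MISSENSE, CONSEQUENCE_OTHER)


@dataclass(frozen=True)
class SampleRecord:
    """One study subject: id, cohort membership and case/control status."""

    sample_id: str
    cohort_id: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in (CASE, CONTROL):
            raise InputFormatError(
                f"status must be '{CASE}' or '{CONTROL}', got {self.status!r}"
            )

    @property
    def is_case(self) -> bool:
        return self.status == CASE


@dataclass(frozen=True)
class VariantSite:
    """A single bi-allelic variant (multi-allelics pre-split).

    ``consequence`` is one of ``disrupting``/``missense``/``other`` after
    annotation; ``panel_af`` is the reference-panel alternate-allele
    frequency, ``None`` when the variant is absent from the panel.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = CONSEQUENCE_OTHER
    panel_af: float | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputFormatError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InputFormatError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise InputFormatError(f"unknown consequence {self.consequence!r}")
        if self.panel_af is not None and not (0.0 <= self.panel_af <= 1.0):
            raise InputFormatError(f"panel_af out of [0,1]: {self.panel_af}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class QualifyingRule:
    """Inclusion rule for the collapsing analysis.

    Defaults mirror the standard rare-variant burden design: disrupting or
    missense consequence, reference-panel MAF <= 0.01 (inclusive), and site
    call rate >= 0.95 in each group.
    """

    max_panel_maf: float = 0.01
    allowed_classes: frozenset[str] = frozenset({CONSEQUENCE_DISRUPTING, CONSEQUENCE_MISSENSE})
    min_site_call_rate: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_panel_maf <= 0.5):
            raise InputFormatError(f"max_panel_maf must be in [0, 0.5]: {self.max_panel_maf}")
        if not self.allowed_classes:
            raise InputFormatError("allowed_classes must be non-empty")


@dataclass(frozen=True)
class GeneTarget:
    """Targeted intervals of a gene, 1-based inclusive, merged and sorted."""

    gene: str
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise InputFormatError(f"gene {self.gene}: no intervals")
        for chrom, start, end in self.intervals:
            if start > end or start < 1:
                raise InputFormatError(
                    f"gene {self.gene}: bad interval {chrom}:{start}-{end}"
                )

    @staticmethod
    def from_raw(gene: str, intervals: list[tuple[str, int, int]]) -> "GeneTarget":
        """Build a target, merging overlapping/adjacent intervals per chrom."""
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(intervals):
            if merged and merged[-1][0] == chrom and start <= merged[-1][2] + 1:
                prev = merged[-1]
                merged[-1] = (chrom, prev[1], max(prev[2], end))
            else:
                merged.append((chrom, start, end))
        return GeneTarget(gene=gene, intervals=tuple(merged))

    def n_positions(self) -> int:
        return sum(end - start + 1 for _, start, end in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in self.intervals)


@dataclass
class GenotypeMatrix:
    """Samples x sites alternate-allele counts with missingness.

    ``calls[i, j]`` is the count for sample ``i`` at site ``j``; ``-1``
    marks a missing call.
    """

    samples: list[SampleRecord]
    sites: list[VariantSite]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise InputFormatError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise InputFormatError(f"calls contain values outside {{0,1,2,{MISSING}}}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise InputFormatError("duplicate sample ids in matrix")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([s.is_case for s in self.samples], dtype=bool)

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return self.n_samples - self.n_cases

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def site_index(self, key: tuple[str, int, str, str]) -> int:
        for j, site in enumerate(self.sites):
            if site.key == key:
                return j
        raise KeyError(key)

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=list(self.sites),
            calls=self.calls[idx, :],
        )

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[i] for i in idx],
            calls=self.calls[:, idx],
        )

    def with_sites(self, sites: list[VariantSite]) -> "GenotypeMatrix":
        """Replace site metadata (e.g. after annotation), keeping calls."""
        if len(sites) != self.n_sites:
            raise InputFormatError("site list length mismatch")
        return GenotypeMatrix(samples=list(self.samples), sites=sites, calls=self.calls)


# ---------------------------------------------------------------------------
# readers


def read_phenotype_table(path) -> list[SampleRecord]:
    """Read a TSV of ``sample_id, cohort_id, status`` into SampleRecords.

    Status tokens are mapped case-insensitively (case/control, CA/CO, 1/0,
    affected/unaffected). Duplicate sample ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "cohort_id", "status"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"phenotype table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise InputFormatError(f"duplicate sample ids in phenotype table: {dupes}")
    records = []
    for row in df.itertuples(index=False):
        token = row.status.strip().lower()
        if token not in _STATUS_TOKENS:
            raise InputFormatError(f"unknown status token {row.status!r} for {row.sample_id}")
        records.append(SampleRecord(row.sample_id, row.cohort_id, _STATUS_TOKENS[token]))
    return records


def read_vcf_genotypes(path, phenotypes: list[SampleRecord]) -> GenotypeMatrix:
    """Read GT calls from a VCF v4.x into a GenotypeMatrix.

    Rows follow ``phenotypes`` order; multi-allelic records are split into
    one site per alternate allele (a genotype carrying a different alt
    counts 0); any genotype with a no-call allele ("./." or half-calls)
    maps to missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if not vcf_samples:
        raise InputFormatError(f"{path}: VCF has no sample columns (missing GT FORMAT?)")
    col_of = {s: i for i, s in enumerate(vcf_samples)}
    absent = [p.sample_id for p in phenotypes if p.sample_id not in col_of]
    if absent:
        raise InputFormatError(f"{path}: phenotype samples absent from VCF: {absent}")
    order = np.array([col_of[p.sample_id] for p in phenotypes])

    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if "GT" not in (rec.FORMAT or []):
            raise InputFormatError(f"{path}: record {rec.CHROM}:{rec.POS} lacks GT")
        gts = np.array([g[:2] for g in rec.genotypes], dtype=np.int16)  # n x 2 allele idx
        no_call = (gts < 0).any(axis=1)
        rsid = rec.ID if rec.ID not in (None, ".") else None
        for k, alt in enumerate(rec.ALT, start=1):
            counts = (gts == k).sum(axis=1).astype(np.int8)
            counts[no_call] = MISSING
            sites.append(VariantSite(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF,
                                     alt=alt, rsid=rsid))
            columns.append(counts[order])
    calls = (np.stack(columns, axis=1) if columns
             else np.empty((len(phenotypes), 0), dtype=np.int8))
    return GenotypeMatrix(samples=list(phenotypes), sites=sites, calls=calls)


def read_annotation_table(path) -> dict[tuple[str, int, str, str], tuple[str, str, float | None]]:
    """Read the variant annotation TSV.

    Columns: chrom, pos, ref, alt, gene, consequence, panel_af (blank allowed),
    and optionally rsid. Returns key -> (gene, raw consequence string,
    panel_af-or-None). Duplicate keys with conflicting values are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence", "panel_af"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"annotation table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    table: dict[tuple[str, int, str, str], tuple[str, str, float | None]] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        af = float(row.panel_af) if row.panel_af.strip() else None
        value = (row.gene, row.consequence, af)
        if key in table and table[key] != value:
            raise InputFormatError(
                f"conflicting annotation rows for {key}: {table[key]} vs {value}"
            )
        table[key] = value
    return table


def read_gene_targets(path) -> list[GeneTarget]:
    """Read a BED4 file (0-based half-open, name column = gene).

    Converts to 1-based inclusive and merges overlapping intervals per gene.
    """
    per_gene: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InputFormatError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise InputFormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            per_gene.setdefault(gene, []).append((chrom, start + 1, end))
    return [GeneTarget.from_raw(g, ivs) for g, ivs in per_gene.items()]


# ---------------------------------------------------------------------------
# writers


def write_gene_targets(targets: list[GeneTarget], path) -> None:
    """Write targets back to BED4 (inverse of :func:`read_gene_targets`)."""
    with open(path, "w") as fh:
        for t in targets:
            for chrom, start, end in t.intervals:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{t.gene}\n")


def write_phenotype_table(samples: list[SampleRecord], path) -> None:
    pd.DataFrame(
        {"sample_id": [s.sample_id for s in samples],
         "cohort_id": [s.cohort_id for s in samples],
         "status": [s.status for s in samples]}
    ).to_csv(path, sep="\t", index=False)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf_genotypes(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT, readable by
    :func:`read_vcf_genotypes`. Sites must be bi-allelic (they are, by
    construction of :class:`VariantSite`)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += [s.sample_id for s in matrix.samples]
        fh.write("\t".join(header) + "\n")
        for j, site in enumerate(matrix.sites):
            row = [site.chrom, str(site.pos), site.rsid or ".", site.ref, site.alt,
                   ".", "PASS", ".", "GT"]
            row += [_GT_STRING[int(c)] for c in matrix.calls[:, j]]
            fh.write("\t".join(row) + "\n")


def format_p(p: float) -> str:
    """Scientific notation at 2 significant figures, e.g. 8.6e-05."""
    return f"{p:.1e}"


def _fmt_or(x: float | None) -> str:
    return "n/a" if x is None else f"{x:.2f}"


RESULT_COLUMNS = ["gene", "var_ca", "n_ca", "var_co", "n_co",
                  "p", "or", "ci_low", "ci_high", "p_bonferroni"]


def write_results_table(results, path) -> None:
    """Write burden/single-variant results as TSV.

    p-values are rendered at 2 significant figures, OR/CI at 2 decimals,
    undefined OR/CI as "n/a" — the conventional presentation for this
    analysis. Full precision stays on the BurdenResult objects.
    """
    rows = []
    for r in results:
        rows.append({
            "gene": r.label,
            "var_ca": r.table.a, "n_ca": r.table.n1,
            "var_co": r.table.b, "n_co": r.table.n2,
            "p": format_p(r.p_one_sided),
            "or": _fmt_or(r.odds_ratio),
            "ci_low": _fmt_or(r.ci_low),
            "ci_high": _fmt_or(r.ci_high),
            "p_bonferroni": format_p(r.p_bonferroni),
        })
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)
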