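"""Consequence classification and qualifying-variant selection.

A variant qualifies for the gene burden when its consequence is in the
allowed classes (protein-disrupting or missense by default), its folded
reference-panel MAF is <= the threshold (0.01 by default, inclusive), and
it survived site-level QC. Variants absent from the panel are treated as
MAF 0: a variant never seen in the reference population is the rarest kind,
and excluding novel variants would gut a rare-variant design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import yaml

from .cohort_data import (
    CONSEQUENCE_DISRUPTING,
    CONSEQUENCE_MISSENSE,
    CONSEQUENCE_OTHER,
    QualifyingRule,
    VariantSite,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)

#: annotation strings treated as protein-disrupting. Covers the common
#: SeattleSeq-style and Sequence Ontology vocabularies; canonical splice
#: means the two intronic bases flanking an exon boundary.
DEFAULT_DISRUPTING_TERMS = frozenset({
    "stop-gained", "stop-gain", "nonsense", "stop-lost", "stop-loss",
    "start-lost", "start-loss", "stop-gained-near-splice",
    "frameshift", "frameshift-variant", "frameshift-near-splice",
    "splice-acceptor", "splice-donor", "splice-acceptor-variant",
    "splice-donor-variant", "canonical-splice", "splice-site",
})

DEFAULT_MISSENSE_TERMS = frozenset({
    "missense", "missense-variant", "missense-near-splice",
})


def _normalise(term: str) -> str:
    return term.strip().lower().replace("_", "-").replace(" ", "-")


@dataclass(frozen=True)
class ConsequenceLexicon:
    """Mapping from raw annotation strings to the three consequence classes.

    The default vocabulary is a superset of common annotation-pipeline
    terms; other vocabularies can be mapped by constructing a lexicon from
    a YAML config (see :meth:`from_yaml`). The two term sets must be
    disjoint; anything in neither maps to ``other``.
    """

    disrupting_terms: frozenset[str] = DEFAULT_DISRUPTING_TERMS
    missense_terms: frozenset[str] = DEFAULT_MISSENSE_TERMS

    def __post_init__(self) -> None:
        overlap = set(self.disrupting_terms) & set(self.missense_terms)
        if overlap:
            raise ConfigError(f"lexicon term sets overlap: {sorted(overlap)}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ConsequenceLexicon":
        return cls(
            disrupting_terms=frozenset(_normalise(t) for t in mapping.get("disrupting", [])),
            missense_terms=frozenset(_normalise(t) for t in mapping.get("missense", [])),
        )

    @classmethod
    def from_yaml(cls, path) -> "ConsequenceLexicon":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


DEFAULT_LEXICON = ConsequenceLexicon()


def classify_consequence(
    annotation: str, lexicon: ConsequenceLexicon = DEFAULT_LEXICON
) -> str:
    """Map a raw annotation string to disrupting/missense/other.

    Total and deterministic; unknown strings go to ``other`` with a logged
    warning so vocabulary mismatches are visible but non-fatal.
    """
    term = _normalise(annotation)
    if term in lexicon.disrupting_terms:
        return CONSEQUENCE_DISRUPTING
    if term in lexicon.missense_terms:
        return CONSEQUENCE_MISSENSE
    known_other = {"synonymous", "coding-synonymous", "intron", "intronic", "utr",
                   "utr-3", "utr-5", "3-prime-utr", "5-prime-utr", "intergenic",
                   "upstream-gene", "downstream-gene", "non-coding", "other"}
    if term not in known_other:
        logger.warning("unknown consequence string %r -> 'other'", annotation)
    return CONSEQUENCE_OTHER


def apply_annotations(
    sites: list[VariantSite],
    table: dict[tuple[str, int, str, str], tuple[str, str, float | None]],
    lexicon: ConsequenceLexicon = DEFAULT_LEXICON,
) -> list[VariantSite]:
    """Attach gene, classified consequence and panel AF to matrix sites.

    Sites without an annotation row keep gene "" and consequence ``other``
    (they can never qualify), with a logged warning.
    """
    from dataclasses import replace

    annotated = []
    for site in sites:
        row = table.get(site.key)
        if row is None:
            logger.warning("no annotation for site %s:%s %s>%s",
                           site.chrom, site.pos, site.ref, site.alt)
            annotated.append(site)
            continue
        gene, raw_consequence, panel_af = row
        annotated.append(replace(
            site, gene=gene,
            consequence=classify_consequence(raw_consequence, lexicon),
            panel_af=panel_af,
        ))
    return annotated


def folded_maf(panel_af: float | None) -> float:
    """Minor-allele frequency: fold the alternate AF; absent panel AF -> 0."""
    if panel_af is None:
        return 0.0
    return min(panel_af, 1.0 - panel_af)


def select_qualifying(
    sites: list[VariantSite],
    rule: QualifyingRule = QualifyingRule(),
    retained_sites=None,
) -> dict[str, list[VariantSite]]:
    """Select qualifying variants, grouped by gene.

    A site qualifies iff its consequence is in ``rule.allowed_classes``,
    its folded panel MAF is <= ``rule.max_panel_maf`` (absent counts as 0),
    and — when ``retained_sites`` is given — it survived QC. A pure filter:
    output order follows input order within each gene.
    """
    retained = None if retained_sites is None else set(retained_sites)
    by_gene: dict[str, list[VariantSite]] = {}
    for site in sites:
        if site.consequence not in rule.allowed_classes:
            continue
        if folded_maf(site.panel_af) > rule.max_panel_maf:
            continue
        if retained is not None and site.key not in retained:
            continue
        by_gene.setdefault(site.gene, []).append(site)
    return by_gene
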