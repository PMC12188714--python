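"""Pathway screening of annotated genomes.

Classifies genomes by the oxalate-handling / acetogenic / methanogenic /
sulfate-reducing / formate-oxidation (OAMSF) gene content, scores genome
quality from universal single-copy marker genes, and summarizes pathway
carriage across a genome collection.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

PATHWAY_TAGS = frozenset("OAMSF")

_NORMALIZE_RE = re.compile(r"[^a-z0-9]+")


def normalize_label(label: str) -> str:
    """Case-fold a gene label and strip punctuation/whitespace."""
    return _NORMALIZE_RE.sub("", label.casefold())


def single_copy_reference() -> frozenset[str]:
    """The bundled set of 41 universal single-copy marker gene labels.

    A synthetic stand-in list of ribosomal proteins and core
    information-processing genes, shipped as editable text.
    """
    text = resources.files("oxevo.data").joinpath("single_copy_genes.txt").read_text()
    genes = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return frozenset(genes)


@dataclass(frozen=True)
class PathwayCatalog:
    """Gene label -> set of OAMSF pathway tags.

    Lookup is by normalized label (case-folded, punctuation stripped) so
    annotation-style variants like ``OxlT`` and ``oxlT`` match.
    """

    entries: dict[str, frozenset[str]]
    _index: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("pathway catalog must be non-empty")
        for gene, tags in self.entries.items():
            if not tags:
                raise ValueError(f"catalog gene {gene!r} has no pathway tags")
            bad = set(tags) - PATHWAY_TAGS
            if bad:
                raise ValueError(f"catalog gene {gene!r} has unknown tags {sorted(bad)}")
        object.__setattr__(
            self, "_index", {normalize_label(g): g for g in self.entries}
        )

    def lookup(self, label: str) -> str | None:
        """Return the canonical catalog gene for ``label``, or None."""
        return self._index.get(normalize_label(label))

    def tags(self, gene: str) -> frozenset[str]:
        return self.entries[gene]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_tsv(cls, path) -> "PathwayCatalog":
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"gene", "pathways"} <= set(df.columns):
            raise ValueError("catalog TSV must have columns 'gene' and 'pathways'")
        entries = {
            str(row.gene): frozenset(str(row.pathways).replace(" ", "").split(","))
            for row in df.itertuples()
        }
        return cls(entries)

    @classmethod
    def default(cls) -> "PathwayCatalog":
        """The bundled OAMSF catalog (synthetic stand-in gene list)."""
        with resources.as_file(
            resources.files("oxevo.data").joinpath("oamsf_catalog.tsv")
        ) as p:
            return cls.from_tsv(p)


@dataclass
class AnnotatedGenome:
    """Gene inventory of one genome plus taxonomy and quality scores."""

    genome_id: str
    phylum: str
    genus: str
    genes: list[str]
    completeness: float = 1.0
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError("completeness must be in [0, 1]")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")


@dataclass(frozen=True)
class PathwayProfile:
    """OAMSF pathway membership of one genome."""

    genome_id: str
    pathway_set: frozenset[str]
    gene_hits: dict[str, int]

    @property
    def is_single_function(self) -> bool:
        return len(self.pathway_set) == 1


def assess_quality(
    genome_gene_list: list[str], single_copy_reference: frozenset[str] | set[str]
) -> tuple[float, float]:
    """Completeness and purity of a genome from single-copy marker genes.

    Completeness is the fraction of reference markers present at least
    once; purity is the number of distinct markers present divided by the
    total number of marker occurrences (duplicated markers lower purity,
    indicating a chimeric bin). A genome with no markers at all has
    completeness 0 and, vacuously, purity 1 (no evidence of contamination).
    """
    if not single_copy_reference:
        raise ValueError("single-copy reference set must be non-empty")
    ref = {normalize_label(g) for g in single_copy_reference}
    hits = Counter(normalize_label(g) for g in genome_gene_list if normalize_label(g) in ref)
    distinct = len(hits)
    total = sum(hits.values())
    completeness = distinct / len(ref)
    purity = distinct / total if total else 1.0
    return completeness, purity


def filter_quality(
    genomes: list[AnnotatedGenome],
    min_completeness: float = 0.80,
    min_purity: float = 0.90,
) -> list[AnnotatedGenome]:
    """Retain genomes strictly greater than both quality thresholds.

    Strict inequality: a genome at exactly 80% completeness is rejected.
    """
    for name, thr in (("min_completeness", min_completeness), ("min_purity", min_purity)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    return [
        g
        for g in genomes
        if g.completeness > min_completeness and g.purity > min_purity
    ]


def screen_pathways(genome: AnnotatedGenome, catalog: PathwayCatalog) -> PathwayProfile:
    """Match a genome's gene list against the OAMSF catalog.

    Genes absent from the catalog are ignored; the profile's pathway set is
    the union of the tags of every catalog gene found.
    """
    hits: Counter[str] = Counter()
    tags: set[str] = set()
    for label in genome.genes:
        canonical = catalog.lookup(label)
        if canonical is not None:
            hits[canonical] += 1
            tags |= catalog.tags(canonical)
    return PathwayProfile(genome.genome_id, frozenset(tags), dict(hits))


def _combo_key(pathway_set: frozenset[str]) -> str:
    return "+".join(sorted(pathway_set)) if pathway_set else "none"


@dataclass
class CarriageSummary:
    """Pathway carriage over a genome collection."""

    n_genomes: int
    pathway_table: pd.DataFrame  # per pathway: count, fraction
    combination_table: pd.DataFrame  # per combination (rare ones as "Other")
    oxalate_carriage: float  # fraction of genomes with >= 1 O-pathway gene


def summarize_carriage(
    profiles: list[PathwayProfile], other_threshold: float = 0.01
) -> CarriageSummary:
    """Count and normalize pathway and pathway-combination carriage.

    Combinations observed in fewer than ``other_threshold`` of the genomes
    are aggregated as "Other"; fractions over all reported combinations
    (including "Other" and genomes with no OAMSF genes, "none") sum to 1.
    """
    if not profiles:
        raise ValueError("summarize_carriage requires at least one profile")
    n = len(profiles)

    pathway_counts = {
        tag: sum(1 for p in profiles if tag in p.pathway_set) for tag in sorted(PATHWAY_TAGS)
    }
    pathway_table = pd.DataFrame(
        {
            "pathway": list(pathway_counts),
            "count": list(pathway_counts.values()),
        }
    )
    pathway_table["fraction"] = pathway_table["count"] / n

    combo_counts = Counter(_combo_key(p.pathway_set) for p in profiles)
    rows = []
    other = 0
    for combo, count in sorted(combo_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if count / n < other_threshold:
            other += count
        else:
            rows.append((combo, count))
    if other:
        rows.append(("Other", other))
    combination_table = pd.DataFrame(rows, columns=["combination", "count"])
    combination_table["fraction"] = combination_table["count"] / n

    oxalate = sum(1 for p in profiles if "O" in p.pathway_set) / n
    return CarriageSummary(n, pathway_table, combination_table, oxalate)


def gene_vs_genome_function_split(
    profiles: list[PathwayProfile], catalog: PathwayCatalog
) -> tuple[float, float]:
    """Fractions of single-function genes vs single-function genomes.

    The gene fraction is computed over the distinct catalog genes observed
    anywhere in the collection (each counted once); the genome fraction is
    the share of profiles whose pathway set has exactly one member. The
    contrast between the two is the gene-level vs genome-level view of
    metabolic specialization.
    """
    observed: set[str] = set()
    for p in profiles:
        observed |= set(p.gene_hits)
    if observed:
        single_genes = sum(1 for g in observed if len(catalog.tags(g)) == 1)
        gene_fraction = single_genes / len(observed)
    else:
        gene_fraction = 0.0
    genome_fraction = (
        sum(1 for p in profiles if p.is_single_function) / len(profiles) if profiles else 0.0
    )
    return gene_fraction, genome_fraction
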