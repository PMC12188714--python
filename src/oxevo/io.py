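"""Shared file I/O: FASTA, Newick, TSV tables, cluster sets, JSON truth.

All tables are tab-separated UTF-8 with a header row; missing values are
encoded as "NA". Every reader/writer pair round-trips its data model.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .cluster import ClusterSet
from .screen import AnnotatedGenome
from .synth import AbundanceTable, GroundTruth

NA = "NA"


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record ID (line-ending agnostic)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# -- Newick -----------------------------------------------------------------

def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# -- generic TSV ------------------------------------------------------------

def read_tsv(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=NA)


# -- abundance tables -------------------------------------------------------

def read_abundance(path) -> AbundanceTable:
    """Abundance TSV: first column feature ID, remaining columns samples."""
    df = read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: abundance table needs a feature column and >=1 sample")
    feature_col = df.columns[0]
    counts = df.set_index(feature_col)
    counts.index.name = "feature"
    return AbundanceTable(counts=counts.astype(int))


def write_abundance(table: AbundanceTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", na_rep=NA)


# -- genome tables ----------------------------------------------------------

GENOME_COLUMNS = ["genome_id", "gene_id", "phylum", "genus", "completeness", "purity"]


def write_genomes(genomes: list[AnnotatedGenome], path) -> None:
    rows = [
        {
            "genome_id": g.genome_id,
            "gene_id": gene,
            "phylum": g.phylum,
            "genus": g.genus,
            "completeness": g.completeness,
            "purity": g.purity,
        }
        for g in genomes
        for gene in g.genes
    ]
    write_tsv(pd.DataFrame(rows, columns=GENOME_COLUMNS), path)


def read_genomes(path) -> list[AnnotatedGenome]:
    df = read_tsv(path, required_columns=GENOME_COLUMNS)
    genomes = []
    for gid, sub in df.groupby("genome_id", sort=True):
        first = sub.iloc[0]
        genomes.append(
            AnnotatedGenome(
                genome_id=str(gid),
                phylum=str(first.phylum),
                genus=str(first.genus),
                genes=[str(g) for g in sub.gene_id],
                completeness=float(first.completeness),
                purity=float(first.purity),
            )
        )
    return genomes


# -- cluster sets -----------------------------------------------------------

def write_clusters(clusters: ClusterSet, path) -> None:
    rows = [
        {
            "representative": rep,
            "member": member,
            "identity": clusters.identities.get(member, float("nan")),
            "threshold": clusters.threshold,
            "identity_definition": clusters.identity_definition,
        }
        for rep, members in clusters.clusters.items()
        for member in members
    ]
    write_tsv(pd.DataFrame(rows), path)


def read_clusters(path) -> ClusterSet:
    df = read_tsv(path, required_columns=["representative", "member", "identity", "threshold"])
    mapping: dict[str, list[str]] = {}
    identities: dict[str, float] = {}
    for row in df.itertuples():
        mapping.setdefault(str(row.representative), []).append(str(row.member))
        identities[str(row.member)] = float(row.identity)
    definition = (
        str(df["identity_definition"].iloc[0]) if "identity_definition" in df.columns else ""
    )
    return ClusterSet(
        mapping, float(df["threshold"].iloc[0]), identity_definition=definition,
        identities=identities,
    )


# -- ground truth -----------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "true_tree": str(truth.true_tree) if truth.true_tree is not None else None,
        "gene_carriers": {g: sorted(c) for g, c in truth.gene_carriers.items()},
        "hgt_events": [list(e) for e in truth.hgt_events],
        "true_omega": truth.true_omega,
        "planted_edges": [list(e) for e in truth.planted_edges],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    tree = (
        TreeNode.read([payload["true_tree"]]) if payload.get("true_tree") else None
    )
    return GroundTruth(
        true_tree=tree,
        gene_carriers={g: set(c) for g, c in payload["gene_carriers"].items()},
        hgt_events=[tuple(e) for e in payload["hgt_events"]],
        true_omega=payload["true_omega"],
        planted_edges=[(a, b, float(r)) for a, b, r in payload["planted_edges"]],
    )
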