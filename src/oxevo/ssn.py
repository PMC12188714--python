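"""Sequence similarity networks across a sweep of homology cutoffs.

Nodes are sequences, edges connect pairs whose global-alignment identity
(shared definition with the clustering module) reaches the cutoff. Sweeping
the cutoff upward peels the network apart into sub-clusters; component
counts and per-component taxonomic purity quantify how gene families track
taxonomy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cluster import pairwise_identity

DEFAULT_CUTOFFS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class SimilarityGraph:
    """Identity-thresholded graph over sequences."""

    graph: nx.Graph
    cutoff: float
    metadata: dict = field(default_factory=dict)

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def identity_matrix(sequences: dict[str, str]) -> pd.DataFrame:
    """All-vs-all pairwise identities (symmetric, diagonal 1)."""
    ids = list(sequences)
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        ident = pairwise_identity(sequences[a], sequences[b])
        mat.loc[a, b] = mat.loc[b, a] = ident
    return mat


def _graph_from_identities(
    ids, identities: pd.DataFrame, cutoff: float, phyla: dict[str, str] | None
) -> SimilarityGraph:
    g = nx.Graph()
    for sid in ids:
        g.add_node(sid, phylum=(phyla or {}).get(sid, "NA"))
    for a, b in itertools.combinations(ids, 2):
        ident = float(identities.loc[a, b])
        if ident >= cutoff:
            g.add_edge(a, b, identity=ident)
    return SimilarityGraph(g, cutoff)


def build_ssn(
    sequences: dict[str, str],
    cutoff: float,
    phyla: dict[str, str] | None = None,
    identities: pd.DataFrame | None = None,
) -> SimilarityGraph:
    """Similarity network keeping edges with identity >= cutoff."""
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    if len(sequences) < 2:
        raise ValueError("at least 2 sequences are required")
    if identities is None:
        identities = identity_matrix(sequences)
    return _graph_from_identities(list(sequences), identities, cutoff, phyla)


def ssn_sweep(
    sequences: dict[str, str],
    cutoffs=DEFAULT_CUTOFFS,
    phyla: dict[str, str] | None = None,
) -> tuple[dict[float, SimilarityGraph], pd.DataFrame]:
    """Build SSNs at each cutoff (ascending) and count components.

    Identities are computed once and reused; edge sets at higher cutoffs
    are subsets of those at lower cutoffs by construction, so component
    counts are non-decreasing in the cutoff.
    """
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    identities = identity_matrix(sequences)
    graphs: dict[float, SimilarityGraph] = {}
    rows = []
    for cutoff in cutoffs:
        sg = build_ssn(sequences, cutoff, phyla=phyla, identities=identities)
        graphs[cutoff] = sg
        rows.append(
            {
                "cutoff": cutoff,
                "n_edges": sg.graph.number_of_edges(),
                "n_components": nx.number_connected_components(sg.graph),
            }
        )
    return graphs, pd.DataFrame(rows)


def taxonomic_purity(graph: SimilarityGraph) -> tuple[pd.DataFrame, float]:
    """Majority-phylum fraction per component, plus size-weighted mean."""
    rows = []
    for k, comp in enumerate(sorted(graph.components, key=lambda c: (-len(c), sorted(c)))):
        phyla = [graph.graph.nodes[v]["phylum"] for v in comp]
        if any(p == "NA" or p is None for p in phyla):
            raise ValueError(f"component {k} contains unlabeled node(s)")
        counts = pd.Series(phyla).value_counts()
        rows.append(
            {
                "component": k,
                "size": len(comp),
                "majority_phylum": counts.index[0],
                "purity": counts.iloc[0] / len(comp),
            }
        )
    table = pd.DataFrame(rows)
    weighted = float(np.average(table["purity"], weights=table["size"])) if len(table) else np.nan
    return table, weighted


def _find_primer(seq: str, primer: str, max_mismatches: int = 2) -> int | None:
    best_pos, best_mm = None, max_mismatches + 1
    for start in range(len(seq) - len(primer) + 1):
        mm = sum(1 for a, b in zip(seq[start : start + len(primer)], primer) if a != b)
        if mm < best_mm:
            best_pos, best_mm = start, mm
    return best_pos if best_mm <= max_mismatches else None


def trim_to_amplicon(
    reference_sequences: dict[str, str],
    region: tuple[int, int] | None = None,
    primers: tuple[str, str] | None = None,
    max_mismatches: int = 2,
) -> dict[str, str]:
    """Cut reference sequences down to the amplicon region.

    Either fixed 0-based half-open ``region`` coordinates, or a
    (forward, reverse) ``primers`` pair located by best match with at most
    ``max_mismatches`` mismatches (the amplicon is the stretch between the
    primers, exclusive). Sequences where the region cannot be located are
    dropped with a warning.
    """
    if (region is None) == (primers is None):
        raise ValueError("provide exactly one of region or primers")
    out: dict[str, str] = {}
    for sid, seq in reference_sequences.items():
        if region is not None:
            start, end = region
            if start < 0 or end > len(seq) or start >= end:
                warnings.warn(f"region {region} out of bounds for {sid}; dropped",
                              stacklevel=2)
                continue
            out[sid] = seq[start:end]
        else:
            fwd, rev = primers
            f = _find_primer(seq, fwd, max_mismatches)
            r = _find_primer(seq, rev, max_mismatches)
            if f is None or r is None or f + len(fwd) >= r:
                warnings.warn(f"primers not located in {sid}; dropped", stacklevel=2)
                continue
            out[sid] = seq[f + len(fwd) : r]
    return out
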