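"""Community-level carriage estimation by marker/16S cluster ratios.

The fraction of a community's species carrying a marker gene (e.g. the
formyl-CoA transferase gene *frc*) is estimated by comparing the number of
identity clusters of the marker to the number of identity clusters of the
16S rRNA gene at the same threshold — clustering both genes normalizes
their different divergence rates. The genome-based carriage of a broader
function (any oxalate-handling gene) is then extrapolated by scaling the
cluster ratio with the genome-level ratio of broad to marker carriage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .cluster import ClusterSet


@dataclass
class CarriageEstimate:
    """Cluster-ratio based community carriage estimate."""

    marker_cluster_count: int
    ssu_cluster_count: int
    cluster_ratio: float
    genome_marker_fraction: float
    genome_function_fraction: float
    extrapolated_carriage: float
    reported_range: tuple[float, float]
    note: str = ""


def cluster_ratio(marker_clusters: ClusterSet, ssu_clusters: ClusterSet) -> float:
    """|marker clusters| / |16S clusters| at a shared identity threshold."""
    if len(marker_clusters) == 0 or len(ssu_clusters) == 0:
        raise ValueError("both cluster sets must be non-empty")
    if marker_clusters.threshold != ssu_clusters.threshold:
        raise ValueError(
            "cluster sets were built at different thresholds "
            f"({marker_clusters.threshold} vs {ssu_clusters.threshold})"
        )
    return len(marker_clusters) / len(ssu_clusters)


def extrapolate_carriage(
    cluster_ratio: float,
    genome_marker_fraction: float,
    genome_function_fraction: float,
    marker_clusters: int = 0,
    ssu_clusters: int = 0,
) -> CarriageEstimate:
    """Extrapolate whole-function carriage from marker cluster ratio.

    extrapolated = cluster_ratio × (genome_function_fraction /
    genome_marker_fraction), capped at 1: if the marker's community-wide
    prevalence is ``cluster_ratio`` and, among genomes, the broad function
    is ``function/marker`` times as common as the marker, the community-
    wide prevalence of the function scales accordingly. The reported range
    spans the genome-based and the extrapolated estimate; both inputs are
    carried in the result so the arithmetic is always auditable.
    """
    for name, val in (
        ("cluster_ratio", cluster_ratio),
        ("genome_marker_fraction", genome_marker_fraction),
        ("genome_function_fraction", genome_function_fraction),
    ):
        if not 0.0 < val <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {val}")
    extrapolated = min(1.0, cluster_ratio * genome_function_fraction / genome_marker_fraction)
    low = min(genome_function_fraction, extrapolated)
    high = max(genome_function_fraction, extrapolated)
    note = (
        "extrapolated = cluster_ratio * genome_function_fraction / "
        "genome_marker_fraction (capped at 1); range spans genome-based and "
        "extrapolated estimates"
    )
    warnings.warn(
        "carriage extrapolation is a back-of-envelope scaling; inspect the "
        "inputs recorded in the estimate",
        stacklevel=2,
    )
    return CarriageEstimate(
        marker_cluster_count=marker_clusters,
        ssu_cluster_count=ssu_clusters,
        cluster_ratio=cluster_ratio,
        genome_marker_fraction=genome_marker_fraction,
        genome_function_fraction=genome_function_fraction,
        extrapolated_carriage=extrapolated,
        reported_range=(low, high),
        note=note,
    )
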