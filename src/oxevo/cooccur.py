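"""FDR-filtered co-occurrence networks over compositional count tables.

Two estimators are provided: plain Pearson correlation on log-transformed
relative abundances, and a SparCC-style basis-correlation estimator that
works from log-ratio variances t_ij = var(log(x_i/x_j)) under the sparsity
approximation, with iterative exclusion of the most-correlated pair.
Edges are retained when the BH-adjusted p-value is below alpha and the
correlation magnitude exceeds r_min. The normalized link-count statistic
divides the number of retained positive edges between two node categories
by the number of node pairs compared.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import AbundanceTable


@dataclass
class CooccurrenceNetwork:
    """FDR-filtered weighted co-occurrence graph over features."""

    graph: nx.Graph
    method: str
    alpha: float
    r_min: float
    metadata: dict = field(default_factory=dict)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, **d} for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "r", "p_raw", "q_fdr"])


def _as_counts(table) -> pd.DataFrame:
    if isinstance(table, AbundanceTable):
        return table.counts
    return table


def _drop_constant(counts: pd.DataFrame) -> pd.DataFrame:
    var = counts.var(axis=1)
    constant = var[var == 0].index
    if len(constant):
        warnings.warn(
            f"excluding {len(constant)} zero-variance feature(s): "
            f"{list(constant)[:5]}...",
            stacklevel=3,
        )
        counts = counts.drop(index=constant)
    return counts


def _build_network(features, r, p, alpha, r_min, method, metadata=None) -> CooccurrenceNetwork:
    pairs = list(itertools.combinations(range(len(features)), 2))
    p_flat = np.array([p[i, j] for i, j in pairs])
    q_flat = multipletests(p_flat, method="fdr_bh")[1] if len(p_flat) else np.array([])
    g = nx.Graph()
    g.add_nodes_from(features)
    for (i, j), p_raw, q in zip(pairs, p_flat, q_flat):
        if q < alpha and abs(r[i, j]) > r_min:
            g.add_edge(
                features[i],
                features[j],
                r=float(r[i, j]),
                p_raw=float(p_raw),
                q_fdr=float(q),
            )
    return CooccurrenceNetwork(g, method, alpha, r_min, metadata or {})


def pearson_network(
    table, alpha: float = 0.05, r_min: float = 0.4
) -> CooccurrenceNetwork:
    """All-pairwise Pearson correlations with BH-FDR edge filtering.

    Counts are converted to relative abundances per sample, a pseudocount
    of 1/depth added, and log10-transformed before correlating: the raw
    counts are compositional and heavy-tailed.
    """
    counts = _drop_constant(_as_counts(table))
    n = counts.shape[1]
    if n < 4:
        raise ValueError("at least 4 samples are required")
    depth = counts.sum(axis=0).to_numpy(dtype=float)
    rel = counts.to_numpy(dtype=float) / depth[None, :]
    logrel = np.log10(rel + 1.0 / depth[None, :])

    r = np.corrcoef(logrel)
    r = np.clip(r, -1.0, 1.0)
    # two-sided t-test p-value for each correlation
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 1.0)
    return _build_network(list(counts.index), r, p, alpha, r_min, "pearson")


def _sparcc_basis_correlations(
    logf: np.ndarray, excluded: set[tuple[int, int]]
) -> np.ndarray:
    """Solve the sparse basis-variance system given excluded pairs.

    With t_ij = var(log f_i/f_j) and basis variances w, the sparse
    approximation gives sum_j t_ij ≈ (d-2) w_i + sum_j w_j; excluded pairs
    are removed from both sides of their rows.
    """
    d = logf.shape[0]
    t = np.var(logf[:, None, :] - logf[None, :, :], axis=2, ddof=1)
    mask = np.ones((d, d), dtype=bool)
    np.fill_diagonal(mask, False)
    for i, j in excluded:
        mask[i, j] = mask[j, i] = False
    m = mask.astype(float)
    # row i: sum_j∈mask t_ij = (n_i - 1) w_i + sum_j∈mask w_j
    A = m.copy()
    np.fill_diagonal(A, m.sum(axis=1) - 1.0)
    b = (t * m).sum(axis=1)
    w, *_ = np.linalg.lstsq(A, b, rcond=None)
    w = np.clip(w, 1e-10, None)
    denom = 2.0 * np.sqrt(np.outer(w, w))
    rho = (w[:, None] + w[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_rho(
    counts: np.ndarray, n_iterations: int, exclusion_threshold: float
) -> np.ndarray:
    d = counts.shape[0]
    fractions = (counts + 1.0) / (counts + 1.0).sum(axis=0, keepdims=True)
    logf = np.log(fractions)
    excluded: set[tuple[int, int]] = set()
    rho = _sparcc_basis_correlations(logf, excluded)
    for _ in range(n_iterations):
        off = np.abs(rho.copy())
        np.fill_diagonal(off, 0.0)
        for i, j in excluded:
            off[i, j] = off[j, i] = 0.0
        i, j = np.unravel_index(int(np.argmax(off)), off.shape)
        if off[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        # keep at least 3 usable partners per feature
        partner_count = np.full(d, d - 1)
        for a, b in excluded:
            partner_count[a] -= 1
            partner_count[b] -= 1
        if partner_count.min() < 3:
            excluded.discard((min(i, j), max(i, j)))
            break
        rho_new = _sparcc_basis_correlations(logf, excluded)
        rho_new[i, j] = rho_new[j, i] = rho[i, j]  # keep last estimate for excluded pair
        rho = rho_new
    return rho


def sparcc_network(
    table,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    alpha: float = 0.05,
    r_min: float = 0.4,
    n_permutations: int = 100,
    seed: int = 0,
) -> CooccurrenceNetwork:
    """SparCC-style compositionally aware co-occurrence network.

    Basis correlations are inferred from log-ratio variances; p-values come
    from permutation of sample labels (each feature's samples shuffled
    independently), which is self-contained and distribution-free. The
    permutation seed is recorded in the network metadata.
    """
    counts_df = _drop_constant(_as_counts(table))
    d, n = counts_df.shape
    if d < 4:
        raise ValueError("SparCC requires at least 4 features")
    if n < 4:
        raise ValueError("at least 4 samples are required")
    counts = counts_df.to_numpy(dtype=float)

    rho = _sparcc_rho(counts, n_iterations, exclusion_threshold)

    rng = np.random.default_rng(seed)
    exceed = np.zeros((d, d))
    abs_obs = np.abs(rho)
    for _ in range(n_permutations):
        perm = np.vstack([row[rng.permutation(n)] for row in counts])
        rho_p = _sparcc_rho(perm, 0, exclusion_threshold)
        exceed += np.abs(rho_p) >= abs_obs
    p = (1.0 + exceed) / (n_permutations + 1.0)
    np.fill_diagonal(p, 1.0)

    return _build_network(
        list(counts_df.index),
        rho,
        p,
        alpha,
        r_min,
        "sparcc",
        metadata={
            "n_permutations": n_permutations,
            "seed": seed,
            "n_iterations": n_iterations,
            "exclusion_threshold": exclusion_threshold,
        },
    )


@dataclass
class LinkCountMatrix:
    """Normalized positive-link counts between node categories."""

    values: pd.DataFrame  # symmetric, in [0, 1]
    denominators: pd.DataFrame
    normalization: str = "pairs"


def normalized_link_counts(
    network: CooccurrenceNetwork,
    category_map: dict[str, str],
    norm: str = "pairs",
) -> LinkCountMatrix:
    """Count retained positive edges per category pair, normalized.

    With ``norm="pairs"`` the denominator is the number of distinct node
    pairs compared: |C1|·|C2| across categories and |C|(|C|−1)/2 within.
    ``norm="nodes"`` divides by the number of nodes involved instead.
    Negative edges are not counted (the statistic is about positive
    co-occurrence).
    """
    if norm not in ("pairs", "nodes"):
        raise ValueError("norm must be 'pairs' or 'nodes'")
    nodes = list(network.graph.nodes)
    missing = [v for v in nodes if v not in category_map]
    if missing:
        raise ValueError(f"uncategorized node(s): {missing[:5]}")
    cats = sorted(set(category_map[v] for v in nodes))
    sizes = {c: sum(1 for v in nodes if category_map[v] == c) for c in cats}

    counts = pd.DataFrame(0.0, index=cats, columns=cats)
    for u, v, d in network.graph.edges(data=True):
        if d["r"] > 0:
            cu, cv = category_map[u], category_map[v]
            counts.loc[cu, cv] += 1
            if cu != cv:
                counts.loc[cv, cu] += 1

    denom = pd.DataFrame(0.0, index=cats, columns=cats)
    for c1 in cats:
        for c2 in cats:
            if norm == "pairs":
                denom.loc[c1, c2] = (
                    sizes[c1] * (sizes[c1] - 1) / 2 if c1 == c2 else sizes[c1] * sizes[c2]
                )
            else:
                denom.loc[c1, c2] = sizes[c1] + (0 if c1 == c2 else sizes[c2])
    with np.errstate(divide="ignore", invalid="ignore"):
        values = counts / denom
    values = values.fillna(0.0)
    return LinkCountMatrix(values, denom, norm)


def export_network(network: CooccurrenceNetwork, out_dir, prefix: str = "network",
                   category_map: dict[str, str] | None = None) -> tuple[str, str]:
    """Write a Cytoscape-loadable edge list and node attribute table."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edge_path = out / f"{prefix}_edges.tsv"
    node_path = out / f"{prefix}_nodes.tsv"
    network.edges.to_csv(edge_path, sep="\t", index=False, na_rep="NA")
    nodes = pd.DataFrame(
        {
            "node": list(network.graph.nodes),
            "category": [
                (category_map or {}).get(v, "NA") for v in network.graph.nodes
            ],
        }
    )
    nodes.to_csv(node_path, sep="\t", index=False, na_rep="NA")
    return str(edge_path), str(node_path)


def read_network(edge_path, alpha: float = 0.05, r_min: float = 0.4,
                 method: str = "unknown") -> CooccurrenceNetwork:
    """Read an exported edge list back into a network object."""
    df = pd.read_csv(edge_path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples():
        g.add_edge(row.source, row.target, r=row.r, p_raw=row.p_raw, q_fdr=row.q_fdr)
    return CooccurrenceNetwork(g, method, alpha, r_min)
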