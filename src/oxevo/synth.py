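"""Synthetic data generation with known ground truth.

Every input the analysis pipeline consumes can be simulated here: a rooted
ultrametric species taxonomy, annotated genomes with pathway gene content
under a configurable horizontal-gene-transfer (HGT) rate, in-frame codon
alignments evolved at a target dN/dS ratio ω, and compositional count
tables with planted correlation structure. All generators are
deterministic given (parameters, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .dnds import (
    BASES,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    is_transition,
)
from .screen import AnnotatedGenome, PathwayCatalog, assess_quality, single_copy_reference


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``hgt_rate`` is the expected number of horizontal transfer events per
    gene per tree; ``omega`` the target dN/dS of the codon simulator;
    ``depth`` the fixed per-sample sequencing depth the count tables are
    closed to; ``corr_spec`` a list of (feature tuple, latent correlation).
    """

    n_species: int = 32
    n_phyla: int = 4
    hgt_rate: float = 0.0
    omega: float = 1.0
    n_codons: int = 300
    n_samples: int = 50
    depth: int = 10_000
    corr_spec: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_phyla < 1 or self.n_phyla > self.n_species:
            raise ValueError("n_phyla must be in [1, n_species]")
        if self.hgt_rate < 0:
            raise ValueError("hgt_rate must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        for _, rho in self.corr_spec:
            if not -1.0 <= rho <= 1.0:
                raise ValueError("correlations must be in [-1, 1]")
        for name in ("n_codons", "n_samples", "depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did — for recovery tests downstream."""

    true_tree: TreeNode | None = None
    gene_carriers: dict[str, set[str]] = field(default_factory=dict)  # gene -> species
    hgt_events: list[tuple[str, str, str]] = field(default_factory=list)  # gene, donor, recipient
    true_omega: dict[str, float] = field(default_factory=dict)  # branch (node name) -> omega
    planted_edges: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class AbundanceTable:
    """Feature x sample count matrix, closed to a fixed depth per sample."""

    counts: pd.DataFrame  # rows: features, columns: samples
    categories: dict[str, str] = field(default_factory=dict)
    latent: pd.DataFrame | None = None  # latent log-abundances (ground truth)

    @property
    def depth(self) -> int:
        return int(self.counts.sum(axis=0).iloc[0])


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def simulate_taxonomy(
    n_species: int, n_phyla: int = 4, seed: int = 0, genera_per_phylum: int = 2
) -> TreeNode:
    """Random rooted ultrametric binary tree with phylum/genus labels.

    Coalescent-style: lineages merge pairwise at exponentially spaced
    times, giving an ultrametric binary tree. Phyla are the ``n_phyla``
    deepest clades that partition the tips (guaranteeing monophyly), and
    genera subdivide each phylum the same way. Tip nodes carry ``phylum``
    and ``genus`` attributes; use :func:`taxonomy_table` to extract them.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not 1 <= n_phyla <= n_species:
        raise ValueError("n_phyla must be in [1, n_species]")
    rng = np.random.default_rng(seed)

    lineages: list[TreeNode] = []
    heights: list[float] = []
    for i in range(n_species):
        tip = TreeNode(name=f"sp{i + 1:04d}")
        lineages.append(tip)
        heights.append(0.0)
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(scale=1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = lineages[i], lineages[j]
        a.length = t - heights[i]
        b.length = t - heights[j]
        parent = TreeNode(children=[a, b])
        lineages[i] = parent
        heights[i] = t
        del lineages[j], heights[j]
    root = lineages[0]
    root.length = None

    def node_height(node: TreeNode) -> float:
        h = 0.0
        cur = node
        while cur.children:
            cur = cur.children[0]
            h += cur.length
        return h

    def split_deepest(blocks: list[TreeNode], k: int) -> list[TreeNode]:
        blocks = list(blocks)
        while len(blocks) < k:
            splittable = [b for b in blocks if b.children]
            if not splittable:
                break
            deepest = max(splittable, key=node_height)
            blocks.remove(deepest)
            blocks.extend(deepest.children)
        return blocks

    phylum_blocks = split_deepest([root], n_phyla)
    for p_idx, block in enumerate(phylum_blocks, start=1):
        phylum = f"Phylum{p_idx:02d}"
        genus_blocks = split_deepest([block], genera_per_phylum)
        for g_idx, gblock in enumerate(genus_blocks, start=1):
            genus = f"{phylum}_Genus{g_idx:02d}"
            for tip in gblock.tips(include_self=True):
                tip.phylum = phylum
                tip.genus = genus
    return root


def taxonomy_table(tree: TreeNode) -> pd.DataFrame:
    """Tip taxonomy (species, genus, phylum) of a simulated tree."""
    rows = [
        {"species": tip.name, "genus": getattr(tip, "genus", "NA"),
         "phylum": getattr(tip, "phylum", "NA")}
        for tip in tree.tips()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene content / genomes
# ---------------------------------------------------------------------------

def _name_internals(tree: TreeNode) -> None:
    i = 0
    for node in tree.preorder(include_self=True):
        if not node.name:
            node.name = f"node{i:04d}"
            i += 1


def simulate_gene_content(
    tree: TreeNode,
    catalog: PathwayCatalog,
    hgt_rate: float = 0.0,
    seed: int = 0,
    gain_node: str | None = None,
    scg_dropout_rate: float = 0.0,
    scg_duplication_rate: float = 0.0,
) -> tuple[list[AnnotatedGenome], GroundTruth]:
    """Evolve pathway gene content along a species tree.

    Each catalog gene is gained once on a uniformly chosen non-root branch
    (or the branch above ``gain_node`` if given), making its carriers
    exactly that clade's tips. A Poisson(``hgt_rate``) number of horizontal
    transfers per gene then copies the gene into recipient clades chosen
    uniformly outside the current carrier set, which is what makes gene
    presence taxonomically incongruent. Every genome additionally carries
    the 41 universal single-copy markers, optionally with per-marker
    dropout/duplication noise so that genome quality varies.
    """
    if hgt_rate < 0:
        raise ValueError("hgt_rate must be >= 0")
    if len(catalog) == 0:
        raise ValueError("pathway catalog must be non-empty")
    rng = np.random.default_rng(seed)
    tree = tree.copy()
    _name_internals(tree)
    nodes = [n for n in tree.preorder(include_self=False)]  # all non-root branches
    tips = list(tree.tips())
    tip_names = [t.name for t in tips]

    truth = GroundTruth(true_tree=tree)
    genome_genes: dict[str, list[str]] = {name: [] for name in tip_names}

    scg = sorted(single_copy_reference())
    for name in tip_names:
        for gene in scg:
            if scg_dropout_rate and rng.random() < scg_dropout_rate:
                continue
            genome_genes[name].append(gene)
            if scg_duplication_rate and rng.random() < scg_duplication_rate:
                genome_genes[name].append(gene)

    for gene in sorted(catalog):
        if gain_node is not None:
            origin = next(n for n in nodes if n.name == gain_node)
        else:
            origin = nodes[rng.integers(len(nodes))]
        carriers = {t.name for t in origin.tips(include_self=True)}
        n_events = rng.poisson(hgt_rate)
        for _ in range(n_events):
            candidates = [n for n in nodes
                          if not {t.name for t in n.tips(include_self=True)} <= carriers]
            if not candidates:
                break
            recipient = candidates[rng.integers(len(candidates))]
            donor = sorted(carriers)[rng.integers(len(carriers))]
            carriers |= {t.name for t in recipient.tips(include_self=True)}
            truth.hgt_events.append((gene, donor, recipient.name))
        truth.gene_carriers[gene] = carriers
        for name in carriers:
            genome_genes[name].append(gene)

    tax = {t.name: (getattr(t, "genus", "NA"), getattr(t, "phylum", "NA")) for t in tips}
    genomes = []
    for name in tip_names:
        completeness, purity = assess_quality(genome_genes[name], frozenset(scg))
        genus, phylum = tax[name]
        genomes.append(
            AnnotatedGenome(
                genome_id=name,
                phylum=phylum,
                genus=genus,
                genes=genome_genes[name],
                completeness=completeness,
                purity=purity,
            )
        )
    return genomes, truth


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

_KAPPA_DEFAULT = 2.0


def _codon_rate_table(omega: float, kappa: float) -> dict[str, tuple[list[str], np.ndarray, float]]:
    """Per-codon neighbour lists and normalized substitution rates.

    Goldman–Yang-style: only single-nucleotide changes, uniform codon
    frequencies, rate ∝ κ for transitions and ∝ ω for nonsynonymous
    changes; changes into stop codons have rate 0. Rates are scaled so the
    mean total leaving rate over sense codons is 1, i.e. branch lengths are
    expected substitutions per codon.
    """
    table: dict[str, tuple[list[str], np.ndarray, float]] = {}
    totals = []
    for codon in SENSE_CODONS:
        neighbors: list[str] = []
        rates: list[float] = []
        for pos in range(3):
            for base in BASES:
                if base == codon[pos]:
                    continue
                neigh = codon[:pos] + base + codon[pos + 1 :]
                if neigh in STOP_CODONS:
                    continue
                rate = kappa if is_transition(codon[pos], base) else 1.0
                if GENETIC_CODE[neigh] != GENETIC_CODE[codon]:
                    rate *= omega
                neighbors.append(neigh)
                rates.append(rate)
        arr = np.array(rates)
        table[codon] = (neighbors, arr, float(arr.sum()))
        totals.append(arr.sum())
    scale = float(np.mean(totals))
    return {
        c: (nb, r / scale, tot / scale) for c, (nb, r, tot) in table.items()
    }


def _evolve_codon(codon: str, t: float, rates, rng: np.random.Generator) -> str:
    """Gillespie simulation of one codon site over branch duration t."""
    remaining = t
    while True:
        neighbors, rate_arr, total = rates[codon]
        if total <= 0:
            return codon
        wait = rng.exponential(1.0 / total)
        if wait >= remaining:
            return codon
        remaining -= wait
        codon = neighbors[rng.choice(len(neighbors), p=rate_arr / total)]


def simulate_codon_alignment(
    tree: TreeNode,
    omega: float,
    n_codons: int,
    seed: int = 0,
    kappa: float = _KAPPA_DEFAULT,
    branch_omega: dict[str, float] | None = None,
) -> tuple[CodonAlignment, GroundTruth]:
    """Evolve an in-frame codon alignment along a tree.

    Branch lengths are interpreted as expected substitutions per codon
    (at the simulation's own (ω, κ)). ``branch_omega`` optionally overrides
    ω on named branches, e.g. to put elevated dN/dS on one clade. No
    indels are simulated and stop codons are unreachable by construction,
    so the output satisfies the codon-alignment invariants exactly.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    rng = np.random.default_rng(seed)
    tree = tree.copy()
    _name_internals(tree)

    rate_cache: dict[float, dict] = {}

    def rates_for(w: float):
        if w not in rate_cache:
            rate_cache[w] = _codon_rate_table(w, kappa)
        return rate_cache[w]

    truth = GroundTruth(true_tree=tree)
    root_seq = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    sequences: dict[str, list[str]] = {}

    node_seq = {tree: root_seq}
    for node in tree.preorder(include_self=False):
        w = (branch_omega or {}).get(node.name, omega)
        truth.true_omega[node.name] = w
        rates = rates_for(w)
        t = node.length if node.length is not None else 0.0
        parent_seq = node_seq[node.parent]
        if t <= 0:
            child = list(parent_seq)
        else:
            child = [_evolve_codon(c, t, rates, rng) for c in parent_seq]
        node_seq[node] = child
        if not node.children:
            sequences[node.name] = child

    ids = tuple(sorted(sequences))
    taxonomy = {}
    for tip in tree.tips():
        taxonomy[tip.name] = (getattr(tip, "genus", "NA"), getattr(tip, "phylum", "NA"))
    aln = CodonAlignment(
        ids=ids,
        sequences=tuple("".join(sequences[i]) for i in ids),
        taxonomy=taxonomy,
    )
    return aln, truth


def two_taxon_tree(branch_length: float) -> TreeNode:
    """Convenience: a two-tip tree with equal branch lengths."""
    a = TreeNode(name="a", length=branch_length)
    b = TreeNode(name="b", length=branch_length)
    return TreeNode(children=[a, b])


def simulate_community_markers(
    n_species: int = 500,
    carriage: float = 0.2,
    length: int = 100,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], set[str]]:
    """A community where a known fraction of species carries a marker gene.

    Every species gets an independent random 16S-like sequence; a fraction
    ``carriage`` of species (chosen at random) additionally carries an
    independent random marker sequence. Independent random sequences sit
    far below any realistic clustering threshold from one another, so
    identity clustering at e.g. 97% recovers one cluster per species for
    each gene — the clean-clustering regime for carriage-ratio recovery.

    Returns (16S sequences, marker sequences, carrier species IDs).
    """
    if not 0.0 < carriage <= 1.0:
        raise ValueError("carriage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1:04d}" for i in range(n_species)]
    n_carriers = int(round(carriage * n_species))
    carriers = set(rng.choice(species, size=n_carriers, replace=False))
    bases = np.array(list(BASES))
    ssu = {
        f"{sp}_ssu": "".join(bases[rng.integers(0, 4, size=length)]) for sp in species
    }
    marker = {
        f"{sp}_marker": "".join(bases[rng.integers(0, 4, size=length)])
        for sp in species
        if sp in carriers
    }
    return ssu, marker, carriers


def simulate_gene_families(
    tree: TreeNode,
    length: int = 200,
    rate: float = 1.0,
    hgt_rate: float = 0.0,
    hgt_noise: float = 0.01,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], list[tuple[str, str]]]:
    """Per-species marker gene sequences evolved along the taxonomy.

    A root sequence evolves by a Jukes–Cantor process (per-branch
    substitution probability 3/4·(1 − exp(−4/3·rate·length))), so deep
    phylum splits leave low between-phylum identity and shallow splits
    high within-phylum identity. A Poisson(``hgt_rate``) number of
    horizontal transfers then overwrite a recipient clade's sequences with
    a donor tip's sequence (plus ``hgt_noise`` per-site mutations), which
    is what erodes the taxonomic purity of similarity-network clusters.

    Returns (sequences by species, phylum by species, [(donor, recipient)]).
    """
    if hgt_rate < 0:
        raise ValueError("hgt_rate must be >= 0")
    rng = np.random.default_rng(seed)
    tree = tree.copy()
    _name_internals(tree)
    base_idx = {b: i for i, b in enumerate(BASES)}

    def mutate(seq: np.ndarray, branch_length: float) -> np.ndarray:
        p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * branch_length))
        hit = rng.random(len(seq)) < p
        out = seq.copy()
        out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        return out

    node_seq = {tree: rng.integers(0, 4, size=length)}
    for node in tree.preorder(include_self=False):
        node_seq[node] = mutate(node_seq[node.parent], node.length or 0.0)

    seqs = {
        tip.name: "".join(BASES[i] for i in node_seq[tip]) for tip in tree.tips()
    }
    phyla = {tip.name: getattr(tip, "phylum", "NA") for tip in tree.tips()}

    events: list[tuple[str, str]] = []
    nodes = [n for n in tree.preorder(include_self=False)]
    tip_names = sorted(seqs)
    for _ in range(rng.poisson(hgt_rate)):
        recipient = nodes[rng.integers(len(nodes))]
        rec_tips = {t.name for t in recipient.tips(include_self=True)}
        donors = [t for t in tip_names if t not in rec_tips]
        if not donors:
            continue
        donor = donors[rng.integers(len(donors))]
        donor_arr = np.array([base_idx[b] for b in seqs[donor]])
        for t in sorted(rec_tips):
            noisy = donor_arr.copy()
            hit = rng.random(length) < hgt_noise
            noisy[hit] = (noisy[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            seqs[t] = "".join(BASES[i] for i in noisy)
        events.append((donor, recipient.name))
    return seqs, phyla, events


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

def simulate_abundance(
    features: list[str],
    corr_spec: list[tuple[tuple[str, ...], float]] | None = None,
    n_samples: int = 50,
    depth: int = 10_000,
    seed: int = 0,
    log_mean_sd: float = 1.0,
    log_sd: float = 1.0,
    categories: dict[str, str] | None = None,
) -> tuple[AbundanceTable, GroundTruth]:
    """Compositional count table with planted latent correlations.

    Latent per-sample log-abundances are multivariate normal with the
    correlation structure planted by ``corr_spec``; exponentiating and
    closing each sample to ``depth`` total counts by multinomial sampling
    produces the observed (compositional) table. Per-feature baseline
    log-means are drawn once with spread ``log_mean_sd``.
    """
    corr_spec = corr_spec or []
    if len(features) < 4:
        raise ValueError("at least 4 features are required")
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if depth < 1000:
        raise ValueError("depth must be >= 1000")
    idx = {f: i for i, f in enumerate(features)}
    p = len(features)

    corr = np.eye(p)
    truth = GroundTruth()
    for group, rho in corr_spec:
        if not -1.0 <= rho <= 1.0:
            raise ValueError("planted correlations must be in [-1, 1]")
        for fa, fb in itertools.combinations(group, 2):
            if fa not in idx or fb not in idx:
                raise ValueError(f"corr_spec references unknown feature in {group}")
            corr[idx[fa], idx[fb]] = corr[idx[fb], idx[fa]] = rho
            truth.planted_edges.append((fa, fb, rho))

    # repair to nearest PSD if the planted structure is inconsistent
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < 1e-10:
        eigval = np.clip(eigval, 1e-10, None)
        corr = eigvec @ np.diag(eigval) @ eigvec.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)

    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, log_mean_sd, size=p)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(p))
    z = rng.standard_normal(size=(n_samples, p)) @ chol.T
    latent = base[None, :] + log_sd * z
    weights = np.exp(latent)
    probs = weights / weights.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, probs[s]) for s in range(n_samples)]).T

    samples = [f"s{j + 1:03d}" for j in range(n_samples)]
    table = AbundanceTable(
        counts=pd.DataFrame(counts, index=features, columns=samples),
        categories=categories or {},
        latent=pd.DataFrame(latent.T, index=features, columns=samples),
    )
    return table, truth
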