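"""End-to-end pipeline driver with provenance manifest.

Runs simulate → screen → cooccur → cluster → dnds → phylo → ssn →
redundancy on a synthetic community and records, for every stage, its
parameters, seed, output files and SHA-256 checksums. All randomness
derives from one top-level seed: stage k uses
``numpy.random.SeedSequence([seed, k])`` reduced to a 31-bit integer, so
changing the top-level seed changes every stochastic stage while keeping
the derivation documented and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster, cooccur, dnds, io, phylo, redundancy, screen, ssn, synth

STAGES = (
    "simulate",
    "screen",
    "cooccur",
    "cluster",
    "dnds",
    "phylo",
    "ssn",
    "redundancy",
)


@dataclass
class PipelineConfig:
    """Validated per-stage parameters for a demo-scale run."""

    seed: int = 0
    n_species: int = 24
    n_phyla: int = 3
    hgt_rate: float = 1.0
    omega: float = 1.0
    n_codons: int = 100
    n_samples: int = 40
    depth: int = 5000
    alpha: float = 0.05
    r_min: float = 0.4
    cluster_threshold: float = 0.97
    ssn_cutoffs: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
    n_bootstrap: int = 200
    cooccur_method: str = "pearson"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.r_min < 1:
            raise ValueError("r_min must be in [0, 1)")
        if not 0.5 < self.cluster_threshold <= 1:
            raise ValueError("cluster_threshold must be in (0.5, 1]")
        if list(self.ssn_cutoffs) != sorted(self.ssn_cutoffs):
            raise ValueError("ssn_cutoffs must be ascending")
        if self.cooccur_method not in ("pearson", "sparcc"):
            raise ValueError("cooccur_method must be pearson or sparcc")
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.validate()
        return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Derived 31-bit stage seed from the top-level seed."""
    k = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> list[dict]:
    """Execute all stages in dependency order; return the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        manifest.append(
            {
                "stage": stage,
                "seed": stage_seed(config.seed, stage),
                "parameters": params,
                "outputs": {str(p.name): _checksum(p) for p in outputs},
            }
        )

    # -- simulate ----------------------------------------------------------
    s = stage_seed(config.seed, "simulate")
    tree = synth.simulate_taxonomy(config.n_species, config.n_phyla, seed=s)
    catalog = screen.PathwayCatalog.default()
    genomes, truth = synth.simulate_gene_content(
        tree, catalog, hgt_rate=config.hgt_rate, seed=s + 1
    )
    aln, aln_truth = synth.simulate_codon_alignment(
        tree, omega=config.omega, n_codons=config.n_codons, seed=s + 2
    )
    features = [f"g{i:03d}" for i in range(8)]
    corr = [((features[0], features[1]), 0.9)]
    table, ab_truth = synth.simulate_abundance(
        features, corr, n_samples=config.n_samples, depth=config.depth, seed=s + 3
    )
    p_tree = out / "taxonomy.nwk"
    io.write_newick(tree, p_tree)
    p_gen = out / "genomes.tsv"
    io.write_genomes(genomes, p_gen)
    p_aln = out / "alignment.fasta"
    io.write_fasta(dict(zip(aln.ids, aln.sequences)), p_aln)
    p_ab = out / "abundance.tsv"
    io.write_abundance(table, p_ab)
    p_truth = out / "ground_truth.json"
    io.write_ground_truth(truth, p_truth)
    record("simulate", {"n_species": config.n_species, "hgt_rate": config.hgt_rate,
                        "omega": config.omega}, [p_tree, p_gen, p_aln, p_ab, p_truth])

    # -- screen -------------------------------------------------------------
    retained = screen.filter_quality(genomes)
    profiles = [screen.screen_pathways(g, catalog) for g in retained]
    summary = screen.summarize_carriage(profiles)
    p_comb = out / "carriage_combinations.tsv"
    io.write_tsv(summary.combination_table, p_comb)
    p_path = out / "carriage_pathways.tsv"
    io.write_tsv(summary.pathway_table, p_path)
    record("screen", {"n_retained": len(retained)}, [p_comb, p_path])

    # -- cooccur ------------------------------------------------------------
    s = stage_seed(config.seed, "cooccur")
    if config.cooccur_method == "sparcc":
        net = cooccur.sparcc_network(table, alpha=config.alpha, r_min=config.r_min, seed=s)
    else:
        net = cooccur.pearson_network(table, alpha=config.alpha, r_min=config.r_min)
    cats = {f: ("planted" if f in features[:2] else "background") for f in features}
    links = cooccur.normalized_link_counts(net, cats)
    edge_path, node_path = cooccur.export_network(net, out, prefix="cooccur",
                                                  category_map=cats)
    p_links = out / "link_counts.tsv"
    io.write_tsv(links.values, p_links, index=True)
    record("cooccur", {"method": net.method, "alpha": config.alpha,
                       "r_min": config.r_min}, [Path(edge_path), Path(node_path), p_links])

    # -- cluster ------------------------------------------------------------
    seqs = dict(zip(aln.ids, aln.sequences))
    clusters = cluster.greedy_cluster(seqs, threshold=config.cluster_threshold)
    p_clu = out / "clusters.tsv"
    io.write_clusters(clusters, p_clu)
    record("cluster", {"threshold": config.cluster_threshold,
                       "n_clusters": len(clusters)}, [p_clu])

    # -- dnds ---------------------------------------------------------------
    s = stage_seed(config.seed, "dnds")
    phylum_map = {sid: ph for sid, (_g, ph) in aln.taxonomy.items()}
    results, profile = dnds.selection_profile(
        aln, phylum_map, alpha=config.alpha, n_bootstrap=config.n_bootstrap, seed=s
    )
    p_pairs = out / "dnds_pairs.tsv"
    io.write_tsv(dnds.results_table(results), p_pairs)
    p_prof = out / "selection_profile.tsv"
    io.write_tsv(profile, p_prof)
    record("dnds", {"alpha": config.alpha, "n_bootstrap": config.n_bootstrap,
                    "seed": s}, [p_pairs, p_prof])

    # -- phylo --------------------------------------------------------------
    tip_dist = tree.tip_tip_distances()
    nj = phylo.nj_tree(tip_dist)
    rt = phylo.reltime(tree.copy())
    p_nj = out / "nj.nwk"
    io.write_newick(nj, p_nj)
    p_rt = out / "reltime.tsv"
    io.write_tsv(phylo.reltime_table(rt), p_rt)
    record("phylo", {}, [p_nj, p_rt])

    # -- ssn ----------------------------------------------------------------
    phyla = {sid: ph for sid, (_g, ph) in aln.taxonomy.items()}
    graphs, sweep = ssn.ssn_sweep(seqs, cutoffs=config.ssn_cutoffs, phyla=phyla)
    p_sweep = out / "ssn_sweep.tsv"
    io.write_tsv(sweep, p_sweep)
    purity_rows = []
    for cutoff, sg in graphs.items():
        _table, weighted = ssn.taxonomic_purity(sg)
        purity_rows.append({"cutoff": cutoff, "mean_purity": weighted})
    p_pur = out / "ssn_purity.tsv"
    io.write_tsv(pd.DataFrame(purity_rows), p_pur)
    record("ssn", {"cutoffs": list(config.ssn_cutoffs)}, [p_sweep, p_pur])

    # -- redundancy ---------------------------------------------------------
    ssu = cluster.greedy_cluster(seqs, threshold=config.cluster_threshold)
    ratio = redundancy.cluster_ratio(clusters, ssu)
    import warnings as _warnings

    o_frac = max(summary.oxalate_carriage, 1e-6)
    marker_frac = max(
        sum(1 for p in profiles if "frc" in p.gene_hits) / max(len(profiles), 1), 1e-6
    )
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        est = redundancy.extrapolate_carriage(
            min(1.0, ratio), min(1.0, marker_frac), min(1.0, o_frac),
            marker_clusters=len(clusters), ssu_clusters=len(ssu),
        )
    p_est = out / "carriage_estimate.tsv"
    io.write_tsv(pd.DataFrame([asdict(est)]), p_est)
    record("redundancy", {"threshold": config.cluster_threshold}, [p_est])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
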