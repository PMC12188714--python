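# Methods

This note documents the models, estimators and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
design decisions taken where several defensible options existed.

## Synthetic data (`oxevo.synth`)

**Taxonomy.** `simulate_taxonomy` draws a rooted ultrametric binary tree by a
Kingman-style coalescent (pairwise merging at exponentially spaced times with
rate k(k−1)/2 among k open lineages). Phyla are defined as the k deepest
clades that partition the tips — obtained by repeatedly splitting the deepest
remaining block — which guarantees monophyly by construction; genera
subdivide each phylum the same way (default two per phylum). All generators
take an explicit integer seed and are bit-deterministic given (parameters,
seed).

**Gene content.** Each catalog gene is gained once on a uniformly chosen
non-root branch, so with `hgt_rate = 0` its carriers are exactly one clade's
tips (pure vertical inheritance). Horizontal transfer is a Poisson process
per gene: each event copies the gene into a uniformly chosen recipient clade
not already fully carrying it, and is recorded as (gene, donor, recipient) in
the ground truth. Genomes also carry the 41 universal single-copy markers;
optional per-marker dropout and duplication rates make completeness and
purity vary, emulating imperfect metagenome-assembled genomes. The generator
does **not** emulate annotation error (mislabelled genes), partial gene
fragments, or lineage-specific gene loss; passing tests therefore show the
screening arithmetic is correct, not that annotation noise is handled.

**Codon alignments.** A Goldman–Yang-style continuous-time process restricted
to single-nucleotide changes, uniform codon frequencies, transition/
transversion ratio κ (default 2), nonsynonymous rate = ω × synonymous rate.
Changes into stop codons have rate zero, so internal stops are unreachable
(equivalent to proposal rejection). Rates are normalized so the mean total
leaving rate over the 61 sense codons equals 1 — branch lengths are expected
substitutions per codon at the simulation's own (ω, κ). Sites evolve
independently by Gillespie simulation along each branch. No indels, no rate
heterogeneity across sites, no codon-frequency bias: ω-recovery results
transfer to real data only insofar as these assumptions hold.

**Abundance tables.** Latent per-sample log-abundances are multivariate
normal with unit variance and a correlation matrix assembled from the planted
(feature-set, ρ) specification (repaired to the nearest positive-semidefinite
matrix if inconsistent); per-feature baseline log-means have spread 1 (a
moderately heavy-tailed community). Exponentiated abundances are closed to a
fixed depth by multinomial sampling, so columns sum exactly to the depth and
the data are genuinely compositional. Multinomial (not Dirichlet-multinomial)
closure is the default; there is no overdispersion beyond the multinomial.
A practical consequence kept visible in the tests: with very few features
(≲10) closure alone induces strong spurious negative correlations in
Pearson-on-log-relative-abundance analyses; null calibration studies
therefore use a realistic panel size of 30 features.

**Gene families and communities.** `simulate_gene_families` evolves a
nucleotide sequence along the taxonomy by a Jukes–Cantor process (per-branch
hit probability 3/4·(1 − e^(−4/3·rate·l))) so sequence identity tracks
phylogenetic depth; HGT events overwrite a recipient clade's sequences with
a donor tip's sequence plus 1% noise. `simulate_community_markers` gives each
of n species an independent random "16S" sequence and a fraction f of them an
independent random marker sequence — under the alignment scoring used here
random DNA pairs sit near 50% identity, far below the 97% threshold, so
clustering recovers one cluster per species (the clean-clustering regime).

## Pathway screening (`oxevo.screen`)

Gene matching is by exact normalized label (case-folded, punctuation
stripped); fuzzy product-string matching is out of scope because the
generator emits canonical labels. The shipped OAMSF catalog (editable TSV) is
a synthetic stand-in: the canonical oxalate-handling genes (oxlT, frc, oxc,
succinyl-CoA- and acetyl-CoA:oxalate transferases, oxalate oxidase/
decarboxylase, oxalate-binding protein) plus representative genes for the
acetogenic, methanogenic, sulfate-reduction and formate pathways, including
one deliberately multi-pathway gene (formate dehydrogenase, tagged A+M+F).
The 41-marker single-copy list is likewise a stand-in (ribosomal proteins and
core information-processing genes). Quality filtering uses strict
inequalities (completeness > 0.80 AND purity > 0.90). A genome containing no
markers has completeness 0 and purity 1 by convention (no evidence of
contamination). Pathway combinations below 1% of genomes are aggregated as
"Other"; fractions including "Other" and "none" sum to 1.

## Co-occurrence networks (`oxevo.cooccur`)

Pearson correlations run on log10(relative abundance + 1/depth); the
pseudocount of one expected count keeps zeros finite while preserving order.
p-values come from the t-transform of r; SparCC p-values from permutation of
each feature's sample labels independently (default 100 permutations, seed
recorded in metadata; permutation replicates skip the pair-exclusion loop for
speed). With m feature pairs, 100 permutations bound the smallest achievable
q-value at roughly m/101, so small edge sets need more permutations to pass
an FDR filter — the correlation estimates themselves are unaffected. The
SparCC basis-variance system sum_j t_ij ≈ (d−2)ω_i + Σ_j ω_j is solved by
least squares, with iterative exclusion of the most correlated pair (above
threshold 0.1, up to 20 iterations, keeping ≥3 usable partners per feature).
Both estimators feed the same edge filter: BH q < α and |r| > r_min (defaults
0.05 and 0.4). Negative edges are kept in the network object but excluded
from the link-count statistic, which counts positive co-occurrence only. The
link-count denominator is the number of node pairs compared (|C1|·|C2|
across, |C|(|C|−1)/2 within); a `norm="nodes"` alternative divides by node
counts instead.

## Identity and clustering (`oxevo.cluster`, `oxevo.ssn`)

Identity = matching columns of the optimal global alignment (match +1,
mismatch 0, linear gap −1) divided by the shorter sequence length — the
CD-HIT convention; the definition string travels with every ClusterSet.
Because co-optimal alignments can differ in match count, arguments are
canonically ordered before aligning, making identity exactly symmetric and
deterministic. Greedy clustering processes sequences longest-first (ties by
sequence then ID) and joins the first representative, in founding order, at
or above the threshold. No k-mer prescreening is used — inputs are
desk-scale. The similarity-network module shares this identity function
(single source of truth), so SSN components and cluster memberships are
mutually consistent. Amplicon trimming takes 0-based half-open coordinates or
locates primers by best match with at most 2 mismatches.

The nearest-reference on/off-target rule replaces a tree-based annotation
check with the equivalent accept/reject contract: a query is on-target iff
its best identity to any reference reaches the threshold; the NJ tree remains
available in `oxevo.phylo` for visual validation.

## dN/dS (`oxevo.dnds`)

Potential sites per codon: at each position, the fraction of single-
nucleotide changes that are synonymous, with changes into stop codons removed
from the denominator (a standard NG86 variant; recorded in output metadata).
s + n = 3 exactly per codon. Observed differences average over all orderings
of the differing positions, discarding pathways through stops; a codon pair
with no stop-free pathway is skipped with a warning, as are columns with
non-ACGT characters (pairwise deletion). Proportions use the pair-averaged
site counts, are Jukes–Cantor corrected, and pS or pN ≥ 3/4 flags the pair as
saturated. The Z-test variance comes from bootstrap over codon columns
(default 1000 replicates, seeded); the bootstrap resamples column indices, so
results are exactly symmetric under argument swap. An analytical-variance
variant was deliberately not implemented: the bootstrap is assumption-light
and the variance method plus replicate count are recorded in every result.
In `selection_profile`, BH correction is applied jointly across all pairs
(separately for the positive and negative one-tailed families), and calls are
binned by unordered phylum pair. A caveat inherited from the method itself:
pathway averaging attributes small fractional nonsynonymous counts even to
purely synonymous histories (through nonsynonymous intermediates), so ω
estimates at very small true ω are near but not exactly zero; and pairwise
comparisons between sequences sharing tree paths are not independent — the
phylum-pair profile is descriptive, not a formal test.

## Phylogenetics (`oxevo.phylo`)

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q-criterion;
ties break on the smallest index pair, branch lengths use the standard
row-sum formulas without clamping (additive inputs are reproduced exactly;
negative estimates are possible on non-additive inputs, as in the classical
algorithm). The relative-time estimator works on branch lengths, not
sequences: post-order, each node's lineage depth h is the tip-count-weighted
mean of (child branch + child depth) — the unweighted mean is available by
flag — and top-down, child time = parent time × h_child/(l + h_child), root
time 1, tips 0. The per-branch relative rate l/Δt then satisfies
branch length = rate × duration exactly, and an ultrametric tree yields equal
rates and times equal to normalized depths. Zero-length internal branches are
collapsed first; the resulting polytomies are handled by the same weighted
mean, while the root must be bifurcating (callers root by outgroup first —
the root is placed at the midpoint of the branch separating the outgroup).
No confidence intervals on node times are provided; bootstrap support values
are pass-through metadata.

## Carriage extrapolation (`oxevo.redundancy`)

The cluster ratio |marker clusters| / |16S clusters| at a common threshold
estimates the fraction of community species carrying the marker, using 16S
clusters as the species denominator to normalize the two genes' different
divergence rates. Extrapolation to a broader function multiplies the ratio by
(genome-survey function fraction / genome-survey marker fraction), capped at
1; the reported range spans the genome-based and extrapolated estimates. The
estimate is a back-of-envelope scaling — a warning says so, and all inputs
are carried in the result object rather than only the output number. It
ignores 16S copy-number variation and abundance weighting by design.

## Validation study sizes

The acceptance studies (tests/test_acceptance.py, scripts/acceptance.py) use:
200 two-taxon alignments of 500 codons for Z-test calibration at ω = 1 and
100 each for power at ω = 3 and 0.2 (branch length 0.4 per lineage, a
moderately long divergence well below saturation); 50 random additive
matrices of 10–30 tips for NJ; 50 20-tip clock trees with one ×3-rate clade
for relative-time recovery; 20 replicates of 24-species/4-phylum gene
families per HGT rate for SSN purity (evaluated at the 70% cutoff, where
phylum families are separated); 200 null and 100 planted 30-feature tables
for FDR and sensitivity; and 500-species communities at carriage 0.05/0.2/0.4
for cluster-ratio recovery. These sizes give stable estimates at desk scale;
all are parameters, not constants, and scale up directly.

## Known limitations

- Alignment-based identity is O(nm) per pair and all-vs-all; tens of
  thousands of sequences would need a prescreen deliberately left out.
- SparCC permutation p-values are resolution-limited by the permutation
  count (see above).
- The codon simulator and the NG86 estimator share the standard genetic
  code table but nothing else; still, both are single-nucleotide-step
  models, so agreement does not validate either against indel-rich or
  frequency-biased evolution.
- Relative times have no calibration and no uncertainty; only their order
  and ratios are meaningful.
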