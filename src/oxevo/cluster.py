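"""Pairwise identity, greedy incremental clustering, and on/off-target calls.

Identity is defined on the optimal global (Needleman–Wunsch) alignment
under match=+1, mismatch=0, linear gap −1, as the number of matching
columns divided by the length of the shorter sequence — the convention of
greedy incremental clusterers such as CD-HIT. The same definition is the
single source of truth for the sequence-similarity-network module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

IDENTITY_DEFINITION = (
    "global alignment (match=+1, mismatch=0, gap=-1); "
    "identity = matches / length of shorter sequence"
)

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of matching positions over the shorter sequence length."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = seq_a.upper(), seq_b.upper()
    if a == b:
        return 1.0
    # canonical argument order: co-optimal alignments can differ in match
    # count, so symmetry is guaranteed by always aligning in a fixed order
    if (len(a), a) > (len(b), b):
        a, b = b, a
    alignment = _aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


@dataclass
class ClusterSet:
    """Partition of sequences into identity clusters.

    ``clusters`` maps each representative (founder) ID to its member IDs,
    representative included; ``identities`` records each member's identity
    to its representative.
    """

    clusters: dict[str, list[str]]
    threshold: float
    identity_definition: str = IDENTITY_DEFINITION
    identities: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_members(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    @property
    def reduction(self) -> float:
        """1 − |clusters| / |input|: how much clustering shrank the set."""
        return 1.0 - len(self.clusters) / self.n_members

    def member_to_representative(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters.items() for m in members}


def greedy_cluster(sequences: dict[str, str], threshold: float = 0.97) -> ClusterSet:
    """CD-HIT-style greedy incremental clustering.

    Sequences are processed longest-first (ties broken lexicographically by
    sequence then ID, for determinism). Each sequence joins the first
    existing cluster — in founding order — whose representative it matches
    at ``threshold`` identity or better; otherwise it founds a new cluster.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    if not sequences:
        raise ValueError("at least one sequence is required")

    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sequences[sid], sid))
    reps: list[str] = []
    clusters: dict[str, list[str]] = {}
    identities: dict[str, float] = {}
    for sid in order:
        seq = sequences[sid]
        for rep in reps:
            ident = pairwise_identity(seq, sequences[rep])
            if ident >= threshold:
                clusters[rep].append(sid)
                identities[sid] = ident
                break
        else:
            reps.append(sid)
            clusters[sid] = [sid]
            identities[sid] = 1.0
    return ClusterSet(clusters, threshold, identities=identities)


def classify_on_target(
    query_seqs: dict[str, str],
    reference_seqs: dict[str, str],
    min_identity: float,
) -> dict[str, bool]:
    """Flag queries on-target by best identity against any reference.

    The nearest-reference rule: a query is on-target iff its best identity
    to any reference sequence reaches ``min_identity``. Off-target queries
    (e.g. amplicons annotated to the wrong gene) are the ones to remove.
    """
    if not reference_seqs:
        raise ValueError("reference set must be non-empty")
    flags: dict[str, bool] = {}
    for qid, qseq in query_seqs.items():
        best = max(pairwise_identity(qseq, ref) for ref in reference_seqs.values())
        flags[qid] = best >= min_identity
    return flags
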