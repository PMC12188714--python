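"""Nei–Gojobori machinery: site counting, pathway averaging, Z-tests."""

import itertools
import math
import warnings

import numpy as np
import pytest

from oxevo import dnds, synth
from oxevo.dnds import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    dnds_pair,
    observed_differences,
    potential_sites,
    selection_profile,
)


def brute_force_differences(codon_a, codon_b):
    """Independent oracle: enumerate every mutational pathway explicitly.

    Walks all orderings of the differing positions, classifying each step
    by translating with the raw genetic-code dict, and averages over the
    stop-free pathways. Deliberately structured as an explicit path walk,
    not shared with the implementation.
    """
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    pathways = []
    for order in itertools.permutations(positions):
        steps = []
        cur = list(codon_a)
        blocked = False
        for pos in order:
            before = "".join(cur)
            cur[pos] = codon_b[pos]
            after = "".join(cur)
            if after in STOP_CODONS:
                blocked = True
                break
            steps.append(GENETIC_CODE[before] == GENETIC_CODE[after])
        if not blocked:
            pathways.append(steps)
    if not pathways:
        return None
    sd = sum(sum(p) for p in pathways) / len(pathways)
    nd = sum(len(p) - sum(p) for p in pathways) / len(pathways)
    return sd, nd


@pytest.mark.parametrize(
    "codon,expected_s",
    [("TTT", 1 / 3), ("GGG", 1.0), ("ATG", 0.0)],
)
def test_potential_sites_enumerated_examples(codon, expected_s):
    s, n = potential_sites(codon)
    assert s == pytest.approx(expected_s)
    assert s + n == pytest.approx(3.0)


def test_potential_sites_sum_to_three_for_all_sense_codons():
    for codon in SENSE_CODONS:
        s, n = potential_sites(codon)
        assert s + n == pytest.approx(3.0)
        assert 0.0 <= s <= 3.0


def test_potential_sites_rejects_stop_codons():
    with pytest.raises(ValueError):
        potential_sites("TAA")


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("TTT", "TTT", (0.0, 0.0)),
        ("TTT", "TTC", (1.0, 0.0)),  # Phe->Phe
        ("TTT", "GTT", (0.0, 1.0)),  # Phe->Val
    ],
)
def test_observed_differences_single_pathway(a, b, expected):
    assert observed_differences(a, b) == expected


def test_observed_differences_match_brute_force_on_sample():
    rng = np.random.default_rng(7)
    codons = list(SENSE_CODONS)
    for _ in range(400):
        a = codons[rng.integers(len(codons))]
        b = codons[rng.integers(len(codons))]
        got = observed_differences(a, b)
        want = brute_force_differences(a, b)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want)
            k = sum(x != y for x, y in zip(a, b))
            assert got[0] + got[1] == pytest.approx(k)


def test_dnds_pair_identical_sequences_neutral():
    seq = "TTTGGGATGCCAAAA"
    r = dnds_pair(seq, seq)
    assert r.dN == r.dS == 0.0
    assert r.call() == "neutral"
    assert r.S + r.N == pytest.approx(len(seq))


def test_dnds_pair_symmetric_under_swap():
    t = synth.two_taxon_tree(0.3)
    aln, _ = synth.simulate_codon_alignment(t, omega=1.0, n_codons=200, seed=11)
    a, b = aln.sequences
    r1 = dnds_pair(a, b, n_bootstrap=200, seed=5)
    r2 = dnds_pair(b, a, n_bootstrap=200, seed=5)
    for fieldname in ("S", "N", "Sd", "Nd", "dS", "dN", "Z", "p_positive", "p_negative"):
        assert getattr(r1, fieldname) == pytest.approx(getattr(r2, fieldname), nan_ok=True)


@pytest.mark.parametrize(
    "omega,expected_call",
    [(3.0, "positive"), (0.2, "negative")],
)
def test_dnds_pair_recovers_selection_regime(omega, expected_call):
    t = synth.two_taxon_tree(0.5)
    aln, _ = synth.simulate_codon_alignment(t, omega=omega, n_codons=1000, seed=23)
    r = dnds_pair(*aln.sequences, n_bootstrap=1000, seed=0)
    assert r.call(alpha=0.05) == expected_call


def test_dnds_pair_agrees_with_independent_ng86_implementation():
    """Cross-check dN/dS against Biopython's NG86 on a simulated pair.

    The two implementations differ in stop-codon bookkeeping (we exclude
    stop neighbours from site denominators), so agreement is to a few
    percent, not exact.
    """
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    t = synth.two_taxon_tree(0.2)
    aln, _ = synth.simulate_codon_alignment(t, omega=1.0, n_codons=300, seed=4)
    a, b = aln.sequences
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dn_ref, ds_ref = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
    r = dnds_pair(a, b, n_bootstrap=100)
    assert r.dN == pytest.approx(dn_ref, rel=0.08)
    assert r.dS == pytest.approx(ds_ref, rel=0.08)


def test_dnds_pair_pairwise_deletion_of_ambiguous_columns():
    a = "TTTGGGNNNCCAATTATTATT"
    b = "TTCGGGAAACCGATTATTATT"
    with pytest.warns(UserWarning, match="skipped"):
        r = dnds_pair(a, b)
    assert r.n_codons_used == 6
    assert r.S + r.N == pytest.approx(18.0)


def test_codon_alignment_rejects_internal_stops():
    with pytest.raises(ValueError, match="stop"):
        CodonAlignment(ids=("x",), sequences=("TTTTAAGGG",))


def test_selection_profile_identical_sequences_all_neutral():
    seq = "TTTGGGATGCCAAAAGACCTG"
    aln = CodonAlignment(
        ids=("a", "b", "c"),
        sequences=(seq, seq, seq),
        taxonomy={"a": ("G1", "P1"), "b": ("G1", "P1"), "c": ("G2", "P2")},
    )
    results, table = selection_profile(aln, n_bootstrap=50)
    assert len(results) == 3
    assert table["positive"].sum() == 0
    assert table["negative"].sum() == 0
    assert table["neutral"].sum() == 3


def test_selection_profile_single_sequence_empty_table():
    aln = CodonAlignment(ids=("a",), sequences=("TTTGGGATGCCA",), taxonomy={"a": ("G", "P")})
    results, table = selection_profile(aln, n_bootstrap=50)
    assert results == []
    assert table.empty


def test_selection_profile_unmapped_taxon_errors():
    aln = CodonAlignment(ids=("a", "b"), sequences=("TTTGGG", "TTTGGG"))
    with pytest.raises(ValueError, match="phylum"):
        selection_profile(aln, {"a": "P1"}, n_bootstrap=10)


def test_selection_profile_between_phylum_positive_enrichment():
    """Elevated ω on the branches separating two phyla shows up as
    positive calls concentrated in the between-phylum bin."""
    tree = synth.simulate_taxonomy(8, 2, seed=3)
    # put strong positive selection on the two deepest branches
    root_children = [c.name for c in [] ]
    t = tree.copy()
    from oxevo.synth import _name_internals

    _name_internals(t)
    branch_omega = {c.name: 4.0 for c in t.children}
    aln, truth = synth.simulate_codon_alignment(
        t, omega=1.0, n_codons=600, seed=9, branch_omega=branch_omega
    )
    phylum_map = {sid: ph for sid, (_g, ph) in aln.taxonomy.items()}
    results, table = selection_profile(aln, phylum_map, n_bootstrap=300, seed=2)
    between = table[table.phylum_a != table.phylum_b].iloc[0]
    within = table[table.phylum_a == table.phylum_b]
    between_rate = between["positive"] / (between[["negative", "neutral", "positive"]].sum())
    within_rate = within["positive"].sum() / max(
        1, within[["negative", "neutral", "positive"]].sum(axis=1).sum()
    )
    assert between_rate > within_rate
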