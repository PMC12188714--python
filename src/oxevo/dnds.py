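"""Pairwise Nei–Gojobori dN/dS estimation with a codon-based Z-test.

The unit of analysis is an in-frame pairwise codon alignment. Potential
synonymous (S) and nonsynonymous (N) sites are counted per codon by
enumerating all nine single-nucleotide neighbours, with changes to stop
codons excluded from the per-position denominator. Observed synonymous and
nonsynonymous differences between two codons are averaged over all
mutational pathways (orderings of the differing positions) that avoid stop
codons. Proportions are Jukes–Cantor corrected and the Z statistic for
selection uses variances estimated by bootstrap over codon columns.

An ω (dN/dS) above 1 indicates positive (diversifying) selection, below 1
purifying selection, and 1 neutrality.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(t) for t in itertools.product(BASES, repeat=3)))
)
SENSE_CODONS = tuple(c for c in SENSE_CODONS if c not in STOP_CODONS)

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def codon_neighbors(codon: str) -> list[tuple[int, str]]:
    """All single-nucleotide neighbours of a codon as (position, codon)."""
    out = []
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                out.append((pos, codon[:pos] + base + codon[pos + 1 :]))
    return out


@lru_cache(maxsize=None)
def potential_sites(codon: str) -> tuple[float, float]:
    """Potential synonymous and nonsynonymous sites of one sense codon.

    For each of the three positions, the synonymous-site contribution is
    the fraction of the single-nucleotide changes at that position that are
    synonymous, with changes creating a stop codon removed from the
    denominator. Returns (s, n) with s + n = 3.
    """
    if codon in STOP_CODONS or any(b not in BASES for b in codon) or len(codon) != 3:
        raise ValueError(f"potential_sites requires a sense codon, got {codon!r}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        legal = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            neigh = codon[:pos] + base + codon[pos + 1 :]
            if neigh in STOP_CODONS:
                continue
            legal += 1
            if GENETIC_CODE[neigh] == aa:
                syn += 1
        if legal:
            s += syn / legal
    return s, 3.0 - s


@lru_cache(maxsize=None)
def observed_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Synonymous/nonsynonymous differences between two sense codons.

    Averages over every ordering of the differing positions, discarding
    pathways that pass through a stop codon. Returns (sd, nd) with
    sd + nd = number of differing positions, or None when every pathway is
    blocked by stop codons (the codon pair is then skipped by callers).
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or len(c) != 3 or any(b not in BASES for b in c):
            raise ValueError(f"observed_differences requires sense codons, got {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_legal = 0
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = 0
        nonsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            n_legal += 1
            syn_total += syn
            nonsyn_total += nonsyn
    if n_legal == 0:
        return None
    return syn_total / n_legal, nonsyn_total / n_legal


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - (4/3) p); nan if saturated."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length, in-frame coding sequences with taxon labels.

    ``taxonomy`` maps sequence ID -> (genus, phylum).
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    taxonomy: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences length mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("alignment sequences must have equal length")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError("alignment length must be a multiple of 3")
        for sid, seq in zip(self.ids, self.sequences):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3].upper()
                if codon in STOP_CODONS:
                    raise ValueError(f"internal stop codon in {sid} at codon {i // 3}")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def sequence(self, sid: str) -> str:
        return self.sequences[self.ids.index(sid)]


@dataclass
class DnDsResult:
    """One pairwise Nei–Gojobori comparison."""

    id_a: str
    id_b: str
    S: float  # potential synonymous sites (averaged over the pair)
    N: float  # potential nonsynonymous sites
    Sd: float  # observed synonymous differences
    Nd: float  # observed nonsynonymous differences
    pS: float
    pN: float
    dS: float  # Jukes-Cantor corrected
    dN: float
    ratio: float  # dN/dS, nan when dS == 0
    Z: float
    p_positive: float
    p_negative: float
    n_codons_used: int
    saturated: bool = False
    q_positive: float = math.nan
    q_negative: float = math.nan
    variance_method: str = "codon_bootstrap"
    n_bootstrap: int = 1000

    def call(self, alpha: float = 0.05, use_fdr: bool = False) -> str:
        p_pos = self.q_positive if use_fdr else self.p_positive
        p_neg = self.q_negative if use_fdr else self.p_negative
        if p_pos < alpha:
            return "positive"
        if p_neg < alpha:
            return "negative"
        return "neutral"


# Fast path: integer-coded lookup tables over the 61 sense codons.
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


@lru_cache(maxsize=1)
def _site_table() -> np.ndarray:
    return np.array([potential_sites(c)[0] for c in SENSE_CODONS])


@lru_cache(maxsize=1)
def _diff_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(SENSE_CODONS)
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    legal = np.ones((n, n), dtype=bool)
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            res = observed_differences(a, b)
            if res is None:
                legal[i, j] = False
            else:
                sd[i, j], nd[i, j] = res
    return sd, nd, legal


def _encode_codons(seq: str) -> np.ndarray:
    """Codon indices; -1 marks columns to skip (non-ACGT or stop)."""
    seq = seq.upper()
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(len(out)):
        out[k] = _CODON_INDEX.get(seq[3 * k : 3 * k + 3], -1)
    return out


def _dn_ds_from_sums(sd, nd, s_sites, n_sites):
    """Vectorized JC-corrected dN and dS from bootstrap sums (nan-safe)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(s_sites > 0, sd / s_sites, 0.0)
        pn = np.where(n_sites > 0, nd / n_sites, 0.0)
        ds = np.where(ps < 0.75, -0.75 * np.log1p(-4.0 * ps / 3.0), np.nan)
        dn = np.where(pn < 0.75, -0.75 * np.log1p(-4.0 * pn / 3.0), np.nan)
    return dn, ds


def dnds_pair(
    seq_a: str,
    seq_b: str,
    id_a: str = "a",
    id_b: str = "b",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> DnDsResult:
    """Nei–Gojobori dN/dS with bootstrap Z-test for one aligned pair.

    Codon columns containing a non-ACGT character or a stop codon in either
    sequence are dropped (pairwise deletion). The Z statistic is
    (dN - dS) / sqrt(Var(dN) + Var(dS)) with variances from resampling
    codon columns with replacement; the bootstrap is symmetric in the two
    sequences, so results are identical under argument swap.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("alignment length must be a multiple of 3")

    codes_a = _encode_codons(seq_a)
    codes_b = _encode_codons(seq_b)
    sd_tab, nd_tab, legal_tab = _diff_tables()
    site_s = _site_table()

    usable = (codes_a >= 0) & (codes_b >= 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"{id_a} vs {id_b}: skipped {n_dropped} codon column(s) with gaps, "
            "ambiguity codes or stop codons",
            stacklevel=2,
        )
    a = codes_a[usable]
    b = codes_b[usable]
    legal = legal_tab[a, b]
    if not legal.all():
        warnings.warn(
            f"{id_a} vs {id_b}: skipped {int((~legal).sum())} codon column(s) "
            "with no stop-free mutational pathway",
            stacklevel=2,
        )
        a, b = a[legal], b[legal]
    m = len(a)
    if m == 0:
        raise ValueError("no usable codon columns in the pair")

    col_sd = sd_tab[a, b]
    col_nd = nd_tab[a, b]
    col_s = 0.5 * (site_s[a] + site_s[b])  # per-column potential syn sites
    col_n = 3.0 - col_s

    S, N = float(col_s.sum()), float(col_n.sum())
    Sd, Nd = float(col_sd.sum()), float(col_nd.sum())
    pS, pN = Sd / S, Nd / N
    dS, dN = jukes_cantor(pS), jukes_cantor(pN)
    saturated = math.isnan(dS) or math.isnan(dN)
    ratio = math.nan
    if not saturated and dS > 0:
        ratio = dN / dS

    if saturated:
        Z = math.nan
        p_pos = p_neg = math.nan
    elif Sd == 0 and Nd == 0:
        Z, p_pos, p_neg = 0.0, 0.5, 0.5
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, m, size=(n_bootstrap, m))
        bs_dn, bs_ds = _dn_ds_from_sums(
            col_sd[idx].sum(axis=1),
            col_nd[idx].sum(axis=1),
            col_s[idx].sum(axis=1),
            col_n[idx].sum(axis=1),
        )
        var = np.nanvar(bs_dn) + np.nanvar(bs_ds)
        if var <= 0:
            Z = 0.0
        else:
            Z = (dN - dS) / math.sqrt(var)
        p_pos = float(norm.sf(Z))
        p_neg = float(norm.cdf(Z))

    return DnDsResult(
        id_a=id_a,
        id_b=id_b,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        ratio=ratio,
        Z=Z,
        p_positive=p_pos,
        p_negative=p_neg,
        n_codons_used=m,
        saturated=saturated,
        n_bootstrap=n_bootstrap,
    )


def selection_profile(
    alignment: CodonAlignment,
    taxon_map: dict[str, str] | None = None,
    alpha: float = 0.05,
    n_bootstrap: int = 1000,
    seed: int = 0,
):
    """Phylum-pair table of selection calls over all sequence pairs.

    Runs every pairwise comparison, applies a Benjamini–Hochberg correction
    jointly across pairs (separately for the positive- and negative-
    selection p-value families), and bins calls by unordered phylum pair.
    Returns (results, table) where table has one row per phylum pair with
    counts of negative / neutral / positive calls.
    """
    import pandas as pd

    if taxon_map is None:
        taxon_map = {sid: phylum for sid, (_genus, phylum) in alignment.taxonomy.items()}
    for sid in alignment.ids:
        if sid not in taxon_map:
            raise ValueError(f"sequence {sid!r} has no phylum mapping")

    results: list[DnDsResult] = []
    for (ia, sa), (ib, sb) in itertools.combinations(zip(alignment.ids, alignment.sequences), 2):
        results.append(
            dnds_pair(sa, sb, id_a=ia, id_b=ib, n_bootstrap=n_bootstrap, seed=seed)
        )

    testable = [r for r in results if not math.isnan(r.p_positive)]
    if testable:
        q_pos = multipletests([r.p_positive for r in testable], method="fdr_bh")[1]
        q_neg = multipletests([r.p_negative for r in testable], method="fdr_bh")[1]
        for r, qp, qn in zip(testable, q_pos, q_neg):
            r.q_positive = float(qp)
            r.q_negative = float(qn)

    rows: dict[tuple[str, str], dict[str, int]] = {}
    for r in results:
        pair = tuple(sorted((taxon_map[r.id_a], taxon_map[r.id_b])))
        bucket = rows.setdefault(pair, {"negative": 0, "neutral": 0, "positive": 0})
        bucket[r.call(alpha=alpha, use_fdr=True) if not math.isnan(r.q_positive) else "neutral"] += 1

    table = pd.DataFrame(
        [
            {"phylum_a": a, "phylum_b": b, **counts}
            for (a, b), counts in sorted(rows.items())
        ]
    )
    return results, table


def results_table(results: list[DnDsResult]):
    """Per-pair results as a DataFrame (for TSV export)."""
    import pandas as pd

    return pd.DataFrame([vars(r) for r in results])
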