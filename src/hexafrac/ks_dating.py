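"""Codon-aware pairwise alignment, NG86 Ks/Ka estimation, and clock dating.

The synonymous distance Ks between two coding sequences is estimated with the
Nei–Gojobori (1986) counting method: synonymous/nonsynonymous site counts per
codon come from enumerating all nine single-nucleotide neighbours (mutations
to stop codons are dropped from the denominator), observed differences between
codon pairs are averaged over all shortest mutational pathways that avoid stop
codons, and proportions are corrected for multiple hits with the Jukes–Cantor
formula d = -(3/4)·ln(1 - (4/3)·p).  Under a molecular clock with synonymous
rate mu per site per year, two lineages that split T years ago accumulate
Ks = 2·mu·T, so T = Ks / (2·mu).

This is a small-Ks-regime approximation: no transition/transversion or codon
frequency weighting (NG86, not YN00), universal genetic code only.  Estimates
with a difference proportion >= 3/4 are flagged saturated and excluded from
summaries rather than extrapolated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

_BASES = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)          # TAA, TAG, TGA
_CODON_TABLE = dict(standard_dna_table.forward_table)        # sense codons only


def _translate_codon(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop codon."""
    return _CODON_TABLE.get(codon)


class SaturationError(ValueError):
    """All pairwise estimates in a summary are saturated."""


# ---------------------------------------------------------------------------
# NG86 site counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def count_sites_ng86(codon: str) -> tuple[float, float, float]:
    """Per-position synonymous site fractions of a sense codon.

    For each of the three positions, the fraction of single-nucleotide
    mutations that are synonymous; mutations creating a stop codon are
    excluded from the denominator.  The sum over positions is the codon's
    contribution to S; 3 minus that sum is its contribution to N.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not a DNA codon: {codon!r}")
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = _translate_codon(codon)
    fractions = []
    for pos in range(3):
        syn = 0
        total = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if mutant in _STOPS:
                continue
            total += 1
            if _translate_codon(mutant) == aa:
                syn += 1
        fractions.append(syn / total if total else 0.0)
    return tuple(fractions)


def _codon_s_count(codon: str) -> float:
    return sum(count_sites_ng86(codon))


@lru_cache(maxsize=None)
def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over stop-free shortest pathways.

    Pathways change the differing positions one at a time in every possible
    order; any ordering that passes through a stop codon is discarded.  If
    every ordering hits a stop the pair contributes its changes counted along
    the (unique) multiset of substitutions with stop-passing orders allowed —
    this cannot occur for sense start/end codons with <= 3 differences under
    the universal code, but the fallback keeps the function total.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        syn = nonsyn = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in _STOPS and not allow_stops:
                return None
            if nxt in _STOPS or current in _STOPS:
                # undefined step class when a stop is involved; count nonsyn
                nonsyn += 1
            elif _translate_codon(nxt) == _translate_codon(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return (syn, nonsyn)

    results = [r for order in itertools.permutations(diff_positions)
               if (r := walk(order, allow_stops=False)) is not None]
    if not results:
        results = [walk(order, allow_stops=True)
                   for order in itertools.permutations(diff_positions)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return (sd, nd)


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gap-free, stop-free paired codon columns from two CDSs."""

    codons_a: list[str]
    codons_b: list[str]
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("unequal codon column counts")
        if not self.codons_a:
            raise ValueError("empty codon alignment")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


def _prepare_cds(cds: str, name: str) -> str:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(cds)} not divisible by 3")
    if cds[-3:] in _STOPS:
        cds = cds[:-3]
    if not cds:
        raise ValueError(f"{name}: empty CDS after trimming terminal stop")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons):
        if c in _STOPS:
            raise ValueError(f"{name}: internal stop codon {c} at codon {i}")
    return cds


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


def codon_align(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Align two CDSs via global protein alignment, back-translated to codons.

    The protein alignment (Needleman–Wunsch, BLOSUM62, gap open -10 /
    extend -1) is mapped back onto codons; columns containing a gap or an
    untranslatable codon are dropped.  Internal stop codons are an input
    error.
    """
    cds_a = _prepare_cds(cds_a, id_a)
    cds_b = _prepare_cds(cds_b, id_b)
    prot_a = str(Seq(cds_a).translate())
    prot_b = str(Seq(cds_b).translate())
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    cols_a: list[str] = []
    cols_b: list[str] = []
    # aligned gives matched (gap-free) blocks in both sequences
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            ca = cds_a[3 * (a_start + off): 3 * (a_start + off) + 3]
            cb = cds_b[3 * (b_start + off): 3 * (b_start + off) + 3]
            if "N" in ca or "N" in cb or ca in _STOPS or cb in _STOPS:
                continue
            cols_a.append(ca)
            cols_b.append(cb)
    if not cols_a:
        raise ValueError(f"no alignable codon columns between {id_a} and {id_b}")
    return CodonAlignment(cols_a, cols_b, id_a, id_b)


# ---------------------------------------------------------------------------
# Ks/Ka estimation
# ---------------------------------------------------------------------------

@dataclass
class KsKaEstimate:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float            # NaN when saturated
    ka: float            # NaN when saturated
    saturated: bool
    n_codons: int
    pair: tuple[str, str] = ("a", "b")


def jukes_cantor(p: float) -> float:
    """JC69 distance for a difference proportion p < 3/4."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def estimate_ks_ka(aln: CodonAlignment) -> KsKaEstimate:
    """NG86 Ks/Ka with Jukes–Cantor correction for one codon alignment."""
    s_a = sum(_codon_s_count(c) for c in aln.codons_a)
    s_b = sum(_codon_s_count(c) for c in aln.codons_b)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * aln.n_codons - S
    Sd = Nd = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        sd, nd = _pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    saturated = pS >= 0.75 or pN >= 0.75
    ks = jukes_cantor(pS) if not saturated else math.nan
    ka = jukes_cantor(pN) if not saturated else math.nan
    return KsKaEstimate(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                        ks=ks, ka=ka, saturated=saturated,
                        n_codons=aln.n_codons, pair=(aln.id_a, aln.id_b))


# ---------------------------------------------------------------------------
# Divergence dating
# ---------------------------------------------------------------------------

DEFAULT_MU = 1.5e-8     # synonymous substitutions per site per year


def divergence_time(ks: float, mu: float = DEFAULT_MU) -> float:
    """Clock dating: T (Mya) = Ks / (2·mu) / 1e6."""
    if ks < 0:
        raise ValueError(f"negative ks {ks}")
    if mu <= 0:
        raise ValueError(f"non-positive mu {mu}")
    return ks / (2.0 * mu) / 1e6


@dataclass
class DivergenceEstimate:
    """Mean Ks and mean divergence time over an ortholog set for a region pair."""

    pair: tuple[str, str]
    n_genes: int
    mean_ks: float
    sd_ks: float
    mean_mya: float
    sd_mya: float


def summarize_pairwise(ks_values: list[float], pair: tuple[str, str] = ("a", "b"),
                       mu: float = DEFAULT_MU) -> DivergenceEstimate:
    """Summarise per-gene Ks values as mean +/- sd Ks and Mya.

    Per-gene times are computed first and then averaged (rather than
    converting the mean Ks), so the reported sd describes the spread of
    gene-level dates.  Population (ddof=0) standard deviations.  Saturated
    (NaN) values must be excluded by the caller; an empty or all-NaN list
    raises :class:`SaturationError`.
    """
    vals = np.asarray([k for k in ks_values if not math.isnan(k)], dtype=float)
    if vals.size == 0:
        raise SaturationError(f"no unsaturated Ks estimates for pair {pair}")
    times = np.array([divergence_time(k, mu) for k in vals])
    return DivergenceEstimate(
        pair=pair,
        n_genes=int(vals.size),
        mean_ks=float(vals.mean()),
        sd_ks=float(vals.std(ddof=0)),
        mean_mya=float(times.mean()),
        sd_mya=float(times.std(ddof=0)),
    )
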