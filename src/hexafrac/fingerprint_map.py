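"""Sulston-score clone overlap testing and stepwise fingerprint contig assembly.

Each BAC clone is reduced to its restriction fingerprint — the sorted list of
fragment sizes.  Two clones that truly overlap share bands; the Sulston score
is the probability of observing at least the matched number of bands by
chance, so low scores indicate real overlap.  Contigs are assembled by
single-linkage clustering under a cutoff that is relaxed stepwise from a
stringent starting value, with questionable (Q) clones flagged and
Q-heavy contigs re-split at higher stringency (a DQer-style pass).

The score follows the classic FPC binomial formulation: with band counts
nL <= nH, matched bands m, and per-band chance-match probability
p = 1 - (1 - 2·tol/gel_length)^nH,

    score = sum_{j=m..nL} C(nL, j) p^j (1-p)^(nL-j)

i.e. the upper tail of Binomial(nL, p) at m.  The contig-building step is a
deliberately simple, fully specified stand-in for FPC's consensus-band
algorithm: single linkage plus a median-score Q criterion, not a re-creation
of FPC internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import binom


@dataclass
class Fingerprint:
    """Sorted band-size list of one clone."""

    clone_id: str
    bands: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.bands):
            raise ValueError(f"{self.clone_id}: non-positive band size")
        self.bands = tuple(sorted(self.bands))

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass
class AssemblyParams:
    tolerance: float = 3.0
    gel_length: float = 1180.0
    cutoff_start: float = 1e-35
    cutoff_end: float = 1e-15
    cutoff_step_factor: float = 1e5
    dq_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.cutoff_start <= self.cutoff_end < 1):
            raise ValueError("need 0 < cutoff_start <= cutoff_end < 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if not (0 < self.dq_fraction < 1):
            raise ValueError("dq_fraction must be in (0, 1)")
        if self.cutoff_step_factor <= 1:
            raise ValueError("cutoff_step_factor must be > 1")

    def schedule(self) -> list[float]:
        """Stepwise cutoffs from start to end (inclusive, clamped)."""
        cutoffs = []
        c = self.cutoff_start
        while c < self.cutoff_end:
            cutoffs.append(c)
            c *= self.cutoff_step_factor
        cutoffs.append(self.cutoff_end)
        return cutoffs


@dataclass
class ContigSet:
    contigs: dict[int, list[str]]            # id -> member clone ids (>= 2)
    singletons: list[str]
    q_clones: set[str] = field(default_factory=set)
    q_fraction: dict[int, float] = field(default_factory=dict)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)


def match_bands(fp_a: Fingerprint, fp_b: Fingerprint, tolerance: float) -> int:
    """Greedy one-to-one band pairing in ascending size order.

    Walking both sorted lists, bands match iff their sizes differ by at most
    ``tolerance``; each band is used at most once, and on a miss the pointer
    of the smaller band advances.
    """
    a, b = fp_a.bands, fp_b.bands
    i = j = m = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tolerance:
            m += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return m


def sulston_score(fp_a: Fingerprint, fp_b: Fingerprint,
                  tolerance: float = 3.0, gel_length: float = 1180.0) -> float:
    """Chance probability of sharing at least the matched number of bands."""
    if fp_a.n_bands < 1 or fp_b.n_bands < 1:
        raise ValueError("fingerprints must have at least one band")
    if tolerance >= gel_length / 2:
        raise ValueError("tolerance must be < gel_length / 2")
    n_low, n_high = sorted((fp_a.n_bands, fp_b.n_bands))
    m = match_bands(fp_a, fp_b, tolerance)
    p = 1.0 - (1.0 - 2.0 * tolerance / gel_length) ** n_high
    # upper tail P(X >= m) of Binomial(n_low, p)
    return float(binom.sf(m - 1, n_low, p))


def _score_matrix(fps: list[Fingerprint], params: AssemblyParams) -> np.ndarray:
    n = len(fps)
    scores = np.ones((n, n))
    for i, j in combinations(range(n), 2):
        s = sulston_score(fps[i], fps[j], params.tolerance, params.gel_length)
        scores[i, j] = scores[j, i] = s
    return scores


def _single_linkage(members: list[int], scores: np.ndarray,
                    cutoff: float) -> list[list[int]]:
    """Connected components among ``members`` over edges score <= cutoff."""
    idx = {m: k for k, m in enumerate(members)}
    parent = list(range(len(members)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(members, 2):
        if scores[a, b] <= cutoff:
            ra, rb = find(idx[a]), find(idx[b])
            if ra != rb:
                parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for m in members:
        comps.setdefault(find(idx[m]), []).append(m)
    return list(comps.values())


def _q_flags(component: list[int], scores: np.ndarray, cutoff: float) -> set[int]:
    """Clones whose median score to contig-mates exceeds cutoff * 1e3."""
    if len(component) < 2:
        return set()
    flagged = set()
    for m in component:
        mates = [scores[m, o] for o in component if o != m]
        if float(np.median(mates)) > cutoff * 1e3:
            flagged.add(m)
    return flagged


def assemble_stepwise(fingerprints: list[Fingerprint],
                      params: AssemblyParams = AssemblyParams()) -> ContigSet:
    """Stepwise-stringency single-linkage assembly with DQer-style breaking.

    At each cutoff of the schedule, clones are clustered by single linkage on
    pairwise Sulston scores; clones whose median score to their contig-mates
    exceeds cutoff*1e3 are flagged Q, and any contig with more than
    ``dq_fraction`` Q clones is re-split at a 100x stricter cutoff.  A final
    pass merges contigs whose best inter-contig pair meets the end cutoff,
    then unplaced clones are reported as singletons.
    """
    if not fingerprints:
        raise ValueError("no fingerprints to assemble")
    usable = [fp for fp in fingerprints if fp.n_bands >= 1]
    empty_ids = [fp.clone_id for fp in fingerprints if fp.n_bands < 1]
    scores = _score_matrix(usable, params)
    n = len(usable)
    all_idx = list(range(n))

    _DQ_FLOOR = 1e-60        # termination guard for the recursive re-split

    def dq_resolve(comp: list[int], cutoff: float) -> list[list[int]]:
        """Accept a contig, or re-split Q-heavy contigs at 100x stricter
        cutoffs until the Q fraction drops below ``dq_fraction``."""
        flags = _q_flags(comp, scores, cutoff)
        if (len(comp) < 2 or len(flags) / len(comp) <= params.dq_fraction
                or cutoff <= _DQ_FLOOR):
            q_flagged.update(flags)
            return [comp]
        out: list[list[int]] = []
        for sub in _single_linkage(comp, scores, cutoff * 1e-2):
            out.extend(dq_resolve(sub, cutoff * 1e-2))
        return out

    components: list[list[int]] = [all_idx]
    q_flagged: set[int] = set()
    for cutoff in params.schedule():
        components = []
        for comp in _single_linkage(all_idx, scores, cutoff):
            components.extend(dq_resolve(comp, cutoff))

    # final merge pass at the end cutoff between surviving contigs; merges
    # that would recreate a Q-heavy (DQer-broken) contig are skipped
    merged = True
    while merged:
        merged = False
        for i, j in combinations(range(len(components)), 2):
            best = min(scores[a, b] for a in components[i] for b in components[j])
            if best <= params.cutoff_end:
                joint = components[i] + components[j]
                flags = _q_flags(joint, scores, params.cutoff_end)
                if len(flags) / len(joint) > params.dq_fraction:
                    continue
                components[i] = joint
                del components[j]
                merged = True
                break

    contigs: dict[int, list[str]] = {}
    singletons: list[str] = list(empty_ids)
    q_fraction: dict[int, float] = {}
    cid = 0
    for comp in sorted(components, key=lambda c: -len(c)):
        if len(comp) >= 2:
            contigs[cid] = sorted(usable[m].clone_id for m in comp)
            nq = sum(1 for m in comp if m in q_flagged)
            q_fraction[cid] = nq / len(comp)
            cid += 1
        else:
            singletons.append(usable[comp[0]].clone_id)
    return ContigSet(contigs=contigs, singletons=sorted(singletons),
                     q_clones={usable[m].clone_id for m in q_flagged},
                     q_fraction=q_fraction)


def evaluate_assembly(contigs: ContigSet,
                      clone_truth: dict[str, tuple[int, int]],
                      min_overlap_bp: int = 30000) -> tuple[float, float, bool]:
    """Precision/recall of co-contig clone pairs against true overlaps.

    A clone pair is a true positive iff it is co-assembled and its true
    genomic intervals overlap by at least ``min_overlap_bp``.  With no
    co-assembled pairs, precision is reported as 1.0 with a degenerate flag.
    Returns (precision, recall, degenerate_precision).
    """
    def overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    co_pairs: set[frozenset[str]] = set()
    for members in contigs.contigs.values():
        for a, b in combinations(members, 2):
            co_pairs.add(frozenset((a, b)))
    true_pairs = {frozenset((a, b))
                  for a, b in combinations(sorted(clone_truth), 2)
                  if overlap(clone_truth[a], clone_truth[b]) >= min_overlap_bp}
    tp = sum(1 for pair in co_pairs if pair in true_pairs)
    degenerate = len(co_pairs) == 0
    precision = 1.0 if degenerate else tp / len(co_pairs)
    recall = 1.0 if not true_pairs else tp / len(true_pairs)
    return precision, recall, degenerate
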