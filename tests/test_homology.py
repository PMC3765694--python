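"""Aligner bounds, chaining optimality, MEM completeness, matrix recovery."""

import random
from itertools import combinations

import numpy as np
import pytest

import hexafrac as hf
from hexafrac.homology import AlignmentHit, _best_monotone_chain

COPIES = ("LF", "MF1", "MF2")
GENOMES = ("A", "B", "C")


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestAlignLocal:
    def test_self_alignment_perfect_identity(self):
        rng = random.Random(1)
        seq = random_dna(rng, 50)
        hit = hf.align_local(seq, seq, mode="exact_sw")
        assert hit.identity == 100.0
        assert hit.score == 50
        assert hit.strand == "+"

    def test_reverse_complement_found_on_minus_strand(self):
        rng = random.Random(2)
        seq = random_dna(rng, 50)
        hit = hf.align_local(seq, hf.revcomp(seq), mode="exact_sw")
        assert hit.identity == 100.0 and hit.strand == "-"

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            hf.align_local("ACGU", "ACGT")

    def test_seeded_score_bounded_by_exact_dp(self):
        rng = random.Random(3)
        for _ in range(30):
            # plant a shared block so seeded mode has a seed to find
            core = random_dna(rng, rng.randint(12, 20))
            query = random_dna(rng, 10) + core + random_dna(rng, 10)
            target = random_dna(rng, 40) + core + random_dna(rng, 40)
            exact = hf.align_local(query, target, mode="exact_sw")
            seeded = hf.align_local(query, target, mode="seeded")
            assert seeded is not None
            assert seeded.score <= exact.score + 1e-9
            if len(core) >= 11:
                # an >= 11-nt exact seed inside the optimal alignment makes
                # the windowed DP recover the optimum
                assert seeded.score == pytest.approx(exact.score)


def make_hits(rng, n, copy=("B", "LF")):
    hits = []
    for i in range(n):
        hits.append(AlignmentHit(
            ref_gene_id=f"g{i}", ref_exon_index=0, copy_key=copy,
            target_start=rng.randint(0, 10_000), target_end=rng.randint(10_001, 11_000),
            strand="+", identity=90.0, score=rng.randint(1, 50),
            coverage=1.0, ref_order=(i, 0)))
    return hits


def brute_force_best_chain(hits):
    """Max weight over all strictly-monotone subsequences, both directions."""
    best = 0.0
    idx = sorted(range(len(hits)), key=lambda i: hits[i].ref_order)
    for r in range(1, len(hits) + 1):
        for sub in combinations(idx, r):
            starts = [hits[i].target_start for i in sub]
            inc = all(a < b for a, b in zip(starts, starts[1:]))
            dec = all(a > b for a, b in zip(starts, starts[1:]))
            if inc or dec or r == 1:
                best = max(best, sum(hits[i].score for i in sub))
    return best


class TestChaining:
    def test_three_collinear_hits_one_forward_chain(self):
        rng = random.Random(4)
        hits = make_hits(rng, 3)
        for i, h in enumerate(hits):
            h.target_start = 100 * i
            h.target_end = 100 * i + 50
        chains = hf.chain_collinear(hits)
        assert len(chains) == 1
        assert chains[0].orientation == "forward"
        assert len(chains[0].hits) == 3

    def test_reversed_target_order_yields_inverted_chain(self):
        rng = random.Random(5)
        hits = make_hits(rng, 4)
        for i, h in enumerate(hits):
            h.target_start = 1000 - 100 * i
            h.target_end = 1000 - 100 * i + 50
            h.strand = "-"
        chains = hf.chain_collinear(hits)
        assert len(chains) == 1 and chains[0].orientation == "inverted"

    @pytest.mark.parametrize("seed", range(6))
    def test_chain_weight_matches_exhaustive_search(self, seed):
        rng = random.Random(seed)
        hits = make_hits(rng, 10)
        for h in hits:
            h.target_start = rng.randint(0, 5000)
        w_f, _ = _best_monotone_chain(hits, +1)
        w_r, _ = _best_monotone_chain(hits, -1)
        assert max(w_f, w_r) == pytest.approx(brute_force_best_chain(hits))

    def test_every_hit_assigned_to_at_most_one_chain(self):
        rng = random.Random(11)
        hits = make_hits(rng, 12)
        chains = hf.chain_collinear(hits)
        seen = [id(h) for c in chains for h in c.hits]
        assert len(seen) == len(set(seen)) == len(hits)


class TestInversions:
    def test_no_inverted_chains_no_calls(self):
        rng = random.Random(6)
        hits = make_hits(rng, 3)
        for i, h in enumerate(hits):
            h.target_start = 100 * i
        chains = hf.chain_collinear(hits)
        assert hf.detect_inversions(chains) == []

    def test_two_separated_inversions_give_two_calls(self):
        # forward run, inverted run, forward run, inverted run
        rng = random.Random(7)
        hits = make_hits(rng, 12)
        layout = [0, 1, 2, 5, 4, 3, 6, 7, 8, 11, 10, 9]
        for i, h in enumerate(hits):
            h.target_start = 500 * layout[i]
            h.target_end = 500 * layout[i] + 100
            if i in (3, 4, 5, 9, 10, 11):
                h.strand = "-"
        chains = hf.chain_collinear(hits)
        calls = hf.detect_inversions(chains, min_genes=2)
        assert len(calls) == 2
        assert set(calls[0].gene_ids) == {"g3", "g4", "g5"}
        assert set(calls[1].gene_ids) == {"g9", "g10", "g11"}

    def test_simulated_five_gene_inversion_recovered_exactly(self):
        anc = hf.simulate_ancestral_region(20, mean_exons_per_gene=2, seed=41)
        params = hf.EvolutionParams(seed=42, exon_del_prob_per_branch=0.0,
                                    n_inversions={"term_B": 1},
                                    inversion_span_genes=(5, 5))
        copies, truth = hf.evolve_polyploid_genomes(anc, params)
        inv_events = [e for e in truth.rearrangements if e.type == "inversion"]
        assert len(inv_events) == 3          # one per sub-genome copy of B
        for event in inv_events:
            copy = copies[("B", event.copy_label)]
            hits = hf.find_orthologs(anc, copy)
            calls = hf.detect_inversions(hf.chain_collinear(hits), min_genes=2)
            assert len(calls) == 1
            assert set(calls[0].gene_ids) == set(event.get("gene_ids"))


def naive_mems(a, b, min_len):
    out = set()
    for i in range(len(a)):
        for j in range(len(b)):
            if a[i] != b[j]:
                continue
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue
            L = 0
            while i + L < len(a) and j + L < len(b) and a[i + L] == b[j + L]:
                L += 1
            if L >= min_len:
                out.add((i, j, L))
    return out


class TestMems:
    def test_self_match_includes_full_length(self):
        rng = random.Random(8)
        seq = random_dna(rng, 300)
        mems = hf.find_mems(seq, seq, min_len=20)
        assert any(m.a_start == 0 and m.length == len(seq) and m.strand == "+"
                   for m in mems)

    def test_reverse_complement_full_length_minus_strand(self):
        rng = random.Random(9)
        seq = random_dna(rng, 300)
        mems = hf.find_mems(seq, hf.revcomp(seq), min_len=20)
        assert any(m.length == len(seq) and m.strand == "-" for m in mems)

    def test_matches_naive_scan_with_planted_block(self):
        rng = random.Random(10)
        block = random_dna(rng, 50)
        a = random_dna(rng, 1000) + block + random_dna(rng, 950)
        b = random_dna(rng, 400) + block + random_dna(rng, 1600)
        mems = hf.find_mems(a, b, min_len=20)
        plus = {(m.a_start, m.b_start, m.length) for m in mems if m.strand == "+"}
        assert plus == naive_mems(a, b, 20)
        assert (1000, 400, 50) in plus

    def test_minus_strand_matches_naive_on_revcomp(self):
        rng = random.Random(12)
        block = random_dna(rng, 30)
        a = random_dna(rng, 300) + block + random_dna(rng, 300)
        b = random_dna(rng, 200) + hf.revcomp(block) + random_dna(rng, 200)
        mems = hf.find_mems(a, b, min_len=20)
        minus = {(m.a_start, m.b_start, m.length) for m in mems if m.strand == "-"}
        expected = {(i, len(b) - (j + L), L)
                    for i, j, L in naive_mems(a, hf.revcomp(b), 20)}
        assert minus == expected
        assert (300, 200, 30) in minus


class TestOrthologsAndMatrix:
    def test_lossless_evolution_every_exon_found_once(self, ancestor_small,
                                                      evolved_lossless,
                                                      presence_lossless):
        copies, _ = evolved_lossless
        n_exons = sum(len(g.exons) for g in ancestor_small.genes)
        assert bool(presence_lossless.retained.values.all())
        hits = hf.find_orthologs(ancestor_small, copies[("B", "LF")])
        assert len(hits) == n_exons      # exactly one locus per exon

    def test_detected_absences_equal_truth_deletions(self, ancestor_small,
                                                     evolved_default,
                                                     presence_default):
        copies, truth = evolved_default
        m = presence_default
        for genome in GENOMES:
            for copy_label in COPIES:
                col = (genome, copy_label)
                for gid in truth.ancestral_exon_counts:
                    surviving = set(truth.surviving_exons(gid, genome,
                                                          copy_label, copies))
                    sub = m.retained.loc[gid, col]
                    detected = {e for e in sub.index if sub.loc[e]}
                    assert detected == surviving, (genome, copy_label, gid)

    def test_tandem_duplication_reports_two_loci(self, ancestor_small):
        params = hf.EvolutionParams(seed=43, exon_del_prob_per_branch=0.0,
                                    n_tandem_dups={"term_B": 1})
        copies, truth = hf.evolve_polyploid_genomes(ancestor_small, params)
        event = next(e for e in truth.rearrangements
                     if e.type == "tandem_dup" and e.copy_label == "LF")
        copy = copies[("B", "LF")]
        hits = hf.find_orthologs(ancestor_small, copy)
        dup_gene = event.get("ancestral_id")
        per_exon = {}
        for h in hits:
            if h.ref_gene_id == dup_gene:
                per_exon.setdefault(h.ref_exon_index, []).append(h)
        assert max(len(v) for v in per_exon.values()) == 2

    def test_impossible_threshold_empties_matrix(self, ancestor_small,
                                                 evolved_lossless):
        copies, _ = evolved_lossless
        m = hf.build_presence_matrix(ancestor_small, [copies[("B", "LF")]],
                                     min_id=101.0)
        assert not m.retained.values.any()

    def test_matrix_monotone_in_thresholds(self, ancestor_small,
                                           evolved_default, presence_default):
        copies, _ = evolved_default
        stricter = hf.build_presence_matrix(
            ancestor_small, [copies[(g, c)] for g in GENOMES for c in COPIES],
            min_id=90.0, min_cov=0.8)
        loose = presence_default.retained
        # raising thresholds never adds a retained cell
        assert not (stricter.retained & ~loose).values.any()
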