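"""Simulator contracts: construction invariants, clock consistency, loss
bookkeeping, digest conservation, library and probe-screen behaviour."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

import hexafrac as hf

COPIES = ("LF", "MF1", "MF2")


class TestAncestralRegion:
    def test_seventeen_genes_in_coordinate_order(self):
        region = hf.simulate_ancestral_region(17, seed=1)
        assert [g.gene_id for g in region.genes] == [f"g{i}" for i in range(1, 18)]
        starts = [g.exons[0][0] for g in region.genes]
        assert starts == sorted(starts)

    def test_single_exon_gene_translates_cleanly(self):
        region = hf.simulate_ancestral_region(1, mean_exons_per_gene=1,
                                              mean_exon_len=300, seed=2)
        gene = region.genes[0]
        protein = Seq(region.cds(gene.gene_id)).translate()
        assert protein.startswith("M") and protein.endswith("*")
        assert "*" not in protein[:-1]

    def test_every_cds_is_stop_free_and_frame_preserving(self):
        region = hf.simulate_ancestral_region(12, seed=3)
        for gene in region.genes:
            cds = region.cds(gene.gene_id)
            assert len(cds) % 3 == 0
            assert all((e - s) % 3 == 0 for s, e in gene.exons)
            assert "*" not in Seq(cds).translate()[:-1]

    def test_fixed_seed_is_byte_identical(self):
        a = hf.simulate_ancestral_region(5, seed=9)
        b = hf.simulate_ancestral_region(5, seed=9)
        assert a.sequence == b.sequence
        assert [(g.gene_id, g.exons) for g in a.genes] == \
               [(g.gene_id, g.exons) for g in b.genes]

    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 0}, {"n_genes": 3, "mean_exon_len": 0},
        {"n_genes": 3, "mean_intergenic_len": -5},
    ])
    def test_non_positive_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            hf.simulate_ancestral_region(**kwargs)


class TestEvolutionParams:
    def test_age_ordering_enforced(self):
        with pytest.raises(ValueError, match="t_wgt"):
            hf.EvolutionParams(t_wgt_mya=3.0, t_b_split_mya=6.0)

    def test_bias_must_be_non_decreasing(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            hf.EvolutionParams(subgenome_bias=(1.3, 1.0, 0.5))


class TestEvolve:
    def test_zero_ages_and_events_reproduce_ancestor(self, ancestor_small):
        params = hf.EvolutionParams(t_wgt_mya=0, t_b_split_mya=0,
                                    t_ac_split_mya=0,
                                    exon_del_prob_per_branch=0.0, seed=5)
        copies, truth = hf.evolve_polyploid_genomes(ancestor_small, params)
        for key, gc in copies.items():
            assert gc.sequence == ancestor_small.sequence, key
        assert truth.loss_events == [] and truth.rearrangements == []

    def test_forced_stem_losses_all_tagged_stem_abc(self, ancestor_small):
        params = hf.EvolutionParams(
            exon_del_prob_per_branch={"stem_ABC": 0.08}, seed=6)
        _, truth = hf.evolve_polyploid_genomes(ancestor_small, params)
        assert truth.loss_events
        assert {e.branch for e in truth.loss_events} == {"stem_ABC"}

    def test_loss_bookkeeping_is_additive(self, evolved_default, ancestor_small):
        # surviving exons + losses on the root-to-tip path = ancestral count
        copies, truth = evolved_default
        paths = {"A": ("stem_ABC", "stem_AC", "term_A"),
                 "B": ("stem_ABC", "term_B"),
                 "C": ("stem_ABC", "stem_AC", "term_C")}
        for genome, path in paths.items():
            for copy_label in COPIES:
                for gid, n_anc in truth.ancestral_exon_counts.items():
                    surviving = truth.surviving_exons(gid, genome, copy_label,
                                                      copies)
                    lost = [e for e in truth.loss_events
                            if e.branch in path and e.copy_label == copy_label
                            and e.gene_id == gid]
                    assert len(surviving) + len(lost) == n_anc, \
                        (genome, copy_label, gid)

    def test_expected_ks_follow_the_clock_exactly(self, evolved_default):
        _, truth = evolved_default
        mu = 1.5e-8
        assert truth.expected_ks["A|C"] == pytest.approx(2 * mu * 3.2e6)
        assert truth.expected_ks["A|B"] == pytest.approx(2 * mu * 6.2e6)
        assert truth.expected_ks["WGT"] == pytest.approx(2 * mu * 11.6e6)

    def test_ref_copy_is_unevolved(self, evolved_default, ancestor_small):
        copies, _ = evolved_default
        assert copies[("REF", "REF")].sequence == ancestor_small.sequence

    def test_same_seed_identical_outputs(self, ancestor_small):
        params = hf.EvolutionParams(seed=13)
        c1, t1 = hf.evolve_polyploid_genomes(ancestor_small, params)
        c2, t2 = hf.evolve_polyploid_genomes(ancestor_small, params)
        assert all(c1[k].sequence == c2[k].sequence for k in c1)
        assert t1.loss_events == t2.loss_events
        assert t1.rearrangements == t2.rearrangements

    def test_saturation_warning_on_deep_trees(self, ancestor_small):
        params = hf.EvolutionParams(t_wgt_mya=40, t_b_split_mya=6.2,
                                    t_ac_split_mya=3.2, seed=7)
        _, truth = hf.evolve_polyploid_genomes(ancestor_small, params)
        assert truth.warnings and "saturation" in truth.warnings[0]

    def test_recovered_ks_matches_clock_at_the_ac_split(self):
        # (((A,C),B),REF) with the default node ages: mean NG86 Ks between A
        # and C should recover 2*mu*t = 0.096 closely at 60 genes
        anc = hf.simulate_ancestral_region(60, seed=31)
        params = hf.EvolutionParams(seed=32, exon_del_prob_per_branch=0.0)
        copies, truth = hf.evolve_polyploid_genomes(anc, params)
        ks_vals = []
        for gid in truth.ancestral_exon_counts:
            est = hf.estimate_ks_ka(hf.codon_align(
                copies[("A", "LF")].cds(gid), copies[("C", "LF")].cds(gid)))
            assert not est.saturated
            ks_vals.append(est.ks)
        mean_ks = float(np.mean(ks_vals))
        assert mean_ks == pytest.approx(0.096, rel=0.15)


class TestDigest:
    def test_no_site_returns_full_length(self):
        assert hf.digest_hindiii("ACGT" * 10) == [40]

    def test_hand_traced_cut_position(self):
        # site at index 3, cleavage between A and AGCTT -> fragments 4 and 8
        assert hf.digest_hindiii("TTTAAGCTTGGG") == [4, 8]

    def test_two_sites_three_fragments(self):
        seq = "CCCC" + "AAGCTT" + "GGGG" + "AAGCTT" + "TTTT"
        frags = hf.digest_hindiii(seq)
        assert len(frags) == 3 and sum(frags) == len(seq)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    @settings(derandomize=True, max_examples=60)
    def test_fragment_lengths_always_sum_to_input(self, seq):
        assert sum(hf.digest_hindiii(seq)) == len(seq)

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            hf.digest_hindiii("ACGTX")


class TestBacLibrary:
    def test_all_empty_when_probability_one(self):
        params = hf.BacLibraryParams(n_clones=20, insert_mean_bp=1000,
                                     insert_sd_bp=100, empty_clone_prob=1.0,
                                     seed=1)
        clones, fps = hf.simulate_bac_library("ACGT" * 1000, params)
        assert all(c.empty for c in clones)
        assert all(fp.n_bands == 0 for fp in fps)

    def test_coverage_definition(self):
        # n x insert = 10 x genome -> coverage 10.0
        assert hf.library_coverage(100, 1000, 10_000) == 10.0

    def test_fixed_seed_identical_intervals(self):
        seq = "ACGT" * 5000
        params = hf.BacLibraryParams(n_clones=15, insert_mean_bp=2000,
                                     insert_sd_bp=200, empty_clone_prob=0.1,
                                     seed=4)
        c1, _ = hf.simulate_bac_library(seq, params)
        c2, _ = hf.simulate_bac_library(seq, params)
        assert [(c.start, c.end, c.empty) for c in c1] == \
               [(c.start, c.end, c.empty) for c in c2]

    def test_genome_shorter_than_insert_rejected(self):
        with pytest.raises(ValueError):
            hf.simulate_bac_library("ACGT" * 10,
                                    hf.BacLibraryParams(insert_mean_bp=1000))


class TestProbeScreen:
    def _clone(self, cid, start, end):
        return hf.BacClone(cid, start, end, empty=False)

    def test_probe_with_no_retained_homolog_yields_zero(self):
        clones = [self._clone("c1", 0, 1000)]
        res = hf.simulate_probe_screen(clones, {"p1": []}, 100)
        assert res[0].n_positive == 0 and res[0].n_true_loci == 0

    def test_overlap_below_threshold_is_negative(self):
        clones = [self._clone("c1", 0, 1000)]
        # abuts the locus with 50 bp overlap < 100 required
        res = hf.simulate_probe_screen(clones, {"p1": [(950, 2000)]}, 100)
        assert res[0].n_positive == 0
        res = hf.simulate_probe_screen(clones, {"p1": [(900, 2000)]}, 100)
        assert res[0].n_positive == 1

    def test_expected_positives_match_binomial_mean(self):
        # single-copy probe in a coverage-c library: E[positives] ~ c
        rng_genome = np.random.default_rng(0)
        L = 200_000
        seq = "".join("ACGT"[i] for i in rng_genome.integers(0, 4, size=L))
        locus = (100_000, 101_000)
        insert = 20_000
        n_clones = 50                      # coverage = 50*20k/200k = 5x
        counts = []
        for rep in range(200):
            params = hf.BacLibraryParams(n_clones=n_clones,
                                         insert_mean_bp=insert,
                                         insert_sd_bp=0, empty_clone_prob=0.0,
                                         seed=rep)
            clones, _ = hf.simulate_bac_library(seq, params)
            res = hf.simulate_probe_screen(clones, {"p": [locus]},
                                           min_overlap_bp=500)
            counts.append(res[0].n_positive)
        # exact binomial mean: a clone is positive iff its start falls in the
        # window [locus_start - insert + ov, locus_end - ov]
        ov = 500
        window = (locus[1] - ov) - (locus[0] - insert + ov) + 1
        expected = n_clones * window / (L - insert + 1)
        assert expected == pytest.approx(n_clones * insert / L, rel=0.15)  # ~ coverage
        assert np.mean(counts) == pytest.approx(expected, rel=0.10)
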