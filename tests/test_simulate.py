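"""Synthetic-genome generator: truth bookkeeping and fixture round-trips."""

import math

import numpy as np
import pytest

import hriquant as hq
from hriquant.simulate import SimParams, emit_fixtures, simulate_gene_counts, true_fhri


class TestGeneratorBasics:
    def test_zero_rates_give_empty_data(self):
        params = SimParams(n_genes=20, n_chromosomes=8, theta4=0.0,
                           k4_mean=0.0, adaptive_curve=(0.0, 0.0, 1.0),
                           n_pop_grid=32)
        genes, truth = simulate_gene_counts(params, seed=0)
        for g in genes:
            assert g.counts.sfs4.n_segregating == 0
            assert g.counts.sfs0.n_segregating == 0
            assert g.counts.D0 == g.counts.D4 == g.counts.Di == 0
        assert truth.f_hri == 0.0

    def test_negative_curve_rejected_at_construction(self):
        with pytest.raises(ValueError):
            SimParams(adaptive_curve=(0.0126, -0.0186, 2.1237))  # < 0 near rr=0

    def test_segregating_sites_scale_linearly_with_sites(self):
        """Poisson means double when the 4-fold site count doubles."""
        base = dict(n_genes=400, n_chromosomes=16, n_pop_grid=32,
                    sigma_L0=0.0, mut_sigma=0.0)
        g1, _ = simulate_gene_counts(SimParams(mean_L0=600, **base), seed=4)
        g2, _ = simulate_gene_counts(SimParams(mean_L0=1200, **base), seed=5)
        s1 = np.mean([g.counts.sfs4.n_segregating for g in g1])
        s2 = np.mean([g.counts.sfs4.n_segregating for g in g2])
        ratio = s2 / s1
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_divergence_counts_near_expectation(self):
        params = SimParams(n_genes=500, n_chromosomes=16, n_pop_grid=32,
                           mut_sigma=0.0, sigma_L0=0.0)
        genes, _ = simulate_gene_counts(params, seed=9)
        # observed raw 4-fold differences, Tamura-corrected back, ~ k4_mean
        from hriquant.counts import tamura_correct
        D4 = sum(g.counts.D4 for g in genes)
        L4 = sum(g.counts.L4 for g in genes)
        ts = sum(g.counts.D4_ts for g in genes)
        k4 = tamura_correct(ts / L4, (D4 - ts) / L4, 0.5)
        assert k4 == pytest.approx(params.k4_mean, rel=0.03)


class TestTruth:
    def test_no_adaptive_component_means_zero_loss(self):
        params = SimParams(adaptive_curve=(0.01, 0.0, 1.0))
        assert true_fhri(params, rr=[0.1, 0.5, 5.0], L0=[100, 100, 100]) == 0.0

    def test_all_genes_above_threshold_mean_zero_loss(self):
        params = SimParams()
        assert true_fhri(params, rr=[3.0, 5.0], L0=[100, 100]) == 0.0

    def test_three_gene_hand_computation(self):
        a, b, c = 0.01, -0.009, 1.0
        params = SimParams(adaptive_curve=(a, b, c))
        rr = [0.5, 1.0, 3.0]
        L0 = [100.0, 100.0, 100.0]
        lost = 100 * (a - (a + b * math.exp(-c * 0.5))) \
            + 100 * (a - (a + b * math.exp(-c * 1.0)))
        want = lost / (300 * a)
        assert true_fhri(params, rr, L0) == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(0.29232, abs=1e-4)

    def test_truth_reproducible_from_stored_per_gene_values(self):
        params = SimParams(n_genes=300, n_chromosomes=16, n_pop_grid=32)
        _, truth = simulate_gene_counts(params, seed=2)
        recomputed = true_fhri(params, truth.rr, truth.L0)
        assert truth.f_hri == recomputed


@pytest.fixture(scope="module")
def fixture_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    params = SimParams(n_genes=5, n_chromosomes=16, mean_L0=400, n_pop_grid=32)
    genes, truth = emit_fixtures(params, seed=77, out_dir=out)
    return out, genes, truth


class TestFixtureRoundTrip:
    def test_files_written(self, fixture_run):
        out, genes, _ = fixture_run
        assert (out / "annotation.gff3").exists()
        assert (out / "recmap.tsv").exists()
        assert (out / "truth.json").exists()
        assert len(list((out / "alignments").glob("*.fasta"))) == len(genes)

    def test_roundtrip_counts_match_simulated(self, fixture_run, rng):
        """Reading the emitted files back through the site classifier and
        counting stages reproduces every simulated quantity exactly
        (haplotype 0 pinned as the divergence line)."""
        from hriquant.pipeline import process_alignment
        from hriquant.sites import read_gene_alignments

        out, genes, _ = fixture_run
        by_id = {g.gene_id: g.counts for g in genes}
        n_seen = 0
        for aln in read_gene_alignments(out / "alignments", out / "annotation.gff3"):
            want = by_id[aln.gene_id]
            got, _ = process_alignment(aln, 16, rng, divergence_haplotype=0)
            assert got is not None
            assert (got.L0, got.L4, got.Li) == (want.L0, want.L4, want.Li)
            assert (got.D0, got.D4, got.Di) == (want.D0, want.D4, want.Di)
            assert (got.D4_ts, got.D4_tv) == (want.D4_ts, want.D4_tv)
            assert np.array_equal(got.sfs0.counts, want.sfs0.counts)
            assert np.array_equal(got.sfs4.counts, want.sfs4.counts)
            assert np.array_equal(got.sfsi.counts, want.sfsi.counts)
            assert got.gc4 == pytest.approx(want.gc4)
            n_seen += 1
        assert n_seen == len(genes)

    def test_site_classes_disjoint_on_fixtures(self, fixture_run):
        from hriquant.sites import (classify_coding_sites,
                                    extract_short_intron_sites,
                                    filter_and_trim_exons, read_gene_alignments)
        out, _, _ = fixture_run
        for aln in read_gene_alignments(out / "alignments", out / "annotation.gff3"):
            kept = filter_and_trim_exons(aln.exons, aln.ingroup_seqs,
                                         aln.outgroup_seq)
            s0, s4 = classify_coding_sites(kept, aln.ingroup_seqs,
                                           aln.outgroup_seq)
            si = extract_short_intron_sites(aln.introns, aln.ingroup_seqs,
                                            aln.outgroup_seq)
            assert len(set(s0) | set(s4) | set(si)) == len(s0) + len(s4) + len(si)

    def test_frameshifted_exon_dropped_by_reader(self, tmp_path):
        """A gene whose exon carries an alignment gap loses that exon."""
        from hriquant.sites import GeneAlignment, filter_and_trim_exons
        seqs = ["ATG" * 20, "ATG" * 10 + "A-G" + "ATG" * 9, "ATG" * 20]
        kept = filter_and_trim_exons([(0, 60)], seqs[:2], seqs[2])
        assert kept == []

    def test_empty_gene_set_is_valid(self, tmp_path):
        params = SimParams(n_genes=0, n_chromosomes=8, n_pop_grid=32)
        genes, truth = emit_fixtures(params, seed=1, out_dir=tmp_path)
        assert genes == []
        assert (tmp_path / "annotation.gff3").exists()


class TestGeneratorAnalyzerConsistency:
    def test_pooled_alpha_recovery_fast_path(self, small_gene_set):
        """With the generating fixation factor supplied, the pooled-bin
        estimate of the adaptive rate matches the generator's curve."""
        params, genes, truth = small_gene_set
        rng = np.random.default_rng(0)
        res, df = hq.fhri_from_genes(genes, rng, n_bins=15,
                                     fixation=truth.fixation_factor)
        assert abs(res.f_hri - truth.f_hri) < 0.06
        # asymptotic bins sit near the curve's plateau
        assert res.ka_no_hri == pytest.approx(params.adaptive_curve[0], rel=0.15)

    def test_mutation_split_breaks_spurious_anticorrelation(self, rng):
        """Ranking by K4,1 and reading out K4,3 gives a mutation-rate axis
        that is clean of the estimator coupling: under true mutation
        heterogeneity the binned K4,3 still orders the bins."""
        from hriquant.binning import pool_bin, rank_bin, split_k4_three
        from hriquant.binning import GeneRecord
        params = SimParams(n_genes=600, n_chromosomes=16, n_pop_grid=32,
                           mut_sigma=0.5)
        genes, truth = simulate_gene_counts(params, seed=21)
        recs = [GeneRecord(g.counts, g.covariates,
                           split_k4_three(g.gene_id, g.counts.D4, g.counts.L4,
                                          rng))
                for g in genes]
        bins = rank_bin(recs, lambda g: g.split.k4_parts[0], 10)
        pooled = [pool_bin(b, f"m{j}") for j, b in enumerate(bins)]
        k43 = [pb.mean_k4_mut for pb in pooled]
        # true mutation heterogeneity: the independent readout still rises
        assert k43[-1] > k43[0]
        rho = np.corrcoef(np.arange(10), k43)[0, 1]
        assert rho > 0.8
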