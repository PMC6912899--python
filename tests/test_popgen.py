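import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
from mitosat.data import DataError, GenotypeTable, HaplotypeAlignment, PopulationMap
from mitosat import popgen
from test_sumstats import make_alignment, make_table


class TestBenjaminiHochberg:
    def test_matches_direct_definition(self):
        # hand-computed: sorted p (.01,.02,.03,.04,.5); adj = p * 5/rank,
        # then enforced monotone from the largest down
        p = np.array([0.03, 0.5, 0.01, 0.04, 0.02])
        adj, rej = popgen.benjamini_hochberg(p, alpha=0.05)
        assert adj == pytest.approx([0.05, 0.5, 0.05, 0.05, 0.05])
        assert rej.tolist() == [True, False, True, True, True]

    def test_adjusted_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        adj, _ = popgen.benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestRarefaction:
    def test_full_sample_equals_observed_count(self):
        t = make_table({"A": [[(10, 11)], [(12, 12)]], "B": [[(10, 10)], [(10, 11)]]})
        out = popgen.rarefied_richness(t, g=4)
        assert out.loc["A", "A_r"] == pytest.approx(3.0)
        assert out.loc["B", "A_r"] == pytest.approx(2.0)

    def test_exclusive_allele_at_full_depth(self):
        t = make_table({"A": [[(9, 9)], [(9, 9)]], "B": [[(5, 5)], [(5, 5)]]})
        out = popgen.rarefied_richness(t, g=4)
        # each pop is fixed for its own exclusive allele
        assert out.loc["A", "A_r"] == pytest.approx(1.0)
        assert out.loc["A", "A_rp"] == pytest.approx(1.0)

    def test_shared_single_allele_has_no_private_richness(self):
        t = make_table({"A": [[(9, 9)], [(9, 9)]], "B": [[(9, 9)], [(9, 9)]]})
        out = popgen.rarefied_richness(t, g=2)
        assert out.loc["A", "A_rp"] == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            pops = {
                lab: [
                    [tuple(sorted(rng.integers(10, 14, size=2)))]
                    for _ in range(int(rng.integers(2, 5)))
                ]
                for lab in "AB"
            }
            t = make_table(pops)
            g = 3
            copies = {
                lab: [a for ind in inds for a in ind[0]] for lab, inds in pops.items()
            }
            if min(len(c) for c in copies.values()) < g:
                continue
            ar, arp = oracles.rarefaction_oracle(copies, g)
            out = popgen.rarefied_richness(t, g=g)
            for lab in "AB":
                assert out.loc[lab, "A_r"] == pytest.approx(ar[lab], abs=1e-10)
                assert out.loc[lab, "A_rp"] == pytest.approx(arp[lab], abs=1e-10)

    def test_insufficient_copies_name_the_location(self):
        t = make_table({"A": [[(10, 11)]], "B": [[(10, 10)], [(10, 11)]]})
        with pytest.raises(DataError, match="'A'"):
            popgen.rarefied_richness(t, g=4)


class TestHwe:
    def test_all_heterozygotes_fis_minus_one(self):
        t = make_table({"A": [[(10, 12)]] * 10})
        res = popgen.hwe_test(t, "A", n_perm=400, rng=np.random.default_rng(0))
        assert res.multilocus_fis == pytest.approx(-1.0)
        assert res.multilocus_p < 0.05

    def test_hardy_weinberg_counts_fis_zero(self):
        inds = [[(10, 10)]] * 25 + [[(10, 12)]] * 50 + [[(12, 12)]] * 25
        t = make_table({"A": inds})
        res = popgen.hwe_test(t, "A", n_perm=200, rng=np.random.default_rng(0))
        # the unbiased Weir-Cockerham f is ~1/(2n-1), not exactly 0, on
        # genotype counts that match Hardy-Weinberg proportions exactly
        assert res.multilocus_fis == pytest.approx(0.0, abs=1 / 99)
        assert res.multilocus_p > 0.5

    def test_fis_matches_variance_component_oracle(self):
        """F_IS = 1 - sum(c)/sum(b+c) recomputed from scratch per locus."""
        rng = np.random.default_rng(12)
        inds = [
            [tuple(sorted(rng.integers(10, 13, size=2))) for _ in range(3)]
            for _ in range(8)
        ]
        t = make_table({"A": inds})
        res = popgen.hwe_test(t, "A", n_perm=0, rng=rng)
        num = den = 0.0
        for l in range(3):
            calls = [ind[l] for ind in inds]
            n = len(calls)
            alleles = sorted({a for g in calls for a in g})
            if len(alleles) < 2:
                continue
            for al in alleles:
                p = sum(g.count(al) for g in calls) / (2 * n)
                h = sum(1 for g in calls if (g[0] == al) != (g[1] == al)) / n
                b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
                num += h / 2
                den += b + h / 2
        assert res.multilocus_fis == pytest.approx(1 - num / den, abs=1e-10)

    def test_monomorphic_locus_excluded(self):
        t = make_table({"A": [[(10, 10), (10, 12)], [(10, 10), (12, 12)]]})
        res = popgen.hwe_test(t, "A", n_perm=50, rng=np.random.default_rng(0))
        assert np.isnan(res.per_locus.loc["L0", "F_IS"])
        assert np.isfinite(res.per_locus.loc["L1", "F_IS"])


class TestJostD:
    def test_identical_distributions_near_zero(self):
        """The sample-size-corrected estimator is slightly negative on
        identical finite samples and approaches 0 as n grows."""
        inds = [[(10, 10)], [(10, 12)], [(12, 12)], [(10, 12)]]
        small = make_table({"A": inds, "B": inds})
        est = popgen.jost_d(small, "A", "B")
        assert est <= 0 and abs(est) < 2 / len(inds)
        big = make_table({"A": inds * 50, "B": inds * 50})
        assert abs(popgen.jost_d(big, "A", "B")) < 0.01

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pops = {
                lab: [
                    [tuple(sorted(rng.integers(10, 15, size=2)))]
                    for _ in range(int(rng.integers(3, 8)))
                ]
                for lab in "AB"
            }
            t = make_table(pops)
            oracle = oracles.jost_d_oracle(
                [ind[0] for ind in pops["A"]], [ind[0] for ind in pops["B"]]
            )
            assert popgen.jost_d(t, "A", "B") == pytest.approx(oracle, abs=1e-10)


class TestPhiSt:
    def test_fixed_haplotypes_is_one(self):
        a = make_alignment({"A": ["AAAA"] * 4, "B": ["TTTT"] * 4})
        assert popgen.phi_st(a, "A", "B") == pytest.approx(1.0)

    def test_matches_amova_oracle(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, size=12)) for _ in range(8)]
        a = make_alignment({"A": seqs[:4], "B": seqs[4:]})
        d2 = oracles.pairwise_diff_matrix(a.sequences)
        _, _, phi = oracles.amova_two_level_oracle(d2, list(a.locations))
        assert popgen.phi_st(a, "A", "B") == pytest.approx(phi, abs=1e-10)


class TestAmova:
    def _seq_data(self):
        return make_alignment(
            {
                "P1": ["AAAA", "AAAT", "AAAA"],
                "P2": ["AATA", "AAAA", "AATA"],
                "P3": ["TTTT", "TTTA", "TTTT"],
                "P4": ["TTAT", "TTTT", "TTAT"],
            }
        )

    def test_components_match_sums_of_squares_oracle(self):
        aln = self._seq_data()
        pmap = PopulationMap({}, {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"})
        res = popgen.amova(aln, pmap, n_perm=0)
        d2 = oracles.pairwise_diff_matrix(aln.sequences)
        sa, sb, sc = oracles.amova_three_level_oracle(
            d2, list(aln.locations), [pmap.group_of(p) for p in aln.locations]
        )
        assert res.components["among_groups"] == pytest.approx(sa, abs=1e-8)
        assert res.components["among_locations_within_groups"] == pytest.approx(sb, abs=1e-8)
        assert res.components["within_locations"] == pytest.approx(sc, abs=1e-8)

    def test_percentages_sum_to_hundred(self):
        aln = self._seq_data()
        pmap = PopulationMap({}, {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"})
        res = popgen.amova(aln, pmap, n_perm=0)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_groups_fixed_for_distinct_haplotypes(self):
        aln = make_alignment(
            {"P1": ["AAAA"] * 3, "P2": ["AAAA"] * 3, "P3": ["TTTT"] * 3, "P4": ["TTTT"] * 3}
        )
        pmap = PopulationMap({}, {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"})
        res = popgen.amova(aln, pmap, n_perm=0)
        assert res.percentages["among_groups"] == pytest.approx(100.0, abs=1e-6)

    def test_no_structure_small_among_group_share(self):
        rng = np.random.default_rng(2)
        seqs = ["AAAA" if rng.random() < 0.5 else "AAAT" for _ in range(40)]
        aln = make_alignment(
            {f"P{i}": seqs[i * 10 : (i + 1) * 10] for i in range(4)}
        )
        pmap = PopulationMap({}, {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"})
        res = popgen.amova(aln, pmap, n_perm=0)
        assert abs(res.percentages["among_groups"]) < 10.0

    def test_single_group_reduces_to_two_level(self):
        aln = self._seq_data()
        pmap = PopulationMap({}, {p: "G" for p in ("P1", "P2", "P3", "P4")})
        res = popgen.amova(aln, pmap, n_perm=0)
        assert set(res.components) == {"among_locations", "within_locations"}

    def test_permutation_p_values_seeded(self):
        aln = self._seq_data()
        pmap = PopulationMap({}, {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"})
        r1 = popgen.amova(aln, pmap, n_perm=99, rng=np.random.default_rng(5))
        r2 = popgen.amova(aln, pmap, n_perm=99, rng=np.random.default_rng(5))
        assert r1.p_values == r2.p_values

    def test_msat_amova_oracle(self):
        rng = np.random.default_rng(4)
        pops = {
            lab: [
                [tuple(sorted(rng.integers(10, 13, size=2))) for _ in range(2)]
                for _ in range(3)
            ]
            for lab in ("P1", "P2", "P3", "P4")
        }
        t = make_table(pops)
        pmap = PopulationMap({}, {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"})
        res = popgen.amova(t, pmap, n_perm=0)
        # oracle distance: gene copies as units, 0/1 mismatch summed over loci
        units, labels = [], []
        for lab, inds in pops.items():
            for ind in inds:
                for copy in range(2):
                    units.append([ind[l][copy] for l in range(2)])
                    labels.append(lab)
        u = np.array(units)
        d2 = (u[:, None, :] != u[None, :, :]).sum(axis=2).astype(float)
        sa, sb, sc = oracles.amova_three_level_oracle(
            d2, labels, [pmap.group_of(p) for p in labels]
        )
        assert res.components["among_groups"] == pytest.approx(sa, abs=1e-8)
        assert res.components["within_locations"] == pytest.approx(sc, abs=1e-8)


class TestPairwiseDifferentiation:
    def test_matrices_and_fdr_flags(self):
        t = make_table(
            {
                "A": [[(10, 10)]] * 6,
                "B": [[(12, 12)]] * 6,
                "C": [[(10, 12)], [(10, 10)], [(12, 12)], [(10, 12)], [(10, 10)], [(12, 12)]],
            }
        )
        res = popgen.pairwise_differentiation(
            msat=t, n_perm=99, rng=np.random.default_rng(0)
        )
        assert res.fst.loc["A", "B"] == pytest.approx(1.0)
        assert res.fst.equals(res.fst.T)
        assert (np.diag(res.fst) == 0).all()
        assert res.significant["fst"].loc["A", "B"]

    def test_small_locations_excluded_with_warning(self):
        t = make_table({"A": [[(10, 10)]] * 3, "B": [[(12, 12)]] * 3, "C": [[(10, 12)]]})
        with pytest.warns(UserWarning, match="n<2"):
            res = popgen.pairwise_differentiation(msat=t, n_perm=0)
        assert "C" not in res.fst.index


class TestNeutrality:
    def test_monomorphic_sample_skipped(self):
        a = make_alignment({"A": ["ACGT"] * 6})
        res = popgen.neutrality_tests(a, "A", n_sim=10, rng=np.random.default_rng(0))
        assert res.skipped

    def test_star_genealogy_gives_negative_d_and_fs(self):
        """One common haplotype plus many singletons (a star-like pattern)
        drives both statistics negative."""
        base = "A" * 40
        seqs = [base] * 15
        for i in range(15):
            seqs.append(base[:i] + "T" + base[i + 1 :])
        a = make_alignment({"A": seqs})
        res = popgen.neutrality_tests(a, "A", n_sim=300, rng=np.random.default_rng(1))
        assert res.tajimas_d < 0
        assert res.fus_fs < 0

    def test_null_p_values_roughly_uniform(self):
        """P-values computed for samples simulated under the null are
        uniform (KS test over repeated draws)."""
        import msprime
        from scipy.stats import kstest

        rng = np.random.default_rng(6)
        n, length = 16, 400
        theta = 4.0
        mu = theta / (2 * 1000.0 * length)
        pvals = []
        sims = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1000.0,
            sequence_length=length, num_replicates=150, random_seed=3,
            record_provenance=False,
        )
        bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
        for i, ts in enumerate(sims):
            mts = msprime.sim_mutations(
                ts, rate=mu, model=msprime.JC69(), random_seed=i + 11,
                record_provenance=False,
            )
            mat = np.tile(bases[rng.integers(0, 4, size=length)], (n, 1))
            positions = mts.tables.sites.position
            for site_id, var in enumerate(mts.variants()):
                col = np.array([a.encode() for a in var.alleles], dtype="S1")
                mat[:, int(positions[site_id])] = col[var.genotypes]
            aln = HaplotypeAlignment(
                [f"s{k}" for k in range(n)], ["A"] * n,
                [row.tobytes().decode() for row in mat],
            )
            if aln.sequences.count(aln.sequences[0]) == n:
                continue
            res = popgen.neutrality_tests(a1 := aln, "A", n_sim=120, rng=rng)
            pvals.append(res.p_fs)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestLdScan:
    def test_planned_count(self):
        assert popgen.ld_test_count(25, 11) == 3300

    def test_perfect_coupling_small_p(self):
        inds = [[(1, 1), (5, 5)]] * 6 + [[(2, 2), (6, 6)]] * 6
        t = make_table({"A": inds})
        df = popgen.ld_scan(t, n_perm=199, rng=np.random.default_rng(0))
        assert len(df) == 1
        assert df["p_value"].iloc[0] < 0.02

    def test_monomorphic_pair_skipped_and_reported_separately(self):
        inds = [[(1, 1), (5, 5)], [(1, 2), (5, 5)]]
        t = make_table({"A": inds})
        df = popgen.ld_scan(t, n_perm=0)
        assert len(df) == 0  # locus 2 monomorphic -> pair not performed

    def test_independent_loci_p_roughly_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(5)
        n_ind, n_loci = 30, 10
        calls = rng.integers(10, 14, size=(n_ind, n_loci, 2)).astype(np.int32)
        t = GenotypeTable(
            [f"A_{i}" for i in range(n_ind)], ["A"] * n_ind,
            [f"L{j}" for j in range(n_loci)], np.sort(calls, axis=2),
        )
        df = popgen.ld_scan(t, n_perm=199, rng=rng)
        assert len(df) == 45
        assert kstest(df["p_value"], "uniform").pvalue > 0.01

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(7)
        calls = np.sort(rng.integers(10, 13, size=(12, 4, 2)), axis=2).astype(np.int32)
        t = GenotypeTable(
            [f"A_{i}" for i in range(12)], ["A"] * 12,
            [f"L{j}" for j in range(4)], calls,
        )
        d1 = popgen.ld_scan(t, n_perm=99, rng=np.random.default_rng(3))
        d2 = popgen.ld_scan(t, n_perm=99, rng=np.random.default_rng(3))
        pd.testing.assert_frame_equal(d1, d2)


class TestDiversityTable:
    def test_columns_and_basic_values(self):
        rng = np.random.default_rng(10)
        calls = np.sort(rng.integers(10, 14, size=(16, 5, 2)), axis=2).astype(np.int32)
        t = GenotypeTable(
            [f"{'AB'[i // 8]}_{i}" for i in range(16)],
            ["A"] * 8 + ["B"] * 8,
            [f"L{j}" for j in range(5)],
            calls,
        )
        aln = make_alignment(
            {"A": ["ACGT", "ACGA", "ACGT", "TCGT"], "B": ["ACGA", "ACGA", "TCGA", "ACGT"]}
        )
        df = popgen.diversity_table(t, aln, hwe_permutations=50, rng=rng)
        assert {"N", "N_a", "A_r", "A_rp", "H_O", "H_E", "F_IS", "HWE_p",
                "N_s", "H", "h", "S", "pi"} <= set(df.columns)
        assert df.loc["A", "N"] == 8
        assert df.loc["A", "N_s"] == 4
        assert 0 <= df.loc["A", "h"] <= 1
        assert df.loc["A", "A_r"] <= df.loc["A", "N_a"]

    def test_per_site_pi_times_length_equals_pairwise_diff(self):
        from mitosat import sumstats

        aln = make_alignment({"A": ["ACGTACGT", "ACGAACGA", "ACGTACGA"]})
        assert sumstats.nucleotide_diversity(aln) * aln.length == pytest.approx(
            sumstats.mean_pairwise_diff(aln)
        )
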