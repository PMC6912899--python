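import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from mitosat.data import DataError, GenotypeTable, HaplotypeAlignment
from mitosat import sumstats as ss


def make_table(pops: dict[str, list[list[tuple[int, int]]]]) -> GenotypeTable:
    """pops[label] = per individual list over loci of (a, b)."""
    ids, locs, rows = [], [], []
    for label, inds in pops.items():
        for k, ind in enumerate(inds):
            ids.append(f"{label}{k}")
            locs.append(label)
            rows.append(ind)
    n_loci = len(rows[0])
    return GenotypeTable(ids, locs, [f"L{j}" for j in range(n_loci)], np.array(rows))


def make_alignment(pops: dict[str, list[str]]) -> HaplotypeAlignment:
    ids, locs, seqs = [], [], []
    for label, pseqs in pops.items():
        for k, s in enumerate(pseqs):
            ids.append(f"{label}{k}")
            locs.append(label)
            seqs.append(s)
    return HaplotypeAlignment(ids, locs, seqs)


class TestMeanAlleles:
    def test_single_locus_two_alleles(self):
        t = make_table({"A": [[(10, 10)], [(10, 12)]]})
        assert ss.mean_num_alleles(t, "A") == 2

    def test_average_over_loci(self):
        t = make_table(
            {"A": [[(10, 11), (1, 2)], [(12, 13), (3, 4)]]}
        )  # 4 and 4 alleles
        assert ss.mean_num_alleles(t, "A") == 4

    def test_monomorphic_is_one(self):
        t = make_table({"A": [[(7, 7)], [(7, 7)]]})
        assert ss.mean_num_alleles(t, "A") == 1


class TestNeiDiversity:
    def test_identical_copies_zero(self):
        t = make_table({"A": [[(7, 7)], [(7, 7)]]})
        assert ss.nei_gene_diversity(t, "A") == 0

    def test_two_distinct_haplotypes_is_one(self):
        a = make_alignment({"A": ["ACGT", "ACGA"]})
        assert ss.nei_gene_diversity(a) == 1.0

    def test_four_copies_frequencies(self):
        # gene-copy frequencies (0.5, 0.25, 0.25) -> (4/3)(1 - 0.375)
        t = make_table({"A": [[(10, 10)], [(12, 14)]]})
        assert ss.nei_gene_diversity(t, "A") == pytest.approx(0.833333333, abs=1e-9)


class TestMgw:
    @pytest.mark.parametrize(
        "genotypes,expected",
        [
            ([(10, 11), (12, 12)], 1.0),  # alleles 10,11,12: 3/3
            ([(10, 12), (10, 12)], 2 / 3),
            ([(10, 10), (10, 10)], 1.0),  # monomorphic: 1/1
        ],
    )
    def test_known_values(self, genotypes, expected):
        t = make_table({"A": [[g] for g in genotypes]})
        assert ss.mgw(t, "A") == pytest.approx(expected)


class TestDeltaMu:
    def test_identical_pops_zero(self):
        t = make_table({"A": [[(10, 12)]], "B": [[(10, 12)]]})
        assert ss.delta_mu_sq(t, "A", "B") == 0

    def test_single_locus_mean_shift(self):
        t = make_table({"A": [[(10, 10)]], "B": [[(13, 13)]]})
        assert ss.delta_mu_sq(t, "A", "B") == 9

    def test_average_over_loci(self):
        t = make_table(
            {"A": [[(10, 10), (10, 10)]], "B": [[(11, 11), (13, 13)]]}
        )
        assert ss.delta_mu_sq(t, "A", "B") == 5


class TestWcFst:
    def test_fixed_demes(self):
        t = make_table({"A": [[(10, 10)]] * 4, "B": [[(12, 12)]] * 4})
        assert ss.wc_fst(t, "A", "B") == pytest.approx(1.0)

    def test_identical_frequencies_small_negative(self):
        """Two finite samples with identical frequencies give the known
        small negative Weir-Cockerham estimate (~ -1/(2n-1)), approaching
        zero as n grows."""
        inds = [[(10, 10)], [(10, 12)], [(12, 12)], [(10, 12)]]
        t = make_table({"A": inds, "B": inds})
        est = ss.wc_fst(t, "A", "B")
        assert est <= 0
        assert abs(est) < 2 / len(inds)
        big = make_table({"A": inds * 100, "B": inds * 100})
        assert abs(ss.wc_fst(big, "A", "B")) < 2 / 400

    def test_monomorphic_defined_zero(self):
        t = make_table({"A": [[(10, 10)]] * 3, "B": [[(10, 10)]] * 3})
        assert ss.wc_fst(t, "A", "B") == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pops = {
                lab: [
                    [tuple(sorted(rng.integers(10, 14, size=2)))]
                    for _ in range(int(rng.integers(4, 9)))
                ]
                for lab in "AB"
            }
            t = make_table(pops)
            oracle = oracles.wc_fst_oracle(
                [[ind[0] for ind in pops["A"]], [ind[0] for ind in pops["B"]]]
            )
            assert ss.wc_fst(t, "A", "B") == pytest.approx(oracle, abs=1e-10)

    def test_invariant_under_allele_relabelling(self):
        rng = np.random.default_rng(1)
        pops = {
            lab: [
                [tuple(sorted(rng.integers(10, 14, size=2)))] for _ in range(6)
            ]
            for lab in "AB"
        }
        t = make_table(pops)
        relabel = {10: 40, 11: 21, 12: 12, 13: 33}
        shifted = {
            lab: [[tuple(sorted(relabel[x] for x in ind[0]))] for ind in inds]
            for lab, inds in pops.items()
        }
        t2 = make_table(shifted)
        assert ss.wc_fst(t, "A", "B") == pytest.approx(
            ss.wc_fst(t2, "A", "B"), abs=1e-12
        )


class TestPairwiseDiff:
    def test_identical_zero(self):
        a = make_alignment({"A": ["ACGT", "ACGT"]})
        assert ss.mean_pairwise_diff(a) == 0

    def test_single_difference(self):
        a = make_alignment({"A": ["ACGT", "ACGA"]})
        assert ss.mean_pairwise_diff(a) == 1

    def test_three_sequences_average(self):
        a = make_alignment({"A": ["AAAA", "AAAT", "GGAT"]})
        # pairwise differences 1, 3, 2 -> mean 2
        assert ss.mean_pairwise_diff(a) == 2

    def test_pairwise_deletion_of_missing(self):
        a = make_alignment({"A": ["ACNT", "A-GT"]})
        assert ss.mean_pairwise_diff(a) == 0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        length = int(rng.integers(1, 30))
        chars = np.array(list("ACGTN-"))
        seqs = [
            "".join(rng.choice(chars, p=[0.3, 0.3, 0.15, 0.15, 0.05, 0.05], size=length))
            for _ in range(n)
        ]
        a = make_alignment({"A": seqs})
        d = oracles.pairwise_diff_matrix(seqs)
        iu = np.triu_indices(n, k=1)
        assert ss.mean_pairwise_diff(a) == pytest.approx(d[iu].mean(), abs=1e-12)


class TestTajimasD:
    def test_no_segregating_sites_flagged_zero(self):
        a = make_alignment({"A": ["ACGT"] * 4})
        d, degen = ss.tajimas_d(a)
        assert d == 0.0 and degen

    def test_matches_formula_oracle(self):
        a = make_alignment({"A": ["AAAA", "AAAT", "ATAT", "TTAT"]})
        d, degen = ss.tajimas_d(a)
        assert not degen
        assert d == pytest.approx(oracles.tajimas_d_oracle(a.sequences), abs=1e-10)

    def test_neutral_simulations_centre_near_zero(self):
        """Under the neutral constant-size coalescent both D and Fs have
        expectation near zero."""
        import msprime

        n, theta, reps = 20, 5.0, 2000
        big_n, length = 1000.0, 1000
        mu = theta / (2 * big_n * length)
        d_vals, fs_vals = [], []
        sims = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=big_n,
            sequence_length=length, num_replicates=reps, random_seed=7,
            record_provenance=False,
        )
        for i, ts in enumerate(sims):
            mts = msprime.sim_mutations(
                ts, rate=mu, model=msprime.JC69(), random_seed=i + 1,
                record_provenance=False,
            )
            g = mts.genotype_matrix()
            counts = np.stack(
                [(g == al).sum(axis=1) for al in range(int(g.max(initial=0)) + 1)],
                axis=1,
            )
            s = int(((counts > 0).sum(axis=1) > 1).sum())
            pi = float(
                ((n**2 - (counts**2).sum(axis=1)) / 2.0).sum() / (n * (n - 1) / 2)
            )
            k = len({tuple(col) for col in g.T})
            d_vals.append(ss._d_from(n, s, pi))
            fs_vals.append(ss._fs_from(n, pi, k))
        assert -0.25 < np.mean(d_vals) < 0.10
        assert abs(np.mean(fs_vals)) < 0.5


class TestFusFs:
    def test_monomorphic_flagged_zero(self):
        a = make_alignment({"A": ["ACGT"] * 5})
        fs, degen = ss.fus_fs(a)
        assert fs == 0.0 and degen

    def test_matches_stirling_enumeration_oracle(self):
        for n, k_obs, theta in [(5, 3, 1.0), (8, 2, 0.5), (10, 7, 3.0)]:
            expected = oracles.fus_fs_oracle(n, k_obs, theta)
            assert ss._fs_from(n, theta, k_obs) == pytest.approx(expected, abs=1e-10)

    def test_ewens_distribution_sums_to_one(self):
        pk = ss.ewens_k_distribution(25, 2.7)
        assert pk.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pk >= 0).all()


class TestHaplotypeFst:
    def test_fixed_haplotypes(self):
        a = make_alignment({"A": ["AAAA"] * 5, "B": ["TTTT"] * 5})
        assert ss.haplotype_fst(a, "A", "B") == pytest.approx(1.0)

    def test_shared_frequencies_small_negative(self):
        seqs = ["AAAA", "AAAT", "AAAA", "AAAT"]
        a = make_alignment({"A": seqs, "B": seqs})
        est = ss.haplotype_fst(a, "A", "B")
        assert est <= 0
        assert abs(est) < 2 / len(seqs)
        big = make_alignment({"A": seqs * 50, "B": seqs * 50})
        assert abs(ss.haplotype_fst(big, "A", "B")) < 0.01


class TestSummarizePair:
    def _paired(self):
        table = make_table(
            {
                "A": [[(10, 12), (20, 20)], [(12, 12), (22, 22)]],
                "B": [[(14, 14), (20, 22)], [(14, 16), (22, 22)]],
            }
        )
        aln = make_alignment(
            {"A": ["ACGT", "ACGA", "ACGT"], "B": ["TCGA", "TCGA", "ACGA"]}
        )
        return table, aln

    def test_vector_shape_and_names(self):
        table, aln = self._paired()
        vec = ss.summarize_pair(table, aln)
        assert len(vec.values) == 19
        assert vec.names == ss.STAT_NAMES
        assert np.isfinite(vec.values).all()

    def test_swapped_labels_swap_fields(self):
        table, aln = self._paired()
        v1 = ss.summarize_pair(table, aln)
        swap = {"A": "B", "B": "A"}
        v2 = ss.summarize_pair(table.relabel(swap), aln.relabel(swap))
        for name in ss.STAT_NAMES:
            if name.endswith("_1"):
                other = name[:-2] + "_2"
                assert v2[name] == pytest.approx(v1[other], abs=1e-12)
            elif name.endswith("_2"):
                other = name[:-2] + "_1"
                assert v2[name] == pytest.approx(v1[other], abs=1e-12)
            else:
                assert v2[name] == pytest.approx(v1[name], abs=1e-12)

    def test_population_mismatch_rejected(self):
        table, aln = self._paired()
        with pytest.raises(DataError, match="two populations"):
            ss.summarize_pair(table, aln.relabel({"B": "C"}))

    def test_fast_path_matches_public_functions(self):
        table, aln = self._paired()
        vec = ss.summarize_pair(table, aln)
        assert vec["sat_K_1"] == pytest.approx(ss.mean_num_alleles(table, "A"))
        assert vec["sat_H_2"] == pytest.approx(ss.nei_gene_diversity(table, "B"))
        assert vec["sat_FST"] == pytest.approx(ss.wc_fst(table, "A", "B"), abs=1e-12)
        assert vec["sat_MGW_1"] == pytest.approx(ss.mgw(table, "A"))
        assert vec["sat_dmu2"] == pytest.approx(ss.delta_mu_sq(table, "A", "B"))
        assert vec["mt_pi_1"] == pytest.approx(
            ss.mean_pairwise_diff(aln, "A"), abs=1e-12
        )
        assert vec["mt_D_2"] == pytest.approx(ss.tajimas_d(aln, "B")[0], abs=1e-12)
        assert vec["mt_Fs_1"] == pytest.approx(ss.fus_fs(aln, "A")[0], abs=1e-12)
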