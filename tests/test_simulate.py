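"""Coalescent simulator, dataset generation and VCF round trips."""

import numpy as np
import pytest

from splitmig import (
    EmptyDatasetError,
    SimulationConfig,
    SplitMigParams,
    build_joint_sfs,
    read_popmap,
    read_vcf,
    simulate_dataset,
    simulate_genealogy,
    write_popmap,
    write_vcf,
)


def harmonic(n):
    return sum(1.0 / i for i in range(1, n))


class TestSimulateGenealogy:
    def test_requires_samples_in_both_demes(self, truth_params, rng):
        with pytest.raises(ValueError):
            simulate_genealogy(2, 0, truth_params, rng)

    def test_rejects_nonfinite_params(self):
        with pytest.raises(ValueError):
            SplitMigParams(nu1=float("nan"), nu2=1.0, T=1.0, m=1.0)
        with pytest.raises(ValueError):
            SplitMigParams(nu1=1.0, nu2=1.0, T=float("inf"), m=1.0)

    def test_panmictic_limit_total_length(self, rng):
        # With T=0 and nu1=nu2=1 the sample is panmictic: the expected total
        # branch length for n haplotypes is 2*sum_{i<n} 1/i in 2N units.
        p = SplitMigParams(nu1=1.0, nu2=1.0, T=1e-12, m=1.0)
        n1, n2 = 3, 3
        reps = 10_000
        tot = np.array(
            [simulate_genealogy(n1, n2, p, rng).total_length for _ in range(reps)]
        )
        expected = 2.0 * harmonic(n1 + n2)
        se = tot.std(ddof=1) / np.sqrt(reps)
        assert abs(tot.mean() - expected) < 3 * se

    def test_no_migration_first_event_is_coalescence(self, rng):
        # With m=0 and a long isolation phase, every event until each deme
        # has a single lineage must be a within-deme coalescence; afterwards
        # the two demes cannot merge before T.
        p = SplitMigParams(nu1=1.0, nu2=1.0, T=10.0, m=1e-300)
        for _ in range(50):
            gen = simulate_genealogy(2, 2, p, rng)
            # the root join (the only cross-deme event) must happen after T
            assert gen.times[-1] >= 10.0
            assert all(t < 10.0 for t in gen.times[:-1])
            # no recorded (non-root) branch mixes the two populations
            for _mask, count1, count2, _length in gen.branches:
                assert count1 == 0 or count2 == 0

    def test_branch_counts_partition_sample(self, truth_params, rng):
        gen = simulate_genealogy(4, 6, truth_params, rng)
        for mask, count1, count2, length in gen.branches:
            assert length >= 0
            assert 0 <= count1 <= 4 and 0 <= count2 <= 6
            assert (count1, count2) != (0, 0)
            assert (count1, count2) != (4, 6)
            assert bin(mask).count("1") == count1 + count2
        assert gen.times == sorted(gen.times)


class TestSimulateDataset:
    def test_invariants(self, small_dataset):
        derived = small_dataset.alleles.sum(axis=1)
        assert derived.min() >= 1
        assert derived.max() <= small_dataset.alleles.shape[1] - 1
        assert small_dataset.alleles.shape[1] == 2 * (
            small_dataset.n1 + small_dataset.n2
        )
        assert small_dataset.provenance["seed"] == 1234

    def test_zero_theta_raises_empty_dataset(self, truth_params):
        config = SimulationConfig(
            n1=2, n2=2, L=200, params=truth_params, theta_locus=1e-9, seed=3
        )
        with pytest.raises(EmptyDatasetError, match="theta_locus"):
            simulate_dataset(config)

    def test_variable_locus_count_matches_simulation_oracle(self, rng):
        # Brute-force oracle: P(>=1 mutation) estimated by direct replicate
        # simulation of Poisson mutation counts on independent genealogies.
        p = SplitMigParams(nu1=1.0, nu2=1.0, T=0.01, m=1.0)
        theta, L = 0.02, 4000
        reps = 4000
        hits = 0
        for _ in range(reps):
            gen = simulate_genealogy(4, 4, p, rng)
            hits += rng.poisson(theta / 2.0 * gen.total_length) > 0
        phat = hits / reps
        config = SimulationConfig(
            n1=2, n2=2, L=L, params=p, theta_locus=theta, seed=99
        )
        ds = simulate_dataset(config)
        sd = np.sqrt(L * phat * (1 - phat) + L**2 * phat * (1 - phat) / reps)
        assert abs(ds.n_loci - L * phat) < 3 * sd

    def test_determinism(self, truth_params):
        config = SimulationConfig(n1=3, n2=3, L=300, params=truth_params, seed=5)
        a = simulate_dataset(config)
        b = simulate_dataset(config)
        assert np.array_equal(a.alleles, b.alleles)
        assert a.locus_ids == b.locus_ids

    def test_extending_L_preserves_earlier_loci(self, truth_params):
        short = simulate_dataset(
            SimulationConfig(n1=3, n2=3, L=100, params=truth_params, seed=5)
        )
        long = simulate_dataset(
            SimulationConfig(n1=3, n2=3, L=200, params=truth_params, seed=5)
        )
        k = short.n_loci
        assert long.locus_ids[:k] == short.locus_ids
        assert np.array_equal(long.alleles[:k], short.alleles)

    def test_pairwise_diversity_matches_theta(self, rng):
        # E[pi] = theta per locus in the panmictic limit, before thinning
        # bias matters (one SNP per locus, small theta). Uses 3000 loci.
        p = SplitMigParams(nu1=1.0, nu2=1.0, T=1e-12, m=1.0)
        theta = 0.02
        ds = simulate_dataset(
            SimulationConfig(n1=3, n2=3, L=3000, params=p, theta_locus=theta, seed=21)
        )
        h = ds.alleles.shape[1]
        d = ds.alleles.sum(axis=1)
        # pi per attempted locus: variable loci only contribute
        pi = (2.0 * d * (h - d) / (h * (h - 1))).sum() / 3000
        # MC error: binomial-ish over loci
        se = np.sqrt((2.0 * d * (h - d) / (h * (h - 1))).var() * ds.n_loci) / 3000
        assert abs(pi - theta) < 4 * se


class TestVcfRoundTrip:
    def test_round_trip_identity(self, small_dataset, tmp_path):
        vcf = tmp_path / "ds.vcf"
        popmap = tmp_path / "ds.popmap"
        write_vcf(small_dataset, vcf)
        write_popmap(small_dataset, popmap)
        back = read_vcf(vcf, read_popmap(popmap))
        assert np.array_equal(back.alleles, small_dataset.alleles)
        assert back.sample_ids == small_dataset.sample_ids
        assert back.sample_pops == small_dataset.sample_pops

    def test_missing_genotype_rejected(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=2>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "c1\t1\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t./.\n"
        )
        with pytest.raises(ValueError, match="missing GT"):
            read_vcf(vcf, {"a": "p1", "b": "p2"})

    def test_unphased_genotype_rejected(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=2>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "c1\t1\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t0/1\n"
        )
        with pytest.raises(ValueError, match="unphased"):
            read_vcf(vcf, {"a": "p1", "b": "p2"})

    def test_sample_absent_from_popmap_rejected(self, small_dataset, tmp_path):
        vcf = tmp_path / "ds.vcf"
        write_vcf(small_dataset, vcf)
        with pytest.raises(ValueError, match="absent"):
            read_vcf(vcf, {"pop1_ind00": "p1"})

    def test_handcrafted_vcf_sfs_matches_hand_count(self, tmp_path):
        # 3 loci, 2+2 individuals; derived counts per pop hand-counted:
        # locus1: pop1 (1,0)=1 copy, pop2 0; locus2: pop1 2, pop2 1;
        # locus3: pop1 0, pop2 3.
        vcf = tmp_path / "hand.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=l1,length=2>\n##contig=<ID=l2,length=2>\n"
            "##contig=<ID=l3,length=2>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            "a1\ta2\tb1\tb2\n"
            "l1\t1\t.\tA\tT\t.\tPASS\t.\tGT\t1|0\t0|0\t0|0\t0|0\n"
            "l2\t1\t.\tA\tT\t.\tPASS\t.\tGT\t1|1\t0|0\t0|1\t0|0\n"
            "l3\t1\t.\tA\tT\t.\tPASS\t.\tGT\t0|0\t0|0\t1|1\t1|0\n"
        )
        ds = read_vcf(vcf, {"a1": "p1", "a2": "p1", "b1": "p2", "b2": "p2"})
        sfs = build_joint_sfs(ds, polarized=True)
        expected = np.zeros((5, 5))
        expected[1, 0] = 1
        expected[2, 1] = 1
        expected[0, 3] = 1
        assert np.array_equal(sfs.values, expected)
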