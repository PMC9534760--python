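"""GENEPOP I/O and Weir–Cockerham theta."""

import numpy as np
import pytest

from oracles import dataset_components_bruteforce
from conftest import fixed_two_pop_dataset

from thermocline import (
    GenotypeDataset,
    bootstrap_fst_ci,
    jackknife_fst_ci,
    multilocus_theta,
    pairwise_fst,
    read_genepop,
    simulate_genotypes,
    wc_theta_locus,
    write_genepop,
    SimulationConfig,
)
from thermocline.popgen import GenepopFormatError, NoVariationError, _all_components


class TestGenepopIO:
    def test_minimal_two_pop_file(self, tmp_path):
        path = tmp_path / "mini.gen"
        path.write_text(
            "mini\nloc1\nPOP\na1 , 0101\na2 , 0102\nPOP\nb1 , 0202\nb2 , 0202\n"
        )
        ds = read_genepop(path)
        assert ds.n_populations == 2
        assert ds.loci == ["loc1"]
        assert set(np.unique(ds.calls)) == {1, 2}

    def test_missing_token_is_missing_call(self, genepop_file):
        ds = read_genepop(genepop_file)
        i = ds.individual_ids.index("up-04")
        assert tuple(ds.calls[i, 2]) == (0, 0)

    def test_population_labels_follow_last_id_convention(self, fixture_dataset):
        assert fixture_dataset.populations == ["upstream", "midstream", "downstream"]

    def test_mixed_token_widths_rejected(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("bad\nloc1\nPOP\na1 , 0101\na2 , 001001\n")
        with pytest.raises(GenepopFormatError, match="token lengths"):
            read_genepop(path)

    def test_odd_length_token_rejected(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("bad\nloc1\nPOP\na1 , 010\n")
        with pytest.raises(GenepopFormatError, match="odd"):
            read_genepop(path)

    def test_missing_pop_section_rejected(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("bad\nloc1\na1 , 0101\n")
        with pytest.raises(GenepopFormatError, match="POP"):
            read_genepop(path)

    def test_write_read_round_trip(self, tmp_path, small_config):
        ds = simulate_genotypes(small_config)
        path = tmp_path / "sim.gen"
        write_genepop(ds, path)
        back = read_genepop(path, pop_names=ds.populations)
        assert back.populations == ds.populations
        assert back.loci == ds.loci
        assert back.individual_ids == ds.individual_ids
        np.testing.assert_array_equal(back.calls, ds.calls)


class TestThetaLocus:
    def test_complete_fixation_gives_one(self):
        ds = fixed_two_pop_dataset(n=10)
        a, b, c = wc_theta_locus(ds, "L1")
        assert a / (a + b + c) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 23])
    def test_fixation_at_any_sample_size(self, n):
        ds = fixed_two_pop_dataset(n=n)
        assert multilocus_theta(ds) == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_population_all_heterozygous(self):
        # one panmictic unit split in two labels: unbiasedness permits a <= 0
        calls = np.tile(np.array([[1, 2]]), (12, 1)).reshape(12, 1, 2)
        ds = GenotypeDataset(
            populations=["X", "Y"],
            loci=["L1"],
            individual_ids=[f"i{k}" for k in range(12)],
            pop_index=np.repeat([0, 1], 6),
            calls=calls,
        )
        a, b, c = wc_theta_locus(ds, "L1")
        assert a <= 0.0

    def test_components_match_bruteforce_oracle(self, fixture_dataset):
        oracle = dataset_components_bruteforce(fixture_dataset)
        for locus in fixture_dataset.loci:
            got = wc_theta_locus(fixture_dataset, locus)
            assert got == pytest.approx(oracle[locus], abs=1e-12)

    def test_monomorphic_locus_zero_components(self):
        calls = np.ones((8, 1, 2), dtype=np.int64)
        ds = GenotypeDataset(
            populations=["A", "B"], loci=["L1"],
            individual_ids=[f"i{k}" for k in range(8)],
            pop_index=np.repeat([0, 1], 4), calls=calls,
        )
        assert wc_theta_locus(ds, "L1") == (0.0, 0.0, 0.0)
        with pytest.raises(NoVariationError):
            multilocus_theta(ds)


class TestMultilocus:
    def test_single_locus_reduces_to_locus_ratio(self, fixture_dataset):
        a, b, c = wc_theta_locus(fixture_dataset, "locA")
        sub = GenotypeDataset(
            populations=fixture_dataset.populations,
            loci=["locA"],
            individual_ids=fixture_dataset.individual_ids,
            pop_index=fixture_dataset.pop_index,
            calls=fixture_dataset.calls[:, :1, :],
        )
        assert multilocus_theta(sub) == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_invariant_to_individual_order(self, fixture_dataset):
        theta = multilocus_theta(fixture_dataset)
        rng = np.random.default_rng(0)
        perm = rng.permutation(fixture_dataset.n_individuals)
        shuffled = GenotypeDataset(
            populations=fixture_dataset.populations,
            loci=fixture_dataset.loci,
            individual_ids=[fixture_dataset.individual_ids[i] for i in perm],
            pop_index=fixture_dataset.pop_index[perm],
            calls=fixture_dataset.calls[perm],
        )
        assert multilocus_theta(shuffled) == pytest.approx(theta, abs=1e-12)

    def test_invariant_to_allele_relabeling_and_locus_order(self, fixture_dataset):
        theta = multilocus_theta(fixture_dataset)
        relabel = {0: 0, 1: 7, 2: 4, 3: 9}
        calls = np.vectorize(relabel.get)(fixture_dataset.calls)
        order = [2, 0, 1]
        ds = GenotypeDataset(
            populations=fixture_dataset.populations,
            loci=[fixture_dataset.loci[i] for i in order],
            individual_ids=fixture_dataset.individual_ids,
            pop_index=fixture_dataset.pop_index,
            calls=calls[:, order, :],
        )
        assert multilocus_theta(ds) == pytest.approx(theta, abs=1e-12)


class TestPairwise:
    def test_two_pops_reduces_to_global(self, fixture_dataset):
        sub = fixture_dataset.subset_populations(["upstream", "midstream"])
        mat = pairwise_fst(sub)
        assert mat.iloc[0, 1] == pytest.approx(multilocus_theta(sub), abs=1e-12)

    def test_symmetric_zero_diagonal(self, fixture_dataset):
        mat = pairwise_fst(fixture_dataset)
        np.testing.assert_array_equal(mat.to_numpy(), mat.to_numpy().T)
        assert (np.diag(mat.to_numpy()) == 0).all()

    def test_excluding_population_leaves_other_pairs(self, fixture_dataset):
        full = pairwise_fst(fixture_dataset)
        sub = pairwise_fst(fixture_dataset.subset_populations(["upstream", "midstream"]))
        assert sub.loc["upstream", "midstream"] == pytest.approx(
            full.loc["upstream", "midstream"], abs=1e-12
        )

    def test_identical_frequency_pair_closest_to_zero(self):
        # pops A and B drawn from the same frequencies, C strongly diverged
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fAB = np.array([0.5, 0.3, 0.2])
            fC = np.array([0.05, 0.05, 0.9])
            calls = np.zeros((60, 2, 2), dtype=np.int64)
            for li in range(2):
                for p, f in enumerate([fAB, fAB, fC]):
                    calls[p * 20:(p + 1) * 20, li, :] = (
                        rng.choice(3, size=(20, 2), p=f) + 1
                    )
            ds = GenotypeDataset(
                populations=["A", "B", "C"], loci=["L1", "L2"],
                individual_ids=[f"i{k}" for k in range(60)],
                pop_index=np.repeat([0, 1, 2], 20), calls=calls,
            )
            mat = pairwise_fst(ds)
            ab = abs(mat.loc["A", "B"])
            if ab < abs(mat.loc["A", "C"]) and ab < abs(mat.loc["B", "C"]):
                hits += 1
        assert hits >= 40  # expectation: the null pair is closest almost always


class TestBootstrapCI:
    def test_identical_loci_collapse_ci(self):
        base = fixed_two_pop_dataset(n=6)
        calls = np.repeat(base.calls, 4, axis=1)
        ds = GenotypeDataset(
            populations=base.populations, loci=[f"L{k}" for k in range(4)],
            individual_ids=base.individual_ids, pop_index=base.pop_index,
            calls=calls,
        )
        lo, hi = bootstrap_fst_ci(ds, n_boot=300, seed=1)
        theta = multilocus_theta(ds)
        assert lo == pytest.approx(theta, abs=1e-12)
        assert hi == pytest.approx(theta, abs=1e-12)

    def test_seed_determinism(self, small_config):
        ds = simulate_genotypes(small_config)
        assert bootstrap_fst_ci(ds, 500, seed=3) == bootstrap_fst_ci(ds, 500, seed=3)

    def test_matches_independent_resampling_oracle(self, small_config):
        ds = simulate_genotypes(small_config)
        n_boot, seed = 500, 9
        lo, hi = bootstrap_fst_ci(ds, n_boot=n_boot, seed=seed)
        comps = np.array(
            [dataset_components_bruteforce(ds)[l] for l in ds.loci]
        )
        rng = np.random.default_rng(seed)  # same documented seed stream
        idx = rng.integers(0, len(ds.loci), size=(n_boot, len(ds.loci)))
        thetas = comps[idx, 0].sum(axis=1) / comps[idx, :].sum(axis=(1, 2))
        olo, ohi = np.percentile(thetas, [2.5, 97.5])
        assert lo == pytest.approx(olo, abs=1e-12)
        assert hi == pytest.approx(ohi, abs=1e-12)

    def test_jackknife_brackets_point(self, small_config):
        ds = simulate_genotypes(small_config)
        lo, hi = jackknife_fst_ci(ds)
        assert lo < multilocus_theta(ds) < hi
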