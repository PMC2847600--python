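import dendropy
import numpy as np
import pytest

from delimix.sim import (
    DemeTree,
    LocusSpec,
    SimulationConfig,
    SimulationError,
    concatenate_alignments,
    simulate_dataset,
    simulate_genealogy,
    sprinkle_mutations,
)


def one_deme_config(n=4, ne=100.0, seed=0, mu=0.0, length=100):
    return SimulationConfig(
        deme_tree=DemeTree.single("D1"),
        deme_sizes={"D1": ne},
        loci=[LocusSpec("L", ploidy=1, inheritance="biparental",
                        ne_multiplier=1.0, length=length, mutation_rate=mu)],
        samples_per_locality=n,
        locality_to_deme={"D1": "D1"},
        seed=seed,
    )


class TestGenealogy:
    def test_mean_tmrca_matches_kingman_expectation(self):
        """E[TMRCA] = 4 N (1 - 1/n) on the locus scale: n=4, Ne_locus=100
        gives 300 generations; Monte-Carlo mean within 10%."""
        cfg = one_deme_config()
        vals = [
            simulate_genealogy(cfg, cfg.loci[0], np.random.default_rng(i)).tmrca
            for i in range(2000)
        ]
        assert abs(np.mean(vals) - 300.0) / 300.0 < 0.10

    def test_genealogy_is_ultrametric(self):
        cfg = one_deme_config(n=6, seed=3)
        gen = simulate_genealogy(cfg, cfg.loci[0])
        depths = [
            sum(e.length for e in lf.ancestor_iter() if False) or
            lf.distance_from_root()
            for lf in gen.tree.leaf_node_iter()
        ]
        assert np.allclose(depths, depths[0], atol=1e-6)

    def test_isolated_demes_never_coalesce(self):
        cfg = SimulationConfig(
            deme_tree=DemeTree([("D1", "D2", "R", 1e9)]),
            deme_sizes={"D1": 100.0, "D2": 100.0, "R": 100.0},
            loci=[LocusSpec("L", ploidy=1, inheritance="biparental",
                            ne_multiplier=1.0)],
            samples_per_locality=2,
            seed=0,
        )
        with pytest.raises(SimulationError, match="no coalescence"):
            simulate_genealogy(cfg, cfg.loci[0])

    def test_zero_size_deme_named_in_error(self):
        with pytest.raises(SimulationError, match="D1"):
            one_deme_config(ne=0.0)

    def test_full_sex_bias_blocks_maternal_migration(self):
        cfg = SimulationConfig(
            deme_tree=DemeTree([("D1", "D2", "R", 5000.0)]),
            deme_sizes={"D1": 100.0, "D2": 100.0, "R": 100.0},
            loci=[
                LocusSpec("mt", ploidy=1, inheritance="maternal"),
                LocusSpec("nuc", ploidy=2, inheritance="biparental"),
            ],
            samples_per_locality=5,
            migration={("D1", "D2"): 0.05, ("D2", "D1"): 0.05},
            sex_bias=1.0,
            seed=4,
        )
        mt = simulate_genealogy(cfg, cfg.loci[0])
        nuc = simulate_genealogy(cfg, cfg.loci[1])
        assert mt.n_migrations == 0
        assert nuc.n_migrations > 0

    def test_deep_split_yields_reciprocal_monophyly(self):
        """Two demes split 10 N generations ago, no migration: the mtDNA
        genealogy shows reciprocal monophyly in > 95% of replicates."""
        wins = 0
        n_rep = 100
        for r in range(n_rep):
            cfg = SimulationConfig(
                deme_tree=DemeTree([("D1", "D2", "R", 2000.0)]),
                deme_sizes={"D1": 200.0, "D2": 200.0, "R": 200.0},
                loci=[LocusSpec("mt", ploidy=1, inheritance="maternal")],
                samples_per_locality=5,
                seed=r,
            )
            gen = simulate_genealogy(cfg, cfg.loci[0])
            ok = True
            for deme in ("D1", "D2"):
                tips = {f"{deme}_{i:02d}" for i in range(5)}
                mrca = gen.tree.mrca(taxon_labels=tips)
                clade = {lf.taxon.label for lf in mrca.leaf_iter()}
                ok = ok and clade == tips
            wins += ok
        assert wins / n_rep > 0.95

    def test_maternal_locus_requires_haploidy(self):
        with pytest.raises(ValueError, match="maternal"):
            LocusSpec("mt", ploidy=2, inheritance="maternal")

    def test_unknown_deme_in_locality_map(self):
        with pytest.raises(ValueError, match="unknown deme"):
            SimulationConfig(
                deme_tree=DemeTree.single("D1"),
                deme_sizes={"D1": 50.0},
                loci=[LocusSpec("L")],
                locality_to_deme={"loc": "NOPE"},
            )


class TestMutations:
    def test_zero_rate_gives_identical_sequences(self):
        cfg = one_deme_config(n=5, mu=0.0, seed=1)
        gen = simulate_genealogy(cfg, cfg.loci[0])
        aln = sprinkle_mutations(gen, cfg.loci[0], np.random.default_rng(0))
        assert len(set(aln.sequences)) == 1

    def test_mutation_count_matches_poisson_mean(self):
        """Pairwise differences on a two-branch genealogy approximate the
        Poisson mean mu * length * branch length within 5% over 1000 reps."""
        length = 20000
        spec = LocusSpec("L", ploidy=1, inheritance="biparental",
                         length=length, mutation_rate=1e-7)
        nwk = "(a:2500,b:2500);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tree.is_rooted = True
        expected = 2 * 1e-7 * length * 2500  # = 10 over both branches;
        # at ~10 hits on 20000 sites multiple hits are negligible, so the
        # pairwise difference count tracks the Poisson mutation count
        rng = np.random.default_rng(0)
        counts = []
        for _ in range(1000):
            aln = sprinkle_mutations(tree, spec, rng)
            a, b = aln.sequences
            counts.append(sum(x != y for x, y in zip(a, b)))
        # finite-sites collisions shave a little off the observable count
        assert abs(np.mean(counts) - expected) / expected < 0.05

    def test_single_branch_mutation_separates_clade(self):
        """A mutation on the branch subtending a clade separates exactly
        that clade at exactly one site."""
        spec = LocusSpec("L", ploidy=1, inheritance="biparental",
                         length=500, mutation_rate=0.0)
        tree = dendropy.Tree.get(
            data="((a:1,b:1):5,(c:1,d:1):5);", schema="newick"
        )
        tree.is_rooted = True
        # rate 0 everywhere, then force one mutation by using a spec with a
        # rate tuned so the expected count on the long branch is ~1 while
        # short branches stay clean is stochastic; instead compare pattern:
        spec_hot = LocusSpec("L", ploidy=1, inheritance="biparental",
                             length=500, mutation_rate=0.0004)
        # branch of length 5 -> mean 1.0 mutation; length 1 -> mean 0.2
        for seed in range(50):
            aln = sprinkle_mutations(tree, spec_hot, np.random.default_rng(seed))
            seqs = dict(zip(aln.copy_ids, aln.sequences))
            diff_ab = sum(x != y for x, y in zip(seqs["a"], seqs["b"]))
            diff_ac = sum(x != y for x, y in zip(seqs["a"], seqs["c"]))
            if diff_ab == 0 and seqs["c"] == seqs["d"] and diff_ac == 1:
                # the only change is a single fixed difference between clades
                return
        pytest.fail("never observed the single-clade-mutation pattern")


class TestDataset:
    def test_reproducible_from_seed(self):
        cfg1 = one_deme_config(n=5, mu=1e-4, seed=9)
        cfg2 = one_deme_config(n=5, mu=1e-4, seed=9)
        d1 = simulate_dataset(cfg1)
        d2 = simulate_dataset(cfg2)
        assert d1.alignments["L"].sequences == d2.alignments["L"].sequences

    def test_adding_locus_does_not_perturb_others(self):
        cfg1 = one_deme_config(n=5, mu=1e-4, seed=9)
        cfg2 = one_deme_config(n=5, mu=1e-4, seed=9)
        cfg2.loci.append(LocusSpec("extra", ploidy=2))
        d1 = simulate_dataset(cfg1)
        d2 = simulate_dataset(cfg2)
        assert d1.alignments["L"].sequences == d2.alignments["L"].sequences

    def test_namespace_closure_and_ploidy(self):
        cfg = SimulationConfig(
            deme_tree=DemeTree([("D1", "D2", "R", 1000.0)]),
            deme_sizes={"D1": 100.0, "D2": 100.0, "R": 100.0},
            loci=[
                LocusSpec("mt", ploidy=1, inheritance="maternal",
                          mutation_rate=1e-5),
                LocusSpec("n1", ploidy=2, mutation_rate=1e-5),
            ],
            samples_per_locality=3,
            seed=2,
        )
        ds = simulate_dataset(cfg)
        inds = set(cfg.individuals())
        assert set(ds.alignments["mt"].copy_ids) == inds
        assert set(ds.alignments["n1"].copy_ids) == {
            f"{i}_{s}" for i in inds for s in "ab"
        }
        assert set(ds.truth.individual_to_deme) == inds

    def test_watterson_recovers_configured_theta(self):
        """Watterson's estimator S / a_n over 1000 replicates is within
        10% of the configured theta.

        With pair-coalescence rate 1/(2 Ne_locus), E[T2] = 2 Ne_locus and
        both lineages mutate, so theta = 4 Ne_locus mu L = 4 here.
        """
        from delimix.popgen import count_variable_sites

        theta = 4 * 100.0 * 1e-5 * 1000  # = 4
        a_n = sum(1.0 / i for i in range(1, 10))
        est = []
        for seed in range(1000):
            cfg = one_deme_config(n=10, ne=100.0, mu=1e-5, length=1000,
                                  seed=seed)
            ds = simulate_dataset(cfg)
            est.append(count_variable_sites(ds.alignments["L"]) / a_n)
        assert abs(np.mean(est) - theta) / theta < 0.10

    def test_concatenation_mirrors_mtdna_regions(self):
        cfg = SimulationConfig(
            deme_tree=DemeTree.single("D1"),
            deme_sizes={"D1": 50.0},
            loci=[
                LocusSpec("cox2", ploidy=1, inheritance="maternal",
                          length=100, mutation_rate=1e-4),
                LocusSpec("cob", ploidy=1, inheritance="maternal",
                          length=150, mutation_rate=1e-4),
            ],
            samples_per_locality=4,
            locality_to_deme={"D1": "D1"},
            seed=5,
        )
        ds = simulate_dataset(cfg)
        cat = concatenate_alignments(
            [ds.alignments["cox2"], ds.alignments["cob"]]
        )
        assert cat.length == 250
        assert set(cat.copy_ids) == set(ds.alignments["cox2"].copy_ids)


class TestNullCalibration:
    def test_single_deme_gsi_p_uniform(self):
        """With one panmictic deme, any locality grouping is arbitrary:
        gsi permutation p-values on the true genealogies are uniform
        (KS at the 1% level over 200 replicates)."""
        from scipy import stats as sps

        from delimix.gsi import gsi_permutation_p

        pvals = []
        for seed in range(200):
            cfg = SimulationConfig(
                deme_tree=DemeTree.single("D1"),
                deme_sizes={"D1": 100.0},
                loci=[LocusSpec("L", ploidy=1, inheritance="biparental",
                                ne_multiplier=1.0)],
                samples_per_locality=5,
                locality_to_deme={"locA": "D1", "locB": "D1"},
                seed=seed,
            )
            gen = simulate_genealogy(cfg, cfg.loci[0])
            group = {f"locA_{i:02d}" for i in range(5)}
            _, p = gsi_permutation_p(gen.tree, group, n_perm=100, seed=seed)
            pvals.append(p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
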