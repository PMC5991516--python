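"""Heterozygosity, d_xy, SNP partitioning, joint SFS and LD thinning."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from rhinopop.diversity import (
    PopulationPanel,
    individual_heterozygosity,
    joint_sfs,
    ld_thin,
    pairwise_divergence,
    partition_snps,
)
from rhinopop.simulate import simulate_coalescent_window
from rhinopop.variants import VariantTable

from conftest import NAN, build_table, random_table, snp


def two_pop_panel(samples, n1):
    return PopulationPanel(
        {s: ("p1" if i < n1 else "p2") for i, s in enumerate(samples)}
    )


class TestHeterozygosity:
    def test_simple_proportion(self):
        rows = [snp("sc", 10 * (i + 1), [(0, 1), (0, 0)]) for i in range(5)]
        t = build_table(["a", "b"], {"sc": 10_000}, rows)
        r = individual_heterozygosity(t, 10_000)
        assert r.per_sample["a"] == pytest.approx(0.0005)
        assert r.per_sample["b"] == 0.0

    def test_denominator_too_small(self):
        t = build_table(["a"], {"sc": 100}, [snp("sc", 1, [(0, 1)]),
                                             snp("sc", 2, [(0, 1)])])
        with pytest.raises(ValueError):
            individual_heterozygosity(t, 1)

    def test_invariant_to_order_and_invariant_sites(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, n_samples=3, n_sites=40)
        base = individual_heterozygosity(t, 50_000).per_sample
        # shuffle record order; the constructor re-sorts, values identical
        perm = rng.permutation(t.n_records)
        shuffled = t.take(perm)
        assert individual_heterozygosity(shuffled, 50_000).per_sample == base
        # appending invariant (hom-ref) sites changes nothing at fixed denominator
        extra = build_table(
            t.samples, t.scaffold_lengths,
            [snp("sc1", 149_999, [(0, 0)] * 3), snp("sc1", 149_998, [(0, 0)] * 3)],
        )
        merged = build_table(
            t.samples, t.scaffold_lengths,
            [
                (str(tab.scaffolds[i]), int(tab.pos[i]), str(tab.ref[i]),
                 tab.alts[i], tab.qual[i], tab.ranksum_p[i],
                 tab.alt_support[i], tab.genotypes[i])
                for tab in (t, extra) for i in range(tab.n_records)
            ],
        )
        assert individual_heterozygosity(merged, 50_000).per_sample == base

    def test_population_means(self, small_sim, small_panel):
        _, table, _ = small_sim
        r = individual_heterozygosity(table, panel=small_panel)
        for pop in small_panel.populations:
            members = small_panel.members(pop)
            assert r.population_means[pop] == pytest.approx(
                np.mean([r.per_sample[s] for s in members])
            )


class TestDivergence:
    def test_identical_homozygous_samples(self):
        # identity in the homozygous sense; a shared heterozygous site still
        # contributes 0.5 expected allele differences per draw
        rows = [snp("sc", 10, [(0, 0), (0, 0)]), snp("sc", 20, [(1, 1), (1, 1)])]
        t = build_table(["a", "b"], {"sc": 1000}, rows)
        r = pairwise_divergence(t, two_pop_panel(t.samples, 1), 1000)
        assert r.dxy == 0.0

    def test_one_fixed_difference(self):
        t = build_table(["a", "b"], {"sc": 1000}, [snp("sc", 10, [(0, 0), (1, 1)])])
        r = pairwise_divergence(t, two_pop_panel(t.samples, 1), 1000)
        assert r.dxy == pytest.approx(0.001)
        assert r.n_pairs == 1

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        t = random_table(rng, n_samples=5, n_sites=60, missing_rate=0.1)
        panel = two_pop_panel(t.samples, 3)
        denom = 200_000
        r = pairwise_divergence(t, panel, denom)
        # exhaustive per-pair per-site reference
        total = 0.0
        n_pairs = 0
        for a in range(3):
            for b in range(3, 5):
                acc = 0.0
                for i in range(t.n_records):
                    ga, gb = t.genotypes[i, a], t.genotypes[i, b]
                    if (ga < 0).any() or (gb < 0).any():
                        continue
                    pa, pb = (ga > 0).sum() / 2, (gb > 0).sum() / 2
                    acc += pa * (1 - pb) + pb * (1 - pa)
                total += acc / denom
                n_pairs += 1
        assert r.dxy == pytest.approx(total / n_pairs, abs=1e-12)


class TestPartition:
    def test_definitions(self):
        # p1 = a,b (4 alleles); p2 = c,d (4 alleles)
        rows = [
            snp("sc", 10, [(0, 1), (0, 1), (0, 1), (0, 0)]),  # f=.5 / .25 shared
            snp("sc", 20, [(1, 1), (1, 1), (1, 1), (1, 1)]),  # fixed both
            snp("sc", 30, [(0, 1), (0, 0), (0, 0), (0, 0)]),  # unique p1
            snp("sc", 40, [(0, 0), (0, 0), (1, 1), (1, 1)]),  # unique p2 (fixed)
            snp("sc", 50, [(1, 1), (1, 1), (0, 1), (0, 0)]),  # fixed p1 / poly p2
            snp("sc", 60, [(0, 0), (0, 0), (0, 0), (0, 0)]),  # invariant
        ]
        t = build_table(["a", "b", "c", "d"], {"sc": 1000}, rows)
        part = partition_snps(t, two_pop_panel(t.samples, 2))
        assert part.shared_polymorphic == 1
        assert part.fixed_both == 1
        assert part.unique == {"p1": 1, "p2": 1}
        assert part.fixed_one_polymorphic_other == 1
        assert part.invariant_total == 1
        assert part.skipped == 0

    def test_hand_tally_20_sites(self):
        """Frozen classification of a 20-site fixture built from known
        genotype patterns (tallied by hand from the rows below)."""
        patterns = {
            "shared": [(0, 1), (0, 0), (0, 1), (1, 1)],
            "fixed_both": [(1, 1)] * 4,
            "uniq1": [(1, 1), (0, 1), (0, 0), (0, 0)],
            "uniq2": [(0, 0), (0, 0), (0, 1), (0, 1)],
            "invariant": [(0, 0)] * 4,
        }
        plan = (["shared"] * 6 + ["fixed_both"] * 3 + ["uniq1"] * 4
                + ["uniq2"] * 5 + ["invariant"] * 2)
        rows = [snp("sc", 10 * (i + 1), patterns[k]) for i, k in enumerate(plan)]
        t = build_table(["a", "b", "c", "d"], {"sc": 1000}, rows)
        part = partition_snps(t, two_pop_panel(t.samples, 2))
        assert (part.shared_polymorphic, part.fixed_both,
                part.unique["p1"], part.unique["p2"],
                part.invariant_total) == (6, 3, 4, 5, 2)

    def test_all_missing_population_skipped(self):
        rows = [snp("sc", 10, [(0, 1), (-1, -1)])]
        t = build_table(["a", "b"], {"sc": 1000}, rows)
        part = partition_snps(t, two_pop_panel(t.samples, 1))
        assert part.skipped == 1 and part.total_classified == 0

    def test_mece_on_fixture(self, small_sim, small_panel):
        _, table, _ = small_sim
        part = partition_snps(table, small_panel)
        assert part.total_classified + part.skipped == table.n_records


class TestJointSFS:
    def test_single_site(self):
        rows = [snp("sc", 10, [(0, 1), (0, 0), (1, 1)])]
        t = build_table(["a", "b", "c"], {"sc": 1000}, rows)
        sfs = joint_sfs(t, two_pop_panel(t.samples, 2))
        assert sfs.counts[1][2] == 1 and sfs.total == 1

    def test_no_segregating_sites(self):
        rows = [snp("sc", 10 * (i + 1), [(0, 0), (0, 0)]) for i in range(4)]
        t = build_table(["a", "b"], {"sc": 1000}, rows)
        sfs = joint_sfs(t, two_pop_panel(t.samples, 1))
        assert sfs.counts[0][0] == 4

    def test_unknown_subset_sample(self, small_sim, small_panel):
        _, table, _ = small_sim
        with pytest.raises(KeyError):
            joint_sfs(table, small_panel, subset=["nobody"])

    def test_conservation(self, small_sim, small_panel):
        _, table, _ = small_sim
        sfs = joint_sfs(table, small_panel)
        assert sfs.total + sfs.n_skipped == table.n_records

    def test_fold_preserves_total(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, n_samples=4, n_sites=50)
        sfs = joint_sfs(t, two_pop_panel(t.samples, 2))
        assert sfs.folded().sum() == pytest.approx(sfs.total)

    def test_neutral_marginal_spectrum(self):
        """Over many neutral coalescent windows the marginal expected count
        at derived-allele frequency i is theta/i.  Class counts within one
        window share a genealogy (overdispersed vs multinomial), so each
        class mean is tested against theta/i with its empirical Monte-Carlo
        standard error rather than a plain chi-square."""
        rng = np.random.default_rng(2024)
        n_dip1, n_dip2, theta, n_windows = 5, 1, 3.0, 2000
        n_hap = 2 * (n_dip1 + n_dip2)
        samples = [f"s{i}" for i in range(n_dip1 + n_dip2)]
        panel = two_pop_panel(samples, n_dip1)
        per_window = np.zeros((n_windows, 2 * n_dip1 + 1))
        for w in range(n_windows):
            haps = simulate_coalescent_window(n_hap, theta, rng)
            if haps.shape[1] == 0:
                continue
            genotypes = haps.reshape(n_dip1 + n_dip2, 2, -1).transpose(2, 0, 1)
            rows = [
                ("sc", j + 1, "A", ("G",), 50.0, NAN, NAN, genotypes[j])
                for j in range(genotypes.shape[0])
            ]
            t = build_table(samples, {"sc": 10_000}, rows)
            per_window[w] = joint_sfs(t, panel).marginal(1)
        for i in range(1, 2 * n_dip1):
            obs = per_window[:, i]
            se = obs.std(ddof=1) / np.sqrt(n_windows)
            assert abs(obs.mean() - theta / i) <= 4 * se, f"class {i}"


class TestLDThin:
    def _table_from_dosages(self, dosages):
        """dosages: (n_sites, n_samples) 0/1/2 matrix."""
        dosages = np.asarray(dosages)
        genos = np.stack([(dosages == 2), (dosages >= 1)], axis=2).astype(np.int8)
        samples = [f"s{i}" for i in range(dosages.shape[1])]
        rows = [
            ("sc", 100 * (i + 1), "A", ("G",), 50.0, NAN, NAN, genos[i])
            for i in range(dosages.shape[0])
        ]
        return build_table(samples, {"sc": 1_000_000}, rows)

    def test_perfectly_correlated_pair(self):
        d = np.array([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0]])
        t = self._table_from_dosages(d)
        out = ld_thin(t, window_snps=5, step_snps=2)
        assert out.n_records == 1 and out.pos[0] == 100  # later SNP removed

    def test_uncorrelated_unchanged(self):
        d = np.array([[0, 0, 1, 1], [0, 1, 0, 1], [1, 1, 1, 1]])  # r2=0 pairs
        t = self._table_from_dosages(d)
        out = ld_thin(t, window_snps=3, step_snps=1)
        assert out.n_records == 3

    def test_monomorphic_treated_as_zero(self):
        d = np.array([[1, 1, 1, 1], [0, 1, 2, 1]])
        t = self._table_from_dosages(d)
        assert ld_thin(t, window_snps=2, step_snps=1).n_records == 2

    def test_matches_independent_greedy_reference(self):
        rng = np.random.default_rng(99)
        # blocks of correlated SNPs: duplicate columns with noise
        base = rng.integers(0, 3, size=(40, 20))
        blocks = [base]
        for _ in range(4):
            noisy = base.copy()
            flip = rng.random(base.shape) < 0.1
            noisy[flip] = rng.integers(0, 3, size=int(flip.sum()))
            blocks.append(noisy)
        d = np.vstack(blocks)[rng.permutation(200)]
        t = self._table_from_dosages(d)
        out = ld_thin(t, window_snps=50, step_snps=10, r2_max=0.1)

        # independent reimplementation of the same greedy rule
        def r2(x, y):
            if x.var() == 0 or y.var() == 0:
                return 0.0
            return float(np.corrcoef(x, y)[0, 1] ** 2)

        dos = t.dosage()
        removed = set()
        start = 0
        while True:
            win = [i for i in range(start, min(start + 50, t.n_records))
                   if i not in removed]
            for ai, a in enumerate(win):
                if a in removed:
                    continue
                for b in win[ai + 1:]:
                    if b in removed:
                        continue
                    if r2(dos[a], dos[b]) > 0.1:
                        removed.add(b)
            if start + 50 >= t.n_records:
                break
            start += 10
        expected = [i for i in range(t.n_records) if i not in removed]
        assert out.pos.tolist() == t.pos[expected].tolist()
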