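"""Phylogeny construction: filter stack, exact tests, parsimony search,
maximum-likelihood assignment and branch scaling."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from clonarch.genome import GENOME_LENGTH
from clonarch.phylogeny import (
    GenotypeMatrix,
    binomial_enrichment_pvalue,
    binomial_two_sided_pvalue,
    build_parsimony_tree,
    assign_mutations_ml,
    exclude_cn_discordant,
    filter_confident_somewhere,
    filter_germline,
    filter_strand_imbalance,
    parsimony_placement,
    scale_branches,
)
from clonarch.simulate import (
    SimulationConfig,
    add_matched_normal,
    sample_biopsies,
    simulate_bulk_reads,
    simulate_copy_number,
    simulate_phylogeny,
)

from conftest import brute_force_parsimony, enumerate_lower_tail_pvalue, enumerate_two_sided_pvalue


# ---------------------------------------------------------------------------
# Exact binomial machinery
# ---------------------------------------------------------------------------


class TestExactBinomialPvalues:
    @pytest.mark.parametrize("k,n", [(0, 1), (1, 1), (0, 20), (10, 20), (7, 30), (20, 20), (15, 30)])
    def test_two_sided_matches_enumeration(self, k, n):
        expected = float(enumerate_two_sided_pvalue(k, n))
        assert binomial_two_sided_pvalue(k, n) == pytest.approx(expected, rel=1e-12)

    def test_strand_imbalance_20_0_equals_2_times_half_to_20(self):
        assert binomial_two_sided_pvalue(20, 20) == pytest.approx(2 * 0.5**20, rel=1e-12)

    def test_untestably_small_counts_give_p_one(self):
        assert binomial_two_sided_pvalue(1, 1) == 1.0
        assert binomial_two_sided_pvalue(0, 0) == 1.0

    def test_enrichment_tail_matches_enumeration(self):
        for k, n, p in [(0, 30, Fraction(1, 2)), (2, 40, Fraction(14, 30)), (15, 30, Fraction(1, 2))]:
            expected = float(enumerate_lower_tail_pvalue(k, n, p))
            got = binomial_enrichment_pvalue(k, n, float(p))
            assert got == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def _site(factory, normal, tumour, pos=1000):
    """One site observed in a matched normal and one tumour sample."""
    rows = []
    for sample, (alt, depth) in {"normal": normal, "t1": tumour}.items():
        rows.append(
            dict(pos=pos, sample=sample, depth=depth, alt_fwd=alt // 2, alt_rev=alt - alt // 2)
        )
    return factory(rows, sample_class={"normal": "normal", "t1": "tissue"})


class TestGermlineFilter:
    def test_heterozygous_germline_removed(self, variant_table_factory):
        t = _site(variant_table_factory, normal=(15, 30), tumour=(14, 30))
        out = filter_germline(t)
        assert out.n_sites == 0

    def test_absent_from_normal_retained(self, variant_table_factory):
        t = _site(variant_table_factory, normal=(0, 30), tumour=(12, 30))
        assert filter_germline(t).n_sites == 1

    def test_embryonic_mosaic_retained(self, variant_table_factory):
        """Low VAF in the normal, clonal in the tumour: kept by design."""
        t = _site(variant_table_factory, normal=(2, 40), tumour=(14, 30))
        assert filter_germline(t).n_sites == 1

    def test_missing_matched_normal_is_an_error(self, variant_table_factory):
        t = variant_table_factory([dict(alt_fwd=5, alt_rev=5)])
        with pytest.raises(ValueError):
            filter_germline(t)


class TestStrandImbalanceFilter:
    def test_near_symmetric_retained(self, variant_table_factory):
        t = variant_table_factory([dict(alt_fwd=8, alt_rev=7)])
        assert filter_strand_imbalance(t).n_sites == 1

    def test_fully_imbalanced_removed(self, variant_table_factory):
        t = variant_table_factory([dict(alt_fwd=20, alt_rev=0)])
        assert filter_strand_imbalance(t, alpha=0.01).n_sites == 0

    def test_single_read_untestable_hence_retained(self, variant_table_factory):
        t = variant_table_factory([dict(alt_fwd=1, alt_rev=0)])
        assert filter_strand_imbalance(t, alpha=0.01).n_sites == 1


class TestConfidentSomewhereFilter:
    def test_boundary_sample_4_of_12_both_strands_retained(self, variant_table_factory):
        t = variant_table_factory([dict(depth=12, alt_fwd=2, alt_rev=2)])
        assert filter_confident_somewhere(t).n_sites == 1

    def test_three_reads_insufficient(self, variant_table_factory):
        t = variant_table_factory([dict(depth=10, alt_fwd=2, alt_rev=1)])
        assert filter_confident_somewhere(t).n_sites == 0

    def test_single_strand_insufficient(self, variant_table_factory):
        t = variant_table_factory([dict(depth=12, alt_fwd=6, alt_rev=0)])
        assert filter_confident_somewhere(t).n_sites == 0

    def test_one_confident_sample_rescues_the_site(self, variant_table_factory):
        rows = [
            dict(pos=1000, sample="a", depth=30, alt_fwd=1, alt_rev=0),
            dict(pos=1000, sample="b", depth=30, alt_fwd=7, alt_rev=8),
        ]
        t = variant_table_factory(rows)
        assert filter_confident_somewhere(t).n_sites == 1


class TestCnDiscordantExclusion:
    def test_flat_diploid_genomes_exclude_nothing(self, variant_table_factory):
        t = variant_table_factory([dict(alt_fwd=5, alt_rev=5)])
        profile = simulate_copy_number(["s1", "s2"])
        out, fraction = exclude_cn_discordant(t, profile)
        assert fraction == 0.0 and out.n_sites == 1

    def test_discordant_segment_fraction_and_variant_removal(self, variant_table_factory):
        seg_len = int(round(0.04 * GENOME_LENGTH))
        profile = simulate_copy_number(
            ["s1", "s2"], overlays=[("s1", "1", 0, seg_len, 1)]
        )
        inside = variant_table_factory([dict(chrom="1", alt_fwd=5, alt_rev=5)])
        inside.df.loc[0, "pos"] = 500  # inside the discordant segment
        out, fraction = exclude_cn_discordant(inside, profile)
        assert fraction == pytest.approx(0.04, abs=1e-6)
        assert out.n_sites == 0

    def test_deletion_only_mode_reports_deleted_fraction(self, variant_table_factory):
        # deletions tiling 40% of the genome in one sample
        target = 0.40 * GENOME_LENGTH
        overlays, acc = [], 0
        from clonarch.genome import AUTOSOMES

        for chrom, length in AUTOSOMES:
            take = int(min(length, target - acc))
            if take <= 0:
                break
            overlays.append(("s1", chrom, 0, take, 1))
            acc += take
        profile = simulate_copy_number(["s1", "s2"], overlays=overlays)
        t = variant_table_factory([dict(chrom="22", alt_fwd=5, alt_rev=5)])
        out, fraction = exclude_cn_discordant(t, profile, mode="deletion_only")
        assert fraction == pytest.approx(0.40, abs=1e-6)

    def test_profile_gap_is_an_error(self, variant_table_factory):
        profile = simulate_copy_number(["s1"])
        profile.df = profile.df[profile.df["chrom"] != "22"]
        with pytest.raises(ValueError):
            exclude_cn_discordant(variant_table_factory([]), profile)


class TestFilterStackProperties:
    def _pipeline_table(self, seed):
        cfg = SimulationConfig(trunk_range=(15, 15), n_clones=6, private_mean=40.0, seed=seed)
        tree = simulate_phylogeny(cfg)
        b = sample_biopsies(tree, 8, 100, seed=seed)
        g = add_matched_normal(b, seed=seed)
        return simulate_bulk_reads(g, 30, 1.0, seed=seed)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_site_filters_commute(self, seed):
        t = self._pipeline_table(seed)
        profile = simulate_copy_number(sorted(set(t.df["sample"])))

        def order_a(x):
            x = filter_germline(x)
            x = filter_strand_imbalance(x)
            x = filter_confident_somewhere(x)
            return exclude_cn_discordant(x, profile)[0]

        def order_b(x):
            x = exclude_cn_discordant(x, profile)[0]
            x = filter_confident_somewhere(x)
            x = filter_germline(x)
            return filter_strand_imbalance(x)

        keys = lambda x: set(  # noqa: E731
            map(tuple, x.df[["chrom", "pos", "ref", "alt"]].drop_duplicates().to_numpy())
        )
        assert keys(order_a(t)) == keys(order_b(t))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_filters_idempotent(self, seed):
        t = self._pipeline_table(seed)
        for f in (filter_germline, filter_strand_imbalance, filter_confident_somewhere):
            once = f(t)
            assert f(once).df.equals(once.df)


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------


def _presence(mat, units=None):
    units = units or [f"u{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(np.asarray(mat, bool), index=units,
                        columns=[f"m{j}" for j in range(mat.shape[1])])


class TestParsimony:
    def test_perfect_phylogeny_score_equals_mutation_count(self):
        # nested, conflict-free characters: one change each
        mat = np.array(
            [
                [1, 1, 1, 0, 0],
                [1, 1, 0, 0, 0],
                [1, 0, 0, 1, 1],
                [1, 0, 0, 1, 0],
            ]
        )
        tree = build_parsimony_tree(_presence(mat))
        assert tree.parsimony_score == mat.shape[1]
        clades = {tree.clade(b) for b in tree.branches()}
        assert frozenset({"u0", "u1"}) in clades and frozenset({"u2", "u3"}) in clades

    def test_homoplasy_score_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(3, 6))
            mat = rng.integers(0, 2, size=(n, int(rng.integers(3, 10))))
            tree = build_parsimony_tree(_presence(mat))
            oracle = brute_force_parsimony(np.vstack([mat, np.zeros((1, mat.shape[1]), int)]))
            assert tree.parsimony_score == oracle

    def test_five_unit_instance_with_conflicting_characters(self):
        mat = np.array(
            [
                [1, 1, 1, 0],
                [1, 1, 0, 1],
                [1, 0, 1, 1],
                [0, 1, 1, 0],
                [0, 0, 0, 1],
            ]
        )
        tree = build_parsimony_tree(_presence(mat))
        oracle = brute_force_parsimony(np.vstack([mat, np.zeros((1, 4), int)]))
        assert tree.parsimony_score == oracle

    def test_heuristic_matches_exhaustive_on_eight_units(self):
        rng = np.random.default_rng(11)
        mat = rng.integers(0, 2, size=(8, 15))
        exact = build_parsimony_tree(_presence(mat), max_exhaustive=8)
        heuristic = build_parsimony_tree(_presence(mat), max_exhaustive=2)
        assert heuristic.parsimony_score >= exact.parsimony_score
        # the greedy + NNI search should land close for these sizes
        assert heuristic.parsimony_score <= exact.parsimony_score + 2

    def test_fewer_than_two_units_rejected(self):
        with pytest.raises(ValueError):
            build_parsimony_tree(_presence(np.array([[1, 0]])))

    def test_deterministic_result(self):
        mat = np.random.default_rng(3).integers(0, 2, size=(6, 12))
        a = build_parsimony_tree(_presence(mat))
        b = build_parsimony_tree(_presence(mat))
        assert a.newick(scaled=False) == b.newick(scaled=False)

    def test_comb_biopsies_reconstruct_star_with_trunk(self):
        cfg = SimulationConfig(trunk_range=(12, 12), n_clones=6, private_mean=60.0, seed=2)
        tree = simulate_phylogeny(cfg)
        b = sample_biopsies(tree, 7, 100, seed=2)
        vt = simulate_bulk_reads(b, 30, 1.0, seed=2)
        matrix = GenotypeMatrix.from_variant_table(vt)
        ptree = build_parsimony_tree(matrix)
        ptree = assign_mutations_ml(ptree, matrix)
        from clonarch.architecture import trunk_length

        assert abs(trunk_length(ptree) - 12) <= 2


# ---------------------------------------------------------------------------
# ML assignment and scaling
# ---------------------------------------------------------------------------


def _matrix(units, alt, depth, min_alt=4, min_vaf=0.3):
    alt = pd.DataFrame(alt, index=units)
    depth = pd.DataFrame(depth, index=units)
    vaf = alt / depth
    presence = (alt >= min_alt) & (vaf >= min_vaf)
    return GenotypeMatrix(presence=presence, alt=alt, depth=depth)


class TestMlAssignment:
    def _two_leaf_tree(self):
        mat = _presence(np.array([[1, 0], [0, 1]]), units=["A", "B"])
        return build_parsimony_tree(mat)

    def test_private_mutation_assigned_to_private_branch(self):
        tree = self._two_leaf_tree()
        m = _matrix(["A", "B"], {"m": [10, 0]}, {"m": [20, 22]})
        out = assign_mutations_ml(tree, m, purity=1.0, epsilon=1e-4)
        carrying = [b for b in out.branches() if out.nodes[b].mutations]
        assert len(carrying) == 1
        assert out.clade(carrying[0]) == frozenset({"A"})

    def test_brute_force_likelihood_agrees(self):
        """Recompute the three branch likelihoods by hand for the 10/20 vs
        0/22 case and check the argmax matches the assignment."""
        from scipy import stats

        tree = self._two_leaf_tree()
        m = _matrix(["A", "B"], {"m": [10, 0]}, {"m": [20, 22]})
        out = assign_mutations_ml(tree, m, purity=1.0, epsilon=1e-4)
        eps = 1e-4
        ll = {}
        for branch in tree.branches():
            clade = tree.clade(branch)
            pa = 0.5 if "A" in clade else eps
            pb = 0.5 if "B" in clade else eps
            ll[branch] = stats.binom.logpmf(10, 20, pa) + stats.binom.logpmf(0, 22, pb)
        best = max(sorted(ll), key=lambda b: ll[b])
        carrying = [b for b in out.branches() if out.nodes[b].mutations]
        assert tree.clade(best) == out.clade(carrying[0])

    def test_clonal_mutation_goes_to_trunk(self):
        tree = self._two_leaf_tree()
        m = _matrix(["A", "B"], {"m": [10, 11]}, {"m": [20, 22]})
        out = assign_mutations_ml(tree, m)
        carrying = [b for b in out.branches() if out.nodes[b].mutations]
        assert out.clade(carrying[0]) == frozenset({"A", "B"})

    def test_zero_count_mutation_flagged_unassignable(self):
        tree = self._two_leaf_tree()
        m = _matrix(["A", "B"], {"m": [0, 0]}, {"m": [20, 22]})
        out = assign_mutations_ml(tree, m)
        assert sum(out.nodes[b].raw_length for b in out.branches()) == 0

    def test_epsilon_to_zero_reproduces_parsimony_placement(self):
        """On noise-free clonal counts the ML argmax equals the
        perfect-phylogeny placement for every mutation."""
        cfg = SimulationConfig(trunk_range=(10, 10), n_clones=5, private_mean=20.0, seed=3)
        tree = simulate_phylogeny(cfg)
        clones = sorted(tree.leaves)
        cols = {}
        for mid in tree.catalog.index:
            cols[str(mid)] = [mid in set(tree.path_mutations(c)) for c in clones]
        presence = pd.DataFrame(cols, index=clones)
        alt = presence.astype(int) * 15
        depth = presence.astype(int) * 0 + 30
        m = GenotypeMatrix(presence=presence, alt=alt, depth=depth)
        ptree = build_parsimony_tree(m)
        out = assign_mutations_ml(ptree, m, purity=1.0, epsilon=1e-9)
        placement = parsimony_placement(ptree, presence)
        for b in out.branches():
            for mut in out.nodes[b].mutations:
                assert placement[mut] == b

    def test_invalid_purity_rejected(self):
        tree = self._two_leaf_tree()
        m = _matrix(["A", "B"], {"m": [10, 0]}, {"m": [20, 22]})
        with pytest.raises(ValueError):
            assign_mutations_ml(tree, m, purity=1.5)


class TestBranchScaling:
    def _tree(self):
        tree = build_parsimony_tree(_presence(np.array([[1, 0], [0, 1]]), units=["A", "B"]))
        for i, b in enumerate(tree.branches()):
            tree.nodes[b].raw_length = 60.0 * (i + 1)
        return tree

    def test_zero_fraction_identity(self):
        out = scale_branches(self._tree(), 0.0)
        for b in out.branches():
            assert out.nodes[b].scaled_length == out.nodes[b].raw_length

    def test_scaling_arithmetic(self):
        out = scale_branches(self._tree(), 0.4)
        assert out.nodes[out.branches()[0]].scaled_length == pytest.approx(100.0)

    def test_one_percent_exclusion_on_a_500_trunk(self):
        tree = self._tree()
        b0 = tree.branches()[0]
        tree.nodes[b0].raw_length = 500.0
        out = scale_branches(tree, 0.01)
        assert out.nodes[b0].scaled_length == pytest.approx(505.0505050505)

    def test_ratios_conserved(self):
        tree = self._tree()
        out = scale_branches(tree, 0.37)
        bs = out.branches()
        for a in bs:
            for b in bs:
                if out.nodes[b].raw_length:
                    assert out.nodes[a].scaled_length / out.nodes[b].scaled_length == pytest.approx(
                        out.nodes[a].raw_length / out.nodes[b].raw_length
                    )

    def test_full_exclusion_rejected(self):
        with pytest.raises(ValueError):
            scale_branches(self._tree(), 1.0)
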