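"""FDSS computation: site classification, histogramming, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdss_abc.fdss import (
    CATEGORIES,
    FDSSConfig,
    FDSSVector,
    FragmentSet,
    classify_site,
    compute_fdss,
    fdss_from_genotypes,
    read_fdss,
    write_fdss,
)

from oracles import brute_force_fdss, random_fragment_instance


class TestClassifySite:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (["A", "G"], ["A", "A"], "private1"),
            (["A", "A"], ["A", "G"], "private2"),
            (["A", "A"], ["G", "G"], "fixed"),
            (["A", "G"], ["A", "G"], "shared"),
            (["A", "A"], ["A", "A"], "none"),
            ([0, 1], [1, 1], "private1"),
        ],
    )
    def test_wakeley_hey_categories(self, a, b, expected):
        assert classify_site(a, b) == expected

    def test_swapping_populations_swaps_private_categories(self):
        rng = np.random.default_rng(0)
        swap = {"private1": "private2", "private2": "private1"}
        for _ in range(100):
            a = list(rng.integers(0, 2, size=2))
            b = list(rng.integers(0, 2, size=2))
            cat = classify_site(a, b)
            assert classify_site(b, a) == swap.get(cat, cat)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 1), min_size=2, max_size=6),
        b=st.lists(st.integers(0, 1), min_size=2, max_size=6),
    )
    def test_categories_are_exhaustive_and_symmetric(self, a, b):
        """Any biallelic fully-called site gets exactly one category, and
        swapping populations swaps only the private labels."""
        cat = classify_site(a, b)
        assert cat in ("private1", "private2", "shared", "fixed", "none")
        swap = {"private1": "private2", "private2": "private1"}
        assert classify_site(b, a) == swap.get(cat, cat)
        # the four segregating categories exclude 'none' exactly when the
        # site is monomorphic-identical across both populations
        assert (cat == "none") == (len(set(a) | set(b)) == 1)

    def test_multiallelic_site_rejected(self):
        with pytest.raises(ValueError, match="two distinct alleles"):
            classify_site(["A", "C"], ["G", "G"])

    def test_missing_call_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_site([-1, 0], [0, 0])


class TestComputeFdss:
    def _single_pair_set(self, private1_counts):
        """Fragments engineered to have given per-fragment private1 counts."""
        frags = []
        for c in private1_counts:
            sites = np.zeros((c, 4), dtype=np.int64)
            sites[:, 0] = 1  # pop0 heterozygous, pop1 monomorphic ref
            frags.append(sites)
        return FragmentSet(frags, ["pop0", "pop0", "pop1", "pop1"])

    def test_private1_histogram_counts_fragments(self):
        config = FDSSConfig(max_seg_sites=5, population_order=("pop0", "pop1"))
        vec = compute_fdss(self._single_pair_set([0, 0, 2]), config)
        hist = vec.pair_histogram("pop0", "pop1", "private1")
        assert hist[0] == 2 and hist[2] == 1 and hist.sum() == 3
        assert hist[1] == 0 and hist[3:].sum() == 0

    def test_last_bin_aggregates_counts_at_or_above_cap(self):
        config = FDSSConfig(max_seg_sites=3, population_order=("pop0", "pop1"))
        vec = compute_fdss(self._single_pair_set([3, 4, 7, 1]), config)
        hist = vec.pair_histogram("pop0", "pop1", "private1")
        assert hist[3] == 3  # the >= cap tail: counts 3, 4 and 7
        assert hist[1] == 1

    def test_empty_fragment_set_rejected(self):
        config = FDSSConfig(max_seg_sites=3, population_order=("pop0", "pop1"))
        with pytest.raises(ValueError, match="empty"):
            compute_fdss(FragmentSet([], ["pop0", "pop0", "pop1", "pop1"]), config)

    def test_absent_population_named_in_error(self):
        config = FDSSConfig(max_seg_sites=3, population_order=("pop0", "popX"))
        fs = FragmentSet([np.zeros((1, 4), dtype=int)], ["pop0", "pop0", "pop1", "pop1"])
        with pytest.raises(KeyError, match="popX"):
            compute_fdss(fs, config)

    def test_vector_length_matches_layout(self):
        config = FDSSConfig()  # 6 populations, cap 100
        assert config.vector_length == 15 * 4 * 101 == 6060

    def test_conservation_and_determinism(self):
        rng = np.random.default_rng(7)
        frags, pops, order = random_fragment_instance(rng, n_pops=3, n_fragments=40)
        config = FDSSConfig(max_seg_sites=4, population_order=order)
        v1 = compute_fdss(FragmentSet(list(frags), pops), config)
        v2 = compute_fdss(FragmentSet(list(frags), pops), config)
        assert np.array_equal(v1.flat, v2.flat)
        assert (v1.counts.sum(axis=2) == 40).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pops = int(rng.integers(2, 5))
        frags, pops, order = random_fragment_instance(
            rng, n_pops=n_pops, n_fragments=30, max_sites=10,
            missing_rate=0.05, multiallelic_rate=0.05,
        )
        cap = int(rng.integers(2, 8))
        config = FDSSConfig(max_seg_sites=cap, population_order=order)
        vec = compute_fdss(FragmentSet(list(frags), pops), config)
        expected = brute_force_fdss(frags, pops, order, cap)
        assert np.array_equal(vec.counts, expected)

    def test_population_swap_symmetry(self):
        rng = np.random.default_rng(3)
        frags, pops, order = random_fragment_instance(rng, n_pops=2, n_fragments=50)
        config = FDSSConfig(max_seg_sites=6, population_order=order)
        swapped = FDSSConfig(max_seg_sites=6, population_order=order[::-1])
        v = compute_fdss(FragmentSet(list(frags), pops), config)
        w = compute_fdss(FragmentSet(list(frags), pops), swapped)
        assert np.array_equal(v.counts[0, 0], w.counts[0, 1])  # private1 <-> private2
        assert np.array_equal(v.counts[0, 1], w.counts[0, 0])
        assert np.array_equal(v.counts[0, 2], w.counts[0, 2])  # shared unchanged
        assert np.array_equal(v.counts[0, 3], w.counts[0, 3])  # fixed unchanged


class TestFdssFromGenotypes:
    def test_het_vs_homref_is_private1(self):
        config = FDSSConfig(max_seg_sites=3, population_order=("pop0", "pop1"))
        frag = np.array([[[0, 1], [0, 0]]])  # one site: pop0 0/1, pop1 0/0
        vec = fdss_from_genotypes([frag], config)
        assert vec.pair_histogram("pop0", "pop1", "private1")[1] == 1

    def test_all_homref_concentrates_at_bin_zero(self):
        config = FDSSConfig(max_seg_sites=3, population_order=("pop0", "pop1"))
        frags = [np.zeros((4, 2, 2), dtype=int) for _ in range(5)]
        vec = fdss_from_genotypes(frags, config)
        assert (vec.counts[:, :, 0] == 5).all() and (vec.counts[:, :, 1:] == 0).all()

    def test_equals_compute_fdss_on_expanded_multisets(self):
        rng = np.random.default_rng(11)
        config = FDSSConfig(max_seg_sites=5, population_order=("pop0", "pop1", "pop2"))
        geno_frags, allele_frags = [], []
        for _ in range(30):
            s = int(rng.integers(0, 6))
            g = rng.integers(0, 2, size=(s, 3, 2))
            geno_frags.append(g)
            allele_frags.append(g.reshape(s, 6).astype(np.int64))
        via_geno = fdss_from_genotypes(geno_frags, config)
        pops = [p for p in config.population_order for _ in range(2)]
        via_alleles = compute_fdss(FragmentSet(allele_frags, pops), config)
        assert np.array_equal(via_geno.flat, via_alleles.flat)

    def test_missing_genotype_drops_site(self):
        config = FDSSConfig(max_seg_sites=3, population_order=("pop0", "pop1"))
        frag = np.array([[[0, 1], [-1, 0]], [[0, 1], [0, 0]]])
        vec = fdss_from_genotypes([frag], config)
        # only the fully-called site counts
        assert vec.pair_histogram("pop0", "pop1", "private1")[1] == 1


def test_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    frags, pops, order = random_fragment_instance(rng, n_pops=2, n_fragments=25)
    config = FDSSConfig(max_seg_sites=4, population_order=order)
    vec = compute_fdss(FragmentSet(list(frags), pops), config)
    path = tmp_path / "obs.fdss"
    write_fdss(path, vec)
    back = read_fdss(path, config)
    assert np.array_equal(back.flat, vec.flat)
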