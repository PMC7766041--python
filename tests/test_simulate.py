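"""Coalescent simulation of fragments and reference tables."""

import numpy as np
import pytest

from fdss_abc.demography import SimulationConfig, toy_constant_size_model
from fdss_abc.simulate import (
    ReferenceTable,
    build_reference_table,
    default_fdss_config,
    fdss_of_fragments,
    simulate_fragments,
    simulate_one,
    simulate_table_row,
)


class TestSimulateOne:
    def test_zero_mutation_rate_concentrates_all_histograms_at_zero(self, toy_model):
        cfg = SimulationConfig(mutation_rate=1e-300)  # effectively zero
        vec = simulate_one(toy_model, {"nC": 10_000.0}, cfg, seed=3, n_fragments=50)
        assert (vec.counts[:, :, 0] == 50).all()
        assert vec.counts[:, :, 1:].sum() == 0

    def test_same_seed_same_params_identical_fdss(self, md_model):
        from fdss_abc.demography import sample_prior

        params = sample_prior(md_model, 21)
        v1 = simulate_one(md_model, params, seed=5, n_fragments=80)
        v2 = simulate_one(md_model, params, seed=5, n_fragments=80)
        assert np.array_equal(v1.flat, v2.flat)

    def test_mean_pairwise_differences_match_coalescent_expectation(self, toy_model):
        # For two chromosomes in a constant-size population the expected
        # number of nucleotide differences per fragment is 4*N*mu*L.
        cfg = SimulationConfig()
        N, L = 12_000.0, cfg.fragment_length
        n_frag = 10_000
        vec = simulate_one(toy_model, {"nC": N}, cfg, seed=17, n_fragments=n_frag)
        # differences within pop1's diploid = sites polymorphic in pop1
        # = private1 + shared of the (pop1, pop2) pair
        bins = np.arange(vec.config.n_bins)
        per_frag = (vec.counts[0, 0] + vec.counts[0, 2])  # histogram over fragments
        mean = (bins * per_frag).sum() / n_frag
        second = (bins**2 * per_frag).sum() / n_frag
        se = np.sqrt(max(second - mean**2, 1e-12) / n_frag)
        expected = 4 * N * cfg.mutation_rate * L
        assert abs(mean - expected) < 3 * se + 1e-9

    def test_mutation_paths_agree_in_distribution(self, toy_model):
        # package infinite-sites dropping vs the engine's mutation generator
        cfg = SimulationConfig()
        n = 4_000
        totals = {}
        for path in ("infinite_sites", "engine"):
            frags = simulate_fragments(
                toy_model, {"nC": 15_000.0}, cfg, seed=23, n_fragments=n, mutations=path
            )
            counts = np.array([g.shape[0] for g in frags.genotypes], dtype=float)
            totals[path] = (counts.mean(), counts.std(ddof=1) / np.sqrt(n))
        m1, se1 = totals["infinite_sites"]
        m2, se2 = totals["engine"]
        assert abs(m1 - m2) < 4 * np.hypot(se1, se2)

    def test_fdss_is_additive_over_fragment_batches(self, toy_model):
        cfg = SimulationConfig()
        fc = default_fdss_config(toy_model, max_seg_sites=10)
        a = simulate_fragments(toy_model, {"nC": 8_000.0}, cfg, seed=31, n_fragments=40)
        b = simulate_fragments(toy_model, {"nC": 8_000.0}, cfg, seed=32, n_fragments=60)
        va = fdss_of_fragments(a, fc)
        vb = fdss_of_fragments(b, fc)
        both = type(a)(
            positions=a.positions + b.positions,
            genotypes=a.genotypes + b.genotypes,
            populations=a.populations,
            fragment_length=a.fragment_length,
        )
        vab = fdss_of_fragments(both, fc)
        assert np.array_equal(vab.counts, va.counts + vb.counts)


@pytest.fixture(scope="module")
def small_table(toy_model):
    return build_reference_table(
        [toy_model], 12, SimulationConfig(), seed=9, n_fragments=25
    )


def test_divergence_between_populations_grows_with_split_time(md_model):
    """Prior-predictive sanity: with no migration, no admixture and equal
    constant sizes, the mean between-population divergence (d_xy) per
    fragment increases with the pair's split time."""
    params = {}
    for name, prior in md_model.priors.items():
        if name.startswith("n"):
            params[name] = 15_000.0
        elif name.startswith("m") or name.startswith("pa"):
            params[name] = 0.0
        elif name.startswith("r"):
            params[name] = 0.01
    # fixed, well-separated event times (years)
    params.update(
        tdEA=35_000.0, tOAbot2=45_000.0, tdOA2=50_000.0, taNEA=40_000.0,
        tdG2BE=60_000.0, taNG2=55_000.0, tdYG2=100_000.0, taBEE=20_000.0,
        tOAbot1=70_000.0, taARP=65_000.0, taD1P=65_000.0, taD2A=25_000.0,
        tdOA1=90_000.0, tdYG1=120_000.0,
    )
    vec = simulate_one(md_model, params, SimulationConfig(), seed=99, n_fragments=6000)

    def mean_dxy(p1, p2):
        bins = np.arange(vec.config.n_bins)
        priv1 = vec.pair_histogram(p1, p2, "private1") @ bins
        priv2 = vec.pair_histogram(p1, p2, "private2") @ bins
        shared = vec.pair_histogram(p1, p2, "shared") @ bins
        fixed = vec.pair_histogram(p1, p2, "fixed") @ bins
        # per-site d_xy is 1 for a fixed difference, 1/2 for any
        # polymorphic pattern with one diploid per population
        return (fixed + 0.5 * (priv1 + priv2 + shared)) / 6000

    d_ea = mean_dxy("E", "A")        # split 35 ky
    d_ye = mean_dxy("Y", "E")        # split ~100 ky (second ghost lineage)
    d_yn = mean_dxy("Y", "N")        # archaic root, 655 ky
    assert d_ea < d_ye < d_yn


class TestReferenceTable:
    def test_balanced_labels_for_two_models(self, sd_model, md_model):
        table = build_reference_table(
            [sd_model, md_model], 3, SimulationConfig(), seed=4, n_fragments=10
        )
        assert table.n_rows == 6
        assert (table.labels == "SD").sum() == (table.labels == "MD").sum() == 3

    def test_rebuild_with_same_seed_is_identical(self, toy_model, small_table):
        again = build_reference_table(
            [toy_model], 12, SimulationConfig(), seed=9, n_fragments=25
        )
        assert np.array_equal(again.stats, small_table.stats)
        assert np.array_equal(again.seeds, small_table.seeds)
        assert again.params.equals(small_table.params)

    def test_row_reproducible_from_recorded_seed(self, toy_model, small_table):
        i = 7
        params = small_table.params.iloc[i].to_dict()
        vec = simulate_one(
            toy_model, params, small_table.sim_config,
            seed=int(small_table.seeds[i]),
            fdss_config=small_table.fdss_config,
            n_fragments=small_table.n_fragments,
        )
        assert np.array_equal(vec.flat, small_table.stats[i])

    def test_save_load_round_trip(self, small_table, tmp_path):
        path = str(tmp_path / "toy.reftable")
        small_table.save(path)
        back = ReferenceTable.load(path)
        assert np.array_equal(back.stats, small_table.stats)
        assert np.array_equal(back.labels, small_table.labels)
        assert back.params.round(9).equals(small_table.params.round(9))
        assert back.fdss_config == small_table.fdss_config

    def test_subsample_keeps_per_model_counts(self, small_table):
        sub = small_table.subsample(5, rng=0)
        assert sub.n_rows == 5

    def test_rejects_invalid_row_count_request(self, toy_model):
        with pytest.raises(ValueError):
            build_reference_table([toy_model], 0, SimulationConfig(), seed=1)
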