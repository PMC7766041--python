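"""Random-forest model choice and quantile-forest estimation."""

import numpy as np
import pandas as pd
import pytest

from fdss_abc.abcrf import (
    ModelChoiceForest,
    ParameterEstimator,
    estimate_parameters,
    select_model,
    train_classifier,
)
from fdss_abc.demography import SimulationConfig
from fdss_abc.fdss import FDSSConfig
from fdss_abc.simulate import ReferenceTable


def make_table(stats, labels, params=None, cap=4, pops=("a", "b")):
    fc = FDSSConfig(max_seg_sites=cap, population_order=pops)
    assert stats.shape[1] == fc.vector_length
    n = len(labels)
    if params is None:
        params = pd.DataFrame({"x": np.zeros(n)})
    model_params = {lab: list(params.columns) for lab in set(labels)}
    return ReferenceTable(
        labels=np.asarray(labels, dtype=object),
        params=params,
        stats=stats.astype(np.int32),
        seeds=np.zeros(n, dtype=np.int64),
        fdss_config=fc,
        sim_config=SimulationConfig(),
        n_fragments=100,
        model_parameters=model_params,
    )


@pytest.fixture(scope="module")
def separable_table():
    rng = np.random.default_rng(0)
    fc = FDSSConfig(max_seg_sites=4, population_order=("a", "b"))
    n, p = 250, fc.vector_length
    x1 = rng.poisson(3.0, size=(n, p))
    x2 = rng.poisson(9.0, size=(n, p))
    return make_table(np.vstack([x1, x2]), ["M1"] * n + ["M2"] * n)


class TestModelChoice:
    def test_separable_classes_have_tiny_prior_error(self, separable_table):
        clf = train_classifier(separable_table, n_trees=200, seed=1)
        assert clf.oob_error_ <= 0.02
        assert clf.confusion_.to_numpy().sum() == separable_table.n_rows
        assert (clf.confusion_.sum(axis=1) == 250).all()

    def test_permuted_labels_give_chance_level_error(self, separable_table):
        rng = np.random.default_rng(5)
        table = make_table(
            separable_table.stats,
            list(rng.permutation(separable_table.labels)),
        )
        clf = train_classifier(table, n_trees=200, seed=2)
        assert abs(clf.oob_error_ - 0.5) <= 0.05

    def test_votes_sum_to_forest_size_and_posterior_high_inside_class(
        self, separable_table
    ):
        clf = train_classifier(separable_table, n_trees=500, seed=3)
        res = select_model(clf, separable_table.stats[10])
        assert res.n_trees == 500
        assert sum(res.votes.values()) == 500
        assert res.selected == "M1"
        assert res.posterior >= 0.95

    def test_single_label_table_rejected(self, separable_table):
        half = make_table(separable_table.stats[:250], ["M1"] * 250)
        with pytest.raises(ValueError, match="two model labels"):
            train_classifier(half, n_trees=50)

    def test_layout_mismatch_names_first_bad_column(self, separable_table):
        clf = train_classifier(separable_table, n_trees=50, seed=4)
        from fdss_abc.fdss import FDSSVector

        other = FDSSConfig(max_seg_sites=4, population_order=("a", "zz"))
        bad = FDSSVector.from_flat(separable_table.stats[0], other)
        with pytest.raises(ValueError, match="column"):
            clf.predict(bad)

    def test_oob_error_invariant_to_row_order(self, separable_table):
        rng = np.random.default_rng(9)
        perm = rng.permutation(separable_table.n_rows)
        shuffled = make_table(
            separable_table.stats[perm], list(separable_table.labels[perm])
        )
        a = train_classifier(separable_table, n_trees=300, seed=11)
        b = train_classifier(shuffled, n_trees=300, seed=11)
        # identical data, different order: OOB error agrees up to forest noise
        assert abs(a.oob_error_ - b.oob_error_) <= 0.02

    def test_posterior_monotone_in_predicted_error(self, separable_table):
        clf = train_classifier(separable_table, n_trees=100, seed=6)
        grid = separable_table.stats[::20].astype(np.float32)
        errs = np.clip(
            clf.error_forest_.predict(grid[:, clf.feature_mask_]), 0, 1
        )
        posts = np.array([r.posterior for r in clf.predict_batch(grid)])
        order = np.argsort(errs)
        assert (np.diff(posts[order]) <= 1e-12).all()


@pytest.fixture(scope="module")
def linear_response_table():
    # stats carry a noisy linear signal about the parameter
    rng = np.random.default_rng(7)
    fc = FDSSConfig(max_seg_sites=4, population_order=("a", "b"))
    n, p = 600, fc.vector_length
    y = rng.uniform(0.0, 10.0, size=n)
    stats = np.clip(rng.normal(0, 1.0, size=(n, p)) + y[:, None], 0, None).round()
    params = pd.DataFrame({"theta": y, "flat": np.full(n, 3.0)})
    return make_table(stats, ["M"] * n, params)


class TestParameterEstimation:
    def test_quantiles_weakly_increasing_and_median_inside(self, linear_response_table):
        summary, est = estimate_parameters(
            linear_response_table, linear_response_table.stats[5], n_trees=100, seed=8
        )
        row = summary.loc["theta"]
        assert row["q05"] <= row["q25"] <= row["median"] <= row["q75"] <= row["q95"]
        assert est.oob_r2_["theta"] > 0.5

    def test_constant_parameter_reported_and_skipped(self, linear_response_table):
        est = ParameterEstimator(n_trees=50, seed=9).fit(linear_response_table)
        assert np.isnan(est.oob_r2_["flat"])
        assert "flat" in est.skipped_
        summary = est.estimate(linear_response_table.stats[0])
        assert "flat" not in summary.index

    def test_estimates_track_the_signal(self, linear_response_table):
        est = ParameterEstimator(n_trees=200, seed=10).fit(linear_response_table)
        truth = linear_response_table.params["theta"].to_numpy()
        batch = est.estimate_batch(linear_response_table.stats[:50])["theta"]
        corr = np.corrcoef(batch["median"].to_numpy(), truth[:50])[0, 1]
        assert corr > 0.9

    def test_noise_statistics_recover_the_prior(self):
        # with pure-noise features the posterior quantiles approach the
        # prior's quantiles (20% tolerance of the prior width)
        rng = np.random.default_rng(11)
        fc = FDSSConfig(max_seg_sites=4, population_order=("a", "b"))
        n, p = 800, fc.vector_length
        y = rng.uniform(0.0, 10.0, size=n)
        stats = rng.poisson(5.0, size=(n, p))
        table = make_table(stats, ["M"] * n, pd.DataFrame({"theta": y}))
        est = ParameterEstimator(n_trees=200, seed=12).fit(table)
        summary = est.estimate(stats[0])
        width = 10.0
        for q, expected in (("q05", 0.5), ("q25", 2.5), ("q75", 7.5), ("q95", 9.5)):
            assert abs(summary.loc["theta", q] - expected) <= 0.2 * width

    def test_multi_model_table_rejected(self, separable_table):
        with pytest.raises(ValueError, match="single-model"):
            ParameterEstimator(n_trees=10).fit(separable_table)
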