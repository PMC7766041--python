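"""ABC random-forest model choice and parameter estimation.

Model choice is a classification problem on reference-table rows: a
random forest votes among demographic models; the prior error rate is the
out-of-bag (OOB) misclassification rate, and the posterior probability of
the selected model is obtained by regressing the OOB misclassification
indicator on the summary statistics and evaluating 1 - predicted error at
the observed point.

Parameter estimation uses one regression forest per parameter.  The
forest induces weights on the training responses (leaf co-occupancy with
the observed point, averaged over trees); posterior mean, median,
variance and quantiles are the weighted statistics of the training
parameter values (quantile-regression-forest scheme).

Split sampling follows the conventions of the standard RF ABC tooling:
sqrt(p) candidate features per split for classification, p/3 with a
minimum leaf of 5 for regression.  Columns with zero variance in the
training table carry no information and are dropped internally; the
external vector layout is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .fdss import FDSSVector
from .simulate import ReferenceTable

DEFAULT_N_TREES = 500

QUANTILES = (0.05, 0.25, 0.75, 0.95)
SUMMARY_COLUMNS = ("mean", "median", "variance", "q05", "q25", "q75", "q95")


def _as_matrix(observed) -> np.ndarray:
    if isinstance(observed, FDSSVector):
        return observed.flat[None, :].astype(np.float32)
    arr = np.asarray(observed, dtype=np.float32)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


@dataclass
class ModelChoiceResult:
    """Outcome of applying the model-choice forest to one observed vector."""

    votes: dict[str, int]
    selected: str
    posterior: float
    prior_error_rate: float
    confusion: pd.DataFrame
    tp_rate: pd.Series

    @property
    def n_trees(self) -> int:
        return int(sum(self.votes.values()))


class ModelChoiceForest:
    """Random-forest classifier over FDSS columns with OOB diagnostics."""

    def __init__(self, n_trees: int = DEFAULT_N_TREES, seed: int | None = None):
        self.n_trees = int(n_trees)
        self.seed = seed

    def fit(self, table: ReferenceTable) -> "ModelChoiceForest":
        labels = np.asarray(table.labels, dtype=object)
        classes = sorted(set(labels))
        if len(classes) < 2:
            raise ValueError("model choice requires at least two model labels")
        X = table.stats.astype(np.float32)
        self.columns_ = table.fdss_config.column_names()
        self.feature_mask_ = X.std(axis=0) > 0
        Xm = X[:, self.feature_mask_]
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            oob_score=True,
            random_state=self.seed,
            n_jobs=1,
        ).fit(Xm, labels)
        oob = self.forest_.oob_decision_function_
        # rows never out of bag (vanishingly rare at 500 trees) count as correct
        valid = ~np.isnan(oob).any(axis=1)
        pred = np.asarray(labels, dtype=object).copy()
        pred[valid] = self.forest_.classes_[np.argmax(oob[valid], axis=1)]
        miss = (pred != labels).astype(np.float64)
        self.oob_error_ = float(miss.mean())
        conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for t, p in zip(labels, pred):
            conf.loc[t, p] += 1
        self.confusion_ = conf
        self.tp_rate_ = pd.Series(
            {c: conf.loc[c, c] / conf.loc[c].sum() for c in classes}, name="tp_rate"
        )
        # posterior-probability recipe: regress the OOB misclassification
        # indicator on the statistics
        err_seed = None if self.seed is None else self.seed + 1
        self.error_forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            random_state=err_seed,
            min_samples_leaf=5,
            max_features=1.0 / 3.0,
            n_jobs=1,
        ).fit(Xm, miss)
        return self

    @property
    def prior_error_rate(self) -> float:
        return self.oob_error_

    def _check_layout(self, observed) -> np.ndarray:
        if isinstance(observed, FDSSVector):
            cols = observed.config.column_names()
            if cols != self.columns_:
                for i, (a, b) in enumerate(zip(cols, self.columns_)):
                    if a != b:
                        raise ValueError(
                            f"observed vector layout mismatch at column {i}: "
                            f"{a!r} != {b!r}"
                        )
                raise ValueError("observed vector layout mismatch: different lengths")
        X = _as_matrix(observed)
        if X.shape[1] != len(self.columns_):
            raise ValueError(
                f"observed vector has {X.shape[1]} columns; expected {len(self.columns_)}"
            )
        return X[:, self.feature_mask_]

    def predict(self, observed) -> ModelChoiceResult:
        return self.predict_batch(observed)[0]

    def predict_batch(self, observed) -> list[ModelChoiceResult]:
        X = self._check_layout(observed)
        n_obs = X.shape[0]
        tree_votes = np.stack(
            [est.predict(X) for est in self.forest_.estimators_], axis=1
        )  # (n_obs, n_trees) of encoded class indices
        proba = self.forest_.predict_proba(X)
        err = np.clip(self.error_forest_.predict(X), 0.0, 1.0)
        classes = list(self.forest_.classes_)
        results = []
        for i in range(n_obs):
            counts = {
                c: int((tree_votes[i] == k).sum()) for k, c in enumerate(classes)
            }
            top = max(counts.values())
            tied = [c for c, v in counts.items() if v == top]
            if len(tied) > 1:
                # break toward higher mean per-tree class probability, then
                # lexicographically
                best = max(tied, key=lambda c: (proba[i][classes.index(c)], ))
                tied = sorted(
                    [c for c in tied if proba[i][classes.index(c)] == proba[i][classes.index(best)]]
                )
                selected = tied[0]
            else:
                selected = tied[0]
            results.append(
                ModelChoiceResult(
                    votes=counts,
                    selected=selected,
                    posterior=float(np.clip(1.0 - err[i], 0.0, 1.0)),
                    prior_error_rate=self.oob_error_,
                    confusion=self.confusion_,
                    tp_rate=self.tp_rate_,
                )
            )
        return results


def train_classifier(
    table: ReferenceTable, n_trees: int = DEFAULT_N_TREES, seed: int | None = None
) -> ModelChoiceForest:
    """Train the model-choice forest on a reference table."""
    return ModelChoiceForest(n_trees=n_trees, seed=seed).fit(table)


def select_model(classifier: ModelChoiceForest, observed) -> ModelChoiceResult:
    """Apply a trained model-choice forest to an observed FDSS vector."""
    return classifier.predict(observed)


# ---------------------------------------------------------------------------
# parameter estimation (quantile regression forests)


class ParameterEstimator:
    """Per-parameter regression forests with QRF posterior summaries."""

    def __init__(
        self,
        n_trees: int = DEFAULT_N_TREES,
        seed: int | None = None,
        min_samples_leaf: int = 5,
        max_features: float = 1.0 / 3.0,
    ):
        self.n_trees = int(n_trees)
        self.seed = seed
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features

    def fit(
        self, table: ReferenceTable, parameters: Sequence[str] | None = None
    ) -> "ParameterEstimator":
        """Fit one regression forest per parameter (optionally a subset)."""
        if len(set(table.labels)) != 1:
            raise ValueError("parameter estimation requires a single-model table")
        X = table.stats.astype(np.float32)
        self.columns_ = table.fdss_config.column_names()
        self.feature_mask_ = X.std(axis=0) > 0
        Xm = X[:, self.feature_mask_]
        if parameters is None:
            self.parameters_ = list(table.params.columns)
        else:
            missing = set(parameters) - set(table.params.columns)
            if missing:
                raise KeyError(f"unknown parameter(s) {sorted(missing)}")
            self.parameters_ = list(parameters)
        self.train_responses_: dict[str, np.ndarray] = {}
        self.forests_: dict[str, RandomForestRegressor] = {}
        self.train_leaves_: dict[str, np.ndarray] = {}
        self.inbag_: dict[str, np.ndarray] = {}
        self.skipped_: dict[str, str] = {}
        oob_r2 = {}
        rng = np.random.default_rng(self.seed)
        for name in self.parameters_:
            y = table.params[name].to_numpy(dtype=np.float64)
            if np.isnan(y).any():
                self.skipped_[name] = "missing values in parameter column"
                oob_r2[name] = np.nan
                continue
            if np.var(y) == 0:
                self.skipped_[name] = "constant parameter column; R^2 undefined"
                oob_r2[name] = np.nan
                continue
            forest = RandomForestRegressor(
                n_estimators=self.n_trees,
                oob_score=True,
                random_state=int(rng.integers(0, 2**31)),
                min_samples_leaf=self.min_samples_leaf,
                max_features=self.max_features,
                n_jobs=1,
            ).fit(Xm, y)
            self.forests_[name] = forest
            self.train_responses_[name] = y
            leaves = forest.apply(Xm)  # (n, T)
            self.train_leaves_[name] = leaves
            # in-bag bootstrap multiplicities per tree: the QRF weight of a
            # training row is how often it occupies the observed leaf in the
            # bootstrap sample, as in the reference RF-ABC implementation
            inbag = np.zeros(leaves.shape, dtype=np.uint8)
            for t, idx in enumerate(forest.estimators_samples_):
                inbag[:, t] = np.bincount(idx, minlength=leaves.shape[0])
            self.inbag_[name] = inbag
            oob_r2[name] = float(forest.oob_score_)
        self.oob_r2_ = pd.Series(oob_r2, name="oob_r2")
        return self

    def _check_layout(self, observed) -> np.ndarray:
        X = _as_matrix(observed)
        if X.shape[1] != len(self.columns_):
            raise ValueError(
                f"observed vector has {X.shape[1]} columns; expected {len(self.columns_)}"
            )
        return X[:, self.feature_mask_]

    def _weights(self, name: str, Xm: np.ndarray) -> np.ndarray:
        """QRF weights: (n_obs, n_train), rows sum to 1.

        Per tree, a training row's weight is its bootstrap multiplicity in
        the leaf that the observed point falls into, normalised by the
        leaf's total in-bag count; rows out of bag for a tree contribute
        nothing through it.
        """
        forest = self.forests_[name]
        leaves_obs = forest.apply(Xm)  # (n_obs, T)
        leaves_train = self.train_leaves_[name]
        inbag = self.inbag_[name]
        n_train, n_trees = leaves_train.shape
        n_obs = Xm.shape[0]
        w = np.zeros((n_obs, n_train), dtype=np.float64)
        for t in range(n_trees):
            lt = leaves_train[:, t]
            order = np.argsort(lt, kind="stable")
            sorted_lt = lt[order]
            obs_leaves = leaves_obs[:, t]
            starts = np.searchsorted(sorted_lt, obs_leaves, side="left")
            ends = np.searchsorted(sorted_lt, obs_leaves, side="right")
            bag = inbag[:, t]
            for j in range(n_obs):
                members = order[starts[j] : ends[j]]
                if members.size:
                    counts = bag[members].astype(np.float64)
                    total = counts.sum()
                    if total > 0:  # every fitted leaf holds in-bag rows
                        w[j, members] += counts / (n_trees * total)
        w /= w.sum(axis=1, keepdims=True)
        return w

    def estimate_batch(self, observed) -> dict[str, pd.DataFrame]:
        """Posterior summaries for a batch of observed vectors.

        Returns ``{parameter: DataFrame(rows=observations)}`` with columns
        mean, median, variance, q05, q25, q75, q95.
        """
        Xm = self._check_layout(observed)
        out: dict[str, pd.DataFrame] = {}
        for name in self.forests_:
            y = self.train_responses_[name]
            order = np.argsort(y, kind="stable")
            y_sorted = y[order]
            w = self._weights(name, Xm)[:, order]
            cum = np.cumsum(w, axis=1)
            mean = w @ y
            var = w @ (y**2) - mean**2
            rows = {
                "mean": mean,
                "variance": np.maximum(var, 0.0),
            }
            for q in (0.5,) + QUANTILES:
                idx = np.minimum(
                    (cum < q - 1e-12).sum(axis=1), len(y_sorted) - 1
                )
                rows[f"q{q}"] = y_sorted[idx]
            df = pd.DataFrame(
                {
                    "mean": rows["mean"],
                    "median": rows["q0.5"],
                    "variance": rows["variance"],
                    "q05": rows["q0.05"],
                    "q25": rows["q0.25"],
                    "q75": rows["q0.75"],
                    "q95": rows["q0.95"],
                }
            )
            out[name] = df
        return out

    def estimate(self, observed) -> pd.DataFrame:
        """Posterior summary for one observed vector.

        DataFrame indexed by parameter with columns mean, median,
        variance, q05, q25, q75, q95 (weakly increasing quantiles).
        """
        batch = self.estimate_batch(observed)
        rows = {name: df.iloc[0] for name, df in batch.items()}
        df = pd.DataFrame(rows).T
        df.index.name = "parameter"
        return df[list(SUMMARY_COLUMNS)]


def estimate_parameters(
    table: ReferenceTable,
    observed,
    n_trees: int = DEFAULT_N_TREES,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ParameterEstimator]:
    """Fit regression forests on a single-model table and summarise the
    posterior at the observed point.  Returns (summary, fitted estimator);
    the estimator carries per-parameter OOB R^2 in ``oob_r2_``."""
    est = ParameterEstimator(n_trees=n_trees, seed=seed).fit(table)
    return est.estimate(observed), est
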