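"""Quality assessment of parameter estimation via pseudo-observed datasets.

A pods set is a collection of datasets simulated under known parameter
vectors.  Re-estimating each pod's parameters with the same machinery
used for real data yields, per parameter: the forest's OOB R^2, the
relative bias, the RMSE, the factor-2 proportion, and the 50%/90%
credible-interval coverage.  For a calibrated Bayesian procedure the
coverages approach their nominal levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abcrf import ParameterEstimator
from .demography import ModelDefinition, SimulationConfig, sample_prior
from .fdss import FDSSConfig
from .simulate import default_fdss_config, simulate_one

REPORT_COLUMNS = ("r2", "bias", "rmse", "factor2", "coverage90", "coverage50")


def relative_bias(estimates: Sequence[float], truth: Sequence[float]) -> float:
    """Mean of (estimate - truth) / truth; 1.0 means a 100% bias."""
    est = np.asarray(estimates, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("estimates and truths must be equal-length and non-empty")
    if np.any(tru == 0):
        raise ValueError("relative bias undefined for a true value of 0")
    return float(np.mean((est - tru) / tru))


def rmse(estimates: Sequence[float], truth: Sequence[float]) -> float:
    """Root mean squared error, in the parameter's units."""
    est = np.asarray(estimates, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("estimates and truths must be equal-length and non-empty")
    return float(np.sqrt(np.mean((est - tru) ** 2)))


def factor2(median_estimates: Sequence[float], truth: Sequence[float]) -> float:
    """Proportion of estimates within [truth/2, 2*truth] (inclusive)."""
    est = np.asarray(median_estimates, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("estimates and truths must be equal-length and non-empty")
    if np.any(tru <= 0):
        raise ValueError("factor 2 requires strictly positive true values")
    return float(np.mean((est >= tru / 2) & (est <= 2 * tru)))


def coverage(
    lower: Sequence[float], upper: Sequence[float], truth: Sequence[float]
) -> float:
    """Proportion of pods whose truth lies inside [lower, upper] (inclusive)."""
    lo = np.asarray(lower, dtype=np.float64)
    hi = np.asarray(upper, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    if not (lo.shape == hi.shape == tru.shape) or lo.size == 0:
        raise ValueError("interval bounds and truths must be equal-length, non-empty")
    if np.any(lo > hi):
        raise ValueError("malformed credible interval: lower > upper")
    return float(np.mean((tru >= lo) & (tru <= hi)))


@dataclass
class PodsSet:
    """Pseudo-observed datasets with their true parameter vectors."""

    model: str
    params: pd.DataFrame
    stats: np.ndarray
    seeds: np.ndarray
    fdss_config: FDSSConfig

    @property
    def n_pods(self) -> int:
        return len(self.params)


def generate_pods(
    model: ModelDefinition,
    n_pods: int,
    config: SimulationConfig = SimulationConfig(),
    seed: int = 1,
    fdss_config: FDSSConfig | None = None,
    n_fragments: int | None = None,
    truth: Mapping[str, float] | None = None,
) -> PodsSet:
    """Simulate pods under a model.

    Truths are drawn from the prior by default (so coverage is
    interpretable as calibration); passing ``truth`` repeats one known
    parameter vector for every pod instead.
    """
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    if fdss_config is None:
        fdss_config = default_fdss_config(model)
    rows = []
    stats = []
    seeds = np.zeros(n_pods, dtype=np.int64)
    for i in range(n_pods):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 1_000_003, i)))
        params = dict(truth) if truth is not None else sample_prior(model, rng)
        sim_seed = int(rng.integers(1, 2**31))
        vec = simulate_one(
            model, params, config, seed=sim_seed, fdss_config=fdss_config,
            n_fragments=n_fragments,
        )
        rows.append(params)
        stats.append(vec.flat)
        seeds[i] = sim_seed
    return PodsSet(
        model=model.name,
        params=pd.DataFrame(rows, columns=model.free_parameters),
        stats=np.vstack(stats).astype(np.int32),
        seeds=seeds,
        fdss_config=fdss_config,
    )


def quality_report(pods: PodsSet, estimator: ParameterEstimator) -> pd.DataFrame:
    """Per-parameter quality indices over a pods set.

    Point estimate for bias/RMSE/factor 2 is the posterior median; the
    50% interval is [q25, q75] and the 90% interval [q05, q95].  R^2 is
    the estimator's OOB R^2.  Parameters the estimator skipped (e.g.
    constant columns) get an all-NaN row.
    """
    summaries = estimator.estimate_batch(pods.stats)
    records = {}
    for name in pods.params.columns:
        truth = pods.params[name].to_numpy(dtype=np.float64)
        row = {c: np.nan for c in REPORT_COLUMNS}
        row["r2"] = estimator.oob_r2_.get(name, np.nan)
        if name in summaries:
            df = summaries[name]
            med = df["median"].to_numpy()
            try:
                row["bias"] = relative_bias(med, truth)
            except ValueError:
                pass
            row["rmse"] = rmse(med, truth)
            try:
                row["factor2"] = factor2(med, truth)
            except ValueError:
                pass
            row["coverage90"] = coverage(df["q05"].to_numpy(), df["q95"].to_numpy(), truth)
            row["coverage50"] = coverage(df["q25"].to_numpy(), df["q75"].to_numpy(), truth)
        records[name] = row
    report = pd.DataFrame(records).T[list(REPORT_COLUMNS)]
    report.index.name = "parameter"
    return report
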