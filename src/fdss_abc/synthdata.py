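"""Fully synthetic "observed" datasets with known truth.

Stands in for the protected real genomes: simulates fragment data under a
known parameter vector of a model, lays the fragments out on a synthetic
contig with 10-kb spacers, and emits a sorted multi-sample VCF, a BED
fragment catalog, trivial masks, a population map and a JSON truth
record.  Re-ingesting the VCF through :mod:`fdss_abc.observed_io` must
reproduce the directly computed FDSS bit-for-bit — the pipeline's
round-trip integration check.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import abcrf
from .demography import ModelDefinition, SimulationConfig, builtin_model, sample_prior
from .fdss import FDSSConfig, FDSSVector
from .observed_io import FragmentCatalog, fdss_from_vcf, write_bed
from .quality import coverage
from .simulate import (
    ReferenceTable,
    SimulatedFragments,
    build_reference_table,
    default_fdss_config,
    fdss_of_fragments,
    simulate_fragments,
)

SYNTH_CONTIG = "syn1"
FILE_DATE = "20200101"  # pinned so identical seeds give identical bytes


@dataclass
class SyntheticTruth:
    model: str
    params: dict[str, float]
    seed: int
    sim_seed: int  # engine seed actually used; re-simulation reproduces the data
    files: dict[str, str]
    n_fragments: int


def _vcf_lines(
    frags: SimulatedFragments,
    starts: np.ndarray,
    sample_names: list[str],
    contig_length: int,
):
    yield "##fileformat=VCFv4.2"
    yield f"##fileDate={FILE_DATE}"
    yield "##source=fdss_abc.synthdata"
    yield f"##contig=<ID={SYNTH_CONTIG},length={contig_length}>"
    yield '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    yield "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    for i in range(frags.n_fragments):
        for j, pos in enumerate(frags.positions[i]):
            row = frags.genotypes[i][j]
            gts = "\t".join(
                f"{row[2 * s]}/{row[2 * s + 1]}" for s in range(len(sample_names))
            )
            # REF/ALT fixed to A/G: the FDSS is allele-label agnostic
            yield (
                f"{SYNTH_CONTIG}\t{int(starts[i]) + int(pos) + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}"
            )


def make_synthetic_observed(
    model: ModelDefinition,
    params: Mapping[str, float] | str = "draw",
    config: SimulationConfig = SimulationConfig(),
    seed: int = 1,
    out_dir: str | os.PathLike = "synthetic_observed",
    n_fragments: int | None = None,
    force: bool = False,
) -> SyntheticTruth:
    """Emit VCF + BED + masks + population map + truth for one dataset."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 77)))
    if isinstance(params, str):
        if params != "draw":
            raise ValueError("params must be a mapping or 'draw'")
        params = sample_prior(model, rng)
    sim_seed = int(rng.integers(1, 2**31))
    frags = simulate_fragments(model, params, config, seed=sim_seed, n_fragments=n_fragments)
    n = frags.n_fragments
    L = config.fragment_length
    gap = 10_000
    starts = gap + np.arange(n, dtype=np.int64) * (L + gap)
    contig_length = int(starts[-1] + L + gap)
    sample_names = list(dict.fromkeys(frags.populations))

    paths = {
        "vcf": str(out / "observed.vcf"),
        "fragments": str(out / "fragments.bed"),
        "include": str(out / "callable.bed"),
        "exclude": str(out / "excluded.bed"),
        "populations": str(out / "pops.tsv"),
        "truth": str(out / "truth.json"),
    }
    with open(paths["vcf"], "w") as fh:
        for line in _vcf_lines(frags, starts, sample_names, contig_length):
            fh.write(line + "\n")
    frames = pd.DataFrame(
        {"contig": SYNTH_CONTIG, "start": starts, "end": starts + L}
    )
    write_bed(paths["fragments"], frames)
    write_bed(
        paths["include"],
        pd.DataFrame({"contig": [SYNTH_CONTIG], "start": [0], "end": [contig_length]}),
    )
    open(paths["exclude"], "w").close()  # no excluded regions on the synthetic contig
    with open(paths["populations"], "w") as fh:
        for s in sample_names:
            fh.write(f"{s}\t{s}\n")
    truth = SyntheticTruth(
        model=model.name,
        params={k: float(v) for k, v in params.items()},
        seed=int(seed),
        sim_seed=sim_seed,
        files=paths,
        n_fragments=n,
    )
    with open(paths["truth"], "w") as fh:
        json.dump(truth.__dict__, fh, indent=1)
    return truth


def ingest_synthetic(truth: SyntheticTruth, fdss_config: FDSSConfig) -> FDSSVector:
    """Re-read an emitted synthetic dataset through the observed-data path."""
    with open(truth.files["populations"]) as fh:
        pop_map = dict(line.split() for line in fh if line.strip())
    catalog = FragmentCatalog.from_bed(truth.files["fragments"], pop_map)
    return fdss_from_vcf(truth.files["vcf"], catalog, pop_map, fdss_config)


def end_to_end_check(
    seed: int,
    n_sims_per_model: int = 2_000,
    n_fragments: int = 1_000,
    n_trees: int = 500,
    config: SimulationConfig = SimulationConfig(),
    table: ReferenceTable | None = None,
    classifier: "abcrf.ModelChoiceForest | None" = None,
    n_observed: int = 1,
    true_model: str = "MD",
    key_params: tuple[str, ...] = ("nAM", "nYG"),
    estimate: bool = True,
) -> dict:
    """Self-contained pipeline check on synthetic data.

    Builds reduced SD+MD reference tables (unless ``table`` is supplied),
    draws ``n_observed`` pseudo-observed datasets under ``true_model``,
    runs model choice and (optionally) parameter estimation, and reports
    the selected model, its posterior probability, and whether the true
    values of ``key_params`` fall inside their 90% credible intervals.
    """
    sd, md = builtin_model("SD"), builtin_model("MD")
    models = {m.name: m for m in (sd, md)}
    if table is None:
        table = build_reference_table(
            [sd, md], n_sims_per_model, config, seed=seed, n_fragments=n_fragments
        )
    clf = classifier if classifier is not None else abcrf.train_classifier(
        table, n_trees=n_trees, seed=seed
    )
    gen = models[true_model]
    observations = []
    for k in range(n_observed):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 999, k)))
        params = sample_prior(gen, rng)
        frags = simulate_fragments(
            gen, params, config, seed=int(rng.integers(1, 2**31)),
            n_fragments=table.n_fragments,
        )
        observations.append((params, fdss_of_fragments(frags, table.fdss_config)))
    estimator = None
    if estimate:
        est_seed = None if seed is None else seed + 13
        estimator = abcrf.ParameterEstimator(n_trees=n_trees, seed=est_seed).fit(
            table.for_model(true_model),
            parameters=[p for p in key_params if p in table.params.columns],
        )
    results = []
    for params, vec in observations:
        choice = clf.predict(vec)
        entry = {
            "selected": choice.selected,
            "posterior": choice.posterior,
            "votes": choice.votes,
            "true_model": true_model,
            "correct": choice.selected == true_model,
        }
        if estimator is not None:
            summary = estimator.estimate(vec)
            entry["truth_in_ci90"] = {
                p: bool(
                    summary.loc[p, "q05"] <= params[p] <= summary.loc[p, "q95"]
                )
                for p in key_params
                if p in summary.index
            }
        results.append(entry)
    report = {
        "prior_error_rate": clf.oob_error_,
        "tp_rate": clf.tp_rate_.to_dict(),
        "n_observed": n_observed,
        "fraction_correct": float(np.mean([r["correct"] for r in results])),
        "fraction_correct_posterior_gt_half": float(
            np.mean([(r["correct"] and r["posterior"] > 0.5) for r in results])
        ),
        "results": results,
    }
    return report
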