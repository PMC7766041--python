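"""Coalescent simulation of fragment data and reference-table construction.

Each simulated dataset is a set of independent fragments (500 bp by
default) simulated under a demographic event list with intra-locus
recombination, summarised as an FDSS vector.  A reference table stacks
(model label, parameter vector, FDSS vector) rows for the forests.

msprime is the engine; merges are expressed as full lineage movements
(ms ``-ej`` semantics) so that ghost demes can persist after daughters
branch off.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import msprime
import numpy as np
import pandas as pd
import tskit

from .demography import (
    Divergence,
    EventList,
    MigrationChange,
    ModelDefinition,
    Pulse,
    SimulationConfig,
    SizeChange,
    build_event_list,
    sample_prior,
)
from .fdss import CATEGORIES, FDSSConfig, FDSSVector, _tally_site_categories

ENGINE = f"msprime-{msprime.__version__}"


def _now() -> str:
    import datetime

    return datetime.datetime.now().isoformat(timespec="seconds")


def event_list_to_demography(ev: EventList) -> msprime.Demography:
    """Translate an engine-agnostic event list into an msprime Demography."""
    dem = msprime.Demography()
    for init in ev.initial:
        dem.add_population(
            name=init.population, initial_size=init.size, growth_rate=init.growth_rate
        )
    for e in ev.events:
        if isinstance(e, Divergence):
            for derived in e.derived:
                dem.add_mass_migration(time=e.time, source=derived, dest=e.ancestral, proportion=1.0)
        elif isinstance(e, Pulse):
            if e.proportion > 0:
                # backward: recipient lineages move to the donor
                dem.add_mass_migration(
                    time=e.time, source=e.dest, dest=e.source, proportion=e.proportion
                )
        elif isinstance(e, MigrationChange):
            # forward donor->recipient == backward recipient->donor
            if e.time == 0:
                dem.set_migration_rate(source=e.dest, dest=e.source, rate=e.rate)
            else:
                dem.add_migration_rate_change(
                    time=e.time, rate=e.rate, source=e.dest, dest=e.source
                )
        elif isinstance(e, SizeChange):
            dem.add_population_parameters_change(
                time=e.time,
                population=e.population,
                initial_size=e.size,
                growth_rate=e.growth_rate,
            )
        else:  # pragma: no cover - exhaustive
            raise TypeError(f"unknown event {e!r}")
    dem.sort_events()
    return dem


def default_fdss_config(model: ModelDefinition, max_seg_sites: int = 100) -> FDSSConfig:
    return FDSSConfig(max_seg_sites=max_seg_sites, population_order=tuple(model.sampled))


@dataclass
class SimulatedFragments:
    """Raw per-fragment output: integer site positions and allele matrices.

    ``genotypes[f]`` has shape (sites, 2 * n_sampled_pops); chromosome
    columns follow the model's sampled-population order, two per diploid.
    Multi-allelic sites (recurrent mutation at one position) are excluded.
    """

    positions: list[np.ndarray]
    genotypes: list[np.ndarray]
    populations: list[str]
    fragment_length: int

    @property
    def n_fragments(self) -> int:
        return len(self.genotypes)


def _throw_mutations(
    ts: tskit.TreeSequence, mu: float, length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Infinite-sites mutation dropping on a simulated ancestry.

    Mutations are Poisson on total branch length per marginal tree, placed
    on branches proportionally to their length; every mutation yields one
    biallelic site (ancestral 0 / derived 1), as in ms.  Continuous
    positions are discretised to unique integers within the fragment.
    Dedicated fast path: equivalent in distribution to the engine's
    mutation generator at these per-fragment mutation rates (recurrent
    hits are negligible at theta << 1); checked against it in the tests.
    """
    n = ts.num_samples
    poss: list[float] = []
    cols: list[np.ndarray] = []
    for tree in ts.trees():
        lam = mu * tree.total_branch_length * tree.span
        k = rng.poisson(lam) if lam > 0 else 0
        if not k:
            continue
        nodes = []
        lens = []
        for u in tree.nodes():
            if tree.parent(u) != tskit.NULL:
                nodes.append(u)
                lens.append(tree.branch_length(u))
        lens_arr = np.asarray(lens)
        chosen = rng.choice(len(nodes), size=k, p=lens_arr / lens_arr.sum())
        left, right = tree.interval
        pos = rng.uniform(left, right, size=k)
        for c, x in zip(chosen, pos):
            col = np.zeros(n, dtype=np.int8)
            col[list(tree.samples(nodes[c]))] = 1
            poss.append(float(x))
            cols.append(col)
    if not poss:
        return np.zeros(0, dtype=np.int64), np.zeros((0, n), dtype=np.int8)
    order = np.argsort(poss, kind="stable")
    ipos = np.floor(np.asarray(poss)[order]).astype(np.int64)
    geno = np.vstack(cols)[order]
    for i in range(1, len(ipos)):  # unique integer positions, order kept
        if ipos[i] <= ipos[i - 1]:
            ipos[i] = ipos[i - 1] + 1
    keep = ipos < length
    return ipos[keep], geno[keep]


def simulate_fragments(
    model: ModelDefinition,
    params: Mapping[str, float],
    config: SimulationConfig = SimulationConfig(),
    seed: int = 1,
    n_fragments: int | None = None,
    sample_ages: Mapping[str, float] | None = None,
    mutations: str = "infinite_sites",
) -> SimulatedFragments:
    """Simulate independent fragments and return raw biallelic genotypes.

    ``mutations`` selects the mutation generator: ``"infinite_sites"``
    (fast path, ms semantics) or ``"engine"`` (msprime's finite-site
    generator; multi-allelic sites are then excluded).
    """
    if mutations not in ("infinite_sites", "engine"):
        raise ValueError(f"unknown mutation generator {mutations!r}")
    n = int(n_fragments if n_fragments is not None else config.n_fragments)
    ev = build_event_list(model, params, config, sample_ages=sample_ages)
    dem = event_list_to_demography(ev)
    samples = [
        msprime.SampleSet(1, population=p, time=age) for p, age in ev.sample_ages.items()
    ]
    ss = np.random.SeedSequence(seed)
    anc_seed, mut_entropy = ss.spawn(2)
    ancestry_seed = int(np.random.default_rng(anc_seed).integers(1, 2**31))
    mut_rng = np.random.default_rng(mut_entropy)
    mut_seeds = mut_rng.integers(1, 2**31, size=n) if mutations == "engine" else None
    rec = config.recombination_rate if config.intra_locus_recombination else 0.0
    replicates = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=config.fragment_length,
        recombination_rate=rec,
        num_replicates=n,
        random_seed=ancestry_seed,
    )
    positions: list[np.ndarray] = []
    genotypes: list[np.ndarray] = []
    for i, ts in enumerate(replicates):
        try:
            if mutations == "infinite_sites":
                pos, geno = _throw_mutations(
                    ts, config.mutation_rate, config.fragment_length, mut_rng
                )
            else:
                mts = msprime.sim_mutations(
                    ts, rate=config.mutation_rate, random_seed=int(mut_seeds[i])
                )
                if mts.num_sites:
                    geno = mts.genotype_matrix()
                    pos = mts.tables.sites.position.astype(np.int64)
                    biallelic = geno.max(axis=1) <= 1
                    geno = geno[biallelic]
                    pos = pos[biallelic]
                else:
                    geno = np.zeros((0, 2 * len(samples)), dtype=np.int32)
                    pos = np.zeros(0, dtype=np.int64)
        except Exception as exc:  # pragma: no cover - engine failure path
            raise RuntimeError(
                f"engine failure at fragment {i} (dataset seed {seed})"
            ) from exc
        positions.append(pos)
        genotypes.append(np.asarray(geno, dtype=np.int8))
    return SimulatedFragments(
        positions=positions,
        genotypes=genotypes,
        populations=[p for p in ev.sample_ages for _ in range(2)],
        fragment_length=config.fragment_length,
    )


def fdss_of_fragments(frags: SimulatedFragments, fdss_config: FDSSConfig) -> FDSSVector:
    """FDSS of simulated fragments (vectorised fast path)."""
    order = list(fdss_config.population_order)
    pop_cols = []
    pops = np.asarray(frags.populations, dtype=object)
    for p in order:
        cols = np.flatnonzero(pops == p)
        if cols.size == 0:
            raise KeyError(f"population {p!r} not present in simulated data")
        pop_cols.append(cols)
    pairs_idx = [
        (order.index(a), order.index(b)) for a, b in fdss_config.pair_list
    ]
    sizes = [g.shape[0] for g in frags.genotypes]
    alleles = (
        np.concatenate(frags.genotypes, axis=0).astype(np.int64)
        if frags.n_fragments
        else np.zeros((0, len(pops)), dtype=np.int64)
    )
    frag_idx = np.repeat(np.arange(frags.n_fragments), sizes)
    counts = _tally_site_categories(
        alleles, frag_idx, pop_cols, pairs_idx, frags.n_fragments, fdss_config.max_seg_sites
    )
    return FDSSVector(counts, fdss_config)


def simulate_one(
    model: ModelDefinition,
    params: Mapping[str, float],
    config: SimulationConfig = SimulationConfig(),
    seed: int = 1,
    fdss_config: FDSSConfig | None = None,
    n_fragments: int | None = None,
) -> FDSSVector:
    """Simulate one dataset under ``params`` and summarise it as an FDSS."""
    if fdss_config is None:
        fdss_config = default_fdss_config(model)
    frags = simulate_fragments(model, params, config, seed=seed, n_fragments=n_fragments)
    return fdss_of_fragments(frags, fdss_config)


# ---------------------------------------------------------------------------
# reference tables


@dataclass
class ReferenceTable:
    """Rows of (model label, parameter vector, FDSS vector).

    ``params`` holds the union of parameter columns over models; entries
    are NaN for parameters a model does not have.
    """

    labels: np.ndarray
    params: pd.DataFrame
    stats: np.ndarray
    seeds: np.ndarray
    fdss_config: FDSSConfig
    sim_config: SimulationConfig
    n_fragments: int
    engine: str = ENGINE
    model_parameters: dict[str, list[str]] = field(default_factory=dict)
    master_seed: int | None = None
    created: str = ""  # timestamp; informational only, excluded from identity

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.params) == self.stats.shape[0] == len(self.seeds) == n):
            raise ValueError("inconsistent row counts in reference table")
        if self.stats.shape[1] != self.fdss_config.vector_length:
            raise ValueError("stats width does not match the FDSS layout")

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    @property
    def model_labels(self) -> list[str]:
        return sorted(set(self.labels))

    def for_model(self, label: str) -> "ReferenceTable":
        mask = self.labels == label
        if not mask.any():
            raise KeyError(f"no rows for model {label!r}")
        cols = self.model_parameters.get(label, list(self.params.columns))
        return ReferenceTable(
            labels=self.labels[mask],
            params=self.params.loc[mask, cols].reset_index(drop=True),
            stats=self.stats[mask],
            seeds=self.seeds[mask],
            fdss_config=self.fdss_config,
            sim_config=self.sim_config,
            n_fragments=self.n_fragments,
            engine=self.engine,
            model_parameters={label: cols},
        )

    def subsample(self, n_per_model: int, rng: np.random.Generator | int) -> "ReferenceTable":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        keep: list[np.ndarray] = []
        for label in self.model_labels:
            idx = np.flatnonzero(self.labels == label)
            if len(idx) < n_per_model:
                raise ValueError(f"model {label} has only {len(idx)} rows")
            keep.append(rng.choice(idx, size=n_per_model, replace=False))
        sel = np.sort(np.concatenate(keep))
        return ReferenceTable(
            labels=self.labels[sel],
            params=self.params.iloc[sel].reset_index(drop=True),
            stats=self.stats[sel],
            seeds=self.seeds[sel],
            fdss_config=self.fdss_config,
            sim_config=self.sim_config,
            n_fragments=self.n_fragments,
            engine=self.engine,
            model_parameters=dict(self.model_parameters),
        )

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Delimited table (one header + one row per simulation) + JSON sidecar."""
        param_cols = list(self.params.columns)
        with open(path, "w") as fh:
            header = ["model", "seed"] + [f"p:{c}" for c in param_cols] + [
                f"s:{c}" for c in self.fdss_config.column_names()
            ]
            fh.write("\t".join(header) + "\n")
            for i in range(self.n_rows):
                row = [str(self.labels[i]), str(int(self.seeds[i]))]
                row += [repr(v) for v in self.params.iloc[i].tolist()]
                row += [str(int(v)) for v in self.stats[i]]
                fh.write("\t".join(row) + "\n")
        meta = {
            "engine": self.engine,
            "n_fragments": self.n_fragments,
            "fdss_config": {
                "max_seg_sites": self.fdss_config.max_seg_sites,
                "population_order": list(self.fdss_config.population_order),
            },
            "sim_config": self.sim_config.__dict__,
            "model_parameters": self.model_parameters,
            "master_seed": self.master_seed,
            "created": self.created or _now(),
        }
        with open(path + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "ReferenceTable":
        with open(path + ".meta.json") as fh:
            meta = json.load(fh)
        fdss_config = FDSSConfig(
            max_seg_sites=meta["fdss_config"]["max_seg_sites"],
            population_order=tuple(meta["fdss_config"]["population_order"]),
        )
        sim_config = SimulationConfig(**meta["sim_config"])
        df = pd.read_csv(path, sep="\t")
        param_cols = [c for c in df.columns if c.startswith("p:")]
        stat_cols = [c for c in df.columns if c.startswith("s:")]
        return cls(
            labels=df["model"].to_numpy(dtype=object),
            params=df[param_cols].rename(columns=lambda c: c[2:]),
            stats=df[stat_cols].to_numpy(dtype=np.int32),
            seeds=df["seed"].to_numpy(dtype=np.int64),
            fdss_config=fdss_config,
            sim_config=sim_config,
            n_fragments=meta["n_fragments"],
            engine=meta["engine"],
            model_parameters={k: list(v) for k, v in meta["model_parameters"].items()},
            master_seed=meta.get("master_seed"),
            created=meta.get("created", ""),
        )


def _row_seed(master_seed: int, model_index: int, row_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=(int(master_seed), model_index, row_index))


def simulate_table_row(
    model: ModelDefinition,
    config: SimulationConfig,
    fdss_config: FDSSConfig,
    master_seed: int,
    model_index: int,
    row_index: int,
    n_fragments: int,
) -> tuple[dict[str, float], int, np.ndarray]:
    """One reference-table row; fully determined by (seed, model, row)."""
    rng = np.random.default_rng(_row_seed(master_seed, model_index, row_index))
    params = sample_prior(model, rng)
    sim_seed = int(rng.integers(1, 2**31))
    vec = simulate_one(
        model, params, config, seed=sim_seed, fdss_config=fdss_config, n_fragments=n_fragments
    )
    return params, sim_seed, vec.flat


def build_reference_table(
    models: Sequence[ModelDefinition],
    n_sims_per_model: int,
    config: SimulationConfig = SimulationConfig(),
    seed: int = 1,
    fdss_config: FDSSConfig | None = None,
    n_fragments: int | None = None,
    out: str | None = None,
    workers: int = 1,
) -> ReferenceTable:
    """Build a reference table by prior-predictive simulation.

    Row ``j`` of model ``i`` is generated from the seed sequence
    ``(seed, i, j)``, so the table is reproducible row-by-row and
    independent of the number of workers.  With ``out`` set, rows are
    flushed to disk incrementally.
    """
    if n_sims_per_model < 1:
        raise ValueError("n_sims_per_model must be >= 1")
    if fdss_config is None:
        fdss_config = default_fdss_config(models[0])
    nf = int(n_fragments if n_fragments is not None else config.n_fragments)
    jobs = [
        (mi, ri) for mi, m in enumerate(models) for ri in range(n_sims_per_model)
    ]
    all_cols: list[str] = []
    for m in models:
        all_cols += [c for c in m.free_parameters if c not in all_cols]
    model_parameters = {m.name: list(m.free_parameters) for m in models}
    sink = None
    if out is not None:
        # metadata first, then rows flushed as they are computed, so a
        # partial table on disk is always a valid (shorter) table
        meta = {
            "engine": ENGINE,
            "n_fragments": nf,
            "fdss_config": {
                "max_seg_sites": fdss_config.max_seg_sites,
                "population_order": list(fdss_config.population_order),
            },
            "sim_config": config.__dict__,
            "model_parameters": model_parameters,
            "master_seed": int(seed),
            "created": _now(),
        }
        with open(out + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        sink = open(out, "w")
        header = ["model", "seed"] + [f"p:{c}" for c in all_cols] + [
            f"s:{c}" for c in fdss_config.column_names()
        ]
        sink.write("\t".join(header) + "\n")

    def emit(mi: int, row) -> None:
        if sink is None:
            return
        params_d, sim_seed, flat = row
        fields = [models[mi].name, str(sim_seed)]
        fields += [repr(params_d.get(c, np.nan)) for c in all_cols]
        fields += [str(int(v)) for v in flat]
        sink.write("\t".join(fields) + "\n")
        sink.flush()

    try:
        if workers > 1:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=workers)(
                delayed(simulate_table_row)(
                    models[mi], config, fdss_config, seed, mi, ri, nf
                )
                for mi, ri in jobs
            )
            for (mi, _), r in zip(jobs, results):
                emit(mi, r)
        else:
            results = []
            for mi, ri in jobs:
                r = simulate_table_row(models[mi], config, fdss_config, seed, mi, ri, nf)
                results.append(r)
                emit(mi, r)
    finally:
        if sink is not None:
            sink.close()
    labels = np.array([models[mi].name for mi, _ in jobs], dtype=object)
    seeds = np.array([r[1] for r in results], dtype=np.int64)
    stats = np.vstack([r[2] for r in results]).astype(np.int32)
    params = pd.DataFrame(
        [{c: r[0].get(c, np.nan) for c in all_cols} for r in results], columns=all_cols
    )
    return ReferenceTable(
        labels=labels,
        params=params,
        stats=stats,
        seeds=seeds,
        fdss_config=fdss_config,
        sim_config=config,
        n_fragments=nf,
        engine=ENGINE,
        model_parameters=model_parameters,
        master_seed=int(seed),
    )
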