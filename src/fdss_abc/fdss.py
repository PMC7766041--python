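"""Frequency Distribution of Segregating Sites (FDSS).

For every unordered pair of populations, each biallelic site falls into one
of four mutually exclusive categories (Wakeley–Hey): private to the first
population, private to the second, shared polymorphism, or fixed
difference.  The FDSS summarises a collection of independent genomic
fragments as, per pair and category, the histogram over fragments of the
number of sites in that category, truncated at a configurable cap.

The flattened vector layout is pair-major, category-second, bin-minor, so
observed and simulated vectors align column-for-column for the random
forests downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: category order used everywhere in the package
CATEGORIES = ("private1", "private2", "shared", "fixed")

#: canonical population order for the out-of-Africa analyses
DEFAULT_POPULATION_ORDER = (
    "Neandertal", "Denisova", "African", "European", "Asian", "Papuan",
)

MISSING = -1


@dataclass(frozen=True)
class FDSSConfig:
    """Layout of the FDSS vector.

    Parameters
    ----------
    max_seg_sites
        Histogram cap ``n``: bins 0..n-1 count fragments with exactly that
        many sites of a category, the last bin (index n) aggregates all
        fragments with >= n sites.
    population_order
        Canonical ordering of population labels; the pair list is all
        unordered pairs in lexicographic-by-index order.
    """

    max_seg_sites: int = 100
    population_order: tuple[str, ...] = DEFAULT_POPULATION_ORDER

    def __post_init__(self) -> None:
        if self.max_seg_sites < 1:
            raise ValueError("max_seg_sites must be >= 1")
        if len(set(self.population_order)) != len(self.population_order):
            raise ValueError("population_order contains duplicates")
        object.__setattr__(self, "population_order", tuple(self.population_order))

    @property
    def pair_list(self) -> tuple[tuple[str, str], ...]:
        return tuple(itertools.combinations(self.population_order, 2))

    @property
    def n_bins(self) -> int:
        return self.max_seg_sites + 1

    @property
    def vector_length(self) -> int:
        return len(self.pair_list) * len(CATEGORIES) * self.n_bins

    def column_names(self) -> list[str]:
        """Column labels of the flattened vector, ``pair|category|bin``."""
        return [
            f"{a}-{b}|{cat}|{b_idx}"
            for (a, b) in self.pair_list
            for cat in CATEGORIES
            for b_idx in range(self.n_bins)
        ]


@dataclass
class FragmentSet:
    """Haplotype fragments: one allele matrix (sites x chromosomes) each.

    Allele codes are small non-negative integers; ``MISSING`` (-1) marks an
    uncalled allele.  All fragments share the same chromosome columns, and
    ``populations[c]`` labels the population of chromosome column ``c``.
    """

    fragments: list[np.ndarray]
    populations: Sequence[str]
    fragment_length: int = 500

    def __post_init__(self) -> None:
        self.populations = list(self.populations)
        counts: dict[str, int] = {}
        for p in self.populations:
            counts[p] = counts.get(p, 0) + 1
        for p, c in counts.items():
            if c < 2 or c % 2:
                raise ValueError(
                    f"population {p!r} contributes {c} chromosomes; "
                    "an even number >= 2 is required"
                )
        n_chrom = len(self.populations)
        for i, frag in enumerate(self.fragments):
            frag = np.asarray(frag)
            if frag.ndim != 2 or frag.shape[1] != n_chrom:
                raise ValueError(
                    f"fragment {i} has shape {frag.shape}; expected (sites, {n_chrom})"
                )
            self.fragments[i] = frag

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def columns_for(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations, dtype=object) == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present in fragment set")
        return idx


@dataclass
class FDSSVector:
    """FDSS histograms: array of shape (n_pairs, 4, max_seg_sites + 1)."""

    counts: np.ndarray
    config: FDSSConfig

    def __post_init__(self) -> None:
        expected = (len(self.config.pair_list), len(CATEGORIES), self.config.n_bins)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")

    @property
    def flat(self) -> np.ndarray:
        return self.counts.reshape(-1)

    @property
    def n_fragments(self) -> int:
        return int(self.counts[0, 0].sum())

    def pair_histogram(self, pop1: str, pop2: str, category: str) -> np.ndarray:
        pair = (pop1, pop2)
        swapped = False
        if pair not in self.config.pair_list:
            pair = (pop2, pop1)
            swapped = True
            if pair not in self.config.pair_list:
                raise KeyError(f"pair {pop1}/{pop2} not in configuration")
        if swapped and category in ("private1", "private2"):
            category = "private2" if category == "private1" else "private1"
        return self.counts[self.config.pair_list.index(pair), CATEGORIES.index(category)]

    def to_row(self) -> str:
        return " ".join(str(int(v)) for v in self.flat)

    @classmethod
    def from_flat(cls, values: np.ndarray, config: FDSSConfig) -> "FDSSVector":
        arr = np.asarray(values, dtype=np.int64).reshape(
            len(config.pair_list), len(CATEGORIES), config.n_bins
        )
        return cls(arr, config)


def write_fdss(path, vector: FDSSVector) -> None:
    """One whitespace-delimited data row with a header naming each column."""
    with open(path, "w") as fh:
        fh.write(" ".join(vector.config.column_names()) + "\n")
        fh.write(vector.to_row() + "\n")


def read_fdss(path, config: FDSSConfig) -> FDSSVector:
    with open(path) as fh:
        header = fh.readline().split()
        if header != config.column_names():
            raise ValueError("FDSS file header does not match the configuration layout")
        values = np.array(fh.readline().split(), dtype=np.int64)
    return FDSSVector.from_flat(values, config)


def classify_site(alleles_pop1: Sequence, alleles_pop2: Sequence) -> str:
    """Classify one biallelic site for a pair of populations.

    Returns one of ``private1``, ``private2``, ``shared``, ``fixed`` or
    ``none`` (monomorphic for the same allele in both — not segregating).
    Raises ``ValueError`` for missing calls or more than two distinct
    alleles across the two populations.
    """
    a1 = list(alleles_pop1)
    a2 = list(alleles_pop2)
    if len(a1) < 2 or len(a2) < 2:
        raise ValueError("each population needs at least two called alleles")
    if MISSING in a1 or MISSING in a2 or None in a1 or None in a2:
        raise ValueError("missing call at site")
    if len(set(a1) | set(a2)) > 2:
        raise ValueError("more than two distinct alleles at site")
    poly1 = len(set(a1)) > 1
    poly2 = len(set(a2)) > 1
    if poly1 and poly2:
        return "shared"
    if poly1:
        return "private1"
    if poly2:
        return "private2"
    return "fixed" if a1[0] != a2[0] else "none"


def _tally_site_categories(
    alleles: np.ndarray,
    frag_idx: np.ndarray,
    pop_columns: list[np.ndarray],
    pairs_idx: list[tuple[int, int]],
    n_fragments: int,
    cap: int,
) -> np.ndarray:
    """Vectorised per-site classification and per-fragment histogramming.

    ``alleles``: (total sites, chromosomes) allele codes with -1 missing,
    ``frag_idx``: fragment index of each site row.  Sites with any missing
    call or more than two distinct alleles overall are excluded entirely.
    """
    n_pairs = len(pairs_idx)
    out = np.zeros((n_pairs, len(CATEGORIES), cap + 1), dtype=np.int64)
    if alleles.shape[0]:
        called = (alleles >= 0).all(axis=1)
        # biallelic across all chromosomes: at most two distinct codes
        lo = np.where(called, alleles.min(axis=1, initial=np.iinfo(np.int64).max, where=alleles >= 0), 0)
        hi = alleles.max(axis=1)
        mid = np.logical_and(alleles != lo[:, None], alleles != hi[:, None]).any(axis=1)
        keep = called & ~mid
        alleles = alleles[keep]
        frag_idx = frag_idx[keep]
    for k, (i, j) in enumerate(pairs_idx):
        a = alleles[:, pop_columns[i]]
        b = alleles[:, pop_columns[j]]
        poly_a = a.max(axis=1) != a.min(axis=1) if a.size else np.zeros(0, bool)
        poly_b = b.max(axis=1) != b.min(axis=1) if b.size else np.zeros(0, bool)
        cat = np.full(a.shape[0], -1, dtype=np.int8)
        cat[poly_a & ~poly_b] = 0
        cat[~poly_a & poly_b] = 1
        cat[poly_a & poly_b] = 2
        fixed = ~poly_a & ~poly_b & (a[:, 0] != b[:, 0]) if a.size else np.zeros(0, bool)
        cat[fixed] = 3
        for c in range(len(CATEGORIES)):
            per_frag = np.bincount(frag_idx[cat == c], minlength=n_fragments)
            out[k, c] = np.bincount(np.minimum(per_frag, cap), minlength=cap + 1)
    return out


def compute_fdss(data: FragmentSet, config: FDSSConfig) -> FDSSVector:
    """Compute the FDSS of a fragment set.

    Every per-pair, per-category histogram sums to ``data.n_fragments``
    (fragments with no site of a category fall in bin 0).
    """
    if data.n_fragments == 0:
        raise ValueError("empty fragment set")
    pop_columns = []
    for pop in config.population_order:
        pop_columns.append(data.columns_for(pop))  # KeyError names the population
    pairs_idx = [
        (config.population_order.index(a), config.population_order.index(b))
        for a, b in config.pair_list
    ]
    n_chrom = len(data.populations)
    if data.n_fragments:
        sizes = [f.shape[0] for f in data.fragments]
        alleles = (
            np.concatenate([f for f in data.fragments], axis=0)
            if sum(sizes)
            else np.zeros((0, n_chrom), dtype=np.int64)
        )
        frag_idx = np.repeat(np.arange(data.n_fragments), sizes)
    counts = _tally_site_categories(
        np.asarray(alleles, dtype=np.int64),
        frag_idx,
        pop_columns,
        pairs_idx,
        data.n_fragments,
        config.max_seg_sites,
    )
    return FDSSVector(counts, config)


def fdss_from_genotypes(
    genotype_fragments: Sequence[np.ndarray],
    config: FDSSConfig,
    fragment_length: int = 500,
) -> FDSSVector:
    """FDSS from unphased diploid genotypes, one individual per population.

    ``genotype_fragments``: per fragment, an array of shape
    (sites, n_populations, 2) of allele codes in ``config.population_order``
    order, with -1 for a missing allele call.  With a single diploid per
    population "polymorphic" is simply "heterozygous", so the result equals
    :func:`compute_fdss` on the implied two-chromosome multisets; phase is
    never consulted.  Sites with any missing call are dropped from the
    fragment's tally.
    """
    n_pops = len(config.population_order)
    expanded = []
    for frag in genotype_fragments:
        frag = np.asarray(frag)
        if frag.ndim != 3 or frag.shape[1:] != (n_pops, 2):
            raise ValueError(
                f"genotype fragment has shape {frag.shape}; expected (sites, {n_pops}, 2)"
            )
        expanded.append(frag.reshape(frag.shape[0], n_pops * 2))
    populations = [p for p in config.population_order for _ in range(2)]
    return compute_fdss(
        FragmentSet(expanded, populations, fragment_length=fragment_length), config
    )
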