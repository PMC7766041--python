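"""Observed-data path: neutral fragment selection and FDSS from VCF.

The study design extracts independent 500-bp fragments, separated by at
least 10 kb, lying outside excluded regions (genes padded by 10 kb, CpG
islands, repeats) and inside an optional callability mask, then computes
the observed FDSS from fully-called biallelic SNP genotypes of one
diploid individual per population.

All interval logic is 0-based half-open; BED is read natively and VCF
positions are converted from 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .fdss import FDSSConfig, FDSSVector, _tally_site_categories

BED_COLUMNS = ["contig", "start", "end"]


def read_bed(path) -> pd.DataFrame:
    """Read the first three BED columns (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=BED_COLUMNS,
        dtype={0: str, 1: np.int64, 2: np.int64},
    )
    return df


def write_bed(path, intervals: pd.DataFrame) -> None:
    intervals[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) intervals (one contig)."""
    if len(intervals) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    iv = intervals[np.argsort(intervals[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def subtract_intervals(base: np.ndarray, cut: np.ndarray) -> np.ndarray:
    """Set difference base \\ cut for merged interval arrays (one contig)."""
    out = []
    for s, e in base:
        cur = s
        for cs, ce in cut:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((cur, min(cs, e)))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64) if out else np.zeros((0, 2), dtype=np.int64)


@dataclass
class FragmentCatalog:
    """Genomic coordinates of the selected fragments (0-based half-open)."""

    fragments: pd.DataFrame  # columns contig, start, end
    sample_populations: dict[str, str] = field(default_factory=dict)
    masks_applied: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fragments = self.fragments.reset_index(drop=True)[BED_COLUMNS]

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def to_bed(self, path) -> None:
        write_bed(path, self.fragments)

    @classmethod
    def from_bed(cls, path, sample_populations: Mapping[str, str] | None = None):
        return cls(read_bed(path), dict(sample_populations or {}))


def select_fragments(
    contig_lengths: Mapping[str, int],
    exclusion_masks: Sequence[pd.DataFrame] = (),
    inclusion_mask: pd.DataFrame | None = None,
    n: int = 10_000,
    fragment_length: int = 500,
    gap: int = 10_000,
    seed: int = 0,
) -> FragmentCatalog:
    """Greedy left-to-right fragment placement with a randomized offset.

    Fragments lie fully inside the inclusion mask (if given), fully
    outside the union of exclusion masks, and pairwise separated by at
    least ``gap`` bp.  Deterministic given ``seed``.  If fewer than ``n``
    qualifying fragments exist, all found are returned with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for contig, length in contig_lengths.items():
        base = np.array([[0, int(length)]], dtype=np.int64)
        if inclusion_mask is not None:
            inc = inclusion_mask[inclusion_mask["contig"] == contig][["start", "end"]]
            base = merge_intervals(inc.to_numpy(dtype=np.int64))
            base = subtract_intervals(
                base, np.array([[length, np.iinfo(np.int64).max]], dtype=np.int64)
            )
        cut = [
            m[m["contig"] == contig][["start", "end"]].to_numpy(dtype=np.int64)
            for m in exclusion_masks
        ]
        cut_merged = merge_intervals(
            np.concatenate(cut) if cut else np.zeros((0, 2), dtype=np.int64)
        )
        allowed = subtract_intervals(base, cut_merged)
        next_start = int(rng.integers(0, fragment_length + gap))
        for s, e in allowed:
            pos = max(int(s), next_start)
            while pos + fragment_length <= e:
                rows.append((contig, pos, pos + fragment_length))
                pos += fragment_length + gap
                next_start = pos
                if len(rows) >= n:
                    break
            if len(rows) >= n:
                break
        if len(rows) >= n:
            break
    if len(rows) < n:
        warnings.warn(
            f"only {len(rows)} qualifying fragments found (requested {n}); "
            "FDSS histograms will sum to the reduced count"
        )
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    return FragmentCatalog(df, masks_applied=[f"{len(exclusion_masks)} exclusion mask(s)"])


def fdss_from_vcf(
    vcf_path,
    catalog: FragmentCatalog,
    population_map: Mapping[str, str],
    config: FDSSConfig,
) -> FDSSVector:
    """Observed FDSS from a sorted VCF and a fragment catalog.

    Only biallelic SNPs with complete diploid calls in every mapped
    sample are counted; indels and multi-allelic records are ignored and
    sites with any missing or half-called genotype are dropped site-wise.
    One diploid sample per population is required.
    """
    vcf = VCF(str(vcf_path))
    by_pop: dict[str, str] = {}
    for sample, pop in population_map.items():
        if sample not in vcf.samples:
            raise ValueError(f"sample {sample!r} not present in {vcf_path}")
        if pop in by_pop:
            raise ValueError(f"population {pop!r} mapped to more than one sample")
        by_pop[pop] = sample
    missing_pops = [p for p in config.population_order if p not in by_pop]
    if missing_pops:
        raise ValueError(f"no sample mapped for population(s) {missing_pops}")
    sample_idx = [vcf.samples.index(by_pop[p]) for p in config.population_order]

    frames = catalog.fragments
    frag_per_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for contig, grp in frames.groupby("contig", sort=False):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        frag_per_contig[str(contig)] = (
            grp["start"].to_numpy()[order],
            grp["end"].to_numpy()[order],
            grp.index.to_numpy()[order],
        )

    site_rows: list[np.ndarray] = []
    site_frag: list[int] = []
    last_pos: dict[str, int] = {}
    for variant in vcf:
        contig = variant.CHROM
        pos0 = variant.POS - 1  # VCF is 1-based
        if last_pos.get(contig, -1) > pos0:
            raise ValueError(f"VCF not sorted at {contig}:{variant.POS}")
        last_pos[contig] = pos0
        if contig not in frag_per_contig:
            continue
        starts, ends, idx = frag_per_contig[contig]
        k = int(np.searchsorted(starts, pos0, side="right")) - 1
        if k < 0 or pos0 >= ends[k]:
            continue
        if not variant.is_snp or len(variant.ALT) != 1:
            continue
        gts = variant.genotypes  # [[a, b, phased], ...]
        alleles = np.empty(2 * len(sample_idx), dtype=np.int64)
        ok = True
        for c, si in enumerate(sample_idx):
            a, b = gts[si][0], gts[si][1]
            if a < 0 or b < 0:
                ok = False
                break
            alleles[2 * c] = a
            alleles[2 * c + 1] = b
        if not ok:
            continue
        site_rows.append(alleles)
        site_frag.append(int(idx[k]))

    n_chrom = 2 * len(config.population_order)
    alleles_mat = (
        np.vstack(site_rows) if site_rows else np.zeros((0, n_chrom), dtype=np.int64)
    )
    frag_idx = np.asarray(site_frag, dtype=np.int64)
    pop_cols = [np.array([2 * i, 2 * i + 1]) for i in range(len(config.population_order))]
    pairs_idx = [
        (config.population_order.index(a), config.population_order.index(b))
        for a, b in config.pair_list
    ]
    counts = _tally_site_categories(
        alleles_mat, frag_idx, pop_cols, pairs_idx, catalog.n_fragments, config.max_seg_sites
    )
    return FDSSVector(counts, config)
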